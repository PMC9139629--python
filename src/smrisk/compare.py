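"""Cohort-level paired comparison of treatment modalities.

Per-patient metrics are computed organ by organ with both risk models,
then each (organ, metric) cell is summarized as median (min-max) per
modality with two-tailed Wilcoxon signed-rank p-values for the three
modality pairs.  P-values are reported raw, one per cell, without
multiple-testing correction.

The signed-rank test here is exact (full permutation distribution of the
rank sum, computed by convolution, valid with midranks for ties) whenever
the number of non-zero within-patient differences is small, and switches
to the tie-corrected normal approximation above ``exact_threshold``.
Zero differences are dropped before ranking (the classical convention);
if every difference is zero the comparison is flagged and p = 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Mapping, NamedTuple, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CohortPlanSet
from .dasu import DasuOrganParams, dasu_risk, default_dasu_registry, lookup_organ
from .errors import PairingError, ValidationError
from .schneider import (
    SchneiderOrganParams,
    default_schneider_registry,
    schneider_risk,
)

__all__ = [
    "METRICS",
    "MODALITY_PAIRS",
    "WilcoxonResult",
    "ComparisonTable",
    "evaluate_cohort",
    "wilcoxon_paired",
    "build_comparison_table",
]

#: metric columns of the per-patient table entering the comparison
METRICS = ("dasu_total_pct", "dasu_fatal_pct", "schneider_incidence")

#: pairwise contrasts, in report column order
MODALITY_PAIRS = (("PBS", "3DCRT"), ("PBS", "IMRT"), ("IMRT", "3DCRT"))

DEFAULT_EXACT_THRESHOLD = 25


class WilcoxonResult(NamedTuple):
    statistic: float  # W+: rank sum of positive differences
    p_value: float  # two-tailed
    n_used: int  # pairs remaining after zero-difference removal
    method: str  # "exact", "approx" or "degenerate"
    all_zero: bool


def evaluate_cohort(
    cohort: CohortPlanSet,
    dasu_registry: Optional[Mapping[str, DasuOrganParams]] = None,
    schneider_registry: Optional[Mapping[str, SchneiderOrganParams]] = None,
    incidence_form: str = "as_printed",
) -> pd.DataFrame:
    """Evaluate both risk models on every (patient, modality, organ) cell.

    Returns a tidy DataFrame with columns ``patient_id, modality, organ,
    dasu_total_pct, dasu_fatal_pct, oed_gy, schneider_incidence``.
    """
    cohort.validate()
    dasu_registry = dasu_registry or default_dasu_registry()
    schneider_registry = schneider_registry or default_schneider_registry()
    rows = []
    for pid in cohort.patients:
        for modality in cohort.modalities:
            organs = cohort.plans[pid][modality]
            for organ in sorted(organs):
                dvh = organs[organ]
                dp = lookup_organ(dasu_registry, organ)
                sp = lookup_organ(schneider_registry, organ)
                sr = schneider_risk(dvh, sp, incidence_form)
                rows.append(
                    {
                        "patient_id": pid,
                        "modality": modality,
                        "organ": organ,
                        "dasu_total_pct": dasu_risk(dvh, dp, "total"),
                        "dasu_fatal_pct": dasu_risk(dvh, dp, "fatal"),
                        "oed_gy": sr.oed,
                        "schneider_incidence": sr.incidence,
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank


def _exact_signed_rank_p(ranks: np.ndarray, w_plus: float) -> float:
    """Two-tailed p from the exact permutation distribution of W+.

    Under the null each difference's sign is an independent fair coin, so
    the distribution of W+ is the convolution of Bernoulli contributions
    {0, r_i}.  Midranks are half-integers at worst; doubling makes every
    contribution integral, and the convolution is a dense polynomial
    product.  Valid for tied ranks; counts stay exact in doubles for the
    n this package meets (2^n < 2^53).
    """
    r2 = np.rint(2.0 * ranks).astype(np.int64)
    total = int(r2.sum())
    coef = np.zeros(total + 1)
    coef[0] = 1.0
    for r in r2:
        coef[r:] += coef[: coef.size - r].copy()
    n_assignments = 2.0 ** len(ranks)
    w2 = int(np.rint(2.0 * w_plus))
    p_le = coef[: w2 + 1].sum() / n_assignments
    p_ge = coef[w2:].sum() / n_assignments
    return min(1.0, 2.0 * min(p_le, p_ge))


def _approx_signed_rank_p(ranks: np.ndarray, w_plus: float) -> float:
    """Tie-corrected normal approximation (no continuity correction)."""
    n = len(ranks)
    mu = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    _, counts = np.unique(ranks, return_counts=True)
    var -= np.sum(counts**3 - counts) / 48.0
    if var <= 0:
        return 1.0
    z = (w_plus - mu) / np.sqrt(var)
    return float(2.0 * stats.norm.sf(abs(z)))


def wilcoxon_paired(
    x: Sequence[float],
    y: Sequence[float],
    zero_method: str = "wilcox",
    exact_threshold: int = DEFAULT_EXACT_THRESHOLD,
    method: str = "auto",
) -> WilcoxonResult:
    """Two-tailed Wilcoxon signed-rank test on paired samples.

    ``zero_method="wilcox"`` drops zero differences before ranking.  With
    ``method="auto"`` the exact permutation distribution is used when the
    post-drop sample size is at most ``exact_threshold``, the normal
    approximation otherwise; ``"exact"``/``"approx"`` force the choice.
    All differences zero is a defined degenerate case: p = 1, flagged.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be 1-D of equal length")
    if x.size < 2:
        raise ValidationError("need at least two pairs")
    if zero_method != "wilcox":
        raise ValueError(f"unsupported zero_method {zero_method!r}")
    d = x - y
    d = d[d != 0.0]
    if d.size == 0:
        warnings.warn("all paired differences are zero; p-value is 1", stacklevel=2)
        return WilcoxonResult(0.0, 1.0, 0, "degenerate", True)
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if method == "auto":
        method = "exact" if d.size <= exact_threshold else "approx"
    if method == "exact":
        p = _exact_signed_rank_p(ranks, w_plus)
    elif method == "approx":
        p = _approx_signed_rank_p(ranks, w_plus)
    else:
        raise ValueError(f"unknown method {method!r}")
    return WilcoxonResult(w_plus, float(p), int(d.size), method, False)


# ---------------------------------------------------------------------------
# report table


@dataclass
class ComparisonTable:
    """Machine twin of the per-organ modality comparison report.

    ``data`` has one row per (organ, metric) with per-modality
    median/min/max columns, one p-value column per modality pair, and
    matching ``sig_*`` flags at the chosen two-tailed alpha.
    """

    data: pd.DataFrame
    alpha: float = 0.05

    def to_markdown(self) -> str:
        """Human-readable table: median (min-max) plus p-values."""
        lines = []
        modalities = ("3DCRT", "IMRT", "PBS")
        header = (
            ["organ", "metric"]
            + list(modalities)
            + [f"{a} vs {b}" for a, b in MODALITY_PAIRS]
        )
        lines.append("| " + " | ".join(header) + " |")
        lines.append("|" + "---|" * len(header))
        for _, row in self.data.iterrows():
            cells = [str(row["organ"]), str(row["metric"])]
            for m in modalities:
                cells.append(
                    f"{row[f'{m}_median']:.3g} "
                    f"({row[f'{m}_min']:.3g}-{row[f'{m}_max']:.3g})"
                )
            for a, b in MODALITY_PAIRS:
                key = f"p_{a.lower()}_vs_{b.lower()}"
                star = "*" if row[key] <= self.alpha else ""
                cells.append(f"p={row[key]:.3g}{star}")
            lines.append("| " + " | ".join(cells) + " |")
        return "\n".join(lines)


def build_comparison_table(
    metrics: pd.DataFrame,
    alpha: float = 0.05,
    metric_columns: Tuple[str, ...] = METRICS,
    exact_threshold: int = DEFAULT_EXACT_THRESHOLD,
    wilcoxon_method: str = "auto",
) -> ComparisonTable:
    """Summarize a per-patient metric table into the comparison report.

    ``metrics`` is the output of :func:`evaluate_cohort`.  Medians and
    ranges are computed from exactly the per-patient values entering the
    signed-rank tests; pairing is by patient within each organ.
    """
    required = {"patient_id", "modality", "organ", *metric_columns}
    missing_cols = required - set(metrics.columns)
    if missing_cols:
        raise ValidationError(f"metric table missing columns {sorted(missing_cols)}")

    rows = []
    for organ, organ_df in metrics.groupby("organ", sort=True):
        wide = {}
        for modality, mod_df in organ_df.groupby("modality"):
            wide[modality] = mod_df.set_index("patient_id")
        patients = sorted(organ_df["patient_id"].unique())
        missing = [
            f"{pid}/{modality}/{organ}"
            for modality in ("3DCRT", "IMRT", "PBS")
            for pid in patients
            if modality not in wide or pid not in wide[modality].index
        ]
        if missing:
            raise PairingError("missing cohort cells: " + ", ".join(missing))
        for metric in metric_columns:
            row = {"organ": organ, "metric": metric}
            series = {
                m: wide[m].loc[patients, metric].to_numpy()
                for m in ("3DCRT", "IMRT", "PBS")
            }
            for m, values in series.items():
                row[f"{m}_median"] = float(np.median(values))
                row[f"{m}_min"] = float(np.min(values))
                row[f"{m}_max"] = float(np.max(values))
            for a, b in MODALITY_PAIRS:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    res = wilcoxon_paired(
                        series[a],
                        series[b],
                        exact_threshold=exact_threshold,
                        method=wilcoxon_method,
                    )
                key = f"p_{a.lower()}_vs_{b.lower()}"
                row[key] = res.p_value
                row[f"sig_{a.lower()}_vs_{b.lower()}"] = res.p_value <= alpha
            rows.append(row)
    return ComparisonTable(data=pd.DataFrame(rows), alpha=alpha)
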