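"""Secondary-cancer risk from the Dasu competition model.

The model balances induction of carcinogenic mutations against killing of
the mutated cells, both described by linear-quadratic (LQ) dose responses.
For a differential DVH with volume fractions ``v_i`` at total doses ``D_i``
delivered in ``n`` fractions the risk is

    Risk = (1 / sum_i v_i) * sum_i v_i * (a1*D_i + b1*D_i^2/n)
                                       * exp(-(a2*D_i + b2*D_i^2/n))

where ``a1`` is the organ's induction coefficient (ICRP 103 risk
coefficient, per Gy), ``a2`` the cell-kill coefficient, and the quadratic
coefficients are tied to the linear ones through a single alpha/beta ratio:
``b_k = a_k / (alpha/beta)``.  The ``D_i^2/n`` terms are the standard LQ
fractionation correction (``beta * D_i * d_i`` with per-fraction dose
``d_i = D_i / n``).  The competing exponential makes the dose response
rise, peak, and decay: at high dose, cells carrying an induced mutation
are sterilized faster than new mutations accrue.

"Total" risk covers induction of any cancer; "fatal" risk only secondary
malignancies resulting in death, via a smaller induction coefficient.
Risks are reported in percent.

The cell-kill coefficient ``a2`` is not organ-resolved in the ICRP tables;
the shipped registry uses 0.25 / Gy for every organ (the value used in the
competition-model literature) and treats it as an explicit, loggable
parameter of every run.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from typing import Dict, Iterable, Mapping, Optional, Union

import numpy as np
import yaml

from .dvh_io import DVH
from .errors import OrganLookupError, ValidationError

__all__ = [
    "DasuOrganParams",
    "DasuRisk",
    "DEFAULT_ALPHA2",
    "DEFAULT_ALPHA_BETA_RATIO",
    "default_dasu_registry",
    "load_dasu_registry",
    "lookup_organ",
    "dasu_risk",
    "dasu_risk_both",
    "dasu_risk_profile",
]

DEFAULT_ALPHA2 = 0.25  # Gy^-1, cell-kill coefficient shared by all organs
DEFAULT_ALPHA_BETA_RATIO = 3.0  # Gy, for organs at risk

RISK_TYPES = ("total", "fatal")


@dataclass(frozen=True)
class DasuOrganParams:
    """Competition-model coefficients for one organ.

    ``beta`` coefficients are never stored: they are always derived as
    ``alpha_k / alpha_beta_ratio`` so the two LQ terms cannot drift apart.
    """

    organ_name: str
    alpha1_total: float  # Gy^-1, induction coefficient, any cancer
    alpha1_fatal: float  # Gy^-1, induction coefficient, fatal cancer
    alpha2: float = DEFAULT_ALPHA2  # Gy^-1, cell-kill coefficient
    alpha_beta_ratio: float = DEFAULT_ALPHA_BETA_RATIO  # Gy

    def __post_init__(self) -> None:
        for name in ("alpha1_total", "alpha1_fatal", "alpha2", "alpha_beta_ratio"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be > 0")

    @property
    def beta1_total(self) -> float:
        return self.alpha1_total / self.alpha_beta_ratio

    @property
    def beta1_fatal(self) -> float:
        return self.alpha1_fatal / self.alpha_beta_ratio

    @property
    def beta2(self) -> float:
        return self.alpha2 / self.alpha_beta_ratio

    def alpha1(self, risk_type: str) -> float:
        if risk_type == "total":
            return self.alpha1_total
        if risk_type == "fatal":
            return self.alpha1_fatal
        raise ValueError(f"risk_type must be one of {RISK_TYPES}, got {risk_type!r}")


@dataclass(frozen=True)
class DasuRisk:
    """Competition-model evaluation of one organ under one plan."""

    organ_name: str
    total_risk: float  # percent
    fatal_risk: float  # percent


# ICRP 103 risk coefficients (fatal / total, per Gy).  Breast and thyroid
# share coefficients but remain distinct entries so lookup stays explicit.
_DEFAULT_COEFFS: Dict[str, tuple] = {
    "lung": (0.0101, 0.0144),
    "breast": (0.0028, 0.0144),
    "esophagus": (0.0014, 0.0015),
    "thyroid": (0.0028, 0.0144),
}


def default_dasu_registry(
    alpha2: float = DEFAULT_ALPHA2,
    alpha_beta_ratio: float = DEFAULT_ALPHA_BETA_RATIO,
) -> Dict[str, DasuOrganParams]:
    """Registry of shipped organ coefficients, keyed by organ name."""
    return {
        organ: DasuOrganParams(
            organ_name=organ,
            alpha1_fatal=fatal,
            alpha1_total=total,
            alpha2=alpha2,
            alpha_beta_ratio=alpha_beta_ratio,
        )
        for organ, (fatal, total) in _DEFAULT_COEFFS.items()
    }


def load_dasu_registry(path: str) -> Dict[str, DasuOrganParams]:
    """Load an organ -> coefficient registry from YAML or JSON.

    Expected layout::

        lung:
          alpha1_total: 0.0144
          alpha1_fatal: 0.0101
          alpha2: 0.25
          alpha_beta_ratio: 3.0
    """
    with open(path, "r", encoding="utf-8") as fh:
        data = json.load(fh) if str(path).endswith(".json") else yaml.safe_load(fh)
    registry = {}
    for organ, spec in data.items():
        registry[organ] = DasuOrganParams(
            organ_name=organ,
            alpha1_total=float(spec["alpha1_total"]),
            alpha1_fatal=float(spec["alpha1_fatal"]),
            alpha2=float(spec.get("alpha2", DEFAULT_ALPHA2)),
            alpha_beta_ratio=float(
                spec.get("alpha_beta_ratio", DEFAULT_ALPHA_BETA_RATIO)
            ),
        )
    return registry


def lookup_organ(registry: Mapping[str, object], organ_name: str):
    """Find an organ's parameters, resolving lateral structures.

    ``breast_left`` / ``breast_right`` (and similar ``_left``/``_right``
    suffixes) fall back to the unlateralized entry when no exact entry
    exists.
    """
    key = organ_name.strip().lower()
    if key in registry:
        return registry[key]
    for suffix in ("_left", "_right"):
        if key.endswith(suffix) and key[: -len(suffix)] in registry:
            return registry[key[: -len(suffix)]]
    raise OrganLookupError(
        f"organ {organ_name!r} not in registry (known: {sorted(registry)})"
    )


def _risk_terms(
    dose: np.ndarray, n_fractions: int, alpha1: float, params: DasuOrganParams
) -> np.ndarray:
    """Per-dose-point risk (percent): induction times surviving fraction."""
    d2n = dose * dose / n_fractions
    beta1 = alpha1 / params.alpha_beta_ratio
    induction = alpha1 * dose + beta1 * d2n
    kill = params.alpha2 * dose + params.beta2 * d2n
    return 100.0 * induction * np.exp(-kill)


def dasu_risk(dvh: DVH, params: DasuOrganParams, risk_type: str = "total") -> float:
    """Competition-model risk (percent) for one organ DVH.

    The DVH must be differential and normalized; the result is the
    volume-fraction-weighted mean of the per-bin risk terms.
    """
    dvh.require_normalized()
    alpha1 = params.alpha1(risk_type)
    terms = _risk_terms(dvh.bin_dose, dvh.n_fractions, alpha1, params)
    return float(np.sum(dvh.bin_volume_fraction * terms) / dvh.total_volume)


def dasu_risk_both(dvh: DVH, params: DasuOrganParams) -> DasuRisk:
    """Total and fatal risk in one call."""
    return DasuRisk(
        organ_name=dvh.organ_name,
        total_risk=dasu_risk(dvh, params, "total"),
        fatal_risk=dasu_risk(dvh, params, "fatal"),
    )


def dasu_risk_profile(
    dose_grid: Iterable[float],
    params: DasuOrganParams,
    n_fractions: int = 1,
    risk_type: str = "total",
) -> np.ndarray:
    """Uniform-dose risk (percent) evaluated element-wise over a dose grid.

    Traces the rise-peak-decay competition curve for plots and scans.
    """
    grid = np.asarray(list(dose_grid) if not isinstance(dose_grid, np.ndarray) else dose_grid, dtype=float)
    if np.any(grid < 0):
        raise ValueError("dose grid must be non-negative")
    if n_fractions < 1:
        raise ValueError("n_fractions must be >= 1")
    return _risk_terms(grid, int(n_fractions), params.alpha1(risk_type), params)
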