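"""Dose-volume histogram container and tabular I/O.

The canonical in-memory representation is the *differential* DVH with
relative (fractional) volumes: bin ``i`` holds the fraction of the organ
volume ``v_i`` receiving total physical dose ``D_i`` (Gy) over ``n``
fractions.  Both secondary-malignancy risk models consume exactly this
volume-weighted discretization, so cumulative or absolute-volume input is
converted once at load time.

Unirradiated organ volume is kept explicitly as a zero-dose bin: the risk
models normalize by the *whole* organ volume, and silently dropping spared
volume would inflate every risk estimate.

File format: two delimited columns ``dose_gy, volume`` (comma, tab or
whitespace), optional ``#``-prefixed header lines carrying ``key=value``
metadata (``organ=``, ``form=``, ``volume_mode=``, ``n_fractions=``,
``prescription_gy=``).  Doses are always Gy; a ``dose_scale`` argument
rescales other units explicitly (no silent cGy autodetection).
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field, replace
from typing import Optional, Union

import numpy as np

from .errors import DVHFormatError, ValidationError

__all__ = [
    "DVH",
    "PlanMeta",
    "load_dvh_table",
    "write_dvh_table",
    "cumulative_to_differential",
    "rebin",
]

MODALITIES = ("3DCRT", "IMRT", "PBS")

#: tolerance on the normalization of differential volume fractions
NORM_TOL = 1e-9


@dataclass
class DVH:
    """A per-organ dose distribution with fractionation context.

    Parameters
    ----------
    organ_name
        Identifier used for parameter-registry lookup (e.g. ``"lung"``).
    bin_dose
        Total physical dose per bin in Gy, non-decreasing, all >= 0.
    bin_volume_fraction
        Non-negative volume per bin.  For a normalized differential DVH
        these are fractions of the whole organ volume and sum to 1.
    n_fractions
        Number of treatment fractions the total dose is split into.
    prescription_dose
        Prescribed target dose in Gy (metadata, optional).
    form
        ``"differential"`` or ``"cumulative"``.  All model code requires
        differential form; cumulative DVHs exist only transiently at load.
    """

    organ_name: str
    bin_dose: np.ndarray
    bin_volume_fraction: np.ndarray
    n_fractions: int = 1
    prescription_dose: Optional[float] = None
    form: str = "differential"

    def __post_init__(self) -> None:
        self.bin_dose = np.asarray(self.bin_dose, dtype=float)
        self.bin_volume_fraction = np.asarray(self.bin_volume_fraction, dtype=float)
        if self.bin_dose.ndim != 1 or self.bin_volume_fraction.ndim != 1:
            raise ValidationError("bin_dose and bin_volume_fraction must be 1-D")
        if self.bin_dose.size == 0:
            raise ValidationError("DVH has no bins")
        if self.bin_dose.size != self.bin_volume_fraction.size:
            raise ValidationError(
                f"bin count mismatch: {self.bin_dose.size} doses vs "
                f"{self.bin_volume_fraction.size} volumes"
            )
        if np.any(self.bin_dose < 0):
            raise ValidationError("negative dose bin")
        if np.any(np.diff(self.bin_dose) < 0):
            raise ValidationError("bin_dose must be non-decreasing")
        if np.any(self.bin_volume_fraction < 0):
            raise ValidationError("negative bin volume")
        if not np.all(np.isfinite(self.bin_dose)) or not np.all(
            np.isfinite(self.bin_volume_fraction)
        ):
            raise ValidationError("non-finite DVH entry")
        if int(self.n_fractions) != self.n_fractions or self.n_fractions < 1:
            raise ValidationError(f"n_fractions must be a positive integer, got {self.n_fractions}")
        self.n_fractions = int(self.n_fractions)
        if self.form not in ("differential", "cumulative"):
            raise ValidationError(f"unknown DVH form {self.form!r}")

    # -- convenience -------------------------------------------------------

    @property
    def n_bins(self) -> int:
        return int(self.bin_dose.size)

    @property
    def total_volume(self) -> float:
        """Sum of bin volumes (1.0 for a normalized differential DVH)."""
        return float(self.bin_volume_fraction.sum())

    @property
    def mean_dose(self) -> float:
        """Volume-weighted mean dose in Gy (differential form only)."""
        self.require_differential()
        return float(
            np.sum(self.bin_dose * self.bin_volume_fraction) / self.total_volume
        )

    def is_normalized(self, tol: float = NORM_TOL) -> bool:
        return abs(self.total_volume - 1.0) <= tol

    def require_differential(self) -> None:
        if self.form != "differential":
            raise ValidationError(
                f"operation requires a differential DVH, got form={self.form!r}"
            )

    def require_normalized(self, tol: float = NORM_TOL) -> None:
        self.require_differential()
        if not self.is_normalized(tol):
            raise ValidationError(
                f"DVH volume fractions sum to {self.total_volume!r}, expected 1"
            )


@dataclass(frozen=True)
class PlanMeta:
    """Plan-level metadata: who was treated, how, with what prescription."""

    patient_id: str
    modality: str
    prescription_dose: float
    n_fractions: int

    def __post_init__(self) -> None:
        if self.modality not in MODALITIES:
            raise ValidationError(
                f"modality must be one of {MODALITIES}, got {self.modality!r}"
            )
        if not self.prescription_dose > 0:
            raise ValidationError("prescription_dose must be > 0")
        if int(self.n_fractions) != self.n_fractions or self.n_fractions < 1:
            raise ValidationError("n_fractions must be a positive integer")


# ---------------------------------------------------------------------------
# conversions


def cumulative_to_differential(dvh: DVH) -> DVH:
    """Convert a cumulative DVH (volume receiving >= D) to differential form.

    Bin volumes are the successive decrements of the cumulative curve and
    bin doses the interval midpoints (second-order accurate).  Any residual
    volume at the highest tabulated dose becomes a final bin at that dose.
    Total volume is conserved: the output sums to the cumulative value at
    the lowest dose.  Zero-volume intervals are dropped.
    """
    if dvh.form != "cumulative":
        raise ValidationError("cumulative_to_differential requires form='cumulative'")
    d = dvh.bin_dose
    v = dvh.bin_volume_fraction
    if np.any(np.diff(v) > 1e-12):
        raise ValidationError("cumulative volume must be non-increasing in dose")
    diffs = np.maximum(v[:-1] - v[1:], 0.0)
    mids = 0.5 * (d[:-1] + d[1:])
    doses = list(mids)
    vols = list(diffs)
    if v[-1] > 0:  # volume receiving >= the last tabulated dose
        doses.append(d[-1])
        vols.append(v[-1])
    doses_a = np.asarray(doses)
    vols_a = np.asarray(vols)
    keep = vols_a > 0
    if not np.any(keep):
        raise ValidationError("cumulative DVH carries no volume")
    return replace(
        dvh,
        bin_dose=doses_a[keep],
        bin_volume_fraction=vols_a[keep],
        form="differential",
    )


def rebin(dvh: DVH, factor: int) -> DVH:
    """Split every bin into ``factor`` equal-volume sub-bins at the same dose.

    Volume is conserved exactly; every volume-weighted metric is invariant.
    Exists to exercise bin-refinement invariance of the risk models.
    """
    dvh.require_differential()
    if int(factor) != factor or factor < 1:
        raise ValueError(f"rebin factor must be a positive integer, got {factor!r}")
    factor = int(factor)
    if factor == 1:
        return replace(dvh)
    return replace(
        dvh,
        bin_dose=np.repeat(dvh.bin_dose, factor),
        bin_volume_fraction=np.repeat(dvh.bin_volume_fraction / factor, factor),
    )


def _pad_spared_volume(dvh: DVH, tol: float = NORM_TOL) -> DVH:
    """Absorb unirradiated volume into a zero-dose bin so fractions sum to 1."""
    total = dvh.total_volume
    if total > 1.0 + tol:
        raise ValidationError(
            f"relative volume fractions sum to {total!r} > 1; "
            "pass volume_mode='absolute' for absolute volumes"
        )
    missing = 1.0 - total
    if missing <= tol:
        return dvh
    d = dvh.bin_dose
    v = dvh.bin_volume_fraction
    if d[0] == 0.0:
        v = v.copy()
        v[0] += missing
    else:
        d = np.concatenate(([0.0], d))
        v = np.concatenate(([missing], v))
    return replace(dvh, bin_dose=d, bin_volume_fraction=v)


# ---------------------------------------------------------------------------
# file I/O

_HEADER_KEYS = ("organ", "form", "volume_mode", "n_fractions", "prescription_gy")


def _parse_header(lines: list[str]) -> dict[str, str]:
    meta: dict[str, str] = {}
    for line in lines:
        body = line.lstrip("#").strip()
        for token in body.replace(",", " ").split():
            if "=" in token:
                key, _, value = token.partition("=")
                if key in _HEADER_KEYS:
                    meta[key] = value
    return meta


def load_dvh_table(
    path: Union[str, os.PathLike, io.TextIOBase],
    dialect: Optional[str] = None,
    volume_mode: Optional[str] = None,
    organ_name: Optional[str] = None,
    n_fractions: Optional[int] = None,
    prescription_dose: Optional[float] = None,
    dose_scale: float = 1.0,
) -> DVH:
    """Read a two-column DVH table and return a normalized differential DVH.

    ``dialect`` (``differential``/``cumulative``) and ``volume_mode``
    (``relative``/``absolute``) override any ``#`` header metadata; when
    neither is given the defaults are differential/relative.  Absolute
    volumes are divided by their total; cumulative tables are converted via
    :func:`cumulative_to_differential`; any remaining unirradiated volume
    is placed in a zero-dose bin so fractions always sum to 1.
    """
    if isinstance(path, io.TextIOBase):
        raw = path.read()
    else:
        with open(path, "r", encoding="utf-8") as fh:
            raw = fh.read()

    header_lines = [ln for ln in raw.splitlines() if ln.lstrip().startswith("#")]
    data_lines = [
        ln for ln in raw.splitlines() if ln.strip() and not ln.lstrip().startswith("#")
    ]
    meta = _parse_header(header_lines)

    rows: list[tuple[float, float]] = []
    for idx, line in enumerate(data_lines):
        parts = [p for p in line.replace(",", "\t").replace(";", "\t").split() if p]
        if len(parts) < 2:
            raise DVHFormatError(f"line {idx + 1}: expected two columns, got {line!r}")
        try:
            rows.append((float(parts[0]), float(parts[1])))
        except ValueError:
            if idx == 0:  # tolerate a single textual header row
                continue
            raise DVHFormatError(f"line {idx + 1}: non-numeric entry in {line!r}")
    if not rows:
        raise ValidationError("empty DVH table")

    dose = np.array([r[0] for r in rows]) * dose_scale
    volume = np.array([r[1] for r in rows])
    if np.any(np.diff(dose) <= 0):
        raise DVHFormatError("dose column must be strictly increasing")
    if np.any(volume < 0):
        raise ValidationError("negative volume in DVH table")

    form = dialect or meta.get("form", "differential")
    if form not in ("differential", "cumulative"):
        raise DVHFormatError(f"unknown dialect {form!r}")
    mode = volume_mode or meta.get("volume_mode", "relative")
    if mode not in ("relative", "absolute"):
        raise DVHFormatError(f"unknown volume_mode {mode!r}")

    if mode == "absolute":
        total = volume.sum() if form == "differential" else volume[0]
        if total <= 0:
            raise ValidationError("absolute DVH carries no volume")
        volume = volume / total

    dvh = DVH(
        organ_name=organ_name or meta.get("organ", "unknown"),
        bin_dose=dose,
        bin_volume_fraction=volume,
        n_fractions=int(n_fractions or meta.get("n_fractions", 1)),
        prescription_dose=(
            prescription_dose
            if prescription_dose is not None
            else (float(meta["prescription_gy"]) if "prescription_gy" in meta else None)
        ),
        form=form,
    )
    if dvh.form == "cumulative":
        dvh = cumulative_to_differential(dvh)
    dvh = _pad_spared_volume(dvh)
    dvh.require_normalized()
    return dvh


def write_dvh_table(dvh: DVH, path: Union[str, os.PathLike]) -> None:
    """Write a DVH in the package's tabular interchange format."""
    lines = [
        "# smrisk DVH table",
        f"# organ={dvh.organ_name} form={dvh.form} volume_mode=relative "
        f"n_fractions={dvh.n_fractions}"
        + (
            f" prescription_gy={dvh.prescription_dose:.17g}"
            if dvh.prescription_dose is not None
            else ""
        ),
        "dose_gy\tvolume",
    ]
    for d, v in zip(dvh.bin_dose, dvh.bin_volume_fraction):
        lines.append(f"{d:.17g}\t{v:.17g}")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")
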