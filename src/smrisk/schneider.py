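"""Organ equivalent dose (OED) and Schneider-model cancer incidence.

The OED concept declares two dose distributions in an organ equivalent if
they predict the same radiation-induced secondary-malignancy incidence.
With a linear-exponential dose response the OED of a differential DVH is

    OED = sum_i v_i * D_i * exp(-alpha_org * D_i) / sum_i v_i      [Gy]

where ``alpha_org`` (per Gy) is the organ-specific sterilization
parameter: the exponential describes the loss of potentially transformed
cells at high dose, so the per-dose contribution peaks at
``D = 1/alpha_org`` and decays beyond it.  As ``alpha_org -> 0`` the OED
tends to the mean organ dose; for any positive ``alpha_org`` it is bounded
above by the mean dose.

The incidence of a secondary malignancy is then

    I_org = I0_org * OED * exp(-alpha_org * OED)

with ``I0_org`` the organ-specific incidence rate (per 10,000 patients per
year per Gy).  This form applies the sterilization exponential a second
time, now to the OED itself; some of the surrounding literature uses the
plain linear form ``I = I0 * OED`` instead.  Both are available through
``incidence_form`` — ``"as_printed"`` (default) keeps the doubly
attenuated form, ``"linear_in_oed"`` the linear one — so the choice is an
explicit, logged parameter rather than a silent convention.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Dict

import numpy as np
import yaml

from .dvh_io import DVH
from .errors import ValidationError

__all__ = [
    "SchneiderOrganParams",
    "SchneiderRisk",
    "INCIDENCE_FORMS",
    "default_schneider_registry",
    "load_schneider_registry",
    "oed",
    "schneider_incidence",
    "schneider_risk",
]

INCIDENCE_FORMS = ("as_printed", "linear_in_oed")


@dataclass(frozen=True)
class SchneiderOrganParams:
    """OED-model coefficients for one organ."""

    organ_name: str
    i0: float  # incidence rate per 10,000 patients per year per Gy
    alpha_org: float  # Gy^-1, sterilization parameter

    def __post_init__(self) -> None:
        if not self.i0 > 0:
            raise ValidationError("i0 must be > 0")
        if not self.alpha_org > 0:
            raise ValidationError("alpha_org must be > 0")


@dataclass(frozen=True)
class SchneiderRisk:
    """OED-model evaluation of one organ under one plan."""

    organ_name: str
    oed: float  # Gy
    incidence: float  # same unit as I0


_DEFAULT_COEFFS: Dict[str, tuple] = {
    "lung": (1.68, 0.129),
    "breast": (0.78, 0.08),
    "esophagus": (0.61, 0.274),
    "thyroid": (0.75, 0.033),
}


def default_schneider_registry() -> Dict[str, SchneiderOrganParams]:
    """Registry of shipped (I0, alpha_org) pairs, keyed by organ name."""
    return {
        organ: SchneiderOrganParams(organ_name=organ, i0=i0, alpha_org=a)
        for organ, (i0, a) in _DEFAULT_COEFFS.items()
    }


def load_schneider_registry(path: str) -> Dict[str, SchneiderOrganParams]:
    """Load an organ -> {i0, alpha_org} registry from YAML or JSON."""
    with open(path, "r", encoding="utf-8") as fh:
        data = json.load(fh) if str(path).endswith(".json") else yaml.safe_load(fh)
    return {
        organ: SchneiderOrganParams(
            organ_name=organ,
            i0=float(spec["i0"]),
            alpha_org=float(spec["alpha_org"]),
        )
        for organ, spec in data.items()
    }


def oed(dvh: DVH, params: SchneiderOrganParams) -> float:
    """Organ equivalent dose in Gy for a normalized differential DVH."""
    dvh.require_normalized()
    d = dvh.bin_dose
    v = dvh.bin_volume_fraction
    return float(np.sum(v * d * np.exp(-params.alpha_org * d)) / np.sum(v))


def schneider_incidence(
    oed_value: float,
    params: SchneiderOrganParams,
    incidence_form: str = "as_printed",
) -> float:
    """Secondary-malignancy incidence for a given OED.

    ``as_printed``: I0 * OED * exp(-alpha_org * OED);
    ``linear_in_oed``: I0 * OED.
    """
    if oed_value < 0:
        raise ValueError(f"OED must be >= 0, got {oed_value!r}")
    if incidence_form == "as_printed":
        return params.i0 * oed_value * float(np.exp(-params.alpha_org * oed_value))
    if incidence_form == "linear_in_oed":
        return params.i0 * oed_value
    raise ValueError(
        f"incidence_form must be one of {INCIDENCE_FORMS}, got {incidence_form!r}"
    )


def schneider_risk(
    dvh: DVH,
    params: SchneiderOrganParams,
    incidence_form: str = "as_printed",
) -> SchneiderRisk:
    """OED and incidence for one organ DVH."""
    oed_value = oed(dvh, params)
    return SchneiderRisk(
        organ_name=dvh.organ_name,
        oed=oed_value,
        incidence=schneider_incidence(oed_value, params, incidence_form),
    )
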