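"""Seeded synthetic cohorts of thoracic-organ DVHs for three modalities.

No patient DVHs ship with this package, so pipeline-level behaviour is
exercised on synthetic cohorts that reproduce the *qualitative* dosimetric
structure of comparative thymic-irradiation planning:

* anterior proton beams (PBS) can spare posterior and lateral structures
  (lungs, esophagus, breasts) almost entirely, so PBS profiles carry large
  zero-dose (spared) volume fractions;
* photon plans (3DCRT, IMRT) bathe large normal-tissue volumes in low and
  intermediate dose, IMRT trading conformality for a wider low-dose bath;
* the thyroid sits out of the anterior beam geometry for every modality,
  so its profile is identical across modalities (a built-in null).

Each generated DVH is a three-part mixture on a fixed dose grid:

* a zero-dose bin of size ``spared_fraction``;
* a low-dose *bath*: a Beta distribution on [0, prescription] with mean
  ``bath_dose_fraction * prescription`` and concentration
  ``shape_concentration``;
* a near-prescription *peak*: a narrow Beta on
  [0.85, 1.05] x prescription with mean exactly the prescription, holding
  ``high_dose_fraction`` of the exposed volume.

Patients are paired by construction: one latent anatomy effect per
patient shifts the spared fraction (on the logit scale) and the bath dose
level in the same direction for all three of that patient's plans, which
is what a within-patient signed-rank comparison requires.

All numeric profile defaults are synthetic calibration values chosen to
reproduce the qualitative contrasts above; they are not measurements.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import yaml
from scipy.special import betainc, expit, logit

from .cohort import CohortPlanSet
from .dvh_io import DVH, MODALITIES, PlanMeta
from .errors import ConfigurationError

__all__ = [
    "ModalityDvhProfile",
    "CohortSpec",
    "DEFAULT_PRESCRIPTIONS",
    "DEFAULT_ORGANS",
    "default_profiles",
    "load_profiles",
    "generate_dvh",
    "generate_cohort",
    "expected_mean_dose",
]

#: empirical (total dose Gy, fractions) support of the study cohort:
#: 45-66 Gy in 25-33 fractions, median 54 Gy / 27 fractions.
DEFAULT_PRESCRIPTIONS: Tuple[Tuple[float, int], ...] = (
    (50.0, 25),
    (50.0, 25),
    (50.0, 25),
    (54.0, 27),
    (50.0, 25),
    (50.0, 25),
    (50.0, 25),
    (54.0, 27),
    (66.0, 33),
    (66.0, 33),
    (54.0, 30),
    (54.0, 30),
    (54.0, 30),
    (45.0, 25),
    (54.0, 30),
    (54.0, 30),
    (54.0, 30),
)

DEFAULT_ORGANS: Tuple[str, ...] = (
    "lung",
    "breast_left",
    "breast_right",
    "esophagus",
    "thyroid",
)

# near-prescription peak: Beta(a, b) scaled to [_HIGH_LO, _HIGH_HI] x Rx.
# mean = 0.85 + 0.75 * 0.20 = 1.00 x prescription exactly.
_HIGH_LO, _HIGH_HI = 0.85, 1.05
_HIGH_A, _HIGH_B = 22.5, 7.5

_BATH_EFFECT_SCALE = 0.25  # bath level multiplier is exp(scale * z)


@dataclass(frozen=True)
class ModalityDvhProfile:
    """Stochastic DVH-shape recipe for one (modality, organ) pair.

    ``spared_fraction_range``: volume fraction receiving ~0 dose.
    ``bath_dose_fraction_range``: mean of the low-dose bath as a fraction
    of the prescription.  ``high_dose_fraction_range``: share of the
    *exposed* volume sitting near the prescription.  All are uniform
    sampling intervals in [0, 1]; ``shape_concentration`` is the Beta
    concentration of the bath (small = broad bath).
    """

    modality: str
    organ_name: str
    spared_fraction_range: Tuple[float, float]
    bath_dose_fraction_range: Tuple[float, float]
    high_dose_fraction_range: Tuple[float, float]
    shape_concentration: float = 2.5

    def __post_init__(self) -> None:
        for name in (
            "spared_fraction_range",
            "bath_dose_fraction_range",
            "high_dose_fraction_range",
        ):
            lo, hi = getattr(self, name)
            if not (0.0 <= lo <= hi <= 1.0):
                raise ConfigurationError(f"{name} must satisfy 0 <= lo <= hi <= 1")
        if not self.shape_concentration > 0:
            raise ConfigurationError("shape_concentration must be > 0")


@dataclass(frozen=True)
class CohortSpec:
    """What synthetic cohort to draw: size, organs, prescriptions, seed."""

    n_patients: int = 17
    organs: Tuple[str, ...] = DEFAULT_ORGANS
    seed: int = 0
    prescriptions: Tuple[Tuple[float, int], ...] = DEFAULT_PRESCRIPTIONS
    patient_effect_sd: float = 0.4
    bin_width: float = 0.5  # Gy

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ConfigurationError("n_patients must be >= 2")
        if not self.organs:
            raise ConfigurationError("organs must be non-empty")
        if not self.prescriptions:
            raise ConfigurationError("prescriptions must be non-empty")
        if not self.bin_width > 0:
            raise ConfigurationError("bin_width must be > 0")


def load_profiles(path) -> Dict[Tuple[str, str], ModalityDvhProfile]:
    """Load a profile registry from YAML.

    Layout: ``organ -> modality -> {ranges...}``; the special modality key
    ``all`` assigns one shared profile object to every modality (used for
    organs whose dose distribution is modality-invariant by design).
    """
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    return _profiles_from_dict(data)


def _profiles_from_dict(data: dict) -> Dict[Tuple[str, str], ModalityDvhProfile]:
    registry: Dict[Tuple[str, str], ModalityDvhProfile] = {}
    for organ, by_modality in data.items():
        if not by_modality:
            raise ConfigurationError(f"empty profile section for organ {organ!r}")
        if "all" in by_modality:
            shared = _profile_from_spec(organ, "all", by_modality["all"])
            for modality in MODALITIES:
                registry[(modality, organ)] = shared
            continue
        for modality, spec in by_modality.items():
            registry[(modality, organ)] = _profile_from_spec(organ, modality, spec)
    return registry


def _profile_from_spec(organ: str, modality: str, spec: dict) -> ModalityDvhProfile:
    try:
        return ModalityDvhProfile(
            modality=modality,
            organ_name=organ,
            spared_fraction_range=tuple(spec["spared_fraction_range"]),
            bath_dose_fraction_range=tuple(spec["bath_dose_fraction_range"]),
            high_dose_fraction_range=tuple(spec["high_dose_fraction_range"]),
            shape_concentration=float(spec.get("shape_concentration", 2.5)),
        )
    except KeyError as exc:
        raise ConfigurationError(f"profile {organ}/{modality} missing key {exc}")


def default_profiles() -> Dict[Tuple[str, str], ModalityDvhProfile]:
    """The shipped synthetic-calibration profile registry."""
    text = (
        resources.files("smrisk").joinpath("data/default_profiles.yaml").read_text()
    )
    return _profiles_from_dict(yaml.safe_load(text))


def _beta_bin_masses(edges: np.ndarray, lo: float, hi: float, a: float, b: float) -> np.ndarray:
    """Probability mass of a Beta(a,b) scaled to [lo, hi] within each bin."""
    x = np.clip((edges - lo) / (hi - lo), 0.0, 1.0)
    cdf = betainc(a, b, x)
    return np.diff(cdf)


def generate_dvh(
    profile: ModalityDvhProfile,
    prescription: float,
    n_fractions: int,
    rng: np.random.Generator,
    patient_effect: float = 0.0,
    bin_width: float = 0.5,
) -> DVH:
    """Draw one differential DVH from a modality/organ profile.

    ``patient_effect`` is the latent anatomy effect ``z``: it lowers the
    spared fraction by ``z`` on the logit scale and multiplies the bath
    dose level by ``exp(0.25 z)``, so plans sharing a patient move
    together.  Fully deterministic given the generator state.
    """
    if not prescription > 0:
        raise ConfigurationError("prescription must be > 0")
    spared = rng.uniform(*profile.spared_fraction_range)
    bath_mu = rng.uniform(*profile.bath_dose_fraction_range)
    high_frac = rng.uniform(*profile.high_dose_fraction_range)

    z = patient_effect
    if 0.0 < spared < 1.0:
        spared = float(expit(logit(spared) - z))
    bath_mu = float(np.clip(bath_mu * np.exp(_BATH_EFFECT_SCALE * z), 1e-3, 0.95))

    if spared >= 1.0 - 1e-12:  # fully spared organ: single zero-dose bin
        return DVH(
            organ_name=profile.organ_name,
            bin_dose=np.array([0.0]),
            bin_volume_fraction=np.array([1.0]),
            n_fractions=n_fractions,
            prescription_dose=prescription,
        )

    n_bins = int(np.ceil(1.1 * prescription / bin_width))
    edges = np.linspace(0.0, n_bins * bin_width, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])

    kappa = profile.shape_concentration
    bath_mass = _beta_bin_masses(
        edges, 0.0, prescription, bath_mu * kappa, (1.0 - bath_mu) * kappa
    )
    high_mass = _beta_bin_masses(
        edges, _HIGH_LO * prescription, _HIGH_HI * prescription, _HIGH_A, _HIGH_B
    )
    exposed = 1.0 - spared
    mass = exposed * ((1.0 - high_frac) * bath_mass + high_frac * high_mass)

    return DVH(
        organ_name=profile.organ_name,
        bin_dose=np.concatenate(([0.0], centers)),
        bin_volume_fraction=np.concatenate(([spared], mass)),
        n_fractions=n_fractions,
        prescription_dose=prescription,
    )


def expected_mean_dose(profile: ModalityDvhProfile, prescription: float) -> float:
    """Analytic expectation of the mean dose of :func:`generate_dvh` draws.

    Valid for ``patient_effect = 0``: with independent uniform draws,
    E[mean dose] = E[1 - spared] * ((1 - E[hf]) * E[bath_mu] + E[hf]) * Rx
    (the peak's mean is exactly the prescription).  The discretized DVH
    carries its mass at bin centers, which perturbs this by O(bin_width^2).
    """
    s = 0.5 * sum(profile.spared_fraction_range)
    b = 0.5 * sum(profile.bath_dose_fraction_range)
    h = 0.5 * sum(profile.high_dose_fraction_range)
    return (1.0 - s) * ((1.0 - h) * b + h) * prescription


def _stream(seed: int, *keys) -> np.random.Generator:
    """Named RNG substream: string keys hash to stable 32-bit words."""
    words = [seed] + [
        zlib.crc32(k.encode()) if isinstance(k, str) else int(k) for k in keys
    ]
    return np.random.default_rng(words)


def generate_cohort(
    spec: CohortSpec,
    profiles: Optional[Dict[Tuple[str, str], ModalityDvhProfile]] = None,
) -> CohortPlanSet:
    """Draw a full paired cohort: every patient gets all three modalities.

    One prescription and one anatomy effect are drawn per patient and
    shared across that patient's plans; every (patient, organ, modality)
    triple then has its own named RNG substream, so adding an organ to the
    spec does not perturb any other organ's draws.
    """
    profiles = default_profiles() if profiles is None else profiles
    for organ in spec.organs:
        for modality in MODALITIES:
            if (modality, organ) not in profiles:
                raise ConfigurationError(
                    f"no profile for modality={modality!r}, organ={organ!r}"
                )

    patients: List[str] = []
    plans: Dict[str, Dict[str, Dict[str, DVH]]] = {}
    meta: Dict[str, Dict[str, PlanMeta]] = {}
    prescriptions = list(spec.prescriptions)
    for i in range(spec.n_patients):
        pid = f"P{i + 1:02d}"
        patients.append(pid)
        prng = _stream(spec.seed, "patient", i)
        rx_dose, rx_fx = prescriptions[prng.integers(len(prescriptions))]
        z = prng.normal(0.0, spec.patient_effect_sd)
        plans[pid] = {}
        meta[pid] = {}
        for modality in MODALITIES:
            meta[pid][modality] = PlanMeta(
                patient_id=pid,
                modality=modality,
                prescription_dose=rx_dose,
                n_fractions=rx_fx,
            )
            plans[pid][modality] = {}
            for organ in spec.organs:
                rng = _stream(spec.seed, "dvh", i, organ, modality)
                plans[pid][modality][organ] = generate_dvh(
                    profiles[(modality, organ)],
                    prescription=rx_dose,
                    n_fractions=rx_fx,
                    rng=rng,
                    patient_effect=z,
                    bin_width=spec.bin_width,
                )
    cohort = CohortPlanSet(patients=patients, plans=plans, meta=meta)
    cohort.validate()
    return cohort
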