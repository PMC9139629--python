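"""Run manifests and end-to-end pipeline orchestration.

A run manifest captures everything needed to recompute a report: input
source (a cohort manifest on disk, or a simulation spec), parameter
registries, every model option, and the seed.  Defaults are materialized
into the manifest that is written next to the outputs, so no setting is
ever implicit in a finished run.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Tuple

import yaml

from . import __version__
from .cohort import CohortPlanSet, load_cohort_manifest, write_cohort
from .compare import DEFAULT_EXACT_THRESHOLD, build_comparison_table, evaluate_cohort
from .dasu import (
    DEFAULT_ALPHA2,
    DEFAULT_ALPHA_BETA_RATIO,
    default_dasu_registry,
    load_dasu_registry,
)
from .errors import ConfigurationError
from .schneider import default_schneider_registry, load_schneider_registry
from .synthetic import CohortSpec, DEFAULT_ORGANS, default_profiles, generate_cohort, load_profiles

__all__ = ["RunManifest", "run_pipeline"]

logger = logging.getLogger("smrisk")


@dataclass
class RunManifest:
    """Fully resolved description of one pipeline run."""

    out_dir: str
    simulate: bool = True
    cohort_manifest: Optional[str] = None  # used when simulate is False
    n_patients: int = 17
    organs: Tuple[str, ...] = DEFAULT_ORGANS
    seed: int = 0
    profiles_path: Optional[str] = None
    dasu_params_path: Optional[str] = None
    schneider_params_path: Optional[str] = None
    alpha2: float = DEFAULT_ALPHA2
    alpha_beta_ratio: float = DEFAULT_ALPHA_BETA_RATIO
    incidence_form: str = "as_printed"
    zero_method: str = "wilcox"
    exact_threshold: int = DEFAULT_EXACT_THRESHOLD
    alpha: float = 0.05
    write_dvhs: bool = False
    tool_version: str = __version__

    def validate(self) -> None:
        if not self.simulate and not self.cohort_manifest:
            raise ConfigurationError(
                "manifest must either set simulate=true or name a cohort_manifest"
            )
        if self.incidence_form not in ("as_printed", "linear_in_oed"):
            raise ConfigurationError(f"bad incidence_form {self.incidence_form!r}")
        if not 0 < self.alpha < 1:
            raise ConfigurationError("alpha must be in (0, 1)")

    @classmethod
    def from_file(cls, path: str) -> "RunManifest":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown manifest fields: {sorted(unknown)}")
        if "organs" in data:
            data["organs"] = tuple(data["organs"])
        return cls(**data)


def _registry_hash(registry) -> str:
    payload = json.dumps(
        {k: asdict(v) for k, v in sorted(registry.items())}, sort_keys=True
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(manifest: RunManifest) -> Path:
    """Simulate or load a cohort, evaluate it, compare modalities, report.

    Writes into ``manifest.out_dir``: ``per_patient_metrics.csv``,
    ``comparison.csv``, ``comparison.md`` and the resolved
    ``manifest_resolved.yaml``; returns the output directory.
    Deterministic given the manifest (including its seed).
    """
    manifest.validate()
    out = Path(manifest.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    dasu_registry = (
        load_dasu_registry(manifest.dasu_params_path)
        if manifest.dasu_params_path
        else default_dasu_registry(
            alpha2=manifest.alpha2, alpha_beta_ratio=manifest.alpha_beta_ratio
        )
    )
    schneider_registry = (
        load_schneider_registry(manifest.schneider_params_path)
        if manifest.schneider_params_path
        else default_schneider_registry()
    )
    logger.info(
        "smrisk %s seed=%s dasu_registry=%s schneider_registry=%s",
        manifest.tool_version,
        manifest.seed,
        _registry_hash(dasu_registry),
        _registry_hash(schneider_registry),
    )

    if manifest.simulate:
        profiles = (
            load_profiles(manifest.profiles_path)
            if manifest.profiles_path
            else default_profiles()
        )
        spec = CohortSpec(
            n_patients=manifest.n_patients,
            organs=tuple(manifest.organs),
            seed=manifest.seed,
        )
        cohort = generate_cohort(spec, profiles)
        if manifest.write_dvhs:
            write_cohort(cohort, out / "cohort")
    else:
        cohort = load_cohort_manifest(manifest.cohort_manifest)

    metrics = evaluate_cohort(
        cohort,
        dasu_registry=dasu_registry,
        schneider_registry=schneider_registry,
        incidence_form=manifest.incidence_form,
    )
    table = build_comparison_table(
        metrics,
        alpha=manifest.alpha,
        exact_threshold=manifest.exact_threshold,
    )

    metrics.to_csv(out / "per_patient_metrics.csv", index=False, float_format="%.12g")
    table.data.to_csv(out / "comparison.csv", index=False, float_format="%.12g")
    (out / "comparison.md").write_text(table.to_markdown() + "\n", encoding="utf-8")
    with open(out / "manifest_resolved.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(asdict(manifest), fh, sort_keys=True)
    logger.info("report written to %s", out)
    return out
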