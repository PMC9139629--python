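"""Cohort container: patient -> modality -> organ -> DVH, plus manifest I/O.

A cohort manifest is a JSON or YAML file of the form::

    patients:
      P01:
        3DCRT:
          meta: {prescription_gy: 54.0, n_fractions: 27}
          organs:
            lung: dvh/P01_3DCRT_lung.tsv
            ...

DVH paths are resolved relative to the manifest file's directory.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List

import yaml

from .dvh_io import DVH, MODALITIES, PlanMeta, load_dvh_table, write_dvh_table
from .errors import PairingError

__all__ = ["CohortPlanSet", "load_cohort_manifest", "write_cohort"]


@dataclass
class CohortPlanSet:
    """All comparative plans for a cohort.

    Every patient must hold the same modalities and the same organs per
    modality, with identical prescription and fractionation across the
    modalities of one patient (the plans are re-plans of one case).
    """

    patients: List[str]
    plans: Dict[str, Dict[str, Dict[str, DVH]]]  # patient -> modality -> organ
    meta: Dict[str, Dict[str, PlanMeta]]  # patient -> modality

    def validate(self) -> None:
        missing: List[str] = []
        if not self.patients:
            raise PairingError("cohort has no patients")
        ref_modalities = sorted(self.plans[self.patients[0]].keys())
        ref_organs = sorted(
            self.plans[self.patients[0]][ref_modalities[0]].keys()
        )
        for pid in self.patients:
            if pid not in self.plans:
                missing.append(f"{pid}: no plans")
                continue
            for modality in ref_modalities:
                if modality not in self.plans[pid]:
                    missing.append(f"{pid}: missing modality {modality}")
                    continue
                for organ in ref_organs:
                    if organ not in self.plans[pid][modality]:
                        missing.append(f"{pid}/{modality}: missing organ {organ}")
            metas = self.meta.get(pid, {})
            rx = {
                (m.prescription_dose, m.n_fractions) for m in metas.values()
            }
            if len(rx) > 1:
                missing.append(f"{pid}: prescription differs across modalities {rx}")
        if missing:
            raise PairingError("incomplete cohort: " + "; ".join(missing))

    @property
    def modalities(self) -> List[str]:
        return sorted(self.plans[self.patients[0]].keys())

    @property
    def organs(self) -> List[str]:
        first = self.plans[self.patients[0]]
        return sorted(first[next(iter(first))].keys())


def load_cohort_manifest(path: str | os.PathLike) -> CohortPlanSet:
    """Read a cohort manifest and all DVH tables it references."""
    path = Path(path)
    with open(path, "r", encoding="utf-8") as fh:
        data = json.load(fh) if path.suffix == ".json" else yaml.safe_load(fh)
    base = path.parent
    patients: List[str] = []
    plans: Dict[str, Dict[str, Dict[str, DVH]]] = {}
    meta: Dict[str, Dict[str, PlanMeta]] = {}
    for pid, modalities in data["patients"].items():
        patients.append(str(pid))
        plans[str(pid)] = {}
        meta[str(pid)] = {}
        for modality, entry in modalities.items():
            m = entry["meta"]
            meta[str(pid)][modality] = PlanMeta(
                patient_id=str(pid),
                modality=modality,
                prescription_dose=float(m["prescription_gy"]),
                n_fractions=int(m["n_fractions"]),
            )
            plans[str(pid)][modality] = {
                organ: load_dvh_table(base / rel)
                for organ, rel in entry["organs"].items()
            }
    cohort = CohortPlanSet(patients=patients, plans=plans, meta=meta)
    cohort.validate()
    return cohort


def write_cohort(cohort: CohortPlanSet, out_dir: str | os.PathLike) -> Path:
    """Write DVH tables plus a JSON manifest; returns the manifest path."""
    out = Path(out_dir)
    (out / "dvh").mkdir(parents=True, exist_ok=True)
    manifest: Dict = {"patients": {}}
    for pid in cohort.patients:
        manifest["patients"][pid] = {}
        for modality, organs in cohort.plans[pid].items():
            m = cohort.meta[pid][modality]
            entry = {
                "meta": {
                    "prescription_gy": m.prescription_dose,
                    "n_fractions": m.n_fractions,
                },
                "organs": {},
            }
            for organ, dvh in organs.items():
                rel = f"dvh/{pid}_{modality}_{organ}.tsv"
                write_dvh_table(dvh, out / rel)
                entry["organs"][organ] = rel
            manifest["patients"][pid][modality] = entry
    manifest_path = out / "manifest.json"
    with open(manifest_path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest_path
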