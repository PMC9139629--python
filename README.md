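# smrisk

Estimation of radiation-induced secondary-malignancy (SM) risk to thoracic
organs at risk from radiotherapy dose–volume histograms (DVHs), with paired
statistical comparison of treatment modalities (3D conformal photon
radiotherapy, intensity-modulated photon radiotherapy, and pencil-beam-scanned
proton therapy: 3DCRT, IMRT, PBS).

It is written for medical physicists and modelling researchers who have
per-organ DVHs for competing plans of the same patients and want per-organ
risk estimates plus a cohort-level significance table — and for anyone who
needs a fully seeded synthetic DVH cohort to test such pipelines when
clinical DVHs cannot be shared.

## Models

Both models consume a differential DVH: volume fractions `v_i` at total
dose `D_i` (Gy) delivered in `n` fractions.

**Competition model (Dasu).** Linear-quadratic induction of carcinogenic
mutations competing against linear-quadratic kill of the mutated cells:

    Risk = (1/Σᵢvᵢ) Σᵢ vᵢ (α₁Dᵢ + β₁Dᵢ²/n) · exp(−(α₂Dᵢ + β₂Dᵢ²/n))

with `β_k = α_k / (α/β)` and `α/β = 3 Gy` for organs at risk. `α₁` is the
ICRP 103 risk coefficient per organ ("total": any induced cancer;
"fatal": lethal ones only); `α₂ = 0.25 Gy⁻¹` is the cell-kill coefficient.
The risk is reported in percent. The dose response rises, peaks at a few
Gy, and decays — high-dose regions contribute little because mutated cells
are sterilized.

**Organ equivalent dose (Schneider).** The OED is the uniform dose with
the same predicted SM incidence as a heterogeneous distribution, using a
linear-exponential response with organ-specific sterilization parameter
`α_org`:

    OED  = Σᵢ vᵢ Dᵢ e^(−α_org·Dᵢ) / Σᵢ vᵢ          [Gy]
    I_org = I0_org · OED · e^(−α_org·OED)

with `I0_org` the organ-specific incidence rate per 10,000 patients per
year per Gy.

**Cohort comparison.** Per organ and metric (total %, fatal %, incidence),
modalities are compared patient-by-patient with the two-tailed Wilcoxon
signed-rank test (exact permutation distribution up to 25 informative
pairs; tie-corrected normal approximation beyond), reported as median
(min–max) per modality plus three pairwise p-values, uncorrected,
significance at p ≤ 0.05.

## Worked example

```python
import smrisk as sm

# a uniform 2 Gy exposure of lung in a single fraction
dvh = sm.DVH("lung", [2.0], [1.0], n_fractions=1)
params = sm.default_dasu_registry()["lung"]
print(sm.dasu_risk(dvh, params, "total"))   # 2.0860714008339754

sp = sm.default_schneider_registry()["lung"]
print(sm.oed(dvh, sp))                      # 1.545190464213856  (Gy)
print(sm.schneider_incidence(5.0, sp))      # 4.4071653536953805

# a synthetic paired cohort: 17 patients x 3 modalities x 5 organs
cohort = sm.generate_cohort(sm.CohortSpec(seed=1))
table = sm.build_comparison_table(sm.evaluate_cohort(cohort)).data
lung = table[(table.organ == "lung") & (table.metric == "dasu_total_pct")]
print(lung[["3DCRT_median", "IMRT_median", "PBS_median", "p_pbs_vs_3dcrt"]])
#    3DCRT_median  IMRT_median  PBS_median  p_pbs_vs_3dcrt
# 9      0.508883     0.587263    0.268075        0.000015
```

The uniform 2 Gy lung exposure carries a 2.09 % modelled total SM risk; its
OED is 1.55 Gy. In the synthetic cohort the proton plans roughly halve the
median lung risk relative to both photon techniques, and with 17 paired
patients the exact signed-rank p-value (1.5 × 10⁻⁵) is the smallest
attainable two-tailed value, while the thyroid — generated identically for
all modalities — stays non-significant.

The same pipeline runs from the shell:

```bash
smrisk simulate --n 17 --seed 1 --out cohort/       # DVH tables + manifest
smrisk compare --manifest cohort/manifest.json --out report/
smrisk run --simulate --n 17 --seed 1 --out report/ # one-shot pipeline
```

Real DVHs enter the same way: two-column `dose_gy, volume` tables
(cumulative or differential, relative or absolute volumes) referenced by a
small JSON/YAML cohort manifest — see `smrisk.dvh_io` for the format.

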