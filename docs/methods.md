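# Methods

## Scope and data model

The package estimates radiation-induced secondary-malignancy (SM) risk per
organ from dose–volume histograms and compares treatment modalities across
a paired patient cohort. The canonical internal object is the
*differential* DVH with relative volumes: bin `i` holds the organ volume
fraction `v_i` receiving total dose `D_i` (Gy) over `n` fractions. Both
risk models are volume-weighted sums over dose bins, so cumulative or
absolute-volume input is converted once at load time:

* cumulative → differential by successive decrements, with the bin dose at
  the interval midpoint (second-order accurate; re-accumulating the output
  reproduces the input exactly);
* absolute volumes divided by their total;
* unirradiated volume kept explicitly as a zero-dose bin. Both models
  normalize by the *whole* organ volume, so dropping spared volume would
  bias every risk upward — for proton plans, which spare large volumes
  entirely, this is the dominant failure mode of naive DVH handling.

Doses are always Gy; other units are converted only through an explicit
`dose_scale` argument, never guessed. DICOM-RT is out of scope; the
documented two-column table plus JSON/YAML cohort manifest is the
interchange contract.

## Competition (Dasu) model

    Risk = (1/Σ v_i) Σ v_i (α₁D_i + β₁D_i²/n) · exp(−(α₂D_i + β₂D_i²/n))

Assumptions: linear-quadratic induction of carcinogenic mutations
(coefficients α₁, β₁) competing with linear-quadratic sterilization of
mutated cells (α₂, β₂); uniform fractionation, so the per-fraction dose in
bin `i` is `D_i/n` and the quadratic terms carry `D_i²/n`; bins respond
independently; no repopulation, repair kinetics, age or sex modifiers, and
no secondary-particle (neutron) dose.

Parameters:

| parameter | unit | default | meaning |
|---|---|---|---|
| α₁ (total) | Gy⁻¹ | per organ (see below) | induction coefficient, any cancer |
| α₁ (fatal) | Gy⁻¹ | per organ | induction coefficient, fatal cancer |
| α₂ | Gy⁻¹ | 0.25 | cell-kill coefficient |
| α/β | Gy | 3 | ratio tying β_k = α_k/(α/β), organs at risk |

Shipped α₁ values (fatal / total, ICRP 103 risk coefficients): lung
0.0101 / 0.0144, breast 0.0028 / 0.0144, esophagus 0.0014 / 0.0015,
thyroid 0.0028 / 0.0144. Breast and thyroid share coefficients but are
distinct registry entries so organ lookup stays explicit; lateralized
names (`breast_left`, `breast_right`) resolve to the base entry.

α₂ is not organ-resolved in the ICRP coefficient tables. The registry uses
0.25 Gy⁻¹ — the value used in the competition-model literature — for every
organ, and the resolved value is materialized into every emitted run
manifest so it is a named, logged parameter rather than a buried constant.
One α/β ratio serves both the induction and the kill term; no second ratio
is defensible from the available coefficient sets. Output is ×100
(percent). With α₂ = 0.25 Gy⁻¹ the uniform-dose response peaks near 4 Gy
at roughly 2 % per unit volume, so organ-level risks are dominated by the
low/intermediate-dose bath, not by the target-dose region.

## Organ-equivalent-dose (Schneider) model

    OED  = Σ v_i D_i e^(−α_org D_i) / Σ v_i        [Gy]
    I    = I0 · OED · e^(−α_org OED)

The equal-volume point sum of the OED definition is implemented as the
volume-fraction-weighted bin sum — DVH bins are the available
discretization of equal-volume dose points. Shipped coefficients
(I0 per 10,000 patients/year/Gy; α_org Gy⁻¹): lung 1.68 / 0.129, breast
0.78 / 0.08, esophagus 0.61 / 0.274, thyroid 0.75 / 0.033.

Two deliberate fidelity choices:

* The incidence formula applies the sterilization exponential a second
  time, to the OED itself. Part of the OED literature uses the plain
  linear form `I = I0·OED`. Both are implemented behind
  `incidence_form` (`as_printed`, the default, vs `linear_in_oed`) so the
  discrepancy is surfaced as a switch instead of silently resolved. For
  the OED ranges the shipped cohorts produce (≤ 1/(α_org·e)) the two
  forms are monotonically related, so comparison p-values are unaffected.
* No fractionation, repair or repopulation correction is applied in the
  OED stage: the linear-exponential form used here has none. The fuller
  mechanistic OED family with repopulation parameters is out of scope.
* The incidence is reported with the I0 unit label ("per 10,000 patients
  per year per Gy"); the label is registry metadata, the number is the
  formula's output. The dimensional tension between that label and the
  OED-multiplied formula is a known ambiguity of the source coefficient
  set, noted rather than resolved.

## Synthetic cohort generator

Clinical plan libraries of this kind cannot be shared, so pipeline-level
behaviour is validated on synthetic cohorts that encode the *qualitative*
dosimetric structure of comparative thoracic planning:

* each DVH is drawn on a 0.5 Gy grid from 0 to 1.1 × prescription as a
  three-part mixture: a zero-dose spared bin; a broad low-dose Beta bath
  on [0, Rx] with mean `bath_dose_fraction·Rx` and concentration
  `shape_concentration`; and a narrow near-prescription Beta peak on
  [0.85, 1.05]·Rx whose mean is exactly the prescription;
* PBS profiles spare large volume fractions of lungs, breasts and
  esophagus; photon profiles expose most of the organ to the bath, IMRT
  slightly more volume at slightly lower level than 3DCRT; the thyroid
  uses one shared profile object for all three modalities and is therefore
  an exact distributional null;
* prescriptions are drawn from the empirical support of the study cohort
  (45–66 Gy in 25–33 fractions, median 54 Gy/27 fx), identical across one
  patient's three plans;
* one latent anatomy effect per patient (normal, σ = 0.4) lowers the
  spared fraction on the logit scale and scales the bath level by
  `exp(0.25·z)` for all of that patient's plans, producing the positive
  within-patient correlation a signed-rank comparison requires.

Randomness is organized as named substreams keyed by seed, patient index,
organ name and modality (names hashed by CRC-32), so adding an organ to a
spec perturbs no other organ's draws and a seed reproduces a cohort
bit-for-bit.

All numeric profile defaults (`src/smrisk/data/default_profiles.yaml`) are
synthetic calibration values, not measurements. What the generator does
*not* emulate: real DVH shapes, anatomical correlation between organs,
inter-center planning differences, motion effects, or absolute clinical
risk levels. Passing pipeline tests therefore demonstrates correct model
arithmetic, pairing and statistics under realistic magnitudes — not
agreement with any patient's risk.

## Statistical comparison

Two-tailed Wilcoxon signed-rank per organ, metric and modality pair. Zero
differences are dropped before ranking (classical convention; exposed as
`zero_method`). With ≤ 25 informative pairs the exact permutation
distribution of the rank sum is computed by convolution — valid with
midranks under ties; counts are exact in double precision for these n —
and above that a tie-corrected normal approximation without continuity
correction is used. The threshold is exposed (`exact_threshold`); the
default cohort size of 17 always takes the exact path, where the smallest
attainable two-tailed p is 2/2¹⁷ ≈ 1.5 × 10⁻⁵. All differences zero is a
defined degenerate case (p = 1, flagged), not an exception. No
multiple-testing correction is applied across organs, metrics or pairs:
each cell reports its raw p-value, matching how such comparison tables are
conventionally presented.

Medians and ranges (min–max) are computed from exactly the per-patient
values entering the tests.

## Numerical choices and degenerate inputs

* Normalization tolerance on volume fractions: 1e-9; risk functions refuse
  unnormalized DVHs rather than renormalizing silently.
* Equal or duplicated bin doses are legal (bin splitting is used to test
  refinement invariance; all metrics are invariant to 1e-12 by
  construction since they are volume-weighted sums).
* Fully spared organs are a single zero-dose bin; every metric is exactly 0.
* Exact signed-rank convolution doubles midranks to integers; two-tailed
  p = min(1, 2·min(P(W ≤ w), P(W ≥ w))).

## Validation problem sizes

The test suite validates each model against independent closed-form
single-term evaluations (1e-9 relative), Monte-Carlo voxel-resampling
oracles (20 random multi-bin DVHs × 10⁶ draws, 3-standard-error
agreement), brute-force enumeration of all 2ⁿ sign assignments for the
signed-rank test (n ≤ 12, exact equality), a 2,000-cohort null simulation
of the type-I error (empirical rate within [0.03, 0.07] at α = 0.05), and
qualitative-structure recovery over default cohorts with seeds 1–10
(significant PBS-vs-photon reductions for lung, breasts and esophagus and
a non-significant thyroid in at least 9 of 10 seeds — the thyroid is a
true null, so occasional 5%-level rejections are expected).

## Known limitations

* Organ-level SM risk models of this family are order-of-magnitude tools;
  absolute risks depend strongly on the unresolved α₂ and on coefficient
  provenance, and should be read comparatively, not as predictions.
* The OED stage ignores fractionation; comparing plans with very different
  fractionation schedules through the OED metric alone is not supported
  by the model form used here.
* The generator's paired effect is a single scalar per patient; real
  anatomy induces organ-specific, geometry-driven correlation structure.
* Exact Wilcoxon p-values are permutation-exact given the observed ranks;
  with heavy ties the test's discreteness makes nominal and attainable
  levels diverge, which the type-I simulation quantifies for the shipped
  generator.
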