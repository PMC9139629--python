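# Synthetic-calibration DVH profiles for the default cohort generator.
#
# These numbers are NOT clinical measurements.  They encode the
# qualitative dosimetric contrasts of comparative thoracic planning with
# anterior proton beams versus photon techniques:
#   * PBS spares a large volume fraction of lungs, breasts and esophagus
#     entirely (large spared_fraction), while the dose level in the
#     exposed bath is broadly similar across modalities;
#   * IMRT exposes the largest volume to the low/intermediate-dose bath
#     (smallest spared_fraction, broadest bath: lowest concentration);
#   * the thyroid lies outside the anterior beam arrangement for every
#     modality, so one shared profile ("all") makes it an exact
#     distributional null across modalities.
#
# Fields per profile (all fractions dimensionless, intervals sampled
# uniformly per plan):
#   spared_fraction_range    : organ volume fraction at ~0 dose
#   bath_dose_fraction_range : mean bath dose as a fraction of the Rx dose
#   high_dose_fraction_range : share of exposed volume near the Rx dose
#   shape_concentration      : Beta concentration of the bath (small = broad)

lung:
  3DCRT:
    spared_fraction_range: [0.25, 0.40]
    bath_dose_fraction_range: [0.10, 0.20]
    high_dose_fraction_range: [0.08, 0.15]
    shape_concentration: 2.5
  IMRT:
    spared_fraction_range: [0.08, 0.20]
    bath_dose_fraction_range: [0.08, 0.16]
    high_dose_fraction_range: [0.05, 0.12]
    shape_concentration: 2.0
  PBS:
    spared_fraction_range: [0.60, 0.80]
    bath_dose_fraction_range: [0.10, 0.20]
    high_dose_fraction_range: [0.08, 0.15]
    shape_concentration: 2.5

breast_left:
  3DCRT:
    spared_fraction_range: [0.05, 0.25]
    bath_dose_fraction_range: [0.12, 0.25]
    high_dose_fraction_range: [0.05, 0.15]
    shape_concentration: 2.5
  IMRT:
    spared_fraction_range: [0.05, 0.20]
    bath_dose_fraction_range: [0.10, 0.20]
    high_dose_fraction_range: [0.03, 0.10]
    shape_concentration: 2.0
  PBS:
    spared_fraction_range: [0.60, 0.85]
    bath_dose_fraction_range: [0.10, 0.22]
    high_dose_fraction_range: [0.02, 0.10]
    shape_concentration: 2.5

breast_right:
  3DCRT:
    spared_fraction_range: [0.05, 0.25]
    bath_dose_fraction_range: [0.12, 0.25]
    high_dose_fraction_range: [0.05, 0.15]
    shape_concentration: 2.5
  IMRT:
    spared_fraction_range: [0.05, 0.20]
    bath_dose_fraction_range: [0.10, 0.20]
    high_dose_fraction_range: [0.03, 0.10]
    shape_concentration: 2.0
  PBS:
    spared_fraction_range: [0.60, 0.85]
    bath_dose_fraction_range: [0.10, 0.22]
    high_dose_fraction_range: [0.02, 0.10]
    shape_concentration: 2.5

esophagus:
  3DCRT:
    spared_fraction_range: [0.05, 0.20]
    bath_dose_fraction_range: [0.15, 0.30]
    high_dose_fraction_range: [0.15, 0.30]
    shape_concentration: 2.5
  IMRT:
    spared_fraction_range: [0.03, 0.15]
    bath_dose_fraction_range: [0.12, 0.25]
    high_dose_fraction_range: [0.12, 0.28]
    shape_concentration: 2.0
  PBS:
    spared_fraction_range: [0.45, 0.75]
    bath_dose_fraction_range: [0.12, 0.25]
    high_dose_fraction_range: [0.10, 0.25]
    shape_concentration: 2.5

thyroid:
  all:
    spared_fraction_range: [0.30, 0.80]
    bath_dose_fraction_range: [0.05, 0.25]
    high_dose_fraction_range: [0.00, 0.05]
    shape_concentration: 1.5
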