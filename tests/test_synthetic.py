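import numpy as np
import pytest
from scipy import stats

from smrisk import CohortSpec, generate_cohort, generate_dvh
from smrisk.dasu import dasu_risk, default_dasu_registry, lookup_organ
from smrisk.errors import ConfigurationError
from smrisk.synthetic import (
    DEFAULT_PRESCRIPTIONS,
    ModalityDvhProfile,
    default_profiles,
    expected_mean_dose,
    load_profiles,
)


@pytest.fixture(scope="module")
def profiles():
    return default_profiles()


class TestGenerateDvh:
    def test_same_seed_is_bit_identical(self, profiles):
        prof = profiles[("3DCRT", "lung")]
        a = generate_dvh(prof, 54.0, 27, np.random.default_rng(5))
        b = generate_dvh(prof, 54.0, 27, np.random.default_rng(5))
        np.testing.assert_array_equal(a.bin_dose, b.bin_dose)
        np.testing.assert_array_equal(a.bin_volume_fraction, b.bin_volume_fraction)

    def test_output_is_valid_normalized_dvh(self, profiles):
        rng = np.random.default_rng(8)
        for key, prof in profiles.items():
            dvh = generate_dvh(prof, 50.0, 25, rng)
            assert dvh.is_normalized(1e-9)
            assert np.all(np.diff(dvh.bin_dose) > 0)
            assert dvh.n_fractions == 25

    def test_full_sparing_yields_single_zero_bin_and_zero_risk(self):
        prof = ModalityDvhProfile(
            modality="PBS",
            organ_name="esophagus",
            spared_fraction_range=(1.0, 1.0),
            bath_dose_fraction_range=(0.1, 0.2),
            high_dose_fraction_range=(0.1, 0.2),
        )
        dvh = generate_dvh(prof, 54.0, 27, np.random.default_rng(0))
        assert dvh.n_bins == 1
        assert dvh.bin_dose[0] == 0.0
        params = lookup_organ(default_dasu_registry(), "esophagus")
        assert dasu_risk(dvh, params) == 0.0

    def test_mean_dose_matches_analytic_expectation(self, profiles):
        # grand mean over many draws vs the expectation of the mixture
        prof = profiles[("3DCRT", "lung")]
        rng = np.random.default_rng(42)
        means = np.array(
            [generate_dvh(prof, 54.0, 27, rng).mean_dose for _ in range(10_000)]
        )
        se = means.std(ddof=1) / np.sqrt(means.size)
        assert abs(means.mean() - expected_mean_dose(prof, 54.0)) < 3 * se

    def test_invalid_prescription_rejected(self, profiles):
        with pytest.raises(ConfigurationError):
            generate_dvh(profiles[("PBS", "lung")], 0.0, 25, np.random.default_rng(0))


class TestGenerateCohort:
    def test_cardinality(self, profiles):
        cohort = generate_cohort(CohortSpec(n_patients=17, seed=1), profiles)
        assert len(cohort.patients) == 17
        n_dvhs = sum(
            len(organs)
            for mods in cohort.plans.values()
            for organs in mods.values()
        )
        assert n_dvhs == 17 * 3 * 5

    def test_seed_reproduces_whole_cohort(self, profiles):
        a = generate_cohort(CohortSpec(n_patients=4, seed=9), profiles)
        b = generate_cohort(CohortSpec(n_patients=4, seed=9), profiles)
        for pid in a.patients:
            for mod in a.plans[pid]:
                for organ, dvh in a.plans[pid][mod].items():
                    other = b.plans[pid][mod][organ]
                    np.testing.assert_array_equal(dvh.bin_dose, other.bin_dose)
                    np.testing.assert_array_equal(
                        dvh.bin_volume_fraction, other.bin_volume_fraction
                    )

    def test_adding_an_organ_leaves_other_draws_untouched(self, profiles):
        small = generate_cohort(CohortSpec(n_patients=3, seed=2, organs=("lung",)), profiles)
        big = generate_cohort(
            CohortSpec(n_patients=3, seed=2, organs=("lung", "esophagus")), profiles
        )
        for pid in small.patients:
            for mod in small.plans[pid]:
                np.testing.assert_array_equal(
                    small.plans[pid][mod]["lung"].bin_volume_fraction,
                    big.plans[pid][mod]["lung"].bin_volume_fraction,
                )

    def test_prescriptions_drawn_from_empirical_support(self, profiles):
        cohort = generate_cohort(CohortSpec(n_patients=17, seed=3), profiles)
        support = set(DEFAULT_PRESCRIPTIONS)
        for pid in cohort.patients:
            metas = cohort.meta[pid]
            pairs = {
                (m.prescription_dose, m.n_fractions) for m in metas.values()
            }
            assert len(pairs) == 1  # same prescription across modalities
            assert pairs <= support

    def test_patient_effect_induces_paired_correlation(self, profiles):
        # latent anatomy effect is shared across a patient's plans, so
        # organ mean dose must rank-correlate positively across modalities
        cohort = generate_cohort(CohortSpec(n_patients=60, seed=3), profiles)
        a = [cohort.plans[p]["3DCRT"]["lung"].mean_dose for p in cohort.patients]
        b = [cohort.plans[p]["PBS"]["lung"].mean_dose for p in cohort.patients]
        assert stats.spearmanr(a, b).statistic > 0

    def test_missing_profile_rejected(self, profiles):
        with pytest.raises(ConfigurationError):
            generate_cohort(CohortSpec(n_patients=3, seed=1, organs=("heart",)), profiles)

    def test_too_small_cohort_rejected(self):
        with pytest.raises(ConfigurationError):
            CohortSpec(n_patients=1)


class TestDefaultProfiles:
    def test_thyroid_profile_is_shared_across_modalities(self, profiles):
        # one object for all three modalities: an exact distributional null
        assert profiles[("3DCRT", "thyroid")] is profiles[("IMRT", "thyroid")]
        assert profiles[("IMRT", "thyroid")] is profiles[("PBS", "thyroid")]

    def test_pbs_spares_more_lung_than_photons(self, profiles):
        pbs = profiles[("PBS", "lung")].spared_fraction_range
        for photon in ("3DCRT", "IMRT"):
            assert pbs[0] > profiles[(photon, "lung")].spared_fraction_range[1]

    def test_profile_registry_covers_all_default_cells(self, profiles):
        from smrisk.dvh_io import MODALITIES
        from smrisk.synthetic import DEFAULT_ORGANS

        for organ in DEFAULT_ORGANS:
            for modality in MODALITIES:
                assert (modality, organ) in profiles

    def test_yaml_override_loading(self, tmp_path):
        path = tmp_path / "profiles.yaml"
        path.write_text(
            "lung:\n  all:\n"
            "    spared_fraction_range: [0.1, 0.2]\n"
            "    bath_dose_fraction_range: [0.1, 0.2]\n"
            "    high_dose_fraction_range: [0.0, 0.1]\n"
        )
        reg = load_profiles(str(path))
        assert reg[("PBS", "lung")].spared_fraction_range == (0.1, 0.2)

    def test_invalid_range_rejected(self):
        with pytest.raises(ConfigurationError):
            ModalityDvhProfile(
                modality="PBS",
                organ_name="lung",
                spared_fraction_range=(0.5, 0.2),
                bath_dose_fraction_range=(0.1, 0.2),
                high_dose_fraction_range=(0.0, 0.1),
            )
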