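"""Synthetic cohort generator: determinism, composition, round-trips, calibration."""

import numpy as np
import pytest
from scipy import stats as sps

from sarcimmune.synthetic import (CohortConfig, SUBTYPE_COUNTS, cohorts_equal,
                                  generate_cohort, read_cohort, write_cohort)

from conftest import NULL_HAZARD, ZERO_MUTATIONS


class TestConfigValidation:
    def test_zero_patients_rejected(self):
        with pytest.raises(ValueError, match="n_patients"):
            CohortConfig(n_patients=0)

    def test_bad_weights(self):
        with pytest.raises(ValueError, match="sum to 1"):
            CohortConfig(subtype_weights={"OS": 0.5, "ES": 0.4})

    def test_bad_censoring(self):
        with pytest.raises(ValueError, match="censoring"):
            CohortConfig(censoring_rate=1.5)

    def test_bad_distribution_parameters(self):
        with pytest.raises(ValueError, match="ap_score"):
            CohortConfig(ap_score_distribution={"low_alpha": -1.0, "low_beta": 2.0,
                                                "high_alpha": 5.0, "high_beta": 1.5,
                                                "high_weight_alpha": 2.0,
                                                "high_weight_beta": 8.0})

    def test_config_round_trips_via_dict(self):
        cfg = CohortConfig(seed=9)
        assert CohortConfig.from_dict(cfg.to_dict()) == cfg


class TestGeneration:
    def test_determinism_across_three_runs(self):
        cohorts = [generate_cohort(CohortConfig(seed=42)) for _ in range(3)]
        assert cohorts_equal(cohorts[0], cohorts[1])
        assert cohorts_equal(cohorts[1], cohorts[2])

    def test_default_composition_matches_trial(self, default_cohort):
        counts = default_cohort.clinical["subtype"].value_counts().to_dict()
        assert counts == SUBTYPE_COUNTS
        sts = default_cohort.clinical.subtype.isin(["SS", "LMS", "DDLPS", "UPS"]).sum()
        assert (sts, len(default_cohort.clinical) - sts) == (13, 18)

    def test_survival_times_positive_and_truth_consistent(self, default_cohort):
        assert (default_cohort.clinical.pfs_days > 0).all()
        assert set(default_cohort.clinical.event.unique()) <= {0, 1}
        cfg = CohortConfig.from_dict(default_cohort.truth["config"])
        assert cfg.seed == 7
        assert cohorts_equal(default_cohort, generate_cohort(cfg))

    def test_tables_reference_existing_patients(self, default_cohort):
        pids = set(default_cohort.clinical.patient_id)
        for name in ["variants", "fusions", "candidates", "tpm", "hla",
                     "cell_fractions", "mixtures"]:
            table = getattr(default_cohort, name)
            assert set(table.patient_id) <= pids

    def test_cell_fractions_on_simplex(self, default_cohort):
        vals = default_cohort.cell_fractions.drop(columns="patient_id").to_numpy()
        assert np.all(vals >= 0)
        np.testing.assert_allclose(vals.sum(axis=1), 1.0, atol=1e-9)

    def test_ap_scores_in_unit_interval(self, default_cohort):
        s = default_cohort.candidates.ap_score
        assert ((s >= 0) & (s <= 1)).all()


class TestRoundTrip:
    def test_write_read_equality(self, default_cohort, tmp_path):
        write_cohort(default_cohort, tmp_path / "cohort")
        back = read_cohort(tmp_path / "cohort")
        assert cohorts_equal(default_cohort, back)

    def test_vcf_mirror_matches_tsv(self, default_cohort, tmp_path):
        from sarcimmune.io import read_variants_vcf, apply_schema, VARIANT_COLUMNS

        write_cohort(default_cohort, tmp_path / "cohort")
        pid = default_cohort.clinical.patient_id.iloc[0]
        tsv = default_cohort.variants[default_cohort.variants.patient_id == pid]
        tsv = apply_schema(tsv, VARIANT_COLUMNS)
        vcf = read_variants_vcf(tmp_path / "cohort" / "vcf" / f"{pid}.vcf", pid)
        vcf = vcf.sort_values("variant_id").reset_index(drop=True)
        tsv = tsv.sort_values("variant_id").reset_index(drop=True)
        for col in ["variant_id", "chrom", "pos", "ref", "alt", "n_callers",
                    "depth_tumor", "alt_reads_tumor", "consequence", "phase_set",
                    "transcript_ids", "protein_id", "aa_ref", "aa_alt", "fs_tail"]:
            assert list(vcf[col]) == list(tsv[col]), col
        np.testing.assert_allclose(vcf.vaf_dna, tsv.vaf_dna, atol=1e-12)

    def test_one_patient_zero_variants(self, tmp_path):
        cfg = CohortConfig(n_patients=1, subtype_weights={"OS": 1.0},
                           mutation_rate_ranges=ZERO_MUTATIONS, seed=3)
        cohort = generate_cohort(cfg)
        assert len(cohort.variants) == 0
        write_cohort(cohort, tmp_path / "c")
        back = read_cohort(tmp_path / "c")
        assert cohorts_equal(cohort, back)
        assert list(back.variants.columns) == list(cohort.variants.columns)


class TestPlantedStructure:
    def test_null_model_marginal_calibration(self):
        """No censoring, all hazard coefficients zero: 10,000 PFS draws follow
        the baseline exponential within KS distance 0.02."""
        cfg = CohortConfig(n_patients=10_000, censoring_rate=0.0,
                           hazard_coefficients=dict(NULL_HAZARD),
                           mutation_rate_ranges=ZERO_MUTATIONS,
                           n_proteins=2, seed=11)
        cohort = generate_cohort(cfg)
        lam0 = np.log(2.0) / cfg.baseline_median_pfs
        ks = sps.kstest(cohort.clinical.pfs_days.to_numpy(), "expon",
                        args=(0, 1 / lam0))
        assert ks.statistic < 0.02

    def test_censoring_rate_controls_event_fraction(self):
        cfg = CohortConfig(n_patients=2000, censoring_rate=0.4,
                           mutation_rate_ranges=ZERO_MUTATIONS,
                           n_proteins=2, seed=5)
        cohort = generate_cohort(cfg)
        censored = 1 - cohort.clinical.event.mean()
        assert censored == pytest.approx(0.4, abs=0.03)

    def test_protective_interaction_lengthens_hh_survival(self):
        """beta_int < 0 lowers the hazard only of the doubly-high stratum."""
        cfg = CohortConfig(n_patients=600, censoring_rate=0.0, seed=21,
                           hazard_coefficients={"t_cell_fraction": 0.0,
                                                "neoantigen_quality": 0.0,
                                                "interaction": -1.0})
        cohort = generate_cohort(cfg)
        tc = np.asarray(list(cohort.truth["t_cell_fraction"].values()))
        q = np.asarray(list(cohort.truth["neoantigen_quality"].values()))
        t = cohort.clinical.pfs_days.to_numpy()
        hh = (tc > np.median(tc)) & (q > np.median(q))
        assert np.median(t[hh]) > 1.5 * np.median(t[~hh])
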