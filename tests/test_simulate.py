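"""Generator: exact composition, determinism, calibration, rank consistency."""

import numpy as np
import pytest
from scipy.special import ndtri

import mrmcroc as m
from mrmcroc.simulate import (DEFAULT_FINDING_MARGINS, calibrate_mu,
                              generate_ratings, generate_truth, mode_mu,
                              population_observed_auc)


class TestComposition:
    def test_default_study_matches_reference_margins(self, default_study):
        truths = default_study.truths
        assert len(truths) == 388
        by_truth = {c: sum(t.truth == c for t in truths)
                    for c in ("malignant", "benign_biopsy", "normal_negative")}
        assert by_truth == {"malignant": 84, "benign_biopsy": 83,
                            "normal_negative": 221}
        for ft, (nm, nb) in DEFAULT_FINDING_MARGINS.items():
            assert sum(t.finding_type == ft and t.is_positive
                       for t in truths) == nm
            assert sum(t.finding_type == ft and t.truth == "benign_biopsy"
                       for t in truths) == nb
        assert sum(t.density == "non_dense" for t in truths) == 206

    def test_every_patient_has_two_sides(self, default_study):
        sides = {}
        for t in default_study.truths:
            sides.setdefault(t.patient_id, set()).add(t.side)
        assert len(sides) == 194
        assert all(v == {"left", "right"} for v in sides.values())

    def test_scaled_composition_is_exact(self):
        cfg = m.SimConfig.with_composition(2, 2, 16, n_patients=10,
                                           modes=("DM",), seed=1)
        truths = generate_truth(cfg)
        assert len(truths) == 20
        assert sum(t.is_positive for t in truths) == 2
        assert sum(t.truth == "benign_biopsy" for t in truths) == 2

    def test_infeasible_composition_rejected(self):
        with pytest.raises(m.ConfigError, match="composition"):
            m.SimConfig(n_patients=5)  # margins demand 388 breasts

    def test_lesion_fields_consistent(self, default_study):
        for t in default_study.truths:
            if t.finding_type == "none":
                assert t.lesion_size_mm is None
            else:
                assert t.lesion_size_mm > 0


class TestRatings:
    def test_full_grid_of_ratings_emitted(self, default_study):
        assert len(default_study.ratings) == 388 * 4 * 4
        rep = m.validate_completeness(default_study)
        assert rep.is_complete
        assert rep.session_report_count == 3104

    def test_pom_present_iff_birads_suspicious(self, small_study):
        for r in small_study.ratings:
            assert (r.pom is not None) == (r.bi_rads >= 3)

    def test_seed_determinism(self, small_cfg):
        a = m.generate_study(small_cfg)
        b = m.generate_study(small_cfg)
        assert a.truths == b.truths and a.ratings == b.ratings
        c = m.generate_study(small_cfg.with_seed(small_cfg.seed + 1))
        assert c.ratings != a.ratings

    def test_pom_rank_consistent_with_latent_score(self, small_cfg):
        truths = generate_truth(small_cfg)
        records, latent = generate_ratings(truths, small_cfg,
                                           return_latent=True)
        idx = {t.case_id: i for i, t in enumerate(truths)}
        modes = list(small_cfg.modes)
        for rdr in range(small_cfg.n_readers):
            for j, mode in enumerate(modes):
                recs = [r for r in records
                        if r.reader_id == f"R{rdr + 1}" and r.mode == mode
                        and r.bi_rads >= 3]
                order = np.argsort([latent[rdr, idx[r.case_id], j]
                                    for r in recs], kind="stable")
                poms = np.array([r.pom for r in recs])[order]
                assert (np.diff(poms) >= 0).all()

    def test_config_round_trips_through_dict(self, small_cfg):
        again = m.SimConfig.from_dict(small_cfg.to_dict())
        assert again == small_cfg


class TestCalibration:
    def test_null_target_gives_zero_shift(self):
        assert calibrate_mu(0.5) == pytest.approx(0.0, abs=1e-12)

    def test_binormal_closed_form_with_unit_variance(self):
        expected = np.sqrt(2.0) * ndtri(0.76)
        assert calibrate_mu(0.76) == pytest.approx(expected, rel=1e-9)

    def test_target_out_of_range_rejected(self):
        with pytest.raises(m.ConfigError):
            calibrate_mu(0.3)
        with pytest.raises(m.ConfigError):
            calibrate_mu(1.0)

    def test_population_auc_monotone_in_shift(self):
        kw = dict(var_case=0.6, var_interaction=0.2, var_resid=1.0,
                  var_reader=0.02, benign_shift=0.3, benign_weight=0.27,
                  cutpoints=(0.5, 1.3))
        aucs = [population_observed_auc(mu, **kw) for mu in (0.5, 1.5, 2.5, 3.5)]
        assert all(a < b for a, b in zip(aucs, aucs[1:]))

    def test_censored_calibration_inverts_population_auc(self):
        kw = dict(var_case=0.6, var_interaction=0.2, var_resid=1.0,
                  var_reader=0.02, benign_shift=0.3, benign_weight=0.27,
                  cutpoints=(0.5, 1.3))
        mu = calibrate_mu(0.88, **kw)
        assert population_observed_auc(mu, **kw) == pytest.approx(0.88,
                                                                  abs=1e-8)

    def test_simulated_auc_recovers_target(self):
        # single reader, large case set: empirical POM AUC ~ population target
        cfg = m.SimConfig.with_composition(
            300, 300, 800, n_patients=700, modes=("DM",), n_readers=1,
            target_auc={"DM": 0.85}, seed=21)
        vals = []
        for s in range(6):
            ds = m.generate_study(cfg.with_seed(100 + s))
            _, mean = m.reader_auc_table(ds, "DM", "pom")
            vals.append(mean)
        assert np.mean(vals) == pytest.approx(0.85, abs=0.012)

    def test_mode_mu_orders_with_targets(self):
        mus = mode_mu(m.SimConfig())
        assert mus["DM"] < mus["DM_DBT"] < mus["AICAD_SM_DBT"]
        assert mus["DM"] < mus["AICAD_SM"]
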