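import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ligphore as lp
from ligphore.hypothesis_engine import (
    calibrate,
    calibrate_regression,
    full_map,
    select_leads,
    superpose,
)
from ligphore.synthetic_data import plant_hypothesis

from conftest import cloud_from, square_hypothesis, typed_rmsd_to
from oracles import grid_superpose_rmsd, mapping_oracle


class TestSuperpose:
    def test_identical_points_identity_transform(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [0, 2, 0]], dtype=float)
        t, rmsd = superpose(pts, pts)
        assert rmsd == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(t.rotation, np.eye(3), atol=1e-9)
        np.testing.assert_allclose(t.translation, 0.0, atol=1e-9)

    def test_translation_is_removed(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [0, 2, 0]], dtype=float)
        _t, rmsd = superpose(pts, pts + [1.0, 0.0, 0.0])
        assert rmsd == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_rotation_grid_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=(4, 3)) * 3
        b = a @ _random_rotation(rng).T + rng.normal(size=3) + rng.normal(
            scale=0.2, size=(4, 3)
        )
        _t, rmsd = superpose(a, b)
        assert rmsd == pytest.approx(grid_superpose_rmsd(a, b), abs=1e-3)

    def test_no_reflection(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=(5, 3))
        b = a.copy()
        b[:, 0] *= -1  # mirrored target must not yield det(R) = -1
        t, _ = superpose(a, b)
        assert np.linalg.det(t.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            superpose(np.zeros((3, 3)), np.zeros((4, 3)))


def _random_rotation(rng):
    from scipy.spatial.transform import Rotation

    return Rotation.random(rng=rng).as_matrix()


def _random_instance(rng, n_cloud, k):
    types = ["HBA", "HBD", "HY", "RA"]
    hyp = [
        (types[i % 4] if k <= 4 else str(rng.choice(types)),
         rng.uniform(-4, 4, 3), float(rng.uniform(0.8, 2.2)),
         float(rng.uniform(0.5, 3.0)))
        for i in range(k)
    ]
    cloud = [(str(rng.choice(types)), rng.uniform(-5, 5, 3)) for _ in range(n_cloud)]
    return hyp, cloud


def _to_engine(hyp, cloud):
    h = lp.Hypothesis(
        [lp.PharmacophoreFeature(t, p, tol, w) for t, p, tol, w in hyp]
    )
    fc = lp.FeatureCloud("x", 0, [lp.Feature(t, p) for t, p in cloud])
    return h, fc


class TestMapping:
    def test_exact_copy_maps_perfectly(self, engine_cfg):
        h = square_hypothesis()
        mr = lp.map_to_hypothesis([cloud_from(h)], h, engine_cfg)
        assert len(mr.correspondence) == 4 and not mr.omitted
        np.testing.assert_allclose(mr.displacements, 0.0, atol=1e-9)
        assert mr.fit == pytest.approx(h.total_weight())

    def test_missing_donor_is_omitted(self, engine_cfg):
        h = square_hypothesis(types=("HBA", "HBD", "HY", "RA"))
        cloud = cloud_from(h)
        hbd_idx = next(i for i, f in enumerate(h.features) if f.ftype == "HBD")
        cloud.features = [f for f in cloud.features if f.ftype != "HBD"]
        mr = lp.map_to_hypothesis([cloud], h, engine_cfg)
        assert len(mr.correspondence) == 3
        assert mr.omitted == [hbd_idx]
        assert mr.fit == pytest.approx(6.0)

    def test_unmappable_cloud_returns_fit_zero(self, engine_cfg):
        h = square_hypothesis(types=("HBA", "HBD", "HY", "RA"))
        cloud = lp.FeatureCloud("x", 0, [lp.Feature("RA", np.zeros(3))])
        mr = lp.map_to_hypothesis([cloud], h, engine_cfg)
        assert not mr.mapped and mr.fit == 0.0

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_bruteforce_enumeration_oracle(self, seed, engine_cfg):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(3, 5))
        hyp, cloud = _random_instance(rng, int(rng.integers(3, 9)), k)
        h, fc = _to_engine(hyp, cloud)
        mr = lp.map_to_hypothesis([fc], h, engine_cfg)
        fit_oracle, corr_oracle = mapping_oracle(
            [cloud], hyp, engine_cfg.max_omitted
        )
        assert mr.fit == pytest.approx(fit_oracle, abs=1e-9)
        assert tuple(mr.correspondence) == corr_oracle

    def test_fit_bounded_by_total_weight(self, engine_cfg):
        rng = np.random.default_rng(99)
        for _ in range(20):
            hyp, cloud = _random_instance(rng, 7, 4)
            h, fc = _to_engine(hyp, cloud)
            mr = lp.map_to_hypothesis([fc], h, engine_cfg)
            assert -1e-12 <= mr.fit <= h.total_weight() + 1e-12


class TestFitFormula:
    def test_zero_displacement_gives_weight_sum(self):
        h = square_hypothesis()
        mr = lp.MappingResult(
            [(i, i) for i in range(4)], [], None, np.zeros(4), 0.0, 0, 0.0
        )
        assert lp.compute_fit(mr, h) == pytest.approx(8.0)

    def test_displacement_at_tolerance_contributes_nothing(self):
        h = square_hypothesis(tolerance=1.6)
        mr = lp.MappingResult(
            [(0, 0)], [1, 2, 3], None, np.array([1.6]), 0.0, 0, 0.0
        )
        assert lp.compute_fit(mr, h) == pytest.approx(0.0)

    def test_half_tolerance_contribution(self):
        h = square_hypothesis(tolerance=1.6, weight=2.0)
        mr = lp.MappingResult(
            [(0, 0)], [1, 2, 3], None, np.array([0.8]), 0.0, 0, 0.0
        )
        assert lp.compute_fit(mr, h) == pytest.approx(1.5)

    @given(st.floats(0.0, 5.0), st.floats(0.0, 5.0))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_non_increasing_in_displacement(self, d1, d2):
        h = square_hypothesis(tolerance=1.6, weight=2.0)
        lo, hi = sorted((d1, d2))
        fit_lo = lp.compute_fit(
            lp.MappingResult([(0, 0)], [1, 2, 3], None, np.array([lo]), 0.0, 0, 0.0), h
        )
        fit_hi = lp.compute_fit(
            lp.MappingResult([(0, 0)], [1, 2, 3], None, np.array([hi]), 0.0, 0, 0.0), h
        )
        assert fit_hi <= fit_lo + 1e-12


class TestActivityEstimation:
    def test_reference_point(self):
        h = square_hypothesis()
        h.b0, h.b1 = 1.0, 0.5
        assert lp.estimate_activity(h, 2.0) == pytest.approx(1.0)

    def test_strictly_decreasing_in_fit(self):
        h = square_hypothesis()
        h.b0, h.b1 = 1.0, 0.5
        assert lp.estimate_activity(h, 5.0) < lp.estimate_activity(h, 4.0)

    def test_noiseless_refit_recovers_coefficients(self):
        rng = np.random.default_rng(3)
        fits = rng.uniform(0, 8, size=20)
        b0, b1 = 1.2, 0.35
        logs = b0 - b1 * fits
        b0_hat, b1_hat = calibrate_regression(fits, logs)
        assert b0_hat == pytest.approx(b0, abs=1e-6)
        assert b1_hat == pytest.approx(b1, abs=1e-6)

    def test_uninformative_fit_collapses_to_constant(self):
        b0, b1 = calibrate_regression(np.full(5, 3.0), np.linspace(0, 1, 5))
        assert b1 == 0.0 and b0 == pytest.approx(0.5)


class TestCostModel:
    def _perfect_training(self, engine_cfg):
        h = square_hypothesis()
        training = [
            lp.TrainingCompound(f"c{i}", [cloud_from(h, f"c{i}")], 2.5)
            for i in range(4)
        ]
        return h, training

    def test_perfect_predictions_closed_form(self, engine_cfg):
        h, training = self._perfect_training(engine_cfg)
        calibrate(h, training, engine_cfg)
        rep = lp.compute_cost(h, training, engine_cfg)
        sigma = math.log10(engine_cfg.uncertainty)
        per_point = math.log2(sigma * math.sqrt(2 * math.pi))
        assert rep.weight_cost == pytest.approx(0.0, abs=1e-12)
        assert rep.error_cost == pytest.approx(len(training) * per_point, abs=1e-9)
        # equal activities: the geometric-mean null model is also perfect
        assert rep.null_cost == pytest.approx(len(training) * per_point, abs=1e-9)

    def test_total_cost_identity(self, engine_cfg):
        rng = np.random.default_rng(11)
        h = plant_hypothesis(5, k=4)
        lib = lp.generate_library(h, lp.SyntheticSpec(n_compounds=10, seed=5))
        training = lib.training_compounds()
        hyp = plant_hypothesis(6, k=4)
        calibrate(hyp, training, engine_cfg)
        rep = lp.compute_cost(hyp, training, engine_cfg, n_config=12)
        assert rep.total_cost == pytest.approx(
            rep.error_cost + rep.weight_cost + rep.config_cost, abs=1e-9
        )
        assert rep.config_cost == pytest.approx(math.log2(12))

    def test_config_cost_capped_at_17_bits(self, engine_cfg):
        h, training = self._perfect_training(engine_cfg)
        calibrate(h, training, engine_cfg)
        rep = lp.compute_cost(h, training, engine_cfg, n_config=2**20)
        assert rep.config_cost == pytest.approx(17.0)

    def test_cost_invariant_under_rigid_motion_of_hypothesis(self, engine_cfg):
        h = plant_hypothesis(2, k=4)
        lib = lp.generate_library(h, lp.SyntheticSpec(n_compounds=8, seed=2))
        training = lib.training_compounds()
        calibrate(h, training, engine_cfg)
        rep = lp.compute_cost(h, training, engine_cfg)
        rng = np.random.default_rng(4)
        rot = _random_rotation(rng)
        shift = rng.uniform(-10, 10, 3)
        moved = lp.Hypothesis(
            [
                lp.PharmacophoreFeature(f.ftype, rot @ f.centroid + shift,
                                        f.tolerance, f.weight)
                for f in h.features
            ],
            b0=h.b0, b1=h.b1,
        )
        rep2 = lp.compute_cost(moved, training, engine_cfg)
        assert rep2.total_cost == pytest.approx(rep.total_cost, abs=1e-6)
        assert rep2.null_cost == pytest.approx(rep.null_cost, abs=1e-12)

    def test_cost_difference_reproduces_published_arithmetic(self):
        assert round(lp.cost_difference(194.608, 73.604), 2) == 121.0
        assert round(lp.cost_difference(194.608, 63.804), 3) == 130.804

    def test_nonpositive_activity_rejected(self, engine_cfg):
        h = square_hypothesis()
        with pytest.raises(ValueError):
            lp.TrainingCompound("bad", [cloud_from(h)], -1.0)


class TestPhases:
    def test_lead_rule_on_published_training_activities(self, training_table, engine_cfg):
        training = [
            lp.TrainingCompound(cid, [], exp)
            for cid, exp, _est in training_table.records
        ]
        leads = select_leads(training, engine_cfg)
        assert sorted(tc.ic50 for tc in leads) == [0.107, 0.194]

    def test_single_compound_training_returns_own_subsets(self, engine_cfg):
        h = square_hypothesis()
        training = [lp.TrainingCompound("only", [cloud_from(h)], 0.5)]
        cands = lp.constructive_phase(training, engine_cfg)
        assert cands  # its own valid k-subsets
        assert all(3 <= len(c.features) <= 4 for c in cands)
        ks = {len(c.features) for c in cands}
        assert 4 in ks

    def test_planted_arrangement_among_candidates(self, engine_cfg):
        h = plant_hypothesis(12, k=4)
        lib = lp.generate_library(h, lp.SyntheticSpec(n_compounds=12, seed=12))
        cands = lp.constructive_phase(lib.training_compounds(), engine_cfg)
        assert any(typed_rmsd_to(h, c) < 1.0 for c in cands)

    def test_subtractive_noop_without_inactives(self, engine_cfg):
        h = square_hypothesis()
        training = [
            lp.TrainingCompound("a", [cloud_from(h, "a")], 0.5),
            lp.TrainingCompound("b", [cloud_from(h, "b")], 5.0),
        ]
        cands = lp.constructive_phase(training, engine_cfg)
        survivors = lp.subtractive_phase(cands, training, engine_cfg)
        assert [id(c) for c in survivors] == [id(c) for c in cands]

    def test_subtractive_removes_arrangement_present_in_inactive(self, engine_cfg):
        h = square_hypothesis()
        # activity gap of 10^4 > 10^3.5 makes compound "dead" inactive
        training = [
            lp.TrainingCompound("lead", [cloud_from(h, "lead")], 0.001),
            lp.TrainingCompound("dead", [cloud_from(h, "dead")], 10.0),
        ]
        cands = lp.constructive_phase(training, engine_cfg)
        survivors = lp.subtractive_phase(cands, training, engine_cfg)
        assert cands and not survivors
        # the inactive indeed fully maps every candidate it killed
        assert all(full_map(training[1].clouds, c, engine_cfg) for c in cands)


class TestOptimization:
    def test_result_length_and_rank_order(self, engine_cfg):
        h = plant_hypothesis(1, k=4)
        lib = lp.generate_library(h, lp.SyntheticSpec(n_compounds=12, seed=1))
        ranked = lp.generate_hypotheses(lib.training_compounds(), engine_cfg)
        assert 1 <= len(ranked) <= engine_cfg.n_hypotheses
        costs = [rep.total_cost for _h, rep in ranked]
        assert costs == sorted(costs)
        assert [hh.rank for hh, _r in ranked] == list(range(1, len(ranked) + 1))

    def test_zero_temperature_accepts_no_uphill_moves(self):
        cfg = lp.EngineConfig(
            anneal=lp.AnnealSchedule(start_temp=1e-13, cooling=0.5, steps=30)
        )
        h = plant_hypothesis(3, k=4)
        lib = lp.generate_library(h, lp.SyntheticSpec(n_compounds=10, seed=3))
        ranked = lp.generate_hypotheses(lib.training_compounds(), cfg)
        for hh, _rep in ranked:
            trace = hh.meta["anneal_trace"]
            accepted = [c for _t, c in trace]
            assert all(b <= a + 1e-9 for a, b in zip(accepted, accepted[1:]))

    def test_deterministic_for_fixed_seed(self, engine_cfg):
        h = plant_hypothesis(4, k=4)
        lib = lp.generate_library(h, lp.SyntheticSpec(n_compounds=10, seed=4))
        tr = lib.training_compounds()
        a = lp.generate_hypotheses(tr, engine_cfg)
        b = lp.generate_hypotheses(tr, engine_cfg)
        assert [round(r.total_cost, 12) for _h, r in a] == [
            round(r.total_cost, 12) for _h, r in b
        ]

    def test_top_model_cost_beats_planted_oracle_bound(self, engine_cfg):
        h = plant_hypothesis(8, k=4)
        lib = lp.generate_library(h, lp.SyntheticSpec(n_compounds=20, seed=8))
        tr = lib.training_compounds()
        planted = lp.Hypothesis(
            [lp.PharmacophoreFeature(f.ftype, f.centroid.copy()) for f in h.features]
        )
        calibrate(planted, tr, engine_cfg)
        ranked = lp.generate_hypotheses(tr, engine_cfg)
        n_config = ranked[0][0].meta["n_config"]
        bound = lp.compute_cost(planted, tr, engine_cfg, n_config=n_config)
        assert ranked[0][1].total_cost <= bound.total_cost + 1.0


class TestHypothesisType:
    def test_feature_count_bounds(self):
        pts = np.eye(3) * 5
        feats = [lp.PharmacophoreFeature("HY", p) for p in pts[:2]]
        with pytest.raises(ValueError):
            lp.Hypothesis(feats)

    def test_min_interfeature_distance_validation(self):
        h = square_hypothesis(side=1.0)
        with pytest.raises(ValueError):
            h.validate(2.0)
        square_hypothesis(side=4.0).validate(2.0)

    def test_json_round_trip(self):
        h = square_hypothesis()
        h.b0, h.b1 = 1.5, 0.3
        back = lp.Hypothesis.from_json(h.to_json())
        assert back.type_multiset() == h.type_multiset()
        np.testing.assert_allclose(back.centroids(), h.centroids())
        assert (back.b0, back.b1) == (1.5, 0.3)
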