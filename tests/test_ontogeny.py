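"""Ontogenetic trajectories, duration ANOVA and heterochrony modes."""

import numpy as np
import pytest
from itertools import combinations

from phylomorph import (OntogenyPair, duration_anova,
                        heterochrony_regression, simulate_heterochrony,
                        trajectory_stats)
from conftest import random_rotation


def _pair(sp, emb, adu, group):
    return OntogenyPair(species_id=sp, embryo_shape=emb, adult_shape=adu,
                        embryo_size=1.0, adult_size=2.0, group=group)


class TestTrajectoryStats:
    def test_identical_groups_zero_angle_and_length_diff(self, rng):
        pairs = []
        for g in ("a", "b"):
            for i in range(3):
                e = np.array([0.0, 0.0, float(i)])
                pairs.append(_pair(f"{g}{i}", e, e + [1.0, 0, 0], g))
        res = trajectory_stats(pairs, n_perm=199, seed=1)
        assert res.angle_deg.loc["a", "b"] == pytest.approx(0.0, abs=1e-10)
        assert res.length_difference.loc["a", "b"] == pytest.approx(0.0)
        assert res.p_length.loc["a", "b"] > 0.5
        assert res.p_angle.loc["a", "b"] > 0.5

    def test_opposite_directions_angle_180(self):
        v = np.array([1.0, 0.0])
        pairs = [
            _pair("a1", np.zeros(2), v, "a"),
            _pair("a2", np.zeros(2), v, "a"),
            _pair("b1", np.zeros(2), -v, "b"),
            _pair("b2", np.zeros(2), -v, "b"),
        ]
        res = trajectory_stats(pairs, n_perm=19, seed=0)
        assert res.angle_deg.loc["a", "b"] == pytest.approx(180.0)

    def test_hand_arithmetic_toy_groups(self):
        # group a: mean embryo (0,0), mean adult (2,0) -> length 2
        # group b: mean embryo (0,0), mean adult (0,1) -> length 1, angle 90
        pairs = [
            _pair("a1", [0.0, 0], [1.0, 0], "a"),
            _pair("a2", [0.0, 0], [3.0, 0], "a"),
            _pair("b1", [0.0, -1], [0.0, 0], "b"),
            _pair("b2", [0.0, 1], [0.0, 2], "b"),
        ]
        res = trajectory_stats(pairs, n_perm=19, seed=0)
        assert res.path_length["a"] == pytest.approx(2.0)
        assert res.path_length["b"] == pytest.approx(1.0)
        assert res.angle_deg.loc["a", "b"] == pytest.approx(90.0)

    def test_exact_permutation_matches_manual_enumeration(self, rng):
        pairs = []
        for g, base in (("a", 0.0), ("b", 0.6)):
            for i in range(3):
                e = rng.standard_normal(3) * 0.1
                pairs.append(_pair(f"{g}{i}", e, e + [1.0 + base, base, 0],
                                   g))
        res = trajectory_stats(pairs, exact=True)

        # manual enumeration of all 6-choose-3 reassignments
        embs = [p.embryo_shape for p in pairs]
        adus = [p.adult_shape for p in pairs]

        def stats(idx_a):
            idx_b = [i for i in range(6) if i not in idx_a]
            va = np.mean([adus[i] for i in idx_a], axis=0) \
                - np.mean([embs[i] for i in idx_a], axis=0)
            vb = np.mean([adus[i] for i in idx_b], axis=0) \
                - np.mean([embs[i] for i in idx_b], axis=0)
            ld = abs(np.linalg.norm(va) - np.linalg.norm(vb))
            cos = va @ vb / np.linalg.norm(va) / np.linalg.norm(vb)
            ang = np.degrees(np.arccos(np.clip(cos, -1, 1)))
            return ld, ang

        obs_ld, obs_ang = stats([0, 1, 2])
        lds, angs = zip(*[stats(list(c))
                          for c in combinations(range(6), 3)])
        p_len = np.mean([ld >= obs_ld - 1e-12 for ld in lds])
        p_ang = np.mean([an >= obs_ang - 1e-12 for an in angs])
        assert res.p_length.loc["a", "b"] == pytest.approx(p_len)
        assert res.p_angle.loc["a", "b"] == pytest.approx(p_ang)

    def test_rotation_invariance(self, rng):
        pairs = []
        for g in ("a", "b"):
            for i in range(4):
                e = rng.standard_normal(4)
                pairs.append(_pair(f"{g}{i}", e,
                                   e + rng.standard_normal(4), g))
        R = random_rotation(rng, 4)
        rot = [_pair(p.species_id, p.embryo_shape @ R, p.adult_shape @ R,
                     p.group) for p in pairs]
        r0 = trajectory_stats(pairs, n_perm=49, seed=3)
        r1 = trajectory_stats(rot, n_perm=49, seed=3)
        assert r0.angle_deg.loc["a", "b"] == pytest.approx(
            r1.angle_deg.loc["a", "b"], abs=1e-10)
        for g in ("a", "b"):
            assert r0.path_length[g] == pytest.approx(r1.path_length[g],
                                                      abs=1e-10)

    def test_single_species_group_rejected(self, rng):
        pairs = [_pair("a1", np.zeros(2), np.ones(2), "a"),
                 _pair("b1", np.zeros(2), np.ones(2), "b"),
                 _pair("b2", np.zeros(2), np.ones(2), "b")]
        with pytest.raises(ValueError, match="fewer than 2"):
            trajectory_stats(pairs)

    def test_non_anchor_stage_warns(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING):
            OntogenyPair("x", np.zeros(2), np.ones(2), 1.0, 2.0,
                         stage="embryo_stage_5")
        assert any("not comparable" in r.message for r in caplog.records)


class TestDurationAnova:
    def test_hand_computed_fixture(self):
        # groups (1,2,3) and (4,5,6): F = (3*(2-3.5)^2+3*(5-3.5)^2)/1 / (4/4)
        F, p = duration_anova([1, 2, 3, 4, 5, 6],
                              ["a", "a", "a", "b", "b", "b"])
        assert F == pytest.approx(13.5)

    def test_calibration_under_null(self, rng):
        hits = 0
        for _ in range(200):
            d = rng.normal(60, 5, size=30)
            labels = np.repeat(["a", "b", "c"], 10)
            if duration_anova(d, labels)[1] <= 0.05:
                hits += 1
        assert hits <= 20   # around the 5% nominal rate

    def test_large_shift_detected(self, rng):
        d = np.concatenate([rng.normal(60, 2, 20), rng.normal(90, 2, 20)])
        labels = np.repeat(["a", "b"], 20)
        F, p = duration_anova(d, labels)
        assert p < 1e-6

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            duration_anova([1.0, 2.0, 3.0], ["a", "a", "b"])


class TestHeterochronyRegression:
    @pytest.mark.parametrize("mode", ["acceleration", "hypermorphosis",
                                      "predisplacement",
                                      "paedomorphic_pattern"])
    def test_planted_modes_recovered(self, mode):
        sh, ls, gr, du, dl = simulate_heterochrony(mode, seed=77)
        res = heterochrony_regression(sh, ls, gr, durations=du,
                                      duration_labels=dl,
                                      ancestor="lizard", descendant="snake",
                                      n_perm=199, seed=5)
        assert res.classification == mode

    def test_double_slope_equal_ranges_is_acceleration(self, rng):
        """Shape moving twice as fast per unit log size, same size span and
        durations: the textbook acceleration signature."""
        v = np.array([1.0, 0.0, 0.0])
        s = np.tile(np.linspace(2.0, 3.0, 25), 2)
        g = np.repeat(["lizard", "snake"], 25)
        slopes = np.where(g == "snake", 0.2, 0.1)
        Y = (slopes * (s - 2.0))[:, None] * v \
            + 0.005 * rng.standard_normal((50, 3))
        du = rng.normal(60, 5, 50)
        res = heterochrony_regression(Y, s, g, durations=du,
                                      duration_labels=g,
                                      ancestor="lizard", descendant="snake",
                                      n_perm=199, seed=1)
        assert res.classification == "acceleration"
        assert res.slope_ratio == pytest.approx(2.0, rel=0.15)

    def test_extended_size_range_is_hypermorphosis(self, rng):
        v = np.array([1.0, 0.0])
        s = np.concatenate([np.linspace(2, 3, 25), np.linspace(2, 4.0, 25)])
        g = np.repeat(["lizard", "snake"], 25)
        Y = (0.1 * (s - 2.0))[:, None] * v \
            + 0.005 * rng.standard_normal((50, 2))
        res = heterochrony_regression(Y, s, g, ancestor="lizard",
                                      descendant="snake", n_perm=199, seed=2)
        assert res.classification == "hypermorphosis"

    def test_intercept_shift_is_predisplacement(self, rng):
        v = np.array([1.0, 0.0])
        s = np.tile(np.linspace(2, 3, 25), 2)
        g = np.repeat(["lizard", "snake"], 25)
        Y = (0.1 * (s - 2.0))[:, None] * v \
            + 0.005 * rng.standard_normal((50, 2))
        Y[g == "snake"] += 0.2 * v
        res = heterochrony_regression(Y, s, g, ancestor="lizard",
                                      descendant="snake", n_perm=199, seed=3)
        assert res.classification == "predisplacement"

    def test_degenerate_size_range_rejected(self, rng):
        Y = rng.standard_normal((10, 2))
        s = np.array([1.0] * 5 + [1.0, 2, 3, 4, 5])
        g = np.repeat(["lizard", "snake"], 5)
        with pytest.raises(ValueError, match="degenerate"):
            heterochrony_regression(Y, s, g)

    def test_classification_reproducible_from_evidence(self):
        sh, ls, gr, du, dl = simulate_heterochrony("acceleration", seed=5)
        res = heterochrony_regression(sh, ls, gr, durations=du,
                                      duration_labels=dl,
                                      ancestor="lizard", descendant="snake",
                                      n_perm=199, seed=6)
        gates = dict(zip(res.evidence["gate"], res.evidence["value"]))
        if gates["truncated"] and not gates["steeper"]:
            expected = "paedomorphic_pattern"
        elif gates["steeper"] and not gates["dur_longer"] \
                and not gates["extends_size"]:
            expected = "acceleration"
        elif gates["shifted"] and not gates["steeper"] \
                and not gates["extends"]:
            expected = "predisplacement"
        elif gates["extends"] and not gates["steeper"]:
            expected = "hypermorphosis"
        else:
            expected = "none"
        assert res.classification == expected
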