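import numpy as np
import pandas as pd
import pytest

from ethodyad.decomposition import VariableSeries
from ethodyad.io import DataError, LabelStream
from ethodyad.transitions import (
    average_graph,
    behavior_pairs,
    binned_labels_exp2,
    compare_transitions,
    discretize_exp1,
    graph_edge_list,
    transition_matrix,
)
from ethodyad.vocab import (
    ACTIVE_CATEGORIES,
    ORIENTATION_STATES,
    WORKING_CATEGORIES,
)


def var(values, name="direction", fps=1.0):
    values = np.asarray(values, dtype=float)
    return VariableSeries("a", name, values, np.isnan(values), np.arange(len(values)) / fps)


def stream(labels, vocab=ACTIVE_CATEGORIES):
    return LabelStream("a", 1.0, vocab, np.asarray(labels))


class TestDiscretizeExp1:
    def test_toward_near_corner(self):
        out = discretize_exp1(var([1.0, 1.0]), var([0.0, 0.0], "distance_cm"), window_s=None)
        assert out.as_names() == ["toward-near", "toward-near"]

    def test_direction_exactly_zero_is_opposite(self):
        out = discretize_exp1(var([0.0, 0.0]), var([1.0, 1.0], "distance_cm"), window_s=None)
        assert out.as_names() == ["opposite-near", "opposite-near"]

    def test_default_distance_threshold_is_half_usable_range(self):
        out = discretize_exp1(
            var([1.0, 1.0]),
            var([12.0, 12.2], "distance_cm"),
            usable_range_cm=24.15,
            window_s=None,
        )
        assert out.as_names() == ["toward-near", "toward-away"]

    def test_sweep_matches_brute_force_thresholding(self):
        rng = np.random.default_rng(0)
        d = rng.uniform(-1, 1, 300)
        r = rng.uniform(0, 24, 300)
        out = discretize_exp1(
            var(d), var(r, "distance_cm"), distance_threshold_cm=12.0, window_s=None
        )
        for i in range(300):
            name = (
                ("toward" if d[i] > 0 else "opposite")
                + "-"
                + ("near" if r[i] < 12.0 else "away")
            )
            assert out.as_names()[i] == name

    def test_window_restricts_to_initial_period(self):
        d = np.ones(100)
        out = discretize_exp1(
            var(d), var(np.zeros(100), "distance_cm"), window_s=40.0
        )
        assert len(out) == 40

    def test_missing_bins_propagate(self):
        out = discretize_exp1(
            var([1.0, np.nan]), var([0.0, 0.0], "distance_cm"), window_s=None
        )
        assert out.labels[1] == -1


class TestBinnedLabelsExp2:
    def _frames(self, names):
        return LabelStream(
            "a", 0.0, WORKING_CATEGORIES,
            np.array([WORKING_CATEGORIES.index(n) for n in names]),
        )

    def test_uniform_bin_keeps_category(self):
        s = self._frames(["huddling"] * 20)
        out = binned_labels_exp2(s, frame_rate_hz=20.0)
        assert out.as_names() == ["huddling"]

    def test_majority_rule(self):
        s = self._frames(["pointing"] * 11 + ["chasing"] * 9)
        out = binned_labels_exp2(s, frame_rate_hz=20.0)
        assert out.as_names() == ["pointing"]

    def test_mirror_roles_collapse_to_interaction_category(self):
        s = self._frames(["being_chased"] * 20)
        out = binned_labels_exp2(s, frame_rate_hz=20.0)
        assert out.as_names() == ["chasing"]

    def test_mirror_drop_option_makes_bins_missing(self):
        s = self._frames(["being_chased"] * 20)
        out = binned_labels_exp2(s, frame_rate_hz=20.0, mirror_collapse="drop")
        assert out.labels[0] == -1

    def test_random_stream_matches_modal_counting_oracle(self):
        rng = np.random.default_rng(1)
        codes = rng.integers(0, 5, 200)  # already active categories
        s = LabelStream("a", 0.0, WORKING_CATEGORIES, codes)
        out = binned_labels_exp2(s, frame_rate_hz=10.0)
        for b in range(20):
            chunk = codes[b * 10 : (b + 1) * 10]
            counts = np.bincount(chunk, minlength=5)
            assert out.labels[b] == counts.argmax()


class TestTransitionMatrix:
    def test_constant_streams_single_cell(self):
        a = stream([0] * 10)
        r = stream([3] * 10)
        tm = transition_matrix(a, r)
        assert tm.probabilities[0, 3] == 1.0
        assert tm.counts.sum() == 9

    def test_vocabulary_sizes(self):
        tm4 = transition_matrix(
            stream([0, 1, 2, 3], ORIENTATION_STATES), stream([0, 1, 2, 3], ORIENTATION_STATES)
        )
        tm5 = transition_matrix(stream([0, 1, 2, 3, 4]), stream([0, 1, 2, 3, 4]))
        assert tm4.counts.shape == (4, 4)
        assert tm5.counts.shape == (5, 5)

    def test_deterministic_periodic_stream_exact_matrix(self):
        # actor A B A B..., reactor = same stream: (A,t)->(B,t+1) always
        labels = np.tile([0, 1], 10)
        s = stream(labels)
        tm = transition_matrix(s, s)
        expect = np.zeros((5, 5))
        expect[0, 1] = 1.0
        expect[1, 0] = 1.0
        assert np.allclose(tm.probabilities[:2], expect[:2])

    def test_row_stochastic_within_1e12(self):
        rng = np.random.default_rng(2)
        a = stream(rng.integers(0, 5, 500))
        r = stream(rng.integers(0, 5, 500))
        tm = transition_matrix(a, r)
        sums = tm.probabilities.sum(axis=1)
        visited = ~tm.unvisited_rows
        assert np.allclose(sums[visited], 1.0, atol=1e-12)

    def test_directionality_is_asymmetric(self):
        # constructed fixture: actor stream drives reactor with a lag
        a = stream([0, 0, 1, 1, 0, 0, 1, 1, 0, 0])
        r = stream([2, 2, 2, 3, 3, 2, 2, 3, 3, 2])
        fwd = transition_matrix(a, r, directionality="male_to_female")
        rev = transition_matrix(r, a, directionality="female_to_male")
        assert not np.allclose(fwd.probabilities, rev.probabilities.T)

    def test_missing_bins_drop_touching_pairs(self):
        a = stream([0, -1, 1, 1])
        r = stream([1, 1, -1, 0])
        tm = transition_matrix(a, r)
        # valid t: t=0 needs r[1]>=0 (yes), t=1 actor missing, t=2 r[3]
        assert tm.counts.sum() == 2

    def test_too_short_raises(self):
        with pytest.raises(DataError):
            transition_matrix(stream([0]), stream([1]))

    def test_recovery_from_known_chain(self):
        """Long streams from a known coupled chain recover the generating
        probabilities within ±0.02."""
        rng = np.random.default_rng(3)
        P = np.array(
            [
                [0.7, 0.1, 0.1, 0.05, 0.05],
                [0.2, 0.6, 0.1, 0.05, 0.05],
                [0.1, 0.1, 0.6, 0.1, 0.1],
                [0.05, 0.05, 0.1, 0.7, 0.1],
                [0.05, 0.05, 0.05, 0.05, 0.8],
            ]
        )
        n = 60000
        cum = np.cumsum(P, axis=1)
        u = rng.random(n)
        x = np.empty(n, dtype=int)
        x[0] = 0
        for t in range(1, n):
            x[t] = np.searchsorted(cum[x[t - 1]], u[t])
        s = stream(x)
        tm = transition_matrix(s, s)
        assert np.max(np.abs(tm.probabilities - P)) < 0.02

    def test_estimates_converge_with_duration(self):
        rng = np.random.default_rng(4)
        P = np.array([[0.8, 0.2], [0.3, 0.7]])

        cum = np.cumsum(P, axis=1)

        def simulate(n):
            u = rng.random(n)
            x = np.empty(n, dtype=int)
            x[0] = 0
            for t in range(1, n):
                x[t] = np.searchsorted(cum[x[t - 1]], u[t])
            return x

        errs = []
        for n in (500, 20000):
            x = simulate(n)
            s = LabelStream("a", 1.0, ("A", "B"), x)
            tm = transition_matrix(s, s)
            errs.append(np.max(np.abs(tm.probabilities - P)))
        assert errs[1] < errs[0]


class TestAverageGraph:
    def _tm(self, probs, dyad_id="d1"):
        counts = np.asarray(probs) * 100
        from ethodyad.transitions import TransitionMatrix

        return TransitionMatrix(dyad_id, "male_to_female", ("A", "B"), counts)

    def test_single_matrix_graph_equals_matrix(self):
        tm = self._tm([[0.6, 0.4], [0.1, 0.9]])
        g = average_graph([tm])
        assert g["A"]["B"]["weight"] == pytest.approx(0.4)
        assert g["A"]["A"]["weight"] == pytest.approx(0.6)  # self-loop kept

    def test_two_matrices_mean_per_edge(self):
        g = average_graph(
            [self._tm([[1.0, 0.0], [0.0, 1.0]]), self._tm([[0.0, 1.0], [1.0, 0.0]], "d2")]
        )
        assert g["A"]["B"]["weight"] == pytest.approx(0.5)

    def test_mixed_vocabularies_rejected(self):
        from ethodyad.transitions import TransitionMatrix

        a = TransitionMatrix("d1", "male_to_female", ("A", "B"), np.eye(2))
        b = TransitionMatrix("d2", "male_to_female", ("X", "Y"), np.eye(2))
        with pytest.raises(ValueError, match="vocabular"):
            average_graph([a, b])

    def test_edge_list_round_trip(self):
        g = average_graph([self._tm([[0.6, 0.4], [0.1, 0.9]])])
        edges = graph_edge_list(g)
        assert len(edges) == 4
        assert set(edges.columns) == {"source", "target", "weight"}


class TestCompareTransitions:
    def _cohort_matrices(self, rng, k, n_per_type, shift=0.0):
        from ethodyad.transitions import TransitionMatrix

        vocab = ORIENTATION_STATES if k == 4 else ACTIVE_CATEGORIES
        mats, types = [], {}
        i = 0
        for dtp in ("matched", "mixed"):
            for _ in range(n_per_type):
                i += 1
                base = rng.uniform(0.5, 1.0, size=(k, k))
                if dtp == "mixed":
                    base[0, 1] += shift
                counts = (base / base.sum(axis=1, keepdims=True)) * 500
                m = TransitionMatrix(f"d{i}", "female_to_male", vocab, counts)
                mats.append(m)
                types[f"d{i}"] = dtp
        return mats, types

    @pytest.mark.parametrize("k,n_pairs,df_num", [(4, 12, 11), (5, 20, 19)])
    def test_pair_counts_and_interaction_df(self, k, n_pairs, df_num):
        rng = np.random.default_rng(5)
        mats, types = self._cohort_matrices(rng, k, 7)
        vocab = mats[0].vocabulary
        assert len(behavior_pairs(vocab)) == n_pairs
        res = compare_transitions(mats, types)
        assert res.effect("interaction")["df_num"] == df_num
        # 7 + 7 dyads -> between-group error df 12, within df num*12
        assert res.effect("dyad_type")["df_den"] == 12
        assert res.effect("interaction")["df_den"] == df_num * 12

    def test_identical_groups_interaction_null_calibrated(self):
        rng = np.random.default_rng(6)
        ps = []
        for _ in range(120):
            mats, types = self._cohort_matrices(rng, 4, 5)
            res = compare_transitions(mats, types, posthoc=False)
            ps.append(res.effect("interaction")["p"])
        rate = np.mean(np.array(ps) < 0.05)
        assert 0.0 <= rate <= 0.12

    def test_shifted_pair_detected_in_posthoc(self):
        rng = np.random.default_rng(7)
        mats, types = self._cohort_matrices(rng, 4, 8, shift=3.0)
        res = compare_transitions(mats, types)
        ph = res.posthoc.set_index("pair")
        target = f"{ORIENTATION_STATES[0]}->{ORIENTATION_STATES[1]}"
        assert bool(ph.loc[target, "significant"])
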