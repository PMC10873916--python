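"""Ground-truth generator: PD algebra, round-trips, sampling contracts."""

import numpy as np
import pytest
from scipy import stats

from netpsych import (SyntheticSpec, TwoGroupSpec, ggm_to_covariance,
                      make_random_sparse_ggm, make_study_fixture,
                      sample_ordinal_responses, sample_two_group)
from netpsych.ggm import precision_to_partial
from netpsych.synthetic import (PDRepairError, _repair_pd,
                                equal_probability_thresholds)


def spec_from_partial(P, seed=0, n=500, n_cat=4):
    p = P.shape[0]
    return SyntheticSpec(
        n_respondents=n, true_partial=P, node_labels=[f"V{i}" for i in range(p)],
        community_assignment={f"V{i}": 0 for i in range(p)},
        thresholds=[equal_probability_thresholds(n_cat)] * p, seed=seed)


class TestGGMAlgebra:
    def test_zero_density_gives_empty_graph_and_identity_covariance(self):
        spec = make_random_sparse_ggm(p=5, edge_density=0.0, seed=0)
        assert np.all(spec.true_partial == 0)
        assert np.allclose(ggm_to_covariance(spec), np.eye(5))

    def test_two_node_covariance_matches_hand_inverse(self):
        # K = [[1, -.5], [-.5, 1]]; standardized inverse has off-diagonal 0.5
        P = np.array([[0.0, 0.5], [0.5, 0.0]])
        S = ggm_to_covariance(spec_from_partial(P))
        assert S[0, 1] == pytest.approx(0.5, abs=1e-12)
        assert np.allclose(np.diag(S), 1.0)

    def test_round_trip_partial_precision_covariance(self):
        spec = make_random_sparse_ggm(p=4, edge_density=0.5, seed=3)
        S = ggm_to_covariance(spec)
        back = precision_to_partial(np.linalg.inv(S))
        assert np.abs(back - spec.true_partial).max() < 1e-10

    def test_requested_density_up_to_pd_rescaling(self):
        spec = make_random_sparse_ggm(p=10, edge_density=0.2, seed=7)
        iu = np.triu_indices(10, k=1)
        assert (np.abs(spec.true_partial[iu]) > 0).sum() == round(0.2 * len(iu[0]))

    def test_determinism_of_generator(self):
        a = make_random_sparse_ggm(p=10, edge_density=0.2, seed=5)
        b = make_random_sparse_ggm(p=10, edge_density=0.2, seed=5)
        assert np.array_equal(a.true_partial, b.true_partial)

    def test_pd_repair_preserves_pattern_and_enforces_margin(self):
        P = np.zeros((4, 4))
        for i in range(4):
            for j in range(4):
                if i != j:
                    P[i, j] = 0.6
        out = _repair_pd(P)
        assert np.linalg.eigvalsh(np.eye(4) - out)[0] >= 0.05 - 1e-9
        assert np.all((out != 0) == (P != 0))

    def test_non_pd_spec_rejected(self):
        P = np.zeros((3, 3))
        P[0, 1] = P[1, 0] = 0.9
        P[1, 2] = P[2, 1] = 0.9
        with pytest.raises(PDRepairError):
            spec_from_partial(P)

    def test_within_community_edges_more_likely(self):
        spec = make_random_sparse_ggm(p=12, edge_density=0.25, seed=11,
                                      community_sizes=[4, 4, 4])
        comm = np.array([spec.community_assignment[l] for l in spec.node_labels])
        iu, ju = np.triu_indices(12, k=1)
        edge = np.abs(spec.true_partial[iu, ju]) > 0
        within = comm[iu] == comm[ju]
        p_within = edge[within].mean()
        p_between = edge[~within].mean()
        assert p_within >= p_between


class TestOrdinalSampling:
    def test_same_seed_identical_tables(self, sparse_spec):
        a = sample_ordinal_responses(sparse_spec)
        b = sample_ordinal_responses(sparse_spec)
        assert a.values.equals(b.values)

    def test_zero_correlation_spec_yields_uncorrelated_items(self):
        spec = make_random_sparse_ggm(p=6, edge_density=0.0, seed=2,
                                      n_respondents=5000)
        t = sample_ordinal_responses(spec)
        C = stats.spearmanr(t.values.to_numpy()).statistic
        off = np.abs(C[~np.eye(6, dtype=bool)])
        assert off.max() < 0.05

    def test_binary_thresholds_give_binary_column(self):
        P = np.zeros((2, 2))
        spec = SyntheticSpec(
            n_respondents=200, true_partial=P, node_labels=["a", "b"],
            community_assignment={"a": 0, "b": 0},
            thresholds=[np.array([0.0]), equal_probability_thresholds(4)], seed=1)
        t = sample_ordinal_responses(spec)
        assert set(t.values["a"].unique()) <= {0, 1}

    def test_marginals_match_gaussian_orthant_probabilities(self):
        spec = make_random_sparse_ggm(p=4, edge_density=0.3, seed=9,
                                      n_respondents=50_000)
        t = sample_ordinal_responses(spec)
        # equal-probability thresholds imply uniform category frequencies
        for col in t.values:
            freqs = t.values[col].value_counts(normalize=True).sort_index().to_numpy()
            assert np.abs(freqs - 0.25).max() < 0.01

    def test_degenerate_threshold_flags_constant_column(self):
        P = np.zeros((2, 2))
        spec = SyntheticSpec(
            n_respondents=50, true_partial=P, node_labels=["a", "b"],
            community_assignment={"a": 0, "b": 0},
            thresholds=[np.array([9.0]), np.array([0.0])], seed=1)
        with pytest.warns(UserWarning, match="constant"):
            t = sample_ordinal_responses(spec)
        assert t.meta["constant_columns"] == ["a"]


class TestTwoGroup:
    def test_multiplier_orders_true_global_strength(self):
        base = make_random_sparse_ggm(p=8, edge_density=0.3, seed=4)
        tg = TwoGroupSpec(base=base, strength_multiplier=1.3,
                          group_sizes=(100, 100))
        assert tg.true_global_strength(1) > tg.true_global_strength(0)

    def test_planted_edges_validated(self):
        base = make_random_sparse_ggm(p=4, edge_density=0.3, seed=4)
        with pytest.raises(ValueError):
            TwoGroupSpec(base=base, strength_multiplier=1.1,
                         planted_edge_diffs=[("V0", "nope", 0.1)],
                         group_sizes=(50, 50))

    def test_grouped_sampling_sizes_and_labels(self):
        base = make_random_sparse_ggm(p=5, edge_density=0.2, seed=6)
        tg = TwoGroupSpec(base=base, strength_multiplier=1.2, group_sizes=(40, 60))
        t = sample_two_group(tg)
        assert len(t.values) == 100
        assert (t.group == 1).sum() == 60


class TestStudyFixture:
    def test_canonical_28_labels(self):
        t, tg = make_study_fixture(seed=0, group_sizes=(60, 60))
        assert list(t.values.columns) == tg.base.node_labels
        assert len(tg.base.node_labels) == 28
        assert tg.base.node_labels[0] == "PHQ1"
        assert tg.base.node_labels[-1] == "SSFr"

    def test_support_suicidality_edge_negative(self):
        _, tg = make_study_fixture(seed=1, group_sizes=(60, 60))
        idx = {l: k for k, l in enumerate(tg.base.node_labels)}
        assert tg.base.true_partial[idx["SSFm"], idx["PHQ9"]] < 0

    def test_group1_globally_stronger_by_construction(self):
        _, tg = make_study_fixture(seed=2, group_sizes=(60, 60))
        assert tg.true_global_strength(1) > tg.true_global_strength(0)

    def test_spec_json_round_trip(self, tmp_path, sparse_spec):
        f = tmp_path / "spec.json"
        sparse_spec.to_json(f)
        back = SyntheticSpec.from_json(f)
        assert np.array_equal(back.true_partial, sparse_spec.true_partial)
        assert back.node_labels == sparse_spec.node_labels
        assert back.seed == sparse_spec.seed
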