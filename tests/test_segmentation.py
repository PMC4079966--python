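"""The three-state bivariate-Gaussian HMM: k-means seeding, Baum-Welch,
Viterbi, run merging and domain construction."""

import itertools

import numpy as np
import pandas as pd
import pytest

import replitime as rt
from replitime.segmentation import _runs, path_logprob

from conftest import boundary_errors, label_accuracy


def random_model(rng, k=3):
    transmat = rng.dirichlet(np.ones(k), size=k)
    startprob = rng.dirichlet(np.ones(k))
    means = rng.normal(0, 3, size=(k, 2))
    covs = np.stack([np.eye(2) * rng.uniform(0.2, 2.0) for _ in range(k)])
    return rt.SegmentationModel(startprob, transmat, rt.EmissionParams(means, covs))


def sample_hmm(model, n, rng):
    states = np.empty(n, dtype=int)
    states[0] = rng.choice(model.n_states, p=model.startprob)
    for t in range(1, n):
        states[t] = rng.choice(model.n_states, p=model.transmat[states[t - 1]])
    obs = np.stack(
        [rng.multivariate_normal(model.emissions.means[s], model.emissions.covs[s]) for s in states]
    )
    return states, obs


def brute_force_best_path(obs, model):
    best_lp, best_path = -np.inf, None
    for path in itertools.product(range(model.n_states), repeat=len(obs)):
        lp = path_logprob(obs, np.array(path), model)
        if lp > best_lp:
            best_lp, best_path = lp, np.array(path)
    return best_lp, best_path


class TestInitKmeans:
    def test_recovers_three_separated_ratio_modes(self):
        rng = np.random.default_rng(0)
        ratio = np.concatenate(
            [rng.normal(-2, 0.1, 300), rng.normal(0, 0.1, 300), rng.normal(2, 0.1, 300)]
        )
        el = np.column_stack([ratio, -ratio]) + rng.normal(0, 0.05, (900, 2))
        model = rt.init_kmeans(ratio, el, seed=0)
        # state emission means in the early channel track the cluster modes
        np.testing.assert_allclose(model.emissions.means[:, 0], [-2, 0, 2], atol=0.1)
        assert model.state_labels == ("late", "indeterminate", "early")

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(1)
        ratio = rng.normal(0, 1, 500)
        el = rng.uniform(0, 2, (500, 2))
        a = rt.init_kmeans(ratio, el, seed=3)
        b = rt.init_kmeans(ratio, el, seed=3)
        np.testing.assert_array_equal(a.emissions.means, b.emissions.means)
        np.testing.assert_array_equal(a.emissions.covs, b.emissions.covs)

    def test_identical_ratios_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            rt.init_kmeans(np.zeros(100), np.ones((100, 2)))

    def test_transitions_self_biased_and_stochastic(self):
        rng = np.random.default_rng(2)
        model = rt.init_kmeans(rng.normal(0, 1, 300), rng.uniform(0, 1, (300, 2)), self_transition=0.998)
        np.testing.assert_allclose(np.diag(model.transmat), 0.998)
        np.testing.assert_allclose(model.transmat.sum(axis=1), 1.0)
        np.testing.assert_allclose(model.startprob, 1 / 3)


class TestBaumWelch:
    def test_loglik_trace_nondecreasing(self):
        rng = np.random.default_rng(3)
        model = random_model(rng)
        _, obs = sample_hmm(model, 400, rng)
        trained = rt.baum_welch_train(obs, model, tol=1e-4, max_iter=100)
        deltas = np.diff(trained.loglik_trace)
        assert (deltas >= -1e-8).all()

    def test_infinite_tolerance_stops_after_one_iteration(self):
        rng = np.random.default_rng(4)
        model = random_model(rng)
        _, obs = sample_hmm(model, 100, rng)
        trained = rt.baum_welch_train(obs, model, tol=np.inf)
        assert len(trained.loglik_trace) == 1
        assert not np.array_equal(trained.emissions.means, model.emissions.means)

    def test_recovers_well_separated_emission_means(self):
        rng = np.random.default_rng(5)
        means = np.array([[0.2, 3.0], [1.5, 1.5], [3.0, 0.2]])
        truth = rt.SegmentationModel(
            np.ones(3) / 3,
            np.full((3, 3), 0.01) + np.eye(3) * 0.97,
            rt.EmissionParams(means, np.stack([np.eye(2) * 0.05] * 3)),
        )
        _, obs = sample_hmm(truth, 3000, rng)
        with np.errstate(invalid="ignore", divide="ignore"):
            ratio = np.log2((obs[:, 0] + 0.1) / (obs[:, 1] + 0.1))
        init = rt.init_kmeans(ratio, obs, seed=0)
        trained = rt.baum_welch_train(obs, init, tol=0.05).relabel_by_ratio()
        order = {l: i for i, l in enumerate(trained.state_labels)}
        est = trained.emissions.means[[order["late"], order["indeterminate"], order["early"]]]
        assert (np.abs(est - means) / np.abs(means)).max() < 0.10

    def test_too_short_sequence_rejected(self):
        rng = np.random.default_rng(6)
        with pytest.raises(ValueError):
            rt.baum_welch_train(np.ones((1, 2)), random_model(rng))

    def test_matches_hmmlearn_likelihood(self):
        """Cross-check the forward pass against an independent HMM library."""
        hmm = pytest.importorskip("hmmlearn.hmm")
        rng = np.random.default_rng(7)
        model = random_model(rng)
        _, obs = sample_hmm(model, 200, rng)
        ref = hmm.GaussianHMM(n_components=3, covariance_type="full", init_params="")
        ref.startprob_ = model.startprob
        ref.transmat_ = model.transmat
        ref.means_ = model.emissions.means
        ref.covars_ = model.emissions.covs
        expected = ref.score(obs)
        from replitime.segmentation import _forward_backward

        loglik, _, _ = _forward_backward(model, model.log_emission(obs))
        assert loglik == pytest.approx(expected, abs=1e-6)


class TestViterbi:
    def test_bins_on_state_means_decode_to_those_states(self):
        rng = np.random.default_rng(8)
        model = random_model(rng)
        model.emissions.means = np.array([[0.0, 0.0], [10.0, 10.0], [-10.0, 10.0]])
        model.emissions.covs = np.stack([np.eye(2) * 0.01] * 3)
        obs = model.emissions.means[[2, 0, 1]]
        np.testing.assert_array_equal(rt.viterbi_decode(obs, model), [2, 0, 1])

    def test_single_bin_picks_highest_weighted_emission(self):
        model = rt.SegmentationModel(
            np.ones(3) / 3,
            np.ones((3, 3)) / 3,
            rt.EmissionParams(
                np.array([[0.0, 0.0], [5.0, 5.0], [9.0, 9.0]]), np.stack([np.eye(2)] * 3)
            ),
        )
        obs = np.array([[5.1, 4.9]])
        assert rt.viterbi_decode(obs, model)[0] == 1

    def test_empty_sequence_gives_empty_path(self):
        rng = np.random.default_rng(9)
        assert rt.viterbi_decode(np.empty((0, 2)), random_model(rng)).size == 0

    def test_matches_exhaustive_enumeration(self):
        """Path and path score equal brute force for sequences of <= 8 bins."""
        rng = np.random.default_rng(10)
        for _ in range(30):
            model = random_model(rng)
            n = int(rng.integers(1, 9))
            obs = rng.normal(0, 2, size=(n, 2))
            path = rt.viterbi_decode(obs, model)
            best_lp, _ = brute_force_best_path(obs, model)
            assert path_logprob(obs, path, model) == pytest.approx(best_lp, abs=1e-9)

    def test_matches_hmmlearn_decode(self):
        hmm = pytest.importorskip("hmmlearn.hmm")
        rng = np.random.default_rng(11)
        model = random_model(rng)
        model.emissions.means *= 2  # separate states to avoid tie ambiguity
        _, obs = sample_hmm(model, 300, rng)
        ref = hmm.GaussianHMM(n_components=3, covariance_type="full", init_params="")
        ref.startprob_ = model.startprob
        ref.transmat_ = model.transmat
        ref.means_ = model.emissions.means
        ref.covars_ = model.emissions.covs
        _, ref_path = ref.decode(obs, algorithm="viterbi")
        np.testing.assert_array_equal(rt.viterbi_decode(obs, model), ref_path)


class TestMergeShortRuns:
    def test_short_middle_run_absorbed(self):
        seq = np.array([0] * 50 + [1] * 10 + [0] * 50)
        np.testing.assert_array_equal(rt.merge_short_runs(seq, 40), np.zeros(110))

    def test_short_run_joins_larger_neighbour(self):
        seq = np.array([0] * 50 + [1] * 39 + [2] * 60)
        merged = rt.merge_short_runs(seq, 40)
        np.testing.assert_array_equal(merged, [0] * 50 + [2] * 99)

    def test_whole_chromosome_run_untouched(self):
        seq = np.full(30, 1)
        np.testing.assert_array_equal(rt.merge_short_runs(seq, 40), seq)

    def test_no_new_labels_and_no_subthreshold_runs(self):
        rng = np.random.default_rng(12)
        seq = rng.integers(0, 3, size=500)
        merged = rt.merge_short_runs(seq, 40)
        assert set(np.unique(merged)) <= set(np.unique(seq))
        runs = _runs(merged)
        assert len(runs) == 1 or all(length >= 40 for _, _, length in runs)

    def test_left_neighbour_wins_flank_ties(self):
        seq = np.array([0] * 50 + [1] * 10 + [2] * 50)
        merged = rt.merge_short_runs(seq, 40)
        np.testing.assert_array_equal(merged, [0] * 60 + [2] * 50)


class TestDomains:
    def grid(self, length=1_000_000):
        return rt.BinGrid({"chr1": length}, width=5_000, step=1_000)

    def model(self):
        return rt.SegmentationModel(
            np.ones(3) / 3,
            np.ones((3, 3)) / 3,
            rt.EmissionParams(np.zeros((3, 2)), np.stack([np.eye(2)] * 3)),
            state_labels=("late", "indeterminate", "early"),
        )

    def test_uniform_sequence_gives_single_domain(self):
        g = self.grid()
        states = np.full(g.n_bins("chr1"), 2)
        doms = rt.states_to_domains(states, "chr1", g, self.model())
        assert len(doms) == 1
        assert doms.iloc[0]["label"] == "early"
        assert doms.iloc[0]["start"] == 0
        assert doms.iloc[0]["end"] == g.starts("chr1")[-1] + g.step

    def test_alternating_runs_tile_without_gap_or_overlap(self):
        g = self.grid(length=400_000)
        states = np.tile(np.repeat([2, 0], 100), 2)
        doms = rt.states_to_domains(states, "chr1", g, self.model())
        assert len(doms) == 4
        assert (doms["start"].to_numpy()[1:] == doms["end"].to_numpy()[:-1]).all()

    def test_scores_are_mean_posterior(self):
        g = rt.BinGrid({"chr1": 10_000}, width=5_000, step=1_000)
        states = np.zeros(10, dtype=int)
        gamma = np.full((10, 3), [0.8, 0.1, 0.1])
        doms = rt.states_to_domains(states, "chr1", g, self.model(), gamma)
        assert doms.iloc[0]["score"] == pytest.approx(0.8)

    def test_overlapping_intervals_rejected(self):
        df = pd.DataFrame(
            {"chrom": ["chr1", "chr1"], "start": [0, 500], "end": [1000, 1500], "label": "early"}
        )
        with pytest.raises(ValueError, match="overlap"):
            rt.DomainSet(intervals=df)


class TestEndToEnd:
    def test_planted_domains_recovered(self, default_segmentation, default_truth):
        """>= 95% of positions get the planted label; median boundary error
        <= 10 kb; < 10% of called genome indeterminate."""
        _, domains, models = default_segmentation
        assert label_accuracy(domains, default_truth) >= 0.95
        assert np.median(boundary_errors(domains, default_truth)) <= 10_000
        iv = domains.intervals
        lengths = iv["end"] - iv["start"]
        ind = lengths[iv["label"] == "indeterminate"].sum() / lengths.sum()
        assert ind < 0.10

    def test_every_training_run_monotone(self, default_segmentation):
        _, _, models = default_segmentation
        for model in models.values():
            assert (np.diff(model.loglik_trace) >= -1e-8).all()

    def test_merged_runs_respect_min_length(self, default_segmentation):
        _, domains, _ = default_segmentation
        for chrom, sub in domains.intervals.groupby("chrom"):
            lengths = (sub["end"] - sub["start"]).to_numpy()
            # 40 one-kb steps, minus the window/step overhang on the last run
            assert (lengths >= 40 * 1_000).sum() >= len(lengths) - 1

    def test_domain_intervals_disjoint_and_sorted(self, default_segmentation):
        _, domains, _ = default_segmentation
        for chrom, sub in domains.intervals.groupby("chrom"):
            starts = sub["start"].to_numpy()
            ends = sub["end"].to_numpy()
            assert (np.diff(starts) > 0).all()
            assert (starts[1:] >= ends[:-1]).all()
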