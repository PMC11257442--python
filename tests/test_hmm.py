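"""HMM fitting, forward/Viterbi recursions and domain segmentation.

The forward likelihood and Viterbi path are checked against exhaustive
enumeration over all state paths for short sequences; the forward
likelihood is additionally cross-checked against an independent HMM
library on identical fixed parameters.
"""

from itertools import product

import numpy as np
import pytest
from scipy.stats import norm

import perichrom as pc
from perichrom.hmm import (DegenerateInputError, StateLabeling, StatePath,
                           transform, CLASS_ORDER)

from conftest import make_track


def random_model(rng, n_states, censored=False):
    pi = rng.dirichlet(np.ones(n_states))
    A = rng.dirichlet(np.ones(n_states), size=n_states)
    means = np.sort(rng.normal(0, 3, n_states))
    sds = rng.uniform(0.3, 2.0, n_states)
    return pc.HmmModel(pi, A, means, sds, censored=censored)


def emission_density(model, x, k):
    """Independent emission density used by the brute-force oracles."""
    if model.censored and x <= 0:
        return norm.cdf(0.0, loc=model.means[k], scale=model.sds[k])
    return norm.pdf(x, loc=model.means[k], scale=model.sds[k])


def brute_force_loglik(model, seq):
    total = 0.0
    for path in product(range(model.n_states), repeat=len(seq)):
        p = model.initial[path[0]] * emission_density(model, seq[0], path[0])
        for t in range(1, len(seq)):
            p *= model.transition[path[t - 1], path[t]] \
                * emission_density(model, seq[t], path[t])
        total += p
    return np.log(total)


def brute_force_viterbi(model, seq):
    best, best_p = None, -1.0
    for path in product(range(model.n_states), repeat=len(seq)):
        p = model.initial[path[0]] * emission_density(model, seq[0], path[0])
        for t in range(1, len(seq)):
            p *= model.transition[path[t - 1], path[t]] \
                * emission_density(model, seq[t], path[t])
        if p > best_p:
            best, best_p = path, p
    return np.array(best)


class TestForward:
    @pytest.mark.parametrize("seed", range(12))
    def test_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(1, 5))
        t = int(rng.integers(1, 9))
        model = random_model(rng, k, censored=bool(seed % 2))
        seq = rng.normal(0, 3, t)
        assert pc.forward_loglik(model, seq) == pytest.approx(
            brute_force_loglik(model, seq), abs=1e-9)

    def test_length_one_closed_form(self):
        rng = np.random.default_rng(3)
        model = random_model(rng, 3)
        x = 0.7
        expected = np.log(np.sum(model.initial
                                 * norm.pdf(x, model.means, model.sds)))
        assert pc.forward_loglik(model, [x]) == pytest.approx(expected, abs=1e-12)

    def test_state_duplication_invariance(self):
        """Splitting a state's initial mass across two identical states
        leaves the likelihood unchanged."""
        pi = np.array([0.6, 0.4])
        A = np.array([[0.7, 0.3], [0.2, 0.8]])
        m1 = pc.HmmModel(pi, A, np.array([0.0, 2.0]), np.array([1.0, 1.0]),
                         censored=False)
        # duplicate state 0: split its initial mass; transitions into the
        # pair are split evenly, rows of the copies identical
        pi3 = np.array([0.3, 0.3, 0.4])
        A3 = np.array([[0.35, 0.35, 0.3],
                       [0.35, 0.35, 0.3],
                       [0.10, 0.10, 0.8]])
        m2 = pc.HmmModel(pi3, A3, np.array([0.0, 0.0, 2.0]),
                         np.array([1.0, 1.0, 1.0]), censored=False)
        seq = [0.5, -1.0, 2.2, 0.0]
        assert pc.forward_loglik(m1, seq) == pytest.approx(
            pc.forward_loglik(m2, seq), abs=1e-12)

    def test_empty_sequence_rejected(self):
        model = random_model(np.random.default_rng(0), 2)
        with pytest.raises(ValueError):
            pc.forward_loglik(model, [])

    def test_agrees_with_hmmlearn_on_fixed_params(self):
        hmmlearn = pytest.importorskip("hmmlearn.hmm")
        rng = np.random.default_rng(7)
        model = random_model(rng, 3, censored=False)
        seq = rng.normal(0, 2, 200)
        ref = hmmlearn.GaussianHMM(n_components=3, covariance_type="diag",
                                   init_params="")
        ref.startprob_ = model.initial
        ref.transmat_ = model.transition
        ref.means_ = model.means[:, None]
        ref.covars_ = (model.sds**2)[:, None]
        assert pc.forward_loglik(model, seq) == pytest.approx(
            ref.score(seq[:, None]), abs=1e-6)


class TestViterbi:
    @pytest.mark.parametrize("seed", range(8))
    def test_short_sequences_match_enumeration(self, seed):
        rng = np.random.default_rng(100 + seed)
        k = int(rng.integers(2, 5))
        model = random_model(rng, k)
        layout = pc.GenomeLayout(("c",), (3_000,))
        raw = np.maximum(np.expm1(rng.normal(0, 2, 3)), 0)
        track = make_track(layout, 1_000, {"c": raw})
        path = pc.decode_states(model, track)
        expected = brute_force_viterbi(model, transform(raw))
        assert np.array_equal(path.states["c"], expected)

    def test_single_bin_argmax(self):
        rng = np.random.default_rng(5)
        model = random_model(rng, 4)
        layout = pc.GenomeLayout(("c",), (1_000,))
        track = make_track(layout, 1_000, {"c": [2.0]})
        path = pc.decode_states(model, track)
        x = transform(np.array([2.0]))[0]
        dens = np.array([emission_density(model, x, k) for k in range(4)])
        assert path.states["c"][0] == np.argmax(model.initial * dens)


class TestFit:
    def test_parameter_recovery_small_genome(self):
        cfg = pc.SynthConfig(seed=4, n_chromosomes=2, chrom_length_bp=15_000_000)
        truth = pc.generate_truth(cfg)
        track, spike = pc.simulate_tracks(truth, "wildtype")[0]
        norm_track = pc.normalize_track(track, pc.compute_scale_factor(spike))
        model = pc.fit_hmm(norm_track, seed=0, n_restarts=2)
        recovered = np.sort(model.means)
        assert np.abs(recovered - np.asarray(cfg.emission_means)).max() < 0.15

    def test_loglik_trace_monotone(self):
        cfg = pc.SynthConfig(seed=4, n_chromosomes=1, chrom_length_bp=10_000_000)
        truth = pc.generate_truth(cfg)
        track, _ = pc.simulate_tracks(truth, "wildtype")[0]
        model = pc.fit_hmm(track, seed=1, n_restarts=1)
        trace = np.asarray(model.loglik_trace)
        assert (np.diff(trace) >= -1e-6 * np.abs(trace[:-1])).all()

    def test_single_state_closed_form(self):
        layout = pc.GenomeLayout(("c",), (20_000,))
        vals = np.array([1.0, 3.0, 0.5, 7.0, 2.0, 4.0, 9.0, 1.5,
                         2.5, 6.0, 0.7, 3.3, 8.0, 1.1, 2.2, 4.4,
                         5.5, 0.9, 3.7, 6.6])
        track = make_track(pc.GenomeLayout(("c",), (20_000,)), 1_000, {"c": vals})
        model = pc.fit_hmm(track, n_states=1, n_restarts=1, censored=False)
        x = transform(vals)
        assert model.means[0] == pytest.approx(x.mean(), abs=1e-6)
        assert model.sds[0] == pytest.approx(x.std(), abs=1e-6)

    def test_constant_track_rejected(self):
        layout = pc.GenomeLayout(("c",), (50_000,))
        track = make_track(layout, 1_000, {"c": np.full(50, 2.0)})
        with pytest.raises(DegenerateInputError):
            pc.fit_hmm(track)

    def test_decode_recovers_planted_states_noise_free(self):
        cfg = pc.SynthConfig(seed=9, n_chromosomes=1, chrom_length_bp=5_000_000,
                             emission_sds=(0.0, 0.0, 0.0, 0.0),
                             replicate_noise_sd=0.0, blacklist_fraction=0.01)
        truth = pc.generate_truth(cfg)
        track, _ = pc.simulate_tracks(truth, "wildtype")[0]
        model = pc.HmmModel(np.full(4, 0.25),
                            np.full((4, 4), 0.01) + np.eye(4) * 0.96,
                            np.asarray(cfg.emission_means),
                            np.full(4, 0.3))
        path = pc.decode_states(model, track)
        assert np.array_equal(path.states["chr1"], truth.states["wildtype"]["chr1"])


class TestLabeling:
    def test_sorted_by_mean(self):
        model = pc.HmmModel(np.full(4, 0.25), np.eye(4),
                            np.array([8.0, 0.0, 3.0, 1.0]),
                            np.full(4, 0.5))
        lab = pc.label_states(model)
        assert lab.state_to_class == {0: "blacklist", 1: "background",
                                      2: "class2", 3: "class1"}

    def test_identity_when_already_sorted(self):
        model = pc.HmmModel(np.full(4, 0.25), np.eye(4),
                            np.array([0.0, 1.0, 3.0, 8.0]), np.full(4, 0.5))
        lab = pc.label_states(model)
        assert [lab.state_to_class[i] for i in range(4)] == list(CLASS_ORDER)

    def test_tied_means_deterministic_with_warning(self):
        model = pc.HmmModel(np.full(4, 0.25), np.eye(4),
                            np.array([0.0, 1.0, 1.0, 8.0]),
                            np.array([0.5, 0.4, 0.2, 0.5]))
        with pytest.warns(RuntimeWarning, match="tie"):
            lab = pc.label_states(model)
        # smaller sd wins the lower class slot
        assert lab.state_to_class[2] == "class1"
        assert lab.state_to_class[1] == "class2"


class TestSegmentation:
    LAB = StateLabeling({0: "background", 1: "class1", 2: "class2",
                         3: "blacklist"})

    def test_runs_become_intervals(self):
        layout = pc.GenomeLayout(("c",), (60_000,))
        path = StatePath({"c": np.array([0, 1, 1, 2, 2, 0])}, 10_000)
        ds = pc.segment_domains(path, self.LAB, layout)
        assert list(ds.df.itertuples(index=False, name=None)) == [
            ("c", 10_000, 30_000, "class1"), ("c", 30_000, 50_000, "class2")]

    def test_all_background_empty(self):
        layout = pc.GenomeLayout(("c",), (40_000,))
        path = StatePath({"c": np.zeros(4, dtype=int)}, 10_000)
        assert pc.segment_domains(path, self.LAB, layout).is_empty

    def test_blacklist_splits_domain(self):
        layout = pc.GenomeLayout(("c",), (50_000,))
        path = StatePath({"c": np.array([1, 1, 3, 1, 1])}, 10_000)
        ds = pc.segment_domains(path, self.LAB, layout)
        assert len(ds) == 2
        assert ds.df["start"].tolist() == [0, 30_000]

    def test_gap_merging_skips_other_class(self):
        layout = pc.GenomeLayout(("c",), (70_000,))
        path = StatePath({"c": np.array([1, 0, 1, 2, 2, 0, 2])}, 10_000)
        ds = pc.segment_domains(path, self.LAB, layout, max_gap_bins=1)
        recs = list(ds.df.itertuples(index=False, name=None))
        # each class bridges its own 1-bin background gap, and the class2
        # run between the class1 runs is never swallowed by class1
        assert recs == [("c", 0, 30_000, "class1"),
                        ("c", 30_000, 70_000, "class2")]

    def test_min_domain_bins_drops_short_runs(self):
        layout = pc.GenomeLayout(("c",), (50_000,))
        path = StatePath({"c": np.array([1, 0, 2, 2, 0])}, 10_000)
        ds = pc.segment_domains(path, self.LAB, layout, min_domain_bins=2)
        assert ds.df["domain_class"].tolist() == ["class2"]

    def test_terminal_partial_bin_clipped_to_chromosome(self):
        layout = pc.GenomeLayout(("c",), (23_000,))
        path = StatePath({"c": np.array([0, 1, 1])}, 10_000)
        ds = pc.segment_domains(path, self.LAB, layout)
        assert ds.df["end"].tolist() == [23_000]

    def test_bp_equals_domain_bins_times_bin_size(self):
        rng = np.random.default_rng(2)
        states = rng.integers(0, 4, 400)
        layout = pc.GenomeLayout(("c",), (4_000_000,))
        path = StatePath({"c": states}, 10_000)
        ds = pc.segment_domains(path, self.LAB, layout)
        n_domain_bins = int(np.isin(states, (1, 2)).sum())
        assert ds.total_bp == n_domain_bins * 10_000


class TestPosteriors:
    def test_rows_sum_to_one_and_match_decode(self):
        from perichrom.hmm import state_posteriors, write_posteriors_tsv

        cfg = pc.SynthConfig(seed=6, n_chromosomes=1, chrom_length_bp=3_000_000)
        truth = pc.generate_truth(cfg)
        track, _ = pc.simulate_tracks(truth, "wildtype")[0]
        model = pc.fit_hmm(track, seed=0, n_restarts=1)
        post = state_posteriors(model, track)
        gamma = post["chr1"]
        assert gamma.shape == (300, 4)
        assert np.allclose(gamma.sum(axis=1), 1.0)
        # posterior argmax decoding equals the exported posteriors' argmax
        path = pc.decode_states(model, track, method="posterior")
        assert np.array_equal(path.states["chr1"], np.argmax(gamma, axis=1))

    def test_tsv_export(self, tmp_path):
        from perichrom.hmm import state_posteriors, write_posteriors_tsv

        cfg = pc.SynthConfig(seed=6, n_chromosomes=1, chrom_length_bp=1_000_000)
        truth = pc.generate_truth(cfg)
        track, _ = pc.simulate_tracks(truth, "wildtype")[0]
        model = pc.fit_hmm(track, seed=0, n_restarts=1)
        out = tmp_path / "post.tsv"
        write_posteriors_tsv(state_posteriors(model, track), 10_000, out)
        lines = out.read_text().splitlines()
        assert lines[0].startswith("chrom\tstart\tp_state0")
        assert len(lines) == 101
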