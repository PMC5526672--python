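"""Dependence statistics, Markov/HMM/mode-model estimation."""

import numpy as np
import pytest

import flywalk as fw
from flywalk.sequences import (
    ModeMarkovModel,
    SymbolSequence,
    build_mode_model,
    check_stationarity,
    dependence_stats,
    fit_markov,
    free_parameters,
    loglik_test,
    train_hmm,
)


def _entropy(p):
    p = np.asarray(p, float)
    p = p[p > 0]
    return -(p * np.log2(p)).sum()


class TestDependence:
    def test_iid_uniform_rho_near_zero(self, rng):
        seqs = [rng.integers(0, 5, size=100) for _ in range(100)]
        d = dependence_stats(seqs, n_boot=200, rng=0)
        # plug-in bias for MI is O(levels^2 / 2 n ln 2)
        bias = 25 / (2 * 10_000 * np.log(2)) / _entropy(np.full(5, 0.2))
        assert d.rho < 5 * bias + d.rho_ci[1]
        assert d.rho < 0.01

    def test_deterministic_cycle_rho_is_one(self):
        seqs = [np.tile([0, 1, 2], 50) for _ in range(10)]
        d = dependence_stats(seqs, n_boot=50, rng=0)
        # finite-pool edge effects perturb the marginal at O(1/n)
        assert d.rho == pytest.approx(1.0, abs=1e-3)

    def test_two_state_chain_matches_closed_form(self):
        P = np.array([[0.9, 0.1], [0.2, 0.8]])
        pi = fw.stationary_distribution(P)
        H_s = _entropy(pi)
        H_c = pi @ np.array([_entropy(P[0]), _entropy(P[1])])
        rho_exact = (H_s - H_c) / H_s
        seqs = fw.generate_symbol_sequences(P, 300, 400, 3)
        d = dependence_stats(seqs, n_boot=200, rng=1)
        assert abs(d.rho - rho_exact) < 0.01
        # order-1 data leaves no residual two-step dependence
        assert abs(d.rho2) < 0.01

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError):
            dependence_stats([], n_boot=10, rng=0)


class TestMarkovFit:
    def test_deterministic_cycle_gives_permutation_matrix(self):
        m = fit_markov([np.tile([0, 1, 2], 40)], order=1)
        expected = np.array([[0, 1, 0], [0, 0, 1], [1, 0, 0]], float)
        np.testing.assert_allclose(m.transition_matrix_, expected, atol=1e-12)

    def test_order_zero_is_marginal(self, rng):
        seqs = [rng.integers(0, 4, size=50) for _ in range(20)]
        m = fit_markov(seqs, order=0)
        pooled = np.concatenate(seqs)
        np.testing.assert_allclose(
            m.probs_, np.bincount(pooled, minlength=4) / len(pooled)
        )

    def test_known_chain_recovered_within_binomial_error(self):
        P = np.array([[0.6, 0.3, 0.1], [0.2, 0.5, 0.3], [0.4, 0.1, 0.5]])
        seqs = fw.generate_symbol_sequences(P, 1, 60_000, 5)
        m = fit_markov(seqs, order=1)
        counts = np.zeros((3, 3))
        a = seqs[0]
        np.add.at(counts, (a[:-1], a[1:]), 1)
        n_row = counts.sum(axis=1, keepdims=True)
        sd = np.sqrt(P * (1 - P) / n_row)
        assert np.all(np.abs(m.transition_matrix_ - P) < 3 * sd + 1e-12)

    def test_order_two_sampling_round_trip(self, rng):
        # a strongly order-2 process: symbol repeats the one two steps back
        seqs = []
        for _ in range(50):
            a = rng.integers(0, 2, size=2).tolist()
            for i in range(2, 60):
                a.append(a[i - 2] if rng.random() < 0.9 else 1 - a[i - 2])
            seqs.append(np.array(a))
        m2 = fit_markov(seqs, order=2)
        gen = m2.sample_sequences(200, 60, rng=1)
        d = dependence_stats(gen, n_boot=50, rng=2)
        assert d.rho2 > 0.3  # generated data preserves two-step structure


class TestHMM:
    def test_one_state_emissions_are_empirical_frequencies(self, rng):
        seqs = [rng.choice(3, size=40, p=[0.5, 0.3, 0.2]) for _ in range(50)]
        hmm = train_hmm(seqs, n_states=1, n_restarts=3, random_state=0)
        pooled = np.concatenate(seqs)
        freq = np.bincount(pooled, minlength=3) / len(pooled)
        np.testing.assert_allclose(
            hmm.params_.emissionprob[0], freq, atol=1e-6
        )

    def test_planted_two_state_model_recovered(self):
        Tr = np.array([[0.85, 0.15], [0.25, 0.75]])
        Em = np.array([[0.9, 0.1, 0.0], [0.0, 0.15, 0.85]])
        seqs = fw.generate_symbol_sequences(Tr, 250, 50, 7, emission=Em)
        hmm = train_hmm(seqs, n_states=2, n_restarts=5, n_train=250,
                        random_state=1)
        got_T = hmm.params_.transmat
        got_E = hmm.params_.emissionprob
        # states identified up to relabeling
        perms = [(0, 1), (1, 0)]
        errs = []
        for p in perms:
            errs.append(
                max(
                    np.abs(got_T[np.ix_(p, p)] - Tr).max(),
                    np.abs(got_E[list(p)] - Em).max(),
                )
            )
        assert min(errs) < 0.05

    def test_same_seed_same_model(self, rng):
        seqs = [rng.integers(0, 4, size=30) for _ in range(60)]
        a = train_hmm(seqs, n_states=2, n_restarts=3, random_state=9)
        b = train_hmm(seqs, n_states=2, n_restarts=3, random_state=9)
        np.testing.assert_array_equal(a.params_.transmat, b.params_.transmat)


class TestModeModel:
    def test_trivial_grouping_equals_order_one_fit(self):
        seqs = fw.generate_symbol_sequences(fw.TABLE1_RATES, 50, 200, 3)
        mm = build_mode_model(seqs, [[0], [1], [2], [3], [4]])
        m1 = fit_markov(seqs, order=1)
        np.testing.assert_allclose(
            mm.transmat_, m1.transition_matrix_, atol=1e-12
        )
        np.testing.assert_allclose(mm.emissionprob_, np.eye(5), atol=1e-12)

    def test_hand_counted_toy(self):
        # sequence a,b,a,b,c,a with grouping {a,b},{c}:
        # group transitions (q0->q0) x3, (q0->q1), (q1->q0);
        # emissions: q0 -> a:3/5, b:2/5; q1 -> c:1
        mm = build_mode_model([np.array([0, 1, 0, 1, 2, 0])], [[0, 1], [2]])
        np.testing.assert_allclose(
            mm.transmat_, [[0.75, 0.25], [1.0, 0.0]], atol=1e-12
        )
        np.testing.assert_allclose(
            mm.emissionprob_, [[0.6, 0.4, 0.0], [0.0, 0.0, 1.0]], atol=1e-12
        )

    def test_rows_sum_to_one_and_one_nonzero_per_column(self):
        seqs = fw.generate_symbol_sequences(fw.TABLE1_RATES, 100, 50, 1)
        grouping = [[0, 1], [2, 3], [4]]
        mm = build_mode_model(seqs, grouping)
        np.testing.assert_allclose(mm.transmat_.sum(axis=1), 1.0, atol=1e-9)
        np.testing.assert_allclose(
            mm.emissionprob_.sum(axis=1), 1.0, atol=1e-9
        )
        assert np.all((mm.emissionprob_ > 0).sum(axis=0) == 1)

    def test_mode_marginals_preserved_by_expansion(self):
        seqs = fw.generate_symbol_sequences(fw.TABLE1_RATES, 200, 100, 5)
        grouping = [[0, 1], [2], [3, 4]]
        mm = build_mode_model(seqs, grouping)
        # expand: sample symbols and re-group
        gen = mm.sample_sequences(200, 100, rng=0)
        regrouped = np.concatenate([mm.mode_of_[s] for s in gen])
        emp = np.bincount(regrouped, minlength=3) / len(regrouped)
        direct = np.concatenate([mm.mode_of_[np.asarray(s)] for s in seqs])
        ref = np.bincount(direct, minlength=3) / len(direct)
        assert 0.5 * np.abs(emp - ref).sum() < 0.02

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            build_mode_model([np.array([0, 1])], [[0, 1], []])

    def test_sub_resolution_transitions_flagged(self):
        mm = ModeMarkovModel(grouping=[[0], [1], [2]])
        seqs = fw.generate_symbol_sequences(
            np.array([[0.998, 0.001, 0.001],
                      [0.3, 0.4, 0.3],
                      [0.3, 0.3, 0.4]]),
            5, 20_000, 3,
        )
        mm.fit(seqs)
        low = mm.low_resolution_transitions(0.005)
        assert len(low) >= 1


class TestFreeParameters:
    @pytest.mark.parametrize(
        "N,M,kind,expected",
        [(5, 15, "hmm", 90), (5, 15, "mm", 30), (1, 1, "hmm", 0)],
    )
    def test_printed_formulas(self, N, M, kind, expected):
        assert free_parameters(N, M, kind) == expected

    def test_mm_needs_enough_symbols(self):
        with pytest.raises(ValueError):
            free_parameters(5, 3, "mm")

    def test_mm_cheaper_than_hmm(self):
        # with a single state the two coincide, so start at N=2
        for N in range(2, 7):
            for M in range(max(N, 2), 16):
                assert free_parameters(N, M, "mm") < free_parameters(
                    N, M, "hmm"
                )


class TestLoglik:
    def test_deterministic_model_scores_zero(self):
        # single-symbol alphabet: the model assigns probability one
        m = fit_markov([np.zeros(30, dtype=int)], order=1)
        mean, sd = loglik_test(m, [np.zeros(30, dtype=int)] * 5, n_sets=3,
                               set_size=5, rng=0)
        assert mean == pytest.approx(0.0, abs=1e-12)

    def test_iid_uniform_closed_form(self, rng):
        A, L = 4, 25
        m = fit_markov([np.tile(np.arange(A), 100)], order=0)
        seqs = [rng.integers(0, A, size=L) for _ in range(40)]
        mean, _ = loglik_test(m, seqs, n_sets=4, set_size=20, rng=1)
        assert mean == pytest.approx(-L * np.log(A), rel=1e-9)

    def test_true_model_beats_perturbed(self):
        P = fw.TABLE1_RATES
        Pp = P.copy()
        Pp[:, 0] += 0.15
        Pp /= Pp.sum(axis=1, keepdims=True)
        true_m = ModeMarkovModel([[i] for i in range(5)]).fit(
            fw.generate_symbol_sequences(P, 500, 30, 0)
        )
        pert_m = ModeMarkovModel([[i] for i in range(5)]).fit(
            fw.generate_symbol_sequences(Pp, 500, 30, 1)
        )
        rng = np.random.default_rng(2)
        wins = 0
        trials = 40
        for _ in range(trials):
            data = fw.generate_symbol_sequences(P, 30, 30, rng)
            lt = np.mean([true_m.log_likelihood(s) for s in data])
            lp = np.mean([pert_m.log_likelihood(s) for s in data])
            wins += lt > lp
        assert wins >= 0.95 * trials

    def test_symbol_outside_alphabet_rejected(self):
        mm = build_mode_model([np.array([0, 1, 0, 1])], [[0], [1]])
        with pytest.raises(ValueError):
            mm.log_likelihood(np.array([0, 2]))


class TestStationarity:
    def _timed(self, seqs, step=0.167, t0=0.0):
        out = []
        t = t0
        for s in seqs:
            out.append(SymbolSequence(s, t + np.arange(len(s)) * step))
            t += len(s) * step
        return out

    def test_stationary_data_not_rejected(self):
        seqs = self._timed(
            fw.generate_symbol_sequences(fw.TABLE1_RATES, 300, 40, 4)
        )
        rep = check_stationarity(seqs, fw.TABLE1_RATES)
        assert rep.chi2_pvalue > 0.01
        assert rep.tv_distance < 0.02

    def test_planted_drift_rejected(self, rng):
        # symbol frequencies drift over the experiment
        seqs = []
        t = 0.0
        for i in range(300):
            p = np.array([0.7, 0.3]) if i < 150 else np.array([0.3, 0.7])
            s = rng.choice(2, size=40, p=p)
            seqs.append(SymbolSequence(s, t + np.arange(40) * 0.167))
            t += 40 * 0.167
        rep = check_stationarity(seqs)
        assert rep.chi2_pvalue < 0.01

    def test_equilibrium_matches_long_run_marginal(self):
        s = fw.sample_state_sequence(fw.TABLE1_RATES, 100_000, 9)
        emp = np.bincount(s, minlength=5) / len(s)
        pi = fw.stationary_distribution(fw.TABLE1_RATES)
        assert 0.5 * np.abs(emp - pi).sum() < 0.01
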