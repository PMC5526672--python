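"""Symbol sequences, Markov-order diagnostics, HMM and mode-model fits.

Classified trajectories become sequences of submode symbols at vR-peak
times.  Two plug-in statistics diagnose how much history matters:

    rho   = I(u_i ; u_{i-1}) / H(u)            (one-step dependence)
    rho_2 = I(u_i ; u_{i-2} | u_{i-1})
            / H(u_i | u_{i-1})                 (residual two-step dependence)

A first-order chain leaves rho_2 ~ 0.  Hidden Markov models over the
submode alphabet (states q, row-stochastic transition Tr and emission
Em matrices) let statistically interchangeable submodes share a state;
when, as observed, almost every submode is dominated by one state, the
hidden layer collapses to a *mode model* (MM): a Markov chain over
modes with a deterministic submode-to-mode map, estimated directly from
submode occurrence frequencies.  An N-state model over M symbols has
N(N-1) + N(M-1) free parameters as an HMM but only N(N-1) + (M-N) as
an MM.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator

from .simulate import (
    _check_stochastic,
    generate_symbol_sequences,
    stationary_distribution,
)

__all__ = [
    "SymbolSequence",
    "DependenceStats",
    "dependence_stats",
    "MarkovChainModel",
    "fit_markov",
    "SubmodeHMM",
    "train_hmm",
    "ModeMarkovModel",
    "build_mode_model",
    "free_parameters",
    "loglik_test",
    "StationarityReport",
    "check_stationarity",
]


@dataclass
class SymbolSequence:
    """Ordered submode ids with their vR-peak times."""

    symbols: np.ndarray
    times: np.ndarray | None = None
    traj_id: str = ""

    def __post_init__(self):
        self.symbols = np.asarray(self.symbols, dtype=np.intp)
        if self.times is not None:
            self.times = np.asarray(self.times, dtype=float)
            if len(self.times) != len(self.symbols):
                raise ValueError("times and symbols length mismatch")
            if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
                raise ValueError("times must be strictly increasing")

    def __len__(self):
        return len(self.symbols)


def _as_symbol_arrays(seqs):
    out = []
    for s in seqs:
        out.append(s.symbols if isinstance(s, SymbolSequence) else
                   np.asarray(s, dtype=np.intp))
    return out


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def _dependence_point(arrs, M):
    """(rho, rho2) plug-in estimates pooled over sequences."""
    pairs = np.zeros((M, M))
    triples = np.zeros((M, M, M))
    marg = np.zeros(M)
    for a in arrs:
        np.add.at(marg, a, 1.0)
        if len(a) >= 2:
            np.add.at(pairs, (a[:-1], a[1:]), 1.0)
        if len(a) >= 3:
            np.add.at(triples, (a[:-2], a[1:-1], a[2:]), 1.0)
    marg = marg / marg.sum()
    H_u = _entropy(marg)
    rho = np.nan
    if pairs.sum() > 0 and H_u > 0:
        pj = pairs / pairs.sum()
        I1 = (
            _entropy(pj.sum(0)) + _entropy(pj.sum(1)) - _entropy(pj.ravel())
        )
        rho = I1 / H_u
    rho2 = np.nan
    if triples.sum() > 0:
        pt = triples / triples.sum()
        # I(u_i; u_{i-2} | u_{i-1}) = H(ui|um1) + H(um2|um1) - H(ui,um2|um1)
        H_01 = _entropy(pt.sum(2).ravel())  # H(um2, um1)
        H_12 = _entropy(pt.sum(0).ravel())  # H(um1, ui)
        H_1 = _entropy(pt.sum((0, 2)))  # H(um1)
        H_012 = _entropy(pt.ravel())
        I2 = H_01 + H_12 - H_1 - H_012
        Hcond = H_12 - H_1  # H(ui | um1)
        rho2 = I2 / Hcond if Hcond > 0 else np.nan
    return rho, rho2


@dataclass
class DependenceStats:
    rho: float
    rho2: float
    rho_ci: tuple
    rho2_ci: tuple
    alphabet_size: int
    n_transitions: int


def dependence_stats(
    seqs, n_boot: int = 1000, rng=None, alphabet_size: int | None = None
) -> DependenceStats:
    """History-dependence fractions rho and rho_2 with bootstrap CI95.

    Plug-in (maximum-likelihood) entropies pooled over sequences; the
    CI resamples whole sequences (trajectories are the independent
    unit).  Short sequences contribute what they can (pairs need length
    >= 2, triples >= 3).
    """
    rng = np.random.default_rng(rng)
    arrs = _as_symbol_arrays(seqs)
    if not arrs or sum(len(a) for a in arrs) == 0:
        raise ValueError("empty sequence pool")
    M = alphabet_size or int(max(a.max() for a in arrs if len(a))) + 1
    rho, rho2 = _dependence_point(arrs, M)
    n = len(arrs)
    boots = np.empty((n_boot, 2))
    for b in range(n_boot):
        pick = rng.integers(n, size=n)
        boots[b] = _dependence_point([arrs[i] for i in pick], M)
    lo = np.full(2, np.nan)
    hi = np.full(2, np.nan)
    for j in range(2):
        col = boots[:, j]
        col = col[np.isfinite(col)]
        if col.size:
            lo[j], hi[j] = np.percentile(col, [2.5, 97.5])
    return DependenceStats(
        rho=rho,
        rho2=rho2,
        rho_ci=(float(lo[0]), float(hi[0])),
        rho2_ci=(float(lo[1]), float(hi[1])),
        alphabet_size=M,
        n_transitions=int(sum(max(len(a) - 1, 0) for a in arrs)),
    )


# ---------------------------------------------------------------------------
# count-based Markov chains


class MarkovChainModel(BaseEstimator):
    """Order-k Markov chain over a finite alphabet, fit by counting.

    order 0 is an independence model (marginal frequencies).  Unseen
    contexts fall back to the marginal distribution and are flagged in
    ``unseen_contexts_``.
    """

    def __init__(self, order: int = 1, alphabet_size: int | None = None,
                 min_context_count: int = 5):
        self.order = order
        self.alphabet_size = alphabet_size
        self.min_context_count = min_context_count

    def fit(self, seqs, y=None):
        if self.order not in (0, 1, 2):
            raise ValueError("order must be 0, 1 or 2")
        arrs = _as_symbol_arrays(seqs)
        M = self.alphabet_size or int(max(a.max() for a in arrs if len(a))) + 1
        k = self.order
        counts = np.zeros((M,) * (k + 1))
        marg = np.zeros(M)
        for a in arrs:
            np.add.at(marg, a, 1.0)
            if len(a) > k:
                idx = tuple(a[i: len(a) - k + i] for i in range(k + 1))
                np.add.at(counts, idx, 1.0)
        self.M_ = M
        self.marginal_ = marg / marg.sum()
        ctx_tot = counts.sum(axis=-1)
        with np.errstate(invalid="ignore", divide="ignore"):
            probs = counts / ctx_tot[..., None]
        unseen = ctx_tot == 0
        probs[unseen] = self.marginal_
        self.probs_ = probs
        self.context_counts_ = ctx_tot
        self.unseen_contexts_ = (
            np.argwhere(unseen) if k > 0 else np.empty((0, 0), dtype=int)
        )
        self.sparse_contexts_ = (
            np.argwhere((ctx_tot > 0) & (ctx_tot < self.min_context_count))
            if k > 0 else np.empty((0, 0), dtype=int)
        )
        return self

    @property
    def transition_matrix_(self) -> np.ndarray:
        if self.order != 1:
            raise AttributeError("transition matrix defined for order 1 only")
        return self.probs_

    def log_likelihood(self, seq) -> float:
        a = seq.symbols if isinstance(seq, SymbolSequence) else np.asarray(seq)
        k = self.order
        with np.errstate(divide="ignore"):
            lp_marg = np.log(self.marginal_)
            lp = np.log(self.probs_)
        ll = lp_marg[a[: min(k, len(a))]].sum() if k else 0.0
        if k == 0:
            return float(lp_marg[a].sum())
        if len(a) > k:
            idx = tuple(a[i: len(a) - k + i] for i in range(k + 1))
            ll += lp[idx].sum()
        return float(ll)

    def sample(self, length: int, rng=None) -> np.ndarray:
        return self.sample_sequences(1, length, rng)[0]

    def sample_sequences(self, n: int, length: int, rng=None):
        """Iterative sampling: first symbols from the marginal, then the
        order-k conditionals (vectorized over sequences)."""
        rng = np.random.default_rng(rng)
        L, k, M = int(length), self.order, self.M_
        out = np.empty((n, L), dtype=np.intp)
        mcum = np.cumsum(self.marginal_)
        warm = L if k == 0 else min(k, L)
        if warm:
            U0 = rng.random((n, warm))
            out[:, :warm] = np.minimum(
                (mcum[None, None, :] < U0[..., None]).sum(axis=-1), M - 1
            )
        if k:
            cum = np.cumsum(self.probs_, axis=-1)
            U = rng.random((n, L))
            for j in range(k, L):
                ctx = tuple(out[:, j - k + i] for i in range(k))
                rows = cum[ctx]
                out[:, j] = np.minimum(
                    (rows < U[:, j: j + 1]).sum(axis=1), M - 1
                )
        return [out[i].copy() for i in range(n)]


def fit_markov(seqs, order: int = 1, alphabet_size: int | None = None
               ) -> MarkovChainModel:
    """Maximum-likelihood order-k chain (k in {0, 1, 2}) from sequences."""
    return MarkovChainModel(order=order, alphabet_size=alphabet_size).fit(seqs)


# ---------------------------------------------------------------------------
# HMM


@dataclass
class HMMParams:
    """Trained hidden-Markov parameters over the submode alphabet."""

    startprob: np.ndarray
    transmat: np.ndarray
    emissionprob: np.ndarray
    log_likelihood: float
    restart_logliks: np.ndarray

    @property
    def n_states(self) -> int:
        return self.transmat.shape[0]

    @property
    def n_symbols(self) -> int:
        return self.emissionprob.shape[1]


class SubmodeHMM(BaseEstimator):
    """Categorical-emission HMM trained by EM from random restarts.

    Each restart draws uniform-then-normalized initial matrices and a
    random training subset of ``n_train`` sequences; the restart with
    the best training log-likelihood wins.  All restart likelihoods are
    retained in ``params_.restart_logliks``.
    """

    def __init__(self, n_states: int = 5, n_restarts: int = 15,
                 n_train: int = 1500, n_iter: int = 200, tol: float = 1e-3,
                 alphabet_size: int | None = None, random_state=None):
        self.n_states = n_states
        self.n_restarts = n_restarts
        self.n_train = n_train
        self.n_iter = n_iter
        self.tol = tol
        self.alphabet_size = alphabet_size
        self.random_state = random_state

    def fit(self, seqs, y=None):
        from hmmlearn.hmm import CategoricalHMM

        if self.n_states < 1:
            raise ValueError("n_states must be >= 1")
        rng = np.random.default_rng(self.random_state)
        arrs = [a for a in _as_symbol_arrays(seqs) if len(a) >= 1]
        M = self.alphabet_size or int(max(a.max() for a in arrs)) + 1
        full_X = np.concatenate(arrs).reshape(-1, 1)
        full_len = [len(a) for a in arrs]
        best = None
        logliks = []
        for _ in range(self.n_restarts):
            take = (
                rng.choice(len(arrs), size=self.n_train, replace=False)
                if len(arrs) > self.n_train
                else np.arange(len(arrs))
            )
            X = np.concatenate([arrs[i] for i in take]).reshape(-1, 1)
            lengths = [len(arrs[i]) for i in take]
            hmm = CategoricalHMM(
                n_components=self.n_states, n_iter=self.n_iter, tol=self.tol,
                init_params="", params="ste",
                random_state=int(rng.integers(2**31 - 1)),
            )
            hmm.n_features = M
            hmm.startprob_ = _random_stochastic(rng, (self.n_states,))
            hmm.transmat_ = _random_stochastic(rng, (self.n_states, self.n_states))
            hmm.emissionprob_ = _random_stochastic(rng, (self.n_states, M))
            try:
                hmm.fit(X, lengths)
                ll = hmm.score(full_X, full_len)
            except Exception:
                continue  # failed restart skipped
            logliks.append(ll)
            if best is None or ll > best[0]:
                best = (ll, hmm)
        if best is None:
            raise RuntimeError("all HMM restarts failed")
        ll, hmm = best
        self.model_ = hmm
        self.params_ = HMMParams(
            startprob=hmm.startprob_.copy(),
            transmat=hmm.transmat_.copy(),
            emissionprob=hmm.emissionprob_.copy(),
            log_likelihood=float(ll),
            restart_logliks=np.asarray(logliks),
        )
        self.alphabet_size_ = M
        return self

    def log_likelihood(self, seq) -> float:
        a = seq.symbols if isinstance(seq, SymbolSequence) else np.asarray(seq)
        if a.max() >= self.alphabet_size_:
            raise ValueError("symbol outside model alphabet")
        return float(self.model_.score(a.reshape(-1, 1)))

    def sample_sequences(self, n: int, length, rng=None):
        rng = np.random.default_rng(rng)
        return generate_symbol_sequences(
            self.params_.transmat, n, length, rng,
            emission=self.params_.emissionprob,
        )


def _random_stochastic(rng, shape):
    m = rng.random(shape)
    if m.ndim == 1:
        return m / m.sum()
    return m / m.sum(axis=-1, keepdims=True)


def train_hmm(seqs, n_states: int, n_restarts: int = 15, n_train: int = 1500,
              random_state=None) -> SubmodeHMM:
    """Best-of-restarts EM fit; thin wrapper over :class:`SubmodeHMM`."""
    return SubmodeHMM(
        n_states=n_states, n_restarts=n_restarts, n_train=n_train,
        random_state=random_state,
    ).fit(seqs)


# ---------------------------------------------------------------------------
# mode model (deterministic emissions)


class ModeMarkovModel(BaseEstimator):
    """Markov chain over modes with deterministic submode-to-mode mapping.

    ``grouping`` is a partition of the submode alphabet (list of symbol
    lists, one per mode).  The mode transition matrix is the
    row-normalized sum of joint submode-transition counts over group
    members, and each mode's emission row holds the within-group
    relative frequencies (so the emission matrix has exactly one
    nonzero per column).
    """

    def __init__(self, grouping=None):
        self.grouping = grouping

    def fit(self, seqs, y=None):
        if not self.grouping:
            raise ValueError("grouping is required")
        groups = [list(g) for g in self.grouping]
        if any(len(g) == 0 for g in groups):
            raise ValueError("empty group in grouping")
        flat = sorted(u for g in groups for u in g)
        M = len(flat)
        if flat != list(range(M)):
            raise ValueError("grouping must partition the alphabet 0..M-1")
        N = len(groups)
        mode_of = np.empty(M, dtype=np.intp)
        for mi, g in enumerate(groups):
            mode_of[np.asarray(g, dtype=int)] = mi

        arrs = _as_symbol_arrays(seqs)
        pair = np.zeros((M, M))
        marg = np.zeros(M)
        for a in arrs:
            if a.size and a.max() >= M:
                raise ValueError("symbol outside grouping alphabet")
            np.add.at(marg, a, 1.0)
            if len(a) >= 2:
                np.add.at(pair, (a[:-1], a[1:]), 1.0)
        mode_pair = np.zeros((N, N))
        np.add.at(mode_pair, (mode_of[:, None], mode_of[None, :]), 0)  # shape
        for i in range(M):
            for j in range(M):
                mode_pair[mode_of[i], mode_of[j]] += pair[i, j]
        rows = mode_pair.sum(axis=1, keepdims=True)
        if (rows == 0).any():
            raise ValueError("a mode has no observed outgoing transitions")
        Tr = mode_pair / rows

        Em = np.zeros((N, M))
        for mi, g in enumerate(groups):
            g = np.asarray(g, dtype=int)
            tot = marg[g].sum()
            if tot == 0:
                raise ValueError(f"group {mi} has no observed symbols")
            Em[mi, g] = marg[g] / tot

        self.n_modes_ = N
        self.alphabet_size_ = M
        self.mode_of_ = mode_of
        self.transmat_ = Tr
        self.emissionprob_ = Em
        self.marginal_ = marg / marg.sum()
        return self

    def mode_sequence(self, seq) -> np.ndarray:
        a = seq.symbols if isinstance(seq, SymbolSequence) else np.asarray(seq)
        return self.mode_of_[a]

    def log_likelihood(self, seq) -> float:
        """Forward log-likelihood of a submode sequence under the MM.

        With deterministic emissions the state path is observed, so the
        forward sum collapses to start + transitions + emissions.
        """
        a = seq.symbols if isinstance(seq, SymbolSequence) else np.asarray(seq)
        if a.max() >= self.alphabet_size_:
            raise ValueError("symbol outside model alphabet")
        m = self.mode_of_[a]
        start = stationary_distribution(self.transmat_)
        with np.errstate(divide="ignore"):
            ll = np.log(start[m[0]]) + np.log(self.emissionprob_[m[0], a[0]])
            if len(a) > 1:
                ll += np.log(self.transmat_[m[:-1], m[1:]]).sum()
                ll += np.log(self.emissionprob_[m[1:], a[1:]]).sum()
        return float(ll)

    def sample_sequences(self, n: int, length, rng=None, symbols: bool = True):
        rng = np.random.default_rng(rng)
        return generate_symbol_sequences(
            self.transmat_, n, length, rng,
            emission=self.emissionprob_ if symbols else None,
        )

    def low_resolution_transitions(self, threshold: float = 0.005) -> np.ndarray:
        """Indices of transition probabilities below the sampling
        resolution of the measured transition rates (~0.005)."""
        return np.argwhere(
            (self.transmat_ > 0) & (self.transmat_ < threshold)
        )


def build_mode_model(seqs, grouping) -> ModeMarkovModel:
    """Estimate a mode model from submode sequences and a grouping."""
    return ModeMarkovModel(grouping=grouping).fit(seqs)


def free_parameters(N: int, M: int, kind: str) -> int:
    """Free parameters of an N-state model over M symbols.

    ``hmm``: N(N-1) transition + N(M-1) emission.  ``mm``: N(N-1) + (M-N)
    (emission columns have one nonzero; requires M >= N).
    """
    if kind == "hmm":
        return N * (N - 1) + N * (M - 1)
    if kind == "mm":
        if M < N:
            raise ValueError("mode model requires M >= N")
        return N * (N - 1) + (M - N)
    raise ValueError(f"unknown kind {kind!r}")


def loglik_test(model, seqs, n_sets: int = 10, set_size: int = 20000,
                rng=None):
    """Mean per-sequence log-likelihood over random test sets.

    Sets of ``set_size`` sequences are drawn (with replacement across
    sets, without within a set when the pool allows); returns
    ``(mean, sd)`` of the per-set mean log-likelihoods.
    """
    rng = np.random.default_rng(rng)
    seqs = list(seqs)
    n = len(seqs)
    size = min(set_size, n)
    means = []
    for _ in range(n_sets):
        take = rng.choice(n, size=size, replace=size > n)
        means.append(
            float(np.mean([model.log_likelihood(seqs[i]) for i in take]))
        )
    means = np.asarray(means)
    return float(means.mean()), float(means.std(ddof=1) if n_sets > 1 else 0.0)


@dataclass
class StationarityReport:
    chi2_pvalue: float
    tv_distance: float
    early_counts: np.ndarray
    late_counts: np.ndarray
    equilibrium: np.ndarray
    empirical: np.ndarray

    def stationary(self, alpha: float = 0.01, tv_max: float = 0.05) -> bool:
        return self.chi2_pvalue >= alpha and self.tv_distance <= tv_max


def check_stationarity(seqs, model=None, alphabet_size: int | None = None
                       ) -> StationarityReport:
    """Compare symbol frequencies between early and late data halves.

    Symbols are split at the median of their times (pooled); a
    chi-square contingency test compares the two halves.  If a model
    with ``transmat_``/``emissionprob_`` (or a plain transition matrix)
    is given, the empirical marginal is also compared with the model's
    equilibrium symbol distribution by total-variation distance.
    """
    syms, times = [], []
    for s in seqs:
        if not isinstance(s, SymbolSequence) or s.times is None:
            raise ValueError("stationarity check needs timed SymbolSequences")
        syms.append(s.symbols)
        times.append(s.times)
    syms = np.concatenate(syms)
    times = np.concatenate(times)
    M = alphabet_size or int(syms.max()) + 1
    med = np.median(times)
    early = np.bincount(syms[times <= med], minlength=M)
    late = np.bincount(syms[times > med], minlength=M)
    keep = (early + late) > 0
    table = np.vstack([early[keep], late[keep]])
    if table.shape[1] < 2:
        p = 1.0
    else:
        p = float(stats.chi2_contingency(table + 0.5)[1])
    empirical = (early + late) / (early + late).sum()

    tv = np.nan
    eq = np.full(M, np.nan)
    if model is not None:
        if hasattr(model, "transmat_"):
            Tr = model.transmat_
            Em = getattr(model, "emissionprob_", None)
        elif hasattr(model, "params_"):
            Tr = model.params_.transmat
            Em = model.params_.emissionprob
        else:
            Tr = _check_stochastic(np.asarray(model))
            Em = None
        pi = stationary_distribution(Tr)
        eq = pi @ Em if Em is not None else pi
        if len(eq) == M:
            tv = float(0.5 * np.abs(eq - empirical).sum())
    return StationarityReport(
        chi2_pvalue=p,
        tv_distance=tv,
        early_counts=early,
        late_counts=late,
        equilibrium=eq,
        empirical=empirical,
    )
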