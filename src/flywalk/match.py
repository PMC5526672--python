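"""Multiset match-fraction statistic and generative-model validation.

A generative sequence model is validated by sampling: draw two subsets
R, R' of real fixed-length sequences and one subset S of model-generated
sequences (|R| = |S|), count exact sequence matches as multiset
intersections (multiplicity-aware, nu_{X ^ Y}(x) = min(nu_X, nu_Y)),

    F_R:R = (1/|R|) sum_r nu_{R ^ R'}(r)
    F_S:R = (1/|R|) sum_s nu_{S ^ R}(s)
    f     = <F_S:R>_N / <F_R:R>_N ,

so f = 1 when model samples are indistinguishable from real ones and
f = 0 when they never match.  Measuring f against sequence length k
(mapped to seconds through the empirical duration of real length-k
sequences) gives the horizon tau_P: the longest duration over which the
model stays at f >= 0.9.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .sequences import SymbolSequence, _as_symbol_arrays

__all__ = [
    "multiset_overlap",
    "match_fraction_sets",
    "matched_fraction",
    "generative_match_test",
    "MatchCurve",
    "match_curve",
    "frequency_comparison",
]


def multiset_overlap(X, Y) -> int:
    """|X ^ Y| counting multiplicity: sum_x min(nu_X(x), nu_Y(x))."""
    cx, cy = Counter(X), Counter(Y)
    return sum(min(n, cy[x]) for x, n in cx.items())


def match_fraction_sets(R, Rp, S):
    """(F_R:R, F_S:R, f) for one explicit draw of the three sets."""
    if not R or not S:
        raise ValueError("pools must be nonempty")
    frr = multiset_overlap(R, Rp) / len(R)
    fsr = multiset_overlap(S, R) / len(R)
    if frr == 0:
        raise ZeroDivisionError("real-real match count is zero; f undefined")
    return frr, fsr, fsr / frr


def _as_matrix(seqs, k: int) -> np.ndarray:
    """(n, k) int matrix from a pool of equal-length sequences."""
    if isinstance(seqs, np.ndarray) and seqs.ndim == 2:
        if seqs.shape[1] != k:
            raise ValueError(f"sequences have length {seqs.shape[1]}, expected {k}")
        return seqs.astype(np.int64, copy=False)
    arrs = _as_symbol_arrays(seqs)
    for i, a in enumerate(arrs):
        if len(a) != k:
            raise ValueError(f"sequence {i} has length {len(a)}, expected {k}")
    return np.asarray(arrs, dtype=np.int64)


def _encode(seqs, k: int, base: int) -> np.ndarray:
    """Length-k symbol sequences as base-``base`` integers (exact-match keys)."""
    mat = _as_matrix(seqs, k)
    if base**k > 2**62:
        raise ValueError("sequence space too large to encode exactly")
    w = base ** np.arange(k, dtype=np.int64)
    return mat @ w


def _overlap_codes(a: np.ndarray, b: np.ndarray) -> int:
    """Multiset intersection size for integer-encoded sequences."""
    ua, ca = np.unique(a, return_counts=True)
    ub, cb = np.unique(b, return_counts=True)
    common, ia, ib = np.intersect1d(ua, ub, assume_unique=True,
                                    return_indices=True)
    if not common.size:
        return 0
    return int(np.minimum(ca[ia], cb[ib]).sum())


def matched_fraction(
    real_pool,
    synth_pool,
    set_size: int,
    N: int = 10,
    rng=None,
    replace: bool = True,
):
    """f over N draws of (R, R' from real; S from synthetic).

    Pools are fixed-length sequence collections; draws are with
    replacement by default (set ``replace=False`` for disjoint draws
    from large pools).  Returns ``(f, details)`` where details carries
    the per-draw F_R:R and F_S:R.
    """
    rng = np.random.default_rng(rng)
    if isinstance(real_pool, np.ndarray) and real_pool.ndim == 2:
        k = real_pool.shape[1]
    else:
        real_pool = _as_symbol_arrays(real_pool)
        if not real_pool:
            raise ValueError("pools must be nonempty")
        k = len(real_pool[0])
    real = _as_matrix(real_pool, k)
    synth = _as_matrix(synth_pool, k)
    if not len(real) or not len(synth):
        raise ValueError("pools must be nonempty")
    base = int(max(real.max(), synth.max())) + 1
    rc = _encode(real, k, base)
    sc = _encode(synth, k, base)
    frr = np.empty(N)
    fsr = np.empty(N)
    for i in range(N):
        R = rng.choice(rc, size=set_size, replace=replace)
        Rp = rng.choice(rc, size=set_size, replace=replace)
        S = rng.choice(sc, size=set_size, replace=replace)
        frr[i] = _overlap_codes(R, Rp) / set_size
        fsr[i] = _overlap_codes(S, R) / set_size
    if frr.mean() == 0:
        raise ZeroDivisionError("real-real match count is zero; f undefined")
    f = fsr.mean() / frr.mean()
    return f, {"F_RR": frr, "F_SR": fsr}


def _windows(seqs, k: int, all_windows: bool = True, rng=None):
    """Length-k contiguous subsequences (with durations when timed).

    With ``all_windows`` every sliding window contributes; otherwise one
    random window per source sequence (windows of one sequence overlap
    and are strongly correlated, which inflates real-real self-matches).
    Returns ``(matrix, durations)`` where matrix is (n_windows, k).
    """
    rng = np.random.default_rng(rng)
    mats, durs = [], []
    for s in seqs:
        a = s.symbols if isinstance(s, SymbolSequence) else np.asarray(s)
        t = s.times if isinstance(s, SymbolSequence) else None
        if len(a) < k:
            continue
        sw = np.lib.stride_tricks.sliding_window_view(a, k)
        dw = t[k - 1:] - t[: len(t) - k + 1] if t is not None else None
        if not all_windows:
            i = int(rng.integers(len(sw)))
            sw = sw[i: i + 1]
            dw = dw[i: i + 1] if dw is not None else None
        mats.append(sw)
        if dw is not None:
            durs.append(dw)
    if not mats:
        return np.empty((0, k), dtype=np.int64), None
    mat = np.concatenate(mats).astype(np.int64)
    return mat, (np.concatenate(durs) if durs else None)


def generative_match_test(
    real_seqs,
    model,
    k: int = 5,
    n_sets: int = 11,
    set_size: int = 5000,
    rng=None,
):
    """Held-out generative validation at fixed sequence length.

    ``n_sets`` disjoint sets of ``set_size`` real length-``k``
    subsequences are drawn without reusing any source sequence across
    sets (one random window per chosen source sequence).  F_R:R averages
    matches between the first set and each remaining one; F_S:R averages
    matches between ``n_sets - 1`` model-generated sets and the first
    real set.  ``model`` needs ``sample_sequences(n, length, rng)``.
    """
    rng = np.random.default_rng(rng)
    pool = [
        s for s in real_seqs
        if len(s.symbols if isinstance(s, SymbolSequence) else s) >= k
    ]
    need = n_sets * set_size
    if len(pool) < need:
        raise ValueError(
            f"pool of {len(pool)} sequences too small for {n_sets} disjoint "
            f"sets of {set_size} (no-reuse protocol)"
        )
    order = rng.permutation(len(pool))
    sets = []
    for j in range(n_sets):
        chunk = order[j * set_size: (j + 1) * set_size]
        rows = []
        for i in chunk:
            a = pool[i]
            a = a.symbols if isinstance(a, SymbolSequence) else np.asarray(a)
            start = rng.integers(0, len(a) - k + 1)
            rows.append(a[start: start + k])
        sets.append(rows)
    base = int(max(max(r.max() for r in rows) for rows in sets)) + 1
    base = max(base, getattr(model, "alphabet_size_", base))
    codes = [_encode(rows, k, base) for rows in sets]
    frr = np.array(
        [_overlap_codes(codes[0], codes[j]) / set_size for j in range(1, n_sets)]
    )
    fsr = []
    for _ in range(n_sets - 1):
        synth = model.sample_sequences(set_size, k, rng)
        fsr.append(_overlap_codes(_encode(synth, k, base), codes[0]) / set_size)
    fsr = np.asarray(fsr)
    if frr.mean() == 0:
        raise ZeroDivisionError("real-real match count is zero; f undefined")
    return fsr.mean() / frr.mean(), {"F_RR": frr, "F_SR": fsr}


@dataclass
class MatchCurve:
    """f as a function of sequence length with its time mapping."""

    k: np.ndarray
    f: np.ndarray
    f_sd: np.ndarray
    duration_s: np.ndarray
    tau_p_s: float
    skipped_k: list
    config: dict

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"k": self.k, "f": self.f, "f_sd": self.f_sd,
             "duration_s": self.duration_s}
        )


def _tau_p(durations: np.ndarray, f: np.ndarray, threshold: float = 0.9
           ) -> float:
    """Largest duration with f >= threshold, linearly interpolated."""
    if not len(f):
        return np.nan
    if f[0] < threshold:
        return 0.0
    below = np.nonzero(f < threshold)[0]
    if not below.size:
        return float(durations[-1])
    j = below[0]
    d0, d1 = durations[j - 1], durations[j]
    f0, f1 = f[j - 1], f[j]
    return float(d0 + (threshold - f0) / (f1 - f0) * (d1 - d0))


def match_curve(
    real_seqs,
    model,
    k_range=range(2, 21),
    set_size: int = 500,
    N: int = 5000,
    rng=None,
    threshold: float = 0.9,
    model_step_s: float = 0.167,
) -> MatchCurve:
    """f(k) with resampling (with replacement) and the horizon tau_P.

    Real length-k pools are all contiguous k-windows of the timed input
    sequences; model pools are generated at matched size.  k values with
    fewer real windows than ``set_size`` are skipped (and recorded).
    Durations use the empirical mean span of the real windows; synthetic
    sequence durations use the fixed ``model_step_s`` per transition
    (167 ms, the modal inter-peak interval).
    """
    rng = np.random.default_rng(rng)
    ks, fs, sds, durs, skipped = [], [], [], [], []
    for k in k_range:
        wins, win_dur = _windows(real_seqs, k, all_windows=False, rng=rng)
        if len(wins) < set_size:
            skipped.append(int(k))
            continue
        n_model = min(max(len(wins), set_size), 20000)
        synth = model.sample_sequences(n_model, k, rng)
        f, det = matched_fraction(
            wins, synth, set_size=set_size, N=N, rng=rng, replace=True
        )
        ks.append(int(k))
        fs.append(f)
        mu_rr = det["F_RR"].mean()
        sds.append(det["F_SR"].std(ddof=1) / mu_rr if mu_rr else np.nan)
        durs.append(
            float(win_dur.mean()) if win_dur is not None
            else (k - 1) * model_step_s
        )
    ks = np.asarray(ks)
    fs = np.asarray(fs)
    durs = np.asarray(durs)
    return MatchCurve(
        k=ks, f=fs, f_sd=np.asarray(sds), duration_s=durs,
        tau_p_s=_tau_p(durs, fs, threshold), skipped_k=skipped,
        config={"set_size": set_size, "N": N, "threshold": threshold},
    )


def frequency_comparison(
    real_seqs,
    model,
    max_k: int = 5,
    n_total: int | None = None,
    rng=None,
    z: float = 2.58,
):
    """Real versus model-predicted log-frequency of unique sequences.

    For each length k = 2..max_k the real pool is all k-windows and the
    model pool is generated at matched size; sequences whose real
    frequency falls below the sampling-error cutoff
    ``0.5 * (z / sqrt(N))**2`` (the frequency whose 99% normal CI
    reaches zero; z = 2.58) are excluded.  Returns ``(DataFrame,
    pearson_r)`` over the retained pairs present in both pools.
    """
    import pandas as pd

    rng = np.random.default_rng(rng)
    rows = []
    for k in range(2, max_k + 1):
        wins, _ = _windows(real_seqs, k)
        if not len(wins):
            continue
        Nk = n_total or len(wins)
        synth = np.asarray(model.sample_sequences(Nk, k, rng), dtype=np.int64)
        base = int(max(wins.max(), synth.max())) + 1
        rc = _encode(wins, k, base)
        sc = _encode(synth, k, base)
        cutoff = 0.5 * (z / np.sqrt(Nk)) ** 2
        ur, cr = np.unique(rc, return_counts=True)
        us, cs = np.unique(sc, return_counts=True)
        fr = dict(zip(ur.tolist(), (cr / len(rc)).tolist()))
        fs = dict(zip(us.tolist(), (cs / len(sc)).tolist()))
        for code, freq in fr.items():
            if freq < cutoff:
                continue
            mfreq = fs.get(code, 0.0)
            rows.append(
                {"k": k, "code": code, "real_freq": freq, "model_freq": mfreq}
            )
    df = pd.DataFrame(rows)
    kept = df[(df.model_freq > 0)]
    if len(kept) >= 2:
        r = float(
            stats.pearsonr(
                np.log10(kept.real_freq), np.log10(kept.model_freq)
            )[0]
        )
    else:
        r = np.nan
    return df, r
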