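"""Time-resolved velocity profiles, distribution overlap, dwell times.

Each mode (or submode) is characterized by its *velocity profile*: the
discretized distribution Pr[vT, vR, vS | t'] of fragment velocities at
each time t' around the turn peak, summarized by the central 68% band
per component.  Profiles are compared with the Bhattacharyya
coefficient for discrete distributions, B(P, P') = sum_v sqrt(P P'),
pooled uniformly over t' (per-t' values are exposed too); significance
comes from a bootstrap that re-splits the pooled fragments at the
original group sizes (p < 0.002 is significant at the 0.05 level under
Bonferroni correction for the 25 mode-pair comparisons).

Dwell (residence) time in a mode is the span between the first and last
vR extrema of an uninterrupted run of that mode; runs touching sequence
edges are censored and excluded, and single-extremum runs contribute
dwell 0 under this last-minus-first convention (an extended variant
adds the half-gaps to the neighboring extrema).  Exponential and
two-component exponential-mixture fits describe the dwell distributions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .phasespace import VelocityGrid
from .segmentation import FragmentSet
from .sequences import SymbolSequence

__all__ = [
    "VelocityProfile",
    "velocity_profile",
    "bhattacharyya",
    "bootstrap_profile_test",
    "DwellResult",
    "dwell_times",
    "fit_dwell",
]


@dataclass
class VelocityProfile:
    """Discretized Pr[v | t'] with a central-band summary."""

    label: str
    tprime: np.ndarray
    grid: VelocityGrid
    hist: np.ndarray  # (n_t, n_occupied_codes) aligned with codes
    codes: np.ndarray  # occupied flat bin codes
    band_low: dict  # component -> per-t' lower percentile
    band_high: dict
    n_fragments: int

    def normalization(self) -> np.ndarray:
        return self.hist.sum(axis=1)


def _bin_codes(frags: FragmentSet, grid: VelocityGrid) -> np.ndarray:
    """(n_fragments, n_t) flat velocity-bin code per sample; -1 out of range."""
    vT = frags.arrays["vT"]
    vR = frags.arrays["vR"]
    vS = frags.arrays["vS"]
    return grid.bin_index(vT.ravel(), vR.ravel(), vS.ravel()).reshape(vT.shape)


def velocity_profile(
    frags: FragmentSet,
    grid: VelocityGrid | None = None,
    band: float = 0.68,
    min_samples: int = 1,
    label: str = "",
) -> VelocityProfile:
    """Per-t' joint velocity histogram plus central-percentile bands.

    The default band of 68% reports the P16..P84 interval per component
    per time point.  Raises when any t' bin has fewer than
    ``min_samples`` in-range samples (listing the offending t').
    """
    grid = grid or VelocityGrid.coarse(8)
    codes = _bin_codes(frags, grid)
    n_t = codes.shape[1]
    occupied = np.unique(codes[codes >= 0])
    hist = np.zeros((n_t, len(occupied)))
    lookup = {c: i for i, c in enumerate(occupied.tolist())}
    short = []
    for t in range(n_t):
        col = codes[:, t]
        col = col[col >= 0]
        if len(col) < min_samples:
            short.append(float(frags.tprime[t]))
            continue
        u, cts = np.unique(col, return_counts=True)
        for c, n in zip(u.tolist(), cts):
            hist[t, lookup[c]] = n
        hist[t] /= hist[t].sum()
    if short:
        raise ValueError(f"too few samples at t' bins {short}")
    lo_q, hi_q = 50 * (1 - band), 50 * (1 + band)
    band_low, band_high = {}, {}
    for comp in ("vT", "vR", "vS"):
        band_low[comp] = np.percentile(frags.arrays[comp], lo_q, axis=0)
        band_high[comp] = np.percentile(frags.arrays[comp], hi_q, axis=0)
    return VelocityProfile(
        label=label, tprime=frags.tprime, grid=grid, hist=hist,
        codes=occupied, band_low=band_low, band_high=band_high,
        n_fragments=len(frags),
    )


def bhattacharyya(P: VelocityProfile, Pp: VelocityProfile,
                  per_tprime: bool = False):
    """Bhattacharyya overlap of two profiles on identical grids.

    B is computed on the joint (v, t') distribution with uniform weight
    over t' (equivalently the mean over t' of the per-t' overlaps);
    ``per_tprime=True`` returns the per-t' values instead.
    """
    if len(P.tprime) != len(Pp.tprime) or not np.allclose(P.tprime, Pp.tprime):
        raise ValueError("profiles have different t' grids")
    for a, b in (
        (P.grid.vT_edges, Pp.grid.vT_edges),
        (P.grid.vR_edges, Pp.grid.vR_edges),
        (P.grid.vS_edges, Pp.grid.vS_edges),
    ):
        if len(a) != len(b) or not np.allclose(a, b):
            raise ValueError("profiles have different velocity grids")
    codes = np.union1d(P.codes, Pp.codes)
    h1 = np.zeros((len(P.tprime), len(codes)))
    h2 = np.zeros_like(h1)
    h1[:, np.searchsorted(codes, P.codes)] = P.hist
    h2[:, np.searchsorted(codes, Pp.codes)] = Pp.hist
    per_t = np.sqrt(h1 * h2).sum(axis=1)
    if per_tprime:
        return per_t
    return float(per_t.mean())


def _pooled_codes(frags: FragmentSet, grid: VelocityGrid):
    codes = _bin_codes(frags, grid)
    n_t = codes.shape[1]
    # joint (t', v-bin) code per sample; out-of-range samples get -1
    joint = np.where(codes >= 0, codes * n_t + np.arange(n_t)[None, :], -1)
    return joint


def _overlap_from_joint(joint_a: np.ndarray, joint_b: np.ndarray, n_t: int
                        ) -> float:
    """Mean-over-t' Bhattacharyya from per-fragment joint codes."""
    a = joint_a[joint_a >= 0]
    b = joint_b[joint_b >= 0]
    ua, ca = np.unique(a, return_counts=True)
    ub, cb = np.unique(b, return_counts=True)
    # per-t' normalization
    ta = ua % n_t
    tb = ub % n_t
    na = np.bincount(ta, weights=ca, minlength=n_t)
    nb = np.bincount(tb, weights=cb, minlength=n_t)
    common, ia, ib = np.intersect1d(ua, ub, assume_unique=True,
                                    return_indices=True)
    if not common.size:
        return 0.0
    tc = common % n_t
    pa = ca[ia] / na[tc]
    pb = cb[ib] / nb[tc]
    per_t = np.bincount(tc, weights=np.sqrt(pa * pb), minlength=n_t)
    valid = (na > 0) & (nb > 0)
    return float(per_t[valid].mean()) if valid.any() else 0.0


def bootstrap_profile_test(
    frags_a: FragmentSet,
    frags_b: FragmentSet,
    grid: VelocityGrid | None = None,
    n_boot: int = 10000,
    rng=None,
):
    """Bootstrap p-value that two fragment groups share a velocity profile.

    The observed Bhattacharyya overlap is compared with a null built by
    pooling both groups and re-splitting into random subsets of the
    original sizes ``n_boot`` times; p is the fraction of null overlaps
    at or below the observed one (small p: the groups are more different
    than chance resampling allows).
    """
    rng = np.random.default_rng(rng)
    if not len(frags_a) or not len(frags_b):
        raise ValueError("both groups must be nonempty")
    grid = grid or VelocityGrid.coarse(8)
    n_t = len(frags_a.tprime)
    ja = _pooled_codes(frags_a, grid)
    jb = _pooled_codes(frags_b, grid)
    observed = _overlap_from_joint(ja, jb, n_t)
    pooled = np.vstack([ja, jb])
    na = len(frags_a)
    n = pooled.shape[0]
    null = np.empty(n_boot)
    for i in range(n_boot):
        perm = rng.permutation(n)
        null[i] = _overlap_from_joint(pooled[perm[:na]], pooled[perm[na:]], n_t)
    p = float(np.mean(null <= observed))
    return p, observed, null


@dataclass
class DwellResult:
    """Dwell-time samples and exponential fit(s) for one mode."""

    mode: object
    samples: np.ndarray  # seconds
    n_runs: int
    rates: np.ndarray | None = None  # 1/s, per mixture component
    weights: np.ndarray | None = None
    log_likelihood: float | None = None
    lr_vs_single: float | None = None


def dwell_times(mode_seqs, extended: bool = False) -> dict:
    """Per-mode dwell samples from timed mode sequences.

    Only sequences of length > 2 with an observed switch both into and
    out of a run contribute (runs at sequence edges are censored);
    dwell = time of last minus first extremum of the run.  With
    ``extended=True`` half the gap to each neighboring extremum is
    added on both sides.
    """
    out: dict = {}
    for s in mode_seqs:
        if not isinstance(s, SymbolSequence) or s.times is None:
            raise ValueError("dwell analysis needs timed SymbolSequences")
        a, t = s.symbols, s.times
        if len(a) <= 2:
            continue
        # run boundaries
        change = np.nonzero(np.diff(a) != 0)[0]
        starts = np.concatenate([[0], change + 1])
        ends = np.concatenate([change, [len(a) - 1]])
        for st, en in zip(starts, ends):
            if st == 0 or en == len(a) - 1:
                continue  # censored at a sequence edge
            dwell = t[en] - t[st]
            if extended:
                dwell += 0.5 * (t[st] - t[st - 1]) + 0.5 * (t[en + 1] - t[en])
            out.setdefault(int(a[st]), []).append(float(dwell))
    return {
        m: DwellResult(mode=m, samples=np.asarray(v), n_runs=len(v))
        for m, v in sorted(out.items())
    }


def _exp_mixture_em(x, k, rng, n_iter=500, tol=1e-10):
    """EM for a k-component exponential mixture; returns (rates, weights, ll)."""
    n = len(x)
    q = np.linspace(0.2, 0.8, k)
    lam = 1.0 / np.maximum(np.quantile(x, q), 1e-12)
    lam = lam * rng.uniform(0.5, 2.0, size=k)
    w = np.full(k, 1.0 / k)
    ll_old = -np.inf
    for _ in range(n_iter):
        logp = np.log(w)[None, :] + np.log(lam)[None, :] - x[:, None] * lam[None, :]
        m = logp.max(axis=1, keepdims=True)
        p = np.exp(logp - m)
        tot = p.sum(axis=1, keepdims=True)
        ll = float((np.log(tot) + m).sum())
        r = p / tot
        w = r.mean(axis=0)
        lam = r.sum(axis=0) / np.maximum((r * x[:, None]).sum(axis=0), 1e-300)
        if abs(ll - ll_old) < tol * max(1.0, abs(ll)):
            ll_old = ll
            break
        ll_old = ll
    return lam, w, ll_old


def fit_dwell(samples, n_components: int = 1, rng=None, n_restarts: int = 5,
              min_samples: int = 20) -> DwellResult:
    """Maximum-likelihood exponential (mixture) fit of dwell samples.

    Zero dwells (single-extremum runs) are shifted by half the smallest
    positive sample so the exponential density is defined; with
    ``n_components=2`` an EM mixture is fit from several restarts and a
    likelihood-ratio statistic against the single-exponential fit is
    reported.
    """
    rng = np.random.default_rng(rng)
    x = np.asarray(
        samples.samples if isinstance(samples, DwellResult) else samples,
        dtype=float,
    )
    if len(x) < min_samples:
        raise ValueError(f"need >= {min_samples} samples, got {len(x)}")
    if np.ptp(x) <= 0:
        raise ValueError("degenerate dwell samples (all equal)")
    pos = x[x > 0]
    x = np.where(x > 0, x, 0.5 * pos.min() if pos.size else 1e-6)

    lam1 = 1.0 / x.mean()
    ll1 = float(len(x) * np.log(lam1) - lam1 * x.sum())
    if n_components == 1:
        return DwellResult(
            mode=None, samples=x, n_runs=len(x), rates=np.array([lam1]),
            weights=np.array([1.0]), log_likelihood=ll1, lr_vs_single=0.0,
        )
    if n_components != 2:
        raise ValueError("n_components must be 1 or 2")
    best = None
    for _ in range(n_restarts):
        lam, w, ll = _exp_mixture_em(x, 2, rng)
        if best is None or ll > best[2]:
            best = (lam, w, ll)
    lam, w, ll = best
    order = np.argsort(lam)[::-1]
    return DwellResult(
        mode=None, samples=x, n_runs=len(x), rates=lam[order],
        weights=w[order], log_likelihood=float(ll),
        lr_vs_single=float(2 * (ll - ll1)),
    )
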