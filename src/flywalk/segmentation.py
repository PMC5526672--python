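"""Iterative-ICA segmentation of velocity trajectories into submodes.

Walking trajectories are cut into fragments around local extrema of the
rotational velocity vR (turn peaks), which recur every ~250 ms and tile
trajectories almost completely.  Each fragment is sign-normalized
(multiplying vR and vS by c = sgn vR(0), so all turns at t'=0 are
positive while the side-slip direction relative to the turn is kept),
assembled column-wise into a matrix, standardized row-wise, whitened,
reduced to the principal components carrying most of the variance, and
decomposed with FastICA (kurtosis-family contrast, repeated from random
initial conditions).  Whenever the distribution of fragment coefficients
in the independent components is multimodal, the fragments are split at
the density valley (or by pairwise k-means in two dimensions) and the
whole procedure recurses on each subset.  Leaves of the resulting tree
are *submodes*: families of trajectory fragments sharing independent
components with unimodal coefficients.

The tree, with all stored transforms, acts as a classifier for new
trajectories (:class:`FragmentSegmenter.predict`).
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning
from sklearn.mixture import GaussianMixture

from .trajectory import VelocityTrajectory, heading_velocity

__all__ = [
    "detect_peaks",
    "Fragment",
    "FragmentSet",
    "extract_fragments",
    "FragmentMatrix",
    "assemble_standardize",
    "whiten_reduce",
    "PCBasis",
    "ICAResult",
    "fit_ica",
    "SplitRule",
    "propose_split",
    "SegmentationConfig",
    "SegmentationNode",
    "SubmodeCatalog",
    "SegmentationDepthError",
    "FragmentSegmenter",
    "iterate_segmentation",
    "classify",
]


# ---------------------------------------------------------------------------
# peaks and fragments


def detect_peaks(vel: VelocityTrajectory, window: int = 2) -> np.ndarray:
    """Indices of local |vR| extrema (turns of either sign).

    ``t`` is a peak iff |vR(t)| >= |vR(t +/- k)| for all k <= window
    (+/-2 frames is +/-83 ms at 30 Hz); plateau ties go to the earliest
    sample.  Endpoints within ``window`` of the trajectory edge are not
    eligible.
    """
    m = np.abs(np.asarray(vel.vR, dtype=float))
    n = len(m)
    if n < 2 * window + 1:
        return np.array([], dtype=int)
    cand = np.ones(n, dtype=bool)
    cand[:window] = cand[n - window:] = False
    for k in range(1, window + 1):
        cand[window:n - window] &= (
            (m[window:n - window] >= m[window - k:n - window - k])
            & (m[window:n - window] >= m[window + k:n - window + k])
        )
    # plateau ties: only the earliest sample of a run of equal values counts
    plateau_start = np.ones(n, dtype=bool)
    plateau_start[1:] = m[1:] != m[:-1]
    return np.nonzero(cand & plateau_start)[0]


@dataclass
class Fragment:
    """One sign-normalized window around a vR extremum (view into a set)."""

    traj_id: str
    peak_frame: int
    peak_time: float
    c: int
    tprime: np.ndarray
    arrays: dict  # component -> values, with c already applied to vR, vS, vH


class FragmentSet:
    """Stacked, t'-aligned fragments.

    ``arrays[comp]`` is (n_fragments, n_t) with the sign convention
    already applied: stored vR, vS and vH are c*vR, c*vS, c*vH.
    """

    COMPONENTS = ("vR", "vT", "vS", "vH")

    def __init__(self, tprime, arrays, traj_ids, peak_frames, peak_times, c,
                 frame_rate):
        self.tprime = np.asarray(tprime, dtype=float)
        self.arrays = {k: np.asarray(v, dtype=float) for k, v in arrays.items()}
        self.traj_ids = list(traj_ids)
        self.peak_frames = np.asarray(peak_frames, dtype=int)
        self.peak_times = np.asarray(peak_times, dtype=float)
        self.c = np.asarray(c, dtype=int)
        self.frame_rate = float(frame_rate)

    def __len__(self) -> int:
        return len(self.c)

    def __getitem__(self, i: int) -> Fragment:
        return Fragment(
            traj_id=self.traj_ids[i],
            peak_frame=int(self.peak_frames[i]),
            peak_time=float(self.peak_times[i]),
            c=int(self.c[i]),
            tprime=self.tprime,
            arrays={k: v[i] for k, v in self.arrays.items()},
        )

    def subset(self, idx) -> "FragmentSet":
        idx = np.asarray(idx)
        return FragmentSet(
            self.tprime,
            {k: v[idx] for k, v in self.arrays.items()},
            [self.traj_ids[i] for i in idx],
            self.peak_frames[idx],
            self.peak_times[idx],
            self.c[idx],
            self.frame_rate,
        )

    def mirrored(self) -> "FragmentSet":
        """The same fragments with turn direction flipped (c negated).

        Because the stored arrays are already sign-normalized, mirroring
        the underlying velocities only flips c; classification must be
        invariant to it.
        """
        return FragmentSet(
            self.tprime, self.arrays, self.traj_ids, self.peak_frames,
            self.peak_times, -self.c, self.frame_rate,
        )


def extract_fragments(
    trajs,
    peaks=None,
    half_width_s: float = 0.3,
    window: int = 2,
) -> FragmentSet:
    """Sign-normalized fragments around vR peaks from one or many trajectories.

    Only full-support fragments are kept (peaks within ``half_width`` of
    a trajectory end are dropped); overlapping fragments are permitted.
    ``half_width_s`` = 0.3 s gives 19 samples per component at 30 Hz
    (0.55 s gives 33).  ``peaks`` may give per-trajectory peak indices;
    otherwise :func:`detect_peaks` is run.
    """
    if isinstance(trajs, VelocityTrajectory):
        trajs = [trajs]
        peaks = [peaks] if peaks is not None else None
    trajs = list(trajs)
    fr = trajs[0].frame_rate
    n_side = int(np.floor(half_width_s * fr))
    tprime = np.arange(-n_side, n_side + 1) / fr

    rows = {comp: [] for comp in FragmentSet.COMPONENTS}
    traj_ids, peak_frames, peak_times, signs = [], [], [], []
    for ti, vel in enumerate(trajs):
        if vel.vH is None:
            heading_velocity(vel)
        vH = np.where(np.isfinite(vel.vH), vel.vH, vel.vR)
        pk = detect_peaks(vel, window=window) if peaks is None else np.asarray(
            peaks[ti], dtype=int
        )
        for p in pk:
            if p - n_side < 0 or p + n_side >= len(vel):
                continue  # no full support
            sl = slice(p - n_side, p + n_side + 1)
            c = 1 if vel.vR[p] >= 0 else -1
            rows["vR"].append(c * vel.vR[sl])
            rows["vT"].append(vel.vT[sl])
            rows["vS"].append(c * vel.vS[sl])
            rows["vH"].append(c * vH[sl])
            traj_ids.append(vel.id)
            peak_frames.append(int(p))
            peak_times.append(float(vel.times[p]))
            signs.append(c)
    arrays = {
        k: (np.vstack(v) if v else np.empty((0, len(tprime)))) for k, v in rows.items()
    }
    return FragmentSet(tprime, arrays, traj_ids, peak_frames, peak_times,
                       signs, fr)


# ---------------------------------------------------------------------------
# matrix assembly, whitening, ICA


@dataclass
class FragmentMatrix:
    """Row-standardized fragment matrix (rows = component x t', cols = fragments)."""

    data: np.ndarray  # standardized, (rows, N)
    components: tuple
    tprime: np.ndarray
    row_component: np.ndarray  # component name per row
    row_tprime: np.ndarray
    row_mean: np.ndarray
    row_sd: np.ndarray

    @property
    def n_fragments(self) -> int:
        return self.data.shape[1]

    def destandardize(self) -> np.ndarray:
        return self.data * self.row_sd[:, None] + self.row_mean[:, None]

    def standardize_new(self, raw: np.ndarray) -> np.ndarray:
        """Apply the stored row parameters to new raw columns."""
        return (raw - self.row_mean[:, None]) / self.row_sd[:, None]


def _stack_components(frags: FragmentSet, components, tprime_mask):
    blocks = [frags.arrays[c][:, tprime_mask].T for c in components]
    raw = np.vstack(blocks)  # (len(components)*n_t, N)
    n_t = int(tprime_mask.sum())
    row_component = np.repeat(list(components), n_t)
    row_tprime = np.tile(frags.tprime[tprime_mask], len(components))
    return raw, row_component, row_tprime


def assemble_standardize(
    frags: FragmentSet,
    components=("vH", "vT"),
    tprime_range_s: float | None = None,
) -> FragmentMatrix:
    """Build and row-standardize the fragment matrix.

    Each row is one (component, t') coordinate; each column one fragment.
    Raises on zero-variance rows (naming the row), since such a row
    cannot be standardized.
    """
    mask = (
        np.ones_like(frags.tprime, dtype=bool)
        if tprime_range_s is None
        else np.abs(frags.tprime) <= tprime_range_s + 1e-9
    )
    raw, row_component, row_tprime = _stack_components(frags, components, mask)
    mean = raw.mean(axis=1)
    sd = raw.std(axis=1)
    bad = np.nonzero(sd <= 0)[0]
    if bad.size:
        i = int(bad[0])
        raise ValueError(
            f"zero-variance row {i} (component {row_component[i]}, "
            f"t'={row_tprime[i]:.4f} s)"
        )
    return FragmentMatrix(
        data=(raw - mean[:, None]) / sd[:, None],
        components=tuple(components),
        tprime=frags.tprime[mask],
        row_component=row_component,
        row_tprime=row_tprime,
        row_mean=mean,
        row_sd=sd,
    )


@dataclass
class PCBasis:
    """Retained-PC whitening transform: s_w = diag(eigvals)^-1/2 E^T z."""

    eigvecs: np.ndarray  # (rows, D)
    eigvals: np.ndarray  # (D,)
    explained_variance: float

    @property
    def D(self) -> int:
        return len(self.eigvals)

    def transform(self, Z: np.ndarray) -> np.ndarray:
        return (self.eigvecs.T @ Z) / np.sqrt(self.eigvals)[:, None]


def whiten_reduce(fm: FragmentMatrix, var_threshold: float = 0.85,
                  max_pcs: int | None = None):
    """Whiten the standardized matrix and keep the leading PCs.

    Retains the smallest number of principal components whose cumulative
    explained variance reaches ``var_threshold`` (optionally capped at
    ``max_pcs``); the returned matrix has identity row covariance.
    """
    if not 0 < var_threshold <= 1:
        raise ValueError("var_threshold must be in (0, 1]")
    Z = fm.data
    N = Z.shape[1]
    cov = (Z @ Z.T) / N
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    cum = np.cumsum(vals) / vals.sum()
    D = int(np.searchsorted(cum, var_threshold - 1e-12) + 1)
    D = min(D, np.sum(vals > 1e-10 * vals[0]))
    if max_pcs is not None:
        D = min(D, max_pcs)
    basis = PCBasis(
        eigvecs=vecs[:, :D].copy(),
        eigvals=vals[:D].copy(),
        explained_variance=float(cum[D - 1]),
    )
    return basis.transform(Z), basis


@dataclass
class ICAResult:
    """FastICA decomposition with a restart-stability diagnostic.

    A component counts as *stable* when a majority of random restarts
    recover it up to sign and permutation (matched |corr| above the
    agreement threshold) and its coefficient distribution is measurably
    non-Gaussian (|excess kurtosis| above the sampling floor).
    ``status`` is ``converged`` when at least one stable component
    exists; isotropic-Gaussian data is unidentifiable by ICA, lands in
    ``no_convergence``, and that is a status, not an exception.
    """

    status: str
    W: np.ndarray | None  # (D, D) demixing in whitened space
    A: np.ndarray | None  # mixing (inverse of W)
    S: np.ndarray | None  # (D, N) coefficients
    stable: np.ndarray | None  # bool per component
    n_restarts: int
    agreement: float  # mean matched |corr| of stable components
    kurtosis: np.ndarray | None = None

    @property
    def converged(self) -> bool:
        return self.status == "converged"


def _matched_corr(Sa: np.ndarray, Sb: np.ndarray) -> np.ndarray:
    """|corr| per component of Sa under the optimal pairing with Sb."""
    Ca = (Sa - Sa.mean(1, keepdims=True)) / Sa.std(1, keepdims=True)
    Cb = (Sb - Sb.mean(1, keepdims=True)) / Sb.std(1, keepdims=True)
    corr = np.abs(Ca @ Cb.T) / Sa.shape[1]
    r, c = linear_sum_assignment(-corr)
    out = np.empty(Sa.shape[0])
    out[r] = corr[r, c]
    return out


def fit_ica(
    Xw: np.ndarray,
    n_restarts: int = 10,
    rng=None,
    agree_corr: float = 0.95,
    max_iter: int = 500,
    tol: float = 1e-4,
    max_match_cols: int = 4000,
) -> ICAResult:
    """Fixed-point ICA (kurtosis contrast) repeated from random restarts.

    FastICA runs ``n_restarts`` times from random initial demixing
    matrices on the pre-whitened input (D, N).  The run that agrees
    best with the others is kept; components that replicate across a
    majority of restarts (and are non-Gaussian beyond the kurtosis
    sampling floor ~ 5 sqrt(24/N)) are flagged stable.  With no stable
    component the status is ``no_convergence``.
    """
    rng = np.random.default_rng(rng)
    D, N = Xw.shape
    if D > N:
        raise ValueError(f"more dimensions ({D}) than fragments ({N})")
    runs = []
    for _ in range(n_restarts):
        w_init = rng.normal(size=(D, D))
        ica = FastICA(
            whiten=False, fun="cube", max_iter=max_iter, tol=tol, w_init=w_init
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            try:
                ica.fit(Xw.T)
            except Exception:
                continue
        internal_ok = ica.n_iter_ < max_iter
        runs.append((ica.components_.copy(), internal_ok))
    runs = [r for r in runs if r[1]] or runs
    if not runs:
        return ICAResult(
            "no_convergence", None, None, None, None, n_restarts, 0.0
        )

    cols = (
        np.arange(N)
        if N <= max_match_cols
        else rng.choice(N, size=max_match_cols, replace=False)
    )
    sources = [W @ Xw[:, cols] for W, _ in runs]
    R = len(runs)
    match = np.zeros((R, R, D))  # match[i, j]: per-component corr of run i vs j
    for i in range(R):
        for j in range(R):
            if i != j:
                match[i, j] = _matched_corr(sources[i], sources[j])
    votes = (match > agree_corr).sum(axis=1)  # (R, D)
    best = int(np.argmax(votes.sum(axis=1)))
    stable = (votes[best] + 1) > R / 2 if R > 1 else np.ones(D, dtype=bool)

    W = runs[best][0]
    S = W @ Xw
    # non-Gaussianity floor: excess kurtosis beyond sampling noise
    Sn = (S - S.mean(1, keepdims=True)) / S.std(1, keepdims=True)
    kurt = (Sn**4).mean(axis=1) - 3.0
    floor = max(0.1, 5.0 * np.sqrt(24.0 / N))
    stable = stable & (np.abs(kurt) > floor)

    if not stable.any():
        return ICAResult(
            "no_convergence", W, np.linalg.pinv(W), S, stable, n_restarts,
            0.0, kurt,
        )
    agree = (
        float(np.mean(match[best, :, :][:, stable][match[best, :, :][:, stable] > 0]))
        if R > 1 else 1.0
    )
    return ICAResult(
        status="converged",
        W=W,
        A=np.linalg.pinv(W),
        S=S,
        stable=stable,
        n_restarts=n_restarts,
        agreement=agree,
        kurtosis=kurt,
    )


# ---------------------------------------------------------------------------
# split proposals


@dataclass
class SplitRule:
    """A binary decision in coefficient space.

    kinds: ``valley1d`` (threshold on one IC, optionally a rotated 2-D
    projection), ``kmeans2d`` (nearest of two centroids on an IC pair),
    ``velocity2d`` (2-component Gaussian mixture on peak velocities,
    used where ICA does not converge).  ``tail`` marks threshold splits
    that separate a heavy one-sided tail rather than two comparable
    modes.
    """

    kind: str
    dims: tuple
    threshold: float | None = None
    direction: np.ndarray | None = None  # projection vector for valley1d
    centroids: np.ndarray | None = None  # (2, 2) for kmeans2d
    mixture: dict | None = None  # for velocity2d
    tail: bool = False
    score: float = 0.0

    def assign(self, S: np.ndarray) -> np.ndarray:
        """Child index (0/1) per column of S (or of the feature matrix)."""
        if self.kind == "valley1d":
            x = self.direction @ S[list(self.dims)]
            return (x > self.threshold).astype(int)
        if self.kind == "kmeans2d":
            pts = S[list(self.dims)].T
            d = ((pts[:, None, :] - self.centroids[None]) ** 2).sum(-1)
            return d.argmin(axis=1)
        if self.kind == "velocity2d":
            m = self.mixture
            pts = S[list(self.dims)].T
            logp = []
            for k in range(2):
                diff = pts - np.asarray(m["means"][k])
                cov = np.asarray(m["covs"][k])
                ic = np.linalg.inv(cov)
                q = np.einsum("ni,ij,nj->n", diff, ic, diff)
                logp.append(
                    np.log(m["weights"][k])
                    - 0.5 * (q + np.log(np.linalg.det(cov)))
                )
            return (logp[1] > logp[0]).astype(int)
        raise ValueError(f"unknown split kind {self.kind!r}")


def _gmm_1d(x: np.ndarray, seed: int):
    x = x.reshape(-1, 1)
    g1 = GaussianMixture(1, random_state=seed).fit(x)
    g2 = GaussianMixture(2, n_init=3, random_state=seed).fit(x)
    return g1, g2


def _valley_1d(x: np.ndarray, g2) -> tuple[float, float] | None:
    """Density valley between the two mixture means.

    Returns (threshold, valley_ratio) where the ratio compares the
    density at the minimum with the lower of the densities at the two
    component means; None when the means are not separated.
    """
    mu = np.sort(g2.means_.ravel())
    if mu[1] - mu[0] <= 1e-12:
        return None
    grid = np.linspace(mu[0], mu[1], 201)
    dens = np.exp(g2.score_samples(grid.reshape(-1, 1)))
    peak = np.exp(g2.score_samples(mu.reshape(-1, 1)))
    j = int(np.argmin(dens))
    if j in (0, len(grid) - 1):
        return None
    ratio = float(dens[j] / peak.min())
    return float(grid[j]), ratio


def _split_candidate_1d(
    x: np.ndarray, seed: int, min_dbic: float, max_valley_ratio: float,
    min_frac: float,
):
    sd = x.std()
    if sd <= 0:
        return None
    xs = (x - x.mean()) / sd
    g1, g2 = _gmm_1d(xs, seed)
    n = len(xs)
    dbic = g1.bic(xs.reshape(-1, 1)) - g2.bic(xs.reshape(-1, 1))
    if dbic < min_dbic:
        return None
    valley = _valley_1d(xs, g2)
    if valley is None:
        return None
    thr_s, ratio = valley
    if ratio > max_valley_ratio:
        return None
    frac = np.mean(xs > thr_s)
    if min(frac, 1 - frac) < min_frac:
        return None
    w = np.sort(g2.weights_)
    sds = np.sqrt(np.sort(g2.covariances_.ravel()))
    tail = bool(w[0] < 0.25 and sds[1] / max(sds[0], 1e-12) > 3.0)
    thr = thr_s * sd + x.mean()
    return {"threshold": thr, "score": float(dbic), "tail": tail}


def propose_split(
    S: np.ndarray,
    rng=None,
    min_dbic: float = 20.0,
    max_valley_ratio: float = 0.7,
    min_frac: float = 0.02,
    min_sep_2d: float = 3.0,
    rotations=(),
    component_mask=None,
) -> SplitRule | None:
    """Scan IC coefficients for separable features.

    One-dimensional components (plus configured rotated projections of
    pairs) are tested for bimodality with a 1-vs-2 Gaussian-mixture BIC
    comparison confirmed by a density-valley criterion; the split
    boundary is the minimum-density point between the modes.  If no 1-D
    feature separates, 2-D pairs are tested and split by pairwise
    k-means.  Returns None when the coefficient distribution has no
    separable feature (the node is a submode).
    """
    rng = np.random.default_rng(rng)
    seed = int(rng.integers(2**31 - 1))
    D, N = S.shape
    dims = (
        np.nonzero(np.asarray(component_mask, dtype=bool))[0]
        if component_mask is not None
        else np.arange(D)
    )
    best = None

    def consider(rule: SplitRule):
        nonlocal best
        if best is None or rule.score > best.score:
            best = rule

    for i in dims:
        cand = _split_candidate_1d(
            S[i], seed, min_dbic, max_valley_ratio, min_frac
        )
        if cand:
            consider(
                SplitRule(
                    kind="valley1d", dims=(i,), threshold=cand["threshold"],
                    direction=np.array([1.0]), tail=cand["tail"],
                    score=cand["score"],
                )
            )
    for ii, i in enumerate(dims):
        for j in dims[ii + 1:]:
            for ang in rotations:
                d = np.array([np.cos(np.radians(ang)), np.sin(np.radians(ang))])
                cand = _split_candidate_1d(
                    d @ S[[i, j]], seed, min_dbic, max_valley_ratio, min_frac
                )
                if cand:
                    consider(
                        SplitRule(
                            kind="valley1d", dims=(i, j),
                            threshold=cand["threshold"], direction=d,
                            tail=cand["tail"], score=cand["score"],
                        )
                    )
    if best is not None:
        return best

    # 2-D pairwise k-means separation
    for ii, i in enumerate(dims):
        for j in dims[ii + 1:]:
            pts = S[[i, j]].T
            scale = pts.std(axis=0)
            scale[scale <= 0] = 1.0
            ptss = pts / scale
            g1 = GaussianMixture(1, random_state=seed).fit(ptss)
            g2 = GaussianMixture(2, n_init=3, random_state=seed).fit(ptss)
            dbic = g1.bic(ptss) - g2.bic(ptss)
            if dbic < min_dbic:
                continue
            mu = g2.means_
            within = np.sqrt(
                np.mean([np.trace(c) / 2 for c in g2.covariances_])
            )
            sep = np.linalg.norm(mu[1] - mu[0]) / max(within, 1e-12)
            if sep < min_sep_2d:
                continue
            frac = g2.predict(ptss).mean()
            if min(frac, 1 - frac) < min_frac:
                continue
            km = KMeans(2, init=mu, n_init=1, random_state=seed).fit(ptss)
            consider(
                SplitRule(
                    kind="kmeans2d", dims=(i, j),
                    centroids=km.cluster_centers_ * scale, score=float(dbic),
                )
            )
    return best


def _velocity_tail_split(
    frags: FragmentSet, seed: int, min_sep: float = 2.0, min_frac: float = 0.02
) -> SplitRule | None:
    """Fallback split on the joint peak-velocity distribution (vT(0), vR(0)).

    Used where ICA does not converge but the subset still shows two tails
    in its joint velocity distribution at the turn peak.
    """
    i0 = len(frags.tprime) // 2
    pts = np.column_stack(
        [frags.arrays["vT"][:, i0], frags.arrays["vR"][:, i0]]
    )
    scale = pts.std(axis=0)
    scale[scale <= 0] = 1.0
    ptss = pts / scale
    g2 = GaussianMixture(2, n_init=3, random_state=seed).fit(ptss)
    within = np.sqrt(np.mean([np.trace(c) / 2 for c in g2.covariances_]))
    sep = np.linalg.norm(g2.means_[1] - g2.means_[0]) / max(within, 1e-12)
    if sep < min_sep:
        return None
    lab = g2.predict(ptss)
    frac = lab.mean()
    if min(frac, 1 - frac) < min_frac:
        return None
    mix = {
        "means": (g2.means_ * scale).tolist(),
        "covs": [
            (c * np.outer(scale, scale)).tolist() for c in g2.covariances_
        ],
        "weights": g2.weights_.tolist(),
    }
    return SplitRule(kind="velocity2d", dims=(0, 1), mixture=mix, score=sep)


# ---------------------------------------------------------------------------
# the segmentation tree


@dataclass
class SegmentationConfig:
    """Parameters of the iterative segmentation.

    The first iteration uses the (vH, vT) representation with an 85%
    variance threshold (heading velocity folds the correlated vR and vS
    into one rotational variable, which helps ICA converge on the full
    heterogeneous dataset); later iterations use all of (vR, vT, vS)
    with a 90% threshold.
    """

    half_width_s: float = 0.3
    peak_window: int = 2
    components_first: tuple = ("vH", "vT")
    components_later: tuple = ("vR", "vT", "vS")
    var_threshold_first: float = 0.85
    var_threshold_later: float = 0.90
    max_pcs: int = 6
    n_restarts: int = 10
    agree_corr: float = 0.95
    min_dbic: float = 20.0
    max_valley_ratio: float = 0.7
    min_frac: float = 0.02
    min_sep_2d: float = 3.0
    rotations: tuple = ()
    min_leaf_size: int = 60
    max_depth: int = 6
    velocity_tail_fallback: bool = False
    force_split: tuple = ()  # node paths where a split attempt is forced
    forbid_split: tuple = ()  # node paths declared leaves

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SegmentationNode:
    """One decision point (or leaf) of the tree with its stored transforms."""

    path: str
    n_fragments: int
    status: str  # split | no_split | non_convergence | ics_equal_input | ...
    components: tuple | None = None
    tprime_mask: np.ndarray | None = None
    row_mean: np.ndarray | None = None
    row_sd: np.ndarray | None = None
    basis: PCBasis | None = None
    W: np.ndarray | None = None
    split: SplitRule | None = None
    children: list = field(default_factory=list)
    leaf_id: int | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def coefficients(self, frags: FragmentSet) -> np.ndarray:
        """Project fragments into this node's IC space using stored transforms."""
        raw, _, _ = _stack_components(frags, self.components, self.tprime_mask)
        Z = (raw - self.row_mean[:, None]) / self.row_sd[:, None]
        return self.W @ self.basis.transform(Z)


class SegmentationDepthError(RuntimeError):
    def __init__(self, msg, partial):
        super().__init__(msg)
        self.partial = partial


def _json_default(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    raise TypeError(type(o))


@dataclass
class SubmodeCatalog:
    """The fitted segmentation tree; leaves are submodes."""

    root: SegmentationNode
    config: SegmentationConfig
    frame_rate: float
    tprime: np.ndarray
    n_leaves: int = 0

    def leaves(self):
        out = []

        def walk(node):
            if node.is_leaf:
                out.append(node)
            for ch in node.children:
                walk(ch)

        walk(self.root)
        return out

    def classify(self, frags: FragmentSet) -> np.ndarray:
        """Leaf (submode) id per fragment, routed with stored transforms."""
        if len(frags.tprime) != len(self.tprime) or not np.allclose(
            frags.tprime, self.tprime
        ):
            raise ValueError("fragment t' grid does not match the catalog")
        labels = np.empty(len(frags), dtype=int)

        def route(node, idx):
            if node.is_leaf:
                labels[idx] = node.leaf_id
                return
            sub = frags.subset(idx)
            if node.split.kind == "velocity2d":
                i0 = len(frags.tprime) // 2
                feats = np.vstack(
                    [sub.arrays["vT"][:, i0], sub.arrays["vR"][:, i0]]
                )
                side = node.split.assign(feats)
            else:
                side = node.split.assign(node.coefficients(sub))
            route(node.children[0], idx[side == 0])
            route(node.children[1], idx[side == 1])

        route(self.root, np.arange(len(frags)))
        return labels

    def _node_dict(self, node: SegmentationNode) -> dict:
        d = {
            "path": node.path,
            "n_fragments": node.n_fragments,
            "status": node.status,
            "leaf_id": node.leaf_id,
        }
        if node.components is not None:
            d.update(
                components=list(node.components),
                tprime_mask=node.tprime_mask,
                row_mean=node.row_mean,
                row_sd=node.row_sd,
                eigvecs=node.basis.eigvecs,
                eigvals=node.basis.eigvals,
                explained=node.basis.explained_variance,
                W=node.W,
            )
        if node.split is not None:
            d["split"] = {
                "kind": node.split.kind,
                "dims": list(node.split.dims),
                "threshold": node.split.threshold,
                "direction": node.split.direction,
                "centroids": node.split.centroids,
                "mixture": node.split.mixture,
                "tail": node.split.tail,
                "score": node.split.score,
            }
        d["children"] = [self._node_dict(ch) for ch in node.children]
        return d

    def to_json(self) -> str:
        return json.dumps(
            {
                "format": "flywalk-submode-catalog/1",
                "frame_rate": self.frame_rate,
                "tprime": self.tprime,
                "n_leaves": self.n_leaves,
                "config": self.config.to_dict(),
                "tree": self._node_dict(self.root),
            },
            default=_json_default,
        )

    @staticmethod
    def _node_from_dict(d: dict) -> SegmentationNode:
        node = SegmentationNode(
            path=d["path"], n_fragments=d["n_fragments"], status=d["status"],
            leaf_id=d["leaf_id"],
        )
        if "components" in d:
            node.components = tuple(d["components"])
            node.tprime_mask = np.asarray(d["tprime_mask"], dtype=bool)
            node.row_mean = np.asarray(d["row_mean"])
            node.row_sd = np.asarray(d["row_sd"])
            node.basis = PCBasis(
                np.asarray(d["eigvecs"]), np.asarray(d["eigvals"]),
                d["explained"],
            )
            node.W = np.asarray(d["W"])
        if d.get("split"):
            s = d["split"]
            node.split = SplitRule(
                kind=s["kind"], dims=tuple(s["dims"]), threshold=s["threshold"],
                direction=None if s["direction"] is None else np.asarray(s["direction"]),
                centroids=None if s["centroids"] is None else np.asarray(s["centroids"]),
                mixture=s["mixture"], tail=s["tail"], score=s["score"],
            )
        node.children = [SubmodeCatalog._node_from_dict(c) for c in d["children"]]
        return node

    @classmethod
    def from_json(cls, s: str) -> "SubmodeCatalog":
        d = json.loads(s)
        cfg = SegmentationConfig(**{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in d["config"].items()
        })
        return cls(
            root=cls._node_from_dict(d["tree"]),
            config=cfg,
            frame_rate=d["frame_rate"],
            tprime=np.asarray(d["tprime"]),
            n_leaves=d["n_leaves"],
        )

    def tree_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()


class FragmentSegmenter(BaseEstimator, ClusterMixin):
    """Iterative-ICA segmentation tree as a clustering estimator.

    Parameters mirror :class:`SegmentationConfig`.  ``fit`` accepts a
    :class:`FragmentSet` (or a list of :class:`VelocityTrajectory`, in
    which case peaks are detected and fragments extracted first) and
    exposes ``catalog_`` (the tree), ``labels_`` (training submode ids)
    and ``n_leaves_``; ``predict`` routes new fragments down the tree.
    """

    def __init__(
        self,
        half_width_s: float = 0.3,
        peak_window: int = 2,
        components_first=("vH", "vT"),
        components_later=("vR", "vT", "vS"),
        var_threshold_first: float = 0.85,
        var_threshold_later: float = 0.90,
        max_pcs: int = 6,
        n_restarts: int = 10,
        agree_corr: float = 0.95,
        min_dbic: float = 20.0,
        max_valley_ratio: float = 0.7,
        min_frac: float = 0.02,
        min_sep_2d: float = 3.0,
        rotations=(),
        min_leaf_size: int = 60,
        max_depth: int = 6,
        velocity_tail_fallback: bool = False,
        force_split=(),
        forbid_split=(),
        random_state=None,
    ):
        self.half_width_s = half_width_s
        self.peak_window = peak_window
        self.components_first = components_first
        self.components_later = components_later
        self.var_threshold_first = var_threshold_first
        self.var_threshold_later = var_threshold_later
        self.max_pcs = max_pcs
        self.n_restarts = n_restarts
        self.agree_corr = agree_corr
        self.min_dbic = min_dbic
        self.max_valley_ratio = max_valley_ratio
        self.min_frac = min_frac
        self.min_sep_2d = min_sep_2d
        self.rotations = rotations
        self.min_leaf_size = min_leaf_size
        self.max_depth = max_depth
        self.velocity_tail_fallback = velocity_tail_fallback
        self.force_split = force_split
        self.forbid_split = forbid_split
        self.random_state = random_state

    def _config(self) -> SegmentationConfig:
        return SegmentationConfig(
            half_width_s=self.half_width_s,
            peak_window=self.peak_window,
            components_first=tuple(self.components_first),
            components_later=tuple(self.components_later),
            var_threshold_first=self.var_threshold_first,
            var_threshold_later=self.var_threshold_later,
            max_pcs=self.max_pcs,
            n_restarts=self.n_restarts,
            agree_corr=self.agree_corr,
            min_dbic=self.min_dbic,
            max_valley_ratio=self.max_valley_ratio,
            min_frac=self.min_frac,
            min_sep_2d=self.min_sep_2d,
            rotations=tuple(self.rotations),
            min_leaf_size=self.min_leaf_size,
            max_depth=self.max_depth,
            velocity_tail_fallback=self.velocity_tail_fallback,
            force_split=tuple(self.force_split),
            forbid_split=tuple(self.forbid_split),
        )

    def _as_fragments(self, X) -> FragmentSet:
        if isinstance(X, FragmentSet):
            return X
        return extract_fragments(
            X, half_width_s=self.half_width_s, window=self.peak_window
        )

    def fit(self, X, y=None):
        cfg = self._config()
        frags = self._as_fragments(X)
        if len(frags) < max(cfg.min_leaf_size, 4):
            raise ValueError(f"too few fragments ({len(frags)}) to segment")
        rng = np.random.default_rng(self.random_state)
        labels = np.full(len(frags), -1, dtype=int)

        def build(idx: np.ndarray, path: str, depth: int) -> SegmentationNode:
            sub = frags.subset(idx)
            node = SegmentationNode(path=path, n_fragments=len(idx), status="")
            if path in cfg.forbid_split:
                node.status = "forbidden"
                return node
            if len(idx) < 2 * cfg.min_leaf_size:
                node.status = "min_size"
                return node
            if depth >= cfg.max_depth:
                node.status = "max_depth"
                raise SegmentationDepthError(
                    f"max depth {cfg.max_depth} exceeded at node {path}", node
                )
            comps = cfg.components_first if depth == 0 else cfg.components_later
            thr = (
                cfg.var_threshold_first if depth == 0 else cfg.var_threshold_later
            )
            fm = assemble_standardize(sub, components=comps)
            Xw, basis = whiten_reduce(fm, var_threshold=thr,
                                      max_pcs=cfg.max_pcs)
            node.components = comps
            node.tprime_mask = np.ones_like(frags.tprime, dtype=bool)
            node.row_mean = fm.row_mean
            node.row_sd = fm.row_sd
            node.basis = basis
            ica = fit_ica(
                Xw, n_restarts=cfg.n_restarts, rng=rng,
                agree_corr=cfg.agree_corr,
            )
            rule = None
            if not ica.converged:
                node.status = "non_convergence"
                if cfg.velocity_tail_fallback:
                    rule = _velocity_tail_split(
                        sub, seed=int(rng.integers(2**31 - 1)),
                        min_frac=cfg.min_frac,
                    )
                if rule is None:
                    return node
                side = rule.assign(
                    np.vstack(
                        [
                            sub.arrays["vT"][:, len(frags.tprime) // 2],
                            sub.arrays["vR"][:, len(frags.tprime) // 2],
                        ]
                    )
                )
            else:
                node.W = ica.W
                forced = path in cfg.force_split
                rule = propose_split(
                    ica.S, rng=rng,
                    min_dbic=0.0 if forced else cfg.min_dbic,
                    max_valley_ratio=1.0 if forced else cfg.max_valley_ratio,
                    min_frac=cfg.min_frac, min_sep_2d=cfg.min_sep_2d,
                    rotations=cfg.rotations, component_mask=ica.stable,
                )
                if rule is None:
                    # distinguish "nothing separable" from "ICA found only
                    # the input (PC) axes again"
                    Wn = np.abs(ica.W) / np.linalg.norm(
                        ica.W, axis=1, keepdims=True
                    )
                    node.status = (
                        "ics_equal_input"
                        if basis.D > 1
                        and np.all(Wn[ica.stable].max(axis=1) > 0.98)
                        else "no_split"
                    )
                    return node
                side = rule.assign(ica.S)
            if min(side.mean(), 1 - side.mean()) * len(idx) < cfg.min_leaf_size:
                node.status = "no_split"
                return node
            node.status = "split"
            node.split = rule
            node.children = [
                build(idx[side == 0], path + "0", depth + 1),
                build(idx[side == 1], path + "1", depth + 1),
            ]
            return node

        root = build(np.arange(len(frags)), "r", 0)
        # assign stable leaf ids in DFS order
        leaf_id = 0

        def number(node):
            nonlocal leaf_id
            if node.is_leaf:
                node.leaf_id = leaf_id
                leaf_id += 1
            for ch in node.children:
                number(ch)

        number(root)
        self.catalog_ = SubmodeCatalog(
            root=root, config=cfg, frame_rate=frags.frame_rate,
            tprime=frags.tprime, n_leaves=leaf_id,
        )
        labels = self.catalog_.classify(frags)
        self.labels_ = labels
        self.n_leaves_ = leaf_id
        self.training_fragments_ = frags
        return self

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "catalog_"):
            raise ValueError("not fitted")
        return self.catalog_.classify(self._as_fragments(X))

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


def iterate_segmentation(trajs, config: SegmentationConfig | None = None,
                         random_state=None) -> SubmodeCatalog:
    """Run the full iterative segmentation; thin wrapper over
    :class:`FragmentSegmenter`."""
    cfg = config or SegmentationConfig()
    seg = FragmentSegmenter(random_state=random_state, **cfg.to_dict())
    seg.fit(trajs)
    return seg.catalog_


def classify(frags_or_trajs, catalog: SubmodeCatalog) -> np.ndarray:
    """Submode label per fragment (peaks detected first for raw trajectories)."""
    if isinstance(frags_or_trajs, FragmentSet):
        return catalog.classify(frags_or_trajs)
    frags = extract_fragments(
        frags_or_trajs, half_width_s=catalog.config.half_width_s,
        window=catalog.config.peak_window,
    )
    return catalog.classify(frags)
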