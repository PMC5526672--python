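"""Velocity phase space: kinematic field and trajectory divergence.

The kinematic field is the bin-wise mean acceleration as a function of
velocity, E[a | v], on a regular grid over (vT, vR, vS), together with
the mean absolute deviation of accelerations about that mean — a local
description of behavior dynamics at one time step.

Trajectory divergence asks how quickly initially similar velocities
separate: small neighborhoods (single occupied grid bins) are sampled at
random, and the geometric spread of the trajectory ensemble passing
through each neighborhood is followed over time,

    sigma_bar(t) = < sigma_t[vT] sigma_t[vR] sigma_t[vS] >_NB
                   / (sigma[vT] sigma[vR] sigma[vS]),

i.e. the product of per-component standard deviations at lag t,
averaged over neighborhoods and normalized by the stationary spread, so
that sigma_bar -> ~1 once trajectories decorrelate.  Conditioning
schemes restrict the ensemble to trajectories with a vR peak a fixed
delay after the neighborhood (optionally of a given mode / profile
quartile), which is how bounded within-mode divergence is exposed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

__all__ = [
    "VelocityGrid",
    "KinematicField",
    "DivergenceCurve",
    "effective_sample_size",
    "integrated_autocorrelation_time",
    "build_kinematic_field",
    "divergence_curve",
]


@dataclass
class VelocityGrid:
    """Regular bin edges over (vT, vR, vS).

    Defaults follow the measured occupancy of walking-fly velocities:
    |vR| < 450 deg/s in 25 deg/s steps, -0.6 <= vT <= 3.2 cm/s in
    0.09 cm/s steps, |vS| < 0.94 cm/s in 0.063 cm/s steps.
    """

    vT_edges: np.ndarray = field(
        default_factory=lambda: np.arange(-0.6, 3.2 + 1e-9, 0.09)
    )
    vR_edges: np.ndarray = field(
        default_factory=lambda: np.arange(-450.0, 450.0 + 1e-9, 25.0)
    )
    vS_edges: np.ndarray = field(
        default_factory=lambda: np.arange(-0.94, 0.94 + 1e-9, 0.063)
    )

    def __post_init__(self) -> None:
        for name in ("vT_edges", "vR_edges", "vS_edges"):
            e = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, e)
            if e.ndim != 1 or len(e) < 2 or not np.all(np.diff(e) > 0):
                raise ValueError(f"{name} must be strictly increasing, length >= 2")

    @classmethod
    def coarse(cls, n: int = 8, vT=(-0.6, 3.2), vR=(-450.0, 450.0), vS=(-0.94, 0.94)):
        """Convenience coarse grid (n bins per component)."""
        return cls(
            vT_edges=np.linspace(*vT, n + 1),
            vR_edges=np.linspace(*vR, n + 1),
            vS_edges=np.linspace(*vS, n + 1),
        )

    @property
    def shape(self):
        return (
            len(self.vT_edges) - 1,
            len(self.vR_edges) - 1,
            len(self.vS_edges) - 1,
        )

    @property
    def n_bins(self) -> int:
        return int(np.prod(self.shape))

    def bin_index(self, vT, vR, vS) -> np.ndarray:
        """Flat bin index per sample; -1 for out-of-range samples."""
        iT = np.searchsorted(self.vT_edges, vT, side="right") - 1
        iR = np.searchsorted(self.vR_edges, vR, side="right") - 1
        iS = np.searchsorted(self.vS_edges, vS, side="right") - 1
        nT, nR, nS = self.shape
        ok = (
            (iT >= 0) & (iT < nT) & (iR >= 0) & (iR < nR) & (iS >= 0) & (iS < nS)
        )
        flat = (iT * nR + iR) * nS + iS
        return np.where(ok, flat, -1)

    def bin_centers(self, flat: np.ndarray) -> np.ndarray:
        """(n, 3) centers (vT, vR, vS) for flat indices."""
        nT, nR, nS = self.shape
        iS = flat % nS
        iR = (flat // nS) % nR
        iT = flat // (nS * nR)
        cT = 0.5 * (self.vT_edges[:-1] + self.vT_edges[1:])
        cR = 0.5 * (self.vR_edges[:-1] + self.vR_edges[1:])
        cS = 0.5 * (self.vS_edges[:-1] + self.vS_edges[1:])
        return np.column_stack([cT[iT], cR[iR], cS[iS]])


def integrated_autocorrelation_time(
    x: np.ndarray, max_tau: float | None = None
) -> float:
    """tau_int = 1 + 2 sum_k rho_k with initial-positive-sequence truncation.

    The empirical autocorrelation is summed until it first drops below
    zero (a standard bias-bounded estimator).  Constant series have
    undefined autocorrelation and return the cap (default n).
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 2:
        raise ValueError("need >= 2 samples")
    cap = float(n) if max_tau is None else float(max_tau)
    x = x - x.mean()
    var = np.dot(x, x)
    if var <= 0:
        return cap
    # FFT autocorrelation
    m = 1 << (2 * n - 1).bit_length()
    f = np.fft.rfft(x, m)
    acf = np.fft.irfft(f * np.conj(f), m)[:n] / var
    rho = acf[1:]
    neg = np.nonzero(rho <= 0)[0]
    stop = neg[0] if neg.size else len(rho)
    tau = 1.0 + 2.0 * rho[:stop].sum()
    return float(np.clip(tau, 1.0, cap))


def effective_sample_size(x: np.ndarray, max_tau: float | None = None) -> float:
    """n_eff = n / tau_int; equals ~n for i.i.d. samples, n/cap when degenerate."""
    x = np.asarray(x, dtype=float)
    return len(x) / integrated_autocorrelation_time(x, max_tau=max_tau)


@dataclass
class KinematicField:
    """Per-bin acceleration statistics over a :class:`VelocityGrid`."""

    grid: VelocityGrid
    mean_accel: np.ndarray  # (n_bins, 3), NaN where empty
    mad_accel: np.ndarray  # (n_bins,), E[|a - <a>|] vector deviation
    counts: np.ndarray  # (n_bins,)
    n_eff: np.ndarray  # (n_bins,)
    retained: np.ndarray  # bool mask, n_eff >= min_eff
    tau_int: float

    def occupied_bins(self) -> np.ndarray:
        return np.nonzero(self.retained)[0]

    def to_frame(self):
        import pandas as pd

        idx = np.nonzero(self.counts > 0)[0]
        centers = self.grid.bin_centers(idx)
        return pd.DataFrame(
            {
                "bin": idx,
                "vT": centers[:, 0],
                "vR": centers[:, 1],
                "vS": centers[:, 2],
                "aT_mean": self.mean_accel[idx, 0],
                "aR_mean": self.mean_accel[idx, 1],
                "aS_mean": self.mean_accel[idx, 2],
                "mad": self.mad_accel[idx],
                "n": self.counts[idx],
                "n_eff": self.n_eff[idx],
                "retained": self.retained[idx],
            }
        )


def _velocity_samples(trajs):
    """Concatenate velocity and acceleration samples over trajectories."""
    vs, accs = [], []
    for t in trajs:
        if t.aT is None:
            raise ValueError(
                f"trajectory {t.id!r}: accelerations missing; "
                "call compute_accelerations first"
            )
        vs.append(t.components().T)
        accs.append(t.accelerations().T)
    return np.concatenate(vs), np.concatenate(accs)


def build_kinematic_field(
    trajs, grid: VelocityGrid | None = None, min_eff: float = 10.0
) -> KinematicField:
    """Bin accelerations by velocity; mean and mean absolute deviation per bin.

    The effective count per bin divides the raw count by the dataset-level
    integrated autocorrelation time (mean over the three velocity
    components); bins with ``n_eff`` below ``min_eff`` are masked out.
    """
    trajs = list(trajs)
    if not trajs:
        raise ValueError("empty input")
    grid = grid or VelocityGrid()
    v, a = _velocity_samples(trajs)
    ok = np.all(np.isfinite(v), axis=1) & np.all(np.isfinite(a), axis=1)
    v, a = v[ok], a[ok]
    flat = grid.bin_index(v[:, 0], v[:, 1], v[:, 2])
    inside = flat >= 0
    flat, a_in = flat[inside], a[inside]

    nb = grid.n_bins
    counts = np.bincount(flat, minlength=nb).astype(float)
    sums = np.zeros((nb, 3))
    for c in range(3):
        sums[:, c] = np.bincount(flat, weights=a_in[:, c], minlength=nb)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = sums / counts[:, None]
    dev = np.linalg.norm(a_in - mean[flat], axis=1)
    mad = np.bincount(flat, weights=dev, minlength=nb)
    with np.errstate(invalid="ignore", divide="ignore"):
        mad = mad / counts

    taus = [
        np.mean(
            [integrated_autocorrelation_time(getattr(t, c))
             for t in trajs if len(t) >= 4]
        )
        for c in ("vT", "vR", "vS")
    ]
    tau = float(np.mean(taus))
    n_eff = counts / tau
    return KinematicField(
        grid=grid,
        mean_accel=mean,
        mad_accel=mad,
        counts=counts,
        n_eff=n_eff,
        retained=n_eff >= min_eff,
        tau_int=tau,
    )


@dataclass
class DivergenceCurve:
    """Normalized ensemble spread sigma_bar(t) after a small neighborhood."""

    t: np.ndarray
    sigma: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    conditioning: str
    n_neighborhoods: int
    repeats: int
    skipped: int

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "t_s": self.t,
                "sigma_bar": self.sigma,
                "ci95_low": self.ci_low,
                "ci95_high": self.ci_high,
            }
        )


def _peak_lookup(trajs, peaks_per_traj, frame_rate, delay_s):
    """Per trajectory: boolean 'peak occurs delay after index i' arrays."""
    d = int(round(delay_s * frame_rate))
    out = []
    for t, peaks in zip(trajs, peaks_per_traj):
        has = np.zeros(len(t), dtype=bool)
        idx = np.asarray(peaks, dtype=int) - d
        idx = idx[(idx >= 0) & (idx < len(t))]
        has[idx] = True
        out.append(has)
    return out


def divergence_curve(
    trajs,
    grid: VelocityGrid | None = None,
    conditioning: str = "none",
    peaks=None,
    peak_modes=None,
    mode=None,
    peak_delay_s: float = 0.1,
    t_max_s: float = 0.6,
    NB: int = 200,
    repeats: int = 50,
    min_trajectories: int = 5,
    rng=None,
) -> DivergenceCurve:
    """sigma_bar(t) averaged over NB randomly sampled occupied bins.

    ``conditioning``:
      * ``"none"`` — all passages through each neighborhood;
      * ``"peak"`` — only passages with a vR peak ``peak_delay_s`` later
        (requires ``peaks``: per-trajectory peak frame indices);
      * ``"mode"`` — additionally the peak is labeled ``mode``
        (requires ``peak_modes`` aligned with ``peaks``).

    Neighborhoods are single occupied bins of ``grid``, sampled without
    replacement; neighborhoods whose conditioned ensemble falls below
    ``min_trajectories`` passages are skipped.  The 95% CI comes from
    ``repeats`` re-draws of the NB neighborhoods.
    """
    rng = np.random.default_rng(rng)
    trajs = list(trajs)
    grid = grid or VelocityGrid()
    fr = trajs[0].frame_rate
    T = int(round(t_max_s * fr))
    tgrid = np.arange(T + 1) / fr

    comp = [t.components() for t in trajs]  # (3, n) each
    flat = [
        grid.bin_index(c[0], c[1], c[2]) for c in comp
    ]

    if conditioning in ("peak", "mode"):
        if peaks is None:
            raise ValueError("conditioning on peaks requires peak indices")
        d = int(round(peak_delay_s * fr))
        allow = []
        for ti, (t, pk) in enumerate(zip(trajs, peaks)):
            ok = np.zeros(len(t), dtype=bool)
            pk = np.asarray(pk, dtype=int)
            if conditioning == "mode":
                if peak_modes is None or mode is None:
                    raise ValueError("mode conditioning requires peak_modes and mode")
                pk = pk[np.asarray(peak_modes[ti]) == mode]
            idx = pk - d
            idx = idx[(idx >= 0) & (idx < len(t))]
            ok[idx] = True
            allow.append(ok)
    else:
        allow = [np.ones(len(t), dtype=bool) for t in trajs]

    # passages: bin -> list of (traj, entry index); consecutive samples in
    # the same bin are one passage, and the forward segment must fit the
    # requested horizon
    passages: dict = {}
    for ti, fl in enumerate(flat):
        n = len(fl)
        entry = np.ones(n, dtype=bool)
        entry[1:] = fl[1:] != fl[:-1]
        valid = np.nonzero(
            (fl >= 0) & entry & allow[ti] & (np.arange(n) + T < n)
        )[0]
        for i in valid:
            passages.setdefault(fl[i], []).append((ti, i))

    # global per-component sd (stationary normalization)
    allv = np.concatenate([c.T for c in comp])
    gsd = np.prod(allv.std(axis=0))

    usable = [b for b, p in passages.items() if len(p) >= min_trajectories]
    skipped = len(passages) - len(usable)
    if not usable:
        raise ValueError("no neighborhood survives conditioning")

    # per-bin normalized spread curves, computed once
    curves = {}

    def c4(m: int) -> float:
        # E[s]/sigma for a Gaussian sample of size m (ddof=1); corrects
        # the small-ensemble bias of the spread product
        return float(
            np.exp(
                0.5 * np.log(2.0 / (m - 1))
                + gammaln(m / 2)
                - gammaln((m - 1) / 2)
            )
        )

    def bin_curve(b):
        if b in curves:
            return curves[b]
        segs = np.empty((len(passages[b]), T + 1, 3))
        for j, (ti, i) in enumerate(passages[b]):
            segs[j] = comp[ti][:, i : i + T + 1].T
        m = segs.shape[0]
        sd = segs.std(axis=0, ddof=1) / c4(m)  # (T+1, 3)
        curves[b] = np.prod(sd, axis=1) / gsd
        return curves[b]

    nb = min(NB, len(usable))
    usable = np.asarray(usable)
    means = np.empty((repeats, T + 1))
    for r in range(repeats):
        chosen = rng.choice(usable, size=nb, replace=False)
        means[r] = np.mean([bin_curve(b) for b in chosen], axis=0)
    mean = means.mean(axis=0)
    sem = means.std(axis=0, ddof=1) / np.sqrt(repeats) if repeats > 1 else np.zeros(T + 1)
    return DivergenceCurve(
        t=tgrid,
        sigma=mean,
        ci_low=mean - 1.96 * sem,
        ci_high=mean + 1.96 * sem,
        conditioning=conditioning,
        n_neighborhoods=nb,
        repeats=repeats,
        skipped=skipped,
    )
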