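"""Trajectory I/O and body-frame kinematics.

A walking fly on a plane is fully described by its centroid position
(x, y, in cm) and body orientation theta (degrees, head direction),
sampled on a uniform time grid.  Whole-animal movement is then captured
by three body-frame velocity components:

* ``vT`` -- translation along the body axis (cm/s),
* ``vR`` -- rotation (deg/s, counterclockwise positive),
* ``vS`` -- side-slip, motion perpendicular to the body axis
  (cm/s, positive toward the animal's left).

This module reads and writes trajectory tables (CSV / HDF5), applies
Gaussian smoothing, and converts position/orientation series to
velocities, accelerations and the combined heading velocity
``vH = vR - d/dt arctan2(vS, vT)`` (deg/s).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

__all__ = [
    "RawTrajectory",
    "VelocityTrajectory",
    "TrajectoryFormatError",
    "TrajectoryValidationError",
    "read_trajectories",
    "write_trajectories",
    "smooth_trajectory",
    "compute_velocities",
    "compute_accelerations",
    "heading_velocity",
    "integrate_velocities",
]

CSV_COLUMNS = ["trajectory_id", "frame", "x_cm", "y_cm", "theta_deg"]


class TrajectoryFormatError(ValueError):
    """Input file does not follow the trajectory schema."""


class TrajectoryValidationError(ValueError):
    """Trajectory content violates an invariant (e.g. skipped frames)."""


@dataclass
class RawTrajectory:
    """Centroid/orientation time series on a uniform frame grid.

    ``theta`` is the head direction in degrees (already disambiguated);
    it may wrap modulo 360 on input and is unwrapped before smoothing
    or differentiation.
    """

    id: str
    frame_rate: float
    times: np.ndarray
    x: np.ndarray
    y: np.ndarray
    theta: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.theta = np.asarray(self.theta, dtype=float)
        n = len(self.times)
        if n < 3:
            raise TrajectoryValidationError(
                f"trajectory {self.id!r}: length {n} < 3"
            )
        for name in ("times", "x", "y", "theta"):
            arr = getattr(self, name)
            if arr.shape != (n,):
                raise TrajectoryValidationError(
                    f"trajectory {self.id!r}: field {name} has shape {arr.shape}"
                )
            if not np.all(np.isfinite(arr)):
                raise TrajectoryValidationError(
                    f"trajectory {self.id!r}: non-finite values in {name}"
                )
        dt = np.diff(self.times)
        expected = 1.0 / self.frame_rate
        bad = np.nonzero(np.abs(dt - expected) > 1e-9)[0]
        if bad.size:
            i = int(bad[0])
            raise TrajectoryValidationError(
                f"trajectory {self.id!r}: non-uniform frame spacing at frame "
                f"{i + 1} (dt={dt[i]:.6g} s, expected {expected:.6g} s)"
            )

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class VelocityTrajectory:
    """Body-frame velocity (and optionally acceleration) series.

    Units: ``vT``, ``vS`` in cm/s; ``vR`` in deg/s; accelerations are the
    per-second derivatives of the corresponding components; ``vH`` in
    deg/s.  ``vH`` is NaN-masked where the planar speed is ~0 (the
    heading direction is undefined there).
    """

    id: str
    frame_rate: float
    times: np.ndarray
    vT: np.ndarray
    vR: np.ndarray
    vS: np.ndarray
    aT: np.ndarray | None = None
    aR: np.ndarray | None = None
    aS: np.ndarray | None = None
    vH: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.vT = np.asarray(self.vT, dtype=float)
        self.vR = np.asarray(self.vR, dtype=float)
        self.vS = np.asarray(self.vS, dtype=float)
        n = len(self.times)
        for name in ("vT", "vR", "vS", "aT", "aR", "aS", "vH"):
            arr = getattr(self, name)
            if arr is None:
                continue
            arr = np.asarray(arr, dtype=float)
            setattr(self, name, arr)
            if arr.shape != (n,):
                raise TrajectoryValidationError(
                    f"trajectory {self.id!r}: component {name} has length "
                    f"{len(arr)}, expected {n}"
                )

    def __len__(self) -> int:
        return len(self.times)

    def components(self) -> np.ndarray:
        """Stacked (3, n) array in (vT, vR, vS) order."""
        return np.vstack([self.vT, self.vR, self.vS])

    def accelerations(self) -> np.ndarray:
        if self.aT is None:
            raise ValueError("accelerations not computed; call compute_accelerations")
        return np.vstack([self.aT, self.aR, self.aS])


# ---------------------------------------------------------------------------
# I/O


def _trajectories_from_frame(df: pd.DataFrame, frame_rate: float):
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise TrajectoryFormatError(f"missing required column(s): {missing}")
    out = []
    for tid, grp in df.groupby("trajectory_id", sort=True):
        grp = grp.sort_values("frame")
        frames = grp["frame"].to_numpy(dtype=float)
        gaps = np.nonzero(np.diff(frames) != 1)[0]
        if gaps.size:
            i = int(gaps[0])
            raise TrajectoryValidationError(
                f"trajectory {tid!r}: skipped frame after frame "
                f"{int(frames[i])}"
            )
        out.append(
            RawTrajectory(
                id=str(tid),
                frame_rate=frame_rate,
                times=frames / frame_rate,
                x=grp["x_cm"].to_numpy(dtype=float),
                y=grp["y_cm"].to_numpy(dtype=float),
                theta=grp["theta_deg"].to_numpy(dtype=float),
            )
        )
    return out


def read_trajectories(path, format: str | None = None, frame_rate: float = 30.0):
    """Read trajectories from a CSV or HDF5 file.

    CSV schema: columns ``trajectory_id, frame, x_cm, y_cm, theta_deg``;
    HDF5 mirror: one group per trajectory holding the same arrays, with a
    ``frame_rate`` attribute.  Returns a list of :class:`RawTrajectory`.
    """
    path = str(path)
    if format is None:
        format = "hdf5" if path.endswith((".h5", ".hdf5")) else "csv"
    if format == "csv":
        df = pd.read_csv(path)
        return _trajectories_from_frame(df, frame_rate)
    if format == "hdf5":
        import h5py

        out = []
        with h5py.File(path, "r") as f:
            for tid in sorted(f.keys()):
                grp = f[tid]
                for name in ("frame", "x_cm", "y_cm", "theta_deg"):
                    if name not in grp:
                        raise TrajectoryFormatError(
                            f"group {tid!r}: missing dataset {name!r}"
                        )
                fr = float(grp.attrs.get("frame_rate", frame_rate))
                frames = np.asarray(grp["frame"], dtype=float)
                gaps = np.nonzero(np.diff(frames) != 1)[0]
                if gaps.size:
                    raise TrajectoryValidationError(
                        f"trajectory {tid!r}: skipped frame after frame "
                        f"{int(frames[int(gaps[0])])}"
                    )
                out.append(
                    RawTrajectory(
                        id=str(tid),
                        frame_rate=fr,
                        times=frames / fr,
                        x=np.asarray(grp["x_cm"], dtype=float),
                        y=np.asarray(grp["y_cm"], dtype=float),
                        theta=np.asarray(grp["theta_deg"], dtype=float),
                    )
                )
        return out
    raise TrajectoryFormatError(f"unknown format {format!r}")


def write_trajectories(trajs, path, format: str | None = None) -> None:
    """Write trajectories to CSV or HDF5 (inverse of :func:`read_trajectories`)."""
    path = str(path)
    if format is None:
        format = "hdf5" if path.endswith((".h5", ".hdf5")) else "csv"
    if format == "csv":
        parts = []
        for t in trajs:
            parts.append(
                pd.DataFrame(
                    {
                        "trajectory_id": t.id,
                        "frame": np.round(t.times * t.frame_rate).astype(int),
                        "x_cm": t.x,
                        "y_cm": t.y,
                        "theta_deg": t.theta,
                    }
                )
            )
        pd.concat(parts, ignore_index=True).to_csv(path, index=False)
        return
    if format == "hdf5":
        import h5py

        with h5py.File(path, "w") as f:
            for t in trajs:
                grp = f.create_group(t.id)
                grp.attrs["frame_rate"] = t.frame_rate
                grp.create_dataset(
                    "frame", data=np.round(t.times * t.frame_rate).astype(int)
                )
                grp.create_dataset("x_cm", data=t.x)
                grp.create_dataset("y_cm", data=t.y)
                grp.create_dataset("theta_deg", data=t.theta)
        return
    raise TrajectoryFormatError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# kinematics


def _unwrap_deg(theta: np.ndarray) -> np.ndarray:
    return np.degrees(np.unwrap(np.radians(theta)))


def smooth_trajectory(raw: RawTrajectory, kernel_sd: float = 1.0) -> RawTrajectory:
    """Gaussian-smooth x, y and unwrapped theta.

    ``kernel_sd`` is the kernel standard deviation in frames (1 frame at
    30 Hz gives FWHM ~ 0.08 s).  ``kernel_sd=0`` is the identity apart
    from the orientation unwrap.
    """
    if kernel_sd < 0:
        raise ValueError("kernel_sd must be >= 0")
    theta = _unwrap_deg(raw.theta)
    if kernel_sd == 0:
        return replace(raw, x=raw.x.copy(), y=raw.y.copy(), theta=theta)
    return replace(
        raw,
        x=gaussian_filter1d(raw.x, kernel_sd, mode="nearest"),
        y=gaussian_filter1d(raw.y, kernel_sd, mode="nearest"),
        theta=gaussian_filter1d(theta, kernel_sd, mode="nearest"),
    )


def compute_velocities(raw: RawTrajectory) -> VelocityTrajectory:
    """Body-frame velocities by central differences (endpoints excluded).

    The lab-frame centroid velocity is projected onto the instantaneous
    body axes: ``vT`` along the heading unit vector (cos, sin theta) and
    ``vS`` along the leftward perpendicular (-sin, cos theta).  ``vR`` is
    the derivative of the unwrapped orientation.
    """
    if len(raw) < 3:
        raise TrajectoryValidationError(
            f"trajectory {raw.id!r}: need >= 3 frames to differentiate"
        )
    theta = _unwrap_deg(raw.theta)
    dt = 1.0 / raw.frame_rate
    # central differences on the interior
    sl = slice(1, -1)
    dx = (raw.x[2:] - raw.x[:-2]) / (2 * dt)
    dy = (raw.y[2:] - raw.y[:-2]) / (2 * dt)
    vR = (theta[2:] - theta[:-2]) / (2 * dt)
    th = np.radians(theta[sl])
    cos, sin = np.cos(th), np.sin(th)
    vT = dx * cos + dy * sin
    vS = -dx * sin + dy * cos
    return VelocityTrajectory(
        id=raw.id,
        frame_rate=raw.frame_rate,
        times=raw.times[sl].copy(),
        vT=vT,
        vR=vR,
        vS=vS,
    )


def compute_accelerations(vel: VelocityTrajectory) -> VelocityTrajectory:
    """Per-component time derivative (central interior, one-sided ends)."""
    dt = 1.0 / vel.frame_rate
    vel.aT = np.gradient(vel.vT, dt)
    vel.aR = np.gradient(vel.vR, dt)
    vel.aS = np.gradient(vel.vS, dt)
    return vel


def heading_velocity(
    vel: VelocityTrajectory, speed_floor: float = 1e-9
) -> VelocityTrajectory:
    """Fill ``vH = vR - d/dt arctan2(vS, vT)`` (degrees per second).

    The two-argument arctangent keeps the side-slip angle defined when
    ``vT`` crosses zero; samples where both vT and vS are ~0 are masked
    with NaN since the heading of motion is undefined there.
    """
    dt = 1.0 / vel.frame_rate
    slip = np.degrees(np.unwrap(np.arctan2(vel.vS, vel.vT)))
    vel.vH = vel.vR - np.gradient(slip, dt)
    degenerate = np.hypot(vel.vT, vel.vS) < speed_floor
    if degenerate.any():
        vel.vH = np.where(degenerate, np.nan, vel.vH)
    return vel


def integrate_velocities(
    vel: VelocityTrajectory,
    x0: float = 0.0,
    y0: float = 0.0,
    theta0: float = 0.0,
) -> RawTrajectory:
    """Reconstruct a centroid path from body-frame velocities.

    Inverse of :func:`compute_velocities` up to cumulative
    finite-difference error; used by the synthetic generator and by
    round-trip tests.
    """
    dt = 1.0 / vel.frame_rate
    theta = theta0 + np.concatenate([[0.0], np.cumsum(vel.vR[:-1] * dt)])
    th = np.radians(theta)
    dx = (vel.vT * np.cos(th) - vel.vS * np.sin(th)) * dt
    dy = (vel.vT * np.sin(th) + vel.vS * np.cos(th)) * dt
    x = x0 + np.concatenate([[0.0], np.cumsum(dx[:-1])])
    y = y0 + np.concatenate([[0.0], np.cumsum(dy[:-1])])
    return RawTrajectory(
        id=vel.id,
        frame_rate=vel.frame_rate,
        times=vel.times.copy(),
        x=x,
        y=y,
        theta=theta,
    )
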