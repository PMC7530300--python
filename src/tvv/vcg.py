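"""Vectorcardiographic reconstruction and trajectory time-quantiles.

The 3-D heart vector (X, Y, Z) is reconstructed from the eight independent
leads by the inverse Dower transformation.  For each beat, the repolarization
trajectory spans J-point + 20 ms through T-end; ``Tr(p)`` is the time (ms,
from the trajectory start) at which the cumulative chord length first reaches
p percent of the total trajectory length.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from tvv.ecg_io import LEADS8, AnnotatedEcg, BeatAnnotation

log = logging.getLogger(__name__)

P_GRID = np.arange(1, 101)

#: inverse Dower coefficients, rows X/Y/Z, columns V1..V6, I, II
_INVERSE_DOWER_V1V6_I_II = np.array([
    [-0.172, -0.074, 0.122, 0.231, 0.239, 0.194, 0.156, -0.010],
    [0.057, -0.019, -0.106, -0.022, 0.041, 0.048, -0.227, 0.887],
    [-0.229, -0.310, -0.246, -0.063, 0.055, 0.108, 0.022, 0.102],
])

# reorder columns to this package's lead order (I, II, V1..V6)
INVERSE_DOWER = _INVERSE_DOWER_V1V6_I_II[:, [6, 7, 0, 1, 2, 3, 4, 5]]

#: forward Dower lead vectors, rows I, II, V1..V6, columns X/Y/Z
DOWER_FORWARD = np.array([
    [0.632, -0.235, 0.059],
    [0.235, 1.066, -0.132],
    [-0.515, 0.157, -0.917],
    [0.044, 0.164, -1.387],
    [0.882, 0.098, -1.277],
    [1.213, 0.127, -0.601],
    [1.125, 0.127, -0.086],
    [0.831, 0.076, 0.230],
])


class TrajectoryError(ValueError):
    pass


@dataclass
class TVectorTrajectory:
    points: np.ndarray  # (n, 3) mV
    t0_ms: float        # absolute time of the first point within the record
    fs: float

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.shape[0] < 2:
            raise TrajectoryError("trajectory needs at least 2 points")

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    def chord_lengths(self) -> np.ndarray:
        return np.linalg.norm(np.diff(self.points, axis=0), axis=1)

    @property
    def total_length(self) -> float:
        return float(self.chord_lengths().sum())


def inverse_dower(lead_samples: np.ndarray) -> np.ndarray:
    """Map mV samples of (I, II, V1..V6) onto the (X, Y, Z) heart vector.

    Accepts a single 8-vector or an (n, 8) matrix; returns matching shape
    with 3 components.
    """
    arr = np.asarray(lead_samples, dtype=float)
    return arr @ INVERSE_DOWER.T


def xyz_signal(ecg: AnnotatedEcg) -> np.ndarray:
    """(n_samples, 3) heart-vector signal for a whole record."""
    assert ecg.lead_names == LEADS8
    return inverse_dower(ecg.signal)


def beat_trajectory(ecg: AnnotatedEcg, beat: BeatAnnotation,
                    xyz: np.ndarray | None = None) -> TVectorTrajectory | None:
    """Trajectory of one beat, or None if the span is degenerate."""
    if not beat.is_usable:
        return None
    start = int(round(beat.j_point + 0.020 * ecg.fs))
    stop = beat.t_end  # inclusive
    if stop - start + 1 < 2:
        log.warning("beat at q=%d excluded: trajectory span < 2 samples",
                    beat.q_on)
        return None
    if xyz is None:
        xyz = xyz_signal(ecg)
    traj = TVectorTrajectory(xyz[start:stop + 1], start * 1000.0 / ecg.fs,
                             ecg.fs)
    if traj.total_length <= 0.0:
        log.warning("beat at q=%d excluded: zero-length trajectory", beat.q_on)
        return None
    return traj


def trajectory_quantiles(traj: TVectorTrajectory,
                         p_grid: np.ndarray = P_GRID) -> np.ndarray:
    """Tr(p) in ms relative to the trajectory start, by linear interpolation
    of the cumulative chord length within the bracketing sample interval."""
    seg = traj.chord_lengths()
    total = seg.sum()
    if total <= 0.0:
        raise TrajectoryError("degenerate trajectory")
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    times_ms = np.arange(traj.n_points) * 1000.0 / traj.fs
    targets = np.asarray(p_grid, dtype=float) / 100.0 * total
    # cum is nondecreasing; np.interp handles flat segments by taking the
    # left-most time at which the target is reached only if cum is strictly
    # increasing, so collapse zero-length segments first.
    keep = np.concatenate([[True], seg > 0])
    return np.interp(targets, cum[keep], times_ms[keep])


def ecg_quantiles(ecg: AnnotatedEcg, p_grid: np.ndarray = P_GRID
                  ) -> dict[str, float] | None:
    """One quantile-table row: beat-averaged Tr(p) plus the mean RR (s).

    Returns None (with a warning) when no usable beat yields a valid
    trajectory, mirroring the exclusion of unusable ECGs.
    """
    xyz = xyz_signal(ecg)
    trs = []
    for beat in ecg.beats:
        traj = beat_trajectory(ecg, beat, xyz=xyz)
        if traj is not None:
            trs.append(trajectory_quantiles(traj, p_grid))
    if not trs:
        log.warning("ECG %s excluded: no usable beat trajectory", ecg.meta)
        return None
    tr_mean = np.mean(trs, axis=0)
    q_times = np.array([b.q_on for b in ecg.usable_beats()], dtype=float)
    rr = float(np.mean(np.diff(q_times)) / ecg.fs) if len(q_times) >= 2 else np.nan
    row: dict[str, float] = {
        "subject": ecg.meta.subject,
        "treatment": ecg.meta.treatment,
        "timepoint": ecg.meta.timepoint,
        "replicate": ecg.meta.replicate,
        "RR_s": rr,
    }
    row.update({f"Tr_{p}": v for p, v in zip(p_grid, tr_mean)})
    return row


TR_COLS = [f"Tr_{p}" for p in P_GRID]
TRC_COLS = [f"Trc_{p}" for p in P_GRID]
META_COLS = ["subject", "treatment", "timepoint", "replicate", "RR_s"]


def quantile_table(ecgs) -> pd.DataFrame:
    """Stack :func:`ecg_quantiles` rows from an iterable of records."""
    rows = [r for r in (ecg_quantiles(e) for e in ecgs) if r is not None]
    return pd.DataFrame(rows)
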