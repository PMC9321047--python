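"""Per-trajectory displacement, speed, rolling-average speed and run lengths.

At the 10 s sampling interval of the time-lapse, the "net distance
traveled in 10 s" (run length) coincides with the single-interval
Euclidean displacement, so both views are served by the same
:func:`step_displacements` series.  Gaps split a trajectory into
segments; no displacement, speed or rolling window ever spans a gap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .exceptions import ValidationError
from .trajectory_io import Trajectory

#: Rolling-average window in frames: 3 successive 10 s intervals = 30 s.
DEFAULT_SMA_WINDOW = 3

#: Run-length histogram bin width in nm.
DEFAULT_BIN_WIDTH_NM = 200.0


@dataclass
class SpeedProfile:
    """Kinematic summary of one trajectory.

    ``speeds[i]`` is the speed over the i-th consecutive observed frame
    pair; ``sma_speeds`` are rolling means over ``window`` successive
    intervals (computed per gap-free segment and concatenated), with
    ``sma_times`` the mean interval end-time of each window.  The trend is
    an ordinary least-squares line of SMA speed against time.
    """

    focus_id: str
    label: str
    step_displacements: np.ndarray  # μm per interval
    speeds: np.ndarray  # μm/s
    sma_speeds: np.ndarray  # μm/s
    sma_times: np.ndarray  # s
    trend_slope: float = float("nan")  # μm/s per s
    trend_intercept: float = float("nan")  # μm/s
    trend_r_squared: float = float("nan")
    trend_p_value: float = float("nan")
    window: int = DEFAULT_SMA_WINDOW


def step_vectors(traj: Trajectory) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Displacement vectors between consecutive observed frames.

    Returns ``(start_frames, vectors, dts)`` where ``vectors[k]`` is the
    3D displacement from frame ``start_frames[k]`` to the next frame and
    ``dts[k]`` the time difference.  Pairs spanning a gap are omitted.
    """
    obs = traj.observed
    if obs.sum() < 2:
        raise ValidationError(
            f"trajectory {traj.focus_id!r}: need >= 2 observed frames"
        )
    pair = obs[:-1] & obs[1:]
    idx = np.nonzero(pair)[0]
    if idx.size == 0:
        raise ValidationError(
            f"trajectory {traj.focus_id!r}: no consecutive observed frames"
        )
    vecs = traj.positions[idx + 1] - traj.positions[idx]
    dts = traj.times[idx + 1] - traj.times[idx]
    return idx, vecs, dts


def step_displacements(traj: Trajectory) -> np.ndarray:
    """Euclidean 3D distance (μm) per consecutive observed frame pair."""
    _, vecs, _ = step_vectors(traj)
    return np.linalg.norm(vecs, axis=1)


def speeds(traj: Trajectory) -> np.ndarray:
    """Speed (μm/s) per consecutive observed frame pair."""
    _, vecs, dts = step_vectors(traj)
    if np.any(dts <= 0):
        raise ValidationError("zero or negative time difference between frames")
    return np.linalg.norm(vecs, axis=1) / dts


def sma_speed(values: np.ndarray, window: int = DEFAULT_SMA_WINDOW) -> np.ndarray:
    """Simple moving average with stride 1 over a speed series."""
    values = np.asarray(values, dtype=float)
    if window < 1:
        raise ValidationError("window must be >= 1")
    if values.size < window:
        raise ValidationError(
            f"series of length {values.size} shorter than window {window}"
        )
    kernel = np.full(window, 1.0 / window)
    return np.convolve(values, kernel, mode="valid")


def speed_trend(
    values: np.ndarray, times: np.ndarray
) -> tuple[float, float, float, float]:
    """OLS fit of a speed series against time.

    Returns ``(slope, intercept, r_squared, p_value)``.  A negative slope
    classifies a focus as slowing; a slope near zero as static.
    """
    values = np.asarray(values, dtype=float)
    times = np.asarray(times, dtype=float)
    if values.size != times.size:
        raise ValidationError("values and times must have equal length")
    if values.size < 3:
        raise ValidationError("need >= 3 points for a trend fit")
    if np.ptp(times) == 0:
        raise ValidationError("constant time vector")
    res = stats.linregress(times, values)
    return (
        float(res.slope),
        float(res.intercept),
        float(res.rvalue**2),
        float(res.pvalue),
    )


def speed_profile(
    traj: Trajectory, window: int = DEFAULT_SMA_WINDOW
) -> SpeedProfile:
    """Full kinematic profile: displacements, speeds, SMA and trend.

    SMA windows are computed per gap-free segment (never spanning a gap)
    and concatenated.  The trend is fitted when at least 3 SMA points
    exist; otherwise the slope/intercept are NaN.
    """
    disps = step_displacements(traj)
    spds = speeds(traj)
    sma_parts: list[np.ndarray] = []
    t_parts: list[np.ndarray] = []
    for seg in traj.segments():
        n_pairs = seg.stop - seg.start - 1
        if n_pairs < window:
            continue
        seg_pos = traj.positions[seg]
        seg_t = traj.times[seg]
        seg_speed = np.linalg.norm(np.diff(seg_pos, axis=0), axis=1) / np.diff(seg_t)
        sma_parts.append(sma_speed(seg_speed, window))
        end_times = seg_t[1:]
        t_parts.append(sma_speed(end_times, window))  # mean window end-time
    sma = np.concatenate(sma_parts) if sma_parts else np.empty(0)
    sma_t = np.concatenate(t_parts) if t_parts else np.empty(0)
    prof = SpeedProfile(
        focus_id=traj.focus_id,
        label=traj.label,
        step_displacements=disps,
        speeds=spds,
        sma_speeds=sma,
        sma_times=sma_t,
        window=window,
    )
    if sma.size >= 3 and np.ptp(sma_t) > 0:
        slope, intercept, r2, p = speed_trend(sma, sma_t)
        prof.trend_slope = slope
        prof.trend_intercept = intercept
        prof.trend_r_squared = r2
        prof.trend_p_value = p
    return prof


def mean_speed(trajectories, per_focus: bool = True) -> float:
    """Average speed (μm/s) across trajectories.

    ``per_focus=True`` averages each focus first and then pools the focus
    means; ``False`` pools all intervals of all foci directly.  Both
    conventions are sensible for "average speed over the first minutes of
    appearance" and neither is privileged.
    """
    if per_focus:
        return float(np.mean([np.mean(speeds(t)) for t in trajectories]))
    return float(np.mean(np.concatenate([speeds(t) for t in trajectories])))


@dataclass
class RunLengthHistogram:
    """Distribution of net distances traveled per interval, in nm."""

    bin_edges: np.ndarray  # nm, contiguous from 0
    counts: np.ndarray
    fractions: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.counts = np.asarray(self.counts, dtype=int)
        total = self.counts.sum()
        self.fractions = (
            self.counts / total if total > 0 else np.zeros_like(self.counts, float)
        )


def run_length_histogram(
    trajectories, bin_width_nm: float = DEFAULT_BIN_WIDTH_NM
) -> RunLengthHistogram:
    """Pooled run-length histogram over all trajectories.

    Displacements (μm per interval) are converted to nm and binned into
    contiguous ``bin_width_nm``-wide bins starting at 0.
    """
    if bin_width_nm <= 0:
        raise ValidationError("bin_width_nm must be positive")
    disps_nm = np.concatenate(
        [step_displacements(t) for t in trajectories]
    ) * 1000.0
    if disps_nm.size == 0:
        raise ValidationError("no displacements to bin")
    n_bins = max(1, int(np.ceil((disps_nm.max() + 1e-12) / bin_width_nm)))
    edges = np.arange(n_bins + 1, dtype=float) * bin_width_nm
    counts, _ = np.histogram(disps_nm, bins=edges)
    return RunLengthHistogram(bin_edges=edges, counts=counts)


def plot_distance_heatmap(trajectories, path) -> None:
    """Render a per-focus distance-per-interval heatmap (foci as columns).

    Intervals spanning gaps are blank, mirroring a "no data" column for a
    focus that appears mid-movie.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n_frames = max(t.n_frames for t in trajectories)
    mat = np.full((n_frames - 1, len(trajectories)), np.nan)
    for j, traj in enumerate(trajectories):
        idx, vecs, _ = step_vectors(traj)
        mat[idx, j] = np.linalg.norm(vecs, axis=1)
    fig, ax = plt.subplots(figsize=(1 + 0.4 * len(trajectories), 6))
    im = ax.imshow(mat, aspect="auto", origin="lower", cmap="viridis")
    ax.set_xlabel("focus")
    ax.set_ylabel("interval index")
    ax.set_xticks(range(len(trajectories)))
    ax.set_xticklabels([t.focus_id for t in trajectories], rotation=90, fontsize=6)
    fig.colorbar(im, ax=ax, label="distance per interval (um)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
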