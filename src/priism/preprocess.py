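"""Input handling, interpolation, framing, mean-shifting and frame blending.

Expression time courses arrive as genes x timepoints matrices of log-scale
intensities, usually unevenly sampled.  Fourier analysis needs evenly sampled,
zero-mean input, so each series is interpolated onto a uniform grid, cut into
overlapping time frames aligned with the light/dark cycle, and mean-shifted
within each frame.  After per-frame processing the frames are blended back into
a single series with weights that favour the centre of each frame, where the
framed transform is most trustworthy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import make_interp_spline

__all__ = [
    "ExpressionMatrix",
    "TimeCourse",
    "FrameSpec",
    "FrameSet",
    "FrameLayout",
    "MeanShiftedSeries",
    "read_expression",
    "write_expression",
    "interpolate_to_grid",
    "make_frames",
    "mean_shift",
    "blend_frames",
]

_GRID_TOL = 1e-9


@dataclass
class ExpressionMatrix:
    """Log-scale expression values for a set of genes at shared timepoints.

    Parameters
    ----------
    gene_ids : list of str
        Row identifiers; must be unique.
    timepoints_h : ndarray
        Strictly increasing sampling times in hours.
    condition : str
        Condition label, e.g. ``"control"`` or ``"treatment"``.
    values : ndarray of shape (n_genes, n_timepoints)
        Log-scale expression intensities.
    """

    gene_ids: list[str]
    timepoints_h: np.ndarray
    condition: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = list(self.gene_ids)
        self.timepoints_h = np.asarray(self.timepoints_h, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if len(set(self.gene_ids)) != len(self.gene_ids):
            dupes = sorted({g for g in self.gene_ids if self.gene_ids.count(g) > 1})
            raise ValueError(f"duplicate gene ids: {dupes}")
        if self.timepoints_h.ndim != 1:
            raise ValueError("timepoints_h must be 1-D")
        diffs = np.diff(self.timepoints_h)
        if np.any(diffs <= 0):
            bad = int(np.argmax(diffs <= 0)) + 1
            raise ValueError(
                f"timepoints must be strictly increasing; violation at column "
                f"{bad} (t={self.timepoints_h[bad]:g} after "
                f"t={self.timepoints_h[bad - 1]:g})"
            )
        if self.values.shape != (len(self.gene_ids), self.timepoints_h.size):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {self.timepoints_h.size} timepoints"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def gene(self, gene_id: str) -> "TimeCourse":
        """Extract one gene's series as a :class:`TimeCourse`."""
        idx = self.gene_ids.index(gene_id)
        return TimeCourse(gene_id, self.timepoints_h.copy(), self.values[idx].copy())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=pd.Index(self.gene_ids, name="gene_id"),
            columns=self.timepoints_h,
        )


@dataclass
class TimeCourse:
    """One gene's expression series g(kT) on a uniform time grid."""

    gene_id: str
    grid_times_h: np.ndarray
    samples: np.ndarray

    def __post_init__(self) -> None:
        self.grid_times_h = np.asarray(self.grid_times_h, dtype=float)
        self.samples = np.asarray(self.samples, dtype=float)
        if self.grid_times_h.size != self.samples.size:
            raise ValueError("grid and samples length mismatch")
        if self.grid_times_h.size >= 2:
            steps = np.diff(self.grid_times_h)
            if np.ptp(steps) > _GRID_TOL:
                raise ValueError("grid spacing is not uniform")

    @property
    def K(self) -> int:
        return self.samples.size

    @property
    def T(self) -> float:
        """Sampling interval in hours."""
        if self.grid_times_h.size < 2:
            raise ValueError("sampling interval undefined for <2 samples")
        return float(self.grid_times_h[1] - self.grid_times_h[0])


@dataclass(frozen=True)
class FrameSpec:
    """One time window [start_h, end_h) on the grid (terminal frame closed)."""

    start_h: float
    end_h: float
    index: int

    def __post_init__(self) -> None:
        if self.end_h <= self.start_h:
            raise ValueError("frame end must exceed frame start")


@dataclass(frozen=True)
class FrameLayout:
    """Photoperiod-aligned framing parameters.

    The first frame may differ in length from the rest (e.g. 26 h when the
    course starts 2 h before a light/dark transition); subsequent frames start
    at each light/dark transition.  ``zt_at_t0`` is the zeitgeber time (hours
    since dawn) at the start of the course.
    """

    first_frame_h: float = 26.0
    frame_h: float = 24.0
    light_h: float = 16.0
    dark_h: float = 8.0
    zt_at_t0: float = 14.0
    edge_weight_floor: float = 0.05
    boundaries: tuple[tuple[float, float], ...] | None = None

    @property
    def photoperiod_h(self) -> float:
        return self.light_h + self.dark_h


@dataclass
class FrameSet:
    """Overlapping frames plus per-frame, per-timepoint blending weights.

    ``weights`` has shape (n_frames, n_grid); each column sums to 1 and a
    frame's weight is zero at timepoints outside it.
    """

    frames: list[FrameSpec]
    grid_times_h: np.ndarray
    weights: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.grid_times_h = np.asarray(self.grid_times_h, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        col_sums = self.weights.sum(axis=0)
        if not np.allclose(col_sums, 1.0, atol=1e-9):
            raise ValueError("blend weights must sum to 1 at every timepoint")

    def frame_indices(self, frame: FrameSpec) -> np.ndarray:
        """Grid indices of the samples belonging to ``frame``.

        Frames are half-open on the right except the terminal frame, which is
        closed, so a 24-h frame on a 2-h grid holds exactly 12 samples and the
        last grid point is still covered.
        """
        t = self.grid_times_h
        last_end = max(f.end_h for f in self.frames)
        if abs(frame.end_h - last_end) <= _GRID_TOL:
            mask = (t >= frame.start_h - _GRID_TOL) & (t <= frame.end_h + _GRID_TOL)
        else:
            mask = (t >= frame.start_h - _GRID_TOL) & (t < frame.end_h - _GRID_TOL)
        return np.nonzero(mask)[0]


@dataclass
class MeanShiftedSeries:
    """A framed series with its mean removed (so the DC Fourier bin is zero)."""

    base: TimeCourse
    removed_mean: float
    samples: np.ndarray

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.size and abs(self.samples.mean()) > 1e-9:
            raise ValueError("mean-shifted samples must have zero mean")


def read_expression(path, condition: str) -> ExpressionMatrix:
    """Read a tab-delimited genes x timepoints matrix.

    The header row gives timepoints in hours; the first column holds gene ids.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    try:
        times = np.array([float(c) for c in df.columns])
    except ValueError as exc:
        raise ValueError(f"non-numeric timepoint in header: {exc}") from exc
    values = np.empty(df.shape, dtype=float)
    raw = df.to_numpy()
    for i in range(df.shape[0]):
        for j in range(df.shape[1]):
            try:
                values[i, j] = float(raw[i, j])
            except (TypeError, ValueError):
                raise ValueError(
                    f"non-numeric value at row {df.index[i]!r}, "
                    f"column t={df.columns[j]}"
                ) from None
    return ExpressionMatrix(
        gene_ids=[str(g) for g in df.index],
        timepoints_h=times,
        condition=condition,
        values=values,
    )


def write_expression(path, m: ExpressionMatrix) -> None:
    """Write a matrix in the same tab-delimited dialect ``read_expression`` reads."""
    df = m.to_frame()
    df.columns = [format(t, "g") for t in m.timepoints_h]
    # %.17g keeps doubles bit-exact across a write/read round trip
    df.to_csv(path, sep="\t", float_format="%.17g")


def interpolate_to_grid(
    m: ExpressionMatrix, grid_step_h: float, spline_degree: int = 3
) -> ExpressionMatrix:
    """Resample every gene onto a uniform grid via B-spline interpolation.

    The grid runs from the first to the last input timepoint in steps of
    ``grid_step_h``.  An interpolating cubic B-spline is fitted per gene, so
    data already on the grid are reproduced (to spline tolerance) and the
    operation is deterministic.
    """
    if grid_step_h <= 0:
        raise ValueError("grid_step_h must be positive")
    if m.timepoints_h.size < spline_degree + 1:
        raise ValueError(
            f"need at least {spline_degree + 1} timepoints for a degree-"
            f"{spline_degree} spline, got {m.timepoints_h.size}"
        )
    t0, t1 = m.timepoints_h[0], m.timepoints_h[-1]
    n_steps = int(round((t1 - t0) / grid_step_h))
    grid = t0 + grid_step_h * np.arange(n_steps + 1)
    grid = grid[grid <= t1 + _GRID_TOL]
    out = np.empty((m.n_genes, grid.size))
    for i in range(m.n_genes):
        spline = make_interp_spline(m.timepoints_h, m.values[i], k=spline_degree)
        out[i] = spline(grid)
    return ExpressionMatrix(list(m.gene_ids), grid, m.condition, out)


def make_frames(grid_times_h: np.ndarray, layout: FrameLayout) -> FrameSet:
    """Segment a uniform grid into overlapping photoperiod-aligned frames.

    Frame 1 spans the first ``first_frame_h`` hours.  Every later frame is a
    ``frame_h``-hour window starting at a light/dark transition and ending on
    or before the grid end; a window that ends exactly where frame 1 ends is
    dropped as redundant.  Blending weights are triangular (peak at the frame
    centre, floor ``edge_weight_floor`` at the edges) and renormalized to sum
    to one per timepoint.
    """
    grid = np.asarray(grid_times_h, dtype=float)
    t_start, t_end = grid[0], grid[-1]
    if layout.boundaries is not None:
        bounds = [tuple(map(float, b)) for b in layout.boundaries]
    else:
        if t_end - t_start < layout.first_frame_h - _GRID_TOL:
            raise ValueError("grid shorter than the first frame")
        bounds = [(t_start, t_start + layout.first_frame_h)]
        first_end = bounds[0][1]
        for trans in _light_dark_transitions(t_start, t_end, layout):
            end = trans + layout.frame_h
            if trans <= t_start + _GRID_TOL or end > t_end + _GRID_TOL:
                continue
            if abs(end - first_end) <= _GRID_TOL:  # duplicate of frame 1's window
                continue
            bounds.append((trans, end))
        bounds.sort()
    frames = [FrameSpec(s, e, i) for i, (s, e) in enumerate(bounds)]
    weights = _triangular_weights(grid, frames, layout.edge_weight_floor)
    return FrameSet(frames, grid, weights)


def _light_dark_transitions(t_start: float, t_end: float, layout: FrameLayout):
    """Times (hours from course start) of every dawn and dusk in the course."""
    period = layout.photoperiod_h
    # zeitgeber time zt: dawn at zt=0, dusk at zt=light_h (mod photoperiod)
    transitions = []
    for zt_event in (0.0, layout.light_h):
        # earliest t >= t_start with (zt_at_t0 + t - t_start) % period == zt_event
        offset = (zt_event - layout.zt_at_t0) % period
        t = t_start + offset
        while t <= t_end + _GRID_TOL:
            transitions.append(t)
            t += period
    return sorted(transitions)


def _triangular_weights(
    grid: np.ndarray, frames: list[FrameSpec], floor: float
) -> np.ndarray:
    last_end = max(f.end_h for f in frames)
    w = np.zeros((len(frames), grid.size))
    for i, f in enumerate(frames):
        terminal = abs(f.end_h - last_end) <= _GRID_TOL
        if terminal:
            inside = (grid >= f.start_h - _GRID_TOL) & (grid <= f.end_h + _GRID_TOL)
        else:
            inside = (grid >= f.start_h - _GRID_TOL) & (grid < f.end_h - _GRID_TOL)
        centre = 0.5 * (f.start_h + f.end_h)
        half = 0.5 * (f.end_h - f.start_h)
        tri = 1.0 - np.abs(grid - centre) / half
        w[i, inside] = np.maximum(tri[inside], floor)
    col = w.sum(axis=0)
    if np.any(col <= 0):
        gaps = grid[col <= 0]
        raise ValueError(f"frames leave grid timepoints uncovered: {gaps}")
    return w / col


def mean_shift(tc: TimeCourse) -> MeanShiftedSeries:
    """Shift a framed series to zero mean, recording the removed mean.

    Zeroing the mean removes the dominant zero-frequency peak from the
    spectrum so it cannot mask the genuinely dominant oscillation; the mean is
    restored after filtering, split across components in proportion to band
    power.
    """
    if tc.samples.size == 0:
        raise ValueError("cannot mean-shift an empty series")
    mu = float(tc.samples.mean())
    return MeanShiftedSeries(base=tc, removed_mean=mu, samples=tc.samples - mu)


def blend_frames(
    per_frame_series: dict[int, np.ndarray], fs: FrameSet
) -> TimeCourse:
    """Merge per-frame series into one full-grid series by weighted averaging."""
    out = np.zeros(fs.grid_times_h.size)
    for f in fs.frames:
        if f.index not in per_frame_series:
            raise ValueError(f"missing series for frame {f.index}")
        idx = fs.frame_indices(f)
        series = np.asarray(per_frame_series[f.index], dtype=float)
        if series.size != idx.size:
            raise ValueError(
                f"frame {f.index} series length {series.size} != {idx.size}"
            )
        out[idx] += fs.weights[f.index, idx] * series
    return TimeCourse("blended", fs.grid_times_h.copy(), out)
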