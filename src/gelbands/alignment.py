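"""Two-stage lane alignment anchored on synthetic-standard (SS) bands.

Gel electrophoresis distorts band positions in two ways: smooth
within-gel curvature ("smile") that varies with lane position, and
between-gel shifts/stretches of the whole migration axis.  The standard
mixture loaded in several lanes of every gel (including the outermost
lanes) provides anchors against which both are corrected:

1. *Within-gel correction* -- each SS band's displacement from the gel-mean
   position is fitted as a polynomial in lane index; every lane is
   resampled by the displacement field interpolated across band positions.
2. *Between-gel alignment* -- each block of data bounded by SS bands is
   stretched or shrunk by piecewise linear interpolation so the anchors
   land on the global (all-gel) mean SS positions, and the lane is
   resampled onto the canonical Rf grid of 1001 points (Rf = 0 to 1 in
   steps of 0.001).

Aligned lanes are then truncated to the 731 grid points covering
Rf 0.09-0.82 (the gel extremes are too variable to retain) and min-max
scaled to [0, 1] to mitigate between-gel intensity variance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from scipy.interpolate import interp1d

from .lane_io import LaneTrace

#: canonical Rf grid: index i <-> Rf = i / (GRID_SIZE - 1)
GRID_SIZE = 1001
#: closed truncation window on the Rf scale
TRUNCATION_WINDOW = (0.09, 0.82)
#: grid indices kept by truncation (90 .. 820 inclusive -> 731 points)
TRUNCATION_SLICE = slice(90, 821)


@dataclass
class SSAnchorSet:
    """Detected synthetic-standard band positions for one gel.

    ``positions[i, k]`` is the position of SS band *k* in usable SS lane
    *i*, on the lane's normalized 0-1 pixel coordinate.  Bands are matched
    to the reference ordering by rank (k-th peak <-> k-th SS band).
    """

    gel_id: str
    lane_indices: np.ndarray  # usable SS lane indices on the gel
    positions: np.ndarray  # (n_usable_ss_lanes, expected_n)
    flagged_lanes: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, float))
        self.lane_indices = np.asarray(self.lane_indices, int)
        if np.any(np.diff(self.positions, axis=1) <= 0):
            raise ValueError(f"anchors must be strictly increasing within each SS lane ({self.gel_id})")

    @property
    def n_bands(self) -> int:
        return self.positions.shape[1]

    def gel_means(self) -> np.ndarray:
        """Gel-mean position of each SS band."""
        return self.positions.mean(axis=0)


@dataclass
class AlignedLane:
    """A lane on the canonical Rf grid (full 1001 or truncated 731 view)."""

    values: np.ndarray
    gel_id: str
    lane_index: int
    sample_id: str
    replicate_id: str
    group: str
    is_ss: bool = False
    channel: str = "universal"
    rf_start: float = 0.0
    scaled: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    @property
    def grid_step(self) -> float:
        return 1.0 / (GRID_SIZE - 1)

    @property
    def rf_axis(self) -> np.ndarray:
        n = self.values.size
        return self.rf_start + np.arange(n) * self.grid_step

    @classmethod
    def from_trace(cls, values: np.ndarray, trace: LaneTrace, **kw) -> "AlignedLane":
        return cls(
            values=values,
            gel_id=trace.gel_id,
            lane_index=trace.lane_index,
            sample_id=trace.sample_id,
            replicate_id=trace.replicate_id,
            group=trace.group,
            is_ss=trace.is_ss,
            channel=trace.channel,
            **kw,
        )


def _refine_peak(values: np.ndarray, idx: int) -> float:
    """Sub-pixel apex via a parabola through the peak and its neighbours."""
    if idx <= 0 or idx >= values.size - 1:
        return float(idx)
    y0, y1, y2 = values[idx - 1], values[idx], values[idx + 1]
    denom = y0 - 2 * y1 + y2
    if denom >= 0:
        return float(idx)
    return float(idx + 0.5 * (y0 - y2) / denom)


def detect_ss_anchors(ss_traces: list[LaneTrace], expected_n: int) -> SSAnchorSet:
    """Peak-pick the SS band maxima of one gel's standard lanes.

    Each usable SS lane contributes exactly ``expected_n`` anchors matched
    to the reference SS ordering by rank.  A lane with a deviant peak
    count is flagged and excluded; fewer than two usable SS lanes make
    the gel unalignable.
    """
    if len(ss_traces) < 2:
        raise ValueError("at least two SS lanes are required to align a gel")
    gel_id = ss_traces[0].gel_id
    rows, lane_idx, flagged = [], [], []
    for t in ss_traces:
        v = t.intensities
        span = v.max() - v.min()
        if span <= 0:
            flagged.append(t.lane_index)
            continue
        scaled = (v - v.min()) / span
        distance = max(3, int(0.4 * v.size / expected_n))
        idx, _ = signal.find_peaks(scaled, height=0.25, distance=distance)
        if idx.size != expected_n:
            flagged.append(t.lane_index)
            continue
        pos = np.array([_refine_peak(scaled, i) for i in idx]) / (v.size - 1)
        rows.append(pos)
        lane_idx.append(t.lane_index)
    if len(rows) < 2:
        raise ValueError(
            f"gel {gel_id!r} is unalignable: only {len(rows)} usable SS lane(s) "
            f"(flagged lanes: {flagged})"
        )
    if flagged:
        warnings.warn(f"gel {gel_id!r}: flagged SS lanes {flagged}", stacklevel=2)
    return SSAnchorSet(
        gel_id=gel_id,
        lane_indices=np.array(lane_idx),
        positions=np.vstack(rows),
        flagged_lanes=flagged,
    )


def within_gel_correct(
    traces: list[LaneTrace], anchors: SSAnchorSet, degree: int = 2
) -> list[LaneTrace]:
    """Remove within-gel band curvature using the SS anchor displacements.

    For each SS band, its displacement from the gel-mean position is
    fitted as a degree-``degree`` polynomial in lane index; the
    displacement field at an arbitrary (lane, position) is linearly
    interpolated across the SS band positions (constant beyond the
    outermost anchors) and subtracted by resampling the lane.
    """
    n_ss = anchors.positions.shape[0]
    if n_ss < degree + 1:
        new_degree = n_ss - 1
        warnings.warn(
            f"gel {anchors.gel_id!r}: only {n_ss} SS lanes; reducing polynomial "
            f"degree {degree} -> {new_degree}",
            stacklevel=2,
        )
        degree = new_degree
    means = anchors.gel_means()
    disp = anchors.positions - means[None, :]  # (n_ss, n_bands)
    coeffs = [
        np.polyfit(anchors.lane_indices, disp[:, k], degree)
        for k in range(anchors.n_bands)
    ]

    corrected = []
    for t in traces:
        d_at_lane = np.array([np.polyval(c, t.lane_index) for c in coeffs])
        x = np.linspace(0.0, 1.0, t.n_pixels)
        # np.interp holds the end values constant outside the anchor range
        shift = np.interp(x, means, d_at_lane)
        src = x + shift
        if np.any(np.diff(src) <= 0):
            raise ValueError(
                f"non-monotone within-gel warp on gel {t.gel_id!r} lane {t.lane_index}"
            )
        values = np.interp(src, x, t.intensities)
        corrected.append(
            LaneTrace(
                intensities=np.clip(values, 0.0, None),
                gel_id=t.gel_id,
                lane_index=t.lane_index,
                sample_id=t.sample_id,
                replicate_id=t.replicate_id,
                group=t.group,
                is_ss=t.is_ss,
                channel=t.channel,
            )
        )
    return corrected


def between_gel_align(
    trace: LaneTrace,
    lane_anchors: np.ndarray,
    global_anchor_means: np.ndarray,
) -> AlignedLane:
    """Warp one lane onto the canonical grid via its gel's SS anchors.

    Each block of data bounded by SS bands is linearly stretched or
    shrunk so the bounding anchors land on the global mean SS positions;
    beyond the outermost anchors the adjacent block's linear map is
    extended.  The result is resampled onto the 1001-point Rf grid.
    """
    lane_anchors = np.asarray(lane_anchors, float)
    global_anchor_means = np.asarray(global_anchor_means, float)
    if lane_anchors.shape != global_anchor_means.shape:
        raise ValueError("anchor vectors must have matching shapes")
    if np.any(np.diff(lane_anchors) <= 0) or np.any(np.diff(global_anchor_means) <= 0):
        raise ValueError(
            f"non-monotone warp (crossing anchors) on gel {trace.gel_id!r} "
            f"lane {trace.lane_index}"
        )
    # inverse warp: for each target Rf, the source position on this gel
    inv = interp1d(
        global_anchor_means,
        lane_anchors,
        kind="linear",
        fill_value="extrapolate",
        assume_sorted=True,
    )
    grid = np.linspace(0.0, 1.0, GRID_SIZE)
    src = inv(grid)
    if np.any(np.diff(src) <= 0):
        raise ValueError(
            f"non-monotone composite warp on gel {trace.gel_id!r} lane {trace.lane_index}"
        )
    x = np.linspace(0.0, 1.0, trace.n_pixels)
    values = np.interp(src, x, trace.intensities)
    return AlignedLane.from_trace(np.clip(values, 0.0, None), trace)


def truncate_and_scale(lane: AlignedLane) -> AlignedLane:
    """Truncate a full-grid lane to Rf 0.09-0.82 and min-max scale to [0, 1]."""
    if lane.values.size != GRID_SIZE:
        raise ValueError(f"expected a full {GRID_SIZE}-point lane, got {lane.values.size}")
    v = lane.values[TRUNCATION_SLICE]
    span = v.max() - v.min()
    if span <= 0:
        raise ValueError(
            f"constant truncated lane {lane.gel_id}:{lane.lane_index}; scaling undefined"
        )
    out = AlignedLane(
        values=(v - v.min()) / span,
        gel_id=lane.gel_id,
        lane_index=lane.lane_index,
        sample_id=lane.sample_id,
        replicate_id=lane.replicate_id,
        group=lane.group,
        is_ss=lane.is_ss,
        channel=lane.channel,
        rf_start=TRUNCATION_WINDOW[0],
        scaled=True,
    )
    return out


def align_experiment(
    traces: list[LaneTrace],
    expected_ss_bands: int,
    degree: int = 2,
) -> tuple[list[AlignedLane], dict]:
    """Full two-stage alignment of a multi-gel experiment.

    Returns the truncated, scaled lanes (samples and SS alike, in input
    order per gel) plus diagnostics: per-gel anchor sets and the global
    anchor means on the Rf scale.
    """
    by_gel: dict[str, list[LaneTrace]] = {}
    for t in traces:
        by_gel.setdefault(t.gel_id, []).append(t)

    anchor_sets: dict[str, SSAnchorSet] = {}
    corrected: dict[str, list[LaneTrace]] = {}
    for gel_id, gel_traces in by_gel.items():
        ss = [t for t in gel_traces if t.is_ss]
        anchors = detect_ss_anchors(ss, expected_ss_bands)
        corrected[gel_id] = within_gel_correct(gel_traces, anchors, degree=degree)
        anchor_sets[gel_id] = anchors

    counts = {a.n_bands for a in anchor_sets.values()}
    if len(counts) != 1:
        raise ValueError(f"inconsistent SS band counts across gels: {counts}")
    global_means = np.mean([a.gel_means() for a in anchor_sets.values()], axis=0)

    aligned: list[AlignedLane] = []
    rejected = []
    for gel_id, gel_traces in corrected.items():
        gel_anchor_means = anchor_sets[gel_id].gel_means()
        for t in gel_traces:
            full = between_gel_align(t, gel_anchor_means, global_means)
            try:
                aligned.append(truncate_and_scale(full))
            except ValueError as exc:
                rejected.append({"gel_id": gel_id, "lane_index": t.lane_index, "reason": str(exc)})
                warnings.warn(str(exc), stacklevel=2)
    diagnostics = {
        "anchor_sets": anchor_sets,
        "global_anchor_means": global_means,
        "rejected": rejected,
    }
    return aligned, diagnostics
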