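"""Gel-image and lane-trace input/output.

A DGGE gel image is stored with the migration (Rf) axis along image rows
(Rf increases with row index) and lanes along image columns.  Each lane is
reduced to a densitometric trace -- the mean grey intensity across the
lane's column span, one value per row -- which is the unit every
downstream step (alignment, band picking, chemometrics) consumes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import tifffile
from PIL import Image

#: metadata columns every lane table must carry, in canonical order
METADATA_COLUMNS = [
    "gel_id",
    "lane_index",
    "sample_id",
    "replicate_id",
    "group",
    "is_SS",
    "channel",
]


@dataclass
class LaneTrace:
    """One lane's raw intensity profile plus its provenance.

    ``intensities`` is on the raw pixel grey scale, one value per image row
    (more than 1000 rows for a full-length gel).  ``is_ss`` marks lanes
    loaded with the synthetic standard used as alignment anchors.
    """

    intensities: np.ndarray
    gel_id: str
    lane_index: int
    sample_id: str
    replicate_id: str
    group: str
    is_ss: bool = False
    channel: str = "universal"

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 1:
            raise ValueError("lane trace must be a 1-D vector")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError(f"non-finite intensities in lane {self.gel_id}/{self.lane_index}")
        if np.any(self.intensities < 0):
            raise ValueError(f"negative intensities in lane {self.gel_id}/{self.lane_index}")

    @property
    def n_pixels(self) -> int:
        return self.intensities.size

    def metadata(self) -> dict:
        return {
            "gel_id": self.gel_id,
            "lane_index": self.lane_index,
            "sample_id": self.sample_id,
            "replicate_id": self.replicate_id,
            "group": self.group,
            "is_SS": self.is_ss,
            "channel": self.channel,
        }


def write_gel_image(path, image: np.ndarray) -> None:
    """Write a 16-bit grayscale gel image as TIFF or PNG (by extension)."""
    image = np.ascontiguousarray(image, dtype=np.uint16)
    path = str(path)
    if path.lower().endswith((".tif", ".tiff")):
        tifffile.imwrite(path, image)
    elif path.lower().endswith(".png"):
        Image.fromarray(image).save(path)
    else:
        raise ValueError(f"unsupported image format: {path}")


def read_gel_image(path) -> np.ndarray:
    path = str(path)
    if path.lower().endswith((".tif", ".tiff")):
        image = tifffile.imread(path)
    elif path.lower().endswith(".png"):
        image = np.asarray(Image.open(path))
    else:
        raise ValueError(f"unsupported image format: {path}")
    return np.asarray(image, dtype=np.uint16)


def write_metadata(path, metadata: pd.DataFrame) -> None:
    metadata.to_csv(path, index=False)


def read_metadata(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"metadata is missing columns: {missing}")
    return df


def write_traces(path, traces: list[LaneTrace]) -> None:
    """Write traces as a wide CSV: first column rf-index, one column per lane."""
    n = traces[0].n_pixels
    if any(t.n_pixels != n for t in traces):
        raise ValueError("all traces in one file must share a pixel count")
    cols = {"rf_index": np.arange(n)}
    for t in traces:
        cols[f"{t.gel_id}:{t.lane_index}"] = t.intensities
    pd.DataFrame(cols).to_csv(path, index=False)


def read_traces(path, metadata: pd.DataFrame) -> list[LaneTrace]:
    df = pd.read_csv(path)
    traces = []
    for _, row in metadata.iterrows():
        key = f"{row.gel_id}:{row.lane_index}"
        if key not in df.columns:
            raise ValueError(f"trace column {key!r} missing from {path}")
        traces.append(
            LaneTrace(
                intensities=df[key].to_numpy(float),
                gel_id=str(row.gel_id),
                lane_index=int(row.lane_index),
                sample_id=str(row.sample_id),
                replicate_id=str(row.replicate_id),
                group=str(row.group),
                is_ss=bool(row.is_SS),
                channel=str(row.channel),
            )
        )
    return traces


def extract_lanes(image: np.ndarray, metadata: pd.DataFrame) -> list[LaneTrace]:
    """Reduce a gel image to one densitometric trace per metadata row.

    ``metadata`` must carry ``col_start``/``col_end`` (half-open column
    spans) alongside the canonical columns.  The trace is the mean grey
    value across the span, per image row, preserving metadata row order.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("gel image must be 2-D grayscale")
    for col in ("col_start", "col_end"):
        if col not in metadata.columns:
            raise ValueError(f"metadata lacks lane span column {col!r}")

    spans = [(int(r.col_start), int(r.col_end)) for _, r in metadata.iterrows()]
    for c0, c1 in spans:
        if c0 < 0 or c1 > image.shape[1] or c1 <= c0:
            raise ValueError(
                f"lane span [{c0},{c1}) outside image width {image.shape[1]}"
            )
    for (s0, e0), (s1, e1) in zip(sorted(spans), sorted(spans)[1:]):
        if s1 < e0:
            raise ValueError(f"overlapping lane spans: [{s0},{e0}) and [{s1},{e1})")

    traces = []
    for _, row in metadata.iterrows():
        c0, c1 = int(row.col_start), int(row.col_end)
        traces.append(
            LaneTrace(
                intensities=image[:, c0:c1].mean(axis=1),
                gel_id=str(row.gel_id),
                lane_index=int(row.lane_index),
                sample_id=str(row.sample_id),
                replicate_id=str(row.replicate_id),
                group=str(row.group),
                is_ss=bool(row.is_SS),
                channel=str(row.channel),
            )
        )
    return traces


@dataclass
class QualityCriteria:
    """Deterministic stand-in for discarding 'visually poor quality' lanes.

    min_dynamic_range is on the raw grey scale; max_saturated_fraction is
    the tolerated fraction of pixels at the 16-bit ceiling; SS lanes must
    additionally show ``min_ss_anchors`` detectable standard bands.
    """

    min_dynamic_range: float = 200.0
    max_saturated_fraction: float = 0.05
    min_ss_anchors: int = 12
    expected_ss_bands: int = 24
    saturation_level: float = 65535.0


def quality_filter(
    traces: list[LaneTrace], criteria: QualityCriteria | None = None
) -> tuple[list[LaneTrace], pd.DataFrame]:
    """Apply the lane quality criteria; return kept lanes + a rejection log.

    Every rejection is logged with its reason.  If all lanes of a sample
    are rejected a warning names the sample (it is dropped downstream).
    """
    from .bands import _find_scaled_peaks  # local import to avoid a cycle

    criteria = criteria or QualityCriteria()
    kept: list[LaneTrace] = []
    log_rows = []
    for t in traces:
        reason = None
        rng_span = float(t.intensities.max() - t.intensities.min())
        sat = float(np.mean(t.intensities >= criteria.saturation_level))
        if rng_span < criteria.min_dynamic_range:
            reason = "dynamic range"
        elif sat > criteria.max_saturated_fraction:
            reason = "saturation"
        elif t.is_ss:
            n_anchors = _find_scaled_peaks(t.intensities, criteria.expected_ss_bands).size
            if n_anchors < criteria.min_ss_anchors:
                reason = "SS anchors"
        if reason is None:
            kept.append(t)
        else:
            log_rows.append({**t.metadata(), "reason": reason})

    log = pd.DataFrame(log_rows, columns=METADATA_COLUMNS + ["reason"])
    sample_ids = {t.sample_id for t in traces if not t.is_ss}
    surviving = {t.sample_id for t in kept if not t.is_ss}
    for sample in sorted(sample_ids - surviving):
        warnings.warn(f"all lanes of sample {sample!r} were rejected", stacklevel=2)
    return kept, log


def traces_to_metadata(traces: list[LaneTrace]) -> pd.DataFrame:
    return pd.DataFrame([t.metadata() for t in traces], columns=METADATA_COLUMNS)
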