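"""Synthetic DGGE cohort and gel generator.

Generates a three-group faecal-fingerprint study entirely in silico: a
latent band atlas (the pool of distinguishable 16S-V3 sequence variants,
each migrating to a fixed Rf), per-subject band sets with group-structured
presence and log-normal relative abundances, duplicate lanes per subject
spread over several gels, synthetic-standard (SS) lanes in at least four
positions per gel including the outermost lanes, and per-gel positional
distortions (global shift, stretch, and lane-dependent "smile" curvature)
that the alignment stage must undo.

The latent truth (each subject's band positions and abundances) is kept
alongside the rendered images so that recovery of band counts, diversity
and similarity statistics by the analysis pipeline can be tested against
known ground truth.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .lane_io import LaneTrace, METADATA_COLUMNS

#: planted bands are floored at this fraction of the lane's tallest band so
#: every planted band clears the detection threshold after 0-1 scaling
ABUNDANCE_FLOOR_RATIO = 0.03


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpeciesPool:
    """Latent band atlas: every distinguishable phylotype's Rf position."""

    band_rfs: np.ndarray
    labels: tuple[str, ...]
    min_spacing: float

    def __post_init__(self) -> None:
        rfs = np.asarray(self.band_rfs, float)
        object.__setattr__(self, "band_rfs", rfs)
        if np.any(np.diff(rfs) <= 0):
            raise ValueError("pool band positions must be strictly increasing")
        if rfs.size > 1 and np.min(np.diff(rfs)) < self.min_spacing - 1e-12:
            raise ValueError(
                f"pool too dense: adjacent spacing {np.min(np.diff(rfs)):.4f} "
                f"< min_spacing {self.min_spacing}"
            )

    def __len__(self) -> int:
        return self.band_rfs.size


@dataclass(frozen=True)
class GroupPreset:
    """Calibrated generator parameters for one subject group."""

    name: str
    n_subjects: int
    band_count_mean: float
    band_count_sd: float
    core_size: int
    accessory_pool_size: int
    intensity_spread: float  # log-scale SD of relative abundances
    shannon_target: float
    dice_target: float  # percent

    def __post_init__(self) -> None:
        if self.core_size > self.band_count_mean:
            raise ValueError(f"{self.name}: core_size exceeds band_count_mean")
        for f in ("n_subjects", "band_count_mean", "band_count_sd", "core_size",
                  "accessory_pool_size", "intensity_spread"):
            if getattr(self, f) < 0:
                raise ValueError(f"{self.name}: {f} must be non-negative")


@dataclass(frozen=True)
class ChannelDesign:
    """Structural layout of a channel's band atlas.

    ``marker_rfs`` are fixed positions planted into the reference group's
    core only -- the discriminant bands the loading analysis should
    recover.  ``shared_core_size`` bands are common to all groups; the two
    patient groups' extra core bands are nested (the smaller patient core
    is a subset of the larger), so the patient groups remain mutually
    confusable while both differ from the reference group.
    """

    channel: str = "universal"
    window: tuple[float, float] = (0.095, 0.815)
    min_spacing: float = 0.0095
    position_jitter: float = 0.0003
    shared_core_size: int = 20
    marker_rfs: tuple[float, ...] = ()
    #: log-abundance offset of marker bands in reference-group subjects;
    #: makes the group-defining bands prominent, as dominant community
    #: members are in real fingerprints
    marker_boost: float = 0.0
    reference_group: str = "control"


@dataclass
class SubjectProfile:
    """A subject's latent band set: positions and relative abundances."""

    subject_id: str
    group: str
    rfs: np.ndarray
    abundances: np.ndarray
    channel: str = "universal"

    def __post_init__(self) -> None:
        self.rfs = np.asarray(self.rfs, float)
        self.abundances = np.asarray(self.abundances, float)
        if np.any(np.diff(self.rfs) <= 0):
            raise ValueError(f"{self.subject_id}: band rfs must be strictly increasing")
        if np.any(self.abundances <= 0):
            raise ValueError(f"{self.subject_id}: abundances must be positive")
        if abs(self.abundances.sum() - 1.0) > 1e-9:
            raise ValueError(f"{self.subject_id}: abundances must sum to 1")

    @property
    def n_bands(self) -> int:
        return self.rfs.size

    def shannon(self) -> float:
        p = self.abundances
        return float(-(p * np.log(p)).sum())


@dataclass(frozen=True)
class SlotAssignment:
    sample_id: str
    replicate_id: str
    group: str
    is_ss: bool = False


@dataclass
class GelLayout:
    """One gel: ordered lane slots, SS positions, distortion parameters."""

    gel_id: str
    slots: list[SlotAssignment]
    shift: float = 0.0
    stretch: float = 0.0
    smile: float = 0.0
    noise_sd: float = 0.002
    n_pixels: int = 1100

    def __post_init__(self) -> None:
        ss = self.ss_slot_indices
        if len(ss) < 4:
            raise ValueError(f"{self.gel_id}: at least 4 SS slots are required")
        if 0 not in ss or (len(self.slots) - 1) not in ss:
            raise ValueError(f"{self.gel_id}: SS must occupy both outermost lanes")

    @property
    def n_lanes(self) -> int:
        return len(self.slots)

    @property
    def ss_slot_indices(self) -> list[int]:
        return [i for i, s in enumerate(self.slots) if s.is_ss]

    def warp(self, rf: float | np.ndarray, lane_index: int) -> np.ndarray:
        """Distorted position of a band planted at ``rf`` in ``lane_index``."""
        u = 2.0 * lane_index / max(self.n_lanes - 1, 1) - 1.0  # -1 .. 1 across gel
        return rf + self.shift + self.stretch * (np.asarray(rf) - 0.5) + self.smile * u * u


@dataclass(frozen=True)
class RenderParams:
    """Physics of lane rendering on the raw pixel scale."""

    n_pixels: int = 1100
    band_sigma: float = 0.0025  # Gaussian band width, Rf units
    baseline: float = 0.02  # flat background, fraction of amplitude scale
    amp_scale: float = 30000.0  # grey value of the tallest band
    brightness_jitter: float = 0.2  # +/- fractional per-lane brightness
    resolvable_spacing: float = 0.005


# ---------------------------------------------------------------------------
# band atlas construction
# ---------------------------------------------------------------------------

def _build_slots(design: ChannelDesign, rng: np.random.Generator) -> np.ndarray:
    """Near-regular grid of band positions with fixed marker slots.

    All slots are at least ``min_spacing`` apart, so any subset is a valid
    (resolvable, non-cross-matching) band universe.
    """
    lo, hi = design.window
    if not (0.0 < lo < hi < 1.0):
        raise ValueError("atlas window must lie inside (0, 1)")
    fixed = sorted(design.marker_rfs)
    if any(not lo < m < hi for m in fixed):
        raise ValueError("marker rfs must lie inside the atlas window")
    bounds = [lo, *fixed, hi]
    step_needed = design.min_spacing + 2 * design.position_jitter
    slots = [np.asarray(bounds)]
    for a, b in zip(bounds, bounds[1:]):
        n_int = int(math.floor((b - a) / step_needed)) - 1
        if n_int > 0:
            xs = a + (b - a) / (n_int + 1) * np.arange(1, n_int + 1)
            xs = xs + rng.uniform(-design.position_jitter, design.position_jitter, n_int)
            slots.append(xs)
    out = np.sort(np.concatenate(slots))
    return out


def build_band_atlas(
    presets: list[GroupPreset],
    design: ChannelDesign,
    seed,
) -> tuple[SpeciesPool, dict[str, dict[str, np.ndarray]]]:
    """Construct the latent atlas and each group's core/accessory indices.

    Returns the pool plus, per group, the index arrays ``core`` and
    ``accessory`` into ``pool.band_rfs``.
    """
    rng = np.random.default_rng(seed)
    slots = _build_slots(design, rng)
    n = slots.size
    labels = tuple(f"{design.channel}_b{i:03d}" for i in range(n))
    pool = SpeciesPool(band_rfs=slots, labels=labels, min_spacing=design.min_spacing)

    marker_idx = np.array(
        [int(np.argmin(np.abs(slots - m))) for m in design.marker_rfs], dtype=int
    )
    by_name = {p.name: p for p in presets}
    if design.reference_group not in by_name:
        raise ValueError(f"no preset for reference group {design.reference_group!r}")
    ref = by_name[design.reference_group]
    others = sorted(
        (p for p in presets if p.name != design.reference_group),
        key=lambda p: p.core_size,
    )

    non_marker = np.setdiff1d(np.arange(n), marker_idx)
    s = design.shared_core_size
    if s > non_marker.size:
        raise ValueError(
            f"atlas holds only {n} slots at spacing {design.min_spacing}; "
            f"cannot place a shared core of {s}"
        )
    shared = non_marker[np.round(np.linspace(0, non_marker.size - 1, s)).astype(int)]
    remaining = np.setdiff1d(non_marker, shared)
    rng.shuffle(remaining)
    remaining = list(remaining)

    def take(k: int) -> np.ndarray:
        if k > len(remaining):
            raise ValueError(
                f"atlas exhausted ({n} slots at spacing {design.min_spacing}): "
                f"needed {k} more core slots"
            )
        out = [remaining.pop() for _ in range(k)]
        return np.asarray(out, dtype=int)

    cores: dict[str, np.ndarray] = {}
    n_ref_extra = ref.core_size - s - marker_idx.size
    if n_ref_extra < 0:
        raise ValueError("reference core smaller than shared core + markers")
    cores[ref.name] = np.sort(np.concatenate([shared, marker_idx, take(n_ref_extra)]))

    prev = shared
    for p in others:
        extra = p.core_size - prev.size if p.core_size > prev.size else 0
        core = np.sort(np.concatenate([prev, take(extra)])) if extra else np.sort(prev[: p.core_size])
        cores[p.name] = core
        prev = core

    roles: dict[str, dict[str, np.ndarray]] = {}
    for p in presets:
        candidates = np.setdiff1d(np.arange(n), cores[p.name])
        if p.name != design.reference_group:
            # marker bands stay exclusive to the reference group
            candidates = np.setdiff1d(candidates, marker_idx)
        if p.accessory_pool_size > candidates.size:
            raise ValueError(
                f"{p.name}: accessory pool of {p.accessory_pool_size} exceeds the "
                f"{candidates.size} free slots (atlas density {n} slots / "
                f"{design.window[1] - design.window[0]:.2f} Rf at spacing {design.min_spacing})"
            )
        accessory = rng.choice(candidates, size=p.accessory_pool_size, replace=False)
        roles[p.name] = {"core": cores[p.name], "accessory": np.sort(accessory)}
    return pool, roles


# ---------------------------------------------------------------------------
# cohort sampling
# ---------------------------------------------------------------------------

def sample_abundances(
    n_bands: int,
    intensity_spread: float,
    rng: np.random.Generator,
    floor_ratio: float = ABUNDANCE_FLOOR_RATIO,
    log_offsets: np.ndarray | None = None,
) -> np.ndarray:
    """Log-normal relative abundances, floored and normalized.

    The floor at ``floor_ratio`` of the tallest band guarantees that every
    planted band's rendered peak clears the detection threshold after
    per-lane 0-1 scaling.  ``log_offsets`` adds per-band offsets on the
    log scale (used to make marker bands prominent).
    """
    mu = log_offsets if log_offsets is not None else 0.0
    v = np.exp(mu + rng.normal(0.0, intensity_spread, n_bands))
    v = np.maximum(v, floor_ratio * v.max())
    return v / v.sum()


def build_cohort(
    presets: list[GroupPreset],
    seed,
    design: ChannelDesign | None = None,
) -> list[SubjectProfile]:
    """Draw the latent cohort: one band set + abundances per subject.

    Per subject, the band count is round(Normal(mean, sd)) clipped to at
    least the core size; bands are the group core plus a uniform draw from
    the group's accessory pool; abundances are log-normal with the group's
    intensity spread.
    """
    design = design or ChannelDesign()
    rng = np.random.default_rng(seed)
    pool, roles = build_band_atlas(presets, design, rng)
    marker_rfs = np.asarray(design.marker_rfs, float)
    subjects: list[SubjectProfile] = []
    for p in presets:
        core = roles[p.name]["core"]
        accessory = roles[p.name]["accessory"]
        for i in range(p.n_subjects):
            count = int(round(rng.normal(p.band_count_mean, p.band_count_sd)))
            count = int(np.clip(count, p.core_size, p.core_size + accessory.size))
            n_acc = count - p.core_size
            acc = rng.choice(accessory, size=n_acc, replace=False) if n_acc else np.array([], int)
            idx = np.sort(np.concatenate([core, acc]))
            offsets = None
            if p.name == design.reference_group and marker_rfs.size and design.marker_boost:
                offsets = np.where(
                    np.isin(pool.band_rfs[idx], marker_rfs), design.marker_boost, 0.0
                )
            abund = sample_abundances(idx.size, p.intensity_spread, rng, log_offsets=offsets)
            subjects.append(
                SubjectProfile(
                    subject_id=f"{p.name}{i + 1:02d}",
                    group=p.name,
                    rfs=pool.band_rfs[idx],
                    abundances=abund,
                    channel=design.channel,
                )
            )
    return subjects


def make_synthetic_standard(
    n_bands: int = 24,
    rf_span: tuple[float, float] = (0.05, 0.95),
    channel: str = "universal",
) -> SubjectProfile:
    """The fixed SS profile: equally spaced, equal-abundance bands.

    One identical profile is loaded in every SS lane of the experiment,
    providing the anchors for within- and between-gel alignment.
    """
    lo, hi = rf_span
    if not (0.0 < lo < hi < 1.0):
        raise ValueError(f"SS span {rf_span} must lie inside (0, 1)")
    if n_bands < 2:
        raise ValueError("SS needs at least 2 bands")
    if n_bands < 10:
        warnings.warn("SS with fewer than 10 bands anchors the warp poorly", stacklevel=2)
    rfs = np.linspace(lo, hi, n_bands)
    return SubjectProfile(
        subject_id="SS",
        group="SS",
        rfs=rfs,
        abundances=np.full(n_bands, 1.0 / n_bands),
        channel=channel,
    )


# ---------------------------------------------------------------------------
# experiment layout
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DistortionParams:
    """Per-gel distortion magnitudes (Rf units; stretch is fractional)."""

    max_shift: float = 0.02
    min_shift: float = 0.008  # keeps unaligned between-gel Dice failing
    max_stretch: float = 0.02
    max_smile: float = 0.01
    min_smile: float = 0.004
    noise_sd: float = 0.002


def design_experiment(
    cohort: list[SubjectProfile],
    seed,
    n_sample_lanes_per_gel: int = 12,
    n_ss_per_gel: int = 4,
    n_replicates: int = 2,
    distortion: DistortionParams | None = None,
    n_pixels: int = 1100,
) -> list[GelLayout]:
    """Assign duplicate lanes of every subject to gels and draw distortions.

    Replicate r of every subject lands on a gel from block r, so each
    sample runs on at least two different gels; every gel carries the SS
    in ``n_ss_per_gel`` slots including both outermost lanes.
    """
    distortion = distortion or DistortionParams()
    rng = np.random.default_rng(seed)
    channel = cohort[0].channel
    order = rng.permutation(len(cohort))
    per_gel = n_sample_lanes_per_gel
    gels_per_rep = math.ceil(len(cohort) / per_gel)

    layouts: list[GelLayout] = []
    gel_counter = 0
    for rep in range(n_replicates):
        rep_order = np.roll(order, rep * max(1, per_gel // 2))
        for g in range(gels_per_rep):
            chunk = rep_order[g * per_gel : (g + 1) * per_gel]
            if chunk.size == 0:
                continue
            sample_slots = [
                SlotAssignment(
                    sample_id=cohort[k].subject_id,
                    replicate_id=f"r{rep + 1}",
                    group=cohort[k].group,
                )
                for k in chunk
            ]
            n_lanes = len(sample_slots) + n_ss_per_gel
            ss_positions = np.round(np.linspace(0, n_lanes - 1, n_ss_per_gel)).astype(int)
            slots: list[SlotAssignment] = []
            it = iter(sample_slots)
            for i in range(n_lanes):
                if i in ss_positions:
                    slots.append(
                        SlotAssignment(sample_id="SS", replicate_id=f"ss{i}", group="SS", is_ss=True)
                    )
                else:
                    slots.append(next(it))
            layouts.append(
                GelLayout(
                    gel_id=f"{channel}_g{gel_counter + 1}",
                    slots=slots,
                    shift=float(rng.uniform(distortion.min_shift, distortion.max_shift) * rng.choice([-1, 1])),
                    stretch=float(rng.uniform(-distortion.max_stretch, distortion.max_stretch)),
                    smile=float(rng.uniform(distortion.min_smile, distortion.max_smile) * rng.choice([-1, 1])),
                    noise_sd=distortion.noise_sd,
                    n_pixels=n_pixels,
                )
            )
            gel_counter += 1
    return layouts


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def render_lane(
    profile: SubjectProfile,
    layout: GelLayout,
    lane_index: int,
    seed,
    params: RenderParams | None = None,
) -> LaneTrace:
    """Render one lane trace: warped Gaussian bands + baseline + noise.

    trace(x) = A * (baseline + sum_i h_i * exp(-(x - warp(rf_i))^2 / 2 sigma^2))
    + Gaussian noise, sampled on a dense pixel grid; h_i is the band's
    relative abundance scaled so the tallest band has height 1.
    """
    params = params or RenderParams()
    rng = np.random.default_rng(seed)
    slot = layout.slots[lane_index]
    warped = np.asarray(layout.warp(profile.rfs, lane_index), float)
    if warped.size > 1 and np.min(np.diff(warped)) < params.resolvable_spacing:
        warnings.warn(
            f"{layout.gel_id} lane {lane_index}: planted bands closer than the "
            f"resolvable spacing {params.resolvable_spacing} after warping",
            stacklevel=2,
        )
    h = profile.abundances / profile.abundances.max()
    x = np.linspace(0.0, 1.0, params.n_pixels)
    comp = np.zeros_like(x)
    for u, hi_ in zip(warped, h):
        comp += hi_ * np.exp(-0.5 * ((x - u) / params.band_sigma) ** 2)
    amp = params.amp_scale * (1.0 + params.brightness_jitter * rng.uniform(-1, 1))
    trace = amp * (params.baseline + comp)
    trace = trace + rng.normal(0.0, layout.noise_sd * amp, trace.size)
    return LaneTrace(
        intensities=np.clip(trace, 0.0, 65535.0),
        gel_id=layout.gel_id,
        lane_index=lane_index,
        sample_id=slot.sample_id,
        replicate_id=slot.replicate_id,
        group=slot.group,
        is_ss=slot.is_ss,
        channel=profile.channel,
    )


def render_gel(
    layout: GelLayout,
    profiles: dict[str, SubjectProfile],
    ss_profile: SubjectProfile,
    seed,
    params: RenderParams | None = None,
) -> list[LaneTrace]:
    """Render every lane of one gel from the latent profiles."""
    params = params or RenderParams()
    seq = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    ss = seq.spawn(layout.n_lanes)
    traces = []
    for i, slot in enumerate(layout.slots):
        profile = ss_profile if slot.is_ss else profiles[slot.sample_id]
        traces.append(render_lane(profile, layout, i, ss[i], params))
    return traces


def render_gel_image(
    layout: GelLayout,
    traces: list[LaneTrace],
    lane_width: int = 8,
    lane_gap: int = 4,
    margin: int = 6,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Compose lane traces into a 16-bit grayscale gel image + metadata.

    Each lane occupies a fixed column band of ``lane_width`` pixels; the
    metadata table carries one row per lane (canonical columns plus the
    column spans needed for extraction).
    """
    if len(traces) != layout.n_lanes:
        raise ValueError(
            f"{layout.gel_id}: {len(traces)} traces for {layout.n_lanes} slots"
        )
    n_rows = traces[0].n_pixels
    width = 2 * margin + layout.n_lanes * lane_width + (layout.n_lanes - 1) * lane_gap
    image = np.zeros((n_rows, width), dtype=np.uint16)
    rows = []
    for i, t in enumerate(traces):
        c0 = margin + i * (lane_width + lane_gap)
        c1 = c0 + lane_width
        column = np.clip(np.round(t.intensities), 0, 65535).astype(np.uint16)
        image[:, c0:c1] = column[:, None]
        rows.append({**t.metadata(), "col_start": c0, "col_end": c1})
    metadata = pd.DataFrame(rows, columns=METADATA_COLUMNS + ["col_start", "col_end"])
    return image, metadata


def simulate_experiment(
    presets: list[GroupPreset],
    seed,
    design: ChannelDesign | None = None,
    n_sample_lanes_per_gel: int = 12,
    n_ss_per_gel: int = 4,
    n_replicates: int = 2,
    distortion: DistortionParams | None = None,
    render_params: RenderParams | None = None,
    ss_bands: int = 24,
    ss_span: tuple[float, float] = (0.05, 0.95),
):
    """End-to-end simulation of one channel's gel experiment.

    Returns ``(cohort, ss_profile, layouts, gels)`` where ``gels`` is a
    list of ``(layout, image, metadata, traces)`` tuples.  Identical seeds
    give bit-identical cohorts and images.
    """
    design = design or ChannelDesign()
    render_params = render_params or RenderParams()
    root = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    cohort_seed, layout_seed, render_seed = root.spawn(3)
    cohort = build_cohort(presets, cohort_seed, design)
    ss_profile = make_synthetic_standard(ss_bands, ss_span, channel=design.channel)
    layouts = design_experiment(
        cohort,
        layout_seed,
        n_sample_lanes_per_gel=n_sample_lanes_per_gel,
        n_ss_per_gel=n_ss_per_gel,
        n_replicates=n_replicates,
        distortion=distortion,
        n_pixels=render_params.n_pixels,
    )
    profiles = {s.subject_id: s for s in cohort}
    gels = []
    for layout, gseed in zip(layouts, render_seed.spawn(len(layouts))):
        traces = render_gel(layout, profiles, ss_profile, gseed, render_params)
        image, metadata = render_gel_image(layout, traces)
        gels.append((layout, image, metadata, traces))
    return cohort, ss_profile, layouts, gels
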