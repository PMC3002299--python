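"""Shared fixtures: a full calibrated study run and small controlled gels."""

from __future__ import annotations

import numpy as np
import pytest

from gelbands.pipeline import RunConfig, run_study
from gelbands.simulate import (
    GelLayout,
    RenderParams,
    SlotAssignment,
    SubjectProfile,
    make_synthetic_standard,
    render_lane,
)


@pytest.fixture(scope="session")
def study():
    """One full study on the calibrated cohort (both channels).

    Shared across the suite: the band statistics, discrimination and
    permutation results are all read off this single run.
    """
    return run_study(RunConfig(seed=1, n_resamples=200))


def make_layout(
    gel_id: str,
    sample_ids: list[str],
    shift: float = 0.0,
    stretch: float = 0.0,
    smile: float = 0.0,
    noise_sd: float = 0.0,
    n_ss: int = 4,
    n_pixels: int = 1100,
) -> GelLayout:
    """A small gel layout with SS lanes at spread positions incl. both ends."""
    n_lanes = len(sample_ids) + n_ss
    ss_pos = set(np.round(np.linspace(0, n_lanes - 1, n_ss)).astype(int))
    slots = []
    it = iter(sample_ids)
    for i in range(n_lanes):
        if i in ss_pos:
            slots.append(SlotAssignment("SS", f"ss{i}", "SS", is_ss=True))
        else:
            slots.append(SlotAssignment(next(it), "r1", "g"))
    return GelLayout(
        gel_id=gel_id,
        slots=slots,
        shift=shift,
        stretch=stretch,
        smile=smile,
        noise_sd=noise_sd,
        n_pixels=n_pixels,
    )


def render_small_gel(layout: GelLayout, profiles: dict[str, SubjectProfile], seed=0,
                     params: RenderParams | None = None):
    """Render every lane of a small layout (SS profile is the default one)."""
    ss_profile = make_synthetic_standard(channel="universal")
    rng_seeds = np.random.SeedSequence(seed).spawn(layout.n_lanes)
    traces = []
    for i, slot in enumerate(layout.slots):
        prof = ss_profile if slot.is_ss else profiles[slot.sample_id]
        traces.append(render_lane(prof, layout, i, rng_seeds[i], params))
    return traces


def flat_profile(subject_id: str, rfs, group: str = "g") -> SubjectProfile:
    rfs = np.asarray(rfs, float)
    return SubjectProfile(
        subject_id=subject_id,
        group=group,
        rfs=rfs,
        abundances=np.full(rfs.size, 1.0 / rfs.size),
    )
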