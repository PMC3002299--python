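"""Calibrated cohort presets and reference summary statistics.

The generator presets below are the package's standard study conditions:
a 22 control / 13 ulcerative-colitis / 11 irritable-bowel-syndrome cohort
profiled on a universal 16S-V3 channel and a Bacteroides-specific
channel, with duplicate lanes per sample across gels.  Core sizes,
accessory-pool sizes and intensity spreads were frozen by Monte Carlo
calibration (``gelbands.calibrate``) so that the latent cohorts reproduce
the reference group statistics in ``REFERENCE_TARGETS``: mean band
counts, intensity-weighted Shannon indices, and within-group median Dice
similarities of the three groups on both channels.
"""

from __future__ import annotations

from .simulate import ChannelDesign, GroupPreset

#: Rf positions of the reference-group marker bands (Bacteroides/
#: Parabacteroides phylotypes enriched in healthy controls); planted into
#: the control core of the universal channel so the discriminant-band
#: ranking has a known truth to recover.
MARKER_RFS = (0.236, 0.259, 0.273, 0.421)

UNIVERSAL_DESIGN = ChannelDesign(
    channel="universal",
    window=(0.095, 0.815),
    min_spacing=0.0095,
    shared_core_size=20,
    marker_rfs=MARKER_RFS,
    marker_boost=1.5,
    reference_group="control",
)

BACTEROIDES_DESIGN = ChannelDesign(
    channel="bacteroides",
    window=(0.095, 0.815),
    min_spacing=0.0095,
    shared_core_size=3,
    marker_rfs=(),
    reference_group="control",
)

UNIVERSAL_PRESETS = [
    GroupPreset(
        name="control",
        n_subjects=22,
        band_count_mean=45.0,
        band_count_sd=3.0,
        core_size=34,
        accessory_pool_size=36,
        intensity_spread=1.02,
        shannon_target=3.25,
        dice_target=82.9,
    ),
    GroupPreset(
        name="UC",
        n_subjects=13,
        band_count_mean=37.0,
        band_count_sd=5.0,
        core_size=24,
        accessory_pool_size=40,
        intensity_spread=1.39,
        shannon_target=2.94,
        dice_target=76.1,
    ),
    GroupPreset(
        name="IBS",
        n_subjects=11,
        band_count_mean=39.0,
        band_count_sd=6.0,
        core_size=23,
        accessory_pool_size=43,
        intensity_spread=1.62,
        shannon_target=2.90,
        dice_target=73.8,
    ),
]

BACTEROIDES_PRESETS = [
    GroupPreset(
        name="control",
        n_subjects=22,
        band_count_mean=14.0,
        band_count_sd=3.3,
        core_size=7,
        accessory_pool_size=40,
        intensity_spread=1.0,
        shannon_target=2.22,
        dice_target=58.8,
    ),
    GroupPreset(
        name="UC",
        n_subjects=13,
        band_count_mean=11.9,
        band_count_sd=2.9,
        core_size=3,
        accessory_pool_size=60,
        intensity_spread=1.0,
        shannon_target=2.06,
        dice_target=36.4,
    ),
    GroupPreset(
        name="IBS",
        n_subjects=11,
        band_count_mean=14.3,
        band_count_sd=2.9,
        core_size=7,
        accessory_pool_size=50,
        intensity_spread=1.0,
        shannon_target=2.25,
        dice_target=55.2,
    ),
]

#: reference group statistics the calibrated cohorts are held against
#: (the published cohort summaries used as calibration targets)
REFERENCE_TARGETS = {
    "universal": {
        "band_count_mean": {"control": 45.0, "UC": 37.0, "IBS": 39.0},
        "band_count_sd": {"control": 3.0, "UC": 5.0, "IBS": 6.0},
        "shannon_mean": {"control": 3.25, "UC": 2.94, "IBS": 2.90},
        "shannon_sd": {"control": 0.16, "UC": 0.29, "IBS": 0.38},
        "dice_median": {"control": 82.9, "UC": 76.1, "IBS": 73.8},
        "dice_iqr": {
            "control": (79.1, 86.7),
            "UC": (70.9, 83.1),
            "IBS": (67.0, 77.5),
        },
        "cv_success_rate": 64.0,
        "cv_components": 4,
    },
    "bacteroides": {
        "band_count_mean": {"control": 14.0, "UC": 11.9, "IBS": 14.3},
        "band_count_sd": {"control": 3.3, "UC": 2.9, "IBS": 2.9},
        "dice_median": {"control": 58.8, "UC": 36.4, "IBS": 55.2},
        "dice_iqr": {
            "control": (51.0, 70.1),
            "UC": (24.5, 49.0),
            "IBS": (48.9, 65.6),
        },
    },
}
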