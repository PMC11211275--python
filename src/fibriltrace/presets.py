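"""Canonical incubation-timepoint presets for the fibrillogenesis timeline.

Seven timepoints (0, 60, 120, 240, 480 min, 24 h, 48 h) span the course of
amyloid-beta 1-42 aggregation. Each preset bundles the study conditions for
that timepoint: amide I secondary-structure fractions, protofibril and
fibril morphology (dimensions and field counts), whether protofibrils are
clustered into a macromolecular network, and the ThT sigmoid parameters of
the aggregation run.

The structure fractions follow the reported ordinal pattern -- random-coil
dominant at early times, an alpha-helix maximum at 120 min, beta-sheet and
coil nearly equal at 120-240 min, and beta-sheet dominant from 480 min
onward -- with concrete values fixed here once (the underlying histogram is
published only graphically).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Tuple

__all__ = [
    "LABELS",
    "LABEL_MINUTES",
    "TimelinePreset",
    "make_timeline_preset",
]

LABELS: Tuple[str, ...] = ("0min", "60min", "120min", "240min", "480min", "24h", "48h")

LABEL_MINUTES: Dict[str, int] = {
    "0min": 0,
    "60min": 60,
    "120min": 120,
    "240min": 240,
    "480min": 480,
    "24h": 1440,
    "48h": 2880,
}

# ThT sigmoid of the single aggregation run: chosen so the symmetric
# tangent-line phase boundaries t_half -/+ 2/k land exactly on the observed
# 8 h exponential onset and 15 h plateau onset.
_THT_PARAMS = (100.0, 1100.0, 4.0 / 7.0, 11.5)  # (F0, Fmax, k /h, t_half h)

# (alpha, beta, coil) fractions per timepoint, summing to 1.
_FRACTIONS: Dict[str, Tuple[float, float, float]] = {
    "0min": (0.18, 0.30, 0.52),
    "60min": (0.24, 0.32, 0.44),
    "120min": (0.30, 0.34, 0.36),
    "240min": (0.24, 0.37, 0.39),
    "480min": (0.18, 0.48, 0.34),
    "24h": (0.13, 0.57, 0.30),
    "48h": (0.10, 0.64, 0.26),
}

# protofibrils: (mean length nm, width nm, height nm, count per field)
_PROTOFIBRILS: Dict[str, Tuple[float, float, float, int]] = {
    "0min": (85.0, 8.0, 0.5, 24),
    "60min": (85.0, 8.0, 0.5, 40),
    "120min": (85.0, 8.0, 0.5, 60),
    "240min": (85.0, 8.0, 0.5, 36),
    "480min": (85.0, 8.0, 0.5, 22),
    "24h": (85.0, 8.0, 0.5, 6),
    "48h": (85.0, 8.0, 0.5, 4),
}

# fibrils: ((min length nm, max length nm), height nm, count per field)
_FIBRILS: Dict[str, Tuple[Tuple[float, float], float, int]] = {
    "0min": ((0.0, 0.0), 0.0, 0),
    "60min": ((0.0, 0.0), 0.0, 0),
    "120min": ((0.0, 0.0), 0.0, 0),
    "240min": ((200.0, 600.0), 4.2, 8),
    "480min": ((250.0, 900.0), 4.2, 10),
    "24h": ((300.0, 1200.0), 4.7, 10),
    "48h": ((300.0, 1400.0), 4.7, 12),
}

# protofibril networks appear after the first hour and grow through 480 min
_NETWORK: Dict[str, bool] = {
    "0min": False,
    "60min": True,
    "120min": True,
    "240min": True,
    "480min": True,
    "24h": False,
    "48h": False,
}

# oligomers (globular aggregates): (diameter nm, height nm, count)
_OLIGOMERS: Dict[str, Tuple[float, float, int]] = {
    "0min": (16.0, 1.2, 10),
    "60min": (16.0, 1.2, 8),
    "120min": (16.0, 1.2, 6),
    "240min": (16.0, 1.2, 6),
    "480min": (16.0, 1.2, 5),
    "24h": (18.0, 1.4, 4),
    "48h": (20.0, 1.5, 5),
}


@dataclass(frozen=True)
class TimelinePreset:
    """Study conditions for one incubation timepoint."""

    label: str
    structure_fractions: Tuple[float, float, float]  # (alpha, beta, coil), sum 1
    protofibril_params: Tuple[float, float, float, int]  # length, width, height nm; count
    fibril_params: Tuple[Tuple[float, float], float, int]  # length range nm, height nm, count
    network_flag: bool
    tht_params: Tuple[float, float, float, float]  # F0, Fmax, k /h, t_half h
    oligomer_params: Tuple[float, float, int] = (16.0, 1.2, 6)

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"unknown timepoint label {self.label!r}; valid: {LABELS}")
        if abs(sum(self.structure_fractions) - 1.0) > 1e-9:
            raise ValueError("structure fractions must sum to 1")
        if any(f < 0 or f > 1 for f in self.structure_fractions):
            raise ValueError("structure fractions must lie in [0, 1]")
        mean_len, width, height, count = self.protofibril_params
        if count > 0 and not (mean_len > 0 and width > 0 and height > 0):
            raise ValueError("protofibril dimensions must be strictly positive")
        (flo, fhi), fheight, fcount = self.fibril_params
        if fcount > 0 and not (0 < flo <= fhi and fheight > 0):
            raise ValueError("fibril dimensions must be strictly positive")
        if LABEL_MINUTES[self.label] < 240 and fcount != 0:
            raise ValueError("fibrils are absent before 240 min")
        f0, fmax, k, t_half = self.tht_params
        if not (fmax > f0 and k > 0 and t_half > 0):
            raise ValueError("invalid ThT sigmoid parameters")

    @property
    def minutes(self) -> int:
        return LABEL_MINUTES[self.label]


def make_timeline_preset(label: str) -> TimelinePreset:
    """Return the preset for one of the seven canonical timepoint labels."""
    if label not in LABELS:
        raise ValueError(f"unknown timepoint label {label!r}; valid labels: {LABELS}")
    return TimelinePreset(
        label=label,
        structure_fractions=_FRACTIONS[label],
        protofibril_params=_PROTOFIBRILS[label],
        fibril_params=_FIBRILS[label],
        network_flag=_NETWORK[label],
        tht_params=_THT_PARAMS,
        oligomer_params=_OLIGOMERS[label],
    )
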