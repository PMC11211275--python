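"""Fibrillogenesis timeline assembly and the beta-sheet transition.

Combines per-timepoint outputs (secondary-structure fractions from the
amide I fit, AFM morphometrics, network coverage) into a chronological
table, locates the timepoint at which the beta-sheet becomes -- and
remains -- the dominant conformation, and writes CSV/JSON reports.

``run_full_timeline`` drives the whole pipeline on synthetic data: for each
canonical timepoint it generates replicate spectra and a topograph from the
preset, runs preprocessing, amide deconvolution and morphometry, fits the
ThT kinetics once, and assembles the table. One integer seed makes the run
reproducible end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np
import pandas as pd

from . import synthgen
from .afm import TipModel, measure_all_objects, network_coverage, segment_objects
from .amide import AmideBandModel, fit_amide_band
from .presets import LABELS, LABEL_MINUTES, make_timeline_preset
from .sers import PreprocessConfig, preprocess_and_average
from .tht import PhaseOnsets, aggregate_wells, fit_sigmoid, phase_onsets

__all__ = [
    "TimepointResult",
    "TimelineTable",
    "build_timeline",
    "detect_beta_transition",
    "report",
    "analyze_timepoint",
    "run_full_timeline",
]

_CLASSES = ("oligomer", "protofibril", "fibril")


@dataclass(frozen=True)
class TimepointResult:
    """Integrated measurements at one incubation timepoint."""

    label: str
    fractions: Tuple[float, float, float]  # (alpha, beta, coil) in %
    morphometrics: Dict[str, Dict[str, float]] = field(default_factory=dict)
    network_coverage: Optional[float] = None
    kinetics: Optional[PhaseOnsets] = None

    def __post_init__(self) -> None:
        if self.label not in LABEL_MINUTES:
            raise ValueError(f"unknown timepoint label {self.label!r}")
        if abs(sum(self.fractions) - 100.0) > 1e-6:
            raise ValueError("fractions must sum to 100")

    @property
    def minutes(self) -> int:
        return LABEL_MINUTES[self.label]


@dataclass(frozen=True)
class TimelineTable:
    """Chronologically ordered timepoint results with unique labels."""

    results: Tuple[TimepointResult, ...]

    def __post_init__(self) -> None:
        labels = [r.label for r in self.results]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate timepoint labels")
        minutes = [r.minutes for r in self.results]
        if minutes != sorted(minutes):
            raise ValueError("results must be chronological")

    def __iter__(self):
        return iter(self.results)

    def __len__(self):
        return len(self.results)


def build_timeline(results: Iterable[TimepointResult]) -> TimelineTable:
    """Order timepoint results chronologically (0 min ... 48 h)."""
    results = list(results)
    if not results:
        raise ValueError("need at least one timepoint result")
    labels = [r.label for r in results]
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate timepoint labels in {labels}")
    return TimelineTable(tuple(sorted(results, key=lambda r: r.minutes)))


def detect_beta_transition(t: TimelineTable) -> Optional[str]:
    """Earliest timepoint from which beta-sheet strictly dominates.

    Returns the first label at which the beta fraction strictly exceeds both
    the alpha and coil fractions *and keeps doing so at every later
    timepoint*; None when no such persistent transition exists.
    """
    dominant = [r.fractions[1] > r.fractions[0] and r.fractions[1] > r.fractions[2] for r in t]
    for i, r in enumerate(t.results):
        if all(dominant[i:]) and dominant[i]:
            return r.label
    return None


def _timeline_frame(t: TimelineTable) -> pd.DataFrame:
    rows = []
    for r in t:
        row: Dict[str, object] = {
            "label": r.label,
            "minutes": r.minutes,
            "alpha_pct": r.fractions[0],
            "beta_pct": r.fractions[1],
            "coil_pct": r.fractions[2],
            "network_coverage": r.network_coverage,
        }
        for cls in _CLASSES:
            stats = r.morphometrics.get(cls, {})
            row[f"{cls}_count"] = stats.get("count", 0)
            for key in ("median_length_nm", "median_height_nm", "median_width_nm"):
                row[f"{cls}_{key}"] = stats.get(key)
        rows.append(row)
    return pd.DataFrame(rows)


def report(t: TimelineTable, outdir, make_plots: bool = False) -> Dict[str, object]:
    """Write timeline.csv, summary.json and (optionally) overview plots."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    frame = _timeline_frame(t)
    frame.to_csv(outdir / "timeline.csv", index=False)
    transition = detect_beta_transition(t)
    kin = next((r.kinetics for r in t if r.kinetics is not None), None)
    summary = {
        "beta_transition": transition,
        "timepoints": [r.label for r in t],
        "kinetics": None
        if kin is None
        else {"t_exponential_h": kin.t_exponential, "t_plateau_h": kin.t_plateau},
    }
    from .io import write_json

    write_json(summary, outdir / "summary.json")
    if make_plots:
        _plot_fractions(frame, outdir / "fractions.png")
    return summary


def _plot_fractions(frame: pd.DataFrame, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    x = np.arange(len(frame))
    width = 0.27
    for i, (col, name) in enumerate(
        [("alpha_pct", "alpha-helix"), ("beta_pct", "beta-sheet"), ("coil_pct", "random coil")]
    ):
        ax.bar(x + (i - 1) * width, frame[col], width, label=name)
    ax.set_xticks(x, frame["label"])
    ax.set_ylabel("amide I contribution (%)")
    ax.set_xlabel("incubation time")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def _summarize_measures(measures) -> Dict[str, Dict[str, float]]:
    out: Dict[str, Dict[str, float]] = {}
    for cls in _CLASSES:
        sel = [m for m in measures if m.object_class == cls]
        if not sel:
            out[cls] = {"count": 0}
            continue
        out[cls] = {
            "count": len(sel),
            "mean_length_nm": float(np.mean([m.length for m in sel])),
            "median_length_nm": float(np.median([m.length for m in sel])),
            "mean_height_nm": float(np.mean([m.height for m in sel])),
            "median_height_nm": float(np.median([m.height for m in sel])),
            "mean_width_nm": float(np.mean([m.width_corrected for m in sel])),
            "median_width_nm": float(np.median([m.width_corrected for m in sel])),
        }
    return out


def _child_seed(seed: int, *key: int) -> int:
    ss = np.random.SeedSequence(entropy=seed, spawn_key=key)
    return int(ss.generate_state(1)[0] % (2**31))


def analyze_timepoint(
    label: str,
    seed: int,
    include_afm: bool = True,
    field_shape: Tuple[int, int] = (1024, 1024),
    n_replicates: int = 50,
    preprocess_cfg: PreprocessConfig = PreprocessConfig(),
    amide_model: AmideBandModel = AmideBandModel(),
) -> TimepointResult:
    """Generate and analyse one timepoint's synthetic measurements."""
    preset = make_timeline_preset(label)
    idx = LABELS.index(label)

    spectra = synthgen.generate_spectrum_set(
        synthgen.spectrum_config_for(preset, n_replicates=n_replicates),
        _child_seed(seed, 1, idx),
    )
    avg = preprocess_and_average(spectra, preprocess_cfg)
    fit = fit_amide_band(avg, amide_model, seed=_child_seed(seed, 2, idx))

    morpho: Dict[str, Dict[str, float]] = {}
    coverage = None
    if include_afm:
        cfg = synthgen.field_config_for(preset, _child_seed(seed, 3, idx), shape=field_shape)
        _, observed = synthgen.generate_topograph(cfg, _child_seed(seed, 4, idx))
        labels_img = segment_objects(observed)
        tip = TipModel(cfg.tip_radius)
        measures = measure_all_objects(observed, labels_img, tip=tip)
        morpho = _summarize_measures(measures)
        classes = {m.label: m.object_class for m in measures}
        coverage = network_coverage(observed, labels_img, classes=classes)

    return TimepointResult(
        label=label,
        fractions=fit.fractions,
        morphometrics=morpho,
        network_coverage=coverage,
    )


def run_full_timeline(
    seed: int,
    labels: Tuple[str, ...] = LABELS,
    include_afm: bool = True,
    field_shape: Tuple[int, int] = (1024, 1024),
    n_replicates: int = 50,
) -> TimelineTable:
    """Run the whole synthetic pipeline across the timepoints.

    The ThT run spans the full 48 h and is fitted once; its phase onsets
    are attached to every timepoint result for context.
    """
    tht_traces = synthgen.generate_tht(
        synthgen.tht_config_for(make_timeline_preset(labels[0])), _child_seed(seed, 0)
    )
    mean_trace, _ = aggregate_wells(tht_traces)
    onsets = phase_onsets(fit_sigmoid(mean_trace))

    results = []
    for label in labels:
        r = analyze_timepoint(
            label,
            seed,
            include_afm=include_afm,
            field_shape=field_shape,
            n_replicates=n_replicates,
        )
        results.append(
            TimepointResult(
                label=r.label,
                fractions=r.fractions,
                morphometrics=r.morphometrics,
                network_coverage=r.network_coverage,
                kinetics=onsets,
            )
        )
    return build_timeline(results)
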