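"""File formats: two-column spectrum CSV, float TIFF topographs with a
pixel-size sidecar, and ThT plate CSV (time_min plus one column per well,
control wells suffixed ``_ctrl``)."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, List, Union

import numpy as np
import pandas as pd
import tifffile

from .afm import Topograph
from .sers import RamanSpectrum
from .tht import FluorescenceTrace

__all__ = [
    "write_spectrum_csv",
    "read_spectrum_csv",
    "write_spectrum_set",
    "read_spectrum_set",
    "write_topograph",
    "read_topograph",
    "write_plate_csv",
    "read_plate_csv",
    "write_json",
]

PathLike = Union[str, Path]


def write_spectrum_csv(s: RamanSpectrum, path: PathLike) -> None:
    pd.DataFrame({"shift_cm1": s.shift, "intensity": s.intensity}).to_csv(
        path, index=False
    )


def read_spectrum_csv(path: PathLike) -> RamanSpectrum:
    df = pd.read_csv(path)
    return RamanSpectrum(df["shift_cm1"].to_numpy(), df["intensity"].to_numpy())


def write_spectrum_set(
    spectra: Iterable[RamanSpectrum], outdir: PathLike, manifest: dict | None = None
) -> List[Path]:
    """One CSV per replicate plus a manifest JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, s in enumerate(spectra):
        p = outdir / f"replicate_{i:03d}.csv"
        write_spectrum_csv(s, p)
        paths.append(p)
    write_json(dict(manifest or {}, n_replicates=len(paths)), outdir / "manifest.json")
    return paths


def read_spectrum_set(indir: PathLike) -> List[RamanSpectrum]:
    paths = sorted(Path(indir).glob("replicate_*.csv"))
    if not paths:
        raise FileNotFoundError(f"no replicate_*.csv files in {indir}")
    return [read_spectrum_csv(p) for p in paths]


def write_topograph(t: Topograph, path: PathLike) -> None:
    """32-bit float TIFF (heights in nm) plus ``<name>.json`` sidecar."""
    path = Path(path)
    tifffile.imwrite(path, t.heights.astype(np.float32))
    write_json({"pixel_size_nm": t.pixel_size}, path.with_suffix(".json"))


def read_topograph(path: PathLike) -> Topograph:
    path = Path(path)
    heights = tifffile.imread(path).astype(float)
    sidecar = path.with_suffix(".json")
    if not sidecar.exists():
        raise FileNotFoundError(f"missing pixel-size sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    return Topograph(heights, float(meta["pixel_size_nm"]))


def write_plate_csv(traces: Iterable[FluorescenceTrace], path: PathLike) -> None:
    traces = list(traces)
    if not traces:
        raise ValueError("no traces to write")
    grid = traces[0].time
    data = {"time_min": grid}
    for tr in traces:
        if tr.time.size != grid.size or not np.allclose(tr.time, grid):
            raise ValueError("all wells must share one time grid")
        name = tr.well_id or f"well{len(data)}"
        if tr.is_control and not name.endswith("_ctrl"):
            name += "_ctrl"
        data[name] = tr.intensity
    pd.DataFrame(data).to_csv(path, index=False)


def read_plate_csv(path: PathLike) -> List[FluorescenceTrace]:
    df = pd.read_csv(path)
    time = df["time_min"].to_numpy()
    return [
        FluorescenceTrace(
            time,
            df[col].to_numpy(),
            well_id=col,
            is_control=col.endswith("_ctrl"),
        )
        for col in df.columns
        if col != "time_min"
    ]


def write_json(obj: dict, path: PathLike) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_json_default) + "\n")


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
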