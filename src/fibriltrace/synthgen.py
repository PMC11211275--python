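"""Synthetic raw-data generators emulating the study's three measurements.

For every incubation timepoint preset the module can produce:

* replicate SERS spectra -- structure and aromatic bands (pseudo-Voigt)
  on a polynomial background with Gaussian noise and Bernoulli cosmic-ray
  spikes;
* AFM topographs -- oligomers, protofibrils (optionally clustered into a
  macromolecular network) and mature fibrils rendered as flat-topped
  ridges on an atomically smooth substrate, forward-convolved with a
  spherical tip and overlaid with substrate roughness noise;
* ThT plate-reader traces -- quintuplicate Boltzmann sigmoids plus flat
  buffer-only controls.

Every generator is a pure function of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.spatial import cKDTree

from .amide import BandComponent, pseudo_voigt
from .afm import Topograph
from .presets import TimelinePreset, make_timeline_preset
from .sers import RamanSpectrum
from .tht import FluorescenceTrace, boltzmann

__all__ = [
    "SpectrumGenConfig",
    "PlacedObject",
    "TopographGenConfig",
    "ThTGenConfig",
    "generate_spectrum_set",
    "generate_topograph",
    "generate_tht",
    "spectrum_config_for",
    "field_config_for",
    "tht_config_for",
    "empty_field_config",
]


# ---------------------------------------------------------------------------
# SERS spectra
# ---------------------------------------------------------------------------

# total amide I structure area (counts * cm^-1) shared by the three
# structure bands in proportion to the preset fractions
_AMIDE_TOTAL_AREA = 5000.0


@dataclass(frozen=True)
class SpectrumGenConfig:
    """Forward model of one replicate SERS acquisition.

    The baseline polynomial is evaluated on the axis rescaled to [-1, 1]
    (coefficients in ascending order, intensity units).
    """

    axis: Tuple[float, float, float] = (950.0, 1800.0, 1.0)  # start, stop, step cm^-1
    bands: Tuple[BandComponent, ...] = ()
    baseline_coeffs: Tuple[float, ...] = (300.0, -80.0, 50.0, -20.0)
    spike_rate: float = 0.001  # probability per bin
    spike_amplitude: float = 30.0  # multiple of noise sd
    noise_sd: float = 5.0  # counts
    n_replicates: int = 50

    def __post_init__(self) -> None:
        start, stop, step = self.axis
        if step <= 0 or stop <= start:
            raise ValueError("axis must have positive step and stop > start")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.noise_sd < 0 or self.spike_rate < 0 or self.spike_amplitude < 0:
            raise ValueError("noise parameters must be >= 0")

    def shift_axis(self) -> np.ndarray:
        start, stop, step = self.axis
        return np.arange(start, stop + step / 2.0, step)


def clean_spectrum(cfg: SpectrumGenConfig) -> RamanSpectrum:
    """The noiseless forward model: sum of bands plus polynomial baseline."""
    shift = cfg.shift_axis()
    for band in cfg.bands:
        if not (shift[0] <= band.center <= shift[-1]):
            raise ValueError(
                f"band center {band.center} cm^-1 outside axis "
                f"({shift[0]}-{shift[-1]} cm^-1)"
            )
    u = (shift - shift.mean()) / ((shift[-1] - shift[0]) / 2.0)
    intensity = np.polynomial.polynomial.polyval(u, np.asarray(cfg.baseline_coeffs, float))
    intensity = intensity + sum(
        (pseudo_voigt(shift, b) for b in cfg.bands), np.zeros_like(shift)
    )
    return RamanSpectrum(shift, intensity)


def generate_spectrum_set(cfg: SpectrumGenConfig, seed: int) -> List[RamanSpectrum]:
    """n_replicates noisy replicate spectra on one common axis."""
    clean = clean_spectrum(cfg)
    rng = np.random.default_rng(seed)
    out = []
    n = clean.shift.size
    for _ in range(cfg.n_replicates):
        noise = rng.normal(0.0, 1.0, n) * cfg.noise_sd
        spike_mask = rng.random(n) < cfg.spike_rate
        spike_height = cfg.spike_amplitude * cfg.noise_sd * rng.uniform(0.5, 1.5, n)
        intensity = clean.intensity + noise + np.where(spike_mask, spike_height, 0.0)
        out.append(RamanSpectrum(clean.shift, intensity))
    return out


def spectrum_config_for(preset: TimelinePreset, n_replicates: int = 50) -> SpectrumGenConfig:
    """Spectrum forward model for one timepoint preset.

    Aromatic Phe/Tyr bands sit at 1003, 1032 and 1592 cm^-1; the three
    amide I structure bands at 1650/1670/1680 cm^-1 share a total area of
    5000 counts*cm^-1 in the preset's (alpha, beta, coil) proportions.
    All three structure bands use the canonical 18 cm^-1 intrinsic width
    and a 50:50 Gauss/Lorentz mix: the amide I sub-bands of one backbone
    mode form a single line-shape family, which is also what makes their
    heavily overlapping areas an identifiable decomposition.
    """
    f_alpha, f_beta, f_coil = preset.structure_fractions
    bands = (
        BandComponent(center=1003.0, fwhm=10.0, eta=0.5, area=900.0),
        BandComponent(center=1032.0, fwhm=10.0, eta=0.5, area=500.0),
        BandComponent(center=1592.0, fwhm=12.0, eta=0.5, area=600.0),
        BandComponent(center=1650.0, fwhm=18.0, eta=0.5, area=_AMIDE_TOTAL_AREA * f_alpha),
        BandComponent(center=1670.0, fwhm=18.0, eta=0.5, area=_AMIDE_TOTAL_AREA * f_beta),
        BandComponent(center=1680.0, fwhm=18.0, eta=0.5, area=_AMIDE_TOTAL_AREA * f_coil),
    )
    return SpectrumGenConfig(bands=bands, n_replicates=n_replicates)


# ---------------------------------------------------------------------------
# AFM topographs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PlacedObject:
    """One rendered surface object.

    ``polyline`` is an (N, 2) array of (x, y) centerline points in nm
    (a single point for globular objects). The object is a flat-topped
    ridge/disk: height ``height`` within ``width/2`` of the centerline.
    Mature fibrils may carry a sinusoidal height modulation along the
    contour (the helical twist), parameterised by amplitude (relative)
    and period (nm).
    """

    object_class: str  # oligomer | protofibril | fibril
    polyline: np.ndarray
    width: float  # nm
    height: float  # nm
    twist_amplitude: float = 0.0
    twist_period: float = 120.0

    def __post_init__(self) -> None:
        poly = np.atleast_2d(np.asarray(self.polyline, dtype=float))
        if poly.ndim != 2 or poly.shape[1] != 2:
            raise ValueError("polyline must be an (N, 2) array of nm points")
        if not (self.width > 0 and self.height > 0):
            raise ValueError("width and height must be > 0")
        object.__setattr__(self, "polyline", poly)


@dataclass(frozen=True)
class TopographGenConfig:
    shape: Tuple[int, int] = (1024, 1024)
    pixel_size: float = 2.0  # nm/px
    substrate_rms: float = 0.2  # nm
    objects: Tuple[PlacedObject, ...] = ()
    tip_radius: float = 8.0  # nm

    def __post_init__(self) -> None:
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be > 0")
        if self.substrate_rms < 0:
            raise ValueError("substrate_rms must be >= 0")
        if not self.tip_radius > 0:
            raise ValueError("tip_radius must be > 0")
        h_nm = self.shape[0] * self.pixel_size
        w_nm = self.shape[1] * self.pixel_size
        for obj in self.objects:
            x, y = obj.polyline[:, 0], obj.polyline[:, 1]
            if x.min() < 0 or y.min() < 0 or x.max() > w_nm or y.max() > h_nm:
                raise ValueError(
                    f"{obj.object_class} centerline leaves the "
                    f"{w_nm:g} x {h_nm:g} nm field"
                )


def _render_object(
    canvas: np.ndarray, obj: PlacedObject, px: float, tip_radius: Optional[float] = None
) -> None:
    """Composite one object into ``canvas`` (in place, by pointwise max).

    With ``tip_radius`` set, the *tip-dilated* continuum surface is
    evaluated analytically at the pixel centres: a flat-topped ridge at
    centreline distance d reads h for d <= w/2 and
    h + sqrt(R^2 - (d - w/2)^2) - R along the spherical-cap flank out to
    the broadening sqrt(h(2R - h)). Evaluating the continuum dilation at
    the sample points (rather than grid-dilating an already sampled
    surface) avoids the half-pixel edge erosion a double discretization
    would introduce; grayscale dilation commutes with pointwise max, so
    per-object compositing is exact.
    """
    poly = obj.polyline
    half_w = obj.width / 2.0
    h_max = obj.height * (1.0 + max(obj.twist_amplitude, 0.0))
    if tip_radius is not None:
        r = float(tip_radius)
        margin = half_w + float(np.sqrt(min(h_max, r) * max(2.0 * r - h_max, r))) + px
    else:
        margin = half_w + px
    seg_start = 0.0
    n_seg = max(poly.shape[0] - 1, 1)
    for s in range(n_seg):
        a = poly[s]
        b = poly[min(s + 1, poly.shape[0] - 1)]
        seg_vec = b - a
        seg_len = float(np.hypot(*seg_vec))
        lo = np.minimum(a, b) - margin
        hi = np.maximum(a, b) + margin
        j0, j1 = max(int(lo[0] / px), 0), min(int(hi[0] / px) + 2, canvas.shape[1])
        i0, i1 = max(int(lo[1] / px), 0), min(int(hi[1] / px) + 2, canvas.shape[0])
        if j1 <= j0 or i1 <= i0:
            continue
        jj, ii = np.meshgrid(np.arange(j0, j1), np.arange(i0, i1))
        pts = np.stack([jj * px, ii * px], axis=-1)  # (x, y) of pixel centres
        if seg_len == 0.0:
            t = np.zeros(pts.shape[:2])
            closest = np.broadcast_to(a, pts.shape)
        else:
            t = np.clip(((pts - a) @ seg_vec) / seg_len**2, 0.0, 1.0)
            closest = a + t[..., None] * seg_vec
        dist = np.hypot(*(pts - closest).transpose(2, 0, 1))
        value = np.full(pts.shape[:2], obj.height)
        if obj.twist_amplitude > 0 and obj.twist_period > 0:
            arclen = seg_start + t * seg_len
            value = obj.height * (
                1.0 + obj.twist_amplitude * np.sin(2.0 * np.pi * arclen / obj.twist_period)
            )
        if tip_radius is None:
            surface = np.where(dist <= half_w, value, 0.0)
        else:
            excess = dist - half_w
            reach = np.sqrt(np.minimum(value, r) * np.maximum(2.0 * r - value, r))
            flank = value + np.sqrt(np.maximum(r**2 - excess**2, 0.0)) - r
            surface = np.where(
                excess <= 0.0,
                value,
                np.where(excess <= reach, np.maximum(flank, 0.0), 0.0),
            )
        region = canvas[i0:i1, j0:j1]
        np.maximum(region, surface, out=region)
        seg_start += seg_len


def generate_topograph(
    cfg: TopographGenConfig, seed: int
) -> Tuple[Topograph, Topograph]:
    """Render (ground_truth, observed) topographs.

    The ground truth has the objects on an ideally flat substrate. The
    observed image is the spherical-tip dilation of that continuum surface,
    evaluated analytically at the pixel centres (see :func:`_render_object`),
    plus Gaussian substrate noise of sd ``substrate_rms``. The analytic
    dilation dominates the grid dilation of the sampled truth everywhere
    (:func:`fibriltrace.afm.dilate_with_tip` takes a max over sampled
    offsets, the continuum takes it over all offsets), so
    ``observed - noise >= dilate_with_tip(ground_truth)`` pointwise.
    """
    px = cfg.pixel_size
    extent = ((cfg.shape[1] - 1) * px, (cfg.shape[0] - 1) * px)  # (x, y) nm
    for obj in cfg.objects:
        half_w = obj.width / 2.0
        lo = obj.polyline.min(axis=0) - half_w
        hi = obj.polyline.max(axis=0) + half_w
        if lo[0] < 0 or lo[1] < 0 or hi[0] > extent[0] or hi[1] > extent[1]:
            raise ValueError(
                f"{obj.object_class} object extends outside the field "
                f"(footprint {lo}-{hi} nm, field {extent} nm)"
            )
    truth_heights = np.zeros(cfg.shape)
    observed_heights = np.zeros(cfg.shape)
    for obj in cfg.objects:
        _render_object(truth_heights, obj, px)
        _render_object(observed_heights, obj, px, tip_radius=cfg.tip_radius)
    truth = Topograph(truth_heights, px)
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, 1.0, cfg.shape) * cfg.substrate_rms
    return truth, Topograph(observed_heights + noise, px)


def empty_field_config(
    shape: Tuple[int, int] = (1024, 1024),
    pixel_size: float = 2.0,
    substrate_rms: float = 0.2,
) -> TopographGenConfig:
    """Object-free substrate with the default mica roughness (0.2 nm RMS)."""
    return TopographGenConfig(
        shape=shape, pixel_size=pixel_size, substrate_rms=substrate_rms, objects=()
    )


def _random_walk_polyline(
    rng: np.random.Generator,
    start: np.ndarray,
    heading: float,
    length: float,
    step: float,
    heading_jitter: float,
) -> np.ndarray:
    n = max(int(round(length / step)), 1)
    seg = length / n
    pts = [np.asarray(start, float)]
    theta = heading
    for _ in range(n):
        theta += rng.normal(0.0, heading_jitter)
        pts.append(pts[-1] + seg * np.array([np.cos(theta), np.sin(theta)]))
    return np.asarray(pts)


def _sample_points(poly: np.ndarray, spacing: float = 8.0) -> np.ndarray:
    """Points every ~spacing nm along a polyline (for collision checks)."""
    if poly.shape[0] == 1:
        return poly
    out = [poly[0]]
    for a, b in zip(poly[:-1], poly[1:]):
        seg = float(np.hypot(*(b - a)))
        k = max(int(np.ceil(seg / spacing)), 1)
        for i in range(1, k + 1):
            out.append(a + (b - a) * i / k)
    return np.asarray(out)


def field_config_for(
    preset: TimelinePreset,
    seed: int,
    shape: Tuple[int, int] = (1024, 1024),
    pixel_size: float = 2.0,
    substrate_rms: float = 0.2,
    tip_radius: float = 8.0,
) -> TopographGenConfig:
    """Random field layout for a timepoint preset.

    Protofibrils and fibrils are random-walk ridges with bounded curvature;
    oligomers are disks. Isolated objects are placed with rejection sampling
    so that their tip-dilated footprints stay separated; when the preset's
    network flag is set, half of the protofibrils are instead packed into a
    cluster disc where they overlap into one macromolecular network.
    """
    rng = np.random.default_rng(seed)
    px = pixel_size
    extent = np.array([(shape[1] - 1) * px, (shape[0] - 1) * px])

    def broadening(h: float) -> float:
        hh = min(h, tip_radius)
        return float(np.sqrt(hh * (2.0 * tip_radius - hh)))

    placed_pts: List[np.ndarray] = []
    placed_rad: List[float] = []
    objects: List[PlacedObject] = []

    def register(obj: PlacedObject) -> None:
        objects.append(obj)
        pts = _sample_points(obj.polyline)
        placed_pts.append(pts)
        placed_rad.append(obj.width / 2.0 + broadening(obj.height) + 4.0)

    def collides(poly: np.ndarray, radius: float) -> bool:
        if not placed_pts:
            return False
        all_pts = np.concatenate(placed_pts)
        all_rad = np.concatenate(
            [np.full(len(p), r) for p, r in zip(placed_pts, placed_rad)]
        )
        tree = cKDTree(all_pts)
        cand = _sample_points(poly)
        dists, idx = tree.query(cand, k=1)
        return bool(np.any(dists < radius + all_rad[idx]))

    def place_ridge(
        cls: str,
        length: float,
        width: float,
        height: float,
        step: float,
        jitter: float,
        avoid: bool,
        center: Optional[np.ndarray] = None,
        cluster_radius: float = 0.0,
        twist_amplitude: float = 0.0,
        max_tries: int = 400,
    ) -> bool:
        edge = width / 2.0 + broadening(height) + tip_radius + 10.0
        radius = width / 2.0 + broadening(height) + 4.0
        for _ in range(max_tries):
            if center is None:
                start = rng.uniform(edge, extent - edge)
            else:
                ang = rng.uniform(0, 2 * np.pi)
                rad = cluster_radius * np.sqrt(rng.uniform())
                start = center + rad * np.array([np.cos(ang), np.sin(ang)])
                start = np.clip(start, edge, extent - edge)
            heading = rng.uniform(0, 2 * np.pi)
            poly = _random_walk_polyline(rng, start, heading, length, step, jitter)
            if np.any(poly.min(axis=0) < edge) or np.any(poly.max(axis=0) > extent - edge):
                continue
            if avoid and collides(poly, radius):
                continue
            register(
                PlacedObject(
                    object_class=cls,
                    polyline=poly,
                    width=width,
                    height=height,
                    twist_amplitude=twist_amplitude,
                )
            )
            return True
        return False

    # mature fibrils first (they need the most room)
    (f_lo, f_hi), f_height, f_count = preset.fibril_params
    for _ in range(f_count):
        place_ridge(
            "fibril",
            length=float(rng.uniform(f_lo, f_hi)),
            width=9.0 if preset.minutes >= 1440 else 8.0,
            height=f_height,
            step=30.0,
            jitter=0.08,
            avoid=True,
            twist_amplitude=0.05,
        )

    # protofibrils: a cluster (network) plus isolated individuals
    p_len, p_width, p_height, p_count = preset.protofibril_params
    n_cluster = p_count // 2 if preset.network_flag else 0
    if n_cluster:
        cluster_radius = 90.0 + 2.2 * n_cluster  # grows with density
        edge = p_width / 2.0 + broadening(p_height) + tip_radius + 10.0 + cluster_radius
        center = rng.uniform(edge, extent - edge)
        for _ in range(n_cluster):
            place_ridge(
                "protofibril",
                length=float(np.clip(rng.normal(p_len, 15.0), 45.0, 1.6 * p_len)),
                width=p_width,
                height=p_height,
                step=15.0,
                jitter=0.12,
                avoid=False,
                center=center,
                cluster_radius=cluster_radius,
            )
    for _ in range(p_count - n_cluster):
        place_ridge(
            "protofibril",
            length=float(np.clip(rng.normal(p_len, 15.0), 45.0, 1.6 * p_len)),
            width=p_width,
            height=p_height,
            step=15.0,
            jitter=0.12,
            avoid=True,
        )

    # oligomers: single-point disks
    o_diam, o_height, o_count = preset.oligomer_params
    for _ in range(o_count):
        edge = o_diam / 2.0 + broadening(o_height) + tip_radius + 10.0
        radius = o_diam / 2.0 + broadening(o_height) + 4.0
        for _ in range(200):
            start = rng.uniform(edge, extent - edge)
            poly = start[None, :]
            if collides(poly, radius):
                continue
            register(
                PlacedObject(
                    object_class="oligomer",
                    polyline=poly,
                    width=o_diam,
                    height=o_height,
                )
            )
            break

    return TopographGenConfig(
        shape=shape,
        pixel_size=pixel_size,
        substrate_rms=substrate_rms,
        objects=tuple(objects),
        tip_radius=tip_radius,
    )


# ---------------------------------------------------------------------------
# ThT traces
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ThTGenConfig:
    """Plate-read forward model: quintuplicate sigmoids plus controls."""

    t_end: float = 48.0  # hours
    dt: float = 2.0  # minutes
    sigmoid: Tuple[float, float, float, float] = (100.0, 1100.0, 4.0 / 7.0, 11.5)
    noise_sd: Optional[float] = None  # a.u.; default 2% of (Fmax - F0)
    n_wells: int = 5
    n_controls: int = 2
    include_control: bool = True

    def __post_init__(self) -> None:
        f0, fmax, k, t_half = self.sigmoid
        if self.t_end <= 0 or self.dt <= 0:
            raise ValueError("t_end and dt must be > 0")
        if not fmax > f0:
            raise ValueError("Fmax must exceed F0")
        if not k > 0:
            raise ValueError("rate k must be > 0")
        if self.n_wells < 1:
            raise ValueError("need at least one sample well")

    @property
    def effective_noise_sd(self) -> float:
        f0, fmax, *_ = self.sigmoid
        return 0.02 * (fmax - f0) if self.noise_sd is None else self.noise_sd


def generate_tht(cfg: ThTGenConfig, seed: int) -> List[FluorescenceTrace]:
    """Simulated plate read: sample wells follow the sigmoid, controls are flat."""
    time_min = np.arange(0.0, cfg.t_end * 60.0 + cfg.dt / 2.0, cfg.dt)
    f0, fmax, k, t_half = cfg.sigmoid
    ideal = boltzmann(time_min / 60.0, f0, fmax, k, t_half)
    sd = cfg.effective_noise_sd
    rng = np.random.default_rng(seed)
    traces = []
    for i in range(cfg.n_wells):
        noise = rng.normal(0.0, 1.0, time_min.size) * sd
        traces.append(
            FluorescenceTrace(time_min, ideal + noise, well_id=f"well{i + 1}")
        )
    if cfg.include_control:
        for i in range(cfg.n_controls):
            noise = rng.normal(0.0, 1.0, time_min.size) * sd
            traces.append(
                FluorescenceTrace(
                    time_min, f0 + noise, well_id=f"well{i + 1}_ctrl", is_control=True
                )
            )
    return traces


def tht_config_for(preset: TimelinePreset) -> ThTGenConfig:
    """ThT forward model for a preset (one aggregation run, 48 h, 2-min reads)."""
    return ThTGenConfig(sigmoid=preset.tht_params)
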