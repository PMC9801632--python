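"""Synthetic two-channel fluorescence microscopy with exact ground truth.

This module emulates confocal sections of virally labeled dopaminergic
projections: a red cytosolic reporter that fills curvilinear axons, and a
green synaptophysin-fused reporter that concentrates in ~1 µm synaptic
boutons placed along those axons. At the midbrain injection site it renders
round labeled somata instead. Every generated scene carries a
:class:`~axonquant.core.GroundTruth` record (axon polylines with exact arc
length, bouton centres, soma centres/areas) so downstream detectors can be
validated against a known answer.

Image formation is deliberately simple but physically ordered: structures are
rasterized plane-by-plane into a z-stack, blurred by an in-plane Gaussian
PSF, and corrupted by either additive Gaussian noise or Poisson shot noise
plus Gaussian read noise. Every generator is a pure function of its
configuration and seed.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from numpy.random import Generator, SeedSequence, default_rng
from scipy.ndimage import gaussian_filter
from shapely.geometry import LineString, box
from skimage.draw import disk as _draw_disk

from .core import ESTROUS_STAGES, GroundTruth, ImageStack, SectionRecord

__all__ = [
    "SimulationConfig",
    "CohortSpec",
    "Cohort",
    "persistent_random_walk",
    "generate_axon_paths",
    "place_boutons",
    "render_section",
    "generate_vta_section",
    "generate_cohort",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Acquisition and scene constants for one simulated section.

    Defaults describe the "10x" imaging mode: 0.62 µm/px so a 1 µm bouton
    spans ~2 px after PSF blur, 10 z-planes spaced 1 µm apart. ``axon_step_um``
    and ``axon_heading_kappa`` set the step length and von Mises heading
    concentration of the persistent random walk that shapes axons (larger
    kappa = straighter axons; ``inf`` = perfectly straight).
    """

    image_size_px: tuple[int, int] = (256, 256)
    pixel_size_um: float = 0.62
    z_planes: int = 10
    z_step_um: float = 1.0
    psf_sigma_um: float = 0.5
    axon_width_um: float = 0.75
    n_axons: int = 12
    axon_intensity: float = 150.0
    bouton_linear_density_per_um: float = 0.16
    bouton_amplitude: float = 160.0
    bouton_diameter_um: float = 1.0
    bouton_red_fraction: float = 0.3
    soma_area_range_um2: tuple[float, float] = (49.0, 200.0)
    soma_intensity: float = 120.0
    soma_clearance_um: float = 2.0
    background_mean: float = 50.0
    background_sd: float = 2.0
    noise_model: str = "poisson_gaussian"
    axon_step_um: float = 2.0
    axon_heading_kappa: float = 12.0
    seed: int = 0

    def __post_init__(self) -> None:
        h, w = self.image_size_px
        if h < 1 or w < 1:
            raise ValueError("image_size_px entries must be positive")
        for name in ("pixel_size_um", "z_step_um", "psf_sigma_um", "axon_width_um",
                     "axon_intensity", "bouton_amplitude", "bouton_diameter_um",
                     "soma_intensity", "axon_step_um"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.z_planes < 1:
            raise ValueError("z_planes must be a positive integer")
        if self.n_axons < 0 or self.bouton_linear_density_per_um < 0:
            raise ValueError("counts and densities must be nonnegative")
        if self.background_mean < 0 or self.background_sd < 0:
            raise ValueError("background parameters must be nonnegative")
        lo, hi = self.soma_area_range_um2
        if not (0 < lo < hi):
            raise ValueError("soma_area_range_um2 must satisfy 0 < low < high")
        if self.noise_model not in ("gaussian", "poisson_gaussian"):
            raise ValueError(f"unknown noise_model {self.noise_model!r}")

    @property
    def field_um(self) -> tuple[float, float]:
        """Physical field of view (width_x, height_y) in µm."""
        h, w = self.image_size_px
        return w * self.pixel_size_um, h * self.pixel_size_um

    def replace(self, **kwargs) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)


def _rng_from(seed_or_rng) -> Generator:
    if isinstance(seed_or_rng, Generator):
        return seed_or_rng
    return default_rng(seed_or_rng)


def persistent_random_walk(
    start: Sequence[float],
    heading: float,
    n_steps: int,
    step_um: float,
    kappa: float,
    rng: Generator,
) -> np.ndarray:
    """Fixed-step persistent random walk with von Mises heading perturbation.

    Returns an ``(n_steps + 1, 2)`` polyline in µm. ``kappa = inf`` yields a
    perfectly straight path.
    """
    if np.isfinite(kappa):
        turns = rng.vonmises(0.0, kappa, size=n_steps)
    else:
        turns = np.zeros(n_steps)
    theta = heading + np.cumsum(turns)
    pts = np.empty((n_steps + 1, 2))
    pts[0] = start
    pts[1:, 0] = start[0] + np.cumsum(step_um * np.cos(theta))
    pts[1:, 1] = start[1] + np.cumsum(step_um * np.sin(theta))
    return pts


def polyline_length(path: np.ndarray) -> float:
    """Arc length of a polyline, µm."""
    d = np.diff(np.asarray(path, dtype=float), axis=0)
    return float(np.hypot(d[:, 0], d[:, 1]).sum())


def clip_paths_to_field(paths: Iterable[np.ndarray], field_um: tuple[float, float]):
    """Intersect polylines with the rectangular field [0, w] × [0, h].

    Returns (clipped polylines, exact total clipped arc length in µm).
    """
    w, h = field_um
    if w <= 0 or h <= 0:
        raise ValueError("field must have positive area")
    frame = box(0.0, 0.0, w, h)
    clipped: list[np.ndarray] = []
    total = 0.0
    for path in paths:
        geom = LineString(np.asarray(path, dtype=float)).intersection(frame)
        if geom.is_empty:
            continue
        parts = getattr(geom, "geoms", [geom])
        for part in parts:
            if part.geom_type != "LineString" or part.length == 0.0:
                continue
            clipped.append(np.asarray(part.coords, dtype=float))
            total += part.length
    return clipped, total


def generate_axon_paths(
    config: SimulationConfig,
    field_um: Optional[tuple[float, float]] = None,
    rng=None,
) -> tuple[list[np.ndarray], float]:
    """Generate ``config.n_axons`` smooth axon polylines clipped to the field.

    Walks start on an expanded frame (half a field-diagonal margin) with
    uniform headings so axons may enter, cross, or leave the field; only the
    in-field portions are returned. The returned total length is the exact
    clipped arc length.
    """
    if field_um is None:
        field_um = config.field_um
    w, h = field_um
    if w <= 0 or h <= 0:
        raise ValueError("field must have positive area")
    rng = _rng_from(config.seed if rng is None else rng)
    diag = float(np.hypot(w, h))
    margin = 0.5 * diag
    n_steps = int(np.ceil(2.0 * diag / config.axon_step_um))
    raw = []
    for _ in range(config.n_axons):
        start = (rng.uniform(-margin, w + margin), rng.uniform(-margin, h + margin))
        heading = rng.uniform(0.0, 2.0 * np.pi)
        raw.append(
            persistent_random_walk(
                start, heading, n_steps, config.axon_step_um, config.axon_heading_kappa, rng
            )
        )
    return clip_paths_to_field(raw, field_um)


def place_boutons(
    paths: Sequence[np.ndarray],
    linear_density_per_um: float,
    rng,
) -> np.ndarray:
    """Drop boutons along axon polylines as a homogeneous Poisson process.

    The expected count is ``linear_density_per_um × total arc length``; each
    bouton sits exactly on a path. Returns an (n, 2) array of µm coordinates.
    """
    if linear_density_per_um < 0:
        raise ValueError("linear density must be nonnegative")
    rng = _rng_from(rng)
    seg_starts, seg_vecs, seg_lens = [], [], []
    for path in paths:
        p = np.asarray(path, dtype=float)
        d = np.diff(p, axis=0)
        lens = np.hypot(d[:, 0], d[:, 1])
        keep = lens > 0
        seg_starts.append(p[:-1][keep])
        seg_vecs.append(d[keep])
        seg_lens.append(lens[keep])
    if not seg_lens or sum(l.sum() for l in seg_lens) == 0.0:
        return np.empty((0, 2))
    starts = np.concatenate(seg_starts)
    vecs = np.concatenate(seg_vecs)
    lens = np.concatenate(seg_lens)
    total = lens.sum()
    n = rng.poisson(linear_density_per_um * total)
    if n == 0:
        return np.empty((0, 2))
    s = rng.uniform(0.0, total, size=n)
    cum = np.concatenate([[0.0], np.cumsum(lens)])
    idx = np.clip(np.searchsorted(cum, s, side="right") - 1, 0, len(lens) - 1)
    frac = (s - cum[idx]) / lens[idx]
    return starts[idx] + frac[:, None] * vecs[idx]


# ---------------------------------------------------------------------------
# rendering

def _paths_to_pixel_mask(paths, config: SimulationConfig, shape):
    """Rasterize each polyline into its own boolean pixel mask by dense
    resampling (4 samples per pixel along the arc, so no pixel the curve
    crosses is skipped)."""
    ps = config.pixel_size_um
    masks = []
    h, w = shape
    for path in paths:
        p = np.asarray(path, dtype=float) / ps
        d = np.diff(p, axis=0)
        seg_len = np.hypot(d[:, 0], d[:, 1])
        cum = np.concatenate([[0.0], np.cumsum(seg_len)])
        total = cum[-1]
        n_samp = max(2, int(np.ceil(total * 4.0)))
        s = np.linspace(0.0, total, n_samp)
        xs = np.interp(s, cum, p[:, 0])
        ys = np.interp(s, cum, p[:, 1])
        cols = np.clip(xs, 0, w - 1e-9).astype(int)
        rows = np.clip(ys, 0, h - 1e-9).astype(int)
        m = np.zeros(shape, dtype=bool)
        m[rows, cols] = True
        masks.append(m)
    # widen to the physical axon width when it exceeds one pixel
    radius = int(round(config.axon_width_um / ps / 2.0 - 0.5))
    if radius > 0:
        from scipy.ndimage import binary_dilation
        from skimage.morphology import disk as _disk

        se = _disk(radius)
        masks = [binary_dilation(m, structure=se) for m in masks]
    return masks


def _add_gaussian_spots(plane: np.ndarray, centers_px: np.ndarray, amplitude: float,
                        sigma_px: float) -> None:
    """Add subpixel-centred Gaussian spots to ``plane`` in place."""
    if len(centers_px) == 0:
        return
    h, w = plane.shape
    half = max(2, int(np.ceil(4.0 * sigma_px)))
    for cx, cy in centers_px:
        c0, r0 = int(np.floor(cx)), int(np.floor(cy))
        rlo, rhi = max(0, r0 - half), min(h, r0 + half + 1)
        clo, chi = max(0, c0 - half), min(w, c0 + half + 1)
        if rlo >= rhi or clo >= chi:
            continue
        rr = np.arange(rlo, rhi)[:, None] + 0.5
        cc = np.arange(clo, chi)[None, :] + 0.5
        plane[rlo:rhi, clo:chi] += amplitude * np.exp(
            -((cc - cx) ** 2 + (rr - cy) ** 2) / (2.0 * sigma_px**2)
        )


def _apply_noise(scene: np.ndarray, config: SimulationConfig, rng: Generator) -> np.ndarray:
    if config.noise_model == "gaussian":
        out = scene + config.background_mean
        if config.background_sd > 0:
            out = out + rng.normal(0.0, config.background_sd, size=scene.shape)
    else:  # poisson_gaussian: shot noise on signal+background, Gaussian read noise
        # Poisson additivity: background and signal photons drawn separately,
        # and signal draws only where the blurred scene is nonzero
        out = rng.poisson(config.background_mean, size=scene.shape).astype(np.float64)
        hot = scene > 0
        if hot.any():
            out[hot] += rng.poisson(scene[hot])
        if config.background_sd > 0:
            out = out + rng.normal(0.0, config.background_sd, size=scene.shape)
    return np.clip(out, 0.0, None)


def render_section(
    truth: GroundTruth,
    config: SimulationConfig,
    rng=None,
) -> tuple[ImageStack, ImageStack]:
    """Render a ground-truth scene into red and green z-stacks.

    Axons are rasterized at ``axon_width_um`` into the red channel on a
    per-structure focal plane; boutons are Gaussian spots of
    ``bouton_diameter_um`` (FWHM) in the green channel and, at
    ``bouton_red_fraction`` of their amplitude, in the red channel (the
    cytosolic reporter also fills boutons, which is what makes single-channel
    bouton thresholding hard). Somata render into both channels. Planes are
    then PSF-blurred and noise is applied per ``noise_model``.
    """
    h, w = config.image_size_px
    ps = config.pixel_size_um
    sigma_psf_px = config.psf_sigma_um / ps
    if 4.0 * sigma_psf_px >= min(h, w):
        raise ValueError("PSF is wider than the imaging field")
    rng = _rng_from(config.seed if rng is None else rng)
    nz = config.z_planes

    red = np.zeros((nz, h, w))
    green = np.zeros((nz, h, w))

    axon_masks = _paths_to_pixel_mask(truth.axon_paths, config, (h, w))
    axon_planes = rng.integers(0, nz, size=len(axon_masks))
    for m, z in zip(axon_masks, axon_planes):
        red[z][m] += config.axon_intensity

    centers_px = truth.bouton_centers_um / ps
    bouton_planes = rng.integers(0, nz, size=len(centers_px))
    sigma_spot_px = config.bouton_diameter_um / 2.355 / ps  # FWHM -> sigma
    for z in range(nz):
        sel = centers_px[bouton_planes == z]
        _add_gaussian_spots(green[z], sel, config.bouton_amplitude, sigma_spot_px)
        _add_gaussian_spots(red[z], sel, config.bouton_red_fraction * config.bouton_amplitude,
                            sigma_spot_px)

    soma_planes = rng.integers(0, nz, size=truth.n_somata)
    for (x, y, area), z in zip(truth.soma_centers_um, soma_planes):
        r_px = np.sqrt(area / np.pi) / ps
        rr, cc = _draw_disk((y / ps, x / ps), r_px, shape=(h, w))
        red[z][rr, cc] += config.soma_intensity
        green[z][rr, cc] += config.soma_intensity

    for z in range(nz):
        if red[z].any():
            red[z] = gaussian_filter(red[z], sigma_psf_px)
        if green[z].any():
            green[z] = gaussian_filter(green[z], sigma_psf_px)

    red = _apply_noise(red, config, rng)
    green = _apply_noise(green, config, rng)
    return (
        ImageStack(red, ps, config.z_step_um),
        ImageStack(green, ps, config.z_step_um),
    )


def generate_vta_section(
    n_cells: int,
    config: SimulationConfig,
    rng=None,
    max_tries_per_cell: int = 2000,
) -> tuple[ImageStack, ImageStack, GroundTruth]:
    """Simulate an injection-site section: non-overlapping labeled somata.

    Soma areas are uniform on ``config.soma_area_range_um2`` and discs are
    placed by rejection sampling with a 1 µm clearance; exceeding the retry
    budget raises rather than silently overlapping cells.
    """
    if n_cells < 0:
        raise ValueError("n_cells must be nonnegative")
    rng = _rng_from(config.seed if rng is None else rng)
    w_um, h_um = config.field_um
    lo, hi = config.soma_area_range_um2
    areas = rng.uniform(lo, hi, size=n_cells)
    radii = np.sqrt(areas / np.pi)
    centers = np.empty((0, 2))
    placed_r: list[float] = []
    rows = []
    for i in range(n_cells):
        r = radii[i]
        for _ in range(max_tries_per_cell):
            x = rng.uniform(r, w_um - r)
            y = rng.uniform(r, h_um - r)
            if len(rows) == 0:
                ok = True
            else:
                c = np.array([row[:2] for row in rows])
                rr = np.array(placed_r)
                ok = bool(np.all(np.hypot(c[:, 0] - x, c[:, 1] - y) > rr + r
                                 + config.soma_clearance_um))
            if ok:
                rows.append((x, y, areas[i]))
                placed_r.append(r)
                break
        else:
            raise RuntimeError(
                f"could not place {n_cells} non-overlapping somata in a "
                f"{w_um:.0f}x{h_um:.0f} µm field"
            )
    truth = GroundTruth(soma_centers_um=np.array(rows).reshape(-1, 3), region_label="VTA")
    red, green = render_section(truth, config, rng=rng)
    return red, green, truth


# ---------------------------------------------------------------------------
# cohorts

@dataclass(frozen=True)
class CohortSpec:
    """Design of a simulated two-sex cohort.

    Labeling efficiency varies per mouse as a single lognormal multiplier
    (mean 1, coefficient of variation ``mouse_effect_cv``) shared by both
    channels: it scales the number of labeled axons per section and the
    number of labeled somata at the injection site together, because
    efficiency is a property of the viral injection, not of the reporter
    channel. ``region_axon_density`` is in axons per µm² of field and must
    order NAC > BLA > PFC.
    """

    n_mice_per_group: dict = field(default_factory=lambda: {"male": 5, "female": 5})
    group_bouton_density: dict = field(
        default_factory=lambda: {"male": 0.16, "female": 0.08}
    )
    mouse_effect_cv: float = 0.2
    n_sections_per_mouse: int = 20
    n_vta_sections_per_mouse: int = 4
    vta_cells_per_section: float = 30.0
    region_axon_density: dict = field(
        default_factory=lambda: {"NAC": 2.0e-3, "BLA": 5.0e-4, "PFC": 1.25e-4}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 1 for n in self.n_mice_per_group.values()):
            raise ValueError("each group needs at least one mouse")
        if any(d < 0 for d in self.group_bouton_density.values()):
            raise ValueError("bouton densities must be nonnegative")
        if self.mouse_effect_cv < 0:
            raise ValueError("mouse_effect_cv must be nonnegative")
        if self.n_sections_per_mouse < 1 or self.n_vta_sections_per_mouse < 1:
            raise ValueError("section counts must be positive")
        if any(d < 0 for d in self.region_axon_density.values()):
            raise ValueError("region axon densities must be nonnegative")


@dataclass
class Cohort:
    """A simulated cohort: sections (with ground truth) plus a manifest."""

    sections: list
    manifest: pd.DataFrame
    mouse_multipliers: dict

    def sections_of(self, mouse_id: str, region: Optional[str] = None):
        return [
            s for s in self.sections
            if s.mouse_id == mouse_id and (region is None or s.region == region)
        ]

    @property
    def mouse_ids(self) -> list[str]:
        return list(dict.fromkeys(s.mouse_id for s in self.sections))


def _default_roi(config: SimulationConfig, margin_px: int = 4) -> np.ndarray:
    h, w = config.image_size_px
    m = margin_px
    return np.array(
        [[m, m], [w - m, m], [w - m, h - m], [m, h - m]], dtype=float
    )


def _lognormal_multiplier(rng: Generator, cv: float) -> float:
    if cv == 0:
        return 1.0
    s2 = np.log1p(cv**2)
    return float(rng.lognormal(mean=-0.5 * s2, sigma=np.sqrt(s2)))


def generate_cohort(spec: CohortSpec, config: SimulationConfig) -> Cohort:
    """Simulate a full cohort: BLA section series plus VTA injection-site
    sections per mouse, with exact ground truth on every section.

    Per mouse, each of ``n_sections_per_mouse`` BLA sections draws its axon
    count from a Poisson law at ``multiplier × region_axon_density['BLA'] ×
    field area``, places boutons at the sex-specific linear density, and is
    rendered with fresh noise. VTA sections hold ``multiplier ×
    vta_cells_per_section`` somata on average. Fully reproducible from
    ``spec.seed``.
    """
    root = SeedSequence(spec.seed)
    field_w, field_h = config.field_um
    field_area = field_w * field_h
    roi = _default_roi(config)
    bla_bregmas = np.linspace(-3000.0, -1000.0, spec.n_sections_per_mouse)
    vta_bregmas = np.linspace(-3600.0, -3100.0, spec.n_vta_sections_per_mouse)
    female_stages = [s for s in ESTROUS_STAGES if s != "NA"]

    sections: list[SectionRecord] = []
    multipliers: dict[str, float] = {}
    rows = []
    mouse_counter = 0
    for sex in sorted(spec.n_mice_per_group):
        n_mice = spec.n_mice_per_group[sex]
        bouton_density = spec.group_bouton_density.get(sex, config.bouton_linear_density_per_um)
        for j in range(n_mice):
            mouse_id = f"{sex[0]}{j + 1:02d}"
            mouse_ss = root.spawn(1)[0]
            rng = default_rng(mouse_ss)
            mult = _lognormal_multiplier(rng, spec.mouse_effect_cv)
            multipliers[mouse_id] = mult
            stage = female_stages[j % len(female_stages)] if sex == "female" else "NA"

            for k in range(spec.n_sections_per_mouse):
                n_axons = int(rng.poisson(mult * spec.region_axon_density["BLA"] * field_area))
                sec_cfg = config.replace(n_axons=n_axons,
                                         bouton_linear_density_per_um=bouton_density)
                paths, length = generate_axon_paths(sec_cfg, rng=rng)
                boutons = place_boutons(paths, bouton_density, rng)
                truth = GroundTruth(
                    axon_paths=paths,
                    total_axon_length_um=length,
                    bouton_centers_um=boutons,
                    region_label="BLA",
                )
                red, green = render_section(truth, sec_cfg, rng=rng)
                rec = SectionRecord(
                    mouse_id=mouse_id, sex=sex, estrous_stage=stage,
                    bregma_um=float(bla_bregmas[k]), region="BLA",
                    red=red, green=green, roi_px=roi.copy(),
                    section_index=k, truth=truth,
                )
                sections.append(rec)
            for k in range(spec.n_vta_sections_per_mouse):
                n_cells = int(rng.poisson(mult * spec.vta_cells_per_section))
                red, green, truth = generate_vta_section(n_cells, config, rng=rng)
                rec = SectionRecord(
                    mouse_id=mouse_id, sex=sex, estrous_stage=stage,
                    bregma_um=float(vta_bregmas[k]), region="VTA",
                    red=red, green=green, roi_px=roi.copy(),
                    section_index=k, truth=truth,
                )
                sections.append(rec)
            mouse_counter += 1

    for s in sections:
        rows.append(
            dict(mouse_id=s.mouse_id, sex=s.sex, estrous_stage=s.estrous_stage,
                 region=s.region, section_index=s.section_index, bregma_um=s.bregma_um)
        )
    manifest = pd.DataFrame(rows)
    return Cohort(sections=sections, manifest=manifest, mouse_multipliers=multipliers)
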