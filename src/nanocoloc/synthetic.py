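"""Synthetic two-channel fluorescence fields of view with ground truth.

This module emulates a high-content nanoparticle-uptake imaging experiment:
adherent cells stained with a nuclear dye (the "DAPI" channel) are incubated
with fluorescent nanoparticles (the "TRITC" channel), washed, and imaged on a
widefield system.  Each generated field of view (FOV) consists of two
registered integer rasters plus a complete ground-truth record of the planted
cell geometries and particle positions, so every downstream stage of the
pipeline (segmentation, QC, colocalization, statistics) can be validated
against known truth.

The generative model, in order:

1.  Cell placement — disks with concentric disk nuclei, centers uniform over
    the FOV, rejection-sampled so nuclei do not overlap.
2.  Particle planting — per-cell particle counts are Poisson with mean
    ``particles_per_cell_mean * base_uptake_rate * uptake_multiplier``,
    where the multiplier encodes phenotype (high-metastatic HM, low-metastatic
    LM, benign) and temperature (endocytosis is essentially abolished at 4 °C).
    Each particle is internalized (inside the cell, with a radial density that
    rises toward the cell edge), adhered (thin annulus on the cell boundary),
    or free (anywhere in the FOV).
3.  Washing — trypsin strips adhered and free particles, PBS strips free
    particles only; a small carryover fraction of free particles survives
    either wash.
4.  Rendering — point emitters and nucleus/cell disks are convolved with a
    Gaussian PSF, modulated by a shared illumination profile (vignetting plus
    a per-FOV smooth fluctuation common to both channels — the realistic
    source of nonzero background colocalization in the controls), then
    corrupted with Poisson shot noise and Gaussian read noise and quantized.

Identical ``(config, seed)`` pairs reproduce bit-identical output.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .errors import PlacementError, ValidationError

PHENOTYPES = ("HM", "LM", "benign", "control_particles_only", "control_cells_only")
WASHES = ("trypsin", "pbs", "none")
PARTICLE_STATUSES = ("internalized", "adhered", "free")

#: Default phenotype uptake multipliers (relative to the base uptake rate).
#: Chosen so that default simulations reproduce the qualitative ordering
#: HM > LM > benign ~ background reported for metastatic vs benign breast
#: epithelial lines; fully user-overridable via SyntheticConfig.
DEFAULT_UPTAKE_MULTIPLIERS = {
    "HM": 2.5,
    "LM": 1.3,
    "benign": 0.1,
    "control_particles_only": 0.0,
    "control_cells_only": 0.0,
}

#: Endocytosis is energy dependent: at 4 °C uptake collapses to a small
#: residual (passive adhesion/carryover), modeled as a 2% rate.
DEFAULT_TEMPERATURE_FACTORS = {37: 1.0, 4: 0.02}


@dataclass(frozen=True)
class ConditionLabel:
    """Experimental condition of one FOV.

    ``phenotype`` is the cell line class (HM/LM/benign) or one of the two
    control classes: particles without cells ("positive" control) and cells
    without particles ("negative" control).
    """

    phenotype: str
    wash: str = "none"
    particle_size_nm: int = 100
    temperature_c: int = 37
    replicate_id: str = "r0"

    def __post_init__(self) -> None:
        if self.phenotype not in PHENOTYPES:
            raise ValidationError(f"unknown phenotype {self.phenotype!r}")
        if self.wash not in WASHES:
            raise ValidationError(f"unknown wash {self.wash!r}")
        if self.particle_size_nm not in (100, 200):
            raise ValidationError(
                f"particle_size_nm must be 100 or 200, got {self.particle_size_nm}"
            )
        if self.temperature_c not in (37, 4):
            raise ValidationError(
                f"temperature_c must be 37 or 4, got {self.temperature_c}"
            )

    @property
    def is_no_cell_control(self) -> bool:
        return self.phenotype == "control_particles_only"

    @property
    def is_no_particle_control(self) -> bool:
        return self.phenotype == "control_cells_only"

    @property
    def key(self) -> str:
        """Stable string identifier used in manifests and result tables."""
        return (
            f"{self.phenotype}_{self.wash}_{self.particle_size_nm}nm_"
            f"{self.temperature_c}C_{self.replicate_id}"
        )

    @property
    def group(self) -> str:
        """Grouping key for statistics: condition without the replicate id."""
        return (
            f"{self.phenotype}_{self.wash}_{self.particle_size_nm}nm_"
            f"{self.temperature_c}C"
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "ConditionLabel":
        return cls(
            phenotype=str(d["phenotype"]),
            wash=str(d["wash"]),
            particle_size_nm=int(d["particle_size_nm"]),
            temperature_c=int(d["temperature_c"]),
            replicate_id=str(d["replicate_id"]),
        )


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic imaging experiment.

    Geometry is specified in microns and converted to pixels internally.
    The default raster is 256x256 at 1.4 um/pixel, i.e. a (358 um)^2 ~
    0.128 mm^2 field — the FOV area of the study design — sampled on a
    coarser grid than the physical camera to keep simulation light; the
    colocalization statistics are sampling-rate agnostic.

    Intensities are in ADU (analog-to-digital units) of an integer camera.
    """

    image_shape: tuple[int, int] = (256, 256)
    pixel_size: float = 1.4  # um / pixel
    n_cells_mean: float = 20.0
    n_cells_sd: float = 10.0
    cell_radius_range: tuple[float, float] = (8.0, 15.0)  # um
    nucleus_to_cell_ratio: float = 0.5
    particles_per_cell_mean: float = 2000.0  # dosed particles per cell
    base_uptake_rate: float = 0.016  # fraction of the dose a unit-multiplier cell retains
    uptake_multipliers: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_UPTAKE_MULTIPLIERS)
    )
    temperature_factors: Mapping[int, float] = field(
        default_factory=lambda: dict(DEFAULT_TEMPERATURE_FACTORS)
    )
    internalized_fraction: float = 0.6
    adhered_fraction: float = 0.2
    edge_bias: float = 3.0  # radial density inside the cell ~ (r/R)^edge_bias
    fov_uptake_cv: float = 0.3  # per-FOV lognormal heterogeneity of uptake
    psf_sigma: float = 1.0  # um
    particle_intensity_mean: float = 100.0  # ADU integrated per particle
    particle_intensity_cv: float = 0.25
    nucleus_intensity_mean: float = 3000.0  # ADU amplitude of the nucleus disk
    cell_haze_fraction: float = 0.3  # diffuse whole-cell signal in the nuclei channel
    crosstalk: float = 0.0025  # nuclei-stain spectral bleed-through into the particle channel
    free_particles_mean: float = 500.0  # planted free particles in a no-cell FOV
    background_level: float = 100.0  # ADU
    read_noise_sd: float = 10.0  # ADU
    vignetting: float = 0.05  # fractional corner falloff of illumination
    shared_background_rel_sd: float = 0.05  # per-FOV shared smooth fluctuation
    bit_depth: int = 16
    wash_carryover: float = 0.05  # fraction of free particles surviving a wash
    seed: int = 0

    def validate(self) -> None:
        h, w = self.image_shape
        if h < 64 or w < 64:
            raise ValidationError(f"image_shape must be at least 64x64, got {h}x{w}")
        if self.internalized_fraction < 0 or self.adhered_fraction < 0:
            raise ValidationError("particle status fractions must be non-negative")
        if self.internalized_fraction + self.adhered_fraction > 1 + 1e-12:
            raise ValidationError(
                "internalized_fraction + adhered_fraction must be <= 1 "
                f"(got {self.internalized_fraction} + {self.adhered_fraction})"
            )
        if not 0 < self.nucleus_to_cell_ratio < 1:
            raise ValidationError("nucleus_to_cell_ratio must be in (0, 1)")
        for name in (
            "pixel_size",
            "psf_sigma",
            "particle_intensity_mean",
            "nucleus_intensity_mean",
            "background_level",
        ):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be strictly positive")
        lo, hi = self.cell_radius_range
        if not 0 < lo <= hi:
            raise ValidationError(f"invalid cell_radius_range {self.cell_radius_range}")
        if self.edge_bias < 0:
            raise ValidationError("edge_bias must be >= 0")
        if not 0 <= self.wash_carryover <= 1:
            raise ValidationError("wash_carryover must be in [0, 1]")
        if self.bit_depth not in (8, 12, 16):
            raise ValidationError("bit_depth must be one of 8, 12, 16")

    def replace(self, **kwargs) -> "SyntheticConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass
class Cell:
    center: tuple[float, float]  # (row, col), pixels
    cell_radius: float  # pixels
    nucleus_radius: float  # pixels


@dataclass
class GroundTruth:
    """Planted geometry and particle record of one FOV (synthetic only).

    ``positions`` is (N, 2) float (row, col) in pixels, ``status`` a length-N
    array over {internalized, adhered, free}, ``cell_index`` the owning cell
    (-1 for free particles).
    """

    cells: list[Cell]
    positions: np.ndarray
    status: np.ndarray
    cell_index: np.ndarray

    @property
    def n_particles(self) -> int:
        return len(self.positions)

    def count(self, status: str) -> int:
        return int(np.sum(self.status == status))

    @property
    def counts_per_cell(self) -> np.ndarray:
        """(n_cells, 2) array of (internalized, adhered) counts per cell."""
        out = np.zeros((len(self.cells), 2), dtype=int)
        for k, st in (("internalized", 0), ("adhered", 1)):
            mask = self.status == k
            idx, counts = np.unique(self.cell_index[mask], return_counts=True)
            out[idx, st] = counts
        return out

    def to_dict(self) -> dict:
        return {
            "cells": [
                {
                    "center": list(c.center),
                    "cell_radius": c.cell_radius,
                    "nucleus_radius": c.nucleus_radius,
                }
                for c in self.cells
            ],
            "positions": self.positions.tolist(),
            "status": self.status.tolist(),
            "cell_index": self.cell_index.tolist(),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "GroundTruth":
        cells = [
            Cell(tuple(c["center"]), float(c["cell_radius"]), float(c["nucleus_radius"]))
            for c in d["cells"]
        ]
        n = len(d["positions"])
        return cls(
            cells=cells,
            positions=np.asarray(d["positions"], dtype=float).reshape(n, 2),
            status=np.asarray(d["status"], dtype=object).astype(str),
            cell_index=np.asarray(d["cell_index"], dtype=int),
        )


@dataclass
class FieldOfView:
    """Two registered integer rasters plus metadata for one imaged region."""

    nuclei_channel: np.ndarray
    particle_channel: np.ndarray
    pixel_size: float
    condition: ConditionLabel
    fov_id: str = ""
    bit_depth: int = 16

    def __post_init__(self) -> None:
        if self.nuclei_channel.shape != self.particle_channel.shape:
            raise ValidationError(
                "nuclei and particle channels must share a shape, got "
                f"{self.nuclei_channel.shape} vs {self.particle_channel.shape}"
            )


def _empty_ground_truth(cells: list[Cell] | None = None) -> GroundTruth:
    return GroundTruth(
        cells=cells or [],
        positions=np.empty((0, 2), dtype=float),
        status=np.empty(0, dtype="U12"),
        cell_index=np.empty(0, dtype=int),
    )


def _place_cells(
    config: SyntheticConfig, n_cells: int, rng: np.random.Generator, max_retries: int = 200
) -> list[Cell]:
    """Rejection-sample cell centers so that nucleus disks do not overlap."""
    h, w = config.image_shape
    lo, hi = config.cell_radius_range
    cells: list[Cell] = []
    for k in range(n_cells):
        for _ in range(max_retries):
            r_cell = rng.uniform(lo, hi) / config.pixel_size
            r_nuc = r_cell * config.nucleus_to_cell_ratio
            center = (rng.uniform(0, h - 1), rng.uniform(0, w - 1))
            # 5 px clearance keeps neighbouring nuclei resolvable after PSF
            # blur and haze overlap (cells themselves may still overlap)
            ok = all(
                np.hypot(center[0] - c.center[0], center[1] - c.center[1])
                >= r_nuc + c.nucleus_radius + 5.0
                for c in cells
            )
            if ok:
                cells.append(Cell(center, r_cell, r_nuc))
                break
        else:
            raise PlacementError(
                f"failed to place cell {k + 1} of {n_cells} after "
                f"{max_retries} retries; FOV too crowded"
            )
    return cells


def _plant_particles(
    config: SyntheticConfig,
    condition: ConditionLabel,
    cells: list[Cell],
    rng: np.random.Generator,
) -> GroundTruth:
    h, w = config.image_shape
    if condition.is_no_particle_control:
        return _empty_ground_truth(cells)

    positions: list[np.ndarray] = []
    statuses: list[np.ndarray] = []
    owners: list[np.ndarray] = []

    if condition.is_no_cell_control or not cells:
        n_free = rng.poisson(config.free_particles_mean)
        if n_free:
            positions.append(
                np.column_stack([rng.uniform(0, h - 1, n_free), rng.uniform(0, w - 1, n_free)])
            )
            statuses.append(np.full(n_free, "free", dtype="U12"))
            owners.append(np.full(n_free, -1, dtype=int))
    else:
        mult = float(config.uptake_multipliers.get(condition.phenotype, 1.0))
        tfac = float(config.temperature_factors.get(condition.temperature_c, 1.0))
        lam = config.particles_per_cell_mean * config.base_uptake_rate * mult * tfac
        # FOV-level biological heterogeneity (shared by all cells in the FOV)
        if config.fov_uptake_cv > 0:
            sigma = np.sqrt(np.log1p(config.fov_uptake_cv**2))
            lam *= rng.lognormal(-0.5 * sigma**2, sigma)
        p_int = config.internalized_fraction
        p_adh = config.adhered_fraction
        for i, cell in enumerate(cells):
            n_c = rng.poisson(lam)
            if n_c == 0:
                continue
            u = rng.random(n_c)
            st = np.full(n_c, "free", dtype="U12")
            st[u < p_int] = "internalized"
            st[(u >= p_int) & (u < p_int + p_adh)] = "adhered"

            pos = np.empty((n_c, 2))
            theta = rng.uniform(0, 2 * np.pi, n_c)
            is_int = st == "internalized"
            is_adh = st == "adhered"
            is_free = st == "free"
            # internalized: area density ~ (r/R)^edge_bias  =>  r = R u^(1/(b+2))
            n_i = int(is_int.sum())
            if n_i:
                r = cell.cell_radius * rng.random(n_i) ** (1.0 / (config.edge_bias + 2.0))
                pos[is_int, 0] = cell.center[0] + r * np.sin(theta[is_int])
                pos[is_int, 1] = cell.center[1] + r * np.cos(theta[is_int])
            # adhered: thin annulus on the cell boundary (on the cell surface,
            # hence just inside the footprint)
            n_a = int(is_adh.sum())
            if n_a:
                r = cell.cell_radius * rng.uniform(0.85, 0.97, n_a)
                pos[is_adh, 0] = cell.center[0] + r * np.sin(theta[is_adh])
                pos[is_adh, 1] = cell.center[1] + r * np.cos(theta[is_adh])
            n_f = int(is_free.sum())
            if n_f:
                pos[is_free, 0] = rng.uniform(0, h - 1, n_f)
                pos[is_free, 1] = rng.uniform(0, w - 1, n_f)

            own = np.full(n_c, i, dtype=int)
            own[is_free] = -1
            positions.append(pos)
            statuses.append(st)
            owners.append(own)

    if positions:
        return GroundTruth(
            cells=cells,
            positions=np.concatenate(positions),
            status=np.concatenate(statuses),
            cell_index=np.concatenate(owners),
        )
    return _empty_ground_truth(cells)


def apply_wash(
    gt: GroundTruth,
    wash: str,
    carryover_fraction: float = 0.0,
    rng: np.random.Generator | None = None,
) -> GroundTruth:
    """Return the ground truth surviving the given wash.

    Trypsin digests the surface proteins trapping particles, removing adhered
    and free particles; PBS removes free particles only.  Either wash leaves a
    ``carryover_fraction`` of the free particles behind (residual background).
    Without an ``rng`` the carryover subset is chosen deterministically
    (evenly spaced free particles, floor of the fractional count).
    """
    if wash not in WASHES:
        raise ValidationError(f"unknown wash {wash!r}")
    if not 0 <= carryover_fraction <= 1:
        raise ValidationError(
            f"carryover_fraction must be in [0, 1], got {carryover_fraction}"
        )
    if wash == "none":
        return gt

    keep = gt.status == "internalized"
    if wash == "pbs":
        keep |= gt.status == "adhered"

    free_idx = np.flatnonzero(gt.status == "free")
    if len(free_idx) and carryover_fraction > 0:
        if rng is not None:
            survive = free_idx[rng.random(len(free_idx)) < carryover_fraction]
        else:
            n_keep = int(np.floor(carryover_fraction * len(free_idx)))
            survive = free_idx[
                np.linspace(0, len(free_idx) - 1, n_keep).astype(int)
            ] if n_keep else free_idx[:0]
        keep[survive] = True

    return GroundTruth(
        cells=gt.cells,
        positions=gt.positions[keep],
        status=gt.status[keep],
        cell_index=gt.cell_index[keep],
    )


def _vignette(shape: tuple[int, int], strength: float) -> np.ndarray:
    h, w = shape
    rr, cc = np.mgrid[0:h, 0:w].astype(float)
    d2 = ((rr - (h - 1) / 2) / (h / 2)) ** 2 + ((cc - (w - 1) / 2) / (w / 2)) ** 2
    return 1.0 - strength * d2 / 2.0


def _smooth_field(shape: tuple[int, int], rng: np.random.Generator) -> np.ndarray:
    """Zero-mean, unit-sd smooth random field (low spatial frequency)."""
    h, w = shape
    f = gaussian_filter(rng.standard_normal((h, w)), sigma=min(h, w) / 8.0)
    sd = f.std()
    if sd < 1e-12:
        return np.zeros(shape)
    return (f - f.mean()) / sd


def _deposit(canvas: np.ndarray, positions: np.ndarray, weights: np.ndarray) -> None:
    """Bilinear deposit of point intensities onto the canvas (in place)."""
    h, w = canvas.shape
    r = np.clip(positions[:, 0], 0, h - 1 - 1e-9)
    c = np.clip(positions[:, 1], 0, w - 1 - 1e-9)
    r0 = np.floor(r).astype(int)
    c0 = np.floor(c).astype(int)
    fr = r - r0
    fc = c - c0
    np.add.at(canvas, (r0, c0), weights * (1 - fr) * (1 - fc))
    np.add.at(canvas, (r0 + 1, c0), weights * fr * (1 - fc))
    np.add.at(canvas, (r0, c0 + 1), weights * (1 - fr) * fc)
    np.add.at(canvas, (r0 + 1, c0 + 1), weights * fr * fc)


def _disk_paint(canvas: np.ndarray, cell: Cell, radius: float, amplitude: float) -> None:
    h, w = canvas.shape
    r0 = max(int(np.floor(cell.center[0] - radius)) - 1, 0)
    r1 = min(int(np.ceil(cell.center[0] + radius)) + 2, h)
    c0 = max(int(np.floor(cell.center[1] - radius)) - 1, 0)
    c1 = min(int(np.ceil(cell.center[1] + radius)) + 2, w)
    if r0 >= r1 or c0 >= c1:
        return
    rr, cc = np.mgrid[r0:r1, c0:c1].astype(float)
    inside = (rr - cell.center[0]) ** 2 + (cc - cell.center[1]) ** 2 <= radius**2
    canvas[r0:r1, c0:c1][inside] += amplitude


def render(
    gt: GroundTruth,
    config: SyntheticConfig,
    condition: ConditionLabel,
    rng: np.random.Generator,
) -> FieldOfView:
    """Render a ground-truth record into a two-channel integer FOV."""
    h, w = config.image_shape
    px = config.pixel_size
    nuclei = np.zeros((h, w), dtype=float)
    particles = np.zeros((h, w), dtype=float)

    for cell in gt.cells:
        amp = config.nucleus_intensity_mean * rng.uniform(0.85, 1.15)
        _disk_paint(nuclei, cell, cell.nucleus_radius, amp)
        # diffuse whole-cell component: cytoplasmic dye background plus
        # out-of-focus light in a widefield system
        _disk_paint(nuclei, cell, cell.cell_radius, amp * config.cell_haze_fraction)

    if gt.n_particles:
        sigma_ln = np.sqrt(np.log1p(config.particle_intensity_cv**2))
        amps = config.particle_intensity_mean * rng.lognormal(
            -0.5 * sigma_ln**2, sigma_ln, gt.n_particles
        )
        _deposit(particles, gt.positions, amps)

    sigma_px = config.psf_sigma / px
    nuclei = gaussian_filter(nuclei, sigma_px)
    particles = gaussian_filter(particles, sigma_px)
    # spectral bleed-through of the bright nuclear stain into the particle
    # channel: the dominant source of background colocalization in FOVs that
    # contain cells but few particles
    if config.crosstalk > 0:
        particles = particles + config.crosstalk * nuclei

    illum = _vignette((h, w), config.vignetting)
    if config.shared_background_rel_sd > 0:
        amp = abs(rng.normal(0.0, config.shared_background_rel_sd))
        illum = illum * (1.0 + amp * _smooth_field((h, w), rng))
    illum = np.clip(illum, 0.0, None)

    max_adu = 2**config.bit_depth - 1
    out = []
    for canvas in (nuclei, particles):
        expected = (canvas + config.background_level) * illum
        observed = rng.poisson(np.clip(expected, 0, None)).astype(float)
        observed += rng.normal(0.0, config.read_noise_sd, (h, w))
        out.append(np.clip(np.rint(observed), 0, max_adu).astype(np.uint16))

    return FieldOfView(
        nuclei_channel=out[0],
        particle_channel=out[1],
        pixel_size=px,
        condition=condition,
        bit_depth=config.bit_depth,
    )


def generate_fov(
    config: SyntheticConfig, condition: ConditionLabel
) -> tuple[FieldOfView, GroundTruth]:
    """Generate one FOV: place cells, plant and wash particles, render.

    The condition's wash is applied to the ground truth before rendering, so
    the returned ground truth describes the particles actually imaged.
    """
    config.validate()
    rng = np.random.Generator(np.random.PCG64(config.seed))

    if condition.is_no_cell_control:
        n_cells = 0
    else:
        n_cells = max(int(round(rng.normal(config.n_cells_mean, config.n_cells_sd))), 0)
    cells = _place_cells(config, n_cells, rng)
    gt = _plant_particles(config, condition, cells, rng)
    gt = apply_wash(gt, condition.wash, config.wash_carryover, rng)
    fov = render(gt, config, condition, rng)
    return fov, gt


DesignEntry = tuple[SyntheticConfig, int]


def generate_experiment(
    design: Mapping[ConditionLabel, DesignEntry] | Sequence[tuple[ConditionLabel, SyntheticConfig, int]],
    master_seed: int,
) -> list[tuple[FieldOfView, GroundTruth]]:
    """Generate a batch of FOVs for a multi-condition design.

    Per-FOV seeds are derived deterministically from ``master_seed``; each
    FOV is tagged with its condition and a sequential ``fov_id``.
    """
    if isinstance(design, Mapping):
        entries = [(cond, cfg, n) for cond, (cfg, n) in design.items()]
    else:
        entries = list(design)
    seen: set[ConditionLabel] = set()
    for cond, _, n_fovs in entries:
        if cond in seen:
            raise ValidationError(f"duplicate condition label {cond.key}")
        seen.add(cond)
        if n_fovs < 1:
            raise ValidationError(f"n_fovs must be >= 1 for {cond.key}")

    seed_rng = np.random.Generator(np.random.PCG64(master_seed))
    out: list[tuple[FieldOfView, GroundTruth]] = []
    for cond, cfg, n_fovs in entries:
        seeds = seed_rng.integers(0, 2**31, size=n_fovs)
        for j, s in enumerate(seeds):
            fov, gt = generate_fov(cfg.replace(seed=int(s)), cond)
            fov.fov_id = f"{cond.group}_{cond.replicate_id}_{j:04d}"
            out.append((fov, gt))
    return out


#: Per-particle-size generator overrides.  200 nm particles carry more dye
#: (rendered brighter per particle) and, unlike 100 nm particles, remain
#: firmly adhered to the cell surface after a PBS wash.
SIZE_PRESETS = {
    100: {"adhered_fraction": 0.0, "internalized_fraction": 0.7, "particle_intensity_mean": 70.0},
    200: {"adhered_fraction": 0.3, "internalized_fraction": 0.5, "particle_intensity_mean": 110.0},
}


def default_design(
    particle_size_nm: int = 100,
    n_fovs: int = 130,
    base_config: SyntheticConfig | None = None,
    include_4c: bool = False,
    washes: Iterable[str] = ("trypsin", "pbs"),
) -> dict[ConditionLabel, DesignEntry]:
    """Build the standard design: three phenotypes x washes plus controls.

    Mirrors the study layout: HM/LM/benign cells washed with trypsin
    (internalized particles only) or PBS (internalized + adhered), one
    particles-without-cells control and one cells-without-particles control
    per particle size; optionally the 4 °C endocytosis-block conditions.
    """
    if particle_size_nm not in SIZE_PRESETS:
        raise ValidationError(f"no preset for particle size {particle_size_nm} nm")
    base = base_config if base_config is not None else SyntheticConfig()
    cfg = base.replace(**SIZE_PRESETS[particle_size_nm])

    design: dict[ConditionLabel, DesignEntry] = {}
    for phen in ("HM", "LM", "benign"):
        for wash in washes:
            cond = ConditionLabel(phen, wash, particle_size_nm, 37)
            design[cond] = (cfg, n_fovs)
    design[ConditionLabel("control_particles_only", "none", particle_size_nm, 37)] = (cfg, n_fovs)
    design[ConditionLabel("control_cells_only", "none", particle_size_nm, 37)] = (cfg, n_fovs)
    if include_4c:
        for wash in washes:
            cond = ConditionLabel("HM", wash, particle_size_nm, 4)
            design[cond] = (cfg, n_fovs)
    return design
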