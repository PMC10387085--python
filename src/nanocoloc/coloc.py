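"""Per-FOV colocalization statistics between particle and nuclei channels.

Four statistics are computed over the full FOV, with no mask and no
intensity threshold (the nuclei channel acts as a cell-position proxy, not a
compartment claim):

* Pearson correlation coefficient of the per-pixel intensities,
* Manders' linear overlap coefficient R = sum(xy) / sqrt(sum(x^2) sum(y^2)),
* slope and intercept of the ordinary least-squares scatter fit of particle
  intensity on nuclei intensity,
* the section cross-correlation: the image is divided into n equal sections
  (a sqrt(n) x sqrt(n) grid, n = 100 by default), per-section intensity sums
  are recorded for each channel, and

      CC = [n * sum(xy) - sum(x) sum(y)]
           / sqrt([n sum(x^2) - (sum x)^2] [n sum(y^2) - (sum y)^2])

  which is algebraically the Pearson correlation of the two section-sum
  vectors.

All accumulation happens in double precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import UndefinedStatisticError, ValidationError
from .synthetic import FieldOfView


@dataclass
class SectionGrid:
    """Per-section summed intensities of the two channels (row-major tiles)."""

    x_sums: np.ndarray  # particle channel
    y_sums: np.ndarray  # nuclei channel
    n: int

    def __post_init__(self) -> None:
        if len(self.x_sums) != self.n or len(self.y_sums) != self.n:
            raise ValidationError(
                f"section vectors must have length n={self.n}, got "
                f"{len(self.x_sums)} and {len(self.y_sums)}"
            )


@dataclass
class ColocalizationResult:
    pearson_r: float
    overlap_R: float
    slope: float
    intercept: float
    n_pixels: int
    section_cc: float | None = None
    n_sections: int | None = None


def _as_pair(ch_particles: np.ndarray, ch_nuclei: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(ch_particles, dtype=float)
    y = np.asarray(ch_nuclei, dtype=float)
    if x.shape != y.shape:
        raise ValidationError(f"channel shapes differ: {x.shape} vs {y.shape}")
    if x.size < 2:
        raise ValidationError("need at least 2 pixels")
    return x.ravel(), y.ravel()


def pearson_coefficient(ch_particles: np.ndarray, ch_nuclei: np.ndarray) -> float:
    """Pearson correlation of per-pixel intensities over the full FOV."""
    x, y = _as_pair(ch_particles, ch_nuclei)
    xc = x - x.mean()
    yc = y - y.mean()
    sx = math.sqrt(float(xc @ xc))
    sy = math.sqrt(float(yc @ yc))
    if sx == 0 or sy == 0:
        raise UndefinedStatisticError(
            "Pearson correlation is undefined for a constant channel"
        )
    return float(xc @ yc) / (sx * sy)


def overlap_coefficient(ch_particles: np.ndarray, ch_nuclei: np.ndarray) -> float:
    """Manders' linear overlap coefficient R (intensities taken non-negative)."""
    x, y = _as_pair(ch_particles, ch_nuclei)
    x = np.abs(x)
    y = np.abs(y)
    sxx = float(x @ x)
    syy = float(y @ y)
    if sxx == 0 or syy == 0:
        raise UndefinedStatisticError("overlap coefficient undefined for all-zero channel")
    return float(x @ y) / math.sqrt(sxx * syy)


def scatter_fit(ch_particles: np.ndarray, ch_nuclei: np.ndarray) -> tuple[float, float]:
    """OLS fit of particle intensity on nuclei intensity: (slope, intercept)."""
    x, y = _as_pair(ch_particles, ch_nuclei)
    # predictor = nuclei channel, response = particle channel
    ym = y.mean()
    yc = y - ym
    denom = float(yc @ yc)
    if denom == 0:
        raise UndefinedStatisticError("scatter fit undefined: constant nuclei channel")
    slope = float(yc @ (x - x.mean())) / denom
    intercept = float(x.mean() - slope * ym)
    return slope, intercept


def make_sections(ch: np.ndarray, n: int = 100) -> np.ndarray:
    """Divide the raster into n equal sections and return per-section sums.

    n must be a perfect square g^2; the image is center-cropped to the
    largest multiple of g in each dimension, then tiled into a g x g grid of
    equal rectangles.  Sums are returned in row-major tile order.
    """
    img = np.asarray(ch, dtype=float)
    if img.ndim != 2:
        raise ValidationError("make_sections expects a 2D raster")
    if n < 2:
        raise ValidationError("n must be >= 2")
    g = math.isqrt(n)
    if g * g != n:
        raise ValidationError(f"n must be a perfect square, got {n}")
    h, w = img.shape
    if h < g or w < g:
        raise ValidationError(f"image {h}x{w} smaller than the {g}x{g} section grid")
    th, tw = (h // g) * g, (w // g) * g
    r0 = (h - th) // 2
    c0 = (w - tw) // 2
    img = img[r0 : r0 + th, c0 : c0 + tw]
    return img.reshape(g, th // g, g, tw // g).sum(axis=(1, 3)).ravel()


def section_grid(ch_particles: np.ndarray, ch_nuclei: np.ndarray, n: int = 100) -> SectionGrid:
    """Build the per-section sum vectors for both channels (identical crop)."""
    x, y = _as_pair(ch_particles, ch_nuclei)  # shape check
    del x, y
    return SectionGrid(
        x_sums=make_sections(ch_particles, n),
        y_sums=make_sections(ch_nuclei, n),
        n=n,
    )


def section_cross_correlation(grid: SectionGrid) -> float:
    """Cross-correlation coefficient of the per-section intensity sums.

    Evaluates CC = [n sum(xy) - sum(x) sum(y)] /
    sqrt([n sum(x^2) - (sum x)^2][n sum(y^2) - (sum y)^2]) in double
    precision (numpy pairwise summation stabilizes the cancellation).
    """
    x = np.asarray(grid.x_sums, dtype=float)
    y = np.asarray(grid.y_sums, dtype=float)
    n = grid.n
    sx = float(np.sum(x))
    sy = float(np.sum(y))
    sxx = float(np.sum(x * x))
    syy = float(np.sum(y * y))
    sxy = float(np.sum(x * y))
    vx = n * sxx - sx * sx
    vy = n * syy - sy * sy
    if vx <= 0 or vy <= 0:
        raise UndefinedStatisticError(
            "section cross-correlation undefined for a constant section vector"
        )
    return (n * sxy - sx * sy) / math.sqrt(vx * vy)


def analyze_fov(
    fov: FieldOfView,
    n_sections: int | None = 100,
    background_subtract: float = 0.0,
) -> ColocalizationResult:
    """Compute all per-FOV colocalization statistics.

    ``background_subtract`` optionally removes a constant offset from both
    channels before analysis (clamped at zero); the default of 0 analyzes
    raw intensities.  ``n_sections=None`` skips the section statistic.
    """
    p = np.asarray(fov.particle_channel, dtype=float)
    nuc = np.asarray(fov.nuclei_channel, dtype=float)
    if background_subtract:
        p = np.clip(p - background_subtract, 0, None)
        nuc = np.clip(nuc - background_subtract, 0, None)

    r = pearson_coefficient(p, nuc)
    overlap = overlap_coefficient(p, nuc)
    slope, intercept = scatter_fit(p, nuc)

    cc = None
    if n_sections is not None:
        grid = section_grid(p, nuc, n_sections)
        cc = section_cross_correlation(grid)

    return ColocalizationResult(
        pearson_r=r,
        overlap_R=overlap,
        slope=slope,
        intercept=intercept,
        n_pixels=p.size,
        section_cc=cc,
        n_sections=n_sections,
    )
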