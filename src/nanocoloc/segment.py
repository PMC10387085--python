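"""Nuclei segmentation and field-of-view quality control.

Cells are counted by segmenting the nuclei channel: Gaussian smoothing,
global Otsu threshold, hole filling, 8-connected labeling and an area filter.
QC then applies the study's inclusion rules: a FOV enters the analysis only
if it contains more than four cells (i.e. at least five) and shows no imaging
artifacts, operationalized here as particle-channel saturation (proxy for
overexpression) and a variance-of-Laplacian focus floor (proxy for focal
depth changes).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label

from .errors import ValidationError
from .synthetic import FieldOfView

logger = logging.getLogger(__name__)

LOW_CELL_COUNT = "LOW_CELL_COUNT"
OVEREXPOSED = "OVEREXPOSED"
OUT_OF_FOCUS = "OUT_OF_FOCUS"


@dataclass
class NucleiLabels:
    """Connected-component labeling of the nuclei channel.

    ``label_raster`` holds 0 for background and 1..n_nuclei for nuclei;
    labels are contiguous and every component's area lies within the
    configured bounds.
    """

    label_raster: np.ndarray
    n_nuclei: int
    areas: list[int]


@dataclass
class QCReport:
    fov_id: str
    n_cells: int
    saturation_fraction: float
    focus_metric: float
    passed: bool = True
    reasons: list[str] = field(default_factory=list)


def segment_nuclei(
    nuclei_channel: np.ndarray,
    min_area: int = 8,
    max_area: int = 400,
    smoothing_sigma: float = 1.0,
    min_contrast: float = 4.0,
) -> NucleiLabels:
    """Segment nuclei and return contiguous labels filtered by area.

    A constant raster, or one whose Otsu split does not separate foreground
    from background by at least ``min_contrast`` background standard
    deviations, yields zero nuclei rather than an error: such FOVs (e.g.
    particles-without-cells controls) genuinely contain no nuclear signal.
    """
    if nuclei_channel.size == 0:
        raise ValidationError("empty nuclei raster")
    if min_area >= max_area:
        raise ValidationError(f"min_area ({min_area}) must be < max_area ({max_area})")

    img = np.asarray(nuclei_channel, dtype=float)
    empty = NucleiLabels(np.zeros(img.shape, dtype=np.int32), 0, [])
    if np.ptp(img) == 0:
        return empty

    smoothed = ndimage.gaussian_filter(img, smoothing_sigma)
    thr = threshold_otsu(smoothed)
    mask = smoothed > thr
    if not mask.any() or mask.all():
        return empty

    # Reject a noise-only split: require real foreground/background contrast.
    bg = smoothed[~mask]
    contrast = (smoothed[mask].mean() - bg.mean()) / max(bg.std(), 1e-9)
    if contrast < min_contrast:
        return empty

    mask = ndimage.binary_fill_holes(mask)
    labeled = cc_label(mask, connectivity=2)
    areas = np.bincount(labeled.ravel())
    out = np.zeros(img.shape, dtype=np.int32)
    kept_areas: list[int] = []
    next_label = 0
    for lbl in range(1, len(areas)):
        if min_area <= areas[lbl] <= max_area:
            next_label += 1
            out[labeled == lbl] = next_label
            kept_areas.append(int(areas[lbl]))
    return NucleiLabels(out, next_label, kept_areas)


def variance_of_laplacian(raster: np.ndarray) -> float:
    """Classic focus score: variance of the Laplacian response."""
    return float(ndimage.laplace(np.asarray(raster, dtype=float)).var())


def assess_fov(
    fov: FieldOfView,
    labels: NucleiLabels,
    min_cells: int = 5,
    max_saturation: float = 0.01,
    min_focus: float = 50.0,
) -> QCReport:
    """Apply the inclusion rules to one FOV; always returns a report.

    "More than four cells" is read strictly: n_cells >= 5 passes.  FOVs of
    the particles-without-cells control bypass the cell-count rule (they
    contain no cells by design).
    """
    reasons: list[str] = []
    n_cells = labels.n_nuclei
    if n_cells < min_cells and not fov.condition.is_no_cell_control:
        reasons.append(LOW_CELL_COUNT)

    max_adu = 2**fov.bit_depth - 1
    saturation = float(np.mean(fov.particle_channel >= max_adu))
    if saturation > max_saturation:
        reasons.append(OVEREXPOSED)

    focus = variance_of_laplacian(fov.nuclei_channel)
    if focus < min_focus:
        reasons.append(OUT_OF_FOCUS)

    return QCReport(
        fov_id=fov.fov_id,
        n_cells=n_cells,
        saturation_fraction=saturation,
        focus_metric=focus,
        passed=not reasons,
        reasons=reasons,
    )


def filter_fovs(
    reports: list[QCReport],
    fovs: list[FieldOfView],
    min_per_condition: int = 110,
) -> list[FieldOfView]:
    """Return the FOVs whose QC report passed, preserving order.

    Logs per-condition pass counts and warns when a condition retains fewer
    than ``min_per_condition`` FOVs.
    """
    if len(reports) != len(fovs):
        raise ValidationError(
            f"got {len(reports)} reports for {len(fovs)} FOVs; one report per FOV required"
        )
    passing = [fov for rep, fov in zip(reports, fovs) if rep.passed]
    counts: dict[str, int] = {}
    for fov in passing:
        counts[fov.condition.group] = counts.get(fov.condition.group, 0) + 1
    for group, n in sorted(counts.items()):
        logger.info("QC: condition %s retains %d FOVs", group, n)
        if n < min_per_condition:
            logger.warning(
                "QC: condition %s retains only %d FOVs (< %d)", group, n, min_per_condition
            )
    if not passing:
        logger.warning("QC: no FOVs passed quality control")
    return passing
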