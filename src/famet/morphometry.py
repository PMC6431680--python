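"""Whole-cell and adhesion size/shape metrics.

Seven metrics form the classifier feature vector, numbered I-VII:

I   ellipticity      moment-invariant shape measure, 1 for any ellipse
II  rectangularity   area / axis-aligned bounding-box area
III cell area        spreading area, µm²
IV  FA size          mean mature-adhesion area, µm²
V   FA aspect ratio  mean major/minor of the moment-equivalent ellipse
VI  E-slope          origin-constrained slope of the E-function, 1/µm
VII G-function       mean nearest-neighbor distance of mature FAs, µm

Solidity, adhesion count and adhesion coverage are computed as auxiliary
metrics but are kept out of the default classifier feature set.

Ellipticity uses the affine moment invariant of second-order central
moments: with central moments m20, m02, m11 and area m00,

    J = (m20 * m02 - m11**2) / m00**4

J equals 1/(16 pi^2) for every filled ellipse; the metric folds J around
that peak so it lies in [0, 1] and equals 1 exactly at an ellipse.
Rectangularity deliberately uses the *axis-aligned* bounding box, so it is
not rotation invariant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from skimage import measure

from .segmentation import FocalAdhesion, Maturity, SegmentationResult

#: ordered classifier feature names (I-VII)
FEATURE_COLUMNS = [
    "ellipticity",
    "rectangularity",
    "cell_area_um2",
    "fa_size_um2",
    "fa_aspect_ratio",
    "e_slope_per_um",
    "g_mean_um",
]

AUX_COLUMNS = ["solidity", "fa_count", "fa_coverage_pct", "n_nascent"]

_ELLIPSE_J = 1.0 / (16.0 * math.pi**2)


def _check_mask(mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    return mask


def cell_area(mask: np.ndarray, pixel_size: float) -> float:
    """Spreading area in µm²: foreground pixel count x pixel_size²."""
    mask = _check_mask(mask)
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    return float(mask.sum()) * pixel_size**2


def ellipticity(mask: np.ndarray) -> float:
    """Moment-invariant ellipticity in [0, 1], peaking at 1 for ellipses."""
    mask = _check_mask(mask)
    mu = measure.moments_central(mask.astype(float), order=2)
    m00 = mu[0, 0]
    # moments_central indexes [row_order, col_order]
    m20, m02, m11 = mu[2, 0], mu[0, 2], mu[1, 1]
    if m20 <= 0 or m02 <= 0:
        raise ValueError("degenerate mask: zero variance along an axis")
    j = (m20 * m02 - m11**2) / m00**4
    if j <= 0:
        raise ValueError("degenerate mask: collinear pixel set")
    if j <= _ELLIPSE_J:
        return float(j / _ELLIPSE_J)
    return float(_ELLIPSE_J / j)


def rectangularity(mask: np.ndarray) -> float:
    """Area over axis-aligned bounding-box area, in (0, 1]."""
    mask = _check_mask(mask)
    rows, cols = np.nonzero(mask)
    h = rows.max() - rows.min() + 1
    w = cols.max() - cols.min() + 1
    return float(mask.sum()) / float(h * w)


def solidity(mask: np.ndarray) -> float:
    """Area over convex-hull area, in (0, 1]; low values mean concave outline."""
    mask = _check_mask(mask)
    labeled = mask.astype(np.uint8)
    rp = measure.regionprops(labeled)[0]
    return float(rp.solidity)


def fa_shape_metrics(fa: FocalAdhesion) -> tuple[float, float]:
    """(size µm², aspect ratio) of one adhesion; ratio from the
    moment-equivalent ellipse and always >= 1."""
    return fa.area, fa.aspect_ratio


@dataclass
class CellFeatureVector:
    """Feature vector for one cell; classifier metrics may be missing
    (None) when the cell has too few mature adhesions."""

    cell_id: str
    class_label: str | None
    ellipticity: float
    rectangularity: float
    cell_area_um2: float
    fa_size_um2: float | None
    fa_aspect_ratio: float | None
    e_slope_per_um: float | None
    g_mean_um: float | None
    solidity: float
    fa_count: int
    fa_coverage_pct: float
    n_nascent: int
    qc_flags: tuple[str, ...] = field(default_factory=tuple)

    @property
    def complete(self) -> bool:
        """True when all seven classifier metrics are defined."""
        return all(
            getattr(self, c) is not None for c in FEATURE_COLUMNS
        )

    def as_dict(self) -> dict:
        d = {"cell_id": self.cell_id, "class": self.class_label}
        for c in FEATURE_COLUMNS + AUX_COLUMNS:
            d[c] = getattr(self, c)
        d["qc_flags"] = ";".join(self.qc_flags)
        return d


def assemble_features(
    seg: SegmentationResult,
    cell_id: str = "cell",
    class_label: str | None = None,
) -> CellFeatureVector:
    """Build the per-cell feature vector from a segmentation result.

    IV and V are means over mature adhesions; VI and VII come from the
    spatial statistics of mature-adhesion centroids relative to the nucleus
    centroid. Cells with no mature adhesion get IV-VII missing; VII also
    needs at least two adhesions. Missing entries are recorded as None and
    the cell is flagged rather than imputed.
    """
    from . import spatial  # local import to avoid a cycle

    px = seg.pixel_size
    area = cell_area(seg.cell_mask, px)
    mature = seg.mature
    flags: list[str] = []

    fa_size = fa_ar = e_slope_v = g_mean = None
    if mature:
        fa_size = float(np.mean([fa.area for fa in mature]))
        fa_ar = float(np.mean([fa.aspect_ratio for fa in mature]))
        if any(fa.degenerate_axes for fa in mature):
            flags.append("degenerate_fa_axes")
        centroids = np.array([fa.centroid for fa in mature])
        rows, cols = np.nonzero(seg.nucleus_mask)
        nuc_centroid = (float(cols.mean()) * px, float(rows.mean()) * px)
        dists = np.hypot(
            centroids[:, 0] - nuc_centroid[0], centroids[:, 1] - nuc_centroid[1]
        )
        if np.any(dists > 0):
            e_slope_v = spatial.e_slope(spatial.e_function(centroids, nuc_centroid))
        else:
            flags.append("all_fas_at_nucleus_centroid")
        if len(mature) >= 2:
            g_mean = spatial.cell_g(spatial.g_function(centroids))
        else:
            flags.append("single_mature_fa")
    else:
        flags.append("no_mature_fa")

    coverage = 100.0 * sum(fa.area for fa in mature) / area if mature else 0.0
    return CellFeatureVector(
        cell_id=cell_id,
        class_label=class_label,
        ellipticity=ellipticity(seg.cell_mask),
        rectangularity=rectangularity(seg.cell_mask),
        cell_area_um2=area,
        fa_size_um2=fa_size,
        fa_aspect_ratio=fa_ar,
        e_slope_per_um=e_slope_v,
        g_mean_um=g_mean,
        solidity=solidity(seg.cell_mask),
        fa_count=len(mature),
        fa_coverage_pct=coverage,
        n_nascent=len(seg.nascent),
        qc_flags=tuple(flags),
    )
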