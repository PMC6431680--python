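"""Synthetic 3-channel single-cell scenes with full ground truth.

Real confocal data for this kind of study are rarely shareable, so the
package ships a generator that emulates the four confinement-state
archetypes a fibrous-substrate experiment produces:

* **A** — well-spread, elongated elliptical cells with elongated adhesions
  distributed across the whole cell body (flat-substrate phenotype).
* **B** — a high-variance mixture of spread lamellar shapes (dense random
  fiber mesh phenotype); its within-class variance is deliberately the
  largest of the four.
* **C** — small, poorly spread cells with few, small adhesions (sparse
  random fiber mesh phenotype); smallest cell area of the four.
* **D** — triangular cells with concave (inward-bowed) edges and large,
  weakly elongated adhesions clustered around the nucleus (woven
  micro-fiber phenotype); lowest solidity of the four.

Each scene is rendered as red (actin: filled cell body with fiber-like
texture), green (vinculin: adhesion puncta over a dim cytosolic background
restricted to the cell) and blue (nucleus ellipse) channels, with additive
Gaussian noise, and carries its ground-truth masks, adhesion centroids,
areas and maturity bins. Fixed seeds give bit-identical scenes.

Alongside image scenes, :func:`sample_feature_table` draws ready-made
7-feature tables from class-conditional Gaussians, for testing the
classification stage in isolation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import draw
from scipy.ndimage import gaussian_filter

from .morphometry import FEATURE_COLUMNS

CLASS_LABELS = ("A", "B", "C", "D")


@dataclass(frozen=True)
class ClassArchetype:
    """Numeric description of one confinement-state class.

    Areas are µm²; ``fa_size_lognormal`` holds (mean, sigma) of log adhesion
    area so that sizes straddle the 0.1/0.2 µm² triage cutoffs;
    ``placement_scale`` (µm) is the spread of the perinuclear cluster and
    the decay length of edge bias; ``intra_class_variance`` multiplies the
    shape-noise amplitude.
    """

    label: str
    shape_family: str  # ellipse | lamellar_blob | small_blob | triangle
    cell_area_range: tuple[float, float]
    fa_count_range: tuple[int, int]
    fa_size_lognormal: tuple[float, float]
    fa_elongation_range: tuple[float, float]
    fa_placement: str  # body_wide | edge_biased | perinuclear_clustered
    placement_scale: float = 6.0
    intra_class_variance: float = 1.0

    def __post_init__(self) -> None:
        if self.cell_area_range[0] >= self.cell_area_range[1]:
            raise ValueError("cell_area_range must be an increasing interval")
        if self.fa_elongation_range[0] < 1.0:
            raise ValueError("adhesion elongation must be >= 1")


#: default archetypes; ranges are package design choices that realize the
#: qualitative class descriptions above (C smallest area, B most variable,
#: D concave/perinuclear with the largest, roundest adhesions).
ARCHETYPES: dict[str, ClassArchetype] = {
    "A": ClassArchetype(
        label="A",
        shape_family="ellipse",
        cell_area_range=(600.0, 1000.0),
        fa_count_range=(25, 45),
        fa_size_lognormal=(math.log(0.45), 0.7),
        fa_elongation_range=(2.0, 3.5),
        fa_placement="body_wide",
        intra_class_variance=1.0,
    ),
    "B": ClassArchetype(
        label="B",
        shape_family="lamellar_blob",
        cell_area_range=(200.0, 1200.0),
        fa_count_range=(6, 45),
        fa_size_lognormal=(math.log(0.5), 0.9),
        fa_elongation_range=(1.2, 3.5),
        fa_placement="body_wide",
        intra_class_variance=2.5,
    ),
    "C": ClassArchetype(
        label="C",
        shape_family="small_blob",
        cell_area_range=(120.0, 320.0),
        fa_count_range=(5, 14),
        fa_size_lognormal=(math.log(0.3), 0.9),
        fa_elongation_range=(1.2, 2.4),
        fa_placement="edge_biased",
        placement_scale=1.5,
        intra_class_variance=1.0,
    ),
    "D": ClassArchetype(
        label="D",
        shape_family="triangle",
        cell_area_range=(400.0, 800.0),
        fa_count_range=(15, 30),
        fa_size_lognormal=(math.log(0.9), 1.0),
        fa_elongation_range=(1.0, 1.6),
        fa_placement="perinuclear_clustered",
        placement_scale=3.0,
        intra_class_variance=0.8,
    ),
}


@dataclass(frozen=True)
class SceneConfig:
    """Rendering parameters shared by all scenes of a run."""

    image_size: tuple[int, int] = (448, 448)
    pixel_size: float = 0.15  # µm per pixel
    z_planes: int = 1
    noise_sd: float = 0.03
    cytosolic_green_level: float = 0.08
    border_margin: int = 3  # px the cell must keep clear of the border

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.z_planes < 1:
            raise ValueError("z_planes must be >= 1")


@dataclass
class GroundTruth:
    """Rendered truth for one scene; coordinates in µm (x right, y down)."""

    cell_mask: np.ndarray
    nucleus_mask: np.ndarray
    fa_centroids: np.ndarray  # (n, 2) in µm
    fa_areas: np.ndarray  # µm²
    fa_maturity: list[str]  # background | nascent | mature


@dataclass
class CellScene:
    """One calibrated multi-channel scene, optionally with ground truth."""

    channels: dict[str, np.ndarray]
    pixel_size: float
    ground_truth: GroundTruth | None = None
    class_label: str | None = None

    def __post_init__(self) -> None:
        shapes = {c: a.shape for c, a in self.channels.items()}
        if len(set(shapes.values())) != 1:
            raise ValueError(f"channel shapes differ: {shapes}")


class SceneGenerationError(RuntimeError):
    """The requested cell could not be placed inside the image."""


# ---------------------------------------------------------------------------
# shape outlines (in µm, centered at the origin)

def _close_ring(theta: np.ndarray, radius: np.ndarray) -> np.ndarray:
    return np.column_stack([radius * np.cos(theta), radius * np.sin(theta)])


def _polygon_area(poly: np.ndarray) -> float:
    x, y = poly[:, 0], poly[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def _ellipse_outline(rng: np.random.Generator, variance: float) -> np.ndarray:
    ar = rng.uniform(1.8, 2.8)
    theta = np.linspace(0, 2 * np.pi, 720, endpoint=False)
    a, b = math.sqrt(ar / math.pi), math.sqrt(1.0 / (ar * math.pi))  # unit area
    r = (a * b) / np.sqrt((b * np.cos(theta)) ** 2 + (a * np.sin(theta)) ** 2)
    wobble = _radial_wobble(rng, theta, 0.025 * variance)
    return _close_ring(theta, r * (1 + wobble))


def _radial_wobble(
    rng: np.random.Generator, theta: np.ndarray, amplitude: float
) -> np.ndarray:
    out = np.zeros_like(theta)
    for k in range(2, 7):
        out += rng.normal(0, amplitude / k) * np.cos(
            k * theta + rng.uniform(0, 2 * np.pi)
        )
    return out


def _blob_outline(
    rng: np.random.Generator,
    variance: float,
    base_amplitude: float,
    stretch_gain: float,
) -> np.ndarray:
    """Wobbled blob with per-scene anisotropy.

    Both the wobble amplitude and the elongation are drawn per scene over
    ranges that grow with ``variance``, so a high-variance class produces a
    mixture running from near-elliptical spread shapes to small irregular
    ones rather than one stereotyped outline.
    """
    theta = np.linspace(0, 2 * np.pi, 720, endpoint=False)
    amp = rng.uniform(0.02, base_amplitude * variance)
    r = 1.0 + _radial_wobble(rng, theta, amp)
    ring = _close_ring(theta, np.clip(r, 0.2, None))
    stretch = rng.uniform(1.0, 1.0 + stretch_gain * variance)
    ring[:, 0] *= stretch
    return ring


def _triangle_outline(rng: np.random.Generator, variance: float) -> np.ndarray:
    """Triangle with edges bowed toward the centroid (concave sides)."""
    base = rng.uniform(0, 2 * np.pi)
    angles = base + np.array([0.0, 2 * np.pi / 3, 4 * np.pi / 3])
    angles += rng.uniform(-0.25, 0.25, size=3)
    radii = 1.0 + rng.uniform(-0.12, 0.12, size=3)
    verts = np.column_stack([radii * np.cos(angles), radii * np.sin(angles)])
    bow = rng.uniform(0.12, 0.22) * min(variance, 1.5)
    pts = []
    for i in range(3):
        p, q = verts[i], verts[(i + 1) % 3]
        t = np.linspace(0, 1, 80, endpoint=False)
        edge = np.outer(1 - t, p) + np.outer(t, q)
        # bow each edge inward, toward the triangle centroid
        inward = -edge / np.linalg.norm(edge, axis=1, keepdims=True)
        edge = edge + inward * (bow * np.sin(np.pi * t))[:, None]
        pts.append(edge)
    return np.vstack(pts)


_OUTLINES = {
    "ellipse": lambda rng, var: _ellipse_outline(rng, var),
    "lamellar_blob": lambda rng, var: _blob_outline(rng, var, 0.075, 0.64),
    "small_blob": lambda rng, var: _blob_outline(rng, var, 0.05, 0.30),
    "triangle": lambda rng, var: _triangle_outline(rng, var),
}


def _rasterize(poly_um: np.ndarray, shape: tuple[int, int], pixel_size: float
               ) -> np.ndarray:
    rows = poly_um[:, 1] / pixel_size
    cols = poly_um[:, 0] / pixel_size
    rr, cc = draw.polygon(rows, cols, shape=shape)
    mask = np.zeros(shape, dtype=bool)
    mask[rr, cc] = True
    return mask


# ---------------------------------------------------------------------------
# scene assembly

def _render_cell_mask(
    archetype: ClassArchetype, config: SceneConfig, rng: np.random.Generator
) -> np.ndarray:
    h, w = config.image_size
    px = config.pixel_size
    margin = config.border_margin
    target_area = rng.uniform(*archetype.cell_area_range)
    for _ in range(25):
        outline = _OUTLINES[archetype.shape_family](rng, archetype.intra_class_variance)
        rot = rng.uniform(0, 2 * np.pi)
        c, s = math.cos(rot), math.sin(rot)
        outline = outline @ np.array([[c, -s], [s, c]])
        outline *= math.sqrt(target_area / _polygon_area(outline))
        center = np.array([w, h]) * px / 2
        center += rng.uniform(-3, 3, size=2)  # µm jitter
        poly = outline + center
        rows = poly[:, 1] / px
        cols = poly[:, 0] / px
        if (
            rows.min() < margin
            or cols.min() < margin
            or rows.max() > h - 1 - margin
            or cols.max() > w - 1 - margin
        ):
            continue
        mask = _rasterize(poly, (h, w), px)
        if mask.any():
            return mask
    raise SceneGenerationError(
        f"cell of area {target_area:.0f} µm² does not fit in a "
        f"{h}x{w} image at {px} µm/px after 25 attempts"
    )


def _render_nucleus(
    cell_mask: np.ndarray, config: SceneConfig, rng: np.random.Generator
) -> np.ndarray:
    px = config.pixel_size
    cell_area = cell_mask.sum() * px**2
    nuc_area = float(np.clip(0.22 * cell_area, 35.0, 130.0))
    dist = ndimage.distance_transform_edt(cell_mask) * px
    cy, cx = np.unravel_index(np.argmax(dist), dist.shape)
    ar = rng.uniform(1.1, 1.5)
    a = math.sqrt(nuc_area * ar / math.pi)  # semi-major, µm
    # shrink until the ellipse fits inside the cell at the deepest point
    max_r = dist[cy, cx] * 0.95
    if a > max_r:
        a = max_r
    b = max(a / ar, 1.5 * px)
    rot = rng.uniform(0, np.pi)
    rr, cc = draw.ellipse(
        cy, cx, a / px, b / px, shape=cell_mask.shape, rotation=rot
    )
    nucleus = np.zeros_like(cell_mask)
    nucleus[rr, cc] = True
    return nucleus & cell_mask


def _sample_fa_positions(
    n: int,
    cell_mask: np.ndarray,
    nucleus_mask: np.ndarray,
    placement: str,
    scale_um: float,
    px: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """FA anchor positions (row, col) in pixels, inside the eroded cell."""
    interior = ndimage.binary_erosion(cell_mask, iterations=2)
    if not interior.any():
        interior = cell_mask
    rows, cols = np.nonzero(interior)
    if placement == "body_wide":
        idx = rng.choice(rows.size, size=n, replace=True)
        return np.column_stack([rows[idx], cols[idx]]).astype(float)
    if placement == "edge_biased":
        # adhesions hug the periphery: exponential bias toward the edge,
        # excluding the nucleus footprint
        outside_nucleus = ~nucleus_mask[rows, cols]
        if outside_nucleus.any():
            rows, cols = rows[outside_nucleus], cols[outside_nucleus]
        dist = ndimage.distance_transform_edt(cell_mask)[rows, cols] * px
        w = np.exp(-dist / max(scale_um, 1e-6))
        w /= w.sum()
        idx = rng.choice(rows.size, size=n, replace=True, p=w)
        return np.column_stack([rows[idx], cols[idx]]).astype(float)
    if placement == "perinuclear_clustered":
        nrows, ncols = np.nonzero(nucleus_mask if nucleus_mask.any() else cell_mask)
        center = np.array([nrows.mean(), ncols.mean()])
        sigma_px = scale_um / px
        out = []
        while len(out) < n:
            cand = center + rng.normal(0, sigma_px, size=2)
            r, c = int(round(cand[0])), int(round(cand[1]))
            if 0 <= r < cell_mask.shape[0] and 0 <= c < cell_mask.shape[1]:
                if interior[r, c]:
                    out.append([cand[0], cand[1]])
        return np.array(out)
    raise ValueError(f"unknown placement {placement!r}")


def _stamp_adhesions(
    archetype: ClassArchetype,
    config: SceneConfig,
    cell_mask: np.ndarray,
    nucleus_mask: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, GroundTruth]:
    """Render adhesion puncta; returns (green intensity, ground truth)."""
    h, w = cell_mask.shape
    px = config.pixel_size
    n = int(rng.integers(archetype.fa_count_range[0], archetype.fa_count_range[1] + 1))
    positions = _sample_fa_positions(
        n, cell_mask, nucleus_mask, archetype.fa_placement,
        archetype.placement_scale, px, rng,
    )
    mu, sigma = archetype.fa_size_lognormal
    areas_um = rng.lognormal(mu, sigma, size=n)
    elong = rng.uniform(*archetype.fa_elongation_range, size=n)
    orient = rng.uniform(0, np.pi, size=n)

    green = np.zeros((h, w), dtype=np.float64)
    label_img = np.zeros((h, w), dtype=np.int32)
    centroids, areas, maturity = [], [], []
    k = 0
    for i in range(n):
        area_px = areas_um[i] / px**2
        a = math.sqrt(area_px * elong[i] / math.pi)  # semi-axes in px
        b = max(a / elong[i], 0.5)
        rr, cc = draw.ellipse(
            positions[i, 0], positions[i, 1], a, b,
            shape=(h, w), rotation=orient[i],
        )
        if rr.size == 0:  # sub-pixel footprint: light the anchor pixel
            rr = np.array([int(round(positions[i, 0]))])
            cc = np.array([int(round(positions[i, 1]))])
        inside = cell_mask[rr, cc]
        rr, cc = rr[inside], cc[inside]
        if rr.size == 0:
            continue
        if label_img[rr, cc].any():  # overlap would corrupt ground truth
            continue
        k += 1
        label_img[rr, cc] = k
        green[rr, cc] = rng.uniform(0.75, 1.0)
        area = rr.size * px**2
        centroids.append((cc.mean() * px, rr.mean() * px))
        areas.append(area)
        if area < 0.1:
            maturity.append("background")
        elif area < 0.2:
            maturity.append("nascent")
        else:
            maturity.append("mature")
    truth = GroundTruth(
        cell_mask=cell_mask,
        nucleus_mask=nucleus_mask,
        fa_centroids=np.array(centroids).reshape(-1, 2),
        fa_areas=np.array(areas),
        fa_maturity=maturity,
    )
    return green, truth


def _fiber_texture(
    cell_mask: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Fiber-like actin texture: blurred random chords across the cell."""
    h, w = cell_mask.shape
    rows, cols = np.nonzero(cell_mask)
    tex = np.zeros((h, w), dtype=np.float64)
    n_fibers = max(10, rows.size // 1500)
    for _ in range(n_fibers):
        i, j = rng.integers(0, rows.size, size=2)
        rr, cc, val = draw.line_aa(rows[i], cols[i], rows[j], cols[j])
        tex[rr, cc] += val
    tex = gaussian_filter(tex, 1.0)
    if tex.max() > 0:
        tex /= tex.max()
    return tex


def _to_stack(img: np.ndarray, config: SceneConfig, rng: np.random.Generator
              ) -> np.ndarray:
    """Optionally expand to a z-stack with per-plane attenuation, add noise."""
    if config.z_planes == 1:
        noisy = img + rng.normal(0, config.noise_sd, img.shape) if config.noise_sd > 0 else img
        return np.clip(noisy, 0.0, 1.0).astype(np.float32)
    focus = (config.z_planes - 1) // 2  # integer: the focal plane is unattenuated
    planes = []
    for z in range(config.z_planes):
        att = math.exp(-0.4 * abs(z - focus))
        plane = img * att
        if config.noise_sd > 0:
            plane = plane + rng.normal(0, config.noise_sd, img.shape)
        planes.append(np.clip(plane, 0.0, 1.0))
    return np.stack(planes).astype(np.float32)


def generate_scene(
    archetype: ClassArchetype | str,
    config: SceneConfig | None = None,
    rng_seed: int | np.random.SeedSequence = 0,
) -> CellScene:
    """Render one synthetic cell scene with ground truth.

    Identical (archetype, config, rng_seed) triples give bit-identical
    scenes. Raises :class:`SceneGenerationError` if the drawn cell cannot
    be placed inside the image after bounded retries.
    """
    if isinstance(archetype, str):
        archetype = ARCHETYPES[archetype]
    config = config or SceneConfig()
    rng = np.random.default_rng(rng_seed)

    cell = _render_cell_mask(archetype, config, rng)
    nucleus = _render_nucleus(cell, config, rng)
    green_fa, truth = _stamp_adhesions(archetype, config, cell, nucleus, rng)

    red = cell * (0.45 + 0.35 * _fiber_texture(cell, rng))
    blue = nucleus * 0.85
    green = np.where(
        green_fa > 0, green_fa, config.cytosolic_green_level * cell
    )

    channels = {
        "red": _to_stack(red, config, rng),
        "green": _to_stack(green, config, rng),
        "blue": _to_stack(blue, config, rng),
    }
    return CellScene(
        channels=channels,
        pixel_size=config.pixel_size,
        ground_truth=truth,
        class_label=archetype.label,
    )


def generate_population(
    n_per_class: int,
    config: SceneConfig | None = None,
    master_seed: int = 0,
    archetypes: dict[str, ClassArchetype] | None = None,
) -> list[CellScene]:
    """``n_per_class`` scenes for each class A-D, seeded from ``master_seed``.

    Per-scene seeds are spawned deterministically, so the population is
    reproducible and individual scenes can be regenerated in isolation.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    archetypes = archetypes or ARCHETYPES
    scenes = []
    for ci, label in enumerate(sorted(archetypes)):
        for i in range(n_per_class):
            ss = np.random.SeedSequence(master_seed, spawn_key=(ci, i))
            scenes.append(generate_scene(archetypes[label], config, ss))
    return scenes


# ---------------------------------------------------------------------------
# class-conditional feature tables

_REALISTIC_MEANS = {
    #           I      II     III    IV    V     VI     VII
    "A": np.array([0.95, 0.60, 800.0, 0.55, 2.60, 0.055, 4.0]),
    "B": np.array([0.84, 0.62, 700.0, 0.60, 2.20, 0.060, 3.5]),
    "C": np.array([0.92, 0.68, 230.0, 0.40, 1.80, 0.090, 3.0]),
    "D": np.array([0.68, 0.44, 600.0, 1.30, 1.30, 0.130, 1.8]),
}
_REALISTIC_SDS = np.array([0.04, 0.06, 120.0, 0.15, 0.30, 0.015, 0.5])
_B_VARIANCE_INFLATION = 2.2  # x on the standard deviation


def sample_feature_table(
    n_per_class: int, separation: str = "realistic", seed: int = 0
) -> pd.DataFrame:
    """Draw labeled 7-feature vectors from class-conditional Gaussians.

    ``separation`` selects the class geometry: ``realistic`` places class
    means to realize the archetype orderings (C smallest area; D lowest
    ellipticity/rectangularity, largest adhesion size, lowest aspect ratio
    and G-function, highest E-slope) with class B given inflated
    covariance; ``strong`` shrinks all spreads so classes are cleanly
    separable; ``weak`` gives every class identical means (pure noise).
    """
    if n_per_class < 2:
        raise ValueError("n_per_class must be >= 2")
    if separation not in ("strong", "weak", "realistic"):
        raise ValueError(f"unknown separation {separation!r}")
    rng = np.random.default_rng(seed)
    grand = np.mean(list(_REALISTIC_MEANS.values()), axis=0)
    rows = []
    for label in CLASS_LABELS:
        if separation == "weak":
            mean, sds = grand, _REALISTIC_SDS
        elif separation == "strong":
            mean, sds = _REALISTIC_MEANS[label], _REALISTIC_SDS * 0.2
        else:
            mean = _REALISTIC_MEANS[label]
            sds = _REALISTIC_SDS * (
                _B_VARIANCE_INFLATION if label == "B" else 1.0
            )
        x = rng.normal(mean, sds, size=(n_per_class, len(mean)))
        frame = pd.DataFrame(x, columns=FEATURE_COLUMNS)
        frame.insert(0, "class", label)
        rows.append(frame)
    table = pd.concat(rows, ignore_index=True)
    table.insert(0, "cell_id", [f"cell_{i:04d}" for i in range(len(table))])
    return table
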