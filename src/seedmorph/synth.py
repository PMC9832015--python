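"""Synthetic chroma-key seed scenes and trait tables with ground truth.

The study population this module emulates is a gene-bank germplasm
collection: hundreds of accessions ("lines"), each photographed as
~41-238 seeds (about 95 on average) spread on a blue chroma-key
background with a 16 mm scale tag. Per-accession trait distributions
are approximately normal with accession-specific location and spread.

Two generators are provided:

* scene generators (``sample_accession`` / ``build_scene`` /
  ``render_scene``) produce an RGB image of non-overlapping rendered
  ellipses plus analytic ground truth, to test segmentation and
  morphometry end to end;
* ``generate_trait_table`` produces per-seed trait records for many
  accessions drawn around planted cluster centers, with optional
  injected defects (zero-valued records, one gross outlier), to test
  the statistics stage against known structure.

All randomness flows through an explicit integer seed; identical seeds
give bit-identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from skimage.draw import disk as _draw_disk
from skimage.draw import ellipse as _draw_ellipse

from .morphometrics import CLUSTER_FEATURES, TRAIT_COLUMNS

# Default palette: dark brown seeds on a blue-dominant background with a
# pure white scale tag -- the blue channel then carries maximal contrast
# (background bright, seeds dark), which is what chroma-key segmentation
# exploits.
BACKGROUND_COLOR = (40, 60, 200)
SEED_COLOR = (80, 50, 30)
TAG_COLOR = (255, 255, 255)


class PlacementError(RuntimeError):
    """Non-overlapping seed placement failed within the retry budget."""


# --------------------------------------------------------------------------
# accession-level shape sampling


@dataclass(frozen=True)
class AccessionParams:
    """Shape distribution of one accession.

    Semi-axes are drawn from a truncated normal (truncated at 0,
    rejection sampling) with the given means and a common coefficient
    of variation ``cv_size``; each seed's orientation is uniform on
    [0, pi).
    """

    accession_id: str
    mean_semi_major: float  # mm
    mean_semi_minor: float  # mm
    cv_size: float = 0.08
    n_seeds: int = 95

    def __post_init__(self) -> None:
        if self.mean_semi_major <= 0 or self.mean_semi_minor <= 0:
            raise ValueError("semi-axis means must be positive")
        if self.mean_semi_major < self.mean_semi_minor:
            raise ValueError("mean_semi_major must be >= mean_semi_minor")
        if not 0 <= self.cv_size < 1:
            raise ValueError("cv_size must be in [0, 1)")
        if self.n_seeds < 0:
            raise ValueError("n_seeds must be >= 0")


@dataclass(frozen=True)
class SeedShape:
    """One seed's true shape: semi-axes in mm and orientation in radians."""

    semi_major_mm: float
    semi_minor_mm: float
    angle: float


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float, size: int) -> np.ndarray:
    """Normal(mean, sd) truncated to (0, inf) by rejection sampling."""
    if sd == 0:
        return np.full(size, mean)
    out = rng.normal(mean, sd, size)
    bad = out <= 0
    while bad.any():
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = out <= 0
    return out


def sample_accession(params: AccessionParams, rng_seed: int) -> list[SeedShape]:
    """Draw ``params.n_seeds`` seed shapes for one accession."""
    rng = np.random.default_rng(rng_seed)
    a = _truncated_normal(rng, params.mean_semi_major, params.cv_size * params.mean_semi_major, params.n_seeds)
    b = _truncated_normal(rng, params.mean_semi_minor, params.cv_size * params.mean_semi_minor, params.n_seeds)
    angles = rng.uniform(0.0, np.pi, params.n_seeds)
    # rare with cv < 1 and ordered means: keep major >= minor per seed
    swap = b > a
    a[swap], b[swap] = b[swap].copy(), a[swap].copy()
    return [SeedShape(float(ai), float(bi), float(t)) for ai, bi, t in zip(a, b, angles)]


# --------------------------------------------------------------------------
# scene construction and rendering


@dataclass(frozen=True)
class EllipsePx:
    """A rendered seed: center (row, col), semi-axes and angle in pixels.

    ``angle`` is the rotation of the major axis away from the column
    (horizontal) axis, in radians.
    """

    center_row: float
    center_col: float
    semi_major_px: float
    semi_minor_px: float
    angle: float


@dataclass
class SceneSpec:
    """Complete description of a synthetic chroma-key scene."""

    image_size: tuple[int, int] = (1400, 1800)  # (rows, cols)
    background_color: tuple[int, int, int] = BACKGROUND_COLOR
    seed_color: tuple[int, int, int] = SEED_COLOR
    tag_color: tuple[int, int, int] = TAG_COLOR
    tag_length_mm: float = 16.0
    tag_length_px: int = 160
    tag_corner: tuple[int, int] = (20, 20)  # top-left (row, col) of the tag
    seed_ellipses: list[EllipsePx] = field(default_factory=list)
    noise_specks: list[tuple[int, int, int]] = field(default_factory=list)  # (row, col, radius)
    shadow_gain: float = 0.0

    @property
    def mm_per_px(self) -> float:
        return self.tag_length_mm / self.tag_length_px

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


@dataclass
class GroundTruth:
    """Analytic per-seed truth for a rendered scene.

    ``seeds`` has one row per seed with analytic area / bounding box /
    major axis / circularity / roundness (mm units via mm_per_px) plus
    the rendered foreground pixel count.
    """

    seeds: pd.DataFrame
    mm_per_px: float
    tag_length_px: int


def build_scene(
    shapes: list[SeedShape],
    mm_per_px: float = 0.1,
    image_size: tuple[int, int] = (1400, 1800),
    tag_length_mm: float = 16.0,
    n_specks: int = 0,
    speck_radius_px: int = 2,
    shadow_gain: float = 0.0,
    non_overlap: bool = True,
    margin_px: int = 4,
    max_retries: int = 500,
    rng_seed: int = 0,
    background_color: tuple[int, int, int] = BACKGROUND_COLOR,
    seed_color: tuple[int, int, int] = SEED_COLOR,
    tag_color: tuple[int, int, int] = TAG_COLOR,
) -> SceneSpec:
    """Place seed shapes (and optional noise specks) into a scene.

    Non-overlap is enforced conservatively through bounding circles
    (radius = semi-major + margin) with rejection sampling, bounded at
    ``max_retries`` draws per seed; seeds and specks never touch the
    scale tag. Raises :class:`PlacementError` when the scene is too
    crowded for the retry budget.
    """
    rng = np.random.default_rng(rng_seed)
    H, W = image_size
    tag_px = int(round(tag_length_mm / mm_per_px))
    tag_r0, tag_c0 = 20, 20
    if tag_r0 + tag_px > H or tag_c0 + tag_px > W:
        raise ValueError("image too small for the scale tag")
    tag_box = (tag_r0, tag_r0 + tag_px - 1, tag_c0, tag_c0 + tag_px - 1)

    placed: list[tuple[float, float, float]] = []  # (row, col, bounding radius)
    ellipses: list[EllipsePx] = []

    def clear_of_tag(r: float, c: float, rad: float) -> bool:
        return not (
            tag_box[0] - rad <= r <= tag_box[1] + rad
            and tag_box[2] - rad <= c <= tag_box[3] + rad
        )

    def try_place(rad: float) -> tuple[float, float]:
        for _ in range(max_retries):
            r = rng.uniform(rad + 1, H - rad - 2)
            c = rng.uniform(rad + 1, W - rad - 2)
            if not clear_of_tag(r, c, rad):
                continue
            if non_overlap and any(
                (r - pr) ** 2 + (c - pc) ** 2 < (rad + prad) ** 2
                for pr, pc, prad in placed
            ):
                continue
            return r, c
        raise PlacementError(
            f"could not place object of radius {rad:.1f}px after {max_retries} tries"
        )

    for s in shapes:
        a_px = s.semi_major_mm / mm_per_px
        b_px = s.semi_minor_mm / mm_per_px
        rad = a_px + margin_px
        r, c = try_place(rad)
        placed.append((r, c, rad))
        ellipses.append(EllipsePx(r, c, a_px, b_px, s.angle))

    specks: list[tuple[int, int, int]] = []
    for _ in range(n_specks):
        rad = speck_radius_px + margin_px
        r, c = try_place(rad)
        placed.append((r, c, rad))
        specks.append((int(round(r)), int(round(c)), speck_radius_px))

    return SceneSpec(
        image_size=image_size,
        background_color=background_color,
        seed_color=seed_color,
        tag_color=tag_color,
        tag_length_mm=tag_length_mm,
        tag_length_px=tag_px,
        tag_corner=(tag_r0, tag_c0),
        seed_ellipses=ellipses,
        noise_specks=specks,
        shadow_gain=shadow_gain,
    )


def _ellipse_perimeter(a: float, b: float) -> float:
    """Ramanujan's second approximation to the ellipse circumference."""
    h = (a - b) ** 2 / (a + b) ** 2
    return np.pi * (a + b) * (1 + 3 * h / (10 + np.sqrt(4 - 3 * h)))


def render_scene(spec: SceneSpec) -> tuple[np.ndarray, GroundTruth]:
    """Rasterize a scene into an RGB uint8 image plus analytic truth.

    Seeds are filled ellipses in the seed colour; the scale tag is a
    solid square of the tag colour at its corner; noise specks are
    seed-coloured disks. ``shadow_gain`` > 0 darkens a thin background
    ring around each seed (a crude soft shadow).
    """
    H, W = spec.image_size
    img = np.empty((H, W, 3), dtype=np.uint8)
    img[:] = np.asarray(spec.background_color, dtype=np.uint8)

    if spec.shadow_gain > 0:
        shade = tuple(
            int(round(v * (1 - spec.shadow_gain))) for v in spec.background_color
        )
        for e in spec.seed_ellipses:
            rr, cc = _draw_ellipse(
                e.center_row, e.center_col,
                e.semi_minor_px + 2, e.semi_major_px + 2,
                shape=(H, W), rotation=e.angle,
            )
            img[rr, cc] = shade

    rows = []
    mpp = spec.mm_per_px
    for i, e in enumerate(spec.seed_ellipses, start=1):
        rr, cc = _draw_ellipse(
            e.center_row, e.center_col,
            e.semi_minor_px, e.semi_major_px,
            shape=(H, W), rotation=e.angle,
        )
        img[rr, cc] = spec.seed_color
        a, b, th = e.semi_major_px, e.semi_minor_px, e.angle
        width_px = 2 * np.sqrt(a**2 * np.cos(th) ** 2 + b**2 * np.sin(th) ** 2)
        height_px = 2 * np.sqrt(a**2 * np.sin(th) ** 2 + b**2 * np.cos(th) ** 2)
        area_px = np.pi * a * b
        per_px = _ellipse_perimeter(a, b)
        rows.append(
            {
                "seed_id": i,
                "area_mm2": area_px * mpp**2,
                "width_mm": width_px * mpp,
                "height_mm": height_px * mpp,
                "major_axis_mm": 2 * a * mpp,
                "perimeter_mm": per_px * mpp,
                "circularity": 4 * np.pi * area_px / per_px**2,
                "roundness": b / a,
                "n_pixels": int(len(rr)),
            }
        )

    for r, c, rad in spec.noise_specks:
        rr, cc = _draw_disk((r, c), rad, shape=(H, W))
        img[rr, cc] = spec.seed_color

    r0, c0 = spec.tag_corner
    img[r0 : r0 + spec.tag_length_px, c0 : c0 + spec.tag_length_px] = spec.tag_color

    truth = GroundTruth(
        seeds=pd.DataFrame(
            rows,
            columns=[
                "seed_id", "area_mm2", "width_mm", "height_mm",
                "major_axis_mm", "perimeter_mm", "circularity", "roundness",
                "n_pixels",
            ],
        ),
        mm_per_px=mpp,
        tag_length_px=spec.tag_length_px,
    )
    return img, truth


def write_scene_png(image: np.ndarray, path) -> None:
    """Write a rendered scene as PNG."""
    import imageio.v3 as iio

    iio.imwrite(path, image)


# --------------------------------------------------------------------------
# trait-table generation (statistics-stage inputs)

def _regular_simplex(n: int) -> np.ndarray:
    """n+1 equidistant points in R^n (unit pairwise distance, centered).

    Closed-form construction: the n unit vectors plus the point
    c * (1,..,1) with c = (1 + sqrt(n+1)) / n is a regular simplex.
    Every coordinate has the same variance across vertices, so a
    per-feature rescaling (e.g. z-scoring a mixture built on it)
    preserves the equidistant geometry.
    """
    V = np.vstack([np.eye(n), ((1 + np.sqrt(n + 1)) / n) * np.ones(n)])
    V -= V.mean(axis=0)
    return V / np.linalg.norm(V[0] - V[1])


_CENTER_BASE = np.array([20.0, 4.5, 5.67, 0.72, 0.62])
_CENTER_SPREAD = np.array([0.55, 0.30, 0.30, 0.25, 0.30])

#: Six planted cluster centers in feature order
#: (area mm^2, width mm, height mm, circularity, roundness): six
#: equally dissimilar seed morphs around a buckwheat-like base shape
#: (mean height near 5.7 mm), each shifted along a different trait
#: combination. Built on a regular simplex so no pair of planted
#: morphs is much closer than any other -- the planted number of
#: clusters is then unambiguous.
DEFAULT_CLUSTER_CENTERS = _CENTER_BASE * (1 + _CENTER_SPREAD * _regular_simplex(5))


@dataclass(frozen=True)
class DefectSpec:
    """Defects to inject into a trait table.

    ``n_zero`` records get one randomly chosen feature set to exactly 0
    (mimicking failed measurements); ``n_outlier`` records get their
    height replaced by ``outlier_factor`` times the global mean height
    (a gross segmentation failure, e.g. two merged rows of seeds).
    """

    n_zero: int = 0
    n_outlier: int = 0
    outlier_factor: float = 17.5
    outlier_feature: str = "height_mm"


def _sample_seeds_per_line(rng: np.random.Generator) -> int:
    """Seeds per accession: mean ~95, clipped to the observed 41-238 range."""
    return int(round(np.clip(rng.normal(94.7, 35.0), 41, 238)))


def generate_trait_table(
    n_lines: int,
    seeds_per_line: int | tuple[int, int] | None = None,
    cluster_centers: np.ndarray | None = None,
    defect_spec: DefectSpec | None = None,
    rng_seed: int = 0,
    n_clusters: int | None = None,
    within_line_cv: float = 0.05,
    line_cv: float = 0.01,
) -> tuple[pd.DataFrame, pd.Series]:
    """Synthesize a trait table around planted cluster centers.

    Each line is assigned to one of the planted centers; its own center
    is the cluster center perturbed by a relative normal jitter of
    ``line_cv`` (the within-cluster spread); individual seed records
    scatter around the line center with coefficient of variation
    ``within_line_cv``, truncated positive. Perimeter and major axis
    are derived from area, circularity and roundness so that the shape
    identities (circularity = 4*pi*A/P^2, roundness = 4A/(pi*M^2)) hold
    exactly for every record.

    ``seeds_per_line``: fixed int, (low, high) for uniform integers, or
    None for the study-like distribution (mean ~95, range 41-238).

    Returns (table, planted_labels) where ``planted_labels`` maps
    accession_id -> planted cluster index (0-based).
    """
    if n_lines < 0:
        raise ValueError("n_lines must be >= 0")
    centers = (
        DEFAULT_CLUSTER_CENTERS if cluster_centers is None else np.asarray(cluster_centers, float)
    )
    if centers.ndim != 2 or centers.shape[1] != len(CLUSTER_FEATURES):
        raise ValueError(f"cluster_centers must be (k, {len(CLUSTER_FEATURES)})")
    if len(np.unique(centers, axis=0)) != len(centers):
        raise ValueError("cluster_centers must be distinct")
    if n_clusters is not None:
        if n_clusters > len(centers):
            raise ValueError(
                f"requested {n_clusters} clusters but only {len(centers)} centers given"
            )
        centers = centers[:n_clusters]

    rng = np.random.default_rng(rng_seed)
    k = len(centers)
    # balanced assignment, shuffled so cluster id is independent of line order
    assignment = rng.permutation(np.arange(n_lines) % k)

    frames = []
    labels = {}
    for i in range(n_lines):
        acc = f"ACC{i:04d}"
        labels[acc] = int(assignment[i])
        center = centers[assignment[i]]
        line_center = center * (1 + line_cv * rng.standard_normal(len(center)))
        line_center = np.clip(line_center, 1e-6, None)
        if seeds_per_line is None:
            n = _sample_seeds_per_line(rng)
        elif isinstance(seeds_per_line, tuple):
            n = int(rng.integers(seeds_per_line[0], seeds_per_line[1] + 1))
        else:
            n = int(seeds_per_line)
        if within_line_cv == 0:
            vals = np.tile(line_center, (n, 1))
        else:
            vals = line_center * (1 + within_line_cv * rng.standard_normal((n, len(center))))
            bad = vals <= 0
            while bad.any():
                noise = 1 + within_line_cv * rng.standard_normal(int(bad.sum()))
                vals[bad] = (np.broadcast_to(line_center, vals.shape)[bad]) * noise
                bad = vals <= 0
        vals[:, 3] = np.clip(vals[:, 3], None, 1.0)  # circularity <= 1
        vals[:, 4] = np.clip(vals[:, 4], None, 1.0)  # roundness <= 1
        df = pd.DataFrame(vals, columns=CLUSTER_FEATURES)
        df.insert(0, "seed_id", np.arange(1, n + 1))
        df.insert(0, "accession_id", acc)
        frames.append(df)

    if frames:
        table = pd.concat(frames, ignore_index=True)
    else:
        table = pd.DataFrame(columns=["accession_id", "seed_id"] + CLUSTER_FEATURES)

    # derived features consistent with the shape identities
    table["perimeter_mm"] = np.sqrt(4 * np.pi * table["area_mm2"] / table["circularity"])
    table["major_axis_mm"] = np.sqrt(4 * table["area_mm2"] / (np.pi * table["roundness"]))
    table = table[TRAIT_COLUMNS]

    if defect_spec is not None and len(table) > 0:
        n_def = defect_spec.n_zero + defect_spec.n_outlier
        if n_def > len(table):
            raise ValueError("more defects requested than records")
        rows = rng.choice(len(table), size=n_def, replace=False)
        zero_rows, out_rows = rows[: defect_spec.n_zero], rows[defect_spec.n_zero :]
        for r in zero_rows:
            feat = CLUSTER_FEATURES[rng.integers(len(CLUSTER_FEATURES))]
            table.loc[r, feat] = 0.0
        if defect_spec.n_outlier:
            mean_h = float(table[defect_spec.outlier_feature].mean())
            table.loc[out_rows, defect_spec.outlier_feature] = (
                defect_spec.outlier_factor * mean_h
            )

    return table, pd.Series(labels, name="planted_cluster", dtype=int)
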