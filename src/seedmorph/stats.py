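"""Collection-level analysis of seed trait tables.

Implements the data-analysis stage of the phenotyping workflow: quality
filtering, per-accession normality screening (Shapiro-Wilk), median
aggregation, k-means clustering of per-line medians with distortion-
elbow model selection, kernel density estimation, and the Spearman
feature-correlation matrix.

The five analysis features, in fixed order, are area (mm^2), width
(mm), height (mm), circularity and roundness
(:data:`~seedmorph.morphometrics.CLUSTER_FEATURES`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.spatial.distance import cdist

from .morphometrics import CLUSTER_FEATURES, LENGTH_FEATURES

# ---------------------------------------------------------------------------
# quality control


@dataclass
class QCReport:
    """Which records QC removed and why."""

    n_input: int
    n_removed_zero: int
    n_removed_outlier: int
    removed: pd.DataFrame  # removed records with a 'qc_reason' column

    @property
    def n_retained(self) -> int:
        return self.n_input - self.n_removed_zero - self.n_removed_outlier


def qc_filter(
    table: pd.DataFrame, outlier_ratio: float = 10.0
) -> tuple[pd.DataFrame, QCReport]:
    """Remove zero-valued and grossly outlying records.

    First removes records with any feature equal to 0 (failed
    measurements), then records where any length/area feature exceeds
    ``outlier_ratio`` times that feature's global median over the
    remaining records. The default ratio of 10 removes e.g. a 99 mm
    "seed" in a collection whose median height is ~5.7 mm while leaving
    ordinary biological variation untouched.
    """
    if outlier_ratio <= 0:
        raise ValueError("outlier_ratio must be positive")
    if table.empty:
        report = QCReport(0, 0, 0, table.assign(qc_reason=pd.Series(dtype=str)))
        return table.copy(), report

    feat_cols = [c for c in table.columns if c in set(CLUSTER_FEATURES + LENGTH_FEATURES)]
    zero_mask = (table[feat_cols] == 0).any(axis=1)
    after_zero = table.loc[~zero_mask]

    length_cols = [c for c in LENGTH_FEATURES if c in table.columns]
    medians = after_zero[length_cols].median()
    out_mask = (after_zero[length_cols] > outlier_ratio * medians).any(axis=1)

    removed_zero = table.loc[zero_mask].assign(qc_reason="zero_value")
    removed_out = after_zero.loc[out_mask].assign(qc_reason="outlier")
    kept = after_zero.loc[~out_mask].reset_index(drop=True)
    report = QCReport(
        n_input=len(table),
        n_removed_zero=int(zero_mask.sum()),
        n_removed_outlier=int(out_mask.sum()),
        removed=pd.concat([removed_zero, removed_out]),
    )
    return kept, report


# ---------------------------------------------------------------------------
# per-line normality screening


@dataclass
class NormalityReport:
    """Shapiro-Wilk screening results.

    ``p_values``: DataFrame indexed by accession_id with one column per
    feature; NaN marks untestable combinations (fewer than 3 records or
    a constant sample). A line fails when any testable feature has
    p < alpha; lines with no testable feature are excluded from the
    failure count.
    """

    p_values: pd.DataFrame
    alpha: float
    fail: pd.Series  # bool per testable line
    untestable: list[str] = field(default_factory=list)

    @property
    def n_failed(self) -> int:
        return int(self.fail.sum())


def normality_screen(table: pd.DataFrame, alpha: float = 0.05) -> NormalityReport:
    """Shapiro-Wilk test per (line, feature) at significance ``alpha``."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    rows = {}
    for acc, group in table.groupby("accession_id", sort=True):
        ps = {}
        for feat in CLUSTER_FEATURES:
            x = group[feat].to_numpy(float)
            if len(x) < 3 or np.ptp(x) == 0:
                ps[feat] = np.nan
            else:
                ps[feat] = float(sps.shapiro(x).pvalue)
        rows[acc] = ps
    p_values = pd.DataFrame.from_dict(rows, orient="index")[CLUSTER_FEATURES]
    p_values.index.name = "accession_id"
    testable = p_values.notna().any(axis=1)
    fail = (p_values < alpha).any(axis=1)[testable]
    untestable = list(p_values.index[~testable])
    return NormalityReport(p_values=p_values, alpha=alpha, fail=fail, untestable=untestable)


# ---------------------------------------------------------------------------
# median aggregation


def line_medians(table: pd.DataFrame) -> pd.DataFrame:
    """Per-accession median of each feature plus seed count.

    Uses the midpoint convention for even counts (numpy median). The
    input should already be QC-filtered.
    """
    grouped = table.groupby("accession_id", sort=True)
    med = grouped[CLUSTER_FEATURES].median()
    med.columns = [f"median_{c.removesuffix('_mm2').removesuffix('_mm')}" for c in med.columns]
    med["n_seeds"] = grouped.size()
    return med.reset_index()


MEDIAN_COLUMNS = ["median_area", "median_width", "median_height", "median_circularity", "median_roundness"]


def median_matrix(summaries: pd.DataFrame, standardize: bool = True) -> np.ndarray:
    """LineSummary frame -> (n_lines, 5) matrix for clustering.

    With ``standardize`` (default) each feature is z-scored; the raw
    mode clusters the mixed-unit medians directly.
    """
    X = summaries[MEDIAN_COLUMNS].to_numpy(float)
    if standardize:
        sd = X.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        X = (X - X.mean(axis=0)) / sd
    return X


# ---------------------------------------------------------------------------
# k-means with distortion-elbow selection


@dataclass
class ClusterModel:
    """A fitted k-means solution.

    ``labels`` are 1-based cluster assignments; ``distortion`` is the
    sum of squared Euclidean distances from each sample to its
    centroid. ``distortion_history`` records the distortion after each
    Lloyd assignment step of the winning restart (non-increasing).
    """

    k: int
    centroids: np.ndarray
    labels: np.ndarray
    distortion: float
    distortion_history: list[float] = field(default_factory=list)


def _kmeans_pp_init(X: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Distance-weighted (k-means++) seeding."""
    n = len(X)
    centers = np.empty((k, X.shape[1]))
    centers[0] = X[rng.integers(n)]
    d2 = ((X - centers[0]) ** 2).sum(axis=1)
    for j in range(1, k):
        total = d2.sum()
        if total <= 0:
            centers[j] = X[rng.integers(n)]
        else:
            centers[j] = X[rng.choice(n, p=d2 / total)]
        d2 = np.minimum(d2, ((X - centers[j]) ** 2).sum(axis=1))
    return centers


def _lloyd(
    X: np.ndarray, centers: np.ndarray, max_iter: int = 300
) -> tuple[np.ndarray, np.ndarray, float, list[float]]:
    """Lloyd iteration to an assignment fixed point.

    Empty clusters are reseeded to the point farthest from its
    centroid, which keeps k centroids and cannot increase distortion
    seen by the history (re-assignment follows immediately).
    """
    labels = np.full(len(X), -1)
    history: list[float] = []
    for _ in range(max_iter):
        d2 = cdist(X, centers, "sqeuclidean")
        new_labels = d2.argmin(axis=1)
        distortion = float(d2[np.arange(len(X)), new_labels].sum())
        history.append(distortion)
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
        for j in range(len(centers)):
            members = X[labels == j]
            if len(members):
                centers[j] = members.mean(axis=0)
            else:
                far = ((X - centers[labels]) ** 2).sum(axis=1).argmax()
                centers[j] = X[far]
    d2 = cdist(X, centers, "sqeuclidean")
    labels = d2.argmin(axis=1)
    distortion = float(d2[np.arange(len(X)), labels].sum())
    return centers, labels, distortion, history


def _restart_seeds(rng_seed: int, n_restarts: int) -> np.ndarray:
    """Shared seed schedule: the same restart seeds for every k."""
    return np.random.SeedSequence(rng_seed).generate_state(n_restarts)


def kmeans_fit(
    X: np.ndarray,
    k: int,
    n_restarts: int = 10,
    rng_seed: int = 0,
    init_centers: list[np.ndarray] | None = None,
) -> ClusterModel:
    """Best-of-restarts Lloyd k-means.

    Each restart starts from k-means++ seeding under a deterministic
    seed schedule derived from ``rng_seed``; the restart with minimum
    distortion wins. ``init_centers`` adds extra warm-start candidate
    initializations (used by :func:`distortion_curve`).
    """
    X = np.asarray(X, float)
    n = len(X)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"k={k} exceeds number of samples n={n}")
    best: ClusterModel | None = None
    inits: list[np.ndarray] = []
    for s in _restart_seeds(rng_seed, n_restarts):
        inits.append(_kmeans_pp_init(X, k, np.random.default_rng(int(s))))
    if init_centers:
        inits.extend(np.asarray(c, float).copy() for c in init_centers)
    for init in inits:
        centers, labels, distortion, history = _lloyd(X, init.copy())
        if best is None or distortion < best.distortion:
            best = ClusterModel(
                k=k,
                centroids=centers,
                labels=labels + 1,
                distortion=distortion,
                distortion_history=history,
            )
    assert best is not None
    return best


@dataclass
class DistortionCurve:
    """(k, distortion) pairs for k = 1..k_max."""

    ks: list[int]
    distortions: list[float]
    models: list[ClusterModel] = field(default_factory=list)

    def model_for(self, k: int) -> ClusterModel:
        return self.models[self.ks.index(k)]


def distortion_curve(
    X: np.ndarray, k_max: int = 10, n_restarts: int = 10, rng_seed: int = 0
) -> DistortionCurve:
    """k-means distortion for k = 1..k_max under a shared seed schedule.

    In addition to the shared random restarts, each k receives a
    warm-start candidate built from the best (k-1)-solution's centroids
    plus the sample currently farthest from its centroid; this
    guarantees the curve is non-increasing in k.
    """
    X = np.asarray(X, float)
    if k_max > len(X):
        raise ValueError(f"k_max={k_max} exceeds number of samples n={len(X)}")
    ks, distortions, models = [], [], []
    prev: ClusterModel | None = None
    for k in range(1, k_max + 1):
        warm = None
        if prev is not None:
            d2 = cdist(X, prev.centroids, "sqeuclidean")
            far = d2[np.arange(len(X)), prev.labels - 1].argmax()
            warm = [np.vstack([prev.centroids, X[far]])]
        model = kmeans_fit(X, k, n_restarts=n_restarts, rng_seed=rng_seed, init_centers=warm)
        ks.append(k)
        distortions.append(model.distortion)
        models.append(model)
        prev = model
    return DistortionCurve(ks=ks, distortions=distortions, models=models)


def select_k_elbow(curve: DistortionCurve) -> int:
    """Elbow of the distortion curve by maximal second forward difference.

    Returns the interior k maximizing D(k-1) - 2 D(k) + D(k+1); ties go
    to the smallest k. Needs at least 3 points.
    """
    d = curve.distortions
    if len(d) < 3:
        raise ValueError("distortion curve needs at least 3 points for elbow selection")
    second = [d[i - 1] - 2 * d[i] + d[i + 1] for i in range(1, len(d) - 1)]
    best_i = int(np.argmax(second))  # argmax takes the first (smallest k) on ties
    return curve.ks[1 + best_i]


# ---------------------------------------------------------------------------
# kernel density estimation


@dataclass
class KDEResult:
    """Gaussian-kernel density estimate on a regular grid.

    The density integrates to ~1 over the grid (the grid spans the data
    range padded by 3 bandwidths); individual density values may exceed
    1 on narrow supports.
    """

    grid: np.ndarray
    density: np.ndarray
    bandwidth: float


def kde_density(
    values,
    bandwidth_rule: str = "scott",
    bandwidth: float | None = None,
    grid_points: int = 256,
) -> KDEResult:
    """Gaussian KDE of one feature.

    ``bandwidth_rule`` "scott" uses h = sigma * n^(-1/5); "fixed" uses
    the supplied ``bandwidth``. Requires at least 2 distinct values.
    """
    x = np.asarray(values, float)
    if len(np.unique(x)) < 2:
        raise ValueError("KDE requires at least 2 distinct values")
    sigma = float(np.std(x, ddof=1))
    if bandwidth_rule == "scott":
        h = sigma * len(x) ** (-1 / 5)
    elif bandwidth_rule == "fixed":
        if bandwidth is None or bandwidth <= 0:
            raise ValueError("fixed bandwidth rule requires a positive bandwidth")
        h = float(bandwidth)
    else:
        raise ValueError(f"unknown bandwidth rule: {bandwidth_rule!r}")
    kde = sps.gaussian_kde(x, bw_method=h / sigma)
    grid = np.linspace(x.min() - 3 * h, x.max() + 3 * h, grid_points)
    density = kde(grid)
    return KDEResult(grid=grid, density=density, bandwidth=h)


# ---------------------------------------------------------------------------
# feature correlations


@dataclass
class CorrelationMatrix:
    """Spearman rank correlations between the five median features."""

    rho: pd.DataFrame
    p_values: pd.DataFrame


def spearman_matrix(summaries: pd.DataFrame) -> CorrelationMatrix:
    """Spearman correlation (midrank ties) between per-line medians.

    p-values use the two-sided t-approximation. Pairs involving a
    constant feature are reported as NaN.
    """
    if len(summaries) < 3:
        raise ValueError("need at least 3 line summaries for correlations")
    X = summaries[MEDIAN_COLUMNS].to_numpy(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        import warnings as _warnings

        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            rho, p = sps.spearmanr(X, axis=0)
    rho = np.atleast_2d(rho)
    p = np.atleast_2d(p)
    np.fill_diagonal(rho, 1.0)
    names = MEDIAN_COLUMNS
    return CorrelationMatrix(
        rho=pd.DataFrame(rho, index=names, columns=names),
        p_values=pd.DataFrame(p, index=names, columns=names),
    )
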