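"""Snow-chemistry preprocessing, ordination and two-table coupling.

The chemistry workflow mirrors standard practice for trace-level ion
chromatography data: censored values (below the analyte's limit of
detection) are imputed as LOD/2, concentrations are log transformed
(pH excluded), and samples are ordinated by PCA.  Group differences
between sampling periods are assessed with a distance-based pseudo-F
permutation test (PERMANOVA), and the coupling between chemistry and
community/function tables is quantified with the RV coefficient of a
co-inertia analysis, tested by row permutation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

logger = logging.getLogger(__name__)

__all__ = [
    "ChemTable",
    "OrdinationResult",
    "CoinertiaResult",
    "impute_below_lod",
    "log_transform",
    "pca",
    "permutation_group_test",
    "coinertia",
]


@dataclass
class ChemTable:
    """Samples x analytes concentration table with censoring metadata.

    Parameters
    ----------
    values
        Concentrations in ppb (pH unitless), samples as rows.  Cells
        flagged in ``below_lod`` hold NaN: the measured value is
        withheld, not stored as a sentinel.
    below_lod
        Boolean mask, same shape as ``values``; True marks a censored
        cell.
    lod
        Per-analyte limit of detection in ppb.  Analytes that cannot be
        censored (pH) may be absent or NaN.
    ph_column
        Name of the single pH column, exempt from the log transform.
    period
        Optional per-sample period labels (``"ES"``/``"LS"``).
    """

    values: pd.DataFrame
    below_lod: pd.DataFrame
    lod: pd.Series
    ph_column: str = "pH"
    period: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.below_lod.shape != self.values.shape:
            raise ValueError("below_lod mask must match values shape")
        if self.ph_column not in self.values.columns:
            raise ValueError(f"pH column {self.ph_column!r} not in table")
        masked_but_present = self.below_lod.to_numpy() & self.values.notna().to_numpy()
        if masked_but_present.any():
            raise ValueError("censored cells must not store a value")

    @property
    def samples(self) -> pd.Index:
        return self.values.index

    @property
    def analytes(self) -> pd.Index:
        return self.values.columns

    def is_censored(self) -> bool:
        return bool(self.below_lod.to_numpy().any())


@dataclass
class OrdinationResult:
    """PCA output: sample scores, analyte loadings, variance fractions."""

    scores: pd.DataFrame
    loadings: pd.DataFrame
    explained_variance: np.ndarray

    def __post_init__(self) -> None:
        ev = np.asarray(self.explained_variance, dtype=float)
        if np.any(ev < -1e-12) or np.any(ev > 1 + 1e-9):
            raise ValueError("explained variance fractions must lie in [0, 1]")
        if np.any(np.diff(ev) > 1e-9):
            raise ValueError("explained variance must be non-increasing")


@dataclass
class CoinertiaResult:
    """RV coefficient with permutation significance and co-inertia scores."""

    rv: float
    p_value: float
    n_perm: int
    x_scores: pd.DataFrame
    y_scores: pd.DataFrame
    singular_values: np.ndarray = field(default_factory=lambda: np.array([]))


def impute_below_lod(table: ChemTable) -> ChemTable:
    """Replace censored cells by LOD/2; leave measured cells untouched.

    Half the detection limit is the conventional single-value imputation
    for left-censored trace chemistry.  The returned table has a cleared
    censoring mask.

    Raises
    ------
    ValueError
        If a censored cell belongs to an analyte with no defined LOD.
    """
    values = table.values.copy()
    mask = table.below_lod
    for analyte in table.analytes:
        col_mask = mask[analyte]
        if not col_mask.any():
            continue
        lod = table.lod.get(analyte, np.nan)
        if lod is None or np.isnan(lod):
            raise ValueError(
                f"analyte {analyte!r} has censored values but no detection limit"
            )
        if lod <= 0:
            raise ValueError(f"analyte {analyte!r} has non-positive LOD {lod}")
        values.loc[col_mask, analyte] = lod / 2.0
    cleared = pd.DataFrame(False, index=mask.index, columns=mask.columns)
    return replace(table, values=values, below_lod=cleared)


def log_transform(table: ChemTable) -> pd.DataFrame:
    """Natural log of every non-pH column; pH passes through unchanged.

    Requires a fully imputed table (no censored cells, all
    concentrations strictly positive).
    """
    if table.is_censored():
        raise ValueError("log_transform requires an imputed table (censored cells remain)")
    out = table.values.copy().astype(float)
    chem_cols = [c for c in out.columns if c != table.ph_column]
    block = out[chem_cols]
    if (block <= 0).any().any() or block.isna().any().any():
        bad = block.columns[((block <= 0) | block.isna()).any()].tolist()
        raise ValueError(f"non-positive or missing values in columns {bad}")
    out[chem_cols] = np.log(block)
    return out


def pca(matrix: pd.DataFrame, n_axes: int = 2, scale: bool = True) -> OrdinationResult:
    """Principal component analysis via SVD of the centred matrix.

    Columns are centred and, by default, standardised to unit variance
    (the analytes span several orders of magnitude in ppb, so a
    correlation-matrix PCA keeps any one ion from dominating the
    biplot).  Scores are the projections of the (centred, scaled) data
    on the loadings; explained variance is each axis' share of total
    variance.
    """
    X = np.asarray(matrix, dtype=float)
    n, p = X.shape
    if n < 2 or p < 2:
        raise ValueError("PCA needs at least 2 samples and 2 variables")
    max_axes = min(n - 1, p)
    if n_axes > max_axes:
        raise ValueError(f"n_axes={n_axes} exceeds min(n_samples-1, n_vars)={max_axes}")
    Xc = X - X.mean(axis=0)
    if scale:
        sd = Xc.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0  # constant columns contribute nothing either way
        Xc = Xc / sd
    _, s, vt = np.linalg.svd(Xc, full_matrices=False)
    total_var = float((s**2).sum())
    if total_var == 0:
        raise ValueError("matrix has zero total variance")
    ev = (s**2) / total_var
    loadings = vt[:n_axes].T
    scores = Xc @ loadings
    axes = [f"PC{i + 1}" for i in range(n_axes)]
    return OrdinationResult(
        scores=pd.DataFrame(scores, index=matrix.index, columns=axes),
        loadings=pd.DataFrame(loadings, index=matrix.columns, columns=axes),
        explained_variance=ev[:n_axes],
    )


def _pairwise_sq(data: np.ndarray | pd.DataFrame, metric: str) -> np.ndarray:
    arr = np.asarray(data, dtype=float)
    if metric == "precomputed":
        if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
            raise ValueError("precomputed distance must be a square matrix")
        return arr**2
    return squareform(pdist(arr, metric=metric)) ** 2


def _pseudo_f(d2: np.ndarray, groups: np.ndarray) -> float:
    """One-way PERMANOVA pseudo-F from squared distances.

    SS_total = sum of all squared pairwise distances / N; SS_within
    sums each group's internal squared distances / group size.
    """
    n = d2.shape[0]
    labels, inv = np.unique(groups, return_inverse=True)
    a = len(labels)
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for g in range(a):
        idx = np.flatnonzero(inv == g)
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    ss_between = ss_total - ss_within
    return (ss_between / (a - 1)) / (ss_within / (n - a))


def permutation_group_test(
    data,
    labels,
    distance: str = "euclidean",
    n_perm: int = 10000,
    seed: int | None = None,
) -> tuple[float, float]:
    """Distance-based pseudo-F test for a two-group difference.

    Equivalent to one-way PERMANOVA (`adonis`): the pseudo-F statistic
    compares between- to within-group sums of squared distances, and
    the p-value is the add-one permutation tail
    ``(1 + #{F_perm >= F_obs}) / (1 + n_perm)``.

    Parameters
    ----------
    data
        Samples x variables matrix, or a square distance matrix when
        ``distance="precomputed"``.
    distance
        Any :func:`scipy.spatial.distance.pdist` metric name
        (``"euclidean"`` for chemistry, ``"braycurtis"`` for community
        tables) or ``"precomputed"``.
    """
    groups = np.asarray(labels)
    uniq, counts = np.unique(groups, return_counts=True)
    if len(uniq) != 2:
        raise ValueError(f"exactly 2 groups required, got {len(uniq)}")
    if counts.min() < 2:
        raise ValueError("each group needs at least 2 samples")
    if n_perm < 99:
        logger.warning("n_perm=%d is low; p-value resolution is %.3f", n_perm, 1 / (n_perm + 1))
    d2 = _pairwise_sq(data, distance)
    if d2.shape[0] != len(groups):
        raise ValueError("labels length does not match number of samples")
    f_obs = _pseudo_f(d2, groups)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(groups)
        if _pseudo_f(d2, perm) >= f_obs:
            hits += 1
    p = (1 + hits) / (1 + n_perm)
    return float(f_obs), float(p)


def _center(df: pd.DataFrame) -> np.ndarray:
    arr = np.asarray(df, dtype=float)
    return arr - arr.mean(axis=0)


def _rv(xc: np.ndarray, yc: np.ndarray) -> float:
    wx = xc @ xc.T
    wy = yc @ yc.T
    num = float((wx * wy).sum())
    den = float(np.sqrt((wx * wx).sum() * (wy * wy).sum()))
    if den == 0:
        raise ValueError("zero-variance table in RV computation")
    return num / den


def coinertia(
    table_x: pd.DataFrame,
    table_y: pd.DataFrame,
    n_perm: int = 10000,
    seed: int | None = None,
    n_axes: int = 2,
) -> CoinertiaResult:
    """Co-inertia analysis of two tables over the same samples.

    The RV coefficient is the matrix correlation
    ``trace(Cxy Cyx) / sqrt(trace(Cxx^2) trace(Cyy^2))`` of the
    column-centred tables — 1 when the two tables carry proportional
    sample configurations, near 0 when unrelated.  Significance comes
    from re-computing RV under random row permutations of one table;
    co-inertia axes are the singular vectors of the cross-covariance.
    """
    if not table_x.index.equals(table_y.index):
        only_x = table_x.index.difference(table_y.index).tolist()
        only_y = table_y.index.difference(table_x.index).tolist()
        raise ValueError(
            "tables must share identically ordered samples; "
            f"only in X: {only_x}; only in Y: {only_y}"
        )
    xc = _center(table_x)
    yc = _center(table_y)
    rv_obs = _rv(xc, yc)

    # permute rows of Y: equivalent to symmetric row/col permutation of
    # its sample-space scalar-product matrix, so recompute from yc rows
    rng = np.random.default_rng(seed)
    n = xc.shape[0]
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if _rv(xc, yc[perm]) >= rv_obs:
            hits += 1
    p = (1 + hits) / (1 + n_perm)

    cross = xc.T @ yc
    u, s, vt = np.linalg.svd(cross, full_matrices=False)
    k = min(n_axes, len(s))
    axes = [f"CoI{i + 1}" for i in range(k)]
    x_scores = pd.DataFrame(xc @ u[:, :k], index=table_x.index, columns=axes)
    y_scores = pd.DataFrame(yc @ vt[:k].T, index=table_y.index, columns=axes)
    return CoinertiaResult(
        rv=float(rv_obs),
        p_value=float(p),
        n_perm=n_perm,
        x_scores=x_scores,
        y_scores=y_scores,
        singular_values=s[:k],
    )
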