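"""Marker-gene tracking: plasmid (cooperation) and antibiotic (competition).

Per-read functional annotations are screened for plasmid structural
genes (GO:0005727 extrachromosomal circular DNA, or a "plasmid" keyword
in the protein name) and antibiotic-related genes (GO:0017000
antibiotic biosynthetic process, or membership in a curated
protein-name list).  Antibiotic resistance gene determinants (ARGDs)
come from reference-database hit tables filtered at e-value < 1e-10,
z-score > 50 and identity > 60%, resolved to one best hit per read.
Counts are normalized by per-sample totals (after eukaryote removal),
compared between periods with a permutation test on group means, and
ARGD transcription is correlated with chemistry by a permutation
Spearman test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import false_discovery_control, rankdata

logger = logging.getLogger(__name__)

__all__ = [
    "PLASMID_GO",
    "ANTIBIOTIC_GO",
    "DiffAbundanceResult",
    "remove_eukaryotes",
    "sample_read_totals",
    "select_plasmid_markers",
    "select_antibiotic_markers",
    "filter_card_hits",
    "normalize_by_total",
    "differential_abundance",
    "argd_richness",
    "spearman_test",
    "feature_set_overlap",
]

PLASMID_GO = "GO:0005727"  # extrachromosomal circular DNA
ANTIBIOTIC_GO = "GO:0017000"  # antibiotic biosynthetic process

#: default significance thresholds for resistance-database hits
CARD_MAX_EVALUE = 1e-10
CARD_MIN_ZSCORE = 50.0
CARD_MIN_IDENTITY = 60.0

ANNOTATION_COLUMNS = [
    "read_id",
    "sample",
    "dataset",
    "period",
    "protein_name",
    "go_ids",
    "tax_id",
    "is_eukaryote",
]

CARD_COLUMNS = ["read_id", "sample", "dataset", "gene", "e_value", "z_score", "pct_identity"]


@dataclass
class DiffAbundanceResult:
    """Per-feature differential abundance between sampling periods."""

    feature: str
    log2fc: float  # LS over ES
    p_value: float
    adjusted_p: float
    mean_es: float
    mean_ls: float
    significant: bool


def remove_eukaryotes(records: pd.DataFrame) -> pd.DataFrame:
    """Drop reads annotated as eukaryotic; keep bacteria/archaea only."""
    if "is_eukaryote" not in records.columns:
        raise ValueError("records lack the is_eukaryote column")
    return records.loc[~records["is_eukaryote"].astype(bool)].copy()


def sample_read_totals(records: pd.DataFrame) -> pd.Series:
    """Retained reads per (sample, dataset) — denominators for normalization."""
    return records.groupby(["sample", "dataset"], sort=True).size()


def _go_set(cell) -> set[str]:
    if isinstance(cell, (set, frozenset, list, tuple)):
        return {str(g).strip() for g in cell}
    if cell is None or (isinstance(cell, float) and np.isnan(cell)):
        return set()
    return {g.strip() for g in str(cell).split(";") if g.strip()}


def _aggregate(records: pd.DataFrame) -> pd.DataFrame:
    """Pivot matched records to a samples x protein_name count table."""
    if records.empty:
        return pd.DataFrame()
    counts = records.groupby(["sample", "protein_name"], sort=True).size()
    return counts.unstack(fill_value=0)


def select_plasmid_markers(records: pd.DataFrame) -> pd.DataFrame:
    """Counts of plasmid structural gene annotations per sample.

    A record matches if GO:0005727 is among its GO ids or its protein
    name contains "plasmid" (case-insensitive substring).
    """
    go_hit = records["go_ids"].map(lambda c: PLASMID_GO in _go_set(c))
    kw_hit = records["protein_name"].str.contains("plasmid", case=False, na=False)
    return _aggregate(records.loc[go_hit | kw_hit])


def _norm_name(name: str) -> str:
    return " ".join(str(name).split()).lower()


def select_antibiotic_markers(
    records: pd.DataFrame, custom_protein_list: list[str] | None = None
) -> pd.DataFrame:
    """Counts of antibiotic biosynthesis/resistance annotations per sample.

    A record matches if GO:0017000 is among its GO ids or its protein
    name exactly matches an entry of the curated list
    (case-insensitive, whitespace-normalized).  Near-miss names are
    deliberately not matched: the list rule is exact.
    """
    names = {_norm_name(n) for n in (custom_protein_list or []) if str(n).strip()}
    if not names:
        logger.warning("empty custom protein list; matching on GO id only")
    go_hit = records["go_ids"].map(lambda c: ANTIBIOTIC_GO in _go_set(c))
    list_hit = records["protein_name"].map(lambda n: _norm_name(n) in names)
    return _aggregate(records.loc[go_hit | list_hit])


def filter_card_hits(
    hits: pd.DataFrame,
    max_evalue: float = CARD_MAX_EVALUE,
    min_zscore: float = CARD_MIN_ZSCORE,
    min_identity: float = CARD_MIN_IDENTITY,
) -> pd.DataFrame:
    """Significance-filter resistance-gene hits, then resolve best hits.

    Keeps hits with e-value strictly below ``max_evalue``, z-score
    strictly above ``min_zscore`` and percent identity strictly above
    ``min_identity``; then retains a single hit per read: highest
    z-score, ties broken by lowest e-value, then lexicographically
    first gene name.  Idempotent by construction.
    """
    ok = (
        (hits["e_value"] < max_evalue)
        & (hits["z_score"] > min_zscore)
        & (hits["pct_identity"] > min_identity)
    )
    passed = hits.loc[ok].copy()
    if passed.empty:
        return passed
    passed = passed.sort_values(
        ["sample", "dataset", "read_id", "z_score", "e_value", "gene"],
        ascending=[True, True, True, False, True, True],
        kind="mergesort",
    )
    best = passed.drop_duplicates(subset=["sample", "dataset", "read_id"], keep="first")
    return best.reset_index(drop=True)


def normalize_by_total(counts: pd.DataFrame, per_sample_totals: pd.Series) -> pd.DataFrame:
    """Relative abundances: count / total retained reads, per sample."""
    totals = per_sample_totals
    if isinstance(totals.index, pd.MultiIndex):
        totals = totals.groupby(level="sample").sum()
    out = counts.astype(float).copy()
    for sample in counts.index:
        total = float(totals.get(sample, 0))
        row = counts.loc[sample]
        if total <= 0:
            if (row != 0).any():
                raise ValueError(f"sample {sample!r} has counts but zero total reads")
            continue
        out.loc[sample] = row / total
    return out


def differential_abundance(
    abundance: pd.DataFrame,
    group_labels,
    n_perm: int = 10000,
    alpha: float = 0.05,
    seed: int | None = None,
) -> list[DiffAbundanceResult]:
    """Permutation test on per-feature group-mean differences.

    Features observed in fewer than two samples are dropped before
    testing.  The statistic is the difference of group means of
    normalized abundance (LS minus ES); the p-value is the two-sided
    add-one permutation tail over random label reassignments.  Fold
    changes use a pseudocount of half the smallest nonzero value in the
    table; a Benjamini-Hochberg adjusted p accompanies the raw p, but
    significance is called on the raw p at ``alpha``.
    """
    labels = np.asarray(group_labels)
    if len(labels) != len(abundance):
        raise ValueError("labels length does not match samples")
    uniq = set(labels)
    if uniq != {"ES", "LS"}:
        raise ValueError(f"need both ES and LS groups, got {sorted(uniq)}")
    is_ls = labels == "LS"
    if is_ls.sum() < 2 or (~is_ls).sum() < 2:
        raise ValueError("each group needs at least 2 samples")

    prevalent = (abundance > 0).sum(axis=0) >= 2
    kept = abundance.loc[:, prevalent]
    if kept.shape[1] == 0:
        return []
    X = kept.to_numpy(dtype=float)
    n, _ = X.shape
    n_ls = int(is_ls.sum())
    n_es = n - n_ls

    mean_ls = X[is_ls].mean(axis=0)
    mean_es = X[~is_ls].mean(axis=0)
    obs = mean_ls - mean_es

    rng = np.random.default_rng(seed)
    # permutation matrix of group indicators, one row per replicate
    perm = np.empty((n_perm, n), dtype=bool)
    base = np.zeros(n, dtype=bool)
    base[:n_ls] = True
    for r in range(n_perm):
        perm[r] = rng.permutation(base)
    pf = perm.astype(float)
    diff_null = pf @ X / n_ls - (1.0 - pf) @ X / n_es
    hits = (np.abs(diff_null) >= np.abs(obs)[None, :] - 1e-15).sum(axis=0)
    pvals = (1 + hits) / (1 + n_perm)
    adjusted = false_discovery_control(pvals, method="bh")

    nonzero = X[X > 0]
    pseudo = nonzero.min() / 2.0 if nonzero.size else 1.0
    log2fc = np.log2(mean_ls + pseudo) - np.log2(mean_es + pseudo)

    return [
        DiffAbundanceResult(
            feature=str(feat),
            log2fc=float(log2fc[k]),
            p_value=float(pvals[k]),
            adjusted_p=float(adjusted[k]),
            mean_es=float(mean_es[k]),
            mean_ls=float(mean_ls[k]),
            significant=bool(pvals[k] < alpha),
        )
        for k, feat in enumerate(kept.columns)
    ]


def argd_richness(
    retained_hits: pd.DataFrame, per_sample_totals: pd.Series, samples=None
) -> pd.DataFrame:
    """Per-sample normalized ARGD load and distinct-gene richness.

    Expects best-hit-resolved hits.  Returns one row per sample with
    ``n_hits_normalized`` (hits / total retained reads) and
    ``n_distinct_genes``.
    """
    totals = per_sample_totals
    if isinstance(totals.index, pd.MultiIndex):
        totals = totals.groupby(level="sample").sum()
    if samples is None:
        samples = sorted(set(retained_hits["sample"]) | set(totals.index))
    rows = []
    for sample in samples:
        sub = retained_hits.loc[retained_hits["sample"] == sample]
        total = float(totals.get(sample, 0))
        n_hits = len(sub)
        if n_hits and total <= 0:
            raise ValueError(f"sample {sample!r} has hits but zero total reads")
        rows.append(
            {
                "sample": sample,
                "n_hits_normalized": n_hits / total if total > 0 else 0.0,
                "n_distinct_genes": int(sub["gene"].nunique()),
            }
        )
    return pd.DataFrame(rows).set_index("sample")


def spearman_test(
    x, y, n_perm: int = 10000, seed: int | None = None
) -> tuple[float, float]:
    """Spearman rho with a two-sided permutation p-value.

    rho is the Pearson correlation of average-ranked values; the
    p-value permutes one variable's ranks, so it is exact in
    distribution for small n where the t approximation is doubtful.
    """
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if xv.shape != yv.shape or xv.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if xv.size < 5:
        raise ValueError("need at least 5 observations")
    if np.all(xv == xv[0]) or np.all(yv == yv[0]):
        raise ValueError("constant vector has no rank correlation")
    rx = rankdata(xv)
    ry = rankdata(yv)
    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    denom = np.linalg.norm(rxc) * np.linalg.norm(ryc)
    rho = float(rxc @ ryc / denom)
    rng = np.random.default_rng(seed)
    perms = rng.permuted(np.tile(ryc, (n_perm, 1)), axis=1)
    null = perms @ rxc / denom
    hits = int(np.count_nonzero(np.abs(null) >= abs(rho) - 1e-12))
    p = (1 + hits) / (1 + n_perm)
    return rho, float(p)


def feature_set_overlap(*sets) -> dict[tuple[bool, ...], int]:
    """Venn-region cardinalities for 2-4 feature-name sets.

    Keys are membership patterns, e.g. ``(True, False, True)`` is the
    region of elements in sets 1 and 3 but not 2; every non-empty
    pattern is reported (possibly with count 0).
    """
    if not 2 <= len(sets) <= 4:
        raise ValueError("feature_set_overlap takes 2 to 4 sets")
    sets = [set(s) for s in sets]
    universe = set().union(*sets)
    regions: dict[tuple[bool, ...], int] = {}
    k = len(sets)
    for code in range(1, 2**k):
        pattern = tuple(bool(code >> i & 1) for i in range(k))
        regions[pattern] = 0
    for item in universe:
        pattern = tuple(item in s for s in sets)
        regions[pattern] += 1
    return regions
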