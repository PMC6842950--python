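"""OTU-table containers, CSS normalization and core-community filtering."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "OtuTable",
    "CoreCommunity",
    "css_normalize",
    "prevalence_filter",
    "core_overlap",
]

PERIODS = ("ES", "LS")


@dataclass
class OtuTable:
    """Integer OTU counts with per-sample period labels and time order.

    ``counts`` holds samples as rows and OTUs as columns.
    ``sample_meta`` is indexed by sample id and must carry a ``period``
    column (``"ES"`` early spring / ``"LS"`` late spring) and a
    ``time_index`` column giving collection order.
    """

    counts: pd.DataFrame
    sample_meta: pd.DataFrame
    taxonomy: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        arr = self.counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise ValueError("OTU counts must be integers")
            self.counts = self.counts.astype(np.int64)
            arr = self.counts.to_numpy()
        if (arr < 0).any():
            raise ValueError("OTU counts must be non-negative")
        missing = self.counts.index.difference(self.sample_meta.index)
        if len(missing):
            raise ValueError(f"samples missing from sample_meta: {missing.tolist()}")
        for col in ("period", "time_index"):
            if col not in self.sample_meta.columns:
                raise ValueError(f"sample_meta lacks required column {col!r}")
        bad = set(self.sample_meta["period"]) - set(PERIODS)
        if bad:
            raise ValueError(f"unknown period labels: {sorted(bad)}")
        for period in PERIODS:
            t = self.sample_meta.loc[self.sample_meta["period"] == period, "time_index"]
            if t.duplicated().any():
                raise ValueError(f"duplicate time indices within period {period}")

    @property
    def samples(self) -> pd.Index:
        return self.counts.index

    @property
    def otus(self) -> pd.Index:
        return self.counts.columns

    def period_of(self, sample: str) -> str:
        return str(self.sample_meta.loc[sample, "period"])

    def samples_in_period(self, period: str) -> list[str]:
        """Sample ids of one period, sorted by collection order."""
        meta = self.sample_meta.loc[self.sample_meta["period"] == period]
        meta = meta.loc[meta.index.intersection(self.counts.index)]
        return meta.sort_values("time_index").index.tolist()

    def period_counts(self, period: str) -> pd.DataFrame:
        """Counts of one period's samples, time-ordered."""
        return self.counts.loc[self.samples_in_period(period)]


@dataclass(frozen=True)
class CoreCommunity:
    """OTUs present in at least ``min_samples`` samples of one period."""

    otu_ids: frozenset
    period: str
    min_samples: int
    n_samples_used: int

    @property
    def threshold(self) -> float:
        """Prevalence fraction corresponding to ``min_samples``."""
        return self.min_samples / self.n_samples_used

    def __len__(self) -> int:
        return len(self.otu_ids)


def css_normalize(
    counts: pd.DataFrame, quantile: float = 0.5, scale_constant: float = 1000.0
) -> pd.DataFrame:
    """Cumulative-sum scaling of a samples x OTUs count table.

    Each sample j is divided by the sum of its nonzero counts that do
    not exceed that sample's ``quantile``-th nonzero count (lower
    quantile convention), then multiplied by ``scale_constant``.
    Truncating the per-sample sum at a quantile keeps a handful of
    dominant OTUs from driving the scaling factor, the failure mode of
    plain total-sum scaling on amplicon data.

    Zeros stay zero.  Raises on an all-zero sample (no scaling factor
    is defined for it).
    """
    if not 0 < quantile <= 1:
        raise ValueError("quantile must be in (0, 1]")
    arr = counts.to_numpy(dtype=float)
    out = np.zeros_like(arr)
    for j, sample in enumerate(counts.index):
        row = arr[j]
        nz = row[row > 0]
        if nz.size == 0:
            raise ValueError(f"sample {sample!r} has no nonzero counts")
        q = np.quantile(nz, quantile, method="lower")
        s = nz[nz <= q].sum()
        out[j] = row * scale_constant / s
    return pd.DataFrame(out, index=counts.index, columns=counts.columns)


def prevalence_filter(
    table: OtuTable, min_samples: int, period: str | None = None
) -> CoreCommunity:
    """Core community: OTUs with nonzero counts in >= min_samples samples.

    Presence is raw count > 0 — membership does not depend on any
    normalization.  ``period`` restricts the computation to one
    sampling period's samples; omit it for a table that holds a single
    period.
    """
    if min_samples < 1:
        raise ValueError("min_samples must be >= 1")
    if period is not None:
        sub = table.period_counts(period)
        label = period
    else:
        periods = set(table.sample_meta.loc[table.samples, "period"])
        if len(periods) != 1:
            raise ValueError("table spans multiple periods; pass period= explicitly")
        label = periods.pop()
        sub = table.counts
    n = len(sub)
    if min_samples > n:
        raise ValueError(f"min_samples={min_samples} exceeds {n} samples in period {label}")
    prevalence = (sub > 0).sum(axis=0)
    members = frozenset(prevalence.index[prevalence >= min_samples])
    return CoreCommunity(
        otu_ids=members, period=label, min_samples=min_samples, n_samples_used=n
    )


def core_overlap(a: CoreCommunity, b: CoreCommunity) -> tuple[int, int, int]:
    """Sizes of two core communities and of their intersection."""
    return len(a.otu_ids), len(b.otu_ids), len(a.otu_ids & b.otu_ids)
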