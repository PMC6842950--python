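"""Synthetic snow-season data with planted, recoverable structure.

The generator emulates the sampling design the analysis assumes: an
early-spring (ES) and a late-spring (LS) series of surface snow
samples, an OTU count table with planted positively and negatively
co-varying OTU pairs, a chemistry table whose organic acids ramp up
across the season with below-detection-limit censoring, marker-gene
count tables with planted between-period log-fold enrichments, and
resistance-database hit tables that straddle the significance
thresholds.  Every table is reproducible from (config, seed), and the
planted structure is returned as an explicit truth object so recovery
can be tested.

Latent OTU model: Gaussian latent series are mapped through a
softmax-style composition and sampled multinomially at a Poisson
sequencing depth — the simplest model that exposes the compositional
effects (closure, depth variation) the downstream pipeline faces.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb

import numpy as np
import pandas as pd

from .chemistry import ChemTable
from .community import OtuTable

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "MarkerTable",
    "generate_otu_series",
    "generate_chemistry",
    "generate_marker_counts",
    "generate_card_hits",
]

# substream tags: one independent child stream per generated table, so
# each table is reproducible from (seed, tag) without generating the others
_STREAM_OTU = 1
_STREAM_CHEM = 2
_STREAM_MARKER = 3
_STREAM_CARD = 4

ORGANIC_ACIDS_UP = ["acetate", "formate", "succinate", "oxalate", "glutarate", "propionate"]
ORGANIC_ACID_DOWN = "lactate"
ORGANIC_ACIDS = ORGANIC_ACIDS_UP + [ORGANIC_ACID_DOWN]
INORGANIC_IONS = ["sulfate", "nitrate", "chloride", "sodium", "calcium", "bromide", "ammonium", "MSA"]


def _default_lod() -> dict[str, float]:
    lods = {a: 0.5 for a in ORGANIC_ACIDS}
    lods.update({a: 1.0 for a in INORGANIC_IONS})
    return lods


@dataclass
class SyntheticConfig:
    """Knobs of the synthetic season; defaults mirror the field design.

    20 ES + 16 LS samples for the OTU series and 8 ES + 12 LS for the
    marker tables reproduce the group imbalance of the study design.
    ``driver_strength`` in [0, 1] is the latent correlation planted in
    co-varying pairs (at ``noise_sd = 1`` it equals the expected latent
    Pearson correlation); ``organic_acid_ramp`` is the total organic
    acid increase per collection step in ppb, set so the seasonal total
    spans from a few ppb to around two thousand.
    """

    n_samples_es: int = 20
    n_samples_ls: int = 16
    n_otus: int = 300
    n_pos_pairs: int = 8
    n_neg_pairs: int = 2
    driver_strength: float = 0.9
    noise_sd: float = 1.0
    depth_mean: float = 10000.0
    organic_acid_ramp: float = 55.0
    lod_table: dict[str, float] = field(default_factory=_default_lod)
    n_marker_features: int = 60
    n_enriched_markers: int = 6
    planted_log2fc: float = 4.0
    nb_dispersion: float = 0.3
    n_marker_samples_es: int = 8
    n_marker_samples_ls: int = 12
    seed: int = 0

    def validate(self) -> None:
        counts = [
            self.n_samples_es,
            self.n_samples_ls,
            self.n_otus,
            self.n_pos_pairs,
            self.n_neg_pairs,
            self.n_marker_features,
            self.n_enriched_markers,
            self.n_marker_samples_es,
            self.n_marker_samples_ls,
        ]
        if any(c < 0 for c in counts):
            raise ValueError("all counts must be non-negative")
        if not 0.0 <= self.driver_strength <= 1.0:
            raise ValueError("driver_strength must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        if self.n_otus >= 2 and self.n_pos_pairs + self.n_neg_pairs > comb(self.n_otus, 2):
            raise ValueError("planted pairs exceed available distinct pairs")
        if self.n_enriched_markers > self.n_marker_features:
            raise ValueError("more enriched features than marker features")
        if not self.lod_table:
            raise ValueError("lod_table must not be empty")
        if self.organic_acid_ramp < 0:
            raise ValueError("organic_acid_ramp must be >= 0")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([int(self.seed), stream]))


@dataclass
class SyntheticTruth:
    """Ground truth of the planted structure.

    ``planted_pairs`` are unordered OTU-id pairs with their planted
    association sign; ``enriched_features`` carry the period the
    feature is enriched in and the signed true log2 fold change (LS
    over ES convention: negative means ES-enriched).
    """

    planted_pairs: list[tuple[str, str, int]] = field(default_factory=list)
    enriched_features: list[tuple[str, str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        keys = [tuple(sorted((i, j))) for i, j, _ in self.planted_pairs]
        if len(keys) != len(set(keys)):
            raise ValueError("planted pairs must be distinct unordered pairs")
        if any(i == j for i, j, _ in self.planted_pairs):
            raise ValueError("planted pairs must join distinct OTUs")
        feats = [f for f, _, _ in self.enriched_features]
        if len(feats) != len(set(feats)):
            raise ValueError("no feature may be enriched twice")

    def positive_pairs(self) -> set[tuple[str, str]]:
        return {tuple(sorted((i, j))) for i, j, s in self.planted_pairs if s == 1}

    def negative_pairs(self) -> set[tuple[str, str]]:
        return {tuple(sorted((i, j))) for i, j, s in self.planted_pairs if s == -1}


@dataclass
class MarkerTable:
    """Marker counts (samples x features) with per-sample period labels."""

    counts: pd.DataFrame
    sample_meta: pd.DataFrame


def _ar1(rng: np.random.Generator, n: int, phi: float = 0.8) -> np.ndarray:
    """Unit-variance AR(1) series — a smooth 'driver' with local runs."""
    innov = rng.normal(size=n) * np.sqrt(1 - phi**2)
    x = np.empty(n)
    x[0] = rng.normal()
    for t in range(1, n):
        x[t] = phi * x[t - 1] + innov[t]
    return x


def _sample_ids(config: SyntheticConfig) -> tuple[list[str], pd.DataFrame]:
    n = config.n_samples_es + config.n_samples_ls
    ids = [f"S{k + 1:02d}" for k in range(n)]
    period = ["ES"] * config.n_samples_es + ["LS"] * config.n_samples_ls
    meta = pd.DataFrame(
        {"period": period, "time_index": np.arange(n, dtype=int)}, index=pd.Index(ids, name="sample")
    )
    return ids, meta


def generate_otu_series(
    config: SyntheticConfig, return_latent: bool = False
) -> tuple[OtuTable, SyntheticTruth]:
    """OTU count time series with planted co-varying pairs.

    Each planted pair shares a smooth latent driver: both members load
    on it with weight ``driver_strength`` (the second member with
    opposite sign for negative pairs) plus independent Gaussian noise;
    non-planted OTUs are independent noise.  Latent series are added to
    static log-abundance offsets, mapped through a softmax to relative
    abundances, and sampled multinomially at Poisson(depth_mean) reads.

    With ``return_latent=True`` the pre-compositional latent series are
    returned as a third element (samples x OTUs), for calibration and
    construction checks.
    """
    config.validate()
    if min(config.n_samples_es, config.n_samples_ls) < 4:
        raise ValueError("each period needs at least 4 samples for a usable time series")
    rng = config.rng(_STREAM_OTU)
    ids, meta = _sample_ids(config)
    n = len(ids)
    p = config.n_otus
    otus = [f"OTU{k + 1:04d}" for k in range(p)]

    n_pairs = config.n_pos_pairs + config.n_neg_pairs
    if 2 * n_pairs <= p:
        members = rng.choice(p, size=2 * n_pairs, replace=False)
        pair_idx = [(int(members[2 * k]), int(members[2 * k + 1])) for k in range(n_pairs)]
    else:  # dense planting: distinct unordered pairs, OTUs may repeat
        pair_idx = []
        seen: set[tuple[int, int]] = set()
        while len(pair_idx) < n_pairs:
            i, j = rng.choice(p, size=2, replace=False)
            key = (min(i, j), max(i, j))
            if key not in seen:
                seen.add(key)
                pair_idx.append((int(i), int(j)))
    signs = [1] * config.n_pos_pairs + [-1] * config.n_neg_pairs

    ds = config.driver_strength
    noise_scale = config.noise_sd * np.sqrt(max(0.0, 1.0 - ds**2))
    latent = rng.normal(size=(n, p)) * config.noise_sd
    for (i, j), sign in zip(pair_idx, signs):
        driver = _ar1(rng, n)
        latent[:, i] = ds * driver + noise_scale * rng.normal(size=n)
        latent[:, j] = sign * ds * driver + noise_scale * rng.normal(size=n)

    base = rng.normal(scale=1.5, size=p)  # static rank-abundance structure
    logits = base[None, :] + latent
    probs = np.exp(logits - logits.max(axis=1, keepdims=True))
    probs /= probs.sum(axis=1, keepdims=True)

    counts = np.empty((n, p), dtype=np.int64)
    for t in range(n):
        depth = rng.poisson(config.depth_mean)
        counts[t] = rng.multinomial(depth, probs[t])

    table = OtuTable(
        counts=pd.DataFrame(counts, index=pd.Index(ids, name="sample"), columns=otus),
        sample_meta=meta,
    )
    truth = SyntheticTruth(
        planted_pairs=[(otus[i], otus[j], s) for (i, j), s in zip(pair_idx, signs)]
    )
    if return_latent:
        latent_df = pd.DataFrame(latent, index=pd.Index(ids, name="sample"), columns=otus)
        return table, truth, latent_df
    return table, truth


def generate_chemistry(
    config: SyntheticConfig, sample_meta: pd.DataFrame | None = None
) -> ChemTable:
    """Seasonal chemistry table with censoring below detection limits.

    Rising organic acids follow linear ramps (weights split the total
    ``organic_acid_ramp`` across acids) plus noise; lactate declines;
    inorganic ions decline or stay flat; pH drifts mildly.  Values
    below an analyte's LOD are withheld and flagged, exactly as a
    chromatography export would report "<LOD".

    ``sample_meta`` (a period/time_index frame as produced for the OTU
    or marker samples) generates chemistry for an arbitrary sample
    series; by default the OTU-series samples are used.
    """
    config.validate()
    rng = config.rng(_STREAM_CHEM)
    if sample_meta is None:
        ids, meta = _sample_ids(config)
    else:
        meta = sample_meta
        ids = list(meta.index)
    n = len(ids)
    t = meta["time_index"].to_numpy(dtype=float)

    # ramp weights over the rising acids, dominated by acetate/formate
    weights = np.array([0.35, 0.25, 0.15, 0.12, 0.08, 0.05])
    base_up = np.array([0.6, 0.5, 0.4, 0.4, 0.3, 0.3])
    cols: dict[str, np.ndarray] = {}
    for k, acid in enumerate(ORGANIC_ACIDS_UP):
        signal = base_up[k] + weights[k] * config.organic_acid_ramp * t
        noise = rng.normal(size=n) * config.noise_sd * (0.05 * signal + 0.1)
        cols[acid] = np.maximum(signal + noise, 0.0)
    lact_signal = np.maximum(5.0 - 5.0 * t / max(n - 1, 1), 0.05)
    cols[ORGANIC_ACID_DOWN] = np.maximum(
        lact_signal + rng.normal(size=n) * config.noise_sd * (0.05 * lact_signal + 0.1), 0.0
    )
    for k, ion in enumerate(INORGANIC_IONS):
        start = 40.0 / (k + 1) + 5.0
        slope = -start * 0.6 / max(n - 1, 1) if k % 2 == 0 else 0.0  # half decline, half flat
        signal = np.maximum(start + slope * t, 0.5)
        cols[ion] = np.maximum(
            signal + rng.normal(size=n) * config.noise_sd * (0.05 * signal + 0.2), 0.0
        )
    ph = 5.3 + 0.01 * t + rng.normal(size=n) * config.noise_sd * 0.05
    cols["pH"] = ph

    values = pd.DataFrame(cols, index=pd.Index(ids, name="sample"))
    lod = pd.Series(config.lod_table, dtype=float)
    below = pd.DataFrame(False, index=values.index, columns=values.columns)
    for analyte in values.columns:
        if analyte == "pH" or analyte not in lod.index:
            continue
        censored = values[analyte] < lod[analyte]
        below[analyte] = censored
        values.loc[censored, analyte] = np.nan
    return ChemTable(
        values=values,
        below_lod=below,
        lod=lod,
        ph_column="pH",
        period=meta["period"],
    )


def _marker_sample_meta(config: SyntheticConfig) -> pd.DataFrame:
    n = config.n_marker_samples_es + config.n_marker_samples_ls
    ids = [f"M{k + 1:02d}" for k in range(n)]
    period = ["ES"] * config.n_marker_samples_es + ["LS"] * config.n_marker_samples_ls
    return pd.DataFrame(
        {"period": period, "time_index": np.arange(n, dtype=int)},
        index=pd.Index(ids, name="sample"),
    )


def generate_marker_counts(config: SyntheticConfig) -> tuple[MarkerTable, SyntheticTruth]:
    """Negative-binomial marker counts with planted period enrichments.

    Enriched features alternate direction (ES, LS, ES, ...) and carry a
    between-period mean ratio of ``2 ** planted_log2fc``; per-sample
    lognormal size factors vary the totals so normalization is actually
    exercised.  Counts are gamma-Poisson draws with dispersion
    ``nb_dispersion`` (variance mu + alpha mu^2).
    """
    config.validate()
    rng = config.rng(_STREAM_MARKER)
    meta = _marker_sample_meta(config)
    n = len(meta)
    features = [f"F{k + 1:03d}" for k in range(config.n_marker_features)]
    mu = rng.lognormal(mean=np.log(50.0), sigma=1.0, size=config.n_marker_features)

    half = config.planted_log2fc / 2.0
    enriched: list[tuple[str, str, float]] = []
    fold = np.ones((n, config.n_marker_features))
    is_ls = (meta["period"] == "LS").to_numpy()
    for k in range(config.n_enriched_markers):
        direction = "ES" if k % 2 == 0 else "LS"
        lfc = -config.planted_log2fc if direction == "ES" else config.planted_log2fc
        enriched.append((features[k], direction, float(lfc)))
        up = ~is_ls if direction == "ES" else is_ls
        fold[up, k] = 2.0**half
        fold[~up, k] = 2.0**-half

    size_factor = rng.lognormal(mean=0.0, sigma=0.4, size=n)
    mean = size_factor[:, None] * mu[None, :] * fold
    shape = 1.0 / config.nb_dispersion
    lam = rng.gamma(shape, mean / shape)
    counts = rng.poisson(lam)

    table = MarkerTable(
        counts=pd.DataFrame(counts, index=meta.index, columns=features), sample_meta=meta
    )
    return table, SyntheticTruth(enriched_features=enriched)


_ES_GENES = ["catB3", "tet(A)", "blaOXA-2", "vanRA"]
_LS_GENES = _ES_GENES + [
    "macB",
    "mexB",
    "aadA2",
    "ermF",
    "sul1",
    "qnrS1",
    "blaTEM-1",
    "dfrA1",
]


def generate_card_hits(config: SyntheticConfig) -> pd.DataFrame:
    """Resistance-database hit table straddling the filter thresholds.

    Late-spring samples draw more hits from a richer gene pool, and the
    per-sample hit rate rises with collection order, planting a
    monotone ARGD-versus-season association.  Around 30% of hits
    violate exactly one threshold (e-value, z-score or identity), and
    some reads carry several passing candidate hits, so both the
    significance filter and the best-hit resolution are exercised.
    """
    config.validate()
    rng = config.rng(_STREAM_CARD)
    meta = _marker_sample_meta(config)
    rows: list[dict] = []
    for sample, row in meta.iterrows():
        period = row["period"]
        t = int(row["time_index"])
        rate = 3.0 + 0.8 * t
        pool = _ES_GENES if period == "ES" else _LS_GENES
        n_reads = rng.poisson(rate)
        for r in range(n_reads):
            read_id = f"{sample}_read{r + 1:04d}"
            n_hits = 1 + rng.binomial(2, 0.25)  # occasionally multi-hit reads
            for _ in range(n_hits):
                gene = str(rng.choice(pool))
                e_value = 10.0 ** -rng.uniform(11, 30)
                z = rng.uniform(51, 120)
                ident = rng.uniform(61, 95)
                if rng.random() < 0.3:  # break exactly one threshold
                    which = rng.integers(3)
                    if which == 0:
                        e_value = 10.0 ** -rng.uniform(2, 10)
                    elif which == 1:
                        z = rng.uniform(5, 50)
                    else:
                        ident = rng.uniform(20, 60)
                rows.append(
                    {
                        "read_id": read_id,
                        "sample": sample,
                        "dataset": "MT",
                        "gene": gene,
                        "e_value": e_value,
                        "z_score": z,
                        "pct_identity": ident,
                    }
                )
    columns = ["read_id", "sample", "dataset", "gene", "e_value", "z_score", "pct_identity"]
    return pd.DataFrame(rows, columns=columns)
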