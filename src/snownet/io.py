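"""Readers, writers, run configuration and the end-to-end pipeline.

All tabular outputs are TSV with a commented ``# key: value`` header
block recording the parameters, seed and config hash in effect, so
every result file is self-describing and grep-able.  Censored
chemistry cells are written as ``<LOD`` and restored to censoring
flags on read.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from . import chemistry as chem
from . import community as comm
from . import lsa as lsa_mod
from . import markers as mk
from . import network as net
from .chemistry import ChemTable
from .community import CoreCommunity, OtuTable
from .lsa import LsaPair
from .simulate import (
    ORGANIC_ACIDS,
    SyntheticConfig,
    SyntheticTruth,
    generate_card_hits,
    generate_chemistry,
    generate_marker_counts,
    generate_otu_series,
)

logger = logging.getLogger(__name__)

LOD_TOKEN = "<LOD"

__all__ = [
    "RunConfig",
    "PipelineReport",
    "load_tables",
    "run_pipeline",
    "read_otu_table",
    "write_otu_table",
    "read_chem_table",
    "write_chem_table",
    "read_annotations",
    "write_annotations",
    "read_card_hits",
    "write_card_hits",
    "read_pairs",
    "write_pairs",
    "read_truth",
    "write_truth",
    "read_protein_list",
    "default_antibiotic_list",
]


# ---------------------------------------------------------------- writers

def _header_block(meta: dict) -> str:
    return "".join(f"# {k}: {v}\n" for k, v in meta.items())


def _write_table(df: pd.DataFrame, path, meta: dict | None = None, sep: str = "\t") -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if meta:
            fh.write(_header_block(meta))
        df.to_csv(fh, sep=sep)


def write_otu_table(table: OtuTable, counts_path, meta_path=None, tax_path=None) -> None:
    """OTU TSV with OTUs as rows (first column ``otu_id``), samples as columns."""
    out = table.counts.T
    out.index.name = "otu_id"
    _write_table(out, counts_path)
    if meta_path is not None:
        _write_table(table.sample_meta, meta_path)
    if tax_path is not None and table.taxonomy is not None:
        _write_table(table.taxonomy, tax_path)


def read_otu_table(counts_path, meta_path, tax_path=None) -> OtuTable:
    counts = pd.read_csv(counts_path, sep="\t", index_col=0, comment="#")
    for col in counts.columns:
        if not np.issubdtype(counts[col].dtype, np.number):
            bad = counts.index[pd.to_numeric(counts[col], errors="coerce").isna()]
            raise ValueError(
                f"non-numeric count at otu {bad.tolist()[:3]}, sample column {col!r}"
            )
    meta = pd.read_csv(meta_path, sep="\t", index_col=0, comment="#")
    tax = pd.read_csv(tax_path, sep="\t", index_col=0, comment="#") if tax_path else None
    counts = counts.T
    counts.index.name = "sample"
    return OtuTable(counts=counts, sample_meta=meta, taxonomy=tax)


def write_chem_table(table: ChemTable, values_path, lod_path) -> None:
    """Chemistry CSV (censored cells as ``<LOD``) plus companion LOD CSV."""
    out = table.values.astype(object).copy()
    mask = table.below_lod
    for col in out.columns:
        out.loc[mask[col], col] = LOD_TOKEN
    _write_table(out, values_path, sep=",")
    lod = table.lod.rename("lod").to_frame()
    lod.index.name = "analyte"
    _write_table(lod, lod_path, sep=",")


def read_chem_table(values_path, lod_path, ph_column: str = "pH", period=None) -> ChemTable:
    raw = pd.read_csv(values_path, index_col=0, comment="#", dtype=str)
    lod = pd.read_csv(lod_path, index_col=0, comment="#")["lod"].astype(float)
    mask = raw.apply(lambda col: col.str.strip() == LOD_TOKEN)
    values = raw.mask(mask).apply(pd.to_numeric)
    return ChemTable(
        values=values, below_lod=mask, lod=lod, ph_column=ph_column, period=period
    )


def write_annotations(records: pd.DataFrame, path) -> None:
    out = records.copy()
    out["go_ids"] = out["go_ids"].map(
        lambda c: ";".join(sorted(mk._go_set(c))) if not isinstance(c, str) else c
    )
    _write_table(out.set_index("read_id"), path)


def read_annotations(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", keep_default_na=False, na_values=[])
    df["is_eukaryote"] = df["is_eukaryote"].astype(str).str.lower().isin(["true", "1"])
    return df


def write_card_hits(hits: pd.DataFrame, path) -> None:
    _write_table(hits.set_index("read_id"), path)


def read_card_hits(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    for col in ("e_value", "z_score", "pct_identity"):
        df[col] = pd.to_numeric(df[col])
    return df


def write_pairs(pairs: list[LsaPair], path, meta: dict | None = None) -> None:
    df = pd.DataFrame([asdict(p) for p in pairs])
    if df.empty:
        df = pd.DataFrame(
            columns=["otu_i", "otu_j", "score", "sign", "p_value", "n_timepoints", "max_delay"]
        )
    _write_table(df.set_index("otu_i"), path, meta=meta)


def read_pairs(path) -> list[LsaPair]:
    df = pd.read_csv(path, sep="\t", comment="#")
    return [
        LsaPair(
            otu_i=str(r.otu_i),
            otu_j=str(r.otu_j),
            score=float(r.score),
            sign=int(r.sign),
            p_value=float(r.p_value),
            n_timepoints=int(r.n_timepoints),
            max_delay=int(r.max_delay),
        )
        for r in df.itertuples()
    ]


def write_truth(truth: SyntheticTruth, path) -> None:
    """Planted structure as line-oriented key/value text."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for i, j, s in truth.planted_pairs:
            fh.write(f"pair\t{i}\t{j}\t{s:+d}\n")
        for feat, direction, lfc in truth.enriched_features:
            fh.write(f"enriched\t{feat}\t{direction}\t{lfc}\n")


def read_truth(path) -> SyntheticTruth:
    pairs, feats = [], []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        kind, *rest = line.split("\t")
        if kind == "pair":
            pairs.append((rest[0], rest[1], int(rest[2])))
        elif kind == "enriched":
            feats.append((rest[0], rest[1], float(rest[2])))
        else:
            raise ValueError(f"unknown truth record {kind!r}")
    return SyntheticTruth(planted_pairs=pairs, enriched_features=feats)


def read_protein_list(path) -> list[str]:
    """Curated protein-name list: plain text, one name per line."""
    return [
        line.strip()
        for line in Path(path).read_text().splitlines()
        if line.strip() and not line.startswith("#")
    ]


def default_antibiotic_list() -> list[str]:
    """Bundled synthetic stand-in for a curated antibiotic protein list."""
    here = Path(__file__).parent / "data" / "synthetic_antibiotic_protein_names.txt"
    return read_protein_list(here)


# ------------------------------------------------------------- run config

@dataclass
class RunConfig:
    """Everything a pipeline run needs: inputs, thresholds, seed, outputs.

    File paths may all be None for a fully synthetic run, in which case
    ``synthetic`` supplies the generator configuration.  ``min_samples``
    for the core-community filter is per period; when left None it
    defaults to half the period's sample count rounded up (so exactly
    50% prevalence is retained) and the value actually used is written
    to the run record.
    """

    # inputs (None => synthesize)
    otu_counts: str | None = None
    otu_meta: str | None = None
    chem_values: str | None = None
    chem_lod: str | None = None
    annotations: str | None = None
    card_hits: str | None = None
    antibiotic_list: str | None = None
    # thresholds
    alpha: float = 0.05
    max_delay: int = 0
    min_samples_es: int | None = None
    min_samples_ls: int | None = None
    css_quantile: float = 0.5
    css_scale: float = 1000.0
    card_max_evalue: float = mk.CARD_MAX_EVALUE
    card_min_zscore: float = mk.CARD_MIN_ZSCORE
    card_min_identity: float = mk.CARD_MIN_IDENTITY
    n_perm_lsa: int = 1000
    n_perm_group: int = 10000
    n_perm_coinertia: int = 10000
    n_perm_diff: int = 10000
    n_perm_spearman: int = 10000
    seed: int = 0
    outdir: str = "snownet_out"
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        synth = raw.pop("synthetic", None)
        cfg = cls(**raw)
        if synth:
            cfg.synthetic = SyntheticConfig(**synth)
        if "seed" not in raw:
            raise ValueError("seed is mandatory in a run configuration")
        cfg.synthetic.seed = cfg.synthetic.seed or cfg.seed
        return cfg

    def config_hash(self) -> str:
        payload = asdict(self)
        payload.pop("outdir", None)  # output location does not change results
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def record(self) -> dict:
        return {
            "config_hash": self.config_hash(),
            "seed": self.seed,
            "alpha": self.alpha,
            "max_delay": self.max_delay,
            "community_distance": "braycurtis",
            "chemistry_distance": "euclidean (log, standardized)",
            "modularity_method": "greedy agglomerative (deterministic)",
            "differential_abundance": "permutation test on normalized group means",
        }


# --------------------------------------------------------------- pipeline

@dataclass
class PipelineReport:
    """Numeric results of one end-to-end run."""

    chem_group_f: float
    chem_group_p: float
    community_group_f: float
    community_group_p: float
    coinertia_rv: float
    coinertia_p: float
    core_sizes: dict
    core_shared: int
    network_summaries: dict
    positive_ratios: dict
    plasmid_diff: list
    antibiotic_diff: list
    argd_richness: pd.DataFrame
    spearman_rho: float
    spearman_p: float
    truth: SyntheticTruth | None = None


def load_tables(config: RunConfig):
    """Load and cross-validate the input tables named in the config.

    Samples present in the OTU table but absent from the chemistry
    table (or vice versa) are reported; a sample without a period label
    is a hard error.
    """
    otu = read_otu_table(config.otu_counts, config.otu_meta)
    chem_table = read_chem_table(config.chem_values, config.chem_lod)
    orphans = otu.samples.difference(chem_table.samples)
    if len(orphans):
        logger.warning("samples without chemistry: %s", orphans.tolist())
    records = read_annotations(config.annotations) if config.annotations else None
    hits = read_card_hits(config.card_hits) if config.card_hits else None
    chem_table.period = otu.sample_meta["period"].reindex(chem_table.samples)
    return otu, chem_table, records, hits


def _min_samples(config: RunConfig, table: OtuTable, period: str) -> int:
    override = config.min_samples_es if period == "ES" else config.min_samples_ls
    if override is not None:
        return override
    n = len(table.samples_in_period(period))
    return int(np.ceil(n / 2))


def _seed(config: RunConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, 100 + stage]))


def _stage_seed(config: RunConfig, stage: int) -> int:
    # small derived integer seeds so stages are independently re-runnable
    return int(np.random.SeedSequence([config.seed, 100 + stage]).generate_state(1)[0] % (2**31))


def run_pipeline(config: RunConfig, write: bool = True) -> PipelineReport:
    """Chain every stage: chemistry, community, LSA, networks, markers.

    With no input files configured, the synthetic generator supplies
    the tables (and the report carries the planted truth for recovery
    checks).  All outputs land in ``config.outdir`` as TSV files with a
    run-record header.
    """
    outdir = Path(config.outdir)
    record = config.record()

    synthetic_run = config.otu_counts is None
    if synthetic_run:
        scfg = config.synthetic
        otu, truth_pairs = generate_otu_series(scfg)
        chem_table = generate_chemistry(scfg)
        marker_table, truth_markers = generate_marker_counts(scfg)
        hits = generate_card_hits(scfg)
        chem_markers = generate_chemistry(scfg, sample_meta=marker_table.sample_meta)
        truth = SyntheticTruth(
            planted_pairs=truth_pairs.planted_pairs,
            enriched_features=truth_markers.enriched_features,
        )
    else:
        otu, chem_table, records, hits = load_tables(config)
        truth = None
        marker_table = None
        chem_markers = None

    # ---- chemistry: impute -> log -> PCA, group test
    imputed = chem.impute_below_lod(chem_table)
    logged = chem.log_transform(imputed)
    ordination = chem.pca(logged, n_axes=2)
    chem_std = (logged - logged.mean()) / logged.std(ddof=1).replace(0, 1.0)
    periods_chem = otu.sample_meta.loc[logged.index, "period"].to_numpy()
    chem_f, chem_p = chem.permutation_group_test(
        chem_std,
        periods_chem,
        distance="euclidean",
        n_perm=config.n_perm_group,
        seed=_stage_seed(config, 1),
    )

    # ---- community: CSS normalize, cores, group test, co-inertia
    normalized = comm.css_normalize(otu.counts, config.css_quantile, config.css_scale)
    periods_otu = otu.sample_meta.loc[otu.samples, "period"].to_numpy()
    comm_f, comm_p = chem.permutation_group_test(
        normalized,
        periods_otu,
        distance="braycurtis",
        n_perm=config.n_perm_group,
        seed=_stage_seed(config, 2),
    )
    cores: dict[str, CoreCommunity] = {}
    for period in ("ES", "LS"):
        cores[period] = comm.prevalence_filter(otu, _min_samples(config, otu, period), period)
    n_es, n_ls, n_shared = comm.core_overlap(cores["ES"], cores["LS"])
    coin = chem.coinertia(
        chem_std,
        normalized.loc[chem_std.index],
        n_perm=config.n_perm_coinertia,
        seed=_stage_seed(config, 3),
    )

    # ---- LSA + networks per period
    summaries: dict[str, net.NetworkSummary] = {}
    ratios: dict[str, float] = {}
    pairs_by_period: dict[str, list[LsaPair]] = {}
    for period in ("ES", "LS"):
        core = cores[period]
        members = sorted(core.otu_ids)
        sub = normalized.loc[otu.samples_in_period(period), members]
        pairs = lsa_mod.lsa_all_pairs(
            sub,
            max_delay=config.max_delay,
            alpha=config.alpha,
            n_perm=config.n_perm_lsa,
            seed=_stage_seed(config, 4),
            time_index=otu.sample_meta.loc[sub.index, "time_index"].to_numpy(),
        )
        pairs_by_period[period] = pairs
        graph = net.build_network(pairs, period=period)
        summary = net.network_summary(graph)
        summaries[period] = summary
        ratios[period] = (
            net.positive_ratio(summary.n_pos_edges, len(core)) if len(core) >= 2 else float("nan")
        )
        if write:
            write_pairs(pairs, outdir / f"lsa_pairs_{period}.tsv", meta=record)
            edges = nx.to_pandas_edgelist(graph)
            _write_table(edges.set_index("source") if not edges.empty else edges, outdir / f"network_{period}.tsv", meta=record)
            outdir.mkdir(parents=True, exist_ok=True)
            nx.write_graphml(graph, outdir / f"network_{period}.graphml")

    # ---- markers
    if synthetic_run:
        marker_norm = mk.normalize_by_total(
            marker_table.counts, marker_table.counts.sum(axis=1)
        )
        labels = marker_table.sample_meta["period"].to_numpy()
        diff = mk.differential_abundance(
            marker_norm,
            labels,
            n_perm=config.n_perm_diff,
            alpha=config.alpha,
            seed=_stage_seed(config, 5),
        )
        plasmid_diff = diff
        antibiotic_diff = []
        retained = mk.filter_card_hits(
            hits, config.card_max_evalue, config.card_min_zscore, config.card_min_identity
        )
        totals = marker_table.counts.sum(axis=1).astype(float)
        richness = mk.argd_richness(retained, totals, samples=marker_table.counts.index)
        chem_m = chem.impute_below_lod(chem_markers)
        acids = [a for a in ORGANIC_ACIDS if a in chem_m.values.columns]
        total_acids = chem_m.values[acids].sum(axis=1).loc[richness.index]
    else:
        plasmid_diff: list = []
        antibiotic_diff: list = []
        totals = pd.Series(dtype=float)
        if records is not None:
            records_clean = mk.remove_eukaryotes(records)
            totals = mk.sample_read_totals(records_clean).groupby(level="sample").sum().astype(float)
            plasmid_counts = mk.select_plasmid_markers(records_clean)
            ab_list = (
                read_protein_list(config.antibiotic_list)
                if config.antibiotic_list
                else default_antibiotic_list()
            )
            antibiotic_counts = mk.select_antibiotic_markers(records_clean, ab_list)
            period_by_sample = records_clean.drop_duplicates("sample").set_index("sample")["period"]

            def _diff(counts: pd.DataFrame, stage: int):
                if counts.empty:
                    return []
                norm = mk.normalize_by_total(counts, totals)
                labels = period_by_sample.reindex(norm.index).to_numpy()
                return mk.differential_abundance(
                    norm,
                    labels,
                    n_perm=config.n_perm_diff,
                    alpha=config.alpha,
                    seed=_stage_seed(config, stage),
                )

            plasmid_diff = _diff(plasmid_counts, 5)
            antibiotic_diff = _diff(antibiotic_counts, 6)
        retained = mk.filter_card_hits(
            hits, config.card_max_evalue, config.card_min_zscore, config.card_min_identity
        ) if hits is not None else pd.DataFrame(columns=mk.CARD_COLUMNS)
        if totals.empty and hits is not None:
            # no annotation table: fall back to hit counts as denominators
            totals = retained.groupby("sample").size().astype(float)
        richness = mk.argd_richness(retained, totals)
        imputed_all = chem.impute_below_lod(chem_table)
        acids = [a for a in ORGANIC_ACIDS if a in imputed_all.values.columns]
        shared = richness.index.intersection(imputed_all.values.index)
        richness = richness.loc[shared]
        total_acids = imputed_all.values.loc[shared, acids].sum(axis=1)

    if len(richness) >= 5:
        rho, sp_p = mk.spearman_test(
            richness["n_hits_normalized"].to_numpy(),
            total_acids.to_numpy(),
            n_perm=config.n_perm_spearman,
            seed=_stage_seed(config, 7),
        )
    else:
        logger.warning("fewer than 5 samples with both ARGD and chemistry; skipping correlation")
        rho, sp_p = float("nan"), float("nan")

    report = PipelineReport(
        chem_group_f=chem_f,
        chem_group_p=chem_p,
        community_group_f=comm_f,
        community_group_p=comm_p,
        coinertia_rv=coin.rv,
        coinertia_p=coin.p_value,
        core_sizes={"ES": n_es, "LS": n_ls},
        core_shared=n_shared,
        network_summaries=summaries,
        positive_ratios=ratios,
        plasmid_diff=plasmid_diff,
        antibiotic_diff=antibiotic_diff,
        argd_richness=richness,
        spearman_rho=rho,
        spearman_p=sp_p,
        truth=truth,
    )

    if write:
        _write_report(report, config, record, ordination)
    return report


def _write_report(report: PipelineReport, config: RunConfig, record: dict, ordination) -> None:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _write_table(ordination.scores, outdir / "chemistry_pca_scores.tsv", meta=record)
    _write_table(ordination.loadings, outdir / "chemistry_pca_loadings.tsv", meta=record)

    rows = []
    for period, s in report.network_summaries.items():
        row = {"period": period, **{k: v for k, v in asdict(s).items()}}
        row["positive_ratio"] = report.positive_ratios[period]
        rows.append(row)
    _write_table(pd.DataFrame(rows).set_index("period"), outdir / "network_summaries.tsv", meta=record)

    stats = pd.DataFrame(
        [
            {"quantity": "chem_group_pseudo_F", "value": report.chem_group_f},
            {"quantity": "chem_group_p", "value": report.chem_group_p},
            {"quantity": "community_group_pseudo_F", "value": report.community_group_f},
            {"quantity": "community_group_p", "value": report.community_group_p},
            {"quantity": "coinertia_rv", "value": report.coinertia_rv},
            {"quantity": "coinertia_p", "value": report.coinertia_p},
            {"quantity": "core_size_ES", "value": report.core_sizes["ES"]},
            {"quantity": "core_size_LS", "value": report.core_sizes["LS"]},
            {"quantity": "core_shared", "value": report.core_shared},
            {"quantity": "spearman_rho", "value": report.spearman_rho},
            {"quantity": "spearman_p", "value": report.spearman_p},
        ]
    ).set_index("quantity")
    _write_table(stats, outdir / "summary_statistics.tsv", meta=record)

    for name, diff in (("plasmid", report.plasmid_diff), ("antibiotic", report.antibiotic_diff)):
        if diff:
            df = pd.DataFrame([asdict(d) for d in diff]).set_index("feature")
            _write_table(df, outdir / f"diff_abundance_{name}.tsv", meta=record)
    _write_table(report.argd_richness, outdir / "argd_richness.tsv", meta=record)
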