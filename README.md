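# snownet

Seasonal shifts between cooperation and competition in snow microbial
communities, quantified from paired early-spring (ES) and late-spring
(LS) sample series.

Arctic surface snow starts the spring as an extremely carbon-poor
habitat and ends it with organic-acid concentrations two to three
orders of magnitude higher. `snownet` implements the analysis pipeline
used to ask whether that nutrient shift moves the bacterial community
from cooperative to competitive interactions:

1. **Chemistry** — below-detection-limit values imputed as LOD/2, log
   transform (pH exempt), PCA ordination, and a distance-based
   pseudo-F permutation test (PERMANOVA) for the ES/LS difference.
2. **Community** — cumulative-sum-scaling (CSS) normalization of OTU
   counts; the *core community* of each period (OTUs present in at
   least half of the period's samples); co-inertia analysis (RV
   coefficient, row-permutation test) coupling chemistry to community
   structure.
3. **Local similarity analysis (LSA)** — for every pair of core OTUs,
   a dynamic program finds the strongest locally aligned co-varying
   run of the two rank-transformed time series (lag 0 in the headline
   pipeline); significance by permutation, edges kept at p < 0.05.
4. **Networks** — signed co-variance networks per period, compared by
   average degree, density, transitivity, greedy modularity Q, vertex
   connectivity, closeness and edge betweenness, plus the
   **positive-interaction ratio** `E+ / C(n, 2)`: positive edges
   standardized by the number of pairs the n-OTU core community could
   form, so different-sized networks are comparable.
5. **Markers** — plasmid structural genes (GO:0005727 or a "plasmid"
   keyword) as cooperation markers and antibiotic genes (GO:0017000 or
   a curated name list) as competition markers; antibiotic resistance
   gene determinants (ARGDs) filtered at e-value < 1e-10, z-score > 50,
   identity > 60% with best-hit resolution; total-read-count
   normalization; period differences by a permutation test on group
   means; ARGD transcription correlated with total organic acids by a
   permutation Spearman test.

A synthetic-data generator (`snownet.simulate`) emulates the study
design — 20 ES + 16 LS amplicon samples, 8 ES + 12 LS meta-omic
samples, planted co-varying OTU pairs, an organic-acid ramp with
censoring, planted marker enrichments — and returns the planted truth
so every stage's recovery can be tested.

## Worked example

Run the full pipeline on a synthetic season (50 OTUs, 5 planted
positive and 2 planted negative pairs):

```python
from snownet.io import RunConfig, run_pipeline
from snownet.simulate import SyntheticConfig

cfg = RunConfig(seed=1, outdir="out",
                n_perm_lsa=499, n_perm_group=999, n_perm_coinertia=999,
                n_perm_diff=4999, n_perm_spearman=4999,
                synthetic=SyntheticConfig(seed=1, n_otus=50,
                                          n_pos_pairs=5, n_neg_pairs=2))
report = run_pipeline(cfg)
```

which prints (via the `snownet all` CLI wrapper):

```
core sizes: ES=50 LS=50 shared=50
ES: 48 nodes, 31+/43- edges, positive ratio 0.025, modularity 0.576
LS: 45 nodes, 31+/40- edges, positive ratio 0.025, modularity 0.543
chemistry period difference: pseudo-F = 21.50, p = 0.001
coinertia RV = 0.126 (p = 0.27)
marker features tested: 60, significant at 0.05: 15
ARGD vs organic acids: rho = 0.70, p = 0.0008
```

Reading the numbers: at a sequencing depth of ~10,000 reads every
synthetic OTU is prevalent enough to enter both cores (50/50/50).  The
chemistry test detects the planted seasonal ramp emphatically
(pseudo-F 21.5 at the permutation floor p = 0.001), and the planted
monotone association between ARGD load and organic acids is recovered
(rho = 0.70).  The co-inertia RV is small and non-significant because
the synthetic OTU drivers are deliberately independent of the
chemistry ramp.  Within-period networks are built from only 16-20
time points at a raw p < 0.05 edge filter, so they contain a ~5%
background of chance edges on top of the planted structure — the
planted-pair recovery tests therefore score the full-season series,
where recovery is 5/5 positive pairs for most seeds.

Every output file in `out/` carries a `# key: value` header recording
the seed, config hash and the decision flags in effect.

The command-line interface mirrors the stages:

```sh
snownet synth --seed 7 --outdir data/
snownet all --config run.yaml
snownet net --pairs out/lsa_pairs_ES.tsv --n-core 59 --out es_summary.tsv
```

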