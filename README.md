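# assemblage

Null-model community-assembly analysis for longitudinal microbiome cohorts.

`assemblage` re-implements, as a tested and reusable pipeline, the
community-assembly toolkit used in neonatal-calf gut microbiome studies:

- **Null models & C-score SES** — fixed-fixed binary randomizations
  (sequential swap, quasiswap) and the checkerboard-score standardized
  effect size, with |SES| > 2 flagging non-random co-occurrence structure.
- **Modified Raup–Crick (βRC)** — pairwise dissimilarity in [−1, 1] from a
  richness-preserving, occupancy-weighted probabilistic null.
- **Modified stochasticity ratio (MST)** — [0, 1] index with 0.5 as the
  boundary between deterministic- (<0.5) and stochastic- (>0.5) dominated
  assembly.
- **PERMDISP** — permutation test comparing actual communities with
  null-simulated communities in βRC space (the per-stratum determinism call).
- **Ecotypes** — Levins niche breadth and generalist / specialist /
  neutralist classification against abundance-quasiswap nulls (95% CI).
- **Co-occurrence networks** — Spearman R > 0.6, P < 0.05 edges; modularity,
  average degree, clustering coefficient, KS comparisons, and the Integrated
  Value of Influence (IVI) with top-10% influential-taxon selection.
- **Two-state Markov model** — continuous-time panel model of per-animal
  assembly-state dynamics with covariate hazard ratios (forward =
  stochastic→deterministic, backward = reverse).
- **Partial Spearman correlation** — taxon abundance vs SES with other taxa
  controlled.
- **Synthetic cohorts** — a generator that emulates a two-arm calf trial
  (84 calves, weeks 1/2/3/6/8, attrition) with planted assembly regimes,
  ecotypes and Markov dynamics, so every stage has ground truth.

## Test

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the release criteria (marginal
conservation, oracle agreement, SES/βRC/MST/PERMDISP calibrations, ecotype
recovery, Markov parameter recovery, end-to-end determinism); the other
files are fast per-module suites.

## CLI

```sh
# synthetic cohort with ground truth
assemblage simulate --n-calves-per-arm 42 --n-taxa 120 --seed 17 --out data/

# per-stratum statistics
assemblage ses      --table data/table.tsv --metadata data/metadata.tsv \
                    --group-by treatment,health,week --n-sim 10000 --seed 17 --out ses.tsv
assemblage rc       --table data/table.tsv --metadata data/metadata.tsv --out rc/
assemblage mst      --table data/table.tsv --metadata data/metadata.tsv --out mst.tsv
assemblage permdisp --table data/table.tsv --metadata data/metadata.tsv --out permdisp.tsv
assemblage ecotypes --table data/table.tsv --metadata data/metadata.tsv --out ecotypes.tsv
assemblage network  --table data/table.tsv --metadata data/metadata.tsv --out nets/

# assembly-state dynamics
assemblage markov --panel results/panel.csv --covariate health --by treatment

# everything, with deterministic per-stage seeding
assemblage run --config cohort.yaml --seed 17 --out results/
```

`assemblage run` writes per-stratum tables (`ses.tsv`, `permdisp.tsv` with
centroid/F/P columns, `mst.tsv` per sample, `ecotypes.tsv`, network
summaries, top-IVI taxa), the assembly panel, the Markov hazard-ratio table
and a machine-readable `run.json`. Runs with the same seed are
byte-identical.

A note on null pools: determinism that acts identically on every sample of a
stratum is invisible to a stratum-local occupancy null. `beta_rc`, `mst` and
`permdisp_vs_null` accept `pool_weights` to test against a regional
(e.g. cohort-wide) pool instead; the pipeline passes cohort-wide occupancy
automatically.

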