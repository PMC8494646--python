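# projcensus

Analysis toolkit for cell-type projection censuses of a cortical area:

- **regions** — hierarchical brain-region ontology with bilateral (ipsi/contra)
  summary targets and roll-up to 13 major brain divisions. The packaged
  default ontology exposes 314 summary targets per hemisphere (628 bilateral
  targets); a small configurable ontology backs the synthetic pipeline.
- **tracer** — weighted connectivity matrices from per-region tracer signal:
  anterograde *output* matrices (true-positive masking, injection-site
  exclusion, fraction-of-total normalization, group averaging) and
  retrograde/rabies *input* matrices (blank-brain false-positive calibration
  at mean + 6 sd), plus division summaries, injection-site distance
  statistics and in-degree.
- **clustering** — complete-linkage agglomerative clustering with
  1 − Spearman ρ distances, dendrogram export (Newick), two-sided Fisher
  exact layer enrichment, within-cluster similarity, and cluster contrasts
  (one-way ANOVA + Tukey HSD on target counts; split-plot interaction of
  cluster × target area).
- **laminar** — cortical layer/sublayer delineation by clustering 25-µm
  soma-depth bins (Euclidean, complete linkage); contiguous same-cluster
  runs become layers.
- **barseq** — barcoded projection count-matrix analysis: spike-in and
  cross-brain normalization, bisecting k-means major classes, recursive
  binary-projection subgrouping that maximizes the entropy reduction of the
  laminar distribution (≤ 3 areas per split, permutation significance),
  laminar re-merging (rank-sum + 200-µm median window within a major class),
  conditional projection probabilities, sublayer enrichment and bootstrap
  cluster homogeneity.
- **single_cell** — SWC morphology validation and per-region axon length
  quantification through a voxel annotation volume; XOR projection
  discreteness testing against fixed-margin shuffles with a one-tailed
  Levene test; NNLS/BVLS decomposition of bulk tracer patterns into
  single-cell cluster proportions (BVLS bounds 0.01–1, clusters with ≥ 15
  members).
- **synth** — seeded generators for every input above with planted ground
  truth (class archetypes, binary projection subgroups tied to laminar
  depths, cluster archetypes), so all recovery metrics are computable.
- **pipeline / cli** — config-driven end-to-end orchestration with a
  machine-readable run report.

## CLI

```sh
projcensus run --seed 1 --out pipeline_out          # full synthetic pipeline
projcensus synthesize --seed 1 --out inputs/        # just the synthetic inputs
projcensus matrix build --kind output --experiments inputs/tracer_signal.csv --out out/
projcensus cluster --matrix out/output_matrix.csv --k 4 --out out/
projcensus layers --somas somas.csv --k 11 --out out/
projcensus barseq --counts counts.csv --meta meta.csv --seed 1 --out out/
projcensus singlecell xor-test --fractions fractions.csv --n-shuffles 100 --seed 1
projcensus singlecell compose --fractions f.csv --clusters c.csv --bulk b.csv --out out/
```

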