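# hiberseq

Analysis toolkit for bulk RNA-seq experiments sampled around an ordered
cycle of physiological states (the six-state torpor–arousal design:
SA, IBA, Ent, LT, Ar, SpD; five replicates per state, with a sex
covariate). It implements, as reusable and tested components:

- **Synthetic data** (`hiberseq.simulate`) — deterministic generators for
  the full input bundle with known ground truth: a sample design,
  negative-binomial count matrices whose state profiles follow ten named
  cluster templates, LSV junction-count tables with planted per-state PSI
  (including retained introns), a hand-constructible annotation-merge
  fixture, and sequences with planted AU-rich pentamers, GC targets and
  motifs.
- **Expression / DE** (`hiberseq.expression`) — median-of-ratios size
  factors, `log2(normalized + 1)` transform, the "≥7 in at least 4/5
  replicates of some state" detection filter, a vectorized
  negative-binomial GLM likelihood-ratio test of state (full: state + sex
  vs reduced: sex), pairwise log2 fold-changes with Normal-prior
  shrinkage and Wald tests, and per-transition up/down summaries around
  the circannual state graph.
- **Pattern clustering** (`hiberseq.clustering`) — per-state mean
  profiles correlated against ten editable reference templates; units are
  assigned to the best correlate at r ≥ 0.8, otherwise `Unassigned`.
- **Splicing** (`hiberseq.splicing`) — Dirichlet-posterior PSI per LSV
  junction per state (replicates pooled), Monte-Carlo dPSI with the
  "99.9% probability of |dPSI| ≥ 0.2 in any pairwise comparison"
  significance rule, summer-dominant-junction orientation, dPSI-pattern
  clustering via the shared template machinery, intron-retention
  default-state classification, and control-intron selection for external
  splice-site scoring.
- **Annotation merge** (`hiberseq.annotation`) — stepwise three-source
  transcript integration (no-exon-overlap supplementation; short
  single-exon transcripts below 90% reciprocal overlap; splice-evidence
  gene reassignment; removal of intron-contained novel transcripts) and
  homology symbol assignment with `_like` / `_containing` coverage
  suffixes. GTF2.2/GFF3 I/O; full provenance logging.
- **Sequence features** (`hiberseq.seqfeatures`) — GC content, ARE
  scoring of 3′UTRs (≥200 nt; classes "no ARE" / score ≥ 8), IUPAC motif
  scanning, k-mer presence enrichment, cluster-by-feature Fisher tests,
  exact Wilcoxon comparisons, and GMT-based over-representation with a
  mandatory explicit background.
- **Pipeline + CLI** (`hiberseq.pipeline`, `hiberseq.cli`) — per-region
  orchestration with a YAML config, deterministic outputs, and a JSON run
  manifest (config snapshot, input checksums, row counts).

## CLI

```sh
# generate a synthetic bundle with ground truth
hiberseq simulate --seed 1 --n-genes 1000 --out-dir bundle/

# individual stages
hiberseq filter --counts bundle/counts.tsv --design bundle/design.csv --out keep.tsv
hiberseq de --counts bundle/counts.tsv --design bundle/design.csv --out de.tsv
hiberseq cluster --counts bundle/counts.tsv --design bundle/design.csv --out clusters.tsv
hiberseq splice --lsv-table bundle/lsv_counts.tsv --design bundle/design.csv --out psi.tsv
hiberseq merge-annotations --primary a.gtf --secondary b.gtf --novel c.gtf \
    --evidence junctions.tsv --out merged.gtf --log provenance.tsv
hiberseq assign-symbols --gtf merged.gtf --hits-primary hits.tsv --out symbols.tsv
hiberseq seqfeat are --fasta utrs.fa --out are.tsv
hiberseq enrich go --genes genes.txt --gmt sets.gmt --background universe.txt --out go.tsv

# everything, from a YAML config
hiberseq run-all --config pipeline.yaml --out-dir out/ --seed 1
```

A minimal `pipeline.yaml`:

```yaml
counts: bundle/counts.tsv
design: bundle/design.csv
lsv_table: bundle/lsv_counts.tsv   # optional
templates: bundle/templates.tsv    # optional, defaults built in
seed: 1
de: {lrt_alpha: 0.001}
splice: {delta: 0.2, prob_threshold: 0.999}
```

## Notes on approximations

- The regularized-log transform is approximated by `log2(normalized + 1)`
  with the detection threshold kept at 7 on the same scale.
- Shrunken fold-changes use a fixed Normal(0, σ²) prior (posterior mean),
  not adaptive shrinkage.
- PSI posteriors pool replicates within a state under a Jeffreys-prior
  Dirichlet; a hierarchical read-rate model is out of scope.
- LRT p-values use a small-sample F calibration (see
  `expression.de_lrt`); it coincides with the chi-square reference
  asymptotically.
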