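# sctreesig

Phylogenetic signal extraction from single-cell RNA-seq. The package
turns noisy, dropout-ridden single-cell measurements into character
alignments suitable for phylogenetic inference and tests whether
regional samples cluster on the resulting trees:

- **expression pipeline** — per-gene standardization (mean 0, sample
  variance 1), five-level ordinal discretization via 60%/90%
  highest-density intervals, removal of phylogenetically uninformative
  genes, ordinal FASTA output. Raw zeros are treated either as unknown
  data (dropout) or as an explicit biological category 0.
- **density filtering** — data-density reporting, a greedy stepwise
  algorithm that removes the worst-covered cells/features until a target
  density or a local maximum is reached (with an auditable trace),
  per-sample selection of the best-covered cells, and raw-count cell QC.
- **SNV pipeline** — per-cell consensus-base character matrices from
  base counts at pre-called candidate sites (ties and zero coverage are
  unknown), nucleotide FASTA output. Variant calling itself is upstream
  and out of scope.
- **tree interface** — newick I/O (single trees and bootstrap/posterior
  samples), cophenetic distances, inputs + run manifests for external
  ML/Bayesian engines, and an internal neighbor-joining builder used as
  test plumbing.
- **clustering tests** — MPD and MNTD with label-permutation nulls,
  rank p-values (p = r/(n_perm+1), never zero), Benjamini–Hochberg FDR,
  union groups ("T1+CTC2"), and mean/95%-interval summaries over tree
  samples.
- **synthetic data** — multi-sample cell phylogenies with optionally
  polyphyletic groups, ordinal characters evolved under a reflecting
  ±1 jump chain, Jukes–Cantor nucleotide characters, per-cell dropout,
  and read-level base-count generation; every stage is testable offline.

## CLI

```sh
sctreesig simulate --seed 1 --outdir data/
sctreesig discretize --matrix data/expression.tsv --labels data/labels.tsv \
    --zero-mode unknown --hdi 0.6,0.9 --min-cells 2 --out ordinal.fasta
sctreesig filter stepwise --in ordinal.fasta --kind ordinal --target 0.5 \
    --out filtered.fasta --trace trace.json
sctreesig filter select --in ordinal.fasta --kind ordinal \
    --labels data/labels.tsv --quota T1=20,T2=6,T3=20,CTC1=6,CTC2=6 \
    --out selected.fasta
sctreesig filter qc --matrix data/expression.tsv --min-genes 250 --min-umi 500 \
    --out qc.tsv
sctreesig snv build --sites data/sites.vcf --counts data/base_counts.tsv \
    --min-cells 2 --out snv.fasta
sctreesig nj --in selected.fasta --kind ordinal --out tree.nwk
sctreesig engine-inputs --in selected.fasta --kind ordinal --outdir engine/
sctreesig cluster-test --tree tree.nwk --labels data/labels.tsv \
    --groups T1,T2,T3,CTC1,CTC2,T1+CTC2,T2+CTC1 --stat mpd,mntd \
    --nperm 999 --seed 42 --alpha 0.05 --out results.tsv
```

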