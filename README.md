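# regstage

Stage-resolved integration of transcription-factor ChIP-seq binding with
expression response, rebuilt as a reusable, tested pipeline and exercised
end-to-end on synthetic data with known ground truth.

What it does:

- **Summit-proximity peak comparison** — two peaks overlap when their
  summits lie within ±200 bp (inclusive); multi-set union merging by
  single-linkage summit clustering, Venn decomposition of the merged pool.
- **Bootstrap overlap significance** — empirical null for three-way peak
  (and gene-list) overlaps: keep one actual set, replace the other two by
  size-matched 400-bp random peak sets drawn from the union pool, rotating
  round-robin over 50,000 iterations; z score and a numerically safe
  one-sided normal-tail P (exact in log10 far below double-precision
  underflow).
- **Peak-to-gene annotation** — promoter (2,000 bp upstream / 500 bp
  downstream of the TSS, strand-aware) > intragenic > intergenic (nearest
  TSS within 100 kb), allocated by summit.
- **Trinary expression patterns** — expressed-gene filter (max log2
  intensity ≥ 6.5), per-comparison two-fold up/down calls (optional
  p ≤ 0.001 conjunction), digit codes (1 up / 0 down / 2 invariant),
  exact-code grouping with a >30-gene retention threshold.
- **Binding × response classes** — two-digit (uninduced, induced) response
  codes for bound genes (00 still_downregulated … 21 upregulated) and
  direct-target fractions.
- **Motif co-localization** — PWM scanning in ±200 bp summit windows (both
  strands, log2-odds), motif-pair counting at ≤20 bp centre-to-centre
  distance, bootstrap z-score matrix against random distal peak sets.
- **Composite profiles** — mean tag density in 50-bp bins over ±5,000 bp
  around summits, per-million normalized; union-peak count matrices and
  Pearson/hierarchical sample clustering.
- **Synthetic-data generators** — peak sets with planted Venn structure,
  tag pileups, expression matrices with planted trinary codes, and genomes
  with motif pairs planted at controlled spacings; every generator is a
  pure function of (parameters, seed).

## CLI

```bash
regstage simulate --out run/ --seed 1          # synthetic input bundle + truth.json
regstage run-all  --out run/ --seed 1 --iters 2000   # all stages + manifest.json
regstage peaks    --out run/ --seed 1          # venn + annotation only
regstage boot     --out run/ --seed 1 --iters 50000
```

Stages: `simulate | peaks | boot | expr | integrate | motif | signal |
run-all`. All take `--config cfg.yaml` (a flat `params:` block mirroring
`AnalysisConfig` field names), `--seed`, and `--out`. Outputs are TSVs with
a header comment recording the config hash and seed; `run-all` writes a
`manifest.json` with config snapshot, input digests and per-stage timings.

## Layout

```
src/regstage/
  core/        domain types (peaks, genes, tags, expression, PWMs, config)
               and readers/writers (narrowPeak, BED6, GTF-lite, TSV,
               JASPAR PFM, FASTA)
  simulate.py  ground-truth synthetic data generators
  peaks.py     summit overlap, union merge, Venn, peak-to-gene allocation
  boot.py      bootstrap overlap significance, z -> P conversion
  expr.py      expression filtering, fold changes, trinary codes, clustering
  integrate.py bound-gene sets, direct targets, response classes
  motif.py     PWM scanning, pair counting, co-localization bootstrap
  signal.py    tag counting, composite profiles, ChIP sample correlation
  cli.py       stage orchestration and the run manifest
```

Conventions: all coordinates are 0-based half-open internally (GTF is
converted on read); tag positions are fragment midpoints; summits anchor
every overlap, annotation and profile computation.
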