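# tfimpact

Rank transcription factors by their impact on a two-group expression
contrast, from ChIP-seq binding evidence.

The pipeline:

1. **Regulatory potential** — each gene gets a score
   `S_g = Σ_i exp(−(0.5 + 4·Δ_i))` over the TF's binding sites whose anchor
   (peak summit, else interval midpoint) lies within a cutoff distance `D`
   of the TSS, with `Δ_i` the anchor–TSS distance normalised by `D`. The
   top-N genes per TF form its regulated gene set (M100/M200/M500/M800 by
   default).
2. **Differential expression** — per-gene Welch t-test (treatment vs
   control) with Benjamini–Hochberg correction produces up/down gene sets
   (adjusted p < 0.01 by default); precomputed lists from any external DE
   engine can be injected instead.
3. **Impact scan** — for every (TF, replicate, D, N) grid cell the impact
   scores `R_up`/`R_down` (fraction of regulated genes that are up/down)
   are tested with an exact hypergeometric upper tail against the gene
   universe (p < 0.001 flag).
4. **Consensus peaks** — intersection of two peak sets (e.g. two cell
   lines) after a strict q-value filter (`q < 1e-10` by convention).
5. **Two-stage enrichment** — GMT categories enriched among the top TF's
   regulated genes (BH-adjusted p < 0.05) are cross-tested for enrichment
   of the up/down sets; categories passing both stages are flagged per
   direction.
6. **Synthetic data** — a seeded generator plants a regulator (peaks near
   its targets' TSS), down/up-regulated gene sets and an enriched category,
   so the whole pipeline is testable without any external downloads.

## CLI

```bash
# generate a synthetic dataset (see SimulationConfig for all knobs)
tfimpact simulate --seed 1 --outdir sim/

# full pipeline from a YAML config (all PipelineConfig fields)
tfimpact run-all --config pipeline.yaml

# individual stages
tfimpact de --matrix sim/expr.tsv --groups sim/groups.tsv --out de.tsv
tfimpact rp --peaks sim/TF01.rep1.narrowPeak --annotation sim/genes.tsv \
            --cutoffs 1000,3000,5000,10000 --out rp.tsv
tfimpact scan --peaks-manifest sim/manifest.tsv --annotation sim/genes.tsv \
              --de de.tsv --out impact.tsv
tfimpact peaks consensus --a a549.narrowPeak --b hepg2.narrowPeak \
                         --qmax 1e-10 --out consensus.bed
tfimpact enrich --regulated top200.txt --gmt sim/categories.gmt \
                --de de.tsv --out enrich.tsv
```

A minimal `pipeline.yaml`:

```yaml
annotation: sim/genes.tsv
peaks_manifest: sim/manifest.tsv
expression: sim/expr.tsv
groups: sim/groups.tsv
gmt: sim/categories.gmt
outdir: out/
```

`run-all` writes per-stage TSVs plus `report.json` with the TF ranking per
grid cell, the overall top TF (highest mean `R_down` on the M200 set across
replicates and distances) and its flagged categories.

## Conventions

- Coordinates are 0-based half-open (BED) throughout; minus-strand TSS is
  `end − 1`.
- narrowPeak column 9 is read as −log10(q) and stored as a raw probability;
  column 10 ≥ 0 sets the summit.
- Gene identifiers are matched case-sensitively; annotations must be
  pre-collapsed to one TSS per gene.
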