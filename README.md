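# spikecap

Capture of non-polyadenylated Pol III transcripts (nc886 as the built-in
model) in droplet-based 5' scRNA-seq via a spiked-in, oligo-tagged
gene-specific primer (GSP) — implemented as a reusable pipeline:

- **`spikecap.design`** — model the five-segment GSP (adaptor / N-spacer /
  feature barcode / N-spacer / target anchor), place anchors outside Pol III
  terminator runs, and reconstruct every library-construction intermediate
  (first-strand cDNA, amplified cDNA, final library) with `N` wildcards.
- **`spikecap.readproc`** — sequence-verify oligo-tagged read pairs:
  Hamming-budget search for the target in R1 and for *both* the feature
  barcode and the target in R2 (the correction for non-specific priming),
  then reconcile mates by read ID.
- **`spikecap.quant`** — barcode-whitelist correction (unique 1-mismatch),
  distinct-UMI counting per cell stratified by mismatch budget 0..M
  (`*_pm`, `*_mm1`, …), MatrixMarket I/O, and merging the target row into a
  gene-expression matrix.
- **`spikecap.simulate`** — a ground-truth read simulator with three cell
  populations (high/low/zero expression), a dominant non-specific read
  class, PCR duplicates and substitution errors; every module is testable
  offline.
- **`spikecap.integrate`** — strict-threshold QC (total UMIs > 2000,
  genes > 200, mito% < 15 by default), log-normalization + per-feature
  z-transform, quantile grouping of target expression with zero-inflation
  handling, and Wilcoxon rank-sum group comparison.

## CLI

```sh
# show the built-in nc886 design and its reconstructed templates
spikecap design

# generate a synthetic run (FASTQ pair + whitelist + truth ledger)
spikecap simulate --out-dir sim/ --seed 1

# sequence-verified filtering of the pair
spikecap filter --r1 sim/sim_R1.fastq --r2 sim/sim_R2.fastq \
    --max-mismatch 1 --out-prefix filtered/pairs

# per-cell mismatch-stratified UMI counts (optionally merged into a GEX matrix)
spikecap count --r1 sim/sim_R1.fastq --r2 sim/sim_R2.fastq \
    --whitelist sim/whitelist.txt --max-budget 5 --merge-budget 1 \
    --out-dir counts/

# QC + normalization + quantile grouping of the merged matrix
spikecap integrate --matrix-dir counts/merged --bins 4 --out-dir integrated/
```

Custom targets/designs are supplied with `--target-fasta` (single-record
FASTA) and `--design-config` (YAML/JSON: either a full `oligo` with the
`adaptor`/`feature_barcode` literals, or explicit segment fields, plus
optional read-anatomy overrides).

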