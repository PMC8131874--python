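# crosshub

Differential intra/inter-chromosomal Hi-C contact analysis with multi-omic
association statistics.

`crosshub` re-implements, as a tested and reusable pipeline, a computational
chain for detecting condition-induced differential chromatin contacts and
relating those "hubs" to other genomic changes:

- **Contact analysis** — HiC-Pro-style valid-pairs parsing, binning of
  intra-chromosomal contacts at 100 kb and inter-chromosomal contacts at
  1 Mb, removal of sex chromosomes and self-interacting bins, ICE matrix
  balancing and A/B-compartment eigenvector scores.
- **Differential count engine** — TMM normalization, RUVg/RUVr/RUVs
  unwanted-variation factors, negative-binomial dispersion estimation
  (Cox-Reid adjusted profile likelihood with shrinkage), NB GLM
  likelihood-ratio tests, BH-FDR, and a select-and-intersect batch strategy.
  The same engine tests contact bin-pairs, 1 Mb coverage bins and generic
  count matrices.
- **Permutation association** — bin-level permutation test of a query
  region/bin set against feature region sets over a binned genome universe,
  with empirical p, z-score and an exact (hypergeometric) cross-check.
- **Companion statistics** — the two-contrast protein ratio consistency
  statistic (delta = phi/beta, threshold ±0.1), a batch-robust small-RNA
  reproducible-direction filter with rpm normalization and z-scores, and
  region-to-gene fold-change aggregation correlated with expression changes
  (Pearson for transcripts, Spearman for proteins).
- **Synthetic data** — generators for every input with planted ground truth
  (inter-chromosomal hub, batch factors, consistent proteins, reproducible
  miRNAs, linked fold changes), so each stage is verifiable at desk scale.

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the end-to-end property checks (planted hub
recovery, null calibration, permutation exactness against exhaustive
enumeration, oracle equivalence for TMM/BH/delta, RUV factor recovery,
compartment recovery, correlation parameter recovery, miRNA consensus
recovery, byte-level determinism).

## CLI

```sh
# generate a synthetic dataset with truth sidecars and a ready config
crosshub simulate --out-dir data/ --seed 1

# run every stage end to end
crosshub run-all --config data/config.yaml --out-dir results/

# individual stages
crosshub hic-bin --pairs EE1=data/EE1.validPairs.tsv ... --chrom-sizes data/chrom.sizes --out-dir out/
crosshub hic-diff --contacts out/contacts_inter.tsv --chrom-sizes data/chrom.sizes \
    --klass inter --groups EE1=EE,EE2=EE,CTL1=CTL,CTL2=CTL --out diff_inter.tsv
crosshub assoc --query hubs.bed --features atac.bed,h3k36me3.bed \
    --chrom-sizes data/chrom.sizes --bin-width 1000000 --n-perm 100000 --seed 1
crosshub compartments --contacts out/contacts_intra.tsv --chrom chr7s \
    --chrom-sizes data/chrom.sizes --out e1.tsv
crosshub delta --ratios ratios.tsv --out delta.tsv
crosshub mirna --counts mirna_counts.tsv --out mirna.tsv
crosshub linkcor --links links.tsv --rpkm-test ee.tsv --rpkm-ref ctl.tsv --gene-fc fc.tsv
```

## File formats

- chrom.sizes: 2-column TSV (name, length), UCSC dialect.
- Valid pairs: TSV with ≥ 7 columns (readID, chr1, pos1, strand1, chr2, pos2,
  strand2), 1-based positions; extra columns ignored.
- BED3/BED6 region files, 0-based half-open; direction encoded as a
  `:up`/`:down` name suffix.
- Counts TSV with `#group`/`#batch` header lines, then features × samples.
- Ratio table TSV: columns id, phi, beta.
- Link table TSV: columns region_id, gene_id, class.

All comment lines starting with `#` are tolerated by every reader.
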