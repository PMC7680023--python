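# holopop

Population-genetic analysis of holobiont (host + algal symbiont)
transcriptome SNP data, as a tested, reusable pipeline:

- **`simdata`** — synthetic dual-compartment datasets with known truth:
  a two-origin × two-state design (VA-B, VA-W, RI-B, RI-W), Balding–Nichols
  neutral drift, origin-level divergent outlier loci, a planted clone pair,
  negative-binomial read depths, MCAR missingness, and a full fixture
  bundle (VCF, population map, contig FASTA, BLAST hit tables, GO
  annotation, truth tables, checksum manifest).
- **`compartment`** — contig binning into host / symbiont / removed classes
  from four BLAST databases, with rRNA (≥78% coverage over ≥100 bp) and
  length (>500 bp) pre-filters.
- **`formats`** — VCF / genepop / population-map readers and writers built
  around a `GenotypeMatrix` (samples × loci alt-allele counts with depth
  and site quality).
- **`filtering`** — the four-step variant filter cascade (genotype depth
  recoding, QUAL/biallelic/mac, two individual-missingness passes, site
  missingness/MAF/mean-depth, per-population exact Hardy–Weinberg test)
  plus one-SNP-per-contig thinning, with a per-step audit report.
- **`clones`** — multilocus clone detection by allelic-difference distances
  (Hamming / Prevosti / Manhattan), complete-linkage clustering, newick
  dendrograms, and a cross-metric concordance report.
- **`outliers`** — covariance-corrected differentiation scores
  (XtX = zᵀΩ⁻¹z over standardized population allele-frequency residuals)
  with pseudo-observed-data calibration at a 0.5% FDR quantile threshold.
- **`popstats`** — Weir–Cockerham variance-component Fst (global and
  pairwise) with 999-permutation tests, and Ho/Hs diversity with Nei's
  small-sample correction.
- **`ordination`** — genotype PCA with mean imputation and population-
  colored plots.
- **`enrichment`** — one-sided Fisher's-exact GO enrichment of
  outlier-bearing genes with Benjamini–Hochberg adjustment.
- **`cli`** — `holopop` command-line front end and a config-driven
  `run_pipeline` orchestrator producing per-stage artifacts and a
  checksum manifest.

Note: the symbiont compartment is represented as diploid genotype calls
(mirroring default diploid variant-caller output) although the algae are
biologically haploid.

## Test

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (estimator
recovery, outlier-scan calibration and power, permutation-test
calibration, clone detection, filter-cascade oracle equivalence, exact-HWE
enumeration, Fisher/hypergeometric identity, format round-trips, and the
qualitative host/symbiont differentiation pattern).

## CLI

```sh
# synthetic bundle with known truth
holopop simulate -o bundle --seed 1

# full pipeline from a YAML config
holopop run -c config.yaml -o rundir
```

Minimal `config.yaml` (paths relative to the config file):

```yaml
vcf: holobiont.vcf
popmap: popmap.csv
annotation: annotation.tsv
fasta: contigs.fasta
blast:
  dirty_coral: blast_dirty_coral.tsv
  dirty_sym: blast_dirty_sym.tsv
  clean_coral: blast_clean_coral.tsv
  clean_sym: blast_clean_sym.tsv
  rRNA_LSU: blast_rRNA_LSU.tsv
  rRNA_SSU: blast_rRNA_SSU.tsv
outliers: {fdr: 0.005, n_pod_loci: 10000, seed: 1}
n_permutations: 999
```

Other subcommands: `partition`, `filter`, `clones` (see `holopop --help`).

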