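# exonmark

Analysis of exon-intron chromatin marking from tiling-array (ChIP-chip) and
short-read (ChIP-seq) data.

Across many genomes, several histone modifications are more abundant over
exons than over the introns that surround them — but raw ChIP signal also
tracks nucleosome density, which itself differs between exons and introns.
`exonmark` implements the full analysis needed to separate the two effects:

- **Two-channel normalization** of tiling-array measurements: background
  correction, per-replicate enrichment ratios, median composites across
  bioreplicates, tile-wise division by a combined H2B + H3 nucleosome-density
  track (and optionally an IgG control), then log2 median-centring and
  scaling to Z-scores. Sequential-ChIP (re-ChIP) arrays get an additional
  control-subtraction step.
- **Exon classification** from multi-transcript annotation: *canonical*
  exons appear in every transcript of a gene, *alternative* exons in only
  some (each with an inclusion fraction); regions where distinct exon
  intervals overlap are excluded as ambiguous.
- **Feature assignment** of array tiles or read bins to exons/introns by
  midpoint, with strand-aware ordinals from both gene ends and a 5′-most-25%
  region split.
- **Metaprofiles** over consensus gene structure (exon 1, intron 1, … exon
  10, or the last five exons), proportional gene-percent profiles with
  flanks, and per-class summaries whose headline number is
  ΔZ = mean(canonical exons) − mean(introns).
- **Significance** by coordinate randomization: observed class means are
  compared with means recomputed after uniformly permuting the signal over
  tile coordinates (empirical and parametric p-values), plus Welch t-tests
  of each exon against its preceding intron.
- **Expression strata**: quartile-based ON/OFF gene calls, cross-platform
  call intersection, and 12-bin percentile stratification.
- **ChIP-seq support**: 5′-start binning of short reads into fixed 200 b
  bins, analysed with the identical feature statistics.
- **A synthetic-data generator** that plants a known per-tile truth
  (exon/intron effects, inclusion-weighted alternative exons, a controllable
  nucleosome-density confound) so every stage of the pipeline can be
  validated against ground truth.

## Quick start (command line)

```sh
# one config drives everything; a `simulate` block generates fixtures
cat > study.yaml <<'YAML'
seed: 7
simulate:
  n_genes: 40
  exon_effect: 0.5       # planted exon enrichment, log2 units
analysis:
  randomizations: 100
YAML

exonmark run-all --config study.yaml --out out/
cat out/report.txt
```

The output directory contains the generated annotation (`annotation.gff3`),
measurement tables, the tile→feature assignment (`assignment.tsv` + BED),
Z-score tracks (bedGraph + wiggle), per-stratum metaprofiles, bootstrap and
t-test tables, and bias calls. Individual stages are also exposed
(`exonmark simulate / preprocess / seqchip / assign / profile / stats /
binreads`); every emitted table records the seed and the normalization chain
in header comments.

## Quick start (library)

```python
from exonmark import SimConfig, simulate_study, profiles, stats
from exonmark.pipeline import preprocess_mark

study = simulate_study(SimConfig(seed=7, n_genes=40, exon_effect=0.5))
m = study.measurements
z = preprocess_mark(m["mark"], m["h2b"], m["h3"]).zscore

summary = profiles.class_means(z, study.assignment)
boot = stats.bootstrap_pvalues(z, study.assignment, R=100, seed=7)
tt = stats.adjacent_pair_ttests(z, study.assignment)
```

Running exactly this (40 genes, 1224 tiles, 1060 assigned) gives:

```text
z median 0, sample SD 1.000000
delta_z                 +1.3392
mean Z canonical exons  +1.2473   (n=86,  empirical p 0.0099, parametric p 9.5e-29)
mean Z alternative      +0.7261   (n=11)  <- between exons and introns
mean Z introns          -0.0919   (n=963)
adjacent-pair t-tests    9 pairs, median p 0.0012
bias call                exon_bias
```

The planted 0.5-log2 exon effect appears as ≈1.34 Z after scaling to unit
dataset SD; alternative exons, whose planted effect is weighted by their
inclusion fraction, fall between canonical exons and introns.

## Testing

```sh
python -m pytest tests/
```

The suite has fast unit/property tests for every module and a slower
end-to-end statistical layer (`tests/test_acceptance.py`, ~1 minute) that
checks null calibration, exact-enumeration agreement of the permutation
test, effect recovery, nucleosome-confound removal, alternative-exon
intermediacy, zero-noise exactness, array/sequencing concordance and the
worked micro-examples.

## Package layout

| module                | contents                                              |
|-----------------------|--------------------------------------------------------|
| `exonmark.annotation` | gene models, exon classification, tile assignment      |
| `exonmark.preprocess` | two-channel normalization chain, seq-ChIP, audit trail |
| `exonmark.chipseq`    | read binning and bin-level feature statistics          |
| `exonmark.expression` | ON/OFF calls, percentile bins, inclusion strata        |
| `exonmark.profiles`   | metaprofiles, class means, gene-percent profiles       |
| `exonmark.stats`      | coordinate-randomization bootstrap, t-tests, bias calls|
| `exonmark.simulate`   | synthetic studies with planted ground truth            |
| `exonmark.validation` | end-to-end statistical validation suites               |
| `exonmark.pipeline`   | config-driven orchestration                            |
| `exonmark.cli`        | `exonmark` command-line entry points                   |
| `exonmark.io`         | GFF3/GTF, BED, bedGraph, wiggle, TSV readers/writers   |
| `exonmark.plotting`   | optional matplotlib rendering                          |
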