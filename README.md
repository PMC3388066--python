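# znfarray

Analysis toolkit for tandem C2H2 zinc-finger (ZnF) arrays, built around four
stages:

1. **Repeat decomposition** (`znfarray.parser`) — split phased array
   nucleotide sequences into 84-nt / 28-aa repeat units, validate the C2H2
   scaffold, and extract the DNA-contact residues at helix positions
   −1, 2, 3 and 6.
2. **Allele cataloguing** (`znfarray.catalog`) — collapse sequences into
   unique nucleotide and amino-acid alleles, assign repeat letter codes
   (synonymous nucleotide variants marked with `*`), report polymorphic
   columns and cross-group allele sharing.
3. **Diversity permutation tests** (`znfarray.diversity`) — the two-group
   statistic (unique alleles in the smaller group) and the multi-group
   dispersion statistic (sum of squared deviations of per-group
   unique/total ratios), with one-tailed Monte-Carlo p-values and an
   exhaustive enumeration oracle for small spectra.
4. **Dot plots & selection** (`znfarray.dotplot`, `znfarray.selection`) —
   windowed-mismatch self dot plots with a quantitative two-block score,
   plus codon site models (M0/M1a/M2a/M3/M7/M8) with GY-style rate
   matrices, Felsenstein-pruning likelihood, nested LRTs, NEB/BEB site
   posteriors, a sitewise per-site omega LRT, and a neighbor-joining
   fallback tree builder.

`znfarray.simulate` generates every input with recorded ground truth
(repeat libraries, diploid populations with allele dropout, grouped
spectra, two-block arrays, codon alignments under the same site models the
fitters implement).  `znfarray.datasets` bundles the published grouped
allele spectrum used for the reanalysis targets.

## CLI

```sh
znf parse    --fasta alleles.fasta --groups groups.tsv --out repeats.tsv
znf catalog  --fasta alleles.fasta --groups groups.tsv --outdir out/
znf divtest  --spectrum spectrum.tsv --stat multi_group --nperm 10000 --seed 1
znf dotplot  --fasta alleles.fasta --window 83 --mismatch-limit 5 --out dp.tsv
znf selection fit      --alignment codons.fasta --model M2a --freq F3x4
znf selection sitewise --alignment codons.fasta --freqtype musegaut --out slr.tsv
znf simulate population --outdir sim/ --seed 1
znf run --config cfg.yaml
```

Input formats: FASTA (one record per phased allele, IDs as
`sampleID.alleleIndex`), a two-column `sample<TAB>group` TSV, spectrum TSVs
as `group<TAB>allele<TAB>count`, newick trees, and a YAML run config
(see `znfarray.io.RunConfig` for the fields).

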