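# microsat

Toolkit for developing and quality-controlling microsatellite (SSR) markers
from assembled transcriptome contigs:

- **mining** — scan FASTA contigs for maximal *perfect* di-/tri-/tetra-
  nucleotide repeats (default: at least 8 whole copies), with canonical
  motif classes (smallest cyclic rotation, strand preserved), flank
  extraction, and TSV/GFF3 reports;
- **genotype data** — GenePop and long-TSV I/O for multi-population diploid
  allele-size tables; pooled per-locus summaries (allele count, H_o,
  H_e = 1 − Σp², percent missing);
- **HWE QC** — chi-square Hardy–Weinberg tests per locus × population with
  a status grid (significant / monomorphic / other), plus two marker-level
  diagnostics: tie-aware Spearman correlation of heterozygote deficit
  (H_e − H_o) with percent missing (the null-allele signature), and one-way
  ANOVA of percent missing across multiplex PCR groups;
- **Fst** — pairwise Weir–Cockerham θ between populations, combined
  ratio-of-sums over alleles and loci, with a labelled plain-text matrix
  format;
- **Mantel** — permutation test of association between two labelled
  distance matrices (aligned by label; one-sided "greater" by default;
  significance from simultaneous row/column permutations, seeded);
- **simulation** — seeded generators for contigs with planted SSRs (exact
  truth tables) and island-model genotypes with a directly parameterized
  generative Fst (Balding–Nichols) and per-locus null-allele rates.

## CLI

A single entry point `microsat` with subcommands. Every run writes a
`<output>.run.json` provenance sidecar (tool version, parameters, input
hashes, seed).

```sh
microsat mine --fasta contigs.fasta --min-repeats 8 --periods 2,3,4 \
    --flank 200 --format tsv --out ssrs.tsv
microsat summarize --genepop data.genepop --groups groups.tsv --out summary.tsv
microsat hwe --genepop data.genepop --alpha 0.05 --grid grid.tsv [--png grid.png]
microsat nulltest --genepop data.genepop          # Spearman deficit-vs-missing
microsat anova --summaries summary.tsv --group-col group
microsat fst --genepop data.genepop --out fst.txt
microsat mantel --matrix-a fst.txt --matrix-b other.txt --n-perm 10000 --seed 17
microsat simulate-contigs --spec cspec.json --out sim.fasta --truth truth.tsv
microsat simulate-genotypes --spec gspec.json --out sim.genepop --truth truth.json
```

Simulation specs are JSON, e.g.

```json
{"n_pops": 4, "n_per_pop": 50, "n_loci": 10, "n_alleles": 5,
 "fst_target": 0.1, "null_rate": 0.1, "seed": 17}
```

## Notes

- Mining reports *perfect* repeats only; a trailing partial motif copy is
  excluded. Non-ACGT characters break runs. Mononucleotide repeats are not
  mined. Reverse complements are not collapsed (transcripts are stranded).
- Pooled H_o can legitimately fall below H_e under population structure
  (Wahlund effect) even without null alleles.
- The Mantel null is label permutation, not a bootstrap of pairs; p-values
  use the add-one rule and are never 0.
- Negative pairwise θ estimates are retained, not clamped.
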