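# mitohet

Analysis of mitochondrial SNP and length heteroplasmy in a multigenerational
snail matriline — with a forward simulator that generates every input the
pipeline consumes, so the whole analysis runs end-to-end without any
external data.

## The problem

Land snails such as *Cepaea* show extreme within-species mitochondrial
variation, and high-depth whole-genome sequencing reveals that much of it
already exists *within* individuals as heteroplasmy: at thousands of
positions a snail's reads carry a low-frequency alternative base. Whether
that signal is biology or sequencing noise, how it relates to mtDNA copy
number, whether selection is already filtering it, and whether it is
transmitted down the maternal line are all questions this package answers
quantitatively:

- **Heteroplasmy calling** from per-site allele-count tables: a site is
  heteroplasmic in an individual when its top non-reference base reaches a
  frequency threshold (2% default, 5% strict) at sufficient depth, plus
  vcftools-style multi-sample VCF filters (quality ≥ Q30/Q90, per-sample
  depth 10–500, missingness < 10%).
- **Copy number**: the ratio of mtDNA copies per nuclear genome,
  R = f_mt · G_nuc / L_mt, from the fraction f_mt of reads that are
  mitochondrial; 25 bp windowed depth; tandem-repeat copy number as the
  depth ratio of the repeat to 1 kb flanks (length heteroplasmy); and an
  OLS test of the association between copy ratio and per-individual
  heteroplasmy.
- **Selection tests**: pooled unique heteroplasmic sites tabulated by gene,
  codon position, and synonymy; chi-squared tests of position 1 vs 3 and
  2 vs 3 against the equal split a coding gene guarantees; the
  McDonald–Kreitman test with neutrality index NI = (Pn/Ps)/(Dn/Ds) and
  α = 1 − NI; sliding-window nucleotide diversity (π, 500-site windows,
  step 100). Under the invertebrate mitochondrial code (NCBI table 5)
  every second-position substitution is nonsynonymous, so a
  third-position excess can only be biological.
- **Inheritance**: sibling shared-site statistics; maternal assignment of
  each offspring of a hermaphrodite pair cross by Pearson-correlating its
  per-site frequencies against both candidate parents (strict criterion:
  exactly one parent positive and significant; loose: best p, ties by R²);
  pooled-variance t-test comparing offspring heteroplasmy by assigned
  mother; and a pedigree mutation-rate estimate
  n_fixed / (n_individuals · L_mt) from the count of majority (>50%)
  alternative alleles.
- **Synthetic matriline**: founder heteroplasmy transmitted through a
  germline bottleneck (binomial resampling of N_b genome copies), de novo
  mutation at an intensity ∝ copy_ratio^−κ, selection as a per-generation
  frequency penalty on nonsynonymous alleles, and Poisson/binomial
  sequencing emulation — every stage's ground truth is known.

## Worked example

`examples/01_simulate_and_call.py` simulates a 12-snail matriline on a 3 kb
toy mitogenome and calls heteroplasmy:

```
14 individuals, 661 called sites
individual  n_variable  pct_sites_variable  mean_freq_excl_zero  mean_freq_incl_zero
      C109          48                1.60                 5.50                 0.09
      C116          37                1.23                 6.04                 0.07
      C451          56                1.87                 5.07                 0.09
      ...
```

Each snail carries tens of heteroplasmic sites (1–2% of the genome), with a
mean alternative-allele frequency of ~5–6% over called sites — the same
order as the real matriline, where individuals averaged ~370 variable sites
and the most heteroplasmic snail had 13% of sites variable.

`examples/02_copy_number.py` converts read fractions into copy ratios and
reads repeat copy number off a depth plateau:

```
mt read fraction 0.0020% -> 4.9 mtDNA copies per nuclear genome
mt read fraction 0.0300% -> 73.9 mtDNA copies per nuclear genome
repeat depth ratio: 2.99 copies per genome (simulated truth 3)
```

`examples/04_inheritance.py` assigns mothers in a simulated pair cross
(8/8 correct under the loose criterion) and prints the mutation-rate
arithmetic: 2 majority variants over 90 snails × 14 kb gives 1.587 × 10⁻⁶
mutations per base per generation.

The full pipeline — simulate, call, copy number, selection, inheritance,
consolidated JSON report — is one command:

```bash
mitohet run-all --seed 1 --out runs/demo
```

On the default 90-individual matriline this reproduces the study's three
signatures: a negative copy-ratio–heteroplasmy association (R² ≈ 0.2),
a strong third-position excess among pooled coding variants, and ≥ 90%
correct loose maternal assignment.

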