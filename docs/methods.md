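# Methods

## Heteroplasmy calling

The caller consumes per-individual, per-site base-count tables (the output
of a pileup summarizer; both a simple TSV dialect and native colon-delimited
lines are read). For each position the highest-count non-reference base is
the candidate alternative; multiallelic positions collapse to that top base,
ties broken in fixed order A<C<G<T. A site is called when

- alternative frequency = top count / row depth ≥ `min_freq` (default 0.02,
  with 0.05 as the strict cross-check), and
- row depth ≥ `min_depth` (default 10).

The frequency denominator is the row's *stated* depth, not the sum of base
counts, so reads dropped upstream (N calls, filtered bases) reduce the
frequency rather than inflate it. Zero-depth rows are skipped and counted.

Per-individual summaries report the variable-site count, that count as a
percent of the mitogenome, and the mean alternative-allele frequency both
over called sites only and over all assayed sites with zeros — the two
conventions differ by an order of magnitude and both are always reported
because either may be meant by a "percent variation per site". With no
called sites the zero-excluded mean is NaN, never 0.

VCF-level filtering mirrors vcftools semantics: biallelic sites only; a
sample whose depth falls outside [`min_depth`, `max_depth`] = [10, 500]
counts as missing; a site is removed when the missing fraction reaches 10%
(strictly fewer than 10% of individuals may be missing) or when site
quality is below Q30 (or Q90 for the conservative pass). No minor-allele
floor: singleton de novo candidates survive.

Batch concordance is a Pearson correlation between two per-key frequency
tables over the union of keys, with a key absent from one batch imputed as
frequency zero. Dropping instead of imputing would inflate the correlation;
the union convention is conservative.

## Copy number

The relative copy number is R = f_mt · G_nuc / L_mt, the expected mtDNA
copies per *haploid* nuclear genome equivalent if reads sample the cell's
DNA content uniformly. Two deliberate simplifications:

- no (1 − f_mt) denominator correction — f_mt ≤ 10⁻³ in all data this
  models, so the correction is below 0.1%;
- no diploidy factor — the haploid-equivalent form reproduces the observed
  5–80 range, so a ×2 would be an arbitrary rescaling.

Windowed depth uses non-overlapping 25 bp windows (the last window may be
short). Repeat copy number is the mean depth over the repeat divided by the
mean over two 1 kb flanks, pooled; flanks wrap on circular genomes and are
truncated — never allowed to re-enter the repeat — when the genome is
short. A zero flank mean yields NaN. The estimate is invariant to rotating
the circular coordinate origin.

The copy-ratio–heteroplasmy association is ordinary least squares of a
per-individual heteroplasmy measure (variable-site count by default, or a
mean frequency) on copy ratio, with a two-sided slope test.

## Selection tests

Sites are pooled as unique (position, alternative-base) pairs across
individuals — a site seen in forty snails counts once — and classified by
gene, codon position and effect via strand-aware codon lookup under the
invertebrate mitochondrial genetic code (NCBI table 5, stop codons TAA/TAG,
start set {ATG, ATA, ATT, ATC, TTG, GTG}). A position inside overlapping
reading frames yields one record per gene. Under table 5 every
second-position substitution changes the amino acid (verified exhaustively
over 64 codons × 3 alternatives), which is what makes the codon-position
spectrum a clean selection assay: sequencing error is position-blind.

Because a coding gene contains equal numbers of first, second and third
positions, the chi-squared tests compare observed counts at positions 1 vs
3 and 2 vs 3 against a 50:50 expectation (Pearson statistic, df = 1, no
continuity correction — the statistic reduces to (n_a−n_b)²/(n_a+n_b)).
Counts below 5 carry an asymptotic-validity flag.

The McDonald–Kreitman test is a two-sided Fisher exact probability on
[[Pn, Ps], [Dn, Ds]]; NI = (Pn/Ps)/(Dn/Ds) and α = 1 − NI are NaN — never
silent zeros — when a denominator count is zero. Per-gene tests are
reported uncorrected (matching standard practice for this analysis), with a
Bonferroni column alongside for transparency. Fixed differences against an
aligned outgroup classify single-position codon differences directly;
multi-position differences take the minimum-change pathway averaged over
substitution orderings, excluding orderings that pass through a stop codon
unless all do.

Nucleotide diversity π uses 500-site windows stepping by 100; per window it
is the mean over sequence pairs of differences per compared site, excluding
alignment columns where either member of the pair has a gap or N. π is
computed over a supplied aligned sequence set (e.g. per-individual
consensus sequences); heteroplasmy-weighted diversity is out of scope.

## Inheritance

Maternal assignment correlates each offspring's per-site alternative-allele
frequencies against each candidate parent over the union of sites variable
in either member (absent sites as zero; an intersection policy is available
but tiny intersections produce spuriously perfect correlations). A parent
qualifies with r > 0 and two-sided p < 0.05. The strict criterion assigns
only when exactly one parent qualifies; the loose criterion assigns the
qualifying parent with the lower p, ties broken by higher R², and abstains
on an exact tie (which keeps the procedure antisymmetric under relabeling
the parents). Undefined correlations never qualify. No multiple-testing
correction is applied across offspring — the procedure is per-offspring —
but a Benjamini–Hochberg column is emitted. One documented confound is not
modelled: when the two candidate parents share a mother, an offspring may
correlate weakly with its father too, which depresses strict-criterion
assignments (both parents qualify) without creating wrong ones.

Offspring groups by assigned mother are compared with a pooled-variance
Student t-test (not Welch): the pooled form is the one that reproduces the
published group comparison from its printed summaries, and it is also
available directly from summary statistics.

The pedigree mutation rate is n_fixed / (n_individuals · L_mt), with
n_fixed the count of distinct (individual, position) sites whose
alternative allele exceeds 50% — mutations treated as being on the way to
fixation. For 2 such sites over 90 individuals and 14 kb this is
1.587 × 10⁻⁶ per base per generation, quoted at two significant figures.

## The synthetic matriline

The generator emulates the study design: a founder mother, a daughter, a
sibship containing the two focal-cross parents (plus extra siblings), 76
focal offspring whose true mother is drawn between the two parents
(hermaphrodite pair mating), and four grandoffspring — 90 individuals over
five generations on a 14,202-base circular mitogenome carrying 13
protein-coding genes, 2 rRNAs and tRNAs, with a tandem tRNA duplication
region.

Transmission model, per individual:

- **Founder heteroplasmy**: 500 sites with exponential frequencies of mean
  2.6% — matching the published profile of the more heteroplasmic focal
  parent (2.6% across 520 sites).
- **Bottleneck**: each offspring's frequency is B/N_b with
  B ~ Binomial(N_b, f_mother), N_b = 100 germline genome copies.
- **De novo mutation**: per-site probability μ · (R/R_mid)^−κ with
  μ = 10⁻² per site per generation, κ = 1 and R_mid the geometric middle
  of the copy-ratio bounds; new alleles seed at frequency 1/N_b. The
  κ-coupling makes low-copy individuals accumulate the heavy, skewed
  variant loads seen in the real data (where the most heteroplasmic snail
  had 13% of sites variable) and produces the negative association between
  copy ratio and heteroplasmy (R² ≈ 0.05–0.3 across seeds at the 2% call
  level, around the published 0.2). Modelling the coupling as causal from
  copy ratio to mutation input is a simulator convenience; the observed
  association is a correlation and implies no direction.
- **Selection**: after transmission, nonsynonymous alternative frequencies
  are multiplied by (1 − s), s = 0.8 — a deterministic penalty rather than
  viability sampling, the simplest model that yields the observed
  signature (third-position excess, synonymous majority among survivors).
  Founders are exempt (their frequencies *are* the configured standing
  variation).
- **Copy ratio**: log-uniform on [5, 80], realized as an exact integer
  mtDNA read count against a fixed total (2 × 10⁸ reads, 3.5 Gb nuclear
  genome) so that the read-fraction arithmetic inverts to the true ratio
  exactly.
- **Sequencing**: depth ~ Poisson(100) per site; the registered
  alternative base receives Binomial(depth, f(1−ε) + (1−f)ε/3) reads with
  ε = 10⁻³ (NovaSeq-like), the two other non-reference bases ε/3 shares,
  and counts always sum to depth.

Determinism: one seed drives everything; per-individual substreams are
derived by stable CRC32 hashing of the individual id, so enlarging a
sibship never changes existing individuals' draws. Identical seeds give
bit-identical outputs (golden-digest tested).

What the generator does **not** emulate — and hence what passing tests do
not establish about real data: NUMT contamination (a key real-world
false-positive source), mapping and alignment artefacts, base-quality
variation along reads, length heteroplasmy interacting with SNP calling,
somatic–germline divergence within an individual, and father-side
correlation from shared grandmothers in the focal cross (parents' founder
profiles are drawn independently in the assignment benchmark, which is the
favourable case for maternal recovery).

## Numerical and design choices

- Coordinates are 1-based inclusive throughout; circular features may wrap
  (start > end) and are unrolled internally. How start-codon search should
  interact with wrap-around genes is undefined in the annotation rules; the
  implementation unrolls the circle.
- Annotation polishing applies the manual rules in order: tRNAs trusted;
  each PCG start moved to the first eligible in-frame start codon nearest
  the preceding gene without overlapping it (a draft already overlapping
  its neighbour keeps its own start — PCG–PCG overlap is resolved
  separately); PCG ends truncated at tRNAs; same-frame PCG overlaps
  truncated, different-frame overlaps kept; truncation remainders flagged
  as abbreviated stops (terminal T or TA, completed by polyadenylation);
  rRNA bounds never extended. The procedure is idempotent.
- The pipeline's pooled codon analysis keeps sites called in ≥ 2
  individuals (configurable), suppressing singleton error calls that would
  otherwise dominate a 90-individual pool; the tabulation function itself
  applies no such filter.
- Statistical routines delegate to scipy (Fisher exact, chi-squared
  survival function, Pearson correlation, OLS, t distribution,
  Benjamini–Hochberg); the package's own tests check them against
  closed-form and enumeration oracles.
- Problem sizes in the test suite: the fast fixtures use a 3 kb toy genome
  with a 12–14 snail pedigree; the integration test runs the full
  90-individual, 14.2 kb default once; the assignment benchmark uses 12
  seeds × 10 offspring; the association calibrations use 10 full-size
  seeds (power) and 120 small-genome seeds (type-I); the false-positive
  calibration simulates 2 × 10⁵ error-only sites against an exact
  multinomial tail.

## Known limitations

- The per-site error model is symmetric and context-free; real error is
  sequence-context dependent, which would make the false-positive
  calibration optimistic on real data.
- Selection acts only through the per-generation frequency penalty on
  nonsynonymous sites; no site-specific coefficients, no positive
  selection within the matriline.
- The mutation-rate estimator takes majority variants as proxies for
  fixation events; it is a deliberately simplified short-term (pedigree)
  rate and will exceed phylogenetic rates.
- Strict-criterion assignments are rare when both candidate parents derive
  from one mother (both correlate with the offspring); the loose criterion
  is the operative one in that regime.
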