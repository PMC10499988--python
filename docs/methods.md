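# Methods

## Library model

An SXCX_nC library displays peptides `S X C X…X C` with n + 1 variable (X)
positions: one between the fixed serine and the first cysteine, n between
the two cysteines. The two cysteines are the unique attachment points of the
perfluoroaromatic cross-linker, so the synthesis alphabet at X positions
excludes cysteine (19 letters). Theoretical diversity is
`alphabet_size^(n+1)`; both the 20-letter count (160,000 for n = 3) and the
19-letter count (130,321) are meaningful depending on whether the variable
positions are taken over the full canonical alphabet or the cysteine-free
trinucleotide set, so diversity is parametric in `alphabet_size` and the
simulation alphabet defaults to 19 letters.

Classification of an observed peptide checks only the fixed skeleton
(length n + 4, S at position 1, C at positions 3 and n + 4, canonical
letters everywhere); any canonical residue is accepted at X positions, since
deletion products and sequencing survivors need not respect the synthesis
alphabet. Deletion products of the n = 4/5 libraries legitimately appear as
n = 3 sequences, so classification spans all design sizes and off-design
peptides are kept (flagged) rather than discarded.

The constant priming regions default to the cloning-template flanks
(`CCCGGGTACCTTTCTATTCTCACTCT` / `GGTGGAGGTTCGGCCGGGCGCTTGATT`); the fixed
Ser (TCT) and Cys (TGT) codons are counted as part of the variable-region
insert so that the translated insert is the complete displayed peptide.

Translation uses the standard genetic code; a stop codon truncates the
peptide and flags the record instead of raising, so the processing pipeline
can discard the read while preserving audit totals.

## Synthetic campaigns

The generator emulates a single-round solution-panning campaign read out on
a 2×75 paired-end run:

- **Naive abundances**: log-normal(μ = 0, σ = 1.5), normalised — a
  long-tailed naive pool in which copy numbers span ~3 orders of magnitude,
  as typical for naive phage libraries. A `uniform` model exists for exact
  tests. Default pool size 10⁴ distinct n = 3 variants at 10⁵ read pairs per
  experiment, giving mean coverage ~10 reads/variant.
- **Selection**: one round is modelled as frequency reweighting
  f_i → λ_i f_i / Σ_j λ_j f_j with λ = 1 for non-binders, followed by
  multinomial read sampling. No phage amplification kinetics are modelled:
  the enrichment statistic only sees counts, and a single round has no
  round-to-round amplification bias to track. Planted binders default to
  λ = 10 at naive frequency 10⁻³ (pinned after the abundance draw), the
  regime in which the power guarantees below are stated.
- **Reads**: forward = barcode (8 nt) + 5′ constant region + insert + 3′
  constant prefix; reverse = reverse complement of the construct's 3′ end;
  both truncated to 75 nt. Errors are independent per-base substitutions
  (default 10⁻³/base); indels, PCR bias, chimeras and per-cycle quality
  decay are deliberately out of scope — the matching rules downstream are
  fixed-offset and length-preserving, so indel reads would simply fail.
  Qualities are Q37 throughout, with an optional fraction of read pairs
  demoted to Q2 to exercise the quality filter.
- **Determinism**: a single seeded generator drives the abundance draw,
  multinomial sampling and error placement in fixed order, so identical
  (config, seed) gives byte-identical FASTQ.

What passing tests on these data do **not** show about real runs: robustness
to indels, adapter read-through, PCR chimeras, quality-correlated errors, or
amplification bias across multiple rounds.

## Read deconvolution

Cascade per read pair, in order: per-base quality ≥ min_q (default Q20) over
both mates → exact barcode match on the leading forward bases (no partial
credit, since only the priming regions are published with a substitution
tolerance) → 5′ priming region on the forward mate and reverse-complemented
3′ priming region at offset 0 of the reverse mate, each Hamming-matched at
its fixed offset with ≤ 1 substitution → cycle-size resolution → exact F/R
agreement over the variable window → translation and classification.

Cycle-size resolution is needed because libraries mix n = 3–5 and the
published processing rules do not state the mechanics: for each design n in
ascending order, the forward read must carry the 3′ constant prefix at the
expected offset (≤ 1 substitution over ≥ 6 overlapping bases) *and* the
forward and reverse variable windows must agree exactly; the first n
satisfying both wins, and failure for every n is recorded as an F/R
mismatch. The quality filter interrogates the whole of both mates — at 2×75
the reads are barcode + priming + insert end to end.

Counting is at the peptide level; a representative DNA insert is retained
per peptide for audit. OK and off-design records both contribute counts;
every input read lands in exactly one audit cell (experiment × status), so
audit totals conserve the input.

## Enrichment statistic

Depths are unequal across experiments, so frequencies are compared as
counts-per-million. The test conditions on the peptide's total count
k = c_test + c_ctrl: under the null, c_test ~ Binomial(k, π₀) with
π₀ = N_test/(N_test + N_ctrl). The two-sided p sums the probabilities of all
outcomes whose pmf does not exceed the observed outcome's (relative tie
tolerance 10⁻¹²). This is implemented by direct pmf summation (vectorised,
grouped by k) rather than through a library call, because the test suite
pins it to brute-force enumeration at 10⁻¹² — `scipy.stats.binomtest`, which
uses a looser tie factor, serves as an independent cross-check instead. An
exact conditional test was chosen because single-round selections are
sequenced once: there are no replicates from which to estimate
overdispersion, and at these depths the exact test is conservative (observed
null false-positive rate ~1% at the 5% threshold).

Fold change is ((c_test + a)/N_test)/((c_ctrl + a)/N_ctrl) with pseudocount
a = 1 applied to the fold only — the p-value stays exact while the fold
remains finite at c_ctrl = 0. Hits require p_raw < 0.05 AND fold > 3, both
strict; nomination intersects the per-comparison hit sets across all
controls by default. The final list is ranked by each peptide's *worst*
(largest) p across comparisons, ties by the smallest fold (descending), then
peptide — the conservative reading of "ranked by p" when several comparisons
exist. BH adjustment is available but off by default, matching the raw-p
hit rule. The p < 0.05 / fold > 3 thresholds and the intersection rule are
the screening convention this pipeline implements; the original analyses
they mirror used an unpublished script whose statistic may differ in detail.

## Motifs

Dipeptides are ordered, adjacent residue pairs over the full displayed
peptide, fixed positions included (whether screening heat maps include the
fixed skeleton is a convention; including it keeps the constant-residue
context visible, e.g. C-X pairs). The default null preserves each position's
composition while making adjacent positions independent:
E[a,b] = Σ_i n·f_i(a)·f_{i+1}(b); an alternative null from naive-library
residue frequencies is available. Enrichment is (obs + 1)/(exp + 1).

Families are connected components of the Hamming graph thresholded at
distance 2 (single linkage) — a deliberate, simple choice where no method is
canonical; at radius 2 on 7-mers it joins sequences sharing ≥ 5 of 7
positions. Consensus is the per-position mode, ties broken alphabetically
and flagged with their positions.

## Binding models

All fits use the exact two-species depletion equilibrium — computed in the
cancellation-safe form f = 2P/(b + √(b² − 4LP)), b = L + P + K_D — because
assay ligand concentrations (1–50 µM) are comparable to the affinities
measured (µM), where the P ≫ L hyperbola is badly biased. Near the
stoichiometric equivalence point (L ≈ P, K_D → 0) the discriminant loses
about half its digits; accuracy there is ~10⁻¹⁰ in f, far below any assay
noise.

- **FP**: r(P) = r_free + (r_bound − r_free)·f, fitted by least squares over
  (log K_D, r_free, r_bound) with a deterministic 7-point log-spaced K_D
  multistart spanning [min conc/10, max conc×10]. A flat titration returns
  an explicit unidentifiable-K_D warning instead of a number.
- **¹⁹F NMR**: binding is modelled as complete signal loss of the bound
  fraction, S(P) = S₀(1 − f) — the slow-exchange broadening picture; partial
  broadening is out of scope. AC50, the protein concentration suppressing
  half the protein-free signal, follows in closed form as K_D + L_tot/2. A
  signal rise beyond 5% of S₀ flags complex binding; an ill-conditioned fit
  falls back to model-free interpolation at S₀/2. L_tot is always an
  explicit input (published titrations used 20 and 50 µM in different
  experiments), never defaulted.
- **ΔΔG**: R·T·ln(K_D,mut/K_D,wt) with R = 1.987×10⁻³ kcal/(mol·K),
  T default 298.15 K (the conversion temperature is rarely reported; it
  enters only linearly). Correlation against externally supplied ΔΔG (e.g.
  from free-energy calculations) is Pearson r with an OLS line; the package
  consumes such values as numbers and computes none itself.

## Problem sizes

The shipped drivers and the acceptance script use 10⁴ variants × 10⁵ read
pairs × 3–4 experiments for campaign-level checks, 200 replicates at 10⁴
reads for the null error rate, 100 replicates at 10⁵ reads for power, and
50 noisy replicates for fit recovery — sizes at which the multinomial
sampling noise, not the replicate count, dominates the quoted tolerances.

## Known limitations

- No indel handling anywhere; a read with an indel in any interrogated span
  is discarded by design.
- Counting aggregates synonymous DNA at the peptide level (one
  representative insert is kept per peptide); clone-level DNA analysis is
  out of scope.
- The enrichment test treats reads as independent draws; clonal phage
  amplification before sequencing would overdisperse counts and make the
  exact test anti-conservative. Single-round campaigns limit, but do not
  eliminate, this effect.
- The NMR model assumes one binding site and complete bound-state signal
  loss; multi-site binding (seen for albumin by ITC) is flagged, not
  modelled.
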