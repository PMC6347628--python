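# Methods

This note records the models, conventions and numerical choices behind
`millet-evol`, and what the synthetic-data generators do and do not emulate.

## 4DTv scoring (`degen4dtv`)

**Site rule.** A codon column is scored iff both codons are free of gaps and
N, identical at positions 1–2, and that prefix belongs to one of the eight
fourfold families of the standard genetic code (derived programmatically
from the code table). This *strict intersection* convention is the
conservative default when two sequences are compared; a `loose` convention
(each codon's own prefix fourfold, prefixes need not match) is available via
`compute_4dtv(..., convention="loose")` for sensitivity analyses. Codons
containing N are excluded rather than treated as matches.

**Statistic.** `4DTv = n_transversions / n_4d_sites`, the raw proportion.
No multiple-hit correction is applied by default: at the 4DTv levels where
peak dating is informative (≲ 0.1) the correction is ≈ 0.5% relative, and
applying it would silently change the meaning of the calibration anchor.
`corrected_4dtv` exposes the two-parameter inversion
`d = −½·ln(1 − 2Q)` for users who want a distance; it is NaN at saturation
(Q ≥ 0.5). Pairs with zero scorable sites return `defined = False` (NaN
value), and are dropped with a logged count before density estimation.

**Anchor extraction.** Collinear blocks with fewer than 5 anchor pairs are
discarded in full; the threshold applies to the block's anchor count, so a
retained block that loses one gene to an unresolvable ID still contributes
its remaining pairs (skips are logged).

**Tandem deduplication.** Genes on one chromosome within `window` gene ranks
(default 5, configurable) form tandem clusters under transitive closure.
Among results that pit one tandem cluster against a single shared homeolog,
exactly one is kept — the one with the most scored sites, ties broken by the
lexicographically smallest gene pair — so a tandem array does not multiply
its vote in the 4DTv distribution. Pairs hitting distinct homeologs are
untouched. The window size and the keep-rule are package choices; nothing
in the underlying procedure canonically fixes them, so both are parameters.

## Peak detection and dating (`wgd_dating`)

Density is a Gaussian kernel sum evaluated on the fixed grid
`0, grid_step, …, 1` (default step 0.001), with bandwidth in data units.
`bandwidth="auto"` uses Silverman's rule `0.9·min(sd, IQR/1.34)·n^(−1/5)`,
falling back to 0.01 for degenerate (near-constant) samples — a case a
generic KDE refuses but which must work here (a point mass is a legitimate
mode). Modes are grid points strictly greater than both neighbours with
density ≥ `min_density_frac` (default 0.05) of the maximum; grid endpoints
are therefore never modes. Fewer than 10 finite values is an explicit
"insufficient data" error.

Dating is strict linear scaling through the origin:
`time = location · anchor_time / anchor_4dtv`. This is deliberately the
simplest clock consistent with using a single anchor; no rate heterogeneity
or mixture deconvolution is attempted. With the conventional grass anchor
(0.38, 70 Myr) a peak at 0.032 dates to 5.89 Myr.

Note an internal tension this linearity inherits: the raw statistic itself
is *not* linear in time (it saturates at ½), so the linear date is an
approximation that is good for young peaks and increasingly compresses deep
ones. This is also why the simulator accepts per-cohort substitution rates:
no single β places the expected 4DTv at both 0.032 for t = 5.8 and 0.38 for
t = 70, so a scenario that fixes both peak locations necessarily uses
cohort-specific rates (`beta_for_target_4dtv` inverts the closed form).

## Substitution simulator (`synthio`, codon pairs)

Null model: only third positions of fourfold-degenerate codons evolve;
positions 1–2 and non-fourfold codons are frozen. This keeps the realized
fourfold-site set constant, makes per-pair ground truth exact, and touches
precisely the sites the statistic reads. Ancestral codons are uniform over
the 61 sense codons (or over the 32 fourfold codons with `fourfold_only`,
which fixes the scorable-site count at the sequence length). Mutation at a
fourfold third position can never create a stop, so frames stay open.

The per-site process is the Kimura two-parameter chain: transition rate α
(A↔G, C↔T) and rate β toward each of the two transversion neighbours. All
states share the exit rate α + 2β, so the exponential-waiting-time process
is simulated exactly by drawing a Poisson((α+2β)·t) event count per site and
typing each event independently (transition with probability α/(α+2β), else
either transversion equally). The testable closed form is
E[observed transversion proportion] = ½·(1 − e^(−8βt)) for two lineages of
length t each; the suite checks it against a numerically exponentiated 4×4
rate matrix and against simulation at 3 standard errors.

Default study conditions for the WGD scenario: 500 pairs per cohort,
500 codons per sequence, cohort times 5.8 / 18 / 70 Myr with rates targeting
4DTv 0.032 / 0.081 / 0.38. These sizes give per-pair sampling noise
(sd ≈ 0.008 at the young peak) small enough for stable mode recovery while
keeping a 20-seed end-to-end run in seconds. Tandem triplets are three
adjacent copies on one chromosome all paired to a single homeolog, evolved
independently from one ancestor at the WGD time.

What the generator does **not** emulate: codon-usage bias, selection,
rate variation across sites or lineages, alignment error, GC drift, and
gene conversion between homeologs. Passing tests show the pipeline's
statistics are correct under the stated null — not that real genomes meet
that null.

## RIL simulation and filtering (`synthio`, `rilfilter`)

Expectation: single-seed-descent selfing from a fully heterozygous F1 gives
`p_het = (1/2)^(g−1)`, homozygotes equal — 31:2:31 at F6, with pooled
heterozygote fraction 2/64 ≈ 3.1%. Markers are independent by default; with
`linkage = r` genotypes follow a first-order Markov chain along marker order
(keep state with probability 1 − r, else redraw from the marker's marginal),
which preserves marginals exactly — adequate because only the per-marker
filter is in scope, not map construction. Miscalls relabel a genotype to
either other state with probability `error_rate/2` each; missingness is
applied last. VCF output is plain v4.2 text with GT calls and a per-marker
QUAL.

Filter conventions (each a strict reading of the criteria): missing fraction
**strictly less than** 0.20 computed over progeny only (named parent samples
are excluded); segregation p **strictly greater than** 1e-5 from Pearson
chi-squared with df = 2, no continuity correction, expected counts from the
marker's **non-missing** total (the natural conditioning; the alternative —
expectations from the full line count — would conflate criteria (a) and
(b)); QUAL ≥ 999 **inclusive**. Biallelic means exactly one ALT and single-
base REF/ALT; failing records are tallied, not errors. A marker is counted
against every criterion it fails. Markers with zero called genotypes fail
the missing criterion and are not segregation-tested. The df-2 identity
`p = e^(−χ²/2)` is asserted to 1e-12 wherever the test runs.

Null calibration uses 50 seeds × 10,000 markers × 132 lines on the
simulator's in-memory genotype matrices with the same vectorized test the
VCF path calls; the full VCF round trip is exercised at 2,000 markers.

## Expression diversity (`synthio`, `famexpr`)

Entropy is Shannon entropy in bits of the gene's tissue proportions
(`0·log 0 = 0`); base 2 is a labeling choice — every comparison made is
base-invariant. All-zero rows are `defined = False`, excluded from family
mean entropy and tallied. Family summaries average **per-gene** entropies
(not the entropy of the summed family profile), which is what "expression
diversity among members" means.

The generator draws each gene's profile from a symmetric Dirichlet with
concentration `specificity` (per-size-class concentrations allowed) and a
log-normal magnitude (location 3.0, scale 1.0 on the natural-log scale,
median ≈ 20 RPKM-like units — a generic bulk-RNA magnitude distribution).
Small concentrations give tissue-specific genes, large give uniform; the
copy-number/entropy gradient used in tests (specificity 10 / 1 / 0.1 for
2- / 4- / 8-copy classes, ≥ 200 genes per class) is a constructed scenario
embodying the qualitative trend, not an inference about any real genome.

The two-proportion test is the pooled z with a Yates-style continuity
correction `½(1/n1 + 1/n2)` by default — on the published family counts
(899/1313 vs 11,773/20,374) it gives p = 3.3e-14, matching the reported
magnitude; the uncorrected variant (`continuity=False`, p = 2.7e-14) is one
flag away. Fisher enrichment uses the standard two-sided convention (sum of
table probabilities ≤ the observed table's) via `scipy.stats.fisher_exact`,
and BH adjustment via `statsmodels` — both are cross-checked in the suite
against exhaustive hypergeometric enumeration (all 2×2 tables with grand
total ≤ 60, deduplicated by the table-symmetry group that provably leaves
the two-sided p invariant) and a brute-force step-up implementation.

## BTB architectures (`btbclass`)

Hits with E-value ≤ 1e-5 (inclusive boundary) are kept; overlapping hits of
the same domain on one protein are union-merged (best E-value retained);
proteins left without a BTB hit are dropped with a logged count. Ordering is
by start, ties by end then label, so classification is a pure function of
the table content. Subgroup names are **generative**: the ordered,
hyphen-joined labels with consecutive duplicates collapsed (tandem BTB-BTB
reads "BTB" — subgroup names never encode within-protein copy counts), with
any out-of-vocabulary domain collapsing the label to "BTB-other". Strict
N-to-C order is used (MATH-BTB ≠ BTB-MATH); presence/absence-only grouping
can be recovered downstream by sorting labels, but is not the default.
Expansion flag: focal count ≥ fold × max(other species) and ≥ 1; when all
other species have zero copies any nonzero focal count flags — documented
behaviour, since 0 → any ratio is "at least twofold".

## Known limitations

- The linear 4DTv clock ignores saturation and rate variation; dates for
  deep peaks are compressed and should be read as order-of-magnitude.
- KDE mode counts depend on bandwidth; Silverman's rule can split a broad
  peak into near-equal twin modes on finite samples (visible in the README
  example's background cohort). Report-level consumers should take the
  highest-density mode per class, as `scripts/acceptance.py` does.
- The RIL simulator models neither residual heterozygosity structure along
  chromosomes beyond first-order linkage, nor allele-specific missingness.
- Expression profiles are compositionally independent across genes; no
  correlation between family members is modelled, so family-level variance
  is understated relative to real paralog families.
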