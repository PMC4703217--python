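# Methods

## Life-table model

A cohort of `N` first-stadium nymphs (`initial_n`) is observed daily;
each record is `(day, n_alive, n_offspring)`. Age is counted with
`x = 1` at the first check after cohort initiation, since the founding
adults are removed after 24 h; this origin is a convention, and any
consistent origin shifts `T` by a constant without changing `R0`. The
schedules are

- `l_x = n_alive(x) / initial_n`,
- `m_x = n_offspring(x) / n_alive(x)` when `n_alive(x) > 0`, else 0.

All individuals are parthenogenetic females, so `m_x` uses the plain
per-survivor divisor with no sex-ratio adjustment. Missed check days
are filled by carrying the last `n_alive` forward with `m_x = 0`
(`fill_gaps=True` in `build_life_table`), which leaves `R0` unchanged
and keeps the age axis contiguous.

`R0 = Σ l_x m_x`, `T = Σ x l_x m_x / R0`, and `r_m = ln(R0)/T` — the
logarithmic approximation, not the Euler–Lotka root; the two agree when
reproduction is concentrated around `T`, and the approximation is what
host-transfer tables report. `r_m` is negative exactly when `R0 < 1`
(a declining population on an unsuitable host). When a replicate
produces no offspring, `R0 = 0` and `T`, `r_m` are reported as
undefined rather than numeric: they are excluded from treatment means
with a logged count, while the observed zero still enters the `R0`
mean.

Aggregation default is per-replicate parameters followed by mean ±
sample SD (SD = 0 for a single replicate): printed SDs require
replicate-level values. A pooled mode is also provided
(`pooled_parameters`): the replicates are merged into one super-cohort
(per day, Σ alive / Σ initial and Σ offspring / Σ alive) and the
parameters computed once. Published r_m values are internally
inconsistent between the two readings — some match the mean of
per-replicate r_m, others match `ln(mean R0)/mean T` — so both modes
exist and the discrepancy is surfaced rather than resolved.

Display rounding is half-up (1 dp for survival percents, `R0` and `T`;
2 dp for `r_m`; integer survey percentages), matching how such tables
are printed.

## Group comparisons

Two groups: Mann–Whitney U, two-sided. The exact null distribution is
used when the combined sample size is ≤ 10 and there are no ties (the
`EXACT_THRESHOLD` balances fidelity against the cost of enumeration);
otherwise the normal approximation with tie correction and continuity
correction. Three or more groups: Kruskal–Wallis with tie correction
and the chi-square approximation on k − 1 degrees of freedom; when
every observation is identical there is no rank variation and the
module returns H = 0, p = 1 directly (the textbook formula is 0/0
there). Both tests are delegated to scipy.stats; the test suite
cross-checks the exact path against an independent full-enumeration
oracle.

Significance display: `**` for p < 0.01, `*` for p < 0.05, and a
compact letter display built from all pairwise Mann–Whitney tests by
the insert-and-absorb method over groups sorted by descending mean.
Two groups share no letter exactly when their pairwise test is
significant at alpha (default 0.05). No multiplicity correction is
applied by default — matching common practice in this literature — and
a Bonferroni flag is available. Sidedness is always two-sided.

## Biotype classifier

A `MarkerDefinition` holds the two primers, five strictly increasing
diagnostic offsets (0-based within the anchored fragment; 1-based in
report strings), the two 5-base patterns (required to differ at every
site, making the calls mutually exclusive), and a primer mismatch
budget (default 2).

Classification: (1) find the forward primer on the given strand or the
reverse complement, best window by fewest mismatches within the
budget, exact matches preferred, forward strand winning ties; (2) the
anchored fragment is everything after the primer match; read the bases
at the five offsets (uppercase, U→T); (3) all five equal to a pattern
gives that biotype; an IUPAC ambiguity code at any diagnostic site
gives `ambiguous`; anything else — including a mix of the two patterns
or a failed primer search — is `other_species`, on the rationale that
divergent species fail a diagnostic assay. A single corrupted
diagnostic site can therefore never flip one biotype into the other.

The published record does not include the amplicon coordinates of the
five SNPs, so the packaged marker uses synthetic offsets
([20, 45, 70, 95, 120] in a 150-nt core flanked by the published
CytbF/16SR primer pair) and the packaged reference FASTA is labelled
synthetic; real-data users supply their own `MarkerDefinition` YAML.

## Survey tables

Calls are grouped by (collection_time, host, morph) by default. Raw
fractions are exact rationals over the unambiguous calls; `ambiguous`
calls are excluded from the denominator and reported in their own
column (printed surveys have no such class, so this is additive).
Display percentages are integer half-up. Some printed survey rows are
not exactly reconstructible from any integer counts (e.g. 2% of 40);
these are treated as rounding artifacts of the source, not modeled.

## Synthetic data

Cohorts: each individual independently survives day `x` with
probability `survival_probs[x-1]` (survival applied first), and each
survivor then contributes Poisson(`fecundity_means[x-1]`) offspring.
Poisson is a modeling choice (simple, non-negative, integer), not an
empirical claim. The per-replicate R0 estimator is unbiased for the
closed form `E[R0] = Σ_x (Π_{i≤x} p_i) f_x`, and `analytic_truth`
derives T and r_m from the expected schedule. Defaults emulate the
host-transfer protocol: cohorts of 10 nymphs, 15 replicates (within
the protocol's 10–30 range), daily survival 0.98 over 20 days, and a
5-day juvenile period followed by 9 reproductive days at 4.5
nymphs/day — analytic R0 ≈ 33, T ≈ 9.9 d, r_m ≈ 0.35/d, in the range
observed for aphids on their natal host.

Amplicons: biotype records share one randomly drawn core per batch
with the pattern written at the diagnostic offsets, primer-flanked;
substitution noise applies only outside the diagnostic sites and
primers, so truth labels remain exact at any noise level.
`other_species` records are uniform-random sequences verified not to
contain the forward primer within the mismatch budget. Every second
record is emitted reverse-complemented to force strand handling.

What the generators do not emulate: real sequencing error at
diagnostic sites, chimeric or truncated reads, indels (the classifier
assumes ungapped fragments), overdispersed fecundity, and
between-replicate environmental variation. Passing tests therefore
demonstrate correctness of the computational pipeline under the stated
model, not robustness to those artifacts.

## Numerical and interface choices

- Sample SD uses ddof = 1; one replicate reports SD = 0.
- Survival percentages carry the last observation forward past a
  cohort's final check; a day before the first check is an error.
- Cohort CSV may include an `initial_n` column; otherwise the first
  day's `n_alive` is used (real day-1 mortality then goes unseen — 
  supply the column when it matters).
- All outputs are TSV with fixed column order; reruns are
  byte-identical. Logs go to stderr only.
- Simulation sizes in the test suite (200 replicates for parameter
  recovery, 2,000 null simulations for the type-I check, 1,000
  fragments for classification) were chosen as the smallest sizes at
  which the 3-standard-error and [0.03, 0.07] bands are meaningful.

## Known limitations

- `r_m = ln(R0)/T` understates the Euler–Lotka rate when reproduction
  is spread widely around `T`; no iterative solver is provided.
- The letter display reflects uncorrected pairwise tests unless the
  Bonferroni flag is set; with many groups its type-I error inflates
  accordingly.
- The classifier handles substitutions only; an indel between the
  primer and the last diagnostic site shifts the frame and will
  typically produce `other_species`.
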