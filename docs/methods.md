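# Methods

## The design problem

A blocking oligonucleotide must satisfy three constraints at once. It
must perfectly match the clade it is meant to suppress (the
*block-set*): with alternating LNAs, one mismatch — especially a central
one — largely disables blocking, so any block-set polymorphism under the
blocker is a failure mode. It must be divergent from every template
whose amplification matters (the *protect-set*), and that divergence
should sit in the window center, where mismatches do the most to relieve
elongation arrest. And it must out-compete the primers kinetically,
which is arranged by tuning its melting temperature a target offset
(default +7 °C) above the hotter primer's.

`nestblock` encodes these as: conservation = fraction of block-set
templates with zero mismatches against the window's degenerate
consensus; divergence = min over the protect-set of
`total + (center_weight − 1) · center` mismatches; a hard filter
dropping windows where any protect template has fewer than
`min_protect_center_mismatches` (default 1) central mismatches; and a
reported `tm_gap` against the primer pair. The scan is exhaustive over
every (start, length) window in the inter-primer region — barcode
fragments are a few hundred columns, so brute force is cheap and fully
deterministic. Ranking is by the weighted score (weights default to
1, 1, 0 for conservation, divergence, |tm_gap|); ties break to the
leftmost window, then the shortest. `design_blockers` evaluates every
scanned length directly and therefore builds candidates without
additional trimming; `build_candidate` on a single window supports
symmetric (default), left or right trimming toward the Tm target.

### Positional conventions

Positions are 1-based, 5′→3′. The primer 3′-class is the five positions
adjacent to the 3′ terminus. The blocker center is `margin < i ≤ L −
margin` with margin 5, so a 16-mer has center {6..11}. The phrase "more
than five bases from either end" could also be read as counting
intervening bases (positions 7–10 for a 16-mer); the margin is exposed
as `end_margin` on the profiling and design APIs for anyone preferring
the stricter reading. Template gap columns under an oligo count as
mismatches and are additionally reported as `alignment_gaps` — an indel
disrupts annealing at least as much as a substitution. Degenerate codes
compare optimistically by base-set intersection (a blocker `Y` matches
both C and T templates). Degenerate-consensus columns fail on gaps and
on codes larger than the per-column cap implied by `max_degeneracy`
(default 4 expansions per candidate).

## Melting temperatures

DNA/DNA stacks use the SantaLucia unified nearest-neighbor ΔH°/ΔS° set
with terminal A·T / G·C initiation terms and the symmetry correction for
self-complementary strands. Tm = ΔH/(ΔS′ + R·ln(C_T/x)) with x = 4
(neither strand in excess; x = 1 for self-complementary duplexes), and
the entropic salt correction ΔS′ = ΔS + 0.368·(N−1)·ln[Na⁺]_eq, with
divalent cations folded in as [Na⁺]_eq = [mono] + 120·√([Mg²⁺] mM).
Defaults mirror a standard metabarcoding PCR mix: 1 µM oligo, 50 mM
monovalent, 2.5 mM Mg²⁺.

Each nearest-neighbor step whose 5′ base is LNA-modified receives a
(ΔΔH, ΔΔS) increment. The default is a single sequence-independent pair,
(−2.5 kcal/mol, −5.0 cal/mol·K), i.e. ΔΔG°₃₇ ≈ −0.95 kcal/mol per
residue, chosen to land in the +2 to +3 °C-per-LNA range reported for
short mixed-sequence oligos; `ThermoParams.lna_increments` accepts a
per-step table for sequence-dependent work. Mismatched duplexes are not
modelled: blockers are tuned on perfect-match Tm only. Degenerate oligos
report the arithmetic mean Tm over their concrete expansions (min/max
also available); expansion is capped (default 512) and overflows are
explicit errors.

Internal consistency check worth knowing: the published 16-mer sparrow
blocker, under these defaults, computes to 0.23 °C above the +7 °C
target over the hotter of the BF1_alt/BR2 annealing regions.

## Read-table analytics

Blocking efficiency is `100·(1 − reads_with/reads_without)`; percent
changes round half away from zero, which reproduces how whole-percent
richness boosts are conventionally printed. Richness applies
minimum-read or minimum-RRA thresholds; RRA denominators are per
sample×condition library totals over all taxa (site-wide RRA uses the
condition-wide total), and site-wide minimum-read thresholds apply to
counts summed across samples. "Pooled" analyses sum counts across
conditions per (sample, taxon) before thresholding. Nest-builder
exclusion is per sample — the same species detected in another species'
nest still counts. Accumulation curves use random permutations of the
sample order (subsampling without replacement, default 100
permutations, explicit seed); the closed-form expectation
E[S_k] = Σ_t (1 − C(N−n_t, k)/C(N, k)) is implemented independently and
used as the calibration oracle in tests. The paired t-test is the
textbook mean-difference statistic with two-sided p from the t
distribution; zero-variance differences return t = 0, p = 1 (all-zero)
or a signed infinity (constant nonzero shift).

Because libraries are sequenced to a fixed depth, suppressing an
abundant taxon frees depth and inflates every other taxon's reads; the
naive with/without ratio therefore *overstates* retention for the
blocked taxon. `relative_retention` removes the shared renormalisation
by dividing by the condition-ratio of reference taxa with known
retention — this is the estimator used for simulator parameter recovery,
and it recovers the configured retention exactly in expectation, whereas
the naive efficiency matches the simulator's renormalised analytic
expectation (both are reported by the acceptance script).

## The simulator

`simulate_template_alignment` plants a design window: the block-set is
identical over the window (optional noise elsewhere), each protect
template differs at exactly the configured number of center positions —
placed at the extreme center offsets first, so no shifted or shortened
window captures them all centrally and the planted window is the unique
score maximum — plus background substitutions away from the window
(default rate 0.05). The columns flanking the window are deleted in the
block-set, giving the window indel boundaries as real cross-clade
alignments have.

`simulate_read_tables` draws each library as a multinomial of fixed
depth (default 10⁵) over per-taxon weights
`θ_i · (1 + e·δ^{m3})^C` — exponential PCR with base efficiency e
(default 0.9) penalised by δ (default 0.5) per 3′-terminal primer
mismatch over C = 50 cycles — with the blocker condition multiplying
weights by r_strong = 0.001 (perfect center match) or r_weak = 0.9
(any center mismatch). The default community has one dominant
nest-builder at 60% of template molecules, ten rarer animal taxa and an
abundant poorly-amplifying non-target background, echoing nest samples
dominated by host and fungal reads. All randomness flows from one seed
through per-library SeedSequence streams, so outputs are byte-identical
per (scenario, seed).

What the simulator does *not* model: sequencing error, chimeras, index
hopping, taxonomic misassignment, PCR stochasticity beyond the
multinomial draw, or inter-nest ecological variation. Passing tests
demonstrate that the design and analysis machinery is correct under the
generative model, not that any particular field study's numbers will
reproduce — study-scale quantities (per-nest richness means, the
82/87-series site-wide richness values, clade-level mismatch fractions)
require the study's own read tables and reference sequences, which this
package does not ship; its analytics accept such tables via
`read_table_from_files` (TSV/CSV/XLSX).

## Problem sizes and numerics

Tests and the acceptance script run the designer on a 120-column,
15-template alignment (≈ a few thousand scanned windows), accumulation
calibration on 10-sample tables with 100 permutations, and retention
recovery over 20 replicate library pairs at depth 10⁵ — all chosen as
the smallest sizes at which the Monte-Carlo checks are statistically
meaningful. Floating-point ties in candidate ranking are broken
lexicographically (score, then leftmost start, then shortest length), so
design output is invariant to template input order.
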