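# Methods

## Degenerate matching model

All sequence comparison is ungapped and IUPAC-set-based. Each of the 15 IUPAC
DNA letters denotes a non-empty subset of {A,C,G,T}; two positions match iff
their sets intersect. For a degenerate primer against a concrete site this
equals the minimum Hamming distance over all concrete expansions of the
primer, i.e. the distance to the best-matching primer formulation — the
quantity of interest when asking whether any molecule in the synthesized
primer mixture can pair with a site. Consequences of the set-intersection
rule:

- a reference `N` (or any ambiguity code) never counts as a mismatch against
  any primer letter: reference ambiguity denotes an unknown base, not a
  different one;
- mismatch counting is symmetric in its two arguments;
- when both sides are degenerate the count is a lower bound over joint
  expansions (sufficient for site profiling, where sites are almost always
  concrete).

Indels are not modeled anywhere: binding sites are primer-length windows and
variants are substitution-only. U and gap characters are rejected (DNA only);
all sequences are uppercased at ingestion. Expansion of a degenerate sequence
refuses above a degeneracy cap (default 4096) since N-rich inputs explode
combinatorially.

## Binding-site search and in-silico PCR

A forward primer is compared against every plus-strand window; a reverse
primer's plus-strand binding site is its reverse complement, so the scan uses
revcomp(primer) and reports strand "−", with the extracted site re-oriented to
read 5'→3' in primer orientation. The scan is vectorized (4-bit base masks,
one AND per window position) and exactly equals the naive per-window mismatch
count; the test suite enforces this equivalence against a brute-force oracle.

Coordinates are 0-based half-open internally; text outputs also print 1-based
inclusive columns because primer names (27F, 341F, 515F, 806R) follow E. coli
numbering, which is 1-based. Default mismatch tolerance for searching and PCR
is 2; mismatches are counted plainly, with no 3'-end weighting, since binding
in a mixture is the modeled phenomenon rather than polymerase extension — an
optional flag disqualifies hits with any mismatch in the final n 3' bases
(n = 2 when enabled) for users who want the stricter rule.

Amplicon prediction selects the best forward hit and the best reverse hit
downstream of it by (combined mismatches, product length, leftmost). The two
footprints may not overlap. The product includes both primer footprints; on
templates laid out per E. coli numbering the V1-V2 / V3-V4 / V4 products are
349 / 466 / 292 bp. Failures are statuses, evaluated in a fixed order —
`no_forward_site`, `no_reverse_site`, `wrong_orientation`,
`length_out_of_bounds` (bounds default 50–2500 bp) — never exceptions. The
summary statistic over a collection is the mean and *population* SD (divide by
n) of product length over amplified records, with the failure count reported
alongside.

## Reference refinement (dereplication at an identity threshold)

References are clustered greedily: records sorted by length descending (ties
by id ascending); each record joins the first existing centroid with identity
≥ threshold (default 0.99), else founds a cluster. The sort order and
first-fit rule are part of the contract — they make the partition
reproducible. Identity is defined as matching columns / alignment length of a
global alignment with free end gaps, where alignment length spans the columns
between the first and last column in which both sequences carry a residue:
terminal overhangs are free, internal gaps count against identity. This is
stated prominently because the threshold is conventional ("99%") while the
identity definition is not, and it changes cluster counts. Alignments come
from Biopython's PairwiseAligner (match 2, mismatch −1, gap open −4, extend
−1, end gaps free); the scoring affects only which optimal alignment is
chosen, identity being computed from the alignment itself.

Above 50,000 input records a shared-8-mer prefilter skips alignments against
centroids sharing no 8-mer with the query. At thresholds ≥ 0.9 on
near-full-length sequences such a pair cannot reach the threshold, so results
equal the unpruned algorithm (enforced by a fixture test); the prefilter is
disabled at lower thresholds.

Quality guards at ingestion (both configurable, disabled with 0): sequences
shorter than 500 bp (near-complete-gene guard) or with more than 5% ambiguity
codes are excluded with a logged count.

## Site-variant profiling and dominant groups

For each reference, the best window for the primer (fewest mismatches,
leftmost tie-break) is extracted under a generous ceiling (default 5
mismatches) so heavily mispaired lineages are still profiled; no-window
records are tallied as misses. Identical site strings are grouped; each
variant row carries total and per-taxon occurrence counts at the grouping rank
(default *order*), the minimum mismatch count, the best-matching expansion,
and the dominant group(s). Dominance is plurality with a 0.5 share floor: the
top taxon is reported alone when it holds at least half the variant's
occurrences, otherwise the top two are listed. The rendered view prints dots
at positions identical to the most common variant so lineage-specific
substitutions stand out.

When references are refined first, occurrences are counted one vote per
centroid (the default pipeline order); counting one vote per raw record is
available by simply not refining.

Groups named below class without an order token (e.g. *Mollicutes* RF39 in
SILVA-style lineages) survive because the lineage parser keeps unprefixed or
unparseable tokens verbatim at their positional rank rather than discarding
them.

## Pool optimization

Greedy weighted set cover over observed occurrence mass. The pool starts as
the original primer (always first, never removed). Each step adds the
candidate covering the most currently-uncovered occurrences at 0 mismatches;
ties prefer lower degeneracy, then lexicographic order. Candidates are
uncovered variant strings verbatim; with `allow_degenerate`, also the IUPAC
position-wise merge of such a variant with an existing pool member, admitted
only if every expansion of the merge is an observed variant or an expansion of
the original primer — degeneracy must never buy coverage of sites nobody
observed, because unobserved expansions only add mispriming risk. A merge
replaces the (non-original) member it merged with. The proposal reports
exact coverage (fraction of occurrence mass matched at 0 mismatches by ≥ 1
member), the per-step gain log, and the residual — the worst remaining
min-mismatch count over uncovered variants. Because each concrete variant
string covers exactly the variants it equals (sets are disjoint unless
degenerate members are introduced), greedy is optimal on variant-only
instances; the suite checks greedy against an exhaustive subset oracle on
instances with ≤ 12 variants and pool sizes 1–4.

## Coverage and profile distortion

Coverage of a taxon under a primer pair is the fraction of its references
whose in-silico PCR status is `amplified` under the tolerance (default 2
mismatches). The model is deliberately binary per reference — no per-copy
efficiency weighting — because the mechanism being screened for is
presence/absence of primer compatibility, and any efficiency model would
imply thermodynamic claims this package does not make. A community profile p
is distorted to p'_i = p_i·c_i / Σ_j p_j·c_j; taxa missing from the coverage
table are treated as fully covered with a warning, and an all-zero product
vector is an explicit error rather than a silent NaN.

Diversity on relative-abundance profiles: Shannon H = −Σ p_i ln p_i (natural
log by default, base selectable; 0·ln 0 := 0) and Simpson reported as the
Gini-Simpson index 1 − Σ p_i², with the concentration Σ p_i² and the inverse
form 1/Σ p_i² also exposed since "Simpson index" is used ambiguously across
the literature; no single variant is asserted as canonical. The heat-map
table is long-format log10(proportion), clamped below at a floor (default −4,
i.e. 0.01%; zeros map to the floor), with the taxon universe being the union
across profiles.

## Synthetic-data generator

The generator exists so every analysis is testable with known ground truth;
it emulates a taxonomically labeled reference set, not 16S biology. A layout
template is a uniform-random background (default 1600 bp, configurable base
frequencies) with one concrete expansion of each primer written at its
footprint — by default the E. coli-numbering footprints 27F-YM 8–27, 338R
338–356, 341F 341–357, 515F 515–532, 806RB 787–806 (1-based inclusive).
Overlapping footprints (338R/341F overlap on the real gene) are handled by
intersecting the primers' position-wise IUPAC constraints and drawing one
concrete base per position, so the planted bases satisfy every primer
simultaneously; an empty intersection is an impossible layout and errors. The
background is rejection-sampled until no off-target window lies within 2
mismatches of any primer, which makes site search unambiguous on fixtures.

A reference set draws, per taxon, one canonical site per primer (fixed across
the taxon's records — binding sites are conserved within lineages, and a fixed
string keeps ground-truth counts exact), then plants declared variants into
exactly round(frequency · n) records chosen without replacement. Variant
overrides are applied after canonical constraints and win position-wise, so a
variant at one primer's site also shows through an overlapping primer's
footprint, as a real substitution would; the manifest records *realized* site
strings and counts (rows altered only via an overlapping primer are labelled
`bystander`). Randomness is numpy's PCG64 seeded from a single integer, with
per-taxon and per-record streams derived via `SeedSequence.spawn`, so
identical spec + seed gives byte-identical FASTA/TSV output regardless of
generation order.

What the generator does **not** emulate: 16S secondary structure, conserved
stems, GC skew, phylogenetic correlation of backgrounds, chimeras, or
length variation of real amplicons across taxa. Passing tests therefore
demonstrate the correctness of the matching, prediction, tallying, clustering
and pooling machinery under controlled conditions — not primer performance on
any real reference snapshot, which depends on the database version used.

## Problem sizes and numerical choices

Test fixtures use 10–20 records per taxon, 200–2000 bp templates, and ≤ 16
sequences per clustering fixture; property suites run a few hundred seeded
random cases per law. All tie-breaks are deterministic and documented above
(hit ordering, centroid first-fit, pool candidate ordering); floating-point
comparisons in profiles use a 1e−9 sum tolerance. The expansion cap (4096),
extraction ceiling (5), off-target rejection radius (2 mismatches) and
amplicon length bounds (50–2500) are all overridable parameters whose defaults
are stated where they are defined.

## Known limitations

- No thermodynamics: no Tm, ΔG, primer-dimer or 3'-extension efficiency
  modeling; mismatch counts are the only binding criterion.
- Ungapped matching cannot represent indel variants of a binding site.
- Greedy clustering depends on the stated input order; it is reproducible but
  not a globally optimal clustering.
- Pool merges are restricted to observed-site-safe degeneracy; a pool designer
  willing to accept broader degeneracy will find more compact pools.
- Coverage is binary per reference; quantitative amplification bias (template
  competition, cycle effects) is out of scope.
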