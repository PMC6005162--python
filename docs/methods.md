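# Methods

## Stem-loop detection

A hairpin is modelled as two reverse-complementary stems of pairing length
≥ `min_stem` (default 4 bp, the shortest stems in structural models of
group II introns) flanking an unpaired loop of 1–`max_loop` nt (default
30). Detection is seed-and-extend over loop centers on an ungapped
sequence: for every candidate loop the innermost flanking pair is tested,
the stem is extended outward while bases are perfect Watson–Crick
complements (no G·T wobble — this is DNA, not folded RNA), and one
unpaired "bulge" base on either strand is tolerated (`non_stem_allowance`,
default 1) once `min_stem` perfect inner pairs are in place. A candidate
whose stem could be extended *inward* is suppressed, because the tighter
stem-loop containing it is always reported instead. Candidates are capped
at `max_stem_search_span` columns (default 120) and ranked by pairing
length, then span.

The scanner runs on the majority consensus *and* on every distinct row,
with coordinates mapped through each row's gap structure. Row scanning
matters for the case where only the inverted sequences form a stem (the
majority form of the region is not a hairpin at all); duplicate structures
are reported once. A bulge adjacent to the loop is equivalently found as a
perfect stem with a longer loop; the called segment and substitution
counts are identical either way.

## Inversion calling

The majority form of each column is the strict consensus (most frequent
unambiguous base; ties broken A<C<G<T; ambiguity codes match only
themselves and never make a column polymorphic). For each stem-loop, every
contiguous sub-segment of the loop — plus the whole stem-loop region, for
the minority-only-stem case — is scored per taxon with
`segment_distances`: `d_before` is the Hamming distance between the
observed and majority segment, `d_after` the distance after
reverse-complementing the observed segment. A taxon carries the inversion
for a segment when

* `d_after ≤ t_after` (default 2), and
* `d_before − d_after ≥ min_before` (default 3): the reversion must
  *explain* at least three substitutions.

The explained-count form of the threshold is deliberate: a marginal 3/2
fit explains a single substitution and arises by chance in inversion-free
alignments at realistic divergence, whereas every credible inversion we
model explains at least three (the weakest published-style case is 5/2).
With this rule the detector makes zero false calls on 200 seeded
inversion-free simulations (40 taxa, 2 kb, ~1–2% pairwise divergence) while
recovering all planted, exactly revertible inversions.

Among candidate segments the winner minimizes the *residual* — `d_after`
plus the mismatches the segment leaves unexplained elsewhere in the
stem-loop span — with ties broken toward larger `d_before`, then the
shorter segment. The residual criterion prefers a whole-loop inversion
over a sub-segment that leaves stray mismatches beside it, and prefers a
sub-loop inversion when the flanks match the majority exactly. Competing
explanations of the same locus from overlapping stem-loop candidates are
deduplicated on the same residual (then stem length). One event is emitted
per stem-loop; taxa matching the minority orientation are grouped into a
single minority set even when they lie on unrelated branches, which is
exactly how homoplasious inversions present. Taxa with a gap in the scored
columns are recorded as not assessable. If the "minority" reaches half of
the assessable taxa the orientation is undefined and an error asks the
caller to orient explicitly.

## Down-weighting

An inversion is one molecular event, so all but one (arbitrary,
`keep_policy` first/last/middle) column of each event segment is excluded.
Plans are written as a NEXUS DATA block plus a MrBayes command block
(`exclude 3-5 9;` — singleton ranges rendered bare, both forms accepted on
read), byte-stable for identical inputs. Coordinates are 1-based inclusive
externally ("start-end", matching the printed site lists) and 0-based
half-open internally. When an event segment intersects a poor-alignment
exclusion range, the poor-alignment exclusion wins and the whole segment is
dropped (no representative survives). Re-scanning the down-weighted
alignment calls no event in any down-weighted segment.

## Subsampling experiments

*Duplication*: K interleaved copies of the matrix; the site-pattern
multiset is exactly K× the original — no new information, only sharpened
sampling of the same patterns.

*Delete-fraction jackknife*: each replicate retains `round(f·L)` distinct
columns (f = fraction retained: 0.04/0.08/0.16 in the intended use; 20
replicates), drawn uniformly without replacement from an optional column
universe (e.g. the non-coding columns after exclusions), emitted in
ascending original order. Rounding is half-up. Each replicate draws from a
generator seeded by `(seed, replicate index)`, so runs are byte-identical
given the config.

*Support bookkeeping*: per reference clade, support per replicate is read
from an annotated tree (absent clade → 0) or computed as clade frequency
in a posterior tree sample after discarding `burn_in_fraction` (default
10%). A replicate *contradicts* a clade when some incompatible clade —
intersecting, neither nested (rooted-clade rule, declared rather than
inferred) — reaches the high threshold there. Categories over R
replicates, checked in this order:

1. `most_high` — ≥ 16 of 20 replicates at ≥ 0.95 ("≥" standardized where
   sources mix > and ≥; the comparator threshold is a parameter);
2. `generally_poor` — ≤ 5 high and ≥ 6 replicates at ≤ 0.05;
3. `rarely_high_rarely_contradicted` — ≤ 5 high and ≤ 1 contradicting
   replicate;
4. `intermediate` otherwise.

The built-in desk-scale support source is neighbor joining on Jukes–Cantor
distances (d = −(3/4)·ln(1 − 4p/3), p over both-unambiguous columns,
p ≥ 3/4 flagged saturated) with column-bootstrap supports; the bookkeeping
is agnostic to where supports come from, and Bayesian posterior samples
can be ingested from newick tree lists. NJ uses lowest-index tie-breaking
and is validated against an exhaustive least-squares topology search on
additive matrices (n ≤ 8) and against an independent NJ implementation.

## Parsimony mapping

Inversion presence/absence characters (minority taxa = 1, not-assessable =
"?") are mapped on a rooted topology by a Sankoff-style dynamic program
(exact on multifurcations, which are treated as given — no resolution
search; "?" is the full state set). The root takes the declared ancestral
state (default 0, the outgroup form — exposed because the outgroup itself
carries the minority form at several real loops) whenever that state is
among the root's minimum-cost states; this always holds when the tree is
rooted with the outgroup as a child of the root. Otherwise the minimum-cost
state is used and flagged, keeping the mapping length equal to the
unconstrained parsimony length. Going root-to-tips, each node takes the
state minimizing subtree cost plus the change indicator; *ties resolve
toward a change* — the accelerated-transformation rule, placing changes as
close to the root as possible. Branch events are labelled gain (0→1) or
loss (1→0); relabelling states with the ancestral state flipped swaps
gains and losses exactly.

## Synthetic data

The generator evolves sites independently along a newick tree under JC or
HKY(κ, π) (rate matrix normalized to one expected substitution per unit
branch length; closed-form JC transition probability, matrix exponential
for HKY). Planted stem-loop scaffolds are written into the root sequence
(random stem, declared loop) and planted inversions are applied as a
single reverse complement of the segment on the stated branch(es),
inherited by descendants; noise windows are overwritten per taxon with
independent sequence, emulating unalignable regions. Scaffold columns
evolve at `stemloop_rate` (default 0): hairpin stems are structurally
constrained, and an invariant scaffold keeps planted inversions exactly
revertible (`d_after = 0`), the configuration the sensitivity tests
assume; with a positive rate, post-inversion substitutions inside planted
segments are logged per event. Every scenario is reproducible from
(manifest, seed), and manifests round-trip through JSON.

The default study-shaped scenario is 40 ingroup taxa plus a more distant
outgroup at ~1–2% crown divergence (matching the published pairwise
identities of ~98.7–99.2%), including a short-branch crown clade that
reproduces the support-starvation phenomenon. Branch lengths in the random
join trees are scaled by 1/(log₂n + 1) so a root-to-tip path hits the
requested depth.

The packaged fixture embeds the eight published stem-loop regions
(majority and minority forms exactly as printed, underscore/bold markup
resolved into bulge positions and inverted segments) in a shared neutral
background of 40-column conserved spacers — longer than `max_loop`, so no
stem-loop can bridge two regions. The original alignment's gap structure
is not reconstructible, so absolute coordinates differ from the printed
ones while the relative structure, minority-taxa lists and substitution
counts are preserved. One published count is not recoverable from the
printed strings themselves: stem-loop F's before-count prints as 6 but
recomputes as 5 over the loop under every segment definition we tried; the
fixture carries our recomputed 5/0 with an explicit discrepancy flag
rather than guessing the original counting rule. The "estrelensis clade"
of 13 sequences is taken as estrelensis1–13; which of the 14 accessions
falls outside the clade is not recorded, and only the set size matters to
the counts.

## Scale of the shipped checks

The test battery runs the specificity check at 200 seeded alignments of 40
taxa × 2 kb, sensitivity at 25 planted scenarios, the JC closed-form check
at L = 10,000 (3 binomial SE), stationary-composition χ² at L = 50,000,
NJ-versus-enumeration at n ≤ 8 and parsimony-versus-enumeration at n ≤ 12 —
sizes chosen so each property is sharply testable while the whole suite
stays desk-scale. The fast-region demonstration uses a 12-taxon caricature
(870 bp fast region, 6 kb heterogeneous compartment, K ∈ {1, 4, 16},
16% jackknife × 20): with the target edge carrying no substitutions in the
short region, duplication never lends it support, while the jackknife of
the long compartment recovers it in most replicates.

## Limitations

* No indel evolution (outside noise windows), no selection, no
  rate-across-sites variation in the simulator.
* No RNA thermodynamics: stems are string-complementarity objects, not
  free-energy structures, and G·T wobble pairs are not accepted.
* The internal support engine is NJ + bootstrap, not Bayesian posterior
  probability; the category rules operate identically on either, but
  absolute support values are not comparable across engines.
* Detection thresholds (`t_after`, `min_before`) are calibrated to the
  published extreme rows and exposed as parameters; alignments far outside
  the ~1–2% divergence regime may need different settings.
* DELTRAN and full MPR enumeration are not implemented; ACCTRAN only.
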