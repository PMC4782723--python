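# Methods

## Identity, alignment and distances

All similarity thresholds refer to **all-columns global identity**: the
number of identical columns of an optimal end-to-end pairwise alignment
divided by the total number of alignment columns, terminal gap columns
included. This is the strictest of the common identity conventions; with
it, a threshold of t = 0.97 over ~380 bp V4 amplicons allows at most ~11
mismatch/gap columns.

Alignments are Needleman–Wunsch/Gotoh global alignments with affine gap
costs, computed by Biopython's `PairwiseAligner`. Default scoring is
match +2, mismatch −4, gap open −20, gap extension −2 (the convention of
the widely used greedy clustering tools); a gap of length k costs
20 + 2(k − 1), and terminal gaps are scored like internal ones. Identity
values can depend on the scoring, so the parameters are explicit and
configurable. Among co-optimal alignments the aligner's first traceback is
used; it is deterministic for a given pair, which is all the pipeline
needs (every threshold decision depends only on the optimal score's
match count, which co-optimal ties perturb by at most one column in
practice — and reproducibly so).

Edit (Levenshtein) distances are computed with edlib, optionally banded:
with a bound k the computation is O(kn) and returns "exceeds" (`None`)
when the true distance is larger. A banded edit distance also provides an
exact prefilter for graph construction: identity ≥ t implies
edit distance ≤ (1 − t)(|a| + |b|), because the non-matching columns of
the optimal alignment form an edit script. Pairs rejected by the band are
skipped without alignment, which keeps the O(n²) all-vs-all stage fast at
the package's intended scale (hundreds to a few thousand amplicons; a
node budget of 5,000 guards the CLI).

## Clustering approaches

**Greedy centroid** processes amplicons in decreasing abundance (ties by
id) and assigns each to the *best-matching* existing centroid at identity
≥ t, ties to the earliest-created centroid, else founds a new OTU. The
published tools accept the *first* centroid above threshold in database
order; best-match assignment removes that heuristic instability while
preserving the radius-cap behaviour under study (every member within t of
its centroid, centroids pairwise below t). One consequence worth knowing:
with best-match assignment an environmental amplicon strictly identical
to a reference always lands in the same OTU as that reference, so the
misclassification scenario requires only near-identity, not identity —
the test suite constructs it with an amplicon 98% identical to a
reference that is itself absorbed by a more abundant centroid on the
other side.

**Network components** are connected components of the threshold graph;
isolated nodes become singletons. Components are numbered by smallest
member id, so results are independent of input order.

**Swarm clustering** grows an OTU from the most abundant pooled amplicon
in generations: every amplicon added in one generation captures pooled
amplicons within edit distance d (default 1). With *breaking* on, a
subseed may capture only amplicons of abundance ≤ its own (the seed's
first generation is unrestricted), so abundance is non-increasing along
capture chains and adjacent abundance peaks stay separate. The exact
abundance condition of the published implementation is not documented at
this level of detail; the non-strict, subseed-relative rule used here is
a recorded design choice and is configurable (`breaking=False` recovers
plain single linkage, which equals the transitive closure of the
distance-≤ d relation — a tested equivalence). With *fastidious* on, each
light OTU (total abundance < boundary, default 3) is grafted onto the
heavy OTU minimising the cross-OTU member edit distance when that minimum
is ≤ 2d; ties prefer the heavier OTU. This mirrors the documented
semantics of the published option directly rather than its
virtual-amplicon implementation. Heavy/light status is decided once, from
the pre-graft totals.

Swarm and network OTUs carry internal edges. For swarm these are the full
distance-≤ d graph restricted to members plus graft edges — not the
capture links only — because the full d-graph is independent of capture
order and matches what a network analysis of the OTU would see.

OTUs with fewer than 3 members (singletons and doubletons) are removed
after clustering — and, by design choice, after fastidious grafting,
since grafting exists precisely to rescue such OTUs.

## Novelty classification

OTUs are classed by composition (mixed / ref_only / env_only). Within
network and swarm OTUs, a multi-source BFS from all reference members
assigns each environmental member its hop distance to the nearest
reference: 1 = covered, finite ≥ 2 = novel variant, ∞ = novel. Greedy
OTUs have no internal topology; rather than fabricating one, path-based
classes are marked not applicable and the composition rule alone decides
(env_only → novel, else covered).

Best-hit identities against the reference set (floor 0.70, below which
"no hit" is reported) are computed for amplicons in env_only OTUs by
default; a flag extends this to all environmental amplicons, which the
covered ⇔ best-hit ≥ t equivalence check requires. The
misclassification audit counts novel-set amplicons with best-hit identity
≥ t (a strict-inequality switch exists because "more than 97%" and
"equal or greater" both circulate as the coverage definition; the
non-strict reading matches the clustering rule and is the default).

## Synthetic communities

The generator emulates, at desk scale, the structure that separates the
three approaches on real surveys:

* **References:** 20 random sequences of 380 bp (the V4 amplicon scale),
  pairwise ≥ 10% diverged (rejection sampling).
* **Known clouds** (12 amplicons per reference by default): a founder at
  Binomial(L, 0.01) substitutions from its reference; satellite chains of
  single mutation events (10% of events are 1-bp indels) capped so
  satellites stay within the greedy radius of the founder; an *anchor*
  pair (reference + 1 substitution, plus its own satellite) giving the
  reference a direct d = 1 neighbourhood, as real communities have;
  and a four-amplicon *stepping-stone chain* sized against the clustering
  threshold: a bridge within t of both reference and founder, and a far
  member M within t of the reference but beyond the greedy radius of the
  founder, with two satellites so M's stranded OTU survives the small-OTU
  filter. Stepping stones are what make the greedy radius cap visibly
  misclassify; the founder's substitution count is clamped (≥ 3 and
  < the threshold margin) so the chain provably spans the radius whenever
  stones are enabled.
* **Novel lineages** (5 by default): founders evolved from a random
  reference at a uniform 5–15% substitution divergence, each with a small
  substitution-only cloud. The generator *verifies*, with the same banded
  edit-distance bound the graph builder uses, that no novel amplicon can
  form a threshold edge to any reference or known-cloud amplicon, and
  redraws otherwise. "Novel lineage" is therefore a structural guarantee:
  in a similarity network these amplicons can only form env_only
  components.
* **Abundances** are Zipf-distributed (exponent 1.5), assigned in
  decreasing order along each cloud's chain structure so the founder is
  the most abundant and abundance is non-increasing along capture chains.

Truth records are recomputed from the sequences: each environmental
amplicon's minimum normalized edit distance to the reference set (edlib,
independent of the Biopython alignment stack), labelled `novel_lineage`
exactly when it exceeds the novelty margin 1 − t.

What the generator does **not** emulate: chimeras, platform-specific
error profiles, taxonomy strings, length variation beyond occasional 1-bp
indels, and the density of real intraspecific variant clouds. Passing
tests therefore demonstrate the *structural* properties of the three
approaches (radius cap, transitive growth, local-threshold gaps), not
field-realistic magnitudes; absolute counts on real surveys depend on
variables the generator fixes.

## Problem sizes and numerical choices

The default community is ~290 amplicons (20 × 12 known + 5 × 6 novel + 20
references), chosen so a full three-approach comparison, including the
all-vs-all graph, runs in seconds to a couple of minutes on one CPU. The
randomized counterexample search for the network zero-misclassification
guarantee runs 100 communities at 150 bp / 3–5 references, where the
threshold margin is 4 columns and stepping stones still fit. Oracle
equivalence tests run at: all sequence pairs of length ≤ 8 over a
two-letter alphabet against an independent affine-gap recursion (plus a
truly exhaustive alignment enumeration up to length 4); 500 random pairs
of length ≤ 20 against full-matrix dynamic programming; 100 random graphs
(n ≤ 40) against boolean transitive closure; 100 random labelled graphs
(n ≤ 50) against Floyd–Warshall.

Tie-breaking is fixed everywhere (abundance then id for processing order;
earliest centroid; lexicographically smallest ids for merged amplicons,
best hits and graft pairs; components numbered by smallest member), so
identical inputs — including shuffled input order — give byte-identical
output tables. Degenerate inputs are defined: empty FASTA → empty list;
zero cloud divergence → clouds collapse onto their references at
dereplication and no env_only OTUs arise; empty sequence or empty
reference list → explicit errors.

## Known limitations

* All-vs-all construction is quadratic; the package deliberately targets
  method comparison at desk scale, not production clustering of millions
  of amplicons.
* The swarm breaking rule is one reasonable formalisation of a behaviour
  the published tool implements heuristically; OTU-level agreement with
  that tool is expected but not bit-guaranteed.
* Whether terminal-gap columns counted in the identity definition of the
  historical all-pairs runs cannot be settled from their documentation;
  the all-columns definition used here is recorded, not asserted as
  identical.
* Best-hit computation aligns every query against every reference;
  fine at 20–100 references, quadratic in general.
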