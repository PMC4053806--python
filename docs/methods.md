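# Methods

## Site preparation

Coordinates are 0-based half-open (BED convention) internally; sequences are
converted to the RNA alphabet on load (T→U; anything outside {A,C,G,U,N} is
rejected).  iCLIP records identify single cross-linked nucleotides, so iCLIP
intervals are widened by 15 nt on each side, clipped at sequence bounds,
before any other processing; HITS-CLIP/PAR-CLIP intervals pass through
unchanged.  Sites longer than 75 nt are excluded from training: such diffuse
peaks no longer anchor a well-defined viewpoint.  Each surviving site is
extended by 150 nt per side (or to the transcript end) to form the folding
context; the original site interval becomes the *viewpoint*.  On the minus
strand the context is reverse-complemented and the viewpoint re-expressed
from the 5' end of the returned strand, so the round trip
context[viewpoint] ↔ genome holds exactly.

Unbound training sites are drawn by shuffling bound-site coordinates within
genes that contain at least one bound site: one negative per positive, equal
length and strand, start uniform within the host gene.  Negatives are
rejection-sampled (up to 1000 draws) so they never overlap a positive —
overlapping "unbound" examples would be label noise — and by default stay in
their source gene to preserve composition (`same_gene=False` pools across
occupied genes).  The uniform-placement model was chosen over permuting
existing starts; both are defensible readings of coordinate shuffling, and
uniform placement is the simpler null.

## Folding and shape-class representatives

Contexts are folded in 150-nt windows with step 37.  Windows enumerate as
full windows while they fit; a final window flush with the 3' end is then
appended so trailing positions are always folded.  Per window up to three
representative structures ("shreps") are kept: candidates are grouped by
abstract *shape*, and per shape class the minimum-energy structure is
retained, subject to the energy band E ≤ (1 − 0.1)·MFE for negative MFE (for
MFE ≥ 0 only the MFE structure is returned).  The MFE structure is always
among the shreps.  Sampling a handful of representative shapes, rather than
committing to the single MFE structure, hedges against the well-known
unreliability of point predictions.

Shape strings ignore stem lengths at every level.  Level 1 keeps all loop
detail (helix brackets plus `_` for unpaired runs), level 3 keeps helix
breaks caused by bulges/internal loops (brackets only), level 5 keeps only
the branching skeleton.  The default abstraction level is 3; like R and D it
is a fittable hyperparameter.

Two backends satisfy the folding contract.  The default is the ViennaRNA
bindings (MFE plus `subopt` within the band; energies kcal/mol).  The
built-in backend is a deterministic Nussinov-style maximizer with base-pair
scores GC=3, AU=2, GU=1 (a crude proxy for stacking strength), minimum
hairpin loop 3, and best-first suboptimal enumeration with an exact bound,
so structures emerge in non-increasing score order; its "energies" are
negated scores in arbitrary units, and the 10% band applies to whichever
backend is active.  The built-in folder exists so every part of the pipeline
is exercisable and testable without a thermodynamics engine; it ignores loop
entropies, so designed hairpins are only guaranteed to fold as designed
under the thermodynamic backend (the synthetic-data hairpin property is
asserted there).

Unpaired positions are classified by standard loop decomposition: paired →
stem (S); unpaired → hairpin (H), internal loop (I), bulge (B), multiloop
(M) by the branching of the enclosing pair, or external (E) with no
enclosing pair.

## Graph encoding

Each shrep becomes one component of the site's graph: nucleotide vertices
with backbone edges in 5'→3' direction, base-pair edges directed from the 5'
partner, and an abstract layer with one vertex per structure element
instance — a stem instance covers both strands of a maximal helix, a loop
instance covers all unpaired positions of one loop, external regions are one
vertex per contiguous run.  Abstract adjacency edges run outer-to-inner
(external → stem → its loop → inner stems → … → hairpins).  Each abstract
element connects to its member nucleotides through a dedicated relation
vertex whose edges are non-traversable: paths can never shortcut through a
loop annotation, which would otherwise destroy sequence order information
within loops.  Finally the entire multi-component graph is duplicated with
all edges reversed and labels prefixed `r`.  Directed traversal alone would
see only downstream context; the mirrored copy restores upstream context
while preserving the 5'→3' asymmetry (a sequence and its reverse get
different features; an undirected single-copy encoding provably cannot
separate them).

All shreps of all windows contribute components to one graph, hence one
feature vector per site: evidence is accumulated over the population of
plausible structures rather than adjudicated between them.

## Kernel features

A feature is an ordered pair of same-radius neighborhood subgraphs.  For
every ordered root pair (u, v) at directed shortest-path distance d ≤ D
(traversable edges only) and every r ≤ R, the feature
(set, r, d, N_r(u), N_r(v)) is counted if u or v lies in the viewpoint.
Neighborhoods follow edge orientation; both members share the radius;
self-pairs (d = 0) count once.  Three feature sets are kept separate and
never mix roots: *ground* (nucleotide roots over backbone + base-pair
edges), *abstract* (element roots over abstract adjacency edges), and
*hybrid* (the endpoints of each hyperedge relation: the element paired with
one of its member nucleotides, required to be in the viewpoint).  Hybrid
features are what make two identical subsequences distinguishable when one
sits in a hairpin loop and the other in an internal loop.

The canonical neighborhood label is a deterministic isomorphism invariant:
the sorted multiset of per-vertex signatures (distance from root, vertex
label, sorted multiset of incident edge descriptors restricted to the
induced subgraph, each carrying edge label, neighbor label, neighbor
distance and orientation).  Labels are hashed with a stable 64-bit hash
folded to 2^bits (default 20); collisions are accepted — the kernel is
approximate by design — and an exact mode keyed by the canonical strings
exists for verification, where the kernel is tested feature-for-feature
against brute-force isomorphism counting.

Vectors are normalized to unit Euclidean norm within each (set, r, d) block
and then globally, preventing large-radius blocks from dominating.  The
viewpoint restriction bounds the influence of any context position: in
sequence mode a nucleotide farther than R + D backbone steps from the
viewpoint cannot affect the vector at all.

## Learning

Classification minimizes λ-regularized hinge loss by Pegasos-style SGD:
learning rate 1/(λ(t + t₀)) with t₀ = 1/λ, seeded per-epoch shuffling,
unregularized bias, weight-scale trick for sparse updates.  Defaults
λ = 10⁻⁴, 10 epochs; training is deterministic under a fixed seed.
Regression is ε-insensitive linear SVR (scikit-learn's LinearSVR, tolerance
10⁻⁶); the contract is the convex optimum, not the solver.

Defaults R = 1, D = 4 (a joint reach of 5 backbone steps) suit motif
detection; ranking graded affinities benefits from larger neighborhoods
(R = 2, D = 6 in the regression experiments, fitted once with the
line-search utility).  Hyperparameters are fitted the way the benchmark
prescribes: round-robin line search, one parameter free at a time over its
grid, scored by cross-validation on a held-aside stratified tuning subset of
min(1000, 10% of n) examples that is then excluded from the performance
assessment.  Evaluation uses stratified tenfold cross-validation;
performance is AUROC (Mann–Whitney, ties half) and average precision (mean
precision at each positive's rank, stable ties); improvements are reported
as relative error reduction (x′ − x)/(1 − x).

## Profiles, site calls, motifs

The margin decomposes exactly over context positions: each feature
occurrence contributes its weight × normalized value, split half/half
between its two roots (fully to the root of a self-pair), a root's share
spread equally over an abstract element's member nucleotides, mirrored
vertices mapped back to their original position.  The positionwise sum
equals margin − bias to floating-point accuracy; this conservation is what
makes the profile an honest decomposition rather than a heuristic heat map.
Binding scores are averaged over sliding 12-mers; high-affinity calls take
the top 1% of windows across the whole collection (ties broken by sequence
id, then position) and merge overlapping or directly abutting selections,
scoring each merged site by its best member window.  Selection is global
across sequences by default (a per-sequence variant is available).

Motifs pool, per folding hypothesis of each bound site (soft cap 2000
sites), the highest-scoring k-mer inside the viewpoint together with its
structure-element string; the top 1000 give column-frequency matrices over
{A,C,G,U} and {S,E,H,I,M,B}.  Because the scoring window (default 12) is
longer than a typical motif, the window placement jitters over the
(k − motif length + 1) admissible offsets and per-column majorities dilute
accordingly; recovery checks therefore evaluate the matrix at the motif's
own length, where an implanted 8-mer shows a clear (> 0.5, typically ≈ 0.7)
aligned majority, and only an enrichment well above the 0.25 background at
k = 12.

## Synthetic data

The generator emulates the two training regimes.  *Classification*:
positives are uniform-background sequences (default 60 nt, 500 + 500) with
an implanted motif (default `ACGUACGU`) mutated per position at rate 0.1;
negatives are background.  In `hairpin_loop` context the motif is placed in
the loop of a designed 8-bp stem (stem bases uniform, so base composition
stays neutral), and negatives by default carry the same motif in an
unstructured context: the classes then differ by structural presentation
rather than motif presence, mirroring affinity-assay pools that present
k-mers in both structured and unstructured contexts.  A loop-presented
motif must not be self-complementary — a palindromic motif zips its own loop
shut — so hairpin experiments use the pyrimidine element `UCUUCUUC`,
reminiscent of natural loop-bound pyrimidine tracts.  *Affinity*: sequences
carry the motif with a graded mutation load (uniform over 0–2 of 8
positions) above a floor of background non-binders, and the true affinity is
the best sliding match to the clean motif plus Gaussian noise, sd 0.05
(≈ 10% of the affinity dynamic range, consistent with the high replicate
reproducibility of in vitro affinity assays; heavily damaged motifs fall to
the background floor as they do in a real pull-down).

What the generator does *not* emulate: cross-link-induced mutations and PCR
artifacts, expression-driven coverage bias, transcript-level context (sites
are independent short sequences), cooperative or combinatorial binding, and
protein-specific energetic fine structure.  Passing recovery tests therefore
demonstrates that the machinery detects and localizes the signals it is
pointed at under controlled conditions — not that any particular biological
RBP is modeled correctly.

## Experiment sizes and numerics

The packaged experiments run at desk scale: 500 + 500 sequences for
sequence-only recovery, 150 + 150 over 5 seeds for the structure contrast,
250 + 250 for the binary-to-affinity showcase, 500 + 500 with
tenfold-pooled predictions for regression.  Energy-band comparisons use a
10⁻⁹ slack; profile conservation is asserted to 10⁻⁹ absolute; model
save/load round-trips bit-identically (weights serialized as hex floats).
Ties are broken by stable order everywhere selection occurs.  Degenerate
inputs: unpairable or all-N windows yield a single all-external hypothesis;
empty viewpoints are rejected at construction; single-class training sets
and constant regression targets are errors.

## Known limitations

The hashed feature space admits collisions (exact mode exists for
verification but not for training at scale).  The built-in folder is a
maximum-scoring pairing model, not a thermodynamic one.  Negative sampling
assumes genes are long relative to sites; saturated genes drop negatives
with a warning.  The NSPD kernel's neighborhoods are bounded by R + D, so
dependencies longer than the joint reach (e.g. very long-range pairing
between distant viewpoint positions) enter only through the abstract layer.
Cooperative binding between neighboring sites is out of scope.
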