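# Methods

This note documents the models, parameter choices and numerical conventions
behind `its2morph`, and what the synthetic-data tests do and do not show.

## ITS2 extraction

The spacer is located by scanning for two degenerate flank motifs: the
conserved 3′ end of 5.8S (default `GCATCGATGAAGAACGCAGC`) and 5′ start of
28S (default `GCATATCAATAAGCGGAGGA`), both drawn from the conserved fungal
rDNA consensus. Matching uses the IUPAC alphabet with a mismatch budget
(default 2); the best hit is the one with fewest mismatches, ties broken
toward the leftmost 5.8S / rightmost 28S occurrence, and the ITS2 is the
span strictly between the motifs. This replaces profile-HMM annotation with
a transparent, testable scan; pre-extracted ITS2 input is accepted
unchanged. Before folding, up to 20 nt of each flanking gene is padded back
on (the proximal 5.8S/28S stem stabilizes the fold); padding never invents
bases beyond the source and truncation is logged. By default the pads are
folded but trimmed again before alignment (`keep_pads` retains them);
pairs crossing the pad boundary are dropped at trimming. Reported
coordinates are 1-based inclusive; internal arrays are 0-based.

## Folding model

Folding is a Zuker-style dynamic program over nested structures with a
deliberately simplified energy model (all values kcal/mol, handled
internally as integer tenths so optima are exact):

| term | form | default |
|---|---|---|
| stack of pairs p over q | −(s(p) + s(q)) | s(GC/CG) = 1.7, s(AU/UA) = 1.1, s(GU/UG) = 0.7 |
| hairpin loop, u unpaired | 3.0 + 0.3·u | min loop u ≥ 3 |
| interior/bulge, u unpaired | 2.0 + 0.3·u | u ≤ 30 (larger loops disallowed) |
| multiloop | 3.4 + 0.4·(branches+1) + 0.1·unpaired | |
| exterior bases | free | |

Allowed pairs are the canonical and wobble set {AU, UA, GC, CG, GU, UG};
pseudoknots, dangling ends and coaxial stacking are excluded. A
`pair-count` model (−1.0 per pair, loops free) is available for oracle
work. The model reproduces topology-level behaviour — which helices form,
how many radiate from the central loop — not absolute thermodynamic
energies; externally predicted Vienna-format structures can be injected to
bypass folding entirely, and every downstream stage consumes structures
through that same interface.

Suboptimal structures within 5% of the MFE (at most 50) are enumerated by a
best-first expansion of the DP cases. The case analysis is disjoint, so each
structure appears exactly once, in non-decreasing energy order; on small
sequences the enumeration is provably complete against brute force (tested).
Traceback ties are broken toward the pairing that starts 5′-most, then
toward extending the current helix, making folding fully deterministic.
The *selection rule* keeps the lowest-energy candidate whose annotated
topology has 3–4 principal helices; if none qualifies the MFE structure is
returned flagged `non-canonical topology` (flags propagate, they never
abort the pipeline).

## Helix annotation and topology classes

The central loop is the exterior loop of the structure. An arm is walked
from its outermost pair while each pair has exactly one nested child;
interior loops and bulges do not end a helix, hairpin loops and multiloops
do. An arm whose stem has ≤ 3 total pairs and ends in a multiloop is an
*extended subdomain*: its branches join the radiating-helix list (the 3-pair
threshold is a configurable operationalization; sensitivity to it is why it
is exposed). Principal helices are labelled I, II, III… in 5′→3′ order,
including in subdomain-first topologies, where the labelling is positional
by design. A small helix (2–3 pairs, apical loop) with at least two
principal helices before it and one after is labelled IIa and excluded from
the principal count. The five topology classes: (1) three central helices;
(2) helix I central, II–III on a subdomain; (3) as 2 plus IIa; (4) four
central helices; (5) I–II on a subdomain, III–IV central; anything else is
type 0 (unclassified, flagged). Helix III is taken positionally (third
principal helix); if a different helix is longer a warning is logged. The
basal motif scan searches the first 6 nt of helix III's 5′ strand for UGGC,
then the CGGC variant.

Consensus structures vote per column (majority residue among non-gap rows;
conserved flag above 0.51) and per column *pair* (kept when maintained by
more than half of all records), so a helix paired in a minority of records
drops out of the consensus. Crossing pairs from mixed votes are resolved
greedily 5′-first; ties in the residue vote go to the alphabetically first
base.

## Sequence–structure alignment

Each folded position maps bijectively to one of 12 letters
({A,C,G,U} × {unpaired, open, close}). The default scoring is +3 when
residue and state both match, +1 state-only, −1 residue-only, −2 neither;
gaps cost `gap_open + L·gap_extend` with −5/−1. The matrix is a loadable
TSV so a published ITS2-specific matrix can be dropped in; the default
encodes the structure-over-sequence ordering the method assumes. Pairwise
alignment is Gotoh's affine-gap global DP (tie-break: match/mismatch over
gap, then gap in the first sequence); multiple alignment is progressive —
UPGMA guide tree on score-derived distances d(i,j) = (s_ii + s_jj)/2 − s_ij,
then profile–profile alignment with expected-score columns. Gaps never
encode structure; each record's pairing map is lifted to alignment columns
on demand.

## CBC counting and delimitation

For records x and y, only column pairs (i, j) paired in *both* records are
examined. A CBC requires both residues to differ and both pairs to be valid
(canonical or wobble — G·U counts as maintained on either side); a hemi-CBC
is exactly one differing side with both pairs valid. Columns where the two
records disagree on pairedness are a structural, not substitutional,
difference and contribute to neither count; non-canonical "pairs" never
contribute. Transitions are A↔G and C↔U; INDEL events are maximal runs of
gap-vs-residue columns (columns gapped in both records are dropped first,
and a run switching sides counts as two events).

Delimitation takes the premise that any CBC separates species. The minimal
species count is the chromatic number of the graph with an edge wherever
cbc ≥ 1 — exact by iterative-deepening backtracking up to 16 records,
greedy largest-first (flagged inexact) beyond. Hemi-CBCs are never used for
delimitation. *Absolute identity* is strict by default (identical encoded
strings: gap-free alignment, zero substitutions, identical pairing); a
structure-only mode compares pairing states alone for sensitivity analysis.
Queries identical to a reference (and CBC-free against it) take its name;
identity alongside a CBC raises an inconsistency error, as it signals an
upstream alignment fault. Remaining queries are grouped per genus into
zero-CBC blocks labelled `<Genus> sp. type-NN`, numbered by input order;
genus labels are an explicit input (in practice they come from a
sequence-level phylogeny against curated references, outside this package's
scope). A query with CBCs against every reference and congener is flagged a
putative new species.

## Distances, NJ and bootstrap

The p-distance is the mismatch fraction over co-ungapped columns of the
12-letter encoding; the `poisson-12` correction is
d = −(11/12)·ln(1 − (12/11)·p), capped (default 5.0) and flagged at
saturation. A GTR-style model on the encoded alphabet is not re-derivable
from public sources, so the Poisson-corrected distance stands in as a
closed-form, structure-aware substitute and is labelled as such. NJ is the
canonical Saitou–Nei algorithm; Q-ties break toward the lexicographically
smallest joined pair (clusters compared by smallest leaf name), and negative
branch lengths are clamped to zero with the deficit moved to the sister
branch. Bootstrap pseudo-replicates resample alignment columns with
replacement; supports (0–100) are the percentage of replicates containing
each bipartition, reported on the internal edges of the full-data tree,
with a >50% majority-rule consensus (topology and supports only) as an
alternate output. All resampling is driven by one integer seed.

## Diversity indices

CF = 100·isolates/segments and EIR = 100·infected segments/segments, both
reported to one decimal; RPO = 100·group density/total density. Shannon H′
uses natural logs. Inverse Simpson defaults to the unbiased finite-sample
D = Σ nᵢ(nᵢ−1)/(N(N−1)) (plug-in Σpᵢ² by flag); note the unbiased form can
slightly exceed S_obs in small samples — only the plug-in form is bounded by
S_obs. Fisher's α solves S = α·ln(1 + N/α) by bracketed root-finding
(Brent, xtol 1e-8); α diverges at S = N, which is rejected. Chao1 uses the
bias-corrected form S_obs + F₁(F₁−1)/(2(F₂+1)) by default (classic form by
flag); ACE uses rare-species cutoff 10 and falls back to Chao1 when the
rare-class coverage is zero. Shared-species indices: classic Jaccard
C/(S₁+S₂−C); Bray–Curtis similarity 2·Σmin(nᵢ,mᵢ)/(N₁+N₂); the Chao-shared
estimator adds the three unseen-shared correction terms with bias-corrected
denominators, D₁₂ + f₊₁(f₊₁−1)/(2(f₊₂+1)) + f₁₊(f₁₊−1)/(2(f₂₊+1)) +
f₁₁(f₁₁−1)/(4(f₂₂+1)); the abundance-based Chao–Jaccard uses the U/V
coverage estimators with the (m−1)/m · f₊₁/(2f₊₂) unseen-fraction terms,
U and V capped at 1. Accumulation curves are sample-order randomizations
(mean and SD over permutations, seeded).

One bundled-survey note: the printed infection rate for the third host
plant (63.3%) conflicts with its own effort table, whose infected-segment
sum gives 199/300 = 66.3%. The package always computes from the inputs, so
it reports 66.3 for those counts; the test suite documents the discrepancy
rather than reproducing the printed value.

## Synthetic data

The sequence generator emulates fungal ITS2: records of 145–181 nt folding
into a central loop with 3–4 helices, helix III longest with a UGGC motif
planted at its base, and 20-nt conserved 5.8S/28S proxy flanks. Stems are
random Watson–Crick duplexes; loops and spacers are A/C-biased so they
cannot nucleate stems competing with the planted helices on re-folding —
real spacer loops are not so constrained, which is one of the ways
generated data is cleaner than real data. Species are separated by planting
full compensatory changes (G–C↔A–U, C–G↔U–A) at dedicated stem positions
≥ 2 bp from helix ends (so re-prediction stays consistent), one disjoint
position set per species: every between-species pair then carries the
planted CBCs exactly, and conspecifics none — the delimitation premise is
built in, not discovered. Hemi-CBCs (to wobble pairs), unpaired
substitutions and single-base indels in unpaired regions add within-species
noise. Because positions are globally disjoint, the planted CBC/hemi counts
are exact pairwise ground truth when indels are off (alignment is trivial);
with indels the truth holds provided the aligner recovers homology.
Passing tests on this generator therefore show the machinery is correct
under the model's assumptions; they do not show robustness to homoplasy,
alignment ambiguity in highly divergent spacers, or non-canonical real
structures.

The community generator screens hosts × two sampling events × two leaf
regions (midrib/lamina), infects each segment as a Bernoulli draw (default
segments 300 per host, matching common survey effort), occasionally yields
a second isolate per segment, and draws species abundances from the
log-series (the distribution whose natural parameter is Fisher's α, which
is also why that abundance model was chosen), with identities from a global
pool so hosts share species. Parameter recovery (α within 15% on average at
survey-scale N) is part of the test suite.

## Problem sizes and numerics

Test and acceptance runs use: exhaustive folding oracles at sequence length
≤ 14 (1,000 cases); CBC brute-force scans at ≤ 6 records × 40 columns; NJ
recovery on 200 random additive 6-taxon trees; 100 seeded end-to-end
delimitation runs at 3–6 species × 2 records (using generator truth
structures through the external-structures path, the same interface real
external predictions use); bootstrap checks at 200 replicates; estimator
bounds on 1,000 random communities — sizes chosen so the whole suite stays
interactive while every code path is exercised. Energies compare exactly in
integer tenths; alignment score comparisons use 1e-9 epsilons; DP kernels
are numba-compiled with a pure-Python fallback.

## Known limitations

* The folding energies are model energies, not calibrated free energies;
  agreement with thermodynamic folders is at the topology level only.
* The scoring matrix and distance model are defensible defaults, not the
  (unpublished) ITS2-specific matrices some reference tools ship.
* Greedy coloring beyond 16 records upper-bounds the minimal species count.
* Maximum-likelihood and Bayesian phylogenies are out of scope; NJ with
  bootstrap covers the delimitation-supporting tree.
* The consensus pairing vote can drop sparsely maintained helices entirely
  rather than representing them partially.
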