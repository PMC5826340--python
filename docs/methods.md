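# Methods

This note documents the models, conventions and numerical choices behind
`finrep`, and what the synthetic-data tests do and do not demonstrate about
real sequencing data.

## Coordinates and anchors

All coordinates are 0-based, half-open; only human-readable reports convert
to 1-based. The CDR-H3 of a read is the region strictly between the V
segment's second conserved cysteine codon (the last in-frame TGT/TGC of the
V reference) and the J segment's conserved tryptophan codon (the first
in-frame TGG opening a W-G-x-G motif). Both anchor residues are excluded by
default; `include_anchors=True` yields the IMGT-style junction including
the C and W. Anchors are computed from sequence by these motif rules — so
the toolkit needs no curated database — with an override hook
(`GeneSegment.anchor_offset`) for explicitly annotated references. The
reading frame defaults to 0 per segment and is configurable; N bases never
satisfy a codon test (conservative anchor calling).

## Pre-processing

- **Isotype demultiplexing** searches the 5′ end of the merged read for
  each isotype's primer, allowing partial-primer overlaps of ≥ 10 aligned
  bases and at most ⌊0.2 × matched length⌋ mismatches (the defaults match
  the common adapter-trimming convention `-O 10 -e 0.2`). The best
  placement per isotype minimises errors, ties to the leftmost position;
  an exact tie between isotypes is recorded as ambiguous/unassigned and
  excluded downstream.
- **Quality trimming** removes bases below Q20 from both ends inward and
  discards reads shorter than 30 nt afterwards (LEADING/TRAILING/MINLEN
  semantics). Discard is a counted outcome, not an error.
- **Pair merging** reverse-complements mate 2, scores every ungapped
  overlap ≥ 10 nt by matches − mismatches, and accepts the best overlap
  only if its match count is significant at p = 0.05 under a binomial null
  of 50% per-base identity. The 50% null is deliberate: under a
  uniform-random null (p = 1/4) an overlap with half its bases mismatched
  would still test as "significantly non-random", which is not a usable
  acceptance rule for assembly; requiring identity significantly above one
  half accepts all genuine overlaps and rejects half-corrupted ones.
  Assemblies shorter than 300 nt are rejected (a minimum-length filter, as
  in the assembler whose parameters these mirror). Disagreeing overlap
  bases resolve to the higher-quality base, ties to mate 1 (determinism).
  Every input pair ends in exactly one disposition — discarded, unmerged,
  merged-unassigned, or merged-and-isotyped — and the counts report is
  asserted to partition the input.

## Segment assignment

Each read is aligned locally against **every** candidate germline segment
(no heuristic seeding can change the winner). Scoring defaults: match +2,
mismatch −3, gap open −5, gap extend −2 (first gapped base costs −5, each
additional −2), minimum accepted score 50 — i.e. a 25-nt exact match
passes. Ties are broken by higher identity, then longer aligned span, then
lexicographically smallest segment id, so assignment is a pure function of
the read. Reads are tested in forward orientation (amplicon designs fix
orientation); a reverse-complement rescue can be layered on by the caller.

Two alignment engines back the same scoring scheme: a numba-compiled
affine-gap Smith–Waterman computes score-only rankings of all candidates
(exhaustive scoring at interactive speed), and `Bio.Align.PairwiseAligner`
produces the traceback for the top-scoring candidate(s). The test suite
asserts exact score equality between the two engines on random inputs, and
against an independent full-matrix DP oracle.

**D identification** uses exact substring seeds, not gapped alignment: the
winning D must share ≥ 4 contiguous nt with the CDR-H3 and be strictly
longer than every other candidate's best match, otherwise the call is
ambiguous. This mirrors how heavily trimmed D remnants behave in practice:
a remnant below 4 nt is not identifiable, and chance matches between
non-template insertions and D segments are mostly resolved as ties →
ambiguous. Forward strand only by default.

**Junction profiling** (in the Decombinator tradition) reads deletions off
the alignment spans — `v3_del` = germline V length − V germline-span end,
`j5_del` = J germline-span start — and insertions as the read bases between
consecutive spans: V→D and D→J when D is identified, or a single V→J
insert (non-template bases plus the unidentifiable D remnant) when it is
not. A negative computed insert (overlapping alignments) is clipped to 0
and the record flagged.

**Productivity**: a CDR-H3 is productive when its length is divisible by 3
and its translation contains no stop (and no X from ambiguous bases).
Non-productive records are excluded from amino-acid-level statistics but
retained in V/J usage and combination counts.

## The simulator and what "ground truth" means

`make_germline` builds random segment sets with planted anchors: V
segments (default 291 nt, length a multiple of 3) carry their 2nd-CYS
codon 6 nt before the 3′ end with no in-frame cysteine after it; J
segments (48 nt) carry WGxG starting at offset 6 with none earlier; D
segments are 12–18 nt. Any segment ≥ 90% identical to an existing one is
resampled, so self-alignment is unambiguous. Defaults mirror the torafugu
IgM locus scale (32 V across 3 families × 6 D × 5 J = 960 combinations);
the IgT D/J counts are parameters (defaults 3 and 2), since only the IgM
locus composition is firmly established.

`simulate_repertoire` draws V/D/J by per-class geometric usage weights
(decay 0.85/0.7/0.5 — strongly non-uniform, like real repertoires where a
handful of segments dominate), trims each segment end by a geometric
number of bases (mean 1, so > 80% of junction sides lose 0–2 nt), inserts
Poisson(6) uniform-composition non-template bases at each junction, affixes
the isotype primer and a constant-region stub, optionally applies per-base
substitution errors, and splits the amplicon into overlapping mates
(constant Q37 or a decaying profile). Under this geometry CDR-H3 lengths
are bell-shaped over roughly 8–16 aa — the shape expected of a naïve
repertoire — but all distributions are parameters, not claims; real indel
histograms are only known empirically. Deletions that would exceed the
available bases (or cut into an anchor codon) are resampled, never emitted.

**Junction identifiability.** Junction decompositions are not unique: an
inserted base equal to the adjacent germline base cannot be distinguished
from germline, and inserted bases can counterfeit a short D remnant. No
analysis can recover generative labels on such reads. By default the
simulator therefore rejects-and-resamples junctions whose canonical
re-analysis (alignment spans of the true V and J, exact-substring D
identification) disagrees with the generative truth
(`require_unambiguous_junctions=True`). This is a ground-truthing device:
it guarantees that on noise-free data the pipeline can be held to 100%
exact recovery of every truth field, at the cost of a slightly filtered
junction ensemble. Distribution-level tests (insertion-size calibration,
usage goodness of fit) disable the filter and sample the generative
distributions untouched. Consequently, passing round-trip tests
demonstrates correctness of the bookkeeping and algorithms — not that real
junctions are unambiguous (they are not), and not that real error modes
(PCR bias, chimerism, hypermutation lineages) are handled; those are out
of scope.

## Statistics conventions

- Assignment rates: VJ rate = identifiable-VJ / total isotype reads; VDJ
  rate = identifiable-VDJ / identifiable-VJ. Reported values are
  **truncated** (floored) to 3 decimals — the convention of the reference
  summary tables, verified against all twelve printed cells — via exact
  integer arithmetic, with raw floats kept alongside. The
  convergent-recombination ratio (multi-coded aa / unique aa) is truncated
  the same way.
- Cross-individual count averages round half up to the nearest integer.
- D usage frequencies are normalised over D-identified reads only
  (switchable by filtering the input frame); ambiguous-D reads form their
  own stratum in combination tables and are excluded from both the
  coverage numerator and the theoretical denominator.
- Rarefaction subsamples reads **without replacement** (classic
  rarefaction), 1,000 resamples per depth by default, deterministic under
  a fixed seed; the full-depth value equals the observed distinct count
  exactly, and the depth-k mean is validated against the hypergeometric
  closed form E[distinct] = Σᵢ (1 − C(N−nᵢ, k)/C(N, k)).

## Clustering

Greedy incremental clustering at ≥ 80% identity and ≥ 80% length coverage.
Identity is the maximal number of identically aligned residues between the
pair — computed as a global alignment with free gaps, whose score equals
the longest-common-subsequence length — divided by the shorter sequence's
length (the CD-HIT denominator; an "alignment-columns" mode divides by
len(a) + len(b) − matches instead, the minimal alignment length achieving
the maximal match count, counting gap columns as mismatches). X never
matches, including X–X.

Input order independence is imposed by sorting: length descending, then
total abundance descending, then lexicographic; each sequence joins the
first existing cluster whose representative (the founder, necessarily the
longest member under this order) passes both thresholds. A
residue-composition screen (per-letter minimum counts bound the achievable
match count from above) skips hopeless pairs; because the bound is sound,
the screen provably cannot change the result, which the suite also asserts
empirically — a deliberate substitution for word-based prefilters, whose
bounds do not hold for non-contiguous matches.

## Diversity estimation

ACE with rare/abundant cutoff 10 (the standard Chao–Lee choice;
configurable). Edge cases: no rare clusters → S_ACE = S_obs exactly
(analytic limit); rare group all singletons, or fewer than 2 rare reads →
coverage is 0 and the variance term undefined, so the bias-corrected Chao1
estimator S_obs + F1(F1−1)/(2(F2+1)) is substituted and flagged. When more
than half of all observed clusters are singletons a warning notes the
estimate may be inflated — reported, never silently corrected. The
implementation is cross-checked against an independent reference
implementation (vegan's `estimateR`) and recovers known richness within
±15% on ≥ 80% of 100 simulated geometric-abundance pools sampled at
50–90% — an empirical property of that scenario, not a theorem.

Private (one individual) versus common (≥ 2) clusters are compared by
two-sided Mann–Whitney rank-sum tests on abundance, mean length and
V-mutation load at α = 0.05 — this package's choice of test, labelled as
such, since the comparison is descriptive.

## Problem sizes

The acceptance checks use a 10,000-read noise-free round trip (32×6×5 IgM
plus 32×3×2 IgT germlines, 60% IgM), a 200-sequence clustering oracle, 100
ACE recovery pools of 400 species, and 1,000-resample rarefaction — sizes
chosen so the full suite completes in minutes on a single CPU while every
per-read assertion is still exact, not sampled.

## Known limitations

- Somatic hypermutation lineages, clonal expansion dynamics, PCR
  amplification bias and UMI handling are not modelled.
- The exact alignment parameterisation of the original BLAST-based
  analysis is not public; the documented scoring scheme above is this
  package's conservative, overridable replacement.
- Junction truth is only exactly recoverable under the simulator's
  unambiguity filter (above); on real data a fraction of junction
  decompositions is inherently ambiguous.
- D search is forward-strand, exact-substring only; gapped or
  reverse-strand D matching is out of scope.
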