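# Methods

## The model system

The reference is a pair of circular replicons: a chromosome (default
200 kb) and an F'-like episome (default 100 kb) that carries a 40 kb
block of chromosomal sequence copied verbatim (the "shared block"),
with a 3 kb selectable marker locus (the *lac* analogue) inside the
block's episomal image. These are desk-scale stand-ins for the real
4.6 Mb chromosome + ~100 kb episome: every size is configurable, and
the default scale lets the whole pipeline run in seconds while keeping
all coordinate arithmetic, probe geometry and event sizes realistic.
Base composition is i.i.d. uniform outside planted repeats.
Coordinates are 0-based half-open everywhere internally (BED-native);
replicons are circular, and probe adjacency and called runs may wrap
the origin join.

**REP cassettes.** Junction hotspots in this system are attributed to
the structure-forming potential of REP elements, not their exact
sequence, so REP is modeled as planted 38-nt pseudopalindromes (stem
12–16 nt, loop 4–8 nt, up to 2 stem mismatches) in clusters of 2–4,
~10 clusters per chromosome and ~8 per episome. Cassettes planted
inside the shared block are inherited by the episome with the block,
preserving the string-identity invariant.

**Probe array.** One probe per 100 nt on both replicons (a 4.4 Mb
genome at this spacing is a 44K array; the desk-scale default tiles
2,900 probes). Probes inside masked intervals — the repeat/prophage
analogue, default 10 kb on the chromosome — are removed, and probes
flanking a mask are *not* adjacent for calling purposes.

**Cross-hybridization is not modeled.** Each replicon's probes read
that replicon's copy number only; the ~2× signal that episome-borne
sequence shows against a single-copy reference in the real two-color
assay (and dye bias, GC effects, feature extraction) is out of scope.

## Rearrangement representation and builders

Every structure is an ordered list of oriented reference intervals
(`SegmentPlan`); realization concatenates oriented substrings, and the
copy-number profile counts segment coverage per base (conserved:
Σ profile = Σ segment lengths). The builders construct each observed
class from explicit template switches; they differ only in switch
position and orientation:

* **Amplification**: tandem head-to-tail array over an interval
  containing the marker; one novel junction (end→start).
* **Embedded inverted duplication (EID)**: unit
  [flank+inner(+), inner(−), flank2(+)] — the inner region (which must
  contain the marker) is present twice per unit, once inverted; a
  `triplication` option produces the pre-crossing-over layout with the
  inner region three times per unit. Two template-switch junctions
  carry designed microhomology; with ≥2 copies the tandem unit
  boundary adds the ordinary amplification junction.
* **Partially inverted amplification (PIA)**: unit [left(+), right(−)];
  on the reference map two gained blocks flank an unchanged gap, and
  the inversion's right end coincides with the amplification junction,
  so there are exactly two junction types at any copy number.
* **Embedded deletion**: alternating full and internally deleted units;
  the deleted interval sits at half the amplicon copy number; both
  junctions direct-orientation.
* **Inversion with micro-indels**: the inverted segment's endpoints are
  displaced by signed offsets (|offset| ≤ 100 nt, "a few tens of
  bp"): positive = micro-duplication, negative = micro-deletion;
  realized length changes by exactly the offset sum.
* **Unlinked deletion**: simple loss with one junction.

`compose` applies independent events to one replicon; events must be
≥ 300 nt apart so junction neighbourhoods stay independent.

**Designed microhomology.** Junction microhomology is *constructed*,
not found. For each junction the builder copies the donor-side flank
bases into the acceptor side's parental positions (creating a shared
tract of exactly the designed length) and pins both ends of the tract
with a mismatch, so the measured breakpoint ambiguity equals the design
exactly. All edits go into the isolate's own copy of the reference (its
parental genome); the aCGH reference stays unedited, and copy-number
analysis is unaffected by point edits. A constraint ledger inside the
planting engine records every equality/inequality it establishes, so
junctions designed near one another cannot silently corrupt each other;
each builder verifies measured == designed before returning.

Two geometric choices make the construction well-defined:

* **Stagger at folds.** In an EID the inner(−) copy stops 70–90 nt
  short of the fold point. At an exact foldback the homology tract
  would be forced palindromic and extend symmetrically on both sides,
  making "designed k" unattainable for odd k and ambiguous in general.
  The stagger is below probe spacing, so classification is unaffected.
* **Blunt inversion junctions.** The inversion builder plants
  mismatch-pinned (microhomology-0) junctions. Endpoint offsets are
  then recoverable exactly from sequence: the longest common
  prefix/suffix of the realized molecule against the reference locate
  both breakpoints, and the inverted block is anchored by exhaustive
  shift search over ±100 nt.

**REP snapping.** The cohort simulator places the amplification
junction's donor coordinate inside a REP cassette with probability 0.24
(configurable), reproducing the observed REP junction enrichment as a
recoverable simulation parameter. Snapping is done where coordinates
are drawn (the pipeline), keeping builders deterministic functions of
their interval arguments.

## Calling and classification

The caller is the study's rule, implemented literally and nothing more:
maximal runs of **two or more adjacent probes** at |log2 ratio| ≥ 1
(2-fold, boundary-inclusive) are called; boundaries are the outermost
qualifying probes extended half a spacing; `est_copy = 2^mean_log2`
relative to reference copy 1. No CBS/HMM smoothing. Zero-copy probes
use a 0.01 pseudo-count floor (flagged) so deletions give a deep finite
ratio.

Classification of an isolate's call set (linear copy units):

* **AMP** — gain overlapping the marker locus;
* **EID** — AMP whose interior contains a sub-segment ≥ 1.4× the
  flanking amplicon copy;
* **EMBEDDED_DEL** — interior sub-segment ≤ 0.6×;
* **SPLIT_AMPLICON** — two gains separated by a normal gap with
  est_copy agreeing within 25% (candidate inversion, flagged for PCR
  confirmation);
* **SECONDARY_DEL** — a loss neither overlapping nor within one probe
  spacing of any AMP call;
* **UNCLASSIFIED** otherwise, with a reason.

The flanking amplicon level is the median of the probes near the call
edges (outer ~10%, at least 2 each side), robust to large embedded
regions. Interior sub-segments must span ≥ 3 probes: true embedded
regions span tens of probes, while at σ = 0.2 pairs of adjacent noise
outliers inside a ~220-probe amplicon call are common enough to produce
a few percent false embedded calls per cohort if pairs were accepted.
When both elevated and depressed interior runs appear, the longer one
wins.

## Junction analysis

Microhomology follows the standard structural-variant convention:
the maximal shared tract that makes the breakpoint placement ambiguous
(the junction can be written at mh+1 positions), leftmost placement
reported. A single affine accessor maps realized-molecule offsets to
reference positions for any strand combination, so measurement,
planting and the brute-force test oracle all speak the same geometry.

REP overlap is true iff either parental breakpoint base falls inside a
REP interval (half-open). In-silico PCR uses exact-match primer
binding on both strands (≥ 15 nt); a product forms for every convergent
site pair within the size cap. The unidirectional inversion screen
tiles same-orientation 20-mers every 2 kb across ±25 kb around the
marker: on an uninverted molecule all sites face the same way and no
product can form; an inversion flips interior sites and creates
convergent pairs. For amplified isolates the screen molecule is
realized with tandem copy numbers capped at 2 — inversion geometry is
copy-number independent, and capping keeps the molecule small.

**Detection asymmetry.** Most inversions are invisible to aCGH; the
screen sees only inversions that contain a panel primer site, within
the ±25 kb window. Isolates whose amplification itself contains
inverted structure (EID, split amplicon) trip the screen too, and
without junction sequencing an additional independent inversion there
cannot be separated; the cohort report attributes such signal to the
amplification event (a conservative undercount). This mirrors the
assay's real logic and limits.

## Secondary structure

Hairpins are enumerated as inverted repeats (exact or near-exact
complementarity, default stem ≥ 6, loop 3–50, ≤ 1 mismatch, trailing
mismatches trimmed) rather than by thermodynamic folding: the claims
being tested are positional — does the junction's microhomology
footprint lie on a stem, in a loop, on both, or in unstructured
sequence — not energetic. Defaults always find the planted REP
cassettes (stem 12–16); note that at these permissive settings random
DNA is rarely fully structure-free, so "unstructured" junctions are
uncommon under the defaults; the classification is parameterized and
the planted-structure tests use a stricter bar (stem ≥ 10, exact).
This enumeration is a declared replacement for interactive
structure-drawing software, not claimed equivalent to it.

## Statistics

Fisher's exact test (hypergeometric; the two-sided p sums all tables
with point probability ≤ observed — the minimum-likelihood rule) is
delegated to scipy behind the module surface and is cross-checked in
the test suite against a full-enumeration oracle in exact rational
arithmetic over every table with N ≤ 30. The Peto one-step odds ratio
is implemented here: O = a, E = n₁m₁/N, V = n₁n₂m₁m₂/(N²(N−1)),
OR = exp((O−E)/V), CI = exp((O−E)/V ± z/√V). Tables with m₁ = 0 or
m₁ = N carry no information and are flagged undefined rather than
given a value. Display rounding is half-up at the reported precision;
internal values are full precision. The isolate, not the event, is the
counting unit in cohort comparisons.

## Cohort simulation: study conditions

Defaults are the modeled experiment's own census: 300 amplified
isolates (every one carrying a marker-covering amplification) vs 240
stressed controls carrying none. Amplified-arm mixture: embedded
inverted duplication 16/300, partially inverted amplification 2/300,
embedded deletion 1/300; independent secondary deletion 4/300 and
secondary inversion 2/300 (at most one secondary event per isolate —
no isolate with two is on record, and a flag exposes the choice).
Copy number is lognormal with mean 69.3 and SD 22.9 (clipped to
[5, 250]); amplicon length lognormal with mean 22.7 kb (SD 8 kb, a
package choice — only the mean is reported); embedded duplications
5.2–42.6 kb and always containing the marker; deletions 0.2–7.5 kb
with 1–4 bp junction microhomology, half chromosomal and half
episomal; inversion endpoints offset by up to ±40 nt; complex-event
junction microhomology uniform on 3–30 bp; probe noise σ = 0.2
(chosen so that a 2-fold call threshold sits 5 SD from the null —
detection is essentially perfect, as in the real assay where every
amplification was found). The master seed fans out to per-isolate
generators by a counter scheme, so any isolate is reproducible alone.

**What the generator does not emulate:** real genome sequence and its
repeat landscape, array physics (dye bias, saturation,
cross-hybridization), the stochastic dynamics of expansion under
selection, multi-event interactions within one isolate, and junctions
unresolvable by PCR. Passing tests therefore demonstrate that the
analysis logic is correct on data matching its stated model, not that
the model captures every property of real arrays.

## Calibration (bias and CI coverage)

The repeated-cohort calibration runs 200 seeded cohorts at σ = 0.2
with secondary-deletion probability 0.02 in the amplified arm. A
control arm with zero event probability would make the generating odds
ratio infinite and CI coverage meaningless, so controls carry
secondary deletions at the rate that fixes the generating odds ratio
at 6.2 — the secondary-comparison estimate itself (p₂ ≈ 0.0033).
Secondary events in the calibration are deletions only: inversions are
PCR-only detectable by design, and folding a known detection gap into
a check of estimator unbiasedness would conflate the two. Cohorts with
zero events in both arms are flagged undefined and excluded from the
coverage denominator. Expected behavior (verified analytically with
direct binomial draws before wiring the pipeline): |bias| on the order
of 10⁻⁴ and coverage ≈ 0.96.

## Numerical choices and degenerate inputs

* Threshold "2-fold or more" is inclusive: log2 ratio exactly ±1
  qualifies (tested at the boundary).
* Call boundaries extend half a spacing beyond the outermost
  qualifying probe; boundary error on noise-free data is at most one
  spacing by construction.
* Ties in breakpoint placement are resolved leftmost (standard
  left-alignment).
* A zero-length embedded deletion degenerates to plain amplification;
  a plan without an inversion yields "not applicable" (None) from
  micro-indel recovery; an empty probe table yields an empty call set.
* Planting failures (a junction whose constraints cannot be satisfied,
  e.g. at degenerate geometry) raise rather than silently mis-plant.

## Known limitations

* Isolate-level sequence artifacts (junction-planting edits) mean the
  shared-block identity invariant holds for freshly built references,
  not for isolate-derived copies.
* The inversion screen's sensitivity depends on panel geometry;
  inversions outside the ±25 kb window or shorter than the primer
  spacing can be missed, and inversions co-occurring with EID/split
  amplicons are attributed to the amplification.
* Hairpin calls at the permissive defaults are dense on random DNA;
  stem/loop class frequencies are parameter-dependent and are not
  meaningful as absolute counts.
* The wrap-around (origin-crossing) call path supports interior
  sub-segment analysis only in reference order; simulated events are
  placed away from the origin.
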