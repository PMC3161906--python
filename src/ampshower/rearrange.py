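"""Rearranged replicons as oriented segment lists, and the builders for
every structure class seen in stress-induced amplification cohorts.

All structures are expressed through one representation, a
:class:`SegmentPlan`: an ordered list of oriented reference intervals.
The same repeated-template-switch construction generates every class —
the builders differ only in where the switches land and in what
orientation — followed by unequal crossing-over (NAHR) modeled as direct
repetition of the amplicon unit:

* tandem amplification covering the selectable marker,
* embedded inverted duplication (inner region twice per unit, once
  inverted; optionally an inverted triplication),
* partially inverted amplification (two gained blocks separated by an
  unchanged gap; the amplicon is contiguous once the inversion is
  mapped),
* amplicon with an embedded deletion (deleted region at half copy),
* inversion with micro-indels at its near-reciprocal endpoints,
* simple deletion unlinked to any amplification.

Junction microhomology is *constructed*, not found: each builder plants
the designed homology tract by point-editing the isolate's parental
genome next to the junction, and pins both ends of the tract with a
mismatch so the measured microhomology equals the designed length
exactly.  The inverted segment of fold-type junctions is staggered a few
tens of bases from the fold so no junction is an exact palindrome
(planting at a perfect foldback is degenerate: the tract would be forced
to extend symmetrically on both sides).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._junction import Side, acceptor_side, donor_side, measure_mh, side_value
from ._seq import comp_base, revcomp
from .synthetic_genome import EPISOME, ReferenceModel

Segment = tuple[int, int, str]
Interval = tuple[int, int]

#: minimum reference gap between composed events (keeps each event's
#: junction edit windows isolated from its neighbours')
MIN_EVENT_GAP = 300


class PlanError(ValueError):
    """Invalid segment plan or builder arguments."""


class PlantError(RuntimeError):
    """Junction microhomology could not be planted without conflicts."""


@dataclass(frozen=True)
class DesignedJunction:
    """A junction type created by a builder, with its designed homology."""

    donor: Side
    acceptor: Side
    mh_len: int
    label: str


@dataclass
class Event:
    """One rearrangement event: a reference span replaced by a unit."""

    label: str
    span: Interval
    unit: list[Segment]
    junctions: list[DesignedJunction]
    params: dict = field(default_factory=dict)


@dataclass
class SegmentPlan:
    """An ordered list of oriented reference intervals on one replicon."""

    replicon_id: str
    length: int
    segments: list[Segment]
    events: list[Event] = field(default_factory=list)

    def validate(self) -> None:
        for a, b, s in self.segments:
            if not (0 <= a < b <= self.length):
                raise PlanError(f"segment ({a},{b},{s}) out of bounds [0,{self.length})")
            if s not in "+-":
                raise PlanError(f"bad strand {s!r}")

    def total_length(self) -> int:
        return sum(b - a for a, b, _ in self.segments)

    def designed_junctions(self) -> dict[tuple[Side, Side], DesignedJunction]:
        return {(j.donor, j.acceptor): j for ev in self.events for j in ev.junctions}


@dataclass
class JunctionSpec:
    """One realized junction between adjacent plan segments."""

    left_segment_index: int
    right_segment_index: int
    donor: Side
    acceptor: Side
    mh_len: int           # designed if known, else measured
    measured_mh: int
    mh_seq: str
    junction_seq: str     # +/- 50 nt realized context
    label: str = ""


def identity_plan(ref: ReferenceModel, replicon: str) -> SegmentPlan:
    L = ref.length(replicon)
    return SegmentPlan(replicon, L, [(0, L, "+")])


def assemble(replicon: str, length: int, events: list[Event]) -> SegmentPlan:
    """Lay out events along the reference with identity segments between."""
    events = sorted(events, key=lambda e: e.span[0])
    segments: list[Segment] = []
    cursor = 0
    for ev in events:
        s, e = ev.span
        if not (0 <= s < e <= length):
            raise PlanError(f"event span {ev.span} out of bounds")
        if s < cursor:
            raise PlanError("overlapping event spans")
        if s > cursor:
            segments.append((cursor, s, "+"))
        segments.extend(ev.unit)
        cursor = e
    if cursor < length:
        segments.append((cursor, length, "+"))
    plan = SegmentPlan(replicon, length, segments, events)
    plan.validate()
    return plan


# ---------------------------------------------------------------------------
# Realization and copy-number profiles


def realize_sequence(plan: SegmentPlan, ref: ReferenceModel) -> str:
    """Concatenate oriented reference substrings ('-' = reverse complement)."""
    plan.validate()
    seq = ref.seqs[plan.replicon_id]
    if plan.length != len(seq):
        raise PlanError("plan length does not match reference replicon")
    parts = []
    for a, b, s in plan.segments:
        chunk = bytes(seq[a:b])
        parts.append(chunk if s == "+" else revcomp(chunk))
    return b"".join(parts).decode()


def copy_number_profile(plan: SegmentPlan, ref: ReferenceModel | None = None) -> np.ndarray:
    """Per-base copy number over reference coordinates (orientation-agnostic)."""
    plan.validate()
    if ref is not None and plan.length != ref.length(plan.replicon_id):
        raise PlanError("plan length does not match reference replicon")
    diff = np.zeros(plan.length + 1, dtype=np.int64)
    for a, b, _ in plan.segments:
        diff[a] += 1
        diff[b] -= 1
    return np.cumsum(diff[:-1])


def profile_at_positions(plan: SegmentPlan, positions: np.ndarray) -> np.ndarray:
    """Copy number sampled at sorted positions (fast path for probe arrays)."""
    plan.validate()
    diff = np.zeros(len(positions) + 1, dtype=np.int64)
    for a, b, _ in plan.segments:
        lo = np.searchsorted(positions, a, side="left")
        hi = np.searchsorted(positions, b, side="left")
        diff[lo] += 1
        diff[hi] -= 1
    return np.cumsum(diff[:-1])


# ---------------------------------------------------------------------------
# Junction enumeration


def _continuous(left: Segment, right: Segment, L: int) -> bool:
    a1, b1, s1 = left
    a2, b2, s2 = right
    if s1 != s2:
        return False
    if s1 == "+":
        return a2 % L == b1 % L
    return a1 % L == b2 % L


def junctions_of(plan: SegmentPlan, ref: ReferenceModel, context: int = 50) -> list[JunctionSpec]:
    """Every adjacent segment pair whose reference adjacency is broken.

    The plan is circular: the last/first segment adjacency is included.
    An identity plan therefore has zero junctions.  The realized +/-50 nt
    context is read through the side accessors, so it is exact as long
    as flanking segments are longer than ``context`` (true for every
    builder here).
    """
    plan.validate()
    seq = ref.seqs[plan.replicon_id]
    designed = plan.designed_junctions()
    out: list[JunctionSpec] = []
    n = len(plan.segments)
    for i in range(n):
        left = plan.segments[i]
        j = (i + 1) % n
        right = plan.segments[j]
        if i == j:  # single-segment plan: wrap adjacency with itself
            if _continuous(left, right, plan.length):
                continue
        elif _continuous(left, right, plan.length):
            continue
        donor = donor_side(left)
        acceptor = acceptor_side(right)
        li, lj, mh, mh_seq = measure_mh(seq, donor, acceptor)
        dj = designed.get((donor, acceptor))
        ctx_left = bytes(side_value(seq, donor, t) for t in range(-context, 0))
        ctx_right = bytes(side_value(seq, acceptor, t) for t in range(0, context))
        out.append(
            JunctionSpec(
                left_segment_index=i,
                right_segment_index=j,
                donor=donor,
                acceptor=acceptor,
                mh_len=dj.mh_len if dj else mh,
                measured_mh=mh,
                mh_seq=mh_seq,
                junction_seq=(ctx_left + ctx_right).decode(),
                label=dj.label if dj else "",
            )
        )
    return out


def unique_junctions(junctions: list[JunctionSpec]) -> list[JunctionSpec]:
    """Collapse repeated instances of the same junction type (same sides)."""
    seen: dict[tuple[Side, Side], JunctionSpec] = {}
    for j in junctions:
        seen.setdefault((j.donor, j.acceptor), j)
    return list(seen.values())


# ---------------------------------------------------------------------------
# Microhomology planting engine


@dataclass(frozen=True)
class _Pos:
    idx: int
    comp: bool


def _pos(side: Side, t: int, L: int) -> _Pos:
    return _Pos(side.index(t, L), side.comp)


class _Planter:
    """Plants designed homology tracts by point edits, under constraints.

    Every equality/inequality it establishes is recorded; a later edit to
    a constrained base is only accepted if all recorded constraints still
    hold, so junctions designed close together cannot silently corrupt
    one another (a genuine conflict raises :class:`PlantError`).
    """

    def __init__(self, seq: bytearray, rng: np.random.Generator):
        self.seq = seq
        self.L = len(seq)
        self.rng = rng
        self.constraints: list[tuple[str, _Pos, _Pos]] = []

    def _val(self, p: _Pos) -> int:
        v = self.seq[p.idx]
        return comp_base(v) if p.comp else v

    def _holds(self, c: tuple[str, _Pos, _Pos]) -> bool:
        kind, a, b = c
        return (self._val(a) == self._val(b)) == (kind == "eq")

    def _try_edit(self, idx: int, new_byte: int, extra: list[tuple[str, _Pos, _Pos]]) -> bool:
        old = self.seq[idx]
        self.seq[idx] = new_byte
        affected = [c for c in self.constraints if c[1].idx == idx or c[2].idx == idx]
        if all(self._holds(c) for c in affected + extra):
            self.constraints.extend(extra)
            return True
        self.seq[idx] = old
        return False

    def _require_eq(self, a: _Pos, b: _Pos) -> None:
        c = ("eq", a, b)
        if a.idx == b.idx:
            if a.comp == b.comp:
                self.constraints.append(c)
                return
            raise PlantError("degenerate junction: base would have to equal its complement")
        if self._val(a) == self._val(b):
            self.constraints.append(c)
            return
        # force b to match a (preferred: b is the acceptor's parental side),
        # falling back to editing a
        for target, source in ((b, a), (a, b)):
            want = self._val(source)
            byte = comp_base(want) if target.comp else want
            if self._try_edit(target.idx, byte, [c]):
                return
        raise PlantError("could not plant homology tract base")

    def _require_ne(self, a: _Pos, b: _Pos, candidates: tuple[_Pos, ...]) -> None:
        c = ("ne", a, b)
        if a.idx == b.idx:
            if a.comp != b.comp:
                self.constraints.append(c)  # base vs own complement: always unequal
                return
            raise PlantError("degenerate junction: same base on both sides of a mismatch pin")
        if self._val(a) != self._val(b):
            self.constraints.append(c)
            return
        for cand in candidates:
            order = [x for x in b"ACGT" if x != self.seq[cand.idx]]
            self.rng.shuffle(order)
            for byte in order:
                if self._try_edit(cand.idx, byte, [c]):
                    return
        raise PlantError("could not pin microhomology tract end")

    def plant(self, donor: Side, acceptor: Side, mh_len: int, label: str) -> DesignedJunction:
        """Design a junction with exactly ``mh_len`` bases of microhomology."""
        if mh_len < 0:
            raise PlanError("mh_len must be >= 0")
        L = self.L
        for r in range(1, mh_len + 1):
            self._require_eq(_pos(donor, -r, L), _pos(acceptor, -r, L))
        # pin both ends of the tract so measured homology is exactly mh_len
        r = mh_len + 1
        self._require_ne(
            _pos(donor, -r, L), _pos(acceptor, -r, L),
            (_pos(acceptor, -r, L), _pos(donor, -r, L)),
        )
        self._require_ne(
            _pos(donor, 0, L), _pos(acceptor, 0, L),
            (_pos(donor, 0, L), _pos(acceptor, 0, L)),
        )
        return DesignedJunction(donor, acceptor, mh_len, label)


def _verify_designed(plan: SegmentPlan, ref: ReferenceModel) -> None:
    seq = ref.seqs[plan.replicon_id]
    for dj in plan.designed_junctions().values():
        _, _, mh, _ = measure_mh(seq, dj.donor, dj.acceptor)
        if mh != dj.mh_len:
            raise PlantError(
                f"designed mh {dj.mh_len} but measured {mh} at {dj.label} junction"
            )


# ---------------------------------------------------------------------------
# Builders


def _check_interval(iv: Interval, L: int, name: str) -> None:
    if not (0 <= iv[0] < iv[1] <= L):
        raise PlanError(f"{name} {iv} out of bounds for replicon of length {L}")


def _marker_within(ref: ReferenceModel, replicon: str, iv: Interval) -> bool:
    if replicon != EPISOME:
        return False
    ms, me = ref.marker_locus
    return iv[0] <= ms and me <= iv[1]


def build_amplification(
    ref: ReferenceModel,
    amplicon: Interval,
    copies: int,
    mh_len: int = 5,
    seed: int = 0,
    replicon: str = EPISOME,
) -> SegmentPlan:
    """Tandem head-to-tail array over ``amplicon`` at ``copies`` copies.

    One novel junction type (amplicon end -> amplicon start) whose flanks
    share exactly ``mh_len`` designed bases.  Warns if the amplicon does
    not cover the marker locus: such an event would not be selectable.
    """
    L = ref.length(replicon)
    _check_interval(amplicon, L, "amplicon")
    if copies < 2:
        raise PlanError("copies must be >= 2")
    A, B = amplicon
    if B - A < 2 * (mh_len + 2):
        raise PlanError("amplicon too short for designed microhomology")
    if not _marker_within(ref, replicon, amplicon):
        warnings.warn("amplicon does not cover the marker locus; event is not selectable")
    planter = _Planter(ref.seqs[replicon], np.random.default_rng(seed))
    dj = planter.plant(Side(B, "+"), Side(A, "+"), mh_len, "amplification")
    ev = Event("AMP", (A, B), [(A, B, "+")] * copies, [dj], {"copies": copies})
    plan = assemble(replicon, L, [ev])
    _verify_designed(plan, ref)
    return plan


def build_embedded_inverted_duplication(
    ref: ReferenceModel,
    amplicon: Interval,
    inner: Interval,
    copies: int,
    mh_lens: tuple[int, int] = (8, 8),
    seed: int = 0,
    replicon: str = EPISOME,
    triplication: bool = False,
    require_marker: bool = True,
    amp_mh_len: int = 5,
) -> SegmentPlan:
    """Amplicon whose unit carries ``inner`` twice, once inverted.

    Unit = [left-flank+inner(+), inner(-), right-flank(+)]; per unit the
    inner region is present twice (three times with ``triplication``,
    the pre-crossing-over layout).  The two template-switch junctions
    carry the designed microhomologies ``mh_lens``; with ``copies >= 2``
    the tandem unit boundary adds the ordinary amplification junction.
    The inverted copy is staggered 70-90 nt short of the fold (see module
    docstring); the stagger is below probe spacing.
    """
    L = ref.length(replicon)
    _check_interval(amplicon, L, "amplicon")
    _check_interval(inner, L, "inner")
    A, B = amplicon
    p, q = inner
    if not (A < p and q < B):
        raise PlanError("inner must be strictly inside amplicon")
    if p - A < 100 or B - q < 100:
        raise PlanError("inner too close to amplicon edge (need >= 100 nt flanks)")
    if copies < 1:
        raise PlanError("copies must be >= 1")
    if require_marker and not _marker_within(ref, replicon, inner):
        raise PlanError(
            "marker locus not inside the embedded duplication "
            "(pass require_marker=False to override)"
        )
    rng = np.random.default_rng(seed)
    k1, k2 = mh_lens
    delta1 = int(rng.integers(max(70, k1 + k2 + 10), 91))
    if q - delta1 - p < 100:
        raise PlanError("inner too short for staggered inverted copy")
    planter = _Planter(ref.seqs[replicon], rng)
    junctions = []
    if triplication:
        delta2 = int(rng.integers(max(70, k1 + k2 + 10), 91))
        unit: list[Segment] = [(A, q, "+"), (p, q - delta1, "-"), (p + delta2, B, "+")]
        # switch back into direct orientation downstream of the fold at p
        junctions.append(planter.plant(Side(p, "-"), Side(p + delta2, "+"), k2, "switch2"))
    else:
        unit = [(A, q, "+"), (p, q - delta1, "-"), (q, B, "+")]
        junctions.append(planter.plant(Side(p, "-"), Side(q, "+"), k2, "switch2"))
    junctions.append(planter.plant(Side(q, "+"), Side(q - delta1, "-"), k1, "switch1"))
    if copies >= 2:
        junctions.append(planter.plant(Side(B, "+"), Side(A, "+"), amp_mh_len, "amplification"))
    ev = Event(
        "EID",
        (A, B),
        unit * copies,
        junctions,
        {"copies": copies, "inner": inner, "stagger": delta1, "triplication": triplication},
    )
    plan = assemble(replicon, L, [ev])
    _verify_designed(plan, ref)
    return plan


def build_partially_inverted_amplification(
    ref: ReferenceModel,
    left: Interval,
    right: Interval,
    copies: int,
    mh_lens: tuple[int, int] = (8, 8),
    seed: int = 0,
    replicon: str = EPISOME,
) -> SegmentPlan:
    """Amplicon unit [left(+), right(-)]: two gains split by a normal gap.

    On the reference map the gained region appears discontiguous; mapped
    through the inversion the amplicon is contiguous.  The inversion's
    right end and the amplification share a junction, so there are
    exactly two distinct novel junction types at any copy number.
    """
    L = ref.length(replicon)
    _check_interval(left, L, "left")
    _check_interval(right, L, "right")
    a1, b1 = left
    a2, b2 = right
    if b1 >= a2:
        raise PlanError("left and right must be disjoint with left before right")
    if a2 - b1 < MIN_EVENT_GAP:
        raise PlanError(f"gap between left and right must be >= {MIN_EVENT_GAP} nt")
    if copies < 2:
        raise PlanError("copies must be >= 2")
    rng = np.random.default_rng(seed)
    planter = _Planter(ref.seqs[replicon], rng)
    kA, kB = mh_lens
    jA = planter.plant(Side(b1, "+"), Side(b2, "-"), kA, "switch_inv")
    jB = planter.plant(Side(a2, "-"), Side(a1, "+"), kB, "switch_back")
    unit: list[Segment] = [(a1, b1, "+"), (a2, b2, "-")]
    ev = Event(
        "PIA",
        (a1, b1),
        unit * (copies - 1) + [(a1, b1, "+")],
        [jA, jB],
        {"copies": copies, "left": left, "right": right},
    )
    plan = assemble(replicon, L, [ev])
    _verify_designed(plan, ref)
    return plan


def build_embedded_deletion_amplicon(
    ref: ReferenceModel,
    amplicon: Interval,
    deleted: Interval,
    copies: int,
    mh_lens: tuple[int, int] = (5, 3),
    seed: int = 0,
    replicon: str = EPISOME,
) -> SegmentPlan:
    """Amplicon alternating full and internally deleted units.

    Per unit pair the deleted interval is present at half the amplicon
    copy number; both junction types are in direct orientation.  A
    zero-length ``deleted`` reduces to :func:`build_amplification`.
    """
    L = ref.length(replicon)
    _check_interval(amplicon, L, "amplicon")
    A, B = amplicon
    p, q = deleted
    if q - p == 0:
        return build_amplification(ref, amplicon, copies, mh_lens[0], seed, replicon)
    if not (A < p < q < B):
        raise PlanError("deleted must be strictly inside amplicon")
    if p - A < 100 or B - q < 100:
        raise PlanError("deleted too close to amplicon edge")
    if copies < 2:
        raise PlanError("copies must be >= 2")
    if replicon == EPISOME:
        ms, me = ref.marker_locus
        if p < me and ms < q:
            raise PlanError("deleted interval covers the marker locus (would abolish selection)")
    rng = np.random.default_rng(seed)
    planter = _Planter(ref.seqs[replicon], rng)
    k_amp, k_del = mh_lens
    j_amp = planter.plant(Side(B, "+"), Side(A, "+"), k_amp, "amplification")
    j_del = planter.plant(Side(p, "+"), Side(q, "+"), k_del, "embedded_deletion")
    full: list[Segment] = [(A, B, "+")]
    delcopy: list[Segment] = [(A, p, "+"), (q, B, "+")]
    units: list[Segment] = []
    for i in range(copies):
        units.extend(full if i % 2 == 0 else delcopy)
    ev = Event(
        "EDE", (A, B), units, [j_amp, j_del], {"copies": copies, "deleted": deleted}
    )
    plan = assemble(replicon, L, [ev])
    _verify_designed(plan, ref)
    return plan


def build_inversion_with_indels(
    ref: ReferenceModel,
    inv: Interval,
    left_offset: int = 0,
    right_offset: int = 0,
    seed: int = 0,
    replicon: str = EPISOME,
) -> SegmentPlan:
    """Inversion with endpoints displaced by a few tens of base pairs.

    A positive offset duplicates reference bases at that end
    (micro-duplication), a negative offset loses them (micro-deletion);
    realized length = reference length + left_offset + right_offset.
    Junctions are planted blunt (designed microhomology 0) so the two
    endpoint offsets are recoverable exactly from sequence.
    """
    L = ref.length(replicon)
    _check_interval(inv, L, "inv")
    s, e = inv
    for off, name in ((left_offset, "left_offset"), (right_offset, "right_offset")):
        if abs(off) > 100:
            raise PlanError(f"{name} must be within +/-100 nt (a few tens of base pairs)")
    if e - s <= 2 * 110:
        raise PlanError("inversion too short relative to offsets")
    if s - max(left_offset, 0) < 1 or e + max(right_offset, 0) > L - 1:
        raise PlanError("offsets run off the replicon")
    rng = np.random.default_rng(seed)
    planter = _Planter(ref.seqs[replicon], rng)
    inv_seg: Segment = (s - left_offset, e + right_offset, "-")
    jL = planter.plant(Side(s, "+"), acceptor_side(inv_seg), 0, "inversion_left")
    jR = planter.plant(donor_side(inv_seg), Side(e, "+"), 0, "inversion_right")
    ev = Event(
        "INV",
        (s, e),
        [inv_seg],
        [jL, jR],
        {"inv": inv, "left_offset": left_offset, "right_offset": right_offset},
    )
    plan = assemble(replicon, L, [ev])
    _verify_designed(plan, ref)
    return plan


def build_secondary_deletion(
    ref: ReferenceModel,
    del_interval: Interval,
    mh_len: int = 2,
    seed: int = 0,
    replicon: str = EPISOME,
) -> SegmentPlan:
    """Simple deletion unlinked to amplification; one novel junction."""
    L = ref.length(replicon)
    _check_interval(del_interval, L, "del_interval")
    p, q = del_interval
    if p < 100 or q > L - 100:
        raise PlanError("deletion too close to the origin join")
    if _marker_within(ref, replicon, (p, q)) or (
        replicon == EPISOME and p < ref.marker_locus[1] and ref.marker_locus[0] < q
    ):
        raise PlanError("deletion overlaps the marker locus")
    rng = np.random.default_rng(seed)
    planter = _Planter(ref.seqs[replicon], rng)
    dj = planter.plant(Side(p, "+"), Side(q, "+"), mh_len, "deletion")
    ev = Event("DEL", (p, q), [], [dj], {"length": q - p})
    plan = assemble(replicon, L, [ev])
    _verify_designed(plan, ref)
    return plan


def compose(*plans: SegmentPlan) -> SegmentPlan:
    """Apply independent events from several plans to one replicon.

    Events must be pairwise separated by at least ``MIN_EVENT_GAP`` on the
    reference so their junction neighbourhoods stay independent.
    """
    if not plans:
        raise PlanError("nothing to compose")
    rep = plans[0].replicon_id
    L = plans[0].length
    if any(p.replicon_id != rep or p.length != L for p in plans):
        raise PlanError("compose requires plans on the same replicon")
    events = sorted((ev for p in plans for ev in p.events), key=lambda e: e.span[0])
    for prev, nxt in zip(events, events[1:]):
        if nxt.span[0] - prev.span[1] < MIN_EVENT_GAP:
            raise PlanError(
                f"events {prev.label} and {nxt.label} closer than {MIN_EVENT_GAP} nt"
            )
    return assemble(rep, L, events)
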