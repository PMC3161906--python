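"""Breakpoint junction analysis: microhomology, REP overlap, in-silico
unidirectional PCR for inversion screening, and micro-indel recovery.

Microhomology follows the standard structural-variant convention:
the length of the shared tract that makes the exact breakpoint placement
ambiguous (the junction can be written at mh_len + 1 positions); the
leftmost placement is reported.  Primer binding is exact-match on either
strand — the assay logic here is orientation, not thermodynamics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from intervaltree import IntervalTree

from ._junction import Side, measure_mh, side_value
from ._seq import revcomp
from .rearrange import JunctionSpec, SegmentPlan
from .synthetic_genome import Interval, ReferenceModel


@dataclass
class JunctionReport:
    junction_id: str
    mh_len: int
    mh_seq: str
    at_rep: bool
    donor: Side
    acceptor: Side
    structure_class: str = ""


def microhomology(
    ref_seq: str | bytes | bytearray,
    left_end: Side | tuple[int, str],
    right_start: Side | tuple[int, str],
    max_scan: int = 200,
) -> tuple[int, str]:
    """Microhomology of the junction joining ``left_end`` to ``right_start``.

    ``left_end`` is the donor side (coordinate = exclusive segment end on
    '+', segment start on '-'); ``right_start`` the acceptor side
    (coordinate = segment start on '+', exclusive end on '-').  Returns
    ``(mh_len, mh_seq)`` with the tract in realized orientation.
    """
    if isinstance(left_end, tuple):
        left_end = Side(*left_end)
    if isinstance(right_start, tuple):
        right_start = Side(*right_start)
    seq = ref_seq.encode() if isinstance(ref_seq, str) else ref_seq
    _, _, mh, tract = measure_mh(seq, left_end, right_start, max_scan)
    return mh, tract


def junction_breakpoints(j: JunctionSpec | JunctionReport) -> list[tuple[int, str]]:
    """The two parental breakpoint base coordinates of a junction.

    The donor breakpoint is the last realized base on the left side, the
    acceptor breakpoint the first realized base on the right side; both
    in reference coordinates.
    """
    out = []
    for side, t in ((j.donor, -1), (j.acceptor, 0)):
        if side.strand == "+":
            out.append((side.coord + t, side.strand))
        else:
            out.append((side.coord - 1 - t, side.strand))
    return out


def annotate_rep(
    junction: JunctionSpec | JunctionReport,
    rep_sites: list[Interval] | IntervalTree,
) -> bool:
    """True iff either parental breakpoint lies within a REP interval
    (half-open), on this junction's replicon."""
    tree = rep_sites if isinstance(rep_sites, IntervalTree) else IntervalTree.from_tuples(
        (s, e) for s, e in rep_sites if e > s
    )
    for pos, _strand in junction_breakpoints(junction):
        if tree.overlaps_point(pos):
            return True
    return False


def report_junctions(
    plan_junctions: list[JunctionSpec], ref: ReferenceModel, replicon: str
) -> list[JunctionReport]:
    tree = IntervalTree.from_tuples((s, e) for s, e in ref.rep_sites.get(replicon, []) if e > s)
    reports = []
    for i, j in enumerate(plan_junctions):
        reports.append(
            JunctionReport(
                junction_id=f"{replicon}_j{i:03d}_{j.label or 'novel'}",
                mh_len=j.measured_mh,
                mh_seq=j.mh_seq,
                at_rep=annotate_rep(j, tree),
                donor=j.donor,
                acceptor=j.acceptor,
            )
        )
    return reports


# ---------------------------------------------------------------------------
# In-silico PCR


def _find_all(hay: bytes, needle: bytes) -> list[int]:
    out, i = [], hay.find(needle)
    while i != -1:
        out.append(i)
        i = hay.find(needle, i + 1)
    return out


def primer_sites(seq: bytes, primer: bytes) -> list[tuple[int, str]]:
    """Exact binding sites; '+' sites extend rightward, '-' leftward.

    A '+' site at position p means the primer sequence occurs at
    seq[p:p+len]; a '-' site means its reverse complement occurs there
    (the primer anneals to the plus strand and extends leftward).
    """
    fwd = [(p, "+") for p in _find_all(seq, primer)]
    rev = [(p, "-") for p in _find_all(seq, revcomp(primer))]
    return sorted(fwd + rev)


def unidirectional_pcr(
    sample_seq: str | bytes,
    primer1: str | bytes,
    primer2: str | bytes,
    max_product: int = 20_000,
    warn_ambiguous: bool = True,
) -> list[tuple[int, str]]:
    """Enumerate PCR products from a primer pair on a linear molecule.

    A product forms for every convergent site pair: one '+' site (of
    either primer) left of one '-' site (of either primer), within
    ``max_product``.  Two primers designed in the same orientation on the
    reference therefore give no product unless an inversion has flipped
    one binding site.  Returns (product_size, product_seq) tuples.
    """
    seq = sample_seq.encode() if isinstance(sample_seq, str) else bytes(sample_seq)
    primers = []
    for p in (primer1, primer2):
        p = p.encode() if isinstance(p, str) else bytes(p)
        if len(p) < 15:
            raise ValueError("primers must be >= 15 nt")
        primers.append(p)
    sites: list[tuple[int, str, int]] = []
    for k, p in enumerate(primers):
        hits = primer_sites(seq, p)
        if warn_ambiguous and len(hits) > 1:
            warnings.warn(f"primer {k + 1} has {len(hits)} binding sites (ambiguous assay)")
        sites.extend((pos, strand, len(p)) for pos, strand in hits)
    products = []
    for pos_f, strand_f, _len_f in sites:
        if strand_f != "+":
            continue
        for pos_r, strand_r, len_r in sites:
            if strand_r != "-":
                continue
            end = pos_r + len_r
            size = end - pos_f
            if 0 < size <= max_product:
                products.append((size, seq[pos_f:end].decode()))
    return sorted(set(products))


def pcr_inversion_screen(
    sample_seq: str | bytes,
    panel: list[str | bytes],
    max_product: int = 20_000,
) -> list[tuple[int, str]]:
    """Unidirectional screen with a same-orientation primer panel.

    All panel primers point the same way on the reference; any product
    indicates that an inversion has made some pair convergent.
    """
    seq = sample_seq.encode() if isinstance(sample_seq, str) else bytes(sample_seq)
    all_sites: list[tuple[int, str, int]] = []
    for p in panel:
        p = p.encode() if isinstance(p, str) else bytes(p)
        all_sites.extend((pos, strand, len(p)) for pos, strand in primer_sites(seq, p))
    products = []
    for pos_f, strand_f, _ in all_sites:
        if strand_f != "+":
            continue
        for pos_r, strand_r, len_r in all_sites:
            if strand_r != "-":
                continue
            size = pos_r + len_r - pos_f
            if 0 < size <= max_product:
                products.append((size, seq[pos_f : pos_r + len_r].decode()))
    return sorted(set(products))


# ---------------------------------------------------------------------------
# Micro-indel recovery for inversions


def junction_microindels(
    plan: SegmentPlan, ref: ReferenceModel
) -> tuple[int, int] | None:
    """Recover the two endpoint offsets of an inversion from sequence.

    Aligns the realized molecule to the reference: the longest common
    prefix/suffix locate the two breakpoints (the builder pins both with
    a mismatch, so they are exact), and the inverted block is then
    anchored to the reference by exhaustive shift search.  Returns
    (left_offset, right_offset), or None for a plan without an inversion
    event (not-applicable).
    """
    inv_events = [ev for ev in plan.events if ev.label == "INV"]
    if not inv_events:
        return None
    if len(plan.events) != 1:
        raise ValueError("offset recovery expects a plan with the inversion alone")
    from .rearrange import realize_sequence

    S = bytes(ref.seqs[plan.replicon_id])
    R = realize_sequence(plan, ref).encode()
    L = len(S)
    # longest common prefix / suffix
    lo, hi = 0, min(len(R), L)
    while lo < hi and R[lo] == S[lo]:
        lo += 1
    s = lo
    k = 0
    while k < min(len(R), L) - s and R[len(R) - 1 - k] == S[L - 1 - k]:
        k += 1
    e = L - k
    block = R[s : len(R) - k]
    if not block:
        return (0, 0)
    rc = revcomp(block)
    # anchor the inverted block: rc == S[s - dL : e + dR] for the true offsets
    for d_left in range(-100, 101):
        start = s - d_left
        if start < 0 or start + len(block) > L:
            continue
        if S[start : start + len(block)] == rc:
            d_right = (start + len(block)) - e
            return (d_left, d_right)
    raise ValueError("could not anchor inverted block to the reference")
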