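"""Breakpoint-side accessors and microhomology measurement.

A rearrangement junction joins the *donor* side (the 3' end of the left
segment, where synthesis left its template) to the *acceptor* side (where
synthesis resumed).  Each side is described by a reference coordinate and
a strand; offsets along the realized molecule map back to reference
positions through a single affine rule:

  side (c, '+'):  offset t -> base at (c + t) mod L
  side (c, '-'):  offset t -> complement of base at (c - 1 - t) mod L

For the donor side, ``c`` is the segment's exclusive end on '+' and its
start on '-'; for the acceptor side, ``c`` is the segment start on '+'
and the exclusive end on '-'.  Offsets t < 0 are realized flank bases of
that side; t >= 0 on the donor (t < 0 on the acceptor) are the *parental*
continuation that the rearrangement abandoned.

Microhomology is the standard breakpoint-placement ambiguity: the
maximal shared tract across the join, so the breakpoint can be written at
mh_len + 1 equivalent positions; the leftmost placement is reported.
"""

from __future__ import annotations

from dataclasses import dataclass

from ._seq import comp_base


@dataclass(frozen=True)
class Side:
    """One side of a junction: reference coordinate + strand."""

    coord: int
    strand: str  # '+' or '-'

    def index(self, t: int, L: int) -> int:
        if self.strand == "+":
            return (self.coord + t) % L
        return (self.coord - 1 - t) % L

    @property
    def comp(self) -> bool:
        return self.strand == "-"


def side_value(seq: bytes | bytearray, side: Side, t: int) -> int:
    b = seq[side.index(t, len(seq))]
    return comp_base(b) if side.comp else b


def donor_side(segment: tuple[int, int, str]) -> Side:
    a, b, s = segment
    return Side(b, "+") if s == "+" else Side(a, "-")


def acceptor_side(segment: tuple[int, int, str]) -> Side:
    a, b, s = segment
    return Side(a, "+") if s == "+" else Side(b, "-")


def measure_mh(
    seq: bytes | bytearray, donor: Side, acceptor: Side, max_scan: int = 200
) -> tuple[int, int, int, str]:
    """Measure junction microhomology by breakpoint sliding.

    Returns ``(i, j, mh_len, mh_seq)`` where ``i`` is the leftward and
    ``j`` the rightward extent of the shared tract (mh_len = i + j); the
    tract ``mh_seq`` is reported in realized-molecule orientation with
    the leftmost breakpoint placement.
    """
    i = 0
    while i < max_scan and side_value(seq, donor, -(i + 1)) == side_value(seq, acceptor, -(i + 1)):
        i += 1
    j = 0
    while j < max_scan and side_value(seq, donor, j) == side_value(seq, acceptor, j):
        j += 1
    if i >= max_scan or j >= max_scan:
        raise ValueError("microhomology scan exceeded max_scan; context too short")
    tract = bytes(side_value(seq, donor, t) for t in range(-i, 0)) + bytes(
        side_value(seq, acceptor, t) for t in range(0, j)
    )
    return i, j, i + j, tract.decode()
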