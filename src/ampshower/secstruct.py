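"""DNA stem-loop (hairpin) prediction from inverted repeats.

Junction hotspots in stress-induced amplification lie preferentially on
the stems of predicted secondary structures (REP elements are ~38 bp
pseudopalindromes rich in such potential).  This module enumerates
inverted repeats directly — exact or near-exact complementarity with a
small mismatch budget — rather than folding thermodynamically: the
claims the pipeline tests are positional (is the junction on a stem or
in a loop?), not energetic, and enumeration is exactly testable.

Defaults (min_stem=6, loop 3-50, max_mismatch=1) are chosen so planted
REP cassettes (stem 12-16) are always found while random 50-mers rarely
produce hits.
"""

from __future__ import annotations

from dataclasses import dataclass

from ._junction import Side
from ._seq import comp_base
from .rearrange import JunctionSpec
from .synthetic_genome import Interval


@dataclass(frozen=True)
class StemLoop:
    """A hairpin: stem1 + loop + stem2, stem2 ~ revcomp(stem1)."""

    stem1: Interval
    loop: Interval
    stem2: Interval
    stem_len: int
    mismatches: int

    @property
    def span(self) -> Interval:
        return (self.stem1[0], self.stem2[1])


def find_stemloops(
    seq: str | bytes,
    min_stem: int = 6,
    loop_range: tuple[int, int] = (3, 50),
    max_mismatch: int = 1,
) -> list[StemLoop]:
    """All maximal inverted repeats meeting the parameters.

    For every candidate loop, the stem is grown outward while the
    mismatch budget lasts and then trimmed so it ends on a matching
    pair (a mismatch at the stem tip carries no pairing information).
    Overlapping reports are allowed; results are sorted by stem length
    descending, then position.
    """
    s = seq.encode() if isinstance(seq, str) else bytes(seq)
    n = len(s)
    lo_min, lo_max = loop_range
    if min_stem < 2:
        raise ValueError("min_stem must be >= 2")
    if n < 2 * min_stem + lo_min:
        return []
    found: dict[tuple[int, int, int], int] = {}
    for loop_len in range(lo_min, min(lo_max, n - 2 * min_stem) + 1):
        for loop_start in range(min_stem, n - loop_len - min_stem + 1):
            loop_end = loop_start + loop_len
            stem = 0
            mm = 0
            last_match = 0
            while loop_start - stem - 1 >= 0 and loop_end + stem < n:
                left = s[loop_start - stem - 1]
                right = s[loop_end + stem]
                if comp_base(left) == right:
                    stem += 1
                    last_match = stem
                else:
                    if mm + 1 > max_mismatch:
                        break
                    mm += 1
                    stem += 1
            stem = last_match  # trim trailing mismatches
            if stem >= min_stem:
                key = (loop_start - stem, loop_start, loop_end)
                prev = found.get(key)
                if prev is None or prev < stem:
                    found[key] = stem
    out = []
    for (s1, loop_start, loop_end), stem in found.items():
        mm_used = sum(
            1 for t in range(stem) if comp_base(s[loop_start - 1 - t]) != s[loop_end + t]
        )
        out.append(
            StemLoop(
                stem1=(loop_start - stem, loop_start),
                loop=(loop_start, loop_end),
                stem2=(loop_end, loop_end + stem),
                stem_len=stem,
                mismatches=mm_used,
            )
        )
    out.sort(key=lambda h: (-h.stem_len, h.stem1[0], h.loop[0]))
    return _dedupe_nested(out)


def _dedupe_nested(hairpins: list[StemLoop]) -> list[StemLoop]:
    """Drop hairpins whose stems are strict sub-stems of a longer report
    with the same loop (growth already reports the maximal stem)."""
    keep: list[StemLoop] = []
    seen_loops: dict[Interval, int] = {}
    for h in hairpins:
        best = seen_loops.get(h.loop)
        if best is not None and best > h.stem_len:
            continue
        seen_loops[h.loop] = max(best or 0, h.stem_len)
        keep.append(h)
    return keep


def _overlap(a: Interval, b: Interval) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def classify_junction_structure(
    junction: JunctionSpec,
    ref_seq: str | bytes | bytearray,
    window: int = 100,
    min_stem: int = 6,
    loop_range: tuple[int, int] = (3, 50),
    max_mismatch: int = 1,
) -> str:
    """Class of the junction's microhomology footprint against predicted
    hairpins: 'stem', 'loop', 'both', or 'unstructured'.

    The footprint (the whole shared tract, not a point) is compared with
    every hairpin found within ``window`` nt of the breakpoint on each
    parental side; a footprint entirely within stem intervals is 'stem',
    entirely within a loop 'loop', touching both 'both'.
    """
    from ._junction import measure_mh

    seq = ref_seq.encode() if isinstance(ref_seq, str) else bytes(ref_seq)
    i, j, _, _ = measure_mh(seq, junction.donor, junction.acceptor)
    verdicts = set()
    for side in (junction.donor, junction.acceptor):
        # context in the side's own offset order; for a '-' side this is
        # the reference read backwards (not complemented), under which
        # hairpin pairing relations are preserved with mirrored coordinates
        ctx = bytes(seq[side.index(t, len(seq))] for t in range(-window, window))
        foot = (window - i, window + j)  # footprint in context coordinates
        hairpins = find_stemloops(ctx, min_stem, loop_range, max_mismatch)
        verdicts.add(_footprint_class(foot, hairpins))
    if "both" in verdicts or ("stem" in verdicts and "loop" in verdicts):
        return "both"
    for v in ("stem", "loop"):
        if v in verdicts:
            return v
    return "unstructured"


def _footprint_class(foot: Interval, hairpins: list[StemLoop]) -> str:
    touching = [h for h in hairpins if _overlap(foot, h.span)]
    if not touching:
        return "unstructured"
    on_stem = any(
        _overlap(foot, h.stem1) or _overlap(foot, h.stem2) for h in touching
    )
    on_loop = any(_overlap(foot, h.loop) for h in touching)
    if on_stem and on_loop:
        return "both"
    if on_stem:
        return "stem"
    if on_loop:
        return "loop"
    return "unstructured"
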