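"""Tiling-array copy-number simulation and calling.

The caller implements the cohort study's rule literally: a segment is
called wherever two or more adjacent probes show a 2-fold or more
increase or decrease relative to the reference (|log2 ratio| >= 1,
boundary inclusive).  No smoothing or segmentation model (CBS/HMM) is
applied — the rule is a run-length threshold and that is what runs here.
Probes flanking a masked interval are not adjacent (the run breaks);
the first and last probes of a circular replicon are adjacent, so a run
may wrap the origin.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .rearrange import SegmentPlan, profile_at_positions
from .synthetic_genome import EPISOME, ProbeArray, ReferenceModel

#: pseudo-count floor for zero-copy probes (deletions give a deep,
#: finite negative ratio rather than -inf)
CN_FLOOR = 0.01


@dataclass
class CallSet:
    """Called gain/loss segments plus the probe table they came from."""

    calls: pd.DataFrame  # replicon, start, end, direction, mean_log2, est_copy, n_probes, wraps
    table: pd.DataFrame
    spacing: dict[str, int]
    lengths: dict[str, int]
    classifications: list["Classification"] = field(default_factory=list)
    #: per-replicon (positions, log2 ratios) cache filled by call_segments
    arrays: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)


@dataclass
class Classification:
    event_class: str  # AMP | EID | EMBEDDED_DEL | SPLIT_AMPLICON | SECONDARY_DEL | UNCLASSIFIED
    call_indices: list[int]
    params: dict = field(default_factory=dict)


def probe_profiles(plans: dict[str, SegmentPlan], array: ProbeArray) -> dict[str, np.ndarray]:
    """Copy number of each probe position under the given plans.

    Replicons without a plan are taken as unrearranged (copy 1).
    """
    out = {}
    for rep, pos in array.positions.items():
        if rep in plans:
            out[rep] = profile_at_positions(plans[rep], np.asarray(pos))
        else:
            out[rep] = np.ones(len(pos), dtype=np.int64)
    return out


def simulate_ratios(
    profile_sample: dict[str, np.ndarray],
    profile_reference: dict[str, np.ndarray] | None,
    array: ProbeArray,
    sigma: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-probe log2 ratios: log2(cn_sample/cn_ref) + Normal(0, sigma^2).

    Zero sample copy uses the CN_FLOOR pseudo-count (flagged in the
    ``floored`` column); probes with zero reference copy are dropped
    with a warning.
    """
    rng = np.random.default_rng(seed)
    cols: dict[str, list[np.ndarray]] = {k: [] for k in ("replicon", "pos", "probe_id", "log2_ratio", "floored")}
    for rep in sorted(array.positions):
        pos = np.asarray(array.positions[rep])
        cn_s = np.asarray(profile_sample[rep], dtype=float)
        if profile_reference is None:
            cn_r = np.ones_like(cn_s)
        else:
            cn_r = np.asarray(profile_reference[rep], dtype=float)
        keep = cn_r > 0
        if not keep.all():
            import warnings

            warnings.warn(f"{(~keep).sum()} probes with zero reference copy dropped on {rep}")
        floored = (cn_s <= 0) & keep
        cn_s = np.where(cn_s <= 0, CN_FLOOR, cn_s)
        ratio = np.log2(cn_s[keep] / cn_r[keep])
        if sigma > 0:
            ratio = ratio + rng.normal(0.0, sigma, size=ratio.size)
        cols["replicon"].append(np.full(keep.sum(), rep, dtype=object))
        cols["pos"].append(pos[keep])
        cols["probe_id"].append(np.asarray(array.ids[rep], dtype=object)[keep])
        cols["log2_ratio"].append(ratio)
        cols["floored"].append(floored[keep])
    return pd.DataFrame({k: np.concatenate(v) for k, v in cols.items()})


def _circular_runs(qualify: np.ndarray, adjacent: np.ndarray) -> list[np.ndarray]:
    """Maximal runs of qualifying probes; ``adjacent[i]`` links probe i to
    probe i+1 (the last entry links the last probe back to the first)."""
    n = len(qualify)
    if n == 0:
        return []
    idx = np.flatnonzero(qualify)
    if idx.size == 0:
        return []
    if idx.size == n and bool(adjacent.all()):
        return [np.arange(n)]  # whole replicon qualifies
    # split the qualifying indices wherever consecutiveness or adjacency breaks
    breaks = np.flatnonzero((np.diff(idx) != 1) | ~adjacent[idx[:-1]]) + 1
    runs = np.split(idx, breaks)
    # merge a wrap-around run: last probe chains into probe 0
    if (
        len(runs) >= 2
        and runs[0][0] == 0
        and runs[-1][-1] == n - 1
        and bool(adjacent[n - 1])
    ):
        runs = [np.concatenate([runs[-1], runs[0]])] + runs[1:-1]
    return runs


def call_segments(
    table: pd.DataFrame,
    ref: ReferenceModel,
    threshold_log2: float = 1.0,
    min_probes: int = 2,
) -> CallSet:
    """Maximal runs of >= min_probes adjacent probes beyond the threshold.

    Call boundaries are the outermost qualifying probe positions extended
    by half a probe spacing on each side; est_copy = ref_copy * 2^mean_log2
    with the reference at copy 1.
    """
    if table.empty:
        empty = pd.DataFrame(
            columns=["replicon", "start", "end", "direction", "mean_log2", "est_copy", "n_probes", "wraps"]
        )
        return CallSet(empty, table, dict(ref.array.spacing), {r: ref.length(r) for r in ref.replicons})
    rows = []
    arrays: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for rep, grp in table.groupby("replicon", sort=True):
        pos = grp["pos"].to_numpy()
        if not np.all(np.diff(pos) > 0):
            raise ValueError(f"probe table not sorted by position on {rep}")
        ratio = grp["log2_ratio"].to_numpy()
        arrays[rep] = (pos, ratio)
        sp = ref.array.spacing[rep]
        L = ref.length(rep)
        gaps = np.diff(pos)
        adjacent = np.empty(len(pos), dtype=bool)
        adjacent[:-1] = gaps == sp  # a masked gap (> spacing) breaks adjacency
        adjacent[-1] = (pos[0] + L - pos[-1]) == sp if len(pos) > 1 else False
        for direction, qualify in (
            ("gain", ratio >= threshold_log2),
            ("loss", ratio <= -threshold_log2),
        ):
            for run in _circular_runs(qualify, adjacent):
                if len(run) < min_probes:
                    continue
                first, last = pos[run[0]], pos[run[-1]]
                start = (first - sp // 2) % L
                end = (last + sp // 2) % L
                wraps = start >= end  # interval crosses the origin join
                mean_log2 = float(ratio[run].mean())
                rows.append(
                    {
                        "replicon": rep,
                        "start": int(start),
                        "end": int(end),
                        "direction": direction,
                        "mean_log2": mean_log2,
                        "est_copy": float(2.0 ** mean_log2),
                        "n_probes": int(len(run)),
                        "wraps": bool(wraps),
                    }
                )
    calls = pd.DataFrame(rows, columns=["replicon", "start", "end", "direction", "mean_log2", "est_copy", "n_probes", "wraps"])
    if len(calls) > 1:
        calls = calls.sort_values(["replicon", "start"]).reset_index(drop=True)
    return CallSet(
        calls, table, dict(ref.array.spacing), {r: ref.length(r) for r in ref.replicons}, arrays=arrays
    )


# ---------------------------------------------------------------------------
# Structure classification


def _overlaps_marker(row: pd.Series, ref: ReferenceModel) -> bool:
    if row["replicon"] != EPISOME:
        return False
    ms, me = ref.marker_locus
    return row["start"] < me and ms < row["end"]


def _interior_runs(
    copies: np.ndarray, flank_level: float, factor: float, above: bool, min_run: int = 3
) -> list[tuple[int, int]]:
    """Maximal interior runs (not touching either end) of probes beyond
    factor * flank_level.

    ``min_run`` = 3: embedded sub-segments of interest span tens of
    probes, while pairs of adjacent noise outliers inside a long
    amplicon call are common enough to matter at realistic noise.
    """
    n = len(copies)
    if above:
        mask = copies >= factor * flank_level
    else:
        mask = copies <= factor * flank_level
    mask[0] = mask[-1] = False  # interior only
    runs = []
    i = 0
    while i < n:
        if mask[i]:
            j = i
            while j + 1 < n and mask[j + 1]:
                j += 1
            if j - i + 1 >= min_run:
                runs.append((i, j))
            i = j + 1
        else:
            i += 1
    return runs


def classify_events(
    callset: CallSet,
    ref: ReferenceModel,
    junctions: list | None = None,
    eid_factor: float = 1.4,
    del_factor: float = 0.6,
    split_tolerance: float = 0.25,
) -> list[Classification]:
    """Assign structure classes to a single isolate's call set.

    AMP: gain overlapping the marker locus.  EID: AMP with an interior
    sub-segment at >= eid_factor x the flanking amplicon copy.
    EMBEDDED_DEL: interior sub-segment at <= del_factor x.  SPLIT_AMPLICON:
    two gains separated by a normal gap with est_copy within
    ``split_tolerance`` (a candidate inversion, flagged for PCR
    confirmation).  SECONDARY_DEL: a loss neither overlapping nor within
    one probe spacing of any AMP call.  Anything else: UNCLASSIFIED.
    """
    calls = callset.calls
    out: list[Classification] = []
    callset.classifications = out
    if calls.empty:
        return out
    amp_idx = [
        i for i, row in calls.iterrows() if row["direction"] == "gain" and _overlaps_marker(row, ref)
    ]
    gains = calls[calls["direction"] == "gain"]
    consumed: set[int] = set()

    # split amplicon: pairs of same-replicon gains flanking a normal gap
    for rep, grp in gains.groupby("replicon"):
        idxs = list(grp.index)
        for a, b in zip(idxs, idxs[1:]):
            ra, rb = calls.loc[a], calls.loc[b]
            if ra["wraps"] or rb["wraps"]:
                continue
            gap = rb["start"] - ra["end"]
            if gap <= callset.spacing[rep]:
                continue
            ratio = ra["est_copy"] / rb["est_copy"]
            if 1 - split_tolerance <= ratio <= 1 / (1 - split_tolerance):
                out.append(
                    Classification(
                        "SPLIT_AMPLICON",
                        [int(a), int(b)],
                        {"gap": int(gap), "copy_ratio": float(ratio), "needs_pcr_confirmation": True},
                    )
                )
                consumed.update((a, b))

    for i in amp_idx:
        if i in consumed:
            continue
        row = calls.loc[i]
        all_pos, all_ratio = callset.arrays.get(
            row["replicon"],
            (
                callset.table.loc[callset.table["replicon"] == row["replicon"], "pos"].to_numpy(),
                callset.table.loc[callset.table["replicon"] == row["replicon"], "log2_ratio"].to_numpy(),
            ),
        )
        if row["wraps"]:
            sel = (all_pos >= row["start"]) | (all_pos < row["end"])
        else:
            sel = (all_pos >= row["start"]) & (all_pos < row["end"])
        copies = 2.0 ** all_ratio[sel]
        n = len(copies)
        k = max(2, n // 10)
        flank_level = float(np.median(np.concatenate([copies[:k], copies[-k:]])))
        high = _interior_runs(copies, flank_level, eid_factor, above=True)
        low = _interior_runs(copies, flank_level, del_factor, above=False)
        pos = all_pos[sel]
        # when both directions show interior runs, trust the longer one
        # (short spurious runs can arise from probe noise)
        if high and low:
            if max(b - a for a, b in low) > max(b - a for a, b in high):
                high = []
            else:
                low = []
        if high:
            a, b = max(high, key=lambda r: r[1] - r[0])
            out.append(
                Classification(
                    "EID",
                    [int(i)],
                    {
                        "inner_start": int(pos[a]),
                        "inner_end": int(pos[b]),
                        "inner_copy": float(np.median(copies[a : b + 1])),
                        "amplicon_copy": flank_level,
                    },
                )
            )
        elif low:
            a, b = max(low, key=lambda r: r[1] - r[0])
            out.append(
                Classification(
                    "EMBEDDED_DEL",
                    [int(i)],
                    {
                        "deleted_start": int(pos[a]),
                        "deleted_end": int(pos[b]),
                        "deleted_copy": float(np.median(copies[a : b + 1])),
                        "amplicon_copy": flank_level,
                    },
                )
            )
        else:
            out.append(Classification("AMP", [int(i)], {"est_copy": float(row["est_copy"])}))
        consumed.add(i)

    # losses
    for i, row in calls.iterrows():
        if row["direction"] != "loss" or i in consumed:
            continue
        sp = callset.spacing[row["replicon"]]
        near_amp = False
        for j in amp_idx:
            amp = calls.loc[j]
            if amp["replicon"] != row["replicon"]:
                continue
            if row["start"] < amp["end"] + sp and amp["start"] - sp < row["end"]:
                near_amp = True
        out.append(
            Classification(
                "SECONDARY_DEL" if not near_amp else "UNCLASSIFIED",
                [int(i)],
                {} if not near_amp else {"reason": "loss adjacent to amplification"},
            )
        )
        consumed.add(i)

    # remaining gains that never touched the marker
    for i, row in calls.iterrows():
        if i in consumed or row["direction"] != "gain":
            continue
        out.append(Classification("UNCLASSIFIED", [int(i)], {"reason": "gain without marker overlap"}))
    return out


def isolate_classes(classifications: list[Classification]) -> set[str]:
    return {c.event_class for c in classifications}


def plot_isolate(callset: CallSet, ref: ReferenceModel, path: str) -> None:
    """Scatter of position vs log2 ratio per replicon, with called
    segments shaded (one panel per replicon)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    reps = sorted(callset.table["replicon"].unique())
    fig, axes = plt.subplots(len(reps), 1, figsize=(10, 2.6 * len(reps)), squeeze=False)
    for ax, rep in zip(axes[:, 0], reps):
        grp = callset.table[callset.table["replicon"] == rep]
        ax.plot(grp["pos"], grp["log2_ratio"], ".", ms=2, color="steelblue")
        for _, row in callset.calls[callset.calls["replicon"] == rep].iterrows():
            color = "indianred" if row["direction"] == "gain" else "darkseagreen"
            ax.axvspan(row["start"], row["end"], alpha=0.25, color=color)
        ax.axhline(0, color="k", lw=0.5)
        ax.set_ylabel("log2 ratio")
        ax.set_title(rep)
    axes[-1, 0].set_xlabel("position (nt)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
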