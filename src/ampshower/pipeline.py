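"""End-to-end cohort simulation and analysis.

Simulates a cohort of marker-amplified isolates (every one carrying a
tandem amplification over the selectable marker, with the published
census frequencies of additional structures as defaults) plus stressed
controls carrying none; runs the tiling-array pipeline (ratio simulation
-> calling -> structure classification), the unidirectional-PCR
inversion screen, junction/microhomology/secondary-structure analysis,
and the two cohort comparisons (any additional event; amplification-
independent secondary events) with Fisher's exact test and the Peto
one-step odds ratio.

Determinism: the master seed fans out to per-isolate generators by a
counter scheme (``default_rng([master_seed, isolate_index])``), so any
isolate can be regenerated in isolation.
"""

from __future__ import annotations

import dataclasses
import json
import shutil
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import acgh, junctions, rearrange, secstruct, stats
from .rearrange import MIN_EVENT_GAP, SegmentPlan
from .synthetic_genome import CHROM, EPISOME, ReferenceModel, SimConfig, build_reference, write_reference

MARGIN = 600  # keep events away from the origin join and from each other


@dataclass
class CohortConfig:
    """Study conditions for one simulated cohort (defaults = the census
    frequencies and size distributions of the modeled experiment)."""

    n_amplified: int = 300
    n_control: int = 240
    # primary amplicon structure mixture (amplified isolates)
    p_eid: float = 16 / 300
    p_pia: float = 2 / 300
    p_embedded_del: float = 1 / 300
    # amplification-independent secondary events (amplified isolates)
    p_secondary_del: float = 4 / 300
    p_secondary_inv: float = 2 / 300
    #: secondary-event probability for control isolates (0 by default:
    #: controls showed no copy-number change)
    p_secondary_control: float = 0.0
    # amplification parameters
    copy_mean: float = 69.3
    copy_sd: float = 22.9
    amplicon_len_mean: float = 22_700.0
    amplicon_len_sd: float = 8_000.0
    eid_inner_range: tuple[int, int] = (5_200, 42_600)
    del_len_range: tuple[int, int] = (200, 7_500)
    inv_len_range: tuple[int, int] = (2_000, 8_000)
    micro_indel_max: int = 40
    mh_range: tuple[int, int] = (3, 30)
    del_mh_range: tuple[int, int] = (1, 4)
    rep_snap_prob: float = 0.24
    sigma: float = 0.2
    max_one_secondary: bool = True
    pcr_screen: bool = True
    seed: int = 0
    genome: SimConfig = field(default_factory=SimConfig)

    def validate(self) -> None:
        if self.p_eid + self.p_pia + self.p_embedded_del > 1:
            raise ValueError("primary structure mixture sums above 1")
        if self.p_secondary_del + self.p_secondary_inv > 1:
            raise ValueError("secondary mixture sums above 1")
        for p in (
            self.p_eid, self.p_pia, self.p_embedded_del,
            self.p_secondary_del, self.p_secondary_inv, self.p_secondary_control,
        ):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must be in [0,1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        genome = raw.pop("genome", None)
        cfg = cls(**{k: tuple(v) if isinstance(v, list) else v for k, v in raw.items()})
        if genome:
            for key in ("shared_block", "marker_locus", "rep_stem_range", "rep_loop_range", "rep_cluster_size"):
                if key in genome:
                    genome[key] = tuple(genome[key])
            if "mask" in genome:
                genome["mask"] = {k: [tuple(iv) for iv in v] for k, v in genome["mask"].items()}
            cfg.genome = SimConfig(**genome)
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        raw = dataclasses.asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh)


@dataclass
class IsolateResult:
    isolate_id: str
    group: str  # amplified | control
    truth_primary: str
    truth_secondary: str
    truth_params: dict
    plans: dict[str, SegmentPlan]
    callset: acgh.CallSet | None
    classes: set[str]
    n_inv_products: int = 0


# ---------------------------------------------------------------------------
# Event drawing


def _draw_copies(rng: np.random.Generator, cfg: CohortConfig) -> int:
    m, s = cfg.copy_mean, cfg.copy_sd
    sig2 = np.log1p((s / m) ** 2)
    mu = np.log(m) - sig2 / 2
    return int(np.clip(round(rng.lognormal(mu, np.sqrt(sig2))), 5, 250))


def _draw_amplicon(rng: np.random.Generator, cfg: CohortConfig, ref: ReferenceModel) -> tuple[int, int]:
    """Amplicon interval on the episome containing the marker locus."""
    L = ref.length(EPISOME)
    ms, me = ref.marker_locus
    m, s = cfg.amplicon_len_mean, cfg.amplicon_len_sd
    sig2 = np.log1p((s / m) ** 2)
    mu = np.log(m) - sig2 / 2
    for _ in range(100):
        length = int(np.clip(rng.lognormal(mu, np.sqrt(sig2)), me - ms + 2 * MARGIN, L - 2 * MARGIN))
        lo = max(MARGIN, me + MARGIN // 2 - length)
        hi = min(ms - MARGIN // 2, L - MARGIN - length)
        if lo > hi:
            continue
        A = int(rng.integers(lo, hi + 1))
        B = A + length
        # optionally snap the amplification junction donor end into a REP
        # cassette (junction hotspot at structure-forming repeats)
        if rng.random() < cfg.rep_snap_prob:
            sites = [
                (rs, re)
                for rs, re in ref.rep_sites.get(EPISOME, [])
                if me + MARGIN < rs and re < L - MARGIN and rs > A + (me - A) + 100
            ]
            if sites:
                rs, re = sites[int(rng.integers(len(sites)))]
                B = int(rng.integers(rs + 1, re + 1))
        if A + MARGIN // 2 < ms and B > me + MARGIN // 2:
            return A, B
    raise RuntimeError("could not place amplicon")


def _place_away(
    rng: np.random.Generator,
    L: int,
    length: int,
    forbidden: list[tuple[int, int]],
    tries: int = 60,
) -> tuple[int, int] | None:
    for _ in range(tries):
        s = int(rng.integers(MARGIN, L - MARGIN - length))
        iv = (s, s + length)
        if all(iv[0] - MIN_EVENT_GAP >= e or iv[1] + MIN_EVENT_GAP <= b for b, e in forbidden):
            return iv
    return None


def _mh(rng: np.random.Generator, rng_range: tuple[int, int]) -> int:
    return int(rng.integers(rng_range[0], rng_range[1] + 1))


def build_isolate_plans(
    ref: ReferenceModel, cfg: CohortConfig, rng: np.random.Generator, group: str
) -> tuple[dict[str, SegmentPlan], str, str, dict]:
    """Draw one isolate's rearrangements on a private copy of the reference.

    Returns (plans, truth_primary, truth_secondary, params).  The passed
    ``ref`` must already be the isolate's own copy: builders plant
    junction microhomology into it.
    """
    plans: dict[str, SegmentPlan] = {}
    params: dict = {}
    truth_primary = "NONE"
    truth_secondary = ""
    epi_forbidden: list[tuple[int, int]] = [ref.marker_locus]

    if group == "amplified":
        copies = _draw_copies(rng, cfg)
        seed = int(rng.integers(2**31))
        u = rng.random()
        if u < cfg.p_eid:
            truth_primary = "EID"
            ms, me = ref.marker_locus
            L = ref.length(EPISOME)
            for _ in range(100):
                inner_len = int(rng.integers(*cfg.eid_inner_range))
                lo = max(2 * MARGIN, me + 200 - inner_len)
                hi = min(ms - 200, L - 2 * MARGIN - inner_len)
                if lo > hi:
                    continue
                p = int(rng.integers(lo, hi + 1))
                q = p + inner_len
                A = max(MARGIN, p - int(rng.integers(1_000, 6_000)))
                B = min(L - MARGIN, q + int(rng.integers(1_000, 6_000)))
                if A < p - 150 and q + 150 < B:
                    break
            else:
                raise RuntimeError("could not place embedded inverted duplication")
            mh_lens = (_mh(rng, cfg.mh_range), _mh(rng, cfg.mh_range))
            plan = rearrange.build_embedded_inverted_duplication(
                ref, (A, B), (p, q), copies, mh_lens, seed
            )
            params.update(amplicon=(A, B), inner=(p, q), copies=copies, mh_lens=mh_lens)
        elif u < cfg.p_eid + cfg.p_pia:
            truth_primary = "SPLIT_AMPLICON"
            ms, me = ref.marker_locus
            L = ref.length(EPISOME)
            for _ in range(100):
                left_len = int(rng.integers(8_000, 20_000))
                lo = max(MARGIN, me + 300 - left_len)
                hi = min(ms - 300, L - MARGIN - left_len)
                if lo > hi:
                    continue
                a1 = int(rng.integers(lo, hi + 1))
                b1 = a1 + left_len
                gap = int(rng.integers(1_000, 5_000))
                right_len = int(rng.integers(5_000, 15_000))
                a2, b2 = b1 + gap, b1 + gap + right_len
                if b2 < L - MARGIN:
                    break
            else:
                raise RuntimeError("could not place partially inverted amplification")
            mh_lens = (_mh(rng, cfg.mh_range), _mh(rng, cfg.mh_range))
            plan = rearrange.build_partially_inverted_amplification(
                ref, (a1, b1), (a2, b2), max(copies, 2), mh_lens, seed
            )
            params.update(left=(a1, b1), right=(a2, b2), copies=copies, mh_lens=mh_lens)
        elif u < cfg.p_eid + cfg.p_pia + cfg.p_embedded_del:
            truth_primary = "EMBEDDED_DEL"
            A, B = _draw_amplicon(rng, cfg, ref)
            ms, me = ref.marker_locus
            for _ in range(100):
                dlen = int(rng.integers(500, 3_000))
                zones = [(A + 200, ms - 200 - dlen), (me + 200, B - 200 - dlen)]
                zones = [(a, b) for a, b in zones if a < b]
                if not zones:
                    A, B = _draw_amplicon(rng, cfg, ref)
                    continue
                za, zb = zones[int(rng.integers(len(zones)))]
                p = int(rng.integers(za, zb))
                break
            else:
                raise RuntimeError("could not place embedded deletion")
            mh_lens = (_mh(rng, cfg.mh_range), _mh(rng, cfg.del_mh_range))
            plan = rearrange.build_embedded_deletion_amplicon(
                ref, (A, B), (p, p + dlen), max(copies, 2), mh_lens, seed
            )
            params.update(amplicon=(A, B), deleted=(p, p + dlen), copies=copies, mh_lens=mh_lens)
        else:
            truth_primary = "AMP"
            A, B = _draw_amplicon(rng, cfg, ref)
            mh_len = _mh(rng, cfg.mh_range)
            plan = rearrange.build_amplification(ref, (A, B), copies, mh_len, seed)
            params.update(amplicon=(A, B), copies=copies, mh_len=mh_len)
        plans[EPISOME] = plan
        span = plan.events[0].span
        epi_forbidden.append(span)
        p_del, p_inv = cfg.p_secondary_del, cfg.p_secondary_inv
    else:
        p_del, p_inv = cfg.p_secondary_control, 0.0

    v = rng.random()
    if v < p_del:
        truth_secondary = "SECONDARY_DEL"
        dlen = int(rng.integers(*cfg.del_len_range))
        mh_len = _mh(rng, cfg.del_mh_range)
        seed = int(rng.integers(2**31))
        target = CHROM if (group == "control" or rng.random() < 0.5) else EPISOME
        iv = None
        if target == EPISOME:
            iv = _place_away(rng, ref.length(EPISOME), dlen, epi_forbidden)
            if iv is None:
                target = CHROM
        if target == CHROM:
            # keep clear of masked intervals so the loss stays probe-visible
            iv = _place_away(rng, ref.length(CHROM), dlen, list(ref.mask.get(CHROM, [])))
        if iv is None:
            raise RuntimeError("could not place secondary deletion")
        dplan = rearrange.build_secondary_deletion(ref, iv, mh_len, seed, replicon=target)
        plans[target] = rearrange.compose(plans[target], dplan) if target in plans else dplan
        params.update(secondary_del=iv, secondary_del_replicon=target, secondary_mh=mh_len)
    elif v < p_del + p_inv:
        truth_secondary = "INV"
        L = ref.length(EPISOME)
        ms, me = ref.marker_locus
        ilen = int(rng.integers(*cfg.inv_len_range))
        window = (max(MARGIN, ms - 25_000), min(L - MARGIN, me + 25_000))
        iv = None
        for _ in range(80):
            s = int(rng.integers(window[0], window[1] - ilen))
            cand = (s, s + ilen)
            if all(cand[0] - MIN_EVENT_GAP >= e or cand[1] + MIN_EVENT_GAP <= b for b, e in epi_forbidden):
                iv = cand
                break
        if iv is None:
            iv = _place_away(rng, L, ilen, epi_forbidden)
        if iv is None:
            raise RuntimeError("could not place secondary inversion")
        offs = (int(rng.integers(-cfg.micro_indel_max, cfg.micro_indel_max + 1)),
                int(rng.integers(-cfg.micro_indel_max, cfg.micro_indel_max + 1)))
        seed = int(rng.integers(2**31))
        iplan = rearrange.build_inversion_with_indels(ref, iv, offs[0], offs[1], seed)
        plans[EPISOME] = rearrange.compose(plans[EPISOME], iplan) if EPISOME in plans else iplan
        params.update(secondary_inv=iv, offsets=offs)
    return plans, truth_primary, truth_secondary, params


# ---------------------------------------------------------------------------
# PCR inversion screen


def make_primer_panel(
    ref: ReferenceModel, half_window: int = 25_000, step: int = 2_000, length: int = 20
) -> list[bytes]:
    """Same-orientation 20-mers tiling the region around the marker."""
    seq = bytes(ref.seqs[EPISOME])
    ms, me = ref.marker_locus
    center = (ms + me) // 2
    panel = []
    for off in range(-half_window, half_window + 1, step):
        p = center + off
        if 0 <= p and p + length <= len(seq):
            panel.append(seq[p : p + length])
    return panel


def screen_plan(plan: SegmentPlan) -> SegmentPlan:
    """The plan with tandem copy numbers capped at 2 (inversion geometry
    is copy-number independent; capping keeps the screen molecule small)."""
    events = []
    for ev in plan.events:
        copies = ev.params.get("copies", 1)
        if copies <= 2 or ev.label not in ("AMP", "EID", "PIA", "EDE"):
            events.append(ev)
            continue
        if ev.label in ("AMP", "EID"):
            block = len(ev.unit) // copies
            unit = ev.unit[: 2 * block]
        elif ev.label == "PIA":
            unit = ev.unit[:2] + [ev.unit[-1]]
        else:  # EDE: alternating full / deleted units
            unit = ev.unit[:3]
        events.append(rearrange.Event(ev.label, ev.span, unit, ev.junctions, {**ev.params, "copies": 2}))
    return rearrange.assemble(plan.replicon_id, plan.length, events)


def run_inversion_screen(
    plans: dict[str, SegmentPlan], ref: ReferenceModel, panel: list[bytes], max_product: int = 20_000
) -> int:
    """Number of unidirectional-PCR products on the isolate's episome."""
    if EPISOME in plans:
        molecule = rearrange.realize_sequence(screen_plan(plans[EPISOME]), ref)
    else:
        molecule = ref.seq_str(EPISOME)
    return len(junctions.pcr_inversion_screen(molecule, panel, max_product))


# ---------------------------------------------------------------------------
# Cohort processing


def process_isolate(
    base_ref: ReferenceModel,
    cfg: CohortConfig,
    index: int,
    group: str,
    panel: list[bytes] | None,
) -> IsolateResult:
    rng = np.random.default_rng([cfg.seed, index])
    ref_i = base_ref.copy()
    plans, truth_primary, truth_secondary, params = build_isolate_plans(ref_i, cfg, rng, group)
    profiles = acgh.probe_profiles(plans, base_ref.array)
    table = acgh.simulate_ratios(profiles, None, base_ref.array, cfg.sigma, int(rng.integers(2**31)))
    callset = acgh.call_segments(table, base_ref)
    classifications = acgh.classify_events(callset, base_ref)
    classes = acgh.isolate_classes(classifications)
    n_products = 0
    if panel is not None:
        n_products = run_inversion_screen(plans, ref_i, panel)
        if n_products:
            classes.add("INV_PCR")
    return IsolateResult(
        isolate_id=f"{group[:3]}_{index:05d}",
        group=group,
        truth_primary=truth_primary,
        truth_secondary=truth_secondary,
        truth_params=params,
        plans=plans,
        callset=callset,
        classes=classes,
        n_inv_products=n_products,
    )


def iter_isolates(base_ref: ReferenceModel, cfg: CohortConfig, panel: list[bytes] | None):
    for i in range(cfg.n_amplified):
        yield process_isolate(base_ref, cfg, i, "amplified", panel)
    for i in range(cfg.n_control):
        yield process_isolate(base_ref, cfg, cfg.n_amplified + i, "control", panel)


def simulate_cohort(cfg: CohortConfig) -> tuple[ReferenceModel, list[IsolateResult]]:
    """Convenience wrapper: build the reference and process every isolate."""
    cfg.validate()
    base_ref = build_reference(cfg.genome, seed=cfg.seed)
    panel = make_primer_panel(base_ref) if cfg.pcr_screen else None
    return base_ref, list(iter_isolates(base_ref, cfg, panel))


# event-filter predicates for the two cohort comparisons
EXTRA_CLASSES = {"EID", "SPLIT_AMPLICON", "EMBEDDED_DEL", "SECONDARY_DEL", "INV_PCR", "UNCLASSIFIED"}


def any_extra_event(classes: set[str]) -> bool:
    """Any structural event beyond the plain marker amplification."""
    return bool(classes & EXTRA_CLASSES)


def secondary_event(classes: set[str]) -> bool:
    """Amplification-independent events: unlinked deletions, and PCR-
    detected inversions not already explained by the amplification's own
    inverted structure.  An embedded inverted duplication or a split
    amplicon places inverted sequence near the marker, so the
    unidirectional screen fires on those isolates too; without junction
    sequencing the screen cannot separate an additional independent
    inversion there, and the signal is attributed to the amplification
    event (a conservative undercount, mirroring the assay's logic)."""
    return "SECONDARY_DEL" in classes or (
        "INV_PCR" in classes and not classes & {"SPLIT_AMPLICON", "EID"}
    )


PRIMARY_ORDER = ["EID", "SPLIT_AMPLICON", "EMBEDDED_DEL", "AMP"]


def called_primary(classes: set[str]) -> str:
    for c in PRIMARY_ORDER:
        if c in classes:
            return c
    return "NONE"


@dataclass
class CohortReport:
    isolates: pd.DataFrame
    confusion: pd.DataFrame
    comparisons: dict[str, stats.CohortComparison]
    junction_summary: dict

    def to_json(self) -> dict:
        return {
            "n_isolates": int(len(self.isolates)),
            "confusion": {str(k): {str(kk): int(vv) for kk, vv in v.items()} for k, v in self.confusion.to_dict().items()},
            "comparisons": {k: v.to_dict() for k, v in self.comparisons.items()},
            "junction_summary": self.junction_summary,
        }


def summarize_junctions(
    results: list[IsolateResult], refs_by_isolate: dict[str, ReferenceModel] | None,
    base_ref: ReferenceModel, max_junctions: int = 400
) -> dict:
    """Microhomology / REP / hairpin-context summary over novel junctions.

    Junction sequence context lives on each isolate's own (edited)
    genome; when per-isolate references are not retained the designed
    parameters recorded in the plans are summarized instead.
    """
    mh: list[int] = []
    at_rep = 0
    n = 0
    struct_counts: dict[str, int] = {}
    for res in results:
        if n >= max_junctions:
            break
        ref_i = (refs_by_isolate or {}).get(res.isolate_id)
        for rep, plan in res.plans.items():
            if ref_i is None:
                for dj in plan.designed_junctions().values():
                    mh.append(dj.mh_len)
                    n += 1
                continue
            js = rearrange.unique_junctions(rearrange.junctions_of(plan, ref_i))
            for j in js:
                mh.append(j.measured_mh)
                if junctions.annotate_rep(j, ref_i.rep_sites.get(rep, [])):
                    at_rep += 1
                cls = secstruct.classify_junction_structure(j, ref_i.seqs[rep])
                struct_counts[cls] = struct_counts.get(cls, 0) + 1
                n += 1
    out = {
        "n_junctions": n,
        "mh_min": int(min(mh)) if mh else None,
        "mh_max": int(max(mh)) if mh else None,
        "mh_mean": float(np.mean(mh)) if mh else None,
    }
    if refs_by_isolate:
        out["rep_fraction"] = at_rep / n if n else None
        out["structure_classes"] = struct_counts
    return out


def run_pipeline(
    cfg: CohortConfig,
    outdir: str | Path,
    force: bool = False,
    keep_refs: bool = False,
    write_probe_tables: str = "events",  # none | events | all
) -> CohortReport:
    """Execute every stage and write FASTA/BED/TSV/JSON artifacts.

    The truth table is written before any calling output; classification
    reads only the simulated probe tables, never the truth.
    """
    cfg.validate()
    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()):
        if not force:
            raise FileExistsError(f"output directory {outdir} exists; pass force=True to overwrite")
        shutil.rmtree(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(outdir / "config.yaml")

    base_ref = build_reference(cfg.genome, seed=cfg.seed)
    write_reference(base_ref, outdir / "reference")
    panel = make_primer_panel(base_ref) if cfg.pcr_screen else None

    results: list[IsolateResult] = []
    refs_kept: dict[str, ReferenceModel] = {}
    truth_rows = []
    call_rows = []
    probe_dir = outdir / "probe_tables"
    for res in iter_isolates(base_ref, cfg, panel):
        results.append(res)
        truth_rows.append(
            {
                "isolate_id": res.isolate_id,
                "group": res.group,
                "truth_primary": res.truth_primary,
                "truth_secondary": res.truth_secondary,
                "params": json.dumps(res.truth_params),
            }
        )
        calls = res.callset.calls.copy()
        calls.insert(0, "isolate_id", res.isolate_id)
        call_rows.append(calls)
        has_event = res.truth_primary != "NONE" or res.truth_secondary
        if write_probe_tables == "all" or (write_probe_tables == "events" and has_event):
            probe_dir.mkdir(exist_ok=True)
            res.callset.table.to_csv(probe_dir / f"{res.isolate_id}.tsv", sep="\t", index=False)
        if keep_refs and has_event:
            rng = np.random.default_rng([cfg.seed, int(res.isolate_id.split("_")[1])])
            ref_i = base_ref.copy()
            build_isolate_plans(ref_i, cfg, rng, res.group)
            refs_kept[res.isolate_id] = ref_i

    truth = pd.DataFrame(truth_rows)
    truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    nonempty = [c for c in call_rows if not c.empty]
    if nonempty:
        pd.concat(nonempty, ignore_index=True).to_csv(outdir / "calls.tsv", sep="\t", index=False)
    else:
        call_rows[0].to_csv(outdir / "calls.tsv", sep="\t", index=False)

    amp_results = [r for r in results if r.group == "amplified"]
    ctrl_results = [r for r in results if r.group == "control"]
    comparisons = {
        "any_extra_event": stats.cohort_compare(
            [r.classes for r in amp_results], [r.classes for r in ctrl_results],
            any_extra_event, "any additional structural event",
        ),
        "secondary_only": stats.cohort_compare(
            [r.classes for r in amp_results], [r.classes for r in ctrl_results],
            secondary_event, "amplification-independent secondary events",
        ),
    }

    iso_frame = pd.DataFrame(
        {
            "isolate_id": [r.isolate_id for r in results],
            "group": [r.group for r in results],
            "truth_primary": [r.truth_primary for r in results],
            "truth_secondary": [r.truth_secondary for r in results],
            "called_primary": [called_primary(r.classes) for r in results],
            "called_classes": ["|".join(sorted(r.classes)) for r in results],
        }
    )
    confusion = pd.crosstab(iso_frame["truth_primary"], iso_frame["called_primary"])
    junction_summary = summarize_junctions(
        [r for r in results if r.plans], refs_kept if keep_refs else None, base_ref
    )

    report = CohortReport(iso_frame, confusion, comparisons, junction_summary)
    iso_frame.to_csv(outdir / "classifications.tsv", sep="\t", index=False)
    with open(outdir / "report.json", "w") as fh:
        json.dump(report.to_json(), fh, indent=2)
    _write_markdown_report(report, outdir / "report.md")
    return report


def _write_markdown_report(report: CohortReport, path: Path) -> None:
    lines = ["# Cohort report", ""]
    n_amp = int((report.isolates["group"] == "amplified").sum())
    n_ctrl = int((report.isolates["group"] == "control").sum())
    lines += [f"Isolates: {n_amp} amplified, {n_ctrl} control", "", "## Comparisons", ""]
    for key, cmpn in report.comparisons.items():
        t = cmpn.table
        lines.append(f"### {key}: {cmpn.label}")
        lines.append(f"- table a={t.a} b={t.b} c={t.c} d={t.d}")
        if cmpn.peto.defined:
            lo, hi = cmpn.peto.ci95
            lines.append(
                f"- Peto OR {stats.round_half_up(cmpn.peto.or_hat, 1)} "
                f"(95% CI {stats.round_half_up(lo, 1)}-{stats.round_half_up(hi, 1)})"
            )
        else:
            lines.append("- Peto OR undefined (no events in either cohort)")
        lines.append(f"- Fisher exact p = {cmpn.fisher_p:.3g}")
        lines.append("")
    lines += ["## Truth vs called primary class", "", report.confusion.to_string(), ""]
    lines += ["## Junctions", "", json.dumps(report.junction_summary, indent=2), ""]
    path.write_text("\n".join(lines))


# ---------------------------------------------------------------------------
# Calibration (parameter recovery / CI coverage)


#: odds ratio used as the generating truth for coverage calibration:
#: the secondary-event comparison's own Peto estimate
CALIBRATION_OR = 6.2


def calibration_config(seed: int, p_amplified: float = 0.02) -> CohortConfig:
    """Study conditions for the coverage/bias calibration.

    Amplified isolates carry amplification plus a secondary deletion
    with probability ``p_amplified``; controls carry a secondary
    deletion at the rate that makes the generating odds ratio equal
    CALIBRATION_OR (a zero control rate would make the generating odds
    ratio infinite and coverage meaningless).  Secondary events are
    deletions only (array-visible); the PCR-only inversion channel is
    excluded from a check of detection unbiasedness.
    """
    odds1 = p_amplified / (1 - p_amplified)
    odds2 = odds1 / CALIBRATION_OR
    return CohortConfig(
        p_eid=0.0,
        p_pia=0.0,
        p_embedded_del=0.0,
        p_secondary_del=p_amplified,
        p_secondary_inv=0.0,
        p_secondary_control=odds2 / (1 + odds2),
        sigma=0.2,
        pcr_screen=False,
        seed=seed,
    )


def calibration_run(n_cohorts: int = 200, master_seed: int = 0) -> dict:
    """Repeated-cohort calibration at sigma = 0.2.

    Returns the mean bias of the called secondary-event frequency in the
    amplified arm (true value 0.02) and the coverage of the Peto 95% CI
    for the generating odds ratio, over ``n_cohorts`` seeded cohorts.
    """
    base_cfg = calibration_config(master_seed)
    base_ref = build_reference(base_cfg.genome, seed=master_seed)
    freqs = []
    covered = 0
    defined = 0
    for k in range(n_cohorts):
        cfg = dataclasses.replace(base_cfg, seed=int(np.random.default_rng([master_seed, 7, k]).integers(2**31)))
        amp_classes, ctrl_classes = [], []
        for res in iter_isolates(base_ref, cfg, None):
            (amp_classes if res.group == "amplified" else ctrl_classes).append(res.classes)
        cmpn = stats.cohort_compare(amp_classes, ctrl_classes, secondary_event, "calibration")
        freqs.append(cmpn.table.a / cfg.n_amplified)
        if cmpn.peto.defined:
            defined += 1
            lo, hi = cmpn.peto.ci95
            if lo <= CALIBRATION_OR <= hi:
                covered += 1
    return {
        "n_cohorts": n_cohorts,
        "true_frequency": 0.02,
        "mean_called_frequency": float(np.mean(freqs)),
        "bias": float(np.mean(freqs) - 0.02),
        "defined_cohorts": defined,
        "coverage": covered / defined if defined else float("nan"),
        "generating_or": CALIBRATION_OR,
    }
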