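"""Synthetic reference genomes for the amplification-instability pipeline.

The model system is a circular bacterial chromosome plus a circular
F'-like episome.  The episome carries a block of chromosomal sequence
copied verbatim (the "shared block", the analogue of the IS3-bounded
chromosomal segment on F'128), and inside that block a selectable marker
locus (the *lac* analogue).  Pseudopalindromic ~38-nt REP cassettes are
planted in clusters on both replicons; a tiling oligonucleotide probe
array (default one probe per 100 nt) covers both replicons except for
masked repeat/prophage-like intervals.

Coordinates are 0-based half-open throughout; BED output is native.
"""

from __future__ import annotations

import copy as _copy
import dataclasses
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._seq import random_dna, revcomp, sha256_of

CHROM = "chromosome"
EPISOME = "episome"

Interval = tuple[int, int]


class ConfigError(ValueError):
    """Raised for inconsistent simulation configuration."""


@dataclass
class SimConfig:
    """Geometry of the synthetic reference.

    Defaults are desk-scale (200 kb + 100 kb instead of 4.6 Mb + ~100 kb)
    so the full pipeline runs in seconds; everything is configurable.
    """

    chrom_len: int = 200_000
    episome_len: int = 100_000
    #: interval on the chromosome copied verbatim into the episome
    shared_block: Interval = (120_000, 160_000)
    #: start of the shared-block image on the episome
    shared_image_start: int = 30_000
    #: marker locus ("lac"), episome coordinates, inside the shared image
    marker_locus: Interval = (46_000, 49_000)
    probe_spacing: int = 100
    #: episome probes may be tiled at a different density
    episome_probe_spacing: int | None = None
    #: masked intervals (repeat/prophage analogue), excluded from calling
    mask: dict[str, list[Interval]] = field(
        default_factory=lambda: {CHROM: [(20_000, 26_000), (80_000, 84_000)], EPISOME: []}
    )
    #: number of REP cassette clusters per replicon
    rep_clusters: dict[str, int] = field(default_factory=lambda: {CHROM: 10, EPISOME: 8})
    rep_cassette_len: int = 38
    rep_stem_range: Interval = (12, 16)
    rep_loop_range: Interval = (4, 8)
    rep_max_mismatch: int = 2
    rep_cluster_size: Interval = (2, 4)  # cassettes per cluster, inclusive

    def validate(self) -> None:
        if self.chrom_len <= 0 or self.episome_len <= 0:
            raise ConfigError("replicon lengths must be positive")
        bs, be = self.shared_block
        if not (0 <= bs < be <= self.chrom_len):
            raise ConfigError("shared_block outside chromosome")
        if be - bs >= self.chrom_len:
            raise ConfigError("shared_block must be shorter than the chromosome")
        img = (self.shared_image_start, self.shared_image_start + (be - bs))
        if img[1] > self.episome_len:
            raise ConfigError("shared-block image outside episome")
        ms, me = self.marker_locus
        if not (img[0] <= ms < me <= img[1]):
            raise ConfigError("marker locus must lie inside the shared-block image")
        if self.probe_spacing < 1:
            raise ConfigError("probe spacing must be >= 1")


@dataclass
class ProbeArray:
    """Ordered tiling probes per replicon (positions strictly increasing)."""

    positions: dict[str, np.ndarray]
    ids: dict[str, list[str]]
    spacing: dict[str, int]

    @property
    def n_probes(self) -> int:
        return sum(len(p) for p in self.positions.values())

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for rep in sorted(self.positions):
            rows.append(
                pd.DataFrame(
                    {"replicon": rep, "pos": self.positions[rep], "probe_id": self.ids[rep]}
                )
            )
        return pd.concat(rows, ignore_index=True)


@dataclass
class ReferenceModel:
    """The synthetic chromosome + episome reference all modules consume.

    Sequences are mutable bytearrays: rearrangement builders plant
    junction microhomology by point-editing an isolate's *copy* of the
    model.  A freshly built model satisfies the shared-block identity
    invariant exactly; edited isolate copies may differ at planted bases.
    """

    seqs: dict[str, bytearray]
    shared_block: Interval            # chromosome coordinates
    shared_image: Interval            # episome coordinates
    marker_locus: Interval            # episome coordinates
    rep_sites: dict[str, list[Interval]]
    mask: dict[str, list[Interval]]
    array: ProbeArray
    config: SimConfig

    def seq_str(self, replicon: str) -> str:
        return self.seqs[replicon].decode()

    def length(self, replicon: str) -> int:
        return len(self.seqs[replicon])

    @property
    def replicons(self) -> list[str]:
        return sorted(self.seqs)

    def copy(self) -> "ReferenceModel":
        new = _copy.copy(self)
        new.seqs = {k: bytearray(v) for k, v in self.seqs.items()}
        return new

    def fasta_sha256(self) -> str:
        return sha256_of(b"".join(bytes(self.seqs[r]) for r in self.replicons))


def _make_rep_cassette(cfg: SimConfig, rng: np.random.Generator) -> bytearray:
    """One ~38-nt pseudopalindromic cassette: stem-loop-stem' plus random pad.

    stem' is the reverse complement of stem with up to ``rep_max_mismatch``
    substitutions, mimicking the imperfect palindromy of real REP elements.
    """
    stem = int(rng.integers(cfg.rep_stem_range[0], cfg.rep_stem_range[1] + 1))
    loop = int(rng.integers(cfg.rep_loop_range[0], cfg.rep_loop_range[1] + 1))
    core = 2 * stem + loop
    if core > cfg.rep_cassette_len:
        stem = (cfg.rep_cassette_len - loop) // 2
        core = 2 * stem + loop
    s1 = random_dna(stem, rng)
    lp = random_dna(loop, rng)
    s2 = bytearray(revcomp(bytes(s1)))
    n_mm = int(rng.integers(0, cfg.rep_max_mismatch + 1))
    for pos in rng.choice(stem, size=min(n_mm, stem), replace=False):
        old = s2[pos]
        choices = [b for b in b"ACGT" if b != old]
        s2[pos] = int(rng.choice(choices))
    pad = cfg.rep_cassette_len - core
    left = random_dna(pad // 2, rng)
    right = random_dna(pad - pad // 2, rng)
    return left + s1 + lp + s2 + right


def _plant_rep_clusters(
    seq: bytearray,
    n_clusters: int,
    cfg: SimConfig,
    rng: np.random.Generator,
    forbidden: list[Interval],
) -> list[Interval]:
    """Plant clusters of 2-4 cassettes; returns one interval per cassette."""
    sites: list[Interval] = []
    L = len(seq)
    attempts = 0
    placed = 0
    while placed < n_clusters and attempts < 200 * max(n_clusters, 1):
        attempts += 1
        k = int(rng.integers(cfg.rep_cluster_size[0], cfg.rep_cluster_size[1] + 1))
        span = k * (cfg.rep_cassette_len + 10)
        start = int(rng.integers(500, L - span - 500))
        block = (start - 100, start + span + 100)
        if any(block[0] < e and b < block[1] for b, e in forbidden):
            continue
        pos = start
        for _ in range(k):
            cass = _make_rep_cassette(cfg, rng)
            seq[pos : pos + len(cass)] = cass
            sites.append((pos, pos + len(cass)))
            pos += len(cass) + int(rng.integers(2, 11))
        forbidden.append(block)
        placed += 1
    return sites


def _build_probes(cfg: SimConfig, mask: dict[str, list[Interval]], lengths: dict[str, int]) -> ProbeArray:
    positions: dict[str, np.ndarray] = {}
    ids: dict[str, list[str]] = {}
    spacing: dict[str, int] = {}
    for rep in sorted(lengths):
        sp = cfg.probe_spacing
        if rep == EPISOME and cfg.episome_probe_spacing is not None:
            sp = cfg.episome_probe_spacing
        pos = np.arange(0, lengths[rep] - lengths[rep] % sp, sp, dtype=np.int64)
        keep = np.ones(len(pos), dtype=bool)
        for s, e in mask.get(rep, []):
            keep &= ~((pos >= s) & (pos < e))
        pos = pos[keep]
        positions[rep] = pos
        ids[rep] = [f"{rep}_{i:06d}" for i in range(len(pos))]
        spacing[rep] = sp
    return ProbeArray(positions=positions, ids=ids, spacing=spacing)


def build_reference(config: SimConfig | None = None, seed: int = 0) -> ReferenceModel:
    """Build the synthetic reference; deterministic for a fixed seed.

    Base composition is i.i.d. uniform over {A,C,G,T} outside the planted
    REP cassettes.  REP cassettes inside the shared block are copied to
    the episome along with the block so the identity invariant holds.
    """
    cfg = config or SimConfig()
    cfg.validate()
    rng = np.random.default_rng(seed)

    chrom = random_dna(cfg.chrom_len, rng)
    episome = random_dna(cfg.episome_len, rng)

    bs, be = cfg.shared_block
    img = (cfg.shared_image_start, cfg.shared_image_start + (be - bs))

    # REP on the chromosome (clusters may fall inside the shared block;
    # those are inherited by the episome via the block copy).
    chrom_forbidden = [iv for iv in cfg.mask.get(CHROM, [])]
    chrom_sites = _plant_rep_clusters(chrom, cfg.rep_clusters.get(CHROM, 0), cfg, rng, chrom_forbidden)

    # Copy the shared block into the episome.
    episome[img[0] : img[1]] = chrom[bs:be]

    # Episome REP: inherited sites inside the image, plus fresh clusters
    # planted outside the image (never over the image, to preserve identity).
    epi_sites = [(s - bs + img[0], e - bs + img[0]) for s, e in chrom_sites if s >= bs and e <= be]
    epi_forbidden = [img] + list(cfg.mask.get(EPISOME, []))
    epi_sites += _plant_rep_clusters(episome, cfg.rep_clusters.get(EPISOME, 0), cfg, rng, epi_forbidden)

    lengths = {CHROM: cfg.chrom_len, EPISOME: cfg.episome_len}
    array = _build_probes(cfg, cfg.mask, lengths)

    model = ReferenceModel(
        seqs={CHROM: chrom, EPISOME: episome},
        shared_block=(bs, be),
        shared_image=img,
        marker_locus=cfg.marker_locus,
        rep_sites={CHROM: sorted(chrom_sites), EPISOME: sorted(epi_sites)},
        mask={k: sorted(v) for k, v in cfg.mask.items()},
        array=array,
        config=cfg,
    )
    return model


# ---------------------------------------------------------------------------
# I/O


def _write_bed(path: Path, rows: list[tuple[str, int, int, str]]) -> None:
    with open(path, "w") as fh:
        for rep, s, e, name in rows:
            fh.write(f"{rep}\t{s}\t{e}\t{name}\n")


def _read_bed(path: Path) -> list[tuple[str, int, int, str]]:
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            rep, s, e, name = line.rstrip("\n").split("\t")[:4]
            rows.append((rep, int(s), int(e), name))
    return rows


def write_reference(model: ReferenceModel, outdir: str | Path) -> dict[str, Path]:
    """Write FASTA + BED + probe manifest + YAML geometry; round-trips."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": outdir / "reference.fasta",
        "shared": outdir / "shared_block.bed",
        "marker": outdir / "marker_locus.bed",
        "rep": outdir / "rep_sites.bed",
        "mask": outdir / "mask.bed",
        "probes": outdir / "probes.tsv",
        "meta": outdir / "reference.yaml",
    }
    records = [
        SeqRecord(Seq(model.seq_str(rep)), id=rep, description=f"length={model.length(rep)} circular")
        for rep in model.replicons
    ]
    SeqIO.write(records, paths["fasta"], "fasta")
    _write_bed(
        paths["shared"],
        [
            (CHROM, *model.shared_block, "shared_block"),
            (EPISOME, *model.shared_image, "shared_block_image"),
        ],
    )
    _write_bed(paths["marker"], [(EPISOME, *model.marker_locus, "marker")])
    _write_bed(
        paths["rep"],
        [(rep, s, e, f"REP_{i:03d}") for rep in model.replicons for i, (s, e) in enumerate(model.rep_sites.get(rep, []))],
    )
    _write_bed(
        paths["mask"],
        [(rep, s, e, f"mask_{i:02d}") for rep in model.replicons for i, (s, e) in enumerate(model.mask.get(rep, []))],
    )
    model.array.to_frame().to_csv(paths["probes"], sep="\t", index=False)
    meta = dataclasses.asdict(model.config)
    with open(paths["meta"], "w") as fh:
        yaml.safe_dump(meta, fh)
    return paths


def read_reference(indir: str | Path) -> ReferenceModel:
    """Reconstruct a ReferenceModel written by :func:`write_reference`."""
    indir = Path(indir)
    with open(indir / "reference.yaml") as fh:
        meta = yaml.safe_load(fh)
    for key in ("shared_block", "marker_locus", "rep_stem_range", "rep_loop_range", "rep_cluster_size"):
        meta[key] = tuple(meta[key])
    meta["mask"] = {k: [tuple(iv) for iv in v] for k, v in meta["mask"].items()}
    cfg = SimConfig(**meta)
    seqs: dict[str, bytearray] = {}
    for rec in SeqIO.parse(indir / "reference.fasta", "fasta"):
        seqs[rec.id] = bytearray(str(rec.seq).upper().encode())
        declared = int(rec.description.split("length=")[1].split()[0])
        if declared != len(seqs[rec.id]):
            warnings.warn(f"FASTA header length mismatch for {rec.id}")
    shared_rows = _read_bed(indir / "shared_block.bed")
    shared_block = next((s, e) for rep, s, e, _ in shared_rows if rep == CHROM)
    shared_image = next((s, e) for rep, s, e, _ in shared_rows if rep == EPISOME)
    marker = next((s, e) for _, s, e, _ in _read_bed(indir / "marker_locus.bed"))
    rep_sites: dict[str, list[Interval]] = {r: [] for r in seqs}
    for rep, s, e, _ in _read_bed(indir / "rep_sites.bed"):
        rep_sites[rep].append((s, e))
    mask: dict[str, list[Interval]] = {r: [] for r in seqs}
    for rep, s, e, _ in _read_bed(indir / "mask.bed"):
        mask[rep].append((s, e))
    probes = pd.read_csv(indir / "probes.tsv", sep="\t")
    positions = {rep: grp["pos"].to_numpy() for rep, grp in probes.groupby("replicon")}
    ids = {rep: list(grp["probe_id"]) for rep, grp in probes.groupby("replicon")}
    spacing = {}
    for rep in seqs:
        sp = cfg.probe_spacing
        if rep == EPISOME and cfg.episome_probe_spacing is not None:
            sp = cfg.episome_probe_spacing
        spacing[rep] = sp
    array = ProbeArray(positions=positions, ids=ids, spacing=spacing)
    return ReferenceModel(
        seqs=seqs,
        shared_block=shared_block,
        shared_image=shared_image,
        marker_locus=marker,
        rep_sites={k: sorted(v) for k, v in rep_sites.items()},
        mask={k: sorted(v) for k, v in mask.items()},
        array=array,
        config=cfg,
    )
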