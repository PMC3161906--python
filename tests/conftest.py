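"""Shared fixtures: references are built once per session (deterministic
seeds) and never mutated directly — tests that plant junctions work on
``ref.copy()``."""

import pytest

from ampshower.synthetic_genome import SimConfig, build_reference


@pytest.fixture(scope="session")
def ref():
    """Default desk-scale reference (200 kb chromosome + 100 kb episome)."""
    return build_reference(seed=7)


@pytest.fixture(scope="session")
def tiny_ref():
    """Small reference for brute-force oracles and property tests."""
    cfg = SimConfig(
        chrom_len=20_000,
        episome_len=10_000,
        shared_block=(2_000, 6_000),
        shared_image_start=1_000,
        marker_locus=(2_000, 2_600),
        mask={"chromosome": [], "episome": []},
        rep_clusters={"chromosome": 2, "episome": 2},
    )
    return build_reference(cfg, seed=3)
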