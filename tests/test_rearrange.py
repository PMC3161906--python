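"""Segment plans: realization, copy-number conservation, builders,
designed-microhomology round trips."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ampshower import rearrange as rr
from ampshower._junction import measure_mh
from ampshower._seq import revcomp
from ampshower.synthetic_genome import CHROM, EPISOME


def segments_strategy(L):
    seg = st.tuples(
        st.integers(0, L - 2), st.integers(1, L), st.sampled_from("+-")
    ).map(lambda t: (min(t[0], t[1] - 1), max(t[0] + 1, t[1]), t[2]))
    return st.lists(seg, min_size=1, max_size=8)


def test_identity_plan_realizes_reference(ref):
    for rep in ref.replicons:
        plan = rr.identity_plan(ref, rep)
        assert rr.realize_sequence(plan, ref) == ref.seq_str(rep)
        assert rr.junctions_of(plan, ref) == []


def test_realize_hand_example(tiny_ref):
    # [(0,10,+),(0,10,-)] realizes prefix + its reverse complement
    prefix = tiny_ref.seq_str(EPISOME)[:10]
    plan = rr.SegmentPlan(EPISOME, tiny_ref.length(EPISOME), [(0, 10, "+"), (0, 10, "-")])
    assert rr.realize_sequence(plan, tiny_ref) == prefix + revcomp(prefix)


def test_out_of_bounds_segment_rejected(tiny_ref):
    L = tiny_ref.length(EPISOME)
    plan = rr.SegmentPlan(EPISOME, L, [(0, L + 1, "+")])
    with pytest.raises(rr.PlanError):
        rr.realize_sequence(plan, tiny_ref)


@settings(derandomize=True, max_examples=60, deadline=None)
@given(segs=segments_strategy(10_000))
def test_length_additivity_and_conservation(tiny_ref, segs):
    plan = rr.SegmentPlan(EPISOME, tiny_ref.length(EPISOME), segs)
    realized = rr.realize_sequence(plan, tiny_ref)
    assert len(realized) == sum(b - a for a, b, _ in segs)
    profile = rr.copy_number_profile(plan)
    assert profile.sum() == len(realized)


@settings(derandomize=True, max_examples=40, deadline=None)
@given(segs=segments_strategy(10_000))
def test_profile_matches_bruteforce_counting(tiny_ref, segs):
    plan = rr.SegmentPlan(EPISOME, tiny_ref.length(EPISOME), segs)
    profile = rr.copy_number_profile(plan)
    brute = np.zeros(tiny_ref.length(EPISOME), dtype=int)
    for a, b, _ in segs:
        for pos in range(a, b):
            brute[pos] += 1
    assert np.array_equal(profile, brute)


def test_profile_at_positions_agrees_with_per_base(tiny_ref):
    rng = np.random.default_rng(5)
    L = tiny_ref.length(EPISOME)
    segs = []
    for _ in range(6):
        a = int(rng.integers(0, L - 10))
        b = int(rng.integers(a + 1, L))
        segs.append((a, b, "+-"[int(rng.integers(2))]))
    plan = rr.SegmentPlan(EPISOME, L, segs)
    pos = np.sort(rng.choice(L, size=200, replace=False))
    assert np.array_equal(
        rr.profile_at_positions(plan, pos), rr.copy_number_profile(plan)[pos]
    )


# ---------------------------------------------------------------------------
# Builders


def test_amplification_profile_and_junction(ref):
    r = ref.copy()
    plan = rr.build_amplification(r, (40_000, 62_000), copies=70, mh_len=5, seed=1)
    profile = rr.copy_number_profile(plan)
    assert (profile[40_000:62_000] == 70).all()
    assert profile[:40_000].max() == 1 and profile[62_000:].max() == 1
    js = rr.unique_junctions(rr.junctions_of(plan, r))
    assert len(js) == 1
    assert js[0].measured_mh == 5
    assert len(js[0].mh_seq) == 5


def test_amplification_two_copies_single_junction(ref):
    r = ref.copy()
    plan = rr.build_amplification(r, (40_000, 62_000), copies=2, mh_len=3, seed=2)
    assert len(rr.junctions_of(plan, r)) == 1  # one duplication junction


def test_amplification_without_marker_warns(ref):
    r = ref.copy()
    with pytest.warns(UserWarning, match="not selectable"):
        rr.build_amplification(r, (5_000, 20_000), copies=3, mh_len=4, seed=3)


def test_eid_profile_and_junctions(ref):
    r = ref.copy()
    plan = rr.build_embedded_inverted_duplication(
        r, (38_000, 70_000), (44_000, 55_000), copies=4, mh_lens=(3, 30), seed=2
    )
    profile = rr.copy_number_profile(plan)
    assert profile[39_000] == 4 and profile[69_000] == 4
    assert profile[50_000] == 8  # inner at twice the amplicon copy
    js = {j.label: j for j in rr.unique_junctions(rr.junctions_of(plan, r))}
    # two template-switch junctions plus the ordinary tandem boundary
    assert set(js) == {"switch1", "switch2", "amplification"}
    assert js["switch1"].measured_mh == 3
    assert js["switch2"].measured_mh == 30


def test_eid_precursor_copies_one(ref):
    # the pre-crossing-over structure: flanks at 1, inner at 2, 2 junctions
    r = ref.copy()
    plan = rr.build_embedded_inverted_duplication(
        r, (38_000, 70_000), (44_000, 55_000), copies=1, mh_lens=(5, 5), seed=4
    )
    profile = rr.copy_number_profile(plan)
    assert profile[39_000] == 1 and profile[50_000] == 2
    assert len(rr.unique_junctions(rr.junctions_of(plan, r))) == 2


def test_eid_triplication_layout(ref):
    r = ref.copy()
    plan = rr.build_embedded_inverted_duplication(
        r, (38_000, 70_000), (44_000, 55_000), copies=2, mh_lens=(4, 4), seed=5,
        triplication=True,
    )
    profile = rr.copy_number_profile(plan)
    assert profile[39_000] == 2
    assert profile[50_000] == 6  # inner three times per unit


def test_eid_requires_marker_in_inner(ref):
    r = ref.copy()
    with pytest.raises(rr.PlanError, match="marker"):
        rr.build_embedded_inverted_duplication(
            r, (38_000, 70_000), (52_000, 60_000), copies=2, mh_lens=(3, 3), seed=6
        )
    # explicit override allowed
    plan = rr.build_embedded_inverted_duplication(
        r, (38_000, 70_000), (52_000, 60_000), copies=2, mh_lens=(3, 3), seed=6,
        require_marker=False,
    )
    assert plan.events[0].label == "EID"


def test_pia_profile_and_two_junction_types(ref):
    r = ref.copy()
    plan = rr.build_partially_inverted_amplification(
        r, (40_000, 55_000), (58_000, 66_000), copies=10, mh_lens=(8, 8), seed=3
    )
    profile = rr.copy_number_profile(plan)
    assert (profile[40_000:55_000] == 10).all()
    assert (profile[58_000:66_000] == 10).all()
    assert (profile[55_100:57_900] == 1).all()  # unchanged gap
    assert len(rr.unique_junctions(rr.junctions_of(plan, r))) == 2
    assert profile.sum() == plan.total_length()


def test_pia_overlapping_parts_rejected(ref):
    r = ref.copy()
    with pytest.raises(rr.PlanError):
        rr.build_partially_inverted_amplification(
            r, (40_000, 58_000), (50_000, 66_000), copies=3, mh_lens=(5, 5), seed=1
        )


def test_embedded_deletion_half_copy(ref):
    r = ref.copy()
    plan = rr.build_embedded_deletion_amplicon(
        r, (40_000, 62_000), (52_000, 54_000), copies=4, mh_lens=(5, 3), seed=4
    )
    profile = rr.copy_number_profile(plan)
    assert (profile[40_000:52_000] == 4).all()
    assert (profile[52_000:54_000] == 2).all()  # 2-fold less than the amplicon
    js = rr.unique_junctions(rr.junctions_of(plan, r))
    assert len(js) == 2
    # all junction sides in direct orientation
    for j in js:
        assert j.donor.strand == "+" and j.acceptor.strand == "+"


def test_embedded_deletion_zero_length_degenerates_to_amplification(ref):
    r = ref.copy()
    plan = rr.build_embedded_deletion_amplicon(
        r, (40_000, 62_000), (52_000, 52_000), copies=4, mh_lens=(5, 3), seed=4
    )
    assert plan.events[0].label == "AMP"


def test_embedded_deletion_over_marker_rejected(ref):
    r = ref.copy()
    with pytest.raises(rr.PlanError, match="marker"):
        rr.build_embedded_deletion_amplicon(
            r, (40_000, 62_000), (45_000, 50_000), copies=4, mh_lens=(5, 3), seed=4
        )


def test_inversion_length_bookkeeping(ref):
    r = ref.copy()
    L = ref.length(EPISOME)
    plan = rr.build_inversion_with_indels(r, (20_000, 25_000), 12, -7, seed=5)
    assert len(rr.realize_sequence(plan, r)) == L + 5
    profile = rr.copy_number_profile(plan)
    assert set(np.unique(profile[19_800:25_200])) <= {0, 1, 2}


def test_reciprocal_inversion_preserves_length(ref):
    r = ref.copy()
    L = ref.length(EPISOME)
    plan = rr.build_inversion_with_indels(r, (20_000, 25_000), 0, 0, seed=6)
    assert len(rr.realize_sequence(plan, r)) == L
    assert (rr.copy_number_profile(plan) == 1).all()


def test_inversion_offset_bounds(ref):
    r = ref.copy()
    with pytest.raises(rr.PlanError):
        rr.build_inversion_with_indels(r, (20_000, 25_000), 101, 0, seed=7)


def test_secondary_deletion_conservation(ref):
    r = ref.copy()
    L = ref.length(EPISOME)
    plan = rr.build_secondary_deletion(r, (10_000, 11_600), mh_len=2, seed=6)
    profile = rr.copy_number_profile(plan)
    assert (profile[10_000:11_600] == 0).all()
    assert profile.sum() == L - 1_600


def test_secondary_deletion_over_marker_rejected(ref):
    r = ref.copy()
    with pytest.raises(rr.PlanError):
        rr.build_secondary_deletion(r, (45_000, 50_000), mh_len=2, seed=6)


def test_compose_amplification_plus_deletion(ref):
    r = ref.copy()
    amp = rr.build_amplification(r, (40_000, 62_000), 70, 5, seed=1)
    dele = rr.build_secondary_deletion(r, (80_000, 81_600), 2, seed=6)
    combined = rr.compose(amp, dele)
    assert len(rr.unique_junctions(rr.junctions_of(combined, r))) == 2
    profile = rr.copy_number_profile(combined)
    assert profile[45_000] == 70 and profile[80_500] == 0


def test_compose_rejects_nearby_events(ref):
    r = ref.copy()
    amp = rr.build_amplification(r, (40_000, 62_000), 5, 5, seed=1)
    dele = rr.build_secondary_deletion(r, (62_100, 63_000), 2, seed=6)
    with pytest.raises(rr.PlanError):
        rr.compose(amp, dele)


# ---------------------------------------------------------------------------
# Properties across builders


def _random_builder_plan(ref, rng, kind):
    r = ref.copy()
    seed = int(rng.integers(2**31))
    if kind == 0:
        k = int(rng.integers(0, 31))
        plan = rr.build_amplification(r, (40_000, 62_000), int(rng.integers(2, 90)), k, seed)
    elif kind == 1:
        ks = (int(rng.integers(0, 31)), int(rng.integers(0, 31)))
        plan = rr.build_embedded_inverted_duplication(
            r, (38_000, 70_000), (44_000, 55_000), int(rng.integers(1, 6)), ks, seed
        )
    elif kind == 2:
        ks = (int(rng.integers(0, 31)), int(rng.integers(0, 31)))
        plan = rr.build_partially_inverted_amplification(
            r, (40_000, 55_000), (58_000, 66_000), int(rng.integers(2, 10)), ks, seed
        )
    elif kind == 3:
        ks = (int(rng.integers(0, 31)), int(rng.integers(0, 5)))
        plan = rr.build_embedded_deletion_amplicon(
            r, (40_000, 62_000), (52_000, 54_000), int(rng.integers(2, 8)), ks, seed
        )
    elif kind == 4:
        plan = rr.build_inversion_with_indels(
            r, (20_000, 25_000), int(rng.integers(-50, 51)), int(rng.integers(-50, 51)), seed
        )
    else:
        end = 10_000 + int(rng.integers(200, 7_500))
        plan = rr.build_secondary_deletion(r, (10_000, end), int(rng.integers(0, 5)), seed)
    return r, plan


def test_conservation_property_across_builders(ref):
    # conservation: sum(profile) == sum of segment lengths, 200+ random cases
    rng = np.random.default_rng(42)
    for trial in range(210):
        r, plan = _random_builder_plan(ref, rng, trial % 6)
        assert rr.copy_number_profile(plan).sum() == plan.total_length()


def test_designed_microhomology_roundtrip_across_builders(ref):
    # designed mh equals measured mh for every builder and junction type
    rng = np.random.default_rng(43)
    for trial in range(120):
        r, plan = _random_builder_plan(ref, rng, trial % 6)
        seq = r.seqs[plan.replicon_id]
        for dj in plan.designed_junctions().values():
            _, _, mh, _ = measure_mh(seq, dj.donor, dj.acceptor)
            assert mh == dj.mh_len, (dj.label, dj.mh_len, mh)
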