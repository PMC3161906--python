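"""Ratio simulation, the adjacent-probe calling rule, and structure
classification."""

import numpy as np
import pandas as pd
import pytest

from ampshower import acgh
from ampshower import rearrange as rr
from ampshower.synthetic_genome import CHROM, EPISOME


def _flat_profiles(ref):
    return {rep: np.ones(len(pos), dtype=int) for rep, pos in ref.array.positions.items()}


def _table_with(ref, replicon, ratios_at):
    """Probe table with all ratios zero except {pos: log2} overrides."""
    profiles = _flat_profiles(ref)
    table = acgh.simulate_ratios(profiles, None, ref.array, sigma=0.0, seed=0)
    for pos, value in ratios_at.items():
        sel = (table["replicon"] == replicon) & (table["pos"] == pos)
        assert sel.sum() == 1, f"no probe at {replicon}:{pos}"
        table.loc[sel, "log2_ratio"] = value
    return table


def test_sigma_zero_identical_profiles_give_zero_ratios(ref):
    table = acgh.simulate_ratios(_flat_profiles(ref), None, ref.array, 0.0, 0)
    assert (table["log2_ratio"] == 0).all()


def test_amplicon_ratio_closed_form(ref):
    r = ref.copy()
    plan = rr.build_amplification(r, (40_000, 62_000), copies=70, mh_len=5, seed=1)
    profiles = acgh.probe_profiles({EPISOME: plan}, ref.array)
    table = acgh.simulate_ratios(profiles, None, ref.array, 0.0, 0)
    inside = table[(table["replicon"] == EPISOME) & (table["pos"] == 50_000)]
    assert inside["log2_ratio"].iloc[0] == pytest.approx(np.log2(70), abs=1e-12)


def test_noise_sd_recovered_from_off_event_probes(ref):
    # sigma=0.2 over ~10,000 probes: sample SD within [0.19, 0.21]
    cfg_positions = sum(len(p) for p in ref.array.positions.values())
    reps = (10_000 // cfg_positions) + 1
    sds = []
    for seed in range(reps):
        table = acgh.simulate_ratios(_flat_profiles(ref), None, ref.array, 0.2, seed)
        sds.append(table["log2_ratio"].to_numpy())
    sd = np.concatenate(sds)[:10_000].std(ddof=1)
    assert 0.19 <= sd <= 0.21


def test_zero_copy_uses_floor_and_flags(ref):
    r = ref.copy()
    plan = rr.build_secondary_deletion(r, (10_000, 11_600), 2, seed=6)
    profiles = acgh.probe_profiles({EPISOME: plan}, ref.array)
    table = acgh.simulate_ratios(profiles, None, ref.array, 0.0, 0)
    lost = table[(table["replicon"] == EPISOME) & (table["pos"] == 10_500)]
    assert lost["floored"].iloc[0]
    assert lost["log2_ratio"].iloc[0] == pytest.approx(np.log2(acgh.CN_FLOOR))


def test_single_supra_threshold_probe_not_called(ref):
    table = _table_with(ref, EPISOME, {50_000: 3.0})
    callset = acgh.call_segments(table, ref)
    assert callset.calls.empty


def test_two_adjacent_probes_at_exact_threshold_called(ref):
    # boundary-inclusive: exactly 2-fold on two adjacent probes is a call
    table = _table_with(ref, EPISOME, {50_000: 1.0, 50_100: 1.0})
    calls = acgh.call_segments(table, ref).calls
    assert len(calls) == 1
    row = calls.iloc[0]
    assert row["direction"] == "gain"
    assert row["n_probes"] == 2
    assert row["start"] == 49_950 and row["end"] == 50_150


def test_probes_across_masked_gap_not_adjacent(ref):
    # chromosome mask (20000, 26000): probes at 19900 and 26000 flank it
    table = _table_with(ref, CHROM, {19_900: 2.0, 26_000: 2.0})
    calls = acgh.call_segments(table, ref).calls
    assert calls.empty


def test_run_may_wrap_the_origin(ref):
    L = ref.length(EPISOME)
    table = _table_with(ref, EPISOME, {L - 100: 1.5, 0: 1.5})
    calls = acgh.call_segments(table, ref).calls
    assert len(calls) == 1
    assert bool(calls.iloc[0]["wraps"])


def test_unsorted_table_rejected(ref):
    table = _table_with(ref, EPISOME, {})
    table = table.iloc[::-1].reset_index(drop=True)
    with pytest.raises(ValueError, match="sorted"):
        acgh.call_segments(table, ref)


def test_empty_table_gives_empty_callset(ref):
    empty = pd.DataFrame(columns=["replicon", "pos", "probe_id", "log2_ratio"])
    assert acgh.call_segments(empty, ref).calls.empty


def test_caller_monotone_in_threshold(ref):
    r = ref.copy()
    plan = rr.build_amplification(r, (40_000, 62_000), copies=3, mh_len=5, seed=1)
    profiles = acgh.probe_profiles({EPISOME: plan}, ref.array)
    table = acgh.simulate_ratios(profiles, None, ref.array, 0.3, 5)
    called_bases = []
    for thr in (0.5, 1.0, 1.5, 2.0):
        calls = acgh.call_segments(table, ref, threshold_log2=thr).calls
        called_bases.append(int((calls["end"] - calls["start"]).clip(lower=0).sum()))
    assert called_bases == sorted(called_bases, reverse=True)


def test_noise_free_boundaries_and_exact_copy(ref):
    r = ref.copy()
    plan = rr.build_amplification(r, (40_000, 62_000), copies=70, mh_len=5, seed=1)
    profiles = acgh.probe_profiles({EPISOME: plan}, ref.array)
    table = acgh.simulate_ratios(profiles, None, ref.array, 0.0, 0)
    calls = acgh.call_segments(table, ref).calls
    row = calls[calls["replicon"] == EPISOME].iloc[0]
    spacing = ref.array.spacing[EPISOME]
    assert abs(row["start"] - 40_000) <= spacing
    assert abs(row["end"] - 62_000) <= spacing
    assert row["est_copy"] == pytest.approx(70.0, abs=1e-9)


# ---------------------------------------------------------------------------
# Classification


def _classify_plan(ref, plans, sigma=0.0, seed=0):
    profiles = acgh.probe_profiles(plans, ref.array)
    table = acgh.simulate_ratios(profiles, None, ref.array, sigma, seed)
    callset = acgh.call_segments(table, ref)
    return acgh.isolate_classes(acgh.classify_events(callset, ref))


def test_classifier_identity_on_noise_free_builders(ref):
    cases = {
        "AMP": lambda r: rr.build_amplification(r, (40_000, 62_000), 70, 5, seed=1),
        "EID": lambda r: rr.build_embedded_inverted_duplication(
            r, (38_000, 70_000), (44_000, 55_000), 4, (3, 30), seed=2
        ),
        "SPLIT_AMPLICON": lambda r: rr.build_partially_inverted_amplification(
            r, (40_000, 55_000), (58_000, 66_000), 10, (8, 8), seed=3
        ),
        "EMBEDDED_DEL": lambda r: rr.build_embedded_deletion_amplicon(
            r, (40_000, 62_000), (52_000, 54_000), 4, (5, 3), seed=4
        ),
        "SECONDARY_DEL": lambda r: rr.build_secondary_deletion(r, (10_000, 11_600), 2, seed=6),
    }
    for expected, make in cases.items():
        r = ref.copy()
        classes = _classify_plan(ref, {EPISOME: make(r)})
        assert classes == {expected}, (expected, classes)


def test_amplification_plus_unlinked_loss(ref):
    # the modeled scenario: amplification with an independent 1.6 kb loss
    r = ref.copy()
    amp = rr.build_amplification(r, (40_000, 62_000), 70, 5, seed=1)
    dele = rr.build_secondary_deletion(r, (80_000, 81_600), 2, seed=6)
    classes = _classify_plan(ref, {EPISOME: rr.compose(amp, dele)})
    assert classes == {"AMP", "SECONDARY_DEL"}


def test_loss_adjacent_to_amplification_not_secondary(ref):
    table = _table_with(
        ref, EPISOME,
        {46_000: 6.0, 46_100: 6.0, 46_200: 6.0,  # gain over the marker
         46_300: -2.0, 46_400: -2.0},            # loss touching it
    )
    callset = acgh.call_segments(table, ref)
    classes = acgh.isolate_classes(acgh.classify_events(callset, ref))
    assert "SECONDARY_DEL" not in classes


def test_noisy_amplicon_detection(ref):
    # sigma=0.2: 100 amplicons (copy 70, 22 kb) all detected, boundaries
    # within 2 spacings in >= 95% of cases
    rng = np.random.default_rng(12)
    spacing = ref.array.spacing[EPISOME]
    detected = 0
    tight = 0
    n = 100
    for i in range(n):
        r = ref.copy()
        start = int(rng.integers(5_000, 55_000))
        amplicon = (start, start + 22_000)
        if not (start < 46_000 and amplicon[1] > 49_000):
            amplicon = (30_000, 52_000)
        plan = rr.build_amplification(r, amplicon, 70, 5, seed=int(rng.integers(2**31)))
        profiles = acgh.probe_profiles({EPISOME: plan}, ref.array)
        table = acgh.simulate_ratios(profiles, None, ref.array, 0.2, int(rng.integers(2**31)))
        calls = acgh.call_segments(table, ref).calls
        gains = calls[(calls["replicon"] == EPISOME) & (calls["direction"] == "gain")]
        if gains.empty:
            continue
        detected += 1
        row = max(gains.itertuples(), key=lambda t: t.n_probes)
        if abs(row.start - amplicon[0]) <= 2 * spacing and abs(row.end - amplicon[1]) <= 2 * spacing:
            tight += 1
    assert detected == n
    assert tight >= 0.95 * n


def test_plot_isolate_writes_figure(ref, tmp_path):
    r = ref.copy()
    plan = rr.build_amplification(r, (40_000, 62_000), copies=70, mh_len=5, seed=1)
    profiles = acgh.probe_profiles({EPISOME: plan}, ref.array)
    table = acgh.simulate_ratios(profiles, None, ref.array, 0.2, 3)
    callset = acgh.call_segments(table, ref)
    out = tmp_path / "isolate.png"
    acgh.plot_isolate(callset, ref, str(out))
    assert out.exists() and out.stat().st_size > 0
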