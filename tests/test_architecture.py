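"""Full-length provirus vs. solitary-LTR classification rules."""

import dataclasses
import math

import pytest

from hervmir import architecture as arch
from hervmir import mdte, simulate
from hervmir.annotation_io import (GenomicInterval, MirnaFeature,
                                   RepeatFeature)
from hervmir.architecture import ArchitectureConfig


def _rep(start, end, name, strand="+", chrom="chr1", family="ERV1"):
    return RepeatFeature(GenomicInterval(chrom, start, end, strand),
                         name, "LTR", family)


def _provirus_parts(int_len=8000, ltr_len=450, gap=50, base=10_000,
                    strand="+"):
    ltr5 = _rep(base, base + ltr_len, "LTR7", strand)
    int_start = base + ltr_len + gap
    internal = _rep(int_start, int_start + int_len, "HERV-H-int", strand)
    ltr3 = _rep(int_start + int_len + gap,
                int_start + int_len + gap + ltr_len, "LTR7", strand)
    return [ltr5, internal, ltr3]


def test_config_validation():
    with pytest.raises(ValueError):
        ArchitectureConfig(ltr_len_min=465, ltr_len_max=435)
    with pytest.raises(ValueError):
        ArchitectureConfig(solitary_window=-1)


def test_int_runs_merge_fragments_within_gap():
    single = [_rep(0, 7500, "HERV-H-int")]
    (run,) = arch.build_int_runs(single)
    assert run.member_length_sum == 7500

    frags = [_rep(0, 4000, "HERV-H-int"), _rep(4500, 8500, "HERV-H-int")]
    (run,) = arch.build_int_runs(frags)
    assert run.member_length_sum == 8000
    assert run.member_count == 2

    # gap above the merge threshold stays split
    far = [_rep(0, 4000, "HERV-H-int"), _rep(5500, 9500, "HERV-H-int")]
    assert len(arch.build_int_runs(far)) == 2

    # opposite strands never merge
    mixed = [_rep(0, 4000, "HERV-H-int", "+"),
             _rep(4500, 8500, "HERV-H-int", "-")]
    assert len(arch.build_int_runs(mixed)) == 2


def test_full_length_requires_strictly_over_7kb():
    ok = _provirus_parts(int_len=8000)
    calls = arch.call_full_length(arch.build_int_runs(ok), ok)
    assert len(calls) == 1
    assert calls[0].int_run.member_length_sum == 8000

    short = _provirus_parts(int_len=6900)
    assert arch.call_full_length(arch.build_int_runs(short), short) == []

    # exactly 7000 fails the strict bound, passes the inclusive one
    edge = _provirus_parts(int_len=7000)
    runs = arch.build_int_runs(edge)
    assert arch.call_full_length(runs, edge) == []
    loose = ArchitectureConfig(strict_bounds=False)
    assert len(arch.call_full_length(runs, edge, loose)) == 1


def test_full_length_requires_both_flanks_same_strand():
    parts = _provirus_parts()
    missing_3p = parts[:2]
    assert arch.call_full_length(arch.build_int_runs(missing_3p),
                                 missing_3p) == []
    flipped = [parts[0],
               parts[1],
               dataclasses.replace(parts[2], interval=dataclasses.replace(
                   parts[2].interval, strand="-"))]
    assert arch.call_full_length(arch.build_int_runs(flipped), flipped) == []


def test_full_length_flank_distance_bound():
    parts = _provirus_parts(gap=250)  # beyond flank_max_gap=200
    assert arch.call_full_length(arch.build_int_runs(parts), parts) == []


def test_solitary_window_and_isolation():
    isolated = _rep(100_000, 100_450, "LTR7")
    far_int = _rep(200_000, 205_000, "HERV-H-int")
    calls = arch.call_solitary([isolated], [far_int])
    assert len(calls) == 1
    assert calls[0].nearest_int_gap == 99_550

    near_int = _rep(100_600, 103_000, "HERV-H-int")  # 150 bp away
    assert arch.call_solitary([isolated], [near_int]) == []

    # strict length bounds: 435 and 465 both rejected
    for length in (435, 465):
        ltr = _rep(0, length, "LTR7")
        assert arch.call_solitary([ltr], []) == []
        loose = ArchitectureConfig(strict_bounds=False)
        assert len(arch.call_solitary([ltr], [], loose)) == 1

    # 63 bp scrap is far outside the window
    assert arch.call_solitary([_rep(0, 63, "LTR7C")], []) == []


def test_solitary_isolation_is_strand_agnostic():
    ltr = _rep(100_000, 100_450, "LTR7", "+")
    near_minus = _rep(100_550, 103_000, "HERV-H-int", "-")
    assert arch.call_solitary([ltr], [near_minus]) == []


def test_no_feature_is_both_flank_and_solitary():
    parts = _provirus_parts(ltr_len=450)
    proviruses, solitary, _ = arch.classify_annotation(parts)
    assert len(proviruses) == 1
    flank_ivs = {proviruses[0].ltr5.interval, proviruses[0].ltr3.interval}
    assert all(c.ltr.interval not in flank_ivs for c in solitary)
    assert solitary == []


def test_synthetic_recovery_exact_across_seeds():
    for seed in range(5):
        repeats, truth = simulate.simulate_repeat_annotation(
            5, {"LTR7": 12, "LTR7B": 5, "LTR7C": 3}, 10, 10,
            5_000_000, seed=seed)
        proviruses, solitary, _ = arch.classify_annotation(repeats)
        got_prov = {(p.ltr5.interval.start, p.ltr3.interval.end)
                    for p in proviruses}
        want_prov = {(p["ltr5"][0], p["ltr3"][1]) for p in truth.proviruses}
        assert got_prov == want_prov
        got_sol = {(c.ltr.interval.start, c.subfamily) for c in solitary}
        want_sol = {(s["span"][0], s["subfamily"]) for s in truth.solitary}
        assert got_sol == want_sol


def test_threshold_tightening_is_monotone():
    repeats, _ = simulate.simulate_repeat_annotation(
        5, 20, 10, 10, 5_000_000, seed=3)
    base = ArchitectureConfig()
    n_prov = len(arch.classify_annotation(repeats, base)[0])
    n_sol = len(arch.classify_annotation(repeats, base)[1])
    tighter = [
        dataclasses.replace(base, int_min_len=8200),
        dataclasses.replace(base, ltr_len_min=445),
        dataclasses.replace(base, ltr_len_max=455),
        dataclasses.replace(base, solitary_window=5000),
    ]
    for cfg in tighter:
        prov, sol, _ = arch.classify_annotation(repeats, cfg)
        assert len(prov) <= n_prov
        assert len(sol) <= n_sol


def test_tally_and_empty_annotation():
    assert arch.tally_architecture([], [])["full_length"] == 0
    repeats, truth = simulate.simulate_repeat_annotation(
        5, {"LTR7": 12, "LTR7B": 5, "LTR7C": 3}, 10, 10, 5_000_000, seed=7)
    proviruses, solitary, _ = arch.classify_annotation(repeats)
    tally = arch.tally_architecture(proviruses, solitary)
    assert tally["full_length"] == 5
    assert tally["solitary"] == 20
    assert tally["solitary_by_subfamily"] == {"LTR7": 12, "LTR7B": 5,
                                              "LTR7C": 3}
    assert sum(tally["solitary_by_subfamily"].values()) == tally["solitary"]
    assert sum(tally["solitary_by_chromosome"].values()) == tally["solitary"]


def test_comparison_table_structure():
    table = arch.comparison_table([], [])
    assert list(table.columns) == ["category", "observed", "reference"]
    ref_row = table[table.category == "full_length"].iloc[0]
    assert ref_row.reference == 17
    assert int(table[table.category == "solitary"].iloc[0].reference) == 931


def _mdte_call(mirna_iv, repeat, name):
    mirna = MirnaFeature(mirna_iv, name)
    return mdte.MdteCall(mirna, repeat, mirna_iv.length,
                         repeat.rep_family, repeat.rep_name)


def test_screen_mirna_origin_labels():
    parts = _provirus_parts(base=50_000)
    scrap = _rep(500_000, 500_063, "LTR7C")   # the 63 bp truncated case
    sol = _rep(800_000, 800_450, "LTR7")
    annotation = parts + [scrap, sol]
    proviruses, solitary, _ = arch.classify_annotation(annotation)
    calls = [
        _mdte_call(GenomicInterval("chr1", 500_000, 500_020), scrap, "m1"),
        _mdte_call(GenomicInterval("chr1", 800_100, 800_120), sol, "m2"),
        _mdte_call(GenomicInterval("chr1", parts[1].interval.start + 10,
                                   parts[1].interval.start + 30), parts[1],
                   "m3"),
    ]
    labels = arch.screen_mirna_origin(calls, proviruses, solitary)
    by_repeat = {c.repeat.rep_name: labels[c.mirna.mirna_id] for c in calls}
    assert by_repeat["LTR7C"] == "truncated_element"
    assert by_repeat["LTR7"] == "solitary_ltr"
    assert by_repeat["HERV-H-int"] == "full_length"
    assert arch.screen_mirna_origin([], proviruses, solitary) == {}
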