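"""Seed-site enumeration and duplex DP vs. exhaustive oracle."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hervmir import duplex
from hervmir.duplex import (DEFAULT_MODEL, DuplexScoringModel, find_seed_sites,
                            hybridize, normalize_rna, report_mfe, revcomp_rna)


def random_rna(rng, n):
    return "".join(rng.choice(list("ACGU"), size=n))


# ---------------------------------------------------------------------------
# seed sites
# ---------------------------------------------------------------------------

def test_planted_8mer_site_found_at_known_offset(rng):
    mirna = "UGGGCGAGGGCGAGG" + "ACGUACG"  # arbitrary, >= 8 nt
    site = (duplex._RNA_COMPLEMENT[mirna[7]] + revcomp_rna(mirna[1:7]) + "A")
    utr = random_rna(rng, 40).replace(site[1:7], "CCCCCC") + site + \
        random_rna(rng, 40).replace(site[1:7], "GGGGGG")
    sites = [s for s in find_seed_sites(mirna, utr) if s.site_type == "8mer"]
    assert any(s.utr_position == utr.find(site) for s in sites)


def test_no_seed_match_in_homopolymer_utr():
    mirna = "ACCCCCCGAAAAAAAAA"  # seed 2-7 = CCCCCC, site core GGGGGG
    assert find_seed_sites(mirna, "A" * 60) == []


def test_site_typing_follows_m8_and_a1():
    #            0----+----1
    mirna = "UAGCUUAUCAGACUGAUGUUGA"  # positions 2-7: AGCUUA
    core = revcomp_rna(mirna[1:7])    # UAAGCU
    m8 = duplex._RNA_COMPLEMENT[mirna[7]]
    pad = "CCCC"
    cases = {
        pad + core + pad: "6mer",
        pad + core + "A" + pad: "7mer-A1",
        pad + m8 + core + pad: "7mer-m8",
        pad + m8 + core + "A" + pad: "8mer",
    }
    for utr, expected in cases.items():
        (site,) = find_seed_sites(mirna, utr)
        assert site.site_type == expected, utr


def test_all_core_occurrences_reported_including_overlaps(rng):
    for _ in range(20):
        mirna = random_rna(rng, 20)
        core = revcomp_rna(mirna[1:7])
        utr = random_rna(rng, 30) + core + core[:3] + core + random_rna(rng, 10)
        expected = {i for i in range(len(utr) - 5) if utr[i:i + 6] == core}
        got = {s.core_start for s in find_seed_sites(mirna, utr)}
        assert got == expected


def test_t_and_u_interchangeable():
    assert normalize_rna("acgt") == "ACGU"
    with pytest.raises(ValueError):
        normalize_rna("ACGX")


# ---------------------------------------------------------------------------
# duplex DP
# ---------------------------------------------------------------------------

def oracle_best(mirna, target, model):
    """Exhaustive enumeration of all legal pairings; independent scorer.

    Returns (best score, best -npairs) minimizing lexicographically.
    """
    a = mirna
    c = target[::-1]
    n, m = len(a), len(c)
    best = [0.0, 0]  # empty structure

    def struct_score(pairs):
        s = 0.0
        for (i1, j1), (i2, j2) in zip(pairs, pairs[1:]):
            ga, gc = i2 - i1 - 1, j2 - j1 - 1
            if ga == 0 and gc == 0:
                s += model.stack_energy[(a[i1] + c[j1], a[i2] + c[j2])]
            else:
                s += model.gap_cost(ga, gc)
        return s

    def rec(pairs):
        if pairs:
            s = struct_score(pairs)
            if (s, -len(pairs)) < (best[0], best[1]):
                best[0], best[1] = s, -len(pairs)
        i0 = pairs[-1][0] + 1 if pairs else 0
        j0 = pairs[-1][1] + 1 if pairs else 0
        i_max = min(n, i0 + model.max_bulge + 1) if pairs else n
        j_max = min(m, j0 + model.max_bulge + 1) if pairs else m
        for i in range(i0, i_max):
            for j in range(j0, j_max):
                if model.can_pair(a[i], c[j]):
                    rec(pairs + [(i, j)])

    rec([])
    return best[0], -best[1]


def test_perfect_duplex_scores_sum_of_stacks(rng):
    for _ in range(10):
        mirna = random_rna(rng, 8)
        site = revcomp_rna(mirna)
        result = hybridize(mirna, site)
        # independent hand sum over the 7 helix steps of the full duplex
        c = site[::-1]
        expected = sum(
            DEFAULT_MODEL.stack_energy[(mirna[i] + c[i],
                                        mirna[i + 1] + c[i + 1])]
            for i in range(7))
        assert result.score == pytest.approx(expected)
        assert result.n_pairs == 8


def test_zero_complementarity_gives_empty_pairing():
    result = hybridize("AAAAAAAA", "AAAAAAAA")
    assert result.score == 0.0
    assert result.pairs == ()


def test_empty_or_oversized_sequences_rejected():
    with pytest.raises(ValueError):
        hybridize("", "ACGU")
    with pytest.raises(ValueError):
        hybridize("ACGU" * 20, "ACGU")


def test_dp_equals_exhaustive_enumeration(rng):
    """DP optimum vs. brute force on short random pairs, both models."""
    models = [DEFAULT_MODEL, DuplexScoringModel(gu_allowed=False)]
    for trial in range(200):
        model = models[trial % 2]
        a = random_rna(rng, int(rng.integers(1, 9)))
        t = random_rna(rng, int(rng.integers(1, 9)))
        result = hybridize(a, t, model)
        best_score, best_pairs = oracle_best(a, t, model)
        assert result.score == pytest.approx(best_score, abs=1e-9), (a, t)
        assert result.n_pairs == best_pairs, (a, t)


def test_traceback_score_is_consistent_with_pairing(rng):
    model = DEFAULT_MODEL
    for _ in range(50):
        a = random_rna(rng, int(rng.integers(8, 24)))
        t = random_rna(rng, int(rng.integers(8, 24)))
        result = hybridize(a, t, model)
        # recompute the reported score from the reported pairing
        c_index = {j: len(t) - 1 - j for j in range(len(t))}
        pairs = [(i, c_index[j]) for i, j in result.pairs]
        s = 0.0
        for (i1, j1), (i2, j2) in zip(pairs, pairs[1:]):
            ga, gc = i2 - i1 - 1, j2 - j1 - 1
            if ga == 0 and gc == 0:
                s += model.stack_energy[(a[i1] + t[::-1][j1],
                                         a[i2] + t[::-1][j2])]
            else:
                s += model.gap_cost(ga, gc)
        assert result.score == pytest.approx(s, abs=1e-9)


def test_helix_extension_never_worsens_score():
    mirna = "GCGCGCGC"
    site = revcomp_rna(mirna)
    scores = [hybridize(mirna[:k], revcomp_rna(mirna[:k])).score
              for k in range(2, 9)]
    assert all(b <= a for a, b in zip(scores, scores[1:]))


@settings(max_examples=50, derandomize=True, deadline=None)
@given(st.text(alphabet="ACGU", min_size=1, max_size=7),
       st.text(alphabet="ACGU", min_size=1, max_size=7))
def test_reversal_invariance(a, t):
    fwd = hybridize(a, t)
    rev = hybridize(a[::-1], t[::-1], DEFAULT_MODEL.transposed())
    assert fwd.score == pytest.approx(rev.score, abs=1e-9)


def test_gu_wobble_excluded_when_disallowed():
    model = DuplexScoringModel(gu_allowed=False)
    result = hybridize("GGGGGGGG", "UUUUUUUU", model)
    assert result.pairs == ()
    with_gu = hybridize("GGGGGGGG", "UUUUUUUU")
    assert with_gu.n_pairs > 0


def test_invalid_model_rejected():
    bad = dict(duplex.default_stack_table())
    bad[("GC", "GC")] = +1.0
    with pytest.raises(ValueError):
        DuplexScoringModel(stack_energy=bad)
    with pytest.raises(ValueError):
        DuplexScoringModel(bulge_open=-1.0)


# ---------------------------------------------------------------------------
# windowed report
# ---------------------------------------------------------------------------

def test_report_mfe_perfect_site_beats_seed_only(rng):
    from hervmir.simulate import simulate_sequences

    mirna, utr, truth = simulate_sequences(
        utr_len=160, planted_sites=[(20, "perfect"), (100, "6mer")], seed=4)
    hybrids = report_mfe(mirna, utr)
    assert len(hybrids) >= 2
    best = hybrids[0]
    # the perfect site's window wins
    assert best.site.core_start == min(truth["expected_core_starts"])
    assert best.result.score < hybrids[-1].result.score
    scores = [h.result.score for h in hybrids]
    assert scores == sorted(scores)


def test_report_mfe_empty_cases():
    assert report_mfe("ACCCCCCGAAAAAAAAA", "") == []
    assert report_mfe("ACCCCCCGAAAAAAAAA", "A" * 50) == []


def test_pairing_block_format(rng):
    mirna = random_rna(rng, 20)
    result = hybridize(mirna, revcomp_rna(mirna))
    block = result.format()
    lines = block.split("\n")
    assert len(lines) == 3
    assert lines[0].startswith("target 5'")
    assert lines[2].startswith("miRNA  3'")
    assert lines[1].count("|") + lines[1].count(":") == result.n_pairs
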