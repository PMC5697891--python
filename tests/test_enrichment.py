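import math

import numpy as np
import pytest
from scipy import stats

from splicecomb import enrichment as en
from splicecomb.motif_conservation import MotifHit, SpliceRegion


def _hit(event, motif, region="upstream_intron_3p", conserved=True):
    return MotifHit(motif, event, region, 0, 0, 5, "chrI", "+",
                    species_support=2 if conserved else 0,
                    conserved=conserved)


def test_matched_controls_reproduce_case_histogram(rng):
    case_psi = {f"c{i}": float(p) for i, p in
                enumerate(rng.uniform(5, 95, 40))}
    background = {f"b{i}": float(p) for i, p in
                  enumerate(rng.uniform(5, 95, 2000))}
    sets = en.sample_matched_controls(case_psi, background, n=20, seed=1)
    case_hist = {}
    for p in case_psi.values():
        case_hist[en.psi_bin(p)] = case_hist.get(en.psi_bin(p), 0) + 1
    for cs in sets:
        assert len(cs) == len(case_psi)
        assert len(set(cs)) == len(cs)  # without replacement within a set
        hist = {}
        for e in cs:
            b = en.psi_bin(background[e])
            hist[b] = hist.get(b, 0) + 1
        assert hist == case_hist  # dense background: every bin populated


def test_matched_controls_deterministic_and_bounded(rng):
    case_psi = {"c1": 50.0, "c2": 52.0}
    background = {f"b{i}": float(rng.uniform(45, 60)) for i in range(50)}
    s1 = en.sample_matched_controls(case_psi, background, n=5, seed=9)
    s2 = en.sample_matched_controls(case_psi, background, n=5, seed=9)
    assert s1 == s2
    with pytest.raises(ValueError, match="smaller"):
        en.sample_matched_controls(case_psi, {"b": 50.0}, n=2, seed=0)


def test_all_case_psi_in_one_bin_draws_from_that_bin():
    case_psi = {f"c{i}": 50.0 + i / 10 for i in range(5)}
    background = {f"lo{i}": 20.0 for i in range(20)}
    background.update({f"mid{i}": 51.0 for i in range(20)})
    sets = en.sample_matched_controls(case_psi, background, n=10, seed=0)
    for cs in sets:
        assert all(e.startswith("mid") for e in cs)


def test_enrichment_saturated_cases_vs_empty_controls():
    cases = [f"c{i}" for i in range(8)]
    case_psi = {e: 50.0 for e in cases}
    background = {f"b{i}": 50.0 for i in range(200)}
    hits = [_hit(e, "FOX1") for e in cases]
    res = en.motif_enrichment(cases, case_psi, background, hits, "FOX1",
                              n=20, seed=0)
    assert res.case_proportion == 1.0
    assert res.control_proportion == 0.0
    assert res.p_value < 0.05


def test_enrichment_direction_filter_restricts_cases():
    cases = ["a", "b", "c", "d"]
    case_psi = {e: 50.0 for e in cases}
    background = {f"b{i}": 50.0 for i in range(100)}
    direction = {"a": "increased_inclusion", "b": "increased_inclusion",
                 "c": "increased_skipping", "d": "increased_skipping"}
    hits = [_hit("a", "FOX1"), _hit("b", "FOX1")]
    res = en.motif_enrichment(cases, case_psi, background, hits, "FOX1",
                              direction="increased_inclusion",
                              direction_of=direction, n=10, seed=0)
    assert res.n_cases == 2 and res.case_proportion == 1.0


def test_enrichment_calibrated_under_null(rng):
    """Motif planted at equal frequency in cases and background: the
    one-sided p-value is non-significant in most simulations."""
    sig = 0
    n_sims = 40
    for s in range(n_sims):
        r = np.random.default_rng(1000 + s)
        cases = [f"c{i}" for i in range(20)]
        case_psi = {e: float(r.uniform(5, 95)) for e in cases}
        background = {f"b{i}": float(r.uniform(5, 95)) for i in range(400)}
        hits = [_hit(e, "M") for e in cases if r.random() < 0.3]
        hits += [_hit(e, "M") for e in background if r.random() < 0.3]
        res = en.motif_enrichment(cases, case_psi, background, hits, "M",
                                  n=20, seed=s)
        if res.p_value < 0.05:
            sig += 1
    assert sig / n_sims <= 0.15  # one-sided test, small-sample discrete


def test_positional_bias_profiles():
    hits = [_hit("e1", "M", "upstream_intron_3p"),
            _hit("e2", "M", "downstream_intron_5p"),
            _hit("e2", "M", "alt_exon")]
    bias = en.positional_bias(hits, "M")
    assert bias["flanking_introns"] == 1.0
    assert bias["alt_exon"] == 0.5
    assert bias["constitutive_exons"] == 0.0
    assert en.positional_bias([], "M") == {}


def test_cooccurrence_multiplicative_expectation():
    ids = [f"e{i}" for i in range(100)]
    hits = [_hit(e, "A") for e in ids[:40]] + \
           [_hit(e, "B") for e in ids[20:70]]
    res = en.cooccurrence(ids, hits, "A", "B")
    assert res.n_a == 40 and res.n_b == 50
    assert res.expected == pytest.approx(20.0)
    assert res.observed == 20


def test_cooccurrence_exact_hypergeometric_values():
    # full overlap of 5 and 5 in 10: p = C(5,5)C(5,0)/C(10,5) = 1/252
    r = en.cooccurrence_from_sets(10, set("abcde"), set("abcde"))
    assert r.p_value == pytest.approx(1 / 252)
    # observed 3 of possible 5: P(X>=3) = (100+25+1)/252 = 0.5
    r = en.cooccurrence_from_sets(10, set("abcde"), set("cdefg"))
    assert r.observed == 3
    assert r.p_value == pytest.approx(0.5)
    with pytest.raises(ValueError):
        en.cooccurrence_from_sets(0, set(), set())


def test_cumulative_hypergeometric_matches_enumeration():
    """Upper-tail hypergeometric agrees with explicit combinatorial sums
    for every parameter combination with N <= 12."""
    for n in range(1, 13):
        for k_a in range(0, n + 1):
            for k_b in range(0, n + 1):
                for obs in range(max(0, k_a + k_b - n),
                                 min(k_a, k_b) + 1):
                    exact = sum(
                        math.comb(k_a, x) * math.comb(n - k_a, k_b - x)
                        for x in range(obs, min(k_a, k_b) + 1)
                    ) / math.comb(n, k_b)
                    got = float(stats.hypergeom.sf(obs - 1, n, k_a, k_b))
                    assert got == pytest.approx(exact, rel=1e-9, abs=1e-12)


def test_dinucleotide_frequencies_hand_example():
    f = en.dinucleotide_frequencies("ATGC")
    assert f["AT"] == pytest.approx(1 / 3)
    assert f["TG"] == pytest.approx(1 / 3)
    assert f["GC"] == pytest.approx(1 / 3)
    assert sum(f.values()) == pytest.approx(1.0)
    assert en.dinucleotide_frequencies("A") is None


def _regions(seqs):
    return [SpliceRegion(f"e{i}", "alt_exon", "chrI", "+", (0, len(s)), s)
            for i, s in enumerate(seqs)]


def test_identical_region_sets_show_no_composition_difference(rng):
    seqs = ["".join(rng.choice(list("ACGT"), size=50)) for _ in range(10)]
    df = en.dinucleotide_comparison(_regions(seqs), _regions(seqs))
    assert np.allclose(df.p_value, 1.0, atol=1e-6)
    assert np.allclose(df.fold, 1.0, atol=1e-12)


def test_mannwhitney_matches_brute_force_oracle(rng):
    """U statistic equals the naive count of pairwise wins + half-ties."""
    for _ in range(50):
        a = _regions(["".join(rng.choice(list("ACGT"), size=30))
                      for _ in range(8)])
        b = _regions(["".join(rng.choice(list("ACGT"), size=30))
                      for _ in range(9)])
        df = en.dinucleotide_comparison(a, b)
        for d in ("AA", "AC", "GC"):
            xa = [en.dinucleotide_frequencies(r.sequence)[d] for r in a]
            xb = [en.dinucleotide_frequencies(r.sequence)[d] for r in b]
            u = sum((x > y) + 0.5 * (x == y) for x in xa for y in xb)
            row = df[df.dinucleotide == d.replace("T", "U")].iloc[0]
            assert row.u_statistic == pytest.approx(u)


def test_term_enrichment_flagged_term_stands_out(rng):
    genes = [f"g{i}" for i in range(120)]
    lengths = {g: float(rng.uniform(200, 3000)) for g in genes}
    term_map = {g: {"muscle"} for g in genes[:12]}
    term_map.update({g: {"other"} for g in genes[12:]})
    flagged = set(genes[:12])
    df = en.term_enrichment_length_matched(term_map, flagged, lengths,
                                           n=50, seed=0)
    row = df[df.term == "muscle"].iloc[0]
    assert row.proportion == 1.0
    assert row.control_proportion < 0.2
    assert row.hypergeom_p < 1e-6


def test_term_enrichment_calibrated_when_flag_independent(rng):
    genes = [f"g{i}" for i in range(200)]
    lengths = {g: float(rng.uniform(200, 3000)) for g in genes}
    term_map = {g: {"t1"} if i < 40 else {"t2"} for i, g in enumerate(genes)}
    flagged = {g for g in genes if rng.random() < 0.3}
    df = en.term_enrichment_length_matched(term_map, flagged, lengths,
                                           n=100, seed=1)
    row = df[df.term == "t1"].iloc[0]
    assert abs(row.proportion - row.control_proportion) < 0.2


def test_term_with_too_few_genes_skipped():
    lengths = {"g1": 100.0, "g2": 200.0, "g3": 300.0}
    df = en.term_enrichment_length_matched({"g1": {"rare"}}, set(),
                                           lengths, n=5, seed=0)
    assert df[df.term == "rare"].iloc[0].note == "too_few_genes"


def test_developmental_overlap_hypergeometric():
    universe = {f"g{i}" for i in range(10)}
    a = {f"g{i}" for i in range(5)}
    obs, p = en.developmental_overlap(a, a, universe)
    assert obs == 5
    assert p == pytest.approx(1 / 252)
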