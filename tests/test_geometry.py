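import numpy as np
import pytest

from splicecomb import geometry as geo
from splicecomb.formats_io import AlignmentBlock, AlignmentSet
from splicecomb.motif_conservation import (MotifHit, SpliceRegion,
                                           parse_motif)


def _hit(motif, offset, length=5, event="ev", region="upstream_intron_3p",
         gstart=None, strand="+"):
    return MotifHit(motif, event, region, offset,
                    gstart if gstart is not None else offset, length,
                    "chrI", strand)


def test_pair_spacing_simple_gap():
    rec = geo.pair_spacing([_hit("A", 95, 5)], [_hit("B", 150)],
                           "upstream_intron_3p")
    assert rec.spacing == 50
    assert rec.upstream_motif == "A"


def test_closest_instance_rule():
    """With A at {10, 80} and B at 90, the (80, 90) pair is chosen."""
    rec = geo.pair_spacing([_hit("A", 10), _hit("A", 80)],
                           [_hit("B", 90)], "upstream_intron_3p")
    assert rec.a_offset == (80, 85)
    assert rec.spacing == 5


def test_adjacent_motifs_have_spacing_zero():
    rec = geo.pair_spacing([_hit("A", 10, 5)], [_hit("B", 15)],
                           "upstream_intron_3p")
    assert rec.spacing == 0


def test_motifs_in_other_regions_give_no_record():
    assert geo.pair_spacing([_hit("A", 10)], [_hit("B", 50)],
                            "downstream_intron_5p") is None


def test_spacing_shift_invariance(rng):
    """Spacing is unchanged when the whole coordinate frame shifts."""
    for _ in range(20):
        o1, gap = int(rng.integers(0, 50)), int(rng.integers(0, 60))
        shift = int(rng.integers(1, 1000))
        r1 = geo.pair_spacing([_hit("A", o1)], [_hit("B", o1 + 5 + gap)],
                              "upstream_intron_3p")
        r2 = geo.pair_spacing([_hit("A", o1 + shift)],
                              [_hit("B", o1 + shift + 5 + gap)],
                              "upstream_intron_3p")
        assert r1.spacing == r2.spacing == gap


def _aligned_region(ref_seq, species_rows, start=1000, strand="+"):
    rows = {"cele": ref_seq}
    rows.update(species_rows)
    block = AlignmentBlock("cele", "chrI", start, rows)
    region = SpliceRegion("ev", "upstream_intron_3p", "chrI", strand,
                          (start, start + len(ref_seq.replace("-", ""))),
                          ref_seq.replace("-", ""))
    return region, AlignmentSet("cele", [block])


def _seq_with(motifs_at, length=120):
    seq = list("A" * length)
    for pos, s in motifs_at:
        seq[pos:pos + len(s)] = s
    return "".join(seq)


def test_spacing_conserved_within_20_percent():
    """Reference spacing 50; species at 55 and 58 are inside [40, 60],
    so the pair is conserved."""
    pa, pb = parse_motif("GCAUG", "A"), parse_motif("GCACA", "B")
    ref = _seq_with([(10, "GCATG"), (65, "GCACA")])
    sp1 = _seq_with([(10, "GCATG"), (70, "GCACA")])   # spacing 55
    sp2 = _seq_with([(10, "GCATG"), (73, "GCACA")])   # spacing 58
    region, aln = _aligned_region(ref, {"cbri": sp1, "crem": sp2})
    rec = geo.pair_spacing(
        [_hit("A", 10, 5, gstart=1010)], [_hit("B", 65, 5, gstart=1065)],
        "upstream_intron_3p")
    assert rec.spacing == 50
    geo.spacing_conservation(rec, region, pa, pb, aln)
    assert rec.spacing_conserved
    assert rec.species_spacing == {"cbri": 55, "crem": 58}


def test_spacing_not_conserved_with_single_supporter():
    pa, pb = parse_motif("GCAUG", "A"), parse_motif("GCACA", "B")
    ref = _seq_with([(10, "GCATG"), (65, "GCACA")])
    sp1 = _seq_with([(10, "GCATG"), (76, "GCACA")])   # spacing 61 > 60
    sp2 = _seq_with([(10, "GCATG"), (60, "GCACA")])   # spacing 45, in range
    region, aln = _aligned_region(ref, {"cbri": sp1, "crem": sp2})
    rec = geo.pair_spacing(
        [_hit("A", 10, 5, gstart=1010)], [_hit("B", 65, 5, gstart=1065)],
        "upstream_intron_3p")
    geo.spacing_conservation(rec, region, pa, pb, aln)
    assert not rec.spacing_conserved


def test_zero_reference_spacing_requires_exact_zero():
    pa, pb = parse_motif("GCAUG", "A"), parse_motif("GCACA", "B")
    ref = _seq_with([(10, "GCATG"), (15, "GCACA")])
    exact = _seq_with([(10, "GCATG"), (15, "GCACA")])
    off = _seq_with([(10, "GCATG"), (16, "GCACA")])
    region, aln = _aligned_region(ref, {"cbri": exact, "crem": exact,
                                        "csp11": off})
    rec = geo.pair_spacing(
        [_hit("A", 10, 5, gstart=1010)], [_hit("B", 15, 5, gstart=1015)],
        "upstream_intron_3p")
    assert rec.spacing == 0
    geo.spacing_conservation(rec, region, pa, pb, aln)
    assert rec.spacing_conserved
    assert rec.species_spacing["csp11"] == 1  # off by one, not supporting


def test_spacing_conservation_matches_brute_force(study):
    """Pipeline spacing-conservation flags equal an independent
    enumeration of all species match pairs on the synthetic study."""
    from splicecomb.motif_conservation import find_matches
    from splicecomb.geometry import _region_species_sequence
    from splicecomb.motif_conservation import event_regions, scan_region

    pa = parse_motif("GCAUG", "FOX1")
    pb = parse_motif("GCACA", "MEC8")
    events = {e.event_id: e for e in study.events}
    checked = 0
    for row in study.truth.pairs.itertuples(index=False):
        ev = events[row.event_id]
        regions = {r.label: r for r in
                   event_regions(ev, study.genome, 300)}
        region = regions[row.region]
        ha = scan_region(pa, region)
        hb = scan_region(pb, region)
        rec = geo.pair_spacing(ha, hb, row.region)
        assert rec is not None and rec.spacing == row.spacing
        geo.spacing_conservation(rec, region, pa, pb, study.alignments)
        # brute force across species
        support = 0
        for block in study.alignments.blocks_covering(
                "chrI", (region.interval[0] + region.interval[1]) // 2):
            for sp in block.rows:
                if sp == "cele":
                    continue
                sub = _region_species_sequence(block, sp, region)
                if sub is None:
                    continue
                best = None
                for ia in find_matches(pa, sub):
                    for ib in find_matches(pb, sub):
                        lo, hi = sorted([(ia, ia + 5), (ib, ib + 5)])
                        gap = hi[0] - lo[1]
                        if gap >= 0 and (best is None or
                                         abs(gap - rec.spacing) <
                                         abs(best - rec.spacing)):
                            best = gap
                if best is not None and \
                        0.8 * rec.spacing <= best <= 1.2 * rec.spacing:
                    support += 1
        assert rec.spacing_conserved == (support >= 2)
        assert rec.spacing_conserved == bool(row.spacing_conserved)
        checked += 1
    assert checked > 0


def test_conservation_by_distance_curve_properties():
    records = [(10, True), (20, True), (30, False), (40, True)]
    curve, overall = geo.conservation_by_distance(records)
    assert curve[0] == (10, 1.0)
    assert curve[-1][1] == overall == pytest.approx(3 / 4)
    all_true = [(d, True) for d in (5, 15, 25)]
    curve2, _ = geo.conservation_by_distance(all_true)
    assert all(v == 1.0 for _, v in curve2)
    with pytest.raises(ValueError):
        geo.conservation_by_distance([])


def test_worked_binomial_example_nine_of_ten():
    """9 of 10 events in one direction: two-sided binomial p = 22/1024."""
    obs = []
    for i in range(10):
        order = "ab" if i < 9 else "ba"
        for sp in ("cbri", "crem"):
            obs.append((f"e{i}", order, sp, True))
    summary = geo.classify_ordering(obs)
    assert summary.direction_p == pytest.approx(22 / 1024)
    assert summary.classification == "unidirectional"


def test_balanced_directions_classified_bidirectional():
    obs = []
    for i in range(10):
        order = "ab" if i < 5 else "ba"
        for sp in ("cbri", "crem"):
            obs.append((f"e{i}", order, sp, True))
    summary = geo.classify_ordering(obs)
    assert summary.classification == "bidirectional"


def test_insufficient_events_not_conserved():
    obs = [("e1", "ab", "cbri", True), ("e2", "ab", "cbri", True)]
    s = geo.classify_ordering(obs)
    assert s.classification == "not_conserved"
    assert s.note == "insufficient_events"


def test_random_order_shuffling_rarely_called(rng):
    """Independent 50:50 per-species orders: pairs exceed not_conserved
    at a rate bounded by alpha plus Monte-Carlo error."""
    called = 0
    n = 300
    for _ in range(n):
        obs = []
        for i in range(10):
            order = "ab" if rng.random() < 0.5 else "ba"
            for sp in ("cbri", "crem", "crem2"):
                obs.append((f"e{i}", order, sp, bool(rng.random() < 0.5)))
        if geo.classify_ordering(obs).classification != "not_conserved":
            called += 1
    # alpha=0.05 plus 3 sigma of binomial error at n=300
    assert called / n <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / n)


def test_ordering_recovers_planted_unidirectional_pair(study):
    from splicecomb.motif_conservation import scan_events

    pa = parse_motif("GCAUG", "FOX1")
    pb = parse_motif("GCACA", "MEC8")
    events = {e.event_id: e for e in study.events}
    planted = sorted(set(study.truth.pairs.event_id))
    hits = scan_events([events[e] for e in planted], study.genome,
                       [pa, pb], study.alignments)
    ev_hits = {}
    for h in hits:
        ev_hits.setdefault(h.event_id, {}).setdefault(h.motif,
                                                      []).append(h)
    pair_hits = {e: (m["FOX1"], m["MEC8"]) for e, m in ev_hits.items()
                 if "FOX1" in m and "MEC8" in m}
    summary = geo.ordering_conservation(pair_hits, pa, pb,
                                        study.alignments)
    # generator plants FOX1 upstream of MEC8 in every event
    assert summary.n_ba == 0
    assert summary.reversed == 0
    assert summary.classification == "unidirectional"


def test_relative_positions_signs_and_binomial():
    anchors = {f"e{i}": ([_hit("A", 100, 5, gstart=100)],
                         [_hit("B", 150, 5, gstart=150)])
               for i in range(9)}
    anchors["e9"] = ([_hit("A", 100, 5, gstart=100)],
                     [_hit("B", 60, 5, gstart=60)])
    offsets, n_zero, p = geo.relative_positions(anchors)
    assert offsets.count(50) == 9 and offsets.count(-40) == 1
    assert n_zero == 0
    assert p == pytest.approx(22 / 1024)


def test_pairwise_comparison_count_for_thirteen_motifs():
    motifs = [f"m{i}" for i in range(13)]
    assert len(geo.motif_pairs(motifs)) == 78
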