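import re

import numpy as np
import pytest

from splicecomb import motif_conservation as mc
from splicecomb.event_catalog import build_catalog
from splicecomb.formats_io import (AlignmentBlock, AlignmentSet, Gene,
                                   GeneModelSet, Transcript,
                                   reverse_complement)


def test_parse_simple_consensus():
    pat = mc.parse_motif("GCAUG")
    assert pat.length == 5
    assert [sorted(s) for s in pat.positions] == [
        ["G"], ["C"], ["A"], ["T"], ["G"]]


def test_parse_alternation_pattern():
    pat = mc.parse_motif("U(A|G|U)(A|G)GUU")
    assert pat.length == 6
    assert [set(s) for s in pat.positions] == [
        {"T"}, {"A", "G", "T"}, {"A", "G"}, {"G"}, {"T"}, {"T"}]


def test_parse_iupac_degeneracy():
    pat = mc.parse_motif("GCAYG")
    assert set(pat.positions[3]) == {"C", "T"}


@pytest.mark.parametrize("bad", ["GC(A|)G", "GC(AG", "GCA)G", "", "GXAUG"])
def test_bad_patterns_rejected(bad):
    with pytest.raises(ValueError):
        mc.parse_motif(bad)


def _region(seq, strand="+", label="alt_exon", start=0):
    return mc.SpliceRegion("ev", label, "chrI", strand,
                           (start, start + len(seq)), seq)


def test_scan_finds_single_and_overlapping_hits():
    pat = mc.parse_motif("GCAUG")
    hits = mc.scan_region(pat, _region("AAGCATGAA"))
    assert [h.offset for h in hits] == [2]
    hits = mc.scan_region(pat, _region("GCATGCATG"))
    assert [h.offset for h in hits] == [0, 4]


def test_scan_matches_regex_oracle(rng):
    """Pattern scanning agrees with a lookahead-regex oracle on random
    sequences, including degenerate patterns."""
    patterns = {
        "GCAUG": "GCATG",
        "U(A|G|U)(A|G)GUU": "T[AGT][AG]GTT",
        "GCAYG": "GCA[CT]G",
    }
    for pat_str, regex in patterns.items():
        pat = mc.parse_motif(pat_str)
        for _ in range(100):
            seq = "".join(rng.choice(list("ACGT"), size=300))
            got = [h.offset for h in mc.scan_region(pat, _region(seq))]
            want = [m.start() for m in re.finditer(f"(?=({regex}))", seq)]
            assert got == want


def _cassette_with_introns(up_len, down_len, strand="+"):
    e1 = (100, 200)
    e2 = (200 + up_len, 300 + up_len)
    e3 = (300 + up_len + down_len, 400 + up_len + down_len)
    g = Gene("g", "chrI", strand, [
        Transcript("t1", [e1, e2, e3]),
        Transcript("t2", [e1, e3]),
    ])
    events = build_catalog(GeneModelSet([g]))
    return events[0]


def test_long_intron_regions_take_proximal_windows(rng):
    ev = _cassette_with_introns(1000, 1000)
    genome = {"chrI": "".join(rng.choice(list("ACGT"), size=3000))}
    regions = {r.label: r for r in mc.event_regions(ev, genome)}
    up5 = regions["upstream_intron_5p"]
    up3 = regions["upstream_intron_3p"]
    assert up5.interval == (200, 500)       # first 300 nt of the intron
    assert up3.interval == (900, 1200)      # last 300 nt
    assert up3.interval[1] - up3.interval[0] == 300


def test_short_intron_splits_at_midpoint(rng):
    ev = _cassette_with_introns(400, 400)
    genome = {"chrI": "".join(rng.choice(list("ACGT"), size=2000))}
    regions = {r.label: r for r in mc.event_regions(ev, genome)}
    up5 = regions["upstream_intron_5p"]
    up3 = regions["upstream_intron_3p"]
    assert up5.interval == (200, 400)
    assert up3.interval == (400, 600)       # disjoint halves of 200 nt


def test_minus_strand_regions_are_reverse_complemented(rng):
    ev = _cassette_with_introns(700, 700, strand="-")
    genome = {"chrI": "".join(rng.choice(list("ACGT"), size=3000))}
    regions = mc.event_regions(ev, genome)
    for r in regions:
        s, e = r.interval
        assert r.sequence == reverse_complement(genome["chrI"][s:e])
    labels = {r.label for r in regions}
    assert "upstream_intron_5p" in labels
    # on the minus strand the upstream intron is the genomically-right one
    up = [r for r in regions if r.label.startswith("upstream")]
    down = [r for r in regions if r.label.startswith("downstream")]
    assert min(s for r in up for s in r.interval) > \
        max(s for r in down for s in r.interval)


def _block(rows, ref_start=0):
    return AlignmentBlock("cele", "chrI", ref_start, rows)


def test_conservation_two_species_at_boundary():
    ref = "AAAAGCATGAAAA"
    rows = {"cele": ref, "cbri": ref, "crem": ref,
            "csp11": "CCCCCCCCCCCCC", "cbre": "CCCCCCCCCCCCC"}
    pat = mc.parse_motif("GCAUG")
    hit = mc.MotifHit("FOX1", "ev", "alt_exon", 4, 4, 5, "chrI", "+")
    mc.assess_conservation(hit, pat, AlignmentSet("cele", [_block(rows)]))
    assert hit.species_support == 2
    assert hit.conserved  # >= 2 other species is the boundary


def test_one_species_is_not_conserved():
    ref = "AAAAGCATGAAAA"
    rows = {"cele": ref, "cbri": ref, "crem": "C" * 13}
    pat = mc.parse_motif("GCAUG")
    hit = mc.MotifHit("FOX1", "ev", "alt_exon", 4, 4, 5, "chrI", "+")
    mc.assess_conservation(hit, pat, AlignmentSet("cele", [_block(rows)]))
    assert hit.species_support == 1 and not hit.conserved


def test_match_just_outside_window_does_not_support():
    """A species match 26 columns away fails the 25-column rule; one at
    exactly 25 passes."""
    pat = mc.parse_motif("GCAUG")
    ref = "GCATG" + "A" * 60
    rows26 = {"cele": ref, "cbri": "A" * 26 + "GCATG" + "A" * 34}
    rows25 = {"cele": ref, "cbri": "A" * 25 + "GCATG" + "A" * 35}
    hit = mc.MotifHit("FOX1", "ev", "alt_exon", 0, 0, 5, "chrI", "+")
    mc.assess_conservation(hit, pat, AlignmentSet("cele", [_block(rows26)]))
    assert hit.species_support == 0
    hit2 = mc.MotifHit("FOX1", "ev", "alt_exon", 0, 0, 5, "chrI", "+")
    mc.assess_conservation(hit2, pat, AlignmentSet("cele", [_block(rows25)]))
    assert hit2.species_support == 1


def test_unaligned_hit_flagged():
    pat = mc.parse_motif("GCAUG")
    hit = mc.MotifHit("FOX1", "ev", "alt_exon", 0, 999, 5, "chrI", "+")
    mc.assess_conservation(hit, pat, AlignmentSet("cele", []))
    assert hit.species_support == 0 and hit.note == "unaligned"


def test_gap_column_insertion_changes_nothing(rng):
    """Inserting pure-gap columns shifts columns of all rows equally, so
    conservation calls are invariant."""
    pat = mc.parse_motif("GCAUG")
    for _ in range(30):
        seq = "".join(rng.choice(list("ACGT"), size=40))
        seq = seq[:10] + "GCATG" + seq[15:]
        rows = {"cele": seq,
                "cbri": seq if rng.random() < 0.5 else "C" * 40,
                "crem": seq if rng.random() < 0.5 else "C" * 40}
        hit = lambda: mc.MotifHit("F", "ev", "alt_exon", 10, 10, 5,
                                  "chrI", "+")
        h1 = hit()
        mc.assess_conservation(h1, pat, AlignmentSet("cele",
                                                     [_block(rows)]))
        col = int(rng.integers(0, 41))
        rows_g = {sp: r[:col] + "-" + r[col:] for sp, r in rows.items()}
        h2 = hit()
        mc.assess_conservation(h2, pat, AlignmentSet("cele",
                                                     [_block(rows_g)]))
        assert h1.species_support == h2.species_support


def test_scan_events_recovers_planted_truth(study):
    """Every planted motif instance is found with exactly its planted
    species support."""
    pats = [mc.parse_motif("GCAUG", "FOX1"), mc.parse_motif("GCACA", "MEC8")]
    events = {e.event_id: e for e in study.events}
    truth = study.truth.motifs
    targets = [events[eid] for eid in sorted(set(truth.event_id))]
    hits = mc.scan_events(targets, study.genome, pats, study.alignments)
    index = {(h.event_id, h.motif, h.genomic_start): h for h in hits}
    for row in truth.itertuples(index=False):
        h = index[(row.event_id, row.motif, row.genomic_start)]
        assert h.species_support == row.conservation_species
        assert h.conserved == row.conserved
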