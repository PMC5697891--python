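"""Inter-motif spacing and ordering analyses for co-occurring motif pairs.

Spacing between two different motifs is measured within one intronic
sub-region (5' or 3' proximal 300 nt of a flanking intron) as the gap
between the end of the upstream motif and the start of the downstream
motif, using the closest pair of instances.  A spacing is conserved when
at least two other species carry both motifs with a spacing within +/-20%
of the reference spacing (taking, per species, the instance pair whose
spacing is most similar to the reference).

Ordering asks whether the relative order of two motifs (anywhere in the
two flanking introns) is preserved in other species: per (event, species)
observation, preserved/reversed counts are tested against 50:50 by a
chi-squared test; order-conserved pairs are then classified unidirectional
(one reference order dominates, two-sided binomial) or bidirectional.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
from scipy import stats

from .formats_io import AlignmentBlock, AlignmentSet, reverse_complement
from .motif_conservation import (INTRON_LABELS, MotifHit, MotifPattern,
                                 SpliceRegion, find_matches)


@dataclass
class SpacingRecord:
    event_id: str
    region_label: str
    motif_a: str
    motif_b: str
    spacing: int                  # nt, >= 0
    upstream_motif: str           # which motif comes first (sense)
    a_offset: Tuple[int, int]     # chosen instance [start, end) in region
    b_offset: Tuple[int, int]
    species_spacing: Dict[str, int] = field(default_factory=dict)
    spacing_conserved: bool = False
    note: Optional[str] = None


@dataclass
class OrderingSummary:
    motif_a: str
    motif_b: str
    n_events: int                 # events contributing >=1 observation
    preserved: int                # (event, species) observations
    reversed: int
    n_ab: int                     # events with reference order a-before-b
    n_ba: int
    chi2_p: Optional[float]
    direction_p: Optional[float]
    classification: str           # not_conserved / bidirectional / unidirectional
    note: Optional[str] = None


def motif_pairs(motifs: Sequence[str]) -> List[Tuple[str, str]]:
    """All unordered pairs of distinct motifs (n choose 2 comparisons)."""
    uniq = sorted(dict.fromkeys(motifs))
    return list(itertools.combinations(uniq, 2))


def _closest_pair(instances_a: Sequence[Tuple[int, int]],
                  instances_b: Sequence[Tuple[int, int]],
                  ) -> Optional[Tuple[Tuple[int, int], Tuple[int, int], int]]:
    """Cross pair with minimal non-negative spacing (gap between the end
    of the earlier instance and the start of the later one)."""
    best = None
    for ia in instances_a:
        for ib in instances_b:
            first, second = (ia, ib) if ia[0] <= ib[0] else (ib, ia)
            gap = second[0] - first[1]
            if gap < 0:
                continue  # overlapping instances carry no spacing
            if best is None or gap < best[2]:
                best = (ia, ib, gap)
    return best


def pair_spacing(hits_a: Sequence[MotifHit], hits_b: Sequence[MotifHit],
                 region_label: str) -> Optional[SpacingRecord]:
    """Spacing record for two motifs within one intronic sub-region."""
    ha = [h for h in hits_a if h.region_label == region_label]
    hb = [h for h in hits_b if h.region_label == region_label]
    if not ha or not hb:
        return None
    iv_a = [(h.offset, h.offset + h.length) for h in ha]
    iv_b = [(h.offset, h.offset + h.length) for h in hb]
    best = _closest_pair(iv_a, iv_b)
    if best is None:
        return None
    a_iv, b_iv, gap = best
    upstream = ha[0].motif if a_iv[0] <= b_iv[0] else hb[0].motif
    return SpacingRecord(ha[0].event_id, region_label, ha[0].motif,
                         hb[0].motif, gap, upstream, a_iv, b_iv)


def _region_species_sequence(block: AlignmentBlock, species: str,
                             region: SpliceRegion) -> Optional[str]:
    """Species bases aligned to the columns of a reference region, in the
    region's sense orientation."""
    s, e = region.interval
    if not (block.covers(s) and block.covers(e - 1)):
        return None
    c_lo, c_hi = block.column_of(s), block.column_of(e - 1)
    seq, cols = block.ungapped(species)
    mask = (cols >= c_lo) & (cols <= c_hi)
    sub = "".join(ch for ch, m in zip(seq, mask) if m)
    if region.strand == "-":
        sub = reverse_complement(sub)
    return sub


def spacing_conservation(record: SpacingRecord,
                         region: SpliceRegion,
                         motif_a: MotifPattern,
                         motif_b: MotifPattern,
                         alignments: AlignmentSet,
                         tolerance: float = 0.20,
                         min_species: int = 2) -> SpacingRecord:
    """Set the spacing-conserved flag by re-measuring in other species.

    Per species the pair of instances with the spacing most similar to
    the reference spacing is used; the species counts as supporting when
    that spacing is within ``tolerance`` of the reference (a reference
    spacing of 0 requires exactly 0).
    """
    mid = (region.interval[0] + region.interval[1]) // 2
    blocks = alignments.blocks_covering(region.seq_id, mid)
    ref = record.spacing
    lo, hi = ref * (1 - tolerance), ref * (1 + tolerance)
    support = 0
    for block in blocks:
        n = 0
        for sp in block.rows:
            if sp == block.ref_species:
                continue
            sub = _region_species_sequence(block, sp, region)
            if sub is None:
                continue
            iv_a = [(i, i + motif_a.length)
                    for i in find_matches(motif_a, sub)]
            iv_b = [(i, i + motif_b.length)
                    for i in find_matches(motif_b, sub)]
            best_gap = None
            for ia in iv_a:
                for ib in iv_b:
                    first, second = (ia, ib) if ia[0] <= ib[0] else (ib, ia)
                    gap = second[0] - first[1]
                    if gap < 0:
                        continue
                    if best_gap is None or abs(gap - ref) < abs(best_gap - ref):
                        best_gap = gap
            if best_gap is None:
                continue
            record.species_spacing[sp] = best_gap
            if lo <= best_gap <= hi:
                n += 1
        support = max(support, n)
    if not blocks:
        record.note = "unaligned"
    record.spacing_conserved = support >= min_species
    return record


def conservation_by_distance(records: Sequence[Tuple[int, bool]],
                             thresholds: Optional[Sequence[int]] = None,
                             ) -> Tuple[List[Tuple[int, float]], float]:
    """Cumulative proportion of both-motif-conserved pairs by spacing.

    ``records`` are (spacing, both_conserved) pairs.  For each threshold
    x, the proportion of records with spacing <= x that are conserved.
    Returns the curve and the overall proportion (the reference line).
    """
    if not records:
        raise ValueError("no spacing records")
    spacings = sorted({s for s, _ in records})
    if thresholds is None:
        thresholds = spacings
    curve = []
    for x in thresholds:
        sub = [c for s, c in records if s <= x]
        curve.append((x, float(np.mean(sub)) if sub else float("nan")))
    overall = float(np.mean([c for _, c in records]))
    return curve, overall


def _tpos(hit: MotifHit) -> int:
    """Position along the pre-mRNA (transcription order)."""
    return hit.genomic_start if hit.strand == "+" else -hit.genomic_start


def _nearest_column(cols: Sequence[int], target: int, window: int
                    ) -> Optional[int]:
    best = None
    for c in cols:
        if abs(c - target) <= window and (
                best is None or abs(c - target) < abs(best - target)):
            best = c
    return best


def ordering_observations(events_hits: Dict[str, Tuple[List[MotifHit],
                                                       List[MotifHit]]],
                          motif_a: MotifPattern, motif_b: MotifPattern,
                          alignments: AlignmentSet,
                          window: int = 25):
    """Per-(event, species) order observations for one motif pair.

    For each event with both motifs in its flanking introns, the closest
    pair of instances fixes the reference order; each other species with
    both motifs within ``window`` columns of the reference instances (in
    the same alignment block) contributes one preserved/reversed
    observation.  Yields (event_id, ref_order, species, preserved).
    """
    from .motif_conservation import species_support_columns

    for event_id, (ha, hb) in sorted(events_hits.items()):
        ha = [h for h in ha if h.region_label in INTRON_LABELS]
        hb = [h for h in hb if h.region_label in INTRON_LABELS]
        if not ha or not hb:
            continue
        pairs = [(abs(_tpos(x) - _tpos(y)), x, y) for x in ha for y in hb
                 if _tpos(x) != _tpos(y)]
        if not pairs:
            continue  # identical starts only: order undefined, dropped
        _, hit_a, hit_b = min(pairs, key=lambda t: t[0])
        ref_order = "ab" if _tpos(hit_a) < _tpos(hit_b) else "ba"
        pos_a = (hit_a.genomic_start if hit_a.strand == "+"
                 else hit_a.genomic_start + hit_a.length - 1)
        pos_b = (hit_b.genomic_start if hit_b.strand == "+"
                 else hit_b.genomic_start + hit_b.length - 1)
        blocks = [b for b in alignments.blocks_covering(hit_a.seq_id, pos_a)
                  if b.covers(pos_b)]
        if not blocks:
            continue
        block = blocks[0]
        c_a, c_b = block.column_of(pos_a), block.column_of(pos_b)
        for sp in sorted(block.rows):
            if sp == block.ref_species:
                continue
            cols_a = species_support_columns(block, motif_a, sp,
                                             hit_a.strand)
            cols_b = species_support_columns(block, motif_b, sp,
                                             hit_b.strand)
            na = _nearest_column(cols_a, c_a, window)
            nb = _nearest_column(cols_b, c_b, window)
            if na is None or nb is None or na == nb:
                continue
            preserved = (na < nb) == (c_a < c_b)
            yield event_id, ref_order, sp, preserved


def classify_ordering(observations: Sequence[Tuple[str, str, str, bool]],
                      motif_a: str = "a", motif_b: str = "b",
                      alpha: float = 0.05,
                      min_events: int = 3) -> OrderingSummary:
    """Pair-level classification from (event, ref_order, species,
    preserved) observations.

    Order preservation is tested against 50:50 preserved:reversed with a
    chi-squared test over all observations; if preservation is
    significant, a two-sided binomial test on the per-event reference
    orders separates unidirectional from bidirectional pairs.
    """
    obs = list(observations)
    events = sorted({e for e, *_ in obs})
    ref_orders = {e: o for e, o, *_ in obs}
    n_ab = sum(1 for e in events if ref_orders[e] == "ab")
    n_ba = len(events) - n_ab
    preserved = sum(1 for *_, p in obs if p)
    rev = len(obs) - preserved
    if len(events) < min_events:
        return OrderingSummary(motif_a, motif_b, len(events),
                               preserved, rev, n_ab, n_ba, None, None,
                               "not_conserved", "insufficient_events")
    chi2_p = float(stats.chisquare([preserved, rev]).pvalue)
    if chi2_p >= alpha or preserved <= rev:
        return OrderingSummary(motif_a, motif_b, len(events),
                               preserved, rev, n_ab, n_ba, chi2_p, None,
                               "not_conserved")
    dir_p = float(stats.binomtest(n_ab, len(events), 0.5).pvalue)
    cls = "unidirectional" if dir_p < alpha else "bidirectional"
    return OrderingSummary(motif_a, motif_b, len(events),
                           preserved, rev, n_ab, n_ba, chi2_p, dir_p, cls)


def ordering_conservation(events_hits: Dict[str, Tuple[List[MotifHit],
                                                       List[MotifHit]]],
                          motif_a: MotifPattern, motif_b: MotifPattern,
                          alignments: AlignmentSet,
                          window: int = 25,
                          alpha: float = 0.05,
                          min_events: int = 3) -> OrderingSummary:
    """Classify a motif pair's ordering conservation across species."""
    obs = list(ordering_observations(events_hits, motif_a, motif_b,
                                     alignments, window))
    return classify_ordering(obs, motif_a.name, motif_b.name, alpha,
                             min_events)


def relative_positions(events_hits: Dict[str, Tuple[List[MotifHit],
                                                    List[MotifHit]]],
                       ) -> Tuple[List[int], int, Optional[float]]:
    """Signed offsets of one motif relative to an anchor motif.

    Per event, offset = transcription-order start of the other motif
    minus that of the anchor, using the closest pair of instances in the
    flanking introns; positive = downstream.  Returns (offsets,
    n_zero, two-sided binomial p on the sign counts).
    """
    offsets = []
    for event_id, (anchor_hits, other_hits) in sorted(events_hits.items()):
        aa = [h for h in anchor_hits if h.region_label in INTRON_LABELS]
        oo = [h for h in other_hits if h.region_label in INTRON_LABELS]
        if not aa or not oo:
            continue
        pairs = [(abs(_tpos(o) - _tpos(a)), a, o) for a in aa for o in oo]
        _, a, o = min(pairs, key=lambda t: t[0])
        offsets.append(_tpos(o) - _tpos(a))
    nonzero = [x for x in offsets if x != 0]
    n_zero = len(offsets) - len(nonzero)
    if not nonzero:
        return offsets, n_zero, None
    n_pos = sum(1 for x in nonzero if x > 0)
    p = float(stats.binomtest(n_pos, len(nonzero), 0.5).pvalue)
    return offsets, n_zero, p
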