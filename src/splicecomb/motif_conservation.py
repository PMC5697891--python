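"""Degenerate RNA motif scanning and cross-species conservation calls.

Motifs are short consensus patterns for splicing-factor binding sites —
e.g. GCAUG (FOX-1/ASD-1), GCACA (MEC-8), U(A|G|U)(A|G)GUU (EXC-7) —
written over {A,C,G,U}, with parenthesised alternations and IUPAC codes.
They are scanned in splice-proximal regions (alternative exon, flanking
introns split into 5'/3' sub-regions, flanking constitutive exons; up to
300 nt from each splice site), on the pre-mRNA sense strand.

A motif occurrence is called conserved when an exact match is present in
at least 2 other species of the alignment within 25 alignment columns of
its position in the reference genome — alignment-column space being the
only coordinate system shared between species.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Sequence, Tuple

import pandas as pd

from .event_catalog import ASEvent
from .formats_io import AlignmentBlock, AlignmentSet, reverse_complement

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

REGION_LABELS = (
    "alt_exon",
    "upstream_intron_5p", "upstream_intron_3p",
    "downstream_intron_5p", "downstream_intron_3p",
    "constitutive_up", "constitutive_down",
)
INTRON_LABELS = frozenset(l for l in REGION_LABELS if "intron" in l)


@dataclass(frozen=True)
class MotifPattern:
    name: str
    positions: Tuple[FrozenSet[str], ...]  # allowed DNA bases per position

    @property
    def length(self) -> int:
        return len(self.positions)

    def rna(self) -> str:
        """Human-readable RNA rendering of the pattern."""
        out = []
        for s in self.positions:
            bases = sorted(b.replace("T", "U") for b in s)
            out.append(bases[0] if len(bases) == 1
                       else "(" + "|".join(bases) + ")")
        return "".join(out)


def parse_motif(pattern: str, name: Optional[str] = None) -> MotifPattern:
    """Parse a degenerate RNA pattern into per-position allowed-base sets.

    Accepts IUPAC codes and parenthesised alternations like ``(A|G|U)``;
    T and U are interchangeable (stored as DNA).
    """
    positions: List[FrozenSet[str]] = []
    i, n = 0, len(pattern)
    s = pattern.strip().upper()
    n = len(s)
    while i < n:
        c = s[i]
        if c == "(":
            j = s.find(")", i)
            if j < 0:
                raise ValueError(f"unbalanced parenthesis in {pattern!r}")
            alts = s[i + 1:j].split("|")
            if not alts or any(len(a) != 1 for a in alts) or "" in alts:
                raise ValueError(f"bad alternation in {pattern!r}")
            bases = set()
            for a in alts:
                if a not in IUPAC:
                    raise ValueError(f"unknown base {a!r} in {pattern!r}")
                bases.update(IUPAC[a])
            positions.append(frozenset(bases))
            i = j + 1
        elif c == ")":
            raise ValueError(f"unbalanced parenthesis in {pattern!r}")
        elif c in IUPAC:
            positions.append(frozenset(IUPAC[c]))
            i += 1
        else:
            raise ValueError(f"unknown symbol {c!r} in {pattern!r}")
    if not positions:
        raise ValueError("empty motif pattern")
    return MotifPattern(name or s, tuple(positions))


def match_at(motif: MotifPattern, seq: str, offset: int) -> bool:
    if offset < 0 or offset + motif.length > len(seq):
        return False
    return all(seq[offset + k] in motif.positions[k]
               for k in range(motif.length))


def find_matches(motif: MotifPattern, seq: str) -> List[int]:
    """All (possibly overlapping) match start offsets in a DNA string."""
    return [i for i in range(len(seq) - motif.length + 1)
            if match_at(motif, seq, i)]


@dataclass
class SpliceRegion:
    event_id: str
    label: str
    seq_id: str
    strand: str
    interval: Tuple[int, int]  # genomic, 0-based half-open
    sequence: str              # pre-mRNA sense strand, DNA alphabet

    def genomic_position(self, offset: int) -> int:
        """Genomic position of a sense-strand offset (start of base)."""
        s, e = self.interval
        return s + offset if self.strand == "+" else e - 1 - offset


@dataclass
class MotifHit:
    motif: str
    event_id: str
    region_label: str
    offset: int          # within region, sense orientation
    genomic_start: int   # genomic coordinate of the sense-first base
    length: int
    seq_id: str
    strand: str
    species_support: int = 0
    conserved: bool = False
    note: Optional[str] = None


def _clip(iv: Tuple[int, int], lo: int, hi: int) -> Optional[Tuple[int, int]]:
    s, e = max(iv[0], lo), min(iv[1], hi)
    return (s, e) if s < e else None


def event_regions(event: ASEvent, genome: Dict[str, str],
                  window: int = 300) -> List[SpliceRegion]:
    """Emit the splice-proximal regions of an event.

    Intron sub-regions take up to ``window`` nt from each splice site and
    are split at the midpoint when the intron is shorter than twice the
    window, so the 5'/3' sub-regions never overlap.  Flanking constitutive
    regions take up to ``window`` nt of exon adjacent to the splice site.
    Labels are in transcription orientation ("upstream" = 5' of the
    alternative region on the pre-mRNA); sequences are sense-strand.
    """
    seq = genome.get(event.seq_id)
    if seq is None:
        raise ValueError(f"sequence {event.seq_id} not in genome")
    L = len(seq)
    alt_lo = event.alt_region[0][0]
    alt_hi = event.alt_region[-1][1]
    if alt_lo < 0 or alt_hi > L:
        raise ValueError(f"event {event.event_id} outside sequence bounds")

    left_intron = (event.flank_up[1], alt_lo)       # genomically left
    right_intron = (alt_hi, event.flank_down[0])    # genomically right
    plus = event.strand == "+"

    def intron_parts(iv):
        s, e = iv
        n = e - s
        if n <= 0:
            return None, None
        if n <= 2 * window:
            mid = s + n // 2
            return (s, mid) if s < mid else None, \
                   (mid, e) if mid < e else None
        return (s, s + window), (e - window, e)

    lL, lR = intron_parts(left_intron)    # left intron: left/right halves
    rL, rR = intron_parts(right_intron)

    # map genomic-side sub-regions to transcription-sense labels
    if plus:
        labelled = [
            ("upstream_intron_5p", lL), ("upstream_intron_3p", lR),
            ("downstream_intron_5p", rL), ("downstream_intron_3p", rR),
        ]
    else:
        labelled = [
            ("upstream_intron_5p", rR), ("upstream_intron_3p", rL),
            ("downstream_intron_5p", lR), ("downstream_intron_3p", lL),
        ]

    # constitutive exon slices proximal to the splice sites, clipped to
    # the exon so hits never straddle a splice site
    c1s, c1e = event.flank_up
    c2s, c2e = event.flank_down
    left_const = (max(c1s, c1e - window), c1e)
    right_const = (c2s, min(c2e, c2s + window))
    if plus:
        labelled += [("constitutive_up", left_const),
                     ("constitutive_down", right_const)]
    else:
        labelled += [("constitutive_up", right_const),
                     ("constitutive_down", left_const)]

    # alternative exon(s): whole exon when within 2*window of a splice
    # site, otherwise the two proximal slices
    alt_ivs = []
    for s, e in event.alt_region:
        if e - s <= 2 * window:
            alt_ivs.append((s, e))
        else:
            alt_ivs.append((s, s + window))
            alt_ivs.append((e - window, e))
    labelled += [("alt_exon", iv) for iv in alt_ivs]

    regions = []
    for label, iv in labelled:
        if iv is None:
            continue
        iv = _clip(iv, 0, L)
        if iv is None:
            continue
        sub = seq[iv[0]:iv[1]]
        if not plus:
            sub = reverse_complement(sub)
        regions.append(SpliceRegion(
            event.event_id, label, event.seq_id, event.strand, iv, sub))
    return regions


def scan_region(motif: MotifPattern, region: SpliceRegion) -> List[MotifHit]:
    """All motif occurrences in a region (conservation unset)."""
    hits = []
    for off in find_matches(motif, region.sequence):
        if region.strand == "+":
            gstart = region.interval[0] + off
        else:
            gstart = region.interval[1] - off - motif.length
        hits.append(MotifHit(
            motif.name, region.event_id, region.label, off, gstart,
            motif.length, region.seq_id, region.strand))
    return hits


def _anchor_column(block: AlignmentBlock, hit: MotifHit) -> Optional[int]:
    """Column of the sense-first base of the reference occurrence."""
    pos = (hit.genomic_start if hit.strand == "+"
           else hit.genomic_start + hit.length - 1)
    if not block.covers(pos):
        return None
    return block.column_of(pos)


def species_support_columns(block: AlignmentBlock, motif: MotifPattern,
                            species: str, strand: str) -> List[int]:
    """Columns (of the sense-first base) of motif matches in one species
    row, scanned on the given strand's sense."""
    seq, cols = block.ungapped(species)
    if strand == "-":
        seq = reverse_complement(seq)
        cols = cols[::-1]
    return [int(cols[i]) for i in find_matches(motif, seq)]


def assess_conservation(hit: MotifHit, motif: MotifPattern,
                        alignments: AlignmentSet,
                        min_species: int = 2,
                        window: int = 25) -> MotifHit:
    """Count supporting species and set the conserved flag on a hit.

    A species supports the hit if its row in the covering block contains
    an exact motif match whose start column is within ``window`` columns
    of the reference start column.
    """
    blocks = alignments.blocks_covering(hit.seq_id, hit.genomic_start)
    support = 0
    for block in blocks:
        c = _anchor_column(block, hit)
        if c is None:
            continue
        n = 0
        for sp in block.rows:
            if sp == block.ref_species:
                continue
            cols = species_support_columns(block, motif, sp, hit.strand)
            if any(abs(cc - c) <= window for cc in cols):
                n += 1
        support = max(support, n)
    hit.species_support = support
    hit.conserved = support >= min_species
    if not blocks:
        hit.note = "unaligned"
    return hit


def scan_events(events: Sequence[ASEvent], genome: Dict[str, str],
                motifs: Sequence[MotifPattern],
                alignments: Optional[AlignmentSet] = None,
                window: int = 300,
                min_species: int = 2,
                conservation_window: int = 25,
                ) -> List[MotifHit]:
    """Scan all motifs over all regions of all events; assess conservation
    when alignments are supplied."""
    hits: List[MotifHit] = []
    for ev in events:
        for region in event_regions(ev, genome, window):
            for motif in motifs:
                for hit in scan_region(motif, region):
                    if alignments is not None:
                        assess_conservation(
                            hit, motif, alignments, min_species,
                            conservation_window)
                    hits.append(hit)
    return hits


def hits_to_table(hits: Sequence[MotifHit]) -> pd.DataFrame:
    return pd.DataFrame([{
        "event_id": h.event_id, "motif": h.motif, "region": h.region_label,
        "offset": h.offset, "seq_id": h.seq_id, "genomic_start":
        h.genomic_start, "length": h.length, "strand": h.strand,
        "species_support": h.species_support, "conserved": h.conserved,
        "note": h.note,
    } for h in hits])


def hits_to_bed(hits: Sequence[MotifHit], path: str) -> None:
    """BED6 export: name = motif:region, score = species support."""
    with open(path, "w") as fh:
        for h in sorted(hits, key=lambda h: (h.seq_id, h.genomic_start)):
            fh.write(
                f"{h.seq_id}\t{h.genomic_start}\t{h.genomic_start + h.length}"
                f"\t{h.motif}:{h.region_label}\t{h.species_support}\t"
                f"{h.strand}\n")
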