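"""Build the non-redundant alternative-splicing event catalog.

Every transcript is subdivided into exon trios; comparing trios across the
isoforms of a gene assigns each candidate middle exon (or exon run, or
boundary variant) an event type: cassette, multi-exon cassette,
alternative 5'/3' splice site, or mutually exclusive exons.  Events are
keyed by their junction coordinates so annotation-dialect differences
collapse, and identical junction sets are reported once.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from .formats_io import Gene, GeneModelSet, JunctionKey, Transcript

EVENT_TYPES = ("cassette", "multi_cassette", "alt5", "alt3",
               "mutually_exclusive")

# junction role labels: C1/C2 flanking constitutive exons, A alternative
ROLE_C1A = "C1A"
ROLE_AC2 = "AC2"
ROLE_C1C2 = "C1C2"
ROLE_CiA = "CiA"
ROLE_ACj = "ACj"
ROLE_CiCj = "CiCj"


@dataclass
class ASEvent:
    event_id: str
    gene_id: str
    seq_id: str
    strand: str
    type: str
    alt_region: List[Tuple[int, int]]
    flank_up: Tuple[int, int]    # C1 (genomically left)
    flank_down: Tuple[int, int]  # C2 (genomically right)
    inclusion_junctions: List[Tuple[str, JunctionKey]] = field(
        default_factory=list)
    exclusion_junctions: List[Tuple[str, JunctionKey]] = field(
        default_factory=list)
    novel: bool = False

    def __post_init__(self) -> None:
        if self.type not in EVENT_TYPES:
            raise ValueError(f"unknown event type {self.type!r}")
        inc = {k for _, k in self.inclusion_junctions}
        exc = {k for _, k in self.exclusion_junctions}
        if inc & exc:
            raise ValueError(
                f"event {self.event_id}: inclusion and exclusion junction "
                "sets overlap")

    @property
    def junction_signature(self) -> tuple:
        return (
            tuple(sorted(k for _, k in self.inclusion_junctions)),
            tuple(sorted(k for _, k in self.exclusion_junctions)),
        )

    def upstream_intron(self) -> Tuple[int, int]:
        """Intron between C1 and the alternative region (genomic order)."""
        return (self.flank_up[1], self.alt_region[0][0])

    def downstream_intron(self) -> Tuple[int, int]:
        return (self.alt_region[-1][1], self.flank_down[0])


def _jk(seq_id: str, donor: int, acceptor: int, strand: str) -> JunctionKey:
    return JunctionKey(seq_id, donor, acceptor, strand)


def _cassette_events(gene: Gene) -> List[ASEvent]:
    """Cassette and multi-cassette candidates from trio/skip comparison."""
    events = []
    intron_sets = [set(t.introns()) for t in gene.transcripts]
    all_introns = set().union(*intron_sets) if intron_sets else set()
    for t in gene.transcripts:
        exons = t.exons
        # runs of 1..k consecutive internal exons flanked by c1, c2
        for i in range(1, len(exons) - 1):
            for j in range(i, len(exons) - 1):
                c1, c2 = exons[i - 1], exons[j + 1]
                skip = (c1[1], c2[0])
                if skip not in all_introns or skip in set(t.introns()):
                    continue
                run = exons[i:j + 1]
                if len(run) == 1:
                    etype = "cassette"
                    inc = [
                        (ROLE_C1A, _jk(gene.seq_id, c1[1], run[0][0],
                                       gene.strand)),
                        (ROLE_AC2, _jk(gene.seq_id, run[-1][1], c2[0],
                                       gene.strand)),
                    ]
                else:
                    etype = "multi_cassette"
                    # outermost inclusion junctions only
                    inc = [
                        (ROLE_C1A, _jk(gene.seq_id, c1[1], run[0][0],
                                       gene.strand)),
                        (ROLE_AC2, _jk(gene.seq_id, run[-1][1], c2[0],
                                       gene.strand)),
                    ]
                exc = [(ROLE_C1C2, _jk(gene.seq_id, skip[0], skip[1],
                                       gene.strand))]
                events.append(ASEvent(
                    "", gene.gene_id, gene.seq_id, gene.strand, etype,
                    [tuple(e) for e in run], c1, c2, inc, exc))
    return events


def _altsite_events(gene: Gene) -> List[ASEvent]:
    """Alternative 5'/3' splice-site events: middle exons of two isoforms
    sharing one boundary and differing at the other."""
    events = []
    trios = []
    for t in gene.transcripts:
        for i in range(1, len(t.exons) - 1):
            trios.append((t.exons[i - 1], t.exons[i], t.exons[i + 1]))
    for a in range(len(trios)):
        for b in range(a + 1, len(trios)):
            (c1a, ma, c2a), (c1b, mb, c2b) = trios[a], trios[b]
            if ma == mb:
                continue
            # same flanking introns context: shared C1 donor & C2 acceptor
            if c1a[1] != c1b[1] or c2a[0] != c2b[0]:
                continue
            shared_start = ma[0] == mb[0]
            shared_end = ma[1] == mb[1]
            if shared_start == shared_end:
                continue  # both differ (handled as MXE) or identical
            c1d, c2a_ = c1a[1], c2a[0]
            if shared_start:
                # alternative donor end of the middle exon
                short, long_ = sorted([ma, mb], key=lambda e: e[1])
                ext = (short[1], long_[1])
                varies_at_3p_genomic = True
            else:
                short, long_ = sorted([ma, mb], key=lambda e: -e[0])
                # short starts later (genomically shorter exon)
                ext = (long_[0], short[0])
                varies_at_3p_genomic = False
            # biological type depends on which transcription-direction end
            # varies: donor end varies -> alt5, acceptor end -> alt3
            if gene.strand == "+":
                etype = "alt5" if varies_at_3p_genomic else "alt3"
            else:
                etype = "alt3" if varies_at_3p_genomic else "alt5"
            if varies_at_3p_genomic:
                shared_j = (ROLE_CiA, _jk(gene.seq_id, c1d, long_[0],
                                          gene.strand))
                inc_j = (ROLE_ACj, _jk(gene.seq_id, long_[1], c2a_,
                                       gene.strand))
                exc_j = (ROLE_CiCj, _jk(gene.seq_id, short[1], c2a_,
                                        gene.strand))
            else:
                shared_j = (ROLE_ACj, _jk(gene.seq_id, long_[1], c2a_,
                                          gene.strand))
                inc_j = (ROLE_CiA, _jk(gene.seq_id, c1d, long_[0],
                                       gene.strand))
                exc_j = (ROLE_CiCj, _jk(gene.seq_id, c1d, short[0],
                                        gene.strand))
            events.append(ASEvent(
                "", gene.gene_id, gene.seq_id, gene.strand, etype,
                [ext], c1a, c2a, [shared_j, inc_j], [exc_j]))
    return events


def _mxe_events(gene: Gene) -> List[ASEvent]:
    """Mutually exclusive middle exons: same flanks, disjoint middles that
    never co-occur in any isoform."""
    events = []
    trios = []
    for t in gene.transcripts:
        for i in range(1, len(t.exons) - 1):
            trios.append((t.exons[i - 1], t.exons[i], t.exons[i + 1]))
    exon_sets = [set(map(tuple, t.exons)) for t in gene.transcripts]
    for a in range(len(trios)):
        for b in range(a + 1, len(trios)):
            (c1a, ma, c2a), (c1b, mb, c2b) = trios[a], trios[b]
            if c1a[1] != c1b[1] or c2a[0] != c2b[0] or ma == mb:
                continue
            if not (ma[1] <= mb[0] or mb[1] <= ma[0]):
                continue  # overlapping: alt-site territory
            cooccur = any(
                tuple(ma) in es and tuple(mb) in es for es in exon_sets)
            if cooccur:
                continue
            e5, e3 = sorted([ma, mb])  # genomic order; PSI = 5'-most exon
            inc = [
                (ROLE_C1A, _jk(gene.seq_id, c1a[1], e5[0], gene.strand)),
                (ROLE_AC2, _jk(gene.seq_id, e5[1], c2a[0], gene.strand)),
            ]
            exc = [
                (ROLE_C1A, _jk(gene.seq_id, c1a[1], e3[0], gene.strand)),
                (ROLE_AC2, _jk(gene.seq_id, e3[1], c2a[0], gene.strand)),
            ]
            events.append(ASEvent(
                "", gene.gene_id, gene.seq_id, gene.strand,
                "mutually_exclusive", [tuple(e5), tuple(e3)], c1a, c2a,
                inc, exc))
    return events


def build_catalog(models: GeneModelSet) -> List[ASEvent]:
    """Assemble the non-redundant, deterministically ordered event list."""
    raw: List[ASEvent] = []
    for gene in models.genes:
        raw.extend(_cassette_events(gene))
        raw.extend(_altsite_events(gene))
        raw.extend(_mxe_events(gene))
    # collapse events with identical junction sets; cassette events also
    # subsume MXE candidates that share their junctions
    seen: Dict[tuple, ASEvent] = {}
    for ev in raw:
        sig = ev.junction_signature
        if sig not in seen:
            seen[sig] = ev
    events = sorted(
        seen.values(),
        key=lambda e: (e.seq_id, e.alt_region[0][0], e.alt_region[-1][1],
                       e.type, e.gene_id),
    )
    for i, ev in enumerate(events, 1):
        ev.event_id = f"{ev.gene_id}.{ev.type}.{i:05d}"
    return events


def event_junctions(event: ASEvent) -> Dict[str, List[JunctionKey]]:
    """Role-labelled junction keys of a typed event."""
    if event.type not in EVENT_TYPES:
        raise ValueError(f"untyped or unknown event: {event.type!r}")
    out: Dict[str, List[JunctionKey]] = {}
    for role, key in event.inclusion_junctions + event.exclusion_junctions:
        out.setdefault(role, []).append(key)
    return out


def mark_novel(events: Sequence[ASEvent], models: GeneModelSet) -> None:
    """Flag events whose junctions are absent from the annotation."""
    annotated = set()
    for g in models.genes:
        for t in g.transcripts:
            for d, a in t.introns():
                annotated.add((g.seq_id, d, a))
    for ev in events:
        keys = [k for _, k in ev.inclusion_junctions + ev.exclusion_junctions]
        ev.novel = any(
            (k.seq_id, k.donor_pos, k.acceptor_pos) not in annotated
            for k in keys)


def catalog_to_table(events: Sequence[ASEvent]) -> pd.DataFrame:
    rows = []
    for ev in events:
        rows.append({
            "event_id": ev.event_id,
            "gene_id": ev.gene_id,
            "seq_id": ev.seq_id,
            "strand": ev.strand,
            "type": ev.type,
            "alt_region": ";".join(f"{s}-{e}" for s, e in ev.alt_region),
            "flank_up": f"{ev.flank_up[0]}-{ev.flank_up[1]}",
            "flank_down": f"{ev.flank_down[0]}-{ev.flank_down[1]}",
            "inclusion_junctions": ";".join(
                f"{r}:{k.donor_pos}-{k.acceptor_pos}"
                for r, k in ev.inclusion_junctions),
            "exclusion_junctions": ";".join(
                f"{r}:{k.donor_pos}-{k.acceptor_pos}"
                for r, k in ev.exclusion_junctions),
            "novel": ev.novel,
        })
    return pd.DataFrame(rows)


def catalog_to_gff3(events: Sequence[ASEvent], path: str) -> None:
    """Side export of events as GFF3 features for browser inspection."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for ev in events:
            for s, e in ev.alt_region:
                fh.write(
                    f"{ev.seq_id}\tsplicecomb\t{ev.type}\t{s + 1}\t{e}\t.\t"
                    f"{ev.strand}\t.\tID={ev.event_id};gene={ev.gene_id}\n")
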