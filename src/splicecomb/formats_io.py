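"""Readers, writers and coordinate conventions shared by the whole pipeline.

All internal coordinates are 0-based half-open ``[start, end)``; conversion
to/from the 1-based inclusive convention of GFF3/GTF/MAF happens only at
file boundaries.  Sequences are stored as DNA (T); motif matching converts
to RNA presentation on the fly (see :mod:`splicecomb.motif_conservation`).

A splice junction is keyed by its intron: ``(seq_id, donor_pos,
acceptor_pos, strand)`` where ``donor_pos`` is the first intronic base and
``acceptor_pos`` is one past the last intronic base, both in genomic order
(``donor_pos < acceptor_pos`` always; strand is carried separately so that
counts match events regardless of annotation strand).
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, NamedTuple, Optional, Sequence, Tuple

import gffutils
import numpy as np
import pandas as pd
from Bio import AlignIO, SeqIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

# Default species set: the five Elegans-group nematodes used for
# phylogenetic filtering of motifs.  The first entry is the reference.
ELEGANS_GROUP = ("cele", "cbri", "crem", "csp11", "cbre")

COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


class JunctionKey(NamedTuple):
    """An intron, in genomic order, identifying one splice junction."""

    seq_id: str
    donor_pos: int      # 0-based first intronic position
    acceptor_pos: int   # 0-based one-past-last intronic position
    strand: str


@dataclass
class Transcript:
    transcript_id: str
    exons: List[Tuple[int, int]]  # sorted, non-overlapping, genomic order

    def introns(self) -> List[Tuple[int, int]]:
        return [
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        ]


@dataclass
class Gene:
    gene_id: str
    seq_id: str
    strand: str
    transcripts: List[Transcript]


@dataclass
class GeneModelSet:
    genes: List[Gene]

    def __post_init__(self) -> None:
        for g in self.genes:
            if g.strand not in ("+", "-"):
                raise ValueError(f"gene {g.gene_id}: bad strand {g.strand!r}")
            for t in g.transcripts:
                for s, e in t.exons:
                    if not s < e:
                        raise ValueError(
                            f"transcript {t.transcript_id}: exon [{s},{e}) "
                            "has start >= end"
                        )
                for (s1, e1), (s2, e2) in zip(t.exons, t.exons[1:]):
                    if e1 > s2:
                        raise ValueError(
                            f"transcript {t.transcript_id}: exons overlap "
                            "or are unsorted"
                        )

    def by_gene(self) -> Dict[str, Gene]:
        return {g.gene_id: g for g in self.genes}


@dataclass
class JunctionCountTable:
    """Per-sample junction read counts keyed by intron coordinates."""

    sample_id: str
    counts: Dict[JunctionKey, int] = field(default_factory=dict)

    def get(self, key: JunctionKey) -> int:
        # counts are strand-aware on input but matched strand-free, since
        # a junction's genomic footprint identifies it uniquely
        n = self.counts.get(key)
        if n is None:
            alt = key._replace(strand="-" if key.strand == "+" else "+")
            n = self.counts.get(alt, 0)
        return n


@dataclass
class AlignmentBlock:
    """One syntenic block of the multi-species alignment.

    ``rows`` maps species id to its gapped row (equal lengths); the
    reference species row anchors ``ref_start`` (0-based genomic position
    of its first ungapped base, always on the + strand after
    normalisation).  ``column_of`` / ``position_of`` convert between
    ungapped reference positions and alignment columns.
    """

    ref_species: str
    ref_seq_id: str
    ref_start: int
    rows: Dict[str, str]

    def __post_init__(self) -> None:
        lengths = {len(r) for r in self.rows.values()}
        if len(lengths) > 1:
            raise ValueError("alignment block rows have unequal lengths")
        ref = self.rows[self.ref_species]
        cols = [i for i, c in enumerate(ref) if c != "-"]
        self._cols = np.asarray(cols, dtype=int)

    @property
    def width(self) -> int:
        return len(self.rows[self.ref_species])

    @property
    def ref_length(self) -> int:
        return len(self._cols)

    @property
    def ref_end(self) -> int:
        return self.ref_start + self.ref_length

    def column_of(self, genomic_pos: int) -> int:
        """Alignment column of an ungapped reference genomic position."""
        off = genomic_pos - self.ref_start
        if not 0 <= off < self.ref_length:
            raise IndexError(f"position {genomic_pos} outside block")
        return int(self._cols[off])

    def position_of(self, column: int) -> int:
        """Genomic position of the reference base at/left of a column."""
        idx = int(np.searchsorted(self._cols, column, side="right")) - 1
        if idx < 0:
            raise IndexError(f"column {column} precedes first reference base")
        return self.ref_start + idx

    def covers(self, genomic_pos: int) -> bool:
        return self.ref_start <= genomic_pos < self.ref_end

    def ungapped(self, species: str) -> Tuple[str, np.ndarray]:
        """Ungapped row of a species and the column index of each base."""
        row = self.rows[species]
        cols = np.array([i for i, c in enumerate(row) if c != "-"], dtype=int)
        seq = row.replace("-", "")
        return seq, cols


@dataclass
class AlignmentSet:
    ref_species: str
    blocks: List[AlignmentBlock]

    def blocks_covering(self, seq_id: str, pos: int) -> List[AlignmentBlock]:
        return [
            b for b in self.blocks if b.ref_seq_id == seq_id and b.covers(pos)
        ]


# ---------------------------------------------------------------------------
# gene models


def _validate_annotation_lines(path: str) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise ValueError(
                    f"{path}: malformed annotation line {lineno}: "
                    f"expected 9 tab-separated fields, got {len(fields)}"
                )
            try:
                int(fields[3]), int(fields[4])
            except ValueError:
                raise ValueError(
                    f"{path}: malformed annotation line {lineno}: "
                    "non-integer coordinates"
                ) from None


def read_gene_models(path: str) -> GeneModelSet:
    """Read a GFF3 or GTF annotation into a :class:`GeneModelSet`.

    1-based inclusive file coordinates become 0-based half-open.  Both
    dialects are accepted (gffutils sniffs the attribute syntax); GTF
    gene/transcript features are inferred from exon lines when absent.
    """
    _validate_annotation_lines(path)
    db = gffutils.create_db(
        path,
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
        disable_infer_genes=False,
        disable_infer_transcripts=False,
    )
    genes: List[Gene] = []
    transcript_kinds = ("mRNA", "transcript")
    for gf in db.features_of_type("gene", order_by=("seqid", "start")):
        transcripts = []
        for kind in transcript_kinds:
            for tf in db.children(gf, featuretype=kind, order_by="start"):
                exons = [
                    (ef.start - 1, ef.end)
                    for ef in db.children(tf, featuretype="exon",
                                          order_by="start")
                ]
                if exons:
                    transcripts.append(Transcript(tf.id, exons))
        if transcripts:
            genes.append(Gene(gf.id, gf.seqid, gf.strand, transcripts))
    # orphan exons: exon features whose parent is not a known transcript
    known = {t.transcript_id for g in genes for t in g.transcripts}
    for ef in db.features_of_type("exon"):
        parents = list(db.parents(ef, featuretype=transcript_kinds))
        if not parents:
            raise ValueError(
                f"{path}: exon {ef.id} at {ef.seqid}:{ef.start} has no "
                "parent transcript"
            )
    del known
    return GeneModelSet(genes)


def write_gene_models(models: GeneModelSet, path: str,
                      header_comments: Iterable[str] = ()) -> None:
    """Write a GeneModelSet as GFF3 (internal start + 1 on export)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for line in header_comments:
            fh.write(f"#{line}\n")
        for g in models.genes:
            gs = min(t.exons[0][0] for t in g.transcripts)
            ge = max(t.exons[-1][1] for t in g.transcripts)
            fh.write(
                f"{g.seq_id}\tsplicecomb\tgene\t{gs + 1}\t{ge}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id}\n"
            )
            for t in g.transcripts:
                ts, te = t.exons[0][0], t.exons[-1][1]
                fh.write(
                    f"{g.seq_id}\tsplicecomb\tmRNA\t{ts + 1}\t{te}\t.\t"
                    f"{g.strand}\t.\tID={t.transcript_id};Parent={g.gene_id}\n"
                )
                for i, (s, e) in enumerate(t.exons, 1):
                    fh.write(
                        f"{g.seq_id}\tsplicecomb\texon\t{s + 1}\t{e}\t.\t"
                        f"{g.strand}\t.\tID={t.transcript_id}.e{i};"
                        f"Parent={t.transcript_id}\n"
                    )


# ---------------------------------------------------------------------------
# junction counts

JUNCTION_COLUMNS = ["seq_id", "donor", "acceptor", "strand", "count"]


def read_junction_counts(path: str, sample_id: Optional[str] = None
                         ) -> JunctionCountTable:
    """Read a 5-column tab-separated junction count table (one sample).

    Columns: seq_id, donor, acceptor, strand, count; donor/acceptor are the
    0-based half-open intron boundaries.  Duplicate keys are summed.  A
    comment line ``# sample_id=<id>`` names the sample; otherwise the file
    stem is used.
    """
    if sample_id is None:
        sample_id = os.path.splitext(os.path.basename(path))[0]
        with open(path) as fh:
            for line in fh:
                if line.startswith("#") and "sample_id=" in line:
                    sample_id = line.split("sample_id=", 1)[1].strip()
                if not line.startswith("#"):
                    break
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = set(JUNCTION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    if df.empty:
        return JunctionCountTable(sample_id, {})
    counts_raw = pd.to_numeric(df["count"], errors="raise")
    if (counts_raw < 0).any():
        raise ValueError(f"{path}: negative junction count")
    if not np.allclose(counts_raw, np.round(counts_raw)):
        raise ValueError(f"{path}: non-integer junction count")
    table: Dict[JunctionKey, int] = {}
    for row in df.itertuples(index=False):
        d, a = int(row.donor), int(row.acceptor)
        key = JunctionKey(str(row.seq_id), min(d, a), max(d, a),
                          str(row.strand))
        table[key] = table.get(key, 0) + int(row.count)
    return JunctionCountTable(sample_id, table)


def write_junction_counts(table: JunctionCountTable, path: str,
                          header_comments: Iterable[str] = ()) -> None:
    with open(path, "w") as fh:
        fh.write(f"# sample_id={table.sample_id}\n")
        for line in header_comments:
            fh.write(f"# {line}\n")
        fh.write("\t".join(JUNCTION_COLUMNS) + "\n")
        for key in sorted(table.counts):
            fh.write(
                f"{key.seq_id}\t{key.donor_pos}\t{key.acceptor_pos}\t"
                f"{key.strand}\t{table.counts[key]}\n"
            )


# ---------------------------------------------------------------------------
# alignments


def _split_src(src: str) -> Tuple[str, str]:
    if "." in src:
        sp, seq = src.split(".", 1)
    else:
        sp, seq = src, src
    return sp, seq


def read_alignments(path: str,
                    ref_species: str = ELEGANS_GROUP[0],
                    species: Optional[Sequence[str]] = None,
                    ) -> AlignmentSet:
    """Read a MAF file, keeping rows for ``species`` (default: all seen).

    MAF src fields are ``species.seq_id``.  Blocks lacking the reference
    row are skipped; blocks whose reference row is on the minus strand are
    normalised to reference-forward orientation by reverse-complementing
    every row.
    """
    blocks: List[AlignmentBlock] = []
    for msa in AlignIO.parse(path, "maf"):
        rows: Dict[str, str] = {}
        ref_rec = None
        for rec in msa:
            sp, seq_id = _split_src(rec.id)
            if species is not None and sp not in species and sp != ref_species:
                continue
            rows[sp] = str(rec.seq).upper().replace("U", "T")
            if sp == ref_species:
                ref_rec = rec
                ref_seq_id = seq_id
        if ref_rec is None:
            continue  # no reference row: not anchorable, skip
        ann = ref_rec.annotations
        start = int(ann.get("start", 0))
        strand = int(ann.get("strand", 1))
        if strand == -1:
            size = int(ann["size"])
            src_size = int(ann["srcSize"])
            start = src_size - start - size
            rows = {sp: reverse_complement(r) for sp, r in rows.items()}
        blocks.append(AlignmentBlock(ref_species, ref_seq_id, start, rows))
    return AlignmentSet(ref_species, blocks)


def write_alignments(aln: AlignmentSet, path: str,
                     seq_sizes: Optional[Dict[str, int]] = None,
                     header_comments: Iterable[str] = ()) -> None:
    """Write an AlignmentSet as MAF (reference-forward blocks)."""
    with open(path, "w") as fh:
        fh.write("##maf version=1 scoring=none\n")
        for line in header_comments:
            fh.write(f"# {line}\n")
        for b in aln.blocks:
            fh.write("\na score=0.0\n")
            order = [b.ref_species] + [
                sp for sp in sorted(b.rows) if sp != b.ref_species
            ]
            for sp in order:
                row = b.rows[sp]
                size = len(row) - row.count("-")
                if sp == b.ref_species:
                    src = f"{sp}.{b.ref_seq_id}"
                    start = b.ref_start
                    src_size = (seq_sizes or {}).get(b.ref_seq_id,
                                                     b.ref_end + 1000)
                else:
                    src = f"{sp}.{b.ref_seq_id}"
                    start = 0
                    src_size = max(size, 1)
                fh.write(
                    f"s {src} {start} {size} + {src_size} {row}\n"
                )
        fh.write("\n")


# ---------------------------------------------------------------------------
# genome FASTA


def read_genome(path: str) -> Dict[str, str]:
    """Read a genome FASTA into a dict of uppercase DNA strings (U→T)."""
    return {
        rec.id: str(rec.seq).upper().replace("U", "T")
        for rec in SeqIO.parse(path, "fasta")
    }


def write_genome(genome: Dict[str, str], path: str) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in
        genome.items()
    ]
    SeqIO.write(records, path, "fasta")


# ---------------------------------------------------------------------------
# result tables


def write_table(df: pd.DataFrame, path: str,
                header_comments: Iterable[str] = ()) -> None:
    """Write a result table: commented header lines, then TSV with '.' for
    missing values."""
    with open(path, "w") as fh:
        for line in header_comments:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False, na_rep=".")


def read_table(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", na_values=["."])
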