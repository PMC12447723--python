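"""On-disk formats: FASTA, BED12, GTF/GFF3 conversion, and the splice-score table.

All coordinates are 0-based half-open internally; conversions to and from
1-based formats (GTF/GFF3) happen only at the parse boundary.

Splice-score offset convention
------------------------------
A splice boundary sits between two bases on the forward strand.  The
``offset`` column of a score record is the 0-based forward-strand coordinate
of the base immediately to the *right* of that boundary.  For an intron
occupying forward interval ``[s, e)``:

* left boundary  -> offset ``s``  (``+`` donor / ``-`` acceptor)
* right boundary -> offset ``e``  (``+`` acceptor / ``-`` donor)

so a ``+`` donor offset points at the G of the intronic GT, and a ``+``
acceptor offset points at the first exonic base after the AG.
"""

from __future__ import annotations

import gzip
import io
import logging
import re
from dataclasses import dataclass, field

from Bio import SeqIO

logger = logging.getLogger(__name__)

_NON_ACGTN = re.compile(r"[^ACGTN]")

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class ParseError(ValueError):
    """Malformed input file; message carries the offending line number."""


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


@dataclass
class GenomeSequence:
    """One FASTA record: uppercase sequence over {A,C,G,T,N}."""

    name: str
    seq: str
    index_in_file: int  # 1-based ordinal of the record in the FASTA

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class GeneModel:
    """One transcript with BED12 semantics (0-based half-open exon blocks)."""

    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    exons: list[tuple[int, int]]
    name: str
    gene_id: str = ""

    def __post_init__(self) -> None:
        if not self.gene_id:
            self.gene_id = self.name

    @property
    def introns(self) -> list[tuple[int, int]]:
        """Gaps between consecutive exons, forward-strand coordinates."""
        return [
            (self.exons[k][1], self.exons[k + 1][0])
            for k in range(len(self.exons) - 1)
        ]


@dataclass(frozen=True, order=True)
class ScoreRecord:
    """One line of the 5-column splice-score table."""

    chrom: str
    offset: int
    strand: str
    site_type: str  # 'D' or 'A'
    score: int = field(compare=False, default=0)


def _open_text(path, mode: str = "rt"):
    """Open plain or gzip file as text; gzip is detected by magic bytes."""
    if "r" in mode:
        with open(path, "rb") as fh:
            magic = fh.read(2)
        if magic == b"\x1f\x8b":
            return io.TextIOWrapper(gzip.open(path, "rb"))
        return open(path, "rt")
    if str(path).endswith(".gz"):
        return io.TextIOWrapper(gzip.open(path, mode.replace("t", "") + "b"))
    return open(path, mode)


def normalize_seq(seq: str) -> str:
    """Uppercase and map any character outside ACGTN to N."""
    return _NON_ACGTN.sub("N", seq.upper())


def read_fasta(path) -> list[GenomeSequence]:
    """Load all records of a plain or gzip-compressed FASTA into memory."""
    with _open_text(path) as fh:
        first = fh.readline()
        if first == "":
            raise ParseError(f"{path}: empty FASTA (line 1)")
        if not first.startswith(">"):
            raise ParseError(f"{path}: line 1 does not start with '>'")
        fh.seek(0)
        records = [
            GenomeSequence(rec.id, normalize_seq(str(rec.seq)), i)
            for i, rec in enumerate(SeqIO.parse(fh, "fasta"), start=1)
        ]
    for rec in records:
        if not rec.seq:
            raise ParseError(f"{path}: record '{rec.name}' has empty sequence")
    return records


def write_fasta(seqs: list[GenomeSequence], path, width: int = 80) -> None:
    with _open_text(path, "wt") as fh:
        for rec in seqs:
            fh.write(f">{rec.name}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def read_bed12(path) -> list[GeneModel]:
    """Parse a 12-column BED file into GeneModels (exons from block arithmetic)."""
    models = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 12:
                raise ParseError(f"{path}:{lineno}: expected 12 columns, got {len(cols)}")
            chrom, start, end, name = cols[0], int(cols[1]), int(cols[2]), cols[3]
            strand = cols[5]
            if strand not in "+-":
                raise ParseError(f"{path}:{lineno}: bad strand {strand!r}")
            n_blocks = int(cols[9])
            sizes = [int(x) for x in cols[10].rstrip(",").split(",")]
            starts = [int(x) for x in cols[11].rstrip(",").split(",")]
            if len(sizes) != n_blocks or len(starts) != n_blocks:
                raise ParseError(f"{path}:{lineno}: blockCount mismatch")
            exons = [(start + s, start + s + z) for s, z in zip(starts, sizes)]
            for (a0, b0), (a1, b1) in zip(exons, exons[1:]):
                if a1 < b0:
                    raise ParseError(f"{path}:{lineno}: overlapping blocks")
            if exons[0][0] < start or exons[-1][1] > end:
                raise ParseError(f"{path}:{lineno}: blocks out of transcript range")
            models.append(GeneModel(chrom, strand, start, end, exons, name))
    return models


def write_bed12(models: list[GeneModel], path) -> None:
    with _open_text(path, "wt") as fh:
        for g in models:
            sizes = ",".join(str(b - a) for a, b in g.exons) + ","
            starts = ",".join(str(a - g.tx_start) for a, _ in g.exons) + ","
            fh.write(
                "\t".join(
                    [
                        g.chrom,
                        str(g.tx_start),
                        str(g.tx_end),
                        g.name,
                        "0",
                        g.strand,
                        str(g.tx_start),
                        str(g.tx_end),
                        "0",
                        str(len(g.exons)),
                        sizes,
                        starts,
                    ]
                )
                + "\n"
            )


_GTF_TX = re.compile(r'transcript_id\s+"([^"]+)"')
_GTF_GENE = re.compile(r'gene_id\s+"([^"]+)"')


def _gff3_attrs(s: str) -> dict[str, str]:
    out = {}
    for part in s.split(";"):
        if "=" in part:
            k, v = part.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def gxf_to_bed12(path, dialect: str) -> list[GeneModel]:
    """Convert GTF or GFF3 annotation to GeneModels (one per transcript).

    Exon features are grouped by transcript_id (GTF) or Parent (GFF3);
    1-based inclusive coordinates become 0-based half-open.  Exons lacking a
    grouping key are skipped (count logged as a warning).
    """
    dialect = dialect.upper()
    if dialect not in ("GTF", "GFF3"):
        raise ValueError(f"unknown dialect {dialect!r}")
    exons_by_tx: dict[str, list] = {}
    meta: dict[str, tuple[str, str, str]] = {}  # tx -> (chrom, strand, gene_id)
    tx_to_gene: dict[str, str] = {}
    n_skipped = 0
    with _open_text(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 9:
                continue
            chrom, _, feature, start, end, _, strand, _, attrs = cols[:9]
            if dialect == "GFF3" and feature in ("mRNA", "transcript"):
                a = _gff3_attrs(attrs)
                if "ID" in a and "Parent" in a:
                    tx_to_gene[a["ID"]] = a["Parent"]
            if feature != "exon":
                continue
            if dialect == "GTF":
                m_tx = _GTF_TX.search(attrs)
                tx = m_tx.group(1) if m_tx else None
                m_g = _GTF_GENE.search(attrs)
                gene = m_g.group(1) if m_g else tx
            else:
                tx = _gff3_attrs(attrs).get("Parent")
                gene = None  # resolved after the pass, via mRNA records
            if tx is None:
                n_skipped += 1
                continue
            iv = (int(start) - 1, int(end))
            exons_by_tx.setdefault(tx, []).append(iv)
            meta.setdefault(tx, (chrom, strand, gene or tx))
    if n_skipped:
        logger.warning("gxf_to_bed12: skipped %d exon(s) without transcript key", n_skipped)
    models = []
    for tx, exons in exons_by_tx.items():
        chrom, strand, gene = meta[tx]
        if dialect == "GFF3":
            gene = tx_to_gene.get(tx, tx)
        exons = sorted(set(exons))
        models.append(
            GeneModel(chrom, strand, exons[0][0], exons[-1][1], exons, tx, gene)
        )
    models.sort(key=lambda g: (g.chrom, g.tx_start, g.name))
    return models


def write_score_file(records: list[ScoreRecord], path) -> None:
    """Serialize score records as the 5-column TAB format (optionally gzip)."""
    seen = set()
    with _open_text(path, "wt") as fh:
        for r in records:
            key = (r.chrom, r.offset, r.strand, r.site_type)
            if key in seen:
                raise ValueError(f"duplicate score record {key}")
            seen.add(key)
            fh.write(f"{r.chrom}\t{r.offset}\t{r.strand}\t{r.site_type}\t{r.score}\n")


class ScoreTable:
    """Indexed lookup (chrom, offset, strand, site_type) -> integer score."""

    def __init__(self, records: list[ScoreRecord] | None = None):
        self._d: dict[tuple[str, int, str, str], int] = {}
        for r in records or []:
            self.add(r)

    def add(self, r: ScoreRecord) -> None:
        key = (r.chrom, r.offset, r.strand, r.site_type)
        if key in self._d:
            raise ValueError(f"duplicate score record {key}")
        self._d[key] = r.score

    def get(self, chrom: str, offset: int, strand: str, site_type: str, default=None):
        return self._d.get((chrom, offset, strand, site_type), default)

    def __len__(self) -> int:
        return len(self._d)

    def __iter__(self):
        for (chrom, offset, strand, st), score in sorted(self._d.items()):
            yield ScoreRecord(chrom, offset, strand, st, score)


def read_score_file(path) -> ScoreTable:
    table = ScoreTable()
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) != 5:
                raise ParseError(f"{path}:{lineno}: expected 5 columns")
            chrom, offset, strand, st, score = cols
            if strand not in "+-" or st not in "DA":
                raise ParseError(f"{path}:{lineno}: bad strand/type {strand} {st}")
            table.add(ScoreRecord(chrom, int(offset), strand, st, int(score)))
    return table
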