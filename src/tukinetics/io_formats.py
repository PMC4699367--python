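"""Annotation, read and count-table I/O plus normalized abundance units.

Internal coordinates are 0-based half-open throughout; GTF is converted on
ingest (1-based inclusive) and on export.  Gene models are restricted to at
most one intron (two exons), mirroring the usual selection for splicing-
kinetics work in budding yeast where multi-intron genes are rare and excluded.

The counting unit is the *fragment* (a read pair collapses to one record),
which is what FPKM normalizes.
"""

from __future__ import annotations

import os
import tempfile
from dataclasses import dataclass, field

import gffutils
import pandas as pd
import pysam

__all__ = [
    "TranscriptModel",
    "ReadRecord",
    "read_annotation",
    "write_annotation",
    "load_reads",
    "write_read_table",
    "count_regions",
    "REGION_COLUMNS",
    "fpkm",
]

#: columns of a count table, in transcription order.  ``exon1`` is the first
#: transcribed exon (rightmost genomic exon on the minus strand).
REGION_COLUMNS = ["exon1", "intron", "exon2", "junction", "b5", "b3", "assigned"]

TRANSCRIPT_CLASSES = (
    "RP-intronic",
    "non-RP-intronic",
    "CUT",
    "SUT",
    "XUT",
    "snoRNA",
    "other",
)


@dataclass
class TranscriptModel:
    """A gene with at most two exons (hence at most one intron).

    ``exons`` are genomic intervals, 0-based half-open, sorted by start.
    ``tx_class`` is a free-form transcript class label; the simulator uses
    the yeast vocabulary (RP-intronic, non-RP-intronic, CUT, SUT, XUT,
    snoRNA, other).
    """

    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    tx_class: str = "other"
    sequence: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        exons = sorted(tuple(e) for e in self.exons)
        if not exons:
            raise ValueError(f"{self.gene_id}: at least one exon required")
        if len(exons) > 2:
            raise ValueError(
                f"{self.gene_id}: at most one intron (two exons) supported"
            )
        for (s, e) in exons:
            if not (0 <= s < e):
                raise ValueError(f"{self.gene_id}: bad exon interval ({s}, {e})")
        if len(exons) == 2 and exons[0][1] >= exons[1][0]:
            raise ValueError(f"{self.gene_id}: exons overlap or touch")
        self.exons = exons

    # ------------------------------------------------------------------ span
    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def intron(self) -> tuple[int, int] | None:
        """Genomic intron interval, or None for single-exon genes."""
        if len(self.exons) == 1:
            return None
        return (self.exons[0][1], self.exons[1][0])

    @property
    def has_intron(self) -> bool:
        return self.intron is not None

    # ----------------------------------------------------- transcription order
    @property
    def exons_tx_order(self) -> list[tuple[int, int]]:
        """Exons ordered 5'->3' in the direction of transcription."""
        return self.exons if self.strand == "+" else list(reversed(self.exons))

    @property
    def exon1_length(self) -> int:
        e = self.exons_tx_order[0]
        return e[1] - e[0]

    @property
    def exon2_length(self) -> int:
        if not self.has_intron:
            return 0
        e = self.exons_tx_order[1]
        return e[1] - e[0]

    @property
    def intron_length(self) -> int:
        iv = self.intron
        return 0 if iv is None else iv[1] - iv[0]

    @property
    def mature_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def precursor_length(self) -> int:
        return self.end - self.start


@dataclass
class ReadRecord:
    """One aligned fragment reduced to genomic blocks on its gene.

    Blocks are 0-based half-open, sorted, non-overlapping; a junction
    fragment has two blocks separated by the intron.
    """

    read_id: str
    gene_id: str
    blocks: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        blocks = sorted(tuple(b) for b in self.blocks)
        for (s, e) in blocks:
            if not (0 <= s < e):
                raise ValueError(f"{self.read_id}: bad block ({s}, {e})")
        for (_, e0), (s1, _) in zip(blocks, blocks[1:]):
            if s1 < e0:
                raise ValueError(f"{self.read_id}: overlapping blocks")
        self.blocks = blocks

    @property
    def start(self) -> int:
        return self.blocks[0][0]

    @property
    def end(self) -> int:
        return self.blocks[-1][1]

    @property
    def aligned_length(self) -> int:
        return sum(e - s for s, e in self.blocks)


# --------------------------------------------------------------------------
# annotation I/O
# --------------------------------------------------------------------------

def read_annotation(path: str, dialect: str | None = None) -> list[TranscriptModel]:
    """Read GTF (ENSEMBL dialect) or BED6 into gene models.

    GTF coordinates are 1-based inclusive on disk and converted to the
    internal 0-based half-open convention.  BED6 yields single-exon models.
    """
    if dialect is None:
        dialect = "bed" if str(path).endswith(".bed") else "gtf"
    if dialect == "bed":
        return _read_bed(path)
    if dialect != "gtf":
        raise ValueError(f"unknown annotation dialect {dialect!r}")
    _validate_gtf_lines(path)
    try:
        db = gffutils.create_db(
            str(path),
            ":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
            disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
    except Exception as exc:  # surface parse failures with context
        raise ValueError(f"malformed GTF {path}: {exc}") from exc
    genes: dict[str, dict] = {}
    order: list[str] = []
    for feat in db.all_features(featuretype="exon", order_by=("seqid", "start")):
        gid = feat.attributes.get("gene_id", [feat.id])[0]
        if gid not in genes:
            genes[gid] = {
                "chrom": feat.seqid,
                "strand": feat.strand,
                "exons": [],
                "tx_class": feat.attributes.get("transcript_class", ["other"])[0],
            }
            order.append(gid)
        # GTF 1-based inclusive -> 0-based half-open
        genes[gid]["exons"].append((feat.start - 1, feat.end))
    return [
        TranscriptModel(
            gene_id=gid,
            chrom=g["chrom"],
            strand=g["strand"],
            exons=g["exons"],
            tx_class=g["tx_class"],
        )
        for gid, g in ((gid, genes[gid]) for gid in order)
    ]


def _validate_gtf_lines(path: str) -> None:
    """Reject malformed GTF lines with the offending line number."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise ValueError(
                    f"malformed GTF {path}:{lineno}: expected 9 tab-separated "
                    f"fields, got {len(fields)}"
                )
            if not (fields[3].isdigit() and fields[4].isdigit()):
                raise ValueError(
                    f"malformed GTF {path}:{lineno}: non-numeric coordinates"
                )


def _read_bed(path: str) -> list[TranscriptModel]:
    models = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(f"{path}:{lineno}: BED6 needs 6 columns")
            chrom, start, end, name, _score, strand = fields[:6]
            models.append(
                TranscriptModel(
                    gene_id=name,
                    chrom=chrom,
                    strand=strand,
                    exons=[(int(start), int(end))],
                )
            )
    return models


def write_annotation(
    models: list[TranscriptModel], path: str, fmt: str = "gtf"
) -> None:
    """Write models as GTF (1-based inclusive) or BED6 (gene spans only)."""
    with open(path, "w") as fh:
        if fmt == "gtf":
            for m in models:
                attrs = (
                    f'gene_id "{m.gene_id}"; transcript_id "{m.gene_id}.1"; '
                    f'transcript_class "{m.tx_class}";'
                )
                fh.write(
                    f"{m.chrom}\ttukinetics\tgene\t{m.start + 1}\t{m.end}\t.\t"
                    f"{m.strand}\t.\t{attrs}\n"
                )
                for s, e in m.exons:
                    fh.write(
                        f"{m.chrom}\ttukinetics\texon\t{s + 1}\t{e}\t.\t"
                        f"{m.strand}\t.\t{attrs}\n"
                    )
        elif fmt == "bed":
            for m in models:
                fh.write(
                    f"{m.chrom}\t{m.start}\t{m.end}\t{m.gene_id}\t0\t{m.strand}\n"
                )
        else:
            raise ValueError(f"unknown annotation format {fmt!r}")


# --------------------------------------------------------------------------
# read I/O
# --------------------------------------------------------------------------

READ_TABLE_COLUMNS = ["read_id", "gene_id", "block_starts", "block_ends", "category"]


def load_reads(
    path: str, models: list[TranscriptModel], fmt: str | None = None
) -> dict[str, list[ReadRecord]]:
    """Load aligned fragments from SAM/BAM or the internal read-table TSV.

    Returns ``{gene_id: [ReadRecord, ...]}``.  SAM records are assigned to
    the unique gene whose span contains them; unassignable records are
    dropped.  Secondary/supplementary/unmapped records are skipped (the
    uniquely-mapped-fragment convention).
    """
    if fmt is None:
        fmt = "tsv" if str(path).endswith((".tsv", ".txt")) else "sam"
    by_gene: dict[str, list[ReadRecord]] = {m.gene_id: [] for m in models}
    if fmt == "tsv":
        df = pd.read_csv(path, sep="\t", dtype=str)
        for row in df.itertuples(index=False):
            starts = [int(x) for x in str(row.block_starts).split(",")]
            ends = [int(x) for x in str(row.block_ends).split(",")]
            rec = ReadRecord(row.read_id, row.gene_id, list(zip(starts, ends)))
            if rec.gene_id in by_gene:
                by_gene[rec.gene_id].append(rec)
        return by_gene
    index: dict[str, list[TranscriptModel]] = {}
    for m in models:
        index.setdefault(m.chrom, []).append(m)
    with pysam.AlignmentFile(str(path), "r") as sam:
        for aln in sam.fetch(until_eof=True):
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            blocks = _merge_adjacent(aln.get_blocks())
            gene = _assign_gene(index.get(aln.reference_name, []), blocks)
            if gene is not None:
                by_gene[gene.gene_id].append(
                    ReadRecord(aln.query_name, gene.gene_id, blocks)
                )
    return by_gene


def _merge_adjacent(blocks: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Collapse abutting blocks (pysam splits on CIGAR ops, not just introns)."""
    merged: list[list[int]] = []
    for s, e in sorted(blocks):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [tuple(b) for b in merged]


def _assign_gene(models, blocks):
    lo, hi = blocks[0][0], blocks[-1][1]
    for m in models:
        if m.start <= lo and hi <= m.end:
            return m
    return None


def write_read_table(reads: dict[str, list[ReadRecord]], path: str) -> None:
    """Write the internal read-table TSV (documented, bit-exact format)."""
    rows = []
    for gene_id in sorted(reads):
        for rec in reads[gene_id]:
            rows.append(
                {
                    "read_id": rec.read_id,
                    "gene_id": gene_id,
                    "block_starts": ",".join(str(s) for s, _ in rec.blocks),
                    "block_ends": ",".join(str(e) for _, e in rec.blocks),
                    "category": "",
                }
            )
    pd.DataFrame(rows, columns=READ_TABLE_COLUMNS).to_csv(path, sep="\t", index=False)


# --------------------------------------------------------------------------
# region counting
# --------------------------------------------------------------------------

def count_regions(
    reads: dict[str, list[ReadRecord]],
    models: list[TranscriptModel],
    min_anchor: int = 5,
) -> pd.DataFrame:
    """Count fragments per gene region.

    Regions (transcription order): ``exon1``, ``intron``, ``exon2`` receive
    +1 for every fragment overlapping them by >= 1 nt; these overlap counts
    are not mutually exclusive.  ``junction`` counts fragments whose blocks
    skip the entire intron with >= ``min_anchor`` nt aligned in both exons;
    ``b5``/``b3`` count fragments with a block crossing the 5'/3'
    exon-intron border with >= ``min_anchor`` nt on each side (borders named
    in transcription order).  ``assigned`` is the number of fragments
    assigned to the gene.  Empty input yields a zero table.
    """
    table = pd.DataFrame(
        0, index=[m.gene_id for m in models], columns=REGION_COLUMNS, dtype=int
    )
    table.index.name = "gene_id"
    by_id = {m.gene_id: m for m in models}
    for gene_id, recs in reads.items():
        m = by_id.get(gene_id)
        if m is None:
            continue
        for rec in recs:
            for col in _read_regions(rec, m, min_anchor):
                table.at[gene_id, col] += 1
            table.at[gene_id, "assigned"] += 1
    return table


def _overlap(block, iv):
    return max(0, min(block[1], iv[1]) - max(block[0], iv[0]))


def _read_regions(rec: ReadRecord, m: TranscriptModel, min_anchor: int) -> list[str]:
    regions: list[str] = []
    iv_intron = m.intron
    ex = m.exons  # genomic order
    names = ("exon1", "exon2") if m.strand == "+" else ("exon2", "exon1")
    for name, exon in zip(names, ex):
        if any(_overlap(b, exon) for b in rec.blocks):
            regions.append(name)
    if iv_intron is None:
        return regions
    if any(_overlap(b, iv_intron) for b in rec.blocks):
        regions.append("intron")
    # junction: two blocks flanking the intron, gap == intron, anchored
    if len(rec.blocks) == 2:
        (s0, e0), (s1, e1) = rec.blocks
        if (e0, s1) == iv_intron and e0 - s0 >= min_anchor and e1 - s1 >= min_anchor:
            regions.append("junction")
    # boundaries: a single block crossing an exon/intron border
    left, right = iv_intron
    b_left, b_right = ("b5", "b3") if m.strand == "+" else ("b3", "b5")
    for s, e in rec.blocks:
        if s <= left - min_anchor and e >= left + min_anchor:
            regions.append(b_left)
        if s <= right - min_anchor and e >= right + min_anchor:
            regions.append(b_right)
    return regions


def fpkm(count: float, region_length_nt: float, total_mapped_fragments: float) -> float:
    """Fragments per kilobase of feature per million mapped fragments."""
    if region_length_nt <= 0:
        raise ValueError("region length must be positive")
    if total_mapped_fragments <= 0:
        raise ValueError("total mapped fragments must be positive")
    return 1e9 * count / (region_length_nt * total_mapped_fragments)
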