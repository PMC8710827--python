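"""Readers, writers and the core domain containers.

Internal coordinates are 1-based inclusive throughout; BED-like input
(0-based half-open) is converted at the boundary. ``order_index`` is the
0-based rank of a gene along its chromosome by start coordinate and is the
coordinate system of all synteny operations.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

TISSUES = ("root", "shoot")
TIME_POINTS = (0, 6, 24)


class ValidationError(ValueError):
    """Raised when an input violates a documented invariant."""


@dataclass
class GeneModel:
    gene_id: str
    chromosome: str
    start: int  # 1-based inclusive
    end: int    # inclusive
    strand: str = "+"
    order_index: int = -1

    def __post_init__(self):
        if self.start > self.end:
            raise ValidationError(f"{self.gene_id}: start {self.start} > end {self.end}")
        if self.strand in ("−",):  # unicode minus
            self.strand = "-"
        if self.strand not in ("+", "-"):
            raise ValidationError(f"{self.gene_id}: bad strand {self.strand!r}")


@dataclass
class Genome:
    """Ordered gene models on named chromosomes, optionally with sequences."""

    name: str
    genes: list[GeneModel] = field(default_factory=list)
    cds: dict[str, str] | None = None
    proteins: dict[str, str] | None = None

    def __post_init__(self):
        self.assign_order()

    # -- structure -----------------------------------------------------
    def assign_order(self) -> None:
        """(Re)assign order_index per chromosome by start coordinate."""
        ids = set()
        for g in self.genes:
            if g.gene_id in ids:
                raise ValidationError(f"duplicate gene_id {g.gene_id!r}")
            ids.add(g.gene_id)
        by_chrom: dict[str, list[GeneModel]] = {}
        for g in self.genes:
            by_chrom.setdefault(g.chromosome, []).append(g)
        for genes in by_chrom.values():
            genes.sort(key=lambda g: (g.start, g.gene_id))
            for i, g in enumerate(genes):
                g.order_index = i

    @property
    def chromosomes(self) -> list[str]:
        seen = dict.fromkeys(g.chromosome for g in self.genes)
        return list(seen)

    def genes_on(self, chromosome: str) -> list[GeneModel]:
        out = [g for g in self.genes if g.chromosome == chromosome]
        out.sort(key=lambda g: g.order_index)
        return out

    def gene(self, gene_id: str) -> GeneModel:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)

    def order_map(self) -> dict[str, tuple[str, int]]:
        """gene_id -> (chromosome, order_index)."""
        return {g.gene_id: (g.chromosome, g.order_index) for g in self.genes}

    def validate_sequences(self) -> None:
        """Check the CDS/protein invariants (length multiple of 3, consistent)."""
        if self.cds:
            for gid, seq in self.cds.items():
                if len(seq) == 0 or len(seq) % 3 != 0:
                    raise ValidationError(f"{gid}: CDS length {len(seq)} not a positive multiple of 3")
                if self.proteins and gid in self.proteins:
                    if len(self.proteins[gid]) != len(seq) // 3:
                        raise ValidationError(f"{gid}: protein length != CDS length / 3")


# ---------------------------------------------------------------------------
# gene tables
# ---------------------------------------------------------------------------

def read_gene_table(path: str | Path, dialect: str = "bed") -> Genome:
    """Read a gene-position table into a :class:`Genome`.

    ``dialect='bed'``: whitespace-separated ``chrom start end gene_id strand``
    with 0-based half-open coordinates. ``dialect='gff'``: 9-column GFF-like
    lines (1-based inclusive) whose attribute column carries ``ID=``.
    """
    path = Path(path)
    if dialect not in ("bed", "bed-like", "gff", "gff-like"):
        raise ValueError(f"unknown dialect {dialect!r}")
    genes: list[GeneModel] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            try:
                if dialect.startswith("bed"):
                    chrom, start, end, gid, strand = fields[:5]
                    start_i = int(start) + 1  # to 1-based inclusive
                    end_i = int(end)
                else:
                    if len(fields) < 9:
                        raise ValueError("expected 9 columns")
                    chrom, _src, _feat, start, end, _score, strand, _frame, attrs = fields[:9]
                    start_i, end_i = int(start), int(end)
                    gid = None
                    for item in attrs.rstrip(";").split(";"):
                        key, _, val = item.strip().partition("=")
                        if key == "ID":
                            gid = val
                    if gid is None:
                        raise ValueError("no ID= attribute")
                gene = GeneModel(gid, chrom, start_i, end_i, strand)
            except (ValueError, IndexError) as exc:
                raise ValidationError(f"{path}:{lineno}: malformed row ({exc})") from exc
            if gid in seen:
                raise ValidationError(f"{path}:{lineno}: duplicate gene_id {gid!r}")
            seen.add(gid)
            genes.append(gene)
    return Genome(name=path.stem, genes=genes)


def write_gene_table(genome: Genome, path: str | Path, dialect: str = "bed") -> None:
    with open(path, "w") as fh:
        for g in sorted(genome.genes, key=lambda g: (g.chromosome, g.start)):
            if dialect.startswith("bed"):
                fh.write(f"{g.chromosome}\t{g.start - 1}\t{g.end}\t{g.gene_id}\t{g.strand}\n")
            else:
                fh.write(f"{g.chromosome}\twgdkit\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\tID={g.gene_id}\n")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into an id -> sequence mapping (order preserved)."""
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq)
        if not seq:
            raise ValidationError(f"empty record {rec.id!r} in {path}")
        if rec.id in records:
            raise ValidationError(f"duplicate record id {rec.id!r} in {path}")
        records[rec.id] = seq
    return records


def write_fasta(records: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    seqs = [SeqRecord(Seq(s), id=name, description="") for name, s in records.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqs)


# ---------------------------------------------------------------------------
# design table and counts
# ---------------------------------------------------------------------------

class DesignTable:
    """Sample sheet for the salt-stress design: tissue x time x replicate."""

    COLUMNS = ("sample_id", "tissue", "time_h", "replicate")

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in self.COLUMNS if c not in frame.columns]
        if missing:
            raise ValidationError(f"design table missing columns {missing}")
        df = frame.loc[:, list(self.COLUMNS)].copy()
        df["time_h"] = df["time_h"].astype(int)
        df["replicate"] = df["replicate"].astype(int)
        bad_tissue = set(df["tissue"]) - set(TISSUES)
        if bad_tissue:
            raise ValidationError(f"unknown tissue values {sorted(bad_tissue)}")
        bad_time = set(df["time_h"]) - set(TIME_POINTS)
        if bad_time:
            raise ValidationError(f"unknown time points {sorted(bad_time)}")
        if df.duplicated(["tissue", "time_h", "replicate"]).any():
            raise ValidationError("duplicated (tissue, time_h, replicate)")
        if df["sample_id"].duplicated().any():
            raise ValidationError("duplicated sample_id")
        n_rep = df.groupby(["tissue", "time_h"]).size()
        if (n_rep < 2).any():
            few = n_rep[n_rep < 2].index.tolist()
            raise ValidationError(f"fewer than 2 replicates for {few}")
        self.frame = df.reset_index(drop=True)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DesignTable":
        return cls(pd.read_csv(path, sep="\t"))

    def to_tsv(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    @property
    def sample_ids(self) -> list[str]:
        return self.frame["sample_id"].tolist()

    def samples_for(self, tissue: str, time_h: int) -> list[str]:
        m = (self.frame["tissue"] == tissue) & (self.frame["time_h"] == int(time_h))
        return self.frame.loc[m, "sample_id"].tolist()

    def __len__(self) -> int:
        return len(self.frame)


def read_counts(path: str | Path, design_path: str | Path) -> tuple[pd.DataFrame, DesignTable]:
    """Read a gene x sample count TSV together with its design table.

    Columns are reordered to design order; counts must be non-negative
    integers and every matrix sample must appear in the design.
    """
    counts = pd.read_csv(path, sep="\t", index_col=0)
    design = DesignTable.from_tsv(design_path)
    missing = [s for s in counts.columns if s not in design.sample_ids]
    if missing:
        raise ValidationError(f"samples {missing} absent from design table")
    absent = [s for s in design.sample_ids if s not in counts.columns]
    if absent:
        raise ValidationError(f"design samples {absent} absent from count matrix")
    counts = counts.loc[:, design.sample_ids]
    values = counts.to_numpy()
    if (values < 0).any():
        raise ValidationError("negative counts in matrix")
    if not (values == values.astype(int)).all():
        raise ValidationError("non-integer counts in matrix")
    return counts.astype(int), design


# ---------------------------------------------------------------------------
# synteny blocks TSV (external interface)
# ---------------------------------------------------------------------------

def write_blocks_tsv(blocks: Iterable, path: str | Path, comment: str | None = None) -> None:
    from .synteny import SyntenyBlock  # local import avoids a cycle

    rows = []
    for b in blocks:
        rows.append({
            "block_id": b.block_id, "genome_a": b.genome_a, "chrom_a": b.chrom_a,
            "genome_b": b.genome_b, "chrom_b": b.chrom_b, "n_pairs": b.n_pairs,
            "orientation": b.orientation,
            "mean_ks": "" if b.mean_ks is None else f"{b.mean_ks:.6f}",
            "block_class": b.block_class or "",
            "pairs": ";".join(f"{ga}|{gb}|{r}" for ga, gb, r in b.pairs),
        })
    buf = _io.StringIO()
    if comment:
        buf.write(f"# {comment}\n")
    pd.DataFrame(rows).to_csv(buf, sep="\t", index=False)
    Path(path).write_text(buf.getvalue())


def read_blocks_tsv(path: str | Path) -> list:
    from .synteny import SyntenyBlock

    df = pd.read_csv(path, sep="\t", comment="#", keep_default_na=False)
    blocks = []
    for _, row in df.iterrows():
        pairs = []
        if row["pairs"]:
            for item in str(row["pairs"]).split(";"):
                ga, gb, r = item.split("|")
                pairs.append((ga, gb, int(r)))
        blocks.append(SyntenyBlock(
            block_id=str(row["block_id"]), genome_a=row["genome_a"], chrom_a=str(row["chrom_a"]),
            genome_b=row["genome_b"], chrom_b=str(row["chrom_b"]), pairs=pairs,
            orientation=row["orientation"],
            mean_ks=float(row["mean_ks"]) if row["mean_ks"] != "" else None,
            block_class=row["block_class"] or None,
        ))
    return blocks
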