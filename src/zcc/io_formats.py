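"""Readers and writers for every external format the toolkit touches.

Inputs: FASTA genomes, gene annotations (GFF3 or a 4-column TSV dialect),
replication-origin tables (DoriC-like CSV) and per-genome metadata tables.
Output: the per-genome results table (TSV or JSON).

Coordinate convention: every external file is 1-based inclusive (the GFF3
convention); the conversion to the internal 0-based half-open convention
happens exactly once, in :mod:`zcc.replichore`, never here.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

__all__ = [
    "GenomeSequence",
    "GeneRecord",
    "OriCRecord",
    "GenomeMetadata",
    "ResultRecord",
    "read_fasta",
    "write_fasta",
    "read_genes",
    "write_genes_tsv",
    "read_oric_table",
    "read_metadata_table",
    "write_results_table",
    "read_results_table",
]

# IUPAC nucleotide codes for DNA (no U: RNA is rejected).
IUPAC_DNA = frozenset("ACGTRYSWKMBDHVN")


@dataclass
class GenomeSequence:
    """One genome (or replicon) sequence, residues upper-cased IUPAC DNA."""

    genome_id: str
    residues: str
    topology: str = "circular"  # circular | linear

    def __post_init__(self) -> None:
        if self.topology not in ("circular", "linear"):
            raise ValueError(f"topology must be circular or linear, got {self.topology!r}")

    @property
    def length(self) -> int:
        return len(self.residues)


@dataclass
class GeneRecord:
    """A gene interval, 1-based inclusive on the deposited forward strand.

    A gene wrapping the origin of a circular replicon is stored with
    ``start > end`` and ``wraps=True``.
    """

    genome_id: str
    start: int
    end: int
    strand: str  # + | -
    label: str = ""
    wraps: bool = False

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.label!r}: strand must be + or -, got {self.strand!r}")
        if self.start < 1 or self.end < 1:
            raise ValueError(f"gene {self.label!r}: coordinates are 1-based, got {self.start}..{self.end}")
        if self.end < self.start and not self.wraps:
            raise ValueError(
                f"gene {self.label!r}: end < start ({self.start}..{self.end}) without wraps flag"
            )


@dataclass
class OriCRecord:
    """A replication-origin interval as curated in DoriC-like tables."""

    genome_id: str
    oric_start: int
    oric_end: int


@dataclass
class GenomeMetadata:
    """Phylum and polymerase annotations for one genome.

    ``has_polc`` may be ``None`` (unknown); such genomes are excluded from
    polymerase cross-tabulations but kept in phylum summaries.
    """

    genome_id: str
    phylum: str
    has_polc: bool | None = None
    dnae_types: frozenset[str] = field(default_factory=frozenset)
    gc_content: float | None = None


@dataclass
class ResultRecord:
    """One row of the per-genome results table."""

    genome_id: str
    length: int | None = None
    gc_content: float | None = None
    zcc: float | None = None
    zcc_degenerate: bool = False
    rymk: float | None = None
    rymk_degenerate: bool = False
    ori: int | None = None
    ter: int | None = None
    ori_source: str | None = None
    sgd_fraction: float | None = None
    phylum: str | None = None


def _validate_residues(genome_id: str, residues: str) -> None:
    for offset, ch in enumerate(residues):
        if ch not in IUPAC_DNA:
            raise ValueError(
                f"record {genome_id!r}: invalid nucleotide {ch!r} at offset {offset} "
                "(IUPAC DNA codes only; U is not accepted)"
            )


def read_fasta(path: str | Path, topology: str = "circular") -> list[GenomeSequence]:
    """Read a FASTA file into :class:`GenomeSequence` records, in file order.

    Residues are upper-cased and validated against the IUPAC DNA alphabet;
    the header token before the first whitespace becomes ``genome_id``.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        residues = str(rec.seq).upper()
        _validate_residues(rec.id, residues)
        records.append(GenomeSequence(genome_id=rec.id, residues=residues, topology=topology))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(seqs: Iterable[GenomeSequence], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(s.residues), id=s.genome_id, description="") for s in seqs
    ]
    SeqIO.write(records, str(path), "fasta")


def _genes_from_gff3(path: Path, genome_id_filter: str | None, feature_type: str) -> list[GeneRecord]:
    # gffutils builds an in-memory sqlite db; fine at the annotation sizes here.
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True, merge_strategy="create_unique"
    )
    genes: list[GeneRecord] = []
    for feat in db.features_of_type(feature_type, order_by=("seqid", "start")):
        if genome_id_filter is not None and feat.seqid != genome_id_filter:
            continue
        if feat.strand not in ("+", "-"):
            raise ValueError(
                f"gene {feat.id!r} on {feat.seqid}: strand {feat.strand!r} not in {{+,-}}"
            )
        genes.append(
            GeneRecord(
                genome_id=feat.seqid,
                start=feat.start,
                end=feat.end,
                strand=feat.strand,
                label=feat.id or "",
            )
        )
    return genes


def _genes_from_tsv(path: Path, circular: bool) -> list[GeneRecord]:
    genes: list[GeneRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if lineno == 1 and fields[:2] == ["seq_id", "start"]:
                continue  # optional header
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: expected 4 tab-separated columns")
            seq_id, start_s, end_s, strand = fields[:4]
            label = fields[4] if len(fields) > 4 else f"gene_{lineno}"
            start, end = int(start_s), int(end_s)
            wraps = end < start
            if wraps and not circular:
                raise ValueError(
                    f"{path}:{lineno}: end < start is only valid on circular replicons"
                )
            genes.append(
                GeneRecord(
                    genome_id=seq_id, start=start, end=end, strand=strand,
                    label=label, wraps=wraps,
                )
            )
    return genes


def read_genes(
    path: str | Path,
    format: str = "tsv",
    feature_type: str = "gene",
    circular: bool = True,
    genome_id: str | None = None,
) -> list[GeneRecord]:
    """Read gene annotations from GFF3 or the 4-column TSV dialect.

    GFF3: only features of ``feature_type`` (default ``gene``) are kept;
    ``.`` strands are an error since strand assignment is the whole point.
    TSV: tab-separated ``seq_id  start  end  strand`` (header optional,
    optional 5th label column), 1-based inclusive.
    """
    path = Path(path)
    if format == "gff3":
        return _genes_from_gff3(path, genome_id, feature_type)
    if format == "tsv":
        return _genes_from_tsv(path, circular)
    raise ValueError(f"unknown gene annotation format {format!r}")


def write_genes_tsv(genes: Iterable[GeneRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("seq_id\tstart\tend\tstrand\tlabel\n")
        for g in genes:
            fh.write(f"{g.genome_id}\t{g.start}\t{g.end}\t{g.strand}\t{g.label}\n")


def read_oric_table(
    path: str | Path,
    columns: dict[str, str] | None = None,
    genome_lengths: dict[str, int] | None = None,
) -> list[OriCRecord]:
    """Read a DoriC-like CSV of replication-origin intervals.

    ``columns`` maps the logical names ``genome_id``, ``oric_start`` and
    ``oric_end`` to the CSV's actual column names (DoriC's schema varies
    between releases).  Duplicate genome ids keep the first row with a
    warning.  When ``genome_lengths`` is given, coordinates are validated
    against them.
    """
    colmap = {"genome_id": "genome_id", "oric_start": "oric_start", "oric_end": "oric_end"}
    if columns:
        colmap.update(columns)
    df = pd.read_csv(path)
    missing = [c for c in colmap.values() if c not in df.columns]
    if missing:
        raise ValueError(
            f"oriC table {path} is missing columns {missing}; expected "
            f"{sorted(colmap.values())} (remap with the columns option)"
        )
    records: list[OriCRecord] = []
    seen: set[str] = set()
    for _, row in df.iterrows():
        gid = str(row[colmap["genome_id"]])
        if gid in seen:
            logger.warning("duplicate oriC row for %s: keeping the first", gid)
            continue
        seen.add(gid)
        start, end = int(row[colmap["oric_start"]]), int(row[colmap["oric_end"]])
        if genome_lengths is not None and gid in genome_lengths:
            n = genome_lengths[gid]
            for pos in (start, end):
                if not 1 <= pos <= n:
                    raise ValueError(
                        f"oriC position {pos} for {gid} outside [1, {n}]"
                    )
        records.append(OriCRecord(genome_id=gid, oric_start=start, oric_end=end))
    return records


_TRUE = {"true", "1", "yes", "t"}
_FALSE = {"false", "0", "no", "f"}


def read_metadata_table(path: str | Path) -> list[GenomeMetadata]:
    """Read a metadata TSV: genome_id, phylum, has_polc, dnae_types[, gc_content].

    ``has_polc`` accepts true/false/unknown (blank = unknown); ``dnae_types``
    is a comma-separated set, e.g. ``DnaE1,DnaE2``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"genome_id", "phylum"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"metadata table {path} is missing columns {sorted(missing)}")
    out: list[GenomeMetadata] = []
    for _, row in df.iterrows():
        polc_raw = str(row.get("has_polc", "")).strip().lower()
        if polc_raw in _TRUE:
            has_polc: bool | None = True
        elif polc_raw in _FALSE:
            has_polc = False
        else:
            has_polc = None
        dnae_raw = str(row.get("dnae_types", "")).strip()
        dnae = frozenset(t.strip() for t in dnae_raw.split(",") if t.strip())
        gc_raw = str(row.get("gc_content", "")).strip()
        out.append(
            GenomeMetadata(
                genome_id=str(row["genome_id"]),
                phylum=str(row["phylum"]),
                has_polc=has_polc,
                dnae_types=dnae,
                gc_content=float(gc_raw) if gc_raw else None,
            )
        )
    return out


# Deterministic column order of the results table.
_RESULT_COLUMNS = [
    "genome_id", "length", "gc_content", "zcc", "zcc_degenerate",
    "rymk", "rymk_degenerate", "ori", "ter", "ori_source",
    "sgd_fraction", "phylum",
]
_FLOAT_COLUMNS = ("gc_content", "zcc", "rymk", "sgd_fraction")
_INT_COLUMNS = ("length", "ori", "ter")


def _format_cell(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, float):
        return "" if math.isnan(value) else repr(value)
    return str(value)


def write_results_table(records: Sequence[ResultRecord], path: str | Path, format: str = "tsv") -> None:
    """Write per-genome results as TSV or a JSON array with identical keys."""
    rows = [{c: getattr(r, c) for c in _RESULT_COLUMNS} for r in records]
    path = Path(path)
    if format == "tsv":
        with open(path, "w") as fh:
            fh.write("\t".join(_RESULT_COLUMNS) + "\n")
            for row in rows:
                fh.write("\t".join(_format_cell(row[c]) for c in _RESULT_COLUMNS) + "\n")
    elif format == "json":
        with open(path, "w") as fh:
            json.dump(rows, fh, indent=1)
            fh.write("\n")
    else:
        raise ValueError(f"unknown results format {format!r}")


def read_results_table(path: str | Path, format: str = "tsv") -> list[ResultRecord]:
    """Inverse of :func:`write_results_table` (lossless round trip)."""
    path = Path(path)
    if format == "json":
        with open(path) as fh:
            rows = json.load(fh)
    elif format == "tsv":
        rows = []
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            for line in fh:
                cells = line.rstrip("\n").split("\t")
                rows.append(dict(zip(header, (c if c != "" else None for c in cells))))
    else:
        raise ValueError(f"unknown results format {format!r}")

    records = []
    for row in rows:
        kw: dict = {"genome_id": str(row["genome_id"])}
        for c in _INT_COLUMNS:
            v = row.get(c)
            kw[c if c != "length" else "length"] = int(v) if v is not None else None
        for c in _FLOAT_COLUMNS:
            v = row.get(c)
            kw[c] = float(v) if v is not None else None
        for c in ("zcc_degenerate", "rymk_degenerate"):
            v = row.get(c)
            kw[c] = (v is True) or (isinstance(v, str) and v.lower() == "true")
        for c in ("ori_source", "phylum"):
            v = row.get(c)
            kw[c] = str(v) if v is not None else None
        records.append(ResultRecord(**kw))
    return records
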