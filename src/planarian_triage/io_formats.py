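"""Readers and writers for the standard formats the pipeline consumes.

All external coordinates (tabular BLAST, RepeatMasker ``.out``) are 1-based
inclusive; internally everything is 0-based half-open.  The conversion lives
in exactly two helpers, :func:`to_internal` and :func:`to_external`, so the
convention is testable in one place.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


DB_TAGS = frozenset(
    {"SILVA", "MITO", "UNIPROT", "CEGMA_BUSCO", "HELMINTH_EST", "NT", "GENOME", "OTHER"}
)


def to_internal(start_1based: int, end_1based: int) -> tuple[int, int]:
    """Convert a 1-based inclusive interval to 0-based half-open."""
    if start_1based < 1 or end_1based < start_1based:
        raise FormatError(
            f"invalid 1-based interval [{start_1based}, {end_1based}]"
        )
    return start_1based - 1, end_1based


def to_external(start0: int, end0: int) -> tuple[int, int]:
    """Convert a 0-based half-open interval back to 1-based inclusive."""
    if start0 < 0 or end0 <= start0:
        raise FormatError(f"invalid 0-based half-open interval [{start0}, {end0})")
    return start0 + 1, end0


@dataclass(frozen=True)
class FastaRecord:
    id: str
    description: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("FASTA record with empty id")
        if not self.sequence:
            raise FormatError(f"FASTA record {self.id!r} with empty sequence")
        if any(c.isspace() for c in self.sequence):
            raise FormatError(f"whitespace inside sequence of {self.id!r}")


@dataclass(frozen=True)
class TabularHit:
    """One row of outfmt-6-style tabular BLAST output (optionally + qcov/scov)."""

    qid: str
    sid: str
    pident: float
    aln_len: int
    mismatches: int
    gapopen: int
    qstart: int
    qend: int
    sstart: int
    send: int
    evalue: float
    bitscore: float
    db_tag: str = "OTHER"
    qcov: float | None = None
    scov: float | None = None

    def __post_init__(self) -> None:
        if self.db_tag not in DB_TAGS:
            raise FormatError(f"unknown db_tag {self.db_tag!r}")
        if self.qstart > self.qend:
            raise FormatError(
                f"hit {self.qid!r}->{self.sid!r}: qstart {self.qstart} > qend {self.qend}"
            )
        if min(self.qstart, self.qend, self.sstart, self.send) < 1:
            raise FormatError(f"hit {self.qid!r}->{self.sid!r}: non-positive coordinate")
        if self.evalue < 0:
            raise FormatError(f"hit {self.qid!r}->{self.sid!r}: negative evalue")


@dataclass(frozen=True)
class RepeatMaskerHit:
    score: int
    pct_div: float
    pct_del: float
    pct_ins: float
    seq_name: str
    qstart: int
    qend: int
    strand: str
    repeat_name: str
    repeat_class_family: str

    def __post_init__(self) -> None:
        if self.qstart > self.qend:
            raise FormatError(
                f"RepeatMasker hit on {self.seq_name!r}: qstart > qend"
            )
        if self.strand not in {"+", "C"}:
            raise FormatError(f"invalid strand {self.strand!r}")


@dataclass(frozen=True)
class GafRecord:
    db: str
    object_id: str
    symbol: str
    qualifier: str
    go_id: str
    evidence_code: str
    aspect: str

    def __post_init__(self) -> None:
        if not (
            self.go_id.startswith("GO:")
            and len(self.go_id) == 10
            and self.go_id[3:].isdigit()
        ):
            raise FormatError(f"malformed GO id {self.go_id!r}")
        if not self.evidence_code:
            raise FormatError("empty evidence code")
        if self.aspect not in {"P", "F", "C"}:
            raise FormatError(f"invalid aspect {self.aspect!r}")


@dataclass
class CountTable:
    """Integer count matrix keyed by row (transcript/gene) and column (sample/cell) ids."""

    row_ids: list[str]
    col_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if len(set(self.row_ids)) != len(self.row_ids):
            raise FormatError("duplicate row ids in count table")
        if len(set(self.col_ids)) != len(self.col_ids):
            raise FormatError("duplicate column ids in count table")
        if self.counts.shape != (len(self.row_ids), len(self.col_ids)):
            raise FormatError(
                f"count matrix shape {self.counts.shape} inconsistent with "
                f"{len(self.row_ids)} rows x {len(self.col_ids)} cols"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(self.counts, 1), 0)):
                raise FormatError("fractional counts in count table")
            self.counts = self.counts.astype(np.int64)
        if (self.counts < 0).any():
            raise FormatError("negative counts in count table")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.row_ids, columns=self.col_ids)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[FastaRecord]:
    path = Path(path)
    records: list[FastaRecord] = []
    seen: set[str] = set()
    parsed = list(SeqIO.parse(str(path), "fasta"))
    if not parsed:
        raise FormatError(f"{path}: no FASTA records found")
    for rec in parsed:
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id):].lstrip()
        records.append(FastaRecord(rec.id, desc, str(rec.seq)))
    return records


def write_fasta(records: Iterable[FastaRecord], path: str | Path, width: int = 60) -> None:
    seen: set[str] = set()
    seqrecs = []
    for r in records:
        if r.id in seen:
            raise FormatError(f"duplicate FASTA id {r.id!r}")
        seen.add(r.id)
        seqrecs.append(SeqRecord(Seq(r.sequence), id=r.id, description=r.description))
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqrecs)


# ---------------------------------------------------------------------------
# Tabular BLAST


def read_blast_tab(path: str | Path, db_tag: str) -> list[TabularHit]:
    """Parse outfmt-6-style rows; columns 13-14, when present, are qcov/scov."""
    path = Path(path)
    hits: list[TabularHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 12:
                raise FormatError(f"{path}:{lineno}: expected >= 12 columns, got {len(parts)}")
            try:
                hit = TabularHit(
                    qid=parts[0],
                    sid=parts[1],
                    pident=float(parts[2]),
                    aln_len=int(parts[3]),
                    mismatches=int(parts[4]),
                    gapopen=int(parts[5]),
                    qstart=int(parts[6]),
                    qend=int(parts[7]),
                    sstart=int(parts[8]),
                    send=int(parts[9]),
                    evalue=float(parts[10]),
                    bitscore=float(parts[11]),
                    db_tag=db_tag,
                    qcov=float(parts[12]) if len(parts) > 12 else None,
                    scov=float(parts[13]) if len(parts) > 13 else None,
                )
            except ValueError as exc:
                if isinstance(exc, FormatError):
                    raise FormatError(f"{path}:{lineno}: {exc}") from None
                raise FormatError(f"{path}:{lineno}: unparseable numeric field ({exc})") from None
            hits.append(hit)
    return hits


def write_blast_tab(hits: Iterable[TabularHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            cols = [
                h.qid, h.sid, f"{h.pident:g}", str(h.aln_len), str(h.mismatches),
                str(h.gapopen), str(h.qstart), str(h.qend), str(h.sstart),
                str(h.send), f"{h.evalue:g}", f"{h.bitscore:g}",
            ]
            if h.qcov is not None:
                cols.append(f"{h.qcov:g}")
                cols.append(f"{h.scov:g}" if h.scov is not None else "")
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# RepeatMasker .out


def read_repeatmasker_out(path: str | Path) -> list[RepeatMaskerHit]:
    """Parse a standard RepeatMasker ``.out`` file (3 header lines, whitespace-split)."""
    path = Path(path)
    hits: list[RepeatMaskerHit] = []
    with open(path) as fh:
        lines = fh.readlines()
    for lineno, line in enumerate(lines, 1):
        if lineno <= 3:  # two header lines + blank
            continue
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) < 11:
            raise FormatError(f"{path}:{lineno}: truncated RepeatMasker row")
        try:
            hits.append(
                RepeatMaskerHit(
                    score=int(parts[0]),
                    pct_div=float(parts[1]),
                    pct_del=float(parts[2]),
                    pct_ins=float(parts[3]),
                    seq_name=parts[4],
                    qstart=int(parts[5]),
                    qend=int(parts[6]),
                    strand=parts[8],
                    repeat_name=parts[9],
                    repeat_class_family=parts[10],
                )
            )
        except ValueError as exc:
            if isinstance(exc, FormatError):
                raise FormatError(f"{path}:{lineno}: {exc}") from None
            raise FormatError(f"{path}:{lineno}: unparseable field ({exc})") from None
    return hits


def write_repeatmasker_out(hits: Iterable[RepeatMaskerHit], path: str | Path) -> None:
    header = (
        "   SW  perc perc perc  query     position in query    matching "
        "repeat        position in repeat\n"
        "score  div. del. ins.  sequence  begin  end   (left)  repeat        "
        "class/family   begin  end (left) ID\n"
        "\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        for i, h in enumerate(hits, 1):
            left = "(0)"
            fh.write(
                f"{h.score:5d} {h.pct_div:5.1f} {h.pct_del:4.1f} {h.pct_ins:4.1f}  "
                f"{h.seq_name} {h.qstart} {h.qend} {left} {h.strand} "
                f"{h.repeat_name} {h.repeat_class_family} 1 1 (0) {i}\n"
            )


# ---------------------------------------------------------------------------
# GAF


def read_gaf(path: str | Path) -> list[GafRecord]:
    path = Path(path)
    records: list[GafRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.startswith("!") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 15:
                raise FormatError(
                    f"{path}:{lineno}: GAF row has {len(parts)} columns, expected >= 15"
                )
            records.append(
                GafRecord(
                    db=parts[0],
                    object_id=parts[1],
                    symbol=parts[2],
                    qualifier=parts[3],
                    go_id=parts[4],
                    evidence_code=parts[6],
                    aspect=parts[8],
                )
            )
    return records


def write_gaf(records: Iterable[GafRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("!gaf-version: 2.1\n")
        for r in records:
            cols = [""] * 17
            cols[0] = r.db
            cols[1] = r.object_id
            cols[2] = r.symbol
            cols[3] = r.qualifier
            cols[4] = r.go_id
            cols[5] = "PMID:0"
            cols[6] = r.evidence_code
            cols[8] = r.aspect
            cols[11] = "protein"
            cols[12] = "taxon:1"
            cols[13] = "20180101"
            cols[14] = r.db
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# Count matrices


def read_counts(path: str | Path, fmt: str = "tsv") -> CountTable:
    """Read a count matrix.

    ``tsv``: header row of sample ids, first column row ids.
    ``mtx_triplet``: ``path`` is the MatrixMarket-style triplet file; sibling
    files ``<path>.rows`` and ``<path>.cols`` hold row/column ids, one per line.
    """
    path = Path(path)
    if fmt == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        arr = df.to_numpy()
        if arr.size and not np.issubdtype(arr.dtype, np.number):
            raise FormatError(f"{path}: non-numeric counts")
        if np.any(arr < 0):
            raise FormatError(f"{path}: negative counts")
        if not np.all(np.equal(np.mod(arr, 1), 0)):
            raise FormatError(f"{path}: fractional counts")
        return CountTable(
            [str(i) for i in df.index], [str(c) for c in df.columns], arr.astype(np.int64)
        )
    if fmt == "mtx_triplet":
        rows = Path(str(path) + ".rows").read_text().split()
        cols = Path(str(path) + ".cols").read_text().split()
        from scipy.io import mmread

        mat = mmread(str(path))
        arr = np.asarray(mat.todense() if hasattr(mat, "todense") else mat)
        if np.any(arr < 0):
            raise FormatError(f"{path}: negative counts")
        if not np.all(np.equal(np.mod(arr, 1), 0)):
            raise FormatError(f"{path}: fractional counts")
        return CountTable(rows, cols, arr.astype(np.int64))
    raise ValueError(f"unknown count format {fmt!r}")


def write_counts(table: CountTable, path: str | Path, fmt: str = "tsv") -> None:
    path = Path(path)
    if fmt == "tsv":
        table.to_frame().to_csv(path, sep="\t", index_label="id")
        return
    if fmt == "mtx_triplet":
        from scipy.io import mmwrite
        from scipy.sparse import coo_matrix

        mmwrite(str(path), coo_matrix(table.counts))
        Path(str(path) + ".rows").write_text("\n".join(table.row_ids) + "\n")
        Path(str(path) + ".cols").write_text("\n".join(table.col_ids) + "\n")
        return
    raise ValueError(f"unknown count format {fmt!r}")
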