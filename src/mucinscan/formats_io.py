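"""Readers and writers for the standard formats the pipeline touches.

All residue coordinates in this package are 1-based and inclusive, matching
the Pfam/HMMER reporting convention.  Domain coordinates are taken from the
*envelope* columns of hmmscan's per-domain tabular output, because the
envelope bounds the full domain occurrence and is what architecture
construction needs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "FormatError",
    "ProteinRecord",
    "DomainHit",
    "ExpressionMatrix",
    "CtRecord",
    "DOMAIN_VOCABULARY",
    "DEFAULT_NAME_MAP",
    "read_fasta",
    "write_fasta",
    "parse_domtblout",
    "write_domtblout",
    "read_expression_tsv",
    "write_expression_tsv",
    "read_ct_table",
    "write_ct_table",
]

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")
VALID_RESIDUES = AMINO_ACIDS | {"X"}

#: Internal controlled vocabulary for mucin-relevant protein domains.
DOMAIN_VOCABULARY = ("VWD", "C8", "TIL", "VWC", "CTCK", "Mucin2_WxxW", "other")

#: Default mapping from Pfam family names onto the internal vocabulary.
DEFAULT_NAME_MAP: Mapping[str, str] = {
    "VWD": "VWD",
    "C8": "C8",
    "TIL": "TIL",
    "VWC": "VWC",
    "CTCK": "CTCK",
    "Cys_knot": "CTCK",
    "Mucin2_WxxW": "Mucin2_WxxW",
}


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True)
class ProteinRecord:
    """One protein sequence flowing through the evidence funnel."""

    id: str
    description: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("protein record with empty id")
        if not self.sequence:
            raise FormatError(f"protein {self.id!r} has an empty sequence")
        bad = set(self.sequence) - VALID_RESIDUES
        if bad:
            raise FormatError(
                f"protein {self.id!r} contains illegal residue(s) "
                f"{sorted(bad)}; allowed: 20 canonical amino acids + X"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class DomainHit:
    """One domain match on one protein (envelope coordinates, 1-based)."""

    protein_id: str
    family: str
    start: int
    end: int
    i_evalue: float
    score: float

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise FormatError(
                f"hit {self.family} on {self.protein_id}: invalid coordinates "
                f"{self.start}..{self.end}"
            )
        if not self.i_evalue > 0:
            raise FormatError(
                f"hit {self.family} on {self.protein_id}: i-Evalue must be > 0"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class CtRecord:
    """One qPCR well: a raw Ct measurement for one gene in one sample."""

    sample_id: str
    fish_id: str
    tissue: str
    group: str
    gene: str
    replicate: int
    ct: float

    def __post_init__(self) -> None:
        if self.replicate not in (1, 2):
            raise FormatError(
                f"sample {self.sample_id} gene {self.gene}: replicate must be "
                f"1 or 2, got {self.replicate}"
            )
        if not self.ct > 0:
            raise FormatError(
                f"sample {self.sample_id} gene {self.gene}: Ct must be > 0"
            )


class ExpressionMatrix:
    """Genes (rows) x tissues (columns) FPKM matrix.

    Thin wrapper around a pandas DataFrame that enforces non-negativity and
    the canonical genes-in-rows orientation.
    """

    def __init__(self, frame: pd.DataFrame):
        if frame.columns.duplicated().any():
            raise FormatError("duplicate tissue names in expression matrix")
        if frame.index.duplicated().any():
            raise FormatError("duplicate gene ids in expression matrix")
        if frame.isna().any().any():
            raise FormatError("missing FPKM cells are not allowed")
        if (frame.values < 0).any():
            raise FormatError("negative FPKM values are not allowed")
        self.frame = frame.astype(float)

    @property
    def genes(self) -> list[str]:
        return list(self.frame.index)

    @property
    def tissues(self) -> list[str]:
        return list(self.frame.columns)

    def max_fpkm(self, gene: str) -> float:
        return float(self.frame.loc[gene].max())

    def __contains__(self, gene: str) -> bool:
        return gene in self.frame.index

    def __eq__(self, other: object) -> bool:
        return isinstance(other, ExpressionMatrix) and self.frame.equals(other.frame)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a protein FASTA file; sequences are upper-cased and validated."""
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate record id {rec.id!r} in {path}")
        seen.add(rec.id)
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id):].strip()
        records.append(
            ProteinRecord(id=rec.id, description=desc, sequence=str(rec.seq).upper())
        )
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    seqs = [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.description)
        for r in records
    ]
    SeqIO.write(seqs, str(path), "fasta")


# ---------------------------------------------------------------------------
# hmmscan per-domain table (domtblout dialect)

# Column layout of hmmscan --domtblout: 22 whitespace-delimited columns plus a
# free-text target description.  For hmmscan the *target* is the Pfam family
# and the *query* is the protein.
_DOMTBL_NCOL = 23
_COL_FAMILY = 0
_COL_PROTEIN = 3
_COL_IEVALUE = 12
_COL_SCORE = 13
_COL_ENV_FROM = 19
_COL_ENV_TO = 20


def parse_domtblout(
    path: str | Path, name_map: Mapping[str, str] | None = None
) -> list[DomainHit]:
    """Parse an hmmscan per-domain table into :class:`DomainHit` rows.

    ``name_map`` maps Pfam family names onto the internal domain vocabulary;
    unmapped families become ``"other"``.  Comment lines (``#``) are skipped;
    coordinates come from the envelope columns.
    """
    if name_map is None:
        name_map = DEFAULT_NAME_MAP
    hits: list[DomainHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            fields = line.split(None, _DOMTBL_NCOL - 1)
            if len(fields) < _DOMTBL_NCOL - 1:
                raise FormatError(
                    f"{path}:{lineno}: expected {_DOMTBL_NCOL} columns, "
                    f"got {len(fields)}"
                )
            try:
                hit = DomainHit(
                    protein_id=fields[_COL_PROTEIN],
                    family=name_map.get(fields[_COL_FAMILY], "other"),
                    start=int(fields[_COL_ENV_FROM]),
                    end=int(fields[_COL_ENV_TO]),
                    i_evalue=float(fields[_COL_IEVALUE]),
                    score=float(fields[_COL_SCORE]),
                )
            except (ValueError, FormatError) as exc:
                raise FormatError(f"{path}:{lineno}: malformed row: {exc}") from exc
            hits.append(hit)
    return hits


def write_domtblout(hits: Iterable[DomainHit], path: str | Path) -> None:
    """Write hits in the hmmscan per-domain column layout.

    Only the columns this pipeline consumes carry real information; the
    remaining columns are filled with plausible placeholders so that any
    domtblout reader accepts the file.
    """
    with open(path, "w") as fh:
        fh.write("# target name  accession  tlen  query name  accession  qlen"
                 "  E-value  score  bias  #  of  c-Evalue  i-Evalue  score"
                 "  bias  from  to  from  to  from  to  acc"
                 "  description of target\n")
        for h in hits:
            dom_len = h.end - h.start + 1
            row = [
                h.family, "-", str(dom_len), h.protein_id, "-", "0",
                f"{h.i_evalue:.2g}", f"{h.score:.1f}", "0.0", "1", "1",
                f"{h.i_evalue:.2g}", f"{h.i_evalue:.2g}", f"{h.score:.1f}",
                "0.0", "1", str(dom_len), str(h.start), str(h.end),
                str(h.start), str(h.end), "0.99", "-",
            ]
            fh.write(" ".join(row) + "\n")


# ---------------------------------------------------------------------------
# Expression matrix (TSV, genes in rows)


def read_expression_tsv(path: str | Path) -> ExpressionMatrix:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    try:
        frame = frame.apply(pd.to_numeric)
    except (ValueError, TypeError) as exc:
        raise FormatError(f"{path}: non-numeric FPKM cell: {exc}") from exc
    return ExpressionMatrix(frame)


def write_expression_tsv(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.frame.to_csv(path, sep="\t", index_label="gene")


# ---------------------------------------------------------------------------
# qPCR Ct table (long format)

_CT_COLUMNS = ["sample_id", "fish_id", "tissue", "group", "gene", "replicate", "ct"]


def read_ct_table(path: str | Path) -> list[CtRecord]:
    """Read a long-format Ct table.

    Rows with an empty Ct cell are treated as absent wells and dropped;
    a non-numeric Ct is a format error.
    """
    frame = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _CT_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    records: list[CtRecord] = []
    for idx, row in frame.iterrows():
        raw_ct = row["ct"]
        if raw_ct is None or (isinstance(raw_ct, float) and math.isnan(raw_ct)) \
                or str(raw_ct).strip() == "":
            continue  # absent well
        try:
            ct = float(raw_ct)
        except ValueError as exc:
            raise FormatError(
                f"{path}: row {idx + 2}: non-numeric Ct {raw_ct!r}"
            ) from exc
        records.append(
            CtRecord(
                sample_id=row["sample_id"],
                fish_id=row["fish_id"],
                tissue=row["tissue"],
                group=row["group"],
                gene=row["gene"],
                replicate=int(row["replicate"]),
                ct=ct,
            )
        )
    return records


def write_ct_table(records: Sequence[CtRecord], path: str | Path) -> None:
    frame = pd.DataFrame([r.__dict__ for r in records], columns=_CT_COLUMNS)
    frame.to_csv(path, sep="\t", index=False)
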