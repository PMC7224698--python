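"""Reading, validating and writing CDS FASTA and expression tables.

A coding sequence record (:class:`CdsRecord`) is a pre-extracted CDS:
length divisible by three, alphabet A/C/G/T/N, and — in strict mode —
no internal stop codon. Expression tables are plain tab-separated files
with columns ``transcript_id  gene_symbol  description  expression``,
emulating an RNA-seq derived list of expressed transcripts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import ValidationError
from .genetic_code import STOP_CODONS

logger = logging.getLogger(__name__)

_ALPHABET = frozenset("ACGTN")

EXPRESSION_COLUMNS = ("transcript_id", "gene_symbol", "description", "expression")


@dataclass(frozen=True)
class CdsRecord:
    """A validated coding sequence.

    Attributes
    ----------
    transcript_id : accession of the transcript (e.g. ``NM_013557.2``)
    gene_symbol : gene symbol, may be empty
    sequence : uppercase DNA, length divisible by 3
    """

    transcript_id: str
    gene_symbol: str
    sequence: str

    @property
    def n_codons(self) -> int:
        return len(self.sequence) // 3

    def codons(self) -> list[str]:
        """Frame-0, non-overlapping triplets."""
        s = self.sequence
        return [s[i : i + 3] for i in range(0, len(s), 3)]


def validate_cds(record: CdsRecord, strict: bool = False) -> str | None:
    """Return a reason string if ``record`` is invalid, else ``None``.

    Always enforced: non-empty, length divisible by 3, alphabet
    A/C/G/T/N. With ``strict``: additionally no internal stop codon
    (a stop in any frame-0 position before the final codon).
    """
    seq = record.sequence
    if not seq:
        return "empty sequence"
    if len(seq) % 3 != 0:
        return f"length {len(seq)} not divisible by 3"
    bad = set(seq) - _ALPHABET
    if bad:
        return f"invalid characters {sorted(bad)}"
    if strict:
        for i in range(0, len(seq) - 3, 3):
            if seq[i : i + 3] in STOP_CODONS:
                return f"internal stop codon {seq[i:i + 3]} at codon {i // 3}"
    return None


def _parse_header(description: str) -> tuple[str, str]:
    """Split a FASTA description into (transcript_id, gene_symbol)."""
    parts = description.split()
    tid = parts[0] if parts else ""
    symbol = parts[1] if len(parts) > 1 else ""
    return tid, symbol


def read_cds_fasta(path: str | Path, strict: bool = False) -> list[CdsRecord]:
    """Read a (multi-)FASTA of coding sequences.

    Invalid records are dropped with a logged reason when ``strict`` is
    off; with ``strict`` on, the first invalid record raises
    :class:`ValidationError` naming the record and the rule violated.
    """
    records: list[CdsRecord] = []
    for seqrec in SeqIO.parse(str(path), "fasta"):
        tid, symbol = _parse_header(seqrec.description)
        rec = CdsRecord(tid, symbol, str(seqrec.seq).upper())
        reason = validate_cds(rec, strict=strict)
        if reason is None:
            records.append(rec)
        elif strict:
            raise ValidationError(f"record {tid!r}: {reason}")
        else:
            logger.info("dropping record %r: %s", tid, reason)
    return records


def write_cds_fasta(records: Iterable[CdsRecord], path: str | Path) -> None:
    """Write records as unwrapped FASTA, header ``>id symbol``."""
    seqrecs = [
        SeqRecord(
            Seq(r.sequence),
            id=r.transcript_id,
            description=r.gene_symbol,
        )
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=None)
        writer.write_file(seqrecs)


def read_expression_table(path: str | Path) -> pd.DataFrame:
    """Read a TSV expression table (``#`` lines are comments)."""
    table = pd.read_csv(path, sep="\t", comment="#", dtype={"gene_symbol": str})
    return validate_expression_table(table)


def validate_expression_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = set(EXPRESSION_COLUMNS) - set(table.columns)
    if missing:
        raise ValidationError(f"expression table missing columns {sorted(missing)}")
    if table["transcript_id"].duplicated().any():
        dupes = table.loc[table["transcript_id"].duplicated(), "transcript_id"]
        raise ValidationError(f"duplicate transcript ids: {list(dupes)[:5]}")
    if (table["expression"] < 0).any():
        raise ValidationError("negative expression values")
    return table


def write_expression_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def filter_expressed(table: pd.DataFrame, min_expression: float = 0.0) -> pd.DataFrame:
    """Rows with expression strictly above ``min_expression``, order kept."""
    if min_expression < 0:
        raise ValidationError("min_expression must be >= 0")
    return table[table["expression"] > min_expression]


def select_by_keyword(table: pd.DataFrame, keyword: str) -> pd.DataFrame:
    """Rows whose description contains ``keyword`` (case-insensitive).

    Plain substring match, no regular expressions — mirrors building a
    functional subset (e.g. all kinases) by a keyword search over gene
    descriptions.
    """
    if not keyword:
        raise ValidationError("keyword must be non-empty")
    mask = (
        table["description"]
        .fillna("")
        .str.contains(keyword, case=False, regex=False)
    )
    return table[mask]


def records_by_id(records: Sequence[CdsRecord]) -> dict[str, CdsRecord]:
    return {r.transcript_id: r for r in records}
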