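"""Reading, validating and codon-tokenizing CDS records.

A CDS set destined for codon-usage statistics has to be clean: in frame,
long enough to give stable per-gene indices, and free of internal stops.
This module turns raw FASTA entries into per-gene codon count tables and
collects (rather than raises on) per-gene rejections, mirroring a screening
pipeline that drops failing candidates but keeps the batch alive.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genetic_code import ALL_CODONS, GeneticCode, standard_code

logger = logging.getLogger(__name__)

_DNA = set("ACGT")


class FastaFormatError(ValueError):
    """Malformed FASTA input (parse failure or duplicate gene ids)."""


class CdsValidationError(ValueError):
    """A single CDS failed validation under the active policy."""

    def __init__(self, gene_id: str, reason: str):
        super().__init__(f"{gene_id}: {reason}")
        self.gene_id = gene_id
        self.reason = reason


@dataclass(frozen=True)
class CdsRecord:
    gene_id: str
    sequence: str


@dataclass(frozen=True)
class ValidationPolicy:
    """How strictly raw CDS are screened before codon counting.

    min_length is in nucleotides; 300 bp keeps per-gene indices (notably ENC)
    away from their worst small-sample behaviour.  Ambiguous bases (N, R, Y,
    ...) invalidate only the containing codon, never the gene.
    """

    min_length: int = 300
    frame: Literal["reject", "trim"] = "reject"
    internal_stop: Literal["reject", "mask"] = "reject"


@dataclass(frozen=True)
class ValidatedCds:
    gene_id: str
    codons: tuple[str, ...]
    n_skipped_ambiguous: int
    length_nt: int
    terminal_stop: str | None = None
    n_masked_internal_stops: int = 0


@dataclass(frozen=True)
class Rejection:
    gene_id: str
    reason: str


@dataclass(frozen=True)
class CodonCountTable:
    """Counts of all 64 codons for one gene (or one pooled group).

    Stop codons never contribute to ``total_codons``; a validated CDS has had
    them stripped or masked already, so their counts are zero by construction.
    """

    gene_id: str
    counts: dict[str, int]
    total_codons: int


def read_cds_fasta(path: str | Path) -> list[CdsRecord]:
    """Read a multi-record FASTA; the header token before the first whitespace
    is the gene id.  Duplicate ids are an error; an empty file logs a warning.
    """
    path = Path(path)
    try:
        records = [
            CdsRecord(gene_id=rec.id, sequence=str(rec.seq).upper().replace("U", "T"))
            for rec in SeqIO.parse(str(path), "fasta")
        ]
    except ValueError as exc:  # Biopython signals malformed FASTA via ValueError
        raise FastaFormatError(f"{path}: {exc}") from exc
    if not records:
        logger.warning("no FASTA records found in %s", path)
    ids = Counter(r.gene_id for r in records)
    dups = sorted(i for i, n in ids.items() if n > 1)
    if dups:
        raise FastaFormatError(f"{path}: duplicate gene ids: {', '.join(dups)}")
    return records


def write_cds_fasta(records: Iterable[CdsRecord | ValidatedCds], path: str | Path) -> None:
    """Write records (raw or validated) back to FASTA, unwrapped lines."""
    out = []
    for rec in records:
        if isinstance(rec, ValidatedCds):
            seq = "".join(rec.codons) + (rec.terminal_stop or "")
        else:
            seq = rec.sequence
        out.append(SeqRecord(Seq(seq), id=rec.gene_id, description=""))
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=None)
        writer.write_file(out)


def validate_cds(
    record: CdsRecord,
    policy: ValidationPolicy = ValidationPolicy(),
    code: GeneticCode | None = None,
) -> ValidatedCds:
    """Screen one CDS and tokenize it into frame-0 codons.

    A terminal stop codon is recorded and excluded from the codon list; an
    ambiguous codon is skipped and counted.  Raises CdsValidationError with
    the reason on rejection.
    """
    code = code or standard_code()
    seq = record.sequence.upper().replace("U", "T")
    if len(seq) < policy.min_length:
        raise CdsValidationError(
            record.gene_id, f"length {len(seq)} below minimum {policy.min_length}"
        )
    if len(seq) % 3 != 0:
        if policy.frame == "reject":
            raise CdsValidationError(record.gene_id, "length not multiple of 3")
        seq = seq[: len(seq) - len(seq) % 3]

    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    terminal_stop = None
    if codons and codons[-1] in code.stop_codons:
        terminal_stop = codons.pop()

    kept: list[str] = []
    n_ambiguous = 0
    n_masked = 0
    for i, codon in enumerate(codons):
        if not set(codon) <= _DNA:
            n_ambiguous += 1
            continue
        if codon in code.stop_codons:
            if policy.internal_stop == "reject":
                raise CdsValidationError(
                    record.gene_id, f"internal stop codon {codon} at codon {i + 1}"
                )
            logger.warning("%s: masking internal stop %s at codon %d", record.gene_id, codon, i + 1)
            n_masked += 1
            continue
        kept.append(codon)
    return ValidatedCds(
        gene_id=record.gene_id,
        codons=tuple(kept),
        n_skipped_ambiguous=n_ambiguous,
        length_nt=len(seq),
        terminal_stop=terminal_stop,
        n_masked_internal_stops=n_masked,
    )


def validate_batch(
    records: Iterable[CdsRecord],
    policy: ValidationPolicy = ValidationPolicy(),
    code: GeneticCode | None = None,
) -> tuple[list[ValidatedCds], list[Rejection]]:
    """Validate a batch; rejections are collected, never fatal."""
    accepted: list[ValidatedCds] = []
    rejected: list[Rejection] = []
    for rec in records:
        try:
            accepted.append(validate_cds(rec, policy, code))
        except CdsValidationError as exc:
            rejected.append(Rejection(gene_id=exc.gene_id, reason=exc.reason))
    return accepted, rejected


def count_codons(v: ValidatedCds) -> CodonCountTable:
    counts = dict.fromkeys(ALL_CODONS, 0)
    for codon in v.codons:
        counts[codon] += 1
    return CodonCountTable(gene_id=v.gene_id, counts=counts, total_codons=len(v.codons))


def pool_counts(tables: Iterable[CodonCountTable], label: str = "pooled") -> CodonCountTable:
    """Element-wise sum of count tables (usage-weighted pooling)."""
    tables = list(tables)
    if not tables:
        raise ValueError("cannot pool an empty list of count tables")
    counts = dict.fromkeys(ALL_CODONS, 0)
    for t in tables:
        for codon, n in t.counts.items():
            counts[codon] += n
    return CodonCountTable(
        gene_id=label, counts=counts, total_codons=sum(t.total_codons for t in tables)
    )


def write_rejections_tsv(rejections: Iterable[Rejection], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\treason\n")
        for r in rejections:
            fh.write(f"{r.gene_id}\t{r.reason}\n")
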