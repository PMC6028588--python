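"""mRNA records and FASTA input.

Each analyzed mRNA consists of its 5' UTR plus the first 100 nt of coding
sequence.  The CDS start (0-based index of the first start-codon nucleotide)
is supplied per record, either as a ``|cds_start=<int>`` suffix on the FASTA
header or through a two-column sidecar TSV (record_id, cds_start).
Coordinates are 0-based, half-open throughout.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path

from Bio import SeqIO

from .energy import SequenceAlphabetError, normalize_rna

__all__ = ["MRNARecord", "read_fasta_with_cds", "CDS_WINDOW"]

log = logging.getLogger(__name__)

#: Length of coding sequence retained downstream of the start codon.
CDS_WINDOW = 100

_CDS_TOKEN = re.compile(r"\|cds_start=(\d+)")

START_CODONS = ("AUG", "GUG", "UUG")


@dataclass(frozen=True)
class MRNARecord:
    """One mRNA analysis window: 5' UTR + first 100 nt of CDS."""

    id: str
    sequence: str  # normalized RNA alphabet, already truncated at cds_start+100
    cds_start: int

    def __post_init__(self) -> None:
        seq = normalize_rna(self.sequence)
        if not 0 <= self.cds_start < len(seq):
            raise ValueError(
                f"{self.id}: cds_start {self.cds_start} outside sequence "
                f"of length {len(seq)}"
            )
        object.__setattr__(self, "sequence", seq[: self.cds_start + CDS_WINDOW])

    @property
    def utr(self) -> str:
        return self.sequence[: self.cds_start]

    @property
    def start_codon(self) -> str:
        return self.sequence[self.cds_start : self.cds_start + 3]

    @property
    def has_canonical_start(self) -> bool:
        return self.start_codon in START_CODONS


def _read_sidecar(path: str | Path) -> dict[str, int]:
    table: dict[str, int] = {}
    for line_no, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 2:
            raise ValueError(f"{path}:{line_no}: expected 'record_id<TAB>cds_start'")
        table[fields[0]] = int(fields[1])
    return table


def read_fasta_with_cds(
    fasta_path: str | Path, sidecar_path: str | Path | None = None
) -> tuple[list[MRNARecord], list[str]]:
    """Load mRNA records from FASTA, resolving the CDS start per record.

    Records lacking a resolvable CDS start, with a CDS start beyond the
    sequence, or with an invalid alphabet are skipped; each skip is logged
    and returned in the error list.  Duplicate record ids are a hard error.
    Non-AUG/GUG/UUG start codons are accepted with a warning.
    """
    sidecar = _read_sidecar(sidecar_path) if sidecar_path else {}
    records: list[MRNARecord] = []
    errors: list[str] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        header = rec.description
        m = _CDS_TOKEN.search(header)
        rec_id = rec.id.split("|")[0]
        if rec_id in seen:
            raise ValueError(f"duplicate record id {rec_id!r} in {fasta_path}")
        seen.add(rec_id)
        if m:
            cds_start = int(m.group(1))
        elif rec_id in sidecar:
            cds_start = sidecar[rec_id]
        else:
            errors.append(f"{rec_id}: no cds_start in header or sidecar; skipped")
            log.error(errors[-1])
            continue
        raw = str(rec.seq)
        if raw != raw.upper().replace("T", "U"):
            log.info("%s: DNA/lowercase alphabet converted to RNA", rec_id)
        try:
            record = MRNARecord(id=rec_id, sequence=raw, cds_start=cds_start)
        except (ValueError, SequenceAlphabetError) as exc:
            errors.append(f"{rec_id}: {exc}; skipped")
            log.error(errors[-1])
            continue
        if not record.has_canonical_start:
            log.warning(
                "%s: non-canonical start codon %r at cds_start %d",
                rec_id,
                record.start_codon,
                cds_start,
            )
        records.append(record)
    return records, errors
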