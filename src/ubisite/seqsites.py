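"""Protein sequences and lysine sites.

FASTA I/O, enumeration of lysine (K) residues as candidate ubiquitination
sites, extraction of K-centred sequence windows with boundary truncation,
and a greedy redundancy filter based on a k-mer containment identity
estimate.

Coordinates are 1-based and inclusive everywhere a user sees them, matching
the convention of the site databases this tool consumes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

#: the 20 canonical residues plus tolerated ambiguity codes
AMBIGUITY_CODES = frozenset("XUBZJO*")
CANONICAL = frozenset("ACDEFGHIKLMNPQRSTVWY")
ALLOWED_RESIDUES = CANONICAL | AMBIGUITY_CODES


class FastaFormatError(ValueError):
    """Raised for malformed FASTA input."""


@dataclass(frozen=True)
class ProteinRecord:
    """One protein: accession, free-text description, uppercase sequence."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"protein {self.id!r}: empty sequence")
        if any(c.isspace() for c in self.sequence):
            raise ValueError(f"protein {self.id!r}: whitespace in sequence")
        bad = set(self.sequence) - ALLOWED_RESIDUES
        if bad:
            raise ValueError(
                f"protein {self.id!r}: unexpected residue codes {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class SiteRecord:
    """A lysine site: protein accession, 1-based position, optional label.

    ``label`` is 1 for an experimentally verified ubiquitination site,
    0 for a (presumed) non-site, and None when unknown.
    """

    protein_id: str
    position: int
    residue: str = "K"
    label: int | None = None

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError("position is 1-based and must be >= 1")
        if self.residue != "K":
            raise ValueError(f"site residue must be 'K', got {self.residue!r}")
        if self.label not in (None, 0, 1):
            raise ValueError(f"label must be 0, 1 or None, got {self.label!r}")


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a multi-record FASTA file (wrapped or unwrapped lines).

    Sequences are uppercased; record order is preserved.  An empty file
    yields an empty list.  A record with an empty sequence, a duplicate id,
    or leading non-header content raises :class:`FastaFormatError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text()
    stripped = text.lstrip()
    if stripped and not stripped.startswith(">"):
        raise FastaFormatError(
            f"{path}: first non-blank line does not start with '>'")
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            raise FastaFormatError(f"{path}: record {rec.id!r} has an empty sequence")
        if rec.id in seen:
            raise FastaFormatError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        records.append(ProteinRecord(id=rec.id, sequence=seq,
                                     description=rec.description))
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path,
                width: int = 60) -> None:
    """Write records as FASTA with lines wrapped at ``width`` residues."""
    with open(path, "w") as fh:
        for rec in records:
            header = rec.description if rec.description else rec.id
            if not header.startswith(rec.id):
                header = f"{rec.id} {header}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i:i + width] + "\n")


def enumerate_lysines(protein: ProteinRecord,
                      labels: dict[int, int] | None = None) -> list[SiteRecord]:
    """One :class:`SiteRecord` per 'K' residue, positions ascending, 1-based.

    Ambiguity codes are never counted as lysines.  ``labels`` optionally
    maps 1-based positions to binary labels.
    """
    labels = labels or {}
    return [SiteRecord(protein_id=protein.id, position=i + 1,
                       label=labels.get(i + 1))
            for i, aa in enumerate(protein.sequence) if aa == "K"]


def extract_window(sequence: str, position: int, flank: int) -> str:
    """Subsequence of ``flank`` residues either side of the lysine at
    ``position`` (1-based).

    Windows running past either terminus are truncated to the residues that
    exist — never padded with placeholder characters — so the result covers
    positions ``max(1, position-flank) .. min(L, position+flank)`` and has
    length at most ``2*flank + 1``.
    """
    if flank < 1:
        raise ValueError(f"flank must be >= 1, got {flank}")
    if not 1 <= position <= len(sequence):
        raise ValueError(f"position {position} outside sequence of length "
                         f"{len(sequence)}")
    if sequence[position - 1] != "K":
        raise ValueError(f"position {position} is {sequence[position - 1]!r}, "
                         "not 'K'")
    start = max(1, position - flank)
    stop = min(len(sequence), position + flank)
    return sequence[start - 1:stop]


def window_center(position: int, flank: int) -> int:
    """1-based position of the lysine inside its extracted window."""
    return position - max(1, position - flank) + 1


def _kmer_set(sequence: str, k: int) -> set[str]:
    return {sequence[i:i + k] for i in range(len(sequence) - k + 1)}


def kmer_identity(seq_a: str, seq_b: str, k: int = 5) -> float:
    """Containment identity estimate: shared k-mers over the k-mers of the
    shorter sequence.  0 when either sequence is shorter than ``k``."""
    ka, kb = _kmer_set(seq_a, k), _kmer_set(seq_b, k)
    if len(seq_a) > len(seq_b):
        ka, kb = kb, ka
    if not ka:
        return 0.0
    return len(ka & kb) / len(ka)


def redundancy_filter(records: Sequence[ProteinRecord],
                      identity_threshold: float = 0.3,
                      k: int = 5) -> list[ProteinRecord]:
    """Greedy representative selection to curb training-set homology.

    Records are processed longest-first (ties broken by id); a record is
    discarded when its k-mer containment identity to any already-kept
    representative exceeds ``identity_threshold``.  The result is a subset
    of the input, returned in the original input order.
    """
    if not 0 < identity_threshold < 1:
        raise ValueError("identity_threshold must be in (0, 1)")
    order = sorted(records, key=lambda r: (-len(r.sequence), r.id))
    kept: list[ProteinRecord] = []
    kept_ids: set[str] = set()
    for rec in order:
        if all(kmer_identity(rec.sequence, other.sequence, k=k)
               <= identity_threshold for other in kept):
            kept.append(rec)
            kept_ids.add(rec.id)
    return [r for r in records if r.id in kept_ids]


def sites_to_frame(sites: Sequence[SiteRecord]) -> pd.DataFrame:
    """Site table with columns protein_id, position, residue, label."""
    return pd.DataFrame({
        "protein_id": [s.protein_id for s in sites],
        "position": [s.position for s in sites],
        "residue": [s.residue for s in sites],
        "label": [s.label if s.label is not None else pd.NA for s in sites],
    }).astype({"label": "Int64"})


def write_site_table(sites: Sequence[SiteRecord], path: str | Path) -> None:
    sites_to_frame(sites).to_csv(path, sep="\t", index=False)


def read_site_table(path: str | Path) -> list[SiteRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str})
    out: list[SiteRecord] = []
    for row in df.itertuples(index=False):
        label = None if pd.isna(row.label) else int(row.label)
        out.append(SiteRecord(protein_id=row.protein_id,
                              position=int(row.position),
                              residue=str(row.residue), label=label))
    return out
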