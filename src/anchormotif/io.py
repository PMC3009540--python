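"""Sequence input/output, terminal extraction, and redundancy reduction.

Positive (presumed co-sorted) and negative (background) protein sets are
held as :class:`Dataset` objects of labelled :class:`SequenceRecord`.
Redundancy reduction follows the greedy longest-first clustering scheme:
sequences are sorted by descending length, each joins the first existing
representative it matches at or above the identity threshold, otherwise it
founds a new cluster, and only representatives are kept.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import pandas as pd
from Bio import Align, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .alphabet import sanitize
from .util import InputError

logger = logging.getLogger(__name__)

Label = Literal["positive", "negative"]
End = Literal["N", "C"]


@dataclass(frozen=True)
class SequenceRecord:
    """A labelled protein sequence over the 21-letter extended alphabet."""

    id: str
    residues: str
    label: Label

    def __post_init__(self) -> None:
        if not self.residues:
            raise InputError(f"record {self.id!r} has an empty sequence")
        if self.label not in ("positive", "negative"):
            raise InputError(f"record {self.id!r} has invalid label {self.label!r}")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class Dataset:
    """An ordered collection of records with unique ids."""

    records: list[SequenceRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.id in seen:
                raise InputError(f"duplicate sequence id {rec.id!r}")
            seen.add(rec.id)

    @property
    def n_pos(self) -> int:
        return sum(1 for r in self.records if r.label == "positive")

    @property
    def n_neg(self) -> int:
        return sum(1 for r in self.records if r.label == "negative")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def subset(self, ids: Iterable[str]) -> "Dataset":
        wanted = set(ids)
        return Dataset([r for r in self.records if r.id in wanted])


@dataclass(frozen=True)
class TerminalSegment:
    """A K-residue N- or C-terminal slice of a parent sequence."""

    parent_id: str
    end: End
    k: int
    residues: str

    def __len__(self) -> int:
        return len(self.residues)


def read_fasta(path: str | Path, label: Label) -> Dataset:
    """Read a FASTA file into a labelled :class:`Dataset`.

    Non-standard residue letters are mapped to ``X``; the total number of
    sanitised characters is logged.  Empty files, empty sequences and
    duplicate ids raise :class:`InputError`.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"FASTA file not found: {path}")
    records: list[SequenceRecord] = []
    n_sanitized = 0
    for entry in SeqIO.parse(str(path), "fasta"):
        cleaned, n_mapped = sanitize(str(entry.seq))
        n_sanitized += n_mapped
        if not cleaned:
            raise InputError(f"record {entry.id!r} in {path} has an empty sequence")
        records.append(SequenceRecord(entry.id, cleaned, label))
    if not records:
        raise InputError(f"no FASTA records parsed from {path}")
    if n_sanitized:
        logger.info(
            "sanitized %d non-standard residue letters to 'X' in %s",
            n_sanitized,
            path,
        )
    return Dataset(records)


def write_fasta(ds: Dataset, path: str | Path) -> None:
    entries = [
        SeqRecord(Seq(r.residues), id=r.id, description=r.label) for r in ds
    ]
    SeqIO.write(entries, str(path), "fasta")


def extract_terminal(record: SequenceRecord, end: End = "N", k: int = 200) -> TerminalSegment:
    """Extract the K-residue prefix (N) or suffix (C) of a record."""
    if k < 1:
        raise ValueError("terminal length k must be >= 1")
    if end == "N":
        residues = record.residues[:k]
    elif end == "C":
        residues = record.residues[-k:]
    else:
        raise ValueError(f"end must be 'N' or 'C', got {end!r}")
    return TerminalSegment(record.id, end, k, residues)


def _aligner() -> Align.PairwiseAligner:
    # Identity scoring: match 1, mismatch 0, linear gap -1.  We want the
    # alignment maximising identical columns, not similarity.
    al = Align.PairwiseAligner()
    al.mode = "global"
    al.match_score = 1.0
    al.mismatch_score = 0.0
    al.open_gap_score = -1.0
    al.extend_gap_score = -1.0
    return al


def pairwise_identity(
    a: str, b: str, denominator: Literal["alignment", "shorter"] = "alignment"
) -> float:
    """Fraction of identical positions under a global alignment of a and b.

    ``denominator="alignment"`` divides by the alignment length including
    gap columns (the package default); ``"shorter"`` divides by the shorter
    sequence length (the CD-HIT convention) for parity checks.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    alignment = _aligner().align(a, b)[0]
    identities = alignment.counts().identities
    if denominator == "alignment":
        denom = alignment.length
    elif denominator == "shorter":
        denom = min(len(a), len(b))
    else:
        raise ValueError(f"unknown denominator convention {denominator!r}")
    return identities / denom


def reduce_redundancy(
    ds: Dataset,
    threshold: float = 0.8,
    denominator: Literal["alignment", "shorter"] = "alignment",
) -> tuple[Dataset, pd.DataFrame]:
    """Greedy longest-first identity clustering; keep one representative per cluster.

    Returns the reduced dataset (original record order preserved) and a
    cluster report mapping every removed id to its representative with the
    identity that joined them.
    """
    if not (0 < threshold <= 1):
        raise ValueError("threshold must be in (0, 1]")
    order = sorted(ds.records, key=lambda r: (-len(r.residues), r.id))
    representatives: list[SequenceRecord] = []
    rows = []
    for rec in order:
        joined = None
        for rep in representatives:
            ident = pairwise_identity(rec.residues, rep.residues, denominator)
            if ident >= threshold:
                joined = (rep.id, ident)
                break
        if joined is None:
            representatives.append(rec)
        else:
            rows.append(
                {"removed_id": rec.id, "representative_id": joined[0], "identity": joined[1]}
            )
    kept = {r.id for r in representatives}
    report = pd.DataFrame(rows, columns=["removed_id", "representative_id", "identity"])
    return ds.subset(kept), report
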