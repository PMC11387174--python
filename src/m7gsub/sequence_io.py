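"""FASTA and site-table I/O with explicit coordinate conventions.

All public coordinates are 1-based and inclusive: position 1 is the first
nucleotide of a transcript.  Sequences are RNA over the alphabet
``{A, C, G, U, N}``; DNA input is accepted and ``T`` is silently mapped to
``U`` on ingest, any other character is rejected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

RNA_ALPHABET = frozenset("ACGUN")

#: Regulators with trained reference models: the METTL1-WDR4 writer complex
#: and the three QKI reader isoforms.
KNOWN_REGULATORS = ("METTL1", "WDR4", "QKI5", "QKI6", "QKI7")

POSITIVE = 1
NEGATIVE = 0


class FastaParseError(ValueError):
    """Raised when a FASTA file is structurally invalid."""


class SequenceValidationError(ValueError):
    """Raised when a sequence contains characters outside {A,C,G,U,N}."""


def normalize_rna(raw: str, *, context: str = "") -> str:
    """Uppercase, map T->U and validate against the RNA alphabet."""
    seq = raw.upper().replace("T", "U")
    bad = set(seq) - RNA_ALPHABET
    if bad:
        where = f" in {context}" if context else ""
        raise SequenceValidationError(
            f"non-IUPAC RNA character(s) {sorted(bad)}{where}; "
            "allowed: A, C, G, U, N (T is accepted and mapped to U)"
        )
    return seq


@dataclass(frozen=True)
class RNASequence:
    """A named RNA sequence over ``{A,C,G,U,N}``.

    Input is normalized on construction: uppercased, ``T`` mapped to ``U``.
    """

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("RNASequence id must be non-empty")
        if not self.seq:
            raise ValueError(f"RNASequence {self.id!r}: sequence must be non-empty")
        object.__setattr__(self, "seq", normalize_rna(self.seq, context=f"record {self.id!r}"))

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class SiteRecord:
    """A candidate guanosine site on a transcript, 1-based.

    Both positive and negative sites are guanines; the centre-base check is
    enforced lazily at window extraction, where the transcript is available.
    """

    transcript_id: str
    position: int  # 1-based
    regulator: str
    label: int = POSITIVE

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(
                f"site {self.transcript_id}:{self.position}: positions are 1-based (>= 1)"
            )
        if self.label not in (POSITIVE, NEGATIVE):
            raise ValueError(f"label must be {POSITIVE} (positive) or {NEGATIVE} (negative)")


@dataclass(frozen=True)
class LabeledWindow:
    """A fixed, odd-length window centred on a G, with a binary label.

    ``origin`` records the (transcript_id, position) the window came from,
    or a synthetic tag.
    """

    window: RNASequence
    label: int
    origin: tuple = field(default=())

    def __post_init__(self) -> None:
        L = len(self.window)
        if L % 2 == 0:
            raise ValueError(f"window length must be odd, got {L}")
        centre = self.window.seq[(L - 1) // 2]
        if centre != "G":
            raise ValueError(
                f"window centre must be G, got {centre!r} (origin={self.origin})"
            )
        if self.label not in (POSITIVE, NEGATIVE):
            raise ValueError("label must be 0 or 1")

    @property
    def length(self) -> int:
        return len(self.window)


def read_fasta(path: str | Path) -> list[RNASequence]:
    """Read a FASTA file into validated :class:`RNASequence` records.

    ``T`` is mapped to ``U`` and case is normalized.  Duplicate ids and
    empty records are rejected.
    """
    records: list[RNASequence] = []
    seen: set[str] = set()
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta")):
        if not rec.id:
            raise FastaParseError(f"{path}: record {i + 1} has an empty header")
        if len(rec.seq) == 0:
            raise FastaParseError(f"{path}: record {i + 1} ({rec.id!r}) is empty")
        if rec.id in seen:
            raise FastaParseError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        records.append(RNASequence(id=rec.id, seq=str(rec.seq)))
    if not records:
        raise FastaParseError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Sequence[RNASequence], path: str | Path) -> None:
    """Write records as standard FASTA with 60-column line wrapping."""
    if not records:
        raise ValueError("cannot write an empty FASTA file")
    bio = [SeqRecord(Seq(r.seq), id=r.id, description="") for r in records]
    with open(path, "w") as fh:
        SeqIO.write(bio, fh, "fasta")


def read_site_table(path: str | Path) -> list[SiteRecord]:
    """Read a tab-delimited site table.

    Expected header: ``transcript_id  position  regulator [label]``.  When
    the label column is absent every row is positive.  Duplicate
    (transcript, position, regulator, label) rows collapse to one.  Unknown
    regulator names produce a warning but are retained.
    """
    path = Path(path)
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    if not lines:
        raise ValueError(f"{path}: empty site table")
    header = lines[0].split("\t")
    required = ["transcript_id", "position", "regulator"]
    if header[: len(required)] != required:
        raise ValueError(
            f"{path}: header must start with {required!r}, got {header!r}"
        )
    has_label = len(header) > 3 and header[3] == "label"

    records: list[SiteRecord] = []
    seen: set[tuple] = set()
    unknown: set[str] = set()
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}:{lineno}: expected >= 3 tab-separated fields")
        tx, pos_str, reg = fields[0], fields[1], fields[2]
        try:
            pos = int(pos_str)
        except ValueError:
            raise ValueError(
                f"{path}:{lineno}: position {pos_str!r} is not an integer"
            ) from None
        label = POSITIVE
        if has_label and len(fields) > 3 and fields[3]:
            lab = fields[3].strip().lower()
            if lab in ("positive", "pos", "1"):
                label = POSITIVE
            elif lab in ("negative", "neg", "0"):
                label = NEGATIVE
            else:
                raise ValueError(f"{path}:{lineno}: unknown label {fields[3]!r}")
        if reg not in KNOWN_REGULATORS:
            unknown.add(reg)
        key = (tx, pos, reg, label)
        if key in seen:
            continue
        seen.add(key)
        records.append(SiteRecord(transcript_id=tx, position=pos, regulator=reg, label=label))
    if unknown:
        warnings.warn(
            f"{path}: unknown regulator name(s) {sorted(unknown)}; rows retained",
            stacklevel=2,
        )
    return records


def write_site_table(records: Iterable[SiteRecord], path: str | Path) -> None:
    """Write sites as a TSV with the canonical four-column header."""
    with open(path, "w") as fh:
        fh.write("transcript_id\tposition\tregulator\tlabel\n")
        for r in records:
            lab = "positive" if r.label == POSITIVE else "negative"
            fh.write(f"{r.transcript_id}\t{r.position}\t{r.regulator}\t{lab}\n")
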