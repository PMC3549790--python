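"""Reading, validating and windowing promoter sequences.

Promoter segments are expected as plain FASTA, typically the region
-499..+100 relative to the transcription start site (TSS); with that
convention the TSS sits at 0-based offset 500 of a 600 nt segment.
Group metadata (species, tissue) comes from a separate TSV file keyed
by sequence id.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO

logger = logging.getLogger(__name__)

ALPHABET = frozenset("ACGTN")

#: TSS offset implied by the -499..+100 segment convention.
DEFAULT_TSS_OFFSET = 500


@dataclass(frozen=True)
class PromoterSequence:
    """A validated promoter segment.

    ``sequence`` is uppercase over {A,C,G,T,N}.  ``tss_offset`` is the
    0-based index of the TSS within the segment (500 for a -499..+100
    extract), or None when unknown.
    """

    id: str
    sequence: str
    species: str | None = None
    tissue: str | None = None
    tss_offset: int | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if not self.sequence:
            raise ValueError(f"sequence {self.id!r} is empty")
        bad = next(
            ((i, c) for i, c in enumerate(self.sequence) if c not in ALPHABET),
            None,
        )
        if bad is not None:
            i, c = bad
            raise ValueError(
                f"sequence {self.id!r}: illegal character {c!r} at position {i}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def n_fraction(self) -> float:
        return self.sequence.count("N") / len(self.sequence)

    @property
    def high_n(self) -> bool:
        """True when more than 10% of bases are ambiguous (N)."""
        return self.n_fraction > 0.10


@dataclass(frozen=True)
class SlidingWindowConfig:
    """Window geometry for profile extraction.

    The defaults (30 nt window, step 1) are the granularity at which
    promoter patterns keep sharp, class-distinguishing features; a
    relative GC% rescales each window's C+G share by the whole
    segment's C+G percentage.
    """

    window_size: int = 30
    step: int = 1
    relative_cg: bool = True

    def __post_init__(self) -> None:
        if self.window_size < 2:
            raise ValueError("window_size must be >= 2")
        if self.step < 1:
            raise ValueError("step must be >= 1")

    def n_windows(self, length: int) -> int:
        if length < self.window_size:
            raise ValueError(
                f"sequence of length {length} is shorter than the window "
                f"({self.window_size} nt); provide at least {self.window_size} nt"
            )
        return (length - self.window_size) // self.step + 1


def normalize_sequence(raw: str, seq_id: str = "?") -> str:
    """Uppercase, map U->T, reject anything outside {A,C,G,T,N}."""
    seq = raw.upper().replace("U", "T")
    for i, c in enumerate(seq):
        if c not in ALPHABET:
            raise ValueError(
                f"sequence {seq_id!r}: illegal character {c!r} at position {i}"
            )
    return seq


def read_fasta(
    path: str | Path, tss_offset: int | None = DEFAULT_TSS_OFFSET
) -> list[PromoterSequence]:
    """Read a multi-record FASTA of promoter segments.

    Sequences are uppercased, U is mapped to T, and any residue outside
    {A,C,G,T,N} raises with its position.  Duplicate ids and empty files
    are errors.
    """
    path = Path(path)
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = normalize_sequence(str(rec.seq), rec.id)
        records.append(
            PromoterSequence(id=rec.id, sequence=seq, tss_offset=tss_offset)
        )
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    logger.info("read %d promoter sequences from %s", len(records), path)
    return records


def write_fasta(seqs: Iterable[PromoterSequence], path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.id}\n")
            for i in range(0, len(s.sequence), 70):
                fh.write(s.sequence[i : i + 70] + "\n")


def read_metadata(path: str | Path) -> dict[str, tuple[str, str]]:
    """Read TSV metadata ``id<TAB>species<TAB>tissue`` (with header).

    Missing species/tissue fields may be empty strings.  Rows with the
    wrong column count raise with their line number.
    """
    path = Path(path)
    mapping: dict[str, tuple[str, str]] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.strip():
            raise ValueError(f"{path}: missing header line")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 3:
                raise ValueError(
                    f"{path}: line {lineno}: expected 3 tab-separated "
                    f"columns, got {len(parts)}"
                )
            seq_id, species, tissue = parts
            mapping[seq_id] = (species, tissue)
    logger.info("read metadata for %d ids from %s", len(mapping), path)
    return mapping


def attach_metadata(
    seqs: list[PromoterSequence], meta: dict[str, tuple[str, str]]
) -> list[PromoterSequence]:
    """Return sequences annotated with species/tissue; report orphan ids."""
    known = {s.id for s in seqs}
    orphans = sorted(set(meta) - known)
    if orphans:
        logger.warning(
            "%d metadata ids not present in the sequence collection: %s",
            len(orphans),
            ", ".join(orphans[:10]),
        )
    out = []
    for s in seqs:
        if s.id in meta:
            species, tissue = meta[s.id]
            out.append(
                PromoterSequence(
                    id=s.id,
                    sequence=s.sequence,
                    species=species or None,
                    tissue=tissue or None,
                    tss_offset=s.tss_offset,
                )
            )
        else:
            out.append(s)
    return out


def extract_windows(
    seq: PromoterSequence | str, cfg: SlidingWindowConfig | None = None
) -> list[str]:
    """Slide a window 5'->3' over the sequence and return the subsequences.

    Window k starts at 0-based offset ``k * step``; the count is
    ``floor((L - window_size)/step) + 1``.
    """
    cfg = cfg or SlidingWindowConfig()
    s = seq.sequence if isinstance(seq, PromoterSequence) else seq
    n = cfg.n_windows(len(s))
    return [s[k * cfg.step : k * cfg.step + cfg.window_size] for k in range(n)]


def window_count(length: int, cfg: SlidingWindowConfig) -> int:
    return cfg.n_windows(length)


def _check_count(length: int, window: int, step: int) -> int:  # pragma: no cover
    # reference formula kept next to the implementation it documents
    return math.floor((length - window) / step) + 1
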