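"""Alignment parsing and bootstrap resampling of RNA-Seq reads.

The bootstrap unit is the read (the fragment, for paired-end data): when a
read ID is drawn, *all* of its alignments enter the bootstrap sample, and a
read drawn ``m`` times contributes its alignments ``m`` times.  Every
bootstrap sample therefore contains exactly as many reads as the original
sample, while its alignment count varies with the multiplicity and ambiguity
of the selected reads.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import numpy as np
import pysam

__all__ = [
    "AlignmentRecord",
    "ReadAlignmentSet",
    "BootstrapSample",
    "load_alignments",
    "bootstrap_resample",
    "materialize_bootstrap",
]


@dataclass(frozen=True)
class AlignmentRecord:
    """One alignment of one read to one transcript.

    ``weight`` is a compatibility score in (0, 1]; it scales the alignment's
    contribution in the E-step of the quantifier and defaults to 1.
    """

    read_id: str
    transcript_id: str
    weight: float = 1.0

    def __post_init__(self) -> None:
        if not self.weight > 0:
            raise ValueError(
                f"alignment weight must be > 0, got {self.weight!r} "
                f"for read {self.read_id!r}"
            )


class ReadAlignmentSet:
    """All mapped alignments of one sample, grouped by read ID.

    Attributes
    ----------
    alignments
        Mapping ``read_id -> list[AlignmentRecord]``; every read has at
        least one alignment.
    read_ids
        Ordered list of distinct read IDs (insertion order).
    num_reads
        Number of distinct read IDs.
    """

    def __init__(self, alignments: Mapping[str, list[AlignmentRecord]]):
        bad = [r for r, recs in alignments.items() if not recs]
        if bad:
            raise ValueError(f"reads with no alignments: {bad[:5]}")
        self.alignments: dict[str, list[AlignmentRecord]] = dict(alignments)
        self.read_ids: list[str] = list(self.alignments)
        self.num_reads: int = len(self.read_ids)

    def __len__(self) -> int:
        return self.num_reads

    @property
    def num_alignments(self) -> int:
        return sum(len(v) for v in self.alignments.values())

    def iter_records(self) -> Iterator[AlignmentRecord]:
        for rid in self.read_ids:
            yield from self.alignments[rid]

    @classmethod
    def from_records(cls, records: Iterable[AlignmentRecord]) -> "ReadAlignmentSet":
        grouped: dict[str, list[AlignmentRecord]] = {}
        for rec in records:
            grouped.setdefault(rec.read_id, []).append(rec)
        return cls(grouped)


@dataclass
class BootstrapSample:
    """A with-replacement resample of a :class:`ReadAlignmentSet`.

    ``multiplicities`` maps each *selected* read ID to the number of times it
    was drawn; the multiplicities sum to ``source.num_reads``.
    """

    source: ReadAlignmentSet
    multiplicities: dict[str, int]
    index: int = 1

    def __post_init__(self) -> None:
        total = sum(self.multiplicities.values())
        if total != self.source.num_reads:
            raise ValueError(
                f"multiplicities sum to {total}, expected {self.source.num_reads}"
            )
        missing = [r for r in self.multiplicities if r not in self.source.alignments]
        if missing:
            raise ValueError(f"unknown read IDs in bootstrap sample: {missing[:5]}")


def load_alignments(path: str | os.PathLike, id_collapse_policy: str = "fragment") -> ReadAlignmentSet:
    """Read a SAM/BAM file and group mapped alignments by read ID.

    Parameters
    ----------
    path
        SAM or BAM file with transcript-space alignments (reference names
        are transcript IDs).
    id_collapse_policy
        ``"fragment"`` (default): both mates of a paired-end fragment share
        the query name and are treated as one resampling unit.
        ``"mate"``: mates get distinct IDs (``/1``, ``/2`` suffixes).

    Unmapped, secondary and supplementary records are grouped like any other
    mapped alignment except that unmapped records are dropped entirely; a
    read that appears only unmapped is absent from the result.
    """
    if id_collapse_policy not in ("fragment", "mate"):
        raise ValueError(f"unknown id_collapse_policy {id_collapse_policy!r}")
    grouped: dict[str, list[AlignmentRecord]] = {}
    try:
        with pysam.AlignmentFile(os.fspath(path), check_sq=False) as fh:
            for rec in fh:
                if rec.is_unmapped:
                    continue
                rid = rec.query_name
                if id_collapse_policy == "mate" and rec.is_paired:
                    rid = f"{rid}/{2 if rec.is_read2 else 1}"
                grouped.setdefault(rid, []).append(
                    AlignmentRecord(read_id=rid, transcript_id=rec.reference_name)
                )
    except (OSError, ValueError) as exc:
        raise IOError(f"cannot read alignment file {os.fspath(path)!r}: {exc}") from exc
    if not grouped:
        raise ValueError(f"no mapped reads in alignment file {os.fspath(path)!r}")
    return ReadAlignmentSet(grouped)


def bootstrap_resample(sample: ReadAlignmentSet, seed: int) -> BootstrapSample:
    """Draw N read IDs with replacement, uniformly over the read list.

    Deterministic: the same ``(sample, seed)`` yields identical
    multiplicities.
    """
    n = sample.num_reads
    if n < 1:
        raise ValueError("cannot resample an empty alignment set")
    rng = np.random.default_rng(seed)
    draws = rng.integers(0, n, size=n)
    counts = np.bincount(draws, minlength=n)
    mult = {
        sample.read_ids[i]: int(c) for i, c in enumerate(counts) if c > 0
    }
    return BootstrapSample(source=sample, multiplicities=mult)


def materialize_bootstrap(bs: BootstrapSample) -> Iterator[AlignmentRecord]:
    """Emit the alignments of a bootstrap sample, in read-ID order.

    A read selected ``m`` times has its full alignment list emitted ``m``
    times; one linear pass over the source.
    """
    for rid in bs.source.read_ids:
        m = bs.multiplicities.get(rid, 0)
        if m:
            recs = bs.source.alignments[rid]
            for _ in range(m):
                yield from recs
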