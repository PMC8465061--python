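"""Refinement of raw selection-round reads into clean fixed-length cores.

A read passes when (i) its mean Phred quality reaches the threshold, (ii)
both flank anchors are located — leftmost match, each tolerating a small
number of mismatches — in the read or its reverse complement, and (iii) the
segment between the anchors has exactly the expected core length.  Cores are
reported in template orientation.  Deduplication (exact forward-strand string
identity; reverse-complement pairs are deliberately kept, preserving strand
information for palindrome analysis) is a separate, idempotent step.
"""
from __future__ import annotations

import dataclasses
import math
from collections.abc import Iterable, Sequence
from pathlib import Path

from Bio import SeqIO
from Bio.SeqRecord import SeqRecord

from .seqs import revcomp


@dataclasses.dataclass
class RefinedCoreSet:
    """Refined cores plus per-filter accounting.

    ``stats`` keys: n_input, passed, quality_failed, flank_failed,
    length_failed, duplicates_removed, duplicate_fraction.  The failure
    counts plus ``passed`` always sum to ``n_input``.
    """

    cores: list[str]
    stats: dict

    def __len__(self) -> int:
        return len(self.cores)


def _find_anchor(seq: str, anchor: str, max_mm: int, start: int = 0) -> int:
    """0-based leftmost position (>= start) where anchor matches with <= max_mm
    mismatches; -1 if absent."""
    la, ls = len(anchor), len(seq)
    for i in range(start, ls - la + 1):
        mm = 0
        for a, b in zip(anchor, seq[i : i + la]):
            if a != b:
                mm += 1
                if mm > max_mm:
                    break
        else:
            return i
    return -1


def _extract_core(seq: str, left: str, right: str, mm_left: int, mm_right: int) -> str | None:
    """Core between the anchors, or None if either anchor is absent."""
    i = _find_anchor(seq, left, mm_left)
    if i < 0:
        return None
    j = _find_anchor(seq, right, mm_right, start=i + len(left))
    if j < 0:
        return None
    return seq[i + len(left) : j]


def refine_reads(
    reads: Iterable[SeqRecord] | str | Path,
    left_anchor: str,
    right_anchor: str,
    core_length: int = 24,
    min_mean_quality: float = 20.0,
    max_anchor_mismatches: int | None = None,
) -> RefinedCoreSet:
    """Extract randomized cores from FASTQ reads.

    ``reads`` may be SeqRecords (with ``phred_quality`` annotations) or a
    FASTQ path.  ``max_anchor_mismatches`` defaults to one mismatch per ten
    anchor bases (rounded up), applied per anchor.  Malformed records raise a
    hard error naming the record index.
    """
    if not left_anchor or not right_anchor:
        raise ValueError("anchors must be non-empty")
    if core_length < 1:
        raise ValueError("core_length must be >= 1")
    if isinstance(reads, (str, Path)):
        reads = SeqIO.parse(str(reads), "fastq")
    mm_left = (
        max_anchor_mismatches
        if max_anchor_mismatches is not None
        else math.ceil(len(left_anchor) / 10)
    )
    mm_right = (
        max_anchor_mismatches
        if max_anchor_mismatches is not None
        else math.ceil(len(right_anchor) / 10)
    )
    left_anchor = left_anchor.upper()
    right_anchor = right_anchor.upper()

    cores: list[str] = []
    n_input = quality_failed = flank_failed = length_failed = 0
    for idx, rec in enumerate(reads):
        n_input += 1
        try:
            quals = rec.letter_annotations["phred_quality"]
            seq = str(rec.seq).upper()
        except (KeyError, AttributeError) as exc:
            raise ValueError(f"malformed FASTQ record at index {idx}") from exc
        if len(quals) != len(seq) or len(seq) == 0:
            raise ValueError(f"malformed FASTQ record at index {idx}")
        if sum(quals) / len(quals) < min_mean_quality:
            quality_failed += 1
            continue
        core = _extract_core(seq, left_anchor, right_anchor, mm_left, mm_right)
        if core is None:
            core = _extract_core(revcomp(seq), left_anchor, right_anchor, mm_left, mm_right)
        if core is None:
            flank_failed += 1
            continue
        if len(core) != core_length:
            length_failed += 1
            continue
        cores.append(core)
    stats = {
        "n_input": n_input,
        "passed": len(cores),
        "quality_failed": quality_failed,
        "flank_failed": flank_failed,
        "length_failed": length_failed,
        "duplicates_removed": 0,
        "duplicate_fraction": 0.0,
    }
    return RefinedCoreSet(cores=cores, stats=stats)


def deduplicate(cores: Sequence[str] | RefinedCoreSet) -> RefinedCoreSet:
    """Drop later exact string duplicates, keeping first occurrences.

    Reverse-complement pairs are *not* collapsed.  Idempotent.
    """
    if isinstance(cores, RefinedCoreSet):
        base_stats = dict(cores.stats)
        seqs = cores.cores
    else:
        seqs = list(cores)
        base_stats = {
            "n_input": len(seqs),
            "passed": len(seqs),
            "quality_failed": 0,
            "flank_failed": 0,
            "length_failed": 0,
        }
    if len({len(s) for s in seqs}) > 1:
        raise ValueError("mixed core lengths; refine before deduplicating")
    seen: set[str] = set()
    unique: list[str] = []
    for s in seqs:
        if s not in seen:
            seen.add(s)
            unique.append(s)
    removed = len(seqs) - len(unique)
    stats = dict(base_stats)
    stats["duplicates_removed"] = removed
    stats["duplicate_fraction"] = removed / len(seqs) if seqs else 0.0
    return RefinedCoreSet(cores=unique, stats=stats)


def write_cores_fasta(cores: Sequence[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, c in enumerate(cores):
            fh.write(f">core_{i}\n{c}\n")


def read_cores_fasta(path: str | Path) -> list[str]:
    return [str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")]
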