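"""Sequence-verified filtering of oligo-tagged read pairs.

R1 (cell barcode + UMI + TSO + sense insert) is screened for the target's
5' prefix downstream of the fixed read anatomy; R2 (antisense insert) must
carry BOTH the feature barcode and target sequence within a Hamming mismatch
budget.  Surviving mates are reconciled into pairs by read ID.

Matching is substitution-only (Hamming): an ``N`` in the read always counts
as a mismatch, an ``N`` in the pattern matches any base.
"""

from __future__ import annotations

import gzip
import io
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Union

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from spikecap.design import DesignError, GSPDesign, TargetGene, reverse_complement

__all__ = [
    "ReadRecord",
    "ReadPair",
    "MatchHit",
    "FilterConfig",
    "FilterSummary",
    "find_best_match",
    "filter_r1",
    "filter_r2",
    "reconcile_pairs",
    "read_fastq",
    "write_fastq",
    "normalize_read_id",
]

_N_BYTE = ord("N")


def normalize_read_id(title: str) -> str:
    """Strip the comment (first whitespace onward) and a trailing /1 or /2."""
    head = title.split(None, 1)[0]
    if head.endswith(("/1", "/2")):
        head = head[:-2]
    return head


@dataclass(frozen=True)
class ReadRecord:
    """One FASTQ record with normalized ID."""

    read_id: str
    seq: str
    qual: str

    def __post_init__(self) -> None:
        if len(self.seq) != len(self.qual):
            raise ValueError(
                f"{self.read_id}: sequence and quality lengths differ "
                f"({len(self.seq)} vs {len(self.qual)})"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class ReadPair:
    """A reconciled mate pair."""

    read_id: str
    r1: ReadRecord
    r2: ReadRecord


@dataclass(frozen=True)
class MatchHit:
    """Best approximate occurrence of a named pattern in a read."""

    pattern_name: str
    position: int
    mismatches: int
    orientation: str  # "forward" | "reverse-complement"


@dataclass(frozen=True)
class FilterConfig:
    """Knobs for the R1/R2 filters.

    ``r1_insert_offset`` is where the cDNA insert begins on R1 (cell barcode
    + UMI + TSO, 39 for the default anatomy).  ``r1_query_len`` /
    ``r2_query_len`` bound the portion of the target searched in each mate;
    the R2 query is taken 3'-anchored at the anchor-interval end, where the
    antisense insert begins.
    """

    max_mismatch: int = 1
    search_both_orientations: bool = True
    r1_insert_offset: int = 39
    r1_query_len: int = 40
    r2_query_len: int = 40
    min_read_len: int = 0

    def __post_init__(self) -> None:
        if self.max_mismatch < 0:
            raise ValueError("max_mismatch must be >= 0")
        if self.r1_insert_offset < 0:
            raise ValueError("r1_insert_offset must be >= 0")
        if self.r1_query_len < 1 or self.r2_query_len < 1:
            raise ValueError("query lengths must be >= 1")


@dataclass
class FilterSummary:
    """Bookkeeping counters emitted alongside every filter run."""

    reads_in: int = 0
    reads_passed: int = 0
    reads_skipped_short: int = 0

    def as_dict(self) -> dict:
        return {
            "reads_in": self.reads_in,
            "reads_passed": self.reads_passed,
            "reads_skipped_short": self.reads_skipped_short,
        }


def _seq_to_bytes(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def _mismatch_profile(read: np.ndarray, pattern: np.ndarray) -> np.ndarray:
    """Hamming mismatches of ``pattern`` at every offset of ``read``."""
    windows = sliding_window_view(read, len(pattern))
    informative = pattern != _N_BYTE  # pattern N matches anything
    mm = (windows != pattern) | (windows == _N_BYTE)  # read N always mismatches
    return (mm & informative).sum(axis=1)


def find_best_match(
    read_seq: str,
    pattern: str,
    max_mismatch: int,
    both_orientations: bool = False,
    pattern_name: str = "pattern",
) -> Optional[MatchHit]:
    """Best approximate occurrence of ``pattern`` in ``read_seq``, or ``None``.

    Every offset is scored by Hamming distance; the hit with the fewest
    mismatches within ``max_mismatch`` wins, ties broken by smallest offset,
    then forward orientation.  A pattern longer than the read yields ``None``.
    """
    if not pattern:
        raise ValueError("empty pattern")
    if max_mismatch < 0:
        raise ValueError("max_mismatch must be >= 0")
    if len(pattern) > len(read_seq):
        return None

    read = _seq_to_bytes(read_seq)
    candidates: list[tuple[int, int, int, str]] = []  # (mm, pos, orient_rank, orient)
    queries = [("forward", pattern)]
    if both_orientations:
        queries.append(("reverse-complement", reverse_complement(pattern)))
    for rank, (orient, query) in enumerate(queries):
        profile = _mismatch_profile(read, _seq_to_bytes(query))
        best = int(profile.min())
        if best <= max_mismatch:
            pos = int(np.argmin(profile))
            candidates.append((best, pos, rank, orient))
    if not candidates:
        return None
    mm, pos, _, orient = min(candidates)
    return MatchHit(
        pattern_name=pattern_name, position=pos, mismatches=mm, orientation=orient
    )


def filter_r1(
    reads: Iterable[ReadRecord],
    target: TargetGene,
    cfg: FilterConfig,
    summary: Optional[FilterSummary] = None,
) -> Iterator[tuple[ReadRecord, MatchHit]]:
    """Select R1 reads carrying the sense target prefix after the fixed anatomy.

    The query is ``target.sequence[:r1_query_len]`` searched at read positions
    >= ``r1_insert_offset`` (forward strand only — R1 reads the sense insert).
    Too-short reads are skipped and counted, never errors.  Input order is
    preserved.
    """
    query = target.sequence[: cfg.r1_query_len]
    for read in reads:
        if summary is not None:
            summary.reads_in += 1
        if len(read) < cfg.r1_insert_offset + len(query) or len(read) < cfg.min_read_len:
            if summary is not None:
                summary.reads_skipped_short += 1
            continue
        hit = find_best_match(
            read.seq[cfg.r1_insert_offset :],
            query,
            cfg.max_mismatch,
            both_orientations=False,
            pattern_name=target.name,
        )
        if hit is not None:
            hit = MatchHit(
                pattern_name=hit.pattern_name,
                position=hit.position + cfg.r1_insert_offset,
                mismatches=hit.mismatches,
                orientation=hit.orientation,
            )
            if summary is not None:
                summary.reads_passed += 1
            yield read, hit


def r2_target_query(target: TargetGene, design: GSPDesign, query_len: int) -> str:
    """The target window searched in R2: 3'-anchored at the anchor-interval end.

    The antisense insert in R2 begins at the anchor, so the informative target
    sequence is the window immediately upstream of (and including) the anchor.
    """
    if design.anchor_interval is None:
        raise DesignError("design has no anchor_interval; call locate_anchor")
    end = design.anchor_interval[1]
    return target.sequence[max(0, end - query_len) : end]


def filter_r2(
    reads: Iterable[ReadRecord],
    target: TargetGene,
    design: GSPDesign,
    cfg: FilterConfig,
    summary: Optional[FilterSummary] = None,
    require_target: bool = True,
) -> Iterator[tuple[ReadRecord, MatchHit, Optional[MatchHit]]]:
    """Select R2 reads carrying BOTH the feature barcode and the target.

    Both patterns are searched in both orientations (the target is expected
    antisense).  ``require_target=False`` degrades to barcode-only selection —
    the uncorrected counting mode that admits non-specific priming products.
    Emits ``(read, barcode_hit, target_hit)``; ``target_hit`` is ``None`` only
    in barcode-only mode.
    """
    tquery = r2_target_query(target, design, cfg.r2_query_len)
    min_len = max(len(design.feature_barcode), len(tquery) if require_target else 0)
    for read in reads:
        if summary is not None:
            summary.reads_in += 1
        if len(read) < min_len or len(read) < cfg.min_read_len:
            if summary is not None:
                summary.reads_skipped_short += 1
            continue
        bc_hit = find_best_match(
            read.seq,
            design.feature_barcode,
            cfg.max_mismatch,
            both_orientations=cfg.search_both_orientations,
            pattern_name="feature_barcode",
        )
        if bc_hit is None:
            continue
        t_hit: Optional[MatchHit] = None
        if require_target:
            t_hit = find_best_match(
                read.seq,
                tquery,
                cfg.max_mismatch,
                both_orientations=cfg.search_both_orientations,
                pattern_name=target.name,
            )
            if t_hit is None:
                continue
        if summary is not None:
            summary.reads_passed += 1
        yield read, bc_hit, t_hit


def reconcile_pairs(
    r1_pass: Iterable[str],
    r2_pass: Iterable[str],
    r1_source: Iterable[ReadRecord],
    r2_source: Iterable[ReadRecord],
) -> Iterator[ReadPair]:
    """Pair up mates whose IDs passed both filters.

    Emits exactly the intersection of the two pass sets, in R1-source order.
    A duplicate ID within either source is a hard error (ambiguous pairing).
    """
    wanted = set(r1_pass) & set(r2_pass)
    r1_by_id: dict[str, ReadRecord] = {}
    for rec in r1_source:
        if rec.read_id in r1_by_id:
            raise ValueError(f"duplicate read ID in R1 source: {rec.read_id}")
        r1_by_id[rec.read_id] = rec
    seen_r2: dict[str, ReadRecord] = {}
    for rec in r2_source:
        if rec.read_id in seen_r2:
            raise ValueError(f"duplicate read ID in R2 source: {rec.read_id}")
        seen_r2[rec.read_id] = rec
    for read_id, r1 in r1_by_id.items():
        if read_id in wanted and read_id in seen_r2:
            yield ReadPair(read_id=read_id, r1=r1, r2=seen_r2[read_id])


# ---------------------------------------------------------------------------
# FASTQ I/O (gzip-transparent by filename)
# ---------------------------------------------------------------------------

def _open_text(path: Union[str, Path], mode: str) -> io.TextIOBase:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode + "t")  # type: ignore[return-value]
    return open(path, mode)


def read_fastq(path: Union[str, Path]) -> Iterator[ReadRecord]:
    """Stream a FASTQ file as :class:`ReadRecord` with normalized IDs."""
    from Bio.SeqIO.QualityIO import FastqGeneralIterator

    with _open_text(path, "r") as handle:
        for title, seq, qual in FastqGeneralIterator(handle):
            yield ReadRecord(normalize_read_id(title), seq.upper(), qual)


def write_fastq(records: Iterable[ReadRecord], path: Union[str, Path]) -> int:
    """Write records as FASTQ; returns the number written."""
    n = 0
    with _open_text(path, "w") as handle:
        for rec in records:
            handle.write(f"@{rec.read_id}\n{rec.seq}\n+\n{rec.qual}\n")
            n += 1
    return n


def write_summary(path: Union[str, Path], payload: dict) -> None:
    with open(path, "w") as handle:
        json.dump(payload, handle, indent=2, sort_keys=True)
        handle.write("\n")
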