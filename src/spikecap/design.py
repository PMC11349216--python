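"""Spike-in oligo design: target model, GSP segmentation, and template reconstruction.

The gene-specific primer (GSP) is a five-segment oligo::

    adaptor -- spacer1 (N) -- feature_barcode -- spacer2 (N) -- target_anchor

whose 3' anchor is reverse-complementary to a window near the target's 3' end.
From a validated design this module rebuilds every intermediate molecule of the
library construction (first-strand cDNA, amplified cDNA, final library), with
randomized positions carried as literal ``N`` wildcards.

All sequences are stored DNA-sense 5'->3'; RNA input (``U``) is normalized to
``T`` on ingestion.  Coordinates are 0-based, half-open.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

__all__ = [
    "DesignError",
    "TargetGene",
    "GSPDesign",
    "ReadAnatomy",
    "TemplateSet",
    "reverse_complement",
    "parse_gsp",
    "design_gsp",
    "mask_polIII_motifs",
    "build_templates",
]

_DNA_ALPHABET = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class DesignError(ValueError):
    """Raised when an oligo cannot be parsed, designed, or templated."""


def reverse_complement(seq: str) -> str:
    """Reverse-complement a DNA string over {A,C,G,T,N}.

    ``N`` maps to ``N``; the empty string maps to itself.  Raises
    :class:`DesignError` naming the position of the first non-DNA character.
    """
    for i, ch in enumerate(seq):
        if ch not in _DNA_ALPHABET:
            raise DesignError(f"non-DNA character {ch!r} at position {i}")
    return seq.translate(_COMPLEMENT)[::-1]


def _normalize_sequence(seq: str, *, allow_n: bool = False) -> str:
    """Uppercase, U->T, and validate alphabet."""
    out = seq.strip().upper().replace("U", "T")
    allowed = _DNA_ALPHABET if allow_n else frozenset("ACGT")
    for i, ch in enumerate(out):
        if ch not in allowed:
            raise DesignError(f"non-DNA character {ch!r} at position {i}")
    return out


@dataclass(frozen=True)
class TargetGene:
    """A named reference sequence with intervals masked against primer placement.

    Parameters
    ----------
    name
        Identifier for the target (e.g. ``"nc886"``).
    sequence
        Sense-strand sequence, DNA or RNA; normalized to uppercase DNA.
    masked_intervals
        0-based half-open intervals unusable as a primer anchor (terminator
        T-runs, internal promoter boxes).
    """

    name: str
    sequence: str
    masked_intervals: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", _normalize_sequence(self.sequence))
        if not self.sequence:
            raise DesignError("target sequence must be non-empty")
        ivs = tuple((int(a), int(b)) for a, b in self.masked_intervals)
        n = len(self.sequence)
        for a, b in ivs:
            if not (0 <= a <= b <= n):
                raise DesignError(
                    f"masked interval [{a},{b}) outside [0,{n}) for {self.name}"
                )
        object.__setattr__(self, "masked_intervals", ivs)

    def __len__(self) -> int:
        return len(self.sequence)

    def is_masked(self, start: int, end: int) -> bool:
        """True if [start, end) intersects any masked interval."""
        return any(start < b and a < end for a, b in self.masked_intervals)

    def with_mask(self, start: int, end: int) -> "TargetGene":
        """Return a copy with one more masked interval appended."""
        return replace(
            self, masked_intervals=self.masked_intervals + ((start, end),)
        )


@dataclass(frozen=True)
class GSPDesign:
    """The five-segment spike-in oligo.

    ``anchor_interval`` is the 0-based half-open window on the target whose
    reverse complement equals ``target_anchor``; it is ``None`` until the
    design has been located on a target (see :meth:`locate_anchor`).
    """

    adaptor: str
    spacer1_len: int
    feature_barcode: str
    spacer2_len: int
    target_anchor: str
    anchor_interval: Optional[tuple[int, int]] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "adaptor", _normalize_sequence(self.adaptor))
        object.__setattr__(
            self, "feature_barcode", _normalize_sequence(self.feature_barcode)
        )
        object.__setattr__(
            self, "target_anchor", _normalize_sequence(self.target_anchor)
        )
        if self.spacer1_len < 0 or self.spacer2_len < 0:
            raise DesignError("spacer lengths must be non-negative")
        for name in ("adaptor", "feature_barcode", "target_anchor"):
            if not getattr(self, name):
                raise DesignError(f"{name} must be non-empty")

    @property
    def oligo(self) -> str:
        """Full oligo 5'->3' with spacers as literal N's."""
        return (
            self.adaptor
            + "N" * self.spacer1_len
            + self.feature_barcode
            + "N" * self.spacer2_len
            + self.target_anchor
        )

    def locate_anchor(self, target: TargetGene) -> "GSPDesign":
        """Locate the anchor's reverse complement on ``target`` and record it.

        The window must occur exactly once; masked-interval overlap is a
        design error.
        """
        window = reverse_complement(self.target_anchor)
        first = target.sequence.find(window)
        if first < 0:
            raise DesignError(
                f"anchor reverse complement not found in {target.name}"
            )
        if target.sequence.find(window, first + 1) >= 0:
            raise DesignError(
                f"anchor reverse complement ambiguous in {target.name}"
            )
        interval = (first, first + len(window))
        return replace(self, anchor_interval=interval)

    def validate(self, target: TargetGene) -> None:
        """Check the anchor invariants against ``target``."""
        if self.anchor_interval is None:
            raise DesignError("design has no anchor_interval; call locate_anchor")
        a, b = self.anchor_interval
        if target.sequence[a:b] != reverse_complement(self.target_anchor):
            raise DesignError(
                f"anchor does not reverse-complement {target.name}[{a}:{b}]"
            )
        if target.is_masked(a, b):
            raise DesignError(
                f"anchor interval [{a},{b}) overlaps a masked interval"
            )


@dataclass(frozen=True)
class ReadAnatomy:
    """Fixed-length layout of the 5' library read structure.

    Defaults follow the 10x Chromium 5' chemistry: 16-nt cell barcode, 10-nt
    UMI, 13-nt TSO, the Read-1 sequencing adapter, and the flanking P5/P7
    stubs added at library construction.
    """

    cell_barcode_len: int = 16
    umi_len: int = 10
    tso: str = "TTTCTTATATGGG"
    read1_adapter: str = "CTACACGACGCTCTTCCGATCT"
    library_p5_prefix: str = "ACACTCTTTCC"
    library_p7_suffix: str = "AGCCCACGAGAC"

    def __post_init__(self) -> None:
        if self.cell_barcode_len <= 0 or self.umi_len <= 0:
            raise DesignError("cell barcode and UMI lengths must be positive")
        for name in ("tso", "read1_adapter", "library_p5_prefix", "library_p7_suffix"):
            value = getattr(self, name)
            if not value:
                raise DesignError(f"anatomy field {name} must be non-empty")
            object.__setattr__(self, name, _normalize_sequence(value))

    @property
    def r1_insert_offset(self) -> int:
        """Offset of the cDNA insert in R1: CB + UMI + TSO."""
        return self.cell_barcode_len + self.umi_len + len(self.tso)


@dataclass(frozen=True)
class Segment:
    """One named block of a template; ``seq`` may be all-N wildcard filler."""

    name: str
    seq: str

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class TemplateSet:
    """Top-strand templates of each library-construction intermediate.

    Each template is held as an ordered list of named segments so that
    wildcard blocks (cell barcode, UMI, spacers) keep their identities;
    string forms concatenate the segments.  Bottom strands are derived on
    demand via :func:`reverse_complement`.
    """

    first_strand_segments: tuple[Segment, ...]
    amplified_segments: tuple[Segment, ...]
    library_segments: tuple[Segment, ...]

    @staticmethod
    def _join(segments: Sequence[Segment]) -> str:
        return "".join(s.seq for s in segments)

    @property
    def first_strand_cdna(self) -> str:
        return self._join(self.first_strand_segments)

    @property
    def amplified_cdna_top(self) -> str:
        return self._join(self.amplified_segments)

    @property
    def library_top(self) -> str:
        return self._join(self.library_segments)

    def segment_length(self, template: str, name: str) -> int:
        """Width of the named segment in one of the three templates."""
        segments = {
            "first_strand": self.first_strand_segments,
            "amplified": self.amplified_segments,
            "library": self.library_segments,
        }[template]
        for seg in segments:
            if seg.name == name:
                return len(seg)
        raise KeyError(f"no segment {name!r} in {template} template")


def parse_gsp(oligo: str, adaptor: str, feature_barcode: str) -> GSPDesign:
    """Segment a printed oligo by locating the adaptor and barcode literals.

    The adaptor must be the oligo prefix and the feature barcode must occur
    exactly once downstream; the gap between them (all ``N``) is spacer1, the
    ``N``-run after the barcode is spacer2, and the remaining suffix is the
    target anchor.
    """
    oligo = _normalize_sequence(oligo, allow_n=True)
    adaptor = _normalize_sequence(adaptor)
    feature_barcode = _normalize_sequence(feature_barcode)

    def _find_unique(pattern: str, label: str) -> int:
        first = oligo.find(pattern)
        if first < 0:
            raise DesignError(f"{label} not found in oligo")
        if oligo.find(pattern, first + 1) >= 0:
            raise DesignError(f"{label} occurs more than once in oligo")
        return first

    if _find_unique(adaptor, "adaptor") != 0:
        raise DesignError("adaptor is not the oligo prefix")
    bc_start = _find_unique(feature_barcode, "feature barcode")

    spacer1 = oligo[len(adaptor) : bc_start]
    if set(spacer1) - {"N"}:
        raise DesignError("spacer1 region between adaptor and barcode is not all N")

    after_bc = oligo[bc_start + len(feature_barcode) :]
    spacer2_match = re.match("N*", after_bc)
    spacer2_len = spacer2_match.end() if spacer2_match else 0
    anchor = after_bc[spacer2_len:]
    if not anchor:
        raise DesignError("target anchor missing: oligo ends at spacer2")
    if "N" in anchor:
        raise DesignError("target anchor contains N wildcards")

    return GSPDesign(
        adaptor=adaptor,
        spacer1_len=len(spacer1),
        feature_barcode=feature_barcode,
        spacer2_len=spacer2_len,
        target_anchor=anchor,
    )


def mask_polIII_motifs(target: TargetGene, min_t_run: int = 4) -> TargetGene:
    """Mask the 3'-terminal oligo-T terminator run, if long enough.

    Pol III terminators are runs of consecutive T's at the transcript 3' end;
    the maximal terminal run is masked when its length is at least
    ``min_t_run``.  Internal promoter boxes (box A/B) have no fixed
    coordinates and are left to the caller via :meth:`TargetGene.with_mask`.
    """
    if min_t_run < 1:
        raise DesignError("min_t_run must be >= 1")
    seq = target.sequence
    run = 0
    while run < len(seq) and seq[len(seq) - 1 - run] == "T":
        run += 1
    if run >= min_t_run:
        return target.with_mask(len(seq) - run, len(seq))
    return target


def design_gsp(
    target: TargetGene,
    anchor_len: int,
    feature_barcode: str,
    adaptor: str,
    spacer_lens: tuple[int, int] = (10, 9),
) -> GSPDesign:
    """Place the anchor at the 3'-most unmasked window of width ``anchor_len``.

    Raises :class:`DesignError` listing the masked intervals when no legal
    window exists.
    """
    n = len(target.sequence)
    if anchor_len < 1 or anchor_len > n:
        raise DesignError(f"anchor_len {anchor_len} not in [1, {n}]")
    for start in range(n - anchor_len, -1, -1):
        if not target.is_masked(start, start + anchor_len):
            window = target.sequence[start : start + anchor_len]
            return GSPDesign(
                adaptor=adaptor,
                spacer1_len=spacer_lens[0],
                feature_barcode=feature_barcode,
                spacer2_len=spacer_lens[1],
                target_anchor=reverse_complement(window),
                anchor_interval=(start, start + anchor_len),
            )
    raise DesignError(
        f"no unmasked window of width {anchor_len} in {target.name}; "
        f"masked intervals: {list(target.masked_intervals)}"
    )


def build_templates(
    design: GSPDesign,
    target: TargetGene,
    anatomy: ReadAnatomy,
    nontemplated_c: int = 3,
) -> TemplateSet:
    """Reconstruct the library-construction intermediates from a located design.

    first-strand cDNA (the extended GSP):
        full oligo + reverse complement of the target upstream of the anchor
        + non-templated C's appended by the reverse transcriptase.
    amplified cDNA top strand:
        Read-1 adapter, cell-barcode and UMI wildcards, TSO, the sense target
        through the anchor end, then the reverse-complemented oligo payload.
    library top strand:
        the amplified core flanked by the P5/P7 stubs.
    """
    design.validate(target)
    assert design.anchor_interval is not None
    a_start, a_end = design.anchor_interval

    first_strand = (
        Segment("adaptor", design.adaptor),
        Segment("spacer1", "N" * design.spacer1_len),
        Segment("feature_barcode", design.feature_barcode),
        Segment("spacer2", "N" * design.spacer2_len),
        Segment("target_anchor", design.target_anchor),
        Segment("target_extension", reverse_complement(target.sequence[:a_start])),
        Segment("nontemplated_c", "C" * nontemplated_c),
    )
    amplified = (
        Segment("read1_adapter", anatomy.read1_adapter),
        Segment("cell_barcode", "N" * anatomy.cell_barcode_len),
        Segment("umi", "N" * anatomy.umi_len),
        Segment("tso", anatomy.tso),
        Segment("target_sense", target.sequence[:a_end]),
        Segment("spacer2", "N" * design.spacer2_len),
        Segment("feature_barcode_rc", reverse_complement(design.feature_barcode)),
        Segment("spacer1", "N" * design.spacer1_len),
        Segment("adaptor_rc", reverse_complement(design.adaptor)),
    )
    library = (
        (Segment("p5_prefix", anatomy.library_p5_prefix),)
        + amplified
        + (Segment("p7_suffix", anatomy.library_p7_suffix),)
    )
    return TemplateSet(
        first_strand_segments=first_strand,
        amplified_segments=amplified,
        library_segments=library,
    )
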