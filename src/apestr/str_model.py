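"""Repeat-array sequence model for short tandem repeats (STRs).

An STR allele, read out by sequencing rather than by fragment length, is a
stretch of DNA made of tandem runs of short motifs (2-6 bp), possibly broken
by interstitial material, and flanked by locus-specific sequence.  This module
decomposes such a repeat region into maximal motif runs (:class:`RepeatBlock`)
and the material between them (:class:`Interruption`), classifies the
resulting architecture (perfect / interrupted / imperfect / compound and the
hybrid classes), and names alleles at two resolutions:

* the CE-equivalent label — total repeat-region length divided by the length
  of the locus' canonical motif, written in the forensic ``n.p`` convention
  (e.g. ``9.3`` for 9 full repeats plus 3 bases), which is what a length-based
  capillary-electrophoresis assay would report;
* the sequence-level designation — the repeat-region string itself
  (``array_seq``) and the region plus trimmed flanks (``full_seq``), which
  distinguishes same-length isoalleles.

Bracketed notation such as ``[GGAA]3[GGCA]2`` or ``[AGAT]3 GAT [AGAT]2`` is
read and written losslessly.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from enum import Enum
from typing import Iterable, Sequence

__all__ = [
    "Motif",
    "RepeatBlock",
    "Interruption",
    "StructuralClass",
    "AlleleStructure",
    "AlleleDesignation",
    "decompose_repeat_region",
    "classify_structure",
    "is_repeat_derived",
    "structure_from_region",
    "structure_from_extracted",
    "ce_label_from_length",
    "ce_designation",
    "format_bracketed",
    "parse_bracketed",
    "structure_to_record",
]

_DNA = frozenset("ACGT")


def _check_dna(seq: str, what: str = "sequence") -> None:
    for i, ch in enumerate(seq):
        if ch not in _DNA:
            raise ValueError(f"non-ACGT character {ch!r} in {what} at position {i}")


@dataclass(frozen=True, order=True)
class Motif:
    """A repeat unit in its locus-canonical phase.

    Cyclic rotations are *not* normalized: ``AGAT`` and ``GATA`` are distinct
    motifs, because each locus reports its repeats in a fixed phase.
    """

    sequence: str

    def __post_init__(self) -> None:
        _check_dna(self.sequence, "motif")
        if not 2 <= len(self.sequence) <= 6:
            raise ValueError(f"motif must be 2-6 bases, got {self.sequence!r}")

    @property
    def length(self) -> int:
        return len(self.sequence)

    def __str__(self) -> str:
        return self.sequence


def _as_motifs(motif_set: Iterable[Motif | str]) -> tuple[Motif, ...]:
    out = []
    for m in motif_set:
        out.append(m if isinstance(m, Motif) else Motif(m))
    return tuple(out)


@dataclass(frozen=True)
class RepeatBlock:
    """``count`` tandem copies of ``motif`` starting at 0-based ``start``."""

    motif: Motif
    count: int
    start: int

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError("block count must be >= 1")

    @property
    def span(self) -> int:
        return self.count * self.motif.length

    @property
    def end(self) -> int:
        return self.start + self.span

    @property
    def sequence(self) -> str:
        return self.motif.sequence * self.count


@dataclass(frozen=True)
class Interruption:
    """Material between repeat blocks.

    ``derived`` is true when the segment looks like damaged or partial repeat
    (within Hamming distance 1 of a locus motif, or a one-base-short partial
    copy of one in any phase), and false for unrelated insertions.
    """

    sequence: str
    start: int
    derived: bool

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError("interruption must be >= 1 base")

    @property
    def end(self) -> int:
        return self.start + len(self.sequence)


class StructuralClass(str, Enum):
    PERFECT = "perfect"
    INTERRUPTED = "interrupted"
    IMPERFECT = "imperfect"
    COMPOUND = "compound"
    COMPOUND_INTERRUPTED = "compound_interrupted"
    IMPERFECT_COMPOUND = "imperfect_compound"
    UNCLASSIFIED = "unclassified"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


def is_repeat_derived(seq: str, motif_set: Iterable[Motif | str]) -> bool:
    """Is ``seq`` repeat-derived material with respect to ``motif_set``?

    True when ``seq`` is within Hamming distance 1 of some motif (same
    length), or is a contiguous ``L-1``-base fragment of a motif of length
    ``L`` in any phase (i.e. a substring of the doubled motif).  ``GACA`` and
    ``GAT`` are derived relative to {GATA}; ``NNNNN``-style unrelated
    insertions are not.
    """
    for m in _as_motifs(motif_set):
        ms = m.sequence
        if len(seq) == m.length:
            if sum(a != b for a, b in zip(seq, ms)) <= 1:
                return True
        elif len(seq) == m.length - 1 and seq in ms + ms:
            return True
    return False


def decompose_repeat_region(
    region: str,
    motif_set: Sequence[Motif | str],
    min_run: int = 2,
) -> tuple[list[RepeatBlock], list[Interruption]]:
    """Decompose ``region`` into maximal motif runs and interruptions.

    Deterministic greedy scan, left to right: at each position the motif
    producing the longest run (in bases) is preferred, ties broken by motif
    order in ``motif_set``; runs shorter than ``min_run`` copies are treated
    as interstitial material.  Adjacent unexplained bases are merged into a
    single :class:`Interruption`.  Concatenating blocks and interruptions in
    order reconstructs ``region`` exactly.
    """
    motifs = _as_motifs(motif_set)
    if not motifs:
        raise ValueError("motif_set must be non-empty")
    if min_run < 2:
        raise ValueError("min_run must be >= 2")
    if not region:
        raise ValueError("region must be non-empty")
    _check_dna(region, "region")

    n = len(region)
    blocks: list[RepeatBlock] = []
    gaps: list[tuple[int, int]] = []  # (start, end) of unexplained stretches
    gap_start: int | None = None
    i = 0
    while i < n:
        best: tuple[int, int, Motif, int] | None = None  # (-bases, order, motif, count)
        for order, m in enumerate(motifs):
            L = m.length
            c = 0
            while region.startswith(m.sequence, i + c * L):
                c += 1
            if c >= min_run:
                bases = c * L
                if best is None or bases > -best[0]:
                    best = (-bases, order, m, c)
        if best is not None:
            if gap_start is not None:
                gaps.append((gap_start, i))
                gap_start = None
            _, _, m, c = best
            blocks.append(RepeatBlock(m, c, i))
            i += c * m.length
        else:
            if gap_start is None:
                gap_start = i
            i += 1
    if gap_start is not None:
        gaps.append((gap_start, n))

    interruptions = [
        Interruption(region[a:b], a, is_repeat_derived(region[a:b], motifs))
        for a, b in gaps
    ]
    return blocks, interruptions


def classify_structure(
    blocks: Sequence[RepeatBlock],
    interruptions: Sequence[Interruption],
) -> StructuralClass:
    """Assign the structural class of a decomposed repeat region.

    One motif with no interruptions is *perfect*; interruptions make it
    *interrupted* (non-repeat material) or *imperfect* (repeat-derived
    material, which takes precedence).  Two or more distinct equal-length
    motifs give the *compound* counterparts.  Blocks whose motifs differ in
    length, or a region with no blocks at all, are *unclassified*.
    """
    if not blocks:
        return StructuralClass.UNCLASSIFIED
    motif_seqs = {b.motif.sequence for b in blocks}
    motif_lens = {b.motif.length for b in blocks}
    if len(motif_lens) > 1:
        return StructuralClass.UNCLASSIFIED
    any_derived = any(x.derived for x in interruptions)
    if len(motif_seqs) == 1:
        if not interruptions:
            return StructuralClass.PERFECT
        return StructuralClass.IMPERFECT if any_derived else StructuralClass.INTERRUPTED
    if not interruptions:
        return StructuralClass.COMPOUND
    return (
        StructuralClass.IMPERFECT_COMPOUND
        if any_derived
        else StructuralClass.COMPOUND_INTERRUPTED
    )


@dataclass(frozen=True)
class AlleleStructure:
    """A decomposed repeat region plus its trimmed flanking sequence."""

    region: str
    blocks: tuple[RepeatBlock, ...]
    interruptions: tuple[Interruption, ...]
    flank5: str = ""
    flank3: str = ""
    structural_class: StructuralClass = StructuralClass.UNCLASSIFIED

    def __post_init__(self) -> None:
        parts = sorted(
            [(b.start, b.sequence) for b in self.blocks]
            + [(x.start, x.sequence) for x in self.interruptions]
        )
        rebuilt = "".join(s for _, s in parts)
        if rebuilt != self.region:
            raise ValueError(
                "blocks + interruptions do not reconstruct the region "
                f"({rebuilt!r} != {self.region!r})"
            )

    @property
    def full_sequence(self) -> str:
        return self.flank5 + self.region + self.flank3


def structure_from_region(
    region: str,
    motif_set: Sequence[Motif | str],
    min_run: int = 2,
    flank5: str = "",
    flank3: str = "",
) -> AlleleStructure:
    """Decompose and classify ``region`` (flanks passed through verbatim)."""
    blocks, interruptions = decompose_repeat_region(region, motif_set, min_run)
    return AlleleStructure(
        region=region,
        blocks=tuple(blocks),
        interruptions=tuple(interruptions),
        flank5=flank5,
        flank3=flank3,
        structural_class=classify_structure(blocks, interruptions),
    )


def structure_from_extracted(
    extracted: str,
    motif_set: Sequence[Motif | str],
    min_run: int = 2,
) -> AlleleStructure:
    """Build a structure from an anchor-to-flank extracted sequence.

    The extracted string normally carries a few non-repeat bases on either
    side of the array.  The repeat region proper runs from the start of the
    first block to the end of the last; the leading and trailing remainders
    become ``flank5`` / ``flank3``.  If no block is found the whole string is
    kept as an unclassified region with empty flanks.
    """
    blocks, interruptions = decompose_repeat_region(extracted, motif_set, min_run)
    if not blocks:
        return AlleleStructure(
            region=extracted,
            blocks=(),
            interruptions=tuple(interruptions),
            structural_class=StructuralClass.UNCLASSIFIED,
        )
    lo, hi = blocks[0].start, blocks[-1].end
    inner_blocks = tuple(replace(b, start=b.start - lo) for b in blocks)
    inner_irq = tuple(
        replace(x, start=x.start - lo)
        for x in interruptions
        if x.start >= lo and x.end <= hi
    )
    return AlleleStructure(
        region=extracted[lo:hi],
        blocks=inner_blocks,
        interruptions=inner_irq,
        flank5=extracted[:lo],
        flank3=extracted[hi:],
        structural_class=classify_structure(inner_blocks, inner_irq),
    )


def ce_label_from_length(region_len: int, motif_len: int) -> str:
    """CE-equivalent label in the forensic ``n.p`` convention.

    ``region_len // motif_len`` full repeats; a non-zero remainder ``p`` is
    appended as ``.p`` (so 39 bases of a 4-base motif is ``9.3``).
    """
    n, p = divmod(region_len, motif_len)
    return str(n) if p == 0 else f"{n}.{p}"


@dataclass(frozen=True)
class AlleleDesignation:
    """An allele named at all three resolution layers.

    ``ce_label`` is what length-based genotyping would see; ``array_seq``
    additionally resolves same-length repeat-array variants; ``full_seq``
    additionally resolves flanking-sequence variants.
    """

    ce_label: str
    array_seq: str
    full_seq: str


def ce_designation(structure: AlleleStructure, canonical: Motif | str) -> AlleleDesignation:
    canonical = canonical if isinstance(canonical, Motif) else Motif(canonical)
    return AlleleDesignation(
        ce_label=ce_label_from_length(len(structure.region), canonical.length),
        array_seq=structure.region,
        full_seq=structure.full_sequence,
    )


def format_bracketed(structure: AlleleStructure) -> str:
    """Render the region as bracketed notation, e.g. ``[AGAT]3 GAT [AGAT]2``."""
    parts = sorted(
        [(b.start, f"[{b.motif.sequence}]{b.count}") for b in structure.blocks]
        + [(x.start, x.sequence) for x in structure.interruptions]
    )
    return " ".join(s for _, s in parts)


_BRACKET_RE = re.compile(r"\[([ACGT]+)\](\d+)")
_LITERAL_RE = re.compile(r"[ACGT]+")


def parse_bracketed(
    text: str,
    motif_set: Sequence[Motif | str],
) -> AlleleStructure:
    """Parse bracketed notation back into an :class:`AlleleStructure`.

    Whitespace between terms is optional.  Malformed syntax is rejected with
    the 0-based offset of the offending character.  ``motif_set`` is used
    only to set interruption ``derived`` flags and never restricts which
    motifs may appear inside brackets.
    """
    motifs = _as_motifs(motif_set)
    pos = 0
    offset = 0  # position within the reconstructed region
    blocks: list[RepeatBlock] = []
    gaps: list[tuple[str, int]] = []
    region_parts: list[str] = []
    while pos < len(text):
        if text[pos].isspace():
            pos += 1
            continue
        if text[pos] == "[":
            m = _BRACKET_RE.match(text, pos)
            if m is None:
                raise ValueError(f"malformed bracket term at offset {pos}")
            motif, count = Motif(m.group(1)), int(m.group(2))
            if count < 1:
                raise ValueError(f"repeat count must be >= 1 at offset {pos}")
            blocks.append(RepeatBlock(motif, count, offset))
            seq = motif.sequence * count
        else:
            m = _LITERAL_RE.match(text, pos)
            if m is None:
                raise ValueError(f"unexpected character {text[pos]!r} at offset {pos}")
            seq = m.group(0)
            gaps.append((seq, offset))
        region_parts.append(seq)
        offset += len(seq)
        pos = m.end()
    # merge adjacent literal segments (can arise from "GA T" style input)
    merged: list[tuple[str, int]] = []
    for seq, start in gaps:
        if merged and merged[-1][1] + len(merged[-1][0]) == start:
            merged[-1] = (merged[-1][0] + seq, merged[-1][1])
        else:
            merged.append((seq, start))
    interruptions = tuple(
        Interruption(seq, start, is_repeat_derived(seq, motifs)) for seq, start in merged
    )
    region = "".join(region_parts)
    if not region:
        raise ValueError("empty bracketed structure")
    blocks_t = tuple(blocks)
    return AlleleStructure(
        region=region,
        blocks=blocks_t,
        interruptions=interruptions,
        structural_class=classify_structure(blocks_t, interruptions),
    )


def structure_to_record(
    structure: AlleleStructure, canonical: Motif | str | None = None
) -> dict:
    """JSON-serializable record of a structure (and its CE label if asked)."""
    rec = {
        "region": structure.region,
        "blocks": [
            {"motif": b.motif.sequence, "count": b.count, "start": b.start}
            for b in structure.blocks
        ],
        "interruptions": [
            {"sequence": x.sequence, "start": x.start, "derived": x.derived}
            for x in structure.interruptions
        ],
        "class": structure.structural_class.value,
    }
    if canonical is not None:
        canonical = canonical if isinstance(canonical, Motif) else Motif(canonical)
        rec["ce_label"] = ce_label_from_length(len(structure.region), canonical.length)
    return rec
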