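"""From sequencing reads to per-locus genotype calls.

The caller mirrors an anchor-based workflow for amplicon STR sequencing of
short single-end reads: each read is searched for a locus-specific 5' anchor
placed just upstream of the repeat array and for a 3' flanking sequence
downstream of it; the bases strictly between are the extracted allele
sequence.  Extracted sequences are tallied per locus by exact identity and a
genotype is called when the locus reaches ``min_depth`` reads (>= 20 by
default).

Null alleles — alleles that fail to amplify because of a variant under a
primer — make a heterozygote look homozygous.  The two cases are separated by
read depth normalized against known heterozygote calls from the same sample:
a true homozygote carries two amplifying copies, so its depth should be about
twice the per-allele depth of a heterozygote.  A single-allele locus is
called homozygous only when its depth reaches ``tau`` times the reference
per-allele heterozygote depth (``tau = 1.5``, the midpoint between the 1x
and 2x expectations); otherwise it is flagged as a heterozygote with a null.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .str_model import (
    AlleleDesignation,
    Motif,
    ce_designation,
    structure_from_extracted,
)

__all__ = [
    "LocusDefinition",
    "ExtractStatus",
    "AlleleTally",
    "CallStatus",
    "GenotypeCall",
    "read_qc",
    "extract_repeat_region",
    "assign_read",
    "tally_alleles",
    "tally_dataset",
    "call_genotype",
    "call_sample",
    "call_dataset",
    "amplification_matrix",
]


@dataclass(frozen=True)
class LocusDefinition:
    """Anchors, flanks and motif inventory driving extraction and naming."""

    name: str
    anchor5: str
    flank3: str
    motifs: tuple[Motif, ...]
    canonical: Motif
    region_range: tuple[int, int]

    def __post_init__(self) -> None:
        if not self.anchor5 or not self.flank3:
            raise ValueError(f"{self.name}: anchor5 and flank3 must be non-empty")
        if self.canonical not in self.motifs:
            raise ValueError(f"{self.name}: canonical motif not in motif set")
        lo, hi = self.region_range
        if lo < 0 or hi < lo:
            raise ValueError(f"{self.name}: invalid region_range {self.region_range}")


# ---------------------------------------------------------------------------
# read QC


def read_qc(
    reads: Iterable[tuple[str, str, str]],
    min_len: int = 50,
    qual_window: int = 4,
    qual_mean: float = 20.0,
    adapter: str | None = None,
) -> list[tuple[str, str, str]]:
    """Sliding-window quality trimming of phred-33 reads.

    ``reads`` are ``(id, sequence, quality_string)`` triples.  An optional
    adapter is stripped when it is an exact prefix of the read.  The read is
    truncated at the start of the first ``qual_window``-wide window whose
    mean quality falls below ``qual_mean``; reads shorter than ``min_len``
    after trimming are dropped.
    """
    out = []
    for rid, seq, qual in reads:
        if len(seq) != len(qual):
            raise ValueError(f"read {rid!r}: sequence/quality length mismatch")
        if adapter and seq.startswith(adapter):
            seq = seq[len(adapter):]
            qual = qual[len(adapter):]
        phred = [ord(c) - 33 for c in qual]
        cut = len(seq)
        for i in range(0, len(seq) - qual_window + 1):
            if sum(phred[i : i + qual_window]) / qual_window < qual_mean:
                cut = i
                break
        if cut >= min_len:
            out.append((rid, seq[:cut], qual[:cut]))
    return out


# ---------------------------------------------------------------------------
# anchored extraction


class ExtractStatus(Enum):
    OK = "ok"
    NO_ANCHOR = "no_anchor"
    NO_FLANK = "no_flank"
    AMBIGUOUS = "ambiguous"
    OUT_OF_RANGE = "out_of_range"


def _find_approx(hay: str, needle: str, max_mm: int, start: int = 0) -> list[int]:
    """Positions of best substitution-only matches (no indels).

    Returns the list of positions achieving the minimum mismatch count, if
    that minimum is <= ``max_mm``; otherwise an empty list.  Exact hits are
    located with ``str.find`` first; the mismatch scan only runs when none
    exist.
    """
    exact = []
    p = hay.find(needle, start)
    while p != -1:
        exact.append(p)
        p = hay.find(needle, p + 1)
    if exact:
        return exact
    if max_mm == 0 or len(hay) - start < len(needle):
        return []
    a = np.frombuffer(hay[start:].encode(), dtype=np.uint8)
    k = np.frombuffer(needle.encode(), dtype=np.uint8)
    mm = (sliding_window_view(a, len(k)) != k).sum(axis=1)
    best = int(mm.min())
    if best > max_mm:
        return []
    return [start + int(i) for i in np.flatnonzero(mm == best)]


def extract_repeat_region(
    read: str,
    locus: LocusDefinition,
    max_mismatch: int = 1,
) -> tuple[ExtractStatus, str | None]:
    """Extract the allele sequence between anchor5 and flank3.

    Both landmarks are located by substitution-only matching with up to
    ``max_mismatch`` mismatches, best hit leftmost; multiple equally good
    hits are ambiguous and rejected.  The extracted sequence must fall inside
    the locus' expected length range.
    """
    hits = _find_approx(read, locus.anchor5, max_mismatch)
    if not hits:
        return ExtractStatus.NO_ANCHOR, None
    if len(hits) > 1:
        return ExtractStatus.AMBIGUOUS, None
    a_end = hits[0] + len(locus.anchor5)
    fhits = _find_approx(read, locus.flank3, max_mismatch, start=a_end)
    if not fhits:
        return ExtractStatus.NO_FLANK, None
    if len(fhits) > 1:
        return ExtractStatus.AMBIGUOUS, None
    region = read[a_end : fhits[0]]
    lo, hi = locus.region_range
    if not lo <= len(region) <= hi:
        return ExtractStatus.OUT_OF_RANGE, None
    return ExtractStatus.OK, region


def assign_read(
    read: str,
    loci: Sequence[LocusDefinition],
    max_mismatch: int = 1,
) -> tuple[str, str | None, str | None]:
    """Assign a read to a locus and extract its allele sequence.

    Loci whose anchor occurs exactly in the read are tried first; only when
    none does is the mismatch-tolerant scan run across all loci.  Returns
    ``(outcome, locus_name, region)`` where outcome is ``"ok"``,
    ``"ambiguous"`` (extraction succeeded at more than one locus, or an
    in-locus ambiguity) or ``"unassigned"``.
    """
    candidates = [l for l in loci if read.find(l.anchor5) != -1]
    if not candidates:
        candidates = list(loci)
    hits = []
    saw_ambiguous = False
    for locus in candidates:
        status, region = extract_repeat_region(read, locus, max_mismatch)
        if status is ExtractStatus.OK:
            hits.append((locus.name, region))
            if len(hits) > 1:
                return "ambiguous", None, None
        elif status is ExtractStatus.AMBIGUOUS:
            saw_ambiguous = True
    if len(hits) == 1:
        return "ok", hits[0][0], hits[0][1]
    return ("ambiguous" if saw_ambiguous else "unassigned"), None, None


# ---------------------------------------------------------------------------
# tallies


@dataclass
class AlleleTally:
    """Exact-sequence read-depth tally for one sample x locus."""

    counts: dict[str, int] = field(default_factory=dict)
    n_unassigned: int = 0
    n_ambiguous: int = 0
    stutter_merged: dict[str, str] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def add(self, seq: str, depth: int = 1) -> None:
        self.counts[seq] = self.counts.get(seq, 0) + depth


def tally_alleles(
    reads: Iterable[str],
    locus: LocusDefinition,
    max_mismatch: int = 1,
    stutter_fold: bool = False,
    stutter_ratio: float = 0.15,
) -> AlleleTally:
    """Group extracted sequences of one locus' reads by exact identity.

    With ``stutter_fold`` on, a sequence exactly one canonical-motif copy
    shorter than a sequence holding at least ``1/stutter_ratio`` times its
    depth is folded into the longer one and recorded in ``stutter_merged``.
    Folding is off by default: calling tolerates stutter through the
    heterozygote balance threshold instead.
    """
    tally = AlleleTally()
    for read in reads:
        status, region = extract_repeat_region(read, locus, max_mismatch)
        if status is ExtractStatus.OK:
            tally.add(region)
        elif status is ExtractStatus.AMBIGUOUS:
            tally.n_ambiguous += 1
        else:
            tally.n_unassigned += 1
    if stutter_fold:
        _fold_stutter(tally, locus.canonical.length, stutter_ratio)
    return tally


def _fold_stutter(tally: AlleleTally, motif_len: int, stutter_ratio: float) -> None:
    ordered = sorted(tally.counts, key=lambda s: (tally.counts[s], s))
    for seq in ordered:
        if seq not in tally.counts:
            continue
        depth = tally.counts[seq]
        parents = [
            t
            for t in tally.counts
            if len(t) == len(seq) + motif_len and depth < stutter_ratio * tally.counts[t]
        ]
        if parents:
            target = max(parents, key=lambda t: (tally.counts[t], t))
            tally.counts[target] += depth
            del tally.counts[seq]
            tally.stutter_merged[seq] = target


def tally_dataset(
    reads_by_sample: Mapping[str, Iterable[str]],
    loci: Sequence[LocusDefinition],
    max_mismatch: int = 1,
) -> tuple[dict[str, dict[str, AlleleTally]], dict[str, dict[str, int]]]:
    """Assign every read of every sample and build per-locus tallies.

    Returns the tallies plus a per-sample accounting of unassigned and
    ambiguous reads, so assigned + unassigned + ambiguous always equals the
    input read count.
    """
    out: dict[str, dict[str, AlleleTally]] = {}
    accounting: dict[str, dict[str, int]] = {}
    for sample in sorted(reads_by_sample):
        tallies = {l.name: AlleleTally() for l in loci}
        acct = {"assigned": 0, "unassigned": 0, "ambiguous": 0}
        for read in reads_by_sample[sample]:
            outcome, name, region = assign_read(read, loci, max_mismatch)
            if outcome == "ok":
                tallies[name].add(region)
                acct["assigned"] += 1
            else:
                acct[outcome] += 1
        out[sample] = tallies
        accounting[sample] = acct
    return out, accounting


# ---------------------------------------------------------------------------
# genotype calling


class CallStatus(str, Enum):
    GENOTYPED_HET = "genotyped_het"
    GENOTYPED_HOM = "genotyped_hom"
    HET_WITH_NULL = "het_with_null"
    LOW_DEPTH = "low_depth"
    FAILED = "failed"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


GENOTYPED = (CallStatus.GENOTYPED_HET, CallStatus.GENOTYPED_HOM)


@dataclass(frozen=True)
class GenotypeCall:
    sample: str
    locus: str
    alleles: tuple[AlleleDesignation, ...]  # 0-2 distinct alleles
    depths: tuple[int, ...]
    status: CallStatus


def call_genotype(
    counts: Mapping[str, int],
    min_depth: int = 20,
    het_balance: float = 0.3,
    ref_het_depth: float | None = None,
    tau: float = 1.5,
) -> tuple[list[str], list[int], CallStatus]:
    """Call a genotype from an exact-sequence depth tally.

    An empty tally is ``failed``; total depth below ``min_depth`` (applied
    per locus) is ``low_depth``.  The top two sequences form a heterozygote
    when minor/major depth >= ``het_balance``; otherwise a single allele
    survives and is homozygous only when its depth reaches
    ``tau * ref_het_depth``, else a heterozygote with a null allele.
    """
    if not counts:
        return [], [], CallStatus.FAILED
    total = sum(counts.values())
    if total < min_depth:
        return [], [], CallStatus.LOW_DEPTH
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    if len(ranked) >= 2 and ranked[1][1] / ranked[0][1] >= het_balance:
        (a1, d1), (a2, d2) = ranked[0], ranked[1]
        return [a1, a2], [d1, d2], CallStatus.GENOTYPED_HET
    a, d = ranked[0]
    if ref_het_depth is None:
        raise ValueError("ref_het_depth required to resolve single-allele loci")
    if d >= tau * ref_het_depth:
        return [a], [d], CallStatus.GENOTYPED_HOM
    return [a], [d], CallStatus.HET_WITH_NULL


def _designate(seq: str, locus: LocusDefinition, min_run: int = 2) -> AlleleDesignation:
    structure = structure_from_extracted(seq, locus.motifs, min_run)
    return ce_designation(structure, locus.canonical)


def _provisional_het_depths(
    tallies: Mapping[str, AlleleTally],
    min_depth: int,
    het_balance: float,
) -> list[int]:
    """Per-allele depths of unambiguous heterozygote calls (first pass)."""
    depths = []
    for name in sorted(tallies):
        counts = tallies[name].counts
        if not counts or sum(counts.values()) < min_depth:
            continue
        ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        if len(ranked) >= 2 and ranked[1][1] / ranked[0][1] >= het_balance:
            depths.extend([ranked[0][1], ranked[1][1]])
    return depths


def call_sample(
    tallies: Mapping[str, AlleleTally],
    loci: Mapping[str, LocusDefinition],
    sample: str,
    min_depth: int = 20,
    het_balance: float = 0.3,
    tau: float = 1.5,
    run_ref_het_depth: float | None = None,
) -> list[GenotypeCall]:
    """Two-pass calling for one sample.

    Pass one collects the per-allele depths of unambiguous heterozygote calls
    and takes their median as the sample's reference heterozygote depth (the
    run-level median is the fallback when the sample has none); pass two
    resolves every locus, including the homozygote-versus-null decision.
    """
    het_depths = _provisional_het_depths(tallies, min_depth, het_balance)
    if het_depths:
        ref = float(statistics.median(het_depths))
    elif run_ref_het_depth is not None:
        ref = float(run_ref_het_depth)
    else:
        raise ValueError(f"sample {sample}: no heterozygote calls and no run fallback")
    calls = []
    for name in sorted(loci):
        seqs, depths, status = call_genotype(
            tallies[name].counts if name in tallies else {},
            min_depth=min_depth,
            het_balance=het_balance,
            ref_het_depth=ref,
            tau=tau,
        )
        designations = tuple(_designate(s, loci[name]) for s in seqs)
        calls.append(GenotypeCall(sample, name, designations, tuple(depths), status))
    return calls


def call_dataset(
    reads_by_sample: Mapping[str, Iterable[str]],
    loci: Sequence[LocusDefinition],
    min_depth: int = 20,
    het_balance: float = 0.3,
    tau: float = 1.5,
    max_mismatch: int = 1,
) -> list[GenotypeCall]:
    """Full pipeline: assign reads, tally, and call every sample x locus."""
    tallies, _ = tally_dataset(reads_by_sample, loci, max_mismatch)
    locus_map = {l.name: l for l in loci}
    # run-level fallback reference from all samples' unambiguous hets
    all_het: list[int] = []
    for sample in tallies:
        all_het.extend(_provisional_het_depths(tallies[sample], min_depth, het_balance))
    run_ref = float(statistics.median(all_het)) if all_het else None
    calls: list[GenotypeCall] = []
    for sample in sorted(tallies):
        calls.extend(
            call_sample(
                tallies[sample],
                locus_map,
                sample,
                min_depth=min_depth,
                het_balance=het_balance,
                tau=tau,
                run_ref_het_depth=run_ref,
            )
        )
    return calls


# ---------------------------------------------------------------------------
# amplification summary


@dataclass
class AmplificationSummary:
    """Locus x sample status matrix plus the three-way locus grouping."""

    status: "object"  # pandas.DataFrame, loci x samples
    locus_groups: dict[str, str]  # locus -> core | partial | failed_or_restricted
    n_core: int


def amplification_matrix(
    calls: Iterable[GenotypeCall],
    group_of: Mapping[str, str],
) -> AmplificationSummary:
    """Summarize amplification behaviour across the panel.

    A locus is *core* when fully genotyped (het or hom) in every sample,
    *failed_or_restricted* when it failed in every member of at least one
    (sub)species group (which takes precedence — a locus dead in one species
    is species-restricted regardless of its behaviour elsewhere), and
    *partial* otherwise (individual dropouts, null evidence, or low depth).
    """
    import pandas as pd

    calls = list(calls)
    samples = sorted({c.sample for c in calls})
    loci = sorted({c.locus for c in calls})
    unknown = [s for s in samples if s not in group_of]
    if unknown:
        raise ValueError(f"samples missing from group table: {unknown}")
    status = pd.DataFrame("failed", index=loci, columns=samples, dtype=object)
    for c in calls:
        status.loc[c.locus, c.sample] = c.status.value
    members: dict[str, list[str]] = {}
    for s in samples:
        members.setdefault(group_of[s], []).append(s)
    groups: dict[str, str] = {}
    for locus in loci:
        row = status.loc[locus]
        if any(
            all(row[s] == CallStatus.FAILED.value for s in mem)
            for mem in members.values()
        ):
            groups[locus] = "failed_or_restricted"
        elif all(row[s] in (x.value for x in GENOTYPED) for s in samples):
            groups[locus] = "core"
        else:
            groups[locus] = "partial"
    n_core = sum(1 for g in groups.values() if g == "core")
    return AmplificationSummary(status=status, locus_groups=groups, n_core=n_core)
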