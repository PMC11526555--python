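"""Synthetic populations, genotypes and reads for pipeline validation.

The generator emulates the statistical structure of a cross-species STR
amplicon-sequencing study so that every pipeline stage can be exercised and
validated without any real data:

* five (sub)species groups with unequal sample sizes (defaults 14 / 4 / 16 /
  6 / 12, chimpanzee, bonobo and three gorilla taxa by shape);
* a 27-locus autosomal STR panel whose alleles are structured sequences
  (variable repeat blocks plus fixed flanking margins), with per-group allele
  frequency spectra that diverge hierarchically (genus level > subspecies
  level) and carry group-informative same-length isoalleles in both the
  repeat array and the flanks;
* Hardy–Weinberg genotypes with optional within-group inbreeding ``F``
  (``P(hom_i) = p_i^2 + p_i (1 - p_i) F``);
* null alleles from primer-site variants: each allele copy is silenced
  independently with a per-locus, per-group probability; probability 1 in a
  group reproduces species-restricted amplification failure;
* per-allele read depth with smooth multiplicative overdispersion — depth is
  ``round(m * G)`` with ``G ~ Gamma(1/d, d)`` (the gamma mixing component of
  a Poisson-Gamma negative binomial), so ``dispersion -> 0`` recovers exact
  mean depths; a per-sample amplification factor adds realistic inter-sample
  scatter that the caller's per-sample normalization must absorb;
* stutter reads missing one canonical-motif copy (the dominant n-1 mode) and
  uniform per-base substitution error, with constant Q30 qualities.

A ``SimTruth`` ledger records, per sample x locus, the true alleles, null
flags, emitted read counts and the status the caller is expected to report,
so recovery can be measured exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .allele_caller import CallStatus, LocusDefinition
from .str_model import Motif

__all__ = [
    "ReadModel",
    "LocusSim",
    "PopulationConfig",
    "SimTruthRecord",
    "default_panel",
    "simulate_population",
    "inject_null_alleles",
    "simulate_reads",
    "expected_status",
]

GROUPS = (("Ptr", 14), ("Ppa", 4), ("Ggg", 16), ("Gbg", 6), ("Gbb", 12))
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class ReadModel:
    """Read-emission parameters.

    ``mean_depth`` is the expected read count per locus (each allele copy
    emits half); ``dispersion`` is the squared coefficient of variation of
    the multiplicative depth noise (0 = deterministic depths);
    ``sample_depth_cv`` scales whole samples up or down, mimicking input DNA
    quality differences.
    """

    mean_depth: float = 100.0
    dispersion: float = 0.01
    stutter_rate: float = 0.08
    error_rate: float = 0.002
    sample_depth_cv: float = 0.15

    def __post_init__(self) -> None:
        if self.mean_depth <= 0 or self.dispersion < 0:
            raise ValueError("mean_depth must be > 0 and dispersion >= 0")
        for r in (self.stutter_rate, self.error_rate):
            if not 0 <= r <= 1:
                raise ValueError("rates must be in [0, 1]")


@dataclass
class LocusSim:
    """One locus: its definition, allele catalogue and per-group spectra."""

    definition: LocusDefinition
    freqs: dict[str, dict[str, float]]  # group -> insert sequence -> frequency
    null_freq: dict[str, float]  # group -> per-allele-copy silencing probability

    def __post_init__(self) -> None:
        for group, f in self.freqs.items():
            if abs(sum(f.values()) - 1.0) > 1e-9:
                raise ValueError(
                    f"{self.definition.name}/{group}: frequencies must sum to 1"
                )
        for group, q in self.null_freq.items():
            if not 0 <= q <= 1:
                raise ValueError("null frequencies must be in [0, 1]")


@dataclass
class PopulationConfig:
    groups: tuple[tuple[str, int], ...]
    loci: list[LocusSim]
    inbreeding: dict[str, float]
    read_model: ReadModel
    seed: int


@dataclass
class SimTruthRecord:
    sample: str
    locus: str
    alleles: tuple[str, str]  # insert sequences (between anchor and flank)
    nulls: tuple[bool, bool]
    read_counts: tuple[int, int] = (0, 0)
    stutter_reads: int = 0
    error_reads: int = 0

    @property
    def n_null(self) -> int:
        return int(self.nulls[0]) + int(self.nulls[1])


def expected_status(rec: SimTruthRecord) -> CallStatus:
    """The call status a perfect caller should report for this cell."""
    if rec.n_null == 2:
        return CallStatus.FAILED
    if rec.n_null == 1:
        return CallStatus.HET_WITH_NULL
    return (
        CallStatus.GENOTYPED_HOM
        if rec.alleles[0] == rec.alleles[1]
        else CallStatus.GENOTYPED_HET
    )


# ---------------------------------------------------------------------------
# default study-shaped panel


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return bytes(_BASES[rng.integers(0, 4, n)]).decode()


def _substitute(seq: str, pos: int) -> str:
    swap = {"A": "C", "C": "A", "G": "T", "T": "G"}
    return seq[:pos] + swap[seq[pos]] + seq[pos + 1 :]


_MOTIF_POOL = [
    ("AATG",),
    ("AGAT",),
    ("GATA",),
    ("TCTA", "TCTG"),
    ("AGAA",),
    ("GGAA", "GGCA"),
    ("TAGA",),
    ("ATCT",),
    ("AGAT", "AGAC"),
    ("TCTA",),
    ("GAAA",),
    ("CTTT",),
]

# species-restricted / failed amplification plan for the non-core loci
_NULL_PLAN: dict[int, dict[str, float]] = {
    # STR14-18: sporadic primer-site nulls in every group
    **{i: {g: 0.05 for g, _ in GROUPS} for i in range(13, 18)},
    18: {"Ppa": 1.0},  # fails in bonobo only
    19: {"Ptr": 1.0, "Ppa": 1.0},  # amplifies only in gorillas
    20: {"Ptr": 1.0},
    21: {"Ggg": 1.0, "Gbg": 1.0, "Gbb": 1.0},  # Pan-only locus
    22: {"Gbb": 1.0},
    23: {"Gbg": 1.0},
    24: {"Ppa": 1.0, "Gbg": 1.0},
    25: {g: 1.0 for g, _ in GROUPS},  # dead in every group
    26: {g: 1.0 for g, _ in GROUPS},
}


def default_panel(
    seed: int,
    groups: tuple[tuple[str, int], ...] = GROUPS,
    n_loci: int = 27,
    read_model: ReadModel | None = None,
) -> PopulationConfig:
    """Build the default study-shaped panel.

    27 loci; the first 13 are a synthetic "core" free of null alleles, five
    show sporadic nulls in all groups, seven fail wholesale in particular
    groups and two fail everywhere — mirroring the three-way amplification
    grouping of a cross-species panel.  Allele catalogues hold ~5 length
    classes per locus, each with up to three isoalleles (canonical array, an
    array-internal substitution, a flanking substitution); isoform preference
    differs by group so sequence-level typing is more informative than
    length-level typing, while length spectra diverge hierarchically
    (Pan vs Gorilla more than subspecies within a genus).
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 421]))
    group_names = [g for g, _ in groups]
    loci: list[LocusSim] = []
    for idx in range(n_loci):
        name = f"STR{idx + 1:02d}"
        motifs = tuple(Motif(m) for m in _MOTIF_POOL[idx % len(_MOTIF_POOL)])
        canonical = motifs[0]
        L = canonical.length
        anchor5 = _random_dna(rng, 20)
        flank3 = _random_dna(rng, 20)
        m5 = _random_dna(rng, 6)
        m3 = _random_dna(rng, 6)

        # allele catalogue: ~5 length classes x up to 3 isoforms
        c0 = int(rng.integers(7, 11))
        lengths = list(range(c0, c0 + 5))
        catalogue: dict[int, list[str]] = {}
        for c in lengths:
            if len(motifs) >= 2:
                split = max(2, c // 2)
                array = motifs[0].sequence * split + motifs[1].sequence * (c - split)
            else:
                array = canonical.sequence * c
            iso0 = m5 + array + m3
            iso1 = m5 + _substitute(array, (len(array) // 2) // L * L + 1) + m3
            iso2 = _substitute(m5, 2) + array + m3
            catalogue[c] = [iso0, iso1, iso2]

        # hierarchical length-class divergence: genus then group
        root = rng.dirichlet(np.full(len(lengths), 2.0))
        genus_w = {
            "Pan": root * rng.gamma(8.0, 1 / 8.0, len(lengths)),
            "Gorilla": root * rng.gamma(8.0, 1 / 8.0, len(lengths)),
        }
        iso_prefs = [
            np.array(p)
            for p in ([0.7, 0.2, 0.1], [0.2, 0.7, 0.1], [0.1, 0.2, 0.7],
                      [0.45, 0.45, 0.1], [0.1, 0.45, 0.45])
        ]
        freqs: dict[str, dict[str, float]] = {}
        for gi, group in enumerate(group_names):
            genus = "Pan" if group.startswith("P") else "Gorilla"
            w = genus_w[genus] * rng.gamma(12.0, 1 / 12.0, len(lengths))
            w = w / w.sum()
            pref = iso_prefs[gi % len(iso_prefs)]
            table: dict[str, float] = {}
            for c, wc in zip(lengths, w):
                for iso, seq in enumerate(catalogue[c]):
                    p = float(wc * pref[iso])
                    if p >= 0.01:
                        table[seq] = table.get(seq, 0.0) + p
            if len(table) < 2:  # keep every locus polymorphic in every group
                c_lo, c_hi = lengths[0], lengths[-1]
                table = {catalogue[c_lo][0]: 0.5, catalogue[c_hi][0]: 0.5}
            total = sum(table.values())
            freqs[group] = {s: p / total for s, p in sorted(table.items())}

        max_len = max(len(s) for c in catalogue.values() for s in c)
        min_len = min(len(s) for c in catalogue.values() for s in c)
        definition = LocusDefinition(
            name=name,
            anchor5=anchor5,
            flank3=flank3,
            motifs=motifs,
            canonical=canonical,
            region_range=(max(0, min_len - L - 4), max_len + L + 4),
        )
        null = {g: 0.0 for g in group_names}
        null.update(_NULL_PLAN.get(idx, {}))
        loci.append(LocusSim(definition=definition, freqs=freqs, null_freq=null))
    return PopulationConfig(
        groups=tuple(groups),
        loci=loci,
        inbreeding={g: (0.1 if g == "Gbb" else 0.0) for g in group_names},
        read_model=read_model or ReadModel(),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# genotypes


def simulate_population(
    config: PopulationConfig, rng: np.random.Generator | None = None
) -> dict[tuple[str, str], SimTruthRecord]:
    """Draw genotypes for every sample x locus under HWE with inbreeding F.

    With probability ``F`` the two allele copies are identical by descent
    (one draw, duplicated), otherwise both are drawn independently — which
    realizes ``P(hom_i) = p_i^2 + p_i(1 - p_i)F`` and
    ``P(het_ij) = 2 p_i p_j (1 - F)``.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    truth: dict[tuple[str, str], SimTruthRecord] = {}
    for group, n in config.groups:
        f_coef = config.inbreeding.get(group, 0.0)
        for i in range(n):
            sample = f"{group}_{i + 1:02d}"
            for locus in config.loci:
                table = locus.freqs[group]
                seqs = list(table)
                p = np.array([table[s] for s in seqs])
                if rng.random() < f_coef:
                    a = b = seqs[rng.choice(len(seqs), p=p)]
                else:
                    a = seqs[rng.choice(len(seqs), p=p)]
                    b = seqs[rng.choice(len(seqs), p=p)]
                truth[(sample, locus.definition.name)] = SimTruthRecord(
                    sample=sample,
                    locus=locus.definition.name,
                    alleles=(a, b),
                    nulls=(False, False),
                )
    return truth


def inject_null_alleles(
    truth: Mapping[tuple[str, str], SimTruthRecord],
    config: PopulationConfig,
    rng: np.random.Generator | None = None,
) -> dict[tuple[str, str], SimTruthRecord]:
    """Silence allele copies independently with the per-locus, per-group rate."""
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    null_of = {l.definition.name: l.null_freq for l in config.loci}
    group_of_sample = lambda s: s.rsplit("_", 1)[0]
    out = {}
    for key in sorted(truth):
        rec = truth[key]
        q = null_of[rec.locus].get(group_of_sample(rec.sample), 0.0)
        nulls = (bool(rng.random() < q), bool(rng.random() < q))
        out[key] = SimTruthRecord(
            sample=rec.sample, locus=rec.locus, alleles=rec.alleles, nulls=nulls
        )
    return out


# ---------------------------------------------------------------------------
# reads


def _stutter(insert: str, canonical: Motif) -> str | None:
    """Remove one canonical-motif copy from the first tandem run, if any."""
    doubled = canonical.sequence * 2
    pos = insert.find(doubled)
    if pos == -1:
        return None
    return insert[:pos] + insert[pos + canonical.length :]


def _depth(rng: np.random.Generator, mean: float, dispersion: float) -> int:
    if dispersion == 0:
        return int(round(mean))
    g = rng.gamma(1.0 / dispersion, dispersion)
    return int(round(mean * g))


def simulate_reads(
    truth: Mapping[tuple[str, str], SimTruthRecord],
    config: PopulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, list[tuple[str, str]]], dict[tuple[str, str], SimTruthRecord]]:
    """Emit single-end reads (anchor + insert + flank) for every allele copy.

    Returns ``reads_by_sample`` (lists of ``(read_id, sequence)``) and the
    truth ledger updated with realized read counts.  Null allele copies emit
    nothing.  Reads carry constant Q30 qualities when written to FASTQ.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    model = config.read_model
    defs = {l.definition.name: l.definition for l in config.loci}
    samples = sorted({s for s, _ in truth})
    cv2 = model.sample_depth_cv**2
    sample_factor = {
        s: (float(rng.gamma(1.0 / cv2, cv2)) if cv2 > 0 else 1.0) for s in samples
    }
    reads_by_sample: dict[str, list[tuple[str, str]]] = {s: [] for s in samples}
    updated: dict[tuple[str, str], SimTruthRecord] = {}
    for key in sorted(truth):
        rec = truth[key]
        locus = defs[rec.locus]
        counts = [0, 0]
        n_stutter = 0
        n_error = 0
        per_copy_mean = model.mean_depth / 2.0 * sample_factor[rec.sample]
        for copy in (0, 1):
            if rec.nulls[copy]:
                continue
            depth = _depth(rng, per_copy_mean, model.dispersion)
            counts[copy] = depth
            insert = rec.alleles[copy]
            stutter_insert = _stutter(insert, locus.canonical)
            for j in range(depth):
                seq_insert = insert
                if stutter_insert is not None and rng.random() < model.stutter_rate:
                    seq_insert = stutter_insert
                    n_stutter += 1
                read = locus.anchor5 + seq_insert + locus.flank3
                k = rng.binomial(len(read), model.error_rate)
                if k > 0:
                    n_error += 1
                    arr = bytearray(read.encode())
                    for pos in rng.choice(len(arr), size=k, replace=False):
                        arr[pos] = int(
                            _BASES[(int(np.searchsorted(_BASES, arr[pos])) + int(rng.integers(1, 4))) % 4]
                        )
                    read = arr.decode()
                rid = f"{rec.sample}:{rec.locus}:{copy}:{j}"
                reads_by_sample[rec.sample].append((rid, read))
        updated[key] = SimTruthRecord(
            sample=rec.sample,
            locus=rec.locus,
            alleles=rec.alleles,
            nulls=rec.nulls,
            read_counts=(counts[0], counts[1]),
            stutter_reads=n_stutter,
            error_reads=n_error,
        )
    return reads_by_sample, updated
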