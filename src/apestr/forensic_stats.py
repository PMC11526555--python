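"""Per-locus and combined forensic / population-genetic statistics.

Statistics follow the standard forensic definitions as used by STRAF-style
tools.  With allele frequencies :math:`p_i` and ``n`` sampled chromosomes:

* observed heterozygosity ``Hobs`` — fraction of heterozygous genotypes;
* unbiased expected heterozygosity (Nei)
  :math:`H_{exp} = \\frac{n}{n-1}\\,(1 - \\sum_i p_i^2)`;
* polymorphism information content
  :math:`PIC = 1 - \\sum_i p_i^2 - \\sum_{i<j} 2 p_i^2 p_j^2`;
* match probability :math:`PM = \\sum_g f_g^2` over observed genotype
  frequencies (not HWE expectations), and power of discrimination
  :math:`PD = 1 - PM`;
* power of exclusion :math:`PE = h^2 (1 - 2 h H^2)` and typical paternity
  index :math:`TPI = 1/(2H)` with :math:`h = H_{obs}`, :math:`H = 1 - h`;
* inbreeding coefficient :math:`F_{is} = 1 - H_{obs}/H_{exp}` by default,
  with a Weir–Cockerham-style variant available;
* an exact-style permutation test of Hardy–Weinberg equilibrium on the
  statistic :math:`|H_{obs} - H_{exp}|`;
* the combined random match probability, the product of per-locus PM over
  unlinked loci (computed in log space).

Alleles are counted at three nested resolutions — CE-equivalent length,
repeat-array sequence, and array plus flanking sequence — so the increment of
allelic diversity contributed by sequence-level typing can be reported.

Genotypes flagged as heterozygote-with-null or low-depth carry incomplete
information (a single observed allele is not a genotype) and are excluded
from all statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Hashable, Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "FrequencyTable",
    "LocusStats",
    "allele_frequencies",
    "heterozygosity",
    "hwe_permutation_test",
    "fis",
    "pic",
    "match_probability",
    "pe_tpi",
    "combined_rmp",
    "diversity_increments",
    "bonferroni",
    "locus_stats",
]

Pair = tuple[Hashable, Hashable]


@dataclass(frozen=True)
class FrequencyTable:
    """Allele relative frequencies at one locus, over ``n_chrom`` chromosomes."""

    freqs: dict
    n_chrom: int

    def __post_init__(self) -> None:
        if self.n_chrom > 0 and abs(sum(self.freqs.values()) - 1.0) > 1e-9:
            raise ValueError("frequencies must sum to 1")

    def get(self, allele, default=0.0):
        return self.freqs.get(allele, default)


def allele_frequencies(genotypes: Iterable[Pair]) -> FrequencyTable:
    """Counting-based allele frequencies; both alleles of each genotype count."""
    counts: dict = {}
    n = 0
    for a, b in genotypes:
        counts[a] = counts.get(a, 0) + 1
        counts[b] = counts.get(b, 0) + 1
        n += 2
    if n == 0:
        raise ValueError("no usable genotypes")
    return FrequencyTable({k: c / n for k, c in counts.items()}, n)


def heterozygosity(
    genotypes: Sequence[Pair], unbiased: bool = True
) -> tuple[float, float | None]:
    """(Hobs, Hexp); Hexp is Nei-unbiased and None when n_chrom < 4."""
    genotypes = list(genotypes)
    if not genotypes:
        raise ValueError("no usable genotypes")
    hobs = sum(1 for a, b in genotypes if a != b) / len(genotypes)
    ft = allele_frequencies(genotypes)
    raw = 1.0 - sum(p * p for p in ft.freqs.values())
    if not unbiased:
        return hobs, raw
    if ft.n_chrom < 4:
        return hobs, None
    return hobs, ft.n_chrom / (ft.n_chrom - 1) * raw


def hwe_permutation_test(
    genotypes: Sequence[Pair],
    n_perm: int = 2000,
    seed: int | np.random.Generator = 0,
) -> float:
    """Permutation test of Hardy–Weinberg equilibrium.

    The observed statistic is ``|Hobs - Hexp|``; the null distribution is
    built by shuffling the ``2n`` allele copies into random pairs.  The
    p-value is ``(1 + #{perm >= obs}) / (n_perm + 1)``.  A monomorphic locus
    returns 1 by convention.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    genotypes = list(genotypes)
    alleles = [x for g in genotypes for x in g]
    if len(set(alleles)) < 2:
        return 1.0
    hobs, hexp = heterozygosity(genotypes)
    if hexp is None:
        return 1.0
    obs = abs(hobs - hexp)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    # integer-code alleles for fast vectorized pairing
    uniq = {a: i for i, a in enumerate(sorted(set(alleles), key=repr))}
    arr = np.array([uniq[a] for a in alleles], dtype=np.int32)
    perm = rng.permuted(np.tile(arr, (n_perm, 1)), axis=1)
    pairs = perm.reshape(n_perm, -1, 2)
    hobs_perm = (pairs[:, :, 0] != pairs[:, :, 1]).mean(axis=1)
    # Hexp is invariant under permutation of the allele copies
    stat_perm = np.abs(hobs_perm - hexp)
    return float((1 + int((stat_perm >= obs - 1e-12).sum())) / (n_perm + 1))


def fis(genotypes: Sequence[Pair], method: str = "nei") -> float | None:
    """Inbreeding coefficient for a single population.

    ``nei`` (default): :math:`1 - H_{obs}/H_{exp}` with unbiased Hexp.
    ``wc``: Weir–Cockerham-style estimator built from per-allele variance
    components, :math:`\\hat f = 1 - \\bar c / (\\bar b + \\bar c)` with
    ``c = h/2`` and ``b = \\frac{n}{n-1}[p(1-p) - h\\,(2n-1)/(4n)]`` where
    ``h`` is the observed heterozygote frequency involving the allele and
    ``n`` the number of genotypes.  Returns None when Hexp is 0 or undefined.
    """
    genotypes = list(genotypes)
    if method == "nei":
        hobs, hexp = heterozygosity(genotypes)
        if hexp is None or hexp == 0:
            return None
        return 1.0 - hobs / hexp
    if method == "wc":
        n = len(genotypes)
        if n < 2:
            return None
        ft = allele_frequencies(genotypes)
        b_sum = c_sum = 0.0
        for allele, p in ft.freqs.items():
            h = sum(1 for g in genotypes if (allele in g) and g[0] != g[1]) / n
            b_sum += n / (n - 1) * (p * (1 - p) - h * (2 * n - 1) / (4 * n))
            c_sum += h / 2
        if b_sum + c_sum == 0:
            return None
        return 1.0 - c_sum / (b_sum + c_sum)
    raise ValueError(f"unknown Fis method {method!r}")


def pic(freqs: FrequencyTable | Mapping | Sequence[float]) -> float:
    """Polymorphism information content of a frequency vector."""
    if isinstance(freqs, FrequencyTable):
        p = np.array(list(freqs.freqs.values()))
    elif isinstance(freqs, Mapping):
        p = np.array(list(freqs.values()))
    else:
        p = np.asarray(freqs, dtype=float)
    s2 = float((p**2).sum())
    s4 = float((p**4).sum())
    return 1.0 - s2 - (s2 * s2 - s4)


def match_probability(genotypes: Sequence[Pair]) -> tuple[float, float]:
    """(PM, PD) from observed genotype frequencies.

    PM is the probability that two individuals drawn at random (with
    replacement) from the cohort share an unordered genotype.
    """
    genotypes = [tuple(sorted(g, key=repr)) for g in genotypes]
    if not genotypes:
        raise ValueError("no usable genotypes")
    n = len(genotypes)
    counts: dict = {}
    for g in genotypes:
        counts[g] = counts.get(g, 0) + 1
    pm = sum((c / n) ** 2 for c in counts.values())
    return pm, 1.0 - pm


def pe_tpi(hobs: float) -> tuple[float, float | None]:
    """Power of exclusion and typical paternity index from Hobs."""
    if not 0 <= hobs <= 1:
        raise ValueError("Hobs must be in [0, 1]")
    h, bigh = hobs, 1.0 - hobs
    pe = h * h * (1.0 - 2.0 * h * bigh * bigh)
    tpi = None if bigh == 0 else 1.0 / (2.0 * bigh)
    return pe, tpi


def combined_rmp(per_locus_pm: Sequence[float]) -> float:
    """Product of per-locus match probabilities over unlinked loci."""
    if len(per_locus_pm) == 0:
        raise ValueError("need at least one per-locus PM")
    if any(not 0 <= x <= 1 for x in per_locus_pm):
        raise ValueError("PM values must be in [0, 1]")
    if any(x == 0 for x in per_locus_pm):
        return 0.0
    return math.exp(sum(math.log(x) for x in per_locus_pm))


def diversity_increments(
    alleles: Iterable[tuple[Hashable, Hashable, Hashable]],
) -> tuple[int, int, int]:
    """Distinct allele counts at the three nested resolution layers.

    Each item is ``(ce_label, array_seq, full_seq)`` for one distinct allele
    observation.  Returns ``(N_length, N_array, N_full)``; the sequence-layer
    increments are ``N_array - N_length`` (variation inside the array) and
    ``N_full - N_array`` (variation in the flanks).
    """
    ce, arr, full = set(), set(), set()
    for c, a, f in alleles:
        ce.add(c)
        arr.add((c, a))
        full.add((c, a, f))
    return len(ce), len(arr), len(full)


def bonferroni(p_values: Sequence[float], alpha: float = 0.05, m: int | None = None) -> list[bool]:
    """Family-wise significance flags: flag iff ``p < alpha / m``."""
    if m is None:
        m = len(p_values)
    if m < 1:
        raise ValueError("family size must be >= 1")
    return [p < alpha / m for p in p_values]


@dataclass
class LocusStats:
    """The STRAF-style per-locus summary at one resolution layer."""

    locus: str
    n: int
    n_alleles: int
    hobs: float
    hexp: float | None
    pic: float
    pm: float
    pd: float
    pe: float
    tpi: float | None
    fis: float | None
    hwe_p: float
    counts_by_layer: tuple[int, int, int]  # (N_length, N_array, N_full)


def locus_stats(
    locus: str,
    genotypes: Sequence[Pair],
    layer_alleles: Iterable[tuple[Hashable, Hashable, Hashable]],
    n_perm: int = 2000,
    seed: int | np.random.Generator = 0,
) -> LocusStats:
    """All per-locus statistics from fully genotyped calls at one layer."""
    genotypes = list(genotypes)
    ft = allele_frequencies(genotypes)
    hobs, hexp = heterozygosity(genotypes)
    pm, pd_ = match_probability(genotypes)
    pe, tpi = pe_tpi(hobs)
    return LocusStats(
        locus=locus,
        n=len(genotypes),
        n_alleles=len(ft.freqs),
        hobs=hobs,
        hexp=hexp,
        pic=pic(ft),
        pm=pm,
        pd=pd_,
        pe=pe,
        tpi=tpi,
        fis=fis(genotypes),
        hwe_p=hwe_permutation_test(genotypes, n_perm=n_perm, seed=seed),
        counts_by_layer=diversity_increments(layer_alleles),
    )
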