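"""Relatedness screening, relative pruning and (sub)species assignment.

Relatedness between two multilocus genotypes is scored by maximum likelihood
over relationship categories defined by their IBD-sharing coefficients
``k = (k0, k1, k2)``: unrelated U(1,0,0), half-sib HS(1/2,1/2,0), full-sib
FS(1/4,1/2,1/4) and parent-offspring PO(0,1,0).  Per locus,

    P(g1, g2 | k) = k0 P(g1)P(g2) + k1 P1(g1,g2) + k2 P(g1) [g1 = g2],

where ``P1`` is the probability of the pair given one allele shared IBD (one
allele of g1 picked uniformly is copied into g2, the other drawn from the
population frequencies) and genotype probabilities assume HWE.  No
genotyping-error term is modelled.  Log-likelihoods sum over loci and the
best-supported category wins.

Pruning removes the fewest samples (greedy highest-degree-first on the graph
of forbidden pairs) so that no retained pair is of a forbidden category.

Assignment scores one individual's multilocus genotype against each group's
allele-frequency table under HWE, by default leaving the individual's own
alleles out of its source group's frequencies.  This is a desk-scale
likelihood surrogate for admixture/discriminant clustering and works at any
resolution layer, which is what lets sequence-level and length-level typing
be compared on equal footing.

Alleles unseen in a frequency table are smoothed to ``eps = 1/(2 n_chrom + 1)``
so no likelihood is ever exactly zero for that reason.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Hashable, Iterable, Mapping, Sequence

from .forensic_stats import FrequencyTable, allele_frequencies

__all__ = [
    "IBD_CATEGORIES",
    "AssignmentResult",
    "genotype_log_prob",
    "pair_likelihood",
    "relatedness_pair",
    "relatedness_screen",
    "prune_relatives",
    "assign_individual",
    "assignment_loo",
]

Pair = tuple[Hashable, Hashable]

#: IBD-sharing coefficients (k0, k1, k2) per relationship category.
IBD_CATEGORIES: dict[str, tuple[float, float, float]] = {
    "U": (1.0, 0.0, 0.0),
    "HS": (0.5, 0.5, 0.0),
    "FS": (0.25, 0.5, 0.25),
    "PO": (0.0, 1.0, 0.0),
}


def _eps(ft: FrequencyTable) -> float:
    return 1.0 / (2 * ft.n_chrom + 1)


def _freq(ft: FrequencyTable, allele) -> float:
    return ft.freqs.get(allele, _eps(ft))


def _genotype_prob(g: Pair, ft: FrequencyTable) -> float:
    a, b = g
    pa, pb = _freq(ft, a), _freq(ft, b)
    return pa * pa if a == b else 2.0 * pa * pb


def genotype_log_prob(g: Pair, ft: FrequencyTable) -> float:
    return math.log(_genotype_prob(g, ft))


def _transition_prob(g1: Pair, g2: Pair, ft: FrequencyTable) -> float:
    """P(g2 | g1, one allele shared IBD): copy one allele of g1 uniformly,
    draw the other allele of g2 from the population."""
    c, d = g2
    total = 0.0
    for x in g1:
        if c == d:
            p = _freq(ft, c) if x == c else 0.0
        elif x == c:
            p = _freq(ft, d)
        elif x == d:
            p = _freq(ft, c)
        else:
            p = 0.0
        total += 0.5 * p
    return total


def pair_likelihood(
    g1: Pair, g2: Pair, ft: FrequencyTable, k: tuple[float, float, float]
) -> float:
    """Single-locus likelihood of an unordered genotype pair given k."""
    k0, k1, k2 = k
    p = 0.0
    if k0:
        p += k0 * _genotype_prob(g1, ft) * _genotype_prob(g2, ft)
    if k1:
        p += k1 * _genotype_prob(g1, ft) * _transition_prob(g1, g2, ft)
    if k2 and tuple(sorted(g1, key=repr)) == tuple(sorted(g2, key=repr)):
        p += k2 * _genotype_prob(g1, ft)
    return p


def relatedness_pair(
    g1: Mapping[str, Pair],
    g2: Mapping[str, Pair],
    freqs: Mapping[str, FrequencyTable],
    categories: Mapping[str, tuple[float, float, float]] | None = None,
    min_shared_loci: int = 5,
) -> tuple[str, dict[str, float]]:
    """Best-supported relationship category and per-category log-likelihood.

    ``g1`` / ``g2`` map locus name to an allele pair; only loci genotyped in
    both individuals and present in ``freqs`` contribute.
    """
    if categories is None:
        categories = IBD_CATEGORIES
    shared = sorted(set(g1) & set(g2) & set(freqs))
    if len(shared) < min_shared_loci:
        raise ValueError(f"only {len(shared)} shared loci; need >= {min_shared_loci}")
    logl = {}
    for name, k in categories.items():
        total = 0.0
        for locus in shared:
            p = pair_likelihood(g1[locus], g2[locus], freqs[locus], k)
            total += math.log(p) if p > 0 else -math.inf
        logl[name] = total
    best = max(sorted(logl), key=lambda c: logl[c])
    return best, logl


def relatedness_screen(
    genotypes: Mapping[str, Mapping[str, Pair]],
    group_of: Mapping[str, str],
    categories: Mapping[str, tuple[float, float, float]] | None = None,
    min_shared_loci: int = 5,
) -> list[dict]:
    """All within-group pairs, scored with leave-pair-out frequencies.

    For each pair, the group's allele frequencies are recomputed from every
    other member so neither individual informs its own test.
    """
    rows = []
    groups: dict[str, list[str]] = {}
    for s in sorted(genotypes):
        groups.setdefault(group_of[s], []).append(s)
    for group in sorted(groups):
        members = groups[group]
        for s1, s2 in itertools.combinations(members, 2):
            others = [s for s in members if s not in (s1, s2)]
            pool = others if others else [s1, s2]  # degenerate 2-member group
            loci = sorted(set(genotypes[s1]) & set(genotypes[s2]))
            freqs = {}
            for locus in loci:
                pairs = [genotypes[s][locus] for s in pool if locus in genotypes[s]]
                if pairs:
                    freqs[locus] = allele_frequencies(pairs)
            best, logl = relatedness_pair(
                genotypes[s1], genotypes[s2], freqs, categories, min_shared_loci
            )
            rows.append(
                {
                    "sample1": s1,
                    "sample2": s2,
                    "group": group,
                    "best": best,
                    **{f"logL_{c}": logl[c] for c in logl},
                }
            )
    return rows


def prune_relatives(
    pair_categories: Iterable[tuple[str, str, str]],
    samples: Iterable[str],
    forbidden: Sequence[str] = ("PO", "FS", "HS"),
) -> list[str]:
    """Retain the samples left after greedily breaking all forbidden pairs.

    ``pair_categories`` yields ``(sample1, sample2, category)``.  The sample
    of highest forbidden-pair degree is removed first (ties broken by sample
    id, lowest first), until no forbidden pair remains.  Whitelisting a
    category (e.g. tolerating half-sibs in a highly inbred group) is done by
    leaving it out of ``forbidden``.
    """
    keep = set(samples)
    edges = {
        frozenset((a, b))
        for a, b, cat in pair_categories
        if cat in forbidden and a != b
    }
    edges = {e for e in edges if e <= keep}
    while edges:
        degree: dict[str, int] = {}
        for e in edges:
            for s in e:
                degree[s] = degree.get(s, 0) + 1
        victim = min(degree, key=lambda s: (-degree[s], s))
        keep.discard(victim)
        edges = {e for e in edges if victim not in e}
    return sorted(keep)


@dataclass
class AssignmentResult:
    sample: str
    log_likelihoods: dict[str, float]
    best_group: str
    margin: float  # log-likelihood gap to the runner-up (>= 0)


def assign_individual(
    sample: str,
    genotype: Mapping[str, Pair],
    tables: Mapping[str, Mapping[str, FrequencyTable]],
    min_loci: int = 5,
) -> AssignmentResult:
    """Score a multilocus genotype against each group's frequency tables.

    Only loci present in *every* group's table (and in the genotype)
    contribute, so the per-group log-likelihoods sum over the same loci and
    are directly comparable; otherwise a group with a restricted usable
    panel would win by accumulating fewer negative terms.
    """
    shared = sorted(
        set(genotype).intersection(*(set(tables[g]) for g in tables))
    )
    if len(genotype) < min_loci:
        raise ValueError(f"{sample}: fewer than {min_loci} genotyped loci")
    if not shared:
        raise ValueError(f"{sample}: no locus is usable in every group")
    logl = {
        group: sum(genotype_log_prob(genotype[l], tables[group][l]) for l in shared)
        for group in sorted(tables)
    }
    ranked = sorted(logl, key=lambda g: (-logl[g], g))
    best = ranked[0]
    margin = logl[best] - logl[ranked[1]] if len(ranked) > 1 else math.inf
    return AssignmentResult(sample, logl, best, margin)


def assignment_loo(
    genotypes: Mapping[str, Mapping[str, Pair]],
    group_of: Mapping[str, str],
    min_loci: int = 5,
) -> list[AssignmentResult]:
    """Leave-one-out self-assignment for every individual.

    Each individual is scored against all groups, with its own two allele
    copies removed from its source group's frequency estimates first.
    """
    members: dict[str, list[str]] = {}
    for s in sorted(genotypes):
        members.setdefault(group_of[s], []).append(s)

    def table_for(group: str, exclude: str | None) -> dict[str, FrequencyTable]:
        pool = [s for s in members[group] if s != exclude]
        loci = sorted({l for s in pool for l in genotypes[s]})
        out = {}
        for locus in loci:
            pairs = [genotypes[s][locus] for s in pool if locus in genotypes[s]]
            if pairs:
                out[locus] = allele_frequencies(pairs)
        return out

    results = []
    base = {g: table_for(g, None) for g in members}
    for sample in sorted(genotypes):
        own = group_of[sample]
        tables = dict(base)
        tables[own] = table_for(own, sample)
        tables = {g: t for g, t in tables.items() if t}
        results.append(assign_individual(sample, genotypes[sample], tables, min_loci))
    return results
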