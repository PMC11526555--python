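"""Independent brute-force oracles used to validate the implementation.

These deliberately recompute quantities by direct enumeration or dynamic
programming, never by calling the code paths they check.
"""

from __future__ import annotations

from functools import lru_cache


def dp_max_coverage(region: str, motifs: list[str], min_run: int = 2) -> int:
    """Maximum number of bases coverable by non-overlapping motif runs of
    length >= min_run copies (equivalently: minimum unexplained bases, then
    maximum total block length)."""
    n = len(region)
    motifs = list(motifs)

    @lru_cache(maxsize=None)
    def best(i: int) -> int:
        if i >= n:
            return 0
        out = best(i + 1)  # leave base i unexplained
        for m in motifs:
            L = len(m)
            c = 0
            while region.startswith(m, i + c * L):
                c += 1
            for k in range(min_run, c + 1):
                out = max(out, k * L + best(i + k * L))
        return out

    return best(0)


def pic_double_sum(freqs: list[float]) -> float:
    s = 1.0 - sum(p * p for p in freqs)
    for i in range(len(freqs)):
        for j in range(i + 1, len(freqs)):
            s -= 2.0 * freqs[i] ** 2 * freqs[j] ** 2
    return s


def pm_pairwise(genotypes: list[tuple]) -> float:
    """Match probability by explicit O(n^2) comparison of unordered pairs."""
    n = len(genotypes)
    norm = [tuple(sorted(g, key=repr)) for g in genotypes]
    matches = sum(1 for a in norm for b in norm if a == b)
    return matches / (n * n)


def hexp_direct(genotypes: list[tuple]) -> float:
    alleles = [x for g in genotypes for x in g]
    n = len(alleles)
    counts: dict = {}
    for a in alleles:
        counts[a] = counts.get(a, 0) + 1
    raw = 1.0 - sum((c / n) ** 2 for c in counts.values())
    return n / (n - 1) * raw


def hobs_direct(genotypes: list[tuple]) -> float:
    return sum(1 for a, b in genotypes if a != b) / len(genotypes)
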