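"""End-to-end validation experiments over the synthetic panel.

Each function here runs one self-contained experiment — simulate, analyse,
score against the simulation truth — and returns plain numbers.  They are the
single source of truth for the package's recovery figures: the test suite,
the acceptance script and the analysis drivers all call these.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np

from .allele_caller import (
    CallStatus,
    GenotypeCall,
    amplification_matrix,
    call_dataset,
)
from .forensic_stats import allele_frequencies, hwe_permutation_test
from .population_analysis import (
    IBD_CATEGORIES,
    assignment_loo,
    relatedness_pair,
)
from .simulate import (
    PopulationConfig,
    SimTruthRecord,
    default_panel,
    expected_status,
    inject_null_alleles,
    simulate_population,
    simulate_reads,
)
from .str_model import ce_designation, structure_from_extracted

__all__ = [
    "group_of_sample",
    "truth_calls",
    "end_to_end_roundtrip",
    "hwe_type1_calibration",
    "relatedness_recovery",
    "assignment_layer_comparison",
]


def group_of_sample(sample: str) -> str:
    return sample.rsplit("_", 1)[0]


def _designate(insert: str, locus_sim) -> tuple[str, str, str]:
    d = ce_designation(
        structure_from_extracted(insert, locus_sim.definition.motifs),
        locus_sim.definition.canonical,
    )
    return d.ce_label, d.array_seq, d.full_seq


def truth_calls(
    truth: Mapping[tuple[str, str], SimTruthRecord], config: PopulationConfig
) -> list[GenotypeCall]:
    """Express the simulation truth in the caller's own call format."""
    sims = {l.definition.name: l for l in config.loci}
    calls = []
    for key in sorted(truth):
        rec = truth[key]
        status = expected_status(rec)
        visible = [a for a, n in zip(rec.alleles, rec.nulls) if not n]
        distinct = sorted(set(visible))
        from .str_model import AlleleDesignation

        alleles = tuple(
            AlleleDesignation(*_designate(a, sims[rec.locus])) for a in distinct
        )
        calls.append(GenotypeCall(rec.sample, rec.locus, alleles, (), status))
    return calls


def end_to_end_roundtrip(seed: int, config: PopulationConfig | None = None) -> dict:
    """Simulate the default panel, run the full caller, score the recovery.

    Returns genotype accuracy over cells with no null allele, the detection
    rate of heterozygotes carrying a null, and whether the amplification
    matrix grouping of the called data matches the grouping of the realized
    truth exactly.
    """
    if config is None:
        config = default_panel(seed)
    truth = inject_null_alleles(simulate_population(config), config)
    reads, truth = simulate_reads(truth, config)
    loci = [l.definition for l in config.loci]
    calls = call_dataset(
        {s: [seq for _, seq in rs] for s, rs in reads.items()}, loci
    )
    by_key = {(c.sample, c.locus): c for c in calls}
    sims = {l.definition.name: l for l in config.loci}

    n_clean = n_clean_correct = 0
    n_null = n_null_flagged = 0
    for key in sorted(truth):
        rec = truth[key]
        call = by_key[key]
        want = expected_status(rec)
        if rec.n_null == 0:
            n_clean += 1
            want_alleles = sorted({_designate(a, sims[rec.locus])[2] for a in rec.alleles})
            got_alleles = sorted({a.full_seq for a in call.alleles})
            if call.status == want and got_alleles == want_alleles:
                n_clean_correct += 1
        elif rec.n_null == 1:
            n_null += 1
            if call.status is CallStatus.HET_WITH_NULL:
                n_null_flagged += 1

    group_of = {s: group_of_sample(s) for s in {k[0] for k in truth}}
    called_summary = amplification_matrix(calls, group_of)
    truth_summary = amplification_matrix(truth_calls(truth, config), group_of)
    return {
        "n_no_null_cells": n_clean,
        "genotype_accuracy": n_clean_correct / n_clean,
        "n_het_null_cells": n_null,
        "het_null_detection": n_null_flagged / n_null if n_null else float("nan"),
        "called_locus_groups": called_summary.locus_groups,
        "planted_locus_groups": truth_summary.locus_groups,
        "grouping_matches": called_summary.locus_groups == truth_summary.locus_groups,
        "n_core_called": called_summary.n_core,
        "n_core_planted": truth_summary.n_core,
        # loci producing a genotype in at least one individual somewhere
        "n_amplifying_loci": int(
            (truth_summary.status != CallStatus.FAILED.value).any(axis=1).sum()
        ),
    }


def hwe_type1_calibration(
    seed: int,
    n_loci: int = 1000,
    n_samples: int = 100,
    n_alleles: int = 6,
    n_perm: int = 1000,
    alpha: float = 0.05,
) -> dict:
    """Empirical type-I error of the HWE permutation test under true HWE.

    Each locus draws its own allele-frequency spectrum (Dirichlet(2)) and
    ``n_samples`` genotypes by independent pairing of allele copies.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 11]))
    rejections = 0
    for _ in range(n_loci):
        p = rng.dirichlet(np.full(n_alleles, 2.0))
        copies = rng.choice(n_alleles, size=2 * n_samples, p=p)
        genotypes = [tuple(copies[2 * i : 2 * i + 2]) for i in range(n_samples)]
        pval = hwe_permutation_test(genotypes, n_perm=n_perm, seed=rng)
        if pval <= alpha:
            rejections += 1
    return {"type1_rate": rejections / n_loci, "n_loci": n_loci, "alpha": alpha}


def relatedness_recovery(
    seed: int,
    n_pairs: int = 200,
    n_loci: int = 10,
    n_alleles: int = 6,
) -> dict:
    """Binary full-sib versus unrelated screening accuracy.

    ``n_pairs`` full-sib pairs are built by Mendelian sampling from simulated
    parents; ``n_pairs`` unrelated pairs are drawn independently.  Every pair
    is classified by maximum likelihood restricted to the two competing
    categories; population allele frequencies are uniform and known.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 12]))
    freqs = {
        f"L{i}": allele_frequencies(
            [(a, b) for a in range(n_alleles) for b in range(n_alleles)]
        )
        for i in range(n_loci)
    }

    def random_geno():
        return {
            f"L{i}": (int(rng.integers(n_alleles)), int(rng.integers(n_alleles)))
            for i in range(n_loci)
        }

    def child(p1, p2):
        return {
            l: (p1[l][int(rng.integers(2))], p2[l][int(rng.integers(2))])
            for l in p1
        }

    binary = {c: IBD_CATEGORIES[c] for c in ("U", "FS")}
    correct = {"FS": 0, "U": 0}
    for _ in range(n_pairs):
        p1, p2 = random_geno(), random_geno()
        best, _ = relatedness_pair(child(p1, p2), child(p1, p2), freqs, binary)
        correct["FS"] += best == "FS"
        best, _ = relatedness_pair(random_geno(), random_geno(), freqs, binary)
        correct["U"] += best == "U"
    return {
        "fs_recovery": correct["FS"] / n_pairs,
        "u_recovery": correct["U"] / n_pairs,
        "accuracy": (correct["FS"] + correct["U"]) / (2 * n_pairs),
        "n_pairs": n_pairs,
    }


def assignment_layer_comparison(seed: int, n_loci: int = 13) -> dict:
    """Leave-one-out (sub)species assignment at sequence vs length resolution.

    Uses the true genotypes of the default panel's core loci; accuracy is the
    fraction of individuals assigned back to their own group.
    """
    config = default_panel(seed)
    truth = simulate_population(config)
    core = [l for l in config.loci if l.definition.name <= f"STR{n_loci:02d}"]
    sims = {l.definition.name: l for l in core}
    genotypes_seq: dict[str, dict] = {}
    genotypes_ce: dict[str, dict] = {}
    for (sample, locus), rec in truth.items():
        if locus not in sims:
            continue
        layers = [_designate(a, sims[locus]) for a in rec.alleles]
        genotypes_seq.setdefault(sample, {})[locus] = tuple(l[2] for l in layers)
        genotypes_ce.setdefault(sample, {})[locus] = tuple(l[0] for l in layers)
    group_of = {s: group_of_sample(s) for s in genotypes_seq}

    def accuracy(genotypes):
        results = assignment_loo(genotypes, group_of)
        return sum(r.best_group == group_of[r.sample] for r in results) / len(results)

    acc_seq = accuracy(genotypes_seq)
    acc_ce = accuracy(genotypes_ce)
    return {
        "accuracy_sequence": acc_seq,
        "accuracy_length": acc_ce,
        "n_individuals": len(genotypes_seq),
        "n_loci": n_loci,
    }
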