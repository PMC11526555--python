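# Methods

This note records the models, estimators, conventions and deliberate design
choices implemented in `apestr`, and what validation on the synthetic panel
does and does not demonstrate.

## Repeat-array model

A repeat region is decomposed into maximal tandem runs of 2–6 bp motifs and
the material between them. The decomposer is a deterministic greedy scan:
left to right, at each position the motif giving the longest run (in bases)
is taken, ties broken by motif order in the locus definition; runs shorter
than `min_run = 2` copies are treated as interstitial material. A single
motif copy flanked by other material is therefore an interruption, not a
one-unit array — the convention a curator uses when bracketing short
structures. The greedy result is validated in the test suite against a
dynamic-programming oracle that minimizes unexplained bases (equivalently,
maximizes bases covered by blocks) over a structured-plus-random corpus of
strings up to 40 bp; the two agree everywhere on that corpus, so the greedy
scan is used in production for its speed and determinism.

Motifs are compared in their locus-canonical phase only; cyclic rotations
(`AGAT` vs `GATA`) are distinct motifs, because published locus structures
are phased.

**Repeat-derived material.** An interruption is classed as repeat-derived
when it is within Hamming distance 1 of a locus motif (same length), or is a
one-base-short contiguous fragment of the motif in any phase (a substring of
the doubled motif). This operationalizes the intuition that `GACA` and `GAT`
are damaged/partial copies of `GATA` while an unrelated insertion is not.
The phase-agnostic fragment rule (rather than a strict prefix rule) is
needed because a partial copy left behind by slippage can start mid-motif.

**Structural classes.** One motif: perfect (no interruptions), interrupted
(only non-derived interruptions), imperfect (any derived interruption —
derived takes precedence). Two or more distinct motifs of equal length:
compound / compound interrupted / imperfect compound by the same rule.
Blocks with motifs of unequal length (e.g. a tetramer plus a dinucleotide
array) are reported as unclassified rather than forced into a class.

**Allele naming.** Three nested layers: the CE-equivalent label
⌊L/m⌋ with the remainder as a fractional digit (region length L, canonical
motif length m; 39 bp of a tetramer → `9.3`), the repeat-array sequence, and
array plus trimmed flanks. In extracted reads, the region runs from the
first to the last repeat block; leading/trailing non-repeat bases between
anchor and flank are the trimmed flanks, so flanking SNVs are visible only
at the full-sequence layer and array SNVs at both sequence layers.

## Allele calling

Reads are quality-trimmed with a sliding window (width 4, mean Q ≥ 20,
truncation at the first failing window; minimum post-trim length 50 bp) and
an optional exact-prefix adapter strip. This is intentionally a simplified
QC step, not a re-implementation of a full trimmer.

Extraction is substitution-only matching (≤ `max_mismatch`, default 1; no
indels, for determinism and speed) of the 5´ anchor and the 3´ flank;
multiple equally good hits, or a hit at more than one locus, make a read
ambiguous and it is dropped with separate accounting, so
assigned + unassigned + ambiguous always equals the input read count.

Calling per locus: total depth < 20 → low depth; top two sequences with
minor/major ≥ 0.3 → heterozygote; otherwise the single surviving allele is
homozygous iff its depth ≥ τ · d_het with τ = 1.5, else a heterozygote with
a null allele. d_het is the median per-allele depth of the sample's own
unambiguous heterozygote calls (first pass), falling back to the run-wide
median for samples without heterozygote calls. τ = 1.5 is the midpoint
between the 1× depth expected for the visible allele of a null heterozygote
and the 2× depth expected for a true homozygote; it is configurable, as is
the per-sample versus per-run reference. The ≥ 20-read threshold is applied
per locus. Stutter folding (merging a sequence exactly one canonical-motif
copy shorter than a ≥ 1/0.15-fold deeper sequence) is available but off by
default: calling tolerates stutter through the balance threshold, and real
MPS pipelines handle stutter upstream.

The amplification summary groups loci three ways: *core* (genotyped in every
sample), *failed_or_restricted* (zero reads in every member of at least one
group — this takes precedence, since a species-restricted locus is such
regardless of its behaviour elsewhere), *partial* otherwise.

## Statistics

All statistics are computed from fully genotyped calls only; heterozygotes
with a null and low-depth calls are excluded, because a single observed
allele is not a genotype (and retaining them is exactly what inflates
F_is at null-prone loci).

* H_exp uses Nei's unbiased correction n/(n−1) on 1 − Σp²; the uncorrected
  variant is selectable. H_exp is undefined below 4 chromosomes.
* PM is the sum of squared *observed* genotype frequencies (the
  probability two randomly drawn cohort members match), not an HWE-expected
  quantity; PD = 1 − PM. The combined RMP multiplies per-locus PM across
  loci in log space, under the standard unlinked-loci product rule.
* PE = h²(1 − 2hH²) and TPI = 1/(2H) with h = H_obs, H = 1 − h; TPI is
  reported missing at H_obs = 1. These are the standard forensic
  definitions and are labelled as such in output metadata.
* F_is defaults to 1 − H_obs/H_exp; a Weir–Cockerham-style single-population
  estimator built from per-allele variance components (f̂ = 1 − c̄/(b̄+c̄))
  is selectable. Both recover a planted F = 0.2 within ±0.05 at n = 500 in
  the test suite.
* The HWE test permutes the 2n allele copies into random pairs and compares
  |H_obs − H_exp| against the permutation distribution, with
  p = (1 + #{perm ≥ obs})/(n_perm + 1); monomorphic loci return p = 1. Its
  empirical type-I error at α = 0.05 over 1000 HWE-simulated loci
  (n = 100 genotypes, Dirichlet(2) spectra, 1000 permutations) is measured
  at run time and falls within [0.03, 0.07].
* Bonferroni flags use strict p < α/m with the family = loci × groups
  actually tested.

## Relatedness and assignment

Pairwise relatedness is maximum likelihood over IBD-sharing categories
k = (k0,k1,k2): U(1,0,0), HS(½,½,0), FS(¼,½,¼), PO(0,1,0), with the
standard no-error conditional pair probabilities (the 1-IBD term copies one
uniformly chosen allele of the first genotype and draws the other from the
population). No genotyping-error term is modelled; under this model the
likelihood is symmetric in the pair for every category, PO included, and a
pair sharing no allele at any locus has PO likelihood zero. Screening uses
leave-pair-out frequencies within groups. The headline benchmark is the
binary screening question — classify simulated pairs as full-sib or
unrelated with categories restricted to {U, FS} — because with all four
categories the dominant confusion is FS↔HS, which is a different question
than detecting relatedness.

Pruning is greedy vertex removal on the forbidden-pair graph
(highest degree first, ties by lowest sample id) until no PO/FS/HS pair
remains; HS can be whitelisted per group, as appropriate for a highly
inbred population in which half-sib predictions reflect background
similarity rather than pedigree.

Assignment scores an individual's multilocus genotype against each group's
allele frequencies under HWE, leaving the individual's own alleles out of
its source group. Only loci usable in *every* candidate group contribute, so
log-likelihoods are comparable; unseen alleles are smoothed to
ε = 1/(2·n_chrom + 1). This is a deliberate desk-scale surrogate for
admixture-MCMC or discriminant clustering: it answers "which group's
spectrum best explains this genotype", not "how many clusters are there",
and no K-selection is attempted.

## Synthetic data

The generator's defaults mirror the study shape: groups n = 14/4/16/6/12;
27 loci (13 null-free core, 5 with 5% per-copy primer-site nulls
everywhere, 7 silenced wholesale in specific groups, 2 dead everywhere);
mean locus depth 100 (half per allele copy), stutter 0.08, per-base error
0.002. Allele catalogues carry ~5 length classes per locus with up to three
isoalleles each (canonical array, an array-internal substitution, a flanking
substitution); length spectra diverge hierarchically (genus more than
subspecies) and isoform preference differs by group, so sequence-level
typing carries more group information than length-level typing — the
property the assignment comparison measures.

Depth is modelled as round(m·G), G ~ Gamma(1/d, d), i.e. the gamma mixing
component of a Poisson–Gamma negative binomial with the discrete Poisson
layer omitted, so that dispersion d (the squared CV, default 0.01) is the
single noise knob and d → 0 recovers exact mean depths as the calibration
limit. A per-sample Gamma factor (CV 0.15) emulates input-quality
differences; the caller's per-sample heterozygote normalization must absorb
it, and does. Stutter removes one canonical-motif copy from the first
tandem run (the dominant n−1 mode only; no n+1 stutter, no PCR-duplicate or
index-hopping model, no paired ends). Qualities are constant Q30; the
quality trimmer is exercised by dedicated low-quality fixture reads instead.

**What passing on this generator shows — and does not.** It shows the
pipeline's logic is correct under its own assumptions: exact-sequence
tallying, depth-based null diagnosis at moderate overdispersion,
homogeneous per-locus amplification. Real MPS panels have locus-specific
amplification efficiencies, PCR stutter spectra broader than single n−1
events, sequence-dependent error, and contamination, none of which are
emulated; recovery rates on real data will be lower, and per-locus (rather
than per-sample) heterozygote normalization may be preferable there.

## Numerical and reproducibility choices

Seeds fan out through `numpy` `SeedSequence` children, so every stage is
independently reproducible; identical config + seed gives byte-identical
outputs, including permutation tests. Permutation p-values use the +1
correction and a 1e-12 tie tolerance on the statistic. Combined RMPs are
accumulated in log space. All coordinates are 0-based half-open. Degenerate
inputs have defined behaviour: empty tallies are failed calls, monomorphic
loci give p = 1 and undefined F_is, H_obs = 1 gives an undefined TPI,
zero-usable-genotype loci are skipped with a warning rather than reported.

## Known limitations

Substitution-only anchor matching cannot rescue reads with indels in the
anchor or flank. The null-allele rule depends on depth homogeneity across
loci within a sample; panels with strong locus effects need a per-locus
reference. Relatedness likelihoods ignore genotyping error and background
inbreeding, which inflates HS calls in inbred groups (hence the whitelist).
The assignment op is not a clustering method and assumes the candidate
groups are specified.
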