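# Methods

`svpopgen` analyses merged multi-sample structural-variant (SV) call sets —
biallelic presence/absence loci of 50 bp–1 Mb with diploid genotypes — for
cohorts of wild and domestic populations, the setting typical of livestock
domestication studies. This note documents the statistical procedures, the
synthetic-data model the test suite relies on, and the numerical and design
choices made where a convention had to be fixed.

## Data model and conventions

An `SvSet` is an ordered list of loci (DEL, DUP, INV, INS, TRA) with a
`samples × loci` dosage matrix in {0, 1, 2} and a dedicated missing sentinel
(never 0, so frequency denominators always exclude missing calls). VCF
coordinates (1-based inclusive) are preserved on records; every interval
operation uses the 0-based half-open span `[start−1, end)`, which matches BED
and makes interval arithmetic unambiguous. Insertions are treated as 1-bp
points at the insertion site: the length-fraction overlap rules used
throughout are undefined for inserted sequence. Translocations are a single
locus with one genotype column and an optional partner breakend. Multiallelic
records are rejected; merged SV call sets are presence/absence.

## Diversity statistics

Per-site nucleotide diversity uses the small-sample-corrected pairwise
formula `π = n/(n−1) · 2p(1−p)` with `n = 2 · n_called` sequences; it equals
the mean allele difference over all C(n,2) sequence pairs (the test suite
proves this against brute-force enumeration). Windowed π over 10-Mb windows
is reported under **both** denominators — per bp (`sum π / window length`)
and per SV site (`mean π over sites`) — because the per-bp convention of
sliding-window tools yields values ~1e−6 for SV data while the per-site
convention yields values near 2p(1−p); both columns are explicit so the user
picks the convention, and neither is asserted against published values.

Heterozygosity is the fraction of heterozygous calls among non-missing calls
at segregating sites within a stratum.

F_ST is the Weir & Cockerham (1984) two-level variance-component estimator
computed from genotype counts: among-population (a), among-individual (b) and
within-individual (c) components, with observed heterozygosity entering c.
Per-site θ̂ = a/(a+b+c) is kept unclamped (negative values retained; clamping
biases sums). The genome-wide value is the weighted ratio of sums
Σa / Σ(a+b+c) over defined loci, matching the "weighted" convention of
standard tools; a mean-of-ratios alternative is also reported. Loci
monomorphic across the pooled sample, or with fewer than two called diploids
in any population, are undefined and excluded (with counts). "Global" F_ST
is the per-locus mean of each breed-vs-all-other-breeds θ̂, undefined below
two defined contrasts.

LD is the squared Pearson correlation of genotype dosages over samples called
at both loci — a deterministic, phase-free dialect that differs from
haplotype-based EM r²; the decay profile bins same-chromosome pairs to 300 kb.

## Selection scans

Ancestral states are polarized on the majority allele of a designated wild
proxy population; ties are ambiguous and excluded, loci without wild calls
are unpolarizable. The differentiation index `DI_SV` is the signed difference
in derived-allele frequency, domestic minus wild; candidates come from the
upper tail because domestication scans target derived-allele rise in
domestics (the sign convention is this package's documented choice).

Permutation P-values for pairwise θ̂ shuffle sample labels and use the strict
rule `P = #{θ̂_perm > θ̂_obs}/B` with B = 200 by default; P = 0 is reportable,
and an optional (k+1)/(B+1) smoothing exists. By default one label
permutation per replicate is shared across all loci, preserving inter-locus
correlation; per-locus independent shuffling is available and is what the
calibration tests use. Because ties between permuted and observed θ̂ are not
counted, the null distribution of P is slightly depressed at small group
sizes; calibration is demonstrated at 60+60 samples on loci with MAF ≥ 0.1.

PBS for focal population 1 is `(T12 + T13 − T23)/2` with
`T = −log(1 − θ̂)`, θ̂ clamped below 1 only to avoid log(0); negative θ̂
passes through (T < 0 allowed).

Top-quantile candidate rules place the threshold at descending rank
⌈q·m⌉ over the m defined loci and include ties; combined rules are set
intersections; thresholds are stored so calls are reproducible and
idempotent. Grouped allele-frequency comparisons use a two-sided Wilcoxon
rank-sum on per-population frequencies: exact enumeration (tie-safe) when the
smaller group has ≤ 10 populations, the normal approximation with tie
correction otherwise, with Benjamini–Hochberg adjustment across the SV set.

## Interval genomics

Breakpoint density counts SV breakpoints (two per span SV, one per insertion,
one per chromosome involved in a translocation) in 1-Mb windows at a 500-kb
step; a breakpoint in the overlap of two windows counts in both. Hotspots are
the top decile of windows by count (genome-wide by default; per-chromosome
optional), ties included, with adjacent/overlapping hotspot windows merged
into regions. Telomeric regions are the first and last 5 Mb of each
chromosome — assemblies don't encode centromeres, and for the acrocentric
chromosomes of sheep and goats the distal 5 Mb is the arm end; a single-end
option exists — compared to the remaining 1-Mb bins by a two-sided Wilcoxon
rank-sum on per-bin breakpoint counts, with an optional chromosome exclusion
list.

Fractional overlap matching mirrors BEDtools `-f/-F` with `-e` (either side
suffices) or both-side semantics and `-v` (invert): novelty against a
published catalog uses 30%/30% either-side reciprocal overlap; QTL and peak
comparisons use 50%/50%. QTL fold enrichment for an individual's carried SVs
is observed matches over the expectation under uniform placement
(`carried × merged QTL span / genome span`); the formula is this package's
interpretation of a named but undefined quantity, and a pseudocount of 0.5
replaces a zero observed count for the log2 (flagged). Peak-SVs have ≥ 50% of
their length inside the merged open-chromatin peak set, with overlap
accumulating across peaks. Promoter peaks intersect a TSS ± 2 kb window
(consistent with the 2-kb flank of the genic annotation; "annotated as
promoters" is otherwise undefined); remaining peaks are enhancer candidates,
and SV-supported candidates contain ≥ 50% of some SV's length.

## Genic annotation

SVs are classified into seven categories — intergenic, intronic, exonic,
2-kb upstream, 2-kb downstream, 3′ UTR, 5′ UTR — by ≥ 1 bp positional overlap
with strand-aware feature spans; one SV can carry several categories
simultaneously, and intergenic means no feature and no flank of any gene is
touched. UTRs are derived from CDS bounds when present; genes without CDS
simply cannot receive UTR assignments (no inference). Summaries report both
category incidences and distinct-SV counts, since published totals can follow
either convention.

## Convergence test

Shared orthologs between two species' candidate gene sets are counted through
a one-to-one ortholog map. The permutation null draws uniform random gene
sets of the observed sizes from an explicit universe of ortholog pairs, so
null counts are hypergeometric with mean `nA·nB/U`; `P = #{k_perm ≥ k_obs}/B`
(upper tail). The universe is a required argument because it changes the
answer materially: with U ≈ 20,000 annotated genes and candidate sets of
~1,500 and ~1,100 genes, the hypergeometric expectation (~84) already exceeds
an observed count of 79, so a significant excess implies a much smaller
effective universe (e.g., SV-genes only). The expectation is always reported
alongside P so this dependence is visible.

## Introgression scan

A domestic population's SV is a candidate introgression when it is carried in
that population, has frequency exactly 0 in every other domestic population,
frequency exactly 1 in at least one wild species, and frequency 0 in the
designated outgroup species (excluding shared ancestry); populations need ≥ 2
samples, and only recipients with **more than** 2 candidate SVs are reported
(guarding against drift). Fixation/absence are evaluated over non-missing
calls; a population with no genotyped call cannot certify absence, so the
locus fails there (conservative). A frequency tolerance (default 0) exists
because exactness is fragile under missingness at small n.

## Association post-processing

The per-SV score is an ordinary least-squares regression of phenotype on
dosage — deliberately simple, without kinship correction, existing to produce
`(β̂, se, MAF, N)` end-to-end on synthetic data; the variance-explained
formula `2β̂²m(1−m) / (2β̂²m(1−m) + 2N·se²·m(1−m))` accepts externally fitted
mixed-model summary statistics and is evaluated exactly as written (the MAF
factor cancels algebraically to `β̂²/(β̂²+N·se²)`, which the tests assert).
Significant SVs are the top 5% of smallest P values, ties included. The qPCR
copy-number rule classifies ΔΔCT values in the inclusive interval
[1.414, 2.449] (√2 to √6) as a normal copy number of two; the rule is applied
as printed on its ratio-like scale without reinterpretation.

## Synthetic cohort generator

`simulate_cohort` draws a multi-population diploid SV cohort:

* **Type mix** {DEL 0.77, DUP 0.05, INV 0.02, INS 0.10, TRA 0.06},
  approximating the composition of domestic-sheep call sets; lengths are
  log-uniform per type within [50 bp, 1 Mb], with defaults (e.g., DEL
  50 bp–10 kb) chosen so most SVs are shorter than 1 kb.
* **Positions** from a mixture of a uniform background and Gaussian hotspot
  clusters (weight w gives the cluster a w : 1 share of loci against the
  whole background), truncated to chromosome bounds.
* **Frequencies** from the Balding–Nichols construction: ancestral
  `p0 ~ Beta(0.3, 2)` (rare-skewed), population frequency
  `~ Beta(p0(1−F)/F, (1−p0)(1−F)/F)` for drift parameter F, genotypes
  binomial(2, p). The closed-form expectation E[F_ST] = F is what makes
  desk-scale parameter-recovery tests possible; the weighted θ̂ recovers
  F ∈ {0.05, 0.15, 0.3} within ±0.003 at 5,000 loci and 30+30 samples.
* **Planted signals**: selected loci get a frequency shift δ in target
  populations (clipped to [0, 1]; a pinned ancestral frequency that cannot
  absorb the shift is rejected before sampling) — frequency shift rather
  than a selection coefficient because the scans detect frequency
  differentiation directly; introgressed loci are constructed to satisfy the
  introgression criteria exactly on realized genotypes (donor wild species
  forced to fixation, other domestics and the outgroup to absence, recipient
  carriers re-drawn until present); phenotypes are `y = Σ β_k g_k + ε`.
* Loci are independent; there is no recombination map or background LD (LD
  tests use explicitly duplicated columns). Translocations get a partner
  breakend on another chromosome but one genotype column.

The default scenario (three chromosomes of 40–60 Mb, a wild ancestral proxy,
a distant wild outgroup, two native and one improved population, ~2,000 loci,
2% missingness) is the study-like condition used across the tests. Scaling:
test and acceptance runs use 10³–10⁴ loci and tens of samples — the sizes at
which the closed-form recoveries above are informative — rather than
genome-scale counts.

**What passing tests do and do not show.** The generator reproduces the
*statistical* structure the methods assume (drift-divergent frequencies,
rare-skewed spectrum, clustered breakpoints, exact planted signals); it does
not emulate SV-calling artifacts, genotyping error correlated with depth,
linkage between loci, or population admixture. Recovery results therefore
validate the implementations, not the robustness of the methods to real-data
pathologies. One known gap: with the Beta(0.3, 2) ancestral law at 60
diploids, the realized fraction of segregating loci with sample MAF < 0.01
is ~8% (only singletons can fall below 0.01 at 120 alleles), so the
generator's rare skew is expressed in the ancestral law (~33% of loci below
p0 = 0.01) and in a left-shifted folded spectrum (median segregating MAF
~0.12), not in the sample-MAF tail that a 500+-sample cohort would show.

## Reproducibility

Every stochastic operation takes an explicit seed; the pipeline manifest
records the seed, thresholds, inputs and package version, and two runs with
identical configuration produce byte-identical tables (fixed float
formatting). Threshold records accompany every top-quantile call so candidate
sets can be re-derived without re-ranking.
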