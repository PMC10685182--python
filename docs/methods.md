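# Methods

## Data model

Genotype tables hold STR calls as strings ("15", "9.3", the off-ladder
sentinel "OL"); comparisons go through parsed (repeat, microvariant) keys,
never floats, so microvariant alleles such as 9.3 are exact. Autosomal and
female-X calls are unordered diploid pairs; male-X calls are single
hemizygous alleles; missing calls are absent and excluded from all
denominators rather than imputed. Wide files carry two columns per locus
(`<locus>_1`, `<locus>_2`, the second empty for male X); long files carry
one row per allele copy. Allele-frequency tables store per-locus
allele → proportion maps with the number of allele copies sampled; on read,
per-locus sums within 0.5% of 1 are renormalized with a warning, anything
worse is rejected. Pooled X frequencies use the hemizygous convention:
each male contributes one allele copy and each female two, so the
denominator is n_m + 2·n_f.

## Simulation model

Subpopulation divergence follows the Balding–Nichols model: given an
ancestral frequency vector p and divergence F ∈ [0, 1), a subpopulation's
frequency vector is a single Dirichlet draw with concentrations
αᵢ = pᵢ(1−F)/F, giving E[qᵢ] = pᵢ and Var[qᵢ] = F·pᵢ(1−pᵢ). This model is
chosen because the θ-corrected match-probability formulas are exactly its
conditional genotype probabilities, which makes the RMP audit
self-consistent: the simulator, the Weir–Cockerham estimator and the audit
check one another. Alleles with ancestral frequency zero are excluded from
the Dirichlet (a zero concentration is undefined) and stay absent.

One frequency draw is shared by all individuals of a (subpopulation,
locus) pair; genotypes are then independent Hardy–Weinberg draws (two
allele draws per diploid, one per male X). The generator therefore models
drift between subpopulations, not inbreeding within individuals, family
structure, mutation, stutter/dropout artifacts, or linkage between loci —
loci are independent by construction, so passing tests say nothing about
real linkage groups beyond the estimators' behaviour under the null.

The bundled panel uses the real 21 autosomal and 19 X locus names of the
two kits this package emulates, with per-locus allele counts drawn
uniformly from 5–22 (the span seen at X-STRs in such kits) and ancestral
frequencies from a flat Dirichlet floored at 0.0025 — the smallest
frequency a single observation in a few-hundred-sample database produces.
The default two-subpopulation model uses a cognate cohort of 333 males and
88 females (a typical mostly-male forensic collection) and a larger
non-cognate reference population, both diverged at the same F from a
common ancestor; F defaults to 0.01, inside the 0.0016–0.0170 range of
recommended corrections for closely related East Asian populations that
the audit sweeps.

An off-ladder injector gives a Bernoulli(rate) subset of individuals one
allele absent from a chosen reference database (two repeat units above the
largest known allele), emulating profiles a non-cognate database cannot
price; the audit removes such profiles first, as practice does.

## Forensic parameters

All per-locus quantities reduce to the power sums a_k = Σᵢ pᵢᵏ:

* He (and X gene diversity HD): unbiased n/(n−1)·(1 − a₂) on n sampled
  allele copies.
* PIC = 1 − a₂ − a₂² + a₄.
* MP/PD: observed-genotype mode by default (Σ over squared observed
  genotype proportions, the convention STR summary tools report), with an
  expected-HWE mode available.
* PE = h²(1 − 2hH²) and TPI = 1/(2H) with h the observed heterozygote
  fraction, H = 1 − h. At H = 0 TPI is reported as +inf with a warning.
* X discrimination: PD_m = 1 − a₂, PD_f = 1 − 2a₂² + a₄ (equal to one
  minus the sum of squared HWE genotype probabilities; verified by
  enumeration in the tests).
* Combinations: CPM = Π MP, CPD = 1 − CPM, and all exclusion-type powers
  combine as 1 − Π(1 − x); adding loci is monotone.

### Mean exclusion chance

The MEC family is defined operationally by an exact enumeration engine
over pedigree configurations weighted by HWE/random-mating probabilities:

* father–daughter duo (X): a random man's single X allele must match one
  of the daughter's two alleles;
* mother–daughter trio (X): the mother's genotype restricts which daughter
  allele can be paternal; the man is excluded if his allele is outside
  that set;
* autosomal trio: mother and child determine the obligate paternal allele
  set; a random diploid man is excluded if neither allele is in it.

The closed forms — duo 1 − 2a₂ + a₃; X trio 1 − a₂ − a₂² + a₄; autosomal
trio 1 − 2a₂ + a₃ + 3a₂a₃ − 3a₅ − 2a₂² + 2a₄ — are verified against the
engine to 1e−12 over a thousand random frequency vectors and used as fast
equivalents. Published MEC variant names are not uniquely attached to
formulas in the literature this package follows, so reports name the
pedigree scenario, not an author. Enumeration refuses vectors above 60
alleles (cubic cost); the closed forms have no limit.

## Exact tests

**HWE.** Conditional on allele counts, every pairing of the allele pool is
equally likely under HWE, inducing the classical distribution
P(table) ∝ 2^het / Π G_ij! over genotype tables. The p-value is the total
probability of tables no more probable than the observed one. Tables with
≤3 alleles and ≤50 individuals are enumerated completely (recursive
generation under the count constraints). Larger tables are sampled
exactly: each Monte-Carlo replicate is a fresh random permutation of the
allele pool paired into genotypes — iid draws from the same conditional
law that the classical genotype-switching Markov chain targets, chosen
over the chain because it needs no dememorization or mixing diagnostics
and vectorizes across replicates. The default is 10,000 replicates
(Monte-Carlo SE ≤ 0.005); p = (b+1)/(B+1). Monomorphic loci return p = 1
with a note. Ties in the ordering statistic are included via a 1e−9 log
tolerance.

**LD.** Male X haplotypes (phase known): G statistic on the two-locus
contingency table, null built by permuting one locus across individuals.
Female unphased genotypes: two-locus haplotype frequencies by EM (double
heterozygotes split between the two phase resolutions by their current
likelihoods), likelihood ratio against the product of allele frequencies,
same permutation null. Permutation p-values are (b+1)/(n+1), so never
exactly zero; at least 100 permutations are required.

## Population structure

Weir–Cockerham (1984) θ with the usual a/b/c variance components per
allele, summed over alleles and loci before taking the ratio. X loci enter
through the haploid ANOVA form (MSP/MSG with n_c), pooling allele copies
(males 1, females 2); its between/within components are added to the same
numerator/denominator sums. Negative estimates are retained. Permutation
p-values reassign individuals (with all their calls) between the two
populations. The estimator is validated three ways: exact 1.0 on fixed
differences, |θ| < 0.005 on identical-frequency populations, and recovery
of a true Balding–Nichols F = 0.01 within [0.005, 0.02] at 100 loci ×
200 diploids per population — the simulator and estimator serving as
mutual oracles, since no closed-form finite-sample expectation exists.

PCoA is classical metric scaling: Gower double-centering of −D²/2,
symmetric eigendecomposition, coordinates as eigenvectors scaled by
√eigenvalue. Negative eigenvalues (non-Euclidean input) are reported but
excluded from coordinates and from the explained-variance denominator.
The implementation is cross-checked against scikit-bio's PCoA in the test
suite. Heatmap support is limited to reordering a distance matrix by
average-linkage leaf order; no plotting dependency.

## RMP audit conventions

d = log₁₀(RMP_cognate / RMP_noncognate), so d > 0 flags overstated
evidence. The cognate RMP is computed at F = 0 (one's own database needs
no subpopulation correction); configurable. The rare-allele policy is
strict by default — an allele absent from the database raises — with an
optional logged frequency floor for practitioners; the audit instead
removes profiles carrying alleles the non-cognate database lacks before
computing anything, mirroring forensic practice with off-ladder alleles.
Summaries report percent of profiles strictly above each threshold
(0, 0.5, 1, 2 by default; non-increasing by construction), the mean, and
the n−1 sample SD (a single profile yields SD 0 with a note).

Because both subpopulations diverge independently at F from the ancestor,
their pairwise separation exceeds F itself, and the cognate database is
estimated from the cohort's own finite sample; the audit's mean d at F = 0
is therefore comfortably positive, and sweeping F through the true value
drives it through zero — the qualitative pattern the acceptance checks
assert, rather than any data-dependent percentages.

## Pipeline and determinism

Each stage's RNG seed is derived from the root seed and the stage name
(CRC32 mix, kept below 2³¹), so stages can be re-run in isolation and
identical configs produce byte-identical outputs (checksummed in
`manifest.json`; verified by re-running the demo). A failing stage renames
its partial outputs to `*.partial` and aborts with the stage name. The
demo and test problem sizes (hundreds of individuals, tens of loci,
hundreds to thousands of Monte-Carlo replicates) were chosen as the
smallest sizes at which the statistical properties under test are
well-resolved; every size is a parameter and scales up freely.

## Known limitations

Single-source profiles only (no mixture deconvolution); no kinship
likelihood ratios beyond the exclusion-chance summaries; no mutation-aware
paternity indices; LD machinery handles pairs of loci, not multi-locus
phasing; admixture inference and plotting are out of scope. The exact HWE
p-values are discrete, hence slightly conservative for very small or
skewed tables — the calibration check passes at n = 200 with 8 alleles but
should not be expected for, say, biallelic tables at n = 10.
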