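# Methods

This note documents the models, algorithms and numerical choices behind
`binqtl`, and what the simulation-based tests do and do not establish.

## Simulator

**Genomes and maps.** Two inbred parents differ at a panel of biallelic SNPs
placed uniformly at random on each chromosome. The physical-to-genetic map is
linear per chromosome (constant cM/Mb, default 1); no recombination landscape
is modelled, because nothing downstream depends on rate heterogeneity and a
linear map keeps every closed-form check exact.

**RILs.** Each line is an independent single-seed-descent lineage from the
F1. One selfing generation draws an egg and a pollen gamete from the current
plant; crossovers per gamete are Poisson with mean equal to the chromosome's
genetic length in Morgans, positions uniform on the map (no interference —
the Haldane process; the paper-style Kosambi map function is still used for
*estimation*, which at bin-scale distances differs from Haldane by far less
than sampling error). `n_selfing_generations` counts selfing meioses applied
to the F1, so g = 6 produces F7 plants (F6:7 seed families) with expected
residual heterozygosity (1/2)⁶ ≈ 1.56 % per locus — a property the test
suite verifies at 10,000 lines.

**GBS observations.** Read depth per line × SNP is Poisson(mean depth);
depth 0 is missing. Each read reports one of the two homologues and flips
parent with the error rate (default 1 %). A site is called heterozygous only
when both parental alleles are seen, so at < 0.1× coverage true heterozygous
segments appear as ~50:50 salt-and-pepper homozygous calls — exactly the
pattern the sliding window is designed to recognize. Sites are sampled
independently per SNP (no restriction-site clustering): cluster sampling
would change the variance, not the mean, of per-line coverage, and nothing
downstream uses within-read linkage.

**Phenotypes.** A record in location j, year k, replicate l is

    y = intercept + Σ_q effect_q(genotype) + loc_j + year_k
        + (line:loc)_ij + (line:year)_ik + ε_ijkl

with effect_q = +a / d / −a for AA / AB / BB, an additional polygenic
N(0, σ²_poly) line effect, and independent normal interaction and residual
draws. The default architecture (`paper_like_phenotype_spec`) plants one
completely dominant major QTL (a = d = 1.41 trait units) and three minor
additive QTLs (0.40 / −0.52 / 0.44), spaced ≥ 60 cM so linkage covariance
between planted effects is < 1 %. The components
(σ²_poly = 3.76, σ²_L:Loc = σ²_L:Year = 0.30, σ²_res = 1.951, 2 locations ×
2 years × 2 replicates) are solved so that the major QTL explains 25.0 % of
the per-environment line-mean variance and the entry-mean heritability is
0.890; both values are available in closed form (`planted_pve`,
`planted_h2`) and are what the recovery tests compare against.

## Bin-map construction

**Window calling.** Windows of 20 *observed* SNPs slide by 2 along each
line's chromosome. A window is called A (or B) when that parent's allele
fraction among its calls — heterozygous calls counting half — reaches the
purity threshold (default 0.7), H otherwise, missing below 5 calls. Each
observed SNP takes the majority vote of the up-to-10 windows covering it;
ties resolve to H. The purity threshold, minimum calls and vote rule are the
package's own concretization of a "modified sliding window" and are all
configurable.

**QC.** Lines are dropped below the minimum genotyped-SNP count or above
10 % heterozygosity / 200 breakpoints (the published thresholds). The
coverage criterion is expressed as a genotyped-SNP count because fold
coverage is not observable from a genotype matrix; scale it to the panel
(the default 20,000 matches a ~1.7 M-SNP panel at 0.08×). Bins are dropped
above a 2:1 homozygote ratio or 10 % heterozygosity. Both filters are
idempotent.

**Imputation.** After heterozygous consensus calls are recoded missing (the
published order of operations), each track is completed by the Viterbi path
of a two-state chain: states are the parental homozygotes, the switch
probability between adjacent SNPs is the selfed-RIL discordance
R = 2r/(1 + 2r) with r from the inverse Kosambi function of the cM gap, and
emissions flip with a 0.5 % error rate (unstated in the source pipeline;
configurable). Observed calls are never overwritten — the path only fills
gaps — so imputation cannot erase evidence.

**Bins and the genetic map.** Chromosomes are partitioned at the union of
all lines' breakpoints (equivalently: adjacent SNP columns are merged while
no line differs); edges sit at midpoints between flanking SNPs, 0-based
half-open internally, 1-based inclusive in reports. Distances between
adjacent bins come from hom/hom discordance via r = R/(2 − 2R), then
Kosambi. Pairs with < 20 informative lines borrow the nearest informative
distance (logged). Two known small biases, both shared with the standard
est.map-style pipeline: (i) the F∞ correction overstates what an F7
population can show — realized map expansion at g = 6 is slightly below the
asymptotic factor 2 — and (ii) crossovers hidden inside residual
heterozygous segments are invisible to hom/hom counts. Together they
shorten the estimated map by ~5–10 % at g = 6 (exact at large g); the
map-length recovery test bounds this at 10 %.

## QTL scan

The likelihood core is Haley–Knott-style regression on bin genotypes
(additive coding, missing mean-imputed): LOD = (n/2) log₁₀(RSS₀/RSS₁).
Regression is appropriate here because imputed bins are near-fully
informative, making the EM mixture over pseudomarkers unnecessary; an exact
normal-equations oracle in the tests pins the implementation to 1e-8.
Degenerate cases: constant or collinear genotype columns give LOD 0 with a
warning; an exact fit is capped (r² ≤ 1 − 1e-12) rather than infinite.

**Cofactors.** Composite interval mapping uses forward stepwise selection of
up to k = 5 cofactor bins (≥ 10 cM apart), and drops any cofactor within a
10-cM window of the tested bin. k and the window are declared defaults —
the source analysis does not state its cofactor rule. Bins sharing an
exclusion pattern are scanned as one residualized block, so a genome scan is
a handful of matrix products.

**Permutations.** Line phenotypes are permuted jointly against the whole
genotype matrix (preserving LD); the threshold is the m-th smallest of the B
genome-wide maximum LODs with m = max(1, ⌈(1 − α)B⌉) — so B = 1000, α = 0.05
gives the 950th order statistic, and α = 1 the minimum. With cofactors
configured, every permutation re-selects its own cofactors; the zero-cofactor
case is fully vectorized. The resulting test is exact by exchangeability up
to order-statistic granularity (rejection probability 6/101 ≈ 0.059 at
B = 100), which the 200-run type-I-error check brackets with a binomial band
around 0.05.

**Peaks, intervals, effects.** QTLs are extracted greedily from the LOD
curve above the threshold. Each peak gets a support interval by the
1.5-LOD-drop rule, expanded outward to the first bin falling below
(peak − 1.5); a side that never falls below clips at the chromosome end and
is flagged. A candidate peak whose support interval overlaps an accepted
QTL's interval on the same chromosome is treated as a shoulder of that
signal — the cofactor-exclusion window produces exactly such ghost peaks
~10 cM off a strong QTL — and is retired without being reported. The
additive effect is a = (mean_AA − mean_BB)/2, PVE is the single-locus model
sum-of-squares share × 100, and the positive allele is the parent whose
genotype increases the trait. Estimates at a detected peak carry ~1 %
attenuation from peak-bin mismatch; the parameter-recovery test therefore
evaluates the estimator at the planted locus, where it is unbiased.

## Trait statistics

Variance components of value = Line + Loc + Year + Line:Loc + Line:Year + ε
(line terms random, location/year fixed) are estimated by expected mean
squares (ANOVA method of moments), which coincides with REML on the balanced
designs the simulator produces; negative estimates clip to 0 with a warning,
unbalanced cell sizes fall back to the mean cell count with a warning, and a
single-replicate design uses the three-way interaction as residual.
Heritability is the entry-mean formula above. Segregation tests are Pearson
χ² against arbitrary expected ratios (df = classes − 1); at n = 12 the
approximation tracks the exact binomial mid-p within 0.02. Marker–trait
profiles use Welch's t-test by default (a plain "Student's t-test" leaves
the variance assumption open; the pooled version is a flag), two-sided,
reported as −log₁₀ p. NIL similarity is 100·(total − discordant)/total to
one decimal, taking explicit counts so pooled (sequence + PCR) or
sequence-only conventions are both expressible.

## Fine-mapping

A recombinant is valid when its ordered region markers show exactly one
het↔hom transition (missing markers widen the breakpoint interval to the
flanking informative markers; multi-transition or mixed-parent patterns are
rejected). A subfamily t-test at α = 0.05 places the QTL in the
heterozygous segment when significant, in the homozygous segment otherwise —
the published decision rule verbatim. Each assignment becomes a directional
bound at the flanking marker on the *excluded* side of the breakpoint;
bounds are intersected and clipped to the prior interval. Conflicting
constraint sets either raise an error naming the clash (default) or, in
`drop-weakest` mode, iteratively set aside the conflicting constraint whose
p-value is closest to the significance boundary, reporting it as
inconsistent rather than silently dropping it. This mirrors how a handful of
"supporting" recombinants can coexist with one fluke test: with ~11
subfamilies at α = 0.05 roughly one false side-assignment is expected
per campaign, and weakest-evidence resolution recovers the true interval in
> 90 % of simulated campaigns. Gene lookup uses the any-overlap (≥ 1 bp)
convention on 1-based inclusive annotation coordinates.

## Test and acceptance problem sizes

Desk-scale defaults are 2 chromosomes × 150 Mb at 1 cM/Mb with 2,000 SNPs
and 200–670 lines. Two deliberate departures: the breakpoint recall/FDR
study uses a 60,000-SNP panel (5 kb spacing), because breakpoint resolution
is set by *observed*-marker spacing (panel spacing ÷ coverage fraction) and
the emulated study's panel is ~0.8 SNPs/kb — at 2,000 SNPs a 20-SNP window
spans tens of Mb and short double-crossover segments become invisible; and
heritability/variance-component runs use a 200-SNP panel, since only QTL
genotypes enter the phenotype model. Monte-Carlo suites use 200 scan
replicates at n = 670, 200 null scans with 100 permutations, 100
heritability replicates and 500 progeny subfamilies; the acceptance script
scales some of these down (25 scan replicates, 100 null scans, 50
heritability replicates) and labels every output with the n used.

**What passing does not show.** The simulator draws interference-free
crossovers on a linear map, error rates homogeneous across sites, phenotypes
exactly normal with balanced designs, and GBS sites independent. Real data
violate all four (crossover interference, pericentromeric recombination
suppression, batch and alignment artifacts, unbalanced augmented field
designs); the guarantees verified here are about the inference chain's
correctness, not about robustness to those violations.

## Known limitations

* Variance components require (near-)balance; no standard errors or BLUPs.
* Multi-environment traits are scanned per environment; no joint
  multi-environment or multi-QTL model beyond CIM cofactors, no epistasis.
* The genetic-map shortening at low g described above.
* `classify_recombinant` assumes a single breakpoint inside the marker
  region; genuine double recombinants are excluded, not modelled.
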