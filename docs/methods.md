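# Methods

`selfdiv` re-implements, on synthetic data with known ground truth, a
population-genetic analysis of how reproductive mode — exclusive selfing,
partial selfing (mixed mating), or predominant outcrossing — shapes genetic
diversity and genetic load. The system it emulates is a set of experimentally
evolved *C. elegans*-like populations genotyped at a few hundred biallelic
SNPs on 6 chromosomes of 50 cM, from which inbred lines are derived by
single-individual selfing for 13–16 generations. The three pillars are
(1) multilocus diversity statistics on phased SNP samples, (2) a neutral
forward simulator of inbreeding by selfing that turns an observed sample into
drift-only credible intervals for post-inbreeding diversity, and (3) survival
analysis of line extinction during enforced selfing.

## Diversity statistics

Per biallelic SNP with ALT frequency p: expected heterozygosity He = 2p(1−p)
and observed heterozygosity Ho = the fraction of heterozygous individuals.
Missing allele calls are excluded from every denominator; an individual with
a missing call at a marker is dropped at that marker only.

**Fis.** The multilocus fixation index is the ratio-of-means form
Fis = 1 − mean(Ho)/mean(He), computed over SNPs with He ≥ 0.05 (default
`min_He`). The filter guards against the unstable per-locus ratios of nearly
fixed SNPs; the ratio-of-means (rather than a mean of per-locus Fis values)
is the standard multilocus estimator and is robust to low-He loci. At neutral
mixed-mating equilibrium with selfing rate s, Fis → s/(2−s); this closed form
anchors the simulator tests (s = 0, 0.5, 1 → Fis = 0, 1/3, 1).

**Identity disequilibrium g2.** Variance in inbreeding history under partial
selfing makes heterozygosity correlated across loci within individuals. g2 is
the standardized excess of two-locus heterozygosity,
E[h_i h_j]/(E[h_i] E[h_j]) − 1 over marker pairs i ≠ j, estimated with the
David et al. (2007) multilocus estimator: per locus pair, the cross-moment in
the denominator runs over ordered pairs of *distinct* individuals, which
removes the finite-sample bias of plugging the same individual into both
factors; numerators and denominators are summed over pairs before the ratio
is taken. Missing data are handled by restricting each locus pair to
individuals typed at both loci (pairwise-complete), and the standard error
comes from a seeded bootstrap over individuals (default 200 replicates).
g2 is undefined (NaN) when no individual is heterozygous anywhere — the
situation of an exclusively selfing population — and the implementation is
validated against a brute-force double-loop over the definition at 1e−10
relative tolerance.

**Effective number of haplotypes he.** A multi-allelic diversity measure:
within non-overlapping windows of 10 consecutive SNPs (trailing remainders
dropped), he = 1/Σ k_i² where k_i is the frequency of window-haplotype i.
Each phased individual contributes its two window-haplotypes (the haploid
unit, default); counting unordered diploid haplotype pairs instead is
available behind `unit="diploid"` since the window definition admits either
reading. Individuals with any missing call in a window are dropped from that
window only. Genome-wide summaries of He, Ho and he average per-chromosome
means across chromosomes (`per_chromosome=True`, matching the per-chromosome
analysis of the simulator); flat averaging is a flag.

**Jackknife sample-size matching.** Statistics on line panels (often > 50
lines) are compared with 16-individual population samples as the mean over
delete-d subsets of exactly 16 individuals: all C(n,16) subsets when at most
`max_subsets` (default 200) exist, otherwise that many seeded random subsets.

**Allele-frequency-change correlation.** For samples A (ancestral),
B (evolved), C (inbred lines) on one marker panel: the Pearson correlation of
Δ1 = p_B − p_A against Δ2 = p_C − p_B over markers polymorphic in A. A
negative correlation means line derivation tended to undo the frequency
changes of experimental evolution. Pearson was chosen because the comparison
is about linear reversal of frequency changes; Spearman would discard the
magnitudes that carry the signal.

## Linkage disequilibrium

For within-chromosome SNP pairs with allele frequencies in [0.05, 0.95]:
r² = D²/(p_i q_i p_j q_j). On phased data D = P(1,1) − p_i p_j counted
directly from gametes. On unphased data the Burrows composite estimator
D = (E[XY] − 4 p_i p_j)/2 (X, Y = ALT dosages) is used because it needs no
haplotype inference; operations that genuinely require phase refuse unphased
input rather than pseudo-phasing.

Decay with genetic distance c (cM) is summarised by least squares on Sved's
drift–recombination expectation E[r²] = 1/(1 + 4xc). x is fitted on the log
scale (positivity by construction; restarts over a geometric grid of starting
values), with the SE delta-transformed from the curvature of the fit.
Replicate populations are fitted separately and pooled by inverse-variance
weighting — a fixed-effects stand-in for a nonlinear mixed model with
replicate random effects, adequate for point comparison of decay rates and
chosen to keep the dependency surface small. Parameter recovery is verified
on synthetic pairs (x = 25, Gaussian noise σ = 0.05, 2000 pairs: within 10%).

## Neutral selfing simulator

Meiosis uses complete crossover interference: at most one crossover per
chromosome per meiosis, occurring with probability equal to the chromosome's
map length in Morgans (0.5 for 50 cM, capped at 1), the breakpoint placed
between consecutive SNPs with probability proportional to the inter-SNP cM
distance, and the transmitted arm chosen with probability 1/2. This is the
only reading of "at most one crossover on a 50 cM map" that reproduces both
the 0.5 crossover frequency and interval-weighted placement; it is verified
by tallying 10⁵ meioses (crossover frequency, chi-square GOF on placement)
and by the heterozygosity-halving law: selfed lineages lose half their
per-locus heterozygosity per generation regardless of recombination
(Ho_t = Ho_0·2^−t, checked at t = 1, 5, 13, 16 within 3 Monte-Carlo SEs).

`neutral_inbreeding_sim` conditions on an observed phased sample (16
individuals in the study design): each of n_sims = 1000 replicates samples
n_lines founders with replacement, selfs each lineage at N = 1 for 13 or 16
generations (no selection, no mutation, no outcrossing, no extinction),
jackknife-subsamples the lines to 16, and records He/Ho/he with chromosomes
analysed separately and averaged. The empirical 2.5/97.5 percentiles give the
drift-only 95% credible interval; an observed value is scored inside/above/
below. Diversity above the interval indicates balancing (overdominant or
associative-overdominant) selection during inbreeding; below, purging.
Seeding is strict: a fixed seed reproduces results bit-identically.

The number of lines sampled per replicate is a required configuration value
(50 in the bundled analyses, matching "usually more than 50 surviving
lines"); the rescue of failed reproduction during real line derivation
(effective size slightly above 1) is not modelled — strict N = 1 selfing is
simulated.

## Survival analysis

Line extinction is right-censored event data on a generation grid: extinct
lines contribute events, lines alive at the assay end (13 or 16 generations)
are censored there. The survival function is the Kaplan-Meier product-limit
estimate, computed via `lifelines` (Greenwood variance, log(−log S)
pointwise 95% bands) and checked against explicit risk-set bookkeeping at
1e−10. Blocks are pooled by default; hazard regression (Cox models) is out
of scope — curves and survival fractions are exported for external tools.

## Synthetic-data generator

The generator defines the study conditions. A founder pool of 16 distinct
haplotypes (alleles i.i.d. Bernoulli(1/2) per site — echoing a hybrid
population founded from 16 wild isolates) initialises N = 1000 diploids on
6 chromosomes × 124 evenly spaced SNPs of 50 cM each (744 SNPs, the scale of
the genotyped panel; test-scale runs use 6 × 20). Ten generations of random
mating recombine the pool into realistic linkage structure (burn-in), then
50 generations run at the target selfing rate s: each offspring selfs with
probability s, otherwise two distinct random parents outcross. Viability
selection is rejection sampling: a zygote survives with probability equal to
its multiplicative fitness across selected loci (recessive deleterious:
1, 1−hs′, 1−s′ for 0/1/2 copies; overdominant: homozygotes 1−s′; repulsion
lethals: pairwise loci with deleterious recessives on opposite phases). The
selfing rate keeps the symbol s; selection coefficients are written s′.
Sex-determination mechanics (males/females/hermaphrodites) are abstracted
into the scalar s, since every statistic implemented depends on mating
outcomes only.

`derive_lines` mimics the line-derivation protocol: each generation, up to
`brood_size` selfed zygotes are attempted and the first that survives
viability selection continues the line; a generation with no survivor is a
failed reproduction, and two failures of the same transition (one backup
attempt, the "failed twice" extinction rule) end the line. Neutral
derivations never go extinct and are vectorised in lock-step.
`generate_line_extinctions` produces geometric extinction times under a
constant hazard (S(t) = (1−h)^t), giving closed-form survival fixtures.

### The overdominance power check

The qualitative signature to reproduce: surviving inbred lines from
populations with balancing selection are *more* diverse than the drift-only
interval predicts. Heterozygosity loss under selfing is absorbing, so a line
stays heterozygous at a locus for 13 generations with probability
(1/(2−s′))^13 under brood-level viability filtering — negligible unless
homozygotes are effectively lethal. The power-check regime is therefore:
one symmetric overdominant locus mid-chromosome on each of the 6
chromosomes, s′ = 0.95 during population evolution (which keeps most
sampled individuals heterozygous at those loci), and lethal homozygotes
(s′ = 1) with brood size 150 (realistic for *C. elegans*) during line
derivation. Lines from heterozygous founders then retain heterozygosity at
every balanced locus while homozygous-founder lines die, and the effective
haplotype number among surviving lines falls above the neutral 95% interval
in ≈100% of trials; neutrally derived line sets fall inside it at the
nominal ≈95% rate. Deriving selected lines from a *neutral* sample instead
lands below the interval: survivors then descend only from the few
heterozygous founders, and that founder bottleneck outweighs the retained
heterozygosity — which is why the power check evolves the balanced loci in
the population first. The SNP-diversity (He) analogue of the signature is
much weaker in this generator: pooled allele frequencies are nearly
conserved by drift at these line numbers, so the He interval is tight around
the founder value and retention moves it little.

## Numerical choices and degenerate inputs

* Allele calls are int8 with −1 as the missing sentinel; frequencies over
  all-missing markers are NaN and flagged.
* g2 needs ≥ 2 individuals and ≥ 2 markers; locus pairs with < 2
  pairwise-complete individuals are skipped; a zero denominator yields NaN.
* The LD fit requires ≥ 10 pairs spanning a positive cM range;
  non-convergence after all restarts raises with diagnostics.
* Fis raises when no marker passes the He filter; jackknife with fewer
  individuals than the subset size falls back to the full sample with a
  warning.
* Zero-length maps (all positions equal) and single-marker chromosomes
  disable recombination naturally; windows never span chromosomes.
* All randomness flows through `numpy.random.Generator` objects seeded at
  the interface; nothing reads global RNG state.

## What the synthetic data do and do not show

The generator reproduces the features the statistics are sensitive to:
mixed-mating equilibrium Fis and g2, founder-limited haplotype diversity,
LD that decays more slowly the higher the selfing rate, heterozygosity decay
and drift during line derivation, and constant-hazard extinction. It does
not emulate real genotyping error, ascertainment of SNP panels, the
fog-2/xol-1 sex-determination genetics, population-size fluctuations during
culture, or mutation (none is expected over these time scales). Passing
tests therefore validate the estimators and the simulator against known
ground truth, not the biological conclusions of any particular experiment;
with real VCF/TSV genotypes, maps and line records, the same pipeline
computes the same quantities under the documented assumptions.

## Problem sizes in the bundled analyses

Population simulations run at N = 500–1000 for 30–50 generations; drift-only
intervals use 1000 simulation replicates of 50 lines; calibration uses 200
neutral trials and the power check 40–60 selected trials; the halving law is
measured on 2×10⁵ lineages. These sizes put Monte-Carlo error well inside
the tolerances asserted while keeping any single analysis in the minutes
range on one CPU.
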