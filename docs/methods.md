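# Methods

`strigops` re-implements, at desk scale, the population-genomic toolkit used
to contrast the surviving island kākāpō population against the extinct
mainland population: mutational-load statistics on polarized SNP matrices,
runs-of-homozygosity inbreeding estimates, and a non-Wright-Fisher forward
simulator of deleterious-mutation dynamics under contrasting demographies.
This note documents the models, the parameter choices that matter, the
numerical conventions, and what the synthetic data do and do not establish.

## Empirical statistics

### Data model and polarization

All statistics operate on a complete (no missing genotypes) biallelic SNP
matrix of **derived-allele dosages** (0/1/2 per diploid individual), aligned
1:1 with per-site annotations: a GERP conservation score, a SNPeff-style
impact category (LOW / MODERATE / HIGH / MODIFIER), and an ancestral-allele
call from an outgroup. Polarization re-expresses VCF ALT dosages as derived
dosages: unchanged where the ancestral allele is the REF, complemented
(0↔2) where it is the ALT. Sites with an unknown ancestral allele, or one
matching neither REF nor ALT, are dropped and tallied rather than guessed.
Sites are 1-based inclusive internally (the VCF dialect); BED masks are
0-based half-open and converted at the boundary. Statistics refuse matrices
with missing genotypes — the analysis design uses only sites covered in all
individuals, so no bootstrapping over allele counts is needed.

### GERP-weighted relative load

Per individual,

    load = Σ_{sites with GERP > 2} dosage × GERP  /  Σ_{all sites} dosage

with heterozygous sites contributing one derived allele and
homozygous-derived sites two. The denominator includes *all* derived
alleles, including those at sites below the numerator threshold; the
alternative reading (restricting the denominator to sites with GERP < 1)
changes only the scale, not the population contrast, and is not used.
Heterozygotes count at full weight regardless of dominance; an h-weighted
variant is deliberately not the default because the load definition is a
descriptive allele count, not a fitness prediction.

### Impact-category counts and tests

Counts of heterozygous and homozygous-derived genotypes per individual and
category, with Welch two-sample t tests (two-sided,
Welch–Satterthwaite degrees of freedom) between two named populations for
het, hom and total-allele counts. Significance stars follow the usual
figure convention (\*\*\* p < 0.001).

### R_xy

For a variant category C, with per-site derived-allele frequencies
f\_i^x = d\_i^x / n\_i^x,

    R_xy = Σ_{i∈C} f_i^x (1 − f_i^y)  /  Σ_{i∈C} f_i^y (1 − f_i^x).

R_xy = 1 means no frequency change; R_xy < 1 a relative deficit in
population x (the orientation used when x is the island population and y
the mainland reference). Site eligibility defaults to at least one derived
allele observed **in each** population ("intersection"); a "union" switch
(≥1 derived allele across the pooled populations) is provided because the
eligibility sentence in the source protocol is ambiguous, and the CLI can
report both. Uncertainty comes from a delete-one-block jackknife over
consecutive blocks of 1,000 eligible sites in genome order; a final short
block is kept if it reaches half the block size, else merged into its
predecessor. The 95% CI is the normal approximation estimate ± 1.96 SE.
With a zero denominator the result carries an explicit `undefined` status;
with fewer than two blocks the point estimate is returned with `no_ci`.

### Genotype distances and neighbor joining

Per site, d = 0 for identical homozygotes, 0.5 if either genotype is
heterozygous, 1 for opposite homozygotes. D_ij is the mean over sites
(normalizing by the number of compared sites M, so D ∈ [0, 1]); a physical
region length can be used instead by option, since the "region length" in
the printed formula is not defined numerically. Neighbor joining
(Saitou–Nei) is delegated to scikit-bio; the package's contribution is the
distance definition, and tests verify NJ inverts additive matrices exactly.

### Diversity and heterozygosity

Windowed nucleotide diversity uses the unbiased per-site estimator
2f(1−f)·n/(n−1) (n = called alleles), summed per window and divided by the
window length in bp (default 10 kb windows tiling each chromosome's covered
range). Individual heterozygosity is reported as heterozygous sites per kb
of covered span.

### Runs of homozygosity

The detector reproduces the windowed PLINK rule with the study's
parameters: 100-SNP windows sliding one SNP at a time, a window is
homozygous with ≤ 1 heterozygous call, a SNP is in a homozygous segment
when ≥ 5% of the windows covering it are homozygous, and candidate
segments must have ≥ 25 SNPs, ≥ 100 kb, mean density ≤ 50 kb/SNP,
inter-SNP gaps ≤ 1,000 kb and ≤ 750 heterozygous calls. A stricter
sensitivity variant (1 het per segment, 100 kb/SNP density, 500 kb gap) is
available as `RohParams().strict()`. Conventions stated explicitly because
they are not printed in the protocol: only windows fully inside a
chromosome count (edge SNPs overlap fewer windows); candidates are split at
over-limit gaps *before* the SNP-count/length filters; segment boundaries
are the first and last SNP coordinates. The detector is verified
exhaustively against a plain-loop oracle on fixtures up to 5,000 SNPs.
F_ROH sums segment lengths at ≥ 100 kb and ≥ 2 Mb thresholds over a genome
length that defaults to the span covered by the analyzed sites (a fixed
assembly length can be supplied).

The LoF-in-ROH contrast computes, per individual, the count of HIGH-impact
sites carried (dosage ≥ 1; a hom-only switch exists) inside vs outside that
individual's ROH, each normalized by homozygous LOW-impact (synonymous)
sites in the same regions, compared by a paired two-sided t test.
Individuals with an empty normalizer are excluded and reported.

## Forward simulator

### Model

A non-Wright-Fisher, individual-based, age-structured model with one
simulation step = one year. Each year:

1. **Reproduction.** Every mature female pairs with one mature male drawn
   with probability proportional to (age − maturity age + 1), so older
   males pair more readily. Clutch size is round(Normal(3, 1.5)) truncated
   at 0 — mostly 2–4, occasionally 0. Offspring are male with probability
   2/3 (the observed skew), age 0, with maturity drawn uniformly from 7–11
   years (females) or 5–7 years (males). Each offspring receives one
   recombined gamete per parent plus Poisson(μ × genome bp) new mutations
   per gamete.
2. **Aging.** Everyone ages one year.
3. **Survival.** Survival probability is
   base(age) × min(1, K/N) × w, where base is 0.55 in the first year of
   life and 0.97 per adult year (death above age 90), min(1, K/N) is the
   density regulation toward the carrying capacity K, and w is the
   multiplicative genetic fitness Π(1+s) over homozygous ×
   Π(1+hs) over heterozygous mutations, clamped to [0, 1].

Generation time is **emergent**: nothing in the model sets it directly.
The maturity ranges, clutch distribution, pairing rule and sex ratio are
fixed by field observation; the survival schedule is the genuinely free
part and was calibrated once so that the realized mean parental age at
offspring birth lands near the published emergent value of ~16 steps /
16.5 years. With the defaults above the model yields ≈ 16.2–16.4 years.

A caveat worth stating: the census-to-effective-size ratio that emerges
from this realization is ≈ 3.3–4.0 (Ne measured from neutral-marker
heterozygosity decay per realized generation), somewhat above the 2.8
used to set census sizes in the original design. Generation time and
census/Ne trade off structurally here: because density regulation
multiplies survival at every age, equilibrium adult lifetimes are
near-geometric, which fixes the variance in lifetime reproductive success;
schedules that push census/Ne down to ~3.0 push generation time up to
18–19 years. We prioritized the generation-time match and report the
ratio as measured.

### Genomes, DFE and load

Genomes are 3,291 genes × 1.5 kb over 23 chromosomes (4,936,500 bp per
individual, ~20% of the exome), genes evenly spaced over a 1.16 Gb physical
span; recombination occurs only between genes with switch probability
1 − exp(−r·d) per boundary (r = 10⁻⁹/bp), never within genes; chromosomes
assort independently. The per-bp per-generation mutation rate is
1.33 × 10⁻⁸ (0.89 × 10⁻⁹/site/year × 15-year generations). New mutations
are neutral : deleterious at 1 : 2.31; deleterious effects are −Gamma with
mean 0.024 and sd 0.14 (shape ≈ 0.0294, scale ≈ 0.8167), floored at
s = −1 (lethal); dominance h ∈ {0, 0.25, 0.5} is fixed per run. Mutation
classes: weak (−0.001 ≤ s < 0), mild (−0.01 ≤ s < −0.001), strong
(s < −0.01). Note the floor slightly shrinks the realized moments (mean
−0.021, sd 0.105); the *distribution* parameters are the printed ones and
the sampler exposes un-floored draws for moment checks.

Additive genetic load is reported as a positive magnitude:
Σ|s| over homozygous + Σh|s| over heterozygous mutations, plus a
population-level fixed-load term. Fixed mutations are stripped from
haplotypes with their |s| accumulated into that term (and the cached
fitnesses renormalized), leaving every individual's total load exactly
invariant at the step of removal — this is tested to machine precision.

### Scenarios, burn-in and desk scaling

Four carrying-capacity trajectories target long-term Ne of 10,000
(Stable), 6,000 (Mainland), 1,000 (Stewart Island) and 100 (Extreme), with
census K = 2.8 × Ne. Declines interpolate K exponentially from the
equilibration level over the first 20% of the scenario steps, then hold —
the published trajectories are schematic, so a smooth decline with that
time constant is a package choice.

Burn-in follows the standard rescaling trick: a fast phase at N/10 with
μ, r and s multiplied by 10 (diversity equilibrates at the same π level),
then the stored coefficients are divided back, fitnesses recomputed, and
the population equilibrates at full K until the trailing-window linear
trend of π is statistically flat (two-sided slope test, α = 0.05, window
150 steps, checked every 50). A run that hits the step cap is returned
with an explicit non-stationary flag. The tree-sequence coalescence check
of the original pipeline is replaced by this π-stationarity criterion,
which is the observable the protocol itself tracks.

A single desk-scale divisor (default 20 in tests and the acceptance
script) divides all K values and the gene count while μ is scaled up to
preserve the per-genome mutation input. Problem sizes used here: scenario
runs of 2,500 steps at census K ≤ 1,400 with 10 replicates per arm for the
Stewart-vs-Mainland contrast; the Extreme scenario is exercised at divisor
10 because at divisor 20 its terminal census (14 birds) goes stochastically
extinct. At this scale Ne·s is 20-fold smaller than in the full model, so
drift-driven signals (diversity loss, hence fewer segregating deleterious
alleles in the small population; load increase under Extreme decline)
reproduce robustly, while the subtler purging-vs-drift ordering of load
between Stewart Island and Mainland does not always resolve — the
replicate contrast is therefore tested on deleterious-allele counts, which
is also where the published significance statement is made.

All randomness flows from one seeded `numpy` Generator per run; replicate
r of a batch derives its seed from the base seed and r, and seeds are
recorded in outputs.

Sampled simulated genomes can be exported as an already-polarized genotype
matrix (and VCF) with sites at their simulated coordinates, so the ROH,
diversity and distance statistics run directly on simulation output.
Functional impact categories are deliberately not fabricated for simulated
sites — the simulator's selection classes are not SNPeff categories.

## Synthetic data

The generator emulates the *statistical structure* the empirical analyses
assume: two populations with complete biallelic genotypes drawn
binomially from per-site frequencies (shared Beta-distributed base
spectrum), impact categories assigned independently of frequency, a GERP
track with a configurable constrained fraction, ancestral-allele calls
(REF by default; a configurable fraction flipped to ALT to exercise
polarization), a planted per-category island frequency deficit (island
frequencies multiplied by a factor, giving a known truth R_xy), and
planted long homozygous tracts in island individuals (forced homozygous at
the population frequency). Positions are uniform at ~1 SNP/kb so the ROH
window parameters operate at realistic density. Generation is a pure
function of the spec; the same spec yields byte-identical files.

What the synthetic data do **not** model: linkage disequilibrium beyond
the planted tracts, coalescent genealogy, sequencing error, reference
bias, or any correlation between impact category and frequency other than
the planted deficit. Passing recovery tests therefore demonstrates
estimator correctness (the statistics recover what was planted), not
robustness to the correlated noise of real resequencing data.

Note on the planted R_xy: for a deficit factor c, the truth value is
Σc·f(1−f) / Σf(1−c·f) over category sites, which approaches c only in the
rare-allele limit; the truth table records the exact value and recovery
tests compare against it.

## Numerical and interface choices

- Jackknife blocks are consecutive eligible sites in genome order; ties
  and short final blocks handled as described above.
- The ROH window fraction uses only fully-contained windows; a chromosome
  with fewer SNPs than one window yields no calls (warned).
- Welch tests return NaN with fewer than two observations per side;
  scenario comparisons with identical replicate sets report p = 1.
- Output TSVs carry a header comment with package version, seed and a
  configuration hash.
- The CLI (`strigops synth | empirical | roh | rxy | simulate | compare`)
  is a thin orchestration layer; the library functions are the interface.

## Known limitations

- Census/Ne sits ~30% above the design factor 2.8, as discussed above.
- The mortality schedule, decline shape and mast-year phenology are not
  printed in the source protocol; the choices here are documented single
  calibrations, not inferences.
- Desk-scale runs cannot reproduce the absolute published numbers
  (F_ROH of 53%/15%, 17.6/34.1 LoF per genome, 1.1×/1.9× load ratios),
  which depend on access-controlled genomes and full-scale simulations;
  the package reproduces formulas, worked examples, emergent life-history
  statistics and qualitative scenario contrasts.
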