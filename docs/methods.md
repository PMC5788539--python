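# Methods

## The biological setting and what the package models

A highly selfing nematode metapopulation consists of a small number of
genome-wide homozygous multilocus haplotypes — clonal genotype labels —
distributed over ephemeral resource patches (rotting fruits or stems).
Each patch is a *deme*: it is colonized by a few immigrating dauer larvae,
booms by selfing reproduction, and disperses. Outcrossing is rare, so
heterozygotes (F1s of two haplotypes) and recombinant mosaics are
exceptional individuals, and almost all information is carried by which
haplotypes co-occur where.

`demeseed` implements the analysis chain from a filtered genotype matrix to
a colonization-bottleneck estimate, plus the statistics around it. The
input is a biallelic SNP matrix with calls in {hom-ref, het, hom-alt,
missing} and sample metadata (location, date, substrate, 2-D metre
coordinates).

## Haplotype calling (`haplocall`)

**Site filters.** A site is kept when its call rate is at least
`min_call_rate` (default 0.7) and its heterozygous fraction among
non-missing calls is at most `max_het_fraction` (default 0.5). In selfing
populations a mostly-het site is the signature of mismapping, duplications
or PCR error, not of real variation; "mostly" is read as a strict majority.
Within a 36-bp RAD locus, SNPs whose calls define identical partitions of
the individuals (fully in phase, including repulsion-phase coding) carry
one signal; only the lowest-position one is retained. Two sites with no
mutually called individual cannot be shown to be in phase and are both
kept.

**Clustering.** Individuals without het calls are grouped by exact identity
of their non-missing calls: joining a group requires agreement with every
member at all mutually called sites and a mutual overlap of at least
`min_overlap` (default 0.5) of all sites. Individuals are processed
most-complete-first and join the largest compatible group, so an individual
carrying a private genotyping error founds a group that stays a singleton
rather than seeding a spurious major haplotype. Groups of two or more
individuals become major haplotypes, named `H<loc>1, H<loc>2, …` in
descending individual count; per-site consensus is the majority call with
ties broken toward hom-ref (deterministic). Singletons within
`minor_variant_max_diff` (default 2: one real mutation plus one error
site) of a major become its minor variants (`H<loc>1-1, …`); singletons
farther from every group become majors of their own; singletons with
insufficient overlap everywhere are unassigned.

**Heterozygotes.** For a het-bearing individual, the pair (h1, h2)
explaining the most het calls is selected; the individual is F1(h1, h2)
when its het calls cover at least `f1_min_het_fraction` (default 0.9,
reading "heterozygous at nearly all diagnostic sites" as ≥ 90%) of the
h1/h2-diagnostic sites where it has data, and its remaining calls match the
shared consensus exactly. Anything less is flagged contaminated: partial
heterozygosity is the signature of low quality or partial PCR
contamination, not of a real cross.

**Recombinants.** A homozygous individual that matches no catalog entry is
painted against its best-matching haplotype (the background) and the
haplotype that best explains its discordant sites (the donor — which need
not be the overall second-best match). Maximal runs of at least
`min_block_sites` (default 3) consecutive diagnostic sites from the donor
become segments with breakpoint intervals between the flanking diagnostic
positions. An isolated discordant site is treated as mutation or error and
falls back to the minor-variant logic; this is what separates a genuine
chromosomal mosaic from a one-SNP variant. In the full pipeline the
recombinant check runs on singleton majors before naming, so a mosaic is
reported as a recombinant rather than founding its own haplotype.

## Spatial co-occurrence and the under-sampling correction (`cooccur`)

**Transect projection.** Where sampling follows a band, a single coordinate
is obtained by orthogonal projection onto the first principal axis of the
sample positions, oriented to increase southward with the northmost sample
at 0 m. Note the orientation rule references the compass, so a rotated
copy of a point cloud can yield the reflected position multiset; distances
along the transect are invariant.

**Co-occurrence curve.** An *event* is a pair (eligible sample s, unordered
haplotype pair {h1, h2}) such that each haplotype is observed in at least
one eligible sample within the distance threshold of s (s included) and at
least one of the two is observed in s itself; the event co-occurs when both
are. Eligibility requires at least `min_n` genotyped individuals (curves
are reported for `min_n` ∈ {2, 6} by default) and a non-excluded substrate
(leaf litter, soil, grass, moss and snails are excluded by default — they
reflect transport, not boom-phase demes; samples with unknown substrate are
excluded whenever an exclusion list is active). The event definition is a
package decision — only the plotted quantity, not its enumeration, is
standard — and is locked by a hand-enumerated fixture test. Distances are
Euclidean on (x, y), falling back to absolute transect-position differences.
Thresholds are inclusive. Minor variants count under their parent major;
an F1 attests both parents locally and contributes both; recombinants
count under their background haplotype.

**Observed multi-genotype proportion.** Among eligible samples that have
two haplotypes locally available within `mixing_radius_m` (default 1 m),
the fraction whose own individuals show at least two haplotypes.

**MLE correction.** A sample with a single observed genotype among n_j
genotyped individuals may still hold two. With within-sample genotype
frequency f ~ U(0, 1), the miss probability is E_f[f^{n_j} + (1-f)^{n_j}]
(exactly 2/(n_j + 1)). The likelihood of the single/multi flags,

L(θ) = Π_multi θ(1 − miss_j) × Π_single [(1 − θ) + θ·miss_j],

is maximized over θ ∈ [0, 1] by golden-section search to 1e-6. In the
Monte-Carlo mode each replicate re-estimates miss_j from 10,000 fresh
uniform draws (the only stochastic element; the replicate SD is the
reported uncertainty), and the estimate is the replicate mean; the
closed-form mode substitutes 2/(n_j + 1) and is deterministic — it serves
as the oracle for the Monte-Carlo path. θ̂ is flagged non-identifiable at
the boundary (all samples multi, or all n_j = 1, where singles carry no
information).

## The colonization model (`founder`)

Founder number i per deme is Poisson(λ) conditioned on i ≥ 1; the source
pool holds two genotypes at frequencies f and 1 − f (the model is
two-genotype by construction; f is the frequency among potential
immigrants). The single-genotype probability is the truncated series given
in the README, evaluated by the multiplicative recurrence
term_i = term_{i−1}·λ/i (no factorials) with `expm1`-stable denominators;
a monomorphic source (f ∈ {0, 1}) returns exactly 1. The analytic limit

p_single = (e^{−(1−f)λ} + e^{−fλ} − 2e^{−λ}) / (1 − e^{−λ})

is exposed separately as the correctness oracle; the truncated series
agrees with it to ≤ 1e-10 for λ ≤ 100 (the Poisson mass beyond i = 200 is
negligible there).

λ solves p_single(λ, f) = 1 − p_multi by bracketed bisection to
|Δλ| ≤ 1e-8 on (1e-6, 200]; p_single is strictly decreasing in λ so
bisection is exact. The upper bound matches the summation cap. For extreme
f the equation has no root below the cap and the estimate is clipped at
200, flagged: this clipping is normative — it is what bounds the
heavy-tailed uniform-prior mean (≈ 11 with ~0.3% of trials clipped).
Monte-Carlo prior fits draw one f per trial (frequencies vary between
trials, not within one) and report mean and median of the per-trial λ; the
median of an even trial count is the midpoint of the central order
statistics. Reported precision follows convention: one decimal for fixed-f
fits, nearest integer for Monte-Carlo summaries; full precision is always
in the result object. Under the per-trial interpretation the beta(2,2)
median computes to ≈ 3.4 — only the beta mean (≈ 4.8) is treated as a
quantitative reference point.

## Population statistics (`popstats`)

**Spectra.** Individual-based proportions (summing to 1 per group, F1s as
their own category) and positive-sample-based proportions (a sample can
carry several haplotypes, so these can sum to > 1), grouped by location
and optionally year.

**Temporal heterogeneity.** Pearson's chi-squared statistic against a
Monte-Carlo null of tables drawn uniformly with both margins fixed
(Patefield's algorithm via `scipy.stats.random_table`); the P-value uses
the add-one estimator (1 + #{sim ≥ obs})/(n_sim + 1), so P ≥ 1/(n_sim+1)
and never 0.

**F-statistics.** Weir–Cockerham (1984) variance components a (among
groups), b (among individuals within groups) and c (within individuals)
are computed per locus from subpopulation allele frequencies, observed
heterozygosities and sample sizes; multi-locus estimates are ratios of
summed components (the "weighted" estimator), never means of per-locus
ratios. F1 heterozygotes contribute both alleles. The hierarchical
extension (individuals ⊂ samples ⊂ locations) is a nested moment ANOVA on
allele indicators with Searle's unequal-size coefficients — the lowest
level is always balanced (two alleles per called individual), which keeps
the coefficients simple — reporting location-level, sample-in-total and
sample-within-location indices as ratios of summed components. The
two-level estimator is verified against hand-computed mean-squares ANOVA
values on small worked instances; published F-statistics from the original
survey require its per-individual supplementary tables and are not
reproduced here.

**Divergence.** Pairwise haplotype divergence divides differing consensus
sites by the surveyed base-pair total (default 30 bp × 7760 RAD fragments
= 232,800 bp), under-estimating genome-wide diversity by construction
(stringent filtering, in-phase collapsing).

## The synthetic generator (`sim`) — what it does and does not emulate

Defaults are the study conditions the pipeline targets: three major
haplotypes at intermediate pool frequencies (0.21/0.46/0.33), founder
counts zero-truncated Poisson with λ = 2.9, one sample per deme with 2–12
genotyped individuals, outcross (F1) probability 0.009 per individual
(heterozygotes under 1%), recombinant probability 0.003, 275 biallelic
sites over chromosomes I–V and X, 5% missing calls, 0.2% call errors
(flips to a uniformly chosen different state), and sample positions in a
~200 m × 10 m band. Haplotype consensus vectors are random draws with a
minimum pairwise distance of 5 sites so clustering is identifiable (real
major haplotypes differ by tens of SNPs). Founder lineages expand equally
— sampled individuals draw their lineage uniformly over founders — a
declared minimal assumption, not an observed growth model. F1 and
recombinant individuals require two distinct founder genotypes in the
deme, so their realized frequency sits slightly below the nominal rate at
small λ. All randomness flows from one integer seed through spawned
sub-streams, so changing the noise level does not reshuffle the
demography.

Not emulated: generation timelines, dauer biology, migration kinetics
between demes (demes are independent), selection, and mutation during the
simulation. Passing recovery tests therefore validates the inference
machinery under the model's own assumptions — not robustness to ecological
structure the generator does not contain.

## Problem sizes and determinism

Recovery tests run at the sizes that make their error bars meaningful:
2000 demes for founder-λ recovery (λ ∈ {3, 5, 10}, within 20%), 5000 demes
for pool-frequency conservation, 200 samples for the θ̂ correction
(sampling SD ≈ 0.054, estimated by an independent Monte-Carlo study of the
data-generating process), 10⁵–10⁶ draws for Monte-Carlo convergence
checks, and 10⁵ simulated tables for the chi-squared null (where the
fixed-margins null is compared with the asymptotic tail only on
large-count tables, since the conditional distribution is discrete).
Simulations use a compact 12-site layout where only demography matters.
Every stochastic routine takes an explicit seed and is bit-reproducible;
pipeline reports contain all seeds and parameters and carry no timestamps,
so two runs of the same config are identical.

## Known limitations

- The clustering is greedy (largest-compatible-group); heavy missingness
  combined with genotyping error can still split or merge groups, and one
  residual spurious small group on noisy data is possible. The error-free
  partition is recovered exactly.
- The co-occurrence event definition conditions on pairs and samples
  jointly; alternative enumerations (per-pair only, per-sample only) would
  give different denominators and are not implemented.
- The founder model is two-genotype; demes carrying three or more
  haplotypes are counted simply as multi-genotype.
- Transect orientation depends on the compass convention described above.
- The hierarchical F-statistic is a moment estimator; no confidence
  intervals (jackknife/bootstrap over loci) are provided.
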