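# Methods

This note documents the models, conventions, and numerical choices behind
ploidykit, and what its simulator does and does not emulate.

## Coordinates and genome model

All positions are 1-based inclusive (VCF convention). A `GenomeSpec`
carries per-chromosome physical length, centromere position, and a
monotone piecewise-linear bp→cM genetic map; masks and maps interpolate
linearly between anchors. Two specs ship with the package:

- **GRCh37-like default** — 22 autosomes + X with GRCh37 lengths and
  centromere positions. The genetic map uses female per-chromosome totals
  (autosomal sum ≈ 43.8 Morgans, so a simulated gamete carries ~44
  crossovers, inside the 41–46 band reported for human preimplantation
  embryos) with three linear segments per chromosome: a ±20 Mb
  pericentromeric band damped to 40 % of the chromosome-average rate, and
  distal segments rescaled so the chromosome total is preserved. This is a
  deliberately simple stand-in for a published female map; any map can be
  supplied as a TSV of (chrom, bp, cM) anchors.
- **Toy genome** — four chromosomes (100/80/60/40 Mb), mid-chromosome
  centromeres, uniform 1 cM/Mb. Used for fast tests; note that a 10 Mb
  pericentromeric window on this genome is 20 cM of map, so
  analyses that rely on pericentromeric crossover suppression (the
  isodiploidy screen) are validated on the GRCh37-like spec instead.

Pericentromeric masks support a genetic radius (the 5 cM convention used
for meiotic-phase calls, computed on the spec's map — in effect the female
map, since the errors analyzed are maternal) and a physical radius (the
10 Mb convention used by the isodiploidy screen). Both are configurable.

## Meiosis simulator

Each chromosome enters meiosis as a bivalent of four chromatids. Chiasmata
are Poisson with mean 2L (L the map length in Morgans) per bivalent, placed
uniformly on the genetic map, without interference — the downstream
statistics are insensitive to interference, and no interference model is
part of the analyses being exercised. No obligate chiasma is enforced.
Each chiasma joins one chromatid from each homolog; chromatid identity
follows the centromere, so an exchange moves the segment distal to the
breakpoint on its arm (and any earlier breakpoints inside that segment).

Ground truth distinguishes **chromatid breakpoints** from **state
switches**: after several exchanges a chiasma can swap segments of
identical ancestry, which changes nothing at the sequence level. The
simulator therefore evaluates ancestry immediately left and right of every
chiasma (via sentinel positions) and records only true flips of the
retained pair's BPH/SPH state as `truth_switches`.

Segregation modes: normal meiosis retains one chromatid; whole-genome MI
failure retains one chromatid from *each* homolog (pericentromeric alleles
from both homologs — BPH — on every chromosome); MII failure retains both
sisters of one homolog (pericentromeric SPH). Recombination-failure
oocytes are the same with zero chiasmata; an isodiploid egg is an MII
failure fertilized by nothing. Paternal meiosis is simulated only as
gametes (one, or two for paternal triploidy), since no paternal crossover
mapping is consumed downstream.

Observation model (`ErrorModel`): depth is negative-binomial with mean
360× (dispersion 4, truncated at 10,000×; only the mean and range of the
platform are known, the dispersion is a knob); alt reads are binomial in
the true allele fraction with a 0.2 % per-read mis-read rate; discrete
genotype-call errors are injected at rate ε = 0.42 % by re-drawing the
site's dosage class uniformly among the other classes — matching how a
flat per-SNP error rate enters the recombination error argument. ε applies
to the embryo sample; parents carry read noise only.

## Genotype calling and filters

Diploid calls from BAF: hom-ref < 0.05, het 0.2–0.8, hom-alt > 0.95, with
the gaps (0.05–0.2, 0.8–0.95) as explicit no-calls. (The clinical
pipeline's description assigns both tails to "homozygous reference"; the
upper tail is read as homozygous *alternate* — the only reading under
which hom-alt calls exist.) Triploid dosage bands sit on the 1/3 and 2/3
allele-ratio modes: [0, 0.10) AAA, (0.20, 0.45) AAB, (0.55, 0.80) ABB,
(0.90, 1] BBB; the inter-band gaps absorb noise rather than forcing calls.
Haploid samples use the homozygous tails only.

Site filters: biallelic, depth strictly > 20× in all three samples,
autosomal. The 5–95 % embryo-BAF window is applied for
heterozygosity-fraction work (isodiploidy) but **not** for trio
concordance analysis, where homozygous embryo calls (AAA) are required
SPH evidence; one config switch (`SiteFilters.embryo_baf_window`) controls
this, defaulting to off.

The genome-wide ploidy classifier calls haploid when the het-BAF (0.1–0.9)
fraction falls below 0.02, triploid when het-band BAF mass concentrates
within ±0.08 of 1/3 or 2/3 rather than 1/2, diploid otherwise; thresholds
are config defaults tuned on the simulator (the clinical caller is
proprietary). Sex karyotypes are read from supplied X/Y copy-number
values; CN segmentation itself is out of scope.

## Origin scores

Natural logs throughout (only the sign is interpreted). A zero count on
one side yields ±∞ with a flag rather than a pseudocount; a pseudocount
option exists for tiny panels. Calls use the strict sign (threshold 0);
an indeterminate band is configurable. Pericentromeric evidence from all
chromosomes is pooled into one score (the closest reading of a genome-wide
score); a per-chromosome breakdown is emitted for inspection. For haploid
embryos only the parental score is computed — the erring parent left no
material to type, so MI/MII is unidentifiable.

## Recombination analysis

The delta track is defined at SNPs where the erring parent is heterozygous
and the other parent homozygous: −1 = consistent only with BPH, +1 = only
SPH, 0 = uninformative (or consistent with neither — a genotyping error;
such sites stay in the track but are excluded, by default, from the
sliding windows so that a window always spans three *informative* SNPs).
A state is assigned where the 3-SNP mean reaches exactly ±1 (all three
agree), matching the three-consecutive-errors argument (0.0042³ ≈ 7×10⁻⁸);
intermediate means leave the state unchanged. A switch yields a window
from the last SNP of the old state's run to the first SNP of the new
one's. Window counts therefore undercount true crossovers wherever an
inter-crossover gap holds fewer than three informative SNPs — the expected
behavior at sparse panel density, and the reason detected genome-wide
counts sit below the 41–46 crossovers a dense assay would find. Usable-SNP
counts per chromosome are emitted alongside raw counts; any further
normalization is left to the caller.

The genotyping-error rate is estimated where **both parents are
homozygous**: there the triploid embryo dosage is fully determined, so
every wrong class is detectable and the estimate is unbiased. Restricting
to mother-heterozygous informative sites would detect only one of the
three wrong classes (~ε/3).

The array-style segmenter smooths a binary het/hom track with a 50-SNP
moving average from the centromere outward: BPH at window mean ≥ 0.90, SPH
at ≤ 0.50, intermediate means keep the previous label; each label change
is pulled back half a window so the breakpoint sits near where the state
actually flipped, and arms shorter than one window are labeled from what
is available with a low-confidence flag. The overlap permutation test
re-places each window uniformly on its chromosome (same size) and reports
p = (1 + #{null ≥ observed})/(R + 1).

## Isodiploidy screen

Heterozygosity is BAF ∈ [0.1, 0.9]; the total fraction includes autosomes
and X (screening targets 46,XX-called samples), the pericentromeric
fraction uses a 10 Mb physical radius. A sample screens positive when its
total het fraction is below the cohort mean AND one-sided exact binomial
tests reject (α = 0.05) that its pericentromeric het count matches (i) the
cohort's mean pericentromeric rate and (ii) its own total fraction. The
underlying clinical procedure named no test; the exact binomial pair is
the weakest-assumption implementation of the described logic, and both
thresholds are configurable. Expert review of PGT plots is replaced by an
automatic stand-in — a run of ≥ 10 consecutive homozygous pericentromeric
SNPs on ≥ 20 chromosomes plus a fingerprint check (fraction of co-called
sites sharing an allele; opposite homozygotes are the informative
disagreements) — which approximates but cannot reproduce manual
adjudication.

## Cohort statistics

Logistic regression is embryo-level (each embryo one Bernoulli trial) of
abnormality on age covariates, reporting per-year odds ratios with Wald
CIs; cycles are not modeled as clusters by default. SART strata are
<35, 35–37, 38–40, 41–42, >42 with left-inclusive boundaries. The
recurrence test permutes abnormality labels within each stratum while
preserving every cycle's embryo count; the statistic is the number of
cycles with ≥ k abnormal embryos, p = (1 + #{null ≥ observed})/(R + 1)
with R = 10,000 by default, Bonferroni-corrected over all populated
(stratum × k) cells. Compounding a per-year OR across a decade uses
OR^Δage; note 1.059¹⁰ ≈ 1.77, so a "76 % higher at 40 vs 30" phrasing
implies an unrounded OR slightly below 1.059 — the closed form is
implemented, no attempt is made to match 76 exactly.

## Synthetic cohorts

`simulate_cohort` draws maternal ages from Normal(35.65, 2.9) truncated to
[20, 47]; paternal age = maternal + Normal(1.6, 3) (the offset spread is a
choice made to induce the maternal–paternal collinearity the multivariate
analysis resolves); embryos per cycle = 1 + Poisson(3.8) (mean ≈ 4.8,
matching ~96,000 embryos per 20,000 cycles); per-embryo abnormality is
logistic in maternal age with OR 1.046/year anchored at a 1.13 % rate at
the mean age; abnormal embryos are 83 % triploid; triploids are maternal
with probability 0.946 and MI with probability 0.333; haploids are
paternal-error with probability 0.989. Sex karyotypes follow the same
generative model the moments estimators invert, so the two modules share
one truth. An optional per-couple odds multiplier creates recurrence
clusters.

## What the simulator does not emulate

No mosaicism, segmental events, mitotic errors, or single-chromosome
aneuploidy (whole-genome events only); no linkage disequilibrium or
realistic allele-frequency spectrum (frequencies are Uniform(0.1, 0.9));
no crossover interference; no amplicon-specific depth biases or
allele-specific amplification bias; paternal meiosis is not crossover-
mapped. Passing tests therefore demonstrate correctness of the estimators
and detectors under the stated error model, not robustness to platform
artifacts absent from that model.

## Problem sizes in the test suite

The acceptance properties run at sizes chosen to exercise the asymptotics
without waste: 200 trios at 600 SNPs on the toy genome for the
detector-vs-oracle equivalence; 100 trios at 800 SNPs for origin-call
accuracy; a 2,001-sample screen at 800 SNPs on the GRCh37-like genome;
20,000 cycles (~96,000 embryos) for the odds-ratio recovery; 10⁵
permutation replicates for the analytic overlap check. Closed-form checks
(moments, Clopper–Pearson, exact binomial) are exact.

## Known limitations

- The moments estimators assume the generative model (independence of
  parental and meiotic origin, equal meiotic split in both sexes); raw
  estimates outside [0, 1] are flagged `valid=false`, never clamped, and
  small-N estimates are noisy because the MI numerator is a difference of
  large counts.
- Bootstrap CIs for derived moments quantities are an extension beyond the
  simple-proportion intervals and are labeled as such; the MI component's
  bootstrap distribution is heavy-tailed at small N.
- The 3-SNP window detector cannot see crossovers separated by fewer than
  three informative SNPs, and window endpoints are SNP positions, not
  breakpoint estimates.
- The isodiploidy screen's recall degrades when pericentromeric site
  counts are small or the pericentromeric window is a large fraction of
  the genetic map (see the toy-genome caveat above).
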