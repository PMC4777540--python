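# Methods

## The measurement model: collapsed-paralog variant profiles

The central major urinary protein (MUP) genes are a tandem array of >98%
identical paralogs, so short reads cannot be assigned to individual gene
copies. Instead, all reads from the family are aligned to one representative
paralog and each site is summarised as the *percentage of reads carrying the
non-reference base* in each individual. This representation deliberately
mixes allelic and paralogous variation: for the scent phenotype it does not
matter whether a novel isoform arose as an allele or a paralog. The package's
core container, `VariantProfileMatrix`, holds these percentages (on the
0-100 scale, as the source tables print them) with a per-cell mask.

Variant calling from per-site base counts applies a hard coverage rule:
base counts below `min_reads` (default 100, against typical >7000x coverage)
are treated as sequencing noise and contribute nothing; a site whose total
coverage falls below the threshold is masked. Whether the threshold applies
per base (default) or only to the site total is configurable, since marginal
coverage makes the two genuinely different. When more than one alternative
base clears the threshold their counts are summed into a single
non-reference percentage with a warning; the tables this mirrors list one
alternative per site. Coordinates are opaque labels (no liftover, no strand
logic), and the bundled table transcriptions preserve the printed row order,
which for a minus-strand gene is *decreasing* in genomic coordinate.

Blank cells in transcribed tables read as 0 and unmasked: the printed tables
use blanks for absence, and masking information is not printed.

## The pairwise difference index

For individuals *i*, *j* and a site class *C*:

PD'(i,j) = Σ_{k∈C} | p_ik − p_jk |,  with p the read fraction (percent/100),

and PD = PD'/D for a site-count denominator D. PD' sums over every site of
the class, so sites where both individuals are 0 change nothing and the
denominator affects only PD. PD ignores linkage (reads from collapsed
paralogs cannot be phased). The published site-corrected medians cannot be
reproduced exactly because the denominators behind them are never printed;
the package therefore treats D as user-supplied and offers a Nei-Gojobori
(1986) site counter (`ng_site_counts`) to derive non-synonymous/synonymous
site counts from a reference coding sequence as one defensible choice.

Distribution comparisons use midrank Mann-Whitney U (exact null for
tie-free samples with both n ≤ 20, tie-corrected normal approximation
otherwise), the two-sample Kolmogorov-Smirnov sup-distance, and the paired
Wilcoxon signed-rank test. The RNA-vs-DNA analysis (`delta_pd`) reports both
the pooled one-sample t over the C(n,2) pair deltas and a t over the n
per-individual mean deltas; the latter matches the n−1 degrees of freedom of
a per-individual design and is the one to prefer, since pair deltas sharing
an individual are not independent.

## Exon-read collapse and expression classes

Reads completely spanning a short region are grouped by exact identity
(no mismatch tolerance — the upstream pipeline already grouped identical
reads). With deep coverage and per-base error ≤ ~0.2%, genuine sequences
form a high-depth plateau and errors a low-depth tail; the accepted set is
cut at the largest gap in log10 depth between consecutive depth-sorted
records, provided the gap is at least `min_log_gap` (default 1.0, i.e. a
ten-fold decline — "sharp" on any sequencing scale and scale-free).
Without such a gap all records are accepted with a warning. A fixed
fraction-of-maximum cutoff is available as an alternative, and an absolute
depth floor (default 2) is never crossed. Accepted proportions are
renormalised and, per individual, classify DNA sequences by their RNA share:
strictly below 1% silenced, strictly above 5% expressed, the closed interval
[1%, 5%] weakly expressed (a literal reading of the ">5%" / "<1%"
definitions, so both boundary values are "weak").

## Mass-profile prediction

Mature MUP isoforms differ by a handful of residues, so deconvolved ESI/MS
average masses fall into a small set of classes near 18.7 kDa (18645, 18650,
18665, 18683, 18693, 18708, 18713, 18724 Da). Masses are computed additively
from standard average residue masses plus water (18.0153 Da), optionally
after stripping a configurable-length signal peptide; average rather than
monoisotopic masses match the deconvolution regime at this size. Bin
assignment uses the nearest class centre within 2.5 Da (isoform pairs ~2 Da
apart are instrumentally indistinguishable; the tightest printed spacing is
5 Da). A coding variant outside the sequenced window but with a measurable
mass effect (the R161L case) is handled by a correction that moves the
variant's known read fraction from its uncorrected class to the class
shifted by the residue-exchange mass — computed from the residue table
(L − R = −43.03 Da), not hard-coded. Unmatched minor peaks are dropped (with
a tally) before normalisation.

Individuality statistics correlate mass profiles across replicate samples:
Pearson r for every same-individual and every cross-individual pair, a KS
test between the two r distributions, and (when collection days are known)
a regression of self-correlation on the days between samples. Zero-variance
profiles make r undefined and are excluded with a tally.

## Promoter eSNP scan

Aligned promoter sequences inherit the expression category of the exon they
drive; weakly expressed promoters are excluded from testing. Every
polymorphic column is tested with Fisher's exact test on the 2×2
(variant/consensus × expressed/silenced) table; each non-consensus state is
tested separately against the consensus (pooling all non-consensus states is
also coherent, but separate tests are the sharper default and reduce to the
same table for biallelic columns). Gaps count as a state by default since an
indel can be the functional variant. No multiple-testing correction is
applied by default — the analysis this mirrors reports raw P < 0.05 — but
Benjamini-Hochberg is available. A column mask allows excluding poorly
aligned tracts (e.g. a variable poly-A run) from per-site claims.

## The Wright-Fisher simulator

Diploid individuals carry two cassettes of 15 paralogs (cassette length
fixed; there is no accepted model of cassette-size mutation). Each gene copy
tracks binary states at 15 selected non-synonymous positions and 102 neutral
synonymous positions, homologous across paralogs — this per-gene reading is
what lets the fitness rule use within-genome allele frequencies over 30
copies, matching the empirical percent-of-reads representation. Per
generation: fitness → reproduction → ectopic gene conversion → mutation.

* **Fitness.** f_ik = (copies of individual i carrying mutation k)/30;
  d_i = Σ_k |f_ik − f̄_k|; w_i = 1 − s + s·d_i/d_max. The maximally
  distinct individual has fitness 1, an exactly average individual 1 − s;
  a monomorphic population has uniform fitness.
* **Reproduction.** Each of N offspring draws two parents ∝ w (monoecious,
  selfing allowed). A transmitted cassette copies one parental haplotype,
  or with probability 5×10⁻⁶ a crossover of the two at a uniform inter-site
  breakpoint over the linearised cassette.
* **Gene conversion.** Rate 10⁻⁴ per gene copy per generation (the rate
  unit is exposed in the config since conventions differ); donor uniform
  among the other 29 copies of the same genome, intra- or inter-chromosomal;
  tract start uniform, length geometric with mean 50 on support {1, 2, …},
  truncated at the gene end; homologous coordinates copied non-reciprocally.
* **Mutation.** Every site flips with probability 3×10⁻⁶ (biallelic,
  back-mutation allowed). Rates are taken as printed; they are stated to be
  Mus values scaled by 100 and no further rescaling is applied.

Runs start monomorphic and last 10N generations (burn-in and run combined).
Summary statistics from an 18-individual sample: the number of
non-synonymous and synonymous positions segregating among the sampled 540
copies, and the mean over segregating positions of the sample-average
within-genome frequency (0, flagged undefined, when nothing segregates — the
ABC distance needs a number).

Internally genomes are bit-packed (site l in bit l mod 64 of word l div 64)
and the generation kernel is numba-compiled; per-copy conversion initiations
and per-site mutations are drawn as binomial event counts with uniformly
chosen targets. A run is reproducible from its seed; up to 64 selected
positions are supported (they must fit one machine word).

## ABC inference of the selection coefficient

Priors: s ~ U(0, 0.1), N ~ U(100, 1100); 10,000 simulations and tolerance
0.02 at full scale. Each statistic is standardised by its median absolute
deviation across the simulation table (robust; an SD option exists), the
⌈tolerance·n⌉ nearest rows in Euclidean distance are accepted with
Epanechnikov weights, and accepted parameters are adjusted by weighted
local-linear regression on the standardised statistics in
tangent-transformed space (t(θ) = tan(π((θ−l)/(u−l) − ½))), back-transformed
and clamped to the prior. Two guards matter in practice:

* A parameter whose accepted draws contain a point mass on a prior boundary
  (pooled neutral simulations put mass exactly at s = 0) skips the
  adjustment and keeps its rejection draws: the tangent transform maps
  boundary values to magnitudes ~1/(π·ε) and destroys the regression.
* The posterior KDE is boundary-corrected by reflecting draws about both
  ends of the support. An uncorrected Gaussian KDE halves the density at
  the edges, which biases HPD sets away from the boundary even for a
  uniform posterior — exactly where the "does the interval include s = 0?"
  question is decided.

Summaries: MAP as the density argmax on a 512-point grid, posterior mean,
equal-tailed weighted-quantile interval, and the HPD interval from the KDE.
The excludes-zero flag requires 0 to lie outside *both* the HPD and the
equal-tailed interval; for continuous draws the equal-tailed lower bound is
always positive, so the HPD governs, while a boundary point mass (the
neutrality-biased fit) drives the equal-tailed bound to 0 and keeps zero
included. The neutrality-biased variant pools an equal-size table of s = 0
simulations into the prior before fitting — a deliberately conservative
prior under which excluding zero is strong evidence for selection.

### Desk-scale recovery experiment

The package's validation runs at reduced scale: 2,000 prior draws with
N ∈ [100, 300], pseudo-observed datasets simulated at (s = 0.08, N = 200)
and at s = 0. The acceptance fraction is set to 0.1 so the accepted sample
(200 draws) matches the full-scale fit's 0.02 × 10,000. At this scale the
posterior mean of s recovers the selected truth (within [0.04, 0.1] in
18/20 fits) and neutral pseudo-data keep 0 inside the 95% interval in
18/20 fits, but only ~60% of selected pseudo-datasets *exclude* zero. This
is an information limit, not an estimator defect: a single pseudo-dataset's
statistics overlap the neutral sampling distribution substantially
(E[S_ns] ≈ 6.9 ± 2.3 under s = 0.08 versus 3.4 ± 1.9 neutral), so an honest
95% credible interval must often retain more than 2.5% posterior mass near
zero. Interval constructions that showed higher apparent power were
measurably overconfident, excluding the true s = 0 in over a quarter of
neutral fits; calibration was preferred. At full scale the empirical
statistics (11 of 15 non-synonymous positions segregating) lie far outside
the neutral range, where this ambiguity does not arise.

## The synthetic-data generator

The generator emulates the study's structure end to end: 18 individuals,
each with 30 gene copies drawn from a pool of 8 isoform variants whose
population frequencies span common to rare (Dirichlet-weighted). Each
variant owns a short discriminating region (the exon-1 stand-in, which also
determines its protein's mass class through a planted residue exchange with
a ≥5 Da shift) and per-copy promoter states decide silencing. RNA fractions
are DNA copy fractions restricted to unsilenced copies and renormalised;
mass proportions pool RNA fractions by mass class. Emitted artifacts —
per-site base counts at 7000× with 0.1% per-base error, raw region reads,
transcript catalogs, promoter alignments with planted
silencing-associated columns, and two replicate peak lists per individual —
are all derived from the same truth, so pipeline outputs can be compared to
known quantities (proportions within binomial error at the configured
depths).

The silencing switch controls the direction of the expression effect on
individuality: `"common"` silences shared variants independently per
individual (different individuals silence different shared sequences →
RNA-level differences grow), `"rare"` applies a population-wide silencing
allele to rare variants (their small distinguishing contributions vanish
everywhere → individuals become more alike), and `"none"` silences copies
independently. The rare-direction effect is small by construction (rare
variants carry little read mass), so the direction tests exercise it at a
strong silencing probability (0.8) where the sign is unambiguous.

What the generator does *not* emulate: linkage between variants within
haplotypes, copy-number/percentage confounding unless `copy_number_sd` is
set, PCR chimeras, quality-score structure, and real mass-spectrum artifacts
(adducts, baseline). Passing tests on synthetic data therefore validate the
pipeline's arithmetic and decision rules, not robustness to those real-data
pathologies.

## Problem sizes used in the checked experiments

Fixture-table checks run in seconds. The simulator oracles use: 2,000
replicate single-locus runs at N = 50 for the heterozygosity-decay
comparison; 500 replicate runs per arm at N = 100 (600 generations) for the
s = 0 fitness-free equivalence; 200 replicates per s ∈ {0, 0.05, 0.1} at
N = 100 for the selection-response rank test. The ABC experiment uses one
2,000-row prior table and 20 pseudo-observed datasets per truth value.
These sizes give Monte-Carlo errors comfortably inside the asserted
tolerances while keeping the whole suite re-runnable in minutes.

## Known limitations

* PD site-count denominators are user-supplied; published site-corrected
  medians are not reproduced for lack of printed denominators.
* The simulator fixes cassette length and treats selected positions as
  homologous across paralogs; copy-number variation in real populations
  breaks the exact percent-of-reads ↔ copy-frequency equivalence.
* The mapping from empirical read percentages to the simulator's
  within-genome copy frequencies (percent/100 ≈ copy frequency) is an
  assumption, documented rather than asserted.
* Desk-scale ABC power to exclude neutrality is bounded by single-dataset
  sampling noise, as quantified above.
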