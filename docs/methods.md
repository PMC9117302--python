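# Methods

This note documents the models and procedures implemented in `rilmap`,
the defaults and why they were chosen, what the simulator does and does
not emulate, and the numerical decisions made where the design was open.

## Coordinate conventions

All stages share one frame: 1-based, inclusive bp positions; the Mbp unit
of position `bp` is `ceil(bp / 1e6)`; Mbp intervals are inclusive of both
endpoint units, so `[start, end]` covers `end − start + 1` units. A
chromosome split at a translocation breakpoint produces a
pseudo-chromosome that keeps the original bp coordinates (a coordinate
*span*, not a renumbered sequence), so positions on the detached segment
remain directly comparable with the source assembly. Splitting conserves
total genome size by construction. When a breakpoint falls inside a
megabase, the boundary unit is touched by both parts; unit bookkeeping is
per span, so coverage arithmetic never double-counts within one span.

The bundled 21-chromosome layout (7 homoeologous groups × 3 subgenomes)
totals 10,272 Mbp; per-chromosome sizes are plausible placeholders
(C-genome chromosomes largest) because no authoritative per-chromosome
table is bundled — real analyses should supply their own two-column
layout file or GFF3 `##sequence-region` headers.

## Marker curation

GBS genotype matrices in an F-generation biparental RIL are sparse
(often >30% missing), contain residual true heterozygosity plus spurious
heterozygote calls, and a small rate of miscalls and reverse-phased
markers. The curation chain is: filter → phase → sort → correct → impute.

**Filtering.** Markers are retained when missingness ≤ 0.50, minor allele
frequency ≥ 0.30 and heterozygosity ≤ 0.10 (all at equality, matching the
"maximum"/"minimum" threshold semantics). MAF and het fraction are
computed over non-missing calls; a heterozygous call contributes half an
allele to each parent. Removals are attributed to the first failing rule
(missing → MAF → het), so report counts reconcile exactly.

**Double crossovers as a quality score.** A double crossover (DXO) is a
homozygous call that differs from both nearest non-missing homozygous
neighbours while those neighbours agree. In a selfed RIL, true tight
double recombination is rare, so DXO counts per marker flag phase errors
and garbage markers, and counts per line flag problem lines.

**Phase/outlier correction.** A marker is phase-flipped when flipping
reduces its DXO count by ≥ 40% of its scoreable cells (a reverse-phased
marker scores near 100%, a clean one near 0%); after optimal phasing,
markers whose DXO rate still exceeds 0.10 are removed (a marker random
with respect to its neighbours scores ~25% in either phase, well above
the ceiling; a clean marker with 1% miscalls scores ~1%, well below).
Decisions require ≥ 8 scoreable cells. Iteration runs to a fixed point
with a 10-pass cap; non-convergence is reported, not fatal. The
heuristic targets *isolated* reverse-phase markers; two adjacent
reverse-phase markers shield each other and are a known limitation.

**Imputation.** Per line and chromosome, in order: (1) residual DXO
singletons are set to the flanking call; (2) missing runs flanked by the
same homozygous call become that call; (3) runs with differing flanks are
filled toward each flank up to the midpoint, leaving a configurable
central uncertainty zone (default 1 cell) missing — the crossover
position inside the run is unknowable, so the center stays missing;
(4) heterozygous calls are never altered, nothing crosses a chromosome
boundary, and leading/trailing runs stay missing by default (no second
flank — conservative, as a manual curator would leave them). Singleton
repair is applied in-place left-to-right and iterated to a true fixed
point, which makes the whole imputation operator idempotent (verified by
a property test over random call strings).

What the accuracy tests show: on simulated populations with 30% missing
data and 1% miscalls, >99% of newly filled cells match the simulation
truth. Error sources in real data not fully emulated — non-random
missingness (restriction-site polymorphism makes missingness
haplotype-correlated), allele-specific amplification bias, and paralog
collapse — would lower that figure, which is why every rule is
switchable and parameterised.

## Recombination landscape

The observed recombination rate between two markers is the fraction of
discordant parental calls among lines homozygous and non-missing at both
markers. Pairs informed by fewer than 10 lines are treated as missing
rather than zero — a zero from 3 lines would otherwise paint false
pseudo-linkage. Values above 0.5 (sampling noise or residual phase
error) are capped at 0.5 and the count of capped cells is logged. `r` is
deliberately *not* corrected back to a per-meiosis recombination
frequency; the inverse Haldane–Waller map correction `R = 2r/(1+2r)` for
selfed RILs is available (`r_to_meiotic`) but off by default, because the
heat-map scale and the anomaly thresholds are defined on the observed
rate, which tops out at 0.5.

**Windows.** Full window width 16 Mbp (±8 Mbp around the tested
coordinate), centers at integer multiples of the step (default 10 Mbp;
1 Mbp for fine scans). Placing centers on the step lattice makes a
coarser grid an exact subsample of a finer one (tested invariant). A
window containing no marker is represented by the markers immediately
adjacent to it (one on each side when available), so all uniformly spaced
windows carry values. Cell values are means of pairwise `r` over all
distinct marker pairs, one from each window; self-pairs (markers shared
by overlapping windows) are excluded, which keeps the diagonal
interpretable.

**Anomaly detection.** Candidate cells have `r ≤ 0.2` (the heat-map's
teal anchor — the value below which window pairs look "linked").
Inter-chromosome candidate blocks of ≥ 2 contiguous cells are reported as
pseudo-linkage. Intra-chromosome candidates must additionally have window
centers ≥ 50 Mbp apart (closely spaced windows are genuinely linked:
with ~0.2 cM/Mbp, windows 50 Mbp apart are ≥ 4 standard errors above the
threshold for 200 lines, while adjacent windows would trigger constantly)
and at least one window outside the central 50% of the chromosome
(suppression toward the centromere is the expected baseline, not an
anomaly). Region bounds are reported as window-center positions; their
resolution is therefore one window by construction. All of these are
package decisions — the minimum informative-line count, the cap at 0.5
and the pericentromere mask have no external prescription.

**Distortion.** Per marker, the parent-A frequency among homozygous calls
with an exact two-sided binomial test against 1:1 segregation.

**Heat maps** use a piecewise-linear RGB blend anchored at yellow
(`r = 0`), teal (`r = 0.2`) and burgundy (`r = 0.5`); missing cells are
grey; only the lower triangle is drawn.

## QTL scan

The scan statistic at a marker is `TS = n · ln(RSS_reduced / RSS_full)`
over the lines homozygous at the marker (and at the covariate marker,
when one is declared) with a finite phenotype. The full model fits a mean
per marker class (plus a covariate-class effect); the reduced model drops
the marker term. This variance ratio approximates the likelihood-ratio
statistic and converts exactly to `LOD = TS/(2 ln 10)`, reproducing the
LOD 5 ↔ TS ≈ 23 anchor; it is invariant to affine transformation of the
phenotype (tested). The statistic is direction-free; the one-tailed
character of a two-class comparison is carried in the reported effect
sign and high-value parent rather than by halving p-values. The allele
effect is the full difference between homozygous class means (the effect
of a homozygous substitution); a half-difference convention is a trivial
division by two for users who prefer it.

Markers with an empty class, fewer than 20 usable lines, or a constant
phenotype are undefined (missing in the profile, logged); a genuinely
zero residual variance raises an error in the scalar API.

**Permutation thresholds** use max-T resampling: each of the (default
10,000; any number ≥ 100) permutations shuffles the phenotype across
phenotyped lines with one shared permutation for the whole genome scan,
and records the genome-wide maximum TS. `threshold(α)` is the
`floor(α·n_perm)`-th largest maximum, so a fresh null scan exceeds it
with probability `k/(n_perm+1) ≈ α`. Calibration is verified empirically:
over 200 simulated null traits, the exceedance count of the α = 0.05
threshold (1,000 permutations each) must fall in the exact binomial 99%
interval.

**Peak calling** is iterative per chromosome: the maximum-TS marker
strictly above the threshold is a peak (ties break to the lowest
coordinate); its support interval is the contiguous run of markers with
`TS ≥ 0.80 × peak` (a 20% fall-off), truncated at regions claimed by
previous peaks; the interval widened by 75 Mbp on each side is then
masked before searching for further peaks. Interval ends are marker
positions rounded to Mbp units — no interpolation between markers, since
nothing is known between them.

Recovery behaviour (measured, not assumed): with one additive QTL
explaining 20% of single-environment variance in a 200-line F6 RIL and a
~0.1 cM/Mbp map — the low recombination-per-physical-distance regime
that makes physically referenced intervals span tens of Mbp, as they do
in large suppressed-recombination genomes — the fall-off interval covers
the true position in ≳ 95% of replicates, and the mean estimated
substitution effect is unbiased. At genetically dense maps (≥ 1 cM
between adjacent markers) fall-off intervals become very narrow relative
to peak-location noise and their coverage drops well below 90%; users
mapping in small, recombination-rich genomes should widen intervals or
use resampling-based supports instead.

## Candidate-gene co-location

Genome coverage `p` is the merged width of the (optionally widened,
per-chromosome clipped) QTL intervals in Mbp units divided by the total
genome units. The closed-form null is the binomial tail
`P(K ≥ N) = Σₖ₌ₙᴹ C(M,k) pᵏ(1−p)^{M−k}`, evaluated by direct summation
(`P(K ≥ 0)` is exactly 1; `P(K ≥ 1) = 1 − (1−p)^M` is verified
analytically, and the whole function is cross-checked against the scipy
survival function). Overlap counting is integer-Mbp: a gene co-locates
when its Mbp-rounded position lies inside any interval, endpoints
inclusive, each gene counted once.

The bootstrap relaxes the binomial's assumptions (sampling with
replacement, uniform gene density, fractional coverage): each replicate
places `M` genes on the genome's 1 Mbp units with probability
proportional to a gene-density profile (uniform unless a per-Mbp count
table, derivable from any annotation, is supplied), rejecting draws
within 100 Mbp of an accepted gene *on the same chromosome* — a 100 Mbp
distance between different chromosomes is undefined, so the constraint is
intra-chromosomal. Each gene gets a 1,000-draw retry budget; replicates
that exhaust it are redrawn from scratch and counted in the diagnostics.
Tails come with Monte-Carlo standard errors `sqrt(P̂(1−P̂)/n_boot)`. With
uniform density and no separation constraint the bootstrap converges to
the binomial (tested at 10⁶ replicates, 3 SE).

## The simulator

The simulator generates the statistical structure the analysis assumes,
with truth records for every oracle. Meiosis is explicit per selfing
generation (single-seed descent from the F1), so F4 vs F6 vs F8 genuinely
change residual heterozygosity (halving per generation, tested).
Crossover counts per chromosome are Poisson with mean equal to the
genetic length (`cM/Mbp × physical length`); positions are uniform; there
is no interference — the simplest model consistent with everything the
analysis measures. Adjacent-marker discordance in deep RILs matches the
Haldane–Waller expectation `2r/(1+2r)` (tested against the closed form).

**Translocation heterozygotes** are modelled by their observable meiotic
consequences, not cytologically. When an individual is heterozygous for
the rearrangement (zygosity is proxied by the parental origin at the
breakpoint regions — a deliberate simplification that leaves a small
residue of apparent recombination in coupled blocks), the donor and
recipient chromosomes segregate with a shared phase anchored at the
midpoint of each chromosome's largest non-recombining interval, and
crossovers are confined to the declared recombining regions of the
quadrivalent. Gametes carrying the *deficiency* product (recipient
distal region from the non-carrier parent together with the donor distal
region from the carrier — i.e. missing the translocated segment) survive
with a configurable probability. The asymmetry matters: duplication
gametes are viable, deficiency gametes are selected against, and that is
what drives allele-frequency distortion toward the carrier parent in
linked regions (tested by a sign test over replicates). Homozygous
individuals (either configuration) undergo normal meiosis.

**Inversion heterozygotes** permit crossovers only outside the inverted
interval; no selection is modelled, since single-crossover products in a
pericentric inversion are effectively removed by inviability and the
observable consequence — suppressed recombination — is captured by the
restriction itself.

**Phenotypes** are additive: trait value = grand mean + Σ effect·score
(score +1/−1/0 for the two homozygous classes and heterozygotes) + a
shared environment shift + per-line residual noise. When a per-QTL
variance-explained target is given instead of a residual SD, the residual
is derived assuming allele scores of ±1 at frequency ½
(`σ² = Σa²·(1−h²)/h²`); `h²` is defined per single environment.

**Degradation** is independent per cell with priority missing → spurious
het → miscall (opposite parent), truth retained separately. Defaults
(30% missing, 1% spurious het, 1% miscall) emulate a mid-coverage GBS
assay. Not emulated: haplotype-correlated missingness, batch effects,
paralog-driven heterozygote excess, and genotyping errors correlated
along lanes — all reasons why passing tests bound, but do not guarantee,
behaviour on real data.

**Study-condition choices for the validation suites** (all fixed a
priori from the power analyses sketched above): rearrangement detection
uses two 200 Mbp chromosomes at 4 cM/Mbp so the recombining arms are
several Morgans long and anomaly bounds are resolvable at ±1 window;
permutation calibration uses 1,000 markers on five chromosomes at
0.2 cM/Mbp with 1,000 permutations per trait; QTL recovery uses
0.1 cM/Mbp as described; curation properties use an F7 population (so
residual true heterozygosity ≈ 1.5% does not dominate the imputed-cell
error budget) at 30% missing / 1% miscall.

## Numerical and degenerate-input decisions

* Ties at a profile maximum break to the lowest genomic coordinate.
* `TS` is clipped at 0 (the nested-model ratio cannot mathematically be
  below 1; floating-point noise can dip it).
* Markers with zero non-missing calls get MAF 0 and het 0, so the
  identity-threshold filter `(1.0, 0.0, 1.0)` retains them.
* The vectorised scan kernel marks undefined tests (empty class, too few
  lines) as missing rather than raising, so one bad marker never aborts a
  scan; the per-trait pipeline isolates failures the same way.
* Bootstrap feasibility is checked up front: `M` genes must fit the
  layout's capacity of separated positions, else the call errors out
  rather than looping.
* All randomness flows through `numpy.random.default_rng` seeded
  explicitly; a simulation seed is mandatory, and identical seeds give
  byte-identical outputs (tested).

## Known limitations

* The curation heuristics are a reconstruction of manual-curation
  practice; their parameters are exposed precisely because no external
  specification of the original rules is available.
* Zygosity at rearrangements is probe-based; lines that fix at the probe
  but remain heterozygous elsewhere briefly escape the coupling model.
* No crossover interference, no epistasis, no G×E beyond an additive
  environment shift.
* Anomaly region bounds are window-quantised; breakpoint refinement
  belongs to genome-alignment tools, not to segregation data.
* Fall-off support intervals are heuristic, not confidence intervals;
  their empirical coverage depends strongly on the genetic density of the
  map (see the QTL section).
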