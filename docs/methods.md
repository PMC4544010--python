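# Methods

## Threshold classification and subpopulation structure

Single-molecule RNA FISH yields integer transcript counts per cell per
gene.  Cells are called (+)/(−) per gene by a fixed cutoff with the strict
convention: a cell is negative iff its count is strictly less than the
cutoff, so a cell at exactly the cutoff is positive.  The shipped cutoffs
are 30 transcripts for *Nanog*, 80 for *Oct4*, 30 for *Crabp2*, 50 for *T*
and 10 for *Tbx6*; with clearly bimodal count distributions the calls are
insensitive to the exact value.  The nested-hierarchy summary counts cells
negative for successive prefixes of a gene ordering (e.g. [Nanog, Oct4]),
which is monotone non-increasing by construction.  Co-expression of a gene
pair is a 2×2 cross-tabulation; the overlap is scored against an
independence null by the hypergeometric upper tail P(X ≥ observed) given
the two marginals.  Subpopulation fold changes divide group centers (mean
by default; median by flag — the choice is not pinned down by the
motivating analyses, and means are the convention for FISH count data).
When either center is zero a pseudocount of 1 is added to both and the
result carries an explicit flag; silent NaNs or unflagged regularization
are never produced.  Cells missing a queried gene are rejected, not
imputed.

## Greedy GO summarization

Given category → gene-set annotations (pre-propagated; no ontology-graph
handling) with a root annotating every gene, the greedy ranking repeatedly
selects, among categories whose *original* size exceeds `min_size` (root
always eligible), the one maximizing
|remaining genes ∩ remaining interest| / |remaining genes|, then removes
its remaining genes from all categories and from the interest set,
terminating when the root is selected (immediately if the best
concentration is zero).  Both numerator and denominator use residual gene
sets — the self-consistent reading of "remove all genes in the selected
category after each step"; eligibility uses original size because the size
filter is meant to exclude narrow terms a priori, not terms that happen to
have been eaten by earlier selections.  Ties break by larger residual size,
then lexicographic id — deterministic and order-independent.  Gene
assignment ("falling") uses original membership and the earliest selected
category, so it is defined for any gene, inside or outside the interest
set.  Default `min_size` is 750 genes, the scale at which broad
biological-process terms survive.

## DE post-processing

Benjamini–Hochberg adjustment is the standard step-up (delegated to
statsmodels); hits are adjusted p ≤ FDR with an inclusive boundary, 10%
FDR by default.  NA p-values are excluded from the adjustment and flagged.
Quadrant analysis classifies only genes that are hits in *both* contrasts:
sign agreement of the log2 fold changes is "coherent", disagreement
"incoherent", and zero fold change in either contrast excludes the gene
with a flag.  The sign convention is positive = higher in the second
condition of each contrast.  Binding-overlap fractions are
|bound ∩ hits| / |bound| per (factor, hit-type) with |hits| / |universe| as
the background; factors with no bound genes return NaN with an `undefined`
flag.  Directional gene-set summaries report hit counts, up/down splits and
the bias (up − down)/(up + down).  Upstream testing (size factors,
dispersion estimation) is out of scope: the package consumes fold changes
and p-values from any method, and the test suite drives FDR-control
simulations with a deliberately simple per-gene t-test on log counts.

## Switching dynamics

Units are hours; rates per hour.  The two-state model gives the closed-form
relaxation above; its central consequence is that the exponential
regeneration rate k_down + k_up is identical from high- and low-sorted
initial conditions.  The mixture sort model has three compartments —
reversible (+), reversible (−), irreversible (−) — with the sorted low pool
initialized as (fn_fraction, 1 − fn_fraction − irr_fraction, irr_fraction).
The reversible pair is autonomous (mass-conserving, relaxing at
k_down + k_up) and the irreversible pool is a pure exponential at the net
growth penalty g (≤ 0 typical, default 0), so the whole system is solved in
closed form; no numerical integrator is needed and probability is conserved
to machine precision when g = 0.  With irr_fraction > 0 and g < 0 the
low-sorted side approaches the steady-state positive fraction strictly
later than the high-sorted side — the signature that distinguishes an
"unstable equilibrium" (irreversible exit) from pure reversible switching.
The exact mixture composition is this package's reading of the verbal model
(false-negative positives plus non-returning negatives); the growth-penalty
term is optional and off by default.

`fit_rates` minimizes squared error of the closed form against an observed
positive-fraction trajectory.  Initialization is a deterministic 5×5
log10-rate grid over [10⁻³, 10¹] per rate followed by bounded
Levenberg–Marquardt-style refinement (scipy `least_squares`,
xtol=ftol=gtol=10⁻¹⁴), so fits are reproducible given the data.  The
two-state fit estimates (k_down, k_up, q0); the mixture fit estimates
(k_down, k_up, irr_fraction) with fn_fraction and growth penalty held
fixed, because a five-parameter fit from a single fraction trajectory is
not identifiable.  Flat trajectories (range < 10⁻¹⁰) return a
non-identifiable diagnostic rather than an arbitrary rate.  The agent
simulator draws exact exponential waiting times per cell (cells are
independent), removes growth-penalized irreversible cells at rate −g, and
converges to the closed-form trajectory as n grows (checked at 10⁴ cells,
max deviation < 0.02).

## Synthetic data: what it emulates and what it does not

Generators emulate the *structure* of the measured data, not its full
biology.  Class compositions are stratified-exact (a class of n cells
contributes exactly n rows) so printed population compositions can be
encoded verbatim; there is deliberately no multinomial scatter.  Within
class, count distributions are configurable — rounded lognormal
(median-parameterized) for marker-positive classes, negative binomial
(mean/dispersion, variance μ + αμ²) for near-zero classes, constants for
degenerate cases — because the underlying experiments report thresholds and
fold changes, not distribution families.  Guards rejection-sample each
(class, gene) onto its class's side of the cutoff with a safety margin
(default 0.2, i.e. positives ≥ 1.2× cutoff, negatives < 0.8× cutoff), so
downstream classification recovers latent labels exactly.  Passing tests on
guarded fixtures therefore demonstrates correct plumbing and exact
agreement with the printed compositions; it does not validate cutoff choice
or distributional realism on real FISH data, where the (+)/(−) modes are
separated but not guard-separated.  Cell-cycle, cell-volume and imaging
effects are not modeled.

Shipped fixtures: a 1189-cell Nanog/Oct4 fixture (1129/16/44 composition,
so 60 Nanog(−) of which 44 Oct4(−)); a 2360-cell Nanog/Crabp2/T fixture
(138 Nanog(−) cells of which 25 express a lineage marker, including exactly
2 Crabp2(+)T(+) cells — the printed "(18%, N = 138)" is read as 18% of the
138 Nanog(−) cells, one of two defensible readings); a 764-cell Tbx6/T/Oct4
fixture (2 Tbx6(+) inside 7 T(+), all Oct4(−)); and a 2000-cell reporter
fixture.  The reporter fixture uses a 15% Nanog(−) class and a reporter
false-negative probability of 0.15/0.85 ≈ 0.176 among Nanog(+) cells, so
the implied share of truly-positive cells among reporter-negative cells is
exactly 50%; at n = 2000 the VNP(−) pool is ~600 cells and the observed
share is within ±5 percentage points of 50% for essentially any seed
(3σ ≈ 3.9 points).  False negatives keep their Nanog count distribution
untouched — only the reporter counts are suppressed.  Bulk counts are NB
with a common dispersion and optional log-uniform baseline means; planted
genes multiply the condition-2 mean by 2^log2fc and are reported in a truth
table.  GO universes plant interest-gene concentrations exactly by
construction (planted categories draw only unused genes); non-planted genes
are interest at a configurable background rate, and `overlap_rate` controls
sharing between non-planted categories.

All randomness flows from one explicit integer seed per generator call; no
global state.  Identical config + seed gives byte-identical output.

## Problem sizes and numerical choices

The test and acceptance suites run at the sizes stated in their docstrings:
the shipped fixture sizes (764–2360 cells), 500 random universes for the
greedy-selection oracle check, 10⁴ random vectors for the BH oracle, 200
planted bulk simulations (300 genes, 3 vs 3 replicates, 10% planted at
4-fold, dispersion 0.05) for FDR control, and 100 noisy replicates (1%
Gaussian noise, 13 time points over 72 h) for rate recovery.  Tolerances:
rate agreement between sorted sides 10⁻⁶; noiseless rate recovery 10⁻⁴
relative; noisy recovery < 5% median relative error on k_down + k_up;
realized FDP within 2× nominal; NB moments within 10% at 10⁴ draws.

## Known limitations

* Threshold inference from bimodal distributions is out of scope; cutoffs
  are inputs.
* The mixture sort model is phenomenological: no transcriptional bursting,
  cell-cycle structure or spatial/colony effects, and exponential kinetics
  throughout.
* Guarded fixtures cannot probe classification robustness near the cutoff.
* The greedy summarization's residual/residual concentration is one
  self-consistent reading; a variant using original denominators would rank
  ties differently (not implemented).
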