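# Methods

This note documents the models, estimators and numerical choices behind
`emt_nfatc`, and states what the shipped defaults do and do not claim.

## The mechanistic circuit model

The core epithelial–mesenchymal (EMT) decision circuit couples the
miR-200 microRNA family, the ZEB transcription factor (mRNA `m_Z` and
protein `Z` tracked separately) and an external EMT-inducing signal
represented by a clamped SNAIL level `S` (molecules).  The coupled model
adds E-cadherin `E` and the calcium-responsive transcription factor
NFATc `N`.  Every species obeys

    dX/dt = g_X * prod_i H(A_i; A0_i, n_i, lambda_i) - k_X * X

with shifted Hill factors `H = (1 + lambda (A/A0)^n) / (1 + (A/A0)^n)`
(1 with no regulator, `lambda` at saturation; `lambda > 1` activation,
`< 1` inhibition).  The miR-200 → ZEB-mRNA edge instead uses the
microRNA binding-site formalism: with `M_i(mu)` the binomial probability
that `i` of 6 sites are occupied (per-site ratio `mu/mu0`), translation
is scaled by `L(mu) = sum l_i M_i`, mRNA active degradation is
`Ym(mu) = sum gamma_m_i M_i`, and miR-200 is itself consumed through
duplexes at `m_Z * Ymu(mu)`, `Ymu = sum i gamma_mu_i M_i`.  NFATc is
constitutive (`dN/dt = g_N - k_N N`), so at steady state `N* = g_N/k_N`
and all NFATc Hill factors are constants; the NFATc self-activation edge
of the topology is folded into `g_N`.  SNAIL enters only as the clamped
input.

### Topology

Eleven signed edges over {SNAIL, miR-200, ZEB, E-cad, NFATc}: SNAIL→ZEB,
SNAIL⊣miR-200, ZEB⊣miR-200, miR-200⊣ZEB (binding-site), ZEB→ZEB,
ZEB⊣E-cad, E-cad⊣ZEB (indirect, via beta-catenin sequestration),
NFATc→ZEB, NFATc→miR-200, NFATc→E-cad, SNAIL→SNAIL — 6 activations and
5 inhibitions.  The published schematic is not machine-readable and the
identity of the eleventh (activating) edge cannot be pinned down from
text alone.  Five constraint-consistent readings were evaluated against
the reported ensemble statistics (NFATc→SNAIL, NFATc or SNAIL
self-amplification, SNAIL→NFATc, E-cad→NFATc); only SNAIL
self-amplification reproduces both the tristable-phase enrichment and
the hybrid-dominant basin sizes, and it leaves SNAIL's role in the
mechanistic model untouched (the self-edge is inert under clamping).
Users can supply any other reading as a `.topo` file.

### Parameters and calibration

Core-circuit rates and Hill blocks are the published values of the
miR-200/ZEB/SNAIL binding-site model (g_mu = 2100 /h, g_mz = 11 /h,
g_Z = 100 /h per mRNA, k = 0.05/0.5/0.1 /h, mu0 = 10^4 molecules,
six sites).  Two groups of numbers are calibrated, not published, and
are flagged as such in `params.py`:

* `gamma_mu` scaled to 0.5x the literature values.  Weaker
  duplex-mediated miR-200 consumption keeps the partially silenced
  hybrid branch viable across the SNAIL window the analyses probe
  (roughly 320–415 thousand molecules); with the literature values the
  hybrid branch folds ~50k molecules earlier and the hybrid well is
  never the deeper one at 330k.
* the five coupling blocks: NFATc→miR-200 lambda = 1.25, NFATc→ZEB
  lambda = 1.3, NFATc→E-cad lambda = 2.0 (thresholds at N* = 1000
  molecules, n = 2), ZEB⊣E-cad (220k, 2, 0.1) and E-cad⊣ZEB
  (100k, 2, 0.46).

Calibration targets (in this order): the coupled circuit keeps hybrid
and mesenchymal states coexisting at S = 323k and 330k with the hybrid
well the deeper one, and is mesenchymal-dominant at 380k; its hybrid
window is strictly wider than the core's; low SNAIL is monostable
epithelial with no monostable hybrid regime anywhere.  The resulting
structure is {E} → {E,M} → {E,H,M} (~318–322k) → {H,M} (~322–417k) →
{M} for the coupled circuit and a hybrid window of ~218–278k for the
core.

### Phenotype bands

Fig-style E/H/M bands for trajectories are derived per model from its
own bifurcation diagram: mesenchymal = ZEB mRNA above the largest fold
value, epithelial = below the smallest, hybrid = between.  With the
calibrated defaults, a step to S = 330k molecules drives the core model
from its epithelial state into its mesenchymal band in ~10^2 hours,
while the coupled model relaxes onto its (stable) hybrid branch and
never enters its mesenchymal band: NFATc does not merely slow complete
EMT here, it stalls it.  We report the stalled transition as an infinite
time-to-band; this is the strongest form of the delayed-EMT comparison
and mirrors the biology (cell lines holding a stable hybrid phenotype
unless NFATc is removed).  A deterministic trajectory from an epithelial
start necessarily ends on the hybrid attractor whenever one exists — the
miR-200 level relaxes quasi-statically onto the hybrid branch — so a
finite-vs-finite comparison at 330k would require the hybrid state to
vanish there, contradicting the landscape analyses.

## Bifurcation analysis

Grid sweeps (default 0–500k molecules, 126–251 points) run multi-start
root finding at each S, warm-started from the neighbouring S.  Root
finding operates in log coordinates on degradation-normalised residuals
(well-scaled across species spanning five decades); starts are
log-uniform over [1e-2, 1.2] x each species' production bound, plus
deterministic epithelial/mesenchymal archetype corners.  Roots are
deduplicated at 1% relative tolerance (levels floored at one molecule)
and tagged stable when the finite-difference Jacobian's leading
eigenvalue real part is below -1e-6 /h.  Stable states are linked into
branches by nearest-neighbour continuation in log ZEB mRNA (tolerance
0.8 log units, ties broken by smallest absolute difference); the
lowest branch is epithelial, the highest mesenchymal, anything between
hybrid.  Fold positions are refined by bisection to 0.1% of the grid
span.  The hybrid interval is the S range carrying a stable hybrid
state.

Sensitivity analysis perturbs every continuous scalar parameter (rates,
thresholds, fold changes, mu0) by ±10% one at a time and re-measures the
hybrid interval by direct fold tracking of the hybrid branch (march +
bisection), seeded from the baseline branch; the baseline is measured
with the same estimator so the 0%-perturbation anchor is exact, and one
batch entry is cross-checked against an independent full sweep in the
tests.  Integer Hill cooperativities and the per-site microRNA vectors
are excluded — a ±10% change of an integer exponent is not meaningful,
and the site vectors are not single scalars.  The reference line is the
percent change from removing NFATc altogether (core vs coupled
interval).  In this calibration ZEB self-activation is the most
sensitive parameter group, matching the published ranking; the
NFATc–miR-200 interaction, also singled out there, is mild here because
its calibrated fold change is small.

## Quasi-steady-state reduction and stochastic landscapes

ZEB mRNA, E-cadherin and NFATc relax fast relative to ZEB protein and
miR-200; setting their derivatives to zero closes the system to two ODEs
in (Z, mu) whose fixed points coincide exactly with the full model's
(tested).  The reduced system is simulated with Euler–Maruyama
(`x += f dt + sigma sqrt(dt) xi`, dt = 0.01 h, negative proposals
reflected), bit-reproducible per seed.

* **Noise.**  Additive, per-variable amplitude = fraction x the
  geometric mean of the hybrid and mesenchymal attractor levels at that
  S (all attractors when no hybrid exists).  Attractor levels span
  ~50-fold, so a fraction of the absolute range would swamp the
  low-level hybrid well entirely; and scaling by the H/M pair — which
  exists across the whole probed window — keeps the amplitude smooth
  across the epithelial fold instead of jumping when the E state
  appears.  The default fractions (5% for ZEB protein, 12% for miR-200)
  are a calibration: symmetric 5% noise produces no basin exchange
  within 10^6 h at S = 323–330k (nothing can be estimated), while
  symmetric noise warm enough to mix (≥7.5%) preferentially erodes the
  low-level hybrid well and inverts the landscape.  A warmer miR-200
  channel opens the mesenchymal→hybrid return path (miR-200 recovery
  against ZEB suppression) at amplitudes that leave both wells intact.
  One consequence inside the tristable window: the hybrid state
  exchanges rapidly with the adjacent near-fold epithelial state, so
  its residence time there is short even though its well is the deeper
  of H/M — matching the published picture of a hybrid state that is
  protected yet not globally dominant.  Only orderings and trends of
  residence times/barriers are claimed, never absolute values.
* **Basins.**  Each recorded point is assigned to the basin its grid
  cell's noise-free relaxation converges to (log-space grid, default
  60–80 cells/axis; steps clamped to 20% of the level for stiffness;
  cells not converging within the horizon fall back to the nearest
  attractor in log space and are counted).  Voronoi assignment would
  mislabel the non-convex basins near the separatrix.
* **Mean residence time** = mean contiguous-run length x recording
  interval, per basin; occupancy fractions sum to one by construction;
  states never visited are reported absent, not zero.
* **Quasi-potential** U = -ln P of the 2-D histogram in log coordinates
  (default 100–120 cells/axis, Gaussian smoothing 1.5 cells), shifted
  to min 0; one minimum per deterministic attractor (lowest-U cell
  within 0.5 log units; an attractor whose neighbourhood was never
  visited has no minimum and infinite barriers); saddles by union-find
  flooding of cells in ascending U with 8-neighbour connectivity — a
  minimum's saddle level is the U at which its component first touches
  another minimum's component; barrier = saddle − minimum.
* **Escape conditioning.**  Runs start alternately in each basin, and a
  state's barrier is estimated from the runs that started in its own
  basin (the Kramers escape barrier).  Pooling runs across basins
  weights the wells by the arbitrary start allocation rather than by
  the dynamics whenever transitions are rare, which buries genuine
  depth differences of a few tenths of a natural-log unit — exactly the
  margins at S = 323–330k.  Residence times pool all runs.

## Random-parameter ensembles

For topology-level statistics every species, including SNAIL and
miR-200, is an ordinary node with shifted-Hill regulation (no
binding-site formalism).  Per model: g ~ U[1,100] /h, k ~ U[0.1,1] /h
per node; per edge n ~ U{1..6}, lambda ~ U[1,100] for activation and its
reciprocal for inhibition; thresholds ~ U[0.02, 1.98] x the source's
median operating level.  That median is estimated by Monte Carlo with
*every* incoming regulation at half effect (fold change drawn from the
edge's own distribution): modulating by inhibitors only, or by nothing,
leaves thresholds far below the operating levels of strongly activated
nodes, saturating their downstream Hills and collapsing the multistable
fraction of these circuits to under 1% — an order of magnitude below
published ensemble analyses.

Each model is relaxed from 100 log-uniform initial conditions (Euler,
dt = 0.1 h, up to 1000 h, convergence when the degradation-normalised
rhs drops below 1e-6); endpoints are deduplicated at 1% in log levels.
All states of an ensemble are pooled, log2 levels z-scored per node, and
labelled M (z_ZEB > 0 > z_miR200), H (both > 0), E (z_miR200 > 0 >
z_ZEB); the fourth quadrant is reported as an explicit unlabelled bin.
A model's phase is its set of state labels; phase counts partition the
ensemble.  Frequencies are reported as mean ± sd over three replicate
ensembles (fresh seeds) and compared between topologies by two-tailed
equal-variance t-tests on the replicate counts.

Relative stability relaxes 1000 fresh log-uniform starts per multistable
model (three independent batches for error bars) and counts arrivals per
labelled state, matching each endpoint to the nearest recorded state in
log space (unmatched arrivals go to an explicit overflow bin, so counts
always sum to 1000).

## Sign randomization

The null model keeps every edge's endpoints — hence all in/out degrees —
and permutes which edges activate, under the global constraint that the
activation count matches the wild type; per-node sign counts are
deliberately *not* conserved.  All C(11,6) = 462 assignments are
enumerated lexicographically and the wild type excluded (461 networks).
Comparisons run the ensemble on a seeded subsample and report the
wild-type phase fraction's percentile.  Edge rewiring is a different
null model and is not offered.

## Synthetic inputs

All inputs are generated: topologies and calibrated parameter files,
toy circuits with recomputed (never stored) ground truth — an
unregulated node (state g/k), a hand-parameterised bistable toggle
verified against a brute-force grid, a symmetric double well with known
wells/separatrix for the basin and barrier estimators — and a seeded
example trajectory.  One master seed derives per-file sub-seeds
(master x 1000 + counter, mod 2^31) and a manifest records SHA-256
checksums; regeneration is byte-identical.  The generator emulates
*inputs* to the computation, not biology: there is no transcriptional
bursting, no cell-to-cell parameter variability, no measurement noise,
and the noise driving the landscapes is a modelling device.  Passing
tests certify the computational pipeline, not the biological fidelity
of any particular rate constant.

## Problem sizes

Shipped analysis and test sizes (the package's desk scale): sweeps of
126–251 S points; landscapes of 4 seeds x 2–6 x 10^5 h (dt 0.01 h,
recorded every 0.5 h); ensembles of 1000–2000 models x 100 initial
conditions x 3 replicates; randomization subsamples of 10–25 of the 461
networks; relative stability over all multistable models of one
ensemble x 1000 starts x 3 batches.  The `full` pipeline preset mirrors
the published sizes (10^4 models, all 461 networks, 10 noise seeds).

## Known limitations

* The coupled-circuit parameterisation is calibrated to qualitative
  targets, not fitted to data; absolute levels and times are not
  meaningful beyond orderings.
* Additive noise with calibrated per-variable amplitudes is a choice;
  multiplicative or intrinsic (birth–death) noise would change absolute
  residence times and possibly the crossover location, though not the
  deterministic structure.
* Two landscape claims cannot hold together in this model family and we
  chose the barrier orderings: the tristable {E,H,M} window necessarily
  ends at the epithelial fold just below 323k molecules, so the hybrid
  well — calibrated to be the deeper of H/M at 323–330k — is also the
  deepest state inside the adjacent tristable window; a hybrid state
  with *sub*-maximal residence time there would require the H/M depth
  ordering to flip across ~2k molecules, or an epithelial well deep
  enough to dominate, which additive noise spanning the ~100-fold
  attractor-level range precludes (the epithelial ZEB coordinate, ~10^4
  molecules, is over-driven by any amplitude that still perturbs the
  mesenchymal state at ~10^6).
* Ensemble statistics are reconstruction-dependent at the margins: with
  the shipped topology the {H,M} phase frequency rises under NFATc
  coupling (the robust increases are {E,H} and {E,H,M}), the wild type
  is extreme in the {E,H} randomization comparison as well as {E,H,M},
  and in {E,H,M}-phase models the epithelial basin is the largest
  rather than the smallest.  Alternative readings of the unreadable
  schematic edge shift which of these hold; none of the readings we
  evaluated satisfies all published trends simultaneously.
* No delays, no spatial coupling, no cell populations, no parameter
  fitting; SNAIL is an input, not a regulated species, in the
  mechanistic model.
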