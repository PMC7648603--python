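# Methods

## The piecewise-linear RD model

Each component is a pathway activity, not a single molecule.  Production is
a clamped linear function of the weighted regulatory inputs,
`Phi(sum_j a_ij u_j + b_i; fmax_i)`, with first-order degradation `c_i` and
Fickian diffusion `D_i` on a 1-D axis.  The clamp is the model's only
nonlinearity: it bounds growing patterns (peaks ride the production
ceiling, troughs the zero floor), which is what makes wave shifts under
inhibition appear as bounded movements of troughs or peaks.  Basal inputs
are set so the uniform steady state is at concentration 1 and production
sits strictly inside the linear region there; for externally supplied
coefficient sets the steady state is solved from the linear system and the
same interiority check applies.

Random parameterisations follow fixed laws: interaction magnitudes uniform
on (0, 1] with the topology's signs; the composite self-weight
`a_ii - c_i` drawn from the same law (negative without autoregulation,
positive with it, in which case `c_i` is drawn separately); diffusivities
reciprocal-uniform on [1, 10000]; production ceilings uniform on
[1.5, 3] x `c_i`.  These laws are the study conditions for every screen in
the package and are not adjusted per experiment.

## Linear stability and DDI classification

The dispersion relation diagonalises `J - k^2 diag(D)` with
`J = a - diag(c)` over a wide logarithmic wavenumber grid (default 128
points, quadratically refined at the maximum; the batched screening path
uses 120 fixed points without refinement).  A parameter set counts as
stationary, non-oscillating DDI when all eigenvalues of `J` have negative
real part, some mode with `k > 0` grows, the growth band is finite, and
the leading eigenvalue at the band maximum is real within
`|Im| < 1e-9 (1 + |Re|)`.  The phase signature is the sign pattern of the
leading eigenvector, canonicalised so its first entry is positive; entries
below 1e-9 of the vector norm mark the phase indeterminate and such sets
are excluded from phase counting.  These numeric criteria replace the
closed-form three-component inequalities of the original stability
literature; on the coefficient grids used here the two give the same
stationary-instability verdicts, and the numeric form is
dimension-agnostic.

Domain rescaling multiplies all rates by one factor and all diffusivities
by an additional squared space factor so that a target wavelength
(default: 3.25-3.5 waves on the 100-cell domain) and growth rate (default
0.1 per time unit) are met; DDI status and phase are invariant under this
rescaling.

## Simulation

Explicit forward Euler with a conservative zero-flux 3-point Laplacian on
100 cells, `dx = 1`, `dt = 0.2 min(dx^2 / max D, 1 / max kinetic rate)`.
Initial conditions are uniform noise of amplitude 0.01 around the uniform
steady state.  Simulations run for 30-40 growth e-foldings (T = 300-400
after rescaling); a batched path integrates up to 64 parameter sets at
once, grouping by stiffness and stopping early once profiles stop
changing.  Convergence for screening uses a 1% relative profile-change
criterion over the final tenth of the run ("stable amplitude"); the
single-run default is 1e-4.  Parameter sets whose rescaled dynamics would
need more than 60,000 steps (marginal growth relative to diffusive
stiffness) are excluded from screens — the scaled-set-must-fit-the-
simulation requirement of the original workflow; this biases screens
toward moderate diffusivity contrasts and is the main respect in which
screen populations differ from the raw sampling law.

## Loop analysis and perturbation-sign prediction

An RD-capable network embeds a *core*: a positive feedback loop (possibly
a single autoactivation) and a negative feedback loop that shares at least
one component with it and runs through at least one component outside it.
All analysis happens in phase-transformed coordinates: flipping the sign
of every edge incident to an out-of-phase component makes the patterned
mode nominally all-positive, in which coordinates a valid embedding has an
all-positive cycle for the positive loop, a negative cycle whose
inhibitory edges all enter the positive loop, and the remaining components
wired in chains (positive entry and interior edges, exit edge of either
sign) attached to core components.

The response of an established pattern to inhibiting component t is
predicted from the embedding: every component carries a net activation
sign sigma(t) onto the core positive loop (positive-loop members +1;
negative-loop members the sign of their path into the positive loop;
chained components the product of their exit sign and their anchor's
sign), and inhibition of t moves the whole transformed pattern in the
direction -sigma(t), so the real-space change of readout r is
`-sigma(t) * s_r * s_t` with `s` the phase vector.  Self-inhibition of a
component with a stabilising (negative-loop) role raises that component's
own level.  Predictions are unioned over all structural embeddings;
disagreement marks the entry core-dependent.  This rule was validated by
sampling 10^2-10^3 DDI-conditioned parameterisations for every
three-component minimal structure and for dozens of five-component ones:
where the conditional response sign is unique the rule reproduces it
exactly, and the remaining cells (self-inhibition of a both-loops
component; certain multi-loop interactions) are genuinely
parameter-dependent, with the rule following the direction that dominates
when the embedding's own loops dominate.  A free-magnitude symbolic
treatment of the steady-state sensitivity (adjugate signs) was evaluated
and rejected: it leaves the overwhelming majority of topologies
unconstrained because it ignores the inequalities that DDI competence
imposes.

## Enumerating minimal topologies

The constructive atlas enumerates, for phase-labelled components, every
core (positive cycle x negative cycle, with the negative loop's inhibitory
edges delivered into the positive loop from outside it) combined with
every minimal wiring of the remaining components, deduplicates the
resulting signed graphs, and keeps those from which no single interaction
can be deleted without losing strong connectivity or an embedded valid
structure.  The deletion test deliberately uses a more permissive sign
rule (inhibitory shortcuts between positive-loop members are accepted,
since conditioned sampling shows such systems do pattern); the
enumeration's own sign rule excludes them, which removes the class of
networks in which every component net-activates the core.  For three
components and one phase group this yields 45 minimal topologies; for the
five-component ruga system (Wnt, mFGF, Hh in phase; eFGF, BMP out of
phase) 39,755.

Response grouping partitions the enumeration by the predicted
readout-response signature over the five inhibitions (Wnt at the
production level, the others at the response level, matching the
pharmacology); topologies whose alternative cores disagree form a single
core-dependent class.  The observational filter keeps signatures with Wnt
down, BMP up, Hh up and determinate opposing FGF effects; the temporal
filter keeps topologies possessing a core whose positive loop is exactly
{Wnt, eFGF} with Hh in the negative loop.

Known limitation: the published counts for three of the filtered stages
differ slightly from this reconstruction (the diffusivity-constrained
three-component stage, the response-consistent five-component count, and
the temporal count).  The discrepancies trace to a handful of
parameter-dependent prediction cells and marginal grid points whose exact
analytic tie-breaks are not recoverable from the published materials; the
package reports its own computed values rather than adopting the printed
ones.

## In-silico inhibition

Response inhibition scales every weight out of the target by `1 - alpha`
(its self-weight included); production inhibition scales the whole clamped
production term.  Perturbed runs restart from the established pattern,
modelling acute inhibitor addition to a patterned explant (restarting from
noise is available).  The calibrated strength alpha_max is found by
reducing alpha by a factor of 0.25 from complete inhibition
(1, 0.25, 0.0625, 0.015625) until the run re-stabilises with the same
whole-wave count; the geometric reading was adopted because the
arithmetic ladder's floor of 0.25 destroys the pattern in ~95% of valid
two-component parameterisations, which would leave screens of the
published scale nearly empty.  Wave shifts are classified bounded-up /
bounded-down when the mean moves with the troughs / peaks beyond 5% of
the pre-perturbation amplitude.

## Stripe quantification

Stripes are staining maxima (peak prominence >= 0.2 of the normalised
range); boundaries sit at half the height from peak to adjacent trough,
with linear interpolation between samples.  Adjacent peaks whose
intervening trough stays above one third of the peak-to-trough height form
a fused block, split by thresholding against the line joining the block's
outer half-height boundaries (the fused-block rule is underspecified in
the source description; this linear-interpolation reading is the package's
choice).  The most anterior call is flagged unreliable.  Contralateral
shelves are aligned by the rigid shift minimising the squared anchor
(ruga 1 / ruga 8) differences; pairing is greedy by distance, with lost
rugae recorded at width 0 and interrugal intensity, and fusions split in
proportion to control widths.  Displacement statistics report the
fractions of pairs beyond one median untreated displacement.

Kymographs align profiles at ruga 3, average them in a 0.2-day moving
window (total width) on a 600-point time grid, mask cells supported by
fewer than two traces, and re-reference to distance from ruga 8 using a
linear fit of the ruga-3-to-8 distance against age (the growth is linear,
and per-window offsets would jitter rows coherently).  The re-referencing
interpolation never bridges masked holes.  Onset of periodic expression is
where the Spearman correlation with the Shh kymograph (computed per AP
position across time samples, average ranks for ties, bootstrap CIs over
time points) reaches half of its final level — the mean over the anterior
third — and *stays* there up to the anterior reference region, scanning
anteriorly from just anterior of ruga 8; a bare first crossing is
meaningless because staging jitter creates transient correlation pockets
at steep intensity gradients.  For anti-correlated targets the symmetric
negative crossing is reported.

## The synthetic cohort

The generator emulates sequential stripe addition under linear growth: a
new stripe appears one wavelength (150 um) anterior of ruga 8 every 0.4
days (realistic for 4-5 rugae over E12.5-14.0) and is advected anteriorly
at 375 um/day, so stripe age increases with distance from ruga 8.  Stripes
are raised-cosine bumps (full width 60 um, half-height width 30 um).
In-phase readouts reproduce the stripe pattern once a stripe is older than
the gene's onset lag (Hh target 0.15 d, mesenchymal FGF target 0.3 d);
out-of-phase readouts are expressed broadly and *lose* expression at
stripes with the gene's lag (BMP target 0.25 d; epithelial FGF target
immediate) — matching how those targets behave in tissue.  Gaussian
multiplicative (5%) and additive (3%) staining noise is applied before
min-max normalisation; embryo weights grow linearly with age and are
recorded in 25 mg bins.  Contralateral effects scale stripe width and
height per pathway archetype, with stripes below a detection threshold
dropped.

What passing tests on this cohort do show: the pipeline recovers stripe
geometry to better than 10%, staging to < 0.05 days RMS, the signed
direction of all four pharmacological archetypes, and the
simultaneous-versus-lagging partition of pathway onsets.  What they do not
show: robustness to section-to-section registration errors, non-stationary
wavelengths, saturating stain chemistry, or anything about 2-D shelf
geometry — none of which the generator emulates.

## Numerical and design choices, briefly

* Oscillation tolerance `|Im| < 1e-9 (1+|Re|)`; leading-eigenvalue ties by
  larger real part then smaller imaginary magnitude.
* Stride subsampling of the coefficient grid is supported for desk-scale
  screens; full-grid counts are grid-value-sensitive and are reported, not
  asserted.
* The wave count is half the number of sign changes of the demeaned
  profile (values within 1e-9 of the mean snapped to zero so exact-period
  boundaries count).
* Problem sizes in the shipped tests: 50 DDI parameterisations per valid
  three-component topology for the prediction-versus-simulation
  comparison (500 total), 60-specimen cohorts, 3-value coefficient grids
  for screen property checks.  These are the package's standard desk-scale
  settings.
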