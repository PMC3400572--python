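# Methods

This note documents the models, numerics, and design choices behind
`dendsum`. The package studies how the *location* of excitatory synapses on
a pyramidal-neuron basal dendrite shapes their interaction: distal inputs
mostly lower the local NMDA-spike threshold of more proximal inputs, while
proximal inputs both lower the threshold and boost the response magnitude
of distal inputs. Everything runs on synthetic or simulated data; no
recordings are shipped.

## The reduced cell

The default morphology is a ball-and-stick: an isopotential sphere-
equivalent soma carrying four identical terminal basal dendrites of
275 um, plus a myelinated axon (10 x 2 um hillock; three 100 x 1.5 um
internodes separated by 1 x 1 um nodes) for spike initiation. Standard
passive and active parameters:

| property | value |
| --- | --- |
| R_m | dendrites 10 kOhm cm^2, axon nodes 0.05, other 20 |
| C_m | dendrites 2 uF/cm^2, myelin 0.05, other 1 |
| R_a | 100 Ohm cm |
| E_leak | -70 mV |
| gbar_Na | dendrites 0.006 S/cm^2 (tapering linearly to 0 at 200 um), soma 0.25, non-myelinated axon 5, myelin 0.006 |
| gbar_K | dendrites 0.0003, soma 0.03, axon 0.05 |
| E_Na / E_K | +60 / -90 mV |
| AMPA | g_max 1.5 nS, tau 0.05/0.5 ms |
| NMDA | g_max 3.56 nS (single pulse) or 3.9 nS (Poisson runs), tau 2.1/18.8 ms, Mg block B(V) = 1/(1+exp(-(V+12)/10)) |

Terminal dendrites carry a spine-area correction: membrane capacitance and
leak conductance are multiplied by 2.0. Synaptic conductances are
difference-of-exponentials waveforms peak-normalized to g_max; each
activation contributes one AMPA and one NMDA conductance at the same site.
Synapse clusters are centered on a stated path distance with 0.5 um
spacing. Stimulus coordinates are path distances from the soma along the
dendrite; the soma's own extent does not count.

**Calibration.** Three quantities were fixed once, by a coarse parameter
scan, and not revisited: the branch diameter (0.7 um), the effective soma
diameter (60 um), and a +25 mV voltage shift applied to the
Hodgkin-Huxley rate functions. The large effective soma lumps the somatic
plus proximal-apical membrane load of a full layer-5 reconstruction that
the reduced morphology does not represent; the voltage shift sets the
axo-somatic spike threshold high enough that subthreshold two-input
protocols remain spike-free while strong current drive still fires the
cell. With these values, single-site ramps give max NRLE ~3.4-3.5 at both
70 and 160 um and the (90, 150) um double-pulse grid peaks at ~16.4 mV at
the soma.

HH kinetics are the classic m^3 h sodium and n^4 potassium formulations
(n^1 selectable), with all rates multiplied by a Q10 factor of
2.3^((35-23)/10) ~ 2.72 for 35 C.

## Numerics

The cable equation is discretized per section into the smallest odd number
of segments making each segment no longer than min(lambda_100/10, 10 um),
with the frequency-dependent length constant
lambda_f = (1/2) sqrt(d / (pi f R_a C_m)) (spine-corrected C_m where
applicable). Odd counts guarantee a segment center at each section
midpoint, giving stable recording/stimulus placement. Children of the soma
attach at the soma's central segment; other children attach at the
parent's distal end.

Time stepping is a staggered semi-implicit scheme: the voltage advances by
backward Euler with an exact O(n) Gaussian elimination on the tree per
step (Hines ordering; numba-accelerated when available, with an identical
pure-python fallback); channel gates use Rush-Larsen exponential updates
at the previous voltage; synaptic conductances are sampled at the step
midpoint and the NMDA Mg block at the linearly extrapolated midpoint
voltage. The midpoint sampling matters: with end-of-step sampling the peak
EPSP carries a ~2-3% first-order error at dt = 0.1 ms, with midpoint
sampling it drops to ~0.3% away from the regenerative threshold (points
straddling the NMDA-spike jump converge more slowly, as any bistable
transition does). Each simulation starts from a resting state obtained by
200 ms of stimulus-free settling, cached per parameter set; with no
stimulus the somatic voltage drifts by < 0.5 mV over 500 ms.

Internal units: mV, ms, nA, uS, nF.

## NRLE and threshold detection

For each point of an input-output curve from the second onward, a
least-squares line through all preceding points is extrapolated to that
point's abscissa; the maximum ratio of actual to extrapolated response is
the NRLE, and the maximizing index is the just-suprathreshold point (the
point before it, just-subthreshold). A curve counts as spiking when its
NRLE exceeds a jump criterion (default 1.3). Three edge rules:

* curves that do not include an x = 0 sample are anchored with the
  physically forced point (0, 0), making the first fit well-posed
  (toggleable);
* when exactly one preceding point is available (only possible on
  modulator-biased curves whose first sample sits at x = 0 with a nonzero
  response), the degenerate "line" is the horizontal through that point --
  this is what makes the circle fiducial detectable when a strong bias
  pushes the first distal increment over threshold;
* non-positive extrapolations are skipped with a logged warning (the
  ratio is meaningless there).

NRLE is invariant to separate positive rescaling of both axes, which is
exactly why heterogeneous cells can be compared after two-factor
normalization.

## Two-compartment circuit

The time-invariant circuit has a proximal node (doubling as the soma
readout) and a distal node joined by an axial conductance (2.5 A.U.), each
with a leak to rest (proximal 4, distal 0.25 A.U.) and a steady NMDA
source of 0.5 A.U. per synapse gated by a softened Mg block
B(V) = 1/(1+exp(-(V+22)/12)) (the softening stands in for the AMPA
fraction the circuit omits). Voltages are absolute mV (rest -70, synaptic
reversal 0) so the printed block midpoint is meaningful; "A.U." applies to
conductances and currents only, and a final linear output scale maps the
proximal depolarization onto mV of somatic response (fixed by matching the
surface's overall peak to the cable model's grid peak).

The distal Kirchhoff equation is explicit in the proximal voltage, so the
system reduces to one equation in V_dist, scanned over [E_rest, E_syn]
for sign changes and refined by Brent's method to KCL residuals below
1e-9. All roots are retained; the rest-connected (lowest) root is the
default solution, matching a quasi-static reading of the time-invariant
model. A 2-D damped-Newton solve from many starts and a capacitive ODE
relaxation both serve as independent test oracles. The current-to-overcome
(CTO) at a node held at voltage V is the NMDA drive minus the net
leak+axial current with the other node settled passively; it vanishes
exactly at steady states.

## Two-input protocols

Grid experiments activate a proximal (90 um) and a distal (150 um)
cluster simultaneously over 0-40 synapses per site and record the peak
somatic depolarization. The canonical protocol is the 50 Hz double pulse:
two activations 20 ms apart with the NMDA conductance doubling from 2.23
to 4.46 nS on the second pulse (AMPA fixed at 1.5 nS) -- a per-pulse
conductance schedule, not a kinetic scheme, because that is how the
facilitation is specified. Single-pulse (uncaging-like) ramps use NMDA
3.56 nS. NMDA-receptor block is modeled by zeroing the NMDA conductance.
Grids default to steps of 2 synapses (21 x 21); peak responses are cached
by configuration so families and maps reuse each other's simulations.

Curve families are orthogonal slices of a map. The asymmetry metric is the
relative increase of a driver curve's maximum under the strongest
modulation level; threshold shifts are tracked as the NRLE-maximizing
index per modulation level until no jump remains.

**Between-branch additivity.** The within/between contrast is quantified
with the distal modulator restricted to counts below its own local-spike
threshold (0-9 synapses) and the proximal driver over its full range;
the between layout moves the distal cluster to a sibling dendrite at the
same path distance. The additivity deviation is
max |r(i,j) - r(i,0) - r(0,j) + r(0,0)| divided by the family's dynamic
range. On the full 0-40 x 0-40 grid the contrast collapses to ~1.8x on
this reduced cell: single-branch responses are large (~16 mV) relative to
the soma's load, so deep-saturation corners interact through the soma
even across branches. In the sub-spike-modulator regime -- the regime the
suprathreshold protocol also uses -- the contrast is ~6x.

## Fiducial normalization

Four landmarks of a cell's two-input family (distal driver, proximal
modulator view): triangle = just-suprathreshold distal-alone response
(driver intensity, peak); square / pentagon = just-sub/supra-threshold
proximal-alone peaks (x = 0); circle = just-suprathreshold distal response
under a simultaneous just-subthreshold proximal bias. The fixed template
is triangle (1, 1), square (0, 0.6), pentagon (0, 2.4), circle
(0.6, 2.2). Per cell, one horizontal and one vertical factor minimize the
MSE between scaled fiducials and template -- a separable least-squares
problem with the closed form a_x = sum(x_i t_x,i)/sum(x_i^2) over the
nonzero-x landmarks (triangle and circle both contribute) and the
analogous a_y over all four. Only these two factors rescale the cell's
full table (both intensity axes share a_x), so the landmark fit cannot
overfit the curves. The orthogonal (proximal-driver) view is rigidly
scaled by a single landmark: the pentagon, carrying its driver intensity,
goes to (1, 2.4). When extracting landmarks from measured tables, the
recorded zero-stimulus samples of the "alone" curves are dropped in favor
of the exact anchored origin, since they are pure measurement noise.

## Synthetic cohorts

A cohort emulates the heterogeneity the normalization assumes: each of 6
cells is the canonical model-generated map with both intensity axes
multiplied by a hidden x-scale and responses by a hidden y-scale
(log-normal, unit median, sigma 0.3 -- positivity-preserving and
symmetric on the log scale), subsampled to 29-56 stimulus pairs (a preset
fixes per-cell counts summing to 294), plus additive Gaussian measurement
noise (default 0.3 mV, ~2% of the response range; the true experimental
magnitude is not known, so this is a stated assumption). The subsample
always contains the fiducial-defining curves (both alone-ramps and the
distal ramps bracketing the subthreshold proximal bias). A draw is
rejected and retried when fiducial extraction fails *or* detects the jump
at the wrong (unwarped) stimulus level -- the synthetic counterpart of an
experimenter visually confirming the spike threshold; at the default
noise this retry fires occasionally, at 50 mV noise generation correctly
gives up.

What the generator does *not* emulate: cell-to-cell differences in curve
shape (every cell is a warp of one canonical surface), correlated or
multiplicative measurement noise, stimulation-channel crosstalk, and
pharmacological condition effects (a metadata label at most). Passing
recovery tests therefore show that the normalization machinery inverts
exactly the heterogeneity it models -- axis scaling plus additive noise --
not that real slice data obey that model.

## Spike-rate protocol

Independent 50 Hz Poisson trains (exponential inter-event intervals,
per-synapse streams, seeded) drive a proximal (90 um) and a distal
(190 um) group for 500 ms with NMDA fixed at 3.9 nS (no pulse-to-pulse
facilitation under asynchronous drive). The soma receives a
piecewise-constant Gaussian bias current redrawn every 0.1 ms; the printed
0.75 +/- 1 nA applies to a full reconstruction, so on the reduced cell
the mean is auto-calibrated by bisection to a 0.5-2 Hz background (the
operative specification) with the s.d. kept at 1 nA. Spikes are upward
0 mV crossings with a 2 ms refractory window -- unambiguous on HH-style
spikes -- and rates average over the 500 ms window and over repetitions
(default 20; analysis scripts use 8, tests fewer). Rate curves are
fitted with r(x) = r0 + A/(1+exp(-(x-theta)/s)) by multi-start least
squares (threshold starts spanning the driver range, two steepness
starts); gain is the maximum slope alpha = A/(4s); near-flat curves are
flagged rather than fitted.

## EPSP distance sweep

AMPA-only synapses (0.2/2 ms, 2 nS) probe cable filtering: per set, one
synapse on each of 4 randomly selected dendrites at a common path
distance, activated simultaneously on a passive membrane with R_m and C_m
scaled by 1.6 (matching the slower half-width range of the visual-cortex
data this analysis mirrors). The default sweep tree has eight terminal
dendrites with heterogeneous lengths (255-310 um) and diameters
(0.6-0.9 um) so random sets differ. Metrics: amplitude = peak minus
baseline mean; half-width at 50% amplitude and 10-90% rise time (20-80%
selectable), both with linear interpolation between samples. On this
reduced tree only the orderings are meaningful -- amplitude falls,
half-width and rise time grow with distance; the printed compound-EPSP
means of the original layer-3 study require that reconstruction, which
users can supply as SWC.

## Problem sizes

Default experiment sizes were chosen for desk-scale runs on one core: the
acceptance pipeline uses 20-point ramps at two sites plus one 21 x 21
double-pulse grid (~1 min total); the test suite adds the between-branch
comparison (9 x 4 grids in both layouts), a 41 x 41 two-compartment
surface with a multi-start Newton cross-check, small Poisson-rate
experiments (2 x 2 grid, 5 repetitions), and a 4-set EPSP sweep (~2 min
total). The full-figure analysis scripts under `analysis/` use larger
grids and repetitions and state their runtimes in their docstrings.

## Known limitations

* The reduced morphology reproduces the *form* of the location-dependent
  interactions, not the printed statistics of any full reconstruction;
  the effective soma absorbs the missing arbor.
* The suprathreshold gain/threshold asymmetry does not emerge cleanly on
  the reduced cell: under sustained asynchronous drive the thin branch's
  NMDA plateau ignites abruptly (near-bistable) rather than gradually,
  and the bias-depolarized somatic operating point compresses firing to
  roughly 0-10 Hz, so same-branch modulation occludes more than it
  modulates. The spike-rate machinery itself (Poisson drive, spike
  counting, sigmoid fits, additivity metric) is exact and tested; the
  full-arbor pattern needs a full-arbor model, which users can supply as
  SWC.
* NMDA facilitation is a per-pulse conductance schedule; no use-dependent
  kinetics.
* No calcium dynamics, plateau potentials, or inhibition.
* The backward-Euler/midpoint scheme is robust but first-order at spike
  onset; spike *counts* are stable, spike shapes are not resolution-
  independent at dt = 0.1 ms.
* The two-compartment solver assumes the scanned interval
  [E_rest - 1, E_syn + 1] brackets all roots, which holds for
  physiological parameters (drives are depolarizing, reversal at 0 mV).
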