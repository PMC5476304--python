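# Methods

## The model

`mprfit` studies membrane potential resonance (MPR) in the pacemaker PD
neuron of the crab pyloric network with a single-compartment voltage-clamp
model.  Because the voltage is prescribed, the membrane equation never has
to be solved; the measured quantity is the clamp current

    I_clamp = I_Cm + I_L + I_Ca + I_H,

with capacitive current `I_Cm = C_m dV/dt`, ohmic leak
`I_L = g_L (V - E_L)`, a low-threshold calcium current
`I_Ca = g_Ca m_Ca^3 h_Ca (V - E_Ca)` and a hyperpolarization-activated
inward current `I_H = g_H m_H (V - E_H)`.  Each gate relaxes to a sigmoid
steady state,

    dx/dt = (x_inf(V) - x) / tau_x,   x_inf(V) = 1 / (1 + exp((V - V_x)/k_x)),

so only three ODEs (m_H, m_Ca, h_Ca) are integrated.  Slope factors are
fixed: k_mCa = -8 mV (calcium activation opens with depolarization),
k_hCa = +6 mV (inactivation), k_mH = +7 mV.  The sign of k_mH deserves a
note: the H gate must open with *hyper*polarization — it carries inward
current at the bottom of the oscillation range, deactivates slowly on
depolarization, and shifting its midpoint from -70 to -96 mV must rescale
the fitted g_H upward roughly tenfold — all of which require a decreasing
m_H_inf(V).  With the opposite sign the H current degenerates into a
quasi-static leak and optimization simply switches it off, which
contradicts the sizeable fitted g_H of real PD populations.

The I_H time constant is voltage dependent,
`tau_mH(V) = tau_mH_max / (1 + exp((V + 110)/-13))` (ms), close to its
maximum over the working range; the calcium time constants are
voltage independent.  Eight parameters are free (Table: bounds in
`params.DEFAULT_BOUNDS`): g_L in [0, 0.15] uS, g_H and g_Ca in
[0, 0.35] uS, tau_mH_max in [0, 3000] ms, V_half_mCa and V_half_hCa in
[-75, -30] mV, tau_mCa in [0, 100] ms, tau_hCa in [0, 1000] ms.

Reversal potentials are not experimentally pinned for this preparation;
the defaults E_L = -60, E_Ca = +120, E_H = -20 mV are typical crustacean
stomatogastric values and are configuration-overridable.  Fitted maximal
conductances trade off against the assumed driving forces, so their
absolute scale is comparable across studies only up to that choice.  A
probe over E_Ca in {60, 90, 120} and E_H in {-40, -20, 0} mV moved the
best attainable fit error by well under one percentage point, so none of
the population-level conclusions depend on the choice.

## Clamp protocol and impedance measurement

The impedance probe is a logarithmic ZAP sweep: V(t) = v0 + v1 sin(2 pi
F(t)) with F(t) = f_lo t (f_hi/f_lo)^(t/T), v0 = -45 mV, v1 = 15 mV,
f_lo = 0.1 Hz, f_hi = 4 Hz, T = 100 s, preceded by three 0.1 Hz sine
cycles that join the chirp with continuous value and slope (130 s total).
The phase function is implemented exactly in this printed form; its literal
instantaneous frequency overshoots f_hi near t = T, which only produces
trailing fast cycles that the profile builder truncates at 1.15 f_hi.
Frequencies are always assigned per cycle as the reciprocal of the measured
trough-to-trough period, never from F'(t).

Impedance is measured cycle by cycle (no Fourier estimates): |Z| is the
ratio of voltage to current peak-to-peak amplitude (mV/nA = MOhm) and the
phase is 2 pi f times the lag from the current peak to the voltage peak,
wrapped to (-pi, pi], so a capacitive current (peaking early) gives
negative phase.  Peak times are refined by a three-point parabola.  The
first two pre-cycles are discarded as equilibration; the final pre-cycle is
retained because it is the only cycle measured exactly at f_lo — without
it the lowest measured cycle sits ~18% above f_lo and Z(f0) becomes an
extrapolation.

## Attributes and objectives

Ten scalar attributes summarize a profile (all extracted inside the
[0.1, 4] Hz band):

* Z side: Z0 = Z(0.1 Hz); the resonance peak (f_res, Z_max) from a local
  quadratic fit around the discrete maximum; Z(4 Hz); and the impedance at
  the two *bandwidth pin* frequencies 0.4 and 2.5 Hz.  The pins are the
  half-height frequencies of the reference neuron's profile — the level
  midway between its peak and its 4 Hz endpoint — and fitted profiles are
  pinned to the target's points at the target's own frequencies.  (The
  profile's own half-height crossings are reported separately; their spread
  is the bandwidth Lambda_1/2.)  Q_Z = Z_max - Z0 is the resonance power.
* phi side: phi(0.1 Hz); the maximal advance (f_phimax, phi_max); the zero
  crossing f_phi0 (phasonance) by linear interpolation; phi(2 Hz); and the
  maximal delay (f_phimin, phi_min).

Each attribute defines one objective: the normalized distance between the
model's and the target's attribute.  Frequencies are normalized by the
target frequency, impedances by the target impedance, and phases by a fixed
0.5 rad scale (phase targets can be zero, so a relative error is not
defined for them).  Pinned fixed-frequency attributes contribute |delta|
of the value alone; two-coordinate attributes contribute the Euclidean
norm of their normalized coordinates.  Failed simulations receive a large
finite penalty (1e6) on all objectives; individually undefined attributes
(no resonance, no zero crossing) receive 1e3 on their objective, so broken
candidates still flow through the selection machinery.

The reference target is the printed profile of a single biological PD
neuron: Z points (0.1, 8.2), (1, 13.7), (0.4, 11.65), (2.5, 11.65),
(4, 9.6) (Hz, MOhm) and phase points (0.1, 0), (0.4, 0.5), (1.05, 0),
(2, -0.4), (4, -0.4) (Hz, rad).  The published phase value at 2 Hz is
garbled ("-4"); -0.4 rad restores the dropped decimal and is the only
reading consistent with the phase profiles of models that capture every
other attribute (their phase is nearly flat between 2 and 4 Hz).
Similarly, the printed half-height values equal (Z_max + Z(4 Hz))/2
exactly, which fixes the half-level convention described above.

**Acceptance screen.**  A model is accepted when every acceptance-relevant
attribute is within 5% of the target: relative errors for Z0, f_res,
Z_max, Z(4), the two pins, f_phi0, phi(2) and phi_min, and |phi(0.1)| <=
0.05 rad for the zero-valued phase target.  phi_max is excluded: single
compartment models systematically undershoot the biological ~0.5 rad
advance, plausibly reflecting morphology or currents outside the model.

## Search

NSGA-II over the eight-parameter box: random uniform initialization
(population 100), binary tournament mating, simulated binary crossover
(distribution index 20, 0.5 per gene), bounded polynomial mutation (rate
1/8 per gene, index 20), and (mu+lambda) elitist survival through fast
non-dominated sorting with crowding distance, run for 200 generations per
seed with 3-5 seeds pooled.  Of each generation's parent pairs, 30% are
recombined by an arithmetic *line* crossover (children drawn on the
parents' connecting segment, alpha ~ U(-0.25, 1.25)) instead of SBX, and
60% by SBX; 10% pass through unchanged.  The acceptable-model set is a
narrow valley running diagonally through parameter space, and per-gene
mixing of two valley points tends to leave the valley; children along the
parents' difference vector follow it, which turns the final percent of
refinement from a matter of seed luck into routine convergence.

A second adaptation was necessary.  With ten strongly correlated objectives,
essentially every candidate is non-dominated within a few generations;
truncating a single giant front by crowding alone preserves per-objective
extremes while churning away balanced solutions, and the search provably
stalls (the identical machinery solves two-objective benchmarks to
optimality).  Selection is therefore hybrid: rank ties in the mating
tournament are broken by the *acceptance score* — the largest
acceptance-relevant attribute error, the same scalar the 5% screen
thresholds — and front truncation fills half its slots with the lowest
scores, the other half by crowding.  Dominance ranking, the operators and
the elitist structure are otherwise canonical.  Every evaluated candidate
that passes the screen is archived with its generation, so the "optimal
dataset" pools good models found anywhere along the search; near-duplicate
parameter vectors (6 significant digits) are merged.

Under these settings a run archives thousands of accepted models against a
self-consistent (synthetic) target.  Against the biological target the
accepted region is an order of magnitude tighter — its best attainable
max-error is ~4.5%, reached in a neighbourhood of the published population
medians — and individual seeds either break into it (then archiving
thousands of models) or plateau just outside (~5.5-6%); pooling several
seeds is what makes the accepted set reliably non-empty, which is the same
reason the original protocol pools repeated runs.

## Numerical integration

Gates are advanced with Heun's explicit trapezoidal rule (the standard
reading of "modified Euler") at dt = 0.2 ms; voltage, its analytic
derivative and the sigmoid tables are evaluated per sample inside a
compiled kernel.  When a time constant falls below the step (possible at
the box edge, tau -> 0), that gate is set directly to its steady state —
the physically correct fast limit — and gates are clipped to [0, 1] as a
safety net; a warning is raised when dt exceeds half the smallest time
constant.  I_Cm uses the analytic chirp derivative, keeping phase
estimates free of differentiation noise.

dt = 0.5 ms is the *fast mode* used for population-scale work: across
dt in {0.5, 0.2, 0.1} every reported attribute of a resonant model moves
by less than 0.1% (and the acceptance screen's witness model by < 0.2%),
two orders below the acceptance tolerance.  Traces and small analyses
default to 0.2 ms.

## Synthetic targets

`synthetic.make_target` turns any sufficiently resonant parameter set
(Q_Z/Z0 >= 0.1) into a fitting target by measuring its attributes through
the full simulate -> profile -> attributes chain, re-anchoring the
bandwidth pins at the truth's own half-height crossings.  Optional noise
multiplies the Z and phi values by 1 + sigma N(0,1) — attributes are what
the fit consumes, so that is where measurement noise belongs; frequencies
stay clean.  The generator emulates the role of the biological recording
exactly (ten attribute points), but not trial-to-trial variability,
electrode artifacts or unmodelled currents, so passing recovery tests
demonstrates identifiability of this model family under its own
assumptions, not robustness to biological mismatch.

## Population analyses

*Correlations.*  Pairwise Pearson coefficients over the accepted
population, with a permutation test (default 1000 permutations, two-sided
on |R|) and a regression-slope t test; the procedure is repeated over
random 20-model subsets (2000 by default) and the fraction of subsets with
p < 0.01 is reported.  An optional Benjamini-Hochberg column is available
and clearly an extension — the original screen is raw p < 0.01.  The
population splits into low and high g_Ca groups at 0.05 uS (ties go high);
the per-group p-value matrix is reported with the low group in the lower
triangle.

*Voltage-range experiment.*  Accepted models are re-profiled with the
clamp floor moved from -60 to -70 mV and the shifts in f_res and Z_max
recorded.  The "intermediate" subset is the part of the accepted
population whose shifted-range profile reproduces the biological response
— f_res reduced by ~0.24 Hz with Z_max unchanged — each within 5%.

*Sensitivity.*  Multiplicative parameters are stepped as
p = exp(+-0.001*1.15^n) p0 and both axes use log-changes, so a power-law
attribute recovers its exponent exactly; additive voltage midpoints move
in +-0.5 mV increments with the raw mV change on the x axis.  Symmetric
pairs are added until R^2 of the linear fit drops below 0.98.  For
correlated pairs, the population line is fit in median-normalized space
(each multiplicative parameter divided by the group median; additive
voltages in raw mV) — "perpendicular" is meaningless across raw units —
and each sampled model is explored along the parallel and perpendicular
lines through its own point, the second parameter following the line.
Paired parallel-vs-perpendicular slope magnitudes are compared per model
(sign/Wilcoxon tests); no repeated-measures ANOVA machinery is attempted.

## Problem sizes used by the test suite and acceptance script

Fitting runs use the 0.5 ms fast mode: the biological-target population
pools seeds 1-3 at 100 x 150 (population x generations) in the test suite
and 100 x 170 in the reproduction script; parameter recovery uses three
synthetic targets at 100 x 100; the variant analyses (V_half_mH = -96 mV,
g_H = 0) use scaled 48 x 60 runs.  Downstream analyses
subsample the accepted population (hundreds of models for the V_low
experiment, tens for sensitivity lines) — spreads shrink but group means
and orderings are stable at these sizes.

## Known limitations

* Absolute conductance scales inherit the assumed reversal potentials.
* The accepted region around the literal printed target is narrow, so
  whether a *specific* seed's search enters it is stochastic; pooled
  multi-seed runs are the supported protocol.
* The acceptance handling of zero-valued phase targets (|phi| <= 0.05 rad)
  is a convention; the original work does not define "5% of zero".
* Current-clamp behaviour, spiking currents and calcium dynamics are out
  of scope; the TTX-like, decentralized voltage-clamp preparation is the
  only regime represented.
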