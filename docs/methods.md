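# Methods

## Signal model and fitting

A stopped-flow FRET time course is modelled as a sum of exponential
relaxations, `F(t) = F0 + Σᵢ Fᵢ·exp(−k_app,i·t)` with baseline `F0`
(volts), per-phase amplitudes `Fᵢ` (volts, sign giving the direction of
the fluorescence change) and apparent rates `k_app,i` (s⁻¹). Fits use
nonlinear least squares (Levenberg–Marquardt via lmfit) initialised by
variable projection: candidate rates are scanned on a log grid from half
a decay per trace to the angular-Nyquist scale of the sampling,
`π/(10·Δt)`, with baseline and amplitudes solved linearly at each
candidate. This initialisation is robust to the hundred-fold rate
separations between fast and slow conformational phases and, on
noiseless synthetic input, the refined fit recovers the generating
parameters to better than 10⁻⁶ relative error. Standard errors are
asymptotic (covariance scaled by reduced chi-square). The phase count
(1 or 2) is chosen by small-sample-corrected AIC when not supplied; ties
favour one phase. Two-phase fits whose rates are separated by less than
3-fold are flagged as poorly separable; a rate whose standard error
exceeds the rate itself is flagged unidentifiable rather than trusted.

Replicates are fitted independently and aggregated per concentration as
mean ± SD (phases matched by decreasing rate); averaging the traces
before fitting is available as an option. Rate–concentration series are
fitted with the two-step rapid-equilibrium law
`k_app = V_max·[C]/(K_s + [C])` or the bimolecular law
`k_app = k₁·[C] + k₋₁` (statsmodels WLS), weighted by 1/SD² and falling
back to unweighted when any SD is zero (e.g. noiseless data or
numerically identical replicates, where tiny SDs from floating-point
cancellation are snapped to zero below 10⁻¹² relative). The hyperbolic
law carries no intercept by default; a `+k_rev` intercept variant is
available but off. Confidence intervals are t-based at the fit's
residual degrees of freedom. Perfectly curvature-free series leave
`V_max` and `K_s` identified only as a ratio; such fits are returned
with an ill-conditioning warning and a `K_s` upper bound rather than an
exception.

The amplitude-weighted average rate is
`k_AV = Σ Fᵢ·k_app,i / Σ Fᵢ` (interpreting the denominator as the sum
over all phase amplitudes, consistent with its error propagation). Its
uncertainty combines, in quadrature, the relative errors of the
amplitude–rate products in the numerator and of the amplitude sum in the
denominator, each term built from the per-phase means and SDs. The
statistic is bounded by the minimum and maximum phase rates, invariant
under phase reordering and under homogeneous rescaling of all
(Fᵢ, σ_Fᵢ) pairs. The titration pipeline also computes `k_AV` per
replicate and reports the mean ± SD across replicates, since averaging
the nonlinear statistic per replicate and averaging its inputs first do
not commute.

Cycle chaining accumulates the signed total amplitude of each reaction
into a cumulative level profile normalised to [0, 1]. For a
signal-conserving cycle the closure residual (final minus initial level)
is zero within the propagated standard error of the amplitude estimates.

## Synthetic study conditions

The generator emulates the stopped-flow design the analysis targets:
1000 samples per trace on a linear grid over five time constants of the
slowest phase, 7 replicates per reaction spawned deterministically from
a single master seed, additive i.i.d. Gaussian noise with SD equal to 2%
of the total signal amplitude (a typical photomultiplier shot-noise
scale; configurable — the instrument noise magnitude and acquisition
window are not constrained by the data being emulated), and titrant in
pseudo-first-order excess over the 0.05 µM labelled complex (a warning,
not an error, below 5-fold excess, matching real designs that titrate
down to the complex concentration). Mixing dead time, photobleaching and
mixing artifacts are not modelled; fluorophores are static per-species
fluorescence levels with no photophysics. Passing recovery tests on
these data therefore demonstrates correctness of the estimators under
the stated noise model, not robustness to instrument systematics.

Titrations can be generated two ways. The ODE route integrates the
two-step scheme R + L ⇌ RL → RL* (LSODA, rtol 10⁻⁹) with the binding
step equilibrating 100× faster than the isomerization, and reproduces
the rapid-equilibrium closed form within 5% whenever binding relaxation
exceeds 50× the conformational rate; a single-step bimolecular variant
gives the linear law exactly. The scenario catalogue instead draws each
phase's apparent rate directly from its rate law (the model fitted to
real data), because a sequential mechanistic chain cannot make two
phases saturate independently — the phase-wise kernel is the
phenomenology the per-phase analysis assumes, and the ODE route is
cross-validated against it in the monophasic case.

Scenario defaults: six titrant concentrations between 0.05 and 1 µM
(0.1–1 µM for the bimolecular tRNA scenarios); `K_s = 0.1 µM` for every
hyperbolic phase, chosen once so the grid spans half- to ten-fold
saturation as in measured rate plots (no equilibration constant is
otherwise pinned down); total amplitudes 2.3, 0.8, 0.7, 0.4, 0.3 and
1.5 V for the 30S, IF2, IF1, tRNA, mRNA and 50S reactions — the 30S
value is the measured 1.4 + 0.9 V split, the others are chosen at the
measured per-reaction scale with signed amplitudes summing to zero so
the cycle closes; the amplitude split of the mRNA-programmed tRNA
scenario is taken 50/50 (unreported). Its two phases overlap in rate at
low titrant; the 1/SD² weighting naturally downweights those points.

## Accessible-volume engine

The dye is a sphere of radius 4.5 Å on a linker of length 15 Å and width
4.5 Å (single-radius AV model; the three-radius variant is out of
scope). A cubic grid of side 2·(linker length + dye radius), default
spacing 1.0 Å (valid range 0.3–2 Å), is centred on the attachment atom
(the labelled cysteine sulfur; the attachment atom itself is excluded
from the clash set). A node is linker-passable when its clearance from
every atom surface exceeds half the linker width, and dye-placeable when
the clearance exceeds the dye radius; van der Waals radii are
element-based (H 1.10, C 1.70, N 1.55, O 1.52, S 1.80, P 1.80 Å;
unknown elements default to 1.70 Å with a warning).

Tether path lengths are shortest passable paths: nodes whose straight
segment to the attachment point is passable (sampled at half-grid steps)
enter a multi-source Dijkstra at their exact Euclidean distance, and the
remainder is bridged over the 26-connected grid with Euclidean edge
weights (scipy sparse graph). The line-of-sight seeding is essential:
the pure 26-neighbour chamfer metric overestimates distances by up to
~11% in skew directions, which would shrink an unobstructed AV well
below the analytic ball of the linker length; with seeding the
unobstructed AV volume matches (4/3)πL³ to a fraction of one grid shell
and improves under grid refinement. A fully buried site yields an empty
AV with a flag, not an exception. The engine is verified against an
independently coded brute-force oracle (per-node exhaustive checks,
hand-rolled heap Dijkstra) on small fixtures, and obeys the expected
monotonicities (longer linker ⇒ superset; wider linker or larger dye ⇒
subset).

Inter-AV distance distributions enumerate all donor–acceptor point pairs
exhaustively up to 10⁷ pairs, else draw seeded uniform pairs
(Monte-Carlo mode agrees with exhaustive means within sampling error);
histograms use 1 Å bins from zero. The interdomain compaction coordinate
is the Euclidean distance between the Cα atoms of the two labelled
positions (65 and 166 by default), vectorised over coordinate ensembles.
State mapping min–max normalises modelled distances and measured
cumulative FRET levels with inverted orientation (shortest distance ↔
maximal FRET) and reports their Spearman rank correlation; it makes no
claim about which structural intermediate corresponds to which kinetic
phase beyond rank order. Conversion of ⟨R_DA⟩ to FRET efficiency is
deliberately excluded: it would require a Förster radius for this dye
pair that is not established.

## Full-cycle run and problem sizes

`run_cycle` executes the six reactions at the scenario defaults,
recovers every phase's saturating parameter with its CI, chains
amplitudes, and models per-state distances on isolated two-site toy
fixtures (grid spacing 1.5 Å in this stage, Monte-Carlo distance
sampling with 5·10⁴ pairs) for the seven cycle states, whose nominal
separations (33–60 Å) follow the compact-free / extended-30S-bound /
IF1-IF2-compacted / reopened / compact-again progression. All randomness
descends from one master seed; reports embed the seed, a config hash and
the package version, and identical configurations reproduce outputs
byte-identically. A full default cycle runs in about two seconds on one
CPU; each acceptance scenario (42 traces of 1000 points plus the
saturation fits) runs in well under a second.

## Known limitations

Global multi-curve fitting with shared microscopic constants, Bayesian
uncertainty, vendor instrument formats and MD production are out of
scope. The AV contract is grid-based and validated against analytic
limits and an internal oracle, not against any external positioning
software; absolute modelled distances on real deposited structures
(an optional, network-dependent workflow) should be treated as
approximate. Efficiencies computed from peak areas or counts assume
pre-integrated inputs; peak detection is not included.
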