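# Methods

## Model

`delaynet` treats each white-matter connection as a transmission line whose
delay is fixed by the microstructure of its largest axons. The chain of
closed-form relations is applied at the *connection* level, to
bundle-averaged quantities:

* **MTV** `= 1 − PD/PD_f` is the macromolecular tissue volume, an MRI proxy
  for myelin content (PD_f is the proton density of free water).
* **AVF** `= (1 − MTV)(1 − f_csf)·f_r` is the axonal volume fraction,
  combining the myelin estimate with the diffusion-derived restricted
  (`f_r`) and free-water (`f_csf`) fractions. A hindered fraction `f_h` is
  produced by the same diffusion models but enters no equation here; it is
  carried only as optional metadata.
* **g-ratio** `g = sqrt(1/(1 + MTV/AVF))` (Stikov model), implemented as
  `sqrt(AVF/(AVF + MTV))` — algebraically identical but finite for
  vanishing AVF.
* **Velocity** `v = k·d·sqrt(−ln g)` (Rushton model) with `k = 7·10⁶ s⁻¹`,
  the value giving best agreement with single-neuron simulations in the
  literature. Diameters are micrometres at every interface and converted to
  metres inside this one formula; with d ≈ 3.4 μm, g ≈ 0.7 this yields
  ≈ 12–13 m/s. `g = 1` (no myelin) gives v = 0 by the formula; callers that
  need a finite value can clamp g to 1 − 1e−12.
* **Delay** `τ = L/v` in seconds (lengths in metres); reports print
  milliseconds.

Applying the formulas to edge-averaged inputs is not identical to averaging
voxel-wise formula outputs along streamlines; the two agree only to first
order. All analyses here operate at the per-connection level, so the
edge-level application matches the analysis level, and no claim is made
about order-of-operations equivalence.

## Group network

Delays are computed per subject and edge (edges with undefined g-ratio or
zero velocity are dropped with a warning), then assembled under the
inclusion rule *more than 4 streamlines in at least 9 subjects* — both
inequalities read literally, so a count of exactly 4 never contributes and
an edge present in 8 subjects is excluded. Retained-edge weights are means
over exactly the subjects passing the count criterion; zero-imputation
would bias lengths and diameters downward and is not used. The group delay
is the mean of contributing subjects' delays (`subject_mean`); dividing
group-mean length by group-mean velocity is available as
`delay_aggregation="ratio_of_means"` and differs by a few percent in
practice. A post-hoc bundle filter removes edges with mean diameter
strictly below 1 μm (an edge at exactly 1 μm is kept), mirroring the
spurious-bundle filter of single-subject tractography pipelines.

## Delay-length regression

Ordinary least squares of delay on length, *with* intercept: the implied
constant velocity uses only the slope (v = 1/slope), but suppressing the
intercept would hide a poor fit, so the origin-forced variant is an option
(`through_origin=True`), not the default. The slope is reported at full
precision; an undefined velocity (slope ≤ 0, e.g. constant delays) is
`None`, never NaN-by-accident. Band fractions use closed intervals.

## Graph analysis

Shortest paths use Dijkstra on the delay matrix (scipy's csgraph backend);
disconnected pairs are infinite, with no harmonic-mean fallback.
Betweenness applies the proportion formula directly:
`C_B(i) = Σ ρ_hj(i)/ρ_hj / ((N−1)(N−2))` over ordered pairs with endpoints
excluded — for symmetric networks ordered counting simply doubles
numerator and denominator. Path multiplicities are counted with a relative
tie tolerance of 1e−9 on path delays (configurable): floating-point sums
make exact tie equality fragile, while genuinely distinct delays in these
networks differ by far more than the tolerance. The implementation is
cross-checked in the test suite against exhaustive simple-path enumeration
(≤ 8 nodes) and against networkx's Brandes implementation.

The constant-velocity comparison reports
`100·(sp_cv − sp_est)/sp_est`; the sign and denominator convention is
declared in the output metadata rather than asserted as canonical. Block
summaries partition off-diagonal entries into subcortical (either endpoint
subcortical — taking precedence), LH/RH intra-hemispheric and
inter-hemispheric cortico-cortical blocks; an absent block reports n = 0.

## Kuramoto simulation

The printed delayed Kuramoto equation is integrated exactly as written:
identical natural frequency ω = 2π·40 rad/s (the 40 Hz gamma reading of
"natural frequency"; the conversion is configurable), binary coupling
matrix, **no** 1/N normalisation of the coupling sum (a normalisation
switch exists for sensitivity checks, default off). Integration is explicit
Euler at dt = 1 ms — the delay history buffer requires a fixed step — from
0 to 1 s, with delays rounded to the nearest step (a rounded delay of 0
reads the current phase; rounding up is available). History for t < 0 is
free rotation `θ(0) + ωt`. Initial phases are uniform on [0, 2π); the sweep
randomises only initial phases across its runs, each run seeded as
`SeedSequence([master, coupling_index, run_index])` so any run replays
bit-exactly. Synchrony and metastability are the mean and SD of r(t) over
samples in [0.3 s, 0.7 s], endpoints included. The full protocol is 100
coupling values (0.1–10, step 0.1) × 100 runs; the default pipeline and the
acceptance script use a scaled-down grid (0.5–10, step 0.5; 10 runs),
which resolves the transition location to within a grid step at a fraction
of the cost. The "critical coupling" is the first grid value whose mean
synchrony exceeds 0.5.

## Synthetic generator

The generator emulates the *outputs* of an MRI/tractography front end at
the connection level — never voxels, streamlines or images. Defaults are
the emulated study conditions: 14 subjects, 82 ROIs (34 cortical + 7
subcortical per hemisphere, i.e. a Desikan-Killiany-sized parcellation
after removing cerebellum and brainstem), group edge density 0.25.

* **Lengths** are truncated-gamma on [0.01, 0.25] m (shape 2.4, scale
  0.033 — frozen from a one-off calibration to give a long right tail with
  roughly a quarter of connections below 0.05 m), shared across subjects up
  to 2% multiplicative jitter since length is anatomy-driven.
* **Diameters** are normal around 3.4 μm (SD 0.25 μm) with an extra
  0.6 μm of spread below 0.05 m, reproducing the pronounced short-bundle
  variability; this puts roughly 80% of edges in the 3–4 μm band.
* **The g–d relation** is induced mechanistically: MTV is partially a
  (negative) linear function of the standardised diameter plus noise, and g
  follows through the AVF/Stikov formulas, keeping every edge
  self-consistent under the closed-form model. The MTV–diameter correlation
  is the target R² inflated by a dilution factor 0.87 accounting for the
  f_r/f_csf noise g inherits; the resulting g-on-d R² stays within ±0.05
  of the 0.43 target across seeds (the contract tested is ±0.15).
* **Streamline counts** are Poisson around per-edge gamma-distributed
  means (mean 30 — the count distribution is otherwise unconstrained and
  this is a free choice), with 5% per-subject edge dropout, so the
  inclusion rule has real work to do.
* **Constant-velocity mode** samples diameters within 4 SD of the mean,
  perturbs the target velocity by lognormal noise (fractional SD 0.02 by
  default), and inverts Rushton then Stikov for the g and MTV that
  reproduce each edge velocity exactly; microstructure carries no subject
  jitter in this mode, so length/delay equals the edge velocity identically
  per subject. A target velocity requiring g below 1e−8 at the largest
  admissible diameter is rejected as unachievable.

What the generator does **not** emulate: tractography biases (gyral bias,
bottleneck false positives), distance-dependent streamline attrition,
spatially correlated microstructure, or the exact marginal distributions of
any real dataset. Tests passing on synthetic stacks therefore demonstrate
the correctness and calibration of the *pipeline*, not properties of any
particular acquisition.

## Numerical choices and degenerate inputs

* Formula functions broadcast elementwise and accept a boolean mask;
  masked-out entries are returned as zero and never validated, so sparse
  symmetric matrices keep their pattern, symmetry and zero diagonal.
* Domain violations raise a `DomainError` naming the offending field;
  configuration objects collect *all* violations into one `ConfigError`.
* An empty retained edge set is an explicit `EmptyNetworkError`, not an
  empty result.
* Kuramoto integration aborts with the step index on any non-finite phase;
  the maximum delay must be strictly below the simulated duration.
* r(t) is clipped to [0, 1] against rounding at the 1e−16 level.

## Problem sizes

The default test suite and the acceptance script run the full 82-ROI
pipeline but the scaled-down Kuramoto grid (2 conditions × 20 couplings ×
10 runs, ~1 minute total); graph oracle checks use 200 random graphs of at
most 8 nodes, where exhaustive path enumeration is feasible. The
`--full-protocol` pipeline flag restores the 100 × 100 sweep grid.

## Known limitations

* Diffusion MRI resolves only the largest axons (the upper tail of the
  diameter distribution), so estimated velocities describe the fastest
  fibres of each bundle, not the bundle average — inherent to the approach
  being modelled, and inherited by the synthetic defaults.
* The Rushton model was derived for peripheral nerve; its constant k is a
  literature value, not fitted here.
* Betweenness tie handling is tolerance-based; graphs engineered with
  near-tolerance weight differences can flip multiplicities.
* The Euler integrator is first-order; dt = 1 ms matches the emulated
  protocol but is not adaptive, and very strong coupling (k·degree ≫ 1/dt)
  would require a smaller step.
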