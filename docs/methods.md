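# Methods

`ssepat` analyzes semi-solid-extrusion (SSE) 3D printing of dosage forms
through the pressure signal of an instrumented, motor-driven printhead: it
characterizes the extrudability of a paste from a plunger pressure–time
trace, reduces oscillatory and creep rheometry to the usual gel descriptors,
models the printer's motion from gcode, and turns a whole batch print into
per-printlet quality records. Because the package ships no hardware, a
physics-based simulator generates every input from known ground truth; this
note describes the models, the defaults and the choices made where the
design was open.

## Extrusion simulator

The syringe content is treated as a quasi-statically pressurized reservoir
coupled to a capillary (the print nozzle). Per sample of length `dt`:

* inflow `Q_in = v_plunger · A_syringe` (mm³/s),
* `dP/dt = (Q_in − Q_out) / C`, with `C` the volumetric compliance of
  mass + syringe + seal (mm³/kPa),
* `Q_out = 0` while the internal pressure is below the yield pressure
  `P_y`; above it, Herschel–Bulkley capillary flow: wall stress
  `τ_w = P·r/(2L)`, yield stress `τ_y = P_y·r/(2L)`, wall shear rate
  `γ̇_w = ((τ_w − τ_y)/K)^{1/n}`, and the power-law Rabinowitsch flow
  `Q_out = π r³ · n/(3n+1) · γ̇_w`.

For `n = 1`, `τ_y = 0` this reduces exactly to Hagen–Poiseuille, which the
tests use as an independent closed-form oracle. The measured channel adds a
constant plunger-friction baseline (`F_friction/A_syringe`) and i.i.d.
Gaussian sensor noise; the noise- and friction-free internal pressure is
retained on every trace so that baseline correction can be validated against
ground truth. Extruded mass integrates `ρ·Q_out`.

Default parameters (all overridable):

| parameter | default | rationale |
|---|---|---|
| syringe bore `D` | 19.3 mm | 20 mL Luer-Lock barrel; makes `TPS·(LH/D)²` reproduce the 0.010/0.020/0.030 mm/s protocol speeds |
| nozzle bore | 0.61 mm | 20-gauge tapered tip |
| nozzle length `L` | 25 mm | typical wetted length of that tip |
| compliance `C` | 0.8 mm³/kPa | gives a ~2-minute elastic ramp to yield at the 10 mm/s protocol speed and elastic slopes (`A/C ≈ 370 kPa/mm`) on the scale instrument tables report |
| yield pressure `P_y` | 400 kPa | mid-range of printhead yield points for stiff pharmaceutical pastes |
| consistency `K` | 5 Pa·sⁿ | see below |
| flow index `n` | 0.4 | strongly shear-thinning paste |
| friction force | 2 N | plunger–barrel sliding friction |
| noise SD | 3 kPa | calibrated pressure sensor |

The flow curve is deliberately flat near yield (`K` small relative to the
yield stress, so the steady excess over `P_y` is ~10–20 kPa): the yield
point of the profile extractor is defined as the departure of the
pressure–displacement curve from linearity, and that definition only
identifies the underlying yield pressure sharply when the post-yield
transition is itself sharp. A mass with a broad transition has no single
"pressure where flow starts" to recover. The consequence is that simulated
maximum pressures sit just above the yield pressure, whereas the published
profiles show maxima well above yield; the simulator trades that shape
fidelity for an unambiguous ground truth.

Transient upsets are injected as events: a **clog** scales the nozzle radius
down by its magnitude over its window (pressure climbs at `Q_in/C` toward a
much higher steady level); a **bubble** multiplies the compliance by
`1 + magnitude` with stored volume conserved at onset, so the pressure drops
instantly by `1/(1+magnitude)` and recovers while the extra compliance
persists. Both match the operational signatures used for in-line detection
(pressure rise = obstruction, pressure drop = entrained air).

## Extrudability profile

`extract_profile` locates the compression step and the following hold from
the displacement channel, then computes:

* **Linear (elastic) region** — expanding-window regression of pressure on
  displacement from the start of compression, keeping the longest prefix
  with R² ≥ 0.99 (default), then trimmed backwards while the window's last
  sample deviates more than `rel_tol` from the window's own fit (R² alone
  barely reacts when the window creeps past the yield bend). Its slope is
  the **Young modulus** (kPa/mm).
* **Yield point / yield time** — first sample whose pressure departs from
  the linear fit by more than `rel_tol` (default 5%), sustained for 3
  samples as a noise guard.
* **Maximum pressure** — channel maximum over the compression step.
* **Steady flow** — mean pressure/force over the last 20% of compression.
* **Pressure at flow cessation** — mean over the final 5 s of the hold.
  (The hold, not the post-retraction dwell, is used; by then the pressure
  has relaxed to just above the yield pressure.)
* **Shear rate** `4Q/(πr³)` with `Q = PDS·A_syringe = π·LH²·TPS/4`. The
  legacy shorthand "print speed × syringe radius" is dimensionally
  inconsistent and only available behind `literal=True`.
* **Steady shear stress** — steady force divided by the nozzle
  cross-section `πr²` (default), or the capillary wall stress `ΔP·r/(2L)`
  via `stress_convention="capillary-wall"`. Neither convention reproduces
  published stress columns from published pressures; the nozzle-area
  convention is the default because it matches the stated "area of the tip"
  reading, and all internal identities (apparent viscosity × shear rate =
  stress) hold under either.
* **Viscosities** — apparent = stress/shear-rate (kPa·s); dynamic from the
  capillary force balance `μ = F·π·D⁴/(128·Q·L·A)` (Pa·s). Note that
  stress (kPa) over shear rate (1/s) yields kPa·s, not the mPa·s scale some
  instrument tables label; the package reports SI-consistent units.

All thresholds live in `ProfileConfig` — the detection criteria have no
standard published values, so the defaults were chosen for robustness on
the simulator and are fully configurable.

Baseline correction subtracts a time-interpolated friction-only (empty
syringe) run recorded under the same protocol, clipping at zero; runs whose
durations differ by more than 5% are rejected as protocol mismatches.

## Rheology summaries

* **Gel classification**: gel-like iff G′ > G″ at every frequency and the
  two log–log slopes differ by ≤ 0.1 (parallel weak power laws).
* **Amplitude sweep**: yield stress = lowest stress where G′ leaves the
  plateau median by > 5%; flow stress = the G′/G″ crossover located by
  log-linear interpolation between the bracketing points (arithmetic
  bracket mean available via flag).
* **Creep recovery**: per 60 s on / 60 s off cycle at 500 Pa, recovery
  % = 100·(peak − residual)/(peak − initial). Strains are read from the
  last sample strictly before each step boundary so the instantaneous
  elastic jump at the boundary is not mixed into the wrong phase.

The rheometer simulator uses weak power-law sweeps, a plateau-then-decay
amplitude response (G″ decaying with half the exponent of G′ so the moduli
cross above the characteristic stress) and Boltzmann superposition of a
Burgers (Maxwell + Kelvin–Voigt) compliance for multi-cycle creep — so the
unrecovered strain per cycle has the closed form `σ·t_on/η₁` used as an
oracle.

## Motion model and PAT

The batch designer lays cylindrical printlets (6 mm radius, 2.4 mm height,
0.61 mm layers → 4 layers) on a square grid. "Spaced by 1 cm" is read as a
10 mm edge-to-edge gap (22 mm pitch), since a 10 mm center pitch would
overlap 12 mm printlets. Toolpaths are a minimal slicer's: two concentric
perimeters plus rectilinear infill at the configured fraction, alternating
direction by layer. Priming printlets print first in scan order; the main
printlets receive their speeds by a seeded uniform permutation that rewrites
only the F words of printing moves.

The motion timeline replays gcode with constant-velocity kinematics — no
acceleration model, because the analysis is defined in terms of commanded
speed. Print-run simulation couples the commanded nozzle speed to the
plunger through `PDS = TPS·(LH/D)²` on extruding moves and zero on travel,
and shares the timeline's time base, so trace/timeline synchronization is
exact by construction (a configurable offset exists for imported data).

Per-printlet records carry the time-weighted mean pressure, the trapezoidal
force–time AUC (force = pressure × syringe cross-section, N·s), duration,
weight (from the extruded-mass channel when present) and anomaly flags.

Anomaly detection uses a trailing 10 s rolling median as the local baseline
and the scaled MAD of the full residual series as a global robust noise
floor; excursions beyond 4 robust SDs sustained ≥ 1 s become events
(same-kind events closer than 1 s merge), attributed to the printlet active
at peak deviation. The baseline is trailing rather than centered because a
centered median tracks a slow clog ramp perfectly and would never flag it;
the global (not rolling) MAD avoids the complementary failure where the
ramp inflates the local MAD and masks itself. Sustained-duration filtering
is applied before merging so that isolated noise spikes cannot chain into
spurious events during the initial pressurization ramp.

## Quality statistics

Printlet photographs are thresholded (Otsu), labelled, and measured per
connected component: equivalent-circle diameter `2√(A/π)` (robust to edge
notches; a minimum-enclosing-circle variant was considered and rejected for
that reason), circularity `4πA/P²`, dimensional accuracy
`100·(1 − |d − d_design|/d_design)`, and an edge-defect flag when
circularity < 0.85. Instrument comparison is OLS of B on A per parameter
with Pearson r and its two-sided t-test p. Speed-effect testing runs
per-response one-way ANOVA plus Tukey HSD at family level 0.05, and the
multivariate Wilks' lambda, Pillai's trace and Roy's greatest root from the
eigenvalues of `W⁻¹B`; a singular within-matrix degrades gracefully to
univariate-only output.

## What the simulator does and does not capture

The generator reproduces the *structure* of real data — friction baselines,
elastic ramps, yield, shear-thinning steady flow, relaxation, speed-dependent
pressures and AUCs, clog/air signatures, gel-like sweeps, partially
recoverable creep, disk-grid batch images — with known ground truth. It does
not model temperature dependence of rheology (temperature is a label;
different temperatures are represented by supplying different fluid
parameters), wall slip, thixotropic structure build-up, acceleration-limited
kinematics, drying shrinkage, or lighting/perspective artifacts in images.
Passing tests therefore demonstrate that the analysis recovers the
quantities this model encodes, not that the model exhausts real printer
behaviour.

## Problem sizes and determinism

Default analyses run a full 60 + 10-printlet batch (≈ 3 500 s of print time
sampled at 10 Hz) and characterization cycles of 670/335/242 s at 10 Hz;
property suites use ~20 seeded replicates. Every stochastic operation takes
an explicit integer seed into `numpy.random.default_rng`; identical seeds
give bit-identical outputs, and the pipeline manifest records the seed and
a config hash.
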