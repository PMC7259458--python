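# Methods

## Model

Each muscle–tendon unit (MTU) is a Hill-type actuator: a contractile
fiber (with a parallel passive elastic element) in series with an elastic
tendon, under the fixed-width pennation assumption (the product
L·sin θ is constant, anchored at the pennation angle θ₀ at optimal fiber
length L₀). All fiber lengths are expressed in units of L₀ at 100%
activation and all forces in units of the maximal isometric force
F₁₀₀ₘₐₓ. A fixed-end contraction at activation *a* is the static balance

(a·f_act(L) + f_pas(L))·cos θ(L) = f_ten(ε),  ε = (L_MTU − L·L₀·cos θ − TSL)/TSL,

with TSL the tendon slack length. No force–velocity or activation
dynamics are modeled: the quantities of interest are the settled
equilibrium length and force, which a forward simulation of a fixed-end
contraction converges to. The reported force is the *active* fiber force
resolved along the tendon; the passive fiber force participates in the
balance but is not counted as force capacity.

### Constitutive curves

* **Active F–L**: Gaussian bell `exp(-(L/L0_eff - 1)^2 / w)`. The width
  `w ≈ 0.1139` is fixed analytically by the anchor
  f_act(0.809) = 0.726 at full activation
  (`w = 0.191^2 / (−ln 0.726)`), the one printed point of the reference
  curve family. A Gaussian was chosen over a spline because it is
  single-parameter, smooth, strictly unimodal, and anchored exactly by
  that point.
* **Activation-dependent shift**: the active optimum sits at
  `L0_eff = 1 + s·(1 − a)` with shift fraction s = 0.15 — 15% longer in
  the passive muscle, the typical value reported for voluntary and
  stimulated muscle — interpolated linearly in (1 − a), the simplest
  form consistent with both endpoints. Only the optimum location moves;
  the curve width is not rescaled (an open choice; no data constrain a
  width change here).
* **Passive fiber F–L**: zero at or below L₀, then
  `expm1(k·(L−1)/e_p)/expm1(k)` with strain-at-F₁₀₀ₘₐₓ e_p = 0.6 and
  shape k = 4 — conventional values; the curve is normalized to reach 1
  at L = 1.6.
* **Tendon force–strain**: quadratic toe continuing C¹ into a linear
  region, parameterized by the strain at F₁₀₀ₘₐₓ ε₀ = 0.04 and the toe
  fraction 0.5 (the toe spans half of ε₀). Both are configurable because
  tendon stiffness is species- and tendon-specific; results at a given
  T/M ratio scale with ε₀. The inverse (strain from force) is closed
  form, which the equilibrium solver and the slack-length calibration
  exploit.

### Equilibrium solver

The balance is parameterized by fiber length: the muscle force at a
candidate length fixes the tendon strain through the inverse tendon
curve and hence an implied MTU length; the root of implied-minus-actual
MTU length is bracketed on normalized lengths [0.01, 1.9]·L0_eff (257
point scan, then Brent's method at ~machine tolerance). Among multiple
sign changes — possible on the descending limb against a near-slack
tendon — the *longest* root is taken, the state continuously connected
to the passive state. Degenerate cases: a zero-length tendon cannot
stretch, so compliant variants reduce to rigid geometry; at zero
activation with the fiber at or below L₀ the zero-force equilibrium is a
continuum, resolved by convention to the tendon-exactly-at-slack
(rigid-geometry) state; an MTU shorter than any force-bearing
configuration returns a flagged slack state with zero force. Converged
solves satisfy a normalized force residual of 1e−9 (typically ~1e−15).

## Calibration

L₀ = L_f·2.36/L_s converts a measured fascicle length at sarcomere
length L_s (µm) to optimal fiber length (2.36 µm is the optimal
sarcomere length for this species). CSA = m/(1060·L₀) and
F₁₀₀ₘₐₓ = 3·10⁵·CSA use muscle density 1060 kg/m³ and specific tension
3·10⁵ N/m². The tendon slack length solves
MTU_model − L_m·cos θ − TSL·(1 + ε(F_p)) = 0 with
F_p = f_pas(L_m/L₀)·cos θ; because F_p depends only on the measured
fiber state, the equation is monotone in TSL and the bracketed solve is
exact to the requested tolerance (recovery on forward-generated data is
~1e−12 m). The calibration accepts any curve set, so measured tendon
curves can replace the default parameterization.

## Sweep design

The factorial sweep crosses muscles × 3 variants × activations
{0, 25, 50, 75, 100%} × 80 passive MTU lengths. Lengths are placed in
normalized fiber-length space: the span 0.55–1.45 is divided into 4 base
regions ("postures") of 20 evenly spaced deviations each, and each
target is mapped to an MTU length by the closed-form zero-activation
inverse. Normalized-space placement gives every muscle identical
operating-range coverage regardless of absolute size, standing in for
the joint-angle sweeps of a full skeletal model (the induced quantity —
passive MTU length — is swept directly). For the packaged 39-muscle
table this is 46,800 conditions, solved in ~15 s on one CPU. Each
variant carries its own activation-0 reference length: the rigid variant
cannot stretch its tendon, so above L₀ its passive fiber is longer than
the compliant variants'. Non-converged conditions are excluded (never
imputed) and more than 1% of them aborts the run; the default
configuration produces none.

## Analyses

1. **Group means**: records are binned by compliance (T/M < 2 vs ≥ 2),
   passive-length limb (ascending < 0.95, plateau 0.95–1.05, descending
   > 1.05 — the plateau band is a convention, configurable) and
   activation; means of length, force and ΔL = L_a − L_0 are reported
   per variant. The mixed-effects inference that consumed these cells in
   the original study design is deliberately not reimplemented.
2. **Sensitivity maps**: matched conditions of two variants are compared
   through %ΔF = 100·(F_complex − F_simple)/F_simple, binned on passive
   length (5% of L₀ steps) × T/M ratio (0.2-wide bins below T/M 2,
   1-wide above); each bin reports its count and the fraction with
   |%ΔF| > 10%. The criterion is two-sided: increases and decreases in
   capacity count alike. %ΔF is undefined when the simpler model's force
   is below 1e−6 (all activation-0 records, deep-slack states); such
   records are excluded and counted rather than capped, since the ratio
   diverges.
3. **Joint capacity**: all muscles of a joint are activated at a uniform
   25% and totalled over a 2°-step angle sweep; moment arms come from
   the tendon-excursion relation r = −dL_MTU/dθ (central difference,
   one-sided at domain boundaries). The F₁₀₀ₘₐₓ-weighted mean moment arm
   summarizes gearing. Reference-posture force and moment are compared
   with the sweep maxima.

## Synthetic data

The packaged table ships the published tendon slack lengths and optimal
fiber lengths of all 39 actuators (21 hip, 18 ankle) with pennation 0
(no pennation angles are printed for this set) and a flagged placeholder
F₁₀₀ₘₐₓ = 30 N — every normalized analysis (lengths, multipliers, %ΔF)
is invariant to it, so only absolute joint-scan newtons are synthetic by
construction. T/M ratios are recomputed from the stored lengths rather
than trusting the printed ratio column (which contains rounding
inconsistencies); the printed column is kept separately for
fixture-integrity checks. Random generators produce muscle sets with
uniform or bimodal T/M distributions (bimodal group means pinned to the
requested "hip-like"/"ankle-like" centers, default 0.71 and 7.82) and
linear MTU-length-vs-angle joint geometries with drawn constant moment
arms, placed so the passive fiber at the reference angle lands on a
requested limb of the F–L curve. All generators are
seed-deterministic.

What the synthetic inputs do *not* emulate: the real limb's
angle-to-MTU-length maps (multi-joint muscles, wrapping surfaces,
nonconstant moment arms), measured tendon curves per muscle, muscle
masses, or pennation. Passing tests therefore validate the mechanism and
its qualitative structure — shortening grows with T/M, compliance
reduces ascending-limb force, sensitivity troughs sit at/above L₀ and
migrate rightward with compliance, hip-like vs ankle-like joint
contrasts — not the original study's absolute magnitudes, which depend
on those unpublished data.

## Numerical choices and limitations

* Brent root-finding at xtol 1e−14; residual tolerance 1e−9; the
  rightmost-root convention ties the solution to the passive branch.
* The 257-point bracket scan bounds the risk of missing a sign change;
  the solver is cross-checked against a 1e−6-step brute-force grid scan
  of the imbalance function (independent formulation via the forward
  tendon curve) over hundreds of random conditions in the tests.
* Zero-tendon muscles are treated rigidly in all variants — exactly, not
  in a small-TSL limit — avoiding the singular strain definition.
* The most compliant bands (T/M ≳ 5 at full activation) have no
  zero-fraction trough at the 10% criterion: compliance matters at every
  passive length there. This is a finding, not an artifact.
* Static equilibria only: no force–velocity effects, no history
  dependence, no activation dynamics; results apply to settled fixed-end
  contractions.
* The default tendon curve is generic; muscles whose tendons are much
  stiffer or more compliant than ε₀ = 0.04 will shift every
  compliance-dependent boundary reported here.
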