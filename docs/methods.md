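# Methods

## Scope and assumptions

All models in this package are algebraic steady states: no ODE
integration, no stochastic (intrinsic-noise) simulation. Signals are
dimensionless — concentrations are scaled by their dissociation
constants, promoter activities are normalised so the maximum of the
promoter under test (PUT) is 1 and its basal level is β. The PUT is
assumed monotone with two distinct levels; the concrete transfer
function used throughout is the Hill form `p(u) = (uⁿ+β)/(1+uⁿ)`,
chosen to mirror the activation term of the molecular model. Any
monotone callable obeying the same invariants (p(0)=β, p→1, monotone)
can be substituted wherever a model factory is accepted.

## Linear block models

The three topologies are pure algebra on p:

| topology | output | optimal Fs |
|---|---|---|
| OL  | max(ε, p − Fs)            | none |
| ICF | max(ε, p·(1+Fs) − Fs)     | β/(1−β) |
| DNF | max(ε, (p − Fs)/(1 − Fs)) | β |

The ICF inverter branch is Fs·(1−p) (complement of the PUT through a
gain), the DNF feedback inverter Fs·(1−out); both reconstructions are
validated by the fact that they reproduce the closed-form optima
exactly (basal output reaches zero at Fs*, maximum stays 1). DNF
requires Fs < 1 — at unit feedback gain the fixed point diverges.

**Output floor ε (default 1e-3, configurable).** Physically signals
cannot go negative and any measurement has a noise floor; numerically
a strictly-zero OFF state would make FCA infinite. FCA is therefore
always ON/max(OFF, ε), which produces the observed plateau of FCA at
1/ε beyond the optimal loop strength. ε = 1e-3 corresponds to a floor
three decades below the normalised maximum, a typical cytometry
autofluorescence-to-saturation span.

## Molecular three-node models

ICF is an explicit feedforward chain (y = Fs/(1+xⁿ), then
z = A(x)/(1+yᵐ) with A(x) = α(xⁿ+β)/(1+xⁿ)); no iteration, hence no
numerical tolerance. Two exact consequences used as oracles: at Fs=0,
FCA = 1/β; with m=1, FCA(Fs) = (1+Fs)/β.

DNF couples y = Fs/(1+zʰ) with z = A/(1+yᵐ). The steady state is the
root of the scalar residual r(z) = z − A/(1+y(z)ᵐ), which satisfies
r(0) < 0 ≤ r(A), so a root is always bracketed in [0, A]. For
m·h ≤ 1 the residual is monotone and Brent's method (a bracketing
bisection-family method with superlinear convergence) converges
unconditionally; tolerances are xtol=1e-15, rtol≈9e-16, and the
returned residual is checked against the requested tolerance (default
1e-12). For m·h > 1 the motif can be multistable: 400 log-spaced scan
points locate every sign change, each root is refined, all are
reported, and the smallest is returned with a `multistable` flag. The
smallest-root convention is a deterministic, conservative choice (the
low branch is the one reached from the unswitched state); the
reference parameter set (m=h=1) is monostable, so the policy only
matters for exploratory parameter sets.

Saturation limits ("x→∞") are evaluated at x = 1e6. Wide-grid
fold-change computations use x ∈ [1e-4, 1e6]: at the grid ends the
truncation error of both the activation term and the inhibitor level
is below 2e-5 relative for Fs ≤ 20, comfortably inside the 1e-4
tolerance at which the ICF closed form is asserted. (A narrower grid,
e.g. [1e-3, 1e3], leaves ~6e-4 of inhibitor at the top end at Fs=20
and visibly biases the ON state.)

## Genetic four-node models

The implemented circuits chain PUT → TetR ⊣ PtetO(LuxR) →
P_lux(reverse) ⊣ output. Node laws: t = θ·p (TetR), active TetR
t/(1+aTc) (competitive inducer binding — the inducer releases
repression without degrading the protein), L = λ/(1+(t_eff)^q) (LuxR
from the TetR-repressed promoter), w = Fs·L (the AHL concentration and
reverse-promoter strength are folded into the single knob Fs, which is
how the loop is tuned experimentally).

The reverse promoter's interference with the output defaults to
**subtractive**, z = max(ε, α·p − w), because both physical
realisations (RNA-polymerase collisions in transcriptional
interference; antisense-RNA capture of the sense mRNA) remove a flux
proportional to the reverse-promoter activity rather than rescaling
the forward rate. A **divisive** Hill-repression variant
z = α·p/(1+wᵐ) is retained as a configuration option for sensitivity
analysis. Mechanistic RNA-level detail (duplex formation, collision
kinetics) is deliberately coarse-grained into these two laws, and
plasmid copy number is lumped into the gains α, θ, λ.

ICF wiring (TetR driven by the PUT only) is an explicit chain. DNF
wiring also reduces TetR by the reverse promoter (t = max(0, θp − w)
or its divisive analogue), giving a scalar fixed point in w on
[0, Fs·λ]. It is solved by damped fixed-point iteration (damping 0.5,
budget 500, tolerance 1e-10) with a Brent fallback on the bracket —
the residual w − g(w) changes sign across the bracket, so the
fallback cannot fail.

**Shipped default parameter set** (`DEFAULT_GENETIC_PARAMS`): β=0.1,
n=1.5, α=10, θ=5, q=2, λ=1, aTc=0, subtractive mode, ε=1e-3. With
these values both wirings show an interior FCA optimum: once the OFF
state is driven to the floor, further loop strength only erodes the
ON state (α − w(ON) falls roughly linearly in Fs), so FCA rises
steeply and then declines — the qualitative behaviour the four-node
design is meant to capture. θ=5 and q=2 give the inverting switch a
usable ON/OFF contrast (25× LuxR repression at full PUT activity)
without bistability in the subtractive DNF.

## Metrics

* **FCA** = ON/max(OFF, ε). ON/OFF are the curve's endpoint outputs
  (the transfer functions here are monotone); an `extrema` mode uses
  max/min over the curve for biphasic data.
* **Sensitivity** S = d ln(out)/d ln(in), computed by central
  differences on the log-log curve (one-sided at the ends) via
  `np.gradient`. This implements the fold-change-over-fold-change
  ratio (dOut/⟨Out⟩)/(dIn/⟨In⟩) with ⟨·⟩ read as the local value.
  Closed-form check for the bare PUT: S is maximal at u = β^(1/(2n))
  with value n(1−√β)/(1+√β).
* **MDL** is the input where S peaks. Ties break toward the smallest
  input, with a 1e-12 relative tolerance on the maximum so that
  floating-point noise on flat curves cannot move the argmax.
* **Threshold** is the input where the output crosses the geometric
  mean √(ON·OFF) — half the fold change on the logarithmic scale —
  located by linear interpolation in log-log space; a curve that
  never crosses returns NaN rather than raising. For the bare PUT
  the threshold and the MDL coincide at β^(1/(2n)).
* **Sweeps** evaluate all metrics per Fs; argmax(FCA)/argmin(MDL) tie
  toward the smaller Fs for determinism.
* **Design diagrams** classify (β, Fs) cells as optimal-FCA when
  FCA ≥ (1−δ)·max over Fs at that β, and optimal-MDL when
  MDL ≤ min/(1−δ) — the same relative tolerance applied on the other
  side, so δ→1 degenerates to everything-optimal on both criteria.
  Default δ = 0.05; the diagrams are qualitative design aids, not
  quantitative claims.

## Curve fitting

Both phenomenological forms — Hill `y = b + a·u/(1+u)` and biphasic
`y = b + a·u/(1+u)²`, u = (d/K₁)^{n₁} — are fitted in log₁₀(y) space
because fluorescence data span decades and log-space residuals weight
the decades evenly. Bounds: b ∈ [0, max y], a ∈ (0, 10·max y],
K₁ ∈ [min dose/10, max dose·10], n₁ ∈ (0.01, 6]. Optimisation is
bounded trust-region least squares with 5 starts: the first anchors
K₁ at the dose nearest the half-range response with n₁ = 1.5, the
rest draw K₁ and n₁ from a seeded RNG (`random_state`, recorded on
the estimator). Flags are honest rather than silent: `degenerate_`
when the data span < 5% dynamic range (amplitude unidentifiable),
`k1_at_bound_` when the fitted K₁ sits within 1% (log-range) of its
search bound, `converged_` straight from the optimiser status.

The biphasic form multiplies a Hill activation by its own complement
with shared K₁ and n₁, so it is symmetric in log-dose about K₁ and
peaks at exactly d = K₁ with height b + a/4 — `biphasic_peak` is an
identity on the fitted parameters, not a numerical search. A variant
with independent constants for the rising and falling arms
(`shared_constants=False`) exists for sensitivity analysis but is not
the default.

Note on model mismatch: fitting the biphasic form to saturating
monotone data does **not** push K₁ to the dose bound in log space —
the global optimum is an interior K₁ with a shallow n₁ (verified by a
constrained refit at the bound, which costs ~4× the residual). The
mismatch signal is the residual itself plus the deferred peak, and
the tests assert exactly that.

**Bootstrap.** `bootstrap_k1` resamples replicates with replacement
(200 draws by default) and refits each resample. With the typical 3
biological replicates a naive percentile interval is far too narrow —
measured coverage was ~60% at nominal 95%, the classic small-n
bootstrap undercoverage — so the default interval is Student-t on
log K₁: centre at the full-data fit, halfwidth t₀.₉₇₅,ₙ₋₁ × bootstrap
SE. This restores near-nominal coverage; the percentile interval
remains available as `method="percentile"`.

## Synthetic cytometry generator

The generator emulates the measurement chain of a flow-cytometry
dose-response experiment: per-cell fluorescence is log-normal with
geometric mean equal to the model's steady-state output and log-sd
`log_cv` (default 0.5 — a broad but realistic population spread; the
value is a generator choice, not a measured constant), 10000 cells
per well, 3 biological replicates per dose, each well summarised by
its geometric mean. Optional knobs, both 0 by default: a
between-replicate log-normal day effect and an additive
autofluorescence floor. All randomness flows through explicit seeds
(`numpy.random.default_rng`); sweep members derive distinct
per-condition seeds from the base seed, so whole families are
reproducible member-by-member. In the log_cv → 0 limit the generator
returns the model curve bitwise (the degenerate draw is special-cased
to avoid exp(log(m)) rounding).

What it does **not** emulate: forward/side scatter and gating,
instrument saturation, asymmetric or multimodal populations,
cell-count variation between wells, and correlated noise across doses
beyond the optional day effect. Passing end-to-end tests therefore
demonstrates correctness of the summarisation and inference chain
under idealised log-normal noise, not robustness to every artefact of
real cytometry data.

## Problem sizes and tolerances

Default analysis sizes, chosen to keep every closed-form comparison
well inside its tolerance: 601-point log grids for single curves,
x ∈ [1e-4, 1e6] for fold-change evaluations (see above), 201-point Fs
grids for sweeps, 1e-4 step for the linear-optimum grid searches,
200 Monte-Carlo trials for recovery rates. DNF solver tolerance
1e-12 (molecular) and 1e-10 (genetic); both solvers verify and report
the achieved residual rather than trusting iteration counts.

## Known limitations

* Steady states only; transient or adaptation behaviour is out of
  scope by design.
* The genetic four-node model is a coarse-grained reconstruction; its
  parameters (θ, q, λ) are effective gains, not measured biochemical
  constants, and the interior-optimum claim is about the shipped
  default set, not all parameter choices.
* The multistability policy (smallest root) is a reporting convention;
  hysteresis and basins of attraction are not modelled.
* FCA endpoint convention assumes monotone transfer curves; use the
  `extrema` mode for non-monotone data.
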