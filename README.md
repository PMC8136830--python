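# circuitfca

Steady-state models, fold-change metrics and dose-response fitting for
gene circuits that optimise **fold-change activation (FCA)** — the
ON/OFF ratio of a promoter — by wrapping a leaky promoter in an
**indirect coherent feedforward (ICF)** loop or a **double negative
feedback (DNF, mutual inhibition)** loop. Both designs suppress the
basal (leaky) output of a promoter under test while preserving its
maximum, which is what raises FCA; the package quantifies how the
achievable improvement depends on the loop strength F_s and on the
promoter's basal level β.

It is written for synthetic biologists and modellers who design such
circuits (e.g. TetR/PtetO inverting switches combined with a
LuxR/P_lux reverse promoter acting as a tunable subtraction) and want
to pick the loop strength before building anything.

## Models

The promoter under test is a normalised Hill transfer function with
basal level β ∈ (0,1) and maximum 1:

    p(u) = (uⁿ + β) / (1 + uⁿ)

Three tiers of circuit model act on it:

* **Linear block models** — OL (open loop): `out = p − Fs`;
  ICF: `out = p − Fs·(1−p)`; DNF fixed point: `out = (p − Fs)/(1 − Fs)`;
  all clipped below at a noise floor ε. Closed-form optimal loop
  strengths: `Fs* = β/(1−β)` (ICF) and `Fs* = β` (DNF).
* **Molecular three-node models** — output z activated by input x and
  repressed by inhibitor y:

      z = α·(xⁿ+β)/(1+xⁿ) · 1/(1+yᵐ),
      y = Fs/(1+xⁿ)        (ICF)   or   y = Fs/(1+zʰ)   (DNF)

  The ICF chain is explicit; the DNF fixed point is solved on a
  guaranteed bracket (for m=h=1 it is the positive root of
  z² + z(1+Fs−A) − A = 0 with A = α(xⁿ+β)/(1+xⁿ)). ICF fold change is
  `(1+Fs)/β`, monotone in Fs; DNF fold change peaks at an interior Fs.
* **Genetic four-node models** — the wet-lab wiring
  PUT → TetR ⊣ PtetO(LuxR) → P_lux(reverse) ⊣ output, with aTc
  reducing active TetR and AHL folded into Fs; reverse-promoter
  interference modelled as a subtraction (default) or Hill repression.

On any dose-response curve the package computes FCA, the pointwise
logarithmic sensitivity `S = d ln(out)/d ln(in)`, its maximum, the
**MDL** (input where S peaks), and the switching threshold (log-midpoint
crossing), plus Fs sweeps and β–Fs design diagrams. Measured or
simulated curves are fitted with a monotone Hill form
`y = b + a·u/(1+u)` or the biphasic form `y = b + a·u/(1+u)²`
(`u = (d/K₁)^{n₁}`, peak at d = K₁ with height b + a/4), by bounded
multistart least squares in log space. A synthetic flow-cytometry
generator (log-normal cell populations summarised by geometric means
over 10000 events × 3 replicates) closes the loop for end-to-end
testing with known ground truth.

## Worked example

Find the optimal loop strength of the molecular DNF circuit at the
reference parameters (β=0.1, α=10, n=1.5, m=h=1):

```python
import numpy as np
from circuitfca import (MolecularParams, dose_response, sweep_fs,
                        fit_biphasic, biphasic_peak)

params = MolecularParams()          # beta=0.1, alpha=10, n=1.5, m=h=1
x = np.geomspace(1e-4, 1e6, 301)    # dimensionless input grid

def dnf(fs):
    return lambda xx: dose_response("DNF", params.with_fs(fs), xx).outputs

sweep = sweep_fs(dnf, np.linspace(0, 20, 201), x, floor=0.0)
print(f"optimal loop strength Fs* = {sweep.argmax_fca:.2f}")
print(f"maximum fold change  FCA  = {sweep.fca.max():.2f}")
print(f"no-loop fold change  FCA0 = {sweep.fca[0]:.2f}   (= 1/beta)")

fit = fit_biphasic(sweep.fs_grid[1:], sweep.fca[1:])
peak_fs, peak_fca = biphasic_peak(fit)
print(f"biphasic fit peak: Fs = {peak_fs:.2f}, FCA = {peak_fca:.2f}")
```

prints

```
optimal loop strength Fs* = 6.50
maximum fold change  FCA  = 30.93
no-loop fold change  FCA0 = 10.00   (= 1/beta)
biphasic fit peak: Fs = 5.80, FCA = 31.13
```

The bare promoter has FCA = 1/β = 10; the mutual-inhibition loop
triples it, but only in a narrow band of loop strengths around
Fs ≈ 6.5 — overdriving the loop suppresses the maximum too. The
biphasic fit summarises the sweep the way one would summarise an
experimental FCA-versus-AHL curve; its peak location is the fitted
K₁ by construction.

The same pipeline is scriptable from the shell:

```sh
circuitfca sweep --out-dir runs/dnf \
  --set family=molecular --set topology=DNF \
  --set fs_min=0 --set fs_max=20 --set fs_points=201
```

which writes `sweep.csv`, `sweep.json` (argmax/argmin) and a
`manifest.json` that reproduces the run exactly.

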