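# rpacircuit

Simulation and analysis toolkit for a **robust perfect adaptation (RPA)**
gene circuit: a two-node negative feedback loop whose buffer node carries
**linear weak positive feedback**. The package is for synthetic/systems
biologists who want to design, screen or fit this circuit family: it
implements the ODE model, the adaptation-error statistic used to score
step responses, an in-silico parameter-cassette robustness screen,
circuit-variant (topology-disruption) analysis, fitting and
promoter-substitution prediction, and a synthetic-data generator emulating
cytometry-style readouts so every stage is testable offline.

## The model

Output node A and buffer node B, with Hill regulation combined by AND
logic and first-order removal:

```
dA/dt = α₁ · D(I) · [ B^n_BA/(K_BA^n_BA + B^n_BA) + β_BA ] − γ_A A
dB/dt = α₂ · [ 1/(1 + (A/K_AB)^n_AB) + β_AB ] · S(B)        − γ_B B
```

`D(I)` is the inducer drive (indirect derepression), and `S(B)` the buffer
self-activation. When the self-activation is *linear and weak*
(`B ≪ K_BB`, `n_BB = 1`, small leaks), the steady state of the B equation
pins the repression factor at `γ_B K_BB / α₂`, so the output settles at

```
A* = K_AB · (α₂/(γ_B K_BB) − 1)^(1/n_AB)
```

for **every** input: the circuit responds with a transient pulse and
returns to the same level. Adaptation quality is scored with the
adaptation error

```
AErr = |Output₁ − Output₂| / Output₁
```

(Output₁ = settled post-step output, Output₂ = unswitched control level).
Null (constitutive) or cooperative (`n_BB = 2.3`, bistable) replacements of
the positive feedback, and deletion of the repression, each break
adaptation in characteristic ways — all reproducible with the packaged
variants. See `docs/methods.md` for assumptions, parameter choices and
numerics.

## Worked example

```python
import numpy as np
from rpacircuit import (StepExperiment, defaults_v1, simulate_step,
                        evaluate_step_response)

p = defaults_v1("hill")                       # saturating reference circuit
exp = StepExperiment(2.0, 300.0, np.arange(0.0, 24.01, 0.1))
stepped, control = simulate_step(exp, p)      # pre-equilibrates at 2 uM
res = evaluate_step_response(stepped, control)
print(f"baseline  output2 = {res.output2:.3f} a.u.")
print(f"settled   output1 = {res.output1:.3f} a.u.")
print(f"AErr = {res.aerr:.4f}   peak fold = {res.peak_fold:.2f} "
      f"at t = {res.peak_time:.2f} h   adapts: {res.adapts}")
```

prints

```
baseline  output2 = 1.399 a.u.
settled   output1 = 1.412 a.u.
AErr = 0.0094   peak fold = 1.44 at t = 1.00 h   adapts: False
```

The output pulses ~1.4-fold when the inducer steps 150-fold (2 → 300 μM)
and settles back to within 1% of the unswitched control (AErr ≈ 0.009 —
near-perfect adaptation; the strict `adapts` classification additionally
requires a ≥ 1.5-fold pulse, which this gentle stimulus does not reach).
Scaling the self-activation strength ×2/×0.25 or the B→A activation
×0.2/×0.04 keeps AErr ≤ 0.05; replacing the positive feedback with a
constitutive promoter raises AErr above 0.2 (and more for stronger
promoters); deleting the repression makes the output rise without any
adapted decrease.

The same API is exposed as a CLI:

```
rpacircuit simulate --params params.yaml --input-initial 2 --input-final 300 --out traj.csv
rpacircuit aerr --trajectories traj.csv
rpacircuit scan --variant null_pf --n 200 --seed 1 --out report.json
```

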