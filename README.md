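# campmmo

Conductance-based modelling of **cAMP-induced mixed-mode oscillations
(MMOs) in cortical pyramidal neurons**, and the slow-fast geometry that
explains them.

In layer-V pyramidal cells, raising cyclic AMP (e.g. through adenosine
A2a-receptor agonists) activates two opposing ion channels at once: the
depolarizing HCN channel and the hyperpolarizing M-type K⁺ (Kv7) channel.
Instead of simply speeding up or slowing down firing, this can switch the
cell from regular action-potential (AP) firing into MMOs — full APs
interleaved with small subthreshold oscillations (SAOs) — which sharply
lowers the firing rate. `campmmo` is for computational neuroscientists who
want to simulate these in-silico drug experiments and dissect the
dynamical mechanism behind them.

## The model

A single-compartment Hodgkin–Huxley-type model with five state variables
— membrane potential `V` and gating variables `h` (fast-Na⁺ inactivation),
`s` (slow K⁺), `r` (HCN) and `w` (M) —

```
Cm dV/dt = −I_NaF − I_NaP − I_KS − I_L − I_HCN − I_M + I_App
  dp/dt = (p∞(V) − p)/τp(V),   p ∈ {h, s, r, w}
```

with instantaneous Na⁺ activation (`m∞³`, `n∞³`),
`I_HCN = (g_HCN + cAMP·Δg_HCN)·r·(V − E_HCN)` and
`I_M = (g_M + cAMP·Δg_M)·w·(V − E_K)`. The binary `cAMP` flag also shifts
the HCN half-activation voltage ν from 103.5 to 95 mV. Drug conditions
(`Ctrl`, `CGS`, `ZD`, `ZD+CGS`, `XE`, `XE+CGS`, `FSK`, `FSK+Lin`) are
parameter presets: HCN block (ZD7288) zeroes `g_HCN`, M block
(XE991/Linopirdine) reduces `g_M`/`Δg_M`, A2aR agonism (CGS21680) or
adenylate-cyclase activation (Forskolin) sets `cAMP = 1`.

The model has three timescales (`V` fast; `h`, `s` slow; `r`, `w`
super-slow). Freezing the super-slow pair at its time average — absorbed
into scaled parameters `w̃ = (1 + cAMP·Δg_M/g_M)·w`,
`r̃ = (1 + cAMP·Δg_HCN/g_HCN)·r` — leaves a 3D slow-fast subsystem whose
critical manifold `s = γ(V, h)` is folded. A **folded-node singularity**
on the hyperpolarized fold generates the SAOs: orbits entering its funnel
rotate a number of times set by the rotational sector (bounded by canard
orbits) in which they land. The package computes all of these objects
explicitly.

## Worked example

```python
from campmmo import condition_params, integrate, detect_events, mmo_signature
from campmmo.simulation import trim_to_complete_blocks, mmo_interval

# elevated cAMP at 250 uA/cm^2: bursting MMOs
p = condition_params("CGS").with_(IApp=250.0)
traj = integrate(p, 450.0)                      # RK4, dt = 0.001 ms
events = detect_events(traj.window(350.0))      # post-transient peaks
sig = mmo_signature(trim_to_complete_blocks(events))
print(sig.blocks[:4], "->", sig)

# applied-current range with MMOs under control conditions
print(mmo_interval("Ctrl"))
```

prints

```
((2, 3), (2, 2), (2, 3), (2, 2)) -> 2322
(80.9375, 223.4375)
```

i.e. with elevated cAMP the cell fires bursts of 2 APs separated by 2–3
SAOs, and the control neuron shows MMOs for applied currents between
≈81 and ≈223 μA/cm² (silent below, tonically spiking above). The same
analyses are available from the command line:

```bash
campmmo simulate --condition CGS --iapp 250 --out out/cgs250
campmmo intervals --condition Ctrl
campmmo reduce --condition CGS --iapp 250
campmmo geometry --condition CGS --iapp 250
campmmo reproduce list
```

`campmmo geometry` reports the folded node of the reduced subsystem — at
the CGS/250 averaged gates it sits on the hyperpolarized fold at
`V ≈ −71.06 mV` with eigenvalue ratio `μ ≈ 0.014` — and the canard
orbits found by slow-manifold reconstruction.

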