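# Methods

This note documents the model, the numerical procedures and the design
choices behind `campmmo`, in enough detail to reproduce or audit every
number the package computes.

## Model

Single-compartment, Hodgkin–Huxley-type cortical pyramidal cell with six
currents: fast Na⁺ (`I_NaF`, activation `m∞³` instantaneous, inactivation
`h` dynamic), persistent Na⁺ (`I_NaP`, `n∞³` instantaneous), slow K⁺
(`I_KS`, gate `s`), leak, HCN (`I_HCN`, gate `r`) and M-type K⁺ (`I_M`,
gate `w`; reversal at `E_K`). Units: mV, ms, mS/cm², μA/cm², μF/cm².

Defaults (mS/cm² unless noted): `g_NaF=1000`, `g_NaP=1`, `g_KS=40`,
`g_L=11.3`, `g_HCN=23`, `g_M=50`, `Δg_HCN=12`, `Δg_M=50`, `C_m=0.9`
μF/cm², `E_Na=50`, `E_K=−84`, `E_L=−83.38`, `E_HCN=−50` mV. Rate
constants are corrected to `T=37 °C` by Q10 factors (`Q^((T−T_ref)/10)`)
referenced to 20 °C for the Na⁺/K⁺ gates and to 35 °C for the HCN gate,
the temperatures at which the respective kinetics were characterised. The
M gate has no temperature factor; its kinetics are used as given. cAMP is
a binary flag: it adds `Δg_HCN`, `Δg_M` to the HCN/M conductances and
shifts the HCN half-activation `ν` from 103.5 mV to 95 mV. Drug-condition
presets map pharmacology onto parameters (HCN block → `g_HCN=Δg_HCN=0`;
M block → `g_M=Δg_M=0`; partial M inhibition on a cAMP-raised background
→ `Δg_M=20`; agonists → `cAMP=1`).

Assumptions inherited with the model: no channel noise, no spatial
structure, cAMP treated as binary rather than as a concentration.

### Rate-function singularities

The `a·(V+b)/(1−exp(−(V+b)/c))` rate expressions have removable
singularities at `V=−b`. These are filled with the analytic (l'Hôpital)
limit `a·c`, via a short series for `|V+b|` small, so every rate is
continuous and exact to machine precision — no ε-offsets. The same
expressions are implemented once more with analytic derivatives in the
geometry module, where fold curves require exact `d/dV` of the current
kinetics; the two routes are cross-checked in the tests.

## Numerics

**Integration.** Fixed-step classical RK4, compiled with numba. Reference
step `dt = 0.001 ms` for single traces; regime and frequency scans use
`dt = 0.002 ms` (halving it moves detected regime boundaries by well
under 1 μA/cm², asserted in the tests). State is recorded every 0.01 ms —
APs last ~1 ms, so peak detection is unaffected. A per-step guard aborts
integration if `V` leaves (−150, 80) mV; the 3D integrators need this
because slow-manifold reconstruction deliberately integrates off the
physiological attractor. The RK4 trace agrees with a DOP853 reference at
`rtol=1e−10` to < 0.1 mV over 50 ms.

**Initial conditions.** `V₀ = −70 mV` with every gate at its steady state
`p∞(V₀)` — a state near rest on the hyperpolarized attracting sheet.

**Event detection.** Local maxima of `V(t)` via peak finding with a
prominence filter; a peak is an AP (LAO) if it exceeds −20 mV, otherwise
an SAO. APs overshoot 0 mV and SAOs stay below −60 mV here, so the
threshold is uncritical. The prominence filter is 0.2 mV: measured SAO
prominences in mixed-mode regimes range from ~0.005 to ~0.9 mV (they grow
along each subthreshold epoch), while genuinely spiking traces contain no
subthreshold maxima at all, even at 10⁻⁴ mV prominence. A 1 mV filter
would misclassify mid-range mixed-mode states as spiking; 0.2 mV
separates the regimes cleanly and still rejects integration ripple.

**Regimes.** `silent` = no LAO after the transient; `MMO` = LAOs and SAOs
both present; `spiking` = LAOs only. Classification simulates 1000 ms and
analyses the last 500 ms (MMO periods can exceed 100 ms near regime
boundaries; doubling the horizon does not move the reported boundaries).
Interval endpoints along `I_App` come from a coarse scan (step 20 μA/cm²
over [0, 400]) plus bisection to ±0.5 μA/cm².

**Firing frequency.** LAO count per analysed second over [350 ms, end] of
a 1000 ms run, on a 5 μA/cm² grid; the crossing of two f–I curves is the
linearly interpolated zero of their difference, restricted to currents
where both cells fire (an exactly-zero difference at a grid point is
resolved as the centre of the flat run).

**Upper firing limit.** Above the mixed-mode range the AP amplitude
declines continuously with drive until the oscillation collapses into
depolarization block (constant depolarized `V`). Because the peaks pass
below any fixed amplitude threshold well before firing stops, this
boundary is bisected on the disappearance of detected oscillation events
of either kind, not on the LAO label.

## Reduction to the slow-fast subsystem

Time-scale separation (measured on simulated MMO traces, subthreshold
segments): `τ_V/τ_s < 0.004`, `τ_s/τ_w < 0.2`, with
`τ_V = C_m/g_tot` and `g_tot` the summed chord conductances
`g_NaF·m∞³·h + g_NaP·n∞³ + g_KS·s + g_L + g_HCN_eff·r + g_M_eff·w` (an
effective membrane time constant; the definition is ours and the ratios
are reported as soft diagnostics, not tuned quantities).

The super-slow gates are frozen at trapezoidal time-averages over
[350, 450] ms of a 450 ms run (the transient is over well before 350 ms;
the window covers ≈5–10 attractor periods). The cAMP increments are
absorbed into `w̃ = (1+cAMP·Δg_M/g_M)·w`, `r̃ = (1+cAMP·Δg_HCN/g_HCN)·r`,
making the reduced (V, h, s) model independent of the cAMP flag; a
blocked channel (zero base conductance) leaves its gate unscaled since
the current vanishes anyway. Projected onto (w̃, r̃), 5D trajectories hug
a line `r̃ = m·w̃ + q`, fitted by ordinary least squares of `r̃` on `w̃`
(`w̃` is the bifurcation parameter); the RMS residual is ~1–2 % of the
`r̃` range.

A caveat that matters downstream: averaging a ~15 ms-period attractor
over a 100 ms window leaves a phase-alignment bias of order ±0.002 in
`w̃`. The *regime* of the reduced model is robust to this, but the exact
SAO count per MMO block is not (see Limitations).

## Bifurcation analysis

Interactive continuation software is replaced by deterministic
primitives:

- **Equilibria.** At an equilibrium `h=h∞(V)`, `s=s∞(V)`, so equilibria
  are roots of a scalar current balance in `V`, bracketed on a 0.5 mV
  grid and refined by Brent's method; every root is reported (the scanned
  regimes have exactly one). Stability from the eigenvalues of a central
  finite-difference 3×3 Jacobian.
- **Hopf points.** Bisection (Brent) on the real part of the complex
  eigenvalue pair along the constraint line (or along `w̃` at fixed `r̃`
  for the two-parameter Hopf curve); the residual real part at the
  reported point is < 10⁻⁶ ms⁻¹.
- **Attractor classes.** Long transient-discarded simulation of the 3D
  model per parameter point, classified by the same event machinery
  (equilibrium / LAO-cycle / MMO). The discontinuous jump from the
  relaxation-cycle branch to the chaotic/MMO attractor is bisected on the
  first appearance of SAOs to 10⁻⁴ in `w̃`.
- **Floquet multipliers.** The period-1 cycle is located on a Poincaré
  section placed on the slow subthreshold rise (V = −70 mV, where linear
  interpolation of the crossing is accurate); the monodromy matrix is
  integrated with the variational equations (DOP853, rtol 10⁻¹⁰) over one
  period. The trivial multiplier is recovered to ~3·10⁻⁶.
- **Minimal Δg_M.** The control MMO upper endpoint does not depend on
  Δg_M, so the smallest increment for which the elevated-cAMP MMO band
  reaches beyond the control band is bisected on
  `upper(cAMP=1, Δg_M) > upper(cAMP=0)` to ±0.25 mS/cm².

## Slow-fast geometry

The critical manifold is the explicit graph `s = γ(V, h)` (linear in both
`h` and `s`-elimination), decomposed into an HCN/M-free backbone plus
shifts proportional to `r̃` and `w̃`; it is singular at `V = E_K`, where
the K⁺ driving force vanishes, and all root scans exclude that point. The
fold set `df/dV = 0` eliminates to a graph `h = ψ(V) = ψ0 + ψr` with

```
ψ0 = (−[(V−E_K)·dV(I_NaP) − I_NaP] + g_L(E_K−E_L) − I_App) / D
ψr = g_HCN (E_K−E_HCN) r̃ / D,   D = (V−E_K)A′(V) − A(V)
```

(`A = g_NaF m∞³ (V−E_Na)`), re-derived from scratch here; the
implementation is validated against the defining identity
`|df/dV| < 10⁻⁸` at `(V, ψ(V))` (achieved: ~10⁻¹⁵, using analytic rate
derivatives). In the (V, h) plane the fold set is one connected curve
whose two steep arms are the physiological folds — L⁻ (hyperpolarized,
near −71 mV at the parameters of interest) and L⁺ (near −38 mV) — so the
branches are traced parametrically in `h`, taking the outermost roots in
`V` of `df/dV` for each `h`.

The desingularized reduced flow (time rescaled by `−C_m·df/dV`, which
preserves orientation on attracting sheets and reverses it on the
repelling sheet) is evaluated with `s` eliminated through `γ`. Folded
singularities are roots of its `V`-component along the fold, classified
by the 2×2 Jacobian eigenvalues. At the elevated-cAMP, 250 μA/cm²
averaged gates the model has a single folded **node** on L⁻
(V ≈ −71.06 mV, eigenvalues both negative, ratio μ ≈ 0.014) plus a
single ordinary singularity (the unstable 3D equilibrium), and the node
persists under ±5 % perturbation of (w̃, r̃).

**Canards and sectors.** The strong canard ξ₀ is integrated from small
offsets along the strong eigendirection of the node (forward and
backward, in the desingularized flow). Secondary canards come from
slow-manifold reconstruction: forward orbits from a seed line on the
attracting sheet Sa⁻ (2 mV hyperpolarized of L⁻ at the funnel's `h`
values — γ steepens so quickly towards `E_K` that more distant seeds
contract onto the weak canard before reaching the section) and backward
orbits from seeds near Sa⁺ chosen at `s` values just below the section
(solved exactly from γ's linearity in `h`, started 1 mV inside the sheet
because the true slow manifold lies O(ε) inside the critical manifold).
Both families stop on the plane `Σ_FS: s = s_FN + σ`, placed *upstream*
of the node (the slow flow arrives with `s` decreasing) with
`σ = 2 % of |s_FN|` by default; their polyline intersections on the plane
are canard points. Because the repelling manifold spans < 1 mV in `V`
near the node, few backward orbits reach the section and only a few
intersections are resolvable; the full rotational-sector structure is
therefore computed by brute force — rotation counts of forward orbits
along the reconstructed attracting curve, with each count jump bisected
to 10⁻⁵ in `h`. Rotation counting uses the same 0.2 mV prominence filter
as the event detector, so sector indices and measured SAO counts are
directly comparable. For the mixed-mode attractors at 250 and
300 μA/cm² (elevated cAMP), the sector of every funnel-crossing return
predicts its measured SAO count exactly; returns that never reach the
section are regular jumps (the mechanism behind multi-AP bursts).

## Problem sizes

Regime scans: ~40 simulations of 1 s model time per condition (coarse
step 20 μA/cm² + bisection to ±0.5). f–I curves: 29 currents × 2
conditions. MMO-onset bisection: ~40 3D simulations. Δg_M threshold: ~7
upper-endpoint evaluations (bisection to ±0.25 mS/cm²), each a ~20-
simulation scan. Slow-manifold reconstruction: 50–200 seeds per family;
sector maps: ~30 grid counts plus bisections. The full acceptance run
takes ≈3 min on one core; the test suite ≈8 min.

## Limitations

- The LAO/SAO discrimination is amplitude-based; it is sharp for this
  model (no intermediate-amplitude events occur) but the 0.2 mV
  prominence convention decides how many of the smallest rotations near
  the folded node count as "visible" SAOs.
- The exact SAO count per MMO block of the *reduced* model is a
  knife-edge function of the frozen (w̃, r̃): shifts of ±0.002 — the size
  of the averaging phase bias — change the block composition (e.g. from
  1-AP blocks with 3–4 SAOs to alternating 1- and 6-SAO blocks) while
  leaving the regime, the folded-node structure and the sector/SAO
  consistency intact. Quantities built on regime boundaries are robust;
  quantities built on individual block compositions of the reduced model
  are not, and the full 5D block structure is the reliable observable.
- Regime boundaries are defined by simulation-classified attractors; a
  boundary defined instead by continuation of the first period-doubling
  would differ by a few μA/cm², which matters only for quantities that
  take differences of boundaries (the minimal-Δg_M threshold inherits a
  ±2–3 mS/cm² sensitivity through its shallow crossing).
- No continuation of unstable periodic orbits or of the full
  period-doubling cascade; saddle-node-of-periodic-orbit structure is
  only visible as hysteresis in attractor scans. No rigorous ε-asymptotics
  (the maximal SAO number from μ is not computed).
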