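# Methods

`vasodyn` simulates the vasodynamics of mouse cerebral arterioles as the
interplay of four processes: passive wall distension, the delayed myogenic
response, neurogenic modulation, and an astrocytic constriction-triggered
dilation rule, on top of quasi-static network hemodynamics.  This note
records the model equations, the default parameters and their provenance
(measured physiology vs. package calibration), the numerical choices, and
the known limitations.

## Network geometry

The cerebrovascular network is a graph of cylindrical segments between one
arterial inlet (ABN) and one venous outlet (VBN).  Defaults:

- **Penetrating arterioles (PAs):** 30 chains of 28 segments, each 30 um
  long (840 um total depth).  The maximal active diameter tapers linearly
  from 18 um at the surface to 12.6 um at depth; each segment uses the value
  at its midpoint.  Wall thickness is fixed at h = 0.1 x d_active_max.  The
  relative contractility index of a PA segment is its taper diameter divided
  by the surface diameter (monotonically non-increasing with depth).
- **Pial tree:** the feeding pial geometry is not constrained by published
  numbers beyond the total count of 1009 arteriolar segments (pial + PA);
  we generate a balanced binary tree from the ABN with exactly 169 segments
  and 30 leaves (the PA roots), 50 um per segment, diameters tapering
  40 -> 20 um from inlet to PA roots.  This is a plausible, configurable
  choice, not a reconstruction of any measured pial network.
- **Downstream microvessels:** every PA node feeds one fixed (non-reactive)
  chain of 7 segments — a precapillary sphincter, three transitional-zone
  orders and three capillary orders — draining to the VBN.  Each chain is an
  equivalent single tube for a bed of 2^m parallel Murray-law daughters at
  order m: diameter d_local x 2^(-m/12) (Murray's 2^(-m/3) per daughter
  compensated by the 2^(m/4) parallel-count factor on a D^4 conductance),
  further scaled by (1/28)^(1/4) because each chain lumps 1/28 of a PA's
  bed.  Distributing offtakes along the PA reproduces the physiological
  depth-decreasing flow profile; a single-outlet ("leaf") variant is kept as
  a config option but leaves the vasomotion loop gain marginally
  subcritical, so network oscillations slowly damp in that geometry.

With these defaults the intravascular pressure inside PAs spans ~30-57 mmHg
at an inlet pressure of 60 mmHg, matching the stated physiological IP band
(30-65 mmHg across the 40-80 mmHg inlet range).

## Hemodynamics

Flow is quasi-static Poiseuille flow: per-segment conductance
G = pi D^4 / (128 mu L); nodal pressures solve the Kirchhoff system with
Dirichlet pressures at ABN/VBN (sparse LU per step).  Derived per segment:
flow Q = G dP; intravascular pressure IP = mean of the end-node pressures
(symmetric choice; the sources are silent); circumferential wall stress
WS = IP D / h (Laplace); wall shear stress WSS = 32 mu |Q| / (pi D^3)
(Poiseuille wall shear; no formula is printed in the sources).  Viscosity
defaults to a constant 3 mPa s; a diameter-dependent in-vitro apparent
viscosity law (Pries-type, hematocrit 0.45) is available behind the same
interface.  Units: mmHg, nl/min, um, mPa s; WS in mmHg, WSS in dyn/cm^2;
all conversions live in `hemodynamics.py`.

Stress normalizers: WS_max and WSS_max per segment are recorded from a
pressure sweep ABNP = 40..130 mmHg with arteriolar segments maximally
constricted (0.768 x d_active_max, the active-diameter span of the
reference segment).  They normalize the mechanosensing sigmoids of the
cellular model.

## Macro-scale segment model (vasomotion engine)

Per arteriolar segment, at the main step dt1 = 0.2 s:

1. Hemodynamic solve with the previous diameters -> WS(i).
2. Delayed myogenic potential:
   `V_init = -45 + MR_F (WS(i - MR_D/dt1) - WS_avg)` with MR_F = 19e-3
   mV/mmHg and MR_D = 5 s.  WS_avg is frozen at the initial autoregulated
   state; the history ring is pre-filled with WS_avg so V starts at
   baseline.
3. Gap-junction coupling: `V <- V + (dt2/RC) * sum_nb (V_nb - V)` on the
   arteriolar adjacency (segments sharing a node), iterated at
   dt2 = 1e-4 s with RC = 1e-3 s until the per-iteration change falls
   below 1e-6 mV or the inner time reaches dt1.  Because the adjacency is
   static, the production engine applies the precomputed dense propagator
   `M^(dt1/dt2)` (repeated squaring) — the same linear map as the loop
   without early exit; the iterative form is retained and tested for
   equivalence.
4. Components: `D_MR = (-45 - V_final)` (1 mV = 1 um, exposed as the
   `mV_to_um` parameter) and
   `D_PD = 0.9 Dmax (1 + 0.5 (1 - exp(-0.003 WS)))`.
5. Commit `D = D_PD + D_MR`, clipped to at most 15 %/s dilation and
   7.5 %/s constriction of the previous diameter.

During neurally driven runs the myogenic term is inhibited by the delayed
range-normalized gamma-band envelope and damped by its smoothed version:
`D = D_PD + (D_MR - 10 GB(t - 1.9 s)) * (1 - GB_S(t - 1.9 s))`; the
astrocytic rule adds its potassium pulse to the same inhibition term
(additive; the sources describe the rule only qualitatively).

**Initial autoregulated state.** At the working inlet pressure (60 mmHg) a
uniform tone scale s is applied to all arteriolar diameters such that total
network inflow equals the inflow at the lower autoregulation limit (40 mmHg,
fully dilated) — the flat part of the autoregulation curve (s ~ 0.73 by
root finding).  This constricted initial state lies below the passive
equilibrium, so the first steps dilate at the rate limit and bootstrap the
oscillation deterministically; no random perturbation is used anywhere in
the macro engine.

**Observed regime.** With the defaults, all 1009 segments synchronize into
sustained triangular ~0.13 Hz oscillations.  For the PA segment whose mean
diameter is ~17.5 um: peak-to-trough amplitude ~27 % of the mean with
15/7.5 %/s limits, ~41 % with 15/15, ~27 % with 15/15 and MR_D = 3 s; the
passive component carries ~18 % of the amplitude.  The measured segment is
selected by mean diameter (the population the source describes), not by
depth — amplitude grows with depth in this geometry.

## Cellular PA-segment model

Each segment lumps one SMC and one EC compartment.  Functional forms are
quasi-linear sigmoids `s(x) = 1/(1+exp(-k(x-1/2)))` of normalized stress
(x = WS/WS_max or WSS/WSS_max) and first-order lags:

- Mechanotransduction (lag tau_mct = 5 s): IP3/DAG targets s(x); SMC Kir
  open probability 1 - s(x); EC Kir open probability follows WSS with a fast
  lag; a mechanosensory microdomain Ca pool (tau 0.5 s) sharpens the
  depolarizing current's activation.
- SMC membrane: outward-positive currents; lumped depolarizing current
  g_dep a (V - 0); Kir current with sqrt(K_ex/4) conductance scaling,
  inward-rectification gate (blocked ~25 mV above E_K), and Nernst E_K;
  Kv and BK outward currents (BK gated by voltage, Glu-BK microdomain Ca,
  and — weakly — NO/cGMP; the fast neural-NO action is routed through the
  crossbridge phosphatase instead, following the assumed MLCP pathway);
  myoendothelial junction current (V_smc - V_ec)/R_MGJ with R_MGJ = 1 GOhm;
  homocellular gap coupling between adjacent segments with R = 100 MOhm,
  scaled so the electrotonic length is ~20 segments (GOhm-scale membranes
  against 100-MOhm junctions) and integrated implicitly (backward-Euler
  diffusion along the chain) for unconditional stability.  The EC carries a
  WSS-activated Kir and the MGJ current.  The glutamate microdomain's BK
  shift is scaled so the maximal 1.2 AU level yields the reported ~3.5 %
  steady dilation at IP = 50 mmHg.
- Calcium: first-order to a sigmoid of V (VOCC activation), faster when
  rising (constriction) than falling (dilation) — the asymmetry that
  produces the 4.2 s vs 5.2 s half-period lags.
- Crossbridge: four-state (M, Mp, AMp, AM) cycle with phosphorylation rate
  k_MLCK = Hill(Ca) and dephosphorylation k_MLCP = k0 (1 + beta NO/cGMP);
  tone = AMp + 0.3 AM.  NO thus desensitizes tone to Ca (the assumed
  fast-acting NO pathway), and also shifts BK activation.
- Wall: D = D_passive(WS) - c x contractility x tone x Dmax, with the
  passive ceiling 1.3 x Dmax and c calibrated so maximal sustained tone at
  WS_max develops ~42 % myogenic tone.

Virtual protocols: pressure myography (no flow, EC Kir silent; in-silico
IP = ex-vivo IP + 25 mmHg offset; passive mode clamps tone at zero) and
voltage clamp (gating pre-equilibrated at the IP, then the steady membrane
current evaluated per command potential; RMP by root bracketing, RMR as the
inverse slope at RMP).

**Operating-point anchoring.** The mechanosensing sigmoids carry
per-segment midpoints that are re-centered on the segment's *settled* wall
stress (`CellularPA.equilibrate`, and the pre-settle phase of network runs,
alternate relaxation with re-anchoring until self-consistent).  This
emulates per-depth tuning of baseline diameter and contractile expression:
every segment then autoregulates around a comparable point of its transfer
functions regardless of cortical depth.  Without it, deep segments sit in
the sigmoid tails, carry almost no tone, and none of the depth-dependent
functional-hyperemia features appear.  The pressure-myography and
voltage-clamp protocols deliberately do *not* re-anchor per pressure step —
there the fixed transfer function *is* the object under study.

**Calibration.** The delay-chain targets — ~9.4 s oscillation period
(≈0.1 Hz), a 5.2 s dilation half-phase, damping of the single-PA
oscillation over 2–3 minutes — together with the physiological V (−50…−20
mV) and Ca (100–450 nM) ranges fix the free constants: membrane charging is
fast (C_m/g ≈ 50–150 ms, physically realistic — the slow WS→V lag comes
from mechanotransduction, not membrane charging), the mechanosensing
sigmoid is steep (k = 21), VOCC activation has a 3.5 mV slope, MLCK follows
a Hill(n=4, 210 nM) of Ca, the crossbridge rates carry a global ×1.55
scale, and Ca relaxes with 1.55 s (falling) / 0.4 s (rising) time
constants.  `calibrate_delay_chain()` re-measures the timing from a
single-segment in-network run; with these defaults it reports a 9.0–9.4 s
period and a 5.2 s dilation half-phase.  The individual stage extremum lags
distribute somewhat differently from the nominal 2.0/1.5/1.7 s split (more
of the lag sits in the mechanotransduction→V stage, less in the Ca→diameter
stage) while the half-period sums match; the nominal split is not asserted
anywhere.

## Stimuli

Neurogenic impulses raise NO instantly in segments deeper than 600 um and
with an onset delay (600 - depth)/400 um/s above that; NO decays
exponentially with tau = 5 s.  Potassium and glutamate act only while the
stimulus is on.  The gamma-band pipeline: range normalization to [0,1],
then a smoothed copy that tracks increases instantly and decays with
tau = 5 s (tied to NO clearance); both drive the macro model with a 1.9 s
lag.  A synthetic gamma-band generator (band-limited 0.01-0.3 Hz positive
envelope with step-like transitions, binned at 0.4 s) stands in for in-vivo
recordings, which are not packaged; a two-column CSV loader accepts real
data.  The astrocytic rule fires when the smoothed fractional constriction
rate exceeds 2 %/s, injects a 2 s myogenic-inhibition pulse, and is then
refractory for 10 s; the threshold, amplitude and refractory period are
free parameters (the sources give no numbers).

## Numerical choices

- Macro: dt1 = 0.2 s, dt2 = 1e-4 s (the sources print both 0.1 and 0.4 ms;
  we default to 0.1 ms, configurable), coupling tolerance 1e-6 mV,
  stability guard dt2/RC x max_degree < 1.
- Cellular: explicit Euler; default dt 1e-4 s; protocol and test runs use
  1-2 ms (the fastest state time constant is ~40 ms, so this is well inside
  the stability margin); myosin fractions are renormalized each step.
- Steady states are detected by relative diameter drift < 1e-7 per second.
- Rate limiting clips the full candidate diameter (passive + modulated
  myogenic) against the previously committed diameter.
- Amplitude metrics use the last 200 s of a 600 s run; peak detection uses
  a prominence of 1 % of the mean diameter; the onset estimator fits a
  4-parameter sigmoid and thresholds its derivative at 5 % of the maximum
  slope (configurable).

## What the synthetic data does and does not show

The synthetic gamma-band envelope reproduces the band limitation, the
positivity and the step-like transitions of integrated gamma-band power,
but not the heavy-tailed burst statistics or any coupling between neural
activity and the instantaneous vascular state.  Passing tests therefore
demonstrate that the model responds to a realistic *class* of drives as
described, not that it reproduces any particular animal's recording.
Similarly, the generated network is statistically plausible, not a measured
angioarchitecture; quantities that depend on unprinted geometric detail
(notably the vasomotion amplitudes) are expected to match only within a few
percentage points.

## Known limitations

- No pulsatile (cardiac) flow, hematocrit phase separation, or red-blood-
  cell deformability feedback; no K_ATP/metabolic or acidosis pathways.
- The downstream microvessel chains are passive; their diameters do not
  autoregulate with inlet pressure.
- The cellular model is a reduced phenomenology: currents are normalized,
  not fitted to patch-clamp recordings; absolute conductances are effective
  parameters.
- The astrocytic rule is a threshold heuristic, not a mechanistic
  TRPV4/Ca2+ endfoot model.
- Deterministic dynamics: all delays and rates are fixed, so sustained
  oscillations are single-frequency; in vivo they are stochastic and
  multi-frequency.
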