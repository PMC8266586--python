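# if3cycle

Pre-steady-state FRET kinetics and accessible-volume dye modelling of the
bacterial translation initiation factor IF3 cycle.

IF3 is a two-domain fidelity factor of bacterial translation initiation:
its N- and C-terminal domains (IF3N, IF3C) occupy alternative binding
sites on the 30S ribosomal subunit and rearrange in response to every 30S
ligand — IF1, IF2, initiator fMet-tRNA, mRNA and finally the 50S subunit.
A doubly labelled factor (donor on IF3N, silent acceptor on IF3C) reports
these interdomain movements as donor-fluorescence changes in a
stopped-flow instrument: rising fluorescence means the domains move
apart, falling fluorescence means compaction.

`if3cycle` is a library plus CLI for analysing (and synthesizing) such
experiments end to end:

* **Signal model.** Time courses relax as a sum of exponential phases,
  `F(t) = F0 + Σᵢ Fᵢ·exp(−k_app,i·t)`, fitted by variable-projection
  initialised nonlinear least squares (1 or 2 phases, AICc selection).
* **Mechanism diagnosis.** The concentration dependence of an apparent
  rate is fitted with the two-step binding law
  `k_app = V_max·[C]/(K_s + [C])` (rapid binding equilibrium followed by
  a conformational change) or the bimolecular law
  `k_app = k₁·[C] + k₋₁`, with 1/SD² weighting over replicates.
* **Rate statistics.** Multiphasic reactions are summarised by the
  amplitude-weighted average rate `k_AV = Σ Fᵢ·k_app,i / Σ Fᵢ` with
  term-by-term error propagation, and the signed reaction amplitudes are
  chained into a cumulative cycle profile whose closure to zero expresses
  conservation of the FRET signal over a full initiation round.
* **Structural modelling.** Accessible volumes (AV) of tethered dyes
  (linker length 15 Å, width 4.5 Å, dye radius 4.5 Å) are computed by a
  grid flood fill with steric clearance tests; inter-AV distance
  distributions give the mean donor–acceptor distance ⟨R_DA⟩ per complex
  state, which is rank-aligned against the measured FRET levels.
* **Synthetic data.** Every stage is testable without downloads: a
  generator produces multi-exponential traces with Gaussian instrument
  noise, titrations integrated from the underlying ODE schemes, and toy
  PDB structures with exactly known geometry.

The fitting components are scikit-learn style estimators
(`MultiExponentialModel`, `SaturationCurveFit`) and compose with sklearn
tooling; the module-level functions (`fit_exponential`,
`fit_titration_pipeline`, …) are thin wrappers over them.

## Worked example

Recover the saturating rates of the biphasic 30S-binding reaction from a
synthetic titration (7 replicates, 1000 points per trace, 2% amplitude
noise, six 30S concentrations between 0.05 and 1 µM):

```python
from if3cycle import REACTIONS, generate_scenario, fit_titration_pipeline

traces = generate_scenario(REACTIONS["30S"], seed=7)
result = fit_titration_pipeline(traces, n_phases=2)
for series, sat in zip(result.series, result.saturation):
    lo, hi = sat.ci95("vmax")
    print(f"{series.phase_label}: V_max = {sat.params['vmax']:.1f} "
          f"+/- {sat.stderr['vmax']:.1f} 1/s  (95% CI {lo:.1f}-{hi:.1f}), "
          f"K_s = {sat.params['ks']:.3f} uM")
kav = result.k_av_propagated()
print(f"k_AV = {kav.k_av:.1f} +/- {kav.sigma:.1f} 1/s")
```

prints

```
fast: V_max = 112.4 +/- 1.1 1/s  (95% CI 109.2-115.6), K_s = 0.098 uM
slow: V_max = 5.2 +/- 0.0 1/s  (95% CI 5.2-5.2), K_s = 0.099 uM
k_AV = 65.9 +/- 2.6 1/s
```

The generating kernel (fast phase saturating at 113 s⁻¹, slow at
5.2 s⁻¹, K_s = 0.1 µM) is recovered within the fitted confidence
intervals; `k_AV` summarises the two phases weighted by their amplitude
shares (1.4 V and 0.9 V).

The same analysis is available from a shell:

```bash
if3cycle simulate --reaction 30S --seed 7 --out 30s.csv
if3cycle titrate 30s.csv --phases 2
if3cycle run-cycle --seed 0 --out-dir out/      # the full six-reaction cycle
```

`run-cycle` generates and fits all six reactions of the initiation cycle,
chains their amplitudes (closure residual ≈ 0), models per-state inter-dye
distances through the AV engine on toy fixtures, and reports the rank
alignment between modelled distances and measured FRET levels.

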