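# biofilmnmr

Time-resolved solid-state NMR (ssNMR) analysis of biofilm composition,
degradation kinetics and molecular dynamics.

Bacterial biofilms — here the *Bacillus subtilis* pellicle model — build a
matrix of extracellular polymeric substances (exopolysaccharides, proteins,
eDNA, lipids) that matures within ~48 h and is then actively degraded during
dispersal. ssNMR can watch this non-destructively: quantitative direct
polarization (DP) spectra give total carbon content, short-recycle-delay DP
selects the mobile (liquid-like) phase, and cross polarization (CP) selects
the rigid phase. This package turns processed spectra and peak/integral
tables into the quantities that describe that life cycle, for spectroscopists
and microbiologists who have the spectra but not the analysis plumbing:

* **Carbon biomass density** — spectral integral normalized by sample mass
  *m* and number of scans *NS*, `ρ = ∫I(δ) dδ / (m·NS)`, proportional to the
  carbon weight fraction and hence comparable across samples. Component
  classes are quantified over fixed chemical-shift windows (carbohydrates
  74–105 ppm; proteins 10–29, 34–48, 106–124, 132–160 ppm, excluding lipid
  signals).
* **Mobile fraction** — density ratio of the 2 s-recycle DP spectrum to the
  quantitative DP spectrum over a region.
* **Degraded-matrix composition** — for first-order degradation,
  `[S] = C₀e^(−kt)` and the degraded quantity `D = C₀(1 − e^(−kt))·V` is
  proportional to the average substrate concentration. With equal volume and
  total biomass across two intervals, the protein/carbohydrate percentages
  (p₁, c₁) and (p₂, c₂) of the degraded matrix solve
  `p₁+c₁ = p₂+c₂ = 100`, `p₁/p₂ = D_P1/D_P2`, `c₁/c₂ = D_C1/D_C2`.
* **Site dynamics** — ¹³C T1 by three-parameter inversion-recovery fitting
  `I(t) = A + B·e^(−t/T1)`, and order parameters `S = δ_eff/δ_rigid` from
  DIPSHIFT dipolar dephasing curves, simulated by powder-averaging the
  MAS-modulated C–H dipolar phase (FSLG-scaled; CH and CH₂ multiplicities).
* **Sugar partition clustering** — per-monosaccharide biofilm/medium integral
  ratios over days 2–5, standardized, projected onto 2 principal components
  and clustered with silhouette-guided K-means.

A first-class synthetic-data generator emits complete, ground-truth-annotated
datasets (spectra, recovery series, dephasing curves, sugar and peak-volume
tables) so that every stage is testable end to end without any instrument
data. The T1 and order-parameter fitters and the clustering stage are
scikit-learn-style estimators (`fit`, fitted `*_` attributes,
`get_params`/`set_params`) and compose with sklearn tooling.

## Worked example

```python
from biofilmnmr.kinetics import solve_proportions
from biofilmnmr.synthetic import build_scenario, render_spectrum
from biofilmnmr.quant import total_biomass_series

# degraded-matrix composition from measured degraded quantities
# (proteins 49.28/31.31, carbohydrates 14.18/33.43 on days 3/4)
sol = solve_proportions(49.28, 31.31, 14.18, 33.43)
print(f"day-3 interval: proteins {sol.p1:.1f}%, carbohydrates {sol.c1:.1f}%")
print(f"day-4 interval: proteins {sol.p2:.1f}%, carbohydrates {sol.c2:.1f}%")

# quantify a synthetic 5-day time course
scenario = build_scenario(seed=7)
spectra = [render_spectrum(scenario, day, mode)
           for day in scenario.days for mode in ("qDP", "DP2s")]
print(total_biomass_series(spectra).round(3).to_string(index=False))
```

prints

```
day-3 interval: proteins 78.8%, carbohydrates 21.2%
day-4 interval: proteins 50.1%, carbohydrates 49.9%
 day  density  relative_density  mobile_fraction
   1    0.585             0.728            0.887
   2    0.803             1.000            0.890
   3    0.494             0.615            0.801
   4    0.251             0.312            0.818
   5    0.161             0.200            0.790
```

The solver says the matrix degraded in the day-3 interval was ~79% protein,
falling to an even split a day later — proteins go first, exopolysaccharides
follow. The time course shows the biofilm peaking on day 2 (reference 1.0),
decaying to 20% of maximum by day 5, and its mobile phase shrinking from
~89% to ~79% as the flexible matrix is preferentially consumed (the ~1–3
point offsets from the generator's true values are the documented
short-recycle saturation bias and inter-window tail leakage).

## Command line

```bash
biofilmnmr simulate -c bsubtilis-5day -o run/ --seed 7   # synthetic dataset
biofilmnmr analyze  -c bsubtilis-5day -o run/            # all stages
biofilmnmr recover  -c bsubtilis-5day -o run/            # vs. ground truth
```

`analyze` writes per-stage CSV tables (biomass series, component table,
degraded-matrix proportions, T1 fits, order parameters, PCA scores/labels)
plus a JSON run report with warnings, seeds and input checksums.

## Layout

| module | contents |
| --- | --- |
| `biofilmnmr.spectra` | `Spectrum1D` container, 2-column text + JSON sidecar I/O |
| `biofilmnmr.synthetic` | scenario/ground-truth types, spectrum and table emitters |
| `biofilmnmr.quant` | region integration, densities, mobile fractions, 7-category grouping |
| `biofilmnmr.kinetics` | first-order model, proportion solver |
| `biofilmnmr.dynamics` | inversion-recovery and DIPSHIFT estimators, dephasing simulator |
| `biofilmnmr.clustering` | ratio features, PCA, silhouette-guided K-means |
| `biofilmnmr.pipeline` / `cli` | config, orchestration, reports, recovery suite |

See `docs/methods.md` for the models, assumptions, parameter defaults and
known limitations.
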