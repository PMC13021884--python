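# fermrsm

Response-surface optimization of biocontrol fermentation media, with the
bioassay statistics that surround it.

`fermrsm` is aimed at microbiologists and biostatisticians optimizing the
fermentation medium of an antagonistic micro-organism (for instance a
*Bacillus* strain antagonizing *Fusarium* wilt pathogens). It covers the
complete desk-side pipeline of such a study:

* **Bioassay scoring** — dual-culture inhibition rate
  `(Dc − Dt)/(Dc − plug) × 100`, spore-germination rate and its relative
  inhibition, plant-disease severity index
  `Σ(nᵍ·g)/(N·g_max) × 100` on a 0–6 wilt scale, the control effect
  (relative disease-index reduction vs the untreated control), and
  growth increments; plus one-way ANOVA and Duncan's multiple range
  test to produce the letter codes of assay result tables.
* **Design of experiments** — rotatable central composite designs
  (2ᵏ factorial core at ±1, 2k axial runs at ±(2ᵏ)^¼, replicated center
  runs) and exact coded ↔ actual level conversion
  `x = (amount − center)/Δ`.
* **Second-order modelling** — ordinary least squares for the full
  quadratic surface

  y = b₀ + Σᵢ bᵢxᵢ + Σᵢ bᵢᵢxᵢ² + Σᵢ<ⱼ bᵢⱼxᵢxⱼ

  with a partial (drop-one) sum-of-squares ANOVA, per-term partial
  correlations `sign(b)·√(F/(F+df))`, a lack-of-fit test against pure
  error from replicate runs, and α-threshold model simplification.
* **Effect analysis** — single-factor and two-factor sub-models (other
  factors fixed at coded 0), analytic vertices and stationary points
  with Hessian classification, response-trend zoning around a
  stationary point, and surface grids for plotting.
* **Optimization** — exhaustive lattice search over per-factor coded
  level sets (e.g. 5⁴ = 625 candidate media), decoded into g/L amounts.
* **Simulation** — seeded generators for CCD response tables from a
  known surface plus Gaussian noise, and for assay-level records, so
  estimator bias, standard errors, and lack-of-fit power are all
  quantifiable.

## Worked example

The package ships the complete worked example of a published four-factor
medium optimization (peptone, sucrose, potassium nitrate, sodium
chloride; response = inhibition-zone diameter in mm) as built-in
constants: the 31-run design, the fitted model, the per-term p-values.

```python
from fermrsm.reference import REFERENCE_MODEL, FACTORS, REPORTED_OPTIMUM_CODED
from fermrsm.effects import single_factor_submodel, stationary_point, \
    truncate, two_factor_submodel
from fermrsm.optimize import predict_at

# single-factor dose-response for peptone (other factors at coded 0)
sub = single_factor_submodel(REFERENCE_MODEL, "peptone")
print(truncate(sub.evaluate(0.518), 2))        # 10.34  (mm)

# stationary point of the peptone-sucrose interaction surface
sp = stationary_point(two_factor_submodel(REFERENCE_MODEL, "peptone", "sucrose"))
print(round(sp.coordinates[0], 4), sp.nature)  # -0.8415 saddle

# predicted inhibition zone at the optimal medium, and its recipe
print(round(predict_at(REFERENCE_MODEL, REPORTED_OPTIMUM_CODED)))  # 40  (mm)
print({f.name: round(f.decode(c), 3)
       for f, c in zip(FACTORS, REPORTED_OPTIMUM_CODED)})
# {'peptone': 10.423, 'sucrose': 1.042, 'potassium_nitrate': 1.551,
#  'sodium_chloride': 5.5}
```

The numbers mean: holding the other factors at their center levels, the
peptone dose-response peaks near coded 0.52 at a 10.34 mm inhibition
zone; the peptone–sucrose surface has its stationary point at peptone
≈ −0.84 coded units (a saddle — the strong interaction dominates the
curvature); and the optimal medium (10.42 g/L peptone, 1.04 g/L
sucrose, 1.55 g/L KNO₃, 5.5 g/L NaCl) is predicted to give a 40 mm
inhibition zone.

The same report end-to-end, including the 625-scheme lattice search,
ANOVA-based model simplification and greenhouse control-effect
computations:

```bash
fermrsm reproduce            # JSON report to stdout
fermrsm reproduce --out report.json
```

Other subcommands (`design`, `fit`, `effects`, `optimize`, `assay`,
`simulate`) expose each pipeline stage on CSV/JSON files; see
`fermrsm --help`.

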