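# streakdyn

Quantitative analysis of primitive-streak cell dynamics in the gastrulating
amniote embryo, built around the cell population that matters most for
posterior body formation: neuromesodermal progenitors (NMPs), the bipotent
cells of the anterior primitive-streak (PS) epiblast that contribute to both
the spinal cord and the paraxial mesoderm.

Establishing that such a population exists and persists requires several
independent quantitative arguments, each implemented here as a tested,
reusable module:

- **`streakdyn.kinematics`** — cell-track analysis: registration to the
  regressing node, lateral-to-medial (v_LM) and anteroposterior (v_AP)
  velocities, track angles with the midline, AP speed profiles, track
  longevity (cohort survival after 1 and 2 h), intensity gradients of
  ingression along the streak, and inter-division times.
- **`streakdyn.clones`** — clone identification from retroviral barcodes
  (exact 24-mer grouping) and from three-channel combinatorial nuclear
  colors (normalization to hue fractions, K-means with silhouette > 0.4
  filtering, ternary-plot coordinates), then potency (N / M / NM) and
  anterior/posterior classification.
- **`streakdyn.popmodel`** — the geometric-series growth model
  `U_n = q^n · U_0` with `q = 2(1 − f_ingress)`: forward projection,
  division counts to reach a target population, implied cell-cycle time,
  a stochastic branching-process counterpart, and least-squares recovery of
  `(q, f)` from noisy counts.
- **`streakdyn.imagequant`** — nucleus counting on two-channel stains:
  top-percentile thresholding (default 1.3%), mask AND, 8-connected particle
  analysis with area < 500 px², mitotic indices in 250 µm ROIs, and
  dual-threshold mitosis detection for live nuclear markers.
- **`streakdyn.dynamics`** — dynamically variable genes along a pseudotime
  ordering: for each gene, the sliding 100-cell windows with maximal and
  minimal mean expression are compared by t-test, Benjamini–Hochberg
  corrected (FDR < 0.01), then z-scaled, smoothed and ranked by peak.
- **`streakdyn.synthetic`** — generators for all of the above (tracks with
  programmed convergence/ingression/division gradients, clone color and
  barcode tables, two-channel blob images, pseudotime expression matrices)
  with ground truth retained, so every estimator is scored against known
  parameters.

## Worked example: NMP self-renewal arithmetic

Tracked cells in the anterior PS show that only ~35% of daughters ingress
into the mesoderm per division, while the SOX2/T (NMP) population grows from
about 50 to 550 cells over roughly 40 hours. The geometric model turns those
two observations into a cell-cycle estimate:

```python
from streakdyn import popmodel as pm

model = pm.PopulationModel(U0=50, f_ingress=0.35)
print(model.q)                          # 1.3
print(pm.project(model, 9)[1])          # 530
print(pm.project(model, 10)[1])         # 689
print(pm.divisions_to_reach(model, 550))  # (9, 10)
print(pm.cycle_time(40.0, 10))          # 4.0
```

A doubling parameter of q = 2 × 0.65 = 1.3 takes 50 cells to 530–689 cells
in 9–10 division rounds, so reaching ~550 cells in 40 h implies a cell
cycle of about 4 h — fast division plus limited ingression is sufficient to
amplify the progenitor pool. The same numbers are available from the shell:

```sh
$ streakdyn popmodel project --u0 50 --f-ingress 0.35 --n 10
{
  "q": 1.3,
  "n": 10,
  "U_n": 689,
  "U_n_exact": 689.2924592450003
}
```

The stochastic counterpart and the fitting routine close the loop: counts
simulated by `stochastic_growth_sim` (each daughter ingresses independently)
average to the geometric projection, and `fit_growth` recovers
`f_ingress = 0.35 ± 0.05` from counts with 10% lognormal observation noise.

## Simulating and analyzing a dataset

```sh
streakdyn simulate tracks --seed 1 --out sim/
streakdyn kinematics --tracks sim/tracks.csv --node sim/node.csv --out kin/
streakdyn simulate expression --seed 1 --out expr/
streakdyn dyngenes --expr expr/expression.csv --out genes/
```

`kin/reports.json` then contains per-region angle fractions and longevity
ratios; `genes/dynamic_genes.csv` holds per-gene window positions, t
statistics and FDR-adjusted p-values, with the peak-ranked smoothed heatmap
in `genes/heatmap.csv`.

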