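# laminaq

Quantification and classification of 3D nuclear-lamina shape from confocal
Z-stacks.

## The problem

The nuclear lamina — the lamin A/B meshwork lining the inner nuclear
membrane — is smooth and elliptical in healthy proliferating cells but
wrinkles, folds and locally accumulates lamin A as cells senesce, age, or
undergo apoptosis, and in laminopathies. `laminaq` turns that qualitative
observation into numbers: it segments the closed 3D lamina surface of a
single nucleus from a fluorescence Z-stack and computes three dimensionless
per-cell descriptors,

- **intensity** — mean lamina intensity normalised by the whole-nucleus
  mean, I = ⟨I_shell⟩ / ⟨I_nucleus⟩ (drops when lamin redistributes inward),
- **skewness** — g₁ = m₃/m₂^{3/2} of the lamina intensity distribution,
- **curvature** — area-weighted mean |K| · R_eq², with K the Gaussian
  curvature, R_eq = (3V/4π)^{1/3}; exactly 1 for a sphere, > 1 for wrinkled
  or blebbed envelopes,

then separates labelled cell populations with a Fisher linear discriminant,
reporting the leave-one-out cross-validated error e ± √(e(1−e)/N) and a
label-permutation p-value. A FRAP module estimates lamin mobility (T/2 = τ
ln 2 and the immobile fraction from a single-exponential recovery fit), and a
synthetic-nucleus simulator provides full ground truth (analytic Gaussian
curvature, known intensity model, population labels) so every stage is
testable without microscope data.

Intended users: cell biologists and image analysts quantifying nuclear
envelope phenotypes (senescence screening, laminopathy models, cell-batch QC
before transplantation), and anyone needing a tested Gaussian-curvature
estimator for closed voxel-derived surfaces.

## Worked example

Simulate two small populations (smooth "fresh" vs wrinkled, hotspot-bearing
"senescent" nuclei), run the full pipeline, and classify:

```python
import pandas as pd
from laminaq import (PHENOTYPE_TEMPLATES, simulate_population, compute_features,
                     FeatureParams, SegmentationParams, PopulationDataset, loocv_error)

params = FeatureParams(segmentation=SegmentationParams(min_volume_nm3=5e9))
cells = simulate_population(
    {k: PHENOTYPE_TEMPLATES[k] for k in ("fresh", "senescent")},
    n_per_label=8, jitter=0.1, seed=42,
)
rows = [compute_features(stack, params, cell_id=str(i), label=truth.label).as_dict()
        for i, (stack, truth) in enumerate(cells)]
df = pd.DataFrame(rows)
print(df.groupby("label")[["intensity", "skewness", "curvature"]].mean().round(3))

res = loocv_error(PopulationDataset(df, ("intensity", "skewness", "curvature")),
                  n_perm=199, seed=1)
print(f"LOO error {100*res.error_rate:.1f}% +/- {100*res.error_sd:.1f}% "
      f"(N={res.n_cells}, p={res.p_value:.4g})")
```

Output:

```
           intensity  skewness  curvature
label
fresh          0.918    -0.092      0.970
senescent      0.663    -0.514      2.118
LOO error 0.0% +/- 0.0% (N=16, p=0.005)
```

Read it as: senescent shells carry a lower normalised intensity (lamin has
moved off the envelope relative to the whole nucleus) and roughly double the
sphere-normalised curvature (wrinkling), and the two populations separate
perfectly under leave-one-out cross-validation; the permutation p-value
0.005 is the smallest reachable with 199 permutations.

The same pipeline runs from the shell:

```bash
lamina run --config examples/demo_config.yaml --out results/demo
lamina frap --traces traces.csv --out frap.json
```

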