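# neomrs

In-vivo short-echo-time (TE 12 ms) proton MRS analysis of the neonatal
rabbit brain at 7 T, built for the study design that compares newborns with
intrauterine growth restriction (IUGR, induced by uteroplacental vessel
ligation) against littermate controls in three brain regions (cortex,
hippocampus, striatum). The package is aimed at MR spectroscopists and
methods researchers who want a fully testable, self-contained re-creation
of that analysis: every stage runs on synthetic data the package generates
itself, so no scanner export is needed.

## What it does

* **Synthetic study generator** — PRESS-like complex spectra assembled from
  25 metabolite line lists plus 11 macromolecule components, a partially
  suppressed water line whose chemical shift encodes the voxel temperature,
  matched water-reference scans, labeled brain phantoms, and cohort
  metadata with the study's group structure (6 controls + 5 IUGR from 3
  litters × 3 regions) and published effect sizes.
* **Linear-combination quantification** (`LinearCombinationModel` /
  `LCMResults`) — non-negative basis-set fitting with polynomial baseline,
  global shift/phase/damping nuisances, Cramér–Rao lower bounds, a
  CRLB < 50 % retention filter, water-referenced absolute concentrations
  with a water-T2 correction (T2 = 158 ms), and QC metrics (water FWHM,
  total-choline SNR).
* **Brain thermometry** — the water–choline chemical-shift distance
  `Dist` mapped through the linear calibration
  `T(°C) = −82.33·(Dist + 1.21) + 255.94`.
* **Volumetry** — region volumes from an integer label map (NIfTI) and
  exact analytic tissue composition of an axis-aligned MRS voxel.
* **Spectral-pattern classification** — unit-norm spectral vectors
  (4 Hz apodization, linear baseline, choline referencing to 3.21 ppm,
  UL2 normalization of 4.25–0.5 ppm), region concatenation, sequential
  forward floating feature selection, Fisher LDA, 2-D latent projection,
  and out-of-bag bootstrap evaluation (1000 repetitions).
* **Group statistics** — Shapiro-Wilk-gated t / Mann-Whitney comparisons,
  percent changes, and GLM adjustment for brain temperature, voxel tissue
  fraction, litter and neighbor stillbirths.

## Worked example

```python
import numpy as np
from neomrs import (LinearCombinationModel, absolute_concentration,
                    estimate_voxel_temperature, simulate_spectrum)
from neomrs.simulate import baseline_concentrations, default_basis

conc = baseline_concentrations("cortex")          # µmol/g ground truth
spec, ref = simulate_spectrum(conc, temp_c=31.5, seed=1)

print(round(estimate_voxel_temperature(spec), 2))

basis = default_basis()
res = LinearCombinationModel(spec, basis).fit()
absolute_concentration(res, ref, proton_counts=basis.protons)
tab = res.table
tcr = tab.loc[["creatine", "phosphocreatine"], "concentration"].sum()
print(round(tcr, 2), tab.loc["naa", "crlb_pct"].round(1))
```

prints

```
31.48
2.96 1.9
```

i.e. the voxel temperature is recovered within a few hundredths of a degree
of the simulated 31.5 °C, the total creatine pool comes back near the
3.0 µmol/g generator baseline after water-referenced scaling, and NAA is
quantified with a 1.9 % Cramér–Rao bound — comfortably inside the 50 %
retention filter.

The full pipeline (simulate → quantify → thermometry → volumetry →
classify → statistics) runs from the command line:

```bash
neomrs run --config config.yaml      # see neomrs.pipeline.PipelineConfig
neomrs simulate --out bundle --seed 1
neomrs thermometry --in bundle/spectra/C1_cortex.txt
```

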