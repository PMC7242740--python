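# omihet

Single-cell **optical metabolic imaging (OMI)** analysis of tumor organoids:
fluorescence-lifetime (FLIM/TCSPC) decay fitting, per-cell metabolic
endpoints and the OMI index, Gaussian-mixture subpopulation modeling with the
weighted heterogeneity index (wH-index), and effect-size-based drug-response
classification.

## Who this is for

Labs screening patient-derived tumor organoids with label-free two-photon
microscopy of NAD(P)H and FAD autofluorescence. Bulk viability assays
average away cellular heterogeneity; a minority subpopulation of
drug-resistant cells can be invisible to them. This package quantifies drug
response *per cell* and summarizes how heterogeneous that response is, down
to a predicted responder / non-responder call per treatment arm.

## The model

**Lifetime fitting.** Each pixel of a TCSPC stack holds a photon-arrival
histogram modeled as a two-exponential decay convolved with the instrument
response function (IRF):

```
I(t) = α₁ exp(−t/τ₁) + α₂ exp(−t/τ₂) + C
τₘ  = α₁τ₁ + α₂τ₂
```

τ₁ and τ₂ separate the free and protein-bound co-enzyme pools (free NAD(P)H
is the short component; free FAD is the long one). Fitting is weighted least
squares by iterative re-convolution, with the linear parameters (α₁, α₂, C)
solved by non-negative least squares inside a two-parameter search over
(τ₁, τ₂).

**Per-cell endpoints.** Cytoplasms are segmented from NAD(P)H intensity
(Otsu threshold + marker watershed), and three endpoints are averaged per
cell: the optical redox ratio (NAD(P)H/FAD intensity), NAD(P)H τₘ and FAD
τₘ. Each endpoint is centered on the mean of control cells of the same
patient and timepoint; the **OMI index** combines them with coefficients
(1, 1, −1). A decrease versus control indicates drug response.

**Heterogeneity.** The OMI index distribution of each cell group is fit by
1-D Gaussian mixtures with g = 1..3 components; g is selected by AIC
(`2k − 2 ln L`, k = 3g − 1). From the selected model,

```
wH = Σᵢ (1 − pᵢ ln(pᵢ+1)) · (σᵢ + dᵢ)
```

where pᵢ, σᵢ are the mixing proportion and SD of subpopulation i and dᵢ its
distance to the mixture median. Quadratic entropy, a Kolmogorov–Smirnov
normality distance, and the Tukey-fence outlier percentage are computed
alongside.

**Response.** Treatment effect size is Glass's Δ =
(mean(control) − mean(treated)) / SD(control); group differences use the
Wilcoxon rank-sum test. A treatment arm is classified `predicted_responder`
when Δ ≥ 0.75 **and** the wH-index decreases with treatment.

## Worked example

Simulate one patient's cohort (6 control + 6 treated organoids, 40
cells each) where the drug shifts all three endpoints in the response
direction by ~1.5 control-SD on the OMI index and homogenizes the
population, then analyze it:

```python
import numpy as np
from omihet.simulate import (CohortSimSpec, TreatmentSpec, MixtureComponent,
                             generate_cell_table)
from omihet.quantify import omi_index
from omihet.response import response_report
from omihet.heterogeneity import select_model, wh_index

d = 1.5 / np.sqrt(3.0)   # per-endpoint shift, control-SD units
arm = TreatmentSpec("gemcitabine",
                    mixture=[MixtureComponent(1.0, (-d, -d, d), 0.6)],
                    organoid_sd_multiplier=0.3)
spec = CohortSimSpec(n_patients=1, organoids_per_patient=6,
                     cells_per_organoid=40, treatments=[arm], seed=1)
cells = omi_index(generate_cell_table(spec))
print(response_report(cells))

control = cells.loc[cells.treatment == "control", "omi_index"].to_numpy()
model = select_model(control)
print(f"control subpopulations: g={model.g}, wH={wh_index(model):.4f}")
```

Output:

```
patient_id   treatment  glass_delta   wilcoxon_p  wh_control  wh_treated      classification
       P01 gemcitabine     1.893383 1.630133e-67    0.052931    0.030811 predicted_responder
control subpopulations: g=1, wH=0.0529
```

Glass's Δ ≈ 1.9 (a large mean OMI-index decrease), and the wH-index drops
from 0.053 to 0.031 (the treated population is *more* homogeneous), so the
arm is called a predicted responder. A heterogeneous, weak, or
subpopulation-split response flips the call to `predicted_non_responder`.

## Command line

The same pipeline runs from a shell, end to end or stage by stage:

```bash
omihet run-all  --seed 11 --out-dir out/          # simulate → fit → segment →
                                                  # quantify → heterogeneity →
                                                  # respond → report
omihet simulate --seed 11 --out-dir out/          # or any single stage
```

Outputs are CSV tables (cells, heterogeneity profiles, response report),
TIFF images/masks, and PNG plots with CSV twins; every CSV header carries
the config hash and seed, and reruns with the same seed are byte-identical.

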