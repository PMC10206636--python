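# vdpkit

Quantification of pulmonary **ventilation defect percent (VDP)** from 3-D
ventilation images — Technegas SPECT or hyperpolarized ¹²⁹Xe MRI — together
with a digital dual-modality lung phantom and the agreement statistics needed
to compare the two modalities.

Ventilation imaging maps where inhaled gas (or a gas-like aerosol) actually
reaches the lung. The standard summary measure is the VDP: the volume of
poorly ventilated lung as a percentage of the thoracic cavity volume,

```
VDP = 100 × V_defect / V_cavity .
```

Two established segmentation methods define "defect" from the voxel
intensities inside a thoracic-cavity mask:

* **Adaptive thresholding (VDP_T)** — a voxel is defect if its intensity is
  strictly below `0.5 × Mean_5–80`, where `Mean_5–80` is the mean intensity
  of cavity voxels between the 5th and 80th intensity percentiles (computed
  with an exact, interpolation-free rank window: ascending 1-based ranks
  `0.05·N < r ≤ 0.80·N`).
* **k-means clustering (VDP_K)** — the cavity intensities are binned into
  k = 5 clusters by deterministic 1-D Lloyd iteration; the lowest-signal
  cluster is the defect.

The package is aimed at researchers developing or validating VDP pipelines:
because public co-registered SPECT/MRI ventilation datasets are scarce, it
ships a **phantom module** that generates ground-truth ventilation fields with
a known defect fraction and observes them through SPECT-like (Gaussian PSF,
tidal-breathing smear, Poisson counts, optional hot-spots) and MRI-like
(anisotropic voxels, coil-bias field, Rician noise) forward models, so every
stage of the pipeline is verifiable against known truth. A **compare module**
provides Bland–Altman agreement, Spearman/Pearson correlation with exact
small-n permutation p-values, and normality-gated paired and group
comparisons.

Segmentation is exposed as scikit-learn style estimators
(`AdaptiveThresholdSegmenter`, `VentilationKMeans`) over the 1-D cavity
intensity sample, with thin functional wrappers for volume/mask inputs.

## Worked example

```python
import numpy as np
from vdpkit import (PhantomSpec, SpectModel, MriModel, make_phantom,
                    simulate_spect, simulate_mri, segment_threshold,
                    segment_kmeans, compute_vdp)

spec = PhantomSpec(defect_fraction_target=0.15, seed=3)
truth = make_phantom(spec)
print(f"true defect fraction: {truth.true_defect_fraction:.4f}")

spect_vol, spect_cav = simulate_spect(truth, SpectModel(seed=3))
mri_vol, mri_cav = simulate_mri(truth, MriModel(seed=3))

for name, vol, cav in (("SPECT", spect_vol, spect_cav),
                       ("MRI", mri_vol, mri_cav)):
    vdp_t = compute_vdp(segment_threshold(vol, cav), cav, vol)
    vdp_k = compute_vdp(segment_kmeans(vol, cav), cav, vol)
    print(f"{name}: VDP_T = {vdp_t.vdp_percent:.1f}%, "
          f"VDP_K = {vdp_k.vdp_percent:.1f}%")
```

prints

```
true defect fraction: 0.1511
SPECT: VDP_T = 13.4%, VDP_K = 12.4%
MRI: VDP_T = 14.4%, VDP_K = 13.6%
```

The phantom hides 15.1% of the cavity inside low-signal defects; both
segmentation methods recover it to within a couple of percentage points on
each degraded observation, with the threshold method reading slightly higher
than k-means (it also sweeps up hypo-ventilated voxels, not only the defect
mode). On noise-free, blur-free observations both methods recover the true
fraction almost exactly.

The same pipeline is available from the shell:

```bash
vdpkit phantom --defect-fraction 0.15 --seed 3 --out ph/
vdpkit simulate spect --truth-dir ph/ --out sim/
vdpkit vdp sim/spect.nii.gz sim/spect_cavity.nii.gz --method both
vdpkit experiment config.yaml        # full simulated cohort + statistics
vdpkit stats cohort.csv              # re-run the comparison battery
```

`vdpkit experiment` generates a cohort of phantoms, quantifies all four VDPs
per subject (method × modality), and writes `cohort.csv`, `stats.csv`
(Spearman, Bland–Altman, paired tests, optional group comparisons), and a
provenance log (package version, config hash, per-subject seeds).

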