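# nlsd — Non-Local SVD Denoising of 3-D MR Magnitude Images

Magnitude MR images carry Rician noise: each voxel is
z = √((u+n₁)² + n₂²) with u the clean magnitude and n₁, n₂ Gaussian, so the
noise is signal-dependent and biased in dark regions. Plain smoothing
removes it at the cost of the fine anatomical detail that matters for
reading the image. `nlsd` implements a sparse-representation denoiser for
people working with volumetric MR data (phantom studies, preprocessing
before segmentation, method comparisons) that filters noise while keeping
edges and thin structures.

## Method

The pipeline, run inside a variance-stabilizing transform (VST) that makes
the noise additive with flat std γ:

1. **Sparse model.** The stabilized volume is split into all overlapping
   n×n×n sub-volumes, vectorized into Y ∈ R^{n³×P}, and coded by KSVD/OMP:
   min ‖Y − DA‖²_F s.t. ‖α_c‖₀ ≤ L.
2. **Atom reinforcement.** Each atom's *global influence* gi_k is the
   fraction of signals using it; the dictionary is reinforced,
   D′ = D·Diag(1 + δ·GI) (δ = 8), and Y is re-coded against D′ — common
   patterns (tissue interfaces) win the greedy atom selection more often,
   which counteracts the blurring that patch averaging would cause.
3. **Non-local grouping.** Similar signals are found through the code, not
   a spatial window: candidates for ŷ_c are all signals whose strongest atom
   is one of ŷ_c's atoms, accepted when
   ‖ŷ_j − ŷ_c‖/‖ŷ_c‖ ≤ (b − a·‖ŷ_c‖/n^{3/2})(1+γ), a = 0.06, b = 0.18.
4. **SVD filtering.** Each group matrix X = [ŷ_c, SS(ŷ_c)] is truncated to
   the largest rank k whose discarded energy Σ_{i>k}σ_i² still reaches the
   noise energy τ(γ); ŷ_c is re-estimated as the column mean of X̂.
5. **Rarity-weighted aggregation.** Voxels are recomposed as weighted means
   over covering patches with weights R_c = ⟨GI, |α_c|⟩, favouring frequent
   (well-estimated) sub-volumes.
6. **Scales.** Steps 1–5 run per patch size n ∈ {3, 4}; the outputs are
   averaged, un-normalized, and mapped back through the exact-unbiased
   inverse VST.

See `docs/methods.md` for the full model, numerical choices, and limits.

## Worked example

```python
import numpy as np
from nlsd import (PhantomSpec, make_phantom, add_rician_noise,
                  nlsd_denoise, NlsdConfig, psnr, ssim)

clean = make_phantom(PhantomSpec(shape=(48, 48, 48), seed=7))
sigma = 0.05 * float(clean.data.max())          # 5% Rician noise
noisy = add_rician_noise(clean, sigma, seed=11)

out = nlsd_denoise(noisy, sigma=sigma, cfg=NlsdConfig(seed=7))

print("psnr noisy", round(psnr(clean, noisy), 3), "-> out", round(psnr(clean, out), 3))
print("ssim noisy", round(ssim(clean, noisy), 4), "-> out", round(ssim(clean, out), 4))
```

Output (a few minutes on one CPU):

```
psnr noisy 25.441 -> out 31.951
ssim noisy 0.7621 -> out 0.9148
```

The noisy phantom sits at 25.4 dB PSNR against the clean reference; the
denoised volume gains ~6.5 dB (noise energy down ~4.5×) and the structural
similarity rises from 0.76 to 0.91 — noise is removed while the ellipsoid
interfaces stay sharp.

The same is available from a shell:

```bash
nlsd simulate --shape 48,48,48 --sigma-pct 5 --seed 7 \
     --out-clean clean.nii --out noisy.nii
nlsd denoise --in noisy.nii --sigma-pct 5 --out den.nii --seed 7
nlsd eval --ref clean.nii --test den.nii       # JSON: psnr_db, ssim, ...
```

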