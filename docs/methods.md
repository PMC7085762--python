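# Methods

`nlsd` denoises 3-D MR magnitude volumes corrupted by Rician noise. The
method combines a learned sparse dictionary model with non-local low-rank
filtering: the sparse code, not a spatial search window, decides which
patches are similar, and the noise level decides how hard each group of
similar patches is filtered. This note documents the model, the numerical
choices, and what the synthetic test bed does and does not demonstrate.

## Noise model and variance stabilization

A magnitude voxel is z = sqrt((u + n1)² + n2²), with u the clean magnitude
and n1, n2 i.i.d. zero-mean Gaussians of std σ — a Rice(u, σ) variable whose
noise std and bias both depend on u. The pipeline therefore runs inside a
variance-stabilizing transform (VST): a monotone map f with
std[f(z) | u] ≈ γ constant for all u, so the interior stages can treat the
noise as additive with known flat std.

The stabilizer is tabulated numerically, once, in σ = 1 units (the general
case rescales as f_σ(z) = σ·f₁(z/σ)):

* Rice mean m(u) and std s(u) are evaluated in closed form via
  exponentially scaled Bessel functions (stable at high SNR).
* The first-order stabilizer slope f′(t) = γ / s(m⁻¹(t)) is refined by a
  fixed-point iteration: the conditional std of f(z) is measured by
  quadrature over the Rice density on a u-grid, and the slope is rescaled
  until the std profile is flat. Sixteen iterations bring the residual
  deviation to ≤ 3% over u/σ ∈ [0, 10] and ≤ 1.1% over [2, 10], measured by
  quadrature.
* γ is normalized so f(z) ~ z at high SNR, hence γ = σ in input units.

Two inverses are exposed, because they answer different questions. The
algebraic inverse f⁻¹ makes forward→inverse the exact identity on
deterministic data. The exact-unbiased inverse maps the *expected* stabilized
value E[f(z)|u] back to u; it is the right inverse for a denoised estimate,
since it also removes the Rician bias (at u = 0 the raw magnitude has mean
≈ 1.25σ, which the unbiased inverse sends back to ≈ 0). The pipeline uses
the unbiased inverse; the two coincide at high SNR. Note the consequence:
forward-then-unbiased-inverse on noise-free data is *not* the identity at
low SNR (it applies a bias correction the data never suffered), which is why
the round-trip contract is stated for the algebraic mode.

A blind noise estimator is provided for convenience: the median absolute
deviation of the finest-scale wavelet detail coefficients (÷ 0.6745),
restricted to foreground (approximation band above its Otsu threshold),
because background Rician noise is Rayleigh-deflated by ≈ 0.655 and would
bias a whole-volume MAD low. It is plumbing, not a contribution; σ can and
should be supplied when known.

## Stage 1 — sparse model and atom reinforcement

The stabilized volume, rescaled to [0, 1] (the scale factor is kept and
inverted later; the similarity threshold below presumes unit-range
intensities), is decomposed into all fully interior n×n×n sub-volumes
(stride 1), vectorized into Y (n³ × P). KSVD learns a dictionary D (K
atoms, unit norm) with per-column sparsity L, alternating batch OMP with
per-atom rank-1 SVD updates; unused or near-duplicate atoms (|cos| > 0.99)
are replaced by the worst-represented training signal. Because greedy OMP is
not an exact minimizer, each re-encoding keeps, per column, the better of
the new code and the carried-over one, which makes the recorded objective
provably non-increasing.

The global influence gi of an atom is the fraction of signals whose code
uses it (nonzero test at 1e-12). The dictionary is reinforced as
D′ = D·Diag(1 + δ·gi), δ = 8 by default, and the volume is re-coded by OMP
against D′. The reinforcement acts through atom *selection*: amplified
(common) atoms win the greedy correlation step more often, steering the
representation toward recurrent structure (tissue interfaces), while the
least-squares fit keeps Ŷ = D′A consistent with Y. Applying D′ to the
*old* code instead would simply inflate common components by up to
(1 + δ·max gi) and measurably destroys PSNR; the re-coding reading is the
one under which δ = 8 is beneficial, consistent with its intended role.
`recode_reinforced=False` restores the literal no-recode composition.

## Stage 2 — non-local grouping and SVD filtering

For each signal c, the influencer set I(c) holds the atoms with nonzero
coefficients in α_c; the candidate set contains every signal whose single
strongest atom (max |coefficient|, ties to the lowest index) lies in I(c).
Candidates are accepted when

    ‖ŷ_j − ŷ_c‖ / ‖ŷ_c‖ ≤ (b − a·‖ŷ_c‖/n^{3/2})·(1 + γ),

a = 0.06, b = 0.18: the threshold moves in [b−a, b], tighter for bright
references (the eye is less tolerant of errors there) and looser at higher
noise. For near-zero references (‖ŷ_c‖ ≤ 1e-6) the left side degenerates to
‖ŷ_j‖. ‖ŷ_c‖/n^{3/2} is clamped at 1 against reconstruction overshoot.

The group matrix X = [ŷ_c, SS(ŷ_c)] is SVD-truncated: keep the largest rank
k whose discarded tail energy Σ_{i>k} σ_i² still reaches τ, with floor
k = 1. The default calibration is τ = γ²·n³·l — the expected Frobenius
noise energy of an n³×l matrix under i.i.d. noise of std γ; the `literal`
mode τ = γ² is also available but is dimensionally mismatched to a
multi-entry Frobenius norm and truncates almost nothing on [0, 1]-scaled
data. The reference is re-estimated as the plain column mean of the
truncated group, and all groups are formed against the stage *input*
(Jacobi-style batch update), so the result is independent of processing
order.

Two approximation knobs bound the cost, both seeded, configurable, and
disabled in every oracle test: a group-size cap (default 96, keeping the
nearest members by relative distance — the group mean is insensitive to the
distant tail) and a per-atom candidate-bucket cap (default 1024, random
subsample). The bucket cap exists because with fully overlapped patches a
uniform-background atom can be the top influencer of half the volume, which
would make even the nearest-96 selection quadratic. Logs report how often
each cap bites.

## Aggregation and scaling

Each voxel is covered by up to n³ patches; its estimate is the
rarity-weighted mean of the values those patches propose, with rarity
R_c = ⟨gi, |α_c|⟩ (floored at 1e-12). Frequent signals carry larger group
averages and hence better estimates, so they are weighted up. Absolute
coefficients are used (a switch restores the signed dot product): with
signed values a frequent signal could score negative, contradicting the
intended "frequent ⇒ trustworthy" semantics. If every patch covering a voxel
has zero weight, the mean falls back to uniform for that voxel.
Numerically, the aggregation accumulates weighted deviations from a
per-voxel reference proposal, so aggregating unmodified patches reproduces
the volume bit-exactly.

The whole two-stage process runs once per scale n ∈ {3, 4} (one dictionary
per scale, since atom dimensionality differs), and the per-scale volumes are
averaged voxelwise: small patches preserve detail, larger ones suppress more
noise. Finally the [0, 1] normalization is undone and the exact-unbiased
inverse VST maps back to magnitude units.

## Parameters

| name | default | meaning |
| --- | --- | --- |
| `scales` | (3, 4) | sub-volume edges; averaged per voxel |
| `delta` | 8 | reinforcement strength; 0 disables |
| `a`, `b` | 0.06, 0.18 | similarity-threshold interval [b−a, b] |
| `K` | 4·n³ | atoms per scale (~4× overcomplete) |
| `L` | 5 | max nonzeros per code column |
| `iters` | 10 | KSVD iterations |
| `train_subsample` | 30 000 | training columns (seeded); code covers all P |
| `group_cap` | 96 | max similar-signal group size |
| `bucket_cap` | 1024 | max per-atom candidate bucket |
| `energy_scale` | scaled | τ calibration (γ²·n³·l) vs `literal` (γ²) |
| `vst` | foi_tabulated | `none` treats noise as additive Gaussian |

δ, a, b and the scale set are the method's reference operating point; K, L, the
iteration count and the initialization (seeded random data columns) have no
canonical values and follow standard dictionary-denoising practice; all are
exposed in `NlsdConfig` and the YAML config.

## Synthetic test bed

The phantom generator builds nested ellipsoidal compartments at distinct
plateau intensities over a dark exterior, with Gaussian-tapered boundaries
and two congruent satellite ellipsoids on opposite sides of the volume —
guaranteeing genuinely non-local self-similarity, which the grouping tests
assert directly. It emulates the piecewise-smooth, repeated-structure
character of anatomical volumes but none of the rest of real MR data: no
bias fields, no partial-volume texture, no anatomy-specific contrast, no
spatially varying or correlated noise. Passing the end-to-end tests shows
the pipeline removes stationary Rician noise from piecewise-smooth
self-similar volumes; it does not certify performance on clinical data.

The default evaluation volume is 48³ with 5% noise, chosen so a full
two-scale run finishes in a few minutes on one CPU while still containing
~10⁵ overlapping patches per scale; the same code runs unmodified on
full-resolution phantoms (e.g. 181×217×181), only slower. Quality metrics
are PSNR (peak = max of the clean reference, matching the %-of-max noise
convention) and Gaussian-weighted SSIM (std 1.5, 11-sample window, K1=0.01,
K2=0.03) computed over full 3-D windows, with a slice-wise 2-D mode for
comparison with 2-D conventions.

## Degenerate inputs and tie-breaks

Constant volumes estimate σ = 0; all-zero patches get empty codes, form
singleton groups, and pass through unchanged; all-zero codes floor their
rarity at 1e-12; top-influencer ties break to the lowest atom index; SVD
truncation always keeps at least one component; negative intensities on
input are clamped to zero with a logged count; 4-D inputs are rejected.
All randomness (noise draws, dictionary init, training subsample, bucket
subsampling) flows from explicit seeds, and a fixed configuration reruns
bit-identically.

## Known limitations

* The literal-τ mode is faithful to the stated rank rule but ineffective on
  normalized data; the scaled default is our calibration of that rule.
* The group/bucket caps trade fidelity for tractability on large volumes;
  oracle tests run uncapped, so the caps are exercised only by the
  end-to-end tests and logs.
* Spatially varying noise maps and parallel-imaging noise correlation are
  out of scope; σ is assumed stationary.
* The stabilizer table covers u/σ ≤ 40 with linear continuation above;
  inputs vastly brighter than 40σ rely on the (accurate) high-SNR asymptote.
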