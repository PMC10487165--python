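# Methods

## Scope and data model

The package analyses multispectral image stacks of food items: per item and
view, 19 narrow-band shots (center wavelengths 385–1020 nm) plus one RGB
shot captured under white light, each a 16-bit frame. Band membership
follows the counting used in the selection-rate analyses: the white LED
covers roughly 430–640 nm, so 385/405 nm count as UV, the nine channels
430–660 nm as VIS, and the eight channels 810–1020 nm as NIR. (An
alternative convention places everything above 640 nm in NIR; we keep
645/660 nm in VIS so the UV/VIS/NIR census is 2/9/8.)

A packaged CSV of 101 food items supplies names, weights and caloric
values. Three items have no caloric value ("N/a"); these are parsed as
missing, never as zero, and excluded from calorie summaries and from the
caloric-difference pair set. A printed `0.00` is a true (present) zero and
is only replaced later, in the regression labels. Summary statistics use
the sample (n−1) standard deviation.

## Feasibility statistics

**Masked histograms.** Each shot carries a binary food mask; brightness
histograms count only in-mask pixels, with B equal-width bins (default 256)
spanning the full 16-bit range so any two histograms share one binning. An
item's representative histogram pools all of its views (per-shot versus
pooled is not empirically distinguishable here; pooling stabilises small
synthetic datasets).

**Bhattacharyya distance.** D_B = −ln Σ√(p·q). The natural log is a
convention choice; the distance is 0 iff the histograms agree bin-wise and
is returned as `inf` for disjoint supports. A bounded variant
(1 − Σ√(p·q) ∈ [0,1]) is available via `clamp=True` for users who want a
saturating score.

**Cumulative ratio.** Per item pair, the band representative distance is
the maximum D_B over the band's wavelengths (VIS vs UV∪NIR). F_C(T_V,
T_NV) is the fraction of visually-confusable pairs (D_B^(V) < T_V) that are
separable outside the visible band (D_B^(NV) > T_NV). An empty denominator
is an error (grid cells are reported as NaN), never a silent zero.

**Caloric correlations.** D_c(n,m) = |c_n − c_m|/(c_n + c_m); ρ(λ) is the
Pearson correlation between D_B(·|λ) and D_c over pairs with valid
calories and finite distances (≥3 pairs required). Band means of ρ are
compared with a two-sided two-sample Welch t-test on Fisher-z transformed
values; the test's name is recorded in the output metadata since the
choice of significance test is a package convention. Degenerate input
(zero variance in both bands) returns p = 1 when the means agree.

## Preprocessing

Shot-to-shot LED intensity drift is compensated by the scale factor
α = μ_shot/μ_ref: pixels are divided by α so the shot mean lands on the
per-wavelength reference μ_ref (the mean of per-shot means across many
shots). Normalization is idempotent; a zero-mean shot is an error. Frames
are resized to 64×64 with bilinear interpolation over the entire frame (no
cropping; the 640×480 aspect ratio is deliberately not preserved). The RGB
shot splits into its R, G, B planes. Assembled CNN inputs order channels
canonically (RGB planes first, then ascending wavelength), rescale
intensities to [0,1], and report an *image count* that counts the RGB shot
once even though it contributes three channels — curves over wavelength
sets are indexed by shots, not channels. Exact-zero calorie labels become
5 kcal (the nutrition-table minimum) so relative-error losses are defined.

## CNN estimators

Architecture (C input channels, 64×64): conv 11×11 (16 filters) → ReLU →
max-pool 4×4 → conv 7×7 (32 filters) → ReLU → max-pool 4×4 → flatten →
FC 112 → ReLU → FC 128 → ReLU → output. Classification uses a soft-max
output with cross-entropy; regression a single linear unit with the MAPE
loss, 100·mean(|t − y|/t). Convolutions are valid with stride 1; pooling
stride equals the window with floor truncation (64→54→13→7→1). Any
configuration that collapses the spatial size fails at build time.

Choices the architecture spec leaves open: convolution filter counts
default to 16/32 (desk-scale experiments use 8/16); the optimizer is Adam
(lr 1e-3, β 0.9/0.999), initialisation He-style and seeded; mini-batch 32;
the regression output bias starts at the mean training target so relative
errors begin O(1). Both passes of the convolution are evaluated in the
Fourier domain with zero-padding to the frame size, which is exactly the
valid-mode spatial convolution (verified against central finite
differences in the test suite) and is what makes CPU-only training of this
kernel geometry fast. Training is bit-reproducible given the seed on a
fixed platform. The reference epoch budget is 1000; all desk-scale
experiments in this repository use 150 (80 inside selection loops), which
is past loss-plateau on the synthetic datasets.

MAPE's gradient is discontinuous where prediction equals truth; Adam
handles the kink, but finite-difference checks exclude crossing points.

## Wavelength selection

One iteration of the piecewise search does: (1) *forward selection* — try
adding each wavelength outside the working set, keep the argmin of the
loss; (2) *backward elimination* — try removing each member, keep the
argmin; (3) *final forward selection* — add the best wavelength from
outside the reduced set (possibly re-adding the one just removed). The net
effect is +1 per iteration; iterating to the full set yields one best set
per cardinality, and the overall optimum is the recorded set with minimal
loss. Only end-of-iteration sets compete for the optimum; intermediate
forward/backward sets are logged in the trace but do not.

The loss of a candidate set is the final validation loss (cross-entropy or
MAPE, matching the task) of a CNN trained on that set's channels —
validation rather than training loss, since selecting on training loss
rewards overfitting. Losses are memoized by canonical set key, and each
set trains with a seed derived from (global seed, set key) so repeated
evaluations are identical and cacheable. Ties break deterministically:
smallest wavelength wins, RGB outranks all. In `include_rgb` mode the
search starts from {RGB} and never removes it, and the cardinality-1 entry
is {RGB} itself. Selection-rate summaries count how often each wavelength
appears across per-cardinality best sets; band shares divide the
narrow-band slots among UV/VIS/NIR.

The search is a heuristic: it does not guarantee the global optimum over
all 2^N subsets (the trace makes every evaluation auditable, and the test
suite proves each *step* optimal against enumeration for ≤4 wavelengths).

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes, not
the photographs themselves. Per class it draws a latent composition
(water, sugar, fat mass fractions), a smooth random reflectance curve over
wavelength, a silhouette (disk/square/annulus/blob), and a multiplicative
sinusoidal texture. Calories follow an Atwater-style rule,
kcal = weight·(4·sugar + 9·fat), with per-item weights drawn around the
food-table mean (141 ± 20 g). NIR reflectance is coupled to caloric
density (`nir_coupling`, default 1; 0 decouples it for null experiments),
so caloric differences are readable from NIR brightness but not from the
visible channels, mirroring how water/sugar content modulates real NIR
reflectance.

*Confusable pairs* copy everything from their mate — silhouette, texture,
UV/VIS/RGB and all NIR reflectances — except the designated NIR channel
(default 890 nm), shifted by exactly `nir_delta` (default 0.3), and the
sugar fraction, shifted by 0.8·`nir_delta` (reducing water when sugar has
no headroom) so the pair's calories differ by a guaranteed margin. This
plants pairs that are visually identical yet nutritionally different, with
exactly one separating channel.

Rendering: the silhouette and texture are defined in object coordinates
and each view rotates those coordinates (angle = view·360°/n_views), so
in-mask brightness distributions are rotation-covariant across views up to
resampling. In-mask intensity is reflectance × full scale × texture; the
whole frame — background included — is scaled by a per-shot log-normal
illumination jitter (σ = 0.05), which is what makes mean-normalization
able to cancel the drift, then Gaussian sensor noise (σ = 200 on the
16-bit scale) is added and the frame clipped to [0, 65535]. Every shot
derives its random stream from (seed, item, view, wavelength), so datasets
are reproducible shot-by-shot. The texture amplitude (0.3) is chosen so
in-mask histograms are wide enough that Bhattacharyya distances vary
smoothly with reflectance differences instead of saturating.

Default study conditions: 6 classes (two confusable pairs), 8 views, 72×96
frames, every 4th view held out for validation (a 75/25 split, echoing the
reference 10,909/3,636 train/validation proportion). Feasibility-oriented
statistics use a wider 14-class, 2-view dataset so the 91 item pairs give
stable Pearson correlations.

What the generator does **not** emulate: real food reflectance spectra,
specular highlights, shadows, camera vignetting, wavelength-dependent
focus, or segmentation error (masks are exact). Passing tests therefore
demonstrate that the statistics, the estimators and the selection search
recover planted structure under controlled noise — not that any particular
accuracy carries over to physical acquisitions.

## Problem sizes and numerical choices

Desk-scale experiments (6 classes × 8 views, ≤5 candidate wavelengths,
150/80 epochs, 8/16 conv filters) run the full pipeline in minutes on one
CPU; the 20-wavelength search at 1000 epochs is supported but
long-running. Histograms default to 256 bins (64 in small synthetic
experiments, where in-mask pixel counts are ~10³ per view). Ties,
degenerate inputs and undefined statistics raise errors or NaN flags
rather than silently coercing (empty masks, zero-variance correlations,
empty F_C denominators, zero-mean shots, zero regression targets).

## Known limitations

- The CNN is CPU-bound NumPy; it is sized for the 64×64/two-conv geometry,
  not a general deep-learning framework.
- Bhattacharyya distances on narrow synthetic histograms can be infinite
  (disjoint supports); the bounded `clamp` variant exists for that case,
  and correlation profiles drop non-finite distances.
- The piecewise search inherits the heuristic's known blind spots; with
  noisy CNN losses the selected sets vary with the seed (the per-set seed
  derivation keeps any single run reproducible).
- Single synthetic camera: the 4-camera rig is emulated by the view axis.
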