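# Methods

`fuzzynir` implements a spectra-to-storage-class analysis for FT-NIR
diffuse-reflectance data: multiplicative scatter correction (MSC),
supervised dimension reduction by orthogonal linear discriminant analysis
(OLDA), and classification of the reduced scores by three fuzzy clustering
algorithms — fuzzy C-means (FCM), K-harmonic means (KHM) and
Gustafson–Kessel (GK) — under a chained-initialization protocol. Because
no spectral archive is bundled, a synthetic generator reproduces the
statistical structure the analysis assumes, and every claim the tests make
is a claim about that structure.

## Synthetic spectra

Each storage-day class `c ∈ {1..6}` has a noiseless template

    T_c(ν) = b0 + b1 t + b2 t²  +  Σ_j (a_j + (c−1) s_j) exp(−(ν − ν_j)² / 2σ_j²)

on a strictly decreasing grid of 1557 wavenumbers from 10 000 to
4 000 cm⁻¹ (`t` is the grid coordinate normalized to [0, 1]). Defaults put
Gaussian peaks at ν_j = 5200 and 6900 cm⁻¹ (widths 200 / 300 cm⁻¹,
amplitudes 0.80 / 0.50 AU) on a quadratic baseline (0.30, 0.10, 0.05).
Storage time acts only through the per-class amplitude increments
s = (0.012, 0.008) AU, so adjacent days overlap at the peak bottoms while
distant days separate — the geometry the classification exploits.

A sample of class `c` is `α T_c + β + ε` with `α ~ 1 + N(0, 0.05²)`,
`β ~ N(0, 0.02²)` and heteroscedastic noise `ε` of s.d. 0.005 AU,
tripled inside the 4000–4350 cm⁻¹ water band. The scatter model is exactly
the affine model MSC assumes, which makes MSC correctness exactly testable
(scatter-free data must be a fixed point; affinely distorted data must be
restored to machine precision). One generator is seeded per dataset and
the draw order is fixed (slopes, offsets, noise; samples class-major), so
datasets are bitwise reproducible.

Default noise/step sizes were calibrated once so that the end-to-end
pipeline on the default preset lands where a real storage study plausibly
does: test accuracies in the high 80s to low 90s percent, confusion
concentrated between neighbouring days, day 1 vs day 6 fully separated.
The `well_separated_config` preset (steps 0.05 / 0.035 AU, noise
0.002 AU) makes the classes essentially recoverable, and is what the
parameter-recovery tests use: on it, failure to reach ≥ 95 % accuracy
indicates an implementation defect, not a hard dataset.

What the generator does *not* emulate: baseline drift correlated across
samples, wavelength-dependent (non-affine) scatter, chemically structured
class differences (real storage shifts specific N–H/C–H bands
asymmetrically), and non-Gaussian instrument noise. Passing tests
therefore validate the algorithms and their contracts, not the field
performance of the pipeline on pork spectra.

## Multiplicative scatter correction

The reference ("standard") spectrum is the mean of the calibration
spectra. Each sample x is regressed on the reference r by ordinary least
squares over all wavenumbers, `x ≈ intercept + slope · r`, and corrected
as `(x − intercept)/slope`. The reference is fitted on the training split
only and reused for the test split, so no test information leaks into
preprocessing (a flag allows the all-data variant). Slopes with
`|slope| < 1e−8` are treated as degenerate: the sample is returned
uncorrected and flagged, rather than amplified by a near-zero division.
MSC is idempotent: a second pass yields slopes 1 and intercepts 0 to
1e−10.

## Orthogonal linear discriminant analysis

With k classes, between-class scatter S_b, within-class S_w and total
S_t = S_b + S_w, classical LDA maximizes trace(S_w⁻¹S_b) — undefined here
because d = 1557 greatly exceeds n = 270 (the small-sample-size regime:
S_w and S_t are singular). OLDA instead maximizes the pseudo-inverse
criterion

    G* = argmax_G trace( (Gᵀ S_t G)⁺ · Gᵀ S_b G )

and orthonormalizes the solution. The solver uses reduced factorizations
only: an economy SVD of the centered data gives the nonzero eigenspace of
S_t; the class-mean factor H_b (columns √n_c(μ_c − μ)) is whitened in that
space; the SVD of the whitened factor yields discriminant directions with
per-direction criterion contributions (its squared singular values);
QR-orthonormalization then produces G with GᵀG = I spanning the same
subspace — the criterion is invariant to that basis change. No d × d
matrix is ever formed. Numerical rank uses the standard threshold
`max(n, d)·eps·σ_max`. Column signs are fixed (largest-magnitude entry
positive) so score plots are reproducible. When S_w is nonsingular the
subspace provably coincides with classical LDA's, and the tests verify
this against an independent generalized-eigenvalue solve to principal
angles < 1e−6.

A consequence worth knowing: in the small-sample regime the training
classes are fully separable inside the span of the data, so each retained
component contributes criterion value ≈ 1 and the component shares come
out ≈ 1/q each (20 % per component at q = 5). Equal shares are thus a
structural property of the pseudo-inverse criterion here, not evidence
that the components are equally informative about test data.

## Fuzzy clustering

All three algorithms share the partition contract (memberships in [0, 1],
every sample's memberships summing to 1), the stopping rule (maximum
absolute center change below `tol`, default 1e−5, checked after each full
sweep; membership-change criterion available by flag) and the iteration
semantics: one iteration is one full update sweep, so a run initialized at
a fixed point reports `n_iter = 1`. Defaults follow the study protocol:
c = 6, fuzzifier m = 2, KHM power p = 2, at most 100 sweeps.

* **FCM** alternates u_ik = [Σ_j (d²_ik/d²_jk)^{1/(m−1)}]⁻¹ with
  v_i = Σ_k u_ik^m x_k / Σ_k u_ik^m, minimizing J = Σ u^m d²; the recorded
  objective is non-increasing (tested with 1e−10 slack).
* **KHM** uses memberships ∝ d^{−p−2} and per-sample boosting weights
  w(x) = Σ_l d_l^{−p−2} / (Σ_l d_l^{−p})², which up-weight samples no
  center covers well; this is why KHM is insensitive to initialization,
  and the tests require ≥ 90 % of random starts to reach within 1 % of the
  best objective on separable data.
* **GK** replaces the Euclidean norm with per-cluster Mahalanobis norms
  A_i = (ρ_i det F_i)^{1/q} F_i⁻¹ from fuzzy covariances
  F_i = Σ u^m (x−v)(x−v)ᵀ / Σ u^m under a fixed-volume constraint
  (ρ_i = 1), capturing ellipsoidal clusters.

Numerical choices. Squared distances are floored at 1e−12; a sample
coinciding with one or more centers gets uniform membership over the
coincident centers and zero elsewhere (this also makes duplicate centers
safe). Membership ratios are computed against the per-column minimum
distance so large exponents (e.g. KHM at p = 50) cannot overflow. Raw GK
covariances on near-collinear score clouds can be ill-conditioned, so F_i
is blended toward a determinant-scaled identity by γ (default 1e−6) and
eigenvalue-floored to condition number ≤ 1e10; setting γ = 1 forces the
norms to identity exactly, in which case GK provably coincides with FCM —
a limit the tests assert sweep-by-sweep. A cluster whose membership mass
vanishes raises a collapse error naming the cluster. Argmax ties in hard
assignment go to the lowest cluster index.

## Protocol and evaluation

The pipeline stratifies a seeded 2:1 train/test split (45/22 per class for
67-sample classes — infeasible ratios are rejected per class), fits MSC
and OLDA on the training half, projects the test half to q = k − 1 = 5
scores, and clusters the test scores. Initialization is chained: FCM
starts from the first test sample of each class in class order, runs to
convergence, and its centers seed KHM and GK — with crisp, well-separated
score clusters both seeded algorithms then terminate after a single sweep,
the signature the report's iteration column makes visible. Clusters are
mapped to days either by fixed order (valid because of the one-seed-per-
class initialization) or by minimum-misclassification Hungarian
assignment; accuracy, misclassification count and the confusion matrix are
mutually consistent by construction and checked as such.

## Known limitations

* The generator's class structure is amplitude-only and isotropic in
  score space; GK's adaptive norms therefore buy nothing here and GK
  tracks FCM, whereas on real spectra GK can behave very differently
  (including failing to converge within 100 sweeps). The GK-specific
  geometry tests use separately constructed anisotropic data instead.
* Reported accuracies on synthetic presets characterize the pipeline
  under the generator's assumptions only; they are not estimates of
  performance on laboratory spectra.
* Problem sizes in tests and drivers (402 × 1557 spectra, 132-sample
  evaluation) match the study design and keep every stage well under a
  minute on one CPU.
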