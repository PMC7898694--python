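# Methods

This note records the model implemented by `fibert1`, the defaults and
why they were chosen, what the synthetic phantoms do and do not
emulate, and the numerical decisions made where the design was open.

## Signal model and units

A voxel is a discrete weighted set of axisymmetric diffusion tensors
paired with longitudinal relaxation rates,
P(**D**, R₁) = {(D∥, D⊥, θ, φ, R₁, w)_n}. The forward signal for a
measurement with b-tensor (b, b_Δ, Θ, Φ), repetition time τ_R and echo
time τ_E is

    S_m = Σ_n w_n · exp(−b·D_iso,n·(1 + 2·b_Δ·D_Δ,n·P₂(cos β_mn)))
              · (1 − 2·exp((τ_E/2 − τ_R)·R₁,n) + exp(−τ_R·R₁,n))

with β the angle between the encoding and tensor symmetry axes,
D_iso = (D∥+2D⊥)/3 and D_Δ = (D∥−D⊥)/(D∥+2D⊥) ∈ [−0.5, 1]. The
closed-form contraction is algebraically identical to the elementwise
Frobenius product of the full 3×3 tensors; tests verify agreement to
1e−12 relative. The relaxation factor describes saturation recovery
with a spoiled spin echo; no inversion preparation is modelled.

Units are fixed package-wide: diffusivities μm²/ms, b in ms/μm² (so
b:D is dimensionless), times in seconds, R₁ in s⁻¹. Fiber orientations
are axes, not vectors: antipodal directions are identified everywhere,
and the stored representative has cos θ ≥ 0.

## Monte Carlo inversion

Per voxel the algorithm iterates non-negative least squares
(`scipy.optimize.nnls`) over randomly sampled candidate components:

1. **Initialization** — `n_initial = 200` candidates drawn with D∥,
   D⊥ log-uniform on [5×10⁻³, 5] μm²/ms, R₁ log-uniform on
   [0.1, 2] s⁻¹, cos θ uniform on [0, 1), φ uniform on [0, 2π).
   Log-uniform sampling of the scale parameters spans their decades
   evenly, the standard choice for inverse-Laplace spectra.
2. **Proliferation** — `n_proliferation = 30` rounds; each adds
   max(200 − survivors, 50) fresh random candidates and refits.
   Adding columns can only lower the optimal NNLS residual.
3. **Mutation/extinction** — `n_mutation = 30` rounds; each appends a
   perturbed copy of every survivor (D∥, D⊥, R₁ multiplied by
   exp(ε), ε ~ N(0, 0.2²), orientation tilted by up to 10°, clipped to
   the sampling ranges) and refits, so offspring compete directly with
   their parents; components driven to zero weight go extinct. An
   earlier variant that perturbed the whole surviving set jointly and
   accepted it only when the residual did not increase converged far
   more slowly (noise-free single-fiber errors of 5–11% versus ~1%
   with competition), so the competitive form is used. Either way the
   residual is non-increasing across rounds, here by construction.
4. **Output** — the `n_output = 50` heaviest components are refitted
   once; Σw estimates S₀.

Ill-conditioning is embraced rather than regularized: the inversion is
repeated on `n_bootstrap = 96` with-replacement resamplings of the
measurement rows (signal and kernel rows jointly), and all downstream
quantities are medians across these bootstrap solutions. Bootstrap
solutions are never merged into one component set — component
correspondence across bootstraps is undefined — only their statistics
are aggregated.

Every bootstrap has its own RNG spawned from the voxel seed, and voxel
seeds derive from the master seed plus the voxel index, so results are
bit-identical for any worker count and any execution order.

## Descriptors and bins

Per bootstrap, weight-normalized means E[χ], variances V[χ] and
covariances C[χ, χ′] are computed for χ ∈ {D_iso, D_Δ², R₁}
(central moments with weights normalized to one), then medians are
taken across bootstraps. Components can first be restricted to closed
rectangular bins of (D_iso, D∥/D⊥, R₁):

| bin  | D_iso (μm²/ms) | D∥/D⊥        | R₁ (s⁻¹)   | targets |
|------|----------------|--------------|------------|---------|
| thin | [0.1, 2]       | [4, 1000]    | [0.01, 10] | white matter |
| thick| [0.1, 2]       | [0.01, 4]    | [0.01, 10] | gray matter |
| big  | [2, 10]        | [0.01, 1000] | [0.01, 10] | CSF |

All interval bounds are closed, so a component on a shared boundary
(ratio exactly 4) belongs to both thin and thick; this avoids silent
gaps and keeps thin ∪ thick tiling the ratio axis. Bin fractions are
weight fractions Σw_bin/Σw (map intensity should scale with signal
contribution, not component count) and are averaged, not medianed,
across bootstraps, so an occasionally-empty bin renders dim rather
than invisible. Segmentation maps use RGB =
[f_thin, f_thick, f_big]/max; orientation maps use the weighted mean
tensor diagonal [E[D_xx], E[D_yy], E[D_zz]]/max scaled by f_bin.

## ODFs

Thin-bin components of each bootstrap are smeared onto the nodes of a
geodesic icosphere (default 4 subdivisions, 2562 nodes, ~4° node
spacing) with the antipodally symmetric Watson kernel
exp(κ·((u·n)² − 1)), normalized over nodes so each bootstrap deposits
exactly its thin-bin weight. The default κ ≈ 63.5 gives a kernel FWHM
of 12°, comparable to the mesh spacing — one smoothness knob,
adjustable per call. Node radii and the per-node kernel-weighted means
Ê[χ] are medians across bootstraps. Peaks are adjacency-graph local
maxima, antipodally deduplicated and merged within 15° (symmetric
lobes otherwise produce plateau-tie duplicates), ignoring nodes below
5% of the maximum radius.

## Density-peak clustering (MC-DPC)

Thin-bin orientations of each bootstrap are clustered on the
projective sphere with the metric arccos|u·v|. Local density ρ_i is
the total weight within the cutoff d_c (default 20°; cluster count on
the two-orthogonal-bundle phantom is stable for d_c anywhere in
10–40°); δ_i is the distance to the nearest denser point. Centers are
the points above the largest gap in the sorted ρ·δ sequence — a
parameter-free knee rule — and every point joins its nearest denser
neighbor's cluster. Per-bootstrap clusters are matched greedily to
consensus orientations (seeded by the first non-empty bootstrap,
within d_c); clusters appearing in fewer than half the bootstraps are
discarded as spurious. Cluster orientation is the weighted geometric
median computed by Weiszfeld iterations on sign-aligned vectors
(tolerance 1e−8, at most 1000 iterations, initialized from the
dominant scatter eigenvector). Cluster weights are bootstrap medians
normalized to sum to one across retained clusters.

E°[T₁] is the weighted mean of 1/R₁, computed independently of
E°[R₁]; the two are not reciprocal unless the within-cluster R₁
variance vanishes. Bundle labels assign each cluster to the nearest
laboratory axis (precedence x > y > z on exact ties). Group
comparisons use two-sided Mann–Whitney U tests: the exact null
distribution when the pooled sample is ≤ 20 without ties, the
tie-corrected normal approximation otherwise. Stars follow
0.05 ≤ p < 0.1 (\*), 0.01 ≤ p < 0.05 (\*\*), p < 0.01 (\*\*\*); the
thresholds are half-open, so p = 0.1 earns no star.

## Synthetic phantoms and what they show

The default acquisition scheme has 363 points: per repetition time
(τ_R = 1, 2, 5 s; τ_E = 120 ms) one b = 0 reference, spherical
encoding at b = 0.1, 0.5, 1, 2 ms/μm², and linear and planar shells at
b = 0.5, 1, 2 ms/μm² with 12/21/25 electrostatically repulsed
directions — 121 points per τ_R block. The exact per-shell composition
of such protocols varies between sites; the totals, shapes, b-range
and τ_R values here define this package's reference condition, and
any measured scheme can be loaded from a plain-text table (including
full 3×3 b-tensors, eigendecomposed with an axisymmetry tolerance).

Phantom voxels combine stick-like fibers (D∥ = 2, D⊥ = 0.2 μm²/ms,
typical white matter) at a prescribed crossing angle with distinct R₁
values, plus optional isotropic pools (gray-matter-like: D_iso = 0.8
μm²/ms, R₁ = 0.6 s⁻¹; CSF-like: D_iso = 3 μm²/ms, R₁ = 0.25 s⁻¹),
giving the expected R₁ ordering WM > GM > CSF. Noise is Rician,
√((S+ε₁)² + ε₂²) with ε ~ N(0, σ²), where σ is set from the SNR of
the spherically encoded signal at b = 0.1 ms/μm² and the longest τ_R
(falling back to S₀/SNR with a warning when the scheme lacks such a
point); SNR = 40 is the reference noisy condition.

Phantoms emulate partial voluming, crossing geometry, relaxation
contrast and magnitude noise. They do **not** emulate imaging
artifacts (eddy currents, motion, B₁ inhomogeneity, magnetization
transfer, slice-profile effects), dispersion of fiber orientations
within a bundle, exchange between compartments, or time-dependent
diffusion — so passing tests demonstrate correctness of the inversion
and clustering machinery under the stated forward model, not accuracy
on scanner data subject to those effects.

## Validation sizes and observed behavior

The test suite and `scripts/acceptance.py` use: noise-free
single-fiber and 90°-crossing inversions at the full default settings;
the SNR = 40 crossing condition with 96 bootstraps over 8 independent
noise realizations (the suite uses 5); tissue-ordering checks with 12
bootstraps per archetype voxel. These sizes are this package's
validation conditions; all run on one core in minutes. Under the
SNR = 40 condition the pipeline consistently recovers both crossing
clusters within ~3° with the correct R₁ ordering, while E°[T₁] is
overestimated by roughly 15–20% (median across clusters) — a known
consequence of repeating the same diffusion block at every τ_R, which
limits diffusion-relaxation correlation in the kernel; the bias is
reported by the acceptance script rather than corrected.

## Known limitations

- Axisymmetric tensors only; no non-axisymmetric D, no restriction or
  exchange.
- Manual thin/thick/big binning; components outside all bins
  contribute only to global statistics.
- The quasi-genetic search is stochastic: component-level solutions
  differ between seeds even noise-free; only ensemble statistics are
  stable.
- Greedy cross-bootstrap cluster matching can mislabel clusters when
  two true populations lie within d_c of each other; reduce d_c for
  tighter crossings (resolution is ultimately limited by the angular
  kernel and noise).
- ODF rendering is left to the user; exports are plain arrays plus
  mesh topology.
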