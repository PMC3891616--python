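# Methods

## Models

All four clusterers alternate a closed-form membership (or typicality)
update with a weighted-mean prototype update until the prototypes stop
moving. For data X ∈ ℝ^{N×q}, prototypes V ∈ ℝ^{K×q} and squared
distances d²_ij = (xᵢ−vⱼ)ᵀA(xᵢ−vⱼ):

**FCM** minimizes Σᵢⱼ u_ij^m d²_ij over row-stochastic U. Updates:
u_ij = (Σ_s (d²_ij/d²_is)^{1/(m−1)})^{−1} and
vⱼ = Σᵢ u_ij^m xᵢ / Σᵢ u_ij^m. The membership update runs first each
sweep, so the first iterate depends only on the initial prototypes.

**PCM** minimizes Σᵢⱼ t_ij^m d²_ij + Σⱼ ηⱼ Σᵢ (1−t_ij)^m over
unconstrained T ∈ (0,1]^{N×K}. Updates: t_ij = (1+d²_ij/ηⱼ)^{−1/(m−1)}
and the same weighted-mean prototype rule. Columns are decoupled, so
prototypes can collapse; a `CoincidentClustersWarning` is emitted
whenever two terminal prototypes lie within `tol`. A standalone PCM run
is seeded by an internal FCM run (memberships and centers), the
standard remedy for its initialization sensitivity.

**PFCM** carries both matrices in one objective,
Σᵢⱼ (a·u_ij^m + b·t_ij^η) d²_ij + Σⱼ γⱼ Σᵢ (1−t_ij)^η, with
t_ij = 1/(1+((b/γⱼ)d²_ij)^{1/(η−1)}); its fuzzy update is identical to
FCM's and its prototypes are (a·u^m + b·t^η)-weighted means. With b → 0
it reduces to FCM (verified to 1e-4 at b = 1e-8).

**Hybrid (HPFCM)**: stage 1 runs FCM to convergence; stage 2 estimates
the per-cluster scales from the terminal fuzzy partition and freezes
them; stage 3 iterates the PCM updates starting from the FCM
memberships and centers. The result carries the stage-1 fuzzy matrix,
the terminal typicality matrix and prototypes, and both stages'
diagnostics.

## Scale calibration

The possibilistic updates need a per-cluster squared-distance scale
(ηⱼ, or γⱼ in PFCM) fixing where typicality crosses ½. Two estimators
are provided, both computed once from a terminal FCM partition and
frozen:

* `weighted_mean` — ηⱼ = Σᵢ u_ij^m d²_ij / Σᵢ u_ij^m, the classical
  choice; default for standalone PCM and for PFCM's γⱼ.
* `core_median` — the median d²_ij over the cluster's fuzzy core
  (u_ij > 0.5 + 1e−3; the guard keeps points ambivalent between two
  clusters, up to FCM's convergence error, out of every core); default
  for the hybrid's stage 2. Falls back to the weighted mean for a
  cluster with an empty core.

The distinction matters under contamination, which is the regime the
possibilistic stage exists for. A gross outlier holds membership ≈ 1/K
in every cluster while sitting at huge d², so the weighted mean can be
inflated an order of magnitude above the within-cluster scatter; the
possibilistic stage then leaks mass across clusters and contracts the
prototypes — on the 12-point benchmark this inflated scale (η ≈ 7.9)
is precisely what produces the degraded PCM solution (±2.15 instead of
±3.14). The core median is insensitive to a minority of outliers and on
the same benchmark gives η ≈ 2.03, matching the scale (η = 2) under
which the hybrid is known to recover the ideal centroids. Both
estimators, a scalar `fixed_scale`, and a `scale_multiplier` are
exposed on every possibilistic runner and in the CLI.

## Parameters

| parameter | meaning | default |
|---|---|---|
| m | fuzzifier exponent (>1); softness of memberships | 2 |
| η | typicality exponent in PFCM (>1) | 2 |
| a, b | PFCM weights of the fuzzy / possibilistic terms | 1, 1 |
| tol | max-abs prototype change declaring convergence | 1e-5 |
| max_iter | cap on alternating sweeps | 300 |
| n_init | seeded random restarts, best final objective kept | 1 |
| norm matrix A | symmetric positive-definite distance metric | identity |

Distances are squared Euclidean by default; an arbitrary positive-
definite A is supported (validated by Cholesky) but per-cluster or
adaptive metrics are out of scope.

## Numerical choices

* Initialization samples K rows uniformly without replacement from the
  *unique* rows of X (falling back to raw rows when fewer than K
  distinct patterns exist). Coincident prototypes are a fixed point of
  every update scheme here, so on quantized inputs (e.g. noise-free
  phantom intensities) raw-row sampling would silently waste clusters.
* A point coincident with a prototype (d² < 1e−12) takes crisp
  membership in the coincident cluster of lowest index — the
  continuity limit of the update, which requires positive distances.
* The membership update normalizes distances by the row minimum before
  the negative power, so extreme fuzzifiers underflow gracefully
  instead of overflowing.
* Objective traces are recorded after every sweep and are
  non-increasing by construction (each half-update is the exact
  minimizer of its subproblem; the possibilistic trace assumes frozen
  scales); tests allow 1e−8 slack for round-off.
* Hard labels take the argmax of the typicality matrix when present,
  else of the fuzzy matrix; ties resolve to the lowest cluster index.
* Cluster-to-class matching solves the optimal assignment problem on
  the contingency table (scipy's Hungarian solver) with an index-based
  perturbation far below one count, making ties deterministic.
* The prototype error against ideal centroids is the squared Frobenius
  norm minimized over row permutations (also solved as an assignment),
  so it is invariant to cluster numbering.

## Synthetic data

`make_blobs` draws isotropic Gaussian clusters (default spread 0.5 at
centers ±3 in 2-D) plus uniform "gross" outliers from a box (default
±20 per axis — an order of magnitude beyond the cluster region, so
that contamination is unambiguous rather than marginal). `make_phantom`
builds a nested-disc 2-D image — background plus concentric rings
standing in for CSF/GM/WM — with per-region intensities (default 0.05,
0.35, 0.65, 0.95) and additive Gaussian noise whose σ is a stated
percentage of the intensity range, the percent convention of simulated
brain-MRI noise sweeps. Default ring radii give the interior regions
equal pixel counts, mirroring the comparable areas of gray and white
matter in a real slice; evenly spaced radii would shrink the innermost
tissue to a few percent of the pixels. Both generators are pure
functions of their arguments including the seed.

What the phantoms do **not** emulate: partial-volume mixing at tissue
boundaries, bias fields, Rician noise statistics, or scanner
artifacts. Consequently the phantom benchmarks show that the full
segmentation pipeline (image → features → clustering → label map →
per-tissue scores) is correct and stable under noise, but they cannot
reproduce the large FCM-vs-possibilistic accuracy gaps seen on real
MRI: with equal-variance Gaussian class noise and no outliers, the
FCM decision boundary (the midpoint between prototypes) is already
essentially optimal, and all four algorithms agree to within a few
10⁻⁴ in per-tissue accuracy. The algorithms' distinctive behavior is
instead exercised where it has signal — under gross outliers (blob
benchmarks) and on the 12-point benchmark.

Benchmark problem sizes: phantoms are 64×64 pixels over noise levels
0–9% with five seeds per level; blob experiments use 100 points per
cluster with 5% outliers. These sizes give sampling error well below
every tolerance asserted.

## Known limitations

* Scales are estimated once and frozen; re-estimation schedules inside
  the possibilistic loop (PCM-II style) are not implemented.
* The hybrid's two stages share one (m, tol, max_iter) set.
* Per-voxel features default to intensity only; multi-channel data is
  supported as multi-column input but no spatial regularization is
  applied.
* The Huang accuracy leaves surplus clusters (K ≠ number of classes)
  unmatched; objects in unmatched clusters count as errors.
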