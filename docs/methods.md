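# Methods

`myotract` reconstructs muscle fiber architecture from diffusion-weighted
MRI and quantifies the resulting tract geometry. This note records the
models the package implements, the parameters that matter, what the
synthetic phantoms do and do not emulate, and the numerical and design
choices made where the problem left them open.

## Coordinate contract

All geometry is computed in world RAS millimetres. Voxel indices are
0-based; a voxel's world position is the centre of its cell
(`affine @ (i, j, k, 1)`). Streamline files store world-mm points (TCK
natively; TRK converted by nibabel on read/write). Gradient tables are
FSL-style `.bval`/`.bvec` text; both the 3×N and N×3 layouts are accepted.
Entries with `b ≤ 50 s/mm²` count as baselines — tolerant of vendor jitter
and unambiguous at the b = 400 s/mm² working point of muscle DTI.

## Diffusion signal model and tensor fit

The per-voxel signal model throughout is a stick mixture:

    S(g) = S0 · [ c_iso · exp(−b·d_iso) + Σ_f v_f · exp(−b·d_stick·(g·n_f)²) ]

with unit fiber directions `n_f`, stick volume fractions `v_f`, and an
isotropic compartment filling the remaining volume (`c_iso = 1 − Σ v_f`).
Default diffusivities are physiologic for muscle tissue and free fluid:
`d_stick = 1.5e−3 mm²/s`, `d_iso = 2.0e−3 mm²/s`, and a 10% isotropic
fraction inside fully fiber-occupied voxels.

Tensor estimation is ordinary log-linear least squares of
`log S(g) = log S0 − b·gᵀDg` per masked voxel — deterministic and exact on
noise-free single-tensor data (the test suite asserts recovery to 1e−10
relative). Weighted or nonlinear fits would gain little at the SNR ≥ 20
regime targeted here and would cost determinism in edge cases. Negative
eigenvalues are clamped to zero and the voxel flagged (`clamped_mask`)
rather than refit: simple and auditable. FA uses the standard
`sqrt(3/2)·‖λ − λ̄‖/‖λ‖` with FA = 0 for all-zero eigenvalues.

Direction-encoded color maps default to R ← |x| (right-left),
G ← |y| (antero-posterior), B ← |z| (cranio-caudal); the red/green
assignment is configurable (`convention="ap-red"`) because both
conventions circulate in the muscle-imaging literature.

SNR is measured as the b0 tissue-ROI mean over the noise std from a
background ROI. The background of a magnitude image is Rayleigh
distributed, so the raw std understates the per-channel Gaussian σ by
`sqrt(2 − π/2) ≈ 0.655`; the default estimate corrects for this so that a
phantom generated at target SNR 30 measures 30. `correction="none"` gives
the literal ratio.

## Synthetic phantoms

The generator stands in for in-vivo scans, which cannot be redistributed.
It emulates the acquisition's essentials: 1 baseline + 32 non-collinear
directions (electrostatically spread, deterministic) at b = 400 s/mm²,
coarse voxels, Rician magnitude noise at a target b0 SNR (per-channel σ =
S0/SNR, two independent Gaussian channels, one global σ), and tubular
bundles with sub-voxel partial volume (3× per-axis supersampling of each
voxel against the tube geometry — analytic tube–voxel overlap would be
unnecessary precision).

Default grid: 32×32×12 voxels at 1.5 mm isotropic (48×48×18 mm). This is
finer than the scan's 3-mm slices so that multi-bundle geometry is
resolvable at desk scale; acquisition-like geometry can be configured. A
two-voxel border in x/y carries no signal ("air") and serves as the SNR
background region.

Geometries:

- `straight` — one tube along +x; the calibration case.
- `arc` — one curved tube (circular arc).
- `crossing` — two straight tubes through the centre at a configurable
  angle (default 90°).
- `purse_string` — two mirrored arcs (radius 40 mm, lateral span ±19 mm)
  that pass the midline offset by ±2.5 mm and cross each other at two
  para-midline points at ≈40°, enclosing a central "perineal-body" lens.
  Every truth fiber starts on one lateral side and ends on the other. The
  two bundles are related by a 180° rotation about the vertical axis, so
  their oriented heading distributions mirror about 90° on every world
  axis.

Ground truth is first-class: labelled truth tracts (parallel offset copies
of each centerline, offsets uniform over the tube cross-section) and a
per-voxel map of stick orientations and volume fractions, used by the
recovery scores in `myotract.scoring`.

What the phantoms do **not** emulate: eddy currents, susceptibility
distortion, coil sensitivity profiles, T2 decay, physiological motion,
fiber undulation or dispersion within a bundle, and realistic anatomy
outside the bundles (the background is homogeneous isotropic tissue).
Passing tests therefore demonstrate correctness of the algorithms under
the stated signal model and noise, not robustness to every artifact of
real muscle DTI.

## FACT tracking

Deterministic streamline propagation along the per-voxel principal
eigenvector: the direction is re-sampled at each voxel entry (nearest
voxel, no interpolation — the defining FACT behaviour) and sign-aligned
with the incoming direction; both half-tracks from each seed are
concatenated. Termination on FA below threshold, turning angle above
threshold, grid exit, or a step cap. Defaults: FA threshold 0.10 and
angle threshold 60° (midpoints of the 0.08–0.15 and 50–70° ranges
appropriate for low-FA muscle), step = half the smallest voxel dimension,
one centred seed per voxel (more are jittered reproducibly). The length
floor removing fiber fragments is 40 mm at acquisition scale; for desk
phantoms the pipeline scales it to 0.25× the grid diagonal (17.6 mm at
default size).

## Global tractography

The core of the package: a Gibbs point process of oriented line segments
("particles") optimized by simulated annealing.

**State.** Each particle has a position, an axis (antipodal unit vector),
fixed half-length, and two endpoints that can bind pairwise into chains.
Defaults follow the muscle-reconstruction parameter set: segment length
1.172 mm, width 0.3 mm, signal weight 0.096, density penalty 0.2,
temperatures 0.1 → 0.001. The desk default of 2×10⁵ iterations suits
phantom grids; the full-scale budget (5×10⁸) remains a configuration
choice.

**External (data) energy.** Each particle contributes a stick template
`weight · exp(−b·d_stick·(g·n)²)` to the voxels its axis traverses,
apportioned by traversed length (5-point quadrature along the axis; the
0.3 mm width motivates treating the segment as a line at ≥1.5 mm voxels).
Both the predicted and the observed normalized signal are mean-subtracted
across gradient directions, so the isotropic baseline cancels and only the
anisotropic shape is fit:

    E_ext = λ · Σ_v Σ_g ( S̃_pred(v,g) − S̃_obs(v,g) )²

λ (`external_scale`) calibrates energy units to the temperature range:
λ = 0.4/weight² puts typical per-particle energies between the start and
end temperatures — fluid at T = 0.1, locked by T = 0.001. (With λ =
1/weight² the configuration froze several degrees of orientation
dispersion in place; the calibration is a property of the energy/
temperature pairing, not a data-dependent tuning.)

**Internal (prior) energy.** Free endpoints cost `+density_penalty` each.
A bound endpoint pair costs

    +c_s · (1 − exp(−gap²/σ_gap² − bend²/σ_bend²))

where `gap` is the endpoint separation (mm) and `bend` the angle between
the *chain-directed* outgoing vectors (radians): a perfect head-to-tail,
collinear join costs nothing, a strained one up to `c_s`. Two structural
points here were reached by analysis of failure modes and are deliberate:

- The mismatch-cost form (rather than a pure bonus `−c_s·exp(...)`)
  prevents a runaway subsidy in which every bind is worth a fixed energy
  gain regardless of geometry; with a pure bonus, chain growth pays for
  particles beyond the data-matched count and the surplus disperses
  orientations.
- The bend is measured between chain-directed endpoint vectors, not
  antipodal axes. Otherwise two parallel side-by-side segments can bind
  head-to-head at "zero bend", which is a 180° fold of the chain; that
  single definition error produced metre-long folded chains inside a
  50 mm phantom.

Defaults: `c_s = 0.45` (a geometry-blind bind, worth 2×0.2 in endpoint
savings, is then unfavorable), `σ_gap = 2 × segment length` (joins must
tolerate the sub-voxel strand spacing irregularity that the voxel-level
data term cannot see), `σ_bend = 0.45 rad` (≈26°: tolerates
orientation-noise joins, forbids 90° turns), connect radius 3.5 × segment
length.

**Moves and sampling.** Metropolis–Hastings over birth/death (reversible
jump against a unit-rate Poisson reference on the masked volume ×
orientation space; death targets unbound particles), Gaussian shift and
rotate (widths shrink with √(T/T_start) as the schedule cools), and
connect/disconnect. Connect draws a free endpoint uniformly and its
partner from the Boltzmann weights of the candidate pair energies;
forward and reverse proposal probabilities enter the acceptance ratio
exactly, including the two-sided path to the same pair. On an enumerable
toy model (one voxel, six discrete orientations, ≤3 particles) the
fixed-temperature chain reproduces the exactly enumerated Boltzmann
distribution within multinomial error — the statistical-correctness
anchor of the module.

**Annealing schedule.** One exponential temperature schedule, split into
an orientation-refinement phase with connection moves disabled (default
first 75% of iterations; rotate-heavy move mix) and a chain-assembly
phase (connect/disconnect-heavy). With binding active from the start,
bonds — worth far more than the final temperature — froze early-stage
orientation disorder into chains that no local move could repair (bound
particles cannot die); annealing the orientation field first removed
roughly half of the final orientation error at the same iteration budget.
Initial configurations place `init_density` particles per masked voxel
(default 5) with orientations seeded from the local tensor principal
eigenvector plus 0.1 rad jitter; `init_mode="random"` is available and
converges to the same straight-phantom error given ~5× the iterations.

**Streamline extraction.** Chains are read out as polylines through
endpoint midpoints; cycles break at their largest-bend link. An optional
deterministic fiber-building pass (`stitch_radius`, used by the pipeline
at 4 × segment length) merges chain ends whose continuation directions
agree within 0.7 rad and whose partner lies geometrically ahead, nearest
gaps first. This bridges sub-voxel strand holes — the data term is
voxel-grained and cannot reward sub-voxel continuity — while the bend gate
prevents joins across crossing bundles.

## Tract geometry

Each tract is parametrized per world axis as a truncated cosine series
`x(t) = Σ c_k cos(πkt)` on t ∈ [0,1] (default order 9). The even
extension makes the basis complete for open curves. The parameter is
normalized cumulative arc length by default (sampling-density independent;
`parameter="uniform"` reproduces curves given in their own uniform
parameter exactly), and the least-squares fit carries trapezoid quadrature
weights so it approximates the continuous L² projection — coefficients
then move by <1e−3 mm under 2× polyline resampling. Heading angles are
`arccos(t̂·axis)` of the oriented tangent in [0,180]°; curvature is
`|x′×x″|/|x′|³` from analytic derivatives. Profile samples sit at interval
midpoints because every cosine series is exactly stationary at t = 0 and
1, where the curvature quotient is meaningless.

Plane slicing reports one record per strict sign change of the signed
plane distance along the polyline, with linear interpolation of the
crossing point; vertices landing exactly on the plane count as crossings
only if the polyline continues to the opposite side.

For population statistics each tract is first canonically oriented: the
traversal direction is chosen so that (mean tangent) × (mean curvature
normal) points along +z, with the antipodal sign rule as fallback for
near-straight tracts. The gross tangent and curvature come from a smooth
order-3 cosine fit (raw second differences of reconstructed polylines are
noise-dominated), and the curvature direction averages only the component
normal to the tangent (the tangential part of x″ integrates to ~0 over a
cosine series). Under this convention mirrored bundle pairs traverse in
opposite directions and their pooled heading distribution is symmetric
about 90° on every axis. `heading_symmetry` reports |mean − 90| per axis;
given two bundle labels (e.g. from clustering, as in the left/right
transverse-perinea analysis) it reports the deviation of the two bundle
means' midpoint, which is insensitive to imbalance in recovered tract
counts. Histograms default to 10° bins over [0, 180].

## Bundle clustering

Tracts are resampled to 20 equidistant points; the pairwise distance is
the symmetrized mean-closest-point distance (the standard of the tract-
clustering literature). Affinity is `exp(−d²/σ²)` with σ defaulting to the
median off-diagonal distance (scale-free). Eigenvectors 2 and 3 of the
symmetrically normalized affinity, rescaled back to the random-walk
eigenvectors and sign-fixed (largest-magnitude entry positive), embed each
tract in 2-D; k-means (k = 2 for the left/right bundle use case,
seed-deterministic) cuts the embedding. The all-identical-tract corner
case (constant affinity; fully degenerate spectrum) maps every tract to
one point by convention. Purity against truth labels is the fraction of
tracts whose cluster majority matches their own label.

## Pipeline

`run_pipeline` chains phantom generation (or input loading) → tensor fit →
FACT → global tracking → geometry quantification → clustering → truth
scoring, writing every intermediate in a standard format (NIfTI, TCK, CSV,
JSON) plus a `report.json` validated against a shipped schema of required
keys. Configuration is one TOML file mirroring the CLI flags; TOML was
chosen over YAML for its stdlib parser and unambiguous numbers. A single
global seed derives every stage's RNG. Stage failures are recorded in the
report and halt downstream stages.

## Problem sizes used in validation

The validation suite and the acceptance script run, at default phantom
size: the 10⁶-step fixed-temperature Boltzmann comparison; straight-bundle
recovery at 2×10⁵ annealing iterations (infinite SNR); crossing and
purse-string reconstructions at 4×10⁵ iterations (SNR 30, and SNR ∞/15
for clustering); and ≥10⁴ accepted moves for the incremental-energy
integrity check. These sizes give stable statistics on one CPU core in a
few minutes per reconstruction.

## Known limitations

- The energy functional is this package's own concrete design; published
  global trackers share its structure (stick data term, chain prior,
  birth/death annealing) but differ in detail, so parameter values are not
  interchangeable with other software.
- The data term is voxel-grained; sub-voxel strand continuity is governed
  entirely by the connection prior and the extraction stitching pass.
- At muscle-like SNR (30) the per-segment orientation error floor is
  ~10–12°, an information limit of 33 directions at b = 400 rather than a
  sampler deficiency (the infinite-SNR floor at the same budget is ~4–5°).
- Tensor-informed initialization accelerates convergence but inherits the
  tensor's ambiguity in crossing voxels; those regions rely on the
  annealing to reorganize, which is why crossing reconstructions use a
  larger iteration budget.
- FACT's seeding density and step size are configuration, not estimated;
  comparisons against it hold under its stated defaults.
- k-means with k fixed by the user is the final clustering step;
  model-order selection is out of scope.
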