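# Methods

## Model

`walkfuse` fuses J candidate binary segmentations `L^j` of one target
intensity volume `I` into a final segmentation. The candidates are
assumed to be registered onto the target grid already; fusion never
resamples. The method has four stages.

**Vote map and partition.** The weighted vote fraction
`v(x) = Σ_j w^j L^j(x) / Σ_j w^j` is read as the probability that voxel
`x` carries the structure label. Two class-specific confidence thresholds
split the grid: `x` is confident structure when `v(x) > LT1`, confident
background when `1 − v(x) > LT0`, and low-confidence (`S_L`) otherwise.
The comparisons are strict, with one deliberate exception: a voxel at an
exact vote tie (`v = 0.5`) is assigned to the high-confidence class named
by the vote tie policy *only when the corresponding threshold is exactly
0.5*. Without this rule, the degenerate setting `LT0 = LT1 = 0.5` — which
must reproduce plain majority vote verbatim, with an empty `S_L` — would
leak tie voxels into `S_L` whenever J is even. At any threshold above 0.5
tie voxels are low-confidence, as they should be.

**Patches.** `S_L` voxels are ranked by the count of high-confidence
voxels among their 26-connected neighbors (descending, ties broken by
lexicographic voxel index); a voxel is seed-eligible when that count
reaches `ceil(mixing_ratio · L_patch³)`. The pass over the ranked list is
static: a candidate that is already inside an earlier patch is skipped,
which prevents stacks of near-duplicate cubes. Cubes of side `L_patch`
are clipped at the grid border. Where cubes overlap, a contested `S_L`
voxel belongs to the nearest seed in Euclidean voxel distance, the
earlier seed keeping ties, so patch memberships are disjoint by
construction; `S_L` voxels in no cube are reported as unreachable and
keep the majority-vote label. The emitted coverage fraction
(`|S_L in patches| / |S_L|`) lets users detect the under-coverage regime
of too-small patches or too-demanding mixing ratios, where refinement
quality degrades simply because little of `S_L` is ever visited.

**Patch MRF.** Each patch hosts a binary MRF over its owned `S_L` voxels
plus the high-confidence voxels inside its cube, whose labels are fixed
boundary data. Cliques are singletons and 6-adjacent pairs within that
node set; pairs crossing the patch boundary are not modeled, which is
what makes the per-patch problems independent and the merge
order-invariant. The singleton potential is the Gaussian negative
log-likelihood `½ log(2πσ_y²) + (f − μ_y)²/(2σ_y²)`, so lower total
energy is higher posterior probability and the per-voxel argmin is a MAP
update; the normalization constant is kept because σ differs between
classes and therefore moves decisions. The pairwise potential is `−λ`
for equal neighbor labels and `+λ` otherwise, `λ ≥ 0`; increasing `λ`
makes exact-minimum configurations provably no less homogeneous (the
standard exchange argument), and `λ = 0` decouples the field into
per-voxel Gaussian classification.

`(μ_y, σ_y)` are the sample mean and SD (ddof = 1) of the patch's
high-confidence intensities of class `y`. A class with fewer than
`n_min = 5` in-cube samples falls back to the whole-volume
high-confidence statistics of that class — boundary patches routinely
contain a single class — and a class absent from the entire volume is an
error. SDs are floored at `ε_σ` = 1e−3 of the volume's intensity range
to keep degenerate (constant-intensity) fits finite.

**Walks.** Within a patch, the `S_L` voxels form a graph with edges
between 6-adjacent pairs weighted by the squared intensity difference
`(f_i − f_j)²`. Prim's algorithm from the seed builds a minimum spanning
tree of the seed's connected component; edge-weight ties are broken by
lexicographic (parent, child) index, so the tree and its insertion order
are deterministic. The walk visits voxels exactly once in insertion
order — the only ordering the construction itself defines — and sets
each to the label minimizing its conditional energy given the current
configuration, ties keeping the current label. Updates are immediately
visible to later voxels; this sequential visibility is the mechanism by
which label confidence propagates from the seed outward, and it is
deliberately a single pass (the method's point is to be non-iterative,
unlike ICM/EM). Every update is a conditional argmin, so the patch energy
is non-increasing along the walk; the walk does not, however, guarantee
the global energy minimum — see Limitations. `S_L` voxels disconnected
from the seed's component fall back to the majority-vote label.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `lt0` | 0.8 | background confidence threshold (on `1 − v`) |
| `lt1` | 0.6 | structure confidence threshold (on `v`) |
| `patch_length` | 11 | cubic patch side, voxels (odd) |
| `mixing_ratio` | 0.0075 | min high-confidence fraction around a seed; with `patch_length = 11` this is 10 of 26 neighbors |
| `lam` | 0.2 | pairwise coupling strength; 0 disables smoothing |
| `tie_policy` | background | resolution of exact vote ties |
| `epsilon_sigma` | 1e−3 × intensity range | floor on fitted σ |
| `n_min` | 5 | per-class in-patch samples before volume-wide fallback |

The asymmetric default thresholds reflect that background consensus is
easier to reach than structure consensus near a thin boundary. The
screening ratio `ρ = |S_L| / |structure voxels of the majority vote|` is
reported to judge threshold pairs: values in (0.5, 1) leave a useful but
bounded amount of uncertainty; `ρ ≈ 0` means nothing will be refined,
`ρ > 1` means the thresholds doubt more voxels than the structure holds.
A `neonate` preset sets `lt0 = lt1 = 0.7`, suited to reversed-contrast,
lower-consensus data. Larger patches improve accuracy at cubically
growing cost; higher mixing ratios reduce patch count and coverage.

## Synthetic data

The phantom generator exists so the full pipeline is testable end to end
without any imaging data. The ground truth is an implicit ellipsoid
(default semi-axes 14 × 9 × 7 voxels on a 64³ grid — a hippocampus-like
aspect ratio at desk scale) perturbed by a unit-RMS band-limited Gaussian
random field (amplitude 0.3, correlation scale 8 voxels), giving a
smooth, connected, non-trivial surface. Intensities are class-Gaussian —
structure N(110, 12²), background N(60, 12²), a T1-like contrast of
about four noise SDs — with optional per-axis linear drift and optional
reversed contrast (the unmyelinated-neonate regime).

Candidates emulate atlas-propagation error, which is spatially
correlated and surface-localized rather than i.i.d.: each candidate is
the truth warped by an independent smooth random displacement field
(default RMS 2 voxels, correlation scale 6), optionally dilated/eroded by
up to one voxel, with 2% label flips inside the boundary band. All
disagreement is confined to a declared band around the truth surface
(default: displacement + morphology + 1 voxels), so structure cores and
far background are unanimous by construction. A shared displacement
component applied to a random candidate subset can emulate systematic
(correlated) atlas bias; its default magnitude is 0.

What passing phantom tests shows: that the method recovers
boundary-localized, spatially correlated candidate error when intensity
is informative — the regime the method targets. What it does not show:
performance under MR artifacts the generator omits (Rician noise,
nonlinear bias fields, partial-volume mixtures), under registration
failures larger than the boundary band, or on real anatomy with
ambiguous intensity boundaries.

## Numerical and design choices

- **Energy sign convention.** Potentials are negative log-likelihoods, so
  argmin(U) is the MAP configuration; `λ` is defined non-negative with
  equal-label energy `−λ`, making "larger λ, smoother output" the
  explicit, testable direction.
- **Determinism everywhere.** Seed ranking, patch ownership, Prim ties,
  and conditional-energy ties all have fixed deterministic tie-breaks;
  the fusion path contains no randomness at all, so identical inputs give
  byte-identical outputs.
- **Patch independence.** Because memberships are disjoint and boundary
  cliques are unmodeled, patches can be processed in any order with
  identical results.
- **Degenerate inputs.** Empty `S_L` is not an error (output = majority
  vote); `J = 1` gives a binary vote map, hence empty `S_L` and identity
  output; a class with no high-confidence voxels anywhere raises rather
  than guessing; both-empty Dice raises rather than returning 0.
- **Study sizes.** The bundled paired study uses 20 phantoms at 64³ with
  J = 9, ~35 s total on one CPU; exhaustive-enumeration oracles in the
  test suite cap patches at ≤ 10–12 free voxels (2¹⁰–2¹² configurations).

## Known limitations

- Binary labels only; multi-structure fusion would need a multi-class
  field and is not attempted.
- The one-pass walk is a greedy, order-dependent inference: it descends
  energy but does not reach the global minimum in general, and its
  output homogeneity is not exactly monotone in `λ` (measured on the
  default phantom, the discordant-pair count over the sweep
  λ ∈ {0, 0.1, 0.2, 0.5, 1} is 2092, 2058, 2038, 2020, 2022 — a 0.1%
  uptick at the last step). Monotonicity is guaranteed, and verified
  exhaustively in the tests, only for exact global minimizers on small
  patches.
- Patch generation is a heuristic cover, not a graph partition; with
  small patches or strict mixing ratios parts of `S_L` go unrefined
  (watch the coverage field of the report).
- Weighted voting is supported, but estimating weights from
  atlas-target similarity is out of scope by design — the method's
  premise is to decouple fusion from the atlas library after
  registration.
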