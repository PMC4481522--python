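# Methods

`valvemorph` quantifies the silica morphology of diatom valve interiors
(tree-like radial ribs vs cross-linked meshes), relates it to the growth
phases of silicon-limited batch cultures, and closes the loop with a
valve-inheritance mixing model. This note records the models, the
parameters that matter, and the design choices made where the design was
genuinely open.

## 1. Skeleton-graph morphometry

A valve image is reduced to a one-pixel-wide skeleton (crop → band-pass
→ Otsu threshold → thinning → spur pruning) and the skeleton to a graph:

* **Vertices** are *junctions* (pixels with ≥ 3 skeleton neighbors,
  merged into one vertex when adjacent — thinning produces small pixel
  blobs at crossings, and merging stabilizes node counts) and
  *extremities* (free ends). A component that is a pure loop has neither;
  it receives an anchor vertex of a third kind, `cycle`, carrying a
  self-loop edge, so that the face count below stays exact.
* **Edges** are the pixel polylines between vertices, with diagonal
  steps counted √2. Edge kinds: *branch* (junction↔extremity),
  *segment* (junction↔junction), *isolated* (component without a
  junction). *Master* junctions have ≥ 3 incident segments; *master*
  segments join two master junctions.
* **Meshes** are areas fully surrounded by silica: 4-connected
  background components not touching the image border, measured in
  enclosed pixels (converted to µm² via the pixel size). Foreground is
  8-connected, background 4-connected — the standard duality without
  which hole counts are inconsistent.

Pixel adjacency drops a diagonal link whenever the two pixels share an
orthogonal skeleton neighbor: such links are redundant for connectivity
and would otherwise create zero-area triangular cycles. With this
reduction the skeleton is a planar embedded graph and the Euler relation

    n_meshes = E − V + C

holds exactly; it is asserted as an oracle (flood-fill count vs graph
cyclomatic number) over generated patterns spanning the whole supply
range. Faces enclosed entirely inside one merged junction cluster are
counted by flood-filling the cluster pixels and represented as
zero-length self-loops, so the relation survives even pathologically
dense crossings.

Per image 22 features are computed (counts, per-kind lengths in µm,
mesh count/areas in µm², the mesh index = total length per mesh, the
branching interval = total length per junction, the equivalent-area
valve diameter from the convex hull, and rimoportulae per valve area —
the rimoportula count is a manual annotation input, not detected).
`total_length = total_segment_length + total_branch_length +
total_isolated_length` is an invariant checked on every image.

**Numerical choices.** Band-pass is a difference of Gaussians; defaults
σ = 3 and 40 px for SEM-scale images (1 and 60 px in the synthetic
pipeline, whose ribs are thinner than real SEM granularity).
Binarization is Otsu's global threshold — parameter-free and apt for
bimodal SEM contrast; a constant image is rejected ("no contrast").
Spur pruning removes terminal branches shorter than `prune_px`
(default 4 px) to suppress thinning artifacts; `prune_px = 0` preserves
homotopy exactly (component and hole counts are invariant under
thinning, and tests assert this). Vertices and edges are ordered
row-major by anchor pixel, so graphs are deterministic.

## 2. Tree/mesh classification

Features are min–max normalized to [0, 1] per column, fitted on the
full table so labeled and unlabeled rows share one scale; constant
columns map to 0. Classifiers: a single decision tree (DTC, retained
behind a `DeprecationWarning` because single trees are less accurate),
a random forest (RFC), and extremely randomized trees (ETC), all from
scikit-learn. Accuracy is measured by stratified 5-fold
cross-validation repeated 40 times with distinct seeds (k is a
convention choice; 5 works for small training sets). Hyperparameters
can be selected from a declared grid (`n_estimators` ∈ {100, 300},
`max_depth` ∈ {None, 5}) by maximizing mean CV accuracy, ties toward
the simpler model.

The *meshiness* of an image is the ensemble's probability for the mesh
class (`p_mesh`; the tree weight is `1 − p_mesh`). A condition's
meshiness is the **mean of per-image probabilities**; the fraction of
hard calls (`p_mesh > 0.5`, exactly 0.5 → "mixed") is reported
alongside, since either aggregation is defensible. Feature importances
are mean impurity decreases normalized to sum 1, reported per repeat.

## 3. Population dynamics

Cell density and biovolume come from integrating Coulter-counter style
volume histograms: `density = dilution × Σcounts / analyzed volume`
(defaults: 50-fold dilution, 0.1 mL), biovolume uses geometric bin
midpoints (appropriate for log-spaced bins).

The doubling timescale τ of the initial exponential phase is fitted as
ordinary least squares of log₂ density on time (`d(t) = d₀·2^{t/τ}`),
which is exact under multiplicative noise and yields a closed-form CI
for τ by the delta method. The fit window is either fixed (e.g. the
first 50 h) or adaptive: all points strictly before the detected
plateau.

Growth phases: **phase II** (plateau) begins at the first measurement
interval whose relative growth rate falls below 10% of the phase-I rate
ln2/τ fitted on the first four points — "growth rate approaches zero"
needs a tolerance, and 10% of the initial rate is configurable. The
rate test runs on a 3-point running median of the density: the median
of a monotone triple is its center point, so noiseless series are
unchanged, while single-point counting noise on a plateau no longer
fakes growth. **Phase III** (regrowth) begins at the first subsequent
measurement whose density step exceeds 20% — a +19% step must not
trigger it, +25% must, and both boundaries are tested.

## 4. Valve-inheritance mixing model

At division each daughter keeps one parental valve and builds one new
valve. Assuming phase-I (Si-replete) valves retain their pattern and
all post-depletion valves are tree-like with mesh weight
`1 − mesh_p1`, the final population meshiness is the weighted average

    meshiness = [d_p1·mesh_p1 + (d_p2p3 − d_p1)·(1 − mesh_p1)] / d_p2p3.

The model is expressed in cell densities; valve counts carry a factor 2
that cancels. The stochastic simulator works in valves (every cell is a
pair of valve meshiness values), divides a binomially drawn subset of
cells per schedule step so the population tracks a target density
trajectory, and verifies the cancellation: its endpoint converges to
the closed form as 1/√n₀ and is asserted within 3 SE over replicates.
Divisions are binomial deliberately — with exact division counts the
population meshiness is a deterministic function of the final count and
the Monte-Carlo check would be vacuous. No dissolution, remodeling, or
death is modeled (schedules must be non-decreasing).

## 5. Synthetic data: what it emulates and what it does not

**Valve patterns** are grown as a lattice branching walk: `n_ribs`
silica ribs radiate from a filled central hub, advance outward in 2-px
steps with angular jitter clamped to ±1 rad of the radial direction,
and split dichotomously with probability `branch_prob` per step. A rib
approaching existing silica (within 4 px Chebyshev) either **fuses**
with it — probability `supply`, drawing a bridge and creating a mesh —
or terminates. Hence `supply = 0` can draw no cross-link at all and the
skeleton is provably a forest (zero bounded faces, a tested invariant),
while `supply = 1` cross-links every encounter; mean mesh count is
monotone in supply (Spearman test over seeds). This mirrors the
diffusion-limited-deposition picture in which low silicon supply yields
trees and high supply compact, connected deposits, but it is *not* a
physical deposition simulation — it is fast, exactly seedable (same
spec + seed ⇒ bit-identical images) and spans the same morphological
continuum, which is all the pipeline needs. Rendering dilates ribs to
~3 px, fills sub-resolution (≤ 2 px) background pinches left where
diverging rib tubes separate, and adds optional Gaussian gray noise.
Labels are assigned from supply (≤ 0.2 tree, ≥ 0.8 mesh, otherwise
mixed) as generator metadata. Real SEM artifacts — charging, shading
beyond a smooth gradient, girdle-band debris, 3-D relief — are not
emulated, so classifier accuracies on synthetic tables bound what the
code does, not what real imagery would give. Rib spacing and mesh-size
distribution are visually calibrated, configurable defaults.

**Population series** follow d₀·2^{t/τ} to a plateau, then regrowth.
Defaults emulate the 14 °C culture: d₀ = 0.33·10⁶ cells/mL,
τ = 40.9 h, plateau 1.16·10⁶ (so the phase-II onset is 74 h), regrowth
to 1.66× the plateau. Regrowth opens with a 25% synchronized division
burst inside one sampling interval: with the smooth alternative, no
interval at these ratios ever exceeds the 20% change-point rule, i.e.
the burst is what makes phase III detectable at all — real cultures
show exactly such partially synchronized rebounds. Volume histograms
are lognormal mixtures on 64 log-spaced bins over 10–300 µm³ whose
modes drift right during the plateau (girdle-band elongation) and gain
a small-volume mode during regrowth. Histogram counts are expected
(real-valued) counts scaled so integration reproduces the density
exactly at zero noise; observation noise is multiplicative with a
given CV.

**Feature tables** draw the 22 features from per-class normals
truncated at zero, with a configurable pooled-SD separation on the
discriminative features (mesh counts/areas and segment totals up for
the mesh class, branch/extremity totals down). Separation 0 makes the
classes exchangeable (CV accuracy ≈ 0.5); separation ≥ 4 reproduces
the ≥ 95% accuracy regime.

## 6. Problem sizes and runtime

Tests and the acceptance script use 80–96 px-radius patterns, 60-image
batches per class, 40-repeat cross-validation, and n₀ = 10⁵ cells ×
20 replicates for the inheritance oracle — the smallest sizes at which
the tree/mesh continuum is morphologically rich and the stochastic
checks have useful power. All randomness flows from explicit integer
seeds; every generator and the full pipeline are bit-reproducible, and
pipeline outputs carry the configuration hash.

## 7. Known limitations

* The generator's supply→label thresholds are metadata, not biology;
  "mixed" patterns have no ground-truth meshiness beyond supply itself.
* The 22-feature schema follows the angiogenesis-network naming
  tradition plus the two valve-scale features (diameter, rimoportulae
  per area); other tools' exact definitions of "master" elements vary.
* Mesh areas are enclosed-pixel counts, so one-pixel-wide passages
  merge adjacent meshes that a sub-pixel method might separate.
* The mixing model ignores dissolution, mortality and aggregation; it
  is a bookkeeping identity under its assumptions, and the simulator
  tests the bookkeeping, not the biology.
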