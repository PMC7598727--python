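# Methods

This document defines the quantities `fibriltwist` computes, lists every
tunable parameter with its unit, default, and rationale, and records the
numerical choices and known limitations. All internal lengths are
nanometres; file readers convert at the boundary (PDB/GRO store Ångströms).

## Model and conventions

### Topology

A peptide of sequence `s` is a chain of `len(s)` residues, each contributing
three backbone beads (N, CA, C, in that order) plus one side-chain bead (SC)
for every non-glycine residue. The default sequence GNNQQNY therefore has
3×7 + 6 = 27 beads per peptide. Beads are stored peptide-major, residue-major
within a peptide. The mutant sequence GNNQQNA is predefined as well.

### Cluster detection

Two peptides are linked when **any** bead–bead distance is strictly below
the cutoff (default 0.5 nm), with distances taken under the minimum-image
convention in an orthorhombic periodic box. Clusters are the connected
components of this link graph (single linkage); a component of size 1 is a
*monomer*, not a cluster. Neighbour search uses a periodic k-d tree
(`scipy.spatial.cKDTree(boxsize=L)`); tree results are filtered with a
strict `< cutoff` comparison so the boundary case is unambiguous. The
cutoff must be below half the smallest box edge, otherwise the minimum
image is not unique and the call is rejected.

### Unwrapping

A cluster that crosses a periodic boundary is rebuilt in two stages.
First, each peptide is made internally contiguous by a bead-by-bead
minimum-image walk along its own chain (a wrapped frame may split single
peptides). Second, the cluster's peptides are shifted by integer box
vectors along a breadth-first traversal of the link graph, using the
specific linking bead pair recorded during cluster detection; each newly
placed peptide is positioned so its linking bead sits in the minimum image
of its already-placed neighbour's bead. The result is translation-exact:
descriptors on the unwrapped cluster reproduce the pre-split reference to
1e−10 (verified over hundreds of random split trials).

### Gyration shape

For bead positions of one unwrapped cluster, the gyration tensor
S = (1/N) Σ (r − r̄)(r − r̄)ᵀ has eigenvalues λx² ≤ λy² ≤ λz².
Reported are Rg = √(λx² + λy² + λz²) (nm), the raw asphericity
b = λz² − (λx² + λy²)/2 (nm²), and the normalised asphericity
b_norm = b / (λx² + λy² + λz²) ∈ [0, 1] (0 for a sphere, 1 for a rod).
The eigensolve is `numpy.linalg.eigh` on the symmetric tensor.

### End-to-end correlation

The end-to-end vector of a peptide runs from the backbone N of residue 1 to
the backbone C of the last residue, normalised. For a cluster of M
peptides,

    Cn = 2 / (M(M−1)) · Σ_{i<j} (n̂ᵢ · n̂ⱼ)²

The square makes Cn insensitive to chain direction: 1 for parallel *or*
antiparallel alignment, 1/3 in the isotropic limit. When a wrapped frame is
analysed, vectors are taken from the unwrapped peptide coordinates.

### Beta content

Backbone dihedrals are measured per interior residue (terminal residues
lack one of φ, ψ): φ(i) = C(i−1)–N(i)–CA(i)–C(i),
ψ(i) = N(i)–CA(i)–C(i)–N(i+1), via `MDAnalysis.lib.distances.calc_dihedrals`
(IUPAC sign convention). A residue is *beta* when
φ ∈ [−180°, −45°] and ψ ∈ [45°, 180°] ∪ [−180°, −120°] — a deliberately
broad strand region appropriate for a coarse-grained geometry. The
cluster's beta content is the mean number of beta residues per peptide;
for 7-residue chains it is bounded by the 5 interior residues.

### Distance histograms and the order score

Pairwise peptide mass-center distances within one unwrapped cluster are
binned at 0.02 nm (default) into a normalised histogram. The order score
smooths the histogram twice with a 3-bin moving average, detects local
maxima with `scipy.signal.find_peaks` requiring a prominence of 20% of the
smoothed maximum (suppressing sparse-histogram jitter; `find_peaks` also
handles the plateaus that smoothing isolated spikes creates), and reports
the fraction of the probability mass beyond the first-neighbour peak that
sits in peak bins and their immediate neighbours. Regular packings
concentrate essentially all mass in narrow shells (score → 1); amorphous
packings spread it (low score). The default ordered/disordered threshold
is 0.5. `second_maximum` returns the distance of the second smoothed peak,
the empirical stand-in for the reference spacing fit below.

### Helicity

For a fibril-like cluster with peptide mass centers cᵢ:

1. **Axis.** The axis Â is the principal direction of the centered
   covariance of the axis points (the centers by default) — equivalently
   the total-least-squares line through them. It is oriented from the
   first toward the last input point along the projection, which makes the
   reported per-pair signs deterministic.
2. **Ribbons.** Centers are sorted by axial projection; consecutive
   entries chain into the same ribbon when both the longitudinal gap
   d∥ ≤ d∥0 = s∥·dm2(M) and the radial-offset difference
   d⊥ ≤ d⊥0 = s⊥·dm2(M) hold, where dm2(M) = a/M + b is the fitted
   reference spacing (a = 9.6192 nm, b = −0.0009 nm, s∥ = 0.88,
   s⊥ = 0.47). Known ribbon memberships can be supplied to bypass the
   automatic assignment.
3. **Pair twist.** For consecutive ribbon members i, i+1 with radial
   vectors rᵢ, rᵢ₊₁ (center minus its foot on the axis):
   ĝᵢ = rᵢ/|rᵢ|, êᵢ₊₁ = (Â × rᵢ₊₁)/|Â × rᵢ₊₁|, and h = ĝᵢ · êᵢ₊₁.
4. **Cluster helicity.** H is the mean over ribbons (with ≥ 2 members and
   defined twists) of the per-ribbon mean h.

**Sign convention.** The tangential direction is ê = Â × r̂ — the
right-handed azimuthal direction about the axis. With this choice an ideal
helix whose azimuth advances by Δφ per step yields h = −sin Δφ for every
pair, hence H = −sin Δφ: right-handed twist gives negative H, and
mirroring the structure flips the sign. (The opposite cross order r̂ × Â
would flip all signs; fixing the convention here is what makes reported
handedness meaningful.)

**Axis-fit exactness.** For an azimuthally symmetric fibril — n ≥ 2
ribbons at equal angular offsets 2πk/n with common twist and rise — the
centroid of each axial layer lies exactly on the helix axis, so the layer
spread is purely axial and the covariance eigenvector is *exactly* the
helix axis. This is why multi-ribbon ground-truth fibrils reproduce
H = −sin Δφ to 1e−6. A *single* helix has no such cancellation: its
centers form a one-sided arc whose covariance tilts the fitted axis
slightly (dot product with the true axis ≈ 0.99 even for full turns),
biasing |H| upward by a few percent. Tests and documentation treat that
bias as a property of the estimator, not noise.

**Axis-reversal behaviour.** Flipping the axis orientation flips the sign
of every individual pair twist (ê reverses, ĝ does not). The cluster value
H, however, is invariant: ribbons are traversed in projection-sorted
order, so reversing the axis also reverses the traversal, and the two sign
flips cancel. The orientation rule therefore only fixes the bookkeeping of
individual h values; H does not depend on it.

**Fragmentation limitation.** The consecutive-run chaining operates on a
single projection-sorted sequence. Geometries in which several ribbons
interleave in projection (e.g. multiple ribbons sharing axial layers)
fragment under automatic assignment, because same-layer neighbours from
different ribbons break the d⊥ test. Supply the known membership in such
cases; the automatic path is intended for single-ribbon or well-gapped
structures.

### Kinetics and scaling

- **t½** — first time the monomer count crosses N0/2, linearly
  interpolated between the bracketing frames.
- **tmax** — time of the maximum of the cluster count after a centered
  moving average (default window 5 frames; earliest frame wins ties).
- **Master curves** — Nm/N0 against t/t½ and Nc/N0 against t/tmax;
  `collapse_gap` reports the maximum vertical gap between two scaled runs
  on a common logarithmic time grid.
- **Power-law fits** — unweighted least squares in log–log space
  (`scipy.stats.linregress`): Rg ∝ M^α over sizes M < M* (default 25), and
  Rg − Rg* ∝ (M − M*)^β over M > M* with Rg* = 1.332 nm. Defaults for
  M* and Rg* mark the empirical amorphous→fibril crossover; both are
  configurable.
- **Concentrations** — c0 = N0 / (N_A · L³) reported in mM; the
  equilibrium monomer concentration is the tail-mean monomer count (tail
  starting when the largest cluster first attains its final size) divided
  by the box volume.
- **Units** — helpers convert J ↔ kcal/mol (per particle, via N_A),
  Å ↔ nm, K → J (thermal energy k_B·T), and simulation time units τ ↔ ps
  given a user-supplied τ in ps (τ is treated as an opaque constant).

### Stochastic coalescence model

A well-mixed, spatially implicit aggregation model: entities of sizes
{sᵢ} coalesce pairwise with rate K(sᵢ, sⱼ); clusters (size ≥ 2) may shed a
monomer with a constant detachment rate. Simulation is exact
(Gillespie): waiting times are exponential in the total rate and events
are drawn proportionally to their rates. Provided kernels: constant
K = k0 and sum K = k0(i + j). With a constant kernel the entity count is a
pure death chain with rate k0·n(n−1)/2, whose mean has a closed form via
the matrix exponential of the chain generator — used as the reference
solution in the tests. Total peptide number is conserved at every event;
without detachment the absorbing state is a single cluster of size N0.

## Parameters

| Parameter | Unit | Default | Rationale |
|---|---|---|---|
| `cutoff` | nm | 0.5 | bead contact distance defining a link |
| `dm2_a` (a) | nm | 9.6192 | fitted reference-spacing law dm2(M) = a/M + b |
| `dm2_b` (b) | nm | −0.0009 | intercept of the same fit |
| `s_par` (s∥) | — | 0.88 | longitudinal ribbon cutoff as a fraction of dm2 |
| `s_perp` (s⊥) | — | 0.47 | perpendicular ribbon cutoff as a fraction of dm2 |
| `hist_bin_width` | nm | 0.02 | distance-histogram resolution |
| `beta_region` | deg | φ∈[−180,−45], ψ∈[45,180]∪[−180,−120] | broad strand region for CG geometry |
| `smooth_window` | frames | 5 | moving average for tmax robustness |
| `m_star` (M*) | peptides | 25 | amorphous→fibril crossover size |
| `rg_star` (Rg*) | nm | 1.332 | mean Rg at the crossover size |
| `xyz_unit` | — | nm | unit of XYZ files (internal unit is always nm) |
| `axis_selection` | — | all | beads used for axis points (`all` or `side_chain`) |

All of these live in `AnalysisConfig`, round-trip through YAML unchanged,
and are echoed into every CLI output's metadata header.

## Synthetic generators: scope and limits

The generators produce *geometric* fixtures with known answers, not
physical configurations:

- `build_helical_fibril` places rigid extended-peptide templates with mass
  centers at (r cos φ, r sin φ, m·rise), φ = 2πk/n_ribbons + m·Δφ, long
  axes radial. Ground truth: axis, ribbon membership, H = −sin Δφ.
  Gaussian coordinate noise (amplitude ε, seeded) is added last.
  Construction fails if inter-center spacing drops below a bead clash
  distance (0.05 nm).
- `build_parallel_sheet` stacks identical extended peptides; the
  antiparallel variant rotates alternate peptides 180° about an axis
  perpendicular to the end-to-end vector, mapping that vector exactly onto
  its negative so Cn = 1 holds to machine precision for both orientations.
- `build_amorphous_cluster` samples centers uniformly in a ball with a
  minimum-separation rejection rule and isotropic orientations.
- `build_monomer_gas` guarantees no inter-peptide contact within the
  clustering cutoff, including across boundaries.
- `split_across_boundary` translates and wraps a frame, deliberately
  cutting structures across faces for round-trip tests.
- `simulate_coalescence` is the Gillespie model above.

All generation is bit-reproducible for a given seed and parameter set. The
generators make no claim of thermodynamic realism: templates are rigid,
there is no force field, and the coalescence model has no spatial
structure.

## Numerical choices

- Strict `<` at the clustering cutoff; k-d tree candidates re-checked
  against minimum-image distances.
- `numpy.linalg.eigh` for all symmetric eigenproblems; degenerate axis
  fits (no unique principal direction) are flagged `ill_defined`, and
  zero-spread inputs are rejected.
- Dihedrals via MDAnalysis (vectorised, IUPAC convention); an independent
  four-point torsion oracle in the test suite cross-checks the convention.
- Log–log fits are unweighted; the fit domain is reported alongside the
  exponent and standard error so truncation choices are visible.
- Default problem sizes in tests and the acceptance script (clusters of
  4–30 peptides, fibrils of 20–90, coalescence with N0 = 72, 100–200
  replicates) are the package's own choices, sized to give sub-minute,
  deterministic verification on one CPU while leaving Monte-Carlo
  tolerances statistically meaningful.
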