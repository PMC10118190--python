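# Methods

This note records the models, parameter choices, and numerical decisions
behind `gefprobe`, and what the synthetic data generators do and do not
emulate.

## Exchange kinetics

**Model.** A nucleotide-exchange fluorescence trace is modelled as a
mono-exponential decay from the reaction start `t0`:

```
f(t) = (a0 − a_plateau) · exp(−k_obs · (t − t0)) + a_plateau
```

This is the standard apparent-rate description of a pseudo-first-order
exchange reaction under excess unlabelled nucleotide. It assumes a single
dominant exchange process; multi-phasic traces are outside scope and will
show up as structured residuals.

**Normalisation.** Each trace is divided by the mean of its baseline
window, the `baseline_window_s = 300 s` (default) preceding `t0`. At least
3 baseline samples and a positive baseline mean are required; otherwise a
`NormalizationError` is raised rather than silently producing nonsense.
Normalisation makes `a0 ≈ 1` and puts traces from different wells on a
common scale.

**Fitting.** Nonlinear least squares (`scipy.optimize.curve_fit`,
Levenberg–Marquardt within bounds, `k ≥ 0`, tolerances 1e-10) on the
post-start samples (`≥ 10` required). Initial guesses: `a0` from the first
post-start value, `a_plateau` from the tail mean, `k` from a log-linear
regression of `log(f − plateau)` — this makes convergence robust across
the four decades of rate the assay spans (`k_obs` from 1e-4 to 1e-1 s⁻¹
with 2–15 s sampling over 1–2 h records).

**No-decay detection.** Before fitting, the head mean (first
`max(3, min(10, n/10))` post-start samples) is compared with the tail mean
(last 10%) against a noise floor of 3× the baseline standard deviation. A
difference below the floor flags `no_decay`: the trace is reported as flat
(a meaningful result for an inactive GEF), not force-fit. The head window
is deliberately short so that fast decays (`k ≈ 0.1 s⁻¹`, ~90% complete
within 25 s) are not mistaken for flat traces.

**Activation call.** The statistic is the fold change of the arm means,
`mean k_obs(GEF) / mean k_obs(intrinsic)`. With ≥ 3 replicates per arm the
95% CI is a bootstrap percentile interval over replicate resampling
(2000 resamples, seeded); with fewer, a delta-method interval from the
per-fit standard errors. The call is *active* iff fold ≥ `fold_threshold`
(default 2.0) **and** the CI excludes 1; *inactive* iff the CI upper bound
is below the threshold; otherwise *indeterminate*. An intrinsic arm that is
entirely `no_decay` yields *indeterminate* (no finite denominator).

## Superposition, RMSD, RMSF

Optimal rigid superposition uses the Kabsch algorithm (SVD of the
cross-covariance, determinant correction to enforce a proper rotation).
Fits on < 3 atoms or collinear selections raise `IllPosedFitError`. The
test suite validates every fit against an independent quaternion
(key-matrix) RMSD oracle.

RMSD series superpose each frame independently onto a reference (frame 0
by default) over Cα atoms. RMSF uses two rounds of iterative
mean-structure superposition, then per-residue
`sqrt(⟨|x − ⟨x⟩|²⟩)`. For isotropic per-axis jitter of standard deviation
σ the expected RMSF is `σ√3`; validation uses a single jittered residue in
the middle of a 100-residue chain because rigid-body fitting absorbs a few
percent of the apparent fluctuation of residues near chain ends (a
geometric property of least-squares superposition, not an implementation
artifact).

## Coordinate PCA

PCA is performed on the covariance of flattened, superposed Cα coordinates
of every `stride`-th frame (default stride 5 — the conventional
subsampling for long trajectories; default 20 components). Frames are
aligned onto their mean iteratively until the mean is a numerical fixed
point (tolerance 1e-12), so that re-projecting training frames reproduces
the fitted scores exactly. The converged mean is then rotated into a
canonical pose (principal axes with deterministic signs, right-handed),
which makes components invariant to the global pose of the input ensemble,
not just its internal motions. Variance fractions are
`λ_k / Σ λ_all` over *all* eigenvalues, so retained fractions never
overstate explained variance. Component signs are fixed (largest-magnitude
coefficient positive) for reproducibility. Extreme-projection frames along
a chosen component are exported as structures for visual comparison.

## Steric binding compatibility

Each ensemble frame is superposed onto the template over a user- or
auto-mapped anchor (auto mapping aligns the Cα sequences globally and
pairs non-gap columns; ≥ 3 pairs required). Two atoms clash when
`d < r_i + r_j − overlap_threshold`, with van der Waals radii from a
standard table (unknown elements fall back to 1.70 Å with a logged
warning) and `overlap_threshold = 0.4 Å`, the conventional severe-clash
cutoff; a fixed distance cutoff mode is also available. Heavy atoms only
by default (hydrogens are usually absent or unreliable in both
crystallographic templates and coarse ensembles). A frame is compatible
when it has at most `max_clashes = 0` clashing pairs; the headline
statistic is the percentage of compatible frames. Distances use a full
pairwise matrix (`scipy.spatial.distance.cdist`) — exact, no spatial
pruning — and the tests compare the complete clash set against a
brute-force loop oracle.

## Sequence analysis

Percent identity between two aligned rows counts matching columns over
columns ungapped in both sequences (default) or over the full alignment
length. Family substructure is found by greedy diagonal-square clustering
of the identity matrix: scanning left to right, each cluster is the
largest contiguous square whose off-diagonal mean (or minimum, under the
strict criterion) stays at or above the threshold (default 35%). The
greedy result matches an exhaustive reference on random matrices; note
that for adversarial (non-block-structured) matrices, cluster boundaries
are not guaranteed to nest monotonically as the threshold rises — the
nesting property holds for block-structured inputs, which is the intended
regime. Key-residue divergence flags alignment columns where the query
differs from a consensus supported by at least a `conservation_quorum`
(default 0.8) of the other sequences; columns without such a consensus are
reported separately as "not conserved" rather than flagged. Global
alignment uses BLOSUM62 with affine gaps (open 10, extend 0.5) via
Biopython's `PairwiseAligner`; the score is validated against an
independent Gotoh dynamic-programming oracle.

## Synthetic data generators

The generators produce data whose ground truth is known *by construction*,
so recovery can be tested exactly:

- **Toy ensembles** — an idealised helical Cα chain (radius 2.3 Å, rise
  1.5 Å per residue, 100° twist) with per-residue isotropic Gaussian
  jitter and random global rigid transforms. They emulate the *statistics*
  of a flexible protein (known RMSF profile), not its energetics or
  covalent geometry.
- **Mode ensembles** — displacements along designed collective directions
  that are orthogonalised against the six rigid-body modes, so
  superposition removes *exactly* the rigid motion and the PCA spectrum
  equals the designed variances (a rank-1 ensemble yields PC1 fraction
  1.0 to machine precision).
- **Binding scenarios** — an anchor chain plus a flexible loop that is
  either placed clear of, or driven into, a partner chain held at the
  template position, with per-frame labels; the compatible percentage is
  exact by construction.
- **Synthetic MSAs** — a root sequence mutated into per-block ancestors
  and members with mutation counts solved from the requested within- and
  between-block identities (realised identities land within a few points
  at the default length 400). No indels: the generator targets identity
  structure, not gap patterns.
- **Ortholog pairs** — a random sequence plus a copy with an exact number
  of substitutions, standing in for closely related cross-species
  orthologs (e.g. small GTPases, which exceed 90% identity across
  vertebrates). These are labelled synthetic; the package ships no real
  biological sequences.
- **Traces** — flat baseline plus the mono-exponential model plus i.i.d.
  Gaussian noise (default σ = 0.01 of the normalised amplitude, typical
  for plate-reader fluorescence after normalisation). Not emulated:
  photobleaching drift, lamp flicker, mixing dead time.

All randomness flows through `numpy.random.default_rng` seeds below 2³¹;
every generator returns its ground truth alongside the data, and
`write_scenario` serialises both to disk.

## Pipeline determinism

The pipeline report contains the package version, a SHA-256 hash of the
analysis-relevant config (seed + stages; the output directory is
excluded), and per-stage summaries with rounded floats — never
timestamps or absolute paths. Reruns of the same config are byte-identical.
Stage failures abort with a coded `StageError` and a `FAILED` marker file
next to whatever artifacts were already written.

## Validation study sizes

The acceptance studies (see `scripts/acceptance.py`) use sizes chosen to
make the statistical assertions sharp yet fast: 100 traces per rate decade
(median relative error), 200 simulated experiments per classification
scenario with 3 replicates per arm, 100-frame binding scenarios with an
exact intrusion count, 10,000 frames for RMSF (5% tolerance on `σ√3`),
5,000 frames for the two-mode variance split (±0.02), and 1,000 random
8×8 matrices for cluster-finder equivalence. These are the package's own
validation choices, sized so the whole script runs in well under a minute.

## Limitations

- Kinetics assumes a single exponential phase and homoscedastic noise; it
  does not model mixing dead time, drift, or inner-filter effects.
- Clash detection is rigid: the template GTPase is fixed, side chains do
  not repack, so the compatibility percentage is a conservative geometric
  screen, not a binding free-energy estimate.
- Coordinate PCA mixes rigid-residual and internal motion when
  superposition is imperfect; mass weighting is not applied.
- The PDB reader covers standard single-character-altloc, no-insertion-code
  files; insertion codes are rejected explicitly rather than guessed.
- The greedy cluster finder is order-dependent by design (left-to-right,
  largest square first), matching the sequence ordering of the input MSA.
- Activation classification compares arm means; it does not model
  concentration–response (a catalytic efficiency would require a titration
  series).
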