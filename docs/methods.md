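# Methods

This note records the models implemented in `shiftensemble`, the defaults
and why they were chosen, the numerical decisions, and what the synthetic
generators do and do not emulate.

## Scaling

Backbone shifts are mapped per nucleus through
`f(x) = log_a((x − y_min)/(y_max − y_min) + 1) + θ` with `y_min`/`y_max`
taken from the experimental reference.  The argument of the log lies in
[1, 2] for in-range values, so `f` is strictly increasing and exactly
invertible; `f(y_min) = θ` and `f(y_max) = log_a 2 + θ`.  Defaults are
`a = 10` and `θ = 0`, the values the method settles on for real
transthyretin data; `θ` is applied to the amide proton only, where
reference-dependent systematic offsets between predictor and experiment
are largest (magnitudes near 0.05–0.07 in scaled units on real data).  `θ`
enters after the log map, so the package treats it as a dimensionless
offset in scaled space even though it is conventionally quoted in ppm.

Values below `y_min − (y_max − y_min)` fall outside the log domain; the
transform raises a domain error naming the offending residue rather than
clipping, since such a value means the library and reference disagree
grossly for that nucleus.

Hyperparameter tuning minimises the squared residual of the full
constrained fit in scaled space over `(a, θ_HN)`, with `a ∈ [1.1, 10]` and
`θ ∈ [−0.2, 0.2]`.  The aggregation of the objective over nuclei is not
canonical; the total squared residual of the stacked scaled problem is
used.  The inner solve makes the objective potentially multimodal, so a
multi-start L-BFGS-B loop (four log-spaced starts in `a`) is run, and when
the objective is flat — e.g. when the library contains the reference and
the residual is zero everywhere — the defaults `(10, 0)` are kept.

## Regression

The solve is two-stage: plain non-negative least squares (Lawson–Hanson
KKT active set, `scipy.optimize.nnls`) gives a non-negative start, which
is normalised and refined by SLSQP under `Σw = 1`, `w ≥ 0`.  A final
exact polish solves the equality-constrained least-squares KKT system on
the active set (minimum-norm solve, dropping negative coordinates until
feasible), which both sharpens the optimum to machine precision on
well-posed problems and resolves ties among equal-residual solutions
toward minimum-norm weights.  Degenerate all-zero design columns are
dropped with a warning.

Feature selection keeps `S = {j : w_j ≥ ε·max(w)}` with `ε = 10⁻⁵`,
inclusive, applied once; the model is refit on `S` with the same
constraints, and weights off the support are exactly zero.  Since the
feasible set of the refit contains the truncated solution, the refit
residual on the full support can never exceed the pre-selection residual.

R² is computed per nucleus **in ppm space**: predictions are mapped back
through the inverse scaling before residual and total sums of squares are
formed.  This makes per-nucleus scores comparable to the shift-predictor
literature and independent of `(a, θ)`.  The total score is the product of
the four per-nucleus values; it is reported as missing if any nucleus has
zero reference variance.

## Secondary structure

Per-residue proportions are plain (or weight-normalised) class fractions
over conformers; the β-core `B` uses a strict majority (`P > 0.5`, so a
residue at exactly 50 % is out), and per-conformer β fractions are counted
over `B` or over any user-supplied residue subset.  Ensemble-level class
proportions are the mean over residues of the weighted per-residue
fractions.

External STRIDE/DSSP reports are parsed from their text forms (ASG lines;
`#  RESIDUE` data blocks), with several conformer blocks per file, and
codes mapped H→α, G→3₁₀, E/B→β, T→turn, else coil (configurable).

The built-in assigner is deliberately simple and approximate, not a
STRIDE/DSSP replacement: helices are detected from Cα (i,i+3)/(i,i+4)
distance signatures (ideal α ≈ 5.2/6.4 Å, ideal 3₁₀ ≈ 6.0/8.6 Å, windows
±~0.5 Å around these), β-sheet requires an extended residue
(d(i−1,i+1) > 6.2 Å) *plus* a nonlocal spatial bridge partner (< 5.5 Å Cα,
sequence separation ≥ 3) that is itself extended — so an isolated extended
chain is never sheet — and chain reversals (d(i,i+3) < 7 Å) without
helical geometry are turns.  It uses Cα coordinates only, so it cannot see
hydrogen-bond registers, bulges or bifurcated sheets.

## Contact maps and clustering

Contacts are strict `d(Cα,Cα) < 7.5 Å` (the boundary convention is a
choice; the cutoff itself is the standard one).  Clustering operates on
flattened upper-triangle contact maps of the *supported* conformers.
Because the clustered object is the predicted ensemble, whose members
appear with unequal populations, the PCA is weight-aware: weighted mean
centring and SVD of sqrt(w)-scaled rows, with k-means (fixed seed,
`n_init = 10`) receiving the same weights.  `k` is always user-chosen; a
silhouette helper exists but is never applied automatically.  The AB-loop
observable defaults to the Cα pair (17, 24), with the atom selectable.

## Order parameters

The weighted ensemble is expanded to exactly `total = 1000` frames by
largest-remainder apportionment (ties broken by index; any conformer with
`w ≥ 1/(2·total)` is guaranteed a copy), so counts are within one of
`total·w_i`.  iRED builds `M_ij = ⟨P₂(μ_i·μ_j)⟩` over frames from unit
N–H vectors (prolines and H-less residues excluded), diagonalises, sorts
eigenvalues descending (index tie-break) and attributes the **five**
largest modes to overall reorientation — the standard convention, since a
rigid body's `M` has rank ≤ 5; `S²_i = 1 − Σ_{m>5} λ_m (m_i)²`.  S² is
reported raw (small negatives are diagnostic); a clamp to [0, 1] is
available behind a flag.  At least six residues are required, otherwise
mode separation is undefined.

A practical caveat the tests make explicit: with independent per-residue
internal motions, the isotropic part of the motional covariance leaks
into the five retained modes at order `(1 − S²)·5/N` for `N` probed
vectors, so iRED converges to the model-free value only for large `N`.
The cone-model checks therefore use 150 probe vectors and 5,000 frames,
where the bias is within the ±0.05 band for semi-angles up to 60°.

## Validation metrics

Per-nucleus shift errors are `f(δ_reg) − f(δ_ref)` in scaled space; the
per-residue combined error defaults to the Euclidean norm over nuclei.
The additive written form of this quantity is preserved as
`norm="sum"` (sum of magnitudes — magnitudes, so the result remains a
norm: non-negative and zero iff all per-nucleus errors vanish).  Residues
missing a nucleus on either side are dropped from that nucleus only.  The
|ΔS²| track joins on the residue intersection and the association is
summarised by a Spearman rank correlation.

## Synthetic generators

All generators are pure functions of `(spec, seed)`.  Defaults describe
the desk-scale study conditions: 50 candidate conformers over 30 residues,
three active states with populations (0.5, 0.3, 0.2), and 20° cone motion.

*Backbones* are built by NeRF chaining of ideal internal coordinates from
a segment plan (helix/strand/3₁₀ at ideal dihedrals, coil drawn from broad
allowed regions), with H, O and Cβ placed by standard geometry, per-
conformer dihedral jitter (6°) and 0.03 Å coordinate noise.  A requested
pair distance (the AB-loop observable) is met by hinge rotation with a
vectorised angle scan.

*Shift tables* are a random-coil base per (residue type, nucleus) — a
small packaged table of representative literature-style values, not
load-bearing for any test — plus a static per-residue environment field
shared by all conformers (σ: 0.45/3.5/1.2/1.5 ppm for HN/NH/CA/CB,
emulating the sequence/context dispersion that gives real spectra their
range), plus the conformer's secondary-structure offset and per-conformer
Gaussian diversity (σ: 0.25/2.0/0.8/0.8 ppm).  The diversity term is what
makes the regression identifiable; the environment term is what keeps
library columns inside the scaling domain, as in real data.

*References* are convex mixtures of library columns plus per-nucleus
measurement noise (σ: 0.02/0.2/0.1/0.1 ppm).  The mixture is composed in
the projection space of the scaling and mapped back to ppm by a fixed-
point iteration (the scaling ranges derive from the reference itself);
this makes the noiseless ground truth exactly recoverable, since the log
map does not commute with ppm-space averaging.  The literal ppm-space
mixture is available as `mixture_space="ppm"`.

*Cone ensembles* draw per-residue vectors uniformly from spherical caps
about fixed random axes and apply one uniform random global rotation per
frame; the closed-form order parameter is `S² = [cos α (1 + cos α)/2]²`.

What the generators do **not** emulate: force-field-quality conformational
sampling, predictor systematic errors (the synthetic "predictor" is
unbiased by construction), ring-current and pH effects, sparse/ambiguous
assignments beyond simple omission, and anisotropic or correlated internal
motions.  Passing tests therefore demonstrate the correctness of the
estimator and statistics under the stated noise model, not the accuracy of
any particular shift predictor on real proteins.

## Problem sizes and determinism

Tests and the acceptance script run synthetic problems at desk scale
(libraries up to 200 conformers, 12–30 residues, 5,000-frame vector
ensembles), chosen so the full suite completes in well under a minute per
module while keeping every tolerance meaningful.  All randomness flows
from explicit seeds; k-means and the hinge search are deterministic given
the seed; eigen-decomposition ties are broken by index.

## Known limitations

- The regression assumes predictor errors are homogeneous across
  conformers; systematic predictor bias maps directly into the weights.
- Weight identifiability degrades when library columns are nearly
  collinear (structurally similar conformers split populations
  arbitrarily within the equal-residual set; the minimum-norm tie-break
  makes the reported split deterministic but not physically meaningful).
- The built-in secondary-structure assigner is Cα-geometric and
  approximate; use STRIDE/DSSP output where available.
- iRED S² for small residue counts carries the rank-5 leakage bias noted
  above; profiles from short constructs should be read accordingly.
- pH mismatch between prediction and experiment is recorded as metadata
  only and not corrected.
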