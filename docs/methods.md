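# Methods

This note records the models, conventions and design choices behind each
analysis stage, what the synthetic-data generator does and does not
emulate, and the numerical decisions that affect results.

## Coordinate model and superposition

Coordinates are Cartesian, in Å; frame times in ps; residue numbering is
1-based PDB `seq_id` (chains need not start at 1). Trajectories are assumed
whole and imaged — the package performs no periodic-boundary treatment, and
nothing is mass-weighted.

Rigid-body fits are unweighted least squares via the Kabsch SVD
construction with the determinant correction, so the returned rotation is
always proper (det = +1), including for planar and mirror-degenerate
inputs. Fit sets of fewer than three atoms or (near-)collinear geometry are
rejected: a collinear fit set leaves the rotation about the line
undetermined and downstream statistics would absorb an arbitrary spin.

RMSF and PCA use an iterated mean reference: frames are fitted to the first
frame, the mean structure is computed, frames are refitted to that mean and
the mean recomputed (two passes). This is standard essential-dynamics
practice and converges quickly; the reference is therefore self-consistent
rather than an arbitrary frame. Per-residue RMSF is the fluctuation of the
residue's Cα about its time-average position after superposition.

A caveat worth knowing: superposition removes six rigid degrees of freedom,
so for a system of N fitted atoms an isotropic jitter of width σ yields an
RMSF of σ√3·√(1 − 2/N) rather than exactly σ√3. Tests use systems large
enough for this bias to be negligible.

## gromos clustering

Clustering operates on a precomputed symmetric matrix of pairwise
superposed RMSDs (fit and measure atoms are the same combined selection,
mirroring a gmx-cluster-style atom list). The iteration counts, for every
unassigned frame, its unassigned neighbors within the cutoff; the frame
with the most neighbors becomes a center and it plus its neighbors form a
family; repeat until all frames are assigned. Ties on neighbor count are
broken toward the lower frame index so the partition is deterministic.
Families are reported largest first. The default cutoff is 1.8 Å.
Replicas are concatenated before the matrix is built; frame provenance is
the concatenation order.

## Essential-dynamics PCA

The 3N×3N covariance of Cα displacements (after the iterated-mean fit) is
diagonalized exactly with `eigh`; eigenvalues are clipped at zero (the
matrix is PSD up to round-off) and sorted descending, and each
eigenvector's sign is fixed by making its largest-magnitude component
positive, so the decomposition is reproducible bit-for-bit. The
per-residue projection of mode k is the Euclidean norm of the mode's
(x,y,z) sub-vector at each residue; squared projections sum to one. For
hinge-type motions the recommended fit set is the static core: fitting on
all Cα folds part of the moving block's net translation into the removed
center of mass and understates the mode's variance share.

## Cross-correlation (DCCM)

For residues i and j the correlation is the Pearson coefficient of the 3-D
Cα displacement vectors: the numerator is the time-averaged dot product of
displacements from the time mean, the denominator the geometric mean of the
displacement variances. There is no per-component (9-entry) variant. The
fit set for the preceding superposition defaults to the analyzed Cα set.
Replicas are pooled before averaging (a per-replica mode can be had by
analyzing replicas separately). A residue whose displacement variance falls
below 1e-15 Å² (superposition round-off scale) is reported by name as
zero-variance rather than producing NaNs.

Classification uses strict inequalities — |C| must exceed the threshold
(default 0.6) — and excludes the diagonal. Region block summaries average
C_ij over all cross pairs of two named, disjoint residue ranges.

## SASA and contacts

Shrake–Rupley with a deterministic golden-section spiral of n points
(default 960) on each atom's expanded sphere (vdW + probe, probe default
1.4 Å, Bondi radii bundled). A surface point is buried if strictly inside
any other atom's expanded sphere; points exactly on a neighbor's surface
(the coincident-spheres degenerate case) are credited to the lower-index
atom rather than left to floating-point round-off. Hydrogens are excluded
by default. Group SASA is the per-frame sum over the group's atoms computed
in the context of the whole structure; a stride parameter subsamples frames
since SASA is the costliest stage.

Contacts: two residues are in contact in a frame iff any inter-atom
distance between the two selections is strictly below the cutoff (default
4.0 Å, heavy atoms by the caller's selection); the frequency of occurrence
is the fraction of frames in contact, and pairs never in contact are
omitted from the table.

## Protein structure network

`n_ij` is the time-averaged count of side-chain heavy-atom pairs (one atom
from each residue) within the 4.5 Å cutoff — fractional values are
expected; glycines simply never contribute. The interaction strength is
`I_ij = n_ij/√(N_i N_j)·100` (percent) and pairs with `I_ij > I_min` become
edges. `I_min` deliberately has no default: it sets the sparsity of the
graph and must be chosen per study.

Normalization factors come in two modes. *User* mode takes an explicit
table per residue type. *Empirical* mode (default) computes, for each
residue type, the maximum over residues of that type of the residue's total
time-averaged side-chain contact pairs (Σ_j n_ij), floored at 1; the table
is computed once per trajectory and written to the report so runs are
auditable. Empirical factors rescale all strengths of a residue-type pair
by a constant, so rankings within a trajectory are unaffected by the mode.

Hubs are nodes with degree ≥ min_degree (default 3). Communities are the
connected components of the filtered graph (isolated nodes are not
communities), largest first. Communication paths are shortest by hop count,
with ties broken by the larger minimum edge strength along the path (the
weakest link limits communication) and then lexicographically; a
disconnected pair returns an explicit "disconnected" result. Graph
difference requires the same residue universe and reports edges unique to
each graph and shared.

## Synthetic trajectories and their ground truth

The generator emulates the *phenomenology* a trajectory-analysis pipeline
must recover, not physics. The base fold is a gentle helix (Cα every 3.8 Å
along the axis, helix radius 2 Å, period 10 residues) with 0–4 side-chain
carbon pseudo-atoms per residue at 1.5 Å spacing. The helix exists for a
numerical reason: a straight chain is collinear, the rotation fit about the
chain axis would be undefined, and noise would inject a large random spin
into every frame.

Planted features, all driven by one seeded generator (same spec ⇒
bit-identical output):

* **Correlated regions.** A region pair with target Pearson ρ shares a
  scalar latent factor along the chain axis; the per-residue weights are
  made mean-free over all Cα (so the superposition's translation cannot
  touch the field) and the axis choice makes the field torque-free (so the
  rotation fit cannot either). The amplitude is the positive root of a
  quadratic in a², making the planted population correlation exact; the
  realized sample correlation is recorded in the ground truth. Each region
  may appear in only one plan entry; multiple entries must be balanced
  (equal-size, anti-correlated) pairs, because unbalanced fields leak a
  shared background term whose joint effect has no closed form.
* **Sub-states.** Frame states are sampled i.i.d. by occupancy. A state
  reshapes the surface patch's side chains: a contraction factor scales
  the side-chain offsets toward the Cα, plus an optional rigid translation.
  The closed state of the TPP1-like preset contracts to 0.25 and tucks 2 Å
  toward the helix interior, which both buries the patch (SASA roughly
  halves) and separates the states by ~2.5 Å in the preset cluster metric.
  A pure rigid translation was tried first and rejected: in this toy fold
  every translation direction *increases* patch SASA, because the extended
  bundle is already occluded by its neighbors.
* **Hinge mode.** An optional residue block moves coherently along an axis
  with Gaussian amplitude; the normalized 3N mode vector is recorded.
* **Contacts.** Each planned pair toggles per frame (Bernoulli) between a
  planted 3.0 Å and 9.0 Å atom distance, realized by overriding one
  side-chain atom position after noise; the event series is recorded.
* **Noise.** Isotropic Gaussian σ (default 0.1 Å) on every atom.

What the generator does *not* emulate: bonded geometry and excluded volume,
realistic side-chain rotamers, solvent, force-field energetics, kinetics
(frames are exchangeable, not time-correlated). Passing tests therefore
demonstrate that the analysis operations are correct and recover planted
signals of realistic magnitude — not that the pipeline's scientific
conclusions transfer to any particular real protein.

The TPP1-like preset is bookkeeping only: 130 residues numbered 90–219,
regions I = 123–141, II = 158–178, III = 207–219, patch = {168, 169, 171,
183, 212, 215}, one anti-correlated region pair (I, II, ρ = −0.5), a 70/30
open/closed equilibrium and one 0.4-probability contact. No structural
realism is claimed.

## Problem sizes and numerical choices

* Planted-correlation recovery is validated at 5000 frames on a 60-residue
  chain (10 seeds per ρ); sampling error of a block mean is well under the
  ±0.05 acceptance band there.
* The hinge-recovery check uses a 30-residue chain with a 10-residue block
  at 10:1 amplitude over noise, fitted on the static core; the analytic
  variance fraction A²n_b/(A²n_b + 3Nσ²) ≈ 0.917 sits above the 0.9
  criterion by construction.
* Sub-state recovery clusters 400 frames (sizes checked against binomial
  3σ); contact recovery uses 2000 frames (±0.02 ≈ 2σ binomial).
* Distance cutoffs are strict (<); cluster neighbor tests are inclusive
  (≤ cutoff), matching the "within threshold" reading.
* CSV outputs use fixed float formatting and the run log contains no
  timestamps, so identical inputs reproduce reports byte-for-byte.
* Degenerate inputs: single-frame trajectories are rejected for RMSF/PCA/
  DCCM; empty selections raise naming the unmatched ranges; asymmetric
  matrices are rejected by clustering and PCA; `I_min < 0` and
  classification thresholds outside (0, 1) are rejected.

## Known limitations

* The gromos implementation materializes the full frames×frames matrix;
  with the batched-SVD pair fit this is comfortable to a few thousand
  frames but is quadratic in memory and time beyond that.
* Empirical PSN normalization is ensemble-dependent: comparing two systems
  is cleanest with a shared user-supplied table (the difference report
  compares edge sets, which is robust to a common rescaling only within a
  residue-type pair).
* "Secondary-structure Cα" selections are user-supplied residue ranges;
  there is no DSSP-style assignment.
* SASA point counts below a few hundred bias areas of small exposed caps;
  the default 960 keeps the isolated-sphere error well under 1%.
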