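# Methods

## Scope and data model

`loopshape` operates on *conformer ensembles*: ordered sets of structures
(homology models or trajectory frames) sharing one atom topology, held as
multi-model PDB on disk. A loop is specified declaratively (`LoopSpec`) by
its chain, two anchor residues and one or more reference residues, and is
resolved per conformer into concrete coordinate sets (`LoopSelection`).
DOPE and SOAP pseudo-energies are consumed as externally produced inputs
(TSV); the package never computes scoring functions itself.

Conventions adopted where the underlying definitions admit choices:

* **Loop membership.** The loop consists of the residues *strictly between*
  the anchors; anchors are attachment points — fixed stems, not loop. A
  flag (`include_anchors_in_loop`) flips this, since published residue
  counts for loops sometimes include the anchors.
* **Anchor centroid** = unweighted midpoint of the two anchor Cα atoms.
* **Reference centroid** = mean Cα position of the named reference residues
  (a single residue's "centroid" is its Cα). Generalising from one
  conserved Trp to any residue set costs nothing and covers more systems.
* **Heavy atoms** = all non-hydrogen atoms; hydrogens are dropped on read.
  `loop_prot_sh` and `loop_prot_v2a` therefore use heavy atoms; a
  `ca_only` switch restricts them to Cα atoms for Cα-trace fixtures.
* **`loop_max_cons_distance_bb`** reads "consecutive" as the bonded
  backbone pairs N(i)–Cα(i), Cα(i)–C(i), C(i)–N(i+1). A max over *all*
  backbone pairs would essentially duplicate `loop_max_distance`; the
  bonded reading instead flags chain breaks and distorted geometry. A pure
  Cα trace falls back to consecutive Cα–Cα distances.
* **Residue numbering** is author numbering, unaltered. Insertion codes in
  the loop range are rejected rather than silently renumbered. For
  alternate locations the highest-occupancy conformer is kept.

Degenerate cases are explicit: a rank-deficient (coplanar/collinear) loop
gives hull ratio 0 with a warning; a selection with no non-loop atoms gives
`loop_prot_sh = NaN`; loops shorter than 4 residues have no i..i+3 ladder
and require an explicit `allow_short`. Undefined values are never silently
zero, and all-NaN columns are dropped before any multivariate step.

## Representative selection

Columns are centred and scaled to sample (ddof = 1) standard deviation 1 —
required because the features mix Å-scale geometry with unitless
pseudo-energies. PCA keeps the smallest leading set of components whose
cumulative explained variance reaches `variance_retained` (default 0.95);
each component is sign-fixed so its largest-magnitude loading is positive,
making loadings reproducible across BLAS builds. K-means (k-means++, best
of `n_init = 10` restarts, fixed seed) partitions the reduced scores.

The per-cluster representative is the **medoid** — the member minimising
the sum of Euclidean distances to its cluster's members in the reduced
space, ties broken to the lowest row index. "Median model" is not
well-defined in multivariate space; the medoid is the standard analogue and
is guaranteed to be an actual ensemble member. The number of clusters is
not estimated automatically: k = 3 by default (three conformational
families is the common working hypothesis for hinge-like loops), with an
optional silhouette sweep over k = 2..10 reported for guidance only.
DOPE/SOAP join the feature block by default (`use_scores`), since the
selection is meant to spread candidates over geometry *and* quality;
`--geometry-only` excludes them.

## Flexibility classification

Dispersion is measured as RSD = 100·sd/mean (%) per geometric descriptor
(sample sd; scores are excluded — RSD is meaningless for signed
pseudo-energies, and an RSD is only computed for columns with positive
mean). The decision rule: among the arch-shape parameters, `ach_ach_dist`
is high-variance for static loops too (the anchor region is exactly where
static-loop models differ), so it carries no vote; the verdict is

* **flexible** — ≥ 2 of {`loop_anchor_mean`, `loop_ref_min`,
  `loop_max_distance`} have RSD > threshold (default 8 %),
* **static** — none do,
* **indeterminate** — exactly one does.

The threshold and the 2-of-3 rule are this package's operationalisation of
the observed static/flexible RSD contrast; both are configurable, and the
full RSD table plus the rule trace are always reported so a user can apply
their own cut. RSD is invariant under rigid motion and uniform scaling of
the input coordinates, which the tests assert end-to-end.

## State analysis

Frames from all runs are pooled and described by the four arch-shape
parameters. They are standardized by the pooled mean/sd (the runs must be
clustered in one shared space; raw Å values would let `loop_anchor_mean`
and `loop_max_distance` dominate `loop_ref_min`), then K-means with fixed
seed assigns k states. States are named by ascending centroid
`loop_ref_min`: the state closest to the reference centroid is **closed**
(loop wrapped towards the active site), the farthest **open**
(solvent-exposed), the middle **semi-open**; for k ≠ 3 ordinal names are
used. Occupancy is the per-run fraction of frames per state; transitions
are raw counts of consecutive frame pairs (no dwell-time smoothing — a
possible extension). Trajectories are accepted as multi-model PDB or as
precomputed descriptor TSVs; native MD trajectory formats are out of scope.

Structure averaging is the per-atom arithmetic mean over models (optionally
after Kabsch superposition onto the first model), and RMSD uses the
least-squares proper rotation (reflections excluded), via
`scipy.spatial.transform.Rotation.align_vectors`.

## Synthetic generator

The generator produces the *conditions* the pipeline claims to handle, not
realistic protein physics. Loop Cα atoms lie on a circular arc between
anchors fixed at (0,0,0) and (d,0,0) (d = 10 Å default), solved so every
consecutive chord equals the Cα spacing (3.8 Å); pseudo N/C atoms sit
±1.2 Å along the local chain tangent with a fixed 0.25 Å out-of-plane
pucker (a perfectly coplanar loop would make the hull descriptor
degenerate, which real backbones never are); the reference residue sits
8 Å off-plane on the closed side; an optional 60-atom hemispherical shell
≈ 6 Å clear of the arc provides protein context.

Per-model variation:

* `sigma_arch` (rad) — rotation of the arc plane about the anchor–anchor
  axis; the flexible loop's swing.
* `sigma_radial` — fractional jitter of the arc radius. The arc is
  *re-solved* at the scaled radius, keeping chord lengths exact, so the
  loop endpoints drift near (not off) the fixed anchors like a hinging
  loop; consecutive Cα spacing is preserved exactly on every template arc.
  Additive positional jitter is applied after the template is built, so
  the spacing guarantee applies to the noise-free template.
* `sigma_anchor` (Å) — per-axis jitter on the anchors and their adjacent
  loop residues; the static loop's anchor-region variability.

Regime presets: **static** = (σ_arch 0.02 rad, σ_anchor 0.6 Å) — the shape
holds, the anchor separation varies (its RSD lands near 8–9 %, above the
threshold, reproducing the signature that anchor distance disperses even
in static loops); **flexible** = (σ_arch 0.6 rad, σ_radial 0.15) — three
arch parameters disperse well past 8 %. Pseudo-DOPE/SOAP are a labelled
toy: mean loop-Cα distance to the protein-context centroid plus N(0, 0.1)
noise, so "lowest DOPE" prefers compact conformers; they exist to exercise
score columns, not to imitate statistical potentials.

State-switching series use per-state arc orientations (default −1.2, −0.6,
0.0 rad from closed to open) *and* per-state radius scales (default 0.92,
1.0, 1.08): a purely rotational state change would leave
`loop_anchor_mean` and `loop_max_distance` mathematically invariant
(rotation about an axis through the anchor midpoint), concentrating all
signal in one descriptor, whereas observed loop states differ in several
parameters at once; the compact-closed/extended-open coupling restores
that. Label sequences spend largest-remainder-rounded per-state frame
budgets in geometric dwell segments (mean `mean_dwell` = 20 frames), so
empirical occupancies match the target mix to rounding accuracy while
dwell structure and transitions remain stochastic. Ground-truth labels are
returned for recovery tests.

What the generator does **not** emulate: Ramachandran statistics, side
chains, sterics/clashes, solvent, or the conformer distribution of any real
modelling engine. Passing tests therefore demonstrate the *procedural*
correctness of descriptors, selection, classification and state assignment
under controlled geometry — not predictive accuracy on real proteins.

## Numerical choices

* Nearest-neighbour `loop_prot_sh` uses a k-d tree and is tested bit-equal
  to brute force; hull volume/area comes from Qhull with an explicit
  rank-3 check first.
* PCA is validated in tests against an `eigh` eigendecomposition of the
  sample covariance; K-means determinism is fixed by seed.
* Sample (ddof = 1) standard deviations throughout; at ensemble sizes of
  10³–10⁴ the ddof choice is negligible but it must be pinned for exact
  tests.
* Medoid and lowest-DOPE ties break to the first/lowest index,
  deterministically.
* Arc solving uses Brent root-finding on the chord-sum equation to 1e-13;
  infeasible anchor separation (> chord sum) raises with the feasible
  range.

## Problem sizes

The test suite and acceptance script run the pipeline at sizes chosen to
exercise every statistical claim while staying desk-scale: 100 random
selections for oracle agreement, 100 rigid motions, a 1,000-model
three-regime ensemble for selection, 100 replicate ensembles of 200 models
per regime for classifier recovery (40 per regime in the test suite), and
5,000-frame trajectories for state recovery. Full-scale reproduction of
ensemble statistics from 10,000-model modelling runs or microsecond MD is
out of scope: those inputs require external engines, and this package's
claims about them are limited to faithfully computing the statistics once
such data are supplied as multi-model PDB or descriptor tables.

## Known limitations

* Insertion codes and mmCIF input are unsupported; PDB only.
* One loop per analysis; multi-loop coupling is not modelled.
* The static/flexible rule is a threshold heuristic, not a significance
  test; formal dispersion statistics are intentionally out of scope.
* Transition counts are raw consecutive-frame counts; no Markov-state
  estimation or lag analysis.
* The 8 % threshold, k = 3 and the 0.95 variance cut are defaults with
  clear provenance but no universal justification; all are exposed as
  parameters.
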