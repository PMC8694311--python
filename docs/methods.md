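# Methods

This note documents the models, numerical choices, and limitations behind
`ensemblefit`, in the order data flows through the package.

## NOE buildup calibration (`noe_pipeline`)

The package works in the isolated spin-pair approximation: each proton
pair's NOESY cross peak grows linearly with mixing time in the initial-rate
regime, with rate σᵢⱼ ∝ ⟨rᵢⱼ⁻⁶⟩. Intensities are first reduced to the
geometric-mean normalized form η = √(cross₁·cross₂/(diag₁·diag₂)), which
cancels common instrumental scale (tested as a property) and is symmetric
in the two cross peaks. σ is the least-squares slope of η vs mixing time
*through the origin* — η(0) = 0 holds by construction of the normalization,
and an intercept would only absorb noise; a free-intercept fit exists for
diagnostics but never feeds calibration. Curves are accepted when
r² > 0.95 (conventional definition, 1 − SS_res/SS_tot about the mean) and
σ > 0.

Distances follow from `r = r_ref (σ_ref/σ)^(1/6)` against an internal
geminal methylene reference at r_ref = 1.78 Å. Only rate ratios enter, so
any common scale on the rates cancels (tested). Choices where the
literature is silent or conventions vary:

* **Restraint tolerance: ±10% of r** — matches the noise level used in the
  validation protocol; per-restraint experimental uncertainties are rarely
  available for this kind of data set. Configurable.
* **5.5 Å cap** — the r⁻⁶ dependence makes longer distances ill-determined;
  capped restraints are flagged and excluded from fitting by default rather
  than silently used.
* **Missing/zero diagonals** — that mixing time is dropped, never imputed;
  a pair left with fewer than three points yields no curve.

No relaxation-matrix (spin-diffusion) treatment is attempted; the linear
model is the regime the calibration equations assume.

## Back-calculated observables (`observables`)

Distances average over the ensemble as r_eff = (Σ wᵢ rᵢ⁻⁶)^(−1/6) (slow
internal motion, the averaging NAMFIS-type analyses use); an r⁻³ option
exists and is off by default. Degenerate proton groups (methyls,
methylenes without stereoassignment) are handled by r⁻⁶ summation over the
equivalent partners before the −1/6 power.

Couplings average linearly: J_calc = Σ wᵢ J(φᵢ) with
J(θ) = A cos²θ + B cosθ + C. The default coefficient set is the
Vuister–Bax HN–Hα calibration (A = 6.51, B = −1.76, C = 1.60 Hz,
θ = φ − 60°), the de facto standard for ³J(HN–Hα); a Pachler-type set
(9.5/−1.6/1.8, θ = dihedral directly) ships for Hα–Hβ couplings. The
choice is per-restraint configurable and recorded in solution metadata.
The fit uses J values directly rather than converting them to dihedral
ranges first — equivalent information without extra cutoffs; this is a
deliberate design decision and may differ from workflows that fit φ
windows.

## Population fitting (`ensemble_fit`)

Objective: Σ over restraints of ((obs − calc(w))/tol)², distances and
couplings on equal footing through their tolerances (the exact weighting
used by historical NAMFIS implementations is not published; ours is
recorded in output metadata). The optimizer is SLSQP over the simplex
(box bounds [0,1] plus an equality constraint on the sum) with an analytic
gradient; the r_eff(w) map makes the distance terms non-convex, so the
solver restarts from the uniform point plus 49 seeded Dirichlet(1) draws
(`n_starts=50` default; `random_state` should always be set). Convergence
controls: `ftol=1e-12`, `maxiter=500`. The best start wins; a
non-converged result is still returned, flagged via `converged_`.

Model-size control is a 1% weight floor with prune-and-refit, repeated
until stable — mirroring the reporting convention of ensemble analyses
(members under 1% are not reported) rather than an information criterion.
Ties between geometrically identical members are broken by the optimizer's
landing point; duplicated geometries split weight arbitrarily among
themselves while the total per unique geometry is preserved (tested).

**Validation** re-fits under (a) uniform multiplicative ±10% noise on every
observed value, per trial, and (b) leave-one-restraint-out jackknifing,
recording full-pool weight vectors and the maximum weight shift; all trials
derive from one seed and are bit-reproducible. A calibration caveat the
test suite encodes: at the 10% noise level a single trial can legitimately
reassign weight between conformers 1–2 Å apart (the restraints move by a
full tolerance), so quantitative per-member stability is asserted at the
2% noise regime, and only qualitative retention (weight above the floor in
most trials) at 10%.

**Bioactive matching** (`match_reference`) superposes each retained member
onto a reference structure over a chosen atom selection and reports members
with RMSD ≤ 0.7 Å with their weights. The comparison uses the same mass
weighting as clustering by default, switchable, since published analyses do
not always state which was used for the reference comparison.

## Clustering (`clustering`)

Greedy Daura/GROMOS loop on the pairwise post-superposition RMSD matrix:
repeatedly extract the structure with the most neighbors within the cutoff
(plus itself) as a cluster. Ties on neighbor count break toward the lowest
input index — the original description is silent and determinism is
required. Extraction order yields non-increasing cluster sizes, so clusters
are reported in size order with singletons counted as clusters. The
default criterion is mass-weighted RMSD at 0.7 Å over the macrocycle
selection; `cutoff_sweep` reports cluster counts and largest-cluster
fractions across cutoffs (the count is not guaranteed monotone for a greedy
scheme in general, though it is on the well-separated planted sets used in
tests). Cluster sizes are reported both as counts and trajectory
fractions.

## Torsion reports (`dihedral_analysis`)

Wedge histograms: ten 36° bins over (−180°, 180°], edges anchored at
−180° exactly, intervals half-open (lo, hi] — the anchor and boundary rule
are conventions fixed for determinism. Each retained member (weight ≥ 1%)
contributes its weight to the wedge containing its dihedral, so heights sum
to the retained weight. Reference angles overlay as 1°-wide markers; −180°
maps to the +180° position by the half-open rule. Rotamer classes:
g+ = (0°, 120°], g− = [−120°, 0°), anti = remainder — note 0° itself falls
in *anti* under this convention. Two ensembles' histograms are compared by
total variation distance per torsion (published comparisons are typically
visual; a number is more testable).

## Pool hygiene (`pool_tools`)

Energy window: keep entries with E − E_min ≤ 42 kJ/mol, boundary inclusive
and shift-invariant. Deduplication: greedy scan at a 2.0 Å RMSD cutoff,
lowest-energy-first when energies exist (keep the low-energy representative
of each redundancy class), input order otherwise. The guaranteed property
is that every dropped entry lies within the cutoff of some survivor;
survivors are *not* guaranteed pairwise farther than the cutoff (greedy
packing), and both facts are stated and tested as such. The pipeline order
is fixed: filter, then dedupe. Superposed comparison is the default, with
an in-place option for pre-aligned pools.

## Synthetic studies (`synthetic_data`)

The generator emulates the experimental design the package targets, with
every quantity derived from one seed:

* **Template** — a hard-coded 31-atom, four-residue cyclic-peptide-like
  fragment (backbone N/H/CA/HA/C/O per residue, a two-carbon side chain
  with a geminal HB pair on residue 2, a side chain on residue 4), built by
  NeRF chain extension from ideal internal coordinates. The geminal
  HB2–HB3 separation is 1.780 Å by tetrahedral construction — the internal
  reference. Ring closure of the bridge is *notional*: conformers are
  rebuilt as an open chain, which preserves everything the inference
  machinery sees (distances, dihedrals, clashes) without a ring-closure
  solver. Residue-2 chirality is switchable (+1/−1), giving epimeric pools
  whose χ-type torsions mirror.
* **Pools** — torsions sampled from peptide backbone basins
  ((−75°,145°), (−65°,−40°), (−140°,135°), (60°,45°)) and staggered χ
  basins (±60°, 180°), each with 12° Gaussian jitter; conformers with any
  non-bonded pair (graph distance > 2 bonds) closer than 1.5 Å are
  rejected. The first pool member is always the unperturbed template.
* **NOESY** — σ per pair proportional to the planted ensemble's ⟨r⁻⁶⟩, the
  constant fixed by forcing the reference pair to σ_ref = 0.3 s⁻¹;
  cross = diag·σ·t·(1+ε) with ε ~ U(±noise), diagonals constant at 10⁵ so
  the linear-buildup model is exact at zero noise (an exponential diagonal
  decay knob exists in principle but acceptance-level tests isolate the
  implemented equations). Schedule: 100–700 ms in 100 ms steps.
* **J tables** — linear Karplus averages over the planted members plus
  Gaussian noise (σ in Hz).
* **Planted truth** — default study: pool of 20, four members at
  40/30/20/10%, the 20% member designated the "bioactive" reference. The
  noisy harness uses 2% intensity noise and 0.15 Hz J noise (~2% of a
  typical coupling).

What passing tests show — and what they do not: the synthetic data obey the
exact forward model the package inverts (linear buildups, no spin
diffusion, no peak overlap, complete assignment, a pool that genuinely
contains the true members). Recovery there demonstrates correctness of the
equations, optimizer, and plumbing, not performance on real spectra, where
assignment errors, spin diffusion, and pool incompleteness dominate.

## Problem sizes and determinism

Default study sizes (20-conformer pools, 12+4 restraints, 50 noisy
re-draws, 30-structure clustering sets over 20 seeds) keep the full test
suite and the acceptance script in the tens-of-seconds range while leaving
the weight-recovery problem genuinely underdetermined-looking (20 unknowns,
16 restraints) — uniqueness comes from the simplex constraints, which is
the regime the method lives in. All random draws flow through
`numpy.random.SeedSequence` children of a single scenario seed; fits are
deterministic given `random_state`.

## Known limitations

* Isolated spin-pair approximation throughout; no relaxation-matrix back-calculation.
* No symmetry-corrected RMSD: atom correspondence is fixed by construction,
  so symmetric side chains would need pre-matched naming.
* The greedy deduplication and Daura loops are O(n²) in pool size; pools of
  tens of thousands of snapshots should be strided first (`--stride`).
* The synthetic template is a stand-in geometry, not a parameterized force
  field: energies are not simulated, and pool entries carry energies only
  when supplied externally.
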