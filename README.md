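# ensemblefit

Solution-ensemble deconvolution of flexible molecules — macrocyclic
peptides in particular — from NMR observables.

A flexible ligand in solution is not one structure but a population-weighted
ensemble, and the protein-bound ("bioactive") conformation may be one of its
minor members. `ensemblefit` takes the two standard solution observables —
NOESY buildup intensities and vicinal scalar couplings (³J) — together with
a pre-computed conformer pool, and answers: *which conformers are populated,
and at what molar fractions?* It also provides the simulation-side
counterpart: Daura/GROMOS clustering of snapshot sets and RMSD
cross-comparison against the fitted ensemble, plus population-weighted
torsion (wedge) histograms for comparing conformational preferences.

## The model

**NOE calibration.** Cross/diagonal peak quartets are reduced to
normalized intensities η = √(cross₁·cross₂ / (diag₁·diag₂)). In the
initial-rate (isolated spin-pair) regime η grows linearly with mixing time;
the slope σᵢⱼ is fit through the origin and accepted when r² > 0.95.
Distances follow from an internal reference pair of known separation
(geminal methylene protons, 1.78 Å):

    r_ij = r_ref · (σ_ref / σ_ij)^(1/6)

**Ensemble back-calculation.** For candidate weights **w** on the simplex,
distances average as ⟨r⁻⁶⟩-weighted effective distances,
r_eff = (Σᵢ wᵢ rᵢ⁻⁶)^(−1/6), and couplings average linearly through the
Karplus curve J(θ) = A·cos²θ + B·cosθ + C (Vuister–Bax HN–Hα coefficients
by default, θ = φ − 60°).

**NAMFIS-style fit.** The weights minimize the tolerance-scaled SSE
Σ_k ((obs_k − calc_k(w))/tol_k)² over the simplex (SLSQP, analytic
gradient, 50 seeded multi-starts). Members below a 1% floor are pruned and
the fit repeated. The solution is validated by re-fitting under 10% random
noise on every observation and under leave-one-restraint-out jackknifing,
and by the observed-vs-back-calculated table.

**MD-side analysis.** Conformer/snapshot sets are clustered with the greedy
Daura algorithm (most-neighbors center extraction at a mass-weighted RMSD
cutoff, 0.7 Å default) and cluster centers are cross-compared to the fitted
ensemble members (comparable ⇔ RMSD ≤ 0.7 Å).

Everything is testable end to end because the package ships a synthetic
study generator with known ground truth: a 31-atom cyclic-peptide-like
template rebuilt at sampled torsions, a planted sparse ensemble, and NOESY/J
tables simulated from the same equations run in reverse.

## Worked example

Generate a noiseless synthetic study (20-conformer pool, four planted
members at 40/30/20/10%), calibrate, fit, and cluster:

```bash
ensemblefit synth --seed 42 --pool-size 20 -o demo
ensemblefit calibrate --peaks demo/peaks.csv --ref-pair HB2-HB3 -o demo/restraints.csv
ensemblefit fit --pool demo/pool.pdb --restraints demo/restraints.csv \
    --j demo/jtable.csv --seed 7 -o demo/solution.json
ensemblefit cluster --traj demo/pool.pdb --cutoff 0.7 -o demo/clusters.json
```

which prints

```
wrote synthetic study to demo
12 restraints written (0 curves rejected)
sse=8.703e-05; ensemble: conf_000=40.0%, conf_001=30.0%, conf_003=10.0%, conf_008=20.0%
19 clusters; largest holds 10.0% of 20 structures
```

The fit recovers exactly the planted members (`demo/truth.json` lists
`conf_000/001/008/003` at 40/30/20/10%) with weights right on the planted
values and a residual SSE near zero — at zero noise the twelve calibrated
distances plus four couplings identify the planted ensemble uniquely. The
cluster line shows the same pool is geometrically diverse (19 clusters of
20 members at 0.7 Å), i.e. recovery is not an artifact of redundant
geometries.

The same workflow is available as a library; see `ensemblefit.NamfisFitter`
(a scikit-learn-style estimator: `fit(pool, distance_restraints,
j_restraints)`, fitted attributes `member_ids_`, `member_weights_`,
`sse_`), `ensemblefit.daura_cluster`, `ensemblefit.wedge_histogram`, and
the `ensemblefit.synthetic_data` module.

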