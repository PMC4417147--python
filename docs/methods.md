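# Methods

`chromens` infers an ensemble of 3D chromosome conformations from 3C-based
interaction-frequency data by combining a polymer-physics prior with a
Gaussian restraint likelihood under a Bayesian model, solved with an
EM-style alternation between structure optimisation and nuisance-parameter
grid search.  This note records the model, its assumptions, the numerical
choices, and what the synthetic benchmarks do and do not demonstrate.

## Chain model and conformational energy

A chromosome is a linear chain of `n` segments — one per restriction
fragment — joined at `n + 1` end points `s_1 … s_{n+1}`.  Work is done in
reduced units: length unit = 30 nm (the excluded-volume size δ), energy
unit = kBT.  At 300 K these reproduce the SI values kBT ≈ 4.1e−21 J,
k_s ≈ 2.3e−3 J/m², k_θ ≈ 1.7e−20 J/rad².

The conformational energy is

    E = Σ_i ½ k_s (l_i − l_i0)²                        (stretching)
      + Σ_i ½ k_θ θ_i²                                 (bending)
      + Σ_{i<j} 4ε[(δ/d_ij)¹² − (δ/d_ij)⁶ + ¼]·1[d_ij < 2^{1/6}δ]   (WCA)

with defaults k_s = 500 kBT/δ², k_θ = 4 kBT/rad², ε = 1 kBT.  The rest
length of a segment is its base-pair count divided by the fibre packing
density (130 bp/nm) and by the 30 nm length scale, so a 3 900 bp fragment
has rest length 1.  θ_i is the planar angle between consecutive bond
vectors, computed as a clamped arccos; a dihedral is not defined for two
vectors, so the bending term is the standard discrete worm-like-chain form.
The Weeks–Chandler–Andersen (WCA) term is the Lennard–Jones potential
truncated and shifted at 2^{1/6}δ: purely repulsive, continuous at the
cutoff, and summed over **all** end-point pairs including adjacent ones
(the stretch term dominates bonded pairs anyway).  A coincident pair maps
to `+inf` energy rather than an exception so optimisers can reject the
state.

Consequence worth knowing: segments shorter than ~2^{1/6}δ ≈ 34 nm of fibre
(≈ 4.4 kb) are inflated by the WCA repulsion between their own end points —
their realised bond lengths sit near δ rather than at their nominal rest
length.  This is a property of the energy model, not a bug, and it is why
the conversion scale is calibrated against realised chain statistics (below).

The analytic gradient of all three terms is implemented and verified against
central finite differences (max relative error < 1e−4 on batteries of random
chains); near-collinear angles use the stable limit θ/sin θ → 1.

## Restraints

Interaction frequencies convert to target distances through the power law
D = β·F^(−α).  The exponent α is a nuisance parameter estimated by EM; the
scale β is calibrated once per run and then held fixed, because letting the
scale float during the α search would make the two unidentifiable.  Pairs
with frequency at or below a floor yield **no** restraint: an unobserved
contact is censoring, not a measurement of a large distance.

Each restraint anchors at the two fragment midpoints: a ligation event
localises within a fragment, and midpoints keep the restraint symmetric in
its two fragments.  The likelihood of record i is Gaussian in distance,
with common standard deviation σ; with Jeffreys priors 1/σ and 1/α on the
positive nuisance parameters the per-structure log-posterior is

    L(S | D, σ, α) = −log σ − log α − E/kBT − (1/2σ²) Σ_i (D_i^S − D_i)² − m log σ.

σ doubles as the inverse weight between the data term and the energy prior:
1/(2σ²) is the data weight, and σ̂ absorbs model misfit (ensemble averaging,
conversion error) on top of measurement noise — it should not be read as an
estimate of assay noise alone.

## Ensemble and EM

An ensemble is k weighted conformations (k = 200 by default at full scale);
weights are the normalised per-member likelihoods, computed in log space
with log-sum-exp.  The EM objective is the ensemble likelihood Σ_i w_i L_i.

One iteration alternates:

* **E step** — every member is optimised by gradient ascent on its
  log-posterior at the current (α, σ), using a backtracking line search
  (initial step 1e−2 reduced units, halved until the objective improves,
  doubled after an accepted step, capped at 1).  Members are independent;
  the implementation runs them as one vectorised batch with per-member step
  sizes.  Weights and log-likelihoods are then recomputed.
* **M step** — grid search over (α, τ = 1/(2σ²)) maximising the ensemble
  likelihood with structures and weights fixed; targets are re-converted at
  each candidate α with β fixed.  A coarse 10-point scan per axis over
  α ∈ [0.1, 1.5], τ ∈ [0.1, 10] is followed by a 10-point fine scan inside
  the coarse cells bracketing the optimum.  Ties break toward smaller α,
  then smaller σ.  The landscape is single-peaked in practice, so the
  two-stage scan finds the same point as a dense scan to within one fine
  step (verified against a dense-scan oracle in the tests).

Convergence is declared when the relative change of the ensemble likelihood
drops below 1e−4 (default), or after 20 iterations with a logged warning.
The per-iteration trace records the ensemble likelihood, α, σ and the
Pearson correlation between ensemble-averaged back-computed distances and
the current targets.

### Initialisation

The pool of k starting conformations comes from overdamped Langevin
("Brownian") dynamics on the conformational energy,

    s ← s − (dt/γ)∇E + √(2 kBT dt/γ)·ξ,

started from a random walk with the segment rest lengths and confined to a
sphere (default radius: a quarter of the rest contour length) by radial
reflection.  Defaults dt = 1e−4, γ = 1, 50 000 steps; the deterministic
per-step displacement is clipped at 0.1 reduced units per component to tame
the d^−13 WCA force when noise pushes two beads very close.  The whole pool
propagates as one batch, and every source of randomness derives from a
single integer seed, so runs are exactly reproducible.

The nuisance parameters are initialised data-driven rather than by a blind
random draw: an M-step grid search over the uniform-weight Brownian pool
picks the (α, σ) whose target curve best matches the energy-equilibrated
starting geometry; β is then re-calibrated once at that α and the M step
repeated.  The alternative — α drawn uniformly over its grid with β
anchored at that draw — frequently produces target sets that no conformation
inside the confinement sphere can realise; the first M step then collapses
τ to its grid floor, the structures decouple from the data, and the EM
settles into a spurious fixed point.  Initialising from the pool starts the
search inside the basin the data support and removes the failure mode.

β calibration inside the run equates the mean converted adjacent-pair
distance with the mean adjacent **midpoint distance of the Brownian pool**
(a statistic of the prior ensemble).  The simpler anchor — the mean rest
length, exposed as `calibrate_beta` — is biased ~8 % high because thermal
bending and the WCA inflation of short segments contract realised adjacent
midpoint separations below the nominal rest length; that bias propagates
into α̂ at about −0.04.

## Validation machinery

* **k-fold cross-validation** partitions the restraint records (seeded,
  sizes within one of each other), reruns the full EM on each training set
  (including its own β calibration), and scores each held-out record by
  comparing the ensemble-weighted back-computed distance with the target
  converted at the **training** α̂ — the test fold never informs the model
  that predicts it.
* **Superposition** uses the Kabsch/SVD algorithm (via
  `scipy.spatial.transform.Rotation.align_vectors`), which returns a proper
  rotation, so mirror images are never matched; RMSD is computed from the
  superposed coordinates.  Ensembles align onto their highest-weight member
  (weight ties break to the lower index).
* **Locus queries** map a base-pair position to a 3D point by linear
  interpolation inside its containing fragment (cut sites map exactly to
  end points) and report the weight-averaged distance in nm.
* **Contact counting** reports fragment-midpoint pairs at least five
  segments apart in sequence whose ensemble-expected distance falls in
  45–100 nm.
* **Distance-vs-separation trend**: the expected spatial distance of every
  fragment pair against its genomic separation is fitted with a saturating
  exponential d(s) = d_max(1 − e^{−s/s0}).  The curve family is a modelling
  choice — the observed behaviour is monotone rise with saturation, which
  this family captures with two interpretable parameters (plateau d_max in
  nm, crossover s0 in bp); it is swappable behind `fit_saturating_curve`.

## Synthetic instances

The generator emulates a yeast-chromosome-scale experiment: a chain of
(default) 20 fragments with log-uniform lengths in 1–40 kb, a ground-truth
**ensemble** of 5 conformations drawn by the same Brownian dynamics (20 000
steps — enough to decorrelate from the straight-walk start at these chain
sizes), and frequencies obtained by inverting the conversion law on
ensemble-averaged midpoint distances with Gaussian noise added in distance
space (truncated at 5 % of the mean so distances stay positive), default
σ* = 0.1 reduced units = 3 nm.  The default conversion exponent is
α* = 0.5; the default scale is "calibrated": β* equals the mean adjacent
ensemble distance, which centres adjacent frequencies near 1, mirroring a
normalised contact map.

What passing these benchmarks shows: the estimator recovers the conversion
exponent and the target-consistent geometry when the data were generated by
the model the method assumes.  What it does not show: robustness to count
overdispersion, coverage bias, unnormalised matrices, trans contacts or
mapping artefacts — real Hi-C preprocessing is explicitly out of scope and
the generator makes no attempt to mimic raw count statistics.  Because a
single conformation cannot realise population-averaged distances exactly,
σ̂ converges to the ensemble-averaging misfit (≈ 0.7–1 reduced units on the
default instance), far above the injected σ* — expected behaviour, and the
reason σ recovery is not a benchmark target.

## Operating configurations and problem sizes

Library defaults are the full-scale settings (k = 200, 50 000 Brownian
steps, 2 000 ascent steps).  The shipped benchmarks run at desk scale,
chosen so the whole battery completes in minutes on one CPU:

| study | instance | inference settings |
|---|---|---|
| headline recovery + convergence | default instance, seed 42 | k = 20, 5 000 Brownian steps, 6 000 ascent steps |
| 10-replicate median α error | fresh instance per seed | k = 6, 3 000 Brownian steps, 4 000 ascent steps |
| 5-fold cross-validation | noiseless instance | k = 6, 3 000 Brownian steps, 4 000 ascent steps |

At these sizes the headline run recovers α within one-to-two fine-grid
steps of α* = 0.5 with restraint correlation > 0.95, the replicate median
|α̂ − α*| sits below the fine-grid resolution (≈ 0.035), and noiseless
cross-validation pools above r = 0.97.

## Numerical choices and degenerate inputs

* Zero-length bonds and coincident excluded-volume pairs raise a
  degenerate-geometry error in the public API; inside line searches they
  map to −inf posterior so trial steps are rejected, and inside the
  stochastic integrator their force contribution is zeroed (the next noise
  kick breaks the tie).
* Weight normalisation is log-sum-exp throughout; weights validate to sum
  to 1 within 1e−9.
* Asymmetric input matrices are symmetrised by averaging with a warning;
  negative entries and ragged rows are hard errors with line numbers.
* Fragment indices are 1-based on disk, 0-based in memory; genomic
  coordinates are 0-based half-open everywhere.
* Structure files store nm (XYZ) or nm in the Å fields of a CA-trace PDB;
  round-trips are lossless to 1e−3 nm.

## Known limitations

* Gradient ascent is a local optimiser: a single structure started far from
  the data-consistent basin can stall in a tangled configuration.  The
  ensemble (k members, likelihood weighting) is the mitigation, not a
  guarantee.
* β fixed after calibration means residual scale error is absorbed by α̂;
  the pool-based calibration keeps this below one fine-grid step on the
  benchmark family, but data whose adjacent-pair frequencies are heavily
  corrupted would shift it.
* The Gaussian likelihood is the only noise model implemented; count-based
  likelihoods (e.g. Poisson) are out of scope.
* Single chromosome, cis contacts only; no matrix normalisation.
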