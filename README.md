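# chromens

Bayesian ensemble inference of 3D chromatin structure from 3C-based
interaction-frequency data.

Chromosome conformation capture (3C/Hi-C) assays measure how often pairs of
genomic loci are ligated together, averaged over millions of cells.
`chromens` turns such a fragment-level contact map into an **ensemble** of
weighted 3D conformations of the chromosome, for researchers who want
physically plausible structures rather than a single consensus model: the
population averaging and the dynamic nature of interphase chromatin make a
one-structure answer ill-posed.

## The model

The chromosome is a bead–spring polymer: a chain of `n` segments (one per
restriction fragment) with conformational energy

    E = Σ ½k_s(l_i − l_i0)²  +  Σ ½k_θ θ_i²  +  Σ_{d_ij < 2^{1/6}δ} 4ε[(δ/d_ij)¹² − (δ/d_ij)⁶ + ¼]

(stretching, bending, and purely repulsive Weeks–Chandler–Andersen excluded
volume; δ = 30 nm, energies in kBT).  Contact frequencies convert to target
distances via the power law `D = β·F^(−α)`, each restraint carries Gaussian
noise σ, and a Boltzmann prior `Pr(S) ∝ exp(−E/kBT)` plus Jeffreys priors
on (σ, α) give the per-structure log-posterior

    L(S | D, σ, α) = −log σ − log α − E/kBT − (1/2σ²)Σ(D_i^S − D_i)² − m·log σ.

An EM algorithm alternates between (E) optimising every conformation in the
ensemble by gradient ascent and re-weighting members by their normalised
likelihoods, and (M) a coarse-then-fine grid search over (α, 1/(2σ²))
maximising the ensemble likelihood `Σ w_i L_i`.  Structures initialise from
confined Brownian (overdamped Langevin) simulation of the energy model.
See `docs/methods.md` for assumptions, parameter tables and limitations.

## Worked example

Generate a synthetic chromosome-scale instance, infer an ensemble, and
query it:

```sh
$ cat > spec.json <<'EOF'
{"n_segments": 8, "seed": 19}
EOF
$ chromens simulate spec.json demo_fixture
wrote fixture with 8 fragments to demo_fixture

$ cat > config.json <<'EOF'
{"k": 6, "brownian_steps": 2000, "ascent_max_steps": 2000}
EOF
$ chromens infer demo_fixture/frequencies.tsv demo_fixture/fragments.tsv \
      demo_run --config config.json --seed 5
alpha=0.5494 sigma=0.2236 iterations=11 converged=True

$ chromens query demo_run/ensemble demo_fixture/fragments.tsv \
      chrS:2000-4000 chrS:60000-64000
chrS:2000-4000	chrS:60000-64000	187.5
```

`alpha` is the fitted frequency→distance exponent (the instance was
generated at α* = 0.5), `sigma` the fitted restraint noise in reduced
length units (1 unit = 30 nm; here it mostly reflects ensemble-averaging
misfit, see the methods note), and the query output is the
ensemble-expected spatial distance between the two locus midpoints in
nanometres.  `demo_run/` also contains the per-iteration trace
(`trace.tsv`), the ensemble with its weights (`ensemble/`), and an
`effective_config.json` echo sufficient to re-run the job.

The same operations are available as library calls (`chromens.run_em`,
`chromens.expected_distance`, `chromens.cross_validate`, …); subcommands
`validate` (k-fold cross-validation) and `align` (Kabsch/SVD superposition
of the ensemble onto its highest-weight member) cover the standard
assessment workflow.

## File formats

* frequency matrix — square TSV with fragment labels, or triplet TSV
  `i<TAB>j<TAB>F` (1-based indices);
* fragment table — BED-like 3-column TSV (chrom, start, end), 0-based
  half-open, contiguous;
* structures — XYZ in nm, or PDB CA-pseudo-atom trace;
* ensemble — one structure file per member plus `weights.tsv`
  (`index  weight  log_likelihood`);
* synthetic fixture — the above plus `manifest.json` recording the
  generating parameters (true α, β, σ, seed).

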