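# cagefold

Kinetic and thermodynamic analysis of an enzyme folding inside a
chaperonin cage, built around five measurement modalities:

- **Progress curves** (`cagefold.progress`): fit the lag model
  `[P](t) = V·t + A·(e^(−λt) − 1)` to A340 traces, select a
  depletion-safe fit window, test residual randomness, and run
  Michaelis–Menten analysis of the steady-state velocities.
- **Rate inference** (`cagefold.rates`): fit the substrate dependence
  `λ(S) = k₁ + k₋₁/(Kₐ·S + 1)` of the lag rate, map the reduced-χ²
  surface over (k₁, k₋₁) with Kₐ profiled out, derive Δχ²=1 confidence
  intervals, and classify the mechanism (a λ that falls with substrate
  is conformational selection; one that rises is induced fit or
  substrate penetration).
- **Equilibrium stability** (`cagefold.equilibrium`): two-state GuHCl
  denaturation with linear baselines, ligand-linkage extrapolation
  `ΔG(S) = ΔG⁰ − RT·ln(1 + S/Kₘ)` to zero cofactor, and apparent-Tm
  estimation from the derivative of dye melts.
- **Anisotropy** (`cagefold.anisotropy`): build
  `r(t) = (I∥ − G·I⊥)/(I∥ + 2G·I⊥)` from polarized photon decays and
  fit the rotational correlation time.
- **Synthetic data** (`cagefold.simulate`): seeded generators for every
  input above, including a stiff ODE simulation of the full
  folding–binding–catalysis scheme with hidden ground truth.

`cagefold.kinetics` holds the closed forms these stages share, including
`ΔG = RT·ln(k₋₁/k₁)` and the cage-vs-bulk destabilization.

**Sign convention:** `delta_g` is the *folding* free energy — positive
means the unfolded state is favored. Every report restates this.

## Command line

One subcommand per analysis stage:

```sh
cagefold simulate --out data/ --seed 1            # synthetic datasets + truth.json
cagefold fit-progress data/progress_00.csv --substrate-conc 1e-5
cagefold fit-lambda data/lambda.csv --surface-out surface.csv
cagefold fit-denaturation den_*.csv --ligand-conc 5e-5 --ligand-conc 1.5e-4 --ligand-conc 4e-4
cagefold fit-melt data/melt.csv
cagefold fit-anisotropy data/anisotropy.csv
cagefold pipeline --config config.yaml           # full cage-vs-bulk report
```

All inputs are plain CSV with a header row (`time_s,a340`;
`dhf_M,lambda_per_s,lambda_err_per_s`; `guhcl_M,fluorescence`;
`temp_C,fluorescence`; `t_ns,counts_parallel,counts_perpendicular`).
The pipeline config is YAML; unknown keys are rejected. See
`cagefold.pipeline.PipelineConfig` for the manifest layout.

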