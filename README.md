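# ddtcycle

Stochastic checkpoint models of cell-cycle timing: maximum-likelihood
fitting of drift-diffusion+threshold (DDT) convolution models to
intermitotic-time (IMT) data, with AICc model selection, bootstrap
inference, a lineage-data censoring pipeline, and phase analysis.

## The problem

Even isogenic cells vary widely in how long they take to divide.  Where in
the cell cycle does this variability come from?  `ddtcycle` addresses the
question with a deliberately simple top-down model: the cycle is a sequence
of `m >= 1` checkpoints, and passage of checkpoint `i` happens when a latent
variable obeying

    dy_i = mu_i dt + sigma_i dW_t,    y_i(0) = 0,

first reaches 1.  Each passage time is then Wald (inverse Gaussian)
distributed,

    f(t; mu, sigma) = (sigma^2 2 pi t^3)^(-1/2) exp(-(mu t - 1)^2 / (2 sigma^2 t)),

with mean `1/mu`, variance `sigma^2/mu^3` and CV `sigma/sqrt(mu)`, and the
IMT density is the m-fold convolution of the component densities.  Fitting
DDT1/DDT2/DDT3 and the exponentially-modified Gaussian (EMG) competitor to
IMT samples and comparing them by AICc asks the data how many kinetically
distinct steps the cycle exposes — and labeling the fitted checkpoints by
CV ("H" for the most variable, "L" for the rest) plus a translation fit
against Fucci-resolved G1 / S-G2-M durations places the variable step
inside G1.

The numerically delicate part is that maximum-likelihood estimation
routinely proposes *highly concentrated* components (a checkpoint with
near-zero variance) which a fixed grid cannot resolve.  `ddtcycle`
implements the adaptive remedy: such components are detected and replaced
by Dirac point masses at their means, turning their contribution to the
convolution into an exact translation, with a reported first-order error
bound.  See `docs/methods.md` for the full account.

Audience: quantitative cell biologists and modelers working with
single-cell time-lapse lineage data (per-cell birth/division/death times,
optionally a Fucci G1→S marker), and anyone needing reliable MLE for
convolutions of inverse-Gaussian laws.

## Worked example

```python
from ddtcycle import CheckpointParams, DDTModel, fit_mle, simulate_imt

truth = DDTModel([
    CheckpointParams(mu=0.25, sigma=1.0),   # H: mean 4 h, CV 2.0
    CheckpointParams(mu=0.10, sigma=0.05),  # L: mean 10 h, CV 0.16
])
imts = simulate_imt(truth, n=2000, seed=42)
fit = fit_mle(imts, family="ddt", m=2, seed=42)
print(fit.theta)
```

Running `python examples/01_simulate_and_fit.py` (which wraps the above)
prints:

```
simulated n=2000 IMTs: mean 13.93 h, sd 8.20 h
fitted (H block first, by CV): mu_H=0.260 sigma_H=1.054  mu_L=0.099 sigma_L=0.050
checkpoint means: 3.85 h and 10.08 h (true: 4.00 and 10.00)
log-likelihood -5402.4, converged=True, grid drift 7.02e-08 per datum
```

The fitted blocks are reported in canonical order (descending CV): `mu_H`
and `sigma_H` describe the highly-variable checkpoint (recovered mean
3.85 h vs the true 4 h), `mu_L`/`sigma_L` the tight one (10.08 h vs 10 h).
The grid drift is the per-observation change in log-likelihood when the
density grid is refined — a value this small says the reported optimum is
grid-independent.

The other example scripts walk through the remaining capabilities, one per
file: `02_censoring_walkthrough.py` (death/EoE/crowding censoring of a
synthetic time-lapse experiment), `03_model_selection.py` (AICc/AICp
ranking of DDT1/DDT2/DDT3/EMG), `04_bootstrap_comparison.py` (percentile
intervals and the pooled two-sample parameter test), and
`05_phase_offset.py` (H/L phase ranking and recovery of a constant G1
offset from Fucci-style phase data).

## Command line

The same pipeline is scriptable from a shell; every stochastic command
requires `--seed` and identical invocations give byte-identical outputs:

```bash
ddtcycle simulate --params 0.25:1.0,0.1:0.05 --n-cells 500 --seed 1 --out lineage.csv
ddtcycle censor   --input lineage.csv --seed 1 --out imts.txt --report censor.yaml
ddtcycle fit      --imts imts.txt --seed 1 --out results.yaml
ddtcycle bootstrap --imts imts.txt --family ddt -m 2 -B 200 --seed 1 --out ensemble.csv
ddtcycle phases   --input lineage.csv --seed 1 --out phases.yaml
```

Lineage tables are plain CSV with columns `cell_id, birth_time_h,
division_time_h, death_time_h, observed_end_h` (optionally
`fucci_onset_h`); empty fields mean "absent"; all times are hours.

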