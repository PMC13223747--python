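# mplselect

Selection-coefficient inference from allele-frequency time series, with a
full statistical characterization of how **limited sampling** (finite sample
size per time point) and **genetic drift** (finite population size) degrade
the estimate.

The package is aimed at population geneticists analyzing temporal allele
counts — evolve-and-resequence experiments, longitudinal pathogen sequencing,
historical morph surveys — who want a closed-form, interpretable estimate of
the selection coefficient *s*, together with analytic error bars, detection
limits, and a rigorous benchmark against an HMM that models the sampling
process explicitly.

## The estimator

A single bi-allelic locus evolves in a Wright–Fisher population of size *N*
with mutant fitness 1 + *s* and symmetric per-generation mutation rate *μ*.
Approximating the Wright–Fisher transition by its diffusion limit and
discretizing gives a Gaussian path likelihood for frequencies
x(t₀), …, x(t_K) sampled Δt_k generations apart. Its maximizer is closed
form (the marginal-path-likelihood, MPL, estimate):

    ŝ_MPL = [ x(t_K) − x(t₀) − μ Σ_k Δt_k (1 − 2 x(t_k)) ] / Σ_k Δt_k v(t_k),

with v = x(1 − x) and sums over k = 0 … K−1. When only counts c(t_k) from
n_s(t_k) sampled individuals are available, plugging in x̂ = c/n_s biases the
denominator; the per-time factor n_s/(n_s − 1) corrects it exactly under
binomial sampling, giving the practical estimator ŝ = D̂ / V̂.

The key precision quantity is the **integrated variance**
V = Σ_k Δt_k v(t_k). The analytic theory shipped here gives:

* mean: E[ŝ] = ŝ_MPL (first order), hence ≈ *s*;
* sampling-only variance σ²_s = O(n_s⁻¹ V⁻²), from exact closed-form
  moments of D̂ and V̂;
* drift-only variance σ²_d ≥ 1/(N·V), the Cramér–Rao bound, which is tight;
* total variance Var[ŝ] ≈ σ²_s + σ²_d, an asymptotically Gaussian ŝ, and
  the minimum selection coefficient detectable at the 5% level, solving
  Var[ŝ] = (s_min/2)².

A grid HMM benchmark (Gaussian path-likelihood transitions on 100 frequency
bins, binomial emissions, forward algorithm, Nelder–Mead in *s*) provides
the estimate ŝ_LS that *does* model limited sampling, for head-to-head
comparisons.

## Worked example

```sh
mplselect simulate --N 1000 --s 0.02 --mu 1e-3 --x0 0.1 --T 450 \
    --model det --out traj.tsv
mplselect observe --traj traj.tsv --dt 10 --ns 20 --seed 4 --out obs.tsv
mplselect estimate --obs obs.tsv --mu 1e-3 --N 1000 --ci
```

```json
{
  "s_hat": 0.01672268907563025,
  "numerator": 0.9950000000000001,
  "denominator": 59.50000000000001,
  "bias_corrected": true,
  "ci_low": 0.009359023799991043,
  "ci_high": 0.025846637411862116
}
```

A trajectory generated at *s* = 0.02 and observed with only 20 samples every
10 generations yields ŝ ≈ 0.017: the net frequency change minus the mutation
flux (numerator ≈ 1.0) divided by the bias-corrected integrated sample
variance (denominator ≈ 59.5). The 95% likelihood-ratio interval
(0.009, 0.026) excludes 0 — selection is detected. The same data through the
HMM benchmark (`mplselect hmm-estimate --obs obs.tsv --N 1000 --mu 1e-3`)
give ŝ_LS ≈ 0.016, nearly identical, illustrating the robustness of the
closed form to sampling noise it does not model.

Detection power planning:

```sh
mplselect power --N 1000 --T 50    # {"s_min": 0.04151582174553897}
mplselect power --N 1000 --T 150   # {"s_min": 0.014920657146814635}
```

Tripling the observation horizon from 50 to 150 generations lowers the
smallest detectable coefficient from above 4% to below 2%.

The same functionality is available as a library (`mplselect.s_hat`,
`mplselect.variance_report`, `mplselect.min_detectable_s`,
`mplselect.fit_s_ls`, …); Monte-Carlo sweeps over designs run through
`mplselect experiment --config cfg.json`.

Real diploid count data (e.g. the classic *medionigra* morph series, with
codominant fitnesses 1, 1+s, 1+2s) are analyzed with `--diploid`, which
treats counts as allele counts on 2N gametes; supply the published yearly
allele counts as a TSV (`generation  sample_size  mutant_count`, years
mapped to generations) under `data/medionigra.tsv` to reproduce the
published estimates (ŝ = −0.049 for 1939–1995; −0.058 for 1939–1999).

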