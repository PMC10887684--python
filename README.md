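# wextropy

Non-parametric estimation of **weighted extropy** for positive lifetime
data, with an emphasis on reliability modelling.

Extropy, the complementary dual of Shannon entropy, measures how
concentrated a density is: `J(X) = -1/2 ∫₀^∞ f(x)² dx`. It is
shift-independent, which is a drawback whenever *where* an event happens
matters (a device failing at 100 hours is not the same news as one failing
at 10 000 hours). The **weighted extropy**

```
Jʷ(X) = -1/2 ∫₀^∞ x f(x)² dx
```

weights the squared density by the outcome itself, producing a
shift-dependent uncertainty measure for positive random variables: more
negative values mean higher uncertainty. In reliability work, of several
competing systems the one with the most negative estimated `Jʷ` is the
least reliable.

## What the package provides

- **Three non-parametric estimators** of `Jʷ` from a sample
  `X₁, …, Xₙ > 0`:
  - `we_lkde` — plugs in the *log-kernel* density estimator
    `f̂_log(x) = (1/nh) Σᵢ (1/x) K((log x - log Xᵢ)/h)`, a kernel smoother
    applied in log space and transported back, well suited to skewed and
    heavy-tailed lifetimes;
  - `we_kde` — plugs in the ordinary Rosenblatt–Parzen estimator
    `f̂(x) = (1/nh) Σᵢ K((x - Xᵢ)/h)`;
  - `we_empirical` — the kernel-smoothed order-statistic spacing sum
    `-1/4 Σᵢ (X²ᵢ₊₁:ₙ - X²ᵢ:ₙ) f̂²(Xᵢ:ₙ)`.
- **Bandwidth selection**: the Sheather–Jones solve-the-equation plug-in
  (on raw data for the KDE, on log data for the L-KDE) and the
  AMISE-optimal bandwidth `h_opt = (B/(A n))^{1/5}` of the L-KDE weighted
  extropy for a known distribution.
- **Asymptotic theory**: leading bias `-(h²/2)∬_{x>y}[f + 3xf' + x²f'']f`
  and variance `(C_k/nh)∬_{x>y} f³/x` of the L-KDE estimator, and the
  AMISE decomposition they imply.
- **Parametric plug-in** (`we_parametric`): maximum-likelihood fit of an
  exponential or lognormal model, evaluated at the closed forms
  `Jʷ(Exp(λ)) = -1/8` (any rate) and `Jʷ(LN(μ,σ)) = -1/(4σ√π)`.
- **A Monte Carlo engine** (`run_bias_rmse_table`, `run_moment_table`)
  producing mean (H), |bias| and RMSE tables across sample sizes for the
  five study distributions: Exp(1), standard lognormal, uniform(0,1), the
  density `2x` on (0,1), and Rayleigh(1).
- **A CLI** (`wextropy estimate | compare | simulate`) for estimating from
  files, ranking competing systems by reliability, and writing the Monte
  Carlo tables as CSV.

## Worked example

Sixty lifetimes drawn from an exponential model with rate 0.64
(thousands of cycles to failure):

```python
import numpy as np
from wextropy import WeightedExtropy

rng = np.random.default_rng(7)
data = rng.exponential(scale=1 / 0.64, size=60)

res = WeightedExtropy(data).fit(method="lkde", n_boot=200, seed=1)
print(res.summary())
```

```
Weighted Extropy Estimation Results
===========================================
Method:               lkde
No. observations:     60
Bandwidth (plug-in):  0.458452
Weighted extropy:     -0.117548
Bootstrap s.e.:       0.0188365  (200 reps)
95% CI:               [-0.154467, -0.0806294]
===========================================
```

The log-kernel estimate `-0.1175` sits near the exponential family's
theoretical value `Jʷ = -0.125` (which is the same for every rate, so the
parametric route `fit(method="parametric", family="exponential")` returns
exactly `-0.125`). On the same data the ordinary-kernel estimator gives
`-0.1323` and the spacing estimator `-0.1478`; the spread between methods
at n = 60 is of the same order as the bootstrap standard error.

From the shell:

```sh
wextropy estimate lifetimes.txt --method lkde
wextropy compare sys1.txt sys2.txt sys3.txt --method lkde
wextropy simulate --out tables/ --seed 1 --reps 1000
```

`compare` ranks the systems from most negative (least reliable) to least
negative weighted extropy.

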