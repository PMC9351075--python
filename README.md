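# profilemix

Latent profile analysis for small samples: restricted Gaussian profile
mixtures with multistart mode diagnostics, multi-criteria model
evaluation, multiple-imputation extension of a class structure to
secondary indicators, and latent class regression — plus a synthetic-data
generator that mirrors the model, so every stage is testable without any
external dataset.

## Who this is for

Researchers trying to parse heterogeneity within a clinical or
neurodevelopmental cohort of modest size (n ≲ 150) from continuous
indicators — e.g. standardized neuropsychological scores, with
log-transformed EEG band powers as a secondary domain. At these sample
sizes mixture models are estimable but fragile: the loglikelihood is
multimodal, information criteria disagree, and unrestricted models waste
degrees of freedom. This package operationalizes a workflow built around
three ideas:

1. **Parameter restrictions conserve power.** Classes can be *fixed*
   (an entire mean vector pinned to constants, e.g. a "low average"
   reference class at −0.5 on every z-scored indicator and a "high
   average" class at +0.5) or tied by *equality groups* (one indicator's
   mean equated across chosen classes).
2. **Convergence structure is a diagnostic.** Fitting ~1000 random
   starts and grouping solutions into modes (up to class relabelling)
   exposes instability that no single fit index shows.
3. **No automatic winner.** Model comparison reports loglikelihood,
   AIC, BIC, relative entropy, posterior crispness, residual variance
   fractions, and convergence tallies side by side, and flags when the
   criteria disagree.

## The model

A finite mixture of conditionally independent Gaussians with pooled
variances (one σ_j² per indicator, shared across classes):

    f(y_i) = Σ_c π_c Π_j N(y_ij; μ_cj, σ_j²)

fitted by EM with restrictions enforced in the M-step, Aitken-projected
stopping, and a variance floor against likelihood spikes. Free
parameters: k = (free mean cells) + J + (C − 1). Secondary indicators
are profiled by class via multiple imputation: subjects are repeatedly
assigned to classes from their posterior probabilities, and per-class
means are pooled with Rubin's rules, T = W̄ + (1 + 1/D)·B, so intervals
carry both membership uncertainty and sampling error. Covariates enter
through a multinomial-logit model for the class proportions, estimated
jointly with the mixture. See `docs/methods.md` for the full account.

## Worked example

```python
import profilemix as pm
from profilemix.multistart import align_classes

scen = pm.default_scenario(seed=7)        # 5-class study truth, n=120
sim = pm.simulate(scen)                   # primary + EEG-like + binary
spec = pm.two_reference_spec(5, 7)        # classes 0/1 fixed at ∓0.5
ms = pm.run_multistart(sim.primary, spec, n_starts=200, seed=1)
rep = pm.fit_report(ms.best, sim.primary, ms)
print(f"modes={ms.n_modes}  top-mode share={ms.top_mode_fraction:.0%}  "
      f"LL={rep.loglik:.2f}")
print(f"k={rep.k}  AIC={rep.aic:.2f}  BIC={rep.bic:.2f}  "
      f"entropy={rep.entropy:.2f}")
```

prints

```
modes=8  top-mode share=36%  LL=-1064.31
k=32  AIC=2192.61  BIC=2281.81  entropy=0.86
```

The restricted five-class model uses 32 parameters (21 free means for
the three unrestricted classes, 7 pooled variances, 4 proportions); 36%
of 200 random starts reach the top mode, and entropy 0.86 says the
posterior classification is reasonably crisp. Aligning fitted classes to
generator truth shows the class sizes are recovered:

```
low average        pi_hat=0.43  (truth 0.42)
high average       pi_hat=0.28  (truth 0.34)
low ctrl/high mem  pi_hat=0.12  (truth 0.09)
high IQ            pi_hat=0.11  (truth 0.06)
below average      pi_hat=0.06  (truth 0.09)
```

Extending the model to the secondary (EEG-like) indicators with D = 20
imputation draws recovers the elevated theta power planted in class 2:

```python
ext = pm.extend_model(sim.secondary, ms.best.posteriors, D=20, seed=2)
```

```
class_index  pooled_mean  ci_low  ci_high      # theta band
          0         0.14   -0.13     0.41
          1         0.12   -0.23     0.46
          2         0.65    0.07     1.23
          3         0.15   -0.42     0.72
          4        -0.30   -0.90     0.29
```

Only class 2's interval excludes zero — the wide intervals elsewhere
are the honest price of ~10–50 subjects per class.

The same workflow is scriptable end to end:

```bash
profilemix simulate --n 120 --seed 7 --out-prefix sim_
profilemix pipeline --data sim_primary.csv --secondary sim_secondary.csv \
    --binary sim_binary.csv --seed 11 --out-dir run/
```

Every stochastic command requires `--seed`; the run directory carries a
manifest (inputs, seeds, settings, versions) from which every exported
number is recomputable.

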