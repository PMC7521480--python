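# telegraphkit

Stochastic models of transcriptional bursting for single-cell mRNA count
data: exact chemical-master-equation (CME) solutions of telegraph-family
gene-expression models, burst size/frequency estimators, analytic
mean–variance constraint surfaces, genetic-algorithm fitting of model CDFs
to count distributions, burstiness trend regression across conditions, and
an exact Gillespie simulator that generates every input the pipeline needs
together with its ground truth.

It is written for quantitative biologists analysing smFISH or scRNA-seq
count data of inducible genes (cytokines such as TNF-α and IL-1β are the
motivating examples) who want to move between three descriptions of the
same biology: kinetic rate constants, burst statistics, and empirical
mean–variance trends.

## The models

Each gene has two independent alleles. In the **one-step (telegraph)
model** an allele switches off→on at rate *k*<sub>on</sub> and on→off at
*k*<sub>off</sub>; mRNA is transcribed at *k*<sub>t</sub> only in the on
state and degrades at *k*<sub>d</sub>. Variants add a constitutive leak
*k*<sub>0</sub>, or an upstream chromatin-opening step (off↔I↔on with rates
*t*<sub>on</sub>, *t*<sub>off</sub>) in which the intermediate state is
either silent or *permissive* (transcribing at a low rate *k*<sub>0</sub>).
The CME over (allele configuration, mRNA count ≤ *M*) — 3(*M*+1) states for
one-step variants, 6(*M*+1) for two-step — is solved by the action of the
sparse generator's matrix exponential (time courses) or a null-space solve
(steady states).

Key closed forms for the two-allele telegraph model at steady state:

- mean  μ = 2 *k*<sub>on</sub> *k*<sub>t</sub> / (*k*<sub>d</sub> (*k*<sub>on</sub>+*k*<sub>off</sub>))
- variance  σ² = μ [1 + *k*<sub>t</sub> *k*<sub>off</sub> / ((*k*<sub>on</sub>+*k*<sub>off</sub>)(*k*<sub>on</sub>+*k*<sub>off</sub>+*k*<sub>d</sub>))]
- kinetic burst size *b*<sub>k</sub> = *k*<sub>t</sub>/*k*<sub>off</sub> and frequency *f*<sub>k</sub> = 2 *k*<sub>on</sub> *k*<sub>off</sub>/((*k*<sub>on</sub>+*k*<sub>off</sub>) *k*<sub>d</sub>)
- moment burst size *b*<sub>m</sub> = σ²/μ (the Fano factor) and frequency *f*<sub>m</sub> = μ/(*b*<sub>m</sub>−1)

The relative errors (kinetic − moment)/kinetic between the two estimator
families are available in closed form and vanish in the bursty regime
*k*<sub>off</sub> ≫ *k*<sub>on</sub>, *k*<sub>t</sub> ≫ *k*<sub>off</sub> ≫ *k*<sub>d</sub>.
A linear mean–variance trend σ² = αμ + σ₀ across conditions pins the
kinetics to a surface in (*k*<sub>off</sub>, *k*<sub>on</sub>,
*k*<sub>t</sub>) space; in the bursty regime the burst size is fixed at
α − 1 and expression is tuned purely by frequency modulation.

## Worked example

```python
import telegraphkit as tk

# fitted TNF-alpha one-step rates (min^-1; k_t in mRNA/min per allele)
spec = tk.GeneModelSpec("one_step", k_on=0.02, k_off=0.12,
                        k_t=16.8, k_d=0.014, M=2000)

mu, var = tk.steady_state_moments(spec)
print(f"steady state: mean={mu:.1f}, Fano={var/mu:.1f}")

kin = tk.kinetic_estimators(spec)
mom = tk.moment_estimators(mu, var)
err = tk.estimator_errors(spec)
print(f"b_k={kin.size:.0f}, b_m={mom.size:.1f}, "
      f"burst-size error={err.b_error:.1%}")

ms = tk.moments(tk.steady_state(spec))   # full CME cross-check
print(f"CME: mean={ms.mean:.1f}, Fano={ms.fano:.1f}")
```

prints

```
steady state: mean=342.9, Fano=94.5
b_k=140, b_m=94.5, burst-size error=32.5%
CME: mean=342.9, Fano=94.5
```

Reading: at these rates the gene makes ~343 mRNA on average with
super-Poissonian noise (Fano 94.5). The kinetic burst size is 140 mRNA per
burst, while the moment estimator — exact only in the bursty limit —
underestimates it by ~30% because *k*<sub>off</sub>/*k*<sub>on</sub> is
only 6. The CME numbers confirm the closed forms.

A shell session covering simulation and trend fitting:

```bash
telegraphkit simulate --alpha 40 --n-conditions 6 --n-cells 1000 \
    --seed 7 --out sim/
telegraphkit estimate --counts sim/cond_00.csv
telegraphkit surface --alpha 40 --out surface.csv
```

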