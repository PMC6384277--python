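# nirsinfo

Information-theoretic evaluation of skin-blood-flow (SBF) attenuation for
functional near-infrared spectroscopy (fNIRS).

## The problem

fNIRS measures cortical hemodynamics through the scalp, so every channel is
contaminated by scalp-layer blood flow — a quasi-global additive
interference. Several attenuation algorithms exist (resting-baseline PCA
spatial filtering; ICA removal of the most spatially uniform component), but
reducing the interference is not the same as preserving the cortical
signal: any filter destroys information, and a filter judged only by how
little interference remains may have thrown the cortical activity away with
it.

`nirsinfo` quantifies both sides of that trade-off. For a recording X
before attenuation, X′ after, and a simultaneously sampled SBF trace Y, it
evaluates five inequality criteria built on transfer entropy (TE),
mutual information and conditional differential entropy (all in nats):

| | inequality | meaning |
|---|---|---|
| c1 | T(Y→X′) ≤ T(Y→X) | less interference is transferred into X′ |
| c2 | H(Y\|X) ≤ H(Y\|X′) | X′ reveals less about the interferer |
| c3 | H(X\|Y) ≤ H(X′\|Y) | the interferer reveals less about X′ |
| c4 | H(X\|X′) ≤ H(X\|Y) | X′ explains X better than Y does |
| c5 | H(X\|X′) ≤ H(X′) | the preservation margin H(X′) − H(X\|X′) ≥ 0 |

c1–c3 certify interference reduction; c4 guards against "attenuation" that
replaces the signal with the interferer; the c5 margin is the score by
which competing attenuation settings (PC1, PC12, PC123, IC1) are ranked.

Transfer entropy is estimated with Kraskov–Stögbauer–Grassberger
k-nearest-neighbour estimators (Frenzel–Pompe construction for the
conditional mutual information, Kozachenko–Leonenko for entropies), with a
Gaussian closed-form family as a fast exact alternative. The package also
ships the two attenuation algorithms, the preprocessing chain
(baseline normalisation, zero-phase 0.01–0.6 Hz first-order Butterworth
band-pass, linear detrend), a fully specified synthetic verification study,
and the nonparametric statistics layer (Wilcoxon rank-sum/signed-rank with
z-scale effect sizes, Kruskal–Wallis with r = √(H/N), Bonferroni).

## Worked example

```python
import nirsinfo as ni

cfg = ni.StudyConfig(
    simulation=ni.SimulationConfig(n_rounds=10),
    estimator=ni.EstimatorConfig(method="ksg", lag_max=10),
    analysis_channels=(0,),
    seed=11,
)
report = ni.run_simulation_study(cfg)
print(report.summary())
```

prints

```
Simulation study summary
========================
rounds: 10   channels analysed: (0,)   estimator: ksg
study lag (grand-average argmax): 3

criterion satisfaction rate per setting (fraction of rounds):
  PC1    c1=1.00  c2=1.00  c3=1.00  c4=0.00  c5=1.00
  PC12   c1=1.00  c2=1.00  c3=1.00  c4=0.00  c5=1.00
  PC123  c1=1.00  c2=1.00  c3=1.00  c4=0.00  c5=1.00
  IC1    c1=1.00  c2=1.00  c3=1.00  c4=0.00  c5=1.00

information-preservation margin H(X') - H(X|X') (mean over rounds):
  IC1    +0.342
  PC1    +0.110
  PC12   +0.099
  PC123  +0.068

mean variance explained by PC1: 88.18%
ICA attribution frequency: ch1: 20%, ch2: 20%, ch3: 20%, ch4: 40%
mean |r| (removed component vs true noise): 0.81
```

Reading this: the grand-average TE lag scan peaks at lag 3; every
attenuation setting reduces the transfer of interferer information in every
round (c1), tells less about the interferer (c2, c3) and keeps a positive
preservation margin (c5). c4 fails here because in this synthetic regime
the interferer is 2.3× stronger than the signal, so the raw recording
genuinely resembles Y more than it resembles any noise-free reconstruction
— see `docs/methods.md` for why that is a property of the simulation, not
a bug. The PCA filter is highly specific (one leading component carries
≈88% of resting variance), while ICA's uniform component tracks the true
interferer at |r| ≈ 0.8 but attributes it to a different channel from
round to round.

There is also a CLI mirroring the library:

```sh
nirsinfo simulate --seed 1 --out sim/
nirsinfo attenuate sim/round000_observed.csv sim/round000_noise.csv out.csv \
    --algorithm pca --components 12
nirsinfo evaluate x.csv xp.csv y.csv --lag 3 --out report
nirsinfo study --config study.yml --seed 1 --out results/
```

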