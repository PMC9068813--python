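# nelfkit

Quantitative analysis of enhancer-RNA-driven NELF release and RNA
polymerase II promoter-proximal pausing.

Enhancer RNAs (eRNAs) are unstable long non-coding RNAs transcribed from
active enhancers.  One proposed mechanism for their function is direct:
sufficiently long, guanosine-containing eRNAs bind the negative elongation
factor (NELF) at multiple sites and detach it from the paused elongation
complex (PEC = Pol II + DSIF + NELF), releasing Pol II into productive
elongation.  Testing that mechanism quantitatively takes several unrelated
measurements — gel-shift titrations, nascent-transcription coverage, 5′-end
sequencing, protein-RNA crosslinking in vivo (eCLIP) and in vitro (XL-MS),
and chemical structure probing (SHAPE-MaP).  `nelfkit` packages the
analysis layer of all of them for anyone who has such data in hand, plus
synthetic-data generators so the whole pipeline runs and is testable
without any download.

## What's in the box

| module     | analysis                                                        |
|------------|-----------------------------------------------------------------|
| `emsa`     | release fractions from gel densitometry; apparent K_d by quadratic (ligand-depletion) single-site fits; pause-release time courses |
| `pausing`  | pausing index PI = density(TSS−100..+200) / density(TSS+400..+800); NELF occupancy tiers; Kolmogorov–Smirnov comparisons |
| `tss`      | TSS calling from 5′-end pileups; extragenic (gene ±2 kb) filter; one-TSS-per-enhancer assignment; >1.5-fold induction classification |
| `eclip`    | crosslink sites from R2 first nucleotides; 1-based distance windows (1–200, 201–400, …); expression-normalized meta-profiles; chi-squared comparisons |
| `shape`    | SHAPE reactivities (modified − untreated rate, box-plot/2–8% normalization); structured/intermediate/flexible classes by median reactivity; positional G-content tests |
| `xlms`     | crosslink-search filtering (minions ≥ 7, TIC ≥ 0.15, ID score ≥ 20); per-residue nseen aggregation; subunit/domain proportions |
| `simulate` | generators for all of the above with ground-truth sidecars      |
| `core`/`io`| interval/track/site data model; BED6, bedGraph pairs, FASTA, TSV |

The central binding model: with R the total PEC concentration (0.1 µM in
the standard assay) and L the total eRNA concentration, the released
fraction is

    f(L) = A · (R + L + K_d − sqrt((R + L + K_d)² − 4RL)) / (2R)

fitted by bounded multistart least squares for the apparent K_d and
amplitude A.  The quadratic form matters because L and R are comparable —
a hyperbolic fit would bias K_d low.

## Worked example

Simulate a noisy release curve at the standard concentration series
(0.15–1.8 µM eRNA, 0.1 µM PEC) with true K_d 0.14 µM, and fit it:

```python
import numpy as np
from nelfkit import emsa, simulate

cfg = simulate.SimConfig(seed=7, kd_true=0.14, noise_sd=0.05)
curve, truth = simulate.simulate_binding_curve(cfg)
print(np.round(curve.fractions, 3))
# [0.493 0.644 0.747 0.843 0.97  0.819]

fit = emsa.fit_binding(curve)
print(f"kd={fit.kd:.3f} amplitude={fit.amplitude:.3f} stderr={fit.kd_stderr:.3f}")
# kd=0.098 amplitude=0.939 stderr=0.037
```

The fitted K_d of 0.098 µM sits within one standard error of the
generating 0.14 µM — about what a single 5%-noise titration can resolve;
across 200 such curves the median recovered K_d lands within 15% of truth
(see the test suite).  The same objects work for pausing and crosslink
analyses:

```python
from nelfkit import eclip, pausing

tracks, genes, _ = simulate.simulate_nascent_coverage(
    simulate.SimConfig(seed=7, pausing_index_true=5.0, conditions=("KCl_0",)))
table = pausing.pausing_index_table(tracks["KCl_0"], genes)
print(round(table["pi"].median(), 3))
# 4.963

cfg = simulate.SimConfig(seed=7)           # 70% of crosslinks in nt 1-200
units = simulate.enhancer_units(cfg)
sites, _ = simulate.simulate_crosslink_sites(cfg, units)
assignments, _ = eclip.assign_to_units(sites, units)
dist = eclip.window_distribution(assignments, edges=(200, 400, 600))
print(dist.labels, np.round(dist.proportions, 3))
# ['1-200', '201-400', '401-600'] [0.689 0.168 0.144]
```

A `nelfkit` console script exposes the same steps as subcommands
(`tss-call`, `tss-assign`, `pausing-index`, `eclip-windows`, `emsa-fit`,
`shape-react`, `g-bins`, `xlms-aggregate`, `simulate`); run
`nelfkit --help` for options.

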