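# emt-nfatc

Multistability, stochastic landscapes and ensemble statistics of the
coupled EMT–NFATc gene regulatory circuit.

Carcinoma cells can occupy a hybrid epithelial/mesenchymal (E/M) state —
co-expressing epithelial markers such as E-cadherin with mesenchymal
drivers such as ZEB — that is more metastasis-prone than either pure
phenotype.  *Phenotypic stability factors* (PSFs) are regulators that
widen the range of EMT-inducing signal over which this hybrid state
survives.  This package implements a complete computational analysis of
the calcium-responsive transcription factor NFATc as a PSF for the
miR-200/ZEB/SNAIL decision circuit, for researchers in cancer systems
biology and gene-network dynamics.

## The models

**Mechanistic ODE model.**  Each species follows
`dX/dt = g_X · Π H(A; A0, n, λ) − k_X · X`, with shifted Hill factors
`H = (1 + λ(A/A0)^n) / (1 + (A/A0)^n)` for transcriptional regulation
and a microRNA binding-site formalism for miR-200 silencing of ZEB
mRNA: with `M_i(μ)` the binomial occupancy of `i` of 6 sites,
translation is scaled by `L(μ) = Σ l_i M_i`, mRNA degradation gains
`Ym(μ) = Σ γm_i M_i`, and miR-200 is consumed at `m_Z · Yμ(μ)`.
SNAIL is a clamped input `S` (molecules); the coupled model adds
E-cadherin and constitutive NFATc on top of the 3-species core.
Bifurcation sweeps in `S` classify stable branches as epithelial (E),
hybrid (H) or mesenchymal (M) and measure the hybrid-enabling interval.

**Stochastic landscape.**  A quasi-steady-state reduction to
(ZEB protein, miR-200) is driven with additive noise (Euler–Maruyama);
trajectories are coarse-grained into basin itineraries for mean
residence times, and `U = −ln P` of the sampled density gives
quasi-potential barrier heights.

**Topology-level statistics.**  A random-circuit-perturbation ensemble
(all species dynamical, all edges shifted-Hill, kinetic parameters
sampled per model) phenotypes every stable state by ZEB/miR-200
z-scores, bins each model into a phase ({E}, {E,H}, {E,H,M}, ...), and
compares topologies; a degree-preserving sign-randomization null model
(all C(11,6) − 1 = 461 permutations of the wild type's edge signs)
locates the wild type within the randomized distribution.

## Worked example

```python
import numpy as np
from emt_nfatc import default_core_parameters, default_coupled_parameters
from emt_nfatc.bifurcation import sweep, hybrid_interval

grid = np.linspace(0, 500e3, 126)
for name, p in [("coupled", default_coupled_parameters()),
                ("core", default_core_parameters())]:
    d = sweep(p, grid, seed=0)
    lo, hi = hybrid_interval(d, p)
    print(f"{name}: hybrid window [{lo/1e3:.1f}k, {hi/1e3:.1f}k] "
          f"= {(hi-lo)/1e3:.1f}k molecules")
```

prints

```
coupled: hybrid window [312.5k, 405.5k] = 93.0k molecules
core: hybrid window [217.0k, 275.5k] = 58.5k molecules
```

— the NFATc-coupled circuit holds the hybrid E/M state over a ~1.6-fold
wider SNAIL range than the core circuit (the PSF signature).  From an
epithelial start at S = 330,000 molecules the core circuit's ZEB mRNA
enters its mesenchymal band after ~78 h while the coupled circuit
settles on its hybrid branch and never completes EMT
(`analysis/03_delayed_emt.py`); the stochastic landscape at
S = 323–330k has the hybrid well deeper than the mesenchymal one, with
the ordering reversed by S = 380k (`analysis/05_landscape_mrt.py`) —
NFATc blocks complete EMT, yet inside the tristable window the hybrid
state is not the longest-lived one: its non-canonical PSF behaviour.

The numbered scripts under `analysis/` run the full study in order
(circuits and null model, bifurcation, delayed EMT, sensitivity,
landscapes, ensembles, randomization, relative stability), each writing
tables under `results/` and printing its headline findings.  The same
stages are available as a CLI (`emt-nfatc --help`) including an
end-to-end `emt-nfatc repro --out DIR --seed 1729`.

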