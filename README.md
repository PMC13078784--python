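# memfret

Single-molecule FRET conformational-state inference for membrane-embedded
receptors, with coarse-grained lipid-accessibility metrics.

## The scientific problem

The intracellular region of a receptor tyrosine kinase such as EGFR can sit
*compact* against the membrane or swing *open* away from it, and the balance
between the two states — and hence access of ATP and adaptor proteins to the
kinase — depends on the lipid composition around the receptor. Immobilized
receptor nanodiscs probed by confocal TCSPC report this equilibrium through
the donor fluorescence lifetime: energy transfer to an acceptor shortens the
donor lifetime as the labelled C-terminal tail approaches the membrane.

This package implements the full inference chain from raw photon records to
per-condition conformational amplitudes:

1. **Trace segmentation** — photon streams are binned at 100 ms; constant-
   intensity regions are found by recursive binary segmentation of the
   Poisson counts with a Monte-Carlo-calibrated likelihood-ratio test; only
   molecules with a single downward photobleaching step to background in
   both channels (acceptor bleaching first) are kept, and donor photons
   before acceptor photobleaching form the FRET-level photon set.
2. **Lifetime estimation** — consecutive bunches of 1000 donor photons are
   fit by per-photon maximum likelihood with the density
   `p(t) = (1−b)·[IRF ⊗ exp(−t/τ)]|[0,W] + b/W`, where the Gaussian-IRF
   convolution is the exponentially modified Gaussian in closed form,
   truncated to the laser period W = 12.5 ns, and the background fraction
   b is fixed from a blank.
3. **Distance conversion** — `E = 1 − τ_DA/τ_D` and the Förster relation
   `r = R₀((1−E)/E)^{1/6}` (R₀ = 8.4 nm for the snap surface 594/Cy5 pair,
   7.5 nm for snap surface 594/atto647N) give per-bunch distances; medians
   carry seeded percentile-bootstrap 95% CIs and distances far beyond R₀
   are flagged as outside the FRET range.
4. **State model** — lifetime distributions of all conditions are fit
   jointly with a Gaussian mixture whose peak positions and widths are
   shared while amplitudes vary per condition; the component count is
   chosen by `BIC = −2 ln L + k ln n` (n = total bunch count), component
   separation is scored by Ashman's
   `D = |μ₁−μ₂| / √((σ₁²+σ₂²)/2)` (D > 2 means well separated), and
   EGF-induced open-state amplitude changes are tabulated with one-way
   ANOVA comparisons (significance p ≤ 0.001).
5. **Trajectory metrics** — for coarse-grained simulation frames: the
   number of lipid-bead/ATP-site-bead pairs within 16 Å (a steric proxy for
   ATP-site accessibility), the residue 721–1186 distance, WHAM reweighting
   of umbrella-biased collective-variable series, and three-partition block
   error bars.

Because raw photon streams and trajectories for this kind of study are
rarely deposited, a first-class synthetic-data module
(`memfret.synthetic`) generates every input — two-state lifetime mixtures
(peaks 1.3 and 2.7 ns, widths 0.35 and 0.67 ns, open-state amplitudes
42–96% depending on lipid condition), photon streams with single-step
photobleaching, harmonically biased Langevin series, and labelled bead
clouds — all bit-reproducible from a seed.

## Worked example

```python
import numpy as np
from memfret.pipeline import ConditionConfig, RunConfig, run_pipeline
from memfret.statemodel import fit_global_mixture

cfg = RunConfig(
    conditions=[
        ConditionConfig("15% POPS -EGF", egf=False),
        ConditionConfig("15% POPS +EGF", egf=True, pair_with="15% POPS -EGF"),
        ConditionConfig("30% POPS -EGF", egf=False),
        ConditionConfig("30% POPS +EGF", egf=True, pair_with="30% POPS -EGF"),
    ],
    n_molecules=200,
    stages=("simulate", "segment", "fit"),
)
report = run_pipeline(cfg, seed=0)
model = fit_global_mixture(report.lifetimes, k=2, seed=0)
print(np.round(model.means, 3), np.round(model.sigmas, 3))
for cond, w in model.weights.items():
    print(f"{cond}: open {100 * w[1]:.1f}%")
```

prints

```
[1.369 2.742] [0.386 0.745]
15% POPS -EGF: open 67.0%
15% POPS +EGF: open 87.9%
30% POPS -EGF: open 75.4%
30% POPS +EGF: open 95.8%
```

— the recovered shared peaks sit at ≈1.37 and ≈2.74 ns (the generator's
two conformational states at 1.3/2.7 ns) and each condition's open-state
amplitude tracks the fraction of open molecules the simulation actually
drew, with EGF raising the open amplitude by ~20–24 points in both lipid
conditions.

The numbered drivers under `analysis/` run the same chain as a narrative:
`01_simulate_photon_streams.py` → … → `07_atp_binding_gels.py`, each
printing what it found and writing its tables under `results/`. The CLI
exposes the same stages (`memfret report --config cfg.yaml --seed 1 --out
out/`).

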