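# macpol — a mechanistic model of macrophage M1/M2 polarization

Macrophages polarize along a continuous spectrum between classical
(pro-inflammatory, **M1**) and alternative (anti-inflammatory/pro-angiogenic,
**M2**) activation, driven by cytokines and by the oxygen state of the
tissue.  `macpol` is a Python package for simulating and analyzing a
mechanistic, multi-pathway ordinary-differential-equation model of this
process: the IFN-γ/JAK/STAT1/IRF-1 axis, the IL-4/JAK/STAT6/IRF-4/AKT axis
and an oxygen/PHD/HIF-1/2 module, coupled through SOCS negative feedback,
microRNA regulation (miR-93, miR-3473b), the IRG-1/itaconate/ROS metabolic
loop, and autocrine IFN-γ.  It is aimed at systems-biology researchers who
want to run stimulation, perturbation, sensitivity and calibration
experiments on this network — or on their own reaction networks written in
the same declarative form.

The shipped network has **80 state nodes** drawn from **34 functionally
unique species** and **130 reactions** in deterministic mass-action and
Hill kinetics,

- mass action: `v = k · Π xᵢ^sᵢ` (with a reverse term `kf·Π reactants −
  kr·Π products` for reversible binding),
- Hill activation/inhibition: `v = V · Xⁿ/(Kⁿ + Xⁿ)` or
  `V · Kⁿ/(Kⁿ + Xⁿ)` for a regulator X,

with state in molecules per cell and time in hours.  Doses in ng/ml are
converted to molecules per cell as `dose · 10⁻⁹ / MW · N_A / density`
(default plating density 10⁶ cells/ml).  Polarization is summarized by the
**M1/M2 score** — the product of six M1 marker levels (iNOS, TNFα, IL-12,
CXCL9, CXCL10 mRNA, IFN-γ) divided by the product of three M2 marker
levels (Arg-1, IL-10, VEGF), evaluated at 24 h by default.

The rate constants of the shipped network are order-of-magnitude estimates
calibrated to the network's documented qualitative behaviors, not measured
values; see `docs/methods.md` for the model's provenance and assumptions.

## A worked example

```python
import numpy as np
from macpol import StimulusEvent, build_full_model, equilibrate, run_scenario
from macpol.fullmodel import MW_IFNG

model = build_full_model()
baseline = equilibrate(model)              # unpolarized, normoxic state
base = model.with_initial_state(baseline)

res = run_scenario(base, events=[StimulusEvent("IFNg_ext", 10.0, MW_IFNG, 0.0)],
                   horizon=48.0)
pstat1 = res["pSTAT1"] + 2 * res["pSTAT1_dim"] + 2 * res["pSTAT1_n"]
print(res.time[np.argmax(pstat1)], pstat1.max() / pstat1[-1])
```

prints

```
3.6 3.879…
```

phospho-STAT1 peaks 3.6 hours after the 10 ng/ml IFN-γ stimulus at about
3.9 times its 48-h level: the transient peak-then-decay shape produced by
SOCS1/SOCS3 feedback sequestering the activated receptor complexes.  The
scripts in `examples/` walk through the other capabilities one at a time:

| script | shows |
|---|---|
| `examples/01_stimulation_time_course.py` | stimulation, marker fold changes |
| `examples/02_perturbations_and_score.py` | overexpression/silencing edits, IFN-γ/IL-4 antagonism, M1/M2 score |
| `examples/03_hypoxia_prcc.py` | Latin-hypercube + PRCC sensitivity under 2% O₂ |
| `examples/04_calibration_bootstrap.py` | pattern-search calibration, bootstrap identifiability |
| `examples/05_model_io_and_registry.py` | SBML/TSV round trips, calibration registry |

A thin command line mirrors the library (`macpol simulate`, `sensitivity`,
`calibrate`, `bootstrap`, `export-sbml`, `report`); scenario presets such
as `hypoxia_stat1_inh` package the standard perturbation protocols
(inhibition = the named production or binding rate at 10%, overexpression
= 50× initial level with unchanged production, silencing = zero initial
and zero production).

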