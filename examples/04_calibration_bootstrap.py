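"""Parameter calibration and bootstrap uncertainty on a toy cascade.

Generates synthetic noisy measurements from a ligand/receptor/STAT toy
model, refits two rate constants by pattern search from a displaced start,
and runs a small dataset-level bootstrap to contrast an identifiable rate
with a weakly identified one.
"""

import numpy as np

from macpol import (Scenario, StimulusEvent, ToySpec, bootstrap_fit,
                    equilibrate, fit, make_synthetic_datasets, make_toy)

model, _ = make_toy(ToySpec("ligand_receptor_stat"))
model = model.with_initial_state(equilibrate(model))


def step(name, dose):
    return Scenario(name=name, stimuli=[
        StimulusEvent("L", dose, time_added=0.0, in_copies=True)],
        horizon=24.0)


scens = [(step("hi", 1e4), "pS", np.array([0.5, 1, 2, 4, 8, 16.0])),
         (step("lo", 2e3), "pS", np.array([0.5, 1, 2, 4, 8, 16.0])),
         (step("inh", 1e4), "I", np.array([1, 2, 4, 8, 16.0]))]
datasets = make_synthetic_datasets(model, scens, noise_cv=0.05, seed=1)

truth = {k: model.parameters[k] for k in ("k_phos", "k_fb")}
start = model.copy()
start.parameters["k_phos"] = truth["k_phos"] * 3
start.parameters["k_fb"] = truth["k_fb"] / 3
bounds = {k: (v / 10, v * 10) for k, v in truth.items()}
result = fit(start, datasets, list(truth), bounds=bounds, seed=0,
             n_starts=1, max_iter=60)
for k, v in truth.items():
    print(f"{k}: true {v:.4g}, recovered {result.parameters[k]:.4g} "
          f"(ratio {result.parameters[k] / v:.3f})")
print(f"weighted SSE at the optimum: {result.objective_value:.4g}")
# both rates return to within a few percent of truth despite the 5% noise
# and the 3x displaced start

from macpol.toys import with_decoy_subnetwork

boot_model = with_decoy_subnetwork(model)  # adds an unobservable Z module
free = ["k_phos", "sz"]
boot_bounds = {k: (boot_model.parameters[k] / 10, boot_model.parameters[k] * 10)
               for k in free}
estimates = bootstrap_fit(boot_model, datasets, free, n_boot=5, seed=2,
                          start_jitter=0.5, bounds=boot_bounds,
                          n_starts=1, max_iter=25)
for k in free:
    vals = np.array([e[k] for e in estimates])
    print(f"bootstrap log-spread of {k}: {np.std(np.log(vals), ddof=1):.3f}")
# the phosphorylation rate is pinned by the data (small spread); sz feeds a
# subnetwork the observables cannot reach, so its jittered replicates stay
# scattered — structural non-identifiability made visible
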