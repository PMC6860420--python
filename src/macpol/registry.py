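"""Calibration dataset registry for the full polarization network.

The registry mirrors the structure of the literature calibration corpus the
network was built against — over 70 normalized measurement series (time
courses and single timepoints) with over 300 datapoints spanning the IFN-γ,
IL-4 and hypoxia arms.  Each entry records the stimulation scenario
(cytokine dose in ng/ml, oxygen condition, miR-mimic transfection), the
observable, the time grid and the normalization convention of its source
figure.

Measurement values are SYNTHETIC: the actual literature numbers are not
redistributable tables, so values are generated by simulating the model at
nominal parameters and applying seeded multiplicative lognormal noise.  The
registry therefore exercises the calibration machinery at the corpus's
documented scale and structure; it is not a transcription of the literature
values themselves.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .calibrate import CalibDataset
from .fullmodel import MW_IFNG, MW_IL4, build_full_model
from .model import ModelDefinition
from .scenarios import NormalizationMode, Scenario, normalize_series
from .simulate import OxygenCondition, StimulusEvent, equilibrate, run_scenario

__all__ = ["RegistryEntry", "REGISTRY_ENTRIES", "build_calibration_registry",
           "registry_summary", "write_registry_tsv", "load_registry_tsv"]

TC = (0.0, 1.0, 2.0, 4.0, 8.0, 12.0, 24.0)       # canonical time course
TC_EARLY = (0.0, 0.25, 0.5, 1.0, 2.0, 4.0, 8.0)  # early signaling course
TC_LONG = (0.0, 4.0, 8.0, 12.0, 24.0, 36.0, 48.0)


@dataclass(frozen=True)
class RegistryEntry:
    """Declarative description of one calibration series."""

    id: str
    observable: str
    times: tuple[float, ...]
    norm: str = "to_max"             # NormalizationMode.mode
    norm_ref: float | None = None
    ifng: float = 0.0                # ng/ml at t=0
    il4: float = 0.0                 # ng/ml at t=0
    o2: float | None = None          # percent, applied at t=0
    mimic: tuple[str, float] | None = None  # (miR species, copies at t=0)
    level: str = "protein"
    source: str = "synthetic"

    def scenario(self) -> Scenario:
        events = []
        if self.ifng > 0:
            events.append(StimulusEvent("IFNg_ext", self.ifng, MW_IFNG, 0.0))
        if self.il4 > 0:
            events.append(StimulusEvent("IL4", self.il4, MW_IL4, 0.0))
        if self.mimic is not None:
            sp, copies = self.mimic
            events.append(StimulusEvent(sp, copies, time_added=0.0,
                                        in_copies=True))
        oxygen = OxygenCondition(self.o2, 0.0) if self.o2 is not None else None
        horizon = max(self.times[-1], 24.0)
        return Scenario(name=self.id, stimuli=events, oxygen=oxygen,
                        horizon=horizon)


def _ifng_entries() -> list[RegistryEntry]:
    e = []
    for dose in (1.0, 10.0):
        tag = f"ifng{dose:g}"
        e += [
            RegistryEntry(f"{tag}_boundIFNg", "IFNg_RC", TC_EARLY,
                          ifng=dose, source="receptor-bound IFN-γ decay"),
            RegistryEntry(f"{tag}_pJAK", "IFNg_RCp", TC_EARLY, ifng=dose,
                          source="receptor-associated JAK phosphorylation"),
            RegistryEntry(f"{tag}_pSTAT1", "pSTAT1", TC_EARLY, ifng=dose,
                          source="STAT1 phosphorylation"),
            RegistryEntry(f"{tag}_IRF1", "IRF1", TC, ifng=dose,
                          source="IRF-1 expression"),
            RegistryEntry(f"{tag}_iNOS", "iNOS", TC, ifng=dose,
                          source="iNOS expression"),
        ]
    e += [
        RegistryEntry("ifng10_TNFa", "TNFa_sec", TC, norm="to_t0", ifng=10.0,
                      source="secreted TNFα"),
        RegistryEntry("ifng10_IL12", "IL12_sec", TC, ifng=10.0,
                      source="secreted IL-12"),
        RegistryEntry("ifng10_CXCL9", "CXCL9_sec", TC, ifng=10.0,
                      source="secreted CXCL9"),
        RegistryEntry("ifng10_CXCL10", "CXCL10_mRNA", TC, ifng=10.0,
                      level="mRNA", source="CXCL10 mRNA"),
        RegistryEntry("ifng10_miR3473b", "miR3473b", TC, ifng=10.0,
                      level="miR", source="miR-3473b downregulation"),
        RegistryEntry("ifng10_itaconate", "ITA", (18.0,),
                      norm="to_reference_time", norm_ref=18.0, ifng=10.0,
                      source="itaconate at 18 h"),
        RegistryEntry("m3473mimic_PTEN", "PTEN", (36.0,), norm="to_t0",
                      mimic=("miR3473b", 5.0e4),
                      source="PTEN after miR-3473b mimic (36 h)"),
        RegistryEntry("ifng10_HIF1a", "HIF1a", TC, ifng=10.0,
                      source="HIF-1α under IFN-γ (normoxia)"),
        RegistryEntry("ifng10hyp_HIF1a", "HIF1a", TC, ifng=10.0, o2=2.0,
                      source="HIF-1α under IFN-γ + hypoxia"),
        RegistryEntry("ifng10_SOCS1", "SOCS1", TC_EARLY, ifng=10.0,
                      source="SOCS1 induction"),
        RegistryEntry("ifng10_SOCS3", "SOCS3", TC_EARLY, ifng=10.0,
                      source="SOCS3 induction"),
        RegistryEntry("ifng10_pSTAT1n", "pSTAT1_n", TC_EARLY, ifng=10.0,
                      source="nuclear pSTAT1"),
        RegistryEntry("ifng1_CXCL10", "CXCL10_mRNA", TC, ifng=1.0,
                      level="mRNA", source="CXCL10 mRNA (low dose)"),
        RegistryEntry("ifng10_IRF9", "IRF9", TC, ifng=10.0,
                      source="IRF-9 expression"),
        RegistryEntry("ifng10_IRG1", "IRG1", TC, ifng=10.0,
                      source="IRG-1 expression"),
        RegistryEntry("ifng10_pAKT", "pAKT", TC, norm="to_t0", ifng=10.0,
                      source="AKT deactivation under IFN-γ"),
        RegistryEntry("ifng10_PTEN", "PTEN", TC, norm="to_t0", ifng=10.0,
                      source="PTEN de-repression"),
    ]
    return e


def _il4_entries() -> list[RegistryEntry]:
    e = []
    for dose in (5.0, 20.0):
        tag = f"il4{dose:g}"
        e += [
            RegistryEntry(f"{tag}_pSTAT6", "pSTAT6", TC_EARLY, il4=dose,
                          source="STAT6 phosphorylation"),
            RegistryEntry(f"{tag}_IRF4", "IRF4", TC, il4=dose,
                          source="IRF-4 upregulation"),
            RegistryEntry(f"{tag}_Arg1", "Arg1", TC_LONG, il4=dose,
                          source="Arg-1 expression"),
        ]
    e += [
        RegistryEntry("il420_IRF4_24h", "IRF4", (24.0,),
                      norm="to_reference_time", norm_ref=24.0, il4=20.0,
                      source="IRF-4 at 24 h"),
        RegistryEntry("il420_pAKT", "pAKT", TC_EARLY, il4=20.0,
                      source="AKT activation"),
        RegistryEntry("il420_PPARg", "PPARg", (18.0,), norm="to_t0", il4=20.0,
                      source="PPARγ at 18 h"),
        RegistryEntry("il420_Arg1_24h", "Arg1", (24.0,),
                      norm="to_reference_time", norm_ref=24.0, il4=20.0,
                      source="Arg-1 at 24 h"),
        RegistryEntry("il420_IL10", "IL10_sec", (24.0,), norm="to_t0",
                      il4=20.0, source="IL-10 secretion at 24 h"),
        RegistryEntry("il420_VEGF", "VEGF_sec", (24.0,), norm="to_t0",
                      il4=20.0, source="VEGF secretion at 24 h"),
        RegistryEntry("il420_TNFa", "TNFa_sec", (24.0,), norm="to_t0",
                      il4=20.0, source="TNFα downregulation at 24 h"),
        RegistryEntry("il420_HIF2a", "HIF2a", TC, il4=20.0,
                      source="HIF-2α under IL-4 (normoxia)"),
        RegistryEntry("il420hyp_HIF2a", "HIF2a", TC, il4=20.0, o2=2.0,
                      source="HIF-2α under IL-4 + hypoxia"),
        RegistryEntry("il420_pSTAT6n", "pSTAT6_n", TC_EARLY, il4=20.0,
                      source="nuclear pSTAT6"),
        RegistryEntry("il420_SOCS1", "SOCS1", TC_EARLY, il4=20.0,
                      source="SOCS1 induction by IL-4"),
        RegistryEntry("il420_MRC1", "MRC1", TC_LONG, il4=20.0,
                      source="MRC1/CD206 expression"),
        RegistryEntry("il45_IL10", "IL10_sec", TC, norm="to_t0", il4=5.0,
                      source="IL-10 secretion time course"),
        RegistryEntry("il45_VEGF", "VEGF_sec", TC, norm="to_t0", il4=5.0,
                      source="VEGF secretion time course"),
        RegistryEntry("il420_HIF1a", "HIF1a", TC, norm="to_t0", il4=20.0,
                      source="HIF-1α under IL-4 (minimal change)"),
    ]
    return e


def _hypoxia_entries() -> list[RegistryEntry]:
    return [
        RegistryEntry("hyp3_HIF1a", "HIF1a", TC, o2=3.0,
                      source="HIF-1α stabilization, 3% O2"),
        RegistryEntry("hyp3_HIF2a", "HIF2a", TC, o2=3.0,
                      source="HIF-2α stabilization, 3% O2"),
        RegistryEntry("hyp05_HIF1a_24h", "HIF1a", (24.0,),
                      norm="to_reference_time", norm_ref=24.0, o2=0.5,
                      source="HIF-1α at 24 h, 0.5% O2"),
        RegistryEntry("hyp05_HIF2a_24h", "HIF2a", (24.0,),
                      norm="to_reference_time", norm_ref=24.0, o2=0.5,
                      source="HIF-2α at 24 h, 0.5% O2"),
        RegistryEntry("hyp1_iNOS_8h", "iNOS", (8.0,), norm="to_t0", o2=1.0,
                      source="iNOS at 8 h, 1% O2"),
        RegistryEntry("hyp1_Arg1_8h", "Arg1", (8.0,), norm="to_t0", o2=1.0,
                      source="Arg-1 at 8 h, 1% O2"),
        RegistryEntry("hyp03_TNFa_24h", "TNFa_sec", (24.0,), norm="to_t0",
                      o2=0.3, source="TNFα secretion at 24 h, 0.3% O2"),
        RegistryEntry("hyp1_IFNg", "IFNg_ext", TC, norm="to_t0", o2=1.0,
                      source="IFN-γ secretion, 1% O2"),
        RegistryEntry("hyp1_VEGF_24h", "VEGF_sec", (24.0,), norm="to_t0",
                      o2=1.0, source="VEGF secretion at 24 h, 1% O2"),
        RegistryEntry("hyp2_miR93_12h", "miR93", (12.0,), norm="to_t0",
                      o2=2.0, level="miR", source="miR-93 at 12 h, 2% O2"),
        RegistryEntry("hyp2m93_IFNg_12h", "IFNg_ext", (12.0,), norm="to_t0",
                      o2=2.0, mimic=("miR93", 5.0e4),
                      source="IFN-γ at 12 h, 2% O2 + miR-93 mimic"),
        RegistryEntry("hyp2m93_TNFa", "TNFa_sec", TC, norm="to_t0", o2=2.0,
                      mimic=("miR93", 5.0e4),
                      source="TNFα under hypoxia + miR-93 mimic"),
        RegistryEntry("hyp2_PHD", "PHD", TC, norm="to_t0", o2=2.0,
                      source="PHD feedback induction"),
        RegistryEntry("hyp2_IRF9", "IRF9", TC, norm="to_t0", o2=2.0,
                      source="IRF-9 de-repression in hypoxia"),
        RegistryEntry("hyp2_IRF1", "IRF1", TC, norm="to_t0", o2=2.0,
                      source="IRF-1 induction in hypoxia"),
        RegistryEntry("hyp2_IRG1", "IRG1", TC, norm="to_t0", o2=2.0,
                      source="IRG-1 induction in hypoxia"),
        RegistryEntry("hyp2m93_IRF9", "IRF9", TC, norm="to_t0", o2=2.0,
                      mimic=("miR93", 5.0e4),
                      source="IRF-9 under miR-93 mimic"),
        RegistryEntry("hyp2m93_IRG1", "IRG1", TC, norm="to_t0", o2=2.0,
                      mimic=("miR93", 5.0e4),
                      source="IRG-1 under miR-93 mimic"),
        RegistryEntry("hyp2_Arg1", "Arg1", TC_LONG, norm="to_t0", o2=2.0,
                      source="Arg-1 time course in hypoxia"),
        RegistryEntry("hyp2_VEGF", "VEGF_sec", TC_LONG, norm="to_t0", o2=2.0,
                      source="VEGF time course in hypoxia"),
        RegistryEntry("hyp2_miR93", "miR93", TC, norm="to_t0", o2=2.0,
                      level="miR", source="miR-93 time course in hypoxia"),
    ]


def _costim_entries() -> list[RegistryEntry]:
    return [
        RegistryEntry("costim_iNOS", "iNOS", TC, norm="to_t0",
                      ifng=10.0, il4=5.0,
                      source="iNOS under simultaneous IFN-γ + IL-4"),
        RegistryEntry("costim_Arg1", "Arg1", TC, norm="to_t0",
                      ifng=10.0, il4=5.0,
                      source="Arg-1 under simultaneous IFN-γ + IL-4"),
        RegistryEntry("costim_TNFa", "TNFa_sec", TC, norm="to_t0",
                      ifng=10.0, il4=5.0,
                      source="TNFα under simultaneous IFN-γ + IL-4"),
        RegistryEntry("costim_IL10", "IL10_sec", TC, norm="to_t0",
                      ifng=10.0, il4=5.0,
                      source="IL-10 under simultaneous IFN-γ + IL-4"),
    ]


REGISTRY_ENTRIES: tuple[RegistryEntry, ...] = tuple(
    _ifng_entries() + _il4_entries() + _hypoxia_entries() + _costim_entries())


def build_calibration_registry(
    model: ModelDefinition | None = None,
    noise_cv: float = 0.08,
    seed: int = 13,
    baseline=None,
    entries=None,
) -> list[CalibDataset]:
    """Simulate every registry entry and package noisy normalized datasets."""
    model = model or build_full_model()
    entries = entries if entries is not None else REGISTRY_ENTRIES
    if baseline is None:
        baseline = equilibrate(model, residual_tol=1e-6)
    base_model = model.with_initial_state(baseline)
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(np.log1p(noise_cv ** 2))
    idx = model.species_index
    out = []
    cache: dict[tuple, object] = {}  # entries sharing a scenario share one run
    for entry in entries:
        scen = entry.scenario()
        key = (entry.ifng, entry.il4, entry.o2, entry.mimic, scen.horizon)
        result = cache.get(key)
        if result is None:
            result = run_scenario(base_model, events=scen.stimuli,
                                  oxygen=scen.oxygen, horizon=scen.horizon,
                                  n_grid=121)
            cache[key] = result
        mode = NormalizationMode(entry.norm, reference=entry.norm_ref)
        utr = float(baseline[idx[entry.observable]]) \
            if entry.norm == "to_untreated" else None
        series = normalize_series(result[entry.observable], result.time, mode,
                                  untreated=utr, species=entry.observable)
        values = np.interp(entry.times, result.time, series)
        if noise_cv > 0:
            values = values * rng.lognormal(-sigma ** 2 / 2, sigma,
                                            size=len(values))
        out.append(CalibDataset(
            id=entry.id, scenario=scen, observable=entry.observable,
            points=tuple(zip(entry.times, values)),
            normalization=mode, level=entry.level,
            source=f"synthetic | {entry.source}"))
    return out


def registry_summary(datasets: list[CalibDataset]) -> dict:
    return {
        "n_datasets": len(datasets),
        "n_points": int(sum(len(d.points) for d in datasets)),
        "n_observables": len({d.observable for d in datasets}),
        "n_timecourse": sum(len(d.points) > 1 for d in datasets),
        "n_single_timepoint": sum(len(d.points) == 1 for d in datasets),
    }


def write_registry_tsv(datasets: list[CalibDataset], path: str | Path) -> Path:
    """One row per point with dataset metadata columns (S3-table style)."""
    rows = []
    for d in datasets:
        for t, v in d.points:
            rows.append({
                "dataset": d.id, "observable": d.observable, "level": d.level,
                "time_h": t, "value": v, "normalization": d.normalization.mode,
                "norm_reference": d.normalization.reference,
                "weight": d.effective_weight, "source": d.source,
            })
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return path


def load_registry_tsv(path: str | Path,
                      entries=None) -> list[CalibDataset]:
    """Rebuild datasets from a registry TSV (scenarios from REGISTRY_ENTRIES)."""
    entries = {e.id: e for e in (entries or REGISTRY_ENTRIES)}
    frame = pd.read_csv(path, sep="\t")
    out = []
    for ds_id, grp in frame.groupby("dataset", sort=False):
        if ds_id not in entries:
            raise KeyError(f"registry TSV references unknown dataset {ds_id!r}")
        entry = entries[ds_id]
        ref = grp["norm_reference"].iloc[0]
        mode = NormalizationMode(grp["normalization"].iloc[0],
                                 reference=None if pd.isna(ref) else float(ref))
        out.append(CalibDataset(
            id=ds_id, scenario=entry.scenario(),
            observable=grp["observable"].iloc[0],
            points=tuple(zip(grp["time_h"], grp["value"])),
            normalization=mode, level=grp["level"].iloc[0],
            source=grp["source"].iloc[0]))
    return out
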