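"""Synthetic inputs with the statistical structure the analyses assume.

Nothing from the original wet-lab experiments is deposited, so every
pipeline stage is exercised on generated data.  Packaged *effect
profiles* encode the study's printed effect sizes (a four-fold aspartate
increase in MPC1-null MEFs, 46 differential ions among 222 in the
normal-diet embryonic brain, a residual 30% lactate increase under the
ketogenic diet, MPC1 transcript at 5% of wild type) so that downstream
recovery is a sharp test; everything not printed (baseline intensities,
the identity of unnamed differential ions) is a documented free choice.

All generators are deterministic under a fixed seed and emit ground
truth alongside the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from .diff_stats import SampleDesign
from .fia_annotation import CompoundRecord, enumerate_ions, load_compound_library
from .isotope_correction import NATURAL_13C_ABUNDANCE, contaminate_mid, correction_matrix
from .respirometry import OCRTrace
from .tracer_sim import FluxScenario, TracerSpec, build_network, simulate_steady_state

__all__ = [
    "EffectProfile",
    "load_profile",
    "list_profiles",
    "gen_intensity_matrix",
    "gen_isotopologue_data",
    "gen_fia_peaklist",
    "gen_ocr_trace",
    "gen_cq_table",
    "OCR_PLATEAUS",
]

#: internal seed fixing per-ion baseline abundances across runs (baselines
#: are a property of the emulated tissue, not of the sampling noise)
_BASELINE_SEED = 20160513


@dataclass
class EffectProfile:
    """Programmed group effects for one synthetic study arm.

    ``fold_changes`` maps metabolite -> mutant/wild-type ratio (absent
    metabolites are unaffected, ratio 1); hits are by construction the
    metabolites with |log2 ratio| > 0.5.
    """

    name: str
    kind: str
    diet: str = "normal"
    n_per_group: int = 4
    cv: float = 0.10
    fold_changes: dict[str, float] = field(default_factory=dict)
    baselines: dict[str, float] = field(default_factory=dict)
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        for met, fc in self.fold_changes.items():
            if fc <= 0:
                raise ValueError(f"{self.name}: fold change for {met} must be > 0")

    @property
    def hits(self) -> set[str]:
        return {m for m, fc in self.fold_changes.items() if abs(np.log2(fc)) > 0.5}


def _profile_store() -> dict:
    ref = resources.files("mpctrace") / "data" / "profiles.yaml"
    with resources.as_file(ref) as p, open(p) as fh:
        return yaml.safe_load(fh)


def list_profiles() -> list[str]:
    return sorted(_profile_store())


def load_profile(name: str) -> EffectProfile:
    store = _profile_store()
    if name not in store:
        raise KeyError(f"unknown profile {name!r}; available: {sorted(store)}")
    raw = dict(store[name])
    known = {"kind", "diet", "n_per_group", "cv", "fold_changes", "baselines"}
    extra = {k: v for k, v in raw.items() if k not in known}
    return EffectProfile(
        name=name,
        kind=raw["kind"],
        diet=raw.get("diet", "normal"),
        n_per_group=int(raw.get("n_per_group", 4)),
        cv=float(raw.get("cv", 0.10)),
        fold_changes=dict(raw.get("fold_changes", {})),
        baselines=dict(raw.get("baselines", {})),
        extra=extra,
    )


def _lognormal_sigma(cv: float) -> float:
    # CV of a log-normal with log-sd sigma is sqrt(exp(sigma^2) - 1)
    return float(np.sqrt(np.log1p(cv**2)))


def _brain_baselines(library: list[CompoundRecord]) -> dict[str, float]:
    rng = np.random.default_rng(_BASELINE_SEED)
    ids = [c.compound_id for c in library]
    values = np.exp(rng.normal(11.0, 1.0, size=len(ids)))
    return dict(zip(ids, values))


def gen_intensity_matrix(
    profile: EffectProfile,
    seed: int,
    library: list[CompoundRecord] | None = None,
    n_per_group: int | None = None,
    cv: float | None = None,
):
    """Samples x metabolites intensity matrix with programmed group effects.

    Intensity = baseline x (fold change if mutant) x log-normal noise at
    the profile's coefficient of variation.  Returns ``(matrix, design,
    truth)`` where truth lists each metabolite's programmed fold change
    and hit status.
    """
    n = int(n_per_group if n_per_group is not None else profile.n_per_group)
    cv = float(cv if cv is not None else profile.cv)
    if profile.kind == "brain":
        if library is None:
            library = load_compound_library()
        baselines = _brain_baselines(library)
    else:
        baselines = dict(profile.baselines)
    mets = list(baselines)
    rng = np.random.default_rng(seed)
    sigma = _lognormal_sigma(cv)
    rows, design_rows = [], []
    for genotype in ("wt", "gt"):
        for i in range(1, n + 1):
            sid = f"{genotype}_{profile.diet}_{i}"
            vals = []
            for met in mets:
                mu = baselines[met]
                if genotype == "gt":
                    mu *= profile.fold_changes.get(met, 1.0)
                noise = np.exp(rng.normal(0.0, sigma)) if sigma > 0 else 1.0
                vals.append(mu * noise)
            rows.append(pd.Series(vals, index=mets, name=sid))
            design_rows.append({"sample_id": sid, "genotype": genotype,
                                "diet": profile.diet})
    matrix = pd.DataFrame(rows)
    design = SampleDesign(pd.DataFrame(design_rows))
    truth = pd.DataFrame(
        {
            "metabolite_id": mets,
            "fold_change": [profile.fold_changes.get(m, 1.0) for m in mets],
            "is_hit": [m in profile.hits for m in mets],
        }
    )
    return matrix, design, truth


def gen_isotopologue_data(
    scenario: FluxScenario,
    tracer: TracerSpec,
    p_nat: float = NATURAL_13C_ABUNDANCE,
    noise: float = 0.0,
    seed: int = 0,
):
    """Raw isotopologue fraction table emulating a tracer experiment.

    Ground-truth MIDs from the steady-state simulator are
    forward-contaminated with natural ¹³C at ``p_nat``, multiplied by
    log-normal noise of relative magnitude ``noise`` and renormalised.
    Returns ``(table, truth)``: a tidy frame (metabolite, isotopologue,
    fraction) and the clean simulator MIDs.
    """
    network = build_network(scenario)
    truth = simulate_steady_state(network, tracer)
    rng = np.random.default_rng(seed)
    records = []
    for met, mid in truth.items():
        n = mid.size - 1
        raw = contaminate_mid(mid, correction_matrix(n, p_nat)) if p_nat > 0 else mid
        if noise > 0:
            raw = raw * np.exp(rng.normal(0.0, noise, size=raw.size))
            raw = raw / raw.sum()
        for i, frac in enumerate(raw):
            records.append({"metabolite_id": met, "isotopologue": i,
                            "fraction": float(frac)})
    return pd.DataFrame.from_records(records), truth


def gen_fia_peaklist(
    library: list[CompoundRecord],
    mass_error_sd: float = 0.0,
    n_decoys: int = 0,
    seed: int = 0,
    adducts=("deprotonated",),
    max_isotope: int = 0,
    decoy_margin: float = 0.005,
):
    """Centroid peak list emulating negative-mode flow-injection QTOF output.

    One peak per in-range library ion (m/z jittered by a Gaussian of sd
    ``mass_error_sd``), plus ``n_decoys`` uniform-random peaks kept at
    least ``decoy_margin`` Da away from every candidate so they can
    never be annotated at the default tolerance.  Returns ``(peaks,
    truth)``; truth maps each true peak to its source ion ('' for
    decoys).
    """
    rng = np.random.default_rng(seed)
    candidates = enumerate_ions(library, adducts=adducts, max_isotope=max_isotope)
    cand_mz = np.array([c.mz for c in candidates])
    records = []
    for cand in candidates:
        mz = cand.mz + (rng.normal(0.0, mass_error_sd) if mass_error_sd > 0 else 0.0)
        intensity = float(np.exp(rng.normal(9.0, 0.5)) * 0.5**cand.isotope_shift)
        records.append({"mz": float(mz), "intensity": intensity,
                        "compound_id": cand.compound_id, "adduct": cand.adduct,
                        "isotope_shift": cand.isotope_shift})
    added = 0
    while added < n_decoys:
        mz = rng.uniform(50.0, 1000.0)
        if np.min(np.abs(cand_mz - mz)) < decoy_margin:
            continue
        records.append({"mz": float(mz), "intensity": float(np.exp(rng.normal(7.0, 0.5))),
                        "compound_id": "", "adduct": "", "isotope_shift": -1})
        added += 1
    truth = pd.DataFrame.from_records(records)
    peaks = truth[["mz", "intensity"]].copy()
    return peaks, truth


#: programmed phase plateaus (pmol O2/min/well) for the OCR generator.
#: Basal respiration is unaffected by MPC loss in permeabilized cells;
#: the fCCP-evoked maximum collapses with pyruvate/malate as the only
#: substrates unless membrane-permeable methyl pyruvate bypasses the
#: carrier; succinate feeds complex II downstream of the block.
OCR_PLATEAUS: dict[tuple[str, bool], dict[str, float]] = {
    ("wt", False): {"basal": 60.0, "fccp": 150.0, "succinate_rotenone": 180.0,
                    "antimycin_a": 15.0},
    ("wt", True): {"basal": 60.0, "fccp": 155.0, "succinate_rotenone": 180.0,
                   "antimycin_a": 15.0},
    ("mutant", False): {"basal": 55.0, "fccp": 45.0, "succinate_rotenone": 175.0,
                        "antimycin_a": 15.0},
    ("mutant", True): {"basal": 60.0, "fccp": 148.0, "succinate_rotenone": 178.0,
                       "antimycin_a": 15.0},
}

#: one measurement loop = 30 s mixing + 60 s waiting + 120 s measuring
_LOOP_SECONDS = 210.0


def gen_ocr_trace(
    scenario: str = "wt",
    methyl_pyruvate: bool = False,
    seed: int = 0,
    noise_sd: float = 0.0,
    loops_per_phase: int = 3,
    cell_count: float = 30_000.0,
):
    """Piecewise-constant OCR trace with injection events.

    Returns ``(trace, plateaus)`` where plateaus are the programmed
    noise-free phase levels.
    """
    key = (scenario, methyl_pyruvate)
    if key not in OCR_PLATEAUS:
        raise ValueError(f"unknown OCR scenario {scenario!r}")
    plateaus = OCR_PLATEAUS[key]
    rng = np.random.default_rng(seed)
    times, ocr, injections = [], [], []
    t = _LOOP_SECONDS
    for phase in ("basal", "fccp", "succinate_rotenone", "antimycin_a"):
        if phase != "basal":
            injections.append((t - _LOOP_SECONDS / 2.0, phase))
        for _ in range(loops_per_phase):
            times.append(t)
            level = plateaus[phase]
            ocr.append(level + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0))
            t += _LOOP_SECONDS
    trace = OCRTrace(
        times=np.array(times), ocr=np.array(ocr), injections=injections,
        cell_count=cell_count, well_id=f"{scenario}{'+mepyr' if methyl_pyruvate else ''}",
    )
    return trace, dict(plateaus)


def gen_cq_table(
    profile: EffectProfile | None = None,
    seed: int = 0,
    n_per_group: int | None = None,
    noise_sd: float | None = None,
):
    """qPCR Cq table for MPC1/MPC2 with a 28S reference.

    Cq values are arranged so that the 2^-ddCq method recovers the
    programmed relative expressions (wild-type calibrator): the target
    Cq of a genotype is offset by -log2(relative expression) cycles.
    Returns ``(table, truth)``; truth lists the programmed expression
    per genotype and gene.
    """
    if profile is None:
        profile = load_profile("paper_qpcr")
    if profile.kind != "qpcr":
        raise ValueError(f"profile {profile.name!r} is not a qPCR profile")
    n = int(n_per_group if n_per_group is not None else profile.n_per_group)
    sd = float(noise_sd if noise_sd is not None else profile.extra.get("noise_sd", 0.0))
    ref_gene = profile.extra["reference_gene"]
    ref_cq = float(profile.extra["reference_cq"])
    baseline = profile.extra["baseline_cq"]
    rel = profile.extra["relative_expression"]
    rng = np.random.default_rng(seed)
    rows, truth_rows = [], []
    for genotype, gene_rel in rel.items():
        for i in range(1, n + 1):
            sid = f"{genotype}_{i}"
            noise = rng.normal(0.0, sd) if sd > 0 else 0.0
            rows.append({"sample_id": sid, "genotype": genotype,
                         "gene": ref_gene, "cq": ref_cq + noise})
            for gene, expr in gene_rel.items():
                noise = rng.normal(0.0, sd) if sd > 0 else 0.0
                cq = baseline[gene] - np.log2(expr) + noise
                rows.append({"sample_id": sid, "genotype": genotype,
                             "gene": gene, "cq": float(cq)})
        for gene, expr in gene_rel.items():
            truth_rows.append({"genotype": genotype, "gene": gene,
                               "relative_expression": expr})
    return pd.DataFrame.from_records(rows), pd.DataFrame.from_records(truth_rows)
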