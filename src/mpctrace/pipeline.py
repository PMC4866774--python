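"""End-to-end study runners.

Each study generates its synthetic inputs, runs the corresponding stage
sequence and writes plain TSV tables plus a human-readable text report
into an output directory.  All randomness flows from the single config
seed, so two runs with the same config produce byte-identical files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import diff_stats, respirometry, synthetic_data
from .fia_annotation import IonAnnotator, load_compound_library
from .isotope_correction import NATURAL_13C_ABUNDANCE
from .tracer_sim import SCENARIOS, TracerSpec

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_study", "write_report", "STUDIES"]

STUDIES = ("tracer", "mef_targeted", "brain", "ocr", "qpcr")

#: the three tracer experiments of the labeling study
TRACERS = {
    "U13C_glucose": TracerSpec.uniform("glucose"),
    "U13C_glutamine": TracerSpec.uniform("glutamine"),
    "1_13C_glutamine": TracerSpec.positional("glutamine", {1}),
}

_REPORTED_POOLS = ("citrate", "succinate", "malate", "aspartate")
_FLOAT_FMT = "%.10g"


@dataclass
class RunConfig:
    """Configuration for one study run."""

    study: str
    seed: int = 1
    outdir: Path = Path("mpctrace_out")
    q_thresh: float = 0.01
    fc_thresh: float = 0.5
    tolerance: float = 0.001
    p_nat: float = NATURAL_13C_ABUNDANCE
    options: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.study not in STUDIES:
            raise ValueError(f"unknown study {self.study!r}; choose from {STUDIES}")
        for fname in ("q_thresh", "fc_thresh", "tolerance"):
            if getattr(self, fname) <= 0:
                raise ValueError(f"{fname} must be positive")
        if not 0 <= self.p_nat < 1:
            raise ValueError("p_nat must be in [0, 1)")
        self.outdir = Path(self.outdir)


def _child_seeds(seed: int, n: int) -> list[int]:
    state = np.random.SeedSequence(seed).generate_state(n)
    return [int(s % (2**31)) for s in state]


def _write(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index, float_format=_FLOAT_FMT)


def _run_tracer(cfg: RunConfig, out: Path) -> dict:
    summary: dict = {"study": "tracer", "scenarios": {}}
    frames = []
    for scen_name, scenario in SCENARIOS.items():
        summary["scenarios"][scen_name] = {}
        for tracer_name, tracer in TRACERS.items():
            table, truth = synthetic_data.gen_isotopologue_data(
                scenario, tracer, p_nat=cfg.p_nat, noise=0.0, seed=cfg.seed
            )
            table.insert(0, "tracer", tracer_name)
            table.insert(0, "scenario", scen_name)
            frames.append(table)
            key_fracs = {}
            for pool in _REPORTED_POOLS:
                mid = truth[pool]
                key_fracs[pool] = {
                    "M+1": float(mid[1]), "M+2": float(mid[2]), "M+3": float(mid[3]),
                }
            summary["scenarios"][scen_name][tracer_name] = key_fracs
    _write(pd.concat(frames, ignore_index=True), out / "simulated_mids.tsv")
    return summary


def _run_mef_targeted(cfg: RunConfig, out: Path) -> dict:
    profile = synthetic_data.load_profile("paper_mef_targeted")
    matrix, design, truth = synthetic_data.gen_intensity_matrix(profile, cfg.seed)
    fc = diff_stats.fold_change_table(matrix, design)
    _write(matrix, out / "mef_abundances.tsv", index=True)
    _write(design.frame, out / "mef_design.tsv")
    _write(truth, out / "mef_truth.tsv")
    _write(fc, out / "mef_fold_changes.tsv")
    ratios = dict(zip(fc["metabolite_id"], fc["ratio"]))
    return {
        "study": "mef_targeted",
        "fold_changes": {k: float(v) for k, v in ratios.items()},
        "aspartate_ratio": float(ratios["aspartate"]),
    }


def _run_brain(cfg: RunConfig, out: Path) -> dict:
    seeds = _child_seeds(cfg.seed, 4)
    library = load_compound_library()

    # annotation stage on a clean flow-injection fixture
    peaks, peak_truth = synthetic_data.gen_fia_peaklist(
        library, mass_error_sd=0.0, n_decoys=0, seed=seeds[0]
    )
    annotator = IonAnnotator(adducts=("deprotonated",), max_isotope=0,
                             tolerance=cfg.tolerance).fit(library)
    ion_table = annotator.transform(peaks.itertuples(index=False, name=None))
    _write(ion_table, out / "brain_ion_table.tsv")

    # genotype screens per diet on profile-matched intensity matrices
    matrices, designs, screens = {}, {}, {}
    for diet, seed in (("normal", seeds[1]), ("keto", seeds[2])):
        profile = synthetic_data.load_profile(f"paper_brain_{diet}")
        matrix, design, truth = synthetic_data.gen_intensity_matrix(
            profile, seed, library=library
        )
        screen = diff_stats.univariate_screen(
            matrix, design, diet=diet, q_thresh=cfg.q_thresh, fc_thresh=cfg.fc_thresh
        )
        matrices[diet], designs[diet], screens[diet] = matrix, design, screen
        _write(matrix, out / f"brain_matrix_{diet}.tsv", index=True)
        _write(design.frame, out / f"brain_design_{diet}.tsv")
        _write(truth, out / f"brain_truth_{diet}.tsv")
        _write(screen, out / f"brain_screen_{diet}.tsv")

    hits = {
        diet: set(s.loc[s["passes"], "metabolite_id"]) for diet, s in screens.items()
    }
    union_hits = sorted(hits["normal"] | hits["keto"])

    # PCA across both diets
    combined = pd.concat([matrices["normal"], matrices["keto"]])
    combined_design = diff_stats.SampleDesign(
        pd.concat([designs["normal"].frame, designs["keto"].frame], ignore_index=True)
    )
    scores, loadings, explained = diff_stats.pca(np.log2(combined), scale=False)
    _write(scores.iloc[:, :5], out / "brain_pca_scores.tsv", index=True)
    _write(loadings.iloc[:, :5], out / "brain_pca_loadings.tsv", index=True)

    # energy charge and the keto-diet residual lactate effect
    pcr = diff_stats.pcr_cr_ratio(combined, combined_design)
    _write(pcr, out / "brain_pcr_cr.tsv")
    pcr_means = (
        pcr.groupby(["genotype", "diet"])["pcr_cr"].mean().to_dict()
    )
    keto_fc = diff_stats.fold_change_table(matrices["keto"], designs["keto"])
    lactate_ratio = float(
        keto_fc.set_index("metabolite_id").loc["lactate", "ratio"]
    )

    total_var = float(np.sum(explained))
    return {
        "study": "brain",
        "n_ions_annotated": int(len(ion_table)),
        "hits_per_diet": {d: len(h) for d, h in hits.items()},
        "union_hit_count": len(union_hits),
        "union_hits": union_hits,
        "pc1_variance_pct": float(100 * explained[0] / total_var),
        "pc2_variance_pct": float(100 * explained[1] / total_var),
        "pcr_cr_group_means": {f"{g}/{d}": float(v) for (g, d), v in pcr_means.items()},
        "keto_lactate_increase_pct": 100.0 * (lactate_ratio - 1.0),
    }


def _run_ocr(cfg: RunConfig, out: Path) -> dict:
    seeds = _child_seeds(cfg.seed, 3)
    conditions = [("wt", False, seeds[0]), ("mutant", False, seeds[1]),
                  ("mutant", True, seeds[2])]
    rows, values = [], {}
    subtract = cfg.options.get("subtract_floor", True)
    for scen, mepyr, seed in conditions:
        trace, plateaus = synthetic_data.gen_ocr_trace(
            scen, methyl_pyruvate=mepyr, seed=seed,
            noise_sd=cfg.options.get("noise_sd", 2.0),
        )
        value = respirometry.fccp_driven_ocr(trace, subtract_floor=subtract)
        per_cell = respirometry.cell_normalize(value, trace.cell_count)
        values[trace.well_id] = float(value)
        for t, o in zip(trace.times, trace.ocr):
            rows.append({"well_id": trace.well_id, "time_s": t, "ocr": o})
        rows_inj = [{"well_id": trace.well_id, "time_s": t, "ocr": np.nan,
                     "injection": lab} for t, lab in trace.injections]
        rows.extend(rows_inj)
        values[f"{trace.well_id}_per_1e4_cells"] = float(per_cell)
    _write(pd.DataFrame(rows), out / "ocr_traces.tsv")
    return {"study": "ocr", "fccp_driven_ocr": values}


def _run_qpcr(cfg: RunConfig, out: Path) -> dict:
    table, truth = synthetic_data.gen_cq_table(seed=cfg.seed)
    _write(table, out / "qpcr_cq.tsv")
    _write(truth, out / "qpcr_truth.tsv")
    result = {}
    for gene in ("MPC1", "MPC2"):
        rel = diff_stats.qpcr_relative_expression(table, target=gene)
        _write(rel, out / f"qpcr_relative_{gene}.tsv")
        result[gene] = {
            g: float(v) for g, v in
            rel.groupby("genotype")["relative_expression"].mean().items()
        }
    return {"study": "qpcr", "relative_expression": result}


_RUNNERS = {
    "tracer": _run_tracer,
    "mef_targeted": _run_mef_targeted,
    "brain": _run_brain,
    "ocr": _run_ocr,
    "qpcr": _run_qpcr,
}


def run_study(cfg: RunConfig) -> dict:
    """Run one study end to end; returns the summary dict and writes
    tables plus ``report_<study>.txt`` under ``cfg.outdir``."""
    out = cfg.outdir / cfg.study
    out.mkdir(parents=True, exist_ok=True)
    logger.info("running study=%s seed=%d q<%g |log2FC|>%g tol=%g Da",
                cfg.study, cfg.seed, cfg.q_thresh, cfg.fc_thresh, cfg.tolerance)
    summary = _RUNNERS[cfg.study](cfg, out)
    summary["seed"] = cfg.seed
    summary["thresholds"] = {
        "q_thresh": cfg.q_thresh, "fc_thresh": cfg.fc_thresh,
        "tolerance_da": cfg.tolerance, "p_nat": cfg.p_nat,
    }
    report = write_report(summary)
    (out / f"report_{cfg.study}.txt").write_text(report)
    return summary


def _fmt(value, nd=4):
    return f"{value:.{nd}g}" if isinstance(value, float) else str(value)


def write_report(summary: dict) -> str:
    """Render a study summary as a plain-text report."""
    lines = ["mpctrace study report", "====================="]
    if not summary:
        return "\n".join(lines) + "\n"
    study = summary.get("study", "?")
    lines.append(f"study: {study}")
    if "seed" in summary:
        lines.append(f"seed: {summary['seed']}")
    if "thresholds" in summary:
        th = summary["thresholds"]
        lines.append(
            "thresholds: q_thresh=%s fc_thresh=%s tolerance_da=%s p_nat=%s"
            % (th["q_thresh"], th["fc_thresh"], th["tolerance_da"], th["p_nat"])
        )
    if study == "tracer":
        for scen, tracers in summary["scenarios"].items():
            for tracer, pools in tracers.items():
                for pool, fracs in pools.items():
                    if tracer == "U13C_glucose":
                        shown = {"M+2": fracs["M+2"]}
                    elif tracer == "U13C_glutamine":
                        shown = {"M+2": fracs["M+2"], "M+3": fracs["M+3"]}
                    else:
                        shown = {"M+1": fracs["M+1"]}
                    frac_txt = " ".join(f"{k}={v:.4f}" for k, v in shown.items())
                    lines.append(f"  {scen} {tracer} {pool}: {frac_txt}")
    elif study == "mef_targeted":
        for met, ratio in summary["fold_changes"].items():
            lines.append(f"  fold change gt/wt {met}: {_fmt(float(ratio))}")
    elif study == "brain":
        lines.append(f"  annotated metabolite ions: {summary['n_ions_annotated']}")
        for diet, n in summary["hits_per_diet"].items():
            lines.append(f"  screen hits ({diet} diet): {n}")
        lines.append(f"  union hits across diets: {summary['union_hit_count']}")
        lines.append(f"  PC1 variance: {summary['pc1_variance_pct']:.1f}%")
        for grp, v in summary["pcr_cr_group_means"].items():
            lines.append(f"  PCr/Cr mean {grp}: {_fmt(float(v))}")
        lines.append(
            "  keto-diet lactate increase gt vs wt: "
            f"{summary['keto_lactate_increase_pct']:.1f}%"
        )
    elif study == "ocr":
        for well, v in summary["fccp_driven_ocr"].items():
            lines.append(f"  fCCP-driven OCR {well}: {_fmt(float(v))}")
    elif study == "qpcr":
        for gene, groups in summary["relative_expression"].items():
            for genotype, v in groups.items():
                lines.append(
                    f"  {gene} relative expression {genotype}: {_fmt(float(v))}"
                )
    return "\n".join(lines) + "\n"
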