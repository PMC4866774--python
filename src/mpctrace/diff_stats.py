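"""Differential metabolomics statistics.

Covers the downstream analyses of both the targeted MEF dataset and the
non-targeted brain metabolome: principal component analysis, the
per-metabolite genotype screen (Student's t on log intensities with
Benjamini-Hochberg FDR, significance requiring q below a threshold and
|log2 fold change| above one), fold-change tables against a reference
genotype, the phosphocreatine/creatine energy-charge ratio, and qPCR
relative expression by the 2^-ddCq method.

Fold changes are reported mutant over wild type throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

__all__ = [
    "SampleDesign",
    "pca",
    "bh_qvalues",
    "univariate_screen",
    "UnivariateScreen",
    "fold_change_table",
    "pcr_cr_ratio",
    "qpcr_relative_expression",
]


@dataclass
class SampleDesign:
    """Sample annotations: genotype in {wt, gt}, diet in {normal, keto}."""

    frame: pd.DataFrame  # columns: sample_id, genotype, diet

    def __post_init__(self):
        required = {"sample_id", "genotype", "diet"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValueError(f"design is missing columns {sorted(missing)}")
        if self.frame[list(required)].isna().any().any():
            raise ValueError("design contains missing factor labels")

    def samples(self, genotype: str | None = None, diet: str | None = None) -> list[str]:
        sel = self.frame
        if genotype is not None:
            sel = sel[sel["genotype"] == genotype]
        if diet is not None:
            sel = sel[sel["diet"] == diet]
        return sel["sample_id"].tolist()


def pca(matrix: pd.DataFrame, scale: bool = False):
    """Full principal component analysis of a samples x metabolites matrix.

    Columns are mean-centred (and unit-scaled when ``scale`` is true)
    before singular value decomposition.  Returns ``(scores, loadings,
    explained_variance)`` with ``scores @ loadings.T`` reconstructing the
    centred matrix and explained variances summing to the total variance.
    """
    X = np.asarray(matrix, dtype=float)
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("PCA needs at least 2 samples and 2 metabolites")
    centred = X - X.mean(axis=0)
    if scale:
        sd = centred.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        centred = centred / sd
    if np.allclose(centred, 0.0):
        warnings.warn("constant matrix: all principal components have zero variance")
    u, s, vt = np.linalg.svd(centred, full_matrices=False)
    scores = u * s
    loadings = vt.T
    explained = s**2 / (X.shape[0] - 1)
    n_comp = scores.shape[1]
    comp_names = [f"PC{i + 1}" for i in range(n_comp)]
    scores = pd.DataFrame(scores, index=matrix.index, columns=comp_names)
    loadings = pd.DataFrame(loadings, index=matrix.columns, columns=comp_names)
    return scores, loadings, explained


def bh_qvalues(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _two_sample_t(a: np.ndarray, b: np.ndarray, equal_var: bool) -> tuple[float, float]:
    # degenerate case: no variance anywhere and equal means -> uninformative
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        if a[0] == b[0]:
            return 0.0, 1.0
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    if np.isnan(p):  # zero pooled variance with unequal means
        return np.inf if a.mean() > b.mean() else -np.inf, 0.0
    return float(t), float(p)


def univariate_screen(
    matrix: pd.DataFrame,
    design: SampleDesign,
    diet: str | None = None,
    q_thresh: float = 0.01,
    fc_thresh: float = 0.5,
    log_transform: bool = True,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Per-metabolite genotype screen (gt vs wt) within one diet.

    The t statistic is computed on log2-transformed intensities (MS
    intensity noise is close to log-normal); the fold change is the
    ratio of raw group means, mutant over wild type.  q values are BH
    across all metabolites in the matrix; a metabolite passes when
    ``q < q_thresh`` and ``|log2 fold change| > fc_thresh``.
    """
    gt = design.samples(genotype="gt", diet=diet)
    wt = design.samples(genotype="wt", diet=diet)
    if len(gt) < 2 or len(wt) < 2:
        raise ValueError("each genotype group needs >= 2 samples")
    A = matrix.loc[gt]
    B = matrix.loc[wt]
    records = []
    for met in matrix.columns:
        a, b = A[met].to_numpy(float), B[met].to_numpy(float)
        ta, tb = (np.log2(a), np.log2(b)) if log_transform else (a, b)
        t, p = _two_sample_t(ta, tb, equal_var)
        log2fc = float(np.log2(a.mean() / b.mean()))
        records.append({"metabolite_id": met, "log2fc": log2fc, "t": t, "p": p})
    out = pd.DataFrame.from_records(records)
    out["q"] = bh_qvalues(out["p"].to_numpy())
    out["passes"] = (out["q"] < q_thresh) & (out["log2fc"].abs() > fc_thresh)
    return out


class UnivariateScreen(BaseEstimator):
    """Estimator form of the genotype screen; ``fit`` stores the
    differential table as ``results_`` and the passing set as ``hits_``."""

    def __init__(self, diet=None, q_thresh=0.01, fc_thresh=0.5,
                 log_transform=True, equal_var=True):
        self.diet = diet
        self.q_thresh = q_thresh
        self.fc_thresh = fc_thresh
        self.log_transform = log_transform
        self.equal_var = equal_var

    def fit(self, matrix: pd.DataFrame, design: SampleDesign):
        self.results_ = univariate_screen(
            matrix, design, diet=self.diet, q_thresh=self.q_thresh,
            fc_thresh=self.fc_thresh, log_transform=self.log_transform,
            equal_var=self.equal_var,
        )
        self.hits_ = set(self.results_.loc[self.results_["passes"], "metabolite_id"])
        return self


def fold_change_table(
    matrix: pd.DataFrame,
    design: SampleDesign,
    group_genotype: str = "gt",
    reference_genotype: str = "wt",
    diet: str | None = None,
) -> pd.DataFrame:
    """Per-metabolite ratio of group means relative to a reference group."""
    grp = design.samples(genotype=group_genotype, diet=diet)
    ref = design.samples(genotype=reference_genotype, diet=diet)
    if not ref:
        raise ValueError("reference group is empty")
    grp_mean = matrix.loc[grp].mean(axis=0)
    ref_mean = matrix.loc[ref].mean(axis=0)
    undefined = ref_mean == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = grp_mean / ref_mean
    ratio[undefined] = np.nan
    return pd.DataFrame(
        {
            "metabolite_id": matrix.columns,
            "ratio": ratio.to_numpy(),
            "undefined_reference": undefined.to_numpy(),
        }
    )


def pcr_cr_ratio(
    matrix: pd.DataFrame,
    design: SampleDesign,
    pcr: str = "phosphocreatine",
    cr: str = "creatine",
) -> pd.DataFrame:
    """Per-sample phosphocreatine/creatine ratio with group means.

    The ratio is an in-vivo energy-charge proxy; a drop in the mutant
    indicates an energy deficit.  Samples with zero creatine are flagged
    (ratio NaN) rather than dropped.
    """
    for met in (pcr, cr):
        if met not in matrix.columns:
            raise KeyError(f"metabolite {met!r} not present in the matrix")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = matrix[pcr] / matrix[cr]
    ratio = ratio.replace([np.inf, -np.inf], np.nan)
    out = design.frame.set_index("sample_id").copy()
    out["pcr_cr"] = ratio
    out["zero_creatine"] = (matrix[cr] == 0).to_numpy()
    return out.reset_index()


def qpcr_relative_expression(
    cq: pd.DataFrame,
    target: str,
    reference: str = "28S",
    calibrator_genotype: str = "wt",
) -> pd.DataFrame:
    """Relative expression by the 2^-ddCq method.

    ``cq`` is a tidy table with columns sample_id, genotype, gene, cq.
    dCq = Cq(target) - Cq(reference) per sample; ddCq subtracts the mean
    dCq of the calibrator (wild-type) group; relative expression is
    2^-ddCq, so the calibrator group averages ~1.
    """
    wide = cq.pivot_table(index=["sample_id", "genotype"], columns="gene",
                          values="cq", aggfunc="mean")
    for gene in (target, reference):
        if gene not in wide.columns or wide[gene].isna().any():
            raise ValueError(f"missing Cq values for gene {gene!r}")
    if not np.isfinite(wide[[target, reference]].to_numpy()).all():
        raise ValueError("Cq values must be finite")
    wide = wide.reset_index()
    wide["dcq"] = wide[target] - wide[reference]
    calib = wide.loc[wide["genotype"] == calibrator_genotype, "dcq"]
    if calib.empty:
        raise ValueError(f"no samples with calibrator genotype {calibrator_genotype!r}")
    wide["ddcq"] = wide["dcq"] - calib.mean()
    wide["relative_expression"] = 2.0 ** (-wide["ddcq"])
    return wide[["sample_id", "genotype", "dcq", "ddcq", "relative_expression"]]
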