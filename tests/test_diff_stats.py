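"""Differential statistics: PCA identities, t-test and BH arithmetic
against hand-computed oracles, fold changes, PCr/Cr and 2^-ddCq."""

import numpy as np
import pandas as pd
import pytest

from mpctrace.diff_stats import (
    SampleDesign,
    bh_qvalues,
    fold_change_table,
    pca,
    pcr_cr_ratio,
    qpcr_relative_expression,
    univariate_screen,
)


def _design(samples):
    return SampleDesign(pd.DataFrame(samples))


def _two_group_matrix(a_rows, b_rows, metabolites, diet="normal"):
    data, design = [], []
    for i, row in enumerate(a_rows):
        sid = f"wt_{i}"
        data.append(pd.Series(row, index=metabolites, name=sid))
        design.append({"sample_id": sid, "genotype": "wt", "diet": diet})
    for i, row in enumerate(b_rows):
        sid = f"gt_{i}"
        data.append(pd.Series(row, index=metabolites, name=sid))
        design.append({"sample_id": sid, "genotype": "gt", "diet": diet})
    return pd.DataFrame(data), _design(design)


# ------------------------------------------------------------------ PCA


def test_pca_reconstruction_identity(rng):
    X = pd.DataFrame(rng.lognormal(10, 1, size=(8, 20)))
    scores, loadings, explained = pca(X)
    centred = X.to_numpy() - X.to_numpy().mean(axis=0)
    np.testing.assert_allclose(scores.to_numpy() @ loadings.to_numpy().T,
                               centred, atol=1e-9)
    total_var = centred.var(axis=0, ddof=1).sum()
    assert explained.sum() == pytest.approx(total_var, rel=1e-9)


def test_pca_duplicated_samples_zero_variance():
    X = pd.DataFrame([[1.0, 2.0, 3.0]] * 4)
    with pytest.warns(UserWarning, match="constant"):
        scores, _, explained = pca(X)
    assert np.allclose(scores, 0.0)
    assert np.allclose(explained, 0.0)


def test_pca_perfect_correlation_single_component():
    x = np.array([1.0, 2.0, 3.0, 4.0])
    X = pd.DataFrame({"a": x, "b": 2 * x})
    _, _, explained = pca(X)
    assert explained[0] / explained.sum() == pytest.approx(1.0, abs=1e-12)


def test_pca_scores_invariant_to_metabolite_order(rng):
    X = pd.DataFrame(rng.normal(size=(6, 10)),
                     columns=[f"m{i}" for i in range(10)])
    scores_a, _, _ = pca(X)
    shuffled = X[list(rng.permutation(X.columns))]
    scores_b, _, _ = pca(shuffled)
    # equal up to per-component sign
    for col in scores_a.columns:
        same = np.allclose(scores_a[col], scores_b[col], atol=1e-9)
        flip = np.allclose(scores_a[col], -scores_b[col], atol=1e-9)
        assert same or flip, col


# ------------------------------------------------------------------ BH


def test_bh_single_and_stepup_examples():
    assert bh_qvalues([0.03]) == pytest.approx([0.03])
    # m*p/rank = [.04,.04,.04,.04] after cumulative min
    np.testing.assert_allclose(bh_qvalues([0.01, 0.02, 0.03, 0.04]),
                               [0.04, 0.04, 0.04, 0.04], atol=1e-12)


def test_bh_matches_stepup_arithmetic(rng):
    p = rng.uniform(size=40)
    m = p.size
    order = np.argsort(p)
    stepup = p[order] * m / np.arange(1, m + 1)
    stepup = np.minimum.accumulate(stepup[::-1])[::-1]
    expected = np.empty(m)
    expected[order] = np.minimum(stepup, 1.0)
    np.testing.assert_allclose(bh_qvalues(p), expected, atol=1e-12)


def test_bh_monotone_in_p_rank(rng):
    p = rng.uniform(size=25)
    q = bh_qvalues(p)
    order = np.argsort(p)
    assert np.all(np.diff(q[order]) >= -1e-12)


def test_bh_rejects_out_of_range():
    with pytest.raises(ValueError):
        bh_qvalues([0.5, 1.2])


# ------------------------------------------------------------------ screen


def test_screen_identical_groups_no_hits():
    X, design = _two_group_matrix([[10, 5]] * 3, [[10, 5]] * 3, ["a", "b"])
    out = univariate_screen(X, design)
    assert not out["passes"].any()
    assert np.allclose(out["p"], 1.0)


def test_screen_matches_hand_t_test():
    """wt = [10,11,9], gt = [20,22,18]: pooled-variance t = 7.745967 on the
    raw scale, two-sided p = 0.0014965, log2FC = 1."""
    X, design = _two_group_matrix([[10.0], [11.0], [9.0]],
                                  [[20.0], [22.0], [18.0]], ["m"])
    out = univariate_screen(X, design, log_transform=False)
    assert out.loc[0, "t"] == pytest.approx(7.745966692, abs=1e-8)
    assert out.loc[0, "p"] == pytest.approx(0.001496481, abs=1e-8)
    assert out.loc[0, "log2fc"] == pytest.approx(1.0, abs=1e-12)


def test_screen_threshold_consistency(rng):
    """Relaxing either threshold never shrinks the passing set."""
    X, design = _two_group_matrix(
        rng.lognormal(3, 0.2, size=(4, 30)).tolist(),
        (rng.lognormal(3, 0.2, size=(4, 30)) * rng.choice([1, 3], 30)).tolist(),
        [f"m{i}" for i in range(30)],
    )
    strict = univariate_screen(X, design, q_thresh=0.01, fc_thresh=0.5)
    loose_q = univariate_screen(X, design, q_thresh=0.05, fc_thresh=0.5)
    loose_fc = univariate_screen(X, design, q_thresh=0.01, fc_thresh=0.2)
    hits = lambda df: set(df.loc[df["passes"], "metabolite_id"])  # noqa: E731
    assert hits(strict) <= hits(loose_q)
    assert hits(strict) <= hits(loose_fc)


def test_screen_requires_replicates():
    X, design = _two_group_matrix([[1.0]], [[2.0]], ["m"])
    with pytest.raises(ValueError):
        univariate_screen(X, design)


# ------------------------------------------------------------------ ratios


def test_fold_change_reference_vs_itself_is_one(rng):
    X, design = _two_group_matrix(rng.lognormal(2, 0.1, (3, 4)).tolist(),
                                  rng.lognormal(2, 0.1, (3, 4)).tolist(),
                                  list("abcd"))
    fc = fold_change_table(X, design, group_genotype="wt", reference_genotype="wt")
    np.testing.assert_allclose(fc["ratio"], 1.0, atol=1e-12)


def test_fold_change_zero_reference_flagged():
    X, design = _two_group_matrix([[0.0], [0.0]], [[1.0], [2.0]], ["m"])
    fc = fold_change_table(X, design)
    assert fc.loc[0, "undefined_reference"]
    assert np.isnan(fc.loc[0, "ratio"])


def test_pcr_cr_ratio_values_and_flags():
    X, design = _two_group_matrix([[4.0, 4.0], [6.0, 3.0]],
                                  [[2.0, 4.0], [1.0, 2.0]],
                                  ["phosphocreatine", "creatine"])
    out = pcr_cr_ratio(X, design)
    by_sample = out.set_index("sample_id")["pcr_cr"]
    assert by_sample["wt_0"] == pytest.approx(1.0)
    assert by_sample["wt_1"] == pytest.approx(2.0)
    assert by_sample["gt_0"] == pytest.approx(0.5)
    with pytest.raises(KeyError):
        pcr_cr_ratio(X[["creatine"]].assign(x=1.0), design)


# ------------------------------------------------------------------ qPCR


def _cq_table(ddcq_by_genotype, n=3):
    rows = []
    for genotype, offset in ddcq_by_genotype.items():
        for i in range(n):
            sid = f"{genotype}_{i}"
            rows.append({"sample_id": sid, "genotype": genotype,
                         "gene": "28S", "cq": 15.0})
            rows.append({"sample_id": sid, "genotype": genotype,
                         "gene": "MPC1", "cq": 22.0 + offset})
    return pd.DataFrame(rows)


def test_qpcr_calibrator_is_one_and_doubling_rule():
    table = _cq_table({"wt": 0.0, "het": 1.0})
    rel = qpcr_relative_expression(table, target="MPC1")
    means = rel.groupby("genotype")["relative_expression"].mean()
    assert means["wt"] == pytest.approx(1.0, abs=1e-12)
    assert means["het"] == pytest.approx(0.5, abs=1e-12)


def test_qpcr_4_32_cycles_is_five_percent():
    table = _cq_table({"wt": 0.0, "gt": 4.32})
    rel = qpcr_relative_expression(table, target="MPC1")
    gt = rel.loc[rel["genotype"] == "gt", "relative_expression"].mean()
    assert gt == pytest.approx(0.0500668, abs=1e-6)


def test_qpcr_missing_reference_rejected():
    table = _cq_table({"wt": 0.0})
    with pytest.raises(ValueError):
        qpcr_relative_expression(table, target="MPC1", reference="18S")


def test_design_validation():
    with pytest.raises(ValueError):
        SampleDesign(pd.DataFrame({"sample_id": ["a"], "genotype": ["wt"]}))
    with pytest.raises(ValueError):
        SampleDesign(pd.DataFrame({"sample_id": ["a"], "genotype": [None],
                                   "diet": ["normal"]}))
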