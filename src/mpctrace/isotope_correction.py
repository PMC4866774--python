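"""Correction of measured isotopologue intensities for natural ¹³C.

Even a chemically unlabeled metabolite shows M+1, M+2, ... signals
because each of its n carbons is ¹³C with probability ~1.07% in nature.
The correction models this as a binomial contamination acting on the
tracer-derived labeling state: with j tracer-labeled carbons, the
remaining n-j positions each pick up a natural ¹³C independently, so

    P(observe M+i | truly M+j) = C(n-j, i-j) p^(i-j) (1-p)^(n-i),  i >= j.

Stacking these into a lower-triangular matrix C gives measured = C @ true;
the correction solves the triangular system and renormalises.  Only
carbon is corrected (H/N/O natural isotopes are ignored), and n may be a
fragment carbon count for fragment-specific acquisitions.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import solve_triangular
from scipy.stats import binom
from sklearn.base import BaseEstimator, TransformerMixin

from .mid import validate_mid

__all__ = [
    "NATURAL_13C_ABUNDANCE",
    "CorrectionMatrix",
    "correction_matrix",
    "correct_mid",
    "contaminate_mid",
    "NaturalAbundanceCorrector",
]

#: standard natural abundance of ¹³C
NATURAL_13C_ABUNDANCE = 0.0107


class CorrectionMatrix:
    """Lower-triangular natural-abundance contamination matrix.

    ``entries[i, j]`` is the probability of observing i total labeled
    carbons given j tracer-labeled carbons; columns sum to one.
    """

    def __init__(self, n_carbons: int, p_nat: float, entries: np.ndarray):
        self.n_carbons = n_carbons
        self.p_nat = p_nat
        self.entries = entries

    def __repr__(self):  # pragma: no cover
        return f"CorrectionMatrix(n_carbons={self.n_carbons}, p_nat={self.p_nat})"


def correction_matrix(n_carbons: int, p_nat: float = NATURAL_13C_ABUNDANCE) -> CorrectionMatrix:
    """Build the (n+1) x (n+1) contamination matrix for an n-carbon species."""
    if n_carbons < 1:
        raise ValueError("n_carbons must be >= 1")
    if not 0.0 <= p_nat < 1.0:
        raise ValueError(f"p_nat must be in [0, 1), got {p_nat}")
    n = n_carbons
    m = np.zeros((n + 1, n + 1))
    for j in range(n + 1):
        # i - j extra labels among the n - j non-tracer positions
        m[j:, j] = binom.pmf(np.arange(n - j + 1), n - j, p_nat)
    return CorrectionMatrix(n, p_nat, m)


def contaminate_mid(true_mid, cm: CorrectionMatrix) -> np.ndarray:
    """Forward-apply natural abundance: what the instrument would measure."""
    mid = validate_mid(true_mid)
    if mid.size != cm.n_carbons + 1:
        raise ValueError(f"MID length {mid.size} != n_carbons+1 = {cm.n_carbons + 1}")
    out = cm.entries @ mid
    return out / out.sum()


def correct_mid(raw, cm: CorrectionMatrix) -> np.ndarray:
    """Remove natural-abundance contamination from a measured MID.

    Solves the lower-triangular system exactly, clamps any (noise-driven)
    negative entries to zero and renormalises to sum one.
    """
    mid = validate_mid(raw)
    if mid.size != cm.n_carbons + 1:
        raise ValueError(f"MID length {mid.size} != n_carbons+1 = {cm.n_carbons + 1}")
    diag = np.diag(cm.entries)
    if np.any(diag <= 1e-12):
        raise ValueError("correction matrix is singular (p_nat too close to 1)")
    x = solve_triangular(cm.entries, mid, lower=True)
    x = np.clip(x, 0.0, None)
    total = x.sum()
    if total <= 0.0:
        raise ValueError("corrected MID vanished; input is not a valid measurement")
    return x / total


class NaturalAbundanceCorrector(BaseEstimator, TransformerMixin):
    """Transformer applying natural-¹³C correction row-wise.

    Rows of ``X`` are measured MIDs of an ``n_carbons``-carbon species
    (shape ``(n_samples, n_carbons + 1)``); ``transform`` returns the
    corrected MIDs.  Stateless apart from the precomputed matrix, which
    is exposed as ``matrix_`` after :meth:`fit`.
    """

    def __init__(self, n_carbons: int = 4, p_nat: float = NATURAL_13C_ABUNDANCE):
        self.n_carbons = n_carbons
        self.p_nat = p_nat

    def fit(self, X=None, y=None):
        self.matrix_ = correction_matrix(self.n_carbons, self.p_nat)
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "matrix_"):
            self.fit()
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_carbons + 1:
            raise ValueError(
                f"expected {self.n_carbons + 1} isotopologue columns, got {X.shape[1]}"
            )
        return np.vstack([correct_mid(row, self.matrix_) for row in X])

    def inverse_transform(self, X) -> np.ndarray:
        """Forward contamination (the inverse of the correction)."""
        if not hasattr(self, "matrix_"):
            self.fit()
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return np.vstack([contaminate_mid(row, self.matrix_) for row in X])
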