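"""Mass isotopomer distributions (MIDs).

A MID for an n-carbon metabolite is a length-(n+1) vector of fractions
over the isotopologues M+0 ... M+n.  Entries are non-negative and sum
to one; ``validate_mid`` enforces this contract everywhere MIDs cross a
module boundary.
"""

from __future__ import annotations

import numpy as np

__all__ = ["validate_mid", "convolve_mids", "fractional_labeling"]

#: absolute tolerance on the sum-to-one constraint
MID_ATOL = 1e-9


def validate_mid(mid, *, atol: float = 1e-6, name: str = "mid") -> np.ndarray:
    """Return ``mid`` as a float array after checking MID invariants.

    Parameters
    ----------
    mid : array-like
        Candidate fraction vector over M+0 ... M+n.
    atol : float
        Tolerance on non-negativity and on the sum-to-one constraint.
        Measured data that passed noise and renormalisation upstream is
        accepted at this looser tolerance; simulator output satisfies
        the hard ``MID_ATOL`` bound.
    """
    arr = np.asarray(mid, dtype=float)
    if arr.ndim != 1 or arr.size < 1:
        raise ValueError(f"{name} must be a 1-D vector, got shape {arr.shape}")
    if np.any(arr < -atol):
        raise ValueError(f"{name} has negative entries: {arr}")
    total = arr.sum()
    if not np.isclose(total, 1.0, atol=max(atol, 1e-9), rtol=0.0):
        raise ValueError(f"{name} does not sum to 1 (sum={total!r})")
    return arr


def convolve_mids(a, b) -> np.ndarray:
    """Condense two carbon backbones: discrete convolution of their MIDs.

    Models a condensation reaction (e.g. the citrate synthase step
    joining a 2-carbon acetyl unit with 4-carbon oxaloacetate): the
    isotopologue of the product is the sum of the isotopologues of the
    two independent substrates.
    """
    a = validate_mid(a, name="a")
    b = validate_mid(b, name="b")
    out = np.convolve(a, b)
    # exact renormalisation guards against float drift
    return out / out.sum()


def fractional_labeling(mid) -> float:
    """Carbon-weighted mean label content, sum(i * M_i) / n."""
    arr = validate_mid(mid)
    n = arr.size - 1
    if n == 0:
        return 0.0
    return float(np.dot(np.arange(arr.size), arr) / n)
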