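"""Accurate-mass annotation of negative-mode flow-injection QTOF peaks.

Flow-injection analysis has no chromatographic separation, so the only
identification handle is the centroid m/z.  Annotation enumerates, for
every compound in a library, the ionic species it can form in negative
mode (deprotonated [M-H]-, fluoride [M+F]-, sodium [M+Na-2H]- and
potassium [M+K-2H]- adducts, each optionally carrying extra ¹³C
isotopes), keeps those inside the recorded m/z window (50-1000 by
default) and matches observed peaks to candidates within an absolute
tolerance in Daltons (0.001 by default).  Peaks matching several
candidates keep all matches, with the smallest-|error| match flagged as
primary; the downstream unit of analysis is the annotated metabolite
ion, one row per (compound, adduct).
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from pyteomics import mass as _ptmass
from sklearn.base import BaseEstimator

__all__ = [
    "CompoundRecord",
    "IonCandidate",
    "Annotation",
    "ADDUCT_DELTAS",
    "C13_MASS_SHIFT",
    "load_compound_library",
    "enumerate_ions",
    "annotate_peaks",
    "collapse_to_ion_table",
    "IonAnnotator",
]

#: m/z offsets of the supported negative-mode ionic species, in Da
ADDUCT_DELTAS: dict[str, float] = {
    "deprotonated": -1.007276,   # [M-H]-
    "fluoride": +18.998403,      # [M+F]-
    "sodium": +20.974666,        # [M+Na-2H]-
    "potassium": +36.948606,     # [M+K-2H]-
}

#: mass difference ¹³C - ¹²C, Da
C13_MASS_SHIFT = 1.003355

MZ_MIN, MZ_MAX = 50.0, 1000.0
DEFAULT_TOLERANCE = 0.001


@dataclass(frozen=True)
class CompoundRecord:
    """A library entry: neutral compound with formula and monoisotopic mass."""

    compound_id: str
    name: str
    formula: str
    monoisotopic_mass: float

    def __post_init__(self):
        if self.monoisotopic_mass <= 0:
            raise ValueError(f"{self.compound_id}: mass must be > 0")
        if self.formula:
            calc = _ptmass.calculate_mass(formula=self.formula)
            if abs(calc - self.monoisotopic_mass) > 1e-4:
                raise ValueError(
                    f"{self.compound_id}: mass {self.monoisotopic_mass} inconsistent "
                    f"with formula {self.formula} ({calc:.6f})"
                )


@dataclass(frozen=True)
class IonCandidate:
    """A predicted ionic species of a library compound."""

    compound_id: str
    adduct: str
    isotope_shift: int
    mz: float


@dataclass(frozen=True)
class Annotation:
    """A peak matched to a candidate within tolerance."""

    peak_mz: float
    intensity: float
    candidate: IonCandidate
    mass_error: float
    primary: bool


def load_compound_library(path=None) -> list[CompoundRecord]:
    """Read a compound library TSV (compound_id, name, formula,
    monoisotopic_mass).  Without a path, the packaged library is used:
    a synthetic stand-in for a mouse metabolome database, sized and
    seeded with the metabolites relevant to embryonic brain extracts."""
    if path is None:
        ref = resources.files("mpctrace") / "data" / "synthetic_compound_library.tsv"
        with resources.as_file(ref) as p:
            df = pd.read_csv(p, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    return [
        CompoundRecord(r.compound_id, r.name, r.formula, float(r.monoisotopic_mass))
        for r in df.itertuples(index=False)
    ]


def enumerate_ions(
    library: list[CompoundRecord],
    adducts=("deprotonated", "fluoride", "sodium", "potassium"),
    max_isotope: int = 2,
    mz_range: tuple[float, float] = (MZ_MIN, MZ_MAX),
) -> list[IonCandidate]:
    """All (compound, adduct, isotope) species with m/z inside the window."""
    if not adducts:
        raise ValueError("adduct set must be non-empty")
    unknown = set(adducts) - set(ADDUCT_DELTAS)
    if unknown:
        raise ValueError(f"unknown adduct labels: {sorted(unknown)}")
    if max_isotope < 0:
        raise ValueError("max_isotope must be >= 0")
    lo, hi = mz_range
    out = []
    for comp in library:
        for adduct in adducts:
            base = comp.monoisotopic_mass + ADDUCT_DELTAS[adduct]
            for k in range(max_isotope + 1):
                mz = base + k * C13_MASS_SHIFT
                if lo <= mz <= hi:
                    out.append(IonCandidate(comp.compound_id, adduct, k, mz))
    out.sort(key=lambda c: (c.mz, c.compound_id, c.adduct, c.isotope_shift))
    return out


def annotate_peaks(
    peaks,
    candidates: list[IonCandidate],
    tolerance: float = DEFAULT_TOLERANCE,
) -> list[Annotation]:
    """Match (m/z, intensity) peaks to candidates within ``tolerance`` Da.

    Candidates are searched in a sorted structure; all matches within
    tolerance are reported, the smallest-|error| one flagged primary.
    Unmatched peaks are omitted.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    cands = sorted(candidates, key=lambda c: c.mz)
    cand_mz = [c.mz for c in cands]
    annotations: list[Annotation] = []
    for mz, intensity in peaks:
        lo = bisect_left(cand_mz, mz - tolerance)
        hi = bisect_right(cand_mz, mz + tolerance)
        matches = [c for c in cands[lo:hi] if abs(mz - c.mz) <= tolerance]
        if not matches:
            continue
        best = min(matches, key=lambda c: abs(mz - c.mz))
        for cand in matches:
            annotations.append(
                Annotation(
                    peak_mz=float(mz),
                    intensity=float(intensity),
                    candidate=cand,
                    mass_error=float(mz - cand.mz),
                    primary=cand is best,
                )
            )
    for ann in annotations:
        assert abs(ann.mass_error) <= tolerance
    return annotations


def collapse_to_ion_table(annotations: list[Annotation]) -> pd.DataFrame:
    """One row per distinct (compound, adduct) metabolite ion.

    Intensities of the monoisotopic (isotope-0) matches are summed;
    rows are ordered deterministically by ion m/z.  This is the unit on
    which the differential statistics operate.
    """
    rows: dict[tuple[str, str], dict] = {}
    for ann in annotations:
        c = ann.candidate
        key = (c.compound_id, c.adduct)
        entry = rows.setdefault(
            key,
            {
                "compound_id": c.compound_id,
                "adduct": c.adduct,
                "mz": c.mz - c.isotope_shift * C13_MASS_SHIFT,
                "intensity": 0.0,
                "n_peaks": 0,
            },
        )
        if c.isotope_shift == 0:
            entry["intensity"] += ann.intensity
        entry["n_peaks"] += 1
    df = pd.DataFrame.from_records(
        list(rows.values()),
        columns=["compound_id", "adduct", "mz", "intensity", "n_peaks"],
    )
    return df.sort_values("mz", kind="mergesort").reset_index(drop=True)


class IonAnnotator(BaseEstimator):
    """Estimator wrapping library-based accurate-mass annotation.

    ``fit`` enumerates ion candidates from the library; ``transform``
    maps a peak list (iterable of (m/z, intensity)) to the collapsed
    metabolite-ion table.
    """

    def __init__(
        self,
        adducts=("deprotonated", "fluoride", "sodium", "potassium"),
        max_isotope: int = 2,
        tolerance: float = DEFAULT_TOLERANCE,
        mz_range: tuple[float, float] = (MZ_MIN, MZ_MAX),
    ):
        self.adducts = adducts
        self.max_isotope = max_isotope
        self.tolerance = tolerance
        self.mz_range = mz_range

    def fit(self, library: list[CompoundRecord], y=None):
        self.candidates_ = enumerate_ions(
            library, adducts=self.adducts, max_isotope=self.max_isotope,
            mz_range=self.mz_range,
        )
        return self

    def annotate(self, peaks) -> list[Annotation]:
        return annotate_peaks(peaks, self.candidates_, tolerance=self.tolerance)

    def transform(self, peaks) -> pd.DataFrame:
        return collapse_to_ion_table(self.annotate(peaks))
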