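"""Extracellular-flux (Seahorse-style) oxygen consumption summaries.

Traces are sequences of timestamped OCR measurement loops punctuated by
compound injections.  In the permeabilized-cell assay modeled here,
oligomycin is present from the start, so the phases of interest are
basal (before any injection), fCCP (uncoupler-stimulated maximal
respiration), succinate/rotenone and antimycin A (non-mitochondrial
floor).  "fCCP-driven OCR" is the mean of the fCCP phase minus the mean
of the antimycin A phase; the floor subtraction can be switched off.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["OCRTrace", "segment_phases", "fccp_driven_ocr", "cell_normalize"]

PHASE_LABELS = ("fccp", "succinate_rotenone", "antimycin_a")


@dataclass
class OCRTrace:
    """Timestamped OCR measurements with injection events.

    ``times`` must be strictly increasing and non-negative; injections
    are (time, label) pairs with labels from ``PHASE_LABELS``.
    """

    times: np.ndarray
    ocr: np.ndarray
    injections: list[tuple[float, str]] = field(default_factory=list)
    cell_count: float | None = None
    well_id: str = "well"

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.ocr = np.asarray(self.ocr, dtype=float)
        if self.times.size != self.ocr.size:
            raise ValueError("times and ocr must have equal length")
        if self.times.size and self.times[0] < 0:
            raise ValueError("measurements before time 0 are invalid")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        self.injections = sorted(self.injections, key=lambda e: e[0])
        for _, label in self.injections:
            if label not in PHASE_LABELS:
                raise ValueError(f"unknown injection label {label!r}")


def segment_phases(trace: OCRTrace) -> dict[str, np.ndarray]:
    """Partition measurements into phases delimited by injections.

    Returns an ordered mapping phase label -> OCR values; the phase
    before the first injection is ``"basal"``.  Every measurement
    belongs to exactly one phase.
    """
    edges = [t for t, _ in trace.injections] + [np.inf]
    labels = ["basal"] + [label for _, label in trace.injections]
    phases: dict[str, np.ndarray] = {}
    start = -np.inf
    for label, end in zip(labels, edges):
        sel = (trace.times > start) & (trace.times <= end) if np.isfinite(end) \
            else (trace.times > start)
        phases[label] = trace.ocr[sel]
        start = end
    return phases


def fccp_driven_ocr(trace: OCRTrace, subtract_floor: bool = True) -> float:
    """Uncoupler-stimulated respiration above the non-mitochondrial floor.

    Mean OCR of the fCCP phase, minus the mean of the antimycin A phase
    when ``subtract_floor`` is true.  Raises ``ValueError`` naming any
    missing phase.
    """
    phases = segment_phases(trace)
    needed = ["fccp"] + (["antimycin_a"] if subtract_floor else [])
    for label in needed:
        if label not in phases or phases[label].size == 0:
            raise ValueError(f"trace {trace.well_id!r} has no measurements in "
                             f"phase {label!r}")
    value = float(np.mean(phases["fccp"]))
    if subtract_floor:
        value -= float(np.mean(phases["antimycin_a"]))
    return value


def cell_normalize(value: float, cell_count: float, per: float = 1e4) -> float:
    """OCR per ``per`` cells (default 10^4), from a DAPI-derived count."""
    if cell_count <= 0:
        raise ValueError("cell count must be > 0")
    return value / cell_count * per
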