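"""Steady-state simulation of ¹³C label propagation through central carbon
metabolism.

The model covers the reactions needed to interpret glucose and glutamine
tracer experiments in cells with or without a functional mitochondrial
pyruvate carrier (MPC):

* glycolysis (glucose -> 2 pyruvate) and lactate exchange,
* pyruvate dehydrogenase (PDH; pyruvate C1 released as CO2),
* citrate synthase (CS; acetyl-CoA + oxaloacetate -> citrate),
* the oxidative TCA spiral citrate -> alpha-ketoglutarate -> succinate,
  each step releasing one CO2 (alpha-KG loses its C1),
* rotational symmetry of succinate and fumarate,
* reductive carboxylation (alpha-KG + CO2 -> citrate) followed by citrate
  cleavage into oxaloacetate and acetyl-CoA,
* glutamine -> glutamate -> alpha-KG anaplerosis (carbons preserved),
* pyruvate carboxylation (pyruvate + CO2 -> oxaloacetate),
* oxaloacetate <-> aspartate exchange (carbons preserved).

Fluxes are parameterised as *branch fractions* (`FluxScenario`) because
mass isotopomer distributions depend only on the relative contribution of
each producing route to a pool, not on absolute rates.  Pools are
represented positionally (probability over the 2^n labeling patterns of an
n-carbon molecule), which makes atom-mapped condensations, cleavages and
symmetry operations exact; MIDs are obtained by marginalising over the
number of labeled positions.

The CO2 pool is held at natural (unlabeled) composition: the system is
open and refixation of released ¹³CO2 is not tracked, so carbons entering
via carboxylation reactions arrive unlabeled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product as _cartesian

import numpy as np

from .mid import validate_mid

__all__ = [
    "TracerSpec",
    "FluxScenario",
    "AtomMappedReaction",
    "ReactionNetwork",
    "build_network",
    "simulate_steady_state",
    "CarbonPool",
    "SCENARIOS",
]

#: metabolite pools and their carbon counts
POOL_CARBONS: dict[str, int] = {
    "glucose": 6,
    "pyruvate": 3,
    "lactate": 3,
    "acetyl_coa": 2,
    "citrate": 6,
    "akg": 5,
    "succinate": 4,
    "fumarate": 4,
    "malate": 4,
    "oaa": 4,
    "aspartate": 4,
    "glutamate": 5,
    "glutamine": 5,
}

SUBSTRATE_CARBONS = {"glucose": 6, "glutamine": 5}

#: pools whose two molecular orientations are chemically indistinguishable
SYMMETRIC_POOLS = frozenset({"succinate", "fumarate"})


@dataclass(frozen=True)
class TracerSpec:
    """A ¹³C tracer: which substrate, which carbons, what enrichment.

    ``labeled_positions`` uses 1-based carbon numbering; for glutamine,
    C1 is the alpha-carboxyl carbon (the one lost by alpha-KG
    dehydrogenase on the oxidative route).
    """

    substrate: str
    labeled_positions: frozenset[int]
    enrichment: float = 1.0

    def __post_init__(self):
        if self.substrate not in SUBSTRATE_CARBONS:
            raise ValueError(f"unknown tracer substrate {self.substrate!r}")
        n = SUBSTRATE_CARBONS[self.substrate]
        object.__setattr__(self, "labeled_positions", frozenset(self.labeled_positions))
        if any(not (1 <= p <= n) for p in self.labeled_positions):
            raise ValueError(
                f"labeled positions {sorted(self.labeled_positions)} outside "
                f"{self.substrate} carbon range 1..{n}"
            )
        if not 0.0 <= self.enrichment <= 1.0:
            raise ValueError(f"enrichment must be in [0, 1], got {self.enrichment}")

    @classmethod
    def uniform(cls, substrate: str, enrichment: float = 1.0) -> "TracerSpec":
        """[U-¹³C] tracer: all carbons labeled."""
        n = SUBSTRATE_CARBONS[substrate]
        return cls(substrate, frozenset(range(1, n + 1)), enrichment)

    @classmethod
    def positional(cls, substrate: str, positions, enrichment: float = 1.0) -> "TracerSpec":
        """Positionally labeled tracer, e.g. [1-¹³C]glutamine."""
        return cls(substrate, frozenset(positions), enrichment)


@dataclass(frozen=True)
class FluxScenario:
    """Branch-fraction parameterisation of the network.

    Parameters
    ----------
    f_mpc : float
        Fraction of mitochondrial acetyl-CoA derived from glycolytic
        pyruvate via MPC and PDH.  ``f_mpc = 0`` encodes the MPC1-null
        state; the remainder of acetyl-CoA arrives unlabeled (fatty
        acids, ketone bodies).
    f_gln : float
        Fraction of alpha-KG produced from glutamine (anaplerosis); the
        remainder comes from oxidative citrate turnover.
    f_reductive : float
        Fraction of alpha-KG consumed by reductive carboxylation to
        citrate (the rest is oxidised to succinate).
    f_anaplerotic_pc : float
        Fraction of oxaloacetate produced by pyruvate carboxylation.
    dilution : float
        Fraction of each interior pool exchanged with unlabeled medium
        per iteration (a simple isotopic-dilution term).
    name : str
        Free-form label used in error messages and reports.
    """

    f_mpc: float = 1.0
    f_gln: float = 0.5
    f_reductive: float = 0.0
    f_anaplerotic_pc: float = 0.0
    dilution: float = 0.0
    name: str = "scenario"

    def __post_init__(self):
        for fname in ("f_mpc", "f_gln", "f_reductive", "f_anaplerotic_pc", "dilution"):
            val = getattr(self, fname)
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"{fname} must be in [0, 1], got {val}")


#: packaged flux scenarios: plausible branch fractions for wild-type MEFs
#: and for MPC1-null MEFs (pyruvate entry blocked, glutamine anaplerosis
#: and reductive carboxylation up).  MID bar heights were never reported
#: as fluxes, so these encode directions, not fitted values.
SCENARIOS: dict[str, FluxScenario] = {
    "wt": FluxScenario(
        f_mpc=0.9, f_gln=0.65, f_reductive=0.12, f_anaplerotic_pc=0.08,
        dilution=0.1, name="wt",
    ),
    "mutant": FluxScenario(
        f_mpc=0.0, f_gln=0.9, f_reductive=0.45, f_anaplerotic_pc=0.0,
        dilution=0.1, name="mutant",
    ),
}


@dataclass(frozen=True)
class AtomMappedReaction:
    """One producing route for a pool, with its carbon map.

    ``carbon_map[k]`` gives the origin of product carbon k+1 as a pair
    ``(substrate_index, substrate_carbon)`` (both referring to
    ``substrates``, carbon 1-based), or ``None`` when the carbon enters
    from the unlabeled CO2 pool.  Substrate carbons absent from the map
    are released as CO2.
    """

    product: str
    substrates: tuple[str, ...]
    carbon_map: tuple
    weight: float
    label: str = ""

    def __post_init__(self):
        n_prod = POOL_CARBONS[self.product]
        if len(self.carbon_map) != n_prod:
            raise ValueError(
                f"{self.label or self.product}: carbon map has {len(self.carbon_map)} "
                f"entries for a {n_prod}-carbon product"
            )
        seen = set()
        for entry in self.carbon_map:
            if entry is None:
                continue
            si, ci = entry
            if not 0 <= si < len(self.substrates):
                raise ValueError(f"{self.label}: substrate index {si} out of range")
            if not 1 <= ci <= POOL_CARBONS[self.substrates[si]]:
                raise ValueError(f"{self.label}: carbon {ci} out of range")
            if (si, ci) in seen:
                raise ValueError(f"{self.label}: substrate carbon {(si, ci)} mapped twice")
            seen.add((si, ci))

    @property
    def released(self) -> tuple:
        """Substrate carbons lost as CO2 (not mapped to any product carbon)."""
        mapped = {e for e in self.carbon_map if e is not None}
        out = []
        for si, sub in enumerate(self.substrates):
            for ci in range(1, POOL_CARBONS[sub] + 1):
                if (si, ci) not in mapped:
                    out.append((sub, ci))
        return tuple(out)


@dataclass
class ReactionNetwork:
    """Active atom-mapped routes for a given flux scenario."""

    scenario: FluxScenario
    reactions: list[AtomMappedReaction] = field(default_factory=list)
    pools: dict[str, int] = field(default_factory=lambda: dict(POOL_CARBONS))
    symmetric: frozenset[str] = SYMMETRIC_POOLS
    exogenous: tuple[str, ...] = ("glucose", "glutamine")

    def producers(self, pool: str) -> list[AtomMappedReaction]:
        return [r for r in self.reactions if r.product == pool]

    def has_route(self, label: str) -> bool:
        return any(r.label == label for r in self.reactions)


def _identity_map(n: int) -> tuple:
    return tuple((0, c) for c in range(1, n + 1))


def build_network(scenario: FluxScenario) -> ReactionNetwork:
    """Instantiate the atom-mapped network for a flux scenario.

    Routes whose branch weight is zero are omitted, so e.g.
    ``f_reductive = 0`` yields no alpha-KG -> citrate edge and
    ``f_mpc = 0`` yields no PDH edge.
    """
    r = []

    def add(product, substrates, carbon_map, weight, label):
        if weight > 0.0:
            r.append(AtomMappedReaction(product, tuple(substrates), tuple(carbon_map),
                                        float(weight), label))

    s = scenario
    # glycolysis: glucose C1-C3 and C4-C6 each give one pyruvate
    # (pyruvate C1 = carboxyl; the C1-C3 half inverts its carbon order)
    add("pyruvate", ["glucose"], [(0, 3), (0, 2), (0, 1)], 0.5, "glycolysis_upper")
    add("pyruvate", ["glucose"], [(0, 4), (0, 5), (0, 6)], 0.5, "glycolysis_lower")
    add("lactate", ["pyruvate"], _identity_map(3), 1.0, "ldh")
    # PDH releases pyruvate C1 as CO2; remaining acetyl-CoA is unlabeled
    # (beta-oxidation / ketone bodies)
    add("acetyl_coa", ["pyruvate"], [(0, 2), (0, 3)], s.f_mpc, "pdh")
    add("acetyl_coa", [], [None, None], 1.0 - s.f_mpc, "acetyl_other")
    # citrate production: CS balances oxidative IDH consumption
    # (1 - f_gln), reductive carboxylation contributes f_reductive.
    w_cs, w_red = 1.0 - s.f_gln, s.f_reductive
    if w_cs == 0.0 and w_red == 0.0:
        w_cs = 1.0  # no citrate turnover through the cycle; CS still fills the pool
    # citrate carbons 1-4 from OAA C1-C4, 5-6 from acetyl-CoA C1-C2
    add("citrate", ["oaa", "acetyl_coa"],
        [(0, 1), (0, 2), (0, 3), (0, 4), (1, 1), (1, 2)], w_cs, "cs")
    # reductive carboxylation: inverse of the oxidative IDH map, with the
    # incoming carboxyl (citrate C1) from unlabeled CO2
    add("citrate", ["akg"],
        [None, (0, 3), (0, 2), (0, 1), (0, 5), (0, 4)], w_red, "idh_reductive")
    # oxidative IDH: citrate C1 (the OAA C1 carboxyl) released as CO2;
    # alpha-KG C1 traces back to OAA C4, C4/C5 to the acetyl carbons
    add("akg", ["citrate"], [(0, 4), (0, 3), (0, 2), (0, 6), (0, 5)],
        1.0 - s.f_gln, "idh_oxidative")
    add("akg", ["glutamate"], _identity_map(5), s.f_gln, "glutaminolysis")
    add("glutamate", ["glutamine"], _identity_map(5), 1.0, "glutaminase")
    # alpha-KG dehydrogenase releases alpha-KG C1
    add("succinate", ["akg"], [(0, 2), (0, 3), (0, 4), (0, 5)], 1.0, "akgdh")
    add("fumarate", ["succinate"], _identity_map(4), 1.0, "sdh")
    add("malate", ["fumarate"], _identity_map(4), 1.0, "fumarase")
    # OAA sources: malate dehydrogenase (oxidative return), citrate
    # cleavage (reductive return), pyruvate carboxylase
    add("oaa", ["malate"], _identity_map(4),
        (1.0 - s.f_anaplerotic_pc) * (1.0 - s.f_reductive), "mdh")
    add("oaa", ["citrate"], [(0, 1), (0, 2), (0, 3), (0, 4)],
        (1.0 - s.f_anaplerotic_pc) * s.f_reductive, "citrate_cleavage")
    add("oaa", ["pyruvate"], [(0, 1), (0, 2), (0, 3), None],
        s.f_anaplerotic_pc, "pyruvate_carboxylase")
    add("aspartate", ["oaa"], _identity_map(4), 1.0, "aat")
    return ReactionNetwork(scenario=s, reactions=r)


# ---------------------------------------------------------------------------
# positional label propagation


def _unlabeled(n: int) -> np.ndarray:
    d = np.zeros(1 << n)
    d[0] = 1.0
    return d


def _tracer_distribution(tracer: TracerSpec) -> np.ndarray:
    n = SUBSTRATE_CARBONS[tracer.substrate]
    d = np.zeros(1 << n)
    pattern = 0
    for pos in tracer.labeled_positions:
        pattern |= 1 << (pos - 1)
    d[0] += 1.0 - tracer.enrichment
    d[pattern] += tracer.enrichment
    return d


def _reverse_permutation(n: int) -> np.ndarray:
    """Index map sending each pattern to the pattern with carbon order reversed."""
    idx = np.arange(1 << n)
    out = np.zeros_like(idx)
    for bit in range(n):
        out |= ((idx >> bit) & 1) << (n - 1 - bit)
    return out


def _route_distribution(rxn: AtomMappedReaction, dists: dict[str, np.ndarray]) -> np.ndarray:
    """Positional distribution of the product of one route, assuming the
    labeling states of distinct substrate molecules are independent."""
    n_prod = POOL_CARBONS[rxn.product]
    out = np.zeros(1 << n_prod)
    sub_states = []
    for sub in rxn.substrates:
        d = dists[sub]
        nz = np.flatnonzero(d)
        sub_states.append([(int(s), d[s]) for s in nz])
    if not sub_states:  # all product carbons unlabeled (e.g. external acetyl-CoA)
        sub_states = [[(0, 1.0)]]
        # carbon_map entries are all None in this case
    for combo in _cartesian(*sub_states):
        prob = 1.0
        for _, p in combo:
            prob *= p
        if prob == 0.0:
            continue
        pattern = 0
        for k, entry in enumerate(rxn.carbon_map):
            if entry is None:
                continue
            si, ci = entry
            if (combo[si][0] >> (ci - 1)) & 1:
                pattern |= 1 << k
        out[pattern] += prob
    return out


def _mid_from_positional(dist: np.ndarray, n: int) -> np.ndarray:
    popcount = np.array([bin(i).count("1") for i in range(1 << n)])
    mid = np.zeros(n + 1)
    np.add.at(mid, popcount, dist)
    return mid / mid.sum()


def simulate_steady_state(
    network: ReactionNetwork,
    tracer: TracerSpec,
    *,
    tol: float = 1e-9,
    max_iter: int = 10_000,
) -> dict[str, np.ndarray]:
    """Fixed-point iteration of pool labeling states under a tracer.

    Each interior pool is replaced, synchronously, by the flux-weighted
    mixture of its producing routes (condensations as products of
    independent substrate states, decarboxylations/cleavages as
    marginalisations, symmetric pools orientation-averaged), then mixed
    with the unlabeled medium according to ``scenario.dilution``.

    Returns a mapping metabolite -> MID (length n_carbons + 1, summing
    to one).  Raises ``RuntimeError`` naming the scenario if the
    iteration does not converge within ``max_iter``.
    """
    scen = network.scenario
    dists: dict[str, np.ndarray] = {
        pool: _unlabeled(n) for pool, n in network.pools.items()
    }
    for sub in network.exogenous:
        if sub == tracer.substrate:
            dists[sub] = _tracer_distribution(tracer)

    reverse_perm = {p: _reverse_permutation(network.pools[p]) for p in network.symmetric}
    producers = {
        pool: network.producers(pool)
        for pool in network.pools
        if pool not in network.exogenous
    }

    for _ in range(max_iter):
        new: dict[str, np.ndarray] = {}
        for pool, rxns in producers.items():
            n = network.pools[pool]
            if not rxns:
                mix = _unlabeled(n)
            else:
                total_w = sum(r.weight for r in rxns)
                mix = np.zeros(1 << n)
                for rxn in rxns:
                    mix += (rxn.weight / total_w) * _route_distribution(rxn, dists)
            if pool in network.symmetric:
                mix = 0.5 * (mix + mix[reverse_perm[pool]])
            if scen.dilution > 0.0:
                mix = (1.0 - scen.dilution) * mix + scen.dilution * _unlabeled(n)
            new[pool] = mix
        delta = max(np.max(np.abs(new[p] - dists[p])) for p in new)
        dists.update(new)
        if delta < tol:
            break
    else:
        raise RuntimeError(
            f"label propagation did not converge within {max_iter} iterations "
            f"for scenario {scen.name!r}"
        )

    mids = {
        pool: _mid_from_positional(dists[pool], n)
        for pool, n in network.pools.items()
    }
    for pool, mid in mids.items():
        validate_mid(mid, atol=1e-9, name=pool)
    return mids


@dataclass
class CarbonPool:
    """A metabolite pool together with its simulated or measured MID."""

    metabolite_id: str
    n_carbons: int
    mid: np.ndarray

    def __post_init__(self):
        if self.n_carbons < 1:
            raise ValueError("n_carbons must be positive")
        self.mid = validate_mid(self.mid, atol=1e-9, name=self.metabolite_id)
        if self.mid.size != self.n_carbons + 1:
            raise ValueError(
                f"{self.metabolite_id}: MID length {self.mid.size} != n_carbons+1"
            )
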