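"""Atom-transition simulator: network structure, label routing, oracle
equivalence against direct enumeration of labeled-atom placements."""

import numpy as np
import pytest

from mpctrace.tracer_sim import (
    SCENARIOS,
    FluxScenario,
    TracerSpec,
    build_network,
    simulate_steady_state,
)


def mids_for(scenario, tracer, **kw):
    return simulate_steady_state(build_network(scenario), tracer, **kw)


# ---------------------------------------------------------------------------
# independent oracle: single-pass propagation over dicts of label tuples


def _unlab(n):
    return {(0,) * n: 1.0}


def _tracer_dist(tracer, n):
    pattern = tuple(1 if i + 1 in tracer.labeled_positions else 0 for i in range(n))
    d = {(0,) * n: 1.0 - tracer.enrichment}
    d[pattern] = d.get(pattern, 0.0) + tracer.enrichment
    return d


def _remap(d, idx):
    """Product distribution: product carbon k comes from substrate carbon
    idx[k] (1-based) or is unlabeled when idx[k] is None."""
    out = {}
    for pat, p in d.items():
        new = tuple(pat[i - 1] if i is not None else 0 for i in idx)
        out[new] = out.get(new, 0.0) + p
    return out


def _join(d1, d2):
    out = {}
    for p1, w1 in d1.items():
        for p2, w2 in d2.items():
            out[p1 + p2] = out.get(p1 + p2, 0.0) + w1 * w2
    return out


def _mix(terms):
    total = sum(w for w, _ in terms)
    out = {}
    for w, d in terms:
        for pat, p in d.items():
            out[pat] = out.get(pat, 0.0) + (w / total) * p
    return out


def _sym(d):
    out = {}
    for pat, p in d.items():
        out[pat] = out.get(pat, 0.0) + p / 2
        rev = pat[::-1]
        out[rev] = out.get(rev, 0.0) + p / 2
    return out


def _to_mid(d, n):
    mid = np.zeros(n + 1)
    for pat, p in d.items():
        mid[sum(pat)] += p
    return mid


def single_pass_oracle(tracer, s: FluxScenario):
    """Exhaustive atom-placement enumeration for acyclic configurations
    (requires f_gln = 1 so the cycle-closing citrate->aKG edge is off)."""
    assert s.f_gln == 1.0 and s.dilution == 0.0
    glc = _tracer_dist(tracer, 6) if tracer.substrate == "glucose" else _unlab(6)
    gln = _tracer_dist(tracer, 5) if tracer.substrate == "glutamine" else _unlab(5)
    pyr = _mix([(0.5, _remap(glc, [3, 2, 1])), (0.5, _remap(glc, [4, 5, 6]))])
    lac = pyr
    accoa = _mix([(s.f_mpc, _remap(pyr, [2, 3])), (1.0 - s.f_mpc, _unlab(2))])
    glu = gln
    akg = glu  # f_gln = 1
    succ = _sym(_remap(akg, [2, 3, 4, 5]))
    fum = _sym(succ)
    mal = fum
    if s.f_reductive > 0:
        cit = _remap(akg, [None, 3, 2, 1, 5, 4])
        oaa = _mix(
            [
                ((1 - s.f_anaplerotic_pc) * (1 - s.f_reductive), mal),
                ((1 - s.f_anaplerotic_pc) * s.f_reductive, _remap(cit, [1, 2, 3, 4])),
                (s.f_anaplerotic_pc, _remap(pyr, [1, 2, 3, None])),
            ]
        )
    else:
        oaa = _mix(
            [
                (1 - s.f_anaplerotic_pc, mal),
                (s.f_anaplerotic_pc, _remap(pyr, [1, 2, 3, None])),
            ]
        )
        cit = _join(oaa, accoa)
    asp = oaa
    pools = {
        "glucose": (glc, 6), "glutamine": (gln, 5), "pyruvate": (pyr, 3),
        "lactate": (lac, 3), "acetyl_coa": (accoa, 2), "glutamate": (glu, 5),
        "akg": (akg, 5), "succinate": (succ, 4), "fumarate": (fum, 4),
        "malate": (mal, 4), "oaa": (oaa, 4), "citrate": (cit, 6),
        "aspartate": (asp, 4),
    }
    return {k: _to_mid(d, n) for k, (d, n) in pools.items()}


ORACLE_SCENARIOS = [
    FluxScenario(f_mpc=0.7, f_gln=1.0, f_reductive=0.0, f_anaplerotic_pc=0.2,
                 name="acyclic_oxidative"),
    FluxScenario(f_mpc=0.3, f_gln=1.0, f_reductive=0.4, f_anaplerotic_pc=0.1,
                 name="acyclic_reductive"),
]
TRACERS = [
    TracerSpec.uniform("glucose", 0.9),
    TracerSpec.uniform("glutamine", 0.9),
    TracerSpec.positional("glutamine", {1}, 0.9),
]


@pytest.mark.parametrize("scenario", ORACLE_SCENARIOS, ids=lambda s: s.name)
@pytest.mark.parametrize("tracer", TRACERS,
                         ids=["U13C-glc", "U13C-gln", "1-13C-gln"])
def test_simulator_matches_enumeration_oracle(scenario, tracer):
    """On acyclic single-pass configurations the fixed-point simulator must
    equal direct enumeration over labeled-atom placements."""
    expected = single_pass_oracle(tracer, scenario)
    got = mids_for(scenario, tracer)
    for pool, mid in expected.items():
        np.testing.assert_allclose(got[pool], mid, atol=1e-9, err_msg=pool)


# ---------------------------------------------------------------------------
# network structure


def test_network_symmetry_flags_and_branch_edges():
    net = build_network(FluxScenario(name="default"))
    assert "succinate" in net.symmetric and "fumarate" in net.symmetric
    assert not build_network(FluxScenario(f_reductive=0.0)).has_route("idh_reductive")
    assert build_network(FluxScenario(f_reductive=0.3)).has_route("idh_reductive")
    assert not build_network(FluxScenario(f_mpc=0.0)).has_route("pdh")


def test_atom_maps_conserve_carbon():
    net = build_network(FluxScenario(f_mpc=0.5, f_gln=0.5, f_reductive=0.3,
                                     f_anaplerotic_pc=0.2))
    for rxn in net.reactions:
        n_sub = sum(net.pools[s] for s in rxn.substrates)
        n_mapped = sum(1 for e in rxn.carbon_map if e is not None)
        assert n_mapped + len(rxn.released) == n_sub


# ---------------------------------------------------------------------------
# label-routing claims


def test_unlabeled_tracer_gives_unlabeled_pools():
    mids = mids_for(SCENARIOS["wt"], TracerSpec.uniform("glucose", enrichment=0.0))
    for pool, mid in mids.items():
        assert mid[0] == pytest.approx(1.0, abs=1e-9), pool


def test_mpc_block_abolishes_glucose_m2():
    """Without MPC/PDH flux, glycolytic carbon cannot reach the TCA cycle."""
    scenario = FluxScenario(f_mpc=0.0, f_gln=0.9, f_reductive=0.45,
                            f_anaplerotic_pc=0.0, name="mpc_null")
    mids = mids_for(scenario, TracerSpec.uniform("glucose"))
    for pool in ("citrate", "succinate", "malate", "aspartate"):
        assert mids[pool][2] == pytest.approx(0.0, abs=1e-9), pool
    # glycolytic pools remain fully labeled
    assert mids["pyruvate"][3] == pytest.approx(1.0, abs=1e-9)
    assert mids["lactate"][3] == pytest.approx(1.0, abs=1e-9)


def test_no_reductive_flux_no_m1_from_1_13c_glutamine():
    scenario = FluxScenario(f_mpc=0.5, f_gln=0.8, f_reductive=0.0,
                            f_anaplerotic_pc=0.0, name="oxidative_only")
    mids = mids_for(scenario, TracerSpec.positional("glutamine", {1}))
    for pool in ("succinate", "malate", "aspartate"):
        assert mids[pool][1] == pytest.approx(0.0, abs=1e-9), pool


def test_single_oxidative_pass_succinate_m4():
    """[U-13C]glutamine through one oxidative turn: alpha-KG M+5 loses one
    labeled CO2, leaving succinate M+4."""
    scenario = FluxScenario(f_mpc=0.0, f_gln=1.0, f_reductive=0.0, name="one_turn")
    mids = mids_for(scenario, TracerSpec.uniform("glutamine"))
    assert mids["succinate"][4] == pytest.approx(1.0, abs=1e-9)


def test_aspartate_m1_strictly_increases_with_reductive_fraction():
    tracer = TracerSpec.positional("glutamine", {1})
    values = []
    for fr in (0.0, 0.15, 0.3, 0.45, 0.6):
        scenario = FluxScenario(f_mpc=0.0, f_gln=0.8, f_reductive=fr,
                                name=f"red_{fr}")
        values.append(mids_for(scenario, tracer)["aspartate"][1])
    assert all(b > a for a, b in zip(values, values[1:])), values


def test_citrate_m2_nondecreasing_in_f_mpc():
    tracer = TracerSpec.uniform("glucose")
    values = []
    for fm in (0.0, 0.25, 0.5, 0.75, 1.0):
        scenario = FluxScenario(f_mpc=fm, f_gln=0.7, f_reductive=0.1,
                                f_anaplerotic_pc=0.05, name=f"mpc_{fm}")
        values.append(mids_for(scenario, tracer)["citrate"][2])
    assert all(b >= a for a, b in zip(values, values[1:])), values


@pytest.mark.parametrize("scenario", list(SCENARIOS.values()), ids=lambda s: s.name)
@pytest.mark.parametrize("tracer", TRACERS,
                         ids=["U13C-glc", "U13C-gln", "1-13C-gln"])
def test_all_mids_valid(scenario, tracer):
    mids = mids_for(scenario, tracer)
    for pool, mid in mids.items():
        assert np.all(mid >= -1e-12), pool
        assert mid.sum() == pytest.approx(1.0, abs=1e-9), pool


def test_succinate_orientation_assignment_is_immaterial():
    """Feeding succinate in the reversed carbon orientation must not change
    any downstream MID (rotational symmetry of the molecule)."""
    import dataclasses

    scenario = FluxScenario(f_mpc=0.4, f_gln=0.7, f_reductive=0.2,
                            f_anaplerotic_pc=0.1, name="sym_check")
    tracer = TracerSpec.positional("glutamine", {1, 2})
    net = build_network(scenario)
    baseline = simulate_steady_state(net, tracer)

    flipped = build_network(scenario)
    for i, rxn in enumerate(flipped.reactions):
        if rxn.label == "akgdh":
            flipped.reactions[i] = dataclasses.replace(
                rxn, carbon_map=rxn.carbon_map[::-1]
            )
    alt = simulate_steady_state(flipped, tracer)
    for pool in ("succinate", "fumarate", "malate", "oaa", "aspartate", "citrate"):
        np.testing.assert_allclose(alt[pool], baseline[pool], atol=1e-9,
                                   err_msg=pool)


def test_nonconvergence_names_scenario():
    scenario = FluxScenario(f_mpc=1.0, f_gln=0.2, name="impatient")
    with pytest.raises(RuntimeError, match="impatient"):
        mids_for(scenario, TracerSpec.uniform("glucose"), max_iter=2)


def test_invalid_tracer_and_scenario_rejected():
    with pytest.raises(ValueError):
        TracerSpec.positional("glutamine", {7})
    with pytest.raises(ValueError):
        TracerSpec.uniform("glucose", enrichment=1.2)
    with pytest.raises(ValueError):
        FluxScenario(f_mpc=-0.1)
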