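"""Fracture criterion: component labelling and first-crossing search."""

import dataclasses

import numpy as np
import pytest

from femurmech.fe import ElementStrainField, MaterialAndCriterionConfig
from femurmech.fracture import (
    MODE_COMPRESSIVE,
    MODE_NONE,
    MODE_TENSILE,
    exceeding_components,
    fracture_load,
)
from femurmech.meshing import REGION_CORTICAL, REGION_TRABECULAR

CFG = MaterialAndCriterionConfig()
RNG = np.random.default_rng(42)


def chain_field(e_max, e_min, volume, region=None, adjacency=None):
    """Strain field on a 1D chain of elements (i adjacent to i+1)."""
    n = len(e_max)
    if adjacency is None:
        adjacency = np.stack([np.arange(n - 1), np.arange(1, n)], axis=1)
    if region is None:
        region = np.full(n, REGION_CORTICAL, dtype=np.uint8)
    return ElementStrainField(
        e_max=np.asarray(e_max, dtype=float),
        e_min=np.asarray(e_min, dtype=float),
        volume=np.asarray(volume, dtype=float),
        region=np.asarray(region), adjacency=adjacency,
        F_ref=CFG.F_ref, case="test")


def brute_force_components(mask, adjacency, volumes):
    """Union-find oracle for face-connected components."""
    parent = {i: i for i in np.where(mask)[0]}

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for a, b in adjacency:
        if mask[a] and mask[b]:
            parent[find(a)] = find(b)
    comps = {}
    for i in parent:
        comps.setdefault(find(i), []).append(i)
    return sorted((sorted(v), volumes[v].sum()) for v in comps.values())


def test_zero_field_has_no_exceeding_components():
    f = chain_field(np.zeros(5), np.zeros(5), np.full(5, 10.0))
    comps = exceeding_components(f, 10000.0, CFG)
    assert comps[MODE_TENSILE].max_volume() == 0.0
    assert comps[MODE_COMPRESSIVE].max_volume() == 0.0


def test_two_adjacent_exceeding_elements_merge_into_one_component():
    # two face-adjacent 60 mm^3 elements above the tensile limit at F
    e = np.array([0.008, 0.008, 0.001])
    f = chain_field(e, -0.1 * e, np.array([60.0, 60.0, 60.0]))
    comps = exceeding_components(f, CFG.F_ref, CFG)
    assert len(comps[MODE_TENSILE].volumes) == 1
    assert comps[MODE_TENSILE].volumes[0] == pytest.approx(120.0)
    assert set(comps[MODE_TENSILE].elements[0]) == {0, 1}


def test_trabecular_elements_are_excluded_from_the_criterion():
    e_min = np.array([-0.02, -0.02, -0.0001])
    region = np.array([REGION_TRABECULAR, REGION_CORTICAL, REGION_CORTICAL],
                      dtype=np.uint8)
    f = chain_field(np.zeros(3), e_min, np.full(3, 200.0), region=region)
    comps = exceeding_components(f, CFG.F_ref, CFG)
    assert comps[MODE_COMPRESSIVE].volumes == [pytest.approx(200.0)]
    assert set(comps[MODE_COMPRESSIVE].elements[0]) == {1}


def test_first_crossing_at_6400_newtons_compressive():
    """A 150 mm^3 compressive group that first qualifies at 6400 N."""
    # elements reach eps_c exactly between 6300 and 6400 N
    scale = CFG.F_ref / 6400.0
    e_min = np.full(4, -(CFG.eps_compressive + 1e-9) * scale)
    f = chain_field(np.zeros(4), e_min, np.full(4, 37.5))
    res = fracture_load(f, CFG)
    assert res.load == 6400.0
    assert res.mode == MODE_COMPRESSIVE
    assert res.failing_volume == pytest.approx(150.0)


def test_component_below_critical_volume_never_fractures():
    scale = CFG.F_ref / CFG.F_max
    f = chain_field(np.full(3, 0.1 * scale), np.zeros(3), np.full(3, 30.0))
    res = fracture_load(f, CFG)
    assert res.load is None
    assert res.mode == MODE_NONE
    assert not res.fractured
    # the same component with 100 mm^3 fractures
    f2 = chain_field(np.full(3, 0.1 * scale), np.zeros(3),
                     np.full(3, 100.0 / 3))
    assert fracture_load(f2, CFG).fractured


def linear_scan_oracle(field, cfg):
    """Exhaustive 100-step scan, independent of the bisection code."""
    n = int(cfg.F_max / cfg.dF)
    for k in range(1, n + 1):
        F = k * cfg.dF
        emax, emin = field.at_load(F)
        cort = field.region == REGION_CORTICAL
        for mode, mask in ((MODE_TENSILE, cort & (emax > cfg.eps_tensile)),
                           (MODE_COMPRESSIVE,
                            cort & (emin < -cfg.eps_compressive))):
            comps = brute_force_components(mask, field.adjacency,
                                           field.volume)
            if any(v >= cfg.V_crit for _, v in comps):
                return F
    return None


def random_field(rng, n=60):
    e_max = rng.uniform(0, 2e-4, n)
    e_min = -rng.uniform(0, 3e-4, n)
    vol = rng.uniform(5.0, 80.0, n)
    region = rng.choice([REGION_CORTICAL, REGION_TRABECULAR], size=n,
                        p=[0.7, 0.3]).astype(np.uint8)
    # random sparse adjacency on a ring plus chords
    adj = [(i, (i + 1) % n) for i in range(n)]
    adj += [tuple(rng.choice(n, 2, replace=False)) for _ in range(n // 2)]
    return chain_field(e_max, e_min, vol, region=region,
                       adjacency=np.array(adj))


def test_bisection_equals_exhaustive_scan_on_random_fields():
    rng = np.random.default_rng(2024)
    checked_fractures = 0
    for _ in range(50):
        f = random_field(rng)
        expect = linear_scan_oracle(f, CFG)
        got = fracture_load(f, CFG)
        assert got.load == expect
        if expect is not None:
            checked_fractures += 1
    assert checked_fractures >= 10     # the ensemble exercises both outcomes


def test_exceedance_sets_grow_monotonically_with_load():
    rng = np.random.default_rng(5)
    f = random_field(rng)
    prev_t = prev_c = None
    for F in np.arange(CFG.dF, CFG.F_max + 1, CFG.dF * 7):
        emax, emin = f.at_load(F)
        cort = f.region == REGION_CORTICAL
        t = set(np.where(cort & (emax > CFG.eps_tensile))[0])
        c = set(np.where(cort & (emin < -CFG.eps_compressive))[0])
        if prev_t is not None:
            assert prev_t <= t and prev_c <= c
        prev_t, prev_c = t, c


def test_uniform_strengthening_scales_fracture_load():
    """Scaling all strains by k < 1 raises the load by 1/k (grid-rounded)."""
    rng = np.random.default_rng(77)
    f = random_field(rng)
    base = fracture_load(f, CFG)
    if base.load is None or base.load > 4000:
        f = chain_field(np.full(5, 3e-4), np.zeros(5), np.full(5, 40.0))
        base = fracture_load(f, CFG)
    k = 0.5
    weaker = dataclasses.replace(f, e_max=f.e_max * k, e_min=f.e_min * k)
    res = fracture_load(weaker, CFG)
    expect = np.ceil(base.load / k / CFG.dF - 1e-9) * CFG.dF
    if expect <= CFG.F_max:
        assert res.load == pytest.approx(expect, abs=CFG.dF)
    else:
        assert res.load is None


def test_mode_tie_resolves_to_compressive():
    scale = CFG.F_ref / 5000.0
    e_max = np.array([CFG.eps_tensile * 1.0001 * scale] * 3)
    e_min = np.array([-CFG.eps_compressive * 1.0001 * scale] * 3)
    f = chain_field(e_max, e_min, np.full(3, 50.0))
    res = fracture_load(f, CFG)
    assert res.mode == MODE_COMPRESSIVE
    assert res.tie


def test_locality_result_ignores_trabecular_strains():
    rng = np.random.default_rng(9)
    f = random_field(rng)
    noisy = dataclasses.replace(
        f,
        e_max=np.where(f.region == REGION_TRABECULAR, 1.0, f.e_max),
        e_min=np.where(f.region == REGION_TRABECULAR, -1.0, f.e_min))
    assert fracture_load(noisy, CFG).load == fracture_load(f, CFG).load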