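"""Droplet signal model, gating, sorting rounds and the mock experiment."""

import numpy as np
import pytest

from ribodrop.droplet_sim import (
    DEFAULT_OPTICS,
    DropletEvents,
    EffectParams,
    EmptyPoolError,
    OpticsModel,
    RoundSpec,
    SwitchPhenotype,
    alternating_schedule,
    assign_phenotypes,
    build_gate,
    droplet_signals,
    expression_level,
    generate_events,
    regenerate_pool,
    simulate_mock,
    simulate_round,
    simulate_screen,
    sort_droplets,
)
from ribodrop.encapsulation import LoadingModel, lambda_for_occupancy


NOISELESS = OpticsModel(noise_cv=0.0)


# --------------------------------------------------------------------- Hill


def test_expression_level_hill():
    ph = SwitchPhenotype(off_level=1.0, on_level=20.0, ec50=1.6, hill=1.0)
    assert expression_level(ph, 0.0) == 1.0
    assert expression_level(ph, 1.6) == pytest.approx(10.5)  # midpoint
    assert expression_level(ph, 10.0) == pytest.approx(1 + 19 * 10 / 11.6)
    with pytest.raises(ValueError):
        expression_level(ph, -1.0)


def test_assign_phenotypes_contract(tiny_design):
    ph = assign_phenotypes(tiny_design, planted_fraction=0.0, seed=0)
    assert all(p.class_label in ("constitutive", "dead") for p in ph.values())
    assert all(p.on_level == p.off_level for p in ph.values())

    ph1 = assign_phenotypes(tiny_design, planted_fraction=0.5, seed=4)
    ph2 = assign_phenotypes(tiny_design, planted_fraction=0.5, seed=4)
    assert ph1 == ph2
    switches = [p for p in ph1.values() if p.class_label == "on_switch"]
    assert len(switches) == 10
    assert all(p.on_level > p.off_level for p in switches)
    # default effect range covers the strongest observed response (~19.7x)
    lo, hi = EffectParams().ratio_range
    assert lo <= 19.7 <= hi


# ------------------------------------------------------------------ signals


def test_droplet_signals_empty_and_cap():
    ph = {"v": SwitchPhenotype(2.4, 2.4)}
    rox, gfp = droplet_signals([], ph, 0.0, NOISELESS, seed=0)
    assert rox == NOISELESS.rox_baseline and gfp == NOISELESS.gfp_baseline
    # expression at 2x the cap reads identically to the cap
    rox1, gfp1 = droplet_signals(["v"], ph, 0.0, NOISELESS, seed=0)
    ph_cap = {"v": SwitchPhenotype(NOISELESS.gfp_cap, NOISELESS.gfp_cap)}
    rox2, gfp2 = droplet_signals(["v"], ph_cap, 0.0, NOISELESS, seed=0)
    assert gfp1 == pytest.approx(gfp2)
    assert rox1 > NOISELESS.rox_baseline


def test_droplet_signals_deterministic_with_seed():
    ph = {"v": SwitchPhenotype(0.5, 0.5)}
    a = droplet_signals(["v"], ph, 0.0, DEFAULT_OPTICS, seed=9)
    b = droplet_signals(["v"], ph, 0.0, DEFAULT_OPTICS, seed=9)
    assert a == b


def test_saturation_never_inflates_on_off_ratio(rng):
    """The split-GFP ceiling can only compress a measured ON/OFF ratio."""
    capped = OpticsModel(noise_cv=0.0, gfp_cap=1.2)
    uncapped = OpticsModel(noise_cv=0.0, gfp_cap=1e9)
    for _ in range(100):
        off = rng.uniform(0.02, 0.5)
        on = off * rng.uniform(1.5, 30.0)
        ph = {"v": SwitchPhenotype(off, on)}
        ratios = []
        for optics in (capped, uncapped):
            _, g_on = droplet_signals(["v"], ph, 1e6, optics, seed=0)
            _, g_off = droplet_signals(["v"], ph, 0.0, optics, seed=0)
            ratios.append(g_on / g_off)
        assert ratios[0] <= ratios[1] + 1e-9


# ------------------------------------------------------------------- gating


def _two_level_population(n=20_000, bright_fraction=0.02, seed=0):
    pool = {"bright": bright_fraction, "dim": 1 - bright_fraction}
    ph = {
        "bright": SwitchPhenotype(1.0, 1.0),
        "dim": SwitchPhenotype(0.05, 0.05),
    }
    loading = LoadingModel(lambda_for_occupancy(0.30))
    return generate_events(pool, n, loading, ph, NOISELESS, 0.0, seed=seed)


def test_gate_cap_is_respected():
    events = _two_level_population()
    for mode, cap in (("high_gfp", 0.03), ("low_gfp", 0.10), ("high_gfp", 0.005)):
        gate = build_gate(events, mode, cap)
        assert gate.membership(events).mean() <= cap + 1e-12


def _constructed_two_level_events(n=20_000, n_positive=2000, n_high=150):
    """Noise-free population with exactly two GFP levels among positives."""
    rox = np.ones(n)
    gfp = np.ones(n)
    rox[:n_positive] = 21.0
    gfp[:n_positive] = 2.0
    gfp[:n_high] = 21.0
    return DropletEvents(
        ligand_conc=0.0,
        bead_count=(rox > 1).astype(int),
        rox=rox,
        gfp=gfp,
        in_gate=np.zeros(n, bool),
        sorted_flag=np.zeros(n, bool),
        bead_droplet=np.arange(n_positive),
        bead_variant=np.zeros(n_positive, int),
        variant_ids=["v"],
    )


def test_gate_separates_two_levels_exactly():
    events = _constructed_two_level_events()
    gate = build_gate(events, "high_gfp", 0.03)
    member = gate.membership(events)
    assert member.sum() == 150
    assert (events.gfp[member] == 21.0).all()
    # a cap between the low-cluster size (1850) and all positives (2000)
    # pins the boundary exactly between the two levels
    low_gate = build_gate(events, "low_gfp", 0.095)
    low_member = low_gate.membership(events)
    assert low_member.sum() == 1850
    assert (events.gfp[low_member] == 2.0).all()


def test_gate_requires_rox_positive_cluster():
    pool = {"v": 1.0}
    ph = {"v": SwitchPhenotype(0.5, 0.5)}
    empty = generate_events(pool, 5000, LoadingModel(0.0), ph, DEFAULT_OPTICS, 0.0, 1)
    with pytest.raises(ValueError):
        build_gate(empty, "high_gfp", 0.03)


def test_gate_rejects_small_populations_and_bad_caps():
    events = _two_level_population(n=20_000)
    with pytest.raises(ValueError):
        build_gate(events, "high_gfp", 0.2)
    small = _two_level_population(n=500)
    with pytest.raises(ValueError):
        build_gate(small, "high_gfp", 0.03)


def test_sorter_error_limits():
    events = _two_level_population()
    gate = build_gate(events, "high_gfp", 0.03)
    sort_droplets(events, gate, false_sort=0.0, miss=0.0, seed=0)
    assert (events.sorted_flag == events.in_gate).all()
    sort_droplets(events, gate, false_sort=0.0, miss=1.0, seed=0)
    assert not events.sorted_flag.any()


def test_regenerate_pool_proportional_and_normalized():
    events = _two_level_population()
    gate = build_gate(events, "high_gfp", 0.03)
    sort_droplets(events, gate, false_sort=0.0, miss=0.0, seed=0)
    pool = regenerate_pool(events, pcr_bias_cv=0.0, seed=0)
    assert sum(pool.values()) == pytest.approx(1.0, abs=1e-9)
    sorted_beads = events.sorted_flag[events.bead_droplet]
    counts = np.bincount(events.bead_variant[sorted_beads], minlength=2)
    expected = counts / counts.sum()
    for idx, vid in enumerate(events.variant_ids):
        assert pool.get(vid, 0.0) == pytest.approx(expected[idx], abs=1e-12)


def test_regenerate_pool_empty_halt():
    events = _two_level_population()
    gate = build_gate(events, "high_gfp", 0.03)
    sort_droplets(events, gate, false_sort=0.0, miss=1.0, seed=0)
    with pytest.raises(EmptyPoolError):
        regenerate_pool(events, seed=0)


# ------------------------------------------------------------------- rounds


def test_on_round_enriches_a_strong_switch():
    pool = {"switch": 0.01}
    ph = {"switch": SwitchPhenotype(0.05, 1.0, ec50=1.6, class_label="on_switch")}
    for i in range(99):
        vid = f"dead{i}"
        pool[vid] = 0.01
        ph[vid] = SwitchPhenotype(0.05, 0.05, class_label="dead")
    spec = RoundSpec(sort_target="ON", ligand_conc=5.0, n_droplets=50_000)
    result = simulate_round(pool, spec, ph, seed=3)
    assert result.pool["switch"] > pool["switch"] * 5
    assert result.metrics.in_gate_fraction <= spec.gate_cap + 1e-12
    # determinism
    again = simulate_round(pool, spec, ph, seed=3)
    assert again.pool == result.pool


def test_screen_history_and_normalization(tiny_design):
    ph = assign_phenotypes(tiny_design, planted_fraction=0.2, seed=1)
    pool = {v: 1.0 for v in ph}
    schedule = alternating_schedule(1, n_droplets=20_000)
    history = simulate_screen(pool, schedule, ph, seed=0)
    assert history.n_cycles == 2 and not history.halted
    for cycle_pool in history.pools:
        assert sum(cycle_pool.values()) == pytest.approx(1.0, abs=1e-9)
    frame = history.abundance_frame()
    assert frame.shape[1] == 2
    assert np.allclose(frame.sum(axis=0), 100.0)


def test_screen_enriches_planted_switches(tiny_design):
    ph = assign_phenotypes(tiny_design, planted_fraction=0.1, seed=1)
    planted = [v for v, p in ph.items() if p.class_label == "on_switch"]
    pool = {v: 1.0 for v in ph}
    history = simulate_screen(
        pool, alternating_schedule(4, n_droplets=50_000), ph, seed=5
    )
    initial = sum(history.pools[0].get(v, 0) for v in planted)
    final = sum(history.pools[-1].get(v, 0) for v in planted)
    assert final > 2 * initial


# --------------------------------------------------------------------- mock


def test_mock_clumping_dilutes_template_enrichment():
    for seed in (0, 1):
        report = simulate_mock(seed=seed)  # default loading has clump_p=0.3
        assert report.template_enrichment_fold < report.droplet_enrichment_fold
        assert report.droplet_enrichment_fold > 10


def test_mock_monoclonal_perfect_sorter_purifies_templates():
    """At near-monoclonal loading with a perfect sorter, every sorted
    droplet carries exactly the desired template, so the template
    composition of the recovered pool matches the droplet-level purity."""
    report = simulate_mock(
        loading=LoadingModel(0.05, 0.0),
        n_droplets=400_000,
        false_sort=0.0,
        miss=0.0,
        seed=7,
    )
    assert report.template_fraction_after == pytest.approx(
        report.droplet_fraction_after, rel=0.05
    )
    assert report.droplet_fraction_after > 0.99


def test_mock_purity_and_efficiency_ranges():
    report = simulate_mock(seed=0)
    assert 75.0 <= report.purity <= 92.0
    assert report.efficiency > 90.0
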