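import math

import numpy as np
import pandas as pd
import pytest

from oracles import oracle_two_group_power
from patchkit.stats import (
    STUDY_ARMS,
    StatsConfig,
    build_summary_table,
    compare_all_groups,
    compare_fi_curves,
    compare_scalar_feature,
)

CONTROL, SALINE, NBOH = STUDY_ARMS


def test_identical_multisets_give_p_one_under_rank_test():
    values = {CONTROL: [1.0, 2.0, 3.0, 4.0, 5.0], SALINE: [5.0, 4.0, 3.0, 2.0, 1.0]}
    comp = compare_scalar_feature(
        values, (CONTROL, SALINE), StatsConfig(policy="nonparametric")
    )
    assert comp.p_value == pytest.approx(1.0, abs=1e-9)
    assert not comp.significant


def test_degenerate_constant_groups_flagged():
    values = {CONTROL: [2.0] * 5, SALINE: [2.0] * 5}
    comp = compare_scalar_feature(values, (CONTROL, SALINE))
    assert comp.degenerate and comp.p_value == 1.0


def test_minimum_group_size_enforced():
    with pytest.raises(ValueError, match="3 values"):
        compare_scalar_feature({CONTROL: [1.0, 2.0], SALINE: [1.0, 2.0, 3.0]},
                               (CONTROL, SALINE))


def test_three_identical_groups_are_all_nonsignificant():
    base = list(np.random.default_rng(0).normal(0, 1, 12))
    values = {g: base for g in STUDY_ARMS}
    for correction in ("holm", "dunn_kw"):
        comps = compare_all_groups(values, StatsConfig(correction=correction))
        omnibus, pairwise = comps[0], comps[1:]
        assert omnibus.test_name == "kruskal_wallis"
        assert not omnibus.significant
        assert len(pairwise) == 3
        for c in pairwise:
            assert c.p_adjusted == pytest.approx(1.0, abs=1e-6)
            assert not c.significant


def test_single_shifted_group_yields_exactly_two_significant_contrasts():
    rng = np.random.default_rng(12)
    base = rng.normal(0, 1, 20)
    values = {
        CONTROL: base,
        SALINE: rng.normal(2.0, 1, 20),  # shifted by 2 SD
        NBOH: base + rng.normal(0, 1e-6, 20),
    }
    comps = compare_all_groups(values, StatsConfig(correction="holm"))
    sig = {(c.group_a, c.group_b) for c in comps[1:] if c.significant}
    assert sig == {(CONTROL, SALINE), (SALINE, NBOH)}


def test_missing_arm_raises():
    with pytest.raises(ValueError, match="arms"):
        compare_all_groups({CONTROL: [1.0, 2.0, 3.0], SALINE: [1.0, 2.0, 3.0]})


def test_adjusted_p_never_below_raw_p():
    rng = np.random.default_rng(5)
    for _ in range(10):
        values = {g: rng.normal(rng.uniform(-1, 1), 1, 10) for g in STUDY_ARMS}
        for correction in ("holm", "dunn_kw"):
            for c in compare_all_groups(values, StatsConfig(correction=correction)):
                assert c.p_adjusted >= c.p_value - 1e-12
                assert 0.0 <= c.p_value <= 1.0


def test_power_matches_bruteforce_monte_carlo_oracle():
    """Empirical power at a 1.5 SD shift, n = 12, within 3 points of the oracle."""
    reps = 1000
    rng = np.random.default_rng(100)
    config = StatsConfig(policy="parametric")
    hits = 0
    for _ in range(reps):
        values = {
            CONTROL: rng.standard_normal(12),
            SALINE: rng.standard_normal(12) + 1.5,
        }
        if compare_scalar_feature(values, (CONTROL, SALINE), config).significant:
            hits += 1
    power = hits / reps
    oracle = oracle_two_group_power(np.random.default_rng(200), 12, 1.5, reps)
    assert abs(power - oracle) < 0.03


def test_fi_permutation_identical_groups_give_p_one():
    curves = [np.array([0.0, 2.0, 5.0, 9.0]) + i for i in range(6)]
    by_group = {CONTROL: curves, SALINE: list(curves)}
    comp = compare_fi_curves(by_group, (CONTROL, SALINE), StatsConfig(permutations=1000))
    assert comp.statistic == 0.0
    assert comp.p_value == 1.0


def test_fi_permutation_detects_generator_gain_reduction():
    """Cells drawn with a 0.7 gain multiplier separate from controls at n=15."""
    from patchkit.spikes import compute_fi_curve
    from patchkit.synthetic import GroupEffects, _draw_cell_params, fi_protocol, simulate_current_clamp

    def curves(effects, seed0):
        out = []
        for i in range(15):
            rng = np.random.default_rng(seed0 + i)
            membrane, _ = _draw_cell_params(rng, effects)
            rec = simulate_current_clamp(membrane, fi_protocol(), seed0 + i)
            out.append(compute_fi_curve(rec).frequencies)
        return out

    by_group = {
        CONTROL: curves(GroupEffects(), 1000),
        SALINE: curves(GroupEffects(fi_gain=0.7), 2000),
    }
    config = StatsConfig(permutations=5000, seed=7)
    comp = compare_fi_curves(by_group, (CONTROL, SALINE), config)
    assert comp.significant

    # relabeling symmetry: swapping the pair gives the identical p-value
    flipped = compare_fi_curves(by_group, (SALINE, CONTROL), config)
    assert flipped.p_value == comp.p_value

    # Monte-Carlo stability: doubling permutations moves p by < 2 MC SE
    comp2 = compare_fi_curves(
        by_group, (CONTROL, SALINE), StatsConfig(permutations=10000, seed=8)
    )
    se = math.sqrt(max(comp.p_value, 1 / 5001) * (1 - comp.p_value) / 5000)
    assert abs(comp2.p_value - comp.p_value) <= 2 * se + 2e-4


def test_fi_mismatched_grids_raise():
    by_group = {CONTROL: [np.zeros(5)] * 3, SALINE: [np.zeros(4)] * 3}
    with pytest.raises(ValueError, match="grid"):
        compare_fi_curves(by_group, (CONTROL, SALINE))


def test_summary_table_structure_and_gating():
    rng = np.random.default_rng(3)
    rows = []
    for g in STUDY_ARMS:
        for i in range(6):
            rows.append(
                {
                    "cell_id": f"{g}_{i}",
                    "group": g,
                    "feat_a": rng.normal(0, 1),
                    "feat_b": rng.normal(5, 1),
                }
            )
    features = pd.DataFrame(rows)
    qc = pd.DataFrame(
        {
            "cell_id": features["cell_id"],
            "passed": [cid != f"{CONTROL}_0" for cid in features["cell_id"]],
        }
    )
    summary, comps = build_summary_table(features, qc, ["feat_a", "feat_b"])
    pairwise = summary[summary["group_a"] != "all"]
    assert len(pairwise) == 6  # 3 contrasts x 2 features

    # the excluded cell's value is absent from its group mean
    row = pairwise[(pairwise["feature"] == "feat_a") & (pairwise["group_a"] == CONTROL)].iloc[0]
    kept = features[(features["group"] == CONTROL) & (features["cell_id"] != f"{CONTROL}_0")]
    assert row["n_a"] == 5
    assert row["mean_a"] == pytest.approx(kept["feat_a"].mean())
    # SEM equals sd / sqrt(n), recomputed independently
    assert row["sem_a"] == pytest.approx(kept["feat_a"].std(ddof=1) / math.sqrt(5))


def test_summary_table_requires_qc_for_every_cell():
    features = pd.DataFrame(
        {"cell_id": ["a", "b"], "group": [CONTROL, SALINE], "x": [1.0, 2.0]}
    )
    qc = pd.DataFrame({"cell_id": ["a"], "passed": [True]})
    with pytest.raises(ValueError, match="absent"):
        build_summary_table(features, qc, ["x"])
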