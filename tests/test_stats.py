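import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from conftest import brute_force_mannwhitney
from vesica.stats import (
    EffectDesign,
    build_table1,
    count_events,
    describe,
    mann_whitney,
    min_detectable_effect,
)


# -------------------------------------------------------------- describing

def test_describe_basic():
    s = describe([1.0, 2.0, 3.0], label="g", day=4)
    assert (s.mean, s.sd, s.median, s.min, s.max) == (2.0, 1.0, 2.0, 1.0, 3.0)
    assert s.n == 3 and not s.degenerate


def test_describe_singleton_degenerate():
    s = describe([1.7])
    assert s.mean == s.median == s.min == s.max == 1.7
    assert s.sd == 0.0 and s.degenerate


def test_describe_empty_rejected():
    with pytest.raises(ValueError):
        describe([])


# ------------------------------------------------------------------ events

def test_count_events_rule():
    design = EffectDesign(effect_size=1.3)
    assert count_events([], 1.11, design) == 0
    assert count_events([1.2, 1.35, 0.9, 2.0], 1.11, design) == 2
    # both conditions required: 1.4 clears d but not the control max
    assert count_events([1.4], 1.5, design) == 0
    # strict inequality: a tie with either threshold is not an event
    assert count_events([1.3], 1.0, design) == 0
    assert count_events([1.5], 1.5, design) == 0


@given(
    ratios=st.lists(st.floats(0.1, 5.0), min_size=1, max_size=20),
    idx=st.integers(0, 19),
    bump=st.floats(0.0, 3.0),
)
def test_count_events_monotone_in_each_ratio(ratios, idx, bump):
    design = EffectDesign()
    idx = idx % len(ratios)
    before = count_events(ratios, 1.1, design)
    raised = list(ratios)
    raised[idx] += bump
    assert count_events(raised, 1.1, design) >= before


# ------------------------------------------------------------ mann-whitney

def test_mann_whitney_separated_samples():
    r = mann_whitney([1, 2, 3], [4, 5, 6])
    assert r.u == 0.0
    assert r.p == pytest.approx(0.10, abs=1e-12)
    assert r.method == "exact enumeration"


def test_mann_whitney_symmetry():
    x, y = [1.2, 3.4, 2.2, 5.0], [2.5, 4.1, 0.3]
    a = mann_whitney(x, y)
    b = mann_whitney(y, x)
    assert a.p == pytest.approx(b.p, rel=1e-12)
    assert b.u == pytest.approx(len(x) * len(y) - a.u, abs=1e-9)


def test_mann_whitney_matches_brute_force_enumeration():
    """Exact p equals full permutation enumeration for every group-size pair
    up to 5x5 on tie-free inputs."""
    rng = np.random.default_rng(17)
    for n1 in range(1, 6):
        for n2 in range(1, 6):
            for _ in range(3):
                pooled = rng.permutation(np.linspace(0.1, 9.9, n1 + n2))
                x, y = pooled[:n1], pooled[n1:]
                res = mann_whitney(x, y)
                u_oracle, p_oracle = brute_force_mannwhitney(x, y)
                assert res.u == pytest.approx(u_oracle, abs=1e-9)
                assert res.p == pytest.approx(p_oracle, abs=1e-12)


def test_mann_whitney_fallback_paths():
    rng = np.random.default_rng(3)
    big = mann_whitney(rng.normal(size=15), rng.normal(size=15))
    assert "normal approximation" in big.method
    tied = mann_whitney([1.0, 1.0, 2.0], [1.0, 3.0, 4.0])
    assert "normal approximation" in tied.method
    assert 0 < tied.p <= 1
    with pytest.raises(ValueError):
        mann_whitney([], [1.0])


def test_mann_whitney_type_I_error_calibration():
    """Under the null at n = 9 vs 9, rejection at alpha = 0.05 lands in
    [0.03, 0.07] over 1000 replicates."""
    rng = np.random.default_rng(42)
    rejections = 0
    for _ in range(1000):
        x = rng.normal(size=9)
        y = rng.normal(size=9)
        if mann_whitney(x, y).p < 0.05:
            rejections += 1
    assert 0.03 <= rejections / 1000 <= 0.07


# ------------------------------------------------------------------- power

def test_min_detectable_effect_design_values():
    d9 = min_detectable_effect(9, EffectDesign())
    assert round(d9, 1) == 1.3
    assert d9 == pytest.approx(1.3207, abs=1e-4)
    assert min_detectable_effect(16, EffectDesign()) == pytest.approx(0.99, abs=5e-3)
    assert min_detectable_effect(10**6, EffectDesign()) == pytest.approx(0.004, abs=5e-4)


def test_min_detectable_effect_monotonicity():
    design = EffectDesign()
    ds = [min_detectable_effect(n, design) for n in range(2, 50)]
    assert all(a > b for a, b in zip(ds, ds[1:]))
    # more power (smaller beta) demands a larger detectable effect
    assert min_detectable_effect(9, EffectDesign(beta=0.1)) > min_detectable_effect(
        9, EffectDesign(beta=0.2)
    )
    # one-sided design needs a smaller effect than two-sided
    assert min_detectable_effect(9, EffectDesign(two_sided=False)) < min_detectable_effect(
        9, EffectDesign(two_sided=True)
    )


def test_design_validation():
    with pytest.raises(ValueError):
        EffectDesign(alpha=0.0)
    with pytest.raises(ValueError):
        EffectDesign(beta=1.0)
    with pytest.raises(ValueError):
        min_detectable_effect(1, EffectDesign())


# ----------------------------------------------------------------- table 1

def _ratio_frame():
    rows = []
    rng = np.random.default_rng(8)
    for g, shift in [("control", 0.0), ("25-30Gy", 0.35), ("35-40Gy", 0.8)]:
        for i in range(6 if g == "control" else 9):
            for day in (4, 28):
                rows.append(
                    {
                        "rat_id": f"{g}-{i}",
                        "group": g,
                        "day": day,
                        "ratio": float(0.95 + shift + 0.1 * rng.standard_normal()),
                    }
                )
    return pd.DataFrame(rows)


def test_build_table1_structure():
    report = build_table1(_ratio_frame())
    df = report.to_frame()
    assert len(df) == 6  # 3 groups x 2 days
    assert set(df["day"]) == {4, 28}
    irradiated = df[df["group"] != "control"]
    assert irradiated["n_events"].notna().all()
    assert df.loc[df["group"] == "control", "n_events"].isna().all()
    # three pairwise tests per day
    assert len(report.tests) == 6
    assert all(0 < t.p <= 1 for t in report.tests.values())
    text = report.format_text()
    assert "control" in text and "35-40Gy" in text
    assert "mean±SD" in text


def test_build_table1_missing_control_rejected():
    df = _ratio_frame()
    with pytest.raises(ValueError, match="control"):
        build_table1(df[df["group"] != "control"])


def test_build_table1_degenerate_identical_groups():
    rows = [
        {"rat_id": f"{g}-{i}", "group": g, "day": 4, "ratio": 1.0}
        for g in ("control", "irr") for i in range(4)
    ]
    report = build_table1(pd.DataFrame(rows))
    irr = [s for s in report.summaries if s.label == "irr"][0]
    assert irr.n_events == 0
    (t,) = report.tests.values()
    assert t.p == pytest.approx(1.0, abs=1e-9)


def test_build_table1_holm_adjustment_never_decreases_p():
    raw = build_table1(_ratio_frame(), holm=False)
    adj = build_table1(_ratio_frame(), holm=True)
    for key in raw.tests:
        assert adj.tests[key].p >= raw.tests[key].p - 1e-15
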