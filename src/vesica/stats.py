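"""Dose-response group analysis of corrected thickness ratios.

Per group and follow-up day: descriptive statistics (mean, sample SD,
median, min-max), counting of "thickening events" (a rat whose corrected
ratio exceeds both the control group's maximum on that day and the design
effect size), Mann-Whitney-Wilcoxon rank-sum comparisons between groups,
and the standard two-sample minimum-detectable-effect arithmetic behind
the n = 9 per group design (effect size 1.3 at alpha = 0.05, power 0.80).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "EffectDesign",
    "GroupSummary",
    "TestResult",
    "describe",
    "count_events",
    "mann_whitney",
    "min_detectable_effect",
    "build_table1",
    "Table1Report",
]


@dataclass(frozen=True)
class EffectDesign:
    """Study design parameters for the effect-size rule and power arithmetic."""

    effect_size: float = 1.3
    alpha: float = 0.05
    beta: float = 0.20
    two_sided: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 < self.beta < 1:
            raise ValueError("beta must be in (0, 1)")
        if self.effect_size <= 0:
            raise ValueError("effect size must be > 0")


@dataclass
class GroupSummary:
    """Descriptives (and, for irradiated groups, event counts) per group/day."""

    label: str
    day: int | None
    n: int
    mean: float
    sd: float
    median: float
    min: float
    max: float
    n_events: int | None = None
    event_fraction: float | None = None
    control_max: float | None = None
    effect_size: float | None = None
    degenerate: bool = False


@dataclass(frozen=True)
class TestResult:
    """Mann-Whitney U outcome: U of the first sample and two-sided p."""

    u: float
    p: float
    method: str
    n1: int
    n2: int


def describe(ratios, label: str = "", day: int | None = None) -> GroupSummary:
    """Mean, sample SD (n-1), median and range of a ratio list.

    A single observation yields SD 0 with the ``degenerate`` flag set
    (the n-1 denominator is undefined there).
    """
    x = np.asarray(list(ratios), dtype=float)
    if x.size == 0:
        raise ValueError("cannot describe an empty group")
    degenerate = x.size == 1
    sd = 0.0 if degenerate else float(np.std(x, ddof=1))
    return GroupSummary(
        label=label,
        day=day,
        n=int(x.size),
        mean=float(np.mean(x)),
        sd=sd,
        median=float(np.median(x)),
        min=float(np.min(x)),
        max=float(np.max(x)),
        degenerate=degenerate,
    )


def count_events(ratios, control_max: float, design: EffectDesign) -> int:
    """Count rats whose ratio strictly exceeds BOTH thresholds.

    A thickening event requires the corrected ratio to be above the control
    group's maximum on the same day AND above the design effect size.
    """
    x = np.asarray(list(ratios), dtype=float)
    if x.size and np.any(x <= 0):
        raise ValueError("ratios must be positive")
    if control_max <= 0:
        raise ValueError("control_max must be > 0")
    return int(np.sum((x > control_max) & (x > design.effect_size)))


def mann_whitney(x, y) -> TestResult:
    """Two-sided Mann-Whitney-Wilcoxon rank-sum test.

    Exact null distribution when n1*n2 <= 100 and the pooled sample is
    tie-free; otherwise the normal approximation with continuity and tie
    correction.  U is reported for the first sample.
    """
    a = np.asarray(list(x), dtype=float)
    b = np.asarray(list(y), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    tie_free = np.unique(pooled).size == pooled.size
    if a.size * b.size <= 100 and tie_free:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method,
                           use_continuity=True)
    label = "exact enumeration" if method == "exact" else "normal approximation (tie-corrected)"
    return TestResult(u=float(res.statistic), p=float(res.pvalue), method=label,
                      n1=int(a.size), n2=int(b.size))


def min_detectable_effect(n_per_group: int, design: EffectDesign = EffectDesign()) -> float:
    """Minimum detectable standardised effect for two groups of size n.

    The standard two-sample normal-approximation identity
    ``d = (z_{1-alpha/2} + z_{1-beta}) * sqrt(2/n)`` (``z_{1-alpha}`` for a
    one-sided design).  At n = 9, alpha = 0.05 two-sided and power 0.80 this
    gives 1.32, i.e. 1.3 at one decimal.
    """
    if n_per_group < 2:
        raise ValueError("need at least 2 per group")
    z_a = sps.norm.ppf(1 - design.alpha / 2) if design.two_sided else sps.norm.ppf(1 - design.alpha)
    z_b = sps.norm.ppf(1 - design.beta)
    return float((z_a + z_b) * np.sqrt(2.0 / n_per_group))


@dataclass
class Table1Report:
    """Per-group/day descriptives, event counts and pairwise tests."""

    summaries: list[GroupSummary]
    tests: dict[str, TestResult]
    design: EffectDesign
    control_label: str

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.summaries:
            rows.append(
                {
                    "group": s.label,
                    "day": s.day,
                    "n": s.n,
                    "mean": s.mean,
                    "sd": s.sd,
                    "median": s.median,
                    "min": s.min,
                    "max": s.max,
                    "n_events": s.n_events,
                    "event_fraction": s.event_fraction,
                    "control_max": s.control_max,
                    "degenerate": s.degenerate,
                }
            )
        return pd.DataFrame(rows)

    def to_json(self) -> str:
        payload = {
            "design": asdict(self.design),
            "control_label": self.control_label,
            "groups": [asdict(s) for s in self.summaries],
            "tests": {k: asdict(v) for k, v in self.tests.items()},
        }
        return json.dumps(payload, indent=1)

    def format_text(self) -> str:
        """Human-readable block mirroring a results table."""
        lines = []
        df = self.to_frame()
        for (label,), sub in df.groupby(["group"], sort=False):
            lines.append(f"{label}")
            for _, r in sub.iterrows():
                ev = ""
                if r["n_events"] is not None and not pd.isna(r["n_events"]):
                    ev = f"  events {int(r['n_events'])}/{int(r['n'])}"
                lines.append(
                    f"  day {int(r['day']):>2}: mean±SD {r['mean']:.2f}±{r['sd']:.2f}  "
                    f"median (min–max) {r['median']:.2f} ({r['min']:.2f}–{r['max']:.2f}){ev}"
                )
        for key, t in self.tests.items():
            lines.append(f"  {key}: U={t.u:.1f}, p={t.p:.4g} [{t.method}]")
        return "\n".join(lines)


def build_table1(
    ratios: pd.DataFrame,
    design: EffectDesign = EffectDesign(),
    control_label: str = "control",
    holm: bool = False,
) -> Table1Report:
    """Aggregate per-rat corrected ratios into the group-level report.

    ``ratios`` needs columns ``rat_id, group, day, ratio``.  The control
    group defines the per-day maximum for event counting; pairwise
    Mann-Whitney tests compare each irradiated group against control and
    irradiated groups against each other, per day.  ``holm=True``
    additionally applies a Holm step-down adjustment across the pairwise
    p-values of each day.
    """
    req = {"rat_id", "group", "day", "ratio"}
    missing = req - set(ratios.columns)
    if missing:
        raise ValueError(f"ratio table lacks columns: {sorted(missing)}")
    groups = list(dict.fromkeys(ratios["group"]))
    if control_label not in groups:
        raise ValueError(f"control group {control_label!r} missing from ratio table")
    irradiated = [g for g in groups if g != control_label]
    days = sorted(int(d) for d in ratios["day"].unique())

    summaries: list[GroupSummary] = []
    tests: dict[str, TestResult] = {}
    for day in days:
        day_rows = ratios[ratios["day"] == day]
        control = day_rows.loc[day_rows["group"] == control_label, "ratio"].to_numpy()
        if control.size == 0:
            raise ValueError(f"control group has no ratios at day {day}")
        cmax = float(np.max(control))
        for g in groups:
            vals = day_rows.loc[day_rows["group"] == g, "ratio"].to_numpy()
            if vals.size == 0:
                continue
            s = describe(vals, label=g, day=day)
            if g != control_label:
                n_ev = count_events(vals, cmax, design)
                s.n_events = n_ev
                s.event_fraction = n_ev / s.n
                s.control_max = cmax
                s.effect_size = design.effect_size
            summaries.append(s)
        day_tests: dict[str, TestResult] = {}
        for g in irradiated:
            vals = day_rows.loc[day_rows["group"] == g, "ratio"].to_numpy()
            if vals.size:
                day_tests[f"{g} vs {control_label} (day {day})"] = mann_whitney(vals, control)
        for i, g1 in enumerate(irradiated):
            for g2 in irradiated[i + 1 :]:
                v1 = day_rows.loc[day_rows["group"] == g1, "ratio"].to_numpy()
                v2 = day_rows.loc[day_rows["group"] == g2, "ratio"].to_numpy()
                if v1.size and v2.size:
                    day_tests[f"{g1} vs {g2} (day {day})"] = mann_whitney(v1, v2)
        if holm and day_tests:
            keys = list(day_tests)
            pvals = np.array([day_tests[k].p for k in keys])
            order = np.argsort(pvals)
            m = len(pvals)
            adj = np.empty(m)
            running = 0.0
            for rank, idx in enumerate(order):
                running = max(running, (m - rank) * pvals[idx])
                adj[idx] = min(running, 1.0)
            for k, p_adj in zip(keys, adj):
                t = day_tests[k]
                day_tests[k] = TestResult(t.u, float(p_adj), t.method + " + Holm", t.n1, t.n2)
        tests.update(day_tests)
    return Table1Report(summaries=summaries, tests=tests, design=design,
                        control_label=control_label)
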