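"""Three-arm group comparisons of scalar features and f-I curves.

The default testing policy is normality-gated for two-group contrasts
(Shapiro-Wilk in both groups, then Welch's t, otherwise Mann-Whitney U) and
Kruskal-Wallis followed by pairwise contrasts with a multiplicity correction
for the three-arm family.  Two corrections are offered: Holm over
per-contrast two-sample tests, and Dunn's rank-based post hoc (the classic
companion of Kruskal-Wallis) with Holm adjustment.  f-I curves are compared
by a cell-level permutation test on the maximum absolute pointwise
difference of group mean frequencies (max-T), which makes no distributional
or sphericity assumptions.

All stochastic procedures are reproducible bit-for-bit given the configured
seed.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .recording import GroupLabel

__all__ = [
    "StatsConfig",
    "GroupComparison",
    "compare_scalar_feature",
    "compare_all_groups",
    "compare_fi_curves",
    "build_summary_table",
    "STUDY_ARMS",
]

STUDY_ARMS = (GroupLabel.CONTROL.value, GroupLabel.PAE_SALINE.value, GroupLabel.PAE_NBOH.value)


@dataclass(frozen=True)
class StatsConfig:
    policy: str = "auto"  # auto | nonparametric | parametric
    correction: str = "holm"  # holm | dunn_kw | none
    alpha: float = 0.05
    normality_alpha: float = 0.05
    permutations: int = 5000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.policy not in ("auto", "nonparametric", "parametric"):
            raise ValueError(f"unknown policy {self.policy!r}")
        if self.correction not in ("holm", "dunn_kw", "none"):
            raise ValueError(f"unknown correction {self.correction!r}")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")
        if self.permutations < 1000:
            raise ValueError("permutations must be >= 1000")


@dataclass
class GroupComparison:
    feature: str
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    mean_a: float
    sem_a: float
    mean_b: float
    sem_b: float
    test_name: str
    statistic: float
    p_value: float
    p_adjusted: float
    significant: bool
    degenerate: bool = False


def _sem(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        return float("nan")
    return float(np.std(x, ddof=1) / math.sqrt(x.size))


def _two_sample(a: np.ndarray, b: np.ndarray, config: StatsConfig) -> tuple[str, float, float, bool]:
    """(test name, statistic, p, degenerate) under the configured policy."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
        return "degenerate", 0.0, 1.0, True

    if config.policy == "parametric":
        use_t = True
    elif config.policy == "nonparametric":
        use_t = False
    else:
        normal_a = a.size >= 3 and sps.shapiro(a).pvalue > config.normality_alpha
        normal_b = b.size >= 3 and sps.shapiro(b).pvalue > config.normality_alpha
        use_t = normal_a and normal_b
    if use_t:
        res = sps.ttest_ind(a, b, equal_var=False)
        return "welch_t", float(res.statistic), float(res.pvalue), False
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return "mann_whitney_u", float(res.statistic), float(res.pvalue), False


def compare_scalar_feature(
    values_by_group: Mapping[str, Sequence[float]],
    pair: tuple[str, str],
    config: StatsConfig | None = None,
    feature: str = "",
) -> GroupComparison:
    """Two-group contrast on one scalar feature (no multiplicity correction)."""
    config = config or StatsConfig()
    ga, gb = pair
    a = np.asarray(values_by_group[ga], dtype=float)
    b = np.asarray(values_by_group[gb], dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("need at least 3 values per group")
    name, stat, p, degenerate = _two_sample(a, b, config)
    return GroupComparison(
        feature=feature,
        group_a=ga,
        group_b=gb,
        n_a=a.size,
        n_b=b.size,
        mean_a=float(np.mean(a)),
        sem_a=_sem(a),
        mean_b=float(np.mean(b)),
        sem_b=_sem(b),
        test_name=name,
        statistic=stat,
        p_value=p,
        p_adjusted=p,
        significant=p < config.alpha,
        degenerate=degenerate,
    )


def _dunn_pairwise(
    values_by_group: Mapping[str, np.ndarray], pairs: list[tuple[str, str]]
) -> dict[tuple[str, str], tuple[float, float]]:
    """Dunn's post hoc z tests on pooled ranks, with tie correction."""
    labels = list(values_by_group)
    pooled = np.concatenate([values_by_group[g] for g in labels])
    sizes = {g: values_by_group[g].size for g in labels}
    ranks = sps.rankdata(pooled)
    mean_rank: dict[str, float] = {}
    start = 0
    for g in labels:
        mean_rank[g] = float(np.mean(ranks[start : start + sizes[g]]))
        start += sizes[g]
    n = pooled.size
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / (12.0 * (n - 1)) if n > 1 else 0.0
    var_base = n * (n + 1) / 12.0 - tie_term
    out = {}
    for ga, gb in pairs:
        se = math.sqrt(var_base * (1.0 / sizes[ga] + 1.0 / sizes[gb]))
        if se == 0.0:
            out[(ga, gb)] = (0.0, 1.0)
            continue
        z = (mean_rank[ga] - mean_rank[gb]) / se
        out[(ga, gb)] = (z, 2.0 * sps.norm.sf(abs(z)))
    return out


def compare_all_groups(
    values_by_group: Mapping[str, Sequence[float]],
    config: StatsConfig | None = None,
    feature: str = "",
) -> list[GroupComparison]:
    """Kruskal-Wallis omnibus plus the three corrected pairwise contrasts.

    Requires exactly the three study arms.  The first returned entry is the
    omnibus (``group_a = group_b = "all"``); the rest are pairwise with
    ``p_adjusted`` carrying the configured correction.
    """
    config = config or StatsConfig()
    missing = [g for g in STUDY_ARMS if g not in values_by_group]
    if missing or len(values_by_group) != 3:
        raise ValueError(f"expected exactly the three study arms; missing {missing}")
    groups = {g: np.asarray(values_by_group[g], dtype=float) for g in STUDY_ARMS}

    pooled = np.concatenate(list(groups.values()))
    degenerate = bool(np.all(pooled == pooled[0]))
    if degenerate:
        h, p_omni = 0.0, 1.0
    else:
        h, p_omni = sps.kruskal(*groups.values())
    omnibus = GroupComparison(
        feature=feature,
        group_a="all",
        group_b="all",
        n_a=pooled.size,
        n_b=pooled.size,
        mean_a=float(np.mean(pooled)),
        sem_a=_sem(pooled),
        mean_b=float(np.mean(pooled)),
        sem_b=_sem(pooled),
        test_name="kruskal_wallis",
        statistic=float(h),
        p_value=float(p_omni),
        p_adjusted=float(p_omni),
        significant=p_omni < config.alpha,
        degenerate=degenerate,
    )

    pairs = list(itertools.combinations(STUDY_ARMS, 2))
    results: list[GroupComparison] = []
    if config.correction == "dunn_kw":
        dunn = _dunn_pairwise(groups, pairs)
        for ga, gb in pairs:
            z, p = dunn[(ga, gb)]
            a, b = groups[ga], groups[gb]
            results.append(
                GroupComparison(
                    feature=feature,
                    group_a=ga,
                    group_b=gb,
                    n_a=a.size,
                    n_b=b.size,
                    mean_a=float(np.mean(a)),
                    sem_a=_sem(a),
                    mean_b=float(np.mean(b)),
                    sem_b=_sem(b),
                    test_name="dunn",
                    statistic=z,
                    p_value=p,
                    p_adjusted=p,
                    significant=False,
                    degenerate=degenerate,
                )
            )
    else:
        for pair in pairs:
            results.append(compare_scalar_feature(groups, pair, config, feature))

    if config.correction != "none":
        raw = [r.p_value for r in results]
        adj = multipletests(raw, alpha=config.alpha, method="holm")[1]
        for r, p_adj in zip(results, adj):
            r.p_adjusted = float(max(p_adj, r.p_value))
            r.significant = r.p_adjusted < config.alpha
    else:
        for r in results:
            r.significant = r.p_value < config.alpha
    return [omnibus] + results


def compare_fi_curves(
    curves_by_group: Mapping[str, Sequence[Sequence[float]]],
    pair: tuple[str, str],
    config: StatsConfig | None = None,
    currents: Sequence[float] | None = None,
) -> GroupComparison:
    """Cell-level permutation test on f-I curves (max-T statistic).

    ``curves_by_group[label]`` is a list of per-cell frequency vectors on a
    shared current grid.  The statistic is the maximum absolute pointwise
    difference of group mean frequencies; group labels are permuted at the
    cell level, and the p-value uses the add-one estimator.  Swapping the
    pair gives an identical p-value by symmetry of the statistic.
    """
    config = config or StatsConfig()
    ga, gb = pair
    a = np.asarray(curves_by_group[ga], dtype=float)
    b = np.asarray(curves_by_group[gb], dtype=float)
    if a.ndim != 2 or b.ndim != 2 or a.shape[1] != b.shape[1]:
        raise ValueError("f-I curves must share the current grid across groups")

    def max_t(x: np.ndarray, y: np.ndarray) -> float:
        return float(np.max(np.abs(x.mean(axis=0) - y.mean(axis=0))))

    observed = max_t(a, b)
    pooled = np.vstack([a, b])
    n_a = a.shape[0]
    rng = np.random.default_rng(config.seed)
    count = 0
    for _ in range(config.permutations):
        perm = rng.permutation(pooled.shape[0])
        if max_t(pooled[perm[:n_a]], pooled[perm[n_a:]]) >= observed:
            count += 1
    p = (count + 1) / (config.permutations + 1)

    mean_total_a = a.mean(axis=1)
    mean_total_b = b.mean(axis=1)
    return GroupComparison(
        feature="fi_curve",
        group_a=ga,
        group_b=gb,
        n_a=n_a,
        n_b=b.shape[0],
        mean_a=float(np.mean(mean_total_a)),
        sem_a=_sem(mean_total_a),
        mean_b=float(np.mean(mean_total_b)),
        sem_b=_sem(mean_total_b),
        test_name=f"permutation_max_t[{config.permutations}]",
        statistic=observed,
        p_value=p,
        p_adjusted=p,
        significant=p < config.alpha,
        degenerate=observed == 0.0,
    )


def build_summary_table(
    features: pd.DataFrame,
    qc: pd.DataFrame,
    feature_names: Sequence[str],
    config: StatsConfig | None = None,
) -> tuple[pd.DataFrame, list[GroupComparison]]:
    """Per-feature, per-contrast summary over QC-passed cells.

    ``features`` needs ``cell_id`` and ``group`` columns plus one column per
    feature; ``qc`` needs ``cell_id`` and ``passed``.  A feature cell missing
    from the QC table is an error (gate totality).
    """
    config = config or StatsConfig()
    missing = set(features["cell_id"]) - set(qc["cell_id"])
    if missing:
        raise ValueError(f"cells present in features but absent from qc: {sorted(missing)}")
    passed_ids = set(qc.loc[qc["passed"].astype(bool), "cell_id"])
    kept = features[features["cell_id"].isin(passed_ids)]

    rows = []
    comparisons: list[GroupComparison] = []
    for name in feature_names:
        by_group = {
            g: kept.loc[kept["group"] == g, name].dropna().to_numpy()
            for g in STUDY_ARMS
        }
        if any(v.size < 3 for v in by_group.values()):
            continue
        for comp in compare_all_groups(by_group, config, feature=name):
            comparisons.append(comp)
            rows.append(
                {
                    "feature": comp.feature,
                    "group_a": comp.group_a,
                    "group_b": comp.group_b,
                    "n_a": comp.n_a,
                    "n_b": comp.n_b,
                    "mean_a": comp.mean_a,
                    "sem_a": comp.sem_a,
                    "mean_b": comp.mean_b,
                    "sem_b": comp.sem_b,
                    "test": comp.test_name,
                    "statistic": comp.statistic,
                    "p_value": comp.p_value,
                    "p_adjusted": comp.p_adjusted,
                    "significant": comp.significant,
                }
            )
    return pd.DataFrame(rows), comparisons
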