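"""Post-simulation metrics and statistics.

Maturation time (first post-confluence day with an osteocyte), per-day
census tables, BIC-selected Gaussian-mixture cluster counts of osteocyte
positions (a regularity readout: layer-polarised deposition yields a more
consistent cluster count across runs than cell-autonomous polarity), and
the group-comparison tests used on simulation output (Kruskal-Wallis with
an exact-permutation oracle mode, two-way main-effect comparison with day
as covariate, Dunn / Bonferroni post-hocs).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.mixture import GaussianMixture

from .core import AgentKind
from .engine import Trajectory


def maturation_day(traj: Trajectory) -> Optional[int]:
    """First post-confluence day with at least one osteocyte, or None.

    Counted in whole 72-iteration days from first confluence; an osteocyte
    appearing within day d (iterations (d-1)*72+1 .. d*72 after confluence)
    is "observed on day d pc", and osteocytes already present at confluence
    give day 0.
    """
    it = traj.events.get("first_osteocyte")
    if it is None or traj.confluent_since is None:
        return None
    if it < traj.confluent_since:
        return 0
    ipd = traj.config.iterations_per_day
    return math.ceil((it - traj.confluent_since) / ipd)


def census_by_day(traj: Trajectory) -> pd.DataFrame:
    """Tidy long table (day_pc x kind -> count) of the post-confluence census."""
    rows = []
    for rec in traj.records:
        if rec["day_pc"] is None:
            continue
        for kind in AgentKind:
            name = kind.name.lower()
            rows.append(
                {"day": int(rec["day_pc"]), "kind": name, "count": rec[name], "height": rec["height"]}
            )
    return pd.DataFrame(rows, columns=["day", "kind", "count", "height"])


def osteocyte_positions(traj: Trajectory) -> np.ndarray:
    """(N, 3) osteocyte coordinates of the final state."""
    state = traj.final_state
    if state is None:
        raise ValueError("trajectory was run without keep_final_state")
    return state.pos[state.kind == int(AgentKind.OSTEOCYTE)].copy()


@dataclass
class ClusterReport:
    """BIC curve over candidate cluster counts and the argmin k*."""

    best_k: int
    bic: dict[int, float] = field(default_factory=dict)
    n_points: int = 0


def cluster_count_bic(
    points: Sequence, k_max: int = 8, seed: int = 0, n_init: int = 3
) -> ClusterReport:
    """Select the number of spatial clusters by Gaussian-mixture BIC.

    Fits full-covariance Gaussian mixtures for k = 1..k_max with seeded
    restarts and returns the argmin-BIC k plus the whole curve; k values
    with more components than points are skipped with a warning.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or len(pts) < 2:
        raise ValueError("cluster analysis needs at least two points")
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    bic: dict[int, float] = {}
    for k in range(1, k_max + 1):
        if k > len(pts):
            warnings.warn(f"skipping k={k}: only {len(pts)} points")
            continue
        gmm = GaussianMixture(
            n_components=k,
            covariance_type="full",
            n_init=n_init,
            random_state=seed,
            reg_covar=1e-4,
        )
        gmm.fit(pts)
        bic[k] = float(gmm.bic(pts))
    best = min(bic, key=bic.get)
    return ClusterReport(best_k=best, bic=bic, n_points=len(pts))


def regularity_score(reports: Sequence[ClusterReport]) -> float:
    """Dispersion (variance) of the per-run best cluster count.

    Lower dispersion = a more regular, reproducible osteocyte arrangement
    across replicate runs of one hypothesis.
    """
    if len(reports) < 2:
        raise ValueError("need at least two runs per hypothesis")
    ks = np.array([r.best_k for r in reports], dtype=float)
    return float(np.var(ks, ddof=1))


# ---------------------------------------------------------------------------
# rank-based group comparison
# ---------------------------------------------------------------------------

def _kruskal_h(groups: list[np.ndarray]) -> float:
    """Kruskal-Wallis H with tie correction."""
    pooled = np.concatenate(groups)
    n = len(pooled)
    ranks = stats.rankdata(pooled)
    start = 0
    h = 0.0
    for g in groups:
        r = ranks[start : start + len(g)]
        h += r.sum() ** 2 / len(g)
        start += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1.0 - (counts**3 - counts).sum() / (n**3 - n)
    return h / tie if tie > 0 else 0.0


def rank_test_groups(groups: Sequence[Sequence[float]], method: str = "auto"):
    """Kruskal-Wallis k-sample rank test; returns (statistic, p).

    ``method``: "asymptotic" (chi-square, the default behaviour of "auto"),
    or "exact", which enumerates all assignments of the pooled sample to
    the group sizes — feasible only for tiny samples and intended as a
    built-in oracle for the asymptotic path. When all observations across
    all groups are identical, p = 1 by convention.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need >= 2 non-empty groups")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    if method == "auto":
        method = "asymptotic"
    if method == "asymptotic":
        res = stats.kruskal(*groups)
        return float(res.statistic), float(res.pvalue)
    if method != "exact":
        raise ValueError(f"unknown method {method!r}")
    h_obs = _kruskal_h(groups)
    sizes = [len(g) for g in groups]
    n = len(pooled)
    idx = np.arange(n)
    count = 0
    total = 0
    # enumerate multiset splits of the pooled sample into the group sizes
    for assignment in _assignments(idx, sizes):
        perm_groups = [pooled[list(a)] for a in assignment]
        if _kruskal_h(perm_groups) >= h_obs - 1e-12:
            count += 1
        total += 1
    return float(h_obs), count / total


def _assignments(idx: np.ndarray, sizes: list[int]):
    """All ways to split idx into consecutive groups of the given sizes."""
    if len(sizes) == 1:
        yield (tuple(idx),)
        return
    for combo in itertools.combinations(idx, sizes[0]):
        rest = np.setdiff1d(idx, combo)
        for tail in _assignments(rest, sizes[1:]):
            yield (combo,) + tail


# ---------------------------------------------------------------------------
# factorial comparison with post-hoc family
# ---------------------------------------------------------------------------

@dataclass
class ComparisonReport:
    """Main-effect p-value and the adjusted post-hoc p per comparison."""

    main_effect_p: float
    posthoc: pd.DataFrame  # columns: group_a, group_b, p_raw, p_adj, significant
    anova_table: pd.DataFrame


def _dunn_z(ranks_a, ranks_b, n_total, tie_term) -> float:
    var = (n_total * (n_total + 1) / 12.0 - tie_term) * (
        1.0 / len(ranks_a) + 1.0 / len(ranks_b)
    )
    if var <= 0:  # fully tied data carries no rank information
        return 0.0
    return (np.mean(ranks_a) - np.mean(ranks_b)) / math.sqrt(var)


def factorial_comparison(
    table: pd.DataFrame,
    group: str = "spec",
    covariate: str = "day",
    value: str = "count",
    posthoc: str = "dunn_vs_control",
    control: Optional[str] = None,
    alpha: float = 0.05,
) -> ComparisonReport:
    """Group main-effect with the day as covariate, plus a post-hoc family.

    The main effect is a linear-model F-test of the group factor with the
    day as covariate. Post-hoc ``dunn_vs_control`` compares every group to
    the control on Kruskal ranks (Dunn's z with tie correction, adjusted
    for the number of comparisons); ``bonferroni_all_pairs`` adjusts
    all-pairs Dunn z-tests by the full pair count.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    required = {group, covariate, value}
    if not required <= set(table.columns):
        raise ValueError(f"table must have columns {sorted(required)}")
    levels = sorted(table[group].unique())
    cells = {
        (g, d)
        for g, d in itertools.product(levels, sorted(table[covariate].unique()))
    } - set(map(tuple, table[[group, covariate]].drop_duplicates().to_numpy()))
    if cells:
        raise ValueError(f"missing design cells: {sorted(cells)}")

    df = table.rename(columns={group: "grp", covariate: "cov", value: "val"})
    model = smf.ols("val ~ C(grp) + cov", data=df).fit()
    anova = sm.stats.anova_lm(model, typ=2)
    main_p = float(anova.loc["C(grp)", "PR(>F)"])

    pooled = df["val"].to_numpy(float)
    ranks = stats.rankdata(pooled)
    group_ranks = {g: ranks[(df["grp"] == g).to_numpy()] for g in levels}
    n = len(pooled)
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = (counts**3 - counts).sum() / (12.0 * (n - 1))

    if posthoc == "dunn_vs_control":
        if control is None:
            raise ValueError("dunn_vs_control needs a control group name")
        pairs = [(control, g) for g in levels if g != control]
    elif posthoc == "bonferroni_all_pairs":
        pairs = list(itertools.combinations(levels, 2))
    else:
        raise ValueError(f"unknown posthoc {posthoc!r}")

    m = len(pairs)
    rows = []
    for a, b in pairs:
        z = _dunn_z(group_ranks[a], group_ranks[b], n, tie_term)
        p_raw = 2 * stats.norm.sf(abs(z))
        p_adj = min(1.0, p_raw * m)
        rows.append(
            {
                "group_a": a,
                "group_b": b,
                "z": z,
                "p_raw": p_raw,
                "p_adj": p_adj,
                "significant": p_adj < alpha,
            }
        )
    return ComparisonReport(
        main_effect_p=main_p, posthoc=pd.DataFrame(rows), anova_table=anova
    )
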