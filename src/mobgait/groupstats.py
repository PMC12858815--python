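"""Group comparison and correlation statistics for three-group cohorts.

For every feature: Shapiro-Wilk on the within-group residuals and Levene's
test gate the omnibus test (one-way ANOVA when residuals are normal and
variances homogeneous, Kruskal-Wallis otherwise); p-values are adjusted
with the Benjamini-Hochberg step-up within each feature family at an FDR
of 0.05; eta-squared reports the effect size (SS_between/SS_total for
ANOVA, the rank-based (H - k + 1)/(n - k) analogue for Kruskal-Wallis).
Features passing the adjusted threshold get pairwise post hoc tests
(independent t-tests after ANOVA, Dunn's rank z-tests otherwise, both at
alpha = 0.05 without further multiplicity correction).  Spearman
correlations are computed per group with strength categories
|rho| <= 0.25 weak, (0.25, 0.50] moderate, (0.50, 0.75] strong,
> 0.75 very strong.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .config import StatsConfig

log = logging.getLogger("mobgait.stats")

GROUPS = ("MSA", "PSP", "PD")


# ----------------------------------------------------------------------
# test selection and omnibus tests
# ----------------------------------------------------------------------

def choose_test(groups: dict[str, np.ndarray], cfg: StatsConfig | None = None) -> str | None:
    """Pick ``"anova"`` or ``"kruskal"``; None when a group is too small.

    ANOVA requires normally distributed residuals (Shapiro-Wilk) and
    homogeneous variances (Levene) at the assumption alpha.
    """
    cfg = cfg or StatsConfig()
    arrays = [np.asarray(v, dtype=float) for v in groups.values()]
    if any(a.size < cfg.min_group_n for a in arrays):
        return None
    residuals = np.concatenate([a - a.mean() for a in arrays])
    try:
        p_norm = stats.shapiro(residuals).pvalue
        p_var = stats.levene(*arrays, center="mean").pvalue
    except ValueError:
        return "kruskal"
    if np.isnan(p_norm) or np.isnan(p_var):
        return "kruskal"
    if p_norm > cfg.assumption_alpha and p_var > cfg.assumption_alpha:
        return "anova"
    return "kruskal"


def eta_squared_anova(groups: list[np.ndarray]) -> float:
    """SS_between / SS_total."""
    allv = np.concatenate(groups)
    grand = allv.mean()
    ss_total = float(((allv - grand) ** 2).sum())
    if ss_total == 0.0:
        return float("nan")
    ss_between = float(sum(a.size * (a.mean() - grand) ** 2 for a in groups))
    return ss_between / ss_total


def eta_squared_kruskal(h: float, k: int, n: int) -> float:
    """Rank-based analogue (H - k + 1)/(n - k), floored at 0."""
    if n <= k:
        return float("nan")
    return float(np.clip((h - k + 1) / (n - k), 0.0, 1.0))


@dataclass
class OmnibusResult:
    feature: str
    test: str  # "anova" | "kruskal"
    statistic: float
    p_value: float
    eta_squared: float
    p_adjusted: float = float("nan")
    posthoc: dict[tuple[str, str], float] = field(default_factory=dict)
    degenerate: bool = False


def omnibus(
    feature: str, groups: dict[str, np.ndarray], cfg: StatsConfig | None = None
) -> OmnibusResult | None:
    """Assumption-gated omnibus test with effect size; None = skipped."""
    cfg = cfg or StatsConfig()
    clean = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    clean = {k: v[np.isfinite(v)] for k, v in clean.items()}
    test = choose_test(clean, cfg)
    if test is None:
        log.info("feature %s skipped: a group has fewer than %d observations",
                 feature, cfg.min_group_n)
        return None
    arrays = list(clean.values())
    allv = np.concatenate(arrays)
    if np.ptp(allv) == 0.0:
        log.warning("feature %s degenerate: constant across all subjects", feature)
        return OmnibusResult(feature=feature, test=test, statistic=float("nan"),
                             p_value=1.0, eta_squared=float("nan"), degenerate=True)
    if test == "anova":
        res = stats.f_oneway(*arrays)
        eta2 = eta_squared_anova(arrays)
    else:
        res = stats.kruskal(*arrays)
        eta2 = eta_squared_kruskal(res.statistic, len(arrays), allv.size)
    return OmnibusResult(feature=feature, test=test, statistic=float(res.statistic),
                         p_value=float(res.pvalue), eta_squared=eta2)


# ----------------------------------------------------------------------
# multiplicity adjustment
# ----------------------------------------------------------------------

def adjust_bh(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order preserving)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ----------------------------------------------------------------------
# post hoc tests
# ----------------------------------------------------------------------

def dunn_test(groups: dict[str, np.ndarray]) -> dict[tuple[str, str], float]:
    """Dunn's pairwise rank z-tests (tie-corrected, unadjusted p-values)."""
    labels = list(groups)
    arrays = [np.asarray(groups[k], dtype=float) for k in labels]
    allv = np.concatenate(arrays)
    n = allv.size
    ranks = stats.rankdata(allv)
    mean_ranks = {}
    i = 0
    for label, a in zip(labels, arrays):
        mean_ranks[label] = ranks[i:i + a.size].mean()
        i += a.size
    _, counts = np.unique(allv, return_counts=True)
    tie_term = float(((counts**3 - counts).sum()) / (12.0 * (n - 1))) if n > 1 else 0.0
    base_var = n * (n + 1) / 12.0 - tie_term

    out: dict[tuple[str, str], float] = {}
    for a, b in itertools.combinations(labels, 2):
        na, nb = len(groups[a]), len(groups[b])
        se = np.sqrt(base_var * (1.0 / na + 1.0 / nb))
        z = (mean_ranks[a] - mean_ranks[b]) / se if se > 0 else 0.0
        out[(a, b)] = float(2.0 * stats.norm.sf(abs(z)))
    return out


def posthoc(
    groups: dict[str, np.ndarray], parametric: bool
) -> dict[tuple[str, str], float]:
    """Pairwise p-values: independent t-tests (parametric) or Dunn's test."""
    clean = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    clean = {k: v[np.isfinite(v)] for k, v in clean.items()}
    if parametric:
        out = {}
        for a, b in itertools.combinations(clean, 2):
            out[(a, b)] = float(stats.ttest_ind(clean[a], clean[b]).pvalue)
        return out
    return dunn_test(clean)


# ----------------------------------------------------------------------
# correlations
# ----------------------------------------------------------------------

def strength_of(rho: float, cfg: StatsConfig | None = None) -> str:
    """Strength category of a correlation coefficient (total on |rho|)."""
    cfg = cfg or StatsConfig()
    if not np.isfinite(rho):
        return "undefined"
    r = abs(rho)
    for edge, label in zip(cfg.strength_bins, cfg.strength_labels):
        if r <= edge:
            return label
    return cfg.strength_labels[-1]


def spearman_matrix(
    table: pd.DataFrame,
    features_a: list[str],
    features_b: list[str],
    group_col: str = "group",
    cfg: StatsConfig | None = None,
) -> pd.DataFrame:
    """Per-group Spearman grid between two feature sets (long format).

    Pairwise deletion per cell; cells with fewer than the minimum number of
    complete pairs, or a constant feature, are marked undefined.
    """
    cfg = cfg or StatsConfig()
    rows = []
    for group, sub in table.groupby(group_col, sort=False):
        for fa in features_a:
            for fb in features_b:
                x = sub[fa].to_numpy(dtype=float)
                y = sub[fb].to_numpy(dtype=float)
                ok = np.isfinite(x) & np.isfinite(y)
                rho, p = float("nan"), float("nan")
                if ok.sum() >= cfg.min_pairs_corr and np.ptp(x[ok]) > 0 and np.ptp(y[ok]) > 0:
                    rho, p = stats.spearmanr(x[ok], y[ok])
                rows.append({
                    "group": group, "feature_a": fa, "feature_b": fb,
                    "rho": float(rho), "p_value": float(p),
                    "strength": strength_of(rho, cfg), "n": int(ok.sum()),
                })
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
# full report
# ----------------------------------------------------------------------

@dataclass
class GroupStatsReport:
    """Machine-readable group-comparison report."""

    omnibus: pd.DataFrame
    correlations: pd.DataFrame
    alpha: float
    group_labels: tuple[str, ...]

    def significant(self) -> pd.DataFrame:
        return self.omnibus[self.omnibus["p_adjusted"] < self.alpha]

    # -- lossless JSON round trip ------------------------------------
    def to_json(self, path=None) -> str:
        payload = {
            "alpha": self.alpha,
            "group_labels": list(self.group_labels),
            "omnibus": self.omnibus.to_dict(orient="list"),
            "omnibus_columns": list(self.omnibus.columns),
            "correlations": self.correlations.to_dict(orient="list"),
            "correlations_columns": list(self.correlations.columns),
        }
        text = json.dumps(payload, indent=2, sort_keys=True, allow_nan=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "GroupStatsReport":
        if hasattr(source, "read"):
            payload = json.load(source)
        else:
            try:
                payload = json.loads(source)
            except (json.JSONDecodeError, ValueError):
                with open(source) as fh:
                    payload = json.load(fh)
        return cls(
            omnibus=pd.DataFrame(payload["omnibus"])[payload["omnibus_columns"]],
            correlations=pd.DataFrame(payload["correlations"])[payload["correlations_columns"]],
            alpha=payload["alpha"],
            group_labels=tuple(payload["group_labels"]),
        )


def _pair_col(a: str, b: str) -> str:
    return f"p_{a}_{b}"


def run_group_analysis(
    table: pd.DataFrame,
    families: dict[str, list[str]],
    correlation_pairs: tuple[list[str], list[str]] | None = None,
    cfg: StatsConfig | None = None,
    group_col: str = "group",
) -> GroupStatsReport:
    """Per-family omnibus + BH + gated post hoc, plus the correlation grid.

    ``families`` maps a family name (clinical / IGA / PAM) to its feature
    columns; BH adjustment is applied within each family (as the results
    tables are reported), or globally when the config says so.
    """
    cfg = cfg or StatsConfig()
    group_labels = tuple(dict.fromkeys(table[group_col]))
    pair_names = list(itertools.combinations(group_labels, 2))

    results: list[tuple[str, OmnibusResult]] = []
    for family, features in families.items():
        if not features:
            log.info("family %s skipped: no features", family)
            continue
        for feature in features:
            if feature not in table.columns:
                log.warning("feature %s not in table; skipped", feature)
                continue
            groups = {
                g: table.loc[table[group_col] == g, feature].to_numpy(dtype=float)
                for g in group_labels
            }
            res = omnibus(feature, groups, cfg)
            if res is not None:
                results.append((family, res))

    # BH within family (or globally)
    if cfg.bh_scope == "global":
        scopes: dict[str, list[OmnibusResult]] = {"all": [r for _, r in results]}
    else:
        scopes = {}
        for family, res in results:
            scopes.setdefault(family, []).append(res)
    for members in scopes.values():
        adj = adjust_bh([r.p_value for r in members])
        for r, p in zip(members, adj):
            r.p_adjusted = float(p)

    # gated post hoc
    for _, res in results:
        if res.degenerate or not res.p_adjusted < cfg.alpha:
            continue
        groups = {
            g: table.loc[table[group_col] == g, res.feature].to_numpy(dtype=float)
            for g in group_labels
        }
        res.posthoc = posthoc(groups, parametric=res.test == "anova")

    rows = []
    for family, res in results:
        row = {
            "family": family,
            "feature": res.feature,
            "test": res.test,
            "statistic": res.statistic,
            "p_value": res.p_value,
            "p_adjusted": res.p_adjusted,
            "eta_squared": res.eta_squared,
            "degenerate": res.degenerate,
        }
        for a, b in pair_names:
            row[_pair_col(a, b)] = res.posthoc.get((a, b), float("nan"))
        rows.append(row)
    omnibus_df = pd.DataFrame(rows, columns=[
        "family", "feature", "test", "statistic", "p_value", "p_adjusted",
        "eta_squared", "degenerate", *[_pair_col(a, b) for a, b in pair_names],
    ])

    if correlation_pairs is not None:
        corr = spearman_matrix(table, *correlation_pairs, group_col=group_col, cfg=cfg)
    else:
        corr = pd.DataFrame(columns=["group", "feature_a", "feature_b",
                                     "rho", "p_value", "strength", "n"])
    return GroupStatsReport(omnibus=omnibus_df, correlations=corr,
                            alpha=cfg.alpha, group_labels=group_labels)
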