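"""Statistics on the sampled locations.

Three questions, matching how zone-based sampling schemes are evaluated:

* point-basis: how do the microbial indicators co-vary with the landscape
  attributes? (Pearson correlation table)
* cluster-basis: do the indicators differ among the delineated zones?
  (one-way ANOVA with Tukey-HSD pairwise comparisons and compact letters)
* site-basis: is the single BMU site a good stand-in for its zone's mean?
  (per-cluster one-sample t-test of the non-BMU members against the BMU
  value -- the BMU contributes one observation, so a two-sample test is
  not possible)

No multiple-testing correction is applied across indicators; alpha = 0.05
throughout unless overridden.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

DEFAULT_ALPHA = 0.05

#: landscape attribute columns, in reporting order
ATTRIBUTE_COLUMNS = (
    "elevation", "slope", "aspect", "plan_curvature", "emi_hh", "emi_vv",
)


def correlation_table(
    table: pd.DataFrame,
    attributes=ATTRIBUTE_COLUMNS,
    indicators=None,
    round_to: int | None = None,
) -> pd.DataFrame:
    """Pearson r for every (attribute x indicator) pair.

    Rows are attributes, columns indicators.  Cells involving a constant
    column are undefined and reported as NaN.  ``round_to=2`` reproduces
    report precision.
    """
    if len(table) < 3:
        raise ValueError("need at least 3 rows for correlations")
    if indicators is None:
        indicators = [c for c in table.columns if c not in attributes]
    out = pd.DataFrame(index=list(attributes), columns=list(indicators), dtype=float)
    for a in attributes:
        av = table[a].to_numpy(dtype=float)
        for ind in indicators:
            iv = table[ind].to_numpy(dtype=float)
            ok = np.isfinite(av) & np.isfinite(iv)
            if ok.sum() < 3 or av[ok].std() == 0 or iv[ok].std() == 0:
                out.loc[a, ind] = np.nan
                continue
            out.loc[a, ind] = sps.pearsonr(av[ok], iv[ok]).statistic
    return out.round(round_to) if round_to is not None else out


def _compact_letters(names, means, nonsig_pairs):
    """Compact letter display from the non-significant pair relation.

    Groups sharing a letter are not significantly different; letters are
    assigned to the maximal cliques of the non-significance graph, in
    descending order of the best mean each clique contains.
    """
    idx = list(range(len(names)))
    nonsig = set(nonsig_pairs) | {(j, i) for i, j in nonsig_pairs}
    cliques = []
    for size in range(len(idx), 0, -1):
        for sub in combinations(idx, size):
            if any(set(sub) <= set(c) for c in cliques):
                continue
            if all((a, b) in nonsig for a, b in combinations(sub, 2)):
                cliques.append(sub)
    cliques.sort(key=lambda c: -max(means[i] for i in c))
    letters = {i: "" for i in idx}
    for li, clique in enumerate(cliques):
        ch = chr(ord("a") + li)
        for i in clique:
            letters[i] += ch
    return {names[i]: letters[i] for i in idx}


@dataclass
class AnovaResult:
    indicator: str
    f_statistic: float
    p_value: float
    group_stats: pd.DataFrame  # cluster, n, mean, se
    pairwise: pd.DataFrame     # cluster_a, cluster_b, diff, p
    letters: dict
    alpha: float

    @property
    def significant(self) -> bool:
        return bool(np.isfinite(self.p_value) and self.p_value < self.alpha)


def anova_by_cluster(
    table: pd.DataFrame,
    indicator: str,
    cluster_col: str = "cluster",
    alpha: float = DEFAULT_ALPHA,
) -> AnovaResult:
    """One-way ANOVA of an indicator across clusters, with Tukey HSD.

    Records with a missing indicator value are dropped.  If every value is
    identical the F statistic is undefined and reported as NaN.
    """
    sub = table[[cluster_col, indicator]].dropna()
    ids = sorted(sub[cluster_col].unique())
    groups = [sub.loc[sub[cluster_col] == c, indicator].to_numpy(dtype=float) for c in ids]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >=2 clusters with >=2 members each")
    means = np.array([g.mean() for g in groups])
    gstats = pd.DataFrame({
        "cluster": ids,
        "n": [len(g) for g in groups],
        "mean": means,
        "se": [g.std(ddof=1) / np.sqrt(len(g)) for g in groups],
    })
    if np.ptp(np.concatenate(groups)) == 0:
        pw = pd.DataFrame(columns=["cluster_a", "cluster_b", "diff", "p"])
        letters = {c: "a" for c in ids}
        return AnovaResult(indicator, np.nan, np.nan, gstats, pw, letters, alpha)
    f, p = sps.f_oneway(*groups)
    tukey = sps.tukey_hsd(*groups)
    rows, nonsig = [], []
    for i, j in combinations(range(len(ids)), 2):
        pv = float(tukey.pvalue[i, j])
        rows.append({
            "cluster_a": ids[i], "cluster_b": ids[j],
            "diff": means[i] - means[j], "p": pv,
        })
        if pv >= alpha:
            nonsig.append((i, j))
    letters = _compact_letters(ids, means, nonsig)
    return AnovaResult(indicator, float(f), float(p), gstats,
                       pd.DataFrame(rows), letters, alpha)


def bmu_representativeness(
    table: pd.DataFrame,
    indicator: str,
    cluster_col: str = "cluster",
    role_col: str = "role",
    alpha: float = DEFAULT_ALPHA,
) -> pd.DataFrame:
    """Per cluster: one-sample t-test of non-BMU members vs the BMU value.

    The table must mark the BMU row of each cluster in ``role_col``
    (value ``"BMU"``, case-insensitive).  Returns one row per cluster with
    t, two-sided p, and a ``different`` flag at the given alpha; clusters
    whose members have zero variance are flagged undefined.
    """
    is_bmu = table[role_col].astype(str).str.upper() == "BMU"
    out = []
    for c in sorted(table[cluster_col].unique()):
        in_c = table[cluster_col] == c
        bmu_vals = table.loc[in_c & is_bmu, indicator]
        if len(bmu_vals) != 1:
            raise ValueError(f"cluster {c} must have exactly one BMU row")
        members = table.loc[in_c & ~is_bmu, indicator].dropna().to_numpy(dtype=float)
        if len(members) < 3:
            raise ValueError(f"cluster {c} needs >=3 non-BMU members")
        mu0 = float(bmu_vals.iloc[0])
        if members.std(ddof=1) == 0:
            out.append({"cluster": c, "bmu_value": mu0, "member_mean": members.mean(),
                        "t": np.nan, "p": np.nan, "different": None,
                        "note": "zero member variance; test undefined"})
            continue
        res = sps.ttest_1samp(members, popmean=mu0)
        out.append({"cluster": c, "bmu_value": mu0, "member_mean": members.mean(),
                    "t": float(res.statistic), "p": float(res.pvalue),
                    "different": bool(res.pvalue < alpha), "note": ""})
    return pd.DataFrame(out)


def cluster_ratio_summary(
    table: pd.DataFrame,
    indicator: str,
    cluster_col: str = "cluster",
    round_to: int | None = None,
) -> pd.DataFrame:
    """Matrix of cluster-mean ratios: entry (i, j) = mean_i / mean_j.

    Ratios against a zero mean are undefined (NaN).  ``round_to=2``
    matches report precision.
    """
    sub = table[[cluster_col, indicator]].dropna()
    ids = sorted(sub[cluster_col].unique())
    means = {c: sub.loc[sub[cluster_col] == c, indicator].mean() for c in ids}
    out = pd.DataFrame(index=ids, columns=ids, dtype=float)
    for i in ids:
        for j in ids:
            out.loc[i, j] = means[i] / means[j] if means[j] != 0 else np.nan
    return out.round(round_to) if round_to is not None else out
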