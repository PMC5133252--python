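"""Gene-usage frequencies and univariate statistics.

Frequencies are always computed over unique clonotypes (never raw reads)
per donor x subset, at the gene, family, or family-combination level
(VDJ triples for heavy chain, VJ pairs for light chains). Comparisons
between subsets use two-way ANOVA with per-key post-hoc contrasts
(Holm-Sidak adjusted), paired Wilcoxon / Mann-Whitney tests, and a
Gaussian random-intercept mixed model (donor as random effect) with a
likelihood-ratio test for the subset fixed effect.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests

from .types import Clonotype, SUBSETS, parse_gene_name

logger = logging.getLogger(__name__)

__all__ = [
    "UsageTable",
    "ComparisonResult",
    "usage_frequencies",
    "combination_tensor",
    "compare_usage",
    "mixed_model_lrt",
]


@dataclass
class UsageTable:
    """Donor x subset x key frequency table (percent of clonotypes).

    ``data`` is tidy with columns donor_id, subset, key, frequency;
    for every donor x subset cell the frequencies sum to 100 and the
    clonotype denominator is recorded.
    """

    axis: str  # gene | family | family_combination
    chain: str
    data: pd.DataFrame
    denominators: dict[tuple[str, str], int] = field(default_factory=dict)

    @property
    def keys(self) -> list[str]:
        return sorted(self.data["key"].unique())

    def wide(self) -> pd.DataFrame:
        """(donor, subset) x key matrix with absent keys at 0."""
        return (
            self.data.pivot_table(
                index=["donor_id", "subset"], columns="key",
                values="frequency", fill_value=0.0,
            )
            .sort_index()
        )

    def subset_means(self) -> pd.DataFrame:
        """Across-donor mean frequency per subset x key (for bubble plots)."""
        return (
            self.data.groupby(["subset", "key"], observed=True)["frequency"]
            .mean().unstack(fill_value=0.0)
        )


@dataclass
class ComparisonResult:
    key: str
    groups: tuple[str, ...]
    statistic: float
    raw_p: float
    adjusted_p: float
    method: str
    effect: float  # mean(group2) - mean(group1), percentage points
    note: str = ""


def _axis_key(cl: Clonotype, axis: str, chain: str) -> str:
    v = parse_gene_name(cl.v_call)
    if axis == "gene":
        return v.gene_label
    if axis == "family":
        return v.family_label
    if axis == "family_combination":
        j = parse_gene_name(cl.j_call)
        if chain == "IGH":
            d = parse_gene_name(cl.d_call) if cl.d_call else None
            dfam = f"D{d.family}" if d else "D?"
            return f"V{v.family}-{dfam}-J{j.family}"
        return f"V{v.family}-J{j.family}"
    raise ValueError(f"unknown axis {axis!r}")


def usage_frequencies(
    clonotypes: Iterable[Clonotype],
    axis: str = "family",
    chain: str = "IGH",
    segment: str = "V",
) -> UsageTable:
    """Percent usage per donor x subset.

    ``axis='gene'``/``'family'`` tabulates the segment given by
    ``segment`` ('V', 'D' or 'J'); ``axis='family_combination'`` tabulates
    VDJ (heavy) or VJ (light) family triples/pairs. Every observed key is
    present in every donor x subset cell (0 when absent); donor x subset
    cells with zero clonotypes are excluded and logged.
    """
    counts: dict[tuple[str, str], dict[str, int]] = {}
    for cl in clonotypes:
        if cl.chain != chain:
            continue
        if axis == "family_combination":
            key = _axis_key(cl, axis, chain)
        else:
            call = {"V": cl.v_call, "D": cl.d_call, "J": cl.j_call}[segment]
            if not call:
                continue
            g = parse_gene_name(call)
            key = g.gene_label if axis == "gene" else g.family_label
        cell = (cl.donor_id, cl.subset)
        counts.setdefault(cell, {})
        counts[cell][key] = counts[cell].get(key, 0) + 1

    all_keys = sorted({k for cell in counts.values() for k in cell})
    rows = []
    denominators = {}
    for cell in sorted(counts):
        total = sum(counts[cell].values())
        if total == 0:
            logger.info("excluding empty donor x subset cell %s", cell)
            continue
        denominators[cell] = total
        for key in all_keys:
            rows.append(
                {
                    "donor_id": cell[0],
                    "subset": cell[1],
                    "key": key,
                    "frequency": 100.0 * counts[cell].get(key, 0) / total,
                }
            )
    return UsageTable(
        axis=axis if axis != "gene" else "gene",
        chain=chain,
        data=pd.DataFrame(rows, columns=["donor_id", "subset", "key", "frequency"]),
        denominators=denominators,
    )


def combination_tensor(clonotypes: Iterable[Clonotype], chain: str = "IGH") -> UsageTable:
    """VDJ (heavy) or VJ (light) family-combination frequencies."""
    return usage_frequencies(clonotypes, axis="family_combination", chain=chain)


def _adjust(pvals: Sequence[float], method: str) -> np.ndarray:
    if not len(pvals):
        return np.array([])
    method_map = {"holm-sidak": "holm-sidak", "bh": "fdr_bh", "holm": "holm"}
    return multipletests(pvals, method=method_map[method])[1]


def compare_usage(
    table: UsageTable,
    subsets: Sequence[str] | None = None,
    method: str = "anova",
    adjust: str = "holm-sidak",
    paired: bool | None = None,
) -> list[ComparisonResult]:
    """Per-key subset comparisons on per-donor frequencies.

    ``method='anova'`` fits the two-way layout (subset x key) and reports
    per-key pairwise subset contrasts (t tests on donor frequencies),
    adjusted across all key x pair hypotheses; ``'wilcoxon'`` /
    ``'mannwhitney'`` run the corresponding rank tests per key and pair.
    With ``paired=None`` the paired test is used whenever both subsets
    cover the same donors (bone-marrow and blood subsets come from the
    same donors in this design).
    """
    subsets = [s for s in (subsets or SUBSETS) if s in set(table.data["subset"])]
    wide = table.wide()
    results: list[ComparisonResult] = []
    raw_ps: list[float] = []
    for key in wide.columns:
        series = wide[key]
        for s1, s2 in itertools.combinations(subsets, 2):
            x = series.xs(s1, level="subset")
            y = series.xs(s2, level="subset")
            note = ""
            if len(x) < 2 or len(y) < 2:
                note = "insufficient_replication"
            use_paired = paired
            common = x.index.intersection(y.index)
            if use_paired is None:
                use_paired = len(common) == len(x) == len(y) and len(common) > 1
            xv, yv = x.to_numpy(float), y.to_numpy(float)
            effect = float(np.mean(yv) - np.mean(xv))
            stat, p = _pair_test(xv, yv, x, y, common, method, use_paired)
            results.append(
                ComparisonResult(
                    key=key, groups=(s1, s2), statistic=stat, raw_p=p,
                    adjusted_p=p, method=method, effect=effect, note=note,
                )
            )
            raw_ps.append(p)
    adj = _adjust(raw_ps, adjust)
    for r, ap in zip(results, adj):
        r.adjusted_p = float(max(ap, r.raw_p))
    return results


def _pair_test(xv, yv, x, y, common, method: str, use_paired: bool):
    if method == "anova":
        if use_paired and len(common) > 1:
            d = (y.loc[common] - x.loc[common]).to_numpy(float)
            if np.allclose(d, 0) and np.ptp(d) == 0:
                return 0.0, 1.0
            res = stats.ttest_1samp(d, 0.0)
        else:
            if np.ptp(np.concatenate([xv, yv])) == 0:
                return 0.0, 1.0
            res = stats.ttest_ind(xv, yv)
        stat, p = float(res.statistic), float(res.pvalue)
    elif method == "wilcoxon" and use_paired and len(common) > 1:
        d = (y.loc[common] - x.loc[common]).to_numpy(float)
        if np.allclose(d, 0):
            return 0.0, 1.0
        res = stats.wilcoxon(d)
        stat, p = float(res.statistic), float(res.pvalue)
    else:  # mannwhitney, or wilcoxon without shared donors
        if np.ptp(np.concatenate([xv, yv])) == 0:
            return 0.0, 1.0
        res = stats.mannwhitneyu(xv, yv, alternative="two-sided")
        stat, p = float(res.statistic), float(res.pvalue)
    if np.isnan(p):
        stat, p = 0.0, 1.0
    return stat, p


def usage_anova(table: UsageTable, subsets: Sequence[str] | None = None) -> pd.DataFrame:
    """Global two-way ANOVA (subset x key) on per-donor frequencies."""
    df = table.data.copy()
    if subsets:
        df = df[df["subset"].isin(subsets)]
    model = smf.ols("frequency ~ C(subset) * C(key)", data=df).fit()
    return sm.stats.anova_lm(model, typ=2)


def random_intercept_loglik(
    y: np.ndarray, X: np.ndarray, groups: np.ndarray,
    beta: np.ndarray, sigma2_b: float, sigma2_e: float,
) -> float:
    """Exact Gaussian log-likelihood of a random-intercept model.

    Marginal covariance within group g is sigma2_e I + sigma2_b J; the
    determinant and quadratic form have closed forms via Woodbury. Used
    both by the grid/optimizer oracle in tests and as a convergence check.
    """
    ll = 0.0
    resid = y - X @ beta
    for g in np.unique(groups):
        r = resid[groups == g]
        n = len(r)
        denom = sigma2_e + n * sigma2_b
        logdet = (n - 1) * np.log(sigma2_e) + np.log(denom)
        quad = (r @ r) / sigma2_e - sigma2_b * r.sum() ** 2 / (sigma2_e * denom)
        ll += -0.5 * (n * np.log(2 * np.pi) + logdet + quad)
    return float(ll)


def mixed_model_lrt(
    properties: pd.DataFrame,
    property_name: str,
    subsets: Sequence[str] | None = None,
    donor_col: str = "donor_id",
    subset_col: str = "subset",
) -> ComparisonResult:
    """Likelihood-ratio test for a subset effect on one CDR3 property.

    Fits the Gaussian random-intercept models ``property ~ subset +
    (1|donor)`` (full) and ``property ~ 1 + (1|donor)`` (null) by maximum
    likelihood and compares 2 * (llf_full - llf_null) to chi-square with
    (number of subsets - 1) degrees of freedom. ML (not REML) is used
    because the LRT compares fixed-effect structures.
    """
    df = properties[[donor_col, subset_col, property_name]].dropna().copy()
    if subsets:
        df = df[df[subset_col].isin(subsets)]
    # order by developmental stage so `effect` reads naive-vs-preB etc.
    order = {s: i for i, s in enumerate(SUBSETS)}
    present = sorted(df[subset_col].unique(),
                     key=lambda s: (order.get(s, len(order)), s))
    if len(present) < 2:
        raise ValueError("need at least 2 subsets")
    if df[donor_col].nunique() < 3:
        raise ValueError("need at least 3 donors")
    y = df[property_name].to_numpy(float)
    if np.ptp(y) == 0:
        return ComparisonResult(
            key=property_name, groups=tuple(present), statistic=0.0,
            raw_p=1.0, adjusted_p=1.0, method="mixed_lrt", effect=0.0,
            note="zero_variance",
        )
    df = df.rename(columns={property_name: "y"})
    note = ""

    def _fit(formula):
        model = smf.mixedlm(formula, df, groups=df[donor_col])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(reml=False)
            if not np.isfinite(res.llf):
                res = model.fit(reml=False, method="powell")
        return res

    full = _fit(f"y ~ C({subset_col})")
    null = _fit("y ~ 1")
    if not (full.converged and null.converged and np.isfinite(full.llf)
            and np.isfinite(null.llf)):
        note = "non_convergence"
    lrt = max(0.0, 2.0 * (full.llf - null.llf))
    dof = len(present) - 1
    p = float(stats.chi2.sf(lrt, dof))
    means = df.groupby(subset_col)["y"].mean()
    effect = float(means.loc[present[-1]] - means.loc[present[0]])
    return ComparisonResult(
        key=property_name, groups=tuple(present), statistic=float(lrt),
        raw_p=p, adjusted_p=p, method="mixed_lrt", effect=effect, note=note,
    )
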