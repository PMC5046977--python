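"""Validation statistics: age-adjusted regression, one-tailed rank tests,
ROC/AUC with confidence intervals, age matching, and the binomial comparison
of per-type significance counts.

These are the tests used to check that a clock behaves like a mitotic
clock: association of the score with division-count estimates after
removing the trivial age effect, elevation of the score in tumors or
lesions relative to (age-matched) normals, discrimination of lesion status
by ROC, and a sign test comparing how often two scores reach per-cancer-type
correlation significance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import InputError
from .io import SampleSheet


@dataclass(frozen=True)
class RegressionReport:
    coefficient: float
    std_error: float
    t: float
    p_two_sided: float
    p_one_sided: float
    r_squared: float
    n: int


@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float
    p_value: float
    method: str                      # "exact" or "normal"
    p_value_unadjusted: float | None = None   # set when age adjustment applied


@dataclass(frozen=True)
class ROCReport:
    auc: float
    ci_low: float
    ci_high: float
    n_pos: int
    n_neg: int
    method: str = "delong"


def age_adjusted_association(y, x, age, hypothesized_sign: int = 1) -> RegressionReport:
    """OLS of y on x and age; the report is for the x coefficient.

    ``p_one_sided`` is ``p_two_sided/2`` when the fitted coefficient has the
    hypothesized sign (default positive), else ``1 - p_two_sided/2``.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    age = np.asarray(age, dtype=float)
    ok = ~(np.isnan(y) | np.isnan(x) | np.isnan(age))
    y, x, age = y[ok], x[ok], age[ok]
    n = y.size
    if n < 4:
        raise InputError("need at least 4 complete (y, x, age) triples")
    if np.std(x) > 0 and np.std(age) > 0:
        r = float(np.corrcoef(x, age)[0, 1])
        if abs(r) > 0.999:
            raise InputError(f"x is collinear with age (|r|={abs(r):.4f})")
    X = np.column_stack([np.ones(n), x, age])
    import statsmodels.api as sm

    fit = sm.OLS(y, X).fit()
    coef = float(fit.params[1])
    p2 = float(fit.pvalues[1])
    p1 = p2 / 2.0 if np.sign(coef) == np.sign(hypothesized_sign) else 1.0 - p2 / 2.0
    return RegressionReport(
        coefficient=coef,
        std_error=float(fit.bse[1]),
        t=float(fit.tvalues[1]),
        p_two_sided=p2,
        p_one_sided=p1,
        r_squared=float(fit.rsquared),
        n=n,
    )


def _age_residualize(values: np.ndarray, age: np.ndarray) -> np.ndarray:
    X = np.column_stack([np.ones_like(age), age])
    coef, *_ = np.linalg.lstsq(X, values, rcond=None)
    return values - X @ coef


def one_tailed_wilcoxon(
    group_a,
    group_b,
    paired: bool = False,
    alternative: str = "greater",
    age: tuple | None = None,
    pair_ids: tuple | None = None,
) -> WilcoxonResult:
    """One-tailed rank test of group_a against group_b.

    ``alternative="greater"`` tests whether group_a values are larger than
    group_b's. Unpaired data use the Wilcoxon rank-sum (Mann-Whitney) test,
    exact when the pooled sample is <= 20 without ties, otherwise the normal
    approximation with tie correction. ``paired=True`` uses the Wilcoxon
    signed-rank test on the within-pair differences (the paired analogue of
    the rank-sum test), exact under the same smallness/no-ties condition.

    ``age``: optional (ages_a, ages_b); both groups are then replaced by
    residuals from a pooled OLS of value on age before ranking, and the
    unadjusted p-value is reported alongside. ``pair_ids``: optional
    (ids_a, ids_b) for paired data; unmatched IDs raise an error listing the
    orphans, and group_b is reordered to group_a's pairing.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if alternative not in ("greater", "less"):
        raise InputError("alternative must be 'greater' or 'less'")
    if a.size == 0 or b.size == 0:
        raise InputError("both groups must be non-empty")
    if paired:
        if pair_ids is not None:
            ids_a, ids_b = (list(pair_ids[0]), list(pair_ids[1]))
            orphans = sorted(set(ids_a) ^ set(ids_b))
            if orphans:
                raise InputError(f"unmatched pair IDs: {orphans}")
            order = [ids_b.index(i) for i in ids_a]
            b = b[order]
        if a.size != b.size:
            raise InputError("paired groups must have equal lengths")

    unadjusted: float | None = None
    if age is not None:
        age_a = np.asarray(age[0], dtype=float)
        age_b = np.asarray(age[1], dtype=float)
        unadjusted = one_tailed_wilcoxon(a, b, paired=paired, alternative=alternative).p_value
        pooled = np.concatenate([a, b])
        resid = _age_residualize(pooled, np.concatenate([age_a, age_b]))
        a, b = resid[: a.size], resid[a.size :]

    if paired:
        d = a - b
        no_zeros = np.all(d != 0)
        no_ties = np.unique(np.abs(d)).size == d.size
        exact = d.size <= 20 and no_zeros and no_ties
        res = stats.wilcoxon(
            a, b, alternative=alternative, method="exact" if exact else "approx"
        )
        method = "exact" if exact else "normal"
    else:
        pooled = np.concatenate([a, b])
        no_ties = np.unique(pooled).size == pooled.size
        exact = pooled.size <= 20 and no_ties
        res = stats.mannwhitneyu(
            a, b, alternative=alternative, method="exact" if exact else "asymptotic"
        )
        method = "exact" if exact else "normal"
    return WilcoxonResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        method=method,
        p_value_unadjusted=unadjusted,
    )


def _delong_variance(pos: np.ndarray, neg: np.ndarray) -> tuple[float, float]:
    """AUC and its DeLong variance via midrank structural components."""
    m, n = pos.size, neg.size
    allv = np.concatenate([pos, neg])
    r_all = stats.rankdata(allv)
    r_pos = stats.rankdata(pos)
    r_neg = stats.rankdata(neg)
    auc = (r_all[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (r_all[:m] - r_pos) / n
    v01 = 1.0 - (r_all[m:] - r_neg) / m
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return float(auc), float(s10 / m + s01 / n)


def roc_auc(
    scores,
    labels,
    ci_method: str = "delong",
    seed: int = 0,
    n_boot: int = 2000,
    alpha: float = 0.05,
) -> ROCReport:
    """AUC (Mann-Whitney probability, ties 0.5) with a 95% CI.

    ``labels`` are binary (1 = positive class). The default DeLong CI is
    deterministic; ``ci_method="bootstrap"`` stratified-resamples both
    classes ``n_boot`` times with the given seed and takes percentile
    bounds. CIs are clipped to [0, 1] and widened to contain the AUC.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if pos.size == 0 or neg.size == 0:
        raise InputError("both classes must be present")
    auc, var = _delong_variance(pos, neg)
    if ci_method == "delong":
        z = stats.norm.ppf(1 - alpha / 2)
        half = z * np.sqrt(max(var, 0.0))
        lo, hi = auc - half, auc + half
    elif ci_method == "bootstrap":
        rng = np.random.default_rng(seed)
        boots = np.empty(n_boot)
        for i in range(n_boot):
            bp = rng.choice(pos, pos.size, replace=True)
            bn = rng.choice(neg, neg.size, replace=True)
            boots[i], _ = _delong_variance(bp, bn)
        lo, hi = np.quantile(boots, [alpha / 2, 1 - alpha / 2])
    else:
        raise InputError("ci_method must be 'delong' or 'bootstrap'")
    lo = min(max(float(lo), 0.0), auc)
    hi = max(min(float(hi), 1.0), auc)
    return ROCReport(
        auc=auc, ci_low=lo, ci_high=hi, n_pos=pos.size, n_neg=neg.size, method=ci_method
    )


def age_match_pairs(
    pheno: SampleSheet,
    group_a: str,
    group_b: str,
    tolerance: float = 5.0,
    group_column: str = "group",
) -> list[tuple[str, str]]:
    """Greedy nearest-age matching of group_a to group_b samples.

    Candidate pairs within ``tolerance`` years are taken smallest age gap
    first, ties broken by sample ID order (group_a's ID, then group_b's),
    each sample used at most once. Deterministic; an empty result is valid.
    """
    groups = pheno.column(group_column)
    ages = pheno.age
    a_ids = [s for s in pheno.sample_ids if groups.loc[s] == group_a and pd.notna(ages.loc[s])]
    b_ids = [s for s in pheno.sample_ids if groups.loc[s] == group_b and pd.notna(ages.loc[s])]
    candidates = sorted(
        (
            (abs(ages.loc[ia] - ages.loc[ib]), str(ia), str(ib))
            for ia in a_ids
            for ib in b_ids
            if abs(ages.loc[ia] - ages.loc[ib]) <= tolerance
        ),
    )
    used_a: set[str] = set()
    used_b: set[str] = set()
    pairs: list[tuple[str, str]] = []
    for _, ia, ib in candidates:
        if ia in used_a or ib in used_b:
            continue
        pairs.append((ia, ib))
        used_a.add(ia)
        used_b.add(ib)
    return pairs


def compare_significance_counts(sig_a, sig_b) -> float:
    """One-sided sign test that score A reaches significance in more types.

    Discordant types (significant for A only vs B only) are compared under
    Binomial(n_discordant, 1/2); the p-value is the upper tail toward A.
    With no discordant types p = 1.
    """
    a = np.asarray(sig_a, dtype=bool)
    b = np.asarray(sig_b, dtype=bool)
    if a.shape != b.shape:
        raise InputError("significance vectors must have equal length")
    n_a_only = int(np.sum(a & ~b))
    n_disc = n_a_only + int(np.sum(~a & b))
    if n_disc == 0:
        return 1.0
    return float(stats.binomtest(n_a_only, n_disc, 0.5, alternative="greater").pvalue)
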