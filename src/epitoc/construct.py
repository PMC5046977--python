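"""Mitotic-clock CpG selection: age EWAS, FDR control and the filter cascade.

The selection pipeline regresses each probe's beta values on chronological
age (with plate/sex and cell-fraction covariates), controls the false
discovery rate by Benjamini-Hochberg, and then filters the age-associated
probes down to the clock sets:

* hyper ("pcgtAge"-style) set: positive age coefficient, TSS200 promoter
  probe, fetal ground-state beta strictly below 0.2 in every fetal sample,
  and PRC2/Polycomb-marked promoter;
* hypo ("hypoAge"-style) set: negative age coefficient, TSS200 probe, fetal
  beta at least 0.3 in every fetal sample.

Filters are conjunctive, so clock membership does not depend on cascade
order; the audit counts (how many probes each filter removed) do.

Regression direction: methylation beta is the response, age the predictor,
so the age coefficient is interpretable as methylation drift per year.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .deconv import CellFractions
from .exceptions import InputError, RangeError, ValidationError
from .io import BetaMatrix, ClockDefinition, ProbeAnnotation, SampleSheet


@dataclass(frozen=True)
class SelectionParams:
    """Thresholds of the clock-selection cascade.

    ``fetal_hyper_bound`` is a strict upper bound (a probe whose fetal beta
    equals the bound in any fetal sample is excluded from the hyper set);
    ``fetal_hypo_bound`` is an inclusive lower bound.
    """

    fdr_threshold: float = 0.05
    fetal_hyper_bound: float = 0.2
    fetal_hypo_bound: float = 0.3
    require_tss200: bool = True
    require_prc2_for_hyper: bool = True

    def __post_init__(self) -> None:
        for name in ("fdr_threshold", "fetal_hyper_bound", "fetal_hypo_bound"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValidationError(f"{name} must lie in (0,1), got {v}")


def apply_bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-preserving in the input."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.isnan(p).any():
        raise RangeError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _build_design(
    pheno: SampleSheet,
    covariates: tuple[str, ...],
    cell_fractions: CellFractions | None,
) -> pd.DataFrame:
    """Intercept + age + covariate contrasts (+ cell fractions, one dropped)."""
    cols: dict[str, pd.Series] = {"intercept": pd.Series(1.0, index=pheno.sample_ids)}
    cols["age"] = pheno.age.astype(float)
    design = pd.DataFrame(cols)
    for cov in covariates:
        col = pheno.column(cov)
        if pd.api.types.is_numeric_dtype(col):
            design[cov] = col.astype(float)
        else:
            dummies = pd.get_dummies(col.astype(str), prefix=cov, drop_first=True)
            design = design.join(dummies.astype(float))
    if cell_fractions is not None:
        # Fractions sum to one, so one cell type is dropped to keep the
        # design full rank alongside the intercept.
        fr = cell_fractions.weights.iloc[:, :-1]
        fr = fr.reindex(design.index)
        design = design.join(fr.astype(float))
    return design


def _check_collinear(design: pd.DataFrame) -> None:
    X = design.drop(columns="intercept")
    if X.shape[1] < 2:
        return
    corr = X.corr().to_numpy()
    names = X.columns
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            if abs(corr[i, j]) > 0.9999:
                raise InputError(
                    f"collinear covariates: {names[i]!r} and {names[j]!r}"
                )


def _ols_block(Y: np.ndarray, X: np.ndarray, age_col: int):
    """Per-row OLS of Y rows on shared design X; returns (coef, se, t, p) for age.

    Y is probes x samples (no NaN), X is samples x k.
    """
    n, k = X.shape
    XtX_inv = np.linalg.pinv(X.T @ X)
    H = XtX_inv @ X.T                      # k x n
    coefs = Y @ H.T                        # probes x k
    resid = Y - coefs @ X.T
    dof = n - k
    sigma2 = (resid**2).sum(axis=1) / dof
    se = np.sqrt(np.maximum(sigma2, 0.0) * XtX_inv[age_col, age_col])
    b = coefs[:, age_col]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, b / se, np.inf * np.sign(b))
    p = 2.0 * stats.t.sf(np.abs(t), dof)
    return b, se, t, p


def run_ewas(
    beta: BetaMatrix,
    pheno: SampleSheet,
    covariates: tuple[str, ...] = (),
    cell_fractions: CellFractions | None = None,
) -> pd.DataFrame:
    """Per-probe OLS of beta on age plus covariates.

    Returns a DataFrame indexed by probe with columns ``age_coefficient``,
    ``std_error``, ``t_statistic``, ``p_value``, ``q_value`` (BH over all
    tested probes), ``n_obs`` and ``skipped`` (reason, empty if tested).
    Probes with too few complete observations or constant beta are skipped
    and flagged, with NaN statistics.
    """
    design = _build_design(pheno, tuple(covariates), cell_fractions)
    design = design.loc[beta.sample_ids.intersection(design.index)]
    design = design.dropna(axis=0)
    k = design.shape[1]
    # design has intercept + age + the extra covariates; the sample floor is
    # (number of extra covariates) + 3, i.e. one residual dof beyond the fit
    if design.shape[0] < k + 1:
        raise InputError(
            f"need at least {k + 1} samples with complete covariate data, "
            f"have {design.shape[0]}"
        )
    _check_collinear(design)
    X = design.to_numpy(dtype=float)
    age_col = int(design.columns.get_loc("age"))
    Y = beta.values.loc[:, design.index].to_numpy(dtype=float)
    min_obs = k + 1

    out = pd.DataFrame(
        {
            "age_coefficient": np.nan,
            "std_error": np.nan,
            "t_statistic": np.nan,
            "p_value": np.nan,
            "q_value": np.nan,
            "n_obs": 0,
            "skipped": "",
        },
        index=beta.probe_ids,
    )

    complete = ~np.isnan(Y).any(axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # all-NaN rows
        constant = np.nanmax(Y, axis=1) == np.nanmin(Y, axis=1)
    out.loc[beta.probe_ids[constant], "skipped"] = "constant"

    full = complete & ~constant
    if full.any():
        b, se, t, p = _ols_block(Y[full], X, age_col)
        out.loc[beta.probe_ids[full], "age_coefficient"] = b
        out.loc[beta.probe_ids[full], "std_error"] = se
        out.loc[beta.probe_ids[full], "t_statistic"] = t
        out.loc[beta.probe_ids[full], "p_value"] = p
        out.loc[beta.probe_ids[full], "n_obs"] = X.shape[0]

    # Probes with missing cells: per-probe complete-case fit.
    for i in np.flatnonzero(~complete & ~constant):
        y = Y[i]
        obs = ~np.isnan(y)
        probe = beta.probe_ids[i]
        if obs.sum() < min_obs:
            out.loc[probe, "skipped"] = "too_few_obs"
            continue
        if np.ptp(y[obs]) == 0:
            out.loc[probe, "skipped"] = "constant"
            continue
        b, se, t, p = _ols_block(y[obs][None, :], X[obs], age_col)
        out.loc[probe, ["age_coefficient", "std_error", "t_statistic", "p_value"]] = [
            b[0], se[0], t[0], p[0],
        ]
        out.loc[probe, "n_obs"] = int(obs.sum())

    tested = out["p_value"].notna()
    if tested.any():
        out.loc[tested, "q_value"] = apply_bh_fdr(out.loc[tested, "p_value"].to_numpy())
    return out


def select_clock_cpgs(
    ewas: pd.DataFrame,
    annot: ProbeAnnotation,
    fetal_beta: BetaMatrix,
    params: SelectionParams = SelectionParams(),
) -> tuple[ClockDefinition | None, ClockDefinition | None, dict]:
    """Run the filter cascade; returns (hyper clock, hypo clock, audit).

    A clock is ``None`` when its final set is empty (with an audit entry).
    The audit maps filter names to the number of candidate probes removed at
    that step, in cascade order, separately for the hyper and hypo branches.
    """
    audit: dict[str, dict[str, int]] = {"hyper": {}, "hypo": {}}
    tested = ewas[ewas["p_value"].notna()]

    sig = tested[tested["q_value"] < params.fdr_threshold]
    n_sig = len(sig)

    ann = annot.data.reindex(sig.index)
    fetal = fetal_beta.values

    def _branch(direction: str) -> set[str]:
        a = audit[direction]
        a["fdr"] = len(tested) - n_sig
        if direction == "hyper":
            cand = sig.index[sig["age_coefficient"] > 0]
        else:
            cand = sig.index[sig["age_coefficient"] < 0]
        a["direction"] = n_sig - len(cand)
        if params.require_tss200:
            keep = ann.loc[cand, "tss200"].fillna(False).astype(bool)
            a["tss200"] = int((~keep).sum())
            cand = cand[keep.to_numpy()]
        # fetal ground-state filter; probes absent or missing in the fetal
        # matrix are excluded and audited separately
        in_fetal = fetal.reindex(cand)
        no_missing = ~in_fetal.isna().any(axis=1)
        a["fetal_missing"] = int((~no_missing).sum())
        cand = cand[no_missing.to_numpy()]
        fvals = fetal.loc[cand]
        if direction == "hyper":
            keep = (fvals < params.fetal_hyper_bound).all(axis=1)
        else:
            keep = (fvals >= params.fetal_hypo_bound).all(axis=1)
        a["fetal_ground_state"] = int((~keep).sum())
        cand = cand[keep.to_numpy()]
        if direction == "hyper" and params.require_prc2_for_hyper:
            keep = ann.loc[cand, "prc2"].fillna(False).astype(bool)
            a["prc2"] = int((~keep).sum())
            cand = cand[keep.to_numpy()]
        a["selected"] = len(cand)
        return set(cand)

    hyper_ids = _branch("hyper")
    hypo_ids = _branch("hypo")
    audit["n_tested"] = len(tested)
    audit["n_significant"] = n_sig

    hyper = (
        ClockDefinition("hyper", "hyper", frozenset(hyper_ids), params.fetal_hyper_bound)
        if hyper_ids
        else None
    )
    hypo = (
        ClockDefinition("hypo", "hypo", frozenset(hypo_ids), params.fetal_hypo_bound)
        if hypo_ids
        else None
    )
    return hyper, hypo, audit
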