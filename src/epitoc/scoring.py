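"""Clock scoring, per-tissue calibration, and stem-cell-division estimates.

The replication-error model behind these operations: methylation errors
accumulate linearly with the total number of divisions each stem cell has
incurred,

    TNSC(s, t) = A(s) * [IR(t) + E(s) * ER(t)]

with A the chronological age, IR the tissue's intrinsic stem-cell division
rate (divisions per stem cell per year), and E/ER an exposure level and the
extrinsic division rate it induces. The clock score (mean beta over the
clock CpGs) is linear in TNSC, so in healthy samples of one tissue it is
linear in age:

    score = alpha' + gamma' * A + noise

and fitting (alpha', gamma') in healthy samples lets the score be inverted
to a division estimate for a non-healthy sample of the same tissue:

    TNSC = (score - alpha') * IR / gamma'

The score ratio (score1 - alpha')/(score2 - alpha') equals the TNSC ratio
and needs no IR estimate.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .exceptions import InputError, ValidationError
from .io import BetaMatrix, ClockDefinition, SampleSheet

#: Intrinsic stem-cell division rates, divisions per stem cell per year,
#: from published estimates for normal tissues.
TISSUE_RATES: dict[str, float] = {
    "colon": 73.0,
    "rectum": 73.0,
    "esophagus": 17.4,
    "head-and-neck": 21.5,
    "liver": 0.9125,
    "lung": 0.07,
    "pancreas": 1.0,
    "thyroid": 0.087,
}


@dataclass(frozen=True)
class Calibration:
    """Per-tissue linear calibration of the clock score against age."""

    tissue: str
    alpha_prime: float
    gamma_prime: float
    ir: float | None = None
    n_fit: int | None = None
    r_squared: float | None = None

    def __post_init__(self) -> None:
        if self.ir is not None and self.ir <= 0:
            raise ValidationError("ir must be positive where present")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "Calibration":
        with open(path) as fh:
            return cls(**json.load(fh))


#: Calibrations published for the original clock: whole blood (training
#: cohort), TCGA normal breast, TCGA normal lung. Users may override.
SHIPPED_CALIBRATIONS: dict[str, Calibration] = {
    "whole-blood": Calibration("whole-blood", 0.052, 0.000345),
    "breast-normal": Calibration("breast-normal", 0.053, 0.000165),
    "lung-normal": Calibration("lung-normal", 0.021, 0.000588, ir=TISSUE_RATES["lung"]),
}


def compute_clock_score(
    beta: BetaMatrix, clock: ClockDefinition, min_coverage: float = 0.95
) -> pd.DataFrame:
    """Per-sample clock score: mean of non-missing betas over the clock CpGs.

    Returns a DataFrame indexed by sample with columns ``score``,
    ``n_probes_used``, ``coverage`` and ``flagged``. Samples whose clock-CpG
    coverage falls below ``min_coverage`` are flagged and given no score —
    scores are only comparable across samples when probe support matches.
    """
    present = beta.probe_ids.intersection(clock.probe_ids)
    if len(present) == 0:
        raise InputError(f"no probes of clock {clock.name!r} found in the beta matrix")
    sub = beta.values.loc[present]
    n_used = sub.notna().sum(axis=0)
    coverage = n_used / len(clock.probe_ids)
    score = sub.mean(axis=0, skipna=True)
    flagged = coverage < min_coverage
    score = score.where(~flagged)
    return pd.DataFrame(
        {
            "score": score,
            "n_probes_used": n_used.astype(int),
            "coverage": coverage,
            "flagged": flagged,
        }
    )


def calibrate_clock(
    scores: pd.DataFrame | pd.Series,
    pheno: SampleSheet,
    tissue: str,
    ir: float | None = None,
) -> Calibration:
    """OLS fit of score on age in healthy samples of one tissue.

    ``scores`` is the output of :func:`compute_clock_score` (or a plain
    Series of scores indexed by sample). A negative fitted slope is allowed
    but flagged with a warning: the inversion to division counts is then
    invalid.
    """
    s = scores["score"] if isinstance(scores, pd.DataFrame) else scores
    common = s.dropna().index.intersection(pheno.age.dropna().index)
    if len(common) < 3:
        raise InputError("need at least 3 scored samples with ages")
    y = s.loc[common].to_numpy(dtype=float)
    a = pheno.age.loc[common].to_numpy(dtype=float)
    if np.ptp(a) == 0:
        raise InputError("all ages identical: slope unidentifiable")
    X = np.column_stack([np.ones_like(a), a])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ coef
    ss_res = float(((y - fitted) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    if coef[1] <= 0:
        warnings.warn(
            f"fitted slope gamma'={coef[1]:.3g} is not positive; "
            "division-count inversion is invalid for this calibration",
            stacklevel=2,
        )
    return Calibration(
        tissue=tissue,
        alpha_prime=float(coef[0]),
        gamma_prime=float(coef[1]),
        ir=ir,
        n_fit=len(common),
        r_squared=r2,
    )


def estimate_tnsc(score, calib: Calibration):
    """Invert a clock score to divisions per stem cell: (score - a')*IR/g'.

    Accepts a scalar or array of scores. Negative estimates (score below the
    calibration intercept) are returned as-is with a warning, never
    truncated — silent truncation would hide calibration misfit.
    """
    if calib.ir is None:
        raise InputError(
            "calibration has no IR; use tnsc_ratio, which needs no division rate"
        )
    if calib.gamma_prime <= 0:
        raise ValidationError("inversion requires gamma_prime > 0")
    score_arr = np.asarray(score, dtype=float)
    tnsc = (score_arr - calib.alpha_prime) * calib.ir / calib.gamma_prime
    if np.any(tnsc < 0):
        warnings.warn(
            "negative division estimate(s): score below the calibration "
            "intercept (returned unclipped)",
            stacklevel=2,
        )
    return tnsc if score_arr.ndim else float(tnsc)


def tnsc_ratio(score1: float, score2: float, calib: Calibration) -> float:
    """Ratio of division counts of two samples; independent of IR.

    Equals ``estimate_tnsc(score1)/estimate_tnsc(score2)`` whenever the
    calibration carries an IR.
    """
    denom = score2 - calib.alpha_prime
    if denom == 0:
        raise InputError("score2 equals the calibration intercept: ratio undefined")
    return (score1 - calib.alpha_prime) / denom


def excess_divisions(
    tnsc_lesion: float,
    tnsc_normal: float,
    stem_fraction: float,
    total_stem_cells: float,
) -> float:
    """Additional divisions attributable to a lesion.

    Computed as (tnsc_lesion / tnsc_normal) * stem_fraction * total_stem_cells
    — the published arithmetic multiplies the division-count *ratio* by the
    lesion's stem-cell count. Note a difference-based formula would give a
    different number; this follows the printed calculation.
    """
    if tnsc_normal == 0:
        raise InputError("tnsc_normal must be nonzero")
    for name, v in (
        ("tnsc_lesion", tnsc_lesion),
        ("tnsc_normal", tnsc_normal),
        ("stem_fraction", stem_fraction),
        ("total_stem_cells", total_stem_cells),
    ):
        if v <= 0:
            raise ValidationError(f"{name} must be positive, got {v}")
    return (tnsc_lesion / tnsc_normal) * stem_fraction * total_stem_cells


def add_tnsc(scores: pd.DataFrame, calib: Calibration) -> pd.DataFrame:
    """Return ``scores`` with ``tnsc`` and ``tnsc_negative`` columns added."""
    out = scores.copy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        out["tnsc"] = estimate_tnsc(out["score"].to_numpy(), calib)
    out["tnsc_negative"] = out["tnsc"] < 0
    return out
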