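"""Reference-based cell-type deconvolution by constrained least squares.

Bulk methylation is modelled as a convex combination of cell-type reference
profiles: for each sample we solve

    minimize   || R w - b ||^2
    subject to w >= 0,  sum(w) = 1

over the probes shared between the bulk matrix and the reference. The
estimated fractions are intended as covariates for the age EWAS, where
shifts in cell composition would otherwise masquerade as age-associated
methylation change.

The solver identifies the active set with non-negative least squares on a
penalty-augmented system and then polishes the solution on its support by
solving the equality-constrained KKT system exactly, so vertex inputs and
exact convex combinations are recovered to machine precision.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .exceptions import InputError, ValidationError
from .io import BetaMatrix, _check_unique


@dataclass
class CellTypeReference:
    """Reference beta profiles, probes x cell types, no missing values."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        _check_unique(self.values.index, "probe IDs")
        _check_unique(self.values.columns, "cell types")
        if self.values.shape[1] < 2:
            raise ValidationError("reference needs at least 2 cell types")
        vals = self.values.to_numpy()
        if np.isnan(vals).any():
            raise ValidationError("reference matrix contains missing values")
        if ((vals < 0) | (vals > 1)).any():
            raise ValidationError("reference betas must lie in [0, 1]")

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def cell_types(self) -> pd.Index:
        return self.values.columns


@dataclass
class CellFractions:
    """Estimated per-sample cell-type fractions on the probability simplex.

    ``weights`` rows are NaN for samples rejected for insufficient probe
    coverage; those sample IDs are listed in ``rejected``.
    """

    weights: pd.DataFrame          # samples x cell types
    fit_residual: pd.Series        # per-sample RMS residual
    rejected: list[str]

    @property
    def sample_ids(self) -> pd.Index:
        return self.weights.index

    @property
    def cell_types(self) -> pd.Index:
        return self.weights.columns


def read_cell_reference(path, dialect: str = "tsv") -> CellTypeReference:
    sep = "\t" if dialect == "tsv" else ","
    df = pd.read_csv(path, sep=sep, index_col=0).astype(float)
    df.index = df.index.astype(str)
    return CellTypeReference(df)


def write_cell_fractions(fracs: CellFractions, path) -> None:
    out = fracs.weights.copy()
    out["fit_residual"] = fracs.fit_residual
    out.to_csv(path, index_label="sample_id", na_rep="NA")


def _solve_simplex_ls(R: np.ndarray, b: np.ndarray) -> np.ndarray:
    """min ||R w - b||^2 s.t. w >= 0, sum(w) = 1. Deterministic."""
    m, k = R.shape
    # Support identification: penalized NNLS with a heavy sum-to-one row.
    rho = 1e4 * max(1.0, float(np.abs(R).max())) * np.sqrt(m)
    A = np.vstack([R, rho * np.ones((1, k))])
    y = np.append(b, rho)
    w0, _ = nnls(A, y)
    support = w0 > 1e-9
    if not support.any():
        support[:] = True
    # Exact KKT polish on the support; drop the most negative entry until
    # the equality-constrained solution is feasible (deterministic rule).
    while True:
        idx = np.flatnonzero(support)
        Rs = R[:, idx]
        ks = idx.size
        G = Rs.T @ Rs
        kkt = np.zeros((ks + 1, ks + 1))
        kkt[:ks, :ks] = 2.0 * G
        kkt[:ks, ks] = 1.0
        kkt[ks, :ks] = 1.0
        rhs = np.append(2.0 * Rs.T @ b, 1.0)
        sol, *_ = np.linalg.lstsq(kkt, rhs, rcond=None)
        ws = sol[:ks]
        if ks == 1 or (ws >= -1e-12).all():
            break
        support[idx[np.argmin(ws)]] = False
    w = np.zeros(k)
    w[idx] = np.clip(ws, 0.0, None)
    w /= w.sum()
    return w


def estimate_cell_fractions(beta: BetaMatrix, ref: CellTypeReference) -> CellFractions:
    """Estimate cell-type fractions for every sample of ``beta``.

    Probes in ``beta`` absent from the reference are ignored (the reference
    defines the feature space). Missing betas at shared probes are dropped
    per sample from the objective; samples with more than 50% of the shared
    probes missing are rejected (NaN row, listed in ``rejected``).
    """
    shared = ref.probe_ids.intersection(beta.probe_ids)
    if len(shared) == 0:
        raise InputError("no probes shared between beta matrix and reference")
    R_full = ref.values.loc[shared].to_numpy()
    # Degenerate reference: identical columns make fractions non-identifiable.
    k = R_full.shape[1]
    for i in range(k):
        for j in range(i + 1, k):
            if np.allclose(R_full[:, i], R_full[:, j]):
                warnings.warn(
                    f"reference columns {ref.cell_types[i]!r} and "
                    f"{ref.cell_types[j]!r} are identical over shared probes; "
                    "fractions between them are not identifiable (solver "
                    "ties resolved deterministically by column order)",
                    stacklevel=2,
                )
    B = beta.values.loc[shared].to_numpy()
    n_shared = len(shared)
    weights = np.full((beta.shape[1], k), np.nan)
    resid = np.full(beta.shape[1], np.nan)
    rejected: list[str] = []
    for s in range(beta.shape[1]):
        obs = ~np.isnan(B[:, s])
        if obs.sum() <= n_shared * 0.5:
            rejected.append(str(beta.sample_ids[s]))
            continue
        w = _solve_simplex_ls(R_full[obs], B[obs, s])
        weights[s] = w
        r = R_full[obs] @ w - B[obs, s]
        resid[s] = float(np.sqrt(np.mean(r**2)))
    return CellFractions(
        weights=pd.DataFrame(weights, index=beta.sample_ids, columns=ref.cell_types),
        fit_residual=pd.Series(resid, index=beta.sample_ids, name="fit_residual"),
        rejected=rejected,
    )
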