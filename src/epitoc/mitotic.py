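"""Expression-based mitotic index over a nine-gene proliferation panel.

The default panel is the intersection of two well-validated proliferation
signatures: CDKN3, ILF2, KDELR2, RFC4, TOP2A, MCM3, KPNA2, CKS2 and CDC2.
CDC2 is the historical symbol for CDK1, so the matcher accepts either
(preferring CDC2 when both are present). The index is the arithmetic mean
expression over the panel genes on whatever scale the matrix supplies; no
internal log transform is applied.
"""

from __future__ import annotations

import pandas as pd

from .exceptions import InputError

DEFAULT_PANEL: tuple[str, ...] = (
    "CDKN3",
    "ILF2",
    "KDELR2",
    "RFC4",
    "TOP2A",
    "MCM3",
    "KPNA2",
    "CKS2",
    "CDC2",
)

_ALIASES: dict[str, tuple[str, ...]] = {"CDC2": ("CDC2", "CDK1")}


def _resolve_panel(expr_genes: pd.Index, panel: tuple[str, ...]) -> tuple[list[str], list[str]]:
    """Map panel symbols to matrix rows; returns (present rows, missing symbols)."""
    present: list[str] = []
    missing: list[str] = []
    for gene in panel:
        for candidate in _ALIASES.get(gene, (gene,)):
            if candidate in expr_genes:
                present.append(candidate)
                break
        else:
            missing.append(gene)
    return present, missing


def compute_mitotic_index(
    expr: pd.DataFrame,
    panel: tuple[str, ...] = DEFAULT_PANEL,
    allow_partial: bool = False,
) -> pd.DataFrame:
    """Per-sample mean expression over the proliferation panel.

    ``expr`` is genes x samples. Returns a DataFrame indexed by sample with
    columns ``index`` (mean over present panel genes, skipping missing
    cells) and ``genes_used``. Unless ``allow_partial``, every panel gene
    must be present (up to the CDC2/CDK1 alias).
    """
    rows, missing = _resolve_panel(expr.index, tuple(panel))
    if missing and not allow_partial:
        raise InputError(f"panel genes absent from expression matrix: {missing}")
    if not rows:
        raise InputError("no panel genes present in expression matrix")
    sub = expr.loc[rows]
    return pd.DataFrame(
        {
            "index": sub.mean(axis=0, skipna=True),
            "genes_used": sub.notna().sum(axis=0).astype(int),
        }
    )
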