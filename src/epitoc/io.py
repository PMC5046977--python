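"""Readers, writers and in-memory containers for the toolkit's tabular artifacts.

Conventions
-----------
* Methylation beta matrices are probes-in-rows, samples-in-columns. A
  transposed file is never guessed at; it surfaces later as an ID mismatch.
* Missing-value tokens ``NA``, ``NaN`` and the empty string (case-insensitive)
  are read as missing.
* Probe IDs are opaque strings: no ``cg``-prefix validation, so the toolkit
  works with any platform's identifiers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import FormatError, RangeError, SchemaError, ValidationError

MISSING_TOKENS = ("NA", "NaN", "nan", "na", "NAN", "")

_SAMPLE_SHEET_OPTIONAL = ("sex", "plate", "tissue", "group", "pair_id", "exposure")


def _check_unique(ids, what: str) -> None:
    idx = pd.Index(ids)
    if idx.has_duplicates:
        dups = idx[idx.duplicated()].unique().tolist()
        raise FormatError(f"duplicate {what}: {dups[:5]}")


@dataclass
class BetaMatrix:
    """Methylation beta fractions, probes x samples, values in [0, 1] or NaN."""

    values: pd.DataFrame
    n_clipped: int = 0

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        _check_unique(self.values.index, "probe IDs")
        _check_unique(self.values.columns, "sample IDs")
        vals = self.values.to_numpy()
        bad = (vals < 0) | (vals > 1)
        if np.any(bad):
            i, j = np.argwhere(bad)[0]
            raise RangeError(
                f"beta out of [0,1]: probe {self.values.index[i]!r}, "
                f"sample {self.values.columns[j]!r}, value {vals[i, j]}"
            )

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class SampleSheet:
    """Per-sample phenotypes. ``sample_id`` and ``age`` are mandatory."""

    data: pd.DataFrame  # indexed by sample_id

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "sample IDs")
        if "age" not in self.data.columns:
            raise SchemaError("sample sheet lacks required column 'age'")
        ages = pd.to_numeric(self.data["age"], errors="coerce")
        neg = ages < 0
        if neg.any():
            row = self.data.index[neg.to_numpy()][0]
            raise ValidationError(f"negative age for sample {row!r}")
        self.data = self.data.assign(age=ages)

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.index

    @property
    def age(self) -> pd.Series:
        return self.data["age"]

    def has(self, column: str) -> bool:
        return column in self.data.columns and self.data[column].notna().any()

    def column(self, name: str) -> pd.Series:
        if name not in self.data.columns:
            raise SchemaError(f"sample sheet has no column {name!r}")
        return self.data[name]


@dataclass
class ProbeAnnotation:
    """Probe -> (gene, TSS200, PRC2) annotation table."""

    data: pd.DataFrame  # indexed by probe_id; columns gene, tss200, prc2

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "probe IDs")
        for col in ("tss200", "prc2"):
            if col not in self.data.columns:
                raise SchemaError(f"probe annotation lacks column {col!r}")
            self.data[col] = self.data[col].astype(bool)
        gene = self.data.get("gene")
        if gene is None:
            raise SchemaError("probe annotation lacks column 'gene'")
        gene = gene.fillna("").astype(str)
        self.data = self.data.assign(gene=gene)
        bad = self.data["tss200"] & (gene == "")
        if bad.any():
            raise ValidationError(
                f"probe {self.data.index[bad.to_numpy()][0]!r} is TSS200 but has no gene"
            )

    @property
    def probe_ids(self) -> pd.Index:
        return self.data.index


@dataclass(frozen=True)
class ClockDefinition:
    """A named CpG set with a direction and the ground-state bound used to build it.

    ``direction`` is ``"hyper"`` (methylation gained with divisions; fetal
    ground state below ``ground_state_bound``) or ``"hypo"`` (methylation
    lost; fetal ground state at or above the bound).
    """

    name: str
    direction: str
    probe_ids: frozenset[str]
    ground_state_bound: float = field(default=0.2)

    def __post_init__(self) -> None:
        if self.direction not in ("hyper", "hypo"):
            raise ValidationError(f"direction must be hyper/hypo, got {self.direction!r}")
        if len(self.probe_ids) == 0:
            raise ValidationError(f"clock {self.name!r} has an empty probe set")

    def __len__(self) -> int:
        return len(self.probe_ids)


# ---------------------------------------------------------------------------
# Beta matrices
# ---------------------------------------------------------------------------

def read_beta_matrix(path, dialect: str = "tsv", clip_out_of_range: bool = False) -> BetaMatrix:
    """Read a probes x samples beta matrix from TSV/CSV.

    First column = probe IDs, header row = sample IDs. ``NA``/``NaN``/empty
    cells become missing. With ``clip_out_of_range`` values are clipped into
    [0, 1] and the number of clipped cells is reported on the returned
    object's ``n_clipped``; otherwise any out-of-range value raises
    :class:`RangeError` naming the offending probe, sample and value.
    """
    sep = "\t" if dialect == "tsv" else ","
    df = pd.read_csv(
        path, sep=sep, index_col=0, na_values=list(MISSING_TOKENS), keep_default_na=False
    )
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise FormatError(f"non-numeric beta value in {path}: {exc}") from exc
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    n_clipped = 0
    if clip_out_of_range:
        vals = df.to_numpy()
        bad = (vals < 0) | (vals > 1)
        n_clipped = int(np.nansum(bad))
        df = df.clip(0.0, 1.0)
    return BetaMatrix(df, n_clipped=n_clipped)


def write_beta_matrix(beta: BetaMatrix, path, dialect: str = "tsv") -> None:
    sep = "\t" if dialect == "tsv" else ","
    beta.values.to_csv(path, sep=sep, index_label="probe_id", na_rep="NA")


# ---------------------------------------------------------------------------
# Sample sheets
# ---------------------------------------------------------------------------

def read_sample_sheet(path) -> SampleSheet:
    """Read a CSV sample sheet; ``sample_id`` and ``age`` columns are required."""
    df = pd.read_csv(path, na_values=list(MISSING_TOKENS), keep_default_na=False)
    if "sample_id" not in df.columns:
        raise SchemaError("sample sheet lacks required column 'sample_id'")
    if "age" not in df.columns:
        raise SchemaError("sample sheet lacks required column 'age'")
    df["sample_id"] = df["sample_id"].astype(str)
    df = df.set_index("sample_id")
    if "exposure" in df.columns:
        df["exposure"] = pd.to_numeric(df["exposure"], errors="coerce")
        if (df["exposure"] < 0).any():
            raise ValidationError("negative exposure value")
    return SampleSheet(df)


def write_sample_sheet(sheet: SampleSheet, path) -> None:
    sheet.data.to_csv(path, index_label="sample_id", na_rep="NA")


# ---------------------------------------------------------------------------
# Probe annotation
# ---------------------------------------------------------------------------

def read_probe_annotation(path) -> ProbeAnnotation:
    """Read a TSV with columns probe_id, gene, tss200 (0/1), prc2 (0/1)."""
    df = pd.read_csv(path, sep="\t", na_values=list(MISSING_TOKENS), keep_default_na=False)
    for col in ("probe_id", "gene", "tss200", "prc2"):
        if col not in df.columns:
            raise SchemaError(f"probe annotation lacks column {col!r}")
    df["probe_id"] = df["probe_id"].astype(str)
    df = df.set_index("probe_id")
    df["tss200"] = df["tss200"].astype(float).astype(bool)
    df["prc2"] = df["prc2"].astype(float).astype(bool)
    return ProbeAnnotation(df)


def write_probe_annotation(annot: ProbeAnnotation, path) -> None:
    out = annot.data.copy()
    out["tss200"] = out["tss200"].astype(int)
    out["prc2"] = out["prc2"].astype(int)
    out.to_csv(path, sep="\t", index_label="probe_id")


# ---------------------------------------------------------------------------
# Clock definitions
# ---------------------------------------------------------------------------

def read_clock_definition(path) -> ClockDefinition:
    """Read a clock file: one probe ID per line, '#key: value' metadata header."""
    meta: dict[str, str] = {}
    probes: list[str] = []
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if ":" in body:
                    key, _, val = body.partition(":")
                    meta[key.strip().lower()] = val.strip()
                continue
            probes.append(line)
    if not probes:
        raise ValidationError(f"clock file {path} contains no probe IDs")
    seen: set[str] = set()
    for p in probes:
        if p in seen:
            raise FormatError(f"duplicate probe ID in clock file: {p!r}")
        seen.add(p)
    direction = meta.get("direction", "hyper")
    bound = float(meta.get("ground_state_bound", 0.2 if direction == "hyper" else 0.3))
    return ClockDefinition(
        name=meta.get("name", "clock"),
        direction=direction,
        probe_ids=frozenset(probes),
        ground_state_bound=bound,
    )


def write_clock_definition(clock: ClockDefinition, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#name: {clock.name}\n")
        fh.write(f"#direction: {clock.direction}\n")
        fh.write(f"#ground_state_bound: {clock.ground_state_bound}\n")
        for probe in sorted(clock.probe_ids):
            fh.write(probe + "\n")


# ---------------------------------------------------------------------------
# Expression matrices (genes x samples)
# ---------------------------------------------------------------------------

def read_expression_matrix(path, dialect: str = "tsv") -> pd.DataFrame:
    """Read a genes x samples expression TSV; returns a float DataFrame."""
    sep = "\t" if dialect == "tsv" else ","
    df = pd.read_csv(
        path, sep=sep, index_col=0, na_values=list(MISSING_TOKENS), keep_default_na=False
    )
    df = df.astype(float)
    df.index = df.index.astype(str)
    _check_unique(df.index, "gene IDs")
    return df
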