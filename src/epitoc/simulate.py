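"""Generative simulator of the replication-error methylation model.

Each simulated sample s of tissue t accrues stem-cell divisions

    TNSC(s) = A(s) * [IR(t) + E(s) * ER(t)]

(A = age in years, IR = intrinsic divisions/stem cell/year, E = exposure
level, ER = exposure-induced extrinsic rate). Planted clock CpGs drift
linearly with divisions from a fetal ground state g_c at per-division rate
xi_c:

    mean beta = clip(g_c + xi_c * TNSC, 0, 1)   (hyper; minus for hypo)

Non-clock probes are static, except a subset of cell-type marker probes
whose bulk value is a mixture of cell-type-specific levels with
age-trending mixing proportions — the confounder that motivates
reference-based deconvolution. Observed betas are drawn from a
mean-preserving beta distribution at a configured precision (respecting the
[0, 1] support), a matched fetal ground-state matrix obeys the clock
construction bounds (< 0.2 hyper, >= 0.3 hypo in every fetal sample), and a
nine-gene proliferation expression panel tracks the division rate.

Defaults emulate a blood cohort: ages 20-100, intrinsic rate 12
divisions/stem cell/year, per-CpG drift xi ~ U(1e-5, 5e-5) per division so
the score-age slope is of the order of published blood calibrations
(~3.5e-4/year), and beta-noise precision 1000 (per-probe sd ~ 0.01).
All randomness flows from the config's mandatory seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .deconv import CellFractions, CellTypeReference
from .exceptions import InputError, ValidationError
from .io import BetaMatrix, ProbeAnnotation, SampleSheet
from .mitotic import DEFAULT_PANEL
from .scoring import TISSUE_RATES

SCENARIOS = (
    "healthy-blood",
    "multi-tissue-normal",
    "tumor-vs-normal",
    "lesion-progression",
    "exposure-dose",
)


@dataclass(frozen=True)
class SimulationConfig:
    """Full parameterization of a simulated cohort. Frozen; seed mandatory."""

    seed: int
    scenario: str = "custom"
    n_samples: int = 500
    n_probes: int = 2000
    n_clock_hyper: int = 50
    n_clock_hypo: int = 50
    age_range: tuple[float, float] = (20.0, 100.0)
    constant_age: float | None = None
    tissues: tuple[tuple[str, float], ...] = (("blood", 12.0),)
    exposure_kind: str = "none"            # none | lognormal | uniform
    exposure_params: tuple[float, float] = (0.0, 0.5)
    er: float = 0.0                        # extrinsic divisions/stem cell/yr per unit E
    group_structure: str = "none"          # none | paired | progression
    group_labels: tuple[str, ...] = ("normal",)
    group_exposure_scale: tuple[float, ...] = (0.0,)
    hyper_ground_range: tuple[float, float] = (0.05, 0.15)
    hypo_ground_range: tuple[float, float] = (0.45, 0.70)
    xi_range: tuple[float, float] = (1e-5, 5e-5)
    n_fetal: int = 52
    fetal_noise_sd: float = 0.01
    n_cell_types: int = 5
    cell_marker_fraction: float = 0.10
    cell_trend_scale: float = 0.5
    cell_logit_noise: float = 0.3
    noise_precision: float | None = 1000.0
    expression_slope: float = 0.05
    expression_noise_sd: float = 0.3
    n_expression_background: int = 20

    def __post_init__(self) -> None:
        if self.er < 0:
            raise ValidationError("er must be nonnegative")
        for _, ir in self.tissues:
            if ir < 0:
                raise ValidationError("tissue division rates must be nonnegative")
        lo, hi = self.hyper_ground_range
        if not (0 < lo <= hi < 0.2):
            raise ValidationError("hyper ground-state range must lie inside (0, 0.2)")
        lo, hi = self.hypo_ground_range
        if not (0.3 <= lo <= hi < 1):
            raise ValidationError("hypo ground-state range must lie inside [0.3, 1)")


@dataclass(frozen=True)
class CohortTruth:
    """Generating quantities: per-sample divisions and rates, per-probe clock
    membership and drift rates."""

    tnsc: pd.Series                 # age * (IR + E*ER), exact
    rate: pd.Series                 # IR + E*ER (divisions/stem cell/year)
    clock_hyper: frozenset[str]
    clock_hypo: frozenset[str]
    xi: pd.Series                   # per clock probe, beta change per division
    ground_state: pd.Series         # per clock probe


@dataclass
class SimulatedCohort:
    config: SimulationConfig
    beta: BetaMatrix
    pheno: SampleSheet
    annot: ProbeAnnotation
    fetal_beta: BetaMatrix
    cell_reference: CellTypeReference | None
    true_fractions: CellFractions | None
    expr: pd.DataFrame
    truth: CohortTruth


def default_config(scenario: str, seed: int = 0) -> SimulationConfig:
    """A fully specified config for one of the documented study designs.

    healthy-blood        single-tissue healthy cohort, no exposure (the
                         clock-construction setting)
    multi-tissue-normal  healthy samples across the eight tissues with
                         published division rates (score vs TNSC design)
    tumor-vs-normal      age-sharing normal/tumor pairs, tumors carry a
                         log-normal exposure (paired elevation design)
    lesion-progression   normal / lesion / progressing-lesion groups with
                         increasing exposure (ROC designs)
    exposure-dose        identically aged samples with a continuous
                         exposure, e.g. smoking pack-years (dose design)
    """
    base = SimulationConfig(seed=seed, scenario=scenario)
    if scenario == "healthy-blood":
        return base
    if scenario == "multi-tissue-normal":
        return replace(
            base,
            n_samples=320,
            tissues=tuple(sorted(TISSUE_RATES.items())),
            n_cell_types=0,
        )
    if scenario == "tumor-vs-normal":
        return replace(
            base,
            n_samples=120,
            tissues=(("lung", TISSUE_RATES["lung"]),),
            group_structure="paired",
            group_labels=("normal", "tumor"),
            group_exposure_scale=(0.0, 1.0),
            exposure_kind="lognormal",
            exposure_params=(0.0, 0.5),
            er=30.0,
            age_range=(40.0, 80.0),
            n_cell_types=0,
        )
    if scenario == "lesion-progression":
        return replace(
            base,
            n_samples=90,
            tissues=(("lung", TISSUE_RATES["lung"]),),
            group_structure="progression",
            group_labels=("normal", "lesion", "progressed"),
            group_exposure_scale=(0.0, 1.0, 3.0),
            exposure_kind="lognormal",
            exposure_params=(0.0, 0.5),
            er=0.1,
            age_range=(50.0, 80.0),
            n_cell_types=0,
        )
    if scenario == "exposure-dose":
        return replace(
            base,
            n_samples=500,
            tissues=(("buccal", 5.0),),
            constant_age=53.0,
            exposure_kind="uniform",
            exposure_params=(0.0, 50.0),
            er=0.1,
            group_labels=("exposed",),
            group_exposure_scale=(1.0,),
            n_cell_types=0,
        )
    raise InputError(f"unknown scenario {scenario!r}; choose one of {SCENARIOS}")


def _draw_exposure(rng: np.random.Generator, cfg: SimulationConfig, n: int) -> np.ndarray:
    if cfg.exposure_kind == "none":
        return np.zeros(n)
    if cfg.exposure_kind == "lognormal":
        mu, sigma = cfg.exposure_params
        return rng.lognormal(mu, sigma, size=n)
    if cfg.exposure_kind == "uniform":
        lo, hi = cfg.exposure_params
        return rng.uniform(lo, hi, size=n)
    raise InputError(f"unknown exposure_kind {cfg.exposure_kind!r}")


def _softmax(z: np.ndarray) -> np.ndarray:
    e = np.exp(z - z.max(axis=0))
    return e / e.sum(axis=0)


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Generate a full cohort (beta, phenotypes, annotation, fetal matrix,
    cell reference + true fractions, expression, truth) from the config.

    Bit-identical for identical configs. Clock means that would leave [0, 1]
    are clipped and the number of clipped probe-sample cells is warned about.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_samples

    # ----- samples: groups, pairing, tissue, age, exposure -----------------
    tissue_names = [t for t, _ in cfg.tissues]
    tissue_ir = dict(cfg.tissues)
    if cfg.group_structure == "paired":
        n_pairs = n // 2
        sample_ids = [f"{g}{i:04d}" for i in range(n_pairs) for g in ("N", "T")]
        pair_id = [f"P{i:04d}" for i in range(n_pairs) for _ in range(2)]
        group = [g for _ in range(n_pairs) for g in cfg.group_labels]
        scale = np.array([s for _ in range(n_pairs) for s in cfg.group_exposure_scale])
        pair_ages = (
            np.full(n_pairs, cfg.constant_age)
            if cfg.constant_age is not None
            else rng.uniform(*cfg.age_range, size=n_pairs)
        )
        age = np.repeat(pair_ages, 2)
        tissue = [tissue_names[i % len(tissue_names)] for i in range(n_pairs) for _ in range(2)]
        n = 2 * n_pairs
    else:
        sample_ids = [f"S{i:04d}" for i in range(n)]
        pair_id = [""] * n
        k = len(cfg.group_labels)
        group = [cfg.group_labels[i * k // n] for i in range(n)]
        scale = np.array([cfg.group_exposure_scale[i * k // n] for i in range(n)])
        age = (
            np.full(n, cfg.constant_age)
            if cfg.constant_age is not None
            else rng.uniform(*cfg.age_range, size=n)
        )
        tissue = [tissue_names[i % len(tissue_names)] for i in range(n)]

    exposure = scale * _draw_exposure(rng, cfg, n)
    ir = np.array([tissue_ir[t] for t in tissue])
    rate = ir + exposure * cfg.er
    tnsc = age * rate

    pheno = SampleSheet(
        pd.DataFrame(
            {
                "age": age,
                "sex": rng.choice(["F", "M"], size=n),
                "plate": rng.choice(["plate1", "plate2"], size=n),
                "tissue": tissue,
                "group": group,
                "pair_id": pair_id,
                "exposure": exposure,
            },
            index=pd.Index(sample_ids, name="sample_id"),
        )
    )

    # ----- probes ----------------------------------------------------------
    n_hyper, n_hypo = cfg.n_clock_hyper, cfg.n_clock_hypo
    n_marker = int(round(cfg.cell_marker_fraction * cfg.n_probes)) if cfg.n_cell_types else 0
    n_bg = cfg.n_probes - n_hyper - n_hypo - n_marker
    if n_bg < 0:
        raise ValidationError("n_probes too small for the planted probe classes")
    probe_ids = pd.Index([f"cg{i:07d}" for i in range(cfg.n_probes)], name="probe_id")
    hyper_ids = probe_ids[:n_hyper]
    hypo_ids = probe_ids[n_hyper : n_hyper + n_hypo]
    marker_ids = probe_ids[n_hyper + n_hypo : n_hyper + n_hypo + n_marker]
    bg_ids = probe_ids[n_hyper + n_hypo + n_marker :]

    g_hyper = rng.uniform(*cfg.hyper_ground_range, size=n_hyper)
    g_hypo = rng.uniform(*cfg.hypo_ground_range, size=n_hypo)
    xi = rng.uniform(*cfg.xi_range, size=n_hyper + n_hypo)
    xi_hyper, xi_hypo = xi[:n_hyper], xi[n_hyper:]

    mean = np.empty((cfg.n_probes, n))
    mean[:n_hyper] = g_hyper[:, None] + xi_hyper[:, None] * tnsc[None, :]
    mean[n_hyper : n_hyper + n_hypo] = (
        g_hypo[:, None] - xi_hypo[:, None] * tnsc[None, :]
    )
    n_clipped = int(((mean[: n_hyper + n_hypo] < 0) | (mean[: n_hyper + n_hypo] > 1)).sum())
    if n_clipped:
        warnings.warn(
            f"clock drift left [0,1] for {n_clipped} probe-sample cells (clipped)",
            stacklevel=2,
        )
    np.clip(mean[: n_hyper + n_hypo], 0.0, 1.0, out=mean[: n_hyper + n_hypo])

    # cell-type markers mixed by age-trending proportions
    if cfg.n_cell_types:
        m_cell = rng.uniform(0.1, 0.9, size=(n_marker, cfg.n_cell_types))
        base_logit = rng.normal(0.0, 0.5, size=cfg.n_cell_types)
        trend = rng.uniform(-1.0, 1.0, size=cfg.n_cell_types) * cfg.cell_trend_scale
        # systematic age trend plus per-sample compositional variation
        z = (
            base_logit[:, None]
            + trend[:, None] * (age[None, :] - 60.0) / 40.0
            + rng.normal(0.0, cfg.cell_logit_noise, size=(cfg.n_cell_types, n))
        )
        w = _softmax(z)  # cell types x samples
        mean[n_hyper + n_hypo : n_hyper + n_hypo + n_marker] = m_cell @ w
        cell_types = pd.Index([f"celltype{k}" for k in range(cfg.n_cell_types)])
        cell_reference = CellTypeReference(
            pd.DataFrame(m_cell, index=marker_ids, columns=cell_types)
        )
        true_fractions = CellFractions(
            weights=pd.DataFrame(w.T, index=pheno.sample_ids, columns=cell_types),
            fit_residual=pd.Series(0.0, index=pheno.sample_ids, name="fit_residual"),
            rejected=[],
        )
    else:
        cell_reference = None
        true_fractions = None

    bg_mean = rng.uniform(0.05, 0.95, size=n_bg)
    mean[n_hyper + n_hypo + n_marker :] = bg_mean[:, None]

    # measurement noise: mean-preserving beta family at given precision
    if cfg.noise_precision is None:
        observed = mean
    else:
        mu = np.clip(mean, 1e-6, 1.0 - 1e-6)
        prec = cfg.noise_precision
        observed = rng.beta(mu * prec, (1.0 - mu) * prec)
    beta = BetaMatrix(pd.DataFrame(observed, index=probe_ids, columns=pheno.sample_ids))

    # ----- fetal ground-state matrix (bounds enforced per fetal sample) ----
    fetal_base = np.empty(cfg.n_probes)
    fetal_base[:n_hyper] = g_hyper
    fetal_base[n_hyper : n_hyper + n_hypo] = g_hypo
    if n_marker:
        fetal_base[n_hyper + n_hypo : n_hyper + n_hypo + n_marker] = m_cell.mean(axis=1)
    fetal_base[n_hyper + n_hypo + n_marker :] = bg_mean
    fetal = fetal_base[:, None] + rng.normal(0.0, cfg.fetal_noise_sd, size=(cfg.n_probes, cfg.n_fetal))
    fetal[:n_hyper] = np.clip(fetal[:n_hyper], 0.001, 0.199)
    fetal[n_hyper : n_hyper + n_hypo] = np.clip(
        fetal[n_hyper : n_hyper + n_hypo], 0.301, 0.999
    )
    fetal[n_hyper + n_hypo :] = np.clip(fetal[n_hyper + n_hypo :], 0.0, 1.0)
    fetal_ids = pd.Index([f"fetal{j:03d}" for j in range(cfg.n_fetal)])
    fetal_beta = BetaMatrix(pd.DataFrame(fetal, index=probe_ids, columns=fetal_ids))

    # ----- probe annotation -------------------------------------------------
    tss200 = np.zeros(cfg.n_probes, dtype=bool)
    prc2 = np.zeros(cfg.n_probes, dtype=bool)
    tss200[: n_hyper + n_hypo] = True
    prc2[:n_hyper] = True
    n_rest = cfg.n_probes - n_hyper - n_hypo
    tss200[n_hyper + n_hypo :] = rng.random(n_rest) < 0.3
    prc2[n_hyper + n_hypo :] = rng.random(n_rest) < 0.25
    gene = np.array([f"GENE{i}" if t else "" for i, t in enumerate(tss200)], dtype=object)
    annot = ProbeAnnotation(
        pd.DataFrame({"gene": gene, "tss200": tss200, "prc2": prc2}, index=probe_ids)
    )

    # ----- expression: proliferation panel tracks the division rate --------
    panel_base = rng.uniform(4.0, 8.0, size=len(DEFAULT_PANEL))
    expr_panel = (
        panel_base[:, None]
        + cfg.expression_slope * rate[None, :]
        + rng.normal(0.0, cfg.expression_noise_sd, size=(len(DEFAULT_PANEL), n))
    )
    bg_expr = rng.uniform(2.0, 10.0, size=cfg.n_expression_background)[:, None] + rng.normal(
        0.0, cfg.expression_noise_sd, size=(cfg.n_expression_background, n)
    )
    expr = pd.DataFrame(
        np.vstack([expr_panel, bg_expr]),
        index=pd.Index(
            list(DEFAULT_PANEL)
            + [f"BGGENE{i}" for i in range(cfg.n_expression_background)],
            name="gene_id",
        ),
        columns=pheno.sample_ids,
    )

    truth = CohortTruth(
        tnsc=pd.Series(tnsc, index=pheno.sample_ids, name="tnsc"),
        rate=pd.Series(rate, index=pheno.sample_ids, name="rate"),
        clock_hyper=frozenset(hyper_ids),
        clock_hypo=frozenset(hypo_ids),
        xi=pd.Series(xi, index=probe_ids[: n_hyper + n_hypo], name="xi"),
        ground_state=pd.Series(
            np.concatenate([g_hyper, g_hypo]),
            index=probe_ids[: n_hyper + n_hypo],
            name="ground_state",
        ),
    )
    return SimulatedCohort(
        config=cfg,
        beta=beta,
        pheno=pheno,
        annot=annot,
        fetal_beta=fetal_beta,
        cell_reference=cell_reference,
        true_fractions=true_fractions,
        expr=expr,
        truth=truth,
    )


def write_cohort(cohort: SimulatedCohort, out_dir) -> None:
    """Write every artifact of a cohort in the toolkit's standard dialects."""
    from pathlib import Path

    from .deconv import write_cell_fractions
    from .io import (
        write_beta_matrix,
        write_probe_annotation,
        write_sample_sheet,
    )

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_beta_matrix(cohort.beta, out / "beta.tsv")
    write_sample_sheet(cohort.pheno, out / "pheno.csv")
    write_probe_annotation(cohort.annot, out / "annotation.tsv")
    write_beta_matrix(cohort.fetal_beta, out / "fetal_beta.tsv")
    if cohort.cell_reference is not None:
        cohort.cell_reference.values.to_csv(out / "cell_reference.tsv", sep="\t")
        write_cell_fractions(cohort.true_fractions, out / "true_fractions.csv")
    cohort.expr.to_csv(out / "expression.tsv", sep="\t")
    truth = pd.DataFrame(
        {"tnsc": cohort.truth.tnsc, "rate": cohort.truth.rate}
    )
    truth.to_csv(out / "truth_samples.tsv", sep="\t", index_label="sample_id")
    probes = pd.DataFrame(
        {
            "xi": cohort.truth.xi,
            "ground_state": cohort.truth.ground_state,
            "clock": [
                "hyper" if p in cohort.truth.clock_hyper else "hypo"
                for p in cohort.truth.xi.index
            ],
        }
    )
    probes.to_csv(out / "truth_probes.tsv", sep="\t", index_label="probe_id")
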