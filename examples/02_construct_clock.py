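"""Construct a mitotic clock from a cohort: EWAS -> FDR -> filter cascade.

Runs the full selection pipeline on a simulated blood cohort (with
cell-composition confounding) and reports how well the constructed hyper
clock recovers the planted clock CpGs, plus the per-filter audit.
"""

import epitoc as e

cohort = e.simulate_cohort(e.default_config("healthy-blood", seed=42))

# cell fractions as EWAS covariates (here the simulator's true fractions;
# estimate_cell_fractions(cohort.beta, cohort.cell_reference) in practice)
ewas = e.run_ewas(cohort.beta, cohort.pheno, covariates=("sex", "plate"),
                  cell_fractions=cohort.true_fractions)
hyper, hypo, audit = e.select_clock_cpgs(ewas, cohort.annot, cohort.fetal_beta)

print(f"tested probes: {audit['n_tested']}, q<0.05: {audit['n_significant']}")
print("hyper-branch audit (probes removed per filter):", audit["hyper"])
print(f"hyper clock: {len(hyper)} CpGs; hypo clock: {len(hypo)} CpGs")

planted = set(cohort.truth.clock_hyper)
found = set(hyper.probe_ids)
sens = len(found & planted) / len(planted)
fi = len(found - planted) / len(found)
print(f"sensitivity vs planted clock: {sens:.2f}; false inclusion: {fi:.2f}")
# sensitivity = fraction of truly drifting CpGs recovered; false inclusion =
# fraction of the constructed clock that was not planted.
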