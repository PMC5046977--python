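"""Generate a synthetic cohort and write every artifact to disk.

The written files (beta matrix, sample sheet, probe annotation, fetal
ground-state matrix, cell reference, expression matrix, truth tables) are
in the toolkit's standard TSV/CSV dialects and can be fed back through the
CLI (`epitoc construct`, `epitoc score`, ...).
"""

import tempfile
from pathlib import Path

import epitoc as e

cfg = e.default_config("healthy-blood", seed=1)
cohort = e.simulate_cohort(cfg)
out = Path(tempfile.mkdtemp(prefix="epitoc_sim_"))
e.write_cohort(cohort, out)

print(f"wrote {cohort.beta.shape[0]} probes x {cohort.beta.shape[1]} samples to {out}:")
for f in sorted(out.iterdir()):
    print(f"  {f.name}  ({f.stat().st_size // 1024} KB)")
print(f"planted clock: {len(cohort.truth.clock_hyper)} hyper + "
      f"{len(cohort.truth.clock_hypo)} hypo CpGs; "
      f"ages {cohort.pheno.age.min():.0f}-{cohort.pheno.age.max():.0f}")
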