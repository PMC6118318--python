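"""Run every pipeline stage end to end on a freshly simulated cohort.

Simulate -> write VCF/PED -> missingness filter -> trio genetics ->
association -> risk attribution, all driven by one config and seed; the
output directory holds one TSV per stage plus a run log and summary.
"""

from pathlib import Path

import triovar as tv

sim = tv.SimulationConfig(n_trios=80, n_case_only=10, n_controls=90, seed=3)
cohort = tv.simulate_cohort(sim, out_dir="example_run/input")

# declare the risk panel explicitly (variant key, display label, class);
# without a panel file the pipeline falls back to frequency-derived classes
lines = ["variant\tlabel\tclass"]
for v in cohort.genotypes.variants:
    if v.variant_id.startswith(("common", "rare")):
        cls = "common" if v.variant_id.startswith("common") else "rare"
        lines.append(f"{v.chrom}:{v.pos}:{v.ref}:{v.alt}\t{v.variant_id}\t{cls}")
Path("example_run/input/panel.tsv").write_text("\n".join(lines) + "\n")

config = tv.PipelineConfig(
    vcf="example_run/input/cohort.vcf",
    ped="example_run/input/cohort.ped",
    panel="example_run/input/panel.tsv",
    out_dir="example_run/report",
    seed=3,
)
out = tv.run_pipeline(config)

print(f"stage tables written to {out}:")
for path in sorted(Path(out).iterdir()):
    print(f"  {path.name}")
print()
print(Path(out, "summary.txt").read_text())
print("Every threshold applied (missingness 10%, burden MAF cap 5%, rare-MAF")
print("1%, de novo MAF 0.5%) is recorded in run.log; rerunning with the same")
print("seed reproduces every table byte for byte.")
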