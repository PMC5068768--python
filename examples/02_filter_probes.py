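"""Apply the probe-exclusion stack to one simulated cohort.

Probes are removed if (1) any sample's detection P-value exceeds 0.05,
(2) an annotated SNP sits at the single-base extension or the CpG site
itself (offsets 0-2), (3) they lie on chrX/chrY, or (4) they appear on a
named exclusion list — here the brain cell-type-marker probes whose
methylation tracks neuronal proportion rather than diagnosis.
"""

from methbump import FilterConfig, run_filter_stack, simulate_study

study = simulate_study(seed=42)
cohort = study.cohorts[0]

config = FilterConfig(exclusion_lists={"celltype": study.celltype_probes})
filtered, manifest, report = run_filter_stack(
    cohort.betas, cohort.detp, study.manifest, config
)

for line in report.to_lines():
    print(line)
# The per-stage counts use sequential semantics: each stage is tallied on the
# probes surviving the previous stages, so the counts sum to input - output.
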