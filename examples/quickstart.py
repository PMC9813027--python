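"""Simulate a reference-size reader study and run the primary comparison."""

import mrmcroc as m

ds = m.generate_study(seed=1)
audit = m.validate_completeness(ds)
print(f"breasts: {audit.n_cases}  readers: {audit.n_readers}  "
      f"session reports: {audit.session_report_count}  "
      f"complete: {audit.is_complete}")

for mode in ("DM", "AICAD_SM"):
    aucs, mean = m.reader_auc_table(ds, mode, "pom")
    cells = "  ".join(f"{r}: {a:.3f}" for r, a in sorted(aucs.items()))
    print(f"{mode:9s} POM AUC  {cells}  mean: {mean:.3f}")

spec = m.BootstrapSpec(n_case_resamples=1000, n_reader_resamples=100, seed=1)
comp = m.compare_modes(ds, "DM", "AICAD_SM", "pom", spec)
print(f"difference (AICAD_SM - DM): {comp.difference:.3f}  "
      f"95% CI ({comp.ci_low:.3f}, {comp.ci_high:.3f})  "
      f"P = {comp.p_value:.4f}")

perf = m.perf_by_stratum(ds, "DM", "overall")
print(f"DM sensitivity {100 * perf.sensitivity:.1f}%  "
      f"specificity {100 * perf.specificity:.1f}%")
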