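"""Run the whole survey pipeline and write the report bundle.

One call chains: simulate -> profile -> scan+filter -> per-group survey
statistics -> NJ phylogeny -> reference-anchored clades -> per-clade
consensus logos -> conserved sites -> clade length comparisons -> report.
"""

from famsurvey import SurveyConfig, run_survey_pipeline
from famsurvey.pipeline import render_report

result = run_survey_pipeline(SurveyConfig(seed=42))

print(f"hits: {len(result.hits)}  rejected: {len(result.rejected_ids)}")
print("\nper-group survey statistics:")
cols = ["group", "percent_with_genes", "count_mode", "pct_N", "pct_middle", "pct_C"]
print(result.group_stats[cols].round(1).to_string(index=False))

print("\nclades:")
for c in result.clades:
    print(f"  {c.clade_name}: {len(c.member_ids)} members "
          f"(groups: {', '.join(c.groups_spanned)})")

paths = render_report(result, "scratch/example_report")
print(f"\nreport bundle: {sorted(paths)}")
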