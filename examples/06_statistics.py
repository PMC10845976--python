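"""Box summaries and pairwise t-tests of clade protein lengths.

The survey compares full protein lengths between clades with notched Tukey
box statistics and pooled-variance t-tests (p < 0.05 significant,
p < 0.001 highly significant; a Bonferroni column is included for
transparency).
"""

from famsurvey import SurveyConfig, run_survey_pipeline
from famsurvey.stats import box_summary

result = run_survey_pipeline(SurveyConfig(seed=42))

print("clade protein-length box summaries:")
for name, box in sorted(result.length_boxes.items()):
    print(f"  {name}: n={box['n']}  median={box['median']:.0f}  "
          f"IQR=[{box['q1']:.0f}, {box['q3']:.0f}]  outliers={len(box['outliers'])}")

print("\npairwise t-tests (protein length):")
cols = ["group_a", "group_b", "t", "p", "significant", "p_bonferroni"]
print(result.length_ttests[cols].round(4).to_string(index=False))
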