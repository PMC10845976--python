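"""Per-clade consensus logos, conserved sites, and motif-block recovery.

Within a clade, column information content (log2 20 minus entropy, bits)
and the modal residue summarize conservation. Across clades, sites where
every clade is conserved -- and dominant sites where all clades agree on
the residue -- mirror a kingdom-wide logo comparison. The three motif
blocks become identifiable at kingdom depth, where the linker saturates.
"""

import numpy as np

from famsurvey import SurveyConfig, run_survey_pipeline
from famsurvey.consensus import call_conserved_sites
from famsurvey.pipeline import motif_block_study

result = run_survey_pipeline(SurveyConfig(seed=42))

for name, logo in sorted(result.logos.items()):
    print(f"{name}: {logo.n_members} members, "
          f"mean ic {logo.ic.mean():.2f} bits, "
          f"min occupancy {logo.occupancy.min():.2f}")

report = call_conserved_sites(list(result.logos.values()))
print(f"\nconserved sites (all clades >= 2 bits): {len(report.positions)}")
print(f"dominant sites (same residue everywhere):  {len(report.dominant_positions)}")

planted, recovered = motif_block_study(seed=42)
print("\nmotif-block recovery at kingdom depth (20 clades, deep divergence):")
print(f"  planted:   {planted}")
print(f"  recovered: {recovered}")
offs = [abs(r - p) for pb, rb in zip(planted, recovered) for p, r in zip(pb, rb)]
print(f"  max boundary offset: {max(offs)} columns")
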