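"""Coordinate cleaning and name reconciliation against the backbones.

Reports the per-step cleaning tallies and the checklist-comparison table
(shared / synonymous / not-found) for both backbones.
"""

import pandas as pd

from karstflora.pipeline import PipelineConfig, run_stage

CFG = PipelineConfig(outdir="results/pipeline", seed=0)

if __name__ == "__main__":
    run_stage("clean", CFG)
    clean = pd.read_csv(CFG.out / "clean_report.csv")
    lost = clean.loc[clean["step"] == "percent_lost", "count"].iloc[0]
    print(f"coordinate cleaning lost {lost}% of records")
    cong = pd.read_csv(CFG.out / "congruence_report.csv")
    print("checklist congruence (percent of verbatim names):")
    print(cong.pivot(index="class", columns="backbone", values="percent"))
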