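"""IUCN cross-tabulation and the extent summary table, plus the final
report bundle.
"""

import pandas as pd

from karstflora.pipeline import PipelineConfig, run_stage

CFG = PipelineConfig(outdir="results/pipeline", seed=0)

if __name__ == "__main__":
    run_stage("conservation", CFG)
    run_stage("report", CFG)
    summary = pd.read_csv(CFG.out / "summary_table.csv", header=[0, 1],
                          index_col=0)
    print("extent summary (value / % of landscape total):")
    print(summary.to_string())
    tab = pd.read_csv(CFG.out / "conservation_crosstab.csv", header=[0, 1],
                      index_col=0)
    print("\nIUCN cross-tabulation:")
    print(tab.to_string())
    print(f"\nfull report bundle: {CFG.out / 'report.txt'}")
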