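"""Project records, build the 50/10 km grids and the three extents.

The NBZ karst map is buffered by 5 km into BZ5 (compensating for the
5 km coordinate uncertainty on half the records) and the study area is
the bounding box of the karst.
"""

import json

from karstflora.pipeline import PipelineConfig, run_stage

CFG = PipelineConfig(outdir="results/pipeline", seed=0)

if __name__ == "__main__":
    run_stage("grid", CFG)
    with open(CFG.out / "grid.json") as fh:
        grid = json.load(fh)
    areas = grid["areas_km2"]
    total = CFG.synthetic.width_km * CFG.synthetic.height_km
    for label, area in areas.items():
        print(f"{label:11s} {area:10.0f} km^2  ({100 * area / total:.1f}% "
              f"of the landscape)")
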