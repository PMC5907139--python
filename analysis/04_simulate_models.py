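"""Simulate the Boolean scaffold of every DUSP with known regulation.

Clamps Herceptin ON from t = 0, runs each model to its attractor and
compares the node pattern classes against the stated qualitative outcomes
(DUSP2/4/5 oscillate, DUSP1 decays after an initial plateau, Survival stays
ON). Exports heatmaps and the outcome table.
"""

from pathlib import Path

import pandas as pd

from duspboolnet.engine import Trajectory, export_heatmap, symbol_string
from duspboolnet.models import (
    INFERENCE_TARGETS,
    MODELLED_DUSPS,
    build_model,
    simulate_model,
)

OUT = Path(__file__).resolve().parents[1] / "results"


def main():
    OUT.mkdir(exist_ok=True)
    rows = []
    for dusp in MODELLED_DUSPS:
        if dusp in INFERENCE_TARGETS:
            continue
        model = build_model(dusp)
        attractor, classes = simulate_model(model, herceptin=1)
        traj = Trajectory(
            states=attractor.transient + attractor.cycle,
            mode="sync",
            clamps={"Herceptin": 1, "Basal": 1},
        )
        export_heatmap(traj, OUT / f"model_{dusp}")
        sym = symbol_string(attractor.values(dusp), compress=True)
        for node, expected in model.expected.items():
            rows.append(
                dict(dusp=dusp, node=node, expected=expected,
                     observed=classes[node], agrees=classes[node] == expected)
            )
        print(f"{dusp}: {classes[dusp]} (pattern {sym}), "
              f"Survival {classes['Survival']}, "
              f"transient {attractor.transient_length}, "
              f"cycle {attractor.cycle_length}")
    outcome = pd.DataFrame(rows)
    outcome.to_csv(OUT / "model_outcomes.tsv", sep="\t", index=False)
    n_ok = int(outcome["agrees"].sum())
    print(f"{n_ok}/{len(outcome)} expected qualitative outcomes reproduced")


if __name__ == "__main__":
    main()
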