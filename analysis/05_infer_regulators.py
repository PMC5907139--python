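"""Infer the unknown inducing kinases of DUSP3, DUSP9, DUSP16 and DUSP23.

For each target, every non-empty OR-combination of {ERK, JNK, p38} is
simulated and scored against the experimental pattern descriptor: the
cluster descriptor when the DUSP clustered, its own series pattern when it
did not (DUSP16). JNK↔p38-symmetric hypotheses are reported as one class.
"""

import json
from pathlib import Path

import pandas as pd

from duspboolnet.clustering import (
    UNCLUSTERED,
    assign_patterns,
    cluster,
    correlation_matrix,
)
from duspboolnet.inference import (
    infer_regulators,
    report_to_dict,
    top_symmetry_classes,
)
from duspboolnet.models import INFERENCE_TARGETS
from duspboolnet.pipeline import DEFAULT_CUT_HEIGHT
from duspboolnet.qpcr import frame_to_series

OUT = Path(__file__).resolve().parents[1] / "results"


def main():
    frame = pd.read_csv(OUT / "expression_series.tsv", sep="\t")
    series = frame_to_series(frame)
    asg = cluster(correlation_matrix(series), DEFAULT_CUT_HEIGHT)
    patterns = assign_patterns(series, asg)

    payload = {}
    for dusp in INFERENCE_TARGETS:
        cid = asg.assignment.get(dusp, UNCLUSTERED)
        exp = patterns[cid] if cid != UNCLUSTERED else patterns[dusp]
        reports = infer_regulators(dusp, exp)
        tops = [
            "{" + ", ".join(sorted("+".join(sorted(m)) for m in cls)) + "}"
            for cls in top_symmetry_classes(reports)
        ]
        payload[dusp] = {
            "experimental_pattern": exp,
            "ranking": [report_to_dict(r) for r in reports],
            "top_classes": tops,
        }
        print(f"{dusp} (pattern {exp}): top symmetry class(es) {', '.join(tops)}")
    with open(OUT / "inference.json", "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
    print(f"wrote {OUT / 'inference.json'}")


if __name__ == "__main__":
    main()
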