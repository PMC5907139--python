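"""ΔΔCT fold-change time courses from the CT table.

Normalizes every gene against the mean of Actinb and GAPDH per replicate,
references each time point to the untreated t = 0 sample, and tests each
time point against the control (Welch, two-sided). Writes the series table.
"""

from pathlib import Path

import pandas as pd

from duspboolnet.qpcr import process_ct_table, series_frame

OUT = Path(__file__).resolve().parents[1] / "results"


def main():
    table = pd.read_csv(OUT / "ct_table.csv")
    series = process_ct_table(table)
    frame = series_frame(series)
    frame.to_csv(OUT / "expression_series.tsv", sep="\t", index=False)
    n_sig = int(frame["significant"].sum())
    n_rows = len(frame)
    print(f"wrote {OUT / 'expression_series.tsv'}: {len(series)} genes, "
          f"{n_sig}/{n_rows} gene×time points significant vs t=0 (p < 0.05)")


if __name__ == "__main__":
    main()
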