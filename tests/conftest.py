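import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")

from duspboolnet.engine import parse_rules


@pytest.fixture
def toggle_net():
    return parse_rules("A* = not A\n")


@pytest.fixture
def feedback_net():
    """Two-node negative feedback loop: ERK* = not D, D* = ERK."""
    return parse_rules("ERK* = not D\nD* = ERK\n")


@pytest.fixture
def dusp5_loop():
    return parse_rules(
        "#input: Basal\nERK* = Basal and not DUSP5\nDUSP5* = ERK\n"
    )


def make_ct_table(gene_cts, ref_ct=15.0, times=(0, 2, 4), reps=((1, 1),)):
    """Tidy CT table: gene_cts maps gene -> CT per time; references constant."""
    rows = []
    for gene, cts in gene_cts.items():
        for t, ct in zip(times, cts):
            for b, r in reps:
                rows.append(
                    dict(gene=gene, time_h=float(t), bio_rep=b, tech_rep=r, ct=ct)
                )
    for ref in ("Actinb", "GAPDH"):
        for t in times:
            for b, r in reps:
                rows.append(
                    dict(gene=ref, time_h=float(t), bio_rep=b, tech_rep=r, ct=ref_ct)
                )
    return pd.DataFrame(rows)


@pytest.fixture
def ct_table_factory():
    return make_ct_table


class FakeSeries:
    """Minimal series object for clustering tests."""

    def __init__(self, fold_change, times=None):
        self.fold_change = np.asarray(fold_change, dtype=float)
        self.times = (
            np.arange(len(self.fold_change), dtype=float)
            if times is None
            else np.asarray(times, dtype=float)
        )


@pytest.fixture
def fake_series():
    return FakeSeries
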