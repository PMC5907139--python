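"""ΔΔCT processing of qPCR threshold-cycle tables.

Input is a tidy CT table with columns ``gene, time_h, bio_rep, tech_rep, ct``
containing the target genes and the two reference genes (Actinb, GAPDH) at
every (time, replicate).  Per replicate,

    ΔCT(t)  = CT_target(t) − mean(CT_Actinb(t), CT_GAPDH(t))
    ΔΔCT(t) = ΔCT(t) − mean over control replicates of ΔCT(t0)
    fold    = 2^(−ΔΔCT)

ΔΔCT is propagated per replicate (not on averaged CTs) so that replicate
spread survives into the reported standard errors.  The point estimate per
time is the geometric mean of the replicate fold changes, which makes
fold(t0) = 1 exactly by construction; the SE is the standard error of the
replicate fold changes.  Significance versus the untreated control uses a
two-sided Welch t-test on the per-replicate −ΔΔCT (log2 fold) values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "REFERENCE_GENES",
    "TIME_POINTS_H",
    "ExpressionSeries",
    "delta_delta_ct",
    "summarize_replicates",
    "test_vs_control",
    "process_ct_table",
    "series_frame",
]

REFERENCE_GENES = ("Actinb", "GAPDH")
TIME_POINTS_H = (0, 2, 4, 12, 24)

REQUIRED_COLUMNS = ("gene", "time_h", "bio_rep", "tech_rep", "ct")


@dataclass
class ExpressionSeries:
    """Control-normalized fold-change time course for one gene."""

    gene: str
    times: np.ndarray
    fold_change: np.ndarray  # geometric mean over replicates; 1.0 at control
    se: np.ndarray
    p_vs_control: np.ndarray  # NaN at the control time
    n: np.ndarray
    replicate_folds: dict = field(default_factory=dict)  # time -> array

    def log10_values(self) -> np.ndarray:
        return np.log10(self.fold_change)


def _validate(records: pd.DataFrame):
    missing = [c for c in REQUIRED_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"CT table lacks column(s): {missing}")
    if not np.all(np.isfinite(records["ct"])) or (records["ct"] <= 0).any():
        raise ValueError("CT values must be finite and > 0")


def _ref_ct(records: pd.DataFrame, refs) -> pd.DataFrame:
    """Mean reference CT per (time, bio_rep, tech_rep)."""
    ref = records[records["gene"].isin(refs)]
    for r in refs:
        if r not in set(ref["gene"]):
            raise ValueError(f"reference gene {r!r} missing from CT table")
    wide = ref.pivot_table(
        index=["time_h", "bio_rep", "tech_rep"], columns="gene", values="ct"
    )
    if wide[list(refs)].isna().any().any():
        raise ValueError("a reference gene is missing at some (time, replicate)")
    return wide[list(refs)].mean(axis=1).rename("ref_ct")


def delta_delta_ct(
    records: pd.DataFrame,
    gene: str,
    refs=REFERENCE_GENES,
    control_time: float = 0,
) -> ExpressionSeries:
    """ΔΔCT fold-change series for one gene, replicates propagated."""
    _validate(records)
    ref_ct = _ref_ct(records, refs)
    target = records[records["gene"] == gene]
    if target.empty:
        raise ValueError(f"gene {gene!r} not present in CT table")
    merged = target.set_index(["time_h", "bio_rep", "tech_rep"]).join(
        ref_ct, how="left"
    )
    if merged["ref_ct"].isna().any():
        raise ValueError(
            f"missing reference CT for some replicate of gene {gene!r}"
        )
    merged = merged.reset_index()
    merged["dct"] = merged["ct"] - merged["ref_ct"]
    ctrl = merged[merged["time_h"] == control_time]["dct"]
    if ctrl.empty:
        raise ValueError(
            f"control time {control_time} absent for gene {gene!r}"
        )
    merged["ddct"] = merged["dct"] - ctrl.mean()
    merged["fold"] = 2.0 ** (-merged["ddct"])

    times = np.array(sorted(merged["time_h"].unique()))
    fold, se, ns, pvals = [], [], [], []
    rep_folds = {}
    ctrl_log2 = -merged.loc[merged["time_h"] == control_time, "ddct"].to_numpy()
    for t in times:
        sub = merged[merged["time_h"] == t]
        folds = sub["fold"].to_numpy()
        rep_folds[float(t)] = folds
        _, s = summarize_replicates(folds)
        # geometric mean via mean ΔCT − mean control ΔCT: at the control
        # time the two means are the same numbers, so fold is exactly 1
        fold.append(float(2.0 ** -(sub["dct"].mean() - ctrl.mean())))
        se.append(s)
        ns.append(len(folds))
        if t == control_time or len(folds) < 2 or ctrl_log2.size < 2:
            pvals.append(np.nan)  # control itself, or too few replicates
        else:
            p, _ = test_vs_control(-sub["ddct"].to_numpy(), ctrl_log2)
            pvals.append(p)
    return ExpressionSeries(
        gene=gene,
        times=times,
        fold_change=np.array(fold),
        se=np.array(se),
        p_vs_control=np.array(pvals),
        n=np.array(ns),
        replicate_folds=rep_folds,
    )


def summarize_replicates(values) -> tuple[float, float]:
    """Mean and standard error (sd/√n, ddof=1) of replicate values."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("no replicate values")
    if values.size == 1:
        return float(values[0]), float("nan")
    return float(values.mean()), float(
        values.std(ddof=1) / np.sqrt(values.size)
    )


def test_vs_control(values, control, alpha: float = 0.05) -> tuple[float, bool]:
    """Two-sided Welch t-test of replicate values against the control group.

    Returns (p, significant).  Two identical zero-variance groups get p = 1
    by convention.
    """
    values = np.asarray(values, dtype=float)
    control = np.asarray(control, dtype=float)
    if values.size < 2 or control.size < 2:
        raise ValueError("need >= 2 replicates in each group")
    if values.std() == 0 and control.std() == 0:
        p = 1.0 if values.mean() == control.mean() else 0.0
    else:
        p = float(stats.ttest_ind(values, control, equal_var=False).pvalue)
    return p, bool(p < alpha)


def process_ct_table(
    records: pd.DataFrame, refs=REFERENCE_GENES, control_time: float = 0
) -> dict[str, ExpressionSeries]:
    """ΔΔCT series for every non-reference gene in the table."""
    _validate(records)
    genes = [g for g in records["gene"].unique() if g not in refs]
    return {
        g: delta_delta_ct(records, g, refs=refs, control_time=control_time)
        for g in genes
    }


def series_frame(series: dict[str, ExpressionSeries]) -> pd.DataFrame:
    """Long-format table (gene, time_h, fold_change, se, p, significant, n)."""
    rows = []
    for gene, s in series.items():
        for i, t in enumerate(s.times):
            p = s.p_vs_control[i]
            rows.append(
                {
                    "gene": gene,
                    "time_h": float(t),
                    "fold_change": s.fold_change[i],
                    "se": s.se[i],
                    "p": p,
                    "significant": bool(p < 0.05) if np.isfinite(p) else False,
                    "n": int(s.n[i]),
                }
            )
    return pd.DataFrame(rows)


def frame_to_series(df: pd.DataFrame) -> dict[str, ExpressionSeries]:
    """Rebuild ExpressionSeries point estimates from a series table
    (replicate-level detail is not recoverable)."""
    out = {}
    for gene, sub in df.groupby("gene", sort=False):
        sub = sub.sort_values("time_h")
        out[gene] = ExpressionSeries(
            gene=gene,
            times=sub["time_h"].to_numpy(),
            fold_change=sub["fold_change"].to_numpy(),
            se=sub["se"].to_numpy(),
            p_vs_control=sub["p"].to_numpy(),
            n=sub["n"].to_numpy(),
        )
    return out
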