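"""Filtering, median-of-ratios size-factor normalization and small utilities.

Counts live in a pandas DataFrame (genes x samples, ``gene_id`` index); the
sample sheet in a DataFrame with one row per sample.  Stage labels are a pure
function of (condition, week): controls are "normal", tumor weeks 6/8/10/12
map to hyperplasia, adenoma/MIN, early carcinoma and late carcinoma.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

TUMOR_STAGE_BY_WEEK = {
    6: "hyperplasia",
    8: "adenoma/MIN",
    10: "early carcinoma",
    12: "late carcinoma",
}
# ordinal stage coding used throughout: control -> 0, tumor weeks -> 1..4
STAGE_ORDINAL = {"normal": 0, "hyperplasia": 1, "adenoma/MIN": 2, "early carcinoma": 3, "late carcinoma": 4}


class ZeroLibraryError(ValueError):
    pass


class NoReferenceGeneError(ValueError):
    pass


def read_counts(path: str | Path) -> pd.DataFrame:
    counts = pd.read_csv(path, sep="\t", index_col="gene_id")
    if counts.index.duplicated().any():
        raise ValueError("duplicate gene ids in count matrix")
    if counts.columns.duplicated().any():
        raise ValueError("duplicate sample ids in count matrix")
    if (counts.to_numpy() < 0).any():
        raise ValueError("negative counts")
    return counts


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    sheet = pd.read_csv(path)
    required = {"sample_id", "condition", "week"}
    missing = required - set(sheet.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    return add_stage_labels(sheet)


def add_stage_labels(sheet: pd.DataFrame) -> pd.DataFrame:
    sheet = sheet.copy()
    bad = ~sheet["condition"].isin(["tumor", "control"])
    if bad.any():
        raise ValueError(f"unknown condition values: {sheet.loc[bad, 'condition'].unique()}")
    sheet["stage"] = [
        TUMOR_STAGE_BY_WEEK[w] if c == "tumor" else "normal"
        for c, w in zip(sheet["condition"], sheet["week"])
    ]
    sheet["stage_ord"] = sheet["stage"].map(STAGE_ORDINAL)
    return sheet


def read_truth(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene_id", keep_default_na=False)


def filter_low_expression(counts: pd.DataFrame, cpm_threshold: float = 1.0) -> pd.DataFrame:
    """Drop transcriptionally inactive genes.

    A gene is removed iff its counts-per-million fall below ``cpm_threshold``
    in strictly more than half of the samples.  Library sizes are column sums
    of the input matrix, before any gene removal; retained gene order is
    preserved.
    """
    if counts.shape[1] < 2:
        raise ValueError("need at least 2 samples to filter")
    lib = counts.sum(axis=0)
    zero = lib[lib <= 0]
    if len(zero):
        raise ZeroLibraryError(f"sample(s) with zero library size: {list(zero.index)}")
    cpm = counts * 1e6 / lib
    n_below = (cpm < cpm_threshold).sum(axis=1)
    keep = n_below <= counts.shape[1] / 2
    return counts.loc[keep]


def estimate_size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    s_j = median over reference genes of count_gj / geomean_g, where the
    reference set is genes with no zero count (positive geometric mean).
    """
    x = counts.to_numpy(dtype=float)
    ref = (x > 0).all(axis=1)
    if not ref.any():
        raise NoReferenceGeneError(
            "no gene has all-positive counts; consider adding a pseudo-count "
            "before estimating size factors (not applied automatically)"
        )
    logx = np.log(x[ref])
    log_geomean = logx.mean(axis=1)
    ratios = np.exp(logx - log_geomean[:, None])
    s = np.median(ratios, axis=0)
    return pd.Series(s, index=counts.columns, name="size_factor")


@dataclass
class NormalizedMatrix:
    """Size-factor-normalized expression with a log2(x + 1) view."""

    values: pd.DataFrame
    log_pseudocount: float = 1.0

    @property
    def log2(self) -> pd.DataFrame:
        return np.log2(self.values + self.log_pseudocount)

    @property
    def gene_ids(self):
        return self.values.index

    @property
    def sample_ids(self):
        return self.values.columns


def normalize(counts: pd.DataFrame, size_factors: pd.Series) -> NormalizedMatrix:
    """Divide each sample's counts by its size factor."""
    if not counts.columns.equals(size_factors.index):
        size_factors = size_factors.reindex(counts.columns)
        if size_factors.isna().any():
            raise ValueError("size factors do not cover all samples")
    return NormalizedMatrix(counts / size_factors)


def ddct_fold_change(
    ct_target_case: float,
    ct_ref_case: float,
    ct_target_ctrl: float,
    ct_ref_ctrl: float,
) -> float:
    """Relative qPCR fold change by the 2^-ddCt method.

    dCt = Ct(target) - Ct(reference gene) in each of case and control;
    fold change = 2^-(dCt_case - dCt_ctrl).
    """
    cts = (ct_target_case, ct_ref_case, ct_target_ctrl, ct_ref_ctrl)
    if not all(math.isfinite(c) for c in cts):
        raise ValueError("non-finite Ct value")
    ddct = (ct_target_case - ct_ref_case) - (ct_target_ctrl - ct_ref_ctrl)
    return 2.0 ** (-ddct)


def write_size_factors(s: pd.Series, path: str | Path) -> None:
    s.rename_axis("sample_id").to_csv(path)
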