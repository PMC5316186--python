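"""Monotonic expression-trend clustering along tumor progression.

The genes with the highest |loading| on a chosen PC (default PC1, top 1,000)
are summarized by relative expression ratios: mean tumor normalized expression
at weeks 8, 10 and 12 divided by the week-6 mean.  Ratio vectors are grouped
by k-means over a scanned k range; the k at the elbow of the total
within-cluster sum-of-squares (WSS) curve — operationalized as the maximal
discrete second difference over interior k — is chosen unless overridden.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .pca import PCAResult
from .preprocess import NormalizedMatrix

logger = logging.getLogger(__name__)

RATIO_WEEKS = (8, 10, 12)


def select_trend_genes(pca: PCAResult, n: int = 1000, component: str = "PC1") -> list[str]:
    """The n genes with largest absolute loading on ``component``."""
    load = pca.loadings[component].abs()
    if n > len(load):
        warnings.warn(f"requested {n} genes but only {len(load)} have loadings; using all")
        n = len(load)
    order = load.sort_values(ascending=False, kind="stable")
    return list(order.index[:n])


@dataclass
class TrendClustering:
    ratios: pd.DataFrame   # genes x (ratio_w8, ratio_w10, ratio_w12)
    labels: pd.Series      # gene -> cluster (for chosen k)
    wss: dict[int, float]  # k -> total within-cluster SS
    chosen_k: int


def choose_k_by_elbow(wss: dict[int, float]) -> int:
    """Elbow = interior k maximizing WSS(k-1) - 2 WSS(k) + WSS(k+1)."""
    ks = sorted(wss)
    if len(ks) < 3:
        return ks[-1] if ks else 1
    interior = ks[1:-1]
    second_diff = {k: wss[k - 1] - 2 * wss[k] + wss[k + 1] for k in interior if (k - 1 in wss and k + 1 in wss)}
    if not second_diff:
        return ks[-1]
    return max(second_diff, key=lambda k: (second_diff[k], -k))


def compute_ratios(norm: NormalizedMatrix, sheet: pd.DataFrame, genes: list[str]) -> pd.DataFrame:
    """Mean tumor normalized expression at weeks 8/10/12 over the week-6 mean.

    Ratios are taken on the linear normalized scale.  Genes whose week-6 tumor
    mean is zero are dropped with a logged reason.
    """
    tumor = sheet[sheet["condition"] == "tumor"]
    means = {}
    for week in (6, *RATIO_WEEKS):
        cols = tumor.loc[tumor["week"] == week, "sample_id"].tolist()
        if not cols:
            raise ValueError(f"no tumor samples at week {week}")
        means[week] = norm.values.loc[genes, cols].mean(axis=1)
    base = means[6]
    keep = base > 0
    if (~keep).any():
        logger.warning("dropping %d gene(s) with zero week-6 tumor mean", int((~keep).sum()))
    ratios = pd.DataFrame(
        {f"ratio_w{w}": means[w][keep] / base[keep] for w in RATIO_WEEKS}
    )
    ratios.index.name = "gene_id"
    return ratios


def trend_cluster(
    norm: NormalizedMatrix,
    sheet: pd.DataFrame,
    genes: list[str],
    k_range: range = range(1, 11),
    seed: int = 0,
    n_restarts: int = 10,
    k_override: int | None = None,
) -> TrendClustering:
    """k-means over ratio vectors with elbow-based (or manual) choice of k."""
    ratios = compute_ratios(norm, sheet, genes)
    x = ratios.to_numpy(dtype=float)
    wss: dict[int, float] = {}
    labels_by_k: dict[int, np.ndarray] = {}
    for k in sorted(k_range):
        if k > len(ratios):
            break
        km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
        lab = km.fit_predict(x)
        wss[k] = float(km.inertia_)
        labels_by_k[k] = lab
    if not wss:
        raise ValueError("empty k range")
    chosen = k_override if k_override is not None else choose_k_by_elbow(wss)
    if chosen not in labels_by_k:
        raise ValueError(f"chosen k={chosen} outside the scanned range {sorted(wss)}")
    return TrendClustering(
        ratios=ratios,
        labels=pd.Series(labels_by_k[chosen], index=ratios.index, name="cluster"),
        wss=wss,
        chosen_k=chosen,
    )
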