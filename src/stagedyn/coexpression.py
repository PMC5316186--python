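"""Signed co-expression network, modules, eigengenes and permutation tests.

The network is built from Pearson correlations of log-normalized expression:
signed adjacency a_ij = ((1 + cor_ij)/2)^beta maps correlation -1 -> 0 and
+1 -> 1 so anti-correlated genes are unconnected.  The topological overlap
measure TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)
smooths adjacency by shared neighborhoods and 1 - TOM serves as the
clustering dissimilarity.  Modules come from average-linkage hierarchical
clustering with a static cut; each module is summarized by its eigengene (PC1
of the standardized member submatrix), tested for association with ordinal
tumor stage by a Spearman label-permutation test, and scored for preservation
in an independent expression set by a simplified two-statistic Z-summary
(module density and intramodular-connectivity correlation against random
same-size gene sets; > 2 moderate, > 10 high preservation).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import permutations as iter_permutations

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import rankdata

logger = logging.getLogger(__name__)


@dataclass
class NetworkModel:
    genes: list[str]
    correlation: np.ndarray
    adjacency: np.ndarray     # zero diagonal
    tom: np.ndarray           # unit diagonal
    beta: float

    @property
    def connectivity(self) -> np.ndarray:
        return self.adjacency.sum(axis=1)


def build_network(log_expr: pd.DataFrame, beta: float = 12.0) -> NetworkModel:
    """Signed adjacency and TOM from a genes x samples log-expression matrix.

    Zero-variance genes are dropped with a logged reason; beta must be > 0.
    """
    if beta <= 0:
        raise ValueError("soft power beta must be > 0")
    if log_expr.shape[1] < 4:
        raise ValueError("need at least 4 samples to build a network")
    x = log_expr.to_numpy(dtype=float)
    sd = x.std(axis=1)
    keep = sd > 0
    if (~keep).any():
        logger.warning("dropping %d zero-variance gene(s) from the network", int((~keep).sum()))
        x = x[keep]
    genes = list(log_expr.index[keep])
    cor = np.corrcoef(x)
    cor = np.clip(cor, -1.0, 1.0)
    adj = ((1.0 + cor) / 2.0) ** beta
    np.fill_diagonal(adj, 0.0)
    tom = tom_from_adjacency(adj)
    return NetworkModel(genes=genes, correlation=cor, adjacency=adj, tom=tom, beta=beta)


def tom_from_adjacency(adjacency: np.ndarray) -> np.ndarray:
    """Topological overlap matrix of a symmetric adjacency in [0, 1].

    TOM_ij = (sum_{u != i,j} a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij);
    the diagonal is set to 1.
    """
    adj = adjacency.copy()
    np.fill_diagonal(adj, 0.0)
    k = adj.sum(axis=1)
    numerator = adj @ adj + adj
    denominator = np.minimum.outer(k, k) + 1.0 - adj
    tom = numerator / denominator
    np.fill_diagonal(tom, 1.0)
    return tom


def tom_bruteforce(adjacency: np.ndarray) -> np.ndarray:
    """Triple-loop TOM oracle (small inputs only)."""
    a = adjacency.copy()
    np.fill_diagonal(a, 0.0)
    m = a.shape[0]
    k = a.sum(axis=1)
    tom = np.eye(m)
    for i in range(m):
        for j in range(m):
            if i == j:
                continue
            shared = sum(a[i, u] * a[u, j] for u in range(m) if u != i and u != j)
            tom[i, j] = (shared + a[i, j]) / (min(k[i], k[j]) + 1.0 - a[i, j])
    return tom


@dataclass
class ModuleSet:
    """Gene -> module assignment; module 0 is unassigned/grey.

    Modules are labeled 1, 2, ... by decreasing size.
    """

    assignment: pd.Series
    cut_height: float
    min_size: int

    def modules(self) -> list[int]:
        return sorted(m for m in self.assignment.unique() if m != 0)

    def members(self, module: int) -> list[str]:
        return list(self.assignment.index[self.assignment == module])

    def sizes(self) -> pd.Series:
        return self.assignment[self.assignment != 0].value_counts().sort_index()


def detect_modules(net: NetworkModel, cut_height: float = 0.8, min_size: int = 30) -> ModuleSet:
    """Average-linkage clustering on 1 - TOM with a static cut."""
    dism = 1.0 - net.tom
    np.fill_diagonal(dism, 0.0)
    dism = (dism + dism.T) / 2.0
    z = linkage(squareform(dism, checks=False), method="average")
    raw = fcluster(z, t=cut_height, criterion="distance")
    counts = pd.Series(raw).value_counts()
    # order surviving clusters by decreasing size (ties by original label)
    big = [c for c in counts.index if counts[c] >= min_size]
    big.sort(key=lambda c: (-counts[c], c))
    relabel = {c: i + 1 for i, c in enumerate(big)}
    labels = np.array([relabel.get(c, 0) for c in raw])
    if not big:
        warnings.warn("no module reached the minimum size; all genes unassigned")
    return ModuleSet(
        assignment=pd.Series(labels, index=net.genes, name="module"),
        cut_height=cut_height,
        min_size=min_size,
    )


def module_eigengene(log_expr: pd.DataFrame, members: list[str]) -> tuple[pd.Series, float]:
    """Module eigengene: PC1 over samples of the standardized member submatrix.

    Returns (eigengene with unit variance across samples, variance explained).
    The sign is aligned so the eigengene correlates non-negatively with the
    module's mean standardized profile.  Constant genes are dropped.
    """
    if len(members) < 2:
        raise ValueError("module eigengene needs at least 2 genes")
    x = log_expr.loc[members].to_numpy(dtype=float)
    sd = x.std(axis=1, ddof=1)
    keep = sd > 0
    if (~keep).any():
        logger.warning("dropping %d constant gene(s) from eigengene computation", int((~keep).sum()))
        x = x[keep]
        sd = sd[keep]
    if x.shape[0] < 2:
        raise ValueError("too few non-constant genes for an eigengene")
    z = (x - x.mean(axis=1, keepdims=True)) / sd[:, None]
    u, svals, vt = np.linalg.svd(z, full_matrices=False)
    pc1 = vt[0]
    mean_profile = z.mean(axis=0)
    if np.dot(pc1, mean_profile) < 0:
        pc1 = -pc1
    eig = pc1 / pc1.std(ddof=1)
    var_explained = float(svals[0] ** 2 / (svals**2).sum())
    return pd.Series(eig, index=log_expr.columns, name="eigengene"), var_explained


def intramodular_connectivity(net: NetworkModel, members: list[str]) -> pd.Series:
    """kWithin: each member's summed adjacency to the other members."""
    idx = [net.genes.index(g) for g in members]
    sub = net.adjacency[np.ix_(idx, idx)]
    return pd.Series(sub.sum(axis=1), index=members, name="kWithin")


def hub_genes(net: NetworkModel, modules: ModuleSet, n: int = 20) -> dict[int, list[str]]:
    """Top-n genes per module by intramodular connectivity (ties by gene id)."""
    out: dict[int, list[str]] = {}
    for m in modules.modules():
        kwithin = intramodular_connectivity(net, modules.members(m))
        order = sorted(kwithin.index, key=lambda g: (-kwithin[g], g))
        out[m] = order[: max(n, 0)]
    return out


def _spearman(x: np.ndarray, y: np.ndarray) -> float:
    rx = rankdata(x)
    ry = rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = np.sqrt((rx**2).sum() * (ry**2).sum())
    if denom == 0:
        raise ValueError("constant input; Spearman correlation undefined")
    return float((rx * ry).sum() / denom)


def stage_association_permtest(
    eigengene: pd.Series,
    sheet: pd.DataFrame,
    n_permutations: int = 10_000,
    seed: int = 0,
    exact: bool = False,
) -> tuple[float, float]:
    """Spearman correlation of the eigengene with ordinal tumor stage plus a
    label-permutation p-value.

    Stage coding: control -> 0, tumor weeks 6/8/10/12 -> 1..4.  Two-sided
    empirical p = (1 + #{perm: |rho*| >= |rho|}) / (B + 1).  ``exact=True``
    enumerates all label permutations instead (small n only).
    """
    sheet = sheet.set_index("sample_id").loc[eigengene.index]
    stage = sheet["stage_ord"].to_numpy(dtype=float)
    if len(np.unique(stage)) < 2:
        raise ValueError("need at least 2 distinct stage values")
    e = eigengene.to_numpy(dtype=float)
    if np.std(e) == 0:
        raise ValueError("constant eigengene; correlation undefined")
    rho = _spearman(e, stage)

    re = rankdata(e)
    re = re - re.mean()
    rs = rankdata(stage)
    norm_e = np.sqrt((re**2).sum())
    norm_s = np.sqrt(((rs - rs.mean()) ** 2).sum())
    if exact:
        perms = np.array(list(iter_permutations(rs)))
        n_used = len(perms)
    else:
        rng = np.random.default_rng(seed)
        perms = np.array([rng.permutation(rs) for _ in range(n_permutations)])
        n_used = n_permutations
    rho_star = (perms - rs.mean()) @ re / (norm_e * norm_s)
    n_extreme = int(np.sum(np.abs(rho_star) >= abs(rho) - 1e-12))
    if exact:
        p = n_extreme / n_used
    else:
        p = (1 + n_extreme) / (n_used + 1)
    return rho, float(p)


@dataclass
class PreservationResult:
    table: pd.DataFrame  # module, z_density, z_connectivity, z_summary, flag


def preservation_z(
    ref_net: NetworkModel,
    modules: ModuleSet,
    test_log_expr: pd.DataFrame,
    n_null: int = 200,
    seed: int = 0,
) -> PreservationResult:
    """Simplified module-preservation Z-summary in an independent test set.

    For each module: (i) density = mean within-module adjacency in the test
    network; (ii) correlation between reference and test intramodular
    connectivity.  Each statistic is standardized against ``n_null`` random
    same-size gene sets drawn from the test network; Zsummary is the median of
    the two Z scores.  Flags: 'high' > 10, 'moderate' > 2, else 'low'.
    """
    rng = np.random.default_rng(seed)
    common = [g for g in ref_net.genes if g in test_log_expr.index]
    test_net = build_network(test_log_expr.loc[common], beta=ref_net.beta)
    test_idx = {g: i for i, g in enumerate(test_net.genes)}
    ref_idx = {g: i for i, g in enumerate(ref_net.genes)}
    rows = []
    for m in modules.modules():
        members = [g for g in modules.members(m) if g in test_idx]
        if len(members) < 3:
            warnings.warn(f"module {m} has fewer than 3 genes in the test set; skipped")
            continue
        size = len(members)

        def stats_for(genes: list[str]) -> tuple[float, float]:
            ti = [test_idx[g] for g in genes]
            ri = [ref_idx[g] for g in genes]
            a_test = test_net.adjacency[np.ix_(ti, ti)]
            a_ref = ref_net.adjacency[np.ix_(ri, ri)]
            density = a_test.sum() / (size * (size - 1))
            k_test = a_test.sum(axis=1)
            k_ref = a_ref.sum(axis=1)
            if k_test.std() == 0 or k_ref.std() == 0:
                k_cor = 0.0
            else:
                k_cor = float(np.corrcoef(k_ref, k_test)[0, 1])
            return float(density), k_cor

        obs_density, obs_kcor = stats_for(members)
        null_density = np.empty(n_null)
        null_kcor = np.empty(n_null)
        pool = np.array(test_net.genes)
        for b in range(n_null):
            draw = list(rng.choice(pool, size=size, replace=False))
            null_density[b], null_kcor[b] = stats_for(draw)

        def z(obs: float, null: np.ndarray) -> float:
            sd = null.std(ddof=1)
            if sd == 0:
                return 0.0
            return float((obs - null.mean()) / sd)

        z_density = z(obs_density, null_density)
        z_kcor = z(obs_kcor, null_kcor)
        z_summary = float(np.median([z_density, z_kcor]))
        flag = "high" if z_summary > 10 else ("moderate" if z_summary > 2 else "low")
        rows.append(
            {
                "module": m,
                "density": obs_density,
                "connectivity_cor": obs_kcor,
                "z_density": z_density,
                "z_connectivity": z_kcor,
                "z_summary": z_summary,
                "flag": flag,
            }
        )
    return PreservationResult(table=pd.DataFrame(rows))
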