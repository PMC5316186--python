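"""Per-stage negative-binomial differential expression.

Two-group comparison in the classical conditional exact-test formulation:
counts are scaled to a common effective library (pseudo-counts), a common NB
dispersion is estimated by profile likelihood across genes with per-gene
moment estimates shrunk toward it, and the two-sided p-value is computed
conditionally on the two groups' pseudo-count total.  In the Poisson limit
(phi = 0) the conditional distribution is binomial.

Benjamini-Hochberg adjustment is applied within each stage; a gene is called
differentially expressed when |log2FC| exceeds the fold-change threshold and
the adjusted FDR falls below the cutoff (defaults: fold change > 2,
FDR < 0.05).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import gammaln, logsumexp
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

STAGE_WEEKS = (6, 8, 10, 12)

_PHI_FLOOR = 1e-8


@dataclass
class DispersionModel:
    """Common NB dispersion plus shrunken per-gene ('tagwise') dispersions.

    ``prior_weight`` is the prior mass, in pseudo-gene residual degrees of
    freedom, pulling each gene's method-of-moments estimate toward the common
    value; each tagwise estimate is a convex combination of the two.
    """

    common: float
    tagwise: np.ndarray
    prior_weight: float
    phi_max: float = 10.0


def _nb_loglik(y: np.ndarray, mu: np.ndarray, phi: float) -> float:
    """Summed NB log-likelihood; continuous in y (pseudo-counts need not be integer)."""
    mu = np.maximum(mu, 1e-10)
    if phi < _PHI_FLOOR:
        return float(np.sum(y * np.log(mu) - mu - gammaln(y + 1.0)))
    r = 1.0 / phi
    return float(
        np.sum(
            gammaln(y + r) - gammaln(r) - gammaln(y + 1.0)
            + r * np.log(r / (r + mu))
            + y * np.log(mu / (r + mu) + 1e-300)
        )
    )


def equalize_counts(counts: pd.DataFrame, size_factors: pd.Series) -> pd.DataFrame:
    """Scale counts to a common effective library: count / s_j x geomean(s)."""
    s = size_factors.reindex(counts.columns).to_numpy(dtype=float)
    geomean = np.exp(np.mean(np.log(s)))
    return counts * (geomean / s)


def fit_dispersion(
    pseudo: pd.DataFrame,
    groups: np.ndarray | list,
    prior_weight: float = 10.0,
    phi_max: float = 10.0,
) -> DispersionModel:
    """Estimate common and tagwise NB dispersions from equalized pseudo-counts.

    The common dispersion maximizes the summed NB log-likelihood over all genes
    with group means profiled out (replaced by group sample means).  Per-gene
    method-of-moments estimates phi_g = (s2 - m)/m2 are pooled within groups
    and shrunk toward the common value with ``prior_weight`` pseudo-genes of
    prior mass.  All estimates are clipped to [0, phi_max].
    """
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) != 2:
        raise ValueError("exactly two groups required")
    y = pseudo.to_numpy(dtype=float)
    masks = [groups == g for g in labels]
    for g, m in zip(labels, masks):
        if m.sum() < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples")

    mu = np.empty_like(y)
    group_means = []
    group_sizes = []
    for m in masks:
        gm = y[:, m].mean(axis=1)
        mu[:, m] = gm[:, None]
        group_means.append(gm)
        group_sizes.append(int(m.sum()))

    def neg_ll(log10_phi: float) -> float:
        phi = 10.0 ** log10_phi
        ll = _nb_loglik(y, mu, phi)
        # Cox-Reid adjustment: penalize by half the log Fisher information of
        # each profiled group mean, n_k * mu / (1 + phi * mu); without it the
        # profile likelihood underestimates phi badly at small replicate counts
        for gm, n_k in zip(group_means, group_sizes):
            info = n_k * gm / (1.0 + phi * gm)
            ll -= 0.5 * float(np.sum(np.log(np.maximum(info, 1e-10))))
        return -ll

    res = minimize_scalar(neg_ll, bounds=(-8.0, np.log10(phi_max)), method="bounded")
    common = float(np.clip(10.0 ** res.x, 0.0, phi_max))
    if common <= 10 ** -7.5:  # boundary: Poisson-compatible data
        common = 0.0

    # pooled within-group moments for the per-gene estimate
    num = np.zeros(y.shape[0])
    den = np.zeros(y.shape[0])
    df = 0.0
    for m in masks:
        n_k = int(m.sum())
        mk = y[:, m].mean(axis=1)
        vk = y[:, m].var(axis=1, ddof=1)
        num += (n_k - 1) * (vk - mk)
        den += (n_k - 1) * np.maximum(mk, 1e-10) ** 2
        df += n_k - 1
    phi_mom = np.clip(num / den, 0.0, phi_max)
    tagwise = (prior_weight * common + df * phi_mom) / (prior_weight + df)
    tagwise = np.clip(tagwise, 0.0, phi_max)
    return DispersionModel(common=common, tagwise=tagwise, prior_weight=prior_weight, phi_max=phi_max)


def _conditional_logpmf(s: int, n1: int, n2: int, phi: float) -> np.ndarray:
    """Log-probabilities of splits (a, s-a) of the total s between two groups.

    Group totals are NB convolutions with sizes n_i / phi; conditioning on the
    total cancels the common mean, leaving a negative-hypergeometric form.  At
    phi = 0 the conditional law is Binomial(s, n1/(n1+n2)).
    """
    a = np.arange(s + 1, dtype=float)
    if phi < _PHI_FLOOR:
        pi = n1 / (n1 + n2)
        logw = (
            gammaln(s + 1.0) - gammaln(a + 1.0) - gammaln(s - a + 1.0)
            + a * np.log(pi) + (s - a) * np.log1p(-pi)
        )
    else:
        r1, r2 = n1 / phi, n2 / phi
        logw = (
            gammaln(a + r1) - gammaln(a + 1.0)
            + gammaln(s - a + r2) - gammaln(s - a + 1.0)
        )
    return logw - logsumexp(logw)


def nb_exact_test(
    group1: np.ndarray,
    group2: np.ndarray,
    phi: float,
    prior_count: float = 0.5,
    exact_total_cap: int = 5000,
) -> tuple[float, float]:
    """Two-sided conditional NB exact test on equalized pseudo-counts.

    Returns (log2FC, p).  log2FC = log2((mean1 + c) / (mean2 + c)) with prior
    count c; group totals are rounded half-up to integers for the conditional
    distribution.  The two-sided p sums the probabilities of all splits no more
    likely than the observed one.  Totals above ``exact_total_cap`` use a
    normal approximation to the conditional distribution.
    """
    if phi < 0:
        raise ValueError("dispersion must be non-negative")
    g1 = np.asarray(group1, dtype=float)
    g2 = np.asarray(group2, dtype=float)
    n1, n2 = len(g1), len(g2)
    log2fc = float(np.log2((g1.mean() + prior_count) / (g2.mean() + prior_count)))

    y1 = int(np.floor(g1.sum() + 0.5))  # round half up
    y2 = int(np.floor(g2.sum() + 0.5))
    s = y1 + y2
    if s == 0:
        return log2fc, 1.0

    if s <= exact_total_cap:
        logp = _conditional_logpmf(s, n1, n2, phi)
        obs = logp[y1]
        p = float(np.exp(logsumexp(logp[logp <= obs + 1e-10])))
        if p > 1.0 - 1e-9:  # all splits included; absorb logsumexp round-off
            p = 1.0
        return log2fc, min(p, 1.0)

    # normal approximation: conditional mean s*pi, variance v1*v2/(v1+v2)
    pi = n1 / (n1 + n2)
    mu_hat = s / (n1 + n2)
    v1 = n1 * (mu_hat + phi * mu_hat**2)
    v2 = n2 * (mu_hat + phi * mu_hat**2)
    m = s * pi
    sd = np.sqrt(v1 * v2 / (v1 + v2))
    lo = norm.cdf((y1 + 0.5 - m) / sd)
    hi = norm.sf((y1 - 0.5 - m) / sd)
    return log2fc, float(min(1.0, 2.0 * min(lo, hi)))


@dataclass
class StageContrastTable:
    """Per-gene, per-stage tumor-vs-control contrasts (long format)."""

    table: pd.DataFrame  # columns: gene_id, week, log2fc, pvalue, fdr, is_deg, direction
    lfc_threshold: float = 1.0
    fdr_threshold: float = 0.05

    def lfc_matrix(self) -> pd.DataFrame:
        """genes x weeks matrix of log2 fold changes."""
        return self.table.pivot(index="gene_id", columns="week", values="log2fc")

    def deg_sets(self) -> dict[int, set]:
        return {
            int(w): set(sub.loc[sub["is_deg"], "gene_id"])
            for w, sub in self.table.groupby("week")
        }

    def deg_union(self) -> set:
        out: set = set()
        for s in self.deg_sets().values():
            out |= s
        return out


def call_stage_degs(
    counts: pd.DataFrame,
    size_factors: pd.Series,
    sheet: pd.DataFrame,
    lfc_threshold: float = 1.0,
    fdr_threshold: float = 0.05,
    prior_count: float = 0.5,
    exact_total_cap: int = 5000,
    dispersion_prior_weight: float = 10.0,
) -> StageContrastTable:
    """Run the NB exact test tumor-vs-control at each week, with BH per stage."""
    frames = []
    for week in sorted(sheet["week"].unique()):
        sub = sheet[sheet["week"] == week]
        tumor = sub.loc[sub["condition"] == "tumor", "sample_id"].tolist()
        ctrl = sub.loc[sub["condition"] == "control", "sample_id"].tolist()
        if not tumor or not ctrl:
            raise ValueError(f"week {week} lacks tumor or control samples")
        cols = tumor + ctrl
        pseudo = equalize_counts(counts[cols], size_factors[cols])
        groups = np.array(["tumor"] * len(tumor) + ["control"] * len(ctrl))
        disp = fit_dispersion(pseudo, groups, prior_weight=dispersion_prior_weight)
        y = pseudo.to_numpy(dtype=float)
        t_idx = np.arange(len(tumor))
        c_idx = np.arange(len(tumor), len(cols))
        lfc = np.empty(len(counts))
        pval = np.empty(len(counts))
        for i in range(len(counts)):
            lfc[i], pval[i] = nb_exact_test(
                y[i, t_idx], y[i, c_idx], disp.tagwise[i],
                prior_count=prior_count, exact_total_cap=exact_total_cap,
            )
        fdr = multipletests(pval, method="fdr_bh")[1]
        is_deg = (np.abs(lfc) > lfc_threshold) & (fdr < fdr_threshold)
        direction = np.where(is_deg, np.where(lfc > 0, "up", "down"), "")
        frames.append(
            pd.DataFrame(
                {
                    "gene_id": counts.index,
                    "week": int(week),
                    "log2fc": lfc,
                    "pvalue": pval,
                    "fdr": fdr,
                    "is_deg": is_deg,
                    "direction": direction,
                }
            )
        )
    return StageContrastTable(
        pd.concat(frames, ignore_index=True),
        lfc_threshold=lfc_threshold,
        fdr_threshold=fdr_threshold,
    )


def stage_overlap(table: StageContrastTable) -> dict:
    """Venn partition of DEG sets across the four stages plus summary counts."""
    sets = table.deg_sets()
    weeks = sorted(sets)
    union: set = set()
    for s in sets.values():
        union |= s
    venn: dict[str, int] = {}
    for r in range(1, len(weeks) + 1):
        for combo in combinations(weeks, r):
            inside = set.intersection(*(sets[w] for w in combo)) if combo else set()
            outside = set.union(*(sets[w] for w in weeks if w not in combo), set())
            venn["&".join(f"w{w}" for w in combo)] = len(inside - outside)
    all_four = set.intersection(*(sets[w] for w in weeks)) if weeks else set()
    per_stage = {}
    for w in weeks:
        sub = table.table[(table.table["week"] == w) & table.table["is_deg"]]
        per_stage[f"w{w}"] = {
            "up": int((sub["direction"] == "up").sum()),
            "down": int((sub["direction"] == "down").sum()),
            "total": int(len(sub)),
        }
    return {
        "venn": venn,
        "union": len(union),
        "all_stages_intersection": len(all_four),
        "all_stages_fraction": (len(all_four) / len(union)) if union else 0.0,
        "per_stage": per_stage,
    }
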