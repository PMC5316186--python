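"""Sample PCA on log-normalized expression and covariate association.

PCA is run on the top-variance genes of the log2(normalized + 1) matrix with
per-gene centering, via SVD, with a deterministic sign convention.  Covariate
association regresses each top PC's sample scores on each known covariate:
simple linear regression (slope t-test) for continuous covariates, one-way
ANOVA for categorical ones; entries are -log10 p.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import NormalizedMatrix


@dataclass
class PCAResult:
    scores: pd.DataFrame        # samples x components
    loadings: pd.DataFrame      # genes x components
    variance_ratio: np.ndarray  # non-increasing, sums to <= 1
    zero_variance_input: bool = False


def _fix_signs(scores: np.ndarray, loadings: np.ndarray) -> None:
    """Deterministic sign convention: each loading vector sums >= 0; on a tie
    the first nonzero loading is made positive."""
    for k in range(loadings.shape[1]):
        total = loadings[:, k].sum()
        if total < 0:
            flip = True
        elif total > 0:
            flip = False
        else:
            nz = np.nonzero(loadings[:, k])[0]
            flip = len(nz) > 0 and loadings[nz[0], k] < 0
        if flip:
            loadings[:, k] *= -1
            scores[:, k] *= -1


def compute_pca(norm: NormalizedMatrix, n_top_var_genes: int = 500) -> PCAResult:
    """PCA of samples on the highest-variance genes of the log view."""
    logx = norm.log2
    if logx.shape[1] < 3:
        raise ValueError("PCA needs at least 3 samples")
    variances = logx.var(axis=1, ddof=1)
    n = min(n_top_var_genes, len(variances))
    if n < n_top_var_genes:
        warnings.warn(
            f"requested {n_top_var_genes} top-variance genes but only {n} available; using all"
        )
    top = variances.sort_values(ascending=False, kind="stable").index[:n]
    x = logx.loc[top].to_numpy(dtype=float)
    centered = x - x.mean(axis=1, keepdims=True)
    total_var = float((centered**2).sum())
    if total_var == 0.0:
        k = min(x.shape) if min(x.shape) > 0 else 1
        pcs = [f"PC{i + 1}" for i in range(min(x.shape[1], len(top)))]
        return PCAResult(
            scores=pd.DataFrame(0.0, index=logx.columns, columns=pcs),
            loadings=pd.DataFrame(0.0, index=top, columns=pcs),
            variance_ratio=np.zeros(len(pcs)),
            zero_variance_input=True,
        )
    # SVD of genes x samples centered matrix: U holds loadings, V^T scores
    u, svals, vt = np.linalg.svd(centered, full_matrices=False)
    k = len(svals)
    scores = vt.T * svals  # samples x k
    loadings = u  # genes x k, orthonormal
    _fix_signs(scores, loadings)
    var_ratio = svals**2 / total_var
    pcs = [f"PC{i + 1}" for i in range(k)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=logx.columns, columns=pcs),
        loadings=pd.DataFrame(loadings, index=top, columns=pcs),
        variance_ratio=var_ratio,
    )


@dataclass
class CovariateAssociation:
    neglog10_p: pd.DataFrame  # covariates x PCs
    test_used: dict[str, str] = field(default_factory=dict)
    degenerate: list[str] = field(default_factory=list)


DEFAULT_COVARIATES = ("condition", "stage", "litter", "batch", "age")


def covariate_association(
    pca: PCAResult,
    sheet: pd.DataFrame,
    n_pcs: int = 4,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
) -> CovariateAssociation:
    """-log10 p of regressing each top PC's scores on each covariate."""
    sheet = sheet.set_index("sample_id").loc[pca.scores.index]
    pcs = list(pca.scores.columns[:n_pcs])
    out = pd.DataFrame(0.0, index=list(covariates), columns=pcs)
    tests: dict[str, str] = {}
    degenerate: list[str] = []
    for cov in covariates:
        if cov not in sheet.columns:
            raise ValueError(f"covariate {cov!r} missing from sample sheet")
        values = sheet[cov]
        continuous = pd.api.types.is_numeric_dtype(values) and values.nunique() > 2
        tests[cov] = "linear_regression" if continuous else "anova"
        if values.nunique() < 2:
            degenerate.append(cov)
            continue
        for pc in pcs:
            y = pca.scores[pc].to_numpy(dtype=float)
            if continuous:
                res = stats.linregress(values.to_numpy(dtype=float), y)
                p = res.pvalue
            else:
                groups = [y[values.to_numpy() == lvl] for lvl in values.unique()]
                groups = [g for g in groups if len(g) > 0]
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    p = stats.f_oneway(*groups).pvalue
            if not np.isfinite(p):
                p = 1.0
            out.loc[cov, pc] = -np.log10(max(p, 1e-300))
    return CovariateAssociation(neglog10_p=out, test_used=tests, degenerate=degenerate)
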