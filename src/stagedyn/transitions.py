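"""Inter-stage transition-pattern classification.

For each gene with a full set of four per-stage log2 fold changes R(1..4), the
log-ratio change over transition i is LRC_i = R(i+1) - R(i), i = 1..3
(hyperplasia -> adenoma/MIN -> early carcinoma -> late carcinoma).  Each LRC
column is standardized across genes to a z-score and trinarized against a
threshold tau: +1 if z >= tau, -1 if z <= -tau, else 0.  With three
transitions and three statuses there are 3^3 = 27 possible patterns; the
all-constant pattern (0,0,0) receives group id 14 under the fixed encoding
id = 9*d1 + 3*d2 + d3 + 1 with digit d = status + 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd

from .diffexpr import StageContrastTable

logger = logging.getLogger(__name__)

TRANSITION_NAMES = ("H->N", "N->EC", "EC->LC")
_STATUS_CHAR = {-1: "-", 0: "0", 1: "+"}


def group_id_of(status: tuple[int, int, int]) -> int:
    d = [s + 1 for s in status]
    return 9 * d[0] + 3 * d[1] + d[2] + 1


def pattern_code(status: tuple[int, int, int]) -> str:
    return ",".join(_STATUS_CHAR[s] for s in status)


def enumerate_patterns() -> pd.DataFrame:
    """All 27 status triples with ids, codes and the malignant-transition flag
    (second transition, adenoma/MIN -> early carcinoma, non-constant)."""
    rows = []
    for status in product((-1, 0, 1), repeat=3):
        rows.append(
            {
                "group_id": group_id_of(status),
                "status1": status[0],
                "status2": status[1],
                "status3": status[2],
                "code": pattern_code(status),
                "malignant_transition": status[1] != 0,
            }
        )
    return pd.DataFrame(rows).sort_values("group_id").reset_index(drop=True)


def compute_lrc(contrasts: StageContrastTable, genes=None) -> pd.DataFrame:
    """Per-gene LRC triple from the four stage log2 fold changes.

    Default gene subset: the union of all per-stage DEGs.  Genes missing any
    stage value are dropped with a logged reason.  The triple telescopes:
    lrc1 + lrc2 + lrc3 = R(4) - R(1).
    """
    lfc = contrasts.lfc_matrix()
    if genes is None:
        genes = sorted(contrasts.deg_union())
    genes = [g for g in genes if g in lfc.index]
    sub = lfc.loc[genes]
    complete = sub.notna().all(axis=1)
    if (~complete).any():
        dropped = list(sub.index[~complete])
        logger.warning("dropping %d gene(s) with missing stage log2FC: %s", len(dropped), dropped[:10])
        sub = sub.loc[complete]
    weeks = sorted(sub.columns)
    vals = sub[weeks].to_numpy(dtype=float)
    lrc = np.diff(vals, axis=1)
    return pd.DataFrame(lrc, index=sub.index, columns=["lrc1", "lrc2", "lrc3"])


@dataclass
class TransitionProfileTable:
    """LRC triples, z-scores, trinarized statuses and 27-group ids per gene."""

    table: pd.DataFrame  # lrc1..3, z1..3, status (3-char code), group_id
    tau: float

    def group_counts(self) -> pd.Series:
        return self.table["group_id"].value_counts().sort_index()


def classify_transitions(
    lrc: pd.DataFrame,
    tau: float = 1.0,
    pooled_z: bool = False,
) -> TransitionProfileTable:
    """Standardize LRCs to z-scores and trinarize at +-tau standard deviations.

    z-scores are computed per transition column by default (``pooled_z=True``
    standardizes all three columns against the pooled mean and SD).
    """
    if len(lrc) < 2:
        raise ValueError("need at least 2 genes to compute z-scores")
    x = lrc[["lrc1", "lrc2", "lrc3"]].to_numpy(dtype=float)
    if pooled_z:
        mean, sd = x.mean(), x.std(ddof=1)
        if sd == 0:
            raise ValueError("zero spread in LRCs; provide a larger gene set")
        z = (x - mean) / sd
    else:
        mean = x.mean(axis=0)
        sd = x.std(axis=0, ddof=1)
        if (sd == 0).any():
            bad = [TRANSITION_NAMES[i] for i in np.nonzero(sd == 0)[0]]
            raise ValueError(f"zero SD in transition column(s) {bad}; provide a larger gene set")
        z = (x - mean) / sd
    status = np.where(z >= tau, 1, np.where(z <= -tau, -1, 0))
    codes = [pattern_code(tuple(row)) for row in status]
    gids = [group_id_of(tuple(row)) for row in status]
    table = pd.DataFrame(
        {
            "lrc1": x[:, 0], "lrc2": x[:, 1], "lrc3": x[:, 2],
            "z1": z[:, 0], "z2": z[:, 1], "z3": z[:, 2],
            "status": codes,
            "group_id": gids,
        },
        index=lrc.index,
    )
    return TransitionProfileTable(table=table, tau=tau)
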