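"""Gene-set over-representation by the hypergeometric upper tail.

Gene sets come from GMT files (tab-separated: name, description, members).
For a query of n genes drawn from a universe of N, a set with K members in
the universe and an overlap of x with the query scores
p = P(X >= x), X ~ Hypergeometric(N, K, n), with Benjamini-Hochberg FDR
across sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests


@dataclass
class GeneSetCollection:
    sets: dict[str, set[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)


class GMTParseError(ValueError):
    pass


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file; duplicate members within a set are collapsed."""
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GMTParseError(f"line {lineno}: expected >= 3 tab-separated fields")
            name, desc, *members = fields
            if name in sets:
                raise GMTParseError(f"line {lineno}: duplicate set name {name!r}")
            members = {m for m in members if m}
            if not members:
                raise GMTParseError(f"line {lineno}: set {name!r} has no members")
            sets[name] = members
            descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, members in collection.sets.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *sorted(members)]) + "\n")


def ora_test(
    query: Iterable[str],
    universe: Iterable[str],
    collection: GeneSetCollection,
) -> pd.DataFrame:
    """Hypergeometric over-representation of each set in the query.

    Sets are intersected with the universe before testing; the query must be a
    subset of the universe.
    """
    universe = set(universe)
    query = set(query)
    if not query or not universe:
        raise ValueError("query and universe must be non-empty")
    if not query <= universe:
        raise ValueError("query must be a subset of the universe")
    n_universe, n_query = len(universe), len(query)
    rows = []
    for name, members in collection.sets.items():
        in_universe = members & universe
        overlap = len(in_universe & query)
        k = len(in_universe)
        p = float(hypergeom.sf(overlap - 1, n_universe, k, n_query)) if k else 1.0
        rows.append(
            {
                "set": name,
                "overlap": overlap,
                "set_size": k,
                "query_size": n_query,
                "universe_size": n_universe,
                "pvalue": min(p, 1.0),
            }
        )
    result = pd.DataFrame(rows)
    if len(result):
        result["fdr"] = multipletests(result["pvalue"], method="fdr_bh")[1]
    else:
        result["fdr"] = []
    return result.sort_values("pvalue", kind="stable").reset_index(drop=True)
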