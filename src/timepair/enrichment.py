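"""Hypergeometric over-representation analysis of a query gene set.

Takes any GMT-style collection (e.g. a pathway-database export) and an
explicit gene universe — the universe is a required input because the
choice (all annotated genes vs expressed genes) changes every p value.
No pathway content is bundled.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError


@dataclass
class GeneSetCollection:
    """Named gene sets plus the universe they are tested against.

    Set members outside the universe are ignored at test time.
    """

    sets: dict[str, list[str]]
    universe: set[str]

    def __post_init__(self) -> None:
        if not self.universe:
            raise ValidationError("universe must be non-empty")
        if not self.sets:
            raise ValidationError("collection must contain at least one gene set")


def hypergeometric_ora(query: set[str], collection: GeneSetCollection) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of ``query`` in each set.

    For each set with m genes in the universe, the p value is the
    probability of observing >= k overlapping genes when drawing
    |query| genes from the universe without replacement. Results are
    sorted by ascending p; k = 0 reports p = 1. A Benjamini-Hochberg
    column accompanies the raw p values.
    """
    if not query:
        raise ValidationError("empty query gene set")
    universe = collection.universe
    q = set(query) & universe
    if not q:
        raise ValidationError("query has no genes in the universe")
    n_universe = len(universe)
    n_query = len(q)
    rows = []
    for name, genes in collection.sets.items():
        members = set(genes) & universe
        m = len(members)
        k = len(q & members)
        expected = n_query * m / n_universe
        if k == 0:
            p = 1.0
        else:
            p = float(stats.hypergeom.sf(k - 1, n_universe, m, n_query))
        rows.append(
            {"set": name, "set_size": m, "overlap": k, "expected": expected, "p": p}
        )
    table = pd.DataFrame(rows)
    table["padj"] = multipletests(table["p"].to_numpy(), method="fdr_bh")[1]
    return table.sort_values("p", kind="stable").reset_index(drop=True)
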