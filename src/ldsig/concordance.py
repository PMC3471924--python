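"""Gene-set overlap statistics and cross-species direction-concordance calls.

Overlap: hypergeometric enrichment of a gene list against an annotation set
within a stated gene universe, reporting the overlap fraction as a rounded
percentage (the display convention of the printed overlap table).

Concordance: a gene's strain responses agree with a human comparator when it
is up in the sensitive strain, down or unchanged in the resistant strain and
up in the human set — or the full mirror image.  "No change" means failing
the low-dose list criteria, not a tested equivalence; genes the human set
reports in both directions are never concordant and are counted separately.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import pandas as pd
from scipy import stats

from .data_io import GeneSet

logger = logging.getLogger("ldsig")

__all__ = ["OverlapResult", "ConcordanceCall", "overlap_test", "concordance"]

_DIR_LABEL = {1: "up", -1: "down", 0: "ns"}
_HUMAN_LABEL = {1: "up", -1: "down", 0: "both"}


@dataclass
class OverlapResult:
    k: int
    n_list: int
    fraction: int  # percent, rounded to integer for report
    hypergeom_p: float


@dataclass
class ConcordanceCall:
    gene: str
    dir_sensitive: str  # up / down / ns
    dir_resistant: str  # up / down / ns
    dir_human: str  # up / down / both
    concordant: bool


def overlap_test(gene_list, gene_set: GeneSet, universe: int) -> OverlapResult:
    """Hypergeometric enrichment of ``gene_list`` in ``gene_set``.

    ``universe`` is the size of the assayed gene universe; the upper-tail
    p-value is P(X >= k) for X hypergeometric(universe, |set|, |list|).
    """
    glist = set(gene_list)
    members = set(gene_set.members)
    if universe < len(glist) or universe < len(members):
        raise ValueError("universe smaller than the list or the set")
    k = len(glist & members)
    n_list = len(glist)
    frac = int(round(100 * k / n_list)) if n_list else 0
    p = float(stats.hypergeom.sf(k - 1, universe, len(members), n_list))
    return OverlapResult(k=k, n_list=n_list, fraction=frac, hypergeom_p=p)


def _is_concordant(s: int, r: int, h: int) -> bool:
    if h == 0:
        return False
    return (s == 1 and r in (0, -1) and h == 1) or (s == -1 and r in (0, 1) and h == -1)


def concordance(
    sensitive: Mapping[str, int],
    resistant: Mapping[str, int],
    human: GeneSet,
    categories: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Direction-concordance calls over the genes of a directed human set.

    ``sensitive`` / ``resistant`` map gene symbols to +1/-1 (from the
    low-dose gene lists; genes absent from a map count as no-change).
    ``human`` is a directed gene set whose per-member signs use +1 (up),
    -1 (down) and 0 (reported in both directions).  Symbols are compared
    case-folded across species.  Returns one row per human-set gene with the
    three direction labels, the concordance flag and, when ``categories``
    is given (gene -> label), a category column.
    """
    if human.directions is None:
        raise ValueError("human gene set must be directed")
    sens = {g.casefold(): int(v) for g, v in sensitive.items()}
    res = {g.casefold(): int(v) for g, v in resistant.items()}
    rows = []
    for gene in sorted(human.members):
        h = int(human.directions.get(gene, 0))
        s = sens.get(gene.casefold(), 0)
        r = res.get(gene.casefold(), 0)
        rows.append(
            {
                "gene": gene,
                "dir_sensitive": _DIR_LABEL[s],
                "dir_resistant": _DIR_LABEL[r],
                "dir_human": _HUMAN_LABEL[h],
                "concordant": _is_concordant(s, r, h),
                "category": (categories or {}).get(gene, "unassigned"),
            }
        )
    out = pd.DataFrame(
        rows,
        columns=["gene", "dir_sensitive", "dir_resistant", "dir_human",
                 "concordant", "category"],
    )
    n_both = int((out["dir_human"] == "both").sum()) if len(out) else 0
    logger.info(
        "concordance: %d/%d concordant (%d human-both genes excluded from calls)",
        int(out["concordant"].sum()) if len(out) else 0, len(out), n_both,
    )
    return out
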