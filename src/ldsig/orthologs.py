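"""Translate mouse gene signatures into human gene space.

Mapping is table-driven and lossy: genes absent from the table are reported
as dropped, one-to-many mappings resolve deterministically (lexicographically
first human symbol by default, or expand to all targets), and many-to-one
collisions deduplicate with a logged warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .data_io import OrthologTable

logger = logging.getLogger("ldsig")

__all__ = ["MappedSignature", "map_signature"]


@dataclass
class MappedSignature:
    """Human-space signature plus the genes lost in translation."""

    human_genes: list[str]
    directions: dict[str, int] = field(default_factory=dict)
    dropped: list[str] = field(default_factory=list)


def map_signature(
    genes: Sequence[str],
    table: OrthologTable,
    directions: Mapping[str, int] | None = None,
    expand_multi: bool = False,
) -> MappedSignature:
    """Map mouse symbols to human symbols through an ortholog table.

    Unmapped mouse genes land in ``dropped``.  A mouse gene with several
    human orthologs contributes the lexicographically first one (all of them
    with ``expand_multi=True``); the choice is logged.  Output is
    deduplicated; when two mouse genes hit the same human symbol the first
    occurrence (and its direction) wins, with a warning.
    """
    human: list[str] = []
    out_dir: dict[str, int] = {}
    dropped: list[str] = []
    for mouse in genes:
        targets = table.pairs.get(mouse)
        if not targets:
            dropped.append(mouse)
            continue
        chosen = sorted(targets) if expand_multi else [sorted(targets)[0]]
        if len(targets) > 1 and not expand_multi:
            logger.warning(
                "map_signature: %s has %d human orthologs; using %s",
                mouse, len(targets), chosen[0],
            )
        for h in chosen:
            if h in out_dir or (h in human and directions is None):
                logger.warning(
                    "map_signature: human symbol %s already mapped; keeping first", h
                )
                continue
            human.append(h)
            if directions is not None:
                out_dir[h] = int(directions.get(mouse, 0))
    return MappedSignature(human_genes=human, directions=out_dir, dropped=dropped)
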