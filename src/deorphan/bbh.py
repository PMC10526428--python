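"""Bidirectional best hit (BBH) orthology checks.

A cross-species ortholog claim suggested by tree proximity (e.g. a
putative yeast counterpart of a vertebrate-restricted carrier) can be
probed by reciprocal best hits: the pair must be each other's unique
highest-scoring global alignment across the two proteomes. Score ties
for the best hit void reciprocity (conservative) and are logged.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

from .curation import ProteinRecord
from .pairwise import global_align

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BestHit:
    query_id: str
    target_id: str
    score: float
    tied: bool  # another target reached the same best score


@dataclass(frozen=True)
class BBHPair:
    id_a: str
    id_b: str
    score_ab: float
    score_ba: float
    reciprocal: bool = True


def best_hits(
    query_set: Sequence[ProteinRecord],
    target_set: Sequence[ProteinRecord],
    **align_kwargs,
) -> dict:
    """Best global-alignment hit in ``target_set`` for every query.

    Ties are broken toward the smallest target id and flagged. Returns
    ``{query_id: BestHit}``.
    """
    if not query_set or not target_set:
        raise ValueError("both proteome sets must be non-empty")
    out: dict[str, BestHit] = {}
    for query in query_set:
        scored = []
        for target in target_set:
            aln = global_align(
                query.sequence, target.sequence,
                id_a=query.id, id_b=target.id, **align_kwargs,
            )
            scored.append((target.id, aln.score))
        best_score = max(s for _, s in scored)
        winners = sorted(t for t, s in scored if s == best_score)
        if len(winners) > 1:
            logger.info(
                "query %s: best-hit tie among %s at score %s",
                query.id, winners, best_score,
            )
        out[query.id] = BestHit(
            query_id=query.id, target_id=winners[0],
            score=best_score, tied=len(winners) > 1,
        )
    return out


def reciprocal_best_hits(
    set_a: Sequence[ProteinRecord],
    set_b: Sequence[ProteinRecord],
    **align_kwargs,
) -> list:
    """Unique reciprocal best-hit pairs between two proteomes.

    Symmetric up to pair orientation: swapping the arguments yields the
    same pairs with ids exchanged.
    """
    ab = best_hits(set_a, set_b, **align_kwargs)
    ba = best_hits(set_b, set_a, **align_kwargs)
    pairs = []
    for a_id in sorted(ab):
        hit = ab[a_id]
        if hit.tied:
            continue
        back = ba.get(hit.target_id)
        if back is None or back.tied or back.target_id != a_id:
            continue
        pairs.append(BBHPair(
            id_a=a_id, id_b=hit.target_id,
            score_ab=hit.score, score_ba=back.score,
        ))
    return pairs
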