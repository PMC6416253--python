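"""Dew-drop pooling: one composite embedding library from several trees.

Monthly series from single trees are far too short for state-space
reconstruction on their own (24--36 points).  Dew-drop pooling combines the
per-individual series — each z-scored to a common scale — into one library
of embedding vectors, so neighbors for a target in one tree may come from
any tree, while no vector ever straddles two individuals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .embedding import DelayEmbedding, embed
from .panel import ExpressionPanel, PanelIntegrityError


@dataclass(frozen=True)
class CompositeLibrary:
    """Pooled embedding for one gene over all individuals."""

    gene: str
    embedding: DelayEmbedding
    individuals: tuple[str, ...]
    total_points: int


def pool_individuals(
    panel: ExpressionPanel, gene: str, E: int, tau: int = 1
) -> CompositeLibrary:
    """Build the pooled library for ``gene``.

    Requires identical time coverage across individuals (the series are
    aligned calendar months); differing coverage is an error naming the
    offenders.
    """
    segments = panel.segments(gene)
    lengths = {ind: len(v) for ind, v in segments.items()}
    if len(set(lengths.values())) > 1:
        raise PanelIntegrityError(
            f"individuals differ in time coverage for gene {gene!r}: {lengths}"
        )
    emb = embed(segments, E=E, tau=tau)
    return CompositeLibrary(
        gene=gene,
        embedding=emb,
        individuals=emb.segment_ids,
        total_points=int(sum(lengths.values())),
    )


def panel_segments(panel: ExpressionPanel, gene: str) -> dict[str, np.ndarray]:
    """Per-individual series arrays for a gene (sorted individual order)."""
    return panel.segments(gene)


__all__ = ["CompositeLibrary", "pool_individuals", "panel_segments"]
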