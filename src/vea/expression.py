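"""Expression probability ratio (EPR) of pathways in a target tissue.

EPR is the fraction of a pathway's genes with expression evidence (RNA or
protein) in the tissue — equivalently the mean of per-gene expressed
indicators. Genes without evidence count as not expressed.
"""
from __future__ import annotations

import logging
from dataclasses import replace
from typing import Sequence

from .errors import ConfigError
from .types import (
    EprResult,
    ExpressionProfile,
    PathwayDB,
    PathwayEnrichmentResult,
)

logger = logging.getLogger(__name__)


def compute_epr(
    pathway_id: str, pathway_db: PathwayDB, expr: ExpressionProfile
) -> EprResult:
    """EPR of one pathway: expressed genes / total genes."""
    if pathway_id not in pathway_db.pathways:
        raise ConfigError(f"unknown pathway: {pathway_id}")
    genes = pathway_db.pathways[pathway_id]
    no_evidence = sum(1 for g in genes if g not in expr.expressed)
    if no_evidence:
        logger.debug(
            "pathway %s: %d/%d genes without expression evidence (count as not expressed)",
            pathway_id, no_evidence, len(genes),
        )
    n_expressed = sum(1 for g in genes if expr.is_expressed(g))
    return EprResult(pathway_id=pathway_id, n_genes=len(genes), n_expressed=n_expressed)


def attach_epr(
    results: Sequence[PathwayEnrichmentResult],
    pathway_db: PathwayDB,
    expr: ExpressionProfile,
) -> list[PathwayEnrichmentResult]:
    """Return the results with the ``epr`` field populated (idempotent).

    Results whose pathway is absent from the database keep a missing EPR
    with a warning.
    """
    out: list[PathwayEnrichmentResult] = []
    for r in results:
        if r.pathway_id not in pathway_db.pathways:
            logger.warning("pathway %s not in database; EPR left missing", r.pathway_id)
            out.append(replace(r))
            continue
        out.append(replace(r, epr=compute_epr(r.pathway_id, pathway_db, expr).epr))
    return out
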