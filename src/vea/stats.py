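"""The statistical core of variant enrichment analysis (VEA).

For every pathway, the number of group-shared ("common") variants falling in
the pathway's genes is compared against a reference-population background
with a two-sided Fisher's exact test on the 2x2 table

    (case_in, case_out)
    (bg_in,   bg_out)

where in/out is relative to the pathway's gene set and the margins are the
totals over the shared test universe (the union of all pathway gene sets).
Raw p-values are adjusted with Benjamini-Hochberg over all pathways of the
run; a pathway is "enriched" when its adjusted p falls below alpha
(default 0.05), and enriched pathways are ranked by ImportantVar count, by
odds ratio (above a threshold, default 1.5), or by expression probability
ratio.
"""
from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .cohort import GroupVariantProfile
from .errors import ConfigError, VeaError
from .types import (
    DAMAGING,
    AnnotatedVariant,
    BackgroundCounts,
    ContingencyTable2x2,
    ImportantVarPolicy,
    PathwayDB,
    PathwayEnrichmentResult,
)

logger = logging.getLogger(__name__)

# Tables whose point probability is within this relative factor of the
# observed one are counted into the two-sided p (the R convention).
_TWO_SIDED_REL_TOL = 1e-7


def fisher_exact_2x2(table: ContingencyTable2x2) -> tuple[float, float]:
    """Two-sided Fisher exact p and sample odds ratio for one 2x2 table.

    The p-value is the sum of hypergeometric probabilities, conditional on
    the observed margins, of all tables whose point probability does not
    exceed the observed one (within relative tolerance 1e-7). The odds
    ratio is the sample OR ``(case_in*bg_out)/(case_out*bg_in)``; when any
    cell is zero the Haldane-Anscombe +0.5 correction is applied to all
    four cells for the OR only, never for p. A table with an empty row or
    column margin is undefined: p := 1.
    """
    a, b, c, d = table.cells()
    # odds ratio with zero-cell correction
    if 0 in (a, b, c, d):
        odds = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        odds = (a * d) / (b * c)
    n = a + b + c + d
    row1, col1 = a + b, a + c
    if row1 == 0 or row1 == n or col1 == 0 or col1 == n:
        return 1.0, odds
    lo = max(0, col1 - (n - row1))
    hi = min(row1, col1)
    support = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(support, n, row1, col1)
    p_obs = pmf[a - lo]
    p = float(pmf[pmf <= p_obs * (1.0 + _TWO_SIDED_REL_TOL)].sum())
    return min(1.0, p), odds


def bh_fdr(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise VeaError("p-values must lie in [0, 1]")
    return list(multipletests(p, method="fdr_bh")[1])


def classify_important(
    v: AnnotatedVariant, policy: Optional[ImportantVarPolicy] = None
) -> bool:
    """Decide whether a variant is an ImportantVar.

    True iff the number of damaging predictor verdicts (categorical calls
    plus scores reaching their cutoff) is at least ``policy.min_damaging``,
    OR the functional class is in the policy's impact set. Missing evidence
    never counts as damaging.
    """
    policy = policy or ImportantVarPolicy()
    if v.func_class in policy.functional_classes:
        return True
    n_damaging = sum(1 for call in v.predictor_calls.values() if call == DAMAGING)
    for name, cutoff in policy.score_cutoffs.items():
        score = v.predictor_scores.get(name)
        if score is not None and score >= cutoff:
            n_damaging += 1
    return n_damaging >= policy.min_damaging


def run_vea(
    profile: GroupVariantProfile,
    background: BackgroundCounts,
    pathway_db: PathwayDB,
    policy: Optional[ImportantVarPolicy] = None,
    alpha: float = 0.05,
) -> list[PathwayEnrichmentResult]:
    """Test every pathway for variant enrichment of one group.

    ``profile`` and ``background`` are expected already restricted to the
    pathway universe (see :func:`vea.cohort.restrict_to_universe`); case_in
    counts DISTINCT common variants whose gene set intersects the pathway,
    bg_in sums the per-gene background counts over the pathway's genes.
    The BH-FDR family is all pathways of this run.
    """
    if not pathway_db.pathways:
        raise ConfigError("pathway database is empty")
    bg_total = background.total
    if bg_total <= 0:
        raise ConfigError("background has zero total variants; no test possible")
    policy = policy or ImportantVarPolicy()
    case_total = len(profile.common_variants)

    gene_to_vars: dict[str, set] = {}
    for key, v in profile.variant_annotations.items():
        for g in v.genes:
            gene_to_vars.setdefault(g, set()).add(key)
    important = {
        key: classify_important(v, policy)
        for key, v in profile.variant_annotations.items()
    }

    results: list[PathwayEnrichmentResult] = []
    p_values: list[float] = []
    for pid in sorted(pathway_db.pathways):
        genes = pathway_db.pathways[pid]
        vars_in: set = set()
        for g in genes:
            vars_in |= gene_to_vars.get(g, set())
        case_in = len(vars_in)
        bg_in = sum(background.per_gene.get(g, 0) for g in genes)
        table = ContingencyTable2x2(
            case_in, case_total - case_in, bg_in, bg_total - bg_in
        )
        p, odds = fisher_exact_2x2(table)
        imp_genes: dict[str, int] = {}
        for g in sorted(genes):
            n = sum(1 for key in gene_to_vars.get(g, ()) if important[key])
            if n:
                imp_genes[g] = n
        results.append(
            PathwayEnrichmentResult(
                pathway_id=pid,
                name=pathway_db.name_of(pid),
                table=table,
                odds_ratio=odds,
                p_value=p,
                fdr=1.0,
                n_important_var=sum(1 for key in vars_in if important[key]),
                important_var_genes=imp_genes,
                genes=tuple(sorted(g for g in genes if gene_to_vars.get(g))),
            )
        )
        p_values.append(p)
    for r, fdr in zip(results, bh_fdr(p_values)):
        r.fdr = float(fdr)
        r.enriched = r.fdr < alpha
    logger.info(
        "group %s: %d pathways tested, %d enriched at alpha=%g",
        profile.group, len(results), sum(r.enriched for r in results), alpha,
    )
    return results


def rank_results(
    results: Sequence[PathwayEnrichmentResult],
    mode: str = "important_var",
    or_threshold: float = 1.5,
) -> list[PathwayEnrichmentResult]:
    """Rank enrichment results for reporting.

    ``important_var``: by ImportantVar count, descending. ``odds_ratio``:
    keep only results with OR above ``or_threshold`` and at least one
    ImportantVar, sort by OR descending. ``epr``: by expression probability
    ratio, descending (EPR must be attached). Ties always break by
    pathway ID ascending.
    """
    rows = list(results)
    if mode == "important_var":
        return sorted(rows, key=lambda r: (-r.n_important_var, r.pathway_id))
    if mode == "odds_ratio":
        kept = [r for r in rows if r.odds_ratio > or_threshold and r.n_important_var >= 1]
        return sorted(kept, key=lambda r: (-r.odds_ratio, r.pathway_id))
    if mode == "epr":
        if any(r.epr is None for r in rows):
            raise ConfigError("EPR ranking requested but EPR is not attached")
        return sorted(rows, key=lambda r: (-r.epr, r.pathway_id))
    raise ConfigError(f"unknown ranking mode: {mode!r}")
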