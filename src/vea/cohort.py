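"""Group-level common-variant profiles.

A group's "CommonVar" set is the exact intersection of its members' variant
sets: a variant must be carried by every individual in the group to count.
Zygosity is ignored (carrying the alternate allele, het or hom, counts).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Sequence, Union

from .errors import ConfigError
from .types import (
    DAMAGING,
    FUNC_SEVERITY,
    MISSING,
    TOLERATED,
    AnnotatedVariant,
    BackgroundCounts,
    PathwayDB,
    VariantKey,
)

logger = logging.getLogger(__name__)


@dataclass
class GroupVariantProfile:
    """One patient group's common-variant set with per-gene tallies."""

    group: str
    common_variants: frozenset[VariantKey]
    per_gene_counts: dict[str, int]
    variant_annotations: dict[VariantKey, AnnotatedVariant]
    n_individuals: int


def common_variants(
    individual_variant_sets: Sequence[Iterable[VariantKey]],
) -> frozenset[VariantKey]:
    """Exact set intersection of the members' variant sets."""
    if not individual_variant_sets:
        raise ConfigError("a group must have at least one member")
    sets = [frozenset(s) for s in individual_variant_sets]
    out = sets[0]
    for s in sets[1:]:
        out &= s
    return out


def _merge_annotations(records: Sequence[AnnotatedVariant]) -> AnnotatedVariant:
    """Resolve annotation conflicts across members for one variant key.

    Functional class: most severe wins. Predictor call: damaging if any
    member says damaging, else tolerated if any says tolerated, else
    missing. Scores: the maximum available value (higher = more damaging
    for phred-like scales).
    """
    base = records[0]
    genes = frozenset().union(*(r.genes for r in records))
    func = min((r.func_class for r in records), key=lambda c: FUNC_SEVERITY[c])
    pred_names = set()
    for r in records:
        pred_names |= set(r.predictor_calls)
    calls = {}
    for name in pred_names:
        seen = {r.predictor_calls.get(name, MISSING) for r in records}
        if DAMAGING in seen:
            calls[name] = DAMAGING
        elif TOLERATED in seen:
            calls[name] = TOLERATED
        else:
            calls[name] = MISSING
    score_names = set()
    for r in records:
        score_names |= set(r.predictor_scores)
    scores = {}
    for name in score_names:
        vals = [
            r.predictor_scores.get(name)
            for r in records
            if r.predictor_scores.get(name) is not None
        ]
        scores[name] = max(vals) if vals else None
    return AnnotatedVariant(
        key=base.key,
        genes=genes,
        func_class=func,
        predictor_calls=calls,
        predictor_scores=scores,
    )


def build_group_profile(
    group_label: str,
    members: Sequence[Sequence[AnnotatedVariant]],
) -> GroupVariantProfile:
    """Intersect member variant sets and tally distinct common variants per
    gene (a variant annotated to k genes contributes to all k)."""
    if not members:
        raise ConfigError(f"group {group_label!r} has no members")
    member_maps = []
    for member in members:
        m: dict[VariantKey, list[AnnotatedVariant]] = {}
        for v in member:
            m.setdefault(v.key, []).append(v)
        member_maps.append(m)
    common = common_variants([set(m) for m in member_maps])
    annotations: dict[VariantKey, AnnotatedVariant] = {}
    for key in common:
        records = [r for m in member_maps for r in m.get(key, ())]
        annotations[key] = _merge_annotations(records)
    per_gene: dict[str, int] = {}
    for v in annotations.values():
        for g in v.genes:
            per_gene[g] = per_gene.get(g, 0) + 1
    return GroupVariantProfile(
        group=group_label,
        common_variants=common,
        per_gene_counts=per_gene,
        variant_annotations=annotations,
        n_individuals=len(members),
    )


def restrict_to_universe(
    obj: Union[GroupVariantProfile, BackgroundCounts],
    pathway_db: PathwayDB,
) -> Union[GroupVariantProfile, BackgroundCounts]:
    """Restrict a profile or background to the pathway universe.

    Only genes appearing in at least one pathway are retained; a variant
    keeps only its in-universe gene assignments and is dropped entirely if
    none remain. An empty result is an error because no test is possible.
    """
    universe = pathway_db.universe()
    if isinstance(obj, BackgroundCounts):
        kept = {g: n for g, n in obj.per_gene.items() if g in universe}
        n_removed = len(obj.per_gene) - len(kept)
        if n_removed:
            logger.info("background: %d genes outside the pathway universe removed", n_removed)
        if not kept:
            raise ConfigError("background has no genes in the pathway universe")
        return BackgroundCounts(per_gene=kept, meta=dict(obj.meta))
    if isinstance(obj, GroupVariantProfile):
        annotations: dict[VariantKey, AnnotatedVariant] = {}
        for key, v in obj.variant_annotations.items():
            genes = v.genes & universe
            if genes:
                annotations[key] = replace(v, genes=genes)
        n_removed = len(obj.variant_annotations) - len(annotations)
        if n_removed:
            logger.info(
                "group %s: %d common variants outside the pathway universe removed",
                obj.group, n_removed,
            )
        if not annotations:
            raise ConfigError(
                f"group {obj.group!r} has no common variants in the pathway universe"
            )
        per_gene: dict[str, int] = {}
        for v in annotations.values():
            for g in v.genes:
                per_gene[g] = per_gene.get(g, 0) + 1
        return GroupVariantProfile(
            group=obj.group,
            common_variants=frozenset(annotations),
            per_gene_counts=per_gene,
            variant_annotations=annotations,
            n_individuals=obj.n_individuals,
        )
    raise ConfigError(f"cannot restrict object of type {type(obj).__name__}")
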