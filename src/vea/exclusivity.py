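"""Set algebra over per-group enriched-pathway lists and the DEG overlay.

An "exclusive enriched pathway" (eEP) is a pathway enriched in exactly one
group: the singleton region of the Venn partition of the per-group enriched
sets. A differentially-expressed-gene (DEG) list can additionally be tested
for pathway over-representation and overlaid on the eEP sets with a second
Venn partition.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Optional

from scipy.stats import hypergeom

from .errors import ConfigError
from .stats import bh_fdr
from .types import PathwayDB, VennPartition

logger = logging.getLogger(__name__)


def venn_partition(ep_sets: Mapping[str, Iterable[str]]) -> VennPartition:
    """Partition pathways by the exact subset of groups they occur in.

    Every nonempty subset of group labels gets a (possibly empty) region;
    regions are pairwise disjoint and jointly cover the union of inputs.
    """
    if len(ep_sets) < 2:
        raise ConfigError("a Venn partition needs at least 2 groups")
    groups = tuple(ep_sets)
    sets = {g: frozenset(s) for g, s in ep_sets.items()}
    regions: dict[frozenset[str], set[str]] = {}
    for r in range(1, len(groups) + 1):
        for combo in combinations(sorted(groups), r):
            regions[frozenset(combo)] = set()
    membership: dict[str, set[str]] = {}
    for g, s in sets.items():
        for pid in s:
            membership.setdefault(pid, set()).add(g)
    for pid, owners in membership.items():
        regions[frozenset(owners)].add(pid)
    return VennPartition(
        groups=groups,
        regions={k: frozenset(v) for k, v in regions.items()},
    )


@dataclass
class OraResult:
    """Over-representation of a DEG list in one pathway."""

    pathway_id: str
    overlap: int
    n_pathway: int
    p_value: float
    fdr: float


def deg_ora(
    deg_genes: Iterable[str],
    pathway_db: PathwayDB,
    universe: Optional[Iterable[str]] = None,
    alpha: float = 0.05,
    significant_only: bool = True,
) -> dict[str, OraResult]:
    """Hypergeometric over-representation of a gene list in each pathway.

    For a pathway with K genes in the universe (size M) and a DEG draw of
    size N, p = P(X >= observed overlap) under the hypergeometric null;
    BH-FDR over all tested pathways. Returns pathways with fdr < alpha
    (or all tested pathways when ``significant_only`` is false).
    """
    uni = frozenset(universe) if universe is not None else pathway_db.universe()
    deg = frozenset(deg_genes) & uni
    n_dropped = len(frozenset(deg_genes)) - len(deg)
    if n_dropped:
        logger.info("DEG list: %d genes outside the universe dropped", n_dropped)
    if not deg:
        raise ConfigError("DEG list has no genes in the universe")
    M, N = len(uni), len(deg)
    tested: list[tuple[str, int, int, float]] = []
    for pid in sorted(pathway_db.pathways):
        genes = pathway_db.pathways[pid] & uni
        if not genes:
            logger.warning("pathway %s disjoint from the universe; skipped", pid)
            continue
        K = len(genes)
        k = len(genes & deg)
        # P(X >= k); sf(k-1) is exactly 1.0 at k = 0
        p = float(hypergeom.sf(k - 1, M, K, N))
        tested.append((pid, k, K, min(1.0, p)))
    fdrs = bh_fdr([t[3] for t in tested])
    out: dict[str, OraResult] = {}
    for (pid, k, K, p), fdr in zip(tested, fdrs):
        if significant_only and not fdr < alpha:
            continue
        out[pid] = OraResult(pathway_id=pid, overlap=k, n_pathway=K, p_value=p, fdr=float(fdr))
    return out


def overlay_venn(
    eep: Mapping[str, Iterable[str]],
    deg_ep: Iterable[str],
    deg_label: str = "DEG",
) -> VennPartition:
    """Venn partition of the per-group eEP sets plus the DEG-derived
    enriched-pathway set."""
    if deg_label in eep:
        raise ConfigError(f"group label {deg_label!r} collides with the DEG set label")
    sets = {g: frozenset(s) for g, s in eep.items()}
    sets[deg_label] = frozenset(deg_ep)
    return venn_partition(sets)


def write_venn_json(partition: VennPartition, path: str | Path) -> None:
    """Write a Venn partition as JSON: sorted '+'-joined region key ->
    sorted pathway IDs."""
    Path(path).write_text(
        json.dumps(partition.to_json_dict(), indent=1, sort_keys=True) + "\n"
    )
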