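"""Shared fixtures: tiny hand-built inputs plus small seeded synthetic runs."""
from __future__ import annotations

import pytest

from vea import (
    AnnotatedVariant,
    BackgroundCounts,
    ExpressionProfile,
    PathwayDB,
    SimulationConfig,
    VariantKey,
)


def av(chrom="1", pos=100, ref="A", alt="G", genes=("NOD2",),
       func="nonsynonymous_SNV", calls=None, scores=None) -> AnnotatedVariant:
    """Shorthand constructor for AnnotatedVariant in tests."""
    return AnnotatedVariant(
        key=VariantKey.from_raw(chrom, pos, ref, alt),
        genes=frozenset(genes),
        func_class=func,
        predictor_calls=dict(calls or {}),
        predictor_scores=dict(scores or {}),
    )


@pytest.fixture
def tiny_db() -> PathwayDB:
    return PathwayDB(
        pathways={
            "R-HSA-0001": frozenset({"NOD2", "IL1B"}),
            "R-HSA-0002": frozenset({"IL1B", "TNF", "PSTPIP1"}),
            "R-HSA-0003": frozenset({"MEFV"}),
        },
        names={
            "R-HSA-0001": "innate sensing",
            "R-HSA-0002": "cytokine signaling",
            "R-HSA-0003": "pyrin",
        },
    )


@pytest.fixture
def tiny_background() -> BackgroundCounts:
    return BackgroundCounts(
        per_gene={"NOD2": 10, "IL1B": 5, "TNF": 8, "PSTPIP1": 3, "MEFV": 4},
        meta={"ancestry": "nfe", "af_threshold": "0.01"},
    )


@pytest.fixture
def tiny_expression() -> ExpressionProfile:
    return ExpressionProfile(
        tissue="skin",
        expressed={"NOD2": True, "IL1B": True, "TNF": False, "PSTPIP1": False},
    )


@pytest.fixture
def small_sim_config() -> SimulationConfig:
    """Desk-scale synthetic study: quick enough for every test."""
    return SimulationConfig(
        seed=7,
        group_sizes={"G1": 3, "G2": 3},
        n_genes=150,
        n_pathways=25,
        pathway_size_range=(4, 10),
        n_deg=30,
    )
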