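"""Core domain types shared across the VEA pipeline.

The unit counted everywhere is a normalized variant identity
(:class:`VariantKey`); everything else wraps variant sets, gene sets and
per-gene tallies around it.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

from .errors import VeaError

#: Functional classes ordered most-severe first; used to resolve annotation
#: conflicts across individuals for the same variant.
FUNC_CLASSES: tuple[str, ...] = (
    "stopgain",
    "stoploss",
    "startloss",
    "splicing",
    "nonsynonymous_SNV",
    "synonymous_SNV",
    "other",
)
FUNC_SEVERITY: dict[str, int] = {c: i for i, c in enumerate(FUNC_CLASSES)}

DAMAGING = "damaging"
TOLERATED = "tolerated"
MISSING = "missing"

_ALLELE_ALPHABET = frozenset("ACGTN")


def normalize_func_class(raw: str) -> str:
    """Map an annotator functional-class string onto the canonical vocabulary.

    Unknown labels collapse to ``"other"``; whitespace becomes underscores so
    e.g. ``"nonsynonymous SNV"`` and ``"nonsynonymous_SNV"`` are equivalent.
    """
    label = raw.strip().replace(" ", "_")
    if label in FUNC_SEVERITY:
        return label
    # annotators write splicing region labels in several forms
    if label.lower().startswith("splic"):
        return "splicing"
    return "other"


@dataclass(frozen=True, slots=True)
class VariantKey:
    """Normalized identity of one bi-allelic variant.

    ``chrom`` is stored without any ``chr`` prefix, ``pos`` is 1-based and
    alleles are uppercase. Construct via :meth:`from_raw` to apply
    normalization (multi-allelic records must be split by the caller first).
    """

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise VeaError(f"variant position must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise VeaError(f"ref and alt alleles are identical: {self.ref}")
        for allele in (self.ref, self.alt):
            if not allele or not set(allele) <= _ALLELE_ALPHABET:
                raise VeaError(f"allele {allele!r} is not over ACGTN")

    @classmethod
    def from_raw(cls, chrom: str, pos: int, ref: str, alt: str) -> "VariantKey":
        """Build a key from raw fields: strip ``chr`` prefix, uppercase
        alleles, and trim the shared suffix then prefix (minimal indel
        normalization; the prefix trim advances ``pos``)."""
        c = chrom.strip()
        if c.lower().startswith("chr"):
            c = c[3:]
        r, a = ref.strip().upper(), alt.strip().upper()
        p = int(pos)
        while len(r) > 1 and len(a) > 1 and r[-1] == a[-1]:
            r, a = r[:-1], a[:-1]
        while len(r) > 1 and len(a) > 1 and r[0] == a[0]:
            r, a = r[1:], a[1:]
            p += 1
        return cls(c, p, r, a)


@dataclass(slots=True)
class AnnotatedVariant:
    """A :class:`VariantKey` plus gene assignment(s), functional class and
    per-predictor damage evidence."""

    key: VariantKey
    genes: frozenset[str]
    func_class: str = "other"
    predictor_calls: dict[str, str] = field(default_factory=dict)
    predictor_scores: dict[str, Optional[float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.genes:
            raise VeaError(f"variant {self.key} has no gene assignment")


@dataclass
class PathwayDB:
    """Pathway-ID -> gene-set mapping defining the test universe."""

    pathways: dict[str, frozenset[str]]
    names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pid, genes in self.pathways.items():
            if not genes:
                raise VeaError(f"pathway {pid} has an empty gene set")

    def universe(self) -> frozenset[str]:
        """Union of all pathway gene sets — the shared denominator frame."""
        out: set[str] = set()
        for genes in self.pathways.values():
            out |= genes
        return frozenset(out)

    def name_of(self, pid: str) -> str:
        return self.names.get(pid, pid)

    def __len__(self) -> int:
        return len(self.pathways)


@dataclass
class BackgroundCounts:
    """Per-gene counts of reference-population common variants.

    Derived offline from an ancestry-restricted population sites table (e.g.
    gnomAD nfe at allele frequency >= ``af_threshold``); the threshold and
    ancestry travel with the data as metadata, not as code.
    """

    per_gene: dict[str, int]
    meta: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for gene, n in self.per_gene.items():
            if n < 0:
                raise VeaError(f"negative background count for {gene}: {n}")

    @property
    def total(self) -> int:
        return sum(self.per_gene.values())


@dataclass
class ExpressionProfile:
    """Per-gene expressed/not-expressed flags for one tissue, with the raw
    RNA/protein evidence they were derived from."""

    tissue: str
    expressed: dict[str, bool]
    evidence: dict[str, dict] = field(default_factory=dict)

    def is_expressed(self, gene: str) -> bool:
        """Genes without evidence count as not expressed."""
        return self.expressed.get(gene, False)


@dataclass(frozen=True, slots=True)
class ContingencyTable2x2:
    """Variant-count table for one pathway: case/background x in/out."""

    case_in: int
    case_out: int
    bg_in: int
    bg_out: int

    def __post_init__(self) -> None:
        for name in ("case_in", "case_out", "bg_in", "bg_out"):
            if getattr(self, name) < 0:
                raise VeaError(f"negative cell {name} in contingency table")

    def cells(self) -> tuple[int, int, int, int]:
        return (self.case_in, self.case_out, self.bg_in, self.bg_out)


@dataclass(frozen=True)
class ImportantVarPolicy:
    """Rules deciding when a variant counts as an ImportantVar.

    A variant is important when at least ``min_damaging`` predictor verdicts
    are damaging (categorical call, or numeric score >= its cutoff) OR its
    functional class carries direct impact. Missing evidence never counts.
    """

    score_cutoffs: Mapping[str, float] = field(
        default_factory=lambda: {"CADD": 20.0}
    )
    min_damaging: int = 1
    functional_classes: frozenset[str] = frozenset(
        {"nonsynonymous_SNV", "stopgain", "stoploss", "startloss"}
    )


@dataclass
class EprResult:
    """Expression probability ratio of one pathway in one tissue."""

    pathway_id: str
    n_genes: int
    n_expressed: int

    @property
    def epr(self) -> float:
        return self.n_expressed / self.n_genes


@dataclass
class PathwayEnrichmentResult:
    """One row of a VEA report."""

    pathway_id: str
    name: str
    table: ContingencyTable2x2
    odds_ratio: float
    p_value: float
    fdr: float
    n_important_var: int
    important_var_genes: dict[str, int] = field(default_factory=dict)
    genes: tuple[str, ...] = ()
    epr: Optional[float] = None
    enriched: bool = False


@dataclass
class VennPartition:
    """Disjoint regions of a Venn diagram over per-group pathway sets.

    ``regions`` maps every nonempty subset of ``groups`` to the pathways
    present in exactly those groups; region sets are pairwise disjoint and
    jointly cover the union of the inputs.
    """

    groups: tuple[str, ...]
    regions: dict[frozenset[str], frozenset[str]]

    def region(self, *labels: str) -> frozenset[str]:
        return self.regions.get(frozenset(labels), frozenset())

    def exclusive_of(self, label: str) -> frozenset[str]:
        """Pathways present in exactly one group (the eEP set for a group)."""
        return self.region(label)

    def to_json_dict(self) -> dict[str, list[str]]:
        return {
            "+".join(sorted(k)): sorted(v) for k, v in self.regions.items()
        }
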