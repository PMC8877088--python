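"""Seeded generators for every pipeline input, with planted enrichment.

The generator emulates the study design the pipeline targets: a few small
patient groups whose members share most of their called variants, tested
against an ancestry-restricted population background. Per-gene variant
counts are Poisson with mean ``variant_rate`` (the background rate); a
cohort variant is group-shared with probability ``sharing`` and otherwise
private to one member, so the all-member intersection recovers the shared
set. Planting multiplies the shared-variant rate of a pathway's genes by a
factor f — exactly the alternative hypothesis the per-pathway Fisher table
tests — while the background stays at the baseline rate.

Variants are synthetic keys on a pseudo-chromosome ("chrS") with globally
unique sequential positions; no reference genome is involved. All outputs
are byte-deterministic functions of the configuration (including its seed).
"""
from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import numpy as np

from .errors import ConfigError
from .types import (
    DAMAGING,
    MISSING,
    TOLERATED,
    AnnotatedVariant,
    BackgroundCounts,
    ExpressionProfile,
    PathwayDB,
    VariantKey,
)
from . import formats_io

_BASES = np.array(list("ACGT"))

# fixed substream ids so generators are independent of call order
_STREAM_PATHWAYS = 1
_STREAM_BACKGROUND = 2
_STREAM_COHORT = 3
_STREAM_EXPRESSION = 4
_STREAM_DEG = 5


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study.

    Defaults emulate a small three-group exome cohort (three individuals per
    group), 1000 genes, 200 pathways, a per-gene background rate of 2
    common variants and a within-group sharing probability of 0.8.
    ``planted`` maps pathway-ID -> enrichment factor f >= 1 applied to the
    shared-variant rate of that pathway's genes in every group, or
    group-label -> {pathway-ID: f} for group-specific planting.
    """

    seed: int = 0
    group_sizes: dict[str, int] = field(
        default_factory=lambda: {"G1": 3, "G2": 3, "G3": 3}
    )
    n_genes: int = 1000
    n_pathways: int = 200
    pathway_size_range: tuple[int, int] = (5, 30)
    variant_rate: float = 2.0
    sharing: float = 0.8
    planted: dict = field(default_factory=dict)
    func_class_probs: dict[str, float] = field(
        default_factory=lambda: {
            "nonsynonymous_SNV": 0.45,
            "synonymous_SNV": 0.30,
            "stopgain": 0.04,
            "stoploss": 0.01,
            "startloss": 0.01,
            "splicing": 0.05,
            "other": 0.14,
        }
    )
    predictor_damaging_prob: float = 0.3
    predictor_missing_prob: float = 0.1
    predictors: tuple[str, ...] = ("SIFT", "PolyPhen2", "FATHMM")
    expression_prob: float = 0.7
    tissue: str = "skin"
    n_deg: int = 100
    deg_multiplier: float = 1.0

    def validate(self) -> None:
        lo, hi = self.pathway_size_range
        if self.n_pathways < 1 or self.n_genes < 1:
            raise ConfigError("n_pathways and n_genes must be >= 1")
        if not (1 <= lo <= hi):
            raise ConfigError("pathway_size_range must satisfy 1 <= lo <= hi")
        if hi > self.n_genes:
            raise ConfigError(
                f"largest pathway size {hi} exceeds gene pool {self.n_genes}"
            )
        if not self.group_sizes or any(n < 1 for n in self.group_sizes.values()):
            raise ConfigError("every group needs at least one member")
        for p in (self.sharing, self.predictor_damaging_prob,
                  self.predictor_missing_prob, self.expression_prob):
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"probability {p} outside [0, 1]")
        if self.variant_rate < 0:
            raise ConfigError("variant_rate must be nonnegative")
        total = sum(self.func_class_probs.values())
        if not math.isclose(total, 1.0, rel_tol=1e-9):
            raise ConfigError("func_class_probs must sum to 1")

    def gene_pool(self) -> list[str]:
        return [f"GENE{i:04d}" for i in range(self.n_genes)]

    def planted_for_group(self, group: str) -> dict[str, float]:
        """Normalize ``planted`` to a per-group pathway->factor map."""
        if self.planted and all(isinstance(v, Mapping) for v in self.planted.values()):
            return dict(self.planted.get(group, {}))
        return dict(self.planted)


def _rng(cfg: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, stream])


def simulate_pathway_db(cfg: SimulationConfig) -> PathwayDB:
    """Sample pathway gene sets (overlap allowed) from the gene pool."""
    cfg.validate()
    rng = _rng(cfg, _STREAM_PATHWAYS)
    pool = np.array(cfg.gene_pool())
    lo, hi = cfg.pathway_size_range
    sizes = rng.integers(lo, hi + 1, size=cfg.n_pathways)
    pathways: dict[str, frozenset[str]] = {}
    names: dict[str, str] = {}
    for i, size in enumerate(sizes, start=1):
        pid = f"R-SIM-{i:04d}"
        genes = rng.choice(pool, size=int(size), replace=False)
        pathways[pid] = frozenset(genes.tolist())
        names[pid] = f"Simulated pathway {i}"
    return PathwayDB(pathways=pathways, names=names)


def simulate_background(cfg: SimulationConfig) -> BackgroundCounts:
    """Per-gene reference common-variant counts ~ Poisson(variant_rate)."""
    cfg.validate()
    rng = _rng(cfg, _STREAM_BACKGROUND)
    counts = rng.poisson(cfg.variant_rate, size=cfg.n_genes)
    per_gene = {g: int(c) for g, c in zip(cfg.gene_pool(), counts)}
    return BackgroundCounts(
        per_gene=per_gene,
        meta={"ancestry": "nfe", "af_threshold": "0.01", "source": "simulated"},
    )


def _draw_annotations(
    rng: np.random.Generator, cfg: SimulationConfig, genes: list[str], start_pos: int
) -> list[AnnotatedVariant]:
    """Vectorized draw of n annotated variants, one per entry of ``genes``,
    at sequential positions starting at ``start_pos``."""
    n = len(genes)
    if n == 0:
        return []
    ref_idx = rng.integers(0, 4, size=n)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n)) % 4
    classes = list(cfg.func_class_probs)
    func = rng.choice(classes, size=n, p=list(cfg.func_class_probs.values()))
    npred = len(cfg.predictors)
    miss = rng.random(size=(n, npred + 1)) < cfg.predictor_missing_prob
    dam = rng.random(size=(n, npred + 1)) < cfg.predictor_damaging_prob
    # CADD phred: damaging draws land above the conventional 20 cutoff
    cadd = np.where(
        dam[:, npred],
        rng.uniform(20.0, 40.0, size=n),
        rng.uniform(0.0, 19.9, size=n),
    )
    out: list[AnnotatedVariant] = []
    for i in range(n):
        calls = {}
        for j, pred in enumerate(cfg.predictors):
            if miss[i, j]:
                calls[pred] = MISSING
            else:
                calls[pred] = DAMAGING if dam[i, j] else TOLERATED
        scores = {"CADD": None if miss[i, npred] else round(float(cadd[i]), 2)}
        out.append(
            AnnotatedVariant(
                key=VariantKey(
                    chrom="S",
                    pos=start_pos + i,
                    ref=str(_BASES[ref_idx[i]]),
                    alt=str(_BASES[alt_idx[i]]),
                ),
                genes=frozenset({genes[i]}),
                func_class=str(func[i]),
                predictor_calls=calls,
                predictor_scores=scores,
            )
        )
    return out


def simulate_cohort(
    cfg: SimulationConfig, pathway_db: PathwayDB
) -> dict[str, list[list[AnnotatedVariant]]]:
    """Generate per-individual annotated variant lists for every group.

    Group-shared variants are drawn per gene at rate
    ``variant_rate * sharing * f`` (f the gene's largest planted factor, 1
    if unplanted) and placed in every member's list; private noise variants
    are drawn per member at rate ``variant_rate * (1 - sharing)`` with
    globally unique positions, so they are never all-member-shared.
    """
    cfg.validate()
    rng = _rng(cfg, _STREAM_COHORT)
    pool = cfg.gene_pool()
    gene_index = {g: i for i, g in enumerate(pool)}
    next_pos = 1
    cohort: dict[str, list[list[AnnotatedVariant]]] = {}
    for group in cfg.group_sizes:
        n_members = cfg.group_sizes[group]
        factors = np.ones(cfg.n_genes)
        for pid, f in cfg.planted_for_group(group).items():
            if pid not in pathway_db.pathways:
                raise ConfigError(f"planted pathway {pid} not in the database")
            if f < 1:
                raise ConfigError(f"planted factor for {pid} must be >= 1, got {f}")
            for g in pathway_db.pathways[pid]:
                i = gene_index[g]
                factors[i] = max(factors[i], f)
        shared_counts = rng.poisson(cfg.variant_rate * cfg.sharing * factors)
        shared_genes = [
            pool[i] for i in range(cfg.n_genes) for _ in range(shared_counts[i])
        ]
        shared = _draw_annotations(rng, cfg, shared_genes, next_pos)
        next_pos += len(shared)
        members: list[list[AnnotatedVariant]] = []
        private_rate = cfg.variant_rate * (1.0 - cfg.sharing)
        for _ in range(n_members):
            private_counts = rng.poisson(private_rate, size=cfg.n_genes)
            private_genes = [
                pool[i] for i in range(cfg.n_genes) for _ in range(private_counts[i])
            ]
            private = _draw_annotations(rng, cfg, private_genes, next_pos)
            next_pos += len(private)
            members.append(list(shared) + private)
        cohort[group] = members
    return cohort


def simulate_expression(cfg: SimulationConfig) -> ExpressionProfile:
    """Bernoulli(expression_prob) expressed flags with consistent evidence."""
    cfg.validate()
    rng = _rng(cfg, _STREAM_EXPRESSION)
    n = cfg.n_genes
    expressed = rng.random(n) < cfg.expression_prob
    rna_hi = rng.uniform(1.0, 50.0, size=n)
    rna_lo = rng.uniform(0.0, 0.99, size=n)
    protein_choice = rng.integers(0, 3, size=n)
    levels = np.array(["Low", "Medium", "High"])
    flags: dict[str, bool] = {}
    evidence: dict[str, dict] = {}
    for i, gene in enumerate(cfg.gene_pool()):
        if expressed[i]:
            rna = round(float(rna_hi[i]), 3)
            protein = str(levels[protein_choice[i]])
        else:
            rna = round(float(rna_lo[i]), 3)
            protein = "Not detected"
        flags[gene] = bool(expressed[i])
        evidence[gene] = {"rna_value": rna, "protein_level": protein}
    return ExpressionProfile(tissue=cfg.tissue, expressed=flags, evidence=evidence)


def simulate_deg_list(
    cfg: SimulationConfig,
    pathway_db: PathwayDB,
    enriched_pathway: Optional[str] = None,
) -> list[str]:
    """Sample a DEG gene list, optionally over-sampling one pathway's genes
    at odds multiplier ``deg_multiplier`` (infinity takes all of them)."""
    cfg.validate()
    rng = _rng(cfg, _STREAM_DEG)
    pool = cfg.gene_pool()
    n_deg = min(cfg.n_deg, cfg.n_genes)
    if enriched_pathway is None:
        picked = rng.choice(pool, size=n_deg, replace=False)
        return sorted(picked.tolist())
    if enriched_pathway not in pathway_db.pathways:
        raise ConfigError(f"unknown pathway for DEG planting: {enriched_pathway}")
    target = pathway_db.pathways[enriched_pathway]
    if math.isinf(cfg.deg_multiplier):
        rest = sorted(set(pool) - target)
        fill = max(0, n_deg - len(target))
        extra = rng.choice(rest, size=min(fill, len(rest)), replace=False)
        return sorted(set(target) | set(extra.tolist()))
    weights = np.array([cfg.deg_multiplier if g in target else 1.0 for g in pool])
    picked = rng.choice(pool, size=n_deg, replace=False, p=weights / weights.sum())
    return sorted(picked.tolist())


# ---------------------------------------------------------------------------
# file emission

_FUNC_OUT = {
    "nonsynonymous_SNV": "nonsynonymous SNV",
    "synonymous_SNV": "synonymous SNV",
}

_TSV_HEADER = (
    "Chr\tStart\tEnd\tRef\tAlt\tGene.refGene\tExonicFunc.refGene\t"
    "SIFT_pred\tPolyphen2_HDIV_pred\tFATHMM_pred\tCADD_phred"
)

_CALL_OUT = {DAMAGING: "D", TOLERATED: "T", MISSING: "."}


def write_annotator_tsv(variants: list[AnnotatedVariant], path: str | Path) -> None:
    """Write variants in the annotator-TSV dialect formats_io reads back."""
    lines = [_TSV_HEADER]
    for v in sorted(variants, key=lambda v: (v.key.chrom, v.key.pos, v.key.alt)):
        cadd = v.predictor_scores.get("CADD")
        lines.append(
            "\t".join(
                [
                    f"chr{v.key.chrom}",
                    str(v.key.pos),
                    str(v.key.pos + len(v.key.ref) - 1),
                    v.key.ref,
                    v.key.alt,
                    ";".join(sorted(v.genes)),
                    _FUNC_OUT.get(v.func_class, v.func_class),
                    _CALL_OUT[v.predictor_calls.get("SIFT", MISSING)],
                    _CALL_OUT[v.predictor_calls.get("PolyPhen2", MISSING)],
                    _CALL_OUT[v.predictor_calls.get("FATHMM", MISSING)],
                    "." if cadd is None else f"{cadd:.2f}",
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


_VCF_HEADER = """\
##fileformat=VCFv4.2
##contig=<ID=chrS>
##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol(s)">
##INFO=<ID=FUNC,Number=1,Type=String,Description="Exonic functional class">
##INFO=<ID=SIFT,Number=1,Type=String,Description="SIFT call">
##INFO=<ID=POLYPHEN2,Number=1,Type=String,Description="PolyPhen2 call">
##INFO=<ID=FATHMM,Number=1,Type=String,Description="FATHMM call">
##INFO=<ID=CADD,Number=1,Type=Float,Description="CADD phred score">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO"""


def write_vcf(variants: list[AnnotatedVariant], path: str | Path) -> None:
    """Write variants as a minimal single-sample VCF 4.2 (vcf dialect)."""
    lines = [_VCF_HEADER]
    for v in sorted(variants, key=lambda v: (v.key.chrom, v.key.pos, v.key.alt)):
        cadd = v.predictor_scores.get("CADD")
        info = [
            f"GENE={','.join(sorted(v.genes))}",
            f"FUNC={v.func_class}",
        ]
        for pred, key in (("SIFT", "SIFT"), ("PolyPhen2", "POLYPHEN2"), ("FATHMM", "FATHMM")):
            call = v.predictor_calls.get(pred, MISSING)
            if call != MISSING:
                info.append(f"{key}={_CALL_OUT[call]}")
        if cadd is not None:
            info.append(f"CADD={cadd:.2f}")
        lines.append(
            "\t".join(
                [
                    f"chr{v.key.chrom}",
                    str(v.key.pos),
                    ".",
                    v.key.ref,
                    v.key.alt,
                    ".",
                    "PASS",
                    ";".join(info),
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_expression_tsv(expr: ExpressionProfile, path: str | Path) -> None:
    lines = ["gene\ttissue\trna_value\tprotein_level"]
    for gene in sorted(expr.evidence):
        ev = expr.evidence[gene]
        lines.append(
            f"{gene}\t{expr.tissue}\t{ev['rna_value']}\t{ev['protein_level']}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_bundle(
    cfg: SimulationConfig,
    out_dir: str | Path,
    write_vcfs: bool = False,
    deg_pathway: Optional[str] = None,
) -> dict:
    """Generate and write the complete input bundle plus a manifest.

    Emits pathways.gmt, background.tsv, expression.tsv, deg.txt, one
    annotator TSV per individual (optionally VCFs too), a ready-to-run
    ``config.yaml`` for ``vea run``, and ``manifest.json`` recording the
    configuration and planted truth.
    """
    import yaml

    cfg.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    db = simulate_pathway_db(cfg)
    bg = simulate_background(cfg)
    cohort = simulate_cohort(cfg, db)
    expr = simulate_expression(cfg)
    deg = simulate_deg_list(cfg, db, enriched_pathway=deg_pathway)

    formats_io.write_gmt(db, out / "pathways.gmt")
    formats_io.write_background_counts(bg, out / "background.tsv")
    write_expression_tsv(expr, out / "expression.tsv")
    (out / "deg.txt").write_text("\n".join(deg) + "\n")
    group_files: dict[str, list[str]] = {}
    for group, members in cohort.items():
        paths = []
        for j, member in enumerate(members, start=1):
            p = out / f"{group}_ind{j}.tsv"
            write_annotator_tsv(member, p)
            paths.append(p.name)
            if write_vcfs:
                write_vcf(member, out / f"{group}_ind{j}.vcf")
        group_files[group] = paths

    run_config = {
        "groups": {g: files for g, files in group_files.items()},
        "dialect": "annotator_tsv",
        "pathways": "pathways.gmt",
        "background": "background.tsv",
        "expression": {"path": "expression.tsv", "tissue": cfg.tissue},
        "deg": "deg.txt",
        "alpha": 0.05,
        "or_threshold": 1.5,
        "out": "results",
    }
    (out / "config.yaml").write_text(yaml.safe_dump(run_config, sort_keys=True))

    manifest = {
        "config": asdict(cfg),
        "planted": {g: cfg.planted_for_group(g) for g in cfg.group_sizes},
        "deg_pathway": deg_pathway,
        "files": {
            "pathways": "pathways.gmt",
            "background": "background.tsv",
            "expression": "expression.tsv",
            "deg": "deg.txt",
            "groups": group_files,
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    return manifest
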