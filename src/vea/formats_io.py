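"""Readers and writers for every external file the pipeline touches.

All parsing normalizes into the domain types of :mod:`vea.types`; no
statistics live here. Every reader accounts for dropped records
(``rows_in == kept + sum(dropped by reason)``) and logs a parse summary.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .errors import ConfigError, FileFormatError
from .types import (
    DAMAGING,
    MISSING,
    TOLERATED,
    AnnotatedVariant,
    BackgroundCounts,
    ContingencyTable2x2,
    ExpressionProfile,
    PathwayDB,
    PathwayEnrichmentResult,
    VariantKey,
    normalize_func_class,
)

logger = logging.getLogger(__name__)

#: Column order of TSV/JSON enrichment reports.
REPORT_COLUMNS = (
    "pathway_id",
    "name",
    "case_in",
    "case_out",
    "bg_in",
    "bg_out",
    "odds_ratio",
    "p_value",
    "fdr",
    "n_important_var",
    "epr",
    "genes",
)

# Fraction of data rows allowed to fail record-level parsing before the whole
# file is rejected.
_MAX_BAD_FRACTION = 0.01


@dataclass
class ColumnMap:
    """Maps logical fields onto annotator column names (TSV dialect) or VCF
    INFO keys (vcf dialect). Defaults follow common multianno output."""

    chrom: str = "Chr"
    pos: str = "Start"
    ref: str = "Ref"
    alt: str = "Alt"
    gene: str = "Gene.refGene"
    func_class: str = "ExonicFunc.refGene"
    predictor_calls: Mapping[str, str] = field(
        default_factory=lambda: {
            "SIFT": "SIFT_pred",
            "PolyPhen2": "Polyphen2_HDIV_pred",
            "FATHMM": "FATHMM_pred",
        }
    )
    predictor_scores: Mapping[str, str] = field(
        default_factory=lambda: {"CADD": "CADD_phred"}
    )
    #: annotator one-letter codes counted as a damaging call ("D" deleterious/
    #: probably damaging, "P" possibly damaging, "A" disease-causing).
    damaging_codes: frozenset[str] = frozenset({"D", "P", "A"})


#: INFO-key mapping used when reading the vcf dialect.
VCF_INFO_MAP = ColumnMap(
    gene="GENE",
    func_class="FUNC",
    predictor_calls={"SIFT": "SIFT", "PolyPhen2": "POLYPHEN2", "FATHMM": "FATHMM"},
    predictor_scores={"CADD": "CADD"},
)

_NULL_TOKENS = {"", ".", "NA", "NONE", "NAN", "UNKNOWN"}


@dataclass
class ParseSummary:
    """Accounting of one variant-table read."""

    n_records: int = 0
    n_kept: int = 0
    dropped: dict[str, int] = field(default_factory=dict)

    def drop(self, reason: str) -> None:
        self.dropped[reason] = self.dropped.get(reason, 0) + 1

    @property
    def n_dropped(self) -> int:
        return sum(self.dropped.values())


def _parse_genes(raw: str) -> frozenset[str]:
    parts: set[str] = set()
    for chunk in raw.replace(";", ",").split(","):
        g = chunk.strip().upper()
        if g and g not in _NULL_TOKENS:
            parts.add(g)
    return frozenset(parts)


def _parse_call(raw: Optional[str], damaging_codes: frozenset[str]) -> str:
    if raw is None:
        return MISSING
    code = str(raw).strip()
    if not code or code in _NULL_TOKENS:
        return MISSING
    return DAMAGING if code.upper() in damaging_codes else TOLERATED


def _parse_score(raw) -> Optional[float]:
    if raw is None:
        return None
    text = str(raw).strip()
    if not text or text in _NULL_TOKENS:
        return None
    try:
        return float(text)
    except ValueError:
        return None


def _select_panel(
    cmap: ColumnMap, predictor_panel: Optional[Sequence[str]]
) -> tuple[dict[str, str], dict[str, str]]:
    calls = dict(cmap.predictor_calls)
    scores = dict(cmap.predictor_scores)
    if predictor_panel is not None:
        panel = set(predictor_panel)
        calls = {k: v for k, v in calls.items() if k in panel}
        scores = {k: v for k, v in scores.items() if k in panel}
    return calls, scores


def read_variant_table(
    path: str | Path,
    dialect: str = "annotator_tsv",
    predictor_panel: Optional[Sequence[str]] = None,
    column_map: Optional[ColumnMap] = None,
    keep_filters: Iterable[str] = ("PASS", "."),
    return_summary: bool = False,
):
    """Read one individual's annotated variants.

    Parameters
    ----------
    path
        Input file.
    dialect
        ``"annotator_tsv"`` (tab-separated annotator output) or ``"vcf"``
        (single-sample VCF 4.x with annotations in INFO).
    predictor_panel
        Restrict the predictor columns read to these predictor names;
        ``None`` reads the whole configured panel.
    column_map
        Column/INFO-key mapping; defaults per dialect.
    keep_filters
        VCF FILTER values to keep (vcf dialect only).
    return_summary
        If true, return ``(variants, ParseSummary)`` instead of the list.

    Multi-allelic records are split into one variant per alternate allele;
    variants without any gene assignment are dropped (counted in the
    summary). The file is rejected if more than 1% of records fail
    record-level parsing.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"variant table not found: {path}")
    if dialect == "annotator_tsv":
        variants, summary = _read_annotator_tsv(
            path, column_map or ColumnMap(), predictor_panel
        )
    elif dialect == "vcf":
        variants, summary = _read_vcf(
            path, column_map or VCF_INFO_MAP, predictor_panel, set(keep_filters)
        )
    else:
        raise ConfigError(f"unknown variant-table dialect: {dialect!r}")

    n_bad = summary.dropped.get("bad_coordinate", 0) + summary.dropped.get(
        "bad_allele", 0
    )
    if summary.n_records and n_bad / summary.n_records > _MAX_BAD_FRACTION:
        raise FileFormatError(
            f"{path}: {n_bad}/{summary.n_records} records failed to parse "
            f"(>{_MAX_BAD_FRACTION:.0%})"
        )
    logger.info(
        "%s: %d records read, %d variants kept, dropped %s",
        path.name,
        summary.n_records,
        summary.n_kept,
        summary.dropped or "{}",
    )
    if return_summary:
        return variants, summary
    return variants


def _build_variant(
    chrom, pos, ref, alt, gene_raw, func_raw, call_fields, score_fields,
    damaging_codes, summary,
) -> Optional[AnnotatedVariant]:
    """Shared record assembly for both dialects; returns None on a drop."""
    summary.n_records += 1
    genes = _parse_genes(gene_raw)
    if not genes:
        summary.drop("no_gene")
        return None
    try:
        key = VariantKey.from_raw(chrom, pos, ref, alt)
    except (ValueError, TypeError):
        summary.drop("bad_allele")
        return None
    calls = {
        name: _parse_call(raw, damaging_codes) for name, raw in call_fields
    }
    scores = {name: _parse_score(raw) for name, raw in score_fields}
    summary.n_kept += 1
    return AnnotatedVariant(
        key=key,
        genes=genes,
        func_class=normalize_func_class(func_raw),
        predictor_calls=calls,
        predictor_scores=scores,
    )


def _read_annotator_tsv(path, cmap, predictor_panel):
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in (cmap.chrom, cmap.pos, cmap.ref, cmap.alt, cmap.gene, cmap.func_class):
        if col not in df.columns:
            raise ConfigError(f"{path}: required column {col!r} missing")
    calls_map, scores_map = _select_panel(cmap, predictor_panel)
    for name, col in list(calls_map.items()):
        if col not in df.columns:
            logger.warning("%s: predictor column %r absent; %s treated as missing",
                           path.name, col, name)
            del calls_map[name]
    for name, col in list(scores_map.items()):
        if col not in df.columns:
            logger.warning("%s: score column %r absent; %s treated as missing",
                           path.name, col, name)
            del scores_map[name]

    summary = ParseSummary()
    variants: list[AnnotatedVariant] = []
    for row in df.itertuples(index=False):
        row_d = dict(zip(df.columns, row))
        try:
            pos = int(str(row_d[cmap.pos]).strip())
        except ValueError:
            summary.n_records += 1
            summary.drop("bad_coordinate")
            continue
        v = _build_variant(
            row_d[cmap.chrom],
            pos,
            row_d[cmap.ref],
            row_d[cmap.alt],
            row_d[cmap.gene],
            row_d[cmap.func_class],
            [(n, row_d[c]) for n, c in calls_map.items()],
            [(n, row_d[c]) for n, c in scores_map.items()],
            cmap.damaging_codes,
            summary,
        )
        if v is not None:
            variants.append(v)
    return variants, summary


def _read_vcf(path, cmap, predictor_panel, keep_filters):
    from cyvcf2 import VCF

    calls_map, scores_map = _select_panel(cmap, predictor_panel)
    summary = ParseSummary()
    variants: list[AnnotatedVariant] = []
    vcf = VCF(str(path))
    try:
        for rec in vcf:
            # cyvcf2 reports None for PASS or '.'
            if rec.FILTER is not None and rec.FILTER not in keep_filters:
                summary.n_records += len(rec.ALT) or 1
                for _ in rec.ALT or [None]:
                    summary.drop("filtered")
                continue
            info = rec.INFO
            gene_raw = str(info.get(cmap.gene) or "")
            func_raw = str(info.get(cmap.func_class) or "")
            call_fields = [(n, info.get(k)) for n, k in calls_map.items()]
            score_fields = [(n, info.get(k)) for n, k in scores_map.items()]
            for alt in rec.ALT:
                v = _build_variant(
                    rec.CHROM, rec.POS, rec.REF, alt, gene_raw, func_raw,
                    call_fields, score_fields, cmap.damaging_codes, summary,
                )
                if v is not None:
                    variants.append(v)
    finally:
        vcf.close()
    return variants, summary


def read_gmt(path: str | Path) -> PathwayDB:
    """Read gene sets in GMT format (``id<TAB>name<TAB>gene...``).

    Duplicate genes within a line are deduplicated; a line without genes is
    skipped with a warning; a duplicate pathway ID rejects the file.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"GMT file not found: {path}")
    pathways: dict[str, frozenset[str]] = {}
    names: dict[str, str] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 2:
            raise FileFormatError(f"{path}:{lineno}: expected >=2 tab-separated fields")
        pid, name = fields[0].strip(), fields[1].strip()
        genes = frozenset(
            g.strip().upper() for g in fields[2:] if g.strip()
        )
        if pid in pathways:
            raise FileFormatError(f"{path}:{lineno}: duplicate pathway ID {pid}")
        if not genes:
            logger.warning("%s:%d: pathway %s has no genes; skipped", path.name, lineno, pid)
            continue
        pathways[pid] = genes
        names[pid] = name
    return PathwayDB(pathways=pathways, names=names)


def write_gmt(db: PathwayDB, path: str | Path) -> None:
    """Write a PathwayDB as GMT with deterministic ordering."""
    lines = []
    for pid in sorted(db.pathways):
        lines.append("\t".join([pid, db.name_of(pid), *sorted(db.pathways[pid])]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_background_counts(path: str | Path) -> BackgroundCounts:
    """Read a per-gene count table of reference-population common variants.

    Format: ``#``-prefixed ``key=value`` metadata lines, then ``gene<TAB>count``
    rows. Duplicate gene rows are summed with a warning; a negative or
    non-integer count rejects the file naming the row.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"background counts file not found: {path}")
    meta: dict[str, str] = {}
    per_gene: dict[str, int] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if "=" in body:
                k, v = body.split("=", 1)
                meta[k.strip()] = v.strip()
            continue
        fields = line.split("\t")
        if len(fields) < 2:
            raise FileFormatError(f"{path}:{lineno}: expected gene<TAB>count")
        gene = fields[0].strip().upper()
        try:
            count = int(fields[1].strip())
        except ValueError:
            raise FileFormatError(
                f"{path}:{lineno}: non-integer count {fields[1]!r} for {gene}"
            ) from None
        if count < 0:
            raise FileFormatError(f"{path}:{lineno}: negative count for {gene}")
        if gene in per_gene:
            logger.warning("%s:%d: duplicate gene %s; counts summed", path.name, lineno, gene)
            per_gene[gene] += count
        else:
            per_gene[gene] = count
    meta.setdefault("ancestry", "nfe")
    return BackgroundCounts(per_gene=per_gene, meta=meta)


def write_background_counts(bg: BackgroundCounts, path: str | Path) -> None:
    lines = [f"# {k}={v}" for k, v in sorted(bg.meta.items())]
    lines += [f"{g}\t{bg.per_gene[g]}" for g in sorted(bg.per_gene)]
    Path(path).write_text("\n".join(lines) + "\n")


def read_expression_table(
    path: str | Path,
    tissue: str,
    rna_threshold: float = 1.0,
    protein_levels: Iterable[str] = ("Low", "Medium", "High"),
) -> ExpressionProfile:
    """Read a per-gene tissue expression table (HPA-style TSV).

    A gene is expressed when its RNA value reaches ``rna_threshold`` OR its
    protein level is in ``protein_levels``. The requested tissue must exist
    in the table.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"expression table not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("gene", "tissue", "rna_value", "protein_level"):
        if col not in df.columns:
            raise ConfigError(f"{path}: required column {col!r} missing")
    available = sorted(df["tissue"].unique())
    sub = df[df["tissue"] == tissue]
    if sub.empty:
        raise ConfigError(
            f"{path}: tissue {tissue!r} not present; available: {available}"
        )
    accepted = set(protein_levels)
    expressed: dict[str, bool] = {}
    evidence: dict[str, dict] = {}
    for row in sub.itertuples(index=False):
        gene = str(row.gene).strip().upper()
        rna = _parse_score(row.rna_value)
        protein = str(row.protein_level).strip()
        flag = (rna is not None and rna >= rna_threshold) or (protein in accepted)
        expressed[gene] = expressed.get(gene, False) or flag
        evidence[gene] = {"rna_value": rna, "protein_level": protein}
    return ExpressionProfile(tissue=tissue, expressed=expressed, evidence=evidence)


def read_deg_list(path: str | Path) -> frozenset[str]:
    """Read a plain-text gene list (one symbol per line, ``#`` comments)."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"DEG list not found: {path}")
    genes = set()
    for line in path.read_text().splitlines():
        body = line.split("#", 1)[0].strip()
        if body:
            genes.add(body.upper())
    return frozenset(genes)


def _fmt_float(x: Optional[float]) -> str:
    if x is None:
        return "NA"
    return format(float(x), ".10g")


def write_report(
    results: Sequence[PathwayEnrichmentResult],
    path: str | Path,
    format: str = "tsv",
    preserve_order: bool = False,
) -> None:
    """Write an enrichment report with deterministic row and column order.

    Rows are sorted by adjusted p ascending with pathway-ID tiebreak unless
    ``preserve_order`` is set (used for pre-ranked tables). The JSON format
    round-trips losslessly through :func:`read_report`.
    """
    rows = list(results)
    if not preserve_order:
        rows.sort(key=lambda r: (r.fdr, r.pathway_id))
    path = Path(path)
    if format == "tsv":
        lines = ["\t".join(REPORT_COLUMNS)]
        for r in rows:
            lines.append(
                "\t".join(
                    [
                        r.pathway_id,
                        r.name,
                        str(r.table.case_in),
                        str(r.table.case_out),
                        str(r.table.bg_in),
                        str(r.table.bg_out),
                        _fmt_float(r.odds_ratio),
                        _fmt_float(r.p_value),
                        _fmt_float(r.fdr),
                        str(r.n_important_var),
                        _fmt_float(r.epr),
                        ",".join(r.genes),
                    ]
                )
            )
        path.write_text("\n".join(lines) + "\n")
    elif format == "json":
        payload = [
            {
                "pathway_id": r.pathway_id,
                "name": r.name,
                "case_in": r.table.case_in,
                "case_out": r.table.case_out,
                "bg_in": r.table.bg_in,
                "bg_out": r.table.bg_out,
                "odds_ratio": r.odds_ratio,
                "p_value": r.p_value,
                "fdr": r.fdr,
                "n_important_var": r.n_important_var,
                "important_var_genes": {
                    g: r.important_var_genes[g] for g in sorted(r.important_var_genes)
                },
                "genes": list(r.genes),
                "epr": r.epr,
                "enriched": r.enriched,
            }
            for r in rows
        ]
        path.write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")
    else:
        raise ConfigError(f"unknown report format: {format!r}")


def read_report(path: str | Path, format: str = "json") -> list[PathwayEnrichmentResult]:
    """Read back an enrichment report (JSON is lossless; TSV loses the
    per-gene ImportantVar map and the enriched flag)."""
    path = Path(path)
    results: list[PathwayEnrichmentResult] = []
    if format == "json":
        for d in json.loads(path.read_text()):
            results.append(
                PathwayEnrichmentResult(
                    pathway_id=d["pathway_id"],
                    name=d["name"],
                    table=ContingencyTable2x2(
                        d["case_in"], d["case_out"], d["bg_in"], d["bg_out"]
                    ),
                    odds_ratio=d["odds_ratio"],
                    p_value=d["p_value"],
                    fdr=d["fdr"],
                    n_important_var=d["n_important_var"],
                    important_var_genes=dict(d["important_var_genes"]),
                    genes=tuple(d["genes"]),
                    epr=d["epr"],
                    enriched=d["enriched"],
                )
            )
    elif format == "tsv":
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        for row in df.itertuples(index=False):
            epr = None if row.epr == "NA" else float(row.epr)
            results.append(
                PathwayEnrichmentResult(
                    pathway_id=row.pathway_id,
                    name=row.name,
                    table=ContingencyTable2x2(
                        int(row.case_in), int(row.case_out), int(row.bg_in), int(row.bg_out)
                    ),
                    odds_ratio=float(row.odds_ratio),
                    p_value=float(row.p_value),
                    fdr=float(row.fdr),
                    n_important_var=int(row.n_important_var),
                    genes=tuple(g for g in row.genes.split(",") if g),
                    epr=epr,
                )
            )
    else:
        raise ConfigError(f"unknown report format: {format!r}")
    return results
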