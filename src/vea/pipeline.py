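"""End-to-end orchestration: files in, reports out.

Mirrors the full workflow: per-group common-variant extraction, per-group
enrichment against the population background, Venn partition of the
enriched sets into exclusive enriched pathways (eEP), ranked eEP tables,
and the optional DEG over-representation overlay.
"""
from __future__ import annotations

import logging
import re
from pathlib import Path

import yaml

from . import formats_io
from .cohort import build_group_profile, restrict_to_universe
from .config import RunConfig

from .exclusivity import deg_ora, overlay_venn, venn_partition, write_venn_json
from .expression import attach_epr
from .stats import rank_results, run_vea

logger = logging.getLogger(__name__)

RANK_MODES = ("important_var", "odds_ratio", "epr")


def _safe_label(label: str) -> str:
    return re.sub(r"[^A-Za-z0-9_.-]+", "_", label)


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the configured workflow; returns a summary dict.

    All outputs are deterministic functions of the inputs. On failure every
    file written so far is removed so no partial output survives.
    """
    cfg.check_files()
    out = Path(cfg.out)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(path: Path):
        written.append(path)
        return path

    try:
        return _run(cfg, out, emit)
    except Exception:
        for p in written:
            p.unlink(missing_ok=True)
        raise


def _run(cfg: RunConfig, out: Path, emit) -> dict:
    db = formats_io.read_gmt(cfg.pathways)
    background = restrict_to_universe(
        formats_io.read_background_counts(cfg.background), db
    )
    expr = None
    if cfg.expression is not None:
        expr = formats_io.read_expression_table(
            cfg.expression.path,
            tissue=cfg.expression.tissue,
            rna_threshold=cfg.expression.rna_threshold,
            protein_levels=cfg.expression.protein_levels,
        )
    policy = cfg.important_var.to_policy()

    group_results = {}
    ep_sets: dict[str, set[str]] = {}
    for label, files in cfg.groups.items():
        members = [
            formats_io.read_variant_table(f, dialect=cfg.dialect) for f in files
        ]
        profile = restrict_to_universe(build_group_profile(label, members), db)
        results = run_vea(profile, background, db, policy=policy, alpha=cfg.alpha)
        if expr is not None:
            results = attach_epr(results, db, expr)
        safe = _safe_label(label)
        formats_io.write_report(results, emit(out / f"enrichment_{safe}.tsv"), "tsv")
        formats_io.write_report(results, emit(out / f"enrichment_{safe}.json"), "json")
        eps = {r.pathway_id for r in results if r.enriched}
        emit(out / f"ep_{safe}.txt").write_text(
            "\n".join(sorted(eps)) + ("\n" if eps else "")
        )
        group_results[label] = results
        ep_sets[label] = eps

    summary: dict = {
        "n_pathways": len(db),
        "groups": {g: {"n_enriched": len(s)} for g, s in ep_sets.items()},
    }

    eep: dict[str, set[str]] = {}
    if len(ep_sets) >= 2:
        partition = venn_partition(ep_sets)
        write_venn_json(partition, emit(out / "eep_venn.json"))
        eep = {g: set(partition.exclusive_of(g)) for g in ep_sets}
        for g in ep_sets:
            summary["groups"][g]["n_exclusive"] = len(eep[g])
    else:
        logger.info("fewer than 2 groups: Venn/eEP stage skipped")
        eep = dict(ep_sets)

    for label, results in group_results.items():
        safe = _safe_label(label)
        exclusive = [r for r in results if r.pathway_id in eep.get(label, set())]
        for mode in RANK_MODES:
            if mode == "epr" and expr is None:
                continue
            ranked = rank_results(exclusive, mode=mode, or_threshold=cfg.or_threshold)
            formats_io.write_report(
                ranked, emit(out / f"eep_{safe}_by_{mode}.tsv"), "tsv",
                preserve_order=True,
            )

    if cfg.deg is not None:
        deg = formats_io.read_deg_list(cfg.deg)
        ora = deg_ora(deg, db, alpha=cfg.alpha, significant_only=False)
        lines = ["pathway_id\toverlap\tn_pathway\tp_value\tfdr\tsignificant"]
        for pid in sorted(ora):
            r = ora[pid]
            lines.append(
                f"{pid}\t{r.overlap}\t{r.n_pathway}\t"
                f"{format(r.p_value, '.10g')}\t{format(r.fdr, '.10g')}\t"
                f"{int(r.fdr < cfg.alpha)}"
            )
        emit(out / "deg_ora.tsv").write_text("\n".join(lines) + "\n")
        deg_ep = {pid for pid, r in ora.items() if r.fdr < cfg.alpha}
        if eep:
            write_venn_json(
                overlay_venn(eep, deg_ep), emit(out / "overlay_venn.json")
            )
        summary["deg_n_enriched"] = len(deg_ep)

    # provenance echo of the executed configuration
    emit(out / "run_config.yaml").write_text(
        yaml.safe_dump(cfg.model_dump(mode="json"), sort_keys=True)
    )
    return summary
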