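"""Pipeline orchestration: run every stage from one config and emit a
consolidated report.

Stages whose inputs are absent are skipped; a stage failure is recorded in
the report's ``errors`` section and independent stages still run.  All
randomness flows from the single config seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import asepyro, io, promoter, qpcr, regdiv, reporter, seqvar
from .seqvar import PROMOTER, TRANSCRIPT, HaplotypeSet

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Inputs and knobs for one pipeline run.

    File paths may be ``None`` to skip the corresponding stage.  FASTA
    record ids follow the ``{group}_{region}`` convention written by the
    synthetic generator (``NL_cds``, ``AR_prom``, ``HY_prom_nl`` ...).
    """

    transcripts_fasta: str | None = None
    promoters_fasta: str | None = None
    genotype_tsv: str | None = None
    motifs_tsv: str | None = None
    counts_tsv: str | None = None
    ct_tsv: str | None = None
    luminescence_tsv: str | None = None

    p1: str = "NL"
    p2: str = "AR"
    hybrid: str = "HY"
    calibrator: str = "AR"
    target_gene: str = "p38"
    reference_gene: str = "beta_actin"
    marker: str = "S7"
    cds_start: int = 272
    cds_end: int = 1357
    alpha: float = 0.05
    epsilon: float = 0.5
    pooling: str = "pooled"
    seed: int = 0
    outdir: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def validate(self) -> None:
        labels = (self.p1, self.p2, self.hybrid)
        if len(set(labels)) != 3:
            raise ValueError("group labels p1/p2/hybrid must be distinct")
        for name in (
            "transcripts_fasta", "promoters_fasta", "genotype_tsv",
            "motifs_tsv", "counts_tsv", "ct_tsv", "luminescence_tsv",
        ):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name}: {p} does not exist")


def _seqvar_stage(cfg: RunConfig) -> dict[str, Any]:
    seqs = io.read_fasta(cfg.transcripts_fasta)
    hap = lambda g: HaplotypeSet(g, TRANSCRIPT, seqs[f"{g}_cds"])
    hybrid = hap(cfg.hybrid) if f"{cfg.hybrid}_cds" in seqs else None
    gt = pd.read_csv(cfg.genotype_tsv, sep="\t") if cfg.genotype_tsv else None
    variants = seqvar.call_variants(hap(cfg.p1), hap(cfg.p2), hybrid, gt)
    partition = seqvar.classify_fixed_differences(variants, cfg.p1, cfg.p2)
    annotations = {}
    for v in variants:
        ann = seqvar.annotate_coding(v, cfg.cds_start, cfg.cds_end, hap(cfg.p1))
        if ann is not None:
            annotations[v.label] = dataclasses.asdict(ann)
    table = io.variants_to_dataframe(variants)
    return {
        "variants": table.to_dict(orient="records"),
        "fixed": [v.label for v in partition["fixed"]],
        "polymorphic": [v.label for v in partition["polymorphic"]],
        "coding_annotations": annotations,
        "n_variants": len(variants),
    }


def _promoter_stage(cfg: RunConfig) -> dict[str, Any]:
    seqs = io.read_fasta(cfg.promoters_fasta)
    p1 = HaplotypeSet(cfg.p1, PROMOTER, seqs[f"{cfg.p1}_prom"])
    p2 = HaplotypeSet(cfg.p2, PROMOTER, seqs[f"{cfg.p2}_prom"])
    hyb_keys = [k for k in seqs if k.startswith(f"{cfg.hybrid}_prom")]
    hybrid = (
        tuple(HaplotypeSet(cfg.hybrid, PROMOTER, seqs[k]) for k in hyb_keys[:2])
        if len(hyb_keys) == 2
        else None
    )
    variants = promoter.call_promoter_variants(p1, p2, hybrid=hybrid)
    motifs = (
        promoter.load_motifs(cfg.motifs_tsv) if cfg.motifs_tsv else []
    )
    diffs = promoter.diff_tfbs(p1, p2, variants, motifs) if motifs else []
    return {
        "variants": io.variants_to_dataframe(variants).to_dict(orient="records"),
        "tfbs_diffs": [dataclasses.asdict(d) for d in diffs],
        "n_variants": len(variants),
    }


def _ase_stage(cfg: RunConfig) -> dict[str, Any]:
    counts = pd.read_csv(cfg.counts_tsv, sep="\t")
    result = asepyro.estimate_ase(counts, pooling=cfg.pooling)
    return dataclasses.asdict(result)


def _qpcr_stage(cfg: RunConfig) -> dict[str, Any]:
    ct = pd.read_csv(cfg.ct_tsv, sep="\t")
    rel = qpcr.ddct(
        ct,
        calibrator=cfg.calibrator,
        target=cfg.target_gene,
        reference=cfg.reference_gene,
        alpha=cfg.alpha,
    )
    out = {
        "group_stats": rel.group_stats.to_dict(orient="records"),
        "anova_pvalue": rel.anova_pvalue,
        "calibrator": rel.calibrator,
        "A": qpcr.parental_divergence_A(rel, cfg.p1, cfg.p2),
    }
    if rel.pairwise is not None:
        out["pairwise"] = rel.pairwise.to_dict(orient="records")
    return out, rel


def run_pipeline(cfg: RunConfig) -> dict[str, Any]:
    """Execute all configured stages in dependency order.

    Returns the consolidated report (also written as JSON and Markdown
    when ``cfg.outdir`` is set).  The report's ``errors`` maps stage name
    to message for every stage that failed; downstream stages depending on
    a failed stage are skipped.
    """
    cfg.validate()
    report: dict[str, Any] = {"config": dataclasses.asdict(cfg), "errors": {}}
    rel = None
    ase_result = None

    if cfg.transcripts_fasta:
        try:
            report["coding"] = _seqvar_stage(cfg)
        except Exception as exc:
            log.exception("seqvar stage failed")
            report["errors"]["seqvar"] = str(exc)
    if cfg.promoters_fasta:
        try:
            report["promoter"] = _promoter_stage(cfg)
        except Exception as exc:
            log.exception("promoter stage failed")
            report["errors"]["promoter"] = str(exc)
    if cfg.counts_tsv:
        try:
            report["ase"] = _ase_stage(cfg)
            ase_result = asepyro.estimate_ase(
                pd.read_csv(cfg.counts_tsv, sep="\t"), pooling=cfg.pooling
            )
        except Exception as exc:
            log.exception("ase stage failed")
            report["errors"]["ase"] = str(exc)
    if cfg.ct_tsv:
        try:
            out, rel = _qpcr_stage(cfg)
            report["expression"] = out
        except Exception as exc:
            log.exception("qpcr stage failed")
            report["errors"]["qpcr"] = str(exc)
    if rel is not None:
        try:
            call = regdiv.classify_inheritance(
                rel, cfg.hybrid, cfg.p1, cfg.p2, alpha=cfg.alpha,
                epsilon=cfg.epsilon,
            )
            report["inheritance"] = dataclasses.asdict(call)
        except Exception as exc:
            log.exception("inheritance stage failed")
            report["errors"]["inheritance"] = str(exc)
        if ase_result is not None:
            try:
                a = qpcr.parental_divergence_A(rel, cfg.p1, cfg.p2)
                ct_res = regdiv.decompose_cis_trans(
                    a, ase_result, alpha=cfg.alpha, epsilon=cfg.epsilon
                )
                report["cistrans"] = dataclasses.asdict(ct_res)
            except Exception as exc:
                log.exception("cistrans stage failed")
                report["errors"]["cistrans"] = str(exc)
    if cfg.luminescence_tsv:
        try:
            lum = pd.read_csv(cfg.luminescence_tsv, sep="\t")
            act = reporter.promoter_activity(lum, p1=cfg.p1, p2=cfg.p2)
            report["reporter"] = dataclasses.asdict(act)
        except Exception as exc:
            log.exception("reporter stage failed")
            report["errors"]["reporter"] = str(exc)

    if cfg.outdir:
        outdir = Path(cfg.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "report.json").write_text(
            json.dumps(report, indent=2, default=str) + "\n"
        )
        (outdir / "report.md").write_text(render_markdown(report))
    return report


def render_markdown(report: dict[str, Any]) -> str:
    """Human-readable one-page summary of a pipeline report."""
    lines = ["# hybridase run report", ""]
    if "coding" in report:
        c = report["coding"]
        lines += [
            "## Coding variants",
            f"- {c['n_variants']} variants; fixed inter-parental: "
            f"{', '.join(c['fixed']) or 'none'}",
            "",
        ]
        for rec in c["variants"]:
            ann = c["coding_annotations"].get(rec["label"])
            syn = (
                " (synonymous)" if ann and ann["synonymous"]
                else " (nonsynonymous)" if ann else ""
            )
            lines.append(f"  - {rec['label']}: {rec['rendering']}{syn}")
        lines.append("")
    if "promoter" in report:
        p = report["promoter"]
        lines += ["## Promoter variants", f"- {p['n_variants']} variants"]
        for rec in p["variants"]:
            lines.append(f"  - {rec['label']}: {rec['rendering']}")
        for d in p["tfbs_diffs"]:
            lines.append(
                f"  - TFBS {d['motif']} present only in {d['allele_with_site']} "
                f"(span {d['site_span']}, variant {d['overlapping_variant']})"
            )
        lines.append("")
    if "ase" in report:
        a = report["ase"]
        lines += [
            "## Allele-specific expression",
            f"- parent-1 allele frequency {a['freq_p1']:.3f} "
            f"[{a['ci_low']:.3f}, {a['ci_high']:.3f}], "
            f"cis effect B = {a['cis_effect_B']:.3f} "
            f"(bias p = {a['pvalue_bias']:.3g})",
            "",
        ]
    if "expression" in report:
        e = report["expression"]
        lines += ["## Relative expression (2^-ddCt)"]
        for rec in e["group_stats"]:
            lines.append(
                f"  - {rec['group']}: {rec['mean_fold']:.3f} ± "
                f"{rec['sd_fold']:.3f} ({rec['letter']})"
            )
        lines += [f"- combined cis+trans effect A = {e['A']:.3f}", ""]
    if "inheritance" in report:
        i = report["inheritance"]
        lines += [
            "## Inheritance mode",
            f"- {i['mode']} (hybrid {i['hybrid_mean']:.3f} vs MPV {i['mpv']:.3f})",
            "",
        ]
    if "cistrans" in report:
        c = report["cistrans"]
        lines += [
            "## Cis/trans decomposition",
            f"- A = {c['A']:.3f}, B = {c['B']:.3f}, T = {c['T']:.3f} -> "
            f"{c['category']}",
            "",
        ]
    if "reporter" in report:
        r = report["reporter"]
        p = r["pvalue"]
        lines += [
            "## Promoter activity (dual luciferase)",
            f"- fold P1/P2 = {r['fold_p1_vs_p2']:.3f}"
            + (f" (p = {p:.3g})" if p is not None else ""),
            "",
        ]
    if report["errors"]:
        lines += ["## Errors"]
        for stage, msg in report["errors"].items():
            lines.append(f"- {stage}: {msg}")
        lines.append("")
    return "\n".join(lines)
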