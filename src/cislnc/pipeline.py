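"""End-to-end orchestration: annotation -> paired DE -> cis screen ->
association (-> qPCR), with a machine-readable run summary and an audit log.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import annotation as ann
from . import association as assoc
from . import cis_screen as screen_mod
from . import paired_de as de_mod
from . import qpcr as qpcr_mod

logger = logging.getLogger(__name__)

_PATH_KEYS = (
    "annotation", "expression_a", "metadata_a", "expression_b", "metadata_b",
    "methylation", "qpcr_plate",
)


@dataclass
class RunConfig:
    """Paths and parameters for a full pipeline run."""

    annotation: Path
    expression_a: Path
    metadata_a: Path
    expression_b: Path
    metadata_b: Path
    outdir: Path
    methylation: Optional[Path] = None
    qpcr_plate: Optional[Path] = None
    qpcr_reference_gene: str = "RNA18S"
    qpcr_control_condition: str = "non_targeting"
    qpcr_knocked_gene: Optional[str] = None
    qpcr_readout_gene: Optional[str] = None
    alpha: float = 0.05
    fc_threshold: float = 1.5
    max_gap: int = 1500
    pseudocount: float = 0.01
    test: str = "wilcoxon"
    association_cohort: str = "b"
    correlation_scope: str = "tumors"  # tumors | all

    def validate(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.fc_threshold < 1:
            raise ValueError(f"fc_threshold must be >= 1, got {self.fc_threshold}")
        if self.max_gap < 0:
            raise ValueError(f"max_gap must be >= 0, got {self.max_gap}")
        if self.pseudocount <= 0:
            raise ValueError(f"pseudocount must be > 0, got {self.pseudocount}")
        if self.test not in ("wilcoxon", "ttest"):
            raise ValueError(f"test must be 'wilcoxon' or 'ttest', got {self.test!r}")
        if self.association_cohort not in ("a", "b"):
            raise ValueError("association_cohort must be 'a' or 'b'")
        if self.correlation_scope not in ("tumors", "all"):
            raise ValueError("correlation_scope must be 'tumors' or 'all'")
        for key in _PATH_KEYS:
            path = getattr(self, key)
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(f"{key}: no such file: {path}")


def load_config(path: str | Path, outdir: str | Path, **overrides) -> RunConfig:
    """Load a flat YAML config; relative paths resolve against the file.

    Keyword overrides (e.g. from CLI flags) take precedence over the file.
    """
    path = Path(path)
    with path.open() as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in fields(RunConfig)}
    cfg_kwargs = {k: v for k, v in raw.items() if k in known}
    unknown = set(raw) - known - {"simulation"}
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg_kwargs.update({k: v for k, v in overrides.items() if v is not None})
    for key in _PATH_KEYS:
        val = cfg_kwargs.get(key)
        if val is not None:
            p = Path(val)
            cfg_kwargs[key] = p if p.is_absolute() else path.parent / p
    cfg = RunConfig(outdir=Path(outdir), **cfg_kwargs)
    cfg.validate()
    return cfg


def _setup_run_logger(outdir: Path) -> logging.Logger:
    run_logger = logging.getLogger("cislnc.run")
    run_logger.setLevel(logging.INFO)
    for h in list(run_logger.handlers):
        run_logger.removeHandler(h)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(
        logging.Formatter("%(asctime)s\t%(levelname)s\t%(message)s",
                          datefmt="%Y-%m-%dT%H:%M:%S")
    )
    run_logger.addHandler(handler)
    return run_logger


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        return wrapper
    return deco


def run_all(cfg: RunConfig) -> dict:
    """Execute every stage and return (and write) the run summary.

    Outputs under ``cfg.outdir``: pairs.tsv, de_a.tsv, de_b.tsv,
    candidates.tsv, associations.tsv, optional qpcr tables, summary.json
    and run.log.  All analysis stages are deterministic, so reruns on the
    same inputs reproduce the TSV outputs byte for byte.
    """
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log = _setup_run_logger(outdir)
    for key in ("alpha", "fc_threshold", "max_gap", "pseudocount", "test",
                "association_cohort", "correlation_scope"):
        log.info("param\t%s=%s", key, getattr(cfg, key))
    for key in _PATH_KEYS:
        log.info("input\t%s=%s", key, getattr(cfg, key))

    genes = _stage("annotation")(ann.read_gtf)(cfg.annotation)
    pairs = _stage("annotation")(ann.neighbor_pairs)(genes, max_gap=cfg.max_gap)
    ann.write_pairs_tsv(pairs, outdir / "pairs.tsv")
    n_lnc = sum(g.biotype == "lncRNA" for g in genes)
    n_pcg = sum(g.biotype == "protein_coding" for g in genes)
    log.info("stage annotation: %d genes (%d lncRNA, %d protein_coding), "
             "%d neighbor pairs within %d bp", len(genes), n_lnc, n_pcg,
             len(pairs), cfg.max_gap)

    @_stage("paired_de")
    def _de(expr_path, meta_path, label):
        cohort = de_mod.read_cohort(expr_path, meta_path)
        de = de_mod.call_deregulated(
            cohort, alpha=cfg.alpha, fc_threshold=cfg.fc_threshold,
            pseudocount=cfg.pseudocount, test=cfg.test,
        )
        de_mod.write_de_tsv(de, outdir / f"de_{label}.tsv")
        log.info("stage paired_de[%s]: %d genes tested, %d deregulated",
                 label, len(de), int(de["deregulated"].sum()))
        return cohort, de

    cohort_a, de_a = _de(cfg.expression_a, cfg.metadata_a, "a")
    cohort_b, de_b = _de(cfg.expression_b, cfg.metadata_b, "b")

    consistent = _stage("cis_screen")(screen_mod.cross_cohort_deregulated)(de_a, de_b)
    candidates = _stage("cis_screen")(screen_mod.screen)(de_a, de_b, pairs)
    ranked = screen_mod.rank_candidates(candidates)
    screen_mod.write_candidates_tsv(ranked, outdir / "candidates.tsv")
    n_discordant = sum(p.concordance == "discordant" for p in ranked)
    log.info("stage cis_screen: %d cross-cohort deregulated genes, %d candidate "
             "pairs (%d discordant)", len(consistent), len(ranked), n_discordant)

    assoc_results = _stage("association")(_associate_candidates)(cfg, cohort_a, cohort_b, ranked)
    assoc_results.to_csv(outdir / "associations.tsv", sep="\t", index=False,
                         float_format="%.6g")
    log.info("stage association: %d candidate pairs characterized", len(assoc_results))

    qpcr_summary = {}
    if cfg.qpcr_plate is not None:
        plate = _stage("qpcr")(qpcr_mod.read_plate_csv)(
            cfg.qpcr_plate, cfg.qpcr_reference_gene, cfg.qpcr_control_condition
        )
        quantities = qpcr_mod.quantify_all(plate)
        qpcr_mod.write_quantities_tsv(quantities, outdir / "qpcr_quantities.tsv")
        if cfg.qpcr_knocked_gene and cfg.qpcr_readout_gene:
            report = _stage("qpcr")(qpcr_mod.knockdown_report)(
                plate, cfg.qpcr_knocked_gene, cfg.qpcr_readout_gene
            )
            qpcr_mod.write_quantities_tsv(report, outdir / "qpcr_knockdown.tsv")
            knocked = report[(report["role"] == "knocked")
                             & (report["fold_reduction"].notna())]
            if len(knocked):
                best = knocked.loc[knocked["fold_reduction"].idxmax()]
                qpcr_summary = {
                    "qpcr_max_fold_reduction": round(float(best["fold_reduction"]), 4),
                    "qpcr_max_fold_reduction_condition": str(best["condition"]),
                }
        log.info("stage qpcr: %d (gene, condition) quantities", len(quantities))

    summary = {
        "genes_annotated": len(genes),
        "genes_lncRNA": n_lnc,
        "genes_protein_coding": n_pcg,
        "genes_tested_a": int(len(de_a)),
        "genes_tested_b": int(len(de_b)),
        "deregulated_a": int(de_a["deregulated"].sum()),
        "deregulated_b": int(de_b["deregulated"].sum()),
        "cross_cohort_consistent": len(consistent),
        "pairs_within_max_gap": len(pairs),
        "candidates": len(ranked),
        "discordant_candidates": n_discordant,
        "concordant_candidates": sum(p.concordance == "concordant" for p in ranked),
        "mixed_candidates": sum(p.concordance == "mixed" for p in ranked),
        "parameters": {
            "alpha": cfg.alpha,
            "fc_threshold": cfg.fc_threshold,
            "max_gap": cfg.max_gap,
            "pseudocount": cfg.pseudocount,
            "test": cfg.test,
        },
        **qpcr_summary,
    }
    with (outdir / "summary.json").open("w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    log.info("run complete: %d candidates (%d discordant)", len(ranked), n_discordant)
    return summary


def _associate_candidates(
    cfg: RunConfig,
    cohort_a: de_mod.PairedExpressionSet,
    cohort_b: de_mod.PairedExpressionSet,
    candidates,
) -> pd.DataFrame:
    """Spearman/tertile/methylation/stage characterization per candidate."""
    cohort = cohort_b if cfg.association_cohort == "b" else cohort_a
    sample_ids = (cohort.condition_samples("tumor") if cfg.correlation_scope == "tumors"
                  else cohort.samples["sample_id"].tolist())
    betas = None
    if cfg.methylation is not None:
        betas = pd.read_csv(cfg.methylation, sep="\t", index_col=0)
    stage = cohort.sample_stage().reindex(sample_ids).dropna()
    stage_levels = stage.unique()

    rows = []
    for pair in candidates:
        lnc_expr = cohort.values.loc[pair.lnc_id, sample_ids].astype(float)
        pcg_expr = cohort.values.loc[pair.pcg_id, sample_ids].astype(float)
        pcg_betas = None
        if betas is not None and pair.pcg_id in betas.index:
            pcg_betas = betas.loc[pair.pcg_id].astype(float)
        res = assoc.associate_pair(lnc_expr, pcg_expr, pair.lnc_id, pair.pcg_id,
                                   pcg_betas=pcg_betas)
        row = {
            "lnc_id": res.lnc_id,
            "pcg_id": res.pcg_id,
            "rho": res.rho,
            "rho_p": res.rho_p,
            "tertile_p": res.tertile_p,
            "tertile_direction": res.tertile_direction,
            "methylation_p": res.methylation_p,
            "methylation_direction": res.methylation_direction,
        }
        if len(stage_levels) == 2:
            idx = stage.index.tolist()
            _, row["stage_p_lnc"] = de_mod.two_group_test(
                lnc_expr.loc[idx].to_numpy(), stage.to_numpy()
            )
            _, row["stage_p_pcg"] = de_mod.two_group_test(
                pcg_expr.loc[idx].to_numpy(), stage.to_numpy()
            )
        rows.append(row)
    cols = ["lnc_id", "pcg_id", "rho", "rho_p", "tertile_p", "tertile_direction",
            "methylation_p", "methylation_direction", "stage_p_lnc", "stage_p_pcg"]
    frame = pd.DataFrame(rows)
    return frame.reindex(columns=[c for c in cols if len(frame) == 0 or c in frame.columns])
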