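"""Synthetic two-cohort datasets with known ground truth.

Emulates the statistical structure the cis-lncRNA screen assumes: two
paired tumor/normal cohorts (36 and 54 pairs by default, mirroring a
discovery and a validation LUAD cohort) over a shared gene annotation,
with

* log2-normal baseline expression shared between cohorts, so planted
  effects point the same way in both;
* planted discordant lncRNA/protein-coding neighbor pairs (lncRNA down,
  partner up in tumors) within a configurable genomic gap, plus matched
  decoy neighbor pairs carrying no effect;
* a per-tumor latent factor loading the two pair members with opposite
  signs, producing within-tumor anti-correlation of tunable strength;
* tumor stage labels under which the planted lncRNA decreases (and its
  partner increases) with stage;
* DNA-methylation beta values for planted partner genes coupled to the
  lncRNA's tumor expression on the logit scale;
* qPCR Ct plates back-constructed from chosen condition-level ddCt values
  for the five-condition siRNA knockdown design (untreated, GAPDH positive
  control, non-targeting control, and two siRNA doses), read in triplicate.

All randomness derives from one global seed; each stage hashes a label
into a child seed, so adding a stage never perturbs earlier draws, and
identical seeds give byte-identical output files.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .annotation import GeneRecord
from .paired_de import PairedExpressionSet
from .qpcr import QpcrPlate

QPCR_CONDITIONS = (
    "untreated",
    "gapdh_sirna",
    "non_targeting",
    "sirna_12.5nM",
    "sirna_25nM",
)
QPCR_REFERENCE_GENE = "RNA18S"
QPCR_CONTROL_CONDITION = "non_targeting"


def child_rng(seed: int, label: str) -> np.random.Generator:
    """Deterministic child generator from a global seed and a stage label."""
    digest = hashlib.sha256(f"{seed}:{label}".encode()).digest()
    return np.random.default_rng(int.from_bytes(digest[:8], "little"))


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic dataset.

    Defaults mirror the analyzed cohorts (36 and 54 tumor/normal pairs)
    and plant strong, screenable effects: 4-fold tumor shifts,
    anti-correlation strength 0.8 and neighbor gaps within the 1.5 kb
    proximity window.  ``noise_sd`` is the residual log2 biological
    variability per gene and sample.
    """

    seed: int = 0
    n_patients_a: int = 36
    n_patients_b: int = 54
    n_genes: int = 500
    frac_lnc: float = 0.3
    n_planted_pairs: int = 3
    n_decoy_pairs: int = 3
    n_planted_singletons: int = 20
    effect_fold: float = 4.0
    coupling: float = 0.8
    noise_sd: float = 0.5
    methyl_coupling: float = 0.8
    methyl_noise_sd: float = 0.3
    methyl_baseline_beta: float = 0.3
    gap_range: tuple[int, int] = (0, 1500)
    stage_effect: float = 0.5
    baseline_log2_mean: float = 5.0
    baseline_log2_sd: float = 1.5
    chrom_length: int = 250_000_000

    def __post_init__(self) -> None:
        for name in ("n_patients_a", "n_patients_b", "n_genes", "n_planted_pairs"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.frac_lnc < 1:
            raise ValueError("frac_lnc must lie in (0, 1)")
        if not 0 <= self.coupling <= 1:
            raise ValueError("coupling must lie in [0, 1]")
        if not 0 <= self.methyl_coupling <= 1:
            raise ValueError("methyl_coupling must lie in [0, 1]")
        if self.effect_fold < 1:
            raise ValueError("effect_fold must be >= 1")
        lo, hi = self.gap_range
        if lo < 0 or hi < lo:
            raise ValueError("gap_range must satisfy 0 <= lo <= hi")
        needed = 2 * (self.n_planted_pairs + self.n_decoy_pairs) + self.n_planted_singletons
        if needed > self.n_genes:
            raise ValueError("n_genes too small for the requested planted structure")


@dataclass
class TruthTable:
    """Ground truth of the planted structure, for oracle-based evaluation."""

    planted_pairs: list[dict]  # lnc_id, pcg_id, lnc_direction, pcg_direction, gap_bp
    decoy_pairs: list[dict]  # lnc_id, pcg_id, gap_bp
    planted_singletons: list[dict]  # gene_id, direction
    null_genes: list[str]

    def pair_frame(self) -> pd.DataFrame:
        rows = [dict(kind="planted", **p) for p in self.planted_pairs]
        rows += [
            dict(kind="decoy", lnc_direction="flat", pcg_direction="flat", **p)
            for p in self.decoy_pairs
        ]
        return pd.DataFrame(
            rows,
            columns=["kind", "lnc_id", "pcg_id", "lnc_direction", "pcg_direction", "gap_bp"],
        )

    def gene_frame(self) -> pd.DataFrame:
        rows = []
        for p in self.planted_pairs:
            rows.append({"gene_id": p["lnc_id"], "role": "pair_lnc",
                         "direction": p["lnc_direction"]})
            rows.append({"gene_id": p["pcg_id"], "role": "pair_pcg",
                         "direction": p["pcg_direction"]})
        for p in self.decoy_pairs:
            rows.append({"gene_id": p["lnc_id"], "role": "decoy_lnc", "direction": "flat"})
            rows.append({"gene_id": p["pcg_id"], "role": "decoy_pcg", "direction": "flat"})
        for s in self.planted_singletons:
            rows.append({"gene_id": s["gene_id"], "role": "singleton",
                         "direction": s["direction"]})
        for g in self.null_genes:
            rows.append({"gene_id": g, "role": "null", "direction": "flat"})
        return pd.DataFrame(rows, columns=["gene_id", "role", "direction"])

    def effect_sign(self, gene_id: str) -> int:
        """+1 up, -1 down, 0 none, for any gene."""
        for p in self.planted_pairs:
            if gene_id == p["lnc_id"]:
                return 1 if p["lnc_direction"] == "up" else -1
            if gene_id == p["pcg_id"]:
                return 1 if p["pcg_direction"] == "up" else -1
        for s in self.planted_singletons:
            if gene_id == s["gene_id"]:
                return 1 if s["direction"] == "up" else -1
        return 0


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------

def simulate_annotation(cfg: SimulationConfig) -> tuple[list[GeneRecord], TruthTable]:
    """Place genes on a synthetic chromosome.

    Planted and decoy lncRNA/protein-coding pairs receive a gap drawn
    uniformly from ``gap_range`` (a gap of 0 means the genes are
    immediately adjacent); all other genes sit more than 10 kb apart so no
    accidental neighbor pairs arise.
    """
    rng = child_rng(cfg.seed, "annotation")
    n_pairs = cfg.n_planted_pairs + cfg.n_decoy_pairs
    n_lnc = max(n_pairs, round(cfg.frac_lnc * cfg.n_genes))
    n_other = round(0.05 * cfg.n_genes)
    n_pcg = cfg.n_genes - n_lnc - n_other
    if n_pcg < n_pairs:
        raise ValueError("not enough protein-coding genes for the requested pairs")

    lnc_ids = [f"LNC{i:04d}" for i in range(n_lnc)]
    pcg_ids = [f"PCG{i:04d}" for i in range(n_pcg)]
    oth_ids = [f"OTH{i:04d}" for i in range(n_other)]

    genes: list[GeneRecord] = []
    cursor = 10_000

    def _advance() -> int:
        nonlocal cursor
        cursor += 10_001 + int(rng.integers(0, 5_000))
        return cursor

    def _place(gene_id: str, biotype: str, length: int) -> GeneRecord:
        nonlocal cursor
        start = cursor
        end = start + length - 1
        cursor = end + 1
        strand = "+" if rng.random() < 0.5 else "-"
        return GeneRecord(gene_id, gene_id, "chrS1", start, end, strand, biotype)

    def _place_pair(lnc_id: str, pcg_id: str) -> tuple[GeneRecord, GeneRecord, int]:
        nonlocal cursor
        gap = int(rng.integers(cfg.gap_range[0], cfg.gap_range[1] + 1))
        lnc_len = int(rng.integers(300, 3_000))
        pcg_len = int(rng.integers(1_000, 5_000))
        lnc_first = bool(rng.random() < 0.5)
        if lnc_first:
            lnc = _place(lnc_id, "lncRNA", lnc_len)
            cursor += gap
            pcg = _place(pcg_id, "protein_coding", pcg_len)
        else:
            pcg = _place(pcg_id, "protein_coding", pcg_len)
            cursor += gap
            lnc = _place(lnc_id, "lncRNA", lnc_len)
        return lnc, pcg, gap

    planted_pairs: list[dict] = []
    decoy_pairs: list[dict] = []
    for i in range(cfg.n_planted_pairs):
        lnc, pcg, gap = _place_pair(lnc_ids[i], pcg_ids[i])
        genes += [lnc, pcg]
        planted_pairs.append(
            {"lnc_id": lnc.gene_id, "pcg_id": pcg.gene_id,
             "lnc_direction": "down", "pcg_direction": "up", "gap_bp": gap}
        )
        _advance()
    for j in range(cfg.n_decoy_pairs):
        idx = cfg.n_planted_pairs + j
        lnc, pcg, gap = _place_pair(lnc_ids[idx], pcg_ids[idx])
        genes += [lnc, pcg]
        decoy_pairs.append({"lnc_id": lnc.gene_id, "pcg_id": pcg.gene_id, "gap_bp": gap})
        _advance()

    singles = lnc_ids[n_pairs:] + pcg_ids[n_pairs:] + oth_ids
    for gene_id in singles:
        biotype = {"L": "lncRNA", "P": "protein_coding", "O": "other"}[gene_id[0]]
        length = int(rng.integers(300, 3_000) if biotype == "lncRNA"
                     else rng.integers(1_000, 5_000))
        genes.append(_place(gene_id, biotype, length))
        _advance()

    if cursor > cfg.chrom_length:
        raise ValueError(
            f"layout infeasible: {cfg.n_genes} genes need {cursor} bp but the "
            f"chromosome is {cfg.chrom_length} bp"
        )

    # singleton deregulated genes drawn from non-pair lncRNA/protein-coding genes
    eligible = [g for g in singles if not g.startswith("OTH")]
    picked = rng.choice(len(eligible), size=cfg.n_planted_singletons, replace=False)
    planted_singletons = [
        {"gene_id": eligible[k], "direction": "up" if rng.random() < 0.5 else "down"}
        for k in sorted(picked)
    ]
    planted_ids = (
        {p["lnc_id"] for p in planted_pairs}
        | {p["pcg_id"] for p in planted_pairs}
        | {s["gene_id"] for s in planted_singletons}
    )
    null_genes = [g.gene_id for g in genes if g.gene_id not in planted_ids]
    truth = TruthTable(
        planted_pairs=planted_pairs,
        decoy_pairs=decoy_pairs,
        planted_singletons=planted_singletons,
        null_genes=null_genes,
    )
    return genes, truth


def write_gtf(genes: Sequence[GeneRecord], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for g in genes:
            attrs = (
                f'gene_id "{g.gene_id}"; gene_name "{g.gene_name}"; '
                f'gene_biotype "{g.biotype}";'
            )
            fh.write(
                f"{g.chrom}\tcislnc_sim\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )


# ---------------------------------------------------------------------------
# Expression cohorts
# ---------------------------------------------------------------------------

def _latent_loading(cfg: SimulationConfig) -> float:
    """Loading that yields within-tumor |rho| ~= coupling given noise_sd."""
    c = cfg.coupling
    if c <= 0:
        return 0.0
    if c >= 1:
        return max(cfg.noise_sd, 1.0)
    return cfg.noise_sd * math.sqrt(c / (1.0 - c))


def simulate_cohort(
    cfg: SimulationConfig,
    genes: Sequence[GeneRecord],
    truth: TruthTable,
    label: str,
) -> PairedExpressionSet:
    """One paired tumor/normal cohort over the simulated annotation.

    Baseline per-gene log2 means are drawn from a child seed that does not
    depend on the cohort label, so both cohorts share them and planted
    effects replicate across cohorts by construction.
    """
    if label not in ("a", "b"):
        raise ValueError(f"cohort label must be 'a' or 'b', got {label!r}")
    n = cfg.n_patients_a if label == "a" else cfg.n_patients_b
    gene_ids = [g.gene_id for g in genes]
    n_genes = len(gene_ids)
    gene_pos = {g: i for i, g in enumerate(gene_ids)}

    mu = child_rng(cfg.seed, "baseline").normal(
        cfg.baseline_log2_mean, cfg.baseline_log2_sd, n_genes
    )
    rng = child_rng(cfg.seed, f"cohort:{label}")

    delta = np.zeros(n_genes)
    log2_fold = math.log2(cfg.effect_fold)
    for g in gene_ids:
        sign = truth.effect_sign(g)
        if sign:
            delta[gene_pos[g]] = sign * log2_fold

    normal_log2 = mu[:, None] + rng.normal(0.0, cfg.noise_sd, (n_genes, n))
    tumor_noise = rng.normal(0.0, cfg.noise_sd, (n_genes, n))

    lam = _latent_loading(cfg)
    latent = np.zeros((n_genes, n))
    for pair in truth.planted_pairs:
        z = rng.normal(0.0, 1.0, n)
        latent[gene_pos[pair["lnc_id"]]] = -lam * z
        latent[gene_pos[pair["pcg_id"]]] = +lam * z
        if cfg.coupling >= 1:  # perfect coupling: drop residual noise on the pair
            tumor_noise[gene_pos[pair["lnc_id"]]] = 0.0
            tumor_noise[gene_pos[pair["pcg_id"]]] = 0.0

    stages = np.array(["I"] * (n - n // 2) + ["II"] * (n // 2))
    stages = stages[rng.permutation(n)]
    stage_adj = np.zeros((n_genes, n))
    stage_ii = stages == "II"
    for pair in truth.planted_pairs:
        for gid in (pair["lnc_id"], pair["pcg_id"]):
            sign = truth.effect_sign(gid)
            stage_adj[gene_pos[gid], stage_ii] = sign * cfg.stage_effect

    tumor_log2 = mu[:, None] + delta[:, None] + latent + stage_adj + tumor_noise

    prefix = label.upper()
    patients = [f"{prefix}{i + 1:03d}" for i in range(n)]
    tumor_ids = [f"{p}T" for p in patients]
    normal_ids = [f"{p}N" for p in patients]
    values = pd.DataFrame(
        np.concatenate([2.0**tumor_log2, 2.0**normal_log2], axis=1),
        index=pd.Index(gene_ids, name="gene_id"),
        columns=tumor_ids + normal_ids,
    )
    samples = pd.DataFrame(
        {
            "sample_id": tumor_ids + normal_ids,
            "patient_id": patients + patients,
            "condition": ["tumor"] * n + ["normal"] * n,
            "stage": list(stages) + list(stages),
        }
    )
    return PairedExpressionSet(values=values, samples=samples)


# ---------------------------------------------------------------------------
# Methylation
# ---------------------------------------------------------------------------

def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def simulate_methylation(
    cfg: SimulationConfig,
    truth: TruthTable,
    cohort: PairedExpressionSet,
    label: str = "b",
) -> pd.DataFrame:
    """Per-gene methylation betas over the cohort's tumor samples.

    Planted partner genes get beta = logistic(a + methyl_coupling * z + noise)
    where z is the z-scored log2 tumor expression of the paired lncRNA, so
    high-lncRNA tumors carry higher partner methylation; every other gene's
    betas are independent of expression.
    """
    rng = child_rng(cfg.seed, f"methylation:{label}")
    tumor_ids = cohort.condition_samples("tumor")
    gene_ids = list(cohort.gene_ids)
    n = len(tumor_ids)
    a = math.log(cfg.methyl_baseline_beta / (1 - cfg.methyl_baseline_beta))
    logit = a + rng.normal(0.0, cfg.methyl_noise_sd, (len(gene_ids), n))
    pos = {g: i for i, g in enumerate(gene_ids)}
    for pair in truth.planted_pairs:
        lnc_expr = np.log2(cohort.values.loc[pair["lnc_id"], tumor_ids].to_numpy(float))
        sd = lnc_expr.std()
        z = (lnc_expr - lnc_expr.mean()) / (sd if sd > 0 else 1.0)
        logit[pos[pair["pcg_id"]]] += cfg.methyl_coupling * z
    betas = _logistic(logit)
    return pd.DataFrame(betas, index=pd.Index(gene_ids, name="gene_id"), columns=tumor_ids)


# ---------------------------------------------------------------------------
# qPCR plates
# ---------------------------------------------------------------------------

def simulate_qpcr(
    true_ddct: Mapping[str, Mapping[str, float]],
    replicate_sd: float = 0.05,
    n_replicates: int = 3,
    seed: int = 0,
    reference_gene: str = QPCR_REFERENCE_GENE,
    control_condition: str = QPCR_CONTROL_CONDITION,
    conditions: Sequence[str] = QPCR_CONDITIONS,
    base_ct: float = 25.0,
    reference_ct: float = 12.0,
) -> QpcrPlate:
    """Back-construct a Ct plate whose condition-level ddCt (vs the control
    condition, normalized to the reference gene) equals ``true_ddct`` up to
    replicate noise.

    ``true_ddct`` maps gene -> condition -> cycles; unlisted conditions get
    0.  A per-condition global Ct shift (shared by target and reference, as
    loading differences would be) is added and cancels in dCt.
    """
    if replicate_sd < 0:
        raise ValueError("replicate_sd must be >= 0")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if control_condition not in conditions:
        raise ValueError(f"control condition {control_condition!r} not among conditions")
    rng = child_rng(seed, "qpcr")
    genes = sorted(true_ddct) + [reference_gene]
    rows = []
    for condition in conditions:
        shift = float(rng.normal(0.0, 0.2))
        for gene in genes:
            if gene == reference_gene:
                level = reference_ct
            else:
                level = base_ct + float(true_ddct[gene].get(condition, 0.0))
            for rep in range(1, n_replicates + 1):
                noise = float(rng.normal(0.0, replicate_sd)) if replicate_sd > 0 else 0.0
                rows.append(
                    {"gene": gene, "condition": condition, "replicate": rep,
                     "ct": level + shift + noise}
                )
    wells = pd.DataFrame(rows, columns=["gene", "condition", "replicate", "ct"])
    return QpcrPlate(wells=wells, reference_gene=reference_gene,
                     control_condition=control_condition)


def make_knockdown_plate(
    knockdown_fold: float = 3.42,
    readout_fold: float = 1.57,
    knocked_gene: str = "LNC_target",
    readout_gene: str = "PCG_readout",
    replicate_sd: float = 0.05,
    n_replicates: int = 3,
    seed: int = 0,
) -> QpcrPlate:
    """Five-condition siRNA knockdown plate with chosen condition-level truths.

    At the high siRNA dose the knocked gene is reduced ``knockdown_fold``-fold
    and the readout gene increased ``readout_fold``-fold relative to the
    non-targeting control; the low dose carries a weaker version of both
    effects, and the GAPDH positive-control siRNA suppresses GAPDH.
    """
    true_ddct = {
        knocked_gene: {
            "sirna_12.5nM": math.log2(max(1.0, knockdown_fold * 0.6)),
            "sirna_25nM": math.log2(knockdown_fold),
        },
        readout_gene: {
            "sirna_12.5nM": -math.log2(max(1.0, readout_fold * 0.75)),
            "sirna_25nM": -math.log2(readout_fold),
        },
        "GAPDH": {"gapdh_sirna": math.log2(5.0)},
    }
    return simulate_qpcr(
        true_ddct, replicate_sd=replicate_sd, n_replicates=n_replicates, seed=seed
    )


# ---------------------------------------------------------------------------
# Whole-dataset convenience
# ---------------------------------------------------------------------------

@dataclass
class SyntheticDataset:
    cfg: SimulationConfig
    genes: list[GeneRecord]
    truth: TruthTable
    cohort_a: PairedExpressionSet
    cohort_b: PairedExpressionSet
    methylation_b: pd.DataFrame
    qpcr_plate: QpcrPlate


def simulate_dataset(cfg: SimulationConfig) -> SyntheticDataset:
    """Generate every artifact the pipeline consumes, in memory."""
    genes, truth = simulate_annotation(cfg)
    cohort_a = simulate_cohort(cfg, genes, truth, "a")
    cohort_b = simulate_cohort(cfg, genes, truth, "b")
    methylation_b = simulate_methylation(cfg, truth, cohort_b, label="b")
    plate = make_knockdown_plate(seed=cfg.seed)
    return SyntheticDataset(cfg, genes, truth, cohort_a, cohort_b, methylation_b, plate)


def write_dataset(cfg: SimulationConfig, outdir: str | Path) -> dict[str, Path]:
    """Write the full synthetic dataset plus a run-ready config file."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ds = simulate_dataset(cfg)
    paths = {
        "annotation": outdir / "annotation.gtf",
        "expression_a": outdir / "expression_a.tsv",
        "metadata_a": outdir / "metadata_a.tsv",
        "expression_b": outdir / "expression_b.tsv",
        "metadata_b": outdir / "metadata_b.tsv",
        "methylation": outdir / "methylation_b.tsv",
        "qpcr_plate": outdir / "qpcr_plate.csv",
        "truth_pairs": outdir / "truth_pairs.tsv",
        "truth_genes": outdir / "truth_genes.tsv",
        "config": outdir / "config.yaml",
    }
    write_gtf(ds.genes, paths["annotation"])
    for label, cohort in (("a", ds.cohort_a), ("b", ds.cohort_b)):
        cohort.values.to_csv(paths[f"expression_{label}"], sep="\t", float_format="%.6g")
        cohort.samples.to_csv(paths[f"metadata_{label}"], sep="\t", index=False)
    ds.methylation_b.to_csv(paths["methylation"], sep="\t", float_format="%.6g")
    ds.qpcr_plate.wells.to_csv(paths["qpcr_plate"], index=False, float_format="%.6g")
    ds.truth.pair_frame().to_csv(paths["truth_pairs"], sep="\t", index=False)
    ds.truth.gene_frame().to_csv(paths["truth_genes"], sep="\t", index=False)

    run_config = {
        "annotation": "annotation.gtf",
        "expression_a": "expression_a.tsv",
        "metadata_a": "metadata_a.tsv",
        "expression_b": "expression_b.tsv",
        "metadata_b": "metadata_b.tsv",
        "methylation": "methylation_b.tsv",
        "qpcr_plate": "qpcr_plate.csv",
        "qpcr_reference_gene": QPCR_REFERENCE_GENE,
        "qpcr_control_condition": QPCR_CONTROL_CONDITION,
        "qpcr_knocked_gene": "LNC_target",
        "qpcr_readout_gene": "PCG_readout",
        "alpha": 0.05,
        "fc_threshold": 1.5,
        "max_gap": 1500,
        "pseudocount": 0.01,
        "test": "wilcoxon",
        "simulation": {k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in asdict(cfg).items()},
    }
    with paths["config"].open("w") as fh:
        yaml.safe_dump(run_config, fh, sort_keys=True)
    return paths
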