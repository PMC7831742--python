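"""Paired tumor/normal differential expression calling.

Genes are tested per cohort with a two-sided Wilcoxon signed-rank test on
matched tumor/normal pairs, fold change is the ratio of condition means on
the linear (RPKM) scale with a small pseudocount, and p-values are
Benjamini-Hochberg adjusted across all genes in the cohort.  A gene is
called deregulated when q < alpha and the linear fold change passes the
threshold in either direction (FC >= 1.5 or <= 1/1.5 by default).

The signed-rank test uses an exact null distribution (full enumeration of
sign assignments, computed by a dynamic program that tolerates tied
absolute differences) for small samples and the tie- and
continuity-corrected normal approximation otherwise.  A two-group
Mann-Whitney U test with the same exact/approximate split backs the
tertile and stage contrasts elsewhere in the pipeline.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats as sps
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

EXACT_WILCOXON_MAX_N = 25
EXACT_MANNWHITNEY_MAX_N = 12

TestMode = Literal["exact", "approx", "auto"]


# ---------------------------------------------------------------------------
# Cohort container
# ---------------------------------------------------------------------------

@dataclass
class PairedExpressionSet:
    """Expression matrix plus sample metadata enforcing tumor/normal pairing.

    ``values``: genes x samples, non-negative RPKM-like units.
    ``samples``: one row per sample with columns
    ``sample_id, patient_id, condition, stage`` (stage may be missing).
    """

    values: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.samples = self.samples.reset_index(drop=True)
        required = {"sample_id", "patient_id", "condition"}
        missing = required - set(self.samples.columns)
        if missing:
            raise ValueError(f"sample metadata missing columns: {sorted(missing)}")
        if "stage" not in self.samples.columns:
            self.samples["stage"] = pd.NA
        bad_cond = set(self.samples["condition"]) - {"tumor", "normal"}
        if bad_cond:
            raise ValueError(f"unknown condition labels: {sorted(bad_cond)}")
        unknown = set(self.samples["sample_id"]) - set(self.values.columns)
        if unknown:
            raise ValueError(f"samples absent from expression matrix: {sorted(unknown)}")
        if self.values.index.hasnans or not self.values.index.is_unique:
            raise ValueError("gene_ids must be unique and non-missing")
        vals = self.values[self.samples["sample_id"]]
        if vals.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        if (vals.to_numpy() < 0).any():
            raise ValueError("expression values must be non-negative")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    def validate_pairing(self) -> None:
        """Every patient must contribute exactly one tumor and one normal."""
        counts = (
            self.samples.groupby(["patient_id", "condition"], sort=True)
            .size()
            .unstack(fill_value=0)
            .reindex(columns=["tumor", "normal"], fill_value=0)
        )
        bad = counts[(counts["tumor"] != 1) | (counts["normal"] != 1)]
        if len(bad):
            raise ValueError(
                "unpaired or duplicated samples for patient_ids: "
                + ", ".join(map(str, bad.index.tolist()))
            )

    def paired_matrices(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        """(tumor, normal) matrices with columns aligned patient-by-patient."""
        self.validate_pairing()
        meta = self.samples.sort_values(["patient_id", "condition"])
        tumor_ids = meta.loc[meta["condition"] == "tumor"].set_index("patient_id")["sample_id"]
        normal_ids = meta.loc[meta["condition"] == "normal"].set_index("patient_id")["sample_id"]
        patients = sorted(tumor_ids.index)
        return (
            self.values[tumor_ids.loc[patients].tolist()],
            self.values[normal_ids.loc[patients].tolist()],
        )

    def condition_samples(self, condition: str) -> list[str]:
        return self.samples.loc[self.samples["condition"] == condition, "sample_id"].tolist()

    def sample_stage(self) -> pd.Series:
        return self.samples.set_index("sample_id")["stage"]


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    """Expression TSV: first column gene_id, remaining columns sample ids."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "gene_id"
    return df


def read_metadata_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"sample_id": str, "patient_id": str})


def read_cohort(expression_path: str | Path, metadata_path: str | Path) -> PairedExpressionSet:
    return PairedExpressionSet(
        values=read_expression_tsv(expression_path),
        samples=read_metadata_tsv(metadata_path),
    )


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank
# ---------------------------------------------------------------------------

def _signed_rank_statistic(diffs: np.ndarray) -> tuple[float, np.ndarray]:
    """W+ (rank sum of positive differences) and the average ranks of |d|."""
    ranks = sps.rankdata(np.abs(diffs))
    w_plus = float(ranks[diffs > 0].sum())
    return w_plus, ranks

def _exact_signed_rank_p(w_plus: float, ranks: np.ndarray) -> float:
    """Two-sided exact p over all 2^n sign assignments, tied ranks allowed.

    Average ranks are halves of integers, so doubling makes every achievable
    W+ an integer; the number of sign assignments reaching each doubled sum
    is accumulated by a subset-sum dynamic program, which enumerates the
    same distribution as brute force at polynomial cost.
    """
    doubled = np.rint(2 * ranks).astype(np.int64)
    total = int(doubled.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in doubled:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    n_assign = counts.sum()  # == 2^n
    w2 = int(np.rint(2 * w_plus))
    p_ge = counts[w2:].sum() / n_assign
    p_le = counts[: w2 + 1].sum() / n_assign
    return min(1.0, 2.0 * min(p_le, p_ge))


def wilcoxon_signed_rank(
    x: Sequence[float],
    y: Sequence[float],
    mode: TestMode = "auto",
) -> tuple[float, float]:
    """Two-sided paired Wilcoxon signed-rank test; returns (W+, p).

    Zero differences are dropped before ranking; ties in |d| receive average
    ranks.  The exact null (all sign assignments) is used when
    mode="exact", or in auto mode when at most 25 nonzero differences
    remain; otherwise the normal approximation with continuity and tie
    correction.  All-zero differences give p = 1 with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 1:
        raise ValueError("need at least one pair")
    diffs = x - y
    diffs = diffs[diffs != 0]
    if diffs.size == 0:
        logger.warning("all paired differences are zero; p-value set to 1")
        return 0.0, 1.0
    w_plus, ranks = _signed_rank_statistic(diffs)
    n = diffs.size
    exact = mode == "exact" or (mode == "auto" and n <= EXACT_WILCOXON_MAX_N)
    if exact:
        return w_plus, _exact_signed_rank_p(w_plus, ranks)
    res = sps.wilcoxon(
        diffs, zero_method="wilcox", correction=True, alternative="two-sided",
        method="approx",
    )
    return w_plus, float(res.pvalue)


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------

def mann_whitney(
    a: Sequence[float],
    b: Sequence[float],
    mode: TestMode = "auto",
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U; returns (U of group a, p).

    Exact p enumerates all C(n, n_a) assignments of the pooled average
    ranks when n_a + n_b <= 12 (or mode="exact"); larger samples use the
    tie-corrected normal approximation with continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    n_a = a.size
    u_a = float(ranks[:n_a].sum() - n_a * (n_a + 1) / 2)
    n = pooled.size
    exact = mode == "exact" or (mode == "auto" and n <= EXACT_MANNWHITNEY_MAX_N)
    if exact:
        us = np.array(
            [
                ranks[list(idx)].sum() - n_a * (n_a + 1) / 2
                for idx in combinations(range(n), n_a)
            ]
        )
        eps = 1e-9
        p_ge = np.mean(us >= u_a - eps)
        p_le = np.mean(us <= u_a + eps)
        return u_a, min(1.0, 2.0 * min(p_le, p_ge))
    res = sps.mannwhitneyu(a, b, use_continuity=True, alternative="two-sided",
                           method="asymptotic")
    return u_a, float(res.pvalue)


def two_group_test(
    values: Sequence[float],
    labels: Sequence,
    mode: TestMode = "auto",
) -> tuple[float, float]:
    """Mann-Whitney U between the two levels of ``labels``.

    Returns (U of the first level in sorted label order, two-sided p).
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    levels = np.unique(labels)
    if levels.size != 2:
        raise ValueError(f"labels must have exactly two levels, got {levels.tolist()}")
    a = values[labels == levels[0]]
    b = values[labels == levels[1]]
    return mann_whitney(a, b, mode=mode)


# ---------------------------------------------------------------------------
# Fold change, BH, cohort-level calling
# ---------------------------------------------------------------------------

def fold_change(
    x: Sequence[float],
    y: Sequence[float],
    pseudocount: float = 0.01,
) -> tuple[float, float]:
    """Linear fold change (mean(x)+pc)/(mean(y)+pc) and its log2."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    fc = (float(np.mean(x)) + pseudocount) / (float(np.mean(y)) + pseudocount)
    return fc, math.log2(fc)


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_deregulated(
    cohort: PairedExpressionSet,
    alpha: float = 0.05,
    fc_threshold: float = 1.5,
    pseudocount: float = 0.01,
    test: Literal["wilcoxon", "ttest"] = "wilcoxon",
    mode: TestMode = "auto",
    bh_groups: Optional[pd.Series] = None,
) -> pd.DataFrame:
    """Per-gene deregulation calls for one paired cohort.

    Returns a frame indexed by gene_id with columns
    ``fc, log2fc, direction, p, q, deregulated``.  BH adjustment is applied
    once across all genes (or within the strata of ``bh_groups``, e.g.
    biotype, when given).  ``deregulated`` requires q < alpha and
    |log2 FC| >= log2(fc_threshold).
    """
    if not (0 < alpha < 1):
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if fc_threshold < 1:
        raise ValueError(f"fc_threshold must be >= 1, got {fc_threshold}")
    tumor, normal = cohort.paired_matrices()
    t_arr, n_arr = tumor.to_numpy(), normal.to_numpy()
    genes = cohort.gene_ids

    pvals = np.empty(len(genes))
    fcs = np.empty(len(genes))
    for i in range(len(genes)):
        x, y = t_arr[i], n_arr[i]
        if test == "wilcoxon":
            _, pvals[i] = wilcoxon_signed_rank(x, y, mode=mode)
        elif test == "ttest":
            res = sps.ttest_rel(x, y)
            pvals[i] = 1.0 if np.isnan(res.pvalue) else float(res.pvalue)
        else:
            raise ValueError(f"unknown test {test!r}")
        fcs[i], _ = fold_change(x, y, pseudocount=pseudocount)

    if bh_groups is None:
        qvals = bh_adjust(pvals)
    else:
        qvals = np.empty_like(pvals)
        groups = bh_groups.reindex(genes)
        for level in groups.dropna().unique():
            sel = (groups == level).to_numpy()
            qvals[sel] = bh_adjust(pvals[sel])
        na = groups.isna().to_numpy()
        if na.any():
            qvals[na] = bh_adjust(pvals[na])

    log2fc = np.log2(fcs)
    direction = np.where(fcs > 1, "up", np.where(fcs < 1, "down", "flat"))
    dereg = (qvals < alpha) & (np.abs(log2fc) >= math.log2(fc_threshold))
    return pd.DataFrame(
        {
            "fc": fcs,
            "log2fc": log2fc,
            "direction": direction,
            "p": pvals,
            "q": qvals,
            "deregulated": dereg,
        },
        index=genes,
    )


def write_de_tsv(de: pd.DataFrame, path: str | Path) -> None:
    de.to_csv(path, sep="\t", index_label="gene_id", float_format="%.6g")
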