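"""Within-tumor characterization of candidate cis-pairs.

For a candidate lncRNA/protein-coding pair the evidence beyond differential
expression is (i) Spearman correlation of the two genes across tumors,
(ii) a Mann-Whitney contrast of the partner gene between the top and bottom
expression tertiles of the lncRNA, and (iii), when DNA methylation
beta-values are available, the same tertile contrast on the partner gene's
methylation (and the reverse: expression contrasted between methylation
tertiles).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import permutations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats as sps

from .paired_de import mann_whitney

logger = logging.getLogger(__name__)

EXACT_SPEARMAN_MAX_N = 9


@dataclass(frozen=True)
class SpearmanResult:
    rho: float
    p: float
    exact: bool


@dataclass(frozen=True)
class TertileSplit:
    """Bottom and top floor(n/3) samples ranked by one gene's expression."""

    low: tuple[str, ...]
    high: tuple[str, ...]
    ranking_gene: str


@dataclass(frozen=True)
class ContrastResult:
    p: float
    direction: str  # higher_in_low | higher_in_high | none
    median_low: float
    median_high: float


@dataclass(frozen=True)
class AssociationResult:
    lnc_id: str
    pcg_id: str
    rho: float
    rho_p: float
    tertile_p: float
    tertile_direction: str
    methylation_p: Optional[float] = None
    methylation_direction: Optional[str] = None


def spearman(x: Sequence[float], y: Sequence[float]) -> SpearmanResult:
    """Spearman rank correlation with a two-sided p-value.

    rho is the Pearson correlation of average ranks.  For n <= 9 the
    p-value is exact, from the permutation distribution of rho over all n!
    rank orderings of one vector; larger samples use the t-distribution
    approximation.  Zero rank variance in either input leaves rho
    undefined (NaN, with a warning).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("spearman needs two equal-length vectors with n >= 3")
    rx, ry = sps.rankdata(x), sps.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        logger.warning("constant input: Spearman correlation undefined")
        return SpearmanResult(rho=float("nan"), p=float("nan"), exact=False)
    n = x.size
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= EXACT_SPEARMAN_MAX_N:
        perms = np.array(list(permutations(ry)))
        rxc = rx - rx.mean()
        pc = perms - perms.mean(axis=1, keepdims=True)
        rhos = (pc @ rxc) / np.sqrt((pc**2).sum(axis=1) * (rxc**2).sum())
        p = float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
        return SpearmanResult(rho=rho, p=p, exact=True)
    res = sps.spearmanr(x, y)
    return SpearmanResult(rho=rho, p=float(res.pvalue), exact=False)


def tertile_split(values: pd.Series, ranking_gene: str = "") -> TertileSplit:
    """Split samples into bottom/top floor(n/3) thirds by ``values``.

    ``values`` is indexed by sample_id.  Ties are broken by sample_id so
    the split is deterministic; a tie spanning a tertile boundary is
    flagged with a warning because group membership then hinges on that
    arbitrary order.
    """
    n = len(values)
    if n < 3:
        raise ValueError(f"tertile split needs at least 3 samples, got {n}")
    k = n // 3
    order = values.reset_index()
    order.columns = ["sample_id", "value"]
    order = order.sort_values(["value", "sample_id"], kind="mergesort")
    vals = order["value"].to_numpy()
    if vals[k - 1] == vals[k] or vals[n - k] == vals[n - k - 1]:
        logger.warning(
            "tied values span a tertile boundary; membership decided by sample_id order"
        )
    sample_ids = order["sample_id"].tolist()
    return TertileSplit(
        low=tuple(sample_ids[:k]),
        high=tuple(sample_ids[n - k:]),
        ranking_gene=ranking_gene or str(values.name or ""),
    )


def tertile_contrast(split: TertileSplit, partner: pd.Series) -> ContrastResult:
    """Mann-Whitney contrast of ``partner`` between the split's tertiles.

    Direction compares group medians of the partner variable.
    """
    wanted = list(split.low) + list(split.high)
    missing = [s for s in wanted if s not in partner.index or pd.isna(partner.get(s))]
    if missing:
        raise ValueError(f"partner values missing for samples: {missing}")
    low_vals = partner.loc[list(split.low)].to_numpy(dtype=float)
    high_vals = partner.loc[list(split.high)].to_numpy(dtype=float)
    _, p = mann_whitney(low_vals, high_vals)
    med_low = float(np.median(low_vals))
    med_high = float(np.median(high_vals))
    if med_low > med_high:
        direction = "higher_in_low"
    elif med_high > med_low:
        direction = "higher_in_high"
    else:
        direction = "none"
    return ContrastResult(p=p, direction=direction, median_low=med_low, median_high=med_high)


def methylation_contrast(split: TertileSplit, betas: pd.Series) -> ContrastResult:
    """Contrast methylation beta-values between lncRNA-expression tertiles."""
    _check_betas(betas)
    return tertile_contrast(split, betas)


def expression_by_methylation(
    betas: pd.Series,
    expression: pd.Series,
    ranking_gene: str = "",
) -> ContrastResult:
    """Reverse contrast: split samples by methylation tertiles and compare
    the gene's expression between them."""
    _check_betas(betas)
    split = tertile_split(betas, ranking_gene=ranking_gene)
    return tertile_contrast(split, expression)


def _check_betas(betas: pd.Series) -> None:
    vals = betas.dropna().to_numpy(dtype=float)
    if np.any((vals < 0) | (vals > 1)):
        raise ValueError("methylation beta values must lie in [0, 1]")


def associate_pair(
    lnc_expr: pd.Series,
    pcg_expr: pd.Series,
    lnc_id: str,
    pcg_id: str,
    pcg_betas: Optional[pd.Series] = None,
) -> AssociationResult:
    """Full within-tumor characterization of one candidate pair.

    All series are indexed by tumor sample_id.  Correlation and tertile
    contrasts are computed over the samples shared by both expression
    vectors; methylation contrasts additionally require betas for the
    tertile samples.
    """
    common = lnc_expr.index.intersection(pcg_expr.index)
    lnc_expr = lnc_expr.loc[common]
    pcg_expr = pcg_expr.loc[common]
    corr = spearman(lnc_expr.to_numpy(), pcg_expr.to_numpy())
    split = tertile_split(lnc_expr, ranking_gene=lnc_id)
    tert = tertile_contrast(split, pcg_expr)
    meth_p = meth_dir = None
    if pcg_betas is not None:
        meth = methylation_contrast(split, pcg_betas)
        meth_p, meth_dir = meth.p, meth.direction
    return AssociationResult(
        lnc_id=lnc_id,
        pcg_id=pcg_id,
        rho=corr.rho,
        rho_p=corr.p,
        tertile_p=tert.p,
        tertile_direction=tert.direction,
        methylation_p=meth_p,
        methylation_direction=meth_dir,
    )


def associations_to_frame(results: Sequence[AssociationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "lnc_id": r.lnc_id,
                "pcg_id": r.pcg_id,
                "rho": r.rho,
                "rho_p": r.rho_p,
                "tertile_p": r.tertile_p,
                "tertile_direction": r.tertile_direction,
                "methylation_p": r.methylation_p,
                "methylation_direction": r.methylation_direction,
            }
            for r in results
        ],
        columns=[
            "lnc_id", "pcg_id", "rho", "rho_p", "tertile_p",
            "tertile_direction", "methylation_p", "methylation_direction",
        ],
    )
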