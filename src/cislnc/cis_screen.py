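"""Cross-cohort intersection of deregulation calls with neighbor pairs.

A candidate cis-pair is a lncRNA/protein-coding neighbor pair (within the
proximity window) where both genes are significantly deregulated in both
cohorts, each gene in a consistent direction across cohorts.  Pairs are
classified by concordance: ``discordant`` (lnc and partner move in opposite
directions — the pattern least explicable by locus-level passenger events
such as copy-number change and therefore the screen's focus),
``concordant`` (same direction), or ``mixed`` (relationship differs
between cohorts; only reachable when direction consistency is relaxed,
retained for completeness).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .annotation import NeighborPair


@dataclass(frozen=True)
class CisPair:
    """A candidate lncRNA/protein-coding cis-pair with per-cohort evidence."""

    lnc_id: str
    pcg_id: str
    chrom: str
    gap_bp: int
    relation: str
    same_strand: bool
    lnc_direction_by_cohort: Mapping[str, str]
    pcg_direction_by_cohort: Mapping[str, str]
    lnc_q_by_cohort: Mapping[str, float]
    pcg_q_by_cohort: Mapping[str, float]
    lnc_log2fc_by_cohort: Mapping[str, float]
    pcg_log2fc_by_cohort: Mapping[str, float]
    concordance: str  # concordant | discordant | mixed
    candidate: bool


def cross_cohort_deregulated(de_a: pd.DataFrame, de_b: pd.DataFrame) -> set[str]:
    """Genes deregulated in BOTH cohorts with the same direction.

    ``de_a``/``de_b`` are ``call_deregulated`` outputs indexed by gene_id.
    Genes absent from either cohort are excluded.
    """
    common = de_a.index.intersection(de_b.index)
    if len(common) == 0:
        raise ValueError("the two cohorts share no genes")
    a, b = de_a.loc[common], de_b.loc[common]
    keep = a["deregulated"] & b["deregulated"] & (a["direction"] == b["direction"])
    return set(common[keep])


def _concordance(lnc_dirs: Mapping[str, str], pcg_dirs: Mapping[str, str]) -> str:
    rels = {cohort: lnc_dirs[cohort] == pcg_dirs[cohort] for cohort in lnc_dirs}
    if all(rels.values()):
        return "concordant"
    flipped = {"up": "down", "down": "up"}
    if all(pcg_dirs[c] == flipped.get(lnc_dirs[c], "flat") for c in lnc_dirs):
        return "discordant"
    return "mixed"


def screen(
    de_a: pd.DataFrame,
    de_b: pd.DataFrame,
    pairs: Sequence[NeighborPair],
) -> list[CisPair]:
    """Candidate cis-pairs: neighbor pairs whose two genes both pass the
    cross-cohort deregulation filter.  Output order follows the (already
    deterministic) neighbor-pair table."""
    consistent = cross_cohort_deregulated(de_a, de_b)
    out: list[CisPair] = []
    for p in pairs:
        if p.lnc_id not in consistent or p.pcg_id not in consistent:
            continue
        lnc_dirs = {"a": de_a.loc[p.lnc_id, "direction"], "b": de_b.loc[p.lnc_id, "direction"]}
        pcg_dirs = {"a": de_a.loc[p.pcg_id, "direction"], "b": de_b.loc[p.pcg_id, "direction"]}
        out.append(
            CisPair(
                lnc_id=p.lnc_id,
                pcg_id=p.pcg_id,
                chrom=p.chrom,
                gap_bp=p.gap_bp,
                relation=p.relation,
                same_strand=p.same_strand,
                lnc_direction_by_cohort=lnc_dirs,
                pcg_direction_by_cohort=pcg_dirs,
                lnc_q_by_cohort={"a": float(de_a.loc[p.lnc_id, "q"]),
                                 "b": float(de_b.loc[p.lnc_id, "q"])},
                pcg_q_by_cohort={"a": float(de_a.loc[p.pcg_id, "q"]),
                                 "b": float(de_b.loc[p.pcg_id, "q"])},
                lnc_log2fc_by_cohort={"a": float(de_a.loc[p.lnc_id, "log2fc"]),
                                      "b": float(de_b.loc[p.lnc_id, "log2fc"])},
                pcg_log2fc_by_cohort={"a": float(de_a.loc[p.pcg_id, "log2fc"]),
                                      "b": float(de_b.loc[p.pcg_id, "log2fc"])},
                concordance=_concordance(lnc_dirs, pcg_dirs),
                candidate=True,
            )
        )
    return out


def rank_candidates(
    pairs: Sequence[CisPair],
    prefer: str = "discordant",
) -> list[CisPair]:
    """Preferred concordance class first, then by the lncRNA's best
    (minimum) cohort q-value; stable for ties."""
    return sorted(
        pairs,
        key=lambda p: (p.concordance != prefer, min(p.lnc_q_by_cohort.values())),
    )


def candidates_to_frame(pairs: Sequence[CisPair]) -> pd.DataFrame:
    """Ranked candidate table matching the TSV interface."""
    rows = []
    for rank, p in enumerate(pairs, start=1):
        rows.append(
            {
                "lnc_id": p.lnc_id,
                "pcg_id": p.pcg_id,
                "chrom": p.chrom,
                "gap_bp": p.gap_bp,
                "relation": p.relation,
                "same_strand": p.same_strand,
                "lnc_log2fc_a": p.lnc_log2fc_by_cohort["a"],
                "lnc_log2fc_b": p.lnc_log2fc_by_cohort["b"],
                "lnc_q_a": p.lnc_q_by_cohort["a"],
                "lnc_q_b": p.lnc_q_by_cohort["b"],
                "pcg_log2fc_a": p.pcg_log2fc_by_cohort["a"],
                "pcg_log2fc_b": p.pcg_log2fc_by_cohort["b"],
                "pcg_q_a": p.pcg_q_by_cohort["a"],
                "pcg_q_b": p.pcg_q_by_cohort["b"],
                "concordance": p.concordance,
                "rank": rank,
            }
        )
    cols = [
        "lnc_id", "pcg_id", "chrom", "gap_bp", "relation", "same_strand",
        "lnc_log2fc_a", "lnc_log2fc_b", "lnc_q_a", "lnc_q_b",
        "pcg_log2fc_a", "pcg_log2fc_b", "pcg_q_a", "pcg_q_b",
        "concordance", "rank",
    ]
    return pd.DataFrame(rows, columns=cols)


def write_candidates_tsv(pairs: Sequence[CisPair], path: str | Path) -> None:
    candidates_to_frame(pairs).to_csv(path, sep="\t", index=False, float_format="%.6g")
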