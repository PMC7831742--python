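"""Gene-level annotation handling and biotype-aware neighbor pairing.

A cis-acting lncRNA screen needs to know, for every lncRNA, which
protein-coding genes lie within a small genomic window (1.5 kb by default)
of its gene body.  This module reads gene records from a GTF, computes
interval gaps on 1-based inclusive coordinates, and enumerates all
lncRNA/protein-coding neighbor pairs within a maximum gap.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
import pyranges as pr

logger = logging.getLogger(__name__)

#: GTF biotype strings collapsed onto the lncRNA class.  Annotation releases
#: differ in nomenclature; ``processed_transcript`` is excluded by default
#: because it also covers non-lnc fragments (override via ``lnc_biotypes``).
DEFAULT_LNC_BIOTYPES = frozenset(
    {"lncRNA", "lincRNA", "antisense", "sense_intronic", "sense_overlapping"}
)

#: non-lnc, non-coding biotypes that are expected and silently mapped to
#: ``other`` (anything outside this set still maps to ``other`` but warns).
KNOWN_OTHER_BIOTYPES = frozenset(
    {"other", "misc_RNA", "miRNA", "snRNA", "snoRNA", "rRNA", "pseudogene",
     "processed_pseudogene", "unprocessed_pseudogene", "TEC"}
)

_ATTR_RE = re.compile(r'(\S+)\s+"([^"]*)"')


@dataclass(frozen=True)
class GeneRecord:
    """One annotated gene: location (1-based inclusive), strand and biotype."""

    gene_id: str
    gene_name: str
    chrom: str
    start: int
    end: int
    strand: str
    biotype: str

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"{self.gene_id}: start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(f"{self.gene_id}: end {self.end} < start {self.start}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-', got {self.strand!r}")


@dataclass(frozen=True)
class NeighborPair:
    """A lncRNA/protein-coding pair with the gap between their gene bodies.

    ``gap_bp`` counts bases strictly between the two intervals: 0 means the
    intervals intersect or are immediately adjacent (no bases between), and
    that case is classified as ``overlap``.  ``relation`` is defined on the
    + genomic axis regardless of strand.
    """

    lnc_id: str
    pcg_id: str
    chrom: str
    gap_bp: int
    relation: str  # overlap | lnc_upstream | lnc_downstream
    same_strand: bool


def map_biotype(raw: str, lnc_biotypes: frozenset[str] = DEFAULT_LNC_BIOTYPES) -> str:
    """Collapse a raw GTF biotype onto {lncRNA, protein_coding, other}."""
    if raw in lnc_biotypes:
        return "lncRNA"
    if raw == "protein_coding":
        return "protein_coding"
    return "other"


def _parse_attributes(field: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(field))


def read_gtf(
    path: str | Path,
    lnc_biotypes: Iterable[str] = DEFAULT_LNC_BIOTYPES,
) -> list[GeneRecord]:
    """Read gene features from an Ensembl-style GTF into GeneRecords.

    Only ``gene`` features are kept.  Biotype comes from the
    ``gene_biotype`` or ``gene_type`` attribute and is mapped onto
    {lncRNA, protein_coding, other}; unknown strings map to ``other``
    with a logged warning.  Malformed lines raise with their line number.
    """
    lnc_set = frozenset(lnc_biotypes)
    records: list[GeneRecord] = []
    seen: set[str] = set()
    warned: set[str] = set()
    path = Path(path)
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(
                    f"{path}: malformed GTF line {lineno}: expected 9 tab-separated "
                    f"fields, got {len(fields)}"
                )
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, attrs_s = fields
            if feature != "gene":
                continue
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ValueError(f"{path}: malformed coordinates on line {lineno}") from exc
            attrs = _parse_attributes(attrs_s)
            if "gene_id" not in attrs:
                raise ValueError(f"{path}: missing gene_id attribute on line {lineno}")
            gene_id = attrs["gene_id"]
            if gene_id in seen:
                raise ValueError(f"{path}: duplicate gene_id {gene_id!r} on line {lineno}")
            seen.add(gene_id)
            raw_biotype = attrs.get("gene_biotype", attrs.get("gene_type", ""))
            biotype = map_biotype(raw_biotype, lnc_set)
            if (
                biotype == "other"
                and raw_biotype not in KNOWN_OTHER_BIOTYPES
                and raw_biotype not in warned
            ):
                warned.add(raw_biotype)
                logger.warning(
                    "biotype %r not in the mapping table; treating as 'other'", raw_biotype
                )
            records.append(
                GeneRecord(
                    gene_id=gene_id,
                    gene_name=attrs.get("gene_name", gene_id),
                    chrom=chrom,
                    start=start,
                    end=end,
                    strand=strand,
                    biotype=biotype,
                )
            )
    return records


def gene_gap(a: GeneRecord, b: GeneRecord) -> Optional[int]:
    """Bases strictly between two gene bodies; 0 if they intersect.

    Returns None when the genes sit on different chromosomes (the gap is
    undefined).  Symmetric in its arguments.
    """
    if a.chrom != b.chrom:
        return None
    if a.start <= b.end and b.start <= a.end:
        return 0
    if a.end < b.start:
        return b.start - a.end - 1
    return a.start - b.end - 1


def _relation(lnc: GeneRecord, pcg: GeneRecord, gap: int) -> str:
    if gap == 0:
        return "overlap"
    return "lnc_upstream" if lnc.end < pcg.start else "lnc_downstream"


def neighbor_pairs(
    genes: Sequence[GeneRecord],
    max_gap: int = 1500,
) -> list[NeighborPair]:
    """All (lncRNA, protein-coding) pairs with gene-body gap <= ``max_gap``.

    Strand is recorded but never used as a filter: the screen's criterion is
    purely distance.  Output is sorted by (chrom, lnc start, pcg start) so
    it does not depend on input gene order.
    """
    if max_gap < 0:
        raise ValueError(f"max_gap must be >= 0, got {max_gap}")
    by_id = {g.gene_id: g for g in genes}
    lncs = [g for g in genes if g.biotype == "lncRNA"]
    pcgs = [g for g in genes if g.biotype == "protein_coding"]
    if not lncs or not pcgs:
        return []

    def _ranges(gs: Sequence[GeneRecord]) -> pr.PyRanges:
        return pr.PyRanges(
            pd.DataFrame(
                {
                    "Chromosome": [g.chrom for g in gs],
                    "Start": [g.start - 1 for g in gs],  # to 0-based half-open
                    "End": [g.end for g in gs],
                    "gene_id": [g.gene_id for g in gs],
                }
            )
        )

    # slack = max_gap + 1 turns "extended intervals intersect" into
    # "gap <= max_gap" for half-open coordinates; the exact gap filter below
    # makes the boundary case explicit.
    joined = _ranges(lncs).join(_ranges(pcgs), slack=max_gap + 1, suffix="_pcg")
    pairs: list[NeighborPair] = []
    if len(joined) > 0:
        for lnc_id, pcg_id in zip(joined.df["gene_id"], joined.df["gene_id_pcg"]):
            lnc, pcg = by_id[lnc_id], by_id[pcg_id]
            gap = gene_gap(lnc, pcg)
            if gap is None or gap > max_gap:
                continue
            pairs.append(
                NeighborPair(
                    lnc_id=lnc_id,
                    pcg_id=pcg_id,
                    chrom=lnc.chrom,
                    gap_bp=gap,
                    relation=_relation(lnc, pcg, gap),
                    same_strand=lnc.strand == pcg.strand,
                )
            )
    pairs.sort(
        key=lambda p: (p.chrom, by_id[p.lnc_id].start, p.lnc_id,
                       by_id[p.pcg_id].start, p.pcg_id)
    )
    return pairs


def pairs_to_frame(pairs: Sequence[NeighborPair]) -> pd.DataFrame:
    """Neighbor-pair table with columns matching the TSV interface."""
    return pd.DataFrame(
        [
            {
                "lnc_id": p.lnc_id,
                "pcg_id": p.pcg_id,
                "chrom": p.chrom,
                "gap_bp": p.gap_bp,
                "relation": p.relation,
                "same_strand": p.same_strand,
            }
            for p in pairs
        ],
        columns=["lnc_id", "pcg_id", "chrom", "gap_bp", "relation", "same_strand"],
    )


def write_pairs_tsv(pairs: Sequence[NeighborPair], path: str | Path) -> None:
    pairs_to_frame(pairs).to_csv(path, sep="\t", index=False)
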