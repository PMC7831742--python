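"""Relative qPCR quantification by the 2^-ddCt method.

Ct replicates are averaged per (gene, condition); dCt subtracts the
endogenous-control gene (e.g. 18S rRNA) within the condition; ddCt
subtracts the baseline condition's dCt (the non-targeting siRNA control in
a knockdown experiment); relative quantity is 2^-ddCt, and a knockdown is
reported as its fold reduction 1/rq.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import pandas as pd


@dataclass
class QpcrPlate:
    """Ct triplicates per (gene, condition) with an endogenous control.

    ``wells``: frame with columns ``gene, condition, replicate, ct``.
    """

    wells: pd.DataFrame
    reference_gene: str
    control_condition: str

    def __post_init__(self) -> None:
        required = {"gene", "condition", "replicate", "ct"}
        missing = required - set(self.wells.columns)
        if missing:
            raise ValueError(f"plate table missing columns: {sorted(missing)}")
        if (self.wells["ct"] <= 0).any():
            raise ValueError("Ct values must be positive")
        conditions = self.conditions
        ref = self.wells[self.wells["gene"] == self.reference_gene]
        missing_ref = set(conditions) - set(ref["condition"])
        if missing_ref:
            raise ValueError(
                f"reference gene {self.reference_gene!r} not measured in "
                f"conditions: {sorted(missing_ref)}"
            )

    @property
    def conditions(self) -> list[str]:
        return sorted(self.wells["condition"].unique())

    @property
    def genes(self) -> list[str]:
        return sorted(self.wells["gene"].unique())

    def mean_ct(self, gene: str, condition: str) -> float:
        sel = self.wells[(self.wells["gene"] == gene) & (self.wells["condition"] == condition)]
        if sel.empty:
            raise ValueError(f"no wells for gene {gene!r} in condition {condition!r}")
        return float(sel["ct"].mean())


@dataclass(frozen=True)
class RelativeQuantity:
    target_gene: str
    condition: str
    delta_ct: float
    delta_delta_ct: float
    rq: float
    fold_reduction: Optional[float]  # 1/rq when rq < 1, else None


def read_plate_csv(
    path: str | Path,
    reference_gene: str,
    control_condition: str,
) -> QpcrPlate:
    """Plate CSV with columns gene, condition, replicate, ct."""
    wells = pd.read_csv(path, dtype={"gene": str, "condition": str})
    return QpcrPlate(wells=wells, reference_gene=reference_gene,
                     control_condition=control_condition)


def delta_ct(plate: QpcrPlate, gene: str, condition: str) -> float:
    """Replicate-mean Ct(gene) minus replicate-mean Ct(reference), within
    one condition."""
    return plate.mean_ct(gene, condition) - plate.mean_ct(plate.reference_gene, condition)


def relative_quantity(plate: QpcrPlate, gene: str, condition: str) -> RelativeQuantity:
    """2^-ddCt relative quantity of ``gene`` in ``condition`` against the
    plate's control condition."""
    if condition not in plate.conditions:
        raise ValueError(f"condition {condition!r} not on plate")
    if plate.control_condition not in plate.conditions:
        raise ValueError(f"control condition {plate.control_condition!r} not on plate")
    dct = delta_ct(plate, gene, condition)
    ddct = dct - delta_ct(plate, gene, plate.control_condition)
    rq = 2.0 ** (-ddct)
    return RelativeQuantity(
        target_gene=gene,
        condition=condition,
        delta_ct=dct,
        delta_delta_ct=ddct,
        rq=rq,
        fold_reduction=(1.0 / rq) if rq < 1 else None,
    )


def quantify_all(plate: QpcrPlate) -> pd.DataFrame:
    """Relative quantities for every (gene, condition) on the plate."""
    rows = []
    for gene in plate.genes:
        for condition in plate.conditions:
            sel = plate.wells[
                (plate.wells["gene"] == gene) & (plate.wells["condition"] == condition)
            ]
            if sel.empty:
                continue
            rq = relative_quantity(plate, gene, condition)
            rows.append(
                {
                    "gene": gene,
                    "condition": condition,
                    "delta_ct": rq.delta_ct,
                    "delta_delta_ct": rq.delta_delta_ct,
                    "rq": rq.rq,
                    "fold_reduction": rq.fold_reduction,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["gene", "condition", "delta_ct", "delta_delta_ct", "rq", "fold_reduction"],
    )


def knockdown_report(
    plate: QpcrPlate,
    knocked_gene: str,
    readout_gene: str,
) -> pd.DataFrame:
    """Per-condition relative quantities for the knocked gene and a readout
    gene, against the non-targeting control condition.

    On a successful knockdown the knocked gene's rq falls below 1 (its fold
    reduction is reported); the readout gene's rq shows any secondary
    response (e.g. de-repression of a neighbor).
    """
    if plate.control_condition not in plate.conditions:
        raise ValueError(
            f"non-targeting control condition {plate.control_condition!r} absent from plate"
        )
    rows = []
    for gene in (knocked_gene, readout_gene):
        for condition in plate.conditions:
            sel = plate.wells[
                (plate.wells["gene"] == gene) & (plate.wells["condition"] == condition)
            ]
            if sel.empty:
                continue
            rq = relative_quantity(plate, gene, condition)
            rows.append(
                {
                    "gene": gene,
                    "role": "knocked" if gene == knocked_gene else "readout",
                    "condition": condition,
                    "delta_ct": rq.delta_ct,
                    "delta_delta_ct": rq.delta_delta_ct,
                    "rq": rq.rq,
                    "fold_reduction": rq.fold_reduction,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["gene", "role", "condition", "delta_ct", "delta_delta_ct", "rq",
                 "fold_reduction"],
    )


def write_quantities_tsv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.6g")
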