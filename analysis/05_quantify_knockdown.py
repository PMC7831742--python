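#!/usr/bin/env python
"""Quantify the siRNA knockdown qPCR plate by 2^-ddCt against the
non-targeting control: fold reduction of the knocked lncRNA and the relative
quantity of the neighboring protein-coding readout gene, per condition.

Reads scratch/simdata/qpcr_plate.csv; writes results/qpcr_knockdown.tsv.
"""

from pathlib import Path

from cislnc.qpcr import knockdown_report, read_plate_csv, write_quantities_tsv

ROOT = Path(__file__).resolve().parent.parent
SIM = ROOT / "scratch" / "simdata"
RESULTS = ROOT / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    plate = read_plate_csv(SIM / "qpcr_plate.csv", reference_gene="RNA18S",
                           control_condition="non_targeting")
    report = knockdown_report(plate, "LNC_target", "PCG_readout")
    write_quantities_tsv(report, RESULTS / "qpcr_knockdown.tsv")
    for _, row in report[report["condition"].str.startswith("sirna")].iterrows():
        extra = (f", {row['fold_reduction']:.2f}-fold reduction"
                 if row["fold_reduction"] == row["fold_reduction"] else "")
        print(f"{row['gene']} ({row['role']}) @ {row['condition']}: "
              f"rq={row['rq']:.3f}{extra}")
    print(f"wrote {RESULTS / 'qpcr_knockdown.tsv'}")


if __name__ == "__main__":
    main()
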