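#!/usr/bin/env python
"""Screen for candidate cis-acting lncRNAs: intersect the two cohorts'
deregulation calls with lncRNA/protein-coding neighbor pairs within 1.5 kb
and classify each candidate's concordance.

Reads scratch/ outputs of 01 and 02; writes results/candidates.tsv.
"""

from pathlib import Path

import pandas as pd

from cislnc.annotation import neighbor_pairs, read_gtf
from cislnc.cis_screen import rank_candidates, screen, write_candidates_tsv

ROOT = Path(__file__).resolve().parent.parent
SIM = ROOT / "scratch" / "simdata"
RESULTS = ROOT / "results"


def _read_de(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="gene_id")
    df["deregulated"] = df["deregulated"].astype(bool)
    return df


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    genes = read_gtf(SIM / "annotation.gtf")
    pairs = neighbor_pairs(genes, max_gap=1500)
    de_a = _read_de(ROOT / "scratch" / "de_a.tsv")
    de_b = _read_de(ROOT / "scratch" / "de_b.tsv")
    candidates = rank_candidates(screen(de_a, de_b, pairs))
    write_candidates_tsv(candidates, RESULTS / "candidates.tsv")

    truth = pd.read_csv(SIM / "truth_pairs.tsv", sep="\t")
    planted = set(map(tuple, truth.loc[truth["kind"] == "planted", ["lnc_id", "pcg_id"]].values))
    decoys = set(map(tuple, truth.loc[truth["kind"] == "decoy", ["lnc_id", "pcg_id"]].values))
    found = {(c.lnc_id, c.pcg_id) for c in candidates}
    print(f"{len(pairs)} neighbor pairs within 1.5 kb; {len(candidates)} candidates "
          f"({sum(c.concordance == 'discordant' for c in candidates)} discordant)")
    print(f"planted pairs recovered: {len(found & planted)}/{len(planted)}; "
          f"decoy pairs admitted: {len(found & decoys)}/{len(decoys)}")
    print(f"wrote {RESULTS / 'candidates.tsv'}")


if __name__ == "__main__":
    main()
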