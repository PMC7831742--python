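#!/usr/bin/env python
"""Characterize each candidate pair within cohort-B tumors: Spearman
correlation, partner expression between lncRNA tertiles, partner
methylation between lncRNA tertiles, and stage I-vs-II contrasts.

Reads scratch/ outputs of 01-03; writes results/associations.tsv.
"""

from pathlib import Path

import pandas as pd

from cislnc.association import associate_pair
from cislnc.paired_de import read_cohort, two_group_test

ROOT = Path(__file__).resolve().parent.parent
SIM = ROOT / "scratch" / "simdata"
RESULTS = ROOT / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    cohort = read_cohort(SIM / "expression_b.tsv", SIM / "metadata_b.tsv")
    betas = pd.read_csv(SIM / "methylation_b.tsv", sep="\t", index_col=0)
    candidates = pd.read_csv(RESULTS / "candidates.tsv", sep="\t")
    tumors = cohort.condition_samples("tumor")
    stage = cohort.sample_stage().reindex(tumors)

    rows = []
    for _, cand in candidates.iterrows():
        lnc_expr = cohort.values.loc[cand["lnc_id"], tumors].astype(float)
        pcg_expr = cohort.values.loc[cand["pcg_id"], tumors].astype(float)
        res = associate_pair(lnc_expr, pcg_expr, cand["lnc_id"], cand["pcg_id"],
                             pcg_betas=betas.loc[cand["pcg_id"]].astype(float))
        _, stage_p = two_group_test(lnc_expr.to_numpy(), stage.to_numpy())
        rows.append({
            "lnc_id": res.lnc_id, "pcg_id": res.pcg_id,
            "rho": round(res.rho, 3), "rho_p": res.rho_p,
            "tertile_p": res.tertile_p, "tertile_direction": res.tertile_direction,
            "methylation_p": res.methylation_p,
            "methylation_direction": res.methylation_direction,
            "stage_p_lnc": stage_p,
        })
        print(f"{res.lnc_id}/{res.pcg_id}: rho={res.rho:.2f} (p={res.rho_p:.2g}), "
              f"partner {res.tertile_direction} across lnc tertiles "
              f"(p={res.tertile_p:.2g}), methylation {res.methylation_direction} "
              f"(p={res.methylation_p:.2g}), lnc stage contrast p={stage_p:.2g}")
    pd.DataFrame(rows).to_csv(RESULTS / "associations.tsv", sep="\t", index=False)
    print(f"wrote {RESULTS / 'associations.tsv'}")


if __name__ == "__main__":
    main()
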