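import numpy as np
import pandas as pd
import pytest

from cislnc.annotation import gene_gap, read_gtf
from cislnc.association import tertile_contrast, tertile_split
from cislnc.paired_de import call_deregulated
from cislnc.simulate import (
    SimulationConfig,
    make_knockdown_plate,
    simulate_annotation,
    simulate_cohort,
    simulate_methylation,
    simulate_qpcr,
    write_dataset,
    write_gtf,
)

SMALL = dict(n_genes=40, n_planted_pairs=2, n_decoy_pairs=1, n_planted_singletons=2)


class TestConfig:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"frac_lnc": 0.0},
            {"coupling": 1.5},
            {"effect_fold": 0.5},
            {"gap_range": (-1, 100)},
            {"gap_range": (500, 100)},
            {"n_genes": 5},  # too small for default planted structure
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimulationConfig(**kwargs)


class TestAnnotation:
    def test_planted_gaps_within_range(self):
        cfg = SimulationConfig(seed=2, gap_range=(100, 1000), **SMALL)
        _, truth = simulate_annotation(cfg)
        assert len(truth.planted_pairs) == 2
        for p in truth.planted_pairs:
            assert 100 <= p["gap_bp"] <= 1000

    def test_same_seed_byte_identical_gtf(self, tmp_path):
        cfg = SimulationConfig(seed=7, **SMALL)
        for name in ("a.gtf", "b.gtf"):
            genes, _ = simulate_annotation(cfg)
            write_gtf(genes, tmp_path / name)
        assert (tmp_path / "a.gtf").read_bytes() == (tmp_path / "b.gtf").read_bytes()

    def test_truth_gaps_match_remeasured_gene_gap(self, tmp_path):
        """Round trip: gaps in the truth table equal gaps re-measured from
        the emitted GTF by the annotation module."""
        cfg = SimulationConfig(seed=3, **SMALL)
        genes, truth = simulate_annotation(cfg)
        write_gtf(genes, tmp_path / "sim.gtf")
        by_id = {g.gene_id: g for g in read_gtf(tmp_path / "sim.gtf")}
        for p in truth.planted_pairs + truth.decoy_pairs:
            assert gene_gap(by_id[p["lnc_id"]], by_id[p["pcg_id"]]) == p["gap_bp"]

    def test_infeasible_layout_rejected(self):
        cfg = SimulationConfig(seed=0, chrom_length=10_000, **SMALL)
        with pytest.raises(ValueError, match="infeasible"):
            simulate_annotation(cfg)

    def test_truth_partition_is_disjoint_and_complete(self):
        cfg = SimulationConfig(seed=5, **SMALL)
        genes, truth = simulate_annotation(cfg)
        planted = (
            {p["lnc_id"] for p in truth.planted_pairs}
            | {p["pcg_id"] for p in truth.planted_pairs}
            | {s["gene_id"] for s in truth.planted_singletons}
        )
        assert planted.isdisjoint(truth.null_genes)
        assert planted | set(truth.null_genes) == {g.gene_id for g in genes}


class TestCohort:
    def test_degenerate_parameters_give_null_pair(self):
        cfg = SimulationConfig(seed=4, coupling=0.0, effect_fold=1.0, **SMALL)
        genes, truth = simulate_annotation(cfg)
        cohort = simulate_cohort(cfg, genes, truth, "a")
        de = call_deregulated(cohort)
        pair = truth.planted_pairs[0]
        assert not de.loc[pair["lnc_id"], "deregulated"]
        assert not de.loc[pair["pcg_id"], "deregulated"]

    def test_planted_pcg_detected_across_seeds(self):
        """With a 4-fold planted shift and 30 pairs the partner gene must be
        called deregulated in at least 19 of 20 seeds."""
        hits = 0
        for seed in range(20):
            cfg = SimulationConfig(seed=seed, n_patients_a=30, **SMALL)
            genes, truth = simulate_annotation(cfg)
            de = call_deregulated(simulate_cohort(cfg, genes, truth, "a"))
            hits += bool(de.loc[truth.planted_pairs[0]["pcg_id"], "deregulated"])
        assert hits >= 19

    def test_baselines_shared_across_cohorts(self):
        cfg = SimulationConfig(seed=6, **SMALL)
        genes, truth = simulate_annotation(cfg)
        a = simulate_cohort(cfg, genes, truth, "a")
        b = simulate_cohort(cfg, genes, truth, "b")
        mean_a = np.log2(a.values[a.condition_samples("normal")]).mean(axis=1)
        mean_b = np.log2(b.values[b.condition_samples("normal")]).mean(axis=1)
        assert np.corrcoef(mean_a, mean_b)[0, 1] > 0.9

    def test_stage_labels_balanced_and_shared_within_patient(self):
        cfg = SimulationConfig(seed=8, **SMALL)
        genes, truth = simulate_annotation(cfg)
        cohort = simulate_cohort(cfg, genes, truth, "b")
        per_patient = cohort.samples.groupby("patient_id")["stage"].nunique()
        assert (per_patient == 1).all()
        counts = cohort.samples[cohort.samples["condition"] == "tumor"]["stage"].value_counts()
        assert abs(counts["I"] - counts["II"]) <= 1

    def test_planted_lnc_lower_in_stage_ii_tumors(self):
        cfg = SimulationConfig(seed=9, n_patients_b=60, **SMALL)
        genes, truth = simulate_annotation(cfg)
        cohort = simulate_cohort(cfg, genes, truth, "b")
        tumors = cohort.samples[cohort.samples["condition"] == "tumor"]
        lnc = truth.planted_pairs[0]["lnc_id"]
        expr = np.log2(cohort.values.loc[lnc, tumors["sample_id"]].astype(float))
        by_stage = expr.groupby(tumors.set_index("sample_id")["stage"]).mean()
        assert by_stage["II"] < by_stage["I"]


class TestMethylation:
    def test_betas_within_unit_interval(self, default_dataset):
        betas = default_dataset.methylation_b.to_numpy()
        assert betas.min() >= 0.0 and betas.max() <= 1.0

    def test_zero_coupling_gives_no_systematic_contrast(self):
        """With methyl_coupling=0 the tertile contrast on partner betas has
        no consistent direction; the mean |median difference| across seeds
        stays below the noise scale."""
        diffs = []
        for seed in range(20):
            cfg = SimulationConfig(seed=seed, methyl_coupling=0.0, **SMALL)
            genes, truth = simulate_annotation(cfg)
            cohort = simulate_cohort(cfg, genes, truth, "b")
            betas = simulate_methylation(cfg, truth, cohort, "b")
            pair = truth.planted_pairs[0]
            tumors = cohort.condition_samples("tumor")
            split = tertile_split(
                cohort.values.loc[pair["lnc_id"], tumors].astype(float), pair["lnc_id"]
            )
            res = tertile_contrast(split, betas.loc[pair["pcg_id"]].astype(float))
            diffs.append(res.median_high - res.median_low)
        assert abs(np.mean(diffs)) < 0.05  # noise scale on the beta axis


class TestQpcrSimulation:
    def test_zero_ddct_gives_unit_rq(self):
        from cislnc.qpcr import quantify_all

        plate = simulate_qpcr({"T": {}}, replicate_sd=0.0, seed=1)
        table = quantify_all(plate)
        assert table[table["gene"] == "T"]["rq"].to_numpy() == pytest.approx(1.0)

    def test_same_seed_identical_plate(self):
        p1 = make_knockdown_plate(seed=5)
        p2 = make_knockdown_plate(seed=5)
        pd.testing.assert_frame_equal(p1.wells, p2.wells)

    def test_five_condition_design_present(self):
        plate = make_knockdown_plate(seed=0)
        assert plate.conditions == sorted(
            ["untreated", "gapdh_sirna", "non_targeting", "sirna_12.5nM", "sirna_25nM"]
        )


class TestWriteDataset:
    def test_all_artifacts_written_and_deterministic(self, tmp_path):
        cfg = SimulationConfig(seed=11, **SMALL)
        paths1 = write_dataset(cfg, tmp_path / "d1")
        paths2 = write_dataset(cfg, tmp_path / "d2")
        for key in paths1:
            assert paths1[key].exists()
            assert paths1[key].read_bytes() == paths2[key].read_bytes(), key
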