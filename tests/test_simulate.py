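"""Synthetic-data generator: contracts, determinism, truth invariants, calibration."""

from __future__ import annotations

import numpy as np
import pytest

import editome.simulate as sim
from editome.simulate import (
    GENOTYPES,
    PlacementError,
    SimConfig,
    SizingError,
    detection_probability,
    plant_truth,
    simulate_genome,
    simulate_pileups,
)

from oracles import detection_probability_bf


def _tiny_config(**overrides) -> SimConfig:
    base = dict(
        contig_lengths={"chr1": 6000},
        n_genes=6,
        n_snps=10,
        n_shared_sites=20,
        private_sites={"WT": 2, "Adar_het": 2, "RdRp_tg": 2, "DoubleHet": 8},
        repeat_density={"SINE": 300.0, "LINE": 0.0, "DNA_transposon": 0.0, "other_retrotransposon": 0.0},
        seed=5,
    )
    base.update(overrides)
    return SimConfig(**base)


class TestGenomeConstruction:
    def test_empty_genome_has_requested_length_and_no_features(self):
        cfg = _tiny_config(n_genes=0, n_snps=0, n_shared_sites=0,
                           private_sites={}, repeat_density={})
        genome, features = simulate_genome(cfg)
        assert len(genome["chr1"]) == 6000
        assert len(features.genes) == 0 and len(features.repeats) == 0

    def test_gene_structure_contract(self):
        cfg = _tiny_config(n_genes=2, exons_per_gene=3)
        _, features = simulate_genome(cfg)
        assert features.gene_ids == {"gene0000", "gene0001"}
        for gid, sub in features.genes.groupby("gene_id"):
            classes = list(sub["feature_class"])
            assert classes.count("five_prime_utr") == 1
            assert classes.count("three_prime_utr") == 1
            assert classes.count("cds") == 3
            assert classes.count("intron") == 2
            # strand-consistent, non-overlapping, contiguous tiling
            assert sub["strand"].nunique() == 1
            ordered = sub.sort_values("start")
            assert (ordered["start"].to_numpy()[1:] == ordered["end"].to_numpy()[:-1] + 1).all()

    def test_contig_too_small_raises_sizing_error_naming_contig(self):
        cfg = _tiny_config()
        cfg.contig_lengths = {"chrTiny": 500}
        with pytest.raises(SizingError, match="chrTiny"):
            simulate_genome(cfg)

    def test_same_seed_gives_identical_dataset_files(self, tmp_path):
        from editome.simulate import write_dataset

        cfg = _tiny_config()
        write_dataset(cfg, tmp_path / "a")
        write_dataset(_tiny_config(), tmp_path / "b")
        for name in ("genome.fa", "genes.bed", "repeats.bed", "truth_edits.tsv",
                     "pileups/rna_DoubleHet_2.tsv", "pileups/dna_exome_pool.tsv"):
            assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes(), name


class TestTruthPlanting:
    def test_degenerate_weights_put_all_sites_in_three_prime_utr(self):
        cfg = _tiny_config(placement_weights={"three_prime_utr": 1.0})
        genome, features = simulate_genome(cfg)
        truth = plant_truth(cfg, genome, features)
        assert (truth.edits["feature_class"] == "three_prime_utr").all()

    def test_double_het_unique_quota_arithmetic(self):
        cfg = _tiny_config(n_shared_sites=60, private_sites={"DoubleHet": 40})
        genome, features = simulate_genome(cfg)
        truth = plant_truth(cfg, genome, features)
        only_dh = truth.edits[
            (truth.edits["f_DoubleHet"] > 0)
            & (truth.edits[[f"f_{g}" for g in GENOTYPES if g != "DoubleHet"]] == 0).all(axis=1)
        ]
        assert len(only_dh) == 40
        assert (truth.edits["f_DoubleHet"] > 0).sum() == 100

    def test_edit_sites_sit_on_adenosines_of_their_strand(self, sim_bundle):
        edits = sim_bundle.truth.edits
        plus = edits[edits["strand"] == "+"]
        minus = edits[edits["strand"] == "-"]
        assert (plus["ref"] == "A").all() and (plus["change"] == "A>G").all()
        assert (minus["ref"] == "T").all() and (minus["change"] == "T>C").all()
        for row in edits.sample(50, random_state=0).itertuples(index=False):
            assert sim_bundle.genome[row.contig][row.pos - 1] == row.ref

    def test_snp_and_edit_positions_are_disjoint(self, sim_bundle):
        truth = sim_bundle.truth
        edit_pos = set(zip(truth.edits["contig"], truth.edits["pos"]))
        assert not (edit_pos & truth.snp_positions())

    def test_placement_error_when_class_pool_exhausted(self):
        cfg = _tiny_config(n_genes=1, n_shared_sites=500, placement_weights={"five_prime_utr": 1.0})
        genome, features = simulate_genome(cfg)
        with pytest.raises(PlacementError, match="five_prime_utr"):
            plant_truth(cfg, genome, features)

    @pytest.mark.parametrize("f", [0.1, 0.3, 0.6])
    def test_detection_probability_matches_binomial_sum_oracle(self, f):
        got = detection_probability(f, depth_mean=50.0, error_rate=0.005)
        expected = detection_probability_bf(f, 50.0, 0.005)
        assert got == pytest.approx(expected, abs=1e-9)

    def test_expected_consensus_counts_use_fourth_power_of_detection(self, sim_bundle):
        truth, cfg = sim_bundle.truth, sim_bundle.config
        edited = truth.edits[truth.edits["f_WT"] > 0]
        manual = sum(
            detection_probability_bf(f, cfg.rna_coverage_mean, cfg.error_rate) ** 4
            for f in edited["f_WT"]
        )
        assert truth.expected_consensus_sites["WT"] == pytest.approx(manual, rel=1e-6)


class TestPileups:
    def test_zero_noise_pileups_contain_only_reference_counts(self):
        cfg = _tiny_config(error_rate=0.0, n_snps=0, n_shared_sites=0, private_sites={})
        genome, features = simulate_genome(cfg)
        truth = plant_truth(cfg, genome, features)
        rna, _ = simulate_pileups(genome, truth, cfg)
        df = rna["WT_1"]
        ref_count = np.choose(
            df["ref"].map({"A": 0, "C": 1, "G": 2, "T": 3}).to_numpy(),
            [df["nA"].to_numpy(), df["nC"].to_numpy(), df["nG"].to_numpy(), df["nT"].to_numpy()],
        )
        assert (ref_count == df["depth"].to_numpy()).all()

    def test_homozygous_snp_gives_pure_alternate_dna_evidence(self):
        cfg = _tiny_config(error_rate=0.0, het_fraction=0.0, n_shared_sites=0, private_sites={})
        genome, features = simulate_genome(cfg)
        truth = plant_truth(cfg, genome, features)
        _, dna = simulate_pileups(genome, truth, cfg)
        df = dna["exome_pool"].set_index("pos")
        for row in truth.snps.itertuples(index=False):
            rec = df.loc[row.pos]
            assert rec[f"n{row.alt}"] == rec["depth"]

    def test_editing_fraction_calibrated_at_high_depth(self):
        """Empirical G fraction at planted sites converges to the configured
        fraction adjusted for the symmetric error model (3-SE tolerance)."""
        cfg = _tiny_config(
            contig_lengths={"chr1": 2000}, n_genes=0, n_snps=0,
            n_shared_sites=20, private_sites={},
            placement_weights={"intergenic": 1.0},
            rna_coverage_mean=1000.0,
            edit_fraction_range=(0.5, 0.5),
            repeat_density={},
        )
        genome, features = simulate_genome(cfg)
        truth = plant_truth(cfg, genome, features)
        rna, _ = simulate_pileups(genome, truth, cfg)
        df = rna["WT_1"].set_index("pos")
        e = cfg.error_rate
        p_expected = 0.5 * (1 - e) + 0.5 * e / 3
        variant = depth = 0
        for row in truth.edits.itertuples(index=False):
            rec = df.loc[row.pos]
            variant += rec["nG"] if row.change == "A>G" else rec["nC"]
            depth += rec["depth"]
        se = np.sqrt(p_expected * (1 - p_expected) / depth)
        assert abs(variant / depth - p_expected) < 3 * se

    def test_pileups_sorted_and_depth_consistent(self, sim_bundle):
        df = sim_bundle.rna["RdRp_tg_3"]
        assert (df[["nA", "nC", "nG", "nT"]].sum(axis=1) == df["depth"]).all()
        for _, sub in df.groupby("contig"):
            assert sub["pos"].is_monotonic_increasing


class TestConfigValidation:
    @pytest.mark.parametrize(
        "overrides",
        [
            {"edit_fraction_range": (0.0, 0.5)},
            {"placement_weights": {"intergenic": 0.7}},
            {"animals_per_genotype": 0},
            {"private_sites": {"Nope": 3}},
            {"error_rate": 1.5},
        ],
    )
    def test_invalid_configs_rejected(self, overrides):
        with pytest.raises(ValueError):
            _tiny_config(**overrides)

    def test_config_round_trips_through_dict(self):
        cfg = _tiny_config()
        assert SimConfig.from_dict(cfg.to_dict()) == cfg
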