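"""Shared fixtures: a desk-scale simulated study and a hand-built annotation."""

from __future__ import annotations

from types import SimpleNamespace

import pandas as pd
import pytest

from editome.annotate import FeatureTable
from editome.calling import call_edit_sites, call_exome_snps
from editome.consensus import GenotypeEditome
from editome.simulate import (
    GENOTYPES,
    SimConfig,
    plant_truth,
    simulate_genome,
    simulate_pileups,
)

#: scaled-down study: same structure (4 genotypes x 4 animals, depth 50,
#: fractions >= 0.2, error 0.005, DoubleHet private pool ~55% of the common
#: editome) on a 40 kb genome so the whole suite stays fast
SMALL_SIM = dict(
    contig_lengths={"chr1": 20_000, "chr2": 20_000},
    n_genes=40,
    n_snps=60,
    n_shared_sites=120,
    private_sites={"WT": 8, "Adar_het": 8, "RdRp_tg": 8, "DoubleHet": 75},
    seed=11,
)


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    return SimConfig(**SMALL_SIM)


@pytest.fixture(scope="session")
def sim_bundle(small_config):
    """Genome, truth, pileups, mask, per-animal calls and consensus editomes."""
    genome, features = simulate_genome(small_config)
    truth = plant_truth(small_config, genome, features)
    rna, dna = simulate_pileups(genome, truth, small_config)
    mask = call_exome_snps(list(dna.values()))
    calls = {}
    editomes = {}
    for g in GENOTYPES:
        per = {}
        for a in range(small_config.animals_per_genotype):
            sid = f"{g}_{a + 1}"
            per[sid] = call_edit_sites(rna[sid], mask, features, genome=genome, animal_id=sid, genotype=g)
        calls[g] = per
        editomes[g] = GenotypeEditome.build(g, per, features)
    return SimpleNamespace(
        config=small_config, genome=genome, features=features, truth=truth,
        rna=rna, dna=dna, mask=mask, calls=calls, editomes=editomes,
    )


@pytest.fixture(scope="session")
def sim_dataset(small_config, tmp_path_factory):
    """The same small study written to disk in interchange formats."""
    from editome.simulate import write_dataset

    outdir = tmp_path_factory.mktemp("dataset")
    return write_dataset(small_config, outdir)


@pytest.fixture()
def toy_features() -> FeatureTable:
    """Two genes (one per strand) and overlapping repeats on a 1 kb contig."""
    genes = pd.DataFrame(
        [
            ("chr1", 101, 120, "+", "geneA", "five_prime_utr"),
            ("chr1", 121, 180, "+", "geneA", "cds"),
            ("chr1", 181, 220, "+", "geneA", "intron"),
            ("chr1", 221, 280, "+", "geneA", "cds"),
            ("chr1", 281, 340, "+", "geneA", "three_prime_utr"),
            ("chr1", 401, 460, "-", "geneB", "three_prime_utr"),
            ("chr1", 461, 520, "-", "geneB", "cds"),
            ("chr1", 521, 540, "-", "geneB", "five_prime_utr"),
        ],
        columns=["contig", "start", "end", "strand", "gene_id", "feature_class"],
    )
    repeats = pd.DataFrame(
        [
            ("chr1", 300, 500, "LINE"),
            ("chr1", 440, 470, "SINE"),
            ("chr1", 600, 700, "SINE"),
            ("chr1", 650, 680, "DNA_transposon"),
        ],
        columns=["contig", "start", "end", "repeat_class"],
    )
    return FeatureTable(genes, repeats, {"chr1": 1000})
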