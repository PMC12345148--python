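"""Edit calling: threshold rules, strand logic, masking, and the brute-force oracle."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from editome.calling import (
    CallThresholds,
    ReferenceMismatchError,
    SnpMask,
    SnpThresholds,
    call_edit_sites,
    call_exome_snps,
    merge_known_variants,
)
from editome.io import OrderingError
from editome.annotate import FeatureTable

from oracles import naive_edit_calls

THRESH = CallThresholds()


def pileup_row(contig="chr1", pos=1, ref="A", nA=0, nC=0, nG=0, nT=0, sample_id="s1"):
    depth = nA + nC + nG + nT
    return dict(contig=contig, pos=pos, ref=ref, nA=nA, nC=nC, nG=nG, nT=nT,
                depth=depth, sample_id=sample_id)


def as_pileup(rows) -> pd.DataFrame:
    return pd.DataFrame(rows)


def permissive_mask(pileup: pd.DataFrame) -> SnpMask:
    """Every position assessable, none masked."""
    return SnpMask(assessable=set(zip(pileup["contig"], pileup["pos"].astype(int))))


class TestExomeSnpCalling:
    def test_het_hom_and_clean_positions(self):
        dna = as_pileup([
            pileup_row(pos=10, ref="A", nA=20, nG=20),      # het SNP
            pileup_row(pos=20, ref="A", nA=40),             # clean
            pileup_row(pos=30, ref="C", nT=40),             # hom SNP
            pileup_row(pos=40, ref="A", nA=2, nG=2),        # depth 4 < 10
        ])
        mask = call_exome_snps(dna)
        assert mask.positions == {("chr1", 10), ("chr1", 30)}
        assert ("chr1", 40) in mask.unassessable
        assert ("chr1", 20) in mask.assessable and ("chr1", 20) not in mask

    def test_alt_fraction_threshold_boundary(self):
        dna = as_pileup([pileup_row(pos=1, ref="A", nA=36, nG=4)])  # 10% exactly
        assert ("chr1", 1) in call_exome_snps(dna, SnpThresholds(min_alt_fraction=0.1))
        dna = as_pileup([pileup_row(pos=1, ref="A", nA=37, nG=3)])
        assert ("chr1", 1) not in call_exome_snps(dna)

    def test_multiple_dna_samples_are_pooled(self):
        a = as_pileup([pileup_row(pos=5, ref="A", nA=3, nG=3, sample_id="d1")])
        b = as_pileup([pileup_row(pos=5, ref="A", nA=3, nG=3, sample_id="d2")])
        mask = call_exome_snps([a, b])
        assert ("chr1", 5) in mask  # pooled depth 12, alt 50%

    def test_unsorted_dna_raises_with_position(self):
        dna = as_pileup([pileup_row(pos=9, nA=20), pileup_row(pos=3, nA=20)])
        with pytest.raises(OrderingError, match="chr1:3"):
            call_exome_snps(dna)


class TestMaskMerging:
    def test_union_is_idempotent_and_tracks_provenance(self):
        base = call_exome_snps(as_pileup([pileup_row(pos=10, ref="A", nA=20, nG=20)]))
        merged = merge_known_variants(base, [("chr1", 10), ("chr2", 99)])
        again = merge_known_variants(merged, [("chr1", 10), ("chr2", 99)])
        assert again.positions == {("chr1", 10), ("chr2", 99)}
        assert again.provenance[("chr1", 10)] == {"exome", "known"}
        assert again.provenance[("chr2", 99)] == {"known"}
        assert base.positions == {("chr1", 10)}  # input not mutated

    def test_merge_size_equals_set_union_on_random_sets(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            a = {("chr1", int(p)) for p in rng.integers(1, 200, rng.integers(0, 50))}
            b = {("chr1", int(p)) for p in rng.integers(1, 200, rng.integers(0, 50))}
            mask = SnpMask(provenance={k: {"exome"} for k in a})
            assert merge_known_variants(mask, b).positions == a | b


class TestEditCalling:
    def test_plus_strand_call_arithmetic(self, toy_features):
        pileup = as_pileup([pileup_row(pos=290, ref="A", nA=14, nG=6)])  # inside geneA 3'UTR
        calls = call_edit_sites(pileup, permissive_mask(pileup), toy_features)
        assert len(calls) == 1
        row = calls.iloc[0]
        assert (row["change"], row["strand"], row["genes"]) == ("A>G", "+", "geneA")
        assert row["editing_fraction"] == pytest.approx(0.30)
        assert row["depth"] == 20 and row["variant_reads"] == 6

    def test_minus_strand_gene_accepts_tc_and_rejects_ag(self, toy_features):
        pileup = as_pileup([
            pileup_row(pos=470, ref="T", nT=21, nC=9),   # geneB (-): T>C ok
            pileup_row(pos=480, ref="A", nA=21, nG=9),   # geneB (-): A>G inconsistent
        ])
        calls = call_edit_sites(pileup, permissive_mask(pileup), toy_features)
        assert list(calls["pos"]) == [470]
        assert calls.iloc[0]["change"] == "T>C"
        assert calls.iloc[0]["editing_fraction"] == pytest.approx(0.30)

    def test_intergenic_sites_accepted_unstranded_for_both_orientations(self, toy_features):
        pileup = as_pileup([
            pileup_row(pos=50, ref="A", nA=14, nG=6),
            pileup_row(pos=60, ref="T", nT=14, nC=6),
        ])
        calls = call_edit_sites(pileup, permissive_mask(pileup), toy_features)
        assert set(calls["change"]) == {"A>G", "T>C"}
        assert set(calls["strand"]) == {"."}
        assert set(calls["genes"]) == {""}

    def test_masked_position_yields_no_call(self, toy_features):
        pileup = as_pileup([pileup_row(pos=50, ref="A", nA=10, nG=10)])
        mask = permissive_mask(pileup)
        mask.provenance[("chr1", 50)] = {"exome"}
        assert len(call_edit_sites(pileup, mask, toy_features)) == 0

    def test_unassessable_dropped_by_default_but_toggleable(self, toy_features):
        pileup = as_pileup([pileup_row(pos=50, ref="A", nA=14, nG=6)])
        mask = SnpMask()  # no DNA evidence anywhere
        assert len(call_edit_sites(pileup, mask, toy_features)) == 0
        keep = CallThresholds(drop_unassessable=False)
        assert len(call_edit_sites(pileup, mask, toy_features, keep)) == 1

    def test_complex_position_excluded(self, toy_features):
        # G passes but C also at 10% -> likely unmasked variant or artifact
        pileup = as_pileup([pileup_row(pos=50, ref="A", nA=32, nG=4, nC=4)])
        calls = call_edit_sites(pileup, permissive_mask(pileup), toy_features,
                                emit_flagged=True)
        assert "complex" in calls.iloc[0]["filter_flags"]

    def test_fraction_window_excludes_residual_homozygous_changes(self, toy_features):
        pileup = as_pileup([
            pileup_row(pos=50, ref="A", nG=40),             # fraction 1.0
            pileup_row(pos=60, ref="A", nA=97, nG=3),       # fraction 0.03 < 0.05
        ])
        assert len(call_edit_sites(pileup, permissive_mask(pileup), toy_features)) == 0

    def test_reference_mismatch_raises(self, toy_features):
        pileup = as_pileup([pileup_row(pos=50, ref="A", nA=14, nG=6)])
        genome = {"chr1": "C" * 1000}
        with pytest.raises(ReferenceMismatchError, match="chr1:50"):
            call_edit_sites(pileup, permissive_mask(pileup), toy_features, genome=genome)

    def test_unsorted_rna_rejected(self, toy_features):
        pileup = as_pileup([pileup_row(pos=60, nA=10), pileup_row(pos=50, nA=10)])
        with pytest.raises(OrderingError):
            call_edit_sites(pileup, permissive_mask(pileup), toy_features)


def _random_instance(seed: int, n_positions: int = 4000):
    rng = np.random.default_rng(seed)
    gene_rows = []
    cursor = 1
    for i in range(30):
        cursor += int(rng.integers(10, 120))
        strand = "+" if rng.random() < 0.5 else "-"
        for cls in ("five_prime_utr", "cds", "intron", "three_prime_utr"):
            length = int(rng.integers(5, 60))
            gene_rows.append(("chr1", cursor, cursor + length - 1, strand, f"g{i}", cls))
            cursor += length
    contig_len = cursor + 200
    genes = pd.DataFrame(gene_rows, columns=["contig", "start", "end", "strand", "gene_id", "feature_class"])
    features = FeatureTable(genes, None, {"chr1": contig_len})

    pos = np.sort(rng.choice(np.arange(1, contig_len + 1), size=n_positions, replace=False))
    refs = rng.choice(list("ACGT"), size=n_positions)
    depth = rng.integers(0, 60, size=n_positions)
    counts = np.zeros((n_positions, 4), dtype=int)
    for i in range(n_positions):
        counts[i] = rng.multinomial(depth[i], rng.dirichlet([8, 0.5, 0.5, 0.5]))
    # put the bulk of reads on the reference base
    ref_idx = np.array(["ACGT".index(r) for r in refs])
    for i in range(n_positions):
        counts[i, 0], counts[i, ref_idx[i]] = counts[i, ref_idx[i]], counts[i, 0]
    pileup = pd.DataFrame({
        "contig": "chr1", "pos": pos, "ref": refs,
        "nA": counts[:, 0], "nC": counts[:, 1], "nG": counts[:, 2], "nT": counts[:, 3],
        "depth": counts.sum(axis=1), "sample_id": "rand",
    })
    all_pos = {("chr1", int(p)) for p in pos}
    masked = {("chr1", int(p)) for p in rng.choice(pos, size=200, replace=False)}
    unassessable = {("chr1", int(p)) for p in rng.choice(pos, size=200, replace=False)}
    mask = SnpMask(
        provenance={k: {"exome"} for k in masked},
        assessable=all_pos - masked - unassessable,
        unassessable=unassessable,
    )
    return pileup, mask, features


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_calls_equal_naive_position_by_position_filter(seed):
    pileup, mask, features = _random_instance(seed)
    calls = call_edit_sites(pileup, mask, features)
    got = set(zip(calls["contig"], calls["pos"].astype(int), calls["change"],
                  calls["variant_reads"].astype(int)))
    expected = naive_edit_calls(pileup, mask.positions, mask.assessable, features, THRESH)
    assert got == expected


def test_call_count_monotone_under_threshold_tightening():
    pileup, mask, features = _random_instance(9)
    baseline = len(call_edit_sites(pileup, mask, features))
    for th in (
        CallThresholds(min_depth=15),
        CallThresholds(min_depth=25),
        CallThresholds(min_variant_reads=5),
        CallThresholds(min_variant_reads=8),
        CallThresholds(min_fraction=0.1, max_fraction=0.9),
    ):
        assert len(call_edit_sites(pileup, mask, features, th)) <= baseline
    # and jointly tightening both axes is monotone along the path
    ns = [len(call_edit_sites(pileup, mask, features, CallThresholds(min_depth=d, min_variant_reads=v)))
          for d, v in ((10, 3), (15, 4), (20, 5), (30, 7))]
    assert ns == sorted(ns, reverse=True)
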