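"""Synthetic editome datasets with known ground truth.

Emulates the study design that motivates this package: four mouse genotypes
(wild type, an ADAR1 heterozygote, a viral-RdRp transgenic whose dsRNA
chronically activates MDA5, and the double heterozygote carrying both
alleles), four animals per genotype, colony-shared germline SNPs, and
genotype-dependent A-to-I editing. Editing appears in RNA evidence as A>G
(or T>C for minus-strand transcripts) because inosine is read as guanosine;
DNA evidence never shows it.

The genotype regime is structured so that the first three genotypes share a
common pool of edited sites plus small private pools, while the double
heterozygote additionally carries a large private pool — sized by default to
yield a 50–65% excess of consensus sites and by far the largest uniquely
edited set. Planted sites are concentrated in intergenic regions and 3'UTRs
and may fall inside repeat elements, mirroring where ADAR substrates
(inverted repeats, retroelement transcripts) live in real genomes.

Coverage is Poisson (truncated at depth >= 1) and sequencing error is a
symmetric substitution to each non-reference base at rate e/3, which keeps
the detection probability of a planted site analytically tractable: the
truth object records, per site and genotype, the closed-form probability
that all animals of the genotype detect it under the default calling
thresholds, and the implied expected consensus-site counts.
"""

from __future__ import annotations

import dataclasses
import json
import math
import os
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from . import io as eio
from .annotate import FeatureTable, GENE_COLUMNS, REPEAT_COLUMNS

GENOTYPES = ("WT", "Adar_het", "RdRp_tg", "DoubleHet")

_BASES = np.frombuffer(b"ACGT", dtype="S1").astype("U1")
_BASE_INDEX = {b: i for i, b in enumerate("ACGT")}

# fixed spawn keys: all randomness flows from one seed; each stream gets a
# stable offset so adding animals never reshuffles existing ones
_STREAM_GENOME = (0,)
_STREAM_TRUTH = (1,)
_STREAM_EXPRESSION = (2,)


def _rng(seed: int, key: tuple[int, ...]) -> np.random.Generator:
    return np.random.Generator(np.random.PCG64(np.random.SeedSequence(entropy=seed, spawn_key=key)))


class SizingError(ValueError):
    """A contig cannot hold its requested gene quota."""


class PlacementError(ValueError):
    """A feature class lacks enough adenosines for its planted-site quota."""


@dataclass
class SimConfig:
    """Study-condition parameters for the synthetic editome.

    Defaults encode the qualitative regime of the modelled study: 4 genotypes
    x 4 animals, editing fractions >= 0.2, RNA depth ~50x, a DoubleHet private
    pool sized for a ~56% consensus-site excess over the other genotypes, and
    ISG expression multipliers placing DoubleHet 4-fold above RdRp_tg.
    """

    contig_lengths: dict[str, int] = field(default_factory=lambda: {"chr1": 60_000, "chr2": 60_000})
    n_genes: int = 120
    exons_per_gene: int = 2
    utr5_len: int = 60
    exon_len: int = 150
    intron_len: int = 120
    utr3_len: int = 200
    #: elements per megabase
    repeat_density: dict[str, float] = field(
        default_factory=lambda: {"SINE": 350.0, "LINE": 170.0, "DNA_transposon": 80.0, "other_retrotransposon": 80.0}
    )
    repeat_lengths: dict[str, int] = field(
        default_factory=lambda: {"SINE": 150, "LINE": 600, "DNA_transposon": 300, "other_retrotransposon": 400}
    )
    animals_per_genotype: int = 4
    n_snps: int = 150
    het_fraction: float = 0.5
    #: sites edited in every genotype
    n_shared_sites: int = 360
    #: sites edited only in one genotype; DoubleHet's pool drives the excess
    private_sites: dict[str, int] = field(
        default_factory=lambda: {"WT": 25, "Adar_het": 25, "RdRp_tg": 25, "DoubleHet": 240}
    )
    edit_fraction_range: tuple[float, float] = (0.2, 0.7)
    placement_weights: dict[str, float] = field(
        default_factory=lambda: {
            "intergenic": 0.50,
            "three_prime_utr": 0.30,
            "cds": 0.08,
            "intron": 0.08,
            "five_prime_utr": 0.04,
        }
    )
    rna_coverage_mean: float = 50.0
    dna_coverage_mean: float = 40.0
    error_rate: float = 0.005
    isg_fraction: float = 0.30
    isg_multipliers: dict[str, float] = field(
        default_factory=lambda: {"WT": 1.0, "Adar_het": 1.5, "RdRp_tg": 4.0, "DoubleHet": 16.0}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in ("n_genes", "exons_per_gene", "utr5_len", "exon_len", "intron_len", "utr3_len",
                     "animals_per_genotype", "n_snps", "n_shared_sites"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.animals_per_genotype < 1:
            raise ValueError("animals_per_genotype must be >= 1")
        if any(length <= 0 for length in self.contig_lengths.values()):
            raise ValueError("contig lengths must be positive")
        if set(self.private_sites) - set(GENOTYPES):
            raise ValueError(f"private_sites keys must be in {GENOTYPES}")
        if any(n < 0 for n in self.private_sites.values()):
            raise ValueError("private site counts must be >= 0")
        lo, hi = self.edit_fraction_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("edit fractions must lie in (0, 1)")
        if not math.isclose(sum(self.placement_weights.values()), 1.0, abs_tol=1e-9):
            raise ValueError("placement weights must sum to 1")
        if not (0.0 <= self.error_rate < 1.0):
            raise ValueError("error_rate must be in [0, 1)")
        if not (0.0 <= self.het_fraction <= 1.0):
            raise ValueError("het_fraction must be in [0, 1]")
        if not (0.0 <= self.isg_fraction <= 1.0):
            raise ValueError("isg_fraction must be in [0, 1]")

    @property
    def gene_span(self) -> int:
        return (
            self.utr5_len
            + self.exons_per_gene * self.exon_len
            + max(self.exons_per_gene - 1, 0) * self.intron_len
            + self.utr3_len
        )

    @property
    def total_sites(self) -> int:
        return self.n_shared_sites + sum(self.private_sites.values())

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["edit_fraction_range"] = list(self.edit_fraction_range)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimConfig":
        d = dict(d)
        if "edit_fraction_range" in d:
            d["edit_fraction_range"] = tuple(d["edit_fraction_range"])
        return cls(**d)


@dataclass
class SimulationTruth:
    """Planted ground truth plus the analytic detection oracle."""

    snps: pd.DataFrame  # contig, pos, ref, alt, zygosity
    edits: pd.DataFrame  # contig, pos, ref, strand, change, feature/repeat/gene, uniqueness, f_*, p_consensus_*
    isg_genes: set[str]
    expected_consensus_sites: dict[str, float]

    def site_keys(self, genotype: str, min_consensus_prob: float = 0.0) -> set[tuple[str, int, str]]:
        """Planted (contig, pos, change) keys edited in `genotype`.

        With ``min_consensus_prob`` > 0 restrict to sites whose closed-form
        probability of passing consensus in all animals is at least that value
        (the "detectable" subset used by recovery tests).
        """
        sub = self.edits[self.edits[f"f_{genotype}"] > 0]
        if min_consensus_prob > 0:
            sub = sub[sub[f"p_consensus_{genotype}"] >= min_consensus_prob]
        return set(zip(sub["contig"], sub["pos"], sub["change"]))

    def snp_positions(self) -> set[tuple[str, int]]:
        return set(zip(self.snps["contig"], self.snps["pos"]))

    def write(self, outdir: str | os.PathLike) -> None:
        outdir = str(outdir)
        self.snps.to_csv(os.path.join(outdir, "truth_snps.tsv"), sep="\t", index=False)
        self.edits.to_csv(os.path.join(outdir, "truth_edits.tsv"), sep="\t", index=False)
        with open(os.path.join(outdir, "truth.json"), "w") as fh:
            json.dump(
                {
                    "isg_genes": sorted(self.isg_genes),
                    "expected_consensus_sites": self.expected_consensus_sites,
                },
                fh,
                indent=2,
                sort_keys=True,
            )


# ---------------------------------------------------------------------------
# detection oracle

def detection_probability(
    f: float,
    depth_mean: float,
    error_rate: float,
    min_depth: int = 10,
    min_variant_reads: int = 3,
    min_fraction: float = 0.05,
    max_fraction: float = 0.95,
    complex_fraction: float | None = 0.05,
) -> float:
    """Probability that one animal's RNA evidence passes the calling thresholds.

    Depth is zero-truncated Poisson(``depth_mean``); given depth d the variant
    read count is Binomial(d, p) with p = f(1-e) + (1-f)e/3 (an edited
    molecule survives as G with probability 1-e; an unedited one is misread as
    G with probability e/3). The call passes when d >= min_depth and the
    variant count k satisfies k >= min_variant_reads and
    min_fraction <= k/d <= max_fraction, and neither of the two remaining
    bases reaches ``complex_fraction`` of the depth (each such count is
    Binomial(d, e/3); the two are treated as independent, an excellent
    approximation at realistic error rates).
    """
    e = error_rate
    p = f * (1.0 - e) + (1.0 - f) * e / 3.0
    d_hi = int(stats.poisson.ppf(1.0 - 1e-12, depth_mean)) + 1
    d = np.arange(max(min_depth, 1), d_hi + 1)
    if d.size == 0:
        return 0.0
    w = stats.poisson.pmf(d, depth_mean) / (1.0 - stats.poisson.pmf(0, depth_mean))
    k_lo = np.maximum(min_variant_reads, np.ceil(min_fraction * d)).astype(int)
    k_hi = np.floor(max_fraction * d).astype(int)
    prob = stats.binom.cdf(k_hi, d, p) - stats.binom.cdf(k_lo - 1, d, p)
    if complex_fraction is not None:
        k_cx = np.ceil(complex_fraction * d).astype(int)
        p_other_ok = stats.binom.cdf(k_cx - 1, d, e / 3.0)
        prob = prob * p_other_ok**2
    return float(np.sum(w * np.clip(prob, 0.0, 1.0)))


def false_call_probability(
    depth_mean: float,
    error_rate: float,
    min_depth: int = 10,
    min_variant_reads: int = 3,
    min_fraction: float = 0.05,
    max_fraction: float = 0.95,
) -> float:
    """Per-position probability of a spurious call at an unedited A/T site."""
    return detection_probability(
        0.0, depth_mean, error_rate, min_depth, min_variant_reads, min_fraction, max_fraction
    )


# ---------------------------------------------------------------------------
# genome

def simulate_genome(config: SimConfig) -> tuple[dict[str, str], FeatureTable]:
    """Random reference sequence plus a tiled gene/repeat annotation.

    Genes are non-overlapping 5'UTR–CDS(/intron)–3'UTR loci on random strands
    (for a minus-strand gene the 3'UTR is leftmost in genome coordinates);
    repeat elements are placed uniformly and may overlap genes, as in real
    genomes.
    """
    rng = _rng(config.seed, _STREAM_GENOME)
    genome: dict[str, str] = {}
    for contig, length in config.contig_lengths.items():
        codes = rng.integers(0, 4, size=length)
        genome[contig] = "".join(_BASES[codes])

    # apportion genes to contigs by length (largest remainder)
    contigs = list(config.contig_lengths)
    lengths = np.array([config.contig_lengths[c] for c in contigs], dtype=float)
    if config.n_genes and contigs:
        exact = config.n_genes * lengths / lengths.sum()
        quotas = np.floor(exact).astype(int)
        for i in np.argsort(-(exact - quotas))[: config.n_genes - quotas.sum()]:
            quotas[i] += 1
    else:
        quotas = np.zeros(len(contigs), dtype=int)

    gene_rows: list[tuple] = []
    gene_counter = 0
    span = config.gene_span
    for contig, quota in zip(contigs, quotas):
        length = config.contig_lengths[contig]
        spare = length - quota * span
        if spare < 0:
            raise SizingError(
                f"contig {contig} (length {length}) too small for {quota} genes of span {span}"
            )
        gaps = rng.multinomial(spare, np.full(quota + 1, 1.0 / (quota + 1))) if quota else []
        cursor = 1
        for g in range(quota):
            cursor += int(gaps[g])
            gene_id = f"gene{gene_counter:04d}"
            gene_counter += 1
            strand = "+" if rng.random() < 0.5 else "-"
            parts = [("five_prime_utr", config.utr5_len)]
            for e in range(config.exons_per_gene):
                parts.append(("cds", config.exon_len))
                if e < config.exons_per_gene - 1:
                    parts.append(("intron", config.intron_len))
            parts.append(("three_prime_utr", config.utr3_len))
            if strand == "-":
                parts = parts[::-1]
            for cls, flen in parts:
                if flen > 0:
                    gene_rows.append((contig, cursor, cursor + flen - 1, strand, gene_id, cls))
                    cursor += flen

    repeat_rows: list[tuple] = []
    for contig in contigs:
        length = config.contig_lengths[contig]
        for cls in sorted(config.repeat_density):
            n = int(round(config.repeat_density[cls] * length / 1e6))
            rlen = min(config.repeat_lengths[cls], length)
            for start in sorted(int(s) for s in rng.integers(1, length - rlen + 2, size=n)):
                repeat_rows.append((contig, start, start + rlen - 1, cls))

    genes = pd.DataFrame(gene_rows, columns=GENE_COLUMNS)
    repeats = pd.DataFrame(repeat_rows, columns=REPEAT_COLUMNS)
    return genome, FeatureTable(genes, repeats, config.contig_lengths)


# ---------------------------------------------------------------------------
# truth planting

def _position_classes(config: SimConfig, genome: Mapping[str, str], features: FeatureTable):
    """Per-contig arrays of feature class and transcript strand per base."""
    class_of: dict[str, np.ndarray] = {}
    strand_of: dict[str, np.ndarray] = {}
    order = {"intron": 1, "cds": 2, "five_prime_utr": 3, "three_prime_utr": 4}
    for contig, length in config.contig_lengths.items():
        class_of[contig] = np.zeros(length, dtype="U16")
        class_of[contig][:] = "intergenic"
        strand_of[contig] = np.full(length, ".", dtype="U1")
    if len(features.genes):
        rows = features.genes.assign(_prec=features.genes["feature_class"].map(order))
        for row in rows.sort_values("_prec").itertuples(index=False):
            class_of[row.contig][row.start - 1 : row.end] = row.feature_class
            strand_of[row.contig][row.start - 1 : row.end] = row.strand
    return class_of, strand_of


def plant_truth(config: SimConfig, genome: Mapping[str, str], features: FeatureTable) -> SimulationTruth:
    """Plant germline SNPs and genotype-structured edit sites; record the oracle.

    Germline SNPs are uniform over the genome and colony-shared. Edit sites
    are drawn per feature class according to ``placement_weights`` (counts
    multinomial over classes), always at an adenosine of the transcribed
    strand, and never at a SNP position. Shared-pool sites carry one editing
    fraction across all genotypes; private-pool sites are edited only in
    their genotype.
    """
    rng = _rng(config.seed, _STREAM_TRUTH)
    class_of, strand_of = _position_classes(config, genome, features)
    contigs = list(config.contig_lengths)
    seq_arr = {c: np.frombuffer(genome[c].encode(), dtype="S1").astype("U1") for c in contigs}

    # SNPs, uniform over concatenated coordinates
    bounds = np.cumsum([0] + [config.contig_lengths[c] for c in contigs])
    total = int(bounds[-1])
    snp_flat = np.sort(rng.choice(total, size=min(config.n_snps, total), replace=False))
    snp_rows = []
    n_het = int(round(config.het_fraction * len(snp_flat)))
    zygosity = np.array(["het"] * n_het + ["hom"] * (len(snp_flat) - n_het))
    rng.shuffle(zygosity)
    snp_positions: set[tuple[str, int]] = set()
    for flat, zyg in zip(snp_flat, zygosity):
        ci = int(np.searchsorted(bounds, flat, side="right")) - 1
        contig, pos0 = contigs[ci], int(flat - bounds[ci])
        ref = seq_arr[contig][pos0]
        alt = "ACGT".replace(ref, "")[rng.integers(0, 3)]
        snp_rows.append((contig, pos0 + 1, ref, alt, zyg))
        snp_positions.add((contig, pos0 + 1))
    snps = pd.DataFrame(snp_rows, columns=["contig", "pos", "ref", "alt", "zygosity"])

    # candidate adenosine pools per feature class (disjoint: genes do not overlap)
    classes = sorted(config.placement_weights)
    weights = np.array([config.placement_weights[c] for c in classes])
    pools: dict[str, list[tuple[str, int]]] = {cls: [] for cls in classes}
    for contig in contigs:
        seq = seq_arr[contig]
        cls_arr = class_of[contig]
        strand = strand_of[contig]
        for cls in classes:
            if cls == "intergenic":
                ok = (cls_arr == "intergenic") & ((seq == "A") | (seq == "T"))
            else:
                ok = (cls_arr == cls) & (
                    ((strand == "+") & (seq == "A")) | ((strand == "-") & (seq == "T"))
                )
            for pos0 in np.flatnonzero(ok):
                key = (contig, int(pos0) + 1)
                if key not in snp_positions:
                    pools[cls].append(key)

    n_total = config.total_sites
    per_class = rng.multinomial(n_total, weights) if n_total else np.zeros(len(classes), dtype=int)
    chosen: list[tuple[str, int]] = []
    for cls, need in zip(classes, per_class):
        pool = pools[cls]
        if need > len(pool):
            raise PlacementError(
                f"feature class {cls}: {need} sites requested but only "
                f"{len(pool)} eligible adenosines available"
            )
        idx = rng.choice(len(pool), size=need, replace=False)
        chosen.extend(pool[int(i)] for i in idx)

    order = rng.permutation(len(chosen))
    chosen = [chosen[int(i)] for i in order]
    labels = ["shared"] * config.n_shared_sites
    for g in GENOTYPES:
        labels.extend([g] * config.private_sites.get(g, 0))

    lo, hi = config.edit_fraction_range
    fractions = rng.uniform(lo, hi, size=len(chosen))
    edit_rows = []
    for (contig, pos), label, f in zip(chosen, labels, fractions):
        ref = seq_arr[contig][pos - 1]
        assignment = features.assign_feature(contig, pos)
        if assignment.feature_class == "intergenic":
            strand = "+" if ref == "A" else "-"  # orientation implied by the edited base
        else:
            strand = strand_of[contig][pos - 1]
        change = "A>G" if ref == "A" else "T>C"
        row = {
            "contig": contig,
            "pos": pos,
            "ref": ref,
            "strand": strand,
            "change": change,
            "feature_class": assignment.feature_class,
            "repeat_class": assignment.repeat_class,
            "gene_id": assignment.gene_id,
            "uniqueness": label,
        }
        for g in GENOTYPES:
            row[f"f_{g}"] = f if (label == "shared" or label == g) else 0.0
        edit_rows.append(row)
    edits = pd.DataFrame(edit_rows)
    if not len(edits):
        edits = pd.DataFrame(
            columns=["contig", "pos", "ref", "strand", "change", "feature_class", "repeat_class",
                     "gene_id", "uniqueness"] + [f"f_{g}" for g in GENOTYPES]
        )

    # analytic consensus oracle: detection prob per animal, to the n-th power
    p_cache: dict[float, float] = {}

    def _p(f: float) -> float:
        if f not in p_cache:
            p_cache[f] = detection_probability(f, config.rna_coverage_mean, config.error_rate)
        return p_cache[f]

    expected: dict[str, float] = {}
    for g in GENOTYPES:
        fcol = edits[f"f_{g}"].to_numpy() if len(edits) else np.array([])
        probs = np.array([_p(float(f)) ** config.animals_per_genotype if f > 0 else 0.0 for f in fcol])
        edits[f"p_consensus_{g}"] = probs
        expected[g] = float(probs.sum())

    gene_ids = sorted(features.gene_ids)
    n_isg = int(round(config.isg_fraction * len(gene_ids)))
    isg = set(rng.choice(gene_ids, size=n_isg, replace=False)) if n_isg else set()
    edits = edits.sort_values(["contig", "pos"], kind="mergesort").reset_index(drop=True)
    return SimulationTruth(snps, edits, isg, expected)


# ---------------------------------------------------------------------------
# pileups

def _truncated_poisson(rng: np.random.Generator, mean: float, size: int) -> np.ndarray:
    d = rng.poisson(mean, size)
    zero = np.flatnonzero(d == 0)
    while zero.size:
        d[zero] = rng.poisson(mean, zero.size)
        zero = zero[d[zero] == 0]
    return d


def _simulate_track(
    rng: np.random.Generator,
    ref_codes: np.ndarray,
    depth_mean: float,
    alt_codes: np.ndarray,
    alt_fracs: np.ndarray,
    error_rate: float,
) -> np.ndarray:
    """Base-count matrix (L x ACGT) for one sample over one contig."""
    length = ref_codes.size
    depth = _truncated_poisson(rng, depth_mean, length)
    alt_mol = np.zeros(length, dtype=np.int64)
    has_alt = alt_fracs > 0
    alt_mol[has_alt] = rng.binomial(depth[has_alt], alt_fracs[has_alt])
    molecules = np.zeros((length, 4), dtype=np.int64)
    np.add.at(molecules, (np.arange(length), ref_codes), depth - alt_mol)
    if has_alt.any():
        np.add.at(molecules, (np.flatnonzero(has_alt), alt_codes[has_alt]), alt_mol[has_alt])
    if error_rate <= 0:
        return molecules
    observed = np.zeros_like(molecules)
    others = {b: [o for o in range(4) if o != b] for b in range(4)}
    third = np.full(3, 1.0 / 3.0)
    for b in range(4):
        n = molecules[:, b]
        err = rng.binomial(n, error_rate)
        observed[:, b] += n - err
        spread = rng.multinomial(err, third)
        for j, o in enumerate(others[b]):
            observed[:, o] += spread[:, j]
    return observed


def _alt_arrays(
    config: SimConfig,
    truth: SimulationTruth,
    contig: str,
    genotype: str | None,
) -> tuple[np.ndarray, np.ndarray]:
    """Alternate-base code and molecular fraction per position.

    With ``genotype`` None only germline SNPs contribute (DNA evidence);
    otherwise planted edits of that genotype are added on top of SNPs.
    """
    length = config.contig_lengths[contig]
    alt_codes = np.zeros(length, dtype=np.int64)
    alt_fracs = np.zeros(length, dtype=float)
    snps = truth.snps[truth.snps["contig"] == contig] if len(truth.snps) else truth.snps
    if len(snps):
        pos0 = snps["pos"].to_numpy(dtype=np.int64) - 1
        alt_codes[pos0] = [_BASE_INDEX[a] for a in snps["alt"]]
        alt_fracs[pos0] = np.where(snps["zygosity"].to_numpy() == "hom", 1.0, 0.5)
    if genotype is not None and len(truth.edits):
        edits = truth.edits[(truth.edits["contig"] == contig) & (truth.edits[f"f_{genotype}"] > 0)]
        if len(edits):
            epos0 = edits["pos"].to_numpy(dtype=np.int64) - 1
            # inosine reads as G on the edited strand: A>G on plus, T>C on minus
            alt_codes[epos0] = np.where(edits["change"].to_numpy() == "A>G", _BASE_INDEX["G"], _BASE_INDEX["C"])
            alt_fracs[epos0] = edits[f"f_{genotype}"].to_numpy()
    return alt_codes, alt_fracs


def _track_frame(contig: str, ref_chars: np.ndarray, counts: np.ndarray, sample_id: str) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "contig": contig,
            "pos": np.arange(1, ref_chars.size + 1),
            "ref": ref_chars,
            "nA": counts[:, 0],
            "nC": counts[:, 1],
            "nG": counts[:, 2],
            "nT": counts[:, 3],
            "depth": counts.sum(axis=1),
            "sample_id": sample_id,
        }
    )


def rna_sample_ids(config: SimConfig) -> dict[str, list[str]]:
    """Deterministic per-genotype RNA sample identifiers."""
    return {g: [f"{g}_{a + 1}" for a in range(config.animals_per_genotype)] for g in GENOTYPES}


DNA_SAMPLE_ID = "exome_pool"


def simulate_pileups(
    genome: Mapping[str, str],
    truth: SimulationTruth,
    config: SimConfig,
) -> tuple[dict[str, pd.DataFrame], dict[str, pd.DataFrame]]:
    """Per-animal RNA pileups and a pooled colony DNA (exome-style) pileup.

    RNA counts reflect germline zygosity plus the animal's genotype editing;
    DNA counts reflect zygosity only. Each output frame is sorted by
    (contig, pos) with contigs in configuration order.
    """
    contigs = list(config.contig_lengths)
    ref_codes = {}
    ref_chars = {}
    for c in contigs:
        chars = np.frombuffer(genome[c].encode(), dtype="S1").astype("U1")
        ref_chars[c] = chars
        # ACGT is alphabetically sorted, so searchsorted is a direct code lookup
        ref_codes[c] = np.searchsorted(np.array(list("ACGT")), chars)

    rna: dict[str, pd.DataFrame] = {}
    for gi, genotype in enumerate(GENOTYPES):
        for ai in range(config.animals_per_genotype):
            sample_id = f"{genotype}_{ai + 1}"
            rng = _rng(config.seed, (3, gi, ai))
            frames = []
            for contig in contigs:
                alt_codes, alt_fracs = _alt_arrays(config, truth, contig, genotype)
                counts = _simulate_track(
                    rng, ref_codes[contig], config.rna_coverage_mean, alt_codes, alt_fracs, config.error_rate
                )
                frames.append(_track_frame(contig, ref_chars[contig], counts, sample_id))
            rna[sample_id] = pd.concat(frames, ignore_index=True)

    rng = _rng(config.seed, (4,))
    frames = []
    for contig in contigs:
        alt_codes, alt_fracs = _alt_arrays(config, truth, contig, None)
        counts = _simulate_track(
            rng, ref_codes[contig], config.dna_coverage_mean, alt_codes, alt_fracs, config.error_rate
        )
        frames.append(_track_frame(contig, ref_chars[contig], counts, DNA_SAMPLE_ID))
    dna = {DNA_SAMPLE_ID: pd.concat(frames, ignore_index=True)}
    return rna, dna


# ---------------------------------------------------------------------------
# expression

def simulate_expression(features: FeatureTable, truth: SimulationTruth, config: SimConfig) -> pd.DataFrame:
    """Gene-by-sample count matrix with genotype-dependent ISG induction.

    Baseline means are log-normal across genes; ISG genes are scaled by the
    genotype's multiplier (DoubleHet 3–5x RdRp_tg by default); counts are
    Poisson with mild log-normal extra noise, so group separation at four
    animals per genotype is strong for high-fold-change genes and imperfect
    for weakly expressed ones.
    """
    rng = _rng(config.seed, _STREAM_EXPRESSION)
    gene_ids = sorted(features.gene_ids)
    base = rng.lognormal(mean=np.log(8.0), sigma=1.2, size=len(gene_ids))
    is_isg = np.array([g in truth.isg_genes for g in gene_ids])
    data = {}
    for genotype in GENOTYPES:
        mult = config.isg_multipliers.get(genotype, 1.0)
        mu = np.where(is_isg, base * mult, base)
        for ai in range(config.animals_per_genotype):
            noise = rng.lognormal(0.0, 0.2, size=len(gene_ids))
            data[f"{genotype}_{ai + 1}"] = rng.poisson(mu * noise)
    return pd.DataFrame(data, index=pd.Index(gene_ids, name="gene_id"))


# ---------------------------------------------------------------------------
# dataset writer

def write_dataset(config: SimConfig, outdir: str | os.PathLike) -> dict[str, object]:
    """Simulate everything and write the standard-format dataset.

    Produces genome.fa, genes.bed, repeats.bed, truth files, per-sample
    pileup TSVs under pileups/, isg_list.txt, expression.tsv and
    sample_sheet.tsv; returns a manifest of paths plus in-memory objects.
    """
    outdir = str(outdir)
    os.makedirs(os.path.join(outdir, "pileups"), exist_ok=True)
    genome, features = simulate_genome(config)
    truth = plant_truth(config, genome, features)
    rna, dna = simulate_pileups(genome, truth, config)
    expression = simulate_expression(features, truth, config)

    eio.write_fasta(genome, os.path.join(outdir, "genome.fa"))
    features.to_bed(os.path.join(outdir, "genes.bed"), os.path.join(outdir, "repeats.bed"))
    truth.write(outdir)
    paths: dict[str, object] = {
        "genome": os.path.join(outdir, "genome.fa"),
        "genes_bed": os.path.join(outdir, "genes.bed"),
        "repeats_bed": os.path.join(outdir, "repeats.bed"),
        "isg_list": os.path.join(outdir, "isg_list.txt"),
        "expression": os.path.join(outdir, "expression.tsv"),
        "sample_sheet": os.path.join(outdir, "sample_sheet.tsv"),
        "rna_pileups": {},
        "dna_pileups": {},
    }
    sheet_rows = []
    for sample_id, df in rna.items():
        path = os.path.join(outdir, "pileups", f"rna_{sample_id}.tsv")
        eio.write_pileup(df, path)
        paths["rna_pileups"][sample_id] = path
        genotype, animal = sample_id.rsplit("_", 1)
        sheet_rows.append({"sample_id": sample_id, "animal": animal, "genotype": genotype, "pileup": path})
    for sample_id, df in dna.items():
        path = os.path.join(outdir, "pileups", f"dna_{sample_id}.tsv")
        eio.write_pileup(df, path)
        paths["dna_pileups"][sample_id] = path
    pd.DataFrame(sheet_rows).to_csv(paths["sample_sheet"], sep="\t", index=False)
    with open(paths["isg_list"], "w") as fh:
        for g in sorted(truth.isg_genes):
            fh.write(g + "\n")
    expression.to_csv(paths["expression"], sep="\t")
    paths.update({"config": config, "genome_seq": genome, "features": features, "truth": truth})
    return paths
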