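"""End-to-end editome pipeline: mask -> call -> consensus -> annotate -> compare.

A declarative :class:`PipelineConfig` names every input (genome FASTA,
feature/repeat BED, per-sample RNA pileups, DNA exome pileups, optional ISG
list / DEG table / known-variant list) and all thresholds. ``run_pipeline``
validates inputs up front, runs every stage, writes standard-format
artifacts plus a provenance manifest, and returns a
:class:`ComparisonReport`. Reruns with an identical config are
byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from . import io as eio
from .annotate import FeatureTable, distribution_summary
from .calling import (
    CallThresholds,
    SnpThresholds,
    call_edit_sites,
    call_exome_snps,
    merge_known_variants,
)
from .consensus import (
    GenotypeEditome,
    percent_change,
    unique_sets,
    venn_partition,
    venn_table,
)
from .isg import deg_isg_summary, isg_edit_proportion, minimal_deg_call
from .simulate import GENOTYPES

logger = logging.getLogger("editome")


class ValidationError(ValueError):
    pass


@dataclass
class SampleEntry:
    sample_id: str
    animal: str
    genotype: str
    pileup: str


@dataclass
class PipelineConfig:
    genome_fasta: str = ""
    genes_bed: str = ""
    repeats_bed: str | None = None
    samples: list[SampleEntry] = field(default_factory=list)
    dna_pileups: list[str] = field(default_factory=list)
    isg_list: str | None = None
    deg_table: str | None = None
    expression: str | None = None
    known_variants: str | None = None
    genotype_labels: tuple[str, ...] = GENOTYPES
    baseline: str = "WT"
    snp_thresholds: SnpThresholds = field(default_factory=SnpThresholds)
    call_thresholds: CallThresholds = field(default_factory=CallThresholds)
    #: consensus requirement; None means every animal of the genotype
    n_required: int | None = None
    deg_lfc_cut: float = 1.0
    #: adjusted-p cutoff used when summarizing the built-in rank-test caller;
    #: with 4 animals per group the exact test cannot reach BH-adjusted 0.05
    deg_p_cut: float = 0.1
    seed: int = 0
    outdir: str = "editome_out"

    # -- serialization (lossless round trip) --------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["genotype_labels"] = list(self.genotype_labels)
        return d

    def to_json(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        d["samples"] = [SampleEntry(**s) for s in d.get("samples", [])]
        d["genotype_labels"] = tuple(d.get("genotype_labels", GENOTYPES))
        d["snp_thresholds"] = SnpThresholds(**d.get("snp_thresholds", {}))
        d["call_thresholds"] = CallThresholds(**d.get("call_thresholds", {}))
        return cls(**d)

    @classmethod
    def from_json(cls, path: str | os.PathLike) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()


@dataclass
class ComparisonReport:
    """Cross-genotype comparison: counts, Venn cells, unique sets, ISG stats."""

    genotype_counts: dict
    feature_summary: pd.DataFrame
    venn_genes: dict
    venn_sites: dict
    unique_genes: dict
    unique_sites: dict
    site_percent_change: dict
    gene_percent_change: dict
    isg: dict
    deg_summary: pd.DataFrame

    def to_dict(self) -> dict:
        return {
            "genotype_counts": self.genotype_counts,
            "feature_summary": self.feature_summary.to_dict(orient="records"),
            "venn_genes": {k: len(v) for k, v in _named_cells(self.venn_genes).items()},
            "venn_sites": {k: len(v) for k, v in _named_cells(self.venn_sites).items()},
            "unique_genes": {g: sorted(v) for g, v in self.unique_genes.items()},
            "unique_sites": {g: sorted(map(_site_str, v)) for g, v in self.unique_sites.items()},
            "site_percent_change": self.site_percent_change,
            "gene_percent_change": self.gene_percent_change,
            "isg": self.isg,
            "deg_summary": self.deg_summary.to_dict(orient="records"),
        }


def _site_str(key) -> str:
    return f"{key[0]}:{key[1]}:{key[2]}"


def _named_cells(cells: dict) -> dict:
    order = {g: i for i, g in enumerate(GENOTYPES)}
    return {
        "&".join(sorted(k, key=lambda g: order.get(g, 99))): v
        for k, v in sorted(cells.items(), key=lambda kv: (len(kv[0]), sorted(kv[0])))
    }


# ---------------------------------------------------------------------------
# validation

def validate_inputs(config: PipelineConfig) -> list[dict]:
    """Structured issue list; never raises, never mutates inputs."""
    issues: list[dict] = []

    def issue(kind: str, path: str | None, message: str) -> None:
        issues.append({"kind": kind, "path": path, "message": message})

    if not config.samples:
        issue("sample_sheet", None, "no samples declared")
    seen = set()
    for s in config.samples:
        if s.sample_id in seen:
            issue("sample_sheet", None, f"duplicate sample id {s.sample_id!r}")
        seen.add(s.sample_id)
        if s.genotype not in config.genotype_labels:
            issue("sample_sheet", None, f"sample {s.sample_id!r}: genotype {s.genotype!r} not in declared labels")
        if not s.pileup:
            issue("sample_sheet", None, f"sample {s.sample_id!r}: no pileup path")
        elif not os.path.exists(s.pileup):
            issue("missing_file", s.pileup, "RNA pileup not found")
        else:
            _check_pileup_file(s.pileup, issue)
    for path in config.dna_pileups:
        if not os.path.exists(path):
            issue("missing_file", path, "DNA pileup not found")
        else:
            _check_pileup_file(path, issue)
    if not config.dna_pileups:
        issue("sample_sheet", None, "no DNA pileups declared; germline masking impossible")

    if not config.genome_fasta or not os.path.exists(config.genome_fasta):
        issue("missing_file", config.genome_fasta or None, "genome FASTA not found")
    else:
        try:
            seqs = eio.read_fasta(config.genome_fasta)
            with open(config.genome_fasta) as fh:
                n_headers = sum(1 for line in fh if line.startswith(">"))
            if not seqs or len(seqs) != n_headers or any(len(s) == 0 for s in seqs.values()):
                issue("malformed", config.genome_fasta, "FASTA truncated or has empty records")
        except Exception as exc:  # pyfaidx raises several types on malformed input
            issue("malformed", config.genome_fasta, f"FASTA not well-formed: {exc}")
    for path, required in ((config.genes_bed, True), (config.repeats_bed, False)):
        if path is None and not required:
            continue
        if not path or not os.path.exists(path):
            issue("missing_file", path or None, "feature BED not found")
        else:
            try:
                eio.read_bed(path)
            except Exception as exc:
                issue("malformed", path, f"BED not well-formed: {exc}")
    for path in (config.isg_list, config.deg_table, config.expression, config.known_variants):
        if path and not os.path.exists(path):
            issue("missing_file", path, "optional input not found")
    return issues


def _check_pileup_file(path: str, issue) -> None:
    try:
        df = eio.read_pileup(path)
        eio.check_pileup_sorted(df, name=path)
    except eio.OrderingError as exc:
        issue("unsorted", path, str(exc))
    except Exception as exc:
        issue("malformed", path, f"pileup not readable: {exc}")


# ---------------------------------------------------------------------------
# run

def run_pipeline(config: PipelineConfig) -> ComparisonReport:
    """Execute every stage and write artifacts under ``config.outdir``.

    Raises :class:`ValidationError` (before any computation or output) if
    ``validate_inputs`` finds problems.
    """
    issues = validate_inputs(config)
    if issues:
        raise ValidationError(f"{len(issues)} input problem(s): " + "; ".join(i["message"] for i in issues[:5]))

    outdir = config.outdir
    os.makedirs(os.path.join(outdir, "calls"), exist_ok=True)
    os.makedirs(os.path.join(outdir, "consensus"), exist_ok=True)

    genome = eio.read_fasta(config.genome_fasta)
    contig_lengths = {c: len(s) for c, s in genome.items()}
    features = FeatureTable.from_bed(config.genes_bed, config.repeats_bed, contig_lengths)
    logger.info("loaded genome (%d contigs) and features (%d gene rows, %d repeats)",
                len(genome), len(features.genes), len(features.repeats))

    dna = [eio.read_pileup(p) for p in config.dna_pileups]
    mask = call_exome_snps(dna, config.snp_thresholds)
    if config.known_variants:
        if config.known_variants.endswith(".vcf"):
            known = [(c, p) for c, p, _ in eio.read_mask_vcf(config.known_variants)]
        else:
            known = eio.read_position_list(config.known_variants)
        mask = merge_known_variants(mask, known)
    logger.info("germline mask: %d positions (%d assessable)", len(mask), len(mask.assessable))
    eio.write_mask_vcf(
        sorted((c, p, "N", "N", ",".join(sorted(src))) for (c, p), src in mask.provenance.items()),
        os.path.join(outdir, "snp_mask.vcf"),
        contig_lengths,
    )

    by_genotype: dict[str, dict[str, pd.DataFrame]] = {}
    for entry in config.samples:
        pileup = eio.read_pileup(entry.pileup)
        calls = call_edit_sites(
            pileup, mask, features, config.call_thresholds,
            genome=genome, animal_id=entry.animal, genotype=entry.genotype,
        )
        logger.info("sample %s: %d pileup records -> %d calls", entry.sample_id, len(pileup), len(calls))
        eio.write_calls_vcf(calls, os.path.join(outdir, "calls", f"{entry.sample_id}.vcf"), contig_lengths)
        calls.to_csv(os.path.join(outdir, "calls", f"{entry.sample_id}.tsv"), sep="\t", index=False)
        by_genotype.setdefault(entry.genotype, {})[entry.sample_id] = calls

    editomes: dict[str, GenotypeEditome] = {}
    for genotype in config.genotype_labels:
        if genotype not in by_genotype:
            continue
        ed = GenotypeEditome.build(genotype, by_genotype[genotype], features, config.n_required)
        editomes[genotype] = ed
        logger.info("genotype %s: %d consensus sites, %d consensus genes",
                    genotype, len(ed.consensus_sites), len(ed.consensus_genes))

    # annotation + per-genotype summary over consensus sites
    annotated_frames = []
    for genotype, ed in editomes.items():
        if ed.consensus_sites:
            sites = pd.DataFrame(sorted(ed.consensus_sites), columns=["contig", "pos", "change"])
            ann = features.assign_many(sites)
        else:
            ann = pd.DataFrame(columns=["contig", "pos", "change", "feature_class", "gene_id", "repeat_class"])
        ann["genotype"] = genotype
        ann.to_csv(os.path.join(outdir, "consensus", f"{genotype}_sites.tsv"), sep="\t", index=False)
        with open(os.path.join(outdir, "consensus", f"{genotype}_genes.tsv"), "w") as fh:
            fh.write("gene_id\n")
            for g in sorted(ed.consensus_genes):
                fh.write(g + "\n")
        annotated_frames.append(ann)
    annotated = pd.concat(annotated_frames, ignore_index=True) if annotated_frames else pd.DataFrame()
    summary = distribution_summary(annotated) if len(annotated) else distribution_summary(
        pd.DataFrame(columns=["feature_class", "repeat_class", "gene_id", "genotype"])
    )
    summary.to_csv(os.path.join(outdir, "feature_summary.tsv"), sep="\t", index=False)

    gene_cells = venn_partition({g: ed.consensus_genes for g, ed in editomes.items()})
    site_cells = venn_partition({g: ed.consensus_sites for g, ed in editomes.items()})
    uniq_genes = unique_sets(gene_cells)
    uniq_sites = unique_sets(site_cells)
    venn_table(gene_cells, list(editomes)).to_csv(os.path.join(outdir, "venn_genes.tsv"), sep="\t", index=False)
    venn_table(site_cells, list(editomes)).to_csv(os.path.join(outdir, "venn_sites.tsv"), sep="\t", index=False)

    counts = {g: {"n_genes": len(ed.consensus_genes), "n_sites": len(ed.consensus_sites)} for g, ed in editomes.items()}
    site_pc = gene_pc = {}
    if config.baseline in editomes and counts[config.baseline]["n_sites"] > 0:
        site_pc = percent_change({g: c["n_sites"] for g, c in counts.items()}, config.baseline)
    if config.baseline in editomes and counts[config.baseline]["n_genes"] > 0:
        gene_pc = percent_change({g: c["n_genes"] for g, c in counts.items()}, config.baseline)

    # ISG statistics
    isg_results: dict[str, dict] = {}
    deg_summary = pd.DataFrame(columns=["contrast", "direction", "n_deg", "n_deg_isg", "isg_fraction"])
    if config.isg_list:
        isgs = eio.read_gene_list(config.isg_list)
        site_genes = {}
        if len(annotated):
            for row in annotated.itertuples(index=False):
                if row.gene_id:
                    site_genes[(row.contig, int(row.pos), row.change)] = [row.gene_id]
        for genotype, ed in editomes.items():
            try:
                isg_results[genotype] = isg_edit_proportion(
                    uniq_sites.get(genotype, set()), ed.consensus_sites, site_genes, isgs
                )
            except ValueError as exc:
                isg_results[genotype] = {"error": str(exc)}
        deg = None
        if config.deg_table:
            deg = pd.read_csv(config.deg_table, sep="\t")
        elif config.expression:
            counts_mat = pd.read_csv(config.expression, sep="\t", index_col=0)
            groups = {}
            for entry in config.samples:
                groups.setdefault(entry.genotype, []).append(entry.sample_id)
            groups = {g: s for g, s in groups.items() if all(x in counts_mat.columns for x in s)}
            contrasts = [(g, config.baseline) for g in editomes if g != config.baseline and g in groups]
            if config.baseline in groups and contrasts:
                deg = minimal_deg_call(counts_mat, groups, contrasts)
        if deg is not None and len(deg):
            deg_summary = deg_isg_summary(deg, isgs, config.deg_lfc_cut, config.deg_p_cut)
            deg.to_csv(os.path.join(outdir, "deg_table.tsv"), sep="\t", index=False)
        deg_summary.to_csv(os.path.join(outdir, "deg_isg_summary.tsv"), sep="\t", index=False)

    report = ComparisonReport(
        genotype_counts=counts,
        feature_summary=summary,
        venn_genes=gene_cells,
        venn_sites=site_cells,
        unique_genes=uniq_genes,
        unique_sites=uniq_sites,
        site_percent_change=site_pc,
        gene_percent_change=gene_pc,
        isg=isg_results,
        deg_summary=deg_summary,
    )
    with open(os.path.join(outdir, "report.json"), "w") as fh:
        json.dump(report.to_dict(), fh, indent=2, sort_keys=True)

    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "editome_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "n_samples": len(config.samples),
        "mask_positions": len(mask),
        "genotype_counts": counts,
    }
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return report
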