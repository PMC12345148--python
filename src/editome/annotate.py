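"""Genomic feature and repeat-class annotation of edited sites.

A :class:`FeatureTable` holds two interval layers in 1-based inclusive
coordinates: gene features (5'UTR / CDS / intron / 3'UTR, with gene id and
strand) and repeat elements (SINE / LINE / DNA transposon / other
retrotransposon). Each site receives exactly one feature class, chosen by
fixed precedence 3'UTR > 5'UTR > CDS > intron, falling back to intergenic;
repeat class is assigned independently by overlap, so a site can be e.g.
intron + SINE. The 3'UTR-first precedence reflects that UTR-annotated bases
are reported as UTR rather than generic exon.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd
from intervaltree import IntervalTree

from . import io as eio

FEATURE_CLASSES = ("three_prime_utr", "five_prime_utr", "cds", "intron", "intergenic")
GENE_FEATURE_CLASSES = ("three_prime_utr", "five_prime_utr", "cds", "intron")
REPEAT_CLASSES = ("SINE", "LINE", "DNA_transposon", "other_retrotransposon")

#: lower value wins when a site overlaps several gene features
_PRECEDENCE = {cls: i for i, cls in enumerate(GENE_FEATURE_CLASSES)}

GENE_COLUMNS = ["contig", "start", "end", "strand", "gene_id", "feature_class"]
REPEAT_COLUMNS = ["contig", "start", "end", "repeat_class"]


class CoordinateError(ValueError):
    """A position falls outside its contig."""


@dataclass(frozen=True)
class FeatureAssignment:
    """Single-site annotation: one feature class, optional repeat class and gene."""

    feature_class: str
    gene_id: str | None
    repeat_class: str | None


class FeatureTable:
    """Interval map of gene features and repeat elements.

    Parameters
    ----------
    genes
        DataFrame with columns contig, start, end, strand, gene_id,
        feature_class (1-based inclusive; feature_class in
        ``GENE_FEATURE_CLASSES``).
    repeats
        DataFrame with columns contig, start, end, repeat_class.
    contig_lengths
        Optional bounds used to validate intervals and site coordinates.
    """

    def __init__(
        self,
        genes: pd.DataFrame,
        repeats: pd.DataFrame | None = None,
        contig_lengths: Mapping[str, int] | None = None,
    ):
        self.genes = genes.reset_index(drop=True) if len(genes) else pd.DataFrame(columns=GENE_COLUMNS)
        if repeats is None or not len(repeats):
            repeats = pd.DataFrame(columns=REPEAT_COLUMNS)
        self.repeats = repeats.reset_index(drop=True)
        self.contig_lengths = dict(contig_lengths) if contig_lengths else None
        self._validate()
        self._feature_trees: dict[str, IntervalTree] = {}
        self._span_trees: dict[str, IntervalTree] = {}
        self._repeat_trees: dict[str, IntervalTree] = {}
        self._build_trees()

    # -- construction -------------------------------------------------------

    def _validate(self) -> None:
        bad = set(self.genes["feature_class"]) - set(GENE_FEATURE_CLASSES) if len(self.genes) else set()
        if bad:
            raise ValueError(f"unknown gene feature classes: {sorted(bad)}")
        bad = set(self.repeats["repeat_class"]) - set(REPEAT_CLASSES) if len(self.repeats) else set()
        if bad:
            raise ValueError(f"unknown repeat classes: {sorted(bad)}")
        if self.contig_lengths is not None:
            for df, what in ((self.genes, "gene feature"), (self.repeats, "repeat")):
                for row in df.itertuples(index=False):
                    length = self.contig_lengths.get(row.contig)
                    if length is None or row.start < 1 or row.end > length:
                        raise CoordinateError(
                            f"{what} interval {row.contig}:{row.start}-{row.end} outside contig bounds"
                        )

    def _build_trees(self) -> None:
        for row in self.genes.itertuples(index=False):
            self._feature_trees.setdefault(row.contig, IntervalTree()).addi(
                row.start, row.end + 1, (row.feature_class, row.gene_id, row.strand)
            )
        if len(self.genes):
            spans = (
                self.genes.groupby("gene_id", sort=True)
                .agg(contig=("contig", "first"), start=("start", "min"), end=("end", "max"), strand=("strand", "first"))
                .reset_index()
            )
        else:
            spans = pd.DataFrame(columns=["gene_id", "contig", "start", "end", "strand"])
        self._gene_spans = spans
        for row in spans.itertuples(index=False):
            self._span_trees.setdefault(row.contig, IntervalTree()).addi(
                row.start, row.end + 1, (row.gene_id, row.strand)
            )
        for row in self.repeats.itertuples(index=False):
            self._repeat_trees.setdefault(row.contig, IntervalTree()).addi(
                row.start, row.end + 1, row.repeat_class
            )

    @classmethod
    def from_bed(
        cls,
        genes_bed: str,
        repeats_bed: str | None = None,
        contig_lengths: Mapping[str, int] | None = None,
    ) -> "FeatureTable":
        """Load from the interchange BED layout.

        Gene BED names are ``gene_id|feature_class`` (column 6 = strand);
        repeat BED names are the repeat class.
        """
        gdf = eio.read_bed(genes_bed)
        if len(gdf):
            split = gdf["name"].str.split(eio.BED_FEATURE_SEP, n=1, expand=True)
            genes = pd.DataFrame(
                {
                    "contig": gdf["contig"],
                    "start": gdf["start"],
                    "end": gdf["end"],
                    "strand": gdf["strand"],
                    "gene_id": split[0],
                    "feature_class": split[1],
                }
            )
        else:
            genes = pd.DataFrame(columns=GENE_COLUMNS)
        repeats = None
        if repeats_bed is not None:
            rdf = eio.read_bed(repeats_bed)
            repeats = pd.DataFrame(
                {"contig": rdf["contig"], "start": rdf["start"], "end": rdf["end"], "repeat_class": rdf["name"]}
            )
        return cls(genes, repeats, contig_lengths)

    def to_bed(self, genes_bed: str, repeats_bed: str | None = None) -> None:
        gdf = pd.DataFrame(
            {
                "contig": self.genes["contig"],
                "start": self.genes["start"],
                "end": self.genes["end"],
                "name": self.genes["gene_id"] + eio.BED_FEATURE_SEP + self.genes["feature_class"],
                "strand": self.genes["strand"],
            }
        )
        eio.write_bed(gdf, genes_bed)
        if repeats_bed is not None:
            rdf = pd.DataFrame(
                {
                    "contig": self.repeats["contig"],
                    "start": self.repeats["start"],
                    "end": self.repeats["end"],
                    "name": self.repeats["repeat_class"],
                    "strand": ".",
                }
            )
            eio.write_bed(rdf, repeats_bed)

    # -- queries ------------------------------------------------------------

    @property
    def gene_ids(self) -> set[str]:
        return set(self._gene_spans["gene_id"])

    @property
    def gene_spans(self) -> pd.DataFrame:
        """Full gene intervals (UTRs + exons + introns), one row per gene."""
        return self._gene_spans

    def genes_at(self, contig: str, pos: int) -> list[tuple[str, str]]:
        """(gene_id, strand) of every gene whose full span contains pos."""
        tree = self._span_trees.get(contig)
        if tree is None:
            return []
        return sorted(iv.data for iv in tree.at(pos))

    def _check_bounds(self, contig: str, pos: int) -> None:
        if self.contig_lengths is not None:
            length = self.contig_lengths.get(contig)
            if length is None or pos < 1 or pos > length:
                raise CoordinateError(f"site {contig}:{pos} outside contig bounds")

    def assign_feature(self, contig: str, pos: int) -> FeatureAssignment:
        """Classify one site by precedence; repeats assigned independently."""
        self._check_bounds(contig, pos)
        feature_class, gene_id = "intergenic", None
        tree = self._feature_trees.get(contig)
        if tree is not None:
            hits = [iv.data for iv in tree.at(pos)]
            if hits:
                # precedence, then gene id for a deterministic tie-break
                cls, gid, _ = min(hits, key=lambda d: (_PRECEDENCE[d[0]], d[1]))
                feature_class, gene_id = cls, gid
        repeat_class = None
        rtree = self._repeat_trees.get(contig)
        if rtree is not None:
            rhits = [(iv.end - iv.begin, iv.data) for iv in rtree.at(pos)]
            if rhits:
                repeat_class = min(rhits)[1]  # smallest interval, then alphabetical
        return FeatureAssignment(feature_class, gene_id, repeat_class)

    def assign_many(self, sites: pd.DataFrame) -> pd.DataFrame:
        """Vector version of :meth:`assign_feature` for a contig/pos frame."""
        assignments = [self.assign_feature(c, p) for c, p in zip(sites["contig"], sites["pos"])]
        out = sites.copy()
        out["feature_class"] = [a.feature_class for a in assignments]
        out["gene_id"] = [a.gene_id for a in assignments]
        out["repeat_class"] = [a.repeat_class for a in assignments]
        return out


def distribution_summary(assignments: pd.DataFrame, by: str = "genotype") -> pd.DataFrame:
    """Per-genotype site counts and proportions per feature class and repeat class.

    ``assignments`` needs columns ``feature_class``, ``repeat_class`` (may be
    None), optional ``gene_id``, and the grouping column. Returns one row per
    group with total sites, total edited genes (distinct non-null gene ids),
    per-class counts ``n_<class>`` and proportions ``p_<class>`` (summing to 1
    over feature classes), and repeat counts ``n_repeat_<class>``.
    """
    rows = []
    groups = assignments.groupby(by, sort=True) if len(assignments) else []
    for label, sub in groups:
        n = len(sub)
        row: dict[str, object] = {by: label, "n_sites": n}
        row["n_genes"] = int(sub["gene_id"].dropna().nunique()) if "gene_id" in sub else 0
        fcounts = sub["feature_class"].value_counts()
        for cls in FEATURE_CLASSES:
            cnt = int(fcounts.get(cls, 0))
            row[f"n_{cls}"] = cnt
            row[f"p_{cls}"] = cnt / n if n else 0.0
        rcounts = sub["repeat_class"].value_counts()
        for cls in REPEAT_CLASSES:
            row[f"n_repeat_{cls}"] = int(rcounts.get(cls, 0))
        rows.append(row)
    if not rows:
        row = {by: None, "n_sites": 0, "n_genes": 0}
        for cls in FEATURE_CLASSES:
            row[f"n_{cls}"] = 0
            row[f"p_{cls}"] = 0.0
        for cls in REPEAT_CLASSES:
            row[f"n_repeat_{cls}"] = 0
        rows.append(row)
    return pd.DataFrame(rows)
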