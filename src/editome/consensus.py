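"""Replicate-consensus editome sets and cross-genotype comparison.

The consensus rules follow the replicate logic of the study design: a SITE
(identified by contig, position and change, so opposite-orientation events
at one coordinate are distinct) counts for a genotype only when the
identical site is called in every animal of that genotype; a GENE counts
when every animal has at least one passing call anywhere within the gene's
full span — the per-animal sites need not coincide, so the consensus gene
set is not simply the genes of the consensus sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Hashable, Iterable, Mapping

import pandas as pd

from .annotate import FeatureTable

SiteKey = tuple[str, int, str]  # (contig, pos, change)


class ParameterError(ValueError):
    pass


class ConsistencyError(ValueError):
    """Calls reference a gene id absent from the feature table."""


def site_keys(calls: pd.DataFrame) -> set[SiteKey]:
    """(contig, pos, change) keys of a per-animal call frame."""
    return set(zip(calls["contig"], calls["pos"].astype(int), calls["change"]))


def gene_keys(calls: pd.DataFrame, features: FeatureTable | None = None) -> set[str]:
    """Gene ids credited by a per-animal call frame (a call may credit several)."""
    genes: set[str] = set()
    for entry in calls["genes"]:
        if entry:
            genes.update(entry.split(","))
    if features is not None:
        unknown = genes - features.gene_ids
        if unknown:
            raise ConsistencyError(f"call gene ids absent from feature table: {sorted(unknown)[:5]}")
    return genes


def consensus_sites(
    per_animal: Mapping[str, pd.DataFrame | set],
    n_required: int | None = None,
) -> set[SiteKey]:
    """Sites called in at least ``n_required`` animals (default: all of them).

    The default all-animal rule is the strict replicate-consensus criterion;
    the k-of-n generalization is provided for sensitivity analyses.
    """
    if not per_animal:
        raise ParameterError("need at least one animal")
    n_animals = len(per_animal)
    if n_required is None:
        n_required = n_animals
    if not (1 <= n_required <= n_animals):
        raise ParameterError(f"n_required={n_required} outside [1, {n_animals}]")
    tallies: dict[SiteKey, int] = {}
    for calls in per_animal.values():
        keys = calls if isinstance(calls, (set, frozenset)) else site_keys(calls)
        for key in keys:
            tallies[key] = tallies.get(key, 0) + 1
    return {key for key, n in tallies.items() if n >= n_required}


def consensus_genes(
    per_animal: Mapping[str, pd.DataFrame],
    features: FeatureTable,
    n_required: int | None = None,
) -> set[str]:
    """Genes with >= 1 passing call (any position in the full span) per animal."""
    if not per_animal:
        raise ParameterError("need at least one animal")
    n_animals = len(per_animal)
    if n_required is None:
        n_required = n_animals
    if not (1 <= n_required <= n_animals):
        raise ParameterError(f"n_required={n_required} outside [1, {n_animals}]")
    tallies: dict[str, int] = {}
    for calls in per_animal.values():
        for gene in gene_keys(calls, features):
            tallies[gene] = tallies.get(gene, 0) + 1
    return {gene for gene, n in tallies.items() if n >= n_required}


@dataclass
class GenotypeEditome:
    """One genotype's consensus editome plus the per-animal call index."""

    genotype: str
    consensus_sites: set[SiteKey]
    consensus_genes: set[str]
    per_animal_calls: dict[str, pd.DataFrame] = field(default_factory=dict)

    @classmethod
    def build(
        cls,
        genotype: str,
        per_animal: Mapping[str, pd.DataFrame],
        features: FeatureTable,
        n_required: int | None = None,
    ) -> "GenotypeEditome":
        return cls(
            genotype=genotype,
            consensus_sites=consensus_sites(per_animal, n_required),
            consensus_genes=consensus_genes(per_animal, features, n_required),
            per_animal_calls=dict(per_animal),
        )


# ---------------------------------------------------------------------------
# Venn partitioning

def venn_partition(sets: Mapping[str, Iterable[Hashable]]) -> dict[frozenset, set]:
    """Partition the union of labeled sets into the 2^k - 1 membership cells.

    Every element lands in exactly one cell keyed by the frozenset of labels
    whose sets contain it; empty cells are present with empty membership so
    four genotypes always yield 15 cells.
    """
    labels = list(sets)
    if len(set(labels)) != len(labels):
        raise ParameterError("duplicate set labels")
    as_sets = {lab: set(s) for lab, s in sets.items()}
    cells: dict[frozenset, set] = {}
    for r in range(1, len(labels) + 1):
        for combo in combinations(labels, r):
            cells[frozenset(combo)] = set()
    for element in set().union(*as_sets.values()) if as_sets else set():
        members = frozenset(lab for lab in labels if element in as_sets[lab])
        cells[members].add(element)
    return cells


def venn_counts(cells: Mapping[frozenset, set]) -> dict[frozenset, int]:
    return {key: len(val) for key, val in cells.items()}


def unique_sets(cells: Mapping[frozenset, set]) -> dict[str, set]:
    """Per-label singleton cells: elements belonging to exactly one set."""
    out: dict[str, set] = {}
    for key, members in cells.items():
        if len(key) == 1:
            (label,) = key
            out[label] = set(members)
    return out


def percent_change(counts: Mapping[str, int], baseline: str = "WT") -> dict[str, float]:
    """100 x (count_g - count_baseline) / count_baseline for each genotype."""
    if baseline not in counts:
        raise ParameterError(f"baseline {baseline!r} not among {sorted(counts)}")
    base = counts[baseline]
    if base == 0:
        raise ZeroDivisionError(f"baseline {baseline!r} has zero count; percent change undefined")
    return {g: 100.0 * (n - base) / base for g, n in counts.items()}


def venn_table(cells: Mapping[frozenset, set], label_order: Iterable[str]) -> pd.DataFrame:
    """Cell-count table with a stable, readable cell naming."""
    order = list(label_order)
    rows = []
    for key in sorted(cells, key=lambda k: (len(k), tuple(order.index(l) for l in sorted(k, key=order.index)))):
        name = "&".join(sorted(key, key=order.index))
        rows.append({"cell": name, "n_labels": len(key), "count": len(cells[key])})
    return pd.DataFrame(rows)
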