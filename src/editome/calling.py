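"""Per-animal A-to-I edit-site calling from RNA pileups with germline masking.

An edited adenosine shows up in RNA evidence as an A>G mismatch on the
transcribed plus strand or T>C on the minus strand (inosine is read as
guanosine). Candidate RNA–DNA differences are filtered against a germline
mask built from whole-exome pileups — a position whose DNA evidence shows a
non-reference allele is a SNP, not an edit — optionally augmented by a
supplied known-variant list. Sites inside an annotated gene must match the
gene's strand; intergenic sites are accepted in either orientation and
reported as unstranded.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .annotate import FeatureTable
from .io import OrderingError, check_pileup_sorted

CALL_COLUMNS = [
    "contig", "pos", "ref", "change", "strand", "depth", "variant_reads",
    "editing_fraction", "genes", "animal_id", "genotype",
]

_TARGET_ALT = {"A": "G", "T": "C"}  # edited-strand readout per reference base
_CHANGE_STRAND = {"A>G": "+", "T>C": "-"}


class ReferenceMismatchError(ValueError):
    """Pileup reference base disagrees with the genome FASTA."""


@dataclass(frozen=True)
class SnpThresholds:
    """Exome SNP-calling rule: depth and minimum alternate-allele fraction."""

    min_depth: int = 10
    min_alt_fraction: float = 0.1


@dataclass(frozen=True)
class CallThresholds:
    """Edit-call filters.

    The defaults (depth >= 10, >= 3 variant reads, editing fraction within
    [0.05, 0.95]) are standard RNA-editing practice; the upper fraction bound
    excludes residual homozygous variants. A position where some other
    non-reference base reaches ``complex_fraction`` is flagged complex and
    excluded as a likely unmasked variant or artifact. With
    ``drop_unassessable`` set, positions lacking adequate DNA evidence are
    excluded conservatively.
    """

    min_depth: int = 10
    min_variant_reads: int = 3
    min_fraction: float = 0.05
    max_fraction: float = 0.95
    complex_fraction: float = 0.05
    drop_unassessable: bool = True


@dataclass
class SnpMask:
    """Positions excluded from edit calling, with per-entry provenance.

    ``provenance`` maps (contig, pos) to a set of source tags ("exome",
    "known"). ``assessable`` holds DNA-covered positions whose depth met the
    SNP-calling minimum; observed positions below it are ``unassessable``.
    """

    provenance: dict[tuple[str, int], set[str]] = field(default_factory=dict)
    assessable: set[tuple[str, int]] = field(default_factory=set)
    unassessable: set[tuple[str, int]] = field(default_factory=set)

    @property
    def positions(self) -> set[tuple[str, int]]:
        return set(self.provenance)

    def __contains__(self, key: tuple[str, int]) -> bool:
        return key in self.provenance

    def __len__(self) -> int:
        return len(self.provenance)


def call_exome_snps(
    dna_pileups: pd.DataFrame | Iterable[pd.DataFrame],
    thresholds: SnpThresholds = SnpThresholds(),
) -> SnpMask:
    """Build a germline mask from DNA base-count evidence.

    Multiple DNA samples are pooled by summing counts per position. A
    position is masked iff pooled depth >= ``min_depth`` and any
    non-reference base reaches ``min_alt_fraction`` of the depth; covered
    positions below ``min_depth`` are recorded as unassessable.
    """
    if isinstance(dna_pileups, pd.DataFrame):
        dna_pileups = [dna_pileups]
    frames = []
    for df in dna_pileups:
        check_pileup_sorted(df, name=f"DNA pileup {df['sample_id'].iat[0] if len(df) else ''}")
        frames.append(df)
    if not frames:
        return SnpMask()
    pooled = (
        pd.concat(frames, ignore_index=True)
        .groupby(["contig", "pos", "ref"], sort=False, as_index=False)[["nA", "nC", "nG", "nT"]]
        .sum()
    )
    counts = pooled[["nA", "nC", "nG", "nT"]].to_numpy()
    depth = counts.sum(axis=1)
    ref_idx = pooled["ref"].map({"A": 0, "C": 1, "G": 2, "T": 3}).to_numpy()
    alt = counts.copy()
    alt[np.arange(len(alt)), ref_idx] = 0
    with np.errstate(invalid="ignore", divide="ignore"):
        max_alt_frac = np.where(depth > 0, alt.max(axis=1) / np.maximum(depth, 1), 0.0)

    mask = SnpMask()
    deep = depth >= thresholds.min_depth
    is_snp = deep & (max_alt_frac >= thresholds.min_alt_fraction)
    keys = list(zip(pooled["contig"], pooled["pos"].astype(int)))
    for key, snp in zip(keys, is_snp):
        if snp:
            mask.provenance[key] = {"exome"}
    mask.assessable = {k for k, d in zip(keys, deep) if d}
    mask.unassessable = {k for k, d in zip(keys, deep) if not d}
    return mask


def merge_known_variants(mask: SnpMask, known: Iterable[tuple[str, int]]) -> SnpMask:
    """Union a supplied known-variant position list into the mask (idempotent)."""
    merged = SnpMask(
        provenance={k: set(v) for k, v in mask.provenance.items()},
        assessable=set(mask.assessable),
        unassessable=set(mask.unassessable),
    )
    for key in known:
        key = (key[0], int(key[1]))
        merged.provenance.setdefault(key, set()).add("known")
    return merged


def call_edit_sites(
    rna_pileup: pd.DataFrame,
    mask: SnpMask | None,
    features: FeatureTable,
    thresholds: CallThresholds = CallThresholds(),
    genome: Mapping[str, str] | None = None,
    animal_id: str | None = None,
    genotype: str | None = None,
    emit_flagged: bool = False,
) -> pd.DataFrame:
    """Call candidate A-to-I sites for one animal.

    Returns a frame with :data:`CALL_COLUMNS`, sorted by position; every
    returned call passed all filters. With ``emit_flagged`` every reference-
    A/T position with at least one variant read is returned together with a
    ``filter_flags`` column (empty for passing calls) for auditability.

    Raises :class:`~editome.io.OrderingError` on unsorted input and
    :class:`ReferenceMismatchError` when a pileup reference base disagrees
    with the supplied genome.
    """
    check_pileup_sorted(rna_pileup, name="RNA pileup")
    if animal_id is None:
        animal_id = str(rna_pileup["sample_id"].iat[0]) if len(rna_pileup) else ""
    if genotype is None:
        genotype = ""

    df = rna_pileup
    if genome is not None and len(df):
        for contig, sub in df.groupby("contig", sort=False):
            seq = genome[contig]
            refs = np.frombuffer(seq.encode(), dtype="S1").astype("U1")[sub["pos"].to_numpy() - 1]
            bad = np.flatnonzero(refs != sub["ref"].to_numpy())
            if bad.size:
                pos = int(sub["pos"].iloc[bad[0]])
                raise ReferenceMismatchError(
                    f"pileup ref {sub['ref'].iloc[bad[0]]} != genome {refs[bad[0]]} at {contig}:{pos}"
                )

    df = df[df["ref"].isin(_TARGET_ALT)].copy()
    if not len(df):
        out = pd.DataFrame(columns=CALL_COLUMNS + (["filter_flags"] if emit_flagged else []))
        return out

    is_a = df["ref"].to_numpy() == "A"
    nA, nC, nG, nT = (df[c].to_numpy() for c in ("nA", "nC", "nG", "nT"))
    depth = df["depth"].to_numpy()
    variant = np.where(is_a, nG, nC)
    other_max = np.where(is_a, np.maximum(nC, nT), np.maximum(nG, nA))
    with np.errstate(invalid="ignore", divide="ignore"):
        fraction = np.where(depth > 0, variant / np.maximum(depth, 1), 0.0)
        other_frac = np.where(depth > 0, other_max / np.maximum(depth, 1), 0.0)

    df["change"] = np.where(is_a, "A>G", "T>C")
    df["variant_reads"] = variant
    df["editing_fraction"] = fraction
    df["complex_flag"] = other_frac >= thresholds.complex_fraction

    if not emit_flagged:
        keep = (
            (depth >= thresholds.min_depth)
            & (variant >= thresholds.min_variant_reads)
            & (fraction >= thresholds.min_fraction)
            & (fraction <= thresholds.max_fraction)
            & ~df["complex_flag"].to_numpy()
        )
        df = df[keep]
    else:
        df = df[df["variant_reads"].to_numpy() >= 1]

    rows = []
    for row in df.itertuples(index=False):
        key = (row.contig, int(row.pos))
        flags: set[str] = set()
        if row.depth < thresholds.min_depth:
            flags.add("low_depth")
        if row.variant_reads < thresholds.min_variant_reads:
            flags.add("few_variant_reads")
        if row.editing_fraction < thresholds.min_fraction:
            flags.add("low_fraction")
        if row.editing_fraction > thresholds.max_fraction:
            flags.add("high_fraction")
        if row.complex_flag:
            flags.add("complex")
        if mask is not None:
            if key in mask:
                flags.add("masked")
            elif thresholds.drop_unassessable and key not in mask.assessable:
                flags.add("unassessable")

        want_strand = _CHANGE_STRAND[row.change]
        containing = features.genes_at(row.contig, int(row.pos))
        if containing:
            credited = [gid for gid, strand in containing if strand == want_strand]
            if credited:
                strand, genes = want_strand, ",".join(sorted(credited))
            else:
                flags.add("strand_inconsistent")
                strand, genes = want_strand, ""
        else:
            strand, genes = ".", ""

        if flags and not emit_flagged:
            continue
        rec = {
            "contig": row.contig,
            "pos": int(row.pos),
            "ref": row.ref,
            "change": row.change,
            "strand": strand,
            "depth": int(row.depth),
            "variant_reads": int(row.variant_reads),
            "editing_fraction": float(row.editing_fraction),
            "genes": genes,
            "animal_id": animal_id,
            "genotype": genotype,
        }
        if emit_flagged:
            rec["filter_flags"] = ";".join(sorted(flags))
        rows.append(rec)

    out = pd.DataFrame(rows, columns=CALL_COLUMNS + (["filter_flags"] if emit_flagged else []))
    return out.sort_values(["contig", "pos"], kind="mergesort").reset_index(drop=True)


def with_thresholds(thresholds: CallThresholds, **overrides) -> CallThresholds:
    """Convenience for threshold sweeps in sensitivity analyses."""
    return replace(thresholds, **overrides)
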