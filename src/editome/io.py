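"""File-format interchange for the editome pipeline.

All in-memory coordinates are 1-based inclusive. BED files are 0-based
half-open and are converted exactly once, at parse/write time. Pileups are
tab-separated site records; masks and per-animal calls round-trip through
minimal VCF.
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping

import pandas as pd
import pyfaidx
import pysam

PILEUP_COLUMNS = ["contig", "pos", "ref", "nA", "nC", "nG", "nT", "depth", "sample_id"]

BED_FEATURE_SEP = "|"


class FormatError(ValueError):
    """Malformed interchange file."""


class OrderingError(ValueError):
    """Input records violate the required (contig, pos) sort order."""


# ---------------------------------------------------------------------------
# coordinate conversions (BED 0-based half-open <-> internal 1-based inclusive)

def bed_to_internal(start: int, end: int) -> tuple[int, int]:
    return start + 1, end


def internal_to_bed(start: int, end: int) -> tuple[int, int]:
    return start - 1, end


# ---------------------------------------------------------------------------
# FASTA

def write_fasta(sequences: Mapping[str, str], path: str | os.PathLike, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    fa = pyfaidx.Fasta(str(path))
    return {name: str(fa[name][:]) for name in fa.keys()}


# ---------------------------------------------------------------------------
# pileups

def write_pileup(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(path, sep="\t", index=False, columns=PILEUP_COLUMNS)


def read_pileup(path: str | os.PathLike, check_sorted: bool = False) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={
            "contig": str,
            "pos": int,
            "ref": str,
            "nA": int,
            "nC": int,
            "nG": int,
            "nT": int,
            "depth": int,
            "sample_id": str,
        },
    )
    missing = set(PILEUP_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"pileup {path} missing columns: {sorted(missing)}")
    if check_sorted:
        check_pileup_sorted(df, name=str(path))
    return df


def check_pileup_sorted(df: pd.DataFrame, name: str = "pileup") -> None:
    """Raise OrderingError naming the first offending record if unsorted."""
    for contig, sub in df.groupby("contig", sort=False):
        pos = sub["pos"].to_numpy()
        bad = (pos[1:] <= pos[:-1]).nonzero()[0]
        if bad.size:
            i = int(bad[0]) + 1
            raise OrderingError(
                f"{name}: records not sorted by position at {contig}:{int(pos[i])} "
                f"(row {int(sub.index[i])})"
            )


# ---------------------------------------------------------------------------
# BED

def read_bed(path: str | os.PathLike) -> pd.DataFrame:
    """Read a 6-column BED into internal coordinates (columns start/end 1-based inclusive)."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["contig", "start", "end", "name", "score", "strand"],
        dtype={"contig": str, "start": int, "end": int, "name": str, "score": str, "strand": str},
        comment="#",
    )
    df["start"] = df["start"] + 1
    return df


def write_bed(df: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write internal-coordinate intervals (contig,start,end,name,strand) as 6-column BED."""
    out = pd.DataFrame(
        {
            "contig": df["contig"],
            "start": df["start"] - 1,
            "end": df["end"],
            "name": df["name"],
            "score": ".",
            "strand": df.get("strand", "."),
        }
    )
    out.to_csv(path, sep="\t", index=False, header=False)


# ---------------------------------------------------------------------------
# minimal VCF (CHROM POS ID REF ALT QUAL FILTER INFO)

_VCF_HEADER = "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO"


def _vcf_preamble(contig_lengths: Mapping[str, int] | None, info_lines: Iterable[str]) -> list[str]:
    lines = ["##fileformat=VCFv4.2", "##source=editome"]
    if contig_lengths:
        for name, length in contig_lengths.items():
            lines.append(f"##contig=<ID={name},length={length}>")
    lines.extend(info_lines)
    lines.append(_VCF_HEADER)
    return lines


def write_mask_vcf(
    mask_entries: Iterable[tuple[str, int, str, str, str]],
    path: str | os.PathLike,
    contig_lengths: Mapping[str, int] | None = None,
) -> None:
    """Write SNP-mask positions. Entries are (contig, pos, ref, alt, provenance)."""
    lines = _vcf_preamble(
        contig_lengths,
        ['##INFO=<ID=SOURCE,Number=.,Type=String,Description="Mask provenance">'],
    )
    for contig, pos, ref, alt, source in mask_entries:
        lines.append(f"{contig}\t{pos}\t.\t{ref}\t{alt or '.'}\t.\t.\tSOURCE={source}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_mask_vcf(path: str | os.PathLike) -> list[tuple[str, int, set[str]]]:
    """Return (contig, pos, provenance set) triples from a mask VCF."""
    out = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            source = rec.info.get("SOURCE", ())
            if isinstance(source, str):
                source = (source,)
            out.append((rec.chrom, rec.pos, set(",".join(source).split(","))))
    return out


_CALL_INFO_LINES = [
    '##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
    '##INFO=<ID=VR,Number=1,Type=Integer,Description="Variant (edited) reads">',
    '##INFO=<ID=EF,Number=1,Type=Float,Description="Editing fraction">',
    '##INFO=<ID=STRAND,Number=1,Type=String,Description="Transcript strand (+,-,.)">',
    '##INFO=<ID=GENE,Number=.,Type=String,Description="Containing gene ids">',
    '##INFO=<ID=ANIMAL,Number=1,Type=String,Description="Animal id">',
    '##INFO=<ID=GENOTYPE,Number=1,Type=String,Description="Genotype label">',
]


def write_calls_vcf(
    calls: pd.DataFrame,
    path: str | os.PathLike,
    contig_lengths: Mapping[str, int] | None = None,
) -> None:
    """Write per-animal edit calls (A>G as REF=A/ALT=G, T>C as REF=T/ALT=C)."""
    lines = _vcf_preamble(contig_lengths, _CALL_INFO_LINES)
    for row in calls.itertuples(index=False):
        ref, alt = row.change.split(">")
        info = (
            f"DP={row.depth};VR={row.variant_reads};EF={row.editing_fraction:.6g};"
            f"STRAND={row.strand};ANIMAL={row.animal_id};GENOTYPE={row.genotype}"
        )
        if row.genes:
            info += f";GENE={row.genes}"
        lines.append(f"{row.contig}\t{row.pos}\t.\t{ref}\t{alt}\t.\tPASS\t{info}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_calls_vcf(path: str | os.PathLike) -> pd.DataFrame:
    """Read a per-animal call VCF back into the calling DataFrame schema."""
    rows = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            gene = rec.info.get("GENE", ())
            if isinstance(gene, str):
                gene = (gene,)
            rows.append(
                {
                    "contig": rec.chrom,
                    "pos": rec.pos,
                    "ref": rec.ref,
                    "change": f"{rec.ref}>{rec.alts[0]}",
                    "strand": rec.info["STRAND"],
                    "depth": int(rec.info["DP"]),
                    "variant_reads": int(rec.info["VR"]),
                    "editing_fraction": float(rec.info["EF"]),
                    "genes": ",".join(gene),
                    "animal_id": rec.info["ANIMAL"],
                    "genotype": rec.info["GENOTYPE"],
                }
            )
    from .calling import CALL_COLUMNS  # local import to avoid a cycle

    return pd.DataFrame(rows, columns=CALL_COLUMNS)


# ---------------------------------------------------------------------------
# plain lists / tables

def read_gene_list(path: str | os.PathLike) -> set[str]:
    """One gene id per line; blank lines and #-comments ignored."""
    out = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.add(line)
    return out


def read_position_list(path: str | os.PathLike) -> list[tuple[str, int]]:
    """TSV of contig<TAB>pos (1-based); raises FormatError with the line number."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(f"{path}: line {lineno}: expected contig<TAB>pos")
            try:
                out.append((parts[0], int(parts[1])))
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: non-integer position") from exc
    return out
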