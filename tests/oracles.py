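"""Independent brute-force re-implementations used as test oracles.

Deliberately naive: explicit loops, exact arithmetic, no shared code with
the package's vectorized implementations.
"""

from __future__ import annotations

import math

import numpy as np


def detection_probability_bf(
    f: float,
    depth_mean: float,
    error_rate: float,
    min_depth: int = 10,
    min_variant_reads: int = 3,
    min_fraction: float = 0.05,
    max_fraction: float = 0.95,
    complex_fraction: float | None = 0.05,
) -> float:
    """Closed-form per-animal detection probability via direct summation.

    Mirrors the full calling rule: the depth window, the variant-read count
    and fraction window, and exclusion of positions where either remaining
    base reaches the complex-fraction cutoff (each Binomial(d, e/3),
    independently).
    """
    e = error_rate
    p = f * (1 - e) + (1 - f) * e / 3
    norm = 1.0 - math.exp(-depth_mean)
    total = 0.0
    d = min_depth
    while True:
        log_pmf = d * math.log(depth_mean) - depth_mean - math.lgamma(d + 1)
        pmf = math.exp(log_pmf) / norm
        if d > depth_mean and pmf < 1e-14:
            break
        inner = 0.0
        k_lo = max(min_variant_reads, math.ceil(min_fraction * d))
        k_hi = math.floor(max_fraction * d)
        for k in range(k_lo, k_hi + 1):
            inner += math.comb(d, k) * p**k * (1 - p) ** (d - k)
        if complex_fraction is not None:
            q = e / 3
            k_cx = math.ceil(complex_fraction * d)
            p_one_ok = sum(
                math.comb(d, k) * q**k * (1 - q) ** (d - k) for k in range(0, k_cx)
            )
            inner *= p_one_ok**2
        total += pmf * inner
        d += 1
    return total


def naive_edit_calls(pileup, mask_positions, assessable, features, th):
    """Position-by-position filter identical in spirit to a manual analysis."""
    out = set()
    for row in pileup.itertuples(index=False):
        if row.ref == "A":
            variant, change, want = row.nG, "A>G", "+"
            others = max(row.nC, row.nT)
        elif row.ref == "T":
            variant, change, want = row.nC, "T>C", "-"
            others = max(row.nG, row.nA)
        else:
            continue
        if row.depth < th.min_depth or variant < th.min_variant_reads:
            continue
        frac = variant / row.depth
        if frac < th.min_fraction or frac > th.max_fraction:
            continue
        if others / row.depth >= th.complex_fraction:
            continue
        key = (row.contig, int(row.pos))
        if key in mask_positions:
            continue
        if th.drop_unassessable and key not in assessable:
            continue
        genes = features.genes_at(row.contig, int(row.pos))
        if genes and not any(strand == want for _, strand in genes):
            continue
        out.add((row.contig, int(row.pos), change, int(variant)))
    return out


def intersect_bf(sets):
    """Element-by-element membership count intersection."""
    universe = set()
    for s in sets:
        universe |= set(s)
    return {x for x in universe if all(x in s for s in sets)}


def venn_bf(labeled_sets):
    """Exhaustive membership enumeration of Venn cells."""
    cells = {}
    universe = set()
    for s in labeled_sets.values():
        universe |= set(s)
    for x in universe:
        members = frozenset(lab for lab, s in labeled_sets.items() if x in s)
        cells.setdefault(members, set()).add(x)
    return cells


def assign_bf(contig, pos, gene_rows, repeat_rows):
    """Linear scan over every interval; precedence and tie-break by hand."""
    precedence = {"three_prime_utr": 0, "five_prime_utr": 1, "cds": 2, "intron": 3}
    hits = [
        (precedence[cls], gid, cls)
        for (ctg, start, end, _strand, gid, cls) in gene_rows
        if ctg == contig and start <= pos <= end
    ]
    if hits:
        _, gene_id, feature_class = min(hits)
    else:
        feature_class, gene_id = "intergenic", None
    rhits = [
        (end - start + 1, cls)
        for (ctg, start, end, cls) in repeat_rows
        if ctg == contig and start <= pos <= end
    ]
    repeat_class = min(rhits)[1] if rhits else None
    return feature_class, gene_id, repeat_class


def fisher_two_sided_bf(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by enumerating all tables with fixed margins."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def table_prob(x: int) -> float:
        return (
            math.comb(r1, x) * math.comb(r2, c1 - x) / math.comb(n, c1)
        )

    p_obs = table_prob(a)
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        px = table_prob(x)
        if px <= p_obs * (1 + 1e-9):
            total += px
    return min(total, 1.0)


def bh_adjust_bf(pvalues):
    """Benjamini–Hochberg step-up with an explicit backward minimum pass."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    adjusted = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * m / rank)
        adjusted[idx] = running
    return adjusted
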