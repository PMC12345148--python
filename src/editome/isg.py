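"""Interferon-stimulated-gene (ISG) classification and enrichment statistics.

ISG membership is always an input list (e.g. derived from the Interferome
database), never computed here. The module summarizes differential-
expression tables against that list, applies the log(x + pseudocount)
transform used for expression heatmaps, and tests whether a genotype's
uniquely edited sites are enriched in ISG transcripts with a 2x2 Fisher
exact test. A minimal rank-test DEG caller is included purely as plumbing so
the synthetic pipeline runs end to end; it is a stand-in, not a serious
differential-expression method.
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .consensus import SiteKey

DEG_COLUMNS = ["gene_id", "log2fc", "p", "p_adj", "contrast"]


class InputError(ValueError):
    pass


def deg_isg_summary(
    deg: pd.DataFrame,
    isgs: Iterable[str],
    lfc_cut: float = 1.0,
    p_cut: float = 0.05,
) -> pd.DataFrame:
    """Per-contrast DEG counts and the fraction that are known ISGs.

    ``deg`` needs columns gene_id, log2fc, p_adj, contrast. Counts are
    stratified by direction: a gene passes when p_adj < ``p_cut`` and
    log2fc >= ``lfc_cut`` (up) or <= -``lfc_cut`` (down).
    """
    isgs = set(isgs)
    rows = []
    for contrast, sub in deg.groupby("contrast", sort=True) if len(deg) else []:
        if sub["gene_id"].duplicated().any():
            dup = sub.loc[sub["gene_id"].duplicated(), "gene_id"].iloc[0]
            raise InputError(f"duplicate gene id {dup!r} within contrast {contrast!r}")
        passing = sub[sub["p_adj"] < p_cut]
        for direction, dsub in (
            ("up", passing[passing["log2fc"] >= lfc_cut]),
            ("down", passing[passing["log2fc"] <= -lfc_cut]),
        ):
            n_deg = len(dsub)
            n_isg = int(dsub["gene_id"].isin(isgs).sum())
            rows.append(
                {
                    "contrast": contrast,
                    "direction": direction,
                    "n_deg": n_deg,
                    "n_deg_isg": n_isg,
                    "isg_fraction": n_isg / n_deg if n_deg else float("nan"),
                }
            )
    return pd.DataFrame(rows, columns=["contrast", "direction", "n_deg", "n_deg_isg", "isg_fraction"])


def log_transform_matrix(matrix, pseudocount: float = 1.0, base: float | None = None):
    """Elementwise log(x + pseudocount); zero maps to 0 when pseudocount is 1.

    ``base`` None means the natural logarithm; any positive base is accepted.
    Negative input raises, since expression values must be non-negative.
    """
    arr = np.asarray(matrix, dtype=float)
    if np.any(arr < 0):
        raise InputError("expression values must be >= 0")
    out = np.log(arr + pseudocount)
    if base is not None:
        out = out / math.log(base)
    if isinstance(matrix, pd.DataFrame):
        return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)
    return out


def isg_edit_proportion(
    unique_sites: Iterable[SiteKey],
    consensus_sites: Iterable[SiteKey],
    site_genes: Mapping[SiteKey, Iterable[str]],
    isgs: Iterable[str],
) -> dict:
    """Are a genotype's uniquely edited sites enriched in ISG transcripts?

    Considers the genic consensus sites of one genotype (sites mapping to at
    least one gene) and crosses ISG membership (any containing gene in the
    ISG list) with uniqueness (site private to this genotype vs shared).
    Returns the 2x2 table [[unique&ISG, unique&non-ISG], [shared&ISG,
    shared&non-ISG]], the per-stratum ISG proportions, the sample odds ratio
    (+/-inf convention on zero margins) with its Haldane-corrected companion,
    and the two-sided Fisher exact p-value.
    """
    isgs = set(isgs)
    unique_sites = set(unique_sites)
    genic = [s for s in set(consensus_sites) if site_genes.get(s)]
    if not genic:
        raise InputError("no genic consensus sites; ISG proportion undefined")
    a = b = c = d = 0
    for site in genic:
        in_isg = any(g in isgs for g in site_genes[site])
        if site in unique_sites:
            a, b = (a + 1, b) if in_isg else (a, b + 1)
        else:
            c, d = (c + 1, d) if in_isg else (c, d + 1)
    table = [[a, b], [c, d]]
    odds = (a * d) / (b * c) if b * c else (float("inf") if a * d else float("nan"))
    haldane = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    _, p = stats.fisher_exact(table, alternative="two-sided")
    return {
        "table": table,
        "n_unique": a + b,
        "n_shared": c + d,
        "proportion_unique_isg": a / (a + b) if a + b else float("nan"),
        "proportion_shared_isg": c / (c + d) if c + d else float("nan"),
        "odds_ratio": odds,
        "odds_ratio_haldane": haldane,
        "p_value": float(p),
    }


def bh_adjust(pvalues: Iterable[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def minimal_deg_call(
    counts: pd.DataFrame,
    groups: Mapping[str, Iterable[str]],
    contrasts: Iterable[tuple[str, str]],
) -> pd.DataFrame:
    """Plumbing-grade differential expression for the synthetic pipeline.

    For each (test, reference) contrast: log2 fold change of group mean
    counts with one pseudocount, an exact two-sample rank (Mann–Whitney)
    p-value per gene, BH-adjusted within the contrast. Exists so the
    synthetic end-to-end run produces a DEG table; real analyses should
    supply one from a dedicated DE package.
    """
    groups = {g: list(samples) for g, samples in groups.items()}
    for g, samples in groups.items():
        if len(samples) < 2:
            raise InputError(f"group {g!r} has {len(samples)} samples; need >= 2")
        missing = set(samples) - set(counts.columns)
        if missing:
            raise InputError(f"group {g!r} samples missing from count matrix: {sorted(missing)}")
    frames = []
    for test, ref in contrasts:
        x = counts[groups[test]].to_numpy(dtype=float)
        y = counts[groups[ref]].to_numpy(dtype=float)
        lfc = np.log2((x.mean(axis=1) + 1.0) / (y.mean(axis=1) + 1.0))
        pvals = np.ones(len(counts))
        for i in range(len(counts)):
            if np.all(x[i] == x[i][0]) and np.all(y[i] == y[i][0]) and x[i][0] == y[i][0]:
                continue  # identical constant groups: no evidence, p = 1
            pvals[i] = stats.mannwhitneyu(x[i], y[i], alternative="two-sided", method="exact").pvalue
        frames.append(
            pd.DataFrame(
                {
                    "gene_id": counts.index,
                    "log2fc": lfc,
                    "p": pvals,
                    "p_adj": bh_adjust(pvals),
                    "contrast": f"{test}_vs_{ref}",
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=DEG_COLUMNS)
    return pd.concat(frames, ignore_index=True)[DEG_COLUMNS]
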