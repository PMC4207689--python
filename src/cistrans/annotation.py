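"""Peak-to-gene assignment and variant-density analysis of candidate
cis-regulatory elements.

Peaks (ChIP-seq bound regions) are assigned to genes by a proximity rule:
a peak whose center lies within a gene's span belongs to that gene,
otherwise to the gene with the nearest transcriptional start site on the
same chromosome. Variant density around peaks is profiled in sliding
windows (defaults: 50 bp windows stepping 25 bp across a 2 kb span, 79
windows) and tabulated in the central 1 kb, feeding per-kb frequencies and
exact hypergeometric enrichment tests.

All intervals are 0-based half-open (BED convention); variant positions
are 1-based (VCF convention).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

logger = logging.getLogger(__name__)


def peak_center(start: int, end: int) -> int:
    """Floor midpoint of a 0-based half-open interval."""
    return (start + end) // 2


def assign_peaks_to_genes(peaks: pd.DataFrame,
                          genes: pd.DataFrame) -> pd.DataFrame:
    """Assign each peak to exactly one gene.

    Containment is tested on the peak center against gene spans. A center
    inside one or more gene spans is assigned to the containing gene with
    the nearest TSS (flagged ambiguous when several genes contain it);
    otherwise to the gene with the minimal |center - TSS| on the same
    chromosome. All ties break deterministically to the lexicographically
    smallest gene id and are flagged. Peaks on chromosomes without genes
    are returned unassigned (gene_id None) and counted in a log line.

    Returns columns: name, chrom, center, gene_id, method
    (contained | nearest_tss | unassigned), flag (none | ambiguous | tie).
    """
    trees: dict[str, IntervalTree] = {}
    tss_by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, sub in genes.groupby("chrom"):
        tree = IntervalTree()
        for rec in sub.itertuples():
            if rec.start >= rec.end:
                raise ValueError(f"gene {rec.gene_id}: start >= end")
            tree.addi(rec.start, rec.end, rec.gene_id)
        trees[chrom] = tree
        order = np.argsort(sub["tss"].to_numpy())
        tss_by_chrom[chrom] = (sub["tss"].to_numpy()[order],
                               sub["gene_id"].to_numpy()[order])
    tss_all = {rec.gene_id: rec.tss for rec in genes.itertuples()}

    rows, n_unassigned = [], 0
    for rec in peaks.itertuples():
        center = peak_center(rec.start, rec.end)
        row = {"name": rec.name, "chrom": rec.chrom, "center": center,
               "gene_id": None, "method": "unassigned", "flag": "none"}
        tree = trees.get(rec.chrom)
        if tree is None:
            n_unassigned += 1
            rows.append(row)
            continue
        hits = sorted(tree[center], key=lambda iv: iv.data)
        if hits:
            # Containment; among containing genes pick the nearest TSS.
            dists = [(abs(center - tss_all[iv.data]), iv.data) for iv in hits]
            best = min(d for d, _ in dists)
            candidates = sorted(g for d, g in dists if d == best)
            row.update(gene_id=candidates[0], method="contained")
            if len(hits) > 1:
                row["flag"] = "ambiguous"
            if len(candidates) > 1:
                row["flag"] = "tie"
        else:
            tss, ids = tss_by_chrom[rec.chrom]
            dist = np.abs(tss - center)
            best = dist.min()
            candidates = sorted(ids[dist == best])
            row.update(gene_id=candidates[0], method="nearest_tss")
            if len(candidates) > 1:
                row["flag"] = "tie"
        rows.append(row)
    if n_unassigned:
        logger.info("%d peaks on chromosomes with no genes left unassigned",
                    n_unassigned)
    return pd.DataFrame(rows)


def _variant_positions(variants: pd.DataFrame) -> dict[str, np.ndarray]:
    """Sorted 0-based variant coordinates per chromosome."""
    return {chrom: np.sort(sub["pos"].to_numpy() - 1)
            for chrom, sub in variants.groupby("chrom")}


@dataclass
class WindowProfile:
    """Summed variant counts in sliding windows centered on peaks."""

    offsets: np.ndarray   # window midpoint minus peak center, bp
    counts: np.ndarray
    n_peaks: int
    n_excluded: int


def sliding_window_profile(
    peaks: pd.DataFrame,
    variants: pd.DataFrame,
    window: int = 50,
    step: int = 25,
    span: int = 2000,
    contig_lengths: dict[str, int] | None = None,
) -> WindowProfile:
    """Variant counts in windows tiling [center - span/2, center + span/2].

    A variant contributes to every window whose half-open interval
    contains it; counts are summed over peaks. Peaks whose span extends
    past a contig edge (below zero, or beyond ``contig_lengths`` when
    given) are excluded and counted.
    """
    if span % 2 != 0:
        raise ValueError("span must be even")
    if window > span or (span - window) % step != 0:
        raise ValueError("step must divide (span - window), window <= span")
    n_win = (span - window) // step + 1
    starts_rel = np.arange(n_win) * step - span // 2
    offsets = starts_rel + window // 2
    counts = np.zeros(n_win, dtype=int)
    pos_by_chrom = _variant_positions(variants)
    half = span // 2
    n_excluded = 0
    for rec in peaks.itertuples():
        center = peak_center(rec.start, rec.end)
        lo, hi = center - half, center + half
        limit = (contig_lengths or {}).get(rec.chrom)
        if lo < 0 or (limit is not None and hi > limit):
            n_excluded += 1
            continue
        pos = pos_by_chrom.get(rec.chrom)
        if pos is None:
            continue
        inside = pos[np.searchsorted(pos, lo):np.searchsorted(pos, hi)]
        for p in inside:
            rel = p - center + half          # 0 .. span-1
            w_hi = min(rel // step, n_win - 1)
            w_lo = max(int(np.ceil((rel - window + 1) / step)), 0)
            counts[w_lo:w_hi + 1] += 1
    if n_excluded:
        logger.info("excluded %d peaks with truncated windows", n_excluded)
    return WindowProfile(offsets=offsets, counts=counts,
                         n_peaks=len(peaks) - n_excluded,
                         n_excluded=n_excluded)


def central_window_counts(peaks: pd.DataFrame, variants: pd.DataFrame,
                          span: int = 1000) -> pd.Series:
    """Variant count in the half-open central window
    [center - span/2, center + span/2) of each peak, indexed by peak name."""
    pos_by_chrom = _variant_positions(variants)
    half = span // 2
    out = {}
    for rec in peaks.itertuples():
        center = peak_center(rec.start, rec.end)
        pos = pos_by_chrom.get(rec.chrom, np.empty(0, dtype=int))
        out[rec.name] = int(np.searchsorted(pos, center + half)
                            - np.searchsorted(pos, center - half))
    return pd.Series(out, dtype=int, name="n_variants")


def variant_frequency_per_kb(
    counts=None,
    span: int = 1000,
    *,
    total_variants: int | None = None,
    n_peaks: int | None = None,
) -> float:
    """Variants per kb over a set of peaks' central windows.

    Either pass per-peak ``counts`` or the aggregate
    ``total_variants`` / ``n_peaks`` pair.
    """
    if span <= 0:
        raise ValueError("span must be positive")
    if counts is not None:
        arr = np.asarray(counts)
        total_variants, n_peaks = int(arr.sum()), int(arr.size)
    if not n_peaks:
        raise ValueError("zero peaks")
    return total_variants / (n_peaks * span / 1000.0)


def frequency_enrichment_test(k: int, n: int, K: int, N: int) -> float:
    """Upper-tail hypergeometric p-value P(X >= k) for drawing k marked
    items in n draws from a population of N items of which K are marked."""
    if not (0 <= k <= K <= N and 0 <= k <= n <= N):
        raise ValueError("inconsistent counts for hypergeometric test")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def variant_frequency_enrichment(
    subset_counts, all_counts, span: int = 1000) -> dict:
    """Enrichment of variant frequency in a subset of peaks over all peaks.

    Each base pair of a peak's central window is one draw (a position
    holds at most one variant), so the test is exact hypergeometric:
    population = all peaks x span bp with the total variants marked;
    draws = subset peaks x span bp.
    """
    subset_counts = np.asarray(subset_counts)
    all_counts = np.asarray(all_counts)
    k, K = int(subset_counts.sum()), int(all_counts.sum())
    n, N = subset_counts.size * span, all_counts.size * span
    return {
        "subset_variants": k,
        "subset_peaks": int(subset_counts.size),
        "total_variants": K,
        "total_peaks": int(all_counts.size),
        "subset_freq_per_kb": variant_frequency_per_kb(subset_counts, span),
        "total_freq_per_kb": variant_frequency_per_kb(all_counts, span),
        "p_upper": frequency_enrichment_test(k, n, K, N),
    }


def count_histogram(counts, normalize: bool = False) -> pd.Series:
    """Distribution of per-peak variant counts; masses sum to 1 when
    normalized. Empty input yields an empty histogram."""
    arr = np.asarray(list(counts), dtype=int)
    if arr.size == 0:
        return pd.Series(dtype=float)
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")
    values, freq = np.unique(arr, return_counts=True)
    hist = pd.Series(freq.astype(float), index=values)
    if normalize:
        hist = hist / hist.sum()
    return hist


def association_enrichment(gene_set, associated, universe) -> dict:
    """Hypergeometric enrichment of an association flag within a gene set.

    ``associated`` is the set of flagged genes in ``universe``; the test
    asks whether ``gene_set`` contains more flagged genes than expected
    when drawing |gene_set| genes from the universe.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    gene_set = set(gene_set)
    if not gene_set <= universe:
        raise ValueError("gene_set must be a subset of universe")
    associated = set(associated) & universe
    k = len(gene_set & associated)
    n, K, N = len(gene_set), len(associated), len(universe)
    return {
        "k": k, "n": n, "K": K, "N": N,
        "proportion_set": k / n if n else None,
        "proportion_universe": K / N,
        "p_upper": frequency_enrichment_test(k, n, K, N),
    }
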