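"""Weighted fold-change estimation, cis/trans subcategorization, and the
surrounding descriptive analyses.

The central estimator is the inverse-posterior-variance weighted mean of
replicate log-expression parameters; the strain (F0) and allelic (F1)
weighted log2 fold changes y and x feed the four-way subcategorization of
genes driven by combined cis and trans effects:

* CIS-trans  (opposite directions, cis stronger):  x*y > 0 and |x| > |y|
* TRANS-cis  (opposite directions, trans stronger): x*y < 0
* CIS+trans  (same direction, cis stronger):  x*y > 0 and |x| < |y| < 2|x|
* TRANS+cis  (same direction, trans stronger): x*y > 0 and |y| > 2|x|

Boundary points (x*y = 0, |x| = |y|, |y| = 2|x|) fall outside the printed
inequalities and get an explicit "boundary" label.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

LN2 = math.log(2.0)

SUBCATEGORIES = ("CIS_minus_trans", "TRANS_minus_cis",
                 "CIS_plus_trans", "TRANS_plus_cis")
#: Opposite-direction subcategories buffer expression (stabilizing);
#: same-direction ones compound it (destabilizing).
STABILIZING = ("CIS_minus_trans", "TRANS_minus_cis")
DESTABILIZING = ("CIS_plus_trans", "TRANS_plus_cis")


def weighted_mean(means: Sequence[float], variances: Sequence[float]) -> float:
    """Inverse-variance weighted mean: sum(m_i/v_i) / sum(1/v_i)."""
    m = np.asarray(means, dtype=float)
    v = np.asarray(variances, dtype=float)
    if m.size == 0 or m.size != v.size:
        raise ValueError("means and variances must be equal-length, non-empty")
    if not (np.isfinite(m).all() and np.isfinite(v).all()):
        raise ValueError("non-finite input to weighted_mean")
    if (v <= 0).any():
        raise ValueError("variances must be positive")
    w = 1.0 / v
    return float((m * w).sum() / w.sum())


def weighted_log2_fold_change(
    cast_means: Sequence[float], cast_variances: Sequence[float],
    b6_means: Sequence[float], b6_variances: Sequence[float],
) -> float:
    """Weighted log2 fold change, Cast over B6.

    Inputs are natural-log expression parameters with posterior variances;
    the difference of the two inverse-variance weighted means is converted
    to log2 at this single point.
    """
    return (weighted_mean(cast_means, cast_variances)
            - weighted_mean(b6_means, b6_variances)) / LN2


def effect_table(measurements: pd.DataFrame) -> pd.DataFrame:
    """Per-gene weighted log2 fold changes from an expression table.

    x compares the Cast-allele to the B6-allele series within the F1s
    (both crosses pooled); y compares F0 Cast to F0 B6. Only polymorphic
    genes with all six groups present are returned.
    """
    rows = []
    for gene_id, df in measurements.groupby("gene_id", sort=True):
        if not bool(df["polymorphic"].iloc[0]):
            continue
        grp = {g: sub for g, sub in df.groupby("group")}
        needed = {"F0_B6", "F0_CAST", "F1i_B", "F1i_C", "F1r_B", "F1r_C"}
        if not needed <= set(grp):
            continue

        def mv(names):
            sub = pd.concat([grp[n] for n in names])
            return sub["log_mean"].to_numpy(), sub["log_sd"].to_numpy() ** 2

        x = weighted_log2_fold_change(*mv(["F1i_C", "F1r_C"]),
                                      *mv(["F1i_B", "F1r_B"]))
        y = weighted_log2_fold_change(*mv(["F0_CAST"]), *mv(["F0_B6"]))
        rows.append({"gene_id": gene_id, "x": x, "y": y})
    return pd.DataFrame(rows, columns=["gene_id", "x", "y"])


def subcategorize(x: float, y: float) -> str:
    """Assign a combined cis-and-trans gene to its subcategory from the
    F1 allelic (x) and F0 strain (y) weighted log2 fold changes."""
    if not (np.isfinite(x) and np.isfinite(y)):
        raise ValueError("x and y must be finite")
    p = x * y
    if p < 0:
        return "TRANS_minus_cis"
    ax, ay = abs(x), abs(y)
    if p == 0 or ax == ay or ay == 2 * ax:
        return "boundary"
    if ax > ay:
        return "CIS_minus_trans"
    if ay < 2 * ax:
        return "CIS_plus_trans"
    return "TRANS_plus_cis"


@dataclass
class SubcategorySummary:
    counts: dict[str, int]
    n_assignable: int
    n_boundary: int
    stabilizing_fraction: float | None
    destabilizing_fraction: float | None


def summarize_subcategories(labels: Iterable[str]) -> SubcategorySummary:
    """Tally subcategory labels and the stabilizing/destabilizing split.

    Boundary labels are excluded from the assignable denominator. With an
    empty input the fractions are reported as absent (None), not NaN.
    """
    labels = list(labels)
    counts = {c: labels.count(c) for c in SUBCATEGORIES}
    n_boundary = labels.count("boundary")
    n = sum(counts.values())
    stab = sum(counts[c] for c in STABILIZING)
    return SubcategorySummary(
        counts=counts,
        n_assignable=n,
        n_boundary=n_boundary,
        stabilizing_fraction=(stab / n) if n else None,
        destabilizing_fraction=((n - stab) / n) if n else None,
    )


def fpkm_matrix(measurements: pd.DataFrame, groups: Sequence[str]
                ) -> pd.DataFrame:
    """Genes x samples matrix of FPKM-scale values (exponentiated log
    expression), columns named ``group:Rn``."""
    sub = measurements[measurements["group"].isin(list(groups))].copy()
    sub["sample"] = sub["group"] + ":R" + sub["replicate"].astype(str)
    sub["fpkm"] = np.exp(sub["log_mean"])
    return sub.pivot(index="gene_id", columns="sample", values="fpkm")


def replicate_concordance(matrix: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson correlations between sample columns.

    Zero-variance samples yield NaN against every partner, reported as-is
    rather than being silently dropped.
    """
    if matrix.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    return matrix.corr(method="pearson", min_periods=2)


def rank_enrichment(ranked_ids: Sequence[str],
                    known_scores: Mapping[str, int],
                    min_score: int = 1) -> pd.DataFrame:
    """Cumulative count of known genes (database score >= min_score) along
    a ranking. Returns columns rank, gene_id, known, cumulative_known."""
    ids = list(ranked_ids)
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate gene ids in ranking")
    known = [known_scores.get(g, 0) >= min_score for g in ids]
    return pd.DataFrame({
        "rank": np.arange(1, len(ids) + 1),
        "gene_id": ids,
        "known": known,
        "cumulative_known": np.cumsum(known),
    })


def known_fraction(ranked_ids: Sequence[str],
                   known_scores: Mapping[str, int],
                   top_n: int, min_score: int = 1) -> tuple[int, float]:
    """Count and fraction of known genes among the top_n ranked genes."""
    top = list(ranked_ids)[:top_n]
    if not top:
        raise ValueError("empty ranking slice")
    k = sum(known_scores.get(g, 0) >= min_score for g in top)
    return k, k / len(top)


def fisher_exact_two_tailed(table: Sequence[Sequence[int]]) -> float | None:
    """Two-tailed Fisher exact p by hypergeometric probability-mass
    summation (sum of all tables with fixed margins whose probability does
    not exceed the observed one).

    Returns None when a margin is degenerate (the test is undefined).
    """
    (a, b), (c, d) = table
    if min(a, b, c, d) < 0:
        raise ValueError("negative cell count")
    n_total = a + b + c + d
    row1, col1 = a + b, a + c
    if row1 in (0, n_total) or col1 in (0, n_total):
        return None
    kmin, kmax = max(0, row1 + col1 - n_total), min(row1, col1)
    support = np.arange(kmin, kmax + 1)
    pmf = stats.hypergeom.pmf(support, n_total, row1, col1)
    p_obs = stats.hypergeom.pmf(a, n_total, row1, col1)
    p = float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())
    return min(p, 1.0)


def direction_bias_by_foldchange(
    fold_changes: pd.Series,
    associated: pd.Series,
    thresholds: Sequence[float],
) -> pd.DataFrame:
    """Cast-higher proportions by association status across fold-change bins.

    For each threshold t, genes with |log2 fold change| >= t form a 2x2
    table of (associated x Cast-higher); the two-tailed Fisher exact p is
    reported per bin, absent (None) for empty bins or degenerate margins.
    """
    thresholds = list(thresholds)
    if any(t <= 0 for t in thresholds) or sorted(thresholds) != thresholds:
        raise ValueError("thresholds must be positive and increasing")
    fc = fold_changes.astype(float)
    assoc = associated.astype(bool)
    rows = []
    for t in thresholds:
        sel = fc.abs() >= t
        if not sel.any():
            rows.append({"threshold": t, "n": 0, "p": None,
                         "prop_cast_higher_associated": None,
                         "prop_cast_higher_unassociated": None})
            continue
        cast_higher = fc[sel] > 0
        a = int((assoc[sel] & cast_higher).sum())
        b = int((assoc[sel] & ~cast_higher).sum())
        c = int((~assoc[sel] & cast_higher).sum())
        d = int((~assoc[sel] & ~cast_higher).sum())
        rows.append({
            "threshold": t,
            "n": int(sel.sum()),
            "p": fisher_exact_two_tailed([[a, b], [c, d]]),
            "prop_cast_higher_associated": a / (a + b) if a + b else None,
            "prop_cast_higher_unassociated": c / (c + d) if c + d else None,
        })
    return pd.DataFrame(rows)


@dataclass
class TissueComparison:
    """Cross-tissue sharing of isolated cis and trans effects.

    A gene enters the cis comparison only if it is classified cis in one
    tissue and conserved-or-cis in the other (symmetrically for trans);
    genes switching between cis and trans are excluded from both.
    """

    shared_cis: list[str] = field(default_factory=list)
    cis_only_a: list[str] = field(default_factory=list)
    cis_only_b: list[str] = field(default_factory=list)
    shared_trans: list[str] = field(default_factory=list)
    trans_only_a: list[str] = field(default_factory=list)
    trans_only_b: list[str] = field(default_factory=list)
    pearson_r_f0: float | None = None
    pearson_r_f1: float | None = None

    @property
    def cis_tissue_specific_fraction(self) -> float | None:
        n = len(self.shared_cis) + len(self.cis_only_a) + len(self.cis_only_b)
        if n == 0:
            return None
        return (len(self.cis_only_a) + len(self.cis_only_b)) / n

    @property
    def trans_tissue_specific_fraction(self) -> float | None:
        n = (len(self.shared_trans) + len(self.trans_only_a)
             + len(self.trans_only_b))
        if n == 0:
            return None
        return (len(self.trans_only_a) + len(self.trans_only_b)) / n


def compare_tissues(
    class_a: Mapping[str, str],
    class_b: Mapping[str, str],
    effects_a: pd.DataFrame | None = None,
    effects_b: pd.DataFrame | None = None,
) -> TissueComparison:
    """Compare per-gene classifications (gene_id -> winner) between two
    tissues and correlate weighted fold changes over shared-cis genes.

    ``effects_a`` / ``effects_b`` are effect tables (gene_id, x, y); the
    Pearson correlations over shared-cis genes use the F0-based y values
    (pearson_r_f0) and the F1-based x values (pearson_r_f1).
    """
    both = set(class_a) & set(class_b)
    comp = TissueComparison()
    for g in sorted(both):
        ca, cb = class_a[g], class_b[g]
        if ca == "cis" and cb == "cis":
            comp.shared_cis.append(g)
        elif ca == "cis" and cb == "conserved":
            comp.cis_only_a.append(g)
        elif cb == "cis" and ca == "conserved":
            comp.cis_only_b.append(g)
        if ca == "trans" and cb == "trans":
            comp.shared_trans.append(g)
        elif ca == "trans" and cb == "conserved":
            comp.trans_only_a.append(g)
        elif cb == "trans" and ca == "conserved":
            comp.trans_only_b.append(g)
    if effects_a is not None and effects_b is not None and comp.shared_cis:
        ea = effects_a.set_index("gene_id").loc[comp.shared_cis]
        eb = effects_b.set_index("gene_id").loc[comp.shared_cis]
        if len(comp.shared_cis) >= 2:
            comp.pearson_r_f0 = float(stats.pearsonr(ea["y"], eb["y"])[0])
            comp.pearson_r_f1 = float(stats.pearsonr(ea["x"], eb["x"])[0])
    return comp
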