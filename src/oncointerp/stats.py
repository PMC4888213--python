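"""Cohort and per-tumor statistics.

Covers: mutation frequency per megabase, the six-class substitution
spectrum (pyrimidine convention), tumor purity from the somatic
allelic-fraction distribution, CNA-expression support calls, cross-platform
CNA concordance on a break-union genome partition with length-weighted
Pearson correlation, Kolmogorov-Smirnov group comparison, expression level
calls against a reference distribution, fold changes, and nearest-centroid
intrinsic-subtype classification.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

from oncointerp.errors import DomainError
from oncointerp.knowledgebase import GeneLocus
from oncointerp.variant_model import (
    CNASegment,
    ExpressionRecord,
    SomaticVariant,
    SPECTRUM_CLASSES,
    classify_substitution,
)

# ---------------------------------------------------------------------------
# mutation frequency and spectrum
# ---------------------------------------------------------------------------

#: Consequences counted toward the mutations/Mb statistic: non-synonymous
#: SNVs and SNVs altering canonical splice sites.
_FREQUENCY_CONSEQUENCES = frozenset({"missense", "nonsense", "splice_site"})


def mutation_frequency(
    variants: Sequence[SomaticVariant], coding_target_mb: float
) -> float:
    """Somatic mutations per megabase of coding target territory.

    Only non-synonymous SNVs and splice-site SNVs whose impact is on a
    canonical protein isoform are counted; the count is divided by the
    coding-exon area (in Mb) of the sequencing target regions.
    """
    if coding_target_mb <= 0:
        raise DomainError("coding_target_mb must be positive")
    n = sum(
        1
        for v in variants
        if v.is_snv and v.canonical_isoform and v.consequence in _FREQUENCY_CONSEQUENCES
    )
    return n / coding_target_mb


@dataclass(frozen=True)
class SpectrumProfile:
    counts: dict[str, int]
    total: int

    @property
    def fractions(self) -> dict[str, float]:
        if self.total == 0:
            return {c: 0.0 for c in SPECTRUM_CLASSES}
        return {c: self.counts[c] / self.total for c in SPECTRUM_CLASSES}


def spectrum(variants: Sequence[SomaticVariant]) -> SpectrumProfile:
    """Six-class substitution spectrum of a tumor's SNVs (indels excluded)."""
    counts = {c: 0 for c in SPECTRUM_CLASSES}
    total = 0
    for v in variants:
        if not v.is_snv:
            continue
        counts[classify_substitution(v.ref, v.alt)] += 1
        total += 1
    return SpectrumProfile(counts=counts, total=total)


# ---------------------------------------------------------------------------
# tumor purity from allelic fractions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PurityEstimate:
    purity: float
    low_purity: bool  # < 5 %
    reliable: bool  # >= 10 allelic fractions supplied


def _two_cluster_split(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Exact 1-D 2-means: minimize within-cluster sum of squares over all
    sorted split points; returns (lower, upper) clusters."""
    x = np.sort(values)
    n = len(x)
    if n == 1:
        return x[:0], x
    best_k, best_cost = 1, np.inf
    for k in range(1, n):
        lo, hi = x[:k], x[k:]
        cost = ((lo - lo.mean()) ** 2).sum() + ((hi - hi.mean()) ** 2).sum()
        if cost < best_cost - 1e-15:
            best_cost, best_k = cost, k
    return x[:best_k], x[best_k:]


def estimate_purity(afs: Sequence[float]) -> PurityEstimate:
    """Estimate tumor purity from the somatic allelic-fraction distribution.

    Under a diploid-heterozygous model a clonal somatic mutation sits at
    AF = purity/2, so purity = min(1, 2 x the center of the clonal AF
    cluster).  The clonal cluster is taken as the upper of two clusters from
    an exact 1-D two-cluster split of the AFs, and its center as the median
    (robust to outliers).  Fewer than 10 AFs flag the result unreliable;
    purity below 5 % sets ``low_purity``.
    """
    arr = np.asarray(list(afs), dtype=float)
    if arr.size == 0:
        raise DomainError("cannot estimate purity from zero allelic fractions")
    if np.any((arr < 0) | (arr > 1)):
        raise DomainError("allelic fractions must lie in [0, 1]")
    _, upper = _two_cluster_split(arr)
    purity = min(1.0, 2.0 * float(np.median(upper)))
    return PurityEstimate(
        purity=purity, low_purity=purity < 0.05, reliable=arr.size >= 10
    )


# ---------------------------------------------------------------------------
# CNA / expression support
# ---------------------------------------------------------------------------


def cna_expression_support(
    segment: CNASegment,
    locus: GeneLocus,
    expr: ExpressionRecord | None,
) -> str:
    """Judge whether expression supports a CNA call on a gene.

    ``supported``: gain with high expression or loss with low expression;
    ``untestable``: no expression record; ``unsupported`` otherwise.  The
    segment must overlap the gene's locus.
    """
    if not segment.overlaps(locus.chrom, locus.start, locus.end):
        raise DomainError(
            f"segment {segment.chrom}:{segment.start}-{segment.end} does not "
            f"overlap {locus.gene}"
        )
    if expr is None or expr.level == "unknown":
        return "untestable"
    if (segment.call == "gain" and expr.level == "high") or (
        segment.call == "loss" and expr.level == "low"
    ):
        return "supported"
    return "unsupported"


# ---------------------------------------------------------------------------
# cross-platform CNA concordance
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Partition:
    chrom: str
    start: int
    end: int
    seg_a: CNASegment
    seg_b: CNASegment

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class ConcordanceResult:
    r_log2ratio: float  # NaN when undefined (zero variance)
    r_log2mbaf: float
    partitions: tuple[Partition, ...]
    ks: tuple[float, float] | None = None  # (D, p) when a group comparison ran


def _check_non_overlapping(segs: Sequence[CNASegment], label: str) -> None:
    by_chrom: dict[str, list[CNASegment]] = {}
    for s in segs:
        by_chrom.setdefault(s.chrom, []).append(s)
    for chrom, group in by_chrom.items():
        group = sorted(group, key=lambda s: s.start)
        for prev, cur in zip(group, group[1:]):
            if cur.start <= prev.end:
                raise DomainError(
                    f"segments overlap within input {label} on {chrom}: "
                    f"{prev.start}-{prev.end} and {cur.start}-{cur.end}"
                )


def partition_genome(
    segs_a: Sequence[CNASegment], segs_b: Sequence[CNASegment]
) -> list[Partition]:
    """Split the genome territory covered by both inputs at every segment
    break from either input.

    Each resulting partition begins and ends on a break from one of the two
    assays, contains no break inside, and therefore overlaps exactly one
    segment from each input.  Partitions tile the intersection of the two
    covered territories without overlap.
    """
    _check_non_overlapping(segs_a, "A")
    _check_non_overlapping(segs_b, "B")
    partitions = []
    for a in segs_a:
        for b in segs_b:
            if a.chrom != b.chrom:
                continue
            start, end = max(a.start, b.start), min(a.end, b.end)
            if start <= end:
                partitions.append(Partition(a.chrom, start, end, a, b))
    partitions.sort(key=lambda p: (p.chrom, p.start))
    return partitions


def _weighted_pearson(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> float:
    w = w / w.sum()
    mx, my = np.sum(w * x), np.sum(w * y)
    cov = np.sum(w * (x - mx) * (y - my))
    vx, vy = np.sum(w * (x - mx) ** 2), np.sum(w * (y - my) ** 2)
    if vx <= 0 or vy <= 0:
        warnings.warn("zero variance on one platform; weighted correlation undefined")
        return float("nan")
    return float(cov / np.sqrt(vx * vy))


def weighted_concordance(partitions: Sequence[Partition]) -> ConcordanceResult:
    """Length-weighted Pearson correlation of per-partition segment
    statistics between the two platforms (log2ratio and log2mBAF)."""
    if len(partitions) < 2:
        raise DomainError("need >= 2 partitions for a correlation")
    w = np.array([p.length for p in partitions], dtype=float)
    ra = np.array([p.seg_a.log2ratio for p in partitions])
    rb = np.array([p.seg_b.log2ratio for p in partitions])
    ba = np.array([p.seg_a.log2mbaf for p in partitions])
    bb = np.array([p.seg_b.log2mbaf for p in partitions])
    return ConcordanceResult(
        r_log2ratio=_weighted_pearson(ra, rb, w),
        r_log2mbaf=_weighted_pearson(ba, bb, w),
        partitions=tuple(partitions),
    )


def ks_compare(
    group_a: Sequence[float], group_b: Sequence[float]
) -> tuple[float, float]:
    """Two-sided two-sample Kolmogorov-Smirnov test (D statistic and exact
    p value when sample sizes permit), e.g. for FFPE- versus frozen-derived
    concordance distributions."""
    if len(group_a) == 0 or len(group_b) == 0:
        raise DomainError("both groups must be non-empty")
    res = sp_stats.ks_2samp(group_a, group_b, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# expression levels, fold change, subtype call
# ---------------------------------------------------------------------------


def expression_level(
    value: float,
    reference_values: Sequence[float],
    high_quantile: float = 0.75,
    low_quantile: float = 0.25,
) -> str:
    """Summarize an expression value as high/low/intermediate relative to a
    reference distribution (e.g. a public tumor compendium)."""
    ref = np.asarray(list(reference_values), dtype=float)
    if ref.size == 0:
        raise DomainError("reference distribution must be non-empty")
    if not (0 <= low_quantile < high_quantile <= 1):
        raise DomainError("need 0 <= low_quantile < high_quantile <= 1")
    hi = np.quantile(ref, high_quantile)
    lo = np.quantile(ref, low_quantile)
    if value > hi:
        return "high"
    if value < lo:
        return "low"
    return "intermediate"


def fold_change(
    tumor_value: float, normal_value: float, pseudocount: float | None = None
) -> float:
    """Tumor/normal expression ratio; optional pseudocount added to both."""
    if pseudocount is not None:
        if pseudocount <= 0:
            raise DomainError("pseudocount must be positive")
        return (tumor_value + pseudocount) / (normal_value + pseudocount)
    if normal_value <= 0:
        raise DomainError("normal_value must be positive (or supply a pseudocount)")
    return tumor_value / normal_value


def subtype_by_centroid(
    expression: Mapping[str, float] | pd.Series,
    centroids: pd.DataFrame,
    order: Sequence[str] | None = None,
) -> str:
    """Nearest-centroid subtype call by Spearman correlation.

    ``centroids`` is a genes x subtypes table (e.g. the 50-gene intrinsic
    breast-cancer signature with luminal A / luminal B / HER2-enriched /
    basal-like / normal-like columns).  At least half the signature genes
    must be present; the label whose centroid correlates best (Spearman,
    over shared genes) is returned, ties broken by the first label in
    declared order with a warning.
    """
    vec = pd.Series(expression, dtype=float)
    shared = centroids.index.intersection(vec.index)
    if len(shared) < 0.5 * len(centroids.index):
        raise DomainError(
            f"only {len(shared)}/{len(centroids.index)} signature genes present"
        )
    labels = list(order) if order is not None else list(centroids.columns)
    cors = {}
    for label in labels:
        rho = sp_stats.spearmanr(vec.loc[shared], centroids.loc[shared, label]).statistic
        cors[label] = -2.0 if np.isnan(rho) else float(rho)
    best = max(cors.values())
    winners = [lab for lab in labels if cors[lab] >= best - 1e-12]
    if len(winners) > 1:
        warnings.warn(f"subtype tie between {winners}; keeping {winners[0]}")
    return winners[0]


# ---------------------------------------------------------------------------
# TSV exports
# ---------------------------------------------------------------------------


def per_tumor_stats_table(
    tumors: Mapping[str, Sequence[SomaticVariant]], coding_target_mb: float
) -> pd.DataFrame:
    """One row per tumor: mutations/Mb plus the six spectrum fractions."""
    rows = []
    for tumor_id, variants in tumors.items():
        sp = spectrum(variants)
        row = {
            "tumor": tumor_id,
            "mutations_per_mb": mutation_frequency(variants, coding_target_mb),
            "n_snv": sp.total,
        }
        row.update({f"frac[{c}]": f for c, f in sp.fractions.items()})
        rows.append(row)
    return pd.DataFrame(rows)


def concordance_table(
    results: Mapping[str, ConcordanceResult], platform_pair: str = "wes-vs-array"
) -> pd.DataFrame:
    rows = [
        {
            "tumor": tumor,
            "platform_pair": platform_pair,
            "r_log2ratio": res.r_log2ratio,
            "r_log2mbaf": res.r_log2mbaf,
            "n_partitions": len(res.partitions),
        }
        for tumor, res in results.items()
    ]
    return pd.DataFrame(rows)
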