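"""Mutation statistics, purity, CNA concordance, KS, expression, subtyping."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sp_stats

from oncointerp.errors import DomainError
from oncointerp.knowledgebase import GeneLocus
from oncointerp.stats import (
    ConcordanceResult,
    cna_expression_support,
    estimate_purity,
    expression_level,
    fold_change,
    ks_compare,
    mutation_frequency,
    partition_genome,
    spectrum,
    subtype_by_centroid,
    weighted_concordance,
)
from oncointerp.synthetic import CohortConfig, generate_cohort
from oncointerp.variant_model import CNASegment, ExpressionRecord, SomaticVariant


def _snv(ref="G", alt="A", consequence="missense", canonical=True, pos=100):
    return SomaticVariant("chr1", pos, ref, alt, gene="X",
                          consequence=consequence, canonical_isoform=canonical)


# ---------------------------------------------------------------------------
# mutation frequency
# ---------------------------------------------------------------------------


def test_mutation_frequency_is_count_over_area():
    variants = [_snv(pos=i + 1) for i in range(70)]
    assert mutation_frequency(variants, 35.0) == pytest.approx(2.0)
    assert mutation_frequency([], 35.0) == 0.0
    with pytest.raises(DomainError):
        mutation_frequency(variants, 0.0)


def test_mutation_frequency_counts_only_qualifying_snvs():
    variants = [
        _snv(consequence="missense"),
        _snv(consequence="nonsense"),
        _snv(consequence="splice_site"),
        _snv(consequence="synonymous"),          # excluded
        _snv(consequence="missense", canonical=False),  # excluded
        SomaticVariant("chr1", 7, "GA", "G", gene="X",
                       consequence="frameshift"),  # indel, excluded
    ]
    assert mutation_frequency(variants, 1.0) == 3.0


def test_generated_cohort_recovers_target_median_mutation_rate():
    """19 simulated tumors at a configured median of 2.7/Mb."""
    config = CohortConfig(
        n_patients=19,
        seed=7,
        cancer_type_mixture={"colorectal": 1.0},
        mutations_per_mb_median=2.7,
        coding_target_mb=35.0,
    )
    cohort = generate_cohort(config)
    rates = [mutation_frequency(p.somatic, 35.0) for p in cohort]
    assert np.median(rates) == pytest.approx(2.7, rel=0.10)


# ---------------------------------------------------------------------------
# spectrum
# ---------------------------------------------------------------------------


def test_spectrum_of_pure_ga_snvs_is_all_ct():
    prof = spectrum([_snv("G", "A", pos=i + 1) for i in range(10)])
    assert prof.fractions["C>T"] == 1.0 and prof.total == 10


def test_spectrum_uniform_over_all_twelve_ordered_substitutions():
    import itertools

    variants = [
        SomaticVariant("chr1", i + 1, r, a, gene="X")
        for i, (r, a) in enumerate(itertools.permutations("ACGT", 2))
    ]
    prof = spectrum(variants)
    assert all(f == pytest.approx(1 / 6) for f in prof.fractions.values())


def test_spectrum_invariant_under_reordering_and_fractions_sum_to_one():
    rng = np.random.default_rng(5)
    bases = "ACGT"
    variants = []
    for i in range(60):
        r, a = rng.choice(list(bases), size=2, replace=False)
        variants.append(SomaticVariant("chr1", i + 1, str(r), str(a), gene="X"))
    fwd = spectrum(variants)
    rev = spectrum(variants[::-1])
    assert fwd.counts == rev.counts
    assert sum(fwd.fractions.values()) == pytest.approx(1.0, abs=1e-9)


def test_generated_spectrum_recovers_configured_weights_within_3_sigma():
    weights = (0.05, 0.05, 0.70, 0.05, 0.10, 0.05)
    config = CohortConfig(
        n_patients=1,
        seed=11,
        cancer_type_mixture={"colorectal": 1.0},
        spectrum_weights=weights,
        mutations_per_mb_median=500 / 35.0,
        mutation_rate_sigma=0.0,
        coding_target_mb=35.0,
    )
    cohort = generate_cohort(config)
    prof = spectrum(cohort[0].somatic)
    n = prof.total
    assert n > 300
    for cls, w in zip(sorted(prof.counts), weights):
        sigma = np.sqrt(w * (1 - w) / n)
        assert abs(prof.fractions[cls] - w) < 3 * sigma + 1e-12


# ---------------------------------------------------------------------------
# purity
# ---------------------------------------------------------------------------


def test_purity_diploid_het_limits():
    assert estimate_purity([0.5] * 20).purity == pytest.approx(1.0)
    est = estimate_purity([0.125] * 20)
    assert est.purity == pytest.approx(0.25)
    assert not est.low_purity and est.reliable


def test_purity_below_five_percent_is_flagged():
    est = estimate_purity([0.02] * 30)
    assert est.low_purity and est.purity == pytest.approx(0.04)


def test_purity_few_afs_flagged_unreliable_and_empty_rejected():
    assert not estimate_purity([0.3] * 5).reliable
    with pytest.raises(DomainError):
        estimate_purity([])


def test_purity_recovered_from_generated_tumor_within_tenth():
    config = CohortConfig(
        n_patients=1,
        seed=13,
        cancer_type_mixture={"colorectal": 1.0},
        mutations_per_mb_median=200 / 35.0,
        mutation_rate_sigma=0.0,
        purity_mean=0.6,
        purity_sd=0.0,
        depth_mean=100.0,
    )
    cohort = generate_cohort(config)
    afs = [v.af for v in cohort[0].somatic if v.af is not None]
    assert len(afs) > 100
    assert estimate_purity(afs).purity == pytest.approx(0.6, abs=0.1)


def test_purity_invariant_to_depth_scaling():
    rng = np.random.default_rng(2)
    alts = rng.binomial(100, 0.3, size=50)
    afs_1x = [a / 100 for a in alts]
    afs_10x = [(10 * a) / 1000 for a in alts]
    assert estimate_purity(afs_1x).purity == estimate_purity(afs_10x).purity


# ---------------------------------------------------------------------------
# CNA-expression support
# ---------------------------------------------------------------------------

_LOCUS = GeneLocus("CCND1", "chr11", 69455873, 69455873 + 3 * 295 - 1)


def _seg(call, chrom="chr11", start=69400000, end=69500000):
    return CNASegment(chrom, start, end, 1.2 if call == "gain" else -1.1, 0.4, call)


def test_gain_with_high_expression_is_supported():
    expr = ExpressionRecord("CCND1", 60.0, 1.0, "high")
    assert cna_expression_support(_seg("gain"), _LOCUS, expr) == "supported"


def test_gain_with_low_expression_is_unsupported():
    expr = ExpressionRecord("CCND1", 0.2, 1.0, "low")
    assert cna_expression_support(_seg("gain"), _LOCUS, expr) == "unsupported"


def test_missing_expression_is_untestable_and_overlap_required():
    assert cna_expression_support(_seg("gain"), _LOCUS, None) == "untestable"
    with pytest.raises(DomainError):
        cna_expression_support(_seg("gain", chrom="chr1"), _LOCUS, None)


# ---------------------------------------------------------------------------
# genome partitioning
# ---------------------------------------------------------------------------


def _plain_seg(chrom, start, end, value=0.0, platform="wes"):
    return CNASegment(chrom, start, end, value, value / 2, "normal", platform)


def test_identical_single_segments_give_one_partition():
    a = [_plain_seg("chr1", 1, 100)]
    b = [_plain_seg("chr1", 1, 100, platform="array")]
    parts = partition_genome(a, b)
    assert len(parts) == 1 and (parts[0].start, parts[0].end) == (1, 100)


def test_partition_splits_at_every_break():
    a = [_plain_seg("chr1", 1, 100)]
    b = [_plain_seg("chr1", 1, 50, platform="array"),
         _plain_seg("chr1", 51, 100, platform="array")]
    parts = partition_genome(a, b)
    assert [(p.start, p.end) for p in parts] == [(1, 50), (51, 100)]


def test_overlapping_segments_within_one_input_rejected():
    a = [_plain_seg("chr1", 1, 100), _plain_seg("chr1", 50, 150)]
    with pytest.raises(DomainError):
        partition_genome(a, [_plain_seg("chr1", 1, 100)])


def _brute_force_partitions(segs_a, segs_b):
    """Oracle: per chromosome, cut the covered intersection at the union of
    all segment boundaries and keep pieces covered by both inputs."""
    out = []
    chroms = {s.chrom for s in segs_a} & {s.chrom for s in segs_b}
    for chrom in chroms:
        sa = [s for s in segs_a if s.chrom == chrom]
        sb = [s for s in segs_b if s.chrom == chrom]
        cuts = sorted(
            {s.start for s in sa + sb} | {s.end + 1 for s in sa + sb}
        )
        for lo, hi in zip(cuts, cuts[1:]):
            in_a = next((s for s in sa if s.start <= lo and hi - 1 <= s.end), None)
            in_b = next((s for s in sb if s.start <= lo and hi - 1 <= s.end), None)
            if in_a and in_b:
                out.append((chrom, lo, hi - 1, id(in_a), id(in_b)))
    return sorted(out)


def _random_segments(rng, chrom, platform):
    segs, pos = [], 1
    for _ in range(rng.integers(2, 8)):
        start = pos + int(rng.integers(0, 50))
        end = start + int(rng.integers(1, 200))
        segs.append(_plain_seg(chrom, start, end, float(rng.normal()), platform))
        pos = end + 1
    return segs


def test_partitioning_matches_brute_force_boundary_union():
    rng = np.random.default_rng(17)
    for _ in range(20):
        a = _random_segments(rng, "chr1", "wes") + _random_segments(rng, "chr2", "wes")
        b = _random_segments(rng, "chr1", "array") + _random_segments(rng, "chr2", "array")
        got = sorted(
            (p.chrom, p.start, p.end, id(p.seg_a), id(p.seg_b))
            for p in partition_genome(a, b)
        )
        assert got == _brute_force_partitions(a, b)


def test_partition_lengths_conserve_covered_intersection():
    rng = np.random.default_rng(23)
    a = _random_segments(rng, "chr1", "wes")
    b = _random_segments(rng, "chr1", "array")
    parts = partition_genome(a, b)
    covered = 0
    for sa in a:
        for sb in b:
            covered += max(0, min(sa.end, sb.end) - max(sa.start, sb.start) + 1)
    assert sum(p.length for p in parts) == covered


# ---------------------------------------------------------------------------
# weighted concordance
# ---------------------------------------------------------------------------


def _paired_partitions(values_a, values_b, lengths):
    segs_a, segs_b, pos = [], [], 1
    for va, vb, ln in zip(values_a, values_b, lengths):
        segs_a.append(_plain_seg("chr1", pos, pos + ln - 1, float(va)))
        segs_b.append(_plain_seg("chr1", pos, pos + ln - 1, float(vb), "array"))
        pos += ln
    return partition_genome(segs_a, segs_b)


def test_identical_platforms_give_perfect_correlation():
    vals = [0.1, -0.5, 0.9, 0.0]
    res = weighted_concordance(_paired_partitions(vals, vals, [10, 20, 30, 40]))
    assert res.r_log2ratio == pytest.approx(1.0)
    assert res.r_log2mbaf == pytest.approx(1.0)


def test_negated_platform_gives_minus_one():
    vals = [0.1, -0.5, 0.9, 0.0]
    res = weighted_concordance(
        _paired_partitions(vals, [-v for v in vals], [10, 20, 30, 40])
    )
    assert res.r_log2ratio == pytest.approx(-1.0)


def test_weighted_pearson_matches_direct_formula_oracle():
    rng = np.random.default_rng(31)
    x = rng.normal(size=12)
    y = 0.6 * x + rng.normal(size=12)
    w = rng.integers(5, 500, size=12)
    res = weighted_concordance(_paired_partitions(x, y, list(w)))

    # direct plain-python weighted-covariance oracle
    wt = [float(v) / float(np.sum(w)) for v in w]
    mx = sum(wi * xi for wi, xi in zip(wt, x))
    my = sum(wi * yi for wi, yi in zip(wt, y))
    cov = sum(wi * (xi - mx) * (yi - my) for wi, xi, yi in zip(wt, x, y))
    vx = sum(wi * (xi - mx) ** 2 for wi, xi in zip(wt, x))
    vy = sum(wi * (yi - my) ** 2 for wi, yi in zip(wt, y))
    assert res.r_log2ratio == pytest.approx(cov / np.sqrt(vx * vy), abs=1e-12)


def test_equal_lengths_reduce_to_unweighted_pearson():
    rng = np.random.default_rng(37)
    x, y = rng.normal(size=10), rng.normal(size=10)
    res = weighted_concordance(_paired_partitions(x, y, [50] * 10))
    assert res.r_log2ratio == pytest.approx(sp_stats.pearsonr(x, y).statistic, abs=1e-12)


def test_zero_variance_reports_nan_with_warning():
    with pytest.warns(UserWarning, match="zero variance"):
        res = weighted_concordance(_paired_partitions([1, 1, 1], [0.2, 0.5, 0.9], [5, 5, 5]))
    assert np.isnan(res.r_log2ratio)


# ---------------------------------------------------------------------------
# KS comparison
# ---------------------------------------------------------------------------


def test_ks_identical_samples_have_zero_distance():
    sample = [0.1, 0.4, 0.5, 0.8]
    d, p = ks_compare(sample, sample)
    assert d == 0.0 and p == pytest.approx(1.0)


def test_ks_disjoint_supports_have_distance_one():
    d, _ = ks_compare([1, 2, 3, 4, 5], [10, 11, 12, 13, 14])
    assert d == 1.0


def test_ks_statistic_matches_ecdf_gap_oracle():
    a = [0.12, 0.5, 0.55, 0.8]
    b = [0.1, 0.3, 0.77, 0.9, 0.95]

    def ecdf(sample, x):
        return sum(v <= x for v in sample) / len(sample)

    grid = sorted(a + b)
    oracle = max(abs(ecdf(a, x) - ecdf(b, x)) for x in grid)
    d, _ = ks_compare(a, b)
    assert d == pytest.approx(oracle, abs=1e-12)


def test_ks_empty_group_rejected():
    with pytest.raises(DomainError):
        ks_compare([], [1.0])


# ---------------------------------------------------------------------------
# expression level, fold change
# ---------------------------------------------------------------------------


def test_expression_level_quantile_calls():
    ref = list(np.arange(1, 101, dtype=float))
    assert expression_level(200.0, ref) == "high"
    assert expression_level(0.5, ref) == "low"
    assert expression_level(50.0, ref, 0.75, 0.25) == "intermediate"
    with pytest.raises(DomainError):
        expression_level(1.0, [])


def test_fold_change_arithmetic_and_pseudocount():
    assert fold_change(113.0, 1.0) == pytest.approx(113.0)
    assert fold_change(5.0, 5.0) == pytest.approx(1.0)
    assert fold_change(0.0, 1.0, pseudocount=0.5) == pytest.approx(0.5 / 1.5)
    with pytest.raises(DomainError):
        fold_change(1.0, 0.0)


# ---------------------------------------------------------------------------
# subtype by centroid
# ---------------------------------------------------------------------------

_SUBTYPES = ["luminal A", "luminal B", "HER2 enriched", "basal-like", "normal-like"]


def _centroid_matrix(rng, n_genes=50):
    genes = [f"SIG{i:02d}" for i in range(n_genes)]
    data = rng.normal(size=(n_genes, len(_SUBTYPES)))
    return pd.DataFrame(data, index=genes, columns=_SUBTYPES)


def test_vector_equal_to_centroid_returns_its_label():
    rng = np.random.default_rng(41)
    centroids = _centroid_matrix(rng)
    for label in _SUBTYPES:
        assert subtype_by_centroid(centroids[label], centroids) == label


def test_negated_centroid_is_not_called_as_itself():
    rng = np.random.default_rng(43)
    centroids = _centroid_matrix(rng)
    assert subtype_by_centroid(-centroids["basal-like"], centroids) != "basal-like"


def test_noisy_vectors_recover_their_subtype():
    rng = np.random.default_rng(47)
    centroids = _centroid_matrix(rng)
    correct = 0
    n = 50
    for i in range(n):
        label = _SUBTYPES[i % len(_SUBTYPES)]
        noisy = centroids[label] + rng.normal(scale=0.3, size=len(centroids))
        if subtype_by_centroid(noisy, centroids) == label:
            correct += 1
    assert correct / n >= 0.95


def test_insufficient_gene_overlap_rejected():
    rng = np.random.default_rng(53)
    centroids = _centroid_matrix(rng)
    vec = centroids["luminal A"].iloc[:10]  # only 20 % of signature genes
    with pytest.raises(DomainError):
        subtype_by_centroid(vec, centroids)


def test_tie_broken_by_declared_order_with_warning():
    genes = ["G1", "G2", "G3", "G4"]
    centroids = pd.DataFrame(
        {"alpha": [1.0, 2.0, 3.0, 4.0], "beta": [1.0, 2.0, 3.0, 4.0]}, index=genes
    )
    vec = pd.Series([1.0, 2.0, 3.0, 4.0], index=genes)
    with pytest.warns(UserWarning, match="tie"):
        assert subtype_by_centroid(vec, centroids) == "alpha"
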