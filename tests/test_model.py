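"""Unit and property tests for the genotype-pair likelihood engine."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from _oracle import brute_force_posterior
from conftest import random_site
from tinvar.model import (
    DegenerateLocusError,
    CopyNumberSegment,
    GenotypeLabel,
    GenotypePair,
    ModelParams,
    SiteObservation,
    SitePosterior,
    classify_site,
    enumerate_genotype_pairs,
    read_prob,
    sample_log_likelihood,
    site_posterior,
    tumour_read_fraction,
)


@pytest.mark.parametrize(
    "alpha, cn_t, cn_n, expected",
    [
        (0.5, 2, 2, 0.5),       # symmetric copy numbers
        (0.0, 3, 2, 0.0),       # no aberrant cells
        (0.5, 4, 2, 2.0 / 3.0),  # amplified tumour contributes more reads
        (1.0, 3, 2, 1.0),
    ],
)
def test_tumour_read_fraction(alpha, cn_t, cn_n, expected):
    assert tumour_read_fraction(alpha, cn_t, cn_n) == pytest.approx(expected, abs=1e-12)


def test_tumour_read_fraction_degenerate_locus():
    with pytest.raises(DegenerateLocusError):
        tumour_read_fraction(1.0, 0, 2)
    with pytest.raises(DegenerateLocusError):
        tumour_read_fraction(0.0, 3, 0)


@pytest.mark.parametrize(
    "is_alt, e, f_t, f_g, pi, expected",
    [
        (True, 0.0, 1.0, 1.0, 0.3, 1.0),          # error-free homozygous alt
        (True, 0.01, 0.0, 0.0, 0.7, 0.01 / 3),    # alt only via sequencing error
        (True, 0.0, 0.5, 0.0, 0.2, 0.1),          # pi * f_t
        (False, 0.0, 0.0, 0.0, 0.5, 1.0),
    ],
)
def test_read_prob(is_alt, e, f_t, f_g, pi, expected):
    assert read_prob(is_alt, e, f_t, f_g, pi) == pytest.approx(expected, abs=1e-12)


@pytest.mark.parametrize(
    "cn_n, cn_t, n_pairs, n_somatic, n_germline",
    [(2, 2, 9, 2, 6), (1, 1, 4, 1, 2), (2, 5, 18, 5, 12)],
)
def test_enumerate_genotype_pairs(cn_n, cn_t, n_pairs, n_somatic, n_germline):
    pairs = enumerate_genotype_pairs(cn_n, cn_t)
    assert len(pairs) == n_pairs
    labels = [p.label for p in pairs]
    assert labels.count(GenotypeLabel.SOMATIC) == n_somatic
    assert labels.count(GenotypeLabel.GERMLINE) == n_germline
    assert labels.count(GenotypeLabel.REF) == 1
    # labels follow the (k_g, k_t) definition exactly
    for p in pairs:
        if p.k_g == 0 and p.k_t == 0:
            assert p.label is GenotypeLabel.REF
        elif p.k_g == 0:
            assert p.label is GenotypeLabel.SOMATIC
        else:
            assert p.label is GenotypeLabel.GERMLINE


class TestSampleLogLikelihood:
    def test_zero_depth_is_empty_product(self, diploid):
        ll = sample_log_likelihood(0, 0, GenotypePair(1, 1), diploid, 0.5, 0.01)
        assert ll == 0.0

    def test_counts_mode_all_alt_under_ref_pair(self, diploid):
        ll = sample_log_likelihood(10, 10, GenotypePair(0, 0), diploid, 0.5, 0.01)
        assert ll == pytest.approx(10 * math.log(0.01 / 3), rel=1e-12)

    def test_counts_mode_matches_explicit_per_read_product(self, diploid):
        # depth 30, 15 alt reads under the heterozygous pair at alpha = 0.5
        pair, alpha, e = GenotypePair(1, 1), 0.5, 0.01
        ll = sample_log_likelihood(15, 30, pair, diploid, alpha, e)
        pi = alpha * 2 / (alpha * 2 + (1 - alpha) * 2)
        expected = 1.0
        for _ in range(15):
            expected *= pi * (0.5 * (1 - e) + 0.5 * e / 3) + (1 - pi) * (0.5 * (1 - e) + 0.5 * e / 3)
        for _ in range(15):
            expected *= pi * (0.5 * (1 - e) + 0.5 * e / 3) + (1 - pi) * (0.5 * (1 - e) + 0.5 * e / 3)
        assert ll == pytest.approx(math.log(expected), abs=1e-10)

    def test_per_read_qualities_override_fixed_error(self, diploid):
        # Phred 20 == error 0.01, so a uniform-quality read list must agree
        # exactly with counts mode at base_error 0.01
        quals = [(True, 20.0)] * 5 + [(False, 20.0)] * 15
        ll_q = sample_log_likelihood(5, 20, GenotypePair(0, 1), diploid, 0.8, 0.123, quals)
        ll_c = sample_log_likelihood(5, 20, GenotypePair(0, 1), diploid, 0.8, 0.01)
        assert ll_q == pytest.approx(ll_c, abs=1e-12)

    def test_impossible_reads_give_neg_inf_not_raise(self):
        cn = CopyNumberSegment("1", 1, 100, cn_normal=2, cn_tumour=2)
        site_params_error = 1e-300  # effectively zero error
        ll = sample_log_likelihood(
            5, 10, GenotypePair(0, 0), cn, 0.5, site_params_error
        )
        assert ll == float("-inf") or ll < -3000


class TestSitePosterior:
    def _site(self, t_alt, t_depth, n_alt, n_depth):
        return SiteObservation("1", 500, "A", "T", t_depth, t_alt, n_depth, n_alt)

    def test_clean_reference_site(self, diploid):
        params = ModelParams(alpha_t=0.8, alpha_n=0.10)
        post = site_posterior(self._site(0, 40, 0, 40), diploid, params)
        assert post.map_pair == GenotypePair(0, 0)
        assert post.p_somatic < 1e-3
        assert post.classification is GenotypeLabel.REF

    def test_het_in_both_samples_is_germline(self, diploid):
        params = ModelParams(alpha_t=0.8, alpha_n=0.10)
        post = site_posterior(self._site(18, 40, 20, 40), diploid, params)
        assert post.classification is GenotypeLabel.GERMLINE

    def test_tin_consistent_normal_support_stays_somatic(self, diploid):
        params = ModelParams(alpha_t=0.8, alpha_n=0.10, base_error=0.01)
        post = site_posterior(self._site(16, 40, 2, 40), diploid, params)
        assert post.classification is GenotypeLabel.SOMATIC
        assert post.p_somatic >= params.somatic_threshold

    @pytest.mark.parametrize("case", range(3))
    def test_examples_match_brute_force(self, diploid, case):
        counts = [(0, 40, 0, 40), (18, 40, 20, 40), (16, 40, 2, 40)]
        params = ModelParams(alpha_t=0.8, alpha_n=0.10)
        site = self._site(*counts[case])
        post = site_posterior(site, diploid, params)
        ref = brute_force_posterior(site, diploid, params)
        for pair, prob in post.pairs:
            assert prob == pytest.approx(ref[(pair.k_g, pair.k_t)], abs=1e-10)

    def test_oracle_equivalence_randomized(self):
        """site_posterior agrees with explicit per-read product enumeration
        on 60 random small sites to 1e-10 per genotype pair."""
        rng = np.random.default_rng(20240917)
        for _ in range(60):
            site, cn, params = random_site(rng)
            post = site_posterior(site, cn, params)
            ref = brute_force_posterior(site, cn, params)
            for pair, prob in post.pairs:
                assert abs(prob - ref[(pair.k_g, pair.k_t)]) <= 1e-10
            assert abs(sum(p for _, p in post.pairs) - 1.0) <= 1e-9


@given(
    t_depth=st.integers(0, 60),
    n_depth=st.integers(0, 60),
    t_frac=st.floats(0, 1),
    n_frac=st.floats(0, 1),
    cn_n=st.integers(1, 4),
    cn_t=st.integers(0, 5),
    alpha_t=st.floats(0.05, 1.0),
    alpha_n=st.floats(0.0, 0.5),
)
@settings(max_examples=150, deadline=None, derandomize=True)
def test_posterior_always_normalized(t_depth, n_depth, t_frac, n_frac,
                                     cn_n, cn_t, alpha_t, alpha_n):
    site = SiteObservation(
        "1", 1, "A", "T",
        t_depth, int(round(t_frac * t_depth)),
        n_depth, int(round(n_frac * n_depth)),
    )
    cn = CopyNumberSegment("1", 1, 10, cn_normal=cn_n, cn_tumour=cn_t)
    params = ModelParams(alpha_t=alpha_t, alpha_n=alpha_n)
    post = site_posterior(site, cn, params)
    assert abs(sum(p for _, p in post.pairs) - 1.0) <= 1e-9
    assert post.p_somatic + post.p_germline <= 1.0 + 1e-9


def test_reduction_to_standard_calling(diploid):
    """With alpha_n = 0 a germline-balanced normal (VAF ~ 0.5) can never
    produce a somatic call, whatever the tumour shows."""
    params = ModelParams(alpha_t=0.8, alpha_n=0.0)
    for depth in (20, 40, 80):
        for t_alt_frac in (0.1, 0.3, 0.5, 0.9):
            site = SiteObservation(
                "1", 1, "A", "T", depth, int(t_alt_frac * depth),
                depth, depth // 2,
            )
            post = site_posterior(site, diploid, params)
            assert post.p_somatic < 0.05
            assert post.classification is not GenotypeLabel.SOMATIC


def test_tin_awareness_raises_somatic_posterior(diploid):
    """Alt support in the normal consistent with 10% TiN must count *for*
    somatic when modelled, against it when not."""
    site = SiteObservation("1", 1, "A", "T", 40, 16, 40, 2)
    base = ModelParams(alpha_t=0.8, alpha_n=0.0)
    p0 = site_posterior(site, diploid, base).p_somatic
    p1 = site_posterior(site, diploid, base.with_alpha_n(0.10)).p_somatic
    assert p1 > p0


def test_posterior_monotone_in_normal_alt_count(diploid):
    """For fixed tumour evidence, more alt reads in the normal can only make
    the somatic explanation less likely (verified against the oracle)."""
    params = ModelParams(alpha_t=0.8, alpha_n=0.10)
    depth = 40
    expected_tin_alts = round(depth * 0.10 * 0.5)  # TiN leakage expectation
    prev = None
    for n_alt in range(expected_tin_alts, depth + 1):
        site = SiteObservation("1", 1, "A", "T", 40, 16, depth, n_alt)
        p = site_posterior(site, diploid, params).p_somatic
        ref = brute_force_posterior(site, diploid, params)
        p_ref = sum(v for (kg, kt), v in ref.items() if kg == 0 and kt >= 1)
        assert p == pytest.approx(p_ref, abs=1e-10)
        if prev is not None:
            assert p <= prev + 1e-12
        prev = p


class TestClassify:
    def _post(self, p_som, p_germ, p_ref):
        pairs = [
            (GenotypePair(0, 0), p_ref),
            (GenotypePair(1, 1), p_germ),
            (GenotypePair(0, 1), p_som),
        ]
        return SitePosterior(pairs, p_som, p_germ, max(pairs, key=lambda t: t[1])[0],
                             GenotypeLabel.UNCLASSIFIED)

    def test_somatic_above_threshold(self):
        assert classify_site(self._post(0.99, 0.005, 0.005), 0.95) is GenotypeLabel.SOMATIC

    def test_split_mass_unclassified(self):
        assert classify_site(self._post(0.5, 0.5, 0.0), 0.95) is GenotypeLabel.UNCLASSIFIED

    def test_all_mass_on_ref(self):
        assert classify_site(self._post(0.0, 0.0, 1.0), 0.95) is GenotypeLabel.REF


def test_site_observation_validation():
    with pytest.raises(ValueError):
        SiteObservation("1", 1, "A", "A", 10, 2, 10, 0)
    with pytest.raises(ValueError):
        SiteObservation("1", 1, "A", "T", 10, 12, 10, 0)
    with pytest.raises(ValueError):
        SiteObservation("1", 1, "A", "T", 2, 1, 2, 0,
                        tumour_quals=[(True, 30.0)])  # length != depth


def test_copy_number_segment_validation():
    with pytest.raises(ValueError):
        CopyNumberSegment("1", 10, 5)
    with pytest.raises(ValueError):
        CopyNumberSegment("1", 1, 5, cn_normal=0, cn_tumour=0)
    with pytest.raises(ValueError):
        CopyNumberSegment("1", 1, 5, cn_tumour=2, cn_major=3)
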