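"""Estimation of the normal-sample aberrant cell fraction (the TiN level).

The estimator profiles the marginal likelihood of the paired read counts over
a one-dimensional grid of alpha_n values: at each candidate site the genotype
pair is marginalized out under the same priors and likelihood as the caller,
so the estimate is exactly the alpha_n under which the calling model best
explains the cohort of candidate sites.  Candidate sites are filtered to be
informative (visible in the tumour, not obviously germline, adequately
covered); the profile maximum gives the point estimate and grid points within
1.92 log-units of it form an approximate 95% profile-likelihood interval.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import logsumexp

from .caller import SegmentIndex
from .model import (
    CopyNumberSegment,
    ModelParams,
    SiteObservation,
    enumerate_genotype_pairs,
    pair_log_priors,
    tumour_read_fraction,
)

logger = logging.getLogger(__name__)

__all__ = ["TinEstimate", "select_candidate_sites", "tin_profile_log_likelihood", "estimate_tin"]


@dataclass
class TinEstimate:
    alpha_n_hat: float
    log_likelihood_profile: list[tuple[float, float]]
    n_sites_used: int
    ci_low: float
    ci_high: float
    low_confidence: bool = False
    uninformative: bool = False


def select_candidate_sites(
    sites: Sequence[SiteObservation],
    segments: Sequence[CopyNumberSegment] | SegmentIndex,
    params: ModelParams,
    vaf_min: float = 0.10,
    normal_vaf_max: float = 0.35,
    min_depth: int = 10,
    min_sites: int = 50,
) -> list[SiteObservation]:
    """Sites informative for TiN: somatic-looking in the tumour (VAF >=
    vaf_min), not germline-like in the normal (VAF <= normal_vaf_max), and
    adequately covered in both samples.  Deterministic; order-preserving."""
    out = []
    for s in sites:
        if s.tumour_depth < min_depth or s.normal_depth < min_depth:
            continue
        if s.tumour_alt / s.tumour_depth < vaf_min:
            continue
        if s.normal_alt / s.normal_depth > normal_vaf_max:
            continue
        out.append(s)
    if len(out) < min_sites:
        logger.warning(
            "only %d candidate sites (< %d); TiN estimate will be low-confidence",
            len(out), min_sites,
        )
    return out


def _group_by_segment(
    sites: Sequence[SiteObservation],
    segments: Sequence[CopyNumberSegment] | SegmentIndex,
) -> dict[tuple[int, int], list[SiteObservation]]:
    index = segments if isinstance(segments, SegmentIndex) else SegmentIndex(segments)
    groups: dict[tuple[int, int], list[SiteObservation]] = {}
    for s in sites:
        seg = index.lookup(s.chrom, s.pos)
        groups.setdefault((seg.cn_normal, seg.cn_tumour), []).append(s)
    return groups


def _counts_matrix(
    alt: np.ndarray, depth: np.ndarray, f_t: np.ndarray, f_g: np.ndarray,
    pi: float, error: float,
) -> np.ndarray:
    """Counts-mode log-likelihood, sites x pairs, vectorized."""
    p_alt = pi * (f_t * (1 - error) + (1 - f_t) * (error / 3)) \
        + (1 - pi) * (f_g * (1 - error) + (1 - f_g) * (error / 3))
    p_ref = pi * ((1 - f_t) * (1 - error) + f_t * (error / 3)) \
        + (1 - pi) * ((1 - f_g) * (1 - error) + f_g * (error / 3))
    return (alt[:, None] * np.log(p_alt)[None, :]
            + (depth - alt)[:, None] * np.log(p_ref)[None, :])


def _group_arrays(group: list[SiteObservation]):
    t_alt = np.array([s.tumour_alt for s in group], dtype=float)
    t_dep = np.array([s.tumour_depth for s in group], dtype=float)
    n_alt = np.array([s.normal_alt for s in group], dtype=float)
    n_dep = np.array([s.normal_depth for s in group], dtype=float)
    return t_alt, t_dep, n_alt, n_dep


def _pair_arrays(cn_normal: int, cn_tumour: int, params: ModelParams):
    pairs = enumerate_genotype_pairs(cn_normal, cn_tumour)
    f_t = np.array([p.k_t / cn_tumour if cn_tumour else 0.0 for p in pairs])
    f_g = np.array([p.k_g / cn_normal if cn_normal else 0.0 for p in pairs])
    log_prior = np.array(pair_log_priors(pairs, params))
    return f_t, f_g, log_prior


def tin_profile_log_likelihood(
    sites: Sequence[SiteObservation],
    segments: Sequence[CopyNumberSegment] | SegmentIndex,
    params: ModelParams,
    alpha_n: float,
) -> float:
    """Total log marginal likelihood of the candidate sites at one alpha_n.

    Per site: log sum over genotype pairs of prior(pair) * exp(L_tumour(pair;
    alpha_t) + L_normal(pair; alpha_n)).  Empty input returns 0.
    """
    total = 0.0
    for (cn_n, cn_t), group in _group_by_segment(sites, segments).items():
        f_t, f_g, log_prior = _pair_arrays(cn_n, cn_t, params)
        t_alt, t_dep, n_alt, n_dep = _group_arrays(group)
        pi_t = tumour_read_fraction(params.alpha_t, cn_t, cn_n)
        pi_n = tumour_read_fraction(alpha_n, cn_t, cn_n)
        mat = (_counts_matrix(t_alt, t_dep, f_t, f_g, pi_t, params.base_error)
               + _counts_matrix(n_alt, n_dep, f_t, f_g, pi_n, params.base_error)
               + log_prior[None, :])
        total += float(logsumexp(mat, axis=1).sum())
    return total


def estimate_tin(
    sites: Sequence[SiteObservation],
    segments: Sequence[CopyNumberSegment] | SegmentIndex,
    params: ModelParams,
    grid_step: float = 0.005,
    alpha_max: float = 0.5,
    preselect: bool = True,
    min_sites: int = 50,
) -> TinEstimate:
    """Grid-search maximum of the TiN profile likelihood.

    Ties break toward the smaller alpha_n (the conservative choice: less
    assumed contamination).  A flat profile — e.g. no informative sites —
    yields alpha_n_hat = 0 flagged uninformative.
    """
    if grid_step <= 0:
        raise ValueError("grid_step must be > 0")
    if alpha_max > 0.5:
        raise ValueError("alpha_max must be <= 0.5")
    index = segments if isinstance(segments, SegmentIndex) else SegmentIndex(segments)
    cand = (select_candidate_sites(sites, index, params, min_sites=min_sites)
            if preselect else list(sites))
    grid = np.arange(0.0, alpha_max + grid_step / 2, grid_step)
    grid = np.minimum(grid, alpha_max)

    # precompute the alpha_n-independent parts once per segment group
    groups = _group_by_segment(cand, index)
    pre = []
    for (cn_n, cn_t), group in groups.items():
        f_t, f_g, log_prior = _pair_arrays(cn_n, cn_t, params)
        t_alt, t_dep, n_alt, n_dep = _group_arrays(group)
        pi_t = tumour_read_fraction(params.alpha_t, cn_t, cn_n)
        t_part = (_counts_matrix(t_alt, t_dep, f_t, f_g, pi_t, params.base_error)
                  + log_prior[None, :])
        pre.append(((cn_n, cn_t), f_t, f_g, t_part, n_alt, n_dep))

    profile = np.zeros(len(grid))
    for i, a in enumerate(grid):
        total = 0.0
        for (cn_n, cn_t), f_t, f_g, t_part, n_alt, n_dep in pre:
            pi_n = tumour_read_fraction(float(a), cn_t, cn_n)
            mat = t_part + _counts_matrix(n_alt, n_dep, f_t, f_g, pi_n,
                                          params.base_error)
            total += float(logsumexp(mat, axis=1).sum())
        profile[i] = total

    prof_list = [(float(a), float(v)) for a, v in zip(grid, profile)]
    if len(cand) == 0 or profile.max() - profile.min() < 1e-6:
        return TinEstimate(
            alpha_n_hat=0.0, log_likelihood_profile=prof_list,
            n_sites_used=len(cand), ci_low=0.0, ci_high=float(alpha_max),
            low_confidence=True, uninformative=True,
        )
    best = int(np.argmax(profile))  # first max on an ascending grid: smallest alpha_n
    in_ci = grid[profile >= profile[best] - 1.92]
    return TinEstimate(
        alpha_n_hat=float(grid[best]),
        log_likelihood_profile=prof_list,
        n_sites_used=len(cand),
        ci_low=float(in_ci.min()),
        ci_high=float(in_ci.max()),
        low_confidence=len(cand) < min_sites,
    )
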