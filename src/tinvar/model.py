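"""Genotype-pair likelihood model for tumour/normal pairs with tumour-in-normal
(TiN) contamination.

The model scores every genotype pair (mutant copies in the normal-cell genome,
mutant copies in the tumour-cell genome) consistent with locus-specific copy
number, treating *both* samples as mixtures of tumour and normal cells: the
tumour sample has aberrant cell fraction ``alpha_t`` and the matched normal has
its own aberrant cell fraction ``alpha_n`` (the TiN level).  A read drawn from
a sample arises from a tumour cell with probability proportional to
``alpha * cn_tumour`` and from a normal cell otherwise; given the cell of
origin, the read reports the mutant allele with probability equal to the
mutant-allele fraction of that cell's genotype, corrupted by sequencing error.

Setting ``alpha_n = 0`` recovers conventional matched-normal somatic calling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from functools import lru_cache
from typing import Optional, Sequence

__all__ = [
    "GenotypeLabel",
    "SiteObservation",
    "CopyNumberSegment",
    "ModelParams",
    "GenotypePair",
    "SitePosterior",
    "DegenerateLocusError",
    "tumour_read_fraction",
    "read_prob",
    "enumerate_genotype_pairs",
    "sample_log_likelihood",
    "site_posterior",
    "classify_site",
]

NEG_INF = float("-inf")


class DegenerateLocusError(ValueError):
    """Raised when the cell-mixture read fraction is undefined (zero denominator)."""


class GenotypeLabel(str, Enum):
    REF = "REF"
    GERMLINE = "GERMLINE"
    SOMATIC = "SOMATIC"
    UNCLASSIFIED = "UNCLASSIFIED"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class GenotypePair:
    """(k_g, k_t): mutant-allele copies per normal cell and per tumour cell."""

    k_g: int
    k_t: int

    @property
    def label(self) -> GenotypeLabel:
        if self.k_g >= 1:
            return GenotypeLabel.GERMLINE
        if self.k_t >= 1:
            return GenotypeLabel.SOMATIC
        return GenotypeLabel.REF

    def __str__(self) -> str:
        return f"{self.k_g}/{self.k_t}"


@dataclass
class SiteObservation:
    """Paired tumour/normal read evidence at one genomic site.

    Counts mode stores alt/total read counts per sample; per-read mode
    additionally carries ``(is_alt, phred_quality)`` tuples for every read,
    which override the fixed error rate.
    """

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    tumour_depth: int
    tumour_alt: int
    normal_depth: int
    normal_alt: int
    tumour_quals: Optional[Sequence[tuple[bool, float]]] = None
    normal_quals: Optional[Sequence[tuple[bool, float]]] = None

    def __post_init__(self) -> None:
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"{self.chrom}:{self.pos}: ref and alt alleles identical")
        for name, depth, alt, quals in (
            ("tumour", self.tumour_depth, self.tumour_alt, self.tumour_quals),
            ("normal", self.normal_depth, self.normal_alt, self.normal_quals),
        ):
            if depth < 0 or alt < 0 or alt > depth:
                raise ValueError(
                    f"{self.chrom}:{self.pos}: invalid {name} counts {alt}/{depth}"
                )
            if quals is not None:
                if len(quals) != depth:
                    raise ValueError(
                        f"{self.chrom}:{self.pos}: {name} per-read list length "
                        f"{len(quals)} != depth {depth}"
                    )
                n_alt = sum(1 for is_alt, _ in quals if is_alt)
                if n_alt != alt:
                    raise ValueError(
                        f"{self.chrom}:{self.pos}: {name} per-read alt flags sum to "
                        f"{n_alt}, expected {alt}"
                    )


@dataclass(frozen=True)
class CopyNumberSegment:
    """A copy-number interval: total copies per normal cell and per tumour cell.

    Coordinates are 1-based and inclusive at both ends, matching VCF/pileup
    conventions.  ``cn_major`` optionally records the major-allele copy count
    of the tumour genome (used for reporting only).
    """

    chrom: str
    start: int
    end: int
    cn_normal: int = 2
    cn_tumour: int = 2
    cn_major: Optional[int] = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"segment {self.chrom}:{self.start}-{self.end} reversed")
        if self.cn_normal < 0 or self.cn_tumour < 0:
            raise ValueError("copy numbers must be non-negative")
        if self.cn_normal + self.cn_tumour < 1:
            raise ValueError("cn_normal + cn_tumour must be >= 1")
        if self.cn_major is not None and self.cn_major > self.cn_tumour:
            raise ValueError("cn_major cannot exceed cn_tumour")

    def contains(self, chrom: str, pos: int) -> bool:
        return self.chrom == chrom and self.start <= pos <= self.end


DEFAULT_DIPLOID = CopyNumberSegment("*", 1, 2**31 - 1, cn_normal=2, cn_tumour=2)


@dataclass(frozen=True)
class ModelParams:
    """Calling parameters.

    alpha_t
        Aberrant (tumour) cell fraction of the tumour sample; 1 - alpha_t is
        the classical "normal contamination" of the tumour.
    alpha_n
        Aberrant cell fraction of the matched normal sample — the TiN level.
        The production default of 0.10 reflects the fixed 10% contamination
        setting that suffices to recover variants in typical haematological
        cohorts; set 0 for conventional calling or estimate it from data.
    base_error
        Per-read probability of a miscalled base, used in counts mode; a
        miscall lands on a specific wrong base with probability error/3.
    prior_snp, prior_somatic
        Prior mass that the site is a germline variant / carries a somatic
        mutation; split uniformly over the germline / somatic genotype pairs.
    somatic_threshold
        Posterior probability required to emit a classification.
    """

    alpha_t: float = 1.0
    alpha_n: float = 0.10
    base_error: float = 0.01
    prior_snp: float = 1e-4
    prior_somatic: float = 6e-6
    somatic_threshold: float = 0.95

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha_t <= 1.0:
            raise ValueError("alpha_t must be in [0, 1]")
        if not 0.0 <= self.alpha_n <= 1.0:
            raise ValueError("alpha_n must be in [0, 1]")
        if not 0.0 < self.base_error < 0.75:
            raise ValueError("base_error must be in (0, 0.75)")
        if self.prior_snp < 0 or self.prior_somatic < 0:
            raise ValueError("priors must be non-negative")
        if self.prior_snp + self.prior_somatic >= 1.0:
            raise ValueError("prior_snp + prior_somatic must be < 1")
        if not 0.0 < self.somatic_threshold < 1.0:
            raise ValueError("somatic_threshold must be in (0, 1)")

    def with_alpha_n(self, alpha_n: float) -> "ModelParams":
        return replace(self, alpha_n=alpha_n)


@dataclass
class SitePosterior:
    """Normalized posterior over genotype pairs at one site."""

    pairs: list[tuple[GenotypePair, float]]
    p_somatic: float
    p_germline: float
    map_pair: GenotypePair
    classification: GenotypeLabel
    degenerate: bool = False

    def posterior_of(self, pair: GenotypePair) -> float:
        for p, prob in self.pairs:
            if p == pair:
                return prob
        raise KeyError(pair)


def tumour_read_fraction(alpha: float, cn_tumour: int, cn_normal: int) -> float:
    """Probability that a read from a sample with aberrant cell fraction
    ``alpha`` originated from a tumour cell.

    pi = alpha * cn_tumour / (alpha * cn_tumour + (1 - alpha) * cn_normal):
    cells contribute reads in proportion to their abundance times their local
    copy number.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0, 1]")
    denom = alpha * cn_tumour + (1.0 - alpha) * cn_normal
    if denom <= 0.0:
        raise DegenerateLocusError(
            f"no read-producing copies at this locus "
            f"(alpha={alpha}, cn_tumour={cn_tumour}, cn_normal={cn_normal})"
        )
    return alpha * cn_tumour / denom


def read_prob(
    is_alt_observed: bool, error: float, f_t: float, f_g: float, pi: float
) -> float:
    """Probability of one read's observed base call.

    The read comes from a tumour cell with probability ``pi`` (allele fraction
    ``f_t``) and from a normal cell otherwise (allele fraction ``f_g``).  A
    mutant-chromosome read reports the alt base unless miscalled; a reference
    read reports the alt base only via a miscall to that specific base
    (probability error/3 under a uniform substitution model).
    """
    if is_alt_observed:
        q_t = f_t * (1.0 - error) + (1.0 - f_t) * (error / 3.0)
        q_g = f_g * (1.0 - error) + (1.0 - f_g) * (error / 3.0)
    else:
        q_t = (1.0 - f_t) * (1.0 - error) + f_t * (error / 3.0)
        q_g = (1.0 - f_g) * (1.0 - error) + f_g * (error / 3.0)
    return pi * q_t + (1.0 - pi) * q_g


@lru_cache(maxsize=256)
def enumerate_genotype_pairs(cn_normal: int, cn_tumour: int) -> tuple[GenotypePair, ...]:
    """All (k_g, k_t) pairs on the (cn_normal+1) x (cn_tumour+1) grid.

    No evolutionary constraint ties k_g to k_t: loss of heterozygosity can
    delete germline alleles from the tumour genome, so the full grid is kept.
    """
    if cn_normal < 0 or cn_tumour < 0 or cn_normal + cn_tumour < 1:
        raise ValueError("invalid copy numbers")
    return tuple(
        GenotypePair(k_g, k_t)
        for k_g in range(cn_normal + 1)
        for k_t in range(cn_tumour + 1)
    )


def _allele_fractions(pair: GenotypePair, cn: CopyNumberSegment) -> tuple[float, float]:
    # cn == 0 for a cell class means that class contributes no reads (pi takes
    # care of it); its allele fraction is set to 0 as an inert placeholder.
    f_t = pair.k_t / cn.cn_tumour if cn.cn_tumour > 0 else 0.0
    f_g = pair.k_g / cn.cn_normal if cn.cn_normal > 0 else 0.0
    return f_t, f_g


def sample_log_likelihood(
    alt_count: int,
    depth: int,
    pair: GenotypePair,
    cn: CopyNumberSegment,
    alpha: float,
    error: float,
    quals: Optional[Sequence[tuple[bool, float]]] = None,
) -> float:
    """Log-likelihood of one sample's reads at a site under a genotype pair.

    Counts mode (``quals is None``) treats every non-alt read as the reference
    base and multiplies the two per-read probabilities ``alt_count`` and
    ``depth - alt_count`` times.  Per-read mode uses each read's own Phred
    quality (error = 10**(-Q/10)).  Returns -inf rather than raising when a
    read has probability zero.
    """
    if depth == 0:
        return 0.0
    pi = tumour_read_fraction(alpha, cn.cn_tumour, cn.cn_normal)
    f_t, f_g = _allele_fractions(pair, cn)
    if quals is not None:
        total = 0.0
        for is_alt, q in quals:
            e = 10.0 ** (-q / 10.0)
            p = read_prob(is_alt, e, f_t, f_g, pi)
            if p <= 0.0:
                return NEG_INF
            total += math.log(p)
        return total
    p_alt = read_prob(True, error, f_t, f_g, pi)
    p_ref = read_prob(False, error, f_t, f_g, pi)
    ll = 0.0
    if alt_count > 0:
        if p_alt <= 0.0:
            return NEG_INF
        ll += alt_count * math.log(p_alt)
    if depth - alt_count > 0:
        if p_ref <= 0.0:
            return NEG_INF
        ll += (depth - alt_count) * math.log(p_ref)
    return ll


def pair_log_priors(
    pairs: Sequence[GenotypePair], params: ModelParams
) -> list[float]:
    """Log prior per genotype pair.

    The reference pair takes 1 - prior_snp - prior_somatic; prior_snp is split
    equally across germline pairs and prior_somatic equally across somatic
    pairs.  If a class is absent at this locus (e.g. cn_tumour = 0 leaves no
    somatic pair) the remaining masses are renormalized.
    """
    n_germ = sum(1 for p in pairs if p.label is GenotypeLabel.GERMLINE)
    n_som = sum(1 for p in pairs if p.label is GenotypeLabel.SOMATIC)
    raw = []
    for p in pairs:
        if p.label is GenotypeLabel.REF:
            raw.append(1.0 - params.prior_snp - params.prior_somatic)
        elif p.label is GenotypeLabel.GERMLINE:
            raw.append(params.prior_snp / n_germ)
        else:
            raw.append(params.prior_somatic / n_som)
    total = sum(raw)
    return [math.log(r / total) if r > 0 else NEG_INF for r in raw]


def _log_normalize(log_weights: list[float]) -> Optional[list[float]]:
    """Normalize in log space via max-subtraction; None if all -inf."""
    m = max(log_weights)
    if m == NEG_INF:
        return None
    ws = [math.exp(lw - m) if lw != NEG_INF else 0.0 for lw in log_weights]
    z = sum(ws)
    return [w / z for w in ws]


def site_posterior(
    site: SiteObservation, cn: CopyNumberSegment, params: ModelParams
) -> SitePosterior:
    """Posterior over genotype pairs given both samples' reads.

    The tumour likelihood uses ``alpha_t`` and the normal likelihood uses
    ``alpha_n``: the matched normal is treated exactly like a tumour sample
    with its own aberrant cell fraction, which is what lets genuine somatic
    variants with TiN-consistent read support in the normal remain somatic.
    """
    pairs = enumerate_genotype_pairs(cn.cn_normal, cn.cn_tumour)
    log_prior = pair_log_priors(pairs, params)
    log_post = []
    for lp, pair in zip(log_prior, pairs):
        if lp == NEG_INF:
            log_post.append(NEG_INF)
            continue
        lt = sample_log_likelihood(
            site.tumour_alt, site.tumour_depth, pair, cn,
            params.alpha_t, params.base_error, site.tumour_quals,
        )
        ln = sample_log_likelihood(
            site.normal_alt, site.normal_depth, pair, cn,
            params.alpha_n, params.base_error, site.normal_quals,
        )
        log_post.append(lp + lt + ln)
    probs = _log_normalize(log_post)
    if probs is None:
        # every pair impossible: fall back to a uniform posterior and refuse
        # to classify rather than raise mid-pipeline
        u = 1.0 / len(pairs)
        pp = [(p, u) for p in pairs]
        return SitePosterior(
            pairs=pp,
            p_somatic=sum(w for p, w in pp if p.label is GenotypeLabel.SOMATIC),
            p_germline=sum(w for p, w in pp if p.label is GenotypeLabel.GERMLINE),
            map_pair=pairs[0],
            classification=GenotypeLabel.UNCLASSIFIED,
            degenerate=True,
        )
    pp = list(zip(pairs, probs))
    p_som = sum(w for p, w in pp if p.label is GenotypeLabel.SOMATIC)
    p_germ = sum(w for p, w in pp if p.label is GenotypeLabel.GERMLINE)
    map_pair = max(pp, key=lambda t: t[1])[0]
    post = SitePosterior(
        pairs=pp, p_somatic=p_som, p_germline=p_germ,
        map_pair=map_pair, classification=GenotypeLabel.UNCLASSIFIED,
    )
    post.classification = classify_site(post, params.somatic_threshold)
    return post


def classify_site(posterior: SitePosterior, threshold: float) -> GenotypeLabel:
    """Decision rule on the aggregated posterior.

    SOMATIC if the summed somatic mass reaches the threshold, else GERMLINE,
    else REF if the reference pair itself reaches it; otherwise the site is
    left unclassified.
    """
    if posterior.degenerate:
        return GenotypeLabel.UNCLASSIFIED
    if posterior.p_somatic >= threshold:
        return GenotypeLabel.SOMATIC
    if posterior.p_germline >= threshold:
        return GenotypeLabel.GERMLINE
    p_ref = sum(
        w for p, w in posterior.pairs if p.label is GenotypeLabel.REF
    )
    if p_ref >= threshold:
        return GenotypeLabel.REF
    return GenotypeLabel.UNCLASSIFIED
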