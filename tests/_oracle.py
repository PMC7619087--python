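"""Independent brute-force reference computations for the test suite.

Everything here deliberately avoids the package's log-space code paths:
posteriors are computed as explicit per-read probability products in plain
floats, and binomial pmfs from log-gamma directly.  These are the oracles the
implementation is checked against, never shortcuts into it.
"""

import math


def brute_force_posterior(site, cn, params):
    """Posterior over (k_g, k_t) by explicit per-read product enumeration."""
    pairs = [
        (kg, kt)
        for kg in range(cn.cn_normal + 1)
        for kt in range(cn.cn_tumour + 1)
    ]
    n_germ = sum(1 for kg, kt in pairs if kg >= 1)
    n_som = sum(1 for kg, kt in pairs if kg == 0 and kt >= 1)

    def prior(kg, kt):
        if kg == 0 and kt == 0:
            return 1.0 - params.prior_snp - params.prior_somatic
        if kg >= 1:
            return params.prior_snp / n_germ
        return params.prior_somatic / n_som

    samples = (
        (params.alpha_t, site.tumour_depth, site.tumour_alt, site.tumour_quals),
        (params.alpha_n, site.normal_depth, site.normal_alt, site.normal_quals),
    )
    weights = []
    for kg, kt in pairs:
        w = prior(kg, kt)
        f_t = kt / cn.cn_tumour if cn.cn_tumour else 0.0
        f_g = kg / cn.cn_normal if cn.cn_normal else 0.0
        for alpha, depth, alt, quals in samples:
            pi = (alpha * cn.cn_tumour
                  / (alpha * cn.cn_tumour + (1 - alpha) * cn.cn_normal))
            reads = (quals if quals is not None
                     else [(True, None)] * alt + [(False, None)] * (depth - alt))
            for is_alt, q in reads:
                e = params.base_error if q is None else 10.0 ** (-q / 10.0)
                if is_alt:
                    qt = f_t * (1 - e) + (1 - f_t) * e / 3
                    qg = f_g * (1 - e) + (1 - f_g) * e / 3
                else:
                    qt = (1 - f_t) * (1 - e) + f_t * e / 3
                    qg = (1 - f_g) * (1 - e) + f_g * e / 3
                w *= pi * qt + (1 - pi) * qg
        weights.append(w)
    z = sum(weights)
    return {pair: w / z for pair, w in zip(pairs, weights)}


def brute_force_site_marginal(site, cn, params, alpha_n):
    """log of the genotype-marginalized site likelihood at a given alpha_n,
    by direct (non-log) summation of prior-weighted per-read products."""
    import dataclasses

    p = dataclasses.replace(params, alpha_n=alpha_n)
    pairs = [
        (kg, kt)
        for kg in range(cn.cn_normal + 1)
        for kt in range(cn.cn_tumour + 1)
    ]
    n_germ = sum(1 for kg, kt in pairs if kg >= 1)
    n_som = sum(1 for kg, kt in pairs if kg == 0 and kt >= 1)
    total = 0.0
    for kg, kt in pairs:
        if kg == 0 and kt == 0:
            w = 1.0 - p.prior_snp - p.prior_somatic
        elif kg >= 1:
            w = p.prior_snp / n_germ
        else:
            w = p.prior_somatic / n_som
        f_t = kt / cn.cn_tumour if cn.cn_tumour else 0.0
        f_g = kg / cn.cn_normal if cn.cn_normal else 0.0
        for alpha, depth, alt in (
            (p.alpha_t, site.tumour_depth, site.tumour_alt),
            (alpha_n, site.normal_depth, site.normal_alt),
        ):
            pi = (alpha * cn.cn_tumour
                  / (alpha * cn.cn_tumour + (1 - alpha) * cn.cn_normal))
            e = p.base_error
            p_alt = pi * (f_t * (1 - e) + (1 - f_t) * e / 3) \
                + (1 - pi) * (f_g * (1 - e) + (1 - f_g) * e / 3)
            p_ref = pi * ((1 - f_t) * (1 - e) + f_t * e / 3) \
                + (1 - pi) * ((1 - f_g) * (1 - e) + f_g * e / 3)
            w *= p_alt ** alt * p_ref ** (depth - alt)
        total += w
    return math.log(total)


def log10_binom_pmf(k, n, p):
    """Binomial log10 pmf from log-gamma, independent of scipy.stats."""
    log_comb = (math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1))
    ln = log_comb + k * math.log(p) + (n - k) * math.log(1 - p)
    return ln / math.log(10.0)
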