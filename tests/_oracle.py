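"""Brute-force meta-d' oracle: dense grid over meta-d with criteria profiled.

Independent of metasdt.type2: probabilities are assembled directly from
scipy's normal CDF and the inner criteria optimization uses Nelder-Mead on
its own increment parameterization.  Used to cross-check the package's
analytic-gradient ML fit.
"""

import numpy as np
from scipy.optimize import minimize
from scipy.stats import norm

from metasdt.tables import S1, S2


def _side_nll(counts_side, boundaries, means, sds, resp_probs):
    """NLL contribution of one response side given its K-1 criteria.

    counts_side : (2, K) counts for this response, conf ascending along
        the evidence direction away from the type-1 criterion.
    boundaries : ascending absolute criterion locations for this side,
        *including* the type-1 criterion as the first element.
    """
    nll = 0.0
    for i in range(2):
        cdf = norm.cdf(boundaries, loc=means[i], scale=sds[i])
        areas = np.append(np.diff(cdf), 1.0 - cdf[-1])
        p = areas / resp_probs[i]
        nll -= np.sum(counts_side[i] * np.log(np.maximum(p, 1e-12)))
    return nll


def _profile_side(counts_side, meta_c, means, sds, resp_probs, sign):
    """Optimize one side's K-1 criteria (as log-increments from meta_c)."""
    K = counts_side.shape[1]

    def nll(loginc):
        steps = np.exp(np.clip(loginc, -10, 3))
        offs = np.cumsum(steps)
        bounds = meta_c + sign * offs
        bounds = np.sort(np.concatenate([[meta_c], bounds]))
        if sign < 0:  # S1 side: conf ascends away from meta_c downwards
            val = 0.0
            for i in range(2):
                cdf = norm.cdf(bounds, loc=means[i], scale=sds[i])
                areas = np.concatenate([[cdf[0]], np.diff(cdf)])
                # areas[0] is the lowest region (conf K), ascending order:
                p = areas[::-1] / resp_probs[i]
                val -= np.sum(counts_side[i] * np.log(np.maximum(p, 1e-12)))
            return val
        return _side_nll(counts_side, bounds, means, sds, resp_probs)

    res = minimize(nll, np.full(K - 1, np.log(0.4)), method="Nelder-Mead",
                   options={"xatol": 1e-5, "fatol": 1e-8, "maxiter": 1500})
    return res.fun


def oracle_nll(table, meta_d, rel_criterion, s):
    """Profile NLL at one meta-d value (criteria optimized out)."""
    if s == 1.0:
        mu = meta_d
    else:
        mu = meta_d * np.sqrt((1.0 + s**2) / 2.0) / s
    meta_c = rel_criterion * mu
    means = np.array([-mu / 2.0, mu / 2.0])
    sds = np.array([1.0, 1.0 / s])
    p_s1 = norm.cdf(meta_c, loc=means, scale=sds)
    p_s2 = 1.0 - p_s1
    # counts per response side, conf 1..K
    c_s1 = table.counts[:, S1, :]
    c_s2 = table.counts[:, S2, :]
    nll1 = _profile_side(c_s1, meta_c, means, sds, np.maximum(p_s1, 1e-300), -1)
    nll2 = _profile_side(c_s2, meta_c, means, sds, np.maximum(p_s2, 1e-300), +1)
    return nll1 + nll2


def grid_meta_d(table, rel_criterion, s=1.0, coarse_step=0.1,
                fine_step=0.005, span=None, fine_halfwidth=0.15):
    """Dense grid search for meta-d: coarse scan, then 0.005-step refinement.

    The default coarse window is centered on the table's own closed-form
    d' (computed here from the 2x2 collapse, independently of the fit
    under test), since meta-d lives on the type-1 sensitivity scale.
    """
    if span is None:
        tab2 = table.counts.sum(axis=2)
        h = tab2[S2, S2] / tab2[S2].sum()
        f = tab2[S1, S2] / tab2[S1].sum()
        d0 = norm.ppf(h) - norm.ppf(f)
        span = (d0 - 2.0, d0 + 2.0)
    coarse = np.arange(span[0], span[1] + 1e-9, coarse_step)
    vals = [oracle_nll(table, m, rel_criterion, s) for m in coarse]
    center = coarse[int(np.argmin(vals))]
    fine = np.arange(center - fine_halfwidth, center + fine_halfwidth + 1e-9,
                     fine_step)
    fvals = [oracle_nll(table, m, rel_criterion, s) for m in fine]
    return float(fine[int(np.argmin(fvals))])
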