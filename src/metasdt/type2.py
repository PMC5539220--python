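"""Type-2 SDT: maximum-likelihood meta-d' / meta-da and M-ratio.

The meta-d' idea: ask what type-1 sensitivity an SDT-ideal observer would
need so that, placing confidence criteria optimally around the decision
criterion, it reproduces the *observed* response-conditional confidence
distributions.  That sensitivity, expressed in type-1 units, is meta-d'
(meta-da under unequal evidence variance).  Metacognitive efficiency is the
ratio M-ratio = meta-d'/d' (or meta-da/da): 1 for an observer whose
confidence uses exactly the information in the choice, < 1 when confidence
is noisier than the choice, negative when confidence is anticorrelated with
accuracy.

Model structure
---------------
Evidence x: S1 ~ N(-mu/2, 1), S2 ~ N(+mu/2, 1/s), with s the zROC slope
fixed from the type-1 unequal-variance fit (s = 1 for the equal model) and
mu the mean separation implied by the candidate meta-d.  The type-1
criterion enters at the same *relative* position as in the data
(meta_c = c/d' * mu), and K-1 monotone confidence criteria per response
side partition each response region.  The likelihood is multinomial over
confidence ratings *conditional on* (stimulus, response) — type-1 choice
behaviour is taken from the data, not refit — maximized over meta-d and the
2(K-1) criteria.

A caveat inherited from the unequal-variance variant: the slope s is
estimated from both choices and ratings, then held fixed in the type-2
model, so the two levels are not fully independent there.  This is a
documented limitation of the method, not resolved here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import ndtr

from .tables import S1, S2, RatingTable, pad_counts
from .type1 import Type1Results, Type1SDT

__all__ = [
    "MetaDSDT", "MetaDResults", "MetaMeasure",
    "fit_meta_d", "m_ratio", "type2_predicted_probs",
]

_META_D_BOX = (-5.0, 5.0)
_LOG_INC_BOX = (-7.0, 2.5)
_TINY = 1e-300


def _mu_from_meta_d(meta_d: float, s: float) -> float:
    """Mean separation mu from reported-scale meta-d.

    Equal variance (s=1): mu = meta-d'.  Unequal: meta-da refers to the
    RMS-normalized sensitivity sqrt(2/(1+s^2)) * s * mu, so invert that.
    """
    if s == 1.0:
        return meta_d
    return meta_d * np.sqrt((1.0 + s**2) / 2.0) / s


def _meta_d_from_mu(mu: float, s: float) -> float:
    if s == 1.0:
        return mu
    return mu * s * np.sqrt(2.0 / (1.0 + s**2))


def _conditional_probs(mu: float, meta_c: float,
                       crit_s1: np.ndarray, crit_s2: np.ndarray,
                       s: float) -> np.ndarray:
    """P(conf = k | stimulus, response) as a (2, 2, K) array.

    crit_s1 : descending distances are not assumed — pass actual criterion
        locations, ascending, all <= meta_c (S1-response side).
    crit_s2 : ascending, all >= meta_c (S2-response side).
    """
    K = len(crit_s1) + 1
    cuts = np.concatenate([crit_s1, [meta_c], crit_s2])  # ascending, 2K-1
    out = np.empty((2, 2, K))
    means = (-mu / 2.0, mu / 2.0)
    sds = (1.0, 1.0 / s)
    cdf2 = ndtr((cuts[None, :] - np.array(means)[:, None]) / np.array(sds)[:, None])
    for stim in (S1, S2):
        cdf = cdf2[stim]
        areas = np.diff(np.concatenate([[0.0], cdf, [1.0]]))  # 2K regions
        p_s1 = max(cdf[K - 1], _TINY)        # P(resp S1 | stim)
        p_s2 = max(1.0 - cdf[K - 1], _TINY)
        # regions 0..K-1 lie below meta_c -> response S1, conf K..1
        out[stim, S1, :] = areas[:K][::-1] / p_s1
        out[stim, S2, :] = areas[K:] / p_s2
    return out


def type2_predicted_probs(meta_d: float, meta_c: float,
                          t2_criteria_S1resp, t2_criteria_S2resp,
                          s: float = 1.0) -> np.ndarray:
    """Response-conditional confidence probabilities under a type-2 model.

    Returns a (2, 2, K) array ``P[stim, resp, conf-1]`` with each
    (stim, resp) slice summing to 1.  Criteria are absolute locations on
    the evidence axis; the S1-response criteria must ascend and stay at or
    below ``meta_c``, the S2-response criteria ascend from ``meta_c``.
    """
    if s <= 0:
        raise ValueError("s must be positive")
    c1 = np.asarray(t2_criteria_S1resp, dtype=float)
    c2 = np.asarray(t2_criteria_S2resp, dtype=float)
    if len(c1) != len(c2):
        raise ValueError("criterion vectors must have equal length K-1")
    if np.any(np.diff(c1) <= 0) or np.any(np.diff(c2) <= 0):
        raise ValueError("type-2 criteria must be strictly monotone")
    if (len(c1) and c1[-1] > meta_c) or (len(c2) and c2[0] < meta_c):
        raise ValueError("type-2 criteria must sit on the correct side of meta_c")
    return _conditional_probs(_mu_from_meta_d(meta_d, s), meta_c, c1, c2, s)


@dataclass(frozen=True)
class MetaDResults:
    """Maximum-likelihood type-2 fit for one rating table."""

    meta_d: float
    variance_model: str
    meta_c: float
    t2_criteria_S1resp: np.ndarray
    t2_criteria_S2resp: np.ndarray
    log_likelihood: float
    converged: bool
    n_trials: float
    s: float
    type1: Type1Results = field(repr=False)
    n_starts: int = 3
    meta_d_se: float | None = None

    @property
    def m_ratio(self) -> float:
        """Metacognitive efficiency: meta-d'/d' (equal) or meta-da/da."""
        return m_ratio(self.type1, self).m_ratio

    def summary(self) -> str:
        t1_sens = self.type1.d_prime if self.variance_model == "equal" else self.type1.da
        name = "meta-d'" if self.variance_model == "equal" else "meta-da"
        se = f"{self.meta_d_se:.4f}" if self.meta_d_se is not None else "n/a"
        lines = [
            f"Type-2 SDT fit ({self.variance_model} variance)",
            "=" * 44,
            f"  trials            {self.n_trials:10.1f}",
            f"  {name:<14}    {self.meta_d:10.4f}  (se {se})",
            f"  type-1 sens.      {t1_sens:10.4f}",
            f"  M-ratio           {self.m_ratio:10.4f}",
            f"  zROC slope s      {self.s:10.4f}",
            f"  log-likelihood    {self.log_likelihood:10.3f}",
            f"  converged         {str(self.converged):>10}",
        ]
        return "\n".join(lines)


@dataclass(frozen=True)
class MetaMeasure:
    """M-ratio with its components and variance-model variant."""

    m_ratio: float
    variant: str                      # "equal" | "unequal"
    type1_sensitivity: float
    type2_sensitivity: float


def m_ratio(type1: Type1Results, type2: MetaDResults) -> MetaMeasure:
    """Metacognitive efficiency meta-d'/d' (or meta-da/da).

    Negative type-2 sensitivities are preserved: an observer can be better
    than chance in choices yet anticorrelated in confidence.
    """
    if type2.variance_model == "equal":
        denom = type1.d_prime
    else:
        if type1.variance_model != "unequal":
            raise ValueError("unequal-variance M-ratio needs an unequal type-1 fit")
        denom = type1.da
    if denom == 0:
        raise ValueError("undefined efficiency: type-1 sensitivity is 0")
    return MetaMeasure(
        m_ratio=type2.meta_d / denom,
        variant=type2.variance_model,
        type1_sensitivity=denom,
        type2_sensitivity=type2.meta_d,
    )


class MetaDSDT:
    """Meta-d' model for one rating table (statsmodels-style: ``.fit()``).

    Parameters
    ----------
    table : RatingTable
        Raw counts; padded internally with `padding`.
    variance : {"equal", "unequal"}
        Equal-variance meta-d', or meta-da with s fixed from the type-1
        unequal-variance zROC fit.
    type1 : Type1Results, optional
        Matching type-1 fit; computed from `table` if omitted.
    """

    def __init__(self, table: RatingTable, variance: str = "equal",
                 type1: Type1Results | None = None,
                 padding: str = "only-if-needed"):
        if variance not in ("equal", "unequal"):
            raise ValueError(f"unknown variance model {variance!r}")
        conf_mass = table.counts.sum(axis=(0, 1))
        if np.count_nonzero(conf_mass) < 2:
            raise ValueError("type-2 data degenerate: all confidence ratings "
                             "fall on a single level")
        self.variance = variance
        self.table = pad_counts(table, scheme=padding)
        if type1 is None:
            type1 = Type1SDT(table, variance=variance, padding=padding).fit()
        elif type1.variance_model != variance:
            raise ValueError("type1 fit and variance model disagree")
        self.type1 = type1
        self.s = 1.0 if variance == "equal" else type1.s
        self.K = table.n_levels

    # -- likelihood --------------------------------------------------------

    def _unpack(self, theta: np.ndarray):
        K = self.K
        meta_d = theta[0]
        mu = _mu_from_meta_d(meta_d, self.s)
        rel_c = self.type1.relative_criterion
        if not np.isfinite(rel_c):
            rel_c = 0.0
        meta_c = rel_c * mu
        inc_s1 = np.exp(theta[1:K])
        inc_s2 = np.exp(theta[K:2 * K - 1])
        crit_s1 = meta_c - np.cumsum(inc_s1)[::-1]   # ascending, below meta_c
        crit_s2 = meta_c + np.cumsum(inc_s2)         # ascending, above meta_c
        return mu, meta_c, crit_s1, crit_s2

    def _nll(self, theta: np.ndarray) -> float:
        mu, meta_c, crit_s1, crit_s2 = self._unpack(theta)
        probs = _conditional_probs(mu, meta_c, crit_s1, crit_s2, self.s)
        return -float(np.sum(self.table.counts * np.log(np.maximum(probs, 1e-12))))

    def _nll_and_grad(self, theta: np.ndarray):
        """Objective and analytic gradient (validated against finite differences).

        With cuts t_0..t_{2K-2} (S1-side criteria, the type-1 criterion at
        index K-1, S2-side criteria) the NLL is
        ``-sum_i sum_r n_ir log A_ir + sum_i N_i,resp log D_i,resp`` where
        A are Gaussian region areas and D the response probabilities; the
        gradient chains region-boundary derivatives (normal pdfs) through
        the criterion parameterization and the mean shift in meta-d.
        """
        K = self.K
        mu, meta_c, crit_s1, crit_s2 = self._unpack(theta)
        k_scale = _mu_from_meta_d(1.0, self.s)
        rel_c = self.type1.relative_criterion
        if not np.isfinite(rel_c):
            rel_c = 0.0
        cuts = np.concatenate([crit_s1, [meta_c], crit_s2])
        means = np.array([-mu / 2.0, mu / 2.0])
        sds = np.array([1.0, 1.0 / self.s])
        z = (cuts[None, :] - means[:, None]) / sds[:, None]
        C = ndtr(z)
        phi = np.exp(-0.5 * z**2) / np.sqrt(2 * np.pi)
        # counts in region order (ascending evidence), per stimulus
        n = np.stack([self.table.rating_vector(stim) for stim in (S1, S2)])
        A = np.diff(np.concatenate([np.zeros((2, 1)), C, np.ones((2, 1))], axis=1),
                    axis=1)
        A = np.maximum(A, _TINY)
        D1 = np.maximum(C[:, K - 1], _TINY)
        D2 = np.maximum(1.0 - C[:, K - 1], _TINY)
        N1 = n[:, :K].sum(axis=1)
        N2 = n[:, K:].sum(axis=1)
        nll = -np.sum(n * np.log(A)) + N1 @ np.log(D1) + N2 @ np.log(D2)

        # dNLL/dt_j holding the stimulus means fixed
        G = -(n[:, :-1] / A[:, :-1] - n[:, 1:] / A[:, 1:])
        G[:, K - 1] += N1 / D1 - N2 / D2
        G *= phi / sds[:, None]

        grad = np.empty_like(theta)
        rowsum = G.sum(axis=1)
        # meta-d: all cuts shift by rel_c per unit mu; means shift by -/+ 1/2
        grad[0] = k_scale * ((rel_c + 0.5) * rowsum[0] + (rel_c - 0.5) * rowsum[1])
        inc_s1 = np.exp(theta[1:K])
        inc_s2 = np.exp(theta[K:2 * K - 1])
        g_cuts = G.sum(axis=0)
        # a_l lowers S1-side cuts 0..K-2-l; b_l raises S2-side cuts K-1+l..
        s1_prefix = np.cumsum(g_cuts[:K - 1])            # sum over cuts 0..j
        grad[1:K] = -inc_s1 * s1_prefix[K - 2 - np.arange(K - 1)]
        s2_suffix = np.cumsum(g_cuts[K:][::-1])[::-1]     # sum over cuts K-1+l..2K-2
        grad[K:2 * K - 1] = inc_s2 * s2_suffix
        return float(nll), grad

    # -- fitting -----------------------------------------------------------

    def _start_values(self, rng: np.random.Generator, jitter: bool) -> np.ndarray:
        d0 = self.type1.d_prime if self.variance == "equal" else self.type1.da
        theta = np.empty(2 * self.K - 1)
        theta[0] = np.clip(d0, *_META_D_BOX)
        theta[1:] = np.log(0.35)
        if jitter:
            theta[0] = np.clip(theta[0] + rng.normal(0, 0.5), *_META_D_BOX)
            theta[1:] += rng.normal(0, 0.5, size=2 * self.K - 2)
        return theta

    def fit(self, n_starts: int = 3, seed: int = 0, tol: float = 1e-8) -> MetaDResults:
        """Maximize the response-conditional likelihood.

        Multi-start L-BFGS-B (first start at the type-1 sensitivity, the
        rest jittered with a seeded RNG) to dodge local optima; the best
        optimum is returned with an honest `converged` flag.
        """
        rng = np.random.default_rng(seed)
        bounds = [tuple(_META_D_BOX)] + [tuple(_LOG_INC_BOX)] * (2 * self.K - 2)
        best, best_ok = None, False
        for i in range(max(1, n_starts)):
            theta0 = self._start_values(rng, jitter=i > 0)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                res = minimize(self._nll_and_grad, theta0, method="L-BFGS-B",
                               jac=True, bounds=bounds,
                               options={"ftol": tol, "gtol": 1e-6, "maxiter": 500})
            if best is None or res.fun < best.fun - 1e-12:
                best, best_ok = res, bool(res.success)
            elif res.fun < best.fun + 1e-9:
                best_ok = best_ok or bool(res.success)

        mu, meta_c, crit_s1, crit_s2 = self._unpack(best.x)
        meta_d = float(best.x[0])
        se = self._meta_d_se(best.x)
        return MetaDResults(
            meta_d=meta_d, variance_model=self.variance, meta_c=float(meta_c),
            t2_criteria_S1resp=crit_s1, t2_criteria_S2resp=crit_s2,
            log_likelihood=-float(best.fun), converged=best_ok,
            n_trials=self.table.n_trials, s=self.s, type1=self.type1,
            n_starts=n_starts, meta_d_se=se,
        )

    def _meta_d_se(self, theta: np.ndarray, h: float = 1e-3) -> float | None:
        """Conditional SE from the profile curvature in meta-d (criteria fixed)."""
        t_hi, t_lo = theta.copy(), theta.copy()
        t_hi[0] += h
        t_lo[0] -= h
        curv = (self._nll(t_hi) - 2 * self._nll(theta) + self._nll(t_lo)) / h**2
        if curv <= 0 or not np.isfinite(curv):
            return None
        return float(1.0 / np.sqrt(curv))


def fit_meta_d(table: RatingTable, type1: Type1Results | None = None,
               variance_model: str = "equal", **fit_kwargs) -> MetaDResults:
    """Fit meta-d' (or meta-da) to a rating table; see :class:`MetaDSDT`."""
    return MetaDSDT(table, variance=variance_model, type1=type1).fit(**fit_kwargs)
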