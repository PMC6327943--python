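"""Select regulated TADs from the heavy tail of per-TAD responsive counts.

Responsive genes (differentially expressed or phenotype-correlating, union
over regions and variables) are tallied per TAD; the counts over TADs with
at least one responsive gene form a heavy-tailed sample.  Four candidate
families are fitted by maximum likelihood — zero-truncated Poisson, discrete
power law (x_min = 1), geometric (the discrete exponential) and log-normal —
and ranked by AIC.  A TAD is *regulated* when the fitted survival function
at its count, P(X > n_t), i.e. the chance of another TAD exceeding it, falls
below alpha (default 0.05).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .tad_map import GeneTadMap

FAMILIES = ("poisson", "powerlaw", "exponential", "lognormal")


@dataclass
class TailFit:
    family: str
    params: dict
    loglik: float
    aic: float
    n: int

    def survival(self, x) -> np.ndarray:
        """P(X > x) under the fitted (zero-truncated where discrete) law."""
        x = np.asarray(x, dtype=float)
        p = self.params
        if self.family == "poisson":
            lam = p["lam"]
            sf = stats.poisson.sf(x, lam)
            return sf / (1.0 - np.exp(-lam))
        if self.family == "powerlaw":
            alpha = p["alpha"]
            # P(X > x) = zeta(alpha, floor(x)+1) / zeta(alpha)
            xf = np.floor(x) + 1.0
            return special.zeta(alpha, xf) / special.zeta(alpha, 1.0)
        if self.family == "exponential":
            q = p["q"]
            return q ** np.floor(x)          # geometric on 1, 2, ...
        if self.family == "lognormal":
            if self.params.get("discrete"):
                mu, sigma = p["mu"], p["sigma"]
                z = (np.log(np.floor(x) + 0.5) - mu) / sigma
                lo = (np.log(0.5) - mu) / sigma
                return stats.norm.sf(z) / stats.norm.sf(lo)
            return stats.norm.sf((np.log(x) - p["mu"]) / p["sigma"])
        raise ValueError(self.family)


@dataclass
class RegulatedTadSet:
    tad_ids: list
    tail_probability: pd.Series   # per selected TAD
    count_threshold: int          # smallest selected count
    family: str
    alpha: float


def count_responsive(gmap: GeneTadMap, responsive_sets) -> pd.Series:
    """Distinct responsive genes per TAD (union over regions/variables).

    ``responsive_sets`` is an iterable of gene-id collections (or a single
    collection); a gene responsive in several regions counts once.  TADs
    with zero responsive genes are excluded (the fit sample is the positive
    counts).
    """
    if isinstance(responsive_sets, (set, frozenset, dict)):
        responsive_sets = [responsive_sets]
    union = set()
    for s in responsive_sets:
        union |= set(s)
    if not union:
        raise ValueError("empty responsive union")
    tally = {}
    for g in union:
        t = gmap.gene_to_tad.get(g)
        if t is not None:
            tally[t] = tally.get(t, 0) + 1
    return pd.Series(tally, dtype=int).sort_index()


# ---------------------------------------------------------------------------
# maximum-likelihood fits on positive counts
# ---------------------------------------------------------------------------

def _fit_poisson(x):
    """Zero-truncated Poisson: solve lam / (1 - exp(-lam)) = mean."""
    m = x.mean()
    lam = m
    for _ in range(100):
        f = lam / (1.0 - np.exp(-lam)) - m
        df = (1.0 - np.exp(-lam) - lam * np.exp(-lam)) / (1.0 - np.exp(-lam)) ** 2
        step = f / df
        lam -= step
        if abs(step) < 1e-12:
            break
    lam = max(lam, 1e-9)
    ll = float(np.sum(stats.poisson.logpmf(x, lam)) -
               x.size * np.log1p(-np.exp(-lam)))
    return {"lam": float(lam)}, ll, 1


def _fit_powerlaw(x):
    """Discrete power law p(k) = k^-alpha / zeta(alpha), x_min = 1."""
    slogx = np.log(x).sum()

    def nll(alpha):
        return alpha * slogx + x.size * np.log(special.zeta(alpha, 1.0))

    res = optimize.minimize_scalar(nll, bounds=(1.0001, 20.0), method="bounded")
    alpha = float(res.x)
    return {"alpha": alpha}, float(-res.fun), 1


def _fit_exponential(x):
    """Geometric on {1, 2, ...}: p(k) = (1-q) q^(k-1); MLE q = 1 - 1/mean."""
    m = x.mean()
    q = max(1e-12, 1.0 - 1.0 / m)
    if q == 0:
        ll = 0.0
    else:
        ll = float(x.size * np.log(1 - q) + (x - 1).sum() * np.log(q))
    return {"q": float(q)}, ll, 1


def _fit_lognormal(x, discrete=False):
    """Log-normal by MLE on log counts (continuous approximation), or a
    zero-truncated discretized version (bins [k-1/2, k+1/2])."""
    logx = np.log(x)
    mu, sigma = float(logx.mean()), float(logx.std(ddof=0))
    sigma = max(sigma, 1e-9)
    if not discrete:
        ll = float(np.sum(stats.norm.logpdf(logx, mu, sigma) - logx))
        return {"mu": mu, "sigma": sigma, "discrete": False}, ll, 2

    def nll(theta):
        m, s = theta
        if s <= 1e-6:
            return 1e12
        hi = stats.norm.cdf((np.log(x + 0.5) - m) / s)
        lo = stats.norm.cdf((np.log(x - 0.5) - m) / s)
        norm = stats.norm.sf((np.log(0.5) - m) / s)
        pk = np.clip((hi - lo) / norm, 1e-300, None)
        return -np.log(pk).sum()

    res = optimize.minimize(nll, x0=[mu, sigma], method="Nelder-Mead")
    m, s = res.x
    return {"mu": float(m), "sigma": float(s), "discrete": True}, \
        float(-res.fun), 2


def fit_tail(counts, discrete_lognormal: bool = False):
    """Fit all four families to the positive counts and rank them by AIC.

    Returns ``(fits, best_family)`` with ``fits`` sorted best-first.
    Requires >= 20 positive counts; all-equal counts are degenerate.
    """
    x = np.asarray(counts, dtype=float)
    x = x[x > 0]
    if x.size < 20:
        raise ValueError(f"need >= 20 positive counts, got {x.size}")
    if np.ptp(x) == 0:
        raise ValueError("degenerate sample: all counts equal")
    fitters = {
        "poisson": lambda: _fit_poisson(x),
        "powerlaw": lambda: _fit_powerlaw(x),
        "exponential": lambda: _fit_exponential(x),
        "lognormal": lambda: _fit_lognormal(x, discrete=discrete_lognormal),
    }
    fits = []
    for fam, fn in fitters.items():
        params, ll, k = fn()
        fits.append(TailFit(family=fam, params=params, loglik=ll,
                            aic=2 * k - 2 * ll, n=x.size))
    fits.sort(key=lambda f: f.aic)
    return fits, fits[0].family


def select_regulated(counts: pd.Series, fit: TailFit,
                     alpha: float = 0.05) -> RegulatedTadSet:
    """TADs whose fitted tail probability P(X > n_t) falls below alpha."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    counts = pd.Series(counts).astype(int)
    sf = pd.Series(fit.survival(counts.values), index=counts.index)
    selected = sf.index[sf < alpha]
    sel_counts = counts.loc[selected]
    return RegulatedTadSet(
        tad_ids=sorted(selected),
        tail_probability=sf.loc[selected],
        count_threshold=int(sel_counts.min()) if len(sel_counts) else 0,
        family=fit.family,
        alpha=alpha,
    )
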