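"""Intra-TAD sign-coherence of responsive genes within regulated TADs.

For one brain region, each regulated TAD contributes a deviation
D_t = |#upregulated - #downregulated| over its responsive genes; the test
statistic is the mean D_t over the regulated TADs that contain at least one
responsive gene.  The null re-deals the region's responsive genes (keeping
their signs) uniformly across those same TADs, preserving every TAD's
responsive-gene count, so a globally unbalanced sign pool does not by itself
produce an apparent coherence signal.  The p-value uses the (k+1)/(B+1)
convention, counting ties against rejection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tad_map import GeneTadMap


@dataclass
class CoregulationResult:
    region: str
    deviations: pd.Series       # per regulated TAD with >= 1 responsive gene
    observed_mean: float
    permuted_means: np.ndarray
    pvalue: float
    seed: int

    def __post_init__(self):
        self.permuted_means = np.asarray(self.permuted_means, dtype=float)
        assert self.pvalue >= 1.0 / (self.permuted_means.size + 1)


def _tad_sign_vectors(gmap: GeneTadMap, signed_responsive: dict,
                      regulated_tads) -> dict:
    """regulated TAD -> array of signs of its responsive genes."""
    regulated = set(regulated_tads)
    per_tad = {}
    for g, s in signed_responsive.items():
        t = gmap.gene_to_tad.get(g)
        if t in regulated:
            per_tad.setdefault(t, []).append(int(s))
    return {t: np.asarray(v) for t, v in per_tad.items()}


def sign_deviation(gmap: GeneTadMap, signed_responsive: dict,
                   regulated_tads):
    """Per-TAD D_t = |#up - #down| and their mean over regulated TADs.

    Only regulated TADs containing at least one responsive gene of the
    region contribute; if none does, the statistic is undefined.
    """
    per_tad = _tad_sign_vectors(gmap, signed_responsive, regulated_tads)
    if not per_tad:
        raise ValueError("no responsive gene lies in any regulated TAD")
    dev = pd.Series({t: float(abs(v.sum())) for t, v in per_tad.items()}
                    ).sort_index()
    return dev, float(dev.mean())


def coregulation_test(gmap: GeneTadMap, signed_responsive: dict,
                      regulated_tads, B: int = 1000, seed: int = 0,
                      region: str = "?", pool: str = "regulated"
                      ) -> CoregulationResult:
    """Permutation test of the mean sign deviation.

    Each round shuffles the pooled signs across the responsive-gene slots of
    the regulated TADs (slot counts fixed), recomputes the mean deviation,
    and the p-value is (#{perm >= obs} + 1) / (B + 1).  The default pool is
    the responsive genes already inside regulated TADs; ``pool="all"`` draws
    slot signs without replacement from the region's whole responsive set.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if pool not in ("regulated", "all"):
        raise ValueError("pool must be 'regulated' or 'all'")
    per_tad = _tad_sign_vectors(gmap, signed_responsive, regulated_tads)
    if not per_tad:
        raise ValueError("no responsive gene lies in any regulated TAD")
    tad_order = sorted(per_tad)
    slot_counts = np.array([per_tad[t].size for t in tad_order])
    in_tads = np.concatenate([per_tad[t] for t in tad_order])
    sign_pool = np.asarray(list(signed_responsive.values()), dtype=int) \
        if pool == "all" else in_tads
    n_slots = int(slot_counts.sum())
    observed = np.array([abs(per_tad[t].sum()) for t in tad_order], dtype=float)
    obs_mean = float(observed.mean())

    rng = np.random.default_rng(int(seed))
    bounds = np.cumsum(slot_counts)[:-1]
    perm_means = np.empty(B)
    for b in range(B):
        chunks = deal_signs(sign_pool, n_slots, bounds, rng)
        perm_means[b] = np.mean([abs(c.sum()) for c in chunks])
    n_ge = int((perm_means >= obs_mean - 1e-12).sum())
    dev = pd.Series(observed, index=tad_order)
    return CoregulationResult(
        region=region, deviations=dev, observed_mean=obs_mean,
        permuted_means=perm_means, pvalue=(n_ge + 1) / (B + 1), seed=int(seed),
    )


def deal_signs(sign_pool, n_slots, bounds, rng):
    """One null deal: draw ``n_slots`` signs from the pool without
    replacement and split them into the per-TAD slot chunks."""
    dealt = sign_pool[rng.permutation(sign_pool.size)[:n_slots]]
    return np.split(dealt, bounds)


def sign_balance_table(gmap: GeneTadMap, responsive_by_region: dict,
                       regulated_tads) -> pd.DataFrame:
    """Descriptive per-TAD, per-region signed balance (#up - #down).

    NaN marks TADs without any responsive gene in that region; used to
    inspect cross-region sign reversal (e.g. TADs upregulated in the frontal
    cortex but downregulated in the hypothalamus).
    """
    out = {}
    for region, signed in responsive_by_region.items():
        per_tad = _tad_sign_vectors(gmap, signed, regulated_tads)
        out[region] = {t: int(v.sum()) for t, v in per_tad.items()}
    return pd.DataFrame(out).reindex(sorted(regulated_tads))
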