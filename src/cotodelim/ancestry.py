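"""Admixture-model ancestry estimation and gene-pool post-processing.

The model is the standard unsupervised admixture likelihood for
unlinked biallelic sites: individual i carries ancestry fractions
q_i (summing to 1 over K gene pools), pool k has allele frequency
p_kj at site j, and the diploid dosage g_ij is Binomial(2, sum_k
q_ik p_kj), giving the log-likelihood

    L = sum_ij [ g_ij log(sum_k q_ik p_kj)
               + (2 - g_ij) log(sum_k q_ik (1 - p_kj)) ].

It is maximized here by plain EM (monotone in L), which suffices at
the problem sizes this package targets. Downstream utilities align
cluster labels across runs, average ancestry per taxon, classify taxa
as single-pool (PURE), near-pure (SUBTHRESHOLD, the documented
override window) or ADMIXED, and detect taxa sharing a gene pool.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .datatypes import MISSING, AncestryMatrix, GenotypeMatrix, SampleMap

log = logging.getLogger(__name__)

_EPS = 1e-9

PURE = "PURE"
SUBTHRESHOLD = "SUBTHRESHOLD"
ADMIXED = "ADMIXED"


# ---------------------------------------------------------------------
# model / results

class AdmixtureModel:
    """Unsupervised admixture model for a genotype matrix at a given K.

    Parameters
    ----------
    G : GenotypeMatrix
        Dosage-coded biallelic genotypes; missing entries are skipped
        in the likelihood.
    K : int
        Number of ancestral gene pools (>= 1).
    """

    def __init__(self, G: GenotypeMatrix, K: int):
        if K < 1:
            raise ValueError("K must be >= 1")
        if K > G.n_samples:
            raise ValueError(
                f"K={K} exceeds the number of samples ({G.n_samples})")
        obs = ~G.missing_mask()
        if not obs.any(axis=0).all():
            raise ValueError("site with all genotypes missing")
        self.G = G
        self.K = K
        self._g = np.where(obs, G.dosages, 0).astype(float)
        self._w = obs.astype(float)

    def _init(self, rng: np.random.Generator
              ) -> tuple[np.ndarray, np.ndarray]:
        n, L = self._g.shape
        q = rng.dirichlet(np.ones(self.K), size=n)
        base = self._g.sum(axis=0) / np.maximum(2 * self._w.sum(axis=0), 1)
        p = np.clip(base[None, :] + rng.normal(0, 0.05, (self.K, L)),
                    0.05, 0.95)
        return q, p

    def loglik(self, q: np.ndarray, p: np.ndarray) -> float:
        f1 = np.clip(q @ p, _EPS, None)
        f0 = np.clip(q @ (1.0 - p), _EPS, None)
        ll = self._w * (self._g * np.log(f1)
                        + (2.0 - self._g) * np.log(f0))
        return float(ll.sum())

    def fit(self, seed: int = 0, max_iter: int = 2000, tol: float = 1e-6
            ) -> "AdmixtureResults":
        """Run EM until the per-iteration log-likelihood gain is below
        ``tol`` (relative) or ``max_iter`` is reached."""
        rng = np.random.default_rng(seed)
        g, w = self._g, self._w
        n, L = g.shape
        q, p = self._init(rng)
        j_i = 2.0 * w.sum(axis=1)
        trace = [self.loglik(q, p)]
        for it in range(max_iter):
            f1 = np.clip(q @ p, _EPS, None)
            f0 = np.clip(q @ (1.0 - p), _EPS, None)
            a = w * g / f1
            b = w * (2.0 - g) / f0
            # q-step: expected pool-of-origin counts per individual
            q_new = q * (a @ p.T + b @ (1.0 - p).T) / j_i[:, None]
            q_new /= q_new.sum(axis=1, keepdims=True)
            # p-step: expected alt vs ref draws per pool and site
            u = q.T @ a
            v = q.T @ b
            num = p * u
            den = num + (1.0 - p) * v
            p_new = np.where(den > 0, num / np.maximum(den, _EPS), p)
            p_new = np.clip(p_new, _EPS, 1.0 - _EPS)
            q, p = q_new, p_new
            ll = self.loglik(q, p)
            if not np.isfinite(ll):
                raise FloatingPointError(
                    f"non-finite log-likelihood at iteration {it}")
            trace.append(ll)
            if abs(trace[-1] - trace[-2]) <= tol * (abs(trace[-2]) + 1.0):
                break
        Q = AncestryMatrix(self.G.samples, q,
                           meta={"K": self.K, "seed": seed,
                                 "iterations": len(trace) - 1})
        return AdmixtureResults(self, Q, p, np.array(trace))


@dataclass
class AdmixtureResults:
    """Fitted ancestry fractions, pool allele frequencies and the
    log-likelihood trace of the EM run."""

    model: AdmixtureModel
    Q: AncestryMatrix
    pool_frequencies: np.ndarray
    loglik_trace: np.ndarray

    @property
    def converged(self) -> bool:
        return len(self.loglik_trace) - 1 < 2000

    def predict_dosage(self) -> np.ndarray:
        """Expected dosage 2 * sum_k q_ik p_kj for every (i, j)."""
        return 2.0 * (self.Q.q @ self.pool_frequencies)

    def summary(self) -> str:
        q = self.Q.q
        lines = [
            "Admixture model (EM)",
            f"  samples: {len(self.Q.samples)}   sites: "
            f"{self.model.G.n_sites}   K: {self.Q.K}",
            f"  iterations: {self.Q.meta.get('iterations')}   "
            f"final log-likelihood: {self.loglik_trace[-1]:.2f}",
            f"  mean max ancestry: {q.max(axis=1).mean():.3f}",
        ]
        return "\n".join(lines)


def em_admixture(G: GenotypeMatrix, K: int, seed: int = 0,
                 max_iter: int = 2000, tol: float = 1e-6
                 ) -> tuple[AncestryMatrix, np.ndarray, np.ndarray]:
    """Functional wrapper: returns (Q, pool frequencies, loglik trace)."""
    res = AdmixtureModel(G, K).fit(seed=seed, max_iter=max_iter, tol=tol)
    return res.Q, res.pool_frequencies, res.loglik_trace


# ---------------------------------------------------------------------
# K selection by masked cross-validation

def choose_k_cv(G: GenotypeMatrix, k_grid: list[int], replicates: int = 3,
                mask_fraction: float = 0.1, seed: int = 0,
                max_iter: int = 300, tol: float = 1e-5) -> pd.DataFrame:
    """Choose K by hold-out prediction of masked dosages.

    Per replicate a random ``mask_fraction`` of non-missing dosages is
    hidden, the model fitted on the rest, and the hidden entries
    predicted as 2 * sum_k q_ik p_kj; the CV error is their mean
    squared deviation. Returns a table (K, cv_error) sorted by K, with
    the argmin flagged.
    """
    if not k_grid:
        raise ValueError("empty K grid")
    if not 0 < mask_fraction < 0.5:
        raise ValueError("mask_fraction must be in (0, 0.5)")
    rng = np.random.default_rng(seed)
    obs_idx = np.argwhere(G.dosages != MISSING)
    errors = {k: [] for k in k_grid}
    for rep in range(replicates):
        n_mask = max(1, int(round(mask_fraction * len(obs_idx))))
        sel = rng.choice(len(obs_idx), size=n_mask, replace=False)
        mask = obs_idx[sel]
        dos = G.dosages.copy()
        truth = dos[mask[:, 0], mask[:, 1]].astype(float)
        dos[mask[:, 0], mask[:, 1]] = MISSING
        # drop sites that became all-missing under the mask
        ok = (dos != MISSING).any(axis=0)
        Gm = GenotypeMatrix(G.samples, [s for s, o in zip(G.sites, ok) if o],
                            dos[:, ok])
        col_map = np.cumsum(ok) - 1
        keep = ok[mask[:, 1]]
        rows, cols = mask[keep, 0], col_map[mask[keep, 1]]
        truth = truth[keep]
        for k in k_grid:
            fit_seed = int(rng.integers(0, 2**31 - 1))
            res = AdmixtureModel(Gm, k).fit(seed=fit_seed,
                                            max_iter=max_iter, tol=tol)
            pred = res.predict_dosage()[rows, cols]
            errors[k].append(float(np.mean((pred - truth) ** 2)))
    table = pd.DataFrame({"K": sorted(k_grid),
                          "cv_error": [float(np.mean(errors[k]))
                                       for k in sorted(k_grid)]})
    table["best"] = table["cv_error"] == table["cv_error"].min()
    return table


# ---------------------------------------------------------------------
# label alignment across runs

def align_cluster_labels(reference: AncestryMatrix, other: AncestryMatrix
                         ) -> list[int]:
    """Permutation of ``other``'s columns best matching ``reference``.

    Solved as an optimal assignment maximizing summed column
    correlation; when other.K > reference.K the unmatched columns keep
    their original order after the matched ones. Apply as
    ``other.q[:, perm]``.
    """
    if reference.samples != other.samples:
        raise ValueError("sample lists differ")
    if other.K < reference.K:
        raise ValueError("other must have at least reference.K columns")
    ref, oth = reference.q, other.q
    corr = np.zeros((reference.K, other.K))
    for i in range(reference.K):
        for j in range(other.K):
            a, b = ref[:, i], oth[:, j]
            if a.std() == 0 or b.std() == 0:
                corr[i, j] = 0.0
            else:
                corr[i, j] = np.corrcoef(a, b)[0, 1]
    rows, cols = linear_sum_assignment(-corr)
    perm = [int(cols[np.argwhere(rows == i)[0, 0]])
            for i in range(reference.K)]
    perm += [j for j in range(other.K) if j not in set(perm)]
    return perm


# ---------------------------------------------------------------------
# taxon-level summaries

def taxon_ancestry_profile(Q: AncestryMatrix, M: SampleMap) -> pd.DataFrame:
    """Unweighted mean ancestry vector per taxon (rows sum to 1)."""
    taxon_of = M.taxon_of_sample()
    missing = [s for s in Q.samples if s not in taxon_of]
    if missing:
        raise ValueError(f"sample {missing[0]!r} absent from sample map")
    df = pd.DataFrame(Q.q, index=[taxon_of[s] for s in Q.samples])
    profiles = df.groupby(level=0, sort=False).mean()
    order = [t for t in M.taxa if t in profiles.index]
    for t in set(M.taxa) - set(profiles.index):
        log.warning("taxon %s has no samples in Q; excluded", t)
    return profiles.loc[order]


@dataclass
class PurityCall:
    """Per-taxon gene-pool purity classification.

    ``q_star`` is the maximum mean ancestry over pools;
    PURE iff q* >= pure_threshold, SUBTHRESHOLD iff
    override_floor <= q* < pure_threshold, ADMIXED otherwise.
    ``contributing_pools`` lists pools with mean ancestry >= the minor
    threshold, sorted by decreasing contribution.
    """

    taxon: str
    dominant_pool: int
    q_star: float
    purity_class: str
    contributing_pools: list[int] = field(default_factory=list)

    @property
    def is_admixed(self) -> bool:
        return self.purity_class == ADMIXED


def classify_purity(profile: np.ndarray, taxon: str = "",
                    pure_threshold: float = 0.95,
                    override_floor: float = 0.70,
                    minor_threshold: float = 0.05) -> PurityCall:
    """Classify one taxon-mean ancestry vector."""
    profile = np.asarray(profile, dtype=float)
    if not np.isclose(profile.sum(), 1.0, atol=1e-3):
        raise ValueError("profile does not sum to 1")
    dominant = int(np.argmax(profile))
    q_star = float(profile[dominant])
    if q_star >= pure_threshold:
        cls = PURE
    elif q_star >= override_floor:
        cls = SUBTHRESHOLD
    else:
        cls = ADMIXED
    pools = [int(k) for k in np.argsort(profile)[::-1]
             if profile[k] >= minor_threshold]
    return PurityCall(taxon, dominant, q_star, cls, pools)


def classify_taxa(Q: AncestryMatrix, M: SampleMap, **kwargs
                  ) -> dict[str, PurityCall]:
    """Purity calls for every taxon in one ancestry run."""
    profiles = taxon_ancestry_profile(Q, M)
    return {t: classify_purity(profiles.loc[t].to_numpy(), taxon=t, **kwargs)
            for t in profiles.index}


def shared_pool_pairs(calls: list[PurityCall]) -> list[tuple[str, str]]:
    """Unordered pairs of non-ADMIXED taxa sharing a dominant pool."""
    by_pool: dict[int, list[str]] = {}
    for c in calls:
        if not c.is_admixed:
            by_pool.setdefault(c.dominant_pool, []).append(c.taxon)
    pairs = []
    for members in by_pool.values():
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                pairs.append((members[i], members[j]))
    return pairs


def count_novel_singleton_pools(calls: list[PurityCall],
                                n_legacy_pools: int) -> int:
    """Pools new relative to a coarser run (index >= ``n_legacy_pools``)
    that are the dominant pool of exactly one taxon, regardless of that
    taxon's purity class."""
    holders: dict[int, int] = {}
    for c in calls:
        holders[c.dominant_pool] = holders.get(c.dominant_pool, 0) + 1
    return sum(1 for pool, n in holders.items()
               if pool >= n_legacy_pools and n == 1)
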