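"""Post-variant-calling site filtering, LD pruning and genotype PCA.

These reproduce the standard reduced-representation workflow applied
downstream of a raw VCF: drop sites by missingness, minor allele count
and minor allele frequency, thin the survivors by pairwise linkage
disequilibrium in sliding windows (the PLINK ``--indep-pairwise``
convention: 50-SNP windows advanced in 10-SNP steps, r^2 > 0.1
excluded), and ordinate samples by allele-frequency-standardized PCA.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datatypes import MISSING, GenotypeMatrix


@dataclass
class FilterReport:
    """Site counts at each filtering stage plus the thresholds used."""

    stages: list[tuple[str, int]] = field(default_factory=list)
    thresholds: dict[str, float] = field(default_factory=dict)

    def add(self, stage: str, count: int) -> None:
        if self.stages and count > self.stages[-1][1]:
            raise ValueError("stage counts must be non-increasing")
        self.stages.append((stage, count))

    def to_tsv(self) -> str:
        lines = ["stage\tsites"]
        lines += [f"{s}\t{n}" for s, n in self.stages]
        return "\n".join(lines) + "\n"

    def __getitem__(self, stage: str) -> int:
        for s, n in self.stages:
            if s == stage:
                return n
        raise KeyError(stage)


def _allele_stats(dosages: np.ndarray) -> tuple[np.ndarray, np.ndarray,
                                                np.ndarray]:
    """Per-site (missing fraction, minor allele count, minor allele freq).

    Counts are over non-missing diploid genotypes; the minor allele is
    whichever of ref/alt is less frequent at that site. Sites with all
    genotypes missing get MAC 0 and MAF 0.
    """
    obs = dosages != MISSING
    n_obs = obs.sum(axis=0)
    miss_frac = 1.0 - n_obs / dosages.shape[0]
    alt = np.where(obs, dosages, 0).sum(axis=0)
    total = 2 * n_obs
    ref = total - alt
    mac = np.minimum(alt, ref)
    with np.errstate(invalid="ignore", divide="ignore"):
        maf = np.where(total > 0, mac / np.maximum(total, 1), 0.0)
    return miss_frac, mac, maf


def filter_sites(G: GenotypeMatrix, max_missing: float = 0.15,
                 min_mac: int = 3, min_maf: float = 0.05
                 ) -> tuple[GenotypeMatrix, FilterReport]:
    """Keep sites with missingness <= ``max_missing``, MAC >= ``min_mac``
    and MAF >= ``min_maf`` (all boundaries inclusive on the keep side)."""
    report = FilterReport(thresholds={"max_missing": max_missing,
                                      "min_mac": min_mac,
                                      "min_maf": min_maf})
    report.add("input", G.n_sites)
    miss, mac, maf = _allele_stats(G.dosages)
    keep = miss <= max_missing
    report.add("missingness", int(keep.sum()))
    keep &= mac >= min_mac
    report.add("mac", int(keep.sum()))
    keep &= maf >= min_maf
    report.add("maf", int(keep.sum()))
    return G.take_sites(np.flatnonzero(keep)), report


# ---------------------------------------------------------------------
# LD pruning

def _pairwise_r2(dosages: np.ndarray) -> np.ndarray:
    """Squared Pearson correlation between dosage columns.

    Missing entries are excluded pairwise; monomorphic columns (within
    the shared-observation overlap) yield r^2 = 0 with everything.
    """
    d = np.where(dosages == MISSING, np.nan, dosages).astype(float)
    n, m = d.shape
    r2 = np.zeros((m, m))
    obs = ~np.isnan(d)
    if obs.all():
        sd = d.std(axis=0)
        ok = sd > 0
        c = np.zeros((m, m))
        if ok.any():
            cc = np.corrcoef(d[:, ok], rowvar=False)
            cc = np.atleast_2d(cc)
            c[np.ix_(ok, ok)] = cc
        r2 = np.nan_to_num(c ** 2)
    else:
        for i in range(m):
            for j in range(i + 1, m):
                mask = obs[:, i] & obs[:, j]
                if mask.sum() < 2:
                    continue
                x, y = d[mask, i], d[mask, j]
                if x.std() == 0 or y.std() == 0:
                    continue
                r = np.corrcoef(x, y)[0, 1]
                r2[i, j] = r2[j, i] = r * r
    np.fill_diagonal(r2, 0.0)
    return r2


def _prune_chromosome(dosages: np.ndarray, window: int, step: int,
                      r2_max: float) -> np.ndarray:
    """Greedy within-window pruning; returns a boolean keep mask.

    In each window the pair of retained sites with the highest r^2 above
    the threshold loses its later member; ties go to the pair whose
    later index is larger (deterministic, order-stable).
    """
    m = dosages.shape[1]
    keep = np.ones(m, dtype=bool)
    r2 = _pairwise_r2(dosages)
    start = 0
    while True:
        stop = min(start + window, m)
        idx = np.arange(start, stop)
        while True:
            live = idx[keep[idx]]
            if len(live) < 2:
                break
            sub = r2[np.ix_(live, live)]
            mx = sub.max()
            if mx <= r2_max:
                break
            ii, jj = np.where(sub >= mx - 1e-12)
            later = max(live[max(a, b)] for a, b in zip(ii, jj))
            keep[later] = False
        if stop >= m:
            break
        start += step
    return keep


def ld_prune(G: GenotypeMatrix, window_sites: int = 50,
             step_sites: int = 10, r2_max: float = 0.1
             ) -> tuple[GenotypeMatrix, FilterReport]:
    """Sliding-window LD pruning on dosages (composite LD).

    Windows never span chromosomes. Within each window, sites are
    greedily removed while any retained pair exceeds ``r2_max``.
    """
    report = FilterReport(thresholds={"window": window_sites,
                                      "step": step_sites,
                                      "r2": r2_max})
    report.add("input", G.n_sites)
    chroms = np.array([s.chrom for s in G.sites])
    keep = np.ones(G.n_sites, dtype=bool)
    for chrom in dict.fromkeys(chroms):
        idx = np.flatnonzero(chroms == chrom)
        mask = _prune_chromosome(G.dosages[:, idx], window_sites,
                                 step_sites, r2_max)
        keep[idx] = mask
    report.add("ld_prune", int(keep.sum()))
    return G.take_sites(np.flatnonzero(keep)), report


# ---------------------------------------------------------------------
# genotype PCA

def genotype_pca(G: GenotypeMatrix, n_components: int
                 ) -> tuple[np.ndarray, np.ndarray]:
    """PCA of dosages standardized by sqrt(2p(1-p)).

    Missing dosages are mean-imputed per site; p is the alternate-allele
    frequency over observed genotypes. Returns (scores, variance
    fractions) with components ordered by decreasing eigenvalue.
    """
    if G.n_samples < 2:
        raise ValueError("need at least 2 samples")
    d = np.where(G.dosages == MISSING, np.nan, G.dosages).astype(float)
    p = np.nanmean(d, axis=0) / 2.0
    mean = 2.0 * p
    d = np.where(np.isnan(d), mean[None, :], d)
    scale = np.sqrt(2.0 * p * (1.0 - p))
    poly = scale > 0
    if not poly.any():
        raise ValueError("no polymorphism")
    X = (d[:, poly] - mean[None, poly]) / scale[None, poly]
    u, s, _ = np.linalg.svd(X, full_matrices=False)
    eig = s ** 2
    total = eig.sum()
    k = min(n_components, len(s))
    scores = u[:, :k] * s[:k]
    fractions = eig[:k] / total
    return scores, fractions
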