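"""Genotype-based population structure: LD pruning, PCA, admixture EM, Fst.

PCA uses Patterson normalization (center by 2p, scale by sqrt(p(1-p)),
mean-impute missing) on genotype dosages, or a row-centered decomposition
of a coancestry chunk-count matrix. The unsupervised admixture model is the
standard binomial mixture Bin(g_is | 2, sum_k Q_ik F_ks) fit by plain EM
with random restarts (same likelihood surface as the block-relaxation
solvers used by dedicated tools, deliberately simpler). Fst is the Hudson
estimator as a ratio of averages with small-sample correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average as upgma_linkage
from scipy.spatial.distance import squareform

from .genotypes import MISSING, GenotypeMatrix

__all__ = [
    "PCAResult",
    "AdmixtureResult",
    "ld_prune",
    "pca",
    "admixture_em",
    "hudson_fst",
    "wc_fst",
    "fst_matrix",
    "upgma_tree",
]


@dataclass
class PCAResult:
    coordinates: pd.DataFrame  # individuals x PC1..PCn
    explained_variance: np.ndarray

    def pc(self, k: int) -> np.ndarray:
        """1-based principal-component scores."""
        return self.coordinates[f"PC{k}"].to_numpy()


@dataclass
class AdmixtureResult:
    Q: pd.DataFrame  # individuals x K
    F: np.ndarray  # K x sites
    log_likelihood: float


def _dosage_matrix(g: GenotypeMatrix) -> np.ndarray:
    d = g.dosage.astype(float)
    d[g.dosage == MISSING] = np.nan
    return d


def ld_prune(
    g: GenotypeMatrix, window: int = 200, step: int = 5, r2_max: float = 0.2
) -> np.ndarray:
    """Indices of SNPs surviving sliding-window r^2 pruning.

    Within each window, for every pair with genotype-dosage r^2 above the
    threshold the later SNP is removed; windows advance by ``step``.
    Deterministic and order-fixed.
    """
    if not window > step >= 1:
        raise ValueError("need window > step >= 1")
    d = _dosage_matrix(g)
    keep = np.ones(g.n_sites, dtype=bool)
    col_mean = np.nanmean(d, axis=0)
    filled = np.where(np.isnan(d), col_mean, d)
    for start in range(0, g.n_sites, step):
        idx = np.nonzero(keep[start : start + window])[0] + start
        if idx.size < 2:
            continue
        sub = filled[:, idx]
        sd = sub.std(axis=0)
        ok = sd > 0
        if ok.sum() < 2:
            continue
        sub = (sub[:, ok] - sub[:, ok].mean(axis=0)) / sd[ok]
        r2 = (sub.T @ sub / sub.shape[0]) ** 2
        live = idx[ok]
        for a in range(live.size):
            if not keep[live[a]]:
                continue
            for b in range(a + 1, live.size):
                if keep[live[b]] and r2[a, b] > r2_max:
                    keep[live[b]] = False
    return np.nonzero(keep)[0]


def pca(matrix, n_components: int = 10) -> PCAResult:
    """Principal components of genotypes or of a coancestry matrix.

    Genotype mode drops monomorphic sites, Patterson-normalizes and
    mean-imputes; coancestry mode row-centers the chunk-count matrix.
    """
    if isinstance(matrix, GenotypeMatrix):
        d = _dosage_matrix(matrix)
        p = np.nanmean(d, axis=0) / 2.0
        poly = (p > 0) & (p < 1)
        d = d[:, poly]
        p = p[poly]
        x = (d - 2 * p) / np.sqrt(p * (1 - p))
        x = np.where(np.isnan(x), 0.0, x)
        index = list(matrix.samples)
    else:
        x = np.asarray(
            matrix.chunk_counts if hasattr(matrix, "chunk_counts") else matrix,
            dtype=float,
        )
        index = (
            list(matrix.chunk_counts.index)
            if hasattr(matrix, "chunk_counts")
            else list(range(x.shape[0]))
        )
        x = x - x.mean(axis=0, keepdims=True)
    n = x.shape[0]
    if n < 2:
        raise ValueError("need at least 2 individuals")
    cov = x @ x.T / x.shape[1]
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    rank = int(np.sum(vals > 1e-10 * max(vals[0], 1.0)))
    if n_components > rank:
        import warnings

        warnings.warn(f"n_components truncated to rank {rank}", stacklevel=2)
        n_components = rank
    coords = vecs[:, :n_components] * np.sqrt(np.maximum(vals[:n_components], 0.0))
    return PCAResult(
        coordinates=pd.DataFrame(
            coords, index=index, columns=[f"PC{k + 1}" for k in range(n_components)]
        ),
        explained_variance=vals[:n_components] / vals[vals > 0].sum(),
    )


def _admixture_em_once(d, K, rng, max_iter, tol):
    n, s = d.shape
    called = ~np.isnan(d)
    g = np.where(called, d, 0.0)
    two = np.where(called, 2.0, 0.0)
    Q = rng.dirichlet(np.ones(K), size=n)
    F = rng.uniform(0.05, 0.95, size=(K, s))
    prev = -np.inf
    for _ in range(max_iter):
        P = Q @ F  # expected alt-allele frequency per (i, s)
        P = np.clip(P, 1e-12, 1 - 1e-12)
        # responsibilities of cluster k for alt and ref allele copies
        ll = float(np.sum((g * np.log(P) + (two - g) * np.log1p(-P))[called]))
        if ll < prev - 1e-6:
            raise RuntimeError(f"admixture EM likelihood decreased: {prev} -> {ll}")
        a = g / P  # (n, s)
        b = (two - g) / (1 - P)
        EA = Q[:, :, None] * F[None, :, :] * a[:, None, :]  # hmm memory n*K*s
        EB = Q[:, :, None] * (1 - F)[None, :, :] * b[:, None, :]
        Q = (EA + EB).sum(axis=2)
        Q /= Q.sum(axis=1, keepdims=True)
        F = EA.sum(axis=0) / np.clip((EA + EB).sum(axis=0), 1e-12, None)
        F = np.clip(F, 1e-6, 1 - 1e-6)
        if ll - prev < tol:
            prev = ll
            break
        prev = ll
    return Q, F, prev


def admixture_em(
    g: GenotypeMatrix,
    K: int,
    n_restarts: int = 20,
    max_iter: int = 300,
    tol: float = 1e-4,
    seed: int = 0,
) -> AdmixtureResult:
    """Unsupervised admixture proportions by EM with random restarts.

    Maximizes the binomial likelihood prod Bin(g_is | 2, (QF)_is); the best
    of ``n_restarts`` runs is returned with clusters ordered by the
    lexicographic order of their frequency vectors (label-switching
    resolution).
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    d = _dosage_matrix(g)
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(max_restarts := max(1, n_restarts)):
        Q, F, ll = _admixture_em_once(d, K, rng, max_iter, tol)
        if best is None or ll > best[2]:
            best = (Q, F, ll)
    Q, F, ll = best
    order = sorted(range(K), key=lambda k: tuple(F[k]))
    Q, F = Q[:, order], F[order]
    return AdmixtureResult(
        Q=pd.DataFrame(Q, index=list(g.samples), columns=[f"K{k}" for k in range(K)]),
        F=F,
        log_likelihood=ll,
    )


def _pop_counts(g: GenotypeMatrix, pop: str):
    idx = [i for i, s in enumerate(g.samples) if g.populations[i] == pop]
    if len(idx) < 2:
        raise ValueError(f"population {pop!r} needs >= 2 individuals")
    ac, an = g.allele_counts(idx)
    return ac, an


def hudson_fst(
    g: GenotypeMatrix, pop_a: str, pop_b: str, return_components: bool = False
):
    """Hudson Fst as a ratio of averages with small-sample correction.

    Per site: numerator (pa-pb)^2 - pa(1-pa)/(na-1) - pb(1-pb)/(nb-1),
    denominator pa(1-pb) + pb(1-pa), with n the called haplotype counts.
    """
    ac_a, an_a = _pop_counts(g, pop_a)
    ac_b, an_b = _pop_counts(g, pop_b)
    ok = (an_a > 1) & (an_b > 1)
    pa = ac_a[ok] / an_a[ok]
    pb = ac_b[ok] / an_b[ok]
    num = (
        (pa - pb) ** 2
        - pa * (1 - pa) / (an_a[ok] - 1)
        - pb * (1 - pb) / (an_b[ok] - 1)
    )
    den = pa * (1 - pb) + pb * (1 - pa)
    use = den > 0
    fst = float(num[use].sum() / den[use].sum())
    if return_components:
        return fst, num, den
    return fst


def wc_fst(g: GenotypeMatrix, pop_a: str, pop_b: str) -> float:
    """Weir-Cockerham theta for two populations (alternative estimator).

    Alleles are treated as the sampling unit (haploid ANOVA form, r=2
    groups with the called haplotype counts as sample sizes).
    """
    ac_a, an_a = _pop_counts(g, pop_a)
    ac_b, an_b = _pop_counts(g, pop_b)
    ok = (an_a > 1) & (an_b > 1)
    n1, n2 = an_a[ok].astype(float), an_b[ok].astype(float)
    p1, p2 = ac_a[ok] / n1, ac_b[ok] / n2
    n = n1 + n2
    nbar = n / 2
    nc = n - (n1**2 + n2**2) / n  # r - 1 = 1
    pbar = (n1 * p1 + n2 * p2) / n
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / nbar
    a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - s2 / 2) / (nbar - 1))
    b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - s2 / 2)
    den = a + b
    use = den > 0
    return float(a[use].sum() / den[use].sum())


def fst_matrix(g: GenotypeMatrix, pops: list[str] | None = None) -> pd.DataFrame:
    if pops is None:
        pops = list(dict.fromkeys(g.populations))
    m = pd.DataFrame(0.0, index=pops, columns=pops)
    for i, a in enumerate(pops):
        for b in pops[i + 1 :]:
            f = hudson_fst(g, a, b)
            m.loc[a, b] = m.loc[b, a] = f
    return m


def upgma_tree(dist: pd.DataFrame):
    """UPGMA (average-linkage) clustering of a distance matrix.

    Returns the scipy linkage matrix; merge heights are cophenetic
    distances (ultrametric by construction).
    """
    condensed = squareform(dist.to_numpy(), checks=False)
    return upgma_linkage(condensed)
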