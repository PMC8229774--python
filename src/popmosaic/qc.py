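"""Site/genotype filtering, Hardy-Weinberg exact test, Ti/Tv and kinship.

The filter cascade mirrors a standard VCFtools-style pass over an exome
cohort: non-autosomal and multi-allelic sites are dropped first, genotypes
below the depth/quality floor are masked to missing, then high-coverage and
high-missingness sites are removed. Relatedness uses the KING-robust
within-pair kinship estimator, which is insensitive to population
structure, with greedy pruning above a first/second-degree boundary.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .genotypes import MISSING, GenotypeMatrix, is_autosome

__all__ = [
    "FilterReport",
    "filter_sites",
    "hwe_exact_test",
    "hwe_filter",
    "ti_tv",
    "king_kinship",
    "kinship_matrix",
    "prune_relatives",
]

TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


@dataclass
class FilterReport:
    """Per-rule removal counts for one filtering pass."""

    input_sites: int = 0
    removed: dict = field(default_factory=dict)
    masked_genotypes: int = 0
    surviving_sites: int = 0
    ti_tv: float | None = None

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, default=str)


def filter_sites(
    g: GenotypeMatrix,
    max_mean_depth: float = 35.0,
    min_geno_depth: int = 3,
    min_geno_qual: int = 20,
    max_missing: float = 0.15,
) -> tuple[GenotypeMatrix, FilterReport]:
    """Apply the site/genotype filter cascade in fixed order.

    1. drop non-autosomal and multi-allelic/non-SNP sites;
    2. mask genotypes with depth < min_geno_depth or quality < min_geno_qual;
    3. drop sites with mean depth >= max_mean_depth;
    4. drop sites whose missing fraction (after masking) exceeds max_missing.
    """
    if min(max_mean_depth, min_geno_depth, min_geno_qual, max_missing) < 0:
        raise ValueError("thresholds must be nonnegative")
    report = FilterReport(input_sites=g.n_sites)

    biallelic = np.array(
        [
            len(str(r)) == 1 and len(str(a)) == 1 and str(a) in "ACGT" and r != a
            for r, a in zip(g.ref, g.alt)
        ]
    )
    autosomal = np.array([is_autosome(str(c)) for c in g.chrom])
    keep = biallelic & autosomal
    report.removed["non_autosomal_or_multiallelic"] = int(np.count_nonzero(~keep))
    g = g.take_sites(np.nonzero(keep)[0])

    dosage = g.dosage.copy()
    if g.depth is not None and min_geno_depth > 0:
        mask = (g.depth < min_geno_depth) & (dosage != MISSING)
        dosage[mask] = MISSING
        report.masked_genotypes += int(mask.sum())
    if g.qual is not None and min_geno_qual > 0:
        mask = (g.qual < min_geno_qual) & (dosage != MISSING)
        dosage[mask] = MISSING
        report.masked_genotypes += int(mask.sum())
    g = GenotypeMatrix(
        samples=g.samples,
        chrom=g.chrom,
        pos=g.pos,
        ref=g.ref,
        alt=g.alt,
        dosage=dosage,
        depth=g.depth,
        qual=g.qual,
        populations=g.populations,
    )

    if g.depth is not None:
        mean_depth = g.depth.mean(axis=0)
        keep = mean_depth < max_mean_depth
        report.removed["excess_mean_depth"] = int(np.count_nonzero(~keep))
        g = g.take_sites(np.nonzero(keep)[0])
    else:
        report.removed["excess_mean_depth"] = 0

    miss_frac = (g.dosage == MISSING).mean(axis=0)
    keep = miss_frac <= max_missing
    report.removed["missingness"] = int(np.count_nonzero(~keep))
    g = g.take_sites(np.nonzero(keep)[0])

    report.surviving_sites = g.n_sites
    report.ti_tv = ti_tv(g)
    return g, report


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact two-sided Hardy-Weinberg test.

    Conditional on the allele counts, the p-value sums the probabilities of
    all heterozygote configurations no more probable than the observed one.
    Monomorphic sites return 1 (nothing to reject).
    """
    if min(n_AA, n_Aa, n_aa) < 0 or (n_AA + n_Aa + n_aa) < 1:
        raise ValueError("counts must be nonnegative with positive sum")
    n = n_AA + n_Aa + n_aa
    n_a = 2 * n_aa + n_Aa  # rare or not; symmetry makes the choice irrelevant
    n_a = min(n_a, 2 * n - n_a)
    if n_a == 0:
        return 1.0
    # log P(n_het | n, n_a) up to a shared constant
    het_values = np.arange(n_a % 2, n_a + 1, 2)
    logp = np.array(
        [
            het * math.log(2)
            - math.lgamma((n_a - het) // 2 + 1)
            - math.lgamma(het + 1)
            - math.lgamma(n - (n_a + het) // 2 + 1)
            for het in het_values
        ]
    )
    prob = np.exp(logp - logp.max())
    prob /= prob.sum()
    obs = np.nonzero(het_values == min(n_Aa, n_a))[0]
    if obs.size == 0:  # parity mismatch cannot happen with consistent counts
        raise ValueError("inconsistent genotype counts")
    p_obs = prob[obs[0]]
    return float(min(1.0, prob[prob <= p_obs * (1 + 1e-12)].sum()))


def hwe_filter(
    g: GenotypeMatrix,
    labels: dict[str, str] | None = None,
    alpha: float = 0.05,
    min_pops: int = 2,
) -> tuple[GenotypeMatrix, FilterReport]:
    """Remove sites out of Hardy-Weinberg in at least ``min_pops`` populations."""
    if labels is None:
        if g.populations is None:
            raise ValueError("population labels required")
        pops = np.asarray(g.populations, dtype=object)
    else:
        pops = np.asarray([labels[s] for s in g.samples], dtype=object)
    unique_pops = [p for p in dict.fromkeys(pops)]
    if len(unique_pops) < min_pops:
        import warnings

        warnings.warn(
            f"only {len(unique_pops)} population(s); no site can fail the "
            f">= {min_pops}-population rule",
            stacklevel=2,
        )
    report = FilterReport(input_sites=g.n_sites)
    n_fail = np.zeros(g.n_sites, dtype=int)
    for pop in unique_pops:
        idx = np.nonzero(pops == pop)[0]
        d = g.dosage[idx, :]
        n_aa = (d == 2).sum(axis=0)
        n_het = (d == 1).sum(axis=0)
        n_AA = (d == 0).sum(axis=0)
        pvals = np.array(
            [
                hwe_exact_test(int(a), int(h), int(b)) if a + h + b > 0 else 1.0
                for a, h, b in zip(n_AA, n_het, n_aa)
            ]
        )
        n_fail += pvals < alpha
    keep = n_fail < min_pops
    report.removed["hwe"] = int(np.count_nonzero(~keep))
    out = g.take_sites(np.nonzero(keep)[0])
    report.surviving_sites = out.n_sites
    return out, report


def ti_tv(g: GenotypeMatrix) -> float:
    """Transition/transversion count ratio over sites (inf if no transversions)."""
    ti = tv = 0
    for r, a in zip(g.ref, g.alt):
        r, a = str(r), str(a)
        if len(r) != 1 or len(a) != 1 or r == a:
            continue
        if (r, a) in TRANSITIONS:
            ti += 1
        else:
            tv += 1
    if tv == 0:
        return math.inf if ti > 0 else math.nan
    return ti / tv


def king_kinship(g: GenotypeMatrix, i: str | int, j: str | int) -> float:
    """KING-robust within-pair kinship coefficient.

    phi = (N_het,het - 2 N_opposite_hom) / (N_het(i) + N_het(j)) over
    jointly called sites. Self-comparison gives 0.5; unrelated pairs ~0;
    parent-offspring ~0.25.
    """
    ii = g.sample_index(i) if isinstance(i, str) else i
    jj = g.sample_index(j) if isinstance(j, str) else j
    a = g.dosage[ii]
    b = g.dosage[jj]
    ok = (a != MISSING) & (b != MISSING)
    if not ok.any():
        raise ValueError("no jointly called sites")
    a, b = a[ok], b[ok]
    n_het_het = int(np.count_nonzero((a == 1) & (b == 1)))
    n_opp = int(np.count_nonzero(((a == 0) & (b == 2)) | ((a == 2) & (b == 0))))
    n_het_i = int(np.count_nonzero(a == 1))
    n_het_j = int(np.count_nonzero(b == 1))
    denom = n_het_i + n_het_j
    if denom == 0:
        return math.nan
    return (n_het_het - 2 * n_opp) / denom


def kinship_matrix(g: GenotypeMatrix) -> np.ndarray:
    n = g.n_samples
    phi = np.zeros((n, n))
    for i in range(n):
        phi[i, i] = 0.5
        for j in range(i + 1, n):
            phi[i, j] = phi[j, i] = king_kinship(g, i, j)
    return phi


def prune_relatives(
    g: GenotypeMatrix, threshold: float = 0.177
) -> tuple[GenotypeMatrix, list[str]]:
    """Greedily drop samples until no pair exceeds the kinship threshold.

    While any pair is above threshold, remove the member involved in more
    such pairs; ties go to the sample with more missing genotypes, then to
    the lexicographically larger id.
    """
    phi = kinship_matrix(g)
    np.fill_diagonal(phi, 0.0)
    miss = (g.dosage == MISSING).mean(axis=1)
    alive = set(range(g.n_samples))
    removed: list[int] = []
    while True:
        pairs = [
            (i, j)
            for i in alive
            for j in alive
            if i < j and phi[i, j] > threshold
        ]
        if not pairs:
            break
        degree = {i: 0 for i in alive}
        for i, j in pairs:
            degree[i] += 1
            degree[j] += 1
        worst = max(
            alive,
            key=lambda i: (degree[i], miss[i], g.samples[i]),
        )
        if degree[worst] == 0:
            break
        alive.discard(worst)
        removed.append(worst)
    keep = sorted(alive)
    return g.take_samples(keep), [g.samples[i] for i in removed]
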