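"""Y-STR descent clusters, rho-statistic TMRCA, match profiles, diversity.

Mutational distance between Y-STR haplotypes is the stepwise-model sum of
absolute repeat differences over loci (duplicated loci such as DYS385 can
be masked out). A descent cluster grows from the modal (presumed
ancestral) haplotype by breadth-first addition of sampled haplotypes one
single-step mutation away from a current member; the rho statistic (mean
mutational distance of members to the ancestral haplotype) converts to a
TMRCA given a per-locus mutation rate and generation time, with a
star-genealogy standard error of sqrt(rho/n)/(L*mu) generations.
"""

from __future__ import annotations

from collections import Counter, deque
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simdata import YSTRDataset

__all__ = [
    "DescentCluster",
    "TMRCAEstimate",
    "modal_haplotype",
    "delimit_descent_cluster",
    "cluster_from_sample",
    "rho_tmrca",
    "match_profile",
    "seq_diversity",
]


@dataclass
class DescentCluster:
    ancestral: tuple
    members: list[tuple]  # unique haplotypes in the cluster
    multiplicities: dict  # haplotype -> sample count
    distances: dict  # haplotype -> mutational distance to ancestral

    @property
    def n(self) -> int:
        return sum(self.multiplicities.values())

    @property
    def rho(self) -> float:
        return (
            sum(self.distances[h] * self.multiplicities[h] for h in self.members)
            / self.n
        )


@dataclass
class TMRCAEstimate:
    rho: float
    n_lineages: int
    generations: float
    years: float
    ci_low_years: float
    ci_high_years: float
    mu: float
    n_loci: int
    generation_time: float


def _hap_tuples(data: YSTRDataset, locus_mask=None) -> list[tuple]:
    haps = data.haplotypes
    if locus_mask is not None:
        keep = [i for i, loc in enumerate(data.loci) if loc not in set(locus_mask)]
        haps = haps[:, keep]
    return [tuple(int(x) for x in row) for row in haps]


def modal_haplotype(
    data: YSTRDataset, pop: str | None = None, locus_mask=None
) -> tuple[tuple, float]:
    """Most frequent haplotype and its sample frequency.

    Ties are broken deterministically: smaller total repeat sum first, then
    lexicographically smaller haplotype.
    """
    rows = (
        np.ones(data.n, dtype=bool)
        if pop is None
        else np.asarray(data.labels) == pop
    )
    if not rows.any():
        raise ValueError(f"no haplotypes in population {pop!r}")
    sub = YSTRDataset(
        loci=data.loci, haplotypes=data.haplotypes[rows], labels=data.labels[rows]
    )
    haps = _hap_tuples(sub, locus_mask)
    counts = Counter(haps)
    best = min(counts, key=lambda h: (-counts[h], sum(h), h))
    return best, counts[best] / len(haps)


def _mut_distance(a: tuple, b: tuple) -> int:
    return int(sum(abs(x - y) for x, y in zip(a, b)))


def delimit_descent_cluster(
    data: YSTRDataset,
    ancestral: tuple,
    max_step: int = 1,
    pop: str | None = None,
    locus_mask=None,
) -> DescentCluster:
    """Breadth-first descent cluster around an ancestral haplotype.

    A sampled haplotype joins the cluster when it differs from a current
    member at exactly one locus by at most ``max_step`` repeat units; the
    result is independent of input order.
    """
    rows = (
        np.ones(data.n, dtype=bool)
        if pop is None
        else np.asarray(data.labels) == pop
    )
    sub = YSTRDataset(
        loci=data.loci, haplotypes=data.haplotypes[rows], labels=data.labels[rows]
    )
    haps = _hap_tuples(sub, locus_mask)
    ancestral = tuple(int(x) for x in ancestral)
    if locus_mask is not None and len(ancestral) != len(haps[0]):
        keep = [i for i, loc in enumerate(data.loci) if loc not in set(locus_mask)]
        ancestral = tuple(ancestral[i] for i in keep)
    counts = Counter(haps)
    if ancestral not in counts:
        raise ValueError("ancestral haplotype not present in the sample")

    def one_step(a: tuple, b: tuple) -> bool:
        diffs = [abs(x - y) for x, y in zip(a, b)]
        nz = [d for d in diffs if d > 0]
        return len(nz) == 1 and nz[0] <= max_step

    members = {ancestral}
    queue = deque([ancestral])
    remaining = set(counts) - members
    while queue:
        cur = queue.popleft()
        joined = {h for h in remaining if one_step(cur, h)}
        for h in sorted(joined):
            members.add(h)
            queue.append(h)
        remaining -= joined
    member_list = sorted(members)
    return DescentCluster(
        ancestral=ancestral,
        members=member_list,
        multiplicities={h: counts[h] for h in member_list},
        distances={h: _mut_distance(h, ancestral) for h in member_list},
    )


def cluster_from_sample(
    data: YSTRDataset,
    ancestral,
    pop: str | None = None,
    locus_mask=None,
) -> DescentCluster:
    """All sampled haplotypes as one cluster around a known ancestral type.

    Used when the genealogy is known to be a single descent cluster (e.g.
    simulated star genealogies), so no neighbor-graph delimitation is
    applied; the ancestral haplotype need not be present in the sample.
    """
    rows = (
        np.ones(data.n, dtype=bool)
        if pop is None
        else np.asarray(data.labels) == pop
    )
    sub = YSTRDataset(
        loci=data.loci, haplotypes=data.haplotypes[rows], labels=data.labels[rows]
    )
    haps = _hap_tuples(sub, locus_mask)
    ancestral = tuple(int(x) for x in ancestral)
    counts = Counter(haps)
    members = sorted(counts)
    return DescentCluster(
        ancestral=ancestral,
        members=members,
        multiplicities=dict(counts),
        distances={h: _mut_distance(h, ancestral) for h in members},
    )


def rho_tmrca(
    cluster: DescentCluster,
    mu: float = 0.0025,
    n_loci: int = 10,
    gen_time: float = 30.0,
) -> TMRCAEstimate:
    """TMRCA of a descent cluster from the rho statistic.

    generations = rho / (n_loci * mu); the 95% CI uses the star-genealogy
    standard error sqrt(rho / n) / (n_loci * mu) generations, floored at 0
    years.
    """
    if mu <= 0 or gen_time <= 0 or n_loci < 1:
        raise ValueError("mu, gen_time and n_loci must be positive")
    if cluster.n < 1:
        raise ValueError("empty cluster")
    rho = cluster.rho
    rate = n_loci * mu
    generations = rho / rate
    years = generations * gen_time
    se_gen = np.sqrt(rho / cluster.n) / rate
    half = 1.96 * se_gen * gen_time
    return TMRCAEstimate(
        rho=rho,
        n_lineages=cluster.n,
        generations=generations,
        years=years,
        ci_low_years=max(0.0, years - half),
        ci_high_years=years + half,
        mu=mu,
        n_loci=n_loci,
        generation_time=gen_time,
    )


def match_profile(table: pd.DataFrame, focal_region: str) -> dict:
    """Summaries of a haplotype match-count table.

    ``table`` has columns (population, region, n_matches, sample_size);
    returns the focal region's share of matches, share of sample size and
    their ratio (representation ratio > 1 = more matches than its sampling
    weight predicts).
    """
    if table.empty:
        raise ValueError("empty match table")
    if focal_region not in set(table["region"]):
        raise ValueError(f"region {focal_region!r} not in table")
    total_matches = int(table["n_matches"].sum())
    total_size = int(table["sample_size"].sum())
    focal = table[table["region"] == focal_region]
    if total_matches == 0:
        return {
            "region": focal_region,
            "match_share": np.nan,
            "size_share": focal["sample_size"].sum() / total_size,
            "representation_ratio": np.nan,
        }
    match_share = float(focal["n_matches"].sum() / total_matches)
    size_share = float(focal["sample_size"].sum() / total_size)
    return {
        "region": focal_region,
        "match_share": match_share,
        "size_share": size_share,
        "representation_ratio": match_share / size_share if size_share else np.inf,
    }


def seq_diversity(seqs: list[str]) -> dict:
    """Haplotype and nucleotide diversity of aligned sequences.

    H = n(1 - sum p_i^2)/(n - 1); nucleotide diversity is the mean pairwise
    difference per site over all pairs, with gaps and Ns excluded pairwise.
    """
    n = len(seqs)
    if n < 2:
        raise ValueError("need at least 2 sequences")
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ValueError("sequences must be aligned to equal length")
    arr = np.array([list(s.upper()) for s in seqs])
    counts = Counter(map(tuple, arr))
    freqs = np.array([c / n for c in counts.values()])
    hap_div = n * (1 - np.sum(freqs**2)) / (n - 1)
    valid = np.isin(arr, list("ACGT"))
    pi_sum = 0.0
    n_pairs = 0
    for i in range(n - 1):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            if both.any():
                pi_sum += np.count_nonzero(arr[i, both] != arr[j, both]) / both.sum()
            n_pairs += 1
    seg = int(np.count_nonzero([(len(set(col) & set("ACGT")) > 1) for col in arr.T]))
    return {
        "n": n,
        "n_haplotypes": len(counts),
        "haplotype_diversity": float(hap_div),
        "nucleotide_diversity": float(pi_sum / n_pairs),
        "segregating_sites": seg,
    }
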