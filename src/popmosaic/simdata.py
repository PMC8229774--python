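"""Synthetic cohorts with known truth for admixture and uniparental analyses.

Source allele frequencies follow the Balding–Nichols model: given an
ancestral frequency p and a differentiation parameter F, each source draws
its site frequency from Beta(p(1-F)/F, (1-p)(1-F)/F), so that
Var = F p(1-p). Admixed diploids are built allele-copy by allele-copy from
per-individual ancestry proportions; phased mosaics, parent-offspring duos,
Y-STR genealogies (star and Wright-Fisher with heritable male dominance)
and short sequence sets cover the remaining inputs. Every generator is a
pure function of its parameters and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .genotypes import GenotypeMatrix
from .social import DominanceModel

__all__ = [
    "SourceFrequencies",
    "AdmixtureSpec",
    "YSTRDataset",
    "MosaicPanel",
    "sample_source_frequencies",
    "calibrate_fst",
    "simulate_admixed_genotypes",
    "simulate_source_haplotypes",
    "simulate_haplotype_mosaic",
    "simulate_duo",
    "simulate_ystr",
    "simulate_sequences",
]


@dataclass
class SourceFrequencies:
    """Per-source derived-allele frequencies under Balding–Nichols."""

    freq: np.ndarray  # (n_sources, n_sites)
    anc_freq: np.ndarray  # (n_sites,)
    fst: np.ndarray  # (n_sources,)
    labels: list[str] = field(default_factory=list)

    @property
    def n_sources(self) -> int:
        return self.freq.shape[0]

    @property
    def n_sites(self) -> int:
        return self.freq.shape[1]


@dataclass
class AdmixtureSpec:
    """Ground-truth ancestry make-up of one synthetic population."""

    label: str
    proportions: np.ndarray
    n_individuals: int

    def __post_init__(self) -> None:
        self.proportions = np.asarray(self.proportions, dtype=float)
        if np.any(self.proportions < 0) or abs(self.proportions.sum() - 1) > 1e-9:
            raise ValueError("proportions must be nonnegative and sum to 1")


@dataclass
class YSTRDataset:
    """Y-chromosome microsatellite haplotypes as integer repeat counts."""

    loci: list[str]
    haplotypes: np.ndarray  # (n, L) positive ints
    labels: np.ndarray  # population per haplotype
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int64)
        if self.haplotypes.ndim != 2 or self.haplotypes.shape[1] != len(self.loci):
            raise ValueError("haplotypes must be n x L with L = len(loci)")
        if np.any(self.haplotypes < 1):
            raise ValueError("repeat counts must be positive integers")

    @property
    def n(self) -> int:
        return self.haplotypes.shape[0]


@dataclass
class MosaicPanel:
    """Phased recipient haplotypes with per-site true source ancestry."""

    haps: np.ndarray  # (n_recipients, n_sites) 0/1
    true_source: np.ndarray  # (n_recipients, n_sites) index into source_labels
    true_donor: np.ndarray  # (n_recipients, n_sites) donor hap index within source
    source_labels: list[str]

    def n_segments(self, i: int) -> int:
        """Number of maximal constant-donor segments in recipient i."""
        key = self.true_source[i].astype(np.int64) * 10_000_000 + self.true_donor[i]
        return int(1 + np.count_nonzero(np.diff(key)))


def _rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)


def sample_source_frequencies(
    n_sites: int,
    fst_per_source,
    seed: int,
    anc_range: tuple[float, float] = (0.05, 0.95),
    labels: list[str] | None = None,
) -> SourceFrequencies:
    """Draw ancestral and per-source site frequencies.

    Ancestral frequencies are uniform on ``anc_range`` (bounded away from
    0/1 so synthetic sites segregate); each source then draws from the
    Balding–Nichols Beta around the ancestral frequency.
    """
    fst = np.asarray(fst_per_source, dtype=float)
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    if not np.all(np.isfinite(fst)) or np.any(fst <= 0) or np.any(fst >= 1):
        raise ValueError("each fst must be finite and in (0, 1)")
    rng = _rng(seed)
    p = rng.uniform(anc_range[0], anc_range[1], size=n_sites)
    freq = np.empty((fst.size, n_sites))
    for k, f in enumerate(fst):
        scale = (1 - f) / f
        freq[k] = rng.beta(p * scale, (1 - p) * scale)
    freq = np.clip(freq, 0.0, 1.0)
    if labels is None:
        labels = [f"SRC{k}" for k in range(fst.size)]
    return SourceFrequencies(freq=freq, anc_freq=p, fst=fst, labels=list(labels))


def _hudson_from_counts(ac1, an1, ac2, an2):
    """Per-site Hudson numerator/denominator from allele counts."""
    p1 = ac1 / an1
    p2 = ac2 / an2
    num = (
        (p1 - p2) ** 2
        - p1 * (1 - p1) / (an1 - 1)
        - p2 * (1 - p2) / (an2 - 1)
    )
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return num, den


def _mean_pair_fst(f: float, n_sites: int, sample_sizes, rng) -> float:
    p = rng.uniform(0.05, 0.95, size=n_sites)
    scale = (1 - f) / f
    p1 = rng.beta(p * scale, (1 - p) * scale)
    p2 = rng.beta(p * scale, (1 - p) * scale)
    n1, n2 = (2 * s for s in sample_sizes)
    ac1 = rng.binomial(n1, p1)
    ac2 = rng.binomial(n2, p2)
    num, den = _hudson_from_counts(ac1, np.full(n_sites, n1), ac2, np.full(n_sites, n2))
    keep = den > 0
    return float(num[keep].sum() / den[keep].sum())


def calibrate_fst(
    target_fst: float,
    n_sites: int = 100_000,
    sample_sizes: tuple[int, int] = (9, 8),
    seed: int = 0,
    reps: int = 3,
    rel_tol: float = 0.02,
    max_iter: int = 40,
) -> float:
    """Find the Balding–Nichols F giving a target mean Hudson Fst.

    Bisection on F with Monte-Carlo evaluation of the sample Hudson Fst at
    the given diploid sample sizes. At least 1e5 sites are used internally
    so the Monte-Carlo spread does not stall the search.
    """
    if not (0 < target_fst < 0.5):
        raise ValueError("target_fst must be in (0, 0.5)")
    if target_fst < 1e-4:
        return target_fst
    n_eval = max(int(n_sites), 100_000)
    rng = _rng(seed)

    def mean_fst(f: float) -> float:
        return float(
            np.mean([_mean_pair_fst(f, n_eval, sample_sizes, rng) for _ in range(reps)])
        )

    lo, hi = 1e-6, 0.6
    if mean_fst(hi) < target_fst:
        raise RuntimeError(
            f"target Fst {target_fst} unattainable: Fst({hi}) < target"
        )
    f = target_fst  # E[Hudson Fst] is close to F, so start at the target
    for _ in range(max_iter):
        m = mean_fst(f)
        if abs(m - target_fst) / target_fst <= rel_tol:
            return f
        if m < target_fst:
            lo = f
        else:
            hi = f
        f = 0.5 * (lo + hi)
    return f


def _site_metadata(n_sites: int, rng, mean_spacing: float = 20_000.0):
    """Invent sorted positions over 22 autosomes and random SNP alleles."""
    per = np.full(22, n_sites // 22, dtype=int)
    per[: n_sites % 22] += 1
    chrom, pos = [], []
    for c in range(22):
        gaps = np.maximum(1, rng.exponential(mean_spacing, size=per[c]).astype(np.int64))
        p = np.cumsum(gaps)
        chrom.extend([str(c + 1)] * per[c])
        pos.extend(p.tolist())
    bases = np.array(list("ACGT"), dtype=object)
    ref_i = rng.integers(0, 4, size=n_sites)
    alt_i = (ref_i + rng.integers(1, 4, size=n_sites)) % 4
    return (
        np.asarray(chrom, dtype=object),
        np.asarray(pos, dtype=np.int64),
        bases[ref_i],
        bases[alt_i],
    )


def simulate_admixed_genotypes(
    freqs: SourceFrequencies,
    specs: list[AdmixtureSpec],
    seed: int,
    mean_spacing: float = 20_000.0,
    with_depth: bool = False,
    depth_mean: float = 16.0,
) -> GenotypeMatrix:
    """Simulate diploid genotypes for admixed populations.

    Each of an individual's two allele copies is independently assigned a
    source by the population's ancestry proportions, then drawn
    Bernoulli(source frequency). Realized per-individual ancestry fractions
    are stored in ``extras['ancestry_truth']``.
    """
    rng = _rng(seed)
    k = freqs.n_sources
    for spec in specs:
        if spec.proportions.size != k:
            raise ValueError(
                f"spec {spec.label} has {spec.proportions.size} proportions "
                f"for {k} sources"
            )
    n_sites = freqs.n_sites
    site_idx = np.arange(n_sites)
    samples, pops, rows, truth = [], [], [], []
    for spec in specs:
        for i in range(spec.n_individuals):
            src = rng.choice(k, size=(2, n_sites), p=spec.proportions)
            alleles = rng.random((2, n_sites)) < freqs.freq[src, site_idx]
            rows.append(alleles.sum(axis=0).astype(np.int8))
            truth.append(np.bincount(src.ravel(), minlength=k) / (2 * n_sites))
            samples.append(f"{spec.label}_{i}")
            pops.append(spec.label)
    chrom, pos, ref, alt = _site_metadata(n_sites, rng, mean_spacing)
    depth = qual = None
    if with_depth:
        depth = rng.poisson(depth_mean, size=(len(samples), n_sites)).astype(np.int32)
        qual = rng.integers(30, 100, size=(len(samples), n_sites), dtype=np.int32)
    g = GenotypeMatrix(
        samples=samples,
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        dosage=np.stack(rows),
        depth=depth,
        qual=qual,
        populations=np.asarray(pops, dtype=object),
    )
    g.extras["ancestry_truth"] = np.stack(truth)
    g.extras["source_labels"] = list(freqs.labels)
    return g


def simulate_source_haplotypes(
    freqs: SourceFrequencies, n_haps_per_source: int, seed: int
) -> dict[str, np.ndarray]:
    """Phased 0/1 haplotype panels drawn from each source's frequencies."""
    rng = _rng(seed)
    return {
        lab: (rng.random((n_haps_per_source, freqs.n_sites)) < freqs.freq[k]).astype(
            np.int8
        )
        for k, lab in enumerate(freqs.labels)
    }


def simulate_haplotype_mosaic(
    source_haps: dict[str, np.ndarray],
    proportions,
    switch_rate: float,
    n_recipients: int,
    seed: int,
) -> MosaicPanel:
    """Build recipient haplotypes as mosaics of donor haplotypes.

    Ancestry switches occur at geometric distances with mean 1/switch_rate;
    at each switch a source is chosen by the proportions and a donor
    haplotype uniformly within the source. True per-site source and donor
    labels are returned alongside.
    """
    if not (0 < switch_rate < 1):
        raise ValueError("switch_rate must be in (0, 1)")
    labels = list(source_haps)
    panels = [np.asarray(source_haps[lab]) for lab in labels]
    if any(p.shape[0] < 1 for p in panels) or not panels:
        raise ValueError("every source needs at least one haplotype")
    props = np.asarray(proportions, dtype=float)
    if props.size != len(labels):
        raise ValueError("proportions length must match number of sources")
    n_sites = panels[0].shape[1]
    rng = _rng(seed)
    haps = np.empty((n_recipients, n_sites), dtype=np.int8)
    true_source = np.empty((n_recipients, n_sites), dtype=np.int16)
    true_donor = np.empty((n_recipients, n_sites), dtype=np.int32)
    for r in range(n_recipients):
        pos = 0
        while pos < n_sites:
            src = int(rng.choice(len(labels), p=props))
            donor = int(rng.integers(panels[src].shape[0]))
            seg = int(rng.geometric(switch_rate))
            end = min(pos + seg, n_sites)
            haps[r, pos:end] = panels[src][donor, pos:end]
            true_source[r, pos:end] = src
            true_donor[r, pos:end] = donor
            pos = end
    return MosaicPanel(
        haps=haps, true_source=true_source, true_donor=true_donor, source_labels=labels
    )


def simulate_duo(
    freqs: SourceFrequencies,
    n_unrelated: int,
    seed: int,
    mode: str = "duo",
    mean_spacing: float = 20_000.0,
) -> GenotypeMatrix:
    """One labelled related pair plus unrelated individuals from source 0.

    In ``duo`` mode the offspring inherits one allele from the parent
    (uniform pick per site) and one from the population frequency; in
    ``clone`` mode the second sample is an exact copy of the first.
    """
    if mode not in ("duo", "clone"):
        raise ValueError("mode must be 'duo' or 'clone'")
    rng = _rng(seed)
    p = freqs.freq[0]
    n_sites = p.size
    parent_alleles = (rng.random((2, n_sites)) < p).astype(np.int8)
    parent = parent_alleles.sum(axis=0)
    if mode == "clone":
        child = parent.copy()
    else:
        transmitted = parent_alleles[rng.integers(0, 2, size=n_sites), np.arange(n_sites)]
        child = transmitted + (rng.random(n_sites) < p).astype(np.int8)
    rows = [parent, child]
    samples = ["PARENT", "OFFSPRING" if mode == "duo" else "CLONE"]
    for i in range(n_unrelated):
        rows.append(
            (rng.random(n_sites) < p).astype(np.int8)
            + (rng.random(n_sites) < p).astype(np.int8)
        )
        samples.append(f"U{i}")
    chrom, pos, ref, alt = _site_metadata(n_sites, rng, mean_spacing)
    g = GenotypeMatrix(
        samples=samples,
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        dosage=np.stack(rows).astype(np.int8),
        populations=np.asarray(["POP0"] * len(samples), dtype=object),
    )
    g.extras["pair"] = (samples[0], samples[1])
    return g


def _mutate_ystr(hap: np.ndarray, n_mut: int, rng) -> np.ndarray:
    """Apply single-step +/-1 mutations; the floor at 1 reflects steps up."""
    out = hap.copy()
    if n_mut == 0:
        return out
    loci = rng.integers(0, out.size, size=n_mut)
    steps = rng.choice([-1, 1], size=n_mut)
    for loc, st in zip(loci, steps):
        new = out[loc] + st
        out[loc] = new if new >= 1 else out[loc] - st
    return out


def simulate_ystr(
    mode: str,
    founder,
    generations: float,
    mu: float,
    n_lineages: int,
    dominance: DominanceModel | None = None,
    seed: int = 0,
    loci: list[str] | None = None,
    n_pop: int = 500,
    label: str = "POP",
) -> YSTRDataset:
    """Forward-simulate Y-STR haplotypes.

    star mode: each of ``n_lineages`` sampled lineages independently
    accumulates Poisson(L*mu*generations) single-step mutations from the
    founder (a star genealogy of the given depth). wright_fisher mode: a
    constant population of ``n_pop`` males; sons pick fathers proportionally
    to mating success. With a :class:`DominanceModel`, dominant males have
    success multiplied by b and the dominant class (fixed size ceil(d*n_pop))
    is refilled each generation with fidelity tau from sons of dominant
    fathers, lineage sons first; the lineage-frequency trajectory is
    returned in ``extras['trajectory']``.
    """
    founder = np.asarray(founder, dtype=np.int64)
    L = founder.size
    if loci is None:
        loci = [f"DYS{i:03d}" for i in range(L)]
    if len(loci) != L:
        raise ValueError("founder length does not match loci")
    if not (0 < mu < 0.1):
        raise ValueError("mu must be in (0, 0.1)")
    if generations < 0:
        raise ValueError("generations must be >= 0")
    rng = _rng(seed)
    if mode == "star":
        counts = rng.poisson(L * mu * generations, size=n_lineages)
        haps = np.stack([_mutate_ystr(founder, int(k), rng) for k in counts])
        return YSTRDataset(
            loci=list(loci),
            haplotypes=haps,
            labels=np.asarray([label] * n_lineages, dtype=object),
            extras={"n_mutations": counts},
        )
    if mode != "wright_fisher":
        raise ValueError("mode must be 'star' or 'wright_fisher'")

    n = int(n_pop)
    haps = np.tile(founder, (n, 1))
    if dominance is not None:
        m = math.ceil(dominance.d * n)
        n_lin = int(round(dominance.p0 * n))
        n_dom_lin = min(int(round(dominance.q0 * m)), n_lin, m)
        lineage = np.zeros(n, dtype=bool)
        dominant = np.zeros(n, dtype=bool)
        dominant[:m] = True
        lineage[:n_dom_lin] = True
        lineage[m : m + (n_lin - n_dom_lin)] = True
        reserved = int(round(dominance.tau * m))
    else:
        lineage = dominant = None
    traj = [float(lineage.mean())] if lineage is not None else []
    for _ in range(int(generations)):
        if dominance is not None:
            w = np.where(dominant, dominance.b, 1.0)
            fathers = rng.choice(n, size=n, p=w / w.sum())
        else:
            fathers = rng.integers(0, n, size=n)
        haps = haps[fathers]
        k = rng.poisson(L * mu, size=n)
        for i in np.nonzero(k)[0]:
            haps[i] = _mutate_ystr(haps[i], int(k[i]), rng)
        if dominance is not None:
            lineage = lineage[fathers]
            from_dom = dominant[fathers]
            new_dom = np.zeros(n, dtype=bool)
            cand = np.nonzero(from_dom)[0]
            # lineage sons of dominant fathers first, ties broken by shuffle
            cand = cand[rng.permutation(cand.size)]
            cand = cand[np.argsort(~lineage[cand], kind="stable")]
            take = cand[: min(reserved, cand.size)]
            new_dom[take] = True
            open_slots = m - take.size
            if open_slots > 0:
                rest = np.nonzero(~new_dom)[0]
                new_dom[rng.choice(rest, size=open_slots, replace=False)] = True
            dominant = new_dom
            traj.append(float(lineage.mean()))
    pick = rng.choice(n, size=min(n_lineages, n), replace=False)
    extras = {}
    if dominance is not None:
        extras["trajectory"] = np.asarray(traj)
        extras["lineage"] = lineage[pick]
    return YSTRDataset(
        loci=list(loci),
        haplotypes=haps[pick],
        labels=np.asarray([label] * pick.size, dtype=object),
        extras=extras,
    )


def simulate_sequences(
    root: str, n: int, subs_rate: float, seed: int
) -> tuple[list[str], int]:
    """Independently mutate ``n`` copies of a root sequence.

    Each position mutates with probability ``subs_rate`` to one of the
    three other bases. Returns the sequences and the count of segregating
    sites.
    """
    alphabet = "ACGT"
    root = root.upper()
    if not root or any(c not in alphabet for c in root):
        raise ValueError("root must be a non-empty A/C/G/T string")
    rng = _rng(seed)
    base_idx = {c: i for i, c in enumerate(alphabet)}
    arr = np.asarray([base_idx[c] for c in root], dtype=np.int8)
    seqs = np.tile(arr, (n, 1))
    mask = rng.random(seqs.shape) < subs_rate
    shift = rng.integers(1, 4, size=seqs.shape)
    seqs = np.where(mask, (seqs + shift) % 4, seqs)
    n_seg = int(np.count_nonzero((seqs != seqs[0]).any(axis=0))) if n > 0 else 0
    lut = np.array(list(alphabet))
    return ["".join(lut[s]) for s in seqs], n_seg


def write_ystr_table(data: YSTRDataset, path) -> None:
    import pandas as pd

    df = pd.DataFrame(data.haplotypes, columns=data.loci)
    df.insert(0, "population", data.labels)
    df.insert(0, "sample_id", [f"Y{i}" for i in range(data.n)])
    df.to_csv(path, sep="\t", index=False)


def read_ystr_table(path) -> YSTRDataset:
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    loci = [c for c in df.columns if c not in ("sample_id", "population")]
    return YSTRDataset(
        loci=loci,
        haplotypes=df[loci].to_numpy(),
        labels=df["population"].to_numpy(dtype=object),
    )


def write_fasta(seqs: list[str], path, prefix: str = "seq") -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = [
        SeqRecord(Seq(s), id=f"{prefix}{i}", description="") for i, s in enumerate(seqs)
    ]
    seqio_write(records, str(path), "fasta")
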