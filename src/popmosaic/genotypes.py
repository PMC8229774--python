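"""Core diploid genotype container and text-format I/O.

The :class:`GenotypeMatrix` holds individuals x biallelic sites as dosages
(0/1/2, -1 for missing) plus optional per-genotype depth and quality, and
round-trips through plain-text VCF 4.2. Population labels travel in a
two-column TSV (sample_id, population) as produced by most cohort pipelines.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

MISSING = -1

_AUTOSOMES = {str(i) for i in range(1, 23)} | {f"chr{i}" for i in range(1, 23)}


def is_autosome(chrom: str) -> bool:
    return chrom in _AUTOSOMES


@dataclass
class GenotypeMatrix:
    """Diploid genotypes for ``n_samples`` individuals at ``n_sites`` SNPs.

    dosage is the count of alternate alleles (0, 1, 2) with -1 for a missing
    genotype. ``depth`` and ``qual`` are optional per-genotype integer arrays
    of the same shape. Sites must be position-sorted within chromosome.
    """

    samples: list[str]
    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    dosage: np.ndarray
    depth: np.ndarray | None = None
    qual: np.ndarray | None = None
    populations: np.ndarray | None = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.ref = np.asarray(self.ref, dtype=object)
        self.alt = np.asarray(self.alt, dtype=object)
        if self.dosage.shape != (len(self.samples), self.pos.size):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.samples)} samples x {self.pos.size} sites"
            )
        for chrom in np.unique(self.chrom.astype(str)):
            p = self.pos[self.chrom == chrom]
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"positions not strictly increasing on {chrom}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return self.pos.size

    def sample_index(self, sample: str) -> int:
        return self.samples.index(sample)

    def population_of(self, sample: str) -> str:
        if self.populations is None:
            raise ValueError("no population labels attached")
        return str(self.populations[self.sample_index(sample)])

    def samples_in(self, pop: str) -> list[str]:
        if self.populations is None:
            raise ValueError("no population labels attached")
        return [s for s, p in zip(self.samples, self.populations) if p == pop]

    def take_sites(self, idx: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            samples=list(self.samples),
            chrom=self.chrom[idx],
            pos=self.pos[idx],
            ref=self.ref[idx],
            alt=self.alt[idx],
            dosage=self.dosage[:, idx],
            depth=None if self.depth is None else self.depth[:, idx],
            qual=None if self.qual is None else self.qual[:, idx],
            populations=self.populations,
        )

    def take_samples(self, idx: list[int]) -> "GenotypeMatrix":
        return GenotypeMatrix(
            samples=[self.samples[i] for i in idx],
            chrom=self.chrom,
            pos=self.pos,
            ref=self.ref,
            alt=self.alt,
            dosage=self.dosage[idx, :],
            depth=None if self.depth is None else self.depth[idx, :],
            qual=None if self.qual is None else self.qual[idx, :],
            populations=None
            if self.populations is None
            else np.asarray(self.populations)[idx],
        )

    def allele_counts(self, sample_idx: list[int] | None = None):
        """Alt-allele count and called-haplotype count per site."""
        d = self.dosage if sample_idx is None else self.dosage[sample_idx, :]
        called = d >= 0
        ac = np.where(called, d, 0).sum(axis=0)
        an = 2 * called.sum(axis=0)
        return ac, an

    def allele_freq(self, sample_idx: list[int] | None = None) -> np.ndarray:
        ac, an = self.allele_counts(sample_idx)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(an > 0, ac / np.maximum(an, 1), np.nan)


_GT = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(g: GenotypeMatrix, path: str | Path) -> None:
    """Write a minimal uncompressed VCF 4.2 with GT (+DP/GQ if present)."""
    path = Path(path)
    fmt_keys = ["GT"]
    if g.depth is not None:
        fmt_keys.append("DP")
    if g.qual is not None:
        fmt_keys.append("GQ")
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=popmosaic\n")
        for chrom in dict.fromkeys(g.chrom.astype(str)):
            length = int(g.pos[g.chrom == chrom].max()) + 1000
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if g.depth is not None:
            fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        if g.qual is not None:
            fh.write(
                '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n'
            )
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(g.samples)
            + "\n"
        )
        fmt = ":".join(fmt_keys)
        for s in range(g.n_sites):
            fields = [
                str(g.chrom[s]),
                str(int(g.pos[s])),
                ".",
                str(g.ref[s]),
                str(g.alt[s]),
                ".",
                "PASS",
                ".",
                fmt,
            ]
            for i in range(g.n_samples):
                cell = [_GT[int(g.dosage[i, s])]]
                if g.depth is not None:
                    cell.append(str(int(g.depth[i, s])))
                if g.qual is not None:
                    cell.append(str(int(g.qual[i, s])))
                fields.append(":".join(cell))
            fh.write("\t".join(fields) + "\n")


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read a VCF into a GenotypeMatrix (first ALT allele; others kept verbatim)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    chrom, pos, ref, alt, rows, depths, quals = [], [], [], [], [], [], []
    has_dp = has_gq = False
    for v in vcf:
        chrom.append(v.CHROM)
        pos.append(v.POS)
        ref.append(v.REF)
        alt.append(",".join(v.ALT) if v.ALT else ".")
        # gts012: 0/1/2 = alt dosage, 3 = missing
        gt = np.asarray(v.gt_types, dtype=np.int8)
        gt[gt == 3] = MISSING
        rows.append(gt)
        dp = v.format("DP")
        if dp is not None:
            has_dp = True
            depths.append(np.asarray(dp, dtype=np.int32).ravel())
        gq = v.format("GQ")
        if gq is not None:
            has_gq = True
            quals.append(np.asarray(gq, dtype=np.int32).ravel())
    vcf.close()
    dosage = np.stack(rows, axis=1) if rows else np.zeros((len(samples), 0), np.int8)
    return GenotypeMatrix(
        samples=samples,
        chrom=np.asarray(chrom, dtype=object),
        pos=np.asarray(pos, dtype=np.int64),
        ref=np.asarray(ref, dtype=object),
        alt=np.asarray(alt, dtype=object),
        dosage=dosage,
        depth=np.stack(depths, axis=1) if has_dp else None,
        qual=np.stack(quals, axis=1) if has_gq else None,
    )


def write_population_map(samples: list[str], populations, path: str | Path) -> None:
    pd.DataFrame({"sample_id": samples, "population": list(populations)}).to_csv(
        path, sep="\t", index=False
    )


def read_population_map(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return dict(zip(df["sample_id"], df["population"]))


def attach_populations(g: GenotypeMatrix, pop_map: dict[str, str]) -> GenotypeMatrix:
    g.populations = np.asarray([pop_map[s] for s in g.samples], dtype=object)
    return g
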