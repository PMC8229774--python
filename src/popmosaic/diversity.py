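"""Genome-wide diversity scans: ROH, LD decay, folded SFS, Ho and Fis.

ROH calling follows the PLINK two-pass scheme: 50-SNP sliding windows are
flagged homozygous when they contain at most 1 heterozygote and 5 missing
genotypes; a SNP is eligible when at least 5% of the windows overlapping it
are homozygous; maximal runs of eligible SNPs become segments when they
pass the length (500 kb), SNP-count (100), density (1 SNP / 50 kb) and gap
(500 kb) rules. Windows at chromosome ends are truncated, and eligibility
uses the number of windows actually overlapping the SNP.

LD decay, the folded site-frequency spectrum and Fis control for uneven
sample sizes by downsampling to a fixed number of individuals, repeating
the draw and averaging over replicates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix

__all__ = [
    "ROHSegment",
    "ROHParams",
    "call_roh",
    "roh_summary",
    "roh_regression_residual",
    "LD_BINS",
    "ld_decay",
    "folded_sfs",
    "het_stats",
]

# distance classes in bp; the published list jumps from 35-40 kb to >45 kb,
# leaving a 40-45 kb hole that is preserved here (pairs in it are unbinned)
LD_BINS: list[tuple[float, float]] = [
    (0, 2_000),
    (2_000, 5_000),
    (5_000, 10_000),
    (10_000, 15_000),
    (15_000, 20_000),
    (20_000, 25_000),
    (25_000, 30_000),
    (30_000, 35_000),
    (35_000, 40_000),
    (45_000, np.inf),
]

LD_BINS_FULL = LD_BINS[:-1] + [(40_000, 45_000), (45_000, np.inf)]


@dataclass
class ROHSegment:
    sample: str
    chrom: str
    start: int
    end: int
    n_snps: int

    @property
    def length_kb(self) -> float:
        return (self.end - self.start + 1) / 1000.0


@dataclass
class ROHParams:
    density_kb: float = 50.0  # max average kb per SNP within a segment
    gap_kb: float = 500.0
    min_kb: float = 500.0
    min_snp: int = 100
    win_het: int = 1
    win_missing: int = 5
    win_snp: int = 50
    win_threshold: float = 0.05


def _call_roh_one(chrom, pos, dosage, sample, params: ROHParams) -> list[ROHSegment]:
    s = pos.size
    het = dosage == 1
    miss = dosage == MISSING
    w = params.win_snp
    # windows start at every SNP; truncated at the chromosome end
    c_het = np.concatenate([[0], np.cumsum(het)])
    c_mis = np.concatenate([[0], np.cumsum(miss)])
    ends = np.minimum(np.arange(s) + w, s)
    win_hom = (c_het[ends] - c_het[np.arange(s)] <= params.win_het) & (
        c_mis[ends] - c_mis[np.arange(s)] <= params.win_missing
    )
    # SNP i is covered by windows starting in [i-w+1, i]
    c_hom = np.concatenate([[0], np.cumsum(win_hom)])
    starts = np.maximum(np.arange(s) - w + 1, 0)
    n_hom = c_hom[np.arange(s) + 1] - c_hom[starts]
    n_windows = np.arange(s) - starts + 1
    eligible = n_hom / n_windows >= params.win_threshold

    segments = []
    i = 0
    while i < s:
        if not eligible[i]:
            i += 1
            continue
        j = i
        while j + 1 < s and eligible[j + 1]:
            # split maximal runs at large gaps
            if pos[j + 1] - pos[j] > params.gap_kb * 1000:
                break
            j += 1
        n_snps = j - i + 1
        length = pos[j] - pos[i] + 1
        if (
            n_snps >= params.min_snp
            and length >= params.min_kb * 1000
            and length / n_snps <= params.density_kb * 1000
        ):
            segments.append(
                ROHSegment(
                    sample=sample,
                    chrom=str(chrom),
                    start=int(pos[i]),
                    end=int(pos[j]),
                    n_snps=n_snps,
                )
            )
        i = j + 1
    return segments


def call_roh(g: GenotypeMatrix, params: ROHParams | None = None) -> list[ROHSegment]:
    """PLINK-style runs of homozygosity for every sample."""
    params = params or ROHParams()
    out: list[ROHSegment] = []
    for chrom in dict.fromkeys(g.chrom.astype(str)):
        idx = np.nonzero(g.chrom == chrom)[0]
        pos = g.pos[idx]
        if np.any(np.diff(pos) <= 0):
            raise ValueError(f"sites not sorted on {chrom}")
        for i, sample in enumerate(g.samples):
            out.extend(
                _call_roh_one(chrom, pos, g.dosage[i, idx], sample, params)
            )
    return out


def roh_summary(
    segments: list[ROHSegment], samples: list[str] | None = None
) -> pd.DataFrame:
    """Per-sample nROH, sROH (kb) and mean segment size, with a >2 Mb class."""
    rows = {
        s: {"nROH": 0, "sROH_kb": 0.0, "nROH_gt2Mb": 0, "sROH_gt2Mb_kb": 0.0}
        for s in (samples or [])
    }
    for seg in segments:
        r = rows.setdefault(
            seg.sample, {"nROH": 0, "sROH_kb": 0.0, "nROH_gt2Mb": 0, "sROH_gt2Mb_kb": 0.0}
        )
        r["nROH"] += 1
        r["sROH_kb"] += seg.length_kb
        if seg.length_kb > 2000:
            r["nROH_gt2Mb"] += 1
            r["sROH_gt2Mb_kb"] += seg.length_kb
    df = pd.DataFrame(rows).T
    df["mean_kb"] = np.where(df["nROH"] > 0, df["sROH_kb"] / df["nROH"].clip(lower=1), 0.0)
    return df


def roh_regression_residual(
    summaries: pd.DataFrame, baseline_samples: list[str]
) -> pd.Series:
    """Residual of sROH on nROH relative to an outbred baseline fit.

    Ordinary least squares of sROH against nROH over the baseline samples;
    positive residuals flag individuals whose total ROH length exceeds what
    their segment count predicts (an inbreeding signal).
    """
    base = summaries.loc[baseline_samples]
    if len(base) < 3:
        raise ValueError("need >= 3 baseline samples")
    x = base["nROH"].to_numpy(dtype=float)
    y = base["sROH_kb"].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("baseline nROH is constant; regression undefined")
    slope, intercept = np.polyfit(x, y, 1)
    fitted = slope * summaries["nROH"].to_numpy(dtype=float) + intercept
    return pd.Series(
        summaries["sROH_kb"].to_numpy(dtype=float) - fitted,
        index=summaries.index,
        name="residual_kb",
    )


def _r2_pairs(dos: np.ndarray, pos: np.ndarray, window_bp: float):
    """Genotype-dosage r^2 and bp distance for all pairs within window_bp."""
    s = pos.size
    d_list, r_list = [], []
    x = dos.astype(float)
    mean = x.mean(axis=0)
    sd = x.std(axis=0)
    ok = sd > 0
    xc = (x - mean) / np.where(sd > 0, sd, 1.0)
    n = x.shape[0]
    for i in range(s - 1):
        if not ok[i]:
            continue
        j_max = np.searchsorted(pos, pos[i] + window_bp, side="right")
        js = np.arange(i + 1, j_max)
        js = js[ok[js]]
        if js.size == 0:
            continue
        r = xc[:, js].T @ xc[:, i] / n
        d_list.append(pos[js] - pos[i])
        r_list.append(r**2)
    if not d_list:
        return np.array([]), np.array([])
    return np.concatenate(d_list), np.concatenate(r_list)


def ld_decay(
    g: GenotypeMatrix,
    pop: str,
    window_bp: float = 1_000_000,
    bins: list[tuple[float, float]] | None = None,
    downsample_to: int = 5,
    reps: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean genotype r^2 per distance class, averaged over downsampling reps.

    Individuals are downsampled without replacement to ``downsample_to``
    (fresh draw per replicate, seeds derived from the master seed by
    replicate index); monomorphic SNPs in a replicate are skipped.
    """
    bins = bins if bins is not None else LD_BINS
    idx = [i for i, s in enumerate(g.samples) if g.populations[i] == pop]
    if len(idx) < downsample_to:
        raise ValueError(f"population {pop!r} smaller than downsample_to")
    per_rep = []
    for rep in range(reps):
        rng = np.random.default_rng(seed + rep)
        pick = rng.choice(idx, size=downsample_to, replace=False)
        means = []
        sums = np.zeros(len(bins))
        counts = np.zeros(len(bins))
        for chrom in dict.fromkeys(g.chrom.astype(str)):
            sidx = np.nonzero(g.chrom == chrom)[0]
            dist, r2 = _r2_pairs(
                g.dosage[pick][:, sidx], g.pos[sidx].astype(float), window_bp
            )
            for k, (lo, hi) in enumerate(bins):
                m = (dist >= lo) & (dist < hi)
                sums[k] += r2[m].sum()
                counts[k] += m.sum()
        with np.errstate(invalid="ignore"):
            per_rep.append(np.where(counts > 0, sums / np.maximum(counts, 1), np.nan))
    arr = np.nanmean(np.stack(per_rep), axis=0)
    return pd.DataFrame(
        {
            "bin_lo_bp": [b[0] for b in bins],
            "bin_hi_bp": [b[1] for b in bins],
            "mean_r2": arr,
        }
    )


def folded_sfs(
    g: GenotypeMatrix,
    pop: str,
    downsample_to: int = 5,
    reps: int = 10,
    seed: int = 0,
) -> np.ndarray:
    """Folded site-frequency spectrum with individual downsampling.

    Returns the average over replicates of the proportion vector over
    minor-allele counts 1..downsample_to (2*downsample_to haplotypes,
    folded), computed over sites segregating and fully called in the
    subsample.
    """
    idx = [i for i, s in enumerate(g.samples) if g.populations[i] == pop]
    if len(idx) < downsample_to:
        raise ValueError(f"population {pop!r} smaller than downsample_to")
    n_hap = 2 * downsample_to
    out = np.zeros(downsample_to)
    for rep in range(reps):
        rng = np.random.default_rng(seed + rep)
        pick = rng.choice(idx, size=downsample_to, replace=False)
        d = g.dosage[pick, :]
        complete = (d != MISSING).all(axis=0)
        ac = d[:, complete].sum(axis=0)
        mac = np.minimum(ac, n_hap - ac)
        mac = mac[mac > 0]
        spec = np.bincount(mac, minlength=downsample_to + 1)[1:]
        out += spec / max(spec.sum(), 1)
    return out / reps


def het_stats(g: GenotypeMatrix) -> pd.DataFrame:
    """Per-individual observed heterozygosity and inbreeding coefficient.

    Ho divides the individual's heterozygous sites by the total SNP count
    of the dataset. Fis = (O_hom - E_hom) / (N - E_hom) with the expected
    homozygosity from sample allele frequencies with the n/(n-1)
    small-sample correction, summed over the individual's called sites.
    """
    d = g.dosage
    called = d != MISSING
    ac = np.where(called, d, 0).sum(axis=0)
    an = 2 * called.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(an > 0, ac / np.maximum(an, 1), np.nan)
        corr = np.where(an > 2, an / np.maximum(an - 1, 1), np.nan)
    e_het_site = 2 * p * (1 - p) * corr
    rows = []
    for i, sample in enumerate(g.samples):
        ok = called[i] & np.isfinite(e_het_site)
        n = int(ok.sum())
        if n == 0:
            rows.append({"sample": sample, "Ho": np.nan, "Fis": np.nan})
            continue
        o_hom = int(np.count_nonzero(d[i, ok] != 1))
        e_hom = float(np.sum(1 - e_het_site[ok]))
        ho = np.count_nonzero(d[i] == 1) / g.n_sites
        fis = (o_hom - e_hom) / (n - e_hom) if n != e_hom else np.nan
        rows.append({"sample": sample, "Ho": ho, "Fis": fis})
    return pd.DataFrame(rows).set_index("sample")
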