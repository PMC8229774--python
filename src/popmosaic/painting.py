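"""Simplified Li-Stephens haplotype-copying model and coancestry matrices.

A recipient haplotype is modelled as a mosaic copied from a panel of donor
haplotypes: a hidden Markov chain over donor states with a uniform
switch-to-any-donor transition (probability 1 - exp(-switch_scale) per
inter-site interval, uniform per-site spacing) and a symmetric mis-copy
emission error. The forward-backward recursion yields, per donor, the
expected number of copied segments ("chunks") and the expected copied
length; aggregating chunk counts over donor populations and averaging over
the recipients of each population gives the coancestry matrix and the
per-population copy profiles used downstream for TVD/NJ ancestry geometry.

Numerics use scaled (per-site normalized) forward-backward with log
normalizers, which is underflow-safe for arbitrarily many sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CopyingParams",
    "HaplotypePanel",
    "CoancestryMatrix",
    "paint",
    "forward_backward",
    "estimate_copying_params",
    "coancestry",
]


@dataclass
class CopyingParams:
    """switch_scale: ancestry-switch intensity per inter-site interval;
    mis_copy: per-site emission (mutation) error probability."""

    switch_scale: float = 1e-2
    mis_copy: float = 1e-3

    def __post_init__(self) -> None:
        if self.switch_scale <= 0:
            raise ValueError("switch_scale must be > 0")
        if not (0 < self.mis_copy < 0.5):
            raise ValueError("mis_copy must be in (0, 0.5)")

    @property
    def switch_prob(self) -> float:
        return float(1.0 - np.exp(-self.switch_scale))


@dataclass
class HaplotypePanel:
    """Phased 0/1 haplotypes with per-haplotype individual/population labels."""

    haps: np.ndarray  # (n_haps, n_sites)
    individuals: np.ndarray  # individual id per haplotype
    populations: np.ndarray  # population label per haplotype
    chrom: np.ndarray | None = None  # per-site chromosome, optional

    def __post_init__(self) -> None:
        self.haps = np.asarray(self.haps, dtype=np.int8)
        self.individuals = np.asarray(self.individuals, dtype=object)
        self.populations = np.asarray(self.populations, dtype=object)
        if self.chrom is None:
            self.chrom = np.asarray(["1"] * self.haps.shape[1], dtype=object)

    @property
    def n_haps(self) -> int:
        return self.haps.shape[0]

    @property
    def n_sites(self) -> int:
        return self.haps.shape[1]


@dataclass
class CoancestryMatrix:
    """Recipients x donors expected copied-chunk counts (and lengths)."""

    chunk_counts: pd.DataFrame  # index recipients, columns donors
    chunk_lengths: pd.DataFrame | None = None
    recipient_populations: dict = field(default_factory=dict)
    donor_populations: dict = field(default_factory=dict)

    def individual_profiles(self, donor_pops: dict | None = None) -> pd.DataFrame:
        """Per-recipient copy profiles (rows normalized to sum 1) over donor
        populations."""
        donor_pops = donor_pops or self.donor_populations
        counts = self.chunk_counts
        if donor_pops:
            counts = counts.T.groupby(
                [donor_pops[c] for c in counts.columns]
            ).sum().T
        return counts.div(counts.sum(axis=1), axis=0)

    def population_profiles(self, donor_pops: dict | None = None) -> pd.DataFrame:
        """Average recipient rows per population and normalize to copy profiles.

        The copy profile of a recipient group is the average of the copy
        profiles of its individuals. Columns may additionally be aggregated
        to donor populations via ``donor_pops`` (donor id -> population).
        """
        donor_pops = donor_pops or self.donor_populations
        counts = self.chunk_counts
        if donor_pops:
            counts = counts.T.groupby(
                [donor_pops[c] for c in counts.columns]
            ).sum().T
        row_norm = counts.div(counts.sum(axis=1), axis=0)
        pops = pd.Series(
            [self.recipient_populations[r] for r in counts.index], index=counts.index
        )
        return row_norm.groupby(pops).mean()


def _fb_single_chrom(recipient, donors, params: CopyingParams):
    """Scaled forward-backward over one chromosome.

    Returns (gamma, entries, loglik, exp_switch, exp_mismatch) where
    ``gamma`` is the (n_sites, n_donors) posterior, ``entries`` the expected
    number of entries into each donor state (initial state counted once,
    same-state switches not counted), ``exp_switch`` the expected number of
    switch events over intervals and ``exp_mismatch`` the expected number of
    mis-copy emissions.
    """
    n_d, n_s = donors.shape
    rho = params.switch_prob
    mis = params.mis_copy
    match = donors == recipient[None, :]  # (n_d, n_s)
    emit = np.where(match, 1.0 - mis, mis)

    alpha = np.empty((n_s, n_d))
    c = np.empty(n_s)
    a = emit[:, 0] / n_d
    c[0] = a.sum()
    alpha[0] = a / c[0]
    for t in range(1, n_s):
        a = emit[:, t] * ((1 - rho) * alpha[t - 1] + rho / n_d)
        c[t] = a.sum()
        alpha[t] = a / c[t]

    beta = np.empty((n_s, n_d))
    beta[-1] = 1.0
    for t in range(n_s - 2, -1, -1):
        eb = emit[:, t + 1] * beta[t + 1]
        beta[t] = ((1 - rho) * eb + (rho / n_d) * eb.sum()) / c[t + 1]

    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)

    entries = gamma[0].copy()
    exp_switch = 0.0  # expected visible state changes over intervals
    for t in range(n_s - 1):
        eb = emit[:, t + 1] * beta[t + 1] / c[t + 1]
        # switch channel into each donor, excluding same-state switches
        into = (rho / n_d) * eb * (1.0 - alpha[t])
        entries += into
        exp_switch += into.sum()
    exp_mismatch = float(gamma[~match.T].sum())
    loglik = float(np.log(c).sum())
    return gamma, entries, loglik, exp_switch, exp_mismatch


def forward_backward(recipient, donors, params: CopyingParams):
    """Posterior donor-state probabilities for one recipient haplotype."""
    gamma, entries, loglik, _, _ = _fb_single_chrom(
        np.asarray(recipient), np.asarray(donors), params
    )
    return gamma, entries, loglik


def paint(
    recipient,
    donors: HaplotypePanel,
    params: CopyingParams,
) -> pd.DataFrame:
    """Expected chunk counts and copied lengths per donor haplotype.

    Chromosomes are painted independently; expected counts and lengths
    (in sites) are summed over chromosomes and aggregated per donor
    haplotype row.
    """
    if donors.n_haps == 0:
        raise ValueError("donor panel is empty")
    recipient = np.asarray(recipient)
    if recipient.size != donors.n_sites:
        raise ValueError("recipient and donors must share the site list")
    counts = np.zeros(donors.n_haps)
    lengths = np.zeros(donors.n_haps)
    for chrom in dict.fromkeys(donors.chrom.astype(str)):
        idx = np.nonzero(donors.chrom == chrom)[0]
        gamma, entries, _, _, _ = _fb_single_chrom(
            recipient[idx], donors.haps[:, idx], params
        )
        counts += entries
        lengths += gamma.sum(axis=0)
    return pd.DataFrame(
        {
            "donor_hap": np.arange(donors.n_haps),
            "individual": donors.individuals,
            "population": donors.populations,
            "chunk_count": counts,
            "chunk_length": lengths,
        }
    )


def estimate_copying_params(
    panel: HaplotypePanel,
    n_em_iter: int = 10,
    subset: list[str] | None = None,
    init: CopyingParams | None = None,
    recipients: list[str] | None = None,
    return_history: bool = False,
):
    """EM estimation of switch_scale and mis_copy on a haplotype panel.

    Each haplotype (of the ``recipients`` individuals, by default all) is
    painted against all haplotypes of other individuals; per chromosome,
    expected switch and mismatch counts give the M-step updates, averaged
    over chromosomes weighted by interval/site counts and then over
    individuals. The data log-likelihood is checked to be non-decreasing
    (a decrease beyond 1e-8 indicates a bug); with ``return_history`` the
    per-iteration log-likelihoods are returned alongside the params.
    """
    if panel.n_haps < 2:
        raise ValueError("need at least 2 haplotypes")
    params = init or CopyingParams()
    chroms = list(dict.fromkeys(panel.chrom.astype(str)))
    if subset is not None:
        chroms = [c for c in chroms if c in set(subset)]
    if not chroms:
        raise ValueError("chromosome subset is empty")
    chrom_idx = {c: np.nonzero(panel.chrom == c)[0] for c in chroms}
    if recipients is None:
        recip_rows = range(panel.n_haps)
    else:
        recip_rows = [
            h for h in range(panel.n_haps) if panel.individuals[h] in set(recipients)
        ]
    history = []
    prev_ll = -np.inf
    for _ in range(n_em_iter):
        total_ll = 0.0
        rho_num = rho_den = mis_num = mis_den = 0.0
        for h in recip_rows:
            donor_rows = np.nonzero(panel.individuals != panel.individuals[h])[0]
            n_d = donor_rows.size
            for c in chroms:
                idx = chrom_idx[c]
                _, _, ll, sw, mm = _fb_single_chrom(
                    panel.haps[h, idx], panel.haps[donor_rows][:, idx], params
                )
                total_ll += ll
                # visible changes miss same-donor switches: correct by
                # n_d / (n_d - 1); a single donor carries no information
                rho_num += sw * (n_d / (n_d - 1)) if n_d > 1 else 0.0
                rho_den += idx.size - 1
                mis_num += mm
                mis_den += idx.size
        if total_ll < prev_ll - 1e-8:
            raise RuntimeError(
                f"EM log-likelihood decreased: {prev_ll} -> {total_ll}"
            )
        prev_ll = total_ll
        history.append(total_ll)
        rho = min(max(rho_num / max(rho_den, 1.0), 1e-12), 1 - 1e-12)
        mis = min(max(mis_num / max(mis_den, 1.0), 1e-9), 0.5 - 1e-9)
        params = CopyingParams(
            switch_scale=float(-np.log1p(-rho)), mis_copy=float(mis)
        )
    if return_history:
        return params, history
    return params


def coancestry(
    panel: HaplotypePanel,
    mode: str = "all_vs_all",
    donor_set: list[str] | None = None,
    recipient_set: list[str] | None = None,
    params: CopyingParams | None = None,
) -> CoancestryMatrix:
    """Expected chunk-count coancestry matrix.

    all_vs_all: each individual's haplotypes are painted against all other
    individuals' haplotypes (self-copying excluded; the diagonal is zero).
    donor_recipient: recipients are individuals of ``recipient_set``
    populations, painted only against haplotypes of ``donor_set``
    populations; the two sets must be disjoint as individuals.
    """
    params = params or CopyingParams()
    individuals = list(dict.fromkeys(panel.individuals))
    ind_pop = {
        i: p for i, p in zip(panel.individuals, panel.populations)
    }
    if mode == "all_vs_all":
        recipients = individuals
        donor_rows_for = {
            r: np.nonzero(panel.individuals != r)[0] for r in recipients
        }
    elif mode == "donor_recipient":
        if not donor_set or recipient_set is None:
            raise ValueError("donor_set and recipient_set required")
        recipients = [i for i in individuals if ind_pop[i] in set(recipient_set)]
        donor_rows = np.nonzero(np.isin(panel.populations, list(donor_set)))[0]
        donor_inds = set(panel.individuals[donor_rows])
        if donor_inds & set(recipients):
            raise ValueError("donor and recipient sets must be disjoint")
        if donor_rows.size == 0:
            raise ValueError("no donors found")
        donor_rows_for = {r: donor_rows for r in recipients}
    else:
        raise ValueError("mode must be 'all_vs_all' or 'donor_recipient'")
    if not recipients:
        raise ValueError("no recipients found")

    count_rows = {}
    length_rows = {}
    for r in recipients:
        rows = donor_rows_for[r]
        if rows.size == 0:
            raise ValueError(f"recipient {r} has no donors")
        counts = pd.Series(0.0, index=individuals)
        lengths = pd.Series(0.0, index=individuals)
        for h in np.nonzero(panel.individuals == r)[0]:
            sub = HaplotypePanel(
                haps=panel.haps[rows],
                individuals=panel.individuals[rows],
                populations=panel.populations[rows],
                chrom=panel.chrom,
            )
            res = paint(panel.haps[h], sub, params)
            counts = counts.add(
                res.groupby("individual")["chunk_count"].sum(), fill_value=0.0
            )
            lengths = lengths.add(
                res.groupby("individual")["chunk_length"].sum(), fill_value=0.0
            )
        count_rows[r] = counts
        length_rows[r] = lengths
    chunk_counts = pd.DataFrame(count_rows).T.loc[recipients]
    chunk_lengths = pd.DataFrame(length_rows).T.loc[recipients]
    if mode == "donor_recipient":
        donor_cols = sorted(set(panel.individuals[donor_rows]))
        chunk_counts = chunk_counts[donor_cols]
        chunk_lengths = chunk_lengths[donor_cols]
    return CoancestryMatrix(
        chunk_counts=chunk_counts,
        chunk_lengths=chunk_lengths,
        recipient_populations={r: ind_pop[r] for r in recipients},
        donor_populations={c: ind_pop[c] for c in chunk_counts.columns},
    )
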