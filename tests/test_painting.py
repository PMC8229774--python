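"""Li-Stephens copying engine: forward-backward posteriors, expected chunk
counts, EM parameter estimation and coancestry aggregation."""

import itertools

import numpy as np
import pandas as pd
import pytest

from popmosaic import painting as pnt
from popmosaic import simdata as sim


def enumerate_hmm(recipient, donors, params):
    """Brute-force path enumeration oracle for tiny panels.

    Sums over all donor-state paths to get the posterior per site, the
    expected number of entries into each state (initial state plus
    changes of state) and the likelihood.
    """
    n_d, n_s = donors.shape
    rho = params.switch_prob
    mis = params.mis_copy

    def emit(d, t):
        return 1 - mis if donors[d, t] == recipient[t] else mis

    def trans(a, b):
        return (1 - rho) * (a == b) + rho / n_d

    total = 0.0
    gamma = np.zeros((n_s, n_d))
    entries = np.zeros(n_d)
    for path in itertools.product(range(n_d), repeat=n_s):
        w = emit(path[0], 0) / n_d
        for t in range(1, n_s):
            w *= trans(path[t - 1], path[t]) * emit(path[t], t)
        total += w
        for t, d in enumerate(path):
            gamma[t, d] += w
        entries[path[0]] += w
        for t in range(1, n_s):
            if path[t] != path[t - 1]:
                entries[path[t]] += w
    return gamma / total, entries / total, np.log(total)


@pytest.fixture(scope="module")
def toy_panel():
    rng = np.random.default_rng(3)
    donors = rng.integers(0, 2, size=(3, 5)).astype(np.int8)
    recipient = rng.integers(0, 2, size=5).astype(np.int8)
    return recipient, donors


class TestForwardBackward:
    def test_matches_enumeration_oracle(self, toy_panel):
        recipient, donors = toy_panel
        params = pnt.CopyingParams(switch_scale=0.3, mis_copy=0.1)
        gamma, entries, ll = pnt.forward_backward(recipient, donors, params)
        o_gamma, o_entries, o_ll = enumerate_hmm(recipient, donors, params)
        np.testing.assert_allclose(gamma, o_gamma, atol=1e-12)
        np.testing.assert_allclose(entries, o_entries, atol=1e-12)
        assert ll == pytest.approx(o_ll, abs=1e-12)

    def test_posterior_rows_normalized_long_sequence(self):
        rng = np.random.default_rng(4)
        donors = rng.integers(0, 2, size=(6, 20_000)).astype(np.int8)
        recipient = rng.integers(0, 2, size=20_000).astype(np.int8)
        gamma, _, _ = pnt.forward_backward(
            recipient, donors, pnt.CopyingParams(1e-3, 1e-3)
        )
        np.testing.assert_allclose(gamma.sum(axis=1), 1.0, atol=1e-9)

    def test_identical_recipient_dominates(self):
        rng = np.random.default_rng(5)
        a = rng.integers(0, 2, size=200).astype(np.int8)
        b = 1 - a
        donors = np.stack([a, b])
        res = pnt.paint(
            a,
            pnt.HaplotypePanel(
                donors, np.array(["A", "B"], object), np.array(["A", "B"], object)
            ),
            pnt.CopyingParams(1e-2, 1e-3),
        )
        lengths = res.set_index("individual")["chunk_length"]
        assert lengths["A"] / lengths.sum() >= 0.95


class TestPaint:
    def test_single_donor_one_chunk(self):
        rng = np.random.default_rng(6)
        hap = rng.integers(0, 2, size=500).astype(np.int8)
        panel = pnt.HaplotypePanel(
            hap[None, :], np.array(["D"], object), np.array(["D"], object)
        )
        res = pnt.paint(hap, panel, pnt.CopyingParams(1e-2, 1e-3))
        assert res["chunk_count"].sum() == pytest.approx(1.0, abs=1e-9)
        assert res["chunk_length"].sum() == pytest.approx(500.0, abs=1e-6)

    def test_total_chunks_at_least_one(self, toy_panel):
        recipient, donors = toy_panel
        panel = pnt.HaplotypePanel(
            donors, np.array(["A", "B", "C"], object), np.array(["P"] * 3, object)
        )
        res = pnt.paint(recipient, panel, pnt.CopyingParams(0.5, 0.2))
        assert res["chunk_count"].sum() >= 1.0

    def test_donor_order_invariance(self):
        rng = np.random.default_rng(7)
        donors = rng.integers(0, 2, size=(4, 300)).astype(np.int8)
        recipient = rng.integers(0, 2, size=300).astype(np.int8)
        names = np.array(["A", "B", "C", "D"], object)
        params = pnt.CopyingParams(1e-2, 1e-2)
        res1 = pnt.paint(
            recipient, pnt.HaplotypePanel(donors, names, names), params
        ).set_index("individual")["chunk_count"]
        perm = [2, 0, 3, 1]
        res2 = pnt.paint(
            recipient,
            pnt.HaplotypePanel(donors[perm], names[perm], names[perm]),
            params,
        ).set_index("individual")["chunk_count"]
        pd.testing.assert_series_equal(res1.sort_index(), res2.sort_index())

    def test_zero_donors_rejected(self):
        panel = pnt.HaplotypePanel(
            np.zeros((0, 10), dtype=np.int8),
            np.array([], object),
            np.array([], object),
        )
        with pytest.raises(ValueError):
            pnt.paint(np.zeros(10, dtype=np.int8), panel, pnt.CopyingParams())

    def test_viterbi_limit_on_noiseless_mosaic(self):
        # recipient copied exactly from donors with 2 switches: expected
        # chunk count approaches the true segment count as noise vanishes
        rng = np.random.default_rng(8)
        donors = rng.integers(0, 2, size=(3, 100)).astype(np.int8)
        recipient = np.concatenate(
            [donors[0, :40], donors[1, 40:70], donors[2, 70:]]
        )
        params = pnt.CopyingParams(switch_scale=1e-6, mis_copy=1e-6)
        names = np.array(["A", "B", "C"], object)
        res = pnt.paint(recipient, pnt.HaplotypePanel(donors, names, names), params)
        assert res["chunk_count"].sum() == pytest.approx(3.0, abs=0.05)


class TestEM:
    def test_perfect_copy_estimates_floor(self):
        rng = np.random.default_rng(9)
        hap = rng.integers(0, 2, size=2000).astype(np.int8)
        panel = pnt.HaplotypePanel(
            np.stack([hap, hap]),
            np.array(["R", "D"], object),
            np.array(["R", "D"], object),
        )
        params = pnt.estimate_copying_params(panel, n_em_iter=5, recipients=["R"])
        assert params.mis_copy <= 1e-6
        assert params.switch_scale <= 1e-4

    def test_monotone_likelihood(self, source_panel):
        _, history = pnt.estimate_copying_params(
            source_panel, n_em_iter=6, recipients=["R_0"], return_history=True
        )
        assert all(b >= a - 1e-8 for a, b in zip(history, history[1:]))
        assert history[-1] >= history[0]

    def test_switch_scale_recovery_within_factor_two(self, source_panel):
        params = pnt.estimate_copying_params(
            source_panel, n_em_iter=10, recipients=["R_0"]
        )
        assert 0.5e-3 <= params.switch_scale <= 2e-3


@pytest.fixture(scope="module")
def source_panel():
    """Panel of 5 donor individuals plus one mosaic recipient (truth 1e-3)."""
    f = sim.sample_source_frequencies(10_000, [0.1], seed=21, labels=["A"])
    sh = sim.simulate_source_haplotypes(f, 10, seed=22)
    mos = sim.simulate_haplotype_mosaic(sh, [1.0], 1e-3, 2, seed=23)
    haps = [sh["A"][h] for h in range(10)] + [mos.haps[0], mos.haps[1]]
    inds = [f"A_{h // 2}" for h in range(10)] + ["R_0", "R_0"]
    pops = ["A"] * 10 + ["R"] * 2
    return pnt.HaplotypePanel(
        np.stack(haps), np.asarray(inds, object), np.asarray(pops, object)
    )


@pytest.fixture(scope="module")
def mixed_panel():
    f = sim.sample_source_frequencies(20_000, [0.08, 0.08], seed=31,
                                      labels=["A", "B"])
    sh = sim.simulate_source_haplotypes(f, 8, seed=32)
    return f, sh


class TestCoancestry:
    def _panel(self, sh, mosaics):
        haps, inds, pops = [], [], []
        for lab in ("A", "B"):
            for h in range(8):
                haps.append(sh[lab][h])
                inds.append(f"{lab}_{h // 2}")
                pops.append(lab)
        for h in range(mosaics.haps.shape[0]):
            haps.append(mosaics.haps[h])
            inds.append(f"R_{h // 2}")
            pops.append("R")
        return pnt.HaplotypePanel(
            np.stack(haps), np.asarray(inds, object), np.asarray(pops, object)
        )

    def test_pure_source_mosaics_assigned_to_source(self, mixed_panel):
        _, sh = mixed_panel
        mos = sim.simulate_haplotype_mosaic(sh, [1.0, 0.0], 1e-3, 2, seed=33)
        panel = self._panel(sh, mos)
        cm = pnt.coancestry(
            panel, "donor_recipient", donor_set=["A", "B"], recipient_set=["R"],
            params=pnt.CopyingParams(1e-3, 1e-3),
        )
        prof = cm.population_profiles()
        assert prof.loc["R", "A"] >= 0.90

    def test_identical_recipients_identical_rows(self, mixed_panel):
        _, sh = mixed_panel
        mos = sim.simulate_haplotype_mosaic(sh, [0.5, 0.5], 1e-3, 1, seed=34)
        hap = mos.haps[0]
        haps, inds, pops = [], [], []
        for lab in ("A", "B"):
            for h in range(8):
                haps.append(sh[lab][h])
                inds.append(f"{lab}_{h // 2}")
                pops.append(lab)
        for r in range(2):
            haps.extend([hap, hap])
            inds.extend([f"R_{r}"] * 2)
            pops.extend(["R"] * 2)
        panel = pnt.HaplotypePanel(
            np.stack(haps), np.asarray(inds, object), np.asarray(pops, object)
        )
        cm = pnt.coancestry(
            panel, "donor_recipient", donor_set=["A", "B"], recipient_set=["R"],
            params=pnt.CopyingParams(1e-3, 1e-3),
        )
        np.testing.assert_allclose(
            cm.chunk_counts.loc["R_0"].to_numpy(),
            cm.chunk_counts.loc["R_1"].to_numpy(),
            rtol=1e-9,
        )

    def test_sixty_forty_profile_recovery(self, mixed_panel):
        # 60:40 mosaics: population copy profile within +-5 points
        f = sim.sample_source_frequencies(50_000, [0.08, 0.08], seed=41,
                                          labels=["A", "B"])
        sh = sim.simulate_source_haplotypes(f, 8, seed=42)
        mos = sim.simulate_haplotype_mosaic(sh, [0.6, 0.4], 1e-3, 4, seed=43)
        panel = self._panel(sh, mos)
        cm = pnt.coancestry(
            panel, "donor_recipient", donor_set=["A", "B"], recipient_set=["R"],
            params=pnt.CopyingParams(1e-3, 1e-3),
        )
        # chunk-count profile estimates the redraw mixture proportion
        prof = cm.population_profiles()
        assert abs(prof.loc["R", "A"] - 0.6) <= 0.05
        # copied-length profile tracks each individual's realized site
        # fraction (mosaic truth labels) even more tightly
        lengths = cm.chunk_lengths.T.groupby(
            [cm.donor_populations[c] for c in cm.chunk_lengths.columns]
        ).sum().T
        lengths = lengths.div(lengths.sum(axis=1), axis=0)
        realized = (mos.true_source == 0).mean(axis=1)
        for r, (h1, h2) in enumerate([(0, 1), (2, 3)]):
            true_frac = 0.5 * (realized[h1] + realized[h2])
            assert abs(lengths.loc[f"R_{r}", "A"] - true_frac) <= 0.03

    def test_all_vs_all_zero_diagonal(self, mixed_panel):
        _, sh = mixed_panel
        haps, inds, pops = [], [], []
        for lab in ("A", "B"):
            for h in range(4):
                haps.append(sh[lab][h])
                inds.append(f"{lab}_{h // 2}")
                pops.append(lab)
        panel = pnt.HaplotypePanel(
            np.stack(haps), np.asarray(inds, object), np.asarray(pops, object)
        )
        cm = pnt.coancestry(panel, "all_vs_all", params=pnt.CopyingParams(1e-3, 1e-3))
        diag = np.diag(cm.chunk_counts.loc[
            cm.chunk_counts.index, cm.chunk_counts.index
        ].to_numpy())
        np.testing.assert_allclose(diag, 0.0)

    def test_overlapping_sets_rejected(self, mixed_panel):
        _, sh = mixed_panel
        mos = sim.simulate_haplotype_mosaic(sh, [1, 0], 1e-3, 1, seed=35)
        panel = self._panel(sh, mos)
        with pytest.raises(ValueError):
            pnt.coancestry(
                panel, "donor_recipient", donor_set=["A", "R"], recipient_set=["R"]
            )
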