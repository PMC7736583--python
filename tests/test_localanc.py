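"""Local-ancestry HMM posteriors and the admixture-mapping permutation test."""

import itertools

import numpy as np
import pytest

from sccadmix.errors import InvalidArgumentError
from sccadmix.localanc import (
    LocalAncestryMatrix,
    _forward_backward,
    admixture_map_test,
    infer_local_ancestry,
    mean_ancestry_by_status,
)
from sccadmix.simulate import (
    AncestralPanel,
    SimulationConfig,
    simulate_admixed_cohort,
    simulate_ancestral_frequencies,
)


def exhaustive_posteriors(freqs, gpos, pi, alleles, g):
    """Sum over every hidden path (oracle for small instances)."""
    ell, k = freqs.shape
    stay = np.exp(-g * np.diff(gpos))
    trans = [s * np.eye(k) + (1 - s) * np.tile(pi, (k, 1)) for s in stay]
    em = np.where(alleles[:, None] == 1, freqs, 1 - freqs)
    post = np.zeros((ell, k))
    total = 0.0
    for path in itertools.product(range(k), repeat=ell):
        p = pi[path[0]] * em[0, path[0]]
        for t in range(1, ell):
            p *= trans[t - 1][path[t - 1], path[t]] * em[t, path[t]]
        total += p
        for t in range(ell):
            post[t, path[t]] += p
    return post / total


def panel_from(freqs, gpos, pops=("EUR", "NAM", "AFR")):
    ell = len(freqs)
    return AncestralPanel(
        pop_labels=tuple(pops[: freqs.shape[1]]),
        variant_ids=[f"v{i}" for i in range(ell)],
        allele_freqs=freqs,
        chrom=np.array(["1"] * ell),
        pos_bp=(np.arange(ell) + 1) * 1000,
        gpos=gpos,
    )


class TestForwardBackward:
    def test_matches_exhaustive_path_enumeration(self, rng):
        for trial in range(5):
            freqs = rng.uniform(0.05, 0.95, size=(6, 3))
            gpos = np.sort(rng.uniform(0.001, 0.2, size=6))
            pi = rng.dirichlet([2, 2, 2])
            alleles = rng.integers(0, 2, size=6)
            oracle = exhaustive_posteriors(freqs, gpos, pi, alleles, g=8)
            em = np.where(alleles[:, None] == 1, freqs, 1 - freqs)[None]
            fb = _forward_backward(em, np.exp(-8 * np.diff(gpos)), pi[None])
            assert np.abs(fb[0] - oracle).max() < 1e-10

    def test_uninformative_emissions_return_global_proportions(self, rng):
        freqs = np.full((10, 3), 0.4)
        gpos = np.linspace(0.01, 0.1, 10)
        panel = panel_from(freqs, gpos)
        cfg = SimulationConfig(seed=0, n_individuals=30, dirichlet_alpha=(3, 2, 1))
        genotypes, truth = simulate_admixed_cohort(panel, cfg)
        local = infer_local_ancestry(
            genotypes, panel, g=10, global_props=truth.global_ancestry,
            keep_posteriors=True,
        )
        for i in range(5):
            expect = truth.global_ancestry[i]
            assert np.allclose(local.posteriors[i, 0], expect, atol=1e-9)

    def test_fixed_differences_recover_true_tracts(self):
        panel = simulate_ancestral_frequencies(
            300, 3, 0.2, seed=5, spacing_bp=500_000
        )
        # divergence limit: population 0 carries the alternate allele
        f = np.full((300, 3), 0.005)
        f[:, 0] = 0.995
        panel = panel_from(f, panel.gpos)
        cfg = SimulationConfig(seed=1, n_individuals=50, dirichlet_alpha=(2, 1, 1))
        genotypes, truth = simulate_admixed_cohort(panel, cfg)
        local = infer_local_ancestry(
            genotypes, panel, g=10, global_props=truth.global_ancestry,
            keep_posteriors=True,
        )
        calls = local.posteriors.argmax(axis=3)  # (n, 2, m)
        # populations 1 and 2 are exchangeable here; compare EUR vs non-EUR
        acc = ((calls == 0) == (truth.local_ancestry_true == 0)).mean()
        assert acc > 0.99

    def test_posterior_dosages_sum_to_two_over_populations(self, rng):
        freqs = rng.uniform(0.1, 0.9, size=(20, 3))
        panel = panel_from(freqs, np.linspace(0.01, 0.5, 20))
        cfg = SimulationConfig(seed=2, n_individuals=20, dirichlet_alpha=(2, 2, 2))
        genotypes, truth = simulate_admixed_cohort(panel, cfg)
        local = infer_local_ancestry(
            genotypes, panel, g=10, global_props=truth.global_ancestry,
            keep_posteriors=True,
        )
        sums = local.posteriors.sum(axis=3)
        assert np.allclose(sums, 1.0, atol=1e-9)
        total = local.posteriors.sum(axis=1).sum(axis=2)
        assert np.allclose(total, 2.0, atol=1e-9)

    def test_non_european_relabelling_leaves_eur_dosage_unchanged(self, rng):
        freqs = rng.uniform(0.1, 0.9, size=(15, 3))
        gpos = np.linspace(0.01, 0.3, 15)
        panel = panel_from(freqs, gpos)
        cfg = SimulationConfig(seed=3, n_individuals=15, dirichlet_alpha=(3, 2, 1))
        genotypes, truth = simulate_admixed_cohort(panel, cfg)
        a = infer_local_ancestry(genotypes, panel, 10, truth.global_ancestry)
        swapped = panel_from(freqs[:, [0, 2, 1]], gpos, pops=("EUR", "AFR", "NAM"))
        b = infer_local_ancestry(
            genotypes, swapped, 10, truth.global_ancestry[:, [0, 2, 1]]
        )
        assert np.allclose(a.eur_dosage, b.eur_dosage, atol=1e-12)

    def test_large_gap_limit_is_per_site_bayes_rule(self, rng):
        freqs = rng.uniform(0.1, 0.9, size=(8, 3))
        gpos = np.arange(8) * 50.0 + 1.0  # enormous gaps: g*dd -> inf
        panel = panel_from(freqs, gpos)
        cfg = SimulationConfig(seed=4, n_individuals=10, dirichlet_alpha=(2, 2, 2))
        genotypes, truth = simulate_admixed_cohort(panel, cfg)
        local = infer_local_ancestry(
            genotypes, panel, g=50, global_props=truth.global_ancestry,
            keep_posteriors=True,
        )
        haps = genotypes.haplotypes
        for i in range(10):
            for h in range(2):
                for t in range(8):
                    a = haps[i, h, t]
                    em = freqs[t] if a == 1 else 1 - freqs[t]
                    bayes = truth.global_ancestry[i] * em
                    bayes = bayes / bayes.sum()
                    assert np.allclose(local.posteriors[i, h, t], bayes, atol=1e-8)

    def test_unsorted_positions_rejected(self, rng):
        freqs = rng.uniform(0.2, 0.8, size=(5, 2))
        with pytest.raises(Exception):
            panel_from(freqs, np.array([0.05, 0.01, 0.2, 0.3, 0.4]), pops=("EUR", "NAM"))


class TestAdmixtureMap:
    def _local(self, rng, n=400, m=5, shift=0.0):
        eur = np.clip(rng.beta(3, 2, size=(n, m)) * 2, 0, 2)
        y = rng.random(n) < 0.3
        eur[y, 0] = np.clip(eur[y, 0] + shift, 0, 2)
        return (
            LocalAncestryMatrix(
                samples=[f"s{i}" for i in range(n)],
                variant_ids=[f"v{j}" for j in range(m)],
                eur_dosage=eur,
            ),
            y.astype(int),
        )

    def test_same_seed_reproduces_p_values(self, rng):
        local, y = self._local(rng)
        a = admixture_map_test(local, y, ["v0", "v1"], n_perm=1000, seed=9)
        b = admixture_map_test(local, y, ["v0", "v1"], n_perm=1000, seed=9)
        assert np.array_equal(a.table["p"], b.table["p"])

    def test_bonferroni_threshold_for_16_loci(self, rng):
        from sccadmix.summary import bonferroni_threshold

        local, y = self._local(rng, m=16)
        res = admixture_map_test(
            local, y, [f"v{j}" for j in range(16)], n_perm=1000, seed=1
        )
        assert res.bonferroni_threshold == pytest.approx(0.003125)
        exact, printed = bonferroni_threshold(0.05, 16, sig=2)
        assert exact == res.bonferroni_threshold
        assert printed == pytest.approx(3.1e-3)

    def test_shifted_locus_detected(self, rng):
        local, y = self._local(rng, n=800, shift=0.5)
        res = admixture_map_test(local, y, ["v0", "v1"], n_perm=1000, seed=2)
        tab = res.table.set_index("locus")
        assert tab.loc["v0", "p"] < 0.01
        assert tab.loc["v0", "case_mean_pct"] > tab.loc["v0", "control_mean_pct"]

    def test_add_one_correction_bounds_p_away_from_zero(self, rng):
        local, y = self._local(rng, n=800, shift=1.0)
        res = admixture_map_test(local, y, ["v0"], n_perm=1000, seed=3)
        assert res.table["p"].iloc[0] >= 1.0 / 1001

    def test_single_class_input_rejected(self, rng):
        local, _ = self._local(rng)
        with pytest.raises(InvalidArgumentError):
            admixture_map_test(local, np.ones(400), ["v0"], n_perm=1000, seed=0)

    def test_mean_ancestry_by_status(self, rng):
        local, y = self._local(rng)
        case_pct, control_pct = mean_ancestry_by_status(local, y, "v0")
        frac = local.eur_dosage[:, 0] / 2
        assert case_pct == pytest.approx(100 * frac[y == 1].mean())
        assert control_pct == pytest.approx(100 * frac[y == 0].mean())

    def test_fully_european_cases_give_hundred_percent(self):
        local = LocalAncestryMatrix(
            samples=["a", "b"], variant_ids=["v0"], eur_dosage=np.array([[2.0], [0.5]])
        )
        case_pct, control_pct = mean_ancestry_by_status(local, [1, 0], "v0")
        assert case_pct == 100.0
        assert control_pct == 25.0

    def test_single_individual_per_group_reduction(self):
        local = LocalAncestryMatrix(
            samples=["a", "b"], variant_ids=["v0"], eur_dosage=np.array([[1.2], [0.8]])
        )
        case_pct, control_pct = mean_ancestry_by_status(local, [1, 0], "v0")
        assert case_pct == pytest.approx(60.0)
        assert control_pct == pytest.approx(40.0)
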