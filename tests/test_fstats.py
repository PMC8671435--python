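"""f-statistics: hand-computed oracles, symmetries, simulation recovery."""

import numpy as np
import pytest

from paleostrat.data import MISSING
from paleostrat.fstats import (clade_f4_scan, f3_admixture_test, f4,
                               f4_outlier_scan, fst_hudson)
from paleostrat.jackknife import assign_blocks
from paleostrat.simulate import (SOURCE_NILOTIC, SOURCE_WE, TARGET,
                                 SimulationConfig, simulate_admixed_cohort)
from paleostrat.data import partition_compartments
from conftest import REFS, draw_population, make_dataset


def freq_controlled_dataset(freq_table, chromosomes=None):
    """One diploid individual per population whose genotype encodes the
    wanted frequency exactly (0 -> 0, 0.5 -> 1, 1 -> 2)."""
    pops = list(freq_table)
    geno = np.array([[int(round(2 * f)) for f in freq_table[p]]
                     for p in pops], dtype=np.int8)
    return make_dataset(geno, chromosomes=chromosomes, groups=pops,
                        ploidy="diploid")


class TestF4:
    def setup_method(self):
        self.freqs = {
            "A": [0.0, 0.5, 1.0, 0.5, 0.0, 1.0],
            "B": [1.0, 0.0, 0.5, 0.5, 0.0, 0.0],
            "C": [0.5, 1.0, 0.0, 0.0, 0.5, 1.0],
            "D": [0.0, 0.0, 1.0, 0.5, 1.0, 0.5],
            "E": [1.0, 0.5, 0.5, 0.0, 0.0, 0.0],
        }
        self.ds = freq_controlled_dataset(
            self.freqs, chromosomes=["1", "1", "1", "2", "2", "2"])
        self.blocks = assign_blocks(self.ds.snps, min_blocks=2)

    def oracle(self, a, b, c, d):
        """Direct per-SNP arithmetic: mean of (pA-pB)(pC-pD)."""
        f = {k: np.array(v) for k, v in self.freqs.items()}
        return np.mean((f[a] - f[b]) * (f[c] - f[d]))

    def test_matches_hand_computation(self):
        res = f4(self.ds, "A", "B", "C", "D", blocks=self.blocks)
        assert res.estimate == pytest.approx(self.oracle("A", "B", "C", "D"))

    def test_identical_last_args_give_zero(self):
        res = f4(self.ds, "A", "B", "C", "C", blocks=self.blocks)
        assert res.estimate == 0.0

    def test_antisymmetry(self):
        base = f4(self.ds, "A", "B", "C", "D", blocks=self.blocks).estimate
        assert f4(self.ds, "B", "A", "C", "D",
                  blocks=self.blocks).estimate == pytest.approx(-base)
        assert f4(self.ds, "A", "B", "D", "C",
                  blocks=self.blocks).estimate == pytest.approx(-base)

    def test_linearity_in_third_slot(self):
        """f4(A,B;C,D) + f4(A,B;D,E) = f4(A,B;C,E) exactly."""
        g = lambda *p: f4(self.ds, *p, blocks=self.blocks).estimate
        assert g("A", "B", "C", "D") + g("A", "B", "D", "E") == pytest.approx(
            g("A", "B", "C", "E"), abs=1e-12)

    def test_allele_flip_invariance(self):
        """A global ref/alt flip (g -> 2 - g) flips both factors, leaving
        f4 unchanged."""
        flipped = self.ds.genotypes.copy()
        mask = flipped != MISSING
        flipped[mask] = 2 - flipped[mask]
        ds2 = make_dataset(flipped, chromosomes=["1"] * 3 + ["2"] * 3,
                           groups=list(self.freqs), ploidy="diploid")
        a = f4(self.ds, "A", "B", "C", "D", blocks=self.blocks).estimate
        b = f4(ds2, "A", "B", "C", "D", blocks=self.blocks).estimate
        assert a == pytest.approx(b)

    def test_missing_population_drops_snp(self):
        geno = np.array([[0, 2, 0], [2, MISSING, 2], [0, 2, 0], [2, 0, 2]],
                        dtype=np.int8)
        ds = make_dataset(geno, chromosomes=["1", "2", "2"],
                          groups=["A", "B", "C", "D"])
        res = f4(ds, "A", "B", "C", "D",
                 blocks=assign_blocks(ds.snps, min_blocks=2))
        assert res.n_snps == 2


class TestF3:
    def test_midway_target_is_negative(self):
        """Target frequencies exactly midway between the references at
        every SNP give a negative admixture f3 (with large samples the
        correction term is small)."""
        rng = np.random.default_rng(0)
        p1 = rng.uniform(0.1, 0.9, 400)
        p2 = np.clip(p1 + rng.choice([-0.4, 0.4], 400), 0.01, 0.99)
        pt = (p1 + p2) / 2
        geno = np.vstack([
            draw_population(rng, pt, 80),
            draw_population(rng, p1, 80),
            draw_population(rng, p2, 80),
        ])
        ds = make_dataset(geno, chromosomes=["1"] * 200 + ["2"] * 200,
                          groups=["T"] * 80 + ["R1"] * 80 + ["R2"] * 80,
                          ploidy="pseudohaploid")
        res = f3_admixture_test(ds, "T", "R1", "R2",
                                blocks=assign_blocks(ds.snps, min_blocks=2))
        assert res.estimate < 0

    def test_identical_references_nonnegative(self):
        """f3(T; R, R) is a variance term, never significantly negative."""
        rng = np.random.default_rng(1)
        p = rng.uniform(0.1, 0.9, 400)
        pt = rng.uniform(0.1, 0.9, 400)
        geno = np.vstack([draw_population(rng, pt, 60),
                          draw_population(rng, p, 60)])
        ds = make_dataset(geno, chromosomes=["1"] * 200 + ["2"] * 200,
                          groups=["T"] * 60 + ["R"] * 60)
        res = f3_admixture_test(ds, "T", "R", "R",
                                blocks=assign_blocks(ds.snps, min_blocks=2))
        assert res.estimate > -2 * res.std_error

    def test_admixed_cohort_strongly_negative(self):
        """A two-source admixed cohort against its sources yields
        admixture-f3 evidence beyond the |Z| > 7.5 threshold at 50k SNPs."""
        cfg = SimulationConfig(n_snps_per_chromosome=2500, n_chromosomes=20,
                               n_target_individuals=20, cemetery_split=(10, 10),
                               ancestry_mean=0.40, missing_rate=0.2, seed=29)
        ds, _ = simulate_admixed_cohort(cfg)
        auto = partition_compartments(ds)["autosomes"]
        res = f3_admixture_test(auto, TARGET, SOURCE_NILOTIC, SOURCE_WE)
        assert res.z_score < -7.5

    def test_singleton_target_with_correction_errors(self):
        ds = make_dataset([[0, 2], [2, 0], [0, 0]], groups=["T", "R1", "R2"],
                          ploidy="pseudohaploid")
        with pytest.raises(ValueError, match="inbreed"):
            f3_admixture_test(ds, "T", "R1", "R2",
                              blocks=np.array([0, 1]))


class TestOutlierScan:
    def _cohort(self, seed, shift_individual=False):
        cfg = SimulationConfig(n_snps_per_chromosome=1500, n_chromosomes=14,
                               n_target_individuals=30, cemetery_split=(15, 15),
                               ancestry_sd=0.01, missing_rate=0.2, seed=seed)
        ds, _ = simulate_admixed_cohort(cfg)
        if shift_individual:
            # splice in one individual simulated from a 15-point-higher
            # ancestry mean (same seed -> same SNP map and frequencies)
            cfg2 = SimulationConfig(**{**vars(cfg),
                                       "ancestry_mean": cfg.ancestry_mean + 0.15})
            ds2, _ = simulate_admixed_cohort(cfg2)
            row = ds.group_indices(TARGET)[0]
            ds.genotypes[row] = ds2.genotypes[ds2.group_indices(TARGET)[0]]
        return partition_compartments(ds)["autosomes"]

    def test_homogeneous_pool_has_no_outliers(self):
        auto = self._cohort(31)
        scan = f4_outlier_scan(auto, SOURCE_NILOTIC, SOURCE_WE, TARGET)
        assert sum(r["outlier"] for r in scan) == 0

    def test_planted_shifted_individual_is_flagged(self):
        auto = self._cohort(31, shift_individual=True)
        scan = f4_outlier_scan(auto, SOURCE_NILOTIC, SOURCE_WE, TARGET)
        flagged = [r["individual_id"] for r in scan if r["outlier"]]
        assert flagged == ["KUL_000"]
        planted = next(r for r in scan if r["individual_id"] == "KUL_000")
        # positive Z orientation = excess West-Eurasian-like ancestry
        assert planted["result"].z_score > 5

    def test_unscorable_individual_reported_not_flagged(self):
        auto = self._cohort(33)
        row = auto.group_indices(TARGET)[2]
        auto.genotypes[row] = MISSING
        scan = f4_outlier_scan(auto, SOURCE_NILOTIC, SOURCE_WE, TARGET)
        rec = next(r for r in scan if r["individual_id"] == "KUL_002")
        assert not rec["scorable"] and not rec["outlier"]


class TestCladeScan:
    def test_identical_groups_all_zero(self, small_cohort):
        _, ds, _ = small_cohort
        auto = partition_compartments(ds)["autosomes"]
        idx = auto.group_indices(TARGET)
        out = clade_f4_scan(auto, SOURCE_NILOTIC, REFS[:3], idx, idx)
        assert out["consistent_with_clade"]
        assert all(s.estimate == 0.0 for s in out["statistics"])

    def test_random_split_is_a_clade(self, small_cohort):
        _, ds, _ = small_cohort
        auto = partition_compartments(ds)["autosomes"]
        idx = auto.group_indices(TARGET)
        out = clade_f4_scan(auto, SOURCE_NILOTIC, [SOURCE_WE] + REFS[:3],
                            idx[::2], idx[1::2])
        assert out["consistent_with_clade"]

    def test_ancestry_shifted_split_rejects(self):
        cfg = SimulationConfig(n_snps_per_chromosome=2000, n_chromosomes=14,
                               n_target_individuals=30, cemetery_split=(15, 15),
                               ancestry_sd=0.01, missing_rate=0.2, seed=35)
        ds, _ = simulate_admixed_cohort(cfg)
        cfg2 = SimulationConfig(**{**vars(cfg), "ancestry_mean": 0.67})
        ds2, _ = simulate_admixed_cohort(cfg2)
        idx = ds.group_indices(TARGET)
        half = idx[:15]
        ds.genotypes[half] = ds2.genotypes[ds2.group_indices(TARGET)[:15]]
        auto = partition_compartments(ds)["autosomes"]
        out = clade_f4_scan(auto, SOURCE_NILOTIC, [SOURCE_WE] + REFS[:3],
                            half, idx[15:])
        assert not out["consistent_with_clade"]


class TestHudsonFst:
    def _two_pop_dataset(self, fst, seed, n_snps=20000, n_ind=25):
        rng = np.random.default_rng(seed)
        anc = rng.uniform(0.05, 0.95, n_snps)
        shape = (1 - fst) / fst
        p1 = rng.beta(anc * shape, (1 - anc) * shape)
        p2 = rng.beta(anc * shape, (1 - anc) * shape)
        geno = np.vstack([draw_population(rng, p1, n_ind, "diploid"),
                          draw_population(rng, p2, n_ind, "diploid")])
        chroms = np.repeat([str(c + 1) for c in range(10)], n_snps // 10)
        ds = make_dataset(geno, chromosomes=chroms,
                          genetic_pos=np.tile(
                              np.linspace(0, 1, n_snps // 10), 10),
                          groups=["P1"] * n_ind + ["P2"] * n_ind,
                          ploidy="diploid")
        return ds

    def test_same_population_near_zero(self, small_cohort):
        """Two random halves of one population have FST indistinguishable
        from zero (the finite-sample correction removes the sampling
        variance of the independent halves)."""
        _, ds, _ = small_cohort
        auto = partition_compartments(ds)["autosomes"]
        idx = auto.group_indices(TARGET)
        res = fst_hudson(auto, idx[::2], idx[1::2])
        assert abs(res.estimate) < 2 * res.std_error

    def test_recovers_nominal_divergence(self):
        """Two Balding-Nichols populations each drifted 0.01 from the
        shared ancestor have pairwise Hudson FST 0.01 (the doubled
        between-population numerator is normalized by the doubled
        heterozygosity); the estimate recovers it within 2 SE."""
        ds = self._two_pop_dataset(0.01, 41)
        res = fst_hudson(ds, "P1", "P2")
        assert res.estimate == pytest.approx(0.01, abs=2 * res.std_error)

    def test_monotone_in_divergence(self):
        ests = [fst_hudson(self._two_pop_dataset(f, 43), "P1", "P2").estimate
                for f in (0.001, 0.01, 0.1)]
        assert ests[0] < ests[1] < ests[2]

    def test_singleton_population_errors(self):
        ds = make_dataset([[0, 2], [2, 0]], groups=["A", "B"])
        with pytest.raises(ValueError, match="individuals"):
            fst_hudson(ds, "A", "B", blocks=np.array([0, 1]))


class TestJackknifeCalibration:
    def test_f4_se_tracks_empirical_sd(self):
        """The block-jackknife SE of f4 matches the empirical SD over 100
        independent simulation replicates within a factor of 1.5."""
        rng = np.random.default_rng(47)
        ests, ses = [], []
        for _ in range(100):
            n = 3000
            anc = rng.uniform(0.1, 0.9, n)
            pops = {}
            for name in ("A", "B", "C", "D"):
                shape = (1 - 0.05) / 0.05
                p = rng.beta(anc * shape, (1 - anc) * shape)
                pops[name] = draw_population(rng, p, 10)
            geno = np.vstack(list(pops.values()))
            chroms = np.repeat([str(c + 1) for c in range(6)], n // 6)
            ds = make_dataset(geno, chromosomes=chroms,
                              genetic_pos=np.tile(np.linspace(0, 1, n // 6), 6),
                              groups=sum(([p] * 10 for p in pops), []),
                              ploidy="pseudohaploid")
            res = f4(ds, "A", "B", "C", "D")
            ests.append(res.estimate)
            ses.append(res.std_error)
        ratio = np.mean(ses) / np.std(ests)
        assert 1 / 1.5 < ratio < 1.5
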