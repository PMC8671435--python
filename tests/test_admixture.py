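"""Admixture modeling: f4 systems, weight recovery, cladality, sex bias."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from paleostrat.admixture import (build_f4_system, estimate_sex_bias,
                                  fit_qpadm, model_competition,
                                  qpwave_clade_test, sex_bias_decomposition)
from paleostrat.data import partition_compartments
from paleostrat.fstats import f4
from paleostrat.jackknife import assign_blocks
from paleostrat.simulate import (SOURCE_NILOTIC, SOURCE_WE, TARGET,
                                 SimulationConfig, simulate_admixed_cohort,
                                 simulate_source_frequencies)
from conftest import REFS, draw_population, make_dataset


def synthetic_pops_dataset(seed, extra=None, n_snps=12000, n_ind=20,
                           theta=None, we_component=None):
    """Reference/source/outgroup individuals drawn from a simulated
    frequency tree, optionally plus extra drifted populations and a "Mix"
    target blending Source1 with a West-Eurasian-like component at
    proportion ``theta`` (site-independent frequency mixture).

    ``extra`` maps name -> (base population, drift); ``we_component`` names
    the population (or dict of weights) whose frequencies form the admixed
    component (default Source2)."""
    cfg = SimulationConfig(seed=seed)
    freqs = simulate_source_frequencies(cfg, n_snps=n_snps)
    rng = np.random.default_rng(seed + 1000)
    if extra:
        for name, (base, drift) in extra.items():
            shape = (1 - drift) / drift
            p = np.clip(freqs[base], 1e-4, 1 - 1e-4)
            freqs[name] = rng.beta(p * shape, (1 - p) * shape)
    if theta is not None:
        if we_component is None:
            comp = freqs[SOURCE_WE]
        elif isinstance(we_component, dict):
            comp = sum(wgt * freqs[name] for name, wgt in we_component.items())
        else:
            comp = freqs[we_component]
        freqs["Mix"] = theta * comp + (1 - theta) * freqs[SOURCE_NILOTIC]
    rows, groups = [], []
    for name, p in freqs.items():
        if name == "ancestral":
            continue
        rows.append(draw_population(rng, p, n_ind))
        groups += [name] * n_ind
    chroms = np.repeat([str(c + 1) for c in range(8)], n_snps // 8)
    return make_dataset(np.vstack(rows), chromosomes=chroms,
                        genetic_pos=np.tile(np.linspace(0, 1.2, n_snps // 8), 8),
                        groups=groups, ploidy="pseudohaploid")


class TestF4System:
    def test_dimensions(self, small_cohort):
        _, ds, _ = small_cohort
        auto = partition_compartments(ds)["autosomes"]
        sys = build_f4_system(auto, TARGET, [SOURCE_NILOTIC, SOURCE_WE], REFS)
        k, m = 2, 5
        assert sys.y.shape == (m - 1,)
        assert sys.design.shape == (m - 1, k)
        assert sys.cov.shape == ((k + 1) * (m - 1), (k + 1) * (m - 1))

    def test_under_identified_errors(self, small_cohort):
        _, ds, _ = small_cohort
        auto = partition_compartments(ds)["autosomes"]
        with pytest.raises(ValueError, match="under-identified"):
            build_f4_system(auto, TARGET, [SOURCE_NILOTIC, SOURCE_WE],
                            REFS[:2])

    def test_target_equal_to_single_source(self, small_cohort):
        """With k=1 and the target indices reused as the source, the
        response vector equals the design column exactly."""
        _, ds, _ = small_cohort
        auto = partition_compartments(ds)["autosomes"]
        idx = auto.group_indices(TARGET)
        sys = build_f4_system(auto, idx, [idx], REFS)
        np.testing.assert_allclose(sys.y, sys.design[:, 0], atol=1e-15)

    def test_covariance_diagonal_tracks_fstat_se(self):
        """The system's jackknife covariance diagonal matches the SE the
        f-statistic module reports for the same contrast (no missingness,
        so the SNP masks coincide)."""
        ds = synthetic_pops_dataset(seed=51)
        blocks = assign_blocks(ds.snps)
        sys = build_f4_system(ds, SOURCE_NILOTIC, [SOURCE_WE],
                              ["Out1", "Out2", "Out3"], blocks=blocks)
        res = f4(ds, SOURCE_NILOTIC, "Out1", "Out2", "Out1", blocks=blocks)
        assert np.sqrt(sys.cov[0, 0]) == pytest.approx(res.std_error, rel=0.15)
        assert sys.y[0] == pytest.approx(res.estimate, abs=1e-12)


class TestFitQpadm:
    def test_pure_source_target(self):
        """A target drawn from Source1's own frequencies gets weight ~1."""
        ds = synthetic_pops_dataset(seed=53, theta=0.0)
        fit = fit_qpadm(build_f4_system(ds, "Mix",
                                        [SOURCE_NILOTIC, SOURCE_WE], REFS))
        assert fit.weights[0] == pytest.approx(1.0, abs=2.5 * fit.std_errors[0])
        assert fit.weights.sum() == pytest.approx(1.0, abs=1e-9)

    def test_even_mixture_recovery(self):
        """A 50/50 frequency-mixture target recovers (0.5, 0.5) within
        2 SE with an adequate model fit."""
        ds = synthetic_pops_dataset(seed=55, theta=0.5)
        fit = fit_qpadm(build_f4_system(ds, "Mix",
                                        [SOURCE_NILOTIC, SOURCE_WE], REFS))
        assert fit.weights[1] == pytest.approx(0.5, abs=2 * fit.std_errors[1])
        assert fit.p_value > 0.05

    def test_misspecified_target_rejected(self):
        """A target from a deeply diverged third population is rejected."""
        ds = synthetic_pops_dataset(
            seed=57, extra={"Mystery": ("ancestral", 0.25)})
        fit = fit_qpadm(build_f4_system(ds, "Mystery",
                                        [SOURCE_NILOTIC, SOURCE_WE], REFS))
        assert fit.p_value < 0.05

    def test_reference_reordering_invariance(self, small_cohort):
        _, ds, _ = small_cohort
        auto = partition_compartments(ds)["autosomes"]
        f1 = fit_qpadm(build_f4_system(auto, TARGET,
                                       [SOURCE_NILOTIC, SOURCE_WE], REFS))
        f2 = fit_qpadm(build_f4_system(auto, TARGET,
                                       [SOURCE_NILOTIC, SOURCE_WE],
                                       REFS[::-1]))
        np.testing.assert_allclose(f1.weights, f2.weights, atol=1e-4)


class TestModelCompetition:
    def test_row_count(self):
        ds = synthetic_pops_dataset(seed=59, theta=0.45,
                                    extra={"Decoy": (SOURCE_WE, 0.08)})
        rows = model_competition(ds, "Mix", [SOURCE_WE, "Decoy"],
                                 SOURCE_NILOTIC, REFS[:4])
        assert len(rows) == 2  # n_candidates * (n_candidates - 1)

    def test_proximate_source_survives_distal_fails(self):
        """The target mixes from a population one drift step beyond the
        distal proxy. The proximate proxy keeps fitting with the distal one
        among the references; the distal model collapses once the proximate
        population joins the references, because the target shares drift
        with it that the distal source cannot supply."""
        ds = synthetic_pops_dataset(
            seed=61, theta=0.45, extra={"Proximate": (SOURCE_WE, 0.08)},
            we_component="Proximate")
        rows = model_competition(ds, "Mix", [SOURCE_WE, "Proximate"],
                                 SOURCE_NILOTIC, REFS[:4])
        verdict = {r["kept_source"]: r["survives"] for r in rows}
        assert verdict["Proximate"] and not verdict[SOURCE_WE]

    def test_blended_ancestry_fails_both_proxies(self):
        """When the target's admixed component blends private drift from
        both candidate proxies, each candidate's model fails as soon as the
        other joins the references."""
        ds = synthetic_pops_dataset(
            seed=63, theta=0.45,
            extra={"ProxA": (SOURCE_WE, 0.08), "ProxB": (SOURCE_WE, 0.08)},
            we_component={"ProxA": 0.5, "ProxB": 0.5})
        rows = model_competition(ds, "Mix", ["ProxA", "ProxB"],
                                 SOURCE_NILOTIC, REFS[:4])
        assert not any(r["survives"] for r in rows)


class TestQpWave:
    def test_identical_groups_give_p_one(self, small_cohort):
        _, ds, _ = small_cohort
        auto = partition_compartments(ds)["autosomes"]
        idx = auto.group_indices(TARGET)
        out = qpwave_clade_test(auto, idx, idx, REFS)
        assert out["p_value"] == 1.0
        assert out["consistent_with_clade"]

    def test_shifted_groups_rejected(self):
        cfg = SimulationConfig(n_snps_per_chromosome=2000, n_chromosomes=14,
                               n_target_individuals=30, cemetery_split=(15, 15),
                               ancestry_sd=0.01, missing_rate=0.2, seed=65)
        ds, _ = simulate_admixed_cohort(cfg)
        ds2, _ = simulate_admixed_cohort(
            SimulationConfig(**{**vars(cfg), "ancestry_mean": 0.67}))
        idx = ds.group_indices(TARGET)
        ds.genotypes[idx[:15]] = ds2.genotypes[ds2.group_indices(TARGET)[:15]]
        auto = partition_compartments(ds)["autosomes"]
        out = qpwave_clade_test(auto, idx[:15], idx[15:],
                                [SOURCE_WE] + REFS)
        assert out["p_value"] < 0.05


class TestSexBiasDecomposition:
    def test_published_style_inputs(self):
        """57.5 ± 0.3 % autosomal vs 64.4 ± 1.8 % X gives Z = 3.78 and a
        female fraction of 68% (95% CI 59-77%)."""
        res = sex_bias_decomposition(0.575, 0.003, 0.644, 0.018)
        assert res.z_score == pytest.approx(3.78, abs=0.01)
        assert res.P == pytest.approx(0.68, abs=0.005)
        assert res.P_ci[0] == pytest.approx(0.59, abs=0.005)
        assert res.P_ci[1] == pytest.approx(0.77, abs=0.005)

    def test_no_bias_fixed_point(self):
        res = sex_bias_decomposition(0.6, 0.01, 0.6, 0.02)
        assert res.F == pytest.approx(res.M)
        assert res.P == pytest.approx(0.5)
        assert res.z_score == pytest.approx(0.0)

    @given(st.floats(0.1, 0.9), st.floats(0.1, 0.9))
    @settings(deadline=None, max_examples=100)
    def test_f_plus_m_identity(self, a, x):
        """F + M = 2A identically for any compartment proportions."""
        res = sex_bias_decomposition(a, 0.01, x, 0.02)
        assert res.F + res.M == pytest.approx(2 * a, abs=1e-12)


class TestEstimateSexBias:
    def test_end_to_end_recovery(self):
        """The fitted female fraction's 95% CI covers the generating value
        on a simulated female-biased cohort."""
        cfg = SimulationConfig(n_snps_per_chromosome=1500, n_chromosomes=10,
                               n_target_individuals=40, cemetery_split=(20, 20),
                               female_fraction_we=0.68, missing_rate=0.2,
                               seed=67)
        ds, truth = simulate_admixed_cohort(cfg)
        res = estimate_sex_bias(ds, TARGET, [SOURCE_NILOTIC, SOURCE_WE], REFS)
        assert res.P_ci[0] < 0.68 < res.P_ci[1]
        assert res.z_score > 0  # female-biased => more focal ancestry on X
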