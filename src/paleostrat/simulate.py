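"""Synthetic genotype cohorts with the structure the analyses assume.

The generator emulates a two-source admixed ancient cohort:

* Two allele-frequency-diverged source populations (a Nilotic-like and a
  West-Eurasian-like proxy) plus a set of outgroups, drifted from a shared
  ancestral frequency under the Balding-Nichols model on a small population
  tree so the outgroups are *differentially* related to the two sources
  (which is what makes the f4-based admixture system identifiable).
* An admixed target cohort with per-individual admixture proportion theta_i
  (West-Eurasian-like component) drawn from a truncated normal.
* Local-ancestry tract mosaics: ancestry along each haplotype is a Markov
  process with re-draw events at rate g per Morgan and stationary
  distribution theta_i, so ancestry covariance decays as exp(-g d) — the
  signal the dating module estimates — and the mean tract length of the
  West-Eurasian component is 1 / (g (1 - theta)).
* Sex-biased contributions: with female fraction P of the West-Eurasian
  component, F_i = 2 theta_i P and M_i = 2 theta_i (1 - P) are the female-
  and male-derived amounts (F + M = 2 theta), and the X chromosome is
  simulated with ancestry proportion (2 F + M) / 3 — the exact identity the
  sex-bias estimator inverts.
* Planted relative pairs of degrees 1-3 via gene-dropping: degree d is a
  chain of d meioses (with Poisson crossovers at 1 per Morgan) from the
  founder, each generation mated to a fresh individual of the same
  admixture proportion.
* Pseudo-haploid sampling (one random haplotype per site) and per-call
  Bernoulli missingness.

A truth sidecar records per-individual realized ancestry on autosomes and
X, the F/M split, admixture generations, tract-length summaries, pedigree
links, and cemetery labels, enabling closed-loop parameter-recovery tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data import X_CHROM, GenotypeDataset, write_eigenstrat

SOURCE_NILOTIC = "Source1"
SOURCE_WE = "Source2"
TARGET = "Target"


@dataclass
class SimulationConfig:
    """Study-condition parameters for the synthetic cohort.

    Defaults mirror the structure of the Christian-Period Kulubnarti cohort:
    ~60 admixed individuals averaging ~57% West-Eurasian-like ancestry
    (individual spread roughly 46-64%), ~68% of that component
    female-derived, admixture ~22 generations before sampling, and a 27/39
    split across two cemetery labels.
    """

    n_snps_per_chromosome: int = 1000
    n_chromosomes: int = 22          # autosomes; X is added separately
    chromosome_length: float = 1.5   # Morgans
    include_x: bool = True
    x_length: float = 1.8            # Morgans
    fst_source_divergence: float = 0.08
    n_outgroups: int = 5
    n_reference_individuals: int = 15
    n_target_individuals: int = 66
    ancestry_mean: float = 0.57      # West-Eurasian-like proportion
    ancestry_sd: float = 0.045
    female_fraction_we: float = 0.68
    admixture_generations: object = 22.2   # scalar or per-individual sequence
    missing_rate: float = 0.30
    pseudo_haploid: bool = True
    relative_plan: list = field(default_factory=list)  # [(degree, (cemA, cemB))]
    cemetery_split: tuple = (27, 39)  # (n_R, n_S)
    sampling_midpoint_ce: float = 810.0
    seed: int = 0

    def __post_init__(self):
        for name in ("fst_source_divergence", "ancestry_mean", "ancestry_sd",
                     "female_fraction_we"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name}={v} must lie in (0, 1)")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.seed is None:
            raise ValueError("a seed is mandatory (no silent nondeterminism)")
        if sum(self.cemetery_split) != self.n_target_individuals:
            raise ValueError("cemetery_split must sum to n_target_individuals")
        if 2 * len(self.relative_plan) > self.n_target_individuals:
            raise ValueError("relative_plan requests more individuals than "
                             "n_target_individuals")

    def generations_per_individual(self) -> np.ndarray:
        g = self.admixture_generations
        if np.ndim(g) == 0:
            return np.full(self.n_target_individuals, float(g))
        g = np.asarray(g, dtype=float)
        if g.size != self.n_target_individuals:
            raise ValueError("per-individual generations list has wrong length")
        return g


# -- source frequencies ----------------------------------------------------

def _balding_nichols(rng, p, fst):
    """Drift frequencies from ``p`` with Beta variance fst * p(1-p)."""
    if fst <= 0:
        return p.copy()
    shape = (1.0 - fst) / fst
    return rng.beta(np.maximum(p * shape, 1e-6),
                    np.maximum((1.0 - p) * shape, 1e-6))


def simulate_source_frequencies(config: SimulationConfig, n_snps=None,
                                rng=None) -> dict[str, np.ndarray]:
    """Per-SNP frequencies for the two sources and the outgroups.

    Ancestral frequencies are uniform on (0.05, 0.95). The two sources sit
    on opposite branches of a small tree, each accumulating half the
    nominal divergence, so their realized pairwise Hudson FST is close to
    ``fst_source_divergence``. Outgroups drift from the branch nodes with
    varying depths, making them differentially related to the sources.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if n_snps is None:
        n_snps = config.n_snps_per_chromosome * (
            config.n_chromosomes + (1 if config.include_x else 0))
    fst = config.fst_source_divergence
    anc = rng.uniform(0.05, 0.95, size=n_snps)
    # each side accumulates ~fst of drift variance so the realized pairwise
    # Hudson FST between the two sources comes out near the nominal value
    node_a = _balding_nichols(rng, anc, fst / 2)
    node_b = _balding_nichols(rng, anc, fst / 2)
    freqs = {
        "ancestral": anc,
        SOURCE_NILOTIC: _balding_nichols(rng, node_a, fst / 2),
        SOURCE_WE: _balding_nichols(rng, node_b, fst / 2),
    }
    if config.n_outgroups < 3:
        raise ValueError("need >=3 outgroups for a reference set")
    for j in range(config.n_outgroups):
        side = (node_a, node_b, anc)[j % 3]
        depth = fst / 2 * (1 + j // 3)
        freqs[f"Out{j + 1}"] = _balding_nichols(rng, side, depth)
    return freqs


# -- genetic map -----------------------------------------------------------

def _snp_table(config: SimulationConfig, rng) -> pd.DataFrame:
    chroms = [str(c + 1) for c in range(config.n_chromosomes)]
    lengths = [config.chromosome_length] * config.n_chromosomes
    if config.include_x:
        chroms.append(X_CHROM)
        lengths.append(config.x_length)
    rows = []
    for chrom, length in zip(chroms, lengths):
        g = np.sort(rng.uniform(0.0, length, size=config.n_snps_per_chromosome))
        phys = np.cumsum(rng.integers(100, 3000, size=g.size))
        for i, (gp, pp) in enumerate(zip(g, phys)):
            rows.append((f"snp_{chrom}_{i}", chrom, gp, int(pp), "A", "G"))
    return pd.DataFrame(
        rows, columns=["snp_id", "chromosome", "genetic_pos", "physical_pos",
                       "ref", "alt"])


# -- haplotype machinery ---------------------------------------------------

def _mosaic_states(rng, gpos, length, theta, g) -> np.ndarray:
    """Per-SNP ancestry states of one Markov-mosaic haplotype.

    Re-draw events occur at rate ``g`` per Morgan; at each event the state
    is redrawn Bernoulli(theta), giving stationary distribution theta and
    covariance theta(1-theta) exp(-g d).
    """
    n_events = rng.poisson(g * length)
    bounds = np.sort(rng.uniform(0.0, length, size=n_events))
    states = rng.random(n_events + 1) < theta
    seg = np.searchsorted(bounds, gpos, side="right")
    return states[seg]


def _draw_alleles(rng, states, p_we, p_nil) -> np.ndarray:
    p = np.where(states, p_we, p_nil)
    return (rng.random(p.size) < p).astype(np.uint8)


def _meiosis(rng, hap_pair, gpos, length):
    """One gamete from a pair of (alleles, states) haplotypes with Poisson
    crossovers at rate 1 per Morgan."""
    (a0, s0), (a1, s1) = hap_pair
    n_x = rng.poisson(length)
    bounds = np.sort(rng.uniform(0.0, length, size=n_x))
    phase = (np.searchsorted(bounds, gpos, side="right")
             + rng.integers(0, 2)) % 2
    take1 = phase.astype(bool)
    return (np.where(take1, a1, a0).astype(np.uint8),
            np.where(take1, s1, s0))


def _we_tract_summary(states, gpos, length):
    """Count and mean length of West-Eurasian segments, approximated from
    the per-SNP state sequence (adjacent same-state runs merged)."""
    if states.size == 0 or not states.any():
        return 0, float("nan")
    change = np.flatnonzero(np.diff(states.astype(int)) != 0)
    # boundaries at midpoints between flanking SNPs
    cuts = np.concatenate(([0.0], (gpos[change] + gpos[change + 1]) / 2, [length]))
    seg_states = states[np.concatenate(([0], change + 1))]
    seg_len = np.diff(cuts)
    we_len = seg_len[seg_states.astype(bool)]
    return int(we_len.size), float(we_len.mean())


# -- cohort simulation -----------------------------------------------------

def simulate_admixed_cohort(config: SimulationConfig, source_freqs=None):
    """Generate a :class:`GenotypeDataset` plus a truth sidecar dict.

    The dataset contains reference individuals for each source and outgroup
    population and ``n_target_individuals`` admixed targets with cemetery
    labels; the truth dict records the generating parameters per individual.
    """
    rng = np.random.default_rng(config.seed)
    snps = _snp_table(config, rng)
    if source_freqs is None:
        source_freqs = simulate_source_frequencies(config, n_snps=len(snps),
                                                   rng=rng)
    chrom_arr = snps["chromosome"].to_numpy()
    chroms = list(dict.fromkeys(chrom_arr))
    chrom_slices = {c: np.flatnonzero(chrom_arr == c) for c in chroms}
    chrom_len = {c: (config.x_length if c == X_CHROM
                     else config.chromosome_length) for c in chroms}
    p_we_all = source_freqs[SOURCE_WE]
    p_nil_all = source_freqs[SOURCE_NILOTIC]

    genotype_rows, ind_rows = [], []
    truth_individuals = []

    # --- reference individuals: genotypes drawn straight from pop freqs
    pop_names = [SOURCE_NILOTIC, SOURCE_WE] + [
        f"Out{j + 1}" for j in range(config.n_outgroups)]
    for pop in pop_names:
        p = source_freqs[pop]
        for i in range(config.n_reference_individuals):
            hap1 = (rng.random(p.size) < p).astype(np.uint8)
            hap2 = (rng.random(p.size) < p).astype(np.uint8)
            genotype_rows.append(_finalize_calls(rng, hap1, hap2, config))
            ind_rows.append((f"{pop}_{i}", "unknown", pop, "", np.nan, False))

    # --- target individuals
    n = config.n_target_individuals
    gens = config.generations_per_individual()
    theta = np.clip(rng.normal(config.ancestry_mean, config.ancestry_sd, n),
                    0.02, 0.98)
    P = config.female_fraction_we
    F = np.clip(2 * theta * P, 0.0, 1.0)
    M = np.clip(2 * theta - F, 0.0, 1.0)
    theta_x = np.clip((2 * F + M) / 3.0, 0.0, 1.0)
    sexes = np.where(rng.random(n) < 0.5, "male", "female")

    cemetery = _cemetery_labels(config, rng)
    pair_slots = _relative_slots(config)

    sim_cache = {}  # slot -> simulated haplotype bundle (for relative founders)

    def simulate_target_haplotypes(i):
        """Full (alleles, states) haplotype pairs per chromosome for target i."""
        haps = {}
        for c in chroms:
            idx = chrom_slices[c]
            L = chrom_len[c]
            th = theta_x[i] if c == X_CHROM else theta[i]
            n_hap = 1 if (c == X_CHROM and sexes[i] == "male") else 2
            pair = []
            for _ in range(n_hap):
                st = _mosaic_states(rng, snps["genetic_pos"].to_numpy()[idx],
                                    L, th, gens[i])
                al = _draw_alleles(rng, st, p_we_all[idx], p_nil_all[idx])
                pair.append((al, st))
            if n_hap == 1:
                pair.append(pair[0])  # hemizygous X duplicated for bookkeeping
            haps[c] = pair
        return haps

    relative_links = {i: [] for i in range(n)}
    for (degree, _cems), (slot_a, slot_b) in pair_slots:
        relative_links[slot_a].append((slot_b, degree))
        relative_links[slot_b].append((slot_a, degree))

    descend_from = {}  # slot_b -> (slot_a, degree)
    for (degree, _cems), (slot_a, slot_b) in pair_slots:
        descend_from[slot_b] = (slot_a, degree)

    for i in range(n):
        if i in descend_from:
            founder, degree = descend_from[i]
            if founder not in sim_cache:
                sim_cache[founder] = simulate_target_haplotypes(founder)
            # keep the relative's parameters tied to the founder's
            theta[i] = theta[founder]
            theta_x[i] = theta_x[founder]
            F[i], M[i] = F[founder], M[founder]
            haps = _gene_drop(rng, sim_cache[founder], degree, chroms,
                              chrom_slices, chrom_len, snps, theta[i],
                              theta_x[i], gens[i], p_we_all, p_nil_all)
        else:
            if i not in sim_cache:
                sim_cache[i] = simulate_target_haplotypes(i)
            haps = sim_cache[i]

        geno = np.empty(len(snps), dtype=np.int8)
        realized_auto, realized_x = [], []
        tract_counts, tract_lens = 0, []
        for c in chroms:
            idx = chrom_slices[c]
            (a0, s0), (a1, s1) = haps[c]
            geno[idx] = _finalize_calls(rng, a0, a1, config, in_place=True)
            mean_state = (s0.astype(float) + s1.astype(float)) / 2
            if c == X_CHROM:
                realized_x.append(mean_state.mean())
            else:
                realized_auto.append(mean_state.mean())
                for st in (s0, s1):
                    cnt, ml = _we_tract_summary(
                        st, snps["genetic_pos"].to_numpy()[idx], chrom_len[c])
                    tract_counts += cnt
                    if np.isfinite(ml):
                        tract_lens.append((cnt, ml))
            haps[c] = ((a0, s0), (a1, s1))
        genotype_rows.append(geno)
        ind_rows.append((f"KUL_{i:03d}", sexes[i], TARGET, cemetery[i],
                         config.sampling_midpoint_ce, False))
        total_cnt = sum(c for c, _ in tract_lens)
        mean_tract = (sum(c * m for c, m in tract_lens) / total_cnt
                      if total_cnt else float("nan"))
        truth_individuals.append({
            "individual_id": f"KUL_{i:03d}",
            "theta_we": float(theta[i]),
            "true_autosomal_we": float(np.mean(realized_auto)),
            "true_x_we": float(np.mean(realized_x)) if realized_x else None,
            "true_F": float(F[i]),
            "true_M": float(M[i]),
            "generations": float(gens[i]),
            "cemetery": cemetery[i],
            "relatives": [(f"KUL_{j:03d}", d) for j, d in relative_links[i]],
            "n_we_tracts": tract_counts,
            "mean_we_tract_morgans": mean_tract,
        })

    individuals = pd.DataFrame(
        ind_rows, columns=["individual_id", "sex", "group", "cemetery",
                           "date_midpoint_ce", "exclude"])
    geno = np.vstack(genotype_rows)
    dataset = GenotypeDataset(
        geno, snps, individuals,
        ploidy="pseudohaploid" if config.pseudo_haploid else "diploid")
    truth = {
        "config": {k: (list(v) if isinstance(v, (tuple, list, np.ndarray))
                       else v)
                   for k, v in vars(config).items()},
        "individuals": truth_individuals,
        "female_fraction_we": config.female_fraction_we,
    }
    return dataset, truth


def _finalize_calls(rng, hap1, hap2, config, in_place=False) -> np.ndarray:
    """Collapse a haplotype pair to calls: pseudo-haploid sampling (one
    random haplotype per site, call 0/2) or diploid sum, then missingness."""
    if config.pseudo_haploid:
        pick = rng.random(hap1.size) < 0.5
        calls = np.where(pick, hap1, hap2).astype(np.int8) * 2
    else:
        calls = (hap1 + hap2).astype(np.int8)
    if config.missing_rate > 0:
        calls = calls.copy() if not in_place else calls
        calls[rng.random(calls.size) < config.missing_rate] = 9
    return calls


def _gene_drop(rng, founder_haps, degree, chroms, chrom_slices, chrom_len,
               snps, theta_i, theta_x_i, g_i, p_we, p_nil):
    """Chain ``degree`` meioses down from a founder, mating each generation
    with a fresh unrelated individual of the same admixture parameters."""
    gpos_all = snps["genetic_pos"].to_numpy()
    current = founder_haps
    for _ in range(degree):
        child = {}
        for c in chroms:
            idx = chrom_slices[c]
            gpos = gpos_all[idx]
            L = chrom_len[c]
            th = theta_x_i if c == X_CHROM else theta_i
            gamete = _meiosis(rng, current[c], gpos, L)
            mate_st = _mosaic_states(rng, gpos, L, th, g_i)
            mate_al = _draw_alleles(rng, mate_st, p_we[idx], p_nil[idx])
            child[c] = [gamete, (mate_al, mate_st)]
        current = child
    return current


def _cemetery_labels(config: SimulationConfig, rng) -> list[str]:
    """Cemetery labels honoring the relative plan, independent of genotype."""
    n = config.n_target_individuals
    labels = [None] * n
    for (degree, cems), (sa, sb) in _relative_slots(config):
        labels[sa], labels[sb] = cems
    n_r_left = config.cemetery_split[0] - sum(1 for l in labels if l == "R")
    n_s_left = config.cemetery_split[1] - sum(1 for l in labels if l == "S")
    if n_r_left < 0 or n_s_left < 0:
        raise ValueError("relative_plan cemetery labels exceed cemetery_split")
    pool = ["R"] * n_r_left + ["S"] * n_s_left
    rng.shuffle(pool)
    it = iter(pool)
    return [l if l is not None else next(it) for l in labels]


def _relative_slots(config: SimulationConfig):
    """Deterministic slot assignment: pair j occupies slots (2j, 2j+1)."""
    out = []
    for j, (degree, cems) in enumerate(config.relative_plan):
        if not 1 <= int(degree) <= 3:
            raise ValueError("relative degrees must be 1-3")
        out.append(((int(degree), tuple(cems)), (2 * j, 2 * j + 1)))
    return out


# -- file output -----------------------------------------------------------

def write_simulation(dataset: GenotypeDataset, truth: dict, out_prefix):
    """Write the EIGENSTRAT triple, the metadata TSV sidecar, and the truth
    JSON; returns the paths."""
    paths = list(write_eigenstrat(dataset, out_prefix))
    meta_path = str(out_prefix) + ".meta.tsv"
    dataset.individuals.to_csv(meta_path, sep="\t", index=False)
    truth_path = str(out_prefix) + ".truth.json"
    with open(truth_path, "w") as fh:
        json.dump(truth, fh, indent=1, default=float)
    return paths + [meta_path, truth_path]
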