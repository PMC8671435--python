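"""f-statistics for admixture inference on pseudo-haploid genotype data.

Implements block-jackknifed f4, the admixture-f3 test with the
finite-sample ("inbreed") correction, a leave-one-out per-individual f4
outlier scan, a multi-reference cladality f4 scan, and the Hudson FST
estimator. All statistics are ratio-of-sums across 5 cM jackknife blocks
(complete-case per statistic: any population with zero called slots at a
SNP drops that SNP for that statistic).

Sign conventions (asserted by the test-suite):

* ``f4(A, B; C, D)`` averages ``(pA - pB) * (pC - pD)``; it is antisymmetric
  in (A,B) and in (C,D) and invariant under a joint ref/alt allele flip.
* A *negative* admixture f3(T; R1, R2) indicates T's frequencies are
  intermediate between R1 and R2 — evidence of admixture.
* In the outlier scan, the reported Z is oriented so that *positive* Z
  means the individual carries an excess of ancestry related to the second
  ("West-Eurasian-like") proxy relative to the remaining pool.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import MISSING, GenotypeDataset, allele_frequencies
from .jackknife import assign_blocks, jackknife_from_sums


@dataclass
class FStatResult:
    """A jackknifed statistic: estimate, standard error, Z, block/SNP counts."""

    estimate: float
    std_error: float
    n_blocks: int
    n_snps: int
    label: str = ""

    @property
    def z_score(self) -> float:
        if self.std_error == 0:
            return 0.0 if self.estimate == 0 else float("inf") * np.sign(self.estimate)
        return self.estimate / self.std_error


def _resolve(dataset: GenotypeDataset, pop) -> np.ndarray:
    """A population is a group label or an explicit array of row indices."""
    if isinstance(pop, str):
        return dataset.group_indices(pop)
    return np.asarray(pop)


def _freqs(dataset, pops):
    out = []
    for pop in pops:
        f, s = allele_frequencies(dataset, indices=_resolve(dataset, pop))
        out.append((f, s))
    return out


def _jackknife_stat(terms, usable, blocks, label="") -> FStatResult:
    """Ratio-of-sums jackknife of per-SNP ``terms`` over ``blocks``.

    ``usable`` masks complete-case SNPs; block weights are usable SNP counts.
    """
    if not usable.any():
        raise ValueError("no usable SNPs for this statistic")
    n_blocks = blocks.max() + 1
    t = np.where(usable, terms, 0.0)
    num = np.bincount(blocks, weights=t, minlength=n_blocks)
    wgt = np.bincount(blocks, weights=usable.astype(float), minlength=n_blocks)
    est, se = jackknife_from_sums(num, wgt)
    return FStatResult(est, se, int((wgt > 0).sum()), int(usable.sum()), label)


# -- f4 -------------------------------------------------------------------

def f4(dataset: GenotypeDataset, a, b, c, d, blocks=None) -> FStatResult:
    """f4(A, B; C, D) = mean over SNPs of (pA - pB)(pC - pD).

    SNPs where any of the four populations has no called genotype are
    dropped (complete cases). SE by weighted block jackknife.
    """
    if blocks is None:
        blocks = assign_blocks(dataset.snps)
    (fa, sa), (fb, sb), (fc, sc), (fd, sd) = _freqs(dataset, [a, b, c, d])
    usable = (sa > 0) & (sb > 0) & (sc > 0) & (sd > 0)
    terms = (fa - fb) * (fc - fd)
    return _jackknife_stat(terms, usable, blocks, label="f4")


# -- f3 admixture test ----------------------------------------------------

def f3_admixture_test(dataset: GenotypeDataset, target, ref1, ref2,
                      blocks=None, inbreed_correction: bool = True,
                      ) -> FStatResult:
    """Admixture f3(T; R1, R2) with the finite-sample target correction.

    Per SNP the raw term is ``(pT - p1)(pT - p2)``; with the correction on
    (the 'inbreed'-style unbiased estimator appropriate to pseudo-haploid
    allele draws) the target's sampling variance ``hT / nT`` is subtracted,
    where ``hT = pT (1 - pT) * nT / (nT - 1)`` and ``nT`` counts called
    allele slots. A significantly negative result is evidence that the
    target is admixed between populations related to R1 and R2.
    """
    if blocks is None:
        blocks = assign_blocks(dataset.snps)
    if inbreed_correction and _resolve(dataset, target).size < 2:
        raise ValueError("inbreed correction requires >=2 target individuals "
                         "(unbiased heterozygosity needs two draws)")
    (ft, st), (f1, s1), (f2, s2) = _freqs(dataset, [target, ref1, ref2])
    usable = (st > 0) & (s1 > 0) & (s2 > 0)
    if inbreed_correction:
        usable &= st > 1
    terms = (ft - f1) * (ft - f2)
    if inbreed_correction:
        with np.errstate(invalid="ignore", divide="ignore"):
            h = ft * (1 - ft) * st / np.maximum(st - 1, 1)
            terms = terms - h / np.maximum(st, 1)
    return _jackknife_stat(terms, usable, blocks, label="f3")


# -- leave-one-out outlier scan -------------------------------------------

def f4_outlier_scan(dataset: GenotypeDataset, nilotic_proxy, we_proxy,
                    pool, z_threshold: float = 5.0, blocks=None):
    """Per-individual ancestry-outlier scan.

    For each individual i in the pool, computes
    ``f4(WE_proxy, Nilotic_proxy; i, pool-without-i)`` so that a positive Z
    marks an excess of West-Eurasian-related ancestry in i relative to the
    rest of the pool, and a negative Z an excess of Nilotic-related
    ancestry. Individuals with |Z| above ``z_threshold`` are flagged.

    Returns a list of dicts with individual_id, the FStatResult, the flag,
    and a ``scorable`` field (False when the individual has no usable SNPs).
    """
    if blocks is None:
        blocks = assign_blocks(dataset.snps)
    pool_idx = _resolve(dataset, pool)
    if pool_idx.size < 3:
        raise ValueError("outlier scan needs a pool of >=3 individuals")
    (fn, sn), (fw, sw) = _freqs(dataset, [nilotic_proxy, we_proxy])
    geno = dataset.genotypes[pool_idx]
    called = geno != MISSING
    if dataset.ploidy == "pseudohaploid":
        alt = (geno == 2).astype(float)
        slot = called.astype(float)
    else:
        alt = np.where(called, geno, 0) / 2.0
        slot = called.astype(float)
    pool_alt = alt.sum(axis=0)
    pool_slot = slot.sum(axis=0)

    results = []
    ids = dataset.individuals["individual_id"].to_numpy()
    for row, gidx in enumerate(pool_idx):
        ind_slot = slot[row]
        rest_slot = pool_slot - ind_slot
        usable = (sn > 0) & (sw > 0) & (ind_slot > 0) & (rest_slot > 0)
        if not usable.any():
            results.append({"individual_id": ids[gidx], "result": None,
                            "scorable": False, "outlier": False})
            continue
        with np.errstate(invalid="ignore", divide="ignore"):
            p_ind = alt[row] / np.maximum(ind_slot, 1)
            p_rest = (pool_alt - alt[row]) / np.maximum(rest_slot, 1)
        terms = (fw - fn) * (p_ind - p_rest)
        res = _jackknife_stat(terms, usable, blocks, label="f4_loo")
        results.append({
            "individual_id": ids[gidx], "result": res, "scorable": True,
            "outlier": abs(res.z_score) > z_threshold,
        })
    return results


# -- cladality f4 scan -----------------------------------------------------

def clade_f4_scan(dataset: GenotypeDataset, base_pop, test_pops,
                  group_a, group_b, blocks=None, alpha: float = 0.05):
    """f4(base, test_t; groupA, groupB) for each test population.

    The Bonferroni-adjusted |Z| threshold for ``len(test_pops)`` tests at
    family level ``alpha`` is reported; the verdict is "consistent with a
    clade" iff no statistic exceeds it.
    """
    from scipy.stats import norm

    if blocks is None:
        blocks = assign_blocks(dataset.snps)
    if not test_pops:
        raise ValueError("need >=1 test population")
    stats = []
    ia, ib = _resolve(dataset, group_a), _resolve(dataset, group_b)
    same = np.array_equal(np.sort(ia), np.sort(ib))
    for t in test_pops:
        if same:
            # identical groups: the statistic is exactly zero by construction
            stats.append(FStatResult(0.0, 0.0, 0, 0, label=str(t)))
        else:
            res = f4(dataset, base_pop, t, group_a, group_b, blocks=blocks)
            res.label = str(t)
            stats.append(res)
    threshold = float(norm.ppf(1 - (alpha / 2) / len(test_pops)))
    consistent = all(abs(s.z_score) <= threshold for s in stats)
    return {"statistics": stats, "z_threshold": threshold,
            "consistent_with_clade": consistent}


# -- Hudson FST ------------------------------------------------------------

def fst_hudson(dataset: GenotypeDataset, pop_a, pop_b, blocks=None,
               ) -> FStatResult:
    """Hudson-style FST between two populations, jackknife SE.

    Ratio-of-averages estimator with the finite-sample correction on the
    within-population heterozygosities, using allele-slot counts (so
    pseudo-haploid sampling is handled consistently): per SNP,

        N = (p1 - p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1)
        D = p1(1-p2) + p2(1-p1)

    and FST = sum(N) / sum(D) over blocks.
    """
    if blocks is None:
        blocks = assign_blocks(dataset.snps)
    if _resolve(dataset, pop_a).size < 2 or _resolve(dataset, pop_b).size < 2:
        raise ValueError("Hudson FST needs >=2 individuals per population "
                         "for the finite-sample correction")
    (f1, s1), (f2, s2) = _freqs(dataset, [pop_a, pop_b])
    usable = (s1 > 1) & (s2 > 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        num = ((f1 - f2) ** 2
               - f1 * (1 - f1) / np.maximum(s1 - 1, 1)
               - f2 * (1 - f2) / np.maximum(s2 - 1, 1))
        den = f1 * (1 - f2) + f2 * (1 - f1)
    usable &= den > 0
    if not usable.any():
        raise ValueError("no usable polymorphic SNPs for FST")
    n_blocks = blocks.max() + 1
    nsum = np.bincount(blocks, weights=np.where(usable, num, 0.0),
                       minlength=n_blocks)
    dsum = np.bincount(blocks, weights=np.where(usable, den, 0.0),
                       minlength=n_blocks)
    # jackknife on the ratio of block sums, weighting by denominator mass
    keep = dsum > 0
    est, se = jackknife_from_sums(nsum[keep], dsum[keep])
    return FStatResult(est, se, int(keep.sum()), int(usable.sum()), "fst")
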