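"""Admixture dating from the decay of ancestry covariance along the genome.

After a single admixture pulse g generations ago, recombination breaks
ancestry blocks at rate g per Morgan, so the covariance of local ancestry
between two sites d Morgans apart decays as exp(-g d). With a pair of
reference populations standing in for the two ancestry components, each
SNP carries a weight w_s = p_ref1,s - p_ref2,s and a per-individual signal
x_s = genotype_s/2 - (p_ref1,s + p_ref2,s)/2; the weighted covariance

    C(d) = sum_pairs x_i x_j w_i w_j / sum_pairs w_i^2 w_j^2

(pairs on the same chromosome, binned by genetic distance) then decays as
A exp(-g d) + c, and the fitted decay rate per Morgan IS the point estimate
of generations since admixture. An affine offset c absorbs baseline
covariance from population structure. Standard errors come from a
leave-one-chromosome-out jackknife; generations convert to years with a
28-year generation time and to a calendar interval from the sampling
midpoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.optimize import curve_fit

from .data import MISSING, GenotypeDataset, allele_frequencies
from .fstats import _resolve

DEFAULT_GENERATION_TIME = 28.0  # years


@dataclass
class DecayCurve:
    """Binned ancestry covariance by genetic distance, plus fit results."""

    bin_centers: np.ndarray       # Morgans
    covariance: np.ndarray
    pair_weight: np.ndarray       # per-bin sum of w_i^2 w_j^2
    binsize: float
    maxdis: float
    amplitude: float | None = None
    decay_rate: float | None = None   # per Morgan = generations
    offset: float | None = None
    fit_start: float | None = None
    per_chromosome: dict = field(default_factory=dict, repr=False)


@dataclass
class DateEstimate:
    """Admixture date in generations with jackknife SE and conversions."""

    generations: float
    std_error: float
    generation_time: float = DEFAULT_GENERATION_TIME
    sampling_midpoint_ce: float | None = None
    valid_z_threshold: float = 2.8
    label: str = ""

    @property
    def z_score(self) -> float:
        return self.generations / self.std_error if self.std_error > 0 else np.inf

    @property
    def valid(self) -> bool:
        return self.z_score >= self.valid_z_threshold

    @property
    def years_before_sampling(self) -> float:
        return self.generations * self.generation_time

    @property
    def years_se(self) -> float:
        return self.std_error * self.generation_time

    def years_ci(self, level: float = 0.95) -> tuple[float, float]:
        q = stats.norm.ppf(0.5 + level / 2)
        return (self.years_before_sampling - q * self.years_se,
                self.years_before_sampling + q * self.years_se)

    def calendar_interval(self, level: float = 0.95) -> tuple[float, float]:
        """(early, late) calendar years CE; BCE is negative."""
        if self.sampling_midpoint_ce is None:
            raise ValueError("no sampling midpoint set")
        lo, hi = self.years_ci(level)
        return (self.sampling_midpoint_ce - hi, self.sampling_midpoint_ce - lo)

    def report(self) -> dict:
        """Rounded reporting values (years to nearest 10, calendar years to
        integers); raw values stay on the dataclass."""
        out = {
            "label": self.label,
            "generations": self.generations,
            "se_generations": self.std_error,
            "z": self.z_score,
            "valid": self.valid,
            "years": round(self.years_before_sampling, -1),
            "years_se": round(self.years_se, -1),
            "years_ci95": [round(v, -1) for v in self.years_ci()],
        }
        if self.sampling_midpoint_ce is not None:
            out["calendar_ci95_ce"] = [round(v) for v in
                                       self.calendar_interval()]
        return out


def _signal_and_weight(dataset, subject_indices, ref1, ref2):
    f1, s1 = allele_frequencies(dataset, indices=_resolve(dataset, ref1))
    f2, s2 = allele_frequencies(dataset, indices=_resolve(dataset, ref2))
    ok = (s1 > 0) & (s2 > 0)
    w = np.where(ok, f1 - f2, 0.0)
    geno = dataset.genotypes[np.asarray(subject_indices)]
    called = geno != MISSING
    x = np.where(called, geno / 2.0 - (f1 + f2) / 2.0, 0.0)
    x[:, ~ok] = 0.0
    return x, w, ok


def ancestry_covariance(dataset: GenotypeDataset, subjects, ref1, ref2,
                        binsize: float = 0.001, maxdis: float = 1.0,
                        ) -> DecayCurve:
    """Weighted ancestry covariance binned by genetic distance.

    ``subjects`` is a group label or index array; with several subjects the
    per-pair products are summed over individuals. SNPs where either
    reference is entirely missing are dropped; missing subject genotypes
    contribute zero (this shrinks the amplitude but not the decay rate,
    because missingness is independent of map distance). Per-chromosome bin
    sums are retained for the leave-one-chromosome-out jackknife.
    """
    subject_idx = _resolve(dataset, subjects)
    x, w, ok = _signal_and_weight(dataset, subject_idx, ref1, ref2)
    if not (ok & (w != 0)).any():
        raise ValueError("no polymorphic weighted SNPs between the references")
    chrom = dataset.snps["chromosome"].astype(str).to_numpy()
    gpos = dataset.snps["genetic_pos"].to_numpy(dtype=float)
    n_bins = int(np.ceil(maxdis / binsize))
    per_chrom = {}
    for c in dict.fromkeys(chrom):
        idx = np.flatnonzero((chrom == c) & ok)
        if idx.size < 2:
            continue
        g = gpos[idx]
        wc = w[idx]
        xc = x[:, idx]
        cross = xc.T @ xc              # sum over subjects of x_i x_j
        num_pair = cross * np.outer(wc, wc)
        den_pair = len(subject_idx) * np.outer(wc ** 2, wc ** 2)
        dist = np.abs(g[:, None] - g[None, :])
        iu = np.triu_indices(idx.size, k=1)
        bins = (dist[iu] / binsize).astype(int)
        keep = bins < n_bins
        num = np.bincount(bins[keep], weights=num_pair[iu][keep],
                          minlength=n_bins)
        den = np.bincount(bins[keep], weights=den_pair[iu][keep],
                          minlength=n_bins)
        per_chrom[c] = (num, den)
    if not per_chrom:
        raise ValueError("no chromosome with >=2 usable SNPs")
    num = sum(v[0] for v in per_chrom.values())
    den = sum(v[1] for v in per_chrom.values())
    centers = (np.arange(n_bins) + 0.5) * binsize
    nonzero = den > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = np.where(nonzero, num / np.maximum(den, 1e-300), np.nan)
    return DecayCurve(bin_centers=centers[nonzero], covariance=cov[nonzero],
                      pair_weight=den[nonzero], binsize=binsize,
                      maxdis=maxdis, per_chromosome=per_chrom)


def fit_decay(curve: DecayCurve, start_distance: float = 0.0045,
              ) -> tuple[float, float, float]:
    """Weighted least-squares fit of C(d) = A exp(-lambda d) + c.

    The fit window [start_distance, maxdis] skips the shortest bins, where
    background LD unrelated to admixture dominates. Returns (A, lambda, c);
    lambda per Morgan equals generations since admixture.
    """
    mask = (curve.bin_centers >= start_distance) & np.isfinite(curve.covariance)
    d = curve.bin_centers[mask]
    y = curve.covariance[mask]
    wt = curve.pair_weight[mask]
    if d.size < 10:
        raise ValueError(f"only {d.size} usable bins in the fit window")
    # moment-based initialization
    a0 = max(y.max() - y.min(), 1e-6)
    lam0 = 1.0 / max(d.mean(), 1e-3)
    try:
        popt, _ = curve_fit(
            lambda dd, a, lam, c: a * np.exp(-lam * dd) + c,
            d, y, p0=(a0, lam0, np.median(y)),
            sigma=1.0 / np.sqrt(np.maximum(wt, 1e-300)),
            bounds=([0.0, 0.0, -np.inf], [np.inf, np.inf, np.inf]),
            maxfev=20000)
    except RuntimeError as exc:
        raise RuntimeError(f"decay fit did not converge: {exc}") from exc
    a, lam, c = (float(v) for v in popt)
    curve.amplitude, curve.decay_rate, curve.offset = a, lam, c
    curve.fit_start = start_distance
    return a, lam, c


def date_estimate(dataset: GenotypeDataset, subjects, ref1, ref2,
                  binsize: float = 0.001, maxdis: float = 1.0,
                  start_distance: float = 0.0045,
                  generation_time: float = DEFAULT_GENERATION_TIME,
                  sampling_midpoint_ce=None, label: str = "",
                  ) -> DateEstimate:
    """Admixture date for one subject set, SE by chromosome jackknife.

    A point estimate with z = g/SE below 2.8 is returned flagged invalid
    (callers typically drop such estimates rather than interpret them).
    """
    curve = ancestry_covariance(dataset, subjects, ref1, ref2,
                                binsize=binsize, maxdis=maxdis)
    chroms = list(curve.per_chromosome)
    if len(chroms) < 2:
        raise ValueError("chromosome jackknife needs >=2 chromosomes")
    _, g_full, _ = fit_decay(curve, start_distance)

    reps = []
    for drop in chroms:
        num = sum(v[0] for c, v in curve.per_chromosome.items() if c != drop)
        den = sum(v[1] for c, v in curve.per_chromosome.items() if c != drop)
        nonzero = den > 0
        centers = (np.arange(num.size) + 0.5) * curve.binsize
        sub = DecayCurve(centers[nonzero], num[nonzero] / den[nonzero],
                         den[nonzero], curve.binsize, curve.maxdis)
        try:
            _, lam, _ = fit_decay(sub, start_distance)
        except (RuntimeError, ValueError):
            lam = g_full
        reps.append(lam)
    reps = np.asarray(reps)
    n = reps.size
    se = float(np.sqrt((n - 1) / n * ((reps - reps.mean()) ** 2).sum()))
    if sampling_midpoint_ce is None:
        mids = dataset.individuals["date_midpoint_ce"]
        sub_idx = _resolve(dataset, subjects)
        vals = mids.iloc[np.asarray(sub_idx)].dropna()
        sampling_midpoint_ce = float(vals.mean()) if len(vals) else None
    return DateEstimate(float(g_full), se, generation_time,
                        sampling_midpoint_ce, label=str(label))


def pairwise_date_z(estimates, n_tests: int | None = None,
                    alpha: float = 0.05) -> dict:
    """All pairwise Z-scores for date differences with Bonferroni verdict.

    Z_ij = (g_i - g_j) / sqrt(SE_i^2 + SE_j^2); the two-sided normal
    threshold at alpha / n_tests flags significant pairs. Any flagged pair
    means the single-pulse model cannot explain all subjects — the
    "multiple waves" verdict.
    """
    ests = list(estimates)
    if len(ests) < 2:
        raise ValueError("need >=2 estimates")
    n = len(ests)
    if n_tests is None:
        n_tests = n * (n - 1) // 2
    g = np.array([e.generations for e in ests])
    s = np.array([e.std_error for e in ests])
    z = (g[:, None] - g[None, :]) / np.sqrt(s[:, None] ** 2 + s[None, :] ** 2)
    np.fill_diagonal(z, 0.0)
    threshold = float(stats.norm.ppf(1 - (alpha / 2) / n_tests))
    any_sig = bool((np.abs(z[np.triu_indices(n, k=1)]) > threshold).any())
    return {"z_matrix": z, "threshold": threshold, "n_tests": n_tests,
            "multiple_waves": any_sig,
            "labels": [e.label for e in ests]}
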