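"""Two-source admixture-proportion modeling from f4 systems.

A target population T is modeled as a mixture of k source populations with
weights summing to 1, constrained by its f4 relationships to a set of m
differentially related reference (outgroup) populations. With O_1 as the
base reference, the statistic vector for a population ``pop`` is

    v_j(pop) = f4(pop, O_1; O_j, O_1),  j = 2..m,

and under the admixture model v(T) = sum_i w_i v(S_i). The weights minimize
the covariance-weighted quadratic form of the residual, with the full
(k+1)(m-1)-dimensional jackknife covariance of the statistics estimated
from delete-one-block replicates. The residual chi-square with
dof = (m-1) - (k-1) gives the model-fit p-value. Weight standard errors
come from delete-one-block refits.

The same machinery yields a cladality (rank-0) test for two groups — are
their f4 vectors equal relative to the references — and, run separately on
the autosomes and the X chromosome, the sex-bias decomposition: with A and
X the West-Eurasian-like proportions on autosomes and X chromosome,
F = 3X - 2A and M = 4A - 3X are the female- and male-derived amounts and
P = F / (F + M) = (3X - 2A) / (2A) is the female fraction. The Z-score is
oriented so that positive Z means more of the focal ancestry on the X
chromosome, i.e. female-biased gene flow.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .data import GenotypeDataset, allele_frequencies, partition_compartments
from .fstats import _resolve
from .jackknife import assign_blocks, jackknife_cov, jackknife_se_loo

logger = logging.getLogger(__name__)


@dataclass
class F4System:
    """The f4 statistics constraining an admixture fit.

    ``y`` is the target's statistic vector (length m-1), ``design`` the
    (m-1) x k matrix of source vectors, ``cov`` the full jackknife
    covariance of the stacked (k+1)(m-1) statistics (target first), and
    ``block_num`` / ``block_wgt`` the per-block sums that delete-one
    replicates are rebuilt from.
    """

    y: np.ndarray
    design: np.ndarray
    cov: np.ndarray
    block_num: np.ndarray
    block_wgt: np.ndarray
    n_sources: int
    n_references: int
    source_names: list
    n_snps: int


@dataclass
class AdmixtureFit:
    weights: np.ndarray
    std_errors: np.ndarray
    chi_square: float
    dof: int
    p_value: float
    source_names: list = field(default_factory=list)
    n_snps: int = 0


def build_f4_system(dataset: GenotypeDataset, target, sources, references,
                    blocks=None) -> F4System:
    """Assemble the f4 statistic vector, design matrix and covariance.

    Requires k >= 1 sources and m >= k + 1 references; SNPs where any
    involved population is entirely missing are dropped for all statistics
    (complete cases, 'allsnps: NO' behavior).
    """
    k, m = len(sources), len(references)
    if k < 1:
        raise ValueError("need at least one source")
    if m <= k:
        raise ValueError(f"under-identified system: {m} references for {k} "
                         "sources (need m >= k + 1)")
    if blocks is None:
        blocks = assign_blocks(dataset.snps)
    pops = [target] + list(sources) + list(references)
    freqs, slots = zip(*(allele_frequencies(dataset, indices=_resolve(dataset, p))
                         for p in pops))
    usable = np.logical_and.reduce([s > 0 for s in slots])
    if not usable.any():
        raise ValueError("no SNPs usable across all populations")

    f_t = freqs[0]
    f_s = freqs[1:1 + k]
    f_r = freqs[1 + k:]
    base = f_r[0]
    d = (k + 1) * (m - 1)
    n_blocks = blocks.max() + 1
    terms = np.empty((d, len(usable)))
    row = 0
    for fp in (f_t, *f_s):
        for j in range(1, m):
            terms[row] = (fp - base) * (f_r[j] - base)
            row += 1
    t_mask = np.where(usable, 1.0, 0.0)
    block_wgt = np.bincount(blocks, weights=t_mask, minlength=n_blocks)
    block_num = np.vstack([
        np.bincount(blocks, weights=np.where(usable, t, 0.0),
                    minlength=n_blocks)
        for t in terms]).T  # (n_blocks, d)
    keep = block_wgt > 0
    theta, cov = jackknife_cov(block_num[keep],
                               np.tile(block_wgt[keep, None], (1, d)))
    return F4System(
        y=theta[:m - 1],
        design=theta[m - 1:].reshape(k, m - 1).T,
        cov=cov,
        block_num=block_num[keep],
        block_wgt=block_wgt[keep],
        n_sources=k,
        n_references=m,
        source_names=[str(s) for s in sources],
        n_snps=int(usable.sum()),
    )


def _solve_weights(y, X, omega):
    """Constrained GLS: minimize (y - Xw)' omega (y - Xw) s.t. sum(w) = 1."""
    k = X.shape[1]
    A = X.T @ omega @ X
    b = X.T @ omega @ y
    ones = np.ones(k)
    kkt = np.zeros((k + 1, k + 1))
    kkt[:k, :k] = A
    kkt[:k, k] = ones
    kkt[k, :k] = ones
    rhs = np.concatenate([b, [1.0]])
    sol = np.linalg.solve(kkt, rhs)
    return sol[:k]


def _residual_precision(cov, w, m):
    """Inverse covariance of the residual r = y - Xw for given weights."""
    k = w.size
    L = np.zeros((m - 1, (k + 1) * (m - 1)))
    L[:, :m - 1] = np.eye(m - 1)
    for i in range(k):
        L[:, (i + 1) * (m - 1):(i + 2) * (m - 1)] = -w[i] * np.eye(m - 1)
    c_r = L @ cov @ L.T
    try:
        return np.linalg.inv(c_r)
    except np.linalg.LinAlgError:
        ridge = 1e-9 * np.trace(c_r) / c_r.shape[0]
        logger.warning("singular residual covariance; ridge %.3e applied", ridge)
        return np.linalg.inv(c_r + ridge * np.eye(c_r.shape[0]))


def _fit_weights_full(y, X, cov, m, w0):
    """Minimize q(w) = r(w)' C_r(w)^{-1} r(w) with the weight-dependent
    residual covariance kept inside the objective.

    Keeping C_r(w) inside (rather than iterating a fixed-precision GLS)
    makes the estimator consistent under sampling noise in the source
    statistics — a fixed-design GLS is attenuated toward equal weights
    when the reference/source sample sizes are small.
    """
    from scipy.optimize import minimize

    k = X.shape[1]

    def objective(t):
        w = np.append(t, 1.0 - t.sum())
        omega = _residual_precision(cov, w, m)
        r = y - X @ w
        return r @ omega @ r

    res = minimize(objective, w0[:-1], method="Nelder-Mead",
                   options={"xatol": 1e-8, "fatol": 1e-12, "maxiter": 2000})
    w = np.append(res.x, 1.0 - res.x.sum())
    return w, float(res.fun)


def fit_qpadm(system: F4System, n_gls_iterations: int = 3) -> AdmixtureFit:
    """Fit admixture weights to an :class:`F4System`.

    Weights minimize the covariance-weighted residual quadratic form
    subject to summing to 1; the residual covariance (which depends on the
    weights through the source statistics) is kept inside the objective.
    The residual chi-square with dof = (m-1) - (k-1) gives the model
    p-value; standard errors come from delete-one-block refits.
    """
    k, m = system.n_sources, system.n_references
    # iterated GLS gives a cheap, good starting point
    w = np.full(k, 1.0 / k)
    for _ in range(n_gls_iterations):
        omega = _residual_precision(system.cov, w, m)
        w = _solve_weights(system.y, system.design, omega)
    w, chi2 = _fit_weights_full(system.y, system.design, system.cov, m, w)
    dof = (m - 1) - (k - 1)
    p = float(stats.chi2.sf(chi2, dof))

    # delete-one-block refits for weight SEs
    tot_num = system.block_num.sum(axis=0)
    tot_wgt = system.block_wgt.sum()
    reps = []
    for b in range(system.block_num.shape[0]):
        vb = (tot_num - system.block_num[b]) / (tot_wgt - system.block_wgt[b])
        yb = vb[:m - 1]
        Xb = vb[m - 1:].reshape(k, m - 1).T
        wb, _ = _fit_weights_full(yb, Xb, system.cov, m, w)
        reps.append(wb)
    reps = np.array(reps)
    ses = np.empty(k)
    for i in range(k):
        ses[i] = jackknife_se_loo(w[i], reps[:, i], system.block_wgt)
    return AdmixtureFit(weights=w, std_errors=ses, chi_square=chi2, dof=dof,
                        p_value=p, source_names=system.source_names,
                        n_snps=system.n_snps)


def model_competition(dataset: GenotypeDataset, target, candidate_sources,
                      fixed_source, references, blocks=None,
                      alpha: float = 0.05):
    """Pairwise source competition among candidate proxy populations.

    For each ordered pair (keep, move) of candidates, refits the two-way
    model (fixed_source, keep) with ``move`` appended to the reference set.
    A model that fails (p < alpha) once its rival joins the references
    shares drift with the target through that rival; a model that survives
    identifies the genetically closer proxy. Returns one row per ordered
    pair with the fit and a ``survives`` flag.
    """
    rows = []
    for keep in candidate_sources:
        for move in candidate_sources:
            if move == keep:
                continue
            system = build_f4_system(
                dataset, target, [fixed_source, keep],
                list(references) + [move], blocks=blocks)
            fit = fit_qpadm(system)
            rows.append({"kept_source": str(keep), "moved_to_references":
                         str(move), "fit": fit, "p_value": fit.p_value,
                         "survives": fit.p_value > alpha})
    return rows


def qpwave_clade_test(dataset: GenotypeDataset, group_a, group_b, references,
                      blocks=None) -> dict:
    """Rank-0 cladality test: do two groups share all ancestry sources?

    Tests whether the two groups' f4 vectors relative to the references are
    equal, i.e. whether d_j = f4(groupA, groupB; O_j, O_1) = 0 for all j.
    Chi-square with dof = m - 1; p > 0.05 is reported as consistent with
    the groups forming a clade.
    """
    m = len(references)
    if m < 2:
        raise ValueError("need >=2 references")
    if blocks is None:
        blocks = assign_blocks(dataset.snps)
    ia, ib = _resolve(dataset, group_a), _resolve(dataset, group_b)
    if np.array_equal(np.sort(ia), np.sort(ib)):
        return {"chi_square": 0.0, "dof": m - 1, "p_value": 1.0,
                "consistent_with_clade": True, "n_snps": 0}
    pops = [ia, ib] + list(references)
    freqs, slots = zip(*(allele_frequencies(dataset, indices=_resolve(dataset, p))
                         for p in pops))
    usable = np.logical_and.reduce([s > 0 for s in slots])
    fa, fb = freqs[0], freqs[1]
    f_r = freqs[2:]
    base = f_r[0]
    n_blocks = blocks.max() + 1
    d = m - 1
    block_wgt = np.bincount(blocks, weights=np.where(usable, 1.0, 0.0),
                            minlength=n_blocks)
    block_num = np.vstack([
        np.bincount(blocks,
                    weights=np.where(usable, (fa - fb) * (f_r[j] - base), 0.0),
                    minlength=n_blocks)
        for j in range(1, m)]).T
    keep = block_wgt > 0
    theta, cov = jackknife_cov(block_num[keep],
                               np.tile(block_wgt[keep, None], (1, d)))
    try:
        prec = np.linalg.inv(cov)
    except np.linalg.LinAlgError:
        prec = np.linalg.inv(cov + 1e-12 * np.eye(d))
    chi2 = float(theta @ prec @ theta)
    p = float(stats.chi2.sf(chi2, d))
    return {"chi_square": chi2, "dof": d, "p_value": p,
            "consistent_with_clade": p > 0.05, "n_snps": int(usable.sum())}


# -- sex-biased admixture --------------------------------------------------

@dataclass
class SexBiasResult:
    """X-vs-autosome decomposition of a two-source admixture proportion."""

    p_auto: float
    se_auto: float
    p_x: float
    se_x: float
    z_score: float
    F: float
    M: float
    P: float
    P_se: float
    P_ci: tuple
    level: float = 0.95
    fit_auto: AdmixtureFit | None = None
    fit_x: AdmixtureFit | None = None
    poor_x_fit: bool = False


def sex_bias_decomposition(p_auto, se_auto, p_x, se_x,
                           level: float = 0.95) -> SexBiasResult:
    """Closed-form sex-bias decomposition from compartment proportions.

    With A and X the focal-ancestry proportions on autosomes and X
    chromosome: F = 3X - 2A, M = 4A - 3X (so F + M = 2A identically), and
    the female fraction P = F / (2A). Z = (X - A) / sqrt(se_A^2 + se_X^2),
    positive when the X chromosome carries more of the focal ancestry
    (female-biased gene flow). The CI for P is first-order (delta-method)
    error propagation from (se_A, se_X).
    """
    A, X = float(p_auto), float(p_x)
    F = 3 * X - 2 * A
    M = 4 * A - 3 * X
    z = (X - A) / np.hypot(se_auto, se_x)
    P = F / (2 * A)
    dP_dX = 3 / (2 * A)
    dP_dA = -3 * X / (2 * A ** 2)
    P_se = float(np.hypot(dP_dX * se_x, dP_dA * se_auto))
    q = stats.norm.ppf(0.5 + level / 2)
    ci = (P - q * P_se, P + q * P_se)
    return SexBiasResult(A, float(se_auto), X, float(se_x), float(z),
                         F, M, P, P_se, ci, level)


def estimate_sex_bias(dataset: GenotypeDataset, target, sources, references,
                      blocks=None, focal_source_index: int = 1,
                      level: float = 0.95,
                      x_fit_threshold: float = 0.05) -> SexBiasResult:
    """Fit the admixture model on autosomes and X and decompose sex bias.

    ``focal_source_index`` selects which source's weight is the reported
    proportion (default: the second source, the West-Eurasian-like proxy in
    the simulated cohorts). A poor X-compartment model fit sets the
    ``poor_x_fit`` flag rather than raising.
    """
    parts = partition_compartments(dataset)
    if parts["X"].n_snps == 0:
        raise ValueError("X compartment is empty")
    fits = {}
    for name, part in parts.items():
        system = build_f4_system(part, target, sources, references,
                                 blocks=assign_blocks(part.snps))
        fits[name] = fit_qpadm(system)
    fa, fx = fits["autosomes"], fits["X"]
    i = focal_source_index
    result = sex_bias_decomposition(fa.weights[i], fa.std_errors[i],
                                    fx.weights[i], fx.std_errors[i],
                                    level=level)
    result.fit_auto, result.fit_x = fa, fx
    result.poor_x_fit = fx.p_value < x_fit_threshold
    return result
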