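"""Projection PCA for low-coverage individuals.

Principal components are computed from (typically modern, low-missingness)
reference individuals; held-out (typically ancient, sparse) individuals are
then least-squares-projected onto the loadings restricted to their
non-missing SNPs. This uses every covered SNP of each projected individual
instead of the (much smaller) intersection across all individuals.

SNPs are centered by the reference mean genotype and scaled by
sqrt(p(1 - p)) with p the reference allele frequency — the variance
standardization under binomial sampling. No shrinkage correction of
projected coordinates is applied, so projected and fit coordinates are
comparable only qualitatively.
"""

from __future__ import annotations

from dataclasses import dataclass
import logging

import numpy as np

from .data import MISSING, GenotypeDataset

logger = logging.getLogger(__name__)


@dataclass
class PCAResult:
    snp_index: np.ndarray       # columns of the original dataset retained
    means: np.ndarray
    scales: np.ndarray
    loadings: np.ndarray        # (n_retained_snps, n_components), orthonormal
    eigenvalues: np.ndarray
    reference_coords: np.ndarray
    min_snps: int = 30000


def fit_pca(dataset: GenotypeDataset, reference_indices, n_components: int = 2,
            min_snps: int = 30000) -> PCAResult:
    """Principal components of the reference individuals.

    Missing reference genotypes are mean-imputed (references are expected
    to be near-complete); SNPs monomorphic in the reference are dropped
    with a logged count. Components are ordered by eigenvalue.
    """
    ref = dataset.genotypes[np.asarray(reference_indices)].astype(float)
    ref[ref == MISSING] = np.nan
    scale_geno = 2.0  # genotypes live on 0..2 regardless of ploidy flag
    means = np.nanmean(ref, axis=0)
    p = means / scale_geno
    poly = (p > 0) & (p < 1) & np.isfinite(p)
    n_dropped = int((~poly).sum())
    if n_dropped:
        logger.info("dropping %d monomorphic/uncovered SNPs from PCA", n_dropped)
    idx = np.flatnonzero(poly)
    scales = np.sqrt(p[idx] * (1 - p[idx]))
    z = (ref[:, idx] - means[idx]) / scales
    z = np.where(np.isfinite(z), z, 0.0)
    n_comp = min(n_components, min(z.shape) - 1)
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    loadings = vt[:n_comp].T
    eigenvalues = (s[:n_comp] ** 2) / (z.shape[0] - 1)
    coords = z @ loadings
    return PCAResult(idx, means[idx], scales, loadings, eigenvalues,
                     coords, min_snps)


def project(pca: PCAResult, genotypes) -> tuple[np.ndarray, bool]:
    """Least-squares projection of one individual onto the loadings.

    Only the individual's non-missing SNPs constrain the solution. Returns
    (coordinates, reliable); ``reliable`` is False when fewer than
    ``pca.min_snps`` called SNPs overlap the loading support.
    """
    g = np.asarray(genotypes, dtype=float)[pca.snp_index]
    called = g != MISSING
    n_called = int(called.sum())
    z = (g - pca.means) / pca.scales
    L = pca.loadings[called]
    coords, *_ = np.linalg.lstsq(L, z[called], rcond=None)
    return coords, n_called >= pca.min_snps


def project_all(dataset: GenotypeDataset, pca: PCAResult, indices=None):
    """Project many individuals; returns (coords array, reliable flags)."""
    if indices is None:
        indices = np.arange(dataset.n_individuals)
    coords, flags = [], []
    for i in np.asarray(indices):
        c, ok = project(pca, dataset.genotypes[i])
        coords.append(c)
        flags.append(ok)
    return np.vstack(coords), np.asarray(flags)
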