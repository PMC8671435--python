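"""Block-jackknife resampling over contiguous genomic blocks.

Allele-frequency statistics on linked SNPs are not independent across sites;
standard errors here come from a delete-one jackknife over contiguous blocks
of the genetic map (default 5 cM), which is robust to linkage on scales
shorter than the block. Blocks carry unequal SNP counts, so the weighted
("hole-size" / Busing-style) jackknife is used throughout; with equal
weights it reduces exactly to the classical delete-one jackknife.
"""

from __future__ import annotations

import numpy as np


def assign_blocks(snps, block_size_morgans: float = 0.05,
                  min_blocks: int = 4) -> np.ndarray:
    """Assign each SNP to a contiguous block of the genetic map.

    Blocks are ``block_size_morgans`` wide within a chromosome and never
    span chromosomes. If that yields fewer than ``min_blocks`` non-empty
    blocks (tiny simulated maps), falls back to one block per chromosome.

    Returns an integer block index per SNP (contiguous, 0-based).
    """
    chrom = snps["chromosome"].astype(str).to_numpy()
    gpos = snps["genetic_pos"].to_numpy(dtype=float)
    keys = []
    for c in dict.fromkeys(chrom):
        mask = chrom == c
        g = gpos[mask]
        rel = np.floor((g - g.min()) / block_size_morgans).astype(int)
        keys.extend((c, r) for r in rel)
    _, block = np.unique(np.array([f"{c}::{r}" for c, r in keys]),
                         return_inverse=True)
    # np.unique sorts lexically; remap to order of first appearance
    order = {}
    remapped = np.empty(len(block), dtype=int)
    for i, b in enumerate(block):
        if b not in order:
            order[b] = len(order)
        remapped[i] = order[b]
    if len(order) < min_blocks:
        _, remapped = np.unique(chrom, return_inverse=True)
    return remapped


def block_jackknife(block_stats, block_weights) -> tuple[float, float]:
    """Weighted delete-one jackknife estimate and standard error.

    Parameters
    ----------
    block_stats : per-block statistic values (block means).
    block_weights : per-block positive weights (e.g. usable SNP counts);
        the full-data estimate is the weighted mean of ``block_stats``
        (ratio-of-sums convention).

    With equal weights this reduces to the classical delete-one jackknife:
    ``SE^2 = (n-1)/n * sum((theta_{-i} - mean(theta_{-i}))^2)``.
    """
    x = np.asarray(block_stats, dtype=float)
    w = np.asarray(block_weights, dtype=float)
    keep = w > 0
    x, w = x[keep], w[keep]
    n = x.size
    if n < 2:
        raise ValueError("block jackknife needs >=2 blocks with positive weight")
    W = w.sum()
    total = (w * x).sum()
    theta = total / W
    theta_del = (total - w * x) / (W - w)  # delete-one estimates
    h = W / w                              # hole-size factors
    theta_J = n * theta - ((1.0 - w / W) * theta_del).sum()
    tau = h * theta - (h - 1.0) * theta_del
    var = ((tau - theta_J) ** 2 / (h - 1.0)).sum() / n
    return float(theta), float(np.sqrt(var))


def jackknife_from_sums(num_sums, weight_sums) -> tuple[float, float]:
    """Jackknife for a ratio-of-sums statistic given per-block numerator and
    weight (denominator) sums; convenience wrapper around
    :func:`block_jackknife`."""
    num = np.asarray(num_sums, dtype=float)
    w = np.asarray(weight_sums, dtype=float)
    keep = w > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        means = np.where(keep, num / np.maximum(w, 1e-300), 0.0)
    return block_jackknife(means[keep], w[keep])


def jackknife_se_loo(theta_full, loo_estimates, weights) -> float:
    """Weighted jackknife SE from delete-one estimates of any statistic.

    ``loo_estimates[j]`` is the statistic recomputed without block j and
    ``weights[j]`` the block's weight (hole size). Busing-style formula;
    equal weights reduce to the classical delete-one jackknife.
    """
    loo = np.asarray(loo_estimates, dtype=float)
    w = np.asarray(weights, dtype=float)
    keep = w > 0
    loo, w = loo[keep], w[keep]
    n = loo.size
    if n < 2:
        raise ValueError("need >=2 blocks")
    W = w.sum()
    h = W / w
    theta_J = n * theta_full - ((1.0 - w / W) * loo).sum()
    tau = h * theta_full - (h - 1.0) * loo
    var = ((tau - theta_J) ** 2 / (h - 1.0)).sum() / n
    return float(np.sqrt(var))


def jackknife_cov(num_sums, weight_sums) -> tuple[np.ndarray, np.ndarray]:
    """Delete-one-block jackknife mean and covariance of a statistic vector.

    Parameters
    ----------
    num_sums : (n_blocks, d) per-block numerator sums of the d statistics.
    weight_sums : (n_blocks, d) matching per-block weight sums.

    Each statistic is a ratio of sums over blocks. The covariance uses the
    classical delete-one formula with per-block effective weights equal to
    the mean weight share, which is exact for equal weights and a standard
    first-order approximation for mildly unequal ones.
    """
    num = np.asarray(num_sums, dtype=float)
    w = np.asarray(weight_sums, dtype=float)
    n_blocks, d = num.shape
    if n_blocks < 2:
        raise ValueError("need >=2 blocks")
    tot_num = num.sum(axis=0)
    tot_w = w.sum(axis=0)
    theta = tot_num / tot_w
    # delete-one estimates, one row per left-out block
    with np.errstate(invalid="ignore", divide="ignore"):
        theta_del = (tot_num - num) / (tot_w - w)
    theta_del = np.where(np.isfinite(theta_del), theta_del, theta)
    center = theta_del.mean(axis=0)
    dev = theta_del - center
    cov = (n_blocks - 1) / n_blocks * dev.T @ dev
    return theta, cov
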