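"""Pairwise-mismatch kinship classification and the cross-cemetery test.

For pseudo-haploid data the fraction of discordant calls between two
individuals over their overlapping SNPs (p0) scales with kinship: the
expected discordance is b (1 - k), where b is the unrelated baseline and k
the kinship coefficient (1/2 identical, 1/4 first degree, halving per
degree). Normalizing by the cohort median (assuming most pairs unrelated)
gives a coefficient classified into degree bands at the halving midpoints.

The cross-cemetery machinery: given pairs of known-degree relatives split
across two cemetery labels R and S, the probability that a randomly chosen
relative pair is cross-cemetery — if burial place were independent of
family structure — is p = nR nS / C(nR + nS, 2), where nR and nS count the
distinct individuals involved in pairs of that degree class. Observing c
cross-cemetery pairs out of T yields a one-sided binomial p-value
P(X <= c), X ~ Binomial(T, p): small values mean relatives were buried
together more often than chance predicts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data import MISSING, GenotypeDataset

DEGREE_BANDS = [
    # (upper bound on normalized coefficient, class label)
    (0.625, "identical"),
    (0.8125, 1),
    (0.90625, 2),
    (0.953125, 3),
    (np.inf, "unrelated"),
]


def pairwise_mismatch(dataset: GenotypeDataset,
                      min_overlap: int = 15000,
                      indices=None) -> pd.DataFrame:
    """Mismatch rate p0 for every pair of individuals.

    Returns one row per unordered pair with ``n_overlap`` (SNPs called in
    both) and ``p0`` (fraction discordant). Pairs under ``min_overlap`` are
    later classified "unknown".
    """
    if indices is None:
        indices = np.arange(dataset.n_individuals)
    indices = np.asarray(indices)
    geno = dataset.genotypes[indices]
    called = geno != MISSING
    ids = dataset.individuals["individual_id"].to_numpy()[indices]
    n = len(indices)
    g = np.where(called, geno, -1).astype(np.int8)
    # mismatch: both called and genotypes differ
    rows = []
    for i in range(n):
        both = called[i] & called[i + 1:]
        diff = (g[i] != g[i + 1:]) & both
        n_ov = both.sum(axis=1)
        n_mm = diff.sum(axis=1)
        for off, (ov, mm) in enumerate(zip(n_ov, n_mm)):
            j = i + 1 + off
            p0 = mm / ov if ov > 0 else np.nan
            rows.append((ids[i], ids[j], int(ov), p0))
    df = pd.DataFrame(rows, columns=["id1", "id2", "n_overlap", "p0"])
    df["low_overlap"] = df["n_overlap"] < min_overlap
    return df


def classify_degrees(pairs: pd.DataFrame, baseline: float | None = None,
                     min_pairs: int = 20) -> tuple[pd.DataFrame, float]:
    """Classify pairs into degree bands by median-normalized mismatch.

    The unrelated baseline defaults to the median p0 over all pairs with
    adequate overlap (valid when most pairs are unrelated); pass
    ``baseline`` to override. The normalized coefficient phi = p0/baseline
    is banded at the halving midpoints: < 0.625 identical, then degrees
    1, 2, 3, and >= 0.953125 unrelated. Low-overlap pairs are "unknown".
    """
    usable = pairs[~pairs["low_overlap"] & pairs["p0"].notna()]
    if baseline is None:
        if len(usable) < min_pairs:
            raise ValueError(
                f"only {len(usable)} usable pairs; supply an explicit "
                "baseline (median normalization needs a mostly-unrelated "
                "cohort)")
        baseline = float(usable["p0"].median())
    out = pairs.copy()
    out["phi"] = out["p0"] / baseline
    def band(row):
        if row.low_overlap or not np.isfinite(row.phi):
            return "unknown"
        for upper, label in DEGREE_BANDS:
            if row.phi < upper:
                return label
        return "unrelated"
    out["degree_class"] = [band(r) for r in out.itertuples()]
    return out, baseline


# -- cross-cemetery expectation / binomial test ---------------------------

@dataclass
class CrossCemeteryRow:
    degree_set: tuple
    within_r: int
    within_s: int
    cross: int
    total_pairs: int
    n_individuals_r: int
    n_individuals_s: int
    expected_probability: float
    expected_cross: float
    observed_over_expected: float
    binomial_p: float
    computable: bool = True


def expected_cross_probability(n_r: int, n_s: int) -> float:
    """P(two individuals drawn without replacement are cross-cemetery) =
    nR nS / C(nR + nS, 2)."""
    n = n_r + n_s
    if n < 2:
        return float("nan")
    return n_r * n_s / (n * (n - 1) / 2)


def cross_cemetery_row(n_r, n_s, total_pairs, observed_cross,
                       within_r=0, within_s=0,
                       degree_set=()) -> CrossCemeteryRow:
    """One test row from the summary counts themselves.

    ``binomial_p = P(X <= observed_cross)`` for X ~ Binomial(T, p): the
    probability of as few cross-cemetery relative pairs as observed.
    """
    n = n_r + n_s
    if n < 2:
        return CrossCemeteryRow(tuple(degree_set), within_r, within_s,
                                observed_cross, total_pairs, n_r, n_s,
                                float("nan"), float("nan"), float("nan"),
                                float("nan"), computable=False)
    p = expected_cross_probability(n_r, n_s)
    expected = total_pairs * p
    if p == 0:
        binom_p = 1.0 if observed_cross == 0 else 0.0
    else:
        binom_p = float(stats.binom.cdf(observed_cross, total_pairs, p))
    ratio = observed_cross / expected if expected > 0 else float("nan")
    return CrossCemeteryRow(tuple(degree_set), within_r, within_s,
                            observed_cross, total_pairs, n_r, n_s, p,
                            expected, ratio, binom_p)


def cross_cemetery_test(classified_pairs: pd.DataFrame,
                        cemetery_of: dict,
                        degree_sets=((1,), (2,), (3,), (1, 2), (1, 2, 3)),
                        ) -> list[CrossCemeteryRow]:
    """The full per-degree-class table (single degrees plus pooled sets).

    ``classified_pairs`` needs columns id1, id2, degree_class;
    ``cemetery_of`` maps individual id -> "R" or "S". Within each degree
    set, an individual is counted once per cemetery regardless of how many
    pairs it appears in.
    """
    rows = []
    for degree_set in degree_sets:
        sel = classified_pairs[
            classified_pairs["degree_class"].isin(degree_set)]
        inds = set(sel["id1"]) | set(sel["id2"])
        for i in inds:
            if i not in cemetery_of:
                raise KeyError(f"individual {i!r} lacks a cemetery label")
        n_r = sum(1 for i in inds if cemetery_of[i] == "R")
        n_s = sum(1 for i in inds if cemetery_of[i] == "S")
        w_r = w_s = cross = 0
        for rec in sel.itertuples():
            c1, c2 = cemetery_of[rec.id1], cemetery_of[rec.id2]
            if c1 != c2:
                cross += 1
            elif c1 == "R":
                w_r += 1
            else:
                w_s += 1
        rows.append(cross_cemetery_row(n_r, n_s, len(sel), cross,
                                       w_r, w_s, degree_set))
    return rows


def cross_cemetery_table(rows) -> pd.DataFrame:
    """Rows as a DataFrame shaped like a published relative-pair table."""
    return pd.DataFrame([{
        "degrees": "+".join(str(d) for d in r.degree_set),
        "within_R": r.within_r, "within_S": r.within_s, "cross": r.cross,
        "total_pairs": r.total_pairs, "n_R": r.n_individuals_r,
        "n_S": r.n_individuals_s,
        "expected_probability": r.expected_probability,
        "expected_cross": r.expected_cross,
        "observed_over_expected": r.observed_over_expected,
        "binomial_p": r.binomial_p,
    } for r in rows])


# -- ROH length-bin summary ------------------------------------------------

def roh_bin_summary(segments_cm) -> dict:
    """Sum user-provided ROH segment lengths (cM) into reporting bins:
    total > 4 cM, 4-8 cM, 8-20 cM, and > 20 cM."""
    seg = np.asarray(list(segments_cm), dtype=float)
    seg = seg[seg > 4]
    return {
        "n_segments_gt4": int(seg.size),
        "sum_gt4": float(seg.sum()),
        "sum_4_8": float(seg[(seg > 4) & (seg <= 8)].sum()),
        "sum_8_20": float(seg[(seg > 8) & (seg <= 20)].sum()),
        "sum_gt20": float(seg[seg > 20].sum()),
    }
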