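"""Uniparental (mtDNA / Y chromosome) haplogroup summary statistics.

Haplogroup origin classes (West-Eurasian-predominant vs African-predominant
present-day distribution) are an input annotation, not something computed
here — the module is purely statistical. It provides:

* an exact binomial confidence-interval inversion bounding the fraction of
  maternal ancestry from the focal region, given k of n individuals
  carrying haplogroups of that origin class;
* a Yates-corrected chi-square on a 2x2 haplogroup-origin-by-cemetery
  table;
* count summaries honoring exclusion flags for first-degree relatives
  sharing a matriline or patriline.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats


def binomial_acceptance(k: int, n: int, p: float, level: float = 0.95) -> bool:
    """Is ``k`` inside the exact central (equal-tail) acceptance region of
    Binomial(n, p)? Excluded iff either tail probability is below
    (1 - level)/2; exact tail sums, no normal approximation."""
    tail = (1.0 - level) / 2.0
    lower_tail = stats.binom.cdf(k, n, p)
    upper_tail = stats.binom.sf(k - 1, n, p)
    return bool(lower_tail >= tail and upper_tail >= tail)


def maternal_ancestry_range(n: int, k: int, level: float = 0.95,
                            grid_step: float = 0.01) -> tuple[float, float]:
    """Range of ancestry proportions consistent with observing k of n.

    Scans proportions p on a grid (default 1%) and keeps those whose exact
    central binomial acceptance region at ``level`` contains k; returns the
    (smallest, largest) accepted proportion as percentages. The observed
    haplogroup count thus inverts to an interval of compatible
    population-level maternal-ancestry fractions.
    """
    if not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    grid = np.round(np.arange(0.0, 1.0 + grid_step / 2, grid_step), 10)
    accepted = [p for p in grid if binomial_acceptance(k, n, p, level)]
    if not accepted:
        raise ValueError("no grid proportion accepts the observed count")
    return (100.0 * accepted[0], 100.0 * accepted[-1])


def yates_chi2(table) -> tuple[float, float]:
    """Yates continuity-corrected chi-square on a 2x2 table.

    statistic = sum over cells of (max(|O - E| - 0.5, 0))^2 / E with
    expectations from the margins; p from chi-square with 1 dof.
    """
    obs = np.asarray(table, dtype=float)
    if obs.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if (obs < 0).any():
        raise ValueError("counts must be non-negative")
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    total = obs.sum()
    if (row == 0).any() or (col == 0).any():
        raise ValueError("zero row/column margin")
    expected = np.outer(row, col) / total
    adj = np.maximum(np.abs(obs - expected) - 0.5, 0.0)
    statistic = float((adj ** 2 / expected).sum())
    p_value = float(stats.chi2.sf(statistic, 1))
    return statistic, p_value


def haplogroup_summary(table: pd.DataFrame, origin_column: str,
                       exclude_column: str | None = None) -> pd.DataFrame:
    """Per-cemetery, per-origin-class counts and frequencies.

    ``table`` needs columns ``cemetery`` and ``origin_column``; rows with a
    true ``exclude_column`` flag (first-degree relatives sharing the
    relevant uniparental lineage) are dropped before counting.
    """
    df = table
    if exclude_column is not None:
        df = df[~df[exclude_column].astype(bool)]
    df = df[df[origin_column].notna()]
    counts = (df.groupby(["cemetery", origin_column], observed=True)
              .size().rename("count").reset_index())
    totals = counts.groupby("cemetery")["count"].transform("sum")
    counts["frequency"] = counts["count"] / totals
    return counts


def origin_contingency(table: pd.DataFrame, origin_column: str,
                       exclude_column: str | None = None) -> pd.DataFrame:
    """2x2 (cemetery x origin class) contingency table for yates_chi2."""
    df = table
    if exclude_column is not None:
        df = df[~df[exclude_column].astype(bool)]
    df = df[df[origin_column].notna()]
    ct = pd.crosstab(df["cemetery"], df[origin_column])
    if ct.shape != (2, 2):
        raise ValueError(f"contingency table is {ct.shape}, expected (2, 2)")
    return ct
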