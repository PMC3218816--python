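"""Rank-based false discovery rate estimation for genome scans.

The scan reports, for each SNP at rank ``i`` (ascending combined-test
p-value) among ``N`` tests, the plain rank-based FDR estimate

    fdr_i = p_i * N / i

deliberately *not* monotonized: the estimate at rank 1 may exceed the
estimate at rank 2 when p_1 * N > p_2 * N / 2, which the Benjamini-Hochberg
step-up adjustment would forbid.  The step-up (cumulative-minimum) variant
is available as an optional second column.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["RankedResult", "rank_and_fdr", "count_below_threshold"]


@dataclass(frozen=True)
class RankedResult:
    """One SNP's position in the ranked scan."""

    snp_id: str
    p: float
    rank: int
    fdr: float
    n_tests: int


def rank_and_fdr(
    p_values,
    n_tests: int | None = None,
    snp_ids=None,
    step_up: bool = False,
) -> pd.DataFrame:
    """Rank p-values ascending and attach rank-based FDR estimates.

    Parameters
    ----------
    p_values : array-like of float in [0, 1]
        Combined-test significance levels, one per SNP.
    n_tests : int, optional
        Total number of tests performed.  May exceed ``len(p_values)`` when
        only the top of the scan is supplied (the estimate depends on the
        full test count).  Defaults to ``len(p_values)``.
    snp_ids : sequence of str, optional
        Identifiers; positional labels are generated when omitted.  Ties in
        p are broken by SNP id so ranks are deterministic.
    step_up : bool
        Also emit the Benjamini-Hochberg step-up (monotonized) estimate in
        a ``fdr_step_up`` column.

    Returns
    -------
    pandas.DataFrame with columns ``snp_id, p, rank, fdr`` (and optionally
    ``fdr_step_up``), sorted by rank.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if p.size == 0:
        cols = ["snp_id", "p", "rank", "fdr"] + (["fdr_step_up"] if step_up else [])
        return pd.DataFrame(columns=cols)
    if np.any(np.isnan(p)) or np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if n_tests is None:
        n_tests = m
    if n_tests < m:
        raise ValueError(f"n_tests={n_tests} is smaller than the number of p-values ({m})")
    if snp_ids is None:
        snp_ids = [f"snp{i + 1}" for i in range(m)]
    snp_ids = np.asarray(snp_ids, dtype=object)
    if snp_ids.size != m:
        raise ValueError("snp_ids length must match p_values")

    order = np.lexsort((snp_ids, p))
    ranks = np.arange(1, m + 1)
    p_sorted = p[order]
    fdr = p_sorted * n_tests / ranks
    out = pd.DataFrame(
        {"snp_id": snp_ids[order], "p": p_sorted, "rank": ranks, "fdr": fdr}
    )
    if step_up:
        # BH adjusted value: cumulative minimum from the bottom of the list.
        out["fdr_step_up"] = np.minimum.accumulate(fdr[::-1])[::-1].clip(max=1.0)
    return out.reset_index(drop=True)


def count_below_threshold(p_values, threshold: float) -> int:
    """Number of p-values strictly below ``threshold`` (threshold in (0, 1))."""
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    p = np.asarray(p_values, dtype=float)
    return int(np.count_nonzero(p < threshold))
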