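"""Ranking variants by their enrichment trend across sorting cycles.

The screen's ranking statistic is the slope of a simple (ordinary
least squares) linear regression of each variant's percentage read
abundance against the cycle index 0, 1, ..., C-1, where cycle 0 is the
unsorted input library.  Variants undetected in a cycle contribute an
abundance of exactly 0 (no pseudocounts — the statistic is a slope, not
a log fold change).  The same descending-slope order is used whether the
screen sorted for ON or OFF behavior, since enrichment of the desired
behavior is "up" either way.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .library_design import LibraryDesign
from .seq_pipeline import CountTable


def enrichment_trend(abundances) -> float:
    """OLS slope of abundance (%) against cycle index.

    ``sum((x - xbar)(y - ybar)) / sum((x - xbar)^2)`` with
    ``x = 0..C-1``.
    """
    y = np.asarray(abundances, dtype=float)
    if y.ndim != 1 or y.shape[0] < 2:
        raise ValueError("need at least 2 cycles to fit a trend")
    x = np.arange(y.shape[0], dtype=float)
    xc = x - x.mean()
    return float(xc @ (y - y.mean()) / (xc @ xc))


def _slopes(matrix: np.ndarray) -> np.ndarray:
    """Row-wise OLS slopes against cycle index (vectorized)."""
    n_cycles = matrix.shape[1]
    x = np.arange(n_cycles, dtype=float)
    xc = x - x.mean()
    centered = matrix - matrix.mean(axis=1, keepdims=True)
    return centered @ xc / (xc @ xc)


def rank_variants(abundance: pd.DataFrame) -> pd.DataFrame:
    """Rank all variants by descending enrichment trend.

    ``abundance`` is a variant x cycle percentage matrix with cycles as
    ordered columns.  Ties are broken by larger final-cycle abundance,
    then lexicographic variant id, making the ranking deterministic.

    Returns a DataFrame with columns ``variant_id``, ``slope``,
    ``cycles_detected``, ``final_abundance`` and ``rank`` (1 = largest
    slope), sorted by rank.
    """
    if abundance.shape[1] < 2:
        raise ValueError("need at least 2 cycles to rank variants")
    values = abundance.to_numpy(dtype=float)
    result = pd.DataFrame(
        {
            "variant_id": abundance.index.astype(str),
            "slope": _slopes(values),
            "cycles_detected": (values > 0).sum(axis=1),
            "final_abundance": values[:, -1],
        }
    )
    result = result.sort_values(
        ["slope", "final_abundance", "variant_id"],
        ascending=[False, False, True],
        kind="mergesort",
    ).reset_index(drop=True)
    result["rank"] = np.arange(1, len(result) + 1)
    return result


@dataclass
class CoverageReport:
    """Detected-variant counts per cycle and the dropout list."""

    detected_per_cycle: pd.Series
    dropouts: pd.DataFrame  # columns: variant_id, last_seen_cycle
    design_size: int | None = None

    @property
    def complete_in_cycle0(self) -> bool:
        if not self.design_size:
            return False
        return bool(self.detected_per_cycle.iloc[0] == self.design_size)


def coverage_report(
    counts: CountTable | pd.DataFrame, design: LibraryDesign | None = None
) -> CoverageReport:
    """Per-cycle detected-variant counts plus variants lost along the way.

    A variant is "detected" in a cycle if its count is >= 1.  The dropout
    list holds variants that were detected at some point but are absent
    from the final cycle, with the last cycle in which they were seen —
    the expected signature of stringent later sorting rounds.
    """
    frame = counts.counts if isinstance(counts, CountTable) else counts
    detected = frame > 0
    per_cycle = detected.sum(axis=0)
    ever = detected.any(axis=1)
    lost = ever & ~detected.iloc[:, -1]
    last_seen = [
        detected.columns[np.flatnonzero(detected.loc[v].to_numpy())[-1]]
        for v in frame.index[lost]
    ]
    dropouts = pd.DataFrame(
        {"variant_id": frame.index[lost].astype(str), "last_seen_cycle": last_seen}
    ).reset_index(drop=True)
    from .library_design import design_space_size

    size = design_space_size(design) if design is not None else None
    return CoverageReport(detected_per_cycle=per_cycle, dropouts=dropouts, design_size=size)
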