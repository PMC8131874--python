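"""Two-contrast protein ratio consistency: delta = phi / beta.

Two replicate contrasts of the same comparison (phi = test1/ref1,
beta = test2/ref2) agree when their ratio delta approaches 1; proteins with
|delta - 1| <= tolerance (default 0.1, boundary inclusive) are the retained
replicate-consistent candidates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class DeltaResult:
    """Per-protein consistency call plus a report of excluded inputs."""

    table: pd.DataFrame         # index protein id; columns phi, beta, delta, consistent
    tolerance: float
    excluded: pd.DataFrame      # invalid rows (non-positive / missing ratios)

    @property
    def consistent_ids(self) -> list:
        return list(self.table.index[self.table["consistent"]])

    @property
    def discrepant_ids(self) -> list:
        return list(self.table.index[~self.table["consistent"]])


def read_ratio_table(path) -> pd.DataFrame:
    """TSV with columns (id, phi, beta); '#' comments tolerated."""
    df = pd.read_csv(path, sep="\t", comment="#")
    df.columns = [c.lower() for c in df.columns]
    if not {"id", "phi", "beta"} <= set(df.columns):
        raise ValueError("ratio table needs columns id, phi, beta")
    return df.set_index("id")[["phi", "beta"]]


def compute_delta(table: pd.DataFrame) -> tuple[pd.Series, pd.DataFrame]:
    """delta = phi / beta, untransformed.

    Rows with non-positive, missing or non-finite ratios are excluded and
    returned in a report frame.
    """
    phi = pd.to_numeric(table["phi"], errors="coerce")
    beta = pd.to_numeric(table["beta"], errors="coerce")
    valid = np.isfinite(phi) & np.isfinite(beta) & (phi > 0) & (beta > 0)
    excluded = table.loc[~valid]
    delta = phi[valid] / beta[valid]
    return delta, excluded


def select_consistent(delta: pd.Series, tolerance: float = 0.1,
                      log_symmetric: bool = False) -> tuple[pd.Series, pd.Series]:
    """Partition by |delta - 1| <= tolerance (boundary inclusive).

    Note the asymmetry of the raw-scale rule: delta(phi, beta) = 1/delta(beta,
    phi), but |1/d - 1| != |d - 1| in general, so swapping the contrasts can
    change the call near the boundary.  ``log_symmetric`` switches to the
    swap-invariant rule |log2 delta| <= log2(1 + tolerance).
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be > 0")
    # tiny epsilon keeps the stated boundary (e.g. delta = 1.1) inclusive
    # despite binary floating point (1.1 - 1.0 > 0.1 by ~1e-16)
    eps = 1e-12
    if log_symmetric:
        mask = np.abs(np.log2(delta)) <= np.log2(1.0 + tolerance) + eps
    else:
        mask = (delta - 1.0).abs() <= tolerance + eps
    return delta[mask], delta[~mask]


def delta_analysis(table: pd.DataFrame, tolerance: float = 0.1,
                   log_symmetric: bool = False) -> DeltaResult:
    """Full delta pipeline: ratio validation, delta, consistency partition."""
    delta, excluded = compute_delta(table)
    consistent, _ = select_consistent(delta, tolerance, log_symmetric)
    out = table.loc[delta.index].copy()
    out["delta"] = delta
    out["consistent"] = out.index.isin(consistent.index)
    return DeltaResult(out, tolerance, excluded)
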