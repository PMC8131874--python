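"""Batch-robust small-RNA strategy: low-count filter, rpm, batch-wise fold
changes, reproducible-direction consensus and per-batch z-scores.

Designed for count matrices with a batch effect too strong for factor-based
correction: features are kept only when the test-vs-control fold change has
the same sign in every batch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diffcounts import CountMatrix, GROUP_TEST, GROUP_REF


def filter_low_counts(counts: CountMatrix, min_count: float = 50,
                      rule: str = "mean") -> tuple[CountMatrix, dict]:
    """Drop low-coverage features from raw counts (boundary inclusive).

    ``rule``: 'mean' keeps features with mean count across samples >= min_count,
    'total' uses the row sum, 'all-samples' requires every sample >= min_count.
    """
    df = counts.df
    if rule == "mean":
        keep = df.mean(axis=1) >= min_count
    elif rule == "total":
        keep = df.sum(axis=1) >= min_count
    elif rule == "all-samples":
        keep = (df >= min_count).all(axis=1)
    else:
        raise ValueError(f"unknown rule {rule!r}")
    if not keep.any():
        raise ValueError("low-count filter removed every feature")
    report = {"n_in": len(df), "n_kept": int(keep.sum()), "n_removed": int((~keep).sum()),
              "rule": rule, "min_count": min_count}
    out = CountMatrix(df.loc[keep], counts.groups, counts.batches)
    return out, report


def rpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Reads per million: count / column sum * 1e6."""
    colsum = counts.sum(axis=0).astype(float)
    if (colsum <= 0).any():
        raise ValueError("zero column sum")
    return counts.div(colsum, axis=1) * 1e6


@dataclass
class MirnaResult:
    """Per-feature batch-wise fold changes and the direction-consensus call."""

    table: pd.DataFrame         # log2FC_<batch>..., z_<batch>..., consensus, min_abs_z, retained
    batches: list[str]


def batchwise_consensus(rpm_matrix: pd.DataFrame, groups: dict[str, str],
                        batches: dict[str, str], pseudocount: float = 1.0) -> MirnaResult:
    """Per-batch log2 fold changes, sign consensus, and within-batch z-scores.

    Per batch: log2((mean rpm test + pc) / (mean rpm ref + pc)).  The
    consensus direction is +-1 only when every batch fold change shares one
    sign and none is exactly 0.  z-scores standardize each feature's fold
    change against all features within the batch.
    """
    samples = list(rpm_matrix.columns)
    batch_names = sorted({batches[s] for s in samples})
    fc = {}
    for b in batch_names:
        ee = [s for s in samples if batches[s] == b and groups[s] == GROUP_TEST]
        ctl = [s for s in samples if batches[s] == b and groups[s] == GROUP_REF]
        if not ee or not ctl:
            raise ValueError(f"batch {b!r} lacks a condition ({GROUP_TEST}: {len(ee)}, {GROUP_REF}: {len(ctl)})")
        fc[b] = np.log2((rpm_matrix[ee].mean(axis=1) + pseudocount)
                        / (rpm_matrix[ctl].mean(axis=1) + pseudocount))
    table = pd.DataFrame({f"log2FC_{b}": fc[b] for b in batch_names})
    signs = np.sign(table.to_numpy())
    all_pos = (signs > 0).all(axis=1)
    all_neg = (signs < 0).all(axis=1)
    consensus = np.where(all_pos, 1, np.where(all_neg, -1, 0))
    for b in batch_names:
        col = table[f"log2FC_{b}"]
        sd = col.std(ddof=0)
        if sd == 0:
            table[f"z_{b}"] = 0.0
        else:
            table[f"z_{b}"] = (col - col.mean()) / sd
    zcols = [f"z_{b}" for b in batch_names]
    table["consensus"] = consensus
    table["min_abs_z"] = table[zcols].abs().min(axis=1)
    table["retained"] = consensus != 0
    return MirnaResult(table, batch_names)


def mirna_pipeline(counts: CountMatrix, min_count: float = 50, rule: str = "mean",
                   pseudocount: float = 1.0) -> tuple[MirnaResult, dict]:
    """Filter -> rpm -> batch-wise direction consensus."""
    filtered, report = filter_low_counts(counts, min_count, rule)
    normalized = rpm(filtered.df)
    result = batchwise_consensus(normalized, filtered.groups, filtered.batches, pseudocount)
    report["n_retained"] = int(result.table["retained"].sum())
    return result, report
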