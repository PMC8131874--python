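"""Permutation association of a query bin/region set with feature region sets.

The randomization unit is the genome bin: each iteration resamples the query
bin count uniformly without replacement from the retained bin universe and
recomputes the overlap statistic against the fixed feature set.  An exact
(hypergeometric) computation is available for cross-checks and tiny universes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome import GenomeBins, RegionSet, region_bins
from .diffcounts import bh_fdr


@dataclass
class PermutationResult:
    label: str
    observed: int
    null_mean: float
    null_sd: float
    z: float                    # NaN when null sd is 0
    p_empirical: float
    alternative: str            # 'greater' | 'less'
    n_perm: int
    seed: int
    universe_size: int
    n_query_bins: int

    def to_dict(self) -> dict:
        return {
            "label": self.label, "observed": self.observed,
            "null_mean": self.null_mean, "null_sd": self.null_sd, "z": self.z,
            "p_empirical": self.p_empirical, "alternative": self.alternative,
            "n_perm": self.n_perm, "seed": self.seed,
            "universe_size": self.universe_size, "n_query_bins": self.n_query_bins,
        }


def _as_bins(obj, bins: GenomeBins) -> set[int]:
    if isinstance(obj, RegionSet):
        return region_bins(obj, bins)
    return {int(b) for b in obj}


def overlap_statistic(query, features, bins: GenomeBins) -> int:
    """Number of (deduplicated) query bins containing at least one feature region.

    ``query``/``features`` may be RegionSets or iterables of global bin indices.
    """
    qbins = _as_bins(query, bins)
    if not qbins:
        raise ValueError("empty query: overlap statistic undefined")
    fbins = _as_bins(features, bins)
    return len(qbins & fbins)


def permute_association(query, features, bins: GenomeBins,
                        n_perm: int = 100_000, seed: int = 0,
                        alternative: str = "greater") -> PermutationResult:
    """Empirical association p-value by uniform bin resampling.

    p = (b + 1) / (n_perm + 1) with b the number of null statistics at least
    as extreme as the observed one (add-one correction; p is never 0).
    Deterministic for a given seed.
    """
    if alternative not in ("greater", "less"):
        raise ValueError("alternative must be 'greater' or 'less'")
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} gives poor p-value resolution")
    qbins = np.array(sorted(_as_bins(query, bins)), dtype=np.int64)
    if len(qbins) == 0:
        raise ValueError("empty query: overlap statistic undefined")
    U = bins.n_bins
    nq = len(qbins)
    if nq > U:
        raise ValueError("query has more bins than the universe")
    fbins = _as_bins(features, bins)
    indicator = np.zeros(U, dtype=bool)
    if fbins:
        indicator[np.array(sorted(fbins), dtype=np.int64)] = True
    observed = int(indicator[qbins].sum())

    rng = np.random.default_rng(seed)
    null = np.empty(n_perm, dtype=np.int64)
    chunk = max(1, min(n_perm, int(2e7) // max(U, 1)))
    done = 0
    while done < n_perm:
        c = min(chunk, n_perm - done)
        keys = rng.random((c, U))
        picked = np.argpartition(keys, nq - 1, axis=1)[:, :nq]
        null[done:done + c] = indicator[picked].sum(axis=1)
        done += c
    null_mean = float(null.mean())
    null_sd = float(null.std(ddof=0))
    z = float((observed - null_mean) / null_sd) if null_sd > 0 else float("nan")
    if alternative == "greater":
        b = int((null >= observed).sum())
    else:
        b = int((null <= observed).sum())
    p = (b + 1) / (n_perm + 1)
    return PermutationResult(
        label=getattr(features, "label", "") or "",
        observed=observed, null_mean=null_mean, null_sd=null_sd, z=z,
        p_empirical=p, alternative=alternative, n_perm=n_perm, seed=seed,
        universe_size=U, n_query_bins=nq,
    )


def exact_association(query, features, bins: GenomeBins,
                      alternative: str = "greater") -> float:
    """Exact null tail probability of the bin-overlap statistic.

    Under uniform sampling of |query| distinct bins, the statistic is
    hypergeometric over (universe, feature bins, query bins).
    """
    qbins = _as_bins(query, bins)
    if not qbins:
        raise ValueError("empty query")
    fbins = _as_bins(features, bins)
    U, K, nq = bins.n_bins, len(fbins), len(qbins)
    observed = len(qbins & fbins)
    if alternative == "greater":
        return float(stats.hypergeom.sf(observed - 1, U, K, nq))
    return float(stats.hypergeom.cdf(observed, U, K, nq))


def associate_all(query, feature_sets: Sequence[RegionSet], bins: GenomeBins,
                  n_perm: int = 100_000, seed: int = 0,
                  alternative: str = "greater") -> pd.DataFrame:
    """One permutation test per feature set; per-set seeds derive from the master seed.

    Raw per-set p-values are the headline output; a BH-adjusted column is
    appended as a multiplicity note.
    """
    if not feature_sets:
        raise ValueError("need at least one feature set")
    rows = []
    for i, fs in enumerate(feature_sets):
        r = permute_association(query, fs, bins, n_perm=n_perm, seed=seed + i,
                                alternative=alternative)
        d = r.to_dict()
        d["label"] = fs.label or f"set{i}"
        rows.append(d)
    out = pd.DataFrame(rows)
    out["p_bh"] = bh_fdr(out["p_empirical"].to_numpy())
    return out
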