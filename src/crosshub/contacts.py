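"""Valid-pair parsing, contact binning, filtering, ICE balancing and compartments."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from .genome import ChromSizes, GenomeBins, ParseError, DEFAULT_EXCLUDE, make_bins

W_INTRA_DEFAULT = 100_000
W_INTER_DEFAULT = 1_000_000


@dataclass(frozen=True)
class ValidPair:
    """One Hi-C valid pair; positions 0-based internally (input dialect is 1-based)."""

    read_id: str
    chrom1: str
    pos1: int
    chrom2: str
    pos2: int
    strand1: str = "+"
    strand2: str = "+"


def parse_valid_pairs(path) -> Iterator[ValidPair]:
    """Stream a HiC-Pro-style valid-pairs TSV.

    Expects >=7 columns (readID, chr1, pos1, strand1, chr2, pos2, strand2);
    trailing columns are ignored.  1-based positions are converted to 0-based.
    """
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 7:
                raise ParseError(f"{path}:{lineno}: expected >=7 columns, got {len(f)}")
            try:
                pos1, pos2 = int(f[2]), int(f[5])
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-integer position") from None
            if pos1 < 1 or pos2 < 1:
                raise ParseError(f"{path}:{lineno}: positions must be >=1 (1-based dialect)")
            yield ValidPair(f[0], f[1], pos1 - 1, f[4], pos2 - 1, f[3], f[6])


def read_valid_pairs_frame(path, dedup: bool = False) -> pd.DataFrame:
    """Vectorized valid-pairs reader; same dialect as :func:`parse_valid_pairs`.

    Returns columns chrom1, pos1, chrom2, pos2 with 0-based positions.
    Duplicate lines are counted by default (deduplication is assumed done by
    the valid-pairs producer); ``dedup`` keeps the first line per read id.
    """
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        usecols=[0, 1, 2, 4, 5], names=["read_id", "chrom1", "pos1", "chrom2", "pos2"],
        dtype={"read_id": str, "chrom1": str, "pos1": np.int64, "chrom2": str, "pos2": np.int64},
    )
    if dedup:
        df = df.drop_duplicates(subset="read_id", keep="first")
    df = df.drop(columns="read_id")
    if (df["pos1"] < 1).any() or (df["pos2"] < 1).any():
        raise ParseError(f"{path}: positions must be >=1 (1-based dialect)")
    df["pos1"] -= 1
    df["pos2"] -= 1
    return df


@dataclass
class ContactTable:
    """Long-format binned contacts, one count column per sample.

    ``df`` is indexed by the canonical ordered bin pair (i <= j by global
    index); intra rows have both bins on one chromosome at ``w_intra``
    resolution, inter rows span chromosomes at ``w_inter`` resolution.
    """

    klass: str                       # "intra" | "inter"
    bins: GenomeBins
    df: pd.DataFrame                 # MultiIndex (bin1, bin2); int count columns
    groups: dict[str, str] = field(default_factory=dict)   # sample -> EE/CTL
    batches: dict[str, str] = field(default_factory=dict)  # sample -> batch label

    @property
    def bin_width(self) -> int:
        return self.bins.bin_width

    @property
    def samples(self) -> list[str]:
        return list(self.df.columns)

    def counts(self) -> np.ndarray:
        """features x samples integer count array."""
        return self.df.to_numpy()

    def pair_coords(self) -> pd.DataFrame:
        """chrom/start of both bins for every row (for reporting)."""
        b1 = self.df.index.get_level_values(0).to_numpy()
        b2 = self.df.index.get_level_values(1).to_numpy()
        rec1 = [self.bins.bin_record(i) for i in b1]
        rec2 = [self.bins.bin_record(i) for i in b2]
        return pd.DataFrame(
            {
                "chrom1": [r[0] for r in rec1], "start1": [r[1] for r in rec1],
                "chrom2": [r[0] for r in rec2], "start2": [r[1] for r in rec2],
            },
            index=self.df.index,
        )

    def write_tsv(self, path) -> None:
        out = self.pair_coords().join(self.df)
        with open(path, "w") as fh:
            fh.write(f"# class={self.klass} bin_width={self.bin_width}\n")
            fh.write("# groups=" + ",".join(f"{s}:{g}" for s, g in self.groups.items()) + "\n")
            fh.write("# batches=" + ",".join(f"{s}:{b}" for s, b in self.batches.items()) + "\n")
            out.to_csv(fh, sep="\t", index=False)


def _bin_pairs_frame(
    df: pd.DataFrame, bins_intra: GenomeBins, bins_inter: GenomeBins
) -> tuple[pd.DataFrame, pd.DataFrame, int]:
    """Core binning on a pairs frame -> (intra rows, inter rows, n dropped)."""
    known = set(bins_intra.chroms)
    ok = df["chrom1"].isin(known) & df["chrom2"].isin(known)
    # pairs whose positions exceed the stated chromosome length are invalid input
    dropped = int((~ok).sum())
    d = df.loc[ok]
    sizes = bins_intra.sizes
    lim1 = d["chrom1"].map({c: sizes[c] for c in known})
    lim2 = d["chrom2"].map({c: sizes[c] for c in known})
    bad = (d["pos1"] >= lim1) | (d["pos2"] >= lim2)
    if bad.any():
        raise ParseError(f"{int(bad.sum())} pair(s) with positions beyond chromosome end")
    same = (d["chrom1"] == d["chrom2"]).to_numpy()

    def _tab(sub: pd.DataFrame, gbins: GenomeBins) -> pd.DataFrame:
        if len(sub) == 0:
            return pd.DataFrame(index=pd.MultiIndex.from_arrays([[], []], names=["bin1", "bin2"]))
        off = {c: gbins.offset_of(c) for c in gbins.chroms}
        w = gbins.bin_width
        i = sub["chrom1"].map(off).to_numpy() + sub["pos1"].to_numpy() // w
        j = sub["chrom2"].map(off).to_numpy() + sub["pos2"].to_numpy() // w
        lo, hi = np.minimum(i, j), np.maximum(i, j)
        g = pd.DataFrame({"bin1": lo, "bin2": hi})
        return g.groupby(["bin1", "bin2"]).size().to_frame("count")

    intra = _tab(d.loc[same], bins_intra)
    inter = _tab(d.loc[~same], bins_inter)
    return intra, inter, dropped


def bin_contacts(
    pairs: Iterable[ValidPair] | pd.DataFrame,
    sizes: ChromSizes,
    w_intra: int = W_INTRA_DEFAULT,
    w_inter: int = W_INTER_DEFAULT,
    exclude: Sequence[str] = DEFAULT_EXCLUDE,
    sample: str = "sample",
) -> tuple[ContactTable, ContactTable, int]:
    """Bin one sample's pairs into intra (w_intra) and inter (w_inter) tables.

    Each pair increments exactly one row of exactly one table; pairs touching
    excluded/unknown chromosomes are dropped and tallied.  Returns
    (intra, inter, n_dropped).
    """
    bins_intra = make_bins(sizes, w_intra, exclude)
    bins_inter = make_bins(sizes, w_inter, exclude)
    if isinstance(pairs, pd.DataFrame):
        df = pairs
    else:
        rows = [(p.chrom1, p.pos1, p.chrom2, p.pos2) for p in pairs]
        df = pd.DataFrame(rows, columns=["chrom1", "pos1", "chrom2", "pos2"])
        if len(df) == 0:
            df = pd.DataFrame({"chrom1": pd.Series(dtype=str), "pos1": pd.Series(dtype=np.int64),
                               "chrom2": pd.Series(dtype=str), "pos2": pd.Series(dtype=np.int64)})
    intra_df, inter_df, dropped = _bin_pairs_frame(df, bins_intra, bins_inter)
    intra = ContactTable("intra", bins_intra, intra_df.rename(columns={"count": sample}))
    inter = ContactTable("inter", bins_inter, inter_df.rename(columns={"count": sample}))
    return intra, inter, dropped


def merge_samples(
    tables: Sequence[ContactTable],
    groups: dict[str, str] | None = None,
    batches: dict[str, str] | None = None,
) -> ContactTable:
    """Align single-sample tables by bin-pair key with zero fill."""
    if not tables:
        raise ValueError("no tables to merge")
    first = tables[0]
    for t in tables[1:]:
        if t.klass != first.klass or t.bin_width != first.bin_width:
            raise ValueError("cannot merge tables with different class/bin width")
    merged = pd.concat([t.df for t in tables], axis=1).fillna(0).astype(np.int64)
    merged = merged.sort_index()
    return ContactTable(first.klass, first.bins, merged,
                        groups=dict(groups or {}), batches=dict(batches or {}))


def filter_contacts(table: ContactTable, min_total: int = 0) -> tuple[ContactTable, dict]:
    """Remove intra self-pairs (i == j) and rows with total count < min_total.

    Excluded chromosomes never enter the table (binning drops them); the
    report still carries a per-rule removal tally.
    """
    df = table.df
    b1 = df.index.get_level_values(0).to_numpy()
    b2 = df.index.get_level_values(1).to_numpy()
    keep = np.ones(len(df), dtype=bool)
    n_self = 0
    if table.klass == "intra":
        self_mask = b1 == b2
        n_self = int(self_mask.sum())
        keep &= ~self_mask
    totals = df.to_numpy().sum(axis=1)
    low = (totals < min_total) & keep
    n_low = int(low.sum())
    keep &= ~low
    if not keep.any():
        raise ValueError(f"all rows removed; lower min_total (was {min_total})")
    out = ContactTable(table.klass, table.bins, df.loc[keep],
                       groups=table.groups, batches=table.batches)
    report = {"removed_self_pairs": n_self, "removed_low_count": n_low,
              "n_kept": int(keep.sum())}
    return out, report


@dataclass
class BalancedMatrix:
    """ICE-balanced square intra-chromosomal matrix with per-bin weights."""

    chrom: str
    matrix: np.ndarray          # balanced counts
    weights: np.ndarray         # per-bin multiplicative bias (1 for masked bins)
    mask: np.ndarray            # True where the bin is usable
    converged: bool


def ice_balance(matrix: np.ndarray, chrom: str = "", max_iter: int = 200, tol: float = 1e-8) -> BalancedMatrix:
    """Iterative correction: rescale bins until row sums equalize.

    All-zero bins are masked first and excluded from the row-sum statistics.
    Non-convergence sets ``converged=False`` rather than raising.
    """
    M = np.asarray(matrix, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError("matrix must be square")
    if not np.allclose(M, M.T, rtol=1e-10, atol=1e-10):
        raise ValueError("matrix must be symmetric")
    if (M < 0).any():
        raise ValueError("matrix must be nonnegative")
    n = M.shape[0]
    mask = M.sum(axis=1) > 0
    B = M.copy()
    weights = np.ones(n)
    converged = False
    for _ in range(max_iter):
        s = B.sum(axis=1)
        sm = s[mask]
        if len(sm) == 0:
            break
        target = sm.mean()
        dev = np.abs(sm / target - 1.0).max()
        if dev < tol:
            converged = True
            break
        adj = np.ones(n)
        adj[mask] = s[mask] / target
        B = B / np.outer(adj, adj)
        weights *= adj
    weights[~mask] = 1.0
    return BalancedMatrix(chrom, B, weights, mask, converged)


@dataclass
class EigenResult:
    """Leading-eigenvector compartment scores for one chromosome."""

    chrom: str
    e1: np.ndarray              # NaN for masked bins
    labels: np.ndarray          # 'A', 'B', or '' for masked bins
    mask: np.ndarray
    oriented_by: str = "orientation_track"

    def to_frame(self, bin_width: int, chrom_length: int | None = None) -> pd.DataFrame:
        n = len(self.e1)
        starts = np.arange(n) * bin_width
        ends = starts + bin_width
        if chrom_length is not None:
            ends = np.minimum(ends, chrom_length)
        return pd.DataFrame({"chrom": self.chrom, "start": starts, "end": ends,
                             "E1": self.e1, "label": self.labels})


def compartment_eigenvector(
    bal: BalancedMatrix, orientation_track: np.ndarray | None = None
) -> EigenResult:
    """A/B compartment scores from the leading eigenvector of the O/E correlation matrix.

    Expected counts are per-diagonal means over unmasked entries.  The sign of
    E1 is flipped so that its correlation with ``orientation_track`` is >= 0;
    bins with label 'A' have E1 > 0 after orientation.
    """
    M = bal.matrix
    n = M.shape[0]
    mask = bal.mask.copy()
    if mask.sum() < 4:
        raise ValueError("fewer than 4 unmasked bins")
    idx = np.where(mask)[0]
    sub = M[np.ix_(idx, idx)]
    m = len(idx)
    # observed/expected with per-diagonal expected (computed on the unmasked submatrix)
    d = np.abs(np.subtract.outer(idx, idx))
    oe = np.zeros_like(sub)
    for dist in np.unique(d):
        sel = d == dist
        mu = sub[sel].mean()
        oe[sel] = sub[sel] / mu if mu > 0 else 0.0
    # drop zero-variance columns before correlating
    col_sd = oe.std(axis=0)
    good = col_sd > 1e-12
    if good.sum() < 4:
        raise ValueError("fewer than 4 bins with variance in O/E")
    oe2 = oe[np.ix_(good, good)]
    C = np.corrcoef(oe2, rowvar=False)
    C = np.nan_to_num(C)
    evals, evecs = np.linalg.eigh(C)
    e1_sub = evecs[:, -1]
    e1 = np.full(n, np.nan)
    kept = idx[good]
    e1[kept] = e1_sub
    used = "none"
    if orientation_track is not None:
        ot = np.asarray(orientation_track, dtype=float)
        if len(ot) != n:
            raise ValueError("orientation track length mismatch")
        both = ~np.isnan(e1) & ~np.isnan(ot)
        if both.sum() >= 2 and np.std(ot[both]) > 0 and np.std(e1[both]) > 0:
            r = np.corrcoef(e1[both], ot[both])[0, 1]
            if r < 0:
                e1 = -e1
            used = "orientation_track"
    labels = np.array(["" for _ in range(n)], dtype=object)
    lab_mask = ~np.isnan(e1)
    labels[lab_mask] = np.where(e1[lab_mask] > 0, "A", "B")
    final_mask = lab_mask
    return EigenResult(bal.chrom, e1, labels, final_mask, oriented_by=used)


def intra_matrix(table: ContactTable, chrom: str) -> np.ndarray:
    """Dense symmetric count matrix of one chromosome from an intra ContactTable
    (counts summed across samples)."""
    if table.klass != "intra":
        raise ValueError("need an intra table")
    bins = table.bins
    off = bins.offset_of(chrom)
    n = bins.n_bins_of(chrom)
    b1 = table.df.index.get_level_values(0).to_numpy()
    b2 = table.df.index.get_level_values(1).to_numpy()
    sel = (b1 >= off) & (b1 < off + n) & (b2 >= off) & (b2 < off + n)
    tot = table.df.to_numpy().sum(axis=1)
    M = np.zeros((n, n))
    i = b1[sel] - off
    j = b2[sel] - off
    np.add.at(M, (i, j), tot[sel])
    np.add.at(M, (j, i), np.where(i == j, 0, tot[sel]))
    return M
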