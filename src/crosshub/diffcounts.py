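"""Count-based differential testing engine shared by contacts, bins and matrices.

Normalization (CPM/RPKM/TMM), unwanted-variation factors (RUVg/RUVr/RUVs),
negative-binomial dispersion estimation with Cox-Reid adjustment, NB GLM
likelihood-ratio testing, BH-FDR, and a select-and-intersect batch strategy.

The NB model is parameterized by mean mu and dispersion phi with
variance mu + phi * mu**2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .genome import GenomeBins, Region, RegionSet

GROUP_TEST = "EE"
GROUP_REF = "CTL"


# ---------------------------------------------------------------------------
# containers

@dataclass
class CountMatrix:
    """Integer counts (features x samples) with group/batch labels per sample."""

    df: pd.DataFrame
    groups: dict[str, str]
    batches: dict[str, str] = field(default_factory=dict)
    lib_sizes: pd.Series | None = None

    def __post_init__(self):
        vals = self.df.to_numpy()
        if (vals < 0).any():
            raise ValueError("counts must be nonnegative")
        missing = [s for s in self.df.columns if s not in self.groups]
        if missing:
            raise ValueError(f"samples without group label: {missing}")
        present = {self.groups[s] for s in self.df.columns}
        if not {GROUP_TEST, GROUP_REF} <= present:
            raise ValueError(f"need both {GROUP_TEST} and {GROUP_REF} samples")
        if self.lib_sizes is None:
            self.lib_sizes = self.df.sum(axis=0).astype(float)

    @property
    def samples(self) -> list[str]:
        return list(self.df.columns)

    def group_vector(self) -> np.ndarray:
        return np.array([1.0 if self.groups[s] == GROUP_TEST else 0.0 for s in self.samples])


@dataclass
class NormFactors:
    """TMM scaling factors; geometric mean is 1 by construction."""

    factors: pd.Series
    lib_sizes: pd.Series

    @property
    def effective_lib_sizes(self) -> pd.Series:
        return self.lib_sizes * self.factors


@dataclass
class RUVFactors:
    """Unwanted-variation covariates (samples x k), unit-variance columns."""

    W: np.ndarray
    k: int
    variant: str                         # 'g' | 'r' | 's'
    control_ids: list | None = None


def read_counts_tsv(path) -> CountMatrix:
    """Counts TSV with two '#'-prefixed header lines carrying group and batch labels.

    Layout::

        #group<TAB>EE<TAB>EE<TAB>CTL<TAB>CTL
        #batch<TAB>A<TAB>B<TAB>A<TAB>B
        id<TAB>EE1<TAB>EE2<TAB>CTL1<TAB>CTL2
        feat1<TAB>10<TAB>12<TAB>9<TAB>8
    """
    group_row = batch_row = None
    with open(path) as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            if line.startswith("#group"):
                group_row = line.rstrip("\n").split("\t")[1:]
            elif line.startswith("#batch"):
                batch_row = line.rstrip("\n").split("\t")[1:]
            elif line.startswith("#"):
                pass
            else:
                break
            pos = fh.tell()
        fh.seek(pos)
        df = pd.read_csv(fh, sep="\t", index_col=0)
    if group_row is None:
        raise ValueError(f"{path}: missing '#group' header line")
    samples = list(df.columns)
    if len(group_row) != len(samples):
        raise ValueError(f"{path}: group header length mismatch")
    groups = dict(zip(samples, group_row))
    batches = dict(zip(samples, batch_row)) if batch_row else {}
    return CountMatrix(df, groups, batches)


def write_counts_tsv(cm: CountMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write("#group\t" + "\t".join(cm.groups[s] for s in cm.samples) + "\n")
        if cm.batches:
            fh.write("#batch\t" + "\t".join(cm.batches.get(s, "NA") for s in cm.samples) + "\n")
        cm.df.to_csv(fh, sep="\t")


# ---------------------------------------------------------------------------
# normalization

def cpm(counts: pd.DataFrame, lib_sizes: pd.Series | None = None,
        norm_factors: NormFactors | None = None, log: bool = False,
        prior: float = 0.5) -> pd.DataFrame:
    """Counts per million against the (effective) library size."""
    if norm_factors is not None:
        lib = norm_factors.effective_lib_sizes
    elif lib_sizes is not None:
        lib = lib_sizes
    else:
        lib = counts.sum(axis=0).astype(float)
    if (lib <= 0).any():
        raise ValueError("zero library size")
    out = counts.div(lib, axis=1) * 1e6
    if log:
        out = np.log2(out + prior)
    return out


def rpkm(counts: pd.DataFrame, lengths: pd.Series,
         lib_sizes: pd.Series | None = None,
         norm_factors: NormFactors | None = None) -> pd.DataFrame:
    """Reads per kilobase per million; ``lengths`` in bp, indexed like counts."""
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any() or (lengths <= 0).any():
        raise ValueError("feature lengths must be positive for every feature")
    return cpm(counts, lib_sizes, norm_factors).div(lengths / 1e3, axis=0)


def _tmm_pair(obs: np.ndarray, ref: np.ndarray, No: float, Nr: float,
              trim_logratio: float, trim_abs: float) -> float:
    keep = (obs > 0) & (ref > 0)
    if keep.sum() < 10:
        warnings.warn("fewer than 10 usable features for TMM pair; factor set to 1")
        return 1.0
    o, r = obs[keep].astype(float), ref[keep].astype(float)
    M = np.log2((o / No) / (r / Nr))
    A = 0.5 * np.log2((o / No) * (r / Nr))
    v = (No - o) / (No * o) + (Nr - r) / (Nr * r)   # asymptotic variance of M
    n = len(M)
    rM = stats.rankdata(M)
    rA = stats.rankdata(A)
    loM = np.floor(n * trim_logratio) + 1
    hiM = n + 1 - loM
    loA = np.floor(n * trim_abs) + 1
    hiA = n + 1 - loA
    sel = (rM >= loM) & (rM <= hiM) & (rA >= loA) & (rA <= hiA)
    if not sel.any():
        return 1.0
    f = np.sum(M[sel] / v[sel]) / np.sum(1.0 / v[sel])
    if not np.isfinite(f):
        f = 0.0
    return float(2.0 ** f)


def tmm_factors(counts: pd.DataFrame, lib_sizes: pd.Series | None = None,
                ref_sample: str | None = None,
                trim_logratio: float = 0.3, trim_abs: float = 0.05) -> NormFactors:
    """Trimmed-mean-of-M-values scaling factors, rescaled to geometric mean 1.

    The reference sample is the one whose upper-quartile CPM is closest to the
    mean upper quartile (the standard choice) unless given explicitly.
    """
    if counts.shape[1] < 2:
        raise ValueError("TMM needs at least 2 samples")
    lib = counts.sum(axis=0).astype(float) if lib_sizes is None else lib_sizes.astype(float)
    if (lib <= 0).any():
        raise ValueError("zero library size")
    Y = counts.to_numpy(dtype=float)
    if ref_sample is None:
        f75 = np.array([np.quantile(Y[:, i] / lib.iloc[i], 0.75) for i in range(Y.shape[1])])
        ref_idx = int(np.argmin(np.abs(f75 - f75.mean())))
    else:
        ref_idx = list(counts.columns).index(ref_sample)
    ref = Y[:, ref_idx]
    Nr = lib.iloc[ref_idx]
    facs = np.array([
        _tmm_pair(Y[:, i], ref, lib.iloc[i], Nr, trim_logratio, trim_abs)
        if i != ref_idx else 1.0
        for i in range(Y.shape[1])
    ])
    facs = facs / np.exp(np.mean(np.log(facs)))
    return NormFactors(pd.Series(facs, index=counts.columns), lib)


# ---------------------------------------------------------------------------
# RUV factors

def _unit_variance(W: np.ndarray) -> np.ndarray:
    sd = W.std(axis=0, ddof=1)
    if (sd <= 0).any():
        raise ValueError("degenerate (zero-variance) unwanted-variation factor")
    return W / sd


def ruv_g(counts: pd.DataFrame, control_ids: Sequence, k: int = 1) -> RUVFactors:
    """Unwanted-variation covariates from negative-control features.

    Rows of log(count+0.5) restricted to the controls are centered and the
    sample-side coordinates of the first k singular vectors are returned.
    """
    n = counts.shape[1]
    if k < 1:
        return RUVFactors(np.empty((n, 0)), 0, "g", list(control_ids))
    if k >= n:
        raise ValueError("k must be < number of samples")
    controls = [c for c in control_ids if c in counts.index]
    if len(controls) != len(list(control_ids)):
        raise ValueError("control ids not all present in counts")
    if len(controls) < k + 1:
        raise ValueError(f"need at least k+1={k + 1} control features")
    M = np.log(counts.loc[controls].to_numpy(dtype=float) + 0.5)
    M = M - M.mean(axis=1, keepdims=True)
    if np.allclose(M, 0):
        raise ValueError("control features constant across samples")
    U, S, _ = np.linalg.svd(M.T, full_matrices=False)
    if S[k - 1] <= 1e-12:
        raise ValueError("control features give fewer than k non-degenerate factors")
    W = _unit_variance(U[:, :k])
    return RUVFactors(W, k, "g", list(controls))


def ruv_r(counts: pd.DataFrame, groups: dict[str, str] | np.ndarray, k: int = 1) -> RUVFactors:
    """Unwanted-variation covariates from first-pass residuals.

    log-CPM is regressed on the group design by least squares; W holds the
    first k sample-side singular vectors of the residual matrix.
    """
    n = counts.shape[1]
    if isinstance(groups, dict):
        g = np.array([1.0 if groups[s] == GROUP_TEST else 0.0 for s in counts.columns])
    else:
        g = np.asarray(groups, dtype=float)
    X = np.column_stack([np.ones(n), g])
    rank = np.linalg.matrix_rank(X)
    if k < 1:
        return RUVFactors(np.empty((n, 0)), 0, "r")
    if k > n - rank:
        raise ValueError(f"k={k} exceeds residual degrees of freedom {n - rank}")
    logcpm = cpm(counts, log=True).to_numpy()
    H = X @ np.linalg.pinv(X)
    E = logcpm - logcpm @ H.T                     # residuals, features x samples
    if np.allclose(E, 0, atol=1e-10):
        raise ValueError("residuals are all zero; no estimable unwanted factor")
    U, S, _ = np.linalg.svd(E.T, full_matrices=False)
    if S[k - 1] <= 1e-12:
        raise ValueError("residual matrix yields fewer than k factors")
    W = _unit_variance(U[:, :k])
    return RUVFactors(W, k, "r")


def ruv_s(counts: pd.DataFrame, groups: dict[str, str] | np.ndarray, k: int = 1,
          control_ids: Sequence | None = None) -> RUVFactors:
    """Replicate-group variant: controls centered within each condition, then SVD."""
    n = counts.shape[1]
    if k < 1:
        return RUVFactors(np.empty((n, 0)), 0, "s")
    if k >= n:
        raise ValueError("k must be < number of samples")
    if isinstance(groups, dict):
        labels = np.array([groups[s] for s in counts.columns])
    else:
        labels = np.asarray(groups)
    sub = counts if control_ids is None else counts.loc[list(control_ids)]
    M = np.log(sub.to_numpy(dtype=float) + 0.5)
    centered = M.copy()
    for lab in np.unique(labels):
        sel = labels == lab
        centered[:, sel] = M[:, sel] - M[:, sel].mean(axis=1, keepdims=True)
    if np.allclose(centered, 0):
        raise ValueError("controls constant within replicate groups")
    U, S, _ = np.linalg.svd(centered.T, full_matrices=False)
    if S[k - 1] <= 1e-12:
        raise ValueError("fewer than k non-degenerate factors")
    W = _unit_variance(U[:, :k])
    return RUVFactors(W, k, "s", list(control_ids) if control_ids is not None else None)


# ---------------------------------------------------------------------------
# NB GLM machinery (vectorized over features)

_ETA_LIM = 30.0


def _nb_loglik(Y: np.ndarray, mu: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Row-wise NB log-likelihood; falls back to Poisson for tiny phi."""
    phi = np.broadcast_to(np.asarray(phi, dtype=float)[:, None], Y.shape)
    mu = np.maximum(mu, 1e-12)
    pois = Y * np.log(mu) - mu - special.gammaln(Y + 1)
    tiny = phi < 1e-10
    r = 1.0 / np.where(tiny, 1.0, phi)
    nb = (special.gammaln(Y + r) - special.gammaln(r) - special.gammaln(Y + 1)
          + r * np.log(r / (r + mu)) + Y * np.log(mu / (r + mu)))
    return np.where(tiny, pois, nb).sum(axis=1)


def _fit_nb_glm(Y: np.ndarray, X: np.ndarray, offset: np.ndarray, phi: np.ndarray,
                max_iter: int = 60, tol: float = 1e-10):
    """IRLS fit of NB log-linear models for all features at once.

    Y: G x S counts, X: S x p design, offset: length-S, phi: length-G.
    Returns (beta G x p, mu G x S, loglik G, converged G, xtwx G x p x p).
    """
    G, S = Y.shape
    p = X.shape[1]
    phi = np.asarray(phi, dtype=float)
    eta = np.log(Y + 0.5)
    mu = np.exp(np.clip(eta, -_ETA_LIM, _ETA_LIM))
    beta = np.zeros((G, p))
    converged = np.zeros(G, dtype=bool)
    ridge = 1e-9 * np.eye(p)
    A = None
    for _ in range(max_iter):
        Wt = mu / (1.0 + phi[:, None] * mu)
        z = (eta - offset[None, :]) + (Y - mu) / mu
        A = np.einsum("gs,sp,sq->gpq", Wt, X, X) + ridge
        b = np.einsum("gs,sp->gp", Wt * z, X)
        new_beta = np.linalg.solve(A, b[..., None])[..., 0]
        delta = np.abs(new_beta - beta).max(axis=1)
        beta = new_beta
        eta = offset[None, :] + beta @ X.T
        eta = np.clip(eta, -_ETA_LIM, _ETA_LIM)
        mu = np.exp(eta)
        converged = delta < max(tol, 1e-8)
        if converged.all():
            break
    ll = _nb_loglik(Y, mu, phi)
    Wt = mu / (1.0 + phi[:, None] * mu)
    xtwx = np.einsum("gs,sp,sq->gpq", Wt, X, X)
    return beta, mu, ll, converged, xtwx


def _adjusted_profile_loglik(Y: np.ndarray, X: np.ndarray, offset: np.ndarray,
                             phi: float | np.ndarray) -> np.ndarray:
    """Cox-Reid adjusted profile log-likelihood per feature at dispersion phi."""
    G = Y.shape[0]
    phi_arr = np.full(G, phi, dtype=float) if np.isscalar(phi) else np.asarray(phi, float)
    _, _, ll, _, xtwx = _fit_nb_glm(Y, X, offset, phi_arr)
    sign, logdet = np.linalg.slogdet(xtwx + 1e-12 * np.eye(X.shape[1]))
    return ll - 0.5 * logdet


def estimate_dispersion(counts: pd.DataFrame, design: np.ndarray,
                        offset: np.ndarray | None = None,
                        w0: float = 20.0,
                        max_features: int = 1000) -> tuple[float, pd.Series, pd.Series]:
    """Common and per-feature shrunk NB dispersions.

    The common dispersion maximizes the summed Cox-Reid adjusted profile
    likelihood over (a deterministic subsample of) features.  Per-feature
    optima come from a dispersion grid and are shrunk toward the common value
    with prior weight ``w0`` pseudo-features:
    phi_i = (phi_ML_i + w0 * phi_common) / (1 + w0).

    Returns (common phi, per-feature phi Series, all-zero flag Series).
    """
    Y = counts.to_numpy(dtype=float)
    if offset is None:
        lib = Y.sum(axis=0)
        if (lib <= 0).any():
            raise ValueError("zero library size")
        offset = np.log(lib)
    zero = Y.sum(axis=1) == 0
    usable = np.where(~zero)[0]
    if len(usable) == 0:
        raise ValueError("all features are zero")
    Yu = Y[usable]
    if len(usable) > max_features:
        pick = usable[np.linspace(0, len(usable) - 1, max_features).astype(int)]
        Ysub = Y[pick]
    else:
        Ysub = Yu

    def neg_total(logphi):
        return -float(_adjusted_profile_loglik(Ysub, design, offset, np.exp(logphi)).sum())

    res = optimize.minimize_scalar(neg_total, bounds=(np.log(1e-6), np.log(10.0)),
                                   method="bounded", options={"xatol": 1e-3})
    common = float(np.exp(res.x))

    grid = np.geomspace(1e-6, 10.0, 25)
    apl = np.stack([_adjusted_profile_loglik(Yu, design, offset, g) for g in grid], axis=1)
    phi_ml = grid[np.argmax(apl, axis=1)]
    phi_shrunk = (phi_ml + w0 * common) / (1.0 + w0)
    out = np.full(Y.shape[0], np.nan)
    out[usable] = phi_shrunk
    return common, pd.Series(out, index=counts.index), pd.Series(zero, index=counts.index)


def bh_fdr(pvals: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up: q_(i) = min_{j>=i} p_(j) * m / j.

    NaN p-values are excluded from m and stay NaN.
    """
    p = np.asarray(pvals, dtype=float)
    q = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    ps = p[ok]
    if (ps < 0).any() or (ps > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(ps)
    if m == 0:
        return q
    order = np.argsort(ps, kind="stable")
    ranked = ps[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    qs = np.empty(m)
    qs[order] = np.minimum(ranked, 1.0)
    q[ok] = qs
    return q


def nb_glm_test(counts: pd.DataFrame, groups: dict[str, str] | np.ndarray,
                W: np.ndarray | RUVFactors | None = None,
                norm_factors: NormFactors | None = None,
                dispersions: pd.Series | None = None,
                w0: float = 20.0) -> pd.DataFrame:
    """Per-feature NB GLM likelihood-ratio test of the group effect.

    Fits log-linear NB models with design [intercept, group, W] and offset
    log(effective library size); p-values from the 1-df LRT of the group
    coefficient; returns a DataFrame (log2FC, pvalue, qvalue, direction, test).
    """
    samples = list(counts.columns)
    n = len(samples)
    if isinstance(groups, dict):
        g = np.array([1.0 if groups[s] == GROUP_TEST else 0.0 for s in samples])
    else:
        g = np.asarray(groups, dtype=float)
    if isinstance(W, RUVFactors):
        W = W.W
    W = np.empty((n, 0)) if W is None else np.atleast_2d(np.asarray(W, dtype=float))
    if W.shape[0] != n:
        raise ValueError("W row count must equal number of samples")
    X_full = np.column_stack([np.ones(n), g, W])
    if np.linalg.matrix_rank(X_full) < X_full.shape[1]:
        raise ValueError("design matrix [intercept, group, W] is rank deficient")
    X_null = np.column_stack([np.ones(n), W])
    if norm_factors is None:
        lib = counts.sum(axis=0).astype(float)
    else:
        lib = norm_factors.effective_lib_sizes
    if (lib <= 0).any():
        raise ValueError("zero effective library size")
    offset = np.log(lib.to_numpy())
    Y = counts.to_numpy(dtype=float)
    zero = Y.sum(axis=1) == 0

    if dispersions is None:
        _, disp, _ = estimate_dispersion(counts, X_full, offset, w0=w0)
    else:
        disp = dispersions.reindex(counts.index)
    phi = disp.to_numpy(dtype=float)
    phi_safe = np.where(np.isfinite(phi), phi, 0.1)

    beta_f, _, ll_f, conv_f, _ = _fit_nb_glm(Y, X_full, offset, phi_safe)
    _, _, ll_0, conv_0, _ = _fit_nb_glm(Y, X_null, offset, phi_safe)
    lrt = np.maximum(2.0 * (ll_f - ll_0), 0.0)
    p = stats.chi2.sf(lrt, df=1)
    bad = zero | ~conv_f | ~conv_0 | ~np.isfinite(phi)
    p = np.where(bad, np.nan, p)
    log2fc = beta_f[:, 1] / np.log(2.0)
    log2fc = np.where(zero, np.nan, log2fc)
    q = bh_fdr(p)
    out = pd.DataFrame({
        "log2FC": log2fc,
        "pvalue": p,
        "qvalue": q,
        "direction": np.sign(log2fc),
        "test": "nb_lrt",
    }, index=counts.index)
    out["converged"] = ~bad
    return out


# ---------------------------------------------------------------------------
# strategies on top of the engine

def _pc1_silhouette(values: np.ndarray, g: np.ndarray) -> float:
    """Mean silhouette of the two groups on a 1-D projection."""
    vals = np.asarray(values, float)
    sil = []
    for i in range(len(vals)):
        own = np.abs(vals[i] - vals[(g == g[i]) & (np.arange(len(vals)) != i)])
        other = np.abs(vals[i] - vals[g != g[i]])
        a = own.mean() if len(own) else 0.0
        b = other.mean()
        denom = max(a, b)
        sil.append(0.0 if denom == 0 else (b - a) / denom)
    return float(np.mean(sil))


def _pc1(logcpm: np.ndarray) -> np.ndarray:
    """First principal component of samples from a features x samples matrix."""
    Xc = logcpm - logcpm.mean(axis=1, keepdims=True)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    return Vt[0] * S[0]


def empirical_controls(counts: pd.DataFrame, top_mean_quantile: float = 0.9) -> list:
    """Stable features: top decile of mean count, below-median log-CPM variance."""
    mean = counts.mean(axis=1)
    var = cpm(counts, log=True).var(axis=1)
    hi = mean >= mean.quantile(top_mean_quantile)
    stable = hi & (var <= var[hi].median())
    ids = list(counts.index[stable])
    if len(ids) < 2:
        ids = list(counts.index[hi])
    return ids


def select_and_intersect(counts: CountMatrix, strategies: Sequence[str] = ("g", "r"),
                         k: int = 1, fdr: float = 0.1,
                         control_ids: Sequence | None = None) -> tuple[pd.DataFrame, dict]:
    """Run the NB test once per qualifying RUV variant and intersect the calls.

    A variant qualifies when, after regressing W out of log-CPM, the first
    principal component separates the groups (positive mean silhouette).
    The final call set is significant at ``fdr`` in every qualifying variant.
    """
    if not strategies:
        raise ValueError("need at least one strategy")
    df = counts.df
    g = counts.group_vector()
    nf = tmm_factors(df, counts.lib_sizes)
    logcpm = cpm(df, norm_factors=nf, log=True).to_numpy()
    ctrl = list(control_ids) if control_ids is not None else empirical_controls(df)

    per_variant: dict[str, pd.DataFrame] = {}
    qualified: list[str] = []
    report: dict = {"qualifying": [], "tested": list(strategies)}
    for s in strategies:
        try:
            if s == "g":
                rf = ruv_g(df, ctrl, k)
            elif s == "r":
                rf = ruv_r(df, counts.groups, k)
            elif s == "s":
                rf = ruv_s(df, counts.groups, k, ctrl)
            else:
                raise ValueError(f"unknown strategy {s!r}")
        except ValueError as exc:
            report[f"error_{s}"] = str(exc)
            continue
        # remove W from log-CPM, then check PC1 group separation
        W = rf.W
        H = W @ np.linalg.pinv(W) if W.shape[1] else np.zeros((len(g), len(g)))
        cleaned = logcpm - logcpm @ H.T
        score = _pc1_silhouette(_pc1(cleaned), g)
        report[f"silhouette_{s}"] = score
        if score > 0:
            qualified.append(s)
            per_variant[s] = nb_glm_test(df, counts.groups, rf, nf)
    report["qualifying"] = qualified
    if not qualified:
        empty = pd.DataFrame(columns=["log2FC", "pvalue", "qvalue", "direction", "test"])
        return empty, report
    sig_sets = [set(r.index[(r["qvalue"] < fdr).fillna(False)]) for r in per_variant.values()]
    final_ids = set.intersection(*sig_sets)
    base = per_variant[qualified[0]]
    result = base.loc[base.index.isin(final_ids)].copy()
    report["n_final"] = len(result)
    return result, report


def diff_contact_analysis(table, k: int = 1, fdr: float = 0.05,
                          control_ids: Sequence | None = None) -> tuple[pd.DataFrame, dict]:
    """Differential testing of a filtered multi-sample ContactTable.

    Intra contacts use residual-based (RUVr) covariates; inter contacts use
    control-feature (RUVg) covariates with empirically stable bin-pairs as the
    default negative controls.  Returns (result frame, summary dict); the
    result carries bin coordinates and increased/decreased flags at ``fdr``.
    """
    df = table.df
    if not table.groups:
        raise ValueError("contact table has no sample group labels")
    nf = tmm_factors(df)
    if k > 0:
        if table.klass == "inter":
            ctrl = list(control_ids) if control_ids is not None else empirical_controls(df)
            rf = ruv_g(df, ctrl, k)
        else:
            rf = ruv_r(df, table.groups, k)
        W = rf.W
    else:
        W = None
    res = nb_glm_test(df, table.groups, W, nf)
    res = res.join(table.pair_coords())
    sig = (res["qvalue"] < fdr).fillna(False)
    res["increased"] = sig & (res["log2FC"] > 0)
    res["decreased"] = sig & (res["log2FC"] < 0)
    summary = {
        "class": table.klass,
        "n_tested": int(res["pvalue"].notna().sum()),
        "n_increased": int(res["increased"].sum()),
        "n_decreased": int(res["decreased"].sum()),
        "fdr": fdr,
        "ruv_variant": "g" if table.klass == "inter" else "r",
        "k": k,
    }
    return res, summary


def diff_mark_bins(counts: CountMatrix, bins: GenomeBins, k: int = 1,
                   fdr: float = 0.05) -> tuple[pd.DataFrame, RegionSet, RegionSet]:
    """NB differential test of per-bin coverage; emits up/down bin RegionSets.

    Feature ids must be global bin indices of ``bins``.
    """
    df = counts.df
    nf = tmm_factors(df, counts.lib_sizes)
    W = ruv_r(df, counts.groups, k).W if k > 0 else None
    res = nb_glm_test(df, counts.groups, W, nf)
    sig = (res["qvalue"] < fdr).fillna(False)
    up_regions, down_regions = [], []
    for bin_id in res.index[sig]:
        chrom, start, end = bins.bin_record(int(bin_id))
        direction = 1 if res.at[bin_id, "log2FC"] > 0 else -1
        reg = Region(chrom, start, end, name=f"bin{bin_id}", direction=direction)
        (up_regions if direction > 0 else down_regions).append(reg)
    return res, RegionSet(up_regions, "bins_up"), RegionSet(down_regions, "bins_down")
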