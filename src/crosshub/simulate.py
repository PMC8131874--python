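"""Synthetic inputs with planted ground truth for every pipeline stage.

Generates negative-binomial contact counts with an inter-chromosomal enriched
hub and sample-level batch factors, clustered differential mark regions,
two-contrast protein ratio tables, batch-confounded small-RNA counts with a
reproducible subset, and linked region/gene fold changes with a chosen
correlation.  All generators are pure functions of (config, seed).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import ChromSizes, GenomeBins, Region, RegionSet, make_bins
from .contacts import ContactTable, W_INTRA_DEFAULT, W_INTER_DEFAULT
from .diffcounts import CountMatrix, GROUP_TEST, GROUP_REF


@dataclass
class SimConfig:
    """Defaults mirror a 2+2 replicate design on a toy multi-chromosome genome."""

    n_chroms: int = 8
    chrom_length: int = 10_000_000
    w_intra: int = W_INTRA_DEFAULT
    w_inter: int = W_INTER_DEFAULT
    n_test: int = 2                     # EE samples
    n_ref: int = 2                      # CTL samples
    mu0_intra: float = 20.0
    mu0_inter: float = 100.0
    nb_dispersion: float = 0.01
    decay_alpha: float = 1.0
    hub_fold: float = 2.0
    n_hub_pairs: int = 30
    n_intra_diff_pairs: int = 20
    batch_effect: float = 0.15
    # proteomics
    n_proteins: int = 500
    frac_consistent: float = 0.4
    protein_noise_sd: float = 0.04
    # small RNA
    n_mirna: int = 300
    n_mirna_batches: int = 3
    frac_reproducible: float = 0.5
    mirna_low_frac: float = 0.1
    # linked expression
    n_genes: int = 500
    link_rho: float = 0.6
    seed: int = 0

    def __post_init__(self):
        if self.hub_fold < 1.0:
            raise ValueError("hub_fold must be >= 1")
        for name in ("frac_consistent", "frac_reproducible", "mirna_low_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if not -1.0 <= self.link_rho <= 1.0:
            raise ValueError("link_rho must be in [-1, 1]")


@dataclass
class SimTruth:
    """Planted ground truth; serializable to a JSON sidecar."""

    hub_pairs: list[tuple[int, int]] = field(default_factory=list)   # inter bin-pair keys
    intra_pairs: list[tuple[int, int]] = field(default_factory=list)
    batch_factors: dict[str, float] = field(default_factory=dict)
    consistent_proteins: list[str] = field(default_factory=list)
    reproducible_mirnas: list[str] = field(default_factory=list)
    link_rho: float | None = None
    seed: int = 0

    def to_json(self, path) -> None:
        d = dataclasses.asdict(self)
        d["hub_pairs"] = [list(p) for p in self.hub_pairs]
        d["intra_pairs"] = [list(p) for p in self.intra_pairs]
        Path(path).write_text(json.dumps(d, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path) -> "SimTruth":
        d = json.loads(Path(path).read_text())
        d["hub_pairs"] = [tuple(p) for p in d["hub_pairs"]]
        d["intra_pairs"] = [tuple(p) for p in d["intra_pairs"]]
        return cls(**d)

    def hub_bins(self) -> set[int]:
        return {b for pair in self.hub_pairs for b in pair}


def toy_chrom_sizes(cfg: SimConfig) -> ChromSizes:
    """Toy genome; last autosome is named chr17s next to chr7s as the hub
    partner, plus a half-length chrX to exercise the exclusion rule."""
    names = [f"chr{i}s" for i in range(1, cfg.n_chroms + 1)]
    if cfg.n_chroms >= 8:
        names[7] = "chr17s"
    items = [(n, cfg.chrom_length) for n in names]
    items.append(("chrX", max(cfg.chrom_length // 2, cfg.w_inter)))
    return ChromSizes(items)


def hub_chromosomes(cfg: SimConfig, sizes: ChromSizes) -> tuple[str, str]:
    names = [c for c in sizes.names if c != "chrX"]
    if "chr7s" in names and "chr17s" in names:
        return "chr7s", "chr17s"
    return names[-2], names[-1]


def _sample_names(cfg: SimConfig) -> tuple[list[str], dict[str, str], dict[str, str]]:
    names = [f"EE{i + 1}" for i in range(cfg.n_test)] + [f"CTL{i + 1}" for i in range(cfg.n_ref)]
    groups = {s: (GROUP_TEST if s.startswith("EE") else GROUP_REF) for s in names}
    batches = {s: ("A" if int(s[-1]) % 2 == 1 else "B") for s in names}
    return names, groups, batches


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, phi: float) -> np.ndarray:
    if phi < 1e-12:
        return rng.poisson(mu)
    r = 1.0 / phi
    return rng.negative_binomial(r, r / (r + mu))


@dataclass
class HiCSim:
    cfg: SimConfig
    sizes: ChromSizes
    truth: SimTruth
    intra: ContactTable
    inter: ContactTable
    pair_files: dict[str, Path] = field(default_factory=dict)


def simulate_hic(cfg: SimConfig, out_dir=None, classes: tuple[str, ...] = ("intra", "inter"),
                 materialize: bool | None = None) -> HiCSim:
    """Simulate per-sample contact counts; optionally materialize valid-pairs files.

    Intra pair means follow mu0 * (1 + d)^(-alpha) for bin distance d; inter
    pairs have mean mu0_inter (with mild lognormal heterogeneity).  Hub pairs
    between the two hub chromosomes get mean * hub_fold in test samples only.
    A per-sample batch factor exp(b_s * u_f) with feature loadings u_f enters
    multiplicatively.  When ``out_dir`` is given (or materialize=True), counts
    are written out as that many 1-based valid-pair lines with positions
    uniform within bins, plus a chrX spike to exercise the exclusion rule.
    """
    if materialize is None:
        materialize = out_dir is not None
    if materialize and out_dir is None:
        raise ValueError("materialize requires out_dir")
    sizes = toy_chrom_sizes(cfg)
    samples, groups, batches = _sample_names(cfg)
    b_s = np.array([cfg.batch_effect if batches[s] == "A" else -cfg.batch_effect for s in samples])
    truth = SimTruth(batch_factors={s: float(b) for s, b in zip(samples, b_s)}, seed=cfg.seed)

    frames: dict[str, pd.DataFrame] = {}
    hub_mean_warn = False

    if "inter" in classes:
        rng = np.random.default_rng([cfg.seed, 1])
        bins = make_bins(sizes, cfg.w_inter)
        chrom_rank = bins.chrom_of_array(np.arange(bins.n_bins))
        ii, jj = np.triu_indices(bins.n_bins, k=1)
        diff = chrom_rank[ii] != chrom_rank[jj]
        ii, jj = ii[diff], jj[diff]
        base = cfg.mu0_inter * np.exp(rng.normal(0.0, 0.1, size=len(ii)))
        u = rng.uniform(0.0, 2.0, size=len(ii))
        ca, cb = hub_chromosomes(cfg, sizes)
        a0, an = bins.offset_of(ca), bins.n_bins_of(ca)
        b0, bn = bins.offset_of(cb), bins.n_bins_of(cb)
        in_hub_cross = ((ii >= a0) & (ii < a0 + an) & (jj >= b0) & (jj < b0 + bn))
        cand = np.where(in_hub_cross)[0]
        if cfg.n_hub_pairs > len(cand):
            raise ValueError("not enough cross-hub bin pairs for n_hub_pairs")
        hub_idx = rng.choice(cand, size=cfg.n_hub_pairs, replace=False)
        hub_mask = np.zeros(len(ii), dtype=bool)
        hub_mask[hub_idx] = True
        if (base[hub_mask] * cfg.hub_fold < 1.0).any():
            hub_mean_warn = True
        cols = {}
        for s, b in zip(samples, b_s):
            mu = base * np.exp(b * u)
            if groups[s] == GROUP_TEST:
                mu = mu * np.where(hub_mask, cfg.hub_fold, 1.0)
            cols[s] = _nb_draw(rng, mu, cfg.nb_dispersion)
        inter_df = pd.DataFrame(cols, index=pd.MultiIndex.from_arrays([ii, jj], names=["bin1", "bin2"]))
        frames["inter"] = inter_df
        truth.hub_pairs = [(int(ii[x]), int(jj[x])) for x in sorted(hub_idx)]
        inter_table = ContactTable("inter", bins, inter_df, groups=groups, batches=batches)
    else:
        inter_table = None

    if "intra" in classes:
        rng = np.random.default_rng([cfg.seed, 2])
        bins = make_bins(sizes, cfg.w_intra)
        ii_parts, jj_parts = [], []
        for c in bins.chroms:
            off, n = bins.offset_of(c), bins.n_bins_of(c)
            a, b = np.triu_indices(n, k=0)
            ii_parts.append(a + off)
            jj_parts.append(b + off)
        ii = np.concatenate(ii_parts)
        jj = np.concatenate(jj_parts)
        d = jj - ii
        base = cfg.mu0_intra * (1.0 + d) ** (-cfg.decay_alpha)
        u = rng.uniform(0.0, 2.0, size=len(ii))
        nonself = np.where((d > 0) & (d <= 20))[0]
        n_plant = min(cfg.n_intra_diff_pairs, len(nonself))
        plant = rng.choice(nonself, size=n_plant, replace=False) if n_plant else np.array([], int)
        plant_mask = np.zeros(len(ii), dtype=bool)
        plant_mask[plant] = True
        cols = {}
        for s, b in zip(samples, b_s):
            mu = base * np.exp(b * u)
            if groups[s] == GROUP_TEST:
                mu = mu * np.where(plant_mask, cfg.hub_fold, 1.0)
            cols[s] = _nb_draw(rng, mu, cfg.nb_dispersion)
        intra_df = pd.DataFrame(cols, index=pd.MultiIndex.from_arrays([ii, jj], names=["bin1", "bin2"]))
        frames["intra"] = intra_df
        truth.intra_pairs = [(int(ii[x]), int(jj[x])) for x in sorted(plant)]
        intra_table = ContactTable("intra", bins, intra_df, groups=groups, batches=batches)
    else:
        intra_table = None

    if hub_mean_warn:
        import warnings
        warnings.warn("expected hub mean below 1 read; detection power will be ~0")

    pair_files: dict[str, Path] = {}
    if materialize:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        rng = np.random.default_rng([cfg.seed, 3])
        for s in samples:
            parts = []
            for klass, table in (("intra", intra_table), ("inter", inter_table)):
                if table is None:
                    continue
                gbins = table.bins
                w = gbins.bin_width
                df = frames[klass]
                counts = df[s].to_numpy()
                pos = counts > 0
                b1 = np.repeat(df.index.get_level_values(0).to_numpy()[pos], counts[pos])
                b2 = np.repeat(df.index.get_level_values(1).to_numpy()[pos], counts[pos])
                rec = {i: gbins.bin_record(i) for i in np.unique(np.concatenate([b1, b2]))}
                c1 = np.array([rec[i][0] for i in b1])
                s1 = np.array([rec[i][1] for i in b1])
                e1 = np.array([rec[i][2] for i in b1])
                c2 = np.array([rec[i][0] for i in b2])
                s2 = np.array([rec[i][1] for i in b2])
                e2 = np.array([rec[i][2] for i in b2])
                p1 = s1 + rng.integers(0, e1 - s1)
                p2 = s2 + rng.integers(0, e2 - s2)
                parts.append(pd.DataFrame({"chrom1": c1, "pos1": p1 + 1, "chrom2": c2, "pos2": p2 + 1}))
            # chrX spike: dropped by default exclusion downstream
            n_x = 200
            other = [c for c in sizes.names if c != "chrX"]
            xc = rng.choice(other, size=n_x)
            xp = rng.integers(1, sizes["chrX"], size=n_x)
            op = np.array([rng.integers(1, sizes[c]) for c in xc])
            parts.append(pd.DataFrame({"chrom1": "chrX", "pos1": xp, "chrom2": xc, "pos2": op}))
            allp = pd.concat(parts, ignore_index=True)
            allp.insert(0, "read_id", [f"r{i}" for i in range(len(allp))])
            allp.insert(3, "strand1", "+")
            allp["strand2"] = "-"
            path = out_dir / f"{s}.validPairs.tsv"
            allp[["read_id", "chrom1", "pos1", "strand1", "chrom2", "pos2", "strand2"]].to_csv(
                path, sep="\t", header=False, index=False)
            pair_files[s] = path
        truth.to_json(out_dir / "hic_truth.json")
        from .genome import write_chrom_sizes
        write_chrom_sizes(sizes, out_dir / "chrom.sizes")

    return HiCSim(cfg, sizes, truth,
                  intra_table if intra_table is not None else _empty_table("intra", sizes, cfg),
                  inter_table if inter_table is not None else _empty_table("inter", sizes, cfg),
                  pair_files)


def _empty_table(klass: str, sizes: ChromSizes, cfg: SimConfig) -> ContactTable:
    w = cfg.w_intra if klass == "intra" else cfg.w_inter
    idx = pd.MultiIndex.from_arrays([[], []], names=["bin1", "bin2"])
    return ContactTable(klass, make_bins(sizes, w), pd.DataFrame(index=idx))


def simulate_mark_regions(truth: SimTruth, bins: GenomeBins, n_regions: int = 100,
                          p_in_hub: float = 0.8, seed: int = 0,
                          label: str = "mark") -> RegionSet:
    """Differential-mark regions clustered in hub bins with probability p_in_hub."""
    if not 0.0 <= p_in_hub <= 1.0:
        raise ValueError("p_in_hub must be in [0, 1]")
    hub = sorted(truth.hub_bins())
    if p_in_hub > 0 and not hub:
        raise ValueError("truth has no hub bins but p_in_hub > 0")
    non_hub = sorted(set(range(bins.n_bins)) - set(hub))
    rng = np.random.default_rng([seed, 4])
    regions = []
    for i in range(n_regions):
        use_hub = hub and rng.random() < p_in_hub
        pool = hub if use_hub else non_hub
        b = int(pool[rng.integers(0, len(pool))])
        chrom, start, end = bins.bin_record(b)
        length = int(rng.integers(1_000, 50_001))
        length = min(length, end - start)
        s = int(start + rng.integers(0, end - start - length + 1))
        regions.append(Region(chrom, s, s + length, name=f"{label}_{i}"))
    return RegionSet(regions, label=label)


def simulate_proteomics(cfg: SimConfig) -> tuple[pd.DataFrame, SimTruth]:
    """Two-contrast ratio table with a planted replicate-consistent subset.

    Consistent proteins: log phi = log beta + eps, eps ~ N(0, sd) with sd small
    enough that |phi/beta - 1| <= 0.1 with probability >= 0.95.  Discrepant
    proteins are drawn with |phi/beta - 1| > 0.1 (margin 1.15x to 1.6x).
    """
    rng = np.random.default_rng([cfg.seed, 5])
    n = cfg.n_proteins
    ids = [f"P{i:05d}" for i in range(n)]
    n_cons = int(round(cfg.frac_consistent * n))
    consistent = np.zeros(n, dtype=bool)
    consistent[rng.choice(n, size=n_cons, replace=False)] = True
    beta = np.exp(rng.normal(0.0, 0.3, size=n))
    log_delta = np.where(
        consistent,
        rng.normal(0.0, cfg.protein_noise_sd, size=n),
        rng.choice([-1.0, 1.0], size=n) * rng.uniform(np.log(1.15), np.log(1.6), size=n),
    )
    phi = beta * np.exp(log_delta)
    table = pd.DataFrame({"phi": phi, "beta": beta}, index=pd.Index(ids, name="id"))
    truth = SimTruth(consistent_proteins=[ids[i] for i in range(n) if consistent[i]], seed=cfg.seed)
    return table, truth


def simulate_mirna(cfg: SimConfig, samples_per_condition: int = 2) -> tuple[CountMatrix, SimTruth]:
    """Batch-confounded small-RNA counts with a planted reproducible subset.

    Reproducible features keep one fold-change sign in every batch;
    the remaining expressed features get batch-specific (flipping) signs.
    Library depths differ >= 2x across batches; a low-count fraction is
    planted below the coverage filter.
    """
    rng = np.random.default_rng([cfg.seed, 6])
    n = cfg.n_mirna
    B = cfg.n_mirna_batches
    ids = [f"mir{i:04d}" for i in range(n)]
    n_low = int(round(cfg.mirna_low_frac * n))
    n_rep = int(round(cfg.frac_reproducible * (n - n_low)))
    order = rng.permutation(n)
    low = np.zeros(n, dtype=bool)
    low[order[:n_low]] = True
    rep = np.zeros(n, dtype=bool)
    rep[order[n_low:n_low + n_rep]] = True

    base = np.where(low, rng.uniform(2, 20, size=n), np.exp(rng.uniform(np.log(200), np.log(3000), size=n)))
    magnitude = rng.uniform(0.8, 1.5, size=n)
    rep_sign = rng.choice([-1.0, 1.0], size=n)
    # batch-specific signs for non-reproducible features: force >= 1 flip
    signs = np.tile(rep_sign[:, None], (1, B))
    nonrep = ~rep
    flip_batch = rng.integers(0, B, size=n)
    for b in range(B):
        flip = nonrep & (flip_batch == b)
        signs[flip, b] = -signs[flip, b]
    batch_wobble = np.exp(rng.normal(0.0, 0.4, size=(n, B)))
    depth = 2.0 ** np.arange(B)

    cols, groups, batches = {}, {}, {}
    for b in range(B):
        bname = f"B{b + 1}"
        for grp, tag in ((GROUP_TEST, "EE"), (GROUP_REF, "CTL")):
            for r in range(samples_per_condition):
                sname = f"{tag}_{bname}_{r + 1}"
                mu = base * batch_wobble[:, b] * depth[b]
                if grp == GROUP_TEST:
                    mu = mu * 2.0 ** (signs[:, b] * magnitude)
                cols[sname] = _nb_draw(rng, mu, 0.05)
                groups[sname] = grp
                batches[sname] = bname
    df = pd.DataFrame(cols, index=pd.Index(ids, name="id"))
    truth = SimTruth(reproducible_mirnas=[ids[i] for i in range(n) if rep[i]], seed=cfg.seed)
    return CountMatrix(df, groups, batches), truth


def simulate_links_expression(cfg: SimConfig, n_samples: int = 2):
    """Linked enhancer/promoter RPKM matrices and gene fold changes with
    correlation ``link_rho`` between aggregated region log2FC and gene log2FC.

    Returns (links frame, region RPKM test, region RPKM ref, gene fc Series, truth).
    """
    rng = np.random.default_rng([cfg.seed, 7])
    n = cfg.n_genes
    genes = [f"G{i:05d}" for i in range(n)]
    rho = cfg.link_rho
    cov = np.array([[1.0, rho], [rho, 1.0]])
    latent = rng.multivariate_normal([0.0, 0.0], cov, size=n)
    region_fc = latent[:, 0] * 0.6          # log2 scale
    gene_fc = latent[:, 1] * 0.8

    link_rows = []
    rpkm_test_rows, rpkm_ref_rows, region_ids = [], [], []
    for gi, g in enumerate(genes):
        n_enh = int(rng.integers(1, 3))
        kinds = ["enhancer"] * n_enh + ["promoter"]
        for ri, kind in enumerate(kinds):
            rid = f"{g}_{kind[:3]}{ri}"
            link_rows.append({"region_id": rid, "gene_id": g, "class": kind})
            base = float(np.exp(rng.normal(np.log(50.0), 0.5)))
            ref_vals = base * np.exp(rng.normal(0.0, 0.05, size=n_samples))
            test_vals = base * (2.0 ** region_fc[gi]) * np.exp(rng.normal(0.0, 0.05, size=n_samples))
            region_ids.append(rid)
            rpkm_ref_rows.append(ref_vals)
            rpkm_test_rows.append(test_vals)
    links = pd.DataFrame(link_rows)
    idx = pd.Index(region_ids, name="region_id")
    cols_t = [f"EE{i + 1}" for i in range(n_samples)]
    cols_r = [f"CTL{i + 1}" for i in range(n_samples)]
    rpkm_test = pd.DataFrame(rpkm_test_rows, index=idx, columns=cols_t)
    rpkm_ref = pd.DataFrame(rpkm_ref_rows, index=idx, columns=cols_r)
    gene_fc_series = pd.Series(gene_fc, index=pd.Index(genes, name="gene_id"), name="log2FC")
    truth = SimTruth(link_rho=rho, seed=cfg.seed)
    return links, rpkm_test, rpkm_ref, gene_fc_series, truth


def simulate_mark_bin_counts(truth: SimTruth, bins: GenomeBins, cfg: SimConfig,
                             mu0: float = 300.0, fold: float = 3.0,
                             n_diff: int = 10, phi: float = 0.02) -> tuple[CountMatrix, list[int]]:
    """Per-bin coverage counts with differential bins planted inside the hub.

    Feature ids are global bin indices of ``bins``; ``n_diff`` hub bins get
    mean * fold in test samples.  Returns (CountMatrix, planted bin ids).
    """
    rng = np.random.default_rng([cfg.seed, 9])
    samples, groups, batches = _sample_names(cfg)
    b_s = np.array([truth.batch_factors.get(s, 0.0) for s in samples])
    n = bins.n_bins
    hub = sorted(b for b in truth.hub_bins() if b < n)
    planted = sorted(rng.choice(hub, size=min(n_diff, len(hub)), replace=False).tolist()) if hub else []
    base = mu0 * np.exp(rng.normal(0.0, 0.2, size=n))
    u = rng.uniform(0.0, 2.0, size=n)
    fold_vec = np.ones(n)
    fold_vec[planted] = fold
    cols = {}
    for s, b in zip(samples, b_s):
        mu = base * np.exp(b * u)
        if groups[s] == GROUP_TEST:
            mu = mu * fold_vec
        cols[s] = _nb_draw(rng, mu, phi)
    df = pd.DataFrame(cols, index=pd.Index(np.arange(n), name="bin"))
    return CountMatrix(df, groups, batches), [int(p) for p in planted]


def simulate_batch_counts(n_features: int = 1000, n_per_group: int = 2,
                          batch_scale: float = 0.5, phi: float = 0.05,
                          n_controls: int = 100, mu0: float = 200.0,
                          group_effect: float = 0.0, seed: int = 0):
    """Counts with a planted multiplicative batch factor orthogonal to group.

    Used to validate unwanted-variation factor recovery.  Controls (first
    ``n_controls`` features) carry the batch loading but no group effect.
    Returns (CountMatrix, control ids, planted per-sample batch values).
    """
    rng = np.random.default_rng([seed, 8])
    samples = [f"EE{i + 1}" for i in range(n_per_group)] + [f"CTL{i + 1}" for i in range(n_per_group)]
    groups = {s: (GROUP_TEST if s.startswith("EE") else GROUP_REF) for s in samples}
    b = np.array([(1.0 if i % 2 == 0 else -1.0) for i in range(len(samples))]) * batch_scale
    base = np.exp(rng.normal(np.log(mu0), 0.5, size=n_features))
    u = rng.uniform(0.5, 1.5, size=n_features)
    de = np.zeros(n_features)
    if group_effect:
        hit = rng.choice(np.arange(n_controls, n_features), size=max(1, n_features // 10), replace=False)
        de[hit] = group_effect * rng.choice([-1.0, 1.0], size=len(hit))
    cols = {}
    for si, s in enumerate(samples):
        mu = base * np.exp(b[si] * u)
        if groups[s] == GROUP_TEST:
            mu = mu * 2.0 ** de
        cols[s] = _nb_draw(rng, mu, phi)
    ids = [f"f{i:05d}" for i in range(n_features)]
    df = pd.DataFrame(cols, index=pd.Index(ids, name="id"))
    controls = ids[:n_controls]
    batches = {s: ("A" if i % 2 == 0 else "B") for i, s in enumerate(samples)}
    return CountMatrix(df, groups, batches), controls, dict(zip(samples, b))
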