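"""Region-to-gene fold-change aggregation and correlation with expression changes.

Region (enhancer/promoter) activity RPKM is averaged within condition, then
across the regions linked to each target gene, and only then turned into a
fold change (average-then-FC).  Gene-level fold changes are correlated with
transcriptomic or proteomic fold changes by Pearson and Spearman; the
headline coefficient is Pearson for transcript targets and Spearman for
protein targets, whose fold-change scale is outlier-prone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class LinkCorResult:
    label: str
    region_class: str           # 'enhancer' | 'promoter'
    n_genes: int
    pearson_r: float
    pearson_p: float
    spearman_rho: float
    spearman_p: float
    headline: str               # 'pearson' | 'spearman'

    def to_dict(self) -> dict:
        return self.__dict__.copy()


def read_link_table(path) -> pd.DataFrame:
    """TSV with columns (region_id, gene_id, class)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    need = {"region_id", "gene_id"}
    if not need <= set(df.columns):
        raise ValueError("link table needs columns region_id, gene_id")
    if "class" not in df.columns:
        df["class"] = "enhancer"
    return df


def aggregate_fc_by_gene(region_rpkm_test: pd.DataFrame, region_rpkm_ref: pd.DataFrame,
                         links: pd.DataFrame, pseudocount: float = 0.25) -> pd.Series:
    """Per-gene log2 fold change of linked-region activity.

    Order of operations (fixed): samples are averaged within condition, the
    linked regions of each gene are averaged, and the fold change
    log2((test + pc) / (ref + pc)) is taken last.  Genes whose linked regions
    are all absent from the activity matrices are skipped.
    """
    mean_test = region_rpkm_test.mean(axis=1)
    mean_ref = region_rpkm_ref.mean(axis=1)
    out = {}
    for gene, sub in links.groupby("gene_id"):
        regions = [r for r in sub["region_id"] if r in mean_test.index]
        if not regions:
            continue
        t = mean_test.loc[regions].mean()
        r = mean_ref.loc[regions].mean()
        out[gene] = np.log2((t + pseudocount) / (r + pseudocount))
    return pd.Series(out, name="region_log2FC")


def correlate_fc(gene_fc: pd.Series, target_fc: pd.Series,
                 target_kind: str = "transcript", label: str = "",
                 region_class: str = "enhancer") -> LinkCorResult:
    """Pearson and Spearman correlation of two per-gene fold-change vectors.

    Computed on the gene intersection (>= 3 genes required); the headline
    method follows the target kind ('transcript' -> Pearson,
    'protein' -> Spearman).
    """
    common = gene_fc.index.intersection(target_fc.index)
    if len(common) < 3:
        raise ValueError(f"only {len(common)} genes in common; need >= 3")
    x = gene_fc.loc[common].to_numpy(dtype=float)
    y = target_fc.loc[common].to_numpy(dtype=float)
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero-variance fold-change vector")
    pr = stats.pearsonr(x, y)
    sr = stats.spearmanr(x, y)
    headline = "spearman" if target_kind == "protein" else "pearson"
    return LinkCorResult(label, region_class, len(common),
                         float(pr.statistic), float(pr.pvalue),
                         float(sr.statistic), float(sr.pvalue), headline)


def link_correlation_analysis(region_rpkm_test: pd.DataFrame, region_rpkm_ref: pd.DataFrame,
                              links: pd.DataFrame, target_fc: pd.Series,
                              target_kind: str = "transcript", label: str = "",
                              pseudocount: float = 0.25,
                              de_genes: pd.Index | None = None) -> list[LinkCorResult]:
    """One correlation per region class; restricted to ``de_genes`` when given."""
    results = []
    for cls, sub in links.groupby("class"):
        gene_fc = aggregate_fc_by_gene(region_rpkm_test, region_rpkm_ref, sub, pseudocount)
        if de_genes is not None:
            gene_fc = gene_fc[gene_fc.index.isin(de_genes)]
        results.append(correlate_fc(gene_fc, target_fc, target_kind, label, str(cls)))
    return results
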