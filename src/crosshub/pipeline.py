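"""Pipeline orchestration: config validation, stage execution, run summary.

Stages run in order bin -> filter -> differential contacts -> differential
mark bins -> permutation association -> delta selection -> small-RNA
consensus -> link correlation.  Stages whose inputs are absent are skipped;
a stage error marks dependent stages skipped while independent stages still
run.  Everything is deterministic given the master seed (stage seeds derive
from it by fixed offsets).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .genome import (DEFAULT_EXCLUDE, Region, RegionSet, load_chrom_sizes, make_bins,
                     read_bed, region_bins, write_bed)
from .contacts import bin_contacts, filter_contacts, merge_samples, read_valid_pairs_frame
from .diffcounts import (CountMatrix, diff_contact_analysis, diff_mark_bins,
                         read_counts_tsv, write_counts_tsv)
from .linkcor import link_correlation_analysis, read_link_table
from .mirna import mirna_pipeline
from .permutation import associate_all
from .proteomics import delta_analysis, read_ratio_table
from .simulate import (SimConfig, simulate_hic, simulate_links_expression,
                       simulate_mark_bin_counts, simulate_mark_regions,
                       simulate_mirna, simulate_proteomics)

STAGE_SEED_OFFSETS = {"assoc": 100}


@dataclass
class PipelineConfig:
    chrom_sizes: str | None = None
    valid_pairs: dict = field(default_factory=dict)   # sample -> {path, group, batch}
    feature_beds: list = field(default_factory=list)
    mark_counts: str | None = None
    mirna_counts: str | None = None
    ratio_table: str | None = None
    link_table: str | None = None
    region_rpkm_test: str | None = None
    region_rpkm_ref: str | None = None
    gene_fc: str | None = None
    # parameters (defaults are the published operating points)
    w_intra: int = 100_000
    w_inter: int = 1_000_000
    fdr_contacts: float = 0.05
    fdr_intersect: float = 0.1
    n_perm: int = 100_000
    delta_tol: float = 0.1
    mirna_min_count: float = 50
    k_ruv: int = 1
    min_total: int = 0
    exclude: list = field(default_factory=lambda: list(DEFAULT_EXCLUDE))
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**data)
        cfg.validate(base=Path(path).parent)
        return cfg

    def validate(self, base: Path | None = None) -> None:
        def resolve(p):
            p = Path(p)
            return p if p.is_absolute() or base is None else base / p

        for name in ("chrom_sizes", "mark_counts", "mirna_counts", "ratio_table",
                     "link_table", "region_rpkm_test", "region_rpkm_ref", "gene_fc"):
            p = getattr(self, name)
            if p is not None:
                rp = resolve(p)
                if not rp.exists():
                    raise FileNotFoundError(f"config path {name}={p} does not exist")
                setattr(self, name, str(rp))
        for s, spec in self.valid_pairs.items():
            rp = resolve(spec["path"])
            if not rp.exists():
                raise FileNotFoundError(f"valid pairs for {s}: {spec['path']} does not exist")
            spec["path"] = str(rp)
        self.feature_beds = [str(resolve(p)) for p in self.feature_beds]
        for p in self.feature_beds:
            if not Path(p).exists():
                raise FileNotFoundError(f"feature BED {p} does not exist")
        if not 0 < self.fdr_contacts < 1 or not 0 < self.fdr_intersect < 1:
            raise ValueError("FDR thresholds must be in (0, 1)")
        if self.w_intra < 1 or self.w_inter < 1 or self.n_perm < 1:
            raise ValueError("widths and n_perm must be positive")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_all(config: PipelineConfig, out_dir) -> dict:
    """Execute every stage with available inputs; returns the run summary dict."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"version": __version__, "seed": config.seed, "stages": {}}
    outputs: list[Path] = []

    def record(stage, status, **extra):
        summary["stages"][stage] = {"status": status, **extra}

    inter_filtered = intra_filtered = None
    # --- contacts -----------------------------------------------------------
    if config.chrom_sizes and config.valid_pairs:
        try:
            sizes = load_chrom_sizes(config.chrom_sizes)
            intra_tabs, inter_tabs, groups, batches = [], [], {}, {}
            dropped = {}
            for s, spec in sorted(config.valid_pairs.items()):
                df = read_valid_pairs_frame(spec["path"])
                ti, te, nd = bin_contacts(df, sizes, config.w_intra, config.w_inter,
                                          config.exclude, sample=s)
                intra_tabs.append(ti)
                inter_tabs.append(te)
                dropped[s] = nd
                groups[s] = spec["group"]
                batches[s] = spec.get("batch", "A")
            intra = merge_samples(intra_tabs, groups, batches)
            inter = merge_samples(inter_tabs, groups, batches)
            intra_filtered, rep_i = filter_contacts(intra, config.min_total)
            inter_filtered, rep_e = filter_contacts(inter, config.min_total)
            record("hic_bin", "ok", dropped=dropped,
                   intra_rows=len(intra_filtered.df), inter_rows=len(inter_filtered.df),
                   filter_intra=rep_i, filter_inter=rep_e)
        except Exception as exc:   # noqa: BLE001 - stage isolation
            record("hic_bin", "error", message=str(exc))
    else:
        record("hic_bin", "skipped")

    diff_results = {}
    for klass, table in (("intra", intra_filtered), ("inter", inter_filtered)):
        stage = f"diff_{klass}"
        if table is None:
            record(stage, "skipped")
            continue
        try:
            res, info = diff_contact_analysis(table, k=config.k_ruv, fdr=config.fdr_contacts)
            path = out / f"diff_{klass}.tsv"
            res.to_csv(path, sep="\t")
            outputs.append(path)
            diff_results[klass] = res
            record(stage, "ok", **info, output=path.name)
        except Exception as exc:   # noqa: BLE001
            record(stage, "error", message=str(exc))

    # --- differential mark bins --------------------------------------------
    mark_up = mark_down = None
    if config.mark_counts and config.chrom_sizes:
        try:
            cm = read_counts_tsv(config.mark_counts)
            sizes = load_chrom_sizes(config.chrom_sizes)
            bins = make_bins(sizes, config.w_inter, config.exclude)
            res, mark_up, mark_down = diff_mark_bins(cm, bins, k=config.k_ruv,
                                                     fdr=config.fdr_contacts)
            path = out / "diff_mark_bins.tsv"
            res.to_csv(path, sep="\t")
            outputs.append(path)
            for regs, nm in ((mark_up, "mark_bins_up.bed"), (mark_down, "mark_bins_down.bed")):
                p = out / nm
                write_bed(regs, p)
                outputs.append(p)
            record("diff_mark_bins", "ok", n_up=len(mark_up), n_down=len(mark_down))
        except Exception as exc:   # noqa: BLE001
            record("diff_mark_bins", "error", message=str(exc))
    else:
        record("diff_mark_bins", "skipped")

    # --- permutation association -------------------------------------------
    if "inter" in diff_results and config.feature_beds and config.chrom_sizes:
        try:
            sizes = load_chrom_sizes(config.chrom_sizes)
            bins = make_bins(sizes, config.w_inter, config.exclude)
            res = diff_results["inter"]
            sig = res[res["increased"] | res["decreased"]]
            qbins = sorted({int(b) for pair in zip(
                sig.index.get_level_values(0), sig.index.get_level_values(1)) for b in pair})
            if not qbins:
                record("assoc", "skipped", message="no differential inter bins")
            else:
                feature_sets = [read_bed(p, label=Path(p).stem) for p in config.feature_beds]
                assoc = associate_all(qbins, feature_sets, bins, n_perm=config.n_perm,
                                      seed=config.seed + STAGE_SEED_OFFSETS["assoc"])
                path = out / "association.tsv"
                assoc.to_csv(path, sep="\t", index=False)
                outputs.append(path)
                record("assoc", "ok", n_query_bins=len(qbins),
                       labels=list(assoc["label"]), p=[float(x) for x in assoc["p_empirical"]])
        except Exception as exc:   # noqa: BLE001
            record("assoc", "error", message=str(exc))
    else:
        record("assoc", "skipped")

    # --- proteomics delta ---------------------------------------------------
    if config.ratio_table:
        try:
            table = read_ratio_table(config.ratio_table)
            dres = delta_analysis(table, tolerance=config.delta_tol)
            path = out / "delta.tsv"
            dres.table.to_csv(path, sep="\t")
            outputs.append(path)
            record("delta", "ok", n_consistent=len(dres.consistent_ids),
                   n_discrepant=len(dres.discrepant_ids), n_excluded=len(dres.excluded))
        except Exception as exc:   # noqa: BLE001
            record("delta", "error", message=str(exc))
    else:
        record("delta", "skipped")

    # --- small RNA consensus ------------------------------------------------
    if config.mirna_counts:
        try:
            cm = read_counts_tsv(config.mirna_counts)
            mres, info = mirna_pipeline(cm, min_count=config.mirna_min_count)
            path = out / "mirna.tsv"
            mres.table.to_csv(path, sep="\t")
            outputs.append(path)
            record("mirna", "ok", **info)
        except Exception as exc:   # noqa: BLE001
            record("mirna", "error", message=str(exc))
    else:
        record("mirna", "skipped")

    # --- link correlation ---------------------------------------------------
    if config.link_table and config.region_rpkm_test and config.region_rpkm_ref and config.gene_fc:
        try:
            links = read_link_table(config.link_table)
            rt = pd.read_csv(config.region_rpkm_test, sep="\t", index_col=0, comment="#")
            rr = pd.read_csv(config.region_rpkm_ref, sep="\t", index_col=0, comment="#")
            gfc = pd.read_csv(config.gene_fc, sep="\t", index_col=0, comment="#").iloc[:, 0]
            results = link_correlation_analysis(rt, rr, links, gfc)
            path = out / "link_correlation.tsv"
            pd.DataFrame([r.to_dict() for r in results]).to_csv(path, sep="\t", index=False)
            outputs.append(path)
            record("linkcor", "ok",
                   pearson={r.region_class: r.pearson_r for r in results})
        except Exception as exc:   # noqa: BLE001
            record("linkcor", "error", message=str(exc))
    else:
        record("linkcor", "skipped")

    summary["checksums"] = {p.name: _sha256(p) for p in outputs}
    summary["n_errors"] = sum(1 for s in summary["stages"].values() if s["status"] == "error")
    (out / "run_summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    return summary


def simulate_dataset(cfg: SimConfig, out_dir, null: bool = False, force: bool = False) -> Path:
    """Emit every input ``run_all`` consumes plus truth sidecars and a config YAML."""
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(f"{out} exists and is not empty (use force)")
    out.mkdir(parents=True, exist_ok=True)
    if null:
        cfg = dataclasses.replace(cfg, hub_fold=1.0, link_rho=0.0)

    sim = simulate_hic(cfg, out_dir=out)
    bins_inter = make_bins(sim.sizes, cfg.w_inter)

    feature_beds = []
    # keep feature sets sparse relative to the universe so the association
    # statistic cannot saturate on small test genomes
    n_regions = max(10, bins_inter.n_bins // 3)
    for label, p_hub in (("mark_hub", 0.0 if null else 0.8), ("mark_random", 0.0)):
        regs = simulate_mark_regions(sim.truth, bins_inter, n_regions=n_regions,
                                     p_in_hub=p_hub, seed=cfg.seed, label=label)
        p = out / f"{label}.bed"
        write_bed(regs, p)
        feature_beds.append(p.name)

    mark_cm, planted_bins = simulate_mark_bin_counts(sim.truth, bins_inter, cfg,
                                                     n_diff=0 if null else 10)
    write_counts_tsv(mark_cm, out / "mark_bin_counts.tsv")
    (out / "mark_bins_truth.json").write_text(json.dumps({"planted_bins": planted_bins}))

    prot, prot_truth = simulate_proteomics(cfg)
    prot.to_csv(out / "protein_ratios.tsv", sep="\t")
    prot_truth.to_json(out / "protein_truth.json")

    mirna_cm, mirna_truth = simulate_mirna(cfg)
    write_counts_tsv(mirna_cm, out / "mirna_counts.tsv")
    mirna_truth.to_json(out / "mirna_truth.json")

    links, rt, rr, gfc, link_truth = simulate_links_expression(cfg)
    links.to_csv(out / "links.tsv", sep="\t", index=False)
    rt.to_csv(out / "region_rpkm_EE.tsv", sep="\t")
    rr.to_csv(out / "region_rpkm_CTL.tsv", sep="\t")
    gfc.to_frame().to_csv(out / "gene_fc.tsv", sep="\t")
    link_truth.to_json(out / "link_truth.json")

    config = PipelineConfig(
        chrom_sizes="chrom.sizes",
        valid_pairs={s: {"path": p.name, "group": sim.inter.groups[s],
                         "batch": sim.inter.batches[s]}
                     for s, p in sim.pair_files.items()},
        feature_beds=feature_beds,
        mark_counts="mark_bin_counts.tsv",
        mirna_counts="mirna_counts.tsv",
        ratio_table="protein_ratios.tsv",
        link_table="links.tsv",
        region_rpkm_test="region_rpkm_EE.tsv",
        region_rpkm_ref="region_rpkm_CTL.tsv",
        gene_fc="gene_fc.tsv",
        w_intra=cfg.w_intra,
        w_inter=cfg.w_inter,
        seed=cfg.seed,
    )
    cfg_path = out / "config.yaml"
    cfg_path.write_text(yaml.safe_dump(dataclasses.asdict(config), sort_keys=True))
    return cfg_path
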