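"""End-to-end orchestration: diversity -> ordination -> flavor stats ->
O2PLS/VIP -> correlation network -> core screen, driven by one config.

A run directory receives one artifact per stage plus a manifest JSON
(config hash, seed, package version); re-running the same config and
seed reproduces every output bit-identically apart from timestamps.
The single config seed fans out to per-stage seeds by stable hashing of
the stage name, so adding a stage never perturbs earlier stages.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .community import hellinger_distance, bray_curtis, hca, pcoa, permanova
from .diversity import alpha_diversity_table
from .flavor import flavor_category_counts, pca_fit, pca_q2, taste_class_sums
from .network import correlate, export_network, partner_summary, screen_core, threshold_network
from .o2pls import cross_validate, fit_o2pls, vip_pred
from .simulate import generate_dataset, sample_counts
from .tables import (
    AbundanceTable,
    FlavorTable,
    read_abundance_table,
    read_flavor_table,
    to_relative_abundance,
    write_abundance_table,
    write_flavor_table,
)

__all__ = ["PipelineConfig", "run_pipeline", "stage_seed"]


@dataclass
class PipelineConfig:
    """Everything one analysis run needs; exactly one of input paths / simulate."""

    abundance_path: str | None = None
    flavor_path: str | None = None
    annotation_path: str | None = None
    simulate: dict | None = None  # kwargs for generate_dataset
    metric: str = "hellinger"
    n_perm: int = 999
    o2pls: dict = field(default_factory=lambda: {"K": 2, "nx": 1, "ny": 1})
    cv: bool = False
    correlation_method: str = "pearson"
    thresholds: tuple = (0.7, 0.8)
    vip_cut: float = 1.00
    partner_cut: int = 16
    seed: int = 0
    out_dir: str = "fermcore_run"

    def __post_init__(self) -> None:
        has_paths = self.abundance_path is not None or self.flavor_path is not None
        if has_paths == (self.simulate is not None):
            raise ValueError("config needs exactly one of input paths or a simulate spec")
        for c in self.thresholds:
            if not 0 < c < 1:
                raise ValueError(f"threshold {c} outside (0, 1)")
        if self.vip_cut < 0:
            raise ValueError("vip_cut must be non-negative")
        if self.partner_cut < 0:
            raise ValueError("partner_cut must be non-negative")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "thresholds" in raw:
            raw["thresholds"] = tuple(raw["thresholds"])
        return cls(**raw)


def stage_seed(base_seed: int, stage: str) -> int:
    """Derive a per-stage seed by stable hashing; independent of stage order."""
    digest = hashlib.sha256(f"{base_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _load_inputs(cfg: PipelineConfig, out: Path):
    if cfg.simulate is not None:
        abundance, flavor, truth = generate_dataset(
            **{**cfg.simulate, "seed": cfg.simulate.get("seed", cfg.seed)}
        )
        truth_json = {
            "planted_core": truth.planted_core,
            "K": truth.K, "nx": truth.nx, "ny": truth.ny,
            "noise_sd": truth.noise_sd, "seed": truth.seed,
            "n_samples": truth.n_samples, "n_taxa": truth.n_taxa,
        }
        (out / "truth.json").write_text(json.dumps(truth_json, indent=2))
        write_abundance_table(abundance, out / "abundance.tsv")
        write_flavor_table(flavor, out / "flavor.tsv")
        return abundance, flavor
    if cfg.abundance_path is None or cfg.flavor_path is None:
        raise FileNotFoundError("both abundance_path and flavor_path are required")
    for p in (cfg.abundance_path, cfg.flavor_path):
        if not Path(p).exists():
            raise FileNotFoundError(f"input file not found: {p}")
    from .tables import load_flavor_annotation

    ann = load_flavor_annotation(cfg.annotation_path)
    abundance = read_abundance_table(cfg.abundance_path)
    flavor = read_flavor_table(cfg.flavor_path, annotation=ann)
    return abundance, flavor


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage, write artifacts under ``cfg.out_dir``, return the report."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines = []

    def log(stage, t0):
        log_lines.append(f"{stage}\t{time.time() - t0:.3f}s")

    t0 = time.time()
    abundance, flavor = _load_inputs(cfg, out)
    log("load", t0)

    report: dict = {"stages": {}}

    # 1. alpha diversity (on counts; proportions tables are resampled to counts)
    t0 = time.time()
    if abundance.proportions:
        counts = sample_counts(abundance, depth=10000, seed=stage_seed(cfg.seed, "diversity"))
    else:
        counts = abundance
    div = alpha_diversity_table(counts.data)
    div.to_csv(out / "diversity.tsv", sep="\t")
    report["stages"]["diversity"] = {"mean_shannon": float(div.loc["Mean", "Shannon"])}
    log("diversity", t0)

    # 2. ordination + PERMANOVA
    t0 = time.time()
    rel = abundance if abundance.proportions else to_relative_abundance(abundance)
    dist = hellinger_distance(rel) if cfg.metric == "hellinger" else bray_curtis(rel)
    ord_res = pcoa(dist, n_axes=min(2, dist.n - 1))
    ord_res.coordinates.to_csv(out / "pcoa_coordinates.tsv", sep="\t")
    tree = hca(dist)
    (out / "dendrogram.nwk").write_text(tree.newick + "\n")
    groups = abundance.groups
    if groups is None:
        groups = tree.cut(2)
    perm = permanova(dist, groups, n_perm=cfg.n_perm, seed=stage_seed(cfg.seed, "permanova"))
    report["stages"]["ordination"] = {
        "pc1_variance": float(ord_res.variance_fraction[0]),
        "permanova_p": perm.p_value,
        "permanova_F": perm.pseudo_f,
        "groups": {str(k): int(v) if not isinstance(v, str) else v for k, v in groups.items()},
    }
    log("ordination", t0)

    # 3. flavor PCA / Q2 / taste classes / category counts
    t0 = time.time()
    pca = pca_fit(flavor)
    pca.scores.to_csv(out / "flavor_pca_scores.tsv", sep="\t")
    q2 = pca_q2(flavor, seed=stage_seed(cfg.seed, "flavor_q2"))
    q2.to_csv(out / "flavor_pca_q2.tsv", sep="\t")
    cats = flavor_category_counts(flavor.annotation)
    taste = taste_class_sums(flavor)
    taste.sums.to_csv(out / "taste_classes.tsv", sep="\t")
    report["stages"]["flavor"] = {
        "cum_r2x_2": float(pca.cum_r2x[min(1, len(pca.cum_r2x) - 1)]),
        "category_counts": {k: int(v) for k, v in cats.items()},
    }
    log("flavor", t0)

    # 4. O2PLS + VIP
    t0 = time.time()
    x = rel.data
    y = flavor.data
    if cfg.cv:
        cv_table, (k, nx, ny) = cross_validate(
            x, y, seed=stage_seed(cfg.seed, "o2pls_cv")
        )
        cv_table.to_csv(out / "o2pls_cv.tsv", sep="\t", index=False)
    else:
        k, nx, ny = cfg.o2pls["K"], cfg.o2pls["nx"], cfg.o2pls["ny"]
    model = fit_o2pls(x, y, K=k, nx=nx, ny=ny)
    vip = vip_pred(model).sort_values(ascending=False)
    vip.to_csv(out / "vip_pred.tsv", sep="\t")
    report["stages"]["o2pls"] = {
        "K": k, "nx": nx, "ny": ny,
        "R2X": model.r2x, "R2Y": model.r2y,
        "n_vip_above_1": int((vip > 1.0).sum()),
    }
    log("o2pls", t0)

    # 5. correlation networks
    t0 = time.time()
    r = correlate(rel, flavor, method=cfg.correlation_method)
    nets = {}
    for cutoff in cfg.thresholds:
        net = threshold_network(r, cutoff=cutoff, method=cfg.correlation_method)
        export_network(net, out / f"network_{cutoff}.tsv", format="edge_tsv")
        export_network(
            net, out / f"network_{cutoff}.graphml", format="graphml",
            annotation=flavor.annotation,
        )
        nets[cutoff] = net
    log("network", t0)

    # 6. core screen (on the lower threshold, per the screening rule)
    t0 = time.time()
    screen_net = nets[min(cfg.thresholds)]
    summary = partner_summary(screen_net, flavor.annotation)
    screening = screen_core(summary, vip, vip_cut=cfg.vip_cut, partner_cut=cfg.partner_cut)
    screening.table.to_csv(out / "core_screen.tsv", sep="\t")
    report["stages"]["screen"] = {
        "n_edges": {str(c): nets[c].n_edges for c in cfg.thresholds},
        "n_genera_aa": int((summary["n_aa"] >= 1).sum()),
        "n_genera_vf": int((summary["n_vf"] >= 1).sum()),
        "core": screening.core,
    }
    log("screen", t0)

    cfg_dict = asdict(cfg)
    cfg_dict["thresholds"] = list(cfg.thresholds)
    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "config": cfg_dict,
        "config_hash": hashlib.sha256(
            json.dumps(cfg_dict, sort_keys=True).encode()
        ).hexdigest(),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    (out / "report.json").write_text(json.dumps(report, indent=2, default=float))
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return report
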