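"""End-to-end orchestration: depth classification, site filtering,
imputation, network construction and rho dating, with a machine-readable
report."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .depth import DepthWindows, classify_sites, depth_report
from .filters import classify_titv_matrix, filter_sites, impute_missing
from .io import load_table1, read_call_table, read_haplotype_matrix, write_network
from .network import construct_mj_network
from .rho import clade_age, find_clade_ancestor, rho_estimate

#: populations on the North-American–Siberian side of the basal Y split
DEFAULT_CLADE_POPULATIONS = (
    "Yamal, Siberia",
    "Alaska, USA",
    "Bylott Island, Canada",
    "Eastern Canada",
    "Lassen Co, CA, USA",
    "Gunnison, CO, USA",
)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Configuration for a full run.

    ``matrix`` is either the literal string ``"table1"`` (the packaged
    panel) or a path to a haplotype TSV; ``vcf`` optionally adds a
    depth-classification stage.  ``windows`` is a (error_max, unique_max,
    two_paralog_max) triple or ``"auto"``.  ``clade_populations`` selects
    the nested clade whose age is estimated against ``t_total``.
    """

    matrix: str = "table1"
    sites_path: str | None = None
    samples_path: str | None = None
    vcf: str | None = None
    windows: tuple[int, int, int] | str = (9, 160, 210)
    epsilon: int = 0
    outgroup_age: float = 8.8e6
    t_total: float = 470_000.0
    seed: int = 0
    out_dir: str = "results"
    clade_populations: tuple[str, ...] = DEFAULT_CLADE_POPULATIONS
    network_panels: tuple[str, ...] = ("all_sites", "assayed_sites")

    def validate(self) -> None:
        paths = [self.sites_path, self.samples_path, self.vcf]
        if self.matrix != "table1":
            paths.append(self.matrix)
        for p in paths:
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"input file not found: {p}")
        if self.epsilon < 0:
            raise ValueError("epsilon must be non-negative")
        if self.outgroup_age <= 0 or self.t_total <= 0:
            raise ValueError("calibration ages must be positive")
        if self.windows != "auto":
            e, u, t = self.windows
            DepthWindows(error_max=e, unique_min=e + 1, unique_max=u,
                         two_paralog_max=t)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run all configured stages and write ``report.json`` to the output
    directory.  Partial outputs are preserved on stage failure."""
    cfg.validate()
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__,
        "parameters": {
            "matrix": cfg.matrix,
            "epsilon": cfg.epsilon,
            "outgroup_age_years": cfg.outgroup_age,
            "t_total_years": cfg.t_total,
            "windows": list(cfg.windows) if cfg.windows != "auto" else "auto",
            "seed": cfg.seed,
            "clade_populations": list(cfg.clade_populations),
        },
    }

    # -- depth classification (optional; needs a call table) ---------------
    if cfg.vcf is not None:
        try:
            table = read_call_table(cfg.vcf, format="vcf")
            if cfg.windows == "auto":
                from .depth import suggest_windows

                windows = suggest_windows(
                    [p.pooled_depth for p in table.profiles]
                )
            else:
                e, u, t = cfg.windows
                windows = DepthWindows(error_max=e, unique_min=e + 1,
                                       unique_max=u, two_paralog_max=t)
            labels, summary = classify_sites(table.profiles, windows)
            report["depth"] = {
                "windows": [windows.error_max, windows.unique_max,
                            windows.two_paralog_max],
                **depth_report(labels),
                "n_het_excluded": summary.n_het_excluded,
                "n_multiallelic": len(table.multiallelic_sites),
            }
        except Exception as exc:  # noqa: BLE001 - stage-named re-raise
            _flush(report, out_dir)
            raise PipelineError("classify-depth", str(exc)) from exc

    # -- haplotype matrix --------------------------------------------------
    try:
        if cfg.matrix == "table1":
            m = load_table1()
        else:
            m = read_haplotype_matrix(cfg.matrix, sites_path=cfg.sites_path,
                                      samples_path=cfg.samples_path)
    except Exception as exc:
        _flush(report, out_dir)
        raise PipelineError("load-matrix", str(exc)) from exc

    # -- site filtering ----------------------------------------------------
    try:
        sequenced = [s.identifier for s in m.samples if s.sequenced]
        _, variable = filter_sites(m, ingroup=sequenced)
        ti, tv = classify_titv_matrix(m)
        report["sites"] = {
            "n_sites": m.n_sites,
            "n_variable_in_sequenced": len(variable),
            "n_sequenced_samples": len(sequenced),
            "transitions": ti,
            "transversions": tv,
        }
    except Exception as exc:
        _flush(report, out_dir)
        raise PipelineError("filter-sites", str(exc)) from exc

    # -- networks + rho dating --------------------------------------------
    report["networks"] = {}
    for panel in cfg.network_panels:
        try:
            report["networks"][panel] = _network_stage(m, panel, cfg, out_dir)
        except Exception as exc:
            _flush(report, out_dir)
            raise PipelineError(f"mjn-{panel}", str(exc)) from exc

    _flush(report, out_dir)
    return report


def _network_stage(m, panel: str, cfg: PipelineConfig, out_dir: Path) -> dict:
    if panel == "all_sites":
        sub = m.sequenced_subset()
    elif panel == "assayed_sites":
        sub = m.assayed_subset()
    else:
        raise ValueError(f"unknown network panel {panel!r}")
    sub = impute_missing(sub)
    if sub.has_missing():
        # unimputable rows cannot enter the network
        keep = [s.identifier for i, s in enumerate(sub.samples)
                if not (sub.calls[i] == -1).any()]
        sub = sub.subset(samples=keep)
    net = construct_mj_network(sub, epsilon=cfg.epsilon)

    members_all = [s.identifier for s in sub.samples]
    members_clade = [
        s.identifier for s in sub.samples
        if s.population in cfg.clade_populations
    ]
    entry: dict = {
        "n_samples": sub.n_samples,
        "n_sites": sub.n_sites,
        "n_nodes": net.graph.number_of_nodes(),
        "n_median_nodes": len(net.median_nodes()),
        "n_edges": net.graph.number_of_edges(),
        "root_node": net.root,
    }
    rho_total = rho_estimate(net, net.root, members_all)
    entry["rho_total"] = {"rho": rho_total.rho, "sd": rho_total.sd,
                          "n": rho_total.n}
    if members_clade and len(members_clade) < len(members_all):
        anc = find_clade_ancestor(net, members_clade)
        rho_clade = rho_estimate(net, anc, members_clade)
        age = clade_age(rho_clade, rho_total, t_total=cfg.t_total)
        entry["rho_clade"] = {"rho": rho_clade.rho, "sd": rho_clade.sd,
                              "n": rho_clade.n, "ancestral_node": anc}
        entry["age_estimate"] = {
            "ratio": age.ratio, "t_total": age.t_total,
            "t_point": age.t_point, "t_low": age.t_low, "t_high": age.t_high,
        }
    write_network(net, out_dir / f"network_{panel}.graphml")
    return entry


def _flush(report: dict, out_dir: Path) -> None:
    with open(out_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
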