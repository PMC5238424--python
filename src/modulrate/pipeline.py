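"""Orchestration: one config in, one structured report out.

Stages run in a fixed order (io -> gpa -> transform -> modularity ->
integration -> rates -> clade rates -> skewers).  All randomness derives
from a single master seed through named substreams, so disabling one
stage never changes another stage's draws.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .covariation import cr_test, phylo_pls
from .evolvability import draw_skewers, evolutionary_pmatrix, skewer_indices
from .gpa import gpa, shape_pca
from .io import match_taxa, read_module_map, read_tps, read_tree
from .phylo import phylomorphospace
from .rates import clade_rates, compare_module_rates

__all__ = ["AnalysisConfig", "Report", "run_full_analysis"]

# fixed substream ids: toggling a stage off must not shift another stage's draws
_STAGE_STREAMS = {"modularity": 11, "integration": 12, "rates": 13, "clade_rates": 14, "skewers": 15}


def stage_seed(master_seed: int, stage: str) -> np.random.SeedSequence:
    return np.random.SeedSequence((int(master_seed), _STAGE_STREAMS[stage]))


@dataclass
class AnalysisConfig:
    tps: str
    tree: str
    modules: str
    clades: str | None = None
    tree_format: str = "newick"
    n_perm: int = 9999
    n_sim: int = 999
    n_skewers: int = 1000
    seed: int = 0
    output_dir: str = "modulrate_output"
    run_modularity: bool = True
    run_integration: bool = True
    run_rates: bool = True
    run_skewers: bool = True
    make_plots: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def validate(self) -> None:
        for name in ("tps", "tree", "modules"):
            p = getattr(self, name)
            if not Path(p).is_file():
                raise FileNotFoundError(f"config.{name}: no such file: {p}")
        if self.clades is not None and not Path(self.clades).is_file():
            raise FileNotFoundError(f"config.clades: no such file: {self.clades}")
        for name in ("n_perm", "n_sim", "n_skewers"):
            if getattr(self, name) < 1:
                raise ValueError(f"config.{name} must be >= 1")


@dataclass
class Report:
    config: dict
    provenance: dict
    results: dict = field(default_factory=dict)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {"config": self.config, "provenance": self.provenance, "results": self.results},
            indent=2,
            sort_keys=True,
            default=_jsonable,
        )
        if path is not None:
            Path(path).write_text(payload + "\n")
        return payload


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def _read_clades(path: str) -> dict[str, str]:
    df = pd.read_csv(path)
    if not {"species", "clade"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns species,clade")
    return dict(zip(df["species"].astype(str), df["clade"].astype(str)))


def run_full_analysis(config: AnalysisConfig) -> Report:
    """Run every enabled stage and write report.json plus CSV tables."""
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_dict = {k: getattr(config, k) for k in config.__dataclass_fields__}
    report = Report(
        config=cfg_dict,
        provenance={
            "package": "modulrate",
            "version": __version__,
            "seed": config.seed,
            "config_sha256": hashlib.sha256(
                json.dumps(cfg_dict, sort_keys=True).encode()
            ).hexdigest(),
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        },
    )

    stage = "io"
    try:
        dataset = read_tps(config.tps)
        tree = read_tree(config.tree, format=config.tree_format)
        modules = read_module_map(config.modules)
        if modules.n_landmarks != dataset.n_landmarks:
            raise ValueError(
                f"module map covers {modules.n_landmarks} landmarks, data has {dataset.n_landmarks}"
            )
        dataset, tree = match_taxa(dataset, tree, policy="intersect")
        report.results["io"] = {
            "n_specimens": dataset.n_specimens,
            "n_species": len(dataset.species),
            "n_landmarks": dataset.n_landmarks,
            "tree_ultrametric": tree.is_ultrametric,
        }

        stage = "gpa"
        t0 = time.perf_counter()
        aligned = gpa(dataset)
        space = shape_pca(aligned)
        report.results["gpa"] = {
            "converged": aligned.converged,
            "iterations": aligned.iterations_used,
            "pc_variance_proportions": space.proportion_variance[:5],
            "seconds": round(time.perf_counter() - t0, 3),
        }

        if config.run_modularity:
            stage = "modularity"
            t0 = time.perf_counter()
            mod = cr_test(
                aligned, tree, modules, n_perm=config.n_perm,
                seed=stage_seed(config.seed, "modularity"),
            )
            report.results["modularity"] = {
                "cr": mod.observed_cr,
                "p_value": mod.p_value,
                "n_permutations": mod.n_permutations,
                "exact": mod.exact,
                "permuted": mod.permuted,
                "seconds": round(time.perf_counter() - t0, 3),
            }

        if config.run_integration:
            stage = "integration"
            t0 = time.perf_counter()
            pls = phylo_pls(
                aligned, tree, modules, n_perm=config.n_perm,
                seed=stage_seed(config.seed, "integration"),
            )
            report.results["integration"] = {
                "r_pls": pls.r_pls,
                "p_value": pls.p_value,
                "percent_covariance": pls.percent_covariance,
                "scores_left": pls.scores_left,
                "scores_right": pls.scores_right,
                "permuted": pls.permuted,
                "seconds": round(time.perf_counter() - t0, 3),
            }

        clade_map = _read_clades(config.clades) if config.clades else None
        if config.run_rates:
            stage = "rates"
            t0 = time.perf_counter()
            rr = compare_module_rates(
                aligned, tree, modules, n_sim=config.n_sim,
                seed=stage_seed(config.seed, "rates"),
            )
            report.results["rates"] = {
                "rates": rr.rates,
                "ratio": rr.ratio,
                "ratio_labels": list(rr.ratio_labels),
                "p_value": rr.p_value,
                "null_ratios": rr.null_ratios,
                "seconds": round(time.perf_counter() - t0, 3),
            }
            if clade_map:
                stage = "clade_rates"
                ct = clade_rates(
                    aligned, tree, modules, clade_map, n_sim=config.n_sim,
                    seed=stage_seed(config.seed, "clade_rates"),
                )
                report.results["clade_rates"] = {
                    "clades": ct.clades,
                    "rates": ct.rates,
                    "ratios": ct.ratios,
                    "pairwise_p": {m: P for m, P in ct.pairwise_p.items()},
                    "excluded": ct.excluded,
                    "non_monophyletic": ct.non_monophyletic,
                }

        if config.run_skewers:
            stage = "skewers"
            t0 = time.perf_counter()
            skew = {}
            for m in modules.labels:
                P = evolutionary_pmatrix(aligned, tree, modules, m)
                betas = draw_skewers(
                    P.dim, config.n_skewers, seed=stage_seed(config.seed, "skewers")
                )
                skew[m] = skewer_indices(P, betas).summary
            report.results["skewers"] = {**skew, "n_skewers": config.n_skewers,
                                         "seconds": round(time.perf_counter() - t0, 3)}

        if config.make_plots:
            stage = "plots"
            from . import plotting

            plotting.report_plots(report, aligned, space, tree, outdir)
    except Exception as exc:
        report.provenance["failed_stage"] = stage
        report.to_json(outdir / "report.json")  # flush partial results
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    report.to_json(outdir / "report.json")
    _write_tables(report, outdir)
    return report


def _write_tables(report: Report, outdir: Path) -> None:
    res = report.results
    if "rates" in res:
        rows = []
        labels = res["rates"]["ratio_labels"]
        rows.append(
            {
                "clade": "all",
                f"{labels[0]}_sigma2": res["rates"]["rates"][labels[0]],
                f"{labels[1]}_sigma2": res["rates"]["rates"][labels[1]],
                "ratio": res["rates"]["ratio"],
                "p_value": res["rates"]["p_value"],
            }
        )
        for c in res.get("clade_rates", {}).get("clades", []):
            cr = res["clade_rates"]
            rows.append(
                {
                    "clade": c,
                    f"{labels[0]}_sigma2": cr["rates"][c][labels[0]],
                    f"{labels[1]}_sigma2": cr["rates"][c][labels[1]],
                    "ratio": cr["ratios"][c],
                    "p_value": np.nan,
                }
            )
        pd.DataFrame(rows).to_csv(outdir / "table1_rates.csv", index=False)
    if "skewers" in res:
        rows = []
        for module, summary in res["skewers"].items():
            if not isinstance(summary, dict):
                continue
            for statname in ("mean", "min", "max"):
                row = {"module": module, "statistic": statname}
                row.update({idx: summary[idx][statname] for idx in summary})
                rows.append(row)
        pd.DataFrame(rows).to_csv(outdir / "table2_evolvability.csv", index=False)
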