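"""End-to-end orchestration of the three analyses with seeded provenance.

A :class:`RunConfig` names either an input edge list or a synthetic
spec, toggles the three stages (mesoscale screen, triad significance
profile, evidence-bias analysis), and carries the per-stage parameters
and a master seed.  :func:`run` executes the requested stages in order,
writes every artifact as TSV/JSON into the output directory, and
returns a report bundle.  Identical config + seed give identical
bundles.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import numpy as np
import yaml

from . import __version__
from . import bias as _bias
from . import io as _io
from . import mesoscale as _meso
from . import motifs as _motifs
from . import synth as _synth
from .model import RegulatoryNetwork

__all__ = ["RunConfig", "StageError", "run", "load_config", "default_config"]

log = logging.getLogger("trntopo")


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    # exactly one of the two input sources
    input_edges: Optional[str] = None
    input_nodes: Optional[str] = None
    synthetic: Optional[dict] = None          # SyntheticSpec field overrides

    run_mesoscale: bool = True
    run_tsp: bool = True
    run_bias: bool = True

    # mesoscale parameters
    level: str = "DS"                         # projection screened
    r_min: float = -1.0
    r_max: float = 4.0
    n_points: int = 50
    min_run: Optional[int] = None
    n_restarts: int = 2

    # triad / null-model parameters
    R: int = 200
    n_switch_per_edge: int = 20

    # bias parameters
    exclude_sigma: bool = False

    seed: int = 0
    outdir: str = "trntopo_out"

    def validate(self) -> None:
        has_file = self.input_edges is not None
        has_synth = self.synthetic is not None
        if has_file == has_synth:
            raise ValueError(
                "config must name exactly one of input_edges / synthetic"
            )


def default_config() -> RunConfig:
    return RunConfig(synthetic={})


def load_config(path) -> RunConfig:
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)


def _json_default(o: Any):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON-serializable: {type(o)}")


def _write_json(payload: dict, path: Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True, default=_json_default)


def _zscore_table(z: _motifs.TriadZScores, tsp: Optional[_motifs.TSP], path: Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("triad\tcount\tnull_mean\tnull_std\tz\ttsp\n")
        for h in range(1, 14):
            zval = "undefined" if not z.is_defined(h) else f"{z[h]:.6g}"
            tval = ""
            if tsp is not None:
                tval = "undefined" if not tsp.defined()[h - 1] else f"{tsp[h]:.6g}"
            fh.write(
                f"{h}\t{z.counts[h]}\t{z.ensemble_mean[h-1]:.6g}\t"
                f"{z.ensemble_std[h-1]:.6g}\t{zval}\t{tval}\n"
            )


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            t0 = time.time()
            log.info("stage %s: start", name)
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raised with stage name
                raise StageError(f"stage {name!r} failed: {exc}") from exc
            log.info("stage %s: done in %.1fs", name, time.time() - t0)
            return out
        return wrapper
    return deco


@_stage("load")
def _load(config: RunConfig, outdir: Path) -> tuple[RegulatoryNetwork, Optional[_synth.GroundTruth]]:
    if config.synthetic is not None:
        spec = _synth.SyntheticSpec(**{"seed": config.seed, **config.synthetic})
        net, truth = _synth.generate(spec)
        _io.write_network(net, outdir / "network.tsv", outdir / "nodes.tsv")
        _synth.write_ground_truth(truth, outdir / "ground_truth.json")
        return net, truth
    net = _io.read_network(config.input_edges, config.input_nodes)
    return net, None


@_stage("mesoscale")
def _mesoscale(config: RunConfig, net: RegulatoryNetwork,
               truth, outdir: Path) -> dict:
    view = net.project(config.level)
    screen = _meso.screen_resolution(
        view, config.r_min, config.r_max, n_points=config.n_points,
        seed=config.seed, n_restarts=config.n_restarts,
    )
    plateaus = _meso.detect_plateaus(screen, min_run=config.min_run)

    functional = None
    try:
        keep = _meso.functional_node_filter(net)
        functional = _meso.Partition(
            {i: net.nodes[i].functional_category for i in keep}
        )
    except ValueError:
        log.info("no functional annotations; AW column skipped")

    with open(outdir / "mesoscale_screen.tsv", "w", encoding="utf-8") as fh:
        fh.write("r\tnormalized_r\tn_communities\tQ\tAW_functional\n")
        for p in screen.points:
            aw = ""
            if functional is not None:
                keep = functional.nodes
                aw_val = _meso.asymmetric_wallace(p.partition.restrict(keep), functional)
                aw = "" if aw_val is None else f"{aw_val:.6g}"
            fh.write(
                f"{p.r:.6g}\t{p.normalized_r:.6g}\t{p.n_communities}\t"
                f"{p.modularity.q_total:.6g}\t{aw}\n"
            )
    best = max(screen.points, key=lambda p: p.modularity.q_total)
    _io.write_partition(best.partition.assignment, outdir / "best_partition.tsv")
    report = {
        "level": config.level,
        "n_points": len(screen),
        "plateaus": [
            {"r_start": p.r_start, "r_end": p.r_end, "n_communities": p.n_communities,
             "length": p.length}
            for p in plateaus
        ],
    }
    _write_json(report, outdir / "mesoscale_report.json")
    return report


@_stage("tsp")
def _tsp(config: RunConfig, net: RegulatoryNetwork, outdir: Path) -> dict:
    z = _motifs.zscores(
        net.project("DU"), R=config.R,
        n_switch_per_edge=config.n_switch_per_edge, seed=config.seed,
    )
    try:
        tsp = _motifs.normalize_tsp(z)
    except ValueError:
        tsp = None
    _zscore_table(z, tsp, outdir / "tsp.tsv")
    report = {
        "R": config.R,
        "n_undefined": int((~z.defined()).sum()),
        "z": [None if not z.is_defined(h) else float(z[h]) for h in range(1, 14)],
    }
    _write_json(report, outdir / "tsp_report.json")
    return report


@_stage("bias")
def _bias_stage(config: RunConfig, net: RegulatoryNetwork, outdir: Path) -> dict:
    suspicious = _bias.find_suspicious(net)
    table = _bias.contingency(net, suspicious)
    fisher = _bias.fisher_one_sided(table)
    report: dict[str, Any] = {
        "n_suspicious": len(suspicious),
        "contingency": {"a": table.a, "b": table.b, "c": table.c, "d": table.d},
        "wcl_fraction_suspicious": table.wcl_fraction_suspicious,
        "wcl_fraction_rest": table.wcl_fraction_rest,
        "fisher_p_one_sided": fisher.p_value,
        "fisher_degenerate": fisher.degenerate,
    }
    if table.n_suspicious > 0:
        x = _bias.correction_count(table)
        report["correction_count"] = x
        result = _bias.apply_correction(
            net, x, seed=config.seed, R=config.R,
            n_switch_per_edge=config.n_switch_per_edge,
        )
        with open(outdir / "deleted_links.tsv", "w", encoding="utf-8") as fh:
            fh.write("source\ttarget\n")
            for u, v in result.deleted_edges:
                fh.write(f"{u}\t{v}\n")
        _zscore_table(result.z_before, result.tsp_before, outdir / "tsp_before.tsv")
        _zscore_table(result.z_after, result.tsp_after, outdir / "tsp_after.tsv")
        corr = None
        if result.tsp_before is not None and result.tsp_after is not None:
            corr = _motifs.tsp_correlation(result.tsp_before, result.tsp_after)
        report["tsp_correlation_before_after"] = corr
        report["z_cascade_before"] = None if not result.z_before.is_defined(3) else result.z_before[3]
        report["z_cascade_after"] = None if not result.z_after.is_defined(3) else result.z_after[3]
        report["z_ffl_before"] = None if not result.z_before.is_defined(7) else result.z_before[7]
        report["z_ffl_after"] = None if not result.z_after.is_defined(7) else result.z_after[7]
    if config.exclude_sigma:
        sig = _bias.sigma_excluded_analysis(net)
        report["sigma_excluded"] = {
            "contingency": {"a": sig.table.a, "b": sig.table.b,
                            "c": sig.table.c, "d": sig.table.d},
            "wcl_fraction_suspicious": sig.wcl_fraction_suspicious,
            "wcl_fraction_rest": sig.wcl_fraction_rest,
            "fisher_p_one_sided": sig.fisher.p_value,
            "conclusive": sig.conclusive,
        }
    _write_json(report, outdir / "bias_report.json")
    return report


def run(config: RunConfig) -> dict:
    """Execute the configured stages; returns the summary bundle.

    Every output carries provenance (config echo, seed, version).
    Stage failures raise :class:`StageError`; artifacts of completed
    stages are preserved.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(stream=sys.stderr, level=logging.INFO,
                        format="%(levelname)s %(name)s: %(message)s")

    summary: dict[str, Any] = {
        "version": __version__,
        "seed": config.seed,
        "config": dataclasses.asdict(config),
    }
    net, truth = _load(config, outdir)
    s = net.stats()
    summary["network"] = {
        "name": net.name, "n_nodes": s.n_nodes, "n_links": s.n_links,
        "n_self_loops": s.n_self_loops, "n_regulators": s.n_regulators,
        "n_feedback_loops": s.n_feedback_loops,
    }
    if config.run_mesoscale:
        summary["mesoscale"] = _mesoscale(config, net, truth, outdir)
    if config.run_tsp:
        summary["tsp"] = _tsp(config, net, outdir)
    if config.run_bias:
        summary["bias"] = _bias_stage(config, net, outdir)
    _write_json(summary, outdir / "summary.json")
    return summary
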