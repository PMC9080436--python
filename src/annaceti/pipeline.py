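"""Whole-workflow orchestration from a single declarative config.

A run config (YAML/JSON/TOML file or plain dict) lists the input networks
(files, or ``simulate`` blocks for synthetic skulls), the descriptor and
module-detection options, the morphospace variables and PERMANOVA settings,
and optionally a tree for parsimony mapping.  ``run_pipeline`` executes the
stages in order — descriptors + modules, node metrics, morphospace, phylogeny
mapping — writing deterministic CSV/JSON outputs and returning a manifest
with output paths, input hashes, seeds and versions.  Identical configs and
seeds give byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import pandas as pd

from .descriptors import descriptor_table
from .modularity import consensus_modules, detect_modules
from .morphospace import VARIABLE_PRESETS, pca_correlation, permanova
from .network_model import AnatomicalNetwork, load_edge_list, load_gexf
from .node_metrics import node_metrics_table
from .phylo_mapping import map_descriptors, maps_as_table, parse_newick
from .synthetic_data import SkullGenConfig, generate_skull_network

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and input."""


def load_config(path: str | Path) -> dict:
    """Read a run config from YAML, JSON or TOML by extension."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    suffix = path.suffix.lower()
    if suffix in (".yaml", ".yml"):
        import yaml

        return yaml.safe_load(text)
    if suffix == ".toml":
        import tomllib

        return tomllib.loads(text)
    return json.loads(text)


def _hash_text(text: str) -> str:
    return hashlib.sha256(text.encode("utf-8")).hexdigest()[:16]


def _load_networks(config: dict) -> tuple[list[AnatomicalNetwork], dict[str, str]]:
    networks: list[AnatomicalNetwork] = []
    hashes: dict[str, str] = {}
    for i, entry in enumerate(config.get("taxa", [])):
        if "simulate" in entry:
            sim = dict(entry["simulate"])
            taxon = sim.pop("taxon", f"synthetic_{i}")
            net = generate_skull_network(SkullGenConfig(**sim), taxon=taxon)
            hashes[taxon] = _hash_text(json.dumps(sim, sort_keys=True))
        elif "path" in entry:
            path = Path(entry["path"])
            loader = load_edge_list if path.suffix.lower() in (".csv", ".tsv", ".txt") \
                else load_gexf
            net = loader(path, taxon=entry.get("taxon"))
            hashes[net.taxon] = _hash_text(path.read_text(encoding="utf-8"))
        else:
            raise PipelineError(f"taxa[{i}]: entry needs 'simulate' or 'path'")
        networks.append(net)
    if not networks:
        raise PipelineError("config lists no networks under 'taxa'")
    return networks, hashes


def run_pipeline(config: dict | str | Path, outdir: str | Path | None = None) -> dict:
    """Run networks -> descriptors+modules -> metrics -> morphospace -> phylogeny.

    Returns the run manifest (also written as ``manifest.json`` under the
    output directory).
    """
    if not isinstance(config, dict):
        config = load_config(config)
    from . import __version__

    out = Path(outdir or config.get("outdir", "annaceti_run"))
    manifest: dict = {"version": __version__, "outputs": {}, "stages": []}

    def stage(name: str):
        t0 = time.perf_counter()

        def done() -> None:
            manifest["stages"].append({"stage": name,
                                       "seconds": round(time.perf_counter() - t0, 3)})
            logger.info("stage %s finished in %.3f s", name,
                        time.perf_counter() - t0)
        return done

    def fail(stage_name: str, what: str, exc: Exception):
        raise PipelineError(f"stage {stage_name!r} failed on {what}: {exc}") from exc

    done = stage("load")
    try:
        networks, hashes = _load_networks(config)
    except PipelineError:
        raise
    except Exception as exc:
        fail("load", "network inputs", exc)
    manifest["input_hashes"] = hashes
    done()

    mod_cfg = config.get("modules", {})
    seed = int(mod_cfg.get("seed", 0))
    n_restarts = int(mod_cfg.get("n_restarts", 100))
    resolution = float(mod_cfg.get("resolution", 1.0))
    manifest["module_settings"] = {"seed": seed, "n_restarts": n_restarts,
                                   "resolution": resolution}
    done = stage("modules")
    partitions = []
    for net in networks:
        try:
            partitions.append(detect_modules(net, resolution=resolution,
                                             n_restarts=n_restarts, seed=seed))
        except Exception as exc:
            fail("modules", net.taxon, exc)
    done()

    desc_cfg = config.get("descriptors", {})
    manifest["descriptor_settings"] = {
        "population_sd": bool(desc_cfg.get("population_sd", False)),
        "exclude_low_degree": bool(desc_cfg.get("exclude_low_degree", False)),
        "largest_component": bool(desc_cfg.get("largest_component", False)),
    }
    done = stage("descriptors")
    try:
        table = descriptor_table(networks, partitions,
                                 **manifest["descriptor_settings"])
    except Exception as exc:
        fail("descriptors", "descriptor table", exc)
    (out / "descriptors").mkdir(parents=True, exist_ok=True)
    desc_path = out / "descriptors" / "descriptors.csv"
    table.to_csv(desc_path, index=False)
    manifest["outputs"]["descriptors"] = str(desc_path)
    done()

    done = stage("metrics")
    try:
        metrics = node_metrics_table(networks)
    except Exception as exc:
        fail("metrics", "node metrics", exc)
    (out / "metrics").mkdir(parents=True, exist_ok=True)
    metrics_path = out / "metrics" / "node_metrics.csv"
    metrics.to_csv(metrics_path, index=False)
    manifest["outputs"]["metrics"] = str(metrics_path)
    done()

    done = stage("modules_export")
    (out / "modules").mkdir(parents=True, exist_ok=True)
    mod_path = out / "modules" / "partitions.json"
    payload = [p.to_dict() for p in partitions]
    n_consensus = int(mod_cfg.get("consensus", 0))
    if n_consensus >= 2:
        for net, entry in zip(networks, payload):
            cons = consensus_modules(net, n_runs=n_consensus, seed=seed,
                                     resolution=resolution)
            entry["consensus"] = cons.to_dict()
    mod_path.write_text(json.dumps(payload, indent=1, sort_keys=True),
                        encoding="utf-8")
    manifest["outputs"]["modules"] = str(mod_path)
    done()

    morpho_cfg = config.get("morphospace")
    if morpho_cfg:
        done = stage("morphospace")
        variables = morpho_cfg.get("variables", "cetacean")
        if isinstance(variables, str):
            variables = VARIABLE_PRESETS[variables]
        try:
            result = pca_correlation(table, variables)
        except Exception as exc:
            fail("morphospace", "PCA", exc)
        (out / "morphospace").mkdir(parents=True, exist_ok=True)
        result.scores.to_csv(out / "morphospace" / "scores.csv")
        result.loadings.to_csv(out / "morphospace" / "loadings.csv")
        summary = {"variables": list(variables),
                   "variance_pct": [round(v, 6) for v in result.variance_pct]}
        groups = morpho_cfg.get("groups")
        if groups and morpho_cfg.get("permanova", False):
            perm_seed = int(morpho_cfg.get("seed", 0))
            n_perm = int(morpho_cfg.get("n_perm", 9999))
            try:
                perm = permanova(table, variables, groups, n_perm=n_perm,
                                 seed=perm_seed,
                                 pairwise=bool(morpho_cfg.get("pairwise", False)))
            except Exception as exc:
                fail("morphospace", "PERMANOVA", exc)
            summary["permanova"] = {"F": perm.F, "p": perm.p,
                                    "n_perm": perm.n_perm, "seed": perm.seed,
                                    "distance": perm.distance}
            if perm.pairwise is not None:
                summary["permanova"]["pairwise"] = perm.pairwise.to_dict("records")
        (out / "morphospace" / "summary.json").write_text(
            json.dumps(summary, indent=1, sort_keys=True), encoding="utf-8")
        manifest["outputs"]["morphospace"] = str(out / "morphospace")
        done()

    tree_src = config.get("tree")
    if tree_src:
        done = stage("phylo")
        try:
            tree = parse_newick(tree_src)
            variables = config.get("phylo_variables", ["D", "L", "C", "H", "P"])
            maps = map_descriptors(tree, table, variables=variables)
        except Exception as exc:
            fail("phylo", str(tree_src), exc)
        (out / "phylo").mkdir(parents=True, exist_ok=True)
        maps_as_table(maps).to_csv(out / "phylo" / "ancestral_intervals.csv",
                                   index=False)
        changes = {var: m.total_change for var, m in maps.items()}
        (out / "phylo" / "total_change.json").write_text(
            json.dumps(changes, indent=1, sort_keys=True), encoding="utf-8")
        manifest["outputs"]["phylo"] = str(out / "phylo")
        done()

    out.mkdir(parents=True, exist_ok=True)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True),
                                       encoding="utf-8")
    return manifest
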