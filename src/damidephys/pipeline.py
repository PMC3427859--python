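"""End-to-end pipeline runs driven by a single YAML config.

Both arms — the DamID binding analysis and the clamp-simulation /
feature-extraction study — run from one config with one master seed, and
write a machine-readable run manifest (package version, seed, parameter
values, output digests) so any output can be reproduced exactly. Reruns
with the same config and seed are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import replace
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import ephys_features as ef
from . import ephys_sim as es
from . import io_formats, synthetic_damid
from .model import DamidBindingModel

__all__ = ["ConfigError", "default_config", "load_config", "validate_config",
           "run_damid", "run_ephys"]


class ConfigError(ValueError):
    """Invalid or incomplete run configuration (names the offending key)."""


def default_config() -> dict:
    """Full config with every threshold at its production default."""
    return {
        "seed": 0,
        "damid": {
            "simulate": True,
            "array": {"n_arms": 2, "probes_per_arm": 5000, "spacing_bp": 55,
                      "noise_sd": 0.3, "n_replicates": 3, "dye_swap_replicate": 2},
            "peaks": {"height": 1.0, "min_width": 8},
            "fdr": {"iterations": 20, "height_grid": [0.10, 1.25, 0.05],
                    "width_grid": [6, 15], "consensus": "all", "threshold": 0.001},
            "targets": {"window": 5000, "nearest_only": False},
        },
        "ephys": {
            "groups": {"dmn": {"fast_pApF": 60.1, "slow_pApF": 49.0},
                       "vmn": {"fast_pApF": 42.6, "slow_pApF": 33.3}},
            "n_cells_per_group": 8,
            "cell_sd_frac": 0.08,
            "noise_sd_pA": 2.0,
            "fast_window_ms": [0.5, 5.0],
            "slow_fraction": 0.2,
            "protocols": ["vc90", "vc20", "cc"],
        },
    }


_REQUIRED_DAMID = [
    ("seed", int),
    ("damid.peaks.height", (int, float)),
    ("damid.peaks.min_width", int),
    ("damid.fdr.iterations", int),
    ("damid.fdr.threshold", (int, float)),
    ("damid.targets.window", int),
]
_REQUIRED_EPHYS = [("seed", int), ("ephys.protocols", list)]


def _get(config: Mapping, dotted: str) -> Any:
    node: Any = config
    for part in dotted.split("."):
        if not isinstance(node, Mapping) or part not in node:
            raise ConfigError(f"missing config key: {dotted}")
        node = node[part]
    return node


def validate_config(config: Mapping, arm: str) -> None:
    required = _REQUIRED_DAMID if arm == "damid" else _REQUIRED_EPHYS
    for key, types in required:
        value = _get(config, key)
        if not isinstance(value, types):
            raise ConfigError(f"config key {key} has wrong type "
                              f"({type(value).__name__})")
    if arm == "ephys":
        known = {"vc90", "vc20", "cc"}
        for name in _get(config, "ephys.protocols"):
            if name not in known:
                raise ConfigError(f"unknown protocol name: {name!r} "
                                  f"(expected one of {sorted(known)})")


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError("config file must contain a YAML mapping")
    return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_manifest(out_dir: Path, stage: str, seed: int, params: Mapping) -> None:
    digests = {p.name: _sha256(p) for p in sorted(out_dir.iterdir())
               if p.is_file() and p.name != "manifest.json"}
    manifest = {"package": "damidephys", "version": __version__, "stage": stage,
                "seed": seed, "parameters": params, "file_digests": digests}
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


# ---------------------------------------------------------------------------
# DamID arm
# ---------------------------------------------------------------------------

def run_damid(config: Mapping, out_dir) -> "DamidResults":
    """Simulate/ingest -> orient -> normalize -> call -> FDR -> consensus ->
    targets, with all artifacts and a manifest written to ``out_dir``."""
    validate_config(config, "damid")
    seed = int(_get(config, "seed"))
    dcfg = config["damid"]
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    fdr_cfg = dcfg["fdr"]
    hg = fdr_cfg.get("height_grid", [0.10, 1.25, 0.05])
    heights = np.round(np.arange(hg[0], hg[1] + 1e-9, hg[2]), 6)
    wg = fdr_cfg.get("width_grid", [6, 15])
    widths = np.arange(int(wg[0]), int(wg[1]) + 1)

    model_kw = dict(
        height_threshold=float(_get(config, "damid.peaks.height")),
        min_width=int(_get(config, "damid.peaks.min_width")),
        heights=heights, widths=widths,
        iterations=int(_get(config, "damid.fdr.iterations")),
        consensus_required=fdr_cfg.get("consensus", "all"),
        fdr_threshold=float(_get(config, "damid.fdr.threshold")),
        window_bp=int(_get(config, "damid.targets.window")),
        nearest_only=bool(dcfg.get("targets", {}).get("nearest_only", False)),
    )

    if dcfg.get("simulate", False):
        acfg = dcfg.get("array", {})
        sim = synthetic_damid.ArraySimConfig(seed=seed, **{
            k: v for k, v in acfg.items()
            if k in ("n_arms", "probes_per_arm", "spacing_bp", "noise_sd",
                     "n_replicates", "dye_swap_replicate")})
        model, planted = DamidBindingModel.from_simulation(sim, **model_kw)
        io_formats.write_probe_layout(model.layouts, out / "probes.tsv")
        io_formats.write_genes_gff3(model.genes, out / "genes.gff3")
        for rep, trs in model.tracks.items():
            io_formats.write_ratio_track(trs, model.layouts, out / f"track_{rep}.bedGraph")
        with open(out / "truth_planted.bed", "w") as fh:
            for p in planted:
                lay = model.layouts[p.arm_id]
                s = int(lay.starts[p.first_probe_index])
                e = int(lay.starts[p.last_probe_index] + lay.lengths[p.last_probe_index])
                fh.write(f"{p.arm_id}\t{s}\t{e}\tplanted\t{int(p.height_log2 * 100)}\t.\n")
    else:
        inputs = dcfg.get("inputs")
        if inputs is None:
            raise ConfigError("missing config key: damid.inputs (or set damid.simulate)")
        model = DamidBindingModel.from_files(
            inputs["probes"], inputs["tracks"], inputs.get("genes"),
            dye_swap_replicate=inputs.get("dye_swap_replicate"), **model_kw)

    results = model.fit(seed=seed)
    results.write(out)
    (out / "summary.txt").write_text(results.summary() + "\n")
    _write_manifest(out, "damid", seed, {"peaks": dcfg["peaks"], "fdr": fdr_cfg,
                                         "targets": dcfg.get("targets", {})})
    return results


# ---------------------------------------------------------------------------
# ephys arm
# ---------------------------------------------------------------------------

def _group_cells(gcfg: Mapping, n_cells: int, sd_frac: float,
                 rng: np.random.Generator) -> list[es.CellParams]:
    """Cell population for one group: conductances scaled by lognormal
    cell-to-cell variability around the group's target densities."""
    base = es.params_for_target_densities(gcfg["fast_pApF"], gcfg["slow_pApF"])
    cells = []
    for _ in range(n_cells):
        f = float(np.exp(rng.normal(0.0, sd_frac)))
        s = float(np.exp(rng.normal(0.0, sd_frac)))
        cells.append(replace(base, g_Kfast_nS=base.g_Kfast_nS * f,
                             g_Kslow_nS=base.g_Kslow_nS * s))
    return cells


def run_ephys(config: Mapping, out_dir) -> dict:
    """Simulate the recording study per group and extract all features."""
    validate_config(config, "ephys")
    seed = int(_get(config, "seed"))
    ecfg = config["ephys"]
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    n_cells = int(ecfg.get("n_cells_per_group", 8))
    sd_frac = float(ecfg.get("cell_sd_frac", 0.08))
    noise = float(ecfg.get("noise_sd_pA", 0.0))
    fast_window = tuple(ecfg.get("fast_window_ms", ef.DEFAULT_FAST_WINDOW_MS))
    slow_frac = float(ecfg.get("slow_fraction", ef.DEFAULT_SLOW_FRACTION))
    protocols = ecfg["protocols"]
    groups = ecfg.get("groups", default_config()["ephys"]["groups"])

    proto_map = {"vc90": es.VCProtocol(prepulse_mV=-90.0),
                 "vc20": es.VCProtocol(prepulse_mV=-20.0)}
    feature_tables: dict[str, list[pd.DataFrame]] = {p: [] for p in protocols if p != "cc"}
    labels: list[str] = []
    ap_rows = []
    results: dict = {}

    for gi, (gname, gcfg) in enumerate(sorted(groups.items())):
        rng = np.random.default_rng(np.random.SeedSequence((seed, 10, gi)))
        cells = _group_cells(gcfg, n_cells, sd_frac, rng)
        labels.extend([gname] * n_cells)
        for ci, cell in enumerate(cells):
            # passive properties always come from the hyperpolarizing
            # (-60 -> -90 mV) protocol, where voltage-gated channels are
            # closed; the -20 mV prepulse sweeps reuse the same estimate
            passive_sweeps = es.simulate_voltage_clamp(
                cell, proto_map["vc90"], noise_sd_pA=noise,
                seed=int(rng.integers(2 ** 31)))
            passive = ef.estimate_passive(passive_sweeps)
            if not ef.qc_input_resistance(passive):
                continue
            for pname in protocols:
                if pname == "cc":
                    continue
                sweeps = (passive_sweeps if pname == "vc90" else
                          es.simulate_voltage_clamp(cell, proto_map[pname],
                                                    noise_sd_pA=noise,
                                                    seed=int(rng.integers(2 ** 31))))
                sub = ef.offline_leak_subtract(sweeps, passive)
                feats = ef.measure_features(sub, passive, fast_window, slow_frac)
                feature_tables[pname].append(feats.assign(group=gname, cell=ci))
        if "cc" in protocols:
            cc = es.simulate_current_clamp(
                replace(cells[0], **{"g_Na_nS": 400.0, "g_KDR_nS": 100.0}))
            for _, row in ef.count_aps_sweeps(cc).iterrows():
                ap_rows.append({"group": gname, "current_pA": row["current_pA"],
                                "n_aps": int(row["n_aps"])})

    for pname, tables in feature_tables.items():
        long = pd.concat(tables, ignore_index=True)
        long.to_csv(out / f"features_{pname}.tsv", sep="\t", index=False,
                    float_format="%.6g")
        per_cell = [g.drop(columns=["group", "cell"])
                    for _, g in long.groupby(["group", "cell"], sort=True)]
        per_label = [key[0] for key, _ in long.groupby(["group", "cell"], sort=True)]
        for feat in ("I_Kfast_pApF", "I_Kslow_pApF"):
            iv = ef.build_iv(per_cell, per_label, feature=feat)
            iv.table.to_csv(out / f"iv_{pname}_{feat}.tsv", sep="\t", index=False,
                            float_format="%.6g")
            results[(pname, feat)] = iv
    if ap_rows:
        pd.DataFrame(ap_rows).to_csv(out / "ap_counts.tsv", sep="\t", index=False)
        results["ap_counts"] = pd.DataFrame(ap_rows)

    report = "\n\n".join(results[k].summary() for k in results if isinstance(k, tuple))
    (out / "report.txt").write_text(report + "\n")
    _write_manifest(out, "ephys", seed, {"n_cells_per_group": n_cells,
                                         "noise_sd_pA": noise,
                                         "fast_window_ms": list(fast_window),
                                         "slow_fraction": slow_frac})
    return results
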