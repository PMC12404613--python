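"""End-to-end orchestration of the analysis stages.

Two entry points mirror the two halves of the analysis:

* :func:`run_empirical` — records (real SGA file or synthetic) ->
  preprocessing -> per-law residual tables and binned summaries ->
  optional process-pair analysis; writes plain CSV/JSON plus a manifest.
* :func:`run_models` — the two growth models: a two-sector mutational scan
  with its closed-form exactness check, the mechanistic-model pair-by-law
  deviation matrix, and the gamma sweep.

All randomness flows through ``RunConfig.seed`` (per-stage child seeds are
spawned deterministically and recorded in the manifest); outputs are plain
text so runs are diffable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from . import __version__, go, scott_hwa, sga, synth, weisse
from .laws import LAWS, binned_summary, residuals

__all__ = ["RunConfig", "run_empirical", "run_models"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of a pipeline run; loadable from YAML."""

    outdir: str = "out"
    seed: int = 0
    laws: Tuple[str, ...] = LAWS
    n_bins: int = 10
    lo: float = 0.5
    hi: float = 1.0
    # empirical stage inputs: either a synthetic config or an SGA file
    synth: Optional[synth.SynthConfig] = None
    sga_path: Optional[str] = None
    annotation_path: Optional[str] = None
    strict_filter: bool = False
    run_go: bool = False
    go_min_count: int = 50
    tail_threshold: float = 0.1
    # model stage sizes
    scott_hwa_n: int = 2000
    weisse_scan_n: int = 50
    gamma_values: Tuple[float, ...] = (0.1, 0.03, 0.01, 0.003)
    gamma_n: int = 100
    gamma_pair: Tuple[str, str] = ("v_t", "n_s")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "synth" in raw and raw["synth"] is not None:
            raw["synth"] = synth.SynthConfig(**raw["synth"])
        for key in ("laws", "gamma_values", "gamma_pair"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def config_hash(self) -> str:
        def default(o):
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            raise TypeError(type(o))

        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=default)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _manifest(config: RunConfig, stage: str, extra: dict) -> dict:
    return {
        "package_version": __version__,
        "stage": stage,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": dataclasses.asdict(config),
        **extra,
    }


def _write_manifest(manifest: dict, outdir: Path, name: str) -> None:
    with open(outdir / name, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
        fh.write("\n")


def _load_records(config: RunConfig) -> pd.DataFrame:
    if config.synth is not None:
        cfg = dataclasses.replace(config.synth, seed=config.seed)
        return synth.generate_fitness_table(cfg)
    if config.sga_path is not None:
        return sga.read_sga(config.sga_path)
    raise ValueError("RunConfig needs either a synth config or sga_path")


def run_empirical(config: RunConfig) -> Dict[str, object]:
    """Residual analysis of a double-mutant fitness table.

    Writes, per law, ``residuals_<law>.csv`` and ``binned_<law>.csv``, plus
    ``preprocess_report.json`` and ``manifest_empirical.json``.  With
    ``run_go`` enabled (requires an annotation source), also writes
    ``pair_profiles.csv`` and ``tail_fractions.csv``.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records = _load_records(config)
    records, report = sga.preprocess(records, strict=config.strict_filter)
    report.to_json(outdir / "preprocess_report.json")

    summaries = {}
    for law in config.laws:
        table = residuals(records, law)
        table.to_csv(outdir / f"residuals_{law}.csv", index=False)
        summary = binned_summary(table, config.n_bins, config.lo, config.hi)
        summary.to_csv(outdir / f"binned_{law}.csv")
        meds = summary.table["median"].dropna()
        summaries[law] = {
            "mean_abs_bin_median": float(np.abs(meds).mean()) if len(meds) else None,
            "n_records": int(len(table)),
        }

    go_outputs = None
    if config.run_go:
        go_outputs = _run_go_stage(config, records, outdir)

    manifest = _manifest(
        config,
        "empirical",
        {"preprocess": dataclasses.asdict(report), "law_summaries": summaries},
    )
    _write_manifest(manifest, outdir, "manifest_empirical.json")
    return {"records": records, "report": report, "summaries": summaries,
            "go": go_outputs, "manifest": manifest}


def _run_go_stage(config: RunConfig, records: pd.DataFrame, outdir: Path):
    if config.annotation_path is not None:
        annotation = go.read_annotation_tsv(config.annotation_path)
    elif config.synth is not None and config.synth.n_processes > 0:
        cfg = dataclasses.replace(config.synth, seed=config.seed)
        annotation = synth.generate_annotations(cfg)
    else:
        raise ValueError(
            "GO stage enabled but no annotation source: set annotation_path "
            "or a synth config with n_processes > 0"
        )
    genes = set(records["query_gene"]) | set(records["array_gene"])
    selected = go.select_processes(annotation, genes, config.go_min_count)
    pairs = go.enumerate_disjoint_pairs(selected, annotation, genes)

    profile_rows = []
    table = residuals(records, "product")
    for pair in pairs:
        summary = go.pair_residual_profile(pair, table, config.n_bins, config.lo, config.hi)
        for _, row in summary.table.iterrows():
            profile_rows.append(
                {
                    "process_a": pair.process_a,
                    "process_b": pair.process_b,
                    "bin_center": row["bin_center"],
                    "n": int(row["count"]),
                    "median": row["median"],
                }
            )
    profiles = pd.DataFrame(profile_rows)
    profiles.to_csv(outdir / "pair_profiles.csv", index=False)
    tails = go.intra_vs_inter_tails(table, annotation, config.tail_threshold, selected)
    tails.to_csv(outdir / "tail_fractions.csv", index=False)
    return {"selected": selected, "pairs": pairs, "profiles": profiles, "tails": tails}


def run_models(config: RunConfig) -> Dict[str, object]:
    """Mutational analysis of the two growth models.

    Writes ``scott_hwa_scan.csv`` (with per-law binned residual
    summaries), ``weisse_deviation_matrix.csv``, ``gamma_sweep.csv`` and
    ``manifest_models.json``; the manifest records the closed-form maximum
    error and the gamma-sweep monotonicity flag.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = np.random.SeedSequence(config.seed).spawn(3)
    seed_sh, seed_wm, seed_gs = (
        int(s.generate_state(1)[0] % (2**31)) for s in seeds
    )

    params = scott_hwa.ScottHwaParams()
    scan = scott_hwa.sample_double_mutants(params, n=config.scott_hwa_n, seed=seed_sh)
    scan.to_csv(outdir / "scott_hwa_scan.csv", index=False)
    closed_max_err = float(
        np.nanmax(np.abs(scan["w_xy_model"] - scan["w_xy_closed_form"]))
    )
    for law in config.laws:
        table = pd.DataFrame(
            {
                "query_gene": "kappa_t",
                "array_gene": "kappa_n",
                "w_x": scan["w_x"],
                "w_y": scan["w_y"],
                "w_xy": scan["w_xy_model"],
            }
        )
        summary = binned_summary(
            residuals(table, law), config.n_bins, config.lo, config.hi
        )
        summary.to_csv(outdir / f"scott_hwa_binned_{law}.csv")

    wparams = weisse.WeisseParams.default()
    matrix = weisse.deviation_matrix(n=config.weisse_scan_n, seed=seed_wm, params=wparams)
    matrix.to_csv(outdir / "weisse_deviation_matrix.csv", index=False)

    sweep = weisse.gamma_sweep(
        list(config.gamma_values),
        pair=config.gamma_pair,
        n=config.gamma_n,
        seed=seed_gs,
        params=wparams,
    )
    sweep.to_csv(outdir / "gamma_sweep.csv", index=False)
    by_gamma = sweep.sort_values("gamma", ascending=False)
    monotone = bool(
        by_gamma["median_abs_product_residual"].is_monotonic_decreasing
    )

    manifest = _manifest(
        config,
        "models",
        {
            "stage_seeds": {"scott_hwa": seed_sh, "weisse_matrix": seed_wm,
                            "gamma_sweep": seed_gs},
            "closed_form_max_abs_error": closed_max_err,
            "gamma_sweep_monotone_improvement": monotone,
        },
    )
    _write_manifest(manifest, outdir, "manifest_models.json")
    return {"scan": scan, "matrix": matrix, "sweep": sweep,
            "closed_form_max_abs_error": closed_max_err, "manifest": manifest}
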