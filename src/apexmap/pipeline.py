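"""End-to-end orchestration of the analysis stages from one config.

A run config (YAML mapping, see ``RunConfig``) enables any subset of the
stages ``simulate -> qc -> markers -> ici -> likelihood -> de`` and sets
their parameters. Each stage writes plain-text artifacts into the output
directory and records its parameters and row counts in ``manifest.json``.
All randomness flows from explicit seeds in the config, so re-running a
config reproduces every artifact bit-identically (modulo the manifest
timestamp).
"""

from __future__ import annotations

import json
import logging
import os
import time
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .enrichment import (
    category_enrichment,
    rank_sum_de,
    select_expressing_cells,
    subsample_background,
)
from .ici import IciParams, ici_pipeline
from .io_qc import METADATA_FILE, QcThresholds, cpm, qc_filter, read_matrix
from .likelihood import (
    GraphParams,
    cluster_fractions,
    sample_likelihood_analysis,
)
from .markers import MarkerSet, TissueReference, select_markers, simple_bulk_de
from .simulate import PopulationSpec, SimConfig, simulate_experiment, write_fixture

logger = logging.getLogger(__name__)

STAGE_ORDER = ("simulate", "qc", "markers", "ici", "likelihood", "de")

BULK_COUNTS_FILE = "bulk_counts.tsv"


@dataclass
class RunConfig:
    """Validated run configuration.

    ``stages`` lists enabled stages (subset of ``STAGE_ORDER``); each
    stage key holds that stage's parameter mapping. ``input_dir`` points
    at an existing matrix directory when the simulate stage is disabled.
    """

    out_dir: str
    stages: list[str]
    seed: int = 0
    input_dir: str | None = None
    simulate: dict = field(default_factory=dict)
    qc: dict = field(default_factory=dict)
    markers: dict = field(default_factory=dict)
    ici: dict = field(default_factory=dict)
    likelihood: dict = field(default_factory=dict)
    de: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGE_ORDER)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        self.stages = [s for s in STAGE_ORDER if s in self.stages]
        if "simulate" not in self.stages and self.input_dir is None and self.stages:
            needs_matrix = set(self.stages) & {"qc", "ici", "likelihood", "de"}
            if needs_matrix:
                raise ValueError(
                    "input_dir is required when the simulate stage is disabled"
                )
        if self.input_dir is not None and not os.path.isdir(self.input_dir):
            raise ValueError(f"input_dir does not exist: {self.input_dir}")

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def _build_sim_config(cfg: RunConfig) -> SimConfig:
    params = dict(cfg.simulate)
    pops = params.pop("populations", None)
    kwargs = {**params, "seed": params.get("seed", cfg.seed)}
    if pops is not None:
        kwargs["populations"] = [PopulationSpec(**p) for p in pops]
    if "samples" in kwargs:
        kwargs["samples"] = tuple(kwargs["samples"])
    if "mito_fraction_range" in kwargs:
        kwargs["mito_fraction_range"] = tuple(kwargs["mito_fraction_range"])
    return SimConfig(**kwargs)


def _reference_from_bulk(path: str, t1: str = "adaxial", t2: str = "abaxial") -> TissueReference:
    counts = pd.read_csv(path, sep="\t", index_col=0)
    cpm_cols = {}
    for tissue in (t1, t2):
        cols = [c for c in counts.columns if c.startswith(tissue)]
        if not cols:
            raise ValueError(f"no replicate columns for tissue {tissue!r} in {path}")
        cpm_cols[tissue] = np.column_stack(
            [cpm(counts[c].to_numpy()) for c in cols]
        ).mean(axis=1)
    return TissueReference(
        t1=t1, t2=t2, cpm=pd.DataFrame(cpm_cols, index=counts.index),
        replicate_counts=counts,
    )


def run(config: RunConfig | str | dict) -> dict:
    """Execute the enabled stages in order; returns the manifest dict."""
    if isinstance(config, str):
        config = RunConfig.from_yaml(config)
    elif isinstance(config, dict):
        config = RunConfig(**config)
    os.makedirs(config.out_dir, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "seed": config.seed,
        "stages": {},
    }
    out = config.out_dir
    matrix = meta = reference = None
    marker_sets: dict[str, MarkerSet] | None = None
    ici_result = None

    for stage in config.stages:
        logger.info("running stage %s", stage)
        try:
            if stage == "simulate":
                sim_cfg = _build_sim_config(config)
                reference, matrix, meta, truth = simulate_experiment(sim_cfg)
                matrix_dir = os.path.join(out, "matrix")
                write_fixture(matrix, meta, truth, matrix_dir)
                reference.replicate_counts.to_csv(
                    os.path.join(out, BULK_COUNTS_FILE), sep="\t"
                )
                pd.concat(
                    [pd.DataFrame({"gene_id": g, "tissue": t})
                     for t, g in truth.markers.items()]
                ).to_csv(os.path.join(out, "planted_markers.tsv"),
                         sep="\t", index=False)
                manifest["stages"]["simulate"] = {
                    "params": {**config.simulate, "seed": sim_cfg.seed},
                    "n_genes": matrix.n_genes, "n_cells": matrix.n_cells,
                }
            elif stage == "qc":
                if matrix is None:
                    matrix = read_matrix(config.input_dir)
                    meta = _read_meta(config.input_dir)
                thresholds = QcThresholds(
                    min_genes_detected=config.qc.get("min_genes", 3000),
                    max_umi=config.qc.get("max_umi", 100_000),
                    max_mito_fraction=config.qc.get("max_mito", 0.01),
                    mito_prefix=config.qc.get("mito_prefix", "MT-"),
                )
                matrix, report = qc_filter(matrix, thresholds)
                if meta is not None:
                    meta = meta[meta["barcode"].isin(matrix.cells)].reset_index(
                        drop=True
                    )
                report.to_csv(os.path.join(out, "qc_report.tsv"),
                              sep="\t", index=False)
                manifest["stages"]["qc"] = {
                    "params": asdict(thresholds),
                    "n_cells_kept": matrix.n_cells,
                    "n_cells_removed": int((~report["pass_qc"]).sum()),
                }
            elif stage == "markers":
                if reference is None:
                    bulk_path = config.markers.get(
                        "bulk_counts", os.path.join(out, BULK_COUNTS_FILE)
                    )
                    reference = _reference_from_bulk(bulk_path)
                de_path = config.markers.get("de_table")
                if de_path:
                    de_table = pd.read_csv(de_path, sep="\t")
                else:
                    rc = reference.replicate_counts
                    t1c = [c for c in rc.columns if c.startswith(reference.t1)]
                    t2c = [c for c in rc.columns if c.startswith(reference.t2)]
                    de_table = simple_bulk_de(rc[t1c], rc[t2c])
                    de_table.to_csv(os.path.join(out, "de_table.tsv"),
                                    sep="\t", index=False)
                marker_sets = select_markers(
                    reference, de_table,
                    log2fc_min=config.markers.get("log2fc_min", 2.0),
                    fdr_max=config.markers.get("fdr_max", 0.05),
                )
                pd.concat(
                    [ms.to_frame() for ms in marker_sets.values()]
                ).to_csv(os.path.join(out, "markers.tsv"), sep="\t", index=False)
                manifest["stages"]["markers"] = {
                    "params": dict(config.markers),
                    "n_markers": {t: len(ms) for t, ms in marker_sets.items()},
                }
            elif stage == "ici":
                if matrix is None and config.input_dir:
                    matrix = read_matrix(config.input_dir)
                _require(matrix is not None, "ici needs a matrix")
                _require(marker_sets is not None, "ici needs marker sets")
                params = IciParams(
                    n_permutations=config.ici.get("n_permutations", 1000),
                    significance_percentile=config.ici.get("percentile", 95.0),
                    seed=config.ici.get("seed", config.seed),
                )
                subsets = config.ici.get("subsets")
                ici_result = ici_pipeline(
                    matrix, marker_sets, reference, params, subsets=subsets
                )
                ici_result.table.to_csv(
                    os.path.join(out, "ici_results.tsv"), sep="\t", index=False
                )
                ici_result.category_counts.to_csv(
                    os.path.join(out, "category_counts.tsv"), sep="\t", index=False
                )
                _null_summary(ici_result).to_csv(
                    os.path.join(out, "null_summary.tsv"), sep="\t", index=False
                )
                manifest["stages"]["ici"] = {
                    "params": {"n_permutations": params.n_permutations,
                               "percentile": params.significance_percentile,
                               "seed": params.seed},
                    "category_counts": ici_result.category_counts.to_dict("records"),
                }
            elif stage == "likelihood":
                if meta is None and config.input_dir:
                    meta = _read_meta(config.input_dir)
                _require(meta is not None, "likelihood needs cell metadata")
                gparams = GraphParams(
                    knn=config.likelihood.get("knn", 8),
                    beta=config.likelihood.get("beta", 10.0),
                    kernel=config.likelihood.get("kernel", "gaussian-adaptive"),
                )
                focal = config.likelihood.get("focal", "mut")
                lik = sample_likelihood_analysis(meta, focal, gparams)
                lik.to_csv(os.path.join(out, "likelihood.tsv"),
                           sep="\t", index=False)
                fractions = cluster_fractions(
                    lik, pd.Series(meta["cluster"].to_numpy(),
                                   index=meta["barcode"]).to_dict()
                )
                fractions.to_csv(os.path.join(out, "fractions.tsv"),
                                 sep="\t", index=False)
                manifest["stages"]["likelihood"] = {
                    "params": {**asdict(gparams), "focal": focal},
                    "n_rows": len(lik),
                    "category_totals": lik[
                        lik["cell_replicate"] == lik["likelihood_replicate"]
                    ]["category"].value_counts().to_dict(),
                }
            elif stage == "de":
                if matrix is None and config.input_dir:
                    matrix = read_matrix(config.input_dir)
                _require(matrix is not None, "de needs a matrix")
                genes = config.de.get("group_genes")
                _require(genes is not None, "de stage needs group_genes")
                group = select_expressing_cells(matrix, genes)
                pool = np.array(
                    [c for c in matrix.cells if c not in set(group)], dtype=object
                )
                n_bg = config.de.get("background_n")
                if n_bg:
                    pool = subsample_background(
                        pool, n=min(int(n_bg), len(pool)),
                        seed=config.de.get("seed", config.seed),
                    )
                de_res = rank_sum_de(matrix, group, pool)
                de_res.table.to_csv(os.path.join(out, "de_results.tsv"),
                                    sep="\t", index=False)
                manifest["stages"]["de"] = {
                    "params": dict(config.de),
                    "n_group": len(group), "n_background": len(pool),
                    "n_significant_bonf05": int(
                        (de_res.table["p_bonf"] < 0.05).sum()
                    ),
                }
                if ici_result is not None:
                    mask = np.isin(matrix.cells, group)
                    enr = category_enrichment(
                        ici_result.table["category"], mask
                    )
                    enr.to_csv(os.path.join(out, "category_enrichment.tsv"),
                               sep="\t", index=False)
                    manifest["stages"]["de"]["category_enrichment"] = enr.to_dict(
                        "records"
                    )
        except Exception:
            logger.exception("stage %s failed", stage)
            raise PipelineError(f"stage {stage!r} failed") from None

    with open(os.path.join(out, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, default=_json_default)
    return manifest


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValueError(msg)


def _read_meta(matrix_dir: str) -> pd.DataFrame | None:
    path = os.path.join(matrix_dir, METADATA_FILE)
    return pd.read_csv(path, sep="\t") if os.path.exists(path) else None


def _null_summary(ici_result) -> pd.DataFrame:
    rows = []
    for tissue, null in ici_result.nulls.items():
        flat = null.ravel()
        rows.append(
            {"tissue": tissue, "n_values": flat.size,
             "mean": flat.mean(), "sd": flat.std(),
             "p95": np.percentile(flat, 95),
             "threshold": float(np.unique(ici_result.thresholds[tissue])[0])}
        )
    return pd.DataFrame(rows)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
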