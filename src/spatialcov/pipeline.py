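"""End-to-end pipeline: COVET -> model training -> imputation + niche
inference -> evaluation tables, driven by a single TOML config file.

Example config::

    seed = 0
    out_dir = "run1"

    [data]                      # either paths ...
    spatial_counts = "st.tsv"
    spatial_coords = "coords.csv"
    sc_counts = "sc.tsv"
    # ... or a synthetic preset
    # preset = "small"

    [covet]
    k = 8
    log1p = true

    [model]
    latent_dim = 64
    train_steps = 1000

Every artifact directory receives a ``manifest.json`` recording the config,
its hash, package versions and seeds.
"""

from __future__ import annotations

import hashlib
import json
import sys
import tomllib
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .covet import compute_covet
from .envi import EnviConfig, train
from .io import read_bundle, read_coordinates, write_covet_h5
from .niche_analysis import expression_environment_concordance
from .synthetic import PRESETS, dissociate, simulate_tissue

__all__ = ["run_pipeline", "load_config"]

_REQUIRED = ("seed", "out_dir", "data")


def load_config(path: str | Path) -> dict:
    with open(path, "rb") as f:
        cfg = tomllib.load(f)
    for key in _REQUIRED:
        if key not in cfg:
            raise KeyError(f"config is missing required key {key!r}")
    data = cfg["data"]
    if "preset" not in data and not {"spatial_counts", "spatial_coords",
                                     "sc_counts"} <= set(data):
        raise KeyError(
            "config [data] needs either 'preset' or the three paths "
            "'spatial_counts', 'spatial_coords', 'sc_counts'"
        )
    return cfg


def run_pipeline(config_path: str | Path, log=print) -> dict:
    """Run all stages; returns a dict of artifact paths."""
    cfg = load_config(config_path)
    seed = int(cfg["seed"])
    out = Path(cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}

    def stage(name):
        log(f"[{name}]")

    # -- load or simulate ------------------------------------------------
    stage("load")
    data = cfg["data"]
    if "preset" in data:
        preset = dict(PRESETS[data["preset"]])
        tissue = simulate_tissue(seed=seed, **preset)
        st_counts = tissue.counts_panel
        st_genes = list(tissue.panel)
        coords = tissue.coords
        diss = dissociate(tissue, seed=seed + 1)
        sc_counts, sc_genes = diss["counts"], diss["gene_ids"]
        st_labels = tissue.zone
    else:
        st_bundle = read_bundle(data["spatial_counts"],
                                coords_path=data["spatial_coords"])
        sc_bundle = read_bundle(data["sc_counts"])
        st_counts, st_genes = st_bundle.counts, st_bundle.gene_ids
        coords = st_bundle.coordinates
        sc_counts, sc_genes = sc_bundle.counts, sc_bundle.gene_ids
        st_labels = st_bundle.labels.to_numpy() if st_bundle.labels is not None else None

    # -- covet -----------------------------------------------------------
    stage("covet")
    covet_cfg = cfg.get("covet", {})
    k = int(covet_cfg.get("k", 8))
    log1p = bool(covet_cfg.get("log1p", True))
    covet = compute_covet(st_counts, coords, k=k, gene_ids=st_genes, log1p=log1p)
    covet_path = out / "covet.h5"
    write_covet_h5(covet_path, covet.sigma, covet.sigma_sqrt, st_genes, None,
                   config={"k": k, "log1p": log1p, "seed": seed})
    artifacts["covet"] = str(covet_path)

    # -- train -----------------------------------------------------------
    stage("train")
    model_cfg = dict(cfg.get("model", {}))
    model_cfg.setdefault("seed", seed)
    model_cfg.setdefault("k_niche", k)
    model_cfg.setdefault("covet_transform", "log1p" if log1p else "none")
    envi_config = EnviConfig(**model_cfg)
    model = train(sc_counts, sc_genes, st_counts, st_genes, coords,
                  config=envi_config, covet_sqrt=covet.sigma_sqrt)
    model_path = out / "model.h5"
    model.save(model_path)
    artifacts["model"] = str(model_path)

    # -- impute + infer --------------------------------------------------
    stage("impute")
    st_pos = {g: i for i, g in enumerate(st_genes)}
    st_shared = st_counts[:, [st_pos[g] for g in model.st_genes]]
    imputed = model.impute_genes(st_shared)
    imputed_path = out / "imputed.tsv"
    pd.DataFrame(imputed, columns=model.sc_genes).to_csv(imputed_path, sep="\t",
                                                         index=False)
    artifacts["imputed"] = str(imputed_path)

    stage("infer-covet")
    sc_pos = {g: i for i, g in enumerate(sc_genes)}
    sc_panel = np.asarray(sc_counts)[:, [sc_pos[g] for g in model.st_genes]]
    inferred = model.infer_covet(sc_panel)
    inferred_path = out / "inferred_covet.h5"
    write_covet_h5(inferred_path, inferred @ inferred, inferred, model.st_genes,
                   None, config={"seed": seed})
    artifacts["inferred_covet"] = str(inferred_path)

    # -- evaluation ------------------------------------------------------
    stage("evaluate")
    rows = {"final_train_loss": model.loss_history[-1],
            "initial_train_loss": model.loss_history[0]}
    if st_labels is not None:
        rows["expression_environment_ari"] = expression_environment_concordance(
            st_counts, covet.sigma_sqrt, seed=seed
        )
    eval_path = out / "evaluation.tsv"
    pd.Series(rows).rename_axis("metric").to_frame("value").to_csv(eval_path, sep="\t")
    artifacts["evaluation"] = str(eval_path)

    # -- manifest --------------------------------------------------------
    blob = json.dumps(cfg, sort_keys=True, default=str)
    manifest = {
        "config": cfg,
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
        "package_version": __version__,
        "python": sys.version.split()[0],
        "seed": seed,
        "artifacts": artifacts,
    }
    with open(out / "manifest.json", "w") as f:
        json.dump(manifest, f, indent=2, default=str)
    artifacts["manifest"] = str(out / "manifest.json")
    return artifacts
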