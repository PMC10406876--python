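"""End-to-end orchestration: simulate or load, analyze, compare, report.

The pipeline is driven by a nested-dict config (YAML/JSON on the CLI).
Outputs are plain CSV plus a run log carrying versions, the seed and a
config hash; identical config + seed reproduces byte-identical CSVs.

Config schema (keys under the top level)::

    seed: int
    out_dir: str
    simulate:
      groups:                 # list of per-group blocks
        - name: str
          n_cells: int
          f_true: float       # planted colocalized fraction (ICCS branch)
          n_foci: int         # per channel
          pla_spots: int      # planted puncta per stack (PLA branch)
      image: {...}            # optional FociSimParams overrides
    iccs: {...}               # optional ICCSConfig overrides
    pla: {threshold: "otsu"|float, min_size_vox: int, connectivity: int}
    stats: {alpha_family: float, alpha_var: float}
    inputs:                   # alternative to simulate: load real images
      - {group: str, path: str, channels: [int, int], dna_channel: int}
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .errors import ValidationError
from .iccs import ICCSConfig, radial_profiles, run_iccs
from .io_masks import NuclearMask, read_image, segment_nucleus
from .pla import count_spots
from .stats import GroupSample, compare_groups
from .synth import FociSimParams, NoiseModel, simulate_pla_stack, simulate_two_channel

logger = logging.getLogger(__name__)

_ICCS_KEYS = {
    "max_lag_px",
    "bin_width_px",
    "fit_range_px",
    "exclude_zero_lag",
    "min_pairs_per_lag",
}
_IMAGE_KEYS = {
    "image_size_px",
    "nucleus_semi_axes",
    "psf_sigma_px",
    "amplitude_mean",
    "amplitude_cv",
    "background",
    "jitter_nm",
    "pixel_size_nm",
}


def _require(config: dict, key: str, path: str = "") -> object:
    if key not in config:
        raise ValidationError(f"missing config key: {path}{key}")
    return config[key]


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _iccs_config(config: dict) -> ICCSConfig:
    block = config.get("iccs", {})
    unknown = set(block) - _ICCS_KEYS
    if unknown:
        raise ValidationError(f"unknown iccs config keys: {sorted(unknown)}")
    return ICCSConfig(**block)


def run_pipeline(config: dict) -> dict[str, Path]:
    """Execute the configured workflow and write result files.

    Returns a mapping of artifact names to paths (``cells``,
    ``comparisons``, ``log``).
    """
    if not isinstance(config, dict):
        raise ValidationError("config must be a mapping")
    seed = int(config.get("seed", 0))
    out_dir = Path(_require(config, "out_dir"))
    out_dir.mkdir(parents=True, exist_ok=True)
    if ("simulate" in config) == ("inputs" in config):
        raise ValidationError("config must have exactly one of: simulate, inputs")

    cells: list[dict] = []
    profile_dir = out_dir / "radial_profiles"
    if "simulate" in config:
        cells = _run_simulated(config, seed, profile_dir)
    else:
        cells = _run_from_files(config, profile_dir)

    cells_df = pd.DataFrame(cells)
    cells_path = out_dir / "cells.csv"
    cells_df.to_csv(cells_path, index=False, float_format="%.10g")

    comp_path = out_dir / "comparisons.csv"
    stats_cfg = config.get("stats", {})
    comp_rows = []
    for metric in ("f", "pla_count"):
        if metric not in cells_df.columns or cells_df[metric].isna().all():
            continue
        groups = [
            GroupSample(name=g, values=sub[metric].to_numpy())
            for g, sub in cells_df.groupby("group", sort=True)
            if len(sub) >= 2
        ]
        if len(groups) < 2:
            continue
        report = compare_groups(
            groups,
            alpha_family=float(stats_cfg.get("alpha_family", 0.05)),
            alpha_var=float(stats_cfg.get("alpha_var", 0.05)),
        )
        for pw in report.pairwise:
            comp_rows.append(
                {
                    "metric": metric,
                    "group_a": pw.pair[0],
                    "group_b": pw.pair[1],
                    "anova_F": report.anova_F,
                    "anova_p": report.anova_p,
                    "variance_F_p": pw.variance_F_p,
                    "t_variant": pw.t_variant,
                    "t_p": pw.t_p,
                    "alpha_bonferroni": report.alpha_bonferroni,
                    "significant": pw.significant,
                }
            )
    pd.DataFrame(comp_rows).to_csv(comp_path, index=False, float_format="%.10g")

    log_path = out_dir / "run.log"
    log_path.write_text(
        "\n".join(
            [
                f"iccs-coloc version: {__version__}",
                f"numpy version: {np.__version__}",
                f"seed: {seed}",
                f"config hash: {_config_hash(config)}",
                f"n cells: {len(cells_df)}",
            ]
        )
        + "\n"
    )
    return {"cells": cells_path, "comparisons": comp_path, "log": log_path}


def _run_simulated(config: dict, seed: int, profile_dir: Path) -> list[dict]:
    sim = config["simulate"]
    groups = _require(sim, "groups", "simulate.")
    if not isinstance(groups, list) or not groups:
        raise ValidationError("simulate.groups must be a non-empty list")
    image_over = sim.get("image", {})
    unknown = set(image_over) - _IMAGE_KEYS
    if unknown:
        raise ValidationError(f"unknown simulate.image keys: {sorted(unknown)}")
    iccs_cfg = _iccs_config(config)
    pla_cfg = config.get("pla", {})
    root = np.random.default_rng(seed)
    cells = []
    for grp in groups:
        name = str(_require(grp, "name", "simulate.groups[]."))
        n_cells = int(_require(grp, "n_cells", "simulate.groups[]."))
        f_true = grp.get("f_true")
        n_pla = grp.get("pla_spots")
        for cell in range(n_cells):
            cell_seed = int(root.integers(0, 2**31 - 1))
            row: dict = {"group": name, "cell_id": cell, "seed": cell_seed}
            if f_true is not None:
                kwargs = {k: _as_value(v) for k, v in image_over.items()}
                params = FociSimParams(
                    n_foci_a=int(grp.get("n_foci", 50)),
                    n_foci_b=int(grp.get("n_foci", 50)),
                    f_true=float(f_true),
                    seed=cell_seed,
                    **kwargs,
                )
                image, truth = simulate_two_channel(params)
                mask = NuclearMask(mask=truth.nucleus_mask_true)
                res = run_iccs(image, 0, 1, mask, iccs_cfg)
                row.update(_iccs_row(res))
                _dump_profiles(
                    profile_dir, f"{name}_{cell}", image, mask, iccs_cfg
                )
            if n_pla is not None:
                stack, _ = simulate_pla_stack(
                    n_spots=int(n_pla),
                    noise=NoiseModel(poisson=True),
                    seed=cell_seed + 1,
                )
                spot = count_spots(
                    stack,
                    threshold=pla_cfg.get("threshold", "otsu"),
                    min_size_vox=int(pla_cfg.get("min_size_vox", 4)),
                    connectivity=int(pla_cfg.get("connectivity", 26)),
                )
                row["pla_count"] = spot.count
                row["pla_threshold"] = spot.threshold_used
            cells.append(row)
    return cells


def _run_from_files(config: dict, profile_dir: Path) -> list[dict]:
    iccs_cfg = _iccs_config(config)
    cells = []
    for i, entry in enumerate(config["inputs"]):
        path = Path(str(_require(entry, "path", "inputs[].")))
        if not path.exists():
            raise ValidationError(f"inputs[{i}].path does not exist: {path}")
        channels = entry.get("channels", [0, 1])
        dna = entry.get("dna_channel")
        image = read_image(path)
        if dna is not None:
            mask = segment_nucleus(np.asarray(image.channels[int(dna)], dtype=float))
        else:
            mask = NuclearMask(mask=np.ones(image.shape, dtype=bool))
        res = run_iccs(image, int(channels[0]), int(channels[1]), mask, iccs_cfg)
        row = {"group": entry.get("group", "all"), "cell_id": i, "seed": ""}
        row.update(_iccs_row(res))
        cells.append(row)
        _dump_profiles(profile_dir, f"cell_{i}", image, mask, iccs_cfg)
    return cells


def _as_value(v: object) -> object:
    return tuple(v) if isinstance(v, list) else v


def _iccs_row(res) -> dict:
    return {
        "g0_11": res.fit11.g0,
        "g0_22": res.fit22.g0,
        "g0_12": res.fit12.g0,
        "w_11": res.fit11.w_px,
        "w_22": res.fit22.w_px,
        "w_12": res.fit12.w_px,
        "g_inf_11": res.fit11.g_inf,
        "g_inf_22": res.fit22.g_inf,
        "g_inf_12": res.fit12.g_inf,
        "f_raw": res.f_raw,
        "f": res.f,
        "qc_flags": ";".join(res.qc_flags),
    }


def _dump_profiles(profile_dir: Path, stem: str, image, mask, cfg) -> None:
    profile_dir.mkdir(parents=True, exist_ok=True)
    prof = radial_profiles(image, 0, 1, mask, cfg)
    r = prof["g11"].radii_px
    df = pd.DataFrame(
        {
            "r_px": r,
            "g11": prof["g11"].g,
            "g22": prof["g22"].g,
            "g12": prof["g12"].g,
        }
    )
    df.to_csv(profile_dir / f"{stem}.csv", index=False, float_format="%.10g")
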