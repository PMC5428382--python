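"""File I/O, configuration and the end-to-end pipeline driver.

Formats are deliberately plain: CSV tables (pandas), JSON for transforms,
fits and summaries, single-plane grayscale TIFFs (tifffile), and a
versioned YAML config.  Readers validate headers and units and raise with
the offending column named; ``write(read(x))`` round-trips all numeric
fields at full float precision.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import decay_models as dm
from . import granule_quant as gq
from . import group_stats as gs
from . import registration as reg
from . import synthetic_data as syn

__all__ = [
    "read_observations_csv",
    "write_observations_csv",
    "read_landmarks_csv",
    "write_landmarks_csv",
    "read_records_csv",
    "write_records_csv",
    "read_transform_json",
    "write_transform_json",
    "read_image",
    "write_image",
    "load_config",
    "PipelineConfig",
    "run_pipeline",
]

log = logging.getLogger("clemq")

OBS_COLUMNS = ["t_days", "y", "sem", "n_replicates", "n_cells"]
LANDMARK_COLUMNS = ["label", "x_flm", "y_flm", "x_em", "y_em"]
RECORD_COLUMNS = ["cell_id", "id", "x_nm", "y_nm", "diameter_nm", "pool_505", "pool_tmr", "in_mgb"]


def _require_columns(df: pd.DataFrame, columns: list[str], path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}; found {list(df.columns)}")


def read_observations_csv(path, percent: bool = False) -> list[dm.GranuleAgeObservation]:
    """Read a labeled-fraction table; ``percent=True`` divides y and sem by 100."""
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, OBS_COLUMNS, path)
    scale = 0.01 if percent else 1.0
    obs = []
    for i, row in df.iterrows():
        try:
            obs.append(
                dm.GranuleAgeObservation(
                    t=float(row["t_days"]),
                    y=float(row["y"]) * scale,
                    sem=float(row["sem"]) * scale,
                    n_replicates=int(row["n_replicates"]),
                    n_cells=int(row["n_cells"]),
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path} row {i}: {exc}") from exc
    return obs


def write_observations_csv(path, obs: list[dm.GranuleAgeObservation]) -> None:
    pd.DataFrame(
        [
            {"t_days": o.t, "y": o.y, "sem": o.sem, "n_replicates": o.n_replicates, "n_cells": o.n_cells}
            for o in obs
        ]
    ).to_csv(path, index=False)


def read_landmarks_csv(path) -> list[reg.LandmarkPair]:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, LANDMARK_COLUMNS, path)
    return [
        reg.LandmarkPair(
            p_flm=(float(r.x_flm), float(r.y_flm)),
            p_em=(float(r.x_em), float(r.y_em)),
            label=str(r.label),
        )
        for r in df.itertuples()
    ]


def write_landmarks_csv(path, landmarks: list[reg.LandmarkPair]) -> None:
    pd.DataFrame(
        [
            {"label": lm.label, "x_flm": lm.p_flm[0], "y_flm": lm.p_flm[1], "x_em": lm.p_em[0], "y_em": lm.p_em[1]}
            for lm in landmarks
        ]
    ).to_csv(path, index=False)


def read_records_csv(path) -> list[gq.GranuleRecord]:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, RECORD_COLUMNS, path)
    records = []
    for r in df.itertuples():
        pools = set()
        if bool(r.pool_505):
            pools.add(gq.POOL_505)
        if bool(r.pool_tmr):
            pools.add(gq.POOL_TMR)
        d = float(r.diameter_nm)
        records.append(
            gq.GranuleRecord(
                id=int(r.id),
                centroid=(float(r.x_nm), float(r.y_nm)),
                ellipse=reg.EllipseFit((float(r.x_nm), float(r.y_nm)), d / 2, d / 2, 0.0),
                diameter=d,
                pools=frozenset(pools),
                in_mgb=bool(r.in_mgb),
                cell_id=int(r.cell_id),
            )
        )
    return records


def write_records_csv(path, records: list[gq.GranuleRecord]) -> None:
    pd.DataFrame(
        [
            {
                "cell_id": r.cell_id,
                "id": r.id,
                "x_nm": r.centroid[0],
                "y_nm": r.centroid[1],
                "diameter_nm": r.diameter,
                "pool_505": gq.POOL_505 in r.pools,
                "pool_tmr": gq.POOL_TMR in r.pools,
                "in_mgb": r.in_mgb,
            }
            for r in records
        ]
    ).to_csv(path, index=False)


def read_transform_json(path) -> reg.WarpTransform:
    with open(path) as fh:
        return reg.WarpTransform.from_dict(json.load(fh))


def write_transform_json(path, transform: reg.WarpTransform) -> None:
    with open(path, "w") as fh:
        json.dump(transform.to_dict(), fh, indent=2)


def read_image(path) -> np.ndarray:
    img = tifffile.imread(path)
    if img.ndim != 2:
        raise ValueError(f"{path}: expected a single-plane grayscale image, got shape {img.shape}")
    return np.asarray(img, float)


def write_image(path, image: np.ndarray) -> None:
    tifffile.imwrite(path, np.asarray(image, np.float32))


CONFIG_SCHEMA_VERSION = 1

_KNOWN_KEYS = {
    "schema_version",
    "seed",
    "out_dir",
    "observations_csv",
    "simulate",
    "scene",
    "fit",
    "compare",
    "stats",
    "quantify",
}
_SIMULATE_KEYS = {"params", "times", "n_experiments", "cells_per_group", "granules_per_cell_mean"}
_FIT_KEYS = {"models", "n_starts"}
_COMPARE_KEYS = {"method"}
_STATS_KEYS = {"alpha", "equal_var", "bonferroni"}
_QUANTIFY_KEYS = {"min_area_px", "match_radius_nm"}


@dataclass
class PipelineConfig:
    """Validated pipeline configuration; every seed explicit."""

    seed: int
    out_dir: str
    observations_csv: str | None = None
    simulate: dict = field(default_factory=dict)
    scene: dict = field(default_factory=dict)
    fit: dict = field(default_factory=lambda: {"models": [1, 2, 3], "n_starts": 8})
    compare: dict = field(default_factory=lambda: {"method": "likelihood_ratio"})
    stats: dict = field(default_factory=lambda: {"alpha": 0.05})
    quantify: dict = field(default_factory=dict)


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    unknown = set(raw) - _KNOWN_KEYS
    if unknown:
        raise ValueError(f"{path}: unknown config key(s) {sorted(unknown)}")
    if raw.get("schema_version") != CONFIG_SCHEMA_VERSION:
        raise ValueError(
            f"{path}: schema_version must be {CONFIG_SCHEMA_VERSION}, got {raw.get('schema_version')}"
        )
    if "seed" not in raw:
        raise ValueError(f"{path}: an explicit seed is required")
    for section, keys in (
        ("simulate", _SIMULATE_KEYS),
        ("fit", _FIT_KEYS),
        ("compare", _COMPARE_KEYS),
        ("stats", _STATS_KEYS),
        ("quantify", _QUANTIFY_KEYS),
    ):
        bad = set(raw.get(section, {}) or {}) - keys
        if bad:
            raise ValueError(f"{path}: unknown key(s) {sorted(bad)} in section {section!r}")
    kwargs = {k: v for k, v in raw.items() if k != "schema_version"}
    for sect in ("simulate", "scene", "fit", "compare", "stats", "quantify"):
        if kwargs.get(sect) is None and sect in kwargs:
            kwargs[sect] = {}
    defaults = PipelineConfig(seed=0, out_dir=".")
    for sect in ("fit", "compare", "stats"):
        merged = dict(getattr(defaults, sect))
        merged.update(kwargs.get(sect, {}))
        kwargs[sect] = merged
    return PipelineConfig(**kwargs)


def _params_from_mapping(p: dict) -> dm.DecayParams:
    return dm.DecayParams(
        model_id=int(p.get("model_id", 2)),
        a=float(p.get("a", 0.027)),
        delta=float(p.get("delta", 2.72)),
        tau=float(p.get("tau", 2.85)),
        tau1=float(p["tau1"]) if "tau1" in p else None,
    )


def run_pipeline(config: PipelineConfig) -> dict:
    """Run simulate -> register -> quantify -> stats -> fit -> compare.

    Writes per-stage outputs plus ``summary.json``, ``report.txt`` and a
    ``manifest.json`` listing every artifact.  Deterministic for a given
    config.  A stage failure aborts with the stage named; outputs written
    so far stay on disk, recorded in the manifest.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: list[str] = []
    summary: dict = {"seed": config.seed}
    stage = "setup"

    def _write_manifest() -> None:
        with open(out / "manifest.json", "w") as fh:
            json.dump({"artifacts": manifest, "last_stage": stage}, fh, indent=2)

    try:
        # --- simulate / load observations -------------------------------
        stage = "simulate"
        seed_seq = np.random.SeedSequence(config.seed)
        s_frac, s_scene = [int(s.generate_state(1)[0] % 2**31) for s in seed_seq.spawn(2)]
        if config.observations_csv:
            obs = read_observations_csv(config.observations_csv)
            cell_table = None
            log.info("loaded %d observations from %s", len(obs), config.observations_csv)
        else:
            sim = dict(config.simulate)
            params = _params_from_mapping(sim.pop("params", {}))
            obs, cell_table = syn.generate_fraction_data(params, seed=s_frac, **sim)
            log.info("simulated %d observations (seed %d)", len(obs), s_frac)
        write_observations_csv(out / "observations.csv", obs)
        manifest.append("observations.csv")
        if cell_table is not None:
            cell_table.to_csv(out / "cells.csv", index=False)
            manifest.append("cells.csv")

        # --- scene, registration, quantification ------------------------
        stage = "register"
        spec = syn.SceneSpec(**{**config.scene, "seed": s_scene}) if config.scene is not None else None
        scene = syn.generate_clem_scene(spec)
        landmarks = [
            reg.LandmarkPair((r.x_flm_nm, r.y_flm_nm), (r.x_em_nm, r.y_em_nm), f"bead{r.Index}")
            for r in scene.beads.itertuples()
        ]
        warp = reg.fit_affine(landmarks)
        write_transform_json(out / "transform.json", warp)
        manifest.append("transform.json")

        stage = "quantify"
        q = config.quantify
        em_inverted = scene.em_image.max() - scene.em_image
        em_records = gq.detect_spots(
            em_inverted, pixel_size_nm=scene.spec.em_pixel_nm, min_area_px=q.get("min_area_px", 4)
        )
        spots505 = gq.detect_spots(scene.flm_505, pixel_size_nm=scene.spec.flm_pixel_nm)
        spotstmr = gq.detect_spots(scene.flm_tmr, pixel_size_nm=scene.spec.flm_pixel_nm)
        for rec_list in (spots505, spotstmr):
            for r in rec_list:
                x, y = reg.warp_points(warp, r.centroid)[0]
                r.centroid = (float(x), float(y))
        merged = gq.classify_pools(
            spots505, spotstmr, match_radius_nm=q.get("match_radius_nm", gq.DEFAULT_MATCH_RADIUS_NM)
        )
        write_records_csv(out / "records.csv", merged)
        manifest.append("records.csv")
        # scene-level registration accuracy against ground truth beads
        true_flm_in_em = reg.warp_points(warp, scene.granules[["x_flm_nm", "y_flm_nm"]].to_numpy())
        pairs = [
            (
                reg.EllipseFit(tuple(p), 1.0, 1.0, 0.0),
                reg.EllipseFit((g.x_nm, g.y_nm), 1.0, 1.0, 0.0),
            )
            for p, g in zip(true_flm_in_em, scene.granules.itertuples())
        ]
        err = reg.registration_error(pairs)
        summary["registration"] = {"mean_shift_nm": err.mean, "sd_nm": err.sd, "n": err.n}
        summary["scene"] = {
            "n_granules_truth": int(len(scene.granules)),
            "n_granules_detected_em": len(em_records),
            "n_505_truth": int(scene.granules.pool_505.sum()),
        }

        # --- statistics ---------------------------------------------------
        stage = "stats"
        if cell_table is not None:
            groups = []
            for t, sub in cell_table.groupby("t_days", sort=True):
                per_exp = sub.groupby("experiment").apply(
                    lambda d: d.n_labeled.sum() / d.n_granules.sum(), include_groups=False
                )
                groups.append(gs.AgeGroupSample(age_label=f"{t:g}d", values=tuple(per_exp)))
            f_stat, p_val = gs.one_way_anova(groups)
            posthoc = gs.sequential_posthoc(
                groups,
                alpha=config.stats.get("alpha", 0.05),
                equal_var=config.stats.get("equal_var", False),
                bonferroni=config.stats.get("bonferroni", False),
            )
            summary["anova"] = {"F": f_stat, "p": p_val}
            summary["posthoc"] = {
                "pooled": posthoc.pooled_labels,
                "final_pvalues": posthoc.final_pvalues,
            }

        # --- model fitting and comparison --------------------------------
        stage = "fit"
        fits = [
            dm.fit_decay_model(obs, mid, n_starts=config.fit.get("n_starts", 8), seed=config.seed + mid)
            for mid in config.fit.get("models", [1, 2, 3])
        ]
        for f in fits:
            with open(out / f"fit_model{f.params.model_id}.json", "w") as fh:
                json.dump(f.to_dict(), fh, indent=2)
            manifest.append(f"fit_model{f.params.model_id}.json")

        stage = "compare"
        comparison = dm.compare_models(fits, method=config.compare.get("method", "likelihood_ratio"))
        best = comparison.best_model()
        best_fit = next(f for f in fits if f.params.model_id == best)
        summary["fits"] = {f.params.model_id: f.to_dict() for f in fits}
        summary["comparison"] = comparison.to_dict()
        summary["selected_model"] = best
        summary["half_life_days"] = dm.half_life(best_fit.params)
        with open(out / "comparison.json", "w") as fh:
            json.dump(comparison.to_dict(), fh, indent=2)
        manifest.append("comparison.json")

        stage = "report"
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, default=float)
        manifest.append("summary.json")
        lines = [
            "clemq pipeline report",
            f"seed: {config.seed}",
            f"observations: {len(obs)} timepoints",
            f"selected model: {best} ({comparison.method})",
            f"half-life: {summary['half_life_days']:.2f} days",
            f"registration mean shift: {err.mean:.1f} +/- {err.sd:.1f} nm (n={err.n})",
        ]
        if "anova" in summary:
            lines.append(f"ANOVA: F = {summary['anova']['F']:.2f}, p = {summary['anova']['p']:.3g}")
        (out / "report.txt").write_text("\n".join(lines) + "\n")
        manifest.append("report.txt")
    except Exception as exc:
        _write_manifest()
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    _write_manifest()
    return summary
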