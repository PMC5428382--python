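"""Ground-truth generators for the quantitative CLEM pipeline.

Everything the analysis consumes can be simulated with known truth:

* **Labeled-fraction time courses** — per-cell binomial labeling of
  Poisson-sized granule populations, aggregated per experiment exactly the
  way the real counting was done (3 experiments, ~38 cells per age group,
  plateau labeled fraction a few percent).
* **Paired FLM/EM scenes** — granules as near-circular dense particles
  (diameter 265 +/- 53 nm, truncated below 80 nm) rendered as dark disks
  with a membrane rim in the EM frame and as Gaussian-PSF spots in the
  fluorescence channels; fiducial beads in both frames; the FLM frame is
  the EM frame pushed through a configurable affine distortion plus an
  optional smooth sinusoidal residual field.
* **MGB co-occurrence counts** — binomial draws for young/old rate
  comparisons.

One root seed drives per-component child streams (placement, labeling,
beads, noise), recorded in the scene metadata, so every output is fully
reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .decay_models import DecayParams, GranuleAgeObservation, eval_decay_model
from .registration import WarpTransform

__all__ = [
    "DEFAULT_TIMES_DAYS",
    "SceneSpec",
    "SyntheticScene",
    "generate_fraction_data",
    "generate_clem_scene",
    "generate_mgb_counts",
]

# Cohort ages in days: 5-8 h (midpoint 6.5 h = 0.27 d), then 1-5 days.
DEFAULT_TIMES_DAYS = (0.27, 1.0, 2.0, 3.0, 4.0, 5.0)

# Replicate SEMs of the labeled fraction at the printed dispersion scale
# (0.0010-0.0026), one per cohort age.
DEFAULT_SEMS = (0.0016, 0.0020, 0.0020, 0.0026, 0.0010, 0.0010)


def generate_observations(
    params: DecayParams,
    times=DEFAULT_TIMES_DAYS,
    sems=DEFAULT_SEMS,
    n_replicates: int = 3,
    seed: int = 0,
) -> list[GranuleAgeObservation]:
    """Gaussian observations with *stated* per-age SEMs.

    Draws ``y_i = f(t_i) + Normal(0, sem_i)`` (clipped to [0, 1]) and
    reports ``sem_i`` itself, matching the noise model the weighted fit
    assumes.  This is the construction for estimator-calibration studies
    (coverage, model selection); :func:`generate_fraction_data` simulates
    the full per-cell counting hierarchy instead.
    """
    if len(times) != len(sems):
        raise ValueError("times and sems must have equal length")
    rng = np.random.default_rng(seed)
    obs = []
    for t, sem in zip(times, sems):
        if sem <= 0:
            raise ValueError("sems must be positive")
        y = float(np.clip(eval_decay_model(params, float(t)) + rng.normal(0.0, sem), 0.0, 1.0))
        obs.append(
            GranuleAgeObservation(t=float(t), y=y, sem=float(sem), n_replicates=n_replicates)
        )
    return obs


def generate_fraction_data(
    params: DecayParams,
    times=DEFAULT_TIMES_DAYS,
    n_experiments: int = 3,
    cells_per_group: int = 38,
    granules_per_cell_mean: float = 800.0,
    experiment_cv: float = 0.10,
    seed: int = 0,
) -> tuple[list[GranuleAgeObservation], pd.DataFrame]:
    """Simulate per-cell granule counting for each cohort age.

    Per cell the total granule count is Poisson(``granules_per_cell_mean``)
    and each granule is labeled independently with probability ``y(t)``
    from ``params``, scaled by a per-experiment labeling-efficiency factor
    ``Normal(1, experiment_cv)`` (truncated positive) that emulates the
    between-experiment biological variability dominating the replicate
    SEMs; pure binomial counting noise alone would understate them.  Per
    experiment the labeled fraction pools all cells (sum labeled / sum
    total); the returned observation per age is the mean over experiments
    with ``sem = SD / sqrt(n_experiments)``.

    Returns the observation list and the per-cell table
    (``t_days, experiment, cell, n_granules, n_labeled``).
    """
    if len(times) == 0:
        raise ValueError("need at least one timepoint")
    rng = np.random.default_rng(seed)
    rows = []
    obs: list[GranuleAgeObservation] = []
    for t in times:
        y_true = eval_decay_model(params, float(t))
        if not 0.0 <= y_true <= 1.0:
            raise ValueError(f"model fraction y({t}) = {y_true} is not a probability")
        exp_fracs = []
        n_cells_total = 0
        for e in range(n_experiments):
            eff = max(rng.normal(1.0, experiment_cv), 0.0) if experiment_cv > 0 else 1.0
            p_eff = min(y_true * eff, 1.0)
            n_gran = rng.poisson(granules_per_cell_mean, size=cells_per_group)
            n_lab = rng.binomial(n_gran, p_eff)
            for c in range(cells_per_group):
                rows.append(
                    {
                        "t_days": float(t),
                        "experiment": e,
                        "cell": c,
                        "n_granules": int(n_gran[c]),
                        "n_labeled": int(n_lab[c]),
                    }
                )
            exp_fracs.append(n_lab.sum() / max(n_gran.sum(), 1))
            n_cells_total += cells_per_group
        exp_fracs = np.array(exp_fracs)
        sem = (
            float(exp_fracs.std(ddof=1) / math.sqrt(n_experiments))
            if n_experiments > 1
            else 0.0
        )
        obs.append(
            GranuleAgeObservation(
                t=float(t),
                y=float(exp_fracs.mean()),
                # degenerate zero-spread draws get a tiny floor so the
                # observation invariant (sem > 0 for replicated data) holds
                sem=max(sem, 1e-12),
                n_replicates=n_experiments,
                n_cells=n_cells_total,
            )
        )
    return obs, pd.DataFrame(rows)


@dataclass
class SceneSpec:
    """Parameters of one simulated paired FLM/EM field.

    Pixel sizes default to desk-scale rasters (EM 10 nm/px, FLM 40 nm/px
    over the same 5.12 um field); the acquisition-scale EM pixel size
    1.8844194 nm/px can be set explicitly.  The distortion maps EM-frame
    nm coordinates to FLM-frame nm coordinates.
    """

    em_shape: tuple[int, int] = (512, 512)
    em_pixel_nm: float = 10.0
    flm_shape: tuple[int, int] = (128, 128)
    flm_pixel_nm: float = 40.0
    n_granules: int = 80
    diameter_mean_nm: float = 265.0
    diameter_sd_nm: float = 53.0
    diameter_min_nm: float = 80.0
    p_505: float = 0.027
    p_tmr: float = 0.05
    n_mgbs: int = 2
    mgb_granules_range: tuple[int, int] = (2, 4)
    n_beads: int = 8
    affine_matrix: tuple = ((1.01 * math.cos(0.03), -1.01 * math.sin(0.03)),
                           (1.01 * math.sin(0.03), 1.01 * math.cos(0.03)))
    affine_translation: tuple[float, float] = (40.0, -25.0)
    residual_amplitude_nm: float = 0.0
    residual_period_nm: float = 2000.0
    psf_sigma_nm: float = 60.0
    em_noise_sd: float = 8.0
    flm_noise_sd: float = 2.0
    # clearance factor on the sum of radii; > 1 keeps footprints disjoint
    min_separation_factor: float = 1.1
    placement_retries: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.em_shape + self.flm_shape) <= 0:
            raise ValueError("image shapes must be positive")
        for name in ("em_pixel_nm", "flm_pixel_nm", "diameter_mean_nm", "psf_sigma_nm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("p_505", "p_tmr"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")

    def distortion(self) -> WarpTransform:
        """The affine part of the EM->FLM distortion as a transform."""
        return WarpTransform(
            kind="affine",
            matrix=np.asarray(self.affine_matrix, float),
            translation=np.asarray(self.affine_translation, float),
        )

    def distort(self, points_nm: np.ndarray) -> np.ndarray:
        """Full EM->FLM distortion (affine plus smooth residual field)."""
        pts = np.atleast_2d(np.asarray(points_nm, float))
        out = pts @ np.asarray(self.affine_matrix, float).T + np.asarray(
            self.affine_translation, float
        )
        if self.residual_amplitude_nm > 0:
            phase = 2.0 * math.pi * pts / self.residual_period_nm
            out = out + self.residual_amplitude_nm * np.column_stack(
                [np.sin(phase[:, 1]), np.sin(phase[:, 0])]
            )
        return out


@dataclass
class SyntheticScene:
    """One simulated field with full ground truth."""

    spec: SceneSpec
    granules: pd.DataFrame  # x_nm, y_nm (EM frame), diameter_nm, pool_505, pool_tmr, mgb_id
    beads: pd.DataFrame  # x_em_nm, y_em_nm, x_flm_nm, y_flm_nm
    em_image: np.ndarray
    flm_505: np.ndarray
    flm_tmr: np.ndarray
    transform: WarpTransform  # applied EM->FLM distortion (affine part)
    child_seeds: dict = field(default_factory=dict)


def _place_granules(spec: SceneSpec, rng: np.random.Generator) -> pd.DataFrame:
    field_w = spec.em_shape[1] * spec.em_pixel_nm
    field_h = spec.em_shape[0] * spec.em_pixel_nm
    margin = 0.06 * min(field_w, field_h)
    lo, hi = spec.mgb_granules_range
    mgb_sizes = rng.integers(lo, hi + 1, size=spec.n_mgbs) if spec.n_mgbs else np.array([], int)
    n_free = spec.n_granules - int(mgb_sizes.sum())
    if n_free < 0:
        raise ValueError("MGB membership exceeds the granule count")

    xs, ys, radii, mgb_ids = [], [], [], []

    def draw_radius() -> float:
        while True:
            d = rng.normal(spec.diameter_mean_nm, spec.diameter_sd_nm)
            if d > spec.diameter_min_nm:
                return d / 2.0

    # MGB bodies first: a disk holding its members, itself kept clear of
    # other bodies and free granules
    mgb_centers, mgb_radii = [], []
    for m, size in enumerate(mgb_sizes):
        body_r = 1.6 * spec.diameter_mean_nm * math.sqrt(size) / 2.0 + spec.diameter_mean_nm
        for _ in range(spec.placement_retries):
            cx = rng.uniform(margin + body_r, field_w - margin - body_r)
            cy = rng.uniform(margin + body_r, field_h - margin - body_r)
            if all(
                math.hypot(cx - ox, cy - oy) > body_r + orr
                for (ox, oy), orr in zip(mgb_centers, mgb_radii)
            ):
                break
        else:
            raise RuntimeError("could not place MGB bodies; field too crowded")
        mgb_centers.append((cx, cy))
        mgb_radii.append(body_r)
        for _ in range(size):
            r = draw_radius()
            ang = rng.uniform(0, 2 * math.pi)
            rad = rng.uniform(0, max(body_r - r - 20.0, 1.0))
            xs.append(cx + rad * math.cos(ang))
            ys.append(cy + rad * math.sin(ang))
            radii.append(r)
            mgb_ids.append(m)

    for _ in range(n_free):
        r = draw_radius()
        for _ in range(spec.placement_retries):
            x = rng.uniform(margin, field_w - margin)
            y = rng.uniform(margin, field_h - margin)
            ok = all(
                math.hypot(x - xo, y - yo) >= spec.min_separation_factor * (r + ro)
                for xo, yo, ro in zip(xs, ys, radii)
            ) and all(
                math.hypot(x - cx, y - cy) > br + r
                for (cx, cy), br in zip(mgb_centers, mgb_radii)
            )
            if ok:
                break
        else:
            raise RuntimeError(
                f"could not place {spec.n_granules} non-overlapping granules "
                "within the retry budget; reduce the density"
            )
        xs.append(x)
        ys.append(y)
        radii.append(r)
        mgb_ids.append(-1)

    return pd.DataFrame(
        {
            "x_nm": xs,
            "y_nm": ys,
            "diameter_nm": np.array(radii) * 2.0,
            "mgb_id": mgb_ids,
        }
    )


def _render_em(spec: SceneSpec, granules: pd.DataFrame, beads: np.ndarray, rng) -> np.ndarray:
    h, w = spec.em_shape
    img = np.full((h, w), 200.0)
    yy, xx = np.mgrid[0:h, 0:w]
    px = spec.em_pixel_nm
    for _, g in granules.iterrows():
        r_px = g.diameter_nm / 2.0 / px
        cx, cy = g.x_nm / px, g.y_nm / px
        x0, x1 = max(int(cx - r_px - 3), 0), min(int(cx + r_px + 4), w)
        y0, y1 = max(int(cy - r_px - 3), 0), min(int(cy + r_px + 4), h)
        sub_d = np.hypot(xx[y0:y1, x0:x1] - cx, yy[y0:y1, x0:x1] - cy)
        core = sub_d <= max(r_px - 1.5, 0.5)
        rim = (sub_d <= r_px) & ~core
        patch = img[y0:y1, x0:x1]
        patch[core] = 70.0  # dense core
        patch[rim] = 30.0  # membrane rim
    for bx, by in beads:
        sub_d = np.hypot(xx - bx / px, yy - by / px)
        img[sub_d <= 3.0] = 10.0  # electron-dense bead
    if spec.em_noise_sd > 0:
        img = img + rng.normal(0.0, spec.em_noise_sd, img.shape)
    return np.clip(img, 0, 255)


def _render_flm(
    spec: SceneSpec,
    positions_flm_nm: np.ndarray,
    amplitudes: np.ndarray,
    rng,
) -> np.ndarray:
    h, w = spec.flm_shape
    img = np.zeros((h, w))
    px = spec.flm_pixel_nm
    sigma_px = spec.psf_sigma_nm / px
    yy, xx = np.mgrid[0:h, 0:w]
    for (x_nm, y_nm), amp in zip(positions_flm_nm, amplitudes):
        cx, cy = x_nm / px, y_nm / px
        if not (-4 * sigma_px < cx < w + 4 * sigma_px and -4 * sigma_px < cy < h + 4 * sigma_px):
            continue
        d2 = (xx - cx) ** 2 + (yy - cy) ** 2
        img += amp * np.exp(-d2 / (2.0 * sigma_px**2))
    if spec.flm_noise_sd > 0:
        # shot-noise-like: Poisson on the expected counts plus read noise
        img = rng.poisson(np.maximum(img, 0.0)).astype(float)
        img = img + rng.normal(0.0, spec.flm_noise_sd, img.shape)
    return np.clip(img, 0.0, None)


def generate_clem_scene(spec: SceneSpec) -> SyntheticScene:
    """Simulate one paired FLM/EM field with ground truth.

    Granules are placed without footprint overlap (MGB members exempt:
    they pack inside the MGB body), labeled independently per pool, and
    rendered into an EM image (dark cores with membrane rims on a bright
    background), and 505/TMR fluorescence channels (Gaussian PSF spots at
    the distorted positions).  Fiducial beads appear in both frames.
    """
    root = np.random.SeedSequence(spec.seed)
    s_place, s_label, s_bead, s_noise = root.spawn(4)
    child_seeds = {
        "placement": s_place.entropy,
        "labeling": s_label.entropy,
        "beads": s_bead.entropy,
        "noise": s_noise.entropy,
    }
    rng_place = np.random.default_rng(s_place)
    rng_label = np.random.default_rng(s_label)
    rng_bead = np.random.default_rng(s_bead)
    rng_noise = np.random.default_rng(s_noise)

    granules = _place_granules(spec, rng_place)
    n = len(granules)
    granules["pool_505"] = rng_label.random(n) < spec.p_505
    granules["pool_tmr"] = rng_label.random(n) < spec.p_tmr

    field_w = spec.em_shape[1] * spec.em_pixel_nm
    field_h = spec.em_shape[0] * spec.em_pixel_nm
    margin = 0.08 * min(field_w, field_h)
    # beads keep their EM footprint clear of every granule, and their
    # (brighter) fluorescence spot clear of the *labeled* granules whose
    # PSF spots would otherwise merge with it
    em_clear_nm = 2.0 * spec.em_pixel_nm * 3.0 + 20.0
    psf_clear_nm = 5.0 * spec.psf_sigma_nm
    gx = granules.x_nm.to_numpy()
    gy = granules.y_nm.to_numpy()
    gr = granules.diameter_nm.to_numpy() / 2.0
    labeled = (granules.pool_505 | granules.pool_tmr).to_numpy()
    bead_list: list[tuple[float, float]] = []
    for _ in range(spec.n_beads):
        for _ in range(spec.placement_retries):
            bx = rng_bead.uniform(margin, field_w - margin)
            by = rng_bead.uniform(margin, field_h - margin)
            d = np.hypot(gx - bx, gy - by)
            if (
                np.all(d > gr + em_clear_nm)
                and np.all(d[labeled] > psf_clear_nm)
                and all(
                    math.hypot(bx - ox, by - oy) > psf_clear_nm for ox, oy in bead_list
                )
            ):
                break
        else:
            raise RuntimeError("could not place fiducial beads clear of granules")
        bead_list.append((bx, by))
    beads_em = np.array(bead_list).reshape(spec.n_beads, 2)
    beads_flm = spec.distort(beads_em)
    beads = pd.DataFrame(
        {
            "x_em_nm": beads_em[:, 0],
            "y_em_nm": beads_em[:, 1],
            "x_flm_nm": beads_flm[:, 0],
            "y_flm_nm": beads_flm[:, 1],
        }
    )

    pos_em = granules[["x_nm", "y_nm"]].to_numpy()
    pos_flm = spec.distort(pos_em)
    granules["x_flm_nm"] = pos_flm[:, 0]
    granules["y_flm_nm"] = pos_flm[:, 1]

    em = _render_em(spec, granules, beads_em, rng_noise)
    amp = 400.0
    flm_505 = _render_flm(
        spec, pos_flm[granules.pool_505.to_numpy()], np.full(int(granules.pool_505.sum()), amp), rng_noise
    )
    flm_tmr = _render_flm(
        spec, pos_flm[granules.pool_tmr.to_numpy()], np.full(int(granules.pool_tmr.sum()), amp), rng_noise
    )
    # beads fluoresce in both channels
    bead_spots = _render_flm(spec, beads_flm, np.full(spec.n_beads, 2.5 * amp), rng_noise)
    flm_505 = flm_505 + bead_spots
    flm_tmr = flm_tmr + bead_spots

    return SyntheticScene(
        spec=spec,
        granules=granules,
        beads=beads,
        em_image=em,
        flm_505=flm_505,
        flm_tmr=flm_tmr,
        transform=spec.distortion(),
        child_seeds=child_seeds,
    )


def generate_mgb_counts(
    rate_young: float,
    rate_old: float,
    trials: int | tuple[int, int] = 38,
    seed: int = 0,
) -> dict:
    """Binomial MGB co-occurrence counts for a young and an old age class.

    ``trials`` may be a single per-group cell count or a (young, old)
    pair.  Returns ``{"young": (successes, trials), "old": ...}``.
    """
    for r in (rate_young, rate_old):
        if not 0.0 <= r <= 1.0:
            raise ValueError(f"rates must lie in [0, 1], got {r}")
    t_young, t_old = (trials, trials) if np.isscalar(trials) else trials
    rng = np.random.default_rng(seed)
    return {
        "young": (int(rng.binomial(t_young, rate_young)), int(t_young)),
        "old": (int(rng.binomial(t_old, rate_old)), int(t_old)),
    }
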