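"""Synthetic assay data: simulated worm videos and yoked trial tables.

Two generators make the whole analysis runnable without recordings:

* a kinematic **worm-video simulator** — S-shaped undulating crawlers in
  a circular corral, rendered over uneven illumination with noise, whose
  speed and bend amplitude are depressed by a controllable intoxication
  factor in [0, 1];
* a **yoked trial-table generator** — paired control-line / EtOH-line
  groups sharing a plate effect, with per-generation baselines, an
  intoxication ratio, and a lineage effect that can be confined to the
  F3 generation, reproducing the statistical structure of a
  transgenerational yoked-control experiment.

Both are deterministic given a seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.draw import disk

from .quant import ImageStack

logger = logging.getLogger("wormloco")

__all__ = [
    "WormKinematics",
    "RenderConfig",
    "SimDesign",
    "WormPaths",
    "simulate_worm_paths",
    "render_stack",
    "rasterize_paths",
    "generate_trial_table",
    "TRIAL_TABLE_COLUMNS",
]

GENERATIONS = ("F1", "F2", "F3")
LINEAGES = ("control", "etoh")
CONDITIONS = ("baseline", "etoh")

TRIAL_TABLE_COLUMNS = [
    "pair_id", "plate_id", "generation", "lineage",
    "condition", "n_worms", "area_per_worm",
]


@dataclass
class WormKinematics:
    """Kinematic parameters of one simulated worm.

    The body is a chain of ``n_segments`` points whose tangent angle
    follows a travelling sine wave; the head advances along its local
    tangent.  Intoxication multiplies speed by (1 - s*i) and bend
    amplitude by (1 - a*i), with depression coefficients s and a chosen
    so a fully intoxicated worm still moves sluggishly with narrow bends
    rather than being paralysed.

    Units: pixels, seconds, radians.
    """

    body_length: float = 40.0
    body_width: float = 5.0
    n_segments: int = 25
    bend_amplitude: float = 0.7        # radians, tangent-angle wave amplitude
    undulation_wavelength: float = 0.9  # fraction of body length
    undulation_frequency: float = 0.5   # Hz
    crawl_speed: float = 5.0            # pixels / s
    intoxication: float = 0.0           # in [0, 1]
    turn_rate: float = 0.4              # radians / s of random heading drift
    speed_depression: float = 0.7       # s
    amplitude_depression: float = 0.5   # a

    def __post_init__(self) -> None:
        if not 0.0 <= self.intoxication <= 1.0:
            raise ValueError("intoxication must be in [0, 1]")
        if self.n_segments < 2:
            raise ValueError("need at least 2 body segments")
        if self.effective_speed < 0 or self.effective_amplitude < 0:
            raise ValueError("depression coefficients must keep speed/amplitude >= 0")

    @property
    def effective_speed(self) -> float:
        return self.crawl_speed * (1.0 - self.speed_depression * self.intoxication)

    @property
    def effective_amplitude(self) -> float:
        return self.bend_amplitude * (1.0 - self.amplitude_depression * self.intoxication)


@dataclass
class RenderConfig:
    """Rendering and scene parameters for one corral recording."""

    frame_count: int = 120
    frame_rate: float = 1.0            # Hz
    image_size: tuple[int, int] = (320, 320)   # (H, W)
    corral_center: tuple[float, float] = (160.0, 160.0)  # (y, x)
    corral_radius: float = 150.0
    background_level: float = 150.0
    illumination_gradient: float = 0.15  # intensity per pixel, linear x-ramp
    noise_sd: float = 2.0
    worm_polarity: str = "dark_on_bright"
    worm_contrast: float = 60.0
    bit_depth: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frame_count < 2:
            raise ValueError("frame_count must be >= 2")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.worm_polarity not in ("dark_on_bright", "bright_on_dark"):
            raise ValueError(f"unknown worm_polarity {self.worm_polarity!r}")
        h, w = self.image_size
        cy, cx = self.corral_center
        r = self.corral_radius
        if not (r <= cy <= h - r and r <= cx <= w - r):
            raise ValueError("corral must lie fully inside the image bounds")

    def background(self) -> np.ndarray:
        """Noise-free background: flat level plus a linear illumination ramp."""
        h, w = self.image_size
        ramp = self.illumination_gradient * np.arange(w, dtype=float)
        return np.full((h, w), float(self.background_level)) + ramp[None, :]


@dataclass
class WormPaths:
    """Per-frame body centerlines for a group of simulated worms.

    ``coords`` has shape (n_worms, n_frames, n_segments, 2) holding
    (y, x) pixel positions; ``body_width`` is carried along for
    rasterisation.
    """

    coords: np.ndarray
    body_width: float


def simulate_worm_paths(kin: WormKinematics, cfg: RenderConfig,
                        n_worms: int, seed: int) -> WormPaths:
    """Simulate centerlines of undulating worms confined in the corral.

    Body tangent angles follow a travelling sine wave
    phi(u, t) = heading + A_eff * sin(2*pi*(u/lambda - f*t) + phase),
    integrated from head to tail; the head advances along its local
    tangent at the effective speed and the heading reflects off the
    corral wall.  Random heading drift is scaled by the effective-speed
    ratio (turning requires propulsion), so a fully depressed worm is
    exactly stationary.
    """
    if n_worms < 1:
        raise ValueError("n_worms must be >= 1")
    if kin.body_length >= 2 * cfg.corral_radius:
        raise ValueError(
            f"worm of length {kin.body_length} cannot be placed in a corral of "
            f"diameter {2 * cfg.corral_radius}"
        )
    rng = np.random.default_rng(seed)
    dt = 1.0 / cfg.frame_rate
    v_eff = kin.effective_speed
    a_eff = kin.effective_amplitude
    drift_scale = v_eff / kin.crawl_speed if kin.crawl_speed > 0 else 0.0
    wavelength = kin.undulation_wavelength * kin.body_length
    ds = kin.body_length / (kin.n_segments - 1)
    u = np.arange(kin.n_segments) * ds
    cy, cx = cfg.corral_center
    margin = kin.body_width / 2.0 + 1.0
    place_radius = max(cfg.corral_radius - kin.body_length - margin, 1.0)

    coords = np.empty((n_worms, cfg.frame_count, kin.n_segments, 2), dtype=float)
    for wi in range(n_worms):
        rho = place_radius * np.sqrt(rng.uniform())
        ang = rng.uniform(0, 2 * np.pi)
        head = np.array([cy + rho * np.sin(ang), cx + rho * np.cos(ang)])
        heading = rng.uniform(0, 2 * np.pi)
        phase = rng.uniform(0, 2 * np.pi)
        for ti in range(cfg.frame_count):
            t = ti * dt
            phi = heading + a_eff * np.sin(
                2 * np.pi * (u / wavelength - kin.undulation_frequency * t) + phase
            )
            # integrate tail-ward from the head
            steps = np.stack([np.sin(phi[:-1]), np.cos(phi[:-1])], axis=1) * ds
            pts = head - np.concatenate(
                [np.zeros((1, 2)), np.cumsum(steps, axis=0)], axis=0
            )
            coords[wi, ti] = pts
            # advance head along its local tangent
            head_dir = np.array([np.sin(phi[0]), np.cos(phi[0])])
            new_head = head + v_eff * dt * head_dir
            # reflect heading off the corral wall
            rel = new_head - np.array([cy, cx])
            dist = np.hypot(*rel)
            limit = cfg.corral_radius - margin
            if dist > limit:
                normal = rel / dist
                vec = np.array([np.sin(heading), np.cos(heading)])
                vec = vec - 2.0 * np.dot(vec, normal) * normal
                heading = np.arctan2(vec[0], vec[1])
                new_head = np.array([cy, cx]) + normal * limit
            else:
                heading += kin.turn_rate * dt * drift_scale * rng.standard_normal()
            head = new_head
    return WormPaths(coords=coords, body_width=kin.body_width)


_DISK_CACHE: dict = {}


def _disk_offsets(radius: float) -> tuple[np.ndarray, np.ndarray]:
    """Integer pixel offsets of a filled disk (cached per radius)."""
    key = round(radius, 6)
    if key not in _DISK_CACHE:
        rr, cc = disk((0, 0), max(radius, 0.5))
        _DISK_CACHE[key] = (rr, cc)
    return _DISK_CACHE[key]


def rasterize_paths(paths: WormPaths, shape: tuple[int, int],
                    frame: int | None = None) -> np.ndarray:
    """Boolean footprint of all worms, for one frame or the union over time.

    Each centerline point is stamped as a filled disk of radius
    body_width/2 centred on the nearest pixel, so dense centerlines
    rasterise to thick polylines.
    """
    coords = paths.coords if frame is None else paths.coords[:, frame:frame + 1]
    pts = coords.reshape(-1, 2)
    dy, dx = _disk_offsets(paths.body_width / 2.0)
    yy = (np.rint(pts[:, 0]).astype(int)[:, None] + dy[None, :]).ravel()
    xx = (np.rint(pts[:, 1]).astype(int)[:, None] + dx[None, :]).ravel()
    keep = (yy >= 0) & (yy < shape[0]) & (xx >= 0) & (xx < shape[1])
    mask = np.zeros(shape, dtype=bool)
    mask[yy[keep], xx[keep]] = True
    return mask


def render_stack(paths: WormPaths | None, cfg: RenderConfig) -> ImageStack:
    """Render worm centerlines into a noisy grayscale image stack.

    Each frame is the background (flat level + illumination ramp) plus
    i.i.d. Gaussian noise, with every worm drawn as a thick polyline at
    the configured polarity and contrast.  Intensities are clipped to
    the valid range of the configured bit depth.  Deterministic given
    ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    h, w = cfg.image_size
    bg = cfg.background()
    vmax = 255.0 if cfg.bit_depth == 8 else 65535.0
    sign = -1.0 if cfg.worm_polarity == "dark_on_bright" else 1.0
    frames = np.empty((cfg.frame_count, h, w), dtype=float)
    for ti in range(cfg.frame_count):
        img = bg.copy()
        if paths is not None:
            mask = rasterize_paths(paths, (h, w), frame=ti)
            img[mask] += sign * cfg.worm_contrast
        if cfg.noise_sd > 0:
            img += rng.normal(0.0, cfg.noise_sd, size=(h, w))
        frames[ti] = img
    frames = np.clip(np.rint(frames), 0, vmax)
    dtype = np.uint8 if cfg.bit_depth == 8 else np.uint16
    return ImageStack(frames=frames.astype(dtype), bit_depth=cfg.bit_depth,
                      frame_rate=cfg.frame_rate)


# ---------------------------------------------------------------------------
# Yoked trial tables
# ---------------------------------------------------------------------------

# residual SDs back-calculated from the target yoked-difference SDs:
# D = delta + (eps' - eps)  =>  sd(D) = sqrt(2) * residual_sd
_CHRONIC_D_SD = 0.1475
_INTERMITTENT_D_SD = 0.127


@dataclass
class SimDesign:
    """Generative design of a yoked transgenerational experiment.

    Each yoked pair consists of a control-line group and an EtOH-line
    group on one plate.  Baseline scores are drawn per generation;
    on-EtOH scores are the baseline times (r + plate effect + lineage
    effect + residual), so the plate effect is shared within a pair and
    cancels exactly in the yoked difference — the mechanism that makes
    yoked normalisation matter.

    Defaults are the chronic-paradigm design: pair counts per generation
    (32, 27, 38), a lineage effect of +0.07 confined to F3, and a
    residual SD giving a yoked-difference SD near 0.1475.
    """

    paradigm: str = "chronic"
    n_pairs: dict = field(default_factory=lambda: {"F1": 32, "F2": 27, "F3": 38})
    baseline_mean: dict = field(
        default_factory=lambda: {"F1": 0.020, "F2": 0.020, "F3": 0.016})
    baseline_sd: float = 0.003
    intoxication_ratio: float = 0.5
    lineage_effect: dict = field(
        default_factory=lambda: {"F1": 0.0, "F2": 0.0, "F3": 0.07})
    plate_effect_sd: float = 0.05
    residual_sd: float = _CHRONIC_D_SD / np.sqrt(2.0)
    n_worms_range: tuple[int, int] = (8, 16)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.intoxication_ratio < 1.0:
            raise ValueError("intoxication_ratio must be in (0, 1)")
        if any(n < 1 for n in self.n_pairs.values()):
            raise ValueError("need at least one yoked pair per generation")
        for name in ("baseline_sd", "plate_effect_sd", "residual_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @classmethod
    def chronic(cls, **overrides) -> "SimDesign":
        return cls(**overrides)

    @classmethod
    def intermittent(cls, **overrides) -> "SimDesign":
        defaults = dict(
            paradigm="intermittent",
            n_pairs={"F1": 23, "F2": 6, "F3": 7},
            lineage_effect={"F1": 0.0, "F2": 0.0, "F3": -0.133},
            residual_sd=_INTERMITTENT_D_SD / np.sqrt(2.0),
        )
        defaults.update(overrides)
        return cls(**defaults)


def generate_trial_table(design: SimDesign) -> pd.DataFrame:
    """Draw a yoked trial table (4 rows per pair) from the design.

    Per pair: plate effect p ~ N(0, plate_effect_sd); baselines
    B_c, B_e ~ N(baseline_mean[g], baseline_sd); on-EtOH scores
    E_c = B_c*(r + p + eps), E_e = B_e*(r + p + delta[g] + eps') with
    eps, eps' ~ N(0, residual_sd).  Scores are truncated at 0 (rate
    logged; an error is raised if more than half of all scores would be
    truncated).  Deterministic given ``design.seed``.
    """
    rng = np.random.default_rng(design.seed)
    lo, hi = design.n_worms_range
    rows = []
    truncated = 0
    total_scores = 0
    pair_id = 0
    for gen in GENERATIONS:
        n = design.n_pairs.get(gen, 0)
        if n == 0:
            continue
        p = rng.normal(0.0, design.plate_effect_sd, size=n)
        b_c = rng.normal(design.baseline_mean[gen], design.baseline_sd, size=n)
        b_e = rng.normal(design.baseline_mean[gen], design.baseline_sd, size=n)
        eps_c = rng.normal(0.0, design.residual_sd, size=n)
        eps_e = rng.normal(0.0, design.residual_sd, size=n)
        e_c = b_c * (design.intoxication_ratio + p + eps_c)
        e_e = b_e * (design.intoxication_ratio + p + design.lineage_effect[gen] + eps_e)
        nw_c = rng.integers(lo, hi + 1, size=n)
        nw_e = rng.integers(lo, hi + 1, size=n)
        for k in range(n):
            pair_id += 1
            plate = f"plate_{pair_id:03d}"
            for lineage, b, e, nw in (
                ("control", b_c[k], e_c[k], nw_c[k]),
                ("etoh", b_e[k], e_e[k], nw_e[k]),
            ):
                for condition, score in (("baseline", b), ("etoh", e)):
                    total_scores += 1
                    if score < 0:
                        truncated += 1
                        score = 0.0
                    rows.append((f"{design.paradigm}_{pair_id:03d}", plate, gen,
                                 lineage, condition, int(nw), float(score)))
    table = pd.DataFrame(rows, columns=TRIAL_TABLE_COLUMNS)
    trunc_rate = truncated / total_scores
    if trunc_rate > 0:
        logger.info("trial table: %.1f%% of scores truncated at 0", 100 * trunc_rate)
    if trunc_rate > 0.5:
        raise ValueError(
            f"degenerate design: {100 * trunc_rate:.0f}% of scores truncated at 0")
    table.attrs["truncated_fraction"] = trunc_rate
    return table
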