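"""Synthetic single-molecule data with full ground truth.

Generates the three kinds of data the analysis consumes — per-cluster blink
counts, clustered localization fields, and multi-state trajectories — from
the same generative assumptions the estimators invert:

* cluster centres follow a homogeneous Poisson process (default
  0.63 clusters/um^2);
* each cluster is a monomer or dimer; protomers are labeled with probability
  L (0.81) and detected with probability d (0.79); clusters with no detected
  protomer are rejected and regenerated (the rejection count is recorded so
  detectability corrections can be validated exactly);
* each detected protomer blinks geometric(p) times (default p = 0.27);
* localization noise is isotropic Gaussian (default sigma = 10 nm);
* trajectories are immobile, confined (reflecting disk of radius r_c) or
  free (2D Brownian), with per-axis step variance 2 D dt.

Every generator takes a seed (or an existing Generator) and returns a ground
truth table sufficient to score any downstream estimator without
re-simulation.  Identical seed and config give byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .blink import BlinkHistogram
from .errors import DataError, ParameterError
from .locdata import LocalizationTable
from .spt import MIN_TRACK_LENGTH, TrackSet, Trajectory

__all__ = [
    "PhotophysicsConfig",
    "PopulationConfig",
    "DiffusionConfig",
    "LigandConfig",
    "SimConfig",
    "GroundTruth",
    "sim_blink_counts",
    "sim_localization_field",
    "sim_tracks",
    "sim_ligand_channel",
]


@dataclass
class PhotophysicsConfig:
    p: float = 0.27          # bleach probability per appearance
    d: float = 0.79          # per-protomer detection efficiency
    L: float = 0.81          # labeling efficiency

    @property
    def d_abs(self) -> float:
        return self.d * self.L


@dataclass
class PopulationConfig:
    density: float = 0.63        # clusters per um^2
    dimer_fraction: float = 0.05  # true-population dimer fraction (resting)


@dataclass
class DiffusionConfig:
    # immobile/confined/free; the ligand-stimulated condition
    fractions: tuple[float, float, float] = (0.72, 0.14, 0.14)
    d_free: float = 0.10         # um^2/s
    d_conf: float = 0.05         # um^2/s
    r_conf: float = 100.0        # nm, confinement radius
    track_length_mean: float = 30.0
    n_tracks: int = 500


@dataclass
class LigandConfig:
    bound_fraction: float = 0.5
    registration_sigma: float = 20.0  # nm, channel registration noise
    locs_per_site: int = 1


@dataclass
class SimConfig:
    """All knobs of the generator, mirroring the imaging conditions emulated."""

    seed: int = 0
    fov: tuple[float, float] = (20000.0, 20000.0)  # nm
    n_frames: int = 10000
    frame_time: float = 0.02      # s
    sigma_loc: float = 10.0       # nm
    photophysics: PhotophysicsConfig = field(default_factory=PhotophysicsConfig)
    population: PopulationConfig = field(default_factory=PopulationConfig)
    diffusion: DiffusionConfig = field(default_factory=DiffusionConfig)
    ligand: LigandConfig = field(default_factory=LigandConfig)
    # inter-appearance dark gaps: (max_dark_grouping + 1) + Geometric(1/mean_extra)
    max_dark_grouping: int = 3
    dark_gap_mean_extra: float = 10.0
    # frames per appearance (a burst of `on_frames` consecutive localizations);
    # >1 creates the adjacent-frame re-localizations NeNA needs
    on_frames: int = 1

    def __post_init__(self) -> None:
        ph, pop, dif, lig = self.photophysics, self.population, self.diffusion, self.ligand
        for name, v in (("p", ph.p), ("d", ph.d), ("L", ph.L)):
            if not 0 < v <= 1:
                raise ParameterError(f"photophysics.{name} must be in (0, 1]")
        if not 0 <= pop.dimer_fraction <= 1:
            raise ParameterError("population.dimer_fraction must be in [0, 1]")
        if pop.density <= 0:
            raise ParameterError("population.density must be > 0")
        if abs(sum(dif.fractions) - 1.0) > 1e-9:
            raise ParameterError("diffusion.fractions must sum to 1")
        if min(dif.fractions) < 0:
            raise ParameterError("diffusion.fractions must be >= 0")
        if not 0 <= lig.bound_fraction <= 1:
            raise ParameterError("ligand.bound_fraction must be in [0, 1]")
        if self.sigma_loc < 0 or self.frame_time <= 0 or self.n_frames < 1:
            raise ParameterError("invalid acquisition settings")
        if self.on_frames < 1 or self.max_dark_grouping < 0 or self.dark_gap_mean_extra <= 0:
            raise ParameterError("invalid appearance timing settings")

    # -- serialisation -----------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, payload: dict) -> "SimConfig":
        payload = dict(payload)
        for key, sub in (("photophysics", PhotophysicsConfig),
                         ("population", PopulationConfig),
                         ("diffusion", DiffusionConfig),
                         ("ligand", LigandConfig)):
            if key in payload and isinstance(payload[key], dict):
                payload[key] = sub(**payload[key])
        for key in ("fov",):
            if key in payload and isinstance(payload[key], list):
                payload[key] = tuple(payload[key])
        if isinstance(payload.get("diffusion"), DiffusionConfig):
            d = payload["diffusion"]
            if isinstance(d.fractions, list):
                d.fractions = tuple(d.fractions)
        return cls(**payload)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        if not isinstance(payload, dict):
            raise ParameterError("config file must contain a mapping")
        try:
            return cls.from_dict(payload)
        except TypeError as exc:
            raise ParameterError(f"invalid config field: {exc}") from exc

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(json.loads(json.dumps(self.to_dict())), fh, sort_keys=True)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=list).encode()
        ).hexdigest()[:16]


@dataclass
class GroundTruth:
    """Per-cluster / per-track truth sufficient to score every estimator."""

    clusters: pd.DataFrame | None = None   # id, size, n_labeled, n_detected, n_appearances, x, y, bound
    tracks: pd.DataFrame | None = None     # id, state, D_true, r_conf, length, x0, y0, bound
    n_rejected: int = 0                    # clusters discarded for zero detections


def _rng_streams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def sim_blink_counts(
    n_clusters: int,
    config: SimConfig,
    rng: np.random.Generator | None = None,
    n_max: int = 50,
) -> tuple[BlinkHistogram, GroundTruth]:
    """Simulate per-cluster appearance counts from the counting model.

    Cluster sizes are drawn from the monomer/dimer composition; protomers are
    independently labeled (L) and detected (d); clusters with zero detected
    protomers are rejected and regenerated.  Each detected protomer blinks
    Geometric(p) times and the histogram collects the totals.
    """
    if n_clusters < 1:
        raise ParameterError("n_clusters must be >= 1")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    ph, pop = config.photophysics, config.population

    sizes = np.empty(0, int)
    labeled = np.empty(0, int)
    detected = np.empty(0, int)
    n_rejected = 0
    while len(sizes) < n_clusters:
        remaining = n_clusters - len(sizes)
        draw = max(int(remaining * 2.5), 32)
        s = (rng.random(draw) < pop.dimer_fraction).astype(int) + 1
        lab = rng.binomial(s, ph.L)
        det = rng.binomial(lab, ph.d)
        keep = det >= 1
        # walk the batch only up to the draw that fills the quota, so the
        # rejection count is exact (needed to validate detectability corrections)
        acc = np.cumsum(keep)
        if acc[-1] <= remaining:
            stop = draw
        else:
            stop = int(np.searchsorted(acc, remaining)) + 1
        sel = keep[:stop]
        n_rejected += int(stop - sel.sum())
        sizes = np.concatenate([sizes, s[:stop][sel]])
        labeled = np.concatenate([labeled, lab[:stop][sel]])
        detected = np.concatenate([detected, det[:stop][sel]])
    sizes, labeled, detected = sizes[:n_clusters], labeled[:n_clusters], detected[:n_clusters]

    n_app = rng.geometric(ph.p, n_clusters)
    second = detected == 2
    n_app = n_app + np.where(second, rng.geometric(ph.p, n_clusters), 0)

    truth = GroundTruth(
        clusters=pd.DataFrame({
            "id": np.arange(n_clusters),
            "size": sizes,
            "n_labeled": labeled,
            "n_detected": detected,
            "n_appearances": n_app,
        }),
        n_rejected=n_rejected,
    )
    return BlinkHistogram.from_counts(n_app, n_max=n_max), truth


def _appearance_frames(
    n_app: int, n_frames: int, max_dark: int, mean_extra: float,
    on_frames: int, rng: np.random.Generator
) -> np.ndarray:
    """Start frames of n_app appearances with dark gaps always > max_dark."""
    gaps = (max_dark + 1) + rng.geometric(1.0 / mean_extra, max(n_app - 1, 0))
    step = gaps + on_frames
    offsets = np.concatenate([[0], np.cumsum(step)]) if n_app > 1 else np.array([0])
    span = int(offsets[-1]) + on_frames
    start = int(rng.integers(0, max(n_frames - span, 1)))
    return start + offsets.astype(int)


def sim_localization_field(
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[LocalizationTable, GroundTruth]:
    """Simulate a clustered localization field (one PALM acquisition).

    Cluster centres form a homogeneous Poisson process at the configured
    density; blink counts come from :func:`sim_blink_counts`; appearances are
    one frame long and separated by dark gaps longer than the grouping
    threshold, so appearance extraction at default settings is exact; each
    localization is jittered by Gaussian sigma_loc.
    """
    rng_pop, rng_time, rng_noise, rng_flags = (
        _rng_streams(config.seed, 4) if rng is None else [rng] * 4
    )
    w, h = config.fov
    area_um2 = (w / 1000.0) * (h / 1000.0)
    n_clusters = max(int(rng_pop.poisson(config.population.density * area_um2)), 1)
    centers = np.column_stack([rng_pop.random(n_clusters) * w, rng_pop.random(n_clusters) * h])

    hist, truth = sim_blink_counts(n_clusters, config, rng=rng_pop)
    n_app = truth.clusters["n_appearances"].to_numpy()

    rows = []
    for cid in range(n_clusters):
        starts = _appearance_frames(int(n_app[cid]), config.n_frames,
                                    config.max_dark_grouping,
                                    config.dark_gap_mean_extra,
                                    config.on_frames, rng_time)
        for f0 in starts:
            for f in range(f0, f0 + config.on_frames):
                dx, dy = (rng_noise.normal(0.0, config.sigma_loc, 2)
                          if config.sigma_loc > 0 else (0.0, 0.0))
                rows.append((int(f), centers[cid, 0] + dx, centers[cid, 1] + dy, cid))
    df = pd.DataFrame(rows, columns=["frame", "x", "y", "cluster_id"])
    df = df.sort_values(["frame"], kind="stable").reset_index(drop=True)
    loc = pd.DataFrame({
        "frame": df["frame"].astype(int),
        "x": df["x"], "y": df["y"],
        "precision": config.sigma_loc if config.sigma_loc > 0 else 1.0,
        "channel": 0,
    })
    truth.clusters["x"] = centers[:, 0]
    truth.clusters["y"] = centers[:, 1]
    truth.clusters["bound"] = rng_flags.random(n_clusters) < config.ligand.bound_fraction
    table = LocalizationTable(data=loc, frame_time=config.frame_time, fov=None)
    return table, truth


def sim_tracks(
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[TrackSet, LocalizationTable, GroundTruth]:
    """Simulate three-state trajectories plus their localization table.

    States are drawn from the configured fractions; immobile tracks are static
    points, free tracks are unconstrained 2D Brownian walks, confined tracks
    are Brownian walks radially reflected at r_conf around their origin.
    Localization noise is added to every sample.  Track lengths are geometric
    with the configured mean, floored at the minimum analyzable length.
    """
    rngs = _rng_streams(config.seed, 3) if rng is None else [rng] * 3
    rng_pop, rng_path, rng_noise = rngs
    dif = config.diffusion
    n = dif.n_tracks
    if n < 1:
        raise ParameterError("diffusion.n_tracks must be >= 1")
    w, h = config.fov
    dt = config.frame_time
    states = rng_pop.choice(3, size=n, p=np.asarray(dif.fractions))
    state_names = np.array(["immobile", "confined", "free"])
    lengths = np.maximum(MIN_TRACK_LENGTH, rng_pop.geometric(1.0 / dif.track_length_mean, n))
    margin = max(dif.r_conf, 500.0)
    x0 = margin + rng_pop.random(n) * (w - 2 * margin)
    y0 = margin + rng_pop.random(n) * (h - 2 * margin)
    starts = rng_pop.integers(0, max(config.n_frames - int(lengths.max()), 1), n)

    tracks: list[Trajectory] = []
    rows = []
    for i in range(n):
        L = int(lengths[i])
        pos = np.empty((L, 2))
        pos[0] = (x0[i], y0[i])
        if states[i] == 0:  # immobile
            pos[:] = pos[0]
        else:
            D = dif.d_conf if states[i] == 1 else dif.d_free
            step_sd = np.sqrt(2.0 * D * dt) * 1000.0  # nm per axis
            steps = rng_path.normal(0.0, step_sd, (L - 1, 2))
            if states[i] == 2:  # free
                pos[1:] = pos[0] + np.cumsum(steps, axis=0)
            else:  # confined: radial reflection at r_conf about the origin
                center = pos[0].copy()
                cur = pos[0].copy()
                for k in range(1, L):
                    cur = cur + steps[k - 1]
                    rvec = cur - center
                    r = np.hypot(*rvec)
                    if r > dif.r_conf:
                        cur = center + rvec * ((2 * dif.r_conf - r) / r)
                    pos[k] = cur
        noisy = pos + (rng_noise.normal(0.0, config.sigma_loc, pos.shape)
                       if config.sigma_loc > 0 else 0.0)
        frames = starts[i] + np.arange(L)
        tracks.append(Trajectory(id=i, frames=frames, xy=noisy, channel=0))
        for f, (x, y) in zip(frames, noisy):
            rows.append((int(f), float(x), float(y), i))

    loc = pd.DataFrame(rows, columns=["frame", "x", "y", "track_id"])
    loc = loc.sort_values("frame", kind="stable").reset_index(drop=True)
    loc_table = LocalizationTable(
        data=pd.DataFrame({"frame": loc["frame"].astype(int), "x": loc["x"], "y": loc["y"],
                           "precision": config.sigma_loc if config.sigma_loc > 0 else 1.0,
                           "channel": 0}),
        frame_time=dt, fov=None,
    )
    truth = GroundTruth(tracks=pd.DataFrame({
        "id": np.arange(n),
        "state": state_names[states],
        "D_true": np.where(states == 0, 0.0,
                           np.where(states == 1, dif.d_conf, dif.d_free)),
        "r_conf": np.where(states == 1, dif.r_conf, np.nan),
        "length": lengths,
        "x0": x0, "y0": y0,
        "bound": rng_pop.random(n) < config.ligand.bound_fraction,
    }))
    return TrackSet(tracks=tracks, frame_time=dt), loc_table, truth


def sim_ligand_channel(
    truth: GroundTruth,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> LocalizationTable:
    """Place ligand-channel localizations at bound clusters (or track origins).

    Each bound site receives `locs_per_site` localizations at its position
    plus Gaussian channel-registration noise; channel label is 1.
    """
    if truth.clusters is None and truth.tracks is None:
        raise DataError("ground truth carries no clusters or tracks")
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(5)[-1])
    if truth.clusters is not None:
        sites = truth.clusters.loc[truth.clusters["bound"], ["x", "y"]].to_numpy()
    else:
        sites = truth.tracks.loc[truth.tracks["bound"], ["x0", "y0"]].to_numpy()
    k = config.ligand.locs_per_site
    rows = []
    for (x, y) in sites:
        for j in range(k):
            noise = (rng.normal(0.0, config.ligand.registration_sigma, 2)
                     if config.ligand.registration_sigma > 0 else np.zeros(2))
            rows.append((int(rng.integers(0, config.n_frames)), x + noise[0], y + noise[1]))
    df = pd.DataFrame(rows, columns=["frame", "x", "y"])
    df["channel"] = 1
    df = df.sort_values("frame", kind="stable").reset_index(drop=True)
    return LocalizationTable(data=df, frame_time=config.frame_time, fov=None)
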