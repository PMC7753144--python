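"""Single-particle tracking: linking, MSD curves, diffusion-state classification.

Trajectories are classified into three membrane diffusion states from their
time-averaged mean square displacement (MSD):

* immobile — early-lag MSD stays at the localization-noise floor 4 sigma^2;
* free     — MSD(tau) = 4 D tau + 4 sigma^2 (2D Brownian motion);
* confined — MSD(tau) = P (1 - exp(-4 D0 tau / P)) + 4 sigma^2, a plateau P
  set by the confinement radius.

Confined vs free is decided by model selection on the per-track MSD curve:
the confined model must beat the free one by an F-ratio criterion, reach its
plateau inside the fitted lag window, and show genuine downward curvature
(see :func:`classify_track`).  The apparent diffusion coefficient D is taken
from the linear slope over the first lags in all mobile cases, matching how
per-state coefficients are conventionally reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field


import numpy as np
import pandas as pd
from scipy import optimize

from .errors import ComparisonError, DataError, ParameterError
from .locdata import LocalizationTable

__all__ = [
    "Trajectory",
    "TrackSet",
    "MSDCurve",
    "DiffusionClassification",
    "MobilityReport",
    "link_localizations",
    "compute_msd",
    "classify_track",
    "mobility_report",
    "compare_channels",
]

MIN_TRACK_LENGTH = 8
STATES = ("immobile", "confined", "free")


@dataclass
class Trajectory:
    """One linked single-molecule trajectory (frames strictly increasing)."""

    id: int
    frames: np.ndarray           # int, strictly increasing
    xy: np.ndarray               # (N, 2), nm
    channel: int = 0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, int)
        self.xy = np.asarray(self.xy, float)
        if len(self.frames) != len(self.xy):
            raise ParameterError("frames and xy must have equal length")
        if len(self.frames) > 1 and np.any(np.diff(self.frames) <= 0):
            raise ParameterError("frames must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)


@dataclass
class TrackSet:
    """A collection of trajectories sharing acquisition metadata."""

    tracks: list[Trajectory]
    frame_time: float

    def __len__(self) -> int:
        return len(self.tracks)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for t in self.tracks:
            for f, (x, y) in zip(t.frames, t.xy):
                rows.append((t.id, int(f), float(x), float(y), t.channel))
        return pd.DataFrame(rows, columns=["track_id", "frame", "x", "y", "channel"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame, frame_time: float) -> "TrackSet":
        tracks = []
        for tid, sub in df.groupby("track_id"):
            sub = sub.sort_values("frame")
            channel = int(sub["channel"].iloc[0]) if "channel" in sub.columns else 0
            tracks.append(Trajectory(id=int(tid), frames=sub["frame"].to_numpy(int),
                                     xy=sub[["x", "y"]].to_numpy(float), channel=channel))
        return cls(tracks=tracks, frame_time=frame_time)


def link_localizations(
    table: LocalizationTable,
    max_disp: float = 500.0,
    max_gap: int = 1,
) -> TrackSet:
    """Greedy nearest-neighbour frame-to-frame linking.

    A localization at frame f may extend a track last seen at frame
    f - 1 - gap (gap <= `max_gap` skipped frames) if the jump is at most
    ``max_disp * (gap + 1)`` nm.  Candidate links are taken shortest first;
    ties break toward the lower localization index.  No localization joins
    two tracks.
    """
    if max_disp <= 0 or max_gap < 0:
        raise ParameterError("max_disp must be > 0 and max_gap >= 0")
    table = table.sorted_by_frame()
    frames = table.frames
    coords = table.coords
    channel = (table.data["channel"].to_numpy(int)
               if "channel" in table.data.columns else np.zeros(len(table), int))

    track_frames: list[list[int]] = []
    track_xy: list[list[tuple[float, float]]] = []
    track_last: list[int] = []
    track_channel: list[int] = []
    active: list[int] = []

    for f in np.unique(frames):
        idx = np.flatnonzero(frames == f)
        active = [t for t in active if f - track_last[t] - 1 <= max_gap]
        # candidate (distance, loc_rank, track) triples
        cands = []
        for rank, i in enumerate(idx):
            x, y = coords[i]
            for t in active:
                gap = f - track_last[t] - 1
                px, py = track_xy[t][-1]
                d = float(np.hypot(px - x, py - y))
                if d <= max_disp * (gap + 1):
                    cands.append((d, rank, t, i))
        cands.sort()
        used_tracks: set[int] = set()
        used_locs: set[int] = set()
        for d, rank, t, i in cands:
            if t in used_tracks or i in used_locs:
                continue
            track_frames[t].append(int(f))
            track_xy[t].append((coords[i][0], coords[i][1]))
            track_last[t] = int(f)
            used_tracks.add(t)
            used_locs.add(i)
        for i in idx:
            if i not in used_locs:
                track_frames.append([int(f)])
                track_xy.append([(coords[i][0], coords[i][1])])
                track_last.append(int(f))
                track_channel.append(int(channel[i]))
                active.append(len(track_frames) - 1)

    tracks = [
        Trajectory(id=t, frames=np.array(track_frames[t]), xy=np.array(track_xy[t]),
                   channel=track_channel[t] if t < len(track_channel) else 0)
        for t in range(len(track_frames))
    ]
    return TrackSet(tracks=tracks, frame_time=table.frame_time)


@dataclass
class MSDCurve:
    """Time-averaged MSD: lag times in seconds, MSD in um^2."""

    lags: np.ndarray             # seconds
    msd: np.ndarray              # um^2
    counts: np.ndarray           # displacement pairs per lag


def compute_msd(track: Trajectory, frame_time: float) -> MSDCurve:
    """Time-averaged MSD over internal lags k = 1 .. floor(len/2).

    MSD(k dt) averages |r(t + k) - r(t)|^2 over all start times t present in
    the track; positions are converted from nm^2 to um^2.
    """
    n = len(track)
    if n < MIN_TRACK_LENGTH:
        raise DataError(f"track {track.id} too short for MSD ({n} < {MIN_TRACK_LENGTH})")
    if frame_time <= 0:
        raise ParameterError("frame_time must be > 0")
    frames = track.frames
    xy = track.xy
    kmax = n // 2
    lags = np.arange(1, kmax + 1) * frame_time
    msd = np.zeros(kmax)
    counts = np.zeros(kmax, int)
    for k in range(1, kmax + 1):
        target = frames + k
        j = np.searchsorted(frames, target)
        ok = j < n
        ok[ok] &= frames[j[ok]] == target[ok]
        if not ok.any():
            continue
        disp = xy[j[ok]] - xy[ok]
        msd[k - 1] = float(np.mean(np.sum(disp**2, axis=1))) / 1e6
        counts[k - 1] = int(ok.sum())
    return MSDCurve(lags=lags, msd=msd, counts=counts)


@dataclass
class DiffusionClassification:
    """State call and apparent diffusion coefficient for one trajectory."""

    state: str                   # immobile | confined | free
    D: float                     # um^2/s, from the early-lag linear slope
    diagnostics: dict = field(default_factory=dict)


def _fit_free(lags: np.ndarray, msd: np.ndarray, floor: float) -> float:
    """Least-squares slope of MSD = slope * tau + floor (fixed intercept)."""
    return float(np.dot(lags, msd - floor) / np.dot(lags, lags))


def classify_track(
    msd: MSDCurve,
    sigma_loc: float,
    k_imm: float = 3.0,
    n_fit_lags: int = 4,
    f_crit: float = 4.0,
    ratio_thresh: float = 0.5,
    max_fit_lags: int = 10,
    min_lags: int = 8,
) -> DiffusionClassification:
    """Classify a trajectory as immobile, confined, or free from its MSD.

    Cascade:

    1. immobile when the early-lag MSD (mean of the first two lags) does not
       exceed ``k_imm * 4 sigma_loc^2`` (the localization-noise floor);
    2. otherwise both models are least-squares fitted on a window of up to
       `max_fit_lags` lags (intercept fixed at the noise floor), and confined
       is called only when all three hold:

       * the confined model's extra parameter is statistically warranted —
         its residual improvement passes an F-ratio test at ``f_crit``;
       * the fitted confinement time ``P / (4 D0)`` lies inside the window,
         i.e. the plateau is actually reached (a saturating curve can mimic a
         line when it is not);
       * the curvature ratio — observed MSD at the window end over the
         short-lag linear extrapolation — is below `ratio_thresh`.

    The apparent D always comes from the first-`n_fit_lags` linear slope.
    Tracks with fewer than `min_lags` lags (default 8, i.e. 16 points) are
    unclassifiable: single-track confined-vs-free model selection is
    meaningless on shorter time-averaged MSD curves, whose relative noise at
    lag k is ~sqrt(k/N).
    """
    if sigma_loc <= 0:
        raise ParameterError("sigma_loc must be > 0")
    if len(msd.lags) < max(min_lags, n_fit_lags):
        raise DataError(f"need >= {max(min_lags, n_fit_lags)} MSD lags to classify")
    floor = 4.0 * (sigma_loc / 1000.0) ** 2  # um^2

    early = float(np.mean(msd.msd[:2]))
    lags_fit, msd_fit = msd.lags[:n_fit_lags], msd.msd[:n_fit_lags]
    slope = _fit_free(lags_fit, msd_fit, floor)
    D = max(slope / 4.0, 0.0)

    diag = {"plateau_early": early, "noise_floor": floor, "slope": slope}
    if early <= k_imm * floor:
        return DiffusionClassification(state="immobile", D=D, diagnostics=diag)

    k_star = min(len(msd.lags), max_fit_lags)
    lags_w, msd_w = msd.lags[:k_star], msd.msd[:k_star]
    slope2 = _fit_free(msd.lags[:2], msd.msd[:2], floor)
    extrap = slope2 * lags_w[-1] + floor
    ratio = float(np.mean(msd_w[k_star - 2:k_star]) / max(extrap, 1e-300))

    slope_w = _fit_free(lags_w, msd_w, floor)
    rss_free = float(np.sum((msd_w - (slope_w * lags_w + floor)) ** 2))

    def confined(tau, plateau, d0):
        return plateau * (1.0 - np.exp(-4.0 * d0 * tau / plateau)) + floor

    state = "free"
    rss_conf = np.inf
    f_stat = np.nan
    try:
        p0 = (max(float(msd_w.max()) - floor, 1e-6), max(D, 1e-4))
        popt, _ = optimize.curve_fit(
            confined, lags_w, msd_w, p0=p0,
            bounds=((1e-9, 1e-9), (np.inf, np.inf)), maxfev=5000,
        )
        rss_conf = float(np.sum((msd_w - confined(lags_w, *popt)) ** 2))
        tau_conf = popt[0] / (4.0 * popt[1])
        f_stat = (rss_free - rss_conf) / max(rss_conf / max(k_star - 2, 1), 1e-300)
        diag.update(plateau_fit=float(popt[0]), D0_fit=float(popt[1]),
                    tau_confinement=float(tau_conf))
        if f_stat > f_crit and tau_conf <= lags_w[-1] and ratio < ratio_thresh:
            state = "confined"
    except RuntimeError:
        pass  # confined fit failed to converge; fall back to free
    diag.update(rss_free=rss_free, rss_confined=rss_conf, f_stat=f_stat,
                curvature_ratio=ratio)
    return DiffusionClassification(state=state, D=D, diagnostics=diag)


@dataclass
class MobilityReport:
    """Per-state fractions and diffusion coefficients with bootstrap SEMs."""

    fractions: dict               # state -> fraction
    fractions_sem: dict           # state -> SEM
    D_mean: dict                  # state -> mean apparent D (um^2/s)
    D_sem: dict                   # state -> SEM
    n_tracks: int
    frame_time: float
    condition: str = ""
    settings: dict = field(default_factory=dict)


def _classify_set(
    trackset: TrackSet,
    sigma_loc: float,
    frame_time: float,
    **clf_kwargs,
) -> tuple[np.ndarray, np.ndarray, int]:
    states, Ds, skipped = [], [], 0
    for t in trackset.tracks:
        try:
            curve = compute_msd(t, frame_time)
            c = classify_track(curve, sigma_loc, **clf_kwargs)
        except DataError:
            skipped += 1
            continue
        states.append(c.state)
        Ds.append(c.D)
    return np.array(states), np.array(Ds), skipped


def mobility_report(
    trackset: TrackSet,
    sigma_loc: float,
    frame_time: float | None = None,
    bootstrap_B: int = 500,
    seed: int = 0,
    condition: str = "",
    **clf_kwargs,
) -> MobilityReport:
    """Classify every track and summarise state fractions and coefficients.

    Fractions are pooled over tracks; SEMs come from a bootstrap over tracks
    (deterministic for a given seed).  Requires >= 30 classifiable tracks.
    """
    frame_time = trackset.frame_time if frame_time is None else frame_time
    states, Ds, skipped = _classify_set(trackset, sigma_loc, frame_time, **clf_kwargs)
    n = len(states)
    if n < 30:
        raise DataError(f"too few classifiable tracks ({n} < 30; {skipped} skipped)")

    rng = np.random.default_rng(seed)
    onehot = {s: (states == s).astype(float) for s in STATES}
    boot_frac = {s: np.empty(bootstrap_B) for s in STATES}
    boot_D = {s: np.empty(bootstrap_B) for s in STATES}
    for b in range(bootstrap_B):
        idx = rng.integers(0, n, n)
        for s in STATES:
            sel = onehot[s][idx]
            boot_frac[s][b] = sel.mean()
            boot_D[s][b] = Ds[idx][sel.astype(bool)].mean() if sel.any() else np.nan

    fractions = {s: float(onehot[s].mean()) for s in STATES}
    report = MobilityReport(
        fractions=fractions,
        fractions_sem={s: float(boot_frac[s].std()) for s in STATES},
        D_mean={s: (float(Ds[states == s].mean()) if (states == s).any() else float("nan"))
                for s in STATES},
        D_sem={s: (float(np.nanstd(boot_D[s])) if np.isfinite(boot_D[s]).any()
                   else float("nan")) for s in STATES},
        n_tracks=n,
        frame_time=frame_time,
        condition=condition,
        settings={"sigma_loc": sigma_loc, "bootstrap_B": bootstrap_B, "seed": seed,
                  "skipped": skipped, **clf_kwargs},
    )
    assert abs(sum(report.fractions.values()) - 1.0) < 1e-9
    return report


def compare_channels(report_a: MobilityReport, report_b: MobilityReport) -> pd.DataFrame:
    """Side-by-side comparison of two mobility reports (e.g. receptor vs ligand).

    Differences are a - b; combined SEMs add in quadrature.  Raises
    ComparisonError when frame times differ.
    """
    if abs(report_a.frame_time - report_b.frame_time) > 1e-12:
        raise ComparisonError(
            f"frame times differ: {report_a.frame_time} s vs {report_b.frame_time} s"
        )
    rows = []
    for s in STATES:
        rows.append({
            "state": s,
            "fraction_a": report_a.fractions[s],
            "fraction_b": report_b.fractions[s],
            "fraction_diff": report_a.fractions[s] - report_b.fractions[s],
            "fraction_sem": float(np.hypot(report_a.fractions_sem[s], report_b.fractions_sem[s])),
            "D_a": report_a.D_mean[s],
            "D_b": report_b.D_mean[s],
            "D_diff": report_a.D_mean[s] - report_b.D_mean[s],
            "D_sem": float(np.hypot(report_a.D_sem[s], report_b.D_sem[s])),
        })
    return pd.DataFrame(rows)
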