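"""Molecular counting from blinking statistics (qPALM).

Photoconvertible fluorescent proteins such as mEos4b emit in bursts
("appearances") separated by dark periods, and finally photobleach.  If an
emitter bleaches with probability ``p`` after each appearance, the number of
appearances of one emitter is geometric,

    P(n) = p (1 - p)^(n - 1),          n = 1, 2, ...

and the total appearance count of ``m`` independent emitters is the
negative-binomial convolution

    P(n | m, p) = C(n-1, m-1) p^m (1-p)^(n-m),   n >= m.

A dimer carries two tags, but a tag may go undetected (immature or missed
fluorophore).  With per-protomer detection efficiency ``d``, a dimer that is
seen at all shows a single emitter with probability

    q = 2 (1 - d) / (2 - d)  =  P(exactly one detected | >= 1 detected),

so the appearance-count distribution of observed dimers is

    P_dim(n) = q P(n | 1, p) + (1 - q) P(n | 2, p).

Counting proceeds by (i) grouping localizations into appearance events,
(ii) grouping events into spatial nanoclusters, (iii) histogramming the
per-cluster appearance counts and (iv) fitting the histogram: the geometric
model for a monomeric reference gives ``p``; the dimer model for a dimeric
reference gives ``q`` and hence ``d``; a monomer/dimer mixture with known
``(p, d_abs)`` gives the dimer fraction of the protein of interest.
``d_abs = d x L`` folds in the labeling efficiency ``L`` so the mixture
weight can be corrected for invisible (unlabeled or undetected) protomers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import optimize, stats
from sklearn.cluster import DBSCAN

from .errors import DataError, DomainError, ParameterError
from .locdata import LocalizationTable

__all__ = [
    "PhotophysicsParams",
    "AppearanceEvent",
    "NanoCluster",
    "BlinkHistogram",
    "MixtureFit",
    "pmf_appearances",
    "pmf_dimer",
    "q_to_d",
    "d_to_q",
    "absolute_detection",
    "observed_dimer_fraction",
    "true_dimer_fraction",
    "extract_appearances",
    "cluster_events",
    "fit_p",
    "fit_q",
    "fit_mixture",
    "bootstrap_ci",
]

_EPS = 1e-300


def _check_prob(value: float, name: str, lo_open: bool = False, hi_closed: bool = True) -> float:
    value = float(value)
    lo_ok = value > 0 if lo_open else value >= 0
    hi_ok = value <= 1 if hi_closed else value < 1
    if not (lo_ok and hi_ok and np.isfinite(value)):
        lo = "(0" if lo_open else "[0"
        hi = "1]" if hi_closed else "1)"
        raise ParameterError(f"{name} must be in {lo}, {hi}; got {value}")
    return value


@dataclass(frozen=True)
class PhotophysicsParams:
    """The calibration constants of the counting model.

    p : bleaching probability per appearance, in (0, 1]
    q : probability an observed dimer shows only one emitter, in [0, 1)
    d : per-protomer detection efficiency, in (0, 1]
    L : labeling efficiency, in (0, 1]
    """

    p: float
    d: float
    L: float = 1.0

    def __post_init__(self) -> None:
        _check_prob(self.p, "p", lo_open=True)
        _check_prob(self.d, "d", lo_open=True)
        _check_prob(self.L, "L", lo_open=True)

    @property
    def q(self) -> float:
        return d_to_q(self.d)

    @property
    def d_abs(self) -> float:
        """Absolute detection efficiency d x L."""
        return self.d * self.L


def pmf_appearances(n, m: int, p: float):
    """P(total appearances = n) for m detected emitters, bleach probability p.

    Negative-binomial: C(n-1, m-1) p^m (1-p)^(n-m) on n >= m.
    Scalar or array `n`; raises DomainError when any n < m.
    """
    _check_prob(p, "p", lo_open=True)
    if int(m) != m or m < 1:
        raise ParameterError(f"m must be an integer >= 1; got {m}")
    n_arr = np.asarray(n)
    if np.any(n_arr < m):
        raise DomainError(f"appearance count n must be >= m = {m}")
    out = stats.nbinom.pmf(n_arr - m, m, p)
    return float(out) if np.isscalar(n) else out


def _pmf_m(n_arr: np.ndarray, m: int, p: float) -> np.ndarray:
    """pmf_appearances without the n >= m domain check (0 below support)."""
    return stats.nbinom.pmf(np.asarray(n_arr) - m, m, p)


def pmf_dimer(n, p: float, q: float):
    """Appearance-count pmf of an observed dimer: q-weighted 1/2-emitter mix."""
    _check_prob(p, "p", lo_open=True)
    _check_prob(q, "q", hi_closed=False)
    n_arr = np.asarray(n)
    if np.any(n_arr < 1):
        raise DomainError("appearance count n must be >= 1")
    out = q * _pmf_m(n_arr, 1, p) + (1 - q) * _pmf_m(n_arr, 2, p)
    return float(out) if np.isscalar(n) else out


def q_to_d(q: float) -> float:
    """Per-protomer detection efficiency from the dimer single-emitter fraction.

    d = 2 (1 - q) / (2 - q); inverse of :func:`d_to_q`.
    """
    _check_prob(q, "q", hi_closed=False)
    return 2.0 * (1.0 - q) / (2.0 - q)


def d_to_q(d: float) -> float:
    """q = 2 (1 - d) / (2 - d): chance an observed dimer shows one emitter."""
    _check_prob(d, "d", lo_open=True)
    return 2.0 * (1.0 - d) / (2.0 - d)


def absolute_detection(d: float, L: float) -> float:
    """Absolute detection efficiency d_abs = d x L (rounded only for display)."""
    _check_prob(d, "d", lo_open=True)
    _check_prob(L, "L", lo_open=True)
    return d * L


def observed_dimer_fraction(f_true: float, d_abs: float) -> float:
    """Dimer fraction among *observed* clusters given the true fraction.

    A monomer is observed with probability d_abs, a dimer with
    1 - (1 - d_abs)^2, which tilts the observed mixture toward dimers.
    """
    _check_prob(f_true, "f_true")
    _check_prob(d_abs, "d_abs", lo_open=True)
    p1 = d_abs
    p2 = 1.0 - (1.0 - d_abs) ** 2
    w = f_true * p2
    return w / (w + (1.0 - f_true) * p1)


def true_dimer_fraction(f_obs: float, d_abs: float) -> float:
    """Invert :func:`observed_dimer_fraction` (detectability correction)."""
    _check_prob(f_obs, "f_obs")
    _check_prob(d_abs, "d_abs", lo_open=True)
    p1 = d_abs
    p2 = 1.0 - (1.0 - d_abs) ** 2
    w = f_obs / p2
    return w / (w + (1.0 - f_obs) / p1)


# ---------------------------------------------------------------------------
# Event extraction and spatial clustering
# ---------------------------------------------------------------------------


@dataclass
class AppearanceEvent:
    """One fluorescent burst: a run of localizations with short dark gaps."""

    start_frame: int
    end_frame: int
    x: float
    y: float
    n_locs: int

    @property
    def centroid(self) -> tuple[float, float]:
        return (self.x, self.y)


@dataclass
class NanoCluster:
    """A spatial group of appearance events, treated as one protein assembly."""

    events: list[AppearanceEvent]
    x: float
    y: float
    colocalized: bool = False

    @property
    def n(self) -> int:
        """Appearance count of the cluster."""
        return len(self.events)

    @property
    def centroid(self) -> tuple[float, float]:
        return (self.x, self.y)


def extract_appearances(
    table: LocalizationTable,
    max_dark_frames: int = 3,
    merge_radius: float = 30.0,
) -> list[AppearanceEvent]:
    """Group localizations into appearance events.

    A localization joins an existing event when it lies within `merge_radius`
    (nm) of the event centroid and the number of skipped frames since the
    event was last seen is <= `max_dark_frames`; otherwise it opens a new
    event.  Every localization is assigned to exactly one event.
    """
    if max_dark_frames < 0 or merge_radius <= 0:
        raise ParameterError("max_dark_frames must be >= 0 and merge_radius > 0")
    table = table.sorted_by_frame()
    frames = table.frames
    coords = table.coords

    # open events: parallel arrays for speed
    ev_x: list[float] = []
    ev_y: list[float] = []
    ev_last: list[int] = []
    ev_start: list[int] = []
    ev_n: list[int] = []
    ev_sumx: list[float] = []
    ev_sumy: list[float] = []
    active: list[int] = []  # indices into the arrays above

    for i in range(len(frames)):
        f = int(frames[i])
        x, y = coords[i]
        # retire events whose dark gap is already too long
        active = [j for j in active if f - ev_last[j] - 1 <= max_dark_frames]
        best, best_d2 = -1, merge_radius**2
        for j in active:
            d2 = (ev_x[j] - x) ** 2 + (ev_y[j] - y) ** 2
            if d2 <= best_d2:
                best, best_d2 = j, d2
        if best >= 0:
            ev_n[best] += 1
            ev_sumx[best] += x
            ev_sumy[best] += y
            ev_x[best] = ev_sumx[best] / ev_n[best]
            ev_y[best] = ev_sumy[best] / ev_n[best]
            ev_last[best] = f
        else:
            ev_x.append(x)
            ev_y.append(y)
            ev_sumx.append(x)
            ev_sumy.append(y)
            ev_last.append(f)
            ev_start.append(f)
            ev_n.append(1)
            active.append(len(ev_x) - 1)

    return [
        AppearanceEvent(start_frame=ev_start[j], end_frame=ev_last[j],
                        x=ev_x[j], y=ev_y[j], n_locs=ev_n[j])
        for j in range(len(ev_x))
    ]


def cluster_events(
    events: Sequence[AppearanceEvent],
    eps: float = 50.0,
    min_events: int = 1,
) -> list[NanoCluster]:
    """Density-based grouping of appearance events into nanoclusters (DBSCAN).

    With ``min_events=1`` every event belongs to some cluster (isolated events
    form singletons); with larger ``min_events`` sparse events are dropped.
    """
    if eps <= 0:
        raise ParameterError("eps must be > 0")
    if min_events < 1:
        raise ParameterError("min_events must be >= 1")
    if not events:
        return []
    pts = np.array([[e.x, e.y] for e in events])
    labels = DBSCAN(eps=eps, min_samples=min_events).fit_predict(pts)
    clusters: list[NanoCluster] = []
    for lab in np.unique(labels):
        if lab == -1:
            continue
        members = [events[i] for i in np.flatnonzero(labels == lab)]
        sub = pts[labels == lab]
        clusters.append(NanoCluster(events=members, x=float(sub[:, 0].mean()),
                                    y=float(sub[:, 1].mean())))
    return clusters


# ---------------------------------------------------------------------------
# Histograms and fits
# ---------------------------------------------------------------------------


@dataclass
class BlinkHistogram:
    """Histogram of per-nanocluster appearance counts over n = 1..n_max."""

    counts: np.ndarray
    n_max: int = 50

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, float)
        if len(self.counts) != self.n_max:
            raise ParameterError("counts must have length n_max (bins n = 1..n_max)")
        if np.any(self.counts < 0):
            raise ParameterError("histogram counts must be >= 0")

    @classmethod
    def from_counts(cls, n_values: Sequence[int], n_max: int = 50) -> "BlinkHistogram":
        """Build from raw per-cluster counts; values above n_max are censored
        into the top bin."""
        n_arr = np.asarray(n_values, int)
        if len(n_arr) and n_arr.min() < 1:
            raise ParameterError("appearance counts must be >= 1")
        clipped = np.clip(n_arr, 1, n_max)
        counts = np.bincount(clipped, minlength=n_max + 1)[1:].astype(float)
        return cls(counts=counts, n_max=n_max)

    @classmethod
    def from_clusters(cls, clusters: Sequence[NanoCluster], n_max: int = 50) -> "BlinkHistogram":
        return cls.from_counts([c.n for c in clusters], n_max=n_max)

    @property
    def ns(self) -> np.ndarray:
        return np.arange(1, self.n_max + 1)

    @property
    def total_clusters(self) -> float:
        return float(self.counts.sum())

    @property
    def mean(self) -> float:
        if self.total_clusters == 0:
            raise DataError("empty histogram")
        return float((self.ns * self.counts).sum() / self.total_clusters)

    def to_cluster_counts(self) -> np.ndarray:
        """Expand back to one appearance count per cluster (integer counts)."""
        return np.repeat(self.ns, self.counts.astype(int))


@dataclass
class ScalarFit:
    """A 1-parameter fit with a bootstrap percentile interval."""

    value: float
    ci: tuple[float, float]
    sd: float
    loglik: float
    converged: bool
    at_boundary: bool = False
    settings: dict = field(default_factory=dict)


@dataclass
class MixtureFit:
    """Monomer/dimer mixture fit of a blink histogram.

    ``fractions`` are the detectability-corrected (true-population) fractions;
    ``fractions_observed`` are the raw mixture weights among observed clusters.
    """

    fractions: tuple[float, float]            # (monomer, dimer), true population
    fractions_observed: tuple[float, float]   # (monomer, dimer), observed
    ci: dict
    sd: dict
    loglik: float
    converged: bool
    settings: dict = field(default_factory=dict)

    @property
    def dimer_fraction(self) -> float:
        return self.fractions[1]


def _require_nonempty(hist: BlinkHistogram) -> None:
    if hist.total_clusters < 1:
        raise DataError("empty blink histogram")


def bootstrap_ci(
    hist: BlinkHistogram,
    estimator: Callable[[BlinkHistogram], float],
    B: int = 1000,
    seed: int = 0,
) -> tuple[tuple[float, float], float]:
    """Cluster-level bootstrap of a histogram statistic.

    Resamples `total_clusters` clusters (multinomial over bins) B times and
    returns the (2.5%, 97.5%) percentile interval and the bootstrap SD.
    Deterministic for a given seed.
    """
    if B < 100:
        raise ParameterError("B must be >= 100")
    _require_nonempty(hist)
    rng = np.random.default_rng(seed)
    n_tot = int(round(hist.total_clusters))
    probs = hist.counts / hist.counts.sum()
    reps = np.empty(B)
    for b in range(B):
        counts = rng.multinomial(n_tot, probs).astype(float)
        reps[b] = estimator(BlinkHistogram(counts=counts, n_max=hist.n_max))
    lo, hi = np.percentile(reps, [2.5, 97.5])
    return (float(lo), float(hi)), float(reps.std())


def fit_p(hist: BlinkHistogram, B: int = 1000, seed: int = 0) -> ScalarFit:
    """Maximum-likelihood geometric fit of the bleaching probability.

    For a monomeric reference the appearance count is geometric, whose MLE is
    the closed form p_hat = 1 / mean(n).
    """
    _require_nonempty(hist)

    def estimate(h: BlinkHistogram) -> float:
        return min(1.0, 1.0 / h.mean)

    p_hat = estimate(hist)
    ci, sd = bootstrap_ci(hist, estimate, B=B, seed=seed)
    ll = float(np.sum(hist.counts * np.log(_pmf_m(hist.ns, 1, p_hat) + _EPS)))
    return ScalarFit(value=p_hat, ci=ci, sd=sd, loglik=ll, converged=True,
                     at_boundary=p_hat >= 1.0,
                     settings={"B": B, "seed": seed, "n_max": hist.n_max})


def _mle_q(hist: BlinkHistogram, p: float) -> tuple[float, float, bool]:
    ns = hist.ns
    mono = _pmf_m(ns, 1, p)
    two = _pmf_m(ns, 2, p)

    def nll(q: float) -> float:
        pmf = q * mono + (1 - q) * two
        pmf = pmf / pmf.sum()  # renormalise over the truncation window
        return -float(np.sum(hist.counts * np.log(pmf + _EPS)))

    res = optimize.minimize_scalar(nll, bounds=(0.0, 1.0 - 1e-9), method="bounded",
                                   options={"xatol": 1e-10})
    return float(res.x), -float(res.fun), bool(res.success)


def fit_q(hist: BlinkHistogram, p: float, B: int = 1000, seed: int = 0) -> ScalarFit:
    """Fit the dimer single-emitter fraction q with p fixed (dimeric reference)."""
    _check_prob(p, "p", lo_open=True)
    _require_nonempty(hist)
    q_hat, ll, ok = _mle_q(hist, p)
    ci, sd = bootstrap_ci(hist, lambda h: _mle_q(h, p)[0], B=B, seed=seed)
    boundary = q_hat >= 1.0 - 1e-6 or q_hat <= 1e-9
    return ScalarFit(value=q_hat, ci=ci, sd=sd, loglik=ll, converged=ok and not boundary,
                     at_boundary=boundary,
                     settings={"p": p, "B": B, "seed": seed, "n_max": hist.n_max})


def _mle_mixture(hist: BlinkHistogram, p: float, q: float) -> tuple[float, float, bool]:
    """Observed dimer weight by multinomial MLE on the binned counts."""
    ns = hist.ns
    mono = _pmf_m(ns, 1, p)
    mono = mono / mono.sum()
    dim = q * _pmf_m(ns, 1, p) + (1 - q) * _pmf_m(ns, 2, p)
    dim = dim / dim.sum()

    def nll(w: float) -> float:
        return -float(np.sum(hist.counts * np.log(w * dim + (1 - w) * mono + _EPS)))

    res = optimize.minimize_scalar(nll, bounds=(0.0, 1.0), method="bounded",
                                   options={"xatol": 1e-10})
    return float(res.x), -float(res.fun), bool(res.success)


def _ls_mixture(hist: BlinkHistogram, p: float, q: float) -> tuple[float, float, bool]:
    """Least-squares alternative on the normalised histogram."""
    ns = hist.ns
    mono = _pmf_m(ns, 1, p)
    mono = mono / mono.sum()
    dim = q * _pmf_m(ns, 1, p) + (1 - q) * _pmf_m(ns, 2, p)
    dim = dim / dim.sum()
    y = hist.counts / hist.counts.sum()
    # y ~ mono + w (dim - mono): closed-form projection, clipped to [0, 1]
    delta = dim - mono
    w = float(np.dot(y - mono, delta) / np.dot(delta, delta))
    w = min(1.0, max(0.0, w))
    rss = float(np.sum((y - (mono + w * delta)) ** 2))
    return w, -rss, True


def fit_mixture(
    hist: BlinkHistogram,
    p: float,
    d_abs: float,
    B: int = 1000,
    seed: int = 0,
    objective: str = "mle",
) -> MixtureFit:
    """Monomer/dimer mixture fit with detectability correction.

    With calibrated ``p`` and absolute detection efficiency ``d_abs``, the
    observed histogram is modelled as a two-component mixture of the monomer
    and dimer pmfs (q = d_to_q(d_abs)).  The fitted observed weight is then
    corrected for the different probabilities that monomers (d_abs) and dimers
    (1 - (1-d_abs)^2) are seen at all; the corrected ``fractions`` are the
    headline result.
    """
    _check_prob(p, "p", lo_open=True)
    _check_prob(d_abs, "d_abs", lo_open=True)
    if objective not in ("mle", "ls"):
        raise ParameterError("objective must be 'mle' or 'ls'")
    _require_nonempty(hist)
    q = d_to_q(d_abs)
    solve = _mle_mixture if objective == "mle" else _ls_mixture

    w_obs, ll, ok = solve(hist, p, q)
    f_true = true_dimer_fraction(w_obs, d_abs)

    def est_obs(h: BlinkHistogram) -> float:
        return solve(h, p, q)[0]

    ci_obs, sd_obs = bootstrap_ci(hist, est_obs, B=B, seed=seed)
    ci_true = (true_dimer_fraction(ci_obs[0], d_abs), true_dimer_fraction(ci_obs[1], d_abs))
    # delta-method scale for the corrected fraction
    h = 1e-6
    deriv = (true_dimer_fraction(min(w_obs + h, 1.0), d_abs)
             - true_dimer_fraction(max(w_obs - h, 0.0), d_abs)) / (2 * h)
    return MixtureFit(
        fractions=(1.0 - f_true, f_true),
        fractions_observed=(1.0 - w_obs, w_obs),
        ci={"dimer_observed": ci_obs, "dimer_true": ci_true},
        sd={"dimer_observed": sd_obs, "dimer_true": abs(deriv) * sd_obs},
        loglik=ll,
        converged=ok,
        settings={"p": p, "d_abs": d_abs, "q": q, "B": B, "seed": seed,
                  "objective": objective, "n_max": hist.n_max},
    )
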