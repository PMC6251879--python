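"""Threshold estimation on the bimodal score histogram and the iterative
rater-in-the-loop adjustment.

The log-transformed combined scores of all objects in a sample form a
bimodal histogram: one mode for background signals, one for foci, with a
valley in between.  A starting threshold is taken as the mean of three
independent estimators of that transition point (kernel-density valley,
two-component Gaussian-mixture intersection, Otsu).  Because the two
populations merge around the valley, the threshold is then refined
iteratively: the four objects scoring closest to the current threshold are
shown to a rater, the threshold moves in the direction their verdicts
indicate with a step size that shrinks each round, and the loop stops once
the last six foci-per-cell values vary by less than 5% of their mean.  The
reported foci-per-cell is the mean over those last six thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Protocol, Sequence

import numpy as np

from .core import OEPRecord

__all__ = [
    "RaterOracle",
    "LabelOracle",
    "BoundaryOracle",
    "ThresholdSession",
    "oep_histogram",
    "estimate_start_threshold",
    "adjust_threshold",
    "count_foci",
]


class NoThresholdError(RuntimeError):
    """Raised when no estimator can locate a valley in the histogram."""


class RaterOracle(Protocol):
    """Contract of the rating step: given the records displayed around the
    current threshold, return one binary verdict (True = focus) each."""

    def __call__(self, records: Sequence[OEPRecord]) -> list[bool]: ...


@dataclass
class LabelOracle:
    """Deterministic test oracle answering from a ground-truth label table
    keyed by ``(cell_id, object_id)``."""

    labels: dict

    def __call__(self, records: Sequence[OEPRecord]) -> list[bool]:
        return [bool(self.labels[(r.cell_id, r.object_id)]) for r in records]


@dataclass
class BoundaryOracle:
    """Noiseless rater whose decision boundary is a fixed log-score value."""

    log_threshold: float

    def __call__(self, records: Sequence[OEPRecord]) -> list[bool]:
        return [r.log_oep >= self.log_threshold for r in records]


@dataclass
class ThresholdSession:
    """State of one iterative adjustment run.

    Thresholds live on the log10-score axis.  ``foci_per_cell_history[i]``
    is the foci-per-cell count at ``threshold_history[i]``.
    """

    records: list[OEPRecord]
    n_cells: int
    threshold: float
    threshold_history: list[float] = field(default_factory=list)
    foci_per_cell_history: list[float] = field(default_factory=list)
    step_history: list[float] = field(default_factory=list)
    iterations: int = 0
    converged: bool = False
    final_foci_per_cell: float | None = None


def oep_histogram(
    oeps: Sequence[float], mode: str = "log", bins: int = 60
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of transformed scores.

    ``mode='log'`` bins log10 of the positive scores; ``mode='inverse_log'``
    bins 1/log10 and therefore includes only scores > 1 (where the
    reciprocal is defined).  Returns ``(counts, bin_edges)``.
    """
    vals = np.asarray([v for v in oeps if v > 0], dtype=float)
    if vals.size == 0:
        raise NoThresholdError("no positive scores to histogram")
    if mode == "log":
        x = np.log10(vals)
    elif mode == "inverse_log":
        x = vals[vals > 1.0]
        if x.size == 0:
            raise NoThresholdError("no scores > 1 for the inverse-log histogram")
        x = 1.0 / np.log10(x)
    else:
        raise ValueError(f"unknown histogram mode {mode!r}")
    return np.histogram(x, bins=bins)


def smoothed_mode_positions(x: np.ndarray, bins: int = 60, smooth_bins: float = 2.0):
    """Modes of a Gaussian-smoothed histogram; helper shared by the valley
    estimator and the bimodality check.  Returns (centres, smoothed counts,
    mode indices sorted by height, descending)."""
    from scipy.ndimage import gaussian_filter1d

    counts, edges = np.histogram(x, bins=bins)
    centres = 0.5 * (edges[:-1] + edges[1:])
    smoothed = gaussian_filter1d(counts.astype(float), smooth_bins)
    modes = [
        i
        for i in range(len(smoothed))
        if (i == 0 or smoothed[i] > smoothed[i - 1])
        and (i == len(smoothed) - 1 or smoothed[i] >= smoothed[i + 1])
        and smoothed[i] > 0
    ]
    modes.sort(key=lambda i: -smoothed[i])
    return centres, smoothed, modes


def _density_modes(x: np.ndarray, n_grid: int = 512):
    """Kernel-density estimate and its local maxima."""
    from scipy.stats import gaussian_kde

    kde = gaussian_kde(x)
    grid = np.linspace(x.min(), x.max(), n_grid)
    dens = kde(grid)
    peaks = [
        i
        for i in range(1, len(dens) - 1)
        if dens[i] > dens[i - 1] and dens[i] >= dens[i + 1]
    ]
    return grid, dens, peaks


def _mode_interval(x: np.ndarray, min_mode_frac: float = 0.02) -> tuple[float, float]:
    """Interval bracketing the background/focus transition: from the last
    background-side density mode to the focus mode.

    The focus mode is the rightmost local density maximum whose height is at
    least ``min_mode_frac`` of the global one (foci always form the
    high-score mode, and in low-dose samples it can be far smaller than the
    background mode, so rank-by-height selection is deliberately avoided).
    The lower edge is the rightmost qualifying mode left of the focus mode:
    background signals can themselves be multi-modal, and the transition to
    the focus population is the valley beyond the *last* of their modes.
    """
    grid, dens, peaks = _density_modes(x)
    if not peaks:
        raise NoThresholdError("no density modes")
    main = max(peaks, key=lambda i: dens[i])
    qualifying = [i for i in peaks if dens[i] >= min_mode_frac * dens[main]]
    if len(qualifying) < 2:
        raise NoThresholdError("no second density mode")
    focus = qualifying[-1]
    left = [i for i in qualifying if i < focus]
    return float(grid[left[-1]]), float(grid[focus])


def _kde_valley(x: np.ndarray) -> float:
    """Valley of the kernel-density estimate between the background mode
    and the focus-side mode."""
    grid, dens, _ = _density_modes(x)
    lo_pos, hi_pos = _mode_interval(x)
    lo = int(np.searchsorted(grid, lo_pos))
    hi = int(np.searchsorted(grid, hi_pos))
    if hi <= lo:
        raise NoThresholdError("degenerate mode interval")
    valley = lo + int(np.argmin(dens[lo : hi + 1]))
    return float(grid[valley])


def _bracket_transition(x: np.ndarray) -> np.ndarray:
    """Scores between the background mode and the focus mode.

    The background population can stretch over several decades and carry
    internal structure; a two-class split of the full sample then lands
    inside the background rather than at the background/focus transition.
    Restricting the sample to the inter-mode interval makes the split
    estimators see exactly one transition.
    """
    lo_pos, hi_pos = _mode_interval(x)
    sel = x[(x >= lo_pos) & (x <= hi_pos)]
    if sel.size < 10:
        raise NoThresholdError("too few scores between the modes")
    return sel


def _gmm_intersection(x: np.ndarray) -> float:
    """Decision boundary of a two-component 1-D Gaussian mixture fitted to
    the scores around the transition region: the point between the component
    means where the posteriors cross."""
    from sklearn.mixture import GaussianMixture

    lo_pos, hi_pos = _mode_interval(x)
    # anchoring the component means at the two density modes keeps EM from
    # splitting the (much larger) background population in two
    gmm = GaussianMixture(
        n_components=2,
        random_state=0,
        means_init=np.array([[lo_pos], [hi_pos]]),
    )
    gmm.fit(x.reshape(-1, 1))
    means = np.sort(gmm.means_.ravel())
    if means[1] - means[0] < 1e-9:
        raise NoThresholdError("mixture components collapsed")
    grid = np.linspace(means[0], means[1], 1024)
    post = gmm.predict_proba(grid.reshape(-1, 1))
    left_comp = int(np.argmin(gmm.means_.ravel()))
    crossing = np.nonzero(np.diff((post[:, left_comp] > 0.5).astype(int)))[0]
    if crossing.size == 0:
        raise NoThresholdError("no posterior crossing between component means")
    return float(grid[crossing[0]])


def _otsu(x: np.ndarray, bins: int = 64) -> float:
    """Valley-emphasis Otsu threshold over the transition region.

    Plain Otsu splits the larger class in two when the populations are very
    unbalanced; the valley-emphasis variant (Ng 2006) multiplies the
    between-class variance by one minus the local probability, which pulls
    the threshold into the density valley.
    """
    x = _bracket_transition(x)
    if np.ptp(x) == 0:
        raise NoThresholdError("constant sample")
    counts, edges = np.histogram(x, bins=bins)
    p = counts / counts.sum()
    centres = 0.5 * (edges[:-1] + edges[1:])
    omega = np.cumsum(p)
    mu = np.cumsum(p * centres)
    mu_t = mu[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma_b = (mu_t * omega - mu) ** 2 / (omega * (1.0 - omega))
    crit = (1.0 - p) * np.nan_to_num(sigma_b)
    return float(centres[int(np.argmax(crit))])


def estimate_start_threshold(
    oeps: Sequence[float], return_parts: bool = False
) -> float | tuple[float, dict]:
    """Starting threshold on the log10-score axis: the mean of the three
    estimators (kernel-density valley, Gaussian-mixture intersection, Otsu).

    An estimator that fails to locate a transition is dropped and logged;
    if all fail a :class:`NoThresholdError` propagates.
    """
    vals = np.asarray([v for v in oeps if v > 0], dtype=float)
    if vals.size == 0:
        raise NoThresholdError("no positive scores")
    x = np.log10(vals)
    estimates: dict[str, float] = {}
    for name, fn in (("kde_valley", _kde_valley), ("gmm", _gmm_intersection), ("otsu", _otsu)):
        try:
            estimates[name] = fn(x)
        except NoThresholdError:
            continue
    # an estimate is a transition point only if it sits in the low-density
    # valley between the two modes; an estimate inside either population
    # (between the modes but on a dense slope) has failed and is dropped
    try:
        from scipy.stats import gaussian_kde

        lo_pos, hi_pos = _mode_interval(x)
        kde = gaussian_kde(x)
        ceiling = 0.5 * float(min(kde(lo_pos)[0], kde(hi_pos)[0]))
        estimates = {
            k: v
            for k, v in estimates.items()
            if lo_pos < v < hi_pos and float(kde(v)[0]) <= ceiling
        }
    except NoThresholdError:
        pass
    if not estimates:
        raise NoThresholdError("all starting-threshold estimators failed")
    mean_est = float(np.mean(list(estimates.values())))
    if return_parts:
        return mean_est, estimates
    return mean_est


def count_foci(records: Sequence[OEPRecord], threshold: float, n_cells: int) -> float:
    """Foci per cell: objects with log10 score >= ``threshold`` divided by
    the number of analyzed cells (cells without objects count in the
    denominator)."""
    if n_cells <= 0:
        raise ValueError("need at least one analyzed cell")
    n = sum(1 for r in records if r.log_oep is not None and r.log_oep >= threshold)
    return n / n_cells


def adjust_threshold(
    session: ThresholdSession,
    oracle: RaterOracle,
    n_display: int = 4,
    initial_step: float | None = None,
    decay: float = 0.8,
    sd_fraction: float = 0.05,
    window: int = 6,
    max_iter: int = 60,
) -> ThresholdSession:
    """Iterative rater-in-the-loop refinement of the threshold.

    Each round presents the ``n_display`` not-yet-rated objects whose log
    scores are closest to the current threshold (an object is rated at most
    once; when every object has been rated the pool resets).  The fraction
    rated as foci moves the threshold: objects rated foci push it down (to
    admit them), background verdicts push it up; a balanced verdict leaves
    it in place.  The step starts large (default: a quarter of the distance
    between the two histogram modes) and shrinks by ``decay`` each round,
    floored at one histogram bin width.  The loop converges when the
    standard deviation of the last ``window`` foci-per-cell values drops
    below ``sd_fraction`` of their mean; the final foci-per-cell is their
    mean.
    """
    logs = np.asarray(
        [r.log_oep for r in session.records if r.log_oep is not None], dtype=float
    )
    if logs.size == 0:
        raise NoThresholdError("session has no scored objects")
    rated = [r for r in session.records if r.log_oep is not None]
    shown = np.zeros(len(rated), dtype=bool)

    if initial_step is None:
        centres, _, modes = smoothed_mode_positions(logs)
        if len(modes) >= 2:
            initial_step = abs(centres[modes[0]] - centres[modes[1]]) / 4.0
        else:
            initial_step = np.ptp(logs) / 8.0 if np.ptp(logs) > 0 else 0.1
    bin_width = max(np.ptp(logs) / 60.0, 1e-6)
    step = max(initial_step, bin_width)

    thr = session.threshold
    for _ in range(max_iter):
        if shown.sum() > len(rated) - n_display:
            shown[:] = False  # every object rated once: reset the pool
        dist = np.abs(logs - thr)
        dist[shown] = np.inf
        order = np.argsort(dist)[:n_display]
        shown[order] = True
        display = [rated[i] for i in order]
        verdicts = oracle(display)
        frac = sum(verdicts) / len(verdicts)
        thr = thr - step * (frac - 0.5) * 2.0
        fpc = count_foci(session.records, thr, session.n_cells)
        session.threshold_history.append(thr)
        session.foci_per_cell_history.append(fpc)
        session.step_history.append(step)
        session.iterations += 1
        step = max(step * decay, bin_width)
        if session.iterations >= window:
            last = np.asarray(session.foci_per_cell_history[-window:])
            mean = last.mean()
            if mean > 0 and last.std() < sd_fraction * mean:
                session.converged = True
                break
    session.threshold = thr
    if session.iterations >= window:
        session.final_foci_per_cell = float(
            np.mean(session.foci_per_cell_history[-window:])
        )
    else:
        session.final_foci_per_cell = session.foci_per_cell_history[-1] if session.foci_per_cell_history else None
    return session
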