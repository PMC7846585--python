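"""Validation analytics for closed-loop head-direction sessions.

The central question these statistics answer: did stimulation actually
land in the intended head-direction window, or could the observed
concentration of stimulated angles arise from a behavioral bias (the
animal happening to face that way a lot)?  The test statistic is the
mean resultant vector length

    r = | sum_j (cos theta_j, sin theta_j) | / n,

which is 0 for a uniform circular distribution and 1 for a point mass.
The null distribution is built by resampling, from the full multiset of
angles the animal explored in the session, sets of the same size as the
stimulated-angle set (1000 resamples by default); the observed r is
compared against the 99th percentile of the null.

Also here: radial histograms, false-positive/false-negative rates of
hypothetical head-direction triggers over several window widths with
rotated-window averaging, stimulation-latency accounting from the event
log, and ROI investigation-time scoring for the preference task.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sp_stats

from .arena import ROI
from .engine import SessionLog
from .posture import Posture
from .synthetic import GroundTruthTrack
from .triggers import HeadDirectionWindow, angle_to_reference

__all__ = [
    "CircularSummary",
    "NullDistribution",
    "AccuracyReport",
    "mean_resultant_length",
    "permutation_null",
    "radial_histogram",
    "trigger_accuracy",
    "stimulation_latency",
    "investigation_time",
    "InvestigationReport",
    "preference_ttest",
    "session_angles",
    "stimulated_angles",
]

DEFAULT_WINDOW_WIDTHS = (60, 50, 40, 30, 20, 10)


@dataclass(frozen=True)
class CircularSummary:
    """Concentration summary of a circular sample."""

    n: int
    r: float  # mean resultant vector length in [0, 1]
    mean_angle: float  # deg in (-180, 180]


def mean_resultant_length(angles_deg: Sequence[float]) -> CircularSummary:
    """Mean resultant vector length and mean angle of a circular sample."""
    a = np.asarray(angles_deg, dtype=float)
    if a.size == 0:
        raise ValueError("mean resultant length undefined for an empty sample")
    rad = np.radians(a)
    c = np.cos(rad).sum()
    s = np.sin(rad).sum()
    r = float(np.hypot(c, s) / a.size)
    mean_angle = float(np.degrees(np.arctan2(s, c)))
    return CircularSummary(n=int(a.size), r=r, mean_angle=mean_angle)


@dataclass(frozen=True)
class NullDistribution:
    """Permutation null of the mean resultant length for one session."""

    samples: np.ndarray  # null r values
    observed_r: float
    cutoff_99: float
    p: float  # add-one corrected empirical p

    @property
    def observed_percentile(self) -> float:
        """Percentile rank (%) of the observed r within the null."""
        return float(100.0 * np.mean(self.samples < self.observed_r))

    @property
    def significant(self) -> bool:
        return self.observed_r > self.cutoff_99


def permutation_null(
    all_angles: Sequence[float],
    stim_angles: Sequence[float],
    n_samples: int = 1000,
    seed: int = 0,
) -> NullDistribution:
    """Resampling null for the concentration of stimulated angles.

    Each of ``n_samples`` draws takes ``len(stim_angles)`` angles
    without replacement from the full-session angle multiset and
    records its mean resultant length.  The empirical p uses the
    add-one correction: ``p = (1 + #{null r >= observed r}) / (1 + N)``.
    """
    all_a = np.asarray(all_angles, dtype=float)
    stim_a = np.asarray(stim_angles, dtype=float)
    if stim_a.size == 0:
        raise ValueError("no stimulated angles")
    if stim_a.size > all_a.size:
        raise ValueError("stimulated-angle count exceeds session angle count")
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    rad = np.radians(all_a)
    unit = np.column_stack([np.cos(rad), np.sin(rad)])
    k = stim_a.size
    samples = np.empty(n_samples)
    for i in range(n_samples):
        idx = rng.choice(all_a.size, size=k, replace=False)
        v = unit[idx].sum(axis=0)
        samples[i] = np.hypot(v[0], v[1]) / k
    observed = mean_resultant_length(stim_a).r
    cutoff = float(np.percentile(samples, 99))
    p = float((1 + np.sum(samples >= observed)) / (1 + n_samples))
    return NullDistribution(samples=samples, observed_r=observed,
                            cutoff_99=cutoff, p=p)


def radial_histogram(
    angles_deg: Sequence[float],
    bin_width: float,
    normalize_to: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Normalized angular histogram; bins cover [-180, 180).

    Counts are divided by ``normalize_to`` when given (e.g. the
    whole-session maximum, so a stimulated-angle histogram shares the
    session's scale), else by their own maximum.  Returns
    ``(bin_edges, values)``.
    """
    if bin_width <= 0 or 360.0 % bin_width != 0:
        raise ValueError("bin_width must divide 360")
    a = np.asarray(angles_deg, dtype=float)
    # map (-180, 180] onto [-180, 180) for binning
    a = ((a + 180.0) % 360.0) - 180.0
    edges = np.arange(-180.0, 180.0 + bin_width / 2, bin_width)
    counts, _ = np.histogram(a, bins=edges)
    denom = normalize_to if normalize_to is not None else counts.max()
    if denom == 0:
        values = np.zeros_like(counts, dtype=float)
    else:
        values = counts / float(denom)
    return edges, values


@dataclass(frozen=True)
class AccuracyReport:
    """FP/FN rates (%) of hypothetical head-direction triggers.

    Rates are per-frame: FP among frames where the estimated angle lies
    in the window, FN among frames where the true angle does; mean and
    SD are taken over the rotated window placements of each width.
    """

    per_width: Mapping[int, dict]  # width -> {fp_mean, fp_sd, fn_mean, fn_sd}
    n_rotations: int
    n_frames: int


def trigger_accuracy(
    estimated: Sequence[Posture] | np.ndarray,
    truth: GroundTruthTrack | np.ndarray,
    widths: Sequence[int] = DEFAULT_WINDOW_WIDTHS,
    n_rotations: int = 3,
    reference_point: tuple[float, float] | None = None,
    axis: tuple[str, str] = ("neck", "nose"),
) -> AccuracyReport:
    """False-positive/false-negative rates of head-direction triggers.

    For every window width w, the window ``[j*w, (j+1)*w)`` (angles
    taken mod 360) is placed at ``n_rotations`` consecutive rotations to
    counter non-uniform head-direction occupancy; per placement,
    FP = #{estimated in, true out} / #{estimated in} and
    FN = #{true in, estimated out} / #{true in}.

    ``estimated`` and ``truth`` may be posture/track objects (angles are
    measured to ``reference_point``) or precomputed angle arrays.
    """
    est_angles = _coerce_angles(estimated, reference_point, axis)
    true_angles = _coerce_angles(truth, reference_point, axis)
    if est_angles.shape != true_angles.shape:
        raise ValueError("estimated and truth angle sequences differ in length")
    if n_rotations < 1:
        raise ValueError("n_rotations must be >= 1")
    est = est_angles % 360.0
    tru = true_angles % 360.0
    per_width = {}
    for w in widths:
        fps_, fns_ = [], []
        for j in range(n_rotations):
            lo = (j * w) % 360.0
            hi = lo + w
            est_in = _in_arc(est, lo, hi)
            tru_in = _in_arc(tru, lo, hi)
            n_est = int(est_in.sum())
            n_tru = int(tru_in.sum())
            fp = 100.0 * np.sum(est_in & ~tru_in) / n_est if n_est else 0.0
            fn = 100.0 * np.sum(tru_in & ~est_in) / n_tru if n_tru else 0.0
            fps_.append(fp)
            fns_.append(fn)
        per_width[int(w)] = {
            "fp_mean": float(np.mean(fps_)),
            "fp_sd": float(np.std(fps_)),
            "fn_mean": float(np.mean(fns_)),
            "fn_sd": float(np.std(fns_)),
        }
    return AccuracyReport(per_width=per_width, n_rotations=n_rotations,
                          n_frames=len(est_angles))


def _in_arc(angles, lo, hi):
    """Membership of angles (deg, mod 360) in the arc [lo, hi)."""
    if hi <= 360.0:
        return (angles >= lo) & (angles < hi)
    return (angles >= lo) | (angles < hi - 360.0)


def _coerce_angles(obj, reference_point, axis):
    if isinstance(obj, GroundTruthTrack):
        return np.asarray(obj.angles_to_reference(reference_point), dtype=float)
    if len(obj) and isinstance(obj[0], Posture):
        if reference_point is None:
            raise ValueError("reference_point required with posture input")
        window = HeadDirectionWindow(reference_point=tuple(reference_point),
                                     axis=axis)
        return np.array([angle_to_reference(p, window) for p in obj])
    return np.asarray(obj, dtype=float)


def stimulation_latency(log: SessionLog) -> dict:
    """Frames between the causing frame and the physical onset, per event.

    Returns overall and per-channel mean +/- SD; raises if the log has
    no events.
    """
    if not log.events:
        raise ValueError("no stimulation events in log")
    lat = np.array([e.physical_onset_frame - e.onset_frame for e in log.events],
                   dtype=float)
    out = {"mean": float(lat.mean()), "sd": float(lat.std()), "n": len(lat),
           "per_channel": {}}
    for ch in sorted({e.channel for e in log.events}):
        sub = np.array([e.physical_onset_frame - e.onset_frame
                        for e in log.events if e.channel == ch], dtype=float)
        out["per_channel"][ch] = {"mean": float(sub.mean()),
                                  "sd": float(sub.std()), "n": len(sub)}
    return out


@dataclass(frozen=True)
class InvestigationReport:
    """Per-ROI investigation time for one preference-task session."""

    seconds: Mapping[str, float]
    excluded: bool  # true when no odor source was investigated at all


def investigation_time(
    postures: Sequence[Posture],
    rois: Sequence[ROI],
    part: str = "nose",
    *,
    fps: float,
    nonexclusive: bool = False,
) -> InvestigationReport:
    """Seconds the part spent inside each circular ROI.

    Overlapping ROIs raise unless ``nonexclusive=True`` (a frame then
    counts toward every ROI containing the part).  Sessions with zero
    total investigation are flagged for exclusion.
    """
    if fps <= 0:
        raise ValueError("fps must be > 0")
    if not nonexclusive:
        for i, a in enumerate(rois):
            for b in rois[i + 1:]:
                d = np.hypot(a.center[0] - b.center[0], a.center[1] - b.center[1])
                if d < a.radius + b.radius:
                    raise ValueError(
                        f"ROIs {a.id!r} and {b.id!r} overlap; pass "
                        "nonexclusive=True to count membership in both"
                    )
    frames = {roi.id: 0 for roi in rois}
    for p in postures:
        if p.is_missing(part):
            continue
        x, y = p.xy(part)
        for roi in rois:
            if roi.contains(x, y):
                frames[roi.id] += 1
                if not nonexclusive:
                    break
    seconds = {k: v / fps for k, v in frames.items()}
    return InvestigationReport(
        seconds=seconds, excluded=all(v == 0 for v in frames.values())
    )


def preference_ttest(times_a: Sequence[float], times_b: Sequence[float]):
    """One-tailed paired t-test that investigation of A exceeds B.

    Convenience reporting statistic (standard method); returns the
    scipy result object with ``statistic`` and ``pvalue``.
    """
    return sp_stats.ttest_rel(times_a, times_b, alternative="greater")


def session_angles(log: SessionLog, reference_point, axis=("neck", "nose")
                   ) -> np.ndarray:
    """Head-direction angle to the reference point for every logged frame."""
    frm, to = axis
    ax = log.records[f"{frm}_x"].to_numpy(float)
    ay = log.records[f"{frm}_y"].to_numpy(float)
    bx = log.records[f"{to}_x"].to_numpy(float)
    by = log.records[f"{to}_y"].to_numpy(float)
    heading = np.degrees(np.arctan2(-(by - ay), bx - ax))
    bearing = np.degrees(
        np.arctan2(-(reference_point[1] - ay), reference_point[0] - ax)
    )
    d = heading - bearing
    return -((-d + 180.0) % 360.0 - 180.0)


def stimulated_angles(log: SessionLog, reference_point, axis=("neck", "nose")
                      ) -> np.ndarray:
    """Angles of all frames with stimulation active (status true)."""
    angles = session_angles(log, reference_point, axis)
    mask = log.records["experiment_status"].to_numpy(dtype=bool)
    return angles[mask]
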