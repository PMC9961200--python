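"""Single-curve analysis: contact point, Hertz modulus, force drops, staging.

Only the approach segment is analysed.  All depth quantities are
cantilever-corrected: depth = piezo travel past contact minus the
cantilever deflection F/k.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .core import (
    FitFailureError,
    ForceCurve,
    NoContactError,
    SegmentationError,
)


@dataclass
class AnalysisConfig:
    """Thresholds shared by the contact and drop detectors."""

    baseline_window: int = 250  # leading samples used for noise statistics
    contact_sd_mult: float = 3.0
    contact_persistence: int = 10  # consecutive samples above threshold
    smooth_window: int = 5  # moving-average width for contact detection
    drop_sd_mult: float = 5.0
    drop_floor_nn: float = 0.05  # absolute threshold floor, nN
    drop_window_nm: float = 20.0  # a drop must complete within this travel


@dataclass
class HertzFitResult:
    modulus: float  # Pa
    contact_point: float  # nm on the piezo axis
    poisson_ratio: float
    rms_residual: float  # nN
    fit_range: tuple[float, float]  # (nm, nm) piezo range used


@dataclass
class InsertionEvent:
    index: int  # last sample before the drop
    insertion_force: float  # nN
    drop_magnitude: float  # nN
    insertion_displacement: float  # um, corrected depth from contact
    insertion_time: float  # s
    rank: str  # membrane_first | nucleus_second | other


@dataclass
class CurveSegmentation:
    contact_index: int
    trigger_index: int
    first_drop_index: int | None = None
    second_drop_index: int | None = None
    ab_slope: float = float("nan")  # nN/um on corrected depth
    ab_slope_r2: float = float("nan")


def indentation_depth(piezo_z, force, k: float, z_a: float) -> np.ndarray:
    """Cantilever-corrected indentation depth, nm, floored at zero.

    delta = (piezo_z - z_a) - F/k.  With force in nN and k in N/m the
    deflection F/k is directly in nm.
    """
    piezo_z = np.asarray(piezo_z, dtype=float)
    force = np.asarray(force, dtype=float)
    if piezo_z.size == 0 or force.size == 0:
        raise ValueError("empty input arrays")
    if k <= 0:
        raise ValueError("spring constant must be positive")
    return np.maximum((piezo_z - z_a) - force / k, 0.0)


def hertz_force(modulus: float, radius_um: float, nu: float, depth_nm) -> np.ndarray | float:
    """Spherical-tip contact force, nN, for depth in nm.

    F = (4 sqrt(R) E) / (3 (1 - nu^2)) * delta^{3/2} in SI, returned in nN.
    """
    if nu >= 1.0 or nu < 0.0:
        raise ValueError("Poisson ratio must lie in [0, 1)")
    if modulus <= 0 or radius_um <= 0:
        raise ValueError("modulus and radius must be positive")
    depth = np.asarray(depth_nm, dtype=float)
    if np.any(depth < 0):
        raise ValueError("depth must be non-negative")
    c_si = (4.0 / 3.0) * math.sqrt(radius_um * 1e-6) * modulus / (1.0 - nu * nu)
    out = c_si * np.power(depth * 1e-9, 1.5) * 1e9
    return float(out) if np.isscalar(depth_nm) else out


def _smooth(x: np.ndarray, w: int) -> np.ndarray:
    if w <= 1:
        return x.astype(float)
    kernel = np.ones(w) / w
    pad = w // 2
    xp = np.pad(x, pad, mode="edge")
    return np.convolve(xp, kernel, mode="valid")[: x.size]


def _baseline_stats(curve: ForceCurve, config: AnalysisConfig) -> tuple[float, float]:
    n = min(config.baseline_window, max(50, curve.n_samples // 10))
    base = curve.force[:n]
    return float(np.mean(base)), float(np.std(base, ddof=1))


def detect_contact_point(curve: ForceCurve, config: AnalysisConfig | None = None) -> float:
    """Locate the contact point A on the piezo axis.

    The smoothed force must exceed baseline mean + ``contact_sd_mult`` x
    baseline SD and stay above it for ``contact_persistence`` consecutive
    samples; the reported position is then refined to the first raw sample
    above the threshold in the neighbourhood of that crossing.
    """
    config = config or AnalysisConfig()
    if curve.n_samples < 50:
        raise NoContactError("curve too short for baseline estimation")
    mean, sd = _baseline_stats(curve, config)
    thr = mean + config.contact_sd_mult * max(sd, 1e-9)
    sm = _smooth(curve.force, config.smooth_window)
    above = sm > thr
    p = config.contact_persistence
    if above.size < p:
        raise NoContactError("curve too short for persistence check")
    runs = np.convolve(above.astype(int), np.ones(p, dtype=int), mode="valid")
    hits = np.nonzero(runs == p)[0]
    if hits.size == 0:
        raise NoContactError("no contact found: force never leaves the baseline")
    i = int(hits[0])
    lo = max(0, i - config.smooth_window // 2)
    hi = min(curve.n_samples, i + p)
    raw_hits = np.nonzero(curve.force[lo:hi] > thr)[0]
    j = lo + int(raw_hits[0]) if raw_hits.size else i

    # refine: extrapolate a short linear fit just past the crossing back to
    # the baseline level, removing the threshold-crossing lag on
    # shallow-slope curves
    win = slice(j, min(curve.n_samples, j + 40))
    zf, ff = curve.piezo_z[win], curve.force[win]
    if zf.size >= 5:
        a, b = np.polyfit(zf, ff, 1)
        if a > 0:
            z_ref = (mean - b) / a
            if curve.piezo_z[j] - 150.0 <= z_ref <= curve.piezo_z[j]:
                return float(z_ref)
    return float(curve.piezo_z[j])


def contact_index(curve: ForceCurve, z_a: float) -> int:
    return int(np.searchsorted(curve.piezo_z, z_a, side="left"))


def fit_hertz(
    curve: ForceCurve,
    max_depth: float = 1500.0,
    nu: float = 0.5,
    config: AnalysisConfig | None = None,
) -> HertzFitResult:
    """Least-squares fit of (modulus, contact point) to a spherical-tip curve.

    Depth is recomputed from the candidate contact point at every residual
    evaluation using the measured force for the deflection correction, and
    the fit window is capped at ``max_depth`` nm of corrected depth.
    """
    if curve.tip_kind != "sphere":
        raise ValueError("Hertz fitting requires a spherical tip")
    config = config or AnalysisConfig()
    z_a0 = detect_contact_point(curve, config)
    z = curve.piezo_z
    f = curve.force
    k = curve.spring_constant

    depth0 = (z - z_a0) - f / k
    mask = (z >= z_a0 - 300.0) & (depth0 <= max_depth)
    if mask.sum() < 10:
        raise FitFailureError("too few samples in the fit window", {"n": int(mask.sum())})
    zm, fm = z[mask], f[mask]

    c_unit = (4.0 / 3.0) * math.sqrt(curve.tip_radius * 1e-6) / (1.0 - nu * nu)

    def model(theta):
        e, z_a = theta
        depth = np.maximum((zm - z_a) - fm / k, 0.0)
        return c_unit * e * np.power(depth * 1e-9, 1.5) * 1e9

    d_end = max(float(depth0[mask][-1]), 1.0)
    e0 = max(float(fm[-1]) / max(c_unit * (d_end * 1e-9) ** 1.5 * 1e9, 1e-30), 1.0)
    lb = [1e-2, z_a0 - 400.0]
    ub = [1e8, z_a0 + 400.0]
    res = least_squares(
        lambda th: model(th) - fm,
        x0=[min(max(e0, lb[0] * 2), ub[0] / 2), z_a0],
        bounds=(lb, ub),
        xtol=1e-14, ftol=1e-14, gtol=1e-14,
    )
    if not res.success:
        raise FitFailureError("Hertz fit did not converge", {"status": res.status})
    e_fit, z_a_fit = float(res.x[0]), float(res.x[1])
    rel = lambda v, lo, hi: min(abs(v - lo), abs(v - hi)) / (hi - lo)
    if rel(e_fit, lb[0], ub[0]) < 1e-9:
        raise FitFailureError(
            "fitted modulus hit a parameter bound",
            {"modulus": e_fit, "bounds": (lb[0], ub[0])},
        )
    rms = float(np.sqrt(np.mean(res.fun**2)))
    return HertzFitResult(
        modulus=e_fit,
        contact_point=z_a_fit,
        poisson_ratio=nu,
        rms_residual=rms,
        fit_range=(float(zm[0]), float(zm[-1])),
    )


def detect_force_drops(
    curve: ForceCurve,
    z_a: float | None = None,
    config: AnalysisConfig | None = None,
) -> list[InsertionEvent]:
    """Find penetration events (sudden force decreases) past contact.

    A drop is a decrease of at least ``max(drop_sd_mult x baseline SD,
    drop_floor_nn)`` between the mean of the three samples before and the
    three samples after a candidate index, completing within
    ``drop_window_nm`` of piezo travel.  Events are ranked in order of
    occurrence: membrane first, nucleus second.
    """
    config = config or AnalysisConfig()
    if z_a is None:
        z_a = detect_contact_point(curve, config)
    _, sd = _baseline_stats(curve, config)
    thr = max(config.drop_sd_mult * sd, config.drop_floor_nn)

    f = curve.force
    z = curve.piezo_z
    a_idx = contact_index(curve, z_a)
    n = f.size
    if n - a_idx < 8:
        return []

    # matched-filter step response: mean of 3 before minus mean of 3 after
    kernel = np.array([1, 1, 1, -1, -1, -1]) / 3.0
    resp = np.correlate(f, kernel, mode="valid")  # resp[i] = pre-mean - post-mean at e = i + 2
    # resp index i corresponds to candidate event index e = i + 2
    cand = np.zeros(n, dtype=bool)
    e_idx = np.arange(resp.size) + 2
    valid = (e_idx >= a_idx + 3) & (e_idx < n - 3)
    step_ok = resp >= thr
    neg = np.zeros(resp.size, dtype=bool)
    neg[:] = f[e_idx + 1] - f[e_idx] < 0.0
    cand[e_idx[valid & step_ok & neg]] = True

    # enforce completion window: drop must be realised within drop_window_nm
    win = max(2, int(round(config.drop_window_nm / max(np.median(np.diff(z)), 1e-9))))
    events: list[InsertionEvent] = []
    idxs = np.nonzero(cand)[0]
    if idxs.size == 0:
        return []
    groups: list[list[int]] = [[int(idxs[0])]]
    for i in idxs[1:]:
        if i - groups[-1][-1] <= 3:
            groups[-1].append(int(i))
        else:
            groups.append([int(i)])

    k = curve.spring_constant
    for grp in groups:
        strengths = [resp[e - 2] for e in grp]
        e = grp[int(np.argmax(strengths))]
        pre = f[max(a_idx, e - 2) : e + 1]
        post = f[e + 1 : min(n, e + 1 + win)]
        drop = float(np.max(pre) - np.min(post))
        if drop < thr:
            continue
        f_ins = float(np.mean(pre))
        depth_nm = max((z[e] - z_a) - f_ins / k, 0.0)
        disp_um = depth_nm / 1000.0
        events.append(
            InsertionEvent(
                index=e,
                insertion_force=f_ins,
                drop_magnitude=drop,
                insertion_displacement=disp_um,
                insertion_time=disp_um / curve.approach_speed,
                rank="other",
            )
        )
    for i, ev in enumerate(events):
        ev.rank = "membrane_first" if i == 0 else ("nucleus_second" if i == 1 else "other")
    return events


def segment_curve(
    curve: ForceCurve,
    events: list[InsertionEvent],
    z_a: float | None = None,
    config: AnalysisConfig | None = None,
) -> CurveSegmentation:
    """Label the O-A / A-B / B / B-C stages and fit the elastic A-B slope.

    The slope is an ordinary least-squares fit of force against corrected
    depth (in um) from contact to the first drop, or to the trigger when
    the curve has no drop.
    """
    config = config or AnalysisConfig()
    if z_a is None:
        z_a = detect_contact_point(curve, config)
    a = contact_index(curve, z_a)
    c = curve.n_samples - 1
    b = events[0].index if events else None
    d = events[1].index if len(events) >= 2 else None

    end = b if b is not None else c
    sl = slice(a, end + 1)
    if end - a < 5:
        raise SegmentationError("fewer than 5 samples between contact and drop")
    depth_um = indentation_depth(curve.piezo_z[sl], curve.force[sl], curve.spring_constant, z_a) / 1000.0
    y = curve.force[sl]
    coef = np.polyfit(depth_um, y, 1)
    pred = np.polyval(coef, depth_um)
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return CurveSegmentation(
        contact_index=a,
        trigger_index=c,
        first_drop_index=b,
        second_drop_index=d,
        ab_slope=float(coef[0]),
        ab_slope_r2=r2,
    )


def analyze_curve(
    curve: ForceCurve,
    config: AnalysisConfig | None = None,
    hertz_max_depth: float = 1500.0,
) -> dict:
    """Run the full single-curve pipeline; returns a JSON-serialisable record."""
    config = config or AnalysisConfig()
    z_a = detect_contact_point(curve, config)
    events = detect_force_drops(curve, z_a, config)
    seg = segment_curve(curve, events, z_a, config)
    rec = {
        "contact_point_nm": z_a,
        "strain_label": curve.strain_label,
        "tip_kind": curve.tip_kind,
        "events": [
            {
                "index": ev.index,
                "insertion_force_nN": ev.insertion_force,
                "drop_magnitude_nN": ev.drop_magnitude,
                "insertion_displacement_um": ev.insertion_displacement,
                "insertion_time_s": ev.insertion_time,
                "rank": ev.rank,
            }
            for ev in events
        ],
        "segmentation": {
            "contact_index": seg.contact_index,
            "first_drop_index": seg.first_drop_index,
            "second_drop_index": seg.second_drop_index,
            "trigger_index": seg.trigger_index,
            "ab_slope_nN_per_um": seg.ab_slope,
            "ab_slope_r2": seg.ab_slope_r2,
        },
    }
    if curve.tip_kind == "sphere":
        try:
            fit = fit_hertz(curve, max_depth=hertz_max_depth, config=config)
            rec["hertz"] = {
                "modulus_Pa": fit.modulus,
                "contact_point_nm": fit.contact_point,
                "poisson_ratio": fit.poisson_ratio,
                "rms_residual_nN": fit.rms_residual,
            }
        except FitFailureError as exc:
            rec["hertz"] = {"error": str(exc)}
    return rec
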