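"""Seeded synthetic AFM approach curves with known ground truth.

Each generated trace follows the four-stage morphology of a membrane
penetration experiment: flat baseline before contact, an elastic rise
(Hertz-shaped for a spherical tip, linear for a pyramidal tip), an optional
instantaneous force drop when the membrane is pierced (and a possible
second, deeper drop for the nucleus), then an accelerating rise once the
stiff substrate is felt.  The trace terminates at the first sample whose
noise-free force reaches the trigger force.

The generator solves, sample by sample, the implicit relation

    F = g(delta),   delta = (z - z_A) - F / k

between piezo position ``z`` and force ``F`` (``g`` is the tip-sample force
law on cantilever-corrected depth, ``k`` the cantilever spring constant),
so analysis code that re-derives depth from the trace sees the force law
exactly, to solver precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import brentq
from scipy.stats import truncnorm

from .core import CurveGenError, CurveGroundTruth, EventTruth, ForceCurve

#: hard floor on the sampled insertion force, nN.  Keeps the post-drop force
#: positive and the drop itself resolvable against the detection threshold.
FORCE_FLOOR_NN = 0.25


@dataclass
class CurveGenParams:
    """Parameters of one acquisition condition.

    ``membrane_slope`` is the linear contact stiffness of the elastic stage
    (pyramidal tip); ``cell_modulus`` drives the Hertz-shaped rise of
    spherical-tip curves.  ``strain_label`` only tags the output.
    """

    cell_modulus: float = 1000.0  # Pa
    membrane_slope: float = 3.0  # nN/um
    penetration_probability: float = 0.0
    insertion_force_mean: float = 2.0  # nN
    insertion_force_sd: float = 0.3  # nN
    second_drop_probability: float = 0.0
    post_drop_softening: float = 0.7  # in (0, 1]; post-drop slope = slope / this
    substrate_onset_depth: float = 1.5  # um, corrected depth past contact
    noise_sd: float = 0.02  # nN
    trigger_force: float = 12.0  # nN
    approach_speed: float = 1.0  # um/s
    spring_constant: float = 0.02  # N/m
    tip_kind: str = "pyramid"
    tip_radius: float = 0.01  # um
    strain_label: float = 0.0  # percent
    seed: int = 0

    # generation-grid details (not part of the acquisition metadata)
    contact_z_um: float = 1.0  # true contact position on the piezo axis
    piezo_step_nm: float = 2.0
    max_range_um: float = 6.0
    substrate_quadratic: float = 20.0  # nN/um^2 stiffening past the onset

    def validate(self) -> None:
        if not 0.0 <= self.penetration_probability <= 1.0:
            raise ValueError("penetration_probability must lie in [0, 1]")
        if not 0.0 <= self.second_drop_probability <= 1.0:
            raise ValueError("second_drop_probability must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.trigger_force <= 0:
            raise ValueError("trigger_force must be > 0")
        if self.insertion_force_mean >= self.trigger_force:
            raise ValueError("insertion_force_mean must be below trigger_force")
        if not 0.0 < self.post_drop_softening <= 1.0:
            raise ValueError("post_drop_softening must lie in (0, 1]")
        if self.tip_kind not in ("sphere", "pyramid"):
            raise ValueError("tip_kind must be 'sphere' or 'pyramid'")
        if self.spring_constant <= 0 or self.approach_speed <= 0:
            raise ValueError("spring_constant and approach_speed must be > 0")

    @property
    def min_drop_nn(self) -> float:
        """Smallest realised force step the generator will plant.

        12 sigma of the trace noise keeps every planted step detectable
        above a 5-sigma threshold even after noise is added on both sides
        of the step.
        """
        return max(0.15, 12.0 * self.noise_sd)


def _hertz_coeff_nn_per_nm15(modulus_pa: float, radius_um: float, nu: float = 0.5) -> float:
    # F[N] = (4/3) sqrt(R[m]) E / (1 - nu^2) * delta[m]^1.5 ; converted so that
    # F[nN] = c * delta[nm]^1.5
    c_si = (4.0 / 3.0) * math.sqrt(radius_um * 1e-6) * modulus_pa / (1.0 - nu * nu)
    return c_si * (1e-9) ** 1.5 * 1e9


def _solve_branch(z: np.ndarray, z_a: float, k: float, g, gp, f0: np.ndarray) -> np.ndarray:
    """Vectorised Newton solve of F = g((z - z_a) - F/k) on one branch."""
    f = np.maximum(f0, 0.0)
    for _ in range(100):
        delta = np.maximum(z - z_a - f / k, 0.0)
        resid = f - g(delta)
        slope = 1.0 + gp(delta) / k
        step = resid / slope
        f = f - step
        if np.max(np.abs(step)) < 1e-13:
            break
    return f


def generate_curve(
    params: CurveGenParams,
    *,
    penetrate: bool | None = None,
    insertion_force: float | None = None,
    rng: np.random.Generator | None = None,
) -> ForceCurve:
    """Generate one approach trace.

    ``penetrate`` / ``insertion_force`` override the random draws so batch
    wrappers can realise exact penetration counts and moment-matched force
    samples; both default to seeded sampling from ``params``.
    """
    params.validate()
    if rng is None:
        rng = np.random.default_rng(params.seed)

    k = params.spring_constant  # nN/nm numerically
    z_a = params.contact_z_um * 1000.0
    step = params.piezo_step_nm
    z = np.arange(0.0, params.max_range_um * 1000.0 + step / 2, step)

    slope = params.membrane_slope / 1000.0  # nN/nm
    q = params.substrate_quadratic / 1e6  # nN/nm^2
    d_sub = params.substrate_onset_depth * 1000.0  # nm
    c_hz = _hertz_coeff_nn_per_nm15(params.cell_modulus, params.tip_radius)

    def substrate(d):
        e = np.maximum(d - d_sub, 0.0)
        return q * e * e

    def substrate_p(d):
        return 2.0 * q * np.maximum(d - d_sub, 0.0)

    if params.tip_kind == "sphere":
        base = lambda d: c_hz * np.power(np.maximum(d, 0.0), 1.5)
        base_p = lambda d: 1.5 * c_hz * np.sqrt(np.maximum(d, 0.0))
    else:
        base = lambda d: slope * d
        base_p = lambda d: np.full_like(np.asarray(d, dtype=float), slope)

    def g0(d):
        return base(d) + substrate(d)

    def g0p(d):
        return base_p(d) + substrate_p(d)

    if penetrate is None:
        penetrate = bool(rng.random() < params.penetration_probability)

    d_max = params.max_range_um * 1000.0 - z_a
    if d_max <= 0 or g0(d_max) < params.trigger_force:
        raise CurveGenError(
            "trigger force unreachable within the configured piezo range; "
            "increase max_range_um or substrate stiffening"
        )

    branches = [(z_a, g0, g0p)]  # (z at branch start, g, g')
    truth_events: list[tuple[float, str]] = []  # (z of last pre-drop position, kind)

    if penetrate:
        min_drop = params.min_drop_nn
        lo = max(FORCE_FLOOR_NN, min_drop / 0.8)
        hi = 0.8 * params.trigger_force
        if insertion_force is None:
            a = (lo - params.insertion_force_mean) / max(params.insertion_force_sd, 1e-9)
            b = (hi - params.insertion_force_mean) / max(params.insertion_force_sd, 1e-9)
            f_ins = float(
                truncnorm.rvs(
                    a, b,
                    loc=params.insertion_force_mean,
                    scale=max(params.insertion_force_sd, 1e-9),
                    random_state=rng,
                )
            )
        else:
            f_ins = float(np.clip(insertion_force, lo, hi))

        d_b = brentq(lambda d: g0(d) - f_ins, 0.0, d_max)
        # realised (observed) step in the trace, then the law-level jump that
        # produces it once cantilever relaxation is accounted for
        r1 = float(np.clip(rng.uniform(0.3, 0.6) * f_ins, min_drop, 0.8 * f_ins))
        s2 = slope / params.post_drop_softening  # post-drop linear stiffness
        jump1 = r1 * (1.0 + s2 / k)

        def g1(d, _f0=f_ins - jump1, _db=d_b):
            return _f0 + s2 * (d - _db) + substrate(d) - substrate(np.asarray(_db))

        def g1p(d):
            return s2 + substrate_p(d)

        z_b = z_a + d_b + f_ins / k
        branches.append((z_b, g1, g1p))
        truth_events.append((z_b, "membrane"))

        if g1(d_max) < params.trigger_force:
            raise CurveGenError("trigger force unreachable after membrane drop")
        d_trig = brentq(lambda d: g1(d) - params.trigger_force, d_b, d_max)

        if rng.random() < params.second_drop_probability and (d_trig - d_b) > 200.0:
            d_d = float(rng.uniform(d_b + 0.15 * (d_trig - d_b), d_b + 0.85 * (d_trig - d_b)))
            if d_d - d_b >= 60.0:
                f_pre2 = float(g1(d_d))
                r2 = float(np.clip(rng.uniform(0.4, 0.8), min_drop, 0.6 * f_pre2))
                s3 = float(g1p(d_d))
                jump2 = r2 * (1.0 + s3 / k)

                def g2(d, _f0=f_pre2 - jump2, _dd=d_d):
                    return _f0 + s2 * (d - _dd) + substrate(d) - substrate(np.asarray(_dd))

                def g2p(d):
                    return s2 + substrate_p(d)

                z_d = z_a + d_d + f_pre2 / k
                branches.append((z_d, g2, g2p))
                truth_events.append((z_d, "nucleus"))
                if g2(d_max) < params.trigger_force:
                    raise CurveGenError("trigger force unreachable after nucleus drop")

    force = np.zeros_like(z)
    starts = [b[0] for b in branches] + [np.inf]
    for i, (z0, g, gp) in enumerate(branches):
        mask = (z >= z0) & (z < starts[i + 1])
        if mask.any():
            force[mask] = _solve_branch(z[mask], z_a, k, g, gp, force[mask])

    reached = np.nonzero(force >= params.trigger_force)[0]
    if reached.size == 0:
        raise CurveGenError("trigger force unreachable within the configured piezo range")
    end = int(reached[0])
    z = z[: end + 1]
    force = force[: end + 1]

    contact_index = int(np.searchsorted(z, z_a, side="left"))
    events = []
    for z_e, kind in truth_events:
        idx = int(np.searchsorted(z, z_e, side="right")) - 1
        if idx >= len(z) - 1 or idx <= contact_index:
            continue
        f_pre = float(force[idx])
        step_realised = float(force[idx] - force[idx + 1])
        depth = max((z[idx] - z_a) - f_pre / k, 0.0)
        events.append(EventTruth(idx, float(z[idx]), f_pre, step_realised, depth, kind))

    if params.noise_sd > 0:
        force = force + rng.normal(0.0, params.noise_sd, size=force.size)

    curve = ForceCurve(
        piezo_z=z,
        force=force,
        spring_constant=params.spring_constant,
        approach_speed=params.approach_speed,
        trigger_force=params.trigger_force,
        tip_kind=params.tip_kind,
        tip_radius=params.tip_radius,
        strain_label=params.strain_label,
        seed=params.seed,
        ground_truth=CurveGroundTruth(contact_index, z_a, events),
    )
    curve.validate(trigger_tolerance=max(0.05, 6.0 * params.noise_sd / params.trigger_force))
    return curve


def generate_condition_set(
    params: CurveGenParams,
    n: int,
    *,
    exact_count: bool = False,
    moment_match: bool = False,
) -> list[ForceCurve]:
    """Generate ``n`` curves for one condition.

    With ``exact_count`` the number of penetrating curves is exactly
    ``round(n * penetration_probability)`` on a seed-derived subset;
    otherwise each curve penetrates independently (binomial).  With
    ``moment_match`` (requires ``exact_count``) the sampled insertion
    forces are affinely rescaled so their sample mean and SD equal the
    configured values exactly — a deterministic fixture mode.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if moment_match and not exact_count:
        raise ValueError("moment_match requires exact_count mode")
    ss = np.random.SeedSequence(params.seed)
    children = ss.spawn(n + 1)
    batch_rng = np.random.default_rng(children[n])

    flags: list[bool | None]
    forces: list[float | None] = [None] * n
    if exact_count:
        m = int(round(n * params.penetration_probability))
        order = batch_rng.permutation(n)
        chosen = set(order[:m].tolist())
        flags = [i in chosen for i in range(n)]
        if m > 0:
            sd = max(params.insertion_force_sd, 1e-9)
            lo = max(FORCE_FLOOR_NN, params.min_drop_nn / 0.8)
            hi = 0.8 * params.trigger_force
            a = (lo - params.insertion_force_mean) / sd
            b = (hi - params.insertion_force_mean) / sd
            draws = truncnorm.rvs(
                a, b, loc=params.insertion_force_mean, scale=sd, size=m,
                random_state=batch_rng,
            )
            draws = np.atleast_1d(draws)
            if moment_match and m >= 2 and np.std(draws, ddof=1) > 0:
                draws = (draws - draws.mean()) / np.std(draws, ddof=1)
                draws = params.insertion_force_mean + params.insertion_force_sd * draws
                draws = np.clip(draws, lo, hi)
            it = iter(draws.tolist())
            for i in range(n):
                if flags[i]:
                    forces[i] = next(it)
    else:
        flags = [None] * n

    curves = []
    for i in range(n):
        rng = np.random.default_rng(children[i])
        p = replace(params)  # keep per-curve params identical; rng carries identity
        curves.append(
            generate_curve(p, penetrate=flags[i], insertion_force=forces[i], rng=rng)
        )
    return curves
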