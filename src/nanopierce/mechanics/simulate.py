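"""Quasi-static indentation of the prestressed network by a blunted cone.

The assembled tangent stiffness is material stiffness plus the geometric
(initial-stress) stiffness carried by the beam pretensions and the
membrane tension; it is constant over the indentation, so each depth
increment is an independent linear solve.  Contact is a growing set of
nodes under the tip, coupled to the rigid tip surface through a finite
contact stiffness: the structure under the tip therefore displaces less
when it is stiffer, which is the comparison of interest between the
prestressed and unprestressed states.

Membrane element stresses are evaluated post hoc with the von Karman
stretching strain (in-plane strain from u, v plus 1/2 (grad w)^2), on top
of the isotropic prestress baseline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from ..core import SolverError
from . import elements as el
from .mesh import NetworkModel, PrestressSpec

NDOF = 6  # per node: ux, uy, uz, rx, ry, rz


@dataclass
class Indenter:
    """Blunted cone: spherical cap of ``tip_radius`` blending into a cone
    of ``half_angle_deg`` from the axis."""

    tip_radius: float = 50.0  # nm
    travel: float = 100.0  # nm
    steps: int = 20
    half_angle_deg: float = 30.0
    #: tip-membrane coupling per unit contact area (Winkler foundation),
    #: nN/nm^3; the per-node spring is this times the nodal tributary area,
    #: which keeps the contact model mesh-convergent.
    contact_stiffness_per_area: float = 1e-6

    def __post_init__(self):
        if self.travel < 0 or self.tip_radius <= 0:
            raise ValueError("travel must be >= 0 and tip_radius > 0")

    def profile(self, rho: np.ndarray) -> np.ndarray:
        """Tip surface height above the apex at in-plane radius ``rho``."""
        r = self.tip_radius
        alpha = math.radians(self.half_angle_deg)
        rho = np.asarray(rho, dtype=float)
        rho_t = r * math.cos(alpha)
        sphere = r - np.sqrt(np.maximum(r * r - np.minimum(rho, rho_t) ** 2, 0.0))
        cone = (r - r * math.sin(alpha)) + (rho - rho_t) / math.tan(alpha)
        return np.where(rho <= rho_t, sphere, cone)


@dataclass
class SimResult:
    model: NetworkModel
    indenter: Indenter
    displacement: np.ndarray  # (N, 3) nm, translations at final depth
    rotation: np.ndarray  # (N, 3) rad
    stress_von_mises: np.ndarray  # (T,) Pa per membrane element
    stress_max_principal: np.ndarray  # (T,) Pa
    centroids: np.ndarray  # (T, 2) nm
    max_membrane_stress: float  # Pa, max principal incl. prestress baseline
    step_depths: np.ndarray  # nm
    step_max_stress: np.ndarray  # Pa, per increment
    contact_nodes: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))


def apply_prestress(model: NetworkModel, spec: PrestressSpec) -> NetworkModel:
    """Return a copy of the model carrying the given initial stresses."""
    spec.validate()
    return model.with_prestress(spec)


def _beam_section(area: float, modulus: float, poisson: float):
    # circular section consistent with the given area
    i_sec = area * area / (4.0 * math.pi)
    j_sec = 2.0 * i_sec
    g = modulus / (2.0 * (1.0 + poisson))
    return i_sec, j_sec, g


def assemble_stiffness(model: NetworkModel) -> sp.csr_matrix:
    """Assemble the symmetric tangent stiffness (material + geometric)."""
    n = model.n_nodes
    rows, cols, vals = [], [], []

    def scatter(ke, node_ids, dof_ids):
        gdofs = np.concatenate([np.array(dof_ids) + NDOF * nd for nd in node_ids])
        r = np.repeat(gdofs, gdofs.size)
        c = np.tile(gdofs, gdofs.size)
        rows.append(r)
        cols.append(c)
        vals.append(ke.ravel())

    e_beam = model.beam_modulus * 1e-9  # Pa -> nN/nm^2
    for conn, area, pre in (
        (model.filaments, model.filament_area, model.filament_axial_force()),
        (model.bundles, model.bundle_area, model.bundle_axial_force()),
    ):
        if conn.size == 0:
            continue
        i_sec, j_sec, g = _beam_section(area, e_beam, model.beam_poisson)
        for n1, n2 in conn:
            ke = el.beam_global(
                e_beam, g, area, i_sec, i_sec, j_sec,
                model.nodes[n1], model.nodes[n2], axial_force=pre,
            )
            scatter(ke, (n1, n2), list(range(NDOF)))

    e_mem = model.membrane_modulus * 1e-9
    tension = model.membrane_tension()
    for tri in model.triangles:
        xy = model.nodes[tri][:, :2]
        kp = el.cst_plane_stress(xy, e_mem, model.membrane_poisson, model.thickness)
        ke = np.zeros((9, 9))  # dofs (ux, uy, uz) x 3 nodes
        uv = [0, 1, 3, 4, 6, 7]
        ke[np.ix_(uv, uv)] += kp
        if tension != 0.0:
            kg = el.cst_tension_geometric(xy, tension)
            for comp in range(3):
                ids = [comp, comp + 3, comp + 6]
                ke[np.ix_(ids, ids)] += kg
        scatter(ke, tuple(tri), [0, 1, 2])

    k = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(NDOF * n, NDOF * n),
    ).tocsr()
    return k


def _free_dofs(model: NetworkModel) -> np.ndarray:
    fixed = np.zeros(NDOF * model.n_nodes, dtype=bool)
    for nd in model.clamped_nodes:
        fixed[NDOF * nd : NDOF * nd + NDOF] = True
    return np.nonzero(~fixed)[0]


def membrane_stresses(model: NetworkModel, disp: np.ndarray):
    """Per-element (von Mises, max principal) membrane stress in Pa.

    ``disp`` is the (N, 3) translation field in nm.  Strain is the linear
    in-plane strain from (u, v) plus the von Karman term 1/2 (grad w)^2,
    and the isotropic prestress is added to the stress.
    """
    e_mem = model.membrane_modulus * 1e-9
    nu = model.membrane_poisson
    d = e_mem / (1.0 - nu * nu) * np.array(
        [[1.0, nu, 0.0], [nu, 1.0, 0.0], [0.0, 0.0, (1.0 - nu) / 2.0]]
    )
    sigma0 = model.prestress.membrane * 1e-9  # nN/nm^2
    vm = np.zeros(len(model.triangles))
    p1 = np.zeros(len(model.triangles))
    cent = np.zeros((len(model.triangles), 2))
    for i, tri in enumerate(model.triangles):
        xy = model.nodes[tri][:, :2]
        grad, _ = el.cst_gradients(xy)
        u = disp[tri, 0]
        v = disp[tri, 1]
        w = disp[tri, 2]
        dudx, dudy = grad @ u
        dvdx, dvdy = grad @ v
        dwdx, dwdy = grad @ w
        eps = np.array(
            [
                dudx + 0.5 * dwdx * dwdx,
                dvdy + 0.5 * dwdy * dwdy,
                dudy + dvdx + dwdx * dwdy,
            ]
        )
        s = d @ eps
        sxx, syy, sxy = s[0] + sigma0, s[1] + sigma0, s[2]
        mean = 0.5 * (sxx + syy)
        rad = math.hypot(0.5 * (sxx - syy), sxy)
        p1[i] = (mean + rad) * 1e9  # -> Pa
        vm[i] = math.sqrt(sxx * sxx - sxx * syy + syy * syy + 3 * sxy * sxy) * 1e9
        cent[i] = xy.mean(axis=0)
    return vm, p1, cent


def simulate_indentation(model: NetworkModel, indenter: Indenter) -> SimResult:
    """Press the tip ``indenter.travel`` nm into the membrane centre.

    Vertical tip displacement is prescribed in increments; at each depth
    the nodes inside the tip footprint are coupled to the tip surface via
    the contact stiffness and the linearised equilibrium is solved.
    """
    n = model.n_nodes
    if model.clamped_nodes.size == 0:
        raise SolverError("model has no clamped boundary")
    if indenter.travel > 0 and indenter.steps < 10:
        raise SolverError("indenter travel must be resolved in >= 10 steps")

    k = assemble_stiffness(model)
    free = _free_dofs(model)
    rho = np.hypot(model.nodes[:, 0], model.nodes[:, 1])
    surf = indenter.profile(rho)

    u = np.zeros(NDOF * n)
    depths = []
    step_max = []
    contact_nodes = np.array([], dtype=int)

    if indenter.travel == 0:
        vm, p1m, cent = membrane_stresses(model, np.zeros((n, 3)))
        return SimResult(
            model, indenter, np.zeros((n, 3)), np.zeros((n, 3)),
            vm, p1m, cent, float(p1m.max()) if p1m.size else 0.0,
            np.array([]), np.array([]),
        )

    kc = indenter.contact_stiffness_per_area * model.spacing**2
    for s in range(1, indenter.steps + 1):
        depth = indenter.travel * s / indenter.steps
        contact = np.nonzero(surf < depth)[0]
        if contact.size == 0:
            raise SolverError("tip footprint contains no nodes; refine the mesh")
        wdofs = NDOF * contact + 2
        target = -(depth - surf[contact])

        diag = np.zeros(NDOF * n)
        diag[wdofs] = kc
        ks = k + sp.diags(diag)
        f = np.zeros(NDOF * n)
        f[wdofs] = kc * target

        kff = ks[np.ix_(free, free)].tocsc()
        try:
            lu = spla.splu(kff)
        except RuntimeError as exc:  # pragma: no cover - defensive
            raise SolverError(f"singular stiffness matrix: {exc}") from exc
        uf = lu.solve(f[free])
        if not np.all(np.isfinite(uf)):
            raise SolverError("solver produced non-finite displacements")
        u = np.zeros(NDOF * n)
        u[free] = uf
        disp = u.reshape(n, NDOF)[:, :3]
        _, p1m, _ = membrane_stresses(model, disp)
        depths.append(depth)
        step_max.append(float(p1m.max()))
        contact_nodes = contact

    disp = u.reshape(n, NDOF)[:, :3]
    rot = u.reshape(n, NDOF)[:, 3:]
    vm, p1m, cent = membrane_stresses(model, disp)
    return SimResult(
        model=model,
        indenter=indenter,
        displacement=disp,
        rotation=rot,
        stress_von_mises=vm,
        stress_max_principal=p1m,
        centroids=cent,
        max_membrane_stress=float(p1m.max()),
        step_depths=np.asarray(depths),
        step_max_stress=np.asarray(step_max),
        contact_nodes=contact_nodes,
    )


def midline_profile(result: SimResult, measure: str = "von_mises"):
    """z-displacement and membrane stress along the x-axis midline.

    Returns ``(x, w_z, sigma)``: node positions on the y = 0 line with
    their vertical displacements, and the element stress averaged over the
    two triangle rows adjacent to the midline, interpolated onto the same
    x positions.
    """
    model = result.model
    on_mid = np.abs(model.nodes[:, 1]) < 1e-9
    order = np.argsort(model.nodes[on_mid, 0])
    x = model.nodes[on_mid, 0][order]
    w = result.displacement[on_mid, 2][order]

    stress = result.stress_von_mises if measure == "von_mises" else result.stress_max_principal
    near = np.abs(result.centroids[:, 1]) <= model.spacing
    cx = result.centroids[near, 0]
    cs = stress[near]
    # average the stresses of elements sharing (rounded) centroid x
    key = np.round(cx / model.spacing * 4).astype(int)
    uniq = np.unique(key)
    px = np.array([cx[key == u].mean() for u in uniq])
    ps = np.array([cs[key == u].mean() for u in uniq])
    o = np.argsort(px)
    sigma = np.interp(x, px[o], ps[o])
    return x, w, sigma


def stress_peak_fwhm(x: np.ndarray, sigma: np.ndarray) -> float:
    """Full width at half maximum of the central stress peak.

    The far-field baseline is the median of the outer quarter of the
    profile; crossings of the half level are located by linear
    interpolation on either side of the peak.
    """
    x = np.asarray(x, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    n = x.size
    outer = np.concatenate([sigma[: n // 8 + 1], sigma[-(n // 8 + 1):]])
    base = float(np.median(outer))
    ipk = int(np.argmax(sigma))
    half = base + 0.5 * (sigma[ipk] - base)

    def cross(idx_range, reverse):
        rng = list(idx_range)
        if reverse:
            rng = rng[::-1]
        prev = ipk
        for i in rng:
            if sigma[i] < half:
                x0, x1 = x[i], x[prev]
                s0, s1 = sigma[i], sigma[prev]
                if s1 == s0:
                    return x[i]
                return x0 + (half - s0) * (x1 - x0) / (s1 - s0)
            prev = i
        return x[rng[-1]] if rng else x[ipk]

    left = cross(range(0, ipk), reverse=True)
    right = cross(range(ipk + 1, n), reverse=False)
    return float(right - left)
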