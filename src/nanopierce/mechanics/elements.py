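"""Element matrices: 3-D Euler-Bernoulli beams (material + geometric
stiffness) and constant-strain membrane triangles (plane stress + isotropic
initial-tension stiffness).

Internal mechanics units: length nm, force nN, hence modulus nN/nm^2
(= GPa) and distributed tension nN/nm.  Node DOF order is
(ux, uy, uz, rx, ry, rz).
"""

from __future__ import annotations

import numpy as np


def beam_stiffness_local(e: float, g: float, a: float, iy: float, iz: float,
                         j: float, length: float) -> np.ndarray:
    """12x12 Euler-Bernoulli beam stiffness in local coordinates."""
    le = length
    k = np.zeros((12, 12))
    ea = e * a / le
    gj = g * j / le
    k[0, 0] = k[6, 6] = ea
    k[0, 6] = k[6, 0] = -ea
    k[3, 3] = k[9, 9] = gj
    k[3, 9] = k[9, 3] = -gj

    # bending in the local x-y plane: dofs (uy1, rz1, uy2, rz2)
    kz = e * iz / le**3 * np.array(
        [
            [12, 6 * le, -12, 6 * le],
            [6 * le, 4 * le**2, -6 * le, 2 * le**2],
            [-12, -6 * le, 12, -6 * le],
            [6 * le, 2 * le**2, -6 * le, 4 * le**2],
        ]
    )
    for a_, i in enumerate((1, 5, 7, 11)):
        for b_, jj in enumerate((1, 5, 7, 11)):
            k[i, jj] += kz[a_, b_]

    # bending in the local x-z plane: dofs (uz1, ry1, uz2, ry2), opposite
    # sign convention on the rotation coupling terms
    ky = e * iy / le**3 * np.array(
        [
            [12, -6 * le, -12, -6 * le],
            [-6 * le, 4 * le**2, 6 * le, 2 * le**2],
            [-12, 6 * le, 12, 6 * le],
            [-6 * le, 2 * le**2, 6 * le, 4 * le**2],
        ]
    )
    for a_, i in enumerate((2, 4, 8, 10)):
        for b_, jj in enumerate((2, 4, 8, 10)):
            k[i, jj] += ky[a_, b_]
    return k


def beam_geometric_local(axial_force: float, length: float) -> np.ndarray:
    """12x12 consistent geometric (initial-stress) stiffness for axial force.

    Positive ``axial_force`` = tension, which stiffens the transverse
    response.
    """
    le = length
    n = axial_force
    kg = np.zeros((12, 12))
    m = n / (30.0 * le) * np.array(
        [
            [36, 3 * le, -36, 3 * le],
            [3 * le, 4 * le**2, -3 * le, -(le**2)],
            [-36, -3 * le, 36, -3 * le],
            [3 * le, -(le**2), -3 * le, 4 * le**2],
        ]
    )
    for a_, i in enumerate((1, 5, 7, 11)):
        for b_, jj in enumerate((1, 5, 7, 11)):
            kg[i, jj] += m[a_, b_]
    my = n / (30.0 * le) * np.array(
        [
            [36, -3 * le, -36, -3 * le],
            [-3 * le, 4 * le**2, 3 * le, -(le**2)],
            [-36, 3 * le, 36, 3 * le],
            [-3 * le, -(le**2), 3 * le, 4 * le**2],
        ]
    )
    for a_, i in enumerate((2, 4, 8, 10)):
        for b_, jj in enumerate((2, 4, 8, 10)):
            kg[i, jj] += my[a_, b_]
    return kg


def beam_transform(p1: np.ndarray, p2: np.ndarray) -> tuple[np.ndarray, float]:
    """Rotation matrix (rows = local axes) and length for a 2-node beam."""
    d = np.asarray(p2, dtype=float) - np.asarray(p1, dtype=float)
    length = float(np.linalg.norm(d))
    if length <= 0:
        raise ValueError("zero-length beam element")
    ex = d / length
    ref = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(ex, ref)) > 0.99:
        ref = np.array([1.0, 0.0, 0.0])
    ey = np.cross(ref, ex)
    ey /= np.linalg.norm(ey)
    ez = np.cross(ex, ey)
    r = np.vstack([ex, ey, ez])
    return r, length


def beam_global(e, g, a, iy, iz, j, p1, p2, axial_force=0.0):
    """Global 12x12 beam stiffness (material + geometric)."""
    r, length = beam_transform(p1, p2)
    k = beam_stiffness_local(e, g, a, iy, iz, j, length)
    if axial_force != 0.0:
        k = k + beam_geometric_local(axial_force, length)
    t = np.zeros((12, 12))
    for b in range(4):
        t[3 * b : 3 * b + 3, 3 * b : 3 * b + 3] = r
    return t.T @ k @ t


def cst_gradients(xy: np.ndarray) -> tuple[np.ndarray, float]:
    """Shape-function gradient matrix (2x3) and area of a CST triangle."""
    x, y = xy[:, 0], xy[:, 1]
    b = np.array([y[1] - y[2], y[2] - y[0], y[0] - y[1]])
    c = np.array([x[2] - x[1], x[0] - x[2], x[1] - x[0]])
    area2 = x[0] * b[0] + x[1] * b[1] + x[2] * b[2]
    area = 0.5 * area2
    if area <= 0:
        raise ValueError("degenerate or inverted membrane triangle")
    grad = np.vstack([b, c]) / area2  # rows: d/dx, d/dy of the 3 shape fns
    return grad, area


def cst_plane_stress(xy: np.ndarray, e: float, nu: float, t: float) -> np.ndarray:
    """6x6 in-plane membrane stiffness on dofs (u1, v1, u2, v2, u3, v3)."""
    grad, area = cst_gradients(xy)
    bmat = np.zeros((3, 6))
    bmat[0, 0::2] = grad[0]
    bmat[1, 1::2] = grad[1]
    bmat[2, 0::2] = grad[1]
    bmat[2, 1::2] = grad[0]
    d = e / (1.0 - nu * nu) * np.array(
        [[1.0, nu, 0.0], [nu, 1.0, 0.0], [0.0, 0.0, (1.0 - nu) / 2.0]]
    )
    return t * area * bmat.T @ d @ bmat


def cst_tension_geometric(xy: np.ndarray, tension: float) -> np.ndarray:
    """3x3 initial-tension stiffness for one displacement component.

    ``tension`` is the isotropic membrane tension per unit length
    (prestress x thickness).  The same matrix applies to each of u, v, w.
    """
    grad, area = cst_gradients(xy)
    return tension * area * grad.T @ grad
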