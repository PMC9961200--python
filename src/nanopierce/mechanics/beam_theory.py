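"""Tensioned simply-supported beam under a central transverse load.

Closed-form midspan deflection of the beam-column ODE
EI w'''' - F1 w'' = 0 with a central point load F2 (tension F1 >= 0),
plus a discretised check path that reuses the package's own beam element
matrices.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from . import elements as el

NDOF = 6


def beam_tension_deflection(length: float, ei: float, f1: float, f2: float) -> float:
    """Midspan deflection (same units as F2 L^3 / EI).

    w_mid = (F2 L^3 / 48 EI) * 3 (u - tanh u) / u^3 with
    u = (L/2) sqrt(F1/EI); the F1 = 0 limit is the classical
    F2 L^3 / (48 EI) and the large-tension limit is the taut string
    F2 L / (4 F1).
    """
    if length <= 0 or ei <= 0:
        raise ValueError("length and EI must be positive")
    if f1 < 0:
        raise ValueError("axial tension F1 must be >= 0")
    w0 = f2 * length**3 / (48.0 * ei)
    u = 0.5 * length * np.sqrt(f1 / ei)
    if u < 1e-4:
        factor = 1.0 - 2.0 * u**2 / 5.0 + 17.0 * u**4 / 105.0
    else:
        factor = 3.0 * (u - np.tanh(u)) / u**3
    return w0 * factor


def simply_supported_beam_fe(
    length: float,
    ei: float,
    f1: float,
    f2: float,
    n_elements: int = 200,
) -> float:
    """Midspan deflection from a chain of the package's 3-D beam elements.

    Both translations are pinned at the ends (plus torsion, to remove the
    rigid rotation about the axis); the load is applied at the midspan
    node in -z.  ``n_elements`` must be even so a node sits at midspan.
    """
    if n_elements % 2 != 0:
        raise ValueError("n_elements must be even")
    n_nodes = n_elements + 1
    xs = np.linspace(0.0, length, n_nodes)
    e_mod = 1.0
    i_sec = ei / e_mod
    a_sec = 1.0  # axial stiffness is irrelevant here
    j_sec = 2.0 * i_sec
    g_mod = e_mod / 2.6

    rows, cols, vals = [], [], []
    le = length / n_elements
    p1 = np.zeros(3)
    for e in range(n_elements):
        ke = el.beam_global(
            e_mod, g_mod, a_sec, i_sec, i_sec, j_sec,
            np.array([xs[e], 0.0, 0.0]), np.array([xs[e + 1], 0.0, 0.0]),
            axial_force=f1,
        )
        g = np.concatenate([np.arange(NDOF) + NDOF * e, np.arange(NDOF) + NDOF * (e + 1)])
        rows.append(np.repeat(g, g.size))
        cols.append(np.tile(g, g.size))
        vals.append(ke.ravel())
    k = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(NDOF * n_nodes, NDOF * n_nodes),
    ).tocsr()

    fixed = np.zeros(NDOF * n_nodes, dtype=bool)
    for nd in (0, n_nodes - 1):
        fixed[NDOF * nd + 0] = True  # ux
        fixed[NDOF * nd + 1] = True  # uy
        fixed[NDOF * nd + 2] = True  # uz
        fixed[NDOF * nd + 3] = True  # torsion
    # suppress the lateral bending/torsion family not excited by the load
    for nd in range(n_nodes):
        fixed[NDOF * nd + 1] = True
        fixed[NDOF * nd + 5] = True
    free = np.nonzero(~fixed)[0]

    f = np.zeros(NDOF * n_nodes)
    mid = n_nodes // 2
    f[NDOF * mid + 2] = -f2

    kff = k[np.ix_(free, free)].tocsc()
    u = spla.spsolve(kff, f[free])
    full = np.zeros(NDOF * n_nodes)
    full[free] = u
    return float(abs(full[NDOF * mid + 2]))
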