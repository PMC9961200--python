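"""Construction of the membrane + filament/bundle network model.

The model is a square patch: an orthogonal grid of filament beams, a few
stiffer bundle (stress-fiber) lines running along the long (x) axis, and a
triangulated membrane sheet that conforms to the same grid so that all
junctions share nodes (the no-relative-motion "tie" coupling).  Edge nodes
are fully clamped.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ..core import MeshError

FILAMENT_AREA_NM2 = 38.46
BUNDLE_AREA_NM2 = 400.0
MEMBRANE_THICKNESS_NM = 5.0


@dataclass
class PrestressSpec:
    """Initial stresses, Pa: isotropic membrane stress plus axial stresses
    for the two beam families."""

    membrane: float = 0.0
    filament: float = 0.0
    bundle: float = 0.0

    def validate(self):
        if min(self.membrane, self.filament, self.bundle) < 0:
            raise ValueError("prestress components must be >= 0")


@dataclass
class NetworkModel:
    nodes: np.ndarray  # (N, 3) nm
    filaments: np.ndarray  # (M, 2) node indices
    bundles: np.ndarray  # (B, 2) node indices
    triangles: np.ndarray  # (T, 3) node indices
    clamped_nodes: np.ndarray  # boundary node indices

    filament_area: float = FILAMENT_AREA_NM2  # nm^2
    bundle_area: float = BUNDLE_AREA_NM2  # nm^2
    thickness: float = MEMBRANE_THICKNESS_NM  # nm

    # material defaults (Pa, configurable).  beam_modulus is an *effective*
    # network-scale modulus: it must be soft enough that the prestress
    # geometric stiffness (N L^2 / EI >~ 30 at the crosslink spacing) can
    # dominate element bending, otherwise prestress cannot reshape the
    # response at all; a molecular-scale filament modulus (~GPa) with
    # clamped continuous-rod elements would bury the effect.
    membrane_modulus: float = 1e6
    membrane_poisson: float = 0.3
    beam_modulus: float = 5e6
    beam_poisson: float = 0.3

    prestress: PrestressSpec = field(default_factory=PrestressSpec)

    # grid bookkeeping for profile extraction
    spacing: float = 0.0  # nm
    half_width: float = 0.0  # nm

    @property
    def n_nodes(self) -> int:
        return int(self.nodes.shape[0])

    def with_prestress(self, spec: PrestressSpec) -> "NetworkModel":
        return replace(self, prestress=spec)

    def filament_axial_force(self) -> float:
        """Axial pretension per filament beam, nN (sigma x A)."""
        return self.prestress.filament * 1e-9 * self.filament_area

    def bundle_axial_force(self) -> float:
        return self.prestress.bundle * 1e-9 * self.bundle_area

    def membrane_tension(self) -> float:
        """Isotropic membrane tension per unit length, nN/nm (sigma x t)."""
        return self.prestress.membrane * 1e-9 * self.thickness


def build_network(
    half_width: float,
    filament_spacing: float,
    fiber_lines: int | list[int] = 3,
    **material_overrides,
) -> NetworkModel:
    """Build the square grid model.

    ``fiber_lines`` is either the number of bundle lines (placed on
    evenly spaced interior grid rows, centred) or an explicit list of grid
    row indices.  Triangulation uses checkerboard-alternating diagonals so
    the mesh is mirror-symmetric in x and y.
    """
    if filament_spacing <= 0 or half_width <= 0:
        raise MeshError("half_width and filament_spacing must be positive")
    if half_width < 5.0 * filament_spacing:
        raise MeshError(
            f"degenerate geometry: half_width ({half_width}) must be at least "
            f"5 x filament_spacing ({filament_spacing})"
        )
    ncell = int(round(2.0 * half_width / filament_spacing))
    if abs(ncell * filament_spacing - 2.0 * half_width) > 1e-6 * half_width:
        raise MeshError("2 x half_width must be an integer multiple of filament_spacing")

    nline = ncell + 1
    coords = np.linspace(-half_width, half_width, nline)
    xx, yy = np.meshgrid(coords, coords, indexing="xy")
    nodes = np.column_stack([xx.ravel(), yy.ravel(), np.zeros(nline * nline)])

    def nid(ix, iy):
        return iy * nline + ix

    fil = []
    for iy in range(nline):
        for ix in range(ncell):
            fil.append((nid(ix, iy), nid(ix + 1, iy)))  # along x
    for ix in range(nline):
        for iy in range(ncell):
            fil.append((nid(ix, iy), nid(ix, iy + 1)))  # along y
    filaments = np.array(fil, dtype=int)

    if isinstance(fiber_lines, int):
        if fiber_lines < 0:
            raise MeshError("fiber_lines must be >= 0")
        rows = np.unique(
            np.round(np.linspace(0, ncell, fiber_lines + 2)[1:-1]).astype(int)
        )
    else:
        rows = np.unique(np.asarray(fiber_lines, dtype=int))
        if rows.size and (rows.min() < 0 or rows.max() > ncell):
            raise MeshError("fiber line row index out of range")
    bun = []
    for iy in rows:
        for ix in range(ncell):
            bun.append((nid(ix, int(iy)), nid(ix + 1, int(iy))))
    bundles = np.array(bun, dtype=int).reshape(-1, 2)

    tri = []
    for iy in range(ncell):
        for ix in range(ncell):
            n00 = nid(ix, iy)
            n10 = nid(ix + 1, iy)
            n01 = nid(ix, iy + 1)
            n11 = nid(ix + 1, iy + 1)
            if (ix + iy) % 2 == 0:  # diagonal n00-n11
                tri.append((n00, n10, n11))
                tri.append((n00, n11, n01))
            else:  # diagonal n10-n01
                tri.append((n00, n10, n01))
                tri.append((n10, n11, n01))
    triangles = np.array(tri, dtype=int)

    edge = np.nonzero(
        (np.abs(np.abs(nodes[:, 0]) - half_width) < 1e-9)
        | (np.abs(np.abs(nodes[:, 1]) - half_width) < 1e-9)
    )[0]

    model = NetworkModel(
        nodes=nodes,
        filaments=filaments,
        bundles=bundles,
        triangles=triangles,
        clamped_nodes=edge,
        spacing=float(filament_spacing),
        half_width=float(half_width),
    )
    for key, val in material_overrides.items():
        if not hasattr(model, key):
            raise MeshError(f"unknown material override: {key}")
        setattr(model, key, float(val))
    return model
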