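"""Shared domain objects and exceptions.

Unit conventions at every public interface:

* piezo position / depth   nanometres (nm)
* force                    nanonewtons (nN)
* spring constant          N/m  (numerically identical to nN/nm)
* approach speed           micrometres per second (um/s)
* tip radius               micrometres (um)
* stress / modulus         pascals (Pa)

With these choices ``force / spring_constant`` is directly a cantilever
deflection in nm, which keeps the depth correction free of unit juggling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

TIP_KINDS = ("sphere", "pyramid")


class NanoPierceError(Exception):
    """Base class for all package-specific errors."""


class CurveGenError(NanoPierceError):
    """Synthetic curve generation failed (e.g. trigger force unreachable)."""


class NoContactError(NanoPierceError):
    """No tip-sample contact could be located on a force curve."""


class FitFailureError(NanoPierceError):
    """Nonlinear fit did not converge or hit a parameter bound."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class SegmentationError(NanoPierceError):
    """Curve segmentation is degenerate (too few samples in a stage)."""


class FormatError(NanoPierceError):
    """A curve file is malformed or misses mandatory metadata."""


class MeshError(NanoPierceError):
    """Network mesh construction failed."""


class SolverError(NanoPierceError):
    """Structural solve failed (singular system or non-convergence)."""


@dataclass
class EventTruth:
    """Ground-truth record for one planted force drop.

    ``index`` is the last sample before the drop; the negative step occurs
    between ``index`` and ``index + 1``.  ``force`` is the noise-free force
    at ``index`` (the insertion force), ``step`` the realised noise-free
    force decrease across the drop, ``depth`` the cantilever-corrected
    indentation depth in nm at ``index``.
    """

    index: int
    piezo_z: float
    force: float
    step: float
    depth: float
    kind: str  # "membrane" or "nucleus"


@dataclass
class CurveGroundTruth:
    contact_index: int
    contact_z: float
    events: list[EventTruth] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "contact_index": int(self.contact_index),
            "contact_z": float(self.contact_z),
            "events": [
                {
                    "index": int(e.index),
                    "piezo_z": float(e.piezo_z),
                    "force": float(e.force),
                    "step": float(e.step),
                    "depth": float(e.depth),
                    "kind": e.kind,
                }
                for e in self.events
            ],
        }


@dataclass
class ForceCurve:
    """One AFM approach trace plus its acquisition metadata.

    ``ground_truth`` is only populated for synthetic curves; it never
    round-trips through the on-disk CSV format (a sidecar JSON carries it
    for generated batches).
    """

    piezo_z: np.ndarray  # nm, monotone non-decreasing
    force: np.ndarray  # nN
    spring_constant: float  # N/m
    approach_speed: float  # um/s
    trigger_force: float  # nN
    tip_kind: str
    tip_radius: float  # um
    strain_label: float = 0.0  # substrate strain, percent
    seed: int | None = None
    ground_truth: CurveGroundTruth | None = None

    def __post_init__(self):
        self.piezo_z = np.asarray(self.piezo_z, dtype=float)
        self.force = np.asarray(self.force, dtype=float)

    def validate(self, trigger_tolerance: float = 0.05) -> None:
        """Check the type invariants, raising ``ValueError`` on violation."""
        if self.piezo_z.shape != self.force.shape or self.piezo_z.ndim != 1:
            raise ValueError("piezo_z and force must be 1-D arrays of equal length")
        if self.piezo_z.size < 50:
            raise ValueError(f"curve needs >= 50 samples, got {self.piezo_z.size}")
        dz = np.diff(self.piezo_z)
        if np.any(dz < 0):
            raise ValueError("piezo_z must be monotone non-decreasing")
        uniq = self.piezo_z[np.concatenate(([True], dz > 0))]
        if np.any(np.diff(uniq) <= 0):
            raise ValueError("piezo_z must be strictly increasing after de-duplication")
        if self.tip_kind not in TIP_KINDS:
            raise ValueError(f"tip_kind must be one of {TIP_KINDS}")
        if self.spring_constant <= 0:
            raise ValueError("spring_constant must be positive")
        if self.trigger_force <= 0:
            raise ValueError("trigger_force must be positive")
        if np.max(self.force) > self.trigger_force * (1.0 + trigger_tolerance):
            raise ValueError("force exceeds trigger_force beyond tolerance")

    @property
    def n_samples(self) -> int:
        return int(self.piezo_z.size)
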