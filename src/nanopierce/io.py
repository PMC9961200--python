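"""Curve file format: CSV data columns with a '#'-prefixed key=value header.

Example::

    # spring_constant = 0.02
    # approach_speed = 1.0
    # trigger_force = 12.0
    # tip_kind = pyramid
    # tip_radius = 0.01
    # strain_label = 0.0
    # seed = 7
    piezo_z_nm,force_nN
    0,0.0132...

The round trip is lossless: floats are written with 17 significant digits.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np

from .core import ForceCurve, FormatError

MANDATORY_KEYS = (
    "spring_constant",
    "approach_speed",
    "trigger_force",
    "tip_kind",
    "tip_radius",
    "strain_label",
)


def write_curve(curve: ForceCurve, path: str | Path) -> None:
    curve.validate(trigger_tolerance=1.0)  # structural checks only on write
    buf = _io.StringIO()
    meta = {
        "spring_constant": curve.spring_constant,
        "approach_speed": curve.approach_speed,
        "trigger_force": curve.trigger_force,
        "tip_kind": curve.tip_kind,
        "tip_radius": curve.tip_radius,
        "strain_label": curve.strain_label,
    }
    if curve.seed is not None:
        meta["seed"] = curve.seed
    for key, val in meta.items():
        buf.write(f"# {key} = {val!r}\n" if isinstance(val, str) else f"# {key} = {val:.17g}\n")
    buf.write("piezo_z_nm,force_nN\n")
    for z, f in zip(curve.piezo_z, curve.force):
        buf.write(f"{z:.17g},{f:.17g}\n")
    Path(path).write_text(buf.getvalue())


def read_curve(path: str | Path) -> ForceCurve:
    meta: dict[str, str] = {}
    zs: list[float] = []
    fs: list[float] = []
    saw_header = False
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line[1:].strip()
            if "=" not in body:
                raise FormatError(f"{path}:{lineno}: malformed metadata line")
            key, _, val = body.partition("=")
            meta[key.strip()] = val.strip().strip("'\"")
        elif not saw_header:
            if line.replace(" ", "") != "piezo_z_nm,force_nN":
                raise FormatError(f"{path}:{lineno}: expected column header 'piezo_z_nm,force_nN'")
            saw_header = True
        else:
            parts = line.split(",")
            if len(parts) != 2:
                raise FormatError(f"{path}:{lineno}: expected two columns")
            try:
                zs.append(float(parts[0]))
                fs.append(float(parts[1]))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric data") from exc

    for key in MANDATORY_KEYS:
        if key not in meta:
            raise FormatError(f"{path}: missing mandatory metadata key '{key}'")

    curve = ForceCurve(
        piezo_z=np.asarray(zs),
        force=np.asarray(fs),
        spring_constant=float(meta["spring_constant"]),
        approach_speed=float(meta["approach_speed"]),
        trigger_force=float(meta["trigger_force"]),
        tip_kind=meta["tip_kind"],
        tip_radius=float(meta["tip_radius"]),
        strain_label=float(meta["strain_label"]),
        seed=int(meta["seed"]) if "seed" in meta else None,
    )
    try:
        curve.validate(trigger_tolerance=1.0)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc
    return curve
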