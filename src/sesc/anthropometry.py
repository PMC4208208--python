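"""Literature-based (Winter) body model and the non-subject-specific
SESC comparator built from it.

Anthropometric tables give per-segment mass as a fraction of body mass,
segment length as a fraction of stature and CoM location as a fraction
of segment length from the proximal joint.  Scaling such a table to a
subject's height and mass yields the "literature" body model used by
classical segmentation CoM methods; feeding it through the exact SESC
construction yields literature SESC parameters, which are independent of
body mass (the fractions cancel after division by total mass) and are
conventionally reported normalized by height.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np

from .body_model import BodyModel, BodySegment, Posture
from .sesc_core import SESCParameters, estimate_com, true_sesc_from_model


class TableValidationError(ValueError):
    """An anthropometric table violates its fraction constraints."""


#: merged segment names expected in a table, torso first
MERGED_SEGMENTS = ("torso", "upper_arm", "forearm_hand", "thigh", "shank_foot")
#: segments present once (torso) vs per-side
_BILATERAL = ("upper_arm", "forearm_hand", "thigh", "shank_foot")


@dataclass(frozen=True)
class SegmentFractions:
    mass: float
    length: float
    com: float


@dataclass
class AnthropometricTable:
    """Merged-segment fractions plus torso geometry fractions of stature."""

    name: str
    version: int
    citation: str
    segments: dict[str, SegmentFractions]
    shoulder_halfwidth: float
    hip_halfwidth: float

    def __post_init__(self) -> None:
        missing = [s for s in MERGED_SEGMENTS if s not in self.segments]
        if missing:
            raise TableValidationError(f"table missing segments: {missing}")
        for name, f in self.segments.items():
            for attr in ("mass", "length", "com"):
                val = getattr(f, attr)
                if not 0.0 < val < 1.0:
                    raise TableValidationError(
                        f"{name}.{attr} fraction {val} outside (0, 1)"
                    )
        total = self.segments["torso"].mass + 2.0 * sum(
            self.segments[s].mass for s in _BILATERAL
        )
        if abs(total - 1.0) > 1e-6:
            raise TableValidationError(
                f"mass fractions over the 9-segment model sum to {total}, not 1"
            )

    @classmethod
    def from_dict(cls, d: dict) -> "AnthropometricTable":
        return cls(
            name=d["name"],
            version=int(d["version"]),
            citation=d.get("citation", ""),
            segments={
                k: SegmentFractions(
                    mass=float(v["mass_fraction"]),
                    length=float(v["length_fraction"]),
                    com=float(v["com_fraction"]),
                )
                for k, v in d["segments"].items()
            },
            shoulder_halfwidth=float(d["shoulder_halfwidth_fraction"]),
            hip_halfwidth=float(d["hip_halfwidth_fraction"]),
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "AnthropometricTable":
        return cls.from_dict(json.loads(Path(path).read_text()))


_WINTER_CACHE: AnthropometricTable | None = None


def winter_table() -> AnthropometricTable:
    """The packaged Winter-based merged-segment table."""
    global _WINTER_CACHE
    if _WINTER_CACHE is None:
        text = resources.files("sesc.data").joinpath("winter_table.json").read_text()
        _WINTER_CACHE = AnthropometricTable.from_dict(json.loads(text))
    return _WINTER_CACHE


def body_model_from_table(
    height: float, mass: float, table: AnthropometricTable
) -> BodyModel:
    """Scale a merged-segment table to a subject (symmetric 9-segment model)."""
    if height <= 0 or mass <= 0:
        raise ValueError("height and mass must be positive")
    t = table.segments
    L_torso = t["torso"].length * height
    L_ua = t["upper_arm"].length * height
    L_fa = t["forearm_hand"].length * height
    L_th = t["thigh"].length * height
    L_sh = t["shank_foot"].length * height
    w_sh = table.shoulder_halfwidth * height
    w_hip = table.hip_halfwidth * height

    def seg(sid, parent, frac: SegmentFractions, length, attach):
        return BodySegment(
            id=sid,
            parent_id=parent,
            mass=frac.mass * mass,
            length=length,
            com_offset=(0.0, 0.0, frac.com * length),
            attach_offset=attach,
        )

    segments = (
        seg(1, 0, t["torso"], L_torso, (0.0, 0.0, 0.0)),
        seg(2, 1, t["upper_arm"], L_ua, (0.0, +w_sh, L_torso)),
        seg(3, 2, t["forearm_hand"], L_fa, (0.0, 0.0, L_ua)),
        seg(4, 1, t["upper_arm"], L_ua, (0.0, -w_sh, L_torso)),
        seg(5, 4, t["forearm_hand"], L_fa, (0.0, 0.0, L_ua)),
        seg(6, 1, t["thigh"], L_th, (0.0, +w_hip, 0.0)),
        seg(7, 6, t["shank_foot"], L_sh, (0.0, 0.0, L_th)),
        seg(8, 1, t["thigh"], L_th, (0.0, -w_hip, 0.0)),
        seg(9, 8, t["shank_foot"], L_sh, (0.0, 0.0, L_th)),
    )
    return BodyModel(segments=segments, height=height)


def winter_body_model(
    height: float, mass: float, table: AnthropometricTable | None = None
) -> BodyModel:
    """Literature body model for a subject of the given stature and mass."""
    return body_model_from_table(height, mass, table or winter_table())


def literature_sesc(
    height: float, table: AnthropometricTable | None = None
) -> SESCParameters:
    """Literature SESC parameters (meters, with height attached).

    Mass-independent: the parameter vector scales only with height.  Use
    ``.normalized()`` for the height-normalized values conventionally
    tabulated (e.g. r3 = 0.0022, r6 = 0.0256, r7 = 0.0085 for the packaged
    table, to 4 decimals).
    """
    model = winter_body_model(height, mass=1.0, table=table)
    return true_sesc_from_model(model)


def literature_com_estimate(
    height: float, posture: Posture, table: AnthropometricTable | None = None
) -> np.ndarray:
    """Non-subject-specific CoM estimate: literature SESC on a posture.

    By the serial-chain identity this equals the classical segmentation
    method applied to the scaled literature body model.
    """
    return estimate_com(literature_sesc(height, table=table), posture)
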