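"""Serializable ground-truth record emitted by the simulator.

Every rendered fixture carries a ``GroundTruth`` describing the planted
geometry, trajectories, contact labels and fixed-cell spots, so downstream
stages can be scored against what was actually planted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .geometry import NeuronGeometry
from .kinetics import GroundTruthTrack


@dataclass
class GroundTruth:
    geometry: NeuronGeometry | None = None
    tracks: list[GroundTruthTrack] = field(default_factory=list)
    contact_labels: list[bool] | None = None          # per planted PO
    po_positions_px: np.ndarray | None = None         # (N, 2) planted PO centres
    fixed_spots: dict | None = None                   # fixed-cell spot record
    meta: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "geometry": self.geometry.to_dict() if self.geometry else None,
            "tracks": [t.to_dict() for t in self.tracks],
            "contact_labels": list(map(bool, self.contact_labels))
            if self.contact_labels is not None
            else None,
            "po_positions_px": self.po_positions_px.tolist()
            if self.po_positions_px is not None
            else None,
            "fixed_spots": self.fixed_spots,
            "meta": self.meta,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(
            geometry=NeuronGeometry.from_dict(d["geometry"]) if d.get("geometry") else None,
            tracks=[GroundTruthTrack.from_dict(t) for t in d.get("tracks", [])],
            contact_labels=d.get("contact_labels"),
            po_positions_px=np.asarray(d["po_positions_px"], dtype=float)
            if d.get("po_positions_px") is not None
            else None,
            fixed_spots=d.get("fixed_spots"),
            meta=d.get("meta", {}),
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        return cls.from_dict(json.loads(Path(path).read_text()))
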