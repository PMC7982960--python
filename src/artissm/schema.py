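"""Named landmark vertex sets on the reference topology.

Because dense correspondence gives every subject the reference topology,
landmarks defined once (as vertex-index sets per component) transfer to
every registered subject and every model instance automatically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class SchemaError(KeyError):
    """A biometric asked for a landmark the schema does not provide."""


@dataclass
class LandmarkSchema:
    """Mapping landmark name -> (component label, vertex index array)."""

    entries: dict[str, tuple[str, np.ndarray]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.entries = {
            name: (comp, np.atleast_1d(np.asarray(idx, dtype=np.int64)))
            for name, (comp, idx) in self.entries.items()
        }

    def add(self, name: str, component: str, indices) -> None:
        self.entries[name] = (component, np.atleast_1d(np.asarray(indices, dtype=np.int64)))

    def __contains__(self, name: str) -> bool:
        return name in self.entries

    def require(self, name: str, biometric: str | None = None):
        if name not in self.entries:
            what = f" (needed by biometric {biometric!r})" if biometric else ""
            raise SchemaError(f"landmark {name!r} missing from schema{what}")
        return self.entries[name]

    def points(self, model, name: str, biometric: str | None = None) -> np.ndarray:
        """Landmark coordinates on a LimbModel (or mapping of meshes)."""
        comp, idx = self.require(name, biometric)
        components = getattr(model, "components", model)
        mesh = components[comp]
        verts = getattr(mesh, "vertices", mesh)
        return np.asarray(verts, float)[idx]

    def centroid(self, model, name: str, biometric: str | None = None) -> np.ndarray:
        return self.points(model, name, biometric).mean(axis=0)

    def validate(self, components) -> None:
        for name, (comp, idx) in self.entries.items():
            if comp not in components:
                raise SchemaError(f"landmark {name!r} refers to unknown component {comp!r}")
            n = getattr(components[comp], "n_vertices", None) or len(components[comp].vertices)
            if idx.min() < 0 or idx.max() >= n:
                raise SchemaError(f"landmark {name!r} has vertex indices outside component {comp!r}")

    def to_dict(self) -> dict:
        return {name: {"component": comp, "indices": idx.tolist()}
                for name, (comp, idx) in self.entries.items()}

    @classmethod
    def from_dict(cls, d: dict) -> "LandmarkSchema":
        return cls({name: (e["component"], np.asarray(e["indices"], dtype=np.int64))
                    for name, e in d.items()})
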