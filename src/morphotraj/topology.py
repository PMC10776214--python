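"""Shared template topology: triangulation and bilateral landmark pairing."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Reflection across the midplane x = 0.
_REFLECT = np.array([-1.0, 1.0, 1.0])


class TopologyError(ValueError):
    """Raised when a triangulation or pairing map is inconsistent."""


@dataclass(frozen=True)
class TemplateTopology:
    """Triangulation plus bilateral pairing shared by every configuration.

    Parameters
    ----------
    n_landmarks:
        Number of landmarks L.
    facets:
        ``(F, 3)`` integer array of 0-based landmark index triples.
    paired_map:
        Length-L involution mapping each left-side landmark to its
        right-side counterpart; midline landmarks map to themselves.
        The midplane is ``x = 0`` by convention.
    template_coords:
        Optional ``(L, 3)`` reference coordinates of the template itself.
    """

    n_landmarks: int
    facets: np.ndarray
    paired_map: np.ndarray
    template_coords: np.ndarray | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        facets = np.asarray(self.facets, dtype=int)
        paired = np.asarray(self.paired_map, dtype=int)
        object.__setattr__(self, "facets", facets)
        object.__setattr__(self, "paired_map", paired)
        if self.n_landmarks < 3:
            raise TopologyError("n_landmarks must be >= 3")
        if facets.ndim != 2 or facets.shape[1] != 3:
            raise TopologyError("facets must be an (F, 3) index array")
        if facets.size and (facets.min() < 0 or facets.max() >= self.n_landmarks):
            raise TopologyError("facet indices out of range")
        if paired.shape != (self.n_landmarks,):
            raise TopologyError("paired_map must have length n_landmarks")
        if not np.array_equal(paired[paired], np.arange(self.n_landmarks)):
            raise TopologyError("paired_map is not an involution")
        if self.template_coords is not None:
            coords = np.asarray(self.template_coords, dtype=float)
            if coords.shape != (self.n_landmarks, 3):
                raise TopologyError("template_coords must be (L, 3)")
            object.__setattr__(self, "template_coords", coords)

    @property
    def n_facets(self) -> int:
        return len(self.facets)

    @property
    def midline(self) -> np.ndarray:
        """Indices of landmarks lying on the symmetry plane."""
        return np.flatnonzero(self.paired_map == np.arange(self.n_landmarks))

    def edges(self) -> np.ndarray:
        """Unique undirected edges of the triangulation, sorted pairs."""
        e = np.concatenate(
            [self.facets[:, [0, 1]], self.facets[:, [1, 2]], self.facets[:, [2, 0]]]
        )
        e = np.sort(e, axis=1)
        return np.unique(e, axis=0)

    def mirror(self, coords: np.ndarray) -> np.ndarray:
        """Reflect ``coords`` in the plane x = 0 and relabel paired landmarks.

        For a bilaterally symmetric configuration the result equals the
        input exactly.
        """
        coords = np.asarray(coords, dtype=float)
        if coords.shape[-2] != self.n_landmarks:
            raise TopologyError("coordinate array does not match n_landmarks")
        return (coords * _REFLECT)[..., self.paired_map, :]

    def symmetry_residual(self, coords: np.ndarray) -> float:
        """Max absolute deviation of ``coords`` from reflect-and-relabel symmetry."""
        return float(np.abs(self.mirror(coords) - coords).max())
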