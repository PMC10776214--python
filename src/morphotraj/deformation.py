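"""Per-facet area-change deformation fields between shapes on a shared
triangulation, and Pearson correlations between fields."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from morphotraj.shape_core import scores_to_shape
from morphotraj.topology import TemplateTopology


def facet_areas(coords: np.ndarray, topology: TemplateTopology) -> np.ndarray:
    """Area of each triangular facet: half cross-product magnitude."""
    coords = np.asarray(coords, dtype=float)
    tri = coords[topology.facets]  # (F, 3, 3)
    cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    return 0.5 * np.linalg.norm(cross, axis=1)


@dataclass
class DeformationField:
    """Percentage change of each facet's area from a source to a target shape."""

    values: np.ndarray  # (F,) percent
    topology: TemplateTopology = field(repr=False)
    source: np.ndarray | None = field(default=None, repr=False)
    target: np.ndarray | None = field(default=None, repr=False)
    degenerate: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def __len__(self) -> int:
        return len(self.values)

    def vertex_values(self) -> np.ndarray:
        """Facet values averaged onto vertices (rendering only)."""
        L = self.topology.n_landmarks
        acc = np.zeros(L)
        cnt = np.zeros(L)
        for f, v in zip(self.topology.facets, self.values):
            if np.isfinite(v):
                acc[f] += v
                cnt[f] += 1
        with np.errstate(invalid="ignore"):
            return np.where(cnt > 0, acc / np.maximum(cnt, 1), np.nan)


def deformation_field(
    source: np.ndarray, target: np.ndarray, topology: TemplateTopology
) -> DeformationField:
    """(area_target - area_source) / area_source * 100 per facet.

    Zero-area source facets yield NaN and are reported in ``degenerate``.
    """
    a_src = facet_areas(source, topology)
    a_tgt = facet_areas(target, topology)
    bad = np.flatnonzero(a_src == 0.0)
    if len(bad):
        warnings.warn(f"{len(bad)} zero-area source facet(s); field undefined there", stacklevel=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        vals = (a_tgt - a_src) / a_src * 100.0
    vals[bad] = np.nan
    return DeformationField(
        values=vals, topology=topology, source=np.asarray(source), target=np.asarray(target),
        degenerate=bad,
    )


def rate_effect_field(
    predicted_scores: np.ndarray,
    rate_vector: np.ndarray,
    eigenbasis: np.ndarray,
    consensus: np.ndarray,
    topology: TemplateTopology,
    step: float = 1.0,
) -> DeformationField:
    """Deformation from the predicted shape to (predicted + step * rate).

    The default step of one year shows the morphological effect of the
    instantaneous rate vector.
    """
    predicted_scores = np.asarray(predicted_scores, dtype=float)
    rate_vector = np.asarray(rate_vector, dtype=float)
    if predicted_scores.shape != rate_vector.shape:
        raise ValueError("predicted scores and rate vector dimension mismatch")
    src = scores_to_shape(predicted_scores, eigenbasis, consensus)
    tgt = scores_to_shape(predicted_scores + step * rate_vector, eigenbasis, consensus)
    return deformation_field(src, tgt, topology)


def dimorphism_field(
    female_scores: np.ndarray,
    male_scores: np.ndarray,
    eigenbasis: np.ndarray,
    consensus: np.ndarray,
    topology: TemplateTopology,
) -> DeformationField:
    """Deformation from the predicted female to the predicted male shape."""
    src = scores_to_shape(np.asarray(female_scores, dtype=float), eigenbasis, consensus)
    tgt = scores_to_shape(np.asarray(male_scores, dtype=float), eigenbasis, consensus)
    return deformation_field(src, tgt, topology)


def field_correlation(field_a, field_b) -> float:
    """Pearson correlation of two fields across facets."""
    a = np.asarray(getattr(field_a, "values", field_a), dtype=float)
    b = np.asarray(getattr(field_b, "values", field_b), dtype=float)
    if a.shape != b.shape:
        raise ValueError("fields must have equal facet counts")
    ok = np.isfinite(a) & np.isfinite(b)
    a, b = a[ok], b[ok]
    if a.std() == 0.0 or b.std() == 0.0:
        raise ValueError("zero variance in a field; correlation undefined")
    return float(np.corrcoef(a, b)[0, 1])


def symmetric_color_limits(field: DeformationField, percentile: float = 98.0) -> tuple[float, float]:
    """Symmetric diverging-scale limits at a percentile of |field| (default 98th)."""
    vals = field.values[np.isfinite(field.values)]
    lim = float(np.percentile(np.abs(vals), percentile)) if len(vals) else 1.0
    lim = max(lim, np.finfo(float).tiny)
    return -lim, lim
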