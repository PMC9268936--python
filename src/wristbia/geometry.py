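"""Parametric wrist cross-section geometry.

A single source of truth for the cuboid wrist segment used both by the
lumped parallel-tissue circuit (which only needs per-tissue areas) and by
the voxel field solver (which needs a point classifier).  The cross-section
is a ``width x height`` rectangle (default 50 mm x 30 mm); the segment is
``length`` long (default 100 mm).  Tissue layout by stage:

* ``model1`` - a fat ring under the outer surface, muscle inside, and a
  circular blood-filled artery near the top surface.
* ``model2`` - adds a skin ring outside the fat.
* ``model3`` - adds a rectangular bone block (cortical shell around a
  cancellous core) occupying a fixed fraction of the stage-1 muscle area.

All lengths are SI metres.  The artery is carved last, so it overrides any
layer it intersects.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .errors import ConfigurationError

STAGES = ("model1", "model2", "model3")

#: Tissue names in label order used by the field solver.
TISSUES = ("skin", "fat", "muscle", "blood", "cortical", "cancellous")


@dataclass(frozen=True)
class WristGeometry:
    """Dimensions and layer thicknesses of the cuboid wrist segment."""

    width: float = 0.050            # m, x extent of the cross-section
    height: float = 0.030           # m, y extent of the cross-section
    length: float = 0.100           # m, z extent of the segment
    skin_thickness: float = 0.0015  # m, outer ring (stages 2-3)
    fat_thickness: float = 0.003    # m, ring under the skin
    artery_diameter: float = 0.0025  # m, basal arterial diameter
    artery_depth: float = 0.003     # m, cover from top surface to artery top
    bone_muscle_fraction: float = 0.68  # bone area / stage-1 muscle area
    cortical_share: float = 0.40    # cortical fraction of the bone area
    bone_height: float = 0.019      # m, vertical extent of the bone block
    bone_bottom: float = 0.005      # m, bone block offset from the bottom

    def __post_init__(self):
        for name in ("width", "height", "length", "artery_diameter"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")

    # ------------------------------------------------------------------
    # Derived scalars
    # ------------------------------------------------------------------
    @property
    def cross_section_area(self) -> float:
        return self.width * self.height

    @property
    def artery_center(self) -> tuple[float, float]:
        """(x, y) of the artery axis; x centred, y below the top surface."""
        r = self.artery_diameter / 2.0
        return self.width / 2.0, self.height - self.artery_depth - r

    @property
    def artery_area(self) -> float:
        return math.pi * self.artery_diameter ** 2 / 4.0

    def margin(self, stage: str) -> float:
        """Total ring thickness (skin + fat) outside the muscle region."""
        _check_stage(stage)
        skin = self.skin_thickness if stage in ("model2", "model3") else 0.0
        return skin + self.fat_thickness

    def _inner_rect_area(self, margin: float) -> float:
        w = self.width - 2 * margin
        h = self.height - 2 * margin
        if w <= 0 or h <= 0:
            raise ConfigurationError("layer thicknesses exceed the cross-section")
        return w * h

    @property
    def stage1_muscle_area(self) -> float:
        """Muscle area of model1 with the basal artery; sizes the bone block."""
        return self._inner_rect_area(self.fat_thickness) - self.artery_area

    @property
    def bone_area(self) -> float:
        return self.bone_muscle_fraction * self.stage1_muscle_area

    def bone_rect(self) -> tuple[float, float, float, float]:
        """(x0, x1, y0, y1) of the bone block, centred in x."""
        h = self.bone_height
        w = self.bone_area / h
        x0 = (self.width - w) / 2.0
        y0 = self.bone_bottom
        rect = (x0, x0 + w, y0, y0 + h)
        m = self.margin("model3")
        if x0 < m or y0 < m or rect[1] > self.width - m or rect[3] > self.height - m:
            raise ConfigurationError("bone block does not fit inside the muscle region")
        return rect

    @property
    def cortical_thickness(self) -> float:
        """Shell thickness giving the configured cortical area share."""
        x0, x1, y0, y1 = self.bone_rect()
        w, h = x1 - x0, y1 - y0
        target = self.cortical_share * self.bone_area
        # 2t(w+h) - 4t^2 = target  ->  smaller quadratic root
        p = w + h
        disc = p * p - 4.0 * target
        if disc < 0:
            raise ConfigurationError("cortical share too large for the bone block")
        return (p - math.sqrt(disc)) / 4.0

    # ------------------------------------------------------------------
    # Point classification
    # ------------------------------------------------------------------
    def classify(self, x, y, stage: str, artery_diameter: float | None = None):
        """Vectorised tissue classification of cross-section points.

        Returns an integer array indexing into :data:`TISSUES`.
        """
        _check_stage(stage)
        d = self.artery_diameter if artery_diameter is None else artery_diameter
        x, y = np.broadcast_arrays(np.asarray(x, dtype=float),
                                   np.asarray(y, dtype=float))
        out = np.full(x.shape, TISSUES.index("muscle"), dtype=np.int8)

        edge = np.minimum.reduce([x, self.width - x, y, self.height - y])
        if stage in ("model2", "model3"):
            skin = edge < self.skin_thickness
            fat = (~skin) & (edge < self.skin_thickness + self.fat_thickness)
            out[skin] = TISSUES.index("skin")
            out[fat] = TISSUES.index("fat")
        else:
            out[edge < self.fat_thickness] = TISSUES.index("fat")

        if stage == "model3":
            x0, x1, y0, y1 = self.bone_rect()
            t = self.cortical_thickness
            in_bone = (x >= x0) & (x <= x1) & (y >= y0) & (y <= y1)
            depth = np.minimum.reduce([x - x0, x1 - x, y - y0, y1 - y])
            out[in_bone] = TISSUES.index("cortical")
            out[in_bone & (depth >= t)] = TISSUES.index("cancellous")

        cx, cy0 = self.artery_center
        # keep the cover depth fixed when the diameter varies
        cy = self.height - self.artery_depth - d / 2.0 if artery_diameter else cy0
        out[(x - cx) ** 2 + (y - cy) ** 2 <= (d / 2.0) ** 2] = TISSUES.index("blood")
        return out

    def section_areas(self, stage: str, artery_diameter: float | None = None,
                      resolution: float = 1e-4) -> dict[str, float]:
        """Per-tissue areas (m^2) by fine midpoint quadrature of the layout."""
        nx = int(round(self.width / resolution))
        ny = int(round(self.height / resolution))
        xs = (np.arange(nx) + 0.5) * self.width / nx
        ys = (np.arange(ny) + 0.5) * self.height / ny
        labels = self.classify(xs[:, None], ys[None, :], stage, artery_diameter)
        cell = (self.width / nx) * (self.height / ny)
        counts = np.bincount(labels.ravel(), minlength=len(TISSUES))
        return {t: counts[i] * cell for i, t in enumerate(TISSUES) if counts[i] > 0}

    def with_artery_diameter(self, d: float) -> "WristGeometry":
        return replace(self, artery_diameter=d)


def _check_stage(stage: str) -> None:
    if stage not in STAGES:
        raise ConfigurationError(f"unknown stage {stage!r}; expected one of {STAGES}")
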