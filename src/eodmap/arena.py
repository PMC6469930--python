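"""Arena geometry: circular tank, landmark polygons, home structure.

All geometry lives in centimetres in a tank-centred frame (x to the right,
y up when the arena is plotted).  The video camera looks straight down, so
world coordinates map linearly onto video pixels via ``pixel_scale``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry import Polygon

from .errors import ValidationError

__all__ = ["ArenaLayout", "default_arena"]


@dataclass
class ArenaLayout:
    """Circular tank with named landmark polygons.

    Parameters
    ----------
    tank_center : (float, float)
        Tank centre in cm.
    tank_radius : float
        Tank radius in cm (1.5 m tank -> 75).
    landmarks : dict[str, Polygon]
        Non-enterable landmark polygons, cm coordinates, unique names.
    home : Polygon, optional
        The enterable home structure.  It counts as a landmark for
        rasterisation and attraction, but the fish may swim inside it.
    pixel_scale : float
        cm per video pixel.  The default maps the 1200-px image height
        onto the 150 cm tank diameter.
    video_size : (int, int)
        (width_px, height_px) of the overhead video.
    """

    tank_center: tuple[float, float] = (0.0, 0.0)
    tank_radius: float = 75.0
    landmarks: dict[str, Polygon] = field(default_factory=dict)
    home: Polygon | None = None
    pixel_scale: float = 0.125
    video_size: tuple[int, int] = (1600, 1200)

    def __post_init__(self) -> None:
        if self.pixel_scale <= 0:
            raise ValidationError("pixel_scale must be positive")
        if self.tank_radius <= 0:
            raise ValidationError("tank_radius must be positive")
        cx, cy = self.tank_center
        for name, poly in self.all_polygons().items():
            xs, ys = np.asarray(poly.exterior.coords).T
            if np.any(np.hypot(xs - cx, ys - cy) > self.tank_radius + 1e-9):
                raise ValidationError(f"landmark {name!r} extends outside the tank")

    # -- geometry helpers -------------------------------------------------

    def all_polygons(self) -> dict[str, Polygon]:
        """Landmarks plus home (home under the key ``'home'``)."""
        polys = dict(self.landmarks)
        if self.home is not None:
            polys["home"] = self.home
        return polys

    def blocked_polygons(self) -> dict[str, Polygon]:
        """Polygons the fish cannot enter (everything except home)."""
        return dict(self.landmarks)

    def tank_polygon(self) -> Polygon:
        return shapely.Point(self.tank_center).buffer(self.tank_radius, quad_segs=90)

    def contains(self, x, y) -> np.ndarray:
        """Vectorised test: inside the tank circle."""
        cx, cy = self.tank_center
        return np.hypot(np.asarray(x) - cx, np.asarray(y) - cy) <= self.tank_radius

    def distance_to_landmarks(self, x, y) -> np.ndarray:
        """Distance (cm) from points to the nearest landmark polygon (incl. home).

        Zero inside a polygon.  Returns +inf if the arena has no landmarks.
        """
        polys = list(self.all_polygons().values())
        x = np.asarray(x, dtype=float)
        if not polys:
            return np.full(np.shape(x), np.inf)
        union = shapely.union_all(polys)
        pts = shapely.points(x, np.asarray(y, dtype=float))
        return shapely.distance(pts, union)

    def distance_to_wall(self, x, y) -> np.ndarray:
        """Distance (cm) from interior points to the tank wall."""
        cx, cy = self.tank_center
        r = np.hypot(np.asarray(x) - cx, np.asarray(y) - cy)
        return self.tank_radius - r

    # -- (de)serialisation ------------------------------------------------

    def to_dict(self) -> dict:
        def coords(p: Polygon) -> list[list[float]]:
            return [[float(a), float(b)] for a, b in p.exterior.coords[:-1]]

        return {
            "tank_center": list(self.tank_center),
            "tank_radius": self.tank_radius,
            "landmarks": {k: coords(v) for k, v in self.landmarks.items()},
            "home": coords(self.home) if self.home is not None else None,
            "pixel_scale": self.pixel_scale,
            "video_size": list(self.video_size),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ArenaLayout":
        return cls(
            tank_center=tuple(d["tank_center"]),
            tank_radius=float(d["tank_radius"]),
            landmarks={k: Polygon(v) for k, v in d["landmarks"].items()},
            home=Polygon(d["home"]) if d.get("home") else None,
            pixel_scale=float(d["pixel_scale"]),
            video_size=tuple(d["video_size"]),
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "ArenaLayout":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def default_arena() -> ArenaLayout:
    """A representative layout: 1.5 m circular tank, home box near the wall,
    three acrylic landmarks (trapezoid, bar, triangle) secured to the floor."""
    home = Polygon([(-62, -12), (-40, -12), (-40, 12), (-62, 12)])
    landmarks = {
        "trapezoid": Polygon([(22, 30), (42, 30), (38, 44), (26, 44)]),
        "bar": Polygon([(-12, -48), (18, -48), (18, -40), (-12, -40)]),
        "triangle": Polygon([(38, -22), (52, -28), (46, -10)]),
    }
    return ArenaLayout(landmarks=landmarks, home=home)
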