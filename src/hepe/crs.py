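"""Local projected coordinates and their geographic reporting counterpart.

All analysis runs in a projected CRS with meter units. Geographic
longitude/latitude only ever appear at the reporting boundary (station
input files, ellipse-center tables), so a local equirectangular projection
anchored at a reference point is sufficient: over a city-scale domain
(~10 km) its distortion is far below the cell size of any analysis grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

EARTH_RADIUS_M = 6_371_000.0

#: substrings in a CRS label that indicate degree units (not usable for analysis)
_GEOGRAPHIC_HINTS = ("4326", "longlat", "latlon", "degree", "geographic", "wgs 84", "wgs84")


class GeographicCRSError(ValueError):
    """Raised when a raster or grid declares a degree-unit CRS.

    The analysis requires projected meters; reproject the input first.
    """


def check_projected(crs_label: str) -> None:
    label = crs_label.lower()
    if any(h in label for h in _GEOGRAPHIC_HINTS):
        raise GeographicCRSError(
            f"CRS {crs_label!r} appears to be geographic (degree units); "
            "reproject inputs to a projected CRS in meters before analysis"
        )


@dataclass(frozen=True)
class LocalProjection:
    """Equirectangular projection about (ref_lon, ref_lat) -> (ref_x, ref_y) m."""

    ref_lon: float
    ref_lat: float
    ref_x: float = 0.0
    ref_y: float = 0.0

    def forward(self, lon, lat):
        """Degrees -> projected meters."""
        kx = EARTH_RADIUS_M * math.cos(math.radians(self.ref_lat)) * math.pi / 180.0
        ky = EARTH_RADIUS_M * math.pi / 180.0
        import numpy as np

        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        return self.ref_x + (lon - self.ref_lon) * kx, self.ref_y + (lat - self.ref_lat) * ky

    def inverse(self, x, y):
        """Projected meters -> degrees."""
        kx = EARTH_RADIUS_M * math.cos(math.radians(self.ref_lat)) * math.pi / 180.0
        ky = EARTH_RADIUS_M * math.pi / 180.0
        import numpy as np

        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return self.ref_lon + (x - self.ref_x) / kx, self.ref_lat + (y - self.ref_y) / ky

    @property
    def crs_label(self) -> str:
        return (
            f"LOCAL_EQUIRECT[m] ref_lon={self.ref_lon:.6f} ref_lat={self.ref_lat:.6f} "
            f"ref_x={self.ref_x:.3f} ref_y={self.ref_y:.3f}"
        )

    @classmethod
    def from_crs_label(cls, label: str) -> "LocalProjection":
        if not label.startswith("LOCAL_EQUIRECT"):
            raise ValueError(f"not a local-equirectangular CRS label: {label!r}")
        kv = dict(tok.split("=") for tok in label.split() if "=" in tok)
        return cls(
            ref_lon=float(kv["ref_lon"]),
            ref_lat=float(kv["ref_lat"]),
            ref_x=float(kv["ref_x"]),
            ref_y=float(kv["ref_y"]),
        )
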