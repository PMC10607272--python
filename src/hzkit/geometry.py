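"""Reduce 2D sample coordinates to signed 1D distances from a hybrid-zone baseline.

The baseline is a polyline approximating the centre of the admixture zone.
Each sample's transect position is its minimum Euclidean distance to the
polyline, signed by which side of the nearest segment it falls on (2D
cross-product test; the declared positive side points toward gene pool B, so
fitted clines increase with distance).  Longitude/latitude inputs are
converted to planar km by a local equirectangular projection about the
baseline's mean latitude (x = R cos(phi0) dlambda, y = R dphi, R = 6371 km),
adequate for transects spanning a few hundred km.

When no baseline is supplied, one can be estimated from ancestry q-values by
fitting a logistic surface logit(q) = a + b*east + c*north and taking its
q = 0.5 straight-line contour.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import EstimationError, GeometryError, ParameterError

EARTH_RADIUS_KM = 6371.0


def lonlat_to_km(lonlat: np.ndarray, lon0: float, lat0: float) -> np.ndarray:
    """Equirectangular projection to planar km about (lon0, lat0)."""
    lonlat = np.asarray(lonlat, dtype=float)
    phi0 = np.deg2rad(lat0)
    x = EARTH_RADIUS_KM * np.cos(phi0) * np.deg2rad(lonlat[..., 0] - lon0)
    y = EARTH_RADIUS_KM * np.deg2rad(lonlat[..., 1] - lat0)
    return np.stack([x, y], axis=-1)


def km_to_lonlat(xy: np.ndarray, lon0: float, lat0: float) -> np.ndarray:
    xy = np.asarray(xy, dtype=float)
    phi0 = np.deg2rad(lat0)
    lon = lon0 + np.rad2deg(xy[..., 0] / (EARTH_RADIUS_KM * np.cos(phi0)))
    lat = lat0 + np.rad2deg(xy[..., 1] / EARTH_RADIUS_KM)
    return np.stack([lon, lat], axis=-1)


@dataclass
class Baseline:
    """Ordered polyline with a declared positive side.

    ``positive_side`` is "left" or "right" of the walking direction along the
    vertex order; it should point toward the gene pool whose ancestry the
    cline approaches at +infinity.  ``crs`` is "km" (planar) or "lonlat".
    """

    vertices: np.ndarray
    positive_side: str = "left"
    crs: str = "km"

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise GeometryError("baseline vertices must be an (m, 2) array")
        if self.vertices.shape[0] < 2:
            raise GeometryError("baseline needs at least 2 vertices")
        seg = np.diff(self.vertices, axis=0)
        if np.any(np.hypot(seg[:, 0], seg[:, 1]) == 0.0):
            raise GeometryError("consecutive baseline vertices must be distinct")
        if self.positive_side not in ("left", "right"):
            raise GeometryError("positive_side must be 'left' or 'right'")
        if self.crs not in ("km", "lonlat"):
            raise GeometryError("crs must be 'km' or 'lonlat'")

    @property
    def mean_latitude(self) -> float:
        if self.crs != "lonlat":
            raise GeometryError("mean_latitude only defined for lonlat baselines")
        return float(self.vertices[:, 1].mean())

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(self.vertices, columns=["x", "y"] if self.crs == "km"
                          else ["lon", "lat"])
        with open(path, "w") as fh:
            fh.write(f"# positive_side={self.positive_side} crs={self.crs}\n")
            df.to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "Baseline":
        side, crs = "left", "km"
        with open(path) as fh:
            first = fh.readline()
        skip = 0
        if first.startswith("#"):
            skip = 1
            for tok in first[1:].split():
                if tok.startswith("positive_side="):
                    side = tok.split("=", 1)[1]
                elif tok.startswith("crs="):
                    crs = tok.split("=", 1)[1]
        df = pd.read_csv(path, sep="\t", skiprows=skip)
        return cls(df.to_numpy(dtype=float), positive_side=side, crs=crs)


def _signed_distance_planar(points: np.ndarray, vertices: np.ndarray,
                            positive_side: str) -> np.ndarray:
    """Signed minimum distance from each point to the polyline (planar)."""
    P = np.atleast_2d(points).astype(float)
    V = vertices
    A = V[:-1]                       # (m, 2)
    D = V[1:] - A                    # segment vectors
    L2 = (D * D).sum(axis=1)         # squared lengths

    # per-point, per-segment projection parameter t in [0, 1]
    diff = P[:, None, :] - A[None, :, :]            # (n, m, 2)
    t = np.clip((diff * D[None]).sum(-1) / L2[None], 0.0, 1.0)
    closest = A[None] + t[..., None] * D[None]      # (n, m, 2)
    dvec = P[:, None, :] - closest
    dist = np.hypot(dvec[..., 0], dvec[..., 1])     # (n, m)

    out = np.empty(P.shape[0])
    sign_flip = -1.0 if positive_side == "right" else 1.0
    for i in range(P.shape[0]):
        di = dist[i]
        best = di.min()
        near = np.nonzero(di <= best + 1e-12)[0]
        j = near[0]
        if len(near) > 1 and best > 0:
            # tie at a shared vertex: sign from the angle-bisector normal of
            # the adjacent segments
            j1, j2 = near[0], near[-1]
            d1 = D[j1] / np.hypot(*D[j1])
            d2 = D[j2] / np.hypot(*D[j2])
            bis = d1 + d2
            if np.hypot(*bis) < 1e-12:  # straight-through: either works
                bis = d1
            vtx = closest[i, j1]
            off = P[i] - vtx
            cross = bis[0] * off[1] - bis[1] * off[0]
        else:
            off = P[i] - A[j]
            cross = D[j, 0] * off[1] - D[j, 1] * off[0]
        s = 1.0 if cross > 0 else (-1.0 if cross < 0 else 0.0)
        out[i] = sign_flip * s * best
    return out


def project_to_transect(coords, baseline: Baseline, coords_crs: str | None = None) -> np.ndarray:
    """Signed km distances of sample coordinates from the baseline.

    ``coords`` is an (n, 2) array in the same coordinate system as the
    baseline (``coords_crs`` overrides; lon/lat is auto-projected to planar
    km about the baseline's mean latitude).
    """
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    crs = coords_crs or baseline.crs
    if crs != baseline.crs:
        raise GeometryError("coordinates and baseline must share a coordinate system")
    if baseline.crs == "lonlat":
        lon0 = float(baseline.vertices[:, 0].mean())
        lat0 = baseline.mean_latitude
        P = lonlat_to_km(coords, lon0, lat0)
        V = lonlat_to_km(baseline.vertices, lon0, lat0)
    else:
        P, V = coords, baseline.vertices
    return _signed_distance_planar(P, V, baseline.positive_side)


def estimate_baseline(coords, q_values, crs: str = "km") -> Baseline:
    """Estimate the zone centre line from ancestry q-values.

    Fits logit(q) = a + b*east + c*north by maximum likelihood (binomial
    working likelihood, so fractional q in [0, 1] is fine) and returns the
    q = 0.5 contour as a two-vertex baseline clipped to the sample bounding
    box, positive side toward increasing q.
    """
    import statsmodels.api as sm

    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    q = np.asarray(q_values, dtype=float)
    if coords.shape[0] != q.size:
        raise ParameterError("coords and q_values length mismatch")
    if coords.shape[0] < 10 or not ((q < 0.25).any() and (q > 0.75).any()):
        raise EstimationError(
            "need >= 10 samples spanning q < 0.25 and q > 0.75")
    if crs == "lonlat":
        lon0 = float(coords[:, 0].mean())
        lat0 = float(coords[:, 1].mean())
        xy = lonlat_to_km(coords, lon0, lat0)
    else:
        xy = coords

    X = sm.add_constant(xy)
    qc = np.clip(q, 1e-6, 1.0 - 1e-6)
    try:
        fit = sm.GLM(qc, X, family=sm.families.Binomial()).fit()
    except Exception as e:  # perfect separation etc.
        raise EstimationError(f"logistic surface fit failed: {e}") from e
    a, b, c = fit.params
    if abs(b) < 1e-8 and abs(c) < 1e-8:
        raise EstimationError("no ancestry gradient: baseline non-identifiable")

    # q = 0.5 contour: a + b x + c y = 0
    grad = np.array([b, c])
    norm2 = float(grad @ grad)
    p0 = -a * grad / norm2                # closest contour point to the origin
    direction = np.array([-c, b]) / np.sqrt(norm2)

    # clip the line p0 + t*direction to the sample bounding box (Liang-Barsky)
    lo = xy.min(axis=0)
    hi = xy.max(axis=0)
    t_min, t_max = -np.inf, np.inf
    for dim in range(2):
        if abs(direction[dim]) < 1e-15:
            continue
        t1 = (lo[dim] - p0[dim]) / direction[dim]
        t2 = (hi[dim] - p0[dim]) / direction[dim]
        t_min = max(t_min, min(t1, t2))
        t_max = min(t_max, max(t1, t2))
    if not np.isfinite(t_min) or not np.isfinite(t_max) or t_min >= t_max:
        # contour misses the box; span the box diagonal length around p0
        half = float(np.hypot(*(hi - lo)))
        t_min, t_max = -half, half
    v1 = p0 + t_min * direction
    v2 = p0 + t_max * direction

    # walking v1 -> v2, the gradient (toward increasing q) points to the right:
    # cross(direction, grad) = -|grad|^2 < 0
    verts = np.array([v1, v2])
    if crs == "lonlat":
        verts = km_to_lonlat(verts, lon0, lat0)
    return Baseline(verts, positive_side="right", crs=crs)
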