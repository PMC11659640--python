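"""Palatal reference planes and the seven dimensional traits of one cast.

Given a triangle mesh of a maxillary cast and its named landmarks, this module
derives the reference planes and measurements used throughout the package:

* the **gingival plane** — the total-least-squares (SVD) plane through the
  palatal dento-gingival junction midpoints of all teeth;
* the **mid-palatal plane** — orthogonal to the gingival plane, containing the
  least-squares line through the three raphe landmarks projected onto it;
* the **posterior plane** — transverse (orthogonal to both), through the
  midpoint of the most-distal palatal points of the terminal teeth;
* the seven traits: anterior/posterior width, anterior/posterior depth,
  antero-posterior length, and the surface area and enclosed volume of the
  palate clipped by the gingival and posterior planes.

Missing landmarks are imputed before measurement by mirroring the
configuration across the current mid-sagittal estimate, relabelling left/right
antimeres, rigidly superimposing (Procrustes, no scaling) the mirrored copy
onto the original over shared landmarks, and reading the missing coordinate
off the superimposed copy.

All geometry is derived from landmarks, never from the coordinate axes the
cast happened to be scanned in: every measurement is invariant under rigid
motion of mesh and landmarks together.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import NamedTuple

import numpy as np
import trimesh

from .io_formats import (
    LandmarkSet,
    RAPHE_NAMES,
    STAGE_TEETH,
    TERMINAL_TEETH,
    WIDTH_TEETH,
    antimere_map,
)

logger = logging.getLogger(__name__)

#: on-plane classification tolerance for clipping (mm)
CLIP_TOL = 1e-7
#: half-width of the sagittal band used to collect vault candidates (mm)
DEPTH_BAND = 0.5


class GeometryError(ValueError):
    """Degenerate geometry: collinear points, empty clips, missing landmarks."""


@dataclass(frozen=True)
class Plane:
    """Oriented plane: a point p lies on it iff normal . p == offset.

    ``oriented`` planes carry an interior tag; by convention the interior
    (palatal) half-space is the *negative* side, signed_distance < 0.
    """

    normal: np.ndarray
    offset: float
    oriented: bool = False

    def __post_init__(self) -> None:
        n = np.asarray(self.normal, dtype=float)
        norm = np.linalg.norm(n)
        if not np.isfinite(norm) or abs(norm - 1.0) > 1e-9:
            raise GeometryError("plane normal must be a unit vector")
        object.__setattr__(self, "normal", n)
        object.__setattr__(self, "offset", float(self.offset))

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, float) @ self.normal - self.offset

    def project(self, points: np.ndarray) -> np.ndarray:
        """Orthogonal projection of points onto the plane."""
        pts = np.atleast_2d(np.asarray(points, float))
        out = pts - np.outer(self.signed_distance(pts), self.normal)
        return out[0] if np.asarray(points).ndim == 1 else out

    def oriented_toward(self, interior_point: np.ndarray) -> "Plane":
        """Flip if needed so that ``interior_point`` is on the negative side."""
        s = float(self.signed_distance(np.asarray(interior_point, float)))
        if s > 0:
            return Plane(-self.normal, -self.offset, oriented=True)
        return replace(self, oriented=True)


class PalatalTraits(NamedTuple):
    """The seven palatal measurements of one cast (mm, mm^2, mm^3)."""

    anterior_width: float
    posterior_width: float
    anterior_depth: float
    posterior_depth: float
    ap_length: float
    area: float
    volume: float


# ---------------------------------------------------------------------------
# plane fitting


def fit_plane_svd(points: np.ndarray) -> Plane:
    """Total-least-squares plane through >= 3 points.

    The plane passes through the centroid; its normal is the direction of
    least variance (smallest right singular vector of the centered cloud).
    Sign convention: the normal component of largest magnitude is positive,
    which makes the result deterministic without any anatomical axis.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 3:
        raise GeometryError("plane fit needs an (n>=3, 3) point array")
    centroid = pts.mean(axis=0)
    _, s, vt = np.linalg.svd(pts - centroid, full_matrices=False)
    # collinear cloud: no unique least-variance direction
    if s[1] <= 1e-9 * max(s[0], 1.0):
        raise GeometryError("points are collinear; plane is not unique")
    n = vt[2]
    k = int(np.argmax(np.abs(n)))
    if n[k] < 0:
        n = -n
    return Plane(n / np.linalg.norm(n), float(n @ centroid))


# ---------------------------------------------------------------------------
# landmark completion (mirror + rigid Procrustes)


def _rigid_superimpose(source: np.ndarray, target: np.ndarray):
    """Least-squares rotation R and translation t with R@s + t ~ target.

    Kabsch algorithm: proper rotation (det +1), no scaling.
    """
    src = np.asarray(source, float)
    tgt = np.asarray(target, float)
    sc, tc = src.mean(axis=0), tgt.mean(axis=0)
    H = (src - sc).T @ (tgt - tc)
    U, _, Vt = np.linalg.svd(H)
    D = np.diag([1.0, 1.0, np.sign(np.linalg.det(Vt.T @ U.T))])
    R = Vt.T @ D @ U.T
    return R, tc - R @ sc


def _midsagittal_estimate(lm: LandmarkSet) -> Plane:
    """Mid-sagittal plane estimated from the currently available landmarks."""
    dg = [n for n in lm.points if n.startswith("dg_")]
    if len(dg) < 3:
        raise GeometryError("need at least three dento-gingival landmarks")
    ging = fit_plane_svd(lm.coords(dg))
    return midpalatal_plane(lm, ging)


def complete_landmarks(
    lm: LandmarkSet, antimeres: dict[str, str] | None = None
) -> LandmarkSet:
    """Impute missing landmarks by bilateral mirroring.

    The full configuration is reflected across the current mid-sagittal
    estimate, landmark names are swapped via the antimere map, the reflected
    copy is rigidly superimposed onto the original over shared landmarks, and
    each missing landmark takes its coordinate from the superimposed copy.
    Imputed names are flagged on the returned set.

    At most one member of each antimere pair may be missing; midline (raphe)
    landmarks cannot be imputed this way and must be present.
    """
    if antimeres is None:
        antimeres = antimere_map(lm.stage)
    missing = lm.missing
    if not missing:
        return lm
    for name in RAPHE_NAMES:
        if name in missing:
            raise GeometryError(f"midline landmark {name!r} cannot be imputed")
    pairs_gone = sorted(
        {tuple(sorted((m, antimeres[m]))) for m in missing if antimeres[m] in missing}
    )
    if pairs_gone:
        raise GeometryError(
            f"both antimeres missing, cannot impute: {pairs_gone}"
        )

    mid = _midsagittal_estimate(lm)
    names = sorted(lm.points)
    pts = lm.coords(names)
    reflected = pts - 2.0 * np.outer(mid.signed_distance(pts), mid.normal)
    relabelled = {antimeres[n]: p for n, p in zip(names, reflected)}

    shared = sorted(set(relabelled) & set(lm.points))
    if len(shared) < 3:
        raise GeometryError("too few shared landmarks for superimposition")
    R, t = _rigid_superimpose(
        np.array([relabelled[n] for n in shared]), lm.coords(shared)
    )
    new_points = dict(lm.points)
    for name in missing:
        new_points[name] = R @ relabelled[name] + t
    return replace(
        lm, points=new_points, imputed=lm.imputed | frozenset(missing)
    )


# ---------------------------------------------------------------------------
# reference planes


def gingival_plane(lm: LandmarkSet) -> Plane:
    """SVD plane through all dento-gingival landmarks, vault side interior."""
    dg = [n for n in lm.points if n.startswith("dg_")]
    plane = fit_plane_svd(lm.coords(dg))
    return plane.oriented_toward(lm["raphe_middle"])


def midpalatal_plane(lm: LandmarkSet, gingival: Plane) -> Plane:
    """Plane through the projected raphe line, orthogonal to the gingival plane."""
    raphe = lm.coords(RAPHE_NAMES)
    proj = gingival.project(raphe)
    centroid = proj.mean(axis=0)
    _, s, vt = np.linalg.svd(proj - centroid, full_matrices=False)
    if s[0] <= 1e-9:
        raise GeometryError("raphe landmarks are coincident")
    line_dir = vt[0]
    n = np.cross(gingival.normal, line_dir)
    norm = np.linalg.norm(n)
    if norm <= 1e-12:
        raise GeometryError("raphe line is parallel to the gingival normal")
    n = n / norm
    k = int(np.argmax(np.abs(n)))
    if n[k] < 0:
        n = -n
    return Plane(n, float(n @ centroid))


def transverse_plane(
    point: np.ndarray, gingival: Plane, midpalatal: Plane
) -> Plane:
    """Plane through ``point`` orthogonal to both reference planes."""
    n = np.cross(gingival.normal, midpalatal.normal)
    n = n / np.linalg.norm(n)
    k = int(np.argmax(np.abs(n)))
    if n[k] < 0:
        n = -n
    return Plane(n, float(n @ np.asarray(point, float)))


def posterior_plane(
    lm: LandmarkSet, gingival: Plane, midpalatal: Plane
) -> Plane:
    """Transverse plane through the midpoint of the two distal landmarks.

    The anterior side (containing the incisive papilla) is the interior.
    """
    distal = [f"distal_{t}" for t in TERMINAL_TEETH[lm.stage]]
    for name in distal:
        if name not in lm:
            raise GeometryError(f"distal landmark {name!r} missing")
    mid = lm.coords(distal).mean(axis=0)
    return transverse_plane(mid, gingival, midpalatal).oriented_toward(
        lm["raphe_anterior"]
    )


# ---------------------------------------------------------------------------
# linear measurements


def _width_pair(lm: LandmarkSet, tooth_pair: tuple[str, str]) -> np.ndarray:
    names = [f"dg_{t}" for t in tooth_pair]
    for n in names:
        if n not in lm:
            raise GeometryError(f"required landmark {n!r} missing (after completion)")
    return lm.coords(names)


def measure_widths(lm: LandmarkSet) -> tuple[float, float]:
    """Anterior (inter-canine) and posterior (inter-molar) widths in mm."""
    teeth = WIDTH_TEETH[lm.stage]
    a = _width_pair(lm, teeth["canine"])
    p = _width_pair(lm, teeth["molar"])
    return (
        float(np.linalg.norm(a[0] - a[1])),
        float(np.linalg.norm(p[0] - p[1])),
    )


def _line_depth(
    line_pts: np.ndarray,
    vault_points: np.ndarray,
    gingival: Plane,
    midpalatal: Plane,
    band: float,
) -> float:
    """Distance from the reference line to the deepest raphe-band vault point.

    Candidates are mesh vertices within ``band`` of the mid-palatal plane and
    within ``band`` of the transverse plane containing the line, on the vault
    (interior) side of the gingival plane.  The deepest point maximises the
    drop below the line measured along the gingival normal (for the deepest
    point of a vault this equals its perpendicular distance to the line, and
    a flat palate correctly yields zero).
    """
    a, b = line_pts
    mid = 0.5 * (a + b)
    tplane = transverse_plane(mid, gingival, midpalatal)
    v = np.asarray(vault_points, float)
    sel = (
        (np.abs(midpalatal.signed_distance(v)) <= band)
        & (np.abs(tplane.signed_distance(v)) <= band)
        & (gingival.signed_distance(v) <= CLIP_TOL)
    )
    cand = v[sel]
    if len(cand) == 0:
        raise GeometryError(
            f"no vault vertices within +/-{band} mm of the reference line; "
            "increase the band width"
        )
    drop = (mid - cand) @ gingival.normal
    return float(max(drop.max(), 0.0))


def measure_depths(
    lm: LandmarkSet,
    vault_points: np.ndarray,
    gingival: Plane | None = None,
    midpalatal: Plane | None = None,
    band: float = DEPTH_BAND,
) -> tuple[float, float]:
    """Anterior and posterior palatal depths in mm.

    Depth is the perpendicular distance from the line joining the canine
    (respectively molar) dento-gingival midpoints to the deepest point of the
    palatal vault on the mid-palatal raphe, taken over mesh vertices in the
    raphe band of that line.
    """
    if gingival is None:
        gingival = gingival_plane(lm)
    if midpalatal is None:
        midpalatal = midpalatal_plane(lm, gingival)
    teeth = WIDTH_TEETH[lm.stage]
    ant = _line_depth(
        _width_pair(lm, teeth["canine"]), vault_points, gingival, midpalatal, band
    )
    post = _line_depth(
        _width_pair(lm, teeth["molar"]), vault_points, gingival, midpalatal, band
    )
    return ant, post


def measure_ap_length(lm: LandmarkSet, posterior: Plane) -> float:
    """Perpendicular distance from the incisive papilla to the posterior plane."""
    if "raphe_anterior" not in lm:
        raise GeometryError("raphe_anterior (incisive papilla) missing")
    return float(abs(posterior.signed_distance(lm["raphe_anterior"])))


# ---------------------------------------------------------------------------
# clipping, area, volume


def _slice(mesh: trimesh.Trimesh, plane: Plane, cap: bool) -> trimesh.Trimesh:
    # trimesh keeps the side the normal points toward; interior is negative
    return trimesh.intersections.slice_mesh_plane(
        mesh,
        plane_normal=-plane.normal,
        plane_origin=plane.normal * plane.offset,
        cap=cap,
    )

def clip_palate(
    mesh: trimesh.Trimesh, gingival: Plane, posterior: Plane
) -> trimesh.Trimesh:
    """Vault surface restricted to the interior of both clipping planes.

    Triangles straddling a plane are split at the intersection; the result is
    an open surface whose boundary loops lie on the clipping planes.  Cap
    polygons are *not* added here (see :func:`palatal_volume`).
    """
    if not (gingival.oriented and posterior.oriented):
        raise GeometryError("clipping planes must carry interior orientation")
    out = _slice(mesh, gingival, cap=False)
    if out is None or len(out.faces) == 0:
        raise GeometryError("mesh lies entirely outside the gingival interior")
    out = _slice(out, posterior, cap=False)
    if out is None or len(out.faces) == 0:
        raise GeometryError("mesh lies entirely outside the posterior interior")
    return out


def palatal_area(clipped: trimesh.Trimesh) -> float:
    """Surface area (mm^2) of the clipped vault surface, caps excluded."""
    if len(clipped.faces) == 0:
        raise GeometryError("clipped mesh is empty")
    return float(clipped.area)


def palatal_volume(
    clipped: trimesh.Trimesh, gingival: Plane, posterior: Plane
) -> float:
    """Volume (mm^3) enclosed by the vault surface and the two clipping planes.

    The open boundary of the clipped surface must lie on the clipping planes
    (that is what makes the region closable with planar caps).  The signed
    volume follows from the divergence theorem with the reference origin
    placed on the intersection line of the two planes: both planar caps then
    contribute zero flux, so only the vault triangles need summing and the
    caps never have to be triangulated explicitly.  Returned as an absolute
    value.
    """
    if len(clipped.faces) == 0:
        raise GeometryError("clipped mesh is empty")
    clipped = clipped.copy()
    clipped.merge_vertices()  # the slicer duplicates vertices along cuts
    verts = np.asarray(clipped.vertices, float)

    boundary = _boundary_edges(clipped)
    if len(boundary):
        dg = np.abs(gingival.signed_distance(verts[boundary.ravel()]))
        dp = np.abs(posterior.signed_distance(verts[boundary.ravel()]))
        if np.any(np.minimum(dg, dp) > 1e-6):
            raise GeometryError(
                "open boundary edges off the clipping planes; cannot close"
            )

    # minimum-norm point on the intersection line of the two planes
    A = np.vstack([gingival.normal, posterior.normal])
    b = np.array([gingival.offset, posterior.offset])
    origin = np.linalg.lstsq(A, b, rcond=None)[0]

    tri = verts[np.asarray(clipped.faces, int)] - origin
    signed = np.einsum(
        "ij,ij->i", tri[:, 0], np.cross(tri[:, 1], tri[:, 2])
    ).sum() / 6.0
    return float(abs(signed))


def _boundary_edges(mesh: trimesh.Trimesh) -> np.ndarray:
    """Directed edges of the open boundary (each appears in one face only)."""
    edges = mesh.edges
    order = np.sort(edges, axis=1)
    unique_idx = trimesh.grouping.group_rows(order, require_count=1)
    return edges[unique_idx]


# ---------------------------------------------------------------------------
# full pipeline for one cast


def measure_cast(
    mesh: trimesh.Trimesh,
    lm: LandmarkSet,
    band: float = DEPTH_BAND,
) -> PalatalTraits:
    """Derive planes and compute all seven palatal traits for one cast."""
    lm = complete_landmarks(lm)
    ging = gingival_plane(lm)
    mid = midpalatal_plane(lm, ging)
    post = posterior_plane(lm, ging, mid)
    aw, pw = measure_widths(lm)
    ad, pd_ = measure_depths(lm, mesh.vertices, ging, mid, band=band)
    ap = measure_ap_length(lm, post)
    clipped = clip_palate(mesh, ging, post)
    area = palatal_area(clipped)
    volume = palatal_volume(clipped, ging, post)
    return PalatalTraits(aw, pw, ad, pd_, ap, area, volume)
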