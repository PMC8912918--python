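"""Local membrane features at arbitrary membrane-plane query points.

Six physical features (area per lipid, thickness, mean curvature, headgroup
dipole cosine, headgroup charge, tail order parameter) and 15 lipid-group
densities are evaluated per leaflet at lipid headgroup vertices and read out
at query points through a truncated Gaussian smoothing kernel

    V_smooth(x_p, y_p) = sum_i V_i w_i / sum_i w_i,
    w_i = exp(-(x_i-x_p)^2 / (2 r^2) - (y_i-y_p)^2 / (2 r^2)),

with only vertices within 3 r_smooth (minimum-image periodic distance)
contributing. Surface geometry uses local-PCA plane fits for normals,
periodic 2D Voronoi tessellation for per-lipid area, and local quadratic
(Monge-patch) fits for mean curvature — a lightweight estimator suite for
near-planar bilayers rather than a full surface-parameterization pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import Voronoi, cKDTree

from .frame import MembraneFrame, Trajectory, min_image_dxy
from .groups import DENSITY_GROUPS, in_group

PHYSICAL_FEATURES = ["APL", "thickness", "curvature", "cos_dip", "charge", "order"]
ALL_FEATURES = PHYSICAL_FEATURES + DENSITY_GROUPS


# ---------------------------------------------------------------------------
# smoothing kernel

def smooth_at(vertices: np.ndarray, values: np.ndarray, queries: np.ndarray,
              r_smooth: float = 1.5, box: np.ndarray | None = None) -> np.ndarray:
    """Gaussian-kernel weighted average of vertex values at query points.

    ``vertices`` are (n, 2) lateral positions, ``values`` (n,) with NaN
    marking vertices excluded from a feature (e.g. dipole of a charged
    lipid). Returns one value per query; NaN where no finite-valued vertex
    lies within 3 * r_smooth.
    """
    vertices = np.asarray(vertices, dtype=float)[:, :2]
    values = np.asarray(values, dtype=float)
    queries = np.atleast_2d(np.asarray(queries, dtype=float))[:, :2]
    cutoff = 3.0 * r_smooth
    if box is not None:
        L = np.asarray(box, dtype=float)[:2]
        tree = cKDTree(np.mod(vertices, L), boxsize=L)
        qpts = np.mod(queries, L)
    else:
        tree = cKDTree(vertices)
        qpts = queries
    out = np.full(len(queries), np.nan)
    neighbor_lists = tree.query_ball_point(qpts, cutoff)
    for qi, idx in enumerate(neighbor_lists):
        if not idx:
            continue
        idx = np.asarray(idx)
        v = values[idx]
        ok = np.isfinite(v)
        if not ok.any():
            continue
        idx, v = idx[ok], v[ok]
        if box is not None:
            d = min_image_dxy(vertices[idx], queries[qi], np.asarray(box))
        else:
            d = vertices[idx] - queries[qi]
        w = np.exp(-(d[:, 0] ** 2 + d[:, 1] ** 2) / (2.0 * r_smooth ** 2))
        out[qi] = (v * w).sum() / w.sum()
    return out


# ---------------------------------------------------------------------------
# leaflet assignment and surface geometry

def assign_leaflets(frame: MembraneFrame, smoothing: float = 3.0) -> np.ndarray:
    """Label lipids inner/outer from headgroup height relative to the local
    midplane (Gaussian-smoothed mean headgroup height over both leaflets)."""
    z = frame.head_pos[:, 2]
    local_mid = smooth_at(frame.head_pos[:, :2], z, frame.head_pos[:, :2],
                          r_smooth=smoothing, box=frame.box)
    labels = np.where(z > local_mid, "outer", "inner").astype(object)
    if (labels == "outer").all() or (labels == "inner").all():
        raise ValueError("degenerate single-leaflet assignment")
    return labels


def _periodic_neighbors(xy: np.ndarray, box: np.ndarray, radius: float,
                        k_min: int = 7):
    L = np.asarray(box, dtype=float)[:2]
    pts = np.mod(xy, L)
    tree = cKDTree(pts, boxsize=L)
    lists = tree.query_ball_point(pts, radius)
    need = [i for i, idx in enumerate(lists) if len(idx) < k_min]
    if need:
        _, knn = tree.query(pts[need], k=k_min)
        for row, i in enumerate(need):
            lists[i] = list(np.atleast_1d(knn[row]))
    return lists


def _voronoi_areas(xy: np.ndarray, box: np.ndarray, margin: float = 5.0) -> np.ndarray:
    """Per-point cell areas of the periodic 2D Voronoi tessellation.

    Boundary-band points are replicated into the eight neighbouring images so
    central cells are correct; cell areas then tile the box exactly.
    """
    L = np.asarray(box, dtype=float)[:2]
    pts = np.mod(xy[:, :2], L)
    n = len(pts)
    images = [pts]
    for sx in (-1, 0, 1):
        for sy in (-1, 0, 1):
            if sx == 0 and sy == 0:
                continue
            img = pts + np.array([sx, sy]) * L
            keep = ((img[:, 0] > -margin) & (img[:, 0] < L[0] + margin)
                    & (img[:, 1] > -margin) & (img[:, 1] < L[1] + margin))
            if keep.any():
                images.append(img[keep])
    vor = Voronoi(np.vstack(images))
    areas = np.full(n, np.nan)
    for i in range(n):
        region = vor.regions[vor.point_region[i]]
        if -1 in region or len(region) == 0:
            continue
        poly = vor.vertices[region]
        x, y = poly[:, 0], poly[:, 1]
        areas[i] = 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
    return areas


@dataclass
class LeafletSurface:
    """Per-vertex geometry of one leaflet: outward normals, area per lipid,
    leaflet-to-leaflet thickness and mean curvature."""

    indices: np.ndarray     # lipid indices of this leaflet in the frame
    vertices: np.ndarray    # (n, 3) headgroup positions
    normals: np.ndarray     # (n, 3) outward unit normals
    apl: np.ndarray         # (n,) nm^2
    thickness: np.ndarray   # (n,) nm
    curvature: np.ndarray   # (n,) 1/nm


def local_surface(frame: MembraneFrame, leaflet: str,
                  leaflets: np.ndarray | None = None,
                  neighbor_radius: float = 2.5) -> LeafletSurface:
    """Estimate per-vertex surface geometry of one leaflet.

    Normals come from the smallest principal axis of the 3D neighborhood
    covariance (periodic in x, y), oriented away from the midplane. Mean
    curvature is read off a local quadratic height fit; thickness is the
    along-normal distance between the two leaflets' smoothed height fields.
    """
    labels = frame.leaflets if leaflets is None else leaflets
    sel = np.flatnonzero(labels == leaflet)
    if len(sel) < 10:
        raise ValueError(f"{leaflet} leaflet has fewer than 10 lipids")
    other = np.flatnonzero(labels != leaflet)
    pos = frame.head_pos[sel]
    xy = pos[:, :2]
    box = frame.box
    zsign = 1.0 if leaflet == "outer" else -1.0

    lists = _periodic_neighbors(xy, box, neighbor_radius)
    n = len(sel)
    normals = np.empty((n, 3))
    curvature = np.full(n, np.nan)
    global_normal = np.array([0.0, 0.0, zsign])
    for i, idx in enumerate(lists):
        idx = np.asarray(idx)
        d = np.empty((len(idx), 3))
        d[:, :2] = min_image_dxy(pos[idx], pos[i], box)
        d[:, 2] = pos[idx, 2] - pos[i, 2]
        if len(idx) < 4:
            normals[i] = global_normal
            continue
        cov = d.T @ d / len(idx)
        try:
            w, v = np.linalg.eigh(cov)
        except np.linalg.LinAlgError:
            normals[i] = global_normal
            continue
        nvec = v[:, 0]
        if w[1] < 1e-10:  # collinear neighborhood
            nvec = global_normal
        if nvec[2] * zsign < 0:
            nvec = -nvec
        normals[i] = nvec
        if len(idx) >= 6:
            A = np.column_stack([np.ones(len(idx)), d[:, 0], d[:, 1],
                                 d[:, 0] ** 2, d[:, 0] * d[:, 1], d[:, 1] ** 2])
            coef, *_ = np.linalg.lstsq(A, d[:, 2], rcond=None)
            _, zx, zy, cxx, cxy, cyy = coef
            zxx, zxy, zyy = 2 * cxx, cxy, 2 * cyy
            denom = 2.0 * (1 + zx ** 2 + zy ** 2) ** 1.5
            curvature[i] = ((1 + zy ** 2) * zxx - 2 * zx * zy * zxy
                            + (1 + zx ** 2) * zyy) / denom

    apl = _voronoi_areas(xy, box)
    z_self = smooth_at(xy, pos[:, 2], xy, r_smooth=1.0, box=box)
    z_other = smooth_at(frame.head_pos[other, :2], frame.head_pos[other, 2],
                        xy, r_smooth=1.0, box=box)
    thickness = np.abs(z_self - z_other) * np.abs(normals[:, 2])
    return LeafletSurface(indices=sel, vertices=pos, normals=normals,
                          apl=apl, thickness=thickness, curvature=curvature)


# ---------------------------------------------------------------------------
# per-lipid features

def lipid_order(tails: np.ndarray, normal: np.ndarray) -> float | np.ndarray:
    """Tail order parameter P2 = (3 <cos theta>^2 - 1) / 2.

    ``theta`` are the angles between every adjacent-bead bond of both tails
    and the local normal; the cosines are averaged over all bonds before
    squaring. Bounded in [-0.5, 1]; NaN for tail-less lipids (cholesterol).
    """
    t = np.asarray(tails, dtype=float)
    single = t.ndim == 3
    if single:
        t = t[None]
    nrm = np.atleast_2d(np.asarray(normal, dtype=float))
    nrm = nrm / np.linalg.norm(nrm, axis=-1, keepdims=True)
    if len(nrm) == 1:
        nrm = np.broadcast_to(nrm, (len(t), 3))
    bonds = np.diff(t, axis=2)                       # (n, tails, bonds, 3)
    lengths = np.linalg.norm(bonds, axis=-1)
    cos = np.einsum("ntbk,nk->ntb", bonds, nrm) / np.where(lengths > 0, lengths, np.nan)
    cos = cos.reshape(len(t), -1)
    ok = np.isfinite(cos)
    counts = ok.sum(axis=1)
    mean_cos = np.where(ok, cos, 0.0).sum(axis=1) / np.where(counts > 0, counts, np.nan)
    p2 = 0.5 * (3.0 * mean_cos ** 2 - 1.0)
    return float(p2[0]) if single else p2


def dipole_cos(phosphate: np.ndarray, amine: np.ndarray,
               normal: np.ndarray) -> float | np.ndarray:
    """Cosine of the angle between the phosphate->amine headgroup dipole and
    the local membrane normal; NaN for lipids lacking either bead."""
    p = np.atleast_2d(np.asarray(phosphate, dtype=float))
    a = np.atleast_2d(np.asarray(amine, dtype=float))
    nrm = np.atleast_2d(np.asarray(normal, dtype=float))
    if len(nrm) == 1:
        nrm = np.broadcast_to(nrm, p.shape)
    v = a - p
    lv = np.linalg.norm(v, axis=-1)
    ln = np.linalg.norm(nrm, axis=-1)
    cos = np.einsum("nk,nk->n", v, nrm) / np.where(lv * ln > 0, lv * ln, np.nan)
    return float(cos[0]) if p.shape[0] == 1 and np.ndim(phosphate) == 1 else cos


def group_density(frame: MembraneFrame, group: str, queries: np.ndarray,
                  r_smooth: float = 1.5, leaflet: str | None = None,
                  leaflets: np.ndarray | None = None) -> np.ndarray:
    """Smoothed 0/1 indicator of lipid-group membership at query points."""
    labels = frame.leaflets if leaflets is None else leaflets
    sel = np.arange(frame.n_lipids) if leaflet is None else np.flatnonzero(labels == leaflet)
    ind = np.array([1.0 if in_group(r, group) else 0.0 for r in frame.resnames[sel]])
    return smooth_at(frame.head_pos[sel, :2], ind, queries, r_smooth, frame.box)


class KernelSmoother:
    """Gaussian smoothing of many vertex-value fields at a fixed query set.

    Precomputes the truncated-kernel neighbor lists and weights once, then
    applies them to any number of value vectors (NaN values drop out of the
    weighted average per query).
    """

    def __init__(self, vertices: np.ndarray, queries: np.ndarray,
                 r_smooth: float = 1.5, box: np.ndarray | None = None) -> None:
        vertices = np.asarray(vertices, dtype=float)[:, :2]
        queries = np.atleast_2d(np.asarray(queries, dtype=float))[:, :2]
        self.n_queries = len(queries)
        cutoff = 3.0 * r_smooth
        if box is not None:
            L = np.asarray(box, dtype=float)[:2]
            tree = cKDTree(np.mod(vertices, L), boxsize=L)
            lists = tree.query_ball_point(np.mod(queries, L), cutoff)
        else:
            tree = cKDTree(vertices)
            lists = tree.query_ball_point(queries, cutoff)
        self.idx, self.weights = [], []
        for qi, idx in enumerate(lists):
            idx = np.asarray(idx, dtype=int)
            if len(idx) == 0:
                self.idx.append(idx)
                self.weights.append(np.empty(0))
                continue
            if box is not None:
                d = min_image_dxy(vertices[idx], queries[qi], np.asarray(box))
            else:
                d = vertices[idx] - queries[qi]
            w = np.exp(-(d[:, 0] ** 2 + d[:, 1] ** 2) / (2.0 * r_smooth ** 2))
            self.idx.append(idx)
            self.weights.append(w)

    def apply(self, values: np.ndarray) -> np.ndarray:
        values = np.asarray(values, dtype=float)
        out = np.full(self.n_queries, np.nan)
        for qi, (idx, w) in enumerate(zip(self.idx, self.weights)):
            if len(idx) == 0:
                continue
            v = values[idx]
            ok = np.isfinite(v)
            if not ok.any():
                continue
            ws = w[ok]
            out[qi] = (v[ok] * ws).sum() / ws.sum()
        return out


# ---------------------------------------------------------------------------
# the feature matrix

def _leaflet_feature_table(frame: MembraneFrame, leaflet: str,
                           labels: np.ndarray) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    surf = local_surface(frame, leaflet, leaflets=labels)
    sel = surf.indices
    values: dict[str, np.ndarray] = {
        "APL": surf.apl,
        "thickness": surf.thickness,
        "curvature": surf.curvature,
        "charge": frame.charges[sel].astype(float),
        "order": lipid_order(frame.tails[sel], surf.normals),
        "cos_dip": dipole_cos(frame.phosphate_pos[sel], frame.amine_pos[sel],
                              surf.normals),
    }
    for g in DENSITY_GROUPS:
        values[g] = np.array([1.0 if in_group(r, g) else 0.0
                              for r in frame.resnames[sel]])
    return surf.vertices[:, :2], values


def frame_features(frame: MembraneFrame, queries_xy: np.ndarray,
                   r_smooth: float = 1.5, per_leaflet: bool = False,
                   reassign_leaflets: bool = True) -> pd.DataFrame:
    """All 21 smoothed features of one frame at absolute (x, y) query points.

    Default output averages the two leaflets' smoothed values; with
    ``per_leaflet`` the columns are emitted per leaflet with ``_inner`` /
    ``_outer`` suffixes.
    """
    queries_xy = np.atleast_2d(queries_xy)
    box = frame.box
    if np.any(queries_xy[:, 0] < 0) or np.any(queries_xy[:, 0] > box[0]) \
            or np.any(queries_xy[:, 1] < 0) or np.any(queries_xy[:, 1] > box[1]):
        raise ValueError("query location outside the box")
    labels = assign_leaflets(frame) if reassign_leaflets else frame.leaflets
    cols: dict[str, np.ndarray] = {}
    per_leaf: dict[str, dict[str, np.ndarray]] = {}
    for leaflet in ("inner", "outer"):
        verts, values = _leaflet_feature_table(frame, leaflet, labels)
        smoother = KernelSmoother(verts, queries_xy, r_smooth, box)
        per_leaf[leaflet] = {name: smoother.apply(v) for name, v in values.items()}
    for name in ALL_FEATURES:
        if per_leaflet:
            cols[f"{name}_inner"] = per_leaf["inner"][name]
            cols[f"{name}_outer"] = per_leaf["outer"][name]
        else:
            stacked = np.vstack([per_leaf["inner"][name], per_leaf["outer"][name]])
            cols[name] = np.nanmean(stacked, axis=0)
    return pd.DataFrame(cols)


def feature_matrix(traj: Trajectory, locations: pd.DataFrame,
                   r_smooth: float = 1.5, per_leaflet: bool = False,
                   membrane_id: str = "membrane",
                   reassign_leaflets: bool = True) -> pd.DataFrame:
    """Per-(location, frame) feature rows over a whole trajectory.

    ``locations`` needs columns ``x_rel``, ``y_rel`` (box-relative) and
    ``label`` (1 = porated, 0 = non-porated). Relative coordinates are
    converted with each frame's box, so rows track the same membrane-relative
    spot while the box breathes.
    """
    for col in ("x_rel", "y_rel", "label"):
        if col not in locations.columns:
            raise ValueError(f"locations table lacks column {col!r}")
    rows = []
    for k, frame in enumerate(traj):
        q = np.column_stack([locations["x_rel"].to_numpy() * frame.box[0],
                             locations["y_rel"].to_numpy() * frame.box[1]])
        feats = frame_features(frame, q, r_smooth=r_smooth,
                               per_leaflet=per_leaflet,
                               reassign_leaflets=reassign_leaflets)
        feats.insert(0, "membrane_id", membrane_id)
        feats.insert(1, "location_id", np.arange(len(locations)))
        feats.insert(2, "frame", k)
        feats.insert(3, "x_rel", locations["x_rel"].to_numpy())
        feats.insert(4, "y_rel", locations["y_rel"].to_numpy())
        feats["label"] = locations["label"].to_numpy()
        rows.append(feats)
    return pd.concat(rows, ignore_index=True)
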