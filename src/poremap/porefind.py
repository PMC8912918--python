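"""Semi-automatic localization of the first electroporation event.

A pore in a coarse-grained bilayer shows up as a persistent column of water
beads at the bilayer midplane. Detection proceeds in two stages:

1. *Coarse search* — scan every ``coarse_stride``-th frame starting at
   ``start_frame``; partition the membrane plane into a square grid of
   regions and stop at the first region whose midplane slab holds strictly
   more than ``coarse_water_threshold`` water beads (a fully formed pore).
2. *Precise search* — walk back ``backtrack`` frames and scan forward frame
   by frame, pooling midplane waters over the (2*halfwidth+1)^2 region
   neighborhood (periodic); the first frame exceeding the precise threshold
   whose waters persist in each of the following ``persistence`` frames
   gives the poration time and, via the pooled waters' centroid, the pore
   location in box-relative coordinates.

If the precise stage fails (e.g. strongly undulating membranes), the coarse
scan resumes at the next stride with the midplane re-estimated locally, and
a warning is logged — standing in for visual inspection of the trajectory.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .events import PorationEvent
from .frame import MembraneFrame, Trajectory, min_image_dxy

log = logging.getLogger(__name__)


@dataclass
class PoreSearchParams:
    """Knobs of the two-stage search; defaults follow the detection protocol
    (start at frame 12 since no pore forms before 1.2 ns, scan every 6
    frames, 100 regions, >12 waters coarse, >4 waters precise)."""

    start_frame: int = 12
    coarse_stride: int = 6
    coarse_grid: int = 100              # regions per frame, a perfect square
    coarse_water_threshold: int = 12
    precise_water_threshold: int = 4    # 4 suits APM-like, 6 BPM-like membranes
    backtrack: int = 5
    neighborhood_halfwidth: int = 2
    persistence: int = 2
    midplane_halfwidth: float = 0.5     # nm

    def __post_init__(self) -> None:
        side = math.isqrt(self.coarse_grid)
        if side * side != self.coarse_grid:
            raise ValueError("coarse_grid must be a perfect square")
        for name in ("start_frame", "coarse_stride", "coarse_water_threshold",
                     "precise_water_threshold", "backtrack",
                     "neighborhood_halfwidth", "persistence"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def grid_side(self) -> int:
        return math.isqrt(self.coarse_grid)


def _midplane_z(frame: MembraneFrame) -> float:
    zo = frame.head_pos[frame.leaflets == "outer", 2]
    zi = frame.head_pos[frame.leaflets == "inner", 2]
    if len(zo) == 0 or len(zi) == 0:
        raise ValueError("frame lacks one of the leaflets")
    return 0.5 * (zo.mean() + zi.mean())


def midplane_water(frame: MembraneFrame, halfwidth: float,
                   z_mid: float | None = None) -> np.ndarray:
    """Water bead coordinates within the midplane slab |z - z_mid| < halfwidth."""
    if z_mid is None:
        z_mid = _midplane_z(frame)
    sel = np.abs(frame.water[:, 2] - z_mid) < halfwidth
    return frame.water[sel]


def _region_counts(waters: np.ndarray, box: np.ndarray, side: int) -> np.ndarray:
    ix = np.floor(waters[:, 0] / box[0] * side).astype(int) % side
    iy = np.floor(waters[:, 1] / box[1] * side).astype(int) % side
    counts = np.zeros((side, side), dtype=int)
    np.add.at(counts, (ix, iy), 1)
    return counts


def coarse_search(traj: Trajectory, params: PoreSearchParams,
                  start_frame: int | None = None) -> tuple[int, tuple[int, int]] | None:
    """First (frame, region) whose midplane slab exceeds the coarse threshold.

    Regions are scanned in row-major order within each visited frame, and
    frames at ``start_frame, +stride, ...``; returns None when no scanned
    frame qualifies. The threshold is a strict inequality: exactly
    ``coarse_water_threshold`` beads never fire.
    """
    if len(traj) == 0:
        raise ValueError("empty trajectory")
    start = params.start_frame if start_frame is None else start_frame
    side = params.grid_side
    for t in range(start, len(traj), params.coarse_stride):
        frame = traj[t]
        waters = midplane_water(frame, params.midplane_halfwidth)
        if len(waters) <= params.coarse_water_threshold:
            continue
        counts = _region_counts(waters, frame.box, side)
        hot = np.argwhere(counts > params.coarse_water_threshold)
        if len(hot):
            i, j = hot[0]  # row-major first hit
            return t, (int(i), int(j))
    return None


def _neighborhood_waters(frame: MembraneFrame, region: tuple[int, int],
                         params: PoreSearchParams,
                         local_midplane: bool = False) -> np.ndarray:
    """Midplane waters pooled over the periodic region neighborhood."""
    side = params.grid_side
    hw = params.neighborhood_halfwidth
    z_mid = None
    if local_midplane:
        # re-estimate the midplane from headgroups near the region centre to
        # tolerate membrane curvature
        cx = (region[0] + 0.5) / side * frame.box[0]
        cy = (region[1] + 0.5) / side * frame.box[1]
        d = min_image_dxy(frame.head_pos, np.array([cx, cy]), frame.box)
        near = (d ** 2).sum(axis=1) < (3.0 * frame.box[0] / side) ** 2
        if near.sum() >= 10:
            zo = frame.head_pos[near & (frame.leaflets == "outer"), 2]
            zi = frame.head_pos[near & (frame.leaflets == "inner"), 2]
            if len(zo) and len(zi):
                z_mid = 0.5 * (zo.mean() + zi.mean())
    waters = midplane_water(frame, params.midplane_halfwidth, z_mid=z_mid)
    if len(waters) == 0:
        return waters
    ix = np.floor(waters[:, 0] / frame.box[0] * side).astype(int) % side
    iy = np.floor(waters[:, 1] / frame.box[1] * side).astype(int) % side
    di = (ix - region[0]) % side
    dj = (iy - region[1]) % side
    keep = ((di <= hw) | (di >= side - hw)) & ((dj <= hw) | (dj >= side - hw))
    return waters[keep]


def _periodic_centroid(points: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Centroid of lateral coordinates under periodic wrap (circular mean)."""
    out = np.empty(2)
    for k in range(2):
        ang = points[:, k] / box[k] * 2 * np.pi
        mean_ang = math.atan2(np.sin(ang).mean(), np.cos(ang).mean())
        out[k] = (mean_ang / (2 * np.pi) * box[k]) % box[k]
    return out


def to_relative_coords(point: tuple[float, float], box: tuple[float, float]) -> tuple[float, float]:
    """Box-relative coordinates (x/Lx mod 1, y/Ly mod 1)."""
    lx, ly = float(box[0]), float(box[1])
    if lx <= 0 or ly <= 0:
        raise ValueError("box dimensions must be positive")
    return (point[0] / lx) % 1.0, (point[1] / ly) % 1.0


def precise_search(traj: Trajectory, t: int, region: tuple[int, int],
                   params: PoreSearchParams, membrane_id: str = "membrane",
                   system: str = "", replica: int = 0,
                   local_midplane: bool = False) -> PorationEvent | None:
    """Refine a coarse hit to the first persistent frame and pore centroid.

    Scans frames t - backtrack ... t; at the first frame whose pooled
    neighborhood waters strictly exceed the precise threshold AND whose
    following ``persistence`` frames also contain neighborhood waters,
    returns the event with time = frame index * dt and the pooled waters'
    periodic centroid in relative coordinates.
    """
    for f in range(max(t - params.backtrack, 0), t + 1):
        waters = _neighborhood_waters(traj[f], region, params, local_midplane)
        if len(waters) <= params.precise_water_threshold:
            continue
        persistent = all(
            len(_neighborhood_waters(traj[f + k], region, params, local_midplane)) > 0
            for k in range(1, params.persistence + 1)
            if f + k < len(traj)
        )
        if not persistent:
            continue
        frame = traj[f]
        cx, cy = _periodic_centroid(waters, frame.box)
        x_rel, y_rel = to_relative_coords((cx, cy), (frame.box[0], frame.box[1]))
        return PorationEvent(membrane_id, system, replica,
                             t_ns=f * traj.dt, x_rel=x_rel, y_rel=y_rel)
    return None


def locate_first_pore(traj: Trajectory, params: PoreSearchParams | None = None,
                      membrane_id: str = "membrane", system: str = "",
                      replica: int = 0) -> PorationEvent:
    """Coarse + precise search for the first poration event.

    On precise failure the coarse scan re-enters at the next stride; a second
    failure for the same hit retries with a locally re-estimated midplane
    before moving on. A trajectory with no detectable pore yields a censored
    event at the final frame time.
    """
    params = params or PoreSearchParams()
    start = params.start_frame
    while True:
        hit = coarse_search(traj, params, start_frame=start)
        if hit is None:
            return PorationEvent(membrane_id, system, replica,
                                 t_ns=(len(traj) - 1) * traj.dt,
                                 x_rel=np.nan, y_rel=np.nan, censored=True)
        t, region = hit
        event = precise_search(traj, t, region, params, membrane_id, system, replica)
        if event is not None:
            return event
        log.warning("precise search failed at frame %d region %s; retrying with "
                    "locally re-estimated midplane", t, region)
        event = precise_search(traj, t, region, params, membrane_id, system,
                               replica, local_midplane=True)
        if event is not None:
            return event
        start = t + params.coarse_stride


def locate_all_pores(traj: Trajectory, params: PoreSearchParams | None = None,
                     membrane_id: str = "membrane", system: str = "",
                     replica: int = 0) -> list[PorationEvent]:
    """All simultaneous first-pore events in the earliest qualifying frame.

    When two or more pores form practically simultaneously every hot region
    of the detection frame is reported; regions are merged if adjacent.
    """
    params = params or PoreSearchParams()
    first = locate_first_pore(traj, params, membrane_id, system, replica)
    if first.censored:
        return [first]
    t_first = int(round(first.t_ns / traj.dt))
    scan = t_first + params.coarse_stride  # frame the coarse pass would flag
    side = params.grid_side
    frame = traj[min(scan, len(traj) - 1)]
    waters = midplane_water(frame, params.midplane_halfwidth)
    counts = _region_counts(waters, frame.box, side) if len(waters) else np.zeros((side, side), int)
    hot = np.argwhere(counts > params.coarse_water_threshold)
    events = [first]
    for i, j in hot:
        ev = precise_search(traj, min(scan, len(traj) - 1), (int(i), int(j)),
                            params, membrane_id, system, replica)
        if ev is None or ev.censored:
            continue
        if all(_far(ev, e) for e in events):
            events.append(ev)
    if len(events) > 1:
        log.warning("%d simultaneous pores detected", len(events))
    return events


def _far(a: PorationEvent, b: PorationEvent, min_sep: float = 0.15) -> bool:
    dx = abs(a.x_rel - b.x_rel)
    dy = abs(a.y_rel - b.y_rel)
    dx = min(dx, 1 - dx)
    dy = min(dy, 1 - dy)
    return dx * dx + dy * dy > min_sep ** 2
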