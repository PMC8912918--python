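"""Synthetic coarse-grained membrane and poration-event generator.

This module produces bilayer frames, short trajectories, planted
transmembrane water columns (pores), and first-poration event tables with
the statistical structure the downstream analysis assumes:

* spatially correlated, leaflet-asymmetric lipid composition fields over the
  standard headgroup/saturation lipid groups, emulating the nanodomain
  heterogeneity of mixed plasma membranes;
* tail-bead chains whose orientational disorder increases with the local
  polyunsaturated-lipid (PU) probability, so tail order anticorrelates with
  PU density as in disordered nanodomains;
* a water slab outside the bilayer, with optional inserted midplane water
  columns acting as fully formed pores;
* first-poration times drawn exactly from a piecewise-constant proportional
  hazard lambda_0(t)*exp(beta_i), with pore locations coupled to the local
  PU density.

Nothing here integrates equations of motion; frames are statistical stand-ins
for equilibrated coarse-grained membranes, not mechanics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter

from .events import PorationEvent
from .frame import MembraneFrame, Trajectory
from .groups import head_charge, head_group, tail_group, ZWITTERIONIC_HEADS
from .util import rng_for

BOND_LENGTH = 0.47      # nm, coarse-grained bead spacing
DIPOLE_LENGTH = 0.25    # nm, phosphate -> amine bead distance

# Leaflet composition presets (percent of lipids per leaflet), patterned on a
# published average plasma membrane (APM) and brain plasma membrane (BPM)
# leaflet inventory. Headgroup classes sum to 100; FS/MU/PU sum to
# 100 - CHOL since cholesterol carries no saturation class.
COMPOSITION_PRESETS = {
    "APM": {
        "inner": {"CHOL": 27.7, "PC": 17.9, "PE": 24.5, "SM": 10.6, "GM": 0.0,
                  "PS": 11.3, "PI": 3.7, "PIP": 2.0, "PA": 1.6, "LPC": 0.0,
                  "DAG": 0.5, "CE": 0.3, "FS": 6.6, "MU": 24.6, "PU": 41.1},
        "outer": {"CHOL": 31.7, "PC": 36.4, "PE": 6.6, "SM": 18.7, "GM": 3.7,
                  "PS": 0.0, "PI": 0.0, "PIP": 0.0, "PA": 0.0, "LPC": 1.5,
                  "DAG": 1.0, "CE": 0.4, "FS": 12.2, "MU": 26.7, "PU": 29.4},
    },
    "BPM": {
        "inner": {"CHOL": 44.5, "PC": 12.4, "PE": 22.8, "SM": 2.1, "GM": 0.0,
                  "PS": 9.8, "PI": 5.4, "PIP": 1.4, "PA": 0.3, "LPC": 0.5,
                  "DAG": 0.4, "CE": 0.2, "FS": 5.1, "MU": 13.2, "PU": 37.2},
        "outer": {"CHOL": 45.7, "PC": 23.0, "PE": 9.7, "SM": 8.9, "GM": 11.3,
                  "PS": 0.0, "PI": 0.0, "PIP": 0.0, "PA": 0.0, "LPC": 0.3,
                  "DAG": 0.2, "CE": 0.7, "FS": 22.4, "MU": 15.5, "PU": 16.3},
    },
}

# One representative Martini residue per (headgroup class, saturation class)
# cell that actually occurs in the classification table.
REPRESENTATIVE_SPECIES = {
    ("PC", "FS"): "DPPC", ("PC", "MU"): "POPC", ("PC", "PU"): "PAPC",
    ("PE", "MU"): "POPE", ("PE", "PU"): "PAPE",
    ("SM", "FS"): "DPSM", ("SM", "MU"): "PNSM",
    ("GM", "FS"): "DPG1", ("GM", "MU"): "POG1",
    ("CE", "FS"): "DPCE", ("CE", "MU"): "POCE",
    ("LPC", "FS"): "PPC", ("LPC", "MU"): "OPC", ("LPC", "PU"): "IPC",
    ("DAG", "MU"): "PODG", ("DAG", "PU"): "PADG",
    ("PS", "FS"): "DPPS", ("PS", "MU"): "POPS", ("PS", "PU"): "PAPS",
    ("PI", "MU"): "POPI", ("PI", "PU"): "PAPI",
    ("PA", "MU"): "POPA", ("PA", "PU"): "PAPA",
    ("PIP", "MU"): "POP2", ("PIP", "PU"): "PAP2",
}


def species_fractions(composition: str, leaflet: str) -> dict[str, float]:
    """Per-species lipid fractions for a leaflet preset.

    The preset gives two marginals over the same lipids: headgroup classes and
    saturation classes. Iterative proportional fitting distributes mass over
    the feasible (headgroup, saturation) cells so both marginals are matched,
    then each cell is represented by one Martini species. Cholesterol is its
    own species outside the fit. Fractions sum to 1.
    """
    pct = COMPOSITION_PRESETS[composition][leaflet]
    heads = [h for h in ("PC", "PE", "SM", "GM", "PS", "PI", "PA", "PIP", "LPC", "CE", "DAG")]
    sats = ["FS", "MU", "PU"]
    row = np.array([pct[h] for h in heads], dtype=float)
    col = np.array([pct[s] for s in sats], dtype=float)
    col *= row.sum() / col.sum()  # reconcile rounding between the marginals
    allowed = np.array([[(h, s) in REPRESENTATIVE_SPECIES for s in sats] for h in heads])
    m = allowed.astype(float)
    for _ in range(200):
        rs = m.sum(axis=1, keepdims=True)
        m = np.where(rs > 0, m * np.where(row[:, None] > 0, row[:, None] / np.maximum(rs, 1e-300), 0.0), 0.0)
        cs = m.sum(axis=0, keepdims=True)
        m = np.where(cs > 0, m * np.where(col[None, :] > 0, col[None, :] / np.maximum(cs, 1e-300), 0.0), 0.0)
    fractions = {"CHOL": pct["CHOL"]}
    for i, h in enumerate(heads):
        for j, s in enumerate(sats):
            if allowed[i, j] and m[i, j] > 1e-12:
                fractions[REPRESENTATIVE_SPECIES[(h, s)]] = m[i, j]
    total = sum(fractions.values())
    return {k: v / total for k, v in fractions.items()}


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic membrane.

    ``group_fractions`` maps leaflet -> {species resname: fraction}; fractions
    per leaflet must sum to 1. ``correlation_length`` (nm) sets the smoothing
    scale of the composition fields (``inf`` gives a spatially uniform
    membrane); ``heterogeneity`` scales the log-probability noise amplitude.
    ``order_coupling`` links local PU probability to tail angular disorder
    (radians of extra bond-angle noise per unit PU probability), on top of
    ``base_disorder`` and an independent smoothed disorder field of
    amplitude ``disorder_heterogeneity`` (tail order in real membranes is
    set by many factors beyond local unsaturation, so the PU link is a
    correlation, not a deterministic map). ``diffusion_step`` is the
    per-frame lateral random-walk step (nm) in trajectories.
    """

    box_xy: float = 30.0
    box_z: float = 9.0
    n_lipids_per_leaflet: int = 1500
    composition: str = "APM"
    group_fractions: dict[str, dict[str, float]] | None = None
    correlation_length: float = 3.0
    heterogeneity: float = 1.2
    order_coupling: float = 0.35
    base_disorder: float = 0.3
    disorder_heterogeneity: float = 0.2
    n_tail_beads: int = 4
    water_density: float = 1.0
    bilayer_half_thickness: float = 2.0
    diffusion_step: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.box_xy <= 0 or self.box_z <= 0:
            raise ValueError("box dimensions must be positive")
        if not self.correlation_length > 0:
            raise ValueError("correlation_length must be positive")
        if self.n_tail_beads < 2:
            raise ValueError("tails need at least 2 beads")
        if self.group_fractions is None:
            self.group_fractions = {
                leaf: species_fractions(self.composition, leaf)
                for leaf in ("inner", "outer")
            }
        for leaf, fr in self.group_fractions.items():
            total = sum(fr.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{leaf} leaflet fractions sum to {total}, not 1")
            if any(v < 0 for v in fr.values()):
                raise ValueError("negative lipid fraction")

    @property
    def midplane_z(self) -> float:
        return self.box_z / 2.0


@dataclass
class CompositionFields:
    """Per-leaflet, per-species probability fields on a periodic grid."""

    box_xy: float
    grid_n: int
    species: dict[str, list[str]]              # leaflet -> species order
    probs: dict[str, np.ndarray]               # leaflet -> (grid_n, grid_n, n_species)
    disorder: dict[str, np.ndarray] | None = None  # leaflet -> standardized field

    def cell_of(self, xy: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        g = self.grid_n
        ix = np.floor(np.asarray(xy)[..., 0] / self.box_xy * g).astype(int) % g
        iy = np.floor(np.asarray(xy)[..., 1] / self.box_xy * g).astype(int) % g
        return ix, iy

    def probs_at(self, leaflet: str, xy: np.ndarray) -> np.ndarray:
        ix, iy = self.cell_of(xy)
        return self.probs[leaflet][ix, iy]

    def group_field(self, leaflet: str, group: str) -> np.ndarray:
        """Probability field of a headgroup or saturation lipid group."""
        from .groups import in_group
        sel = np.array([in_group(sp, group) for sp in self.species[leaflet]])
        return self.probs[leaflet][..., sel].sum(axis=-1)

    def pu_field(self, leaflet: str | None = None,
                 smooth_nm: float | None = None) -> np.ndarray:
        """Polyunsaturated-lipid probability field, leaflet-averaged by
        default. ``smooth_nm`` applies a periodic Gaussian blur so the field
        describes PU density at a physical observation scale (a nascent pore
        spans nanometres, not a single composition-grid cell)."""
        if leaflet is not None:
            field = self.group_field(leaflet, "PU")
        else:
            field = 0.5 * (self.group_field("inner", "PU")
                           + self.group_field("outer", "PU"))
        if smooth_nm:
            dx = self.box_xy / self.grid_n
            field = gaussian_filter(field, sigma=smooth_nm / dx, mode="wrap")
        return field


def gen_composition_fields(config: SyntheticConfig, seed: int | None = None,
                           grid_n: int = 64) -> CompositionFields:
    """Smooth per-species probability fields on a periodic grid.

    Independent white noise per species is smoothed with a periodic Gaussian
    filter of width ``correlation_length``, rescaled to unit variance,
    multiplied by ``heterogeneity`` and combined with the configured log
    fractions through a softmax, so the fields are everywhere non-negative,
    sum to 1 over species, and have mean composition close to the configured
    fractions with spatial autocorrelation decaying on the correlation length.
    """
    seed = config.seed if seed is None else seed
    rng = rng_for(seed, "composition-fields")
    dx = config.box_xy / grid_n
    probs = {}
    species = {}
    for leaflet in ("inner", "outer"):
        fr = config.group_fractions[leaflet]
        names = sorted(fr)
        species[leaflet] = names
        f = np.array([fr[s] for s in names], dtype=float)
        logf = np.log(np.maximum(f, 1e-300))
        logits = np.tile(logf, (grid_n, grid_n, 1))
        if math.isfinite(config.correlation_length) and config.heterogeneity > 0:
            sigma = config.correlation_length / dx
            for k in range(len(names)):
                if f[k] <= 0:
                    continue
                noise = rng.standard_normal((grid_n, grid_n))
                smooth = gaussian_filter(noise, sigma=sigma, mode="wrap")
                sd = smooth.std()
                if sd > 0:
                    smooth /= sd
                logits[..., k] = logits[..., k] + config.heterogeneity * smooth
        else:
            # draw (and discard) nothing: infinite correlation length means a
            # spatially uniform membrane equal to the configured fractions
            pass
        logits -= logits.max(axis=-1, keepdims=True)
        p = np.exp(logits)
        p[..., f <= 0] = 0.0
        p /= p.sum(axis=-1, keepdims=True)
        # the softmax of noisy logits biases the areal mean composition away
        # from the configured fractions; rescale species weights until the
        # spatial means match (Sinkhorn-style fixed point)
        for _ in range(200):
            means = p.mean(axis=(0, 1))
            if np.abs(means[f > 0] - f[f > 0]).max() < 1e-12:
                break
            scale = np.where(means > 0, f / np.maximum(means, 1e-300), 0.0)
            p = p * scale
            p /= p.sum(axis=-1, keepdims=True)
        probs[leaflet] = p
    disorder = {}
    for leaflet in ("inner", "outer"):
        if math.isfinite(config.correlation_length):
            noise = rng.standard_normal((grid_n, grid_n))
            smooth = gaussian_filter(noise, sigma=config.correlation_length / dx,
                                     mode="wrap")
            sd = smooth.std()
            disorder[leaflet] = smooth / sd if sd > 0 else smooth
        else:
            disorder[leaflet] = np.zeros((grid_n, grid_n))
    return CompositionFields(box_xy=config.box_xy, grid_n=grid_n,
                             species=species, probs=probs, disorder=disorder)


def _lattice(n: int, box: float, rng: np.random.Generator) -> np.ndarray:
    """n jittered sites of a square lattice covering a box x box patch."""
    nx = math.ceil(math.sqrt(n))
    ny = math.ceil(n / nx)
    if nx * ny < n:
        raise ValueError("lattice cannot host the requested lipid count")
    sx, sy = box / nx, box / ny
    gx, gy = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    sites = np.column_stack([(gx.ravel() + 0.5) * sx, (gy.ravel() + 0.5) * sy])
    keep = rng.choice(len(sites), size=n, replace=False)
    sites = sites[keep]
    sites[:, 0] += rng.uniform(-0.3 * sx, 0.3 * sx, n)
    sites[:, 1] += rng.uniform(-0.3 * sy, 0.3 * sy, n)
    return sites % box


def _grow_tails(anchors: np.ndarray, inward: float, sd_angle: np.ndarray,
                n_tails: int, n_beads: int, rng: np.random.Generator) -> np.ndarray:
    """Kinked-stick tail chains below/above the headgroup anchors.

    Each bond direction is the inward membrane normal tilted by a wrapped
    normal polar angle with per-lipid standard deviation ``sd_angle`` and a
    uniform azimuth. ``inward`` is -1 for the outer leaflet (tails grow down)
    and +1 for the inner leaflet.
    """
    n = len(anchors)
    n_bonds = n_beads - 1
    theta = rng.normal(0.0, 1.0, (n, n_tails, n_bonds)) * sd_angle[:, None, None]
    theta = np.abs((theta + np.pi) % (2 * np.pi) - np.pi)  # wrap, fold to [0, pi]
    phi = rng.uniform(0, 2 * np.pi, (n, n_tails, n_bonds))
    bonds = np.empty((n, n_tails, n_bonds, 3))
    bonds[..., 0] = BOND_LENGTH * np.sin(theta) * np.cos(phi)
    bonds[..., 1] = BOND_LENGTH * np.sin(theta) * np.sin(phi)
    bonds[..., 2] = BOND_LENGTH * inward * np.cos(theta)
    first = np.empty((n, n_tails, 1, 3))
    first[..., :2] = rng.normal(0.0, 0.1, (n, n_tails, 1, 2))
    first[..., 2] = inward * 0.5
    steps = np.concatenate([first, bonds], axis=2)
    tails = anchors[:, None, None, :] + np.cumsum(steps, axis=2)
    return tails


def gen_frame(config: SyntheticConfig, fields: CompositionFields | None = None,
              time: float = 0.0, seed: int | None = None) -> MembraneFrame:
    """One membrane frame drawn from the composition fields.

    Lipids sit on a jittered lattice per leaflet; each lipid's species is
    drawn from the local field; tail chains get angular noise
    ``base_disorder + order_coupling * local PU probability``; a water slab
    fills the box outside the bilayer. Headgroup charges follow the lipid
    classification table.
    """
    if fields is None:
        fields = gen_composition_fields(config)
    seed = config.seed if seed is None else seed
    rng = rng_for(seed, "frame", int(round(time * 1e6)))
    n = config.n_lipids_per_leaflet
    zmid = config.midplane_z
    h = config.bilayer_half_thickness

    res, leaf, heads, phos, amine, tails, charges = [], [], [], [], [], [], []
    for leaflet, zsign in (("inner", -1.0), ("outer", +1.0)):
        xy = _lattice(n, config.box_xy, rng)
        z = zmid + zsign * h + rng.normal(0, 0.08, n)
        pos = np.column_stack([xy, z])
        p = fields.probs_at(leaflet, xy)                    # (n, n_species)
        names = np.array(fields.species[leaflet])
        cum = np.cumsum(p, axis=1)
        u = rng.random(n)
        idx = (u[:, None] > cum).sum(axis=1)
        resnames = names[np.minimum(idx, len(names) - 1)]
        pu_local = fields.group_field(leaflet, "PU")[fields.cell_of(xy)]
        sd_angle = config.base_disorder + config.order_coupling * pu_local
        if fields.disorder is not None:
            sd_angle = np.clip(sd_angle + config.disorder_heterogeneity
                               * fields.disorder[leaflet][fields.cell_of(xy)], 0.0, None)

        ph = np.full((n, 3), np.nan)
        am = np.full((n, 3), np.nan)
        zwit = np.array([head_group(r) in ZWITTERIONIC_HEADS for r in resnames])
        ph[zwit] = pos[zwit]
        tilt = rng.normal(0, 0.4, n)
        azim = rng.uniform(0, 2 * np.pi, n)
        d = np.column_stack([np.sin(tilt) * np.cos(azim),
                             np.sin(tilt) * np.sin(azim),
                             zsign * np.cos(tilt)])
        am[zwit] = pos[zwit] + DIPOLE_LENGTH * d[zwit]

        tl = _grow_tails(pos, -zsign, sd_angle, 2, config.n_tail_beads, rng)
        no_tails = np.array([tail_group(r) is None for r in resnames])
        tl[no_tails] = np.nan

        res.append(resnames)
        leaf.append(np.full(n, leaflet, dtype=object))
        heads.append(pos)
        phos.append(ph)
        amine.append(am)
        tails.append(tl)
        charges.append(np.array([head_charge(r) for r in resnames]))

    slab = config.box_z - 2 * (h + 0.5)
    n_water = int(round(config.water_density * config.box_xy ** 2 * max(slab, 0.0)))
    wz = rng.uniform(0, slab, n_water)
    wz = np.where(wz < slab / 2, wz, wz + 2 * (h + 0.5))  # below and above bilayer
    water = np.column_stack([rng.uniform(0, config.box_xy, n_water),
                             rng.uniform(0, config.box_xy, n_water), wz])

    return MembraneFrame(
        box=np.array([config.box_xy, config.box_xy, config.box_z]),
        time=time,
        resnames=np.concatenate(res).astype(object),
        leaflets=np.concatenate(leaf),
        head_pos=np.vstack(heads),
        phosphate_pos=np.vstack(phos),
        amine_pos=np.vstack(amine),
        tails=np.concatenate(tails, axis=0),
        charges=np.concatenate(charges),
        water=water,
    )


def gen_trajectory(config: SyntheticConfig, n_frames: int, dt: float = 0.1,
                   fields: CompositionFields | None = None,
                   seed: int | None = None) -> Trajectory:
    """Trajectory of ``n_frames`` frames spaced ``dt`` ns apart.

    Frames share lipid identities. Headgroup anchors perform a lateral
    random walk with per-frame step ``config.diffusion_step`` (lateral
    diffusion); tails and the water slab are resampled each frame so local
    features fluctuate. A zero diffusion step reproduces the first frame
    identically in every frame.
    """
    if n_frames < 1:
        raise ValueError("need at least one frame")
    if fields is None:
        fields = gen_composition_fields(config, seed=config.seed if seed is None else seed)
    seed = config.seed if seed is None else seed
    frame0 = gen_frame(config, fields, time=0.0, seed=seed)
    frames = [frame0]
    if config.diffusion_step == 0.0:
        for k in range(1, n_frames):
            f = frame0.copy()
            f.time = k * dt
            frames.append(f)
        return Trajectory(frames, dt=dt)

    rng = rng_for(seed, "trajectory")
    prev = frame0
    zmid = config.midplane_z
    h = config.bilayer_half_thickness
    for k in range(1, n_frames):
        f = prev.copy()
        f.time = k * dt
        step = rng.normal(0, config.diffusion_step, (f.n_lipids, 2))
        f.head_pos[:, :2] = (f.head_pos[:, :2] + step) % config.box_xy
        f.head_pos[:, 2] = zmid + np.where(f.leaflets == "outer", h, -h) \
            + rng.normal(0, 0.08, f.n_lipids)
        for leaflet, zsign in (("inner", -1.0), ("outer", +1.0)):
            sel = f.leaflet_index(leaflet)
            xy = f.head_pos[sel, :2]
            pu_local = fields.group_field(leaflet, "PU")[fields.cell_of(xy)]
            sd_angle = config.base_disorder + config.order_coupling * pu_local
            if fields.disorder is not None:
                sd_angle = np.clip(sd_angle + config.disorder_heterogeneity
                                   * fields.disorder[leaflet][fields.cell_of(xy)], 0.0, None)
            tl = _grow_tails(f.head_pos[sel], -zsign, sd_angle, 2,
                             config.n_tail_beads, rng)
            no_tails = np.isnan(f.tails[sel, 0, 0, 0])
            tl[no_tails] = np.nan
            f.tails[sel] = tl
            zwit = ~np.isnan(f.phosphate_pos[sel, 0])
            f.phosphate_pos[sel] = np.where(zwit[:, None], f.head_pos[sel], np.nan)
            tilt = rng.normal(0, 0.4, len(sel))
            azim = rng.uniform(0, 2 * np.pi, len(sel))
            d = np.column_stack([np.sin(tilt) * np.cos(azim),
                                 np.sin(tilt) * np.sin(azim),
                                 zsign * np.cos(tilt)])
            f.amine_pos[sel] = np.where(zwit[:, None],
                                        f.head_pos[sel] + DIPOLE_LENGTH * d, np.nan)
        wstep = rng.normal(0, config.diffusion_step, f.water.shape[:1] + (2,))
        f.water[:, :2] = (f.water[:, :2] + wstep) % config.box_xy
        frames.append(f)
        prev = f
    return Trajectory(frames, dt=dt)


def plant_pore(traj: Trajectory, location: tuple[float, float], n_waters: int,
               start_frame: int, radius: float = 0.5, z_halfwidth: float = 0.3,
               seed: int = 0) -> Trajectory:
    """Insert a persistent transmembrane water column.

    From ``start_frame`` onward every frame gains ``n_waters`` water beads in
    a disc of ``radius`` nm around ``location`` at the bilayer midplane,
    wrapped periodically. The input trajectory is not modified.
    """
    if n_waters < 0:
        raise ValueError("n_waters must be non-negative")
    box = traj[0].box
    if not (0 <= location[0] <= box[0] and 0 <= location[1] <= box[1]):
        raise ValueError("pore location outside the box")
    if n_waters == 0:
        return traj
    rng = rng_for(seed, "plant-pore")
    zmid = _frame_midplane(traj[0])
    r = radius * np.sqrt(rng.random(n_waters))
    phi = rng.uniform(0, 2 * np.pi, n_waters)
    col = np.column_stack([
        (location[0] + r * np.cos(phi)) % box[0],
        (location[1] + r * np.sin(phi)) % box[1],
        zmid + rng.uniform(-z_halfwidth, z_halfwidth, n_waters),
    ])
    frames = []
    for k, f in enumerate(traj.frames):
        g = f.copy()
        if k >= start_frame:
            g.water = np.vstack([g.water, col])
        frames.append(g)
    return Trajectory(frames, dt=traj.dt)


def _frame_midplane(frame: MembraneFrame) -> float:
    zo = frame.head_pos[frame.leaflets == "outer", 2].mean()
    zi = frame.head_pos[frame.leaflets == "inner", 2].mean()
    return 0.5 * (zo + zi)


@dataclass
class HazardSpec:
    """Piecewise-constant proportional hazard for first-poration times.

    ``interval_endpoints`` are ordered times s_0=0 < s_1 < ... < s_N (ns);
    ``baseline_rates`` gives lambda_j on [s_j, s_{j+1}), one fewer than the
    endpoints; the hazard of system i is lambda_0(t) * exp(betas[i]). Beyond
    the last endpoint the final rate is extended. ``censor_time`` marks
    replicas that never porate within the run.
    """

    interval_endpoints: np.ndarray
    baseline_rates: np.ndarray
    betas: dict[str, float]
    censor_time: float | None = None

    def __post_init__(self) -> None:
        self.interval_endpoints = np.asarray(self.interval_endpoints, dtype=float)
        self.baseline_rates = np.asarray(self.baseline_rates, dtype=float)
        if self.interval_endpoints[0] != 0.0:
            raise ValueError("interval endpoints must start at 0")
        if np.any(np.diff(self.interval_endpoints) <= 0):
            raise ValueError("interval endpoints must be strictly increasing")
        if len(self.baseline_rates) != len(self.interval_endpoints) - 1:
            raise ValueError("need one baseline rate per interval")
        if np.any(self.baseline_rates < 0):
            raise ValueError("baseline rates must be non-negative")
        if np.all(self.baseline_rates == 0) and self.censor_time is None:
            raise ValueError("all-zero hazard with no censoring: no event can occur")


def _sample_first_time(spec: HazardSpec, beta: float, rng: np.random.Generator) -> float:
    """Interval-wise inverse-CDF draw from the piecewise-exponential model."""
    target = rng.exponential(1.0)
    s = spec.interval_endpoints
    rates = spec.baseline_rates * math.exp(beta)
    acc = 0.0
    for j in range(len(rates)):
        width = s[j + 1] - s[j]
        step = rates[j] * width
        if acc + step >= target:
            return s[j] + (target - acc) / rates[j]
        acc += step
    tail_rate = rates[-1]
    if tail_rate > 0:
        return s[-1] + (target - acc) / tail_rate
    return math.inf


def sample_poration_dataset(spec: HazardSpec, n_per_system: int,
                            pu_field: np.ndarray | None = None,
                            coupling: float = 0.0, seed: int = 0,
                            membrane_id: str = "synthetic") -> list[PorationEvent]:
    """First-poration event table drawn from the piecewise hazard.

    Event times come from exact interval-wise inverse-CDF sampling of
    lambda_0(t) exp(beta_i); times beyond ``censor_time`` are recorded as
    censored. Pore (x, y) positions are drawn over the cells of ``pu_field``
    with probability proportional to exp(coupling * standardized PU density),
    uniform when the field is absent or the coupling is zero.
    """
    rng = rng_for(seed, "poration-dataset")
    if pu_field is not None and coupling != 0.0:
        z = pu_field.astype(float)
        sd = z.std()
        z = (z - z.mean()) / sd if sd > 0 else np.zeros_like(z)
        w = np.exp(coupling * z).ravel()
        cell_p = w / w.sum()
        gshape = pu_field.shape
    else:
        cell_p = None
        gshape = (1, 1)
    events = []
    for system, beta in spec.betas.items():
        for rep in range(n_per_system):
            t = _sample_first_time(spec, beta, rng)
            censored = spec.censor_time is not None and t > spec.censor_time
            if math.isinf(t) and spec.censor_time is None:
                raise ValueError("event time diverged without censoring")
            if censored:
                events.append(PorationEvent(membrane_id, system, rep,
                                            float(spec.censor_time), np.nan, np.nan, True))
                continue
            if cell_p is None:
                x_rel, y_rel = rng.random(), rng.random()
            else:
                k = rng.choice(len(cell_p), p=cell_p)
                ix, iy = divmod(k, gshape[1])
                x_rel = (ix + rng.random()) / gshape[0]
                y_rel = (iy + rng.random()) / gshape[1]
            events.append(PorationEvent(membrane_id, system, rep, float(t),
                                        float(x_rel), float(y_rel), False))
    return events
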