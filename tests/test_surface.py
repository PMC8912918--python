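"""Local feature estimators: smoothing kernel closed forms, order parameter
limits, dipole geometry, surface fits on analytic fixtures, partitions."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import poremap
from poremap import surface as sf
from poremap.frame import MembraneFrame
from poremap.groups import DENSITY_GROUPS, UnknownResidueError


def make_frame(head_pos, leaflets, box=(30.0, 30.0, 9.0), resnames=None):
    """Bare geometric frame: no tails, no dipoles, no water."""
    n = len(head_pos)
    head_pos = np.asarray(head_pos, dtype=float)
    if resnames is None:
        resnames = np.array(["POPC"] * n, dtype=object)
    return MembraneFrame(
        box=np.asarray(box, float), time=0.0,
        resnames=np.asarray(resnames, dtype=object),
        leaflets=np.asarray(leaflets, dtype=object),
        head_pos=head_pos,
        phosphate_pos=np.full((n, 3), np.nan),
        amine_pos=np.full((n, 3), np.nan),
        tails=np.full((n, 2, 2, 3), np.nan),
        charges=np.zeros(n), water=np.empty((0, 3)))


def flat_bilayer(n_side=20, box=30.0, z=(2.0, -2.0)):
    u = (np.arange(n_side) + 0.5) * box / n_side
    gx, gy = np.meshgrid(u, u, indexing="ij")
    xy = np.column_stack([gx.ravel(), gy.ravel()])
    outer = np.column_stack([xy, np.full(len(xy), 4.5 + z[0] / 2 + 1.0)])
    inner = np.column_stack([xy, np.full(len(xy), 4.5 + z[1] / 2 - 1.0)])
    heads = np.vstack([outer, inner])
    leaf = np.array(["outer"] * len(xy) + ["inner"] * len(xy), dtype=object)
    return make_frame(heads, leaf, box=(box, box, 9.0))


class TestSmoothAt:
    def test_two_vertex_closed_form(self):
        v = poremap.smooth_at(np.array([[0.0, 0.0], [1.5, 0.0]]),
                              np.array([0.0, 1.0]),
                              np.array([[0.0, 0.0]]), r_smooth=1.5)
        expected = math.exp(-0.5) / (1 + math.exp(-0.5))
        assert v[0] == pytest.approx(expected, abs=1e-12)

    def test_single_vertex_at_query_returns_its_value(self):
        v = poremap.smooth_at(np.array([[3.0, 4.0]]), np.array([7.5]),
                              np.array([[3.0, 4.0]]), r_smooth=1.5)
        assert v[0] == 7.5

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000), st.floats(-50, 50))
    def test_constant_field_is_fixed_point(self, seed, const):
        rng = np.random.default_rng(seed)
        verts = rng.uniform(0, 20, (30, 2))
        q = rng.uniform(0, 20, (5, 2))
        v = poremap.smooth_at(verts, np.full(30, const), q, 1.5,
                              box=np.array([20.0, 20.0]))
        ok = np.isfinite(v)  # queries with no vertex in 3r are undefined
        assert ok.any()
        assert np.allclose(v[ok], const, atol=1e-9)

    def test_small_radius_converges_to_nearest_vertex(self):
        verts = np.array([[1.0, 1.0], [5.0, 5.0]])
        vals = np.array([2.0, 9.0])
        v = poremap.smooth_at(verts, vals, np.array([[1.4, 1.4]]), r_smooth=0.3)
        assert v[0] == pytest.approx(2.0, abs=1e-6)

    def test_out_of_range_query_undefined(self):
        v = poremap.smooth_at(np.array([[0.0, 0.0]]), np.array([1.0]),
                              np.array([[20.0, 20.0]]), r_smooth=1.5)
        assert np.isnan(v[0])

    def test_nan_values_excluded(self):
        v = poremap.smooth_at(np.array([[0.0, 0.0], [0.5, 0.0]]),
                              np.array([np.nan, 3.0]),
                              np.array([[0.0, 0.0]]), r_smooth=1.5)
        assert v[0] == pytest.approx(3.0)


class TestLipidOrder:
    def straight_tails(self, cos_values):
        """One tail whose successive bonds have the given cosines to +z."""
        beads = [np.zeros(3)]
        for c in cos_values:
            s = math.sqrt(1 - c * c)
            beads.append(beads[-1] + 0.47 * np.array([s, 0, c]))
        tail = np.array(beads)
        return np.stack([tail, tail])  # both tails identical

    def test_parallel_bonds_give_one(self):
        tails = self.straight_tails([1.0, 1.0, 1.0])
        assert poremap.lipid_order(tails, np.array([0, 0, 1.0])) == pytest.approx(1.0)

    def test_perpendicular_bonds_give_minus_half(self):
        tails = self.straight_tails([0.0, 0.0, 0.0])
        assert poremap.lipid_order(tails, np.array([0, 0, 1.0])) == pytest.approx(-0.5)

    def test_mean_cosine_half_gives_minus_eighth(self):
        tails = self.straight_tails([0.8, 0.2])  # <cos> = 0.5
        assert poremap.lipid_order(tails, np.array([0, 0, 1.0])) == pytest.approx(-0.125)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_bounded(self, seed):
        rng = np.random.default_rng(seed)
        tails = rng.normal(0, 1, (4, 2, 4, 3))
        p2 = poremap.lipid_order(tails, np.array([0, 0, 1.0]))
        assert np.all(p2 >= -0.5 - 1e-12) and np.all(p2 <= 1 + 1e-12)

    def test_monotone_decreasing_with_injected_noise(self):
        from tests.conftest import small_config
        vals = []
        for disorder in (0.0, 0.3, 0.6):
            cfg = small_config(base_disorder=disorder, order_coupling=0.0,
                               disorder_heterogeneity=0.0, seed=3)
            fr = poremap.gen_frame(cfg, poremap.gen_composition_fields(cfg))
            ok = np.isfinite(fr.tails[:, 0, 0, 0])
            p2 = poremap.lipid_order(fr.tails[ok],
                                     np.tile([0, 0, 1.0], (ok.sum(), 1)))
            vals.append(np.mean(p2))
        assert vals[0] > vals[1] > vals[2]

    def test_headless_lipid_undefined(self):
        p2 = poremap.lipid_order(np.full((2, 3, 3), np.nan), np.array([0, 0, 1.0]))
        assert np.isnan(p2)


class TestDipoleCos:
    def test_along_normal(self):
        assert sf.dipole_cos(np.zeros(3), np.array([0, 0, 0.25]),
                             np.array([0, 0, 1.0])) == pytest.approx(1.0)

    def test_in_plane(self):
        assert sf.dipole_cos(np.zeros(3), np.array([0.25, 0, 0]),
                             np.array([0, 0, 1.0])) == pytest.approx(0.0)

    def test_sixty_degrees(self):
        v = np.array([math.sin(math.pi / 3), 0, math.cos(math.pi / 3)])
        assert sf.dipole_cos(np.zeros(3), 0.25 * v,
                             np.array([0, 0, 1.0])) == pytest.approx(0.5)


class TestLocalSurface:
    def test_flat_bilayer_thickness_curvature_apl(self):
        fr = flat_bilayer()
        surf = sf.local_surface(fr, "outer", leaflets=fr.leaflets)
        assert np.allclose(surf.thickness, 4.0, atol=1e-9)
        assert np.nanmax(np.abs(surf.curvature)) < 1e-6
        n = (fr.leaflets == "outer").sum()
        assert np.nansum(surf.apl) == pytest.approx(30.0 ** 2, rel=1e-9)
        assert np.nanmean(surf.apl) == pytest.approx(30.0 ** 2 / n, rel=1e-9)

    def test_sphere_section_mean_curvature(self):
        R = 10.0
        rng = np.random.default_rng(0)
        xy = rng.uniform(-4, 4, (600, 2))
        z = np.sqrt(R ** 2 - (xy ** 2).sum(axis=1))
        cap = np.column_stack([xy + 15.0, z - R + 6.0])  # dome peak at z=6
        flat = np.column_stack([rng.uniform(0, 30, (400, 2)), np.full(400, 1.0)])
        heads = np.vstack([cap, flat])
        leaf = np.array(["outer"] * len(cap) + ["inner"] * len(flat), dtype=object)
        fr = make_frame(heads, leaf)
        surf = sf.local_surface(fr, "outer", leaflets=fr.leaflets)
        central = (np.abs(cap[:, 0] - 15) < 2) & (np.abs(cap[:, 1] - 15) < 2)
        est = np.nanmean(np.abs(surf.curvature[central]))
        assert est == pytest.approx(1.0 / R, rel=0.10)

    def test_too_few_lipids_rejected(self):
        fr = flat_bilayer(n_side=2)
        with pytest.raises(ValueError):
            sf.local_surface(fr, "outer", leaflets=fr.leaflets)


class TestAssignLeaflets:
    def test_flat_matches_ground_truth(self, frame):
        assert (sf.assign_leaflets(frame) == frame.leaflets).mean() == 1.0

    def test_undulating_bilayer(self):
        rng = np.random.default_rng(1)
        xy = rng.uniform(0, 30, (800, 2))
        wave = np.sin(2 * np.pi * xy[:, 0] / 30.0)
        outer = np.column_stack([xy, 6.5 + wave])
        inner = np.column_stack([xy, 2.5 + wave])
        heads = np.vstack([outer, inner])
        leaf = np.array(["outer"] * 800 + ["inner"] * 800, dtype=object)
        fr = make_frame(heads, leaf)
        agreement = (sf.assign_leaflets(fr) == fr.leaflets).mean()
        assert agreement >= 0.99

    def test_z_flip_swaps_labels(self, frame):
        flipped = frame.copy()
        flipped.head_pos[:, 2] = frame.box[2] - frame.head_pos[:, 2]
        a = sf.assign_leaflets(frame)
        b = sf.assign_leaflets(flipped)
        swap = np.where(a == "outer", "inner", "outer")
        assert (b == swap).mean() == 1.0


class TestGroupDensity:
    def test_all_and_none(self, frame):
        q = np.array([[15.0, 15.0]])
        labels = frame.leaflets
        dens = {g: sf.group_density(frame, g, q, leaflet="outer",
                                    leaflets=labels)[0]
                for g in DENSITY_GROUPS}
        heads12 = ["PC", "PE", "SM", "GM", "PS", "PI", "PA", "PIP",
                   "LPC", "CE", "DAG", "CHOL"]
        assert sum(dens[g] for g in heads12) == pytest.approx(1.0, abs=1e-9)
        assert dens["FS"] + dens["MU"] + dens["PU"] + dens["CHOL"] == \
            pytest.approx(1.0, abs=1e-9)

    def test_unknown_residue_fails_loudly(self, frame):
        bad = frame.copy()
        bad.resnames[0] = "XXXX"
        with pytest.raises(UnknownResidueError, match="XXXX"):
            sf.group_density(bad, "PC", np.array([[1.0, 1.0]]))


@pytest.fixture(scope="module")
def small_matrix(config, fields):
    traj = poremap.gen_trajectory(config, 3, fields=fields)
    locations = pd.DataFrame({"x_rel": [0.2, 0.5, 0.8],
                              "y_rel": [0.3, 0.5, 0.1],
                              "label": [1, 0, 0]})
    return traj, locations


class TestFeatureMatrix:
    def test_shape_contract(self, small_matrix):
        traj, locations = small_matrix
        fm = poremap.feature_matrix(traj, locations)
        assert len(fm) == 3 * 3
        assert all(c in fm.columns for c in sf.ALL_FEATURES)
        assert fm["label"].sum() == 3

    def test_per_leaflet_mean_equals_default(self, small_matrix):
        traj, locations = small_matrix
        avg = poremap.feature_matrix(traj, locations)
        split = poremap.feature_matrix(traj, locations, per_leaflet=True)
        paired = 0.5 * (split["PU_inner"] + split["PU_outer"])
        assert np.allclose(paired, avg["PU"], atol=1e-12)

    def test_uniform_membrane_gives_configured_pu(self, small_matrix):
        from tests.conftest import small_config
        cfg = small_config(correlation_length=np.inf)
        fl = poremap.gen_composition_fields(cfg)
        traj = poremap.gen_trajectory(cfg, 2, fields=fl)
        locations = pd.DataFrame({"x_rel": [0.25, 0.75], "y_rel": [0.25, 0.75],
                                  "label": [0, 0]})
        fm = poremap.feature_matrix(traj, locations)
        pu_cfg = 0.5 * sum(
            sum(v for sp, v in cfg.group_fractions[leaf].items()
                if poremap.synthetic.tail_group(sp) == "PU")
            for leaf in ("inner", "outer"))
        assert np.abs(fm["PU"] - pu_cfg).max() < 0.08  # binomial scatter only

    def test_location_outside_box_rejected(self, small_matrix):
        traj, _ = small_matrix
        bad = pd.DataFrame({"x_rel": [1.2], "y_rel": [0.5], "label": [0]})
        with pytest.raises(ValueError):
            poremap.feature_matrix(traj, bad)
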