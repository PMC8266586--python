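"""Accessible volumes, distance distributions, state mapping, PDB I/O."""

import heapq
import itertools

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from if3cycle.structure import (AccessibleVolume, BuriedSiteWarning, DyeSpec,
                                Structure, StructureFormatError,
                                av_distance_distribution, compute_av,
                                interdomain_coordinate, map_states,
                                read_structure, vdw_radius, write_av_pdb,
                                write_structure)
from if3cycle.synthetic import ToyStructureSpec, gen_toy_structure


def brute_force_av(structure, dye, spacing):
    """Independent oracle: exhaustive per-node check with heapq Dijkstra.

    Re-derives the AV contract from scratch: grid nodes on the cube of
    side 2*(linker_length + dye_radius), clearance thresholds for
    passability and dye placement, line-of-sight entry distances, and a
    hand-rolled Dijkstra over the 26-connected neighbourhood.
    """
    att = structure.atom_index(dye.attachment_serial)
    origin = structure.coords[att]
    others = np.delete(np.arange(len(structure)), att)
    axyz = structure.coords[others]
    ar = structure.radii[others]
    L, w2, rd = dye.linker_length, dye.linker_width / 2, dye.dye_radius
    half = L + rd
    n = int(np.floor(half / spacing))
    rng = range(-n, n + 1)

    def clearance(p):
        if len(axyz) == 0:
            return np.inf
        return np.min(np.linalg.norm(axyz - p, axis=1) - ar)

    nodes = {}
    for ijk in itertools.product(rng, rng, rng):
        p = origin + spacing * np.array(ijk, dtype=float)
        c = clearance(p)
        nodes[ijk] = (p, c)

    def los_ok(p):
        d = np.linalg.norm(p - origin)
        m = max(1, int(np.ceil(2 * d / spacing)))
        for k in range(1, m + 1):
            if clearance(origin + (p - origin) * k / m) <= w2:
                return False
        return True

    dist = {}
    heap = []
    for ijk, (p, c) in nodes.items():
        if c > w2 and np.linalg.norm(p - origin) <= L and los_ok(p):
            d = float(np.linalg.norm(p - origin))
            dist[ijk] = d
            heapq.heappush(heap, (d, ijk))
    offsets = [o for o in itertools.product((-1, 0, 1), repeat=3) if o != (0, 0, 0)]
    while heap:
        d, ijk = heapq.heappop(heap)
        if d > dist.get(ijk, np.inf):
            continue
        for off in offsets:
            nb = tuple(a + b for a, b in zip(ijk, off))
            if nb not in nodes or nodes[nb][1] <= w2:
                continue
            nd = d + spacing * float(np.linalg.norm(off))
            if nd < dist.get(nb, np.inf):
                dist[nb] = nd
                heapq.heappush(heap, (nd, nb))
    points = sorted(
        tuple(np.round(nodes[ijk][0], 6))
        for ijk, d in dist.items()
        if d <= L + 1e-9 and nodes[ijk][1] > rd
    )
    return points


class TestAccessibleVolume:
    def test_unobstructed_site_matches_analytic_ball_volume(self, isolated_pair):
        dye = DyeSpec(attachment_serial=1)
        av = compute_av(isolated_pair, dye, grid_spacing=1.0)
        ball = 4.0 / 3.0 * np.pi * dye.linker_length ** 3
        shell = 4.0 * np.pi * dye.linker_length ** 2 * 1.0
        assert abs(av.volume - ball) <= shell

    def test_volume_converges_with_finer_grid(self, isolated_pair):
        dye = DyeSpec(attachment_serial=1)
        ball = 4.0 / 3.0 * np.pi * dye.linker_length ** 3
        err = {s: abs(compute_av(isolated_pair, dye, grid_spacing=s).volume - ball)
               for s in (1.0, 0.5)}
        assert err[0.5] <= err[1.0]

    def test_slab_confines_av_to_open_half_space(self, slab_structure):
        av = compute_av(slab_structure, DyeSpec(attachment_serial=1),
                        grid_spacing=1.0)
        # slab surface tops out at z = -2; dye centre must clear it by its radius
        assert len(av) > 0
        assert av.points[:, 2].min() > -2.0

    def test_every_av_point_satisfies_tether_and_clash_constraints(
            self, cluttered_structure):
        dye = DyeSpec(attachment_serial=1, linker_length=10.0)
        av = compute_av(cluttered_structure, dye, grid_spacing=1.0)
        assert len(av) > 0
        assert np.all(av.geodesic <= dye.linker_length + 1e-9)
        others = cluttered_structure.coords[1:]
        radii = cluttered_structure.radii[1:]
        for p in av.points:
            clear = np.min(np.linalg.norm(others - p, axis=1) - radii)
            assert clear > dye.dye_radius

    def test_matches_brute_force_oracle_on_small_fixture(self, cluttered_structure):
        dye = DyeSpec(attachment_serial=1, linker_length=8.0,
                      linker_width=3.0, dye_radius=3.0)
        av = compute_av(cluttered_structure, dye, grid_spacing=1.0)
        mine = sorted(tuple(np.round(p, 6)) for p in av.points)
        oracle = brute_force_av(cluttered_structure, dye, 1.0)
        assert mine == oracle

    def test_av_monotone_in_linker_length(self, cluttered_structure):
        short = compute_av(cluttered_structure,
                           DyeSpec(1, linker_length=8.0), grid_spacing=1.0)
        long = compute_av(cluttered_structure,
                          DyeSpec(1, linker_length=12.0), grid_spacing=1.0)
        short_set = {tuple(np.round(p, 6)) for p in short.points}
        long_set = {tuple(np.round(p, 6)) for p in long.points}
        assert 0 < len(short_set) < len(long_set)
        assert short_set <= long_set

    @pytest.mark.parametrize("grow", ["dye_radius", "linker_width"])
    def test_av_antimonotone_in_probe_size(self, cluttered_structure, grow):
        small = compute_av(cluttered_structure,
                           DyeSpec(1, linker_length=10.0, linker_width=3.0,
                                   dye_radius=3.0), grid_spacing=1.0)
        kwargs = dict(linker_length=10.0, linker_width=3.0, dye_radius=3.0)
        kwargs[grow] = 5.0
        big = compute_av(cluttered_structure, DyeSpec(1, **kwargs),
                         grid_spacing=1.0)
        small_set = {tuple(np.round(p, 6)) for p in small.points}
        big_set = {tuple(np.round(p, 6)) for p in big.points}
        assert len(big_set) > 0
        assert big_set <= small_set

    def test_buried_attachment_flagged_not_raised(self):
        # attachment caged by a tight cubic shell of carbons
        shell = [np.array(ijk, dtype=float) * 2.0
                 for ijk in itertools.product((-1, 0, 1), repeat=3)
                 if ijk != (0, 0, 0)]
        coords = np.vstack([[0.0, 0.0, 0.0]] + shell)
        n = len(coords)
        st = Structure(serial=np.arange(1, n + 1),
                       name=np.array(["SG"] + ["C"] * (n - 1)),
                       element=np.array(["S"] + ["C"] * (n - 1)),
                       res_seq=np.arange(1, n + 1),
                       res_name=np.array(["CYS"] + ["OBS"] * (n - 1)),
                       chain=np.array(["A"] * n), coords=coords,
                       radii=np.array([vdw_radius(e) for e in
                                       ["S"] + ["C"] * (n - 1)]),
                       source="cage")
        with pytest.warns(BuriedSiteWarning):
            av = compute_av(st, DyeSpec(attachment_serial=1), grid_spacing=1.0)
        assert av.buried and len(av) == 0

    def test_out_of_range_spacing_rejected(self, isolated_pair):
        with pytest.raises(ValueError):
            compute_av(isolated_pair, DyeSpec(1), grid_spacing=0.1)


class TestDistanceDistribution:
    @staticmethod
    def _point_av(xyz):
        return AccessibleVolume(points=np.array([xyz], dtype=float),
                                grid_spacing=1.0,
                                attachment_xyz=np.array(xyz, dtype=float),
                                geodesic=np.zeros(1))

    def test_two_point_masses_give_their_separation(self):
        d = av_distance_distribution(self._point_av([0, 0, 0]),
                                     self._point_av([0, 0, 42.0]))
        assert d.mean == d.min == d.max == pytest.approx(42.0)
        assert d.sd == 0.0 and d.n_pairs == 1

    def test_far_field_mean_approaches_centre_separation(self):
        sep = 750.0  # 50x the linker length
        st = gen_toy_structure(ToyStructureSpec(geometry="isolated-attachment",
                                                separation=sep))
        av1 = compute_av(st, DyeSpec(1), grid_spacing=1.0)
        av2 = compute_av(st, DyeSpec(2), grid_spacing=1.0)
        d = av_distance_distribution(av1, av2, mode="montecarlo",
                                     n_samples=100_000, seed=0)
        assert d.mean == pytest.approx(sep, rel=0.005)

    def test_montecarlo_agrees_with_exhaustive_within_3se(self, cluttered_structure):
        dye = DyeSpec(1, linker_length=8.0, linker_width=3.0, dye_radius=3.0)
        av = compute_av(cluttered_structure, dye, grid_spacing=1.0)
        shifted = av.transformed(np.eye(3), np.array([25.0, 0.0, 0.0]))
        ex = av_distance_distribution(av, shifted, mode="exhaustive")
        mc = av_distance_distribution(av, shifted, mode="montecarlo",
                                      n_samples=50_000, seed=1)
        se = mc.sd / np.sqrt(mc.n_pairs)
        assert abs(mc.mean - ex.mean) <= 3 * se

    def test_mean_invariant_under_joint_rigid_motion(self, isolated_pair):
        av1 = compute_av(isolated_pair, DyeSpec(1), grid_spacing=1.5)
        av2 = compute_av(isolated_pair, DyeSpec(2), grid_spacing=1.5)
        base = av_distance_distribution(av1, av2, mode="montecarlo",
                                        n_samples=20_000, seed=3)
        R = Rotation.from_euler("xyz", [0.3, -1.1, 2.0]).as_matrix()
        t = np.array([5.0, -17.0, 8.0])
        moved = av_distance_distribution(av1.transformed(R, t),
                                         av2.transformed(R, t),
                                         mode="montecarlo",
                                         n_samples=20_000, seed=3)
        assert moved.mean == pytest.approx(base.mean, rel=1e-12)

    def test_histogram_counts_sum_to_pair_count(self, isolated_pair):
        av1 = compute_av(isolated_pair, DyeSpec(1), grid_spacing=2.0)
        av2 = compute_av(isolated_pair, DyeSpec(2), grid_spacing=2.0)
        d = av_distance_distribution(av1, av2, mode="exhaustive")
        assert d.counts.sum() == d.n_pairs == len(av1) * len(av2)
        assert d.min <= d.mean <= d.max

    def test_empty_av_rejected(self):
        empty = AccessibleVolume(points=np.empty((0, 3)), grid_spacing=1.0,
                                 attachment_xyz=np.zeros(3),
                                 geodesic=np.empty(0), buried=True)
        with pytest.raises(ValueError):
            av_distance_distribution(empty, self._point_av([0, 0, 0]))


class TestInterdomainCoordinate:
    def test_constructed_marker_distance(self):
        st = gen_toy_structure(ToyStructureSpec(geometry="two-domain",
                                                separation=33.0))
        assert interdomain_coordinate(st, 65, 166) == pytest.approx(33.0)

    def test_missing_residue_raises_with_selector(self):
        st = gen_toy_structure(ToyStructureSpec(geometry="two-domain",
                                                separation=33.0))
        with pytest.raises(KeyError, match="res_seq"):
            interdomain_coordinate(st, 65, 999)

    def test_frame_ensemble_matches_hand_computed_norms(self):
        st = gen_toy_structure(ToyStructureSpec(geometry="two-domain",
                                                separation=30.0))
        rng = np.random.default_rng(4)
        frames = np.repeat(st.coords[None], 10, axis=0) + rng.normal(
            0, 0.5, size=(10, len(st), 3))
        series = interdomain_coordinate(st, 65, 166, frames=frames)
        ia = st.atom_index(st.find_atom(res_seq=65, name="CA"))
        ib = st.atom_index(st.find_atom(res_seq=166, name="CA"))
        expected = [np.sqrt(np.sum((f[ia] - f[ib]) ** 2)) for f in frames]
        np.testing.assert_allclose(series, expected, rtol=1e-12)


class TestMapStates:
    def test_two_states_align_perfectly_inverse(self):
        smap = map_states({"open": 60.0, "closed": 40.0},
                          {"open": 0.0, "closed": 1.0})
        assert smap.rank_correlation == pytest.approx(-1.0)
        np.testing.assert_allclose(smap.table["predicted_level"],
                                   smap.table["normalized_level"])

    def test_output_invariant_under_input_permutation(self):
        d = {"a": 60.0, "b": 45.0, "c": 50.0}
        lv = {"a": 0.0, "b": 0.9, "c": 0.5}
        fwd = map_states(d, lv)
        perm = map_states(dict(reversed(d.items())), dict(reversed(lv.items())))
        assert fwd.table.equals(perm.table)
        assert fwd.rank_correlation == perm.rank_correlation

    def test_monotone_six_state_cycle_recovers_exact_rank_alignment(self):
        dists = {f"s{i}": 60.0 - 4.0 * i for i in range(6)}
        levels = {f"s{i}": 0.1 * i for i in range(6)}
        smap = map_states(dists, levels)
        assert smap.rank_correlation == pytest.approx(-1.0)
        assert list(smap.table["state"]) == [f"s{i}" for i in range(6)]

    def test_degenerate_distances_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            map_states({"a": 50.0, "b": 50.0}, {"a": 0.0, "b": 1.0})


class TestPdbIO:
    def test_malformed_atom_line_error_names_the_line(self, tmp_path):
        bad = tmp_path / "bad.pdb"
        bad.write_text(
            "ATOM      1  CA  GLY A   1      10.000  10.000  10.000"
            "  1.00  0.00           C\n"
            "ATOM      2  CA  GLY A   2      xx.000  10.000  10.000"
            "  1.00  0.00           C\n")
        with pytest.raises(StructureFormatError, match="line 2"):
            read_structure(bad)

    def test_chain_exclusion_drops_exactly_that_chain(self, tmp_path,
                                                      slab_structure):
        path = tmp_path / "slab.pdb"
        write_structure(slab_structure, path)
        full = read_structure(path)
        pruned = read_structure(path, exclude_chains=("B",))
        n_b = int(np.sum(full.chain == "B"))
        assert n_b > 0
        assert len(full) - len(pruned) == n_b

    def test_av_cloud_pdb_round_trips_point_count(self, tmp_path, isolated_pair):
        av = compute_av(isolated_pair, DyeSpec(1), grid_spacing=2.0)
        out = tmp_path / "av.pdb"
        write_av_pdb(av, out)
        cloud = read_structure(out)
        assert len(cloud) == len(av)
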