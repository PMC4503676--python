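"""Domain types, CSV round trips and the nest-merging rule."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from antgrad import (
    Colony,
    ColonyMap,
    OccupancyMatrix,
    SiteRecord,
    forager_number,
    merge_close_nests,
    read_colony_table,
    read_occupancy,
    read_sites,
    write_colony_table,
    write_occupancy,
    write_sites,
)


def _write(tmp_path, text, name="colonies.csv"):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestColonyTable:
    def test_parses_valid_rows(self, tmp_path):
        p = _write(
            tmp_path,
            "species,group,x,y,count_1,count_2,count_3,count_4\n"
            "Monomorium,generalist,1.0,2.0,3,17,9,2\n"
            "Tapinoma,generalist,5.5,7.25,4,,,\n"
            "Messor1,seed_specialist,10.0,3.0,5,,,\n",
        )
        cmap = read_colony_table(p, 20, 15, year=2007)
        assert len(cmap) == 3
        assert cmap.colonies[0].forager_counts == (3, 17, 9, 2)
        assert cmap.colonies[1].forager_counts == (4,)
        assert cmap.year == 2007

    def test_out_of_bounds_coordinate_rejected(self, tmp_path):
        p = _write(tmp_path, "species,group,x,y\nA,generalist,-1.0,2.0\n")
        with pytest.raises(ValueError, match="outside"):
            read_colony_table(p, 20, 15)

    def test_malformed_row_names_line(self, tmp_path):
        p = _write(tmp_path, "species,group,x,y\nA,generalist,oops,2.0\n")
        with pytest.raises(ValueError, match="line 2"):
            read_colony_table(p, 20, 15)

    def test_empty_file_gives_empty_map_with_warning(self, tmp_path, caplog):
        p = _write(tmp_path, "")
        with caplog.at_level("WARNING", logger="antgrad"):
            cmap = read_colony_table(p, 20, 15)
        assert len(cmap) == 0
        assert any("empty" in r.message for r in caplog.records)

    def test_round_trip_preserves_fields(self, tmp_path):
        original = ColonyMap(
            "p1", 20, 15, 2008,
            [
                Colony("A", "generalist", 1.234567891, 2.0, (3, 17)),
                Colony("B", "seed_specialist", 19.99, 14.99, (5,)),
            ],
        )
        path = tmp_path / "rt.csv"
        write_colony_table(original, path)
        back = read_colony_table(path, 20, 15, plot_id="p1", year=2008)
        for a, b in zip(original.colonies, back.colonies):
            assert a.species == b.species
            assert a.functional_group == b.functional_group
            assert a.forager_counts == b.forager_counts
            assert abs(a.x - b.x) < 1e-9 and abs(a.y - b.y) < 1e-9


class TestForagerNumber:
    @pytest.mark.parametrize(
        "counts,expected", [((3, 17, 9, 2), 17), ((5,), 5), ((0, 0, 0, 0), 0)]
    )
    def test_max_over_periods(self, counts, expected):
        assert forager_number(Colony("A", "generalist", 0, 0, counts)) == expected

    def test_no_counts_is_an_error(self):
        with pytest.raises(ValueError, match="no recorded forager counts"):
            forager_number(Colony("A", "generalist", 0, 0, ()))


class TestMergeCloseNests:
    def _map(self, coords, species=None, counts=None):
        species = species or ["A"] * len(coords)
        counts = counts or [(1,)] * len(coords)
        return ColonyMap(
            "p", 100, 100, 0,
            [Colony(s, "generalist", x, y, c)
             for s, (x, y), c in zip(species, coords, counts)],
        )

    def test_pair_below_threshold_merges_to_centroid(self):
        merged = merge_close_nests(self._map([(1.0, 1.0), (1.5, 1.0)]))
        assert len(merged) == 1
        assert merged.colonies[0].x == pytest.approx(1.25)

    def test_exactly_threshold_apart_stays_separate(self):
        merged = merge_close_nests(self._map([(1.0, 1.0), (2.0, 1.0)]))
        assert len(merged) == 2

    def test_chain_merges_transitively(self):
        # A-B 0.8 m, B-C 0.8 m, A-C 1.6 m: one nest via the closure,
        # cross-checked against an independent union-find oracle
        coords = [(0.0, 0.0), (0.8, 0.0), (1.6, 0.0)]
        merged = merge_close_nests(self._map(coords))
        assert len(merged) == 1
        assert len(_union_find_clusters(coords, 1.0)) == 1

    def test_forager_counts_combined_elementwise_max(self):
        merged = merge_close_nests(
            self._map([(0, 0), (0.5, 0)], counts=[(3, 17), (9, 2, 4)])
        )
        assert merged.colonies[0].forager_counts == (9, 17, 4)

    def test_different_species_never_merge(self):
        merged = merge_close_nests(self._map([(0, 0), (0.1, 0)], species=["A", "B"]))
        assert len(merged) == 2

    @given(
        coords=st.lists(
            st.tuples(
                st.floats(0, 50, allow_nan=False), st.floats(0, 50, allow_nan=False)
            ),
            min_size=1,
            max_size=12,
        ),
        labels=st.lists(st.sampled_from("AB"), min_size=12, max_size=12),
    )
    @settings(max_examples=60, deadline=None)
    def test_merge_is_idempotent_and_never_grows(self, coords, labels):
        cmap = self._map(coords, species=labels[: len(coords)])
        once = merge_close_nests(cmap)
        twice = merge_close_nests(once)
        assert len(once) <= len(cmap)
        assert {c.species for c in once.colonies} == {c.species for c in cmap.colonies}
        assert len(twice) == len(once)
        assert all(
            (a.x, a.y, a.forager_counts) == (b.x, b.y, b.forager_counts)
            for a, b in zip(once.colonies, twice.colonies)
        )


def _union_find_clusters(coords, threshold):
    parent = list(range(len(coords)))

    def find(i):
        while parent[i] != i:
            i = parent[i]
        return i

    for i in range(len(coords)):
        for j in range(i + 1, len(coords)):
            d = np.hypot(coords[i][0] - coords[j][0], coords[i][1] - coords[j][1])
            if d < threshold:
                parent[find(j)] = find(i)
    return {find(i) for i in range(len(coords))}


class TestOccupancyIO:
    def test_round_trip_identity(self, tmp_path, rng):
        mat = OccupancyMatrix(
            [f"sp{i}" for i in range(4)],
            [f"b{j}" for j in range(10)],
            rng.integers(0, 2, size=(4, 10)),
        )
        path = tmp_path / "occ.csv"
        write_occupancy(mat, path)
        assert read_occupancy(path) == mat

    def test_non_binary_cell_rejected(self, tmp_path):
        p = _write(tmp_path, "species,b1,b2\nA,1,2\n", "occ.csv")
        with pytest.raises(ValueError, match="0 or 1"):
            read_occupancy(p)

    def test_duplicate_bait_label_rejected(self, tmp_path):
        p = _write(tmp_path, "species,b1,b1\nA,1,0\n", "occ.csv")
        with pytest.raises(ValueError, match="duplicate"):
            read_occupancy(p)

    def test_bait_plot_mapping_file(self, tmp_path):
        occ = _write(tmp_path, "species,b1,b2\nA,1,0\nB,0,1\n", "occ.csv")
        mp = _write(tmp_path, "bait,plot\nb1,p1\nb2,p2\n", "map.csv")
        mat = read_occupancy(occ, mp)
        assert mat.bait_plot == {"b1": "p1", "b2": "p2"}


class TestDomainInvariants:
    def test_colony_outside_plot_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            ColonyMap("p", 20, 15, 0, [Colony("A", "generalist", 21.0, 1.0)])

    def test_matrix_rejects_bad_values(self):
        with pytest.raises(ValueError, match="0 or 1"):
            OccupancyMatrix(["A"], ["b1"], [[2]])

    def test_row_totals_and_shared(self, checkerboard_2x3):
        assert checkerboard_2x3.row_totals().tolist() == [1, 1]
        assert checkerboard_2x3.pair_shared()[0, 1] == 0

    def test_site_record_validation(self):
        with pytest.raises(ValueError):
            SiteRecord("bad", -5, {}, 20.0, 100.0)

    def test_sites_round_trip(self, tmp_path, sites):
        path = tmp_path / "sites.csv"
        write_sites(sites, path)
        back = read_sites(path)
        assert [s.site_name for s in back] == [s.site_name for s in sites]
        assert all(
            a.precip_by_year == b.precip_by_year and a.biomass_mean == b.biomass_mean
            for a, b in zip(back, sites)
        )
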