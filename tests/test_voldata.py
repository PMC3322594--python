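"""Map and structure I/O: format round-trips, ordering, subset enforcement."""

import numpy as np
import pytest

from minisitus.voldata import (AtomicModel, MapFormatError, VolumeMap, read_mrc,
                               read_pdb, read_situs, write_mrc, write_pdb,
                               write_situs)


def random_map(rng, dims=(4, 5, 6), width=2.0, origin=(1.0, -2.0, 3.5)):
    return VolumeMap(width, origin, rng.normal(size=dims))


class TestSitusFormat:
    def test_minimal_file(self, tmp_path):
        path = tmp_path / "m.situs"
        path.write_text("2.0 0 0 0 2 1 1\n1 2\n")
        m = read_situs(path)
        assert m.width == 2.0
        assert m.dims == (2, 1, 1)
        assert m.data[0, 0, 0] == 1 and m.data[1, 0, 0] == 2

    def test_round_trip_token_identity(self, tmp_path, rng):
        m = random_map(rng)
        p1, p2 = tmp_path / "a.situs", tmp_path / "b.situs"
        write_situs(m, p1)
        write_situs(read_situs(p1), p2)
        assert p1.read_text().split() == p2.read_text().split()

    def test_round_trip_precision(self, tmp_path, rng):
        m = random_map(rng)
        path = tmp_path / "m.situs"
        write_situs(m, path)
        back = read_situs(path)
        assert np.allclose(back.data, m.data, rtol=1e-5)  # 6 significant digits
        assert np.allclose(back.origin, m.origin)
        assert back.width == m.width

    def test_x_fastest_ordering(self, tmp_path):
        # voxel (i,j,k) holds its own x-fastest linear index
        data = np.arange(8.0).reshape((2, 2, 2), order="F")
        path = tmp_path / "m.situs"
        write_situs(VolumeMap(1.0, (0, 0, 0), data), path)
        tokens = path.read_text().split()
        assert [float(t) for t in tokens[7:]] == list(range(8))

    def test_single_voxel_eighth_token(self, tmp_path):
        path = tmp_path / "m.situs"
        write_situs(VolumeMap(1.0, (0, 0, 0), np.full((1, 1, 1), 5.0)), path)
        assert float(path.read_text().split()[7]) == 5.0

    @pytest.mark.parametrize("content", [
        "2.0 0 0 0 2 2 2\n1 2 3 4 5",          # 5 of 8 values
        "2.0 0 0 x 2 1 1\n1 2",                 # non-numeric header
        "-1.0 0 0 0 2 1 1\n1 2",                # non-positive width
        "2.0 0 0\n",                            # short header
    ])
    def test_malformed_files_rejected(self, tmp_path, content):
        path = tmp_path / "bad.situs"
        path.write_text(content)
        with pytest.raises(MapFormatError):
            read_situs(path)

    def test_arbitrary_whitespace_tolerated(self, tmp_path):
        path = tmp_path / "m.situs"
        path.write_text("1.5\n1 2 3\n2 1\n2\n  4\t5\n6 7\n")
        m = read_situs(path)
        assert m.dims == (2, 1, 2)
        assert list(m.data.ravel(order="F")) == [4, 5, 6, 7]


class TestMRCFormat:
    def test_round_trip(self, tmp_path, rng):
        m = random_map(rng)
        path = tmp_path / "m.mrc"
        write_mrc(m, path)
        back = read_mrc(path)
        assert np.allclose(back.data, m.data, atol=1e-6)
        assert np.allclose(back.origin, m.origin, atol=1e-5)
        assert abs(back.width - m.width) < 1e-6

    def test_byte_swapped_copy_reads_identically(self, tmp_path, rng):
        m = random_map(rng)
        p1, p2 = tmp_path / "le.mrc", tmp_path / "be.mrc"
        write_mrc(m, p1)
        raw = np.frombuffer(p1.read_bytes(), dtype="<u4")
        p2.write_bytes(raw.byteswap().tobytes())
        le, be = read_mrc(p1), read_mrc(p2)
        assert np.array_equal(le.data, be.data)
        assert np.array_equal(le.origin, be.origin)

    def test_unsupported_mode_rejected(self, tmp_path, rng):
        path = tmp_path / "m.mrc"
        write_mrc(random_map(rng), path)
        raw = bytearray(path.read_bytes())
        raw[12:16] = (1).to_bytes(4, "little")  # mode 1 = 16-bit integer
        path.write_bytes(bytes(raw))
        with pytest.raises(MapFormatError, match="mode"):
            read_mrc(path)

    def test_permuted_axes_rejected(self, tmp_path, rng):
        path = tmp_path / "m.mrc"
        write_mrc(random_map(rng), path)
        raw = bytearray(path.read_bytes())
        raw[64:68] = (2).to_bytes(4, "little")  # MAPC=2: y fastest
        path.write_bytes(bytes(raw))
        with pytest.raises(MapFormatError, match="axis"):
            read_mrc(path)

    def test_truncated_file_rejected(self, tmp_path, rng):
        path = tmp_path / "m.mrc"
        write_mrc(random_map(rng), path)
        path.write_bytes(path.read_bytes()[:-40])
        with pytest.raises(MapFormatError, match="truncated"):
            read_mrc(path)

    def test_statistics_fields(self, tmp_path, rng):
        import struct
        m = random_map(rng)
        path = tmp_path / "m.mrc"
        write_mrc(m, path)
        raw = path.read_bytes()
        dmin, dmax, dmean = struct.unpack("<3f", raw[76:88])
        assert dmin == pytest.approx(m.data.min(), rel=1e-6)
        assert dmax == pytest.approx(m.data.max(), rel=1e-6)
        assert dmean == pytest.approx(m.data.mean(), abs=1e-6)

    def test_gemmi_reads_our_mrc(self, tmp_path, rng):
        gemmi = pytest.importorskip("gemmi")
        m = random_map(rng)
        path = tmp_path / "m.mrc"
        write_mrc(m, path)
        g = gemmi.read_ccp4_map(str(path))
        assert np.allclose(np.asarray(g.grid), m.data, atol=1e-5)
        assert g.grid.unit_cell.a == pytest.approx(m.dims[0] * m.width, rel=1e-6)

    def test_start_index_origin_fallback(self, tmp_path, rng):
        import struct
        m = random_map(rng, origin=(0.0, 0.0, 0.0))
        path = tmp_path / "m.mrc"
        write_mrc(m, path)
        raw = bytearray(path.read_bytes())
        struct.pack_into("<3i", raw, 16, 2, 3, 4)  # start indices, origin rec zero
        path.write_bytes(bytes(raw))
        back = read_mrc(path)
        assert np.allclose(back.origin, np.array([2, 3, 4]) * m.width)


class TestCrossFormat:
    def test_situs_and_mrc_writers_agree(self, tmp_path, rng):
        m = random_map(rng)
        write_situs(m, tmp_path / "m.situs")
        write_mrc(m, tmp_path / "m.mrc")
        a = read_situs(tmp_path / "m.situs")
        b = read_mrc(tmp_path / "m.mrc")
        assert np.allclose(a.data, b.data, rtol=1e-5, atol=1e-6)
        assert np.allclose(a.origin, b.origin, atol=1e-5)


class TestVolumeMapModel:
    def test_voxel_position_formula_all_corners(self, rng):
        m = random_map(rng, dims=(3, 4, 5), width=1.25, origin=(-2.0, 0.5, 7.0))
        for corner in [(0, 0, 0), (2, 0, 0), (0, 3, 0), (0, 0, 4), (2, 3, 4)]:
            expected = np.array(m.origin) + m.width * np.array(corner)
            assert np.allclose(m.voxel_position(*corner), expected)

    def test_invalid_maps_rejected(self):
        with pytest.raises(MapFormatError):
            VolumeMap(0.0, (0, 0, 0), np.zeros((2, 2, 2)))
        with pytest.raises(ValueError):
            VolumeMap(1.0, (0, 0, 0), np.zeros((2, 2)))


class TestPDBFormat:
    def test_single_atom_line(self, tmp_path):
        path = tmp_path / "a.pdb"
        path.write_text(
            "ATOM      1  CA  GLY A   1       1.000   0.000   0.000"
            "  1.00  0.00\n")
        model = read_pdb(path)
        assert len(model) == 1
        assert np.allclose(model.coords[0], [1, 0, 0])

    def test_round_trip_100_atoms(self, tmp_path, rng):
        model = AtomicModel(rng.uniform(-99, 99, (100, 3)).round(3),
                            occupancies=rng.uniform(0, 9, 100).round(2),
                            bfactors=rng.uniform(0, 99, 100).round(2))
        path = tmp_path / "m.pdb"
        write_pdb(model, path)
        back = read_pdb(path)
        assert np.array_equal(back.coords, model.coords)
        assert np.array_equal(back.occupancies, model.occupancies)
        assert np.array_equal(back.bfactors, model.bfactors)

    def test_occupancy_columns_55_to_60(self, tmp_path):
        model = AtomicModel([[0.0, 0.0, 0.0]], occupancies=np.array([3.0]))
        path = tmp_path / "m.pdb"
        write_pdb(model, path)
        line = path.read_text().splitlines()[0]
        assert line[54:60] == "  3.00"
        assert read_pdb(path).occupancies[0] == 3.0

    def test_gemmi_reads_our_pdb(self, tmp_path, rng):
        gemmi = pytest.importorskip("gemmi")
        model = AtomicModel(rng.uniform(-20, 20, (5, 3)).round(3),
                            occupancies=np.array([1.0, 0.5, 3.0, 0.25, 0.75]))
        path = tmp_path / "m.pdb"
        write_pdb(model, path)
        st = gemmi.read_structure(str(path))
        atoms = [a for mo in st for ch in mo for r in ch for a in r]
        assert np.allclose([[a.pos.x, a.pos.y, a.pos.z] for a in atoms],
                           model.coords)
        assert np.allclose([a.occ for a in atoms], model.occupancies)

    def test_no_atoms_rejected(self, tmp_path):
        path = tmp_path / "e.pdb"
        path.write_text("REMARK nothing here\nEND\n")
        with pytest.raises(MapFormatError):
            read_pdb(path)

    def test_malformed_coordinates_rejected(self, tmp_path):
        path = tmp_path / "b.pdb"
        path.write_text("ATOM      1  CA  GLY A   1       x.xxx   0.000   "
                        "0.000  1.00  0.00\n")
        with pytest.raises(MapFormatError):
            read_pdb(path)
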