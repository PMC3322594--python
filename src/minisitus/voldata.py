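"""Data model and I/O for density maps and atomic structures.

Three external formats are supported:

* the Situs ASCII map format — a seven-number header ``WIDTH ORIGX ORIGY
  ORIGZ NX NY NZ`` followed by NX*NY*NZ density values with the x index
  changing fastest and z slowest;
* a modern MRC/CCP4 binary subset — 32-bit float mode, axis order x,y,z,
  orthogonal cells with cubic voxels, either endianness (auto-detected);
* fixed-column PDB text (ATOM/HETATM records).

The in-memory :class:`VolumeMap` mirrors the Situs coordinate model: a
cubic lattice with scalar voxel spacing ``width`` (A) whose ``origin`` is
the physical coordinate of voxel (0,0,0); voxel (i,j,k) sits at
``origin + width*(i,j,k)``.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "VolumeMap",
    "AtomicModel",
    "MapHeaderMRC",
    "MapFormatError",
    "read_situs",
    "write_situs",
    "read_mrc",
    "write_mrc",
    "read_pdb",
    "write_pdb",
    "read_map",
    "write_map",
]


class MapFormatError(ValueError):
    """Raised for malformed or out-of-subset map and structure files."""


@dataclass
class VolumeMap:
    """Scalar density on a cubic lattice.

    Attributes
    ----------
    width : float
        Voxel spacing in Angstroms (isotropic).
    origin : ndarray, shape (3,)
        Physical coordinate (A) of voxel (0, 0, 0).
    data : ndarray, shape (nx, ny, nz)
        Density values; ``data[i, j, k]`` is the voxel at
        ``origin + width * (i, j, k)``.
    """

    width: float
    origin: np.ndarray
    data: np.ndarray

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be a 3-D array (nx, ny, nz)")
        if self.width <= 0:
            raise MapFormatError(f"voxel width must be positive, got {self.width}")
        if min(self.data.shape) < 1:
            raise ValueError("all dimensions must be >= 1")

    @property
    def dims(self) -> tuple:
        """(NX, NY, NZ) voxel counts."""
        return self.data.shape

    def voxel_position(self, i, j, k) -> np.ndarray:
        """Physical coordinate (A) of voxel (i, j, k), 0-based."""
        return self.origin + self.width * np.asarray([i, j, k], dtype=float)

    def voxel_positions(self) -> np.ndarray:
        """(N, 3) physical coordinates of all voxels in x-fastest order."""
        nx, ny, nz = self.dims
        idx = np.stack(np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                                   indexing="ij"), axis=-1)
        return self.origin + self.width * idx.reshape(-1, 3, order="F")

    def same_lattice(self, other: "VolumeMap", tol: float = 1e-6) -> bool:
        return (self.dims == other.dims
                and abs(self.width - other.width) <= tol * self.width
                and np.allclose(self.origin, other.origin, atol=tol))

    def copy(self) -> "VolumeMap":
        return VolumeMap(self.width, self.origin.copy(), self.data.copy())

    def with_data(self, data: np.ndarray) -> "VolumeMap":
        """Same lattice, new values."""
        return VolumeMap(self.width, self.origin.copy(), np.asarray(data, dtype=float))


@dataclass
class AtomicModel:
    """Ordered atom records with PDB round-trip fidelity.

    Coordinates are Angstroms; ``occupancy`` carries bead radii or encoded
    densities in the coarse-grained conventions of this package.
    """

    coords: np.ndarray
    names: list = None
    resnames: list = None
    chains: list = None
    resseqs: list = None
    occupancies: np.ndarray = None
    bfactors: np.ndarray = None

    def __post_init__(self):
        self.coords = np.atleast_2d(np.asarray(self.coords, dtype=float))
        n = len(self.coords)
        if self.coords.shape != (n, 3):
            raise ValueError("coords must be (N, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        if self.names is None:
            self.names = ["CA"] * n
        if self.resnames is None:
            self.resnames = ["GLY"] * n
        if self.chains is None:
            self.chains = ["A"] * n
        if self.resseqs is None:
            self.resseqs = list(range(1, n + 1))
        self.occupancies = (np.ones(n) if self.occupancies is None
                            else np.asarray(self.occupancies, dtype=float))
        self.bfactors = (np.zeros(n) if self.bfactors is None
                         else np.asarray(self.bfactors, dtype=float))

    def __len__(self) -> int:
        return len(self.coords)

    @property
    def centroid(self) -> np.ndarray:
        return self.coords.mean(axis=0)

    def transformed(self, rt) -> "AtomicModel":
        """Apply a :class:`~minisitus.transforms.RigidTransform`."""
        return AtomicModel(rt.apply(self.coords), list(self.names), list(self.resnames),
                           list(self.chains), list(self.resseqs),
                           self.occupancies.copy(), self.bfactors.copy())

    def with_coords(self, coords: np.ndarray) -> "AtomicModel":
        return AtomicModel(coords, list(self.names), list(self.resnames),
                           list(self.chains), list(self.resseqs),
                           self.occupancies.copy(), self.bfactors.copy())


# ---------------------------------------------------------------------------
# Situs ASCII format
# ---------------------------------------------------------------------------

def read_situs(path) -> VolumeMap:
    """Read a Situs ASCII map.

    The file starts with seven whitespace-separated numbers, ``WIDTH ORIGX
    ORIGY ORIGZ NX NY NZ``, followed by NX*NY*NZ density values in
    x-fastest order.  Whitespace and line breaks in the data section are
    arbitrary.
    """
    with open(path) as fh:
        tokens = fh.read().split()
    if len(tokens) < 7:
        raise MapFormatError(f"{path}: header needs 7 values, found {len(tokens)}")
    try:
        header = [float(t) for t in tokens[:7]]
    except ValueError as exc:
        raise MapFormatError(f"{path}: non-numeric header token: {exc}") from exc
    width, ox, oy, oz = header[:4]
    nx, ny, nz = (int(v) for v in header[4:7])
    if (nx, ny, nz) != tuple(header[4:7]) or min(nx, ny, nz) < 1:
        raise MapFormatError(f"{path}: dimensions must be positive integers")
    if width <= 0:
        raise MapFormatError(f"{path}: non-positive voxel width {width}")
    expected = nx * ny * nz
    if len(tokens) - 7 != expected:
        raise MapFormatError(
            f"{path}: expected {expected} density values, found {len(tokens) - 7}")
    try:
        values = np.array(tokens[7:], dtype=float)
    except ValueError as exc:
        raise MapFormatError(f"{path}: non-numeric density value: {exc}") from exc
    data = values.reshape((nx, ny, nz), order="F")  # x fastest in file
    return VolumeMap(width, (ox, oy, oz), data)


def write_situs(vmap: VolumeMap, path, per_line: int = 10) -> None:
    """Write a Situs ASCII map: one header line, then densities in
    x-fastest order, ``per_line`` values per line, 6 significant digits."""
    nx, ny, nz = vmap.dims
    flat = vmap.data.ravel(order="F")
    with open(path, "w") as fh:
        ox, oy, oz = vmap.origin
        fh.write(f"{vmap.width:.6g} {ox:.6g} {oy:.6g} {oz:.6g} {nx} {ny} {nz}\n\n")
        for start in range(0, len(flat), per_line):
            fh.write(" ".join(f"{v:.6g}" for v in flat[start:start + per_line]) + "\n")


# ---------------------------------------------------------------------------
# MRC / CCP4 binary subset
# ---------------------------------------------------------------------------

_MRC_HEADER_BYTES = 1024
_KNOWN_MODES = (0, 1, 2, 6, 12)
_FLOAT32_MODE = 2


@dataclass
class MapHeaderMRC:
    """Parsed MRC/CCP4 header fields relevant to the supported subset."""

    dims: tuple
    mode: int
    start: tuple
    intervals: tuple
    cell_lengths: tuple
    cell_angles: tuple
    axis_order: tuple
    dmin: float
    dmax: float
    dmean: float
    origin: tuple
    rms: float = 0.0
    nsymbt: int = 0
    byte_order: str = "<"


def _parse_mrc_header(raw: bytes, path) -> MapHeaderMRC:
    if len(raw) < _MRC_HEADER_BYTES:
        raise MapFormatError(f"{path}: truncated header ({len(raw)} bytes)")

    def ints(bo, n, off=0):
        return struct.unpack(f"{bo}{n}i", raw[off:off + 4 * n])

    # Endianness by header plausibility: dims within [1, 100000] and a
    # known mode code; files from either architecture are accepted.
    byte_order = None
    for bo in ("<", ">"):
        nx, ny, nz, mode = ints(bo, 4)
        if all(1 <= d <= 100000 for d in (nx, ny, nz)) and mode in _KNOWN_MODES:
            byte_order = bo
            break
    if byte_order is None:
        raise MapFormatError(f"{path}: header fails plausibility check (not MRC/CCP4?)")

    i = struct.unpack(f"{byte_order}10i", raw[0:40])
    f = struct.unpack(f"{byte_order}6f", raw[40:64])
    maps = struct.unpack(f"{byte_order}3i", raw[64:76])
    stats = struct.unpack(f"{byte_order}3f", raw[76:88])
    nsymbt = struct.unpack(f"{byte_order}i", raw[92:96])[0]
    origin = struct.unpack(f"{byte_order}3f", raw[196:208])
    rms = struct.unpack(f"{byte_order}f", raw[216:220])[0]
    return MapHeaderMRC(
        dims=i[0:3], mode=i[3], start=i[4:7], intervals=i[7:10],
        cell_lengths=f[0:3], cell_angles=f[3:6], axis_order=maps,
        dmin=stats[0], dmax=stats[1], dmean=stats[2], origin=origin,
        rms=rms, nsymbt=nsymbt, byte_order=byte_order)


def read_mrc(path) -> VolumeMap:
    """Read an MRC/CCP4 map within the supported subset.

    Subset rules, each enforced with a loud error: 32-bit float mode only;
    axis order must be x,y,z (MAPC,MAPR,MAPS = 1,2,3); cell angles 90
    degrees; voxel width equal on all axes within 0.1% (cubic lattice).
    The origin is taken from the ORIGIN record when any component is
    nonzero, otherwise computed as start indices times the voxel width.
    """
    with open(path, "rb") as fh:
        raw = fh.read()
    hdr = _parse_mrc_header(raw[:_MRC_HEADER_BYTES], path)
    if hdr.mode != _FLOAT32_MODE:
        raise MapFormatError(
            f"{path}: mode {hdr.mode} unsupported (only 32-bit float, mode 2)")
    if tuple(hdr.axis_order) != (1, 2, 3):
        raise MapFormatError(
            f"{path}: permuted axis order {hdr.axis_order} unsupported (need 1,2,3)")
    if not np.allclose(hdr.cell_angles, 90.0, atol=1e-3):
        raise MapFormatError(f"{path}: non-orthogonal cell angles {hdr.cell_angles}")
    widths = np.array(hdr.cell_lengths) / np.maximum(np.array(hdr.intervals), 1)
    if widths.min() <= 0:
        raise MapFormatError(f"{path}: non-positive voxel width")
    if (widths.max() - widths.min()) > 1e-3 * widths.mean():
        raise MapFormatError(
            f"{path}: non-cubic voxels {widths} (axes must agree within 0.1%)")
    width = float(widths.mean())

    nx, ny, nz = hdr.dims
    count = nx * ny * nz
    start = _MRC_HEADER_BYTES + hdr.nsymbt
    payload = raw[start:start + 4 * count]
    if len(payload) < 4 * count:
        raise MapFormatError(
            f"{path}: truncated data section ({len(payload)} of {4 * count} bytes)")
    values = np.frombuffer(payload, dtype=np.dtype(f"{hdr.byte_order}f4")).astype(float)
    data = values.reshape((nx, ny, nz), order="F")

    if np.any(np.asarray(hdr.origin) != 0.0):
        origin = np.asarray(hdr.origin, dtype=float)
    else:
        origin = np.asarray(hdr.start, dtype=float) * width
    return VolumeMap(width, origin, data)


def write_mrc(vmap: VolumeMap, path) -> None:
    """Write the map as little-endian MRC2014-style float32, axes x,y,z.

    The ORIGIN record carries the map origin; start indices are zero; the
    density statistics fields (min/max/mean/rms) are filled.
    """
    nx, ny, nz = vmap.dims
    data = vmap.data.astype("<f4")
    hdr = bytearray(_MRC_HEADER_BYTES)
    struct.pack_into("<10i", hdr, 0, nx, ny, nz, _FLOAT32_MODE, 0, 0, 0, nx, ny, nz)
    struct.pack_into("<6f", hdr, 40, nx * vmap.width, ny * vmap.width, nz * vmap.width,
                     90.0, 90.0, 90.0)
    struct.pack_into("<3i", hdr, 64, 1, 2, 3)
    struct.pack_into("<3f", hdr, 76, float(data.min()), float(data.max()),
                     float(data.mean()))
    struct.pack_into("<2i", hdr, 88, 1, 0)          # ISPG volume, NSYMBT 0
    struct.pack_into("<3f", hdr, 196, *vmap.origin)
    hdr[208:212] = b"MAP "
    hdr[212:216] = bytes([0x44, 0x44, 0x00, 0x00])  # little-endian MACHST
    struct.pack_into("<f", hdr, 216, float(data.std()))
    struct.pack_into("<i", hdr, 220, 1)
    hdr[224:224 + 80] = b"minisitus".ljust(80)
    with open(path, "wb") as fh:
        fh.write(bytes(hdr))
        fh.write(data.tobytes(order="F"))


_MRC_SUFFIXES = (".mrc", ".ccp4", ".map")


def read_map(path) -> VolumeMap:
    """Read a map, choosing the format by file suffix (.mrc/.ccp4/.map
    binary, anything else Situs ASCII)."""
    suffix = str(path).lower().rsplit(".", 1)
    if len(suffix) == 2 and f".{suffix[1]}" in _MRC_SUFFIXES:
        return read_mrc(path)
    return read_situs(path)


def write_map(vmap: VolumeMap, path) -> None:
    """Write a map, choosing the format by file suffix as in read_map."""
    suffix = str(path).lower().rsplit(".", 1)
    if len(suffix) == 2 and f".{suffix[1]}" in _MRC_SUFFIXES:
        write_mrc(vmap, path)
    else:
        write_situs(vmap, path)


# ---------------------------------------------------------------------------
# PDB fixed-column text
# ---------------------------------------------------------------------------

def read_pdb(path) -> AtomicModel:
    """Read ATOM/HETATM records from a PDB file; other records are ignored."""
    coords, names, resnames, chains, resseqs, occs, bfs = [], [], [], [], [], [], []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.startswith(("ATOM  ", "HETATM")):
                continue
            try:
                x = float(line[30:38])
                y = float(line[38:46])
                z = float(line[46:54])
            except ValueError as exc:
                raise MapFormatError(
                    f"{path}:{ln}: malformed coordinate columns") from exc
            coords.append((x, y, z))
            names.append(line[12:16].strip() or "CA")
            resnames.append(line[17:20].strip() or "GLY")
            chains.append(line[21].strip() or "A")
            try:
                resseqs.append(int(line[22:26]))
            except ValueError:
                resseqs.append(len(coords))
            occs.append(_float_or(line[54:60], 1.0))
            bfs.append(_float_or(line[60:66], 0.0))
    if not coords:
        raise MapFormatError(f"{path}: no ATOM/HETATM records found")
    return AtomicModel(np.array(coords), names, resnames, chains, resseqs,
                       np.array(occs), np.array(bfs))


def _float_or(text: str, default: float) -> float:
    try:
        return float(text)
    except ValueError:
        return default


def write_pdb(model: AtomicModel, path) -> None:
    """Write fixed-column ATOM records.

    Coordinates use columns 31-54 (%8.3f), occupancy 55-60 (%6.2f) and
    temperature factor 61-66 (%6.2f), per the PDB convention.
    """
    with open(path, "w") as fh:
        for i in range(len(model)):
            name = model.names[i]
            namef = f" {name:<3s}" if len(name) < 4 else name[:4]
            x, y, z = model.coords[i]
            fh.write(
                f"ATOM  {(i + 1) % 100000:5d} {namef} {model.resnames[i]:<3.3s} "
                f"{model.chains[i]:1.1s}{model.resseqs[i] % 10000:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}"
                f"{model.occupancies[i]:6.2f}{model.bfactors[i]:6.2f}\n")
        fh.write("END\n")
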