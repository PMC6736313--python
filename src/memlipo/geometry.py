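"""Structure parsing and per-residue membrane geometry.

Builds, from a PDB file with a declared membrane frame, the
per-residue quantities the energy terms consume: membrane depth at
the Cα, backbone (φ, ψ) dihedrals, a virtual Cβ for glycine, heavy-atom
neighbour counts within 6 and 12 Å of the Cβ, and per-segment helix
tilt angles relative to the membrane normal.

Conventions: depth is measured at the Cα (defined for every residue);
neighbour counts include heavy (non-hydrogen) protein atoms of *other*
residues only; alternate locations other than '' or 'A' are dropped,
as are waters, hetero-compounds and hydrogens.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import gemmi
import numpy as np
from scipy.spatial import cKDTree

from .errors import DataError, GeometryError, ParameterError

log = logging.getLogger(__name__)

PEPTIDE_BOND_MAX = 2.0  # Å, C(i)-N(i+1) distance defining chain continuity


@dataclass(frozen=True)
class MembraneFrame:
    """Membrane normal, midplane offset and leaflet sign convention.

    Depth of a point x is ``inner_leaflet_sign * (x . normal - midplane_offset)``;
    negative depths are the inner (cytoplasmic) leaflet.  The default
    frame matches OPM/PDBTM-style pre-oriented structures: normal along
    laboratory z, midplane at z = 0.
    """

    normal: tuple[float, float, float] = (0.0, 0.0, 1.0)
    midplane_offset: float = 0.0
    inner_leaflet_sign: int = 1

    def __post_init__(self):
        n = np.asarray(self.normal, dtype=float)
        norm = np.linalg.norm(n)
        if norm < 1e-12:
            raise ParameterError("membrane normal must be non-zero")
        object.__setattr__(self, "normal", tuple(n / norm))
        if self.inner_leaflet_sign not in (+1, -1):
            raise ParameterError("inner_leaflet_sign must be +1 or -1")

    @property
    def normal_array(self) -> np.ndarray:
        return np.asarray(self.normal)

    def depth(self, xyz) -> np.ndarray | float:
        xyz = np.asarray(xyz, dtype=float)
        return self.inner_leaflet_sign * (xyz @ self.normal_array
                                          - self.midplane_offset)


@dataclass
class ResidueRecord:
    """One residue's coordinates and derived membrane geometry."""

    chain: str
    resi: int
    amino_acid: str
    ca_xyz: np.ndarray
    n_xyz: np.ndarray
    c_xyz: np.ndarray
    cb_xyz: np.ndarray          # virtual for Gly / when Cβ is missing
    atoms: np.ndarray           # heavy-atom coordinates of this residue
    z: float = 0.0
    phi: float | None = None
    psi: float | None = None
    n6: int | float = 0
    n12: int | float = 0
    burial_weight: float | None = None
    cb_is_virtual: bool = False


@dataclass
class HelixSegment:
    """A helical span with its axis and membrane tilt."""

    chain: str
    start: int
    end: int
    axis: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    tilt_theta: float = 0.0


def dihedral(p1, p2, p3, p4) -> float:
    """Signed torsion angle p1-p2-p3-p4 in degrees, in (-180, 180]."""
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    b3 = np.asarray(p4) - np.asarray(p3)
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = np.linalg.norm(b2)
    if b2n < 1e-12 or np.linalg.norm(n1) < 1e-12 or np.linalg.norm(n2) < 1e-12:
        raise GeometryError("degenerate dihedral geometry")
    ang = np.degrees(np.arctan2(np.cross(n1, n2) @ (b2 / b2n), n1 @ n2))
    return 180.0 if ang <= -180.0 else ang


def place_atom(a, b, c, bond: float, angle: float, torsion: float) -> np.ndarray:
    """Place atom d from internal coordinates (NeRF).

    ``bond`` = |c-d|, ``angle`` = b-c-d in degrees, ``torsion`` =
    a-b-c-d in degrees.
    """
    a, b, c = (np.asarray(x, dtype=float) for x in (a, b, c))
    bc = c - b
    bc_n = np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n_n = np.linalg.norm(n)
    if bc_n < 1e-9 or n_n < 1e-9:
        raise GeometryError("collinear reference atoms")
    bc_u = bc / bc_n
    n_u = n / n_n
    m = np.cross(n_u, bc_u)
    ang = np.radians(angle)
    tor = np.radians(torsion)
    # sign convention chosen so that dihedral(a, b, c, result) == torsion
    d_local = bond * np.array([-np.cos(ang),
                               np.sin(ang) * np.cos(tor),
                               np.sin(ang) * np.sin(tor)])
    return c + d_local[0] * bc_u + d_local[1] * m + d_local[2] * n_u


# ideal tetrahedral Cβ geometry relative to the N-CA-C backbone frame
CB_BOND = 1.53
CB_ANGLE = 110.1          # N-CA-CB, degrees
CB_TORSION = -122.6       # C-N-CA-CB, degrees (L-amino acids)


def virtual_cb(n_xyz, ca_xyz, c_xyz) -> np.ndarray:
    """Ideal Cβ position from the backbone N, CA, C atoms."""
    return place_atom(c_xyz, n_xyz, ca_xyz, CB_BOND, CB_ANGLE, CB_TORSION)


def _one_letter(name: str) -> str | None:
    info = gemmi.find_tabulated_residue(name)
    if info is None or not info.is_amino_acid():
        return None
    code = info.one_letter_code.upper()
    return code if code.isalpha() else None


def load_structure(pdb_source, frame: MembraneFrame | None = None,
                   model_index: int = 0) -> list[ResidueRecord]:
    """Parse a PDB/mmCIF file into per-residue records.

    Keeps the first model by default (NMR entries are represented by
    their first model).  Residues missing any of N, CA, C are skipped
    with a warning.  Returns records with depth, virtual Cβ and (φ, ψ)
    already computed; neighbour counts are filled by
    :func:`annotate_neighbour_counts`.
    """
    frame = frame or MembraneFrame()
    if isinstance(pdb_source, gemmi.Structure):
        st = pdb_source
    else:
        st = gemmi.read_structure(str(pdb_source))
    if len(st) == 0:
        raise DataError("structure contains no models")
    model = st[model_index]

    records: list[ResidueRecord] = []
    for chain in model:
        for res in chain:
            aa = _one_letter(res.name)
            if aa is None or res.is_water():
                continue
            pos = {}
            heavy = []
            for atom in res:
                if atom.has_altloc() and atom.altloc != "A":
                    continue
                if atom.is_hydrogen():
                    continue
                xyz = np.array([atom.pos.x, atom.pos.y, atom.pos.z])
                heavy.append(xyz)
                pos[atom.name] = xyz
            if not all(k in pos for k in ("N", "CA", "C")):
                log.warning("skipping %s/%s%d: incomplete backbone",
                            chain.name, res.name, res.seqid.num)
                continue
            cb = pos.get("CB")
            cb_virtual = cb is None
            if cb_virtual:
                cb = virtual_cb(pos["N"], pos["CA"], pos["C"])
            records.append(ResidueRecord(
                chain=chain.name, resi=res.seqid.num, amino_acid=aa,
                ca_xyz=pos["CA"], n_xyz=pos["N"], c_xyz=pos["C"],
                cb_xyz=cb, atoms=np.array(heavy),
                z=float(frame.depth(pos["CA"])),
                cb_is_virtual=cb_virtual))
    if not records:
        raise DataError("no protein residues with complete backbones found")
    backbone_dihedrals(records)
    return records


def backbone_dihedrals(records: list[ResidueRecord]) -> list[ResidueRecord]:
    """Fill standard φ/ψ in degrees; None at termini and chain breaks."""
    for prev, cur in zip(records, records[1:]):
        if prev.chain != cur.chain:
            continue
        if np.linalg.norm(cur.n_xyz - prev.c_xyz) >= PEPTIDE_BOND_MAX:
            continue  # chain break: dihedrals stay undefined on both sides
        cur.phi = dihedral(prev.c_xyz, cur.n_xyz, cur.ca_xyz, cur.c_xyz)
        prev.psi = dihedral(prev.n_xyz, prev.ca_xyz, prev.c_xyz, cur.n_xyz)
    return records


def neighbour_counts(records: list[ResidueRecord],
                     target: int) -> tuple[int, int]:
    """Heavy atoms of *other* residues within 6 / 12 Å of the target Cβ."""
    cb = records[target].cb_xyz
    n6 = n12 = 0
    for i, rec in enumerate(records):
        if i == target or len(rec.atoms) == 0:
            continue
        d = np.linalg.norm(rec.atoms - cb, axis=1)
        n6 += int((d < 6.0).sum())
        n12 += int((d < 12.0).sum())
    return n6, n12


def annotate_neighbour_counts(records: list[ResidueRecord]) -> list[ResidueRecord]:
    """Fill n6/n12 for every record (KD-tree accelerated)."""
    owner = np.concatenate([np.full(len(r.atoms), i)
                            for i, r in enumerate(records)])
    coords = np.concatenate([r.atoms for r in records])
    tree = cKDTree(coords)
    cbs = np.array([r.cb_xyz for r in records])
    for radius, attr in ((6.0, "n6"), (12.0, "n12")):
        hits = tree.query_ball_point(cbs, r=radius)
        for i, idx in enumerate(hits):
            idx = np.asarray(idx, dtype=int)
            setattr(records[i], attr, int((owner[idx] != i).sum()))
    return records


def helix_axis(ca_coords: np.ndarray) -> np.ndarray:
    """Principal direction of Cα coordinates, oriented N->C."""
    ca = np.asarray(ca_coords, dtype=float)
    centred = ca - ca.mean(axis=0)
    _, _, vt = np.linalg.svd(centred, full_matrices=False)
    axis = vt[0]
    if axis @ (ca[-1] - ca[0]) < 0:
        axis = -axis
    return axis


def helix_tilt(segment: list[ResidueRecord],
               frame: MembraneFrame | None = None) -> HelixSegment:
    """Tilt of a helical span relative to the membrane normal.

    The axis is the largest-variance direction of the Cα cloud; the
    tilt is folded into [0, 90]° (a helix and its reverse are the same
    span).  Requires at least 6 consecutive residues.
    """
    if len(segment) < 6:
        raise ParameterError("helix tilt needs >= 6 residues")
    frame = frame or MembraneFrame()
    axis = helix_axis(np.array([r.ca_xyz for r in segment]))
    cosang = abs(float(axis @ frame.normal_array))
    theta = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
    return HelixSegment(chain=segment[0].chain, start=segment[0].resi,
                        end=segment[-1].resi, axis=axis, tilt_theta=theta)


def find_membrane_spans(records: list[ResidueRecord],
                        half_width: float = 20.0,
                        min_length: int = 6) -> list[list[ResidueRecord]]:
    """Contiguous membrane-embedded runs (|z| <= half_width) per chain."""
    spans: list[list[ResidueRecord]] = []
    run: list[ResidueRecord] = []
    for rec in records:
        inside = abs(rec.z) <= half_width
        if run and (not inside or rec.chain != run[-1].chain):
            if len(run) >= min_length:
                spans.append(run)
            run = []
        if inside:
            run.append(rec)
    if len(run) >= min_length:
        spans.append(run)
    return spans
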