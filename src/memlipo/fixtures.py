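"""Synthetic inputs: ideal helices, decoy ensembles, raw profiles, angles.

Everything the test-suite and worked examples need is generated here
from ideal geometry and seeded random draws, so no external data files
are required.  The raw-profile generator is a synthetic stand-in for
the published deep-mutational insertion-energy tables: it reproduces
the qualitative shape and the quantitative anchors of those curves
(a ~2 kcal/mol Gly penalty at the midplane, ~-2 kcal/mol transfer for
Leu/Ile/Phe, a ~2 kcal/mol inside-preference for Arg/Lys, a His curve
exceeding the 2.3 kcal/mol cap in the outer leaflet) but not the
count-level noise of the underlying deep-sequencing assay.  Real
profile tables can be dropped in through the same CSV interface.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np
from scipy.spatial.transform import Rotation

from .errors import DataError, ParameterError
from .geometry import helix_axis, place_atom
from .profiles import DEPTHS_27, KCAL, AA20, InsertionProfile
from .tilt import TiltSample, quadratic, OBSERVED_TILT_DENSITY

THREE_LETTER = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE", "G": "GLY",
    "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU", "M": "MET", "N": "ASN",
    "P": "PRO", "Q": "GLN", "R": "ARG", "S": "SER", "T": "THR", "V": "VAL",
    "W": "TRP", "Y": "TYR",
}

# ideal backbone internal coordinates (Engh-Huber-like)
B_N_CA, B_CA_C, B_C_N, B_C_O = 1.458, 1.525, 1.329, 1.231
A_N_CA_C, A_CA_C_N, A_C_N_CA, A_CA_C_O = 111.2, 116.2, 121.7, 120.8
OMEGA = 180.0


@dataclass
class HelixSpec:
    """An ideal helix: sequence, dihedrals, tilt and centre depth."""

    sequence: str = "A" * 25
    phi: float = -60.0
    psi: float = -45.0
    tilt: float = 0.0
    center_depth: float = 0.0
    chain: str = "A"


@dataclass
class BuiltHelix:
    """Atom records of a built helix and its PDB serialisation."""

    spec: HelixSpec
    atoms: list = field(default_factory=list)  # (resi, aa3, name, elem, xyz)

    @property
    def ca_coords(self) -> np.ndarray:
        return np.array([xyz for _, _, name, _, xyz in self.atoms
                         if name == "CA"])

    def transformed(self, rotation: np.ndarray, translation: np.ndarray
                    ) -> "BuiltHelix":
        new = [(ri, aa3, name, el, rotation @ xyz + translation)
               for ri, aa3, name, el, xyz in self.atoms]
        return BuiltHelix(spec=self.spec, atoms=new)


def _ideal_cb(n, ca, c):
    # tetrahedral Cβ as a fixed linear combination of backbone vectors
    # (independent of the internal-coordinate construction used for
    # geometry.virtual_cb, so the two routes cross-check each other)
    b = ca - n
    cc = c - ca
    a = np.cross(b, cc)
    return -0.58273431 * a + 0.56802827 * b - 0.54067466 * cc + ca


def build_helix(spec: HelixSpec) -> BuiltHelix:
    """Build an ideal helix with full backbone + Cβ at the requested
    (φ, ψ), tilt it away from the membrane normal about an in-plane
    axis, and centre the Cα centroid at the requested depth."""
    seq = spec.sequence.upper()
    if len(seq) < 4:
        raise ParameterError("helix needs at least 4 residues")
    bad = [aa for aa in seq if aa not in THREE_LETTER]
    if bad:
        raise DataError(f"nonstandard residues {bad!r}")

    n_atoms, ca_atoms, c_atoms = [], [], []
    n = np.array([0.0, 0.0, 0.0])
    ca = np.array([B_N_CA, 0.0, 0.0])
    ang = np.radians(A_N_CA_C)
    c = ca + B_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])
    for i in range(len(seq)):
        if i > 0:
            n = place_atom(n_atoms[-1], ca_atoms[-1], c_atoms[-1],
                           B_C_N, A_CA_C_N, spec.psi)
            ca = place_atom(ca_atoms[-1], c_atoms[-1], n,
                            B_N_CA, A_C_N_CA, OMEGA)
            c = place_atom(c_atoms[-1], n, ca, B_CA_C, A_N_CA_C, spec.phi)
        n_atoms.append(n)
        ca_atoms.append(ca)
        c_atoms.append(c)

    atoms = []
    for i, aa in enumerate(seq):
        aa3 = THREE_LETTER[aa]
        n, ca, c = n_atoms[i], ca_atoms[i], c_atoms[i]
        o = place_atom(n, ca, c, B_C_O, A_CA_C_O, spec.psi + 180.0)
        atoms.append((i + 1, aa3, "N", "N", n))
        atoms.append((i + 1, aa3, "CA", "C", ca))
        atoms.append((i + 1, aa3, "C", "C", c))
        atoms.append((i + 1, aa3, "O", "O", o))
        if aa != "G":
            atoms.append((i + 1, aa3, "CB", "C", _ideal_cb(n, ca, c)))

    helix = BuiltHelix(spec=spec, atoms=atoms)
    axis = helix_axis(helix.ca_coords)
    target = np.array([np.sin(np.radians(spec.tilt)), 0.0,
                       np.cos(np.radians(spec.tilt))])
    rot, _ = Rotation.align_vectors([target], [axis])
    rotated = helix.transformed(rot.as_matrix(), np.zeros(3))
    centroid = rotated.ca_coords.mean(axis=0)
    shift = np.array([0.0, 0.0, spec.center_depth]) - centroid
    return rotated.transformed(np.eye(3), shift)


def to_structure(helices: list[BuiltHelix] | BuiltHelix,
                 name: str = "memlipo-fixture") -> gemmi.Structure:
    """Assemble built helices (one chain each) into a gemmi Structure."""
    if isinstance(helices, BuiltHelix):
        helices = [helices]
    st = gemmi.Structure()
    st.name = name
    model = gemmi.Model("1")
    for hx in helices:
        chain = gemmi.Chain(hx.spec.chain)
        res = None
        for resi, aa3, aname, elem, xyz in hx.atoms:
            if res is None or res.seqid.num != resi:
                res = gemmi.Residue()
                res.name = aa3
                res.seqid = gemmi.SeqId(resi, " ")
                res.het_flag = "A"
                chain.add_residue(res)
                res = chain[-1]
            atom = gemmi.Atom()
            atom.name = aname
            atom.element = gemmi.Element(elem)
            atom.pos = gemmi.Position(*xyz)
            atom.occ = 1.0
            atom.b_iso = 0.0
            res.add_atom(atom)
        model.add_chain(chain)
    st.add_model(model)
    return st


def write_pdb(helices, path: str | Path, name: str = "memlipo-fixture") -> None:
    to_structure(helices, name=name).write_pdb(str(path))


def build_dimer(sequence: str = "A" * 25, separation: float = 8.0,
                tilt: float = 0.0) -> list[BuiltHelix]:
    """Two parallel helices (chains A and B) separated along x."""
    a = build_helix(HelixSpec(sequence=sequence, tilt=tilt, chain="A"))
    b = build_helix(HelixSpec(sequence=sequence, tilt=tilt, chain="B"))
    b = b.transformed(np.eye(3), np.array([separation, 0.0, 0.0]))
    return [a, b]


@dataclass
class Decoy:
    """One perturbed copy of a base structure, with ground truth.

    ``rotation``/``translation``/``center`` record the rigid operation
    applied to the moving segment, so the same perturbation can be
    replayed on a full-atom copy of the base structure.
    """

    decoy_id: str
    coords: np.ndarray
    mode: int
    rmsd_to_base: float
    energy: float
    rotation: np.ndarray | None = None
    translation: np.ndarray | None = None
    center: np.ndarray | None = None

    def apply_rigid(self, xyz: np.ndarray) -> np.ndarray:
        """Replay the stored rigid perturbation on arbitrary coordinates."""
        return ((np.asarray(xyz) - self.center) @ self.rotation.T
                + self.center + self.translation)


def build_decoy_ensemble(base_coords: np.ndarray, n: int,
                         modes: list[tuple[float, tuple]] | None = None,
                         moving: slice | None = None,
                         jitter_rot: float = 0.0,
                         jitter_trans: float = 0.0,
                         seed: int = 0) -> list[Decoy]:
    """Seeded rigid-body decoys of a base coordinate set.

    Each mode is a fixed rigid displacement ``(rotation_deg,
    translation_vector)`` of the ``moving`` row slice (default: the
    second half — the partner chain of a dimer); the rotation is about
    the z axis through the segment centroid.  Decoy *i* belongs to
    mode ``i % len(modes)``, and ``jitter_rot`` (degrees) /
    ``jitter_trans`` (Å) add a small random rigid wobble on top, so
    well-separated modes plant well-separated conformational clusters.
    The mode index also sets the decoy energy (lower for mode 0), so
    energy-ranked clustering recovers the planted structure.
    Ground-truth RMSD to the base is computed by optimal superposition.
    """
    from .selection import kabsch_rmsd

    if n < 1:
        raise ParameterError("need n >= 1 decoys")
    base = np.asarray(base_coords, dtype=float)
    if modes is None:
        modes = [(0.0, (0.0, 0.0, 0.0))]
    if moving is None:
        moving = slice(len(base) // 2, len(base))
    rng = np.random.default_rng(seed)
    decoys = []
    for i in range(n):
        mode = i % len(modes)
        rot_deg, trans_vec = modes[mode]
        rot = Rotation.from_rotvec(np.radians(rot_deg) * np.array([0.0, 0.0, 1.0]))
        translation = np.asarray(trans_vec, dtype=float)
        if jitter_rot > 0:
            axis = rng.normal(size=3)
            axis /= np.linalg.norm(axis)
            wobble = rng.normal(scale=np.radians(jitter_rot))
            rot = Rotation.from_rotvec(wobble * axis) * rot
        if jitter_trans > 0:
            translation = translation + rng.normal(scale=jitter_trans, size=3)
        coords = base.copy()
        seg = coords[moving]
        center = seg.mean(axis=0)
        coords[moving] = (seg - center) @ rot.as_matrix().T + center \
            + translation
        energy = mode * 1.0 + rng.normal(scale=0.05)
        decoys.append(Decoy(decoy_id=f"decoy_{i:04d}", coords=coords,
                            mode=mode, rmsd_to_base=kabsch_rmsd(coords, base),
                            energy=float(energy), rotation=rot.as_matrix(),
                            translation=translation, center=center))
    return decoys


# ---------------------------------------------------------------------------
# synthetic raw insertion profiles

#: membrane-core transfer energy vs Ala, kcal/mol, at the midplane
_CORE_AMPLITUDE = {
    "A": 0.0, "G": 2.0, "L": -2.0, "I": -2.0, "F": -2.0, "V": -1.5,
    "M": -1.2, "W": -0.9, "Y": 0.3, "C": 1.4, "S": 1.4, "T": 0.9,
    "P": 1.0, "H": 3.0, "D": 4.0, "E": 4.0, "N": 3.2, "Q": 3.2,
    "K": 2.2, "R": 2.5,
}
#: leaflet asymmetry (positive-inside rule) via tanh(z/7), kcal/mol
_ASYMMETRY = {"K": 1.035, "R": 1.035, "H": 0.3}
_GAUSS_WIDTH = {"H": 14.0}
_DEFAULT_WIDTH = 12.0
_NOISE_SD = 0.08


def synth_raw_profiles(seed: int = 0) -> dict[str, InsertionProfile]:
    """Synthetic raw 20 x 27 insertion-energy table, kcal/mol, seeded.

    Curves are smooth bell shapes (amplitude = membrane-core transfer
    energy, width ~12 Å) plus a tanh leaflet-asymmetry term for
    Arg/Lys/His and small Gaussian noise, sampled on the 27-knot
    grid spanning -20..+20 Å.
    """
    rng = np.random.default_rng(seed)
    z = DEPTHS_27
    out = {}
    for aa in AA20:
        width = _GAUSS_WIDTH.get(aa, _DEFAULT_WIDTH)
        e = _CORE_AMPLITUDE[aa] * np.exp(-((z / width) ** 2))
        e = e + _ASYMMETRY.get(aa, 0.0) * np.tanh(z / 7.0)
        e = e + rng.normal(scale=_NOISE_SD, size=z.shape)
        out[aa] = InsertionProfile(aa, z.copy(), e, units=KCAL)
    return out


# ---------------------------------------------------------------------------
# tilt-angle samples

def sample_tilt_angles(density: str = "sin", n: int = 1000, seed: int = 0,
                       support: tuple[float, float] | None = None,
                       custom=None) -> TiltSample:
    """Seeded tilt-angle samples from a named density on [0, 90]°.

    * ``"sin"`` — the tilt distribution of unbiased rigid-body
      sampling, drawn exactly by inverse transform.
    * ``"eq2-quadratic"`` — the observed-span quadratic density, drawn
      by rejection on its positive support.
    * ``"custom"`` — any non-negative callable of θ (degrees) over
      ``support``, drawn by rejection.
    """
    if n < 1:
        raise ParameterError("need n >= 1 angles")
    rng = np.random.default_rng(seed)
    if density == "sin":
        angles = np.degrees(np.arccos(1.0 - rng.random(n)))
        return TiltSample(angles)
    if density in ("eq2", "eq2-quadratic"):
        c2, c1, c0 = OBSERVED_TILT_DENSITY
        hi = (-c1 - np.sqrt(c1 * c1 - 4 * c2 * c0)) / (2 * c2)  # positive root
        fn = lambda t: quadratic(OBSERVED_TILT_DENSITY, t)
        lo = 0.0
    elif density == "custom":
        if custom is None or support is None:
            raise ParameterError("custom density needs `custom` and `support`")
        fn = custom
        lo, hi = support
    else:
        raise ParameterError(f"unknown density {density!r}")
    if support is not None:
        lo, hi = support
    grid = np.linspace(lo, hi, 512)
    fmax = float(np.max(fn(grid))) * 1.05
    samples: list[float] = []
    while len(samples) < n:
        t = rng.uniform(lo, hi, size=4 * n)
        y = rng.uniform(0.0, fmax, size=4 * n)
        samples.extend(t[y < fn(t)].tolist())
    return TiltSample(np.asarray(samples[:n]))


def write_angles(sample: TiltSample, path: str | Path) -> None:
    Path(path).write_text("".join(f"{a:.6f}\n" for a in sample.angles))
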