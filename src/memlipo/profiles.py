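"""Processing of depth-dependent amino-acid insertion-energy profiles.

An insertion profile gives the apparent transfer free energy
ΔΔG(Ala→aa) of placing amino acid ``aa`` at a signed membrane depth z
(Å from the midplane, negative = inner/cytoplasmic leaflet), relative
to alanine.  Raw experimental profiles are noisy and asymmetric; this
module turns them into the smoothed, symmetrised, special-cased and
unit-converted curves used at scoring time, and encodes each curve as
a clamped natural cubic spline over the membrane window [-20, +20] Å.

Processing order is fixed: smooth -> symmetrise -> special cases ->
unit conversion -> spline.  The His cap (2.3) and the polar-residue
core averaging are quoted in kcal/mol, so they must precede the
conversion to Rosetta energy units (R.e.u., kcal/mol x 2.94).

Arg, His and Lys are exempt from symmetrisation: the positive-inside
rule makes their insertion energetics genuinely leaflet-dependent.
Ala is the reference amino acid and carries an identically-zero
profile; Pro perturbs the backbone rather than solvating differently
and is likewise assigned a zero lipophilicity profile.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from .errors import DataError, ParameterError, StateError

AA20 = "ACDEFGHIKLMNPQRSTVWY"

#: amino acids whose profiles keep their leaflet asymmetry
ASYMMETRIC_AAS = frozenset("RHK")

#: amino acids whose lipophilicity is identically zero by convention
ZERO_PROFILE_AAS = frozenset("AP")

#: polar residues whose membrane-core mean is applied across the span
CORE_AVERAGED_AAS = "DEQN"

KCAL = "kcal/mol"
REU = "R.e.u."
KCAL_TO_REU = 2.94

HIS_CAP_KCAL = 2.3

N_KNOTS = 27
MEMBRANE_HALF_WIDTH = 20.0
#: canonical processed depth grid: 27 knots spanning -20..+20 Å
DEPTHS_27 = np.linspace(-MEMBRANE_HALF_WIDTH, MEMBRANE_HALF_WIDTH, N_KNOTS)


@dataclass
class InsertionProfile:
    """One amino acid's depth-dependent insertion-energy curve."""

    amino_acid: str
    depths: np.ndarray
    energies: np.ndarray
    units: str = KCAL
    processed: bool = False

    def __post_init__(self) -> None:
        self.depths = np.asarray(self.depths, dtype=float)
        self.energies = np.asarray(self.energies, dtype=float)
        if len(self.amino_acid) != 1 or self.amino_acid not in AA20:
            raise DataError(f"unknown amino acid {self.amino_acid!r}")
        if self.depths.ndim != 1 or self.depths.shape != self.energies.shape:
            raise DataError("depths and energies must be 1-D and equally long")
        if np.any(np.diff(self.depths) <= 0):
            raise DataError("depths must be strictly increasing")
        if self.units not in (KCAL, REU):
            raise DataError(f"unknown units {self.units!r}")

    @property
    def n_knots(self) -> int:
        return len(self.depths)

    def copy(self) -> "InsertionProfile":
        return replace(self, depths=self.depths.copy(),
                       energies=self.energies.copy())


def smooth_profile(raw: InsertionProfile, window: int = 3) -> InsertionProfile:
    """Centred moving average; endpoints use shrunken windows.

    ``window`` must be odd and positive.  ``window=1`` is the identity.
    The depth grid is unchanged.
    """
    if window <= 0 or window % 2 == 0:
        raise ParameterError(f"window must be odd and positive, got {window}")
    n = raw.n_knots
    if n < window:
        raise ParameterError(f"profile has {n} knots < window {window}")
    half = window // 2
    out = np.empty(n)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        out[i] = raw.energies[lo:hi].mean()
    return replace(raw, depths=raw.depths.copy(), energies=out)


def _require_symmetric_grid(p: InsertionProfile) -> None:
    if not np.allclose(p.depths, -p.depths[::-1], atol=1e-6):
        raise DataError(f"{p.amino_acid}: depth grid is not symmetric about 0")


def symmetrise(p: InsertionProfile) -> InsertionProfile:
    """Average E(z) with E(-z); Arg, His and Lys pass through unchanged."""
    _require_symmetric_grid(p)
    if p.amino_acid in ASYMMETRIC_AAS:
        return p.copy()
    sym = 0.5 * (p.energies + p.energies[::-1])
    return replace(p, depths=p.depths.copy(), energies=sym)


def apply_special_cases(
    profiles: Mapping[str, InsertionProfile],
    his_cap: float = HIS_CAP_KCAL,
) -> dict[str, InsertionProfile]:
    """Residue-specific adjustments, applied on the kcal/mol scale.

    * His is capped at ``his_cap`` on the outer half-membrane
      (depths in [0, +20] Å); its inner leaflet is untouched.
    * Cys inherits a copy of the (already adjusted) Ser profile —
      Cys is rare in membrane proteins and of Ser-like polarity.
    * For each of Asp/Glu/Gln/Asn the mean energy over the membrane
      core (depths in [-10, +10] Å) is written to every knot.
    """
    required = set("SH") | set(CORE_AVERAGED_AAS)
    missing = required - set(profiles)
    if missing:
        raise DataError(f"missing required profiles: {sorted(missing)}")
    out = {aa: p.copy() for aa, p in profiles.items()}

    his = out["H"]
    outer = (his.depths >= 0.0) & (his.depths <= MEMBRANE_HALF_WIDTH)
    his.energies[outer] = np.minimum(his.energies[outer], his_cap)

    for aa in CORE_AVERAGED_AAS:
        p = out[aa]
        core = np.abs(p.depths) <= 10.0
        if not core.any():
            raise DataError(f"{aa}: no knots in the membrane core")
        p.energies[:] = p.energies[core].mean()

    out["C"] = replace(out["S"].copy(), amino_acid="C")
    return out


def to_rosetta_units(p: InsertionProfile) -> InsertionProfile:
    """kcal/mol -> R.e.u. via the ref2015 interpolation factor 2.94."""
    if p.units != KCAL:
        raise StateError(f"{p.amino_acid}: profile already in {p.units}")
    return replace(p, depths=p.depths.copy(),
                   energies=p.energies * KCAL_TO_REU, units=REU)


@dataclass
class LipophilicitySpline:
    """Clamped natural cubic spline through a processed profile.

    Continuous with continuous first derivative on the knot span;
    evaluation outside [-20, +20] Å returns the boundary knot value
    (profiles are defined only within the membrane window; outside it
    the base water solvation dominates).
    """

    amino_acid: str
    knots: np.ndarray
    values: np.ndarray
    units: str = REU
    _spline: CubicSpline = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.knots = np.asarray(self.knots, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.knots) < 4:
            raise ParameterError("cubic spline needs at least 4 knots")
        self._spline = CubicSpline(self.knots, self.values, bc_type="natural")

    @property
    def coefficients(self) -> np.ndarray:
        """Piecewise-cubic coefficient matrix (scipy layout, 4 x n-1)."""
        return self._spline.c

    def __call__(self, z):
        zc = np.clip(z, self.knots[0], self.knots[-1])
        return self._spline(zc)

    def derivative(self, z):
        z = np.asarray(z, dtype=float)
        inside = (z >= self.knots[0]) & (z <= self.knots[-1])
        return np.where(inside, self._spline(np.clip(z, self.knots[0],
                                                     self.knots[-1]), 1), 0.0)

    def to_dict(self) -> dict:
        return {
            "amino_acid": self.amino_acid,
            "knots": self.knots.tolist(),
            "values": self.values.tolist(),
            "coefficients": self.coefficients.tolist(),
            "units": self.units,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LipophilicitySpline":
        return cls(amino_acid=d["amino_acid"], knots=d["knots"],
                   values=d["values"], units=d.get("units", REU))


def fit_spline(p: InsertionProfile) -> LipophilicitySpline:
    """Natural cubic spline through all knots of a processed profile."""
    if p.n_knots < 4:
        raise ParameterError("need at least 4 knots to fit a cubic spline")
    return LipophilicitySpline(amino_acid=p.amino_acid, knots=p.depths,
                               values=p.energies, units=p.units)


def process_profiles(
    raw: Mapping[str, InsertionProfile],
    window: int = 3,
    to_reu: bool = True,
    his_cap: float = HIS_CAP_KCAL,
) -> dict[str, InsertionProfile]:
    """Full pipeline: smooth, symmetrise, special cases, convert units.

    Raw profiles must be in kcal/mol with 27 positions each; the raw
    grid is mapped linearly onto depths -20..+20 Å.  Ala and Pro come
    out identically zero regardless of their raw values (reference
    residue and backbone-perturbing residue, respectively).

    The pipeline is deterministic: identical inputs give bit-identical
    outputs.  Set ``to_reu=False`` to stop on the kcal/mol scale.
    """
    staged: dict[str, InsertionProfile] = {}
    for aa, p in raw.items():
        if p.units != KCAL:
            raise StateError(f"{aa}: raw profiles must be in {KCAL}")
        if p.n_knots != N_KNOTS:
            raise DataError(
                f"{aa}: raw profile has {p.n_knots} positions, expected {N_KNOTS}")
        p = replace(p, depths=DEPTHS_27.copy(), energies=p.energies.copy())
        staged[aa] = symmetrise(smooth_profile(p, window=window))
    staged = apply_special_cases(staged, his_cap=his_cap)
    out: dict[str, InsertionProfile] = {}
    for aa, p in staged.items():
        if aa in ZERO_PROFILE_AAS:
            p = replace(p, energies=np.zeros(N_KNOTS))
        if to_reu:
            p = to_rosetta_units(p)
        p.processed = True
        out[aa] = p
    for aa in ZERO_PROFILE_AAS:
        if aa not in out:
            out[aa] = InsertionProfile(aa, DEPTHS_27.copy(), np.zeros(N_KNOTS),
                                       units=REU if to_reu else KCAL,
                                       processed=True)
    return out


def build_splines(
    processed: Mapping[str, InsertionProfile],
) -> dict[str, LipophilicitySpline]:
    return {aa: fit_spline(p) for aa, p in processed.items()}


# ---------------------------------------------------------------------------
# serialisation

def read_raw_profiles(path: str | Path) -> dict[str, InsertionProfile]:
    """Read a raw profile table: columns ``aa, depth, energy_kcal``.

    Comma- or tab-separated; one row per (amino acid, depth).
    """
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    needed = {"aa", "depth", "energy_kcal"}
    if not needed <= set(df.columns):
        raise DataError(f"raw profile table needs columns {sorted(needed)}, "
                        f"got {list(df.columns)}")
    out = {}
    for aa, grp in df.groupby("aa"):
        grp = grp.sort_values("depth")
        out[str(aa)] = InsertionProfile(str(aa), grp["depth"].to_numpy(),
                                        grp["energy_kcal"].to_numpy(),
                                        units=KCAL)
    return out


def write_raw_profiles(profiles: Mapping[str, InsertionProfile],
                       path: str | Path) -> None:
    rows = [(aa, d, e) for aa, p in sorted(profiles.items())
            for d, e in zip(p.depths, p.energies)]
    pd.DataFrame(rows, columns=["aa", "depth", "energy_kcal"]).to_csv(
        path, index=False)


def write_profile_table(processed: Mapping[str, InsertionProfile],
                        path: str | Path) -> None:
    """Processed profiles as a TSV matrix: rows = amino acids, cols = depths."""
    aas = sorted(processed)
    depths = processed[aas[0]].depths
    df = pd.DataFrame({aa: processed[aa].energies for aa in aas},
                      index=depths).T
    df.columns = [f"{d:.3f}" for d in depths]
    df.to_csv(path, sep="\t", index_label="aa")


def splines_to_json(splines: Mapping[str, LipophilicitySpline],
                    path: str | Path | None = None,
                    extra: dict | None = None) -> str:
    doc = {"splines": {aa: s.to_dict() for aa, s in sorted(splines.items())}}
    if extra:
        doc.update(extra)
    text = json.dumps(doc, indent=1)
    if path is not None:
        Path(path).write_text(text)
    return text


def splines_from_json(source: str | Path) -> dict[str, LipophilicitySpline]:
    p = Path(source)
    text = p.read_text() if p.exists() else str(source)
    doc = json.loads(text)
    return {aa: LipophilicitySpline.from_dict(d)
            for aa, d in doc["splines"].items()}
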