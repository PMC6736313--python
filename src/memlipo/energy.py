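"""Runtime membrane energy terms.

Three one-body terms evaluated per residue (or per helical span):

* **Residue lipophilicity** — burial-weighted evaluation of the
  depth-dependent lipophilicity spline; the full solvation energy of
  a residue mixes this with a base water-solvation value as
  ``w * spline(z) + (1 - w) * base``, where w is the burial weight
  (1 = lipid-exposed, 0 = buried/water-embedded).
* **Helicality** — a quartic paraboloid penalty on (φ, ψ) deviations
  from the ideal α-helical centre (-60°, -45°), gated by membrane
  depth (1 / (1 + (z/10)^4), maximal at the midplane) and by the
  exposure weight, so only lipid-exposed residues in the membrane
  core are strongly constrained to helical backbone geometry.
* **Span tilt** — a cubic in the helix tilt angle θ (degrees),
  derived from the observed-vs-expected tilt-angle statistics of
  natural membrane spans (see :mod:`memlipo.tilt`); strictly
  increasing on [0, 60]°, discouraging the large tilt angles that
  random conformational sampling otherwise over-produces.

Angles are in degrees throughout; energies in R.e.u.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from . import burial as _burial
from .errors import DataError, ParameterError
from .geometry import (MembraneFrame, ResidueRecord, annotate_neighbour_counts,
                       find_membrane_spans, helix_tilt, load_structure)
from .profiles import LipophilicitySpline


@dataclass(frozen=True)
class HelicalityParams:
    phi_center: float = -60.0
    psi_center: float = -45.0
    curvature: float = 25.0
    z_halfwidth: float = 10.0

    def __post_init__(self):
        if self.curvature <= 0:
            raise ParameterError("curvature must be positive")


DEFAULT_HELICALITY = HelicalityParams()


@dataclass(frozen=True)
class SpanPenaltyModel:
    """Cubic tilt penalty: a3 θ³ + a2 θ² + a1 θ + a0, θ in degrees."""

    a3: float
    a2: float
    a1: float
    a0: float

    def __call__(self, theta):
        t = np.asarray(theta, dtype=float)
        v = ((self.a3 * t + self.a2) * t + self.a1) * t + self.a0
        return float(v) if v.ndim == 0 else v

    @property
    def coefficients(self) -> tuple[float, float, float, float]:
        return (self.a3, self.a2, self.a1, self.a0)


#: tilt penalty fitted to the observed/expected span-angle statistics
DEFAULT_SPAN_PENALTY = SpanPenaltyModel(a3=1.51e-4, a2=-8.925e-3,
                                        a1=0.187, a0=-0.532)


@dataclass
class ResidueEnergies:
    chain: str
    resi: int
    amino_acid: str
    lipophilicity: float
    helicality: float
    solvation_mix: float
    helicality_defined: bool = True


def _weight(record: ResidueRecord) -> float:
    if record.burial_weight is None:
        raise DataError(f"{record.chain}{record.resi}: burial weight not set")
    return record.burial_weight


def lipophilicity_energy(record: ResidueRecord,
                         splines: Mapping[str, LipophilicitySpline]) -> float:
    """Burial-weighted spline energy: w * spline_aa(z), R.e.u."""
    try:
        spline = splines[record.amino_acid]
    except KeyError:
        raise DataError(f"no lipophilicity spline for {record.amino_acid!r}")
    return _weight(record) * float(spline(record.z))


def solvation_mix(record: ResidueRecord,
                  splines: Mapping[str, LipophilicitySpline],
                  base_solvation: Callable[[ResidueRecord], float] | None = None,
                  ) -> float:
    """Linear mix of membrane lipophilicity and base water solvation.

    ``w * spline(z) + (1 - w) * base``.  The default base term is 0
    (pure lipophilicity mode); inject any per-residue callable to mix
    with an external water-solvation model.
    """
    w = _weight(record)
    base = 0.0 if base_solvation is None else float(base_solvation(record))
    if not np.isfinite(base):
        raise DataError(
            f"{record.chain}{record.resi}: non-finite base solvation")
    spline = splines[record.amino_acid]
    return w * float(spline(record.z)) + (1.0 - w) * base


def helicality_value(phi: float, psi: float, z: float, weight: float,
                     params: HelicalityParams = DEFAULT_HELICALITY) -> float:
    """Pure helicality formula for given dihedrals, depth and weight."""
    r2 = (phi - params.phi_center) ** 2 + (psi - params.psi_center) ** 2
    paraboloid = r2 ** 2 / params.curvature ** 4
    gate = 1.0 / (1.0 + (z / params.z_halfwidth) ** 4)
    return paraboloid * gate * weight


def helicality_penalty(record: ResidueRecord,
                       params: HelicalityParams = DEFAULT_HELICALITY,
                       ) -> tuple[float, bool]:
    """Helicality penalty for a residue; (0.0, False) at termini.

    Returns ``(penalty, defined)`` where ``defined`` is False when φ
    or ψ is unavailable (chain termini / breaks).
    """
    if record.phi is None or record.psi is None:
        return 0.0, False
    return helicality_value(record.phi, record.psi, record.z,
                            _weight(record), params), True


def span_angle_penalty(theta: float,
                       model: SpanPenaltyModel = DEFAULT_SPAN_PENALTY) -> float:
    """Tilt penalty for a span angle θ in [0, 90] degrees."""
    if not 0.0 <= theta <= 90.0:
        raise ParameterError(f"tilt angle {theta} outside [0, 90] degrees")
    return model(theta)


def score_structure(
    pdb_source,
    splines: Mapping[str, LipophilicitySpline],
    frame: MembraneFrame | None = None,
    burial_params: _burial.BurialParams = _burial.FULLATOM,
    helicality_params: HelicalityParams = DEFAULT_HELICALITY,
    span_model: SpanPenaltyModel = DEFAULT_SPAN_PENALTY,
    base_solvation: Callable[[ResidueRecord], float] | None = None,
    spans: list[list[ResidueRecord]] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Score a structure: per-residue table plus totals and span tilts.

    Returns ``(per_residue, summary)`` where ``per_residue`` has one
    row per residue (depth, dihedrals, counts, burial, energies) and
    ``summary`` carries term totals and one (θ, penalty) entry per
    membrane span (detected as contiguous |z| <= 20 Å runs of at least
    6 residues unless ``spans`` is given explicitly).
    """
    frame = frame or MembraneFrame()
    records = load_structure(pdb_source, frame) \
        if not isinstance(pdb_source, list) else pdb_source
    if not records:
        raise DataError("empty residue selection")
    annotate_neighbour_counts(records)
    _burial.annotate_burial(records, burial_params)

    rows = []
    for rec in records:
        lipo = lipophilicity_energy(rec, splines)
        helic, defined = helicality_penalty(rec, helicality_params)
        mix = solvation_mix(rec, splines, base_solvation)
        rows.append({
            "chain": rec.chain, "resi": rec.resi, "aa": rec.amino_acid,
            "z": rec.z, "phi": rec.phi, "psi": rec.psi,
            "n6": rec.n6, "n12": rec.n12, "burial": rec.burial_weight,
            "lipo": lipo, "helicality": helic, "solvation_mix": mix,
            "helicality_defined": defined,
        })
    per_residue = pd.DataFrame(rows)

    if spans is None:
        spans = find_membrane_spans(records)
    span_rows = []
    for seg in spans:
        hs = helix_tilt(seg, frame)
        span_rows.append({"chain": hs.chain, "start": hs.start, "end": hs.end,
                          "theta": hs.tilt_theta,
                          "span_penalty": span_angle_penalty(hs.tilt_theta,
                                                             span_model)})
    summary = {
        "total_lipophilicity": float(per_residue["lipo"].sum()),
        "total_helicality": float(per_residue["helicality"].sum()),
        "total_solvation_mix": float(per_residue["solvation_mix"].sum()),
        "spans": span_rows,
        "total_span_penalty": float(sum(s["span_penalty"] for s in span_rows)),
        "n_residues": len(records),
    }
    return per_residue, summary
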