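"""Model-ensemble post-processing: filters, clustering, native contacts.

Given a table of per-model energies and structural metrics plus model
coordinates, this module implements the selection pipeline applied to
folding/docking ensembles: threshold filters, lowest-energy fraction
selection, score-wise RMSD clustering (each cluster is seeded by the
lowest-energy unclustered model and absorbs everything within an RMSD
cutoff), fraction of native inter-chain contacts, optimal-superposition
RMSD, and median-ΔΔG classification of point mutations as stabilising
or destabilising.

Energy-like metrics that only an external all-atom scorer can provide
(SASA, shape complementarity, binding ΔΔG, rotameric strain) are
consumed as free table columns; helicality totals and helix-helix
distances can be computed natively (see :mod:`memlipo.energy`).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .errors import ConfigurationError, DataError, ParameterError
from .geometry import ResidueRecord

_OPS = {
    "lt": lambda col, v: col < v,
    "le": lambda col, v: col <= v,
    "gt": lambda col, v: col > v,
    "ge": lambda col, v: col >= v,
}


def kabsch_rmsd(coords_a, coords_b) -> float:
    """Minimal RMSD over rigid superposition of two matched point sets."""
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape:
        raise DataError(f"coordinate shapes differ: {a.shape} vs {b.shape}")
    if a.ndim != 2 or a.shape[0] < 3 or a.shape[1] != 3:
        raise DataError("need matched (n >= 3, 3) coordinate arrays")
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    with warnings.catch_warnings():
        # identical / collinear sets make the optimal rotation degenerate,
        # but the residual (hence the RMSD) is still well defined
        warnings.simplefilter("ignore", UserWarning)
        _, rssd = Rotation.align_vectors(ac, bc)
    return float(rssd / math.sqrt(len(a)))


def homodimer_rmsd(coords_a, coords_b, n_first_chain: int) -> float:
    """RMSD of a two-chain homodimer, minimised over the chain swap.

    Chain identity is arbitrary in a homodimer, so both chain mappings
    are tried and the smaller RMSD returned.  ``n_first_chain`` is the
    number of rows belonging to the first chain.
    """
    b = np.asarray(coords_b, dtype=float)
    swapped = np.concatenate([b[n_first_chain:], b[:n_first_chain]])
    return min(kabsch_rmsd(coords_a, b), kabsch_rmsd(coords_a, swapped))


def apply_filters(table: pd.DataFrame,
                  thresholds: Mapping[str, tuple[str, float]],
                  skip_missing: Sequence[str] = ()) -> pd.DataFrame:
    """Drop rows failing any threshold; explicit skipping only.

    ``thresholds`` maps column -> (op, value) with op in lt/le/gt/ge,
    e.g. ``{"helicality": ("lt", 0.1), "ddg_binding": ("lt", -5.0)}``.
    A threshold naming an absent column raises unless that column is
    listed in ``skip_missing``.
    """
    keep = pd.Series(True, index=table.index)
    for col, (op, value) in thresholds.items():
        if op not in _OPS:
            raise ConfigurationError(f"unknown filter op {op!r}")
        if col not in table.columns:
            if col in skip_missing:
                continue
            raise ConfigurationError(
                f"filter on absent column {col!r} (not in skip_missing)")
        keep &= _OPS[op](table[col], value)
    return table[keep]


def top_fraction(table: pd.DataFrame, fraction: float = 0.10,
                 key: str = "total_score") -> pd.DataFrame:
    """Keep the ceil(fraction * n) lowest-``key`` rows; boundary ties kept."""
    if table.empty:
        raise ParameterError("top_fraction needs a non-empty table")
    if not 0 < fraction <= 1:
        raise ParameterError("fraction must be in (0, 1]")
    if key not in table.columns:
        raise ConfigurationError(f"no column {key!r} in score table")
    k = math.ceil(fraction * len(table))
    cutoff = table[key].nsmallest(k).iloc[-1]
    return table[table[key] <= cutoff]


@dataclass
class Cluster:
    representative: str
    members: list[str]
    representative_energy: float
    representative_rmsd_to_reference: float | None = None


@dataclass
class ClusterReport:
    clusters: list[Cluster] = field(default_factory=list)
    unclustered: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {"clusters": [vars(c) for c in self.clusters],
                "unclustered": list(self.unclustered)}


def scorewise_cluster(model_ids: Sequence[str],
                      energies: Sequence[float],
                      coords: Sequence[np.ndarray] | None = None,
                      dist_matrix: np.ndarray | None = None,
                      rmsd_cutoff: float = 4.0,
                      max_clusters: int | None = 5,
                      reference: np.ndarray | None = None) -> ClusterReport:
    """Score-wise clustering of an ensemble.

    Iteratively: the lowest-energy unclustered model seeds a cluster
    and absorbs every unclustered model within ``rmsd_cutoff`` of it
    (itself included); repeat until ``max_clusters`` clusters exist or
    the pool is empty.  Pairwise distances come from ``dist_matrix``
    when given, else from optimal-superposition RMSD of ``coords``.
    """
    n = len(model_ids)
    if n < 1:
        raise ParameterError("need at least one model")
    if len(energies) != n:
        raise DataError("energies and model_ids length mismatch")
    if dist_matrix is None and coords is None:
        raise ParameterError("provide coords or a distance matrix")
    if dist_matrix is not None:
        dist_matrix = np.asarray(dist_matrix, dtype=float)
        if dist_matrix.shape != (n, n):
            raise DataError("distance matrix shape mismatch")

    def dist(i: int, j: int) -> float:
        if dist_matrix is not None:
            return float(dist_matrix[i, j])
        return kabsch_rmsd(coords[i], coords[j])

    energies = np.asarray(energies, dtype=float)
    order = np.argsort(energies, kind="stable")
    unclustered = [int(i) for i in order]
    report = ClusterReport()
    while unclustered and (max_clusters is None
                           or len(report.clusters) < max_clusters):
        rep = unclustered[0]
        members = [i for i in unclustered if dist(rep, i) < rmsd_cutoff
                   or i == rep]
        unclustered = [i for i in unclustered if i not in members]
        rep_rmsd = None
        if reference is not None and coords is not None:
            rep_rmsd = kabsch_rmsd(coords[rep], reference)
        report.clusters.append(Cluster(
            representative=model_ids[rep],
            members=[model_ids[i] for i in members],
            representative_energy=float(energies[rep]),
            representative_rmsd_to_reference=rep_rmsd))
    report.unclustered = [model_ids[i] for i in unclustered]
    return report


def _interchain_contacts(records: list[ResidueRecord],
                         cutoff: float, atom: str) -> set:
    keyed = [(r.chain, r.resi,
              r.cb_xyz if atom == "CB" else r.ca_xyz) for r in records]
    contacts = set()
    for i, (ci, ri, xi) in enumerate(keyed):
        for cj, rj, xj in keyed[i + 1:]:
            if ci == cj:
                continue
            if np.linalg.norm(xi - xj) < cutoff:
                pair = tuple(sorted([(ci, ri), (cj, rj)]))
                contacts.add(pair)
    return contacts


def native_contact_fraction(model: list[ResidueRecord],
                            reference: list[ResidueRecord],
                            contact_cutoff: float = 8.0,
                            atom: str = "CB") -> float | None:
    """Fraction of reference inter-chain contacts preserved in a model.

    A contact is an inter-chain residue pair whose Cβ-Cβ distance
    (virtual Cβ for Gly; ``atom="CA"`` to use Cα) is below the cutoff
    in the reference.  Residues are matched by (chain, residue
    number).  A reference without inter-chain contacts has no defined
    fraction and returns ``None`` rather than 0.
    """
    if atom not in ("CB", "CA"):
        raise ParameterError("atom must be 'CB' or 'CA'")
    ref_contacts = _interchain_contacts(reference, contact_cutoff, atom)
    if not ref_contacts:
        return None
    model_contacts = _interchain_contacts(model, contact_cutoff, atom)
    return len(ref_contacts & model_contacts) / len(ref_contacts)


@dataclass
class DdgReport:
    medians: dict[str, float]
    calls: dict[str, str]               # "stabilising" / "destabilising"
    confusion: dict[str, int]           # TP / TN / FP / FN
    accuracy: float | None
    excluded: list[str] = field(default_factory=list)


def ddg_classify(mutation_tables: Mapping[str, pd.DataFrame],
                 wildtype_table: pd.DataFrame | None = None,
                 labels: Mapping[str, str] | None = None,
                 ddg_column: str = "ddg_binding",
                 threshold: float = 0.0) -> DdgReport:
    """Median-ΔΔG per mutation, sign classification, confusion counts.

    The per-mutation median of ``ddg_column`` (minus the wild-type
    median when a wild-type table is given) is classified as
    destabilising when above ``threshold`` and stabilising otherwise
    (the boundary counts as stabilising).  ``labels`` supplies the
    experimental classes ("stabilising"/"destabilising" or "-"/"+");
    destabilising is the positive class of the confusion matrix.
    Mutations with no surviving models are excluded from the counts.
    """
    wt_median = 0.0
    if wildtype_table is not None:
        if ddg_column not in wildtype_table.columns:
            raise ConfigurationError(f"no column {ddg_column!r} in wild-type "
                                     "table")
        wt_median = float(wildtype_table[ddg_column].median())

    norm = {"+": "destabilising", "-": "stabilising",
            "destabilising": "destabilising", "stabilising": "stabilising",
            "destabilizing": "destabilising", "stabilizing": "stabilising"}
    medians: dict[str, float] = {}
    calls: dict[str, str] = {}
    excluded: list[str] = []
    for mut, table in mutation_tables.items():
        if table.empty:
            excluded.append(mut)
            continue
        if ddg_column not in table.columns:
            raise ConfigurationError(f"no column {ddg_column!r} for {mut}")
        med = float(table[ddg_column].median()) - wt_median
        medians[mut] = med
        calls[mut] = "destabilising" if med > threshold else "stabilising"

    confusion = {"TP": 0, "TN": 0, "FP": 0, "FN": 0}
    accuracy = None
    if labels is not None:
        scored = 0
        for mut, call in calls.items():
            if mut not in labels:
                continue
            truth = norm[str(labels[mut]).lower()]
            scored += 1
            if call == "destabilising":
                confusion["TP" if truth == "destabilising" else "FP"] += 1
            else:
                confusion["TN" if truth == "stabilising" else "FN"] += 1
        if scored:
            accuracy = (confusion["TP"] + confusion["TN"]) / scored
    return DdgReport(medians=medians, calls=calls, confusion=confusion,
                     accuracy=accuracy, excluded=excluded)
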