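"""Kabsch RMSD, filters, score-wise clustering, contacts, ΔΔG calls."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.transform import Rotation

from memlipo import geometry as geo
from memlipo import selection as sel
from memlipo.errors import ConfigurationError, DataError, ParameterError


def brute_force_planar_rmsd(a, b, step=1e-4):
    """Grid-search oracle for planar point sets: scan in-plane rotations
    and in-plane rotations composed with a 180° flip about x."""
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    angles = np.arange(0.0, 2 * np.pi, step)
    cos, sin = np.cos(angles), np.sin(angles)
    best = np.inf
    for flip in (False, True):
        bb = b * np.array([1.0, -1.0, -1.0]) if flip else b
        x = cos[:, None] * bb[:, 0] - sin[:, None] * bb[:, 1]
        y = sin[:, None] * bb[:, 0] + cos[:, None] * bb[:, 1]
        d2 = (x - a[:, 0]) ** 2 + (y - a[:, 1]) ** 2 + bb[:, 2] ** 2
        best = min(best, np.sqrt(d2.mean(axis=1).min()))
    return best


class TestKabsch:
    def test_identity(self):
        pts = np.random.default_rng(0).normal(size=(10, 3))
        assert sel.kabsch_rmsd(pts, pts) == pytest.approx(0.0, abs=1e-7)

    def test_rotated_copy(self):
        pts = np.random.default_rng(1).normal(size=(8, 3)) * 5
        rot = Rotation.random(random_state=2).as_matrix()
        moved = pts @ rot.T + np.array([1.0, 2.0, 3.0])
        assert sel.kabsch_rmsd(pts, moved) == pytest.approx(0.0, abs=1e-6)

    def test_symmetric(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(size=(2, 6, 3))
        assert sel.kabsch_rmsd(a, b) == pytest.approx(sel.kabsch_rmsd(b, a))

    def test_matches_brute_force_on_planar_sets(self):
        rng = np.random.default_rng(4)
        for _ in range(3):
            a = np.column_stack([rng.uniform(-5, 5, (4, 2)), np.zeros(4)])
            b = np.column_stack([rng.uniform(-5, 5, (4, 2)), np.zeros(4)])
            assert sel.kabsch_rmsd(a, b) == pytest.approx(
                brute_force_planar_rmsd(a, b), abs=1e-3)

    def test_shape_mismatch(self):
        with pytest.raises(DataError):
            sel.kabsch_rmsd(np.zeros((4, 3)), np.zeros((5, 3)))

    def test_triangle_inequality(self):
        rng = np.random.default_rng(5)
        a, b, c = rng.normal(size=(3, 7, 3)) * 4
        ab = sel.kabsch_rmsd(a, b)
        bc = sel.kabsch_rmsd(b, c)
        ac = sel.kabsch_rmsd(a, c)
        assert ac <= ab + bc + 1e-9

    def test_homodimer_chain_swap(self):
        rng = np.random.default_rng(6)
        chain_a = rng.normal(size=(5, 3))
        chain_b = chain_a + np.array([8.0, 0, 0])
        dimer = np.concatenate([chain_a, chain_b])
        swapped = np.concatenate([chain_b, chain_a])
        assert sel.homodimer_rmsd(dimer, swapped, 5) \
            == pytest.approx(0.0, abs=1e-6)


class TestFilters:
    @pytest.fixture
    def table(self):
        return pd.DataFrame({
            "model_id": list("abcde"),
            "total_score": [-10.0, -9.0, -8.0, -7.0, -6.0],
            "helicality": [0.05, 0.2, 0.01, 0.5, 0.09],
            "helix_distance": [8.0, 8.5, 9.5, 7.0, 8.9],
        })

    def test_thresholds(self, table):
        out = sel.apply_filters(table, {"helicality": ("lt", 0.1),
                                        "helix_distance": ("lt", 9.0)})
        assert list(out.model_id) == ["a", "e"]

    def test_empty_table(self, table):
        out = sel.apply_filters(table.iloc[0:0], {"helicality": ("lt", 0.1)})
        assert out.empty

    def test_no_thresholds_is_identity(self, table):
        out = sel.apply_filters(table, {})
        assert out.equals(table)

    def test_absent_column_raises(self, table):
        with pytest.raises(ConfigurationError):
            sel.apply_filters(table, {"sasa": ("gt", 500.0)})

    def test_explicit_skip(self, table):
        out = sel.apply_filters(table, {"sasa": ("gt", 500.0)},
                                skip_missing=["sasa"])
        assert len(out) == len(table)

    def test_row_permutation_commutes(self, table):
        thresholds = {"helicality": ("lt", 0.1)}
        shuffled = table.sample(frac=1.0, random_state=1)
        a = set(sel.apply_filters(table, thresholds).model_id)
        b = set(sel.apply_filters(shuffled, thresholds).model_id)
        assert a == b


class TestTopFraction:
    def test_ten_percent_of_fifty(self):
        df = pd.DataFrame({"total_score": np.arange(50.0)})
        assert len(sel.top_fraction(df)) == 5

    def test_boundary_ties_kept(self):
        df = pd.DataFrame({"total_score": [1.0, 2.0, 2.0, 2.0, 5.0,
                                           6.0, 7.0, 8.0, 9.0, 10.0]})
        out = sel.top_fraction(df, fraction=0.2)
        assert len(out) == 4  # rows at the tied cutoff all kept

    def test_full_fraction_identity(self):
        df = pd.DataFrame({"total_score": [3.0, 1.0, 2.0]})
        assert len(sel.top_fraction(df, fraction=1.0)) == 3

    def test_empty_rejected(self):
        with pytest.raises(ParameterError):
            sel.top_fraction(pd.DataFrame({"total_score": []}))


def enumeration_oracle(ids, energies, dist, cutoff, max_clusters):
    """Independent simulation of the stated iterative clustering rule."""
    pool = sorted(range(len(ids)), key=lambda i: (energies[i], i))
    clusters = []
    while pool and (max_clusters is None or len(clusters) < max_clusters):
        rep = pool[0]
        members = set()
        for i in pool:
            if i == rep or dist[rep][i] < cutoff:
                members.add(i)
        clusters.append((ids[rep], sorted(ids[i] for i in members)))
        pool = [i for i in pool if i not in members]
    return clusters, sorted(ids[i] for i in pool)


class TestScorewiseCluster:
    def test_hand_example(self):
        # A(-10), B(-9, 2 Å from A), C(-8, 6 Å from A), D(-7, 3 Å from A)
        dist = np.array([[0, 2, 6, 3],
                         [2, 0, 7, 4],
                         [6, 7, 0, 5],
                         [3, 4, 5, 0]], dtype=float)
        report = sel.scorewise_cluster(list("ABCD"), [-10, -9, -8, -7],
                                       dist_matrix=dist, rmsd_cutoff=4.0,
                                       max_clusters=None)
        assert [c.representative for c in report.clusters] == ["A", "C"]
        assert sorted(report.clusters[0].members) == ["A", "B", "D"]
        assert report.clusters[1].members == ["C"]

    def test_identical_models_single_cluster(self):
        coords = [np.arange(12.0).reshape(4, 3)] * 5
        report = sel.scorewise_cluster([f"m{i}" for i in range(5)],
                                       list(range(5)), coords=coords)
        assert len(report.clusters) == 1
        assert len(report.clusters[0].members) == 5

    def test_zero_cutoff_singletons(self):
        dist = np.full((4, 4), 5.0)
        np.fill_diagonal(dist, 0.0)
        report = sel.scorewise_cluster(list("wxyz"), [4.0, 3.0, 2.0, 1.0],
                                       dist_matrix=dist, rmsd_cutoff=0.0,
                                       max_clusters=None)
        assert [c.representative for c in report.clusters] == list("zyxw")
        assert all(len(c.members) == 1 for c in report.clusters)

    def test_clusters_ordered_by_energy_and_partition(self):
        rng = np.random.default_rng(8)
        n = 8
        m = rng.uniform(0, 8, size=(n, n))
        dist = (m + m.T) / 2
        np.fill_diagonal(dist, 0.0)
        energies = rng.permutation(n).astype(float)
        ids = [f"m{i}" for i in range(n)]
        report = sel.scorewise_cluster(ids, energies, dist_matrix=dist,
                                       max_clusters=None)
        reps = [c.representative_energy for c in report.clusters]
        assert reps == sorted(reps)
        all_members = [m for c in report.clusters for m in c.members]
        assert sorted(all_members) == sorted(ids)  # exactly one cluster each

    def test_representatives_pairwise_separated(self):
        rng = np.random.default_rng(9)
        coords = [rng.normal(size=(6, 3)) * 3 for _ in range(8)]
        report = sel.scorewise_cluster([f"m{i}" for i in range(8)],
                                       list(range(8)), coords=coords,
                                       rmsd_cutoff=2.0, max_clusters=None)
        reps = {c.representative: coords[int(c.representative[1:])]
                for c in report.clusters}
        names = list(reps)
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                assert sel.kabsch_rmsd(reps[a], reps[b]) >= 2.0


def contact_record(chain, resi, xyz):
    xyz = np.asarray(xyz, dtype=float)
    return geo.ResidueRecord(chain=chain, resi=resi, amino_acid="A",
                             ca_xyz=xyz, n_xyz=xyz, c_xyz=xyz, cb_xyz=xyz,
                             atoms=np.array([xyz]))


class TestNativeContacts:
    @pytest.fixture
    def reference(self):
        recs = []
        for i in range(4):
            recs.append(contact_record("A", i + 1, [0.0, 0.0, 20.0 * i]))
            recs.append(contact_record("B", i + 1, [5.0, 0.0, 20.0 * i]))
        return recs

    def test_identity_is_one(self, reference):
        assert sel.native_contact_fraction(reference, reference) == 1.0

    def test_separated_chains_zero(self, reference):
        moved = [contact_record(r.chain, r.resi,
                                r.cb_xyz + (50.0 if r.chain == "B" else 0.0)
                                * np.array([1.0, 0, 0]))
                 for r in reference]
        assert sel.native_contact_fraction(moved, reference) == 0.0

    def test_three_of_four_contacts(self, reference):
        model = [contact_record(r.chain, r.resi,
                                r.cb_xyz + (np.array([45.0, 0, 0])
                                            if (r.chain, r.resi) == ("B", 4)
                                            else 0.0))
                 for r in reference]
        assert sel.native_contact_fraction(model, reference) == 0.75

    def test_zero_contact_reference_undefined(self):
        ref = [contact_record("A", 1, [0, 0, 0]),
               contact_record("B", 1, [100.0, 0, 0])]
        assert sel.native_contact_fraction(ref, ref) is None

    def test_monotone_under_pulling(self, reference):
        fractions = []
        for pull in (0.0, 2.0, 4.0, 8.0, 20.0):
            model = [contact_record(r.chain, r.resi,
                                    r.cb_xyz + (pull if r.chain == "B"
                                                else 0.0)
                                    * np.array([1.0, 0, 0]))
                     for r in reference]
            fractions.append(sel.native_contact_fraction(model, reference))
        assert fractions == sorted(fractions, reverse=True)


class TestDdgClassify:
    def test_sign_agreement(self):
        tables = {"M1": pd.DataFrame({"ddg_binding": [1.0, 1.0, 2.0]}),
                  "M2": pd.DataFrame({"ddg_binding": [-2.0, -2.5]})}
        labels = {"M1": "destabilising", "M2": "stabilising"}
        report = sel.ddg_classify(tables, labels=labels)
        assert report.confusion == {"TP": 1, "TN": 1, "FP": 0, "FN": 0}
        assert report.accuracy == 1.0

    def test_zero_median_is_stabilising(self):
        tables = {"M": pd.DataFrame({"ddg_binding": [0.0]})}
        report = sel.ddg_classify(tables)
        assert report.calls["M"] == "stabilising"

    def test_empty_mutation_excluded(self):
        tables = {"M1": pd.DataFrame({"ddg_binding": [1.0]}),
                  "M2": pd.DataFrame({"ddg_binding": []})}
        report = sel.ddg_classify(tables, labels={"M1": "+", "M2": "-"})
        assert report.excluded == ["M2"]
        assert sum(report.confusion.values()) == 1

    def test_wildtype_reference_shift(self):
        tables = {"M": pd.DataFrame({"ddg_binding": [3.0, 3.0]})}
        wt = pd.DataFrame({"ddg_binding": [5.0]})
        report = sel.ddg_classify(tables, wildtype_table=wt)
        assert report.medians["M"] == pytest.approx(-2.0)
        assert report.calls["M"] == "stabilising"

    def test_synthetic_set_matches_hand_tally(self):
        rng = np.random.default_rng(13)
        true_ddg = rng.uniform(-4, 4, size=32)
        tables, labels = {}, {}
        for i, d in enumerate(true_ddg):
            noise = rng.normal(scale=0.5, size=7)
            tables[f"mut{i}"] = pd.DataFrame({"ddg_binding": d + noise})
            labels[f"mut{i}"] = "+" if d > 0 else "-"
        report = sel.ddg_classify(tables, labels=labels)
        tally = {"TP": 0, "TN": 0, "FP": 0, "FN": 0}
        for i in range(32):
            med = float(np.median(tables[f"mut{i}"]["ddg_binding"]))
            pred_pos = med > 0
            true_pos = labels[f"mut{i}"] == "+"
            key = ("TP" if true_pos else "FP") if pred_pos \
                else ("TN" if not true_pos else "FN")
            tally[key] += 1
        assert report.confusion == tally
        assert report.accuracy == pytest.approx(
            (tally["TP"] + tally["TN"]) / 32)
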