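import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from phasesep.fixtures import make_sticker_toy
from phasesep.pipeline import analyze_model
from phasesep.stickers import (
    ChargeAssignment,
    candidate_residues,
    cluster_stickers,
    net_charge_index,
    sticker_pipeline,
    summarize_stickers,
    threshold_scan,
)
from phasesep.structure_io import Atom, ProteinModel, Residue

from .oracles import centroid_linkage_oracle


def point_model(sequence, coords):
    """Model whose residues are single Cα atoms at the given coordinates."""
    residues = [
        Residue(
            index=i + 1,
            aa=sequence[i],
            atoms=[Atom("CA", "C", coords[i])],
            plddt=90.0,
        )
        for i in range(len(sequence))
    ]
    return ProteinModel(id="points", sequence=sequence, residues=residues)


class TestNCI:
    def test_no_charges_all_zero(self):
        model = point_model("GGGG", np.arange(12).reshape(4, 3) * 2.0)
        nci = net_charge_index(model, [1, 2, 3, 4])
        assert set(nci.values()) == {0}

    def test_four_lysines_self_included(self):
        coords = np.array([[0, 0, 0], [5, 0, 0], [0, 5, 0], [5, 5, 0]], dtype=float)
        model = point_model("KKKK", coords)
        nci = net_charge_index(model, [1, 2, 3, 4])
        assert all(v == 4 for v in nci.values())

    def test_balanced_charges_cancel(self):
        coords = np.array(
            [[0, 0, 0], [4, 0, 0], [0, 4, 0], [2, 2, 2], [4, 4, 0], [2, 0, 3]],
            dtype=float,
        )
        model = point_model("KKKDDD", coords)
        nci = net_charge_index(model, list(range(1, 7)))
        assert set(nci.values()) == {0}

    def test_empty_ssup(self):
        model = point_model("K", np.zeros((1, 3)))
        assert net_charge_index(model, []) == {}

    def test_distance_cutoff_inclusive(self):
        coords = np.array([[0, 0, 0], [14.0, 0, 0]])
        model = point_model("KK", coords)
        nci = net_charge_index(model, [1, 2], distance=14.0)
        assert nci == {1: 2, 2: 2}

    def test_antisymmetry_under_charge_swap(self):
        rng = np.random.default_rng(0)
        coords = rng.uniform(0, 30, size=(12, 3))
        seq = "KKKRDDEEGGSA"
        model = point_model(seq, coords)
        charges = ChargeAssignment()
        ssup = list(range(1, 13))
        nci = net_charge_index(model, ssup, charges=charges)
        swapped = net_charge_index(model, ssup, charges=charges.swapped())
        assert {i: -v for i, v in nci.items()} == swapped

    def test_nonpositive_distance(self):
        model = point_model("K", np.zeros((1, 3)))
        with pytest.raises(ValueError):
            net_charge_index(model, [1], distance=0.0)


class TestCandidates:
    @pytest.mark.parametrize("value,expected", [(4, True), (3, False), (-5, True), (0, False)])
    def test_cutoff(self, value, expected):
        cands = candidate_residues({7: value})
        assert (7 in cands) is expected


class TestClustering:
    def test_two_separated_groups(self):
        coords = np.vstack([
            np.array([[0, 0, 0], [3, 0, 0], [0, 3, 0], [3, 3, 0]], dtype=float),
            np.array([[50, 0, 0], [53, 0, 0], [50, 3, 0], [53, 3, 0]], dtype=float),
        ])
        model = point_model("KKKKDDDD", coords)
        nci = {i: 4 if i <= 4 else -4 for i in range(1, 9)}
        clusters = cluster_stickers(list(range(1, 9)), model, nci)
        assert len(clusters) == 2
        signs = sorted(c.sign for c in clusters)
        assert signs == ["+", "-"]

    def test_single_candidate(self):
        model = point_model("K", np.zeros((1, 3)))
        clusters = cluster_stickers([1], model, {1: 5})
        assert len(clusters) == 1
        assert clusters[0].members == (1,)
        assert clusters[0].sign == "+"

    def test_empty(self):
        model = point_model("K", np.zeros((1, 3)))
        assert cluster_stickers([], model, {}) == []

    def test_zero_sum_cluster_discarded(self, caplog):
        coords = np.array([[0, 0, 0], [3, 0, 0]], dtype=float)
        model = point_model("KD", coords)
        with caplog.at_level("WARNING"):
            clusters = cluster_stickers([1, 2], model, {1: 4, 2: -4})
        assert clusters == []
        assert any("zero-sum" in r.message for r in caplog.records)

    def test_oracle_equivalence_random_sets(self):
        rng = np.random.default_rng(123)
        for _ in range(150):
            n = int(rng.integers(1, 13))
            coords = rng.uniform(0, 60, size=(n, 3))
            seq = "".join(rng.choice(list("KD"), size=n))
            model = point_model(seq, coords)
            # asymmetric magnitudes so no cluster can sum to exactly zero
            nci = {i + 1: (5 if seq[i] == "K" else -4) for i in range(n)}
            clusters = cluster_stickers(list(range(1, n + 1)), model, nci)
            got = sorted(tuple(m - 1 for m in c.members) for c in clusters)
            expected = centroid_linkage_oracle(coords, 14.0)
            assert got == expected
            for c in clusters:
                n_plus = sum(1 for m in c.members if seq[m - 1] == "K")
                n_minus = len(c.members) - n_plus
                if n_plus != n_minus:
                    expected_sign = "+" if n_plus > n_minus else "-"
                else:
                    expected_sign = "+" if 5 * n_plus - 4 * n_minus > 0 else "-"
                assert c.sign == expected_sign


class TestSummary:
    def test_arithmetic(self):
        clusters = [
            type("C", (), {"sign": "+"})(),
            type("C", (), {"sign": "-"})(),
        ]
        s = summarize_stickers(clusters, 100)
        assert (s.n_total, s.n_pairs) == (2, 1)
        assert s.freq_sticker == pytest.approx(0.02)
        assert s.freq_pair == pytest.approx(0.01)

    def test_no_negative_clusters(self):
        clusters = [type("C", (), {"sign": "+"})() for _ in range(3)]
        s = summarize_stickers(clusters, 10)
        assert s.n_pairs == 0

    def test_empty_ssup_zero_frequencies(self):
        s = summarize_stickers([], 0)
        assert s.freq_sticker == 0.0 and s.freq_pair == 0.0


class TestRigidMotionInvariance:
    def test_counts_invariant(self, sticker_toy_21, internal_config):
        base = analyze_model(sticker_toy_21, internal_config)
        rng = np.random.default_rng(9)
        rot = Rotation.random(rng=rng).as_matrix()
        shift = rng.uniform(-50, 50, 3)
        moved = ProteinModel(
            id="moved",
            sequence=sticker_toy_21.sequence,
            residues=[
                Residue(
                    index=r.index,
                    aa=r.aa,
                    atoms=[Atom(a.name, a.element, rot @ a.position + shift) for a in r.atoms],
                    plddt=r.plddt,
                )
                for r in sticker_toy_21.residues
            ],
        )
        after = analyze_model(moved, internal_config)
        assert after.sticker_summary == base.sticker_summary


class TestThresholdScan:
    def test_chargeless_cohort_tie_break(self):
        model = point_model("GGGG", np.arange(12).reshape(4, 3) * 3.0)
        best, fractions = threshold_scan([(model, [1, 2, 3, 4])])
        assert best == 10
        assert set(fractions.values()) == {0.0}

    def test_single_protein_fraction_binary(self, sticker_toy_21):
        ssup = list(range(1, len(sticker_toy_21) + 1))
        _, fractions = threshold_scan([(sticker_toy_21, ssup)])
        assert set(fractions.values()) <= {0.0, 1.0}

    def test_engineered_cohort_prefers_14(self):
        # 3 square clusters; intra-cluster diagonal 13.5 A so candidates only
        # exist at >= 14 A; clusters 60 A apart never merge in 10..20.
        side = 13.5 / np.sqrt(2)
        square = np.array([[0, 0], [side, 0], [0, side], [side, side]])
        coords = np.vstack([
            np.column_stack([square[:, 0] + k * 60.0, square[:, 1], np.zeros(4)])
            for k in range(3)
        ])
        model = point_model("K" * 12, coords)
        ssup = list(range(1, 13))
        best, fractions = threshold_scan([(model, ssup)])
        assert fractions[13] == 0.0
        assert fractions[14] == 1.0
        assert best == 14


def test_pipeline_members_subset_of_ssup(sticker_toy_21, internal_config):
    analysis = analyze_model(sticker_toy_21, internal_config)
    ssup = set(analysis.ssup)
    for cluster in analysis.clusters:
        assert set(cluster.members) <= ssup


def test_heavy_metric_matches_ca_for_point_residues():
    rng = np.random.default_rng(1)
    coords = rng.uniform(0, 40, size=(8, 3))
    model = point_model("KKKKDDDD", coords)
    ssup = list(range(1, 9))
    ca = net_charge_index(model, ssup, metric="ca")
    heavy = net_charge_index(model, ssup, metric="heavy")
    assert ca == heavy
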