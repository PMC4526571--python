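import numpy as np
import pytest

from pocketsim import (
    PCProp,
    Pseudocenter,
    consensus_site,
    make_recovery_family,
    multiple_align,
    pairwise_align,
    pseudocenters,
    read_consensus_json,
    write_consensus,
)
from pocketsim.errors import IncompleteResidueError, TooSmallSiteError
from pocketsim.structure import BindingSite
from .conftest import dummy_ligand, make_residue, site_from_structure


def hexagon_phe(res_seq=1):
    """PHE with an ideal hexagonal ring centred at (10, 0, 0)."""
    ring = []
    for i, name in enumerate(("CG", "CD1", "CE1", "CZ", "CE2", "CD2")):
        ang = np.pi / 3 * i
        ring.append((name, "C", (10 + 1.4 * np.cos(ang), 1.4 * np.sin(ang), 0.0)))
    return make_residue(
        "PHE",
        [("N", "N", (6, 0, 0)), ("CA", "C", (7, 0, 0)), ("C", "C", (7, 1, 0)),
         ("O", "O", (7, 2, 0)), ("CB", "C", (8, 0, 0))] + ring,
        res_seq=res_seq,
    )


def _site(residues):
    return BindingSite(residues=residues, ligand=dummy_ligand(), cutoff=4.0,
                       source_label="fixture")


class TestPseudocenters:
    def test_ser_single_donor_acceptor_at_og(self):
        ser = make_residue("SER", [("N", "N", (-1, 0, 0)), ("CA", "C", (0, 0, 0)),
                                   ("CB", "C", (1, 0, 0)), ("OG", "O", (2, 0, 0))])
        (pc,) = pseudocenters(_site([ser]))
        assert pc.prop is PCProp.DONOR_ACCEPTOR
        np.testing.assert_allclose(pc.coord, [2, 0, 0])

    def test_phe_aromatic_at_ring_centroid(self):
        (pc,) = pseudocenters(_site([hexagon_phe()]))
        assert pc.prop is PCProp.AROMATIC
        np.testing.assert_allclose(pc.coord, [10, 0, 0], atol=1e-12)

    def test_asn_emits_donor_and_acceptor(self):
        asn = make_residue("ASN", [("N", "N", (-1, 0, 0)), ("CA", "C", (0, 0, 0)),
                                   ("CB", "C", (1, 0, 0)), ("CG", "C", (2, 0, 0)),
                                   ("OD1", "O", (3, 0, 0)), ("ND2", "N", (2, 1, 0))])
        props = {pc.prop: pc for pc in pseudocenters(_site([asn]))}
        assert set(props) == {PCProp.DONOR, PCProp.ACCEPTOR}
        np.testing.assert_allclose(props[PCProp.DONOR].coord, [2, 1, 0])
        np.testing.assert_allclose(props[PCProp.ACCEPTOR].coord, [3, 0, 0])

    def test_his_is_aromatic_plus_donor_acceptor(self):
        his = make_residue("HIS", [("N", "N", (-1, 0, 0)), ("CA", "C", (0, 0, 0)),
                                   ("CB", "C", (1, 0, 0)), ("CG", "C", (2, 0, 0)),
                                   ("ND1", "N", (3, 1, 0)), ("CD2", "C", (3, -1, 0)),
                                   ("CE1", "C", (4, 1, 0)), ("NE2", "N", (4, -1, 0))])
        props = {pc.prop for pc in pseudocenters(_site([his]))}
        assert props == {PCProp.AROMATIC, PCProp.DONOR_ACCEPTOR}

    def test_missing_atom_is_error(self):
        broken = make_residue("SER", [("N", "N", (-1, 0, 0)), ("CA", "C", (0, 0, 0)),
                                      ("CB", "C", (1, 0, 0))])
        with pytest.raises(IncompleteResidueError, match="OG"):
            pseudocenters(_site([broken]))


def _random_pc_set(rng, n=8):
    props = [PCProp.ALIPHATIC, PCProp.AROMATIC, PCProp.ACCEPTOR, PCProp.DONOR]
    out = []
    for i in range(n):
        out.append(
            Pseudocenter(
                coord=rng.uniform(-8, 8, 3),
                prop=props[i % len(props)],
                residue_key=("A", i + 1, "ALA"),
                site_label="a",
            )
        )
    return out


def _transformed(pcs, R, t, label="b"):
    return [
        Pseudocenter(coord=R @ p.coord + t, prop=p.prop, residue_key=p.residue_key,
                     site_label=label)
        for p in pcs
    ]


class TestPairwiseAlign:
    def test_exact_recovery_under_rigid_motion(self):
        rng = np.random.default_rng(0)
        a = _random_pc_set(rng)
        from pocketsim import random_rigid

        R, t = random_rigid(rng)
        b = _transformed(a, R, t)
        al = pairwise_align(a, b)
        assert al.score == len(a)
        assert al.rmsd < 1e-6
        assert sorted(al.correspondences) == [(i, i) for i in range(len(a))]

    def test_recovered_transform_matches_generator(self):
        rng = np.random.default_rng(1)
        a = _random_pc_set(rng)
        from pocketsim import random_rigid

        R, t = random_rigid(rng)
        noisy = [
            Pseudocenter(coord=R @ p.coord + t + rng.normal(0, 0.3, 3), prop=p.prop,
                         residue_key=p.residue_key, site_label="b")
            for p in a
        ]
        al = pairwise_align(a, noisy)
        assert al.score == len(a)
        # the estimated b->a transform should invert the planted a->b motion
        R_est, t_est = al.transforms[1]
        xa = np.stack([p.coord for p in a])
        recovered = (np.stack([p.coord for p in noisy]) @ R_est.T) + t_est
        rms = np.sqrt(np.mean(np.sum((recovered - xa) ** 2, axis=1)))
        assert rms < 0.5

    def test_property_mismatch_scores_zero(self):
        rng = np.random.default_rng(2)
        a = [Pseudocenter(rng.uniform(-5, 5, 3), PCProp.AROMATIC, ("A", i, "PHE"), "a")
             for i in range(4)]
        b = [Pseudocenter(p.coord.copy(), PCProp.ACCEPTOR, ("A", p.residue_key[1], "ASP"), "b")
             for p in a]
        assert pairwise_align(a, b).score == 0

    def test_too_small_input_rejected(self):
        rng = np.random.default_rng(3)
        a = _random_pc_set(rng, n=2)
        with pytest.raises(TooSmallSiteError):
            pairwise_align(a, a)

    def test_deterministic(self):
        rng = np.random.default_rng(4)
        a = _random_pc_set(rng, n=10)
        b = _random_pc_set(np.random.default_rng(5), n=10)
        first = pairwise_align(a, b)
        second = pairwise_align(a, b)
        assert first.score == second.score
        assert first.correspondences == second.correspondences
        np.testing.assert_array_equal(first.transforms[1][0], second.transforms[1][0])


class TestMultipleAlign:
    def test_three_identical_sites_full_score(self):
        rng = np.random.default_rng(6)
        a = _random_pc_set(rng)
        al = multiple_align([a, list(a), list(a)])
        assert al.score == len(a)

    def test_two_sites_reduce_to_pairwise(self):
        rng = np.random.default_rng(7)
        a = _random_pc_set(rng)
        b = _random_pc_set(np.random.default_rng(8))
        assert multiple_align([a, b]).score == pairwise_align(a, b).score

    def test_planted_core_recovered(self):
        structs, truth = make_recovery_family(k=5, seed=0)
        sites = [site_from_structure(s, cutoff=14.0, label=f"site{i}")
                 for i, s in enumerate(structs)]
        pc_sets = [pseudocenters(s) for s in sites]
        al = multiple_align(pc_sets, epsilon=3.0)
        assert al.score == truth["core_size"]
        core = set(truth["core_res_seqs"])
        for tup in al.correspondences:
            for s, idx in enumerate(tup):
                assert pc_sets[s][idx].residue_key[1] in core


class TestConsensus:
    def _aligned_family(self, k=5, seed=0):
        structs, truth = make_recovery_family(k=k, seed=seed)
        pc_sets = [
            pseudocenters(site_from_structure(s, cutoff=14.0, label=f"site{i}"))
            for i, s in enumerate(structs)
        ]
        al = multiple_align(pc_sets, epsilon=3.0)
        return al, pc_sets, truth

    def test_identical_sites_merge_everything(self):
        rng = np.random.default_rng(9)
        a = _random_pc_set(rng)
        sites = [a, list(a), list(a)]
        cons = consensus_site(multiple_align(sites), sites)
        assert len(cons.merged) == len(a)
        assert cons.preserved == []

    def test_partition_accounts_for_every_pseudocenter(self):
        al, pc_sets, _ = self._aligned_family()
        cons = consensus_site(al, pc_sets)
        total = sum(len(s) for s in pc_sets)
        assert len(cons.merged) * len(pc_sets) + len(cons.preserved) == total

    def test_class_incompatible_tuple_is_preserved(self):
        # DONOR pseudocenters from LYS (positive) vs ASN (polar) may match
        # geometrically but must not merge.
        coords = [np.zeros(3), np.array([4.0, 0, 0]), np.array([0, 4.0, 0]),
                  np.array([4.0, 4.0, 0])]
        def site(res_names, label):
            return [
                Pseudocenter(coords[i], PCProp.DONOR, ("A", i + 1, res_names[i]), label)
                for i in range(4)
            ]
        s0 = site(["LYS", "ASN", "ASN", "ASN"], "s0")
        s1 = site(["ASN", "ASN", "ASN", "ASN"], "s1")
        s2 = site(["ASN", "ASN", "ASN", "ASN"], "s2")
        al = multiple_align([s0, s1, s2])
        cons = consensus_site(al, [s0, s1, s2])
        merged_names = {m.members[0][1][2] for m in cons.merged}
        assert "LYS" not in merged_names
        preserved_keys = {(p.site_label, p.residue_key) for p in cons.preserved}
        assert ("s0", ("A", 1, "LYS")) in preserved_keys

    def test_pdb_output_encodes_property_and_site_count(self):
        al, pc_sets, _ = self._aligned_family()
        cons = consensus_site(al, pc_sets)
        text = write_consensus(cons, "pdb")
        het = [ln for ln in text.splitlines() if ln.startswith("HETATM")]
        assert len(het) == len(cons.merged) + len(cons.preserved)
        for ln in het[: len(cons.merged)]:
            assert ln[17:20] in {"ARO", "ALI", "DON", "ACC", "DAC"}
            assert float(ln[60:66]) == 3.0

    def test_json_round_trip(self):
        al, pc_sets, _ = self._aligned_family()
        cons = consensus_site(al, pc_sets)
        back = read_consensus_json(write_consensus(cons, "json"))
        assert back.n_sites == cons.n_sites
        assert len(back.merged) == len(cons.merged)
        assert len(back.preserved) == len(cons.preserved)
        for p, q in zip(cons.merged, back.merged):
            np.testing.assert_allclose(p.coord, q.coord)
            assert p.prop is q.prop
            assert p.members == q.members

    def test_empty_consensus_serializes(self):
        from pocketsim.alignment import ConsensusSite

        empty = ConsensusSite(merged=[], preserved=[], n_sites=3)
        assert "END" in write_consensus(empty, "pdb")
        assert read_consensus_json(write_consensus(empty, "json")).merged == []
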