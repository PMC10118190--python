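"""Steric clash detection and the binding-compatibility statistic."""

import numpy as np
import pytest

from _oracles import brute_force_clashes
from gefprobe import synth
from gefprobe.clash import (
    ResidueMap,
    build_residue_map,
    compatibility_fraction,
    detect_clashes,
)
from gefprobe.structures import Atom, Ensemble, SelectionSpec, Structure
from gefprobe.superpose import SelectionError


def _carbon(serial, resnum, xyz, chain="A"):
    return Atom(serial=serial, name="CA", element="C", residue_name="ALA",
                chain_id=chain, residue_number=resnum,
                coords=np.asarray(xyz, float))


class TestDetectClashes:
    def test_distant_carbons_do_not_clash(self):
        a = [_carbon(1, 1, [0, 0, 0])]
        b = [_carbon(2, 2, [4.0, 0, 0])]
        rep = detect_clashes(a, np.array([[0.0, 0, 0]]), b, np.array([[4.0, 0, 0]]))
        assert rep.is_compatible and rep.n_clashes == 0
        assert rep.min_distance == pytest.approx(4.0)

    def test_overlapping_carbons_clash_with_overlap_recorded(self):
        # r_C + r_C = 3.40; at d = 2.0 the overlap is 1.4 >= 0.4
        a = [_carbon(1, 1, [0, 0, 0])]
        b = [_carbon(2, 2, [2.0, 0, 0])]
        rep = detect_clashes(a, np.array([[0.0, 0, 0]]), b, np.array([[2.0, 0, 0]]))
        assert not rep.is_compatible
        i, j, d, overlap = rep.clashing_pairs[0]
        assert d == pytest.approx(2.0)
        assert overlap == pytest.approx(1.4)

    @pytest.mark.parametrize("seed", range(5))
    def test_random_clouds_match_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        ca = rng.uniform(0, 12, size=(50, 3))
        cb = rng.uniform(0, 12, size=(50, 3))
        atoms_a = [_carbon(i, i + 1, ca[i]) for i in range(50)]
        atoms_b = [_carbon(i, i + 1, cb[i], chain="B") for i in range(50)]
        rep = detect_clashes(atoms_a, ca, atoms_b, cb, overlap_threshold=0.4)
        got = {(i, j) for i, j, _, _ in rep.clashing_pairs}
        expected = brute_force_clashes(
            ca, np.full(50, 1.70), cb, np.full(50, 1.70), 0.4
        )
        assert got == expected

    def test_empty_selection_rejected(self):
        with pytest.raises(SelectionError):
            detect_clashes([], np.empty((0, 3)), [], np.empty((0, 3)))


class TestResidueMap:
    def test_identical_anchor_sequences_map_one_to_one(self):
        ens, template, *_ = synth.make_binding_scenario(0.0, 5, seed=1)
        anchor = SelectionSpec(chain_id="A", residue_range=(1, 50))
        rmap = build_residue_map(ens.topology, anchor, template, anchor, mode="auto")
        assert rmap.source == "alignment-derived"
        assert rmap.pairs == [(("A", r), ("A", r)) for r in range(1, 51)]

    def test_insertion_leaves_flanks_paired(self):
        # mobile has a 2-residue insertion relative to the template
        seq = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ"
        mob_atoms = [
            Atom(serial=i + 1, name="CA", element="C",
                 residue_name=_one_to_three(c), chain_id="A",
                 residue_number=i + 1, coords=np.array([3.8 * i, 0.0, 0.0]))
            for i, c in enumerate(seq)
        ]
        tem_seq = seq[:10] + seq[12:]  # residues 11-12 deleted
        tem_atoms = [
            Atom(serial=i + 1, name="CA", element="C",
                 residue_name=_one_to_three(c), chain_id="A",
                 residue_number=i + 1, coords=np.array([3.8 * i, 0.0, 0.0]))
            for i, c in enumerate(tem_seq)
        ]
        mob = Structure(atoms=mob_atoms, label="mob")
        tem = Structure(atoms=tem_atoms, label="tem")
        anchor = SelectionSpec(chain_id="A")
        rmap = build_residue_map(mob, anchor, tem, anchor, mode="auto")
        mapped_mobile = {p[0][1] for p in rmap.pairs}
        assert len(rmap.pairs) == len(tem_seq)
        assert 11 not in mapped_mobile and 12 not in mapped_mobile

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            ResidueMap(pairs=[(("A", 1), ("A", 1)), (("A", 2), ("A", 2))])

    def test_duplicate_residues_rejected(self):
        with pytest.raises(ValueError, match="one-to-one"):
            ResidueMap(pairs=[(("A", 1), ("A", 1)), (("A", 2), ("A", 1)),
                              (("A", 3), ("A", 3))])


def _one_to_three(c):
    from gefprobe.clash import THREE_TO_ONE

    table = {v: k for k, v in THREE_TO_ONE.items()
             if k not in ("SEP", "TPO", "MSE")}
    return table[c]


class TestCompatibility:
    def test_clear_ensemble_is_fully_compatible(self):
        ens, tpl, rmap, rm, rt, _ = synth.make_binding_scenario(0.0, 20, seed=2)
        res = compatibility_fraction(ens, tpl, rmap, rm, rt)
        assert res.percent_compatible == 100.0

    def test_constructed_intrusion_count_recovered_exactly(self):
        ens, tpl, rmap, rm, rt, truth = synth.make_binding_scenario(
            0.3, 100, seed=3, n_intrude=30
        )
        res = compatibility_fraction(ens, tpl, rmap, rm, rt)
        assert res.percent_compatible == 70.0
        flags = [not r.is_compatible for r in res.per_frame]
        assert flags == truth["intruded"]

    def test_infinite_threshold_makes_everything_compatible(self):
        ens, tpl, rmap, rm, rt, _ = synth.make_binding_scenario(1.0, 10, seed=4)
        res = compatibility_fraction(ens, tpl, rmap, rm, rt,
                                     overlap_threshold=float("inf"))
        assert res.percent_compatible == 100.0

    def test_monotone_in_overlap_threshold(self):
        ens, tpl, rmap, rm, rt, _ = synth.make_binding_scenario(0.5, 40, seed=5)
        pcts = [
            compatibility_fraction(ens, tpl, rmap, rm, rt,
                                   overlap_threshold=thr).percent_compatible
            for thr in (0.0, 0.4, 1.0, 4.0)
        ]
        assert pcts == sorted(pcts)

    def test_invariant_under_rigid_transform_of_both_sides(self, rng):
        ens, tpl, rmap, rm, rt, _ = synth.make_binding_scenario(0.4, 30, seed=6)
        base = compatibility_fraction(ens, tpl, rmap, rm, rt)
        rot = synth._random_rotation(rng)
        t = np.array([7.0, -3.0, 1.0])
        moved_ens = Ensemble(topology=ens.topology,
                             frames=[f @ rot.T + t for f in ens.frames],
                             species_label=ens.species_label)
        moved_tpl = tpl.with_coords(tpl.coords @ rot.T + t)
        res = compatibility_fraction(moved_ens, moved_tpl, rmap, rm, rt)
        assert res.percent_compatible == base.percent_compatible
        for r1, r2 in zip(base.per_frame, res.per_frame):
            assert r1.min_distance == pytest.approx(r2.min_distance, abs=1e-9)

    def test_frame_order_permutation_preserves_percentage(self, rng):
        ens, tpl, rmap, rm, rt, _ = synth.make_binding_scenario(0.4, 30, seed=7)
        base = compatibility_fraction(ens, tpl, rmap, rm, rt).percent_compatible
        perm = rng.permutation(ens.n_frames)
        shuffled = Ensemble(topology=ens.topology,
                            frames=[ens.frames[i] for i in perm],
                            species_label=ens.species_label)
        assert compatibility_fraction(shuffled, tpl, rmap, rm, rt).percent_compatible == base

    def test_bernoulli_intrusion_converges_to_rate(self):
        p = 0.3
        ens, tpl, rmap, rm, rt, truth = synth.make_binding_scenario(p, 400, seed=8)
        res = compatibility_fraction(ens, tpl, rmap, rm, rt)
        # exact agreement with the realised labels, binomial-error agreement with p
        assert res.percent_compatible == truth["expected_percent_compatible"]
        se = 100 * np.sqrt(p * (1 - p) / 400)
        assert abs(res.percent_compatible - 100 * (1 - p)) < 4 * se

    def test_empty_region_selection_rejected(self):
        ens, tpl, rmap, rm, rt, _ = synth.make_binding_scenario(0.0, 5, seed=9)
        bad = SelectionSpec(chain_id="Q")
        with pytest.raises(SelectionError):
            compatibility_fraction(ens, tpl, rmap, bad, rt)
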