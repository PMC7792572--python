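"""Backbone PDB I/O, virtual Cβ geometry, and pair-observation extraction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mhcii3dlite.exceptions import GeometryError, ParameterError, PDBParseError
from mhcii3dlite.pdbio import (
    PairObservation,
    ResidueRecord,
    StructureModel,
    extract_pair_observations,
    filter_training_set,
    parse_pdb,
    virtual_cb,
    write_pdb,
)


def _atom_line(serial, name, resname, chain, resseq, x, y, z, record="ATOM"):
    return (
        f"{record:<6}{serial:>5} {name:^4} {resname:<3} {chain}{resseq:>4}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
    )


def _chain_pdb(chain_id="A", residues=("ALA", "ALA", "ALA"), with_cb=True, start=1):
    lines, serial = [], 1
    for i, resname in enumerate(residues):
        x = 3.8 * i
        lines.append(_atom_line(serial, "CA", resname, chain_id, start + i, x, 0, 0))
        serial += 1
        if with_cb and resname != "GLY":
            lines.append(_atom_line(serial, "CB", resname, chain_id, start + i, x, 1.53, 0))
            serial += 1
    return lines


class TestParse:
    def test_counts_and_cb_presence(self):
        text = "\n".join(_chain_pdb() + ["END"])
        m = parse_pdb(text)
        assert list(m.chains) == ["A"]
        assert len(m.chains["A"]) == 3
        assert all(r.cb is not None for r in m.chains["A"])

    def test_glycine_has_no_cb_by_default(self):
        text = "\n".join(_chain_pdb(residues=("ALA", "GLY", "ALA")) + ["END"])
        m = parse_pdb(text)
        assert m.chains["A"][1].aa == "G"
        assert m.chains["A"][1].cb is None

    def test_chain_order_and_residue_lookup(self):
        lines = (
            _chain_pdb("A") + _chain_pdb("B") + _chain_pdb("P", ("ALA",) * 6)
        )
        m = parse_pdb("\n".join(lines + ["END"]))
        assert list(m.chains) == ["A", "B", "P"]
        assert m.residue("P", 5).aa == "A"

    def test_malformed_atom_line_names_line(self):
        with pytest.raises(PDBParseError, match="line"):
            parse_pdb("ATOM  garbage\n")

    def test_empty_structure_rejected(self):
        with pytest.raises(PDBParseError):
            parse_pdb("REMARK nothing here\nEND\n")

    def test_hetatm_ignored_but_mse_kept(self):
        lines = _chain_pdb()
        lines.append(_atom_line(90, "CA", "HOH", "A", 50, 9, 9, 9, record="HETATM"))
        lines.append(_atom_line(91, "CA", "MSE", "A", 60, 12, 0, 0, record="HETATM"))
        m = parse_pdb("\n".join(lines + ["END"]))
        assert [r.aa for r in m.chains["A"]] == ["A", "A", "A", "M"]

    def test_nonstandard_residue_dropped(self):
        lines = _chain_pdb()
        lines.append(_atom_line(90, "CA", "XYZ", "A", 50, 9, 9, 9))
        m = parse_pdb("\n".join(lines + ["END"]))
        assert len(m.chains["A"]) == 3


class TestRoundTrip:
    def test_residue_identity_round_trip(self):
        lines = _chain_pdb("A", ("ALA", "LEU", "PHE"))
        m = parse_pdb("\n".join(lines + ["END"]))
        m2 = parse_pdb(write_pdb(m))
        assert list(m2.chains) == list(m.chains)
        assert [r.aa for r in m2.chains["A"]] == [r.aa for r in m.chains["A"]]
        assert [r.residue_index for r in m2.chains["A"]] == [1, 2, 3]

    def test_coordinates_survive_within_pdb_precision(self):
        rng = np.random.default_rng(0)
        res = [
            ResidueRecord("A", i + 1, "K", rng.uniform(-50, 50, 3), rng.uniform(-50, 50, 3))
            for i in range(5)
        ]
        m = StructureModel(chains={"A": res})
        m2 = parse_pdb(write_pdb(m))
        for r, r2 in zip(res, m2.chains["A"]):
            assert np.allclose(r.ca, r2.ca, atol=5e-4)
            assert np.allclose(r.cb, r2.cb, atol=5e-4)

    def test_write_parse_write_is_stable(self):
        lines = _chain_pdb("A", ("ALA", "GLY", "PHE"))
        m = parse_pdb("\n".join(lines + ["END"]))
        once = write_pdb(m)
        twice = write_pdb(parse_pdb(once))
        assert once == twice

    def test_empty_chain_skipped(self, caplog):
        m = StructureModel(chains={
            "A": [ResidueRecord("A", 1, "A", [0, 0, 0]),
                  ResidueRecord("A", 2, "A", [3.8, 0, 0]),
                  ResidueRecord("A", 3, "A", [7.6, 0, 0])],
            "B": [],
        })
        text = write_pdb(m)
        assert "B" not in [c for c in parse_pdb(text).chains]


class TestVirtualCb:
    # ideal backbone: N and C at 1.46/1.52 A from CA with ~111 deg angle
    N = np.array([1.458, 0.0, 0.0])
    CA = np.array([0.0, 0.0, 0.0])
    C = np.array([-0.55, 1.42, 0.0])

    def test_bond_length(self):
        cb = virtual_cb(self.N, self.CA, self.C)
        assert abs(np.linalg.norm(cb - self.CA) - 1.53) < 0.01

    def test_tetrahedral_angles(self):
        # vector-algebra oracle: both heavy-atom angles at CA are ~109.5 deg
        cb = virtual_cb(self.N, self.CA, self.C)
        for other in (self.N, self.C):
            u = (other - self.CA) / np.linalg.norm(other - self.CA)
            v = (cb - self.CA) / np.linalg.norm(cb - self.CA)
            angle = np.degrees(np.arccos(u @ v))
            assert abs(angle - 109.47) < 2.0

    def test_matches_real_cb_direction(self):
        # reference construction via the standard fitted linear combination
        b = self.CA - self.N
        c = self.C - self.CA
        a = np.cross(b, c)
        ref = -0.58273431 * a + 0.56802827 * b - 0.54067466 * c + self.CA
        cb = virtual_cb(self.N, self.CA, self.C)
        u = (ref - self.CA) / np.linalg.norm(ref - self.CA)
        v = (cb - self.CA) / np.linalg.norm(cb - self.CA)
        assert np.degrees(np.arccos(np.clip(u @ v, -1, 1))) < 15.0

    def test_translation_equivariance(self):
        t = np.array([5.0, -3.0, 2.0])
        cb = virtual_cb(self.N, self.CA, self.C)
        cb_t = virtual_cb(self.N + t, self.CA + t, self.C + t)
        assert np.allclose(cb_t, cb + t)

    def test_collinear_rejected(self):
        with pytest.raises(GeometryError):
            virtual_cb([0, 0, 0], [1, 0, 0], [2, 0, 0])


class TestPairObservations:
    def _two_chain_model(self):
        a = [ResidueRecord("A", i + 1, "A", [3.8 * i, 0, 0]) for i in range(2)]
        b = [ResidueRecord("B", i + 1, "L", [3.8 * i, 0, 5.0]) for i in range(2)]
        return StructureModel(chains={"A": a, "B": b})

    def test_inter_chain_pair_count(self):
        obs = extract_pair_observations(
            self._two_chain_model(), "inter_chain", cutoff=50.0, atom_types=("CA",)
        )
        assert len(obs) == 4
        assert all(o.contact_class == "inter_chain" for o in obs)

    def test_three_four_five_distance(self):
        m = StructureModel(chains={"A": [
            ResidueRecord("A", 1, "A", [0, 0, 0]),
            ResidueRecord("A", 3, "V", [3, 4, 0]),
        ]})
        obs = extract_pair_observations(m, "intra_chain", cutoff=10.0, atom_types=("CA",))
        assert len(obs) == 1
        assert obs[0].distance == pytest.approx(5.0)
        assert (obs[0].aa_a, obs[0].aa_b) == ("A", "V")  # canonical order

    def test_k_min_separation_filter(self):
        m = StructureModel(chains={"A": [
            ResidueRecord("A", i + 1, "A", [3.8 * i, 0, 0]) for i in range(3)
        ]})
        obs = extract_pair_observations(m, "intra_chain", cutoff=50.0, k_min=2,
                                        atom_types=("CA",))
        assert len(obs) == 1
        assert obs[0].distance == pytest.approx(7.6)

    def test_single_chain_pair_count_formula(self):
        n = 8
        m = StructureModel(chains={"A": [
            ResidueRecord("A", i + 1, "A", [3.8 * i, 0, 0]) for i in range(n)
        ]})
        obs = extract_pair_observations(m, "intra_chain", cutoff=1e9, k_min=1,
                                        atom_types=("CA",))
        assert len(obs) == n * (n - 1) // 2

    def test_cutoff_must_be_positive(self):
        with pytest.raises(ParameterError):
            extract_pair_observations(self._two_chain_model(), cutoff=0.0)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_canonical_ordering_symmetry(self, seed):
        """Relabelling which chain is 'first' leaves observations unchanged."""
        rng = np.random.default_rng(seed)
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        a = [ResidueRecord("A", i + 1, rng.choice(aas), rng.uniform(0, 10, 3))
             for i in range(3)]
        b = [ResidueRecord("B", i + 1, rng.choice(aas), rng.uniform(0, 10, 3))
             for i in range(3)]
        m1 = StructureModel(chains={"A": a, "B": b})
        swapped = StructureModel(chains={
            "A": [ResidueRecord("A", r.residue_index, r.aa, r.ca) for r in b],
            "B": [ResidueRecord("B", r.residue_index, r.aa, r.ca) for r in a],
        })
        key = lambda o: (o.aa_a, o.aa_b, round(o.distance, 9))
        obs1 = sorted(map(key, extract_pair_observations(m1, "inter_chain", atom_types=("CA",))))
        obs2 = sorted(map(key, extract_pair_observations(swapped, "inter_chain", atom_types=("CA",))))
        assert obs1 == obs2


class TestTrainingFilter:
    def _model(self, lengths):
        chains = {}
        for k, L in enumerate(lengths):
            cid = chr(ord("A") + k)
            chains[cid] = [
                ResidueRecord(cid, i + 1, "A", [3.8 * i, 4.0 * k, 0]) for i in range(L)
            ]
        return StructureModel(chains=chains)

    def test_monomer_excluded(self):
        assert filter_training_set([self._model([10])]) == []

    def test_dimer_with_short_chain_included(self):
        m = self._model([100, 12])
        assert filter_training_set([m]) == [m]

    def test_dimer_without_window_chain_excluded(self):
        assert filter_training_set([self._model([100, 30])]) == []
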