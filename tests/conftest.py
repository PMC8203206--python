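import numpy as np
import pytest

from dockjury import Atom, ComplexModel, Residue, build_pool, make_reference_dimer

# 3 residues in chain A (one with an altloc pair), 2 in chain B,
# plus a water, a ligand HETATM and a hydrogen that must all be filtered out.
TINY_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  CA AALA A   2       3.000   1.000   0.000  0.60  0.00           C
ATOM      4  CA BALA A   2       3.500   1.000   0.000  0.40  0.00           C
ATOM      5  CA  GLY A   3       5.000   2.000   0.000  1.00  0.00           C
ATOM      6  HA  GLY A   3       5.500   2.500   0.000  1.00  0.00           H
ATOM      7  CA  ALA B  10       1.000   4.000   0.000  1.00  0.00           C
ATOM      8  CB  ALA B  10       2.000   4.500   0.000  1.00  0.00           C
ATOM      9  CA  ALA B  11       4.000   5.000   0.000  1.00  0.00           C
HETATM   10  O   HOH A 101       8.000   8.000   8.000  1.00  0.00           O
HETATM   11  C1  LIG B 201       9.000   9.000   9.000  1.00  0.00           C
END
"""


@pytest.fixture
def tiny_pdb(tmp_path):
    path = tmp_path / "tiny.pdb"
    path.write_text(TINY_PDB)
    return path


@pytest.fixture(scope="session")
def reference_dimer():
    return make_reference_dimer(30, seed=1)


def single_atom_residue(chain_id, seq_num, coords, name="CA", res_name="ALA"):
    return Residue(
        chain_id=chain_id, seq_num=seq_num, icode="", res_name=res_name,
        atoms=[Atom(name=name, element=name[0], coords=np.asarray(coords, float))],
    )


def two_point_model(model_id, dist, chain_b_seq=1):
    """Minimal dimer: one single-atom residue per chain, ``dist`` A apart."""
    return ComplexModel(
        model_id=model_id,
        chains={
            "A": [single_atom_residue("A", 1, (0.0, 0.0, 0.0))],
            "B": [single_atom_residue("B", chain_b_seq, (dist, 0.0, 0.0))],
        },
    )


def random_two_chain_model(seed, n_res_per_chain=20, atoms_per_res=5, spread=18.0):
    """Random blob dimer: two overlapping chains of multi-atom residues,
    dense enough that interfaces are non-trivial."""
    rng = np.random.default_rng(seed)
    chains = {}
    for cid, offset in (("A", 0.0), ("B", 6.0)):
        residues = []
        for i in range(n_res_per_chain):
            center = rng.uniform(0, spread, size=3) + np.array([offset, 0, 0])
            atoms = [
                Atom(name=f"C{j}" if j else "CA", element="C",
                     coords=center + rng.normal(0, 1.2, size=3))
                for j in range(atoms_per_res)
            ]
            residues.append(Residue(cid, i + 1, "", "ALA", atoms))
        chains[cid] = residues
    return ComplexModel(model_id=f"rand{seed}", chains=chains)


@pytest.fixture
def identical_pool(reference_dimer):
    """Three bit-identical copies of the reference dimer."""
    def clone(mid):
        chains = {
            cid: [
                Residue(r.chain_id, r.seq_num, r.icode, r.res_name,
                        [Atom(a.name, a.element, a.coords.copy()) for a in r.atoms])
                for r in residues
            ]
            for cid, residues in reference_dimer.chains.items()
        }
        return ComplexModel(model_id=mid, chains=chains)

    return build_pool([clone("m1"), clone("m2"), clone("m3")], target_id="ident")
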