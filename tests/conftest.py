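import numpy as np
import pytest

from thermocompare.seqstruct_io import Atom, Chain, Residue, Structure
from thermocompare.synthetic_data import BackboneSpec, build_backbone, generate_study_fixture


@pytest.fixture(scope="session")
def study_fixture(tmp_path_factory):
    """Desk-scale synthetic study inputs (2 FASTA, 20 PDB, manifest)."""
    out = tmp_path_factory.mktemp("fixture")
    manifest = generate_study_fixture(out, seed=1234)
    return out, manifest


@pytest.fixture
def ideal_helix():
    """20-residue poly-Ala backbone at canonical alpha-helix torsions."""
    return build_backbone(BackboneSpec(n_residues=20, phi=-57.0, psi=-47.0, omega=180.0))


def random_charged_structure(rng: np.random.Generator, n_residues: int = 30) -> Structure:
    """Residues with charged side-chain atoms scattered in a 20 A box.

    Used to exercise the salt-bridge detector against a brute-force scan.
    """
    from thermocompare.structure_analysis import ACIDIC_ATOMS, BASIC_ATOMS

    names = ["ASP", "GLU", "ARG", "HIS", "LYS", "ALA", "GLY"]
    chain = Chain(id="A")
    for i in range(n_residues):
        res_name = names[rng.integers(len(names))]
        res = Residue(chain_id="A", seq_number=i + 1, res_name=res_name)
        base = rng.uniform(0, 20, size=3)
        res.atoms.append(Atom("CA", base, "C"))
        for atom_name in ACIDIC_ATOMS.get(res_name, ()) + BASIC_ATOMS.get(res_name, ()):
            if rng.random() < 0.9:  # sometimes missing side-chain atoms
                res.atoms.append(Atom(atom_name, base + rng.uniform(-2, 2, size=3), ""))
        chain.residues.append(res)
    return Structure(id="random", chains=[chain])


def brute_force_salt_bridges(structure: Structure, cutoff: float):
    """All-pairs oracle: same atom-name sets and cutoff, no spatial tricks."""
    from thermocompare.structure_analysis import ACIDIC_ATOMS, BASIC_ATOMS

    found = {}
    residues = list(structure.residues())
    for ra in residues:
        if ra.res_name not in ACIDIC_ATOMS:
            continue
        for rb in residues:
            if rb.res_name not in BASIC_ATOMS:
                continue
            best = None
            for an in ACIDIC_ATOMS[ra.res_name]:
                for bn in BASIC_ATOMS[rb.res_name]:
                    aa, bb = ra.atom(an), rb.atom(bn)
                    if aa is None or bb is None:
                        continue
                    d = float(np.linalg.norm(aa.coords - bb.coords))
                    if best is None or d < best:
                        best = d
            if best is not None and best <= cutoff:
                key = ((ra.chain_id, ra.seq_number), (rb.chain_id, rb.seq_number))
                found[key] = (best, f"{ra.res_name}-{rb.res_name}")
    return found
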