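"""Synthetic study inputs: two sequence populations with group-biased residue
frequencies, and toy backbone structures with known dihedrals and planted
salt bridges.

The default group frequency vectors encode the direction of every composition
contrast the comparative analysis is built to detect — the thermophile-like
group is enriched in Ala, Gly, Val, Glu, Asp, Pro, Tyr and Cys and depleted
in Gln, Asn and Arg relative to the mesophile-like group — with mean chain
lengths of ~301 vs ~328 residues. Residues are i.i.d. within a sequence:
every downstream statistic here is composition- or geometry-level, so no
positional structure is needed (an optional motif-enriched spec serves the
acidic-flank PTM rule).

Backbones are built by sequential internal-coordinate (NeRF) placement of
N/CA/C atoms at fixed bond lengths and angles, honouring requested
phi/psi/omega exactly; salt bridges are planted as Asp OD1 / Lys NZ
pseudo-atoms separated by an exact target distance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .seqstruct_io import (
    AMINO_ACIDS,
    Atom,
    Chain,
    ProteinRecord,
    Residue,
    Structure,
    write_fasta,
    write_pdb,
)
from .structure_analysis import dihedral

MIN_LENGTH = 30

# Ideal backbone internal coordinates (Angstrom / degrees)
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7

HELIX = (-57.0, -47.0)
SHEET = (-120.0, 130.0)

#: group-biased residue frequencies (sum to 1); order follows AMINO_ACIDS
THERMOPHILE_FREQS = {
    "A": 0.100, "C": 0.012, "D": 0.055, "E": 0.090, "F": 0.038,
    "G": 0.090, "H": 0.018, "I": 0.060, "K": 0.060, "L": 0.090,
    "M": 0.022, "N": 0.030, "P": 0.050, "Q": 0.020, "R": 0.030,
    "S": 0.055, "T": 0.048, "V": 0.080, "W": 0.012, "Y": 0.040,
}
MESOPHILE_FREQS = {
    "A": 0.070, "C": 0.008, "D": 0.050, "E": 0.060, "F": 0.042,
    "G": 0.060, "H": 0.022, "I": 0.065, "K": 0.065, "L": 0.100,
    "M": 0.028, "N": 0.045, "P": 0.038, "Q": 0.045, "R": 0.055,
    "S": 0.075, "T": 0.065, "V": 0.065, "W": 0.014, "Y": 0.028,
}


@dataclass(frozen=True)
class GroupSpec:
    """Parameters of one synthetic sequence population."""

    label: str
    aa_freq: dict[str, float]
    length_mean: float
    length_sd: float
    n_proteins: int
    seed: int

    def __post_init__(self) -> None:
        if self.n_proteins < 1 or self.length_mean <= 0:
            raise ValueError("n_proteins >= 1 and length_mean > 0 required")
        if set(self.aa_freq) != set(AMINO_ACIDS):
            raise ValueError("aa_freq must cover exactly the 20 standard residues")
        total = sum(self.aa_freq.values())
        if any(v < 0 for v in self.aa_freq.values()) or abs(total - 1.0) > 1e-9:
            raise ValueError(f"aa_freq must be non-negative and sum to 1 (got {total})")


def thermophile_like_spec(n_proteins: int = 200, seed: int = 101) -> GroupSpec:
    return GroupSpec("thermophilic", dict(THERMOPHILE_FREQS), 301.0, 60.0, n_proteins, seed)


def mesophile_like_spec(n_proteins: int = 200, seed: int = 202) -> GroupSpec:
    return GroupSpec("mesophilic", dict(MESOPHILE_FREQS), 328.0, 60.0, n_proteins, seed)


def generate_sequences(spec: GroupSpec) -> list[ProteinRecord]:
    """Draw n_proteins i.i.d. sequences; lengths ~ truncated normal (min 30)."""
    rng = np.random.default_rng(spec.seed)
    aas = list(AMINO_ACIDS)
    probs = np.array([spec.aa_freq[a] for a in aas])
    probs = probs / probs.sum()  # guard fp drift
    records = []
    for i in range(spec.n_proteins):
        length = 0
        while length < MIN_LENGTH:
            length = int(round(rng.normal(spec.length_mean, spec.length_sd)))
        seq = "".join(rng.choice(aas, size=length, p=probs))
        records.append(ProteinRecord(id=f"{spec.label}_{i + 1:04d}", sequence=seq,
                                     group=spec.label))
    return records


# ---------------------------------------------------------------------------
# Backbone builder


@dataclass(frozen=True)
class BackboneSpec:
    """A toy backbone: per-residue torsions plus planted salt-bridge pairs."""

    n_residues: int
    phi: float | Sequence[float] = HELIX[0]
    psi: float | Sequence[float] = HELIX[1]
    omega: float | Sequence[float] = 180.0
    planted_bridges: tuple[tuple[int, int, float], ...] = ()  # (acidic, basic, A) 1-based

    def __post_init__(self) -> None:
        if self.n_residues < 3:
            raise ValueError("need at least 3 residues")
        for pa, pb, d in self.planted_bridges:
            if d <= 0:
                raise ValueError("target distance must be positive")
            if not (1 <= pa <= self.n_residues and 1 <= pb <= self.n_residues) or pa == pb:
                raise ValueError(f"invalid planted bridge positions ({pa}, {pb})")

    def torsion(self, name: str, i: int) -> float:
        v = getattr(self, name)
        return float(v[i]) if isinstance(v, (list, tuple, np.ndarray)) else float(v)


def _place_atom(a, b, c, length: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """NeRF placement: position d with |cd| = length, angle(b,c,d) = angle,
    and torsion(a,b,c,d) = torsion."""
    theta = np.radians(angle_deg)
    chi = np.radians(torsion_deg)
    bc = c - b
    bc_hat = bc / np.linalg.norm(bc)
    ab = b - a
    n_hat = np.cross(ab, bc_hat)
    n_hat = n_hat / np.linalg.norm(n_hat)
    m_hat = np.cross(n_hat, bc_hat)
    d_local = np.array(
        [-length * np.cos(theta), length * np.sin(theta) * np.cos(chi),
         length * np.sin(theta) * np.sin(chi)]
    )
    return c + d_local[0] * bc_hat + d_local[1] * m_hat + d_local[2] * n_hat


def build_backbone(spec: BackboneSpec, structure_id: str = "synthetic") -> Structure:
    """Poly-peptide N/CA/C backbone honouring the requested torsions.

    Residues default to ALA; planted-bridge positions become ASP (with an OD1
    pseudo-atom) and LYS (with NZ) placed so the OD1-NZ separation equals the
    requested target distance exactly.
    """
    n = spec.n_residues
    coords = np.zeros((n, 3, 3))  # residue x (N, CA, C) x xyz
    coords[0, 0] = (0.0, 0.0, 0.0)
    coords[0, 1] = (BOND_N_CA, 0.0, 0.0)
    ang = np.radians(ANGLE_N_CA_C)
    coords[0, 2] = coords[0, 1] + BOND_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])
    for i in range(1, n):
        pn, pca, pc = coords[i - 1]
        ni = _place_atom(pn, pca, pc, BOND_C_N, ANGLE_CA_C_N, spec.torsion("psi", i - 1))
        cai = _place_atom(pca, pc, ni, BOND_N_CA, ANGLE_C_N_CA, spec.torsion("omega", i))
        ci = _place_atom(pc, ni, cai, BOND_CA_C, ANGLE_N_CA_C, spec.torsion("phi", i))
        coords[i] = (ni, cai, ci)

    names = {i: "ALA" for i in range(n)}
    pseudo: dict[int, Atom] = {}
    for pa, pb, target in spec.planted_bridges:
        ia, ib = pa - 1, pb - 1
        ca_a, ca_b = coords[ia, 1], coords[ib, 1]
        sep = float(np.linalg.norm(ca_b - ca_a))
        if sep < 1.5 + target:
            raise ValueError(
                f"cannot plant a {target} A bridge between residues {pa} and {pb}: "
                f"CA separation {sep:.2f} A is too small"
            )
        u = (ca_b - ca_a) / sep
        od1 = ca_a + 1.5 * u
        nz = od1 + target * u
        names[ia], names[ib] = "ASP", "LYS"
        pseudo[ia] = Atom("OD1", od1, "O")
        pseudo[ib] = Atom("NZ", nz, "N")

    chain = Chain(id="A")
    for i in range(n):
        res = Residue(chain_id="A", seq_number=i + 1, res_name=names[i])
        res.atoms = [
            Atom("N", coords[i, 0], "N"),
            Atom("CA", coords[i, 1], "C"),
            Atom("C", coords[i, 2], "C"),
        ]
        if i in pseudo:
            res.atoms.append(pseudo[i])
        chain.residues.append(res)
    structure = Structure(id=structure_id, chains=[chain])

    # sanity: planted separations are exact by construction
    for pa, pb, target in spec.planted_bridges:
        od1 = structure.chains[0].residues[pa - 1].atom("OD1").coords
        nz = structure.chains[0].residues[pb - 1].atom("NZ").coords
        assert abs(float(np.linalg.norm(nz - od1)) - target) < 1e-9
    return structure


# ---------------------------------------------------------------------------
# Study-scale fixture


def _bridge_positions(n_residues: int, n_bridges: int, span: int) -> list[tuple[int, int, float]]:
    """Non-overlapping (i, i+span) pairs spread along the chain, 3.0 A targets."""
    positions = []
    start = 5
    step = span + 5
    for b in range(n_bridges):
        pa = start + b * step
        pb = pa + span
        if pb > n_residues:
            raise ValueError("chain too short for requested bridge count")
        positions.append((pa, pb, 3.0))
    return positions


def generate_study_fixture(out_dir: str | Path, seed: int = 0) -> dict:
    """Write a desk-scale mirror of the study design and return its manifest.

    2 x 200 sequences (FASTA) and 2 x 10 toy structures (PDB): the
    thermophile-like structure set carries 6 planted bridges per 60-residue
    chain vs 5 for the mesophile-like set (a 20% higher rate), and a
    helix-richer region mix (7 helix / 3 sheet vs 5 / 5).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng_seed = int(np.random.SeedSequence(seed).generate_state(1)[0] % (2**31 - 1))

    t_spec = thermophile_like_spec(seed=rng_seed + 1)
    m_spec = mesophile_like_spec(seed=rng_seed + 2)
    fasta_paths = {}
    for spec in (t_spec, m_spec):
        records = generate_sequences(spec)
        path = out_dir / f"{spec.label}.fasta"
        write_fasta(records, path)
        fasta_paths[spec.label] = str(path)

    structure_plan = {
        "thermophilic": {"n_structures": 10, "n_helix": 7, "bridges_per_structure": 6},
        "mesophilic": {"n_structures": 10, "n_helix": 5, "bridges_per_structure": 5},
    }
    n_residues = 60
    pdb_dirs = {}
    backbone_specs: dict[str, list[dict]] = {}
    for label, plan in structure_plan.items():
        pdb_dir = out_dir / f"{label}_pdb"
        pdb_dir.mkdir(exist_ok=True)
        pdb_dirs[label] = str(pdb_dir)
        backbone_specs[label] = []
        for i in range(plan["n_structures"]):
            helix = i < plan["n_helix"]
            phi, psi = HELIX if helix else SHEET
            span = 4 if helix else 2
            bridges = _bridge_positions(n_residues, plan["bridges_per_structure"], span)
            bspec = BackboneSpec(n_residues=n_residues, phi=phi, psi=psi, omega=180.0,
                                 planted_bridges=tuple(bridges))
            structure = build_backbone(bspec, structure_id=f"{label}_{i + 1:02d}")
            write_pdb(structure, pdb_dir / f"{structure.id}.pdb")
            backbone_specs[label].append(
                {"n_residues": n_residues, "phi": phi, "psi": psi, "omega": 180.0,
                 "planted_bridges": bridges}
            )

    manifest = {
        "seed": seed,
        "derived_seed": rng_seed,
        "groups": {
            spec.label: {
                "sequence_spec": asdict(spec),
                "fasta": fasta_paths[spec.label],
                "pdb_dir": pdb_dirs[spec.label],
                "structure_plan": structure_plan[spec.label],
                "backbone_specs": backbone_specs[spec.label],
            }
            for spec in (t_spec, m_spec)
        },
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
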