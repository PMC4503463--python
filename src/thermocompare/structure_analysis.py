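"""Backbone geometry: dihedrals, Ramachandran classification, peptide-bond
planarity, and the geometric salt-bridge census.

Salt bridges are detected as side-chain carboxylate-oxygen / side-chain
nitrogen contacts between an acidic residue (Asp, Glu) and a basic residue
(Arg, His, Lys) within a distance cutoff (default 3.2 A, the VMD saltbr
oxygen-nitrogen default). His nitrogens are included so ASP-HIS and GLU-HIS
dyads are counted. One record per residue pair, at the minimum atom-atom
distance.

Ramachandran regions use rectangular phi/psi windows (editable in
``RAMA_WINDOWS``): a deterministic stand-in for density-contour tables.
Glycine uses the generic windows plus their point mirror (no C-beta);
proline is restricted to phi in [-110, -35].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .seqstruct_io import Residue, Structure

logger = logging.getLogger(__name__)

ACIDIC_RESIDUES = frozenset({"ASP", "GLU"})
BASIC_RESIDUES = frozenset({"ARG", "HIS", "LYS"})

#: side-chain atoms scanned for salt bridges
ACIDIC_ATOMS = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}
BASIC_ATOMS = {"LYS": ("NZ",), "ARG": ("NH1", "NH2", "NE"), "HIS": ("ND1", "NE2")}

DEFAULT_SALTBRIDGE_CUTOFF = 3.2  # Angstrom, O-N
PEPTIDE_BOND_MAX = 2.5  # Angstrom; C(i)-N(i+1) beyond this is a chain break
CIS_MAX_DEG = 30.0
TRANS_DEV_MAX_DEG = 20.0

DYADS = ("ASP-ARG", "ASP-HIS", "ASP-LYS", "GLU-ARG", "GLU-HIS", "GLU-LYS")


# ---------------------------------------------------------------------------
# Dihedrals


def dihedral(p1, p2, p3, p4) -> float:
    """Signed torsion angle (degrees, in (-180, 180]) about the p2->p3 axis."""
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10:
        raise ValueError("dihedral undefined: three consecutive points are collinear")
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, b2 / np.linalg.norm(b2)), n2))
    ang = -np.degrees(np.arctan2(y, x))
    if ang <= -180.0:
        ang += 360.0
    return float(ang)


@dataclass
class BackboneDihedrals:
    """phi/psi/omega for one residue; None where undefined (termini, breaks)."""

    residue: Residue
    phi: float | None = None
    psi: float | None = None
    omega: float | None = None


def _chain_segments(residues: Sequence[Residue]) -> list[list[Residue]]:
    """Split a chain at missing backbone atoms and at C-N distances > 2.5 A."""
    segments: list[list[Residue]] = []
    current: list[Residue] = []
    for res in residues:
        if not res.has_atoms(("N", "CA", "C")):
            logger.warning(
                "%s%s %s: missing backbone atom(s), residue skipped",
                res.chain_id, res.seq_number, res.res_name,
            )
            if current:
                segments.append(current)
            current = []
            continue
        if current:
            prev_c = current[-1].atom("C").coords
            this_n = res.atom("N").coords
            if np.linalg.norm(this_n - prev_c) > PEPTIDE_BOND_MAX:
                segments.append(current)
                current = []
        current.append(res)
    if current:
        segments.append(current)
    return segments


def backbone_dihedrals(structure: Structure) -> list[BackboneDihedrals]:
    """Per-residue phi/psi/omega over every chain, honouring chain breaks.

    phi(i) = C(i-1)-N(i)-CA(i)-C(i); psi(i) = N(i)-CA(i)-C(i)-N(i+1);
    omega(i) = CA(i-1)-C(i-1)-N(i)-CA(i). First residue of a segment has no
    phi/omega; the last has no psi.
    """
    out: list[BackboneDihedrals] = []
    for chain in structure.chains:
        for seg in _chain_segments(chain.residues):
            for i, res in enumerate(seg):
                bd = BackboneDihedrals(residue=res)
                n, ca, c = (res.atom(a).coords for a in ("N", "CA", "C"))
                if i > 0:
                    prev = seg[i - 1]
                    pc = prev.atom("C").coords
                    pca = prev.atom("CA").coords
                    bd.phi = dihedral(pc, n, ca, c)
                    bd.omega = dihedral(pca, pc, n, ca)
                if i < len(seg) - 1:
                    nn = seg[i + 1].atom("N").coords
                    bd.psi = dihedral(n, ca, c, nn)
                out.append(bd)
    return out


# ---------------------------------------------------------------------------
# Ramachandran classification

# (phi_lo, phi_hi, psi_lo, psi_hi) rectangles per region; all editable.
RAMA_WINDOWS: dict[str, list[tuple[float, float, float, float]]] = {
    "helix": [(-160.0, -45.0, -70.0, -5.0)],
    "sheet": [(-180.0, -45.0, 90.0, 180.0), (-180.0, -45.0, -180.0, -150.0)],
    "left_helix": [(35.0, 90.0, -10.0, 70.0)],
    # bridging band between helix and sheet, counted as core loop/turn
    "loop_turn": [(-180.0, -45.0, -5.0, 90.0)],
}
#: non-Gly residues in these windows are disallowed rather than mere outliers
DISALLOWED_WINDOWS: list[tuple[float, float, float, float]] = [
    (0.0, 180.0, -120.0, -30.0),
]
PRO_PHI_RANGE = (-110.0, -35.0)

CORE_REGIONS = frozenset({"helix", "sheet", "left_helix", "loop_turn"})


def _in_window(phi: float, psi: float, win: tuple[float, float, float, float]) -> bool:
    lo_f, hi_f, lo_p, hi_p = win
    return lo_f <= phi <= hi_f and lo_p <= psi <= hi_p


def residue_category(res_name: str, next_res_name: str | None) -> str:
    if next_res_name == "PRO":
        return "pre_pro"
    if res_name == "GLY":
        return "gly"
    if res_name == "PRO":
        return "pro"
    return "generic"


def classify_rama(
    phi: float,
    psi: float,
    res_name: str = "ALA",
    next_res_name: str | None = None,
    windows: Mapping[str, list[tuple[float, float, float, float]]] = RAMA_WINDOWS,
) -> str:
    """Region label for a (phi, psi) point: helix, sheet, left_helix,
    loop_turn, disallowed, or outlier."""
    category = residue_category(res_name, next_res_name)

    def in_any(region: str, f: float, p: float) -> bool:
        return any(_in_window(f, p, w) for w in windows[region])

    mirrors = [(phi, psi)]
    if category == "gly":  # no C-beta: the plot is point-symmetric
        mirrors.append((-phi, -psi))
    for f, p in mirrors:
        if category == "pro" and not (PRO_PHI_RANGE[0] <= f <= PRO_PHI_RANGE[1]):
            continue
        for region in ("helix", "sheet", "left_helix", "loop_turn"):
            if in_any(region, f, p):
                return region
    if category != "gly" and any(_in_window(phi, psi, w) for w in DISALLOWED_WINDOWS):
        return "disallowed"
    return "outlier"


# ---------------------------------------------------------------------------
# Salt bridges


@dataclass(frozen=True)
class SaltBridgeRecord:
    acidic_residue: tuple[str, int, str]  # (chain, seq_number, res_name)
    basic_residue: tuple[str, int, str]
    min_distance: float
    dyad: str

    def __post_init__(self) -> None:
        expected = f"{self.acidic_residue[2]}-{self.basic_residue[2]}"
        if self.dyad != expected:
            raise ValueError(f"dyad {self.dyad!r} inconsistent with residues {expected!r}")


def detect_salt_bridges(
    structure: Structure, cutoff: float = DEFAULT_SALTBRIDGE_CUTOFF
) -> list[SaltBridgeRecord]:
    """One record per (acidic, basic) residue pair whose minimum
    carboxylate-O to side-chain-N distance is within the cutoff."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    acidic: list[tuple[Residue, np.ndarray]] = []
    basic: list[tuple[Residue, np.ndarray]] = []
    for res in structure.residues():
        if res.res_name in ACIDIC_RESIDUES:
            coords = [res.atom(a).coords for a in ACIDIC_ATOMS[res.res_name] if res.atom(a)]
            if coords:
                acidic.append((res, np.array(coords)))
        elif res.res_name in BASIC_RESIDUES:
            coords = [res.atom(a).coords for a in BASIC_ATOMS[res.res_name] if res.atom(a)]
            if coords:
                basic.append((res, np.array(coords)))

    records = []
    for ares, acoords in acidic:
        for bres, bcoords in basic:
            d = np.linalg.norm(acoords[:, None, :] - bcoords[None, :, :], axis=-1)
            dmin = float(d.min())
            if dmin <= cutoff:
                records.append(
                    SaltBridgeRecord(
                        acidic_residue=(ares.chain_id, ares.seq_number, ares.res_name),
                        basic_residue=(bres.chain_id, bres.seq_number, bres.res_name),
                        min_distance=dmin,
                        dyad=f"{ares.res_name}-{bres.res_name}",
                    )
                )
    records.sort(key=lambda r: (r.acidic_residue[0], r.acidic_residue[1],
                                r.basic_residue[0], r.basic_residue[1]))
    return records


def salt_bridge_stats(
    structure: Structure, bridges: Sequence[SaltBridgeRecord]
) -> tuple[float, dict[str, float]]:
    """(bridges per 100 residues, dyad composition as % of all bridges)."""
    total = structure.n_residues
    pct_of_residues = 100.0 * len(bridges) / total if total else 0.0
    dyad_pct = {d: 0.0 for d in DYADS}
    if bridges:
        for rec in bridges:
            dyad_pct[rec.dyad] += 1
        for d in dyad_pct:
            dyad_pct[d] = 100.0 * dyad_pct[d] / len(bridges)
    return pct_of_residues, dyad_pct


# ---------------------------------------------------------------------------
# Planarity and group summary


def peptide_planarity(
    dihedrals: Iterable[BackboneDihedrals],
    cis_max_deg: float = CIS_MAX_DEG,
    trans_dev_max_deg: float = TRANS_DEV_MAX_DEG,
) -> tuple[int, int, int]:
    """(cis, nonplanar, trans) counts over all defined omega torsions.

    cis: |omega| <= 30 deg; trans: within 20 deg of +-180; else nonplanar.
    """
    cis = nonplanar = trans = 0
    for bd in dihedrals:
        if bd.omega is None:
            continue
        w = bd.omega
        if abs(w) <= cis_max_deg:
            cis += 1
        elif abs(w - 180.0) <= trans_dev_max_deg or abs(w + 180.0) <= trans_dev_max_deg:
            trans += 1
        else:
            nonplanar += 1
    return cis, nonplanar, trans


@dataclass
class RamaSummary:
    """Aggregate Ramachandran / planarity accounting for a set of structures."""

    total_residues: int
    classifiable_residues: int
    pct_helix: float
    pct_sheet: float
    pct_left_helix: float
    loop_turn_count: int
    pct_loop_turn: float
    cis_count: int
    nonplanar_count: int
    trans_count: int
    gly_count: int
    pct_gly: float
    pro_count: int
    pre_pro_count: int
    core_count: int
    pct_core: float
    outlier_count: int
    outlier_pct_mean: float
    outlier_pct_range: tuple[float, float]
    disallowed_count: int
    pct_disallowed: float
    nonprotein_count: int

    def to_rows(self) -> list[tuple[str, str]]:
        """Key-value rows in the style of a structure-analysis logistic table."""
        f = lambda x: f"{x:.3f}"
        return [
            ("Total no of residues checked", str(self.total_residues)),
            ("% of residues in alpha-helix", f(self.pct_helix)),
            ("% of residues in beta-sheet", f(self.pct_sheet)),
            ("% of residues in loop or turn", f"{self.loop_turn_count} ({f(self.pct_loop_turn)})"),
            ("% of residues in left handed alpha-helix", f(self.pct_left_helix)),
            ("Cis-peptide bonds", str(self.cis_count)),
            ("Nonplanar peptide bonds", str(self.nonplanar_count)),
            ("Glycine residues", f"{self.gly_count} ({f(self.pct_gly)}%)"),
            ("Residues in core region", f"{self.core_count} ({f(self.pct_core)}%)"),
            (
                "Average % of outlier from different chains",
                f"{f(self.outlier_pct_mean)}; range "
                f"({f(self.outlier_pct_range[0])}-{f(self.outlier_pct_range[1])})",
            ),
            ("Disallowed residues", f"{self.disallowed_count} ({f(self.pct_disallowed)}%)"),
            ("No. residues of type non-protein", str(self.nonprotein_count)),
        ]


def rama_summary(structures: Sequence[Structure], per_chain: bool = True) -> RamaSummary:
    """Aggregate region and planarity tallies over a list of structures.

    Region percentages are over residues with both phi and psi defined;
    the outlier percentage is computed per chain, then averaged, mirroring
    chain-wise reporting.
    """
    if not structures:
        raise ValueError("need at least one structure")
    region_counts = {r: 0 for r in ("helix", "sheet", "left_helix", "loop_turn",
                                    "outlier", "disallowed")}
    total_residues = 0
    gly = pro = pre_pro = 0
    cis = nonplanar = trans = 0
    chain_outlier_pcts: list[float] = []
    nonprotein = 0

    for structure in structures:
        nonprotein += structure.n_nonprotein_residues
        total_residues += structure.n_residues
        for res in structure.residues():
            if res.res_name == "GLY":
                gly += 1
            elif res.res_name == "PRO":
                pro += 1
        dihedrals = backbone_dihedrals(structure)
        c, np_, t = peptide_planarity(dihedrals)
        cis += c
        nonplanar += np_
        trans += t

        by_chain: dict[str, list[str]] = {}
        next_name: dict[int, str | None] = {}
        for i, bd in enumerate(dihedrals):
            nxt = dihedrals[i + 1].residue if i + 1 < len(dihedrals) else None
            next_name[i] = nxt.res_name if nxt and nxt.chain_id == bd.residue.chain_id else None
        for i, bd in enumerate(dihedrals):
            if next_name[i] == "PRO":
                pre_pro += 1
            if bd.phi is None or bd.psi is None:
                continue
            label = classify_rama(bd.phi, bd.psi, bd.residue.res_name, next_name[i])
            region_counts[label] += 1
            by_chain.setdefault(bd.residue.chain_id, []).append(label)
        for labels in by_chain.values():
            if labels:
                chain_outlier_pcts.append(100.0 * labels.count("outlier") / len(labels))

    classifiable = sum(region_counts.values())
    pct = lambda n, d: 100.0 * n / d if d else 0.0
    core = sum(region_counts[r] for r in CORE_REGIONS)
    outlier_pcts = chain_outlier_pcts or [0.0]
    return RamaSummary(
        total_residues=total_residues,
        classifiable_residues=classifiable,
        pct_helix=pct(region_counts["helix"], classifiable),
        pct_sheet=pct(region_counts["sheet"], classifiable),
        pct_left_helix=pct(region_counts["left_helix"], classifiable),
        loop_turn_count=region_counts["loop_turn"],
        pct_loop_turn=pct(region_counts["loop_turn"], classifiable),
        cis_count=cis,
        nonplanar_count=nonplanar,
        trans_count=trans,
        gly_count=gly,
        pct_gly=pct(gly, total_residues),
        pro_count=pro,
        pre_pro_count=pre_pro,
        core_count=core,
        pct_core=pct(core, classifiable),
        outlier_count=region_counts["outlier"],
        outlier_pct_mean=float(np.mean(outlier_pcts)),
        outlier_pct_range=(float(np.min(outlier_pcts)), float(np.max(outlier_pcts))),
        disallowed_count=region_counts["disallowed"],
        pct_disallowed=pct(region_counts["disallowed"], classifiable),
        nonprotein_count=nonprotein,
    )
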