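"""Hydropathy classes, Henderson-Hasselbalch net charge, and isoelectric point.

The net charge of a protein at a given pH is modelled from its ionizable
groups: side chains of Asp, Glu, Cys, Tyr (acidic), His, Lys, Arg (basic),
plus the two chain termini. Each group of count n and dissociation constant
pKa contributes

    basic:   +n / (1 + 10**(pH - pKa))
    acidic:  -n / (1 + 10**(pKa - pH))

The total Q(pH) is strictly decreasing, so the isoelectric point — the pH at
which Q vanishes — is the unique root on [0, 14], found by bisection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from .seqstruct_io import ProteinRecord

HYDROPHOBIC = frozenset("MFAILVWP")
HYDROPHILIC = frozenset("KRDEH")
OTHER = frozenset("SGCTNQY")

ACIDIC_GROUPS = frozenset({"Asp", "Glu", "Cys", "Tyr", "Cterm"})
BASIC_GROUPS = frozenset({"His", "Lys", "Arg", "Nterm"})

_SIDECHAIN_GROUP = {"D": "Asp", "E": "Glu", "C": "Cys", "Y": "Tyr",
                    "H": "His", "K": "Lys", "R": "Arg"}


@dataclass(frozen=True)
class PkaSet:
    """A named table of group pKa values (textbook-style defaults)."""

    name: str
    pka: Mapping[str, float]

    def __post_init__(self) -> None:
        missing = (ACIDIC_GROUPS | BASIC_GROUPS) - set(self.pka)
        if missing:
            raise ValueError(f"pKa set {self.name!r} missing groups: {sorted(missing)}")
        bad = [g for g, v in self.pka.items() if not 0.0 < v < 14.0]
        if bad:
            raise ValueError(f"pKa values outside (0, 14) for: {bad}")

    def sign(self, group: str) -> int:
        if group in BASIC_GROUPS:
            return +1
        if group in ACIDIC_GROUPS:
            return -1
        raise KeyError(f"unknown ionizable group {group!r}")


DEFAULT_PKA = PkaSet(
    name="default",
    pka={
        "Nterm": 9.0, "Cterm": 3.1,
        "Asp": 3.65, "Glu": 4.25, "Cys": 8.3, "Tyr": 10.07,
        "His": 6.0, "Lys": 10.5, "Arg": 12.5,
    },
)

#: EMBOSS iep dialect, selectable via config for comparison runs
EMBOSS_PKA = PkaSet(
    name="emboss",
    pka={
        "Nterm": 8.6, "Cterm": 3.6,
        "Asp": 3.9, "Glu": 4.1, "Cys": 8.5, "Tyr": 10.1,
        "His": 6.5, "Lys": 10.8, "Arg": 12.5,
    },
)

PKA_SETS = {"default": DEFAULT_PKA, "emboss": EMBOSS_PKA}


@dataclass(frozen=True)
class PhysChemProfile:
    """Per-protein hydropathy fractions, charge at pH 7, and pI."""

    protein_id: str
    hydrophobic_pct: float
    hydrophilic_pct: float
    other_pct: float
    net_charge_pH7: float
    pI: float


def hydropathy_fractions(record: ProteinRecord) -> tuple[float, float, float]:
    """Percentages of hydrophobic {M,F,A,I,L,V,W,P}, hydrophilic {K,R,D,E,H},
    and other {S,G,C,T,N,Q,Y} residues; the three sum to 100."""
    n = len(record.sequence)
    n_phob = sum(1 for c in record.sequence if c in HYDROPHOBIC)
    n_phil = sum(1 for c in record.sequence if c in HYDROPHILIC)
    n_other = n - n_phob - n_phil
    return 100.0 * n_phob / n, 100.0 * n_phil / n, 100.0 * n_other / n


def ionizable_census(record: ProteinRecord) -> dict[str, int]:
    """Counts of ionizable groups in a single-chain sequence (termini = 1 each)."""
    census = {g: 0 for g in _SIDECHAIN_GROUP.values()}
    for c in record.sequence:
        g = _SIDECHAIN_GROUP.get(c)
        if g is not None:
            census[g] += 1
    census["Nterm"] = 1
    census["Cterm"] = 1
    return census


def net_charge(census: Mapping[str, int], pH: float, pkas: PkaSet = DEFAULT_PKA) -> float:
    """Henderson-Hasselbalch net charge (elementary charges) at the given pH."""
    q = 0.0
    for group, n in census.items():
        if n < 0:
            raise ValueError(f"negative count for group {group!r}")
        if n == 0:
            continue
        pka = pkas.pka.get(group)
        if pka is None:
            raise KeyError(f"unknown ionizable group {group!r}")
        if pkas.sign(group) > 0:
            q += n / (1.0 + 10.0 ** (pH - pka))
        else:
            q -= n / (1.0 + 10.0 ** (pka - pH))
    return q


def round_charge(q: float) -> int:
    """Integer charge, rounding half away from zero (reporting convention)."""
    import math

    return int(math.floor(q + 0.5)) if q >= 0 else -int(math.floor(-q + 0.5))


def isoelectric_point(
    census: Mapping[str, int], pkas: PkaSet = DEFAULT_PKA, tol: float = 1e-6
) -> float:
    """pH at which the net charge vanishes, by bisection on [0, 14].

    Requires at least one acidic and one basic group so that Q changes sign
    across the interval; Q is strictly decreasing, hence the root is unique.
    """
    lo, hi = 0.0, 14.0
    q_lo, q_hi = net_charge(census, lo, pkas), net_charge(census, hi, pkas)
    if q_lo <= 0.0 or q_hi >= 0.0:
        raise ValueError("no isoelectric point: net charge does not change sign on [0, 14]")
    while hi - lo > min(tol, 1e-9):
        mid = 0.5 * (lo + hi)
        if net_charge(census, mid, pkas) > 0.0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def physchem_profile(record: ProteinRecord, pkas: PkaSet = DEFAULT_PKA) -> PhysChemProfile:
    phob, phil, other = hydropathy_fractions(record)
    census = ionizable_census(record)
    try:
        pi = isoelectric_point(census, pkas)
    except ValueError:
        pi = float("nan")  # sequences with no acidic or no basic group
    return PhysChemProfile(
        protein_id=record.id,
        hydrophobic_pct=phob,
        hydrophilic_pct=phil,
        other_pct=other,
        net_charge_pH7=net_charge(census, 7.0, pkas),
        pI=pi,
    )
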