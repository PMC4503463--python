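"""Amino-acid composition profiles and Sturges-binned group distributions.

Each protein is reduced to a 20-vector of residue percentages; a group of
proteins is then summarised, residue by residue, as a histogram of proteins
over percentage class intervals. The number of class intervals comes from the
Sturges rule k = 1 + 3.322*log10(N) for N observations, with the class width
h = range/k rounded to the nearest integer — so a 0-20% range at N=200 gives
k=9 and 2-point-wide classes (0-2, 2-4, ... 18-20).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .seqstruct_io import AMINO_ACIDS, ProteinRecord


@dataclass(frozen=True)
class CompositionProfile:
    """Percentage of each of the 20 residues in one protein chain."""

    protein_id: str
    percent: Mapping[str, float]

    def __post_init__(self) -> None:
        total = sum(self.percent.values())
        if not math.isclose(total, 100.0, rel_tol=1e-9):
            raise ValueError(f"{self.protein_id}: percentages sum to {total}, not 100")


def composition_profile(record: ProteinRecord) -> CompositionProfile:
    """Residue percentages over the full chain length; absent residues are 0."""
    n = len(record.sequence)
    counts = {aa: 0 for aa in AMINO_ACIDS}
    for c in record.sequence:
        counts[c] += 1
    return CompositionProfile(
        protein_id=record.id, percent={aa: 100.0 * counts[aa] / n for aa in AMINO_ACIDS}
    )


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class BinningScheme:
    """Sturges-rule class intervals over [Mn, Mx].

    Both the raw (unrounded) and rounded class count / width are retained:
    k_raw = 1 + 3.322*log10(N) is rounded half-up to k, and the raw width
    h_raw = (Mx-Mn)/k is rounded to the nearest integer to give h. The edge
    list steps by h from Mn and always covers Mx, so the realised number of
    bins can differ from k (e.g. N=200 over [0,20]: k=9 but ten 2-wide bins).
    """

    N: int
    Mn: float
    Mx: float
    k_raw: float
    k: int
    h_raw: float
    h: float
    edges: tuple[float, ...]

    @property
    def Rx(self) -> float:
        return self.Mx - self.Mn

    @property
    def n_bins(self) -> int:
        return len(self.edges) - 1

    def labels(self) -> list[str]:
        return [f"{lo:g}-{hi:g}" for lo, hi in zip(self.edges[:-1], self.edges[1:])]


def sturges_scheme(N: int, Mn: float, Mx: float) -> BinningScheme:
    """Build the Sturges binning for N observations spanning [Mn, Mx]."""
    if N < 2:
        raise ValueError(f"Sturges rule needs N >= 2 observations, got {N}")
    if Mx <= Mn:
        raise ValueError(f"need Mx > Mn, got [{Mn}, {Mx}]")
    k_raw = 1.0 + 3.322 * math.log10(N)
    k = _round_half_up(k_raw)
    rx = Mx - Mn
    h_raw = rx / k
    h = float(_round_half_up(h_raw))
    if h == 0.0:  # degenerate narrow range: fall back to the unrounded width
        h = h_raw
    n_bins = max(1, math.ceil(rx / h - 1e-12))
    edges = [Mn + i * h for i in range(n_bins)]
    edges.append(max(Mn + n_bins * h, Mx))
    return BinningScheme(N=N, Mn=Mn, Mx=Mx, k_raw=k_raw, k=k, h_raw=h_raw, h=h, edges=tuple(edges))


@dataclass
class BinnedDistribution:
    """Per-group protein counts over one residue's percentage bins."""

    residue: str
    scheme: BinningScheme
    counts_by_group: dict[str, np.ndarray] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for group, counts in self.counts_by_group.items():
            for i, c in enumerate(counts):
                rows.append(
                    {
                        "residue": self.residue,
                        "bin_lo": self.scheme.edges[i],
                        "bin_hi": self.scheme.edges[i + 1],
                        "group": group,
                        "count": int(c),
                    }
                )
        return pd.DataFrame(rows)


def assign_bin(value: float, edges: tuple[float, ...]) -> int:
    """Index of the half-open bin [lo, hi) containing value; last bin closed."""
    if value < edges[0] or value > edges[-1]:
        raise ValueError(f"value {value} outside bin span [{edges[0]}, {edges[-1]}]")
    idx = int(np.searchsorted(edges, value, side="right")) - 1
    return min(idx, len(edges) - 2)


def bin_occupancy(
    profiles_by_group: Mapping[str, Iterable[CompositionProfile]],
    residue: str,
    scheme: BinningScheme,
) -> BinnedDistribution:
    """Histogram each group's proteins by their percentage of one residue."""
    if residue not in AMINO_ACIDS:
        raise ValueError(f"unknown residue code {residue!r}")
    dist = BinnedDistribution(residue=residue, scheme=scheme)
    for group, profiles in profiles_by_group.items():
        counts = np.zeros(scheme.n_bins, dtype=int)
        for prof in profiles:
            counts[assign_bin(prof.percent[residue], scheme.edges)] += 1
        dist.counts_by_group[group] = counts
    return dist


def export_distributions(dists: Iterable[BinnedDistribution], path: str | Path) -> None:
    """TSV export: residue, bin_lo, bin_hi, group, count."""
    frames = [d.to_frame() for d in dists]
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)
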