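"""Rule-based tyrosine phospho-site enumeration.

This is an explicitly rule-based scanner, not a trained predictor: outputs are
labelled "rule-based, not GPS" wherever they surface. Two rules are provided:
``all_tyr`` (every tyrosine) and ``acidic_flank`` (default: a tyrosine with at
least one Asp/Glu within four positions on either side, a crude proxy for the
acidophilic kinase motif preference).
"""

from __future__ import annotations

from dataclasses import dataclass

from .seqstruct_io import ProteinRecord

RULES = ("all_tyr", "acidic_flank")
RULE_LABEL = "rule-based, not GPS"

_FLANK = 4


@dataclass(frozen=True)
class TyrSite:
    """One candidate phospho-tyrosine with its +-4 sequence context."""

    protein_id: str
    position: int  # 1-based
    context: str  # 9-mer, '-'-padded at termini

    def __post_init__(self) -> None:
        if len(self.context) != 2 * _FLANK + 1:
            raise ValueError("context must be a 9-mer")
        if self.context[_FLANK] != "Y":
            raise ValueError("context centre must be Y")


def _context(sequence: str, idx0: int) -> str:
    lo, hi = idx0 - _FLANK, idx0 + _FLANK + 1
    left_pad = "-" * max(0, -lo)
    right_pad = "-" * max(0, hi - len(sequence))
    return left_pad + sequence[max(0, lo):min(len(sequence), hi)] + right_pad


def scan_tyr_sites(record: ProteinRecord, rule: str = "acidic_flank") -> list[TyrSite]:
    """Enumerate candidate Tyr sites under the named rule, ordered by position."""
    if rule not in RULES:
        raise ValueError(f"unknown rule {rule!r}; expected one of {RULES}")
    sites = []
    seq = record.sequence
    for idx0, c in enumerate(seq):
        if c != "Y":
            continue
        if rule == "acidic_flank":
            flank = seq[max(0, idx0 - _FLANK):idx0] + seq[idx0 + 1:idx0 + _FLANK + 1]
            if not any(a in flank for a in "DE"):
                continue
        sites.append(TyrSite(protein_id=record.id, position=idx0 + 1, context=_context(seq, idx0)))
    return sites


def tyr_rate_per_100(record: ProteinRecord, sites: list[TyrSite]) -> float:
    """Candidate sites per 100 residues of chain length."""
    return 100.0 * len(sites) / len(record.sequence)
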