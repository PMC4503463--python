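"""End-to-end group comparison: sequences -> composition / physicochemical /
PTM profiles; structures -> salt bridges / Ramachandran; statistics -> report.

A run is fully specified by a configuration mapping (typically loaded from
YAML) naming at least two groups with FASTA paths and optional PDB
directories, plus thresholds. All group statistics are unpaired (the study
design compares populations); a paired mode by matching record order is
available for matched-homolog inputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from . import __version__
from .composition import (
    BinnedDistribution,
    bin_occupancy,
    composition_profile,
    sturges_scheme,
)
from .group_stats import StatResult, chi_square_independence, mean_se, pearson_correlation, two_sample_t
from .physicochem import PKA_SETS, PkaSet, physchem_profile, round_charge
from .ptm_scan import RULE_LABEL, scan_tyr_sites, tyr_rate_per_100
from .seqstruct_io import AMINO_ACIDS, ProteinRecord, read_fasta, read_pdb
from .structure_analysis import (
    DEFAULT_SALTBRIDGE_CUTOFF,
    DYADS,
    RamaSummary,
    detect_salt_bridges,
    rama_summary,
    salt_bridge_stats,
)

logger = logging.getLogger(__name__)

DEFAULT_CONFIG: dict[str, Any] = {
    "bin_range": [0.0, 20.0],
    "saltbridge_cutoff": DEFAULT_SALTBRIDGE_CUTOFF,
    "pka_set": "default",
    "ptm_rule": "acidic_flank",
    "pH": 7.0,
    "paired": False,
}


@dataclass
class ComparisonReport:
    """All tables produced by one comparison run."""

    groups: list[str]
    sturges: pd.DataFrame
    distributions: list[BinnedDistribution]
    composition_tests: pd.DataFrame  # residue, chi_square, df, p
    physchem: pd.DataFrame  # per-protein profiles
    physchem_summary: pd.DataFrame  # group mean +- SE with t/p
    salt_bridges: pd.DataFrame | None
    salt_bridge_summary: pd.DataFrame | None
    rama_summaries: dict[str, RamaSummary]
    ptm: pd.DataFrame
    ptm_summary: pd.DataFrame
    correlations: pd.DataFrame
    log: dict[str, Any] = field(default_factory=dict)

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.sturges.to_csv(out / "sturges_scheme.tsv", sep="\t", index=False)
        pd.concat([d.to_frame() for d in self.distributions], ignore_index=True).to_csv(
            out / "composition_bins.tsv", sep="\t", index=False
        )
        self.composition_tests.to_csv(out / "composition_chi2.tsv", sep="\t", index=False)
        self.physchem.to_csv(out / "physchem.tsv", sep="\t", index=False)
        self.physchem_summary.to_csv(out / "physchem_summary.tsv", sep="\t", index=False)
        if self.salt_bridges is not None:
            self.salt_bridges.to_csv(out / "salt_bridges.tsv", sep="\t", index=False)
            self.salt_bridge_summary.to_csv(out / "salt_bridge_summary.tsv", sep="\t", index=False)
        if self.rama_summaries:
            rows = []
            for group, summary in self.rama_summaries.items():
                for key, value in summary.to_rows():
                    rows.append({"group": group, "quantity": key, "value": value})
            pd.DataFrame(rows).to_csv(out / "rama_summary.tsv", sep="\t", index=False)
        self.ptm.to_csv(out / "ptm_sites.tsv", sep="\t", index=False)
        self.ptm_summary.to_csv(out / "ptm_summary.tsv", sep="\t", index=False)
        self.correlations.to_csv(out / "correlations.tsv", sep="\t", index=False)
        with open(out / "run_log.json", "w") as fh:
            json.dump(self.log, fh, indent=2, sort_keys=True)


def summarize_group(values) -> tuple[float, float]:
    """Mean and standard error of a group of values (needs >= 2)."""
    return mean_se(values)


def _stat_row(res: StatResult) -> dict[str, float | str]:
    return {"statistic": res.statistic_name, "value": res.value, "df": res.df,
            "p_value": res.p_value, "significance": res.stars()}


def _extended_scheme_edges(scheme_edges: tuple[float, ...], observed_max: float):
    if observed_max <= scheme_edges[-1]:
        return scheme_edges
    return scheme_edges[:-1] + (observed_max,)


def run_comparison(config: Mapping[str, Any]) -> ComparisonReport:
    """Execute every applicable stage for the configured groups."""
    cfg = {**DEFAULT_CONFIG, **dict(config)}
    groups_cfg = cfg.get("groups")
    if not groups_cfg or len(groups_cfg) < 2:
        raise ValueError("config must name at least two groups with FASTA paths")
    pkas: PkaSet = PKA_SETS[cfg["pka_set"]] if isinstance(cfg["pka_set"], str) else cfg["pka_set"]

    records: dict[str, list[ProteinRecord]] = {}
    structures: dict[str, list] = {}
    skipped: dict[str, int] = {}
    for g in groups_cfg:
        label = g["label"]
        records[label] = read_fasta(g["fasta"], group=label,
                                    policy=g.get("policy", "strict"))
        if not records[label]:
            raise ValueError(f"group {label!r}: no valid sequences")
        pdb_dir = g.get("pdb_dir")
        if pdb_dir:
            structures[label] = []
            skipped[label] = 0
            for path in sorted(Path(pdb_dir).glob("*.pdb")):
                try:
                    structures[label].append(read_pdb(path))
                except (ValueError, OSError) as exc:
                    logger.warning("skipping unreadable structure %s: %s", path, exc)
                    skipped[label] += 1
    labels = list(records)
    a, b = labels[0], labels[1]

    # --- composition stage -------------------------------------------------
    profiles = {g: [composition_profile(r) for r in rs] for g, rs in records.items()}
    n_max = max(len(rs) for rs in records.values())
    mn, mx = cfg["bin_range"]
    scheme = sturges_scheme(n_max, mn, mx)
    observed_max = max(p.percent[aa] for ps in profiles.values() for p in ps for aa in AMINO_ACIDS)
    edges = _extended_scheme_edges(scheme.edges, observed_max)
    binning = scheme if edges == scheme.edges else scheme.__class__(
        N=scheme.N, Mn=scheme.Mn, Mx=scheme.Mx, k_raw=scheme.k_raw, k=scheme.k,
        h_raw=scheme.h_raw, h=scheme.h, edges=edges,
    )
    sturges_frame = pd.DataFrame(
        [{"N": scheme.N, "Mn": scheme.Mn, "Mx": scheme.Mx, "Rx": scheme.Rx,
          "k_raw": scheme.k_raw, "k": scheme.k, "h_raw": scheme.h_raw, "h": scheme.h,
          "n_bins": binning.n_bins}]
    )
    distributions = []
    comp_rows = []
    for aa in AMINO_ACIDS:
        dist = bin_occupancy(profiles, aa, binning)
        distributions.append(dist)
        table = np.array([dist.counts_by_group[a], dist.counts_by_group[b]])
        try:
            res = chi_square_independence(table)
            comp_rows.append({"residue": aa, **_stat_row(res)})
        except ValueError as exc:  # all mass in one usable bin
            comp_rows.append({"residue": aa, "statistic": "chi_square",
                              "value": np.nan, "df": np.nan, "p_value": np.nan,
                              "significance": f"not testable: {exc}"})
    composition_tests = pd.DataFrame(comp_rows)

    # --- physicochemical stage ---------------------------------------------
    pc_rows = []
    for g, rs in records.items():
        for r in rs:
            p = physchem_profile(r, pkas)
            pc_rows.append({"group": g, "protein_id": p.protein_id,
                            "hydrophobic_pct": p.hydrophobic_pct,
                            "hydrophilic_pct": p.hydrophilic_pct,
                            "other_pct": p.other_pct,
                            "charge_pH7": p.net_charge_pH7,
                            "charge_pH7_rounded": round_charge(p.net_charge_pH7),
                            "pI": p.pI,
                            "length": len(r)})
    physchem = pd.DataFrame(pc_rows)
    pc_summary_rows = []
    for column in ("hydrophobic_pct", "hydrophilic_pct", "other_pct", "charge_pH7", "pI"):
        xa = physchem.loc[physchem.group == a, column].dropna().to_numpy()
        xb = physchem.loc[physchem.group == b, column].dropna().to_numpy()
        res = two_sample_t(xa, xb)
        ma, sa = mean_se(xa)
        mb, sb = mean_se(xb)
        pc_summary_rows.append({"quantity": column, f"mean_{a}": ma, f"se_{a}": sa,
                                f"mean_{b}": mb, f"se_{b}": sb, **_stat_row(res)})
    physchem_summary = pd.DataFrame(pc_summary_rows)

    # --- structure stage ----------------------------------------------------
    salt_bridges = salt_bridge_summary = None
    rama: dict[str, RamaSummary] = {}
    sb_rates: dict[str, pd.DataFrame] = {}
    if structures:
        sb_rows = []
        rate_rows = []
        for g, structs in structures.items():
            for s in structs:
                bridges = detect_salt_bridges(s, cfg["saltbridge_cutoff"])
                pct, dyad_pct = salt_bridge_stats(s, bridges)
                rate_rows.append({"group": g, "structure_id": s.id,
                                  "n_residues": s.n_residues, "n_bridges": len(bridges),
                                  "pct_of_residues": pct,
                                  **{f"dyad_{d}": dyad_pct[d] for d in DYADS}})
                for rec in bridges:
                    sb_rows.append({"group": g, "structure_id": s.id,
                                    "acidic_chain": rec.acidic_residue[0],
                                    "acidic_resseq": rec.acidic_residue[1],
                                    "basic_chain": rec.basic_residue[0],
                                    "basic_resseq": rec.basic_residue[1],
                                    "distance": rec.min_distance, "dyad": rec.dyad})
            rama[g] = rama_summary(structs)
        salt_bridges = pd.DataFrame(sb_rows)
        rates = pd.DataFrame(rate_rows)
        sb_rates = {g: df for g, df in rates.groupby("group")}
        sb_summary_rows = []
        for column in ["pct_of_residues"] + [f"dyad_{d}" for d in DYADS]:
            xa = rates.loc[rates.group == a, column].to_numpy()
            xb = rates.loc[rates.group == b, column].to_numpy()
            ma, sa = mean_se(xa)
            mb, sb = mean_se(xb)
            try:
                row = _stat_row(two_sample_t(xa, xb))
            except ValueError:
                row = {"statistic": "t", "value": np.nan, "df": np.nan,
                       "p_value": np.nan, "significance": "degenerate"}
            sb_summary_rows.append({"quantity": column, f"mean_{a}": ma, f"se_{a}": sa,
                                    f"mean_{b}": mb, f"se_{b}": sb, **row})
        salt_bridge_summary = pd.DataFrame(sb_summary_rows)

    # --- PTM stage ----------------------------------------------------------
    ptm_rows = []
    rate_by_group: dict[str, list[float]] = {g: [] for g in records}
    for g, rs in records.items():
        for r in rs:
            sites = scan_tyr_sites(r, cfg["ptm_rule"])
            rate_by_group[g].append(tyr_rate_per_100(r, sites))
            for s in sites:
                ptm_rows.append({"group": g, "protein_id": s.protein_id,
                                 "position": s.position, "context": s.context,
                                 "rule": f"{cfg['ptm_rule']} ({RULE_LABEL})"})
    ptm = pd.DataFrame(ptm_rows)
    res = two_sample_t(rate_by_group[a], rate_by_group[b])
    ma, sa = mean_se(rate_by_group[a])
    mb, sb = mean_se(rate_by_group[b])
    ptm_summary = pd.DataFrame(
        [{"quantity": "tyr_sites_per_100_residues",
          "rule": f"{cfg['ptm_rule']} ({RULE_LABEL})",
          f"mean_{a}": ma, f"se_{a}": sa, f"mean_{b}": mb, f"se_{b}": sb,
          **_stat_row(res)}]
    )

    # --- correlations -------------------------------------------------------
    corr_rows = []

    def corr(label: str, x, y) -> None:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        keep = np.isfinite(x) & np.isfinite(y)
        try:
            corr_rows.append({"pair": label, "n": int(keep.sum()),
                              **_stat_row(pearson_correlation(x[keep], y[keep]))})
        except ValueError as exc:
            corr_rows.append({"pair": label, "n": int(keep.sum()), "statistic": "r",
                              "value": np.nan, "df": np.nan, "p_value": np.nan,
                              "significance": f"not testable: {exc}"})

    for g in (a, b):
        sub = physchem[physchem.group == g]
        corr(f"pI_vs_charge[{g}]", sub.pI, sub.charge_pH7)
        corr(f"hydrophilic_vs_hydrophobic[{g}]", sub.hydrophilic_pct, sub.hydrophobic_pct)
        if g in sb_rates:
            rates_g = sb_rates[g]
            merged = sub.merge(
                rates_g[["structure_id", "pct_of_residues", "n_residues"]],
                left_on="protein_id", right_on="structure_id", how="inner",
            )
            if len(merged) >= 3:
                corr(f"saltbridge_vs_charge[{g}]", merged.pct_of_residues, merged.charge_pH7)
                corr(f"saltbridge_vs_residues[{g}]", merged.pct_of_residues, merged.n_residues)
    if len(records[a]) == len(records[b]):  # index-matched cross-group pairs
        pa = physchem[physchem.group == a].reset_index()
        pb = physchem[physchem.group == b].reset_index()
        for column in ("pI", "charge_pH7"):
            corr(f"{column}[{a}]_vs_{column}[{b}]", pa[column], pb[column])
    correlations = pd.DataFrame(corr_rows)

    cfg_hash = hashlib.sha256(
        json.dumps({k: v for k, v in cfg.items() if k != "groups"}, sort_keys=True,
                   default=str).encode()
    ).hexdigest()[:16]
    log = {
        "version": __version__,
        "config": {k: (v if k != "pka_set" or isinstance(v, str) else v.name)
                   for k, v in cfg.items()},
        "config_hash": cfg_hash,
        "groups": {g: {"n_sequences": len(rs),
                       "n_structures": len(structures.get(g, [])),
                       "n_structures_skipped": skipped.get(g, 0)}
                   for g, rs in records.items()},
    }
    return ComparisonReport(
        groups=labels,
        sturges=sturges_frame,
        distributions=distributions,
        composition_tests=composition_tests,
        physchem=physchem,
        physchem_summary=physchem_summary,
        salt_bridges=salt_bridges,
        salt_bridge_summary=salt_bridge_summary,
        rama_summaries=rama,
        ptm=ptm,
        ptm_summary=ptm_summary,
        correlations=correlations,
        log=log,
    )
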