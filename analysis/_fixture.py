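"""Shared access to the synthetic fixture for the numbered analysis scripts."""

import json
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
FIXTURE = ROOT / "scratch" / "fixture"
RESULTS = ROOT / "results"
SEED = 0


def load_manifest() -> dict:
    """Load the fixture manifest, generating the fixture first if absent."""
    manifest_path = FIXTURE / "manifest.json"
    if not manifest_path.exists():
        from thermocompare.synthetic_data import generate_study_fixture

        return generate_study_fixture(FIXTURE, seed=SEED)
    with open(manifest_path) as fh:
        return json.load(fh)


def comparison_config(with_structures: bool = True) -> dict:
    manifest = load_manifest()
    groups = []
    for label, g in manifest["groups"].items():
        entry = {"label": label, "fasta": g["fasta"]}
        if with_structures:
            entry["pdb_dir"] = g["pdb_dir"]
        groups.append(entry)
    return {"groups": groups}
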