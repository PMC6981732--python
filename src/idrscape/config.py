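"""Run configuration: defaults for every stage, YAML overlay, manifesting."""

from __future__ import annotations

import copy
import hashlib
import json
from pathlib import Path

import yaml

#: every stage parameter with its default; a YAML config file overlays
#: sections onto this structure (unknown keys are rejected)
DEFAULTS: dict = {
    "paths": {
        "outdir": "run_out",
        "fasta": None,
        "regions": None,
        "tracks": None,
        "morfs": None,
        "phospho": None,
        "subgroups": None,
        "ap2_msa": None,
        "baseline": None,       # packaged synthetic baseline when None
        "truth": None,
    },
    "simulate": {
        "seed": 1,
        "n_subgroups": 4,
        "members_per_subgroup": 6,
        "emit_internal_tracks": False,
    },
    "profile": {
        "n_boot": 200,
        "ci_level": 0.95,
        "seed": 1,
    },
    "boundary": {"a": 2.785, "b": 1.151},
    "cdf": {
        "bins": [0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9],
        # midpoint boundary calibrated from the packaged ordered/disordered
        # synthetic reference compositions; overridden via config
        "boundary": None,
    },
    "idaa": {"threshold": 0.5},
    "cast": {"threshold": 40.0},
    "morfs": {
        "dip_threshold": 0.5,
        "context_threshold": 0.5,
        "min_length": 5,
        "max_length": 25,
        "context": 10,
        "score_threshold": 0.725,
    },
    "conserve": {
        "min_occupancy": 0.75,
        "min_overlap_cols": 5,
        "identity_threshold": 0.6,
    },
    "tree": {"n_boot": 100, "seed": 1, "support_cutoff": 70.0},
}


def load_config(path: str | Path | None = None) -> dict:
    """Defaults overlaid with a YAML config file (sections of flat keys)."""
    cfg = copy.deepcopy(DEFAULTS)
    if path is None:
        return cfg
    user = yaml.safe_load(Path(path).read_text()) or {}
    for section, values in user.items():
        if section not in cfg:
            raise ValueError(f"unknown config section {section!r}")
        if not isinstance(values, dict):
            raise ValueError(f"config section {section!r} must be a mapping")
        for key, val in values.items():
            if key not in cfg[section]:
                raise ValueError(f"unknown config key {section}.{key}")
            cfg[section][key] = val
    return cfg


def file_digest(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(
    outdir: str | Path,
    stage: str,
    params: dict,
    inputs: dict[str, str | Path],
    outputs: dict[str, str | Path],
) -> Path:
    """Write a per-stage manifest (parameters plus input/output digests)."""
    manifest = {
        "stage": stage,
        "parameters": params,
        "inputs": {
            k: {"path": str(p), "sha256": file_digest(p)}
            for k, p in inputs.items()
            if p is not None and Path(p).exists()
        },
        "outputs": {
            k: {"path": str(p), "sha256": file_digest(p)}
            for k, p in outputs.items()
        },
    }
    path = Path(outdir) / f"manifest_{stage}.json"
    path.write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    return path
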