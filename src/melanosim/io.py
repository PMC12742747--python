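"""Cohort output files and run manifests.

All tables are UTF-8 comma-separated CSV with a header row and empty fields
for missing values; each output declares the package's schema version and
readers reject versions they do not know.  The manifest records the seed,
a hash of the configuration, and the package version, so any output
directory identifies the run that produced it exactly.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from . import __version__
from .calibration import compute_summaries
from .params import SCHEMA_VERSION

__all__ = ["write_outputs", "read_summary", "config_hash"]


def config_hash(params) -> str:
    """SHA-256 of the canonical YAML serialisation of a parameter set."""
    return hashlib.sha256(params.to_yaml().encode()).hexdigest()


def _stamp(frame: pd.DataFrame) -> pd.DataFrame:
    frame = frame.copy()
    frame.insert(0, "schema_version", SCHEMA_VERSION)
    return frame


def write_outputs(cohort, destination, params=None, strata=None) -> dict:
    """Write the event log, tumour table, summary table and manifest of a
    simulated cohort; returns the mapping of logical name to path."""
    dest = Path(destination)
    dest.mkdir(parents=True, exist_ok=True)
    paths = {
        "events": dest / "events.csv",
        "tumours": dest / "tumours.csv",
        "summary": dest / "summary.csv",
        "manifest": dest / "manifest.json",
    }
    _stamp(cohort.events_frame()).to_csv(paths["events"], index=False)
    _stamp(cohort.tumours_frame()).to_csv(paths["tumours"], index=False)
    _stamp(compute_summaries(cohort, strata)).to_csv(paths["summary"], index=False)
    manifest = {
        "schema_version": SCHEMA_VERSION,
        "package_version": __version__,
        "seed": cohort.seed,
        "n": cohort.n,
        "policy": cohort.policy.to_dict() if cohort.policy is not None else None,
        "config_hash": config_hash(params) if params is not None else None,
    }
    with open(paths["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=2)
    return paths


def read_summary(path) -> pd.DataFrame:
    """Read a summary CSV back, rejecting unknown schema versions."""
    frame = pd.read_csv(path)
    versions = set(frame.get("schema_version", pd.Series(dtype=int)).unique())
    if versions != {SCHEMA_VERSION}:
        raise ValueError(f"unsupported summary schema version(s) {sorted(versions)}")
    return frame.drop(columns=["schema_version"])
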