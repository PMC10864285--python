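"""Readers, writers, configuration, and run manifests.

Canonical on-disk dialect is UTF-8 TSV with headers; readers also accept
CSV. Every pipeline run writes a ``manifest.json`` capturing the full
threshold configuration, input digests, seed, and package version, so a
run can be reproduced byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import pathlib
import re
from datetime import datetime, timezone
from typing import Dict, List, Mapping, Optional, Sequence

import pandas as pd
import yaml

from . import __version__
from .microarray import TissuePanel
from .types import ProbeSetProfile, ScreenThresholds

_REP_COL = re.compile(r"^(?P<tissue>.+)\.rep(?P<k>\d+)$")
_PRESENT_COL = re.compile(r"^(?P<tissue>.+)\.present(?P<k>\d+)$")

# Affymetrix MAS5 detection letters: P(resent) is detected, M(arginal)
# and A(bsent) are not.
_PRESENT_MAP = {"P": True, "M": False, "A": False,
                "TRUE": True, "FALSE": False, "1": True, "0": False}


def _read_table(source, **kwargs) -> pd.DataFrame:
    """TSV by default; fall back to comma sniffing for .csv paths."""
    sep = "\t"
    if isinstance(source, (str, pathlib.Path)) and str(source).endswith(".csv"):
        sep = ","
    return pd.read_csv(source, sep=sep, **kwargs)


def parse_present_flag(value) -> bool:
    if isinstance(value, bool):
        return value
    key = str(value).strip().upper()
    if key not in _PRESENT_MAP:
        raise ValueError(f"unrecognized present flag {value!r}")
    return _PRESENT_MAP[key]


def read_expression_matrix(source) -> List[ProbeSetProfile]:
    """Read the wide replicate matrix into probe-set profiles.

    Expected columns: probe_id, gene_id, gene_symbol, then
    ``<tissue>.rep<k>`` intensity and ``<tissue>.present<k>`` flag
    columns. Missing (NaN) replicate cells are skipped.
    """
    df = _read_table(source, dtype={"probe_id": str, "gene_id": str,
                                    "gene_symbol": str})
    for col in ("probe_id", "gene_id", "gene_symbol"):
        if col not in df.columns:
            raise ValueError(f"expression matrix missing column {col!r}")
    rep_cols: Dict[str, list] = {}
    present_cols: Dict[str, list] = {}
    for col in df.columns:
        m = _REP_COL.match(col)
        if m:
            rep_cols.setdefault(m["tissue"], []).append((int(m["k"]), col))
        m = _PRESENT_COL.match(col)
        if m:
            present_cols.setdefault(m["tissue"], []).append((int(m["k"]), col))
    if not rep_cols:
        raise ValueError("no <tissue>.rep<k> columns found")

    profiles = []
    for _, row in df.iterrows():
        intensities = {}
        present = {}
        for tissue, cols in rep_cols.items():
            vals, flags = [], []
            pcols = dict((k, c) for k, c in present_cols.get(tissue, []))
            for k, col in sorted(cols):
                v = row[col]
                if pd.isna(v):
                    continue
                vals.append(float(v))
                if k in pcols and not pd.isna(row[pcols[k]]):
                    flags.append(parse_present_flag(row[pcols[k]]))
                else:
                    flags.append(True)
            if vals:
                intensities[tissue] = vals
                present[tissue] = flags
        profiles.append(ProbeSetProfile(
            probe_id=row["probe_id"], gene_id=row["gene_id"],
            gene_symbol=row["gene_symbol"], intensities=intensities,
            present=present))
    return profiles


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a YAML mapping")
    return cfg


def thresholds_from_config(cfg: Mapping) -> ScreenThresholds:
    section = cfg.get("thresholds", {})
    allowed = {f.name for f in dataclasses.fields(ScreenThresholds)}
    unknown = set(section) - allowed
    if unknown:
        raise ValueError(f"unknown threshold keys: {sorted(unknown)}")
    return ScreenThresholds(**section)


def panel_from_config(cfg: Mapping) -> TissuePanel:
    section = dict(cfg.get("panel", {}))
    if "exclude" in section:
        section["exclude"] = tuple(section["exclude"])
    return TissuePanel(**section)


def file_digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    outdir,
    thresholds: ScreenThresholds,
    inputs: Mapping[str, str],
    seed: Optional[int] = None,
    extra: Optional[Mapping] = None,
) -> str:
    """Write the run manifest next to the outputs; returns its path."""
    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "software": {"name": "ovascreen", "version": __version__},
        "thresholds": thresholds.to_dict(),
        "inputs": {
            name: {"path": str(p), "sha256": file_digest(p)}
            for name, p in inputs.items()
        },
        "seed": seed,
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    if extra:
        manifest.update(extra)
    path = outdir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return str(path)


def packaged_table1() -> pathlib.Path:
    """Path of the packaged screen-results fixture (Table 1 transcription)."""
    return pathlib.Path(__file__).parent / "data" / "table1.tsv"
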