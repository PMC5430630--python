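"""File dialects, configuration and run manifests.

All tables are UTF-8 tab-separated values with a header row and "NA" as the
missing token (metabolite names may contain commas, so TSV over CSV). GWAS
summary-statistics files use the dialect::

    rsid  effect_allele  other_allele  beta  se  pvalue  n  eaf

with ``eaf`` optional. Result writers prepend a comment line carrying the
run-manifest hash so every output is traceable to its configuration.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd

from .mr import SUMMARY_COLUMNS

__all__ = [
    "read_summary_stats",
    "write_summary_stats",
    "read_cohort",
    "write_cohort",
    "write_results",
    "write_manifest",
    "manifest_hash",
]

log = logging.getLogger("hargmr")

_NA = "NA"


def read_summary_stats(path: str | Path) -> pd.DataFrame:
    """Read a GWAS summary-statistics TSV, validating the dialect.

    Raises on missing required columns, duplicate rsids, or non-positive
    standard errors (reported with 1-based data row numbers).
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", na_values=[_NA], comment="#")
    missing = [c for c in SUMMARY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    dup = df["rsid"][df["rsid"].duplicated()]
    if not dup.empty:
        raise ValueError(f"{path}: duplicate rsid(s) {sorted(dup.unique())}")
    bad_se = df.index[~(df["se"] > 0)]
    if len(bad_se):
        raise ValueError(
            f"{path}: non-positive se in row(s) {[int(i) + 1 for i in bad_se]}"
        )
    if "eaf" not in df.columns:
        df["eaf"] = float("nan")
    return df


def write_summary_stats(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    cols = SUMMARY_COLUMNS + (["eaf"] if "eaf" in df.columns else [])
    df[cols].to_csv(path, sep="\t", index=False, na_rep=_NA)
    return path


def read_cohort(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=[_NA], comment="#")


def write_cohort(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    df.to_csv(path, sep="\t", index=False, na_rep=_NA)
    return path


def manifest_hash(manifest: dict) -> str:
    payload = json.dumps(manifest, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def write_manifest(manifest: dict, out_dir: str | Path) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = dict(manifest)
    manifest["manifest_hash"] = manifest_hash(manifest)
    path = out_dir / "run_manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
    return path


def write_results(
    tables: dict[str, pd.DataFrame], out_dir: str | Path, manifest: dict | None = None
) -> list[Path]:
    """Write result tables as TSV, each headed by the manifest-hash comment."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tag = manifest_hash(manifest or {})
    written = []
    for name, table in tables.items():
        path = out_dir / f"{name}.tsv"
        with open(path, "w") as fh:
            fh.write(f"# hargmr run {tag}\n")
            table.to_csv(fh, sep="\t", index=False, na_rep=_NA)
        log.info("wrote %s (%d rows)", path, len(table))
        written.append(path)
    return written
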