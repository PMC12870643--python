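"""Readers and writers for the tab-delimited formats the pipeline exchanges.

All matrices are stored probes-as-rows with the probe id in the first
column; sample tables are one row per sample with ``sample_id`` first.
Everything is plain TSV so intermediate stages can be inspected with
standard command-line tools.
"""

from __future__ import annotations

import pandas as pd


def read_matrix(path) -> pd.DataFrame:
    """Read a probes x samples matrix TSV (first column = probe id)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label="probe_id")


def read_sample_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample_id")


def write_sample_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label="sample_id")


def read_blocklist(path) -> list[str]:
    """One probe id per line; blank lines and '#' comments ignored."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.append(line)
    return out


def read_gmt(path) -> dict[str, list[str]]:
    """Read a GMT gene-set file: set name, description, then members."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(sets: dict[str, list[str]], path, description: str = "") -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")
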