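"""Readers and writers for the pipeline's tabular formats.

All tables are UTF-8, tab-delimited with a header row; missing values
are written as empty strings, never as zeros.  Annotation sets use the
GMT convention: ``term_id <TAB> term_name <TAB> member1 <TAB> member2...``
Malformed files are rejected with a SchemaError listing offending line
numbers.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .synth import PlateLayout

GROWTH_COLUMNS = ["strain_id", "plate_id", "well", "concentration", "replicate", "growth"]
OD_COLUMNS = ["strain_id", "condition", "replicate", "od600", "batch"]
TRUTH_COLUMNS = ["strain_id", "true_class", "true_ic50"]
PLATEMAP_COLUMNS = ["plate_id", "well", "strain_id", "control"]
RESULTS_COLUMNS = ["strain_id", "final_score", "n_spots", "classification"]


class SchemaError(ValueError):
    """A table violated its schema; message lists offending lines."""


def _read_tsv(path, columns: list[str], numeric: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    bad_lines = []
    for col in numeric:
        converted = pd.to_numeric(df[col].replace("", pd.NA), errors="coerce")
        bad = df.index[converted.isna() & (df[col] != "")]
        bad_lines += [(int(i) + 2, col) for i in bad]  # +2: header + 1-based
        df[col] = converted
    if bad_lines:
        msg = "; ".join(f"line {ln}: non-numeric {col!r}" for ln, col in bad_lines)
        raise SchemaError(f"{path}: {msg}")
    return df[columns]


def _check_unique(df: pd.DataFrame, keys: list[str], path) -> None:
    dup = df.duplicated(subset=keys, keep=False)
    if dup.any():
        lines = [int(i) + 2 for i in df.index[dup]]
        raise SchemaError(f"{path}: duplicate {tuple(keys)} rows at lines {lines}")


def read_growth_table(path) -> pd.DataFrame:
    df = _read_tsv(path, GROWTH_COLUMNS, ["concentration", "replicate", "growth"])
    df["replicate"] = df["replicate"].astype(int)
    _check_unique(df, ["strain_id", "plate_id", "concentration", "replicate"], path)
    # every treated (strain, replicate) needs its untreated anchor row
    treated = df[df["concentration"] > 0]
    untreated = set(zip(df.loc[df["concentration"] == 0, "strain_id"],
                        df.loc[df["concentration"] == 0, "replicate"]))
    orphans = set(zip(treated["strain_id"], treated["replicate"])) - untreated
    if orphans:
        raise SchemaError(f"{path}: treated rows without untreated anchor: {sorted(orphans)[:5]}")
    return df


def write_growth_table(df: pd.DataFrame, path) -> None:
    df[GROWTH_COLUMNS].to_csv(path, sep="\t", index=False, na_rep="")


def read_od_table(path) -> pd.DataFrame:
    df = _read_tsv(path, OD_COLUMNS, ["condition", "replicate", "od600"])
    df["replicate"] = df["replicate"].astype(int)
    _check_unique(df, ["strain_id", "condition", "replicate", "batch"], path)
    return df


def write_od_table(df: pd.DataFrame, path) -> None:
    df[OD_COLUMNS].to_csv(path, sep="\t", index=False, na_rep="")


def read_truth_table(path) -> pd.DataFrame:
    df = _read_tsv(path, TRUTH_COLUMNS, ["true_ic50"])
    _check_unique(df, ["strain_id"], path)
    return df


def write_truth_table(df: pd.DataFrame, path) -> None:
    df[TRUTH_COLUMNS].to_csv(path, sep="\t", index=False, na_rep="")


def read_plate_maps(path) -> list[PlateLayout]:
    df = _read_tsv(path, PLATEMAP_COLUMNS, [])
    _check_unique(df, ["plate_id", "well"], path)
    layouts = []
    for pid, grp in df.groupby("plate_id", sort=True):
        layouts.append(
            PlateLayout(
                plate_id=pid,
                wells=dict(zip(grp["well"], grp["strain_id"])),
                control_wells={
                    w: tag for w, tag in zip(grp["well"], grp["control"]) if tag
                },
            )
        )
    return layouts


def write_plate_maps(layouts: list[PlateLayout], path) -> None:
    pd.concat([l.to_frame() for l in layouts], ignore_index=True).to_csv(
        path, sep="\t", index=False, na_rep=""
    )


def write_results_table(df: pd.DataFrame, path) -> None:
    df[RESULTS_COLUMNS].to_csv(path, sep="\t", index=False, na_rep="")


def read_results_table(path) -> pd.DataFrame:
    df = _read_tsv(path, RESULTS_COLUMNS, ["final_score", "n_spots"])
    df["final_score"] = df["final_score"].astype(int)
    df["n_spots"] = df["n_spots"].astype(int)
    return df


def read_gmt(path) -> dict[str, tuple[str, list[str]]]:
    """Parse a GMT file into {term_id: (term_name, members)}."""
    sets: dict[str, tuple[str, list[str]]] = {}
    bad = []
    for ln, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            bad.append(ln)
            continue
        term_id, term_name, members = parts[0], parts[1], [m for m in parts[2:] if m]
        if not members or term_id in sets:
            bad.append(ln)
            continue
        sets[term_id] = (term_name, members)
    if bad:
        raise SchemaError(f"{path}: malformed or duplicate GMT lines {bad}")
    return sets


def write_gmt(sets: dict[str, tuple[str, list[str]]], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for term_id, (name, members) in sets.items():
            fh.write("\t".join([term_id, name, *members]) + "\n")
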