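"""Tab-separated input/output with schema validation.

All pipeline inputs are UTF-8 TSV files with a header row:

- mutations: ``sample  gene  variant_class  damaging_flag  hotspot_flag``
- copy number: ``sample  gene  copy_number``
- ploidy: ``sample  ploidy``
- gene properties: ``gene`` plus the 19 systems-level feature columns
  (``protein_length`` / ``n_domains`` are accepted and ignored)
- annotation: ``gene  category  [role]``

Gene symbols are upper-cased on read; no alias resolution is attempted.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .annotation import GeneAnnotation
from .errors import InputError

_BOOL_MAP = {
    "true": True, "false": False, "1": True, "0": False,
    "t": True, "f": False, "yes": True, "no": False,
}


def _read_tsv(path: str | Path, required: list[str], name: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise InputError(f"{name} file not found: {path}")
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, comment=None)
    except Exception as exc:  # malformed file
        raise InputError(f"cannot parse {name} file {path}: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise InputError(f"{name} file {path} missing columns: {missing}")
    return df


def _to_bool(series: pd.Series, col: str, name: str) -> pd.Series:
    vals = series.fillna("false").astype(str).str.strip().str.lower()
    bad = set(vals.unique()) - set(_BOOL_MAP)
    if bad:
        raise InputError(f"{name}: column {col!r} has non-boolean values {sorted(bad)}")
    return vals.map(_BOOL_MAP)


def read_mutations(path: str | Path) -> pd.DataFrame:
    df = _read_tsv(path, ["sample", "gene", "variant_class", "damaging_flag", "hotspot_flag"], "mutation")
    out = pd.DataFrame(
        {
            "sample": df["sample"].astype(str),
            "gene": df["gene"].astype(str).str.upper(),
            "variant_class": df["variant_class"].astype(str),
            "damaging_flag": _to_bool(df["damaging_flag"], "damaging_flag", "mutation"),
            "hotspot_flag": _to_bool(df["hotspot_flag"], "hotspot_flag", "mutation"),
        }
    )
    return out


def read_cnvs(path: str | Path) -> pd.DataFrame:
    df = _read_tsv(path, ["sample", "gene", "copy_number"], "copy-number")
    try:
        cn = df["copy_number"].astype(float)
    except ValueError as exc:
        raise InputError(f"copy-number file {path}: non-numeric copy_number") from exc
    return pd.DataFrame(
        {"sample": df["sample"].astype(str), "gene": df["gene"].astype(str).str.upper(), "copy_number": cn}
    )


def read_ploidy(path: str | Path) -> pd.DataFrame:
    df = _read_tsv(path, ["sample", "ploidy"], "ploidy")
    try:
        pl = df["ploidy"].astype(float)
    except ValueError as exc:
        raise InputError(f"ploidy file {path}: non-numeric ploidy") from exc
    if (pl <= 0).any():
        raise InputError(f"ploidy file {path}: ploidy must be positive")
    return pd.DataFrame({"sample": df["sample"].astype(str), "ploidy": pl})


def read_properties(path: str | Path) -> pd.DataFrame:
    from .features import SYSTEMS_FEATURES

    df = _read_tsv(path, ["gene"], "property")
    df["gene"] = df["gene"].astype(str).str.upper()
    for col in df.columns:
        if col == "gene":
            continue
        vals = df[col].astype(str).str.strip().str.lower()
        if set(vals.unique()) <= set(_BOOL_MAP):
            df[col] = vals.map(_BOOL_MAP)
        else:
            try:
                df[col] = df[col].astype(float)
            except ValueError as exc:
                raise InputError(f"property file {path}: non-numeric column {col!r}") from exc
    missing = [c for c in SYSTEMS_FEATURES if c not in df.columns]
    if missing:
        raise InputError(f"property file {path} missing columns: {missing}")
    return df


def read_annotation(path: str | Path) -> GeneAnnotation:
    df = _read_tsv(path, ["gene", "category"], "annotation")
    if "role" in df.columns:
        df["role"] = df["role"].where(df["role"].notna() & (df["role"] != ""), None)
    return GeneAnnotation.from_frame(df)


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)
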