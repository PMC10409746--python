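"""Readers and writers for the pipeline's tabular formats.

On-disk canonical form is long (tidy) delimited text with a header row;
the delimiter is inferred from the extension (``.csv`` -> comma, anything
else -> tab). Floats are serialized with ``repr`` round-trip precision.
Roster / DTL configuration travels as YAML or JSON.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .types import (
    AbundanceTable,
    CommunityDesign,
    FormatError,
    StrainInfo,
    ValidationError,
)


def _delimiter(path: str | Path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


class UnknownStrainWarning(UserWarning):
    """A row references a strain absent from the community roster."""


def read_abundance_table(
    path: str | Path,
    roster: CommunityDesign,
    dtl_map: Mapping[str, float] | None = None,
    samples_path: str | Path | None = None,
) -> AbundanceTable:
    """Read a long-format abundance file and apply detection-limit censoring.

    The file needs columns ``sample_id, strain_id, value``. Sample metadata is
    read from ``samples_path`` or, by default, from a ``<stem>.samples.<ext>``
    sidecar next to the abundance file. Values strictly below the strain's DTL
    are flagged censored and stored as 0; rows referencing strains outside the
    roster raise :class:`UnknownStrainWarning` but are kept, flagged as
    contamination via ``in_roster=False`` on the returned table's data frame.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_delimiter(path), float_precision="round_trip")
    for col in ("sample_id", "strain_id", "value"):
        if col not in df.columns:
            raise FormatError(f"abundance file {path.name} missing required column {col!r}")
    neg = df.index[df["value"] < 0]
    if len(neg):
        raise ValidationError(f"negative abundance value at row {neg[0]} of {path.name}")

    if dtl_map is None:
        dtl_map = roster.dtl_map()
    known = set(roster.strain_ids)
    unknown = sorted(set(df["strain_id"]) - known)
    if unknown:
        warnings.warn(
            f"abundance file {path.name} references strain(s) not in the roster "
            f"(flagged as contamination): {unknown}",
            UnknownStrainWarning,
            stacklevel=2,
        )

    dtl = df["strain_id"].map(lambda s: dtl_map.get(s, 0.0)).to_numpy(float)
    v = df["value"].to_numpy(float)
    cens = v < dtl
    df = df.assign(value=np.where(cens, 0.0, v), censored=cens, in_roster=df["strain_id"].isin(known))

    if samples_path is None:
        ext = path.suffix
        samples_path = path.with_suffix(f".samples{ext}")
    samples = pd.read_csv(samples_path, sep=_delimiter(samples_path), float_precision="round_trip")
    table = AbundanceTable(df[AbundanceTable.DATA_COLUMNS], samples)
    table.data["in_roster"] = df["in_roster"].to_numpy()
    return table


def write_abundance_table(table: AbundanceTable, path: str | Path) -> None:
    path = Path(path)
    _write_frame(table.data[AbundanceTable.DATA_COLUMNS], path)
    _write_frame(table.samples, path.with_suffix(f".samples{path.suffix}"))


RELATIONSHIP_COLUMNS = [
    "focal_x",
    "affected_y",
    "environment",
    "r_abs",
    "category",
    "p_raw",
    "p_adjusted",
    "significant",
    "note",
]


def write_relationship_table(relationships: Sequence, path: str | Path) -> None:
    """Serialize strain relationships, one row per (focal x, affected y, environment).

    Accepts StrainRelationship records or an equivalent DataFrame; round-trips
    losslessly through :func:`read_relationship_table` (undefined r_abs is
    stored as the empty field and restored as NaN).
    """
    if isinstance(relationships, pd.DataFrame):
        df = relationships[RELATIONSHIP_COLUMNS]
    else:
        df = pd.DataFrame([r.as_dict() for r in relationships], columns=RELATIONSHIP_COLUMNS)
    _write_frame(df, path)


def read_relationship_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep=_delimiter(path),
        dtype={"note": "string"},
        float_precision="round_trip",
    )
    missing = [c for c in RELATIONSHIP_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"relationship file missing column(s): {missing}")
    df["significant"] = df["significant"].astype(bool)
    df["note"] = df["note"].fillna("").astype(str)
    return df


def _fmt(x) -> str:
    if isinstance(x, float):
        return repr(x)
    return str(x)


def _write_frame(df: pd.DataFrame, path: str | Path) -> None:
    sep = _delimiter(path)
    with open(path, "w") as fh:
        fh.write(sep.join(df.columns) + "\n")
        for row in df.itertuples(index=False):
            fh.write(sep.join("" if _is_na(v) else _fmt(v) for v in row) + "\n")


def _is_na(v) -> bool:
    return v is None or (isinstance(v, float) and v != v)


def read_roster_config(path: str | Path) -> CommunityDesign:
    """Load a roster (strain codes, names, 16S copy numbers, DTLs) from YAML/JSON."""
    path = Path(path)
    with open(path) as fh:
        cfg = json.load(fh) if path.suffix == ".json" else yaml.safe_load(fh)
    strains = tuple(
        StrainInfo(s["strain_id"], s.get("full_name", s["strain_id"]), int(s["n_16S"]), float(s["dtl"]))
        for s in cfg["strains"]
    )
    return CommunityDesign(strains, dropout_of=cfg.get("dropout_of"))


def write_roster_config(roster: CommunityDesign, path: str | Path) -> None:
    path = Path(path)
    cfg = {
        "strains": [
            {"strain_id": s.strain_id, "full_name": s.full_name, "n_16S": s.n_16S, "dtl": s.dtl}
            for s in roster.roster
        ],
    }
    if roster.dropout_of is not None:
        cfg["dropout_of"] = roster.dropout_of
    with open(path, "w") as fh:
        if path.suffix == ".json":
            json.dump(cfg, fh, indent=2)
        else:
            yaml.safe_dump(cfg, fh, sort_keys=False)
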