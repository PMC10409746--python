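"""Domain types shared across the dropout-community pipeline.

The central objects mirror a single-species dropout (leave-one-out) experiment
on a defined bacterial consortium: a roster of strains with strain-specific
16S rRNA gene copy numbers and qPCR detection limits (DTL), community designs
(full consortium or one-strain dropouts), sample metadata, detection-limit
censored absolute abundance tables, and pH records.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd


class ValidationError(ValueError):
    """Raised when a domain invariant is violated."""


class FormatError(ValueError):
    """Raised when an input file does not match the documented schema."""


@dataclass(frozen=True)
class StrainInfo:
    """One community member.

    Parameters
    ----------
    strain_id : str
        Short code, e.g. ``"B.ca"``.
    full_name : str
        Full species/strain name.
    n_16S : int
        16S rRNA gene copies per genome (>= 1). Used to convert qPCR 16S
        copy counts into genome equivalents.
    dtl : float
        Strain-specific qPCR detection limit in copies per 5 ng gDNA
        template (>= 0). Raw readouts below this are treated as not
        detected; the comparison is inclusive (value >= dtl counts as
        detected).
    """

    strain_id: str
    full_name: str
    n_16S: int
    dtl: float

    def __post_init__(self) -> None:
        if self.n_16S < 1:
            raise ValidationError(f"n_16S must be >= 1, got {self.n_16S} for {self.strain_id}")
        if self.dtl < 0:
            raise ValidationError(f"dtl must be >= 0, got {self.dtl} for {self.strain_id}")


@dataclass(frozen=True)
class CommunityDesign:
    """A full consortium or a single-strain dropout of it."""

    roster: tuple[StrainInfo, ...]
    dropout_of: str | None = None

    def __post_init__(self) -> None:
        ids = [s.strain_id for s in self.roster]
        if len(set(ids)) != len(ids):
            raise ValidationError("strain_id values must be unique within a roster")
        if self.dropout_of is not None and self.dropout_of not in ids:
            raise ValidationError(f"dropout_of={self.dropout_of!r} is not in the roster")

    @property
    def strain_ids(self) -> list[str]:
        return [s.strain_id for s in self.roster]

    @property
    def expected_strains(self) -> list[str]:
        """Strains expected in this community (roster minus the dropout)."""
        return [s for s in self.strain_ids if s != self.dropout_of]

    @property
    def label(self) -> str:
        return "full" if self.dropout_of is None else f"minus_{self.dropout_of}"

    def dropout(self, strain_id: str) -> "CommunityDesign":
        return CommunityDesign(self.roster, dropout_of=strain_id)

    def dtl_map(self) -> dict[str, float]:
        return {s.strain_id: s.dtl for s in self.roster}

    def strain(self, strain_id: str) -> StrainInfo:
        for s in self.roster:
            if s.strain_id == strain_id:
                return s
        raise KeyError(strain_id)


@dataclass(frozen=True)
class SampleMeta:
    """Metadata of one cultured well / gut sample.

    ``amount`` is the sample volume (ml) or mass (g); ``amount_unit`` tags
    which. The (community, environment, bio_replicate, tech_replicate)
    combination is unique within a study.
    """

    sample_id: str
    community: str
    environment: str
    bio_replicate: int
    tech_replicate: int
    amount: float = 1.0
    amount_unit: str = "ml"

    def __post_init__(self) -> None:
        if self.amount <= 0:
            raise ValidationError(f"amount must be > 0, got {self.amount}")


@dataclass(frozen=True)
class PHRecord:
    """pH of a spent-culture supernatant together with its fresh-medium reference."""

    sample_id: str
    ph_spent: float
    ph_fresh: float

    def __post_init__(self) -> None:
        for name, v in (("ph_spent", self.ph_spent), ("ph_fresh", self.ph_fresh)):
            if not (0 < v < 14):
                raise ValidationError(f"{name} must lie in (0, 14), got {v}")

    @property
    def delta_ph(self) -> float:
        return self.ph_spent - self.ph_fresh


class AbundanceTable:
    """Detection-limit-censored absolute abundances in long (tidy) form.

    ``data`` holds one row per (sample_id, strain_id) with columns
    ``value`` (non-negative absolute abundance; censored entries carry 0)
    and ``censored`` (bool; authoritative for detection logic).
    ``samples`` holds one row per sample with the SampleMeta fields.
    """

    DATA_COLUMNS = ["sample_id", "strain_id", "value", "censored"]
    SAMPLE_COLUMNS = [
        "sample_id",
        "community",
        "environment",
        "bio_replicate",
        "tech_replicate",
        "amount",
        "amount_unit",
    ]

    def __init__(self, data: pd.DataFrame, samples: pd.DataFrame):
        missing = [c for c in self.DATA_COLUMNS if c not in data.columns]
        if missing:
            raise FormatError(f"abundance data missing required column(s): {missing}")
        missing = [c for c in self.SAMPLE_COLUMNS if c not in samples.columns]
        if missing:
            raise FormatError(f"sample metadata missing required column(s): {missing}")
        neg = data.index[data["value"] < 0]
        if len(neg):
            raise ValidationError(f"negative abundance at row index {neg[0]}")
        self.data = data.reset_index(drop=True)[self.DATA_COLUMNS].copy()
        self.data["censored"] = self.data["censored"].astype(bool)
        self.samples = samples.reset_index(drop=True)[self.SAMPLE_COLUMNS].copy()

    def __len__(self) -> int:
        return len(self.data)

    @property
    def environments(self) -> list[str]:
        return sorted(self.samples["environment"].unique())

    @property
    def communities(self) -> list[str]:
        return sorted(self.samples["community"].unique())

    def merged(self) -> pd.DataFrame:
        return self.data.merge(self.samples, on="sample_id", how="left")

    def replicate_values(
        self,
        strain_id: str,
        community: str,
        environment: str,
        level: str = "well",
    ) -> tuple[np.ndarray, np.ndarray]:
        """Replicate abundances and censoring flags for one strain/community/environment.

        level="well" returns one value per well (the study's N = 3 bio x 3
        tech = 9); level="bio" averages technical replicates within each
        biological replicate first (an averaged value is censored only when
        every contributing well is censored).
        """
        m = self.merged()
        sel = m[
            (m["strain_id"] == strain_id)
            & (m["community"] == community)
            & (m["environment"] == environment)
        ]
        if level == "well":
            return sel["value"].to_numpy(float), sel["censored"].to_numpy(bool)
        if level == "bio":
            g = sel.groupby("bio_replicate").agg(value=("value", "mean"), censored=("censored", "all"))
            return g["value"].to_numpy(float), g["censored"].to_numpy(bool)
        raise ValueError(f"unknown aggregation level {level!r}; use 'well' or 'bio'")

    def to_wide(
        self,
        environment: str | None = None,
        aggregate: str | None = None,
        fill: float = 0.0,
    ) -> pd.DataFrame:
        """Samples x strains matrix for ordination; censored entries contribute 0.

        aggregate="median_community" collapses to one median profile per
        (community, environment) as used for ordination of community medians.
        """
        m = self.merged()
        if environment is not None:
            m = m[m["environment"] == environment]
        if aggregate is None:
            wide = m.pivot_table(index="sample_id", columns="strain_id", values="value", fill_value=fill)
        elif aggregate == "median_community":
            wide = m.pivot_table(
                index=["community", "environment"],
                columns="strain_id",
                values="value",
                aggfunc="median",
                fill_value=fill,
            )
            wide.index = [f"{c}|{e}" for c, e in wide.index]
        else:
            raise ValueError(f"unknown aggregate {aggregate!r}")
        wide.columns.name = None
        wide.index.name = "sample_id"
        return wide

    def sample_groups(self, by: str = "environment") -> pd.Series:
        return self.samples.set_index("sample_id")[by]

    def n_censored(self) -> int:
        return int(self.data["censored"].sum())


def apply_censoring(values: Iterable[float], dtl: float) -> tuple[np.ndarray, np.ndarray]:
    """Censor raw-scale values below an inclusive detection limit.

    Returns (values-with-censored-set-to-0, censored flags). A value equal to
    the DTL counts as detected.
    """
    v = np.asarray(list(values), dtype=float)
    cens = v < dtl
    out = np.where(cens, 0.0, v)
    return out, cens


#: Default 12-member roster. The short codes and species names follow the
#: Oligo-Mouse-Microbiota (OMM12) consortium; the 16S copy numbers and
#: detection limits are SYNTHETIC PLACEHOLDERS (the strain-specific values
#: are not published) and must be replaced with measured values for real
#: data via the roster config.
DEFAULT_ROSTER: tuple[StrainInfo, ...] = (
    StrainInfo("E.fa", "Enterococcus faecalis KB1", 4, 100.0),
    StrainInfo("B.ca", "Bacteroides caecimuris I48", 5, 100.0),
    StrainInfo("B.co", "Blautia coccoides YL58", 6, 100.0),
    StrainInfo("M.in", "Muribaculum intestinale YL27", 3, 100.0),
    StrainInfo("B.an", "Bifidobacterium animalis YL2", 5, 100.0),
    StrainInfo("F.pl", "Flavonifractor plautii YL31", 5, 100.0),
    StrainInfo("E.cl", "Enterocloster clostridioformis YL32", 6, 100.0),
    StrainInfo("C.in", "Clostridium innocuum I46", 5, 100.0),
    StrainInfo("L.re", "Limosilactobacillus reuteri I49", 6, 100.0),
    StrainInfo("A.muc", "Akkermansia muciniphila YL44", 4, 100.0),
    StrainInfo("T.mu", "Turicimonas muris YL45", 7, 100.0),
    StrainInfo("A.mur", "Acutalibacter muris KB18", 5, 100.0),
)


def default_community() -> CommunityDesign:
    return CommunityDesign(DEFAULT_ROSTER)
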