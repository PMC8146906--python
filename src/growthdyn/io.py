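"""Phenotype data model and CSV/wide-matrix interchange.

The canonical representation is a *long-format* table: one row per
(genotype, treatment, replicate, day-after-transplanting, trait)
observation.  Long format preserves replicate-level data needed for
per-day ANOVA and variance decomposition; wide genotype x day matrices
are derived views used by clustering and covariance fitting.

The imaging-day grid is irregular (default days 2..35 with day 30
missing, mirroring a lost imaging day); missing days are represented by
absence from the grid, never by NaN rows, so that time-aware covariance
structures see true day distances.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import json

import numpy as np
import pandas as pd

from .errors import (
    DuplicateKeyError,
    GridError,
    MissingColumnError,
    UnknownTraitError,
    ValidationError,
)

#: The four watering/fertilisation regimes: control, low nitrogen,
#: water stress, combined nitrogen + water stress.
TREATMENTS = ("C", "N", "W", "NW")

#: Traits measuring physical size; must be strictly positive.
SIZE_TRAITS = frozenset({"EBv", "PHg", "CLe", "SCov"})

#: Default imaging-day grid: DAT 2..35 with DAT 30 absent.
DEFAULT_GRID: tuple[int, ...] = tuple(d for d in range(2, 36) if d != 30)

#: Canonical long-format column names.
COLUMNS = ("genotype", "treatment", "replicate", "dat", "trait", "value")

KEY_COLUMNS = ("genotype", "treatment", "replicate", "dat", "trait")


@dataclass(frozen=True)
class GrowthCurve:
    """Mean trajectory of one trait for one genotype x treatment.

    Attributes
    ----------
    genotype_id : str
    treatment : str
        One of ``C``, ``N``, ``W``, ``NW``.
    dats : tuple of int
        Strictly increasing imaging days.
    means : tuple of float
        Replicate-mean trait value per day.
    n_per_point : tuple of int
        Number of non-missing replicates behind each mean.
    """

    genotype_id: str
    treatment: str
    dats: tuple[int, ...]
    means: tuple[float, ...]
    n_per_point: tuple[int, ...]

    def __post_init__(self):
        if not (len(self.dats) == len(self.means) == len(self.n_per_point)):
            raise ValidationError(
                "curve field lengths differ",
                {"invariant": "equal_lengths", "genotype": self.genotype_id},
            )
        d = np.asarray(self.dats)
        if len(d) and np.any(np.diff(d) <= 0):
            raise ValidationError(
                "dats must be strictly increasing",
                {"invariant": "dats_increasing", "genotype": self.genotype_id},
            )
        if any(n < 1 for n in self.n_per_point):
            raise ValidationError(
                "n_per_point must be >= 1",
                {"invariant": "n_per_point", "genotype": self.genotype_id},
            )

    def value_at(self, dat: int) -> float:
        """Mean value at a day; raises :class:`GridError` if off-grid."""
        try:
            i = self.dats.index(int(dat))
        except ValueError:
            raise GridError(
                f"DAT {dat} not on curve grid for {self.genotype_id}/{self.treatment}",
                {"dat": int(dat), "grid": list(self.dats)},
            ) from None
        return self.means[i]

    def as_series(self) -> pd.Series:
        return pd.Series(self.means, index=list(self.dats), name=self.genotype_id)


class TraitTable:
    """Validated long-format phenotype observations.

    Parameters
    ----------
    data : pandas.DataFrame
        Columns ``genotype, treatment, replicate, dat, trait, value``.
    grid : sequence of int, optional
        Declared imaging-day grid (strictly increasing).  Rows with a
        ``dat`` off this grid are rejected.
    validate : bool
        Skip validation only for internally-constructed tables.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        grid: Sequence[int] = DEFAULT_GRID,
        validate: bool = True,
    ):
        grid = tuple(int(d) for d in grid)
        if len(grid) and np.any(np.diff(np.asarray(grid)) <= 0):
            raise ValidationError(
                "grid must be strictly increasing", {"invariant": "grid_increasing"}
            )
        df = data.loc[:, list(COLUMNS)].copy()
        df["genotype"] = df["genotype"].astype(str)
        df["treatment"] = df["treatment"].astype(str)
        df["replicate"] = df["replicate"].astype(int)
        df["dat"] = df["dat"].astype(int)
        df["trait"] = df["trait"].astype(str)
        df["value"] = df["value"].astype(float)
        self.grid = grid
        self.data = df.reset_index(drop=True)
        if validate:
            self._validate()

    # -- validation -------------------------------------------------------

    def _validate(self) -> None:
        df = self.data
        bad_treat = set(df["treatment"]) - set(TREATMENTS)
        if bad_treat:
            raise ValidationError(
                f"unknown treatments {sorted(bad_treat)}",
                {"invariant": "treatment_enum", "values": sorted(bad_treat)},
            )
        if (df["replicate"] < 1).any():
            raise ValidationError(
                "replicate must be a positive integer",
                {"invariant": "replicate_positive"},
            )
        off = sorted(set(df["dat"]) - set(self.grid))
        if off:
            raise GridError(
                f"days {off} are off the declared grid",
                {"invariant": "dat_on_grid", "days": off},
            )
        dup = df.duplicated(subset=list(KEY_COLUMNS), keep=False)
        if dup.any():
            key = tuple(df.loc[dup.idxmax(), list(KEY_COLUMNS)])
            raise DuplicateKeyError(
                f"duplicate observation key {key}",
                {"invariant": "unique_key", "key": list(map(str, key))},
            )
        size = df["trait"].isin(SIZE_TRAITS)
        if (df.loc[size, "value"] <= 0).any():
            bad = df.loc[size & (df["value"] <= 0)].iloc[0]
            raise ValidationError(
                f"size trait {bad['trait']} has non-positive value "
                f"{bad['value']} at {tuple(bad[list(KEY_COLUMNS)])}",
                {"invariant": "size_positive", "trait": str(bad["trait"])},
            )
        if (~np.isfinite(df["value"])).any():
            raise ValidationError(
                "non-finite trait value", {"invariant": "finite_values"}
            )

    # -- accessors --------------------------------------------------------

    @property
    def traits(self) -> list[str]:
        return sorted(self.data["trait"].unique())

    @property
    def genotypes(self) -> list[str]:
        return sorted(self.data["genotype"].unique())

    @property
    def treatments(self) -> list[str]:
        present = set(self.data["treatment"].unique())
        return [t for t in TREATMENTS if t in present]

    def subset(self, trait: str | None = None, treatment: str | None = None) -> pd.DataFrame:
        df = self.data
        if trait is not None:
            if trait not in set(df["trait"]):
                raise UnknownTraitError(
                    f"trait {trait!r} not in table", {"trait": trait}
                )
            df = df[df["trait"] == trait]
        if treatment is not None:
            df = df[df["treatment"] == treatment]
        return df

    def __len__(self) -> int:
        return len(self.data)

    def equals(self, other: "TraitTable") -> bool:
        a = self.data.sort_values(list(KEY_COLUMNS)).reset_index(drop=True)
        b = other.data.sort_values(list(KEY_COLUMNS)).reset_index(drop=True)
        return a.equals(b) and self.grid == other.grid

    # -- IO ---------------------------------------------------------------

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)

    def write_schema(self, path: str | Path) -> None:
        """Emit a JSON sidecar describing the trait list and day grid."""
        schema = {
            "columns": list(COLUMNS),
            "grid": list(self.grid),
            "traits": self.traits,
            "treatments": self.treatments,
            "n_genotypes": len(self.genotypes),
        }
        Path(path).write_text(json.dumps(schema, indent=2) + "\n")


def read_trait_table(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    grid: Sequence[int] = DEFAULT_GRID,
) -> TraitTable:
    """Read and validate a long-format phenotype CSV.

    Parameters
    ----------
    path : path
        CSV with header ``genotype,treatment,replicate,dat,trait,value``
        (or the names given in ``schema``), UTF-8, '.' decimal separator.
    schema : mapping, optional
        Maps canonical column names to the file's column names, e.g.
        ``{"genotype": "line_id"}``.
    grid : sequence of int
        Declared imaging-day grid.

    Raises
    ------
    MissingColumnError
        Naming the first absent column.
    DuplicateKeyError
        Naming the offending key.
    ValidationError
        With row numbers for rows failing numeric parsing.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = pd.read_csv(path, dtype=str, encoding="utf-8")
    rename = {}
    schema = dict(schema or {})
    for canon in COLUMNS:
        src = schema.get(canon, canon)
        if src not in raw.columns:
            raise MissingColumnError(
                f"column {src!r} missing from {path.name}", {"column": src}
            )
        rename[src] = canon
    df = raw.rename(columns=rename).loc[:, list(COLUMNS)]

    bad_rows = []
    for col in ("replicate", "dat", "value"):
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = parsed.isna() & df[col].notna()
        # 1-based data rows (header is row 0)
        bad_rows.extend((int(i) + 1, col) for i in df.index[bad])
        df[col] = parsed
    if bad_rows:
        raise ValidationError(
            f"rows failed numeric parsing: {bad_rows[:10]}",
            {"invariant": "numeric_parse", "rows": bad_rows},
        )
    if df[["replicate", "dat", "value"]].isna().any().any():
        raise ValidationError(
            "missing numeric values", {"invariant": "no_missing_numeric"}
        )
    return TraitTable(df, grid=grid)


def write_trait_table(table: TraitTable, path: str | Path) -> None:
    """Write the canonical CSV (round-trips exactly through read)."""
    table.to_csv(path)


def genotype_means(table: TraitTable, trait: str) -> list[GrowthCurve]:
    """Replicate-mean trajectory per (genotype, treatment) for one trait.

    Means are taken over non-missing replicates at each day;
    ``n_per_point`` records how many replicates contributed.
    """
    df = table.subset(trait=trait)
    curves = []
    agg = (
        df.groupby(["genotype", "treatment", "dat"], sort=True)["value"]
        .agg(["mean", "count"])
        .reset_index()
    )
    for (g, t), grp in agg.groupby(["genotype", "treatment"], sort=True):
        grp = grp.sort_values("dat")
        curves.append(
            GrowthCurve(
                genotype_id=str(g),
                treatment=str(t),
                dats=tuple(int(d) for d in grp["dat"]),
                means=tuple(float(v) for v in grp["mean"]),
                n_per_point=tuple(int(n) for n in grp["count"]),
            )
        )
    return curves


def wide_matrix(
    curves: Iterable[GrowthCurve], treatment: str
) -> pd.DataFrame:
    """Genotype x day profile matrix for one treatment.

    Rows are sorted by genotype id; columns are the union of the curves'
    day grids (which must be mutually consistent).  A genotype missing a
    day gets NaN there — flagged, never imputed.

    Raises
    ------
    GridError
        If two curves disagree on the ordering of shared days.
    """
    rows = {}
    grid: list[int] = []
    for c in curves:
        if c.treatment != treatment:
            continue
        for d in c.dats:
            if d not in grid:
                grid.append(d)
        rows[c.genotype_id] = dict(zip(c.dats, c.means))
    if sorted(grid) != grid:
        raise GridError(
            "curves carry inconsistent day grids", {"invariant": "shared_grid"}
        )
    mat = pd.DataFrame(index=sorted(rows), columns=grid, dtype=float)
    for g, vals in rows.items():
        for d, v in vals.items():
            mat.loc[g, d] = v
    mat.index.name = "genotype"
    mat.columns.name = "dat"
    return mat


def curves_from_matrix(
    mat: pd.DataFrame, treatment: str, n_per_point: int = 1
) -> list[GrowthCurve]:
    """Inverse of :func:`wide_matrix` (NaN cells are dropped per curve)."""
    out = []
    for g, row in mat.iterrows():
        keep = row.notna()
        out.append(
            GrowthCurve(
                genotype_id=str(g),
                treatment=treatment,
                dats=tuple(int(d) for d in row.index[keep]),
                means=tuple(float(v) for v in row[keep]),
                n_per_point=(n_per_point,) * int(keep.sum()),
            )
        )
    return out
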