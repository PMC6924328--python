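"""Compound-list reduction and species-level profile aggregation.

Raw glucosinolate (GS) screens of leaf tissue typically detect more
chromatographic peaks than can be carried into statistics: some peaks
cannot be confirmed as GS, indistinguishable co-eluters must be pooled,
and very late eluters are likely dimers rather than distinct compounds.
This module applies those reduction rules to a flagged compound table and
then collapses a long-format concentration table (plant x compound, with
population and leaf-age structure) into a species x compound profile
matrix of mean concentrations in umol per g dry mass.

Aggregation conventions: replicate plants are averaged within a
(population, leaf-age) cell; populations are averaged with equal weight;
"all leaves" is the equal-weight mean of the young-leaf and old-leaf
species values. Compounds never detected in a species are explicit zeros
so that Euclidean profile distances are defined.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CompoundRecord",
    "read_compound_flags",
    "reduce_compound_list",
    "apply_compound_reduction",
    "read_concentration_table",
    "validate_concentration_table",
    "aggregate_profiles",
    "total_gs",
    "LEAF_AGES",
]

#: Recognised leaf strata in a concentration table.
LEAF_AGES = ("young", "old")

#: Default retention time (minutes) beyond which identified GS peaks are
#: treated as likely dimers and discarded.
DEFAULT_LATE_ELUTION_MIN = 30.0

CONCENTRATION_COLUMNS = [
    "species",
    "population",
    "leaf_age",
    "replicate",
    "compound",
    "concentration_umol_g",
]


@dataclass(frozen=True)
class CompoundRecord:
    """Flags attached to one detected chromatographic peak.

    Parameters
    ----------
    compound_id:
        Peak / compound label, unique within a screen.
    retention_time_min:
        HPLC retention time in minutes; must be nonnegative.
    identified_as_gs:
        Whether the peak could be confirmed as a glucosinolate.
    merge_group:
        Optional group label shared by co-eluting peaks whose mass
        spectra cannot be distinguished; members are summed downstream.
    """

    compound_id: str
    retention_time_min: float
    identified_as_gs: bool = True
    merge_group: str | None = None

    def __post_init__(self) -> None:
        if self.retention_time_min < 0:
            raise ValueError(
                f"retention_time_min must be >= 0, got {self.retention_time_min!r} "
                f"for compound {self.compound_id!r}"
            )


def read_compound_flags(path: str | Path) -> list[CompoundRecord]:
    """Read a compound-flag CSV (``compound,retention_time_min,identified_as_gs,merge_group,notes``)."""
    df = pd.read_csv(path, dtype={"compound": str, "merge_group": str})
    required = {"compound", "retention_time_min", "identified_as_gs"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"compound flag file missing columns: {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        mg = getattr(row, "merge_group", None)
        if mg is not None and (pd.isna(mg) or str(mg).strip() == ""):
            mg = None
        records.append(
            CompoundRecord(
                compound_id=str(row.compound),
                retention_time_min=float(row.retention_time_min),
                identified_as_gs=_as_bool(row.identified_as_gs),
                merge_group=None if mg is None else str(mg),
            )
        )
    return records


def _as_bool(value: object) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    text = str(value).strip().lower()
    if text in {"true", "t", "yes", "y", "1"}:
        return True
    if text in {"false", "f", "no", "n", "0"}:
        return False
    raise ValueError(f"cannot interpret {value!r} as a boolean flag")


def reduce_compound_list(
    records: Sequence[CompoundRecord],
    late_elution_min: float = DEFAULT_LATE_ELUTION_MIN,
) -> tuple[list[str], dict[str, list[str]]]:
    """Apply the discard/merge rules to a flagged compound list.

    Rules, in order: discard peaks not identified as GS; discard peaks
    eluting after ``late_elution_min`` minutes (likely dimers); collapse
    each merge group of indistinguishable co-eluters into a single
    compound whose concentration downstream is the sum of its members.

    Returns
    -------
    retained:
        Compound ids kept for analysis, in input order. A merge group
        appears once, at the position of its first member, under the id
        ``"member1+member2"``.
    merges:
        Mapping from each merged id to the list of member ids.

    Raises
    ------
    ValueError
        If a merge-group member carries a discard flag (contradictory
        flags), if ids are duplicated, or if a merge group has a single
        member.
    """
    if not records:
        raise ValueError("empty compound record list")
    ids = [r.compound_id for r in records]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate compound ids: {dupes}")

    groups: dict[str, list[CompoundRecord]] = {}
    for r in records:
        if r.merge_group is not None:
            groups.setdefault(r.merge_group, []).append(r)
    for name, members in groups.items():
        if len(members) < 2:
            raise ValueError(f"merge group {name!r} has a single member")
        for m in members:
            if not m.identified_as_gs:
                raise ValueError(
                    f"compound {m.compound_id!r} is in merge group {name!r} "
                    "but is not identified as GS (contradictory flags)"
                )
            if m.retention_time_min > late_elution_min:
                raise ValueError(
                    f"compound {m.compound_id!r} is in merge group {name!r} "
                    "but elutes after the dimer cutoff (contradictory flags)"
                )

    retained: list[str] = []
    merges: dict[str, list[str]] = {}
    seen_groups: set[str] = set()
    for r in records:
        if not r.identified_as_gs:
            continue
        if r.retention_time_min > late_elution_min:
            continue
        if r.merge_group is None:
            retained.append(r.compound_id)
        elif r.merge_group not in seen_groups:
            seen_groups.add(r.merge_group)
            members = [m.compound_id for m in groups[r.merge_group]]
            merged_id = "+".join(members)
            retained.append(merged_id)
            merges[merged_id] = members
    return retained, merges


def apply_compound_reduction(
    table: pd.DataFrame,
    retained: Sequence[str],
    merges: Mapping[str, Sequence[str]] | None = None,
) -> pd.DataFrame:
    """Restrict a concentration table to the retained compounds.

    Merge-group members are summed within each sample and relabelled with
    the merged id; compounds not in ``retained`` are dropped. Mass is
    conserved: the total over retained compounds equals the total over
    all contributing raw compounds.
    """
    validate_concentration_table(table)
    merges = dict(merges or {})
    member_to_merged = {m: merged for merged, members in merges.items() for m in members}
    out = table.copy()
    out["compound"] = out["compound"].map(lambda c: member_to_merged.get(c, c))
    out = out[out["compound"].isin(set(retained))]
    keys = ["species", "population", "leaf_age", "replicate", "compound"]
    out = (
        out.groupby(keys, as_index=False, sort=False)["concentration_umol_g"]
        .sum()
    )
    return out.reset_index(drop=True)


def read_concentration_table(path: str | Path) -> pd.DataFrame:
    """Read a long-format concentration CSV and validate it."""
    df = pd.read_csv(path, dtype={"species": str, "population": str, "compound": str})
    validate_concentration_table(df)
    return df


def validate_concentration_table(table: pd.DataFrame) -> None:
    missing = set(CONCENTRATION_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"concentration table missing columns: {sorted(missing)}")
    bad_age = set(table["leaf_age"].unique()) - set(LEAF_AGES)
    if bad_age:
        raise ValueError(f"unknown leaf_age values: {sorted(bad_age)} (expected {LEAF_AGES})")
    conc = table["concentration_umol_g"]
    if not np.isfinite(conc).all():
        raise ValueError("non-finite concentrations present")
    if (conc < 0).any():
        raise ValueError("negative concentrations present")
    keys = ["species", "population", "leaf_age", "replicate", "compound"]
    if table.duplicated(subset=keys).any():
        dupes = table[table.duplicated(subset=keys, keep=False)]
        raise ValueError(
            "duplicate (species, population, leaf_age, replicate, compound) rows:\n"
            f"{dupes.head(10)}"
        )


def aggregate_profiles(
    table: pd.DataFrame,
    retained: Sequence[str],
    leaf_age_mode: str = "all",
) -> pd.DataFrame:
    """Build the species x compound profile matrix of mean concentrations.

    ``table`` must already be restricted to the retained compounds (see
    :func:`apply_compound_reduction`). Per species the mean is taken over
    replicate plants within each (population, leaf_age) cell, then over
    populations with equal weight; for ``leaf_age_mode="all"`` the young
    and old species values are averaged with equal weight. Compounds
    absent from a species are explicit zeros.

    Returns a DataFrame indexed by species with one column per retained
    compound and ``.attrs["leaf_age_mode"]`` set.
    """
    if leaf_age_mode not in ("young", "old", "all"):
        raise ValueError(f"leaf_age_mode must be young/old/all, got {leaf_age_mode!r}")
    validate_concentration_table(table)
    extra = set(table["compound"].unique()) - set(retained)
    if extra:
        raise ValueError(
            f"table contains compounds outside the retained set: {sorted(extra)[:5]} ..."
            if len(extra) > 5
            else f"table contains compounds outside the retained set: {sorted(extra)}"
        )

    ages = LEAF_AGES if leaf_age_mode == "all" else (leaf_age_mode,)
    species = list(dict.fromkeys(table["species"]))
    per_age: list[pd.DataFrame] = []
    for age in ages:
        sub = table[table["leaf_age"] == age]
        present = set(sub["species"].unique())
        absent = [s for s in species if s not in present]
        if absent:
            raise ValueError(
                f"no {age!r}-leaf rows for species: {absent} (requested mode {leaf_age_mode!r})"
            )
        # mean over replicates within (species, population), dense over compounds
        cell = (
            sub.pivot_table(
                index=["species", "population"],
                columns="compound",
                values="concentration_umol_g",
                aggfunc="mean",
                fill_value=0.0,
            )
            .reindex(columns=list(retained), fill_value=0.0)
        )
        # equal-weight mean over populations
        per_age.append(cell.groupby(level="species").mean())
    matrix = sum(per_age) / len(per_age)
    matrix = matrix.reindex(index=species)
    matrix.index.name = "species"
    matrix.columns.name = "compound"
    matrix.attrs["leaf_age_mode"] = leaf_age_mode
    return matrix


def total_gs(data: pd.DataFrame) -> pd.Series:
    """Total GS concentration (umol/g), per sample or per species.

    For a long-format concentration table the total is per plant sample
    (species, population, leaf_age, replicate); for a profile matrix it
    is the per-species row sum.
    """
    if "concentration_umol_g" in data.columns:
        validate_concentration_table(data)
        keys = ["species", "population", "leaf_age", "replicate"]
        totals = data.groupby(keys, sort=False)["concentration_umol_g"].sum()
        totals.name = "total_gs_umol_g"
        return totals
    totals = data.sum(axis=1)
    totals.name = "total_gs_umol_g"
    return totals


def write_profile_csv(matrix: pd.DataFrame, path: str | Path) -> None:
    """Write a profile matrix as CSV (first column ``species``)."""
    matrix.to_csv(path, index_label="species")


def read_profile_csv(path: str | Path) -> pd.DataFrame:
    """Read a profile matrix CSV written by :func:`write_profile_csv`."""
    matrix = pd.read_csv(path, index_col="species")
    if (matrix.values < 0).any() or not np.isfinite(matrix.values).all():
        raise ValueError("profile matrix must be finite and nonnegative")
    matrix.columns.name = "compound"
    return matrix
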