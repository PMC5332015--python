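"""Well-table data model, plate layouts, and delimited-text readers/writers.

The well-table dialect mirrors the public RNAi-record convention for
384-well screens: one row per well per readout, identified by the six
minimal fields (``PlateID``, ``Well``, ``GeneSymbol``, ``EntrezID``,
``siRNAID``, ``WellAnno``) plus raw replicate values (``Rep1Value``,
``Rep2Value``) and, for the primary SMARTpool design, per-replicate cell
counts (``Rep1CellCount``, ``Rep2CellCount``).  Files are UTF-8 CSV with a
mandatory header row; row order carries no meaning.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    DuplicateWellError,
    LayoutCapacityError,
    LayoutValidationError,
    ScreenSchemaError,
    WellTableParseError,
)

# ---------------------------------------------------------------------------
# well addresses

ROW_LETTERS = "ABCDEFGHIJKLMNOP"
N_ROWS = 16
N_COLS = 24

#: canonical well annotation roles
SAMPLE = "sample"
EMPTY = "empty"
NTC_ROLES = ("NTC2", "NTC5")
NEGATIVE_CONTROL_ROLES = ("lipid", "NTC2", "NTC5", "Ppib")
POSITIVE_CONTROL_ROLES = ("Tlr4", "Myd88", "Irak1", "Ikbkg")
TRANSFECTION_QC_ROLES = ("siGFP", "noLPS")
#: fixed placement order for control roles in generated layouts
CONTROL_ROLES = (
    "lipid",
    "NTC2",
    "NTC5",
    "Ppib",
    "siGFP",
    "noLPS",
    "Tlr4",
    "Myd88",
    "Irak1",
    "Ikbkg",
)
ROLES = (SAMPLE,) + CONTROL_ROLES + (EMPTY,)

READOUTS = ("NFKB", "TNF")
DESIGNS = ("primary", "secondary")

#: lenient spellings seen in exported tables -> canonical role names
DEFAULT_ANNOTATION_ALIASES: Mapping[str, str] = {
    "Sample": "sample",
    "SAMPLE": "sample",
    "Mock": "lipid",
    "mock": "lipid",
    "Lipid": "lipid",
    "NTC": "NTC2",
    "ntc2": "NTC2",
    "ntc5": "NTC5",
    "PPIB": "Ppib",
    "ppib": "Ppib",
    "siGfp": "siGFP",
    "sigfp": "siGFP",
    "NoLPS": "noLPS",
    "nolps": "noLPS",
    "Empty": "empty",
    "EMPTY": "empty",
}


def parse_well(text: str) -> tuple[int, int]:
    """Parse ``'A1'`` or ``'A01'`` into 0-based row and 1-based column."""
    s = str(text).strip()
    if len(s) < 2 or s[0].upper() not in ROW_LETTERS:
        raise ValueError(f"invalid well address {text!r}")
    row = ROW_LETTERS.index(s[0].upper())
    try:
        col = int(s[1:])
    except ValueError as exc:
        raise ValueError(f"invalid well address {text!r}") from exc
    if not 1 <= col <= N_COLS:
        raise ValueError(f"well column out of range in {text!r}")
    return row, col


def format_well(row: int, col: int) -> str:
    """Canonical zero-padded form, ``A01`` ... ``P24``."""
    if not (0 <= row < N_ROWS and 1 <= col <= N_COLS):
        raise ValueError(f"well address out of range: row {row}, col {col}")
    return f"{ROW_LETTERS[row]}{col:02d}"


def all_addresses() -> list[str]:
    """All 384 canonical addresses in row-major order."""
    return [format_well(r, c) for r in range(N_ROWS) for c in range(1, N_COLS + 1)]


# ---------------------------------------------------------------------------
# plate layouts

PRIMARY_SAMPLE_COLUMNS = tuple(range(3, 23))
PRIMARY_CONTROL_COLUMNS = (1, 2, 23, 24)
SECONDARY_EMPTY_ROWS = ("A", "C", "O", "P")
SECONDARY_EMPTY_ROWS_SYMMETRIC = ("A", "B", "O", "P")
SECONDARY_EMPTY_COLUMNS = (1, 2, 22, 23, 24)
SECONDARY_CONTROL_COLUMNS = (11, 12, 13)

_GRID_CODES = {
    "sample": "S ",
    "empty": ". ",
    "lipid": "LI",
    "NTC2": "N2",
    "NTC5": "N5",
    "Ppib": "PP",
    "siGFP": "GF",
    "noLPS": "NL",
    "Tlr4": "T4",
    "Myd88": "M8",
    "Irak1": "I1",
    "Ikbkg": "IK",
}


@dataclasses.dataclass(frozen=True)
class PlateLayout:
    """Role assignment for every well of a 384-well plate.

    ``role_by_address`` maps every canonical address to a role; wells not
    usable in the design carry the role ``empty``.
    """

    design: str
    role_by_address: Mapping[str, str]

    @property
    def sample_addresses(self) -> list[str]:
        return sorted(
            (a for a, r in self.role_by_address.items() if r == SAMPLE),
            key=lambda a: (parse_well(a)[1], parse_well(a)[0]),
        )

    @property
    def control_addresses(self) -> list[str]:
        return sorted(
            a
            for a, r in self.role_by_address.items()
            if r not in (SAMPLE, EMPTY)
        )

    def addresses_for_role(self, role: str) -> list[str]:
        return sorted(a for a, r in self.role_by_address.items() if r == role)

    def to_grid(self) -> str:
        """16x24 text grid of two-character role codes, one row per line."""
        lines = []
        for r in range(N_ROWS):
            codes = [
                _GRID_CODES[self.role_by_address[format_well(r, c)]]
                for c in range(1, N_COLS + 1)
            ]
            lines.append(" ".join(codes))
        return "\n".join(lines)


def standard_layout(
    design: str,
    controls_per_role: int = 3,
    *,
    empty_rows: Sequence[str] = SECONDARY_EMPTY_ROWS,
) -> PlateLayout:
    """Deterministic standard layout for a screen design.

    Primary design: sample wells fill columns 3-22 (320 wells); controls
    occupy columns 1, 2, 23, 24 in the fixed role order of
    :data:`CONTROL_ROLES`, ``controls_per_role`` wells each, filled column
    by column from row A.  Secondary design: the outer rows given by
    ``empty_rows`` (by default A, C, O and P, as deposited; pass
    :data:`SECONDARY_EMPTY_ROWS_SYMMETRIC` for the symmetric variant) and
    columns 1, 2, 22, 23, 24 are left empty, with the three central
    columns 11-13 reserved for controls.  The two non-targeting control
    roles receive twice ``controls_per_role`` wells in the secondary
    design so that pooled-NTC statistics are well anchored.
    """
    if design not in DESIGNS:
        raise ValueError(f"unknown design {design!r}")
    if controls_per_role < 3:
        raise ValueError("controls_per_role must be at least 3")

    roles: dict[str, str] = {a: EMPTY for a in all_addresses()}
    if design == "primary":
        for c in PRIMARY_SAMPLE_COLUMNS:
            for r in range(N_ROWS):
                roles[format_well(r, c)] = SAMPLE
        slots = [
            format_well(r, c) for c in PRIMARY_CONTROL_COLUMNS for r in range(N_ROWS)
        ]
        wanted = [(role, controls_per_role) for role in CONTROL_ROLES]
    else:
        usable_rows = [i for i, L in enumerate(ROW_LETTERS) if L not in empty_rows]
        if len(usable_rows) != N_ROWS - len(empty_rows):
            raise ValueError(f"invalid empty_rows {empty_rows!r}")
        sample_cols = [
            c
            for c in range(1, N_COLS + 1)
            if c not in SECONDARY_EMPTY_COLUMNS and c not in SECONDARY_CONTROL_COLUMNS
        ]
        for c in sample_cols:
            for r in usable_rows:
                roles[format_well(r, c)] = SAMPLE
        slots = [
            format_well(r, c) for c in SECONDARY_CONTROL_COLUMNS for r in usable_rows
        ]
        wanted = [
            (role, 2 * controls_per_role if role in NTC_ROLES else controls_per_role)
            for role in CONTROL_ROLES
        ]

    needed = sum(n for _, n in wanted)
    if needed > len(slots):
        raise LayoutCapacityError(
            f"{needed} control wells requested but only {len(slots)} reserved "
            f"wells exist in the {design} design"
        )
    i = 0
    for role, n in wanted:
        for a in slots[i : i + n]:
            roles[a] = role
        i += n
    layout = PlateLayout(design=design, role_by_address=roles)
    validate_layout(layout, empty_rows=empty_rows)
    return layout


def validate_layout(
    layout: PlateLayout, *, empty_rows: Sequence[str] = SECONDARY_EMPTY_ROWS
) -> None:
    """Check the design invariants; raise :class:`LayoutValidationError`."""
    roles = layout.role_by_address
    if set(roles) != set(all_addresses()):
        raise LayoutValidationError("layout must cover exactly the 384 addresses")
    for a, role in roles.items():
        if role not in ROLES:
            raise LayoutValidationError(f"unknown role {role!r} at {a}")
        r, c = parse_well(a)
        if layout.design == "primary":
            if role == SAMPLE and c not in PRIMARY_SAMPLE_COLUMNS:
                raise LayoutValidationError(f"sample well outside columns 3-22: {a}")
            if role not in (SAMPLE, EMPTY) and c not in PRIMARY_CONTROL_COLUMNS:
                raise LayoutValidationError(f"control well outside 1,2,23,24: {a}")
        else:
            if role != EMPTY and (
                ROW_LETTERS[r] in empty_rows or c in SECONDARY_EMPTY_COLUMNS
            ):
                raise LayoutValidationError(f"non-empty well in reserved region: {a}")
            if role not in (SAMPLE, EMPTY) and c not in SECONDARY_CONTROL_COLUMNS:
                raise LayoutValidationError(f"control well outside columns 11-13: {a}")
            if role == SAMPLE and c in SECONDARY_CONTROL_COLUMNS:
                raise LayoutValidationError(f"sample well in control columns: {a}")
    for role in CONTROL_ROLES:
        n = sum(1 for v in roles.values() if v == role)
        if 0 < n < 3:
            raise LayoutValidationError(f"control role {role} has {n} wells (<3)")


# ---------------------------------------------------------------------------
# datasets

#: the six minimal record fields
CARD_FIELDS = ("PlateID", "Well", "GeneSymbol", "EntrezID", "siRNAID", "WellAnno")

PRIMARY_COLUMNS = (
    "PlateID",
    "Well",
    "WellAnno",
    "GeneSymbol",
    "EntrezID",
    "siRNAID",
    "Readout",
    "Rep1Value",
    "Rep2Value",
    "Rep1CellCount",
    "Rep2CellCount",
)
SECONDARY_COLUMNS = (
    "PlateID",
    "Well",
    "WellAnno",
    "GeneSymbol",
    "EntrezID",
    "siRNAID",
    "siRNAIndex",
    "Readout",
    "Rep1Value",
    "Rep2Value",
)
#: columns added by downstream stages, in emitted order
DERIVED_COLUMNS = (
    "NormRep1",
    "NormRep2",
    "ZscoreRep1",
    "ZscoreRep2",
    "Zscore",
    "Pvalue",
    "FractionNTCRep1",
    "FractionNTCRep2",
    "LowCellCount",
    "Group",
    "Selected",
    "ActivityScore",
    "ActivityOutcome",
)

_FLOAT_COLUMNS = (
    "Rep1Value",
    "Rep2Value",
    "NormRep1",
    "NormRep2",
    "ZscoreRep1",
    "ZscoreRep2",
    "Zscore",
    "Pvalue",
    "FractionNTCRep1",
    "FractionNTCRep2",
)
_INT_COLUMNS = (
    "EntrezID",
    "siRNAIndex",
    "Rep1CellCount",
    "Rep2CellCount",
    "ActivityScore",
    "ActivityOutcome",
)


def required_columns(design: str) -> tuple[str, ...]:
    base = CARD_FIELDS + ("Rep1Value", "Rep2Value")
    if design == "primary":
        return base + ("Rep1CellCount", "Rep2CellCount")
    return base


@dataclasses.dataclass
class ScreenDataset:
    """All well records of one screen, as a tidy per-well table.

    ``wells`` holds one row per (plate, well, readout).  Empty wells may be
    present (with missing values) or absent; they never contribute to any
    statistic.
    """

    wells: pd.DataFrame
    design: str

    def __post_init__(self) -> None:
        if self.design not in DESIGNS:
            raise ValueError(f"unknown design {self.design!r}")

    # -- accessors ---------------------------------------------------------
    @property
    def plate_ids(self) -> list[str]:
        return sorted(self.wells["PlateID"].unique())

    @property
    def readouts(self) -> list[str]:
        return sorted(self.wells["Readout"].unique())

    def nonempty(self) -> pd.DataFrame:
        return self.wells[self.wells["WellAnno"] != EMPTY]

    def sample_wells(self) -> pd.DataFrame:
        return self.wells[self.wells["WellAnno"] == SAMPLE]

    def wells_for_role(self, *roles: str) -> pd.DataFrame:
        return self.wells[self.wells["WellAnno"].isin(roles)]

    # -- validation --------------------------------------------------------
    def validate(self, strict: bool = False) -> None:
        """Check dataset invariants.

        Uniqueness of (plate, well, readout) is always enforced.  With
        ``strict=True`` additionally require both readouts on every plate
        and identity fields on all sample wells.
        """
        df = self.wells
        dup = df.duplicated(subset=["PlateID", "Well", "Readout"])
        if dup.any():
            row = df[dup].iloc[0]
            raise DuplicateWellError(
                f"duplicate well {row['PlateID']}/{row['Well']}/{row['Readout']}"
            )
        bad_roles = set(df["WellAnno"].unique()) - set(ROLES)
        if bad_roles:
            raise ScreenSchemaError(f"unknown WellAnno value(s): {sorted(bad_roles)}")
        ctrl = df[~df["WellAnno"].isin((SAMPLE, EMPTY))]
        if (ctrl["GeneSymbol"].fillna("") != "").any():
            raise ScreenSchemaError("control wells must not carry a GeneSymbol")
        if strict:
            per_plate = df.groupby("PlateID")["Readout"].nunique()
            missing = per_plate[per_plate < len(READOUTS)]
            if len(missing):
                raise ScreenSchemaError(
                    f"plate(s) missing a readout: {sorted(missing.index)}"
                )
            samples = self.sample_wells()
            for col in ("GeneSymbol", "siRNAID"):
                if (samples[col].fillna("") == "").any():
                    raise ScreenSchemaError(f"sample wells missing {col}")
            if samples["EntrezID"].isna().any():
                raise ScreenSchemaError("sample wells missing EntrezID")

    # -- comparison --------------------------------------------------------
    def canonical(self) -> pd.DataFrame:
        df = self.wells.sort_values(["Readout", "PlateID", "Well"], kind="mergesort")
        return df.reset_index(drop=True)

    def equals(self, other: "ScreenDataset") -> bool:
        if self.design != other.design:
            return False
        a, b = self.canonical(), other.canonical()
        if list(a.columns) != list(b.columns) or len(a) != len(b):
            return False
        for col in a.columns:
            if not a[col].equals(b[col]):
                return False
        return True

    def copy(self) -> "ScreenDataset":
        return ScreenDataset(self.wells.copy(), self.design)


def _coerce_types(df: pd.DataFrame) -> pd.DataFrame:
    for col in df.columns:
        if col in _FLOAT_COLUMNS:
            df[col] = df[col].astype(float)
        elif col in _INT_COLUMNS:
            df[col] = df[col].astype("Int64")
        elif col == "LowCellCount" or col == "Selected":
            df[col] = df[col].astype("boolean")
        elif df[col].dtype == object:
            df[col] = df[col].where(pd.notna(df[col]), pd.NA)
    return df


def new_dataset(records: Iterable[Mapping] | pd.DataFrame, design: str) -> ScreenDataset:
    """Build a validated dataset from a mapping iterable or DataFrame."""
    df = pd.DataFrame(records)
    base = PRIMARY_COLUMNS if design == "primary" else SECONDARY_COLUMNS
    for col in base:
        if col not in df.columns:
            df[col] = pd.NA
    order = [c for c in base + DERIVED_COLUMNS if c in df.columns]
    df = _coerce_types(df[order].copy())
    ds = ScreenDataset(df, design)
    ds.validate()
    return ds


def read_well_table(
    path,
    design: str,
    *,
    readout: str | None = None,
    aliases: Mapping[str, str] | None = None,
) -> ScreenDataset:
    """Read a delimited well table into a validated :class:`ScreenDataset`.

    Parameters
    ----------
    path:
        CSV file with a header row.
    design:
        ``"primary"`` or ``"secondary"``; controls which columns are
        required.
    readout:
        Readout label to assign when the file has no ``Readout`` column
        (single-readout exports).
    aliases:
        Extra ``WellAnno`` spellings mapped onto the canonical roles, on
        top of :data:`DEFAULT_ANNOTATION_ALIASES`.
    """
    if design not in DESIGNS:
        raise ValueError(f"unknown design {design!r}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in required_columns(design):
        if col not in df.columns:
            raise ScreenSchemaError(col)
    if "Readout" not in df.columns:
        if readout is None:
            raise ScreenSchemaError(
                "Readout (no Readout column and no readout= argument)"
            )
        df["Readout"] = readout
    bad_readout = set(df["Readout"].unique()) - set(READOUTS)
    if bad_readout:
        raise ScreenSchemaError(f"unknown Readout value(s): {sorted(bad_readout)}")

    alias_map = dict(DEFAULT_ANNOTATION_ALIASES)
    if aliases:
        alias_map.update(aliases)
    df["WellAnno"] = df["WellAnno"].map(lambda s: alias_map.get(s, s))
    unknown = set(df["WellAnno"].unique()) - set(ROLES)
    if unknown:
        raise ScreenSchemaError(f"unknown WellAnno value(s): {sorted(unknown)}")

    df["Well"] = [format_well(*parse_well(w)) for w in df["Well"]]

    nonempty = df["WellAnno"] != EMPTY
    numeric = [c for c in _FLOAT_COLUMNS + _INT_COLUMNS if c in df.columns]
    for col in numeric:
        raw = df[col].str.strip()
        vals = pd.to_numeric(raw.replace("", None), errors="coerce")
        bad = nonempty & (raw != "") & vals.isna()
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise WellTableParseError(
                f"non-numeric value {raw.iloc[i]!r} in column {col}, file row {i + 2}"
            )
        missing = nonempty & (raw == "")
        if col in ("Rep1Value", "Rep2Value") and missing.any():
            i = int(np.flatnonzero(missing.to_numpy())[0])
            raise WellTableParseError(
                f"missing {col} for non-empty well, file row {i + 2}"
            )
        if col in _FLOAT_COLUMNS:
            # exact strtod round-trip (to_numeric's fast parser is 1-ulp off)
            def _f(s):
                try:
                    return float(s) if s != "" else np.nan
                except ValueError:
                    return np.nan  # garbage in an empty well
            df[col] = np.array([_f(s) for s in raw], dtype=float)
        else:
            df[col] = vals
    for col in df.columns:
        if col not in numeric and col not in (
            "LowCellCount",
            "Selected",
        ):
            df[col] = df[col].replace("", pd.NA)
    for col in ("LowCellCount", "Selected"):
        if col in df.columns:
            df[col] = df[col].map(
                {"True": True, "False": False, "": pd.NA}
            )

    base = PRIMARY_COLUMNS if design == "primary" else SECONDARY_COLUMNS
    for col in base:
        if col not in df.columns:
            df[col] = pd.NA
    order = [c for c in base + DERIVED_COLUMNS if c in df.columns]
    df = _coerce_types(df[order].copy())
    ds = ScreenDataset(df, design)
    ds.validate()
    return ds


def write_well_table(ds: ScreenDataset, path, include_derived: bool = False) -> None:
    """Write the dataset as UTF-8 CSV in the fixed documented column order.

    Base columns follow :data:`PRIMARY_COLUMNS` / :data:`SECONDARY_COLUMNS`;
    with ``include_derived`` any present :data:`DERIVED_COLUMNS` are
    appended in that order.  Written files re-read to an equal dataset and
    rewriting a re-read file is byte-identical.
    """
    base = PRIMARY_COLUMNS if ds.design == "primary" else SECONDARY_COLUMNS
    cols = [c for c in base if c in ds.wells.columns]
    if include_derived:
        cols += [c for c in DERIVED_COLUMNS if c in ds.wells.columns]
    ds.wells.to_csv(path, index=False, columns=cols, lineterminator="\n")
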