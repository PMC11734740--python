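"""Reading, validating and writing tidy plate-screen tables.

The canonical on-disk format is a long (tidy) CSV/TSV with one row per
(well, channel) measurement and the columns

    plate_id, batch_id, replicate, row, col, role, gene, sirna_id,
    channel, value

Rows and columns are 0-based integers internally.  Readers additionally
accept plate-map conventions: row letters (``A`` = 0) and 1-based column
numbers.  Written files use row letters and 1-based columns, the way
bench scientists label 96-well plates, and round-trip losslessly through
:func:`read_plate_table`.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ROLES",
    "REQUIRED_COLUMNS",
    "PlateMeasurementSet",
    "HitTable",
    "SchemaError",
    "PlateValidationError",
    "read_plate_table",
    "write_plate_table",
    "write_hit_tables",
    "read_hit_tables",
]

ROLES = frozenset({"sample", "negative_control", "positive_control", "mock", "empty"})

REQUIRED_COLUMNS = (
    "plate_id",
    "batch_id",
    "replicate",
    "row",
    "col",
    "role",
    "gene",
    "sirna_id",
    "channel",
    "value",
)

#: Column order of the hit-summary CSV written by :func:`write_hit_tables`.
HIT_SUMMARY_COLUMNS = ("gene", "channel", "tier", "is_hit", "threshold_used")

#: Column order of the companion long pass-matrix CSV.
PASS_MATRIX_COLUMNS = ("gene", "channel", "tier", "sirna_id", "replicate", "score", "passed")


class SchemaError(ValueError):
    """A required column is missing or a schema flag is invalid."""


class PlateValidationError(ValueError):
    """The table violates a plate-data invariant (duplicates, ranges, roles)."""


def _row_letter(i: int) -> str:
    return string.ascii_uppercase[i]


def _parse_row(value: object, row_format: str) -> int:
    s = str(value).strip()
    if row_format == "auto":
        row_format = "letter" if s and s[0].isalpha() else "index0"
    if row_format == "letter":
        s = s.upper()
        if len(s) != 1 or s not in string.ascii_uppercase:
            raise PlateValidationError(f"cannot parse row letter {value!r}")
        return string.ascii_uppercase.index(s)
    i = int(s)
    if row_format == "index1":
        i -= 1
    if i < 0:
        raise PlateValidationError(f"row index {value!r} out of range")
    return i


def _parse_col(value: object, col_format: str) -> int:
    i = int(str(value).strip())
    if col_format == "index1":
        i -= 1
    if i < 0:
        raise PlateValidationError(f"column index {value!r} out of range")
    return i


@dataclass
class PlateMeasurementSet:
    """Tidy per-well screen measurements plus plate geometry.

    ``data`` holds one row per (well, channel) with the canonical columns;
    rows/cols are 0-based integers.  All plates in one set share geometry.
    """

    data: pd.DataFrame
    n_rows: int = 8
    n_cols: int = 12

    def __post_init__(self) -> None:
        self.validate()

    # -- structure -----------------------------------------------------
    @property
    def channels(self) -> list[str]:
        return sorted(self.data["channel"].unique())

    @property
    def plate_ids(self) -> list[str]:
        return sorted(self.data["plate_id"].unique())

    @property
    def replicates(self) -> list[int]:
        return sorted(self.data["replicate"].unique())

    def __len__(self) -> int:
        return len(self.data)

    def subset(self, **by: object) -> "PlateMeasurementSet":
        """Restrict to rows where each keyword column equals the given value."""
        mask = pd.Series(True, index=self.data.index)
        for col, val in by.items():
            mask &= self.data[col] == val
        return PlateMeasurementSet(self.data[mask].reset_index(drop=True),
                                   self.n_rows, self.n_cols)

    # -- validation ----------------------------------------------------
    def validate(self, percent_channels: set[str] | None = None) -> None:
        df = self.data
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"missing required column(s): {', '.join(missing)}")

        bad_roles = set(df["role"].unique()) - ROLES
        if bad_roles:
            raise PlateValidationError(f"unknown role(s): {sorted(bad_roles)}")

        if (df["row"].max() >= self.n_rows) or (df["col"].max() >= self.n_cols):
            raise PlateValidationError(
                f"well coordinates exceed the {self.n_rows}x{self.n_cols} geometry"
            )

        key = ["plate_id", "replicate", "row", "col", "channel"]
        dup = df.duplicated(subset=key)
        if dup.any():
            first = df.loc[dup.idxmax(), key].tolist()
            raise PlateValidationError(f"duplicate well measurement: {first}")

        samples = df[df["role"] == "sample"]
        if samples["gene"].isna().any() or samples["sirna_id"].isna().any():
            raise PlateValidationError("sample wells must carry gene and sirna_id")

        if percent_channels is None:
            percent_channels = set(df["channel"].unique()) - {"KILLING"}
        pct = df[df["channel"].isin(percent_channels) & df["value"].notna()]
        out = pct[(pct["value"] < 0) | (pct["value"] > 100)]
        if not out.empty:
            r = out.iloc[0]
            raise PlateValidationError(
                f"percent value {r['value']} outside [0, 100] at plate "
                f"{r['plate_id']} well ({r['row']}, {r['col']}) channel {r['channel']}"
            )

    def require_negative_controls(self, min_n: int = 2) -> None:
        """Assert every plate carries enough negative-control wells."""
        counts = (
            self.data[self.data["role"] == "negative_control"]
            .groupby("plate_id")["value"].size()
            .reindex(self.plate_ids, fill_value=0)
        )
        short = counts[counts < min_n]
        if not short.empty:
            raise PlateValidationError(
                f"plate(s) with < {min_n} negative controls: {list(short.index)}"
            )


@dataclass
class HitTable:
    """Per-gene, per-channel hit call with its justifying evidence.

    ``pass_matrix``/``score_matrix`` are (siRNA x replicate) arrays; the
    boolean ``is_hit`` must be re-derivable from ``pass_matrix`` under the
    tier's consensus rule.
    """

    gene: str
    channel: str
    tier: str  # primary | secondary | killing
    is_hit: bool
    pass_matrix: np.ndarray
    score_matrix: np.ndarray
    threshold_used: float
    sirna_ids: list[str] = field(default_factory=list)
    replicate_ids: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.pass_matrix = np.asarray(self.pass_matrix, dtype=bool)
        self.score_matrix = np.asarray(self.score_matrix, dtype=float)
        if self.pass_matrix.shape != self.score_matrix.shape:
            raise ValueError("pass_matrix and score_matrix shapes differ")
        if not self.sirna_ids:
            self.sirna_ids = [f"s{i + 1}" for i in range(self.pass_matrix.shape[0])]
        if not self.replicate_ids:
            self.replicate_ids = list(range(1, self.pass_matrix.shape[1] + 1))


def read_plate_table(
    path,
    schema: dict[str, str] | None = None,
    *,
    row_format: str = "auto",
    col_format: str = "index1",
    n_rows: int = 8,
    n_cols: int = 12,
    percent_channels: set[str] | None = None,
    sep: str | None = None,
) -> PlateMeasurementSet:
    """Read a long-format plate table (CSV/TSV) into a validated set.

    Parameters
    ----------
    schema
        Optional mapping from canonical column name to the column name used
        in the file, e.g. ``{"value": "percent_positive"}``.
    row_format
        ``"auto"`` (letters if alphabetic, else 0-based), ``"letter"``,
        ``"index0"`` or ``"index1"``.
    col_format
        ``"index1"`` (plate-map convention, default) or ``"index0"``.
    """
    if row_format not in {"auto", "letter", "index0", "index1"}:
        raise SchemaError(f"unknown row_format {row_format!r}")
    if col_format not in {"index0", "index1"}:
        raise SchemaError(f"unknown col_format {col_format!r}")

    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, dtype={"plate_id": str, "batch_id": str})

    schema = schema or {}
    rename = {src: canon for canon, src in schema.items()}
    df = df.rename(columns=rename)

    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")

    df = df.loc[:, list(REQUIRED_COLUMNS)].copy()
    df["row"] = [_parse_row(v, row_format) for v in df["row"]]
    df["col"] = [_parse_col(v, col_format) for v in df["col"]]
    df["replicate"] = df["replicate"].astype(int)
    df["value"] = df["value"].astype(float)
    df["gene"] = df["gene"].astype("string")
    df["sirna_id"] = df["sirna_id"].astype("string")

    pms = PlateMeasurementSet(df, n_rows=n_rows, n_cols=n_cols)
    pms.validate(percent_channels=percent_channels)
    return pms


def write_plate_table(pms: PlateMeasurementSet, path) -> None:
    """Write a measurement set as canonical CSV (row letters, 1-based cols)."""
    df = pms.data.copy()
    df["row"] = [_row_letter(i) for i in df["row"]]
    df["col"] = df["col"] + 1
    df.loc[:, list(REQUIRED_COLUMNS)].to_csv(path, index=False, float_format="%.12g")


def write_hit_tables(hits: list[HitTable], summary_path, pass_matrix_path) -> None:
    """Write hit calls as a tidy summary CSV plus a long pass-matrix CSV.

    One summary row per (gene, channel, tier); one pass-matrix row per
    (gene, channel, tier, siRNA, replicate).  Round-trips through
    :func:`read_hit_tables`.
    """
    if not hits:
        raise ValueError("refusing to write an empty hit table")

    summary_rows, pass_rows = [], []
    for h in hits:
        summary_rows.append(
            dict(gene=h.gene, channel=h.channel, tier=h.tier,
                 is_hit=h.is_hit, threshold_used=h.threshold_used)
        )
        for i, sirna in enumerate(h.sirna_ids):
            for j, rep in enumerate(h.replicate_ids):
                pass_rows.append(
                    dict(gene=h.gene, channel=h.channel, tier=h.tier,
                         sirna_id=sirna, replicate=rep,
                         score=h.score_matrix[i, j], passed=bool(h.pass_matrix[i, j]))
                )
    pd.DataFrame(summary_rows, columns=list(HIT_SUMMARY_COLUMNS)).to_csv(
        summary_path, index=False, float_format="%.12g")
    pd.DataFrame(pass_rows, columns=list(PASS_MATRIX_COLUMNS)).to_csv(
        pass_matrix_path, index=False, float_format="%.12g")


def read_hit_tables(summary_path, pass_matrix_path) -> list[HitTable]:
    """Inverse of :func:`write_hit_tables`."""
    summary = pd.read_csv(summary_path, dtype={"gene": str})
    passes = pd.read_csv(pass_matrix_path, dtype={"gene": str, "sirna_id": str})

    hits: list[HitTable] = []
    grouped = passes.groupby(["gene", "channel", "tier"], sort=False)
    for srow in summary.itertuples(index=False):
        block = grouped.get_group((srow.gene, srow.channel, srow.tier))
        sirnas = list(dict.fromkeys(block["sirna_id"]))
        reps = sorted(block["replicate"].unique())
        score = np.full((len(sirnas), len(reps)), np.nan)
        passed = np.zeros((len(sirnas), len(reps)), dtype=bool)
        si = {s: i for i, s in enumerate(sirnas)}
        ri = {r: j for j, r in enumerate(reps)}
        for row in block.itertuples(index=False):
            score[si[row.sirna_id], ri[row.replicate]] = row.score
            passed[si[row.sirna_id], ri[row.replicate]] = row.passed
        hits.append(
            HitTable(gene=srow.gene, channel=srow.channel, tier=srow.tier,
                     is_hit=bool(srow.is_hit), pass_matrix=passed,
                     score_matrix=score, threshold_used=float(srow.threshold_used),
                     sirna_ids=sirnas, replicate_ids=[int(r) for r in reps])
        )
    return hits
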