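"""Expression-panel container, I/O, normalization, and winter masking.

The central data structure is :class:`ExpressionPanel`: monthly relative
expression values keyed by ``(gene_id, individual_id, year, month)``.
Deciduous trees carry no leaves from November through May, so those months
hold no transcriptional signal; the analysis convention is to z-score each
(gene, individual) series from its growing-season observations and then set
every November--May value to exactly zero, yielding complete 12-month
calendar years per individual (24 points for a 2-year panel, 36 for 3 years).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Calendar months zeroed by the winter mask (inclusive November--May).
WINTER_MONTHS = frozenset({11, 12, 1, 2, 3, 4, 5})

#: Growing-season months carrying observed expression.
GROWING_MONTHS = (6, 7, 8, 9, 10)

_COLUMNS = ["gene_id", "individual_id", "year", "month", "value"]


class PanelFormatError(ValueError):
    """Malformed panel file: missing column, bad month, non-numeric value."""


class PanelIntegrityError(ValueError):
    """Structurally invalid panel: duplicate timestamps, gaps, bad state."""


@dataclass(frozen=True)
class ExpressionPanel:
    """Monthly expression series keyed by (gene, individual).

    Parameters
    ----------
    data :
        Long-format frame with columns ``gene_id, individual_id, year,
        month, value``, canonically sorted by (gene, individual, year,
        month).
    normalized :
        True once each (gene, individual) series has been z-scored.
    winter_masked :
        True once November--May values have been set to zero and missing
        winter months filled in.
    """

    data: pd.DataFrame
    normalized: bool = False
    winter_masked: bool = False

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in _COLUMNS if c not in df.columns]
        if missing:
            raise PanelFormatError(f"panel missing required columns: {missing}")
        if not df["month"].between(1, 12).all():
            bad = df.loc[~df["month"].between(1, 12), "month"].iloc[0]
            raise PanelFormatError(f"month out of range 1-12: {bad}")
        dup = df.duplicated(subset=["gene_id", "individual_id", "year", "month"])
        if dup.any():
            row = df.loc[dup, ["gene_id", "individual_id", "year", "month"]].iloc[0]
            raise PanelIntegrityError(
                f"duplicate timestamp for {tuple(row)}"
            )
        canon = df.sort_values(
            ["gene_id", "individual_id", "year", "month"], kind="mergesort"
        ).reset_index(drop=True)
        object.__setattr__(self, "data", canon[_COLUMNS])

    # ------------------------------------------------------------------ views
    @property
    def genes(self) -> list[str]:
        return sorted(self.data["gene_id"].unique())

    @property
    def individuals(self) -> list[str]:
        return sorted(self.data["individual_id"].unique())

    def n_points_per_individual(self) -> int:
        """Length of the (common) per-individual time axis."""
        counts = self.data.groupby(["gene_id", "individual_id"]).size()
        if counts.nunique() != 1:
            raise PanelIntegrityError(
                "individuals have differing time coverage: "
                f"{sorted(counts.unique())}"
            )
        return int(counts.iloc[0])

    def series(self, gene: str, individual: str) -> pd.Series:
        """One series ordered by time, indexed by (year, month)."""
        sub = self.data[
            (self.data["gene_id"] == gene)
            & (self.data["individual_id"] == individual)
        ]
        if sub.empty:
            raise KeyError(f"no records for gene={gene!r} individual={individual!r}")
        return pd.Series(
            sub["value"].to_numpy(),
            index=pd.MultiIndex.from_frame(sub[["year", "month"]]),
            name=f"{gene}/{individual}",
        )

    def segments(self, gene: str) -> dict[str, np.ndarray]:
        """Per-individual value arrays ordered by time, for one gene."""
        return {
            ind: self.series(gene, ind).to_numpy()
            for ind in self.individuals
        }

    def month_axis(self, individual: str) -> np.ndarray:
        """Calendar months (1-12) along one individual's time axis."""
        sub = self.data[self.data["individual_id"] == individual]
        gene0 = sub["gene_id"].iloc[0]
        sub = sub[sub["gene_id"] == gene0]
        return sub["month"].to_numpy()


def _require_numeric(df: pd.DataFrame, path: str) -> pd.DataFrame:
    vals = pd.to_numeric(df["value"], errors="coerce")
    if vals.isna().any():
        row = int(df.index[vals.isna()][0]) + 2  # 1-based + header line
        raise PanelFormatError(f"{path}: non-numeric value at line {row}")
    out = df.copy()
    out["value"] = vals.astype(float)
    for col, kind in [("year", int), ("month", int)]:
        try:
            out[col] = out[col].astype(kind)
        except (TypeError, ValueError) as exc:
            raise PanelFormatError(f"{path}: column {col} not integer") from exc
    return out


def read_panel(path, format: str = "long_tsv") -> ExpressionPanel:
    """Read an expression panel from disk.

    ``long_tsv``: tab-separated columns ``gene_id individual_id year month
    value``.  ``wide_csv``: one row per gene, header
    ``gene_id,<individual>:<YYYY-MM>,...``.
    """
    path = str(path)
    if format == "long_tsv":
        df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "individual_id": str})
        missing = [c for c in _COLUMNS if c not in df.columns]
        if missing:
            raise PanelFormatError(f"{path}: missing column(s) {missing}")
        df = _require_numeric(df, path)
    elif format == "wide_csv":
        wide = pd.read_csv(path, dtype={"gene_id": str})
        if "gene_id" not in wide.columns:
            raise PanelFormatError(f"{path}: missing column(s) ['gene_id']")
        records = []
        for col in wide.columns[1:]:
            try:
                ind, ym = col.split(":")
                year, month = ym.split("-")
                year, month = int(year), int(month)
            except ValueError as exc:
                raise PanelFormatError(
                    f"{path}: bad wide header {col!r}, expected <indiv>:<YYYY-MM>"
                ) from exc
            for g, v in zip(wide["gene_id"], wide[col]):
                records.append((g, ind, year, month, v))
        df = pd.DataFrame(records, columns=_COLUMNS)
        df = _require_numeric(df, path)
    else:
        raise ValueError(f"unknown panel format {format!r}")
    return ExpressionPanel(df)


def write_panel(panel: ExpressionPanel, path) -> None:
    """Write a panel as long TSV (full float precision round-trips)."""
    df = panel.data.copy()
    df["value"] = [repr(float(v)) for v in df["value"]]
    df.to_csv(str(path), sep="\t", index=False)


def panel_to_tsv(panel: ExpressionPanel) -> str:
    buf = io.StringIO()
    df = panel.data.copy()
    df["value"] = [repr(float(v)) for v in df["value"]]
    df.to_csv(buf, sep="\t", index=False)
    return buf.getvalue()


def normalize_panel(panel: ExpressionPanel) -> ExpressionPanel:
    """Z-score every (gene, individual) series to mean 0, sd 1 (ddof=1).

    Statistics are computed from the values present in the panel at call
    time: calling before :func:`apply_winter_mask` (the default pipeline
    order) normalizes from growing-season observations only, calling after
    includes the winter zeros.  A constant series cannot reach unit
    variance and raises.
    """
    df = panel.data.copy()
    out = []
    for (gene, ind), sub in df.groupby(["gene_id", "individual_id"], sort=False):
        vals = sub["value"].to_numpy(dtype=float)
        if len(vals) < 2:
            raise PanelIntegrityError(
                f"series ({gene}, {ind}) has fewer than 2 observations"
            )
        sd = vals.std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            raise PanelIntegrityError(
                f"constant series for ({gene}, {ind}): cannot normalize to sd=1"
            )
        sub = sub.copy()
        sub["value"] = (vals - vals.mean()) / sd
        out.append(sub)
    return ExpressionPanel(
        pd.concat(out, ignore_index=True),
        normalized=True,
        winter_masked=panel.winter_masked,
    )


def apply_winter_mask(panel: ExpressionPanel) -> ExpressionPanel:
    """Zero November--May and fill missing winter months with zero records.

    After masking, every individual covers all 12 months of every calendar
    year in its observed span, so a 2-year panel carries 24 points per
    series and a 3-year panel 36.  Masking twice is refused.
    """
    if panel.winter_masked:
        raise PanelIntegrityError("winter mask already applied")
    df = panel.data.copy()
    mask = df["month"].isin(WINTER_MONTHS)
    df.loc[mask, "value"] = 0.0

    fills = []
    for (gene, ind), sub in df.groupby(["gene_id", "individual_id"], sort=False):
        y0, y1 = int(sub["year"].min()), int(sub["year"].max())
        have = set(zip(sub["year"], sub["month"]))
        for year in range(y0, y1 + 1):
            for month in range(1, 13):
                if (year, month) in have:
                    continue
                if month not in WINTER_MONTHS:
                    raise PanelIntegrityError(
                        f"missing growing-season observation for ({gene}, {ind}) "
                        f"at {year}-{month:02d}; imputation is not supported"
                    )
                fills.append((gene, ind, year, month, 0.0))
    if fills:
        df = pd.concat(
            [df, pd.DataFrame(fills, columns=_COLUMNS)], ignore_index=True
        )
    return ExpressionPanel(df, normalized=panel.normalized, winter_masked=True)


@dataclass(frozen=True)
class InductionLabels:
    """Per-(individual, year) floral-induction labels.

    A year counts as a floral induction year when the following spring's
    proportion of reproductive buds exceeds 0.4 (strictly): induction
    precedes anthesis by one year.
    """

    entries: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["individual_id", "year", "induced", "flowering_proportion"]
        )
    )

    def __post_init__(self) -> None:
        req = {"individual_id", "year", "induced"}
        missing = req - set(self.entries.columns)
        if missing:
            raise PanelFormatError(f"labels missing columns: {sorted(missing)}")

    def lookup(self) -> dict[tuple[str, int], bool]:
        return {
            (str(r.individual_id), int(r.year)): bool(r.induced)
            for r in self.entries.itertuples()
        }


def read_labels(path) -> pd.DataFrame:
    """Read a flowering-intensity table: ``individual_id year proportion``."""
    df = pd.read_csv(str(path), sep="\t", dtype={"individual_id": str})
    missing = {"individual_id", "year", "proportion"} - set(df.columns)
    if missing:
        raise PanelFormatError(f"{path}: missing column(s) {sorted(missing)}")
    return df


__all__ = [
    "ExpressionPanel",
    "InductionLabels",
    "PanelFormatError",
    "PanelIntegrityError",
    "WINTER_MONTHS",
    "GROWING_MONTHS",
    "read_panel",
    "write_panel",
    "panel_to_tsv",
    "read_labels",
    "normalize_panel",
    "apply_winter_mask",
]
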