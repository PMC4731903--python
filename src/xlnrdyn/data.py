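"""Time-course containers and tidy-CSV input/output.

All expression data move through one long-format schema with columns
``gene, strain, xylose_mM, time_h, mean_expr, sd_expr, n_rep`` — the
replicate-averaged, reference-gene-normalized transcript levels of an
RT-qPCR time course. A converter from wide per-gene sheets (one column
per time point) is provided for externally formatted tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "TimeCourse",
    "SchemaError",
    "read_timecourses",
    "write_timecourses",
    "timecourses_to_frame",
    "group_by_gene",
    "wide_to_long",
]

TIDY_COLUMNS = ["gene", "strain", "xylose_mM", "time_h", "mean_expr", "sd_expr", "n_rep"]
STRAINS = ("Wt", "Mt")


class SchemaError(ValueError):
    """An input table violates the tidy time-course schema."""


@dataclass(frozen=True)
class TimeCourse:
    """One gene's normalized expression trajectory under one condition."""

    gene: str
    strain: str
    condition: float  # initial D-xylose, mM
    times: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    n_replicates: int = 3

    def __post_init__(self):
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "mean", np.asarray(self.mean, dtype=float))
        object.__setattr__(self, "sd", np.asarray(self.sd, dtype=float))
        if self.strain not in STRAINS:
            raise SchemaError(f"unknown strain {self.strain!r}")
        if self.condition <= 0:
            raise SchemaError("xylose condition must be positive (mM)")
        t = self.times
        if t.ndim != 1 or t.size < 2 or t[0] != 0 or np.any(np.diff(t) <= 0):
            raise SchemaError(
                f"{self.gene}: times must be strictly increasing and start at 0"
            )
        if self.mean.shape != t.shape or self.sd.shape != t.shape:
            raise SchemaError(f"{self.gene}: mean/sd length mismatch with times")
        if np.any(self.sd < 0):
            raise SchemaError(f"{self.gene}: negative sd")
        if int(self.n_replicates) < 1:
            raise SchemaError(f"{self.gene}: n_replicates must be >= 1")

    def __len__(self) -> int:
        return self.times.size


def timecourses_to_frame(tcs: Iterable[TimeCourse]) -> pd.DataFrame:
    rows = []
    for tc in tcs:
        for t, m, s in zip(tc.times, tc.mean, tc.sd):
            rows.append((tc.gene, tc.strain, tc.condition, t, m, s, tc.n_replicates))
    return pd.DataFrame(rows, columns=TIDY_COLUMNS)


def frame_to_timecourses(df: pd.DataFrame) -> list[TimeCourse]:
    missing = [c for c in TIDY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing columns: {missing}")
    bad = df[~df["strain"].isin(STRAINS)]
    if len(bad):
        raise SchemaError(
            f"unknown strain labels in rows {bad.index.tolist()[:5]}: "
            f"{sorted(bad['strain'].unique())}"
        )
    if (df["sd_expr"] < 0).any():
        rows = df.index[df["sd_expr"] < 0].tolist()[:5]
        raise SchemaError(f"negative sd_expr in rows {rows}")
    out = []
    for (gene, strain, cond), g in df.groupby(
        ["gene", "strain", "xylose_mM"], sort=True
    ):
        g = g.sort_values("time_h")
        if g["time_h"].duplicated().any():
            raise SchemaError(f"{gene}: duplicate time points")
        out.append(
            TimeCourse(
                gene=str(gene),
                strain=str(strain),
                condition=float(cond),
                times=g["time_h"].to_numpy(),
                mean=g["mean_expr"].to_numpy(),
                sd=g["sd_expr"].to_numpy(),
                n_replicates=int(g["n_rep"].iloc[0]),
            )
        )
    return out


def read_timecourses(path: str | Path) -> list[TimeCourse]:
    """Load a tidy time-course CSV into validated :class:`TimeCourse` objects."""
    return frame_to_timecourses(pd.read_csv(path))


def write_timecourses(tcs: Iterable[TimeCourse], path: str | Path) -> None:
    # 20-min sampling times are exact thirds; six decimals keep them round-trippable
    timecourses_to_frame(tcs).to_csv(path, index=False, float_format="%.6f")


def group_by_gene(
    tcs: Iterable[TimeCourse],
) -> dict[str, dict[float, TimeCourse]]:
    """Group one strain's courses as gene -> {condition_mM: TimeCourse}."""
    out: dict[str, dict[float, TimeCourse]] = {}
    for tc in tcs:
        out.setdefault(tc.gene, {})[tc.condition] = tc
    return out


def wide_to_long(
    wide: pd.DataFrame,
    strain: str,
    xylose_mM: float,
    sd_wide: pd.DataFrame | None = None,
    n_rep: int = 3,
) -> pd.DataFrame:
    """Convert a wide sheet (genes x time columns, in hours) to the tidy schema."""
    times = [float(c) for c in wide.columns]
    rows = []
    for gene, series in wide.iterrows():
        for j, t in enumerate(times):
            sd = float(sd_wide.loc[gene].iloc[j]) if sd_wide is not None else 0.0
            rows.append((str(gene), strain, xylose_mM, t, float(series.iloc[j]), sd, n_rep))
    return pd.DataFrame(rows, columns=TIDY_COLUMNS)
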