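"""Reading and writing score tables, instruments and reports.

All tabular formats are plain CSV/TSV with a period decimal separator.
Score tables use the header ``raw_score,logit,se``; item calibration files
use ``item,delta,tau_1,...`` with ragged rows allowed so items may differ
in their number of categories.
"""

from __future__ import annotations

import csv
import json
from importlib import resources
from pathlib import Path

import pandas as pd

from .benchmark import BenchmarkReport
from .pcm import Instrument, ItemCalibration
from .transform import ScoreLogitTable, TransformedTable

__all__ = [
    "read_score_table",
    "write_score_table",
    "write_transformed_table",
    "read_instrument",
    "write_benchmark_report",
    "load_ess_table",
    "load_ess_published",
]

_REQUIRED = ("raw_score", "logit", "se")


def _sep_for(path: Path, dialect: str | None) -> str:
    if dialect is not None:
        return {"csv": ",", "tsv": "\t"}[dialect]
    return "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","


def read_score_table(path: str | Path, dialect: str | None = None) -> ScoreLogitTable:
    """Load and validate a raw-score -> logit table from CSV/TSV.

    The file must carry the columns ``raw_score``, ``logit`` and ``se``;
    raw scores must run consecutively from 0 and logits must be strictly
    increasing.  Validation failures name the offending rows.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path, dialect))
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(
            f"{path}: missing required column(s) {missing}; found {list(df.columns)}"
        )
    for col in _REQUIRED:
        bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()].tolist()
        if bad:
            raise ValueError(f"{path}: non-numeric values in '{col}' at rows {bad}")
    try:
        return ScoreLogitTable.from_arrays(df["raw_score"], df["logit"], df["se"])
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc


def write_score_table(
    table: ScoreLogitTable, path: str | Path, dialect: str | None = None
) -> None:
    path = Path(path)
    table.to_dataframe().to_csv(path, sep=_sep_for(path, dialect), index=False)


def write_transformed_table(
    t: TransformedTable,
    path: str | Path,
    dialect: str | None = None,
    spec_path: str | Path | None = None,
) -> None:
    """Write a transformed table as CSV/TSV (full-precision machine output).

    Columns: ``raw_score, logit, se, new_location_real, new_location_int,
    new_se`` plus a 1-decimal display SE.  Optionally dump the resolved
    transformation (kind, s, m, wanted minimum) as JSON next to it.
    """
    path = Path(path)
    t.to_dataframe().to_csv(path, sep=_sep_for(path, dialect), index=False)
    if spec_path is not None:
        Path(spec_path).write_text(json.dumps(t.spec.to_dict(), indent=2) + "\n")


def write_benchmark_report(report: BenchmarkReport, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report.to_dict(), indent=2) + "\n")


def read_instrument(path: str | Path) -> Instrument:
    """Load item calibrations from ``item,delta,tau_1,...`` CSV (ragged ok)."""
    path = Path(path)
    items = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or len(header) < 3 or header[1].strip() != "delta":
            raise ValueError(
                f"{path}: expected header 'item,delta,tau_1,...', got {header}"
            )
        for lineno, row in enumerate(reader, start=2):
            cells = [c for c in (c.strip() for c in row) if c != ""]
            if not cells:
                continue
            if len(cells) < 3:
                raise ValueError(
                    f"{path}: line {lineno}: an item needs delta and >= 1 threshold"
                )
            try:
                delta = float(cells[1])
                taus = tuple(float(c) for c in cells[2:])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: non-numeric value") from exc
            try:
                items.append(ItemCalibration(delta=delta, thresholds=taus))
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from exc
    if not items:
        raise ValueError(f"{path}: no items found")
    return Instrument(tuple(items))


def _data_path(name: str):
    return resources.files("raschscale.data").joinpath(name)


def load_ess_table() -> ScoreLogitTable:
    """Packaged Epworth Sleepiness Scale calibration (25 scores, 0-24).

    Logit locations are the published values; the standard-error column
    carries working values reconstructed to be consistent with every
    published rendering of the table (see the package methods notes).
    """
    with resources.as_file(_data_path("ess_table1.csv")) as p:
        return read_score_table(p)


def load_ess_published() -> pd.DataFrame:
    """Published transformed ESS columns (six transformations).

    One row per raw score with integer location and 1-d.p. SE for the
    0-24, 0-10 and 0-100 user ranges and the LMD, SEM and LSD
    transformations — the reference surface for regression tests.
    """
    with resources.as_file(_data_path("ess_table1_published.csv")) as p:
        return pd.read_csv(p)
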