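"""Affine transformation of Rasch logit measures into user-friendly ranges.

A Rasch analysis locates each raw total score on an interval (logit) scale
together with a standard error.  Because the logit origin and unit are
arbitrary, locations may be mapped through any order-preserving affine map

    y = m + s * x

where ``s`` (the *spacing factor*) converts logit distances into new-scale
distances and ``m`` (the *location factor*) anchors the new minimum.
Standard errors transform as ``SE_y = s * SE_x``.

Besides fully user-defined ranges, three principled spacing factors are
supported, all functions of the maximum raw total score ``L``:

* ``LMD`` — least measurable difference, ``s = L/6``: roughly one new-scale
  integer per observable raw-score step.
* ``SEM`` — standard error of measurement, ``s = sqrt(L)/2.5``: one
  new-scale unit approximates one standard error, so +/- 2 units is an
  approximate 95% confidence interval.
* ``LSD`` — least significant difference, ``s = sqrt(L)/3.5``: the coarsest
  rescaling that does not discard valid information.

For ``L > 6`` these satisfy ``s_LMD > s_SEM > s_LSD``.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "TransformKind",
    "ScoreLogitRow",
    "ScoreLogitTable",
    "TransformSpec",
    "TransformedRow",
    "TransformedTable",
    "round_half_away",
    "logit_range",
    "spacing_factor",
    "location_factor",
    "transform_location",
    "transform_se",
    "transform_table",
]


class TransformKind(str, enum.Enum):
    """Which rule defines the spacing factor."""

    USER = "user"
    LMD = "lmd"
    SEM = "sem"
    LSD = "lsd"


def round_half_away(x: float) -> int:
    """Round to the nearest integer, ties away from zero.

    Python's built-in ``round`` uses banker's rounding; score tables in this
    field are conventionally rounded half away from zero (2.5 -> 3, -2.5 -> -3).
    """
    return int(math.floor(abs(x) + 0.5)) * (1 if x >= 0 else -1)


@dataclass(frozen=True)
class ScoreLogitRow:
    """One raw total score with its logit location and standard error."""

    raw_score: int
    logit: float
    se: float
    is_extreme: bool = False

    def __post_init__(self) -> None:
        if self.se <= 0 or not math.isfinite(self.se):
            raise ValueError(
                f"raw score {self.raw_score}: standard error must be a positive "
                f"finite number, got {self.se!r}"
            )
        if self.raw_score < 0:
            raise ValueError(f"raw score must be non-negative, got {self.raw_score}")


@dataclass(frozen=True)
class ScoreLogitTable:
    """Raw-score -> logit conversion table covering every score 0..L.

    The maximum raw total score ``L`` is taken with the minimum score set at
    0, so a complete table has exactly ``L + 1`` rows with strictly
    increasing logit locations.  Rows for raw scores 0 and L carry
    extrapolated (extreme-score) estimates; they are flagged ``is_extreme``.
    """

    rows: tuple[ScoreLogitRow, ...]

    def __post_init__(self) -> None:
        if len(self.rows) < 2:
            raise ValueError("a score-logit table needs at least 2 rows")
        scores = [r.raw_score for r in self.rows]
        if scores != list(range(len(self.rows))):
            raise ValueError(
                f"raw scores must be consecutive from 0, got {scores}"
            )
        logits = [r.logit for r in self.rows]
        for a, b, r in zip(logits, logits[1:], self.rows[1:]):
            if not b > a:
                raise ValueError(
                    f"logit locations must be strictly increasing; row for raw "
                    f"score {r.raw_score} has logit {b} <= previous {a}"
                )

    @property
    def L(self) -> int:
        """Maximum possible raw total score (minimum set at 0)."""
        return len(self.rows) - 1

    @property
    def logits(self) -> np.ndarray:
        return np.array([r.logit for r in self.rows])

    @property
    def ses(self) -> np.ndarray:
        return np.array([r.se for r in self.rows])

    @property
    def raw_scores(self) -> np.ndarray:
        return np.array([r.raw_score for r in self.rows])

    @classmethod
    def from_arrays(
        cls,
        raw_scores: Iterable[int],
        logits: Iterable[float],
        ses: Iterable[float],
        extreme_flags: Iterable[bool] | None = None,
    ) -> "ScoreLogitTable":
        raw = [int(r) for r in raw_scores]
        lg = [float(x) for x in logits]
        se = [float(x) for x in ses]
        if extreme_flags is None:
            top = max(raw) if raw else 0
            extreme_flags = [r == 0 or r == top for r in raw]
        rows = tuple(
            ScoreLogitRow(r, x, s, bool(e))
            for r, x, s, e in zip(raw, lg, se, extreme_flags)
        )
        return cls(rows)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "raw_score": self.raw_scores,
                "logit": self.logits,
                "se": self.ses,
            }
        )


def logit_range(table: ScoreLogitTable, include_extremes: bool = True) -> float:
    """Span of the logit locations (max minus min).

    By default the extrapolated extreme-score rows are included, as is
    conventional when the table anchors a published transformation.  Pass
    ``include_extremes=False`` to span only the directly estimable scores.
    """
    logits = table.logits
    if not include_extremes:
        mask = ~np.array([r.is_extreme for r in table.rows])
        if mask.sum() < 2:
            raise ValueError("fewer than 2 non-extreme rows; cannot form a range")
        logits = logits[mask]
    return float(logits.max() - logits.min())


def spacing_factor(
    kind: TransformKind | str,
    L: int | None = None,
    wanted_range: float | None = None,
    logit_range: float | None = None,
) -> float:
    """Spacing factor ``s`` for a transformation rule.

    ``LMD`` -> L/6, ``SEM`` -> sqrt(L)/2.5, ``LSD`` -> sqrt(L)/3.5; ``USER``
    -> wanted_range / logit_range.
    """
    kind = TransformKind(kind)
    if kind is TransformKind.USER:
        if wanted_range is None or logit_range is None:
            raise ValueError("USER spacing factor needs wanted_range and logit_range")
        if wanted_range <= 0:
            raise ValueError(f"wanted_range must be positive, got {wanted_range}")
        if logit_range <= 0:
            raise ValueError(f"logit_range must be positive, got {logit_range}")
        return wanted_range / logit_range
    if L is None or L <= 0:
        raise ValueError(f"{kind.value.upper()} spacing factor needs L >= 1, got {L}")
    if kind is TransformKind.LMD:
        return L / 6.0
    if kind is TransformKind.SEM:
        return math.sqrt(L) / 2.5
    return math.sqrt(L) / 3.5


def location_factor(wanted_min: float, logit_min: float, s: float) -> float:
    """Location factor ``m = wanted_min - logit_min * s``."""
    if s <= 0:
        raise ValueError(f"spacing factor must be positive, got {s}")
    return wanted_min - logit_min * s


@dataclass(frozen=True)
class TransformSpec:
    """A fully resolved transformation: ``y = m + s x``.

    ``s`` and ``m`` are carried at full floating precision; two-decimal
    values shown in rendered tables are display-only (rounding ``s`` before
    transforming does not reproduce published tables).
    """

    kind: TransformKind
    s: float
    m: float
    wanted_min: float = 0.0
    wanted_range: float | None = None

    def __post_init__(self) -> None:
        if self.s <= 0:
            raise ValueError(f"spacing factor must be positive, got {self.s}")
        if self.kind is TransformKind.USER and (
            self.wanted_range is None or self.wanted_range <= 0
        ):
            raise ValueError("USER transformations require a positive wanted_range")

    @classmethod
    def resolve(
        cls,
        table: ScoreLogitTable,
        kind: TransformKind | str,
        wanted_min: float = 0.0,
        wanted_range: float | None = None,
        include_extremes: bool = True,
    ) -> "TransformSpec":
        """Resolve ``s`` and ``m`` against a score-logit table.

        LMD/SEM/LSD modes take ``s`` from ``L`` alone; USER mode divides the
        wanted range by the table's logit range.  In every mode the new
        minimum defaults to 0.
        """
        kind = TransformKind(kind)
        rng = logit_range(table, include_extremes=include_extremes)
        s = spacing_factor(kind, L=table.L, wanted_range=wanted_range, logit_range=rng)
        logits = table.logits
        if not include_extremes:
            mask = ~np.array([r.is_extreme for r in table.rows])
            logits = logits[mask]
        m = location_factor(wanted_min, float(logits.min()), s)
        return cls(kind=kind, s=s, m=m, wanted_min=wanted_min, wanted_range=wanted_range)

    def to_dict(self) -> dict:
        return {
            "kind": self.kind.value,
            "s": self.s,
            "m": self.m,
            "wanted_min": self.wanted_min,
            "wanted_range": self.wanted_range,
        }


def transform_location(x: float, spec: TransformSpec) -> float:
    """New-scale location ``y = m + s x`` for a logit location ``x``."""
    return spec.m + spec.s * x


def transform_se(se_x: float, s: float) -> float:
    """New-scale standard error ``SE_y = s * SE_x``."""
    if se_x <= 0:
        raise ValueError(f"standard error must be positive, got {se_x}")
    if s <= 0:
        raise ValueError(f"spacing factor must be positive, got {s}")
    return s * se_x


@dataclass(frozen=True)
class TransformedRow:
    raw_score: int
    new_location_real: float
    new_location_int: int
    new_se: float


@dataclass(frozen=True)
class TransformedTable:
    """Result of applying one TransformSpec to a whole score-logit table."""

    source: ScoreLogitTable
    spec: TransformSpec
    rows: tuple[TransformedRow, ...] = field(default=())

    @property
    def int_locations(self) -> np.ndarray:
        return np.array([r.new_location_int for r in self.rows])

    @property
    def real_locations(self) -> np.ndarray:
        return np.array([r.new_location_real for r in self.rows])

    @property
    def new_ses(self) -> np.ndarray:
        return np.array([r.new_se for r in self.rows])

    @property
    def int_range(self) -> tuple[int, int]:
        ints = self.int_locations
        return int(ints.min()), int(ints.max())

    def to_dataframe(self) -> pd.DataFrame:
        """Machine-readable frame; SEs at full precision plus a 1-d.p. display column."""
        df = self.source.to_dataframe()
        df["new_location_real"] = self.real_locations
        df["new_location_int"] = self.int_locations
        df["new_se"] = self.new_ses
        df["new_se_1dp"] = [round_half_away(se * 10) / 10 for se in self.new_ses]
        return df


def transform_table(table: ScoreLogitTable, spec: TransformSpec) -> TransformedTable:
    """Transform every row of a score-logit table.

    Locations map through ``y = m + s x`` and are additionally rounded half
    away from zero into an integer column; standard errors are multiplied by
    ``s``.
    """
    rows = tuple(
        TransformedRow(
            raw_score=r.raw_score,
            new_location_real=transform_location(r.logit, spec),
            new_location_int=round_half_away(transform_location(r.logit, spec)),
            new_se=transform_se(r.se, spec.s),
        )
        for r in table.rows
    )
    return TransformedTable(source=table, spec=spec, rows=rows)
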