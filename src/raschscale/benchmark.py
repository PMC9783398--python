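"""Benchmark a user-defined transformation range against LMD/SEM/LSD references.

An integer range that is much wider than the least-measurable-difference
(LMD) range implies precision the instrument does not have; one narrower
than the least-significant-difference (LSD) range discards valid
information.  A user range is judged against the integer endpoint ranges of
the three reference transformations, and each transformation is checked for
whether every raw score keeps a distinct integer on the new scale.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass

from .transform import (
    ScoreLogitTable,
    TransformKind,
    TransformSpec,
    TransformedTable,
    transform_table,
)

__all__ = ["Verdict", "BenchmarkReport", "uniqueness_check", "benchmark_range", "adjust_lmd"]


class Verdict(str, enum.Enum):
    TOO_COARSE = "TOO_COARSE"
    ACCEPTABLE = "ACCEPTABLE"
    OVERPRECISE = "OVERPRECISE"


def uniqueness_check(t: TransformedTable) -> bool:
    """True iff every raw score maps to a distinct integer on the new scale."""
    ints = t.int_locations
    return len(set(ints.tolist())) == len(ints)


def _width(rng: tuple[int, int]) -> int:
    return rng[1] - rng[0]


@dataclass(frozen=True)
class BenchmarkReport:
    """Reference ranges, uniqueness flags and the verdict for a user range.

    Widths are compared on rounded integer endpoint ranges, matching how
    published tables present transformed scales (e.g. 0-34 vs 0-24 vs 0-12).
    Boundary equality with the LMD or LSD width counts as ACCEPTABLE: only a
    range strictly wider than the LMD is over-precise and only one strictly
    narrower than the LSD is too coarse.
    """

    user_range: tuple[int, int]
    lmd_range: tuple[int, int]
    sem_range: tuple[int, int]
    lsd_range: tuple[int, int]
    unique_integers: dict[str, bool]
    verdict: Verdict

    @property
    def margins(self) -> dict[str, int]:
        """Signed width margins of the user range against each reference."""
        uw = _width(self.user_range)
        return {
            "vs_lmd": uw - _width(self.lmd_range),
            "vs_sem": uw - _width(self.sem_range),
            "vs_lsd": uw - _width(self.lsd_range),
        }

    def to_dict(self) -> dict:
        return {
            "user": {"range": list(self.user_range), "unique": self.unique_integers["user"]},
            "lmd": {"range": list(self.lmd_range), "unique": self.unique_integers["lmd"]},
            "sem": {"range": list(self.sem_range), "unique": self.unique_integers["sem"]},
            "lsd": {"range": list(self.lsd_range), "unique": self.unique_integers["lsd"]},
            "margins": self.margins,
            "verdict": self.verdict.value,
        }

    def summary(self) -> str:
        lines = [
            f"user range : {self.user_range[0]}-{self.user_range[1]}"
            f" (unique integers: {self.unique_integers['user']})",
            f"LMD range  : {self.lmd_range[0]}-{self.lmd_range[1]}"
            f" (unique integers: {self.unique_integers['lmd']})",
            f"SEM range  : {self.sem_range[0]}-{self.sem_range[1]}",
            f"LSD range  : {self.lsd_range[0]}-{self.lsd_range[1]}",
            f"verdict    : {self.verdict.value}",
        ]
        return "\n".join(lines)


def benchmark_range(table: ScoreLogitTable, user_spec: TransformSpec) -> BenchmarkReport:
    """Judge a user transformation range against the LMD/SEM/LSD references.

    TOO_COARSE if the user integer range is narrower than the LSD range,
    OVERPRECISE if wider than the LMD range, otherwise ACCEPTABLE.  Only the
    range *width* matters; the wanted minimum does not affect the verdict.
    """
    user_t = transform_table(table, user_spec)
    refs = {
        kind.value: transform_table(
            table, TransformSpec.resolve(table, kind, wanted_min=user_spec.wanted_min)
        )
        for kind in (TransformKind.LMD, TransformKind.SEM, TransformKind.LSD)
    }
    uw = _width(user_t.int_range)
    if uw < _width(refs["lsd"].int_range):
        verdict = Verdict.TOO_COARSE
    elif uw > _width(refs["lmd"].int_range):
        verdict = Verdict.OVERPRECISE
    else:
        verdict = Verdict.ACCEPTABLE
    return BenchmarkReport(
        user_range=user_t.int_range,
        lmd_range=refs["lmd"].int_range,
        sem_range=refs["sem"].int_range,
        lsd_range=refs["lsd"].int_range,
        unique_integers={
            "user": uniqueness_check(user_t),
            "lmd": uniqueness_check(refs["lmd"]),
            "sem": uniqueness_check(refs["sem"]),
            "lsd": uniqueness_check(refs["lsd"]),
        },
        verdict=verdict,
    )


def adjust_lmd(
    table: ScoreLogitTable,
    bounds: tuple[float, float] | None = None,
    step: float | None = None,
    wanted_min: float = 0.0,
) -> TransformSpec:
    """LMD spacing factor, redefined if L/6 leaves duplicate integers.

    The working LMD factor is L/6, but instrument/person characteristics can
    require anything between L/9 and L/4 before each raw score keeps its own
    integer.  If L/6 already yields unique integers it is returned
    unchanged; otherwise the interval (default [L/9, L/4]) is scanned from
    the bottom on a grid (default step L/360) and the smallest passing
    factor is returned.  If no factor in bounds passes, a warning is issued
    and the upper bound L/4 is returned.
    """
    L = table.L
    if bounds is None:
        bounds = (L / 9.0, L / 4.0)
    if step is None:
        step = L / 360.0
    lo, hi = bounds
    if not (0 < lo < hi):
        raise ValueError(f"invalid bounds {bounds}")

    def _spec(s: float) -> TransformSpec:
        m = wanted_min - float(table.logits.min()) * s
        return TransformSpec(kind=TransformKind.LMD, s=s, m=m, wanted_min=wanted_min)

    default = _spec(spacing := L / 6.0)
    if lo <= spacing <= hi and uniqueness_check(transform_table(table, default)):
        return default

    s = lo
    while s <= hi + 1e-12:
        cand = _spec(s)
        if uniqueness_check(transform_table(table, cand)):
            return cand
        s += step
    warnings.warn(
        f"no spacing factor in [{lo:.4g}, {hi:.4g}] yields unique integers; "
        f"returning the upper bound L/4 = {hi:.4g}",
        stacklevel=2,
    )
    return _spec(hi)
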