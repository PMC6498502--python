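"""Two-list capture-recapture and multi-period splicing.

When only two lists overlap, the Lincoln–Petersen estimator predicts the
unseen count from the unmatched and matched counts, m_00 = x_10 x_01 / x_11.
A full-period death toll is then spliced from sub-periods estimated by
different means: a three-list model-averaged estimate where three lists
overlap, a raw single-source count where only one list reports (optionally
inflated by that source's estimated sensitivity), and a two-list estimate
where two lists overlap.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from ._util import round_half_up

__all__ = [
    "TwoListTable",
    "SpliceComponent",
    "SpliceResult",
    "petersen_m00",
    "chapman_m00",
    "splice_total",
]

_MODES = ("mse_estimate", "single_source", "two_list")


@dataclass(frozen=True)
class TwoListTable:
    """Overlap counts for two lists: both, first only, second only."""

    x_11: int
    x_10: int
    x_01: int

    def __post_init__(self) -> None:
        if min(self.x_11, self.x_10, self.x_01) < 0:
            raise ValueError("cell counts must be non-negative")

    @property
    def n_obs(self) -> int:
        return self.x_11 + self.x_10 + self.x_01


def petersen_m00(table: TwoListTable) -> float:
    """Lincoln–Petersen estimate of the unseen count, x_10 x_01 / x_11.

    Undefined when no individual appears on both lists; in that case the
    bias-corrected :func:`chapman_m00` remains usable.
    """
    if table.x_11 == 0:
        raise ZeroDivisionError(
            "Petersen estimator undefined with no overlap (x_11 = 0); "
            "consider chapman_m00"
        )
    return table.x_10 * table.x_01 / table.x_11


def chapman_m00(table: TwoListTable) -> float:
    """Chapman's small-sample bias-corrected unseen count,
    (x_10+x_11+1)(x_01+x_11+1)/(x_11+1) − 1 − n_obs, floored at zero.

    Converges to the Petersen value as counts grow."""
    n_hat = (table.x_10 + table.x_11 + 1) * (table.x_01 + table.x_11 + 1) / (
        table.x_11 + 1
    ) - 1
    return max(n_hat - table.n_obs, 0.0)


@dataclass(frozen=True)
class SpliceComponent:
    """One sub-period of the analysis window.

    ``value`` is the period's death count or estimate; ``sensitivity_factor``
    (required iff ``mode == "single_source"``) is the estimated completeness
    of the lone reporting source, used to inflate its raw count.
    """

    label: str
    mode: str
    value: float
    sensitivity_factor: float | None = None

    def __post_init__(self) -> None:
        if self.mode not in _MODES:
            raise ValueError(f"mode must be one of {_MODES}, got {self.mode!r}")
        if self.value < 0:
            raise ValueError("component value must be non-negative")
        if self.mode == "single_source":
            s = self.sensitivity_factor
            if s is None or not (0.0 < s <= 1.0):
                raise ValueError(
                    "single_source components need a sensitivity_factor in (0, 1]"
                )
        elif self.sensitivity_factor is not None:
            raise ValueError("sensitivity_factor is only valid for single_source mode")


@dataclass(frozen=True)
class SpliceResult:
    """Spliced totals: the raw sum (a minimum) and the sensitivity-adjusted
    sum. Rounded values follow the reporting convention; raw values are kept.
    """

    minimum_raw: float
    adjusted_raw: float
    components: tuple[SpliceComponent, ...]

    @property
    def minimum_total(self) -> int:
        return round_half_up(self.minimum_raw)

    @property
    def adjusted_total(self) -> int:
        return round_half_up(self.adjusted_raw)

    def __iter__(self):
        # allows `minimum, adjusted = splice_total(...)`
        return iter((self.minimum_total, self.adjusted_total))


def splice_total(components: Sequence[SpliceComponent]) -> SpliceResult:
    """Assemble the full-period total from sub-period components.

    The minimum total sums the raw counts/estimates; the adjusted total
    divides each single-source count by its sensitivity factor, treating
    that source's completeness as constant over its period.
    """
    if not components:
        raise ValueError("at least one component is required")
    minimum = sum(c.value for c in components)
    adjusted = sum(
        c.value / c.sensitivity_factor if c.mode == "single_source" else c.value
        for c in components
    )
    return SpliceResult(
        minimum_raw=float(minimum),
        adjusted_raw=float(adjusted),
        components=tuple(components),
    )
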