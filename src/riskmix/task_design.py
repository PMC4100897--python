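"""Lotteries, the Holt–Laury multiple price list, and choice-data containers.

The Holt–Laury (HL) multiple price list presents ten ordered binary choices
between a "safe" lottery A (prizes 2.00 / 1.60) and a "risky" lottery B
(prizes 3.85 / 0.10).  In row k the probability of the high prize is k/10 for
both options.  A subject with constant relative risk aversion (CRRA) r who
maximizes expected utility switches from A to B at the row whose indifference
point brackets r, so the switch row reveals an interval for r.

This module holds the immutable design objects (:class:`Lottery`,
:class:`LotteryPair`, :class:`MPLDesign`), the response containers
(:class:`ChoiceRecord`, :class:`ChoiceDataset`), the design constructor
:func:`build_hl_design`, expected values, the CRRA indifference points
(:func:`crra_crossover`), and CSV round-trip I/O.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .exceptions import DomainError, ValidationError

__all__ = [
    "RESPONSES",
    "Lottery",
    "LotteryPair",
    "MPLDesign",
    "ChoiceRecord",
    "ChoiceDataset",
    "build_hl_design",
    "expected_value",
    "crra_crossover",
    "design_table",
    "read_choice_csv",
    "write_choice_csv",
    "round_half_away",
]

#: Admissible response codes.
RESPONSES = ("A", "B", "INDIFFERENT")

#: Baseline HL prizes: (A high, A low, B high, B low), scale 1.
HL_PRIZES = (2.00, 1.60, 3.85, 0.10)

_PROB_TOL = 1e-12


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round with ties going away from zero (the convention of printed MPL tables)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class Lottery:
    """A finite-outcome money lottery: outcome probabilities and prizes."""

    probabilities: tuple[float, ...]
    prizes: tuple[float, ...]

    def __post_init__(self) -> None:
        probs = tuple(float(p) for p in self.probabilities)
        prizes = tuple(float(x) for x in self.prizes)
        object.__setattr__(self, "probabilities", probs)
        object.__setattr__(self, "prizes", prizes)
        if len(probs) != len(prizes) or len(probs) < 1:
            raise ValidationError(
                "probabilities and prizes must have equal length >= 1, "
                f"got {len(probs)} and {len(prizes)}"
            )
        if any(p < 0 or p > 1 for p in probs):
            raise ValidationError(f"probabilities must lie in [0, 1]: {probs}")
        if abs(sum(probs) - 1.0) > _PROB_TOL:
            raise ValidationError(f"probabilities must sum to 1: sum={sum(probs)!r}")
        if any(x <= 0 for x in prizes):
            raise ValidationError(f"prizes must be strictly positive: {prizes}")

    @property
    def n_outcomes(self) -> int:
        return len(self.prizes)


@dataclass(frozen=True)
class LotteryPair:
    """One MPL row: option A vs option B, with its row index and payout scale."""

    option_a: Lottery
    option_b: Lottery
    row_index: int
    scale: float = 1.0

    def __post_init__(self) -> None:
        if not (1 <= self.row_index <= 10):
            raise ValidationError(f"row_index must be in 1..10, got {self.row_index}")
        if self.scale <= 0:
            raise ValidationError(f"scale must be positive, got {self.scale}")

    @property
    def all_prizes(self) -> tuple[float, ...]:
        return self.option_a.prizes + self.option_b.prizes


@dataclass(frozen=True)
class MPLDesign:
    """An ordered 10-row multiple price list at one payout scale."""

    pairs: tuple[LotteryPair, ...]
    scale: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "pairs", tuple(self.pairs))
        if len(self.pairs) != 10:
            raise ValidationError(f"an MPL design has exactly 10 rows, got {len(self.pairs)}")
        for k, pair in enumerate(self.pairs, start=1):
            if pair.row_index != k:
                raise ValidationError(f"pair at position {k} has row_index {pair.row_index}")

    def pair(self, row_index: int) -> LotteryPair:
        if not (1 <= row_index <= 10):
            raise ValidationError(f"row_index must be in 1..10, got {row_index}")
        return self.pairs[row_index - 1]


@dataclass(frozen=True)
class ChoiceRecord:
    """One observed response: subject, task (design), row and choice."""

    subject_id: str
    task_id: str
    row_index: int
    response: str

    def __post_init__(self) -> None:
        if self.response not in RESPONSES:
            raise ValidationError(
                f"response must be one of {RESPONSES}, got {self.response!r}"
            )


@dataclass
class ChoiceDataset:
    """A set of choice records plus the registry of designs they refer to."""

    records: list[ChoiceRecord]
    designs: Mapping[str, MPLDesign]

    def __post_init__(self) -> None:
        self.records = list(self.records)
        self.designs = dict(self.designs)
        self.validate()

    def validate(self) -> None:
        if not self.records:
            raise ValidationError("dataset has no records")
        seen: set[tuple[str, str, int]] = set()
        for i, rec in enumerate(self.records):
            if rec.task_id not in self.designs:
                raise ValidationError(
                    f"record {i}: task_id {rec.task_id!r} has no registered design"
                )
            self.designs[rec.task_id].pair(rec.row_index)  # raises if out of range
            key = (rec.subject_id, rec.task_id, rec.row_index)
            if key in seen:
                raise ValidationError(f"duplicate (subject, task, row) triple {key}")
            seen.add(key)

    @property
    def n_records(self) -> int:
        return len(self.records)

    @property
    def subjects(self) -> list[str]:
        out: list[str] = []
        seen: set[str] = set()
        for rec in self.records:
            if rec.subject_id not in seen:
                seen.add(rec.subject_id)
                out.append(rec.subject_id)
        return out

    @property
    def n_clusters(self) -> int:
        return len(set(r.subject_id for r in self.records))

    def cluster_sizes(self) -> dict[str, int]:
        sizes: dict[str, int] = {}
        for rec in self.records:
            sizes[rec.subject_id] = sizes.get(rec.subject_id, 0) + 1
        return sizes

    def pair_for(self, record: ChoiceRecord) -> LotteryPair:
        return self.designs[record.task_id].pair(record.row_index)

    def subset(self, subject_ids: Iterable[str]) -> "ChoiceDataset":
        keep = set(subject_ids)
        return ChoiceDataset(
            records=[r for r in self.records if r.subject_id in keep],
            designs=self.designs,
        )

    def drop_subject(self, subject_id: str) -> "ChoiceDataset":
        return ChoiceDataset(
            records=[r for r in self.records if r.subject_id != subject_id],
            designs=self.designs,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": [r.subject_id for r in self.records],
                "task_id": [r.task_id for r in self.records],
                "row_index": [r.row_index for r in self.records],
                "response": [r.response for r in self.records],
            }
        )


def build_hl_design(scale: float = 1.0) -> MPLDesign:
    """Construct the 10-row HL price list with all prizes multiplied by ``scale``.

    Row k offers the high prize of each option with probability k/10; row 10
    is degenerate (the high prize is certain).
    """
    if scale <= 0:
        raise DomainError(f"scale must be positive, got {scale}")
    a_hi, a_lo, b_hi, b_lo = (x * scale for x in HL_PRIZES)
    pairs = []
    for k in range(1, 11):
        p = k / 10.0
        if k == 10:
            opt_a = Lottery((1.0,), (a_hi,))
            opt_b = Lottery((1.0,), (b_hi,))
        else:
            opt_a = Lottery((p, 1.0 - p), (a_hi, a_lo))
            opt_b = Lottery((p, 1.0 - p), (b_hi, b_lo))
        pairs.append(LotteryPair(opt_a, opt_b, row_index=k, scale=scale))
    return MPLDesign(pairs=tuple(pairs), scale=scale)


def expected_value(lottery: Lottery) -> float:
    """Expected money value of a lottery, sum of p_i * x_i."""
    return float(np.dot(lottery.probabilities, lottery.prizes))


def _crra_norm(x: float, r: float) -> float:
    # normalized CRRA (x^(1-r) - 1)/(1-r); continuous through r = 1
    if abs(1.0 - r) < 1e-9:
        return math.log(x)
    return (x ** (1.0 - r) - 1.0) / (1.0 - r)


def _eu_norm(lottery: Lottery, r: float) -> float:
    return sum(p * _crra_norm(x, r) for p, x in zip(lottery.probabilities, lottery.prizes))


def crra_crossover(
    pair: LotteryPair, lo: float = -5.0, hi: float = 5.0, xtol: float = 1e-10
) -> float:
    """CRRA coefficient at which an expected-utility agent is indifferent in this row.

    Solves EU_A(r) = EU_B(r) by bracketed bisection on the normalized CRRA
    utility (x^(1-r) - 1)/(1-r), which is continuous through r = 1 and shares
    its indifference points with the unnormalized form.  Returns ``math.inf``
    when option B dominates for every r in the bracket (the degenerate last
    row, where the B prize simply exceeds the A prize).
    """

    def f(r: float) -> float:
        return _eu_norm(pair.option_a, r) - _eu_norm(pair.option_b, r)

    f_lo, f_hi = f(lo), f(hi)
    if f_lo * f_hi > 0:
        grid = np.linspace(lo, hi, 41)
        if all(f(r) < 0 for r in grid):
            return math.inf
        raise DomainError(
            f"no sign change for row {pair.row_index} in [{lo}, {hi}] "
            "and option B does not dominate"
        )
    return float(brentq(f, lo, hi, xtol=xtol))


def design_table(design: MPLDesign) -> pd.DataFrame:
    """The printed form of an MPL design: probabilities, prizes, EVs, crossovers.

    Crossover values are rounded half-away-from-zero to 2 decimals; the
    degenerate last row reports ``inf``.
    """
    rows = []
    for pair in design.pairs:
        a, b = pair.option_a, pair.option_b
        p_hi = a.probabilities[0]
        cross = crra_crossover(pair)
        rows.append(
            {
                "row": pair.row_index,
                "p_high": p_hi,
                "a_high": a.prizes[0],
                "a_low": a.prizes[1] if a.n_outcomes > 1 else a.prizes[0],
                "b_high": b.prizes[0],
                "b_low": b.prizes[1] if b.n_outcomes > 1 else b.prizes[0],
                "ev_a": expected_value(a),
                "ev_b": expected_value(b),
                "ev_diff": expected_value(a) - expected_value(b),
                "crossover": math.inf if math.isinf(cross) else round_half_away(cross, 2),
            }
        )
    return pd.DataFrame(rows)


_CSV_COLUMNS = ["subject_id", "task_id", "row_index", "response"]


def write_choice_csv(dataset: ChoiceDataset, path: str | Path) -> None:
    """Write the records of a dataset as a comma-delimited text file."""
    dataset.to_frame().to_csv(path, index=False)


def read_choice_csv(
    path: str | Path, designs: Mapping[str, MPLDesign] | None = None
) -> ChoiceDataset:
    """Read a choice CSV into a validated :class:`ChoiceDataset`.

    ``designs`` maps each task_id to its MPL design; if omitted, task ids
    ``low`` and ``high`` are resolved to the scale-1 and scale-5 HL designs.
    """
    df = pd.read_csv(path, dtype={"subject_id": str, "task_id": str})
    missing = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"choice CSV {path} is missing columns {missing}")
    if designs is None:
        designs = default_design_registry()
    records = []
    for i, row in enumerate(df.itertuples(index=False)):
        resp = str(row.response)
        if resp not in RESPONSES:
            raise ValidationError(
                f"line {i + 2} of {path}: unknown response code {resp!r} "
                f"(admissible: {RESPONSES})"
            )
        records.append(
            ChoiceRecord(
                subject_id=str(row.subject_id),
                task_id=str(row.task_id),
                row_index=int(row.row_index),
                response=resp,
            )
        )
    return ChoiceDataset(records=records, designs=designs)


def default_design_registry() -> dict[str, MPLDesign]:
    """The study's two tasks: the baseline list and the list scaled up by five."""
    return {"low": build_hl_design(1.0), "high": build_hl_design(5.0)}
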