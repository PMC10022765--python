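"""Best-worst choice-task designs over pairs of instrument dimensions.

Each choice-task shows three options; an option combines one level from each
of two fixed dimensions (e.g. "A3+B1").  Under the default *anti-chain* rule
the three options trade the two dimensions off against each other: levels
strictly increase in one dimension while strictly decreasing in the other, so
no option dominates another a priori.
"""

from __future__ import annotations

import itertools
import logging
import random
from dataclasses import dataclass, field

from .instrument import Instrument

__all__ = ["ChoiceTask", "DesignBlock", "generate_tasks", "allocate_blocks"]

logger = logging.getLogger(__name__)


class DesignError(ValueError):
    """Infeasible design request."""


@dataclass(frozen=True)
class ChoiceTask:
    """Three options over one pair of dimensions.

    Each option is an ordered pair of element codes, one per dimension of
    ``dimension_pair``.
    """

    task_id: str
    dimension_pair: tuple[str, str]
    options: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if len(self.options) != 3:
            raise DesignError(f"task {self.task_id}: need exactly 3 options")
        if len(set(self.options)) != 3:
            raise DesignError(f"task {self.task_id}: options must be distinct")
        for opt in self.options:
            if len(opt) != 2:
                raise DesignError(f"task {self.task_id}: options are element pairs")
        # no two options may share both coordinates (distinctness) and each
        # option's elements must come from the task's two dimensions
        for a, b in self.options:
            if a[0] != self.dimension_pair[0] or b[0] != self.dimension_pair[1]:
                raise DesignError(
                    f"task {self.task_id}: option ({a},{b}) not drawn from "
                    f"dimensions {self.dimension_pair}"
                )


@dataclass(frozen=True)
class DesignBlock:
    """One respondent group's set of tasks, with per-block option orders."""

    block_id: int
    task_ids: tuple[str, ...]
    option_orders: dict[str, tuple[int, int, int]] = field(default_factory=dict)


def _antichain_triples(levels_a: tuple[str, ...], levels_b: tuple[str, ...]):
    """Strictly increasing in A, strictly decreasing in B (3 distinct each)."""
    for sub_a in itertools.combinations(levels_a, 3):
        for sub_b in itertools.combinations(levels_b, 3):
            yield tuple(zip(sub_a, sub_b[::-1]))


def _antichain_triples_fallback(levels_a, levels_b):
    """B side has only 2 levels: allow one repeated level on that side."""
    for sub_a in itertools.combinations(levels_a, 3):
        for hi, lo in itertools.combinations(levels_b[::-1], 2):
            for pattern in ((hi, hi, lo), (hi, lo, lo)):
                yield tuple(zip(sub_a, pattern))


def generate_tasks(instrument: Instrument, rule: str = "antichain") -> list[ChoiceTask]:
    """Enumerate choice-tasks for every unordered pair of dimensions.

    ``rule='antichain'`` produces, per dimension pair, one task for every way
    of choosing 3 levels on each side paired in reversed order (the published
    example task (A3,B1),(A2,B2),(A1,B3) is of this form).  A dimension with
    only 2 levels cannot contribute 3 distinct levels; the rule then permits a
    single repeated level on that side, which is logged.
    """
    if rule != "antichain":
        raise DesignError(f"unknown design rule {rule!r}")
    if len(instrument.dimensions) < 2:
        raise DesignError("need at least 2 dimensions to form choice-tasks")
    tasks: list[ChoiceTask] = []
    counter = itertools.count(1)
    for dim_a, dim_b in itertools.combinations(instrument.dimensions, 2):
        la, lb = dim_a.level_codes, dim_b.level_codes
        if len(la) >= 3 and len(lb) >= 3:
            triples = _antichain_triples(la, lb)
        elif len(la) >= 3:
            logger.warning(
                "dimension %s has <3 levels; allowing one repeated level", dim_b.code
            )
            triples = _antichain_triples_fallback(la, lb)
        elif len(lb) >= 3:
            logger.warning(
                "dimension %s has <3 levels; allowing one repeated level", dim_a.code
            )
            triples = (
                tuple((a, b) for b, a in t)
                for t in _antichain_triples_fallback(lb, la)
            )
            # swap back to (dim_a, dim_b) coordinate order
            triples = [tuple((opt[0], opt[1]) for opt in t) for t in triples]
        else:
            logger.warning(
                "pair (%s,%s): both dimensions have <3 levels; skipped",
                dim_a.code,
                dim_b.code,
            )
            continue
        for t in triples:
            tasks.append(
                ChoiceTask(
                    task_id=f"T{next(counter):03d}",
                    dimension_pair=(dim_a.code, dim_b.code),
                    options=tuple(t),
                )
            )
    return tasks


def allocate_blocks(
    tasks: list[ChoiceTask],
    n_blocks: int,
    tasks_per_block: int,
    n_common: int = 0,
    seed: int = 0,
    partition: bool = True,
) -> list[DesignBlock]:
    """Randomly allocate tasks to respondent blocks.

    ``n_common`` tasks are shown to every block; the remainder of each block
    is drawn from the other tasks.  In partition mode (default) the
    non-common picks are disjoint across blocks, e.g. 86 tasks split as
    2 common + 3x28.  Allocation and per-block option order are reproducible
    from ``seed``.
    """
    n_tasks = len(tasks)
    per_block_extra = tasks_per_block - n_common
    if per_block_extra < 0:
        raise DesignError("n_common exceeds tasks_per_block")
    needed = n_common + (n_blocks * per_block_extra if partition else per_block_extra)
    if needed > n_tasks:
        raise DesignError(
            f"need at least {needed} tasks for {n_blocks} blocks of "
            f"{tasks_per_block} with {n_common} common (have {n_tasks})"
        )
    rng = random.Random(seed)
    ids = [t.task_id for t in tasks]
    common = rng.sample(ids, n_common)
    others = [i for i in ids if i not in common]
    rng.shuffle(others)
    blocks = []
    for b in range(n_blocks):
        if partition:
            extra = others[b * per_block_extra : (b + 1) * per_block_extra]
        else:
            extra = rng.sample(others, per_block_extra)
        task_ids = tuple(common + extra)
        orders = {
            tid: tuple(rng.sample(range(3), 3)) for tid in task_ids
        }
        blocks.append(DesignBlock(block_id=b + 1, task_ids=task_ids, option_orders=orders))
    return blocks
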