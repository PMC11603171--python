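"""Block-level scoring of keypress streams.

Operationalization: accuracy is correct presses / total presses and speed
is correct presses per second.  Press-level ratios are well-defined for
partial sequences and keep accuracy independent of the duration entering
speed's denominator.  A sequence-level alternative (whole correct
sequences per block) is available via ``sequence_level=True`` for users
whose data pipeline counts complete sequences instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

from .cohort import SEQUENCE
from .types import BlockRecord, BlockType, KeypressEvent


@dataclass(frozen=True)
class BlockScore:
    speed: float
    accuracy: float | None  # None when no presses were recorded
    n_presses: int
    n_correct: int

    def __post_init__(self) -> None:
        if self.n_correct > self.n_presses:
            raise ValueError("n_correct cannot exceed n_presses")


def score_block(
    events: Iterable[KeypressEvent],
    duration_s: float = 90.0,
    sequence_level: bool = False,
) -> BlockScore:
    """Score one block of keypresses.

    With ``sequence_level=True``, accuracy counts complete error-free
    nine-press sequences over started sequences, and speed counts presses
    within correct sequences per second.
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    evs = list(events)
    for e in evs:
        if not 0.0 <= e.press_time_s <= duration_s:
            raise ValueError(
                f"press at t={e.press_time_s}s outside block [0, {duration_s}]"
            )
    n = len(evs)
    if n == 0:
        return BlockScore(speed=0.0, accuracy=None, n_presses=0, n_correct=0)
    if not sequence_level:
        n_correct = sum(e.key_pressed == e.key_expected for e in evs)
        return BlockScore(
            speed=n_correct / duration_s,
            accuracy=n_correct / n,
            n_presses=n,
            n_correct=n_correct,
        )
    seq_len = len(SEQUENCE)
    evs_sorted = sorted(evs, key=lambda e: e.press_time_s)
    n_seq_started = math.ceil(n / seq_len)
    n_seq_correct = 0
    for s in range(n // seq_len):
        chunk = evs_sorted[s * seq_len : (s + 1) * seq_len]
        if all(e.key_pressed == e.key_expected for e in chunk):
            n_seq_correct += 1
    return BlockScore(
        speed=n_seq_correct * seq_len / duration_s,
        accuracy=n_seq_correct / n_seq_started,
        n_presses=n,
        n_correct=n_seq_correct * seq_len,
    )


def assemble_block_table(
    events: Iterable[KeypressEvent],
    block_types: Mapping[tuple[int, int], BlockType],
    duration_s: float = 90.0,
) -> list[BlockRecord]:
    """Score keypresses grouped by (participant, day, block) into records.

    ``block_types`` maps (day, block_index) to the block's type; every
    observed block must be covered.  Output is sorted by (participant,
    day, block_index) regardless of input order; blocks with no presses
    get accuracy 0 recorded (flagged by n_presses = 0).
    """
    groups: dict[tuple[str, int, int], list[KeypressEvent]] = {}
    for e in events:
        groups.setdefault((e.participant_id, e.day, e.block_index), []).append(e)
    records = []
    for (pid, day, block), evs in sorted(groups.items()):
        key = (day, block)
        if key not in block_types:
            raise KeyError(f"no block type mapped for day {day}, block {block}")
        score = score_block(evs, duration_s)
        records.append(
            BlockRecord(
                participant_id=pid,
                day=day,
                block_index=block,
                block_type=block_types[key],
                speed=score.speed,
                accuracy=score.accuracy if score.accuracy is not None else 0.0,
                n_presses=score.n_presses,
            )
        )
    return records


def default_block_types(n_days: int = 5) -> dict[tuple[int, int], BlockType]:
    """The study session structure: baseline (day 1, index 0), training
    blocks 1..6 daily, one catch block (index 7) per day.
    """
    types: dict[tuple[int, int], BlockType] = {(1, 0): BlockType.BASELINE}
    for day in range(1, n_days + 1):
        for block in range(1, 7):
            types[(day, block)] = BlockType.TRAINING
        types[(day, 7)] = BlockType.CATCH
    return types
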