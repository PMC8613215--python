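"""Block and condition schedule of the human experiment.

Each participant completes 10 blocks of 12 trials: 4 per virtual-hand
location (Left, Center, Right).  Center trials sit at fixed positions so
that lateral stimulation is always bracketed by the no-conflict condition
(reducing carry-over of the induced proprioceptive drift); the two runs of
four consecutive lateral trials (one all-Left, one all-Right) are placed
between them in random order.  With 14 participants this yields the
1680-trial structure of the study (120 per participant, 40 per condition).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

CONDITIONS = ("Left", "Center", "Right")

#: 1-based within-block positions always occupied by Center trials.  The
#: protocol fixes Center at the beginning, middle and end of each block;
#: with four Center trials per 12-trial block the symmetric double-middle
#: placement (1, 6, 7, 12) is used.
CENTER_POSITIONS = (1, 6, 7, 12)

TRIALS_PER_BLOCK = 12
BLOCKS_PER_PARTICIPANT = 10
TRIALS_PER_CONDITION_PER_BLOCK = 4

GROUPS = ("synchronous", "asynchronous")


def generate_block(rng_seed=None) -> list[str]:
    """One block's 12 condition labels.

    Positions 1, 6, 7, 12 are Center; positions 2-5 and 8-11 hold the
    all-Left and all-Right runs of four, in an order randomized per block.
    """
    rng = np.random.default_rng(rng_seed)
    first, second = ("Left", "Right") if rng.random() < 0.5 else ("Right", "Left")
    block = ["Center"] * TRIALS_PER_BLOCK
    for i, pos in enumerate(range(2, 6)):
        block[pos - 1] = first
    for i, pos in enumerate(range(8, 12)):
        block[pos - 1] = second
    return block


def format_block(block: list[str]) -> str:
    """Human-readable one-line rendering, e.g. ``C L L L L C C R R R R C``."""
    return " ".join(c[0] for c in block)


def generate_schedule(n_participants: int, rng_seed=None) -> pd.DataFrame:
    """Full trial schedule for ``n_participants``.

    Returns one row per trial with columns ``participant`` (1-based),
    ``group`` (alternating synchronous/asynchronous, giving the 7/7 split at
    n = 14), ``block`` (1-10), ``position`` (1-12 within block) and
    ``condition``.  ``n_participants = 0`` yields an empty schedule.
    """
    if n_participants < 0:
        raise ValueError("n_participants must be >= 0")
    rng = np.random.default_rng(rng_seed)
    rows = []
    for p in range(1, n_participants + 1):
        group = GROUPS[(p - 1) % 2]
        for blk in range(1, BLOCKS_PER_PARTICIPANT + 1):
            block = generate_block(rng)
            for pos, cond in enumerate(block, start=1):
                rows.append((p, group, blk, pos, cond))
    return pd.DataFrame(
        rows, columns=["participant", "group", "block", "position", "condition"]
    )
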