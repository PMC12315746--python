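"""Behavioral measures for the sequence-learning task.

Each sequence repetition presents 8 stimulus positions and ends with a
recall test.  Accuracy is the fraction of correctly recalled positions;
a sequence terminates after the third fully-correct recall in total (not
necessarily consecutive) or after eight repetitions.  For sensitivity
analyses each repetition also carries a learning-state label per item
(unknown -> newly_learned -> known -> very_well_known under a cumulative
correct-count rule) and a signed distance to the first fully-correct
recall.  Gaze traces are classified as kept/lost fixation from the
fraction of samples inside a central square.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "accuracy", "completion", "label_learning_states",
    "align_to_first_recall", "classify_fixation", "build_behavior_table",
]

STATES = ("unknown", "newly_learned", "known", "very_well_known")


def accuracy(responses, n_expected: int = 8) -> float:
    """Fraction of correct responses in one repetition's recall test."""
    r = np.asarray(responses)
    if len(r) != n_expected:
        raise ValueError(f"expected {n_expected} graded responses, "
                         f"got {len(r)}")
    return float(np.sum(r != 0) / n_expected)


def completion(fully_correct_flags, required: int = 3, max_reps: int = 8
               ) -> tuple[int, bool]:
    """Repetitions used under the stopping rule, and early-termination flag.

    The sequence stops right after the ``required``-th fully-correct
    repetition (counted in total, not consecutively), else runs ``max_reps``.
    """
    flags = [bool(f) for f in fully_correct_flags]
    n_full = 0
    for i, f in enumerate(flags[:max_reps], start=1):
        n_full += f
        if n_full >= required:
            return i, True
    return max_reps, False


def label_learning_states(
    item_correct: pd.Series | np.ndarray | list,
    thresholds: tuple[int, int, int] = (1, 2, 3),
) -> list[str]:
    """Learning-state label per repetition for one item's recall history.

    Under the default cumulative rule an item is ``unknown`` before its
    first correct recall, ``newly_learned`` at the repetition reaching the
    first cumulative correct, ``known`` at the second, and
    ``very_well_known`` from the third onward (configurable thresholds).
    Once reached, a state is never demoted.
    """
    t_new, t_known, t_very = thresholds
    cum = np.cumsum(np.asarray(item_correct, dtype=bool).astype(int))
    out = []
    for c in cum:
        if c >= t_very:
            out.append("very_well_known")
        elif c >= t_known:
            out.append("known")
        elif c >= t_new:
            out.append("newly_learned")
        else:
            out.append("unknown")
    return out


def align_to_first_recall(fully_correct_flags) -> list:
    """Signed distance of each repetition to the first fully-correct one.

    Distance 0 marks the first full recall, earlier repetitions get
    negative and later ones positive distances; all missing (None) when the
    sequence is never fully recalled.
    """
    flags = [bool(f) for f in fully_correct_flags]
    if not any(flags):
        return [None] * len(flags)
    first = flags.index(True)
    return [i - first for i in range(len(flags))]


def classify_fixation(
    x_deg, y_deg, square_side_deg: float = 1.26, min_fraction: float = 0.9
) -> bool:
    """Kept/lost fixation from a gaze trace over one stimulus period.

    Kept iff the fraction of samples inside the centered square (Chebyshev
    norm, inclusive boundary) is at least ``min_fraction`` (inclusive).
    """
    x = np.asarray(x_deg, dtype=float)
    y = np.asarray(y_deg, dtype=float)
    if x.size == 0 or x.shape != y.shape:
        raise ValueError("gaze trace must be non-empty and x/y aligned")
    half = square_side_deg / 2.0
    inside = np.maximum(np.abs(x), np.abs(y)) <= half + 1e-12
    return bool(inside.mean() >= min_fraction - 1e-12)


def build_behavior_table(
    items: pd.DataFrame,
    state_granularity: str = "item",
) -> pd.DataFrame:
    """Per-repetition behavior table from a long per-item correctness table.

    ``items`` has columns subject, sequence, repetition, item, correct (and
    optionally group).  Output: one row per (subject, sequence, repetition)
    with n_correct, accuracy, fully_correct, learning_state (modal item
    state, or the whole-sequence state when ``state_granularity='sequence'``)
    and distance to first full recall.
    """
    if state_granularity not in ("item", "sequence"):
        raise ValueError("state_granularity must be 'item' or 'sequence'")
    rows = []
    keys = ["subject", "sequence"]
    for (subject, seq), sub in items.groupby(keys, sort=True):
        piv = sub.pivot_table(index="repetition", columns="item",
                              values="correct", aggfunc="first").sort_index()
        reps = piv.index.to_list()
        n_total = piv.shape[1]
        n_correct = piv.sum(axis=1).astype(int)
        fully = (n_correct == n_total)
        distances = align_to_first_recall(fully.to_list())
        if state_granularity == "sequence":
            seq_states = label_learning_states(fully.to_list())
        item_states = {
            item: label_learning_states(piv[item].to_list())
            for item in piv.columns
        }
        group = sub["group"].iloc[0] if "group" in sub.columns else ""
        for k, rep in enumerate(reps):
            if state_granularity == "sequence":
                state = seq_states[k]
            else:
                states_k = [item_states[i][k] for i in piv.columns]
                # modal item state; ties resolve toward the earlier state
                order = {s: j for j, s in enumerate(STATES)}
                counts = pd.Series(states_k).value_counts()
                best = sorted(counts.index,
                              key=lambda s: (-counts[s], order[s]))[0]
                state = best
            rows.append(dict(
                subject=subject, group=group, sequence=seq, repetition=rep,
                n_correct=int(n_correct.loc[rep]), n_total=n_total,
                accuracy=float(n_correct.loc[rep]) / n_total,
                fully_correct=bool(fully.loc[rep]),
                learning_state=state,
                distance=distances[k],
            ))
    return pd.DataFrame(rows)
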