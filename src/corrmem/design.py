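"""Counterbalanced study design: topic rotation and presentation schedules.

A design consists of (a) a topic -> condition assignment per format, built
by rotating equal-sized topic sets through the conditions so each topic
serves each condition in exactly one format, and (b) per-format
presentation schedules for all three phases:

- Phase 1 Block A: two cycles over the 3x-fake critical items interleaved
  with an equal number of real-news fillers (familiarity ratings).
- Phase 1 Block B: the third presentation of the 3x fake items, the
  once-presented fake items, the affirmed-real items, and filler repeats
  (accuracy ratings).
- Phase 2: one real-news headline per critical topic (correction or
  affirmation; detection responses).
- Phase 3: one test trial per critical topic.

Every ordering satisfies the run-length constraint: no more than
``max_run_length`` consecutive items from the same condition (fillers
count as their own category).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from corrmem.config import Condition, ConfigurationError, DesignConfig

__all__ = ["StudyDesign", "make_design"]

FILLER = "FILLER"


@dataclass(frozen=True)
class StudyDesign:
    """Materialized design: condition assignments and presentation schedules.

    Attributes
    ----------
    config:
        The generating :class:`DesignConfig`.
    assignments:
        One row per (format_id, topic_id) with the assigned condition.
        Filler topics carry condition ``FILLER`` and negative topic ids
        are never used; fillers are real topics with ids >=
        ``n_critical_topics``.
    schedule:
        One row per presentation per format: (format_id, phase, block,
        order, topic_id, condition, presentation_index, is_filler).
        ``presentation_index`` counts prior exposures of the same headline
        version within Phase 1 (1-based).
    """

    config: DesignConfig
    assignments: pd.DataFrame
    schedule: pd.DataFrame

    def conditions_for_format(self, format_id: int) -> dict[int, str]:
        sub = self.assignments[self.assignments["format_id"] == format_id]
        return dict(zip(sub["topic_id"], sub["condition"]))


def _constrained_order(labels: list[str], max_run: int,
                       rng: np.random.Generator, max_tries: int = 5000) -> np.ndarray:
    """Random permutation of indices whose label sequence has no run > max_run."""
    labels_arr = np.asarray(labels)
    n = len(labels_arr)
    for _ in range(max_tries):
        perm = rng.permutation(n)
        seq = labels_arr[perm]
        run = 1
        ok = True
        for i in range(1, n):
            run = run + 1 if seq[i] == seq[i - 1] else 1
            if run > max_run:
                ok = False
                break
        if ok:
            return perm
    raise ConfigurationError(
        f"could not order {n} items with max_run_length={max_run}; "
        "constraint may be infeasible for these counts"
    )


def make_design(config: DesignConfig) -> StudyDesign:
    """Build the rotated topic assignment and phase schedules.

    Topic ids ``0 .. n_critical_topics-1`` are critical; ids
    ``n_critical_topics .. n_critical_topics+n_fillers-1`` are Block A
    real-news fillers. Critical topics are split into ``n_formats``
    consecutive sets; in format ``f``, set ``s`` receives condition
    ``(s + f) mod n_conditions``, so across formats each topic appears in
    each condition exactly once.
    """
    rng = np.random.default_rng(config.seed)
    conditions = list(Condition)
    n_cond = len(conditions)
    set_size = config.n_critical_topics // config.n_formats
    if set_size != config.items_per_condition and config.n_formats == n_cond:
        # rotation sets coincide with condition cells in the standard design
        raise ConfigurationError(
            "items_per_condition inconsistent with the set rotation"
        )

    rows = []
    for f in range(config.n_formats):
        for s in range(config.n_formats):
            cond = conditions[(s + f) % n_cond]
            for t in range(s * set_size, (s + 1) * set_size):
                rows.append((f, t, cond.value))
        for t in range(config.n_critical_topics,
                       config.n_critical_topics + config.n_fillers):
            rows.append((f, t, FILLER))
    assignments = pd.DataFrame(rows, columns=["format_id", "topic_id", "condition"])

    sched_rows = []
    for f in range(config.n_formats):
        cmap = dict(
            zip(
                assignments.loc[assignments["format_id"] == f, "topic_id"],
                assignments.loc[assignments["format_id"] == f, "condition"],
            )
        )
        fake3x = [t for t, c in cmap.items() if c == Condition.CORRECTED_3X.value]
        fake1x = [t for t, c in cmap.items() if c == Condition.CORRECTED_1X.value]
        real1x = [t for t, c in cmap.items() if c == Condition.AFFIRMED_REAL.value]
        fillers = [t for t, c in cmap.items() if c == FILLER]

        # Phase 1 Block A: two cycles of (3x fakes + fillers), each item once
        # per cycle, all items once before any repeats.
        block_a_items = fake3x + fillers
        for cycle in (1, 2):
            order = _constrained_order(
                [cmap[t] for t in block_a_items], config.max_run_length, rng
            )
            for pos, idx in enumerate(order):
                t = block_a_items[idx]
                sched_rows.append(
                    (f, "P1_BLOCK_A", cycle, pos, t, cmap[t], cycle, t in fillers)
                )

        # Phase 1 Block B: third 3x presentation + all once-presented items
        # + filler repeats.
        block_b_items = fake3x + fake1x + real1x + fillers
        pres_index = {t: 3 for t in fake3x}
        pres_index.update({t: 1 for t in fake1x + real1x})
        pres_index.update({t: 2 for t in fillers})
        order = _constrained_order(
            [cmap[t] for t in block_b_items], config.max_run_length, rng
        )
        for pos, idx in enumerate(order):
            t = block_b_items[idx]
            sched_rows.append(
                (f, "P1_BLOCK_B", 1, pos, t, cmap[t], pres_index[t], t in fillers)
            )

        # Phases 2 and 3: critical topics only.
        critical = fake3x + fake1x + real1x
        for phase in ("P2", "P3"):
            order = _constrained_order(
                [cmap[t] for t in critical], config.max_run_length, rng
            )
            for pos, idx in enumerate(order):
                t = critical[idx]
                sched_rows.append((f, phase, 1, pos, t, cmap[t], 1, False))

    schedule = pd.DataFrame(
        sched_rows,
        columns=[
            "format_id", "phase", "block", "order", "topic_id",
            "condition", "presentation_index", "is_filler",
        ],
    )
    return StudyDesign(config=config, assignments=assignments, schedule=schedule)
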