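"""Generative emulation of the bipartisan sequential-rating experiment.

The emulated design: 80 rating groups of 50 subjects (25 liberal, 25
conservative) split over four conditions — segregated with liberals first,
segregated with conservatives first, integrated (strict alternation), and
independent (no rating display) — each subject sequentially rating the same
balanced catalog of 20 messages (5 per veracity x lean cell) as true or
false. Decisions are drawn from the logistic choice model in
:mod:`crowdrate.model_core`, so every downstream analysis stage can be
exercised end-to-end without external data.

Within a group only one subject is "active" at a time: for each message the
decisions of subjects 1..N form a sequential history, and the true/false
counts displayed before each decision are stored on every record (both zero
in the independent condition, whose display is blank).

The model operates in correctness space while subjects saw true/false
counts; the two are isomorphic (the displayed counts are the correctness
tallies reflected through the message's veracity sign), and the generator
stores the display-side counts explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Literal, Sequence

import numpy as np
import pandas as pd

from .errors import DecisionSchemaError, InvalidParameterError
from .model_core import MessageSpec
from .simulator import simulate_batch

#: Experimental conditions, in canonical order.
CONDITIONS = (
    "segregated_liberal_first",
    "segregated_conservative_first",
    "integrated",
    "independent",
)

_CONDITION_CODES = {
    "segregated_liberal_first": "segL",
    "segregated_conservative_first": "segC",
    "integrated": "int",
    "independent": "ind",
}

#: Versioned column schema of the decisions table.
SCHEMA_VERSION = 1
DECISION_COLUMNS = (
    "group_id",
    "condition",
    "subject_position",
    "subject_id",
    "ideology",
    "message_id",
    "veracity",
    "lean",
    "choice",
    "correct",
    "displayed_true_count",
    "displayed_false_count",
)

DifficultyLaw = Callable[[np.random.Generator], tuple[float, float]]


@dataclass(frozen=True)
class ExperimentConfig:
    """Full specification of a synthetic rating experiment.

    Per-message difficulty parameters may be scalars (shared by every
    message), sequences with one entry per catalog message, or a sampling
    law drawing ``(d_bar, b)`` pairs. Defaults mirror the emulated design:
    20 groups per condition, 50 subjects per group, a 20-message balanced
    catalog, and the model parameters d_bar = 0.45, b = 0.2, s = 2.35.
    """

    n_segregated_liberal_first: int = 20
    n_segregated_conservative_first: int = 20
    n_integrated: int = 20
    n_independent: int = 20
    group_size: int = 50
    susceptibility: float = 2.35
    n_per_cell: int = 5
    d_bar: float | Sequence[float] = 0.45
    bias: float | Sequence[float] = 0.2
    difficulty_law: DifficultyLaw | None = None
    messages: tuple[MessageSpec, ...] | None = None
    start_ideology: Literal["liberal", "conservative"] = "liberal"
    message_order: Literal["fixed", "shuffled"] = "fixed"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.group_size < 2 or self.group_size % 2 != 0:
            raise InvalidParameterError(
                f"group_size must be even and >= 2, got {self.group_size}"
            )
        for name in (
            "n_segregated_liberal_first",
            "n_segregated_conservative_first",
            "n_integrated",
            "n_independent",
        ):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be >= 0")
        if self.n_groups == 0:
            raise InvalidParameterError("at least one group is required")
        if self.n_per_cell < 1 and self.messages is None:
            raise InvalidParameterError("n_per_cell must be >= 1")
        if self.start_ideology not in ("liberal", "conservative"):
            raise InvalidParameterError(
                f"unknown start_ideology {self.start_ideology!r}"
            )
        if self.message_order not in ("fixed", "shuffled"):
            raise InvalidParameterError(
                f"unknown message_order {self.message_order!r}"
            )
        if (
            self.messages is None
            and self.difficulty_law is None
            and np.isscalar(self.d_bar)
            and np.isscalar(self.bias)
        ):
            # Fail fast on impossible scalar difficulty parameters.
            MessageSpec(
                "config-check", 1, "liberal", float(self.d_bar), float(self.bias)
            )

    @property
    def groups_per_condition(self) -> dict[str, int]:
        return {
            "segregated_liberal_first": self.n_segregated_liberal_first,
            "segregated_conservative_first": self.n_segregated_conservative_first,
            "integrated": self.n_integrated,
            "independent": self.n_independent,
        }

    @property
    def n_groups(self) -> int:
        return sum(self.groups_per_condition.values())


def _catalog_cells(n_per_cell: int) -> list[tuple[str, int, str]]:
    """(lean, veracity, message_id) triples in canonical catalog order."""
    cells = []
    for lean in ("liberal", "conservative"):
        for veracity, tag in ((1, "true"), (-1, "false")):
            for k in range(1, n_per_cell + 1):
                cells.append((lean, veracity, f"{lean[:3]}_{tag}_{k:02d}"))
    return cells


def default_catalog(
    config: ExperimentConfig, rng: np.random.Generator | None = None
) -> tuple[MessageSpec, ...]:
    """Build the message catalog for a configuration.

    An explicit ``config.messages`` tuple is returned as-is (the escape
    hatch for unbalanced unit-test catalogs). Otherwise the catalog is
    balanced across the four veracity x lean cells, with per-message
    (d_bar, b) taken from scalars, per-message sequences, or drawn from
    ``config.difficulty_law`` with a bounded number of redraws for
    invariant-violating pairs.
    """
    if config.messages is not None:
        return tuple(config.messages)
    cells = _catalog_cells(config.n_per_cell)
    n = len(cells)

    def _expand(value: float | Sequence[float], name: str) -> list[float]:
        if np.isscalar(value):
            return [float(value)] * n
        values = [float(x) for x in value]  # type: ignore[union-attr]
        if len(values) != n:
            raise InvalidParameterError(
                f"{name} must be a scalar or have one entry per message "
                f"({n}), got {len(values)}"
            )
        return values

    if config.difficulty_law is not None:
        if rng is None:
            rng = np.random.default_rng(np.random.SeedSequence(config.seed))
        pairs = []
        for _ in cells:
            for _attempt in range(100):
                d_bar, b = config.difficulty_law(rng)
                if 0.0 <= d_bar - b / 2.0 and d_bar + b / 2.0 <= 1.0 and 0 <= b <= 1:
                    pairs.append((float(d_bar), float(b)))
                    break
            else:
                raise InvalidParameterError(
                    "difficulty_law failed to produce a valid (d_bar, b) "
                    "pair within 100 draws"
                )
        d_bars, biases = zip(*pairs)
    else:
        d_bars = _expand(config.d_bar, "d_bar")
        biases = _expand(config.bias, "bias")

    return tuple(
        MessageSpec(
            message_id=mid,
            veracity=veracity,
            lean=lean,
            mean_difficulty=d_bars[i],
            bias=biases[i],
        )
        for i, (lean, veracity, mid) in enumerate(cells)
    )


def _ideology_order(condition: str, config: ExperimentConfig) -> np.ndarray:
    """Per-position ideology labels for one condition."""
    half = config.group_size // 2
    if condition == "segregated_liberal_first":
        order = ["liberal"] * half + ["conservative"] * half
    elif condition == "segregated_conservative_first":
        order = ["conservative"] * half + ["liberal"] * half
    else:
        first = config.start_ideology
        second = "conservative" if first == "liberal" else "liberal"
        order = [first if i % 2 == 0 else second for i in range(config.group_size)]
    return np.array(order)


def generate_experiment(config: ExperimentConfig) -> pd.DataFrame:
    """Generate the full decisions table for a configuration.

    One row per (group, subject, message); rows are ordered by group, then
    subject position, then the subject's message presentation order
    (catalog order unless ``message_order == "shuffled"``), reflecting the
    protocol in which each subject completes all messages before the next
    subject starts.

    For each group and message the decisions form a valid sequential
    history generated by the choice model, with each rater's alignment
    derived from their ideology and the message lean. In segregated
    conditions the stated ideology rates first for every message, so
    same-lean messages are rated aligned-first and cross-lean messages
    misaligned-first. The independent condition forces susceptibility to 0
    and displays no counts.
    """
    root = np.random.SeedSequence(config.seed)
    catalog_seed, sim_seed, order_seed = root.spawn(3)
    catalog = default_catalog(config, np.random.default_rng(catalog_seed))
    n_messages = len(catalog)
    n_pos = config.group_size

    sim_children = sim_seed.spawn(len(CONDITIONS) * n_messages)
    frames: list[pd.DataFrame] = []
    group_offset = 0
    for ci, condition in enumerate(CONDITIONS):
        n_groups = config.groups_per_condition[condition]
        if n_groups == 0:
            continue
        code = _CONDITION_CODES[condition]
        ideologies = _ideology_order(condition, config)
        s_eff = 0.0 if condition == "independent" else config.susceptibility
        group_ids = np.array(
            [f"{code}-{group_offset + g + 1:03d}" for g in range(n_groups)]
        )
        positions = np.arange(1, n_pos + 1)
        subject_ids = np.array(
            [[f"{gid}-s{p:02d}" for p in positions] for gid in group_ids]
        )
        for mi, message in enumerate(catalog):
            rng = np.random.default_rng(sim_children[ci * n_messages + mi])
            aligned = ideologies == message.lean
            d = np.where(aligned, message.d_align, message.d_mis)
            correct, _ = simulate_batch(d, s_eff, n_groups, rng)
            rated_true = correct if message.veracity == 1 else ~correct
            if condition == "independent":
                disp_true = np.zeros((n_groups, n_pos), dtype=int)
                disp_false = np.zeros((n_groups, n_pos), dtype=int)
            else:
                cum_true = np.cumsum(rated_true, axis=1)
                disp_true = np.concatenate(
                    [np.zeros((n_groups, 1), dtype=int), cum_true[:, :-1]], axis=1
                )
                disp_false = (positions - 1)[None, :] - disp_true
            frames.append(
                pd.DataFrame(
                    {
                        "group_id": np.repeat(group_ids, n_pos),
                        "condition": condition,
                        "subject_position": np.tile(positions, n_groups),
                        "subject_id": subject_ids.ravel(),
                        "ideology": np.tile(ideologies, n_groups),
                        "message_id": message.message_id,
                        "veracity": message.veracity,
                        "lean": message.lean,
                        "choice": np.where(
                            rated_true.ravel(), "rated_true", "rated_false"
                        ),
                        "correct": correct.ravel().astype(int),
                        "displayed_true_count": disp_true.ravel(),
                        "displayed_false_count": disp_false.ravel(),
                        "_message_index": mi,
                    }
                )
            )
        group_offset += n_groups

    table = pd.concat(frames, ignore_index=True)
    if config.message_order == "shuffled":
        order_rng = np.random.default_rng(order_seed)
        ranks = np.empty(len(table), dtype=int)
        for _, idx in table.groupby(["group_id", "subject_position"]).indices.items():
            ranks[idx] = order_rng.permutation(len(idx))
        table["_message_index"] = ranks
    table = table.sort_values(
        ["group_id", "subject_position", "_message_index"], kind="stable"
    ).drop(columns="_message_index")
    return table.reset_index(drop=True)


def write_decisions(table: pd.DataFrame, path) -> None:
    """Write a decisions table as UTF-8 comma-separated CSV."""
    missing = set(DECISION_COLUMNS) - set(table.columns)
    if missing:
        raise DecisionSchemaError(f"table is missing columns: {sorted(missing)}")
    table.loc[:, list(DECISION_COLUMNS)].to_csv(path, index=False)


def read_decisions(path) -> pd.DataFrame:
    """Read a decisions table, validating it against the v1 column schema.

    Raises :class:`DecisionSchemaError` on missing or unknown columns so
    that silently incompatible files cannot flow into the analysis.
    """
    table = pd.read_csv(
        path,
        dtype={
            "group_id": str,
            "condition": str,
            "subject_id": str,
            "ideology": str,
            "message_id": str,
            "lean": str,
            "choice": str,
        },
    )
    observed = set(table.columns)
    expected = set(DECISION_COLUMNS)
    if observed != expected:
        raise DecisionSchemaError(
            f"decisions schema v{SCHEMA_VERSION} mismatch; "
            f"missing={sorted(expected - observed)}, "
            f"unknown={sorted(observed - expected)}"
        )
    for col in (
        "subject_position",
        "veracity",
        "correct",
        "displayed_true_count",
        "displayed_false_count",
    ):
        table[col] = table[col].astype(int)
    return table.loc[:, list(DECISION_COLUMNS)]
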