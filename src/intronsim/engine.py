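"""The mutation-and-deletion (MD) and mutation-and-insertion (MI) simulators.

Both models evolve sequences root-to-leaves along a guide tree.  The MD
model starts from a long random ancestor and shrinks toward the leaf target
lengths; the MI model starts from a short ancestor and grows.  Five
parameters control a run:

``L_AS1``   length (bases) of the first ancestral sequence,
``L_AS12``  length of the last ancestral sequence,
``M_1``     substitutions per unit branch length,
``L_ID``    inclusive range of bases removed/added per indel event,
``M_ID``    inclusive range of bases substituted per mutation event.

Intermediate ancestor lengths are scheduled by linear interpolation along
the ancestor index (AS_1 ... AS_K), then clamped so lengths are monotone
along every root-to-leaf path and every direct ancestor is strictly longer
(MD) / shorter (MI) than each of its leaf children.  Along each branch the
engine alternates one mutation event and one indel event, capping the final
draws so the per-branch substitution budget ``round(M_1 * branch_length)``
and the exact child target length are both hit.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace

import numpy as np

from .core import (
    InfeasibleEventError,
    MutationLedger,
    Sequence,
    SubstitutionSampler,
    draw_from_range,
    mutate,
    delete_block,
    insert_block,
    random_sequence,
)
from .tree import GuideTree, TreeNode

__all__ = [
    "MD",
    "MI",
    "ModelParams",
    "StagePlan",
    "ValidityReport",
    "RunResult",
    "PlanningError",
    "InfeasibleBranchError",
    "validate_params",
    "plan_stages",
    "evolve_branch",
    "run",
]

MD = "MD"
MI = "MI"


class PlanningError(ValueError):
    """No stage plan can satisfy the length constraints."""

    def __init__(self, violations: list[tuple[str, str]]):
        self.violations = violations
        pairs = ", ".join(f"{a} vs {l}" for a, l in violations)
        super().__init__(f"unrepairable stage plan; violated (ancestor, leaf): {pairs}")


class InfeasibleBranchError(ValueError):
    """A branch whose endpoint lengths contradict the model direction."""


@dataclass(frozen=True)
class ModelParams:
    """Full parameterisation of one simulator run."""

    mode: str
    L_AS1: int
    L_AS12: int
    M_1: float
    L_ID: tuple[int, int]
    M_ID: tuple[int, int]
    R: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in (MD, MI):
            raise ValueError(f"mode must be {MD!r} or {MI!r}, got {self.mode!r}")
        for name, (lo, hi) in (("L_ID", self.L_ID), ("M_ID", self.M_ID)):
            if lo > hi or lo < 0:
                raise ValueError(f"{name} range [{lo}, {hi}] is empty or negative")
        if self.M_1 <= 0:
            raise ValueError("M_1 must be positive")
        if self.mode == MD and self.L_AS1 < self.L_AS12:
            raise ValueError("MD requires L_AS1 >= L_AS12")
        if self.mode == MI and self.L_AS1 > self.L_AS12:
            raise ValueError("MI requires L_AS1 <= L_AS12")

    def with_seed(self, seed: int) -> "ModelParams":
        return replace(self, seed=seed)


@dataclass
class StagePlan:
    """Per-node target lengths and per-branch substitution budgets."""

    node_target_length: dict[str, int]
    branch_mutation_target: dict[tuple[str, str], int]


@dataclass
class ValidityReport:
    """Outcome of checking ancestor-vs-leaf length constraints."""

    valid: bool
    violations: list[tuple[str, str]] = field(default_factory=list)


_AS_INDEX = re.compile(r"^AS_(\d+)$")


def _backbone_index(tree: GuideTree) -> dict[str, int]:
    """Ancestor ordering used by the interpolation schedule.

    Uses the numeric suffix of ``AS_k`` labels when present, otherwise the
    preorder rank of the internal node.
    """
    internals = tree.internal_nodes()
    index: dict[str, int] = {}
    for rank, node in enumerate(internals, start=1):
        m = _AS_INDEX.match(node.label)
        index[node.label] = int(m.group(1)) if m else rank
    return index


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def _schedule_linear(tree: GuideTree, params: ModelParams) -> dict[str, int]:
    """Linear interpolation of ancestor lengths along the backbone index."""
    index = _backbone_index(tree)
    k_max = max(index.values())
    k_min = min(index.values())
    span = max(k_max - k_min, 1)
    out = {}
    for label, k in index.items():
        frac = (k - k_min) / span
        out[label] = _round_half_up(params.L_AS1 + frac * (params.L_AS12 - params.L_AS1))
    return out


def _plan(
    tree: GuideTree, params: ModelParams, schedule=_schedule_linear
) -> tuple[StagePlan, list[tuple[str, str]]]:
    lengths = schedule(tree, params)
    index = _backbone_index(tree)
    first = min(index, key=index.get)
    last = max(index, key=index.get)
    lengths[first] = params.L_AS1
    lengths[last] = params.L_AS12
    sign = 1 if params.mode == MD else -1  # MD: non-increasing along paths

    # repair pass: clamp free ancestors between their parent and the
    # strict bound imposed by their leaf children
    for parent, child in tree.edges():
        if child.is_leaf:
            continue
        label = child.label
        if label in (first, last):
            continue
        val = lengths[label]
        if sign * val > sign * lengths[parent.label]:
            val = lengths[parent.label]
        bound = _leaf_bound(tree, child, params)
        if bound is not None and sign * val < sign * bound:
            val = bound
        lengths[label] = val

    violations: list[tuple[str, str]] = []
    for node in tree.internal_nodes():
        for child in node.children:
            if child.is_leaf:
                target = tree.leaf_specs[child.label]
                if sign * lengths[node.label] <= sign * target:
                    violations.append((node.label, child.label))
            elif sign * lengths[child.label] > sign * lengths[node.label]:
                # forced by a leaf deeper down: name the offending leaf
                extreme = (max if params.mode == MD else min)(
                    child.leaves(), key=lambda lf: tree.leaf_specs[lf.label]
                )
                violations.append((node.label, extreme.label))

    budgets = {
        (p.label, c.label): _round_half_up(params.M_1 * (c.branch_length or 0.0))
        for p, c in tree.edges()
    }
    return StagePlan(lengths, budgets), violations


def _leaf_bound(tree: GuideTree, node: TreeNode, params: ModelParams) -> int | None:
    targets = [tree.leaf_specs[c.label] for c in node.children if c.is_leaf]
    if not targets:
        return None
    return max(targets) + 1 if params.mode == MD else min(targets) - 1


def validate_params(tree: GuideTree, params: ModelParams) -> ValidityReport:
    """Check that a stage plan can keep every direct ancestor strictly longer
    (MD) / shorter (MI) than each of its leaf children."""
    _, violations = _plan(tree, params)
    return ValidityReport(valid=not violations, violations=violations)


def plan_stages(tree: GuideTree, params: ModelParams, schedule=_schedule_linear) -> StagePlan:
    """Build the stage plan, raising :class:`PlanningError` when invalid."""
    missing = [lab for lab in tree.leaf_labels if lab not in tree.leaf_specs]
    if missing:
        raise PlanningError([("?", lab) for lab in missing])
    plan, violations = _plan(tree, params, schedule)
    if violations:
        raise PlanningError(violations)
    return plan


def evolve_branch(
    parent_seq: Sequence,
    child_target_len: int,
    mutation_target: int,
    params: ModelParams,
    rng: np.random.Generator,
    child_id: str = "",
) -> tuple[Sequence, MutationLedger]:
    """Evolve one branch by alternating mutation and indel events.

    Each cycle substitutes ``min(draw(M_ID), remaining budget)`` bases and
    then removes/adds ``min(draw(L_ID), remaining length difference)``
    bases, so the returned sequence has exactly ``child_target_len`` bases
    and the ledger totals exactly ``mutation_target`` substitutions.
    """
    delta = child_target_len - len(parent_seq)
    if params.mode == MD and delta > 0:
        raise InfeasibleBranchError(
            f"MD branch cannot grow ({len(parent_seq)} -> {child_target_len})"
        )
    if params.mode == MI and delta < 0:
        raise InfeasibleBranchError(
            f"MI branch cannot shrink ({len(parent_seq)} -> {child_target_len})"
        )
    sampler = SubstitutionSampler(params.R, rng)
    seq = Sequence(parent_seq.bases, child_id or parent_seq.id)
    ledger = MutationLedger()
    remaining_mut = mutation_target
    while remaining_mut > 0 or len(seq) != child_target_len:
        progressed = False
        if remaining_mut > 0:
            m = min(
                draw_from_range(*params.M_ID, rng),
                remaining_mut,
                len(seq) - 4,
            )
            if m > 0:
                seq, led = mutate(seq, m, sampler, protect_termini=True)
                ledger.absorb(led)
                remaining_mut -= m
                progressed = True
        gap = child_target_len - len(seq)
        if gap != 0:
            l = min(draw_from_range(*params.L_ID, rng), abs(gap))
            if l > 0:
                seq = (
                    delete_block(seq, l, rng) if gap < 0 else insert_block(seq, l, rng)
                )
                progressed = True
        if not progressed:
            raise InfeasibleEventError(
                f"no progress evolving toward {child_id or child_target_len}"
            )
    return seq, ledger


@dataclass
class RunResult:
    """All sequences and ledgers produced by one simulator run."""

    ancestors: dict[str, Sequence]
    leaves: dict[str, Sequence]
    ledgers: dict[tuple[str, str], MutationLedger]
    params: ModelParams
    seed: int

    @property
    def pooled_ledger(self) -> MutationLedger:
        pooled = MutationLedger()
        for led in self.ledgers.values():
            pooled.absorb(led)
        return pooled

    def all_sequences(self) -> list[Sequence]:
        return list(self.ancestors.values()) + list(self.leaves.values())

    def manifest(self) -> dict:
        return {
            "params": {
                "mode": self.params.mode,
                "L_AS1": self.params.L_AS1,
                "L_AS12": self.params.L_AS12,
                "M_1": self.params.M_1,
                "L_ID": list(self.params.L_ID),
                "M_ID": list(self.params.M_ID),
                "R": self.params.R,
            },
            "seed": self.seed,
            "ledgers": {
                f"{p}->{c}": {
                    "transitions": led.n_transitions,
                    "transversions": led.n_transversions,
                }
                for (p, c), led in self.ledgers.items()
            },
        }


def run(
    tree: GuideTree,
    params: ModelParams,
    rng: np.random.Generator | None = None,
    schedule=_schedule_linear,
) -> RunResult:
    """Simulate one full run: generate AS_1, then evolve every branch in
    preorder.  Every leaf sequence ends at exactly its target length."""
    if rng is None:
        rng = np.random.default_rng(params.seed)
    plan = plan_stages(tree, params, schedule)
    root = tree.root
    ancestors: dict[str, Sequence] = {}
    leaves: dict[str, Sequence] = {}
    ledgers: dict[tuple[str, str], MutationLedger] = {}
    ancestors[root.label] = random_sequence(params.L_AS1, rng, id=root.label)

    for parent, child in tree.edges():
        parent_seq = ancestors[parent.label]
        if child.is_leaf:
            target = tree.leaf_specs[child.label]
        else:
            target = plan.node_target_length[child.label]
        budget = plan.branch_mutation_target[(parent.label, child.label)]
        seq, ledger = evolve_branch(
            parent_seq, target, budget, params, rng, child_id=child.label
        )
        ledgers[(parent.label, child.label)] = ledger
        if child.is_leaf:
            leaves[child.label] = seq
        else:
            ancestors[child.label] = seq
    return RunResult(ancestors, leaves, ledgers, params, params.seed)
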