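"""Model-guided promoter sequence design.

Three strategies generate sequences whose merged ensemble score for an
objective (constitutive activity, induced activity, or activation ratio)
exceeds a threshold:

* screening — sample random library members and keep the ones that pass;
* evolution — iteratively mutate a parent at randomized positions, passing
  the highest-scoring variant to the next cycle, with the per-cycle
  mutation count decreasing over time;
* gradient ascent — relax the one-hot input to a continuous matrix, repeat
  gradient steps on the merged score at randomized positions, and score the
  argmax-rounded sequence after each step.

All strategies protect constant scaffold regions, optionally enforce the
GC-window constraint, and always reject designs containing BsaI sites
(which interfere with downstream assembly).  Scorers are any object with
``score_seqs(seqs, objective)`` (and ``objective_grad(x, objective)`` for
gradient ascent) — normally a trained :class:`~promdesign.model.EnsembleModel`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .scaffold import (
    BASES,
    LibraryScaffold,
    contains_bsai,
    gc_window_ok,
    one_hot,
    decode_one_hot,
    sample_sequence,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Objective:
    target: str  # constitutive_activity | induced_activity | activation_ratio
    merge_mode: str = "mean"
    threshold: float = 0.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.threshold):
            raise ValueError("threshold must be finite")


@dataclass(frozen=True)
class Constraints:
    """Sequence-level acceptance filters applied to candidate designs."""

    gc: bool = False
    gc_window: int = 20
    gc_lo: float = 0.25
    gc_hi: float = 0.80
    bsai: bool = True

    def ok(self, seq: str) -> bool:
        if self.bsai and contains_bsai(seq):
            return False
        if self.gc and not gc_window_ok(seq, self.gc_window, self.gc_lo, self.gc_hi):
            return False
        return True

    def names(self) -> tuple[str, ...]:
        out = []
        if self.gc:
            out.append("gc_window")
        if self.bsai:
            out.append("no_bsai")
        return tuple(out)


@dataclass(frozen=True)
class EvolutionSchedule:
    """Per-cycle variant count and (non-increasing) mutation counts.

    The default decays the mutation count 8 -> 4 -> 2 -> 1 over quartiles
    of the cycle budget.
    """

    variants_per_cycle: int = 100
    mutation_counts: tuple[int, ...] = (8, 4, 2, 1)
    max_cycles: int = 200

    def __post_init__(self) -> None:
        if min(self.mutation_counts) < 1:
            raise ValueError("mutation counts must be >= 1")
        if any(a < b for a, b in zip(self.mutation_counts, self.mutation_counts[1:])):
            raise ValueError("mutation counts must be non-increasing")

    def mutations_at(self, cycle: int) -> int:
        phase = min(
            len(self.mutation_counts) - 1,
            cycle * len(self.mutation_counts) // max(self.max_cycles, 1),
        )
        return self.mutation_counts[phase]


@dataclass
class DesignResult:
    sequence: str
    score: float
    strategy: str
    constraints_applied: tuple[str, ...]
    provenance: dict
    success: bool = True


def score(seq: str, scorer, objective: Objective) -> float:
    """Merged ensemble score of one sequence under the objective."""
    return float(np.asarray(scorer.score_seqs([seq], objective))[0])


def screen(
    scaffold: LibraryScaffold,
    scorer,
    objective: Objective,
    n_target: int,
    rng: np.random.Generator,
    constraints: Constraints = Constraints(),
    batch_size: int = 64,
    max_candidates: int = 100_000,
) -> list[DesignResult]:
    """Sample random library members until ``n_target`` pass the constraints
    and reach the score threshold (or the candidate cap is hit)."""
    if n_target < 1:
        raise ValueError("n_target must be >= 1")
    accepted: list[DesignResult] = []
    tried = 0
    while len(accepted) < n_target and tried < max_candidates:
        batch = [sample_sequence(scaffold, rng) for _ in range(batch_size)]
        tried += len(batch)
        keep = [s for s in batch if constraints.ok(s)]
        if not keep:
            continue
        scores = np.asarray(scorer.score_seqs(keep, objective))
        for s, sc in zip(keep, scores):
            if sc >= objective.threshold and len(accepted) < n_target:
                accepted.append(
                    DesignResult(
                        s,
                        float(sc),
                        "screening",
                        constraints.names(),
                        {"candidates_tried": tried},
                    )
                )
    if len(accepted) < n_target:
        logger.warning(
            "screening exhausted %d candidates with %d/%d accepts",
            tried,
            len(accepted),
            n_target,
        )
    return accepted


def _mutate_randomized(
    seq: str,
    scaffold: LibraryScaffold,
    n_mut: int,
    rng: np.random.Generator,
    rand_positions: np.ndarray,
    freqs: np.ndarray,
) -> str:
    chars = list(seq)
    pick = rng.choice(rand_positions, size=min(n_mut, len(rand_positions)), replace=False)
    for p in pick:
        f = freqs[:, p].copy()
        f[_base_index(chars[p])] = 0.0
        if f.sum() <= 0:
            continue
        f /= f.sum()
        chars[p] = BASES[rng.choice(4, p=f)]
    return "".join(chars)


def _base_index(c: str) -> int:
    return BASES.index(c)


def evolve(
    scaffold: LibraryScaffold,
    scorer,
    objective: Objective,
    schedule: EvolutionSchedule,
    rng: np.random.Generator,
    constraints: Constraints = Constraints(),
    hill_climb: bool = False,
) -> DesignResult:
    """In silico evolution from a random parent.

    Each cycle scores ``variants_per_cycle`` mutants of the parent (mutating
    only randomized positions, with replacement bases drawn from the
    segment's composition); the highest-scoring variant becomes the next
    parent (with ``hill_climb`` the parent is kept if it scores better).
    Stops when the best variant passes constraints and threshold, or the
    cycle budget runs out (returning the best-so-far with success=False).
    """
    rand_positions = np.nonzero(scaffold.randomized_mask())[0]
    freqs = scaffold.base_freq_matrix()
    parent = sample_sequence(scaffold, rng)
    parent_score = float(np.asarray(scorer.score_seqs([parent], objective))[0])
    best_seen = (parent, parent_score)
    log = []
    for cycle in range(schedule.max_cycles):
        n_mut = schedule.mutations_at(cycle)
        variants = [
            _mutate_randomized(parent, scaffold, n_mut, rng, rand_positions, freqs)
            for _ in range(schedule.variants_per_cycle)
        ]
        scores = np.asarray(scorer.score_seqs(variants, objective))
        j = int(scores.argmax())
        best_seq, best_score = variants[j], float(scores[j])
        if hill_climb and parent_score > best_score:
            best_seq, best_score = parent, parent_score
        parent, parent_score = best_seq, best_score
        log.append({"cycle": cycle, "n_mutations": n_mut, "best_score": best_score})
        if best_score > best_seen[1]:
            best_seen = (best_seq, best_score)
        if best_score >= objective.threshold and constraints.ok(best_seq):
            return DesignResult(
                best_seq,
                best_score,
                "evolution",
                constraints.names(),
                {"cycles": log},
            )
    return DesignResult(
        best_seen[0],
        best_seen[1],
        "evolution",
        constraints.names(),
        {"cycles": log},
        success=False,
    )


def gradient_ascent(
    scaffold: LibraryScaffold,
    scorer,
    objective: Objective,
    rng: np.random.Generator,
    constraints: Constraints = Constraints(),
    steps: int = 500,
    step_size: float = 1.0,
) -> DesignResult:
    """Gradient ascent on a continuous relaxation of the one-hot input.

    Starting from a random library member, each step adds
    ``step_size * gradient`` of the merged objective at randomized
    positions (entries for bases the library cannot emit stay frozen, as do
    constant columns), rounds the relaxed matrix to the per-column argmax,
    and scores the rounded sequence.  Accepts when the rounded sequence
    passes constraints and threshold.
    """
    mask = scaffold.randomized_mask()
    freqs = scaffold.base_freq_matrix()
    movable = (freqs > 0) & mask[None, :]
    x = one_hot(sample_sequence(scaffold, rng))
    backbone = one_hot_backbone(scaffold)
    best = (None, -np.inf)
    log = []
    for step in range(steps):
        _, grad = scorer.objective_grad(x, objective)
        x = x + step_size * grad * movable
        rounded = np.where(movable.any(axis=0)[None, :], x, backbone)
        seq = decode_one_hot(np.where(movable, rounded, -np.inf))
        # constant columns come from the scaffold backbone
        seq = "".join(
            b if m else c for b, c, m in zip(seq, scaffold.constant_backbone(), mask)
        )
        sc = float(np.asarray(scorer.score_seqs([seq], objective))[0])
        log.append({"step": step, "score": sc})
        if sc > best[1]:
            best = (seq, sc)
        if sc >= objective.threshold and constraints.ok(seq):
            return DesignResult(
                seq, sc, "gradient_ascent", constraints.names(), {"steps": log}
            )
    return DesignResult(
        best[0],
        best[1],
        "gradient_ascent",
        constraints.names(),
        {"steps": log},
        success=False,
    )


def one_hot_backbone(scaffold: LibraryScaffold) -> np.ndarray:
    """One-hot of constant positions, zeros at randomized positions."""
    x = np.zeros((4, scaffold.total_length))
    mask = scaffold.randomized_mask()
    for p, c in enumerate(scaffold.constant_backbone()):
        if not mask[p]:
            x[_base_index(c), p] = 1.0
    return x


def design_set(
    strategy: str,
    scaffold: LibraryScaffold,
    scorer,
    objective: Objective,
    n_target: int,
    rng: np.random.Generator,
    constraints: Constraints = Constraints(),
    schedule: EvolutionSchedule = EvolutionSchedule(),
    **kwargs,
) -> list[DesignResult]:
    """Produce ``n_target`` accepted designs with the chosen strategy."""
    if strategy == "screening":
        return screen(scaffold, scorer, objective, n_target, rng, constraints, **kwargs)
    out: list[DesignResult] = []
    attempts = 0
    while len(out) < n_target and attempts < 10 * n_target:
        attempts += 1
        if strategy == "evolution":
            res = evolve(scaffold, scorer, objective, schedule, rng, constraints)
        elif strategy == "gradient_ascent":
            res = gradient_ascent(scaffold, scorer, objective, rng, constraints, **kwargs)
        else:
            raise ValueError(f"unknown strategy {strategy!r}")
        if res.success:
            out.append(res)
    return out


def adjust_threshold(
    strategy_runner,
    initial_threshold: float,
    direction: str,
    increment: float = 0.05,
    max_steps: int = 100,
) -> float:
    """Adapt the design threshold to what the strategy can deliver.

    ``strategy_runner(threshold) -> bool`` reports whether a full promoter
    set could be generated within budget at that threshold.  Downward mode
    lowers the threshold in ``increment`` steps until the first success;
    upward (elevated-threshold) mode raises it until production fails and
    returns the last achievable threshold.
    """
    if increment <= 0:
        raise ValueError("increment must be positive")
    t = initial_threshold
    if direction == "down":
        for _ in range(max_steps):
            if strategy_runner(t):
                return t
            t -= increment
        return t
    if direction == "up":
        for _ in range(max_steps):
            if not strategy_runner(t + increment):
                return t
            t += increment
        return t
    raise ValueError("direction must be 'down' or 'up'")


def pairwise_alignment_distances(seqs: list[str], max_pairs: int = 2000, rng=None) -> np.ndarray:
    """Global alignment distances between sequence pairs within a design
    set (a diversity proxy); subsamples pairs beyond ``max_pairs``."""
    from itertools import combinations

    from .reads import nw_distance

    pairs = list(combinations(range(len(seqs)), 2))
    if rng is not None and len(pairs) > max_pairs:
        idx = rng.choice(len(pairs), max_pairs, replace=False)
        pairs = [pairs[i] for i in idx]
    return np.array([nw_distance(seqs[i], seqs[j]) for i, j in pairs])
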