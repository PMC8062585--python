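"""Seed generation and model-guided mutation walks.

A walk starts from a parent set containing one seed. Each round samples a
fixed number of random mutants (each up to a configurable number of
substitutions from a uniformly chosen parent), scores them, records the top
few for output, and promotes the top-scoring mutants to be the next parent
set. The random-walk baseline is identical except that selection is uniform
instead of score-ranked, so the only difference between the arms is model
guidance. Tie-breaking everywhere is score descending, then lexicographic.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from ._util import BASES, check_sequence, derive_rng, random_sequences

Scorer = Callable[[Sequence[str]], np.ndarray]


@dataclass
class WalkConfig:
    rounds: int = 5
    mutants_per_round: int = 10_000
    max_substitutions: int = 4
    parent_cap: int = 200
    selected_per_round: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.rounds, self.mutants_per_round, self.parent_cap, self.selected_per_round) < 0:
            raise ValueError("walk parameters must be non-negative")
        if not self.selected_per_round <= self.parent_cap <= self.mutants_per_round:
            raise ValueError("need selected_per_round <= parent_cap <= mutants_per_round")


@dataclass
class WalkRound:
    parents: list[str]
    mutants: list[str]
    scores: np.ndarray
    selected: list[str]


@dataclass
class WalkTrajectory:
    seed_sequence: str
    provenance: str  # random | experimental | ml_screened
    rounds: list[WalkRound] = field(default_factory=list)

    def candidates(self) -> list[str]:
        """All selected sequences across rounds, deduplicated, order-preserving."""
        seen: dict[str, None] = {}
        for rnd in self.rounds:
            for s in rnd.selected:
                seen.setdefault(s)
        return list(seen)

    def best_score_per_round(self) -> list[float]:
        return [float(r.scores.max()) for r in self.rounds if len(r.scores)]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, rnd in enumerate(self.rounds, start=1):
            sel = set(rnd.selected)
            for mutant, score in zip(rnd.mutants, rnd.scores):
                rows.append(
                    {
                        "round": i,
                        "seed": self.seed_sequence,
                        "mutant": mutant,
                        "score": score,
                        "selected": mutant in sel,
                    }
                )
        return pd.DataFrame(rows)

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def mutate(sequence: str, max_substitutions: int, rng: np.random.Generator) -> str:
    """Random mutant with 0..max_substitutions substitutions (count uniform),
    positions without replacement, new base uniform over the 3 alternatives."""
    check_sequence(sequence)
    n_sub = int(rng.integers(0, max_substitutions + 1))
    if n_sub == 0:
        return sequence
    positions = rng.choice(len(sequence), size=n_sub, replace=False)
    chars = list(sequence)
    for p in positions:
        alternatives = [b for b in BASES if b != chars[p]]
        chars[p] = alternatives[int(rng.integers(0, 3))]
    return "".join(chars)


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _rank_order(mutants: list[str], scores: np.ndarray) -> list[int]:
    """Indices sorted by score descending, ties by sequence ascending."""
    return sorted(range(len(mutants)), key=lambda i: (-scores[i], mutants[i]))


def _run_walk(
    seed_sequence: str,
    scorer: Scorer | None,
    config: WalkConfig,
    provenance: str,
    guided: bool,
) -> WalkTrajectory:
    rng = derive_rng(config.seed, "walk", seed_sequence)
    traj = WalkTrajectory(seed_sequence, provenance)
    parents = [seed_sequence]
    for _ in range(config.rounds):
        round_parents = list(parents)
        parent_idx = rng.integers(0, len(round_parents), size=config.mutants_per_round)
        mutants, origins = [], []
        for pi in parent_idx:
            m = mutate(round_parents[pi], config.max_substitutions, rng)
            mutants.append(m)
            origins.append(round_parents[pi])
        # distance-bound invariant: every mutant stays within reach of its parent
        assert all(
            _hamming(m, o) <= config.max_substitutions for m, o in zip(mutants, origins)
        )
        if guided:
            scores = np.asarray(scorer(mutants), dtype=float)
            order = _rank_order(mutants, scores)
        else:
            scores = (
                np.asarray(scorer(mutants), dtype=float)
                if scorer is not None
                else np.full(len(mutants), np.nan)
            )
            order = list(rng.permutation(len(mutants)))
        selected = [mutants[i] for i in order[: config.selected_per_round]]
        parents = [mutants[i] for i in order[: config.parent_cap]] or round_parents
        traj.rounds.append(WalkRound(round_parents, mutants, scores, selected))
    return traj


def walk(
    seed_sequence: str,
    scorer: Scorer,
    config: WalkConfig,
    provenance: str = "experimental",
) -> WalkTrajectory:
    """Model-guided iterative mutation walk (greedy hill climb with a parent pool)."""
    return _run_walk(seed_sequence, scorer, config, provenance, guided=True)


def random_walk(
    seed_sequence: str,
    config: WalkConfig,
    scorer: Scorer | None = None,
    provenance: str = "random",
) -> WalkTrajectory:
    """Baseline walk with uniform-random selection; identical sampling otherwise.

    A scorer may be supplied purely for bookkeeping (recorded, never used for
    selection)."""
    return _run_walk(seed_sequence, scorer, config, provenance, guided=False)


def screen_random_seeds(
    scorer: Scorer,
    n_candidates: int,
    top_fraction: float,
    seed: int = 0,
    length: int = 40,
    chunk_size: int = 50_000,
) -> list[str]:
    """In-silico seed screening: generate and score uniform random sequences,
    keep the top ceil(n * fraction), streamed in constant memory.

    Ties break score descending then lexicographic; deterministic given seed.
    """
    if not 0 < top_fraction < 1:
        raise ValueError("top_fraction must be in (0,1)")
    keep = math.ceil(n_candidates * top_fraction)
    rng = derive_rng(seed, "screen_random_seeds")
    # min-heap of (score, reversed-tie-key) keeping the best `keep` items
    heap: list[tuple[float, tuple, str]] = []
    remaining = n_candidates
    while remaining > 0:
        batch = random_sequences(min(chunk_size, remaining), length, rng)
        remaining -= len(batch)
        scores = np.asarray(scorer(batch), dtype=float)
        for s, sc in zip(batch, scores):
            # lexicographically smaller sequences must win ties -> invert key
            key = (float(sc), tuple(-ord(c) for c in s), s)
            if len(heap) < keep:
                heapq.heappush(heap, key)
            elif key > heap[0]:
                heapq.heapreplace(heap, key)
    ranked = sorted(heap, key=lambda k: (-k[0], k[2]))
    return [s for _, _, s in ranked]


def evaluate_walks(
    trajectories: Sequence[WalkTrajectory],
    oracle,
    ladder,
) -> pd.Series:
    """Fraction of emitted walk candidates whose true K_D passes each
    stringency threshold of the ladder."""
    candidates: dict[str, None] = {}
    for traj in trajectories:
        for s in traj.candidates():
            candidates.setdefault(s)
    seqs = list(candidates)
    out = {}
    kds = oracle.kds(seqs) if seqs else np.array([])
    for T, thr in zip(ladder.concentrations, ladder.thresholds):
        out[thr] = float((kds <= thr).mean()) if len(kds) else 0.0
    return pd.Series(out, name="candidate_fraction")
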