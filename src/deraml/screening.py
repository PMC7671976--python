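"""Combinatorial candidate enumeration and specificity-shift ranking.

The in-silico screen enumerates every variant composed of 1-3 library
mutations at pairwise-distinct positions, predicts each substrate's
activity with the trained GP models, and sorts candidates by the
specificity-shift score: predicted acetaldehyde-addition activity minus
predicted DRP-cleavage activity. High scores flag variants expected to
gain the aldol-addition capability while losing activity on the natural
phosphorylated substrate.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, product
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .gp import TrainedSpecificityModel, predict
from .kernels import KernelBank
from .variants import PointMutation, Variant

SUBSTRATE_UP = "ACET"
SUBSTRATE_DOWN = "DRP"


@dataclass(frozen=True)
class RankedCandidate:
    """One screened variant with per-substrate predictions and its score."""

    variant: Variant
    predictions: Mapping[str, tuple[float, float]]  # substrate -> (mean, variance)
    score: float

    @property
    def name(self) -> str:
        return str(self.variant)


def enumerate_candidates(
    library: Sequence[PointMutation],
    max_mutations: int = 3,
    exclude: Iterable[Variant | str] = (),
) -> list[Variant]:
    """All 1..max_mutations combinations of library mutations at distinct positions.

    The excluded set (canonical variant strings or Variant objects, e.g.
    everything already measured) is removed. Output order is deterministic:
    ascending mutation count, then canonical string.
    """
    if max_mutations not in (1, 2, 3):
        raise ValueError("max_mutations must be 1, 2 or 3")
    excluded = {str(v) if isinstance(v, Variant) else str(Variant.parse(v)) for v in exclude}
    by_position: dict[int, list[PointMutation]] = {}
    for m in library:
        by_position.setdefault(m.position, []).append(m)
    for muts in by_position.values():
        if len(set(muts)) != len(muts):
            raise ValueError("library contains duplicate mutations")
    positions = sorted(by_position)
    out: list[Variant] = []
    for size in range(1, max_mutations + 1):
        batch = []
        for pos_subset in combinations(positions, size):
            for combo in product(*(by_position[p] for p in pos_subset)):
                v = Variant(combo)
                if str(v) not in excluded:
                    batch.append(v)
        batch.sort(key=str)
        out.extend(batch)
    return out


def count_candidates(library: Sequence[PointMutation], max_mutations: int = 3) -> int:
    """Closed-form candidate count: sums of multiplicity products over position subsets."""
    mult: dict[int, int] = {}
    for m in library:
        mult[m.position] = mult.get(m.position, 0) + 1
    ms = list(mult.values())
    total = 0
    for size in range(1, max_mutations + 1):
        total += sum(int(np.prod(c)) for c in combinations(ms, size))
    return total


def score_candidates(
    models: Mapping[str, TrainedSpecificityModel],
    candidates: Sequence[Variant],
    bank: KernelBank,
    up: str = SUBSTRATE_UP,
    down: str = SUBSTRATE_DOWN,
) -> list[RankedCandidate]:
    """Rank candidates by predicted ``up`` activity minus predicted ``down`` activity.

    Predictive variances are carried along for reporting but do not enter
    the score. Ties break by canonical variant string, ascending.
    """
    for required in (up, down):
        if required not in models:
            raise KeyError(f"no trained model for substrate {required!r}")
    if not candidates:
        return []
    preds: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for substrate, model in models.items():
        preds[substrate] = predict(model, candidates, bank)
    scores = preds[up][0] - preds[down][0]
    ranked = [
        RankedCandidate(
            variant=v,
            predictions={s: (float(mu[i]), float(var[i])) for s, (mu, var) in preds.items()},
            score=float(scores[i]),
        )
        for i, v in enumerate(candidates)
    ]
    ranked.sort(key=lambda c: (-c.score, c.name))
    return ranked


def select_top(ranked: Sequence[RankedCandidate], k: int) -> list[RankedCandidate]:
    """First min(k, n) candidates of a ranking (the manual-review shortlist)."""
    if k < 0:
        raise ValueError("k must be nonnegative")
    return list(ranked[: min(k, len(ranked))])


def shortlist_report(shortlist: Sequence[RankedCandidate]) -> pd.DataFrame:
    """Human-readable shortlist: rank, variant, score, per-substrate mean +/- sd."""
    rows = []
    for rank, c in enumerate(shortlist, start=1):
        row: dict[str, object] = {"rank": rank, "variant": c.name, "score": c.score}
        for substrate, (mu, var) in sorted(c.predictions.items()):
            row[f"{substrate}_mean"] = mu
            row[f"{substrate}_sd"] = float(np.sqrt(var))
        rows.append(row)
    return pd.DataFrame(rows)
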