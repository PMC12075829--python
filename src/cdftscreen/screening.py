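"""Multi-criteria screening of composite candidates.

The engine formalizes a screening narrative: hard filters first (e.g. drop
P-glycoprotein substrates, whose oral bioavailability is compromised by
active efflux), then per-criterion min–max normalization to [0, 1] with the
preference direction applied, a weighted total, a Pareto front over the
directed criteria, and a deterministic top-k selection.

The default configuration encodes the preference directions a composite
food-additive screen argues from — band gap ↑ (kinetic stability), binding
energy ↓ (association strength), dipole ↑ (hydrogen-bonding propensity),
entropy ↓ (conformational predictability), heat capacity ↑ (thermal
tolerance), TPSA ↓ and logP ↑ (absorption) — with weights calibrated to
reproduce the reference dataset's two-winner verdict.  The weights are an
explicit, fully overridable modeling choice, not an objective utility
function.
"""

from __future__ import annotations

from typing import Literal, Optional

import pandas as pd
from pydantic import BaseModel, Field

__all__ = [
    "Criterion",
    "HardFilter",
    "ScreeningConfig",
    "ScreeningReport",
    "default_config",
    "apply_hard_filters",
    "normalize_scores",
    "pareto_front",
    "screen",
]


class Criterion(BaseModel):
    """One scored screening criterion over a candidate-table column."""

    name: str
    direction: Literal["higher_better", "lower_better"]
    weight: float = Field(ge=0.0)


class HardFilter(BaseModel):
    """Equality predicate a candidate must satisfy to stay in the ranking."""

    name: str
    field: str
    equals: object


class ScreeningConfig(BaseModel):
    criteria: list[Criterion]
    hard_filters: list[HardFilter] = []
    top_k: int = 2
    seed: Optional[int] = None

    def normalized_weights(self) -> dict[str, float]:
        total = sum(c.weight for c in self.criteria)
        if total <= 0:
            raise ValueError("criterion weights must sum to a positive value")
        return {c.name: c.weight / total for c in self.criteria}


class ScreeningReport(BaseModel):
    """Outcome of one screening run (deterministic for fixed inputs/config)."""

    excluded: list[tuple[str, str]]  # (pose_id, filter name)
    scores: dict[str, dict[str, float]]  # pose -> criterion -> [0,1] score
    weighted_total: dict[str, float]
    ranking: list[str]
    pareto_front: list[str]
    selected: list[str]
    config: ScreeningConfig


def default_config(seed: int | None = None) -> ScreeningConfig:
    """Default screen: Pgp hard filter plus seven weighted criteria.

    The weight vector is calibrated to reproduce the bundled reference
    verdict and should be treated as a starting point, not a ground truth.
    """
    return ScreeningConfig(
        criteria=[
            Criterion(name="gap", direction="higher_better", weight=0.20),
            Criterion(name="binding_energy", direction="lower_better", weight=0.20),
            Criterion(name="dipole", direction="higher_better", weight=0.10),
            Criterion(name="entropy", direction="lower_better", weight=0.15),
            Criterion(name="heat_capacity", direction="higher_better", weight=0.05),
            Criterion(name="tpsa", direction="lower_better", weight=0.15),
            Criterion(name="logp", direction="higher_better", weight=0.15),
        ],
        hard_filters=[
            HardFilter(name="pgp_non_substrate", field="pgp_substrate", equals=False)
        ],
        top_k=2,
        seed=seed,
    )


def _check_fields(candidates: pd.DataFrame, fields: list[str], what: str) -> None:
    missing = [f for f in fields if f not in candidates.columns]
    if missing:
        raise KeyError(f"{what} reference missing candidate fields: {missing}")


def apply_hard_filters(
    candidates: pd.DataFrame, filters: list[HardFilter]
) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Split candidates into (kept, excluded-with-filter-name).

    ``candidates`` is indexed by pose/candidate id.
    """
    _check_fields(candidates, [f.field for f in filters], "hard filter")
    excluded: list[tuple[str, str]] = []
    keep_mask = pd.Series(True, index=candidates.index)
    for flt in filters:
        failing = candidates.index[candidates[flt.field] != flt.equals]
        for pose in failing:
            if keep_mask[pose]:
                excluded.append((pose, flt.name))
        keep_mask &= candidates[flt.field] == flt.equals
    return candidates[keep_mask], excluded


def normalize_scores(
    candidates: pd.DataFrame, criteria: list[Criterion]
) -> pd.DataFrame:
    """Directed min–max normalization of each criterion column to [0, 1].

    higher_better maps to (x − min)/(max − min), lower_better to the reverse;
    a constant column maps to 0.5 everywhere (weight-neutral in differences).
    """
    _check_fields(candidates, [c.name for c in criteria], "criterion")
    scores = {}
    for criterion in criteria:
        col = candidates[criterion.name].astype(float)
        span = col.max() - col.min()
        if span == 0:
            scores[criterion.name] = pd.Series(0.5, index=col.index)
        elif criterion.direction == "higher_better":
            scores[criterion.name] = (col - col.min()) / span
        else:
            scores[criterion.name] = (col.max() - col) / span
    return pd.DataFrame(scores)


def pareto_front(candidates: pd.DataFrame, criteria: list[Criterion]) -> list[str]:
    """Ids of candidates not dominated on the directed criteria.

    A dominates B when A is at least as good on every criterion and strictly
    better on at least one.
    """
    _check_fields(candidates, [c.name for c in criteria], "criterion")
    # orient every column so that larger is better
    oriented = pd.DataFrame(
        {
            c.name: candidates[c.name].astype(float)
            * (1.0 if c.direction == "higher_better" else -1.0)
            for c in criteria
        }
    )
    ids = list(candidates.index)
    front = []
    for a in ids:
        dominated = False
        for b in ids:
            if a == b:
                continue
            diff = oriented.loc[b] - oriented.loc[a]
            if (diff >= 0).all() and (diff > 0).any():
                dominated = True
                break
        if not dominated:
            front.append(a)
    return front


def screen(candidates: pd.DataFrame, config: ScreeningConfig) -> ScreeningReport:
    """Run the full screen: filter, normalize, weight, rank, select top-k.

    ``candidates`` must be indexed by candidate id and carry every column the
    configured criteria and hard filters reference.  Ties in the weighted
    total break on ascending candidate id; the report is identical for any
    permutation of the input rows.
    """
    candidates = candidates.sort_index(kind="mergesort")
    kept, excluded = apply_hard_filters(candidates, config.hard_filters)
    if kept.empty:
        return ScreeningReport(
            excluded=excluded,
            scores={},
            weighted_total={},
            ranking=[],
            pareto_front=[],
            selected=[],
            config=config,
        )
    scores = normalize_scores(kept, config.criteria)
    weights = config.normalized_weights()
    totals = sum(scores[name] * w for name, w in weights.items())
    ranking = sorted(kept.index, key=lambda pose: (-totals[pose], pose))
    return ScreeningReport(
        excluded=excluded,
        scores={pose: scores.loc[pose].to_dict() for pose in kept.index},
        weighted_total={pose: float(totals[pose]) for pose in kept.index},
        ranking=ranking,
        pareto_front=pareto_front(kept, config.criteria),
        selected=ranking[: config.top_k],
        config=config,
    )
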