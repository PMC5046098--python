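"""Observer preference pairs and inter-rater agreement statistics.

For each correspondence group the best- and worst-VQM branches form one
preference pair, displayed side by side with randomized left/right placement
so the rater cannot infer the computer's choice from position.  A rater picks
the side with the better-looking vessel; agreement between raters (or between
a rater and the automated selection) is summarized by percent agreement and
Cohen's kappa on the left/right choices, with kappa binned into the customary
Landis-Koch categories.

Overall percent agreement across cases pools the per-case agreement counts
(count-weighted); the overall kappa is the unweighted mean of per-case kappas.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .vqm import SelectionResult

__all__ = [
    "PreferencePair",
    "RaterResponse",
    "AgreementSummary",
    "make_preference_pairs",
    "computer_responses",
    "simulate_rater",
    "percent_agreement",
    "cohens_kappa",
    "contingency_table",
    "kappa_category",
    "aggregate_overall",
    "average_kappa",
]

log = logging.getLogger(__name__)


@dataclass
class PreferencePair:
    """One best/worst image pair with its randomized left/right placement."""

    pair_id: int  # the correspondence group id
    left: tuple[str, str]  # (phase, branch id)
    right: tuple[str, str]
    computer_best_side: str  # "left" | "right"
    seed: int

    def __post_init__(self):
        if self.left == self.right:
            raise ValueError("a pair must hold two distinct members")
        if self.computer_best_side not in ("left", "right"):
            raise ValueError("computer_best_side must be 'left' or 'right'")


@dataclass
class RaterResponse:
    """One rater's choice of the better-quality side for one pair."""

    pair_id: int
    chosen_side: str  # "left" | "right"
    rater_id: str = ""

    def __post_init__(self):
        if self.chosen_side not in ("left", "right"):
            raise ValueError("chosen_side must be 'left' or 'right'")


@dataclass
class AgreementSummary:
    """Per-case and overall agreement between two raters."""

    per_case_n: list[int]
    per_case_percent: list[float]
    per_case_kappa: list[float]
    per_case_category: list[str]
    overall_percent: int
    overall_kappa: float
    overall_category: str


def make_preference_pairs(
    selections: Sequence[SelectionResult], seed: int
) -> list[PreferencePair]:
    """One randomized best/worst pair per pairable selection.

    Side assignment is a seeded coin flip per pair; the same seed reproduces
    the layout exactly.  Non-pairable selections (single-member groups) are
    skipped with a log entry.
    """
    rng = np.random.default_rng(seed)
    pairs = []
    for sel in selections:
        if not sel.pairable:
            log.info("group %s has a single member; skipped from pairing", sel.group_id)
            continue
        best_left = bool(rng.integers(0, 2))
        left, right = (sel.best, sel.worst) if best_left else (sel.worst, sel.best)
        pairs.append(
            PreferencePair(
                pair_id=sel.group_id,
                left=left,
                right=right,
                computer_best_side="left" if best_left else "right",
                seed=seed,
            )
        )
    return pairs


def computer_responses(pairs: Sequence[PreferencePair]) -> list[RaterResponse]:
    """The automated selection expressed as left/right choices."""
    return [RaterResponse(p.pair_id, p.computer_best_side, "computer") for p in pairs]


def simulate_rater(
    pairs: Sequence[PreferencePair],
    true_best: dict[int, tuple[str, str]],
    p_correct: float,
    seed: int,
    rater_id: str = "sim",
) -> list[RaterResponse]:
    """A synthetic observer who picks the truly better image with probability p.

    ``true_best`` maps pair id to the (phase, branch id) that is genuinely
    better (e.g. the less blurred phantom phase).  With probability
    1 - p_correct the opposite side is chosen, modelling perceptual noise.
    """
    if not 0 <= p_correct <= 1:
        raise ValueError("p_correct must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    responses = []
    for pair in pairs:
        if true_best[pair.pair_id] == pair.left:
            good_side, bad_side = "left", "right"
        elif true_best[pair.pair_id] == pair.right:
            good_side, bad_side = "right", "left"
        else:
            raise ValueError(f"true best of pair {pair.pair_id} is on neither side")
        side = good_side if rng.random() < p_correct else bad_side
        responses.append(RaterResponse(pair.pair_id, side, rater_id))
    return responses


def _aligned_choices(a: Sequence[RaterResponse], b: Sequence[RaterResponse]):
    da = {r.pair_id: r.chosen_side for r in a}
    db = {r.pair_id: r.chosen_side for r in b}
    if set(da) != set(db):
        raise ValueError("response lists cover different pair ids")
    ids = sorted(da)
    return [da[i] for i in ids], [db[i] for i in ids]


def percent_agreement(a: Sequence[RaterResponse], b: Sequence[RaterResponse]) -> float:
    """Fraction of pairs on which both raters chose the same side (in [0, 1])."""
    ca, cb = _aligned_choices(a, b)
    return sum(x == y for x, y in zip(ca, cb)) / len(ca)


def contingency_table(a: Sequence[RaterResponse], b: Sequence[RaterResponse]) -> np.ndarray:
    """2x2 table of side choices: rows = rater a (left, right), cols = rater b."""
    ca, cb = _aligned_choices(a, b)
    table = np.zeros((2, 2), dtype=int)
    for x, y in zip(ca, cb):
        table[int(x == "right"), int(y == "right")] += 1
    return table


def cohens_kappa(table) -> float:
    """Chance-corrected agreement from a 2x2 contingency table.

    kappa = (Po - Pe) / (1 - Pe) with Po the observed agreement fraction and
    Pe the chance agreement from the row/column marginals.  Perfect observed
    agreement gives kappa = 1 by convention even when Pe = 1.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValueError("table must be 2x2 with non-negative cells")
    n = t.sum()
    if n == 0:
        raise ValueError("empty contingency table")
    po = (t[0, 0] + t[1, 1]) / n
    rows = t.sum(axis=1) / n
    cols = t.sum(axis=0) / n
    pe = float(rows @ cols)
    if po >= 1.0:
        return 1.0
    return float((po - pe) / (1.0 - pe))


_KAPPA_BINS = [
    (-1.0, 0.0, "Less than chance"),
    (0.0, 0.20, "Slight"),
    (0.20, 0.40, "Fair"),
    (0.40, 0.60, "Moderate"),
    (0.60, 0.80, "Substantial"),
    (0.80, 1.0, "Almost perfect"),
]


def kappa_category(kappa: float) -> str:
    """Landis-Koch agreement category for a kappa value.

    Bins: < 0 less than chance; (0, 0.20] slight; (0.20, 0.40] fair;
    (0.40, 0.60] moderate; (0.60, 0.80] substantial; (0.80, 1] almost
    perfect.  Exactly 0 maps to "Slight" (the published bins start at 0.01).
    """
    if not -1.0 <= kappa <= 1.0:
        raise ValueError("kappa must lie in [-1, 1]")
    if kappa < 0:
        return "Less than chance"
    if kappa == 0:
        return "Slight"
    for lo, hi, label in _KAPPA_BINS[1:]:
        if lo < kappa <= hi:
            return label
    return "Almost perfect"


def aggregate_overall(per_case_percent: Sequence[float], per_case_n: Sequence[int]) -> int:
    """Pooled percent agreement over cases from rounded per-case percentages.

    Per-case agreement counts are recovered as round(percent * n / 100),
    summed, and divided by the total pair count; the result is reported as a
    rounded integer percent.
    """
    if len(per_case_percent) != len(per_case_n):
        raise ValueError("per-case lists must have equal length")
    if any(n <= 0 for n in per_case_n):
        raise ValueError("pair counts must be positive")
    counts = [int(np.floor(p * n / 100.0 + 0.5)) for p, n in zip(per_case_percent, per_case_n)]
    total = sum(per_case_n)
    return int(np.floor(100.0 * sum(counts) / total + 0.5))


def average_kappa(per_case_kappa: Sequence[float]) -> float:
    """Unweighted mean of per-case kappas, rounded to 2 decimals for reporting."""
    if len(per_case_kappa) == 0:
        raise ValueError("empty kappa list")
    return float(np.floor(np.mean(per_case_kappa) * 100 + 0.5) / 100)
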