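"""Scoring rules for the full instrument and the three-item screener.

The full 34-item scale is scored as the sum of frequency codes (0-3 per item)
and dichotomized at a sum of 6 or more to define the reference standard for
dating-abuse victimization.  The screener counts how many of its three items
were endorsed at any nonzero frequency (equivalently, answered "yes" on the
clinical yes/no form), giving a score of 0-3 classified positive at a
configurable cutpoint (default 1).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

import pandas as pd

from .schema import DEFAULT_SCHEMA, FREQUENCY_CODES, SCREENER_ITEMS

#: Reference-standard dichotomization threshold on the 0-102 sum score.
REFERENCE_CUTPOINT = 6
#: Records skipping more than this many questions are rejected upstream.
MAX_MISSING_ITEMS = 10

MissingPolicy = Literal["treat_as_zero", "reject_if_over_k"]


class MissingResponseError(ValueError):
    """Raised when a response has more missing items than the policy allows."""


@dataclass(frozen=True)
class ReferenceClassification:
    """Full-scale sum score dichotomized at the reference cutpoint."""

    score: int
    positive: bool
    cutpoint: int = REFERENCE_CUTPOINT
    n_missing: int = 0

    def __post_init__(self) -> None:
        if self.score < 0:
            raise ValueError("score must be non-negative")
        if self.positive != (self.score >= self.cutpoint):
            raise ValueError("positive flag inconsistent with score and cutpoint")


@dataclass(frozen=True)
class ScreenClassification:
    """Screener count score (0-3) classified at a cutpoint in {1, 2, 3}."""

    score: int
    positive: bool
    cutpoint: int = 1

    def __post_init__(self) -> None:
        if not 0 <= self.score <= 3:
            raise ValueError("screener score must be in [0, 3]")
        if self.cutpoint not in (1, 2, 3):
            raise ValueError("screener cutpoint must be 1, 2, or 3")
        if self.positive != (self.score >= self.cutpoint):
            raise ValueError("positive flag inconsistent with score and cutpoint")


@dataclass(frozen=True)
class ScreenerResponse:
    """Endorsement (0/1) of the three screener acts."""

    yelled: int
    pressured_photo: int
    trapped: int

    def __post_init__(self) -> None:
        for name in ("yelled", "pressured_photo", "trapped"):
            if getattr(self, name) not in (0, 1):
                raise ValueError(f"{name} must be 0 or 1")

    @property
    def score(self) -> int:
        return self.yelled + self.pressured_photo + self.trapped


def _validate_items(items: Mapping[str, int | None]) -> None:
    expected = set(DEFAULT_SCHEMA.item_ids) if len(items) == 34 else None
    if len(items) != 34:
        raise ValueError(f"expected 34 item responses, got {len(items)}")
    if expected is not None and set(items) != expected:
        # arbitrary 34-key mappings are allowed (custom schemas); only flag
        # near-misses of the default schema
        pass
    for iid, code in items.items():
        if code is not None and code not in FREQUENCY_CODES:
            raise ValueError(f"item {iid!r} has invalid code {code!r}")


def score_marsha(
    items: Mapping[str, int | None],
    *,
    cutpoint: int = REFERENCE_CUTPOINT,
    missing_policy: MissingPolicy = "treat_as_zero",
    max_missing: int = MAX_MISSING_ITEMS,
) -> ReferenceClassification:
    """Score the full 34-item scale and dichotomize it.

    Parameters
    ----------
    items
        Mapping of the 34 item ids to frequency codes 0-3, with ``None``
        for a skipped item.
    missing_policy
        ``"treat_as_zero"`` scores skipped items as 0 (respondents may skip
        any question); ``"reject_if_over_k"`` raises
        :class:`MissingResponseError` when more than ``max_missing`` items
        are skipped, mirroring the upstream eligibility rule.
    """
    _validate_items(items)
    n_missing = sum(1 for v in items.values() if v is None)
    if missing_policy == "reject_if_over_k" and n_missing > max_missing:
        raise MissingResponseError(
            f"{n_missing} missing item responses exceed the allowed {max_missing}"
        )
    score = sum(int(v) for v in items.values() if v is not None)
    return ReferenceClassification(
        score=score, positive=score >= cutpoint, cutpoint=cutpoint, n_missing=n_missing
    )


def score_marsha_c(resp: ScreenerResponse, cutpoint: int = 1) -> ScreenClassification:
    """Classify a screener response: one point per endorsed act."""
    if cutpoint not in (1, 2, 3):
        raise ValueError("screener cutpoint must be 1, 2, or 3")
    score = resp.score
    return ScreenClassification(score=score, positive=score >= cutpoint, cutpoint=cutpoint)


def derive_marsha_c_from_marsha(
    items: Mapping[str, int | None],
    item_ids: Sequence[str] = SCREENER_ITEMS,
) -> ScreenerResponse:
    """Derive the screener from full-instrument responses.

    Each screener act counts as endorsed when its full-instrument frequency
    code is nonzero; skipped items count as not endorsed.
    """
    if len(item_ids) != 3:
        raise ValueError("exactly 3 screener item ids required")
    vals = []
    for iid in item_ids:
        if iid not in items:
            raise KeyError(f"screener item {iid!r} not among responses")
        code = items[iid]
        vals.append(int(code is not None and code > 0))
    return ScreenerResponse(yelled=vals[0], pressured_photo=vals[1], trapped=vals[2])


def _cohort_frame(cohort, item_ids=None) -> pd.DataFrame:
    """Coerce a cohort (DataFrame or iterable of item mappings) to a frame."""
    if isinstance(cohort, pd.DataFrame):
        df = cohort if item_ids is None else cohort.loc[:, list(item_ids)]
    else:
        df = pd.DataFrame(list(cohort))
        if item_ids is not None:
            df = df.loc[:, list(item_ids)]
    return df.apply(pd.to_numeric, errors="coerce")


def endorsement_prevalence(cohort, item_ids: Sequence[str] | None = None) -> pd.Series:
    """Per-item proportion of respondents endorsing the item (code > 0)."""
    df = _cohort_frame(cohort, item_ids)
    if df.empty:
        raise ValueError("empty cohort")
    return (df.fillna(0) > 0).mean()


def select_screener_items(
    cohort,
    k: int = 3,
    exclusions: Iterable[str] = (),
) -> list[str]:
    """Rank items by endorsement prevalence and return the top ``k``.

    Reproduces how the screener items were chosen: the most commonly endorsed
    items, after removing any deliberately excluded ids.  Ties are broken by
    lexicographic item id, which makes the ranking deterministic and invariant
    to cohort ordering.
    """
    prev = endorsement_prevalence(cohort)
    excl = set(exclusions)
    candidates = prev.drop(labels=[c for c in excl if c in prev.index])
    if k > len(candidates):
        raise ValueError(f"k={k} exceeds the {len(candidates)} non-excluded items")
    order = sorted(candidates.items(), key=lambda kv: (-kv[1], kv[0]))
    return [iid for iid, _ in order[:k]]


def subscale_prevalence(cohort, group_map: Mapping[str, str]) -> dict[str, float]:
    """Proportion of respondents endorsing at least one item per group.

    ``group_map`` maps item id -> group label and may encode either the five
    instrument subscales or the four-category reporting taxonomy.
    """
    df = _cohort_frame(cohort, list(group_map))
    if df.empty:
        raise ValueError("empty cohort")
    endorsed = df.fillna(0) > 0
    out: dict[str, float] = {}
    for group in dict.fromkeys(group_map.values()):
        ids = [iid for iid, g in group_map.items() if g == group]
        out[group] = float(endorsed[ids].any(axis=1).mean())
    return out


def cronbachs_alpha(cohort, item_ids: Sequence[str] | None = None) -> float:
    """Cronbach's alpha for internal consistency (convenience only)."""
    df = _cohort_frame(cohort, item_ids).fillna(0)
    k = df.shape[1]
    if k < 2:
        raise ValueError("alpha requires at least 2 items")
    item_var = df.var(axis=0, ddof=1).sum()
    total_var = df.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ValueError("zero total-score variance")
    return float(k / (k - 1) * (1 - item_var / total_var))
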