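"""Sum-score composites for substantive and style constructs.

The traditional measure of a construct d is the per-person total of recoded
responses, v_d = sum_j s_jd[y_j]: with the trait codes 0..K-1 this is the
ordinary sum score, with an endpoint indicator it counts extreme responses,
and so on.  These composites are what the model-based scores are compared
against.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .model import ResponseMatrix, ScoringFunctionSet

__all__ = ["SumScoreVector", "sum_score", "possible_scores"]


@dataclass(frozen=True)
class SumScoreVector:
    """Per-person sum of recoded responses on one dimension.

    ``scores`` holds the sum over *observed* items; ``n_missing`` the number
    of items that did not contribute.  No imputation or proration is done:
    persons with missing items are simply flagged.
    """

    dimension: str
    scores: np.ndarray
    n_missing: np.ndarray
    person_ids: list[str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {f"v_{self.dimension}": self.scores, "n_missing": self.n_missing},
            index=self.person_ids,
        )


def sum_score(
    responses: ResponseMatrix, s: ScoringFunctionSet, d: int | str
) -> SumScoreVector:
    """Sum of recoded responses v_id = sum_j s_jd[y_ij] per person.

    Missing items contribute nothing to the sum and are counted in
    ``n_missing``.
    """
    if isinstance(d, str):
        d = s.dim_index(d)
    if responses.n_items != s.n_items:
        raise ValidationError(
            f"{responses.n_items} response columns but scoring functions "
            f"for {s.n_items} items"
        )
    recoded = np.full(responses.data.shape, np.nan)
    for j in range(s.n_items):
        col = responses.data[:, j]
        obs = ~np.isnan(col)
        recoded[obs, j] = s.vector(j, d)[col[obs].astype(int)]
    miss = np.isnan(recoded)
    with np.errstate(invalid="ignore"):
        totals = np.nansum(np.where(miss, 0.0, recoded), axis=1)
    return SumScoreVector(
        dimension=s.labels[d],
        scores=totals,
        n_missing=miss.sum(axis=1),
        person_ids=list(responses.person_ids),
    )


def possible_scores(s: ScoringFunctionSet, d: int | str) -> np.ndarray:
    """Ordered distinct attainable sum scores on dimension d.

    Accumulates the set of attainable totals item by item from each item's
    distinct codes (a dynamic-programming sweep, so n binary-coded items
    yield 0..n without enumerating 2^n patterns).  Requires integer codes;
    real-valued codes have no natural score index and are handled by the
    scoring module's exact-sum enumeration instead.
    """
    if isinstance(d, str):
        d = s.dim_index(d)
    for j in range(s.n_items):
        v = s.vector(j, d)
        if not np.all(v == np.round(v)):
            raise ValidationError(
                f"item {j}: non-integer scoring codes on {s.labels[d]!r}; "
                "enumerate attainable real-valued sums via "
                "scoring.summed_score_likelihood instead"
            )
    sums = {0.0}
    for j in range(s.n_items):
        codes = np.unique(s.vector(j, d))
        sums = {t + m for t, m in itertools.product(sums, codes)}
    return np.array(sorted(sums))
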