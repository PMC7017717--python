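"""Latent-trait scoring: response-pattern EAPs and sum-score-to-EAP tables.

Two score types are produced from a fitted (or supplied) model:

* **Pattern EAP** — the posterior mean of the latent traits given a person's
  full response pattern, with the posterior SD as a conditional standard
  error.  Persons with identical patterns get identical scores; persons with
  equal sum scores need not.

* **Sum-score EAP** — the posterior mean of one target trait eta given only
  the sum score v_d of recoded responses on that dimension.  The likelihood
  L_d(v_d | eta, xi) of each attainable sum score at each quadrature node is
  accumulated item-by-item with a polytomous Lord-Wingersky recursion over
  the collapsed (recoded) response functions; multiplying by the grid
  weights and summing over the nuisance dimensions xi yields the marginal
  score probabilities p(v_d) and the conditional moments E(eta | v_d) and
  V(eta | v_d), tabulated once as a translation table and then applied by
  lookup.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .errors import ValidationError
from .estimation import _pattern_logL
from .grid import LatentGrid, build_grid
from .model import ItemParameters, MNRMModel, ResponseMatrix, ScoringFunctionSet
from .sumscores import sum_score

__all__ = [
    "PatternScore",
    "SumScoreLikelihood",
    "TranslationTable",
    "pattern_eap",
    "summed_score_likelihood",
    "translation_table",
    "score_by_sum",
    "compare_scores",
    "ScoreComparison",
]

#: decimals used to merge floating-point sum-score keys in the recursion
_SUM_DECIMALS = 9


@dataclass(frozen=True)
class PatternScore:
    """Per-person EAP vector and posterior SD vector (latent-trait units)."""

    eap: np.ndarray  # (N, D)
    sd: np.ndarray  # (N, D)
    labels: list[str]
    person_ids: list[str]
    all_missing: np.ndarray  # (N,) flag: prior returned, nothing observed

    def to_frame(self) -> pd.DataFrame:
        cols = {}
        for d, lab in enumerate(self.labels):
            cols[f"EAP_{lab}"] = self.eap[:, d]
            cols[f"SD_{lab}"] = self.sd[:, d]
        cols["all_missing"] = self.all_missing
        return pd.DataFrame(cols, index=self.person_ids)


@dataclass(frozen=True)
class SumScoreLikelihood:
    """L_d(v | x) for every attainable sum score v and grid node x."""

    dimension: str
    scores: np.ndarray  # (V,) attainable sums, ascending
    L: np.ndarray  # (V, Q)
    grid: LatentGrid
    target_dim: int


@dataclass(frozen=True)
class TranslationTable:
    """Sum-score-to-EAP table for one dimension.

    Rows are indexed by attainable sum score v: marginal probability p(v),
    EAP E(eta | v), variance V(eta | v) and SD.  ``kernel`` retains the
    nuisance-marginalized weight sum_xi L(v | eta, xi) W(x) per distinct
    eta node (columns ``eta_nodes``).
    """

    dimension: str
    scores: np.ndarray
    p: np.ndarray
    eap: np.ndarray
    var: np.ndarray
    eta_nodes: np.ndarray
    kernel: np.ndarray  # (V, n_eta)

    @property
    def sd(self) -> np.ndarray:
        return np.sqrt(self.var)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                f"v_{self.dimension}": self.scores,
                "p": self.p,
                "EAP": self.eap,
                "SD": self.sd,
            }
        )


def pattern_eap(
    model: MNRMModel, grid: LatentGrid, responses: ResponseMatrix
) -> PatternScore:
    """EAP and posterior SD per person from the full response pattern.

    EAP_d = sum_x x_d L(y|x) W(x) / sum_x L(y|x) W(x); the SD comes from the
    corresponding posterior second moment.  Missing items are skipped; a
    person with no observed items gets the prior mean and SD, flagged.
    """
    ll = _pattern_logL(model.items, model.scoring, grid, responses)
    joint = ll + np.log(grid.weights)
    norm = logsumexp(joint, axis=1)
    post = np.exp(joint - norm[:, None])  # (N, Q)
    eap = post @ grid.nodes
    second = post @ grid.nodes**2
    var = np.maximum(second - eap**2, 0.0)
    return PatternScore(
        eap=eap,
        sd=np.sqrt(var),
        labels=list(model.labels),
        person_ids=list(responses.person_ids),
        all_missing=responses.missing_mask.all(axis=1),
    )


def _collapsed_at_nodes(
    item: ItemParameters, s_j: np.ndarray, d: int, nodes: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Distinct recoded values of item on dimension d and their
    probabilities at every node: (values (M,), probs (Q x M))."""
    from .estimation import _item_logT

    T = np.exp(_item_logT(item, s_j, nodes))  # (Q, K)
    values, inverse = np.unique(s_j[:, d], return_inverse=True)
    probs = np.zeros((nodes.shape[0], values.size))
    for k, m in enumerate(inverse):
        probs[:, m] += T[:, k]
    return values, probs


def summed_score_likelihood(
    model: MNRMModel, s: ScoringFunctionSet, d: int | str, grid: LatentGrid
) -> SumScoreLikelihood:
    """Lord-Wingersky recursion over items for dimension d.

    Starts from item 1's collapsed response function and, for each further
    item, convolves the accumulated table with that item's collapsed
    probabilities:  L_j(v | x) = sum_m T_jd(m | x) L_{j-1}(v - m | x).
    Sum-score keys are exact attainable totals (dictionary accumulation),
    so arbitrary real-valued codes are supported, not just 0..m offsets.
    """
    if isinstance(d, str):
        d = s.dim_index(d)
    Q = grid.n_nodes
    table: dict[float, np.ndarray] = {}
    first = True
    for j, item in enumerate(model.items):
        values, probs = _collapsed_at_nodes(item, s.for_item(j), d, grid.nodes)
        if not np.all(np.isfinite(values)):
            raise ValidationError(f"item {j}: non-finite recoded values")
        if first:
            table = {round(float(m), _SUM_DECIMALS): probs[:, i].copy()
                     for i, m in enumerate(values)}
            first = False
            continue
        new: dict[float, np.ndarray] = {}
        for v, Lv in table.items():
            for i, m in enumerate(values):
                key = round(v + float(m), _SUM_DECIMALS)
                if key in new:
                    new[key] += Lv * probs[:, i]
                else:
                    new[key] = Lv * probs[:, i]
        table = new
    scores = np.array(sorted(table))
    L = np.vstack([table[v] for v in scores]) if scores.size else np.empty((0, Q))
    return SumScoreLikelihood(
        dimension=s.labels[d], scores=scores, L=L, grid=grid, target_dim=d
    )


def translation_table(
    model: MNRMModel,
    s: ScoringFunctionSet,
    d: int | str,
    grid: LatentGrid | None = None,
) -> TranslationTable:
    """Sum-score-to-EAP translation table for dimension d.

    Multiplies the summed-score likelihood by the grid weights, sums over
    the nuisance dimensions to get the marginal kernel in eta, and takes
    weighted node moments:  p(v) = sum_x L(v|x) W(x),
    E(eta|v) = sum_eta eta k_v(eta) / p(v), V by the second moment.
    Unattainable rows (p = 0) are kept with NaN moments rather than divided
    by zero.
    """
    if isinstance(d, str):
        d = s.dim_index(d)
    if grid is None:
        grid = build_grid(49, -6.0, 6.0, R=model.R)
    ssl = summed_score_likelihood(model, s, d, grid)
    weighted = ssl.L * grid.weights  # (V, Q)
    eta_nodes = grid.axes[d]
    idx = grid.axis_index(d)
    kernel = np.zeros((ssl.scores.size, eta_nodes.size))
    for col, e in enumerate(idx):
        kernel[:, e] += weighted[:, col]
    p = kernel.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        eap = np.where(p > 0, kernel @ eta_nodes / p, np.nan)
        second = np.where(p > 0, kernel @ eta_nodes**2 / p, np.nan)
    var = second - eap**2
    return TranslationTable(
        dimension=ssl.dimension,
        scores=ssl.scores,
        p=p,
        eap=eap,
        var=var,
        eta_nodes=eta_nodes,
        kernel=kernel,
    )


def score_by_sum(table: TranslationTable, v: float) -> tuple[float, float]:
    """Look up (EAP, SD) for sum score v; deterministic by construction."""
    key = round(float(v), _SUM_DECIMALS)
    matches = np.where(np.round(table.scores, _SUM_DECIMALS) == key)[0]
    if matches.size == 0 or not np.isfinite(table.p[matches[0]]) or table.p[matches[0]] <= 0:
        lo, hi = table.scores.min(), table.scores.max()
        raise ValidationError(
            f"sum score {v!r} not attainable on {table.dimension!r}; "
            f"attainable scores lie in [{lo:g}, {hi:g}]: "
            f"{np.round(table.scores, 6).tolist()}"
        )
    i = int(matches[0])
    return float(table.eap[i]), float(np.sqrt(table.var[i]))


@dataclass(frozen=True)
class ScoreComparison:
    """Per-person scores under all three methods plus their correlations."""

    scores: pd.DataFrame  # columns v_<dim>, ssEAP_<dim>, EAP_<dim>
    pearson: pd.DataFrame
    spearman: pd.DataFrame
    tables: dict[str, TranslationTable]


def compare_scores(
    responses: ResponseMatrix,
    model: MNRMModel,
    s: ScoringFunctionSet,
    grid: LatentGrid | None = None,
) -> ScoreComparison:
    """Compare sum scores, sum-score EAPs, and pattern EAPs per dimension.

    One translation run is performed per target dimension (the model is
    never altered between runs; only the dimension treated as eta changes).
    Persons with missing items have no defined sum score and get NaN for
    the sum-score-based columns.
    """
    if grid is None:
        grid = build_grid(49, -6.0, 6.0, R=model.R)
    pat = pattern_eap(model, grid, responses)
    cols: dict[str, np.ndarray] = {}
    tables: dict[str, TranslationTable] = {}
    for d, lab in enumerate(s.labels):
        ss = sum_score(responses, s, d)
        tables[lab] = translation_table(model, s, d, grid)
        ss_eap = np.full(responses.n_persons, np.nan)
        complete = ss.n_missing == 0
        for i in np.where(complete)[0]:
            ss_eap[i] = score_by_sum(tables[lab], ss.scores[i])[0]
        cols[f"v_{lab}"] = np.where(complete, ss.scores, np.nan)
        cols[f"ssEAP_{lab}"] = ss_eap
        cols[f"EAP_{lab}"] = pat.eap[:, d]
    frame = pd.DataFrame(cols, index=responses.person_ids)
    pearson = frame.corr(method="pearson")
    spearman = frame.corr(method="spearman")
    return ScoreComparison(
        scores=frame, pearson=pearson, spearman=spearman, tables=tables
    )
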