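"""Built-in worked example: three quality-of-life items with QOL and ERS.

A small, fully specified model used throughout the documentation and tests:
three 7-category items loading on a substantive quality-of-life trait (QOL,
scoring codes 0..6) and extreme response style (ERS, endpoint indicator),
with latent correlation -0.18, plus a tiny 3 x 3 quadrature grid (QOL nodes
-1, 0, 1; ERS nodes -2, 0, 2) on which every scoring quantity can be
followed by hand.  ``expected`` carries the hand-checked reference values
for these fixtures, rounded to the precision at which the item parameters
are stated; regression tests and the ``worked-example`` CLI diff against
them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import LatentGrid, build_grid
from .model import ItemParameters, MNRMModel, ScoringFunctionSet

__all__ = ["WorkedExample", "worked_example"]

#: dimension order of the worked example
QOL, ERS = 0, 1


@dataclass(frozen=True)
class WorkedExample:
    """Fixture bundle for the three-item QOL + ERS example."""

    model: MNRMModel
    scoring: ScoringFunctionSet
    grid: LatentGrid  # 3 x 3 grid: QOL in {-1,0,1}, ERS in {-2,0,2}
    example_item: ItemParameters  # item 2, used for single-item illustrations
    expected: dict

    def node_index(self, qol: float, ers: float) -> int:
        """Index of the grid node at (x_QOL, x_ERS)."""
        m = np.where(
            (self.grid.nodes[:, QOL] == qol) & (self.grid.nodes[:, ERS] == ers)
        )[0]
        if m.size != 1:
            raise KeyError(f"no grid node at QOL={qol}, ERS={ers}")
        return int(m[0])


def worked_example() -> WorkedExample:
    """Build the worked-example fixtures.

    Parameters are stated to two decimals; reference values derived from
    them are reproducible to roughly +/- 0.005 in probabilities (one unit in
    the second decimal), which is the precision asserted by the regression
    tests.
    """
    items = [
        ItemParameters(a=[0.80, 1.68], c=[0.00, 1.84, 2.39, 3.57, 3.94, 3.64, 2.49]),
        ItemParameters(a=[0.46, 1.03], c=[0.00, 1.16, 1.17, 2.56, 2.89, 2.96, 2.72]),
        ItemParameters(a=[0.49, 1.49], c=[0.00, 1.50, 1.97, 2.30, 2.95, 2.65, 1.61]),
    ]
    scoring = ScoringFunctionSet.from_templates(
        ["QOL", "ERS"], ["trait", "ers"], [7, 7, 7]
    )
    R = np.array([[1.0, -0.18], [-0.18, 1.0]])
    model = MNRMModel(items=items, scoring=scoring, R=R)
    grid = build_grid(nodes=[np.array([-1.0, 0.0, 1.0]),
                             np.array([-2.0, 0.0, 2.0])], R=R)

    expected = {
        # single-item category probabilities for item 2 at six latent points,
        # rows keyed by (x_QOL, x_ERS), 2 dp
        "category_probs": {
            (-3, -3): [0.03, 0.60, 0.15, 0.15, 0.05, 0.01, 0.00],
            (0, -3): [0.00, 0.06, 0.06, 0.22, 0.31, 0.34, 0.01],
            (3, -3): [0.00, 0.00, 0.00, 0.03, 0.16, 0.70, 0.10],
            (-3, 3): [0.94, 0.03, 0.01, 0.01, 0.00, 0.00, 0.00],
            (0, 3): [0.05, 0.01, 0.01, 0.03, 0.04, 0.05, 0.81],
            (3, 3): [0.00, 0.00, 0.00, 0.00, 0.00, 0.01, 0.98],
        },
        # normalized quadrature weights, grid columns ordered by
        # (ERS, QOL) = (-2,-1), (-2,0), (-2,1), (0,-1), ... as printed below
        "grid_order": [(-2, -1), (-2, 0), (-2, 1), (0, -1), (0, 0), (0, 1),
                       (2, -1), (2, 0), (2, 1)],
        "weights": [0.019, 0.046, 0.040, 0.215, 0.361, 0.215,
                    0.040, 0.046, 0.019],
        # collapsed ERS response functions T_j^ERS(m | eta, xi) per item,
        # same column order, 3 dp
        "collapsed_ers": {
            (1, 0): [0.997, 0.997, 0.987, 0.910, 0.916, 0.722, 0.259, 0.274, 0.082],
            (2, 0): [0.978, 0.965, 0.924, 0.853, 0.779, 0.606, 0.426, 0.310, 0.164],
            (3, 0): [0.994, 0.994, 0.987, 0.901, 0.901, 0.792, 0.318, 0.317, 0.163],
            (1, 1): [0.003, 0.003, 0.013, 0.090, 0.084, 0.278, 0.741, 0.726, 0.918],
            (2, 1): [0.022, 0.035, 0.076, 0.147, 0.221, 0.394, 0.574, 0.690, 0.836],
            (3, 1): [0.006, 0.006, 0.013, 0.099, 0.099, 0.208, 0.682, 0.683, 0.837],
        },
        # three-item summed-score likelihoods L_3^ERS(v | eta, xi), 3 dp
        "final_likelihood": {
            0: [0.970, 0.957, 0.899, 0.700, 0.643, 0.347, 0.035, 0.027, 0.002],
            1: [0.030, 0.043, 0.099, 0.266, 0.312, 0.450, 0.223, 0.189, 0.047],
            2: [0.000, 0.000, 0.002, 0.033, 0.043, 0.181, 0.452, 0.442, 0.309],
            3: [0.000, 0.000, 0.000, 0.001, 0.002, 0.023, 0.290, 0.342, 0.642],
        },
        # intermediate two-item likelihoods, 3 dp
        "two_item_likelihood": {
            0: [0.975, 0.962, 0.911, 0.776, 0.713, 0.438, 0.110, 0.085, 0.014],
            1: [0.025, 0.038, 0.088, 0.211, 0.268, 0.453, 0.464, 0.414, 0.220],
            2: [0.000, 0.000, 0.001, 0.013, 0.019, 0.110, 0.426, 0.501, 0.767],
        },
        # nuisance-marginalized kernel sum_xi L(v|eta,xi) W(x), columns are
        # eta = -2, 0, 2, 3 dp
        "kernel": {
            0: [0.098, 0.457, 0.003],
            1: [0.006, 0.267, 0.018],
            2: [0.000, 0.062, 0.044],
            3: [0.000, 0.006, 0.039],
        },
        # translation table rows v = 0..3: p(v), E(eta|v), V(eta|v), 3 dp
        "translation": {
            0: (0.558, -0.340, 0.603),
            1: (0.292, 0.082, 0.333),
            2: (0.106, 0.829, 0.979),
            3: (0.045, 1.740, 0.452),
        },
        # example response patterns from a 35-item questionnaire and the
        # sum scores implied by the QOL / ERS / MRS scoring functions
        "patterns_35": {
            "subject1": "11111131116361131163661661161363466",
            "subject2": "00000600043324433564443564551452235",
        },
        "sum_scores_subject1": {"QOL": 105, "ERS": 11, "MRS": 6},
        # published deviance/parameter-count table for the empirical
        # 35-item dataset (not distributed here); used to exercise the
        # fit-index arithmetic only
        "fit_table": [
            # (model, minus2LL, n_params, AIC, BIC), N = 586
            ("QOL", 67424, 245, 67914, 68985),
            ("QOL, MRS", 66325, 281, 66887, 68116),
            ("QOL, ERS", 65008, 281, 65570, 66799),
            ("QOL, ERS, MRS", 63958, 318, 64594, 65984),
        ],
        "fit_N": 586,
        "lrt": {"chi2": 3466, "df": 73},
    }
    return WorkedExample(
        model=model,
        scoring=scoring,
        grid=grid,
        example_item=items[1],
        expected=expected,
    )
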