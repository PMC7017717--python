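"""Core data types and response functions for the multidimensional nominal
response model (MNRM).

The MNRM is a multinomial-logit item response model.  For an item with
categories k = 0..K-1 and a person at latent point x = (x_1..x_D), the
probability of selecting category k is

    T(k | x) = exp(z_k) / sum_m exp(z_m),
    z_k = sum_d a_d * s_kd * x_d + c_k,

where ``a_d`` is the item's overall slope on dimension d, ``c_k`` a category
intercept (c_0 = 0 anchors the scale), and ``s_kd`` a fixed, user-chosen
*scoring function* value giving category k its weight on dimension d.
Scoring functions encode what each dimension means: ``[0, 1, ..., K-1]`` for
an ordinal substantive trait (the generalized-partial-credit convention),
``[1, 0, ..., 0, 1]`` for extreme response style (ERS), a midpoint indicator
for midpoint response style (MRS), and so on.

This module houses the item/model containers, the category response function
and its pairwise-logit view, category recoding, collapsed (per-dimension)
response functions, and parameterization conversions between the
overall-slope and category-slope (nominal) forms.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .errors import (
    CategoryRangeError,
    DimensionMismatchError,
    IdentificationError,
    ValidationError,
)

__all__ = [
    "ItemParameters",
    "ScoringFunctionSet",
    "MNRMModel",
    "ResponseMatrix",
    "category_response_prob",
    "pairwise_logit",
    "recode_response",
    "collapsed_response_prob",
    "to_category_slopes",
    "reparameterize",
]

#: relative singular-value tolerance for the scoring-function rank check
RANK_TOL = 1e-8


def _softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    # max-subtraction so grid extremes with large slopes cannot overflow
    z = z - np.max(z, axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


@dataclass(frozen=True)
class ItemParameters:
    """Slopes and intercepts for a single item.

    Parameters
    ----------
    a : array of shape (D,)
        Overall slope per latent dimension, in log-odds per unit latent
        trait per unit scoring-code difference.
    c : array of shape (K,)
        Category intercepts on the log scale.  The anchor category's
        intercept is exactly 0 (the first category by default; the last
        under the reference='last' convention used by some programs).
    reference : {'first', 'last'}
        Which category anchors the intercepts.
    """

    a: np.ndarray
    c: np.ndarray
    reference: Literal["first", "last"] = "first"

    def __post_init__(self) -> None:
        a = np.atleast_1d(np.asarray(self.a, dtype=float))
        c = np.atleast_1d(np.asarray(self.c, dtype=float))
        object.__setattr__(self, "a", a)
        object.__setattr__(self, "c", c)
        if a.ndim != 1 or c.ndim != 1:
            raise ValidationError("item slopes and intercepts must be 1-D")
        if c.size < 2:
            raise ValidationError("an item needs at least 2 categories")
        if not (np.all(np.isfinite(a)) and np.all(np.isfinite(c))):
            raise ValidationError("item parameters must be finite")
        anchor = 0 if self.reference == "first" else c.size - 1
        if c[anchor] != 0.0:
            raise ValidationError(
                f"intercept of the {self.reference} (anchor) category must be 0, "
                f"got {c[anchor]!r}"
            )

    @property
    def K(self) -> int:
        """Number of response categories."""
        return self.c.size

    @property
    def D(self) -> int:
        """Number of latent dimensions."""
        return self.a.size


class ScoringFunctionSet:
    """Fixed scoring-function vectors for every item x dimension.

    Stores, for each item j, a (K_j x D) matrix whose column d is the
    scoring vector s_jd assigning each category its code on dimension d.
    Codes may be any reals (negative values are legal, as in the
    last-category-referenced ERS convention ``[0, -1, ..., -1, 0]``).

    On construction each item's matrix is checked for identification: the
    K_j x (D+1) matrix [1 | s_j1 ... s_jD] must have full column rank,
    otherwise one dimension's codes are an affine combination of the others
    (e.g. adding ``[0,1,1,1,1,1,0]`` alongside ERS ``[1,0,0,0,0,0,1]``) and
    the model is not estimable.
    """

    def __init__(
        self,
        labels: Sequence[str],
        matrices: Sequence[np.ndarray],
        check: bool = True,
    ) -> None:
        self.labels = list(labels)
        if len(set(self.labels)) != len(self.labels):
            raise ValidationError(f"dimension labels must be unique: {self.labels}")
        self.matrices = [np.atleast_2d(np.asarray(m, dtype=float)) for m in matrices]
        for j, m in enumerate(self.matrices):
            if m.ndim != 2 or m.shape[1] != self.D:
                raise ValidationError(
                    f"item {j}: scoring matrix must be (K_j x {self.D}), got {m.shape}"
                )
            if not np.all(np.isfinite(m)):
                raise ValidationError(f"item {j}: scoring codes must be finite")
        if check:
            self.check_identification()

    @property
    def D(self) -> int:
        return len(self.labels)

    @property
    def n_items(self) -> int:
        return len(self.matrices)

    def K(self, j: int) -> int:
        """Category count of item j."""
        return self.matrices[j].shape[0]

    def for_item(self, j: int) -> np.ndarray:
        """(K_j x D) scoring matrix of item j."""
        return self.matrices[j]

    def vector(self, j: int, d: int) -> np.ndarray:
        """Scoring vector s_jd for item j on dimension d."""
        return self.matrices[j][:, d]

    def dim_index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise ValidationError(
                f"unknown dimension {label!r}; have {self.labels}"
            ) from None

    def check_identification(self) -> None:
        """Raise :class:`IdentificationError` if any item's scoring matrix,
        augmented with the all-ones column, is column-rank deficient."""
        for j, m in enumerate(self.matrices):
            aug = np.column_stack([np.ones(m.shape[0]), m])
            sv = np.linalg.svd(aug, compute_uv=False)
            if sv[-1] < RANK_TOL * sv[0]:
                raise IdentificationError(
                    f"item {j}: scoring functions are linearly dependent "
                    f"(with the constant): {self._offending_pairs(aug)}; "
                    "redundant dimension definitions cannot be estimated"
                )

    def _offending_pairs(self, aug: np.ndarray) -> str:
        names = ["const"] + self.labels
        pairs = []
        for p in range(aug.shape[1]):
            for q in range(p + 1, aug.shape[1]):
                sub = aug[:, [p, q]]
                sv = np.linalg.svd(sub, compute_uv=False)
                if sv[-1] < RANK_TOL * max(sv[0], 1.0):
                    pairs.append(f"{names[p]}~{names[q]}")
        # a dependence can involve >2 columns; fall back to naming all dims
        return ", ".join(pairs) if pairs else "involving " + ", ".join(names[1:])

    @classmethod
    def from_templates(
        cls,
        labels: Sequence[str],
        templates: Sequence[object],
        Ks: Sequence[int],
    ) -> "ScoringFunctionSet":
        """Build from per-dimension templates.

        Each template is either a name (``'trait'``, ``'ers'``, ``'mrs'``),
        an explicit vector broadcast to every item (all K_j must then agree
        with its length), or a sequence of per-item vectors.
        """
        n = len(Ks)
        cols: list[list[np.ndarray]] = []
        for label, tpl in zip(labels, templates):
            cols.append([scoring_template(tpl, K, label) for K in Ks] if isinstance(tpl, str)
                        else _expand_vectors(tpl, Ks, label))
        matrices = [np.column_stack([cols[d][j] for d in range(len(labels))])
                    for j in range(n)]
        return cls(labels, matrices)


def scoring_template(name: str, K: int, label: str = "") -> np.ndarray:
    """Expand a named scoring-function template for a K-category item.

    ``trait``: 0..K-1 (generalized-partial-credit convention);
    ``ers``: endpoint indicator [1, 0, ..., 0, 1];
    ``mrs``: middle-category indicator (K must be odd).
    """
    if name == "trait":
        return np.arange(K, dtype=float)
    if name == "ers":
        s = np.zeros(K)
        s[0] = s[-1] = 1.0
        return s
    if name == "mrs":
        if K % 2 == 0:
            raise ValidationError(
                f"dimension {label!r}: 'mrs' template needs an odd category "
                f"count (no middle category with K={K})"
            )
        s = np.zeros(K)
        s[K // 2] = 1.0
        return s
    raise ValidationError(
        f"dimension {label!r}: unknown scoring template {name!r} "
        "(known: trait, ers, mrs)"
    )


def _expand_vectors(tpl: object, Ks: Sequence[int], label: str) -> list[np.ndarray]:
    arr = np.asarray(tpl, dtype=object)
    if arr.ndim == 1 and np.isscalar(arr[0]) or (
        arr.ndim == 1 and not isinstance(arr[0], (list, tuple, np.ndarray))
    ):
        vec = np.asarray(tpl, dtype=float)
        out = []
        for j, K in enumerate(Ks):
            if vec.size != K:
                raise ValidationError(
                    f"dimension {label!r}: scoring vector of length {vec.size} "
                    f"cannot be broadcast to item {j} with K={K}"
                )
            out.append(vec.copy())
        return out
    vecs = [np.asarray(v, dtype=float) for v in tpl]  # type: ignore[union-attr]
    if len(vecs) != len(Ks):
        raise ValidationError(
            f"dimension {label!r}: got {len(vecs)} scoring vectors for "
            f"{len(Ks)} items"
        )
    for j, (v, K) in enumerate(zip(vecs, Ks)):
        if v.size != K:
            raise ValidationError(
                f"dimension {label!r}, item {j}: scoring vector length "
                f"{v.size} != K={K}"
            )
    return vecs


@dataclass
class MNRMModel:
    """An item list, its scoring functions, and the latent correlation matrix.

    Latent traits are standardized: means fixed at 0, variances at 1, so R
    is a correlation matrix.
    """

    items: list[ItemParameters]
    scoring: ScoringFunctionSet
    R: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        D = self.scoring.D
        if self.R is None:
            self.R = np.eye(D)
        self.R = np.asarray(self.R, dtype=float)
        if self.R.shape != (D, D):
            raise ValidationError(f"R must be {D}x{D}, got {self.R.shape}")
        if not np.allclose(self.R, self.R.T, atol=1e-10):
            raise ValidationError("R must be symmetric")
        if not np.allclose(np.diag(self.R), 1.0, atol=1e-10):
            raise ValidationError("R must have unit diagonal")
        if np.linalg.eigvalsh(self.R)[0] <= 0:
            raise ValidationError("R must be positive definite")
        if len(self.items) != self.scoring.n_items:
            raise ValidationError(
                f"{len(self.items)} items but scoring functions for "
                f"{self.scoring.n_items}"
            )
        for j, item in enumerate(self.items):
            if item.D != D:
                raise DimensionMismatchError(
                    f"item {j}: {item.D} slopes for a {D}-dimensional model"
                )
            if item.K != self.scoring.K(j):
                raise ValidationError(
                    f"item {j}: {item.K} intercepts but scoring vectors of "
                    f"length {self.scoring.K(j)}"
                )

    @property
    def D(self) -> int:
        return self.scoring.D

    @property
    def n_items(self) -> int:
        return len(self.items)

    @property
    def labels(self) -> list[str]:
        return self.scoring.labels


@dataclass
class ResponseMatrix:
    """N x n matrix of integer category responses with missing values.

    Internally a float array where NaN marks a missing response; non-missing
    entries are integers in 0..K_j-1 for their item.
    """

    data: np.ndarray
    item_ids: list[str]
    person_ids: list[str]
    K: np.ndarray  # per-item category counts

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValidationError("response data must be 2-D (persons x items)")
        self.K = np.asarray(self.K, dtype=int)
        n = self.data.shape[1]
        if len(self.item_ids) != n or self.K.size != n:
            raise ValidationError("item ids / category counts do not match data")
        if len(self.person_ids) != self.data.shape[0]:
            raise ValidationError("person ids do not match data")
        obs = ~np.isnan(self.data)
        vals = self.data[obs]
        if vals.size and not np.all(vals == np.round(vals)):
            raise ValidationError("non-integer response codes present")
        for j in range(n):
            col = self.data[:, j]
            bad = np.where(~np.isnan(col) & ((col < 0) | (col >= self.K[j])))[0]
            if bad.size:
                i = int(bad[0])
                raise CategoryRangeError(
                    f"response {col[i]:g} out of range 0..{self.K[j] - 1} at "
                    f"person {self.person_ids[i]!r}, item {self.item_ids[j]!r}"
                )

    @property
    def n_persons(self) -> int:
        return self.data.shape[0]

    @property
    def n_items(self) -> int:
        return self.data.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.data)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, K: Sequence[int] | None = None) -> "ResponseMatrix":
        data = df.to_numpy(dtype=float)
        if K is None:
            with np.errstate(all="ignore"):
                K = np.where(
                    np.all(np.isnan(data), axis=0), 2, np.nanmax(data, axis=0) + 1
                ).astype(int)
            K = np.maximum(K, 2)
        return cls(
            data=data,
            item_ids=[str(c) for c in df.columns],
            person_ids=[str(i) for i in df.index],
            K=np.asarray(K, dtype=int),
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.data, index=self.person_ids, columns=self.item_ids)

    @classmethod
    def from_patterns(cls, patterns: Iterable[str], K: int) -> "ResponseMatrix":
        """Build from digit strings, one person per string ('.' = missing)."""
        rows = []
        for p in patterns:
            rows.append([np.nan if ch in ".-" else int(ch) for ch in p])
        data = np.asarray(rows, dtype=float)
        n = data.shape[1]
        return cls(
            data=data,
            item_ids=[f"item{j + 1}" for j in range(n)],
            person_ids=[str(i + 1) for i in range(data.shape[0])],
            K=np.full(n, K, dtype=int),
        )


# ---------------------------------------------------------------------------
# response functions


def _check_point(item: ItemParameters, s: np.ndarray, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    s = np.atleast_2d(np.asarray(s, dtype=float))
    x = np.atleast_1d(np.asarray(x, dtype=float))
    if s.shape != (item.K, item.D):
        raise DimensionMismatchError(
            f"scoring matrix shape {s.shape} != (K={item.K}, D={item.D})"
        )
    if x.size != item.D:
        raise DimensionMismatchError(
            f"latent point has {x.size} coordinates for a {item.D}-dimensional item"
        )
    return s, x


def logits(item: ItemParameters, s: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Category logits z_k = sum_d a_d s_kd x_d + c_k at latent point x."""
    s, x = _check_point(item, s, x)
    return s @ (item.a * x) + item.c


def category_response_prob(
    item: ItemParameters, s: np.ndarray, x: np.ndarray
) -> np.ndarray:
    """Category response function T(k | x), k = 0..K-1.

    Softmax of the category logits, computed with max-subtraction so that
    |a_d s_kd x_d + c_k| up to ~700 cannot overflow.
    """
    return _softmax(logits(item, s, x))


def pairwise_logit(
    item: ItemParameters, s: np.ndarray, k: int, kprime: int, x: np.ndarray
) -> float:
    """Log-odds of choosing category k over k' at latent point x.

    Equals c_k - c_k' + sum_d a_d (s_kd - s_k'd) x_d, the logistic-regression
    view of the model; identical to log T(k|x) - log T(k'|x).
    """
    s, x = _check_point(item, s, x)
    for kk in (k, kprime):
        if not (0 <= kk < item.K):
            raise CategoryRangeError(f"category {kk} out of range 0..{item.K - 1}")
    if k == kprime:
        return 0.0
    return float(
        item.c[k] - item.c[kprime] + (item.a * (s[k] - s[kprime])) @ x
    )


def recode_response(y: float, s_jd: np.ndarray) -> float:
    """Recode observed category y through scoring vector s_jd: u = s_jd[y].

    Missing responses (None or NaN) propagate as NaN, never as zero.
    """
    s_jd = np.asarray(s_jd, dtype=float)
    if y is None or (isinstance(y, float) and np.isnan(y)):
        return float("nan")
    yi = int(y)
    if yi != y or not (0 <= yi < s_jd.size):
        raise CategoryRangeError(
            f"response {y!r} out of category range 0..{s_jd.size - 1}"
        )
    return float(s_jd[yi])


def collapsed_response_prob(
    item: ItemParameters, s: np.ndarray, d: int, x: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Dimension-d collapsed response function.

    Sums category probabilities over categories sharing a recoded value m,
    i.e. T_d(m | x) = sum_{k : s_kd = m} T(k | x).

    Returns ``(values, probs)`` with the distinct recoded values in
    ascending order and their probabilities.
    """
    s, x = _check_point(item, s, x)
    if not (0 <= d < item.D):
        raise DimensionMismatchError(f"dimension {d} out of range 0..{item.D - 1}")
    T = category_response_prob(item, s, x)
    values, inverse = np.unique(s[:, d], return_inverse=True)
    probs = np.zeros(values.size)
    np.add.at(probs, inverse, T)
    return values, probs


def to_category_slopes(item: ItemParameters, s: np.ndarray) -> np.ndarray:
    """Convert to the nominal (category-slope) parameterization.

    Returns the K x D matrix of category slopes a~_kd = a_d * s_kd, the form
    in which each category carries its own slope relative to a reference
    category.
    """
    s, _ = _check_point(item, s, np.zeros(item.D))
    return s * item.a


def reparameterize(
    item: ItemParameters,
    s: np.ndarray,
    shift: np.ndarray | float = 0.0,
    scale: np.ndarray | float = 1.0,
    reference: Literal["first", "last"] = "first",
) -> tuple[ItemParameters, np.ndarray]:
    """Equivalent parameters under an affine change of scoring functions.

    Per dimension d the codes become ``s'_kd = (s_kd - shift_d) * scale_d``
    with the compensating slope ``a'_d = a_d / scale_d``.  Intercepts are
    re-anchored to the chosen reference category; with ``reference='last'``
    the last category's scoring codes are additionally shifted to zero (so
    its whole logit contribution vanishes, the convention of programs that
    anchor on the last category).  Category probabilities are invariant:
    scaling is absorbed by the slope, and shifting the codes or intercepts
    adds the same amount to every category's logit, which cancels in the
    softmax.
    """
    s, _ = _check_point(item, s, np.zeros(item.D))
    shift = np.broadcast_to(np.asarray(shift, dtype=float), (item.D,)).copy()
    scale = np.broadcast_to(np.asarray(scale, dtype=float), (item.D,)).copy()
    if np.any(scale == 0):
        raise ValidationError("scale must be nonzero in every dimension")
    s_new = (s - shift) * scale
    a_new = item.a / scale
    ref = 0 if reference == "first" else item.K - 1
    if reference == "last":
        s_new = s_new - s_new[ref]
    c_new = item.c - item.c[ref]
    return ItemParameters(a=a_new, c=c_new, reference=reference), s_new
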