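"""Trend testing, ROC classification and effect sizes.

Three statistical layers sit on top of the ABC scores:

* the Jonckheere-Terpstra test for a monotone concentration trend in
  per-replicate ABC values (one-sided, increasing), exact by full
  permutation enumeration for small samples and by a tie-corrected
  normal approximation otherwise;
* an empirical ROC over per-chemical sum-of-ABC scores against binary
  toxicant labels, with the AUC computed as the pair-concordance
  probability (ties counted 1/2) and the operating threshold chosen as
  the cutpoint closest to the (FPR 0, TPR 1) corner;
* Hedges' g, a small-sample-corrected standardized distance of a
  chemical's replicate score distribution from the threshold, screening
  out calls with negligible effect (|g| below 0.2 is conventionally a
  trivial effect).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.stats import norm, rankdata

from .errors import ParameterError, UndefinedEffectError
from .disruption import ChemicalSummary

__all__ = [
    "TrendResult",
    "RocResult",
    "ChemicalCall",
    "jonckheere_terpstra",
    "roc_auc",
    "optimal_threshold",
    "hedges_g",
    "classify_chemical",
]

#: Largest pooled sample size for which the JT null distribution is enumerated.
JT_EXACT_MAX_N = 8


@dataclass(frozen=True)
class TrendResult:
    chemical: str
    jt_statistic: float
    z: float
    p_value: float
    significant: bool
    method: str  # "exact" or "normal"


@dataclass(frozen=True)
class RocResult:
    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float
    n_pos: int
    n_neg: int
    optimal_threshold: float | None = None
    sensitivity: float | None = None
    specificity: float | None = None
    accuracy: float | None = None


@dataclass(frozen=True)
class ChemicalCall:
    chemical: str
    sum_abc: float
    call: str  # "P" or "N"
    hedges_g: float | None
    exceeds_min_effect: bool


def _jt_statistic(groups: list[np.ndarray]) -> float:
    jt = 0.0
    for gi, gj in combinations(groups, 2):
        diff = gj[None, :] - gi[:, None]
        jt += float(np.sum(diff > 0) + 0.5 * np.sum(diff == 0))
    return jt


def _jt_exact_p(pooled: np.ndarray, sizes: list[int], observed: float) -> float:
    """One-sided P(JT >= observed) by enumerating all group assignments."""
    idx_all = tuple(range(pooled.size))
    count = 0
    total = 0

    def recurse(remaining: tuple[int, ...], gi: int, chosen: list[np.ndarray]) -> None:
        nonlocal count, total
        if gi == len(sizes) - 1:
            groups = chosen + [pooled[list(remaining)]]
            total += 1
            if _jt_statistic(groups) >= observed - 1e-9:
                count += 1
            return
        for comb in combinations(remaining, sizes[gi]):
            rest = tuple(i for i in remaining if i not in comb)
            recurse(rest, gi + 1, chosen + [pooled[list(comb)]])

    recurse(idx_all, 0, [])
    return count / total


def jonckheere_terpstra(
    groups: list[np.ndarray] | list[list[float]],
    alpha: float = 0.001,
    chemical: str = "",
) -> TrendResult:
    """One-sided (increasing) Jonckheere-Terpstra trend test.

    ``groups`` are ABC values ordered by increasing concentration.  The
    statistic counts, over every ordered pair of groups, observations in
    the higher-concentration group exceeding those in the lower one
    (ties count 1/2).  For pooled n <= 8 the p-value is exact by full
    enumeration; otherwise a normal approximation with tie-corrected
    variance is used.  A fully tied sample sits at the null expectation
    and gets p = 0.5 by convention.
    """
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2:
        raise ParameterError("need at least two concentration groups")
    if any(g.size == 0 for g in gs):
        raise ParameterError("every group must be nonempty")
    sizes = [g.size for g in gs]
    pooled = np.concatenate(gs)
    N = pooled.size
    jt = _jt_statistic(gs)

    n = np.asarray(sizes, dtype=float)
    mean = (N**2 - np.sum(n**2)) / 4.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    t = tie_counts.astype(float)
    term1 = N * (N - 1) * (2 * N + 5) - np.sum(n * (n - 1) * (2 * n + 5)) - np.sum(
        t * (t - 1) * (2 * t + 5)
    )
    var = term1 / 72.0
    if N > 2:
        var += (np.sum(n * (n - 1) * (n - 2)) * np.sum(t * (t - 1) * (t - 2))) / (
            36.0 * N * (N - 1) * (N - 2)
        )
    var += (np.sum(n * (n - 1)) * np.sum(t * (t - 1))) / (8.0 * N * (N - 1))

    if var <= 0:
        z, p_normal = 0.0, 0.5
    else:
        z = (jt - mean) / np.sqrt(var)
        p_normal = float(norm.sf(z))

    if N <= JT_EXACT_MAX_N:
        p = _jt_exact_p(pooled, sizes, jt) if var > 0 else 0.5
        method = "exact"
    else:
        p = p_normal
        method = "normal"
    return TrendResult(
        chemical=chemical, jt_statistic=jt, z=float(z), p_value=p, significant=p < alpha, method=method
    )


def _as_binary(labels) -> np.ndarray:
    lab = np.asarray(labels)
    if lab.dtype.kind in "b":
        return lab.astype(bool)
    if lab.dtype.kind in "iu":
        return lab != 0
    return np.asarray([str(v).upper() == "P" for v in lab])


def roc_auc(scores, labels) -> RocResult:
    """Empirical ROC and pair-concordance AUC of scores vs. P/N labels.

    AUC = (#{positive outscoring negative} + ties/2) / (n_P * n_N),
    computed from midranks.  ROC points are evaluated at every distinct
    cutpoint: the midpoints between adjacent distinct scores, the lowest
    score (every chemical called P) and +inf (no calls); the call rule
    is score >= threshold.
    """
    s = np.asarray(scores, dtype=float)
    y = _as_binary(labels)
    if s.shape != y.shape:
        raise ParameterError("scores and labels must have equal length")
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ParameterError("both classes must be present")

    ranks = rankdata(s)
    u = float(ranks[y].sum()) - n_pos * (n_pos + 1) / 2.0
    auc = u / (n_pos * n_neg)

    distinct = np.unique(s)
    cuts = np.concatenate([[distinct[0]], (distinct[:-1] + distinct[1:]) / 2.0, [np.inf]])
    tpr = np.array([(s[y] >= c).mean() for c in cuts])
    fpr = np.array([(s[~y] >= c).mean() for c in cuts])
    return RocResult(thresholds=cuts, tpr=tpr, fpr=fpr, auc=auc, n_pos=n_pos, n_neg=n_neg)


def optimal_threshold(roc: RocResult) -> RocResult:
    """Select the cutpoint closest to the (FPR 0, TPR 1) corner.

    Distance is Euclidean, ``sqrt((1 - sens)^2 + (1 - spec)^2)``; ties
    are broken toward higher specificity.  Returns the ROC with the
    operating point filled in; accuracy is computed at that point from
    the class mix implied by the ROC arrays.
    """
    sens = roc.tpr
    spec = 1.0 - roc.fpr
    dist = np.sqrt((1.0 - sens) ** 2 + (1.0 - spec) ** 2)
    best = np.flatnonzero(dist <= dist.min() + 1e-12)
    i = best[np.argmax(spec[best])]
    acc = (sens[i] * roc.n_pos + spec[i] * roc.n_neg) / (roc.n_pos + roc.n_neg)
    return RocResult(
        thresholds=roc.thresholds,
        tpr=roc.tpr,
        fpr=roc.fpr,
        auc=roc.auc,
        n_pos=roc.n_pos,
        n_neg=roc.n_neg,
        optimal_threshold=float(roc.thresholds[i]),
        sensitivity=float(sens[i]),
        specificity=float(spec[i]),
        accuracy=float(acc),
    )


def evaluate_threshold(scores, labels, threshold: float) -> tuple[float, float, float]:
    """Sensitivity, specificity, accuracy of the rule score >= threshold."""
    s = np.asarray(scores, dtype=float)
    y = _as_binary(labels)
    pred = s >= threshold
    tp = int((pred & y).sum())
    tn = int((~pred & ~y).sum())
    sens = tp / int(y.sum())
    spec = tn / int((~y).sum())
    acc = (tp + tn) / y.size
    return sens, spec, acc


def hedges_g(replicate_sums, threshold: float) -> float:
    """Hedges' g of replicate sum-of-ABC scores against a fixed threshold.

    One-sample standardized difference ``J * (mean - threshold) / sd``
    with the small-sample correction ``J = 1 - 3 / (4(n - 1) - 1)`` and
    ``sd`` the sample standard deviation of the replicate sums.
    """
    x = np.asarray(replicate_sums, dtype=float)
    n = x.size
    if n < 2:
        raise UndefinedEffectError("need at least two replicate sums")
    sd = float(np.std(x, ddof=1))
    if sd == 0:
        raise UndefinedEffectError("zero replicate variance; effect size undefined")
    j = 1.0 - 3.0 / (4.0 * (n - 1) - 1.0)
    return j * (float(np.mean(x)) - threshold) / sd


def classify_chemical(
    summary: ChemicalSummary, threshold: float, min_effect: float = 0.2
) -> ChemicalCall:
    """Binary toxicant call: P iff sum-of-ABC >= threshold (boundary counts P)."""
    call = "P" if summary.sum_abc >= threshold else "N"
    g: float | None = None
    if len(summary.replicate_sums) >= 2:
        try:
            g = hedges_g(summary.replicate_sums, threshold)
        except UndefinedEffectError:
            g = None
    return ChemicalCall(
        chemical=summary.chemical,
        sum_abc=summary.sum_abc,
        call=call,
        hedges_g=g,
        exceeds_min_effect=(g is not None and g >= min_effect),
    )
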