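"""Cross-laboratory reproducibility statistics.

The core test statistic is the maximum CDF distance: for each lab, the
largest absolute difference between the empirical CDF of a feature within
that lab and the CDF pooled over all other labs, maximized over labs. Its
null distribution is built by permuting lab assignments (at the mouse
level when a grouping is supplied, leaving per-lab counts intact). A
binary-search power analysis finds the smallest additive shift of one
lab's values that makes the test significant, and a classifier-with-
shuffle-null test asks whether any combination of features decodes lab
identity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold, cross_val_score

__all__ = [
    "PermutationResult",
    "PowerShiftResult",
    "DecodeResult",
    "max_cdf_distance",
    "permutation_test",
    "power_shift",
    "shifted_lab_p",
    "decode_group_null",
]


@dataclass
class PermutationResult:
    statistic: float
    null_statistics: np.ndarray
    p_value: float
    n_perm: int
    seed: Optional[int]
    group_sizes: dict

    @property
    def significant(self) -> bool:
        """Significance at the stringent alpha = 0.01 convention."""
        return self.p_value < 0.01


@dataclass
class PowerShiftResult:
    """Smallest additive shifts of one lab's values reaching significance.

    ``shift_up >= 0`` and ``shift_down <= 0`` satisfy ``p(shift) < alpha``
    and ``p(shift -/+ tol) >= alpha`` under the frozen permutation null;
    both are 0 with ``already_significant`` set when no shift is needed.
    """

    target_lab: str
    shift_up: float
    shift_down: float
    already_significant: bool
    p_at_zero: float
    alpha: float
    tol: float


@dataclass
class DecodeResult:
    accuracy: float
    p_value: float
    null_accuracies: np.ndarray
    classes: list


def _codes(labels) -> tuple[np.ndarray, list]:
    labels = np.asarray(labels)
    classes, codes = np.unique(labels, return_inverse=True)
    return codes, list(classes)


def _stats_from_sorted_codes(
    sorted_codes: np.ndarray, n_labs: int, counts: np.ndarray, valid: np.ndarray
) -> np.ndarray:
    """Max-CDF statistic for each row of a (P, n) matrix of lab codes,
    ordered by the (fixed) sorted feature values.

    Both empirical CDFs are step functions jumping only at sample points,
    so the supremum is attained at the last index of each tied-value run
    (the ``valid`` mask).
    """
    P, n = sorted_codes.shape
    pos = np.arange(1, n + 1)
    best = np.zeros(P)
    for lab in range(n_labs):
        c = counts[lab]
        cum = np.cumsum(sorted_codes == lab, axis=1)
        d = np.abs(cum / c - (pos - cum) / (n - c))[:, valid].max(axis=1)
        np.maximum(best, d, out=best)
    return best


def max_cdf_distance(values, labels) -> float:
    """Largest lab-vs-rest CDF deviation over all labs.

    For each lab, ``D_lab = sup_x |CDF_lab(x) - CDF_rest(x)|`` evaluated
    over the pooled sample; the statistic is ``max_lab D_lab`` and lies in
    [0, 1]. Rank-based, hence invariant under any strictly monotone
    transform of the feature.
    """
    values = np.asarray(values, dtype=float)
    codes, classes = _codes(labels)
    if len(classes) < 2:
        raise ValueError("need at least two labs")
    counts = np.bincount(codes, minlength=len(classes))
    if counts.min() == 0:
        raise ValueError("every lab must be non-empty")
    order = np.argsort(values, kind="stable")
    sv = values[order]
    valid = np.ones(len(sv), dtype=bool)
    valid[:-1] = sv[1:] > sv[:-1]
    return float(
        _stats_from_sorted_codes(codes[order][None, :], len(classes), counts, valid)[0]
    )


def _unit_structure(codes: np.ndarray, units) -> tuple[np.ndarray, np.ndarray]:
    """Collapse values to permutation units (e.g. mice). Returns the
    per-unit lab code and the unit index of every value."""
    if units is None:
        return codes.copy(), np.arange(len(codes))
    units = np.asarray(units)
    uniq, unit_idx = np.unique(units, return_inverse=True)
    unit_codes = np.full(len(uniq), -1, dtype=int)
    for i in range(len(codes)):
        u = unit_idx[i]
        if unit_codes[u] == -1:
            unit_codes[u] = codes[i]
        elif unit_codes[u] != codes[i]:
            raise ValueError("a permutation unit spans multiple labs")
    return unit_codes, unit_idx


def _null_statistics(
    values: np.ndarray,
    unit_codes: np.ndarray,
    unit_idx: np.ndarray,
    n_labs: int,
    counts: np.ndarray,
    n_perm: int,
    rng: np.random.Generator,
    chunk: int = 2000,
) -> np.ndarray:
    order = np.argsort(values, kind="stable")
    sv = values[order]
    valid = np.ones(len(sv), dtype=bool)
    valid[:-1] = sv[1:] > sv[:-1]
    unit_idx_sorted = unit_idx[order]
    out = np.empty(n_perm)
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        perms = np.array([rng.permutation(unit_codes) for _ in range(m)])
        sorted_codes = perms[:, unit_idx_sorted]
        out[done : done + m] = _stats_from_sorted_codes(
            sorted_codes, n_labs, counts, valid
        )
        done += m
    return out


def permutation_test(
    values,
    labels,
    n_perm: int = 50000,
    seed: Optional[int] = None,
    units=None,
) -> PermutationResult:
    """Permutation test of lab exchangeability on one feature.

    The null is built by randomly reassigning labs ``n_perm`` times,
    keeping per-lab counts intact. When ``units`` (e.g. mouse identifiers)
    is given, whole units are relabelled together, matching a design in
    which mice — not individual values — are assigned to labs. The
    p-value uses the add-one estimator
    ``(1 + #{null >= observed}) / (1 + n_perm)``, which differs from the
    plain proportion by at most ``1/n_perm`` and can never be exactly
    zero; ties with the observed statistic count against rejection.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    values = np.asarray(values, dtype=float)
    codes, classes = _codes(labels)
    if len(classes) < 2:
        raise ValueError("need at least two labs")
    counts = np.bincount(codes, minlength=len(classes))
    if counts.min() == 0:
        raise ValueError("every lab must be non-empty")
    observed = max_cdf_distance(values, labels)
    unit_codes, unit_idx = _unit_structure(codes, units)
    rng = np.random.default_rng(seed)
    null = _null_statistics(
        values, unit_codes, unit_idx, len(classes), counts, n_perm, rng
    )
    p = (1.0 + np.sum(null >= observed)) / (1.0 + n_perm)
    return PermutationResult(
        statistic=observed,
        null_statistics=null,
        p_value=float(p),
        n_perm=n_perm,
        seed=seed,
        group_sizes={c: int(n) for c, n in zip(classes, counts)},
    )


def _frozen_p_evaluator(values, labels, target_lab, n_perm, seed, units):
    """p-value of the permutation test as a function of an additive shift
    applied to ``target_lab``, under one frozen set of relabelings drawn
    from ``seed``. The same (seed, n_perm, units) always yields the same
    null, so searches and later verification see an identical landscape."""
    values = np.asarray(values, dtype=float)
    codes, classes = _codes(labels)
    if target_lab not in classes:
        raise ValueError(f"unknown lab {target_lab!r}")
    counts = np.bincount(codes, minlength=len(classes))
    target_mask = np.asarray(labels) == target_lab
    unit_codes, unit_idx = _unit_structure(codes, units)
    rng = np.random.default_rng(seed)
    frozen = np.array([rng.permutation(unit_codes) for _ in range(n_perm)])

    def p_of(shift: float) -> float:
        v = values + shift * target_mask
        order = np.argsort(v, kind="stable")
        sv = v[order]
        valid = np.ones(len(sv), dtype=bool)
        valid[:-1] = sv[1:] > sv[:-1]
        obs = _stats_from_sorted_codes(
            codes[order][None, :], len(classes), counts, valid
        )[0]
        null = _stats_from_sorted_codes(
            frozen[:, unit_idx[order]], len(classes), counts, valid
        )
        return float((1.0 + np.sum(null >= obs)) / (1.0 + n_perm))

    return p_of


def shifted_lab_p(
    values,
    labels,
    target_lab,
    shift: float,
    n_perm: int = 10000,
    seed: Optional[int] = None,
    units=None,
) -> float:
    """p-value after shifting ``target_lab`` by ``shift``, under the same
    frozen permutation null that :func:`power_shift` uses for this
    (seed, n_perm) pair — the verification hook for found shifts."""
    return _frozen_p_evaluator(values, labels, target_lab, n_perm, seed, units)(shift)


def power_shift(
    values,
    labels,
    target_lab,
    alpha: float = 0.01,
    tol: Optional[float] = None,
    n_perm: int = 10000,
    seed: Optional[int] = None,
    units=None,
    max_expansions: int = 20,
    max_refinements: int = 200,
) -> PowerShiftResult:
    """Binary search for the smallest shift of one lab reaching significance.

    All of ``target_lab``'s values are shifted additively; the permutation
    null uses a single frozen set of relabelings (from ``seed``) for every
    shift evaluated, so the search is over a deterministic p-value
    landscape. The bracket is expanded geometrically from one pooled SD
    until significance, then bisected to ``tol`` (default 0.1% of the
    pooled value range); the returned shift additionally satisfies
    ``p(shift - tol * sign) >= alpha``.
    """
    values = np.asarray(values, dtype=float)
    if tol is None:
        tol = 1e-3 * float(np.ptp(values))
        if tol == 0:
            tol = 1e-9
    p_of = _frozen_p_evaluator(values, labels, target_lab, n_perm, seed, units)

    p0 = p_of(0.0)
    if p0 < alpha:
        return PowerShiftResult(str(target_lab), 0.0, 0.0, True, p0, alpha, tol)

    pooled_sd = float(values.std()) or 1.0

    def search(direction: float) -> float:
        lo, hi = 0.0, direction * pooled_sd
        for _ in range(max_expansions):
            if p_of(hi) < alpha:
                break
            lo, hi = hi, hi * 2.0
        else:
            return float("nan")  # no shift in bracket reaches significance
        for _ in range(max_refinements):
            if abs(hi - lo) <= tol:
                break
            mid = 0.5 * (lo + hi)
            if p_of(mid) < alpha:
                hi = mid
            else:
                lo = mid
        # Enforce the defining property against local non-monotonicity.
        for _ in range(max_refinements):
            candidate = hi - direction * tol
            if candidate * direction <= 0 or p_of(candidate) >= alpha:
                break
            hi = candidate
        return hi

    return PowerShiftResult(
        target_lab=str(target_lab),
        shift_up=search(+1.0),
        shift_down=search(-1.0),
        already_significant=False,
        p_at_zero=p0,
        alpha=alpha,
        tol=tol,
    )


def decode_group_null(
    features,
    labels,
    n_shuffles: int = 500,
    seed: Optional[int] = None,
    n_estimators: int = 200,
    n_splits: int = 5,
) -> DecodeResult:
    """Ensemble-of-trees decoding of group identity with a shuffle null.

    Cross-validated accuracy of a random forest predicting the group
    (lab or region) from per-recording features, compared against the
    accuracies obtained after shuffling the labels ``n_shuffles`` times.
    The p-value is the (add-one) fraction of shuffled accuracies at least
    as high as the observed one.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    small = classes[counts < 2]
    if len(small):
        warnings.warn(f"dropping classes with < 2 members: {list(small)}")
        keep = ~np.isin(y, small)
        X, y = X[keep], y[keep]
        classes = classes[counts >= 2]
    if len(classes) < 2:
        raise ValueError("need at least two classes with >= 2 members")

    rng = np.random.default_rng(seed)
    splits = min(n_splits, int(np.bincount(np.unique(y, return_inverse=True)[1]).min()))

    def accuracy(target: np.ndarray) -> float:
        clf = RandomForestClassifier(
            n_estimators=n_estimators, random_state=int(rng.integers(2**31 - 1))
        )
        cv = StratifiedKFold(
            n_splits=splits, shuffle=True, random_state=int(rng.integers(2**31 - 1))
        )
        return float(cross_val_score(clf, X, target, cv=cv, scoring="accuracy").mean())

    observed = accuracy(y)
    null = np.array([accuracy(rng.permutation(y)) for _ in range(n_shuffles)])
    p = (1.0 + np.sum(null >= observed)) / (1.0 + n_shuffles)
    return DecodeResult(
        accuracy=observed, p_value=float(p), null_accuracies=null, classes=list(classes)
    )
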