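"""Group-level inference on normalised volumes.

Two procedures are provided, mirroring common practice in postmortem
volumetry studies:

* **Monte-Carlo permutation tests** for the effects of hemisphere, sex and
  their interaction. The observed contrast is the difference of group
  means; the null distribution is built by randomly redistributing the
  values into two groups of the original sizes. The p-value uses the
  add-one estimator (1 + exceedances) / (1 + n_iter), which is positively
  biased but never zero; ties between a null draw and the observed
  contrast count as exceedances (conservative).
* A **paired two-sided t-test** for comparing the mean volumes of the two
  nuclei across subjects.

Sidedness conventions
---------------------
``"two"`` compares |null| against |observed| (default). ``"greater"`` is
the literal "contrast larger than 95% of the null values" decision rule,
an upper-tail test on the signed contrast. ``"less"`` is the lower tail
and ``"observed"`` tests in the direction of the observed contrast.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "PermutationResult",
    "TTestResult",
    "permutation_contrast",
    "paired_permutation_contrast",
    "interaction_contrast",
    "paired_t_test",
]

_SIDES = ("two", "greater", "less", "observed")
# permutations are generated in chunks to bound memory at large n_iter
_CHUNK = 100_000


@dataclass
class PermutationResult:
    """Outcome of one Monte-Carlo permutation test."""

    contrast_name: str
    C_obs: float                 # mean(group 1) - mean(group 2)
    n_iter: int
    p_value: float               # add-one estimator, in (0, 1]
    exceedance_rank: int         # null draws at least as extreme as C_obs
    seed: int
    sidedness: str
    degenerate: bool = False     # constant input values, null is a point mass
    null_quantiles: tuple[float, ...] | None = None  # 2.5/25/50/75/97.5%

    @property
    def significant(self) -> bool:
        """Decision at the 5% criterion under the configured sidedness."""
        return self.p_value < 0.05


@dataclass
class TTestResult:
    t: float
    df: int
    p_value: float
    sided: str = "two"


def _exceedances(null: np.ndarray, c_obs: float, sidedness: str) -> int:
    # ties count as exceedances; a small tolerance keeps float-noise ties in
    atol = 1e-12 * max(1.0, abs(c_obs))
    if sidedness == "two":
        return int(np.count_nonzero(np.abs(null) >= abs(c_obs) - atol))
    if sidedness == "greater":
        return int(np.count_nonzero(null >= c_obs - atol))
    if sidedness == "less":
        return int(np.count_nonzero(null <= c_obs + atol))
    # "observed": tail in the direction of the observed contrast
    if c_obs >= 0:
        return int(np.count_nonzero(null >= c_obs - atol))
    return int(np.count_nonzero(null <= c_obs + atol))


def permutation_contrast(
    values,
    labels,
    n_iter: int = 1_000_000,
    seed: int = 0,
    sidedness: str = "two",
    contrast_name: str = "contrast",
) -> PermutationResult:
    """Monte-Carlo permutation test on a difference of group means.

    Parameters
    ----------
    values : array-like of float
        One observation per entry (e.g. normalised volumes).
    labels : array-like
        Binary grouping, exactly two distinct values; group 1 is the label
        encountered first. ``C_obs = mean(group1) - mean(group2)``.
    n_iter : int
        Number of random relabelings building the null distribution.
    """
    values = np.asarray(values, dtype=float).ravel()
    labels = np.asarray(labels).ravel()
    if values.shape != labels.shape:
        raise ValueError("values and labels must have equal length")
    if sidedness not in _SIDES:
        raise ValueError(f"sidedness must be one of {_SIDES}")
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    uniq = list(dict.fromkeys(labels.tolist()))
    if len(uniq) != 2:
        raise ValueError(f"labels must contain exactly two groups, got {uniq}")
    g1 = labels == uniq[0]
    n1 = int(g1.sum())
    n2 = values.size - n1
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be nonempty")

    c_obs = float(values[g1].mean() - values[~g1].mean())

    if np.ptp(values) == 0:
        warnings.warn("constant values: permutation null is degenerate, p = 1",
                      stacklevel=2)
        return PermutationResult(contrast_name, c_obs, n_iter, 1.0, n_iter,
                                 seed, sidedness, degenerate=True)

    rng = np.random.default_rng(seed)
    exceed = 0
    null_parts = []
    done = 0
    while done < n_iter:
        m = min(_CHUNK, n_iter - done)
        perm = rng.permuted(np.tile(values, (m, 1)), axis=1)
        c_null = perm[:, :n1].mean(axis=1) - perm[:, n1:].mean(axis=1)
        exceed += _exceedances(c_null, c_obs, sidedness)
        null_parts.append(np.quantile(c_null, [0.025, 0.25, 0.5, 0.75, 0.975]))
        done += m
    p = (1 + exceed) / (1 + n_iter)
    quants = tuple(float(q) for q in np.mean(null_parts, axis=0))
    return PermutationResult(contrast_name, c_obs, n_iter, p, exceed, seed,
                             sidedness, null_quantiles=quants)


def paired_permutation_contrast(
    a,
    b,
    n_iter: int = 1_000_000,
    seed: int = 0,
    sidedness: str = "two",
    contrast_name: str = "paired contrast",
) -> PermutationResult:
    """Sign-flip permutation test on paired observations.

    ``C_obs = mean(a - b)``; the null randomly flips the sign of each
    within-pair difference, respecting the pairing that the grouped
    two-sample permutation ignores.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    if sidedness not in _SIDES:
        raise ValueError(f"sidedness must be one of {_SIDES}")
    d = a - b
    c_obs = float(d.mean())
    if np.all(d == 0):
        warnings.warn("all paired differences are zero: degenerate null, p = 1",
                      stacklevel=2)
        return PermutationResult(contrast_name, c_obs, n_iter, 1.0, n_iter,
                                 seed, sidedness, degenerate=True)
    rng = np.random.default_rng(seed)
    exceed = 0
    done = 0
    while done < n_iter:
        m = min(_CHUNK, n_iter - done)
        signs = rng.integers(0, 2, size=(m, d.size)) * 2 - 1
        c_null = (signs * d).mean(axis=1)
        exceed += _exceedances(c_null, c_obs, sidedness)
        done += m
    p = (1 + exceed) / (1 + n_iter)
    return PermutationResult(contrast_name, c_obs, n_iter, p, exceed, seed,
                             sidedness)


def interaction_contrast(
    left,
    right,
    sex,
    n_iter: int = 1_000_000,
    seed: int = 0,
    sidedness: str = "two",
) -> PermutationResult:
    """Hemisphere-by-sex interaction via permutation of sex labels.

    ``C_obs = mean over males of (left - right) - mean over females of
    (left - right)``; the null permutes the sex labels across subjects
    while keeping each subject's hemisphere pair intact — equivalent to a
    two-sample permutation test on the within-subject differences.
    """
    left = np.asarray(left, dtype=float).ravel()
    right = np.asarray(right, dtype=float).ravel()
    sex = np.asarray(sex).ravel()
    if not (left.shape == right.shape == sex.shape):
        raise ValueError("left, right and sex must have equal length")
    if np.any(np.isnan(left)) or np.any(np.isnan(right)):
        raise ValueError("every subject needs both hemisphere values")
    order = ["male", "female"] if "male" in sex else list(dict.fromkeys(sex))
    d = left - right
    # reorder so group 1 is male (C_obs = male mean - female mean)
    key = np.array([0 if s == order[0] else 1 for s in sex])
    idx = np.argsort(key, kind="stable")
    return permutation_contrast(
        d[idx], key[idx], n_iter=n_iter, seed=seed, sidedness=sidedness,
        contrast_name="interaction")


def paired_t_test(a, b) -> TTestResult:
    """Paired two-sided t-test: t = mean(d) / (sd(d)/sqrt(n)), df = n - 1."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    if a.size < 2:
        raise ValueError("paired t-test needs at least two pairs")
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        raise ValueError(
            "zero variance of paired differences: t statistic undefined "
            "(|t| would be infinite)")
    res = sps.ttest_rel(a, b, alternative="two-sided")
    return TTestResult(t=float(res.statistic), df=int(a.size - 1),
                       p_value=float(res.pvalue))
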