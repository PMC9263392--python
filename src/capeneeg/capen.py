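"""Cross-approximate entropy (C-ApEn) and approximate entropy kernels.

C-ApEn quantifies the asynchrony between two time series by template
matching: length-``m`` patterns from the template series are compared, under
a Chebyshev tolerance ``r``, against patterns of the target series, and the
statistic is the log conditional probability that patterns matching at
length ``m`` keep matching at length ``m+1``:

    C-ApEn(m, r) = Phi^m(r) - Phi^{m+1}(r),
    Phi^k(r)     = mean_i ln( #{ j : d(x_k(i), y_k(j)) <= r } / T )

with embedding vectors ``x_k(i) = [u(i), u(i+lag), ..., u(i+(k-1) lag)]``
taken from the standardized template series and ``y_k(j)`` from the
standardized target series.  Low values mean the two series share recurrent
patterns (synchrony); high values mean pattern recurrence in one series does
not predict the other (asynchrony).

Conventions used here (all deliberate, see the methods note):

* both series are standardized independently; ``r`` is a fraction of the
  (unit) standard deviation, so the statistic is exactly scale and shift
  invariant;
* one common template count ``T = N - m*lag`` is used at both lengths,
  avoiding the count-mismatch bias of the textbook ``N - m + 1`` /
  ``N - m`` convention;
* the tolerance comparison is inclusive (``d <= r``);
* templates with zero matches are dropped from the ``Phi`` averages (no
  pseudo-counts) and reported in ``n_zero_match``.

``apen(u) == capen(u, u)`` exactly, because comparing a series against
itself includes the self-match ``j == i``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit

from .errors import DegenerateSignalError, UndefinedEntropyError


@dataclass(frozen=True)
class CApEnParams:
    """Parameters of the C-ApEn estimator.

    Attributes
    ----------
    m
        Embedding dimension (template length), >= 1.  Default 2, the
        standard choice for cross-ApEn on biomedical series.
    r_frac
        Chebyshev tolerance as a fraction of the series standard deviation,
        in (0, 1).  Default 0.2.
    lag
        Embedding delay in samples, >= 1.  Default 1.
    epoch_len
        Samples per analysis epoch for :func:`epoch_capen`.  Default 1024.
    """

    m: int = 2
    r_frac: float = 0.2
    lag: int = 1
    epoch_len: int = 1024

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError(f"m must be >= 1, got {self.m}")
        if not 0 < self.r_frac < 1:
            raise ValueError(f"r_frac must be in (0, 1), got {self.r_frac}")
        if self.lag < 1:
            raise ValueError(f"lag must be >= 1, got {self.lag}")
        if self.epoch_len <= (self.m + 1) * self.lag + 1:
            raise ValueError(
                f"epoch_len {self.epoch_len} too short for m={self.m}, lag={self.lag}"
            )


@dataclass(frozen=True)
class CApEnResult:
    """C-ApEn estimate with template-count diagnostics.

    ``n_templates_m`` / ``n_templates_m1`` are the template counts that
    entered the Phi averages at lengths m and m+1; ``n_zero_match`` is the
    number of templates dropped at length m+1 for matching nothing (a
    zero-match at length m implies one at m+1, so this is the binding count).
    """

    value: float
    n_templates_m: int
    n_templates_m1: int
    n_zero_match: int


def _standardize(x: np.ndarray, name: str) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    sd = x.std()
    if sd == 0 or not np.isfinite(sd):
        raise DegenerateSignalError(f"{name} series has zero variance")
    return (x - x.mean()) / sd


@njit(cache=True)
def _count_matches(us, vs, m, lag, r, t_count):  # pragma: no cover - jitted
    # Chebyshev template matching with early exit; exact float64 arithmetic,
    # so results are identical to a dense vectorized evaluation.
    counts_m = np.zeros(t_count, np.int64)
    counts_m1 = np.zeros(t_count, np.int64)
    for i in range(t_count):
        cm = 0
        cm1 = 0
        for j in range(t_count):
            matched = True
            for k in range(m):
                if abs(us[i + k * lag] - vs[j + k * lag]) > r:
                    matched = False
                    break
            if matched:
                cm += 1
                if abs(us[i + m * lag] - vs[j + m * lag]) <= r:
                    cm1 += 1
        counts_m[i] = cm
        counts_m1[i] = cm1
    return counts_m, counts_m1


def capen(u: np.ndarray, v: np.ndarray, params: CApEnParams = CApEnParams()) -> CApEnResult:
    """Cross-approximate entropy of target series *v* relative to template series *u*.

    The statistic is directional: templates are drawn from *u* and matched
    against *v*.  ``capen(u, v)`` need not equal ``capen(v, u)``.

    Raises
    ------
    DegenerateSignalError
        If either series has zero variance.
    UndefinedEntropyError
        If every template has zero matches at either length.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape or u.ndim != 1:
        raise ValueError("u and v must be 1-D arrays of equal length")
    m, lag, r = params.m, params.lag, params.r_frac
    n = u.size
    t_count = n - m * lag
    if t_count < 2:
        raise ValueError(f"series of length {n} too short for m={m}, lag={lag}")

    us = _standardize(u, "template")
    vs = _standardize(v, "target")
    counts_m, counts_m1 = _count_matches(us, vs, m, lag, float(r), t_count)

    used_m = counts_m > 0
    used_m1 = counts_m1 > 0
    n_zero = int(t_count - np.count_nonzero(used_m1))
    if not used_m.any() or not used_m1.any():
        raise UndefinedEntropyError(
            f"all {t_count} templates have zero matches "
            f"(m: {int(np.count_nonzero(used_m))} usable, m+1: {int(np.count_nonzero(used_m1))})"
        )
    phi_m = float(np.mean(np.log(counts_m[used_m] / t_count)))
    phi_m1 = float(np.mean(np.log(counts_m1[used_m1] / t_count)))
    return CApEnResult(
        value=phi_m - phi_m1,
        n_templates_m=int(np.count_nonzero(used_m)),
        n_templates_m1=int(np.count_nonzero(used_m1)),
        n_zero_match=n_zero,
    )


def apen(u: np.ndarray, params: CApEnParams = CApEnParams()) -> CApEnResult:
    """Approximate entropy of a single series: ``capen(u, u)`` with self-matches."""
    return capen(u, u, params)


def epoch_capen(
    u: np.ndarray, v: np.ndarray, params: CApEnParams = CApEnParams()
) -> tuple[float, int]:
    """Mean C-ApEn over non-overlapping epochs of ``params.epoch_len`` samples.

    Epochs in which the estimate is undefined or a series is locally
    degenerate are skipped.  Returns ``(mean value, number of valid epochs)``.

    Raises
    ------
    ValueError
        If the series are shorter than one epoch.
    UndefinedEntropyError
        If no epoch yields a finite estimate.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape or u.ndim != 1:
        raise ValueError("u and v must be 1-D arrays of equal length")
    el = params.epoch_len
    n_epochs = u.size // el
    if n_epochs < 1:
        raise ValueError(f"series length {u.size} shorter than one epoch ({el})")
    values = []
    for e in range(n_epochs):
        sl = slice(e * el, (e + 1) * el)
        try:
            res = capen(u[sl], v[sl], params)
        except (DegenerateSignalError, UndefinedEntropyError):
            continue
        if math.isfinite(res.value):
            values.append(res.value)
    if not values:
        raise UndefinedEntropyError(f"no valid epoch out of {n_epochs}")
    return float(np.mean(values)), len(values)


def capen_reference(
    u: np.ndarray, v: np.ndarray, params: CApEnParams = CApEnParams()
) -> float:
    """Exhaustive double-loop C-ApEn for small N; the testing oracle.

    Implements the same statistic as :func:`capen` by explicit enumeration
    over every template pair, with no vectorization shared with the fast
    kernel.  Intended for N <= a few hundred.
    """
    m, lag, r = params.m, params.lag, params.r_frac
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    us = _standardize(u, "template")
    vs = _standardize(v, "target")
    n = len(us)
    t_count = n - m * lag

    def phi(k: int) -> float:
        logs = []
        for i in range(t_count):
            matches = 0
            for j in range(t_count):
                d = 0.0
                for step in range(k):
                    d = max(d, abs(us[i + step * lag] - vs[j + step * lag]))
                if d <= r:
                    matches += 1
            if matches > 0:
                logs.append(math.log(matches / t_count))
        if not logs:
            raise UndefinedEntropyError("reference: all templates zero-match")
        return sum(logs) / len(logs)

    return phi(m) - phi(m + 1)
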