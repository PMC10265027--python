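"""Model comparison and validation: BCa bootstrap, sign tests, k-fold CV.

Confidence intervals use the bias-corrected and accelerated (BCa)
percentile bootstrap: flights are resampled with replacement, the bias
correction z0 comes from the fraction of bootstrap replicates below the
point estimate, and the acceleration from the jackknife skewness of the
statistic. Paired model comparisons use the exact two-tailed sign test on
per-flight error differences. Cross-validation refits the global model on
k-1 folds and scores the median error of the held-out fold, all from the
cached error grid (no re-simulation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import ndtr, ndtri
from scipy.stats import binomtest

from .fitting import ErrorGrid, GlobalFitResult, argmin_lexicographic, global_fit
from .guidance import GuidanceLaw

# resampling is drawn in blocks of this many replicates; with B below this
# the index stream is a single rng.integers(0, n, (B, n)) call
RESAMPLE_CHUNK = 65536


@dataclass
class BootstrapCI:
    point_estimate: float
    lower: float
    upper: float
    level: float = 0.95
    iterations: int = 0
    seed: int | None = None


@dataclass
class SignTestResult:
    p_value: float
    n_positive: int
    n_negative: int
    n_ties: int


@dataclass
class CrossValReport:
    k: int
    fold_assignment: np.ndarray  # fold index per flight
    fold_params: list[GlobalFitResult]
    fold_medians: np.ndarray  # validation median RMS error per fold, metres
    mean_of_medians: float  # metres
    training_eps: float  # full-sample global-fit median error, metres
    seed: int | None = None


def _jackknife_acceleration(jack: np.ndarray) -> float:
    dev = jack.mean() - jack
    denom = np.sum(dev**2) ** 1.5
    if denom == 0.0:
        return 0.0
    return float(np.sum(dev**3) / (6.0 * denom))


def _bca_interval(
    boot: np.ndarray, theta_hat: float, accel: float, level: float
) -> tuple[float, float]:
    """BCa percentile interval from bootstrap replicates of a statistic."""
    boot = np.asarray(boot, dtype=float)
    if np.all(boot == boot[0]) and boot[0] == theta_hat:
        return theta_hat, theta_hat
    prop = np.mean(boot < theta_hat)
    b = len(boot)
    prop = min(max(prop, 1.0 / (b + 1)), b / (b + 1.0))  # keep ndtri finite
    z0 = ndtri(prop)
    alpha = 0.5 * (1.0 - level)
    lo, hi = [], []
    for z_a in (ndtri(alpha), ndtri(1.0 - alpha)):
        adj = z0 + (z0 + z_a) / (1.0 - accel * (z0 + z_a))
        (lo if z_a < 0 else hi).append(ndtr(adj))
    return float(np.quantile(boot, lo[0])), float(np.quantile(boot, hi[0]))


def bca_bootstrap_median(
    values: np.ndarray,
    iterations: int = 10**6,
    seed: int | None = None,
    level: float = 0.95,
) -> BootstrapCI:
    """BCa bootstrap confidence interval for the median of per-flight values.

    Deterministic for a fixed seed. Identical values yield the degenerate
    interval (value, value).
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n < 2:
        raise ValueError("need at least two values to bootstrap")
    if iterations < 100:
        raise ValueError("need at least 100 bootstrap iterations")
    theta_hat = float(np.median(values))
    if np.all(values == values[0]):
        return BootstrapCI(theta_hat, theta_hat, theta_hat, level, iterations, seed)

    rng = np.random.default_rng(seed)
    boot = np.empty(iterations)
    done = 0
    while done < iterations:
        m = min(RESAMPLE_CHUNK, iterations - done)
        idx = rng.integers(0, n, size=(m, n))
        boot[done : done + m] = np.median(values[idx], axis=1)
        done += m

    jack = np.array([np.median(np.delete(values, i)) for i in range(n)])
    accel = _jackknife_acceleration(jack)
    lower, upper = _bca_interval(boot, theta_hat, accel, level)
    return BootstrapCI(theta_hat, lower, upper, level, iterations, seed)


def _global_stats_for_subset(grid: ErrorGrid, law: GuidanceLaw, idx: np.ndarray):
    """(N, K, tau, eps_tilde) of the global fit over a subset of flights."""
    sub = ErrorGrid(
        grid.law, grid.n_axis, grid.k_axis, grid.tau_axis, grid.values[idx]
    )
    res = global_fit(sub, law)
    return res.n_breve, res.k_breve, res.tau_breve, res.eps_tilde


def bootstrap_global(
    grid: ErrorGrid,
    law: GuidanceLaw | None = None,
    iterations: int = 10**3,
    seed: int | None = None,
    level: float = 0.95,
) -> dict[str, BootstrapCI]:
    """BCa bootstrap CIs for the globally fitted parameters and error.

    Each resample draws flights with replacement, recomputes the cell-wise
    median over the cached grid and takes its argmin; no re-simulation is
    performed. Returns intervals for "N", "K", "tau" and "eps".
    """
    law = law or grid.law
    f = grid.n_flights
    if f < 2:
        raise ValueError("need at least two flights to bootstrap")
    point = _global_stats_for_subset(grid, law, np.arange(f))

    rng = np.random.default_rng(seed)
    boot = np.empty((iterations, 4))
    for b in range(iterations):
        idx = rng.integers(0, f, size=f)
        boot[b] = _global_stats_for_subset(grid, law, idx)

    jack = np.empty((f, 4))
    for i in range(f):
        jack[i] = _global_stats_for_subset(grid, law, np.delete(np.arange(f), i))

    out = {}
    for j, name in enumerate(("N", "K", "tau", "eps")):
        accel = _jackknife_acceleration(jack[:, j])
        lower, upper = _bca_interval(boot[:, j], point[j], accel, level)
        out[name] = BootstrapCI(point[j], lower, upper, level, iterations, seed)
    return out


def paired_sign_test(
    eps_a: np.ndarray, eps_b: np.ndarray, drop_ties: bool = True
) -> SignTestResult:
    """Exact two-tailed sign test on paired per-flight errors.

    Tests whether model A's error exceeds model B's more (or less) often
    than chance; zero differences are dropped (classical conditional sign
    test). All-zero differences give p = 1 with a warning.
    """
    eps_a = np.asarray(eps_a, dtype=float)
    eps_b = np.asarray(eps_b, dtype=float)
    if eps_a.shape != eps_b.shape:
        raise ValueError("paired samples must have equal length")
    diff = eps_a - eps_b
    n_pos = int(np.sum(diff > 0))
    n_neg = int(np.sum(diff < 0))
    n_ties = int(np.sum(diff == 0))
    if not drop_ties:
        # conservative: split ties evenly, any odd tie to the smaller count
        half, odd = divmod(n_ties, 2)
        to_pos = half + (odd if n_pos <= n_neg else 0)
        to_neg = n_ties - to_pos
        n_pos += to_pos
        n_neg += to_neg
        n_ties = 0
    m = n_pos + n_neg
    if m == 0:
        warnings.warn("all paired differences are zero; sign test uninformative")
        return SignTestResult(1.0, n_pos, n_neg, n_ties)
    p = binomtest(n_pos, m, 0.5, alternative="two-sided").pvalue
    return SignTestResult(float(min(p, 1.0)), n_pos, n_neg, n_ties)


def make_folds(n: int, k: int, seed: int | None = None) -> np.ndarray:
    """Random partition of n flights into k near-equal folds.

    Returns the fold index of each flight. Fold sizes differ by at most one
    and are equal when k divides n.
    """
    if k < 2:
        raise ValueError("need at least two folds")
    if k > n:
        raise ValueError("more folds than flights")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    fold = np.empty(n, dtype=np.int64)
    sizes = np.full(k, n // k)
    sizes[: n % k] += 1
    start = 0
    for j, s in enumerate(sizes):
        fold[perm[start : start + s]] = j
        start += s
    return fold


def kfold_crossval(
    grid: ErrorGrid,
    k: int = 12,
    seed: int | None = None,
    law: GuidanceLaw | None = None,
) -> CrossValReport:
    """k-fold cross-validation of the globally fitted guidance model.

    Flights are partitioned at random (seeded) into k near-equal folds. For
    each fold the global fit is recomputed on the other k-1 folds and the
    validation score is the median RMS error of the held-out flights at the
    training-optimal parameters. The report's headline number is the mean of
    the k validation medians.
    """
    law = law or grid.law
    f = grid.n_flights
    fold = make_folds(f, k, seed)
    training = global_fit(grid, law)

    n_sel, k_sel = _law_slice_cache(grid, law)
    fold_params: list[GlobalFitResult] = []
    fold_medians = np.empty(k)
    for j in range(k):
        train_idx = np.flatnonzero(fold != j)
        val_idx = np.flatnonzero(fold == j)
        sub = grid.values[train_idx][:, n_sel[:, None], k_sel[None, :], :]
        med = np.median(sub, axis=0)
        i, jj, t = argmin_lexicographic(
            med, grid.n_axis[n_sel], grid.k_axis[k_sel], grid.tau_axis
        )
        gi, gj = int(n_sel[i]), int(k_sel[jj])
        res = GlobalFitResult(
            law,
            float(grid.n_axis[gi]) if law.uses_n else 0.0,
            float(grid.k_axis[gj]) if law.uses_k else 0.0,
            float(grid.tau_axis[t]),
            float(med[i, jj, t]),
            index=(gi, gj, int(t)),
        )
        fold_params.append(res)
        fold_medians[j] = float(np.median(grid.values[val_idx, gi, gj, t]))
    return CrossValReport(
        k=k,
        fold_assignment=fold,
        fold_params=fold_params,
        fold_medians=fold_medians,
        mean_of_medians=float(np.mean(fold_medians)),
        training_eps=training.eps_tilde,
        seed=seed,
    )


def _law_slice_cache(grid: ErrorGrid, law: GuidanceLaw):
    from .fitting import _law_slices

    return _law_slices(grid, law)
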