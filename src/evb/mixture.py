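"""Univariate Gaussian mixture machinery for data-driven biomarker cut-offs.

The cut-off procedure: fit a K-component univariate normal mixture to the
pooled marker values by EM, choose K by sequential parametric-bootstrap
likelihood-ratio tests (the mixtools ``boot.comp`` scheme), then take as
cut-offs the points where the fitted component density curves cross — for a
three-component fit, the crossing of the middle component with each of the
two extreme components.  Crossings of weighted component densities
``pi_i * phi(x; mu_i, sigma_i)`` are equal-posterior (Bayes) boundaries and
are the default; unweighted crossings are available by flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "MixtureModel",
    "CutoffSet",
    "CutoffDerivationError",
    "em_fit",
    "boot_comp",
    "density_crossings",
    "derive_cutoffs",
    "fit_marker_cutoffs",
]

_LOG_2PI = math.log(2.0 * math.pi)


class CutoffDerivationError(RuntimeError):
    """No admissible density crossing exists for the fitted model."""


@dataclass(frozen=True)
class MixtureModel:
    """A fitted K-component univariate Gaussian mixture.

    Components are stored sorted by mean, so label switching across EM
    restarts cannot change any derived quantity.
    """

    k: int
    weights: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    loglik: float
    n: int
    converged: bool
    iterations: int

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")
        if np.any(np.asarray(self.sds) <= 0):
            raise ValueError("component sds must be positive")
        if not np.all(np.diff(self.means) >= 0):
            raise ValueError("components must be sorted by mean")

    def logpdf_components(self, x: np.ndarray) -> np.ndarray:
        """(n, k) matrix of log(pi_j) + log phi(x; mu_j, sigma_j)."""
        x = np.asarray(x, dtype=float)[:, None]
        z = (x - self.means[None, :]) / self.sds[None, :]
        return np.log(self.weights)[None, :] - np.log(self.sds)[None, :] - 0.5 * (z * z + _LOG_2PI)

    def pdf(self, x: np.ndarray) -> np.ndarray:
        return np.exp(self.logpdf_components(np.atleast_1d(x))).sum(axis=1)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        comp = rng.choice(self.k, size=n, p=self.weights)
        return rng.normal(self.means[comp], self.sds[comp])


@dataclass(frozen=True)
class CutoffSet:
    """Two data-driven cut-offs for one marker, with provenance."""

    marker: str
    lower: float
    upper: float
    model: MixtureModel
    cohort: str = ""
    weighted: bool = True
    scale: str = "raw"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValueError(f"cut-offs must satisfy lower < upper, got {(self.lower, self.upper)}")


def _loglik(x: np.ndarray, weights: np.ndarray, means: np.ndarray, sds: np.ndarray) -> float:
    z = (x[:, None] - means[None, :]) / sds[None, :]
    log_comp = np.log(weights)[None, :] - np.log(sds)[None, :] - 0.5 * (z * z + _LOG_2PI)
    m = log_comp.max(axis=1)
    return float((m + np.log(np.exp(log_comp - m[:, None]).sum(axis=1))).sum())


def _em_single(
    x: np.ndarray,
    weights: np.ndarray,
    means: np.ndarray,
    sds: np.ndarray,
    tol: float,
    max_iter: int,
    sd_floor: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float, bool, int]:
    """One EM run from a given start.  Log-likelihood is checked to be
    nondecreasing every iteration (up to round-off)."""
    n = x.size
    prev = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # E step in log space for stability
        z = (x[:, None] - means[None, :]) / sds[None, :]
        log_comp = np.log(weights)[None, :] - np.log(sds)[None, :] - 0.5 * (z * z + _LOG_2PI)
        m = log_comp.max(axis=1)
        log_norm = m + np.log(np.exp(log_comp - m[:, None]).sum(axis=1))
        ll = float(log_norm.sum())
        if ll < prev - 1e-8 * max(1.0, abs(prev)):  # EM guarantee, tolerate round-off
            raise AssertionError(f"EM log-likelihood decreased: {prev} -> {ll}")
        resp = np.exp(log_comp - log_norm[:, None])
        # M step
        nk = resp.sum(axis=0)
        nk = np.maximum(nk, 1e-300)
        weights = nk / n
        means = (resp * x[:, None]).sum(axis=0) / nk
        var = (resp * (x[:, None] - means[None, :]) ** 2).sum(axis=0) / nk
        sds = np.maximum(np.sqrt(var), sd_floor)
        if abs(ll - prev) < tol:
            converged = True
            prev = ll
            break
        prev = ll
    return weights, means, sds, prev, converged, it


def em_fit(
    values: np.ndarray,
    k: int,
    seed: int | None = 0,
    tol: float = 1e-8,
    max_iter: int = 500,
    n_starts: int = 5,
) -> MixtureModel:
    """Fit a k-component univariate Gaussian mixture by EM.

    The best of ``n_starts`` initialisations is returned: one deterministic
    quantile-split start plus seeded random starts.  Component standard
    deviations are floored at ``1e-3 * data range`` to prevent the usual
    single-point likelihood collapse.

    Raises
    ------
    ValueError
        If ``n < 5k``, or the data are degenerate (constant) with k > 1.
    """
    x = np.asarray(values, dtype=float).ravel()
    if not np.all(np.isfinite(x)):
        raise ValueError("values must be finite")
    if k < 1:
        raise ValueError("k must be >= 1")
    if x.size < 5 * k:
        raise ValueError(f"need n >= 5k observations, got n={x.size} for k={k}")
    rng = np.random.default_rng(seed)
    data_range = float(x.max() - x.min())
    sd_floor = max(data_range * 1e-3, 1e-12)

    if data_range == 0.0:
        if k > 1:
            raise ValueError("all values identical: cannot fit k > 1 components")
        return MixtureModel(1, np.array([1.0]), np.array([x[0]]), np.array([sd_floor]), _loglik(x, np.array([1.0]), np.array([x[0]]), np.array([sd_floor])), x.size, True, 0)

    if k == 1:
        mu = float(x.mean())
        sd = max(float(x.std()), sd_floor)
        w, m, s = np.array([1.0]), np.array([mu]), np.array([sd])
        return MixtureModel(1, w, m, s, _loglik(x, w, m, s), x.size, True, 0)

    best = None
    xs = np.sort(x)
    for start in range(max(1, n_starts)):
        if start == 0:
            # quantile split: equal-count blocks
            blocks = np.array_split(xs, k)
            means0 = np.array([b.mean() for b in blocks])
            sds0 = np.array([max(b.std(), sd_floor) for b in blocks])
            weights0 = np.full(k, 1.0 / k)
        else:
            means0 = rng.choice(x, size=k, replace=False)
            order = np.argsort(means0)
            means0 = means0[order]
            sds0 = np.full(k, max(x.std() / k, sd_floor))
            weights0 = rng.dirichlet(np.full(k, 5.0))
        try:
            w, m, s, ll, conv, it = _em_single(x, weights0, means0, sds0, tol, max_iter, sd_floor)
        except (AssertionError, FloatingPointError):
            continue
        if best is None or ll > best[3]:
            best = (w, m, s, ll, conv, it)
    if best is None:
        raise RuntimeError("every EM start failed")
    w, m, s, ll, conv, it = best
    order = np.argsort(m)
    return MixtureModel(k, w[order], m[order], s[order], ll, x.size, conv, it)


def boot_comp(
    values: np.ndarray,
    k_max: int = 3,
    n_boot: int = 100,
    alpha: float = 0.05,
    seed: int | None = 0,
    n_starts: int = 3,
    max_retries: int = 5,
) -> int:
    """Choose the number of mixture components by sequential parametric
    bootstrap likelihood-ratio tests (the ``boot.comp`` scheme).

    For k = 1, 2, ...: fit k and k+1 components, compute the observed LRT
    statistic ``2 (l_{k+1} - l_k)``, simulate ``n_boot`` datasets from the
    k-component fit, refit both models on each, and take p as the fraction
    of bootstrap statistics at least as large as the observed one.  Stops at
    the first k whose test does not reject at level ``alpha``; returns
    ``k_max`` if every test rejects.  Deterministic under a fixed seed.
    """
    x = np.asarray(values, dtype=float).ravel()
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    if k_max == 1:
        return 1
    if n_boot < 20:
        raise ValueError("n_boot must be >= 20")
    rng = np.random.default_rng(seed)
    fit_small = em_fit(x, 1, seed=int(rng.integers(2**31)), n_starts=n_starts)
    for k in range(1, k_max):
        fit_big = em_fit(x, k + 1, seed=int(rng.integers(2**31)), n_starts=n_starts)
        observed = 2.0 * (fit_big.loglik - fit_small.loglik)
        exceed = 0
        for b in range(n_boot):
            for _attempt in range(max_retries):
                xb = fit_small.sample(x.size, rng)
                try:
                    # warm-start each refit from the generating / observed
                    # fits (the boot.comp strategy): far fewer EM iterations
                    # than fresh multi-start, same test statistic.
                    b_small = _refit_from(xb, fit_small)
                    b_big = _refit_from(xb, fit_big)
                except (ValueError, RuntimeError, AssertionError):
                    continue  # redraw the replicate
                stat = 2.0 * (b_big.loglik - b_small.loglik)
                if stat >= observed:
                    exceed += 1
                break
        p = exceed / n_boot
        if p > alpha:
            return k
        fit_small = fit_big
    return k_max


def _refit_from(x: np.ndarray, template: MixtureModel, tol: float = 1e-6, max_iter: int = 300) -> MixtureModel:
    """EM refit of a bootstrap sample, warm-started at a template's parameters."""
    data_range = float(x.max() - x.min())
    sd_floor = max(data_range * 1e-3, 1e-12)
    if data_range == 0.0:
        raise ValueError("degenerate bootstrap sample")
    w, m, s, ll, conv, it = _em_single(
        x,
        template.weights.copy(),
        template.means.copy(),
        np.maximum(template.sds, sd_floor),
        tol,
        max_iter,
        sd_floor,
    )
    order = np.argsort(m)
    return MixtureModel(template.k, w[order], m[order], s[order], ll, x.size, conv, it)


def density_crossings(
    model: MixtureModel,
    i: int,
    j: int,
    weighted: bool = True,
) -> list[float]:
    """Crossing points of two fitted component density curves.

    Solves ``pi_i phi(x; mu_i, s_i) = pi_j phi(x; mu_j, s_j)`` (weighted) or
    the unweighted ``phi_i = phi_j``.  Taking logs gives a quadratic in x
    when the sds differ (0, 1 or 2 real roots) and a linear equation when
    they coincide.  Each root is verified by a sign change of the
    log-density difference; roots are returned sorted.

    Raises
    ------
    ValueError
        If i == j, indices are out of range, or the two components are
        identical (infinite crossing set).
    """
    if i == j:
        raise ValueError("need two distinct components")
    for idx in (i, j):
        if not 0 <= idx < model.k:
            raise ValueError(f"component index {idx} out of range for k={model.k}")
    wi = math.log(model.weights[i]) if weighted else 0.0
    wj = math.log(model.weights[j]) if weighted else 0.0
    mi, si = float(model.means[i]), float(model.sds[i])
    mj, sj = float(model.means[j]), float(model.sds[j])
    if mi == mj and si == sj and wi == wj:
        raise ValueError("identical components: infinite crossing set")

    # log[pi_i phi_i] - log[pi_j phi_j] = a x^2 + b x + c
    a = 0.5 * (1.0 / sj**2 - 1.0 / si**2)
    b = mi / si**2 - mj / sj**2
    c = (wi - wj) - math.log(si / sj) - 0.5 * (mi**2 / si**2 - mj**2 / sj**2)
    if abs(a) < 1e-300:
        if b == 0.0:
            return []  # parallel log-densities, never equal
        roots = [-c / b]
    else:
        disc = b * b - 4.0 * a * c
        if disc < 0:
            return []
        sq = math.sqrt(disc)
        roots = [(-b - sq) / (2.0 * a), (-b + sq) / (2.0 * a)]
    roots = sorted(set(roots))

    def logdiff(x: float) -> float:
        return (
            (wi - wj)
            - math.log(si / sj)
            - 0.5 * ((x - mi) ** 2 / si**2 - (x - mj) ** 2 / sj**2)
        )

    verified = []
    for r in roots:
        eps = 1e-6 * max(1.0, abs(r)) + 1e-9
        if logdiff(r - eps) * logdiff(r + eps) <= 0.0:
            verified.append(float(r))
    return verified


def derive_cutoffs(
    model: MixtureModel,
    marker: str = "",
    cohort: str = "",
    weighted: bool = True,
    scale: str = "raw",
) -> CutoffSet:
    """Cut-offs from a three-component fit: the crossing of the middle
    component with each extreme component, restricted to the interval
    between the respective means.

    If several crossings fall in the admissible interval, the one where the
    lower-mean component dominates to its left is chosen.

    Raises
    ------
    CutoffDerivationError
        If the model is not a 3-component fit with strictly ordered means,
        or no crossing lies in the required interval.
    """
    if model.k != 3:
        raise CutoffDerivationError(f"cut-off derivation requires k=3, got k={model.k}")
    if not (model.means[0] < model.means[1] < model.means[2]):
        raise CutoffDerivationError(f"component means must be strictly ordered, got {model.means}")

    def pick(lo_comp: int, hi_comp: int) -> float:
        lo, hi = float(model.means[lo_comp]), float(model.means[hi_comp])
        candidates = [r for r in density_crossings(model, lo_comp, hi_comp, weighted) if lo < r < hi]
        if not candidates:
            raise CutoffDerivationError(
                f"no crossing of components {lo_comp} and {hi_comp} in ({lo:.4g}, {hi:.4g}); "
                f"model: weights={model.weights}, means={model.means}, sds={model.sds}"
            )
        for r in candidates:  # lower-mean component must dominate just left of the cut
            eps = 1e-6 * max(1.0, abs(r))
            left = model.logpdf_components(np.array([r - eps]))[0]
            if left[lo_comp] >= left[hi_comp]:
                return r
        return candidates[0]

    lower = pick(0, 1)
    upper = pick(1, 2)
    return CutoffSet(marker=marker, lower=lower, upper=upper, model=model, cohort=cohort, weighted=weighted, scale=scale)


def fit_marker_cutoffs(
    values: np.ndarray,
    marker: str,
    cohort: str = "",
    k: int = 3,
    k_max: int = 3,
    n_boot: int = 100,
    alpha: float = 0.05,
    seed: int | None = 0,
    weighted: bool = True,
    run_boot: bool = True,
    n_starts: int = 5,
) -> CutoffSet:
    """End-to-end cut-off derivation for one marker.

    Runs the bootstrap component-number test (unless ``run_boot`` is False),
    then fits ``k`` components regardless — three components are required by
    the crossing construction, so a divergent bootstrap answer is recorded in
    the metadata rather than honoured — and derives the crossing cut-offs.
    """
    x = np.asarray(values, dtype=float).ravel()
    rng = np.random.default_rng(seed)
    meta: dict = {"n": int(x.size), "n_boot": n_boot, "alpha": alpha}
    if run_boot:
        k_selected = boot_comp(x, k_max=k_max, n_boot=n_boot, alpha=alpha, seed=int(rng.integers(2**31)))
        meta["k_selected"] = k_selected
        if k_selected != k:
            meta["warning"] = f"bootstrap selected k={k_selected}; k={k} forced for cut-off derivation"
    model = em_fit(x, k, seed=int(rng.integers(2**31)), n_starts=n_starts)
    cut = derive_cutoffs(model, marker=marker, cohort=cohort, weighted=weighted)
    return CutoffSet(
        marker=marker,
        lower=cut.lower,
        upper=cut.upper,
        model=model,
        cohort=cohort,
        weighted=weighted,
        meta=meta,
    )
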