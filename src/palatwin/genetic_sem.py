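"""Univariate classical-twin variance-component models (ACE/ADE family).

The classical twin design decomposes the phenotypic variance V of a trait
into additive genetic (A = a^2), shared environmental (C = c^2), dominance
genetic (D = d^2) and non-shared environmental (E = e^2) components.  Twin
pairs are modelled as bivariate normal with a common mean mu, diagonal
variance V = a^2 + c^2 + d^2 + e^2 and within-pair covariance

    MZ:  a^2 + c^2 + d^2            DZ:  a^2/2 + c^2 + d^2/4

reflecting the expected twin correlations of latent factors: additive and
dominance effects correlate 1 in monozygotic pairs and 0.5 / 0.25 in
dizygotic pairs, the shared environment correlates 1 in both, the non-shared
environment 0.  C and D are not separately identifiable from twins reared
together, so the candidate set is {ACE, ADE, AE, CE, E}.

Fitting
-------
The joint MZ+DZ log-likelihood depends on the data only through per-zygosity
sufficient statistics, and for any *fixed* standardized composition
(proportions A, C, D, E of V) the MLEs of mu and V are available in closed
form.  Maximum likelihood therefore reduces to a deterministic bounded
search over the standardized simplex: one-dimensional for AE/CE, two-
dimensional for ACE/ADE, trivial for E.  Components may sit on the
boundary at zero.  No random starts or seeds are involved; identical data
give identical fits.

Model choice follows the usual twin-study ladder: a chi-square likelihood
ratio test compares each nested sub-model against the full model of its
branch at alpha = 0.05, AIC (= -2lnL + 2k) compares non-nested survivors,
and the simplest model that is not rejected is reported with standardized
components, profile-likelihood 95% confidence intervals and the
narrow-sense heritability h^2 = a^2 / V.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize, stats

LOG_2PI = float(np.log(2.0 * np.pi))

#: free path coefficients of each candidate model (e is always present)
MODEL_PATHS: dict[str, tuple[str, ...]] = {
    "ACE": ("a", "c", "e"),
    "ADE": ("a", "d", "e"),
    "AE": ("a", "e"),
    "CE": ("c", "e"),
    "DE": ("d", "e"),
    "E": ("e",),
}

#: default candidate ladder; DE exists behind a flag but is excluded by
#: default (dominance without additive influence is biologically implausible)
DEFAULT_CANDIDATES = ("ACE", "ADE", "AE", "CE", "E")

_PATH_TO_COMP = {"a": "A", "c": "C", "d": "D", "e": "E"}


class SemError(ValueError):
    pass


@dataclass(frozen=True)
class PathParams:
    """Path coefficients (trait units) and grand mean of one model."""

    a: float
    c: float
    d: float
    e: float
    mu: float
    model: str

    def __post_init__(self) -> None:
        if self.model not in MODEL_PATHS:
            raise SemError(f"unknown model tag {self.model!r}")
        if self.e <= 0:
            raise SemError("the non-shared environment path e must be positive")
        if self.c != 0 and self.d != 0:
            raise SemError("c and d may not both be nonzero")
        for p in "acd":
            if getattr(self, p) != 0 and p not in MODEL_PATHS[self.model]:
                raise SemError(f"path {p!r} must be 0 under model {self.model}")

    @property
    def total_variance(self) -> float:
        return self.a**2 + self.c**2 + self.d**2 + self.e**2


def expected_pair_covariance(params: PathParams, zygosity: str) -> np.ndarray:
    """Model-implied 2x2 covariance matrix of a twin pair."""
    V = params.total_variance
    if zygosity == "MZ":
        cov = params.a**2 + params.c**2 + params.d**2
    elif zygosity == "DZ":
        cov = 0.5 * params.a**2 + params.c**2 + 0.25 * params.d**2
    else:
        raise SemError(f"zygosity must be MZ or DZ, got {zygosity!r}")
    return np.array([[V, cov], [cov, V]])


# ---------------------------------------------------------------------------
# sufficient statistics and the concentrated likelihood


@dataclass(frozen=True)
class PairStats:
    """Sufficient statistics of one zygosity group's (n, 2) pair array."""

    n: int
    t1: float   # sum of (x1 + x2)
    t2: float   # sum of (x1^2 + x2^2)
    t12: float  # sum of x1 * x2

    @classmethod
    def from_pairs(cls, pairs: np.ndarray) -> "PairStats":
        p = np.asarray(pairs, float)
        if p.ndim != 2 or p.shape[1] != 2:
            raise SemError("pairs must be an (n, 2) array")
        if not np.all(np.isfinite(p)):
            raise SemError("pair values must be finite")
        return cls(
            n=p.shape[0],
            t1=float(p.sum()),
            t2=float((p**2).sum()),
            t12=float((p[:, 0] * p[:, 1]).sum()),
        )


def _neg2ll_correlations(
    r: Sequence[float], groups: Sequence[PairStats]
) -> tuple[float, float, float]:
    """Concentrated -2lnL given per-group within-pair correlations.

    For Sigma_g = V * [[1, r_g], [r_g, 1]], the grand mean and total variance
    have closed-form MLEs:

        mu_hat = beta / alpha,   V_hat = Q(mu_hat) / (2 N)

    where Q is the summed Mahalanobis quadratic form and alpha, beta collect
    the (1 + r_g)-weighted first-moment terms.  Returns
    (-2lnL, V_hat, mu_hat).
    """
    alpha = beta = gamma = 0.0
    N = 0
    for rg, st in zip(r, groups):
        if not -1.0 < rg < 1.0:
            return np.inf, np.nan, np.nan
        one = 1.0 + rg
        w2 = 1.0 / (1.0 - rg**2)
        wr = rg * w2
        alpha += 2.0 * st.n / one
        beta += st.t1 / one
        gamma += w2 * st.t2 - 2.0 * wr * st.t12
        N += st.n
    if N == 0 or alpha <= 0:
        raise SemError("no pairs provided")
    mu = beta / alpha
    qmin = gamma - beta**2 / alpha
    if qmin <= 0:
        return np.inf, np.nan, np.nan
    V = qmin / (2.0 * N)
    n2ll = 2.0 * N * (LOG_2PI + 1.0) + 2.0 * N * np.log(V)
    for rg, st in zip(r, groups):
        n2ll += st.n * np.log(1.0 - rg**2)
    return float(n2ll), float(V), float(mu)


def _implied_correlations(std: Mapping[str, float]) -> tuple[float, float]:
    r_mz = std.get("A", 0.0) + std.get("C", 0.0) + std.get("D", 0.0)
    r_dz = 0.5 * std.get("A", 0.0) + std.get("C", 0.0) + 0.25 * std.get("D", 0.0)
    return r_mz, r_dz


# ---------------------------------------------------------------------------
# model fitting


@dataclass(frozen=True)
class VarianceComponentsFit:
    """One fitted variance-component model."""

    model: str
    params: PathParams
    standardized: dict[str, float]
    minus2lnL: float
    aic: float
    n_free: int
    h2: float
    converged: bool
    n_mz: int
    n_dz: int
    ci95: dict[str, tuple[float, float]] | None = None
    trait: str = ""
    stage: str = ""

    @property
    def free_components(self) -> tuple[str, ...]:
        return tuple(_PATH_TO_COMP[p] for p in MODEL_PATHS[self.model])


def _stats_of(pairs) -> PairStats:
    return pairs if isinstance(pairs, PairStats) else PairStats.from_pairs(pairs)


def _composition(model: str, x: Sequence[float]) -> dict[str, float] | None:
    """Map free simplex coordinates to standardized components, or None if
    outside the simplex."""
    free = [c for c in ("A", "C", "D") if _PATH_TO_COMP.get(c.lower()) and
            c.lower() in MODEL_PATHS[model]]
    vals = list(x)
    if len(vals) != len(free):
        raise SemError("bad composition dimension")
    if any(v < 0.0 for v in vals) or sum(vals) > 1.0 - 1e-12:
        return None
    std = dict.fromkeys("ACDE", 0.0)
    for k, v in zip(free, vals):
        std[k] = float(v)
    std["E"] = 1.0 - sum(vals)
    return std


def _objective(model: str, groups: Sequence[PairStats]):
    def fn(x: np.ndarray) -> float:
        std = _composition(model, np.atleast_1d(x))
        if std is None:
            return np.inf
        return _neg2ll_correlations(_implied_correlations(std), groups)[0]
    return fn


def _moment_start(model: str, groups: Sequence[PairStats]) -> list[float]:
    """Method-of-moments start from the sample within-pair correlations."""
    r = []
    for st in groups:
        mean = st.t1 / (2 * st.n)
        var = st.t2 / (2 * st.n) - mean**2
        cov = st.t12 / st.n - mean**2
        r.append(cov / var if var > 0 else 0.0)
    r_mz, r_dz = r
    clip = lambda v: min(max(v, 0.02), 0.9)  # noqa: E731
    if model == "ACE":
        return [clip(2 * (r_mz - r_dz)), clip(2 * r_dz - r_mz)]
    if model == "ADE":
        return [clip(4 * r_dz - r_mz), clip(2 * r_mz - 4 * r_dz)]
    if model == "AE":
        return [clip(r_mz)]
    if model in ("CE", "DE"):
        return [clip(r_mz)]
    return []


def fit_model(
    mz_pairs,
    dz_pairs,
    model: str = "AE",
    trait: str = "",
    stage: str = "",
    compute_ci: bool = False,
) -> VarianceComponentsFit:
    """Maximum-likelihood fit of one candidate model to MZ and DZ pairs.

    ``mz_pairs`` / ``dz_pairs`` are (n, 2) arrays (or precomputed
    :class:`PairStats`).  Components are constrained non-negative with the
    boundary at zero allowed.  Deterministic: the search runs from the
    method-of-moments start plus fixed perturbations and keeps the best.
    """
    if model not in MODEL_PATHS:
        raise SemError(f"unknown model tag {model!r}")
    st_mz, st_dz = _stats_of(mz_pairs), _stats_of(dz_pairs)
    groups = (st_mz, st_dz)
    obj = _objective(model, groups)
    n_params = len(MODEL_PATHS[model]) - 1  # free simplex coordinates

    converged = True
    if n_params == 0:
        x_best = np.empty(0)
        f_best = obj(x_best)
    elif n_params == 1:
        res = optimize.minimize_scalar(
            lambda s: obj([s]), bounds=(0.0, 1.0 - 1e-9), method="bounded",
            options={"xatol": 1e-12},
        )
        x_best, f_best = np.array([res.x]), float(res.fun)
        # the bounded search cannot land exactly on the boundary; test it
        if obj([0.0]) <= f_best:
            x_best, f_best = np.array([0.0]), obj([0.0])
        converged = bool(res.success)
    else:
        start = np.array(_moment_start(model, groups))
        best = None
        for delta in (0.0, 0.15, -0.15):
            x0 = np.clip(start + delta, 0.01, 0.95)
            if x0.sum() > 0.98:
                x0 = x0 / x0.sum() * 0.98
            # fatol sits just above float noise of a -2lnL of order 1e3
            res = optimize.minimize(
                obj, x0, method="Nelder-Mead",
                options={"xatol": 1e-9, "fatol": 1e-9, "maxiter": 4000},
            )
            if best is None or res.fun < best.fun:
                best = res
        # polish possible boundary solutions (single-component edges)
        edges = [np.zeros(2)]
        for i in range(2):
            e = np.zeros(2)
            r1 = optimize.minimize_scalar(
                lambda s, i=i: obj(np.eye(2)[i] * s),
                bounds=(0.0, 1.0 - 1e-9), method="bounded",
                options={"xatol": 1e-12},
            )
            e[i] = r1.x
            edges.append(e)
        x_best, f_best = best.x, float(best.fun)
        on_edge = False
        for e in edges:
            fe = obj(e)
            if fe < f_best:
                x_best, f_best, on_edge = e, fe, True
        converged = bool(best.success) or on_edge

    std = _composition(model, x_best)
    if std is None:
        raise SemError(f"{model} fit failed to stay on the simplex")
    n2ll, V, mu = _neg2ll_correlations(_implied_correlations(std), groups)
    if not np.isfinite(n2ll):
        raise SemError(f"{model} fit did not converge to a finite likelihood")
    paths = {p: 0.0 for p in "acd"}
    for p in MODEL_PATHS[model]:
        if p != "e":
            paths[p] = float(np.sqrt(std[_PATH_TO_COMP[p]] * V))
    e_path = float(np.sqrt(max(std["E"], 1e-15) * V))
    params = PathParams(
        a=paths["a"], c=paths["c"], d=paths["d"], e=e_path, mu=mu, model=model
    )
    k = n_params + 2  # simplex coordinates + total variance + mean
    fit = VarianceComponentsFit(
        model=model,
        params=params,
        standardized={k_: float(v) for k_, v in std.items()},
        minus2lnL=float(n2ll),
        aic=float(n2ll + 2 * k),
        n_free=k,
        h2=float(std["A"]),
        converged=converged,
        n_mz=st_mz.n,
        n_dz=st_dz.n,
        trait=trait,
        stage=stage,
    )
    if compute_ci:
        fit = confidence_intervals(fit, st_mz, st_dz)
    return fit


def saturated_minus2lnL(mz_pairs, dz_pairs) -> float:
    """-2lnL of the saturated model (free per-zygosity means and covariances).

    Closed form from the per-group MLE mean vector and covariance matrix:
    -2lnL = sum_g n_g (2 log 2pi + log det S_g + 2).
    """
    total = 0.0
    for pairs in (mz_pairs, dz_pairs):
        p = np.asarray(pairs, float)
        if p.ndim != 2 or p.shape[1] != 2 or p.shape[0] < 3:
            raise SemError("saturated model needs (n>=3, 2) pair arrays")
        n = p.shape[0]
        S = np.cov(p, rowvar=False, bias=True)
        sign, logdet = np.linalg.slogdet(S)
        if sign <= 0:
            raise SemError("singular sample covariance")
        total += n * (2.0 * LOG_2PI + logdet + 2.0)
    return float(total)


# ---------------------------------------------------------------------------
# model comparison and selection


@dataclass(frozen=True)
class ModelComparison:
    full: str
    sub: str
    delta_minus2lnL: float
    df: int
    p: float
    aic_full: float
    aic_sub: float


def _is_nested(sub: str, full: str) -> bool:
    return set(MODEL_PATHS[sub]) < set(MODEL_PATHS[full])


def likelihood_ratio_test(
    full: VarianceComponentsFit,
    sub: VarianceComponentsFit,
    boundary: bool = False,
) -> ModelComparison:
    """Chi-square LRT of a nested sub-model against its full model.

    ``boundary=True`` replaces the naive chi-square reference by the 50:50
    boundary mixture for df = 1 (a variance component pinned at zero lies on
    the edge of the parameter space); the naive reference is the default.
    """
    if not _is_nested(sub.model, full.model):
        raise SemError(
            f"{sub.model} is not nested in {full.model}; compare via AIC"
        )
    delta = sub.minus2lnL - full.minus2lnL
    if delta < -1e-6:
        raise SemError(
            f"negative deviance {delta:.2e}: optimizer failure on {full.model}"
        )
    delta = max(delta, 0.0)
    df = full.n_free - sub.n_free
    p = float(stats.chi2.sf(delta, df))
    if boundary and df == 1:
        p = float(0.5 * stats.chi2.sf(delta, 1) + 0.5 * (delta <= 0.0))
    return ModelComparison(
        full=full.model, sub=sub.model, delta_minus2lnL=float(delta), df=df,
        p=p, aic_full=full.aic, aic_sub=sub.aic,
    )


@dataclass(frozen=True)
class SelectionResult:
    selected: VarianceComponentsFit
    comparisons: list[ModelComparison]
    trace: list[str] = field(default_factory=list)


def select_model(
    fits: Mapping[str, VarianceComponentsFit],
    alpha: float = 0.05,
) -> SelectionResult:
    """Most parsimonious model by the LRT ladder plus AIC.

    A sub-model survives if dropping down to it from the full model of its
    branch (ACE, or ADE for the dominance branch) shows no significant loss
    of fit at ``alpha``.  Among surviving models the simplest (fewest free
    parameters) wins; AIC breaks ties between equally simple non-nested
    models.  Any unconverged candidate aborts selection.
    """
    bad = [m for m, f in fits.items() if not f.converged]
    if bad:
        raise SemError(f"unconverged candidate fit(s): {sorted(bad)}")
    comparisons: list[ModelComparison] = []
    trace: list[str] = []
    survivors: list[VarianceComponentsFit] = []
    fulls = [m for m in ("ACE", "ADE") if m in fits]
    for name, fit in fits.items():
        parents = [f for f in fulls if f != name and _is_nested(name, f)]
        rejected = False
        for parent in parents:
            cmp_ = likelihood_ratio_test(fits[parent], fit)
            comparisons.append(cmp_)
            trace.append(
                f"{cmp_.full} vs {cmp_.sub}: delta={cmp_.delta_minus2lnL:.4f} "
                f"df={cmp_.df} p={cmp_.p:.4g}"
            )
            if cmp_.p < alpha:
                rejected = True
        if not rejected:
            survivors.append(fit)
    if not survivors:
        survivors = [fits[m] for m in fulls] or list(fits.values())
    min_free = min(f.n_free for f in survivors)
    simplest = [f for f in survivors if f.n_free == min_free]
    selected = min(simplest, key=lambda f: f.aic)
    trace.append(
        "survivors: " + ", ".join(f"{f.model}(AIC={f.aic:.1f})" for f in survivors)
    )
    trace.append(f"selected: {selected.model}")
    return SelectionResult(selected=selected, comparisons=comparisons, trace=trace)


def fit_candidates(
    mz_pairs, dz_pairs,
    candidates: Sequence[str] = DEFAULT_CANDIDATES,
    trait: str = "", stage: str = "",
    compute_ci: bool = False,
) -> dict[str, VarianceComponentsFit]:
    """Fit every candidate model on identical data."""
    st_mz, st_dz = _stats_of(mz_pairs), _stats_of(dz_pairs)
    if st_mz.n < 10 or st_dz.n < 10:
        raise SemError("need at least 10 pairs per zygosity group")
    return {
        m: fit_model(st_mz, st_dz, m, trait=trait, stage=stage,
                     compute_ci=compute_ci)
        for m in candidates
    }


# ---------------------------------------------------------------------------
# profile-likelihood confidence intervals


_BIG = 1e12


def _profile_neg2ll(
    model: str, comp: str, s: float, groups: Sequence[PairStats]
) -> float:
    """Min -2lnL with standardized component ``comp`` fixed at ``s``.

    The remaining probability mass 1 - s is split over the model's other free
    components (at most two, so the inner problem is at worst 1-D).
    """
    rest = 1.0 - s
    named = [c for c in ("A", "C", "D") if c.lower() in MODEL_PATHS[model]]
    if comp == "E":
        slots = named
    else:
        if comp not in named:
            raise SemError(f"component {comp} is not free under {model}")
        slots = [c for c in named if c != comp] + ["E"]

    def at(w: float) -> float:
        std = dict.fromkeys("ACDE", 0.0)
        std[comp] = s
        if len(slots) == 1:
            std[slots[0]] = rest
        else:
            std[slots[0]] = w * rest
            std[slots[1]] = (1.0 - w) * rest
        if std["E"] <= 1e-12:
            return _BIG
        val = _neg2ll_correlations(_implied_correlations(std), groups)[0]
        return val if np.isfinite(val) else _BIG

    if len(slots) <= 1:
        return at(0.0)
    res = optimize.minimize_scalar(
        at, bounds=(0.0, 1.0), method="bounded", options={"xatol": 1e-10}
    )
    return float(min(res.fun, at(0.0), at(1.0)))


def confidence_intervals(
    fit: VarianceComponentsFit,
    mz_pairs,
    dz_pairs,
    level: float = 0.95,
) -> VarianceComponentsFit:
    """Profile-likelihood intervals on the standardized components.

    Each bound sits where -2lnL rises above the minimum by the chi-square(1)
    quantile of ``level`` (3.841 for 95%), clamped to [0, 1].  The point
    estimate always lies inside the interval.
    """
    groups = (_stats_of(mz_pairs), _stats_of(dz_pairs))
    crit = float(stats.chi2.ppf(level, 1))
    target = fit.minus2lnL + crit
    ci: dict[str, tuple[float, float]] = {}
    for comp in fit.free_components:
        s_hat = fit.standardized[comp]

        def g(s: float) -> float:
            return _profile_neg2ll(fit.model, comp, s, groups) - target

        lo, hi = 0.0, 1.0
        if s_hat > 1e-9 and g(0.0) > 0:
            lo = optimize.brentq(g, 0.0, s_hat, xtol=1e-6)
        if s_hat < 1.0 - 1e-9 and g(1.0 - 1e-9) > 0:
            hi = optimize.brentq(g, s_hat, 1.0 - 1e-9, xtol=1e-6)
        elif s_hat >= 1.0 - 1e-9:
            hi = 1.0
        ci[comp] = (float(np.clip(lo, 0, 1)), float(np.clip(hi, 0, 1)))
    return VarianceComponentsFit(
        **{**fit.__dict__, "ci95": ci}
    )


def heritability(fit: VarianceComponentsFit) -> float:
    """Narrow-sense heritability: additive variance over total variance."""
    return float(fit.standardized["A"])
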