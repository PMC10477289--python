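"""Fitting the brightness model to mean visually scaled brightness data.

The linear transform (a, b) enters the model linearly, so for any candidate
nonlinear parameter set (alpha, beta, gamma, delta1, delta2) the optimal
(a, b) is an ordinary least-squares solve (variable projection).  All
optimisers here therefore search only the nonlinear parameters and profile
(a, b) out, which removes two dimensions and makes the objective cheap and
smooth.

Two known degeneracies are handled explicitly rather than hidden:

* the overall-scale degeneracy: (alpha, beta, a) and (c*alpha, c*beta, a/c)
  give identical predictions, so the profiled RMSE depends on (alpha, beta)
  only through beta/alpha.  The global fit fixes alpha = 1 by default.
* near-flat directions when delta1, delta2 -> 0: the bracket degenerates
  toward the constant alpha + beta, and only products like (alpha+beta)*a
  stay identified.

The staged procedure mirrors the historical modelling sequence: fit the
rating-scale transform of the Fotios-Levermore form and of the
illuminance-only form first, then scan fixed channel-weight pairs with a
tied compression exponent, refine the exponent at the best pair, and finish
with a multistart global fit.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import qmc

from .errors import (
    DegenerateFitError,
    DomainError,
    OptimizationError,
    UndefinedMetricError,
    ValidationError,
)
from .model import BrightnessModelParams, evaluate_m, evaluate_raw

__all__ = [
    "ExperimentDataset",
    "FitResult",
    "FitLedger",
    "rmse",
    "r_squared",
    "fit_linear_ab",
    "fit_quality",
    "profiled_objective",
    "global_fit",
    "grid_oracle",
    "staged_fit",
    "default_weight_pairs",
    "DEFAULT_BOUNDS",
]

DATASET_CSV_COLUMNS = ("id", "Ev_lux", "S_ratio", "G_ratio", "vsb_mean", "vsb_sd", "n")

#: Default box bounds for the nonlinear parameters.  'delta' is the tied
#: exponent delta1 = delta2 used by the weight-scan stages.
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "alpha": (0.0, 2.0),
    "beta": (0.0, 2.0),
    "gamma": (1e-3, 1.5),
    "delta1": (0.0, 1.0),
    "delta2": (0.0, 1.0),
    "delta": (0.0, 1.0),
}

#: Fixed (alpha, beta) channel-weight pairs scanned by the default stage plan.
_WEIGHT_PAIRS = (
    (1.0, 0.0),
    (0.8, 0.2),
    (0.67, 0.33),
    (0.6, 0.4),
    (0.5, 0.5),
    (0.4, 0.6),
    (0.33, 0.67),
    (0.2, 0.8),
    (0.0, 1.0),
)

RMSE_TIE_TOL = 1e-10


def default_weight_pairs() -> tuple[tuple[float, float], ...]:
    """The (alpha, beta) pairs scanned in the weight-scan stage."""
    return _WEIGHT_PAIRS


# ---------------------------------------------------------------------------
# dataset container


@dataclass(frozen=True)
class ExperimentDataset:
    """Per-stimulus signals and mean visually scaled brightness (VSB).

    Arrays are aligned by stimulus: ``Ev`` (lux), ``S``/``G`` (dimensionless
    receptor ratios), ``vsb_mean``/``vsb_sd`` on the 0-100 rating scale and
    ``n_observers`` per stimulus.
    """

    ids: tuple[str, ...]
    Ev: np.ndarray
    S: np.ndarray
    G: np.ndarray
    vsb_mean: np.ndarray
    vsb_sd: np.ndarray
    n_observers: np.ndarray

    def __post_init__(self) -> None:
        arrays = {}
        for nm in ("Ev", "S", "G", "vsb_mean", "vsb_sd"):
            arrays[nm] = np.asarray(getattr(self, nm), dtype=float)
        arrays["n_observers"] = np.asarray(self.n_observers, dtype=int)
        n = len(self.ids)
        for nm, arr in arrays.items():
            if arr.shape != (n,):
                raise ValidationError(f"column {nm} length does not match ids")
            arr.setflags(write=False)
            object.__setattr__(self, nm, arr)
        object.__setattr__(self, "ids", tuple(str(i) for i in self.ids))
        if np.any(arrays["Ev"] <= 0):
            raise ValidationError("all Ev must be positive")
        vsb = arrays["vsb_mean"]
        if np.any(vsb < 0) or np.any(vsb > 100):
            raise ValidationError("vsb_mean must lie in [0, 100]")

    def __len__(self) -> int:
        return len(self.ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.ids,
                "Ev_lux": self.Ev,
                "S_ratio": self.S,
                "G_ratio": self.G,
                "vsb_mean": self.vsb_mean,
                "vsb_sd": self.vsb_sd,
                "n": self.n_observers,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ExperimentDataset":
        missing = [c for c in DATASET_CSV_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"dataset is missing columns {missing}")
        return cls(
            ids=tuple(df["id"].astype(str)),
            Ev=df["Ev_lux"].to_numpy(float),
            S=df["S_ratio"].to_numpy(float),
            G=df["G_ratio"].to_numpy(float),
            vsb_mean=df["vsb_mean"].to_numpy(float),
            vsb_sd=df["vsb_sd"].to_numpy(float),
            n_observers=df["n"].to_numpy(int),
        )

    @classmethod
    def from_csv(cls, path) -> "ExperimentDataset":
        try:
            df = pd.read_csv(path, comment="#")
        except Exception as exc:
            raise ValidationError(f"could not parse dataset CSV {path!s}: {exc}") from exc
        return cls.from_frame(df)


def _require_fittable(dataset: ExperimentDataset) -> None:
    if len(dataset) < 3:
        raise ValidationError("a fit requires at least 3 stimuli")


# ---------------------------------------------------------------------------
# metrics


def rmse(model_values, vsb) -> float:
    """Root mean square error, mean taken over the actual number of points."""
    m = np.asarray(model_values, dtype=float)
    v = np.asarray(vsb, dtype=float)
    if m.shape != v.shape:
        raise ValidationError("model and VSB vectors must have equal length")
    if m.size == 0:
        raise ValidationError("RMSE of empty vectors is undefined")
    return float(np.sqrt(np.mean((m - v) ** 2)))


def r_squared(model_values, vsb) -> float:
    """Coefficient of determination 1 - SSE/SST, SST about the VSB mean."""
    m = np.asarray(model_values, dtype=float)
    v = np.asarray(vsb, dtype=float)
    if m.shape != v.shape:
        raise ValidationError("model and VSB vectors must have equal length")
    if v.size < 3:
        raise ValidationError("R^2 needs at least 3 points")
    sst = float(np.sum((v - v.mean()) ** 2))
    if sst <= 0:
        raise UndefinedMetricError("R^2 undefined: VSB has zero variance")
    sse = float(np.sum((m - v) ** 2))
    return 1.0 - sse / sst


def fit_linear_ab(raw, vsb) -> tuple[float, float]:
    """OLS of vsb on raw: the (a, b) minimising RMSE for fixed nonlinear params."""
    x = np.asarray(raw, dtype=float)
    y = np.asarray(vsb, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValidationError("fit_linear_ab needs two equal-length vectors of size >= 2")
    xc = x - x.mean()
    sxx = float(np.dot(xc, xc))
    if sxx <= 1e-30 * max(1.0, float(np.dot(x, x))):
        raise DegenerateFitError("predictor has (numerically) zero variance")
    a = float(np.dot(xc, y - y.mean()) / sxx)
    b = float(y.mean() - a * x.mean())
    return a, b


def fit_quality(model_values, vsb) -> tuple[float, float]:
    """OLS regression VSB = slope * M + intercept; the ideal fit is (1, 0)."""
    return fit_linear_ab(model_values, vsb)


# ---------------------------------------------------------------------------
# profiled objective


def _as_nonlinear_tuple(nonlinear) -> tuple[float, float, float, float, float]:
    if isinstance(nonlinear, BrightnessModelParams):
        return (
            nonlinear.alpha,
            nonlinear.beta,
            nonlinear.gamma,
            nonlinear.delta1,
            nonlinear.delta2,
        )
    t = tuple(float(v) for v in nonlinear)
    if len(t) != 5:
        raise ValidationError("nonlinear parameters must be (alpha, beta, gamma, delta1, delta2)")
    return t


def profiled_objective(
    nonlinear, dataset: ExperimentDataset
) -> tuple[float, float, float]:
    """RMSE at the given nonlinear parameters with (a, b) solved by OLS.

    Returns ``(rmse, a, b)``.  If the bracket term is numerically constant
    across stimuli the linear solve is degenerate; the intercept-only fit
    (a = 0, b = mean VSB) is returned instead of failing, so optimizers can
    traverse flat regions.
    """
    alpha, beta, gamma, d1, d2 = _as_nonlinear_tuple(nonlinear)
    params = BrightnessModelParams(alpha=alpha, beta=beta, gamma=gamma, delta1=d1, delta2=d2)
    raw = evaluate_raw(params, dataset.Ev, dataset.S, dataset.G)
    try:
        a, b = fit_linear_ab(raw, dataset.vsb_mean)
    except DegenerateFitError:
        a, b = 0.0, float(dataset.vsb_mean.mean())
    return rmse(a * raw + b, dataset.vsb_mean), a, b


# ---------------------------------------------------------------------------
# fit results


@dataclass(frozen=True)
class FitResult:
    """A fitted parameterisation with its quality metrics."""

    label: str
    params: BrightnessModelParams
    rmse: float
    r2: float
    fit_slope: float
    fit_intercept: float
    free_mask: tuple[str, ...]
    n_starts: int = 1
    seed: int | None = None
    converged: bool = True

    def predictions(self, dataset: ExperimentDataset) -> np.ndarray:
        return evaluate_m(self.params, dataset.Ev, dataset.S, dataset.G)

    def to_row(self) -> dict:
        p = self.params
        return {
            "label": self.label,
            "alpha": p.alpha,
            "beta": p.beta,
            "a": p.a,
            "b": p.b,
            "gamma": p.gamma,
            "delta1": p.delta1,
            "delta2": p.delta2,
            "rmse": self.rmse,
            "r2": self.r2,
            "fit_slope": self.fit_slope,
            "fit_intercept": self.fit_intercept,
            "free": "+".join(self.free_mask) if self.free_mask else "a+b",
            "converged": self.converged,
        }


@dataclass
class FitLedger:
    """Ordered collection of FitResult rows (one per fitting stage)."""

    rows: list[FitResult] = field(default_factory=list)

    def append(self, row: FitResult) -> None:
        self.rows.append(row)

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self):
        return iter(self.rows)

    def __getitem__(self, key):
        if isinstance(key, str):
            for r in self.rows:
                if r.label == key:
                    return r
            raise KeyError(key)
        return self.rows[key]

    @property
    def best(self) -> FitResult:
        return min(self.rows, key=lambda r: r.rmse)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.to_row() for r in self.rows])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_markdown(self) -> str:
        df = self.to_frame()
        cols = list(df.columns)
        rows = [cols, ["---"] * len(cols)]
        for _, rec in df.iterrows():
            rows.append(
                [
                    f"{v:.6g}" if isinstance(v, (float, np.floating)) else str(v)
                    for v in rec
                ]
            )
        return "\n".join("| " + " | ".join(r) + " |" for r in rows) + "\n"


def _make_result(
    label: str,
    nonlinear: tuple[float, float, float, float, float],
    dataset: ExperimentDataset,
    free_mask: tuple[str, ...],
    n_starts: int = 1,
    seed: int | None = None,
    converged: bool = True,
) -> FitResult:
    err, a, b = profiled_objective(nonlinear, dataset)
    alpha, beta, gamma, d1, d2 = nonlinear
    params = BrightnessModelParams(alpha, beta, gamma, d1, d2, a=a, b=b)
    m = evaluate_m(params, dataset.Ev, dataset.S, dataset.G)
    slope, intercept = fit_quality(m, dataset.vsb_mean)
    return FitResult(
        label=label,
        params=params,
        rmse=err,
        r2=r_squared(m, dataset.vsb_mean),
        fit_slope=slope,
        fit_intercept=intercept,
        free_mask=free_mask,
        n_starts=n_starts,
        seed=seed,
        converged=converged,
    )


# ---------------------------------------------------------------------------
# optimisation


def _expand(free_names, x, fixed: dict) -> tuple[float, float, float, float, float]:
    d = dict(fixed)
    for nm, xi in zip(free_names, x):
        if nm == "delta":
            d["delta1"] = float(xi)
            d["delta2"] = float(xi)
        else:
            d[nm] = float(xi)
    return (d["alpha"], d["beta"], d["gamma"], d["delta1"], d["delta2"])


def _tie_key(nl: tuple[float, float, float, float, float]) -> tuple[float, ...]:
    alpha, beta, gamma, d1, d2 = nl
    return (gamma, d1, d2, beta)


def _multistart_minimize(
    dataset: ExperimentDataset,
    free: tuple[str, ...],
    fixed: dict,
    bounds: dict,
    n_starts: int,
    seed: int,
    extra_starts: list[np.ndarray] | None = None,
):
    """Bounded multistart local minimisation of the profiled RMSE.

    Returns (best_nonlinear, converged, n_starts_used).  Ties within
    ``RMSE_TIE_TOL`` are broken toward the lexicographically smallest
    (gamma, delta1, delta2, beta).
    """

    # Minimise the mean *squared* error: same argmin as the RMSE but smooth
    # at a perfect fit, where sqrt has unbounded curvature and stalls
    # quasi-Newton steps well above machine precision.
    def fun(x: np.ndarray) -> float:
        try:
            return profiled_objective(_expand(free, x, fixed), dataset)[0] ** 2
        except (DomainError, ValidationError):
            return 1e12

    lo = np.array([bounds[nm][0] for nm in free])
    hi = np.array([bounds[nm][1] for nm in free])
    box = list(zip(lo, hi))

    starts: list[np.ndarray] = []
    if extra_starts:
        starts.extend(np.clip(np.asarray(s, dtype=float), lo, hi) for s in extra_starts)
    if n_starts > 0:
        sampler = qmc.LatinHypercube(d=len(free), seed=seed)
        unit = sampler.random(n_starts)
        starts.extend(lo + unit * (hi - lo))

    candidates = []
    diagnostics = []
    for x0 in starts:
        res = minimize(
            fun,
            x0,
            method="L-BFGS-B",
            bounds=box,
            options={"ftol": 1e-16, "gtol": 1e-14, "maxfun": 20000},
        )
        diagnostics.append({"x0": x0.tolist(), "status": res.status, "message": str(res.message)})
        if np.isfinite(res.fun):
            # status 2 is L-BFGS-B's "rounding errors dominate" stop: with the
            # deliberately tight ftol it means the start is at its numerical
            # floor, which the Nelder-Mead polish below refines further.
            ok = bool(res.success) or res.status == 2
            candidates.append((float(np.sqrt(max(res.fun, 0.0))), np.asarray(res.x), ok))
    if not candidates:
        raise OptimizationError("all optimizer starts failed", diagnostics)
    best_fun = min(c[0] for c in candidates)
    tied = [c for c in candidates if c[0] <= best_fun + RMSE_TIE_TOL]
    best = min(tied, key=lambda c: _tie_key(_expand(free, c[1], fixed)))
    converged = any(c[2] for c in candidates)
    if not converged:
        raise OptimizationError("no optimizer start converged", diagnostics)
    # Derivative-free polish: finite-difference gradients cannot push the
    # squared error below the differencing noise floor, which matters when
    # the model class contains the data exactly.
    polish = minimize(
        fun,
        best[1],
        method="Nelder-Mead",
        bounds=box,
        options={"xatol": 1e-12, "fatol": 1e-24, "maxiter": 4000, "maxfev": 8000},
    )
    x_best = np.asarray(polish.x) if np.isfinite(polish.fun) and polish.fun <= best[0] ** 2 else best[1]
    return _expand(free, x_best, fixed), converged, len(starts)


def global_fit(
    dataset: ExperimentDataset,
    bounds: dict | None = None,
    n_starts: int = 32,
    seed: int = 0,
    free: tuple[str, ...] = ("beta", "gamma", "delta1", "delta2"),
    fixed: dict | None = None,
    extra_starts: list | None = None,
    label: str = "global",
) -> FitResult:
    """Multistart bounded global fit of the nonlinear parameters.

    ``alpha`` is fixed at 1 by default: the channel weights share an overall
    scale with ``a``, so one of them must be pinned for identifiability (pass
    ``fixed``/``free`` to override).  (a, b) are profiled out of every
    evaluation.  Deterministic for a given seed; ties broken toward the
    lexicographically smallest (gamma, delta1, delta2, beta).
    """
    _require_fittable(dataset)
    if n_starts < 1:
        raise ValidationError("n_starts must be >= 1")
    bounds = {**DEFAULT_BOUNDS, **(bounds or {})}
    fixed = dict(fixed) if fixed is not None else {}
    fixed.setdefault("alpha", 1.0)
    for nm in ("alpha", "beta", "gamma", "delta1", "delta2"):
        if nm not in free and nm not in fixed:
            raise ValidationError(f"parameter {nm} is neither free nor fixed")
    nl, converged, used = _multistart_minimize(
        dataset, tuple(free), fixed, bounds, n_starts, seed, extra_starts
    )
    return _make_result(
        label, nl, dataset, tuple(free), n_starts=used, seed=seed, converged=converged
    )


def grid_oracle(
    dataset: ExperimentDataset,
    grid: dict[str, np.ndarray],
    fixed: dict | None = None,
    label: str = "grid_oracle",
) -> FitResult:
    """Exhaustive profiled-RMSE evaluation over a Cartesian parameter grid.

    An independent brute-force verifier for :func:`global_fit`: it returns
    the exact argmin of the evaluated set (same tie-break rule).
    """
    _require_fittable(dataset)
    fixed = dict(fixed) if fixed is not None else {}
    fixed.setdefault("alpha", 1.0)
    names = tuple(grid)
    axes = [np.atleast_1d(np.asarray(grid[nm], dtype=float)) for nm in names]
    if any(a.size == 0 for a in axes):
        raise ValidationError("grid axes must be non-empty")
    for nm in ("alpha", "beta", "gamma", "delta1", "delta2"):
        if nm not in names and nm not in fixed and "delta" not in names:
            raise ValidationError(f"parameter {nm} is neither on the grid nor fixed")
    best: tuple[float, tuple] | None = None
    for combo in itertools.product(*axes):
        nl = _expand(names, np.asarray(combo), fixed)
        try:
            err = profiled_objective(nl, dataset)[0]
        except (DomainError, ValidationError):
            continue
        if (
            best is None
            or err < best[0] - RMSE_TIE_TOL
            or (err <= best[0] + RMSE_TIE_TOL and _tie_key(nl) < _tie_key(best[1]))
        ):
            best = (min(err, best[0]) if best else err, nl)
    if best is None:
        raise OptimizationError("no feasible grid point")
    return _make_result(label, best[1], dataset, names, n_starts=1)


# ---------------------------------------------------------------------------
# staged procedure


def staged_fit(
    dataset: ExperimentDataset,
    stage_plan: list[tuple[str, dict, tuple[str, ...]]] | None = None,
    seed: int = 0,
    n_starts_stage: int = 8,
    n_starts_global: int = 32,
    bounds: dict | None = None,
) -> FitLedger:
    """Run the staged modelling procedure and return the ledger of fits.

    The default plan mirrors the historical sequence:

    1. ``step1_fotios`` — Fotios-Levermore form, only (a, b) fitted;
       ``step1_v_only`` — illuminance-only form, (gamma, a, b) fitted.
    2. ``step2_*`` — for each fixed (alpha, beta) weight pair, fit
       (gamma, delta, a, b) with the two compression exponents tied.
    3. ``step3_delta_refine`` — at the best weight pair with gamma frozen,
       re-fit the tied exponent (delta, a, b).
    4. ``step4_global`` — multistart global fit of (beta, gamma, delta1,
       delta2, a, b) with alpha = 1.

    Each stage's optimiser is seeded with the best feasible point from the
    preceding stages (rescaled onto alpha = 1 for the global stage), so the
    ledger RMSE is non-increasing across steps and the global row is minimal.

    A custom ``stage_plan`` is a list of ``(label, fixed, free)`` entries run
    verbatim (no global stage is appended).
    """
    _require_fittable(dataset)
    bounds = {**DEFAULT_BOUNDS, **(bounds or {})}
    ledger = FitLedger()

    if stage_plan is not None:
        for label, fixed, free in stage_plan:
            if free:
                nl, conv, used = _multistart_minimize(
                    dataset, tuple(free), dict(fixed), bounds, n_starts_stage, seed
                )
                ledger.append(
                    _make_result(label, nl, dataset, tuple(free), used, seed, conv)
                )
            else:
                nl = _expand((), np.empty(0), dict(fixed))
                ledger.append(_make_result(label, nl, dataset, (), 1, seed))
        return ledger

    # Step 1: published forms, rating-scale transform only / plus gamma.
    fotios_fixed = {"alpha": 1.0, "beta": 0.0, "gamma": 1.0, "delta1": 0.24, "delta2": 0.24}
    ledger.append(
        _make_result("step1_fotios", _expand((), np.empty(0), fotios_fixed), dataset, (), 1, seed)
    )
    v_fixed = {"alpha": 1.0, "beta": 0.0, "delta1": 0.0, "delta2": 0.0}
    nl, conv, used = _multistart_minimize(
        dataset, ("gamma",), v_fixed, bounds, n_starts_stage, seed
    )
    ledger.append(_make_result("step1_v_only", nl, dataset, ("gamma",), used, seed, conv))

    # Step 2: scan fixed (alpha, beta) pairs, tied delta.  Seed each scan
    # with the Fotios point (gamma=1, delta=0.24) so the pure-S pair can
    # never do worse than step 1.
    step2: list[FitResult] = []
    fotios_start = np.array([1.0, 0.24])
    for alpha, beta in _WEIGHT_PAIRS:
        fixed = {"alpha": alpha, "beta": beta}
        nl, conv, used = _multistart_minimize(
            dataset,
            ("gamma", "delta"),
            fixed,
            bounds,
            n_starts_stage,
            seed,
            extra_starts=[fotios_start],
        )
        res = _make_result(
            f"step2_alpha{alpha:g}_beta{beta:g}", nl, dataset, ("gamma", "delta"), used, seed, conv
        )
        ledger.append(res)
        step2.append(res)

    # Step 3: freeze (alpha, beta, gamma) at the best pair, refine tied delta.
    best2 = min(step2, key=lambda r: r.rmse)
    p2 = best2.params
    fixed3 = {"alpha": p2.alpha, "beta": p2.beta, "gamma": p2.gamma}
    nl, conv, used = _multistart_minimize(
        dataset,
        ("delta",),
        fixed3,
        bounds,
        n_starts_stage,
        seed,
        extra_starts=[np.array([p2.delta1])],
    )
    res3 = _make_result("step3_delta_refine", nl, dataset, ("delta",), used, seed, conv)
    ledger.append(res3)

    # Step 4: global fit with alpha pinned at 1.  Seed with the best
    # previous point mapped onto alpha = 1 via the scale degeneracy.
    extra = []
    for r in [res3, best2]:
        p = r.params
        if p.alpha > 0:
            extra.append(np.array([p.beta / p.alpha, p.gamma, p.delta1, p.delta2]))
    res4 = global_fit(
        dataset,
        bounds=bounds,
        n_starts=n_starts_global,
        seed=seed,
        extra_starts=extra,
        label="step4_global",
    )
    ledger.append(res4)
    return ledger
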