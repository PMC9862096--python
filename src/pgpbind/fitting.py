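"""Nonlinear least-squares fitting of dose-response data to the speciation model.

The intrinsic analysis fits the microscopic dissociation constant Kd (in
Log10 space, which enforces positivity and matches its LogNormal sampling
behaviour) and, for ATPase data, the per-occupancy activities V_1..V_n with
the basal V0 fixed at 100%.  The engine uses a deterministic multi-start over
log-spaced Kd initialisations to avoid local minima, reports the residual sum
of squares as chi^2, and computes per-parameter confidence intervals by
profiling: the parameter is stepped along a grid, all other parameters are
re-optimised, and the interval is where
chi2(theta) <= chi2_min * (1 + F(1, nu; level)/nu) with nu = N - p.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import lmfit
import numpy as np
import pandas as pd
from scipy import stats

from . import constants as c
from .activity import ActivityProfile, IAAPAssay, atpase_curve, iaap_curve
from .binding import beta1_to_partition, build_binding_model

KD_START_GRID = np.logspace(-8, -3, 8)  # M, deterministic multi-start


@dataclass(frozen=True)
class DoseResponsePoint:
    """One dose-response observation (concentrations in M, response in %)."""

    l_total: float
    response: float
    sd: Optional[float] = None

    def __post_init__(self) -> None:
        if self.l_total < 0:
            raise ValueError("l_total must be non-negative")


@dataclass(frozen=True)
class ModelSpec:
    """Which forward model to fit and the fixed experimental conditions."""

    kind: str                      # "atpase" | "iaap"
    n_sites: int
    p_total: float
    kp_w_lb: float
    v_lb: float
    v_w: float = 1.0
    assay: Optional[IAAPAssay] = None
    v0: float = 100.0
    pgp_molar_volume: float = c.PGP_MOLAR_VOLUME

    def __post_init__(self) -> None:
        if self.kind not in ("atpase", "iaap"):
            raise ValueError("kind must be 'atpase' or 'iaap'")
        if self.kind == "iaap" and self.assay is None:
            object.__setattr__(self, "assay", IAAPAssay())


@dataclass
class FitResult:
    """Best-fit parameters of one dose-response fit."""

    params: dict[str, float]
    stderr: dict[str, Optional[float]]
    chi2: float
    n_sites: int
    ndata: int
    nfree: int
    success: bool
    kp_from_beta1: float
    ci75: dict[str, tuple[float, float]] = field(default_factory=dict)

    @property
    def kd(self) -> float:
        return 10.0 ** self.params["log10_kd"]


@dataclass
class ScanResult:
    """Per-site-count model scan (one independent fit for each n)."""

    table: pd.DataFrame            # columns: n, chi2, kd, kp_beta1, success
    fits: list[FitResult]

    def best_n(self) -> int:
        ok = self.table[self.table.success]
        return int(ok.loc[ok.chi2.idxmin(), "n"])


def _unpack(data: Sequence[DoseResponsePoint]):
    x = np.array([p.l_total for p in data])
    y = np.array([p.response for p in data])
    sd = np.array([p.sd if p.sd is not None else np.nan for p in data])
    return x, y, sd


def _model_curve(params: lmfit.Parameters, x: np.ndarray, spec: ModelSpec) -> np.ndarray:
    kd = 10.0 ** params["log10_kd"].value
    model = build_binding_model(spec.n_sites, kd)
    if spec.kind == "atpase":
        vi = np.array([params[f"v{i}"].value for i in range(1, spec.n_sites + 1)])
        profile = ActivityProfile(vi=vi, v0=spec.v0)
        return atpase_curve(x, model, profile, spec.p_total, spec.kp_w_lb, spec.v_lb, spec.v_w)
    return iaap_curve(x, model, spec.assay, spec.p_total, spec.kp_w_lb, spec.v_lb, spec.v_w)


def _make_params(spec: ModelSpec, kd_init: float, y: np.ndarray, init: Optional[dict]) -> lmfit.Parameters:
    params = lmfit.Parameters()
    params.add("log10_kd", value=float(np.log10(kd_init)), min=-10.0, max=0.0)
    if spec.kind == "atpase":
        lo = min(0.0, float(y.min()) - 100.0)
        hi = max(2000.0, 3.0 * float(y.max()))
        for i in range(1, spec.n_sites + 1):
            params.add(f"v{i}", value=float(np.clip(y.max(), lo + 1, hi - 1)), min=lo, max=hi)
    if init:
        for k, v in init.items():
            params[k].set(value=float(v))
    return params


def fit_dose_response(
    data: Sequence[DoseResponsePoint],
    spec: ModelSpec,
    init: Optional[dict] = None,
    weighted: bool = False,
    kd_starts: Optional[Sequence[float]] = None,
) -> FitResult:
    """Fit the intrinsic speciation model to dose-response data.

    Unweighted residuals by default; pass ``weighted=True`` to use 1/sd
    weighting where per-point standard deviations are available.  The fit is
    repeated from each Kd start value (a deterministic log-spaced grid by
    default) and the lowest-chi^2 solution kept.  Non-convergence is reported
    via ``success=False`` with the best iterate, never silently.
    """
    x, y, sd = _unpack(data)
    nfree = 1 + (spec.n_sites if spec.kind == "atpase" else 0)
    if len(data) < nfree + 1:
        raise ValueError(f"need at least {nfree + 1} points to fit {nfree} parameters")
    use_sd = weighted and np.all(np.isfinite(sd)) and np.all(sd > 0)

    def residual(p: lmfit.Parameters) -> np.ndarray:
        r = _model_curve(p, x, spec) - y
        return r / sd if use_sd else r

    best = None
    starts = KD_START_GRID if kd_starts is None else np.asarray(kd_starts, float)
    for kd0 in starts:
        params = _make_params(spec, kd0, y, init)
        try:
            out = lmfit.minimize(residual, params, method="leastsq")
        except Exception:
            continue
        if best is None or out.chisqr < best.chisqr:
            best = out
    if best is None:
        raise RuntimeError("all fit starts failed")

    pvals = {k: float(v.value) for k, v in best.params.items()}
    perr = {k: (float(v.stderr) if v.stderr is not None else None) for k, v in best.params.items()}
    kd = 10.0 ** pvals["log10_kd"]
    beta1 = spec.n_sites / kd
    return FitResult(
        params=pvals,
        stderr=perr,
        chi2=float(best.chisqr),
        n_sites=spec.n_sites,
        ndata=len(data),
        nfree=nfree,
        success=bool(best.success),
        kp_from_beta1=beta1_to_partition(beta1, spec.pgp_molar_volume),
    )


def scan_site_count(
    data: Sequence[DoseResponsePoint],
    spec: ModelSpec,
    n_max: int,
    weighted: bool = False,
) -> ScanResult:
    """Independent best fit for each site count n = 1..n_max.

    ``kp_beta1`` is the water->protein partition coefficient implied by the
    fitted beta_1 = n/Kd; comparing it with the partition-derived value is the
    model-selection diagnostic for the pocket capacity.
    """
    if n_max < 1:
        raise ValueError("n_max must be >= 1")
    rows, fits = [], []
    for n in range(1, n_max + 1):
        sub = replace(spec, n_sites=n)
        try:
            fit = fit_dose_response(data, sub, weighted=weighted)
            rows.append((n, fit.chi2, fit.kd, fit.kp_from_beta1, fit.success))
            fits.append(fit)
        except Exception:  # propagate failures as flagged rows
            rows.append((n, np.nan, np.nan, np.nan, False))
            fits.append(None)
    table = pd.DataFrame(rows, columns=["n", "chi2", "kd", "kp_beta1", "success"])
    return ScanResult(table=table, fits=fits)


def profile_confidence(
    data: Sequence[DoseResponsePoint],
    spec: ModelSpec,
    fit: FitResult,
    param: str,
    level: float = 0.75,
    step: Optional[float] = None,
    max_steps: int = 60,
    weighted: bool = False,
) -> tuple[float, float]:
    """Profile-likelihood confidence interval for one parameter.

    The parameter is fixed on a grid walked outward from the estimate while
    all other parameters are re-optimised; the crossing of the chi^2 threshold
    is located by bisection.  A profile that never crosses within the walked
    range (or a parameter pinned at a bound) yields a one-sided/open interval
    reported as +-inf on that side.
    """
    if not 0.0 <= level < 1.0:
        raise ValueError("level must be in [0, 1)")
    x, y, sd = _unpack(data)
    use_sd = weighted and np.all(np.isfinite(sd)) and np.all(sd > 0)
    nu = fit.ndata - fit.nfree
    if nu <= 0:
        raise ValueError("no residual degrees of freedom for a profile interval")
    if level == 0.0:
        return (fit.params[param], fit.params[param])
    threshold = fit.chi2 * (1.0 + stats.f.ppf(level, 1, nu) / nu)

    def chi2_at(value: float) -> float:
        params = _make_params(spec, fit.kd, y, fit.params)
        params[param].set(value=value, vary=False)
        if param != "log10_kd":
            params["log10_kd"].set(value=fit.params["log10_kd"])

        def residual(p: lmfit.Parameters) -> np.ndarray:
            r = _model_curve(p, x, spec) - y
            return r / sd if use_sd else r

        if sum(p.vary for p in params.values()) == 0:
            return float(np.sum(residual(params) ** 2))
        out = lmfit.minimize(residual, params, method="leastsq")
        return float(out.chisqr)

    est = fit.params[param]
    if step is None:
        se = fit.stderr.get(param)
        step = max(se, 1e-3) if se else 0.1 * max(abs(est), 1.0)

    interval = profile_interval_from_chi2(
        chi2_at,
        est=est,
        threshold=threshold,
        step=step,
        max_steps=max_steps,
        bounds=_param_bounds(spec, param),
    )
    fit.ci75[param] = interval
    return interval


def profile_interval_from_chi2(
    chi2_at: Callable[[float], float],
    est: float,
    threshold: float,
    step: float,
    max_steps: int = 60,
    bounds: Optional[tuple[float, float]] = None,
) -> tuple[float, float]:
    """Walk a profiled chi^2 curve outward from ``est`` to the threshold crossings.

    Generic over the source of the profiled chi^2 (``chi2_at`` must re-optimise
    any nuisance parameters internally).  Sides that never cross within the
    walked range, or that hit a parameter bound with the profile still below
    the threshold, are reported open (+-inf).
    """

    def walk(direction: float) -> float:
        prev_v = est
        for k in range(1, max_steps + 1):
            v = est + direction * k * step
            at_bound = False
            if bounds is not None:
                if direction < 0 and v <= bounds[0]:
                    v, at_bound = bounds[0], True
                if direction > 0 and v >= bounds[1]:
                    v, at_bound = bounds[1], True
            if chi2_at(v) >= threshold:
                return _bisect_crossing(chi2_at, prev_v, v, threshold)
            prev_v = v
            if at_bound:
                break
        return -np.inf if direction < 0 else np.inf

    return (walk(-1.0), walk(+1.0))


def _param_bounds(spec: ModelSpec, param: str) -> Optional[tuple[float, float]]:
    if param == "log10_kd":
        return (-10.0, 0.0)
    return None


def _bisect_crossing(
    chi2_at: Callable[[float], float], inside: float, outside: float, threshold: float, tol_frac: float = 1e-3
) -> float:
    # resolve the crossing to a fraction of the initial bracket width
    tol = tol_frac * abs(outside - inside)
    while abs(outside - inside) > tol:
        mid = 0.5 * (inside + outside)
        if chi2_at(mid) >= threshold:
            outside = mid
        else:
            inside = mid
    return 0.5 * (inside + outside)
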