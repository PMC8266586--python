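"""Multi-exponential fitting, rate-saturation analysis and rate statistics.

The observable of a stopped-flow FRET experiment relaxes as a sum of
exponential phases,

    F(t) = F0 + sum_i F_i exp(-k_app_i t),

with baseline F0, per-phase amplitudes F_i (volts) and apparent rates
k_app_i (1/s).  The concentration dependence of an apparent rate
diagnoses the mechanism: a two-step binding scheme (rapid binding
equilibrium followed by a conformational change) saturates hyperbolically,

    k_app = V_max [C] / (K_s + [C]),

while a single bimolecular step is linear, k_app = k_on [C] + k_off.
Multiphasic reactions are summarized by the amplitude-weighted average
rate k_AV = sum_i F_i k_app_i / sum_i F_i with an error propagated from
the per-phase means and standard deviations.

The fitting components are scikit-learn style estimators
(:class:`MultiExponentialModel`, :class:`SaturationCurveFit`); the
module-level functions operate on :class:`~if3cycle.traces.Trace`
objects and mirror the estimators.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import lmfit
import numpy as np
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

from .traces import Trace, group_by_concentration


class FitError(RuntimeError):
    """Nonlinear fit failed; carries best-so-far parameters when available."""

    def __init__(self, message: str, best_params: dict | None = None):
        super().__init__(message)
        self.best_params = best_params or {}


class IdentifiabilityWarning(UserWarning):
    """A fitted parameter is poorly constrained by the data."""


def _as_time_1d(X) -> np.ndarray:
    t = np.asarray(X, dtype=float)
    if t.ndim == 2 and t.shape[1] == 1:
        t = t[:, 0]
    if t.ndim != 1:
        raise ValueError("time axis must be 1-D (or a single-column 2-D array)")
    return t


def _multiexp(t, baseline, amplitudes, rates):
    f = np.full_like(t, baseline, dtype=float)
    for a, k in zip(amplitudes, rates):
        f = f + a * np.exp(-k * t)
    return f


class MultiExponentialModel(RegressorMixin, BaseEstimator):
    """Nonlinear least-squares fit of a 1- or 2-phase exponential relaxation.

    Rates are initialized on a log grid spanning the resolvable window
    (from half a decay over the trace to the angular-Nyquist scale of the
    sampling) with amplitudes solved by linear least squares at each
    trial rate (variable projection), followed by joint Levenberg-
    Marquardt refinement.  This is robust to the hundred-fold rate
    separations that occur between fast and slow conformational phases.

    Parameters
    ----------
    n_phases : int
        Number of exponential terms (1 or 2).
    init : dict, optional
        Optional starting guesses: ``baseline``, ``amplitudes``, ``rates``.
    max_iter : int
        Maximum refinement iterations.
    tol : float
        Convergence tolerance on the cost function.
    n_grid : int
        Number of candidate rates per decade-spanning init grid.

    Attributes
    ----------
    baseline_ : float
    amplitudes_, rates_ : ndarray, sorted by decreasing rate
    baseline_stderr_, amplitude_stderrs_, rate_stderrs_ : asymptotic SEs
    residual_sd_ : float
    aicc_ : small-sample-corrected Akaike information criterion
    converged_ : bool
    identifiable_ : per-phase bool, False where a rate is unconstrained
    """

    def __init__(self, n_phases: int = 1, init: dict | None = None,
                 max_iter: int = 500, tol: float = 1e-10, n_grid: int = 14):
        self.n_phases = n_phases
        self.init = init
        self.max_iter = max_iter
        self.tol = tol
        self.n_grid = n_grid

    # -- internals ---------------------------------------------------------

    def _rate_grid(self, t: np.ndarray) -> np.ndarray:
        t_max = t[-1] - t[0]
        dt = np.median(np.diff(t))
        lo = 0.5 / t_max
        hi = np.pi / (10.0 * dt)
        return np.geomspace(lo, hi, self.n_grid)

    @staticmethod
    def _linear_solve(t, y, rates):
        """Solve baseline and amplitudes for fixed rates; return (ssr, coef)."""
        design = np.column_stack([np.ones_like(t)] +
                                 [np.exp(-k * t) for k in rates])
        coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
        resid = y - design @ coef
        return float(resid @ resid), coef

    def _initial_guess(self, t, y):
        if self.init is not None:
            return (float(self.init.get("baseline", y[-1])),
                    np.asarray(self.init["amplitudes"], dtype=float),
                    np.asarray(self.init["rates"], dtype=float))
        grid = self._rate_grid(t)
        best = (np.inf, None, None)
        if self.n_phases == 1:
            for k in grid:
                ssr, coef = self._linear_solve(t, y, [k])
                if ssr < best[0]:
                    best = (ssr, coef, np.array([k]))
        else:
            for i, k1 in enumerate(grid):
                for k2 in grid[:i]:
                    ssr, coef = self._linear_solve(t, y, [k1, k2])
                    if ssr < best[0]:
                        best = (ssr, coef, np.array([k1, k2]))
        _, coef, rates = best
        return float(coef[0]), coef[1:], rates

    def fit(self, X, y):
        """Fit the model.  X is the time axis (s), y the fluorescence (V)."""
        t = _as_time_1d(X)
        y = np.asarray(y, dtype=float)
        if t.shape != y.shape:
            raise ValueError("time and signal length mismatch")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(y))):
            raise ValueError("non-finite values in input")
        n_params = 2 * self.n_phases + 1
        if t.size < 10 * n_params:
            raise ValueError(
                f"need >= {10 * n_params} points for a {self.n_phases}-phase fit")
        if self.n_phases not in (1, 2):
            raise ValueError("n_phases must be 1 or 2")

        f0, amps, rates = self._initial_guess(t, y)
        params = lmfit.Parameters()
        params.add("baseline", value=f0)
        for i in range(self.n_phases):
            params.add(f"amp{i}", value=float(amps[i]))
            params.add(f"rate{i}", value=float(max(rates[i], 1e-9)), min=1e-12)

        def residual(p):
            a = [p[f"amp{i}"].value for i in range(self.n_phases)]
            k = [p[f"rate{i}"].value for i in range(self.n_phases)]
            return y - _multiexp(t, p["baseline"].value, a, k)

        result = lmfit.minimize(residual, params, method="leastsq",
                                max_nfev=self.max_iter * n_params,
                                xtol=self.tol, ftol=self.tol)
        if not result.success:
            best = {name: p.value for name, p in result.params.items()}
            raise FitError(f"exponential fit did not converge: {result.message}",
                           best_params=best)

        order = np.argsort([-result.params[f"rate{i}"].value
                            for i in range(self.n_phases)])
        get = lambda fmt, i: result.params[fmt.format(order[i])]
        self.baseline_ = float(result.params["baseline"].value)
        self.baseline_stderr_ = _stderr(result.params["baseline"])
        self.amplitudes_ = np.array([get("amp{}", i).value
                                     for i in range(self.n_phases)])
        self.rates_ = np.array([get("rate{}", i).value
                                for i in range(self.n_phases)])
        self.amplitude_stderrs_ = np.array([_stderr(get("amp{}", i))
                                            for i in range(self.n_phases)])
        self.rate_stderrs_ = np.array([_stderr(get("rate{}", i))
                                       for i in range(self.n_phases)])
        dof = max(1, t.size - n_params)
        ssr = float(result.residual @ result.residual)
        self.residual_sd_ = np.sqrt(ssr / dof)
        self.aicc_ = _aicc(ssr, t.size, n_params)
        self.n_iter_ = result.nfev
        self.converged_ = bool(result.success)
        self.identifiable_ = np.array([
            np.isfinite(se) and se <= max(k, 1e-300)
            for k, se in zip(self.rates_, self.rate_stderrs_)
        ])
        if self.n_phases == 2 and self.rates_[1] > 0:
            if self.rates_[0] / self.rates_[1] < 3.0:
                warnings.warn(
                    f"phase rates {self.rates_[0]:.3g} and {self.rates_[1]:.3g} "
                    "separated by < 3x: poorly separable",
                    IdentifiabilityWarning)
        return self

    def predict(self, X):
        t = _as_time_1d(X)
        return _multiexp(t, self.baseline_, self.amplitudes_, self.rates_)


def _stderr(param) -> float:
    return float(param.stderr) if param.stderr is not None else np.inf


def _aicc(ssr: float, n: int, p: int) -> float:
    # Gaussian log-likelihood up to a constant; corrected for small samples.
    aic = n * np.log(max(ssr, 1e-300) / n) + 2 * p
    if n - p - 1 > 0:
        aic += 2 * p * (p + 1) / (n - p - 1)
    return float(aic)


@dataclass
class ExpFitResult:
    """Fitted multi-exponential signal model for one trace."""

    baseline: float
    amplitudes: np.ndarray          # volts, sorted by decreasing rate
    rates: np.ndarray               # 1/s
    baseline_stderr: float
    amplitude_stderrs: np.ndarray
    rate_stderrs: np.ndarray
    residual_sd: float
    n_phases: int
    aicc: float
    converged: bool
    identifiable: np.ndarray
    conc_uM: float | None = None
    replicate: int | None = None

    @property
    def total_amplitude(self) -> float:
        return float(np.sum(np.abs(self.amplitudes)))

    @property
    def total_amplitude_stderr(self) -> float:
        return float(np.sqrt(np.sum(self.amplitude_stderrs ** 2)))

    def amplitude_fractions(self) -> np.ndarray:
        return np.abs(self.amplitudes) / self.total_amplitude


def fit_exponential(trace: Trace, n_phases: int = 1,
                    init: dict | None = None) -> ExpFitResult:
    """Fit one trace with ``n_phases`` exponential terms."""
    est = MultiExponentialModel(n_phases=n_phases, init=init)
    est.fit(trace.time, trace.fluorescence)
    return ExpFitResult(
        baseline=est.baseline_, amplitudes=est.amplitudes_, rates=est.rates_,
        baseline_stderr=est.baseline_stderr_,
        amplitude_stderrs=est.amplitude_stderrs_, rate_stderrs=est.rate_stderrs_,
        residual_sd=est.residual_sd_, n_phases=n_phases, aicc=est.aicc_,
        converged=est.converged_, identifiable=est.identifiable_,
        conc_uM=trace.conc_uM, replicate=trace.replicate,
    )


def select_n_phases(trace: Trace) -> int:
    """Choose 1 or 2 exponential phases by corrected AIC; ties favour 1."""
    results = {}
    for n in (1, 2):
        try:
            results[n] = fit_exponential(trace, n_phases=n)
        except (FitError, ValueError):
            pass
    if not results:
        raise FitError("both 1- and 2-phase fits failed")
    if len(results) == 1:
        return next(iter(results))
    return 1 if results[1].aicc <= results[2].aicc else 2


def average_traces(traces: list[Trace]) -> Trace:
    """Pointwise mean of replicate traces sharing one time grid."""
    if not traces:
        raise ValueError("no traces to average")
    t0 = traces[0].time
    for tr in traces[1:]:
        if tr.time.shape != t0.shape or not np.array_equal(tr.time, t0):
            raise ValueError("time grids differ: refusing to average "
                             "(no silent interpolation)")
    mean = np.mean([tr.fluorescence for tr in traces], axis=0)
    first = traces[0]
    return Trace(time=t0.copy(), fluorescence=mean, titrant=first.titrant,
                 conc_uM=first.conc_uM, replicate=None,
                 n_averaged=sum(tr.n_averaged for tr in traces))


@dataclass
class CycleProfile:
    """Chained signed amplitudes across the reactions of a full cycle.

    ``levels`` holds the cumulative fluorescence level at each reaction
    boundary (len = n_reactions + 1, starting at 0); ``normalized_levels``
    min-max rescales them to [0, 1].  ``closure_residual`` is the final
    minus initial level — zero for a signal-conserving cycle.
    """

    signed_amplitudes: np.ndarray
    amplitude_stderrs: np.ndarray
    levels: np.ndarray
    normalized_levels: np.ndarray
    closure_residual: float
    closure_stderr: float


def chain_amplitudes(fits: list[ExpFitResult], signs) -> CycleProfile:
    """Chain per-reaction total amplitudes into a cumulative cycle profile.

    ``signs`` gives the direction of the fluorescence change of each
    reaction (+1 opening / fluorescence increase, -1 closing).
    """
    signs = np.asarray(signs, dtype=float)
    if len(fits) < 2:
        raise ValueError("need >= 2 reactions to chain")
    if signs.shape != (len(fits),):
        raise ValueError("one sign per reaction required")
    for i, f in enumerate(fits):
        if f is None or f.amplitudes.size == 0:
            raise ValueError(f"reaction {i}: missing amplitude (incomplete cycle)")
    amps = np.array([f.total_amplitude for f in fits])
    ses = np.array([f.total_amplitude_stderr for f in fits])
    signed = signs * amps
    levels = np.concatenate([[0.0], np.cumsum(signed)])
    span = np.ptp(levels)
    normalized = (levels - levels.min()) / span if span > 0 else np.zeros_like(levels)
    return CycleProfile(
        signed_amplitudes=signed, amplitude_stderrs=ses, levels=levels,
        normalized_levels=normalized,
        closure_residual=float(levels[-1] - levels[0]),
        closure_stderr=float(np.sqrt(np.sum(ses ** 2))),
    )


@dataclass
class RateSeries:
    """Apparent rate (mean +- SD over replicates) vs titrant concentration."""

    conc_uM: np.ndarray
    k_app: np.ndarray
    sd: np.ndarray
    n_replicates: np.ndarray
    phase_label: str = ""

    def __post_init__(self) -> None:
        self.conc_uM = np.asarray(self.conc_uM, dtype=float)
        self.k_app = np.asarray(self.k_app, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        self.n_replicates = np.asarray(self.n_replicates, dtype=int)
        if np.any(self.conc_uM <= 0):
            raise ValueError("concentrations must be positive")
        if len(np.unique(self.conc_uM)) != self.conc_uM.size:
            raise ValueError("concentrations must be unique")
        if np.any(self.sd < 0):
            raise ValueError("standard deviations must be >= 0")


class SaturationCurveFit(RegressorMixin, BaseEstimator):
    """Weighted fit of an apparent-rate vs concentration dependence.

    ``model="hyperbolic"`` fits k = V_max [C] / (K_s + [C]) (optionally
    plus a constant reverse-rate intercept, off by default);
    ``model="linear"`` fits k = slope [C] + intercept, where the slope is
    the association rate constant (1/(uM s)) and the intercept the
    dissociation rate (1/s).  Points are weighted 1/SD^2; if any SD is
    zero the fit falls back to unweighted.
    """

    def __init__(self, model: str = "hyperbolic", include_intercept: bool = False):
        self.model = model
        self.include_intercept = include_intercept

    def fit(self, X, y, sd=None):
        conc = _as_time_1d(X)
        k = np.asarray(y, dtype=float)
        min_pts = {"hyperbolic": 4, "linear": 3}.get(self.model)
        if min_pts is None:
            raise ValueError(f"unknown model {self.model!r}")
        if conc.size < min_pts:
            raise ValueError(
                f"underdetermined: {self.model} fit needs >= {min_pts} concentrations")
        if sd is not None:
            sd = np.asarray(sd, dtype=float)
            if np.any(sd == 0) or np.any(~np.isfinite(sd)):
                sd = None  # unweighted fallback
        weights = 1.0 / sd ** 2 if sd is not None else np.ones_like(k)

        if self.model == "linear":
            design = sm.add_constant(conc)
            res = sm.WLS(k, design, weights=weights).fit()
            self.intercept_ = float(res.params[0])
            self.slope_ = float(res.params[1])
            self.intercept_stderr_ = float(res.bse[0])
            self.slope_stderr_ = float(res.bse[1])
            self.dof_ = int(res.df_resid)
            self.rss_ = float(res.ssr)
            if self.slope_ < 0:
                warnings.warn("negative fitted slope: linear bimolecular model "
                              "mismatch", IdentifiabilityWarning)
        else:
            params = lmfit.Parameters()
            params.add("vmax", value=float(k.max() * 1.2), min=1e-12)
            params.add("ks", value=float(np.median(conc)), min=1e-12)
            params.add("intercept", value=0.0, vary=self.include_intercept)

            def residual(p):
                pred = p["vmax"].value * conc / (p["ks"].value + conc) \
                    + p["intercept"].value
                return np.sqrt(weights) * (k - pred)

            res = lmfit.minimize(residual, params, method="leastsq",
                                 xtol=1e-12, ftol=1e-12)
            values_ok = all(np.isfinite(p.value) for p in res.params.values())
            if not values_ok:
                raise FitError(f"hyperbolic fit failed: {res.message}",
                               {n: p.value for n, p in res.params.items()})
            # a failed error-bar estimate (ridge-degenerate data) falls
            # through to the ill-conditioning warning below
            self.vmax_ = float(res.params["vmax"].value)
            self.ks_ = float(res.params["ks"].value)
            self.vmax_stderr_ = _stderr(res.params["vmax"])
            self.ks_stderr_ = _stderr(res.params["ks"])
            self.intercept_ = float(res.params["intercept"].value)
            self.intercept_stderr_ = (_stderr(res.params["intercept"])
                                      if self.include_intercept else 0.0)
            n_par = 3 if self.include_intercept else 2
            self.dof_ = max(1, conc.size - n_par)
            self.rss_ = float(res.residual @ res.residual)
            if self.ks_ > conc.max() * 5 or not np.isfinite(self.ks_stderr_) \
                    or self.ks_stderr_ > self.ks_:
                warnings.warn(
                    f"no curvature over the sampled range: K_s ill-conditioned "
                    f"(upper bound ~{max(self.ks_, conc.max()):.3g} uM)",
                    IdentifiabilityWarning)
        return self

    def predict(self, X):
        conc = _as_time_1d(X)
        if self.model == "linear":
            return self.slope_ * conc + self.intercept_
        return self.vmax_ * conc / (self.ks_ + conc) + self.intercept_


@dataclass
class SaturationFit:
    """Fitted rate-concentration law with uncertainties and 95% CIs."""

    model: str                       # "hyperbolic" | "linear"
    params: dict[str, float]         # vmax/ks or slope/intercept
    stderr: dict[str, float]
    dof: int
    rss: float
    phase_label: str = ""

    def ci95(self, name: str) -> tuple[float, float]:
        tcrit = stats.t.ppf(0.975, self.dof)
        half = tcrit * self.stderr[name]
        return self.params[name] - half, self.params[name] + half

    def contains(self, name: str, value: float) -> bool:
        lo, hi = self.ci95(name)
        return lo <= value <= hi


def _saturation_fit_from_estimator(est: SaturationCurveFit,
                                   phase_label: str = "") -> SaturationFit:
    if est.model == "linear":
        params = {"slope": est.slope_, "intercept": est.intercept_}
        stderr = {"slope": est.slope_stderr_, "intercept": est.intercept_stderr_}
    else:
        params = {"vmax": est.vmax_, "ks": est.ks_}
        stderr = {"vmax": est.vmax_stderr_, "ks": est.ks_stderr_}
        if est.include_intercept:
            params["intercept"] = est.intercept_
            stderr["intercept"] = est.intercept_stderr_
    return SaturationFit(model=est.model, params=params, stderr=stderr,
                         dof=est.dof_, rss=est.rss_, phase_label=phase_label)


def fit_hyperbolic(series: RateSeries, include_intercept: bool = False) -> SaturationFit:
    """Weighted hyperbolic (V_max, K_s) fit of a rate series."""
    est = SaturationCurveFit(model="hyperbolic", include_intercept=include_intercept)
    est.fit(series.conc_uM, series.k_app, sd=series.sd)
    return _saturation_fit_from_estimator(est, series.phase_label)


def fit_linear(series: RateSeries) -> SaturationFit:
    """Weighted linear (k_on slope, k_off intercept) fit of a rate series."""
    est = SaturationCurveFit(model="linear")
    est.fit(series.conc_uM, series.k_app, sd=series.sd)
    return _saturation_fit_from_estimator(est, series.phase_label)


@dataclass
class KAvResult:
    """Amplitude-weighted average rate and its propagated uncertainty."""

    k_av: float
    sigma: float
    amplitudes: np.ndarray
    amplitude_sds: np.ndarray
    rates: np.ndarray
    rate_sds: np.ndarray


def k_average(per_phase_stats) -> KAvResult:
    """Amplitude-weighted average rate with term-by-term error propagation.

    ``per_phase_stats`` is a sequence of (F_i mean, F_i sd, k_i mean,
    k_i sd) per phase.  The statistic is

        k_AV = sum_i F_i k_i / sum_i F_i,

    and its sigma combines, in quadrature, the relative error of the
    amplitude-rate products in the numerator and of the amplitude sum in
    the denominator, each built from the per-phase means and SDs.
    k_AV always lies within [min k_i, max k_i]; all-zero SDs give sigma 0.
    """
    stats_arr = np.asarray(per_phase_stats, dtype=float).reshape(-1, 4)
    if stats_arr.shape[0] < 1:
        raise ValueError("need at least one phase")
    F, sF, k, sk = stats_arr.T
    if np.any(F <= 0):
        raise ValueError("amplitudes must be positive (use magnitudes)")
    if np.any(k <= 0):
        raise ValueError("rates must be positive")
    denom = F.sum()
    if denom == 0:
        raise ValueError("zero total amplitude: k_AV undefined")
    num = float(np.sum(F * k))
    k_av = num / denom
    term_sds = np.sqrt((sF / F) ** 2 + (sk / k) ** 2) * F * k
    rel_num = np.sqrt(np.sum(term_sds ** 2)) / num
    rel_den = np.sqrt(np.sum(sF ** 2)) / denom
    sigma = k_av * np.sqrt(rel_num ** 2 + rel_den ** 2)
    return KAvResult(k_av=float(k_av), sigma=float(sigma),
                     amplitudes=F, amplitude_sds=sF, rates=k, rate_sds=sk)


@dataclass
class TitrationFitResult:
    """Per-phase rate series and saturation fits for one titration."""

    series: list[RateSeries]
    saturation: list[SaturationFit]
    replicate_fits: dict[float, list[ExpFitResult]]
    dropped: list[float]
    failures: dict[float, list[str]]
    model: str
    n_phases: int

    def _conc(self, conc: float | None) -> float:
        return max(self.replicate_fits) if conc is None else conc

    def amplitude_fraction(self, phase: int, conc: float | None = None):
        """Mean +- SD of |F_phase| / sum|F| across replicates at one conc."""
        fits = self.replicate_fits[self._conc(conc)]
        fracs = np.array([f.amplitude_fractions()[phase] for f in fits])
        return float(fracs.mean()), float(fracs.std(ddof=1) if len(fracs) > 1 else 0.0)

    def k_av_replicates(self, conc: float | None = None):
        """k_AV computed per replicate, then mean +- SD across replicates."""
        fits = self.replicate_fits[self._conc(conc)]
        kavs = np.array([
            float(np.sum(np.abs(f.amplitudes) * f.rates) / np.sum(np.abs(f.amplitudes)))
            for f in fits
        ])
        return float(kavs.mean()), float(kavs.std(ddof=1) if len(kavs) > 1 else 0.0)

    def k_av_propagated(self, conc: float | None = None) -> KAvResult:
        """k_AV from per-phase replicate means/SDs with error propagation."""
        fits = self.replicate_fits[self._conc(conc)]
        stats_rows = []
        for i in range(self.n_phases):
            amps = np.array([abs(f.amplitudes[i]) for f in fits])
            rates = np.array([f.rates[i] for f in fits])
            stats_rows.append((amps.mean(), amps.std(ddof=1) if len(amps) > 1 else 0.0,
                               rates.mean(), rates.std(ddof=1) if len(rates) > 1 else 0.0))
        return k_average(stats_rows)


def fit_titration_pipeline(traces: list[Trace], n_phases: int | None = None,
                           model="hyperbolic",
                           average_replicates: bool = False) -> TitrationFitResult:
    """Fit a full titration: replicates independently, then rates vs [C].

    Every replicate is fitted with the exponential model; per
    concentration the apparent rates are aggregated as mean +- SD (phases
    matched by decreasing rate); the per-phase series are then fitted
    with the chosen rate law (1/SD^2 weighting).  ``model`` is
    ``"hyperbolic"`` or ``"linear"``, or one such string per phase when
    the phases follow different laws (e.g. a bimolecular first phase
    followed by a saturating conformational phase).  With
    ``average_replicates=True`` the replicates are averaged into a single
    trace before fitting, mirroring on-instrument averaging.

    Per-replicate fit failures are collected; a concentration where every
    replicate failed is dropped with a warning.
    """
    groups = group_by_concentration(traces)
    if len(groups) < 3:
        raise ValueError("need >= 3 concentrations")
    if n_phases is None:
        probe = average_traces(groups[max(groups)])
        n_phases = select_n_phases(probe)

    replicate_fits: dict[float, list[ExpFitResult]] = {}
    failures: dict[float, list[str]] = {}
    dropped: list[float] = []
    for conc, reps in groups.items():
        if average_replicates:
            reps = [average_traces(reps)]
        fits, errs = [], []
        for tr in reps:
            try:
                fits.append(fit_exponential(tr, n_phases=n_phases))
            except (FitError, ValueError) as exc:
                errs.append(f"replicate {tr.replicate}: {exc}")
        if errs:
            failures[conc] = errs
        if not fits:
            warnings.warn(f"concentration {conc} uM dropped: all replicate "
                          "fits failed")
            dropped.append(conc)
            continue
        replicate_fits[conc] = fits

    if len(replicate_fits) < 3:
        raise FitError("fewer than 3 concentrations with successful fits")

    labels = (["fast", "slow"] if n_phases == 2 else ["single"])
    if isinstance(model, str):
        phase_models = [model] * n_phases
    else:
        phase_models = list(model)
        if len(phase_models) != n_phases:
            raise ValueError("one model per phase required")
    series_list, sat_list = [], []
    for phase in range(n_phases):
        concs = np.array(sorted(replicate_fits))
        means, sds, ns = [], [], []
        for c in concs:
            rates = np.array([f.rates[phase] for f in replicate_fits[c]])
            mean = rates.mean()
            sd = rates.std(ddof=1) if rates.size > 1 else 0.0
            if sd < 1e-12 * abs(mean):   # numerically identical replicates
                sd = 0.0
            means.append(mean)
            sds.append(sd)
            ns.append(rates.size)
        series = RateSeries(conc_uM=concs, k_app=np.array(means),
                            sd=np.array(sds), n_replicates=np.array(ns),
                            phase_label=labels[phase])
        series_list.append(series)
        fitter = fit_linear if phase_models[phase] == "linear" else fit_hyperbolic
        sat_list.append(fitter(series))
    return TitrationFitResult(series=series_list, saturation=sat_list,
                              replicate_fits=replicate_fits, dropped=dropped,
                              failures=failures,
                              model=phase_models[0] if len(set(phase_models)) == 1
                              else list(phase_models),
                              n_phases=n_phases)
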