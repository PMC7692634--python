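"""ITC thermogram simulation and model fitting.

Simulates per-injection heats for a perfusion-cell (overflow) titration
under the two-event ligand-bridged dimerization scheme, and fits binding
parameters to measured thermograms by multistart nonlinear least squares,
with a 1:1 single-site null model for comparison.

Heat bookkeeping follows the standard perfusion-cell convention: each
injected aliquot displaces an equal volume of pre-injection cell contents,
so in-cell totals are diluted by ``(1 - v_i/V0)`` before the injectant is
added and the working volume V0 stays constant.  The heat of injection i is

    q_i = V0 * [dH1 * (d[PL] + d[P2L]) + dH2 * d[P2L]] + q_dil

where the deltas are equilibrium concentration changes relative to the
diluted pre-injection state.  Heats are stored in µcal; normalized heats
are reported in kcal per mole of injectant (instrument convention, with
calories as the native unit).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import least_squares

from .equilibria import BindingParameters, Composition, SpeciesState, _solve_raw, solve_species

__all__ = [
    "TitrationProtocol",
    "Thermogram",
    "FitResult",
    "simulate_thermogram",
    "ThermogramFitter",
    "fit_thermogram",
    "compare_models",
    "SCHEMES",
]

SCHEMES = ("double_dependent", "single_site")


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValueError(msg)


@dataclass(frozen=True)
class TitrationProtocol:
    """Injection schedule of a perfusion-cell titration.

    Fields are SI (liters, molar, kelvin).  The classmethod
    :meth:`vp_itc_default` builds the bench-standard design used
    throughout the test suite: 250 µM ligand injected in 8 µL aliquots
    into a 1.4 mL cell containing 20 µM receptor at 25 °C.
    """

    cell_volume: float
    cell_conc: float
    syringe_conc: float
    injection_volumes: tuple
    temperature: float = 298.15

    def __post_init__(self) -> None:
        _require(math.isfinite(self.cell_volume) and self.cell_volume > 0, "cell_volume must be > 0")
        _require(math.isfinite(self.cell_conc) and self.cell_conc > 0, "cell_conc must be > 0")
        _require(math.isfinite(self.syringe_conc) and self.syringe_conc > 0, "syringe_conc must be > 0")
        _require(math.isfinite(self.temperature) and self.temperature > 0, "temperature must be > 0")
        vols = tuple(float(v) for v in self.injection_volumes)
        _require(len(vols) >= 2, "need at least 2 injections")
        _require(all(math.isfinite(v) and v > 0 for v in vols), "injection volumes must be > 0")
        object.__setattr__(self, "injection_volumes", vols)

    @property
    def n_injections(self) -> int:
        return len(self.injection_volumes)

    @classmethod
    def vp_itc_default(cls, n_injections: int = 56) -> "TitrationProtocol":
        return cls(
            cell_volume=1.4e-3,
            cell_conc=20e-6,
            syringe_conc=250e-6,
            injection_volumes=(8e-6,) * n_injections,
            temperature=298.15,
        )


@dataclass(frozen=True)
class Thermogram:
    """A titration protocol plus the integrated heat of each injection (µcal)."""

    protocol: TitrationProtocol
    heats: tuple

    def __post_init__(self) -> None:
        h = tuple(float(q) for q in self.heats)
        _require(len(h) == self.protocol.n_injections,
                 f"{len(h)} heats for {self.protocol.n_injections} injections")
        _require(all(math.isfinite(q) for q in h), "heats must be finite")
        object.__setattr__(self, "heats", h)

    @property
    def normalized(self) -> np.ndarray:
        """Heat per mole of injectant, kcal/mol."""
        v = np.asarray(self.protocol.injection_volumes)
        q_cal = np.asarray(self.heats) * 1e-6
        return q_cal / (self.protocol.syringe_conc * v) / 1e3

    @property
    def molar_ratio(self) -> np.ndarray:
        """In-cell total ligand : total receptor ratio after each injection."""
        p_tot, l_tot = _totals_after_injections(self.protocol)
        return l_tot / p_tot


def _totals_after_injections(protocol: TitrationProtocol):
    """In-cell total concentrations after each injection (overflow dilution)."""
    v0 = protocol.cell_volume
    p = protocol.cell_conc
    l = 0.0
    p_out, l_out = [], []
    for v in protocol.injection_volumes:
        d = 1.0 - v / v0
        p *= d
        l = l * d + protocol.syringe_conc * (v / v0)
        p_out.append(p)
        l_out.append(l)
    return np.asarray(p_out), np.asarray(l_out)


def _response_matrix(protocol: TitrationProtocol, kd1: float, kd2: float,
                     active_fraction: float = 1.0):
    """Per-injection heat-response coefficients for the two events.

    Returns arrays (a, b), in µcal per (cal/mol), such that
    ``q_i = dh1*a_i + dh2*b_i + q_dil``.  ``a_i = V0*(d[PL]+d[P2L])*1e6``
    and ``b_i = V0*d[P2L]*1e6``.  One speciation pass: the pre-state of
    injection i is the post-state of injection i-1.
    """
    v0 = protocol.cell_volume
    p_tot = protocol.cell_conc * active_fraction
    l_tot = 0.0
    _, _, pl_pre, p2l_pre = _solve_raw(p_tot, l_tot, kd1, kd2)
    a = np.empty(protocol.n_injections)
    b = np.empty(protocol.n_injections)
    for i, v in enumerate(protocol.injection_volumes):
        d = 1.0 - v / v0
        p_tot *= d
        l_tot = l_tot * d + protocol.syringe_conc * (v / v0)
        _, _, pl, p2l = _solve_raw(p_tot, l_tot, kd1, kd2)
        d_pl = pl - pl_pre * d
        d_p2l = p2l - p2l_pre * d
        a[i] = v0 * (d_pl + d_p2l) * 1e6
        b[i] = v0 * d_p2l * 1e6
        pl_pre, p2l_pre = pl, p2l
    return a, b


def simulate_thermogram(protocol: TitrationProtocol, params: BindingParameters,
                        active_fraction: float = 1.0) -> Thermogram:
    """Simulate a noise-free thermogram for the two-event scheme.

    Deterministic: identical inputs give bit-identical heats.
    """
    a, b = _response_matrix(protocol, params.kd1, params.kd2, active_fraction)
    heats = params.dh1 * a + params.dh2 * b + params.q_dil
    return Thermogram(protocol=protocol, heats=tuple(heats))


@dataclass(frozen=True)
class FitResult:
    """Point estimates, uncertainties and fit diagnostics for one scheme."""

    params: BindingParameters
    stderr: dict
    residuals: tuple
    rss: float
    model_tag: str
    aic: float
    n_obs: int = 0
    n_params: int = 0

    def __post_init__(self) -> None:
        _require(self.rss >= 0, "rss must be >= 0")
        _require(all(v >= 0 or math.isnan(v) for v in self.stderr.values()),
                 "stderr must be >= 0")

    def summary(self) -> str:
        lines = [f"scheme: {self.model_tag}", f"n_obs: {self.n_obs}",
                 f"rss: {self.rss:.6g}", f"aic: {self.aic:.3f}"]
        p = self.params
        for name, val, unit in (("kd1", p.kd1, "M"), ("kd2", p.kd2, "M"),
                                ("dh1", p.dh1, "cal/mol"), ("dh2", p.dh2, "cal/mol"),
                                ("q_dil", p.q_dil, "ucal")):
            se = self.stderr.get(name, float("nan"))
            lines.append(f"{name}: {val:.6g} +/- {se:.3g} {unit}")
        return "\n".join(lines)


class ThermogramFitter:
    """Least-squares fit of a binding scheme to an ITC thermogram.

    Follows the scikit-learn estimator idiom: constructor takes
    hyper-parameters, ``fit`` estimates parameters and exposes them as
    trailing-underscore attributes, ``predict`` returns model heats.
    ``fit`` accepts a :class:`Thermogram` (a titration is a protocol plus
    a heat series, not a plain feature matrix).

    Parameters
    ----------
    scheme : str
        ``"double_dependent"`` (two sequential events, 5 parameters) or
        ``"single_site"`` (1:1 binding, 3 parameters).
    exclude_first : bool
        Drop injection 1 from the residuals (common ITC practice for
        syringe-diffusion artefacts). Default False.
    sigma : array-like or None
        Per-injection standard deviations of the normalized heats for
        weighted fitting; None (default) = uniform weights.
    n_starts : int
        Number of deterministic multistart points on the log10-Kd grid
        (>= 8 enforced; the double scheme uses a 2-D grid of at least
        this many points).
    active_fraction : float
        Fixed competent-receptor fraction applied to the cell
        concentration; not fitted. Default 1.0.

    Attributes
    ----------
    params_ : BindingParameters
        Point estimates (single_site reports kd2 = inf, dh2 = 0).
    stderr_ : dict
        Jacobian-based standard errors per parameter.
    residuals_ : ndarray
        Data minus model, normalized-heat units, full injection length
        (excluded first injection reported as its residual, unweighted).
    rss_, aic_ : float
        Residual sum of squares over fitted points and
        ``n*ln(rss/n) + 2k``.
    result_ : FitResult
        Everything above as one record.
    """

    def __init__(self, scheme: str = "double_dependent", exclude_first: bool = False,
                 sigma: Optional[Sequence[float]] = None, n_starts: int = 9,
                 active_fraction: float = 1.0):
        self.scheme = scheme
        self.exclude_first = exclude_first
        self.sigma = sigma
        self.n_starts = n_starts
        self.active_fraction = active_fraction

    # -- sklearn plumbing -------------------------------------------------
    def get_params(self, deep: bool = True) -> dict:
        return {"scheme": self.scheme, "exclude_first": self.exclude_first,
                "sigma": self.sigma, "n_starts": self.n_starts,
                "active_fraction": self.active_fraction}

    def set_params(self, **kwargs) -> "ThermogramFitter":
        for k, v in kwargs.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    # -- internals ---------------------------------------------------------
    def _norm_columns(self, tg: Thermogram, kd1: float, kd2: float):
        """Columns of the normalized-heat design matrix for fixed Kd's."""
        proto = tg.protocol
        a_ucal, b_ucal = _response_matrix(proto, kd1, kd2, self.active_fraction)
        v = np.asarray(proto.injection_volumes)
        scale = 1e-9 / (proto.syringe_conc * v)  # µcal -> kcal/mol of injectant
        return a_ucal * scale, b_ucal * scale, scale  # dh1-col, dh2-col, q_dil-col

    def _mask(self, n: int) -> np.ndarray:
        m = np.ones(n, dtype=bool)
        if self.exclude_first:
            m[0] = False
        return m

    def _weights(self, n: int, mask: np.ndarray) -> np.ndarray:
        if self.sigma is None:
            return np.ones(mask.sum())
        s = np.asarray(self.sigma, dtype=float)
        _require(s.shape == (n,), "sigma length must equal injection count")
        _require(np.all(s > 0), "sigma must be > 0")
        return 1.0 / s[mask]

    def _varpro_resid(self, log_kds, y, w, tg, mask, single):
        """Residuals with enthalpies/offset profiled out by linear lstsq."""
        log_kds = np.clip(log_kds, -15.0, 6.0)
        kd1 = 10.0 ** log_kds[0]
        kd2 = math.inf if single else 10.0 ** log_kds[1]
        a, b, c = self._norm_columns(tg, kd1, kd2)
        cols = [a[mask], c[mask]] if single else [a[mask], b[mask], c[mask]]
        design = np.column_stack(cols) * w[:, None]
        coef, *_ = np.linalg.lstsq(design, y * w, rcond=None)
        return (design @ coef - y * w), coef

    def _full_resid(self, theta, y, w, tg, mask, single):
        clip = lambda x: min(max(x, -15.0), 6.0)
        if single:
            kd1, dh1, q_dil = 10.0 ** clip(theta[0]), theta[1], theta[2]
            kd2, dh2 = math.inf, 0.0
        else:
            kd1 = 10.0 ** clip(theta[0])
            kd2 = 10.0 ** clip(theta[1])
            dh1, dh2, q_dil = theta[2], theta[3], theta[4]
        a, b, c = self._norm_columns(tg, kd1, kd2)
        model = dh1 * a + dh2 * b + q_dil * c
        return (model[mask] - y) * w

    def _start_grid(self, single: bool):
        n = max(int(self.n_starts), 8)
        if single:
            return [(g,) for g in np.linspace(-9.0, -3.0, n)]
        side = max(3, math.ceil(math.sqrt(n)))
        g = np.linspace(-7.5, -3.0, side)
        return [(g1, g2) for g1 in g for g2 in g]

    # -- API ----------------------------------------------------------------
    def fit(self, thermogram: Thermogram, y=None) -> "ThermogramFitter":
        """Estimate binding parameters from a thermogram.

        ``y`` is accepted for signature compatibility and must be None
        (the heats live inside the thermogram).
        """
        _require(y is None, "pass the heats inside the Thermogram; y must be None")
        _require(isinstance(thermogram, Thermogram), "fit expects a Thermogram")
        single = self._scheme_is_single()
        n = thermogram.protocol.n_injections
        k = 3 if single else 5
        mask = self._mask(n)
        n_fit = int(mask.sum())
        _require(n_fit >= max(6, k + 1), f"need at least {max(6, k + 1)} fitted injections, have {n_fit}")
        y_data = thermogram.normalized[mask]
        w = self._weights(n, mask)

        best = None
        for start in self._start_grid(single):
            try:
                sol = least_squares(
                    lambda th: self._varpro_resid(th, y_data, w, thermogram, mask, single)[0],
                    x0=np.asarray(start, dtype=float), method="lm",
                    xtol=1e-9, ftol=1e-9, max_nfev=120)
            except Exception:
                continue
            rss = float(np.sum(sol.fun ** 2))
            if best is None or rss < best[0]:
                best = (rss, sol.x)
        if best is None:
            raise RuntimeError("no multistart converged; thermogram may be degenerate")

        # polish on the full parameter vector; gives the covariance Jacobian
        _, coef = self._varpro_resid(best[1], y_data, w, thermogram, mask, single)
        theta0 = np.concatenate([best[1], coef])
        sol = least_squares(self._full_resid, theta0, args=(y_data, w, thermogram, mask, single),
                            method="lm", xtol=1e-13, ftol=1e-13, max_nfev=800)
        theta = sol.x
        rss = float(np.sum(sol.fun ** 2))

        if single:
            params = BindingParameters(kd1=10.0 ** theta[0], kd2=math.inf,
                                       dh1=theta[1], dh2=0.0, q_dil=theta[2])
        else:
            params = BindingParameters(kd1=10.0 ** theta[0], kd2=10.0 ** theta[1],
                                       dh1=theta[2], dh2=theta[3], q_dil=theta[4])

        stderr = self._stderr(sol.jac, rss, n_fit, k, theta, single)
        model = self.predict(thermogram.protocol, params)
        residuals = np.asarray(thermogram.heats) * 0.0
        residuals = thermogram.normalized - model
        aic = n_fit * math.log(max(rss, 1e-300) / n_fit) + 2 * k

        self.params_ = params
        self.stderr_ = stderr
        self.residuals_ = residuals
        self.rss_ = rss
        self.aic_ = aic
        self.n_obs_ = n_fit
        self.result_ = FitResult(params=params, stderr=stderr, residuals=tuple(residuals),
                                 rss=rss, model_tag=self.scheme, aic=aic,
                                 n_obs=n_fit, n_params=k)
        return self

    def _scheme_is_single(self) -> bool:
        _require(self.scheme in SCHEMES, f"scheme must be one of {SCHEMES}, got {self.scheme!r}")
        return self.scheme == "single_site"

    def _stderr(self, jac, rss, n, k, theta, single) -> dict:
        dof = max(n - k, 1)
        try:
            cov = np.linalg.pinv(jac.T @ jac) * (rss / dof)
            se = np.sqrt(np.clip(np.diag(cov), 0, None))
        except np.linalg.LinAlgError:
            se = np.full(len(theta), np.nan)
        ln10 = math.log(10.0)
        if single:
            return {"kd1": ln10 * (10.0 ** theta[0]) * se[0], "kd2": float("nan"),
                    "dh1": se[1], "dh2": float("nan"), "q_dil": se[2]}
        return {"kd1": ln10 * (10.0 ** theta[0]) * se[0],
                "kd2": ln10 * (10.0 ** theta[1]) * se[1],
                "dh1": se[2], "dh2": se[3], "q_dil": se[4]}

    def predict(self, protocol: TitrationProtocol, params: Optional[BindingParameters] = None) -> np.ndarray:
        """Model normalized heats (kcal/mol) for a protocol.

        Uses the fitted parameters unless ``params`` is given.
        """
        if params is None:
            if not hasattr(self, "params_"):
                raise RuntimeError("fit first, or pass params explicitly")
            params = self.params_
        a, b, c = self._norm_columns(Thermogram(protocol, (0.0,) * protocol.n_injections),
                                     params.kd1, params.kd2)
        return params.dh1 * a + params.dh2 * b + params.q_dil * c

    def bootstrap_stderr(self, thermogram: Thermogram, n_boot: int = 100,
                         seed: int = 0) -> dict:
        """Parametric-bootstrap standard errors.

        Resimulates the fitted model, adds Gaussian noise matched to the
        residual scale (µcal), refits, and reports the standard deviation
        of each parameter over replicates.
        """
        if not hasattr(self, "params_"):
            raise RuntimeError("fit first")
        rng = np.random.default_rng(seed)
        base = simulate_thermogram(thermogram.protocol, self.params_, self.active_fraction)
        # residual scale back in µcal
        v = np.asarray(thermogram.protocol.injection_volumes)
        res_ucal = self.residuals_ * thermogram.protocol.syringe_conc * v * 1e9
        sigma = float(np.std(res_ucal[self._mask(len(v))], ddof=1))
        draws = {k: [] for k in ("kd1", "kd2", "dh1", "dh2", "q_dil")}
        for _ in range(n_boot):
            noisy = Thermogram(base.protocol,
                               tuple(np.asarray(base.heats) + rng.normal(0, sigma, len(v))))
            f = ThermogramFitter(**self.get_params()).fit(noisy)
            for k in draws:
                draws[k].append(getattr(f.params_, k))
        return {k: float(np.std([x for x in vs if math.isfinite(x)], ddof=1))
                if any(math.isfinite(x) for x in vs) else float("nan")
                for k, vs in draws.items()}


def fit_thermogram(data: Thermogram, scheme: str = "double_dependent",
                   init: Optional[BindingParameters] = None, **kwargs) -> FitResult:
    """Fit one scheme to a thermogram; thin wrapper over ThermogramFitter.

    ``init``, when given, is added as an extra multistart point via a
    direct polish from it; the multistart grid still runs.
    """
    fitter = ThermogramFitter(scheme=scheme, **kwargs)
    fitter.fit(data)
    if init is not None:
        single = scheme == "single_site"
        theta0 = ([math.log10(init.kd1), init.dh1, init.q_dil] if single else
                  [math.log10(init.kd1), math.log10(init.kd2), init.dh1, init.dh2, init.q_dil])
        mask = fitter._mask(data.protocol.n_injections)
        y = data.normalized[mask]
        w = fitter._weights(data.protocol.n_injections, mask)
        sol = least_squares(fitter._full_resid, np.asarray(theta0),
                            args=(y, w, data, mask, single), method="lm",
                            xtol=1e-13, ftol=1e-13, max_nfev=800)
        if float(np.sum(sol.fun ** 2)) < fitter.rss_ * (1 - 1e-12):
            # the user-supplied start found a better basin; refit from it
            theta = sol.x
            if single:
                better = BindingParameters(kd1=10.0 ** theta[0], kd2=math.inf,
                                           dh1=theta[1], dh2=0.0, q_dil=theta[2])
            else:
                better = BindingParameters(kd1=10.0 ** theta[0], kd2=10.0 ** theta[1],
                                           dh1=theta[2], dh2=theta[3], q_dil=theta[4])
            rss = float(np.sum(sol.fun ** 2))
            n_fit = int(mask.sum())
            k = 3 if single else 5
            stderr = fitter._stderr(sol.jac, rss, n_fit, k, theta, single)
            residuals = data.normalized - fitter.predict(data.protocol, better)
            aic = n_fit * math.log(max(rss, 1e-300) / n_fit) + 2 * k
            return FitResult(params=better, stderr=stderr, residuals=tuple(residuals),
                             rss=rss, model_tag=scheme, aic=aic, n_obs=n_fit, n_params=k)
    return fitter.result_


def compare_models(data: Thermogram, **kwargs) -> list:
    """Fit both schemes with shared weighting; return FitResults sorted by AIC."""
    results = [fit_thermogram(data, scheme=s, **kwargs) for s in SCHEMES]
    return sorted(results, key=lambda r: r.aic)
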