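"""STD-NMR build-up analysis and binding-epitope mapping.

Saturation-transfer difference (STD) NMR reports how close each ligand
proton sits to the receptor surface in the bound state: protons in tight
contact receive more transferred saturation.  The relative STD intensity
of a proton is

    std = (I_off - I_on) / I_off

and its growth with saturation time t follows the mono-exponential
build-up

    std(t) = std_max * (1 - exp(-k_sat * t)),

whose initial slope std0 = std_max * k_sat is the preferred epitope
quantity because it is unbiased by differential proton T1 relaxation.
An epitope map rescales per-proton values so the largest is exactly 100%.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = ["StdSeries", "EpitopeMap", "relative_std", "BuildupFitter",
           "fit_buildup", "epitope_map"]

EPITOPE_METHODS = ("single_time", "initial_slope")


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValueError(msg)


@dataclass(frozen=True)
class StdSeries:
    """Per-proton on/off-resonance intensities across saturation times.

    Parameters
    ----------
    proton_labels : tuple of str
    sat_times : tuple of float, seconds
    i_off : dict proton -> off-resonance reference intensity (> 0)
    i_on : dict proton -> tuple of on-resonance intensities, one per
        sat_time; NaN marks an explicitly missing cell.
    overlap_groups : dict group label -> frozenset of proton labels whose
        peaks overlap and are reported jointly.
    """

    proton_labels: tuple
    sat_times: tuple
    i_off: dict
    i_on: dict
    overlap_groups: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        labels = tuple(self.proton_labels)
        times = tuple(float(t) for t in self.sat_times)
        _require(len(labels) > 0, "need at least one proton")
        _require(len(times) > 0, "need at least one saturation time")
        _require(all(t > 0 for t in times), "saturation times must be > 0")
        _require(len(set(labels)) == len(labels), "duplicate proton labels")
        for p in labels:
            _require(p in self.i_off, f"missing i_off for proton {p!r}")
            _require(self.i_off[p] > 0, f"i_off must be > 0 for proton {p!r}")
            _require(p in self.i_on, f"missing i_on for proton {p!r}")
            row = tuple(float(x) for x in self.i_on[p])
            _require(len(row) == len(times),
                     f"proton {p!r}: {len(row)} i_on values for {len(times)} sat_times")
            _require(all(math.isnan(x) or x >= 0 for x in row),
                     f"i_on must be >= 0 or NaN for proton {p!r}")
        for g, members in self.overlap_groups.items():
            _require(all(m in labels for m in members),
                     f"overlap group {g!r} names unknown protons")
        object.__setattr__(self, "proton_labels", labels)
        object.__setattr__(self, "sat_times", times)
        object.__setattr__(self, "i_on", {p: tuple(float(x) for x in self.i_on[p]) for p in labels})
        object.__setattr__(self, "overlap_groups",
                           {g: frozenset(m) for g, m in self.overlap_groups.items()})

    def group_of(self, proton: str) -> Optional[str]:
        for g, members in self.overlap_groups.items():
            if proton in members:
                return g
        return None


@dataclass(frozen=True)
class EpitopeMap:
    """Per-proton relative STD values scaled so the maximum is 100%."""

    values: dict                 # proton -> percent of maximum
    method_tag: str              # single_time | initial_slope
    reference_time: Optional[float] = None
    overlap_flags: dict = field(default_factory=dict)  # proton -> group label or None

    def __post_init__(self) -> None:
        _require(self.method_tag in EPITOPE_METHODS, f"unknown method {self.method_tag!r}")
        vals = np.asarray(list(self.values.values()))
        _require(np.all(vals > 0) and np.all(vals <= 100.0), "epitope values must be in (0, 100]")
        _require(math.isclose(float(vals.max()), 100.0, rel_tol=0, abs_tol=0),
                 "maximum epitope value must be exactly 100")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "proton": list(self.values),
            "relative_std_percent": list(self.values.values()),
            "overlap_group": [self.overlap_flags.get(p) for p in self.values],
        })


def relative_std(series: StdSeries) -> pd.DataFrame:
    """Relative STD fraction per (proton, sat_time) cell.

    Returns a tidy frame with columns
    ``proton, sat_time_s, std_fraction, overlap_group``; missing cells
    carry NaN in std_fraction.
    """
    rows = []
    for p in series.proton_labels:
        off = series.i_off[p]
        grp = series.group_of(p)
        for t, on in zip(series.sat_times, series.i_on[p]):
            rows.append({"proton": p, "sat_time_s": t,
                         "std_fraction": (off - on) / off,
                         "overlap_group": grp})
    return pd.DataFrame(rows)


class BuildupFitter:
    """Mono-exponential STD build-up fit for one proton (sklearn idiom).

    ``fit(X, y)`` takes saturation times (shape (n,) or (n, 1), seconds)
    and relative STD fractions; exposes ``std_max_``, ``k_sat_`` and the
    initial slope ``std0_ = std_max_ * k_sat_``.  Degenerate data (all
    STD values equal) yields a flagged flat fit with ``std0_ = 0``.
    """

    def __init__(self, max_nfev: int = 2000):
        self.max_nfev = max_nfev

    def get_params(self, deep: bool = True) -> dict:
        return {"max_nfev": self.max_nfev}

    def set_params(self, **kwargs) -> "BuildupFitter":
        for k, v in kwargs.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    @staticmethod
    def _model(t, std_max, k_sat):
        return std_max * (1.0 - np.exp(-k_sat * t))

    def fit(self, X, y) -> "BuildupFitter":
        t = np.asarray(X, dtype=float).reshape(-1)
        s = np.asarray(y, dtype=float).reshape(-1)
        _require(t.shape == s.shape, "X and y must have the same length")
        keep = ~np.isnan(s)
        t, s = t[keep], s[keep]
        _require(len(np.unique(t)) >= 3, "need >= 3 distinct saturation times")
        _require(np.all(t > 0), "saturation times must be > 0")

        if np.ptp(s) == 0.0:
            self.std_max_ = float(s[0])
            self.k_sat_ = float("nan")
            self.std0_ = 0.0
            self.flat_ = True
            return self

        smax0 = max(float(np.max(s)), 1e-12)
        # crude initial rate from the earliest point
        k0 = max(float(s[np.argmin(t)]) / (smax0 * float(np.min(t))), 1e-3)
        popt, _ = curve_fit(self._model, t, s, p0=(smax0, k0),
                            maxfev=self.max_nfev,
                            bounds=((0.0, 0.0), (np.inf, np.inf)))
        self.std_max_ = float(popt[0])
        self.k_sat_ = float(popt[1])
        self.std0_ = self.std_max_ * self.k_sat_
        self.flat_ = False
        return self

    def predict(self, X) -> np.ndarray:
        t = np.asarray(X, dtype=float).reshape(-1)
        if getattr(self, "flat_", False):
            return np.full_like(t, self.std_max_)
        return self._model(t, self.std_max_, self.k_sat_)


def fit_buildup(series: StdSeries) -> pd.DataFrame:
    """Fit the build-up curve of every proton.

    Returns a frame indexed by proton with columns
    ``std_max, k_sat, std0, flat, fitted, overlap_group``.  Protons with
    fewer than 3 usable points are reported unfitted (NaN parameters).
    """
    std = relative_std(series).pivot(index="proton", columns="sat_time_s",
                                     values="std_fraction")
    rows = {}
    t = np.asarray(series.sat_times)
    for p in series.proton_labels:
        s = std.loc[p, list(series.sat_times)].to_numpy(dtype=float)
        n_ok = int(np.sum(~np.isnan(s)))
        if n_ok < 3:
            rows[p] = dict(std_max=np.nan, k_sat=np.nan, std0=np.nan,
                           flat=False, fitted=False, overlap_group=series.group_of(p))
            continue
        f = BuildupFitter().fit(t, s)
        rows[p] = dict(std_max=f.std_max_, k_sat=f.k_sat_, std0=f.std0_,
                       flat=f.flat_, fitted=True, overlap_group=series.group_of(p))
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "proton"
    return out


def epitope_map(series: StdSeries, method: str = "single_time",
                reference_time: Optional[float] = None) -> EpitopeMap:
    """Normalized binding-epitope map.

    method="single_time": per-proton STD fraction at ``reference_time``
    (must be one of the series' saturation times).
    method="initial_slope": per-proton std0 from the build-up fit,
    insensitive to differential T1 relaxation.

    Overlap-group members receive the group's pooled (mean) value and
    keep the group flag; the maximum over protons is scaled to exactly
    100%.
    """
    _require(method in EPITOPE_METHODS, f"method must be one of {EPITOPE_METHODS}")
    if method == "single_time":
        _require(reference_time is not None, "single_time requires reference_time")
        times = np.asarray(series.sat_times)
        hit = np.isclose(times, float(reference_time), rtol=1e-9, atol=0)
        _require(hit.any(), f"reference_time {reference_time} not in sat_times {series.sat_times}")
        idx = int(np.argmax(hit))
        raw = {p: (series.i_off[p] - series.i_on[p][idx]) / series.i_off[p]
               for p in series.proton_labels}
    else:
        fits = fit_buildup(series)
        raw = {p: float(fits.loc[p, "std0"]) for p in series.proton_labels
               if bool(fits.loc[p, "fitted"])}
        _require(len(raw) > 0, "no proton has enough points for a build-up fit")

    # pool overlap groups: every member reports the group mean
    pooled = dict(raw)
    for g, members in series.overlap_groups.items():
        vals = [raw[m] for m in members if m in raw]
        if vals:
            mean = float(np.mean(vals))
            for m in members:
                if m in pooled:
                    pooled[m] = mean

    # protons with nonpositive STD (no transferred saturation) carry no
    # epitope information and are dropped from the map
    pooled = {p: v for p, v in pooled.items() if v > 0}
    _require(len(pooled) > 0, "all STD values are <= 0; no epitope to map")
    top = max(pooled.values())
    values = {p: 100.0 * v / top for p, v in pooled.items()}
    # guard against round-off on the maximum itself
    pmax = max(values, key=values.get)
    values[pmax] = 100.0
    flags = {p: series.group_of(p) for p in values}
    return EpitopeMap(values=values, method_tag=method,
                      reference_time=(float(reference_time) if method == "single_time" else None),
                      overlap_flags=flags)
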