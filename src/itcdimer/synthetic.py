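"""Synthetic ITC and STD-NMR data with known ground truth.

The defaults reproduce the study conditions the analysis targets: a
VP-ITC-style titration of 250 µM ligand in 56 injections of 8 µL into a
1.4 mL cell holding 20 µM receptor at 25 °C, with heats generated by the
two-event scheme (Kd1 = 2.9 µM, Kd2 = 61.5 µM) and 0.5 µcal Gaussian
noise per injection; and STD build-up series at saturation times
0.3, 0.6, 1.0, 2.0, 3.0 s with 2% multiplicative intensity noise.

Enthalpies default to ΔH1 = -8000 cal/mol and ΔH2 = +8000 cal/mol —
opposite signs of magnitudes typical for micromolar protein-ligand
events, chosen so the thermogram shows a clear interior extremum
(the biphasic signature of the second binding event).
Every generator is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Tuple

import numpy as np

from .equilibria import BindingParameters
from .itc import Thermogram, TitrationProtocol, simulate_thermogram
from .std import StdSeries

__all__ = ["SyntheticSpec", "default_spec", "generate_thermogram", "generate_std_series"]

#: default per-proton (std_max, k_sat /s) truth; labels cover one symmetric
#: half of a polysulfonated naphthylurea ligand (naphthalene ring protons,
#: amide-linked phenyl protons, ring methyl)
DEFAULT_STD_TRUTH: Dict[str, Tuple[float, float]] = {
    "H1": (0.50, 1.3),
    "H2": (0.35, 1.1),
    "H3": (0.45, 1.2),
    "H4": (0.40, 1.2),
    "H5": (0.20, 0.9),
    "H6": (0.10, 0.8),
    "CH3": (0.28, 1.0),
}

DEFAULT_OVERLAP_GROUPS = {"g1": frozenset({"H3", "H4"})}

DEFAULT_SAT_TIMES = (0.3, 0.6, 1.0, 2.0, 3.0)


@dataclass(frozen=True)
class SyntheticSpec:
    """Full recipe for one synthetic dataset (ITC and STD)."""

    protocol: TitrationProtocol
    truth: BindingParameters
    noise_sigma_ucal: float = 0.5
    seed: int = 0
    std_truth: dict = field(default_factory=lambda: dict(DEFAULT_STD_TRUTH))
    std_sat_times: tuple = DEFAULT_SAT_TIMES
    std_noise_frac: float = 0.02
    std_i_off: float = 1000.0
    std_overlap_groups: dict = field(default_factory=lambda: dict(DEFAULT_OVERLAP_GROUPS))

    def __post_init__(self) -> None:
        if self.noise_sigma_ucal < 0 or self.std_noise_frac < 0:
            raise ValueError("noise levels must be >= 0")
        if self.std_i_off <= 0:
            raise ValueError("std_i_off must be > 0")


def default_spec(seed: int = 0, n_injections: int = 56,
                 noise_sigma_ucal: float = 0.5) -> SyntheticSpec:
    """The canonical study-condition spec (see module docstring)."""
    return SyntheticSpec(
        protocol=TitrationProtocol.vp_itc_default(n_injections=n_injections),
        truth=BindingParameters(kd1=2.9e-6, kd2=61.5e-6,
                                dh1=-8000.0, dh2=8000.0, q_dil=0.0),
        noise_sigma_ucal=noise_sigma_ucal,
        seed=seed,
    )


def generate_thermogram(spec: SyntheticSpec):
    """Simulate the truth thermogram and add i.i.d. Gaussian heat noise.

    Returns ``(thermogram, truth_record)`` where the truth record is a
    flat dict sufficient to rerun any recovery test.
    """
    clean = simulate_thermogram(spec.protocol, spec.truth)
    rng = np.random.default_rng(spec.seed)
    heats = np.asarray(clean.heats)
    if spec.noise_sigma_ucal > 0:
        heats = heats + rng.normal(0.0, spec.noise_sigma_ucal, heats.size)
    tg = Thermogram(protocol=spec.protocol, heats=tuple(heats))
    truth = {
        "kd1_M": spec.truth.kd1, "kd2_M": spec.truth.kd2,
        "dh1_cal_mol": spec.truth.dh1, "dh2_cal_mol": spec.truth.dh2,
        "q_dil_ucal": spec.truth.q_dil,
        "noise_sigma_ucal": spec.noise_sigma_ucal, "seed": spec.seed,
    }
    return tg, truth


def generate_std_series(spec: SyntheticSpec):
    """Generate an STD build-up series from per-proton (std_max, k_sat).

    On-resonance intensities are ``i_off * (1 - std(t))`` with
    multiplicative Gaussian noise of fractional scale
    ``std_noise_frac``; off-resonance references are noise-free.
    Returns ``(series, truth_record)``.
    """
    rng = np.random.default_rng(spec.seed + 1)  # decouple from the ITC stream
    t = np.asarray(spec.std_sat_times)
    labels = tuple(spec.std_truth)
    i_on = {}
    for p in labels:
        smax, ksat = spec.std_truth[p]
        std = smax * (1.0 - np.exp(-ksat * t))
        on = spec.std_i_off * (1.0 - std)
        if spec.std_noise_frac > 0:
            on = on * (1.0 + rng.normal(0.0, spec.std_noise_frac, on.size))
        i_on[p] = tuple(np.clip(on, 0.0, None))
    series = StdSeries(
        proton_labels=labels,
        sat_times=tuple(float(x) for x in t),
        i_off={p: spec.std_i_off for p in labels},
        i_on=i_on,
        overlap_groups=dict(spec.std_overlap_groups),
    )
    truth = {f"{p}_{k}": v for p in labels
             for k, v in zip(("std_max", "k_sat"), spec.std_truth[p])}
    truth.update({"noise_frac": spec.std_noise_frac, "seed": spec.seed,
                  "i_off": spec.std_i_off})
    return series, truth
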