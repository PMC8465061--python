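"""Quantification of restriction-endonuclease cleavage protection (REPA).

A REPA lane contains a probe DNA carrying a candidate binding site and a
control DNA without one, both exposed to the same type IIS enzyme after
incubation with protein.  Band intensities for the uncleaved and cleaved
species of each DNA give per-lane protection fractions; subtracting the
control's fraction removes per-lane enzyme-activity variation, leaving the
binding-dependent protection signal as a function of protein concentration.
"""
from __future__ import annotations

import dataclasses
import warnings
from collections.abc import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit


@dataclasses.dataclass
class RepaMeasurement:
    """Band intensities for one titration lane."""

    concentration: float  # nM
    probe_uncleaved: float
    probe_cleaved: float
    control_uncleaved: float
    control_cleaved: float

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if f.name != "concentration" and v < 0:
                raise ValueError(f"{f.name} must be >= 0")
        if self.probe_uncleaved + self.probe_cleaved <= 0:
            raise ValueError("at least one probe intensity must be > 0")


@dataclasses.dataclass
class ProtectionCurve:
    """Protection fractions versus protein concentration."""

    concentrations: np.ndarray
    probe_fraction: np.ndarray
    control_fraction: np.ndarray
    normalized: np.ndarray  # probe minus control baseline, clipped to [0, 1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "concentration_nM": self.concentrations,
                "probe_protected_fraction": self.probe_fraction,
                "control_protected_fraction": self.control_fraction,
                "normalized_protection": self.normalized,
            }
        )


def protection_fraction(uncleaved: float, cleaved: float) -> float:
    """Uncleaved fraction: uncleaved / (uncleaved + cleaved).

    Returns NaN (with a warning) when both intensities are zero.
    """
    if uncleaved < 0 or cleaved < 0:
        raise ValueError("intensities must be >= 0")
    total = uncleaved + cleaved
    if total == 0:
        warnings.warn("both band intensities are zero; protection undefined", stacklevel=2)
        return float("nan")
    return uncleaved / total


def protection_curve(measurements: Sequence[RepaMeasurement]) -> ProtectionCurve:
    """Per-lane probe/control protection fractions, sorted by concentration."""
    if not measurements:
        raise ValueError("no measurements")
    concs = np.array([m.concentration for m in measurements])
    if len(np.unique(concs)) != len(concs):
        raise ValueError("duplicate concentrations in titration")
    order = np.argsort(concs)
    ms = [measurements[i] for i in order]
    probe = np.array([protection_fraction(m.probe_uncleaved, m.probe_cleaved) for m in ms])
    ctrl = np.array([protection_fraction(m.control_uncleaved, m.control_cleaved) for m in ms])
    normalized = np.clip(probe - ctrl, 0.0, 1.0)
    return ProtectionCurve(
        concentrations=concs[order],
        probe_fraction=probe,
        control_fraction=ctrl,
        normalized=normalized,
    )


def fit_half_max(curve: ProtectionCurve) -> tuple[float, float]:
    """Summarise a curve with a single-site occupancy fit A*C/(C + K).

    Returns (K, A): the half-maximal concentration K (nM) and the protection
    amplitude A.  Intended as a one-number summary of a titration, not as a
    rigorous affinity measurement.
    """
    c = curve.concentrations
    y = curve.normalized
    if len(c) < 2:
        raise ValueError("need at least 2 lanes to fit an occupancy curve")

    def occ(conc, amp, k):
        return amp * conc / (conc + k)

    p0 = (max(float(y.max()), 1e-3), float(np.median(c[c > 0])) if (c > 0).any() else 1.0)
    popt, _ = curve_fit(occ, c, y, p0=p0, bounds=([0, 1e-9], [1.5, np.inf]), maxfev=10000)
    amp, k = popt
    return float(k), float(amp)


def measurements_from_frame(df: pd.DataFrame) -> list[RepaMeasurement]:
    """Build lane measurements from an intensity CSV table."""
    required = {
        "concentration_nM",
        "probe_uncleaved",
        "probe_cleaved",
        "control_uncleaved",
        "control_cleaved",
    }
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"intensity table missing columns: {sorted(missing)}")
    return [
        RepaMeasurement(
            concentration=float(r.concentration_nM),
            probe_uncleaved=float(r.probe_uncleaved),
            probe_cleaved=float(r.probe_cleaved),
            control_uncleaved=float(r.control_uncleaved),
            control_cleaved=float(r.control_cleaved),
        )
        for r in df.itertuples()
    ]
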