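"""Global 1:1 Langmuir association-then-dissociation kinetics.

Biosensor (BLI/SPR) sensorgrams record response versus time while analyte at
concentration C associates with an immobilised ligand and then dissociates in
buffer.  Under a 1:1 model,

    association  (t <= t_switch):  R(t) = R_eq (1 - exp(-k_obs t)),
                                   k_obs = kon C + koff,
                                   R_eq  = Rmax C / (C + koff/kon)
    dissociation (t >  t_switch):  R(t) = R(t_switch) exp(-koff (t - t_switch))

A single (kon, koff, Rmax) triple is fit jointly to all concentrations by
least squares from multiple log-spaced starts, and K_D = koff/kon is reported
in nM.  Fits whose K_D exceeds the assay's determination limit, that pin a
parameter at its bounds, or that explain less than half the variance are
flagged ambiguous rather than reported as determinate numbers.
"""
from __future__ import annotations

import dataclasses
import itertools
from collections.abc import Sequence

import numpy as np
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator


@dataclasses.dataclass
class Sensorgram:
    """One analyte-concentration trace with its association/dissociation split."""

    concentration: float  # nM (dimeric protein)
    times: np.ndarray  # s
    responses: np.ndarray  # response units
    t_switch: float  # s, association -> dissociation boundary

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if self.times.shape != self.responses.shape:
            raise ValueError("times and responses must have equal length")
        if self.times.size < 2 or (np.diff(self.times) <= 0).any():
            raise ValueError("times must be strictly increasing")
        if not self.times[0] <= self.t_switch <= self.times[-1]:
            raise ValueError("t_switch must lie within the time range")


@dataclasses.dataclass
class KineticFit:
    """Fitted kinetic parameters (one row of a binding-parameter table)."""

    kon: float  # M^-1 s^-1
    koff: float  # s^-1
    kd: float  # nM
    rmax: float  # response units
    r2: float
    status: str  # "ok" | "ambiguous"


def kd_from_rates(kon: float, koff: float) -> float:
    """Equilibrium dissociation constant in nM: koff / kon * 1e9."""
    return koff / kon * 1e9


def model_response(
    kon: float,
    koff: float,
    rmax: float,
    conc: float,
    t: np.ndarray | float,
    t_switch: float,
) -> np.ndarray:
    """Piecewise 1:1 Langmuir response; ``conc`` in nM, rates in molar units."""
    if kon < 0 or koff < 0 or rmax < 0:
        raise ValueError("kon, koff and rmax must be non-negative")
    t = np.asarray(t, dtype=float)
    c_molar = conc * 1e-9
    k_obs = kon * c_molar + koff
    kd_molar = koff / kon if kon > 0 else np.inf
    r_eq = rmax * c_molar / (c_molar + kd_molar) if np.isfinite(kd_molar) else 0.0
    assoc = r_eq * (1.0 - np.exp(-k_obs * np.minimum(t, t_switch)))
    r_switch = r_eq * (1.0 - np.exp(-k_obs * t_switch))
    dissoc = r_switch * np.exp(-koff * np.maximum(t - t_switch, 0.0))
    return np.where(t <= t_switch, assoc, dissoc)


class GlobalKineticFit(BaseEstimator):
    """Global least-squares estimator for (kon, koff, Rmax) over many traces.

    Parameters
    ----------
    ambiguity_kd:
        K_D (nM) above which the fit is reported ambiguous — outside the
        concentration range the assay can determine.
    n_starts:
        Number of multi-start initialisations, log-spaced over
        ``kon_start_range`` x ``koff_start_range``; ties broken by lowest SSE.
    shared_rmax:
        Fit one Rmax across all traces (single sensor load).  With False, one
        Rmax per trace.
    log10_kon_bounds, log10_koff_bounds, log10_rmax_bounds:
        Optimisation box in log10 space; hitting a bound marks the fit
        ambiguous.

    Attributes (after ``fit``)
    --------------------------
    kon_, koff_, kd_, rmax_, r2_, sse_, status_
    """

    def __init__(
        self,
        ambiguity_kd: float = 1000.0,
        n_starts: int = 8,
        shared_rmax: bool = True,
        kon_start_range: tuple[float, float] = (1e4, 1e7),
        koff_start_range: tuple[float, float] = (1e-4, 1e-1),
        log10_kon_bounds: tuple[float, float] = (1.0, 10.0),
        log10_koff_bounds: tuple[float, float] = (-7.0, 2.0),
        log10_rmax_bounds: tuple[float, float] = (-6.0, 4.0),
    ):
        self.ambiguity_kd = ambiguity_kd
        self.n_starts = n_starts
        self.shared_rmax = shared_rmax
        self.kon_start_range = kon_start_range
        self.koff_start_range = koff_start_range
        self.log10_kon_bounds = log10_kon_bounds
        self.log10_koff_bounds = log10_koff_bounds
        self.log10_rmax_bounds = log10_rmax_bounds

    def _residuals(self, params: np.ndarray, sensorgrams: list[Sensorgram]) -> np.ndarray:
        kon, koff = 10.0 ** params[0], 10.0 ** params[1]
        res = []
        for i, sg in enumerate(sensorgrams):
            rmax = 10.0 ** (params[2] if self.shared_rmax else params[2 + i])
            pred = model_response(kon, koff, rmax, sg.concentration, sg.times, sg.t_switch)
            res.append(pred - sg.responses)
        return np.concatenate(res)

    def fit(self, X: Sequence[Sensorgram], y=None):
        sensorgrams = list(X)
        if len(sensorgrams) < 2:
            raise ValueError("global fit requires sensorgrams at >= 2 concentrations")
        n_rmax = 1 if self.shared_rmax else len(sensorgrams)
        max_resp = max(float(np.abs(sg.responses).max()) for sg in sensorgrams)
        rmax0 = np.log10(max(max_resp, 1e-3))
        lo = np.array(
            [self.log10_kon_bounds[0], self.log10_koff_bounds[0]]
            + [self.log10_rmax_bounds[0]] * n_rmax
        )
        hi = np.array(
            [self.log10_kon_bounds[1], self.log10_koff_bounds[1]]
            + [self.log10_rmax_bounds[1]] * n_rmax
        )
        n_kon = max(2, int(np.ceil(np.sqrt(self.n_starts))))
        n_koff = max(2, int(np.ceil(self.n_starts / n_kon)))
        kon_grid = np.log10(np.geomspace(*self.kon_start_range, n_kon))
        koff_grid = np.log10(np.geomspace(*self.koff_start_range, n_koff))
        best = None
        for k0, f0 in itertools.product(kon_grid, koff_grid):
            x0 = np.clip(np.array([k0, f0] + [rmax0] * n_rmax), lo + 1e-9, hi - 1e-9)
            sol = least_squares(
                self._residuals, x0, bounds=(lo, hi), args=(sensorgrams,), method="trf"
            )
            sse = float(np.sum(sol.fun**2))
            if best is None or sse < best[0]:
                best = (sse, sol)
        sse, sol = best
        self.sse_ = sse
        self.kon_ = 10.0 ** sol.x[0]
        self.koff_ = 10.0 ** sol.x[1]
        rmaxes = 10.0 ** sol.x[2:]
        self.rmax_ = float(rmaxes[0]) if self.shared_rmax else rmaxes
        self.kd_ = kd_from_rates(self.kon_, self.koff_)
        all_resp = np.concatenate([sg.responses for sg in sensorgrams])
        sst = float(np.sum((all_resp - all_resp.mean()) ** 2))
        self.r2_ = 1.0 - sse / sst if sst > 0 else 0.0
        at_bound = bool(np.any(sol.x <= lo + 1e-6) or np.any(sol.x >= hi - 1e-6))
        ambiguous = self.kd_ > self.ambiguity_kd or at_bound or self.r2_ < 0.5
        self.status_ = "ambiguous" if ambiguous else "ok"
        return self

    def predict(self, X: Sequence[Sensorgram]) -> list[np.ndarray]:
        """Model responses on each sensorgram's time grid at the fitted parameters."""
        out = []
        for i, sg in enumerate(X):
            rmax = self.rmax_ if self.shared_rmax else self.rmax_[i]
            out.append(
                model_response(self.kon_, self.koff_, rmax, sg.concentration, sg.times, sg.t_switch)
            )
        return out


def fit_global(
    sensorgrams: Sequence[Sensorgram],
    init: tuple[float, float, float] | None = None,
    ambiguity_kd: float = 1000.0,
    **kwargs,
) -> KineticFit:
    """Fit (kon, koff, Rmax) globally and summarise as a :class:`KineticFit`.

    ``init`` optionally adds one (kon, koff, rmax) start to the multi-start
    grid by centring the start ranges on it.
    """
    if init is not None:
        kon0, koff0, _ = init
        kwargs.setdefault("kon_start_range", (kon0 / 3, kon0 * 3))
        kwargs.setdefault("koff_start_range", (koff0 / 3, koff0 * 3))
    est = GlobalKineticFit(ambiguity_kd=ambiguity_kd, **kwargs)
    est.fit(sensorgrams)
    rmax = est.rmax_ if np.isscalar(est.rmax_) else float(np.mean(est.rmax_))
    return KineticFit(
        kon=est.kon_, koff=est.koff_, kd=est.kd_, rmax=rmax, r2=est.r2_, status=est.status_
    )


def sensorgrams_from_frame(df, t_switch: float) -> list[Sensorgram]:
    """Build sensorgrams from a tidy table (concentration_nM, time_s, response)."""
    required = {"concentration_nM", "time_s", "response"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"sensorgram table missing columns: {sorted(missing)}")
    out = []
    for conc, grp in df.groupby("concentration_nM"):
        grp = grp.sort_values("time_s")
        out.append(
            Sensorgram(
                concentration=float(conc),
                times=grp["time_s"].to_numpy(),
                responses=grp["response"].to_numpy(),
                t_switch=t_switch,
            )
        )
    return out


def sensorgrams_to_frame(sensorgrams: Sequence[Sensorgram]):
    """Inverse of :func:`sensorgrams_from_frame` (tidy CSV layout)."""
    import pandas as pd

    rows = []
    for sg in sensorgrams:
        for t, r in zip(sg.times, sg.responses):
            rows.append({"concentration_nM": sg.concentration, "time_s": t, "response": r})
    return pd.DataFrame(rows)
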