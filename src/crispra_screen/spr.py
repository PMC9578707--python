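"""Simulation and fitting of 1:1 Langmuir SPR sensorgrams.

The 1:1 interaction A + B <-> AB observed by surface plasmon resonance has a
closed-form response.  During association at analyte concentration C,

    R(t) = Req * (1 - exp(-(kon*C + koff) * t)),   Req = Rmax * C / (C + KD)

and during dissociation the response decays as R(t_a) * exp(-koff*(t-t_a)).
Kinetic fitting is global nonlinear least squares over all concentration
series simultaneously, with multi-start initialization in log-parameter
space and positivity enforced by the parameterization.  Steady-state
(equilibrium) analysis fits the binding hyperbola Req(C) = Rmax*C/(C+KD).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit, least_squares

__all__ = [
    "SensorgramTrace",
    "KineticsFit",
    "SteadyStateFit",
    "simulate_sensorgram",
    "langmuir_response",
    "LangmuirModel",
    "fit_kinetic",
    "fit_steady_state",
]


@dataclass
class SensorgramTrace:
    """One analyte-concentration series: response (RU) over time (s)."""

    time: np.ndarray
    response: np.ndarray
    concentration: float  # molar
    t_assoc: float  # association phase ends here
    t_dissoc: float  # dissociation phase ends here

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if self.concentration <= 0:
            raise ValueError("analyte concentration must be > 0")
        if not np.all(np.diff(self.time) > 0):
            raise ValueError("time must be strictly increasing")
        if not 0 < self.t_assoc < self.t_dissoc:
            raise ValueError("association must precede dissociation")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.time,
                "response": self.response,
                "concentration": self.concentration,
                "phase": np.where(self.time <= self.t_assoc, "association",
                                  "dissociation"),
            }
        )


def langmuir_response(
    t: np.ndarray, kon: float, koff: float, rmax: float, conc: float, t_assoc: float
) -> np.ndarray:
    """Noise-free 1:1 Langmuir response at times ``t``."""
    t = np.asarray(t, dtype=float)
    kd = koff / kon
    req = rmax * conc / (conc + kd)
    kobs = kon * conc + koff
    r_assoc = req * (1.0 - np.exp(-kobs * np.minimum(t, t_assoc)))
    r_end = req * (1.0 - np.exp(-kobs * t_assoc))
    r_dissoc = r_end * np.exp(-koff * (t - t_assoc))
    return np.where(t <= t_assoc, r_assoc, r_dissoc)


def simulate_sensorgram(
    kon: float,
    koff: float,
    rmax: float,
    concentrations: Sequence[float],
    t_assoc: float = 300.0,
    t_dissoc: float = 600.0,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
    n_points: int = 200,
) -> list[SensorgramTrace]:
    """Simulate one trace per analyte concentration with additive Gaussian
    noise of standard deviation ``noise_sd`` (RU)."""
    if min(kon, koff, rmax) <= 0:
        raise ValueError("kon, koff and Rmax must be positive")
    if rng is None:
        rng = np.random.default_rng()
    t = np.linspace(0.0, t_dissoc, n_points)[1:]  # drop t=0 baseline point
    traces = []
    for conc in concentrations:
        r = langmuir_response(t, kon, koff, rmax, conc, t_assoc)
        if noise_sd > 0:
            r = r + rng.normal(0.0, noise_sd, size=r.shape)
        traces.append(
            SensorgramTrace(
                time=t, response=r, concentration=float(conc),
                t_assoc=t_assoc, t_dissoc=t_dissoc,
            )
        )
    return traces


@dataclass
class KineticsFit:
    """Globally fitted 1:1 kinetic parameters."""

    kon: float  # 1/(M s)
    koff: float  # 1/s
    kd: float  # M
    rmax: float  # RU
    rss: float
    n_points: int
    converged: bool = True
    kon_identifiable: bool = True
    message: str = ""

    def summary(self) -> str:
        lines = [
            "1:1 Langmuir kinetic fit",
            f"  kon  = {self.kon:.4g} 1/(M s)"
            + ("" if self.kon_identifiable else "   [unidentifiable]"),
            f"  koff = {self.koff:.4g} 1/s",
            f"  KD   = {self.kd:.4g} M",
            f"  Rmax = {self.rmax:.4g} RU",
            f"  RSS  = {self.rss:.4g} over {self.n_points} points",
        ]
        if not self.converged:
            lines.append(f"  WARNING: {self.message}")
        return "\n".join(lines)


@dataclass
class SteadyStateFit:
    """Equilibrium fit of the binding hyperbola."""

    kd: float
    rmax: float
    kd_stderr: float
    rmax_stderr: float
    rss: float
    underdetermined: bool = False

    def summary(self) -> str:
        flag = "   [underdetermined: concentrations do not span KD]" if (
            self.underdetermined
        ) else ""
        return (
            "Steady-state (equilibrium) fit\n"
            f"  KD   = {self.kd:.4g} M (se {self.kd_stderr:.2g}){flag}\n"
            f"  Rmax = {self.rmax:.4g} RU (se {self.rmax_stderr:.2g})\n"
            f"  RSS  = {self.rss:.4g}"
        )


class LangmuirModel:
    """Global 1:1 Langmuir model over a set of sensorgram traces.

    ``fit`` performs multi-start nonlinear least squares (8 log-spaced KD
    starts spanning the concentration range) on (log kon, log koff,
    log Rmax), which keeps all parameters positive.
    """

    def __init__(self, traces: Sequence[SensorgramTrace]) -> None:
        if not traces:
            raise ValueError("need at least one trace")
        self.traces = list(traces)

    def _residuals(self, logp: np.ndarray) -> np.ndarray:
        kon, koff, rmax = np.exp(logp)
        res = []
        for tr in self.traces:
            model = langmuir_response(
                tr.time, kon, koff, rmax, tr.concentration, tr.t_assoc
            )
            res.append(tr.response - model)
        return np.concatenate(res)

    def _has_association_data(self) -> bool:
        return any(np.any(tr.time <= tr.t_assoc) for tr in self.traces)

    def _koff_guess(self) -> float:
        # log-linear decay rate of the dissociation tail of the largest trace
        tr = max(self.traces, key=lambda t: t.concentration)
        mask = tr.time > tr.t_assoc
        t, r = tr.time[mask], tr.response[mask]
        pos = r > max(r.max(), 1e-12) * 1e-3
        if pos.sum() >= 2:
            slope = np.polyfit(t[pos], np.log(r[pos]), 1)[0]
            if slope < 0:
                return -slope
        return 1e-2

    def fit(self, n_starts: int = 8) -> KineticsFit:
        if not self._has_association_data():
            return self._fit_dissociation_only()
        rmax0 = max(tr.response.max() for tr in self.traces)
        koff0 = self._koff_guess()
        concs = np.array([tr.concentration for tr in self.traces])
        kd_starts = np.exp(
            np.linspace(
                np.log(concs.min()) - 2.0, np.log(concs.max()) + 2.0, n_starts
            )
        )
        best = None
        n_points = sum(len(tr.time) for tr in self.traces)
        for kd0 in kd_starts:
            x0 = np.log([koff0 / kd0, koff0, max(rmax0, 1e-6)])
            sol = least_squares(
                self._residuals, x0, method="lm", xtol=1e-15, ftol=1e-15,
                gtol=1e-15, max_nfev=20_000,
            )
            if best is None or sol.cost < best.cost:
                best = sol
        kon, koff, rmax = np.exp(best.x)
        rss = float(2.0 * best.cost)
        return KineticsFit(
            kon=float(kon), koff=float(koff), kd=float(koff / kon),
            rmax=float(rmax), rss=rss, n_points=n_points,
            converged=bool(best.success), message=str(best.message),
        )

    def _fit_dissociation_only(self) -> KineticsFit:
        tr = self.traces[0]

        def resid(p):
            r0, koff = np.exp(p)
            return tr.response - r0 * np.exp(-koff * (tr.time - tr.t_assoc))

        r0_guess = max(tr.response.max(), 1e-9)
        sol = least_squares(
            resid, np.log([r0_guess, self._koff_guess()]), xtol=1e-15, ftol=1e-15
        )
        _, koff = np.exp(sol.x)
        return KineticsFit(
            kon=float("nan"), koff=float(koff), kd=float("nan"),
            rmax=float("nan"), rss=float(2.0 * sol.cost),
            n_points=len(tr.time), converged=bool(sol.success),
            kon_identifiable=False,
            message="dissociation-only data: kon/KD/Rmax unidentifiable",
        )


def fit_kinetic(traces: Sequence[SensorgramTrace], n_starts: int = 8) -> KineticsFit:
    """Convenience wrapper around :class:`LangmuirModel`."""
    return LangmuirModel(traces).fit(n_starts=n_starts)


def fit_steady_state(
    concentrations: Sequence[float], responses: Sequence[float]
) -> SteadyStateFit:
    """Least-squares fit of Req(C) = Rmax*C/(C + KD)."""
    c = np.asarray(concentrations, dtype=float)
    r = np.asarray(responses, dtype=float)
    if len(c) < 3:
        raise ValueError("need >= 3 concentrations for a steady-state fit")
    if np.any(c <= 0):
        raise ValueError("concentrations must be > 0")

    def hyperbola(cc, rmax, kd):
        return rmax * cc / (cc + kd)

    p0 = (max(r.max(), 1e-9) * 1.5, np.median(c))
    popt, pcov = curve_fit(
        hyperbola, c, r, p0=p0, bounds=([1e-12, 1e-18], [np.inf, np.inf]),
        maxfev=20_000,
    )
    rmax, kd = popt
    perr = np.sqrt(np.diag(pcov))
    rss = float(np.sum((r - hyperbola(c, *popt)) ** 2))
    # underdetermined when the series never approaches saturation or the
    # ridge between Rmax and KD leaves KD essentially unconstrained
    underdetermined = bool(
        c.max() < kd or (np.isfinite(perr[1]) and perr[1] >= kd)
    )
    return SteadyStateFit(
        kd=float(kd), rmax=float(rmax), kd_stderr=float(perr[1]),
        rmax_stderr=float(perr[0]), rss=rss, underdetermined=underdetermined,
    )
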