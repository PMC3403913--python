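"""Map simulated species onto the experimental measurables.

Western blots resolve the FVa heavy chain and its proteolytic fragments by
size; a fragment is detected whether it is still non-covalently associated
with the light chain or already dissociated, so each band observable sums
every species carrying that fragment.  Cofactor activity tracks the intact
heavy chain; prothrombinase activity additionally credits the partially
cleaved, still-associated cofactor forms with 20 % of full activity.
Empirical time courses are reported relative to their maximal value (RMV),
and initial rates come from monoexponential fits to the early time points.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import curve_fit

from .kinetics import TimeCourse
from .network import FRAGMENTS, SPECIES, SPECIES_FRAGMENTS, SPECIES_INDEX

__all__ = [
    "BANDS",
    "ObservableSeries",
    "ExpFit",
    "band_series",
    "cofactor_activity",
    "prothrombinase_activity",
    "normalize_rmv",
    "fit_monoexponential",
    "initial_rate",
    "EMPIRICAL_SAMPLE_TIMES",
]

#: Western-blot band identities.
BANDS: tuple[str, ...] = FRAGMENTS

#: The densitometry sampling grid used for initial-rate fits (seconds):
#: 0, 0.5, 1, 2, 3, 4 and 6 minutes.
EMPIRICAL_SAMPLE_TIMES: tuple[float, ...] = (0.0, 30.0, 60.0, 120.0, 180.0, 240.0, 360.0)

# species index lists per band, derived from the fragment content table
_BAND_MEMBERS: dict[str, list[tuple[int, int]]] = {band: [] for band in BANDS}
for _sp in SPECIES:
    for _band, _count in SPECIES_FRAGMENTS[_sp].items():
        _BAND_MEMBERS[_band].append((SPECIES_INDEX[_sp], _count))
del _sp, _band, _count

# Species with full cofactor activity vs. partial (20 %): partially cleaved
# forms count only while their heavy-chain fragments are still associated.
_INTACT_SPECIES = [
    SPECIES_INDEX[s] for s in SPECIES if "FVa" in s.split(":")
]
_PARTIAL_SPECIES = [
    SPECIES_INDEX[s]
    for s in SPECIES
    if any(core in s.split(":") for core in ("FVai506", "FVai306", "FVai306/506"))
]
PARTIAL_ACTIVITY_WEIGHT = 0.2


@dataclass(frozen=True)
class ObservableSeries:
    """A named analyte trace derived from a time course."""

    analyte: str
    times: np.ndarray
    values: np.ndarray
    normalized: bool = False
    units: str = "M"

    def value_at(self, t: float) -> float:
        i = int(np.argmin(np.abs(self.times - t)))
        if abs(self.times[i] - t) > 1e-9 + 1e-9 * abs(t):
            raise KeyError(f"time {t} s not on the sampled grid")
        return float(self.values[i])

    def peak_time(self) -> float:
        """Time of the maximum value over the sampled grid (seconds)."""
        return float(self.times[int(np.argmax(self.values))])

    def window(self, t_max: float) -> "ObservableSeries":
        mask = self.times <= t_max * (1 + 1e-12)
        return replace(self, times=self.times[mask], values=self.values[mask])


def band_series(tc: TimeCourse, band: str) -> ObservableSeries:
    """Total concentration of one electrophoretic band over time.

    Includes the fragment both associated with and dissociated from the
    light chain, e.g. the 1-506 band sums FVai506 and its APC-, FXa- and
    FXa·PT-bound complexes.
    """
    if band not in BANDS:
        raise KeyError(f"unknown band {band!r}; expected one of {BANDS}")
    values = np.zeros(len(tc.times))
    for idx, count in _BAND_MEMBERS[band]:
        values += count * tc.y[:, idx]
    return ObservableSeries(band, tc.times, values)


def cofactor_activity(tc: TimeCourse) -> ObservableSeries:
    """Cofactor activity: the cumulative intact heavy chain, relative to t = 0.

    Clotting-assay cofactor activity follows the amount of intact FVa heavy
    chain, so this is the HC band rescaled to its initial value.
    """
    hc = band_series(tc, "HC")
    if hc.values[0] <= 0:
        raise ValueError("no intact FVa at t = 0; cofactor activity undefined")
    return ObservableSeries(
        "cofactor_activity", hc.times, hc.values / hc.values[0], normalized=True,
        units="fraction of t=0",
    )


def prothrombinase_activity(tc: TimeCourse) -> ObservableSeries:
    """Potential prothrombinase activity supported by the cofactor pool.

    Sum of all intact-FVa species plus a 20 %-weighted sum of the partially
    cleaved species whose heavy-chain fragments remain associated
    (FVai506, FVai306, FVai306/506 and their complexes); the dissociated
    cofactor contributes nothing.  Reported relative to the total FVa
    light-chain pool so an all-intact state reads 1.0.
    """
    intact = tc.y[:, _INTACT_SPECIES].sum(axis=1)
    partial = tc.y[:, _PARTIAL_SPECIES].sum(axis=1)
    lc_total = sum(
        tc.y[0, SPECIES_INDEX[s]]
        for s in SPECIES
        if any(core in s.split(":") for core in
               ("FVa", "FVai506", "FVai306", "FVai306/506", "FVai"))
    )
    if lc_total <= 0:
        raise ValueError("no cofactor species at t = 0")
    values = (intact + PARTIAL_ACTIVITY_WEIGHT * partial) / lc_total
    return ObservableSeries(
        "prothrombinase_activity", tc.times, values, normalized=True,
        units="fraction of all-intact",
    )


def normalize_rmv(s: ObservableSeries) -> ObservableSeries:
    """Normalize a series to its maximal value over the sampled grid (RMV)."""
    peak = float(np.max(s.values))
    if peak <= 0:
        raise ValueError(f"cannot RMV-normalize all-zero series {s.analyte!r}")
    return replace(s, values=s.values / peak, normalized=True, units="RMV")


# ---------------------------------------------------------------------------
# Monoexponential initial-rate fits
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExpFit:
    """Result of fitting value(t) = amplitude·exp(−rate·t) (+ plateau)."""

    amplitude: float
    rate: float
    plateau: float
    residual: float
    used_plateau: bool

    @property
    def initial_slope(self) -> float:
        """|d value/dt| at t = 0 on the normalized scale (per second)."""
        return self.amplitude * self.rate


def _fit(times, values, with_plateau):
    if with_plateau:
        def model(t, a, k, c):
            return a * np.exp(-k * t) + c
        p0 = (values[0] - values[-1], 1e-2, values[-1])
        bounds = ([0.0, 0.0, 0.0], [np.inf, np.inf, np.inf])
    else:
        def model(t, a, k):
            return a * np.exp(-k * t)
        p0 = (values[0], 1e-2)
        bounds = ([0.0, 0.0], [np.inf, np.inf])
    popt, _ = curve_fit(model, times, values, p0=p0, bounds=bounds, maxfev=20000)
    resid = float(np.sum((model(times, *popt) - values) ** 2))
    return popt, resid


def fit_monoexponential(
    s: ObservableSeries,
    fit_window: float = 360.0,
    sample_times: Optional[Sequence[float]] = None,
) -> ExpFit:
    """Fit a monophasic exponential decay to an RMV-normalized series.

    The fit uses the empirical sampling grid (0–6 min) by default.  A
    plateau term is added only when it improves the residual decisively
    (F-ratio > 4), mirroring fits to "monophasic exponential decays" that
    do not state a baseline.
    """
    sub = s.window(fit_window)
    if sample_times is None:
        sample_times = [t for t in EMPIRICAL_SAMPLE_TIMES if t <= fit_window]
    times = np.asarray(
        [t for t in sample_times if t <= sub.times[-1] * (1 + 1e-12)], dtype=float
    )
    if len(times) < 3:
        raise ValueError("fit window covers fewer than 3 sample points")
    values = np.asarray([sub.value_at(t) for t in times])
    if not s.normalized:
        peak = float(np.max(values))
        if peak <= 0:
            raise ValueError("cannot normalize an all-zero trace for fitting")
        values = values / peak

    try:
        (a, k), res0 = _fit(times, values, with_plateau=False)
        plateau_fit = None
        if res0 > 0:
            try:
                (ap, kp, cp), res1 = _fit(times, values, with_plateau=True)
                dof0, dof1 = len(times) - 2, len(times) - 3
                if dof1 > 0 and res1 > 0:
                    f_ratio = ((res0 - res1) / 1) / (res1 / dof1)
                    if f_ratio > 4.0:
                        plateau_fit = (ap, kp, cp, res1)
            except RuntimeError:
                pass
        if plateau_fit is not None:
            ap, kp, cp, res1 = plateau_fit
            return ExpFit(float(ap), float(kp), float(cp), res1, True)
        return ExpFit(float(a), float(k), 0.0, res0, False)
    except RuntimeError as exc:
        raise RuntimeError(
            f"monoexponential fit failed to converge for {s.analyte!r}: {exc}"
        ) from exc


def initial_rate(
    s: ObservableSeries,
    starting_conc: float,
    fit_window: float = 360.0,
    sample_times: Optional[Sequence[float]] = None,
) -> float:
    """Initial disappearance rate in pM/s from a monoexponential fit.

    The trace is normalized to its maximum, fitted as A·exp(−k·t), and the
    initial slope A·k rescaled by the starting concentration (molar).
    """
    fit = fit_monoexponential(s, fit_window=fit_window, sample_times=sample_times)
    return fit.initial_slope * starting_conc * 1e12
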