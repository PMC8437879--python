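"""Dose-response analysis for MST (and ELONA-style) titrations.

Microscale thermophoresis reports a normalized fluorescence Fnorm in
per-mille units for each step of a target titration. To compare curves the
per-point Fnorm is shifted by the baseline response (by default the mean
Fnorm at the lowest target concentration), giving dFnorm. A hyperbolic
saturation curve

    dF(c) = A * c / (m + c)

is then least-squares fitted to summarize amplitude ``A`` and the response
midpoint ``m`` — the concentration at half amplitude. The midpoint is a
descriptive curve parameter, NOT an equilibrium dissociation constant: with
whole cells as the titrant a Kd is not identifiable. Amplitude may be
negative (the sign of a thermophoretic response is assay-dependent).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit


def serial_dilution(top: float, steps: int = 16, ratio: float = 2.0) -> np.ndarray:
    """Descending 1:ratio dilution series, e.g. 16 steps 1:1 from 2e7/mL."""
    if steps < 2 or top <= 0 or ratio <= 1:
        raise ValueError("need steps >= 2, top > 0, ratio > 1")
    return top / ratio ** np.arange(steps)


@dataclass(frozen=True)
class Titration:
    """A titration of target concentration against normalized fluorescence.

    ``fnorm`` has shape (n_points, n_replicates); replicate counts must be
    equal across concentration points. Points may be supplied in any order
    and are stored sorted by ascending concentration.
    """

    concentrations: np.ndarray
    fnorm: np.ndarray

    def __post_init__(self) -> None:
        conc = np.asarray(self.concentrations, dtype=float)
        fn = np.atleast_2d(np.asarray(self.fnorm, dtype=float))
        if conc.ndim != 1 or conc.size < 2:
            raise ValueError("need a 1-D concentration series with >= 2 points")
        if np.any(conc <= 0):
            raise ValueError("concentrations must be strictly positive")
        if np.unique(conc).size != conc.size:
            raise ValueError("concentrations must be distinct")
        if fn.shape[0] != conc.size:
            raise ValueError(
                f"fnorm rows ({fn.shape[0]}) != concentration points ({conc.size})"
            )
        order = np.argsort(conc)
        object.__setattr__(self, "concentrations", conc[order])
        object.__setattr__(self, "fnorm", fn[order])

    @classmethod
    def from_tidy(cls, table: pd.DataFrame) -> "Titration":
        """Build from a tidy table with columns concentration, replicate, fnorm."""
        wide = table.pivot(index="concentration", columns="replicate", values="fnorm")
        if wide.isna().any().any():
            raise ValueError("unequal replicate counts across concentration points")
        return cls(concentrations=wide.index.to_numpy(), fnorm=wide.to_numpy())

    @property
    def mean_fnorm(self) -> np.ndarray:
        return self.fnorm.mean(axis=1)


def delta_fnorm(
    titration: Titration, baseline: Optional[float] = None
) -> np.ndarray:
    """Baseline-subtracted response per concentration point (per-mille).

    The baseline defaults to the replicate-mean Fnorm at the lowest
    concentration; pass an explicit value (e.g. from a target-free control
    well) to override. By construction the lowest point maps to 0 under the
    default.
    """
    means = titration.mean_fnorm
    if baseline is None:
        baseline = float(means[0])
    return means - baseline


@dataclass(frozen=True)
class DoseResponseCurve:
    """Summary of a fitted saturation curve.

    ``flag`` is ``None`` for a clean binding fit, ``"non_binding"`` when the
    fitted amplitude is indistinguishable from residual noise, and
    ``"fit_failed"`` when the optimizer did not converge (raw dFnorm values
    are still carried).
    """

    concentrations: np.ndarray
    delta_fnorm: np.ndarray
    amplitude: Optional[float] = None
    midpoint: Optional[float] = None
    signal_to_noise: Optional[float] = None
    residual_sd: Optional[float] = None
    flag: Optional[str] = None

    @property
    def converged(self) -> bool:
        return self.flag != "fit_failed"

    def to_dict(self) -> dict:
        return {
            "amplitude": self.amplitude,
            "midpoint": self.midpoint,
            "signal_to_noise": self.signal_to_noise,
            "residual_sd": self.residual_sd,
            "flag": self.flag,
            "n_points": int(self.concentrations.size),
        }


def _hyperbola(c: np.ndarray, amplitude: float, midpoint: float) -> np.ndarray:
    return amplitude * c / (midpoint + c)


def fit_saturation(
    titration: Titration, baseline: Optional[float] = None
) -> DoseResponseCurve:
    """Least-squares fit of ``dF = A*c/(m+c)`` to a titration.

    Initial values come from the data (terminal response for A, median
    concentration for m); a negative terminal response seeds a negative
    amplitude. Signal-to-noise is |A| / residual standard deviation
    (infinite for an exact fit).
    """
    conc = titration.concentrations
    if conc.size < 4:
        raise ValueError("saturation fit needs >= 4 concentration points")
    dfn = delta_fnorm(titration, baseline=baseline)
    if np.ptp(dfn) == 0:
        # flat response: nothing to fit, no binding signal
        return DoseResponseCurve(
            concentrations=conc,
            delta_fnorm=dfn,
            amplitude=0.0,
            midpoint=None,
            signal_to_noise=0.0,
            residual_sd=float(np.std(dfn)),
            flag="non_binding",
        )
    p0 = (dfn[-1] if dfn[-1] != 0 else 1.0, float(np.median(conc)))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            popt, _ = curve_fit(
                _hyperbola, conc, dfn, p0=p0, maxfev=20_000, xtol=1e-14, ftol=1e-14
            )
    except RuntimeError:
        return DoseResponseCurve(
            concentrations=conc, delta_fnorm=dfn, flag="fit_failed"
        )
    amplitude, midpoint = float(popt[0]), float(popt[1])
    residuals = dfn - _hyperbola(conc, amplitude, midpoint)
    dof = max(conc.size - 2, 1)
    resid_sd = float(np.sqrt(residuals @ residuals / dof))
    if resid_sd > 0:
        snr = abs(amplitude) / resid_sd
    else:
        snr = float("inf") if amplitude != 0 else 0.0
    # amplitude below ~3x residual noise: no resolvable binding signal
    flag = None
    if abs(amplitude) <= 3 * resid_sd or amplitude == 0:
        flag = "non_binding"
    return DoseResponseCurve(
        concentrations=conc,
        delta_fnorm=dfn,
        amplitude=amplitude,
        midpoint=midpoint,
        signal_to_noise=snr,
        residual_sd=resid_sd,
        flag=flag,
    )


def curve_table(curve: DoseResponseCurve) -> pd.DataFrame:
    """Per-point TSV-ready table of concentration vs dFnorm."""
    return pd.DataFrame(
        {"concentration": curve.concentrations, "delta_fnorm": curve.delta_fnorm}
    )
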