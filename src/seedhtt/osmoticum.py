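"""PEG-6000 osmotic calibration after Michel & Kaufmann (1973).

Polyethylene glycol 6000 dissolved in distilled water imposes a defined
negative water potential without entering seeds. The empirical calibration is
a polynomial in concentration C (g PEG per litre of water) and temperature T:

    Ψ [bar] = −1.18·10⁻² C − 1.18·10⁻⁴ C² + 2.67·10⁻⁴ C T + 8.39·10⁻⁷ C² T

reported in bars; 1 MPa = 10 bar. The forward direction evaluates the
polynomial; the inverse (the concentration needed for a target potential at a
given incubation temperature) is obtained by bracketed root-finding, which is
how germination-trial recipes such as the usual Ψ × T concentration tables
are produced.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .errors import ConvergenceError, DataError

# polynomial coefficients, bar scale, C in g/L of water
_C1 = -1.18e-2
_C2 = -1.18e-4
_C3 = 2.67e-4
_C4 = 8.39e-7

#: upper root bracket (g/L); the design range tops out near 400 g/L
MAX_CONCENTRATION = 600.0


def potential_from_concentration(concentration, temperature):
    """Water potential (MPa) of a PEG-6000 solution of C g/L at T °C.

    Vectorized over both arguments. Raises on negative concentrations.
    """
    c = np.asarray(concentration, dtype=float)
    t = np.asarray(temperature, dtype=float)
    if np.any(c < 0):
        raise DataError("PEG concentration must be >= 0 g/L")
    bar = _C1 * c + _C2 * c**2 + _C3 * c * t + _C4 * c**2 * t
    out = bar / 10.0  # bar -> MPa
    return float(out) if out.ndim == 0 else out


def concentration_for_potential(psi: float, temperature: float) -> float:
    """PEG-6000 concentration (g/L) producing water potential ``psi`` at T °C.

    The unique non-negative root of the calibration polynomial, bracketed on
    [0, 600] g/L and solved to |ΔΨ| < 1e-9 MPa. Positive targets are a domain
    error; a target outside the bracket raises rather than extrapolates.
    """
    if psi > 0:
        raise DataError(f"water potential must be <= 0 MPa, got {psi}")
    if psi == 0:
        return 0.0

    def f(c: float) -> float:
        return potential_from_concentration(c, temperature) - psi

    lo, hi = 0.0, MAX_CONCENTRATION
    if f(hi) > 0:
        raise ConvergenceError(
            f"no PEG-6000 concentration <= {MAX_CONCENTRATION} g/L reaches "
            f"{psi} MPa at {temperature} °C"
        )
    return float(brentq(f, lo, hi, xtol=1e-10, rtol=8.9e-16))


def peg_table(psis, temps) -> pd.DataFrame:
    """Concentration grid (g/L): rows = temperatures (°C), columns = Ψ (MPa)."""
    psis = list(psis)
    temps = list(temps)
    if any(p > 0 for p in psis):
        raise DataError("all target water potentials must be <= 0 MPa")
    data = [
        [concentration_for_potential(p, t) for p in psis] for t in temps
    ]
    df = pd.DataFrame(data, index=pd.Index(temps, name="temperature_C"), columns=psis)
    df.columns.name = "water_potential_MPa"
    return df
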