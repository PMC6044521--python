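"""Henderson–Hasselbalch ionization of a weak base.

Trimethoprim (pKa ≈ 7.4) is a weak base whose protonated (ionized) fraction
rises as the medium becomes more acidic; the non-ionized remainder is the
membrane-permeant species. The percent ionized at a given pH is

    %ionized = 100 · 10^(pKa − pH) / (1 + 10^(pKa − pH))

which is strictly decreasing in pH and equals 50% at pH = pKa.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

TRIMETHOPRIM_PKA = 7.4


def percent_ionized(pKa: float, pH: float) -> float:
    """Percent of a weak base in the ionized (protonated) form.

    Computed via the numerically safe logistic form
    ``100 / (1 + 10^(pH − pKa))``, exact for all finite inputs (no overflow
    for large |pKa − pH|). The non-ionized complement is ``100 − result``.
    """
    pKa = float(pKa)
    pH = float(pH)
    if not (math.isfinite(pKa) and math.isfinite(pH)):
        raise ValueError("pKa and pH must be finite")
    x = (pH - pKa) * math.log(10.0)
    if x > 0:  # avoid overflow of e^x for strongly basic media
        e = math.exp(-x)
        return 100.0 * e / (1.0 + e)
    return 100.0 / (1.0 + math.exp(x))


def percent_non_ionized(pKa: float, pH: float) -> float:
    return 100.0 - percent_ionized(pKa, pH)


def ionization_table(pKa: float = TRIMETHOPRIM_PKA, pH_values=(5.0, 7.0, 9.0)) -> pd.DataFrame:
    """Tabulate percent ionized / non-ionized over a set of pH values."""
    pH_values = np.asarray(pH_values, dtype=float)
    ion = np.array([percent_ionized(pKa, p) for p in pH_values])
    return pd.DataFrame(
        {"pH": pH_values, "percent_ionized": ion, "percent_non_ionized": 100.0 - ion}
    )


def format_percent(x: float) -> str:
    """Display helper: one decimal place, the precision used in reports."""
    return f"{x:.1f}"
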