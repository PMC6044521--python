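"""FT-IR spectral cleanup: CO₂-band excision, EMSC scatter correction,
autoscaling.

The pipeline order is fixed: ``remove_co2`` → ``emsc_fit_correct`` →
``autoscale``. CO₂ channels are deleted outright (never interpolated) so the
atmospheric artifact cannot leak into downstream models; EMSC then removes
per-spectrum additive offset, multiplicative path-length scatter and a
polynomial baseline against a reference spectrum; autoscaling standardises
every retained channel to zero mean / unit (n−1) standard deviation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import SpectraMatrix

logger = logging.getLogger(__name__)

#: Excision window bracketing the atmospheric CO₂ asymmetric-stretch band
#: near 2350 cm⁻¹.
DEFAULT_CO2_WINDOW = (2275.0, 2400.0)


def remove_co2(s: SpectraMatrix, window=DEFAULT_CO2_WINDOW) -> SpectraMatrix:
    """Delete every channel whose wavenumber lies in ``[low, high]`` cm⁻¹.

    Channels outside the window are untouched (bit-identical). A window that
    covers no channel is the identity; a window that would delete everything
    is an error.
    """
    low, high = float(window[0]), float(window[1])
    if low > high:
        raise ValueError("window must be (low, high) with low <= high")
    wn = s.wavenumbers
    if high < wn.min() or low > wn.max():
        raise ValueError(
            f"CO2 window [{low}, {high}] outside spectral range "
            f"[{wn.min()}, {wn.max()}]"
        )
    keep = (wn < low) | (wn > high)
    if not keep.any():
        raise ValueError("CO2 window would remove every channel")
    return s.select_channels(keep)


@dataclass
class EMSCParams:
    """EMSC configuration and per-spectrum fitted coefficients.

    The model fitted to each spectrum x over the (rescaled) axis λ̃ ∈ [−1, 1]
    is ``x ≈ a·1 + b·m + Σ_{j=1..p} d_j λ̃^j`` with m the reference spectrum;
    the corrected spectrum is ``(x − a·1 − Σ d_j λ̃^j) / b``. The constant
    baseline term is ``a`` itself (a separate d_0 would be collinear).
    """

    reference: np.ndarray | None = None
    poly_order: int = 2
    b_tol: float = 1e-8
    coefficients: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self):
        if self.poly_order < 0:
            raise ValueError("poly_order must be >= 0")


def _emsc_design(wavenumbers: np.ndarray, reference: np.ndarray, poly_order: int) -> np.ndarray:
    lam = wavenumbers.astype(float)
    # rescale axis to [-1, 1] for a well-conditioned polynomial basis
    t = 2.0 * (lam - lam.min()) / (lam.max() - lam.min()) - 1.0
    cols = [np.ones_like(t), reference]
    for j in range(1, poly_order + 1):
        cols.append(t**j)
    return np.column_stack(cols)


def emsc_fit_correct(
    s: SpectraMatrix, params: EMSCParams | None = None
) -> tuple[SpectraMatrix, EMSCParams]:
    """Fit EMSC to every spectrum by ordinary least squares and correct it.

    The reference defaults to the mean spectrum of the input set (the usual
    choice when no external target is available; supply ``params.reference``
    to reuse a training-set reference on held-out spectra). A fitted
    multiplicative coefficient with ``|b| < b_tol`` marks that spectrum as
    failed (``ok=False`` in the coefficient table) and the spectrum is
    passed through uncorrected rather than divided by a near-zero b.
    """
    if s.n_samples < 1:
        raise ValueError("need at least one spectrum")
    params = params or EMSCParams()
    m = params.reference
    if m is None:
        m = s.intensities.mean(axis=0)
    m = np.asarray(m, dtype=float)
    if m.shape != (s.n_channels,):
        raise ValueError("reference length does not match channel count")

    D = _emsc_design(s.wavenumbers, m, params.poly_order)
    # one least-squares solve for all spectra at once
    coef, *_ = np.linalg.lstsq(D, s.intensities.T, rcond=None)
    coef = coef.T  # [n_samples, 2 + poly_order]
    a = coef[:, 0]
    b = coef[:, 1]
    d = coef[:, 2:]
    baseline = a[:, None] + d @ D[:, 2:].T  # additive part, no reference term
    ok = np.abs(b) >= params.b_tol
    corrected = s.intensities.copy()
    safe_b = np.where(ok, b, 1.0)
    corrected = (s.intensities - baseline) / safe_b[:, None]
    corrected[~ok] = s.intensities[~ok]
    if not ok.all():
        bad = [sid for sid, o in zip(s.sample_ids, ok) if not o]
        logger.warning("EMSC fit failed (|b| < %g) for spectra: %s", params.b_tol, bad)

    cols = {"a": a, "b": b}
    for j in range(d.shape[1]):
        cols[f"d{j + 1}"] = d[:, j]
    cols["ok"] = ok
    table = pd.DataFrame(cols, index=pd.Index(s.sample_ids, name="sample_id"))
    fitted = EMSCParams(
        reference=m, poly_order=params.poly_order, b_tol=params.b_tol, coefficients=table
    )
    out = SpectraMatrix(s.wavenumbers.copy(), corrected, list(s.sample_ids))
    return out, fitted


@dataclass
class ScalingModel:
    """Column standardisation (autoscaling) learned on a training matrix.

    Constant columns (sd = 0) are dropped and recorded, never divided by.
    """

    means: np.ndarray
    sds: np.ndarray
    keep: np.ndarray  # boolean mask over original columns
    dropped: list = field(default_factory=list)

    @property
    def n_kept(self) -> int:
        return int(self.keep.sum())


def autoscale_fit(X: np.ndarray, column_names=None) -> ScalingModel:
    """Learn per-column mean and (n−1) standard deviation.

    Requires ≥2 rows (the sample sd is undefined for one row).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D")
    if X.shape[0] < 2:
        raise ValueError("autoscaling needs at least 2 rows")
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    keep = sds > 0
    names = list(column_names) if column_names is not None else list(range(X.shape[1]))
    dropped = [names[j] for j in np.flatnonzero(~keep)]
    if dropped:
        logger.info("autoscale: dropping %d constant columns: %s", len(dropped), dropped[:10])
    return ScalingModel(means=means, sds=sds, keep=keep, dropped=dropped)


def autoscale_apply(X: np.ndarray, model: ScalingModel) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.shape[1] != model.means.shape[0]:
        raise ValueError("column count does not match fitted model")
    Z = (X[:, model.keep] - model.means[model.keep]) / model.sds[model.keep]
    return Z


def autoscale(X: np.ndarray, column_names=None) -> tuple[np.ndarray, ScalingModel]:
    """Fit-and-apply convenience wrapper."""
    model = autoscale_fit(X, column_names)
    return autoscale_apply(X, model), model


def preprocess_spectra(
    s: SpectraMatrix,
    co2_window=DEFAULT_CO2_WINDOW,
    poly_order: int = 2,
    reference: np.ndarray | None = None,
):
    """Full FT-IR chain: CO₂ excision → EMSC → autoscale.

    Returns ``(Z, info)`` where Z is the autoscaled matrix and ``info``
    carries the corrected spectra, fitted EMSC coefficients, the scaling
    model and the retained wavenumbers.
    """
    cut = remove_co2(s, co2_window)
    corrected, emsc = emsc_fit_correct(cut, EMSCParams(reference=reference, poly_order=poly_order))
    Z, scaler = autoscale(corrected.intensities, column_names=list(corrected.wavenumbers))
    info = {
        "corrected": corrected,
        "emsc": emsc,
        "scaler": scaler,
        "wavenumbers": corrected.wavenumbers[scaler.keep],
    }
    return Z, info
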