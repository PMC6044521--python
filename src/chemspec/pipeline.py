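"""End-to-end convenience chain for the FT-IR arm of the workflow:
preprocess → PCA → PC-DFA → per-pH CPCA blocks."""

from __future__ import annotations

import numpy as np

from .chemometrics import N_PCS_FTIR, fit_cpca, fit_pc_dfa, fit_pca
from .io import SampleDesign, SpectraMatrix
from .preprocess import DEFAULT_CO2_WINDOW, preprocess_spectra


def spectral_pipeline(
    spectra: SpectraMatrix,
    design: SampleDesign,
    co2_window=DEFAULT_CO2_WINDOW,
    poly_order: int = 2,
    n_pcs: int = N_PCS_FTIR,
    cpca_components: int = 2,
) -> dict:
    """Run the fixed preprocessing order and the three multivariate views.

    Returns a dict with the autoscaled matrix ``Z``, class labels aligned to
    its rows, the fitted ``pca`` and ``dfa`` models, and a sample-blocked
    ``cpca`` whose blocks are the pH subgroups (per-sample block coordinates
    expose the within-pH dose trajectories).
    """
    labels = design.labels()
    Z, info = preprocess_spectra(spectra, co2_window=co2_window, poly_order=poly_order)
    y = np.asarray([labels[s] for s in spectra.sample_ids])

    pca = fit_pca(Z, k=min(n_pcs, Z.shape[0] - 1, Z.shape[1]))
    dfa = fit_pc_dfa(Z, y, n_pcs=min(n_pcs, Z.shape[0] - 1, Z.shape[1]))

    t = design.table
    blocks = {}
    for pH in sorted(set(t.loc[t["role"] == "sample", "pH"])):
        rows = np.flatnonzero((t["pH"] == pH).to_numpy() & (t["role"] == "sample").to_numpy())
        blocks[f"pH{pH}"] = rows
    cpca = fit_cpca(Z, blocks, k=cpca_components, mode="samples")

    return {"Z": Z, "labels": y, "info": info, "pca": pca, "dfa": dfa, "cpca": cpca}
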