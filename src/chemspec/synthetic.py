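"""Seeded generators for spectra, peak tables, growth curves and calibration
standards with the statistical structure the downstream analysis assumes.

The emulated experiment is an 8-condition design — pH ∈ {5, 7} crossed with
antibiotic dose ∈ {0, 0.003, 0.03, 0.2} mg L⁻¹ — with six biological
replicates per condition and, for spectra, three technical replicates each.
The generators encode the qualitative structure the real study exhibits:

* the pH level shifts a fixed set of absorbance bands with very little
  within-class variance, so a supervised model splits pH on DF1;
* the dose response is a different band pattern whose amplitude grows
  monotonically with dose, is strongest at pH 7 (where the weak-base drug is
  least ionized and most membrane-permeant) and carries most of the
  biological between-replicate heterogeneity, so unsupervised PC1 isolates
  the (pH 7, 0.2 mg L⁻¹) class;
* spectra carry multiplicative/additive scatter, a polynomial baseline and a
  CO₂ band near 2350 cm⁻¹ — exactly the distortion class the preprocessing
  chain removes;
* metabolite peak areas are log-normal with signed dose effects whose
  directions follow the study's key metabolites (trehalose up / sugars and
  nucleotides down at pH 7, etc.), biological dispersion well above the
  pooled-QC dispersion.

Every generator is a pure function of (config, seed): identical inputs give
bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .growth import GrowthCurve
from .io import PeakTable, SampleDesign, SpectraMatrix, class_label

__all__ = [
    "SpectraSimConfig",
    "PeakSimConfig",
    "GrowthSimConfig",
    "default_design",
    "class_template",
    "simulate_spectra",
    "simulate_peak_table",
    "simulate_growth",
    "simulate_calibration",
    "load_effect_directions",
]

PH_LEVELS = (5, 7)
DOSES = (0.0, 0.003, 0.03, 0.2)
#: Monotone dose-response weight g(dose) in [0, 1] (fraction of the
#: top-dose effect realised at each dose level).
DOSE_RESPONSE = {0.0: 0.0, 0.003: 0.1, 0.03: 0.3, 0.2: 1.0}


def default_design(
    pH_levels=PH_LEVELS,
    doses=DOSES,
    n_bio: int = 6,
    n_tech: int = 3,
    n_qc: int = 0,
) -> SampleDesign:
    """The balanced condition grid: every (pH, dose) with ``n_bio``
    biological × ``n_tech`` technical replicates, plus optional pooled-QC
    rows (used for GC-MS runs, where ``n_tech=1`` is the convention)."""
    rows = []
    for pH in pH_levels:
        for dose in doses:
            for b in range(1, n_bio + 1):
                for t in range(1, n_tech + 1):
                    rows.append(
                        {
                            "sample_id": f"pH{pH}_d{dose:g}_b{b}_t{t}",
                            "pH": pH,
                            "dose": dose,
                            "bio_rep": b,
                            "tech_rep": t,
                            "role": "sample",
                        }
                    )
    for q in range(1, n_qc + 1):
        rows.append(
            {
                "sample_id": f"QC_{q}",
                "pH": pH_levels[0],
                "dose": 0.0,
                "bio_rep": q,
                "tech_rep": 1,
                "role": "QC",
            }
        )
    return SampleDesign(pd.DataFrame(rows), dose_set=tuple(doses))


# ---------------------------------------------------------------------------
# FT-IR spectra

#: Band centres (cm⁻¹) loosely following dried-biomass FT-IR features
#: (CH stretches, ester carbonyl, amides I/II, mixed region, phosphates /
#: polysaccharides).
_BAND_CENTERS = np.array(
    [2960.0, 2925.0, 2870.0, 2850.0, 1740.0, 1655.0, 1545.0, 1455.0, 1400.0, 1240.0, 1080.0, 970.0]
)
_BAND_WIDTHS = np.array([15.0, 15.0, 15.0, 15.0, 12.0, 20.0, 18.0, 14.0, 14.0, 18.0, 25.0, 20.0])
_BAND_HEIGHTS = np.array([0.35, 0.5, 0.3, 0.4, 0.25, 1.0, 0.7, 0.45, 0.4, 0.5, 0.8, 0.3])

#: Band-height shift applied to pH 5 cultures (pH 7 is the reference state).
_PH_EFFECT = np.array([0.0, 0.0, 0.0, 0.05, 0.0, 0.0, 0.08, 0.0, -0.06, 0.0, 0.0, 0.07])
#: Band-height shift at the full (pH 7, 0.2 mg L⁻¹) drug response; scaled by
#: g(dose)·susceptibility(pH) elsewhere. Deliberately disjoint from the pH
#: bands so the two factors are separable directions.
_DOSE_EFFECT = np.array([-0.10, -0.08, 0.0, 0.0, 0.06, -0.12, 0.0, 0.08, 0.0, 0.10, -0.14, 0.0])


@dataclass
class SpectraSimConfig:
    """Generative model for 8-condition FT-IR spectra.

    A clean spectrum is a sum of Gaussian absorbance bands whose heights
    carry the class effects; the recorded spectrum is
    ``a + b·clean + poly(λ̃) + CO₂ band + white noise`` with b log-normal —
    the multiplicative/additive scatter family EMSC is built to remove.
    """

    band_centers: np.ndarray = field(default_factory=lambda: _BAND_CENTERS.copy())
    band_widths: np.ndarray = field(default_factory=lambda: _BAND_WIDTHS.copy())
    band_heights: np.ndarray = field(default_factory=lambda: _BAND_HEIGHTS.copy())
    ph_effect: np.ndarray = field(default_factory=lambda: _PH_EFFECT.copy())
    dose_effect: np.ndarray = field(default_factory=lambda: _DOSE_EFFECT.copy())
    dose_response: dict = field(default_factory=lambda: dict(DOSE_RESPONSE))
    #: drug susceptibility multiplier per pH; the drug is mostly ionized at
    #: pH 5, so the realised dose effect there is a fraction of the pH 7 one
    susceptibility: dict = field(default_factory=lambda: {5: 0.35, 7: 1.0})
    #: per-biological-replicate multiplicative heterogeneity of the dose
    #: response (the dominant within-class variance, riding the dose axis)
    resp_het_sd: float = 0.2
    bio_sd: float = 0.006
    tech_sd: float = 0.004
    scatter_mult_sd: float = 0.08   # σ of log b
    scatter_add_sd: float = 0.02    # σ of additive offset a
    baseline_sd: float = 0.01       # σ of quadratic baseline coefficients
    co2_center: float = 2350.0
    co2_width: float = 12.0
    co2_height: float = 0.15
    co2_height_sd: float = 0.05
    noise_sd: float = 0.002
    wn_max: float = 4000.0
    wn_min: float = 600.0
    wn_step: float = 4.0
    seed: int = 0

    def __post_init__(self):
        for name in ("resp_het_sd", "bio_sd", "tech_sd", "scatter_mult_sd",
                     "scatter_add_sd", "baseline_sd", "co2_height_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        g = [self.dose_response[d] for d in sorted(self.dose_response)]
        if not all(b > a for a, b in zip(g, g[1:])):
            raise ValueError("dose_response must be strictly increasing in dose")

    @property
    def wavenumbers(self) -> np.ndarray:
        return np.arange(self.wn_max, self.wn_min - self.wn_step / 2, -self.wn_step)


def _bands(wn: np.ndarray, centers, widths) -> np.ndarray:
    """Gaussian band shapes, one row per band."""
    return np.exp(-0.5 * ((wn[None, :] - np.asarray(centers)[:, None]) / np.asarray(widths)[:, None]) ** 2)


def _class_heights(cfg: SpectraSimConfig, pH, dose) -> np.ndarray:
    g = cfg.dose_response[float(dose)]
    s = cfg.susceptibility[int(pH)]
    h = cfg.band_heights.copy()
    if int(pH) == 5:
        h = h + cfg.ph_effect
    return h + g * s * cfg.dose_effect


def class_template(cfg: SpectraSimConfig, pH, dose) -> np.ndarray:
    """Noiseless, scatter-free class spectrum (the generator's ground truth)."""
    wn = cfg.wavenumbers
    G = _bands(wn, cfg.band_centers, cfg.band_widths)
    return _class_heights(cfg, pH, dose) @ G


def simulate_spectra(
    cfg: SpectraSimConfig, design: SampleDesign, return_clean: bool = False
):
    """One spectrum per design row; deterministic under (cfg, design).

    QC rows (if any) are generated from the grand-mean class template. With
    ``return_clean=True`` additionally returns the per-sample clean spectra
    (class template + replicate effects, before scatter/baseline/noise) —
    the target the preprocessing chain should recover.
    """
    if design.table.empty:
        raise ValueError("empty design")
    rng = np.random.default_rng(cfg.seed)
    wn = cfg.wavenumbers
    G = _bands(wn, cfg.band_centers, cfg.band_widths)
    co2 = np.exp(-0.5 * ((wn - cfg.co2_center) / cfg.co2_width) ** 2)
    lam = 2.0 * (wn - wn.min()) / (wn.max() - wn.min()) - 1.0
    poly_basis = np.vstack([lam, lam**2])

    classes = sorted({class_label(p, d) for p, d in
                      zip(design.samples()["pH"], design.samples()["dose"])})
    grand = np.mean(
        [_class_heights(cfg, p, d)
         for p in sorted(set(design.samples()["pH"]))
         for d in sorted(set(design.samples()["dose"]))],
        axis=0,
    )

    bio_state: dict = {}
    clean_rows = np.empty((len(design.table), len(wn)))
    raw_rows = np.empty_like(clean_rows)
    n_bands = len(cfg.band_heights)
    for i, row in enumerate(design.table.itertuples(index=False)):
        if row.role == "QC":
            heights = grand.copy()
            base_heights = grand
            dose_part = np.zeros(n_bands)
        else:
            base_heights = _class_heights(cfg, row.pH, row.dose)
            g = cfg.dose_response[float(row.dose)]
            s = cfg.susceptibility[int(row.pH)]
            dose_part = g * s * cfg.dose_effect
            key = (class_label(row.pH, row.dose), row.bio_rep)
            if key not in bio_state:
                bio_state[key] = (
                    rng.normal(0.0, cfg.resp_het_sd),
                    rng.normal(0.0, cfg.bio_sd, size=n_bands),
                )
            het, bio_noise = bio_state[key]
            heights = base_heights + het * dose_part + bio_noise
        heights = heights + rng.normal(0.0, cfg.tech_sd, size=n_bands)
        clean = heights @ G
        b = float(np.exp(rng.normal(0.0, cfg.scatter_mult_sd)))
        a = float(rng.normal(0.0, cfg.scatter_add_sd))
        baseline = rng.normal(0.0, cfg.baseline_sd, size=2) @ poly_basis
        co2_h = max(0.0, rng.normal(cfg.co2_height, cfg.co2_height_sd))
        raw = a + b * clean + baseline + co2_h * co2 + rng.normal(
            0.0, cfg.noise_sd, size=len(wn)
        )
        clean_rows[i] = clean
        raw_rows[i] = raw

    ids = design.sample_ids
    out = SpectraMatrix(wn.copy(), raw_rows, ids)
    if return_clean:
        return out, SpectraMatrix(wn.copy(), clean_rows, ids)
    return out


# ---------------------------------------------------------------------------
# GC-MS peak tables

def load_effect_directions() -> pd.DataFrame:
    """Signed log-fold effect table for the study's key metabolites.

    Columns ``effect_pH5`` / ``effect_pH7`` give the log-scale shift at the
    top dose (0.2 mg L⁻¹) relative to the same-pH control; intermediate
    doses are scaled by the monotone dose-response weight. Signs follow the
    reported biology (osmoprotectant trehalose up and sugars/nucleotides
    down where the drug is most active at pH 7; amino acids up at pH 5).
    """
    with resources.files("chemspec.data").joinpath(
        "metabolite_effect_directions.csv"
    ).open() as fh:
        return pd.read_csv(fh)


@dataclass
class PeakSimConfig:
    """Generative model for GC-MS peak tables (log-normal abundances).

    Feature counts per MSI identification level default to the study
    composition 43 / 20 / 4 / 92 (159 features). ``sample_rsd`` and
    ``qc_rsd`` are log-scale standard deviations (≈ relative SD for small
    values); biological dispersion is well above QC dispersion by default.
    """

    n_features_per_level: tuple = (43, 20, 4, 92)
    effect_table: pd.DataFrame | None = None
    effect_scale: float = 1.0
    dose_response: dict = field(default_factory=lambda: dict(DOSE_RESPONSE))
    base_log_mean: float = 11.0
    base_log_sd: float = 1.2
    sample_rsd: float = 0.20
    qc_rsd: float = 0.05
    n_qc: int = 8
    seed: int = 0

    def __post_init__(self):
        if self.sample_rsd < 0 or self.qc_rsd < 0:
            raise ValueError("dispersions must be >= 0")
        if self.n_qc < 2:
            raise ValueError("need at least 2 QC injections (RSD undefined otherwise)")


def _feature_frame(cfg: PeakSimConfig) -> pd.DataFrame:
    """Feature metadata: named effect metabolites first (level 1), then
    unnamed fillers per level up to the configured composition."""
    eff = cfg.effect_table if cfg.effect_table is not None else load_effect_directions()
    eff = eff.copy()
    rows = []
    per_level = {1: 0, 2: 0, 3: 0, 4: 0}
    for r in eff.itertuples(index=False):
        rows.append(
            {
                "name": r.name,
                "msi_level": int(r.msi_level),
                "retention_index": float(r.retention_index),
                "effect_pH5": float(r.effect_pH5) * cfg.effect_scale,
                "effect_pH7": float(r.effect_pH7) * cfg.effect_scale,
            }
        )
        per_level[int(r.msi_level)] += 1
    for level, total in zip((1, 2, 3, 4), cfg.n_features_per_level):
        if per_level[level] > total:
            raise ValueError(
                f"effect table has {per_level[level]} level-{level} features, "
                f"composition allows {total}"
            )
        for j in range(per_level[level], total):
            name = f"unknown_{j + 1}" if level == 4 else f"feature_L{level}_{j + 1}"
            rows.append(
                {
                    "name": name,
                    "msi_level": level,
                    "retention_index": 900.0 + 10.0 * len(rows),
                    "effect_pH5": 0.0,
                    "effect_pH7": 0.0,
                }
            )
    return pd.DataFrame(rows)


def simulate_peak_table(cfg: PeakSimConfig, design: SampleDesign) -> PeakTable:
    """Log-normal peak areas for every design row (samples and QCs).

    Sample rows get the class effect (signed log shift × dose-response
    weight) plus biological noise; QC rows are drawn around the grand-mean
    profile with the (much smaller) QC dispersion, emulating pooled-sample
    injections.
    """
    if design.table.empty:
        raise ValueError("empty design")
    rng = np.random.default_rng(cfg.seed)
    feats = _feature_frame(cfg)
    p = len(feats)
    base = rng.normal(cfg.base_log_mean, cfg.base_log_sd, size=p)

    eff = {
        5: feats["effect_pH5"].to_numpy(),
        7: feats["effect_pH7"].to_numpy(),
    }
    sample_rows = design.samples()
    phs = sorted(set(sample_rows["pH"]))
    doses = sorted(set(sample_rows["dose"]))
    class_shift = {
        class_label(pH, d): cfg.dose_response[float(d)] * eff[int(pH)]
        for pH in phs
        for d in doses
    }
    grand = base + np.mean([class_shift[c] for c in class_shift], axis=0)

    log_rows = np.empty((len(design.table), p))
    for i, row in enumerate(design.table.itertuples(index=False)):
        if row.role == "QC":
            log_rows[i] = grand + rng.normal(0.0, cfg.qc_rsd, size=p)
        else:
            mu = base + class_shift[class_label(row.pH, row.dose)]
            log_rows[i] = mu + rng.normal(0.0, cfg.sample_rsd, size=p)

    ab = pd.DataFrame(
        np.exp(log_rows), index=pd.Index(design.sample_ids, name="sample_id"),
        columns=feats["name"],
    )
    meta = feats.set_index("name")[["msi_level", "retention_index", "effect_pH5", "effect_pH7"]]
    return PeakTable(ab, meta)


# ---------------------------------------------------------------------------
# growth curves & calibration standards

@dataclass
class GrowthSimConfig:
    """Logistic growth per (pH, dose) with a hard suppression rule at MIC.

    Carrying capacity is ordered pH 7 > pH 5 > pH 9 (the optimum-growth
    ordering); doses at or above the pH-specific MIC collapse the curve to
    near-blank, doses below it shave the plateau proportionally.
    """

    ph_levels: tuple = (5, 7)
    doses: tuple = DOSES
    capacity: dict = field(default_factory=lambda: {5: 0.7, 7: 1.0, 9: 0.45})
    mic: dict = field(default_factory=lambda: {5: 1.0, 7: 0.2, 9: 0.05})
    rate: float = 0.8           # logistic rate, 1/h
    t_mid: float = 6.0          # inflection time, h
    sub_mic_drop: float = 0.35  # fractional plateau loss at dose just below MIC
    suppressed_frac: float = 0.02
    blank: float = 0.02
    t_max: float = 18.0
    t_step: float = 0.5
    noise_sd: float = 0.005
    seed: int = 0

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.t_step <= 0 or self.t_max <= 0:
            raise ValueError("time grid must be increasing")

    @property
    def time(self) -> np.ndarray:
        return np.arange(0.0, self.t_max + self.t_step / 2, self.t_step)


def logistic_od(cfg: GrowthSimConfig, pH, dose, t: np.ndarray) -> np.ndarray:
    """Closed-form noiseless OD trajectory for one condition."""
    K = cfg.capacity[int(pH)]
    mic = cfg.mic[int(pH)]
    if dose >= mic:
        K_eff = cfg.suppressed_frac * K
    else:
        K_eff = K * (1.0 - cfg.sub_mic_drop * dose / mic)
    return cfg.blank + K_eff / (1.0 + np.exp(-cfg.rate * (t - cfg.t_mid)))


def simulate_growth(cfg: GrowthSimConfig) -> list[GrowthCurve]:
    """One curve per (pH, dose) on the configured grid; seeded noise."""
    t = cfg.time
    if not np.all(np.diff(t) > 0):
        raise ValueError("time grid must be strictly increasing")
    rng = np.random.default_rng(cfg.seed)
    curves = []
    for pH in cfg.ph_levels:
        for dose in cfg.doses:
            od = logistic_od(cfg, pH, dose, t)
            if cfg.noise_sd > 0:
                od = od + rng.normal(0.0, cfg.noise_sd, size=len(t))
            od = np.clip(od, 0.0, None)
            curves.append(GrowthCurve(time=t.copy(), od=od, pH=pH, dose=dose))
    return curves


def simulate_calibration(
    n_points: int = 20,
    slope: float = 1250.0,
    intercept: float = 40.0,
    noise_sd: float = 25.0,
    seed: int = 0,
    conc_min: float = 0.05,
    conc_max: float = 10.0,
) -> pd.DataFrame:
    """Calibration standards: a concentration gradient with a linear
    peak-area response plus Gaussian noise. Returns columns
    ``concentration`` (mg L⁻¹) and ``area``."""
    if n_points < 2:
        raise ValueError("need at least 2 calibration points")
    rng = np.random.default_rng(seed)
    conc = np.linspace(conc_min, conc_max, n_points)
    area = slope * conc + intercept + rng.normal(0.0, noise_sd, size=n_points)
    return pd.DataFrame({"concentration": conc, "area": area})
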