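"""GC-MS feature QC filtering, univariate testing and significant-metabolite
mining.

The workflow mirrors standard untargeted-metabolomics practice: features
whose relative standard deviation across pooled-QC injections is too high
are discarded; condition contrasts are tested with a pooled-variance
Student t on log abundances (technical replicates averaged per biological
replicate first, so the degrees of freedom reflect biology, not injections);
and the final "significant metabolite" set is the intersection of the
univariate screen with the top back-projected PC-DFA loadings.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .chemometrics import DFAModel
from .io import PeakTable, SampleDesign, class_label

logger = logging.getLogger(__name__)

DEFAULT_QC_RSD_THRESHOLD = 30.0  # percent


# ---------------------------------------------------------------------------
# QC filtering

def qc_rsd_filter(
    pt: PeakTable, design: SampleDesign, threshold_pct: float = DEFAULT_QC_RSD_THRESHOLD
) -> tuple[PeakTable, pd.DataFrame]:
    """Drop features whose QC relative SD (100·sd/mean, n−1 sd) exceeds the
    threshold.

    Features with zero QC mean are removed with reason ``"zero QC mean"``.
    Lowering the threshold removes a superset of features (monotone).
    Returns the filtered table and a per-feature report.
    """
    qc_ids = list(design.qc()["sample_id"])
    if len(qc_ids) < 2:
        raise ValueError("need at least 2 QC samples to compute an RSD")
    Q = pt.abundances.loc[qc_ids]
    mean = Q.mean(axis=0)
    sd = Q.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        rsd = 100.0 * sd / mean
    report = pd.DataFrame(
        {"qc_mean": mean, "qc_sd": sd, "qc_rsd_pct": rsd}
    )
    report.index.name = "name"
    reasons = pd.Series("", index=report.index, dtype=object)
    removed_zero = mean == 0
    removed_high = (~removed_zero) & (rsd > threshold_pct)
    reasons[removed_zero] = "zero QC mean"
    reasons[removed_high] = f"QC RSD above {threshold_pct:g}%"
    report["passed"] = ~(removed_zero | removed_high)
    report["reason"] = reasons
    keep = report.index[report["passed"]].tolist()
    if len(keep) < len(report):
        logger.info(
            "QC-RSD filter removed %d/%d features", len(report) - len(keep), len(report)
        )
    return pt.subset_features(keep), report


# ---------------------------------------------------------------------------
# univariate testing

def _bio_averaged(pt: PeakTable, design: SampleDesign, label: str) -> pd.DataFrame:
    """Log abundances for one condition, technical replicates averaged per
    biological replicate. Features with any zero abundance in the condition
    are returned as NaN (flagged untestable downstream, not offset)."""
    t = design.samples()
    labels = [class_label(p, d) for p, d in zip(t["pH"], t["dose"])]
    rows = t.loc[[l == label for l in labels]]
    if rows.empty:
        raise ValueError(f"no samples for condition {label!r}")
    vals = pt.abundances.loc[list(rows["sample_id"])]
    logged = vals.where(vals > 0).apply(np.log)
    logged["__bio"] = rows["bio_rep"].values
    return logged.groupby("__bio").mean()


def student_t(
    pt: PeakTable,
    design: SampleDesign,
    contrast: tuple[str, str],
    equal_var: bool = True,
    adjust: bool = True,
) -> pd.DataFrame:
    """Two-sample Student t (pooled variance; Welch by flag) per feature on
    log abundances for a condition contrast ``(A, B)``.

    Returns a per-feature table with t, two-sided p (df = n_A + n_B − 2),
    Benjamini–Hochberg adjusted p (``adjust=True``), the mean log-fold
    difference A − B and its sign. Zero pooled variance is handled
    explicitly: equal means give (t=0, p=1); unequal means give p=0 with a
    ``degenerate`` flag. Features containing zeros are skipped
    (``tested=False``).
    """
    label_a, label_b = contrast
    A = _bio_averaged(pt, design, label_a)
    B = _bio_averaged(pt, design, label_b)
    if len(A) < 2 or len(B) < 2:
        raise ValueError("both conditions need >= 2 biological replicates")
    names = pt.feature_names
    a = A[names].to_numpy()
    b = B[names].to_numpy()
    tested = ~(np.isnan(a).any(axis=0) | np.isnan(b).any(axis=0))

    tstat = np.full(len(names), np.nan)
    pval = np.full(len(names), np.nan)
    degenerate = np.zeros(len(names), dtype=bool)
    if tested.any():
        res = scipy.stats.ttest_ind(
            a[:, tested], b[:, tested], axis=0, equal_var=equal_var
        )
        tstat[tested] = res.statistic
        pval[tested] = res.pvalue
    diff = a.mean(axis=0) - b.mean(axis=0)
    # zero pooled variance handled explicitly (scipy yields nan/inf there)
    zero_var = tested & (np.var(a, axis=0) == 0) & (np.var(b, axis=0) == 0)
    eq = zero_var & (np.abs(diff) < 1e-300)
    ne = zero_var & ~eq
    tstat[eq], pval[eq] = 0.0, 1.0
    pval[ne] = 0.0
    degenerate[ne] = True

    direction = np.zeros(len(names), dtype=int)
    finite = np.isfinite(diff)
    direction[finite] = np.sign(diff[finite])
    out = pd.DataFrame(
        {
            "t": tstat,
            "p": pval,
            "log_fold": diff,
            "direction": direction,
            "tested": tested,
            "degenerate": degenerate,
            "contrast": f"{label_a} vs {label_b}",
        },
        index=pd.Index(names, name="name"),
    )
    if adjust:
        padj = np.full(len(names), np.nan)
        m = tested
        if m.any():
            padj[m] = multipletests(pval[m], method="fdr_bh")[1]
        out["p_adj"] = padj
    return out


# ---------------------------------------------------------------------------
# loading back-projection and mining

def dfa_feature_weights(dfa: DFAModel, n_df: int = 2) -> np.ndarray:
    """Per-feature discriminant weights: PCA loadings composed with the DFA
    canonical vectors (DFA operates in PC space, so the product maps
    original features to DF axes). Returns [n_features, n_df]."""
    W = dfa.pca.loadings[:, : dfa.n_pcs] @ dfa.weights
    return W[:, : min(n_df, W.shape[1])]


def mine_significant(
    pt: PeakTable,
    dfa: DFAModel,
    tests: pd.DataFrame,
    p_cut: float = 0.05,
    top_loading_frac: float = 0.25,
    use_adjusted: bool = False,
) -> pd.DataFrame:
    """Intersect the univariate screen with the top PC-DFA loadings.

    A feature is significant iff its (raw or BH-adjusted) p ≤ ``p_cut`` and
    the magnitude of its back-projected loading on DF1/DF2 ranks within the
    top ``top_loading_frac`` of features. The DFA must have been fitted on
    the same (post-filter) feature set. Output is sorted by p. An empty
    intersection is a valid (logged) outcome, not an error.
    """
    names = pt.feature_names
    if dfa.pca.loadings.shape[0] != len(names):
        raise ValueError("DFA was not fitted on this feature set")
    W = dfa_feature_weights(dfa, n_df=2)
    magnitude = np.abs(W).max(axis=1)
    rank = pd.Series(magnitude, index=names).rank(ascending=False, method="min")
    n_top = max(1, math.ceil(top_loading_frac * len(names)))
    in_top = rank <= n_top

    pcol = "p_adj" if use_adjusted else "p"
    if use_adjusted and "p_adj" not in tests.columns:
        raise ValueError("tests table has no adjusted p column")
    t = tests.loc[names]
    selected = (t[pcol] <= p_cut) & t["tested"] & in_top.values
    out = t[selected].copy()
    out["loading_magnitude"] = magnitude[selected.values]
    out["loading_rank"] = rank[selected].astype(int)
    out = out.sort_values("p")
    if out.empty:
        logger.info("mine_significant: empty intersection at p<=%g, top %g", p_cut, top_loading_frac)
    return out


# ---------------------------------------------------------------------------
# bookkeeping summaries

def msi_level_counts(pt: PeakTable) -> dict[int, int]:
    """Feature counts per MSI identification level; sums to n_features."""
    levels = pt.features["msi_level"]
    if levels.isna().any():
        raise ValueError("features with missing msi_level")
    counts = {lv: int((levels == lv).sum()) for lv in (1, 2, 3, 4)}
    return counts


def condition_summary(pt: PeakTable, design: SampleDesign) -> pd.DataFrame:
    """Per-feature per-condition mean/sd of log abundance and the direction
    (+1/0/−1) versus the same-pH control, the input for relative-level
    overlay tables.

    Requires a dose-0 control at every pH present.
    """
    t = design.samples()
    labels = pd.Series(
        [class_label(p, d) for p, d in zip(t["pH"], t["dose"])], index=t["sample_id"].values
    )
    phs = sorted(set(t["pH"]))
    for pH in phs:
        if class_label(pH, 0.0) not in set(labels):
            raise ValueError(f"missing dose-0 control at pH {pH}")
    logged = pt.abundances.loc[labels.index].where(lambda x: x > 0).apply(np.log)
    rows = []
    means = {}
    for lab in sorted(set(labels)):
        sub = logged.loc[labels[labels == lab].index]
        means[lab] = sub.mean(axis=0)
        rows.append(
            pd.DataFrame(
                {
                    "condition": lab,
                    "mean_log": means[lab],
                    "sd_log": sub.std(axis=0, ddof=1),
                }
            )
        )
    out = pd.concat(rows)
    out.index.name = "name"
    out = out.reset_index()
    # direction vs the same-pH control, on the log scale
    ctrl_means = {lab.split(":")[0]: means[f"{lab.split(':')[0]}:0"] for lab in means}
    delta = np.array(
        [
            out.loc[i, "mean_log"] - ctrl_means[out.loc[i, "condition"].split(":")[0]][out.loc[i, "name"]]
            for i in out.index
        ]
    )
    out["delta_log_vs_control"] = delta
    out["direction"] = np.where(np.abs(delta) < 1e-12, 0, np.sign(delta)).astype(int)
    return out.set_index(["name", "condition"])
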