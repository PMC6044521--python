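"""QC-RSD filtering, Student t testing and significant-metabolite mining."""

import numpy as np
import pandas as pd
import pytest

from chemspec import synthetic as syn
from chemspec.chemometrics import fit_pc_dfa
from chemspec.io import PeakTable, SampleDesign
from chemspec.metabolite_stats import (
    condition_summary,
    mine_significant,
    msi_level_counts,
    qc_rsd_filter,
    student_t,
)
from chemspec.preprocess import autoscale


def _tiny_design(n_bio=3, doses=(0.0, 0.2), n_qc=3):
    rows = []
    for pH in (5, 7):
        for dose in doses:
            for b in range(1, n_bio + 1):
                rows.append(
                    dict(sample_id=f"pH{pH}_d{dose:g}_b{b}", pH=pH, dose=dose,
                         bio_rep=b, tech_rep=1, role="sample")
                )
    for q in range(1, n_qc + 1):
        rows.append(dict(sample_id=f"QC_{q}", pH=5, dose=0.0, bio_rep=q, tech_rep=1, role="QC"))
    return SampleDesign(pd.DataFrame(rows))


def _table(design, values: dict) -> PeakTable:
    names = list(values)
    ab = pd.DataFrame(
        np.column_stack([values[n] for n in names]),
        index=pd.Index(design.sample_ids, name="sample_id"),
        columns=names,
    )
    meta = pd.DataFrame(
        {"msi_level": [1] * len(names), "retention_index": np.arange(len(names)) + 1000.0},
        index=pd.Index(names, name="name"),
    )
    return PeakTable(ab, meta)


class TestQCFilter:
    def _pt(self, qc_vals, design):
        n = len(design.sample_ids)
        col = np.full(n, 10.0)
        qc_rows = [i for i, r in enumerate(design.table["role"]) if r == "QC"]
        col[qc_rows] = qc_vals[: len(qc_rows)]
        return _table(design, {"f": col, "stable": np.full(n, 5.0)})

    def test_identical_qc_values_retained(self):
        design = _tiny_design()
        pt = self._pt([7.0, 7.0, 7.0], design)
        kept, report = qc_rsd_filter(pt, design, threshold_pct=30)
        assert report.loc["f", "qc_rsd_pct"] == 0.0
        assert "f" in kept.feature_names

    def test_hand_computed_rsd_removal(self):
        """QC {10, 20}: mean 15, sd 7.071 -> RSD 47.1% > 30 -> removed."""
        design = _tiny_design(n_qc=2)
        pt = self._pt([10.0, 20.0], design)
        kept, report = qc_rsd_filter(pt, design, threshold_pct=30)
        assert report.loc["f", "qc_rsd_pct"] == pytest.approx(100 * np.sqrt(50) / 15, rel=1e-12)
        assert "f" not in kept.feature_names
        assert "stable" in kept.feature_names

    def test_infinite_threshold_is_identity(self):
        design = _tiny_design(n_qc=2)
        pt = self._pt([10.0, 20.0], design)
        kept, _ = qc_rsd_filter(pt, design, threshold_pct=np.inf)
        assert kept.feature_names == pt.feature_names

    def test_zero_qc_mean_removed_with_reason(self):
        design = _tiny_design(n_qc=2)
        pt = self._pt([0.0, 0.0], design)
        kept, report = qc_rsd_filter(pt, design, threshold_pct=30)
        assert report.loc["f", "reason"] == "zero QC mean"
        assert "f" not in kept.feature_names

    def test_threshold_monotone(self, design_gcms, peak_table_default):
        """Lower thresholds remove a superset of features."""
        prev = None
        for thr in (50.0, 20.0, 5.0, 1.0):
            kept, _ = qc_rsd_filter(peak_table_default, design_gcms, threshold_pct=thr)
            names = set(kept.feature_names)
            if prev is not None:
                assert names <= prev
            prev = names

    def test_single_qc_rejected(self):
        design = _tiny_design(n_qc=1)
        pt = self._pt([10.0], design)
        with pytest.raises(ValueError, match="2 QC"):
            qc_rsd_filter(pt, design)


class TestStudentT:
    def test_identical_groups_give_t0_p1(self):
        design = _tiny_design()
        n = len(design.sample_ids)
        pt = _table(design, {"f": np.full(n, np.e**2)})
        res = student_t(pt, design, ("pH7:0.2", "pH7:0"))
        assert res.loc["f", "t"] == 0.0
        assert res.loc["f", "p"] == 1.0

    def test_hand_computed_t_statistic(self):
        """Log groups {1,2,3} vs {4,5,6}: pooled sd 1, se sqrt(2/3),
        t = -3/sqrt(2/3) = -3.674, two-sided p ~ 0.0214 at 4 df."""
        design = _tiny_design()
        vals = {"f": np.ones(len(design.sample_ids))}
        pt_vals = np.ones(len(design.sample_ids))
        t = design.table
        a_rows = (t["pH"] == 7) & (t["dose"] == 0.2)
        b_rows = (t["pH"] == 7) & (t["dose"] == 0.0)
        pt_vals[a_rows.to_numpy()] = np.exp([1.0, 2.0, 3.0])
        pt_vals[b_rows.to_numpy()] = np.exp([4.0, 5.0, 6.0])
        pt = _table(design, {"f": pt_vals})
        res = student_t(pt, design, ("pH7:0.2", "pH7:0"), adjust=False)
        assert res.loc["f", "t"] == pytest.approx(-3.0 / np.sqrt(2.0 / 3.0), rel=1e-6)
        assert res.loc["f", "p"] == pytest.approx(0.021312, rel=1e-3)
        assert res.loc["f", "direction"] == -1

    def test_zero_variance_unequal_means_degenerate(self):
        design = _tiny_design()
        pt_vals = np.ones(len(design.sample_ids))
        t = design.table
        pt_vals[((t["pH"] == 7) & (t["dose"] == 0.2)).to_numpy()] = np.e
        pt = _table(design, {"f": pt_vals})
        res = student_t(pt, design, ("pH7:0.2", "pH7:0"))
        assert res.loc["f", "p"] == 0.0
        assert bool(res.loc["f", "degenerate"])

    def test_zero_abundance_skips_feature(self):
        design = _tiny_design()
        vals = np.full(len(design.sample_ids), 2.0)
        vals[0] = 0.0
        pt = _table(design, {"f": vals})
        res = student_t(pt, design, ("pH5:0.2", "pH5:0"))
        assert not bool(res.loc["f", "tested"])

    def test_technical_replicates_averaged_before_testing(self):
        """Tripling every sample as technical replicates must not change t
        (df stays biological)."""
        d1 = _tiny_design()
        rows = []
        for r in d1.table.itertuples(index=False):
            if r.role == "QC":
                rows.append(r._asdict())
                continue
            for tr in (1, 2, 3):
                rec = r._asdict()
                rec["tech_rep"] = tr
                rec["sample_id"] = f"{r.sample_id}_t{tr}"
                rows.append(rec)
        d3 = SampleDesign(pd.DataFrame(rows))
        rng = np.random.default_rng(0)
        base = rng.lognormal(2, 0.3, size=len(d1.sample_ids))
        pt1 = _table(d1, {"f": base})
        # identical value per tech replicate -> same bio means
        expand = {s.split("_t")[0] if s.startswith("pH") else s: v
                  for s, v in zip(d1.sample_ids, base)}
        vals3 = np.array([expand[s.rsplit("_t", 1)[0] if s.startswith("pH") else s]
                          for s in d3.sample_ids])
        pt3 = _table(d3, {"f": vals3})
        r1 = student_t(pt1, d1, ("pH7:0.2", "pH7:0"), adjust=False)
        r3 = student_t(pt3, d3, ("pH7:0.2", "pH7:0"), adjust=False)
        assert r1.loc["f", "t"] == pytest.approx(r3.loc["f", "t"], rel=1e-12)
        assert r1.loc["f", "p"] == pytest.approx(r3.loc["f", "p"], rel=1e-12)


@pytest.fixture(scope="module")
def mined(design_gcms):
    pt = syn.simulate_peak_table(syn.PeakSimConfig(seed=3), design_gcms)
    pt, _ = qc_rsd_filter(pt, design_gcms)
    tests = student_t(pt, design_gcms, ("pH7:0.2", "pH7:0"))
    ids = list(design_gcms.samples()["sample_id"])
    Z, _ = autoscale(np.log(pt.abundances.loc[ids].to_numpy()))
    y = np.asarray([design_gcms.labels()[i] for i in ids])
    dfa = fit_pc_dfa(Z, y, n_pcs=25)
    return pt, dfa, tests


class TestMining:
    def test_planted_feature_selected_with_direction(self, mined):
        pt, dfa, tests = mined
        sig = mine_significant(pt, dfa, tests, p_cut=0.001)
        assert "trehalose" in sig.index
        assert sig.loc["trehalose", "direction"] == 1

    def test_p_equal_one_never_selected(self, mined):
        pt, dfa, tests = mined
        forced = tests.copy()
        forced["p"] = 1.0
        assert mine_significant(pt, dfa, forced, p_cut=0.05).empty

    def test_no_op_thresholds_select_everything_tested(self, mined):
        pt, dfa, tests = mined
        sig = mine_significant(pt, dfa, tests, p_cut=1.0, top_loading_frac=1.0)
        assert len(sig) == int(tests["tested"].sum())

    def test_output_sorted_by_p(self, mined):
        pt, dfa, tests = mined
        sig = mine_significant(pt, dfa, tests, p_cut=0.05)
        assert (np.diff(sig["p"].to_numpy()) >= 0).all()


class TestSummaries:
    def test_msi_counts_sum_to_feature_count(self, peak_table_default):
        counts = msi_level_counts(peak_table_default)
        assert sum(counts.values()) == len(peak_table_default.feature_names)
        assert counts == {1: 43, 2: 20, 3: 4, 4: 92}

    def test_empty_table_counts_zero(self):
        design = _tiny_design()
        pt = _table(design, {"f": np.ones(len(design.sample_ids))}).subset_features([])
        assert msi_level_counts(pt) == {1: 0, 2: 0, 3: 0, 4: 0}

    def test_constant_feature_directions_zero(self):
        design = _tiny_design()
        pt = _table(design, {"f": np.full(len(design.sample_ids), 4.0)})
        summary = condition_summary(pt, design)
        assert (summary["direction"] == 0).all()

    def test_planted_monotone_decrease_gives_growing_negative_deltas(self, design_gcms):
        pt = syn.simulate_peak_table(syn.PeakSimConfig(seed=6), design_gcms)
        summary = condition_summary(pt, design_gcms)
        g = summary.xs("glucose", level="name")
        deltas = [g.loc[f"pH7:{d:g}", "delta_log_vs_control"] for d in (0.003, 0.03, 0.2)]
        assert all(d < 0 for d in deltas)
        assert deltas[0] > deltas[1] > deltas[2]

    def test_missing_control_rejected(self):
        design = _tiny_design(doses=(0.0, 0.2))
        keep = [s for s in design.sample_ids if "d0_" not in s or "pH5" in s]
        sub = design.subset(keep)
        pt = _table(sub, {"f": np.ones(len(sub.sample_ids))})
        with pytest.raises(ValueError, match="control"):
            condition_summary(pt, sub)
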