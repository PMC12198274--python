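"""Dose trajectories: arithmetic oracles, spline features, Louvain subgroups."""

import datetime as dt

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from modnet.synthetic import generate_prescription_histories
from modnet.trajectories import (
    FEATURE_COLUMNS,
    PrescriptionRecord,
    TrajectoryCommunities,
    build_monthly_trajectory,
    extract_raw_features,
    fit_smoothed_trajectory,
    louvain_subgroups,
    trajectory_features,
)


def _rec(start, end, dose, drug="methylphenidate", pid="p1"):
    return PrescriptionRecord(pid, start, end, drug, dose)


BIRTH = dt.date(2000, 1, 1)
ASSESS = dt.date(2020, 1, 1)


class TestMonthlyTrajectory:
    def test_full_month_carries_daily_dose(self):
        # April 2010 has 30 days, fully covered -> month mean = 10 mg/day
        tr = build_monthly_trajectory(
            [_rec(dt.date(2010, 4, 1), dt.date(2010, 4, 30), 10.0)], BIRTH, ASSESS
        )
        assert tr.dose[tr.months.get_loc("2010-04")] == pytest.approx(10.0)

    def test_half_covered_month_day_weights(self):
        tr = build_monthly_trajectory(
            [_rec(dt.date(2010, 4, 1), dt.date(2010, 4, 15), 10.0)], BIRTH, ASSESS
        )
        assert tr.dose[tr.months.get_loc("2010-04")] == pytest.approx(10.0 * 15 / 30)

    def test_no_records_all_zero(self):
        tr = build_monthly_trajectory([], BIRTH, ASSESS)
        assert np.all(tr.dose == 0)
        assert len(tr.months) == 241  # 20 years inclusive of both end months

    def test_overlapping_records_sum(self):
        recs = [
            _rec(dt.date(2010, 4, 1), dt.date(2010, 4, 30), 10.0),
            _rec(dt.date(2010, 4, 16), dt.date(2010, 4, 30), 20.0),
        ]
        tr = build_monthly_trajectory(recs, BIRTH, ASSESS)
        assert tr.dose[tr.months.get_loc("2010-04")] == pytest.approx(10 + 20 * 15 / 30)

    def test_dexamphetamine_equivalence_factor(self):
        tr = build_monthly_trajectory(
            [_rec(dt.date(2010, 4, 1), dt.date(2010, 4, 30), 10.0, drug="dexamphetamine")],
            BIRTH, ASSESS,
        )
        assert tr.dose[tr.months.get_loc("2010-04")] == pytest.approx(20.0)

    def test_invalid_record_rejected(self):
        with pytest.raises(ValueError, match="before start"):
            _rec(dt.date(2010, 5, 1), dt.date(2010, 4, 1), 10.0)
        with pytest.raises(ValueError, match="negative dose"):
            _rec(dt.date(2010, 4, 1), dt.date(2010, 5, 1), -1.0)


class TestRawFeatures:
    def test_total_dose_integrates_days(self):
        # 10 mg/day over calendar year 2010 = 10 * 365 mg
        tr = build_monthly_trajectory(
            [_rec(dt.date(2010, 1, 1), dt.date(2010, 12, 31), 10.0)], BIRTH, ASSESS
        )
        onset, stop, total = extract_raw_features(tr)
        assert total == pytest.approx(3650.0)
        assert onset == pytest.approx(10.0, abs=0.01)
        assert stop == pytest.approx(10 + 11 / 12, abs=0.01)

    def test_total_dose_additive_over_disjoint_records(self):
        r1 = [_rec(dt.date(2008, 3, 1), dt.date(2008, 6, 30), 15.0)]
        r2 = [_rec(dt.date(2012, 1, 1), dt.date(2012, 2, 29), 25.0)]
        t_sep = [
            extract_raw_features(build_monthly_trajectory(r, BIRTH, ASSESS))[2]
            for r in (r1, r2)
        ]
        t_both = extract_raw_features(build_monthly_trajectory(r1 + r2, BIRTH, ASSESS))[2]
        assert t_both == pytest.approx(sum(t_sep))

    def test_all_zero_flags_never_treated(self):
        tr = build_monthly_trajectory([], BIRTH, ASSESS)
        onset, stop, total = extract_raw_features(tr)
        assert onset is None and stop is None and total == 0
        feats = trajectory_features([], BIRTH, ASSESS, participant_id="p0")
        assert feats.never_treated and feats.duration == 0

    def test_single_treated_month(self):
        start = dt.date(2008, 1, 1)  # exactly age 8.0
        tr = build_monthly_trajectory([_rec(start, dt.date(2008, 1, 31), 10.0)], BIRTH, ASSESS)
        onset, stop, _ = extract_raw_features(tr)
        assert onset == stop == pytest.approx(8.0, abs=0.01)


class TestSmoothedFeatures:
    def test_constant_trajectory_reproduced(self):
        tr = build_monthly_trajectory(
            [_rec(dt.date(2005, 1, 1), dt.date(2015, 12, 31), 20.0)],
            dt.date(2005, 1, 1), dt.date(2015, 12, 31),
        )
        _, _, duration, max_dose, dose_sd = fit_smoothed_trajectory(tr)
        assert max_dose == pytest.approx(20.0, abs=0.5)
        assert dose_sd <= 0.5
        assert duration == pytest.approx(11.0, abs=0.2)

    def test_half_sine_peak_recovered(self):
        months = pd.period_range("2008-01", periods=60, freq="M")
        from modnet.trajectories import DoseTrajectory

        t = np.arange(60) / 59
        tr = DoseTrajectory(
            participant_id="p",
            birth=dt.date(2000, 1, 1),
            assessment=dt.date(2012, 12, 31),
            months=months,
            dose=40 * np.sin(np.pi * t),
        )
        _, _, _, max_dose, _ = fit_smoothed_trajectory(tr)
        assert abs(max_dose - 40) / 40 <= 0.10

    def test_all_zero_duration_zero(self):
        tr = build_monthly_trajectory([], dt.date(2010, 1, 1), dt.date(2012, 1, 1))
        _, _, duration, max_dose, dose_sd = fit_smoothed_trajectory(tr)
        assert duration == 0 and max_dose == 0 and dose_sd == 0

    def test_too_short_series_rejected(self):
        tr = build_monthly_trajectory([], dt.date(2010, 1, 1), dt.date(2010, 5, 1))
        with pytest.raises(ValueError, match=">= 8 months"):
            fit_smoothed_trajectory(tr)


def _brute_force_modularity(G, partition):
    """Direct evaluation of Q = sum_ij (A_ij - k_i k_j / 2m) delta(c_i c_j) / 2m."""
    W = nx.to_numpy_array(G)
    two_m = W.sum()
    k = W.sum(axis=1)
    nodes = list(G.nodes)
    comm = {}
    for cid, members in enumerate(partition):
        for n in members:
            comm[n] = cid
    q = 0.0
    for i, ni in enumerate(nodes):
        for j, nj in enumerate(nodes):
            if comm[ni] == comm[nj]:
                q += W[i, j] - k[i] * k[j] / two_m
    return q / two_m


class TestLouvain:
    def _blob_features(self, rng, n, center):
        return center + 0.05 * rng.standard_normal((n, 6))

    def test_planted_blobs_recovered_pure(self):
        rng = np.random.default_rng(0)
        a = self._blob_features(rng, 30, np.array([1, 1, 1, -1, -1, -1.0]))
        b = self._blob_features(rng, 30, np.array([-1, -1, -1, 1, 1, 1.0]))
        X = pd.DataFrame(np.vstack([a, b]), columns=list(FEATURE_COLUMNS))
        labels = TrajectoryCommunities(seed=1).fit_predict(X)
        first, second = labels[:30], labels[30:]
        assert len(set(first)) == 1 and len(set(second)) == 1
        assert first[0] != second[0]

    def test_modularity_matches_brute_force_oracle(self):
        rng = np.random.default_rng(1)
        W = rng.uniform(0, 1, (12, 12)) * (rng.random((12, 12)) < 0.5)
        W = np.triu(W, 1)
        W = W + W.T
        G = nx.from_numpy_array(W)
        parts = nx.community.louvain_communities(G, weight="weight", seed=3)
        q_nx = nx.community.modularity(G, parts, weight="weight")
        assert q_nx == pytest.approx(_brute_force_modularity(G, parts), abs=1e-10)

    def test_small_community_flagged_excluded(self):
        rng = np.random.default_rng(2)
        a = self._blob_features(rng, 30, np.array([1, 1, 1, -1, -1, -1.0]))
        b = self._blob_features(rng, 30, np.array([-1, -1, -1, 1, 1, 1.0]))
        # pattern orthogonal to both blobs so the small group stands alone
        c = self._blob_features(rng, 4, np.array([1, 1, -1, 1, 1, -1.0]))
        X = pd.DataFrame(np.vstack([a, b, c]), columns=list(FEATURE_COLUMNS))
        part = louvain_subgroups(X, min_community_size=10, seed=4)
        sizes = part.community_sizes
        small = sizes[sizes < 10]
        assert len(small) >= 1
        assert set(small.index) <= set(part.excluded)
        assert part.retained().isin(sizes[sizes >= 10].index).all()

    def test_partition_beats_singletons(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame(rng.standard_normal((24, 6)), columns=list(FEATURE_COLUMNS))
        est = TrajectoryCommunities(seed=5).fit(X)
        singletons = [{n} for n in est.graph_.nodes]
        q_single = nx.community.modularity(est.graph_, singletons, weight="weight")
        assert est.modularity_ >= q_single

    def test_archetype_recovery_end_to_end(self):
        hist = generate_prescription_histories("early_intense", 25, seed=6)
        hist += generate_prescription_histories("late_moderate", 25, seed=7)
        rows = [
            trajectory_features(h.records, h.birth, h.assessment, h.participant_id).as_row()
            for h in hist
        ]
        X = pd.DataFrame(rows).set_index("participant_id")[list(FEATURE_COLUMNS)]
        part = louvain_subgroups(X, seed=8)
        arch = pd.Series(
            ["early" if i.startswith("early") else "late" for i in part.labels.index],
            index=part.labels.index,
        )
        purity = (
            pd.crosstab(arch, part.labels).max(axis=0).sum() / len(part.labels)
        )
        assert purity >= 0.95
        by_comm = X.groupby(part.labels).mean()
        early_comm = by_comm["onset_age"].idxmin()
        assert by_comm.loc[early_comm, "max_daily_dose"] == by_comm["max_daily_dose"].max()
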