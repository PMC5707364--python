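"""rIBD scan: window tiling, nIBD normalization vs a per-base oracle, the
two threshold modes vs hand computation, proportions, hotspots, and the
elevation association."""

import numpy as np
import pandas as pd
import pytest

from tmpop import intervals as iv
from tmpop.ibd_sim import PlantedWindow, simulate_ibd_tracts, TRACT_COLUMNS
from tmpop.ribd import (
    RibdSummary,
    WindowStats,
    call_introgression,
    elevation_association,
    group_compare,
    hotspot_detection,
    tile_windows,
    window_nibd,
)


class TestTiling:
    def test_partial_window_kept_when_at_least_half(self):
        w = tile_windows({"c": 260_000}, 100_000)
        assert list(w[["start", "end"]].itertuples(index=False, name=None)) == [
            (0, 100_000), (100_000, 200_000), (200_000, 260_000)
        ]

    def test_short_remainder_merged_into_predecessor(self):
        w = tile_windows({"c": 240_000}, 100_000)
        assert list(w[["start", "end"]].itertuples(index=False, name=None)) == [
            (0, 100_000), (100_000, 240_000)
        ]


def tracts_df(rows):
    return pd.DataFrame(rows, columns=TRACT_COLUMNS)


class TestWindowNibd:
    def test_no_tracts_gives_zero_everywhere(self):
        ws = window_nibd(
            tracts_df([]), {"c": 1_000_000}, 100_000,
            panel_sizes={"mex": 4, "par": 4}, maize_lines=["L1"],
        )
        assert (ws.df["ribd"] == 0).all()

    def test_full_panel_sharing_normalizes_to_one(self):
        rows = [
            ("L1", f"mex{i}", "mex", "c", 100_000, 200_000, 1.0) for i in range(4)
        ]
        ws = window_nibd(
            tracts_df(rows), {"c": 400_000}, 100_000,
            panel_sizes={"mex": 4, "par": 4}, maize_lines=["L1"],
        )
        assert ws.df.loc[1, "nibd_mex"] == 1.0
        assert ws.df.loc[0, "nibd_mex"] == 0.0

    def test_tract_beyond_chromosome_rejected(self):
        rows = [("L1", "mex1", "mex", "c", 0, 2_000_000, 1.0)]
        with pytest.raises(ValueError, match="beyond"):
            window_nibd(
                tracts_df(rows), {"c": 1_000_000}, 100_000,
                panel_sizes={"mex": 1, "par": 1}, maize_lines=["L1"],
            )

    def test_counts_match_per_base_overlap_oracle(self):
        rng = np.random.default_rng(6)
        L, W = 1_000_000, 100_000
        lines = ["L1", "L2", "L3"]
        members = {"mex": ["m1", "m2"], "par": ["p1", "p2", "p3"]}
        rows = []
        for line in lines:
            for panel, mem in members.items():
                for m in mem:
                    for _ in range(rng.poisson(3)):
                        s = int(rng.integers(0, L - 1000))
                        e = min(L, s + int(rng.integers(1000, 300_000)))
                        rows.append((line, m, panel, "c", s, e, 1.0))
        ws = window_nibd(
            tracts_df(rows), {"c": L}, W,
            panel_sizes={"mex": 2, "par": 3}, maize_lines=lines,
        )
        df = pd.DataFrame(rows, columns=TRACT_COLUMNS)
        for w in range(L // W):
            ws_start, ws_end = w * W, (w + 1) * W
            for panel, size in (("mex", 2), ("par", 3)):
                vals = []
                for line in lines:
                    base = np.zeros(L, bool)
                    shared = set()
                    for r in df[(df.line_id == line) & (df.panel == panel)].itertuples():
                        cover = np.zeros(L, bool)
                        cover[r.start : r.end] = True
                        if cover[ws_start:ws_end].any():
                            shared.add(r.panel_member_id)
                    vals.append(len(shared) / size)
                got = ws.df.loc[w, f"nibd_{panel}"]
                assert got == pytest.approx(np.mean(vals))


class TestPanelSymmetry:
    def test_ribd_antisymmetric_under_panel_swap(self):
        tr = simulate_ibd_tracts({"c": 2_000_000}, 5, 4, 4, baseline_rate=5e-7, seed=3)
        ws = window_nibd(tr, {"c": 2_000_000}, 100_000,
                         panel_sizes={"mex": 4, "par": 4})
        swapped = tr.copy()
        swapped["panel"] = swapped["panel"].map({"mex": "par", "par": "mex"})
        swapped["panel_member_id"] = swapped["panel_member_id"].str.translate(
            str.maketrans("", "")
        )
        ws2 = window_nibd(swapped, {"c": 2_000_000}, 100_000,
                          panel_sizes={"mex": 4, "par": 4})
        assert np.allclose(ws.df["ribd"], -ws2.df["ribd"])
        assert ws.df["nibd_mex"].between(0, 1).all()
        assert ws.df["nibd_par"].between(0, 1).all()


def _hand_stats(ribd_values, lines=("L1", "L2")):
    n = len(ribd_values)
    df = pd.DataFrame(
        {
            "chrom": "c",
            "start": np.arange(n) * 100_000,
            "end": (np.arange(n) + 1) * 100_000,
            "nibd_mex": np.maximum(ribd_values, 0),
            "nibd_par": np.maximum(-np.asarray(ribd_values), 0),
        }
    )
    df["ribd"] = df["nibd_mex"] - df["nibd_par"]
    per_mex = np.tile(df["nibd_mex"].to_numpy()[:, None], (1, len(lines)))
    per_par = np.tile(df["nibd_par"].to_numpy()[:, None], (1, len(lines)))
    return WindowStats(df, per_mex, per_par, list(lines), {"mex": 4, "par": 4})


class TestCallIntrogression:
    RIBD12 = [0.02, 0.01, 0.03, 0.0, 0.02, 0.01, 0.02, 0.03, 0.01, 0.02, 0.01, 0.40]

    def test_constant_ribd_is_degenerate(self):
        ws = _hand_stats([0.1] * 12)
        with pytest.raises(ValueError, match="sigma"):
            call_introgression(ws, np.ones(12))

    def test_snp_density_filter_applied_before_mu_sigma(self):
        ws = _hand_stats(self.RIBD12)
        dens = np.ones(12)
        dens[:2] = 0.0  # below mean -> dropped from mu/sigma and flags
        s = call_introgression(ws, dens)
        retained = np.asarray(self.RIBD12)[2:]
        assert s.mu == pytest.approx(retained.mean())
        assert s.sigma == pytest.approx(retained.std())
        assert not s.windows.loc[0, "retained"]

    def test_both_modes_match_hand_computation_on_12_window_toy(self):
        r = np.asarray(self.RIBD12)
        mu, sigma = r.mean(), r.std()
        ws = _hand_stats(self.RIBD12)
        z = call_introgression(ws, np.ones(12), "zscore")
        printed = call_introgression(ws, np.ones(12), "as-printed")
        hand_z = (r - mu) / sigma > 2
        hand_p = np.array(
            [(x - mu) / (sigma * x) > 2 if x != 0 else False for x in r]
        )
        assert list(z.windows["flagged"]) == list(hand_z)
        assert list(printed.windows["flagged"]) == list(hand_p)
        # the clear positive outlier is flagged under both rules
        assert z.windows.loc[11, "flagged"] and printed.windows.loc[11, "flagged"]

    def test_proportions_and_union(self):
        ws = _hand_stats(self.RIBD12)
        s = call_introgression(ws, np.ones(12))
        props = s.per_line_proportion(1_200_000)
        assert props["L1"] == pytest.approx(100_000 / 1_200_000)
        assert s.union_proportion(1_200_000) == pytest.approx(100_000 / 1_200_000)

    def test_disjoint_flags_sum_in_union(self):
        """Two lines flagged in disjoint 1-of-100 windows: per-line 1%,
        union 2%."""
        n = 100
        r = np.full(n, 0.01)
        r[10] = 0.5
        r[60] = 0.5
        ws = _hand_stats(list(r))
        s = call_introgression(ws, np.ones(n))
        # restrict line credit to one window each
        s.per_line_flags[:, :] = False
        s.per_line_flags[10, 0] = True
        s.per_line_flags[60, 1] = True
        genome = n * 100_000
        assert s.per_line_proportion(genome)["L1"] == pytest.approx(0.01)
        assert s.union_proportion(genome) == pytest.approx(0.02)

    def test_union_matches_interval_oracle_on_random_flags(self):
        rng = np.random.default_rng(11)
        n = 50
        r = rng.normal(0.01, 0.005, n)
        r[rng.choice(n, 5, replace=False)] += 0.2
        ws = _hand_stats(list(r), lines=("L1", "L2", "L3"))
        s = call_introgression(ws, np.ones(n))
        genome = n * 100_000
        flagged_iv = [
            (int(row.start), int(row.end))
            for row in s.windows[s.per_line_flags.any(axis=1)].itertuples()
        ]
        assert s.union_proportion(genome) == pytest.approx(
            iv.total_length(flagged_iv) / genome
        )


class TestHotspots:
    def test_no_multi_line_window_gives_empty(self):
        ws = _hand_stats([0.01] * 11 + [0.4], lines=("L1",))
        s = call_introgression(ws, np.ones(12))
        assert hotspot_detection(s, 2) == []

    def test_planted_hotspot_recovered_with_sharing_count(self):
        ws = _hand_stats(TestCallIntrogression.RIBD12, lines=("L1", "L2", "L3"))
        s = call_introgression(ws, np.ones(12))
        hot = hotspot_detection(s, 2)
        assert hot == [("c", 1_100_000, 1_200_000, 3)]
        # hotspot intervals are disjoint
        assert iv.merge([(s0, e0) for _, s0, e0, _ in hot]) == [
            (s0, e0) for _, s0, e0, _ in hot
        ]


class TestElevation:
    def test_constant_proportions_report_na(self):
        rho, p = elevation_association([0.1] * 10, range(10))
        assert np.isnan(rho) and np.isnan(p)

    def test_simulated_positive_effect_detected(self):
        rng = np.random.default_rng(12)
        elev = rng.uniform(0, 3000, 400)
        prop = 0.001 + 2e-7 * elev + rng.normal(0, 2e-4, 400)
        rho, p = elevation_association(prop, elev)
        assert rho > 0 and p < 0.01

    def test_null_type_one_error_nominal(self):
        rng = np.random.default_rng(13)
        hits = 0
        n_rep = 200
        for _ in range(n_rep):
            prop = rng.normal(0, 1, 50)
            elev = rng.normal(0, 1, 50)
            _, p = elevation_association(prop, elev)
            hits += p < 0.05
        assert 0.02 <= hits / n_rep <= 0.09

    def test_group_compare_detects_shift(self):
        rng = np.random.default_rng(14)
        hi = rng.normal(0.003, 0.001, 60)
        lo = rng.normal(0.001, 0.001, 60)
        _, p = group_compare(hi, lo)
        assert p < 0.001


class TestPlantedWindowRecovery:
    def test_planted_window_flagged_and_null_calibrated(self):
        """One 100-kb window introgressed in 30% of 20 lines is flagged;
        background false-flag rate stays near the 2-SD tail."""
        lengths = {"chr1": 10_000_000}
        hits, false = 0, []
        for rep in range(20):
            tr = simulate_ibd_tracts(
                lengths, 20, 8, 8, baseline_rate=3e-7,
                planted_windows=[PlantedWindow("chr1", 5_000_000, 5_100_000, 0.3)],
                seed=500 + rep,
            )
            ws = window_nibd(tr, lengths, 100_000)
            s = call_introgression(ws, np.ones(len(ws.df)))
            flags = s.windows["flagged"].to_numpy()
            hits += bool(flags[50])
            false.append(np.delete(flags, 50).mean())
        assert hits >= 18
        assert np.mean(false) <= 0.05
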