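"""Spearman correlation, Bonferroni thresholds, aggregation and the tables."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from tugtmg.stats import (
    TMG_VARIABLES,
    TUG_TIMES,
    bonferroni_threshold,
    build_participant_records,
    correlation_table,
    descriptive_table,
    export_plot_data,
    spearman,
)


def rank_avg(v):
    """Average ranks, pure python (oracle helper)."""
    order = sorted(range(len(v)), key=lambda i: v[i])
    ranks = [0.0] * len(v)
    i = 0
    while i < len(v):
        j = i
        while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
            j += 1
        r = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = r
        i = j + 1
    return ranks


def pearson(a, b):
    n = len(a)
    ma, mb = sum(a) / n, sum(b) / n
    num = sum((x - ma) * (y - mb) for x, y in zip(a, b))
    den = math.sqrt(sum((x - ma) ** 2 for x in a) * sum((y - mb) ** 2 for y in b))
    return num / den


def spearman_oracle(x, y):
    """Exhaustive-enumeration Spearman rho and two-sided permutation p."""
    rx, ry = rank_avg(list(x)), rank_avg(list(y))
    rho = pearson(rx, ry)
    count = 0
    total = 0
    for perm in itertools.permutations(ry):
        total += 1
        if abs(pearson(rx, list(perm))) >= abs(rho) - 1e-12:
            count += 1
    return rho, count / total


class TestSpearman:
    def test_perfect_monotone(self):
        rho, p = spearman([1, 2, 3], [10, 20, 30])
        assert rho == pytest.approx(1.0)
        assert 0 < p <= 1

    def test_perfect_antimonotone(self):
        rho, p = spearman([1, 2, 3, 4], [8, 7, 6, 5])
        assert rho == pytest.approx(-1.0)

    def test_exact_permutation_matches_enumeration_oracle(self):
        x, y = [1, 2, 3, 4, 5], [2, 1, 4, 3, 5]
        rho, p = spearman(x, y)
        rho_o, p_o = spearman_oracle(x, y)
        assert rho == pytest.approx(rho_o, abs=1e-12)
        assert p == pytest.approx(p_o, abs=1e-12)

    def test_exact_permutation_matches_oracle_randomized(self, rng):
        for _ in range(20):
            n = int(rng.integers(3, 8))
            # integer draws produce ties with decent probability
            x = rng.integers(0, n + 2, size=n).astype(float)
            y = rng.normal(size=n)
            if np.ptp(x) == 0:
                continue
            rho, p = spearman(x, y, method="exact")
            rho_o, p_o = spearman_oracle(x, y)
            assert rho == pytest.approx(rho_o, abs=1e-12)
            assert p == pytest.approx(p_o, abs=1e-12)

    def test_t_approximation_against_reference_implementation(self, rng):
        from scipy.stats import spearmanr

        for _ in range(10):
            x, y = rng.normal(size=30), rng.normal(size=30)
            rho, p = spearman(x, y)
            ref = spearmanr(x, y)
            assert rho == pytest.approx(ref.statistic, abs=1e-12)
            assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_invariant_under_monotone_transforms(self, rng):
        x, y = rng.normal(size=15), rng.normal(size=15)
        rho, p = spearman(x, y)
        rho2, p2 = spearman(np.exp(x), y**3)
        assert rho2 == pytest.approx(rho, abs=1e-12)
        assert p2 == pytest.approx(p, abs=1e-12)

    def test_null_calibration_of_t_p_values(self, rng):
        hits, n_rep = 0, 2000
        for _ in range(n_rep):
            _, p = spearman(rng.normal(size=23), rng.normal(size=23))
            hits += p < 0.05
        assert hits / n_rep == pytest.approx(0.05, abs=0.015)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="zero rank variance"):
            spearman([1, 1, 1, 1], [1, 2, 3, 4])
        with pytest.raises(ValueError):
            spearman([1, 2], [3, 4])
        with pytest.raises(ValueError):
            spearman([1, 2, np.nan], [1, 2, 3])


class TestBonferroni:
    def test_printed_threshold_for_twelve_parameters(self):
        assert round(bonferroni_threshold(0.05, 12), 4) == 0.0042

    def test_identity_for_single_test(self):
        assert bonferroni_threshold(0.05, 1) == 0.05

    def test_all_seventy_two_correlations(self):
        assert bonferroni_threshold(0.05, 72) == pytest.approx(0.000694, abs=5e-7)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0.05, 0)
        with pytest.raises(ValueError):
            bonferroni_threshold(1.5, 12)


def toy_dataset(n=6, seed=0, missing_tmg=()):
    rng = np.random.default_rng(seed)
    pids = [f"P{i:02d}" for i in range(n)]
    tug_rows = []
    for pid in pids:
        for k in range(2):
            row = {"participant_id": pid, "test_index": k}
            for t in TUG_TIMES:
                row[f"{t}_s"] = float(rng.uniform(1, 10))
            tug_rows.append(row)
    tmg_rows = []
    for pid in pids:
        if pid in missing_tmg:
            continue
        for m in ("BF", "GM", "VL", "VM"):
            tmg_rows.append(
                {"participant_id": pid, "muscle": m,
                 "Tc_ms": float(rng.uniform(20, 70)), "Td_ms": float(rng.uniform(18, 40)),
                 "Dm_mm": float(rng.uniform(0.5, 11))}
            )
    return pd.DataFrame(tug_rows), pd.DataFrame(tmg_rows)


class TestBuildParticipantRecords:
    def test_means_are_arithmetic(self):
        tug = pd.DataFrame(
            [{"participant_id": "P01", "test_index": 0, "total_s": 18.0},
             {"participant_id": "P01", "test_index": 1, "total_s": 22.0}]
        )
        for t in TUG_TIMES[:-1]:
            tug[f"{t}_s"] = 1.0
        tmg = pd.DataFrame(
            [{"participant_id": "P01", "muscle": m, "Tc_ms": 40.0, "Td_ms": 30.0, "Dm_mm": 5.0}
             for m in ("BF", "GM", "VL", "VM")]
        )
        records, excluded = build_participant_records(tug, tmg)
        assert records.loc["P01", "total_s"] == pytest.approx(20.0)
        assert excluded == []

    def test_participants_missing_a_modality_excluded(self):
        tug, tmg = toy_dataset(n=5, missing_tmg=("P02",))
        records, excluded = build_participant_records(tug, tmg)
        assert len(records) == 4
        assert ("P02", "no TMG measurement") in excluded

    def test_empty_eligible_set_aborts(self):
        tug, tmg = toy_dataset(n=3, missing_tmg=("P00", "P01", "P02"))
        with pytest.raises(ValueError, match="no eligible"):
            build_participant_records(tug, tmg)


class TestCorrelationTable:
    def test_all_pairs_present_and_nested_flags(self):
        tug, tmg = toy_dataset(n=8)
        records, _ = build_participant_records(tug, tmg)
        table = correlation_table(records, alpha=0.05, family_size=12)
        assert len(table) == len(TMG_VARIABLES) * len(TUG_TIMES) == 72
        assert ((~table.sig_adj) | table.sig_raw).all()  # sig_adj => sig_raw
        assert (table.rho.abs() <= 1 + 1e-12).all()
        assert table.p.between(0, 1).all()

    def test_undefined_cells_reported_missing(self):
        tug, tmg = toy_dataset(n=6)
        records, _ = build_participant_records(tug, tmg)
        records["VM_Td"] = 30.0  # zero rank variance
        table = correlation_table(records)
        bad = table[(table.muscle == "VM") & (table.parameter == "Td")]
        assert bad.rho.isna().all()
        assert not bad.sig_raw.any()


class TestDescriptiveTable:
    def test_min_max_and_sample_sd(self):
        tug, tmg = toy_dataset(n=6)
        tug["total_s"] = np.linspace(15.0, 35.0, len(tug))
        tug.loc[0, "total_s"] = 9.76
        tug.loc[1, "total_s"] = 48.67
        table = descriptive_table(tug, tmg)
        row = table[table.variable == "total"].iloc[0]
        assert row["min"] == pytest.approx(9.76)
        assert row["max"] == pytest.approx(48.67)
        v = tug["total_s"]
        assert row["sd"] == pytest.approx(v.std(ddof=1))

    def test_single_value_sd_missing(self):
        tug, tmg = toy_dataset(n=3)
        tug = tug[tug.test_index == 0].iloc[:1]
        table = descriptive_table(tug, tmg)
        assert np.isnan(table[table.variable == "total"].iloc[0]["sd"])

    def test_participant_granularity_averages_first(self):
        tug, tmg = toy_dataset(n=6)
        pooled = descriptive_table(tug, tmg, granularity="pooled")
        per = descriptive_table(tug, tmg, granularity="participant")
        assert pooled[pooled.variable == "total"].iloc[0]["n"] == 12
        assert per[per.variable == "total"].iloc[0]["n"] == 6


class TestDescriptiveSampling:
    def test_pooled_means_track_generating_distribution_at_study_scale(self):
        """A 208-test synthetic study: pooled descriptive means sit within two
        (cluster-aware) standard errors of the generating truncated-normal
        means, for a TUG duration and a muscle parameter."""
        from scipy.stats import truncnorm

        from tugtmg.pipeline import _cohort_inputs, extract_dataset, segment_dataset
        from tugtmg.synth import TMG_LOWER_BOUNDS, TMG_MOMENTS, TUG_MOMENTS, CohortSpec, generate_cohort
        from tugtmg.tug import BandConfig

        spec = CohortSpec(n_participants=26, tests_per_participant=8, seed=314)
        cohort = generate_cohort(spec)
        tug_items, tmg_groups = _cohort_inputs(cohort)
        tug_res, _ = segment_dataset(tug_items, BandConfig())
        tmg_par, _ = extract_dataset(tmg_groups)
        assert len(tug_res) == 208
        table = descriptive_table(tug_res, tmg_par)

        m, sd = TUG_MOMENTS["sit_up"]
        gen_mean = truncnorm.mean((1.0 - m) / sd, 4.0, loc=m, scale=sd)
        pooled = table[table.variable == "sit_up"].iloc[0]["mean"]
        participant_means = tug_res.groupby("participant_id")["sit_up_s"].mean()
        se = participant_means.std(ddof=1) / np.sqrt(len(participant_means))
        assert abs(pooled - gen_mean) <= 2 * se

        m, sd = TMG_MOMENTS["VM"]["Td"]
        gen_mean = truncnorm.mean((TMG_LOWER_BOUNDS["Td"] - m) / sd, 4.0, loc=m, scale=sd)
        vm = tmg_par[tmg_par.muscle == "VM"]["Td_ms"]
        assert abs(vm.mean() - gen_mean) <= 2 * vm.std(ddof=1) / np.sqrt(len(vm))


class TestExportPlotData:
    def test_no_significant_pairs_no_scatter_files(self, tmp_path):
        tug, tmg = toy_dataset(n=6)
        records, _ = build_participant_records(tug, tmg)
        table = correlation_table(records)
        table["sig_raw"] = False
        table["sig_adj"] = False
        written = export_plot_data(records, table, tmp_path)
        assert written["scatter"] == []
        assert (tmp_path / "boxplot_subtasks.csv").exists()

    def test_scatter_points_and_exact_ols_fit(self, tmp_path):
        tug, tmg = toy_dataset(n=3)
        records, _ = build_participant_records(tug, tmg)
        records["VM_Td"] = [1.0, 2.0, 3.0]
        records["sit_up_s"] = [1.0, 2.0, 3.0]
        table = correlation_table(records)
        table["sig_raw"] = (table.muscle == "VM") & (table.parameter == "Td") & (
            table.subtask == "sit_up"
        )
        written = export_plot_data(records, table, tmp_path)
        assert len(written["scatter"]) == 1
        pts = pd.read_csv(written["scatter"][0])
        assert len(pts) == 3
        reg = pd.read_csv(written["regressions"])
        assert reg.iloc[0]["slope"] == pytest.approx(1.0)
        assert reg.iloc[0]["intercept"] == pytest.approx(0.0, abs=1e-12)


class TestCopulaInjection:
    def test_injected_target_recovered_without_bias(self, rng):
        """Latent-level check: the rank-correlation conversion r = 2 sin(pi rho/6)
        produces unbiased Spearman estimates at the study's sample size."""
        from scipy.stats import rankdata

        target = 0.8
        r_lat = 2 * math.sin(math.pi * target / 6)
        chol = np.linalg.cholesky(np.array([[1.0, r_lat], [r_lat, 1.0]]))
        est = []
        for _ in range(500):
            z = rng.standard_normal((23, 2)) @ chol.T
            est.append(np.corrcoef(rankdata(z[:, 0]), rankdata(z[:, 1]))[0, 1])
        assert abs(np.mean(est) - target) < 0.05
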