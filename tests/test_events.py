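import numpy as np
import pandas as pd
import pytest

from auxospore import (
    AnalysisConfig,
    MagDataset,
    MagTable,
    SimConfig,
    audit_controls,
    calibrate_thresholds,
    call_events,
    call_marker_expression,
    filter_mag_samples,
    mag_tpm,
    percentile_threshold,
    simulate_mag_dataset,
    simulate_multispecies,
    summarize_events,
    thresholds_from_pooled,
    tier_sweep,
)
from auxospore.discovery import MarkerPanel


def make_dataset(cells, clade="raphid_pennate"):
    """MagDataset for one MAG from {sample: {gene: count}} plus lengths."""
    genes = sorted({g for c in cells.values() for g in c})
    samples = sorted(cells)
    counts = np.array([[cells[s].get(g, 0.0) for s in samples] for g in genes])
    table = MagTable(gene_ids=np.array(genes),
                     lengths=np.full(len(genes), 1000.0), counts=counts)
    mag_meta = pd.DataFrame({"clade": [clade], "genus": ["Chaetoceros"]},
                            index=pd.Index(["MAG1"], name="mag_id"))
    sample_meta = pd.DataFrame({
        "station": [f"st{i}" for i in range(len(samples))],
        "depth": ["SRF"] * len(samples),
        "size_fraction": ["0.8-5"] * len(samples),
    }, index=pd.Index(samples, name="sample_id"))
    return MagDataset(mags={"MAG1": table}, sample_ids=samples,
                      mag_meta=mag_meta, sample_meta=sample_meta)


class TestMagFilter:
    @pytest.mark.parametrize("reads,genes,kept", [
        (9_999, 1_500, False),   # just under the read bound
        (10_000, 1_000, True),   # at both bounds (strict "less than" reading)
        (50_000, 999, False),    # enough reads, too few genes
    ])
    def test_coverage_boundaries(self, reads, genes, kept):
        per_gene = reads / genes
        counts = np.zeros((1600, 1))
        counts[:genes, 0] = per_gene
        ds = MagDataset(
            mags={"MAG1": MagTable(
                gene_ids=np.array([f"g{i}" for i in range(1600)]),
                lengths=np.full(1600, 1000.0), counts=counts)},
            sample_ids=["s1"],
            mag_meta=pd.DataFrame({"clade": ["centric"], "genus": ["x"]},
                                  index=pd.Index(["MAG1"], name="mag_id")),
            sample_meta=pd.DataFrame({"station": ["st1"], "depth": ["SRF"],
                                      "size_fraction": ["0.8-5"]},
                                     index=pd.Index(["s1"], name="sample_id")),
        )
        out = filter_mag_samples(ds)
        assert bool(out["kept"].iloc[0]) is kept


class TestMagTpm:
    def test_single_gene(self):
        assert mag_tpm([5.0], [1000.0])[0] == pytest.approx(1e6)

    def test_scale_invariance(self):
        a = mag_tpm([10.0, 10.0], [1000.0, 2000.0])
        b = mag_tpm([20.0, 20.0], [1000.0, 2000.0])
        assert np.allclose(a, b)
        assert a[0] == pytest.approx(666666.67, rel=1e-6)

    def test_zero_reads_error(self):
        with pytest.raises(ValueError, match="zero"):
            mag_tpm([0.0], [1000.0])


class TestThresholds:
    def test_percentile_of_1_to_100(self):
        assert percentile_threshold(np.arange(1, 101), 95.0) == pytest.approx(95.05)

    def test_constant_vector(self):
        assert percentile_threshold([4.2] * 10) == pytest.approx(4.2)

    def test_matches_sort_interpolate_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            v = rng.lognormal(3, 1, int(rng.integers(5, 60)))
            x = np.sort(v)
            h = (x.size - 1) * 0.95
            lo = int(np.floor(h))
            expected = x[lo] + (h - lo) * (x[min(lo + 1, x.size - 1)] - x[lo])
            assert percentile_threshold(v) == pytest.approx(expected)

    def test_adding_low_values_never_exceeds_max(self):
        v = list(np.arange(1.0, 101.0))
        t0 = percentile_threshold(v)
        v += [float(x) for x in np.linspace(0, t0 - 1, 37)]
        assert percentile_threshold(v) <= max(v)

    def test_calibrated_from_reference_matrices(self, small_experiment):
        exp = small_experiment
        fam = exp.truth.marker_families[0]
        thr = calibrate_thresholds(
            exp.matrices, exp.families, {"M1": fam}, AnalysisConfig()
        )
        assert thr.loc["M1", "threshold"] > 0
        # matches pooling TPM of member genes over vegetative samples by hand
        from auxospore import tpm_table
        pooled = []
        for sp, m in exp.matrices.items():
            veg = m.samples_where(condition_class="vegetative_control")
            tpm = tpm_table(m.subset_samples(veg))
            genes = exp.families.genes_in(fam, sp)
            pooled.extend(tpm.loc[[g for g in genes if g in tpm.index]]
                          .to_numpy().ravel())
        assert thr.loc["M1", "threshold"] == pytest.approx(
            np.percentile(pooled, 95)
        )

    def test_family_missing_everywhere_errors(self, small_experiment):
        with pytest.raises(ValueError, match="no member"):
            calibrate_thresholds(small_experiment.matrices,
                                 small_experiment.families,
                                 {"M1": "not_a_family"})


class TestMarkerExpressionRule:
    thresholds = pd.Series({"M1": 100.0})
    config = AnalysisConfig()

    def call(self, tpm_val, reads):
        tpm = pd.Series({"g1": tpm_val, "hk": 1e6 - tpm_val})
        counts = pd.Series({"g1": reads, "hk": 1e4})
        return call_marker_expression(tpm, counts, {"g1": "M1"},
                                      self.thresholds, self.config)["M1"]

    def test_one_read_insufficient(self):
        assert self.call(500.0, 1) is False

    def test_tpm_at_threshold_insufficient(self):
        assert self.call(100.0, 5) is False

    def test_above_threshold_two_reads(self):
        assert self.call(100.1, 2) is True

    def test_missing_gene_treated_as_zero(self):
        flags = call_marker_expression(
            pd.Series({"hk": 1e6}), pd.Series({"hk": 100}),
            {"absent": "M1"}, self.thresholds, self.config,
        )
        assert flags["M1"] is False


def cell(spo11_tpm, marker_tpms, depth=50_000):
    """One MAG x sample cell as {gene: count}: 2000 hk genes + markers."""
    genes = {f"hk{i}": depth / 2000.0 for i in range(2000)}
    genes["spo11"] = spo11_tpm / 1e6 * depth
    for i, t in enumerate(marker_tpms):
        genes[f"mk{i + 1}"] = t / 1e6 * depth
    return genes


class TestCallEvents:
    assignments = pd.DataFrame({
        "mag_id": ["MAG1"] * 5,
        "gene_id": ["spo11", "mk1", "mk2", "mk3", "mk4"],
        "marker_label": ["SPO11-2", "M1", "M2", "M3", "M4"],
    })
    thresholds = pd.Series(
        {"SPO11-2": 100.0, "M1": 100.0, "M2": 100.0, "M3": 100.0, "M4": 100.0},
        name="threshold",
    )

    def test_spo11_plus_two_markers_is_event(self):
        ds = make_dataset({"s1": cell(500.0, [500.0, 500.0, 10.0, 10.0])})
        calls = call_events(ds, self.assignments, self.thresholds)
        row = calls.iloc[0]
        assert row["is_event"] and row["tier"] == 2
        assert row["passing_markers"] == "M1;M2"

    def test_spo11_failing_blocks_event(self):
        ds = make_dataset({"s1": cell(10.0, [500.0] * 4)})
        calls = call_events(ds, self.assignments, self.thresholds)
        row = calls.iloc[0]
        assert not row["is_event"] and row["tier"] == 4

    def test_event_counts_monotone_in_comarker_requirement(self):
        rng = np.random.default_rng(1)
        cells = {
            f"s{i}": cell(float(rng.uniform(0, 600)),
                          list(rng.uniform(0, 600, 4)))
            for i in range(12)
        }
        ds = make_dataset(cells)
        calls = call_events(ds, self.assignments, self.thresholds)
        sweep = tier_sweep(calls)
        assert (np.diff(sweep["n_events"]) <= 0).all()
        # nestedness of event sets as the requirement rises
        prev = None
        for k in (1, 2, 3, 4):
            cur = set(calls.loc[calls["spo11_status"] & (calls["tier"] >= k),
                                "sample_id"])
            if prev is not None:
                assert cur <= prev
            prev = cur

    def test_uniform_count_rescaling_invariance(self):
        base = cell(500.0, [500.0, 500.0, 10.0, 10.0])
        doubled = {g: 2 * c for g, c in base.items()}
        c1 = call_events(make_dataset({"s1": base}), self.assignments, self.thresholds)
        c2 = call_events(make_dataset({"s1": doubled}), self.assignments, self.thresholds)
        assert c1.iloc[0]["tier"] == c2.iloc[0]["tier"]
        assert c1.iloc[0]["is_event"] == c2.iloc[0]["is_event"]

    def test_other_clade_excluded(self):
        ds = make_dataset({"s1": cell(500.0, [500.0] * 4)}, clade="other")
        calls = call_events(ds, self.assignments, self.thresholds)
        assert calls.empty

    def test_lenient_spo11_mode(self):
        ds = make_dataset({"s1": cell(50.0, [500.0, 500.0, 10.0, 10.0])})
        strict = call_events(ds, self.assignments, self.thresholds)
        lenient = call_events(ds, self.assignments, self.thresholds,
                              AnalysisConfig(lenient_spo11=True))
        assert not strict.iloc[0]["is_event"]
        assert lenient.iloc[0]["is_event"]


class TestAuditControls:
    def test_no_exceedance_gives_zero_cases(self):
        ds = make_dataset({"s1": cell(10.0, [10.0] * 4)})
        assignments = pd.DataFrame({
            "mag_id": ["MAG1"] * 5,
            "gene_id": ["spo11", "mk1", "mk2", "mk3", "mk4"],
            "marker_label": ["PC", "C1", "C2", "C3", "C4"],
        })
        thr = pd.Series({"PC": 100.0, "C1": 100.0, "C2": 100.0,
                         "C3": 100.0, "C4": 100.0})
        _, n = audit_controls(ds, assignments, thr)
        assert n == 0

    def test_pc_plus_two_controls_is_one_case(self):
        ds = make_dataset({"s1": cell(500.0, [500.0, 500.0, 10.0, 10.0])})
        assignments = pd.DataFrame({
            "mag_id": ["MAG1"] * 5,
            "gene_id": ["spo11", "mk1", "mk2", "mk3", "mk4"],
            "marker_label": ["PC", "C1", "C2", "C3", "C4"],
        })
        thr = pd.Series({"PC": 100.0, "C1": 100.0, "C2": 100.0,
                         "C3": 100.0, "C4": 100.0})
        _, n = audit_controls(ds, assignments, thr)
        assert n == 1


class TestSummaries:
    def test_no_events_all_zero(self):
        calls = pd.DataFrame(columns=["mag_id", "sample_id", "mag_clade",
                                      "panel_used", "spo11_status",
                                      "passing_markers", "tier", "is_event"])
        sample_meta = pd.DataFrame({"station": ["st1"]},
                                   index=pd.Index(["s1"], name="sample_id"))
        mag_meta = pd.DataFrame({"genus": ["x"], "clade": ["centric"]},
                                index=pd.Index(["MAG1"], name="mag_id"))
        s = summarize_events(calls, sample_meta, mag_meta)
        assert s["n_cases"] == 0 and s["station_fraction"] == 0.0

    def test_toy_fractions(self):
        calls = pd.DataFrame({
            "mag_id": ["A", "A", "B"], "sample_id": ["s1", "s2", "s1"],
            "mag_clade": ["centric"] * 3, "panel_used": ["centric"] * 3,
            "spo11_status": [True] * 3, "passing_markers": ["M3;SIG1"] * 3,
            "tier": [2] * 3, "is_event": [True] * 3,
        })
        sample_meta = pd.DataFrame(
            {"station": [f"st{i}" for i in (1, 2, 3, 4, 5)]},
            index=pd.Index([f"s{i}" for i in (1, 2, 3, 4, 5)], name="sample_id"),
        )
        mag_meta = pd.DataFrame({"genus": ["g1"] * 4, "clade": ["centric"] * 4},
                                index=pd.Index(list("ABCD"), name="mag_id"))
        s = summarize_events(calls, sample_meta, mag_meta)
        assert s["n_cases"] == 3
        assert s["station_fraction"] == pytest.approx(0.4)
        assert s["mag_fraction"] == pytest.approx(0.5)
        # case counts equal brute-force enumeration over the event list
        assert s["n_cases"] == sum(calls["is_event"])


class TestSimulatedRecovery:
    def test_single_seed_sensitivity_and_specificity(self):
        study = simulate_mag_dataset(SimConfig(), seed=17)
        thr = thresholds_from_pooled(study.calibration)
        calls = call_events(study.dataset, study.assignments, thr)
        kept = set(zip(calls["mag_id"], calls["sample_id"]))
        truth = study.truth.sexual_cells & kept
        called = set(zip(calls.loc[calls["is_event"], "mag_id"],
                         calls.loc[calls["is_event"], "sample_id"]))
        tp = len(called & truth)
        fp = len(called - study.truth.sexual_cells)
        assert tp / max(len(truth), 1) >= 0.9
        assert fp / max(len(kept) - len(truth), 1) <= 0.01

    def test_low_depth_cells_are_generated_and_removed(self):
        study = simulate_mag_dataset(SimConfig(), seed=17)
        stats = filter_mag_samples(study.dataset)
        assert (~stats["kept"]).any()
        assert (stats.loc[~stats["kept"], "total_reads"] < 10_000).any()
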