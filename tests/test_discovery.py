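import numpy as np
import pandas as pd
import pytest

from auxospore import (
    AnalysisConfig,
    GeneFamilyTable,
    SimConfig,
    discover_markers,
    select_control_markers,
    select_curated_markers,
    simulate_atlas,
    simulate_multispecies,
    specificity_filter,
    tpm_table,
)
from auxospore.de import StagewiseDEResult


def toy_stagewise(rows):
    """StagewiseDEResult from (gene, stage, log2fc, significant) tuples."""
    stages = pd.DataFrame(rows, columns=["gene_id", "stage", "log2fc", "significant"])
    stages["p_raw"] = np.where(stages["significant"], 1e-6, 0.5)
    stages["p_holm"] = stages["p_raw"]
    stages["direction"] = np.where(stages["log2fc"] > 0, "up", "down")
    genes = pd.DataFrame(
        {"p_aggregate": 0.0, "q_screen": 0.0,
         "passes_screen": True},
        index=pd.Index(sorted(set(stages["gene_id"])), name="gene_id"),
    )
    return StagewiseDEResult(genes=genes, stages=stages, alpha=0.05,
                             alpha_conf=0.01, n_pass=len(genes), n_tested=len(genes))


@pytest.fixture()
def toy_families():
    membership = pd.DataFrame({
        "gene_id": [f"{sp}_{fam}" for fam in ("famA", "famB", "famC")
                    for sp in ("sp1", "sp2", "sp3", "sp4")],
        "family_id": [fam for fam in ("famA", "famB", "famC") for _ in range(4)],
        "species": ["sp1", "sp2", "sp3", "sp4"] * 3,
    })
    info = pd.DataFrame({"diatom_specific": [True, True, True]},
                        index=["famA", "famB", "famC"])
    return GeneFamilyTable(membership=membership, family_info=info)


class TestDiscoverSteps:
    def test_family_in_two_species_excluded_step1(self, toy_families):
        expressed = {
            "sp1": {"sp1_famA", "sp1_famB", "sp1_famC"},
            "sp2": {"sp2_famA", "sp2_famB", "sp2_famC"},
            "sp3": {"sp3_famB", "sp3_famC"},
            "sp4": {"sp4_famB", "sp4_famC"},
        }
        stagewise = {
            sp: toy_stagewise([(g, "S", 3.0, True) for g in genes])
            for sp, genes in expressed.items()
        }
        out = discover_markers(toy_families, stagewise, expressed)
        assert out.loc["famA", "status"] == "excluded_step1"
        assert out.loc["famB", "status"] == "ranked"

    def test_downregulated_member_excluded_step2(self, toy_families):
        expressed = {sp: {f"{sp}_famA", f"{sp}_famB"} for sp in
                     ("sp1", "sp2", "sp3", "sp4")}
        stagewise = {}
        for sp in expressed:
            rows = [(f"{sp}_famA", "S", 3.0, True),
                    (f"{sp}_famB", "S", 3.0, True)]
            if sp == "sp3":
                rows.append((f"{sp}_famB", "P", -2.0, True))
            stagewise[sp] = toy_stagewise(rows)
        out = discover_markers(toy_families, stagewise, expressed)
        assert out.loc["famB", "status"] == "excluded_step2"
        assert out.loc["famA", "status"] == "ranked"

    def test_nonsignificant_expressed_member_excluded_step2(self, toy_families):
        expressed = {sp: {f"{sp}_famA"} for sp in ("sp1", "sp2", "sp3", "sp4")}
        stagewise = {
            sp: toy_stagewise([(f"{sp}_famA", "S", 3.0, sp != "sp2")])
            for sp in expressed
        }
        out = discover_markers(toy_families, stagewise, expressed)
        assert out.loc["famA", "status"] == "excluded_step2"

    def test_rank_score_pools_significant_observations(self, toy_families):
        expressed = {sp: {f"{sp}_famA"} for sp in ("sp1", "sp2", "sp3", "sp4")}
        stagewise = {
            sp: toy_stagewise([(f"{sp}_famA", "S", lfc, True)])
            for sp, lfc in zip(expressed, (2.0, 4.0, 6.0, 8.0))
        }
        out = discover_markers(toy_families, stagewise, expressed)
        assert out.loc["famA", "rank_score"] == pytest.approx(5.0)

    def test_empty_family_table_errors(self):
        fams = GeneFamilyTable(
            membership=pd.DataFrame(columns=["gene_id", "family_id", "species"]),
            family_info=pd.DataFrame(columns=["diatom_specific"]),
        )
        with pytest.raises(ValueError, match="empty"):
            discover_markers(fams, {}, {"sp1": set(), "sp2": set(), "sp3": set()})

    def test_order_invariance(self, small_experiment, small_pipeline):
        exp, pl = small_experiment, small_pipeline
        out1 = discover_markers(exp.families, pl["stagewise"], pl["expressed"])
        shuffled = GeneFamilyTable(
            membership=exp.families.membership.sample(frac=1, random_state=1),
            family_info=exp.families.family_info.sample(frac=1, random_state=2),
        )
        out2 = discover_markers(shuffled, pl["stagewise"], pl["expressed"])
        ranked1 = out1[out1.status == "ranked"].index.tolist()
        ranked2 = out2[out2.status == "ranked"].index.tolist()
        assert ranked1 == ranked2


class TestPlantedRecovery:
    def test_planted_families_take_top_ranks(self, small_experiment, small_pipeline):
        exp, pl = small_experiment, small_pipeline
        out = discover_markers(exp.families, pl["stagewise"], pl["expressed"])
        ranked = out[out.status == "ranked"]
        assert set(ranked.index[:3]) == set(exp.truth.marker_families)
        assert not set(exp.truth.control_families) & set(ranked.index)

    def test_every_exclusion_carries_a_step(self, small_experiment, small_pipeline):
        exp, pl = small_experiment, small_pipeline
        out = discover_markers(exp.families, pl["stagewise"], pl["expressed"])
        excluded = out[out.status.str.startswith("excluded")]
        assert set(excluded.status) <= {"excluded_step1", "excluded_step2"}
        assert len(excluded) + (out.status == "ranked").sum() == len(out)


class TestSpecificityFilter:
    @pytest.fixture()
    def leaky_setup(self):
        from auxospore import (compute_cpm, filter_expressed, run_species_de,
                               stagewise_adjust)
        cfg = AnalysisConfig()
        sim = SimConfig(n_families=120, n_planted_markers=5, n_leaky_markers=2)
        exp = simulate_multispecies(sim, seed=21)
        stagewise, expressed = {}, {}
        for sp, m in exp.matrices.items():
            rec = run_species_de(m, sp, cfg)
            stagewise[sp] = stagewise_adjust(rec, cfg.fdr_alpha)
            expressed[sp] = set(filter_expressed(compute_cpm(m), cfg.min_cpm,
                                                 cfg.min_samples))
        cand = discover_markers(exp.families, stagewise, expressed, cfg)
        atlas = simulate_atlas(exp, sim)
        out = specificity_filter(cand, atlas, exp.matrices["sp1"], exp.families, cfg)
        return exp, out

    def test_leaky_families_fail_and_clean_pass(self, leaky_setup):
        exp, out = leaky_setup
        leaky = set(exp.truth.leaky_families)
        clean = set(exp.truth.marker_families) - leaky
        for fam in leaky & set(out.index[out.specificity.notna()]):
            assert out.loc[fam, "specificity"] == "fail"
        selected = set(out.index[out.status == "selected"])
        assert selected <= clean
        assert not selected & leaky

    def test_fold_separation_near_one_fails(self):
        # rule check on synthetic stats: atlas max == sexual mean
        cfg = AnalysisConfig()
        assert not ((50.0 <= cfg.max_nonsexual_tpm)
                    or (50.0 / (50.0 + 1e-3) >= cfg.min_fold_separation))

    def test_zero_atlas_expression_passes(self):
        cfg = AnalysisConfig()
        assert 0.0 <= cfg.max_nonsexual_tpm


class TestCuratedSelection:
    def test_expression_and_significance_required(self):
        candidates = pd.DataFrame({
            "gene_id": ["f1", "f2", "f3", "f4", "n1", "n2"],
            "family_id": ["SIG1", "DNAH9/11/17", "DNAH5/8", "DRC4", "null1", "null2"],
        })
        rows = [(g, "S", 4.0, True) for g in ("f1", "f2", "f3", "f4")]
        rows += [("n1", "S", 0.5, False), ("n2", "S", 0.2, False)]
        sw = toy_stagewise(rows)
        got = select_curated_markers(candidates, sw,
                                     expressed_sexual={"f1", "f2", "f3", "f4", "n1"})
        assert got == ["DNAH5/8", "DNAH9/11/17", "DRC4", "SIG1"]

    def test_unexpressed_candidate_dropped(self):
        candidates = pd.DataFrame({"gene_id": ["f1"], "family_id": ["SIG1"]})
        sw = toy_stagewise([("f1", "S", 4.0, True)])
        assert select_curated_markers(candidates, sw, expressed_sexual=set()) == []


class TestControlSelection:
    def build_families(self, copy_rows):
        membership, info_rows = [], []
        for fam, copies in copy_rows.items():
            info_rows.append({"family_id": fam, "diatom_specific": True})
            for sp, n in copies.items():
                for c in range(n):
                    membership.append({"gene_id": f"{sp}_{fam}_{c}",
                                       "family_id": fam, "species": sp})
        return GeneFamilyTable(
            membership=pd.DataFrame(membership),
            family_info=pd.DataFrame(info_rows).set_index("family_id"),
        )

    def test_eligibility_rules(self):
        fams = self.build_families({
            "target": {"sp1": 1, "sp2": 1, "sp3": 1, "sp4": 1},
            "good": {"sp1": 1, "sp2": 1, "sp3": 1},
            "two_dups": {"sp1": 2, "sp2": 2, "sp3": 1, "sp4": 1},
            "two_species": {"sp1": 1, "sp2": 1},
        })
        genes = fams.membership["gene_id"]
        rng = np.random.default_rng(0)
        tpm = pd.DataFrame(rng.uniform(5, 15, size=(len(genes), 4)),
                           index=genes, columns=list("abcd"))
        sw = {"sp1": toy_stagewise([("sp1_target_0", "S", 3.0, True)])}
        panel = select_control_markers(fams, sw, tpm, {"M1": "target"},
                                       reference_species=["sp1", "sp2", "sp3", "sp4"])
        assert panel.controls == {"C1": "good"}

    def test_upregulated_family_ineligible(self):
        fams = self.build_families({
            "target": {"sp1": 1, "sp2": 1, "sp3": 1},
            "up": {"sp1": 1, "sp2": 1, "sp3": 1},
            "flat": {"sp1": 1, "sp2": 1, "sp3": 1},
        })
        genes = fams.membership["gene_id"]
        tpm = pd.DataFrame(10.0, index=genes, columns=list("ab"))
        sw = {"sp1": toy_stagewise([("sp1_up_0", "S", 5.0, True),
                                    ("sp1_flat_0", "S", 0.1, False)])}
        panel = select_control_markers(fams, sw, tpm, {"M1": "target"})
        assert panel.controls == {"C1": "flat"}

    def test_matching_equals_bruteforce_nearest_neighbour(self):
        rng = np.random.default_rng(8)
        copy_rows = {f"fam{i}": {"sp1": 1, "sp2": 1, "sp3": 1} for i in range(12)}
        copy_rows["t1"] = copy_rows["t2"] = {"sp1": 1, "sp2": 1, "sp3": 1}
        fams = self.build_families(copy_rows)
        genes = fams.membership["gene_id"]
        tpm = pd.DataFrame(rng.lognormal(2, 1, size=(len(genes), 5)),
                           index=genes, columns=list("abcde"))
        sw = {"sp1": toy_stagewise([("sp1_t1_0", "S", 3.0, True)])}
        targets = {"M1": "t1", "M2": "t2"}
        panel = select_control_markers(fams, sw, tpm, targets)

        from auxospore.discovery import _family_expression_stats
        stats = _family_expression_stats(fams, tpm, 1e-3)
        eligible = [f for f in stats.index if f.startswith("fam")] + ["t2"]
        eligible = [f for f in eligible if f not in targets.values()]
        used = set()
        for label, fam in targets.items():
            t = stats.loc[fam]
            dists = {
                c: np.hypot(t["log_mean_tpm"] - stats.loc[c, "log_mean_tpm"],
                            t["cv"] - stats.loc[c, "cv"])
                for c in eligible if c not in used
            }
            best = min(sorted(dists), key=lambda c: dists[c])
            used.add(best)
            ctrl_label = [k for k, v in panel.matched_to.items() if v == label][0]
            assert panel.controls[ctrl_label] == best

    def test_shortfall_raises(self):
        fams = self.build_families({"target": {"sp1": 1, "sp2": 1, "sp3": 1}})
        tpm = pd.DataFrame(10.0, index=fams.membership["gene_id"], columns=["a"])
        with pytest.raises(ValueError, match="eligible"):
            select_control_markers(fams, {}, tpm, {"M1": "target"})
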