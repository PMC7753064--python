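"""Mark/methylation profiling, subgroup voting and additive-effect analysis."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from _oracles import subgroup_by_votes
from epishift.integrate import (
    ALL_MARKS,
    ExpressionTable,
    GeneEpiProfile,
    MarkAlteration,
    MethylPosition,
    additive_effect,
    build_gene_profiles,
    classify_subgroup,
    methylation_expression_correlation,
    pairwise_mark_correlation,
    select_candidates,
    stratified_spearman,
    summarize_methylation,
)
from epishift.intervals import GeneModel, GenomicInterval
from epishift.synthgen import simulate_methylation_expression_pairs


def dmp(i, delta, cgi=False, chrom="chr1", pos=None):
    return MethylPosition(
        cpg_id=f"cg{i}", chrom=chrom, pos=pos if pos is not None else i, delta_beta=delta, q=0.01, in_cgi=cgi
    )


def make_expr(fc_by_gene, n_patients=5, base=4.0, rng=None):
    """Paired FPKM table with exact per-gene tumor/normal log2 offsets."""
    genes = list(fc_by_gene)
    pairs = [(f"P{i}_T", f"P{i}_N") for i in range(n_patients)]
    data = {}
    for i in range(n_patients):
        jitter = 0.0 if rng is None else rng.normal(0, 0.05, len(genes))
        data[f"P{i}_T"] = [
            2.0 ** (base + fc_by_gene[g] + (jitter[k] if rng is not None else 0))
            for k, g in enumerate(genes)
        ]
        data[f"P{i}_N"] = [2.0**base] * len(genes)
    return ExpressionTable(fpkm=pd.DataFrame(data, index=genes), pairs=pairs)


class TestSummarizeMethylation:
    def test_yates_statistic_matches_hand_formula(self):
        dmps = (
            [dmp(i, -0.3) for i in range(8)]
            + [dmp(8, -0.3, cgi=True)]
            + [dmp(9, 0.3, cgi=True)]
        )
        res = summarize_methylation(dmps)
        assert res["n_hypo"] == 9 and res["n_hyper"] == 1
        assert res["cgi_table"].tolist() == [[8, 1], [0, 1]]
        table = np.array([[8, 1], [0, 1]])
        exp = np.outer(table.sum(1), table.sum(0)) / table.sum()
        hand = (((np.abs(table - exp) - 0.5).clip(0) ** 2) / exp).sum()
        assert res["chisq_yates"]["statistic"] == pytest.approx(hand)

    def test_one_sided_table_flagged(self):
        res = summarize_methylation([dmp(i, -0.2, cgi=i % 2 == 0) for i in range(6)])
        assert res["chisq_yates"] is None
        assert res["n_hypo"] == 6

    def test_empty_input(self):
        res = summarize_methylation([])
        assert res["n_total"] == 0 and res["chisq_yates"] is None

    def test_zero_delta_counted_separately(self):
        res = summarize_methylation([dmp(0, 0.0), dmp(1, -0.1), dmp(2, 0.2, cgi=True)])
        assert res["n_zero"] == 1
        assert res["cgi_table"].sum() == 2


class TestBuildGeneProfiles:
    @pytest.fixture
    def gene(self):
        return GeneModel("G1", "chr1", "+", 10_000, 20_000, exons=((10_000, 20_000),))

    def test_single_histone_region(self, gene):
        alt = MarkAlteration(
            "H3K4me3", GenomicInterval("chr1", 9_000, 9_500), "up", stat=1.5
        )
        (prof,) = build_gene_profiles([alt], [], [gene])
        assert prof.marks == {"H3K4me3": "up"} and prof.n_marks == 1

    def test_histone_plus_hypo_dmps(self, gene):
        alt = MarkAlteration(
            "H3K27ac", GenomicInterval("chr1", 9_000, 9_500), "up", stat=1.0
        )
        dmps = [dmp(i, -0.3, pos=9_000 + i) for i in range(3)]
        (prof,) = build_gene_profiles([alt], dmps, [gene])
        assert prof.marks == {"H3K27ac": "up", "mC": "down"}
        assert prof.n_marks == 2

    def test_equal_bp_conflict_drops_mark(self, gene):
        up = MarkAlteration("H3K4me1", GenomicInterval("chr1", 9_000, 9_400), "up")
        down = MarkAlteration("H3K4me1", GenomicInterval("chr1", 10_500, 10_900), "down")
        with pytest.warns(UserWarning, match="tied"):
            profiles = build_gene_profiles([up, down], [], [gene])
        assert profiles == []

    def test_majority_direction_by_bp(self, gene):
        up = MarkAlteration("H3K4me1", GenomicInterval("chr1", 9_000, 9_800), "up")
        down = MarkAlteration("H3K4me1", GenomicInterval("chr1", 10_500, 10_900), "down")
        (prof,) = build_gene_profiles([up, down], [], [gene])
        assert prof.marks["H3K4me1"] == "up"


class TestClassifySubgroup:
    @pytest.mark.parametrize(
        "marks, expected",
        [
            ({"H3K4me3": "up", "mC": "down"}, "active"),
            ({"H3K4me1": "down", "H3K27me3": "up"}, "repressive"),
            ({"H3K27ac": "up", "H3K27me3": "up"}, "poised"),
        ],
    )
    def test_named_examples(self, marks, expected):
        assert classify_subgroup(GeneEpiProfile("g", marks=dict(marks))) == expected

    def test_empty_profile_rejected(self):
        with pytest.raises(ValueError):
            classify_subgroup(GeneEpiProfile("g"))

    def test_exhaustive_partition_matches_voting_oracle(self):
        for assignment in itertools.product([None, "up", "down"], repeat=6):
            marks = {
                m: d for m, d in zip(ALL_MARKS, assignment) if d is not None
            }
            if not marks:
                continue
            got = classify_subgroup(GeneEpiProfile("g", marks=marks))
            assert got == subgroup_by_votes(marks)


class TestAdditiveEffect:
    def test_tumor_equals_normal_gives_zero(self):
        profiles = [
            GeneEpiProfile("g1", marks={"H3K4me3": "up"}),
            GeneEpiProfile("g2", marks={"H3K27me3": "up"}),
        ]
        expr = make_expr({"g1": 0.0, "g2": 0.0})
        table = additive_effect(profiles, expr)
        vals = table.dropna(subset=["mean_log2fc"])
        assert (vals["mean_log2fc"].abs() < 1e-9).all()
        assert vals["paired_t"].isna().all()  # zero differences suppress the test

    def test_paired_t_hand_value(self):
        # patient-level paired differences (1, 2, 3) -> t = 3.464, df 2
        genes = ["g1", "g2"]
        pairs = [(f"P{i}_T", f"P{i}_N") for i in range(3)]
        normal = np.array([4.0, 4.0])
        data = {}
        for i, d in enumerate([1.0, 2.0, 3.0]):
            data[f"P{i}_T"] = 2.0 ** (normal + d)
            data[f"P{i}_N"] = 2.0**normal
        expr = ExpressionTable(pd.DataFrame(data, index=genes), pairs)
        profiles = [GeneEpiProfile(g, marks={"H3K4me3": "up"}) for g in genes]
        table = additive_effect(profiles, expr)
        row = table[(table.group == "1") & (table.subgroup == "active")].iloc[0]
        # the FPKM pseudocount perturbs log2 values in the 4th decimal
        assert row["paired_t"] == pytest.approx(2.0 / (1.0 / np.sqrt(3)), rel=1e-3)

    def test_group_sizes_conserve_genes(self, rng):
        profiles = []
        for i in range(40):
            n = int(rng.integers(1, 7))
            marks = {m: rng.choice(["up", "down"]) for m in list(ALL_MARKS)[:n]}
            profiles.append(GeneEpiProfile(f"g{i}", marks=marks))
        expr = make_expr({f"g{i}": 0.0 for i in range(40)})
        table = additive_effect(profiles, expr)
        assert table["n_genes"].sum() == 40


class TestSelectCandidates:
    def make(self, fc_active, fc_poised=2.0):
        profiles = [
            GeneEpiProfile("act", marks={"H3K4me3": "up"}),
            GeneEpiProfile("pois", marks={"H3K4me3": "up", "H3K27me3": "up"}),
            GeneEpiProfile("rep", marks={"H3K27me3": "up"}),
        ]
        rng = np.random.default_rng(7)
        expr = make_expr(
            {"act": fc_active, "pois": fc_poised, "rep": -1.6}, rng=rng
        )
        return profiles, expr

    def test_active_gene_above_thresholds_is_retained(self):
        profiles, expr = self.make(1.5)
        got = select_candidates(profiles, expr)
        assert got["overexpressed"] == ["act"]
        assert got["underexpressed"] == ["rep"]

    def test_fold_change_boundary_excludes(self):
        profiles, expr = self.make(0.9)
        assert select_candidates(profiles, expr)["overexpressed"] == []

    def test_poised_never_screened(self):
        profiles, expr = self.make(1.5, fc_poised=3.0)
        assert "pois" not in select_candidates(profiles, expr)["overexpressed"]

    def test_too_few_pairs_rejected(self):
        profiles = [GeneEpiProfile("act", marks={"H3K4me3": "up"})]
        expr = make_expr({"act": 2.0}, n_patients=2)
        with pytest.raises(ValueError, match="insufficient pairing"):
            select_candidates(profiles, expr)


class TestMethylationExpressionCorrelation:
    def test_perfect_anticorrelation(self):
        fcs = {f"g{i}": v for i, v in enumerate([-1.0, -0.5, 0.2, 0.8, 1.5])}
        expr = make_expr(fcs)
        db = {g: -v for g, v in fcs.items()}
        res = methylation_expression_correlation(db, expr)
        assert res["r_overall"] == pytest.approx(-1.0)
        assert res["fraction_negative"] == 1.0

    def test_planted_bivariate_normal_recovery(self):
        rng = np.random.default_rng(5)
        rs = []
        for _ in range(100):
            db, fc = simulate_methylation_expression_pairs(2000, -0.4, rng)
            rs.append(stats.pearsonr(db, fc)[0])
        assert abs(np.mean(rs) - (-0.4)) < 0.06

    def test_zero_variance_flagged(self):
        expr = make_expr({"g0": 0.5, "g1": 0.5, "g2": 0.5})
        res = methylation_expression_correlation({"g0": 0.1, "g1": 0.1, "g2": 0.1}, expr)
        assert res["flag"] == "zero-variance input"


class TestStratifiedSpearman:
    def test_monotone_and_reversed(self):
        profiles, fcs = [], {}
        for i in range(8):
            stat = 0.2 * (i + 1)
            profiles.append(
                GeneEpiProfile(
                    f"g{i}", marks={"H3K4me3": "up"}, stats={"H3K4me3": stat}
                )
            )
            fcs[f"g{i}"] = stat  # perfectly monotone with the stat
        table = stratified_spearman(profiles, make_expr(fcs))
        row = table[(table["mark"] == "H3K4me3") & (table["stratum"] == "1 mark")]
        assert row["rho"].iloc[0] == pytest.approx(1.0)
        rev = stratified_spearman(
            profiles, make_expr({g: -v for g, v in fcs.items()})
        )
        row = rev[(rev["mark"] == "H3K4me3") & (rev["stratum"] == "1 mark")]
        assert row["rho"].iloc[0] == pytest.approx(-1.0)

    def test_small_stratum_suppressed(self):
        profiles = [
            GeneEpiProfile("g0", marks={"mC": "down"}, stats={"mC": -0.2})
        ]
        table = stratified_spearman(profiles, make_expr({"g0": 0.5}))
        assert table["rho"].isna().all()

    def test_attenuated_multimark_methylation(self, rng):
        """mC's correlation with expression weakens when other marks co-occur."""
        profiles, fcs = [], {}
        for i in range(120):
            db = float(rng.normal(0, 0.25))
            if i < 60:
                profiles.append(
                    GeneEpiProfile(f"s{i}", marks={"mC": "down"}, stats={"mC": db})
                )
                fcs[f"s{i}"] = -2.0 * db + float(rng.normal(0, 0.1))
            else:
                profiles.append(
                    GeneEpiProfile(
                        f"m{i}",
                        marks={"mC": "down", "H3K4me3": "up"},
                        stats={"mC": db, "H3K4me3": 1.0},
                    )
                )
                fcs[f"m{i}"] = -0.2 * db + float(rng.normal(0, 0.8))
        table = stratified_spearman(profiles, make_expr(fcs)).set_index(
            ["mark", "stratum"]
        )
        assert abs(table.loc[("mC", "1 mark"), "rho"]) > abs(
            table.loc[("mC", ">1 mark"), "rho"]
        )


class TestPairwiseMarkCorrelation:
    @pytest.fixture
    def genes(self):
        return [
            GeneModel(f"g{i}", "chr1", "+", 50_000 * i + 10_000, 50_000 * i + 20_000,
                      exons=((50_000 * i + 10_000, 50_000 * i + 20_000),))
            for i in range(12)
        ]

    def _alts(self, genes, stat_fn_b, rng):
        alts = []
        for i, g in enumerate(genes):
            sa = float(rng.normal(1.0, 0.5))
            alts.append(
                MarkAlteration(
                    "H3K4me3",
                    GenomicInterval(g.chrom, g.tss - 500, g.tss + 500),
                    "up",
                    stat=sa,
                )
            )
            alts.append(
                MarkAlteration(
                    "H3K27ac",
                    GenomicInterval(g.chrom, g.tss - 400, g.tss + 600),
                    "up",
                    stat=stat_fn_b(sa, i),
                )
            )
        return alts

    def test_proportional_stats_give_r_one(self, genes, rng):
        alts = self._alts(genes, lambda sa, i: 2 * sa, rng)
        mat = pairwise_mark_correlation(alts, "promoter", genes)
        assert mat.loc["H3K4me3", "H3K27ac"] == pytest.approx(1.0)

    def test_independent_stats_masked(self, genes):
        rng = np.random.default_rng(3)
        alts = self._alts(genes, lambda sa, i: float(rng.normal()), rng)
        mat = pairwise_mark_correlation(alts, "promoter", genes)
        assert np.isnan(mat.loc["H3K4me3", "H3K27ac"]) or abs(
            mat.loc["H3K4me3", "H3K27ac"]
        ) < 1.0
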