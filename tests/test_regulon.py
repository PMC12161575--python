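import numpy as np
import pandas as pd
import pytest

from regumine.coexpression import CorrelationResult, correlation_pvalue
from regumine.genome import AnnotatedGenome
from regumine.regulon import (
    Regulon,
    anticorrelation_filter,
    assign_targets,
    expand_operons,
    group_loci,
    mannwhitney_one_sided_greater,
    regulon_statistics,
)


def _genome(genes, length=20_000):
    return AnnotatedGenome(
        contigs={"c1": "A" * length}, genes=pd.DataFrame(genes)
    )


def _corr(genes, matrix, n_samples=24):
    m = np.asarray(matrix, float)
    pcc = pd.DataFrame(m, index=genes, columns=genes)
    pvals = pd.DataFrame(correlation_pvalue(m, n_samples), index=genes, columns=genes)
    np.fill_diagonal(pvals.values, 0.0)
    return CorrelationResult(
        pcc=pcc, pvalues=pvals, n_samples=n_samples,
        mean_expression=pd.Series(np.ones(len(genes)), index=genes),
    )


def _locations(rows):
    df = pd.DataFrame(rows)
    if "best_score" not in df:
        df["best_score"] = 25.0
    return df


class TestAssignTargets:
    def test_divergent_site_yields_two_candidates(self):
        genome = _genome(
            [
                {"gene_id": "gL", "contig": "c1", "start": 1000, "end": 2000, "strand": "-"},
                {"gene_id": "gR", "contig": "c1", "start": 2500, "end": 3500, "strand": "+"},
            ]
        )
        locs = _locations(
            [{"contig": "c1", "start": 2240, "end": 2259, "windows": ("gL", "gR")}]
        )
        cands = assign_targets(locs, genome)
        assert set(cands["gene_id"]) == {"gL", "gR"}
        # distance from site to each start codon
        left = cands[cands["gene_id"] == "gL"].iloc[0]
        assert left["distance_to_start"] == 2240 - 2000

    def test_orphan_location_reported_not_dropped(self):
        genome = _genome(
            [{"gene_id": "g", "contig": "c1", "start": 1000, "end": 2000, "strand": "+"}]
        )
        cands = assign_targets(
            _locations([{"contig": "c1", "start": 9000, "end": 9019, "windows": ()}]),
            genome,
        )
        assert len(cands) == 1 and bool(cands.iloc[0]["orphan"])


class TestAnticorrelationFilter:
    @pytest.fixture
    def setup(self):
        genes = ["reg", "gA", "gB", "gC"]
        m = np.eye(4)
        m[0, 1] = m[1, 0] = -0.9   # clear pass
        m[0, 2] = m[2, 0] = 0.69   # positively correlated
        m[0, 3] = m[3, 0] = -0.43  # exact boundary
        corr = _corr(genes, m)
        cands = pd.DataFrame(
            [
                {"location": 0, "gene_id": "gA"},
                {"location": 1, "gene_id": "gB"},
                {"location": 2, "gene_id": "gC"},
                {"location": 3, "gene_id": "missing"},
            ]
        )
        return corr, cands

    def test_status_classes(self, setup):
        corr, cands = setup
        out = anticorrelation_filter(cands, corr, "reg")
        status = dict(zip(out["gene_id"], out["status"]))
        assert status["gA"] == "accepted"
        assert status["gB"] == "positively_correlated"
        assert status["gC"] == "not_significant"  # strict inequality at -0.43
        assert status["missing"] == "untested"

    def test_bh_adjustment_more_conservative(self, setup):
        corr, cands = setup
        raw = anticorrelation_filter(cands, corr, "reg", adjust=None)
        bh = anticorrelation_filter(cands, corr, "reg", adjust="bh")
        assert (bh["pvalue"].dropna() >= raw["pvalue"].dropna() - 1e-15).all()

    def test_unknown_regulator_rejected(self, setup):
        corr, cands = setup
        with pytest.raises(KeyError):
            anticorrelation_filter(cands, corr, "nope")


class TestExpandOperons:
    @pytest.fixture
    def chain_genome(self):
        return _genome(
            [
                {"gene_id": "g1", "contig": "c1", "start": 1000, "end": 2000, "strand": "+"},
                {"gene_id": "g2", "contig": "c1", "start": 2100, "end": 3000, "strand": "+"},
                {"gene_id": "g3", "contig": "c1", "start": 3600, "end": 4500, "strand": "+"},
            ]
        )

    def test_walk_stops_at_large_gap(self, chain_genome):
        genes = ["g1", "g2", "g3"]
        m = np.full((3, 3), 0.9)
        np.fill_diagonal(m, 1.0)
        corr = _corr(genes, m)
        targets = pd.DataFrame([{"gene_id": "g1"}])
        members, operons = expand_operons(
            targets, chain_genome, corr, max_gap=200, min_pcc=0.43
        )
        assert operons["g1"] == ["g1", "g2"]  # 600 bp gap to g3 breaks the walk
        assert members == ["g1", "g2"]

    def test_walk_stops_at_low_coexpression(self, chain_genome):
        genes = ["g1", "g2", "g3"]
        m = np.eye(3)
        m[0, 1] = m[1, 0] = 0.2
        corr = _corr(genes, m)
        members, operons = expand_operons(
            pd.DataFrame([{"gene_id": "g1"}]), chain_genome, corr, max_gap=200, min_pcc=0.43
        )
        assert operons["g1"] == ["g1"]

    def test_opposite_strand_neighbor_not_appended(self):
        genome = _genome(
            [
                {"gene_id": "g1", "contig": "c1", "start": 1000, "end": 2000, "strand": "+"},
                {"gene_id": "g2", "contig": "c1", "start": 2010, "end": 3000, "strand": "-"},
            ]
        )
        corr = _corr(["g1", "g2"], np.full((2, 2), 0.99))
        members, _ = expand_operons(
            pd.DataFrame([{"gene_id": "g1"}]), genome, corr, min_pcc=0.43
        )
        assert members == ["g1"]

    def test_minus_strand_walk_goes_leftward(self):
        genome = _genome(
            [
                {"gene_id": "g1", "contig": "c1", "start": 1000, "end": 2000, "strand": "-"},
                {"gene_id": "g2", "contig": "c1", "start": 2100, "end": 3000, "strand": "-"},
            ]
        )
        m = np.full((2, 2), 0.9)
        np.fill_diagonal(m, 1.0)
        corr = _corr(["g1", "g2"], m)
        members, operons = expand_operons(
            pd.DataFrame([{"gene_id": "g2"}]), genome, corr, max_gap=200, min_pcc=0.43
        )
        assert operons["g2"] == ["g2", "g1"]

    def test_expansion_never_removes_targets(self, scenario):
        # every accepted target stays a member even if nothing is appended
        genome = scenario.genome
        genes = list(genome.genes["gene_id"][:5])
        corr = _corr(genes, np.eye(5))
        members, _ = expand_operons(
            pd.DataFrame({"gene_id": genes}), genome, corr, min_pcc=0.99
        )
        assert set(genes) <= set(members)


class TestGroupLoci:
    def _genome10(self):
        return _genome(
            [
                {"gene_id": f"g{i}", "contig": "c1", "start": 1000 * i, "end": 1000 * i + 900, "strand": "+"}
                for i in range(12)
            ],
            length=20_000,
        )

    def test_adjacent_members_merge(self):
        loci = group_loci(["g0", "g1"], self._genome10())
        assert len(loci) == 1
        assert loci.iloc[0]["genes"] == ("g0", "g1")

    def test_distant_members_split(self):
        loci = group_loci(["g0", "g10"], self._genome10(), max_intervening=5)
        assert len(loci) == 2

    def test_loci_count_non_increasing_in_max_intervening(self):
        members = ["g0", "g3", "g7", "g11"]
        counts = [
            len(group_loci(members, self._genome10(), max_intervening=k))
            for k in range(0, 11)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_grouping_idempotent(self):
        genome = self._genome10()
        loci = group_loci(["g0", "g2", "g9"], genome, max_intervening=2)
        again = group_loci(
            [g for row in loci.itertuples() for g in row.genes], genome, max_intervening=2
        )
        pd.testing.assert_frame_equal(loci, again)


class TestStatistics:
    def test_exact_p_for_complete_separation_three_vs_three(self):
        p = mannwhitney_one_sided_greater(
            np.array([0.9, 0.8, 0.7]), np.array([0.5, 0.4, 0.3])
        )
        assert p == pytest.approx(1 / 20)

    def test_identical_distributions_give_half(self):
        rng = np.random.default_rng(9)
        x, y = rng.normal(size=500), rng.normal(size=500)
        assert 0.3 < mannwhitney_one_sided_greater(x, y) < 0.7

    def test_toy_regulon_medians_match_hand_computation(self):
        genes = ["reg", "a", "b", "c", "d"]
        m = np.eye(5)
        within = {( "a","b"): 0.9, ("a","c"): 0.8, ("a","d"): 0.7,
                  ("b","c"): 0.6, ("b","d"): 0.5, ("c","d"): 0.4}
        for (u, v), r in within.items():
            i, j = genes.index(u), genes.index(v)
            m[i, j] = m[j, i] = r
        to_reg = {"a": -0.25, "b": -0.35, "c": -0.15, "d": -0.3}
        for g, r in to_reg.items():
            i = genes.index(g)
            m[0, i] = m[i, 0] = r
        corr = _corr(genes, m)
        reg = Regulon(
            regulator="reg",
            targets=pd.DataFrame({"gene_id": ["a", "b"]}),
            members=["a", "b", "c", "d"],
            operons={},
            loci=pd.DataFrame(columns=["locus", "contig", "start", "end", "genes"]),
        )
        stats = regulon_statistics(reg, corr)
        assert stats["median_within_pcc"] == pytest.approx(np.median(list(within.values())))
        assert stats["median_regulator_pcc"] == pytest.approx(np.median(list(to_reg.values())))
        # complete separation of 6 within vs 4 negated member-regulator values
        assert stats["mannwhitney_p"] < 0.05

    def test_planted_operons_recovered_on_synthetic_scenario(self, scenario):
        from regumine.coexpression import coexpression_pipeline
        from regumine.calibration import filter_and_dedupe, refined_threshold
        from regumine.motif import Background, pfm_to_pwm
        from regumine.regulon import assemble_regulon
        from regumine.scan import extract_regions, scan, score_threshold_from_pvalue

        bg = Background(0.72)
        pwm = pfm_to_pwm(scenario.pfm, bg)
        hits = scan(
            scenario.genome, extract_regions(scenario.genome), pwm,
            score_threshold_from_pvalue(pwm, bg, 0.01),
        )
        _, locations = filter_and_dedupe(hits, refined_threshold(hits), merge_overlapping=True)
        corr, _ = coexpression_pipeline(scenario.counts)
        regulon, _ = assemble_regulon(
            locations, scenario.genome, corr, scenario.truth.regulator_gene
        )
        truth_ops = {}
        for g in scenario.truth.regulon_genes:
            truth_ops.setdefault(scenario.truth.operon_map[g], set()).add(g)
        complete = sum(
            1 for members in truth_ops.values() if members <= set(regulon.members)
        )
        assert complete / len(truth_ops) >= 0.9
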