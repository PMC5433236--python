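import numpy as np
import pandas as pd
import pytest

from quatscreen import amplicon as amp
from quatscreen import formats
from quatscreen import simulate as sim
from quatscreen.profile import ProfileModel


@pytest.fixture(scope="module")
def populations():
    rng = np.random.default_rng(7)
    fam = sim.make_family(rng, length=60, name="amp")
    pops = {f"pop{i}": sim.mutate_protein(rng, fam.ancestor, 0.12) for i in range(3)}
    nts = {k: sim.backtranslate(rng, p, stop=False) for k, p in pops.items()}
    model = ProfileModel.from_alignment(sorted(pops.items()) + fam.seeds)
    return fam, pops, nts, model


class TestMerging:
    def _pair(self, seq, olap, read_len=60):
        r1 = formats.Read("p1", seq[:read_len], [35] * read_len)
        r2_seq = formats.reverse_complement(seq[read_len - olap :][: read_len])
        r2 = formats.Read("p1", r2_seq, [35] * len(r2_seq))
        return r1, r2

    def test_perfect_overlap_merges_to_expected_length(self):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACGT"), size=90))
        r1, r2 = self._pair(seq, olap=30)
        merged, stats = amp.merge_and_filter([r1], [r2])
        assert stats.merged == 1
        assert len(merged[0].sequence) == len(r1.sequence) + len(r2.sequence) - 30
        assert merged[0].sequence == seq[: len(merged[0].sequence)]

    def test_no_overlap_pair_discarded_and_tallied(self):
        r1 = formats.Read("p1", "A" * 50, [35] * 50)
        r2 = formats.Read("p1", "C" * 50, [35] * 50)
        merged, stats = amp.merge_and_filter([r1], [r2])
        assert merged == []
        assert stats.no_overlap == 1

    def test_low_quality_merged_read_dropped(self):
        rng = np.random.default_rng(1)
        seq = "".join(rng.choice(list("ACGT"), size=90))
        r1 = formats.Read("p1", seq[:60], [10] * 60)
        r2 = formats.Read(
            "p1", formats.reverse_complement(seq[30:90]), [10] * 60
        )
        merged, stats = amp.merge_and_filter([r1], [r2], min_q=25)
        assert merged == []
        assert stats.low_quality == 1

    def test_unpaired_ids_raise_naming_offender(self):
        r1 = formats.Read("lonely", "ACGT" * 10, [35] * 40)
        r2 = formats.Read("other", "ACGT" * 10, [35] * 40)
        with pytest.raises(ValueError, match="lonely"):
            amp.merge_and_filter([r1], [r2])

    def test_higher_quality_base_wins_in_overlap(self):
        rng = np.random.default_rng(9)
        seq = "".join(rng.choice(list("ACGT"), size=60))
        # forward read carries one low-quality miscall inside the overlap
        bad = list(seq[:40])
        bad[30] = {"A": "C", "C": "A", "G": "T", "T": "G"}[bad[30]]
        quals = [40] * 40
        quals[30] = 2
        r1 = formats.Read("p", "".join(bad), quals)
        r2 = formats.Read("p", formats.reverse_complement(seq[20:60]), [40] * 40)
        merged, _ = amp.merge_and_filter([r1], [r2], min_q=0, min_overlap=20)
        assert merged[0].sequence == seq


class TestFrameshiftCorrectPanel:
    def test_read_from_outgroup_homolog_is_not_target(self, populations):
        fam, pops, nts, model = populations
        rng = np.random.default_rng(5)
        outgroup_prot = sim.mutate_protein(rng, fam.ancestor, 0.35)
        panel = dict(pops)
        panel["og:far"] = outgroup_prot
        read = sim.backtranslate(rng, outgroup_prot, stop=False)
        c = amp.frameshift_correct(read, panel, target_ids=set(pops))
        assert c.closest_ref_id == "og:far"
        assert not c.is_target

    def test_exact_target_read_fully_identified(self, populations):
        _, pops, nts, model = populations
        c = amp.frameshift_correct(nts["pop0"], pops, target_ids=set(pops))
        assert c.closest_ref_id == "pop0"
        assert c.protein_identity == 1.0
        assert c.is_target
        assert c.frameshift_count == 0

    def test_stop_codon_read_rejected_by_discrimination(self, populations):
        _, pops, nts, model = populations
        read = nts["pop0"][:30] + "TAA" + nts["pop0"][33:]
        c = amp.frameshift_correct(read, pops, target_ids=set(pops))
        assert c.has_stop and not c.is_target
        kept, tallies = amp.discriminate_targets([c])
        assert kept == []
        assert tallies[c.sample_id].stop_codon == 1

    def test_all_clean_target_reads_pass(self, populations):
        _, pops, nts, model = populations
        cs = [
            amp.frameshift_correct(nts[k], pops, set(pops), read_id=k)
            for k in nts
        ]
        kept, tallies = amp.discriminate_targets(cs)
        assert len(kept) == len(cs)
        assert tallies["sample"].pass_rate == 1.0


class TestClusterTable:
    def _table(self, matrix, cutoff=0.9):
        df = pd.DataFrame(matrix).T
        df.index.name = "sample_id"
        return amp.ClusterTable(cutoff, df)

    def test_min_count_filter_drops_sparse_clusters(self):
        t = self._table({"s1": {"a": 4, "b": 10}, "s2": {"a": 0, "b": 3}})
        kept = t.filter_min_count(5)
        assert list(kept.matrix.columns) == ["b"]

    def test_rarefy_rows_sum_to_depth_and_is_deterministic(self):
        rng = np.random.default_rng(0)
        mat = {f"s{i}": {f"c{j}": int(rng.integers(0, 60)) + 5 for j in range(8)} for i in range(4)}
        t = self._table(mat)
        depth = int(t.matrix.sum(axis=1).min())
        r1 = amp.rarefy(t, depth, seed=123)
        r2 = amp.rarefy(t, depth, seed=123)
        assert (r1.matrix.sum(axis=1) == depth).all()
        assert r1.matrix.equals(r2.matrix)

    def test_rarefy_at_full_depth_changes_nothing(self):
        t = self._table({"s1": {"a": 5, "b": 5}, "s2": {"a": 6, "b": 4}})
        r = amp.rarefy(t, 10, seed=1)
        assert r.matrix.equals(t.matrix)

    def test_rarefy_expected_counts_track_proportions(self):
        # hypergeometric expectation: E[count_c] = depth * n_c / N
        t = self._table({"s1": {"a": 600, "b": 300, "c": 100}})
        depth = 500
        draws = np.array(
            [amp.rarefy(t, depth, seed=s).matrix.loc["s1", "a"] for s in range(300)]
        )
        expect = depth * 0.6
        se = np.sqrt(depth * 0.6 * 0.4 * (1000 - depth) / (1000 - 1)) / np.sqrt(len(draws))
        assert abs(draws.mean() - expect) < 3 * se + 1e-9

    def test_rarefy_depth_above_sample_total_rejected(self):
        t = self._table({"s1": {"a": 3}})
        with pytest.raises(ValueError):
            amp.rarefy(t, 10, seed=0)


class TestDiversityProfile:
    def test_single_sample_all_clusters_fully_prevalent(self):
        df = pd.DataFrame({"a": [5], "b": [9]}, index=["s1"])
        t = amp.ClusterTable(0.9, df)
        prof = amp.diversity_profile({0.9: t})
        assert prof.loc[0, "clusters_>90%"] == 1.0

    def test_sequence_shares_sum_to_one(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(
            rng.integers(0, 30, size=(6, 10)),
            index=[f"s{i}" for i in range(6)],
            columns=[f"c{j}" for j in range(10)],
        )
        t = amp.ClusterTable(0.9, df)
        prof = amp.diversity_profile({0.9: t})
        shares = [prof.loc[0, f"sequences_{lbl}"] for _, _, lbl in amp.PREVALENCE_BINS]
        assert sum(shares) == pytest.approx(1.0)

    def test_cluster_count_non_increasing_at_looser_cutoffs(self, populations):
        fam, pops, nts, model = populations
        rng = np.random.default_rng(8)
        reads = []
        for k, nt in nts.items():
            for i in range(10):
                reads.append((f"{k}_{i}", sim.mutate_protein(rng, pops[k], 0.0), nt))
        corrected = [
            amp.frameshift_correct(nt, pops, set(pops), read_id=rid, sample_id="s1")
            for rid, _, nt in reads
        ]
        counts = []
        for cutoff in (0.99, 0.95, 0.90, 0.80):
            t = amp.cluster_amplicons(corrected, model, pops, identity_cutoff=cutoff)
            counts.append(t.n_clusters)
        assert counts == sorted(counts, reverse=True)


class TestBestMatchIdentity:
    def test_reads_copied_from_references_hit_100(self, populations):
        _, pops, nts, model = populations
        corrected = [
            amp.frameshift_correct(nts[k], pops, set(pops), read_id=k) for k in nts
        ]
        df = amp.best_match_identity(corrected, nts)
        assert (df["identity"] == 1.0).all()

    def test_planted_mutation_level_recovered(self, populations):
        _, pops, nts, model = populations
        rng = np.random.default_rng(3)
        nt = nts["pop0"]
        n_mut = int(round(0.10 * len(nt)))
        pos = rng.choice(len(nt), size=n_mut, replace=False)
        read = list(nt)
        for p in pos:
            read[p] = {"A": "C", "C": "A", "G": "T", "T": "G"}[read[p]]
        c = amp.CorrectedAmplicon(
            "r", "s", "".join(read), "", "pop0", 0.9, 0, False, True
        )
        df = amp.best_match_identity([c], {"pop0": nt})
        assert df.loc[0, "identity"] == pytest.approx(0.90, abs=0.01)

    def test_identity_bounded(self, populations):
        _, pops, nts, model = populations
        c = amp.CorrectedAmplicon("r", "s", "ACGTACGTA", "", "pop0", 0.5, 0, False, True)
        df = amp.best_match_identity([c], nts)
        assert 0.0 <= df.loc[0, "identity"] <= 1.0


class TestCooccurrence:
    def test_identical_rank_pair_always_edged(self):
        df, truth = sim.make_abundance_matrix(
            n_samples=20, n_clusters=6, blocks=[[0, 1]], seed=1
        )
        net = amp.cooccurrence(amp.ClusterTable(0.9, df))
        assert net.graph.has_edge("cl000", "cl001")

    def test_anticorrelated_pair_not_edged(self):
        n = 24
        a = np.arange(1, n + 1)
        df = pd.DataFrame({"a": a, "b": a[::-1], "c": a * 0 + 5}, index=[f"s{i}" for i in range(n)])
        net = amp.cooccurrence(amp.ClusterTable(0.9, df))
        assert not net.graph.has_edge("a", "b")

    def test_low_prevalence_cluster_excluded(self):
        df, truth = sim.make_abundance_matrix(
            n_samples=30, n_clusters=5, blocks=[], low_prevalence={2: 0.4}, seed=3
        )
        name = "cl002"
        assert truth.prevalence[name] < 0.5
        net = amp.cooccurrence(amp.ClusterTable(0.9, df))
        assert name not in net.graph.nodes

    def test_fewer_than_four_samples_rejected(self):
        df = pd.DataFrame({"a": [1, 2, 3], "b": [2, 3, 4]}, index=["s1", "s2", "s3"])
        with pytest.raises(ValueError):
            amp.cooccurrence(amp.ClusterTable(0.9, df))

    def test_edge_attributes_satisfy_thresholds(self):
        df, _ = sim.make_abundance_matrix(
            n_samples=40, n_clusters=12, blocks=[[0, 1, 2]], seed=5
        )
        net = amp.cooccurrence(amp.ClusterTable(0.9, df))
        for _, _, d in net.graph.edges(data=True):
            assert d["rho"] >= 0.5 and d["p"] < 0.01 and d["q"] < 0.01


class TestOrdination:
    def test_identical_samples_land_together(self):
        df = pd.DataFrame(
            {"a": [10, 10, 2], "b": [5, 5, 20], "c": [1, 1, 9]},
            index=["s1", "s2", "s3"],
        )
        ordn = amp.ordinate(amp.ClusterTable(0.9, df), seed=0)
        d12 = np.linalg.norm(
            ordn.coordinates.loc["s1"].to_numpy() - ordn.coordinates.loc["s2"].to_numpy()
        )
        d13 = np.linalg.norm(
            ordn.coordinates.loc["s1"].to_numpy() - ordn.coordinates.loc["s3"].to_numpy()
        )
        assert d12 < 0.1 * d13

    def test_bray_curtis_of_disjoint_samples_is_one(self):
        df = pd.DataFrame({"a": [10, 0], "b": [0, 10]}, index=["s1", "s2"])
        ordn = amp.ordinate(amp.ClusterTable(0.9, df), seed=0)
        assert ordn.dissimilarity.loc["s1", "s2"] == pytest.approx(1.0)

    def test_planted_2d_configuration_embeds_with_low_stress(self):
        # relative-abundance profiles whose Bray-Curtis distances admit an
        # exact 2-D embedding (3 points always do)
        df = pd.DataFrame(
            {
                "a": [30, 10, 5],
                "b": [5, 25, 10],
                "c": [5, 5, 25],
            },
            index=["s1", "s2", "s3"],
        )
        ordn = amp.ordinate(amp.ClusterTable(0.9, df), seed=0)
        assert ordn.stress < 0.01
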