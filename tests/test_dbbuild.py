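import numpy as np
import pytest
from skbio import DistanceMatrix
from skbio.tree import TreeNode

from quatscreen import simulate as sim
from quatscreen.dbbuild import (
    Candidate,
    GeneDatabase,
    Hit,
    SignatureRule,
    assemble_database,
    build_database,
    check_signatures,
    check_synteny,
    dereplicate,
    detect_cutoff,
    phylo_distance_to_top,
    screen_genomes,
)
from quatscreen.formats import FeatureRecord
from quatscreen.profile import ProfileModel


@pytest.fixture(scope="module")
def screen_fixture():
    spec = sim.GenomePlantSpec(
        n_genomes=8, separations=(1, 5, 10), n_traps=1, n_decoys=30,
        backbone_genes=10, target_length=120, partner_length=90,
    )
    genomes, truth = sim.make_genomes(spec, seed=77)
    model = ProfileModel.from_alignment(truth.target_family.seeds)
    return genomes, truth, model


class TestScreenGenomes:
    def test_planted_targets_outrank_all_decoys(self, screen_fixture):
        genomes, truth, model = screen_fixture
        hits = screen_genomes(genomes, model)
        kinds = []
        planted = {(p.genome_id, p.locus_tag): p.kind for p in truth.planted}
        for h in hits:
            kinds.append(planted.get((h.genome_id, h.feature.locus_tag), "backbone"))
        n_targets = len(truth.planted_of_kind("target"))
        assert kinds[:n_targets] == ["target"] * n_targets
        assert "target" not in kinds[n_targets:]

    def test_top_n_zero_yields_empty(self, screen_fixture):
        genomes, _, model = screen_fixture
        assert screen_genomes(genomes, model, top_n=0) == []

    def test_duplicate_genomes_are_collapsed(self, screen_fixture):
        genomes, _, model = screen_fixture
        once = screen_genomes(genomes, model, top_n=10)
        twice = screen_genomes(genomes + genomes, model, top_n=10)
        assert [(h.genome_id, h.score) for h in once] == [
            (h.genome_id, h.score) for h in twice
        ]


class TestDereplicate:
    def _hit(self, gid, tag, protein, score=10.0):
        f = FeatureRecord(gid, "c1", 1, 30, "+", tag, protein=protein)
        f.locus_index = 0
        return Hit(genome_id=gid, feature=f, score=score)

    def test_identical_proteins_collapse_with_members(self):
        hits = [self._hit(g, "t", "MKTA") for g in ("g2", "g1", "g3")]
        uniq = dereplicate(hits)
        assert len(uniq) == 1
        assert uniq[0].member_genome_ids == ["g1", "g2", "g3"]
        # representative from the lexicographically smallest genome
        assert uniq[0].representative.genome_id == "g1"

    def test_single_residue_difference_stays_separate(self):
        hits = [self._hit("g1", "a", "MKTA"), self._hit("g2", "b", "MRTA")]
        assert len(dereplicate(hits)) == 2

    def test_never_more_uniques_than_hits(self):
        rng = np.random.default_rng(0)
        hits = [
            self._hit(f"g{i}", "t", sim.random_protein(rng, 8), score=float(i))
            for i in range(10)
        ]
        assert len(dereplicate(hits)) <= len(hits)


class TestSignatures:
    def test_consensus_residue_passes_own_rule(self, model):
        rec = model.align([("c", model.consensus)])[0]
        k = 5
        rule = SignatureRule(k, frozenset(rec.residue_at(k)), "site")
        assert check_signatures(rec, [rule]) == {"site": True}

    def test_disallowed_residue_fails(self, model):
        rec = model.align([("c", model.consensus)])[0]
        k = 5
        other = ({"A", "C"} - {rec.residue_at(k)}).pop()
        rule = SignatureRule(k, frozenset(other), "site")
        assert check_signatures(rec, [rule]) == {"site": False}

    def test_deletion_at_rule_column_fails(self, model):
        # sequence missing the model's middle -> deletions at central columns
        half = model.consensus[: model.consensus_length // 3]
        rec = model.align([("h", half)])[0]
        k = model.consensus_length - 2
        assert rec.residue_at(k) == "-"
        rule = SignatureRule(k, frozenset("ACDEFGHIKLMNPQRSTVWY"), "site")
        assert check_signatures(rec, [rule]) == {"site": False}


class TestPhyloDistance:
    def test_identical_pair_distance_zero(self):
        d = phylo_distance_to_top([("a", "MKTA"), ("b", "MKTA")], "a")
        assert d["b"] == 0.0

    def test_nj_reproduces_additive_distances(self):
        # Tree ((a:3,b:7):0,(c:8,d:2):0) with a 30-site internal edge,
        # realized by giving every edge its own disjoint set of mutated
        # sites: p-distances are then exactly additive and neighbor joining
        # must reproduce them as path lengths.
        L = 100
        def seq(*mutated_ranges):
            s = ["A"] * L
            for lo, hi in mutated_ranges:
                for k in range(lo, hi):
                    s[k] = "C"
            return "".join(s)

        a = seq((0, 3))
        b = seq((3, 10))
        c = seq((10, 40), (40, 48))
        d_ = seq((10, 40), (48, 50))
        dist = phylo_distance_to_top([("a", a), ("b", b), ("c", c), ("d", d_)], "a")
        assert dist["a"] == 0.0
        assert dist["b"] == pytest.approx(0.10, abs=1e-9)
        assert dist["c"] == pytest.approx(0.41, abs=1e-9)
        assert dist["d"] == pytest.approx(0.35, abs=1e-9)

    def test_distances_non_negative(self):
        rng = np.random.default_rng(1)
        seqs = [(f"s{i}", "".join(rng.choice(list("ACDE"), size=30))) for i in range(6)]
        d = phylo_distance_to_top(seqs, "s0")
        assert all(v >= 0 for v in d.values())


class TestSynteny:
    def test_separation_within_rule_found(self, screen_fixture):
        genomes, truth, _ = screen_fixture
        partner_model = ProfileModel.from_alignment(truth.partner_family.seeds)
        genome_of = {g.genome_id: g for g in genomes}
        for p in truth.planted_of_kind("target"):
            g = genome_of[p.genome_id]
            feat = next(f for f in g.features if f.locus_tag == p.locus_tag)
            res = check_synteny(g, feat, partner_model, partner_cutoff=50.0)
            assert res.partner_found == p.syntenic
            assert res.locus_separation == p.separation
            if res.partner_found:
                assert res.same_contig

    def test_partner_on_other_contig_not_found(self, screen_fixture):
        genomes, truth, _ = screen_fixture
        partner_model = ProfileModel.from_alignment(truth.partner_family.seeds)
        g = genomes[0]
        feat = FeatureRecord("gX", "lonely", 1, 33, "+", "solo", protein="MKTAYIAKQR")
        feat.locus_index = 0
        from quatscreen.formats import GenomeRecord

        lonely = GenomeRecord("gX", {"lonely": "A" * 100}, [feat])
        res = check_synteny(lonely, feat, partner_model, partner_cutoff=10.0)
        assert not res.partner_found
        assert not res.same_contig

    def test_raising_max_separation_never_unsets_partner(self, screen_fixture):
        genomes, truth, _ = screen_fixture
        partner_model = ProfileModel.from_alignment(truth.partner_family.seeds)
        genome_of = {g.genome_id: g for g in genomes}
        for p in truth.planted_of_kind("target"):
            g = genome_of[p.genome_id]
            feat = next(f for f in g.features if f.locus_tag == p.locus_tag)
            found = [
                check_synteny(g, feat, partner_model, 50.0, max_separation=ms).partner_found
                for ms in (5, 10, 11, 20)
            ]
            assert found == sorted(found)


class TestDetectCutoff:
    def test_largest_relative_drop_framed(self):
        scores = [1000, 990, 985, 910, 903, 500, 480]
        assert detect_cutoff(scores) == pytest.approx(701.5)

    def test_two_scores(self):
        assert detect_cutoff([10, 1]) == 5.5

    def test_manual_mode_echoes(self):
        assert detect_cutoff([5, 4, 3], mode="manual", value=906.4) == 906.4

    def test_flat_scores_demand_manual(self):
        with pytest.raises(ValueError, match="no drop"):
            detect_cutoff([7.0, 7.0, 7.0])

    def test_brute_force_over_consecutive_gaps(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            scores = sorted(rng.uniform(10, 1000, size=12), reverse=True)
            got = detect_cutoff(scores)
            # brute force: best relative drop over the interior ranks
            # (neither the top nor the bottom score frames a drop)
            drops = [
                ((scores[i] - scores[i + 1]) / scores[i], i)
                for i in range(1, len(scores) - 2)
            ]
            _, i = max(drops)
            assert got == pytest.approx((scores[i] + scores[i + 1]) / 2)


class TestAssembleAndBuild:
    def test_full_build_recovers_planted_truth(self, screen_fixture):
        genomes, truth, _ = screen_fixture
        fam = truth.target_family
        sigs = [
            SignatureRule(c, frozenset(r), f"sig{c}")
            for c, r in fam.signature_columns.items()
        ]
        n_planted = len(truth.planted_of_kind("target")) + len(truth.planted_of_kind("decoy"))
        db, table, model = build_database(
            genomes,
            seed_alignment=fam.seeds,
            partner_seed_alignment=truth.partner_family.seeds,
            gene_name="target",
            signatures=sigs,
            top_n=n_planted,
        )
        want = {
            f"{p.genome_id}.{p.locus_tag}" for p in truth.planted_of_kind("target")
        }
        got = {r.ref_id for r in db.target_refs}
        assert got == want
        # traps flagged non-syntenous in the candidate table
        trap_ids = {
            f"{p.genome_id}.{p.locus_tag}"
            for p in truth.planted_of_kind("target")
            if not p.syntenic
        }
        tbl = table.set_index("protein_id")
        for tid in trap_ids:
            assert not tbl.loc[tid, "synteny"]
            assert tbl.loc[tid, "status"] == "target"
        # decoys fail signature rules and sit below the cutoff
        assert (~tbl[tbl.status == "below_cutoff"]["residues_ok"]).all()

    def test_target_outgroup_disjoint(self, screen_fixture):
        genomes, truth, _ = screen_fixture
        db, _, _ = build_database(
            genomes, truth.target_family.seeds, gene_name="t", refine_cycles=0
        )
        targets = {r.ref_id for r in db.target_refs}
        out = {r.ref_id for r in db.outgroup_protein_refs}
        assert targets.isdisjoint(out)

    def test_raising_cutoff_never_adds_targets(self, screen_fixture):
        genomes, truth, _ = screen_fixture
        fam = truth.target_family
        db_auto, table, model = build_database(
            genomes, fam.seeds, gene_name="t", refine_cycles=0
        )
        higher = db_auto.cutoff_used * 1.5
        db_high, _, _ = build_database(
            genomes, fam.seeds, gene_name="t", refine_cycles=0,
            cutoff_mode="manual", cutoff_value=higher,
        )
        assert {r.ref_id for r in db_high.target_refs} <= {
            r.ref_id for r in db_auto.target_refs
        }

    def test_identical_double_copy_reported_not_split(self):
        prot = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ" * 2
        rng = np.random.default_rng(0)
        nt = sim.backtranslate(rng, prot, stop=False)
        feats = []
        for i, start in enumerate((1, 1000)):
            f = FeatureRecord("g1", "c1", start, start + len(nt) - 1, "+", f"copy{i}", protein=prot)
            f.locus_index = i
            feats.append(f)
        hits = [Hit("g1", f, 100.0) for f in feats]
        cands = dereplicate(hits)
        db = assemble_database(cands, cutoff=50.0)
        assert db.copy_number["g1"] == 2
        assert len(db.target_refs) == 1
        assert db.multi_copy_nonidentical == []  # identical copies

    def test_fewer_outgroups_than_requested_keeps_all(self, screen_fixture):
        genomes, truth, _ = screen_fixture
        db, _, _ = build_database(
            genomes, truth.target_family.seeds, gene_name="t", refine_cycles=0,
            outgroup_protein_size=10_000, outgroup_nt_size=10_000,
        )
        assert len(db.outgroup_protein_refs) < 10_000

    def test_database_round_trip(self, tmp_path, screen_fixture):
        genomes, truth, _ = screen_fixture
        db, table, model = build_database(
            genomes, truth.target_family.seeds, gene_name="t", refine_cycles=0
        )
        db.save(tmp_path)
        back = GeneDatabase.load(tmp_path)
        assert back.gene_name == db.gene_name
        assert back.cutoff_used == db.cutoff_used
        assert back.target_nt() == db.target_nt()
        assert set(back.outgroup_proteins()) == set(db.outgroup_proteins())
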