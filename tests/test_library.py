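"""Library preparation: parsing, properties, filters, fingerprints,
novelty and leader clustering."""
import pytest
from hypothesis import given, settings, strategies as st

from melapharm import (CompoundRecord, FilterConfig, apply_filters,
                       cluster_leader, compute_properties, fingerprint,
                       nearest_reference_distance, parse_smiles_library,
                       tanimoto_distance)
from melapharm import synthetic as syn

MELATONIN = "CC(=O)NCCc1c[nH]c2ccc(OC)cc12"
MEL_UREA = "NC(=O)NCCc1c[nH]c2ccc(OC)cc12"


def _record(**props) -> CompoundRecord:
    base = dict(id="x", smiles="C", mol_weight=200.0, logp_est=2.0,
                net_charge=0, heavy_atoms=10, pains_flag=False,
                reactive_flag=False)
    base.update(props)
    return CompoundRecord(**base)


class TestParsing:
    def test_valid_lines_become_records(self, tmp_path):
        p = tmp_path / "lib.smi"
        p.write_text(f"{MELATONIN}\tmel\nc1ccccc1\tbenzene\nCCO\tethanol\n")
        parsed = parse_smiles_library(p)
        assert [r.id for r in parsed.records] == ["mel", "benzene", "ethanol"]
        assert parsed.n_skipped == 0

    def test_malformed_line_skipped_with_count(self, tmp_path):
        p = tmp_path / "lib.smi"
        p.write_text("C1CC\tbroken\nCCO\tok\n")
        parsed = parse_smiles_library(p)
        assert parsed.n_skipped == 1
        assert [r.id for r in parsed.records] == ["ok"]

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "lib.smi"
        p.write_text("\n")
        with pytest.raises(ValueError, match="empty"):
            parse_smiles_library(p)


class TestProperties:
    def test_melatonin_has_17_heavy_atoms_and_fragment_mw(self):
        r = compute_properties(CompoundRecord("mel", MELATONIN))
        assert r.heavy_atoms == 17
        assert r.mol_weight == pytest.approx(232.28, abs=0.05)
        assert r.mol_weight <= 250.0
        assert not r.pains_flag and not r.reactive_flag

    def test_glycine_anion_formal_charge(self):
        r = compute_properties(CompoundRecord("gly", "NCC(=O)[O-]"))
        assert r.net_charge == -1

    def test_packaged_pains_template_is_flagged(self, templates):
        row = templates[templates["fail_reason"] == "pains"].iloc[0]
        r = compute_properties(CompoundRecord(row.template_id, row.smiles))
        assert r.pains_flag

    def test_packaged_reactive_template_is_flagged(self, templates):
        row = templates[templates["fail_reason"] == "reactive"].iloc[0]
        r = compute_properties(CompoundRecord(row.template_id, row.smiles))
        assert r.reactive_flag


class TestFilters:
    @pytest.mark.parametrize("props,expect_kept,reason", [
        (dict(mol_weight=250.0), True, None),          # inclusive ceiling
        (dict(mol_weight=251.0), False, "mw"),
        (dict(logp_est=1.0), True, None),              # inclusive bounds
        (dict(logp_est=5.0), True, None),
        (dict(logp_est=0.99), False, "logp"),
        (dict(net_charge=-1), True, None),
        (dict(net_charge=2), False, "charge"),
        (dict(reactive_flag=True), False, "reactive"),
        (dict(pains_flag=True), False, "pains"),
        (dict(mol_weight=300.0, pains_flag=True), False, "mw"),  # first rule
    ])
    def test_boundaries_and_first_failing_rule(self, props, expect_kept, reason):
        kept, rejected = apply_filters([_record(**props)], FilterConfig())
        if expect_kept:
            assert len(kept) == 1 and not rejected
        else:
            assert not kept and rejected[0][1] == reason

    def test_fixture_library_survivor_count_matches_annotation(self):
        lib = syn.gen_library(10, 5, seed=1)
        records = [compute_properties(CompoundRecord(row.compound_id, row.smiles))
                   for row in lib.itertuples()]
        kept, rejected = apply_filters(records)
        assert len(kept) == 10
        # every rejection reason matches its template annotation
        reason_of = dict(zip(lib["compound_id"], lib["fail_reason"]))
        for rec, why in rejected:
            assert reason_of[rec.id] == why

    def test_empty_input_gives_empty_output(self):
        assert apply_filters([], FilterConfig()) == ([], [])

    @given(mw_max=st.floats(180.0, 400.0))
    @settings(max_examples=25, deadline=None)
    def test_filtering_monotone_in_mw_bound(self, mw_max):
        records = [_record(id=f"r{i}", mol_weight=150.0 + 10.0 * i)
                   for i in range(25)]
        kept_tight, _ = apply_filters(records, FilterConfig(mw_max=mw_max))
        kept_loose, _ = apply_filters(records, FilterConfig(mw_max=mw_max + 50.0))
        assert len(kept_loose) >= len(kept_tight)


class TestFingerprints:
    def test_canonicalization_stable(self):
        alt = "COc1ccc2[nH]cc(CCNC(C)=O)c2c1"  # same molecule, different atom order
        assert tanimoto_distance(fingerprint(MELATONIN), fingerprint(alt)) == 0.0

    def test_melatonin_vs_benzene_distant(self):
        d = tanimoto_distance(fingerprint(MELATONIN), fingerprint("c1ccccc1"))
        assert d > 0.5

    def test_melatonin_vs_urea_analog_close(self):
        d = tanimoto_distance(fingerprint(MELATONIN), fingerprint(MEL_UREA))
        assert d <= 0.15

    def test_distance_is_bounded_symmetric_semimetric(self):
        smiles = [MELATONIN, MEL_UREA, "c1ccccc1", "CCO"]
        fps = [fingerprint(s) for s in smiles]
        for i, a in enumerate(fps):
            assert tanimoto_distance(a, a) == 0.0
            for b in fps[i + 1:]:
                d_ab, d_ba = tanimoto_distance(a, b), tanimoto_distance(b, a)
                assert d_ab == d_ba
                assert 0.0 <= d_ab <= 1.0


class TestNovelty:
    def test_member_of_reference_set_has_distance_zero(self):
        mel = CompoundRecord("mel", MELATONIN)
        res = nearest_reference_distance(mel, [CompoundRecord("ref", MELATONIN)])
        assert res.tanimoto_distance == 0.0
        assert res.nearest_reference == "ref"

    def test_single_reference_equals_pairwise_distance(self):
        rec = CompoundRecord("x", MEL_UREA)
        ref = CompoundRecord("mel", MELATONIN)
        res = nearest_reference_distance(rec, [ref])
        expected = tanimoto_distance(fingerprint(rec), fingerprint(ref))
        assert res.tanimoto_distance == expected

    def test_spiked_analog_ranks_closer_than_random_templates(self, templates):
        mel_ref = [CompoundRecord("mel", MELATONIN)]
        analog = CompoundRecord("spike", MEL_UREA)
        d_spike = nearest_reference_distance(analog, mel_ref).tanimoto_distance
        for row in templates[templates["template_id"].isin(
                ["toluene_amide", "logp_high", "dication"])].itertuples():
            other = CompoundRecord(row.template_id, row.smiles)
            assert d_spike < nearest_reference_distance(other, mel_ref).tanimoto_distance

    def test_empty_reference_set_rejected(self):
        with pytest.raises(ValueError):
            nearest_reference_distance(CompoundRecord("x", MELATONIN), [])


class TestLeaderClustering:
    def test_identical_compounds_one_cluster(self):
        recs = [CompoundRecord(f"c{i}", MELATONIN) for i in range(4)]
        scores = {f"c{i}": -30.0 - i for i in range(4)}
        out = cluster_leader(recs, 0.3, scores)
        assert {a.cluster_id for a in out} == {1}
        assert sum(a.is_representative for a in out) == 1
        # representative is the best (most negative) scorer
        rep = next(a for a in out if a.is_representative)
        assert rep.compound_id == "c3"

    def test_all_distant_gives_singletons(self):
        smiles = [MELATONIN, "c1ccccc1", "CC(C)(C)C", "OCC(O)CO"]
        recs = [CompoundRecord(f"c{i}", s) for i, s in enumerate(smiles)]
        scores = {f"c{i}": -40.0 + i for i in range(4)}
        out = cluster_leader(recs, 0.05, scores)
        assert len({a.cluster_id for a in out}) == 4
        assert all(a.is_representative for a in out)

    def test_partition_matches_independent_greedy_run(self):
        """Six-compound toy set: hand-executable greedy leader algorithm
        on the package's own distance matrix must give the same partition."""
        smiles = {
            "a": MELATONIN, "b": MEL_UREA, "c": "c1ccccc1",
            "d": "Cc1ccccc1", "e": "CCO", "f": MELATONIN,
        }
        scores = {"a": -40, "b": -38, "c": -36, "d": -34, "e": -32, "f": -30}
        recs = [CompoundRecord(k, s) for k, s in smiles.items()]
        fps = {k: fingerprint(s) for k, s in smiles.items()}
        threshold = 0.4

        # independent greedy reference: process best-score-first
        order = sorted(smiles, key=lambda k: (scores[k], k))
        leaders, expected = [], {}
        for k in order:
            for leader in leaders:
                if tanimoto_distance(fps[k], fps[leader]) <= threshold:
                    expected[k] = expected[leader]
                    break
            else:
                leaders.append(k)
                expected[k] = len(leaders)

        out = {a.compound_id: a.cluster_id for a in
               cluster_leader(recs, threshold, scores)}
        assert out == expected

    def test_cluster_count_non_increasing_in_threshold(self):
        lib = syn.gen_library(12, 0, seed=4)
        recs = [CompoundRecord(r.compound_id, r.smiles) for r in lib.itertuples()]
        scores = {r.id: -30.0 - i for i, r in enumerate(recs)}
        counts = [len({a.cluster_id for a in cluster_leader(recs, t, scores)})
                  for t in (0.1, 0.3, 0.5, 0.7, 0.9)]
        assert counts == sorted(counts, reverse=True)

    def test_missing_scores_warns_and_uses_input_order(self):
        recs = [CompoundRecord("a", MELATONIN), CompoundRecord("b", "c1ccccc1")]
        with pytest.warns(UserWarning, match="missing docking scores"):
            out = cluster_leader(recs, 0.4, None)
        assert out[0].compound_id == "a"

    def test_exactly_one_cluster_per_compound(self):
        lib = syn.gen_library(10, 5, seed=2)
        recs = [CompoundRecord(r.compound_id, r.smiles) for r in lib.itertuples()]
        scores = {r.id: float(-25 - i) for i, r in enumerate(recs)}
        out = cluster_leader(recs, 0.5, scores)
        assert len(out) == len(recs)
        assert len({a.compound_id for a in out}) == len(recs)
        by_cluster = {}
        for a in out:
            by_cluster.setdefault(a.cluster_id, []).append(a)
        for members in by_cluster.values():
            assert sum(m.is_representative for m in members) == 1
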