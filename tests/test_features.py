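"""Feature extraction: preprocessing, families, entropies, invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from discon.features import (
    build_default_catalog,
    composition_features,
    conditioned_entropy_value,
    extract_features,
    extract_matrix,
    fusion_value,
    longest_strand_free_segment,
    preprocess_tracks,
    pssm_to_probs,
    relative_entropy,
    runs_of,
    segment_features,
    shannon_entropy,
    wop_to_probs,
    _Context,
)
from discon.records import AA_ALPHABET, FormatError
from conftest import make_record, random_full_record

LOG2_20 = np.log2(20)


class TestPreprocess:
    @pytest.mark.parametrize(
        "ss_in,ss_out",
        [
            ("HHEEC", "CCEEC"),  # helix run of 2 < 3 becomes coil
            ("HHHH", "HHHH"),  # run >= 3 untouched
            ("HHHCHH", "HHHCCC"),
            ("EECEE", "EECEE"),  # strand runs never rewritten
        ],
    )
    def test_short_helix_rewrite(self, ss_in, ss_out):
        rec = make_record(sequence="A" * len(ss_in), ss=ss_in)
        assert preprocess_tracks(rec).ss == ss_out

    def test_rsa_exposure_boundary(self):
        rec = make_record(sequence="AA", rsa=[0.25, 0.251])
        out = preprocess_tracks(rec)
        assert out.derived["exposed"].tolist() == [0, 1]

    def test_raw_asa_normalized_by_max_asa(self):
        # A has max ASA 115: raw 57.5 -> RSA 0.5; clipping caps at 1
        rec = make_record(sequence="AA", rsa=np.array([57.5, 500.0]))
        rec.rsa_is_relative = False
        out = preprocess_tracks(rec)
        np.testing.assert_allclose(out.rsa, [0.5, 1.0])

    def test_rigidity_from_bfactor(self):
        rec = make_record(sequence="AAA", bfactor=[-0.5, 0.0, 0.1])
        out = preprocess_tracks(rec)
        assert out.derived["rigid"].tolist() == [1, 1, 0]  # low iff <= 0


class TestComposition:
    def test_degenerate(self):
        vals = composition_features(make_record(sequence="AAAA"))
        assert vals["AAcomp_A"] == 1.0
        assert sum(vals[f"AAcomp_{a}"] for a in AA_ALPHABET) == 1.0

    def test_promoting_groups(self):
        vals = composition_features(make_record(sequence="WYFILVCN"))
        assert vals["AAcomp_order_promoting"] == 1.0
        assert vals["AAcomp_disorder_promoting"] == 0.0

    def test_fractions_sum_to_one(self):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list(AA_ALPHABET), size=83))
        vals = composition_features(make_record(sequence=seq))
        assert sum(vals[f"AAcomp_{a}"] for a in AA_ALPHABET) == pytest.approx(1.0)


def brute_force_runs(mask):
    """Oracle: enumerate maximal True runs by direct scanning."""
    runs, i = [], 0
    mask = list(mask)
    while i < len(mask):
        if mask[i]:
            j = i
            while j < len(mask) and mask[j]:
                j += 1
            runs.append((i, j - i))
            i = j
        else:
            i += 1
    return runs


class TestSegments:
    @given(st.lists(st.booleans(), min_size=1, max_size=40))
    @settings(max_examples=200, deadline=None)
    def test_run_stats_match_brute_force(self, bits):
        mask = np.array(bits)
        L = len(mask)
        runs = brute_force_runs(mask)
        lengths = [r[1] for r in runs]
        stats = segment_features(mask, ladder=(2, 3))
        assert stats["SegCount"] == pytest.approx(len(runs) / L)
        assert stats["SegFrac"] == pytest.approx(sum(lengths) / L)
        assert stats["SegLongest"] == pytest.approx((max(lengths) if lengths else 0) / L)
        assert stats["Seg_2"] == pytest.approx(sum(n for n in lengths if n >= 2) / L)
        assert stats["Seg_3"] == pytest.approx(sum(n for n in lengths if n >= 3) / L)
        if runs:
            assert stats["SegFirst"] == pytest.approx((runs[0][0] + 1) / L)
            assert stats["SegLast"] == pytest.approx((runs[-1][0] + runs[-1][1]) / L)

    def test_rigid_segment_ladder_example(self):
        # one low-B run of 12 residues in a 20-residue chain, k = 10
        mask = np.zeros(20, dtype=bool)
        mask[4:16] = True
        assert segment_features(mask)["Seg_10"] == pytest.approx(12 / 20)
        assert segment_features(mask)["Seg_15"] == 0.0

    def test_state_set_runs(self):
        # "CCHHECC" with states {C,H}: runs CCHH (4) and CC (2)
        mask = np.array([c in "CH" for c in "CCHHECC"])
        stats = segment_features(mask)
        assert stats["SegLongest"] == pytest.approx(4 / 7)
        assert stats["SegFrac"] == pytest.approx(6 / 7)


def brute_force_strand_free(ss):
    best = 0
    for i in range(len(ss)):
        for j in range(i, len(ss)):
            sub = ss[i : j + 1]
            if "E" not in sub:
                best = max(best, len(sub))
    return best


class TestLongestStrandFree:
    @pytest.mark.parametrize("ss,expected", [
        ("CCHHECC", 4),
        ("EEEE", 0),
        ("CHCHCH", 6),
    ])
    def test_examples(self, ss, expected):
        rec = make_record(sequence="A" * len(ss), ss=ss)
        raw, rel = longest_strand_free_segment(rec)
        assert raw == expected
        assert rel == pytest.approx(expected / len(ss))

    @given(st.text(alphabet="HEC", min_size=1, max_size=12))
    @settings(max_examples=150, deadline=None)
    def test_matches_quadratic_oracle(self, ss):
        rec = make_record(sequence="A" * len(ss), ss=ss)
        assert longest_strand_free_segment(rec)[0] == brute_force_strand_free(ss)


class TestFusion:
    def _toy(self):
        # 10 residues; exactly 2..5 (1-based) satisfy all four states
        ss = "CEEEECCCCC"
        domain = [0, 1, 1, 1, 1, 0, 0, 0, 0, 0]
        bf = [1, -1, -1, -1, -1, 1, 1, 1, 1, 1]  # low (rigid) at 2..5
        rsa = [0.9, 0.1, 0.1, 0.1, 0.1, 0.9, 0.9, 0.9, 0.9, 0.9]
        return make_record(sequence="A" * 10, ss=ss, domain=domain, bfactor=bf, rsa=rsa)

    def test_named_quad_conjunction(self):
        ctx = _Context(preprocess_tracks(self._toy()))
        combo = {"ss": "HE", "domain": "in", "bfactor": "low", "exposure": "buried"}
        assert fusion_value(ctx, combo) == pytest.approx(0.4)

    def test_empty_conjunction(self):
        rec = make_record(sequence="A" * 4, ss="EEEE",
                          domain=[1, 1, 1, 1], bfactor=[-1, -1, -1, -1])
        ctx = _Context(preprocess_tracks(rec))
        combo = {"ss": "CH", "bfactor": "high", "domain": "notin"}
        assert fusion_value(ctx, combo) == 0.0

    def test_absorbing_conjunction_equals_ss_composition(self):
        rec = make_record(sequence="A" * 6, ss="HHHEEC",
                          domain=[1] * 6, bfactor=[-1] * 6)
        ctx = _Context(preprocess_tracks(rec))
        conj = fusion_value(ctx, {"ss": "HE", "domain": "in", "bfactor": "low"})
        ss_only = fusion_value(ctx, {"ss": "HE", "domain": "in"})
        assert conj == pytest.approx(ss_only) == pytest.approx(5 / 6)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_conjunction_monotone(self, seed):
        rng = np.random.default_rng(seed)
        rec = preprocess_tracks(random_full_record(rng, length=40))
        ctx = _Context(rec)
        combo = {"ss": "CH", "domain": "in", "exposure": "exposed"}
        full = fusion_value(ctx, combo)
        for source in combo:
            single = fusion_value(ctx, {source: combo[source]})
            assert full <= single + 1e-12


class TestEntropies:
    def test_uniform_wop_row(self):
        p = wop_to_probs(np.full((1, 20), 5.0))
        assert shannon_entropy(p[0]) == pytest.approx(LOG2_20)
        assert relative_entropy(p[0]) == pytest.approx(0.0, abs=1e-12)

    def test_one_hot_wop_row(self):
        row = np.zeros((1, 20))
        row[0, 3] = 100.0
        p = wop_to_probs(row)
        assert shannon_entropy(p[0]) == pytest.approx(0.0, abs=1e-12)
        assert relative_entropy(p[0]) == pytest.approx(LOG2_20)

    def test_half_half_row(self):
        row = np.zeros((1, 20))
        row[0, 0] = row[0, 1] = 50.0
        assert shannon_entropy(wop_to_probs(row)[0]) == pytest.approx(1.0)

    def test_all_zero_wop_row_becomes_uniform(self):
        p = wop_to_probs(np.zeros((1, 20)))
        np.testing.assert_allclose(p[0], 1 / 20)

    def test_pssm_probs_are_normalized_and_monotone(self):
        pssm = np.array([[0] * 19 + [8], [0] * 20])
        p = pssm_to_probs(pssm)
        np.testing.assert_allclose(p.sum(axis=1), 1.0)
        assert p[0, 19] > p[0, 0]  # higher score -> higher probability


class TestConditionedEntropy:
    def _record_with_rows(self, ss, rows):
        wop = np.array(rows, dtype=float)
        return preprocess_tracks(make_record(sequence="A" * len(ss), ss=ss, wop=wop))

    def test_degenerate_rows_under_condition(self):
        one_hot = [100.0] + [0.0] * 19
        rec = self._record_with_rows("HHHC", [one_hot, one_hot, one_hot, [5.0] * 20])
        ctx = _Context(rec)
        val, ok = conditioned_entropy_value(ctx, "wop", "ent", {"type": "ss", "value": "H"})
        assert ok and val == pytest.approx(0.0, abs=1e-12)

    def test_restriction_identity(self):
        rng = np.random.default_rng(5)
        rows = rng.dirichlet(np.ones(20), size=4) * 100
        rec = self._record_with_rows("HHHH", rows)
        ctx = _Context(rec)
        cond, _ = conditioned_entropy_value(ctx, "wop", "ent", {"type": "ss", "value": "H"})
        assert cond == pytest.approx(float(ctx.row_entropies("wop").mean()))

    def test_exposed_subset_hand_computed(self):
        half = [50.0, 50.0] + [0.0] * 18
        quarter = [25.0] * 4 + [0.0] * 16
        one_hot = [100.0] + [0.0] * 19
        rec = make_record(sequence="AAA", ss="CCC", wop=np.array([half, quarter, one_hot]),
                          rsa=[0.9, 0.9, 0.1])
        ctx = _Context(preprocess_tracks(rec))
        val, ok = conditioned_entropy_value(ctx, "wop", "ent",
                                            {"type": "exposure", "value": "exposed"})
        assert ok and val == pytest.approx((1.0 + 2.0) / 2)  # mean of 1-bit and 2-bit rows

    def test_empty_condition_flagged_zero(self):
        rec = self._record_with_rows("CCC", [[5.0] * 20] * 3)
        ctx = _Context(rec)
        val, ok = conditioned_entropy_value(ctx, "wop", "ent", {"type": "ss", "value": "H"})
        assert val == 0.0 and not ok


class TestExtraction:
    def test_vector_shape_determinism_no_nan(self, catalog):
        rng = np.random.default_rng(7)
        rec = random_full_record(rng, length=50)
        fv1 = extract_features(rec, catalog)
        fv2 = extract_features(rec, catalog)
        assert len(fv1.values) == len(catalog)
        assert np.isfinite(fv1.values).all()
        np.testing.assert_array_equal(fv1.values, fv2.values)
        assert fv1.fingerprint == catalog.fingerprint

    def test_missing_track_policy(self, catalog):
        rec = make_record(sequence="ACDEFGHIKL", ss="CCCHHHCCCC")
        fv = extract_features(rec, catalog)
        assert np.isfinite(fv.values).all()
        # every signal-family feature is zero and flagged
        sig_ids = [d.id for d in catalog if d.family == "signal"]
        for fid in sig_ids:
            assert fid in fv.missing
            assert fv.values[catalog.ids.index(fid)] == 0.0

    def test_bounded_families(self, catalog, small_dataset):
        fv = extract_features(small_dataset[0], catalog)
        for j, d in enumerate(catalog):
            v = fv.values[j]
            if d.family in ("aa_comp", "fusion", "exposure"):
                assert 0.0 <= v <= 1.0
            if d.family == "profile_entropy" and d.params["stat"].startswith("row_ent"):
                assert 0.0 <= v <= LOG2_20 + 1e-9
            if d.family == "conditioned_entropy" and d.params["stat"] == "rel_ent":
                assert v >= -1e-12

    def test_ss_compositions_sum_to_one(self, catalog, small_dataset):
        fv = extract_features(small_dataset[3], catalog)
        total = sum(fv.values[catalog.ids.index(f"SS_{s}_SegFrac")] for s in "HEC")
        assert total == pytest.approx(1.0)

    def test_mixed_track_completeness_refused(self, catalog):
        full = make_record(sequence="ACDEF", ss="CCCCC", record_id="a")
        partial = make_record(sequence="ACDEF", record_id="b")
        with pytest.raises(FormatError, match="track completeness"):
            extract_matrix([full, partial], catalog)

    def test_catalog_yaml_round_trip(self, catalog, tmp_path):
        p = tmp_path / "catalog.yaml"
        catalog.to_yaml(p)
        from discon.features import FeatureCatalog
        back = FeatureCatalog.from_yaml(p)
        assert back.ids == catalog.ids
        assert back.fingerprint == catalog.fingerprint
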