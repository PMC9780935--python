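"""MS1 matching, fragment evidence, control exclusion and confidence levels."""

import dataclasses

import pytest

from limoscreen.annotate import (
    AnnotationHit,
    Feature,
    MS2Spectrum,
    assign_fragments,
    control_exclusion,
    default_fragment_rules,
    match_features,
    msi_level,
)
from limoscreen.chemcore import M_H_NEG, anion_mz, ion_mz, parse_formula
from limoscreen.io import parse_msms, table2_features
from limoscreen.pipeline import screen

FRAG_RULES = default_fragment_rules()


def feat(mz, fid="f1", rt=1.0, ms2=None):
    return Feature(fid, mz, rt, (), ms2)


class TestMatch:
    def test_glucuronide_diol_acid_example(self, library):
        hits, unmatched = match_features([feat(375.1304)], library)
        assert not unmatched
        best = hits[0]
        assert best.label == "limonene+COOH+OH+OH glucuronide"
        assert best.theoretical_mz == pytest.approx(375.12967, abs=1e-5)

    def test_zero_tolerance_degenerate(self, library):
        theo = library[0].mz(M_H_NEG)
        hits, _ = match_features([feat(theo)], library, tol_ppm=0.0)
        assert any(h.candidate is library[0] for h in hits)
        _, unmatched = match_features([feat(theo * (1 + 1e-9) + 1e-6)],
                                      library, tol_ppm=0.0)
        assert unmatched

    def test_decoy_mass_is_orphaned(self, library):
        # exhaustively confirmed: no library mass within 10 ppm of 500.0000
        assert all(abs((c.mz(M_H_NEG) - 500.0) / c.mz(M_H_NEG)) * 1e6 > 10
                   for c in library)
        hits, unmatched = match_features([feat(500.0)], library)
        assert not hits and len(unmatched) == 1

    def test_monotone_in_tolerance(self, library, urine_features):
        def key(h):
            return (h.feature_id, h.label)
        for t1, t2 in [(0.5, 2.0), (2.0, 5.0), (5.0, 10.0)]:
            h1, _ = match_features(urine_features, library, tol_ppm=t1)
            h2, _ = match_features(urine_features, library, tol_ppm=t2)
            assert {key(h) for h in h1} <= {key(h) for h in h2}

    def test_hits_ranked_by_abs_ppm(self, library, urine_features):
        hits, _ = match_features(urine_features, library)
        per_feature = {}
        for h in hits:
            per_feature.setdefault(h.feature_id, []).append(h)
        for fh in per_feature.values():
            errs = [abs(h.ppm) for h in fh]
            assert errs == sorted(errs)


class TestFixtureScreen:
    def test_all_features_annotated(self, library, urine_features):
        hits, unmatched = match_features(urine_features, library)
        assert not unmatched
        assert len({h.feature_id for h in hits}) == 23

    def test_distinct_identity_counts(self, library, urine_features,
                                      liver_features):
        urine = screen(urine_features, library)
        liver = screen(liver_features, library)
        assert len(urine.distinct_labels()) == 16
        assert len(liver.distinct_labels()) == 3

    def test_isomer_suffixes_follow_retention_time(self, library,
                                                   urine_features):
        res = screen(urine_features, library)
        # three glucuronide isomers of the hydroxylated acid, rt 2.95 < 3.18 < 3.57
        assert res.display_labels["M4-I"].endswith(" I")
        assert res.display_labels["M4-II"].endswith(" II")
        assert res.display_labels["M4-III"].endswith(" III")


class TestFragments:
    def _hit_for(self, library, label, mz, fid="f1", rt=1.0):
        cand = next(c for c in library if c.label == label)
        return AnnotationHit(fid, mz, rt, cand, cand.mz(M_H_NEG), 0.0)

    def test_glucuronide_evidence_perillic_acid(self, library):
        spec = MS2Spectrum(((261.0763, 10), (175.0230, 3), (165.0923, 45),
                            (113.0241, 35), (99.0081, 20), (85.0295, 55),
                            (71.0141, 40), (59.0142, 100), (44.9993, 25)))
        hit = self._hit_for(library, "limonene+COOH glucuronide", 341.1243)
        out = assign_fragments(hit, spec, FRAG_RULES)
        assert len(out.matched_diagnostics) == 5
        assert out.complement_matched  # 341.1242 - 176.0321 = 165.0921

    def test_sulfate_evidence(self, library):
        spec = MS2Spectrum(((245.0517, 20), (165.0919, 10), (79.9569, 20),
                            (74.0241, 20), (59.0151, 45)))
        hit = self._hit_for(library, "limonene+COOH sulfate", 245.0490)
        out = assign_fragments(hit, spec, FRAG_RULES, frag_tol=0.001)
        assert "O3S" in out.matched_diagnostics  # the SO3 radical anion
        out5 = assign_fragments(hit, spec, FRAG_RULES, frag_tol=0.005)
        assert out5.complement_matched  # 245.0489 - 79.9568 = 165.0921

    def test_unconjugated_candidate_collects_nothing(self, library):
        spec = MS2Spectrum(((175.0248, 50), (113.0244, 100)))
        cand = next(c for c in library if c.label == "limonene+COOH")
        hit = AnnotationHit("f1", 165.0919, 1.0, cand, cand.mz(M_H_NEG), 0.0)
        out = assign_fragments(hit, spec, FRAG_RULES)
        assert out.matched_diagnostics == ()
        assert not out.complement_matched

    def test_diagnostics_never_exceed_precursor(self, library):
        # a spectrum "containing" the glucuronate ion above a tiny precursor
        spec = MS2Spectrum(((175.0248, 100),))
        cand = next(c for c in library if c.label == "limonene+OH glucuronide")
        hit = AnnotationHit("f1", 100.0, 1.0, cand, 100.0, 0.0)
        out = assign_fragments(hit, spec, FRAG_RULES)
        assert "C6H7O6" not in out.matched_diagnostics

    def test_unknown_conjugate_class_raises(self, library):
        hit = self._hit_for(library, "limonene+COOH sulfate", 245.0490)
        with pytest.raises(KeyError):
            assign_fragments(hit, MS2Spectrum(((100.0, 100),)), {})


class TestControlExclusion:
    def _hits(self, library, fids):
        cand = library[0]
        return [AnnotationHit(f, cand.mz(M_H_NEG), 1.0, cand,
                              cand.mz(M_H_NEG), 0.0) for f in fids]

    def test_equal_presence_excluded(self, library):
        hits = self._hits(library, ["f1"])
        inten = {"f1": {"a": 100.0, "b": 100.0}}
        groups = {"a": "HL", "b": "HL0.8"}
        out = control_exclusion(hits, inten, groups, ["HL"])
        assert out[0].control_present

    def test_absent_in_controls_retained(self, library):
        hits = self._hits(library, ["f1"])
        inten = {"f1": {"n1": 0.0, "h1": 0.0, "l1": 500.0, "l2": 800.0}}
        groups = {"n1": "NL", "h1": "HL", "l1": "HL0.1", "l2": "HL0.8"}
        out = control_exclusion(hits, inten, groups, ["NL", "HL"])
        assert not out[0].control_present

    def test_requires_control_samples(self, library):
        hits = self._hits(library, ["f1"])
        with pytest.raises(ValueError):
            control_exclusion(hits, {"f1": {"a": 1.0}}, {"a": "HL0.1"}, [])
        with pytest.raises(ValueError):
            control_exclusion(hits, {"f1": {"a": 1.0}}, {"a": "HL0.1"}, ["NL"])


class TestMsiLevels:
    def _hit(self, library, **kw):
        cand = library[0]
        base = AnnotationHit("f1", cand.mz(M_H_NEG), 1.0, cand,
                             cand.mz(M_H_NEG), 0.0)
        return dataclasses.replace(base, **kw)

    def test_ms2_corroborated_is_level_2(self, library):
        hit = self._hit(library, matched_diagnostics=("C6H7O6",))
        assert msi_level(hit).msi == "2"
        hit = self._hit(library, complement_matched=True)
        assert msi_level(hit).msi == "2"

    def test_ms1_only_is_level_3(self, library):
        assert msi_level(self._hit(library)).msi == "3"

    def test_isotope_floor_rejects(self, library):
        hit = self._hit(library, isotope_score=0.0,
                        matched_diagnostics=("C6H7O6",))
        assert msi_level(hit).msi == "rejected"


def test_printed_spectra_parse_and_fragment_maxima(fixture_df):
    """All packaged product-ion lists parse; abundances are valid percents."""
    n_spectra = 0
    for _, row in fixture_df.iterrows():
        spec = parse_msms(row["msms"])
        if spec is None:
            continue
        n_spectra += 1
        assert all(0 < ab <= 100 for _, ab in spec.fragments)
    assert n_spectra == 22  # one metabolite has no recorded spectrum
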