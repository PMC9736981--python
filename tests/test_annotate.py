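"""MS1 matching, MS2 evidence, confidence tiers, and isomer consolidation."""

import pytest

import biotransid as bt
from biotransid.annotate import MatchEvidence, associate_spectra

PARENT = bt.parse_formula(bt.PARENT_FORMULA)


def negative_peak(mz, rt=9.0, matrix="U", intensity=50000.0, feature_id=None):
    return bt.Peak(matrix, "negative", rt, mz, intensity, feature_id=feature_id)


class TestMatchMS1:
    def test_sulfate_conjugate_matched_within_tolerance(self, candidates):
        (match,) = bt.match_ms1(candidates, [negative_peak(401.06885)])
        assert match.candidate.formula.hill() == "C20H18O7S"
        assert match.ppm == pytest.approx(-2.99, abs=0.01)

    def test_out_of_tolerance_peak_unmatched(self, candidates):
        assert bt.match_ms1(candidates, [negative_peak(401.200)]) == []

    def test_empty_peak_list(self, candidates):
        assert bt.match_ms1(candidates, []) == []

    def test_every_match_within_tolerance(self, candidates, candidate_mzs, fixture_rows):
        config = bt.SyntheticRunConfig(jitter_ppm=5.0, decoy_count_per_matrix=10, seed=11)
        peaks, _ = bt.generate_run(fixture_rows, config, exclusion_masses=candidate_mzs)
        matches = bt.match_ms1(candidates, peaks, max_ppm=10.0)
        assert matches
        assert all(abs(m.ppm) <= 10.0 for m in matches)

    def test_positive_mode_matches_parent_only(self, candidates):
        oxidised_pos = bt.ion_mz(bt.parse_formula("C20H18O5"), "[M+H]+")
        peak = bt.Peak("PM", "positive", 7.9, oxidised_pos, 80000.0)
        assert bt.match_ms1(candidates, [peak]) == []
        parent_peak = bt.Peak("PM", "positive", 11.45, 323.12659, 80000.0)
        (match,) = bt.match_ms1(candidates, [parent_peak])
        assert match.candidate.n_steps == 0

    def test_intensity_thresholds_applied_when_supplied(self, candidates):
        weak = negative_peak(401.06885, intensity=5000.0)
        assert bt.match_ms1(candidates, [weak], thresholds=bt.IntensityThresholds()) == []


class TestMS2Evidence:
    def test_glucuronide_dpis(self):
        spectrum = bt.MS2Spectrum(
            497.14453, "negative", 6.0,
            ((321.11, 100.0), (175.02, 30.0), (113.02, 64.0)),
        )
        hits = bt.match_dpis(spectrum, bt.load_dpi_library())
        labels = {ion.label for ion, _ in hits}
        assert {"glua-175", "glua-113"} <= labels

    def test_parent_core_dpi(self):
        spectrum = bt.MS2Spectrum(
            321.11182, "negative", 11.47, ((321.11, 100.0), (265.05, 18.15)),
        )
        labels = {ion.label for ion, _ in bt.match_dpis(spectrum, bt.load_dpi_library())}
        assert "core-minus-c4h8" in labels

    def test_no_hits_for_unrelated_fragment(self):
        spectrum = bt.MS2Spectrum(1000.0, "negative", 5.0, ((999.0, 100.0),))
        assert bt.match_dpis(spectrum, bt.load_dpi_library()) == []

    def test_formula_dpi_targets_respect_polarity(self):
        lib = [ion for ion in bt.load_dpi_library() if ion.label == "aglycone-anion"]
        neg = bt.MS2Spectrum(497.14453, "negative", 6.0, ((321.11323, 100.0),))
        assert bt.match_dpis(neg, lib)

    @pytest.mark.parametrize(
        "precursor, fragment, label",
        [
            (497.14453, 321.11, "glucuronyl"),
            (401.06885, 321.11, "sulfo"),
            (321.11182, 265.05, "butene"),
        ],
    )
    def test_neutral_losses(self, precursor, fragment, label):
        spectrum = bt.MS2Spectrum(precursor, "negative", 6.0, ((fragment, 100.0),))
        hits = bt.detect_neutral_losses(spectrum, precursor, bt.load_neutral_loss_library())
        assert label in {loss.label for loss, _, _ in hits}

    def test_fragment_equal_to_precursor_is_not_a_loss(self):
        spectrum = bt.MS2Spectrum(401.06885, "negative", 9.0, ((401.06885, 100.0),))
        assert bt.detect_neutral_losses(spectrum, 401.06885, bt.load_neutral_loss_library()) == []

    def test_successive_losses_between_fragment_pairs(self):
        # glucuronide then sulfate: 577.10 -> 497.14 (SO3) -> 321.11 (GluA)
        spectrum = bt.MS2Spectrum(
            577.10120, "negative", 7.28, ((497.145, 80.0), (321.113, 100.0)),
        )
        hits = bt.detect_neutral_losses(
            spectrum, 577.10120, bt.load_neutral_loss_library(),
            include_fragment_pairs=True, tol_da=0.02,
        )
        labels = {loss.label for loss, _, _ in hits}
        assert {"sulfo", "glucuronyl"} <= labels


class TestConfidence:
    def test_tier_rule(self, candidates):
        (match,) = bt.match_ms1(candidates, [negative_peak(401.06885)])
        assert bt.assign_confidence(match, [object(), object()], []) == "A"
        assert bt.assign_confidence(match, [], [object()]) == "B"
        assert bt.assign_confidence(match, [], []) == "C"


def evidence_at(candidates, mz, rt, matrix, feature_id=None):
    (match,) = bt.match_ms1(candidates, [negative_peak(mz, rt=rt, matrix=matrix,
                                                       feature_id=feature_id)])
    return MatchEvidence(match=match)


class TestConsolidation:
    def test_rt_separated_isomers_split(self, candidates):
        mz = 339.12259  # hydration product C20H20O5, three isomers
        evs = [
            evidence_at(candidates, mz, rt, matrix)
            for rt, matrix in [(7.96, "F"), (8.22, "U"), (9.45, "F")]
        ]
        records = bt.consolidate_isomers(evs, rt_tol=0.2)
        assert len(records) == 3

    def test_same_rt_across_matrices_merges(self, candidates):
        evs = [
            evidence_at(candidates, 401.06888, 9.18, matrix)
            for matrix in bt.MATRICES
        ]
        (record,) = bt.consolidate_isomers(evs, rt_tol=0.2)
        assert all(record.matrix_presence.values())

    def test_single_match_single_record(self, candidates):
        records = bt.consolidate_isomers([evidence_at(candidates, 401.06885, 9.08, "PS")])
        assert len(records) == 1

    def test_observation_count_preserved(self, candidates):
        evs = [
            evidence_at(candidates, 339.12259, rt, m)
            for rt, m in [(7.96, "F"), (7.99, "U"), (8.22, "U"), (9.45, "F")]
        ] + [evidence_at(candidates, 401.06885, 9.08, "PS")]
        records = bt.consolidate_isomers(evs, rt_tol=0.2)
        assert sum(len(r.observations) for r in records) == len(evs)

    def test_feature_id_grouping(self, candidates):
        evs = [
            evidence_at(candidates, 337.10727, 8.06, "U", feature_id="M41"),
            evidence_at(candidates, 337.10742, 8.13, "PM", feature_id="M42"),
        ]
        # 0.07 min apart: RT clustering at the 0.2-min default merges them,
        # carried feature labels keep them apart.
        assert len(bt.consolidate_isomers(evs, rt_tol=0.2)) == 1
        assert len(bt.consolidate_isomers(evs, use_feature_ids=True)) == 2


class TestSpectrumAssociation:
    def test_associates_by_mz_rt_polarity(self):
        peak = negative_peak(401.06885, rt=9.08)
        good = bt.MS2Spectrum(401.06885, "negative", 9.10, ((321.11, 100.0),))
        wrong_rt = bt.MS2Spectrum(401.06885, "negative", 10.5, ((321.11, 100.0),))
        wrong_pol = bt.MS2Spectrum(401.06885, "positive", 9.08, ((321.11, 100.0),))
        wrong_mz = bt.MS2Spectrum(402.5, "negative", 9.08, ((321.11, 100.0),))
        assert associate_spectra(peak, [good, wrong_rt, wrong_pol, wrong_mz]) == [good]


class TestPresenceMatrix:
    def test_matrix_from_clean_run(self, clean_result):
        pm = bt.build_presence_matrix(clean_result.annotations)
        assert pm.shape == (72, 7)
        assert pm.loc["M58"].all()
        assert pm["U"].sum() == 43

    def test_empty_annotations(self):
        pm = bt.build_presence_matrix([])
        assert pm.empty

    def test_tiers_partition_annotations(self, clean_result):
        tiers = [a.confidence for a in clean_result.annotations]
        assert set(tiers) <= {"A", "B", "C"}
        assert len(tiers) == 72
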