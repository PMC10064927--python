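import numpy as np
import pytest

from isletkit import synthetic as syn
from isletkit.line_metrics import Polyline
from isletkit.opinions import (
    EditKind,
    GraphicalEdit,
    ImageOpinion,
    IsletOpinion,
    OpinionValidationError,
    Quality,
    Verdict,
    consensus_report,
    read_opinions_csv,
    tally_image_classifications,
    tally_islet_opinions,
    validate_opinion,
    validate_opinions,
    write_opinions_csv,
)
from isletkit.selection import build_validation_set


@pytest.fixture(scope="module")
def manifest_and_bundle(tmp_path_factory):
    out = tmp_path_factory.mktemp("opbundle")
    bundle = syn.make_bundle(out, n_images=8, seed=21, shape_px=(320, 320))
    manifest = build_validation_set(bundle, n_images=8, seed=3, quota_per_image=5)
    return manifest, bundle


def open_line():
    return Polyline(points=((1.0, 1.0), (5.0, 5.0)))


def closed_line():
    return Polyline(points=((1.0, 1.0), (1.0, 8.0), (8.0, 4.0)), closed=True)


class TestValidation:
    def test_true_contour_without_edits_is_valid(self, manifest_and_bundle):
        manifest, _ = manifest_and_bundle
        entry = manifest.entries[0]
        op = IsletOpinion(
            expert="e1", image=entry.image_id, islet=1, verdict=Verdict.TRUE_CONTOUR
        )
        assert validate_opinion(op, manifest) == []

    def test_true_contour_with_edit_is_violation(self, manifest_and_bundle):
        manifest, _ = manifest_and_bundle
        entry = manifest.entries[0]
        op = IsletOpinion(
            expert="e1",
            image=entry.image_id,
            islet=1,
            verdict=Verdict.TRUE_CONTOUR,
            edits=(GraphicalEdit(EditKind.FULL_REDRAW, closed_line()),),
        )
        assert any("must not carry edits" in v for v in validate_opinion(op, manifest))

    @pytest.mark.parametrize(
        "kind, geometry, phrase",
        [
            (EditKind.SEPARATION_LINE, None, "requires geometry"),
            (EditKind.FULL_REDRAW, None, "requires geometry"),
            (EditKind.NOT_AN_ISLET, None, None),  # valid: no geometry
        ],
    )
    def test_geometry_presence_rules(self, manifest_and_bundle, kind, geometry, phrase):
        manifest, _ = manifest_and_bundle
        entry = manifest.entries[0]
        op = IsletOpinion(
            expert="e1",
            image=entry.image_id,
            islet=1,
            verdict=Verdict.FALSE_CONTOUR,
            edits=(GraphicalEdit(kind, geometry),),
        )
        violations = validate_opinion(op, manifest)
        if phrase is None:
            assert violations == []
        else:
            assert any(phrase in v for v in violations)

    def test_separation_line_must_be_open_and_redraw_closed(self, manifest_and_bundle):
        manifest, _ = manifest_and_bundle
        entry = manifest.entries[0]
        bad_sep = IsletOpinion(
            expert="e1", image=entry.image_id, islet=1, verdict=Verdict.FALSE_CONTOUR,
            edits=(GraphicalEdit(EditKind.SEPARATION_LINE, closed_line()),),
        )
        assert any("must be open" in v for v in validate_opinion(bad_sep, manifest))
        bad_redraw = IsletOpinion(
            expert="e1", image=entry.image_id, islet=1, verdict=Verdict.FALSE_CONTOUR,
            edits=(GraphicalEdit(EditKind.FULL_REDRAW, open_line()),),
        )
        assert any("must be closed" in v for v in validate_opinion(bad_redraw, manifest))

    def test_unknown_image_and_islet_rejected(self, manifest_and_bundle):
        manifest, _ = manifest_and_bundle
        assert validate_opinion(
            ImageOpinion(expert="e1", image="nope", quality=Quality.GOOD), manifest
        ) == ["unknown image 'nope'"]
        entry = manifest.entries[0]
        op = IsletOpinion(
            expert="e1", image=entry.image_id, islet=999, verdict=Verdict.SKIPPED
        )
        assert any("unknown islet" in v for v in validate_opinion(op, manifest))

    def test_duplicate_expert_target_pair_rejected(self, manifest_and_bundle):
        manifest, _ = manifest_and_bundle
        entry = manifest.entries[0]
        op = ImageOpinion(expert="e1", image=entry.image_id, quality=Quality.GOOD)
        with pytest.raises(OpinionValidationError, match="duplicate"):
            validate_opinions([op, op], manifest)


class TestImageTallies:
    def test_all_good_is_unanimous(self):
        ops = [
            ImageOpinion(expert=f"e{i}", image=f"img{j}", quality=Quality.GOOD)
            for i in range(8)
            for j in range(8)
        ]
        tallies = tally_image_classifications(ops)
        assert len(tallies) == 8
        assert all(t.unanimous for t in tallies.values())

    def test_one_dissent_breaks_unanimity(self):
        ops = [
            ImageOpinion(expert=f"e{i}", image="img", quality=Quality.GOOD)
            for i in range(7)
        ] + [ImageOpinion(expert="e7", image="img", quality=Quality.BORDERLINE)]
        tally = tally_image_classifications(ops)["img"]
        assert not tally.unanimous
        assert tally.counts == {"GOOD": 7, "BORDERLINE": 1, "UNACCEPTABLE": 0}

    def test_configured_split_reproduced(self):
        """8 experts x 8 images; 4 images unanimous, 4 contested."""
        rng = np.random.default_rng(5)
        ops = []
        for j in range(8):
            dissenter = int(rng.integers(0, 8))
            for i in range(8):
                contested = j >= 4 and i == dissenter
                ops.append(
                    ImageOpinion(
                        expert=f"e{i}",
                        image=f"img{j}",
                        quality=Quality.UNACCEPTABLE if contested else Quality.GOOD,
                    )
                )
        tallies = tally_image_classifications(ops)
        assert sum(t.unanimous for t in tallies.values()) == 4


class TestIsletTallies:
    def test_no_false_verdicts_no_disputed_islets(self):
        ops = [
            IsletOpinion(expert=f"e{i}", image="img", islet=k, verdict=Verdict.TRUE_CONTOUR)
            for i in range(3)
            for k in range(1, 4)
        ]
        totals = tally_islet_opinions(ops)
        assert totals.n_graphical_opinions == 0
        assert totals.n_disputed_islets == 0

    def test_configured_69_opinions_over_24_of_33_islets(self):
        """Fixture emulating a validation round: 33 marked islets, 24 of them
        receiving a total of 69 graphical opinions."""
        rng = np.random.default_rng(17)
        islets = [(f"img{j}", k) for j in range(8) for k in range(1, 6)][:33]
        disputed = [islets[i] for i in rng.choice(33, size=24, replace=False)]
        # Distribute 69 edits over the 24 disputed islets (each >= 1).
        counts = np.ones(24, dtype=int)
        for _ in range(69 - 24):
            counts[rng.integers(0, 24)] += 1
        ops = []
        for (image, islet), n_edits in zip(disputed, counts):
            for e in range(n_edits):
                ops.append(
                    IsletOpinion(
                        expert=f"e{e}", image=image, islet=islet,
                        verdict=Verdict.FALSE_CONTOUR,
                        edits=(GraphicalEdit(EditKind.FULL_REDRAW, closed_line()),),
                    )
                )
        for image, islet in set(islets) - set(disputed):
            ops.append(
                IsletOpinion(expert="e0", image=image, islet=islet, verdict=Verdict.TRUE_CONTOUR)
            )
        totals = tally_islet_opinions(ops)
        assert totals.n_graphical_opinions == 69
        assert totals.n_disputed_islets == 24

    def test_not_an_islet_counts_as_graphical_and_flags_identity(self):
        ops = [
            IsletOpinion(
                expert="e1", image="img", islet=k, verdict=Verdict.FALSE_CONTOUR,
                edits=(GraphicalEdit(EditKind.NOT_AN_ISLET, None),),
            )
            for k in (1, 2)
        ]
        totals = tally_islet_opinions(ops)
        assert totals.n_graphical_opinions == 2
        flagged = [
            t for t in totals.per_islet.values()
            if t.edit_kind_counts["NOT_AN_ISLET"] > 0
        ]
        assert len(flagged) == 2

    def test_totals_conserve_graphical_counts(self, manifest_and_bundle):
        manifest, bundle = manifest_and_bundle
        profiles = [
            syn.ExpertProfile(f"x{i}", jitter_sigma_px=1.0, p_false_call=0.4, seed_offset=i)
            for i in range(5)
        ]
        ops = syn.simulate_opinions(manifest, profiles, bundle, seed=9)
        islet_ops = [o for o in ops if isinstance(o, IsletOpinion)]
        totals = tally_islet_opinions(islet_ops)
        assert totals.n_graphical_opinions == sum(1 for o in islet_ops if o.edits)
        assert totals.n_graphical_opinions == sum(
            len(t.experts_with_edits) for t in totals.per_islet.values()
        )


class TestCsvInterchange:
    def test_opinions_round_trip(self, tmp_path, manifest_and_bundle):
        manifest, bundle = manifest_and_bundle
        profiles = [
            syn.ExpertProfile(f"x{i}", jitter_sigma_px=1.0, p_false_call=0.5, seed_offset=i)
            for i in range(3)
        ]
        ops = syn.simulate_opinions(manifest, profiles, bundle, seed=2)
        path = tmp_path / "opinions.csv"
        write_opinions_csv(ops, path)
        again = read_opinions_csv(path)
        assert len(again) == len(ops)
        for a, b in zip(ops, again):
            assert type(a) is type(b)
            if isinstance(a, IsletOpinion):
                assert (a.expert, a.image, a.islet, a.verdict) == (
                    b.expert, b.image, b.islet, b.verdict,
                )
                assert len(a.edits) == len(b.edits)
                for ea, eb in zip(a.edits, b.edits):
                    assert ea.kind == eb.kind
                    if ea.geometry is not None:
                        assert np.allclose(ea.geometry.as_array(), eb.geometry.as_array())


@pytest.fixture(scope="module")
def report(tmp_path_factory, manifest_and_bundle):
    manifest, bundle = manifest_and_bundle
    profiles = [
        syn.ExpertProfile(f"secret_name_{i}", jitter_sigma_px=1.5,
                          p_false_call=0.4, seed_offset=i)
        for i in range(7)
    ]
    ops = syn.simulate_opinions(manifest, profiles, bundle, seed=6)
    out = tmp_path_factory.mktemp("report")
    csv_path = consensus_report(manifest, ops, bundle, out)
    return manifest, ops, out, csv_path


class TestConsensusReport:

    def test_crops_only_for_disputed_islets(self, report):
        manifest, ops, out, _ = report
        totals = tally_islet_opinions([o for o in ops if isinstance(o, IsletOpinion)])
        crops = {p.name for p in out.glob("*_islet*.png")}
        expected = {
            f"{t.image}_islet{t.islet}.png"
            for t in totals.per_islet.values()
            if t.disputed
        }
        assert crops == expected

    def test_expert_ids_anonymized_in_outputs(self, report):
        _, _, out, csv_path = report
        text = csv_path.read_text()
        assert "secret_name" not in text
        assert ",e1" in text or "e1," in text or "e1;" in text or "e1\n" in text

    def test_deterministic_file_set(self, report, tmp_path, manifest_and_bundle):
        manifest, ops, out, csv_path = report
        _, bundle = manifest_and_bundle
        again = tmp_path / "again"
        consensus_report(manifest, ops, bundle, again)
        assert sorted(p.name for p in again.iterdir()) == sorted(
            p.name for p in out.iterdir()
        )
        assert (again / "consensus.csv").read_bytes() == csv_path.read_bytes()
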