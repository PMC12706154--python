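"""Inverse resolution of duplicated alleles, copy-control, interference."""

import pytest

from startrac import expected_copy_vector, parse_diplotype
from startrac.calling import NO_CALL
from startrac.errors import ActivityError, InconsistentCallsError
from startrac.interpret import (
    annotate_activity,
    copy_control_check,
    flag_interference,
    resolve_duplication,
)
from startrac.io import candidates_for
from startrac.quantify import ChannelGate

from printed_tables import TABLE_COPY_NEUTRAL, TABLE_SV, plexes_of


def _observed_calls(entry, registry):
    """Expand a printed-table entry into channel -> integer call."""
    calls = {}
    for plex_name in plexes_of(entry):
        plex = registry.plexes[plex_name]
        ref_cn, var_cn = entry[plex_name]
        calls[plex.gt_target.ref_label] = ref_cn
        calls[plex.gt_target.var_label] = var_cn
    calls["g.4181C"] = entry["g.4181C"]
    return calls


class TestResolveDuplication:
    def test_duplication_assigned_to_allele_with_two_variant_copies(self, registry):
        report = resolve_duplication(
            {"g.2851C": 1, "g.2851T": 2, "g.4181C": 2}, ("*1", "*2"), registry
        )
        assert report.config_labels == ["*1/*2x2"]
        assert report.unique
        assert "CN_2851" in report.informative_plexes_used

    def test_two_informative_targets_agree(self, registry):
        report = resolve_duplication(
            {"g.1847G": 1, "g.1847A": 2}, ("*4", "*41"), registry
        )
        assert report.config_labels == ["*4x2/*41"]
        assert report.unique

    def test_non_informative_panel_reports_ambiguity(self, registry):
        """CN_2851 and CN_3184 cannot distinguish *2x2/*17 from *2/*17x2."""
        report = resolve_duplication(
            {"g.2851C": 0, "g.2851T": 3, "g.3184G": 3, "g.3184A": 0},
            ("*2", "*17"), registry,
        )
        assert report.config_labels == ["*2/*17x2", "*2x2/*17"]
        assert not report.unique

    def test_no_call_contributes_no_constraint_but_is_reported(self, registry):
        report = resolve_duplication(
            {"g.2851C": 1, "g.2851T": 2, "g.4181C": NO_CALL},
            ("*1", "*2"), registry,
        )
        assert report.config_labels == ["*1/*2x2"]
        assert report.observed["g.4181C"] is NO_CALL
        assert report.copy_control is None

    def test_inconsistent_calls_raise_with_residual(self, registry):
        with pytest.raises(InconsistentCallsError) as err:
            resolve_duplication(
                {"g.2851C": 1, "g.2851T": 2, "g.4181C": 4}, ("*1", "*2"),
                registry,
            )
        assert "g.4181C" in err.value.residual

    def test_deletion_candidate(self, registry):
        report = resolve_duplication(
            {"g.2851C": 1, "g.2851T": 0, "g.4181C": 0}, ("*1", "*5"), registry
        )
        assert report.config_labels == ["*1/*5"]

    @pytest.mark.parametrize(
        "sample", sorted({**TABLE_COPY_NEUTRAL, **TABLE_SV})
    )
    def test_round_trip_includes_consensus_config(self, sample, registry):
        """Feeding the forward model's own copy vector back through the
        resolver always recovers the consensus diplotype."""
        entry = {**TABLE_COPY_NEUTRAL, **TABLE_SV}[sample]
        calls = _observed_calls(entry, registry)
        panel = [registry.plexes[p] for p in plexes_of(entry)]
        report = resolve_duplication(
            calls, candidates_for(entry["diplotype"]), registry, panel
        )
        assert entry["diplotype"] in report.config_labels
        assert report.copy_control is not None and report.copy_control.passed

    # The informativeness law is stated for distinct single-allele candidate
    # pairs, so tandem-hybrid samples are outside its scope.
    _LAW_SAMPLES = sorted(
        s for s, e in TABLE_SV.items()
        if "+" not in e["diplotype"]
        and len(set(candidates_for(e["diplotype"]))) == 2
    )

    @pytest.mark.parametrize("sample", _LAW_SAMPLES)
    def test_uniqueness_iff_informative_call_used(self, sample, registry):
        """A unique resolution requires a valid call from an informative
        plex (single-allele candidate pairs)."""
        entry = TABLE_SV[sample]
        candidates = candidates_for(entry["diplotype"])
        calls = _observed_calls(entry, registry)
        panel = [registry.plexes[p] for p in plexes_of(entry)]
        report = resolve_duplication(calls, candidates, registry, panel)
        assert report.unique == bool(report.informative_plexes_used)

    def test_determinism(self, registry):
        calls = {"g.2851C": 0, "g.2851T": 3, "g.4181C": 3}
        reports = [
            resolve_duplication(calls, ("*2", "*17"), registry)
            for _ in range(3)
        ]
        labels = {tuple(r.config_labels) for r in reports}
        assert len(labels) == 1


class TestCopyControl:
    def test_duplicated_non_reference_allele(self, registry):
        config = parse_diplotype("*1/*4x2", registry)
        cc = copy_control_check(
            {"g.4181C": 2}, [config], registry.panel
        )
        assert cc.passed and cc.expected == 2 and cc.observed == 2

    def test_hybrid_exon9_dropout_lowers_expectation(self, registry):
        config = parse_diplotype("*10x2/*36+*10", registry)
        vec = expected_copy_vector(config, registry.plexes["CN_100"])
        assert vec["g.4181C"] == 3  # *36 exon 9 is CYP2D7-derived
        cc = copy_control_check({"g.4181C": 3}, [config], registry.panel)
        assert cc.passed

    def test_excess_copies_fail(self, registry):
        config = parse_diplotype("*1/*1", registry)
        cc = copy_control_check({"g.4181C": 4}, [config], registry.panel)
        assert not cc.passed and cc.expected == 0


def _gate(channel="g.1847G", pos_mean=6000.0, pos_sd=150.0, modes=1):
    return ChannelGate(channel=channel, n_pos=500, n_neg=1500, threshold=2000,
                       neg_mean=500.0, pos_mean=pos_mean, pos_sd=pos_sd,
                       pos_modes=modes)


class TestInterferenceFlags:
    def test_suppressed_scattered_positive_cluster(self):
        flag = flag_interference(_gate(pos_mean=1500.0, pos_sd=600.0))
        assert flag is not None and flag.signature == "amplitude-suppression"

    def test_multimodal_reference_recommends_alternative(self):
        flag = flag_interference(_gate(channel="ref", modes=2), is_reference=True)
        assert flag is not None and flag.signature == "reference-multimodal"
        assert "alternative reference" in flag.detail

    def test_clean_channel_unflagged(self):
        assert flag_interference(_gate()) is None
        assert flag_interference(_gate(channel="ref"), is_reference=True) is None


class TestActivityScore:
    @pytest.mark.parametrize("label, score, band", [
        ("*2x2/*4", 2.0, "normal metabolizer"),
        ("*2/*4x2", 1.0, "intermediate metabolizer"),
        ("*4/*4", 0.0, "poor metabolizer"),
    ])
    def test_published_examples(self, label, score, band, registry):
        config = parse_diplotype(label, registry)
        got_score, got_band = annotate_activity(config)
        assert got_score == pytest.approx(score)
        assert got_band == band

    def test_missing_allele_raises(self, registry):
        with pytest.raises(ActivityError, match=r"\*41"):
            annotate_activity(parse_diplotype("*1/*41", registry))

    def test_user_table_and_multiplicity(self, registry):
        score, band = annotate_activity(
            parse_diplotype("*1/*41x3", registry),
            activity_table={"*1": 1.0, "*41": 0.5},
        )
        assert score == pytest.approx(2.5)
        assert band == "ultrarapid metabolizer"
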