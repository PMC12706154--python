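"""Forward copy model: allele matrix, hybrids, diplotype labels."""

import dataclasses

import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from startrac import (
    DiplotypeConfig,
    HaplotypeConfig,
    expected_copy_vector,
    informative_assays,
    parse_diplotype,
    render_diplotype,
)
from startrac.alleles import REGIONS
from startrac.errors import DiplotypeParseError, MatrixIncompleteError

from printed_tables import TABLE_COPY_NEUTRAL, TABLE_SV, plexes_of

ALL_SAMPLES = {**TABLE_COPY_NEUTRAL, **TABLE_SV}


@pytest.mark.parametrize("sample", sorted(ALL_SAMPLES))
def test_forward_model_matches_published_calls(sample, registry):
    """Every published CN cell (copy-neutral and SV cohorts) is reproduced,
    including hybrid silencing for the *68 and *36 gene copies."""
    entry = ALL_SAMPLES[sample]
    config = parse_diplotype(entry["diplotype"], registry)
    for plex_name in plexes_of(entry):
        plex = registry.plexes[plex_name]
        vec = expected_copy_vector(config, plex)
        ref_cn, var_cn = entry[plex_name]
        assert vec[plex.gt_target.ref_label] == ref_cn
        assert vec[plex.gt_target.var_label] == var_cn
        assert vec["g.4181C"] == entry["g.4181C"]
        assert vec["ref"] == 2


@pytest.mark.parametrize("sample", sorted(ALL_SAMPLES))
def test_gt_sum_rule(sample, registry):
    """REF + VAR copies at a GT target equal the number of gene copies whose
    region at that target is CYP2D6-derived."""
    entry = ALL_SAMPLES[sample]
    config = parse_diplotype(entry["diplotype"], registry)
    for plex_name in plexes_of(entry):
        plex = registry.plexes[plex_name]
        vec = expected_copy_vector(config, plex)
        d6_copies = sum(
            1 for c in config.gene_copies()
            if c.origin(plex.gt_target.region) == "D6"
        )
        assert vec[plex.gt_target.ref_label] + vec[plex.gt_target.var_label] == d6_copies


def test_swap_symmetry(registry):
    for label in ("*1/*2x2", "*2x2/*68+*4", "*10x2/*36+*10"):
        config = parse_diplotype(label, registry)
        swapped = DiplotypeConfig(config.hapB, config.hapA)
        for plex in registry.panel:
            assert expected_copy_vector(config, plex) == expected_copy_vector(swapped, plex)


@pytest.mark.parametrize(
    "label, region",
    [(label, region) for label in ("*1/*2x2", "*4x2/*41", "*2x2/*17")
     for region in REGIONS],
)
def test_hybrid_conversion_never_increases_signal(label, region, registry):
    """Converting any region of one gene copy to CYP2D7 origin can only
    silence targets, never add signal."""
    config = parse_diplotype(label, registry)
    first, mult = config.hapA.copies[0]
    converted = dataclasses.replace(
        first, d7_regions=first.d7_regions | {region}
    )
    hapA = HaplotypeConfig(((converted, mult),) + config.hapA.copies[1:])
    modified = DiplotypeConfig(hapA, config.hapB)
    for plex in registry.panel:
        base = expected_copy_vector(config, plex)
        conv = expected_copy_vector(modified, plex)
        assert all(conv[ch] <= base[ch] for ch in base)


def test_deletion_homozygote_is_silent(registry):
    config = parse_diplotype("*5/*5", registry)
    for plex in registry.panel:
        vec = expected_copy_vector(config, plex)
        assert vec["ref"] == 2
        assert all(v == 0 for ch, v in vec.items() if ch != "ref")
    assert config.total_gene_copies == 0


def test_unknown_status_raises_naming_allele_and_target(registry):
    """*45 is only resolved where validated data force it; other targets
    must raise rather than guess."""
    config = parse_diplotype("*1/*45", registry)
    with pytest.raises(MatrixIncompleteError) as err:
        expected_copy_vector(config, registry.plexes["CN_2851"])
    assert "*45" in str(err.value)
    assert "g.2851" in str(err.value)
    # but the validated combination works
    vec = expected_copy_vector(config, registry.plexes["CN_1022"])
    assert vec["g.1022C"] == 2 and vec["g.4181C"] == 1


@pytest.mark.parametrize(
    "a, b, plex_names, expected",
    [
        ("*2", "*17", None, {"CN_1022"}),
        ("*4", "*41", ("CN_1847", "CN_2989"), {"CN_1847", "CN_2989"}),
        ("*2", "*2", None, set()),
        ("*1", "*2", None, None),  # every plex differs via g.4181C
    ],
)
def test_informative_assays(a, b, plex_names, expected, registry):
    panel = (registry.panel if plex_names is None
             else [registry.plexes[n] for n in plex_names])
    result = informative_assays(registry.allele(a), registry.allele(b), panel)
    if expected is None:
        assert result == {p.name for p in registry.panel}
    else:
        assert result == expected


def test_informative_assays_empty_panel(registry):
    assert informative_assays(registry.allele("*2"), registry.allele("*17"), []) == set()


def test_informative_assays_warns_on_unknown(registry):
    with pytest.warns(UserWarning, match="UNKNOWN"):
        informative_assays(registry.allele("*45"), registry.allele("*1"),
                           [registry.plexes["CN_2851"]])


@pytest.mark.parametrize("label", [
    "*1/*2x2", "*10x2/*36+*10", "*2/*41x3", "*2x2/*68+*4", "*5/*5", "*1/*5",
])
def test_diplotype_label_round_trip(label, registry):
    assert render_diplotype(parse_diplotype(label, registry)) == label


def test_parse_structure(registry):
    config = parse_diplotype("*10x2/*36+*10", registry)
    assert [(a.name, m) for a, m in config.hapA.copies] == [("*10", 2)]
    assert [(a.name, m) for a, m in config.hapB.copies] == [("*36", 1), ("*10", 1)]
    assert config.total_gene_copies == 4


def test_parse_rejects_unknown_allele(registry):
    with pytest.raises(DiplotypeParseError, match=r"\*1"):
        parse_diplotype("*1/*999", registry)


_FULL_ALLELES = hst.sampled_from(
    ["*1", "*2", "*4", "*10", "*17", "*29", "*41", "*36", "*68", "*5"]
)
_hap = hst.lists(
    hst.tuples(_FULL_ALLELES, hst.integers(1, 4)), min_size=1, max_size=2
)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(hapA=_hap, hapB=_hap)
def test_round_trip_property(hapA, hapB):
    """parse(render(c)) == c over random structural configurations."""
    registry = __import__("startrac").default_registry()

    def build(units):
        return HaplotypeConfig(
            tuple((registry.allele(n), m) for n, m in units)
        )

    config = DiplotypeConfig(build(hapA), build(hapB))
    parsed = parse_diplotype(render_diplotype(config), registry)
    assert parsed.label == config.label
    assert [(a.name, m) for a, m in parsed.hapA.copies] == \
        [(a.name, m) for a, m in config.hapA.copies]
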