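"""Variant grammar, coordinates, haplotype<->sequence conversion, table IO."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mtroute.errors import (
    ContractViolation,
    PositionRangeError,
    SchemaError,
    ValidationError,
    VariantParseError,
)
from mtroute.seqio import (
    GeoPoint,
    MtHaplotype,
    Variant,
    format_variant,
    haplotype_to_sequence,
    parse_angle,
    parse_coordinates,
    parse_region,
    parse_variant_string,
    read_haplotype_table,
    sequence_to_haplotype,
    write_haplotype_table,
)


@pytest.mark.parametrize(
    "token,expected",
    [
        ("16223", Variant(16223, "transition")),
        ("95C", Variant(95, "transversion", "C")),
        ("16189.1C", Variant(16189, "insertion", "C", 1)),
        ("8281d", Variant(8281, "deletion")),
        ("16223!", Variant(16223, "transition", back=True)),
        ("12705!", Variant(12705, "transition", back=True)),
    ],
)
def test_parse_variant_tokens(token, expected):
    assert parse_variant_string(token) == expected


@pytest.mark.parametrize("token", ["", "abc", "100X", "1.C", "100dd", "100CC", "95.0A"])
def test_parse_rejects_malformed_tokens(token):
    with pytest.raises(VariantParseError):
        parse_variant_string(token)


@pytest.mark.parametrize("token", ["0", "16570", "99999C"])
def test_parse_rejects_out_of_range_positions(token):
    with pytest.raises(PositionRangeError):
        parse_variant_string(token)


def test_parse_with_reference_classifies_by_base(ref):
    # pick a reference position and spell out its transition partner
    pos = 500
    base = ref[pos - 1]
    partner = {"A": "G", "G": "A", "C": "T", "T": "C"}[base]
    tv = [b for b in "ACGT" if b not in (base, partner)][0]
    assert parse_variant_string(f"{pos}{partner}", ref).kind == "transition"
    assert parse_variant_string(f"{pos}{tv}", ref).kind == "transversion"
    with pytest.raises(VariantParseError):
        parse_variant_string(f"{pos}{base}", ref)  # derived equals reference


@st.composite
def variants(draw):
    kind = draw(st.sampled_from(["transition", "transversion", "insertion", "deletion"]))
    pos = draw(st.integers(min_value=1, max_value=16569))
    back = draw(st.booleans())
    if kind == "transition":
        return Variant(pos, kind, back=back)
    if kind == "transversion":
        return Variant(pos, kind, draw(st.sampled_from("ACGT")), back=back)
    if kind == "insertion":
        return Variant(pos, kind, draw(st.sampled_from("ACGT")), draw(st.integers(1, 3)), back=back)
    return Variant(pos, kind, back=back)


@settings(max_examples=200, derandomize=True)
@given(variants())
def test_formatter_inverts_parser(v):
    assert parse_variant_string(format_variant(v)) == v


def test_variant_invariants():
    with pytest.raises(ValidationError):
        Variant(100, "transversion")  # transversion needs an explicit base
    with pytest.raises(ValidationError):
        Variant(100, "insertion", "C", 0)  # insertion index starts at 1
    with pytest.raises(PositionRangeError):
        Variant(0, "transition")


def test_angle_and_coordinate_parsing():
    assert parse_angle("12°23´N") == (pytest.approx(12 + 23 / 60), "lat")
    assert parse_angle("130°50´E") == (pytest.approx(130 + 50 / 60), "lon")
    assert parse_angle("01°31´S")[0] == pytest.approx(-(1 + 31 / 60))
    assert parse_angle("43.35E") == (pytest.approx(43.35), "lon")
    p = parse_coordinates("12°28´S-130°50´E")
    assert p.latitude == pytest.approx(-(12 + 28 / 60))
    assert p.longitude == pytest.approx(130 + 50 / 60)
    with pytest.raises(ValidationError):
        parse_coordinates("12°23´N")
    with pytest.raises(ValidationError):
        GeoPoint(95.0, 0.0)


def test_haplotype_invariants():
    with pytest.raises(ValidationError):
        MtHaplotype("x", (Variant(100, "transversion", "C"), Variant(100, "transversion", "A")))
    with pytest.raises(ValidationError):
        MtHaplotype("x", (Variant(100, "transition"),), region=((200, 300),))
    # identical duplicates collapse instead of conflicting
    h = MtHaplotype("x", (Variant(100, "transition"), Variant(100, "transition")))
    assert len(h.variants) == 1


def test_hypermutable_flagging():
    assert Variant(16182, "transition").is_hypermutable()
    assert Variant(16519, "transition").is_hypermutable()
    assert Variant(16189, "insertion", "C", 1).is_hypermutable()
    assert not Variant(16189, "transition").is_hypermutable()  # substitution in tract is kept
    assert not Variant(100, "transition").is_hypermutable()


def test_haplotype_to_sequence_identity_and_substitution(ref):
    interval = (101, 200)
    empty = MtHaplotype("e", (), region=(interval,))
    assert haplotype_to_sequence(empty, ref, interval) == ref[100:200]
    v = Variant(101, "transition")
    h = MtHaplotype("s", (v,), region=(interval,))
    seq = haplotype_to_sequence(h, ref, interval)
    assert seq[0] != ref[100]
    assert seq[1:] == ref[101:200]
    assert sum(a != b for a, b in zip(seq, ref[100:200])) == 1


def test_haplotype_to_sequence_indels_change_length(ref):
    interval = (301, 400)
    ins = MtHaplotype("i", (Variant(350, "insertion", "A", 1),), region=(interval,))
    dele = MtHaplotype("d", (Variant(350, "deletion"),), region=(interval,))
    assert len(haplotype_to_sequence(ins, ref, interval)) == 101
    assert len(haplotype_to_sequence(dele, ref, interval)) == 99


def test_haplotype_to_sequence_rejects_variant_outside_interval(ref):
    h = MtHaplotype("x", (Variant(50, "transition"),), region=((1, 100),))
    with pytest.raises(ContractViolation):
        haplotype_to_sequence(h, ref, (60, 100))


def test_sequence_identity_calls_no_variants(ref):
    h = sequence_to_haplotype(ref[499:600], ref, (500, 600))
    assert h.variants == ()


def test_single_mismatch_called_as_substitution():
    ref = "ACGT" + "A" * 16565  # synthetic 4-bp window inside a full-length reference
    h = sequence_to_haplotype("ACAT", ref, (1, 4))
    assert len(h.variants) == 1
    v = h.variants[0]
    assert v.position == 3 and v.is_substitution and v.derived_state == "A"


def test_substitution_roundtrip_recovers_variant_set(ref):
    rng = np.random.default_rng(7)
    interval = (1000, 1600)
    for _ in range(25):
        positions = rng.choice(np.arange(interval[0], interval[1] + 1), size=8, replace=False)
        vs = []
        for pos in positions:
            pos = int(pos)
            if rng.random() < 0.5:
                vs.append(Variant(pos, "transition"))
            else:
                base = ref[pos - 1]
                partner = {"A": "G", "G": "A", "C": "T", "T": "C"}[base]
                tv = [b for b in "ACGT" if b not in (base, partner)]
                vs.append(Variant(pos, "transversion", str(rng.choice(tv))))
        h0 = MtHaplotype("r", tuple(vs), region=(interval,))
        seq = haplotype_to_sequence(h0, ref, interval)
        h1 = sequence_to_haplotype(seq, ref, interval)
        assert set(h1.variants) == {v.normalize(ref) for v in h0.variants}
        # and back to the same sequence
        assert haplotype_to_sequence(h1, ref, interval) == seq


def _brute_force_placements(ref_seg, seq):
    """All reference positions whose single-base deletion explains seq."""
    return [
        i + 1
        for i in range(len(ref_seg))
        if ref_seg[:i] + ref_seg[i + 1 :] == seq
    ]


def test_homopolymer_indels_right_aligned(ref):
    import re

    run = max(re.finditer(r"(A{3,}|C{3,}|G{3,}|T{3,})", ref[:5000]), key=lambda m: len(m.group()))
    lo, hi = run.start() - 10, run.end() + 10
    seg = ref[lo : hi]
    # deletion: remove the first base of the run; every in-run placement is equal cost
    seq = seg[: run.start() - lo] + seg[run.start() - lo + 1 :]
    h = sequence_to_haplotype(seq, ref, (lo + 1, hi))
    placements = [p + lo for p in _brute_force_placements(seg, seq)]
    assert len(placements) >= 3
    assert [v.kind for v in h.variants] == ["deletion"]
    assert h.variants[0].position == max(placements)
    # insertion: duplicate a run base; the call anchors at the run's last position
    seq_ins = seg[: run.end() - lo] + run.group()[0] + seg[run.end() - lo :]
    h_ins = sequence_to_haplotype(seq_ins, ref, (lo + 1, hi))
    assert [v.kind for v in h_ins.variants] == ["insertion"]
    assert h_ins.variants[0].position == run.end()
    assert h_ins.variants[0].suffix_index == 1


def test_region_parsing():
    assert parse_region("16024-16383;57-372") == ((57, 372), (16024, 16383))
    with pytest.raises(SchemaError):
        parse_region("57-16570")
    with pytest.raises(SchemaError):
        parse_region("x-y")


def test_haplotype_table_roundtrip(tmp_path):
    haps = [
        MtHaplotype(
            "s1",
            (Variant(16223, "transition"), Variant(95, "transversion", "C")),
            region=((1, 16569),),
            origin=GeoPoint(12.5, 44.25),
            population="popA",
        ),
        MtHaplotype("s2", (), region=((57, 372), (16024, 16383)), population="popB"),
    ]
    path = tmp_path / "haps.tsv"
    write_haplotype_table(haps, path)
    back = read_haplotype_table(path)
    assert [h.sample_id for h in back] == ["s1", "s2"]
    assert back[0].variants == haps[0].variants
    assert back[0].origin.latitude == pytest.approx(12.5)
    assert back[1].region == haps[1].region
    assert back[1].origin is None


def test_haplotype_table_missing_column(tmp_path):
    path = tmp_path / "bad.tsv"
    path.write_text("sample_id\tpopulation\nx\ty\n")
    with pytest.raises(SchemaError, match="missing required column"):
        read_haplotype_table(path)


def test_table_accepts_degree_minute_coordinates(tmp_path):
    path = tmp_path / "dm.tsv"
    path.write_text(
        "sample_id\tpopulation\tlatitude\tlongitude\tregion\tvariants\n"
        "s1\tp\t11°00´N\t104°00´E\t1-16569\t16223 95C\n"
    )
    (h,) = read_haplotype_table(path)
    assert h.origin.longitude == pytest.approx(104.0)
    assert len(h.variants) == 2
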