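import numpy as np
import pytest

from rpimer.errors import DotBracketError, LengthMismatchError
from rpimer.sse import (CLASS_ORDER, SSE_ORDER, LengthClass, LengthClassTable,
                        SseType, annotate_structure, decode_joint_symbol,
                        default_length_classes, fit_length_classes,
                        joint_rna_code, joint_symbol, parse_dot_bracket)
from rpimer.synth import StructureGrammar, generate_structure

# --- parsing --------------------------------------------------------------

def test_parse_simple_nesting():
    partner = parse_dot_bracket("((...))")
    assert partner == [6, 5, None, None, None, 1, 0]


def test_parse_all_unpaired():
    assert parse_dot_bracket("....") == [None] * 4


def test_parse_unmatched_open():
    with pytest.raises(DotBracketError) as exc:
        parse_dot_bracket("((.)")
    assert exc.value.position is None  # defect surfaces at end of string


def test_parse_unmatched_close_reports_position():
    with pytest.raises(DotBracketError) as exc:
        parse_dot_bracket(".)(")
    assert exc.value.position == 2


def test_extra_bracket_tiers_rejected():
    with pytest.raises(DotBracketError):
        annotate_structure("([.])")


# --- element decomposition (hand-traced) ----------------------------------

def _elements_by_type(ann):
    out = {}
    for el in ann.elements:
        out.setdefault(el.sse_type, []).append(el)
    return out


def test_hairpin_decomposition_and_classes():
    ann = annotate_structure("((((...))))")
    by = _elements_by_type(ann)
    (stem,) = by[SseType.STEM]
    assert stem.member_positions == (1, 2, 3, 4, 8, 9, 10, 11)
    assert stem.element_length == 4  # base pairs -> Medium (4-5)
    (loop,) = by[SseType.LOOP]
    assert loop.member_positions == (5, 6, 7)
    assert loop.element_length == 3  # -> Short (1-4)
    table = ann.length_table
    assert table.classify(SseType.STEM, 4) is LengthClass.MEDIUM
    assert table.classify(SseType.LOOP, 3) is LengthClass.SHORT


def test_bulge_splits_stem():
    ann = annotate_structure("((..((...))))")
    by = _elements_by_type(ann)
    stems = sorted(by[SseType.STEM], key=lambda e: e.member_positions)
    assert [s.member_positions for s in stems] == [(1, 2, 12, 13), (5, 6, 10, 11)]
    assert all(s.element_length == 2 for s in stems)  # Short (1-3)
    (bulge,) = by[SseType.BULGE]
    assert bulge.member_positions == (3, 4) and bulge.element_length == 2
    assert ann.length_table.classify(SseType.BULGE, 2) is LengthClass.MEDIUM
    (loop,) = by[SseType.LOOP]
    assert loop.member_positions == (7, 8, 9)


def test_single_strand_is_one_other_element():
    ann = annotate_structure("......")
    (el,) = ann.elements
    assert el.sse_type is SseType.OTHER and el.element_length == 6
    assert ann.length_table.classify(SseType.OTHER, 6) is LengthClass.LONG


def test_internal_loop_sums_both_strands():
    ann = annotate_structure("((.((...)).."  "))")
    by = _elements_by_type(ann)
    (internal,) = by[SseType.INTERNAL_LOOP]
    assert internal.member_positions == (3, 11, 12)
    assert internal.element_length == 3


def test_multiloop_interior_is_other():
    ann = annotate_structure("((((...))..((...))))")
    by = _elements_by_type(ann)
    others = by[SseType.OTHER]
    assert [o.member_positions for o in others] == [(10, 11)]


def test_annotation_partitions_random_structures():
    rng = np.random.default_rng(23)
    for _ in range(200):
        n = int(rng.integers(1, 120))
        db = generate_structure(n, seed=rng)
        ann = annotate_structure(db)
        positions = [p for el in ann.elements for p in el.member_positions]
        assert sorted(positions) == list(range(1, n + 1))
        assert len(positions) == len(set(positions))
        # every paired position lies in a Stem
        partner = parse_dot_bracket(db)
        paired = {i + 1 for i, p in enumerate(partner) if p is not None}
        stem_pos = {p for el in ann.elements if el.sse_type is SseType.STEM
                    for p in el.member_positions}
        assert paired == stem_pos


# --- length-class fitting -------------------------------------------------

def test_fit_recovers_equal_tertiles_on_uniform_lengths():
    observed = {SseType.LOOP: list(range(1, 10))}
    table = fit_length_classes(observed)
    assert table.cutoffs[SseType.LOOP] == (3, 6)
    # untouched types keep the defaults
    assert table.cutoffs[SseType.STEM] == default_length_classes().cutoffs[SseType.STEM]


def test_fit_degenerate_constant_lengths_all_short():
    table = fit_length_classes({SseType.BULGE: [2] * 50})
    assert table.cutoffs[SseType.BULGE] == (2, 2)
    assert table.classify(SseType.BULGE, 2) is LengthClass.SHORT


def test_fit_geometric_lengths_near_equiprobable():
    rng = np.random.default_rng(41)
    lengths = rng.geometric(0.1, size=10_000).tolist()
    table = fit_length_classes({SseType.STEM: lengths})
    s, m = table.cutoffs[SseType.STEM]
    arr = np.asarray(lengths)
    masses = [np.mean(arr <= s), np.mean((arr > s) & (arr <= m)), np.mean(arr > m)]
    assert sum(masses) == pytest.approx(1.0)
    for mass in masses:
        assert abs(mass - 1 / 3) < 0.05


# --- joint code -----------------------------------------------------------

def test_joint_code_uniform_case():
    ann = annotate_structure("...")
    code = joint_rna_code("AAA", ann)
    # Other element of length 3 -> Medium
    expected = joint_symbol("A", SseType.OTHER, LengthClass.MEDIUM)
    assert code.tolist() == [expected] * 3


def test_joint_alphabet_size_is_75():
    symbols = {joint_symbol(n, t, c)
               for n in "ACGUX" for t in SSE_ORDER for c in CLASS_ORDER}
    assert symbols == set(range(75))


def test_joint_code_round_trip():
    rng = np.random.default_rng(9)
    for _ in range(20):
        n = int(rng.integers(1, 80))
        seq = "".join(rng.choice(list("ACGUX"), size=n))
        ann = annotate_structure(generate_structure(n, seed=rng))
        code = joint_rna_code(seq, ann)
        per_pos = ann.per_position
        for i, s in enumerate(code):
            nuc, t, c = decode_joint_symbol(int(s))
            assert nuc == seq[i]
            assert (t, c) == per_pos[i][:2]


def test_joint_code_length_mismatch():
    ann = annotate_structure("...")
    with pytest.raises(LengthMismatchError):
        joint_rna_code("AAAA", ann)
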