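import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import naive_kmer_counts
from rpimer.errors import AlphabetError, ConfigError
from rpimer.kmers import (KmerCountTable, build_count_table, count_kmers,
                          count_occurrences, dominance_labels, richness,
                          select_kmers, sse_enrichment_table,
                          string_model_vector)

# --- counting -------------------------------------------------------------

def test_overlapping_occurrences():
    assert count_kmers(["AAAA"], 2, 2) == {"AA": 3}


def test_count_range():
    assert count_kmers(["ACGU"], 2, 3) == {
        "AC": 1, "CG": 1, "GU": 1, "ACG": 1, "CGU": 1}


def test_count_rejects_bad_k():
    with pytest.raises(ConfigError):
        count_kmers(["AA"], 0, 2)
    with pytest.raises(ConfigError):
        count_kmers(["AA"], 3, 2)


def test_counts_match_naive_oracle():
    rng = np.random.default_rng(77)
    for _ in range(100):
        n_strings = int(rng.integers(1, 6))
        corpus = ["".join(rng.choice(list("AUCGX"),
                                     size=int(rng.integers(0, 200))))
                  for _ in range(n_strings)]
        k_min = int(rng.integers(1, 4))
        k_max = int(rng.integers(k_min, 6))
        assert count_kmers(corpus, k_min, k_max) == \
            naive_kmer_counts(corpus, k_min, k_max)


def test_total_count_identity():
    rng = np.random.default_rng(13)
    corpus = ["".join(rng.choice(list("AUCG"), size=int(rng.integers(0, 60))))
              for _ in range(20)]
    for k in range(2, 6):
        counts = count_kmers(corpus, k, k)
        assert sum(counts.values()) == \
            sum(max(0, len(s) - k + 1) for s in corpus)


def test_build_count_table_composes_two_counts():
    rng = np.random.default_rng(21)
    pos = ["".join(rng.choice(list("AUCGX"), size=50)) for _ in range(5)]
    neg = ["".join(rng.choice(list("AUCGX"), size=50)) for _ in range(5)]
    table = build_count_table(pos, neg, "rna_seq", 2, 4)
    g, l = count_kmers(pos, 2, 4), count_kmers(neg, 2, 4)
    assert table.counts == {b: (g.get(b, 0), l.get(b, 0))
                            for b in set(g) | set(l)}


def test_build_count_table_trivial_and_empty():
    t = build_count_table(["AU"], [], "rna_seq", 2, 2)
    assert t.counts == {"AU": (1, 0)}
    assert build_count_table([], [], "rna_seq").counts == {}


def test_build_count_table_rejects_foreign_alphabet():
    with pytest.raises(AlphabetError):
        build_count_table(["AUZ"], [], "rna_seq")


# --- richness -------------------------------------------------------------

@pytest.mark.parametrize("gamma,lam,expected", [
    (22, 10, 2.091),   # enriched in interacting pairs
    (4, 0, 5.000),     # smoothing keeps a zero count finite
    (0, 0, 1.000),     # no data -> no signal
    (19, 5, 3.333),
])
def test_richness_worked_values(gamma, lam, expected):
    assert round(richness(gamma, lam), 3) == expected


def test_richness_log_value():
    assert round(math.log2(richness(77, 161)), 3) == -1.054


def test_richness_rejects_negative_counts():
    with pytest.raises(ConfigError):
        richness(-1, 0)


@given(st.integers(0, 10_000), st.integers(0, 10_000))
@settings(max_examples=200, deadline=None)
def test_richness_reciprocity(a, b):
    assert richness(a, b) * richness(b, a) == pytest.approx(1.0)


@given(st.integers(0, 1000), st.integers(0, 1000))
@settings(max_examples=100, deadline=None)
def test_richness_monotonicity(g, l):
    assert richness(g + 1, l) > richness(g, l)
    assert richness(g, l + 1) < richness(g, l)


# --- selection ------------------------------------------------------------

def _table(counts):
    return KmerCountTable(representation="rna_seq", counts=counts,
                          k_min=2, k_max=2)


def test_select_balanced_kmer_in_neither_set():
    sel = select_kmers(_table({"AA": (10, 10)}), "log_threshold", 1.0)
    assert sel.positive == () and sel.negative == ()


def test_select_negative_by_log_threshold():
    sel = select_kmers(_table({"CC": (0, 5)}), "log_threshold", 1.0)
    assert sel.negative == ("CC",) and sel.positive == ()
    assert math.log2(richness(0, 5)) == pytest.approx(math.log2(1 / 6))


def test_select_exclusive_mode():
    sel = select_kmers(_table({"GG": (3, 0), "UU": (2, 2)}), "exclusive")
    assert sel.positive == ("GG",) and sel.negative == ()


def test_selected_sets_disjoint_on_random_tables():
    rng = np.random.default_rng(31)
    for mode in ("log_threshold", "exclusive"):
        counts = {f"{a}{b}": (int(rng.integers(0, 8)), int(rng.integers(0, 8)))
                  for a in "AUCG" for b in "AUCG"}
        sel = select_kmers(_table(counts), mode, 0.5)
        assert not set(sel.positive) & set(sel.negative)


def test_planted_kmer_selected_across_replicates():
    """A k-mer planted at rate 0.8 in positives vs 0.05 in negatives is
    picked up by the tau=1 threshold in >= 95/100 replicate corpora."""
    motif = "GACUG"
    hits = 0
    for seed in range(100):
        rng = np.random.default_rng(1000 + seed)

        def make(n, rate):
            out = []
            for _ in range(n):
                s = "".join(rng.choice(list("ACGU"), size=120))
                if rng.random() < rate:
                    start = int(rng.integers(0, len(s) - len(motif) + 1))
                    s = s[:start] + motif + s[start + len(motif):]
                out.append(s)
            return out

        table = build_count_table(make(100, 0.8), make(100, 0.05), "rna_seq")
        sel = select_kmers(table, "log_threshold", 1.0)
        hits += motif in sel.positive
    assert hits >= 95


# --- string-model vectors -------------------------------------------------

def _selections():
    return {
        "rna_seq": select_kmers(_table({"GG": (5, 0), "CC": (0, 5)}),
                                "log_threshold", 1.0),
        "prot_seq": select_kmers(
            KmerCountTable("prot_seq", {"12": (4, 0)}, 2, 2),
            "log_threshold", 1.0),
    }


def test_vector_counts_are_normalized_occurrences():
    strings = {"rna_seq": "AGGGAUCCA", "prot_seq": "3412123"}
    vec = string_model_vector(strings, "QQ", _selections())
    assert vec.schema == ("rna_seq:GG", "rna_seq:CC", "prot_seq:12")
    # GG occurs twice (overlapping) in 9 nt; CC once; 12 twice in 7 symbols
    np.testing.assert_allclose(vec.values, [2 / 9, 1 / 9, 2 / 7])


def test_vector_zero_block_when_kmers_absent():
    vec = string_model_vector({"rna_seq": "AUAUAU", "prot_seq": "77777"},
                              "QQ", _selections())
    assert not vec.values.any()


def test_qsqs_concatenates_all_blocks():
    sels = _selections()
    sels["rna_sse"] = select_kmers(
        KmerCountTable("rna_sse", {"AD": (3, 0)}, 2, 2), "log_threshold", 1.0)
    sels["prot_sse"] = select_kmers(
        KmerCountTable("prot_sse", {"ab": (3, 0)}, 2, 2), "log_threshold", 1.0)
    strings = {"rna_seq": "GGAU", "rna_sse": "ADAD",
               "prot_seq": "1212", "prot_sse": "abab"}
    qq = string_model_vector(strings, "QQ", sels)
    ss = string_model_vector(strings, "SS", sels)
    qsqs = string_model_vector(strings, "QSQS", sels)
    assert len(qsqs) == len(qq) + len(ss)


def test_planted_kmer_value_matches_sliding_count():
    rng = np.random.default_rng(5)
    s = "".join(rng.choice(list("ACGU"), size=200))
    s = s[:50] + "GACUG" + s[55:]
    sel = {"rna_seq": select_kmers(_table({"GACUG": (9, 0)}),
                                   "log_threshold", 1.0),
           "prot_seq": _selections()["prot_seq"]}
    vec = string_model_vector({"rna_seq": s, "prot_seq": "11"}, "QQ", sel)
    assert vec.values[0] == pytest.approx(count_occurrences(s, "GACUG") / len(s))


# --- SSE enrichment -------------------------------------------------------

def test_enrichment_smoothed_values():
    # code 'E' (medium loop): 19 positive vs 5 negative occurrences
    table = sse_enrichment_table(["E" * 19], ["E" * 5], mode="smoothed")
    row = table.set_index("code").loc["E"]
    assert round(row["ratio"], 3) == 3.333
    assert round(row["log2_ratio"], 3) == 1.737


def test_enrichment_balanced_code_is_neutral():
    table = sse_enrichment_table(["AB"], ["AB"], mode="plain")
    row = table.set_index("code").loc["A"]
    assert row["ratio"] == 1.0 and row["log2_ratio"] == 0.0


def test_enrichment_plain_zero_negative_flagged_infinite():
    table = sse_enrichment_table(["A"], [], mode="plain")
    row = table.set_index("code").loc["A"]
    assert math.isinf(row["ratio"]) and row["undefined"]


def test_dominance_requires_same_sign_in_both_columns():
    a = sse_enrichment_table(["A" * 8 + "B"], ["A" + "B" * 8], mode="smoothed")
    b = sse_enrichment_table(["A" * 8 + "B" * 8], ["A" + "B"], mode="smoothed")
    dom = dominance_labels(a, b, margin=0.5)
    assert dom["A"] == "Pos"   # enriched in positives in both tables
    assert dom["B"] == ""      # signs disagree between tables
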