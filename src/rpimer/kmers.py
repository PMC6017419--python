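"""Discriminative k-mer mining by smoothed richness.

Every RNA-protein pair contributes four strings: the RNA sequence (5-letter
alphabet), the RNA structure as a per-element SSE code string (15 letters),
the reduced protein sequence (digits 1-7), and the protein structure as
Ramachandran codes (letters a-g).  For each representation we count every
substring beta of length 2..5 once over the positive-pair corpus (count
gamma) and once over the negative-pair corpus (count lambda), and score it
by the additively smoothed *richness*

    R(beta) = (gamma(beta) + 1) / (lambda(beta) + 1)

R >> 1 marks substrings enriched in interacting pairs, R << 1 in
non-interacting pairs, and R near 1 carries no signal; the +1 smoothing
keeps zero counts finite and makes R(a,b) * R(b,a) = 1.  Selected k-mers
(by a threshold on |log2 R|, or by strict exclusivity) become the feature
schema of the string-based models QQ / SS / QS / SQ / QSQS, which combine
RNA-side and protein-side selections from sequence (Q) and structure (S).

Counting is a single pass per k over each corpus string into a hash table:
O(total length) for the fixed k range, and exactly equal to an overlapping
sliding-window count.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .errors import AlphabetError, ConfigError, SchemaError
from .featvec import FeatureVector
from .sse import ELEMENT_CODE_ALPHABET

#: the four string representations of a pair and their alphabets
REPRESENTATIONS = {
    "rna_seq": "AUCGX",
    "rna_sse": ELEMENT_CODE_ALPHABET,
    "prot_seq": "1234567",
    "prot_sse": "abcdefg",
}

#: string-model name -> ordered representations it draws from
MODEL_REPRESENTATIONS = {
    "QQ": ("rna_seq", "prot_seq"),
    "SS": ("rna_sse", "prot_sse"),
    "QS": ("rna_seq", "prot_sse"),
    "SQ": ("rna_sse", "prot_seq"),
    "QSQS": ("rna_seq", "rna_sse", "prot_seq", "prot_sse"),
}


def count_kmers(corpus, k_min: int = 2, k_max: int = 5) -> dict[str, int]:
    """Overlapping-occurrence counts of all substrings of length k_min..k_max.

    One sliding pass per k per string; strings shorter than k contribute
    nothing for that k.  Time linear in total corpus length for a fixed
    k range.
    """
    if k_min < 1:
        raise ConfigError(f"k_min must be >= 1, got {k_min}")
    if k_max < k_min:
        raise ConfigError(f"k_max ({k_max}) < k_min ({k_min})")
    counts: Counter[str] = Counter()
    for s in corpus:
        n = len(s)
        for k in range(k_min, k_max + 1):
            if n < k:
                continue
            counts.update(s[i:i + k] for i in range(n - k + 1))
    return dict(counts)


def richness(gamma: int, lam: int) -> float:
    """Smoothed positive/negative occurrence ratio (gamma+1)/(lambda+1)."""
    if gamma < 0 or lam < 0:
        raise ConfigError(f"counts must be non-negative, got {(gamma, lam)}")
    return (gamma + 1) / (lam + 1)


@dataclass(frozen=True)
class KmerStat:
    beta: str
    gamma: int
    lam: int

    @property
    def richness(self) -> float:
        return richness(self.gamma, self.lam)

    @property
    def log2_richness(self) -> float:
        return math.log2(self.richness)


@dataclass(frozen=True)
class KmerCountTable:
    representation: str
    counts: dict[str, tuple[int, int]]  # beta -> (gamma, lam)
    k_min: int
    k_max: int

    def stats(self) -> list[KmerStat]:
        """All entries, sorted by |log2 richness| descending then by beta."""
        out = [KmerStat(b, g, l) for b, (g, l) in self.counts.items()]
        out.sort(key=lambda s: (-abs(s.log2_richness), s.beta))
        return out


def _validate_alphabet(corpus, representation: str):
    alpha = set(REPRESENTATIONS[representation])
    for i, s in enumerate(corpus):
        bad = set(s) - alpha
        if bad:
            raise AlphabetError(
                f"string #{i} for representation {representation!r} has "
                f"symbols {sorted(bad)} outside its alphabet",
                string_id=str(i))


def build_count_table(pos_corpus, neg_corpus, representation: str,
                      k_min: int = 2, k_max: int = 5) -> KmerCountTable:
    """Joint gamma/lambda table for one representation.

    Corpora are per *pair*: a sequence participating in m pairs appears m
    times and is counted m times (richness compares pair populations, not
    unique chains; deduplicate upstream for a unique-sequence variant).
    """
    if representation not in REPRESENTATIONS:
        raise ConfigError(f"unknown representation {representation!r}")
    _validate_alphabet(pos_corpus, representation)
    _validate_alphabet(neg_corpus, representation)
    gamma = count_kmers(pos_corpus, k_min, k_max)
    lam = count_kmers(neg_corpus, k_min, k_max)
    counts = {b: (gamma.get(b, 0), lam.get(b, 0))
              for b in set(gamma) | set(lam)}
    return KmerCountTable(representation=representation, counts=counts,
                          k_min=k_min, k_max=k_max)


@dataclass(frozen=True)
class KmerSelection:
    representation: str
    positive: tuple[str, ...]  # sorted
    negative: tuple[str, ...]  # sorted
    mode: str
    tau: float | None

    def __post_init__(self):
        if set(self.positive) & set(self.negative):
            raise ValueError("positive and negative selections overlap")

    @property
    def features(self) -> tuple[str, ...]:
        """Feature order: positive set then negative set, each sorted."""
        return self.positive + self.negative


def select_kmers(table: KmerCountTable, mode: str = "log_threshold",
                 tau: float = 1.0) -> KmerSelection:
    """Pick discriminative k-mers from a count table.

    ``log_threshold``: positive set = {beta : log2 R >= tau}, negative set
    = {beta : log2 R <= -tau}.  ``exclusive``: substrings occurring only in
    positives (resp. only in negatives).
    """
    if mode == "log_threshold":
        if tau <= 0:
            raise ConfigError(f"tau must be positive, got {tau}")
        pos = [b for b, (g, l) in table.counts.items()
               if math.log2(richness(g, l)) >= tau]
        neg = [b for b, (g, l) in table.counts.items()
               if math.log2(richness(g, l)) <= -tau]
    elif mode == "exclusive":
        pos = [b for b, (g, l) in table.counts.items() if g > 0 and l == 0]
        neg = [b for b, (g, l) in table.counts.items() if l > 0 and g == 0]
    else:
        raise ConfigError(f"unknown selection mode {mode!r}")
    return KmerSelection(representation=table.representation,
                         positive=tuple(sorted(pos)),
                         negative=tuple(sorted(neg)),
                         mode=mode, tau=tau if mode == "log_threshold" else None)


def count_occurrences(text: str, pattern: str) -> int:
    """Overlapping occurrences of pattern in text."""
    if not pattern:
        raise ConfigError("empty pattern")
    count = start = 0
    while True:
        i = text.find(pattern, start)
        if i < 0:
            return count
        count += 1
        start = i + 1


def string_model_vector(pair_strings: dict[str, str], model: str,
                        selections: dict[str, KmerSelection],
                        normalize: bool = True) -> FeatureVector:
    """Feature vector of one pair under a string model.

    One feature per selected k-mer of each representation the model uses
    (positive set then negative set, sorted), valued by the k-mer's
    overlapping occurrence count in the pair's corresponding string,
    divided by that string's length when ``normalize``.  Blocks are
    concatenated in the model's representation order; QSQS is the
    concatenation of all four blocks.
    """
    if model not in MODEL_REPRESENTATIONS:
        raise ConfigError(f"unknown string model {model!r}")
    values: list[float] = []
    schema: list[str] = []
    for rep in MODEL_REPRESENTATIONS[model]:
        if rep not in selections:
            raise SchemaError(f"no k-mer selection for representation {rep!r}")
        if rep not in pair_strings:
            raise SchemaError(f"pair lacks a string for representation {rep!r}")
        text = pair_strings[rep]
        feats = selections[rep].features
        if not feats:
            continue
        # count all substrings of the pair string once, then look up features
        lens = {len(f) for f in feats}
        local = count_kmers([text], min(lens), max(lens)) if text else {}
        denom = len(text) if (normalize and text) else 1
        for f in feats:
            values.append(local.get(f, 0) / denom)
            schema.append(f"{rep}:{f}")
    return FeatureVector(values=np.asarray(values, dtype=float),
                         schema=tuple(schema))


# --- SSE length-class enrichment report -----------------------------------

def sse_enrichment_table(pos_sse_corpus, neg_sse_corpus,
                         mode: str = "plain") -> "pd.DataFrame":
    """Per-code occurrence comparison over the 15 SSE length-class codes.

    Counts each code letter over the positive and negative per-element SSE
    strings.  ``mode='plain'`` reports the raw ratio gamma/lambda (Inf with
    a flag when lambda is 0); ``mode='smoothed'`` reports the richness
    (gamma+1)/(lambda+1).  Columns: code, gamma, lam, ratio, log2_ratio,
    undefined (flag).
    """
    import pandas as pd

    if mode not in ("plain", "smoothed"):
        raise ConfigError(f"unknown enrichment mode {mode!r}")
    _validate_alphabet(pos_sse_corpus, "rna_sse")
    _validate_alphabet(neg_sse_corpus, "rna_sse")
    gamma = Counter("".join(pos_sse_corpus))
    lam = Counter("".join(neg_sse_corpus))
    rows = []
    for code in ELEMENT_CODE_ALPHABET:
        g, l = gamma.get(code, 0), lam.get(code, 0)
        undefined = False
        if mode == "smoothed":
            ratio = richness(g, l)
        elif l == 0:
            ratio, undefined = math.inf, True
        else:
            ratio = g / l
        log2_ratio = math.log2(ratio) if ratio > 0 else -math.inf
        rows.append({"code": code, "gamma": g, "lam": l, "ratio": ratio,
                     "log2_ratio": log2_ratio, "undefined": undefined})
    return pd.DataFrame(rows)


def dominance_labels(table_a: "pd.DataFrame", table_b: "pd.DataFrame",
                     margin: float = 0.5) -> "pd.Series":
    """Per-code dominance call from two enrichment tables.

    'Pos' (resp. 'Neg') when |log2 ratio| exceeds ``margin`` in *both*
    tables with the same sign; '' otherwise.
    """
    import pandas as pd

    a = table_a.set_index("code")["log2_ratio"]
    b = table_b.set_index("code")["log2_ratio"]
    out = {}
    for code in a.index:
        x, y = a[code], b[code]
        if x > margin and y > margin:
            out[code] = "Pos"
        elif x < -margin and y < -margin:
            out[code] = "Neg"
        else:
            out[code] = ""
    return pd.Series(out, name="dominant")
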