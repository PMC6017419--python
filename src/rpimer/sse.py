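"""RNA secondary-structure elements from dot-bracket strings.

A nested secondary structure decomposes into five element types:

* **Stem** — a maximal run of stacked base pairs (i,j),(i+1,j-1),...;
  any interruption of stacking (even a single-nucleotide bulge) ends the
  run, so a bulged helix yields two Stem elements.  Stem length is counted
  in base pairs by default (nucleotide counting available).
* **Loop** — the unpaired hairpin interior closed by a single helix.
* **InternalLoop** — unpaired runs on *both* strands between two helices;
  one element whose length sums the two runs.
* **Bulge** — an unpaired run on exactly one strand between two helices.
* **Other** — everything else: exterior single strands and multiloop
  interiors; each maximal unpaired run is one element.

Each element additionally carries a length class (Short / Medium / Long)
taken from a per-type cutoff table.  The default cutoffs:

=============  ======  =======  =====
type           Short   Medium   Long
=============  ======  =======  =====
Stem (bp)      1-3     4-5      >=6
Bulge          1-1     2-2      >=3
Loop           1-4     5-6      >=7
InternalLoop   1-2     3-5      >=6
Other          1-2     3-5      >=6
=============  ======  =======  =====

``fit_length_classes`` re-estimates the cutoffs from observed element
lengths so that the three classes are as close to equiprobable as integer
cutoffs allow.

Two serializations are derived from an annotation: the per-position joint
code over the 75-symbol alphabet (nucleotide x type x class) used by the
fixed-length descriptors, and the per-element 15-letter code string
(``A``-``O``) used as the RNA "structure string" for k-mer mining.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .encode import RNA_ALPHABET, RnaSequence
from .errors import DotBracketError, LengthMismatchError


class SseType(str, Enum):
    STEM = "Stem"
    LOOP = "Loop"
    INTERNAL_LOOP = "InternalLoop"
    BULGE = "Bulge"
    OTHER = "Other"


class LengthClass(str, Enum):
    SHORT = "Short"
    MEDIUM = "Medium"
    LONG = "Long"


SSE_ORDER = (SseType.STEM, SseType.LOOP, SseType.INTERNAL_LOOP,
             SseType.BULGE, SseType.OTHER)
CLASS_ORDER = (LengthClass.SHORT, LengthClass.MEDIUM, LengthClass.LONG)

#: one letter per (type, class) combination, typed A-O in SSE_ORDER x
#: CLASS_ORDER order: Stem SML = ABC, Loop = DEF, InternalLoop = GHI,
#: Bulge = JKL, Other = MNO
ELEMENT_CODE_ALPHABET = "ABCDEFGHIJKLMNO"


def element_code(sse_type: SseType, length_class: LengthClass) -> str:
    return ELEMENT_CODE_ALPHABET[
        3 * SSE_ORDER.index(sse_type) + CLASS_ORDER.index(length_class)]


@dataclass(frozen=True)
class DotBracket:
    id: str
    structure: str

    def __post_init__(self):
        bad = set(self.structure) - set("().")
        if bad:
            raise DotBracketError(
                f"structure {self.id!r} has invalid symbols {bad} "
                "(pseudoknot bracket tiers are not supported)")


@dataclass(frozen=True)
class SseElement:
    sse_type: SseType
    member_positions: tuple[int, ...]  # 1-based, sorted
    element_length: int  # base pairs for Stem, unpaired nucleotides otherwise


@dataclass(frozen=True)
class LengthClassTable:
    """Per-type integer cutoffs: Short = [1, short_max],
    Medium = (short_max, medium_max], Long = (medium_max, inf)."""

    cutoffs: dict[SseType, tuple[int, int]]

    def __post_init__(self):
        for t, (s, m) in self.cutoffs.items():
            if not (s >= 1 and m >= s):
                raise ValueError(f"invalid cutoffs for {t}: {(s, m)}")

    def classify(self, sse_type: SseType, length: int) -> LengthClass:
        s, m = self.cutoffs[sse_type]
        if length <= s:
            return LengthClass.SHORT
        if length <= m:
            return LengthClass.MEDIUM
        return LengthClass.LONG


def default_length_classes() -> LengthClassTable:
    return LengthClassTable({
        SseType.STEM: (3, 5),
        SseType.BULGE: (1, 2),
        SseType.LOOP: (4, 6),
        SseType.INTERNAL_LOOP: (2, 5),
        SseType.OTHER: (2, 5),
    })


@dataclass(frozen=True)
class SseAnnotation:
    """Partition of positions 1..n into typed, length-classed elements."""

    id: str
    elements: tuple[SseElement, ...]
    length_table: LengthClassTable
    n: int

    @property
    def per_position(self) -> list[tuple[SseType, LengthClass, int]]:
        """(type, class, element_id) for each position, 0-indexed list."""
        out: list[tuple[SseType, LengthClass, int] | None] = [None] * self.n
        for eid, el in enumerate(self.elements):
            cls = self.length_table.classify(el.sse_type, el.element_length)
            for p in el.member_positions:
                out[p - 1] = (el.sse_type, cls, eid)
        assert all(v is not None for v in out), "annotation does not cover all positions"
        return out  # type: ignore[return-value]

    def element_code_string(self) -> str:
        """15-letter per-element code string, elements ordered by first position."""
        ordered = sorted(self.elements, key=lambda e: e.member_positions[0])
        return "".join(
            element_code(e.sse_type,
                         self.length_table.classify(e.sse_type, e.element_length))
            for e in ordered)

    def __len__(self) -> int:
        return self.n


def parse_dot_bracket(db: DotBracket | str) -> list[int | None]:
    """Pairing table: entry i (0-based) is the 0-based partner, or None.

    Raises :class:`DotBracketError` (with 1-based position) on an
    unmatched bracket.
    """
    structure = db.structure if isinstance(db, DotBracket) else DotBracket("", db).structure
    partner: list[int | None] = [None] * len(structure)
    stack: list[int] = []
    for i, ch in enumerate(structure):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            if not stack:
                raise DotBracketError(
                    f"unmatched ')' at position {i + 1}", position=i + 1)
            j = stack.pop()
            partner[i] = j
            partner[j] = i
    if stack:
        raise DotBracketError(
            f"{len(stack)} unmatched '(' at end of string", position=None)
    return partner


def _helices(partner: list[int | None]) -> list[list[tuple[int, int]]]:
    """Maximal stacked runs of pairs, each as a list of (i, j), i < j, 0-based."""
    helices = []
    n = len(partner)
    seen = [False] * n
    for i in range(n):
        j = partner[i]
        if j is None or j < i or seen[i]:
            continue
        run = [(i, j)]
        seen[i] = seen[j] = True
        a, b = i, j
        while a + 1 < n and partner[a + 1] == b - 1 and b - 1 >= 0:
            a, b = a + 1, b - 1
            run.append((a, b))
            seen[a] = seen[b] = True
        helices.append(run)
    return helices


def annotate_sse(partner: list[int | None],
                 table: LengthClassTable | None = None,
                 id: str = "",
                 stem_length_in_pairs: bool = True) -> SseAnnotation:
    """Decompose a pairing table into SSE elements.

    Classification of each unpaired run follows the loop closed by the
    innermost enclosing helix: hairpin interior -> Loop; two runs between
    two helices -> one InternalLoop; single run between two helices ->
    Bulge; multiloop interiors and exterior strands -> Other.
    """
    if table is None:
        table = default_length_classes()
    n = len(partner)
    elements: list[SseElement] = []

    helices = _helices(partner)
    for run in helices:
        members = tuple(sorted([p for pair in run for p in pair]))
        length = len(run) if stem_length_in_pairs else 2 * len(run)
        elements.append(SseElement(SseType.STEM,
                                   tuple(p + 1 for p in members), length))

    claimed = [False] * n  # unpaired positions assigned to Loop/Internal/Bulge

    # classify the loop closed by each helix's innermost pair
    for run in helices:
        a, b = run[-1]  # innermost pair, a < b
        # children: helices whose outermost pair lies directly inside (a, b)
        inner = []
        k = a + 1
        while k < b:
            if partner[k] is not None:
                j = partner[k]
                inner.append((k, j))
                k = j + 1
            else:
                k += 1
        if not inner:
            members = tuple(range(a + 1, b))
            if members:
                elements.append(SseElement(
                    SseType.LOOP, tuple(p + 1 for p in members), len(members)))
                for p in members:
                    claimed[p] = True
        elif len(inner) == 1:
            (c, d) = inner[0]
            run5 = tuple(range(a + 1, c))       # unpaired 5' side
            run3 = tuple(range(d + 1, b))       # unpaired 3' side
            if run5 and run3:
                members = run5 + run3
                elements.append(SseElement(
                    SseType.INTERNAL_LOOP, tuple(p + 1 for p in members),
                    len(members)))
                for p in members:
                    claimed[p] = True
            elif run5 or run3:
                members = run5 or run3
                elements.append(SseElement(
                    SseType.BULGE, tuple(p + 1 for p in members), len(members)))
                for p in members:
                    claimed[p] = True
        # >= 2 children: multiloop; its unpaired interior falls to Other

    # remaining unpaired runs (exterior + multiloop interiors) -> Other
    i = 0
    while i < n:
        if partner[i] is None and not claimed[i]:
            j = i
            while j + 1 < n and partner[j + 1] is None and not claimed[j + 1]:
                j += 1
            members = tuple(range(i + 1, j + 2))
            elements.append(SseElement(SseType.OTHER, members, len(members)))
            i = j + 1
        else:
            i += 1

    elements.sort(key=lambda e: e.member_positions[0])
    return SseAnnotation(id=id, elements=tuple(elements),
                         length_table=table, n=n)


def annotate_structure(db: DotBracket | str,
                       table: LengthClassTable | None = None,
                       id: str = "") -> SseAnnotation:
    """Convenience: parse + annotate in one call."""
    if isinstance(db, DotBracket) and not id:
        id = db.id
    return annotate_sse(parse_dot_bracket(db), table=table, id=id)


def fit_length_classes(observed: dict[SseType, list[int]],
                       defaults: LengthClassTable | None = None,
                       ) -> LengthClassTable:
    """Choose per-type integer cutoffs making the three classes equiprobable.

    For each type with data, searches integer cutoff pairs (s, m), s <= m,
    minimizing the maximum deviation of any class's empirical mass from
    1/3; ties break toward the smaller cutoffs.  Constant lengths collapse
    both cutoffs onto the constant, putting all mass in Short.  Types with
    no data keep the default cutoffs.
    """
    if defaults is None:
        defaults = default_length_classes()
    cutoffs = dict(defaults.cutoffs)
    for t, lengths in observed.items():
        if not lengths:
            continue
        vals = np.asarray(sorted(lengths))
        uniq = np.unique(vals)
        if len(uniq) == 1:
            v = int(uniq[0])
            cutoffs[t] = (v, v)
            continue
        ntot = len(vals)
        best = None
        candidates = [int(u) for u in uniq]
        for si, s in enumerate(candidates):
            n_short = int(np.searchsorted(vals, s, side="right"))
            for m in candidates[si:]:
                n_med = int(np.searchsorted(vals, m, side="right")) - n_short
                n_long = ntot - n_short - n_med
                dev = max(abs(n_short / ntot - 1 / 3),
                          abs(n_med / ntot - 1 / 3),
                          abs(n_long / ntot - 1 / 3))
                key = (dev, s, m)
                if best is None or key < best:
                    best = key
        assert best is not None
        cutoffs[t] = (best[1], best[2])
    return LengthClassTable(cutoffs)


def fold_with_rnafold(sequences: dict[str, str],
                      executable: str = "RNAfold") -> dict[str, DotBracket]:
    """Predict structures by shelling out to RNAfold (optional helper).

    Runs the external minimum-free-energy folder with default parameters
    and parses its dot-bracket output.  Requires the ViennaRNA ``RNAfold``
    binary on PATH; nothing else in the package depends on this.
    """
    import subprocess

    stdin = "".join(f">{rid}\n{seq}\n" for rid, seq in sequences.items())
    proc = subprocess.run([executable, "--noPS"], input=stdin,
                          capture_output=True, text=True, check=True)
    out: dict[str, DotBracket] = {}
    lines = [l for l in proc.stdout.splitlines() if l.strip()]
    i = 0
    while i + 3 <= len(lines):
        header, _seq, struct_line = lines[i], lines[i + 1], lines[i + 2]
        rid = header.lstrip(">").split()[0]
        structure = struct_line.split(" ", 1)[0]
        out[rid] = DotBracket(id=rid, structure=structure)
        i += 3
    return out


JOINT_ALPHABET_SIZE = 5 * 5 * 3  # nucleotide x SSE type x length class


def joint_symbol(nuc: str, sse_type: SseType, length_class: LengthClass) -> int:
    """Index in [0, 75): lexicographic over (A<C<G<U<X, type order, class order)."""
    ni = "ACGUX".index(nuc)
    return 15 * ni + 3 * SSE_ORDER.index(sse_type) + CLASS_ORDER.index(length_class)


def decode_joint_symbol(s: int) -> tuple[str, SseType, LengthClass]:
    ni, rest = divmod(s, 15)
    ti, ci = divmod(rest, 3)
    return "ACGUX"[ni], SSE_ORDER[ti], CLASS_ORDER[ci]


def joint_rna_code(seq: RnaSequence | str, ann: SseAnnotation) -> np.ndarray:
    """Per-position joint code over the 75-symbol alphabet, as int array."""
    symbols = seq.symbols if isinstance(seq, RnaSequence) else seq
    if len(symbols) != ann.n:
        raise LengthMismatchError(
            f"sequence length {len(symbols)} != structure length {ann.n}")
    per_pos = ann.per_position
    return np.array([joint_symbol(ch, t, c)
                     for ch, (t, c, _eid) in zip(symbols, per_pos)],
                    dtype=np.int64)
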