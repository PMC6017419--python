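"""Fixed-length descriptors for RNA, protein, and RNA-protein pairs.

The RNA descriptor has 75 entries, one per joint (nucleotide, SSE type,
length class) symbol; the protein descriptor has 49 entries, one per
(sequence group, Ramachandran code) combination; a pair concatenates the
two into a 124-dim vector.  Entries are relative frequencies by default
(length-normalized counts, so each block sums to 1 for non-empty input);
raw counts are available behind a flag.

Feature ordering is fixed and documented for reproducibility:
RNA lexicographic over (A<C<G<U<X, Stem<Loop<InternalLoop<Bulge<Other,
Short<Medium<Long); protein lexicographic over (group 1..7, code a..g).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .encode import (PROTEIN_GROUP_ALPHABET, RAMACHANDRAN_ALPHABET,
                     RamachandranString, ReducedProteinSequence)
from .errors import LengthMismatchError, SchemaError
from .sse import CLASS_ORDER, JOINT_ALPHABET_SIZE, SSE_ORDER, decode_joint_symbol

RNA_DIM = JOINT_ALPHABET_SIZE        # 5 x 5 x 3 = 75
PROTEIN_DIM = 7 * 7                  # 49
PAIR_DIM = RNA_DIM + PROTEIN_DIM     # 124


@dataclass(frozen=True)
class FeatureVector:
    values: np.ndarray
    schema: tuple[str, ...]

    def __post_init__(self):
        if len(self.values) != len(self.schema):
            raise SchemaError(
                f"values ({len(self.values)}) and schema ({len(self.schema)}) differ")

    def __len__(self) -> int:
        return len(self.values)


def rna_schema() -> tuple[str, ...]:
    return tuple(f"{nuc}|{t.value}|{c.value}"
                 for nuc in "ACGUX" for t in SSE_ORDER for c in CLASS_ORDER)


def protein_schema() -> tuple[str, ...]:
    return tuple(f"g{g}|{c}"
                 for g in PROTEIN_GROUP_ALPHABET for c in RAMACHANDRAN_ALPHABET)


_RNA_SCHEMA = rna_schema()
_PROTEIN_SCHEMA = protein_schema()


def rna_feature_vector(joint: np.ndarray, normalize: bool = True) -> FeatureVector:
    """75-entry histogram of joint RNA symbols (empty input -> all zeros)."""
    joint = np.asarray(joint, dtype=np.int64)
    counts = np.bincount(joint, minlength=RNA_DIM).astype(float)
    if len(counts) > RNA_DIM:
        raise SchemaError("joint symbol outside [0, 75)")
    if normalize and joint.size:
        counts /= joint.size
    return FeatureVector(values=counts, schema=_RNA_SCHEMA)


def protein_feature_vector(groups: ReducedProteinSequence | str,
                           codes: RamachandranString | str,
                           normalize: bool = True) -> FeatureVector:
    """49-entry joint histogram of (sequence group, structure code).

    When both arguments carry residue position maps the two strings are
    aligned on shared residue indices (reduction drops non-canonical
    residues; dihedral-derived codes drop chain termini); bare strings of
    equal length are paired positionally.
    """
    if isinstance(groups, ReducedProteinSequence) and \
            isinstance(codes, RamachandranString) and \
            groups.positions and codes.positions:
        gmap = dict(zip(groups.positions, groups.groups))
        cmap = dict(zip(codes.positions, codes.codes))
        shared = sorted(set(gmap) & set(cmap))
        gstr = "".join(gmap[p] for p in shared)
        cstr = "".join(cmap[p] for p in shared)
    else:
        gstr = groups.groups if isinstance(groups, ReducedProteinSequence) else groups
        cstr = codes.codes if isinstance(codes, RamachandranString) else codes
        if len(gstr) != len(cstr):
            raise LengthMismatchError(
                f"group string ({len(gstr)}) and code string ({len(cstr)}) "
                "cannot be aligned: unequal lengths and no position maps")
    counts = np.zeros(PROTEIN_DIM)
    for g, c in zip(gstr, cstr):
        counts[7 * PROTEIN_GROUP_ALPHABET.index(g)
               + RAMACHANDRAN_ALPHABET.index(c)] += 1
    if normalize and len(gstr):
        counts /= len(gstr)
    return FeatureVector(values=counts, schema=_PROTEIN_SCHEMA)


def pair_feature_vector(rna: FeatureVector, prot: FeatureVector) -> FeatureVector:
    """Concatenate the 75-dim RNA and 49-dim protein blocks (124 entries)."""
    if len(rna) != RNA_DIM:
        raise SchemaError(f"RNA block has {len(rna)} entries, expected {RNA_DIM}")
    if len(prot) != PROTEIN_DIM:
        raise SchemaError(f"protein block has {len(prot)} entries, expected {PROTEIN_DIM}")
    return FeatureVector(values=np.concatenate([rna.values, prot.values]),
                         schema=rna.schema + prot.schema)


def split_pair_vector(pair: FeatureVector) -> tuple[FeatureVector, FeatureVector]:
    if len(pair) != PAIR_DIM:
        raise SchemaError(f"pair vector has {len(pair)} entries, expected {PAIR_DIM}")
    return (FeatureVector(pair.values[:RNA_DIM], pair.schema[:RNA_DIM]),
            FeatureVector(pair.values[RNA_DIM:], pair.schema[RNA_DIM:]))
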