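"""Discrete alphabets for RNA and protein chains.

Three encodings feed everything downstream:

* RNA sequences over the 5-letter alphabet ``A U C G X``, where ``X``
  stands for any unknown or non-standard nucleotide.
* Protein sequences reduced to 7 physico-chemical groups (dipole moment /
  side-chain volume clustering), serialized as digits ``1``-``7``:

  ==  =================
  1   Ala Gly Val
  2   Ile Leu Phe Pro
  3   Tyr Met Thr Ser
  4   His Asn Gln Trp
  5   Arg Lys
  6   Asp Glu
  7   Cys
  ==  =================

* Protein backbone conformation as Ramachandran codes: each residue's
  (phi, psi) dihedral pair is assigned to one of 7 regions of the
  Ramachandran plot, serialized as letters ``a``-``g``.  The two 7-symbol
  alphabets (digits for sequence, letters for structure) are deliberately
  disjoint so mixed files stay unambiguous.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from .errors import ConfigError

logger = logging.getLogger(__name__)

RNA_ALPHABET = "AUCGX"
PROTEIN_GROUP_ALPHABET = "1234567"
RAMACHANDRAN_ALPHABET = "abcdefg"

#: residue -> group digit, the 7-group reduced amino-acid alphabet
AA_GROUPS: dict[str, str] = {
    "A": "1", "G": "1", "V": "1",
    "I": "2", "L": "2", "F": "2", "P": "2",
    "Y": "3", "M": "3", "T": "3", "S": "3",
    "H": "4", "N": "4", "Q": "4", "W": "4",
    "R": "5", "K": "5",
    "D": "6", "E": "6",
    "C": "7",
}


@dataclass(frozen=True)
class RnaSequence:
    id: str
    symbols: str

    def __post_init__(self):
        bad = set(self.symbols) - set(RNA_ALPHABET)
        if bad:
            raise ValueError(f"RNA sequence {self.id!r} has invalid symbols {bad}")

    def __len__(self) -> int:
        return len(self.symbols)


@dataclass(frozen=True)
class ReducedProteinSequence:
    id: str
    groups: str
    #: 1-based positions in the original sequence kept after dropping
    #: non-canonical residues; aligns ``groups`` with structure strings
    positions: tuple[int, ...] = ()

    def __post_init__(self):
        bad = set(self.groups) - set(PROTEIN_GROUP_ALPHABET)
        if bad:
            raise ValueError(f"reduced sequence {self.id!r} has invalid symbols {bad}")
        if self.positions and len(self.positions) != len(self.groups):
            raise ValueError("position map length must equal group string length")

    def __len__(self) -> int:
        return len(self.groups)


@dataclass(frozen=True)
class DihedralAngles:
    """Backbone (phi, psi) pairs for the residues where both are defined.

    ``residue_indices`` maps each entry back to the 1-based residue number
    in the full chain (the chain termini, and neighbours of residues with
    missing backbone atoms, are omitted).  omega is carried through when
    supplied but nothing downstream consumes it.
    """

    id: str
    residue_indices: tuple[int, ...]
    phi: tuple[float, ...]
    psi: tuple[float, ...]
    omega: tuple[float, ...] | None = None

    def __post_init__(self):
        if not (len(self.residue_indices) == len(self.phi) == len(self.psi)):
            raise ValueError("residue_indices, phi and psi must have equal lengths")
        for angles in (self.phi, self.psi):
            for a in angles:
                if not (-180.0 < a <= 180.0):
                    raise ValueError(f"angle {a} outside (-180, 180]")

    def __len__(self) -> int:
        return len(self.phi)


@dataclass(frozen=True)
class RamachandranString:
    id: str
    codes: str
    positions: tuple[int, ...] = ()

    def __post_init__(self):
        bad = set(self.codes) - set(RAMACHANDRAN_ALPHABET)
        if bad:
            raise ValueError(f"Ramachandran string {self.id!r} has invalid codes {bad}")


def encode_rna_sequence(raw: str, id: str = "") -> RnaSequence:
    """Normalize a raw nucleotide string onto the 5-letter RNA alphabet.

    Case-folds to upper, maps T to U (DNA input tolerated), and maps every
    other non-ACGU character to X.  Total and idempotent by construction.
    """
    out = []
    for ch in raw:
        up = ch.upper()
        if up == "T":
            up = "U"
        # one output symbol per input character, even where Unicode
        # upper-casing expands (e.g. sharp s)
        out.append(up if up in "AUCG" else "X")
    return RnaSequence(id=id, symbols="".join(out))


def reduce_protein_sequence(raw: str, id: str = "") -> ReducedProteinSequence:
    """Map a one-letter amino-acid string onto the 7-group alphabet.

    Non-canonical residues (B, Z, X, U, *, ...) are dropped; the returned
    position map records which 1-based input positions survive so callers
    can realign per-residue structure annotations.
    """
    groups = []
    positions = []
    dropped = []
    for i, ch in enumerate(raw.upper(), start=1):
        g = AA_GROUPS.get(ch)
        if g is None:
            dropped.append((i, ch))
            continue
        groups.append(g)
        positions.append(i)
    if dropped:
        logger.warning(
            "dropped %d non-canonical residue(s) from %r: %s",
            len(dropped), id, dropped[:10],
        )
    return ReducedProteinSequence(id=id, groups="".join(groups),
                                  positions=tuple(positions))


def dihedral(p0, p1, p2, p3) -> float:
    """Torsion angle (degrees, in (-180, 180]) of four points.

    Angle between the plane (p0,p1,p2) and the plane (p1,p2,p3), signed by
    the right-hand rule about the p1->p2 axis; a planar trans arrangement
    gives 180, cis gives 0.
    """
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b1 / np.linalg.norm(b1)))
    ang = math.degrees(math.atan2(y, x))
    if ang <= -180.0:
        ang += 360.0
    return ang


def compute_dihedrals(backbone, id: str = "") -> DihedralAngles:
    """Compute per-residue (phi, psi) from N/CA/C backbone coordinates.

    Parameters
    ----------
    backbone : sequence of residues
        Each residue is a triple ``(N, CA, C)`` of xyz coordinates in
        Angstroem, or ``None`` for a residue with missing backbone atoms.

    phi(i) needs C(i-1); psi(i) needs N(i+1): the first and last residues,
    and any residue adjacent to a gap, end up without a complete (phi, psi)
    pair and are omitted from the result (the position map records which
    residues survive).
    """
    n = len(backbone)
    idx, phis, psis = [], [], []
    for i in range(n):
        if backbone[i] is None:
            continue
        has_prev = i > 0 and backbone[i - 1] is not None
        has_next = i < n - 1 and backbone[i + 1] is not None
        if not (has_prev and has_next):
            continue
        n_prev_c = backbone[i - 1][2]
        n_i, ca_i, c_i = backbone[i]
        n_next = backbone[i + 1][0]
        phis.append(dihedral(n_prev_c, n_i, ca_i, c_i))
        psis.append(dihedral(n_i, ca_i, c_i, n_next))
        idx.append(i + 1)
    return DihedralAngles(id=id, residue_indices=tuple(idx),
                          phi=tuple(phis), psi=tuple(psis))


@dataclass(frozen=True)
class RamachandranRegion:
    """One axis-aligned rectangle on the (phi, psi) torus.

    ``phi_min > phi_max`` (or likewise for psi) denotes a region wrapping
    the +-180 seam.  Membership is inclusive of the lower bound and
    exclusive of the upper.
    """

    code: str
    phi_min: float
    phi_max: float
    psi_min: float
    psi_max: float

    def contains(self, phi: float, psi: float) -> bool:
        return _in_interval(phi, self.phi_min, self.phi_max) and \
            _in_interval(psi, self.psi_min, self.psi_max)


def _in_interval(x: float, lo: float, hi: float) -> bool:
    # torus interval [lo, hi), wrapping the seam when lo > hi;
    # +180 is the same torus point as -180
    if x == 180.0:
        x = -180.0
    if lo <= hi:
        return lo <= x < hi
    return x >= lo or x < hi


@dataclass(frozen=True)
class RamachandranCodebook:
    """Seven labelled conformational regions plus a fallback code.

    The regions need not tile the torus; any (phi, psi) point falling
    outside every rectangle receives ``fallback_code``.  Earlier regions
    win when rectangles overlap (first match in file order).
    """

    regions: tuple[RamachandranRegion, ...]
    codes: tuple[str, ...]
    fallback_code: str

    def __post_init__(self):
        if len(self.codes) != 7:
            raise ConfigError(f"codebook must define exactly 7 codes, got {len(self.codes)}")
        if self.fallback_code not in self.codes:
            raise ConfigError("fallback code must be one of the 7 codes")
        for r in self.regions:
            if r.code not in self.codes:
                raise ConfigError(f"region code {r.code!r} not among codebook codes")

    def assign(self, phi: float, psi: float) -> str:
        for r in self.regions:
            if r.contains(phi, psi):
                return r.code
        return self.fallback_code


def load_codebook(path: str | Path, fallback_code: str = "g",
                  codes: str = RAMACHANDRAN_ALPHABET) -> RamachandranCodebook:
    """Read a codebook region table.

    TSV columns: code, phi_min, phi_max, psi_min, psi_max (degrees);
    multiple rows per code allowed; lines starting with '#' ignored.
    """
    regions = []
    with open(path) as fh:
        header_seen = False
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if not header_seen:
                header_seen = True  # skip header row
                continue
            code, pmin, pmax, smin, smax = line.split("\t")
            regions.append(RamachandranRegion(code, float(pmin), float(pmax),
                                              float(smin), float(smax)))
    return RamachandranCodebook(regions=tuple(regions), codes=tuple(codes),
                                fallback_code=fallback_code)


_default_codebook: RamachandranCodebook | None = None


def default_codebook() -> RamachandranCodebook:
    """The codebook shipped with the package.

    Synthetic stand-in boundaries: seven conventional conformational
    regions (right-handed helix, beta/extended, polyproline-II, left-handed
    helix, extended psi-tail, turn-like epsilon, residual fallback) with
    round-number rectangle edges.  Users with a preferred clustering of the
    Ramachandran plot should load their own table via ``load_codebook``.
    """
    global _default_codebook
    if _default_codebook is None:
        path = resources.files("rpimer").joinpath("data/ramachandran_default.tsv")
        with resources.as_file(path) as p:
            _default_codebook = load_codebook(p)
    return _default_codebook


def assign_ramachandran_codes(angles: DihedralAngles,
                              codebook: RamachandranCodebook | None = None,
                              ) -> RamachandranString:
    """Discretize (phi, psi) pairs into the 7-letter structure alphabet."""
    if codebook is None:
        codebook = default_codebook()
    codes = "".join(codebook.assign(f, s) for f, s in zip(angles.phi, angles.psi))
    return RamachandranString(id=angles.id, codes=codes,
                              positions=angles.residue_indices)
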