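"""Synthetic RPI corpora with planted, controllable signal.

The generator emits everything the pipeline consumes — RNA sequences and
nested dot-bracket structures, protein sequences and backbone dihedral
tables, and a labeled pair list — entirely from a seed.  Discriminative
signal is planted as motifs inserted into positive pairs with probability
``p_pos`` and negative pairs with ``p_neg``; background composition is
i.i.d. uniform over the alphabet, the simplest null under which k-mer
richness concentrates near 1 in the absence of signal.

Structures come from a stochastic nested grammar (stems interrupted by
bulges, internal loops and multiloop branch points, hairpin-capped,
joined by exterior single strands) rather than thermodynamic folding:
downstream tests need coverage of all five SSE types, not realism.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .encode import (AA_GROUPS, DihedralAngles, RamachandranCodebook,
                     default_codebook, encode_rna_sequence)
from .errors import ConfigError, MotifError
from .io import Pair, PairDataset, write_angle_table, write_dot_bracket, \
    write_fasta, write_pairs
from .sse import DotBracket

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class MotifSpec:
    """A substring planted into one representation's raw sequences.

    ``motif`` is written in the raw alphabet (nucleotides for ``rna_seq``,
    one-letter amino acids for ``prot_seq``); ``encoded()`` gives the form
    it takes in the mined representation.
    """

    motif: str
    representation: str  # "rna_seq" or "prot_seq"
    p_pos: float = 0.9
    p_neg: float = 0.05

    def __post_init__(self):
        if self.representation not in ("rna_seq", "prot_seq"):
            raise ConfigError(
                f"motifs can only be planted in raw sequences, got "
                f"{self.representation!r}")
        for p in (self.p_pos, self.p_neg):
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"insertion probability {p} outside [0, 1]")

    def encoded(self) -> str:
        if self.representation == "rna_seq":
            return encode_rna_sequence(self.motif).symbols
        return "".join(AA_GROUPS[a] for a in self.motif.upper())


@dataclass(frozen=True)
class StructureGrammar:
    """Branch probabilities of the nested structure grammar."""

    p_ext_unpaired: float = 0.25   # exterior: emit a single strand vs a module
    p_internal: float = 0.15      # interrupt a stem with an internal loop
    p_bulge: float = 0.15         # interrupt a stem with a one-sided bulge
    p_multi: float = 0.10         # branch into a multiloop

    def __post_init__(self):
        for p in (self.p_ext_unpaired, self.p_internal, self.p_bulge, self.p_multi):
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"grammar probability {p} outside [0, 1]")
        if self.p_internal + self.p_bulge + self.p_multi > 1.0:
            raise ConfigError("stem-interruption probabilities sum past 1")


@dataclass(frozen=True)
class SynthConfig:
    n_pos: int = 200
    n_neg: int = 200
    rna_length: tuple[int, int] = (80, 160)
    protein_length: tuple[int, int] = (120, 250)
    motifs: tuple[MotifSpec, ...] = ()
    grammar: StructureGrammar = field(default_factory=StructureGrammar)
    #: mixture over Ramachandran region codes for sampled dihedrals
    angle_mixture: tuple[tuple[str, float], ...] = (
        ("a", 0.45), ("b", 0.30), ("c", 0.10), ("d", 0.08),
        ("e", 0.04), ("f", 0.03),
    )
    x_prob: float = 0.0  # rate of unknown 'X' nucleotides in the background
    seed: int = 0

    def __post_init__(self):
        for mspec in self.motifs:
            limit = (self.rna_length[0] if mspec.representation == "rna_seq"
                     else self.protein_length[0])
            if len(mspec.motif) > limit:
                raise MotifError(
                    f"motif {mspec.motif!r} longer than minimum "
                    f"{mspec.representation} length {limit}")
        total = sum(w for _, w in self.angle_mixture)
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"angle mixture sums to {total}, expected 1")


# --- structures -----------------------------------------------------------

_MIN_MODULE = 5  # 1 bp stem + 3 nt hairpin loop


def _module(n: int, rng: np.random.Generator, g: StructureGrammar) -> str:
    """A balanced stem-loop module of exactly n characters, n >= 5."""
    max_s = (n - 3) // 2
    s = int(rng.integers(1, min(3, max_s) + 1))
    inner = n - 2 * s
    r = rng.random()
    if r < g.p_internal and inner >= _MIN_MODULE + 4:
        a = int(rng.integers(1, 3))
        b = int(rng.integers(1, 3))
        return "(" * s + "." * a + _module(inner - a - b, rng, g) + "." * b + ")" * s
    if r < g.p_internal + g.p_bulge and inner >= _MIN_MODULE + 2:
        a = int(rng.integers(1, 3))
        mid = _module(inner - a, rng, g)
        if rng.random() < 0.5:
            return "(" * s + "." * a + mid + ")" * s
        return "(" * s + mid + "." * a + ")" * s
    if r < g.p_internal + g.p_bulge + g.p_multi and inner >= 2 * _MIN_MODULE + 2:
        d = int(rng.integers(1, min(2, inner - 2 * _MIN_MODULE) + 1))
        m1 = int(rng.integers(_MIN_MODULE, inner - d - _MIN_MODULE + 1))
        m2 = inner - d - m1
        return ("(" * s + _module(m1, rng, g) + "." * d
                + _module(m2, rng, g) + ")" * s)
    # hairpin: extend the stem so the loop stays small
    t = int(rng.integers(0, (inner - 3) // 2 + 1))
    loop = inner - 2 * t
    return "(" * (s + t) + "." * loop + ")" * (s + t)


def generate_structure(length: int, grammar: StructureGrammar | None = None,
                       seed: int | np.random.Generator = 0,
                       id: str = "") -> DotBracket:
    """Sample a balanced nested dot-bracket string of the given length."""
    if length < 1:
        raise ConfigError(f"length must be >= 1, got {length}")
    g = grammar or StructureGrammar()
    rng = seed if isinstance(seed, np.random.Generator) else \
        np.random.default_rng(seed)
    parts = []
    rem = length
    while rem > 0:
        if rem < _MIN_MODULE or rng.random() < g.p_ext_unpaired:
            d = int(rng.integers(1, min(rem, 4) + 1))
            parts.append("." * d)
            rem -= d
        else:
            m = int(rng.integers(_MIN_MODULE, rem + 1))
            parts.append(_module(m, rng, g))
            rem -= m
    return DotBracket(id=id, structure="".join(parts))


# --- dihedral angles ------------------------------------------------------

def generate_angles(length: int, mixture=None,
                    seed: int | np.random.Generator = 0,
                    codebook: RamachandranCodebook | None = None,
                    id: str = "") -> DihedralAngles:
    """Sample (phi, psi) per interior residue from a mixture over regions.

    Each of residues 2..length-1 draws a region code from the mixture and
    a uniform point inside one of that code's rectangles (chain termini
    carry no complete dihedral pair, matching computed dihedrals).
    """
    rng = seed if isinstance(seed, np.random.Generator) else \
        np.random.default_rng(seed)
    cb = codebook or default_codebook()
    mixture = mixture or SynthConfig().angle_mixture
    codes = [c for c, _ in mixture]
    weights = np.array([w for _, w in mixture], dtype=float)
    weights /= weights.sum()
    by_code = {c: [r for r in cb.regions if r.code == c] for c in codes}
    for c in codes:
        if not by_code[c]:
            raise ConfigError(f"mixture names code {c!r} with no region rectangles")
    idx, phis, psis = [], [], []
    for resi in range(2, length):
        c = codes[int(rng.choice(len(codes), p=weights))]
        region = by_code[c][int(rng.integers(len(by_code[c])))]
        phi = _sample_interval(region.phi_min, region.phi_max, rng)
        psi = _sample_interval(region.psi_min, region.psi_max, rng)
        idx.append(resi)
        phis.append(phi)
        psis.append(psi)
    return DihedralAngles(id=id, residue_indices=tuple(idx),
                          phi=tuple(phis), psi=tuple(psis))


def _sample_interval(lo: float, hi: float, rng) -> float:
    """Uniform draw from a torus interval [lo, hi), mapped into (-180, 180]."""
    span = hi - lo if lo <= hi else (hi + 360.0) - lo
    x = lo + rng.uniform(0.0, span)
    if x > 180.0:
        x -= 360.0
    if x <= -180.0:
        x += 360.0
    return float(x)


# --- full corpora ---------------------------------------------------------

def _random_rna(length: int, x_prob: float, rng) -> str:
    if x_prob > 0:
        syms = rng.choice(list("ACGUX"), size=length,
                          p=[(1 - x_prob) / 4] * 4 + [x_prob])
    else:
        syms = rng.choice(list("ACGU"), size=length)
    return "".join(syms)


def _random_protein(length: int, rng) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def _plant(seq: str, motif: str, rng) -> str:
    start = int(rng.integers(0, len(seq) - len(motif) + 1))
    return seq[:start] + motif + seq[start + len(motif):]


def generate_dataset(cfg: SynthConfig,
                     out_dir: str | Path | None = None) -> PairDataset:
    """Generate a full labeled corpus; optionally write it to disk.

    Each pair gets its own RNA and protein chain.  On-disk layout:
    ``rna.fasta``, ``rna_structures.dbn``, ``proteins.fasta``,
    ``angles/<protein_id>.tsv``, ``pairs.tsv``, ``manifest.json``.
    """
    rng = np.random.default_rng(cfg.seed)
    pairs: list[Pair] = []
    rna_seqs, rna_structs, protein_seqs, protein_angles = {}, {}, {}, {}
    labels = [1] * cfg.n_pos + [0] * cfg.n_neg
    for i, label in enumerate(labels):
        rid, pid = f"R{i:04d}", f"P{i:04d}"
        rlen = int(rng.integers(cfg.rna_length[0], cfg.rna_length[1] + 1))
        plen = int(rng.integers(cfg.protein_length[0], cfg.protein_length[1] + 1))
        rseq = _random_rna(rlen, cfg.x_prob, rng)
        pseq = _random_protein(plen, rng)
        for m in cfg.motifs:
            p = m.p_pos if label == 1 else m.p_neg
            if rng.random() < p:
                if m.representation == "rna_seq":
                    rseq = _plant(rseq, m.motif, rng)
                else:
                    pseq = _plant(pseq, m.motif, rng)
        rna_seqs[rid] = encode_rna_sequence(rseq, id=rid)
        rna_structs[rid] = generate_structure(rlen, cfg.grammar, rng, id=rid)
        protein_seqs[pid] = pseq
        protein_angles[pid] = generate_angles(plen, cfg.angle_mixture, rng, id=pid)
        pairs.append(Pair(rid, pid, label))
    dataset = PairDataset(pairs=pairs, rna_seqs=rna_seqs,
                          rna_structs=rna_structs, protein_seqs=protein_seqs,
                          protein_angles=protein_angles)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_fasta(out / "rna.fasta", {i: s.symbols for i, s in rna_seqs.items()})
        write_dot_bracket(out / "rna_structures.dbn",
                          {i: s.symbols for i, s in rna_seqs.items()}, rna_structs)
        write_fasta(out / "proteins.fasta", protein_seqs)
        angle_dir = out / "angles"
        angle_dir.mkdir(exist_ok=True)
        for pid, ang in protein_angles.items():
            write_angle_table(angle_dir / f"{pid}.tsv", ang)
        write_pairs(out / "pairs.tsv", pairs)
        manifest = asdict(cfg)
        manifest["n_pairs"] = len(pairs)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return dataset


def load_dataset(directory: str | Path) -> PairDataset:
    """Read back a corpus written by :func:`generate_dataset`."""
    from .io import read_angle_table, read_dot_bracket, read_fasta, read_pairs

    d = Path(directory)
    rna_raw = read_fasta(d / "rna.fasta")
    rna_seqs = {i: encode_rna_sequence(s, id=i) for i, s in rna_raw.items()}
    rna_structs = read_dot_bracket(d / "rna_structures.dbn")
    protein_seqs = read_fasta(d / "proteins.fasta")
    protein_angles = {}
    angle_dir = d / "angles"
    if angle_dir.is_dir():
        for path in sorted(angle_dir.glob("*.tsv")):
            protein_angles[path.stem] = read_angle_table(path, id=path.stem)
    pairs = read_pairs(d / "pairs.tsv")
    return PairDataset(pairs=pairs, rna_seqs=rna_seqs, rna_structs=rna_structs,
                       protein_seqs=protein_seqs, protein_angles=protein_angles)
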