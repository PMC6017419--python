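"""On-disk formats and dataset assembly.

Tabular artifacts are TSV (greppable, diff-able); configuration and
manifests are JSON; sequences are standard multi-line FASTA; structures
are Vienna-style dot-bracket records (``>id`` / sequence / structure, an
RNAfold energy suffix on the structure line is tolerated and stripped).
All on-disk residue/nucleotide indices are 1-based.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import classify, featvec, kmers, sse
from .encode import (DihedralAngles, RamachandranCodebook, RamachandranString,
                     RnaSequence, assign_ramachandran_codes,
                     encode_rna_sequence, reduce_protein_sequence)
from .errors import FastaError, LabelError, RpimerError
from .sse import DotBracket, LengthClassTable, SseType, annotate_structure

logger = logging.getLogger(__name__)


# --- FASTA ----------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Order-preserving id -> sequence map; duplicate ids are an error."""
    out: dict[str, str] = {}
    try:
        records = list(SeqIO.parse(str(path), "fasta"))
    except Exception as exc:  # Bio raises ValueError on malformed input
        raise FastaError(f"cannot parse FASTA {path}: {exc}") from exc
    for rec in records:
        if rec.id in out:
            raise FastaError(f"duplicate FASTA id {rec.id!r} in {path}")
        out[rec.id] = str(rec.seq)
    if not out:
        logger.warning("FASTA file %s contains no records", path)
    return out


def write_fasta(path: str | Path, sequences: dict[str, str], width: int = 60):
    records = [SeqRecord(Seq(s), id=i, description="") for i, s in sequences.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# --- dot-bracket ----------------------------------------------------------

def read_dot_bracket(path: str | Path) -> dict[str, DotBracket]:
    """Vienna records: '>id' line, sequence line, structure line.

    A trailing free-energy annotation like ``(((...))) (-3.40)`` is
    stripped from the structure line.
    """
    out: dict[str, DotBracket] = {}
    lines = Path(path).read_text().splitlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if not line:
            i += 1
            continue
        if not line.startswith(">"):
            raise FastaError(f"expected '>' header at line {i + 1} of {path}",
                             line=i + 1)
        rid = line[1:].split()[0]
        if i + 2 >= len(lines):
            raise FastaError(f"truncated record {rid!r} in {path}", line=i + 1)
        struct = lines[i + 2].strip()
        if " " in struct:  # energy suffix, e.g. "(((...))) (-3.40)"
            struct = struct.split(" ", 1)[0]
        if rid in out:
            raise FastaError(f"duplicate structure id {rid!r} in {path}")
        out[rid] = DotBracket(id=rid, structure=struct)
        i += 3
    return out


def write_dot_bracket(path: str | Path, sequences: dict[str, str],
                      structures: dict[str, DotBracket]):
    with open(path, "w") as fh:
        for rid, db in structures.items():
            fh.write(f">{rid}\n{sequences.get(rid, '')}\n{db.structure}\n")


# --- dihedral angle tables ------------------------------------------------

def read_angle_table(path: str | Path, id: str = "") -> DihedralAngles:
    """TSV with columns residue_index, phi, psi[, omega]; '.' = undefined.

    Only residues with both phi and psi defined enter the result.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    idx, phis, psis, omegas = [], [], [], []
    has_omega = "omega" in df.columns
    for _, row in df.iterrows():
        if row["phi"] == "." or row["psi"] == ".":
            continue
        idx.append(int(row["residue_index"]))
        phis.append(float(row["phi"]))
        psis.append(float(row["psi"]))
        if has_omega and row["omega"] != ".":
            omegas.append(float(row["omega"]))
    return DihedralAngles(id=id or Path(path).stem, residue_indices=tuple(idx),
                          phi=tuple(phis), psi=tuple(psis),
                          omega=tuple(omegas) if omegas else None)


def write_angle_table(path: str | Path, angles: DihedralAngles):
    with open(path, "w") as fh:
        fh.write("residue_index\tphi\tpsi\n")
        for i, f, s in zip(angles.residue_indices, angles.phi, angles.psi):
            fh.write(f"{i}\t{f:.4f}\t{s:.4f}\n")


# --- length-class table ---------------------------------------------------

def read_length_table(path: str | Path) -> LengthClassTable:
    df = pd.read_csv(path, sep="\t")
    cutoffs = {SseType(row["type"]): (int(row["short_max"]), int(row["medium_max"]))
               for _, row in df.iterrows()}
    return LengthClassTable(cutoffs)


def write_length_table(path: str | Path, table: LengthClassTable):
    with open(path, "w") as fh:
        fh.write("type\tshort_max\tmedium_max\n")
        for t, (s, m) in table.cutoffs.items():
            fh.write(f"{t.value}\t{s}\t{m}\n")


# --- pair tables ----------------------------------------------------------

@dataclass(frozen=True)
class Pair:
    rna_id: str
    protein_id: str
    label: int  # 1 interacting, 0 not


def read_pairs(path: str | Path) -> list[Pair]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"rna_id", "protein_id", "label"}
    if not required <= set(df.columns):
        raise LabelError(f"pair table {path} lacks columns {required - set(df.columns)}")
    pairs = []
    for rownum, row in enumerate(df.itertuples(index=False), start=2):
        token = str(row.label).strip()
        if token not in ("0", "1"):
            raise LabelError(f"unknown label {token!r} at row {rownum} of {path}")
        pairs.append(Pair(row.rna_id, row.protein_id, int(token)))
    n_pos = sum(p.label for p in pairs)
    if not pairs:
        logger.warning("pair table %s is empty", path)
    else:
        logger.info("read %d pairs (%d positive, %d negative) from %s",
                    len(pairs), n_pos, len(pairs) - n_pos, path)
    return pairs


def write_pairs(path: str | Path, pairs: list[Pair]):
    with open(path, "w") as fh:
        fh.write("rna_id\tprotein_id\tlabel\n")
        for p in pairs:
            fh.write(f"{p.rna_id}\t{p.protein_id}\t{p.label}\n")


# --- the assembled dataset ------------------------------------------------

@dataclass
class PairDataset:
    """Labeled RNA-protein pairs with their sequence/structure registries.

    Structure registries (``rna_structs``, ``protein_angles`` or
    ``protein_codes``) may be left empty for sequence-only (QQ) work; any
    model touching a structure representation requires them.
    """

    pairs: list[Pair]
    rna_seqs: dict[str, RnaSequence] = field(default_factory=dict)
    rna_structs: dict[str, DotBracket] = field(default_factory=dict)
    protein_seqs: dict[str, str] = field(default_factory=dict)
    protein_angles: dict[str, DihedralAngles] = field(default_factory=dict)
    protein_codes: dict[str, RamachandranString] = field(default_factory=dict)
    codebook: RamachandranCodebook | None = None
    length_table: LengthClassTable | None = None
    _annotation_cache: dict[str, sse.SseAnnotation] = field(
        default_factory=dict, repr=False)

    def __post_init__(self):
        for p in self.pairs:
            if p.rna_id not in self.rna_seqs:
                raise RpimerError(f"pair references unknown RNA id {p.rna_id!r}")
            if p.protein_id not in self.protein_seqs:
                raise RpimerError(f"pair references unknown protein id {p.protein_id!r}")

    @property
    def labels(self) -> np.ndarray:
        return np.array([p.label for p in self.pairs], dtype=int)

    def annotation(self, rna_id: str) -> sse.SseAnnotation:
        if rna_id not in self._annotation_cache:
            if rna_id not in self.rna_structs:
                raise RpimerError(f"no structure for RNA {rna_id!r}")
            self._annotation_cache[rna_id] = annotate_structure(
                self.rna_structs[rna_id], table=self.length_table, id=rna_id)
        return self._annotation_cache[rna_id]

    def ramachandran(self, protein_id: str) -> RamachandranString:
        if protein_id not in self.protein_codes:
            if protein_id not in self.protein_angles:
                raise RpimerError(f"no structure for protein {protein_id!r}")
            self.protein_codes[protein_id] = assign_ramachandran_codes(
                self.protein_angles[protein_id], self.codebook)
        return self.protein_codes[protein_id]

    def pair_strings(self, pair: Pair, representations) -> dict[str, str]:
        """The pair's string under each requested representation."""
        out = {}
        for rep in representations:
            if rep == "rna_seq":
                out[rep] = self.rna_seqs[pair.rna_id].symbols
            elif rep == "rna_sse":
                out[rep] = self.annotation(pair.rna_id).element_code_string()
            elif rep == "prot_seq":
                out[rep] = reduce_protein_sequence(
                    self.protein_seqs[pair.protein_id], id=pair.protein_id).groups
            elif rep == "prot_sse":
                out[rep] = self.ramachandran(pair.protein_id).codes
            else:
                raise RpimerError(f"unknown representation {rep!r}")
        return out

    def corpora(self, representation: str) -> tuple[list[str], list[str]]:
        """(positive, negative) per-pair string corpora for one representation.

        A chain appearing in m pairs contributes m strings.
        """
        pos, neg = [], []
        for p in self.pairs:
            s = self.pair_strings(p, [representation])[representation]
            (pos if p.label == 1 else neg).append(s)
        return pos, neg


# --- matrix builders ------------------------------------------------------

def build_feature_matrix(dataset: PairDataset,
                         normalize: bool = True) -> pd.DataFrame:
    """124-column fixed descriptor matrix: rna_id, protein_id, label + features."""
    rows = []
    for p in dataset.pairs:
        joint = sse.joint_rna_code(dataset.rna_seqs[p.rna_id],
                                   dataset.annotation(p.rna_id))
        rvec = featvec.rna_feature_vector(joint, normalize=normalize)
        groups = reduce_protein_sequence(dataset.protein_seqs[p.protein_id],
                                         id=p.protein_id)
        codes = dataset.ramachandran(p.protein_id)
        pvec = featvec.protein_feature_vector(groups, codes, normalize=normalize)
        vec = featvec.pair_feature_vector(rvec, pvec)
        rows.append((p, vec))
    schema = rows[0][1].schema if rows else featvec.rna_schema() + featvec.protein_schema()
    data = {"rna_id": [p.rna_id for p, _ in rows],
            "protein_id": [p.protein_id for p, _ in rows],
            "label": [p.label for p, _ in rows]}
    values = np.array([v.values for _, v in rows]) if rows else np.empty((0, len(schema)))
    for j, name in enumerate(schema):
        data[name] = values[:, j]
    return pd.DataFrame(data)


def mine_kmer_tables(dataset: PairDataset, representations=None,
                     k_min: int = 2, k_max: int = 5,
                     ) -> dict[str, kmers.KmerCountTable]:
    """gamma/lambda count tables for each requested representation."""
    if representations is None:
        representations = list(kmers.REPRESENTATIONS)
    out = {}
    for rep in representations:
        pos, neg = dataset.corpora(rep)
        out[rep] = kmers.build_count_table(pos, neg, rep, k_min=k_min, k_max=k_max)
    return out


def build_string_feature_matrix(dataset: PairDataset, model: str,
                                selections: dict[str, kmers.KmerSelection],
                                normalize: bool = True) -> pd.DataFrame:
    """String-model feature matrix over the selected k-mers."""
    reps = kmers.MODEL_REPRESENTATIONS[model]
    rows = []
    schema = None
    for p in dataset.pairs:
        strings = dataset.pair_strings(p, reps)
        vec = kmers.string_model_vector(strings, model, selections,
                                        normalize=normalize)
        if schema is None:
            schema = vec.schema
        rows.append((p, vec.values))
    if schema is None:
        schema = ()
    data = {"rna_id": [p.rna_id for p, _ in rows],
            "protein_id": [p.protein_id for p, _ in rows],
            "label": [p.label for p, _ in rows]}
    values = np.array([v for _, v in rows]) if rows else np.empty((0, len(schema)))
    for j, name in enumerate(schema):
        data[name] = values[:, j]
    return pd.DataFrame(data)


def matrix_to_xy(matrix: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    meta = ["rna_id", "protein_id", "label"]
    X = matrix.drop(columns=meta).to_numpy(dtype=float)
    y = matrix["label"].to_numpy(dtype=int)
    return X, y


def write_feature_matrix(path: str | Path, matrix: pd.DataFrame):
    matrix.to_csv(path, sep="\t", index=False)


def read_feature_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# --- k-mer statistic tables -----------------------------------------------

def write_kmer_table(path: str | Path, table: kmers.KmerCountTable):
    """TSV sorted by |log2 richness| descending (top-list convention)."""
    with open(path, "w") as fh:
        fh.write("representation\tbeta\tgamma\tlam\trichness\tlog2_richness\n")
        for s in table.stats():
            fh.write(f"{table.representation}\t{s.beta}\t{s.gamma}\t{s.lam}\t"
                     f"{s.richness:.6g}\t{s.log2_richness:.6g}\n")


def read_kmer_table(path: str | Path) -> kmers.KmerCountTable:
    df = pd.read_csv(path, sep="\t", dtype={"beta": str})
    reps = df["representation"].unique()
    if len(reps) != 1:
        raise RpimerError(f"k-mer table {path} mixes representations {list(reps)}")
    counts = {str(r.beta): (int(r.gamma), int(r.lam))
              for r in df.itertuples(index=False)}
    lens = [len(b) for b in counts] or [2]
    return kmers.KmerCountTable(representation=str(reps[0]), counts=counts,
                                k_min=min(lens), k_max=max(lens))


def write_metrics(path: str | Path, report: classify.MetricsReport):
    import json
    payload = report.to_dict()
    payload["flags"] = list(report.flags)
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def write_predictions(path: str | Path, dataset: PairDataset,
                      result: classify.CvResult):
    """Per-pair prediction records (input for length-vs-performance plots)."""
    with open(path, "w") as fh:
        fh.write("rna_id\tprotein_id\tlabel\tprediction\tscore\tfold\n")
        for p, (label, pred, score, fold) in zip(dataset.pairs, result.predictions):
            fh.write(f"{p.rna_id}\t{p.protein_id}\t{label}\t{pred}\t"
                     f"{score:.6g}\t{fold}\n")
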