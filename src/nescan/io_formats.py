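"""Readers and writers for the external formats the pipeline touches.

All residue coordinates are 1-based inclusive throughout the package.
Sequence/track length agreement is deliberately *not* checked here — tracks
can be inspected standalone — the pipeline checks alignment at assembly time
(:func:`nescan.pipeline.run_protein`).

Supported dialects
------------------
* FASTA (standard, via Biopython).
* Disorder tracks in three predictor dialects:
  ``disopred``  — ``idx aa mark propensity`` with mark in ``{., *}``;
  ``spotd``     — ``idx aa propensity label``;
  ``iupred``    — ``idx aa propensity`` with ``#`` comment lines.
* PSIPRED ``.ss2``-style secondary structure: ``idx aa state cC cH cE``.
* Domain / evidence annotations as headerless TSV interval tables.
* PDB for CRM1–peptide template structures (via gemmi; single model,
  first altloc).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

AMINO_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")

DISORDER_DIALECTS = ("disopred", "spotd", "iupred")
DOMAIN_SOURCES = ("smart", "pfam", "ncbi_curated", "cdd")
EVIDENCE_KINDS = ("mutation", "functional", "site")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SequenceRecord:
    """A protein sequence with an accession-like identifier."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise FormatError(f"record {self.id!r}: empty sequence")
        for pos, aa in enumerate(self.sequence, start=1):
            if aa not in AMINO_ALPHABET:
                raise FormatError(
                    f"record {self.id!r}: illegal residue {aa!r} at position {pos}"
                )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class DisorderTrack:
    """Per-residue disorder propensity from one predictor, 1-based."""

    predictor: str
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.predictor not in DISORDER_DIALECTS:
            raise FormatError(f"unknown predictor {self.predictor!r}")
        for pos, v in enumerate(self.values, start=1):
            if not (0.0 <= v <= 1.0):
                raise FormatError(
                    f"{self.predictor} track: value {v} outside [0,1] at residue {pos}"
                )

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class SSTrack:
    """Per-residue secondary structure state (H/E/C) with 0–9 confidence."""

    states: str
    confidence: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.states) != len(self.confidence):
            raise FormatError("state/confidence length mismatch")
        bad = set(self.states) - set("HEC")
        if bad:
            raise FormatError(f"unknown secondary structure state(s) {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.states)


@dataclass(frozen=True)
class DomainAnnotation:
    """A conserved-domain interval, 1-based inclusive."""

    source: str
    name: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.source not in DOMAIN_SOURCES:
            raise FormatError(f"unknown domain source {self.source!r}")
        if not (1 <= self.start <= self.end):
            raise FormatError(f"domain {self.name!r}: bad interval {self.start}-{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class EvidenceAnnotation:
    """An experimental NES-evidence interval, 1-based inclusive."""

    kind: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.kind not in EVIDENCE_KINDS:
            raise FormatError(f"unknown evidence kind {self.kind!r}")
        if not (1 <= self.start <= self.end):
            raise FormatError(f"evidence: bad interval {self.start}-{self.end}")


@dataclass
class StructureCoordinates:
    """Coarse per-residue coordinates for one or more chains.

    Arrays are parallel over residues: backbone N/CA/C/O positions plus a
    side-chain centroid (CA for glycine), in Å.
    """

    chain: np.ndarray        # (n,) str
    resid: np.ndarray        # (n,) int
    resname: np.ndarray      # (n,) str, one-letter where known else 'X'
    n: np.ndarray            # (n,3)
    ca: np.ndarray           # (n,3)
    c: np.ndarray            # (n,3)
    o: np.ndarray            # (n,3)
    centroid: np.ndarray     # (n,3)

    def __post_init__(self) -> None:
        for arr in (self.n, self.ca, self.c, self.o, self.centroid):
            if not np.all(np.isfinite(arr)):
                raise FormatError("non-finite coordinate")
        for ch in np.unique(self.chain):
            ids = self.resid[self.chain == ch]
            if np.any(np.diff(ids) <= 0):
                raise FormatError(f"chain {ch}: residue indices not strictly increasing")

    def __len__(self) -> int:
        return len(self.resid)

    def select_chain(self, chain: str) -> "StructureCoordinates":
        m = self.chain == chain
        return StructureCoordinates(
            self.chain[m], self.resid[m], self.resname[m],
            self.n[m], self.ca[m], self.c[m], self.o[m], self.centroid[m],
        )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into validated :class:`SequenceRecord` objects."""
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    with open(path) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            if rec.id in seen:
                raise FormatError(f"{path}: duplicate record id {rec.id!r}")
            seen.add(rec.id)
            records.append(SequenceRecord(rec.id, str(rec.seq).upper()))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    bio = [_BioSeqRecord(Seq(r.sequence), id=r.id, description="") for r in records]
    with open(path, "w") as handle:
        SeqIO.write(bio, handle, "fasta")


# ---------------------------------------------------------------------------
# disorder tracks
# ---------------------------------------------------------------------------

def _track_rows(path: Path) -> list[tuple[int, list[str]]]:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            rows.append((lineno, stripped.split()))
    if not rows:
        raise FormatError(f"{path}: no data rows")
    return rows


def read_disorder_track(path: str | Path, dialect: str) -> DisorderTrack:
    """Parse one predictor's per-residue disorder propensities.

    Residue numbering must be contiguous from 1; values must lie in [0,1].
    """
    if dialect not in DISORDER_DIALECTS:
        raise FormatError(f"unknown disorder dialect {dialect!r}")
    path = Path(path)
    value_col = {"disopred": 3, "spotd": 2, "iupred": 2}[dialect]
    min_cols = value_col + 1
    if dialect == "spotd":
        min_cols = 4  # idx aa propensity label
    values: list[float] = []
    expect = 1
    for lineno, cols in _track_rows(path):
        if len(cols) < min_cols:
            raise FormatError(f"{path}:{lineno}: expected ≥{min_cols} columns, got {len(cols)}")
        try:
            idx = int(cols[0])
            val = float(cols[value_col])
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from None
        if dialect == "disopred" and cols[2] not in (".", "*"):
            raise FormatError(f"{path}:{lineno}: disopred mark must be '.' or '*'")
        if idx != expect:
            raise FormatError(f"{path}:{lineno}: residue index {idx}, expected {expect}")
        if not (0.0 <= val <= 1.0):
            raise FormatError(f"{path}:{lineno}: propensity {val} outside [0,1]")
        values.append(val)
        expect += 1
    return DisorderTrack(dialect, tuple(values))


def write_disorder_track(track: DisorderTrack, sequence: str, path: str | Path) -> None:
    """Write a track in its own predictor dialect (inverse of the reader)."""
    lines = []
    for i, v in enumerate(track.values):
        aa = sequence[i] if i < len(sequence) else "X"
        if track.predictor == "disopred":
            mark = "*" if v >= 0.5 else "."
            lines.append(f"{i + 1:5d} {aa} {mark} {v:.3f}")
        elif track.predictor == "spotd":
            label = "D" if v >= 0.5 else "O"
            lines.append(f"{i + 1} {aa} {v:.3f} {label}")
        else:
            lines.append(f"{i + 1}\t{aa}\t{v:.4f}")
    header = "# iupred2a-style plain table\n" if track.predictor == "iupred" else ""
    Path(path).write_text(header + "\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# secondary structure (.ss2)
# ---------------------------------------------------------------------------

_SS_ORDER = "CHE"  # column order of the three scores


def read_ss2(path: str | Path) -> SSTrack:
    """Parse a PSIPRED ss2-style table.

    The stored state is the argmax of the three scores; confidence is
    floor(9 × max score), an integer in 0–9.
    """
    path = Path(path)
    states: list[str] = []
    conf: list[int] = []
    expect = 1
    for lineno, cols in _track_rows(path):
        if len(cols) < 6:
            raise FormatError(f"{path}:{lineno}: expected 6 columns, got {len(cols)}")
        idx, _aa, state = int(cols[0]), cols[1], cols[2]
        if state not in "HEC":
            raise FormatError(f"{path}:{lineno}: unknown state {state!r}")
        if idx != expect:
            raise FormatError(f"{path}:{lineno}: residue index {idx}, expected {expect}")
        scores = [float(c) for c in cols[3:6]]
        best = int(np.argmax(scores))
        states.append(_SS_ORDER[best])
        conf.append(min(9, math.floor(9 * scores[best])))
        expect += 1
    return SSTrack("".join(states), tuple(conf))


def write_ss2(track: SSTrack, sequence: str, path: str | Path) -> None:
    lines = ["# PSIPRED-style VFORMAT"]
    for i, (st, cf) in enumerate(zip(track.states, track.confidence)):
        aa = sequence[i] if i < len(sequence) else "X"
        scores = {"C": 0.0, "H": 0.0, "E": 0.0}
        scores[st] = (cf + 0.5) / 9.0 if cf < 9 else 1.0
        rest = (1.0 - scores[st]) / 2.0
        for k in scores:
            if k != st:
                scores[k] = rest
        lines.append(
            f"{i + 1:4d} {aa} {st}  {scores['C']:.3f} {scores['H']:.3f} {scores['E']:.3f}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# interval tables (domains, evidence)
# ---------------------------------------------------------------------------

def read_domains(path: str | Path) -> list[DomainAnnotation]:
    """Read a CD-search-concise-style TSV: source, name, start, end."""
    path = Path(path)
    out = []
    for lineno, cols in _track_rows(path):
        if len(cols) < 4:
            raise FormatError(f"{path}:{lineno}: expected 4 columns")
        try:
            out.append(DomainAnnotation(cols[0], cols[1], int(cols[2]), int(cols[3])))
        except (ValueError, FormatError) as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from None
    return out


def write_domains(domains: Iterable[DomainAnnotation], path: str | Path) -> None:
    lines = [f"{d.source}\t{d.name}\t{d.start}\t{d.end}" for d in domains]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_evidence(path: str | Path) -> list[EvidenceAnnotation]:
    """Read an evidence TSV: kind, start, end."""
    path = Path(path)
    out = []
    for lineno, cols in _track_rows(path):
        if len(cols) < 3:
            raise FormatError(f"{path}:{lineno}: expected 3 columns")
        try:
            out.append(EvidenceAnnotation(cols[0], int(cols[1]), int(cols[2])))
        except (ValueError, FormatError) as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from None
    return out


def write_evidence(evidence: Iterable[EvidenceAnnotation], path: str | Path) -> None:
    lines = [f"{e.kind}\t{e.start}\t{e.end}" for e in evidence]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


# ---------------------------------------------------------------------------
# PDB structures
# ---------------------------------------------------------------------------

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V",
}
_ONE_TO_THREE = {v: k for k, v in _THREE_TO_ONE.items()}

BACKBONE_ATOMS = ("N", "CA", "C", "O")
DEFAULT_GROOVE_WINDOW = (479, 655)


def read_structure(
    path: str | Path,
    chain_map: dict[str, str],
    groove_window: tuple[int, int] = DEFAULT_GROOVE_WINDOW,
) -> StructureCoordinates:
    """Read a CRM1/peptide PDB into coarse per-residue coordinates.

    ``chain_map`` maps roles to chain labels, e.g. ``{"groove": "A",
    "peptide": "B"}``. The groove chain is truncated to ``groove_window``
    (the CRM1 fragment spanning the NES-binding groove). Residues missing a
    backbone atom are dropped with a warning printed to stderr; an empty
    selected chain is an error. Only single-model files are accepted; the
    first altloc is kept.
    """
    import sys

    st = gemmi.read_structure(str(path))
    if len(st) != 1:
        raise FormatError(f"{path}: expected a single-model file, found {len(st)} models")
    st.remove_alternative_conformations()
    model = st[0]

    rows: list[tuple[str, int, str, np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]] = []
    for role, label in chain_map.items():
        chain = model.find_chain(label)
        if chain is None:
            raise FormatError(f"{path}: chain {label!r} ({role}) not found")
        kept = 0
        for res in chain:
            seqid = res.seqid.num
            if role == "groove" and not (groove_window[0] <= seqid <= groove_window[1]):
                continue
            atoms = {a.name: np.array([a.pos.x, a.pos.y, a.pos.z]) for a in res}
            if any(name not in atoms for name in BACKBONE_ATOMS):
                print(
                    f"warning: {path}: chain {label} residue {seqid} missing "
                    "backbone atom(s); dropped",
                    file=sys.stderr,
                )
                continue
            side = [
                xyz for name, xyz in atoms.items()
                if name not in BACKBONE_ATOMS and not name.startswith("H")
            ]
            centroid = np.mean(side, axis=0) if side else atoms["CA"]
            rows.append((
                label, seqid, _THREE_TO_ONE.get(res.name, "X"),
                atoms["N"], atoms["CA"], atoms["C"], atoms["O"], centroid,
            ))
            kept += 1
        if kept == 0:
            raise FormatError(f"{path}: chain {label!r} ({role}) has no usable residues")

    return StructureCoordinates(
        chain=np.array([r[0] for r in rows]),
        resid=np.array([r[1] for r in rows]),
        resname=np.array([r[2] for r in rows]),
        n=np.array([r[3] for r in rows]),
        ca=np.array([r[4] for r in rows]),
        c=np.array([r[5] for r in rows]),
        o=np.array([r[6] for r in rows]),
        centroid=np.array([r[7] for r in rows]),
    )


def write_structure_pdb(coords: StructureCoordinates, path: str | Path) -> None:
    """Write coarse coordinates as a minimal PDB (backbone + centroid CB)."""
    lines = []
    serial = 1
    for i in range(len(coords)):
        res3 = _ONE_TO_THREE.get(str(coords.resname[i]), "UNK")
        for name, xyz in (
            ("N", coords.n[i]), ("CA", coords.ca[i]),
            ("C", coords.c[i]), ("O", coords.o[i]),
        ):
            lines.append(_pdb_atom(serial, name, res3, coords.chain[i], coords.resid[i], xyz))
            serial += 1
        if str(coords.resname[i]) != "G":
            lines.append(_pdb_atom(serial, "CB", res3, coords.chain[i], coords.resid[i],
                                   coords.centroid[i]))
            serial += 1
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def _pdb_atom(serial: int, name: str, res3: str, chain: str, resid: int, xyz) -> str:
    return (
        f"ATOM  {serial:5d} {name:<4s}{res3:>3s} {chain:1s}{resid:4d}    "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00  0.00"
    )
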