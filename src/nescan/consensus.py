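"""NES consensus-pattern compilation, scanning, prioritisation and labeling.

The scanner implements the modified Kosugi consensus classes. A class is an
ordered template of position slots relative to the first hydrophobic anchor
Φ1: Φ slots accept {L,I,V,M,F}; spacer slots accept either any residue (X)
or any residue except Pro/Trp ([^PW]). Thr or Ala may substitute at exactly
one of Φ1/Φ2 for the classes where the consensus allows it. Reverse classes
are mirrored templates scanned against the reversed sequence; their match
coordinates are mapped back to the forward frame of the input sequence.

Class templates (offsets relative to Φ1):

====== ===================== ==========================================
class  Φ offsets             spacer constraints
====== ===================== ==========================================
1a     0, 4, 7, 9            X3 · [^PW]2 · [^PW]
1b     0, 3, 6, 8            X2 · [^PW]2 · [^PW]
2      0, 2, 5, 7            X1 · [^PW]2 · [^PW]
1c     0, 4, 8, 10           X3 · [^PW]3 · [^PW]
1d     0, 3, 7, 9            X2 · [^PW]3 · [^PW]
3      0, 3, 7, 10           X2 · X[^PW]2 · [^PW]2
4      0, 4, 7, 11           X3 · [^PW]2 · XXX with ≥1 Pro
1a-R   mirror of 1a          plus the reverse bulky-residue rule
1c-R   mirror of 1c          plus the reverse bulky-residue rule
====== ===================== ==========================================

The reverse bulky rule requires at least one of the two registry residues
bound in the P0/P1 pockets (in the mirrored frame these are the Φ3/Φ4
slots, i.e. the N-terminal end of the match in original coordinates) to be
Leu, Phe or Met.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

from .io_formats import EvidenceAnnotation

PHI_RESIDUES = frozenset("LIVMF")
TA_RESIDUES = frozenset("TA")
NOPW_FORBIDDEN = frozenset("PWX")  # 'X' (unknown) never satisfies a [^PW] slot
REVERSE_BULKY = frozenset("LFM")

#: classes for which a Φ0 slot (Φ0-X2-Φ1) is part of the consensus diagram.
#: Class 3 has no Φ0 position in the consensus.
PHI0_CLASSES = frozenset({"1a", "1b", "1c", "1d", "2", "4", "1a-R", "1c-R"})

DEFAULT_PHI0_OFFSET = 3
MAX_WINDOW = 25

CLASS_ORDER = ("1a", "1b", "1c", "1d", "2", "3", "4", "1a-R", "1c-R")


class PatternError(ValueError):
    """Raised for unknown class names or unclassifiable matches."""


@dataclass(frozen=True)
class NESClassSpec:
    """One consensus class: Φ-slot offsets and spacer constraints."""

    class_id: str
    direction: str                       # "forward" | "reverse"
    phi_offsets: tuple[int, int, int, int]
    nopw_offsets: frozenset[int]         # spacer offsets restricted to [^PW]
    ta_allowance: bool                   # Thr/Ala at one of Φ1/Φ2
    pro_requirement: Optional[tuple[int, int]] = None  # offsets spanning ≥1 Pro
    reverse_bulky_rule: bool = False

    @property
    def length(self) -> int:
        return self.phi_offsets[-1] + 1

    @property
    def spacer_offsets(self) -> tuple[int, ...]:
        phis = set(self.phi_offsets)
        return tuple(o for o in range(self.length) if o not in phis)


@dataclass
class ConsensusMatch:
    """One consensus hit on a sequence (coordinates 1-based inclusive).

    ``phi_positions`` holds Φ1..Φ4 in registry order; for reverse classes
    they are therefore descending in original sequence coordinates.
    """

    protein_id: str
    class_id: str
    direction: str
    phi_positions: tuple[int, int, int, int]
    ta_used: bool
    phi0: Optional[int] = None
    phi0_hydrophobic: bool = False
    seg_start: int = 0
    seg_end: int = 0
    priority: Optional[int] = None

    @property
    def registry(self) -> tuple[int, ...]:
        """Φ registry incl. Φ0 when hydrophobic, ascending in sequence."""
        pos = list(self.phi_positions)
        if self.phi0 is not None and self.phi0_hydrophobic:
            pos.append(self.phi0)
        return tuple(sorted(pos))

    def window_sequence(self, sequence: str) -> str:
        return sequence[self.seg_start - 1: self.seg_end]


@dataclass(frozen=True)
class CandidateLabel:
    """Candidate-vs-false-positive call for one match."""

    label: str                            # "cand" | "fp"
    matched_evidence: tuple[EvidenceAnnotation, ...]


# ---------------------------------------------------------------------------
# pattern compilation
# ---------------------------------------------------------------------------

_FORWARD_TEMPLATES: dict[str, tuple[tuple[int, int, int, int], tuple[int, ...]]] = {
    # class -> (phi offsets, [^PW]-restricted spacer offsets)
    "1a": ((0, 4, 7, 9), (5, 6, 8)),
    "1b": ((0, 3, 6, 8), (4, 5, 7)),
    "2": ((0, 2, 5, 7), (3, 4, 6)),
    "1c": ((0, 4, 8, 10), (5, 6, 7, 9)),
    "1d": ((0, 3, 7, 9), (4, 5, 6, 8)),
    "3": ((0, 3, 7, 10), (5, 6, 8, 9)),
    "4": ((0, 4, 7, 11), (5, 6)),
}

_TA_CLASSES = frozenset({"1a", "1b", "1c", "1d", "2", "3"})


def compile_patterns(classes: Sequence[str] = CLASS_ORDER) -> list[NESClassSpec]:
    """Compile the consensus class set into :class:`NESClassSpec` objects."""
    specs = []
    for cid in classes:
        if cid.endswith("-R"):
            base = cid[:-2]
            if base not in _FORWARD_TEMPLATES:
                raise PatternError(f"unknown NES class {cid!r}")
            phi, nopw = _FORWARD_TEMPLATES[base]
            specs.append(NESClassSpec(
                class_id=cid, direction="reverse", phi_offsets=phi,
                nopw_offsets=frozenset(nopw), ta_allowance=False,
                reverse_bulky_rule=True,
            ))
        elif cid in _FORWARD_TEMPLATES:
            phi, nopw = _FORWARD_TEMPLATES[cid]
            specs.append(NESClassSpec(
                class_id=cid, direction="forward", phi_offsets=phi,
                nopw_offsets=frozenset(nopw), ta_allowance=cid in _TA_CLASSES,
                pro_requirement=(8, 10) if cid == "4" else None,
            ))
        else:
            raise PatternError(f"unknown NES class {cid!r}")
    return specs


# ---------------------------------------------------------------------------
# scanning
# ---------------------------------------------------------------------------

def _placement_ok(window: str, spec: NESClassSpec) -> Optional[bool]:
    """Check one anchored placement; returns ta_used or None if invalid."""
    phis = [window[o] for o in spec.phi_offsets]
    ta_used = False
    for k, aa in enumerate(phis):
        if aa in PHI_RESIDUES:
            continue
        if spec.ta_allowance and k in (0, 1) and aa in TA_RESIDUES and not ta_used:
            ta_used = True
            continue
        return None
    for o in spec.spacer_offsets:
        if o in spec.nopw_offsets and window[o] in NOPW_FORBIDDEN:
            return None
    if spec.pro_requirement is not None:
        lo, hi = spec.pro_requirement
        if "P" not in window[lo: hi + 1]:
            return None
    return ta_used


def _scan_oriented(sequence: str, spec: NESClassSpec, protein_id: str) -> list[ConsensusMatch]:
    """Scan ``sequence`` (already oriented) with one forward template."""
    out = []
    L = len(sequence)
    for start in range(L - spec.length + 1):
        window = sequence[start: start + spec.length]
        ta = _placement_ok(window, spec)
        if ta is None:
            continue
        positions = tuple(start + o + 1 for o in spec.phi_offsets)
        if spec.reverse_bulky_rule:
            # residues bound in the P0/P1 register: mirrored-frame Φ3/Φ4
            if not ({sequence[positions[2] - 1], sequence[positions[3] - 1]}
                    & REVERSE_BULKY):
                continue
        out.append(ConsensusMatch(
            protein_id=protein_id, class_id=spec.class_id,
            direction=spec.direction, phi_positions=positions, ta_used=ta,
        ))
    return out


def _mirror(match: ConsensusMatch, length: int) -> ConsensusMatch:
    """Map a match found on the reversed sequence back to original coords."""
    flip = lambda p: length - p + 1
    match.phi_positions = tuple(flip(p) for p in match.phi_positions)
    if match.phi0 is not None:
        match.phi0 = flip(match.phi0)
    if match.seg_start:
        match.seg_start, match.seg_end = flip(match.seg_end), flip(match.seg_start)
    return match


def scan(
    sequence: str,
    specs: Optional[Sequence[NESClassSpec]] = None,
    protein_id: str = "query",
) -> list[ConsensusMatch]:
    """Return every anchored placement of every class that satisfies all
    slot constraints, including overlapping hits and multiple classes at the
    same location. Unknown residues ('X') never satisfy a Φ or [^PW] slot.
    """
    if specs is None:
        specs = compile_patterns()
    sequence = sequence.upper()
    matches: list[ConsensusMatch] = []
    rev = sequence[::-1]
    for spec in specs:
        if spec.direction == "forward":
            matches.extend(_scan_oriented(sequence, spec, protein_id))
        else:
            for m in _scan_oriented(rev, spec, protein_id):
                matches.append(_mirror(m, len(sequence)))
    matches.sort(key=_match_sort_key)
    return matches


def _match_sort_key(m: ConsensusMatch):
    return (min(m.phi_positions), m.class_id, m.phi_positions)


# ---------------------------------------------------------------------------
# Φ0 detection, priority, windows
# ---------------------------------------------------------------------------

def detect_phi0(
    match: ConsensusMatch, sequence: str, offset: int = DEFAULT_PHI0_OFFSET
) -> ConsensusMatch:
    """Assign the Φ0 position at ``offset`` residues upstream of Φ1.

    Upstream is in the match's own reading direction, so for reverse-class
    matches Φ0 lies C-terminal of Φ1 in original coordinates. Classes with
    no Φ0 in the consensus (class 3) are left unassigned. ``phi0`` is
    assigned whenever the position exists; ``phi0_hydrophobic`` records
    whether that residue is one of {L,I,V,M,F}.
    """
    if match.class_id not in PHI0_CLASSES:
        return match
    phi1 = match.phi_positions[0]
    pos = phi1 - offset if match.direction == "forward" else phi1 + offset
    if not (1 <= pos <= len(sequence)):
        return match
    match.phi0 = pos
    match.phi0_hydrophobic = sequence[pos - 1] in PHI_RESIDUES
    return match


def assign_priority(match: ConsensusMatch) -> int:
    """Empirical class priority, 1 (best) .. 5.

    1: class 1a with five Φ (hydrophobic Φ0), no Thr/Ala;
    2: class 1a with four Φ, plain 1c, 1a-R, and plain 2/3/4;
    3: classes 1a/1c with Thr/Ala at Φ1 or Φ2;
    4: plain 1b/1d, 1c-R, and classes 2/3 with Thr/Ala;
    5: classes 1b/1d with Thr/Ala.
    """
    cid, ta = match.class_id, match.ta_used
    if cid == "1a" and not ta:
        p = 1 if match.phi0_hydrophobic else 2
    elif cid in ("1c", "2", "3", "4", "1a-R") and not ta:
        p = 2
    elif cid in ("1a", "1c") and ta:
        p = 3
    elif cid == "1c-R" or (cid in ("2", "3") and ta):
        p = 4
    elif cid in ("1b", "1d"):
        p = 5 if ta else 4
    else:
        raise PatternError(f"unclassifiable match: class {cid}, ta_used={ta}")
    match.priority = p
    return p


def extract_window(
    match: ConsensusMatch, sequence: str, max_window: int = MAX_WINDOW
) -> ConsensusMatch:
    """Set the extraction window: one residue before Φ0 through two residues
    after Φ4, clamped at the sequence termini (mirrored for reverse classes).
    """
    L = len(sequence)
    phi1, phi4 = match.phi_positions[0], match.phi_positions[3]
    if match.direction == "forward":
        lo = match.phi0 - 1 if match.phi0 is not None else phi1 - 4
        hi = phi4 + 2
    else:
        hi = match.phi0 + 1 if match.phi0 is not None else phi1 + 4
        lo = phi4 - 2
    match.seg_start = max(1, lo)
    match.seg_end = min(L, hi)
    if match.seg_end - match.seg_start + 1 > max_window:
        raise PatternError("extraction window exceeds the maximum NES length")
    return match


def scan_sequence(
    sequence: str,
    specs: Optional[Sequence[NESClassSpec]] = None,
    protein_id: str = "query",
    phi0_offset: int = DEFAULT_PHI0_OFFSET,
) -> list[ConsensusMatch]:
    """Full per-sequence scan: match, Φ0, priority and extraction window."""
    matches = scan(sequence, specs, protein_id)
    for m in matches:
        detect_phi0(m, sequence, phi0_offset)
        assign_priority(m)
        extract_window(m, sequence)
    matches.sort(key=lambda m: (m.seg_start, m.priority, m.class_id, m.phi_positions))
    return matches


# ---------------------------------------------------------------------------
# grouping and candidate labeling
# ---------------------------------------------------------------------------

def group_overlaps(matches: Sequence[ConsensusMatch], delta: int = 5) -> list[list[ConsensusMatch]]:
    """Group matches whose seg_start values chain within ``delta``.

    Transitive: groups are the connected components of the graph joining
    matches with start difference < delta. Within a group matches are
    ordered by priority, then seg_start, then class id.
    """
    ordered = sorted(matches, key=lambda m: m.seg_start)
    groups: list[list[ConsensusMatch]] = []
    for m in ordered:
        if groups and m.seg_start - groups[-1][-1].seg_start < delta:
            groups[-1].append(m)
        else:
            groups.append([m])
    for g in groups:
        g.sort(key=lambda m: (m.priority if m.priority is not None else 9,
                              m.seg_start, m.class_id))
    return groups


def label_candidate(
    match: ConsensusMatch, evidence: Sequence[EvidenceAnnotation]
) -> CandidateLabel:
    """Label a match ``cand`` iff its Φ2–Φ4 span overlaps any evidence
    interval, else ``fp``."""
    lo = min(match.phi_positions[1], match.phi_positions[3])
    hi = max(match.phi_positions[1], match.phi_positions[3])
    hits = tuple(e for e in evidence if e.start <= hi and lo <= e.end)
    return CandidateLabel("cand" if hits else "fp", hits)
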