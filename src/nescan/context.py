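"""Structural-context annotation of consensus matches.

Each match is placed in the context of the whole protein: intrinsic
disorder (is the segment inside, at the edge of, or outside a highly
ordered region?), conserved domains, and predicted secondary structure
(β-strand content of the segment middle). These are the pre-filters that
separate plausible, CRM1-accessible NES segments from consensus hits
buried in globular folds.

A residue is called ordered ('O') only when *both* primary disorder
predictors (DISOPRED-style and SPOT-Disorder-style tracks) report a
propensity strictly below the cutoff (default 0.1, far stricter than the
predictors' own ~0.5 disorder thresholds); IUPred values are carried for
reporting only. Segment location then uses a 90% majority over the
segment plus 20-residue flanks.

Note on label orientation: the rule is stated here in its self-consistent
form — a window that is >90% disordered residues is located in a
disordered region (DISO), >90% ordered is ORD — matching how the labels
are used everywhere downstream (highlighting, location statistics).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .consensus import ConsensusMatch
from .io_formats import DisorderTrack, DomainAnnotation, SSTrack

DISORDER_CUTOFF = 0.1
LOCATION_FLANK = 20
LOCATION_FRACTION = 0.9
BETA_CUTOFF = 0.5
DOMAIN_EDGE_MARGIN = 5
SMALL_DOMAIN_LENGTH = 50


@dataclass(frozen=True)
class OrderLabeling:
    """Per-residue O/D labels, 1-based, aligned to the sequence."""

    labels: str

    def __post_init__(self) -> None:
        bad = set(self.labels) - set("OD")
        if bad:
            raise ValueError(f"labels must be 'O'/'D', got {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.labels)


@dataclass
class ContextAnnotation:
    """Disorder/domain/β context of one segment, plus display flags."""

    loc_diso: str                  # DISO | boundary | ORD
    loc_cdd: str                   # MID | boundary | small | NA
    beta: Optional[float]          # fraction in [0,1], None if no SS track
    diso_avg: float
    spotd_avg: float
    iup_avg: Optional[float]
    flags: frozenset[str]          # subset of {"_D", "_O", "_beta"}
    highlighted: bool


def order_labels(
    disopred: DisorderTrack,
    spotd: DisorderTrack,
    cutoff: float = DISORDER_CUTOFF,
) -> OrderLabeling:
    """Label each residue 'O' iff both predictors are strictly below
    ``cutoff``, else 'D'."""
    if len(disopred) != len(spotd):
        raise ValueError(
            f"track length mismatch: disopred {len(disopred)} vs spotd {len(spotd)}"
        )
    labels = "".join(
        "O" if (d < cutoff and s < cutoff) else "D"
        for d, s in zip(disopred.values, spotd.values)
    )
    return OrderLabeling(labels)


def segment_location(
    labeling: OrderLabeling,
    seg_start: int,
    seg_end: int,
    flank: int = LOCATION_FLANK,
    frac: float = LOCATION_FRACTION,
) -> str:
    """Classify a segment's disorder location over segment + flanks.

    Over the window [seg_start − flank, seg_end + flank] (truncated at the
    termini; only existing residues enter the denominator): DISO if the
    D-fraction exceeds ``frac``, ORD if the O-fraction does, else boundary.
    """
    L = len(labeling)
    if not (1 <= seg_start <= seg_end <= L):
        raise ValueError(f"segment {seg_start}-{seg_end} outside sequence of length {L}")
    lo = max(1, seg_start - flank)
    hi = min(L, seg_end + flank)
    window = labeling.labels[lo - 1: hi]
    d_frac = window.count("D") / len(window)
    if d_frac > frac:
        return "DISO"
    if 1.0 - d_frac > frac:
        return "ORD"
    return "boundary"


def domain_location(
    domains: Sequence[DomainAnnotation],
    seg_start: int,
    seg_end: int,
    edge: int = DOMAIN_EDGE_MARGIN,
    small_len: int = SMALL_DOMAIN_LENGTH,
) -> str:
    """Classify a segment against conserved-domain intervals.

    NA when no domain overlaps. Otherwise the longest overlapping domain
    governs: ``small`` if that domain is shorter than ``small_len``;
    ``MID`` if the segment lies entirely inside it with more than ``edge``
    residues to both domain ends; else ``boundary``.
    """
    overlapping = [d for d in domains if d.start <= seg_end and seg_start <= d.end]
    if not overlapping:
        return "NA"
    dom = max(overlapping, key=lambda d: (d.length, -d.start))
    if dom.length < small_len:
        return "small"
    inside = dom.start <= seg_start and seg_end <= dom.end
    if inside and (seg_start - dom.start) > edge and (dom.end - seg_end) > edge:
        return "MID"
    return "boundary"


def beta_content(ss: SSTrack, match: ConsensusMatch) -> float:
    """Fraction of predicted β-strand (E) over the middle of the match,
    defined as the closed span from Φ1 to Φ4."""
    lo = min(match.phi_positions[0], match.phi_positions[3])
    hi = max(match.phi_positions[0], match.phi_positions[3])
    states = ss.states[lo - 1: hi]
    return states.count("E") / len(states)


def annotate(
    match: ConsensusMatch,
    labeling: OrderLabeling,
    domains: Sequence[DomainAnnotation],
    ss: Optional[SSTrack],
    disopred: DisorderTrack,
    spotd: DisorderTrack,
    iupred: Optional[DisorderTrack] = None,
    flank: int = LOCATION_FLANK,
    frac: float = LOCATION_FRACTION,
    beta_cutoff: float = BETA_CUTOFF,
) -> ContextAnnotation:
    """Full context annotation and highlight call for one match.

    Flags: ``_D`` when the segment is in a disordered or boundary region,
    ``_O`` when in the ordered region, ``_beta`` when the β content of the
    middle exceeds ``beta_cutoff``. A segment is highlighted (structurally
    plausible NES context) iff it is not in the ordered region and its β
    content does not exceed the cutoff. A missing SS track is treated as
    passing the β criterion (conservative inclusion).
    """
    loc = segment_location(labeling, match.seg_start, match.seg_end, flank, frac)
    loc_cdd = domain_location(domains, match.seg_start, match.seg_end)
    beta = beta_content(ss, match) if ss is not None else None

    flags = set()
    flags.add("_O" if loc == "ORD" else "_D")
    if beta is not None and beta > beta_cutoff:
        flags.add("_beta")
    highlighted = (loc != "ORD") and (beta is None or beta <= beta_cutoff)

    sl = slice(match.seg_start - 1, match.seg_end)
    return ContextAnnotation(
        loc_diso=loc,
        loc_cdd=loc_cdd,
        beta=beta,
        diso_avg=float(np.mean(disopred.values[sl])),
        spotd_avg=float(np.mean(spotd.values[sl])),
        iup_avg=float(np.mean(iupred.values[sl])) if iupred is not None else None,
        flags=frozenset(flags),
        highlighted=highlighted,
    )
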