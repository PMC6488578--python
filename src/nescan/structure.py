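"""Template-based scoring of NES peptides in the CRM1 groove.

The protocol mirrors template-based peptide threading: a consensus match
supplies the Φ registry; the peptide window (Φ0−1 … Φ4+2, clipped at the
protein termini) is placed residue-by-residue onto the backbone anchors of
each class template; conformations are sampled around the threaded pose
(Metropolis chains with local backbone/side-chain moves, then constrained
greedy relaxation of the lowest-energy parents); and the relative binding
energy is

    E_bind = E_complex − E_protein − E_peptide,

each term the mean of the lowest-``k`` ensemble energies, with E_peptide
the minimum free-peptide energy over all template fits. The template with
the lowest E_bind is selected; the whole calculation is replicated over
independent runs and the run mean/sd reported. An interface-accessibility
term penalises cavities at the groove interface:

    E_bind^RSA = <E_bind> + w · RSA        (default w = 0.35).

Energies are in arbitrary backend units. The shipped backend is a
coarse-grained surrogate (pocket burial, soft clash, hydrophobic exposure,
anchor strain); any object satisfying :class:`EnergyBackend` can replace
it. The synthetic template library builds an idealized groove — five
pocket centroids along the groove axis inside a shelled channel — with
per-class peptide backbones whose registry spacings match the class spacer
templates, so the full protocol runs with no structure downloads.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Protocol, Sequence

import numpy as np
from scipy.spatial.distance import cdist
from scipy import stats

from .consensus import ConsensusMatch
from .io_formats import StructureCoordinates, read_structure, FormatError
from . import sasa

# ---------------------------------------------------------------------------
# residue parameters (coarse side-chain model)
# ---------------------------------------------------------------------------

#: Kyte–Doolittle hydropathy; the pocket/exposure terms are monotone in it.
HYDROPHOBICITY = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5, "X": 0.0,
}

#: side-chain sphere radius (Å) for clash/accessibility
SIDECHAIN_RADIUS = {
    "G": 1.0, "A": 1.5, "S": 1.6, "C": 1.8, "T": 1.8, "P": 1.9, "D": 1.9,
    "N": 2.0, "V": 2.1, "E": 2.2, "Q": 2.2, "H": 2.3, "I": 2.35, "L": 2.35,
    "K": 2.4, "M": 2.45, "F": 2.55, "R": 2.6, "Y": 2.65, "W": 2.8, "X": 2.0,
}

#: CA → side-chain-centroid placement distance (Å)
SIDECHAIN_REACH = {
    "G": 0.0, "A": 1.5, "S": 1.7, "C": 1.9, "T": 1.9, "P": 1.9, "D": 2.2,
    "N": 2.2, "V": 2.0, "E": 2.6, "Q": 2.6, "H": 2.7, "I": 2.3, "L": 2.6,
    "K": 3.0, "M": 2.9, "F": 3.4, "R": 3.4, "Y": 3.5, "W": 3.6, "X": 2.2,
}

CA_RADIUS = 1.9

# registry frame: slot offsets are counted from Φ1 in the reading direction
N_FLANK = 4   # slots −4 … −1 before Φ1 (Φ0 at −3)
C_FLANK = 2   # slots after Φ4

REQUIRED_TEMPLATE_CLASSES = ("1a", "1b", "1c", "2", "4", "1a-R")

#: pocket x-coordinates along the groove axis: P0, P1, P2, P3, P4.
#: Spacings follow one-turn-helix rise (1.5 Å/residue) for the class-1a
#: registry: Φ0→Φ1 = 3 steps, Φ1→Φ2 = 4, Φ2→Φ3 = 3, Φ3→Φ4 = 2.
_POCKET_X = np.array([0.0, 4.5, 10.5, 15.0, 18.0])
_POCKET_Z = -2.5
_PHI1_X = 4.5
_FLANK_STEP = 1.5

from .consensus import _FORWARD_TEMPLATES  # class Φ offsets


class EnergyBackend(Protocol):
    """Contract for energy backends: a pure function of coordinates."""

    name: str
    deterministic: bool

    def evaluate(self, model: "ComplexModel") -> float: ...


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class TemplateEntry:
    """One CRM1–NES class template in the registry frame."""

    class_id: str
    provenance: str                      # PDB id or "synthetic…"
    direction: str                       # forward | reverse
    slot_offsets: tuple[int, ...]        # covered registry slots, ascending
    anchor_ca: np.ndarray                # (n_slots, 3) backbone CA anchors
    phi_slots: dict[int, int]            # slot offset -> pocket index 0–4
    pockets: np.ndarray                  # (5, 3) pocket centroids
    groove: StructureCoordinates
    groove_radii: np.ndarray             # per groove residue
    peptide_backbone: StructureCoordinates

    @property
    def template_id(self) -> str:
        return f"{self.class_id}:{self.provenance}"

    @property
    def registry(self) -> dict[int, int]:
        """Slot offset -> row index into the anchor/backbone arrays."""
        return {o: i for i, o in enumerate(self.slot_offsets)}


@dataclass
class ComplexModel:
    """A (possibly groove-free) peptide pose with its template context."""

    template_id: str
    template: TemplateEntry
    aa: str                              # peptide residues, registry order
    slots: tuple[int, ...]               # registry slot per residue
    phi_mask: np.ndarray                 # query Φ residues (bool per residue)
    ca: np.ndarray                       # (n, 3)
    centroid: np.ndarray                 # (n, 3)
    anchor_ca: np.ndarray                # threading anchors, fixed reference
    has_groove: bool = True
    energy: Optional[float] = None
    seed: Optional[int] = None

    def copy(self) -> "ComplexModel":
        return replace(self, ca=self.ca.copy(), centroid=self.centroid.copy())


@dataclass
class BindingResult:
    """E_bind summary for one peptide over a template library."""

    per_template: dict[str, float]
    best_template: str
    best_class: str
    e_bind: float                        # min over per-template means
    e_bind_runs: list[float]             # per-run best E_bind
    e_bind_mean: float
    e_bind_sd: float
    rsa: float
    e_bind_rsa: float
    weight_w: float
    best_model: Optional[ComplexModel] = None


@dataclass
class SamplingConfig:
    """Knobs of the sampling protocol (counts, temperature, move sizes)."""

    n_models: int = 50          # Metropolis chains per template fit
    n_trials: int = 2000        # moves per chain
    n_parents: int = 5          # lowest-energy models selected for relaxation
    n_relax: int = 50           # relax runs per parent
    relax_steps: int = 25       # greedy steps per relax run
    k_lowest: int = 10          # ensemble energies averaged
    n_runs: int = 5             # independent replicate runs
    temperature: float = 1.0
    move_sigma_ca: float = 0.15
    move_sigma_centroid: float = 0.25
    relax_sigma: float = 0.08
    constraint_radius: float = 1.0
    rsa_weight: float = 0.35

    @classmethod
    def fast(cls) -> "SamplingConfig":
        """Desk-scale protocol: same shape, reduced counts."""
        return cls(n_models=6, n_trials=40, n_parents=3, n_relax=4,
                   relax_steps=15, k_lowest=10, n_runs=3)

    @classmethod
    def minimal(cls) -> "SamplingConfig":
        """Near-deterministic: threaded pose plus a short polish."""
        return cls(n_models=2, n_trials=10, n_parents=2, n_relax=1,
                   relax_steps=8, k_lowest=4, n_runs=1)

    @classmethod
    def deterministic(cls) -> "SamplingConfig":
        """No stochastic sampling at all: energies at the threaded pose."""
        return cls(n_models=1, n_trials=0, n_parents=1, n_relax=1,
                   relax_steps=0, k_lowest=1, n_runs=1)


# ---------------------------------------------------------------------------
# synthetic template library
# ---------------------------------------------------------------------------

#: per-class spacer signature: bulge sign and amplitude (Å) for each of
#: the three inter-Φ gaps. Distinct signatures keep the class backbones
#: geometrically distinguishable (cross-class registry RMSD ≥ 2 Å).
_GAP_SIGNATURE = {
    "1a": ((-1, 1, 1), (2.5, 2.5, 1.4)),
    "1b": ((1, -1, 1), (2.5, 1.4, 2.5)),
    "1c": ((1, -1, 1), (2.5, 1.4, 1.4)),
    "1d": ((-1, -1, 1), (2.5, 2.5, 2.5)),
    "2": ((-1, 1, 1), (2.5, 2.5, 2.5)),
    "3": ((1, 1, -1), (2.5, 2.5, 1.4)),
    "4": ((1, 1, 1), (2.5, 2.5, 2.5)),
    "1a-R": ((-1, -1, -1), (2.5, 1.4, 1.4)),
    "1c-R": ((1, 1, -1), (2.5, 1.4, 2.5)),
}

_SYNTHETIC_LIBRARY = (
    # (class_id, provenance, direction, bulge scale)
    ("1a", "6CIT", "forward", 1.0),
    ("1a", "synthetic-superPKI", "forward", 0.96),
    ("1b", "5UWO", "forward", 1.0),
    ("1c", "3GB8", "forward", 1.0),
    ("2", "5UWJ", "forward", 1.0),
    ("2", "3NBZ", "reverse", 0.96),     # HIV-Rev rev-type class-2 groove
    ("4", "5UWS", "forward", 1.0),
    ("1a-R", "5DIF", "reverse", 1.0),
)


def _pockets() -> np.ndarray:
    return np.column_stack([
        _POCKET_X, np.zeros(5), np.full(5, _POCKET_Z)
    ])


def _class_anchor_geometry(class_id: str, bulge_scale: float) -> tuple[
        tuple[int, ...], np.ndarray, dict[int, int]]:
    """CA anchors for the full registry window of one class.

    Φ slots sit directly above their pockets (z = 0); spacer slots are
    interpolated within each inter-Φ gap with a class-specific transverse
    bulge; flank slots continue along the groove axis at helical rise.
    """
    base = class_id[:-2] if class_id.endswith("-R") else class_id
    phi_off = _FORWARD_TEMPLATES[base][0]
    slots = tuple(range(-N_FLANK, phi_off[3] + C_FLANK + 1))
    signs, amps = _GAP_SIGNATURE[class_id]

    xs = {}
    # Φ anchors over pockets P1..P4; Φ0 slot (−3) over P0
    for k, o in enumerate(phi_off):
        xs[o] = _POCKET_X[k + 1]
    xs[-N_FLANK + 1] = _POCKET_X[0]  # slot −3

    anchors = np.zeros((len(slots), 3))
    reg = {o: i for i, o in enumerate(slots)}

    # flanks: linear continuation at helical rise
    for o in range(-N_FLANK, 0):
        anchors[reg[o], 0] = _PHI1_X + _FLANK_STEP * o
    for o in range(phi_off[3], phi_off[3] + C_FLANK + 1):
        anchors[reg[o], 0] = xs[phi_off[3]] + _FLANK_STEP * (o - phi_off[3])
    # Φ anchors
    for o in phi_off:
        anchors[reg[o], 0] = xs[o]
    # spacers: interpolate x within each gap, bulge sideways per the class
    # signature, with an upward lift on positive-sign gaps (open channel
    # mouth) — this is what separates class backbones geometrically
    for g in range(3):
        o_lo, o_hi = phi_off[g], phi_off[g + 1]
        n_seg = o_hi - o_lo
        amp = amps[g] * bulge_scale
        for j, o in enumerate(range(o_lo + 1, o_hi), start=1):
            t = j / n_seg
            anchors[reg[o], 0] = xs[o_lo] + t * (xs[o_hi] - xs[o_lo])
            anchors[reg[o], 1] = signs[g] * amp * np.sin(np.pi * t)
            if signs[g] > 0:
                anchors[reg[o], 2] = 0.55 * amp * np.sin(np.pi * t)

    phi_slots = {o: k + 1 for k, o in enumerate(phi_off)}
    phi_slots[-3] = 0
    return slots, anchors, phi_slots


def _synthetic_groove() -> tuple[StructureCoordinates, np.ndarray]:
    """Idealized shelled channel around the pocket row.

    Pseudo-residues are single spheres (all backbone fields collapse onto
    the sphere centre); the channel is open above the peptide line so
    spacer side chains stay solvent-exposed while pocket-bound side chains
    are buried.
    """
    pts: list[tuple[np.ndarray, str, float]] = []  # (pos, resname, radius)

    xs_long = np.arange(-9.0, 30.1, 2.5)
    # pocket lining: side spheres flanking each pocket
    for x in _POCKET_X:
        for ysign in (-1.0, 1.0):
            pts.append((np.array([x, 3.3 * ysign, -3.3]), "L", 2.3))
    # pocket-floor reporters: deep enough that a full-size Φ side chain
    # occludes their upper face while a shrunken one leaves it open —
    # this is what makes interface cavities visible to the probe
    for x in _POCKET_X:
        pts.append((np.array([x, 0.0, -8.3]), "L", 2.0))
    for x0, x1 in zip(_POCKET_X[:-1], _POCKET_X[1:]):
        pts.append((np.array([(x0 + x1) / 2.0, 0.0, -8.3]), "L", 2.0))
    # channel walls, three layers each side, with an outer shell and a
    # top rim so only the channel mouth above the peptide stays open
    for x in xs_long:
        for ysign in (-1.0, 1.0):
            pts.append((np.array([x, 5.0 * ysign, -0.8]), "S", 2.6))
            pts.append((np.array([x, 5.0 * ysign, -3.4]), "S", 2.6))
            pts.append((np.array([x, 5.0 * ysign, -6.0]), "S", 2.6))
            pts.append((np.array([x, 7.4 * ysign, -1.5]), "A", 3.2))
            pts.append((np.array([x, 7.4 * ysign, -4.5]), "A", 3.2))
            pts.append((np.array([x, 6.2 * ysign, 1.5]), "S", 2.6))
    # cradle shell burying the reporters from below
    for x in np.arange(-9.0, 30.1, 2.5):
        for y in (-3.0, 0.0, 3.0):
            pts.append((np.array([x, y, -10.8]), "A", 3.0))
    # end caps
    for x in (-11.0, 32.0):
        for y in (-2.5, 0.0, 2.5):
            for z in (-1.0, -4.0, -7.0, -9.5):
                pts.append((np.array([x, y, z]), "S", 2.8))

    pos = np.array([p[0] for p in pts])
    names = np.array([p[1] for p in pts])
    radii = np.array([p[2] for p in pts])
    coords = StructureCoordinates(
        chain=np.array(["G"] * len(pts)),
        resid=np.arange(479, 479 + len(pts)),
        resname=names,
        n=pos.copy(), ca=pos.copy(), c=pos.copy(), o=pos.copy(),
        centroid=pos.copy(),
    )
    return coords, radii


def _backbone_from_anchors(anchors: np.ndarray, slots: tuple[int, ...],
                           phi_slots: dict[int, int],
                           pockets: np.ndarray) -> StructureCoordinates:
    """Synthesize a poly-L peptide StructureCoordinates on the anchors."""
    n = len(anchors)
    cen = anchors.copy()
    for i, o in enumerate(slots):
        if o in phi_slots:
            d = pockets[phi_slots[o]] - anchors[i]
            cen[i] = anchors[i] + SIDECHAIN_REACH["L"] * d / np.linalg.norm(d)
        else:
            cen[i] = anchors[i] + np.array([0.0, 0.0, SIDECHAIN_REACH["L"]])
    return StructureCoordinates(
        chain=np.array(["P"] * n),
        resid=np.arange(1, n + 1),
        resname=np.array(["L"] * n),
        n=anchors + np.array([-0.6, 0.4, 0.0]),
        ca=anchors.copy(),
        c=anchors + np.array([0.6, 0.4, 0.0]),
        o=anchors + np.array([0.6, 1.0, 0.0]),
        centroid=cen,
    )


def build_template_library(
    source: str | Path = "synthetic",
    manifest: Optional[str | Path] = None,
) -> list[TemplateEntry]:
    """Build the class template library.

    ``source="synthetic"`` constructs the idealized groove and one entry
    per library template (classes 1a ×2, 1b, 1c, 2 ×2, 4, 1a-R), enough
    for every class query (class-3 queries reuse the class-1a templates,
    as in the crystal-template set). Otherwise ``source`` is a directory
    of PDB files and ``manifest`` a TSV with columns
    class_id, pdb_file, groove_chain, peptide_chain, phi1_resid, direction.
    """
    if str(source) == "synthetic":
        groove, radii = _synthetic_groove()
        pockets = _pockets()
        out = []
        for cid, prov, direction, scale in _SYNTHETIC_LIBRARY:
            geom_class = cid if cid in _GAP_SIGNATURE else "1a"
            slots, anchors, phi_slots = _class_anchor_geometry(geom_class, scale)
            out.append(TemplateEntry(
                class_id=cid, provenance=prov, direction=direction,
                slot_offsets=slots, anchor_ca=anchors, phi_slots=phi_slots,
                pockets=pockets, groove=groove, groove_radii=radii,
                peptide_backbone=_backbone_from_anchors(
                    anchors, slots, phi_slots, pockets),
            ))
        return out
    return _library_from_manifest(Path(source), Path(manifest))


def _library_from_manifest(directory: Path, manifest: Path) -> list[TemplateEntry]:
    entries = []
    seen_classes = set()
    with open(manifest) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split()
            if len(cols) < 6:
                raise FormatError(f"{manifest}:{lineno}: expected 6 columns")
            cid, pdb_file, g_chain, p_chain, phi1_resid, direction = cols[:6]
            coords = read_structure(directory / pdb_file,
                                    {"groove": g_chain, "peptide": p_chain})
            groove = coords.select_chain(g_chain)
            pep = coords.select_chain(p_chain)
            phi1 = int(phi1_resid)
            base = cid[:-2] if cid.endswith("-R") else cid
            if base not in _FORWARD_TEMPLATES:
                raise FormatError(f"{manifest}:{lineno}: unknown class {cid!r}")
            phi_off = _FORWARD_TEMPLATES[base][0]
            if direction == "forward":
                slot_of = {int(r): int(r) - phi1 for r in pep.resid}
            else:
                slot_of = {int(r): phi1 - int(r) for r in pep.resid}
            order = np.argsort([slot_of[int(r)] for r in pep.resid])
            slots = tuple(sorted(slot_of.values()))
            anchors = pep.ca[order]
            phi_slots = {o: k + 1 for k, o in enumerate(phi_off) if o in slots}
            if -3 in slots:
                phi_slots[-3] = 0
            reg = {o: i for i, o in enumerate(slots)}
            pocket_rows = [reg[o] for o in sorted(phi_slots, key=phi_slots.get)]
            pockets = pep.centroid[order][pocket_rows]
            if len(pockets) < 5:  # pad missing pockets by extrapolation
                pockets = np.vstack([pockets[:1]] * (5 - len(pockets)) + [pockets])
            radii = np.array([
                SIDECHAIN_RADIUS.get(str(r), 2.0) for r in groove.resname
            ])
            entries.append(TemplateEntry(
                class_id=cid, provenance=pdb_file.rsplit(".", 1)[0],
                direction=direction, slot_offsets=slots, anchor_ca=anchors,
                phi_slots=phi_slots, pockets=pockets, groove=groove,
                groove_radii=radii, peptide_backbone=pep,
            ))
            seen_classes.add(cid)
    missing = [c for c in REQUIRED_TEMPLATE_CLASSES if c not in seen_classes]
    if missing:
        raise FormatError(f"template manifest missing classes: {missing}")
    return entries


# ---------------------------------------------------------------------------
# threading
# ---------------------------------------------------------------------------

def _oriented_view(sequence: str, match: ConsensusMatch) -> tuple[str, list[int], np.ndarray]:
    """Window residues in the match's reading direction with registry slots.

    Returns (residues, slots, phi positions bool mask), where slots are
    offsets from Φ1 in the reading direction.
    """
    phi1 = match.phi_positions[0]
    positions = list(range(match.seg_start, match.seg_end + 1))
    if match.direction == "reverse":
        positions.reverse()
        slots = [phi1 - p for p in positions]
    else:
        slots = [p - phi1 for p in positions]
    residues = "".join(sequence[p - 1] for p in positions)
    phi_set = set(match.phi_positions)
    if match.phi0 is not None and match.phi0_hydrophobic:
        phi_set.add(match.phi0)
    mask = np.array([p in phi_set for p in positions])
    return residues, slots, mask


def _anchor_for_slot(template: TemplateEntry, slot: int) -> np.ndarray:
    reg = template.registry
    if slot in reg:
        return template.anchor_ca[reg[slot]]
    lo, hi = template.slot_offsets[0], template.slot_offsets[-1]
    if slot < lo:
        step = template.anchor_ca[reg[lo]] - template.anchor_ca[reg[lo + 1]]
        return template.anchor_ca[reg[lo]] + (lo - slot) * step
    step = template.anchor_ca[reg[hi]] - template.anchor_ca[reg[hi - 1]]
    return template.anchor_ca[reg[hi]] + (slot - hi) * step


def thread_peptide(
    sequence: str, match: ConsensusMatch, template: TemplateEntry
) -> ComplexModel:
    """Place the match window on a template's backbone anchors.

    ``sequence`` is the sequence the match coordinates index into (a full
    protein or a peptide with a locally-indexed match). Residues are mapped
    registry-slot to registry-slot; slots outside the template's registry
    are extrapolated along the terminal anchor direction. When the match
    and template read in opposite directions the window is threaded in the
    template's frame (mirrored slots), so e.g. a forward match fitted on a
    reverse template places its Φ residues off the pockets.
    """
    residues, slots, mask = _oriented_view(sequence, match)
    if template.direction != match.direction:
        phi4_slot = max(
            abs(p - match.phi_positions[0]) for p in match.phi_positions
        )
        slots = [phi4_slot - s for s in slots]
        residues = residues[::-1]
        slots.reverse()
        mask = mask[::-1]

    ca = np.array([_anchor_for_slot(template, s) for s in slots])
    centroid = np.empty_like(ca)
    for i, (aa, s) in enumerate(zip(residues, slots)):
        reach = SIDECHAIN_REACH.get(aa, 2.2)
        if s in template.phi_slots:
            d = template.pockets[template.phi_slots[s]] - ca[i]
            nrm = np.linalg.norm(d)
            centroid[i] = ca[i] + (reach * d / nrm if nrm > 1e-9 else 0.0)
        else:
            centroid[i] = ca[i] + np.array([0.0, 0.0, reach])
    return ComplexModel(
        template_id=template.template_id, template=template, aa=residues,
        slots=tuple(slots), phi_mask=mask, ca=ca, centroid=centroid,
        anchor_ca=ca.copy(), has_groove=True,
    )


def strip_groove(model: ComplexModel) -> ComplexModel:
    free = model.copy()
    free.has_groove = False
    return free


# ---------------------------------------------------------------------------
# surrogate energy backend
# ---------------------------------------------------------------------------

class SurrogateEnergy:
    """Coarse-grained stand-in energy for the threading protocol.

    Terms (all in arbitrary units, lower = more stable):

    * pocket:   −w_p · h(aa) · exp(−d(centroid, nearest pocket)²/2σ²)
                summed over peptide residues (h = hydropathy), groove
                models only — rewards burying hydrophobic side chains;
    * exposure: +w_e · max(h, 0) · (1 − pocket proximity) — penalises
                hydrophobic residues out of any pocket (full penalty in
                the free peptide);
    * clash:    +w_c · (d₀ − d)² for peptide/groove sphere pairs below the
                hard-core distance d₀;
    * strain:   +w_s · ‖CA − anchor‖² against the threading anchors, plus
                a side-chain tether +w_t · (|CA−centroid| − reach)².
    """

    name = "coarse-groove-surrogate"
    deterministic = True

    def __init__(self, w_pocket: float = 1.0, sigma: float = 1.5,
                 w_exposure: float = 0.3, w_clash: float = 2.0,
                 clash_core: float = 2.5, w_strain: float = 0.8,
                 w_tether: float = 1.0):
        self.w_pocket = w_pocket
        self.sigma = sigma
        self.w_exposure = w_exposure
        self.w_clash = w_clash
        self.clash_core = clash_core
        self.w_strain = w_strain
        self.w_tether = w_tether

    def evaluate(self, model: ComplexModel) -> float:
        if len(model.aa) == 0:
            return 0.0
        h = np.array([HYDROPHOBICITY.get(aa, 0.0) for aa in model.aa])
        reach = np.array([SIDECHAIN_REACH.get(aa, 2.2) for aa in model.aa])

        e = self.w_strain * float(np.sum((model.ca - model.anchor_ca) ** 2))
        d_side = np.linalg.norm(model.ca - model.centroid, axis=1)
        e += self.w_tether * float(np.sum((d_side - reach) ** 2))

        if model.has_groove:
            t = model.template
            d_pock = cdist(model.centroid, t.pockets).min(axis=1)
            g = np.exp(-(d_pock ** 2) / (2.0 * self.sigma ** 2))
            # pockets reward hydrophobic burial; polar occupants are merely
            # unrewarded (the cavity they leave is charged to the RSA term)
            h_pos = np.maximum(h, 0.0)
            e -= self.w_pocket * float(np.sum(h_pos * g))
            e += self.w_exposure * float(np.sum(h_pos * (1.0 - g)))

            pep_centers = np.vstack([model.ca, model.centroid])
            pep_radii = np.concatenate([
                np.full(len(model.aa), CA_RADIUS),
                np.array([SIDECHAIN_RADIUS.get(aa, 2.0) for aa in model.aa]),
            ])
            d = cdist(pep_centers, t.groove.centroid)
            viol = np.maximum(0.0, self.clash_core - d)
            e += self.w_clash * float(np.sum(viol ** 2))
            del pep_radii  # radii enter accessibility, not the hard core
        else:
            e += self.w_exposure * float(np.sum(np.maximum(h, 0.0)))
        return e


class ScaledBackend:
    """Wrap a backend, scaling its energies by a positive constant."""

    def __init__(self, inner: EnergyBackend, scale: float):
        self.inner = inner
        self.scale = scale
        self.name = f"{inner.name}×{scale}"
        self.deterministic = inner.deterministic

    def evaluate(self, model: ComplexModel) -> float:
        return self.scale * self.inner.evaluate(model)


# ---------------------------------------------------------------------------
# sampling protocol
# ---------------------------------------------------------------------------

def sample_models(
    model: ComplexModel,
    backend: EnergyBackend,
    n_models: int,
    n_trials: int,
    seed: int,
    temperature: float = 1.0,
    move_sigma_ca: float = 0.15,
    move_sigma_centroid: float = 0.25,
) -> list[ComplexModel]:
    """Independent Metropolis chains of local moves from the threaded pose.

    Each chain perturbs one residue per trial (CA displacement plus
    side-chain centroid jitter) and accepts by the Metropolis criterion at
    fixed temperature. Deterministic given the seed; non-finite proposal
    energies are rejected.
    """
    if n_models < 1:
        raise ValueError("n_models must be ≥ 1")
    out = []
    root = np.random.SeedSequence(seed)
    for chain_idx, ss in enumerate(root.spawn(n_models)):
        rng = np.random.default_rng(ss)
        state = model.copy()
        energy = backend.evaluate(state)
        n_res = len(state.aa)
        for _ in range(n_trials):
            r = int(rng.integers(n_res))
            d_ca = rng.normal(0.0, move_sigma_ca, 3)
            d_cen = rng.normal(0.0, move_sigma_centroid, 3)
            u = rng.random()
            old_ca, old_cen = state.ca[r].copy(), state.centroid[r].copy()
            state.ca[r] += d_ca
            state.centroid[r] += d_ca + d_cen
            e_new = backend.evaluate(state)
            if not np.isfinite(e_new) or u >= np.exp(
                min(0.0, -(e_new - energy) / temperature)
            ):
                state.ca[r], state.centroid[r] = old_ca, old_cen
            else:
                energy = e_new
        state.energy = energy
        state.seed = seed + chain_idx
        out.append(state)
    return out


def refine_models(
    models: Sequence[ComplexModel],
    backend: EnergyBackend,
    n_relax: int,
    seed: int,
    n_parents: int = 5,
    relax_steps: int = 25,
    relax_sigma: float = 0.08,
    constraint_radius: float = 1.0,
) -> list[ComplexModel]:
    """Constrained greedy relaxation of the lowest-energy parents.

    The ``n_parents`` best models each seed ``n_relax`` independent descent
    runs; moves are accepted only when they lower the energy and keep every
    CA within ``constraint_radius`` of the parent pose. Children therefore
    never have higher energy than their parent.
    """
    if not models:
        raise ValueError("refine_models needs at least one model")
    parents = sorted(models, key=lambda m: m.energy)[:n_parents]
    root = np.random.SeedSequence(seed)
    children = []
    streams = iter(root.spawn(len(parents) * n_relax))
    for parent in parents:
        for _ in range(n_relax):
            rng = np.random.default_rng(next(streams))
            child = parent.copy()
            energy = parent.energy
            start_ca = parent.ca
            n_res = len(child.aa)
            for _ in range(relax_steps):
                r = int(rng.integers(n_res))
                d_ca = rng.normal(0.0, relax_sigma, 3)
                d_cen = rng.normal(0.0, relax_sigma * 1.5, 3)
                old_ca, old_cen = child.ca[r].copy(), child.centroid[r].copy()
                child.ca[r] += d_ca
                child.centroid[r] += d_ca + d_cen
                e_new = backend.evaluate(child)
                within = np.linalg.norm(child.ca[r] - start_ca[r]) <= constraint_radius
                if np.isfinite(e_new) and e_new < energy and within:
                    energy = e_new
                else:
                    child.ca[r], child.centroid[r] = old_ca, old_cen
            child.energy = energy
            children.append(child)
    return children


def aggregate_energy(energies: Sequence[float] | Sequence[ComplexModel],
                     k: int = 10) -> float:
    """Mean of the ``k`` lowest energies (all of them, with a warning, if
    fewer are supplied)."""
    vals = [m.energy if isinstance(m, ComplexModel) else float(m) for m in energies]
    if not vals:
        raise ValueError("no energies to aggregate")
    if len(vals) < k:
        warnings.warn(
            f"aggregate_energy: only {len(vals)} models for k={k}; using all",
            stacklevel=2,
        )
        k = len(vals)
    return float(np.mean(sorted(vals)[:k]))


# ---------------------------------------------------------------------------
# E_bind protocol
# ---------------------------------------------------------------------------

def _fit_ensemble(pose: ComplexModel, backend: EnergyBackend,
                  config: SamplingConfig, seed: int) -> list[ComplexModel]:
    if config.n_trials == 0 and config.n_models == 1 and config.relax_steps == 0:
        pose = pose.copy()
        pose.energy = backend.evaluate(pose)
        return [pose]
    samples = sample_models(
        pose, backend, config.n_models, config.n_trials, seed,
        config.temperature, config.move_sigma_ca, config.move_sigma_centroid,
    )
    children = refine_models(
        samples, backend, config.n_relax, seed + 1, config.n_parents,
        config.relax_steps, config.relax_sigma, config.constraint_radius,
    )
    return samples + children


def e_bind(
    peptide_seq: str,
    match: ConsensusMatch,
    templates: Sequence[TemplateEntry],
    backend: Optional[EnergyBackend] = None,
    config: Optional[SamplingConfig] = None,
    seed: int = 0,
    compute_rsa: bool = True,
) -> BindingResult:
    """Full E_bind protocol for one peptide over a template library.

    Per run and template: sample/refine the complex and the free peptide,
    aggregate the lowest-``k`` energies, subtract the groove-alone energy
    (cached per template) and the minimum free-peptide energy over all
    fits; select the template with the lowest E_bind. Replicated over
    ``config.n_runs`` runs with independent sub-seeds; the reported
    e_bind_mean/sd are over the per-run best values, and the RSA-corrected
    score is e_bind_mean + w · RSA on the best complex model.
    """
    if not templates:
        raise ValueError("template library is empty")
    backend = backend or SurrogateEnergy()
    config = config or SamplingConfig()

    # groove-alone reference energy, once per template
    e_protein: dict[str, float] = {}
    for t in templates:
        groove_only = ComplexModel(
            template_id=t.template_id, template=t, aa="", slots=(),
            phi_mask=np.zeros(0, bool), ca=np.zeros((0, 3)),
            centroid=np.zeros((0, 3)), anchor_ca=np.zeros((0, 3)),
            has_groove=True,
        )
        e_protein[t.template_id] = backend.evaluate(groove_only)

    per_template_runs: dict[str, list[float]] = {t.template_id: [] for t in templates}
    run_best: list[float] = []
    best_model: Optional[ComplexModel] = None

    root = np.random.SeedSequence(seed)
    run_seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in root.spawn(config.n_runs)]
    for run_seed in run_seeds:
        e_pep_fits: dict[str, float] = {}
        e_cpx: dict[str, float] = {}
        run_models: dict[str, ComplexModel] = {}
        for t_idx, t in enumerate(templates):
            pose = thread_peptide(peptide_seq, match, t)
            ens = _fit_ensemble(pose, backend, config, run_seed + 7 * t_idx)
            e_cpx[t.template_id] = aggregate_energy(ens, config.k_lowest)
            run_models[t.template_id] = min(ens, key=lambda m: m.energy)
            free = strip_groove(pose)
            free_ens = _fit_ensemble(free, backend, config, run_seed + 7 * t_idx + 3)
            e_pep_fits[t.template_id] = aggregate_energy(free_ens, config.k_lowest)
        e_peptide = min(e_pep_fits.values())
        run_e = {
            tid: e_cpx[tid] - e_protein[tid] - e_peptide for tid in e_cpx
        }
        for tid, v in run_e.items():
            per_template_runs[tid].append(v)
        best_tid = min(run_e, key=lambda tid: (run_e[tid], tid))
        run_best.append(run_e[best_tid])
        cand = run_models[best_tid]
        if best_model is None or cand.energy < best_model.energy:
            best_model = cand

    per_template = {tid: float(np.mean(v)) for tid, v in per_template_runs.items()}
    best_tid = min(per_template, key=lambda tid: (per_template[tid], tid))
    e_bind_mean = float(np.mean(run_best))
    e_bind_sd = float(np.std(run_best, ddof=1)) if len(run_best) > 1 else 0.0

    rsa = interface_rsa(best_model) if compute_rsa else 0.0
    return BindingResult(
        per_template=per_template,
        best_template=best_tid,
        best_class=best_tid.split(":")[0],
        e_bind=per_template[best_tid],
        e_bind_runs=run_best,
        e_bind_mean=e_bind_mean,
        e_bind_sd=e_bind_sd,
        rsa=rsa,
        e_bind_rsa=e_bind_mean + config.rsa_weight * rsa,
        weight_w=config.rsa_weight,
        best_model=best_model,
    )


# ---------------------------------------------------------------------------
# interface accessibility
# ---------------------------------------------------------------------------

def interface_rsa(
    model: ComplexModel,
    pocket_reach: float = 6.0,
    probe: float = sasa.DEFAULT_PROBE,
    n_points: int = sasa.DEFAULT_N_POINTS,
) -> float:
    """Summed accessible-surface fraction of the interface residues.

    The interface set defaults to the peptide Φ residues plus the groove
    residues within ``pocket_reach`` Å of any pocket centroid. Each residue
    contributes the area-weighted accessible percentage of its spheres
    (peptide: CA + side-chain centroid; groove: its single pseudo-sphere);
    the result is the per-residue percentage summed over the interface,
    ~0 for a snugly packed complex and growing with interface cavities or
    peptide exposure.
    """
    t = model.template
    n_pep = len(model.aa)
    centers = [model.ca, model.centroid]
    radii = [np.full(n_pep, CA_RADIUS),
             np.array([SIDECHAIN_RADIUS.get(aa, 2.0) for aa in model.aa])]
    if model.has_groove:
        centers.append(t.groove.centroid)
        radii.append(t.groove_radii)
    centers = np.vstack([c for c in centers if len(c)])
    radii = np.concatenate(radii)

    phi_rows = np.where(model.phi_mask)[0]
    groove_rows = np.array([], dtype=int)
    if model.has_groove:
        d = cdist(t.groove.centroid, t.pockets).min(axis=1)
        groove_rows = 2 * n_pep + np.where(d <= pocket_reach)[0]
    if len(phi_rows) == 0 and len(groove_rows) == 0:
        raise ValueError("empty interface residue set")

    # sphere indices: peptide CA i, peptide centroid n_pep+i, groove 2n_pep+j
    subset = np.concatenate([phi_rows, n_pep + phi_rows, groove_rows])
    fracs = sasa.accessible_fractions(centers, radii, probe, n_points, subset)
    areas = (radii[subset] + probe) ** 2

    total = 0.0
    for k, i in enumerate(phi_rows):
        a = areas[k], areas[len(phi_rows) + k]
        f = fracs[k], fracs[len(phi_rows) + k]
        total += (f[0] * a[0] + f[1] * a[1]) / (a[0] + a[1])
    total += float(np.sum(fracs[2 * len(phi_rows):]))
    return 100.0 * total


def rsa_correct(result: BindingResult, w: float = 0.35) -> BindingResult:
    """Apply (or re-apply) the accessibility correction with weight ``w``."""
    return replace(result, weight_w=w, e_bind_rsa=result.e_bind_mean + w * result.rsa)


def optimize_rsa_weight(
    results: Sequence[BindingResult] | Sequence[tuple[float, float]],
    lnkd_values: Sequence[float],
    w_grid: Sequence[float],
) -> float:
    """Grid-search the RSA weight maximizing R² of E_bind^RSA vs lnK_D.

    Ties break toward the smaller weight. Raises on fewer than three pairs
    or zero variance in the response.
    """
    pairs = [
        (r.e_bind_mean, r.rsa) if isinstance(r, BindingResult) else (r[0], r[1])
        for r in results
    ]
    if len(pairs) < 3 or len(lnkd_values) != len(pairs):
        raise ValueError("need ≥3 paired (result, lnK_D) observations")
    e = np.array([p[0] for p in pairs])
    rsa = np.array([p[1] for p in pairs])
    y = np.asarray(lnkd_values, dtype=float)
    if np.ptp(y) == 0:
        raise ValueError("lnK_D values are degenerate (zero variance)")
    best_w, best_r2 = None, -np.inf
    for w in w_grid:
        x = e + w * rsa
        if np.ptp(x) == 0:
            r2 = -np.inf
        else:
            r2 = stats.linregress(x, y).rvalue ** 2
        if r2 > best_r2 + 1e-12:
            best_w, best_r2 = float(w), r2
    if best_w is None:
        raise ValueError("degenerate inputs: no weight gives a defined fit")
    return best_w
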