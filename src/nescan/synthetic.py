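"""Synthetic data generation with ground truth.

Every stage of the pipeline can be exercised without downloads: proteins
with planted NES motifs in controlled structural contexts (disordered
tail, ordered core, order/disorder boundary) plus decoy motifs that match
a consensus class but sit in contexts real NES motifs avoid (ordered
cores, β-strand middles, Thr/Ala-degraded registries); disorder /
secondary-structure / domain tracks consistent with those contexts; toy
groove templates; and labeled peptide benchmarks with synthetic K_D
values generated from the surrogate energy under a known linear law.

Generators are deterministic under their seed and always emit their
ground truth alongside the data.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import io_formats as iof
from .consensus import _FORWARD_TEMPLATES, PHI_RESIDUES, ConsensusMatch
from .structure import (
    C_FLANK, N_FLANK, SamplingConfig, SurrogateEnergy, TemplateEntry,
    build_template_library, e_bind,
)

#: spacer residues that can never satisfy a Φ slot, trigger the no-PW rule,
#: or be mistaken for a Thr/Ala substitution.
_SAFE_SPACERS = "SEQNDGKRH"

#: background residue weights: Φ residues (and the spacer-hostile P/W)
#: damped so spurious consensus matches are rare.
_BACKGROUND_WEIGHTS = {
    aa: (0.05 if aa in PHI_RESIDUES else 0.35 if aa in "PW"
         else 0.4 if aa in "TA" else 1.0)
    for aa in "ACDEFGHIKLMNPQRSTVWY"
}

CONTEXTS = ("disordered_tail", "ordered_core", "boundary")
DECOY_CATEGORIES = ("ordered", "beta", "ala")


@dataclass(frozen=True)
class PlantSpec:
    """One motif to plant: class, Φ1 position, context, decoy category."""

    class_id: str
    position: int                     # absolute 1-based position of Φ1
    context: str = "disordered_tail"
    phi_residues: Optional[tuple[str, ...]] = None
    decoy: bool = False
    category: Optional[str] = None    # ordered | beta | ala (decoys only)

    def __post_init__(self) -> None:
        if self.context not in CONTEXTS:
            raise ValueError(f"unknown context {self.context!r}")
        if self.decoy and self.category not in DECOY_CATEGORIES:
            raise ValueError(f"decoy needs a category from {DECOY_CATEGORIES}")


@dataclass
class PlantedMotif:
    """Ground-truth record of one planted motif or decoy."""

    class_id: str
    phi_positions: tuple[int, ...]
    window: tuple[int, int]
    context: str
    decoy: bool
    category: Optional[str]
    ta_used: bool


@dataclass
class GroundTruth:
    motifs: list[PlantedMotif]
    ordered_regions: list[tuple[int, int]]

    @property
    def planted(self) -> list[PlantedMotif]:
        return [m for m in self.motifs if not m.decoy]

    @property
    def decoys(self) -> list[PlantedMotif]:
        return [m for m in self.motifs if m.decoy]


def _motif_residues(
    class_id: str, rng: np.random.Generator,
    phi_residues: Optional[Sequence[str]] = None,
    degrade_ta: bool = False,
) -> tuple[str, tuple[int, ...], bool]:
    """Build one on-consensus motif core Φ1..Φ4 (+ trailing spacers).

    Returns (residues, Φ offsets within the string, ta_used).
    """
    base = class_id[:-2] if class_id.endswith("-R") else class_id
    phi_off, nopw = _FORWARD_TEMPLATES[base]
    length = phi_off[-1] + 1
    chars = [rng.choice(list(_SAFE_SPACERS)) for _ in range(length)]
    phis = list(phi_residues) if phi_residues else [
        str(rng.choice(list("LIVMF"))) for _ in range(4)
    ]
    ta_used = False
    if degrade_ta:
        phis[0] = "T"
        ta_used = True
    for k, o in enumerate(phi_off):
        chars[o] = phis[k]
    if base == "4":
        lo, hi = 8, 10
        chars[int(rng.integers(lo, hi + 1))] = "P"
    seq = "".join(chars)
    if class_id.endswith("-R"):
        # mirror onto the original strand; bulky rule holds when Φ3/Φ4 of
        # the mirrored frame include L/F/M — ensure it
        if not (set(phis[2:]) & set("LFM")):
            phis[3] = "L"
            chars[phi_off[3]] = "L"
            seq = "".join(chars)
        seq = seq[::-1]
        phi_off = tuple(length - 1 - o for o in phi_off)
    return seq, tuple(phi_off), ta_used


def gen_protein(
    plant_specs: Sequence[PlantSpec],
    length: int,
    seed: int,
) -> tuple[iof.SequenceRecord, GroundTruth]:
    """Sample a background sequence and plant the requested motifs.

    The background uses a Φ-damped residue distribution; planted windows
    (including two flanking residues kept free of Φ residues) must not
    overlap. Ordered-core and boundary contexts define the ordered
    regions later realized by :func:`gen_tracks`.
    """
    rng = np.random.default_rng(seed)
    aas = list(_BACKGROUND_WEIGHTS)
    w = np.array([_BACKGROUND_WEIGHTS[a] for a in aas])
    seq = list(rng.choice(aas, size=length, p=w / w.sum()))

    motifs: list[PlantedMotif] = []
    ordered: list[tuple[int, int]] = []
    used: list[tuple[int, int]] = []
    for spec in plant_specs:
        degrade = spec.decoy and spec.category == "ala"
        core, phi_off, ta = _motif_residues(
            spec.class_id, rng, spec.phi_residues, degrade_ta=degrade)
        if spec.class_id.endswith("-R"):
            # position refers to Φ1, the most C-terminal registry anchor
            start = spec.position - max(phi_off)
        else:
            start = spec.position
        stop = start + len(core) - 1
        win = (max(1, start - 4), min(length, stop + 2))
        if start < 3 or stop > length - 2:
            raise ValueError(f"plant at {spec.position} does not fit in length {length}")
        for lo, hi in used:
            if win[0] <= hi and lo <= win[1]:
                raise ValueError("overlapping plants")
        used.append(win)
        seq[start - 1: stop] = list(core)
        # guard flanks: no accidental Φ (or Thr/Ala/Pro/Trp) extension of
        # the registry into the background on either side
        for p in list(range(start - 4, start)) + list(range(stop + 1, stop + 5)):
            if 1 <= p <= length and seq[p - 1] in "LIVMFTAPW":
                seq[p - 1] = "S"
        phis = tuple(start + o for o in phi_off)
        motifs.append(PlantedMotif(
            class_id=spec.class_id, phi_positions=phis, window=win,
            context=spec.context, decoy=spec.decoy, category=spec.category,
            ta_used=ta,
        ))
        if spec.context == "ordered_core":
            ordered.append((max(1, win[0] - 30), min(length, win[1] + 30)))
        elif spec.context == "boundary":
            mid = (win[0] + win[1]) // 2
            ordered.append((max(1, win[0] - 35), mid))
    ordered = _merge_intervals(ordered)
    record = iof.SequenceRecord(f"synthetic-{seed}", "".join(seq))
    return record, GroundTruth(motifs=motifs, ordered_regions=ordered)


def _merge_intervals(ivs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    for lo, hi in sorted(ivs):
        if out and lo <= out[-1][1] + 1:
            out[-1] = (out[-1][0], max(out[-1][1], hi))
        else:
            out.append((lo, hi))
    return out


def gen_tracks(
    sequence: str,
    truth: GroundTruth,
    seed: int,
    ordered_beta: tuple[float, float] = (2.0, 64.7),   # mean 0.03
    disordered_beta: tuple[float, float] = (7.0, 3.0),  # mean 0.7
) -> tuple[iof.DisorderTrack, iof.DisorderTrack, iof.DisorderTrack,
           iof.SSTrack, list[iof.DomainAnnotation]]:
    """Emit disorder (×3), secondary-structure and domain tracks matching
    the ground-truth layout.

    Ordered-region residues draw disorder propensities from a Beta
    distribution concentrated well below the 0.1 order cutoff; everything
    else from a Beta centred at 0.7, with a short linear blend at region
    edges. Secondary structure: helix over planted motif middles, strand
    over β-decoy middles, coil elsewhere. One domain per ordered region.
    """
    rng = np.random.default_rng(seed)
    L = len(sequence)
    in_order = np.zeros(L, dtype=bool)
    for lo, hi in truth.ordered_regions:
        in_order[lo - 1: hi] = True

    def draw(n_track_seed: int) -> tuple[float, ...]:
        r = np.random.default_rng(seed + n_track_seed)
        a_o, b_o = ordered_beta
        a_d, b_d = disordered_beta
        vals = np.where(in_order, r.beta(a_o, b_o, L), r.beta(a_d, b_d, L))
        # blend across region edges (3 residues each side)
        edges = np.where(np.diff(in_order.astype(int)) != 0)[0]
        for e in edges:
            for k in range(-2, 3):
                i = e + k
                if 0 <= i < L:
                    t = (k + 2) / 4.0
                    lo_v = vals[max(0, e - 3)]
                    hi_v = vals[min(L - 1, e + 4)]
                    vals[i] = lo_v + t * (hi_v - lo_v)
        return tuple(np.clip(vals, 0.0, 1.0))

    diso = iof.DisorderTrack("disopred", draw(11))
    spotd = iof.DisorderTrack("spotd", draw(23))
    iup = iof.DisorderTrack("iupred", draw(37))

    states = ["C"] * L
    conf = [int(rng.integers(4, 9)) for _ in range(L)]
    for m in truth.motifs:
        phis = sorted(m.phi_positions)
        mid = range(phis[0], phis[-1] + 1)
        fill = "E" if (m.decoy and m.category == "beta") else "H"
        for p in mid:
            states[p - 1] = fill
    ss = iof.SSTrack("".join(states), tuple(conf))

    domains = [
        iof.DomainAnnotation("pfam", f"core{i+1}", lo, hi)
        for i, (lo, hi) in enumerate(truth.ordered_regions)
        if hi - lo + 1 >= 30
    ]
    return diso, spotd, iup, ss, domains


def gen_toy_templates(seed: int = 0, jitter: float = 0.02) -> list[TemplateEntry]:
    """Synthetic template library with a seeded anchor jitter.

    The geometry is the idealized groove of
    :func:`nescan.structure.build_template_library`; the jitter (Å,
    Gaussian on backbone anchors) models template-to-template noise
    without moving Φ anchors off their pockets.
    """
    rng = np.random.default_rng(seed)
    templates = build_template_library("synthetic")
    for t in templates:
        t.anchor_ca = t.anchor_ca + rng.normal(0.0, jitter, t.anchor_ca.shape)
    return templates


def match_from_registry(
    sequence: str,
    class_id: str,
    phi_positions: Sequence[int],
    protein_id: str = "peptide",
) -> ConsensusMatch:
    """Build a match object from an annotated registry (no scanning).

    Used for peptides whose registry is known (benchmark annotations,
    engineered mutants that no longer satisfy the consensus).
    """
    direction = "reverse" if class_id.endswith("-R") else "forward"
    pos = sorted(phi_positions)
    if len(pos) == 5:
        phi0, core = (pos[-1], pos[:-1]) if direction == "reverse" else (pos[0], pos[1:])
    elif len(pos) == 4:
        phi0, core = None, pos
    else:
        raise ValueError("registry must have 4 or 5 positions")
    if direction == "reverse":
        core = core[::-1]
    ta = sequence[core[0] - 1] in "TA" or sequence[core[1] - 1] in "TA"
    m = ConsensusMatch(
        protein_id=protein_id, class_id=class_id, direction=direction,
        phi_positions=tuple(core), ta_used=ta,
    )
    if phi0 is not None:
        m.phi0 = phi0
        m.phi0_hydrophobic = sequence[phi0 - 1] in PHI_RESIDUES
    phi1, phi4 = m.phi_positions[0], m.phi_positions[3]
    L = len(sequence)
    if direction == "forward":
        m.seg_start = max(1, (m.phi0 - 1) if m.phi0 else phi1 - 4)
        m.seg_end = min(L, phi4 + 2)
    else:
        m.seg_end = min(L, (m.phi0 + 1) if m.phi0 else phi1 + 4)
        m.seg_start = max(1, phi4 - 2)
    return m


@dataclass
class SyntheticBenchmarkEntry:
    """One synthetic benchmark peptide with its generating truth."""

    name: str
    sequence: str
    class_id: str
    match: ConsensusMatch
    n_degraded: int
    binder: bool
    e_true: float
    rsa: float
    lnkd_true: Optional[float]
    kd_nM: Optional[float]


_BENCH_CLASSES = ("1a", "1b", "1c", "2", "4", "1a-R")


def gen_benchmark(
    n: int,
    noise: float = 1.0,
    seed: int = 0,
    binder_fraction: float = 0.6,
    slope: float = 0.6,
    intercept: float = 14.0,
    w_true: float = 0.35,
    templates: Optional[list[TemplateEntry]] = None,
) -> list[SyntheticBenchmarkEntry]:
    """Labeled peptide set with synthetic affinities.

    Binders are built on-register from the template classes (with 0–2
    Φ→Ala degradations to spread affinities); non-binders carry 3–4
    degradations. Affinities follow
    ``lnK_D = slope · (E + w_true · RSA) + intercept + N(0, noise)``
    where E and RSA come from the surrogate at the threaded pose
    (sampling disabled), so the recovery tests have a known planted law.
    Non-binders get no K_D (below detection), only the truth value.
    """
    if n < 10:
        raise ValueError("n must be ≥ 10")
    rng = np.random.default_rng(seed)
    templates = templates or build_template_library("synthetic")
    config = SamplingConfig.deterministic()
    backend = SurrogateEnergy()

    n_bind = int(round(n * binder_fraction))
    out: list[SyntheticBenchmarkEntry] = []
    for i in range(n):
        binder = i < n_bind
        class_id = _BENCH_CLASSES[i % len(_BENCH_CLASSES)]
        core, phi_off, _ = _motif_residues(class_id, rng)
        # full registry window with flanks
        nfl = "".join(rng.choice(list(_SAFE_SPACERS), N_FLANK))
        cfl = "".join(rng.choice(list(_SAFE_SPACERS), C_FLANK))
        if class_id.endswith("-R"):
            seq = cfl + core + nfl
            phis = tuple(len(cfl) + o + 1 for o in phi_off)
        else:
            seq = nfl + core + cfl
            phis = tuple(N_FLANK + o + 1 for o in phi_off)
        n_deg = int(rng.integers(0, 4)) if binder else int(rng.integers(3, 5))
        seq_l = list(seq)
        deg_sites = rng.permutation(4)[:min(n_deg, 4)]
        ordered_phis = sorted(phis)
        # degrade with a mix of small (A/G/S) and mid-size (V/T) residues so
        # the energy loss and the interface cavity are not perfectly collinear
        for k in deg_sites:
            seq_l[ordered_phis[k] - 1] = str(rng.choice(list("AAGSV")))
        seq = "".join(seq_l)
        match = match_from_registry(seq, class_id, phis, f"bench{i:03d}")
        res = e_bind(seq, match, templates, backend, config,
                     seed=int(rng.integers(2 ** 31)), compute_rsa=True)
        lnkd = slope * (res.e_bind_mean + w_true * res.rsa) + intercept \
            + rng.normal(0.0, noise)
        out.append(SyntheticBenchmarkEntry(
            name=f"bench{i:03d}", sequence=seq, class_id=class_id,
            match=match, n_degraded=n_deg, binder=binder,
            e_true=res.e_bind_mean, rsa=res.rsa, lnkd_true=lnkd,
            kd_nM=float(np.exp(lnkd)) if binder else None,
        ))
    return out


# ---------------------------------------------------------------------------
# demo input bundle
# ---------------------------------------------------------------------------

def write_demo_bundle(out_dir: str | Path, seed: int = 0) -> dict[str, Path]:
    """Write a complete demo input set (FASTA, 3 disorder tracks, ss2,
    domains, evidence) for one synthetic protein with a planted motif in
    a disordered tail plus ordered/β decoys."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    plants = [
        PlantSpec("1a", 150, "disordered_tail"),
        PlantSpec("1a", 60, "ordered_core", decoy=True, category="ordered"),
        PlantSpec("2", 230, "ordered_core", decoy=True, category="beta"),
    ]
    record, truth = gen_protein(plants, 300, seed)
    diso, spotd, iup, ss, domains = gen_tracks(record.sequence, truth, seed + 1)
    planted = truth.planted[0]
    phis = sorted(planted.phi_positions)
    evidence = [iof.EvidenceAnnotation("mutation", phis[0], phis[-1])]

    paths = {
        "fasta": out_dir / "protein.fasta",
        "disopred": out_dir / "protein.diso",
        "spotd": out_dir / "protein.spotd",
        "iupred": out_dir / "protein.iup",
        "ss2": out_dir / "protein.ss2",
        "domains": out_dir / "domains.tsv",
        "evidence": out_dir / "evidence.tsv",
    }
    iof.write_fasta([record], paths["fasta"])
    iof.write_disorder_track(diso, record.sequence, paths["disopred"])
    iof.write_disorder_track(spotd, record.sequence, paths["spotd"])
    iof.write_disorder_track(iup, record.sequence, paths["iupred"])
    iof.write_ss2(ss, record.sequence, paths["ss2"])
    iof.write_domains(domains, paths["domains"])
    iof.write_evidence(evidence, paths["evidence"])
    return paths
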