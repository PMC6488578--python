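# Methods

This note documents the models, rules and numerical choices behind
`nescan`, in the order the pipeline applies them, together with what the
synthetic data do and do not establish about real data.

## Consensus classes and scanning

A class is an ordered slot template relative to the first hydrophobic
anchor Φ1. Φ slots accept {L, I, V, M, F}; spacer slots accept any residue
(X) or any residue except Pro/Trp ([^PW]); `X` (unknown residue) never
satisfies a Φ or [^PW] slot but passes unrestricted spacers. The compiled
templates (Φ offsets from Φ1, then the restricted spacers):

| class | Φ offsets    | spacers                         |
|-------|--------------|---------------------------------|
| 1a    | 0, 4, 7, 9   | X3 · [^PW]2 · [^PW]             |
| 1b    | 0, 3, 6, 8   | X2 · [^PW]2 · [^PW]             |
| 2     | 0, 2, 5, 7   | X1 · [^PW]2 · [^PW]             |
| 1c    | 0, 4, 8, 10  | X3 · [^PW]3 · [^PW]             |
| 1d    | 0, 3, 7, 9   | X2 · [^PW]3 · [^PW]             |
| 3     | 0, 3, 7, 10  | X2 · X[^PW]2 · [^PW]2           |
| 4     | 0, 4, 7, 11  | X3 · [^PW]2 · XXX with ≥ 1 Pro  |
| 1a-R, 1c-R | mirrored | plus the reverse bulky rule    |

Thr or Ala may substitute at exactly one of Φ1/Φ2 for classes
1a/1b/1c/1d/2/3. Class 4 and the reverse classes never use the
substitution: the empirical priority ranking has no rank for those
combinations, and keeping priority a total function decides the question.
The no-Pro/Trp restriction covers only the Φ2→Φ4 spacers; the Φ1→Φ2
spacer accepts anything including Pro (required by the Cyclin D1 peptide,
whose `PTD` spacer precedes Φ2).

Reverse classes are implemented by scanning the reversed sequence with
the forward template and mapping coordinates back; registry slots are
therefore always expressed in the mirrored ("forward-reading") frame. The
bulky rule requires at least one of the two registry residues bound in
the P0/P1 pockets — mirrored-frame Φ3/Φ4, i.e. the N-terminal end of the
match in original coordinates — to be L, F or M. This reading reproduces
both the accepted (CPEB4, hRio2, DEAF1, SGN5) and the rejected
(COMMD1-2: V/V at that end) benchmark entries.

Φ0 sits three residues upstream of Φ1 (Φ0-X2-Φ1), is unrestricted, and is
recorded with a hydrophobicity flag. Class 3 carries no Φ0 slot: in the
benchmark table every hydrophobic residue at Φ1−3 of a class-1a/1b/1c/2/4
peptide is part of the annotated registry, while the class-3 peptides
(mDia2, CDC7, COMMD1) leave that position unannotated even when
hydrophobic. Both the offset and the class set are configurable.

Empirical priority: 1 = class 1a with five Φ (hydrophobic Φ0);
2 = class 1a with four Φ, plain 1c, 1a-R, plain 2/3/4; 3 = 1a/1c with
Thr/Ala; 4 = plain 1b/1d, 1c-R, 2/3 with Thr/Ala; 5 = 1b/1d with Thr/Ala.
Plain class 1c is not named in the published ranking; it is placed with
classes 2/3 (rank 2) because the ranking's own rationale groups 1c with
them by prevalence.

Extraction windows span one residue before Φ0 through two after Φ4
(mirrored for reverse classes), clamped at the termini; no window exceeds
25 residues. Matches whose start positions chain within 5 residues are
grouped transitively; a match is a candidate when its Φ2–Φ4 span overlaps
an experimental-evidence interval, else a false positive.

## Disorder, domains and secondary structure

A residue is ordered ('O') only when *both* primary disorder tracks
(DISOPRED-style and SPOT-Disorder-style) are strictly below 0.1 — a
deliberately strict cutoff compared to the predictors' own ~0.5
thresholds — else 'D'; IUPred values are recorded for reference only.
Over the segment plus 20-residue flanks (truncated at termini; only
existing residues in the denominator): D-fraction > 0.9 → DISO,
O-fraction > 0.9 → ORD, else boundary. The rule is stated here in its
self-consistent orientation (D-majority → DISO); the source text of the
rule transposes the two output labels in a way that contradicts its own
downstream use, and the self-consistent reading is implemented.

Domain location: NA with no overlapping annotated domain; otherwise the
longest overlapping domain governs (deterministic, and biased toward the
folding-unit interpretation): `small` if that domain is < 50 residues,
`MID` if the segment lies inside it with > 5 residues to both domain
ends (the margin is a package choice; no published value exists),
`boundary` otherwise.

β content is the fraction of predicted E states over the segment middle,
fixed as the closed Φ1–Φ4 span (the "middle" is not defined in the
source; this choice is configurable). Flags: `_D` for DISO/boundary
segments, `_O` for ORD, `_beta` when β > 0.5. A segment is highlighted —
structurally plausible — iff it is not ORD and β ≤ 0.5. A missing SS
track leaves β undefined and passes the criterion (conservative
inclusion); missing disorder tracks are an error because the filter is
central.

## Groove templates and threading

The template library holds one entry per crystal-template class
(1a ×2, 1b, 1c, 2 ×2 — one of them the reverse-type HIV-Rev groove — 4,
1a-R); class-3 and class-1d queries are fitted on the other templates,
class 3 canonically landing on class 1a, as with the crystal set. A
library can also be loaded from PDB files plus a manifest (chains, Φ1
residue number, direction); the CRM1 fragment is truncated to residues
479–655 by default.

The synthetic library is an idealized groove: five pocket centroids
P0–P4 along the groove axis at x = 0, 4.5, 10.5, 15.0, 18.0 Å (helical
rise of 1.5 Å/residue over the class-1a registry), 2.5 Å below the
peptide backbone line, inside a shelled channel open above the peptide.
Per class, Φ anchors sit directly over their pockets and spacer anchors
interpolate across each inter-Φ gap with a class-specific transverse
signature (bulge sign and amplitude per gap, amplitudes ≤ 2.5 Å, with an
upward lift on positive gaps). Signatures were chosen by a one-off search
so that any two classes differ by ≥ 2 Å RMSD over shared spacer slots;
same-class duplicate templates differ only by a 0.96 amplitude scale.
Below each pocket sits a "reporter" sphere at a depth chosen so a
full-size Φ side chain occludes its face while a shrunken one (Ala, Gly,
Ser) leaves it probe-accessible — the geometric realization of the
interface-cavity penalty. The remaining shell (walls, outer shell, rim,
cradle, end caps) buries everything except the channel mouth.

Threading maps the match window (Φ0−1 … Φ4+2, clipped at the protein
termini) residue-by-residue onto template anchors by registry slot;
slots outside the template registry extrapolate along the terminal anchor
direction. Side-chain centroids are placed at a residue-specific reach
from the CA: toward the pocket for template Φ slots, outward (+z) for
spacers. When match and template read in opposite directions the window
is threaded mirrored, so Φ residues land off-pocket — this is what lets
the energy reject wrong-direction fits.

## Energy model and sampling

The shipped backend is a coarse surrogate in arbitrary units
(lower = more stable):

* **pocket** − w_p · max(h, 0) · exp(−d²/2σ²) per residue, d the
  centroid-to-nearest-pocket distance, h the Kyte–Doolittle hydropathy
  (w_p = 1, σ = 1.5 Å). Pockets reward hydrophobic burial; polar
  occupants are unrewarded rather than penalized — the cavity they leave
  is charged through the RSA term.
* **exposure** + w_e · max(h, 0) · (1 − proximity) (w_e = 0.3); in the
  free peptide every hydrophobic residue pays the full penalty.
* **clash** + w_c · (d₀ − d)² for peptide/groove sphere pairs below the
  hard core d₀ = 2.5 Å (w_c = 2).
* **strain** + w_s · ‖CA − anchor‖² against the threading anchors
  (w_s = 0.8) plus a centroid tether + w_t · (|CA−centroid| − reach)²
  (w_t = 1).

The monotonicity that drives the mutant discrimination is structural:
replacing any Φ residue by Ala or Gly lowers the pocket reward and the
free-peptide exposure by more than any term it relieves, so E_bind
strictly increases.

Sampling follows the published protocol shape: independent Metropolis
chains (one-residue CA + centroid moves, fixed temperature 1.0) from the
threaded pose; the lowest-energy parents then each seed constrained
greedy relaxation runs (accept only improvements, every CA within a
1.0 Å radius of the parent). E_complex and E_protein aggregate the k
lowest ensemble energies (default k = 10); E_peptide is the minimum
aggregated free-peptide energy over all template fits; per-template
E_bind = E_complex − E_protein − E_peptide; the groove-alone term is
computed once per template and reused across replicate runs. The whole
calculation replicates over n_runs independent sub-seeded runs; the
reported value is the mean/sd of the per-run best E_bind (selection per
run, then averaging).

Default counts follow the protocol at reduced scale (50 chains × 2 000
moves, 5 parents × 50 relax runs, 5 replicate runs). The test suite and
the acceptance script use the packaged `fast` and `minimal`
configurations (down to 2 chains × 10 moves, 1 run): the surrogate's
discrimination is geometric — present at the threaded pose — so the
protocol's conclusions do not depend on sampling depth, and the full
suite stays in tens of seconds. Deterministic checks (linearity under
energy scaling, mutation monotonicity) run with sampling disabled, where
greedy relaxation is invariant under positive scaling of the backend.

## Interface accessibility

Accessibility is Shrake–Rupley-style: Fibonacci-lattice points on each
probe-expanded sphere (probe 1.4 Å, 146 points), a point accessible iff
outside every other expanded sphere. `interface_rsa` sums the per-residue
accessible percentage over the interface set — peptide Φ residues
(area-weighted over their CA and centroid spheres) plus groove residues
within 6 Å of a pocket — in NACCESS-like percent units, which is what
makes the published weight w = 0.35 numerically meaningful next to
E_bind. For an ideal threaded complex the mean interface fraction is
≈ 0.002; each Φ→Ala mutation opens ≈ 7 percent-units of reporter
surface. E_bind^RSA = ⟨E_bind⟩ + w · RSA, computed on the lowest-energy
complex model of the selected template; `optimize_rsa_weight` grid-
searches w for maximal R² against ln K_D (ties toward smaller w).

## Synthetic data

`gen_protein` samples background residues from a Φ-damped distribution
(Φ weight 0.05, Thr/Ala 0.4, Pro/Trp 0.35, others 1.0 — keeping spurious
consensus hits below ~1 per 200 residues) and plants motifs that satisfy
their class exactly, with four-residue guard flanks so the background
cannot extend a registry. Decoys match a consensus class but sit in
contexts real NES avoid: inside an ordered core, with β-strand middles,
or Thr/Ala-degraded. `gen_tracks` realizes the layout: ordered regions
draw disorder from Beta(2.0, 64.7) (mean 0.03; both predictors < 0.1
with probability ≈ 0.98), disordered regions from Beta(7, 3) (mean 0.7),
with a short linear blend at edges; helix over planted middles, strand
over β-decoy middles; one domain per ordered region. `gen_benchmark`
builds on-register peptides with 0–4 Φ degradations drawn from
{A, A, G, S, V} (mixing energy loss and cavity size so E and RSA are not
collinear) and assigns lnK_D = 0.6·(E + w_true·RSA) + 14 + N(0, 1.0),
with E and RSA computed at the threaded pose; non-binders get no K_D.

What passing these tests shows — and does not. The generators emulate
the *decision structure* of real inputs: the 0.1/90% disorder rules see
both outcomes, decoys exercise every rejection path, the benchmark has a
known affinity law. They do not emulate real predictor error statistics,
real sequence composition, or real energetics: the surrogate reproduces
the protocol's qualitative discriminations (pocket burial, direction,
cavities), not Rosetta-scale energies. Accordingly, on the packaged
experimental peptide table the surrogate's E_bind^RSA correlates with
ln K_D only weakly (r ≈ 0.3–0.5, n = 25) — reported honestly by the
acceptance script — whereas on generator-controlled data, where the
affinity law is known, correlation and weight recovery are sharp. A
Rosetta-grade backend can be plugged in through the `EnergyBackend`
contract without touching the protocol.

## Degenerate inputs and tie-breaks

Sequences must be non-empty over the 20 amino acids plus X; tracks must
align with their sequence at pipeline assembly (readers accept standalone
tracks). Exactly-0.1 propensities are disordered (strict "below").
Matches tie-break by seg_start, then priority, then class id, then
registry; template arg-min ties break lexicographically; the RSA-weight
grid search ties toward smaller w. Ensembles smaller than k aggregate
everything with a warning. PDB input is single-model, first altloc;
residues missing backbone atoms are dropped with a warning; glycine
centroids fall back to the CA.

## Known limitations

* The surrogate is not an affinity predictor for real peptides; it is the
  protocol vehicle. Absolute E_bind values are unitless.
* Template-based threading cannot model classes without a geometric
  template better than the nearest available class.
* Reverse-class templates and the class 1c-R slot pattern are mirrored by
  construction (no crystal geometry pins them); 1c-R is flagged
  experimental in the class table.
* The synthetic groove is a caricature: one rigid channel, spherical
  residues, no electrostatics, no water.
* Priority of plain class 1c and the Φ0 class set rest on readings of the
  benchmark annotations, documented above and configurable.
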