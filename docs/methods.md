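# Methods

This note records the models, conventions and parameter choices behind
`crossalpha`, what the synthetic generators do and do not emulate, and the
known limits of each stage.

## Coordinate model and I/O

Structures are plain dataclasses (`Structure → Chain → Residue → Atom`) with
numpy coordinates; gemmi does all PDB/mmCIF syntax. Only polymer amino-acid
residues are read — waters, ligands and hydrogens are dropped, because every
geometric operation here uses backbone heavy atoms and side-chain centroids.
Residue numbering is 1-based author numbering with inclusive ranges;
insertion codes are rejected outright (the peptides this package targets are
short linear chains). For alternate conformations the first altloc
encountered wins, making atom counts deterministic. Biological-assembly
expansion is only ever explicit (`parse_structure(..., biounit=k)`), never
implicit, so biounit-level database filters operate on exactly what the
caller selected. PDB writing enforces the fixed-width format's 99,999-atom
and single-character chain-id limits and directs larger models to mmCIF.

## Ideal helices and filaments (`forge`)

CA atoms are placed *parametrically* on a cylinder: twist 100°/residue, rise
1.5 Å/residue, radius 2.27 Å (the canonical 3.6-residue α-helix). This makes
the i→i+k displacement arithmetic exact by construction — the package's
(+40°, 6.0 Å) / (−60°, 4.5 Å) statements about i,i+4 and i,i+3 pairs are
properties of the canonical helix, not of any fitted model. N, C and O are
attached per residue from offsets expressed in the local
(radial, tangential, axial) frame; the offsets are derived once from a chain
built purely from standard internal coordinates (bonds 1.46/1.53/1.33 Å,
angles 111/117/121°, φ = −57°, ψ = −47°, ω = 180°) and cached. Because the
internal-coordinate helix twists at ≈99°/residue rather than exactly 100°,
peptide-bond lengths in the parametric helix deviate from ideal by a few
hundredths of an Å — irrelevant for every consumer here, which is why the
simpler construction was chosen over enforcing exact closure.

Side chains are reduced to CB (placed by the standard tetrahedral
construction from N/CA/C) plus one pseudo-centroid atom `CEN` at a
per-residue-type distance from CA along the CB direction (1.53 Å for Ala up
to 4.10 Å for Arg). That is deliberately the coarsest representation that
still supports centroid-based knobs-into-holes detection and clasp-contact
mapping; no rotamers, no packing energetics.

`generate_filament` applies the screw operation about +z (copy k rotated by
k·twist, raised by k·rise; Cn adds rotated copies at 360°/n). The cross-α
fixture builder lays one helix tangentially on the tube surface (axis ⊥
filament axis) at a chosen radius and tilt before applying symmetry. The
tilt is a free fixture parameter: real assemblies show a peptide-length-
dependent tilt whose values are not pinned down, so the fixture makes no
claim about it.

Noise is isotropic per-coordinate Gaussian (`jitter_structure`), seeded and
bitwise-reproducible. The closed form used in tests: jittering every
coordinate with σ gives an RMSD to the original of σ√3; two independently
jittered copies differ by σ√6.

Decoy databases are mixtures of 1–3 ideal helices with random 20-letter
sequences in uniformly random rigid poses (chain lengths 30–60 by default,
25–40 in the faster test configurations). When a motif is planted, each
segment becomes one chain: an ideal helix carrying the segment's sequence
plus 5 random flanking residues on each side is rigidly superposed onto the
(noise-perturbed) segment backbone and the window's N/CA/C/O are then set to
the target coordinates exactly, so the planted RMSD is controlled; the cost
is a small backbone discontinuity at the window edges, cosmetic for a
search that only reads backbone windows. What the decoys do **not** emulate:
loops and strands, realistic amino-acid composition, side-chain packing, or
the size and diversity of a real structure database — so passing recovery
tests demonstrates correctness of the search machinery, not expected hit
rates against the PDB.

## Lattice analysis (`lattice`)

Angles wrap to (−180°, 180°]; positive twist means a right-handed 1-start,
and an n-start family is left-handed exactly when wrap(n·twist) < 0. This
single convention simultaneously reproduces right-handed stacking families
and left-handed 11/12-start lateral families for the filaments of interest.

`stacking_direction` selects, among families whose axial step is at most
`axial_cutoff` (default 15 Å ≈ one cross-α helix diameter above the ~10 Å
stacking spacing), the family with the smallest 3D neighbour distance at the
given radius, ties toward smaller n. The winner must also advance less than
`max_angular_step` (default 90°) in azimuth per step. This gate is the one
genuinely open design choice: a gate on the *inclination at the evaluation
radius* (e.g. "< 45° from the axis") looks natural but makes the assignment
radius-dependent — the same family's inclination grows with the radius at
which the net is drawn, so a 3-start stacking family accepted at r = 25 Å
would be rejected at r = 40 Å. The azimuthal-step gate is scale-free, keeps
the assignment invariant across any plausible drawing radius (verified over
10–40 Å for all symmetries of interest), still returns the pure-axial
1-start for near-axial symmetries, and still yields an explicit
"no axial stacking family" outcome when every bounded family is mostly
circumferential.

`fit_symmetry` groups chains into subunits (pass one full Cn ring per group
for cyclic filaments), superposes consecutive subunits optimally, extracts
each transform's screw parameters (axis from the rotation, rise = axial
translation component, twist signed so rise > 0) and averages. Subunit pairs
whose superposition residual exceeds `congruence_tol` (default 1.0 Å — comfortably
above the ≈0.25 Å residual of σ = 0.1 Å jitter, far below any real
mismatch) raise with the residual value. Noise-free round trips recover
(rise, twist) to 1e−6; at σ = 0.1 Å jitter, recovery is within 0.004 Å and
0.11° on 6-subunit fixtures, well inside the 0.05 Å / 0.5° bounds asserted.

Helical nets unroll the surface lattice: subunit k at z = k·rise, abscissa
x = r·θk with θ accumulated modulo 360°. The radius is always caller-
supplied; none of the supported analyses require a canonical radius, and
published net diagrams do not state one.

## Helix geometry (`helixgeom`)

Axis fitting uses the bisector construction: at each interior CA the vector
sum of the two bonds into it points at the helix axis with magnitude
2r(1−cos t); t is estimated from consecutive bisector directions, the
recovered axis points are fitted by a total-least-squares line, and the
direction is oriented N→C. This stays well-conditioned for the 5–7-residue
fragments used in motif work, where cylinder fitting is not. Accuracy on
ideal helices of 7–40 residues is < 0.5°; under σ = 0.2 Å jitter, < 2°.

The crossing angle Ω between oriented axes has magnitude equal to the angle
between direction vectors and sign taken from the common-perpendicular
convention: positive when axis B is rotated counter-clockwise from axis A as
seen along the A→B closest-approach vector. A parallel left-handed-supercoil
coiled-coil pair then scores near −20° and a right-handed GxxxG-like pair
near +40°, which pins the convention to the packing-angle values standard in
the coiled-coil literature. Exactly parallel axes return Ω = 0 with the
line-line distance still reported; intersecting axes default to a positive
sign. Tilt is 90° minus the angle to the filament axis, signed by the axial
component of the N→C direction, so cross-α helices sit near 0°.

Superposition is the standard Kabsch SVD with determinant correction (never
a reflection). Curved helices are handled by fitting axes over explicit
residue windows; there is no automatic kink detection, and helix boundaries
are always explicit inputs (no DSSP).

## Interfaces (`interfaces`)

SASA is Shrake–Rupley sphere sampling on a golden-spiral point set (default
960 points, probe 1.4 Å) with Bondi van-der-Waals radii shipped as package
data; changing that table changes every area downstream, so its values are
pinned by tests. A sample point strictly inside any neighbour's expanded
sphere is occluded; points exactly on a neighbour's surface (coincident
atoms) are broken by atom order so a degenerate pair totals one sphere's
area. Quadrature error on an isolated atom is < 1%, and doubling the point
count moves fixture totals by < 0.5%.

Buried area between chain groups is the symmetric convention
(SASA(A) + SASA(B) − SASA(A∪B))/2, divided by the peptide count of an
*explicit* reporting group — published per-peptide figures do not always say
which group normalizes, so the operation refuses to guess.

Knobs-into-holes uses the side-chain centroid criterion: a residue of one
helix is a knob when its centroid lies within 7.0 Å of at least four
centroids on the partner (glycine's centroid is its CA). This is a
simplification of the full SOCKET algorithm — no packing-angle
classification of knob types — chosen because the reduced CB+centroid
representation supports nothing finer. Heptad letters are assigned from a
caller-provided register anchor.

Clasp contacts: for each subunit, the guanidinium atoms (NE/CZ/NH1/NH2 when
present, else the reduced side-chain proxy) of the two clasp arginines are
tested against heavy atoms of the C-terminal residue of each symmetry
neighbour within ±8 subunits; the nearest neighbour within the 4.0 Å
default cutoff is reported and offsets are aggregated into a consensus. On
noise-free symmetric fixtures the offset is unanimous across all subunits
that possess the relevant neighbour; terminal subunits of a finite filament
can instead report a wrap-around second-shell contact, which the consensus
absorbs. Hydrogen bonds are approximated by heavy-atom distance only (no
angles): fixtures and deposited models alike lack hydrogens.

## Motif search (`motifsearch`)

Database curation follows the standard recipe: keep X-ray structures at
2.6 Å resolution or better (boundary inclusive), ≥ 60% protein residues,
≤ 5000 residues, ≤ 26 chains; entries missing required metadata are rejected
with reason "missing-metadata" rather than raising. Chains are clustered
greedily at 50% global-alignment identity (match +1, mismatch 0, gap
−10/−0.5, identity = identities / alignment length; longest chain founds
each cluster) — the external clustering tool's exact parameters are not
published, and every behaviour relied on (identical vs unrelated vs
60%-identity pairs) is insensitive to them. A biological unit is then
dropped when another unit's chain-cluster multiset strictly contains its
own, with resolution (then id) breaking exact ties; the retained set is
independent of input order.

A motif query is an ordered list of ungapped backbone segments
(N/CA/C/O per residue), possibly from different chains — the clasp motif is
a 7-residue RxxxR helix fragment plus the 5-residue C-terminal fragment of
the docked neighbour; the control motif is the same 7-residue fragment with
a 5-residue fragment of an axially stacked partner. RMSD is over backbone
atoms under one joint superposition of all segments; the cutoff (default
1.0 Å) is inclusive. Candidate windows per segment are admitted by the bound
σ_seg ≤ cutoff·√(A_total/A_seg) (if the joint RMSD is within the cutoff, no
segment's own optimal RMSD can exceed that), combinations are pruned when
any inter-segment centroid distance deviates from the query's by more than
the two segments' combined bounds, and the survivors are scored exactly —
so the pruned search provably returns the brute-force match set, which the
tests verify directly on decoy databases. Segments of one match may not
overlap each other; matches sort by RMSD with (entry, placement) breaking
ties. Redundancy filtering is greedy by ascending RMSD on the matched
fragments ± 15 flanking residues at 50% identity. Whether the "top k"
summaries (divergence curve, logo counts) are taken before or after the
redundancy filter is exposed as an option, with the CLI filtering first by
default.

Full-database-scale searching is explicitly out of scope: the pipeline is
exercised end to end on generated fixture sets (≤ 60 structures), and
database paths are pluggable for anyone with a local structure mirror.
Planted-motif recovery calibrates expectations: at plant noise
σ ∈ {0.1, 0.2, 0.4} Å the planted copy is the rank-1 match across 20 seeds
with observed RMSD within ±30% of σ√3.

## Problem sizes and determinism

Test and acceptance workloads use filaments of 5–12 subunits, decoy
databases of 6–60 structures with chains of 25–40 residues, 960-point SASA
quadrature, and 20-seed recovery sweeps — sizes chosen so the whole suite
exercises every pipeline stage in well under a minute per module while
keeping Monte-Carlo assertions (jitter RMSD, symmetry recovery, planted-
motif recovery) statistically comfortable. Every stochastic stage takes an
explicit integer seed and is bitwise-reproducible; identical configuration
and seed give byte-identical outputs.

## Known limitations

* No nucleic acids, ligands, anisotropic displacement parameters or
  crystallographic symmetry expansion in I/O.
* The ideal-helix backbone is near-ideal, not exactly closed (see above);
  side chains are CB+centroid only.
* Ω's sign is undefined for exactly intersecting or exactly parallel axes
  (reported as positive / zero respectively).
* Buried-area agreement with interface-analysis servers is approximate by
  construction: those tools' interface definitions are not fully public.
* Symmetry inference from image power spectra, map refinement, and design
  energetics are entirely out of scope.
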