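# Methods

## Scope and model

`pocketsim` implements a pipeline for asking whether two or more protein
binding sites, each defined by a bound ligand pose, are similar — and if so,
over what distance from the ligand and through which conserved
physicochemical features. It has four computational stages: ligand-defined
pocket extraction, PMScore similarity scoring, distance-scan similarity
profiles, and pseudocenter-based multiple alignment with consensus-site
generation; plus a seeded synthetic-pocket generator that stands in for the
docked/modelled complexes such comparisons normally start from.

## Pocket definition

A binding site at cutoff *d* contains every standard residue with at least
one heavy atom within *d* Å (Euclidean) of any ligand heavy atom. Choices
behind this definition:

- **Any-heavy-atom contact distance**, not Cα or centroid distance. "Residues
  at a given distance from the ligand" is read as atomic contact; it is the
  definition under which pocket size grows smoothly and monotonically with
  the cutoff (a tested invariant).
- **Hydrogens never participate.** Protonation of docked or modelled
  structures is not reproducible; all distances in the package are between
  heavy atoms.
- **Waters, ions and non-standard residues are excluded** (waters at parse
  time, non-standard residues at extraction with a logged warning).
- **Parsing conventions:** first MODEL only, blank/'A' altlocs only, author
  residue numbering kept. These make parsing of multi-model or
  partially-disordered files deterministic.

## PMScore

Each pocket residue is typed into one of five chemical groups and reduced
to three points: CA, CB, and the unweighted mean of its side-chain heavy
atoms. Glycine degenerates to three coincident points at CA (no virtual CB
is reconstructed — degeneracy keeps the count of 9 distances per residue
pair uniform); alanine's centroid is its CB. A residue missing any expected
side-chain heavy atom is a hard error rather than a silently shifted
centroid.

The group table is a single configurable dictionary
(`pocketsim.constants.GROUP_OF`): aliphatic = GLY ALA VAL LEU ILE MET CYS
PRO, aromatic = PHE TYR TRP, polar = SER THR ASN GLN HIS, positive = LYS
ARG, negative = ASP GLU. The placements of HIS (polar), CYS and PRO
(aliphatic) are conventions, not physical constants; scores are sensitive
to them, and studies that care should state the table they used.

For every unordered residue pair the 9 point–point distances are appended
to a bin keyed by the canonicalized ((group, role), (group, role)) pair —
up to 90 bins (15 group pairs × 6 role pairs) — and each bin is sorted
ascending. Intra-residue distances are never included. Two sites are
compared bin-by-bin with a greedy two-pointer walk: heads within the
tolerance match and both advance, otherwise the smaller head advances. The
walk is symmetric in its arguments; exact ties match at any positive
tolerance. The final score divides total matches by the *larger* site's
distance count (max-normalization only), so a small pocket embedded in a
big one does not score as identical.

Parameters: match tolerance 0.5 Å (reflecting thermal motion of real
structures) and similarity threshold 0.5, both exposed but rarely worth
changing; the threshold call is inclusive (score 0.5 → similar).

## Similarity profiles

The profile re-extracts both pockets from scratch at every cutoff on an
inclusive grid (default 3.5–8.0 Å, step 0.5 Å — the step is a declared
default, not a canonical value) and records the PMScore, the residue
counts, and the threshold call. Cutoffs where either pocket has fewer than
two residues yield recorded gaps rather than errors, so profiles over
sparse pockets stay usable; only a fully undefined profile is an error. The
summary reports the longest contiguous similar interval (ties go to smaller
cutoffs). TSV output is byte-deterministic for identical inputs.

## Site alignment and consensus

Residues are abstracted into typed pseudocenters from a fixed table
(`pocketsim.alignment.PSEUDOCENTER_RULES`): aromatic ring centroids (PHE
TYR TRP HIS), side-chain centroids for aliphatics (including the aliphatic
portions of LYS and ARG), donor points at side-chain nitrogens (LYS ARG TRP
ASN GLN), acceptor points at side-chain oxygens (ASP GLU ASN GLN), and
mixed donor/acceptor points at hydroxyls and the HIS imidazole (SER THR TYR
HIS). HIS contributes an aromatic and a donor/acceptor center; ASN/GLN
contribute a donor and an acceptor.

Pairwise alignment enumerates all property-compatible point triplets whose
intra-triplet distances agree within ε, superposes each candidate by
least-squares rotation (Kabsch), and scores it by greedy closest-first
one-to-one matching of property-compatible points within ε. The best
transform maximizes matched pairs, with ties broken by lower matched-pair
RMSD, then by enumeration order — fully deterministic. Exhaustive triplet
search replaces a geometric-hashing index deliberately: at pocket scale
(tens of pseudocenters) it is exact and fast enough, and far easier to
verify. An exact upper-bound prune (points with any in-range compatible
partner) skips candidates that cannot beat the incumbent without changing
the result. Near-coincident triplets (point separation < 0.5 Å) are skipped
as they define no stable frame.

Multiple alignment is a star: every site is pairwise-aligned onto the
first, and a correspondence tuple exists where a first-site pseudocenter
found a partner in *every* other site. The score is the tuple count; ε
defaults to 3.0 Å (a declared default — no canonical matching radius
exists for pseudocenter alignment).

Consensus generation merges each tuple whose members share the same coarse
class (polar / non-polar / positive / negative, derived from the five-group
table with aromatic+aliphatic collapsing to non-polar) into one point at
the mean transformed position; all other pseudocenters are preserved
unchanged in the reference frame. Merging operates at pseudocenter level
but carries residue identity in the output, and the partition is exact:
every input pseudocenter lands in merged or preserved exactly once (a
tested invariant). This deterministic merge rule replaces any manual
curation step — curation cannot be an operation of a reproducible pipeline.

## Synthetic data

The generator emulates ligand-lining pockets: an abstract ligand of ~20
heavy atoms (HET code "SBX") drawn uniformly in a 3 Å-radius ball, and
residues whose CA positions are sampled so their minimum distance to the
ligand lies in a stated radius band (default 3.5–7.0 Å, 15 residues, crude
3.5 Å CA–CA clash guard, bounded rejection sampling). Side chains are built
from ideal-geometry templates (the chemical component dictionary bundled
with biotite) at random orientations, so generated residues are always
complete. The ligand is a geometric stand-in, not a real molecule: PMScore
and the alignment read only ligand atom positions, never chemistry.

Perturbation operators create controlled relatedness: i.i.d. Gaussian
coordinate noise per protein atom (the ligand stays fixed so pocket
re-extraction remains comparable), within- or cross-group residue
substitutions rebuilt from templates in the original backbone frame, and
rigid motions applied jointly to protein and ligand. Families share a core
pocket, independently perturbed per site, plus per-site private residues in
an outer band; ground truth (core/private membership per site) is returned
as a record and written as a JSON sidecar by the CLI — tests read the
sidecar rather than re-deriving it.

Two named fixture designs cover the recurring experiments:

- **`make_shell_pair`**: a conserved aliphatic inner shell (CA min-distance
  3.5–4.8 Å, so the full core is present in both pockets by 5 Å) plus
  chemically divergent outer shells — compact polar residues (SER/THR) in
  one site, compact negative residues (ASP/GLU) in the other, at
  7.8–9.5 Å so their side chains cannot reach the inner region. Divergent
  outer chemistry is how "randomized surroundings" must be realized for the
  profile to be decisive: it removes the shared distance bins beyond the
  core, so the profile collapses (scores ~0.15–0.25 at 7.5–8 Å) instead of
  hovering near the threshold on chance matches.
- **`make_recovery_family`**: an all-aliphatic core of k residues (each
  emitting exactly one pseudocenter, so the planted core has exactly k
  alignable points) plus per-site private shells confined to one property
  class each, all absent from the core and from the other sites' privates.
  With a 3 Å matching radius, chance-congruent triplets among
  property-compatible private points otherwise tie or beat the true core
  superposition; property-disjoint privates make exact k-point recovery
  the uniquely correct answer rather than the likely one.

What passing tests on this data do *not* show: real pockets have backbone
connectivity, packed (not independently sampled) side chains, rotamer
statistics, partial occupancy and missing atoms. The generator makes no
claim to physical realism (no clash removal beyond the CA guard, no
energies); it provides controlled geometry and chemistry with known ground
truth, which is what the pipeline's correctness arguments need.

## Numerical choices and limitations

- Study sizes used by the tests and the reproduction script — 200 pockets
  (2–30 residues) for identity/symmetry, 100 motions for invariance checks,
  50 replicates per noise level, 102 alignment-recovery replicates — were
  chosen as the smallest sizes at which the statistical contracts are
  stable; all run in well under a minute each on one CPU.
- Noise decay is measured on the standard workflow: pockets re-extracted at
  the 4.0 Å default cutoff from both the original and perturbed structures,
  so noise also moves residues across the pocket boundary, exactly as it
  would in a docking-based study. Measured means over 50 seeds:
  1.000 / 0.886 / 0.604 / 0.446 / 0.346 for σ = 0 / 0.2 / 0.5 / 1.0 / 2.0 Å
  (seed 1 of the reproduction script): monotone, exactly 1 at σ = 0,
  below the 0.5 similarity call by σ = 1 Å.
- PMScore between *unrelated* pockets of equal size and composition does not
  vanish: sorted order statistics of broadly similar distance distributions
  match at ~0.25–0.45 under a 0.5 Å tolerance. The 0.5 threshold should be
  interpreted against this baseline, and no null model is provided — scores
  carry no significance statement.
- Rotation fitting uses scipy's `Rotation.align_vectors`; collinear
  triplets give a non-unique optimum, any minimiser of which is accepted.
- Floating-point determinism: identical inputs give bit-identical scores,
  transforms and serialized outputs on a fixed platform; the golden-output
  contract is defined for a fixed software stack, not across BLAS builds.
- The alignment score is a plain matched-tuple count; no weighting by
  property or distance is applied.
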