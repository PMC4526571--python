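"""Distance-scan similarity profile of a conserved-core pocket pair.

The two pockets share an inner shell near the ligand but have chemically
divergent outer shells. The profile recomputes the PMScore at pocket
cutoffs from 3.5 to 8 A and shows the similarity is confined to the
region the two sites genuinely share.
"""

from pocketsim import make_shell_pair, pocket_ligand, similarity_profile, summarize_profile

(site_a, site_b), truth = make_shell_pair(seed=1)
profile = similarity_profile(
    site_a, pocket_ligand(site_a), site_b, pocket_ligand(site_b)
)

print("cutoff_A  score   n_a  n_b  similar")
for p in profile.points:
    score = "  .  " if p.score is None else f"{p.score:.3f}"
    print(f"  {p.cutoff:4.1f}    {score}  {p.n_res_a:3d}  {p.n_res_b:3d}  {p.similar}")

summary = summarize_profile(profile)
print(f"\nverdict: {summary.verdict}")
print(f"(planted core: {truth['core_size']} shared residues within ~5 A of the ligand)")

# Scores above 0.5 mark cutoffs where the pockets look alike; the fall-off
# past ~6 A shows the similarity does not extend into the divergent shells.
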