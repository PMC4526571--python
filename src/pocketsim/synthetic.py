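"""Seeded synthetic protein-ligand pockets with controlled similarity.

Real polypharmacology comparisons start from docked or modelled complexes
that are rarely deposited; this module replaces them with fully reproducible
stand-ins. A pocket is a loose shell of residues around an abstract
heavy-atom ligand cluster (HET code "SBX"): residue side chains are built
from ideal-geometry templates (the chemical component dictionary bundled
with biotite), placed with the alpha carbon at a controlled distance from
the ligand and oriented randomly. Perturbation operators then create pairs
or families of pockets with known relatedness: Gaussian coordinate noise,
within- or cross-group residue substitutions, rigid motions, and
shared-core/private-shell families with ground truth recorded alongside.

Everything is driven by explicit integer seeds; identical specs produce
byte-identical structures.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

import biotite.structure.info as struc_info

from .constants import STANDARD_RESIDUES
from .errors import GenerationError
from .structure import Atom, LigandPose, Residue, Structure

LIGAND_CODE = "SBX"
_LIGAND_RADIUS = 3.0  # A, radius of the ball holding the ligand atom cluster
_MIN_CA_SEPARATION = 3.5  # A, crude clash guard between placed residues
_MAX_PLACEMENT_TRIES = 500

_ALL_RESIDUES = tuple(sorted(STANDARD_RESIDUES))


@dataclass(frozen=True)
class PocketSpec:
    """Recipe for one synthetic pocket.

    The defaults emulate a ligand-lining shell: ~15 residues whose alpha
    carbons sit 3.5-7 A from the nearest ligand heavy atom, around a
    20-heavy-atom ligand, drawn uniformly from the 20 standard residues.
    """

    n_residues: int = 15
    radius_band: tuple[float, float] = (3.5, 7.0)
    residue_palette: tuple[str, ...] = _ALL_RESIDUES
    palette_weights: tuple[float, ...] | None = None
    ligand_n_atoms: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_residues < 2:
            raise ValueError("n_residues must be >= 2")
        lo, hi = self.radius_band
        if not 0 < lo < hi:
            raise ValueError("radius_band must satisfy 0 < min < max")
        if not self.residue_palette:
            raise ValueError("residue_palette must be non-empty")
        unknown = set(self.residue_palette) - STANDARD_RESIDUES
        if unknown:
            raise ValueError(f"non-standard residues in palette: {sorted(unknown)}")


@dataclass(frozen=True)
class PerturbSpec:
    """Recipe for perturbing a pocket: noise, substitutions, rigid motion."""

    sigma: float = 0.0
    mutation_rate: float = 0.0
    cross_group: bool = True
    rigid: tuple[np.ndarray, np.ndarray] | None = None  # (R, t), applied last
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if not 0 <= self.mutation_rate <= 1:
            raise ValueError("mutation_rate must be in [0, 1]")


_template_cache: dict[str, tuple[list[str], list[str], np.ndarray]] = {}


def _template(res_name: str) -> tuple[list[str], list[str], np.ndarray]:
    """Ideal-geometry heavy atoms of a residue, coordinates centered on CA."""
    if res_name not in _template_cache:
        arr = struc_info.residue(res_name)
        keep = (arr.element != "H") & (arr.atom_name != "OXT")
        names = list(arr.atom_name[keep])
        elements = list(arr.element[keep])
        coords = np.asarray(arr.coord[keep], dtype=float)
        coords = coords - coords[names.index("CA")]
        _template_cache[res_name] = (names, elements, coords)
    return _template_cache[res_name]


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    return Rotation.from_quat(q / np.linalg.norm(q)).as_matrix()


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def random_rigid(rng: np.random.Generator, max_translation: float = 20.0) -> tuple[np.ndarray, np.ndarray]:
    """A uniformly random rotation plus a bounded random translation."""
    return _random_rotation(rng), rng.uniform(-max_translation, max_translation, 3)


def _build_residue(
    res_name: str, chain_id: str, res_seq: int, ca_pos: np.ndarray, rot: np.ndarray
) -> Residue:
    names, elements, coords = _template(res_name)
    placed = coords @ rot.T + ca_pos
    atoms = [
        Atom(name=n, element=e, coord=c)
        for n, e, c in zip(names, elements, placed)
    ]
    return Residue(res_name, chain_id, res_seq, atoms)


def _make_ligand(rng: np.random.Generator, n_atoms: int) -> Residue:
    # uniform in a ball of radius _LIGAND_RADIUS at the origin
    dirs = rng.normal(size=(n_atoms, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    radii = _LIGAND_RADIUS * rng.uniform(0, 1, n_atoms) ** (1 / 3)
    coords = dirs * radii[:, None]
    atoms = [
        Atom(name=f"C{i + 1}", element="C", coord=c, is_hetero=True)
        for i, c in enumerate(coords)
    ]
    return Residue(LIGAND_CODE, "L", 900, atoms)


def _sample_type(rng: np.random.Generator, spec: PocketSpec) -> str:
    if spec.palette_weights is None:
        idx = rng.integers(len(spec.residue_palette))
    else:
        w = np.asarray(spec.palette_weights, dtype=float)
        idx = rng.choice(len(spec.residue_palette), p=w / w.sum())
    return spec.residue_palette[int(idx)]


def _place_cas(
    rng: np.random.Generator,
    lig_coords: np.ndarray,
    n: int,
    band: tuple[float, float],
    existing: list[np.ndarray],
) -> list[np.ndarray]:
    """Sample CA positions whose min distance to the ligand lies in `band`."""
    lo, hi = band
    placed: list[np.ndarray] = []
    for _ in range(n):
        for _attempt in range(_MAX_PLACEMENT_TRIES):
            anchor = lig_coords[rng.integers(len(lig_coords))]
            ca = anchor + rng.uniform(lo, hi) * _random_unit(rng)
            min_d = cdist(ca[None, :], lig_coords).min()
            if min_d < lo:  # min_d <= hi holds by construction
                continue
            others = existing + placed
            if others and cdist(ca[None, :], np.stack(others)).min() < _MIN_CA_SEPARATION:
                continue
            placed.append(ca)
            break
        else:
            raise GenerationError(
                f"could not place residue {len(placed) + 1}/{n} in band {band} "
                f"after {_MAX_PLACEMENT_TRIES} tries"
            )
    return placed


def generate_pocket(spec: PocketSpec, start_seq: int = 1, chain_id: str = "A") -> Structure:
    """Build one synthetic pocket structure (residues + SBX ligand)."""
    rng = np.random.default_rng(spec.seed)
    ligand = _make_ligand(rng, spec.ligand_n_atoms)
    lig_coords = np.stack([a.coord for a in ligand.atoms])
    cas = _place_cas(rng, lig_coords, spec.n_residues, spec.radius_band, [])
    residues = []
    for i, ca in enumerate(cas):
        res_name = _sample_type(rng, spec)
        residues.append(
            _build_residue(res_name, chain_id, start_seq + i, ca, _random_rotation(rng))
        )
    st = Structure(residues=residues)
    st.hetero_groups[(LIGAND_CODE, "L", 900)] = ligand
    return st


def pocket_ligand(structure: Structure) -> LigandPose:
    """The SBX ligand pose of a generated structure."""
    grp = structure.hetero_groups[
        next(k for k in structure.hetero_groups if k[0] == LIGAND_CODE)
    ]
    return LigandPose(code=LIGAND_CODE, atoms=grp.heavy_atoms())


def _backbone_frame_rotation(template_coords, template_names, residue: Residue) -> np.ndarray:
    """Rotation aligning a template's local backbone frame onto a residue's."""
    ca = residue.atom("CA").coord
    pairs_t, pairs_r = [], []
    for name in ("N", "C", "CB"):
        atom = residue.atom(name)
        if atom is None or name not in template_names:
            continue
        vt = template_coords[template_names.index(name)]
        vr = atom.coord - ca
        pairs_t.append(vt / np.linalg.norm(vt))
        pairs_r.append(vr / np.linalg.norm(vr))
    rot, _ = Rotation.align_vectors(np.stack(pairs_r), np.stack(pairs_t))
    return rot.as_matrix()


def _substitute(residue: Residue, new_name: str) -> Residue:
    names, elements, coords = _template(new_name)
    rot = _backbone_frame_rotation(coords, names, residue)
    return _build_residue(
        new_name, residue.chain_id, residue.res_seq, residue.atom("CA").coord, rot
    )


def _mutation_target(rng: np.random.Generator, res_name: str, cross_group: bool) -> str:
    from .constants import GROUP_OF

    group = GROUP_OF[res_name]
    if cross_group:
        pool = [r for r in _ALL_RESIDUES if GROUP_OF[r] is not group]
    else:
        pool = [r for r in _ALL_RESIDUES if GROUP_OF[r] is group and r != res_name]
    return pool[int(rng.integers(len(pool)))]


def perturb_pocket(structure: Structure, spec: PerturbSpec) -> Structure:
    """Apply substitutions, coordinate noise, and an optional rigid motion.

    Substitutions rebuild the side chain from the replacement type's ideal
    template in the original residue's backbone frame; noise is i.i.d.
    Gaussian per protein-atom coordinate (the ligand is left untouched so
    pocket re-extraction stays comparable); the rigid motion, if any, moves
    protein and ligand jointly and is applied last.
    """
    rng = np.random.default_rng(spec.seed)
    residues = list(structure.residues)
    n = len(residues)
    n_mut = round(spec.mutation_rate * n)
    if n_mut:
        chosen = sorted(int(i) for i in rng.choice(n, size=n_mut, replace=False))
        for i in chosen:
            residues[i] = _substitute(
                residues[i], _mutation_target(rng, residues[i].res_name, spec.cross_group)
            )
    out_res = []
    for res in residues:
        coords = np.stack([a.coord for a in res.atoms])
        noisy = coords + rng.normal(0.0, spec.sigma, coords.shape) if spec.sigma > 0 else coords
        out_res.append(
            Residue(
                res.res_name,
                res.chain_id,
                res.res_seq,
                [replace(a, coord=c) for a, c in zip(res.atoms, noisy)],
            )
        )
    hetero = {
        k: Residue(g.res_name, g.chain_id, g.res_seq, list(g.atoms))
        for k, g in structure.hetero_groups.items()
    }
    out = Structure(residues=out_res, hetero_groups=hetero)
    if spec.rigid is not None:
        R, t = spec.rigid
        for res in out.residues:
            res.atoms = [replace(a, coord=R @ a.coord + t) for a in res.atoms]
        for grp in out.hetero_groups.values():
            grp.atoms = [replace(a, coord=R @ a.coord + t) for a in grp.atoms]
    return out


def make_core_family(
    core_spec: PocketSpec,
    n_sites: int,
    private_spec: PocketSpec | None = None,
    perturb: PerturbSpec | None = None,
    private_palettes: tuple[tuple[str, ...], ...] | None = None,
) -> tuple[list[Structure], dict]:
    """A family of pockets sharing a perturbed core plus private residues.

    Emulates the situation where unrelated receptors present the same inner
    shell to a ligand but diverge further out. Returns the structures and a
    ground-truth record naming the planted core and private residues of
    every site; downstream tests should trust the record, not re-derive it.

    `private_palettes`, if given, assigns each site its own private residue
    palette (overriding `private_spec.residue_palette`); choosing chemically
    disjoint palettes makes the planted core the only cross-site signal,
    which is what an unambiguous alignment ground truth requires.
    """
    if n_sites < 2:
        raise ValueError("n_sites must be >= 2")
    perturb = perturb or PerturbSpec()
    core = generate_pocket(core_spec)
    core_seqs = [r.res_seq for r in core.residues]
    structures: list[Structure] = []
    truth_sites = []
    for s in range(n_sites):
        site = perturb_pocket(core, replace(perturb, seed=(perturb.seed + s) % 2**31))
        private_seqs: list[int] = []
        if private_spec is not None and private_spec.n_residues > 0:
            site_spec = private_spec
            if private_palettes is not None:
                site_spec = replace(
                    private_spec,
                    residue_palette=tuple(private_palettes[s % len(private_palettes)]),
                    palette_weights=None,
                )
            rng = np.random.default_rng((private_spec.seed + 7919 * (s + 1)) % 2**31)
            lig_coords = np.stack([a.coord for a in pocket_ligand(site).atoms])
            existing = [r.atom("CA").coord for r in site.residues]
            cas = _place_cas(
                rng, lig_coords, site_spec.n_residues, site_spec.radius_band, existing
            )
            for i, ca in enumerate(cas):
                seq = 101 + i
                res_name = _sample_type(rng, site_spec)
                site.residues.append(
                    _build_residue(res_name, "A", seq, ca, _random_rotation(rng))
                )
                private_seqs.append(seq)
        structures.append(site)
        truth_sites.append(
            {
                "label": f"site{s}",
                "core_res_seqs": list(core_seqs),
                "private_res_seqs": private_seqs,
            }
        )
    ground_truth = {
        "n_sites": n_sites,
        "core_size": len(core_seqs),
        "core_res_seqs": list(core_seqs),
        "sites": truth_sites,
    }
    return structures, ground_truth


# ---------------------------------------------------------------------------
# Named study fixtures
#
# Two recurring experimental designs, packaged so that tests, examples and
# reproduction scripts share one definition.

#: Aliphatic-only core: every core residue emits exactly one pseudocenter,
#: so a k-residue core plants exactly k alignable points.
RECOVERY_CORE_PALETTE = ("LEU", "VAL", "ILE", "MET", "PRO", "ALA")

#: One private property class per site, all absent from the core and from
#: each other, so the planted core is the only cross-site signal and the
#: alignment ground truth is unambiguous.
RECOVERY_PRIVATE_PALETTES = (("PHE",), ("ASP", "GLU"), ("SER", "THR"))


def make_recovery_family(
    k: int, seed: int, sigma: float = 0.3, n_sites: int = 3, n_private: int = 3
) -> tuple[list[Structure], dict]:
    """Triple of pockets with a planted k-point alignment core.

    Core residues are aliphatic (one pseudocenter each); each site adds
    `n_private` residues in an outer shell drawn from a per-site property
    class disjoint from everything else, so exact core recovery is the
    correct answer, not just the likely one.
    """
    core = PocketSpec(
        n_residues=k, radius_band=(3.5, 6.0),
        residue_palette=RECOVERY_CORE_PALETTE, seed=seed,
    )
    private = PocketSpec(
        n_residues=n_private, radius_band=(7.5, 10.5), seed=(seed + 104729) % 2**31,
    )
    perturb = PerturbSpec(sigma=sigma, seed=(seed + 15485863) % 2**31)
    return make_core_family(
        core, n_sites, private, perturb, private_palettes=RECOVERY_PRIVATE_PALETTES
    )


#: Shell-pair design: a shared aliphatic inner shell, plus chemically
#: divergent outer shells (polar in one site, negative in the other) of
#: compact residues whose side chains cannot reach the inner region.
SHELL_CORE_PALETTE = ("LEU", "VAL", "ILE", "ALA", "PRO", "CYS", "MET")
SHELL_OUTER_PALETTES = (("SER", "THR"), ("ASP", "GLU"))


def make_shell_pair(
    seed: int, sigma: float = 0.3, n_core: int = 8, n_outer: int = 12
) -> tuple[list[Structure], dict]:
    """Pocket pair similar near the ligand but divergent further out.

    The conserved core lies within ~5 A of the ligand; the outer shells
    (7.8-9.5 A) differ in chemistry between the two sites, so a similarity
    profile stays above threshold at inner cutoffs and falls well below it
    once the scan reaches the divergent surroundings.
    """
    core = PocketSpec(
        n_residues=n_core, radius_band=(3.5, 4.8),
        residue_palette=SHELL_CORE_PALETTE, seed=seed,
    )
    outer = PocketSpec(
        n_residues=n_outer, radius_band=(7.8, 9.5), seed=(seed + 104729) % 2**31,
    )
    perturb = PerturbSpec(sigma=sigma, seed=(seed + 15485863) % 2**31)
    return make_core_family(core, 2, outer, perturb, private_palettes=SHELL_OUTER_PALETTES)
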