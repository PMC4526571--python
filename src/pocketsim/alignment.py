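"""Multiple binding-site alignment and consensus-site generation.

Each pocket residue is abstracted into *pseudocenters*: 3-D points labelled
with one of five physicochemical capabilities (hydrogen-bond donor,
acceptor, mixed donor/acceptor, hydrophobic aliphatic, aromatic). Two sites
are aligned by searching property-compatible point triplets with congruent
internal distances, superposing each candidate triplet by least squares
(Kabsch), and keeping the rigid transform that lets the most pseudocenters
pair up within a matching radius. Several sites are combined by a star
alignment onto the first site, and positions matched across *all* sites with
a consistent coarse chemistry (polar / non-polar / positive / negative) are
merged into a consensus binding site; everything else is carried through
unchanged, so no pseudocenter is ever lost.

The triplet search is exhaustive rather than hash-indexed: at pocket scale
(a few tens of pseudocenters) exhaustive enumeration is exact, deterministic
and fast enough, which matters more here than asymptotics.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from .constants import GROUP_OF, PHYSCHEM_CLASS_OF_GROUP
from .errors import IncompleteResidueError, TooSmallSiteError
from .structure import BindingSite, Residue

__all__ = [
    "PCProp",
    "Pseudocenter",
    "SiteAlignment",
    "ConsensusPoint",
    "ConsensusSite",
    "pseudocenters",
    "pairwise_align",
    "multiple_align",
    "consensus_site",
    "write_consensus",
    "read_consensus_json",
]


class PCProp(Enum):
    """Physicochemical property carried by a pseudocenter."""

    DONOR = "DON"
    ACCEPTOR = "ACC"
    DONOR_ACCEPTOR = "DAC"
    ALIPHATIC = "ALI"
    AROMATIC = "ARO"


#: Per-residue pseudocenter recipe: (property, atoms averaged for the point).
#: A residue may emit several centers (e.g. TYR: aromatic ring + hydroxyl).
PSEUDOCENTER_RULES: dict[str, tuple[tuple[PCProp, tuple[str, ...]], ...]] = {
    "GLY": ((PCProp.ALIPHATIC, ("CA",)),),
    "ALA": ((PCProp.ALIPHATIC, ("CB",)),),
    "VAL": ((PCProp.ALIPHATIC, ("CB", "CG1", "CG2")),),
    "LEU": ((PCProp.ALIPHATIC, ("CB", "CG", "CD1", "CD2")),),
    "ILE": ((PCProp.ALIPHATIC, ("CB", "CG1", "CG2", "CD1")),),
    "MET": ((PCProp.ALIPHATIC, ("CB", "CG", "SD", "CE")),),
    "CYS": ((PCProp.ALIPHATIC, ("CB", "SG")),),
    "PRO": ((PCProp.ALIPHATIC, ("CB", "CG", "CD")),),
    "PHE": ((PCProp.AROMATIC, ("CG", "CD1", "CD2", "CE1", "CE2", "CZ")),),
    "TYR": (
        (PCProp.AROMATIC, ("CG", "CD1", "CD2", "CE1", "CE2", "CZ")),
        (PCProp.DONOR_ACCEPTOR, ("OH",)),
    ),
    "TRP": (
        (PCProp.AROMATIC, ("CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2")),
        (PCProp.DONOR, ("NE1",)),
    ),
    "HIS": (
        (PCProp.AROMATIC, ("CG", "ND1", "CD2", "CE1", "NE2")),
        (PCProp.DONOR_ACCEPTOR, ("ND1", "NE2")),
    ),
    "SER": ((PCProp.DONOR_ACCEPTOR, ("OG",)),),
    "THR": ((PCProp.DONOR_ACCEPTOR, ("OG1",)),),
    "ASN": ((PCProp.DONOR, ("ND2",)), (PCProp.ACCEPTOR, ("OD1",))),
    "GLN": ((PCProp.DONOR, ("NE2",)), (PCProp.ACCEPTOR, ("OE1",))),
    "LYS": (
        (PCProp.ALIPHATIC, ("CB", "CG", "CD", "CE")),
        (PCProp.DONOR, ("NZ",)),
    ),
    "ARG": (
        (PCProp.ALIPHATIC, ("CB", "CG", "CD")),
        (PCProp.DONOR, ("NE", "NH1", "NH2")),
    ),
    "ASP": ((PCProp.ACCEPTOR, ("OD1", "OD2")),),
    "GLU": ((PCProp.ACCEPTOR, ("OE1", "OE2")),),
}


@dataclass(frozen=True)
class Pseudocenter:
    coord: np.ndarray
    prop: PCProp
    residue_key: tuple[str, int, str]
    site_label: str = ""

    def physchem_class(self) -> str:
        return PHYSCHEM_CLASS_OF_GROUP[GROUP_OF[self.residue_key[2]]]


def _residue_pseudocenters(res: Residue, site_label: str) -> list[Pseudocenter]:
    out = []
    for prop, atom_names in PSEUDOCENTER_RULES[res.res_name]:
        coords = []
        for name in atom_names:
            atom = res.atom(name)
            if atom is None:
                raise IncompleteResidueError(
                    f"{res.res_name} {res.chain_id}{res.res_seq}: missing atom {name} "
                    f"for {prop.name} pseudocenter"
                )
            coords.append(atom.coord)
        out.append(
            Pseudocenter(
                coord=np.mean(coords, axis=0),
                prop=prop,
                residue_key=res.key,
                site_label=site_label,
            )
        )
    return out


def pseudocenters(site: BindingSite) -> list[Pseudocenter]:
    """Emit the typed pseudocenters of every residue in the site, in order."""
    label = site.source_label or "site"
    out: list[Pseudocenter] = []
    for res in site.residues:
        out.extend(_residue_pseudocenters(res, label))
    return out


@dataclass
class SiteAlignment:
    """Rigid transforms into the first site's frame plus matched tuples."""

    transforms: list[tuple[np.ndarray, np.ndarray]]  # (R, t): x_ref = R @ x + t
    correspondences: list[tuple[int, ...]]  # pseudocenter indices, one per site
    score: int
    epsilon: float
    rmsd: float | None  # RMSD over matched pairs/tuples in the reference frame


_IDENTITY = (np.eye(3), np.zeros(3))


def _apply(transform: tuple[np.ndarray, np.ndarray], coords: np.ndarray) -> np.ndarray:
    R, t = transform
    return coords @ R.T + t


def _greedy_match(
    xa: np.ndarray, props_a: list[PCProp], yb: np.ndarray, props_b: list[PCProp],
    epsilon: float,
) -> list[tuple[int, int, float]]:
    """Closest-first one-to-one matching of property-compatible points."""
    d = cdist(xa, yb)
    compat = np.array(
        [[pa is pb for pb in props_b] for pa in props_a], dtype=bool
    )
    cand = np.argwhere(compat & (d <= epsilon))
    order = sorted(range(len(cand)), key=lambda k: (d[cand[k, 0], cand[k, 1]], cand[k, 0], cand[k, 1]))
    used_a: set[int] = set()
    used_b: set[int] = set()
    matched = []
    for k in order:
        i, j = int(cand[k, 0]), int(cand[k, 1])
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        matched.append((i, j, float(d[i, j])))
    return matched


def _kabsch(xa: np.ndarray, xb: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rigid transform taking points xb onto xa."""
    ca = xa.mean(axis=0)
    cb = xb.mean(axis=0)
    with warnings.catch_warnings():
        # collinear triplets give a non-unique optimum; any minimiser is fine
        warnings.simplefilter("ignore", UserWarning)
        rot, _ = Rotation.align_vectors(xa - ca, xb - cb)
    R = rot.as_matrix()
    return R, ca - R @ cb


def pairwise_align(
    a: list[Pseudocenter], b: list[Pseudocenter], epsilon: float = 3.0
) -> SiteAlignment:
    """Best rigid superposition of pseudocenter set b onto set a.

    Exhaustive search over property-compatible, distance-congruent point
    triplets; each candidate transform is scored by greedy closest-first
    matching within `epsilon`. The winner maximizes matched pairs, with ties
    broken by lower matched-pair RMSD, then by enumeration order, so the
    result is deterministic.
    """
    if len(a) < 3 or len(b) < 3:
        raise TooSmallSiteError(
            f"pairwise alignment needs >= 3 pseudocenters per site (got {len(a)}, {len(b)})"
        )
    xa = np.stack([p.coord for p in a])
    xb = np.stack([p.coord for p in b])
    props_a = [p.prop for p in a]
    props_b = [p.prop for p in b]
    by_prop_b: dict[PCProp, list[int]] = {}
    for j, p in enumerate(props_b):
        by_prop_b.setdefault(p, []).append(j)

    da = cdist(xa, xa)
    db = cdist(xb, xb)

    best: tuple[int, float, int] | None = None  # (score, rmsd, candidate index)
    best_result: tuple[tuple[np.ndarray, np.ndarray], list[tuple[int, int, float]]] | None = None
    n_candidates = 0

    for i, j, k in itertools.combinations(range(len(a)), 3):
        # Degenerate (near-coincident) triplets give unstable frames.
        if min(da[i, j], da[i, k], da[j, k]) < 0.5:
            continue
        for bi in by_prop_b.get(props_a[i], ()):
            for bj in by_prop_b.get(props_a[j], ()):
                if bj == bi or abs(da[i, j] - db[bi, bj]) > epsilon:
                    continue
                for bk in by_prop_b.get(props_a[k], ()):
                    if bk == bi or bk == bj:
                        continue
                    if (
                        abs(da[i, k] - db[bi, bk]) > epsilon
                        or abs(da[j, k] - db[bj, bk]) > epsilon
                    ):
                        continue
                    n_candidates += 1
                    transform = _kabsch(
                        xa[[i, j, k]], xb[[bi, bj, bk]]
                    )
                    yb = _apply(transform, xb)
                    # Upper bound on the greedy score: rows with any
                    # compatible partner in range. Skipping candidates that
                    # cannot reach the incumbent changes nothing downstream.
                    if best is not None:
                        d = cdist(xa, yb)
                        ub = 0
                        for ia in range(len(a)):
                            row = by_prop_b.get(props_a[ia], ())
                            if row and d[ia, row].min() <= epsilon:
                                ub += 1
                        if ub < best[0]:
                            continue
                    matched = _greedy_match(xa, props_a, yb, props_b, epsilon)
                    score = len(matched)
                    rmsd = (
                        float(np.sqrt(np.mean([m[2] ** 2 for m in matched])))
                        if matched
                        else float("inf")
                    )
                    if best is None or (score, -rmsd) > (best[0], -best[1]):
                        best = (score, rmsd, n_candidates)
                        best_result = (transform, matched)

    if best_result is None or best[0] == 0:
        return SiteAlignment(
            transforms=[_IDENTITY, _IDENTITY],
            correspondences=[],
            score=0,
            epsilon=epsilon,
            rmsd=None,
        )
    transform, matched = best_result
    return SiteAlignment(
        transforms=[_IDENTITY, transform],
        correspondences=[(m[0], m[1]) for m in matched],
        score=best[0],
        epsilon=epsilon,
        rmsd=best[1],
    )


def multiple_align(
    sites: list[list[Pseudocenter]], epsilon: float = 3.0
) -> SiteAlignment:
    """Star alignment of every site onto the first.

    A correspondence tuple exists where a first-site pseudocenter found a
    property-compatible partner within epsilon in *every* other site's
    pairwise alignment. With two sites this reduces to pairwise_align.
    """
    if len(sites) < 2:
        raise TooSmallSiteError("multiple alignment needs at least 2 sites")
    if len(sites) == 2:
        return pairwise_align(sites[0], sites[1], epsilon)
    aligns = []
    for k, site in enumerate(sites[1:], start=1):
        try:
            aligns.append(pairwise_align(sites[0], site, epsilon))
        except TooSmallSiteError as exc:
            label = site[0].site_label if site else f"site {k}"
            raise TooSmallSiteError(f"{label}: {exc}") from None
    maps = [dict(al.correspondences) for al in aligns]
    tuples: list[tuple[int, ...]] = []
    sq_dev_sum, n_dev = 0.0, 0
    for i0 in range(len(sites[0])):
        if all(i0 in m for m in maps):
            tup = (i0,) + tuple(m[i0] for m in maps)
            tuples.append(tup)
    transforms = [_IDENTITY] + [al.transforms[1] for al in aligns]
    # RMSD of matched members about their tuple mean, in the reference frame
    for tup in tuples:
        coords = np.stack(
            [_apply(transforms[s], sites[s][idx].coord) for s, idx in enumerate(tup)]
        )
        sq_dev_sum += float(np.sum((coords - coords.mean(axis=0)) ** 2))
        n_dev += len(tup)
    rmsd = float(np.sqrt(sq_dev_sum / n_dev)) if n_dev else None
    return SiteAlignment(
        transforms=transforms,
        correspondences=tuples,
        score=len(tuples),
        epsilon=epsilon,
        rmsd=rmsd,
    )


@dataclass(frozen=True)
class ConsensusPoint:
    """One merged consensus position shared by all aligned sites."""

    coord: np.ndarray
    prop: PCProp
    physchem_class: str
    members: tuple[tuple[str, tuple[str, int, str]], ...]  # (site_label, residue_key)


@dataclass
class ConsensusSite:
    merged: list[ConsensusPoint]
    preserved: list[Pseudocenter]  # coordinates already in the reference frame
    n_sites: int


def consensus_site(alignment: SiteAlignment, sites: list[list[Pseudocenter]]) -> ConsensusSite:
    """Merge class-consistent correspondence tuples; preserve the rest.

    Every input pseudocenter ends up in exactly one of merged or preserved;
    preserved points are carried through in the reference frame so the
    consensus is a single coherent object.
    """
    n_sites = len(sites)
    transforms = alignment.transforms
    in_merged: list[set[int]] = [set() for _ in range(n_sites)]
    merged: list[ConsensusPoint] = []
    for tup in alignment.correspondences:
        members = [sites[s][idx] for s, idx in enumerate(tup)]
        classes = {m.physchem_class() for m in members}
        if len(classes) != 1:
            continue  # class-inconsistent tuple: members stay preserved
        coords = np.stack(
            [_apply(transforms[s], sites[s][idx].coord) for s, idx in enumerate(tup)]
        )
        merged.append(
            ConsensusPoint(
                coord=coords.mean(axis=0),
                prop=members[0].prop,
                physchem_class=classes.pop(),
                members=tuple((m.site_label, m.residue_key) for m in members),
            )
        )
        for s, idx in enumerate(tup):
            in_merged[s].add(idx)
    preserved: list[Pseudocenter] = []
    for s, site in enumerate(sites):
        for idx, pc in enumerate(site):
            if idx in in_merged[s]:
                continue
            preserved.append(
                Pseudocenter(
                    coord=_apply(transforms[s], pc.coord),
                    prop=pc.prop,
                    residue_key=pc.residue_key,
                    site_label=pc.site_label,
                )
            )
    return ConsensusSite(merged=merged, preserved=preserved, n_sites=n_sites)


def write_consensus(consensus: ConsensusSite, fmt: str = "pdb", header: list[str] | None = None) -> str:
    """Serialize a consensus site.

    The PDB dialect writes one HETATM pseudo-atom per point; the residue
    name encodes the property (ARO/ALI/DON/ACC/DAC) and the B-factor the
    number of contributing sites (merged points carry the full site count,
    preserved points 1).
    """
    if fmt == "pdb":
        lines = [f"REMARK 300 {h}" for h in (header or [])]
        serial = 1
        for point in consensus.merged:
            x, y, z = point.coord
            lines.append(
                f"HETATM{serial:5d}  C   {point.prop.value:>3} M{serial:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{float(consensus.n_sites):6.2f}           C"
            )
            serial += 1
        for pc in consensus.preserved:
            x, y, z = pc.coord
            lines.append(
                f"HETATM{serial:5d}  C   {pc.prop.value:>3} P{serial:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{1.0:6.2f}           C"
            )
            serial += 1
        lines.append("END")
        return "\n".join(lines) + "\n"
    if fmt == "json":
        doc = {
            "n_sites": consensus.n_sites,
            "merged": [
                {
                    "coord": [float(v) for v in p.coord],
                    "prop": p.prop.name,
                    "physchem_class": p.physchem_class,
                    "members": [
                        {"site": lab, "residue": list(key)} for lab, key in p.members
                    ],
                }
                for p in consensus.merged
            ],
            "preserved": [
                {
                    "coord": [float(v) for v in pc.coord],
                    "prop": pc.prop.name,
                    "residue": list(pc.residue_key),
                    "site": pc.site_label,
                }
                for pc in consensus.preserved
            ],
        }
        if header:
            doc["provenance"] = header
        return json.dumps(doc, indent=2, sort_keys=True) + "\n"
    raise ValueError(f"unknown consensus format {fmt!r}")


def read_consensus_json(text: str) -> ConsensusSite:
    """Inverse of ``write_consensus(..., fmt='json')``."""
    doc = json.loads(text)
    merged = [
        ConsensusPoint(
            coord=np.array(p["coord"]),
            prop=PCProp[p["prop"]],
            physchem_class=p["physchem_class"],
            members=tuple(
                (m["site"], (m["residue"][0], int(m["residue"][1]), m["residue"][2]))
                for m in p["members"]
            ),
        )
        for p in doc["merged"]
    ]
    preserved = [
        Pseudocenter(
            coord=np.array(p["coord"]),
            prop=PCProp[p["prop"]],
            residue_key=(p["residue"][0], int(p["residue"][1]), p["residue"][2]),
            site_label=p["site"],
        )
        for p in doc["preserved"]
    ]
    return ConsensusSite(merged=merged, preserved=preserved, n_sites=doc["n_sites"])
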