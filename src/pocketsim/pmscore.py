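"""PocketMatch-style binding-site similarity (PMScore).

Each pocket residue is reduced to three points — the alpha carbon, the beta
carbon, and the side-chain centroid — and classified into one of five
chemical groups (aliphatic, aromatic, polar, positive, negative). For every
unordered residue pair all nine point-point distances are collected into
bins keyed by the (group, point-role) pair, each bin sorted ascending. Two
pockets are compared bin-by-bin with a greedy two-pointer walk that counts
heads agreeing within a tolerance (0.5 A by default, reflecting thermal
breathing of real structures); the PMScore is the matched count divided by
the larger pocket's total distance count. A score of 0.5 or more is read as
"similar".

The representation is sequence-order-free and invariant under rigid motion
of either pocket, which is the property that makes it usable for comparing
pockets of unrelated proteins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .constants import (
    BACKBONE_ATOMS,
    GROUP_OF,
    SIDE_CHAIN_ATOMS,
    ChemicalGroup,
)
from .errors import (
    ClassificationError,
    ContractViolationError,
    IncompleteResidueError,
    TooSmallSiteError,
)
from .structure import BindingSite, Residue

#: Point roles, in the fixed canonical order used for bin keys.
POINT_ROLES = ("CA", "CB", "CEN")

#: A bin key: canonicalized pair of (group, point-role) labels.
BinKey = tuple[tuple[str, str], tuple[str, str]]


def classify_residue(res_name: str) -> ChemicalGroup:
    """Map a standard 3-letter residue code to its five-way chemical group."""
    try:
        return GROUP_OF[res_name]
    except KeyError:
        raise ClassificationError(f"unknown residue code {res_name!r}") from None


@dataclass(frozen=True)
class ResidueTriplet:
    """The three-point geometric reduction of one residue."""

    p_ca: np.ndarray
    p_cb: np.ndarray
    p_cen: np.ndarray
    group: ChemicalGroup
    residue_key: tuple[str, int, str]

    def points(self) -> np.ndarray:
        return np.stack([self.p_ca, self.p_cb, self.p_cen])


def residue_points(residue: Residue) -> ResidueTriplet:
    """Compute (CA, CB, side-chain centroid) for one residue.

    Glycine degenerates to three coincident points at CA; alanine's centroid
    is its CB. Residues missing any expected side-chain heavy atom are
    rejected outright: a centroid computed over a partial side chain would
    silently shift every distance it participates in.
    """
    name = residue.res_name
    group = classify_residue(name)
    ca = residue.atom("CA")
    if ca is None:
        raise IncompleteResidueError(f"{name} {residue.chain_id}{residue.res_seq}: missing CA")
    p_ca = ca.coord
    if name == "GLY":
        return ResidueTriplet(p_ca, p_ca, p_ca, group, residue.key)
    cb = residue.atom("CB")
    if cb is None:
        raise IncompleteResidueError(f"{name} {residue.chain_id}{residue.res_seq}: missing CB")
    expected = SIDE_CHAIN_ATOMS[name]
    present = {a.name for a in residue.heavy_atoms()}
    missing = [n for n in expected if n not in present]
    if missing:
        raise IncompleteResidueError(
            f"{name} {residue.chain_id}{residue.res_seq}: missing side-chain atoms {missing}"
        )
    side = [a.coord for a in residue.heavy_atoms() if a.name not in BACKBONE_ATOMS]
    p_cen = np.mean(side, axis=0)
    return ResidueTriplet(p_ca, cb.coord, p_cen, group, residue.key)


@dataclass
class DistanceLists:
    """Sorted intra-site distances, binned by (group, point-role) pairs."""

    bins: dict[BinKey, np.ndarray]
    total: int


def _canonical_key(g1: ChemicalGroup, r1: int, g2: ChemicalGroup, r2: int) -> BinKey:
    a = (g1.value, r1)
    b = (g2.value, r2)
    if b < a:
        a, b = b, a
    return ((ChemicalGroup(a[0]).name, POINT_ROLES[a[1]]),
            (ChemicalGroup(b[0]).name, POINT_ROLES[b[1]]))


def build_distance_lists(site: BindingSite) -> DistanceLists:
    """All 9 * C(n,2) inter-residue point distances, binned and sorted.

    Intra-residue distances are never included; only pairs of distinct
    residues contribute.
    """
    triplets = [residue_points(r) for r in site.residues]
    n = len(triplets)
    if n < 2:
        raise TooSmallSiteError(
            f"site {site.source_label or '<unnamed>'} has {n} residue(s); need >= 2"
        )
    pts = np.stack([t.points() for t in triplets])  # (n, 3 roles, 3 xyz)
    g = np.array([t.group.value for t in triplets])
    iu, ju = np.triu_indices(n, k=1)

    # Encode each (group, role) endpoint as g*3 + role; a bin is the sorted
    # endpoint pair, flattened to lo*15 + hi. Ordered role pairs over i<j
    # enumerate each of the 9 per-pair distances exactly once.
    dist_parts: list[np.ndarray] = []
    code_parts: list[np.ndarray] = []
    for r1 in range(3):
        for r2 in range(3):
            d = cdist(pts[:, r1, :], pts[:, r2, :])[iu, ju]
            a = g[iu] * 3 + r1
            b = g[ju] * 3 + r2
            lo = np.minimum(a, b)
            hi = np.maximum(a, b)
            dist_parts.append(d)
            code_parts.append(lo * 15 + hi)
    dists = np.concatenate(dist_parts)
    codes = np.concatenate(code_parts)
    order = np.argsort(codes, kind="stable")
    codes, dists = codes[order], dists[order]
    bins: dict[BinKey, np.ndarray] = {}
    uniq, starts = np.unique(codes, return_index=True)
    bounds = list(starts) + [len(codes)]
    for code, lo_i, hi_i in zip(uniq, bounds[:-1], bounds[1:]):
        lo_ep, hi_ep = divmod(int(code), 15)
        key = _canonical_key(
            ChemicalGroup(lo_ep // 3), lo_ep % 3, ChemicalGroup(hi_ep // 3), hi_ep % 3
        )
        bins[key] = np.sort(dists[lo_i:hi_i])
    total = int(sum(len(v) for v in bins.values()))
    return DistanceLists(bins=bins, total=total)


def match_sorted_lists(a, b, tol: float) -> int:
    """Greedy two-pointer alignment of two ascending distance lists.

    While both lists have unconsumed heads: heads within `tol` match and both
    advance; otherwise the smaller head advances alone. Symmetric in its
    arguments, and exact ties always match for any positive tolerance.
    """
    if tol <= 0:
        raise ValueError("tolerance must be positive")
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if np.any(np.diff(a) < 0) or np.any(np.diff(b) < 0):
        raise ContractViolationError("match_sorted_lists requires ascending input")
    i = j = matches = 0
    na, nb = len(a), len(b)
    while i < na and j < nb:
        if abs(a[i] - b[j]) <= tol:
            matches += 1
            i += 1
            j += 1
        elif a[i] < b[j]:
            i += 1
        else:
            j += 1
    return matches


@dataclass(frozen=True)
class PMScoreResult:
    """PMScore with its bookkeeping: matched count and both list sizes."""

    score: float
    matches: int
    n_a: int
    n_b: int
    tolerance: float


def pmscore(site_a: BindingSite, site_b: BindingSite, tol: float = 0.5) -> PMScoreResult:
    """Compare two binding sites; score = matches / max(total_a, total_b)."""
    try:
        lists_a = build_distance_lists(site_a)
    except TooSmallSiteError as exc:
        raise TooSmallSiteError(f"site A: {exc}") from None
    try:
        lists_b = build_distance_lists(site_b)
    except TooSmallSiteError as exc:
        raise TooSmallSiteError(f"site B: {exc}") from None
    empty = np.empty(0)
    keys = sorted(set(lists_a.bins) | set(lists_b.bins))
    matches = sum(
        match_sorted_lists(lists_a.bins.get(k, empty), lists_b.bins.get(k, empty), tol)
        for k in keys
    )
    score = matches / max(lists_a.total, lists_b.total)
    return PMScoreResult(
        score=score, matches=matches, n_a=lists_a.total, n_b=lists_b.total, tolerance=tol
    )


def classify_similar(result: PMScoreResult, threshold: float = 0.5) -> bool:
    """Similarity call: PMScore at or above the threshold counts as similar."""
    return result.score >= threshold
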