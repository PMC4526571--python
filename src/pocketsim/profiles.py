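"""Distance-scanning similarity profiles.

A single PMScore at one pocket cutoff says whether two sites look alike at
that radius; a *similarity profile* scans the pocket-defining distance from
the ligand (3.5-8.0 A by default) and recomputes the score at each cutoff,
showing at which distances — if any — the two sites are similar, and whether
the similarity is confined to the immediate ligand shell or extends into the
surrounding fold. The pocket is re-extracted from scratch at every cutoff;
nothing is accumulated between grid points.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

from .errors import EmptyProfileError, EmptySiteError
from .pmscore import pmscore
from .structure import LigandPose, Structure, extract_pocket


@dataclass(frozen=True)
class ProfilePoint:
    """PMScore (or an undefined gap) at one pocket cutoff."""

    cutoff: float
    score: float | None
    n_res_a: int
    n_res_b: int
    similar: bool


@dataclass
class SimilarityProfile:
    """Ordered profile points plus the parameters that produced them."""

    points: list[ProfilePoint]
    threshold: float
    tolerance: float
    labels: tuple[str, str] = ("A", "B")

    def defined_points(self) -> list[ProfilePoint]:
        return [p for p in self.points if p.score is not None]


@dataclass(frozen=True)
class ProfileSummary:
    interval: tuple[float, float] | None
    score_min: float
    score_max: float
    score_mean: float
    verdict: str


def _grid(min_cutoff: float, max_cutoff: float, step: float) -> list[float]:
    n = int((max_cutoff - min_cutoff) / step + 1e-9) + 1
    return [round(min_cutoff + k * step, 10) for k in range(n)]


def _pocket_size(structure: Structure, ligand: LigandPose, cutoff: float):
    try:
        site = extract_pocket(structure, ligand, cutoff)
        return site, len(site)
    except EmptySiteError:
        return None, 0


def similarity_profile(
    struct_a: Structure,
    lig_a: LigandPose,
    struct_b: Structure,
    lig_b: LigandPose,
    min_cutoff: float = 3.5,
    max_cutoff: float = 8.0,
    step: float = 0.5,
    tol: float = 0.5,
    threshold: float = 0.5,
    labels: tuple[str, str] = ("A", "B"),
) -> SimilarityProfile:
    """PMScore versus pocket cutoff over an inclusive arithmetic grid.

    Cutoffs where either pocket has fewer than two residues yield a recorded
    gap (score None, similar False) rather than aborting; only a profile
    with no defined point at all is an error.
    """
    if min_cutoff >= max_cutoff:
        raise ValueError("min_cutoff must be below max_cutoff")
    if step <= 0:
        raise ValueError("step must be positive")
    points: list[ProfilePoint] = []
    for cutoff in _grid(min_cutoff, max_cutoff, step):
        site_a, n_a = _pocket_size(struct_a, lig_a, cutoff)
        site_b, n_b = _pocket_size(struct_b, lig_b, cutoff)
        if n_a < 2 or n_b < 2:
            points.append(ProfilePoint(cutoff, None, n_a, n_b, False))
            continue
        result = pmscore(site_a, site_b, tol=tol)
        points.append(
            ProfilePoint(cutoff, result.score, n_a, n_b, result.score >= threshold)
        )
    if not any(p.score is not None for p in points):
        raise EmptyProfileError("no cutoff on the grid yielded two scoreable pockets")
    return SimilarityProfile(points=points, threshold=threshold, tolerance=tol, labels=labels)


def summarize_profile(profile: SimilarityProfile) -> ProfileSummary:
    """Longest contiguous similar interval plus score statistics.

    Ties between equally long similar runs go to the one at smaller cutoffs.
    """
    best: tuple[int, int] | None = None  # (start, end) indices, inclusive
    run_start = None
    pts = profile.points
    for i, p in enumerate(pts + [ProfilePoint(0.0, None, 0, 0, False)]):
        if p.similar and run_start is None:
            run_start = i
        elif not p.similar and run_start is not None:
            if best is None or (i - run_start) > (best[1] - best[0] + 1):
                best = (run_start, i - 1)
            run_start = None
    scores = [p.score for p in profile.defined_points()]
    interval = (pts[best[0]].cutoff, pts[best[1]].cutoff) if best else None
    if interval:
        verdict = f"similar over [{interval[0]:g}-{interval[1]:g} A]"
    else:
        verdict = "not similar"
    return ProfileSummary(
        interval=interval,
        score_min=min(scores),
        score_max=max(scores),
        score_mean=sum(scores) / len(scores),
        verdict=verdict,
    )


def _profile_dict(profile: SimilarityProfile) -> dict:
    return {
        "labels": list(profile.labels),
        "threshold": profile.threshold,
        "tolerance": profile.tolerance,
        "points": [
            {
                "cutoff": p.cutoff,
                "score": p.score,
                "n_res_a": p.n_res_a,
                "n_res_b": p.n_res_b,
                "similar": p.similar,
            }
            for p in profile.points
        ],
    }


def write_profile(profile: SimilarityProfile, fmt: str = "tsv", header: list[str] | None = None) -> str:
    """Serialize a profile as TSV (one row per cutoff) or JSON."""
    if fmt == "tsv":
        lines = [f"# {h}" for h in (header or [])]
        lines.append("cutoff_A\tscore\tn_res_a\tn_res_b\tsimilar")
        for p in profile.points:
            score = "." if p.score is None else repr(p.score)
            lines.append(
                f"{p.cutoff:g}\t{score}\t{p.n_res_a}\t{p.n_res_b}\t{str(p.similar).lower()}"
            )
        return "\n".join(lines) + "\n"
    if fmt == "json":
        doc = _profile_dict(profile)
        if header:
            doc["provenance"] = header
        return json.dumps(doc, indent=2, sort_keys=True) + "\n"
    raise ValueError(f"unknown profile format {fmt!r}")


def read_profile(text: str, fmt: str = "tsv") -> SimilarityProfile:
    """Inverse of :func:`write_profile` (provenance comments are dropped)."""
    if fmt == "tsv":
        rows = [
            ln.split("\t")
            for ln in text.splitlines()
            if ln and not ln.startswith(("#", "cutoff_A"))
        ]
        points = [
            ProfilePoint(
                cutoff=float(c),
                score=None if s == "." else float(s),
                n_res_a=int(na),
                n_res_b=int(nb),
                similar=(sim == "true"),
            )
            for c, s, na, nb, sim in rows
        ]
        return SimilarityProfile(points=points, threshold=0.5, tolerance=0.5)
    if fmt == "json":
        doc = json.loads(text)
        points = [
            ProfilePoint(p["cutoff"], p["score"], p["n_res_a"], p["n_res_b"], p["similar"])
            for p in doc["points"]
        ]
        return SimilarityProfile(
            points=points,
            threshold=doc["threshold"],
            tolerance=doc["tolerance"],
            labels=tuple(doc["labels"]),
        )
    raise ValueError(f"unknown profile format {fmt!r}")
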