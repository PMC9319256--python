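"""Fragment-docking score aggregation and core-binding-region calling.

Long disordered peptides exceed the reliable degree-of-freedom budget of
docking engines, so the sequence is docked as overlapping seven-residue
fragments (see :func:`bindlab.peptides.make_fragments`).  Each residue's
affinity is the arithmetic mean of the scores of all fragments containing
it, producing a per-residue profile whose minimum locates the core binding
region.  Scores follow the docking convention: kcal/mol, more negative is
more favorable.  Terminal residues are covered by fewer fragments and are
flagged as less accurate.

Docking itself is an external, pluggable backend (`run_backend`): any
callable mapping a Fragment to a (score, pose) pair can drive the pipeline,
and results are cached to CSV so repeated runs are idempotent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Protocol, Sequence

import numpy as np
import pandas as pd

from .peptides import Fragment, PeptideSequence

__all__ = [
    "FragmentScore",
    "ResidueAffinityProfile",
    "DockingConfig",
    "aggregate_per_residue",
    "call_core_region",
    "classify_pose_site",
    "run_backend",
]


@dataclass(frozen=True)
class FragmentScore:
    fragment: Fragment
    score: float  # kcal/mol, most favorable = most negative
    pose_id: str | None = None
    pose_coords: np.ndarray | None = None  # (n_atoms, 3) backbone coordinates

    def __post_init__(self) -> None:
        if not np.isfinite(self.score):
            raise ValueError("score must be finite")


@dataclass(frozen=True)
class ResidueAffinityProfile:
    residue_numbers: np.ndarray  # parent numbering
    mean_scores: np.ndarray  # kcal/mol
    n_fragments: np.ndarray  # covering-fragment count per residue
    terminal_flags: np.ndarray  # True where coverage is below the interior maximum
    core_region: tuple[int, int] | None = None
    core_score: float = np.nan
    warnings: tuple[str, ...] = ()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "residue_number": self.residue_numbers,
                "mean_score": self.mean_scores,
                "n_fragments": self.n_fragments,
                "terminal_flag": self.terminal_flags,
            }
        )


@dataclass(frozen=True)
class DockingConfig:
    box_size: tuple[float, float, float] = (50.0, 90.0, 90.0)  # Å
    box_center: tuple[float, float, float] | None = None  # receptor centroid
    exhaustiveness_multiplier: int = 32
    receptor_structure: str | None = None  # PDB id or path

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.box_size):
            raise ValueError("box dimensions must be positive")


def aggregate_per_residue(
    scores: Sequence[FragmentScore], parent: PeptideSequence
) -> ResidueAffinityProfile:
    """Per-residue mean docking score over all fragments covering each residue."""
    if not scores:
        raise ValueError("no fragment scores supplied")
    p_start, p_end = parent.start_number, parent.end_number
    numbers = np.arange(p_start, p_end + 1)
    totals = np.zeros(numbers.size)
    counts = np.zeros(numbers.size, dtype=int)
    for fs in scores:
        frag = fs.fragment
        off = frag.start_number - p_start
        if off < 0 or off + len(frag) > len(parent):
            raise ValueError(
                f"fragment {frag.residues} ({frag.start_number}-{frag.end_number}) "
                "is outside the parent sequence"
            )
        if parent.residues[off : off + len(frag)] != frag.residues:
            raise ValueError(
                f"fragment {frag.residues} does not match parent at "
                f"residue {frag.start_number}"
            )
        totals[off : off + len(frag)] += fs.score
        counts[off : off + len(frag)] += 1
    covered = counts > 0
    means = np.full(numbers.size, np.nan)
    means[covered] = totals[covered] / counts[covered]
    max_cov = counts.max()
    terminal = covered & (counts < max_cov)
    return ResidueAffinityProfile(
        residue_numbers=numbers[covered],
        mean_scores=means[covered],
        n_fragments=counts[covered],
        terminal_flags=terminal[covered],
    )


def call_core_region(
    profile: ResidueAffinityProfile, margin: float = 0.5
) -> tuple[int, int]:
    """Core binding region: maximal contiguous run within ``margin`` kcal/mol
    of the global minimum of the per-residue profile, parent-numbered.

    If disjoint runs fall within the margin, the one containing the global
    minimum is returned and a warning is issued.  A flat profile yields a
    degenerate full-span call, with a warning.
    """
    nums = profile.residue_numbers
    scores = profile.mean_scores
    if nums.size < 7:
        raise ValueError("profile must cover at least 7 residues")
    if np.ptp(scores) == 0:
        warnings.warn("flat affinity profile: degenerate core-region call",
                      stacklevel=2)
        return int(nums[0]), int(nums[-1])
    imin = int(np.argmin(scores))
    within = scores <= scores[imin] + margin
    # contiguous run containing the global minimum
    lo = imin
    while lo > 0 and within[lo - 1]:
        lo -= 1
    hi = imin
    while hi < nums.size - 1 and within[hi + 1]:
        hi += 1
    if within.sum() > (hi - lo + 1):
        warnings.warn(
            "multiple disjoint regions within margin of the minimum; "
            "returning the one containing the global minimum",
            stacklevel=2,
        )
    return int(nums[lo]), int(nums[hi])


def classify_pose_site(
    pose_coords: np.ndarray,
    major_ref_coords: np.ndarray | None,
    minor_ref_coords: np.ndarray | None = None,
    cutoff: float = 5.0,
) -> tuple[str, float]:
    """Classify a docking pose by proximity to reference crystallographic
    NLS ligands marking the receptor's binding sites.

    Returns (label, min_distance) where label is 'major', 'minor' or 'other'
    and the distance is the minimum backbone-backbone atom distance (Å) to
    the closest classifying reference.
    """
    pose = np.asarray(pose_coords, float)
    if pose.size == 0:
        raise ValueError("pose coordinates are empty")
    if major_ref_coords is None or np.asarray(major_ref_coords).size == 0:
        warnings.warn("no major-site reference supplied: classifying as 'other'",
                      stacklevel=2)
        return "other", np.inf

    def _min_dist(a: np.ndarray, b: np.ndarray) -> float:
        diff = a[:, None, :] - b[None, :, :]
        return float(np.sqrt((diff**2).sum(-1)).min())

    d_major = _min_dist(pose, np.asarray(major_ref_coords, float))
    if d_major <= cutoff:
        return "major", d_major
    if minor_ref_coords is not None and np.asarray(minor_ref_coords).size:
        d_minor = _min_dist(pose, np.asarray(minor_ref_coords, float))
        if d_minor <= cutoff:
            return "minor", d_minor
        return "other", min(d_major, d_minor)
    return "other", d_major


class DockingBackend(Protocol):
    def __call__(self, fragment: Fragment, config: DockingConfig) -> tuple[float, str]:
        """Return (best score in kcal/mol, pose identifier) for a fragment."""


def run_backend(
    fragments: Sequence[Fragment],
    config: DockingConfig,
    backend: DockingBackend | None = None,
    cache_path: str | Path | None = None,
) -> list[FragmentScore]:
    """Score fragments with a docking backend, caching results to CSV.

    If ``cache_path`` exists it is loaded and the backend is not invoked
    (idempotence).  Without a backend and without a cache, a clear error
    names the external requirement: a docking engine (e.g. AutoDock Vina)
    must be wrapped as a callable and passed in.
    """
    columns = ["fragment_id", "start_number", "sequence", "score_kcal_mol", "pose_id"]
    if cache_path is not None and Path(cache_path).exists():
        df = pd.read_csv(cache_path)
        missing = set(columns[:4]) - set(df.columns)
        if missing:
            raise ValueError(f"malformed cache {cache_path}: missing columns {missing}")
        by_start = {int(r.start_number): r for r in df.itertuples()}
        out = []
        for frag in fragments:
            if frag.start_number not in by_start:
                raise ValueError(
                    f"cache {cache_path} has no entry for fragment at "
                    f"{frag.start_number}"
                )
            row = by_start[frag.start_number]
            out.append(FragmentScore(frag, float(row.score_kcal_mol),
                                     pose_id=str(getattr(row, "pose_id", ""))))
        return out
    if backend is None:
        raise RuntimeError(
            "no docking backend available: supply a callable wrapping an external "
            "docking engine (e.g. AutoDock Vina), or a cache CSV of scores"
        )
    out = []
    rows = []
    for i, frag in enumerate(fragments):
        try:
            score, pose_id = backend(frag, config)
        except Exception as exc:
            raise RuntimeError(
                f"docking backend failed on fragment {frag.residues}: {exc}"
            ) from exc
        if not np.isfinite(score):
            raise RuntimeError(
                f"malformed backend output for fragment {frag.residues}: {score!r}"
            )
        out.append(FragmentScore(frag, float(score), pose_id=pose_id))
        rows.append((i, frag.start_number, frag.residues, float(score), pose_id))
    if cache_path is not None:
        pd.DataFrame(rows, columns=columns).to_csv(cache_path, index=False)
    return out
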