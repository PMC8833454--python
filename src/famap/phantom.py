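"""Synthetic phantom cohorts with a known ground truth.

This module fabricates everything the mapping/disconnectome chain consumes:

* a thin, connected white-matter "skeleton" (three orthogonal mid-planes of a
  cubic grid — a slab lattice), an integer parcellation, and a contiguous
  "critical" skeleton sub-region;
* per-subject spherical lesions that depress FA locally, plus Gaussian
  measurement noise;
* behavioural scores driven linearly by the mean FA over the critical region
  (a planted effect with known coefficients), and a nuisance covariate mixed
  to a target correlation with the score;
* straight-line tractograms with exact per-region-pair streamline counts.

Default cohort parameters emulate a chronic left-hemisphere stroke study:
101 subjects, an ABA-2-like score scale (intact subjects score ~48, heavily
lesioned ~30, cutoff 44), a covariate correlated at rho = 0.56 with the
score, white-matter FA ~0.6 with a 0.3 drop inside lesions.

Every generator is a pure function of (parameters, seed).
"""

from __future__ import annotations

import collections
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .exceptions import DegenerateInputError, ParameterError
from .io import (
    SkeletonDataset,
    Tractogram,
    Volume,
    VoxelIndex,
    save_volume,
    voxel_to_world,
    write_streamlines,
)

__all__ = [
    "PhantomAnatomy",
    "PhantomCohort",
    "make_phantom_anatomy",
    "simulate_subject_fa",
    "simulate_scores",
    "simulate_tractogram",
    "make_cohort",
    "write_cohort",
    "recovery_scores",
]

_NEIGHBOURS_26 = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
]


@dataclass(frozen=True)
class PhantomAnatomy:
    """Skeleton mask, parcellation and planted critical region on one grid."""

    skeleton_mask: Volume
    parcellation: Volume
    critical_mask: Volume

    def __post_init__(self) -> None:
        if not self.skeleton_mask.same_geometry(self.parcellation):
            raise ParameterError("parcellation geometry differs from skeleton")
        if not self.skeleton_mask.same_geometry(self.critical_mask):
            raise ParameterError("critical mask geometry differs from skeleton")
        if ((self.critical_mask.data > 0) & (self.skeleton_mask.data == 0)).any():
            raise ParameterError("critical mask must be a subset of the skeleton")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.skeleton_mask.shape

    @property
    def affine(self) -> np.ndarray:
        return self.skeleton_mask.affine

    @property
    def skeleton_index(self) -> VoxelIndex:
        return VoxelIndex.from_mask(self.skeleton_mask)

    @property
    def labels(self) -> np.ndarray:
        values = np.unique(self.parcellation.data)
        return values[values > 0]


@dataclass(frozen=True)
class PhantomCohort:
    """A full synthetic cohort bound to its generating parameters."""

    anatomy: PhantomAnatomy
    lesions: tuple
    fa: SkeletonDataset
    scores: np.ndarray
    covariate: np.ndarray
    effect_beta: float
    noise_sd: float
    seed: int

    def __post_init__(self) -> None:
        n = self.fa.n_subjects
        if not (len(self.lesions) == len(self.scores) == len(self.covariate) == n):
            raise ParameterError("cohort components disagree on subject count")

    @property
    def n_subjects(self) -> int:
        return self.fa.n_subjects


def make_phantom_anatomy(
    shape: tuple[int, int, int] = (16, 16, 16),
    n_parcels: int = 4,
    critical_fraction: float = 0.1,
    seed: int = 0,
) -> PhantomAnatomy:
    """Build the phantom anatomy on a unit-spacing grid.

    The skeleton is the union of the three orthogonal mid-planes of the grid,
    inset by a 2-voxel margin — a connected, thin 3D structure. Parcels are
    ``n_parcels`` contiguous slabs along the first axis (inset by 1 voxel on
    the other axes, leaving background at the borders). The critical region
    is grown by breadth-first search over the skeleton (26-connectivity) from
    a seeded random skeleton voxel until it holds
    ``round(critical_fraction * n_skeleton)`` voxels.
    """
    shape = tuple(int(s) for s in shape)
    if any(s < 8 for s in shape):
        raise ParameterError("each grid dimension must be >= 8")
    if n_parcels < 2:
        raise ParameterError("need at least 2 parcels")
    if n_parcels > shape[0]:
        raise ParameterError("more parcels than first-axis voxels")
    if not 0.0 < critical_fraction < 1.0:
        raise ParameterError("critical_fraction must lie in (0, 1)")

    affine = np.eye(4)
    margin = 2
    skel = np.zeros(shape, dtype=np.int16)
    mids = [s // 2 for s in shape]
    sl = [slice(margin, s - margin) for s in shape]
    skel[mids[0], sl[1], sl[2]] = 1
    skel[sl[0], mids[1], sl[2]] = 1
    skel[sl[0], sl[1], mids[2]] = 1

    parc = np.zeros(shape, dtype=np.int16)
    edges = np.linspace(0, shape[0], n_parcels + 1).astype(int)
    inner = (slice(1, shape[1] - 1), slice(1, shape[2] - 1))
    for label, (lo, hi) in enumerate(zip(edges[:-1], edges[1:]), start=1):
        parc[(slice(lo, hi),) + inner] = label

    rng = np.random.default_rng(seed)
    skel_voxels = np.argwhere(skel > 0)
    target = max(1, round(critical_fraction * len(skel_voxels)))
    start = tuple(skel_voxels[rng.integers(len(skel_voxels))])
    crit = np.zeros(shape, dtype=np.int16)
    in_skel = {tuple(v) for v in skel_voxels}
    queue = collections.deque([start])
    seen = {start}
    grown = 0
    while queue and grown < target:
        vox = queue.popleft()
        crit[vox] = 1
        grown += 1
        for d in _NEIGHBOURS_26:
            nb = (vox[0] + d[0], vox[1] + d[1], vox[2] + d[2])
            if nb in in_skel and nb not in seen:
                seen.add(nb)
                queue.append(nb)

    return PhantomAnatomy(
        skeleton_mask=Volume(skel, affine),
        parcellation=Volume(parc, affine),
        critical_mask=Volume(crit, affine),
    )


def simulate_subject_fa(
    anatomy: PhantomAnatomy,
    lesion_center: tuple[int, int, int],
    lesion_radius: float = 4.0,
    base_fa: float = 0.6,
    lesion_fa_drop: float = 0.3,
    fa_noise_sd: float = 0.02,
    seed: int = 0,
) -> tuple[Volume, np.ndarray]:
    """One subject: a spherical lesion and the FA row over skeleton voxels.

    FA at each skeleton voxel is ``base_fa - lesion_fa_drop`` inside the
    lesion ball and ``base_fa`` outside, plus N(0, fa_noise_sd) noise, clipped
    to [0, 1]. The lesion is the world-mm ball intersected with the grid.
    """
    if lesion_radius <= 0:
        raise ParameterError("lesion_radius must be positive")
    if not 0.0 < base_fa <= 1.0:
        raise ParameterError("base_fa must lie in (0, 1]")
    if not 0.0 <= lesion_fa_drop <= base_fa:
        raise ParameterError("lesion_fa_drop must lie in [0, base_fa]")
    if fa_noise_sd < 0:
        raise ParameterError("fa_noise_sd must be non-negative")

    affine = anatomy.affine
    grid = np.indices(anatomy.shape).reshape(3, -1).T
    world = voxel_to_world(grid, affine)
    centre = voxel_to_world(np.asarray(lesion_center, dtype=float), affine)[0]
    inside = ((world - centre) ** 2).sum(axis=1) <= lesion_radius**2
    lesion = Volume(
        inside.reshape(anatomy.shape).astype(np.int16), affine
    )

    index = anatomy.skeleton_index
    in_lesion = lesion.data[index.as_tuple_index()] > 0
    rng = np.random.default_rng(seed)
    fa_row = base_fa - lesion_fa_drop * in_lesion
    if fa_noise_sd > 0:
        fa_row = fa_row + rng.normal(0.0, fa_noise_sd, size=len(index))
    return lesion, np.clip(fa_row, 0.0, 1.0)


def simulate_scores(
    cohort_fa: SkeletonDataset,
    critical_mask: Volume,
    beta0: float = 12.0,
    beta1: float = 60.0,
    noise_sd: float = 3.0,
    covariate_rho: float = 0.56,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Planted linear effect: score_i = beta0 + beta1 * mean critical FA + eps.

    The covariate shares a latent component with the score so that their
    population correlation is ``covariate_rho``; it is reported on a WAB-like
    scale (mean 60, SD 20).
    """
    if not -1.0 < covariate_rho < 1.0:
        raise ParameterError("covariate_rho must lie in (-1, 1)")
    crit_cols = critical_mask.data[cohort_fa.voxel_index.as_tuple_index()] > 0
    if not crit_cols.any():
        raise DegenerateInputError("critical mask hits no skeleton voxel")
    rng = np.random.default_rng(seed)
    mean_crit = cohort_fa.features[:, crit_cols].mean(axis=1)
    scores = beta0 + beta1 * mean_crit
    if noise_sd > 0:
        scores = scores + rng.normal(0.0, noise_sd, size=len(scores))
    sd = scores.std()
    z = (scores - scores.mean()) / sd if sd > 0 else np.zeros_like(scores)
    latent = covariate_rho * z + np.sqrt(1 - covariate_rho**2) * rng.normal(
        0.0, 1.0, size=len(scores)
    )
    covariate = 60.0 + 20.0 * latent
    return scores, covariate


def simulate_tractogram(
    anatomy: PhantomAnatomy,
    pair_counts: dict,
    waypoint_jitter: float = 0.0,
    step_mm: float = 0.5,
    seed: int = 0,
) -> tuple[Tractogram, np.ndarray]:
    """Streamlines with exact per-pair counts between parcels.

    Each streamline starts at a random voxel centre of parcel ``a``, ends in
    parcel ``b``, and is a straight line resampled at ``step_mm`` spacing with
    optional Gaussian jitter (mm) on interior points only (endpoints stay
    inside their parcels). Returns the tractogram and the ground-truth
    (n_streamlines, 2) array of unordered pairs.
    """
    if waypoint_jitter < 0:
        raise ParameterError("waypoint_jitter must be non-negative")
    labels = set(int(v) for v in anatomy.labels)
    for a, b in pair_counts:
        if int(a) not in labels or int(b) not in labels:
            raise ParameterError(f"pair ({a}, {b}) references unknown labels")

    rng = np.random.default_rng(seed)
    parc = anatomy.parcellation.data
    voxels_of = {
        lab: np.argwhere(parc == lab) for lab in sorted(labels)
    }
    streamlines: list[np.ndarray] = []
    truth: list[tuple[int, int]] = []
    for (a, b) in sorted(pair_counts, key=lambda p: (int(p[0]), int(p[1]))):
        count = int(pair_counts[(a, b)])
        a, b = int(a), int(b)
        for _ in range(count):
            va = voxels_of[a][rng.integers(len(voxels_of[a]))]
            vb = voxels_of[b][rng.integers(len(voxels_of[b]))]
            p0 = voxel_to_world(va, anatomy.affine)[0]
            p1 = voxel_to_world(vb, anatomy.affine)[0]
            dist = float(np.linalg.norm(p1 - p0))
            n_pts = max(2, int(np.ceil(dist / step_mm)) + 1)
            t = np.linspace(0.0, 1.0, n_pts)[:, None]
            line = p0[None, :] * (1 - t) + p1[None, :] * t
            if waypoint_jitter > 0 and n_pts > 2:
                line[1:-1] += rng.normal(0.0, waypoint_jitter, size=(n_pts - 2, 3))
            streamlines.append(line)
            truth.append((min(a, b), max(a, b)))
    return (
        Tractogram(streamlines=tuple(streamlines), affine=anatomy.affine),
        np.asarray(truth, dtype=int).reshape(-1, 2),
    )


def make_cohort(
    anatomy: PhantomAnatomy | None = None,
    n_subjects: int = 101,
    lesion_radius: float = 4.0,
    base_fa: float = 0.6,
    lesion_fa_drop: float = 0.3,
    fa_noise_sd: float = 0.02,
    beta0: float = 12.0,
    beta1: float = 60.0,
    noise_sd: float = 3.0,
    covariate_rho: float = 0.56,
    seed: int = 0,
) -> PhantomCohort:
    """Generate a full cohort: lesions, FA rows, scores and covariate.

    Lesion centres are drawn uniformly over skeleton voxels, so lesions
    overlap the critical region for part of the cohort and scores end up
    negatively associated with lesion load. A ``beta1`` of 0 yields a null
    cohort (scores are pure noise).
    """
    if n_subjects < 3:
        raise ParameterError("need at least 3 subjects")
    root = np.random.SeedSequence(seed)
    anatomy_seed, centre_seed, score_seed, *subject_seeds = [
        int(s.generate_state(1)[0] % (2**31)) for s in root.spawn(3 + n_subjects)
    ]
    if anatomy is None:
        anatomy = make_phantom_anatomy(seed=anatomy_seed)
    index = anatomy.skeleton_index
    centre_rng = np.random.default_rng(centre_seed)
    centres = index.coords[
        centre_rng.integers(len(index), size=n_subjects)
    ]
    lesions = []
    rows = []
    for i in range(n_subjects):
        lesion, row = simulate_subject_fa(
            anatomy,
            lesion_center=tuple(centres[i]),
            lesion_radius=lesion_radius,
            base_fa=base_fa,
            lesion_fa_drop=lesion_fa_drop,
            fa_noise_sd=fa_noise_sd,
            seed=subject_seeds[i],
        )
        lesions.append(lesion)
        rows.append(row)
    fa = SkeletonDataset(
        features=np.stack(rows),
        subject_ids=tuple(f"sub-{i:03d}" for i in range(n_subjects)),
        voxel_index=index,
    )
    scores, covariate = simulate_scores(
        fa,
        anatomy.critical_mask,
        beta0=beta0,
        beta1=beta1,
        noise_sd=noise_sd,
        covariate_rho=covariate_rho,
        seed=score_seed,
    )
    return PhantomCohort(
        anatomy=anatomy,
        lesions=tuple(lesions),
        fa=fa,
        scores=scores,
        covariate=covariate,
        effect_beta=beta1,
        noise_sd=noise_sd,
        seed=seed,
    )


def recovery_scores(sig_volume: Volume, critical_mask: Volume) -> tuple[float, float]:
    """(sensitivity, precision) of a significance mask against the planted truth.

    Sensitivity = fraction of critical voxels declared significant; precision
    = fraction of significant voxels that are critical. Precision is reported
    as NaN when nothing is significant.
    """
    sig = sig_volume.data > 0
    crit = critical_mask.data > 0
    tp = float((sig & crit).sum())
    sens = tp / crit.sum() if crit.sum() else float("nan")
    prec = tp / sig.sum() if sig.sum() else float("nan")
    return sens, prec


def write_cohort(
    cohort: PhantomCohort,
    outdir: str | Path,
    tractogram: Tractogram | None = None,
) -> Path:
    """Write a cohort directory: NIfTI volumes, TSV scores, JSON ground truth."""
    import pandas as pd

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    save_volume(cohort.anatomy.skeleton_mask, outdir / "skeleton_mask.nii.gz")
    save_volume(cohort.anatomy.parcellation, outdir / "parcellation.nii.gz")
    save_volume(cohort.anatomy.critical_mask, outdir / "critical_mask.nii.gz")
    fa_dir = outdir / "fa"
    lesion_dir = outdir / "lesions"
    fa_dir.mkdir(exist_ok=True)
    lesion_dir.mkdir(exist_ok=True)
    from .io import project_map

    for i, sid in enumerate(cohort.fa.subject_ids):
        save_volume(
            project_map(cohort.fa.features[i], cohort.fa.voxel_index, fill=0.0),
            fa_dir / f"{sid}_fa.nii.gz",
        )
        save_volume(cohort.lesions[i], lesion_dir / f"{sid}_lesion.nii.gz")
    pd.DataFrame(
        {
            "subject_id": cohort.fa.subject_ids,
            "score": cohort.scores,
            "covariate": cohort.covariate,
        }
    ).to_csv(outdir / "scores.tsv", sep="\t", index=False)
    with open(outdir / "ground_truth.json", "w") as fh:
        json.dump(
            {
                "effect_beta": cohort.effect_beta,
                "noise_sd": cohort.noise_sd,
                "seed": cohort.seed,
                "n_critical_voxels": int(cohort.anatomy.critical_mask.data.sum()),
            },
            fh,
            indent=2,
        )
    if tractogram is not None:
        write_streamlines(tractogram, outdir / "tractogram.tck")
    return outdir
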