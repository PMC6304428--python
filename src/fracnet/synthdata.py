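"""Synthetic inputs: fractal volumes of known dimension and two-group cohorts.

Two generators cover the pipeline's input surface without any imaging
data:

* deterministic binary volumes whose box-counting dimension is known in
  closed form (Menger sponge ``log 20 / log 3``, solid cube 3, sheet 2,
  line 1), used as oracles for the FD estimator;
* two-group cohorts of per-region FD-like values with planted
  block-structured covariance.  Each block of regions loads on one
  latent Gaussian factor; the patient-like group gets weaker loadings,
  which left-shifts its correlation-coefficient distribution and thins
  its thresholded network — the qualitative group effect the analysis is
  meant to detect.  Age and sex enter as linear nuisance effects so the
  residualization step has real work to do.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .covnet import CohortTable
from .fd3d import LabelVolume

__all__ = [
    "FractalSpec",
    "CohortSpec",
    "BlockSpec",
    "make_fractal",
    "make_cohort",
    "study_cohort_spec",
    "null_cohort_spec",
]

FRACTAL_KINDS = ("menger_sponge", "solid_cube", "plane_sheet", "line")


@dataclass
class FractalSpec:
    """A deterministic binary test volume.

    ``menger_sponge`` at recursion ``level`` L occupies exactly 20**L
    voxels of a (3**L)^3 grid; the other kinds fill a cube, a
    one-voxel-thick sheet, or a one-voxel line of the given ``side``.
    """

    kind: str = "menger_sponge"
    level: int = 3
    side: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in FRACTAL_KINDS:
            raise ValueError(f"kind must be one of {FRACTAL_KINDS}")
        if self.level < 0:
            raise ValueError("level must be non-negative")
        if self.kind == "menger_sponge":
            self.side = 3**self.level
        elif self.side is None:
            self.side = 3**self.level if self.level > 0 else 27
        if self.side < 1:
            raise ValueError("side must be positive")


def _menger(level: int) -> np.ndarray:
    if level == 0:
        return np.ones((1, 1, 1), dtype=bool)
    prev = _menger(level - 1)
    s = prev.shape[0]
    out = np.zeros((3 * s,) * 3, dtype=bool)
    for i in range(3):
        for j in range(3):
            for k in range(3):
                # keep a subcube iff at most one coordinate is central
                if (i == 1) + (j == 1) + (k == 1) <= 1:
                    out[i * s : (i + 1) * s, j * s : (j + 1) * s, k * s : (k + 1) * s] = prev
    return out


def make_fractal(spec: FractalSpec) -> LabelVolume:
    """Binary volume for a fractal spec (label 1 = foreground)."""
    s = spec.side
    if spec.kind == "menger_sponge":
        vox = _menger(spec.level)
    elif spec.kind == "solid_cube":
        vox = np.ones((s, s, s), dtype=bool)
    elif spec.kind == "plane_sheet":
        vox = np.zeros((s, s, s if s >= 3 else 3), dtype=bool)
        vox[:, :, 0] = True
    else:  # line
        vox = np.zeros((s, max(s, 3), max(s, 3)), dtype=bool)
        vox[:, 0, 0] = True
    return LabelVolume(vox.astype(np.int16), (1.0, 1.0, 1.0), {1: spec.kind})


# ---------------------------------------------------------------------------
# cohorts


@dataclass
class BlockSpec:
    """A set of regions sharing one latent factor, with per-group loadings."""

    regions: list[int]
    loading_a: float = 0.9
    loading_b: float = 0.9

    def __post_init__(self) -> None:
        for l in (self.loading_a, self.loading_b):
            if not -1.0 <= l <= 1.0:
                raise ValueError("loadings must lie in [-1, 1]")


@dataclass
class CohortSpec:
    """Generative design for a two-group regional-FD cohort.

    Per subject, region i's value is

        baseline + age_coef_i * age + sex_coef_i * sex
                 + global_loading * G + loading * factor(block of i)
                 + N(0, noise_sd)

    with one standard-normal global factor G per subject (shared by all
    regions, giving the correlation-coefficient distribution its
    positive mean, as a shared anatomical scale factor does in real
    morphometry) and one per block.  Group B uses ``global_loading_b``
    and each block's ``loading_b``; setting those below the group-A
    values plants the group effect: weaker positive covariance
    throughout, which left-shifts group B's coefficient distribution.
    Ages are uniform on [30, 70] years and sex is Bernoulli(0.5),
    matching a middle-aged adult cohort.
    """

    n_regions: int = 97
    n_subjects_per_group: int = 40
    blocks: list[BlockSpec] = field(default_factory=list)
    global_loading_a: float = 0.0
    global_loading_b: float = 0.0
    noise_sd: float = 0.5
    baseline: float = 2.4
    age_coef: float | np.ndarray = -0.002
    sex_coef: float | np.ndarray = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects_per_group < 3:
            raise ValueError("need >= 3 subjects per group (correlation degenerate)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        for g in (self.global_loading_a, self.global_loading_b):
            if not -1.0 <= g <= 1.0:
                raise ValueError("global loadings must lie in [-1, 1]")
        seen: set[int] = set()
        for b in self.blocks:
            if seen & set(b.regions):
                raise ValueError("blocks must be disjoint")
            seen |= set(b.regions)
            if any(r < 0 or r >= self.n_regions for r in b.regions):
                raise ValueError("block region index out of range")


def _one_group(
    spec: CohortSpec, loadings: list[float], global_loading: float, rng, group: str
) -> CohortTable:
    n_r, n_s = spec.n_regions, spec.n_subjects_per_group
    age = rng.uniform(30.0, 70.0, size=n_s)
    sex = rng.integers(0, 2, size=n_s).astype(float)

    values = np.full((n_r, n_s), spec.baseline)
    values += np.broadcast_to(np.asarray(spec.age_coef), (n_r,))[:, None] * age
    values += np.broadcast_to(np.asarray(spec.sex_coef), (n_r,))[:, None] * sex
    values += global_loading * rng.standard_normal(n_s)[None, :]
    for block, loading in zip(spec.blocks, loadings):
        factor = rng.standard_normal(n_s)
        values[np.asarray(block.regions, dtype=int)] += loading * factor
    values += rng.normal(0.0, spec.noise_sd, size=(n_r, n_s))

    regions = [f"R{i:03d}" for i in range(n_r)]
    subjects = [f"{group}{j:02d}" for j in range(n_s)]
    return CohortTable(
        pd.DataFrame(values, index=regions, columns=subjects),
        pd.DataFrame({"age": age, "sex": sex}, index=subjects),
    )


def make_cohort(spec: CohortSpec) -> tuple[CohortTable, CohortTable]:
    """Generate the (group A, group B) cohort pair for a spec.

    Deterministic in ``spec.seed``; each group draws from its own
    substream so the groups are independent but individually
    reproducible.
    """
    root = np.random.SeedSequence(spec.seed)
    ss_a, ss_b = root.spawn(2)
    a = _one_group(spec, [b.loading_a for b in spec.blocks], spec.global_loading_a,
                   np.random.default_rng(ss_a), "A")
    b = _one_group(spec, [b.loading_b for b in spec.blocks], spec.global_loading_b,
                   np.random.default_rng(ss_b), "B")
    return a, b


def study_cohort_spec(
    seed: int = 0,
    loading_a: float = 0.65,
    loading_b: float = 0.36,
    global_loading_a: float = 0.45,
    global_loading_b: float = 0.25,
    n_regions: int = 97,
    n_subjects_per_group: int = 40,
    block_size: int = 10,
    n_blocks: int = 8,
    noise_sd: float = 0.75,
) -> CohortSpec:
    """The default two-group design: 40+40 subjects x 97 regions.

    Eight 10-region blocks carry the planted community covariance on
    top of a global factor shared by every region; the remaining
    regions load on the global factor only.  The loadings put group A's
    mean off-diagonal correlation near 0.16 and its within-block
    correlations above the p = 0.001 significance level at n = 40,
    while group B's uniformly weakened loadings (mean correlation near
    0.09) yield a sparser, more fragmented network — the planted
    analogue of a patient group with degraded structural covariance.
    """
    blocks = [
        BlockSpec(
            regions=list(range(k * block_size, (k + 1) * block_size)),
            loading_a=loading_a,
            loading_b=loading_b,
        )
        for k in range(n_blocks)
        if (k + 1) * block_size <= n_regions
    ]
    return CohortSpec(
        n_regions=n_regions,
        n_subjects_per_group=n_subjects_per_group,
        blocks=blocks,
        global_loading_a=global_loading_a,
        global_loading_b=global_loading_b,
        noise_sd=noise_sd,
        seed=seed,
    )


def null_cohort_spec(
    seed: int = 0,
    n_regions: int = 30,
    n_subjects_per_group: int = 20,
    loading: float = 0.6,
    global_loading: float = 0.3,
    block_size: int = 6,
) -> CohortSpec:
    """A no-group-effect design: both groups share identical parameters.

    Used for calibrating the permutation test's type-I error — any
    significant difference between the two groups is a false positive.
    """
    n_blocks = n_regions // (2 * block_size)
    blocks = [
        BlockSpec(
            regions=list(range(k * block_size, (k + 1) * block_size)),
            loading_a=loading,
            loading_b=loading,
        )
        for k in range(n_blocks)
    ]
    return CohortSpec(
        n_regions=n_regions,
        n_subjects_per_group=n_subjects_per_group,
        blocks=blocks,
        global_loading_a=global_loading,
        global_loading_b=global_loading,
        noise_sd=0.5,
        seed=seed,
    )
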