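"""Sparse-testing allocation designs and seeded calibration/prediction splits.

An ``A/B`` design allocates, per environment, A non-overlapping genotypes
(NOG: each tested in exactly one environment) and B overlapping genotypes
(OG: tested in all T environments). For a given design the calibration set
holds (A+B) x T phenotypes covering A x T + B unique genotypes, an average
of (A + B x T)/(A + B) phenotypes per genotype. Designs with A = 0 realise
the CV1 cross-validation scheme (every predicted genotype is unseen); all
others are CV2-like.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AllocationDesign",
    "DesignMetrics",
    "Partition",
    "design_metrics",
    "enumerate_grid",
    "sample_partition",
    "classify_cv_scheme",
]

Cell = tuple[str, str]  # (genotype id, environment id)


@dataclass(frozen=True)
class AllocationDesign:
    A: int  # non-overlapping genotypes per environment
    B: int  # overlapping genotypes (in every environment)
    T: int = 6

    def __post_init__(self) -> None:
        if self.A < 0 or self.B < 0 or self.T < 1:
            raise ValueError("A >= 0, B >= 0, T >= 1 required")
        if self.A + self.B < 1:
            raise ValueError("A + B must be at least 1")

    @property
    def label(self) -> str:
        return f"{self.A}/{self.B}"


@dataclass(frozen=True)
class DesignMetrics:
    n_phenotypes: int
    n_unique_genotypes: int
    avg_phenotypes_per_genotype: float


@dataclass
class Partition:
    """One realized split of the genotype x environment grid."""

    design: AllocationDesign
    replicate: int
    seed: int
    calibration: set[Cell]
    prediction: set[Cell]
    unused: set[Cell] = field(default_factory=set)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (g, e, role, self.replicate)
            for role, cells in (
                ("calib", self.calibration),
                ("pred", self.prediction),
                ("unused", self.unused),
            )
            for g, e in sorted(cells)
        ]
        return pd.DataFrame(rows, columns=["genotype", "env", "role", "replicate"])


def design_metrics(A: int, B: int, T: int) -> DesignMetrics:
    """Phenotype count, unique-genotype count and mean replication of A/B/T."""
    design = AllocationDesign(A, B, T)  # validates, incl. A+B >= 1
    return DesignMetrics(
        n_phenotypes=(design.A + design.B) * design.T,
        n_unique_genotypes=design.A * design.T + design.B,
        avg_phenotypes_per_genotype=(design.A + design.B * design.T)
        / (design.A + design.B),
    )


def enumerate_grid(
    total_genotypes: int = 186,
    T: int = 6,
    calibration_sizes: tuple[int, ...] = (186, 168, 144, 120, 96, 72),
) -> list[tuple[int, AllocationDesign]]:
    """All (calibration size, design) pairs of the experiment grid.

    Per size the maximal-A design size/T is included, then A steps down
    through the multiples of 4 to zero (B making up the difference), e.g.
    size 186 yields 31/0, 28/3, 24/7, ..., 0/31.
    """
    out: list[tuple[int, AllocationDesign]] = []
    for size in calibration_sizes:
        if size % T != 0:
            raise ValueError(f"calibration size {size} not divisible by T={T}")
        a_max = size // T
        a_values = [a_max] + [a for a in range((a_max - 1) // 4 * 4, -1, -4)]
        for A in a_values:
            out.append((size, AllocationDesign(A, a_max - A, T)))
    return out


def classify_cv_scheme(design: AllocationDesign) -> str:
    """CV1 when no genotype is unique to an environment, else CV2-like."""
    return "CV1" if design.A == 0 else "CV2-like"


def sample_partition(
    design: AllocationDesign,
    genotypes: list[str],
    environments: list[str],
    prediction_size: int = 930,
    seed: int = 0,
    replicate: int = 1,
) -> Partition:
    """Draw one random calibration/prediction/unused split for a design.

    NOG genotypes are a seeded shuffle split into T disjoint groups of A
    (one group per environment); OG genotypes come from the remainder and
    enter every environment. The prediction set is a uniform sample of
    ``prediction_size`` non-calibration cells; leftovers are unused.
    """
    T = len(environments)
    if T != design.T:
        raise ValueError(f"design expects {design.T} environments, got {T}")
    need = design.A * T + design.B
    if need > len(genotypes):
        raise ValueError(
            f"design {design.label} needs {need} genotypes, only "
            f"{len(genotypes)} available"
        )
    n_grid = len(genotypes) * T
    n_calib = (design.A + design.B) * T
    if prediction_size > n_grid - n_calib:
        raise ValueError(
            f"prediction_size {prediction_size} exceeds the {n_grid - n_calib} "
            "non-calibration cells"
        )
    rng = np.random.default_rng(seed)
    order = [genotypes[i] for i in rng.permutation(len(genotypes))]
    calibration: set[Cell] = set()
    for j, env in enumerate(environments):
        for g in order[j * design.A : (j + 1) * design.A]:
            calibration.add((g, env))
    for g in order[design.A * T : design.A * T + design.B]:
        for env in environments:
            calibration.add((g, env))
    rest = sorted(
        {(g, e) for g in genotypes for e in environments} - calibration
    )
    pick = rng.choice(len(rest), size=prediction_size, replace=False)
    prediction = {rest[i] for i in pick}
    unused = set(rest) - prediction
    return Partition(design, replicate, seed, calibration, prediction, unused)
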