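"""Factorial layout of the drought-phenotyping trial.

Two contrasting soybean genotypes (drought-tolerant MUNASQA, susceptible
TJ2049) are grown under well-watered and mild water-deficit conditions, with
the stress imposed at two phenological stages (V3, vegetative; R5, seed fill)
and plants sampled at 0, 4 and 8 days after stress (DAS), ten replicate
plants per cell.  Yield is harvested at maturity from 50 plants per genotype
in each of three arms: control, V3-stress and R5-stress.
"""
from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class StudyDesign:
    """Complete factorial layout plus the random seed of a simulated run."""

    genotypes: tuple[str, ...] = ("MUNASQA", "TJ2049")
    treatments: tuple[str, ...] = ("control", "stress")
    stages: tuple[str, ...] = ("V3", "R5")
    sampling_days: tuple[int, ...] = (0, 4, 8)
    replicates_per_cell: int = 10
    yield_plants_per_arm: int = 50
    yield_arms: tuple[str, ...] = ("control", "V3-stress", "R5-stress")
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("genotypes", "treatments", "stages", "sampling_days", "yield_arms"):
            labels = getattr(self, name)
            if len(set(labels)) != len(labels):
                raise ValueError(f"duplicate labels in {name}: {labels}")
        if self.replicates_per_cell <= 0:
            raise ValueError("replicates_per_cell must be positive")
        if self.yield_plants_per_arm <= 0:
            raise ValueError("yield_plants_per_arm must be positive")

    @property
    def n_cells(self) -> int:
        """Design cells per marker (genotype x treatment x stage x DAS)."""
        return (len(self.genotypes) * len(self.treatments)
                * len(self.stages) * len(self.sampling_days))

    @property
    def records_per_marker(self) -> int:
        """Replicate records per fully-covered marker (240 at defaults)."""
        return self.n_cells * self.replicates_per_cell

    @property
    def yield_rows(self) -> int:
        """Rows of the yield table (300 at defaults)."""
        return len(self.genotypes) * len(self.yield_arms) * self.yield_plants_per_arm

    def cells(self):
        """Iterate (genotype, treatment, stage, das) in canonical order."""
        for g in self.genotypes:
            for t in self.treatments:
                for s in self.stages:
                    for d in self.sampling_days:
                        yield (g, t, s, d)


def build_default_design(seed: int = 0) -> StudyDesign:
    """The trial's default layout: 2 x 2 x 2 x 3 x 10 marker records (n = 240
    per marker) and 2 genotypes x 3 arms x 50 yield rows (n = 300)."""
    return StudyDesign(seed=seed)
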