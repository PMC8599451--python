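"""Synthetic bulk expression matrices with species x age block structure.

The model operates in log2 space: each gene has a baseline level, an
optional per-species offset (drawn for a subset of "species genes" to
create species-level separation), and an adult-vs-neonate log2
fold-change for genes belonging to named maturation sets (per species).
Sample noise is additive Gaussian in log2 space; values are returned as
FPKM (``2**x``), so they are non-negative and ratios of group means
recover the planted fold-changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = ["ExprGroup", "ExprSimSpec", "gen_expression"]


@dataclass(frozen=True)
class ExprGroup:
    species: str
    age: str  # "neonate" or "adult"
    n_samples: int


def _default_groups() -> tuple[ExprGroup, ...]:
    return (
        ExprGroup("acomys", "neonate", 4),
        ExprGroup("acomys", "adult", 4),
        ExprGroup("mus", "neonate", 4),
        ExprGroup("mus", "adult", 4),
    )


def _default_sets(n_genes: int) -> dict[str, tuple[int, ...]]:
    names = ("sarcomere", "cell_junctions", "electron_transport_chain",
             "fatty_acid_metabolism")
    size = min(50, max(1, n_genes // 8))
    return {
        name: tuple(range(i * size, (i + 1) * size)) for i, name in enumerate(names)
    }


@dataclass(frozen=True)
class ExprSimSpec:
    n_genes: int = 2000
    groups: tuple[ExprGroup, ...] = field(default_factory=_default_groups)
    maturation_gene_sets: Mapping[str, Sequence[int]] | None = None
    # set name -> species -> adult-vs-neonate log2 fold change
    effect_log2fc: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    species_gene_frac: float = 0.25  # fraction of genes with a species offset
    species_effect_sd: float = 2.0  # log2 units
    species_effect_min: float = 0.0  # minimum |offset| (guaranteed divergence)
    noise_sd: float = 0.25  # log2 units
    baseline_range: tuple[float, float] = (2.0, 8.0)  # log2 FPKM
    seed: int = 0

    def validate(self) -> None:
        if not self.groups:
            raise ValueError("group list must not be empty")
        for g in self.groups:
            if g.n_samples < 2:
                raise ValueError(
                    f"group {g.species}/{g.age} needs >= 2 samples, got {g.n_samples}"
                )
        for name, idx in (self.maturation_gene_sets or {}).items():
            arr = np.asarray(list(idx))
            if arr.size and arr.max() >= self.n_genes:
                raise ValueError(
                    f"gene set {name!r} references index {arr.max()} >= n_genes"
                )

    def gene_sets(self) -> dict[str, tuple[int, ...]]:
        if self.maturation_gene_sets is None:
            return _default_sets(self.n_genes)
        return {k: tuple(v) for k, v in self.maturation_gene_sets.items()}


def gen_expression(
    spec: ExprSimSpec,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Generate ``(matrix, labels, truth)``.

    ``matrix`` is genes x samples in FPKM; ``labels`` has columns
    sample_id/species/age; ``truth`` records the planted per-set log2
    effects, the species-offset gene indices, and the gene sets used.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    sets = spec.gene_sets()
    n_samples = sum(g.n_samples for g in spec.groups)

    gene_ids = [f"g{i:05d}" for i in range(spec.n_genes)]
    sample_ids, species_lab, age_lab = [], [], []
    for g in spec.groups:
        for i in range(g.n_samples):
            sample_ids.append(f"{g.species}_{g.age}_{i}")
            species_lab.append(g.species)
            age_lab.append(g.age)

    baseline = rng.uniform(*spec.baseline_range, size=spec.n_genes)
    n_species_genes = int(round(spec.species_gene_frac * spec.n_genes))
    species_genes = rng.choice(spec.n_genes, n_species_genes, replace=False)
    species_names = sorted({g.species for g in spec.groups})
    offsets = {
        sp: np.zeros(spec.n_genes) for sp in species_names
    }
    for sp in species_names[1:]:  # first species is the reference
        raw = rng.normal(0.0, spec.species_effect_sd, size=n_species_genes)
        if spec.species_effect_min > 0:
            raw = np.sign(raw) * (spec.species_effect_min + np.abs(raw))
        offsets[sp][species_genes] = raw

    log2 = np.empty((spec.n_genes, n_samples))
    col = 0
    for g in spec.groups:
        mean = baseline + offsets[g.species]
        age_shift = np.zeros(spec.n_genes)
        if g.age == "adult":
            for set_name, per_species in spec.effect_log2fc.items():
                lfc = per_species.get(g.species, 0.0)
                if lfc:
                    age_shift[list(sets[set_name])] += lfc
        for _ in range(g.n_samples):
            noise = (
                rng.normal(0.0, spec.noise_sd, size=spec.n_genes)
                if spec.noise_sd > 0
                else 0.0
            )
            log2[:, col] = mean + age_shift + noise
            col += 1

    matrix = pd.DataFrame(2.0**log2, index=gene_ids, columns=sample_ids)
    labels = pd.DataFrame(
        {"sample_id": sample_ids, "species": species_lab, "age": age_lab}
    )
    truth = {
        "set_effects": {k: dict(v) for k, v in spec.effect_log2fc.items()},
        "species_gene_indices": np.sort(species_genes),
        "gene_sets": sets,
    }
    return matrix, labels, truth
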