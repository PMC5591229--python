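"""Synthetic emission matrices with a planted community structure.

Real leaf-emission series are a superposition of an abruptly changing
pulsatile component and a slowly changing one: most cells are exact zeros
(no emission), a minority sit on a low flat plateau (weak baseline
emission), and a few cells carry large heavy-tailed spikes — a given
compound is emitted in large quantity by only a few species.  The
generator reproduces that marginal structure and concentrates the spikes
in chemistry-coherent blocks: each VOC class is affine to one species
block (e.g. a terpene-emitting block versus a sulfur-compound block), so
the block assignment is a planted partition that a correct
threshold → projection → community-detection pipeline should recover.

A configurable number of species emit nothing at all; after any
binarization they have empty incidence rows and appear as degree-0 nodes
of the plants projection, forming the "isolated" pseudo-block of the
planted truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .community import Partition
from .io import EmissionMatrix

__all__ = ["SynthParams", "SynthDataset", "generate", "default_study_params",
           "ISOLATED_BLOCK"]

#: chemical-class codes cycled over blocks (terpene fragments, sulfur
#: compounds, ketones/aldehydes — the classes that dominate the three
#: emitting communities of the reduced-panel analysis)
BLOCK_CLASSES = ("Tp-f", "SC", "K/Ald")

ISOLATED_BLOCK = "isolated"


@dataclass
class SynthParams:
    """Generator configuration.

    Attributes
    ----------
    n_species, n_vocs:
        Matrix dimensions (species rows, protonated-mass columns).
    block_sizes:
        Sizes of the emitting blocks (planted communities).
    n_isolated:
        Species that emit nothing; ``sum(block_sizes) + n_isolated`` must
        equal ``n_species``.
    voc_block_of:
        VOC column index → block index affinity; default splits columns
        proportionally to block sizes.
    p_zero:
        Probability that a non-affine cell is an exact zero.
    plateau_scale:
        Median of the lognormal low-emission plateau, in ncps.
    spike_prob:
        Probability that a block-affine (species, VOC) cell carries a spike.
    spike_tail:
        Pareto shape of the spike magnitude (heavier tail for smaller
        values).
    spike_location_factor:
        Spike minimum as a multiple of ``plateau_scale``.
    spike_distribution:
        ``"pareto"`` (default) or ``"lognormal"`` for the spike magnitude.
    seed:
        Seed of the single random generator used throughout.
    """

    n_species: int = 109
    n_vocs: int = 30
    block_sizes: tuple[int, ...] = (37, 25, 19)
    n_isolated: int = 28
    voc_block_of: dict[int, int] | None = None
    p_zero: float = 0.95
    plateau_scale: float = 0.1
    plateau_sigma: float = 0.5
    spike_prob: float = 0.6
    spike_tail: float = 1.5
    spike_location_factor: float = 10.0
    spike_distribution: str = "pareto"
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(self.block_sizes) + self.n_isolated != self.n_species:
            raise ValueError("block sizes plus isolated species must sum to n_species")
        for p in (self.p_zero, self.spike_prob):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.spike_tail <= 0:
            raise ValueError("spike_tail must be positive")
        if self.spike_distribution not in ("pareto", "lognormal"):
            raise ValueError("spike_distribution must be 'pareto' or 'lognormal'")

    @property
    def n_blocks(self) -> int:
        return len(self.block_sizes)

    def default_voc_blocks(self) -> dict[int, int]:
        """Split VOC columns into contiguous runs proportional to block size."""
        if self.voc_block_of is not None:
            return dict(self.voc_block_of)
        sizes = np.array(self.block_sizes, dtype=float)
        counts = np.maximum(1, np.round(self.n_vocs * sizes / sizes.sum()).astype(int))
        while counts.sum() > self.n_vocs:
            counts[int(np.argmax(counts))] -= 1
        while counts.sum() < self.n_vocs:
            counts[int(np.argmin(counts))] += 1
        out = {}
        j = 0
        for b, c in enumerate(counts):
            for _ in range(int(c)):
                out[j] = b
                j += 1
        return out


@dataclass
class SynthDataset:
    matrix: EmissionMatrix
    truth: Partition
    params: SynthParams
    isolated_species: list[str] = field(default_factory=list)

    def truth_labels_emitting(self) -> dict[str, int]:
        """Planted labels restricted to the emitting (non-isolated) species."""
        iso = set(self.isolated_species)
        return {s: c for s, c in self.truth.membership.items() if s not in iso}

    def write(self, out_dir) -> None:
        from pathlib import Path

        from .io import write_annotation_table, write_emission_matrix, write_partition

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_emission_matrix(self.matrix, out / "matrix.csv")
        write_annotation_table(self.matrix.family_of, out / "families.tsv",
                               columns=("species", "family"))
        write_annotation_table(self.matrix.chem_class_of, out / "voc_classes.tsv",
                               columns=("voc", "chem_class"))
        write_partition(self.truth, out / "truth.json")
        payload = asdict(self.params)
        payload["block_sizes"] = list(self.params.block_sizes)
        with open(out / "params.json", "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True, default=str)
            fh.write("\n")


def default_study_params(seed: int = 0, selected: bool = True) -> SynthParams:
    """Defaults matching the study scale: 109 species, 28 of them silent,
    three emitting blocks sized like the three detected communities, and a
    30-VOC panel (75 VOCs in full-panel mode)."""
    return SynthParams(n_vocs=30 if selected else 75, seed=seed)


def generate(params: SynthParams) -> SynthDataset:
    """Draw one emission matrix plus its planted partition.

    Cell model: a cell is 0 with probability ``p_zero``, otherwise a
    lognormal plateau draw; block-affine cells additionally gain a
    heavy-tailed spike with probability ``spike_prob``.  The spike floor is
    ``spike_location_factor × plateau_scale``, well clear of the plateau,
    so per-VOC boxplots flag spikes as upper outliers.  Isolated species
    are all-zero rows: they emit no protonated mass at all, which is what
    makes them degree-0 in every thresholded projection.  Fully
    reproducible from ``params.seed``.
    """
    rng = np.random.default_rng(params.seed)
    n_sp, n_voc = params.n_species, params.n_vocs
    voc_block = params.default_voc_blocks()

    species_ids = [f"sp{i + 1:03d}" for i in range(n_sp)]
    voc_ids = [f"PM{33 + 2 * j}" for j in range(n_voc)]

    block_of_species = np.full(n_sp, -1, dtype=int)  # -1 = isolated
    pos = 0
    for b, size in enumerate(params.block_sizes):
        block_of_species[pos:pos + size] = b
        pos += size

    mu = np.log(params.plateau_scale)
    zero_mask = rng.random((n_sp, n_voc)) < params.p_zero
    plateau = rng.lognormal(mean=mu, sigma=params.plateau_sigma, size=(n_sp, n_voc))
    values = np.where(zero_mask, 0.0, plateau)

    affine = np.zeros((n_sp, n_voc), dtype=bool)
    for j in range(n_voc):
        affine[:, j] = block_of_species == voc_block[j]
    spike_mask = affine & (rng.random((n_sp, n_voc)) < params.spike_prob)
    loc = params.spike_location_factor * params.plateau_scale
    if params.spike_distribution == "pareto":
        spikes = loc * (1.0 + rng.pareto(params.spike_tail, size=(n_sp, n_voc)))
    else:
        spikes = loc * rng.lognormal(mean=0.0, sigma=1.0, size=(n_sp, n_voc))
    values = values + np.where(spike_mask, spikes, 0.0)
    values[block_of_species < 0, :] = 0.0  # silent species: no emission at all

    chem = {voc_ids[j]: BLOCK_CLASSES[voc_block[j] % len(BLOCK_CLASSES)]
            for j in range(n_voc)}
    fam = {species_ids[i]: (f"block{block_of_species[i] + 1}"
                            if block_of_species[i] >= 0 else ISOLATED_BLOCK)
           for i in range(n_sp)}
    matrix = EmissionMatrix(
        pd.DataFrame(values, index=species_ids, columns=voc_ids),
        family_of=fam, chem_class_of=chem,
    )
    # planted truth: blocks 0..B-1, plus one pseudo-block for the silent set
    membership = {
        species_ids[i]: (int(block_of_species[i]) if block_of_species[i] >= 0
                         else params.n_blocks)
        for i in range(n_sp)
    }
    truth = Partition(membership, algorithm="planted", seed=params.seed,
                      parameters={"isolated_block": params.n_blocks})
    isolated = [species_ids[i] for i in range(n_sp) if block_of_species[i] < 0]
    return SynthDataset(matrix=matrix, truth=truth, params=params,
                        isolated_species=isolated)
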