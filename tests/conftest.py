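from __future__ import annotations

import numpy as np
import pytest

from sulfsig import Sequence, builtin_pb2sf_motifs
from sulfsig.synth import FamilySpec, PlantedMotifSpec, generate_dataset, generate_family

AA20 = "ACDEFGHIKLMNPQRSTVWY"


@pytest.fixture(scope="session")
def motifs():
    return builtin_pb2sf_motifs()


def build_consensus_candidate(motifs, fill: str = "A", length: int = 510) -> Sequence:
    """Positive control: motif consensus strings at their reference offsets,
    wildcard/optional slots and inter-motif spacers filled with ``fill``."""
    chars = [fill] * length
    for m in motifs:
        for k, p in enumerate(m.positions):
            if p.kind == "fixed":
                chars[m.anchor - 1 + k] = p.allowed[0]
    return Sequence(id="consensus_control", residues="".join(chars))


@pytest.fixture(scope="session")
def consensus_candidate(motifs):
    return build_consensus_candidate(motifs)


@pytest.fixture(scope="session")
def planted_family(motifs):
    """n=200 independent-mutant family with all five motifs planted at their
    reference offsets and conservation targets equal to the motif weights."""
    spec = FamilySpec(
        label="fam",
        n_sequences=200,
        ancestor_length=510,
        planted_motifs=tuple(PlantedMotifSpec(m, offset=m.anchor - 1) for m in motifs),
        seed=0,
    )
    return spec, *generate_family(spec)


@pytest.fixture(scope="session")
def three_family_dataset(motifs):
    """2-O-like family plus two motif-free outgroup families (4-O/6-O-like)."""
    plant = tuple(PlantedMotifSpec(m, offset=m.anchor - 1) for m in motifs)

    def fam(label, seed, planted, positive):
        return FamilySpec(
            label=label, n_sequences=10, ancestor_length=510,
            background_substitution=0.05, planted_motifs=planted,
            positive=positive, seed=seed,
        )

    specs = [
        fam("twoO", 1, plant, True),
        fam("fourO", 2, (), False),
        fam("sixO", 3, (), False),
    ]
    return generate_dataset(specs, inter_family_divergence=0.5, seed=0)


def random_protein(rng: np.random.Generator, length: int, seq_id: str = "rand") -> Sequence:
    return Sequence(id=seq_id, residues="".join(AA20[i] for i in rng.integers(0, 20, length)))
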