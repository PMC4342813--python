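"""Shared fixtures: a synthetic reference and seeded haplotype generators."""

from __future__ import annotations

import numpy as np
import pytest

from mtlineage.codec import (
    FRAME_CR,
    Haplotype,
    ReadingFrame,
    deletion,
    insertion,
    substitution,
)
from mtlineage.reference import synthetic_rcrs


@pytest.fixture(scope="session")
def ref():
    return synthetic_rcrs()


@pytest.fixture(scope="session")
def cr_frame() -> ReadingFrame:
    return FRAME_CR


def make_random_haplotype(
    rng: np.random.Generator,
    frame: ReadingFrame,
    ref,
    n_variants: tuple[int, int] = (0, 12),
    indels: bool = False,
    sample_id: str = "",
    population: str = "",
) -> Haplotype:
    """Random haplotype with distinct variant positions inside the frame."""
    positions = frame.positions()
    k = int(rng.integers(n_variants[0], n_variants[1] + 1))
    chosen = rng.choice(len(positions), size=min(k, len(positions)), replace=False)
    variants = []
    for idx in chosen:
        pos = positions[int(idx)]
        kind = rng.random()
        if indels and kind < 0.15:
            variants.append(deletion(pos))
        elif indels and kind < 0.3:
            variants.append(insertion(pos, 1, str(rng.choice(list("ACGT")))))
        else:
            alts = [b for b in "ACGT" if b != ref.base(pos)]
            variants.append(substitution(pos, str(rng.choice(alts))))
    return Haplotype(tuple(variants), frame, sample_id=sample_id, population=population)


@pytest.fixture()
def random_haplotype(ref, cr_frame):
    def factory(seed: int = 0, **kwargs) -> Haplotype:
        return make_random_haplotype(np.random.default_rng(seed), cr_frame, ref, **kwargs)

    return factory
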