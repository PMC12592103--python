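"""Shared fixtures: small deterministic simulations and matrix builders."""

from __future__ import annotations

import numpy as np
import pytest

from salsel.io import GenotypeMatrix
from salsel.simulate import SimulationConfig, simulate


def make_gm(
    dosage,
    groups=None,
    chrom=None,
    pos=None,
    ref=None,
    alt=None,
    samples=None,
    gq=None,
    dp=None,
) -> GenotypeMatrix:
    """Build a GenotypeMatrix from a dosage array with sensible defaults."""
    dosage = np.asarray(dosage, dtype=np.int8)
    n_var, n_samp = dosage.shape
    samples = samples or [f"s{i:03d}" for i in range(n_samp)]
    if groups is None:
        groups = {s: "A" for s in samples}
    elif isinstance(groups, (list, tuple, np.ndarray)):
        groups = dict(zip(samples, groups))
    return GenotypeMatrix(
        samples=samples,
        chrom=np.array(chrom if chrom is not None else ["chr1"] * n_var, dtype=object),
        pos=np.asarray(pos if pos is not None else np.arange(1, n_var + 1) * 10),
        ref=np.array(ref if ref is not None else ["A"] * n_var, dtype=object),
        alt=np.array(alt if alt is not None else ["G"] * n_var, dtype=object),
        dosage=dosage,
        groups=groups,
        gq=None if gq is None else np.asarray(gq),
        dp=None if dp is None else np.asarray(dp),
    )


TINY = dict(
    n_variants=1500,
    n_genes=40,
    n_chromosomes=4,
    chrom_length=400_000,
    seed=13,
)


@pytest.fixture(scope="session")
def tiny_sim():
    """A small but complete simulated experiment (selection planted)."""
    return simulate(SimulationConfig(**TINY))


@pytest.fixture(scope="session")
def tiny_null_sim():
    """Same dimensions with zero planted effects."""
    cfg = dict(TINY)
    cfg["seed"] = 12
    return simulate(SimulationConfig(effect_size=0.0, **cfg))
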