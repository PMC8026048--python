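"""Synthetic spacer-count datasets with the statistical structure the
pipeline assumes.

Emulates a collection of metagenomes, each contributing some number of
CRISPR arrays whose pooled spacer counts follow a configurable generator
law — by default the truncated power law ``p(i) ∝ i^{-2.57} e^{-0.004 i}``
observed in pooled environmental data.  Non-heavy-tailed negative controls
(lognormal, exponential, rounded Gaussian) are provided for the
model-selection checks.

Per-metagenome sizes are drawn log-uniformly from a configurable range
(default 10–10,000 arrays) so that group-level analyses see the realistic
spread from tiny to large samples; habitats are assigned by a proportion
mix.  Everything is deterministic under the spec's seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from .data_io import HABITATS, SpacerCountDataset
from .distributions import DistributionSpec, sample

__all__ = ["SyntheticSpec", "generate_dataset", "generate_negative_control"]

#: default pooled law of the generated arrays
DEFAULT_GENERATOR = DistributionSpec(
    "truncated_powerlaw", {"alpha": 2.57, "lam": 0.004})

#: log-uniform range of arrays per metagenome when no fixed size is given
DEFAULT_SIZE_RANGE = (10, 10_000)


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic metagenome collection.

    ``arrays_per_metagenome`` may be a fixed integer, an explicit per-group
    sequence, or ``None`` to draw sizes log-uniformly from ``size_range``.
    """

    generator: DistributionSpec = DEFAULT_GENERATOR
    n_metagenomes: int = 100
    arrays_per_metagenome: Union[int, Sequence[int], None] = None
    size_range: tuple = DEFAULT_SIZE_RANGE
    habitat_mix: Optional[dict] = None   # habitat -> proportion; uniform if None
    seed: int = 0

    def __post_init__(self):
        if self.n_metagenomes < 1:
            raise ValueError("n_metagenomes must be >= 1")
        a = self.arrays_per_metagenome
        if isinstance(a, int) and a < 1:
            raise ValueError("arrays_per_metagenome must be >= 1")
        if a is not None and not isinstance(a, int):
            if len(a) != self.n_metagenomes:
                raise ValueError("per-group sizes must match n_metagenomes")
            if any(int(x) < 1 for x in a):
                raise ValueError("all group sizes must be >= 1")
        if self.habitat_mix is not None:
            if abs(sum(self.habitat_mix.values()) - 1.0) > 1e-9:
                raise ValueError("habitat proportions must sum to 1")
            unknown = set(self.habitat_mix) - set(HABITATS)
            if unknown:
                raise ValueError(f"unknown habitats {sorted(unknown)}")
        lo, hi = self.size_range
        if not 1 <= lo <= hi:
            raise ValueError("invalid size_range")


def _group_sizes(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    a = spec.arrays_per_metagenome
    if isinstance(a, int):
        return np.full(spec.n_metagenomes, a)
    if a is not None:
        return np.asarray([int(x) for x in a])
    lo, hi = spec.size_range
    return np.rint(np.exp(rng.uniform(np.log(lo), np.log(hi),
                                      spec.n_metagenomes))).astype(int)


def generate_dataset(spec: SyntheticSpec) -> SpacerCountDataset:
    """Generate one dataset: iid per-array counts from the generator law,
    habitats assigned by the mix, sample ids enumerated ``MG000001``...
    """
    rng = np.random.default_rng(spec.seed)
    sizes = _group_sizes(spec, rng)
    n_total = int(sizes.sum())
    counts = sample(spec.generator, n_total,
                    seed=int(rng.integers(2 ** 31 - 1)))

    if spec.habitat_mix is None:
        habitats = list(HABITATS)
        probs = np.full(len(habitats), 1.0 / len(habitats))
    else:
        habitats = list(spec.habitat_mix)
        probs = np.asarray(list(spec.habitat_mix.values()))
    sample_habitat = rng.choice(habitats, size=spec.n_metagenomes, p=probs)

    sample_ids = np.repeat(
        [f"MG{k + 1:06d}" for k in range(spec.n_metagenomes)], sizes)
    habitat_col = np.repeat(sample_habitat, sizes)
    array_ids = np.concatenate(
        [[f"arr{j + 1:06d}" for j in range(sz)] for sz in sizes])
    return SpacerCountDataset.from_records(
        zip(sample_ids, habitat_col, array_ids, counts.tolist()),
        provenance=f"synthetic:{spec.generator.family}:seed={spec.seed}")


_CONTROL_FAMILIES = ("lognormal", "exponential", "gaussian_rounded")


def generate_negative_control(family: str, params: dict, n: int,
                              seed: int) -> SpacerCountDataset:
    """A single-sample dataset from a non-heavy-tailed control law.

    ``gaussian_rounded`` is a rounded positive normal (mean/sd in params);
    ``lognormal`` and ``exponential`` are the discrete families from the
    fitting module.  Used to check the model-selection step does not call
    everything a power law.
    """
    if family not in _CONTROL_FAMILIES:
        raise ValueError(f"control family must be one of {_CONTROL_FAMILIES}")
    if n < 1:
        raise ValueError("n must be >= 1")
    if family == "gaussian_rounded":
        rng = np.random.default_rng(seed)
        mean, sd = params["mean"], params["sd"]
        if sd <= 0:
            raise ValueError("sd must be > 0")
        draws = np.rint(rng.normal(mean, sd, size=4 * n + 64))
        draws = draws[draws >= 1][:n].astype(np.int64)
        if len(draws) < n:  # pathological mean far below 1
            raise ValueError("rounded-Gaussian control yielded too few counts >= 1")
        counts = draws
    else:
        counts = sample(DistributionSpec(family, params), n, seed=seed)
    return SpacerCountDataset.from_records(
        (("MG000001", "Engineered", f"arr{j + 1:06d}", int(c))
         for j, c in enumerate(counts)),
        provenance=f"synthetic-control:{family}:seed={seed}")
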