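"""Two-condition metabolomics-like data with planted correlation blocks.

The generator emulates the structure of a two-condition targeted-profiling
experiment: ~20-30 variables measured on ~30 samples per condition, where
groups of biochemically coupled metabolites co-vary strongly while the rest
fluctuate independently. Correlated blocks follow a single-factor latent
model

    x_j = sqrt(rho) * f + sqrt(1 - rho) * eps_j,

with f and eps_j standard normal, which gives every within-block pair the
same population correlation rho and unit marginal variance. Some blocks are
shared between the two conditions; others exist in only one, which is what a
downstream difference network should recover. Entries are masked completely
at random at ``missing_rate``.

Everything is reproducible from the spec's seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamatrix import DataMatrix
from .network import EdgeRecord, EdgeTable

__all__ = ["Block", "SyntheticSpec", "simulate_condition",
           "simulate_paired_conditions", "known_truth", "default_spec"]


@dataclass(frozen=True)
class Block:
    """A group of variables sharing one latent factor with correlation rho."""

    variables: tuple
    rho: float = 0.9

    def __post_init__(self) -> None:
        object.__setattr__(self, "variables", tuple(self.variables))
        if not 0 < self.rho < 1:
            raise ValueError("rho must be in (0, 1)")
        if len(set(self.variables)) != len(self.variables):
            raise ValueError("block variables must be unique")
        if len(self.variables) < 2:
            raise ValueError("a block needs at least 2 variables")


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the simulated two-condition experiment.

    ``shared_blocks`` are planted in both conditions; ``specific_a`` /
    ``specific_b`` only in their condition (their variables are measured in
    the other condition too, but uncorrelated there). ``noise_variables``
    are never correlated with anything. Within one condition, block
    memberships must be disjoint.
    """

    n_samples: int = 30
    shared_blocks: tuple = ()
    specific_a: tuple = ()
    specific_b: tuple = ()
    noise_variables: tuple = ()
    noise_sd: float = 1.0
    missing_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "shared_blocks", tuple(self.shared_blocks))
        object.__setattr__(self, "specific_a", tuple(self.specific_a))
        object.__setattr__(self, "specific_b", tuple(self.specific_b))
        object.__setattr__(self, "noise_variables", tuple(self.noise_variables))
        if self.n_samples < 3:
            raise ValueError("n_samples must be at least 3")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        for cond_blocks in (self.blocks_for("a"), self.blocks_for("b")):
            seen: set = set()
            for b in cond_blocks:
                overlap = seen.intersection(b.variables)
                if overlap:
                    raise ValueError(
                        f"block memberships overlap within a condition: {overlap}"
                    )
                seen.update(b.variables)

    def blocks_for(self, condition: str) -> tuple:
        """Blocks active in condition ``"a"`` or ``"b"``."""
        if condition == "a":
            return self.shared_blocks + self.specific_a
        if condition == "b":
            return self.shared_blocks + self.specific_b
        raise ValueError(f"condition must be 'a' or 'b', got {condition!r}")

    @property
    def variable_ids(self) -> list:
        """All variables, in a stable order: blocks first, then noise."""
        out: list = []
        for blocks in (self.shared_blocks, self.specific_a, self.specific_b):
            for b in blocks:
                for v in b.variables:
                    if v not in out:
                        out.append(v)
        for v in self.noise_variables:
            if v not in out:
                out.append(v)
        return out


def default_spec(seed: int = 0) -> SyntheticSpec:
    """The default stated world: 24 variables, 30 samples per condition.

    One shared block of 6 (rho=0.9), one condition-specific block of 5 per
    condition (rho=0.9), 8 unstructured noise variables, 5% missing values.
    """
    return SyntheticSpec(
        n_samples=30,
        shared_blocks=(Block(tuple(f"S{i}" for i in range(1, 7)), rho=0.9),),
        specific_a=(Block(tuple(f"A{i}" for i in range(1, 6)), rho=0.9),),
        specific_b=(Block(tuple(f"B{i}" for i in range(1, 6)), rho=0.9),),
        noise_variables=tuple(f"N{i}" for i in range(1, 9)),
        missing_rate=0.05,
        seed=seed,
    )


def _simulate(spec: SyntheticSpec, condition: str,
              rng: np.random.Generator) -> DataMatrix:
    ids = spec.variable_ids
    n = spec.n_samples
    X = pd.DataFrame(
        rng.normal(scale=spec.noise_sd, size=(n, len(ids))),
        index=[f"{condition}{k+1}" for k in range(n)],
        columns=ids,
    )
    for block in spec.blocks_for(condition):
        f = rng.normal(size=n)
        for var in block.variables:
            eps = rng.normal(size=n)
            X[var] = np.sqrt(block.rho) * f + np.sqrt(1 - block.rho) * eps
    if spec.missing_rate > 0:
        mask = rng.random(size=X.shape) < spec.missing_rate
        X = X.mask(mask)
    return DataMatrix(values=X, condition_label=condition)


def simulate_condition(spec: SyntheticSpec, condition: str = "a") -> DataMatrix:
    """Simulate one condition's samples x variables matrix, seeded by the spec."""
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed).spawn(2)[
        0 if condition == "a" else 1])
    return _simulate(spec, condition, rng)


def simulate_paired_conditions(spec: SyntheticSpec) -> tuple[DataMatrix, DataMatrix]:
    """Simulate both conditions with independent sampling noise.

    Shared blocks are correlated in both matrices; condition-specific blocks
    only in theirs, so the difference network of the fitted condition
    networks should recover (mostly) the specific blocks' edges.
    """
    ss_a, ss_b = np.random.SeedSequence(spec.seed).spawn(2)
    a = _simulate(spec, "a", np.random.default_rng(ss_a))
    b = _simulate(spec, "b", np.random.default_rng(ss_b))
    return a, b


def known_truth(spec: SyntheticSpec, condition: str | None = None) -> EdgeTable:
    """The planted edge set: every within-block unordered pair.

    With ``condition`` None, the union over shared and both specific blocks;
    otherwise only the blocks active in that condition.
    """
    if condition is None:
        blocks = spec.shared_blocks + spec.specific_a + spec.specific_b
    else:
        blocks = spec.blocks_for(condition)
    table = EdgeTable()
    for b in blocks:
        vs = b.variables
        for i in range(len(vs)):
            for j in range(i + 1, len(vs)):
                table.append(EdgeRecord(source=str(vs[i]), target=str(vs[j]),
                                        r=b.rho))
    return table
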