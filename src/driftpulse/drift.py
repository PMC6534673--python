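"""Haploid Wright-Fisher forward simulation of a biallelic Y-chromosome marker.

A population is reduced to the frequency of a single "carrier" allele (here a
Y-haplogroup) in a pool of ``N`` transmitting haploid lineages.  Each
generation the whole pool is resampled with replacement, so the carrier count
in the next generation is Binomial(N, p) — the classic haploid Wright-Fisher
step.  Population size is constant and there is no mutation or selection:
frequencies 0 and 1 are absorbing.

Admixture is modelled as a single pulse: a proportion ``alpha`` of the
recipient gene pool is replaced by the source gene pool in one generation,
after which drift resumes from the mixed frequency.

Two implementations of the drift step are provided: the production path draws
the carrier count directly from the binomial distribution, and
:func:`drift_step_literal` resamples ``N`` individual haplotype labels with
replacement.  The two are distributionally identical; the literal form exists
as an independent oracle for the shortcut.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import NamedTuple

import numpy as np

__all__ = [
    "PopulationState",
    "AdmixtureEvent",
    "SampleDraw",
    "drift_step",
    "drift_step_literal",
    "drift_trajectory",
    "admix",
    "sample_observed",
    "drift_freqs",
]

DEFAULT_POPULATION_SIZE = 5000


@dataclass(frozen=True)
class PopulationState:
    """A population's carrier frequency and its haploid effective size.

    Parameters
    ----------
    label
        Population name, used only for reporting.
    freq
        Carrier frequency in [0, 1].  After a drift step this is always an
        integer multiple of ``1/size`` (allele counts are integral).
    size
        Haploid effective population size ``N`` — the number of transmitting
        lineages resampled each generation.  Constant over a simulation.
    """

    label: str
    freq: float
    size: int = DEFAULT_POPULATION_SIZE

    def __post_init__(self) -> None:
        if not (0.0 <= self.freq <= 1.0):
            raise ValueError(
                f"carrier frequency must be in [0, 1], got {self.freq!r} "
                f"for population {self.label!r}"
            )
        if self.size < 1:
            raise ValueError(f"population size must be >= 1, got {self.size!r}")

    @property
    def carrier_count(self) -> float:
        """Carrier allele count implied by the frequency (freq * size)."""
        return self.freq * self.size


@dataclass(frozen=True)
class AdmixtureEvent:
    """A single admixture pulse of proportion ``alpha`` at a given generation.

    ``generation`` counts generations before present, so a pulse at
    generation 30 on a 100-generation timeline happens after 70 generations
    of forward simulation.
    """

    source: str
    recipient: str
    alpha: float
    generation: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError(f"admixture proportion must be in [0, 1], got {self.alpha!r}")
        if self.source == self.recipient:
            raise ValueError(f"source and recipient must differ, both {self.source!r}")
        if self.generation < 0:
            raise ValueError(f"generation must be >= 0, got {self.generation!r}")


class SampleDraw(NamedTuple):
    """A binomial sample from a population: carrier count and sample frequency."""

    count: int
    freq: float


def drift_step(state: PopulationState, rng: np.random.Generator) -> PopulationState:
    """Advance one Wright-Fisher generation.

    The next generation's carrier count is Binomial(N, p) — distributionally
    identical to resampling N haplotypes with replacement.  The input state is
    not modified.
    """
    count = rng.binomial(state.size, state.freq)
    return replace(state, freq=count / state.size)


def drift_step_literal(state: PopulationState, rng: np.random.Generator) -> PopulationState:
    """One generation by explicit with-replacement resampling of N haplotype labels.

    Builds the parental pool of 0/1 alleles and draws N of them with
    replacement.  Used as the distributional oracle for :func:`drift_step`;
    O(N) per step, so only suitable for small N.
    """
    n_carriers = round(state.freq * state.size)
    pool = np.zeros(state.size, dtype=np.int8)
    pool[:n_carriers] = 1
    offspring = rng.choice(pool, size=state.size, replace=True)
    return replace(state, freq=float(offspring.sum()) / state.size)


def drift_trajectory(
    state: PopulationState, generations: int, rng: np.random.Generator
) -> PopulationState:
    """Apply :func:`drift_step` ``generations`` times.

    Frequencies 0 and 1 are absorbing, so the loop short-circuits there
    without changing the distribution of the result.
    """
    if generations < 0:
        raise ValueError(f"generations must be >= 0, got {generations!r}")
    for _ in range(generations):
        if state.freq in (0.0, 1.0):
            break
        state = drift_step(state, rng)
    return state


def admix(
    recipient: PopulationState, source: PopulationState, alpha: float
) -> PopulationState:
    """Apply a single admixture pulse of proportion ``alpha`` into ``recipient``.

    The recipient frequency becomes ``(1 - alpha) * p_recipient + alpha *
    p_source``, rounded to the nearest multiple of ``1/N`` so that the
    subsequent drift step operates on an integral allele count.  The source
    population is unchanged: under constant population sizes the pulse is a
    replacement of part of the recipient gene pool, not a transfer that
    depletes the source.
    """
    if not (0.0 <= alpha <= 1.0):
        raise ValueError(f"admixture proportion must be in [0, 1], got {alpha!r}")
    mixed = (1.0 - alpha) * recipient.freq + alpha * source.freq
    count = round(mixed * recipient.size)
    return replace(recipient, freq=count / recipient.size)


def sample_observed(
    state: PopulationState, n: int, rng: np.random.Generator
) -> SampleDraw:
    """Draw an observed sample of ``n`` haplotypes from the population.

    Sampling is binomial at the population frequency (sampling with
    replacement, appropriate since n << N is not assumed by the model).
    """
    if n < 1:
        raise ValueError(f"sample size must be >= 1, got {n!r}")
    count = int(rng.binomial(n, state.freq))
    return SampleDraw(count=count, freq=count / n)


def drift_freqs(
    freqs: np.ndarray,
    size: int,
    generations: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Vectorised drift of many independent populations of common size ``N``.

    Each entry of ``freqs`` is an independent replicate; all drift for
    ``generations`` Wright-Fisher generations.  Returns a new array; the
    input is not modified.  This is the kernel the model runners use to
    simulate hundreds of thousands of replicates at once.
    """
    if generations < 0:
        raise ValueError(f"generations must be >= 0, got {generations!r}")
    f = np.array(freqs, dtype=np.float64, copy=True)
    if np.any((f < 0.0) | (f > 1.0)):
        raise ValueError("carrier frequencies must be in [0, 1]")
    for _ in range(generations):
        # 0 and 1 are absorbing; binomial handles them exactly, and once every
        # replicate is absorbed further generations are a no-op.
        f = rng.binomial(size, f).astype(np.float64)
        f /= size
        if not np.any((f > 0.0) & (f < 1.0)):
            break
    return f
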