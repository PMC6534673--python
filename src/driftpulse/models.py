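"""Resampling-based model selection for three-population haplogroup frequencies.

The scientific question: are the observed carrier frequencies of a
Y-haplogroup in three population pools — Indo-Europeans (0/2677), Hungarian
Seklers (4/95) and Southern Ural/West Siberians (124/957) — explainable by
pure genetic drift from a common ancestor (Model A), by drift after a single
shared admixture pulse from the Siberian source into both European
populations (Model B), or do the two European populations need *independent*
admixture proportions (Model C)?

Each model is scored by simulation.  A simulated dataset "matches" an
observed sample when the simulated sample frequency falls within a tolerance
band of two standard errors around the observed frequency,

    tolerance = 2 * sqrt(p * (1 - p) / (2 n)),

with an observed frequency of zero replaced by the pseudo-count frequency
1/(n+1) so the band has positive width.  Models A and B are scored by a
success rate over blocks of conditioned simulations (the conditioning pins
down the free parameters; the success criterion tests the remaining
populations).  Model C is a rejection sampler: parameter draws are accepted
only when all three samples match, and the accepted draws form an
approximate posterior.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
import pandas as pd
import yaml

from .drift import DEFAULT_POPULATION_SIZE, drift_freqs

__all__ = [
    "ObservedPopulation",
    "ModelConfig",
    "BlockResult",
    "ReplicationSummary",
    "PosteriorDraws",
    "ConditioningTooRareError",
    "zero_adjust",
    "tolerance",
    "matches",
    "run_model_a_block",
    "run_model_b_block",
    "run_model_c",
    "replicate_success_rate",
    "summarize_posterior",
]

#: Role keys identifying the three populations in a ModelConfig.
ROLE_INDO_EUROPEAN = "indo_european"
ROLE_SEKLER = "sekler"
ROLE_SOURCE = "source"
ROLES = (ROLE_INDO_EUROPEAN, ROLE_SEKLER, ROLE_SOURCE)


class ConditioningTooRareError(RuntimeError):
    """Raised when the conditioning event is too rare to fill a block."""


def zero_adjust(carriers: int, n: int) -> float:
    """Observed frequency with the zero pseudo-count adjustment.

    Returns ``carriers / n`` when any carriers were observed, and the
    pseudo-count frequency ``1 / (n + 1)`` when none were: a frequency of
    exactly zero would give a zero-width tolerance band that no stochastic
    simulation could hit.
    """
    if not (0 <= carriers <= n):
        raise ValueError(f"need 0 <= carriers <= n, got carriers={carriers}, n={n}")
    if carriers == 0:
        return 1.0 / (n + 1)
    return carriers / n


def tolerance(p: float, n: int, variant: str = "paper") -> float:
    """Match tolerance (two standard errors) for an observed frequency.

    variant="paper" uses ``2 * sqrt(p(1-p) / (2n))`` — the standard error
    with a doubled denominator, kept as the canonical rule.  variant
    ="textbook" uses the conventional binomial SE denominator ``n``, exposed
    for sensitivity analysis.
    """
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"frequency must be in [0, 1], got {p!r}")
    if n < 1:
        raise ValueError(f"sample size must be >= 1, got {n!r}")
    if variant == "paper":
        denom = 2 * n
    elif variant == "textbook":
        denom = n
    else:
        raise ValueError(f"unknown tolerance variant {variant!r}")
    return 2.0 * math.sqrt(p * (1.0 - p) / denom)


@dataclass(frozen=True)
class ObservedPopulation:
    """An observed sample: size, carrier count, and the derived match band.

    ``p_adjusted`` and ``tol`` are derived once at construction; a simulated
    sample frequency f matches when ``|f - p_adjusted| <= tol`` (closed
    interval).
    """

    label: str
    n: int
    carriers: int
    tolerance_variant: str = "paper"

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"sample size must be >= 1, got {self.n!r}")
        if not (0 <= self.carriers <= self.n):
            raise ValueError(
                f"need 0 <= carriers <= n for {self.label!r}: "
                f"carriers={self.carriers}, n={self.n}"
            )
        if self.tol == 0.0:
            warnings.warn(
                f"population {self.label!r} has a zero-width tolerance band "
                f"(p_adjusted={self.p_adjusted}): only exact matches are possible",
                stacklevel=2,
            )

    @property
    def p(self) -> float:
        """Raw observed frequency carriers/n."""
        return self.carriers / self.n

    @property
    def p_adjusted(self) -> float:
        return zero_adjust(self.carriers, self.n)

    @property
    def tol(self) -> float:
        return tolerance(self.p_adjusted, self.n, self.tolerance_variant)

    def matches_freq(self, sim_freq: np.ndarray | float) -> np.ndarray | bool:
        """Vectorised match test on simulated sample frequencies."""
        return np.abs(np.asarray(sim_freq) - self.p_adjusted) <= self.tol

    def matches_count(self, counts: np.ndarray) -> np.ndarray:
        """Vectorised match test on simulated sample carrier counts."""
        return self.matches_freq(np.asarray(counts) / self.n)


def matches(sim_freq: float, obs: ObservedPopulation) -> bool:
    """True iff the simulated sample frequency is within the observed band."""
    return bool(obs.matches_freq(sim_freq))


def _default_observed(tolerance_variant: str = "paper") -> dict[str, ObservedPopulation]:
    return {
        ROLE_INDO_EUROPEAN: ObservedPopulation("IndoEuropean", 2677, 0, tolerance_variant),
        ROLE_SEKLER: ObservedPopulation("HungarianSekler", 95, 4, tolerance_variant),
        ROLE_SOURCE: ObservedPopulation("UralSiberian", 957, 124, tolerance_variant),
    }


@dataclass
class ModelConfig:
    """Full demographic and protocol specification for one model run.

    The three populations are identified by role: ``indo_european`` and
    ``sekler`` are the admixture recipients (both test populations), and
    ``source`` is the Southern Ural/West Siberian pool that carries the
    haplogroup.  Time runs over ``total_generations`` discrete generations;
    in Models B and C a single pulse happens ``admixture_generation``
    generations before present, i.e. after ``total_generations -
    admixture_generation`` generations of source drift (override with
    ``pre_admixture_generations`` to shorten the source's pre-pulse history).
    """

    model_id: str = "A"
    effective_size: int = DEFAULT_POPULATION_SIZE
    total_generations: int = 100
    admixture_generation: int = 30
    generation_time_years: float = 30.0  # documentation only; never enters the maths
    observed: Mapping[str, ObservedPopulation] = field(default_factory=_default_observed)
    blocks: int = 100
    sims_per_block: int = 100
    n_accepted: int = 1000
    pre_admixture_generations: int | None = None
    tolerance_variant: str = "paper"
    interval: str = "percentile"
    max_attempts_per_conditioned_sim: int = 10_000_000
    acceptance_floor: float = 1e-6
    batch_size: int = 20_000

    def __post_init__(self) -> None:
        if self.model_id not in ("A", "B", "C"):
            raise ValueError(f"model_id must be one of A, B, C; got {self.model_id!r}")
        if self.admixture_generation >= self.total_generations:
            raise ValueError(
                "admixture_generation must be < total_generations "
                f"({self.admixture_generation} >= {self.total_generations})"
            )
        missing = [r for r in ROLES if r not in self.observed]
        if missing:
            raise ValueError(f"observed populations missing roles: {missing}")

    @property
    def pre_pulse_generations(self) -> int:
        """Generations of source drift before the admixture pulse."""
        if self.pre_admixture_generations is not None:
            return self.pre_admixture_generations
        return self.total_generations - self.admixture_generation

    @classmethod
    def paper_defaults(cls, model_id: str = "A", **overrides) -> "ModelConfig":
        """The canonical three-pool configuration (0/2677, 4/95, 124/957)."""
        return cls(model_id=model_id, **overrides)

    @classmethod
    def from_dict(cls, data: dict) -> "ModelConfig":
        data = dict(data)
        obs = data.pop("observed", None)
        variant = data.pop("tolerance_variant", "paper")
        if obs is not None:
            observed = {}
            for entry in obs:
                entry = dict(entry)
                role = entry.pop("role")
                observed[role] = ObservedPopulation(
                    label=entry["label"],
                    n=int(entry["n"]),
                    carriers=int(entry["carriers"]),
                    tolerance_variant=variant,
                )
            data["observed"] = observed
        if "model" in data:
            data["model_id"] = data.pop("model")
        return cls(tolerance_variant=variant, **data)

    @classmethod
    def from_yaml(cls, path) -> "ModelConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise ValueError(f"config file {path!s} does not contain a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return {
            "model": self.model_id,
            "effective_size": self.effective_size,
            "total_generations": self.total_generations,
            "admixture_generation": self.admixture_generation,
            "generation_time_years": self.generation_time_years,
            "blocks": self.blocks,
            "sims_per_block": self.sims_per_block,
            "n_accepted": self.n_accepted,
            "pre_admixture_generations": self.pre_admixture_generations,
            "tolerance_variant": self.tolerance_variant,
            "interval": self.interval,
            "max_attempts_per_conditioned_sim": self.max_attempts_per_conditioned_sim,
            "acceptance_floor": self.acceptance_floor,
            "batch_size": self.batch_size,
            "observed": [
                {
                    "role": role,
                    "label": obs.label,
                    "n": obs.n,
                    "carriers": obs.carriers,
                }
                for role, obs in self.observed.items()
            ],
        }


@dataclass(frozen=True)
class BlockResult:
    """Outcome of one block of conditioned simulations."""

    successes: int
    conditioned_sims: int
    raw_attempts: int

    def __post_init__(self) -> None:
        if not (0 <= self.successes <= self.conditioned_sims):
            raise ValueError("successes must be in [0, conditioned_sims]")
        if self.raw_attempts < self.conditioned_sims:
            raise ValueError("raw_attempts cannot be below conditioned_sims")

    @property
    def success_rate(self) -> float:
        """Fraction of conditioned simulations that met the success criterion."""
        return self.successes / self.conditioned_sims


@dataclass(frozen=True)
class ReplicationSummary:
    """Mean and spread of per-block success rates, as percentages."""

    model_id: str
    mean_success_rate: float
    sd_success_rate: float
    blocks: int
    block_results: tuple[BlockResult, ...] = ()


@dataclass(frozen=True)
class PosteriorDraws:
    """Accepted parameter vectors from Model C rejection sampling.

    ``draws`` has one row per accepted simulation: the parameter vector
    (``p0`` starting source frequency, ``alpha_sekler``,
    ``alpha_indo_european``), the source population frequency at the final
    generation before sampling (``source_final_freq``), and the three sample
    frequencies that passed the match criteria (``source_sample_freq``,
    ``sekler_sample_freq``, ``ie_sample_freq`` — kept so acceptance is
    auditable after the fact).
    """

    draws: pd.DataFrame
    raw_attempts: int

    @property
    def n_accepted(self) -> int:
        return len(self.draws)

    @property
    def acceptance_rate(self) -> float:
        return self.n_accepted / self.raw_attempts


def _check_attempt_cap(config: ModelConfig, raw_attempts: int, found: int) -> None:
    if raw_attempts > config.max_attempts_per_conditioned_sim * (found + 1):
        raise ConditioningTooRareError(
            f"model {config.model_id}: {raw_attempts} raw simulations produced only "
            f"{found} conditioned simulations (cap "
            f"{config.max_attempts_per_conditioned_sim} raw attempts per conditioned "
            "simulation); the conditioning event is too rare for this configuration"
        )


def _collect_conditioned(
    config: ModelConfig,
    rng: np.random.Generator,
    simulate_batch: Callable[[int], tuple[np.ndarray, dict[str, np.ndarray]]],
) -> tuple[dict[str, np.ndarray], int]:
    """Run batches of raw simulations until ``sims_per_block`` pass conditioning.

    ``simulate_batch(b)`` must return ``(cond_mask, payload)`` where payload
    maps names to per-raw-simulation arrays.  Conditioned simulations are
    kept in draw order; the raw-attempt count covers every simulation up to
    and including the one that filled the block.
    """
    needed = config.sims_per_block
    kept: dict[str, list[np.ndarray]] = {}
    found = 0
    raw_attempts = 0
    batch = config.batch_size
    while found < needed:
        _check_attempt_cap(config, raw_attempts, found)
        cond, payload = simulate_batch(batch)
        idx = np.flatnonzero(cond)
        take = min(len(idx), needed - found)
        if take > 0:
            sel = idx[:take]
            for name, arr in payload.items():
                kept.setdefault(name, []).append(np.asarray(arr)[sel])
            found += take
        if found == needed:
            raw_attempts += int(idx[take - 1]) + 1
        else:
            raw_attempts += batch
        # grow the batch when the conditioning event is rare
        rate = max(found, 1) / max(raw_attempts, 1)
        batch = int(np.clip(2 * (needed - found) / rate, config.batch_size, 2_000_000))
    merged = {name: np.concatenate(parts) for name, parts in kept.items()}
    return merged, raw_attempts


def run_model_a_block(config: ModelConfig, rng: np.random.Generator) -> BlockResult:
    """One block of Model A: pure drift from a shared uniform(0,1) ancestor.

    Three populations inherit one shared starting frequency and drift
    independently for ``total_generations``.  A simulation is *conditioned*
    (retained) when the source-pool sample matches its observed band; it is
    a *success* when the Indo-European and Sekler samples both match too.
    """
    N = config.effective_size
    T = config.total_generations
    obs_src = config.observed[ROLE_SOURCE]
    obs_ie = config.observed[ROLE_INDO_EUROPEAN]
    obs_sek = config.observed[ROLE_SEKLER]

    def simulate_batch(b: int):
        p0 = rng.random(b)
        src_final = drift_freqs(p0, N, T, rng)
        src_counts = rng.binomial(obs_src.n, src_final)
        return obs_src.matches_count(src_counts), {"p0": p0}

    kept, raw_attempts = _collect_conditioned(config, rng, simulate_batch)
    # The recipients drift independently of the source given the shared start,
    # so they only need simulating for the retained draws.
    p0 = kept["p0"]
    ie_final = drift_freqs(p0, N, T, rng)
    sek_final = drift_freqs(p0, N, T, rng)
    ie_ok = obs_ie.matches_count(rng.binomial(obs_ie.n, ie_final))
    sek_ok = obs_sek.matches_count(rng.binomial(obs_sek.n, sek_final))
    successes = int(np.sum(ie_ok & sek_ok))
    return BlockResult(successes, config.sims_per_block, raw_attempts)


def _pulse(alpha: np.ndarray, source_freq: np.ndarray, size: int) -> np.ndarray:
    """Recipient frequency after an alpha pulse into an empty population.

    The mixed frequency ``alpha * p_source`` is rounded to the nearest
    multiple of 1/N so drift resumes from an integral allele count.
    """
    return np.round(alpha * source_freq * size) / size


def run_model_b_block(config: ModelConfig, rng: np.random.Generator) -> BlockResult:
    """One block of Model B: a single shared-proportion pulse into both recipients.

    The source drifts from a uniform(0,1) start; at ``admixture_generation``
    generations before present one pulse with a shared alpha seeds both the
    Indo-European and Sekler populations (previously empty); all three then
    drift to the present.  Conditioning: source and Sekler samples match.
    Success: the Indo-European sample matches as well.
    """
    N = config.effective_size
    pre = config.pre_pulse_generations
    post = config.admixture_generation
    obs_src = config.observed[ROLE_SOURCE]
    obs_ie = config.observed[ROLE_INDO_EUROPEAN]
    obs_sek = config.observed[ROLE_SEKLER]

    def simulate_batch(b: int):
        p0 = rng.random(b)
        alpha = rng.random(b)
        src_pre = drift_freqs(p0, N, pre, rng)
        recipient0 = _pulse(alpha, src_pre, N)
        src_final = drift_freqs(src_pre, N, post, rng)
        sek_final = drift_freqs(recipient0, N, post, rng)
        src_ok = obs_src.matches_count(rng.binomial(obs_src.n, src_final))
        sek_ok = obs_sek.matches_count(rng.binomial(obs_sek.n, sek_final))
        return src_ok & sek_ok, {"recipient0": recipient0}

    kept, raw_attempts = _collect_conditioned(config, rng, simulate_batch)
    # The IE population shares the pulse frequency but drifts independently,
    # so it is simulated only for the retained draws.
    ie_final = drift_freqs(kept["recipient0"], N, post, rng)
    ie_ok = obs_ie.matches_count(rng.binomial(obs_ie.n, ie_final))
    successes = int(np.sum(ie_ok))
    return BlockResult(successes, config.sims_per_block, raw_attempts)


def run_model_c(config: ModelConfig, rng: np.random.Generator) -> PosteriorDraws:
    """Model C rejection sampling with independent pulses into the recipients.

    Draws (p0, alpha_sekler, alpha_indo_european) ~ uniform(0,1)^3, simulates
    as in Model B but with the two independent pulses, and accepts a draw only
    when ALL three final samples match.  Runs until ``n_accepted`` draws are
    accepted.  Populations are tested source-first so that cheap rejections
    skip the recipient simulations (valid: given the drawn parameters the
    three populations drift independently).
    """
    N = config.effective_size
    pre = config.pre_pulse_generations
    post = config.admixture_generation
    obs_src = config.observed[ROLE_SOURCE]
    obs_ie = config.observed[ROLE_INDO_EUROPEAN]
    obs_sek = config.observed[ROLE_SEKLER]

    needed = config.n_accepted
    cols = ("p0", "alpha_sekler", "alpha_indo_european", "source_final_freq",
            "source_sample_freq", "sekler_sample_freq", "ie_sample_freq")
    kept: dict[str, list[np.ndarray]] = {c: [] for c in cols}
    found = 0
    raw_attempts = 0
    batch = config.batch_size
    while found < needed:
        if raw_attempts >= 2_000_000 and found / raw_attempts < config.acceptance_floor:
            raise ConditioningTooRareError(
                f"model C acceptance rate {found}/{raw_attempts} fell below the "
                f"floor {config.acceptance_floor:g}; the observations are "
                "unreachable under the priors"
            )
        p0 = rng.random(batch)
        a_sek = rng.random(batch)
        a_ie = rng.random(batch)
        src_pre = drift_freqs(p0, N, pre, rng)
        src_final = drift_freqs(src_pre, N, post, rng)
        src_counts = rng.binomial(obs_src.n, src_final)
        m_src = np.flatnonzero(obs_src.matches_count(src_counts))

        sek0 = _pulse(a_sek[m_src], src_pre[m_src], N)
        sek_final = drift_freqs(sek0, N, post, rng)
        sek_counts = rng.binomial(obs_sek.n, sek_final)
        sek_ok = obs_sek.matches_count(sek_counts)
        m_sek = m_src[sek_ok]  # batch indices passing source + Sekler

        ie0 = _pulse(a_ie[m_sek], src_pre[m_sek], N)
        ie_final = drift_freqs(ie0, N, post, rng)
        ie_counts = rng.binomial(obs_ie.n, ie_final)
        ie_ok = obs_ie.matches_count(ie_counts)
        acc = m_sek[ie_ok]  # batch indices passing all three criteria

        take = min(len(acc), needed - found)
        if take > 0:
            sel = acc[:take]
            kept["p0"].append(p0[sel])
            kept["alpha_sekler"].append(a_sek[sel])
            kept["alpha_indo_european"].append(a_ie[sel])
            kept["source_final_freq"].append(src_final[sel])
            kept["source_sample_freq"].append(src_counts[sel] / obs_src.n)
            kept["sekler_sample_freq"].append(
                (sek_counts[sek_ok][ie_ok][:take]) / obs_sek.n
            )
            kept["ie_sample_freq"].append(ie_counts[ie_ok][:take] / obs_ie.n)
            found += take
        if found == needed:
            raw_attempts += int(acc[take - 1]) + 1
        else:
            raw_attempts += batch
        rate = max(found, 1) / max(raw_attempts, 1)
        batch = int(np.clip(2 * (needed - found) / rate, config.batch_size, 2_000_000))

    draws = pd.DataFrame({c: np.concatenate(kept[c]) for c in cols})
    return PosteriorDraws(draws=draws, raw_attempts=raw_attempts)


def replicate_success_rate(
    model_runner: Callable[[ModelConfig, np.random.Generator], BlockResult],
    config: ModelConfig,
    rng: np.random.Generator,
) -> ReplicationSummary:
    """Run ``config.blocks`` independent blocks and summarise their success rates.

    Each block gets an independent child random stream spawned from ``rng``,
    so the summary is reproducible for a fixed master seed.  Rates are
    reported as percentages; the spread is the sample SD across blocks
    (ddof=1), reported as 0 with a warning when there is a single block.
    """
    if config.blocks < 1:
        raise ValueError(f"blocks must be >= 1, got {config.blocks!r}")
    streams = rng.spawn(config.blocks)
    results = tuple(model_runner(config, stream) for stream in streams)
    rates = np.array([100.0 * r.success_rate for r in results])
    if config.blocks == 1:
        warnings.warn("single block: SD of success rate is undefined, reporting 0")
        sd = 0.0
    else:
        sd = float(np.std(rates, ddof=1))
    return ReplicationSummary(
        model_id=config.model_id,
        mean_success_rate=float(np.mean(rates)),
        sd_success_rate=sd,
        blocks=config.blocks,
        block_results=results,
    )


def summarize_posterior(
    draws: PosteriorDraws | pd.DataFrame,
    interval: str = "percentile",
    percent: bool = True,
) -> dict[str, dict[str, float]]:
    """Per-parameter mean and interval of the accepted draws.

    interval="percentile" reports the empirical 2.5th-97.5th percentile
    band; interval="minmax" the full range of accepted values.  Both
    extremes are always included under ``min``/``max``.  With
    ``percent=True`` (default) all values are on a 0-100 scale.
    """
    frame = draws.draws if isinstance(draws, PosteriorDraws) else draws
    if len(frame) == 0:
        raise ValueError("no accepted draws to summarise")
    if interval not in ("percentile", "minmax"):
        raise ValueError(f"unknown interval convention {interval!r}")
    scale = 100.0 if percent else 1.0
    out: dict[str, dict[str, float]] = {}
    for name in frame.columns:
        v = frame[name].to_numpy(dtype=float) * scale
        if interval == "percentile":
            lower, upper = np.percentile(v, [2.5, 97.5])
        else:
            lower, upper = v.min(), v.max()
        out[name] = {
            "mean": float(v.mean()),
            "lower": float(lower),
            "upper": float(upper),
            "min": float(v.min()),
            "max": float(v.max()),
        }
    return out
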