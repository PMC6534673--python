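"""Synthetic count tables with known drift/admixture ground truth.

Every downstream stage of the pipeline — table parsing, pooling, match
tolerances, the model runners — is testable without any external data by
generating observations from the same generative process the models assume:
forward drift of a source population, an optional single admixture pulse
into one or two recipient pools, and binomial sampling at the observed
sample sizes.

Three scenarios mirror the three demographic models:

- ``pure_drift``: all pools inherit one starting frequency and drift
  independently (Model A's world).
- ``shared_pulse``: the recipients are seeded by one shared-proportion pulse
  from the source (Model B's world).
- ``independent_pulses``: each recipient gets its own pulse proportion
  (Model C's world).

Each pool's sample can be split across several sub-populations; they draw
from the same pool frequency (the models treat a pool as one panmictic
population), so sub-population structure exercises the pooling code without
adding demographic structure the models do not have.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .counts import CountTable
from .drift import DEFAULT_POPULATION_SIZE, drift_freqs
from .models import _pulse

__all__ = ["ScenarioSpec", "generate_counts", "make_fixture_suite"]

SCENARIOS = ("pure_drift", "shared_pulse", "independent_pulses")

#: Observed pool sample sizes of the three-population study design.
STUDY_SAMPLE_SIZES = {"indo_european": 2677, "sekler": 95, "source": 957}


@dataclass(frozen=True)
class ScenarioSpec:
    """Ground-truth parameters for one synthetic dataset.

    ``alpha_sekler``/``alpha_indo_european`` are ignored under ``pure_drift``;
    under ``shared_pulse`` the Sekler value is used for both recipients.
    """

    scenario_id: str = "independent_pulses"
    p0: float = 0.5
    alpha_sekler: float = 0.3
    alpha_indo_european: float = 0.0
    effective_size: int = DEFAULT_POPULATION_SIZE
    total_generations: int = 100
    admixture_generation: int = 30
    sample_sizes: dict[str, int] = field(
        default_factory=lambda: dict(STUDY_SAMPLE_SIZES)
    )
    subpops_per_pool: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario_id not in SCENARIOS:
            raise ValueError(
                f"scenario_id must be one of {SCENARIOS}, got {self.scenario_id!r}"
            )
        for name in ("p0", "alpha_sekler", "alpha_indo_european"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v!r}")
        if any(n < 1 for n in self.sample_sizes.values()):
            raise ValueError("sample sizes must be >= 1")
        if self.subpops_per_pool < 1:
            raise ValueError("subpops_per_pool must be >= 1")
        if self.admixture_generation >= self.total_generations:
            raise ValueError("admixture_generation must be < total_generations")


def _split_sample(n: int, k: int) -> list[int]:
    """Split a pool sample of n across k sub-populations, sizes as even as possible."""
    base, extra = divmod(n, k)
    sizes = [base + (1 if i < extra else 0) for i in range(k)]
    return [s for s in sizes if s > 0]


def generate_counts(
    spec: ScenarioSpec, rng: np.random.Generator | None = None
) -> tuple[CountTable, dict]:
    """Simulate a scenario and emit a count table plus its ground truth.

    Pool frequencies come from one forward run of the drift engine; each
    sub-population's carrier count is an independent binomial sample from
    its pool frequency.  Returns ``(table, truth)`` where ``truth`` records
    the drawn parameters and the realised final pool frequencies.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    N = spec.effective_size
    pre = spec.total_generations - spec.admixture_generation
    post = spec.admixture_generation

    p0 = np.array([spec.p0])
    if spec.scenario_id == "pure_drift":
        final = {
            pool: float(drift_freqs(p0, N, spec.total_generations, rng)[0])
            for pool in spec.sample_sizes
        }
    else:
        src_pre = drift_freqs(p0, N, pre, rng)
        a_ie = (
            spec.alpha_sekler
            if spec.scenario_id == "shared_pulse"
            else spec.alpha_indo_european
        )
        starts = {
            "source": src_pre,
            "sekler": _pulse(np.array([spec.alpha_sekler]), src_pre, N),
            "indo_european": _pulse(np.array([a_ie]), src_pre, N),
        }
        final = {
            pool: float(drift_freqs(starts[pool], N, post, rng)[0])
            for pool in spec.sample_sizes
        }

    rows = []
    for pool, n_total in spec.sample_sizes.items():
        for i, n_sub in enumerate(_split_sample(n_total, spec.subpops_per_pool), 1):
            carriers = int(rng.binomial(n_sub, final[pool]))
            rows.append(
                {
                    "population": f"{pool}_{i}",
                    "group": pool,
                    "n": n_sub,
                    "carriers": carriers,
                }
            )
    table = CountTable(pd.DataFrame(rows, columns=["population", "group", "n", "carriers"]))
    truth = {
        "spec": asdict(spec),
        "final_pool_freqs": final,
    }
    return table, truth


# --- deterministic fixture suite -------------------------------------------

#: The three-pool study observations: 0/2677, 4/95 (4.2%), 124/957 (13.0%).
#: 0, 4 and 124 are the smallest carrier counts consistent with the printed
#: pooled frequencies at these sample sizes.
STUDY_COUNTS = [
    ("IndoEuropean", "indo_european", 2677, 0),
    ("HungarianSekler", "sekler", 95, 4),
    ("UralSiberian", "source", 957, 124),
]


def make_fixture_suite(seed: int, outdir) -> list[Path]:
    """Write a deterministic suite of small count tables and configs.

    Contents: the study-replica table (pooled values 0%, 4/95, 124/957 at
    n = 2677/95/957, split over sub-populations), one simulated table per
    scenario with its ground-truth JSON sidecar, a degenerate table
    (carriers = n) exercising the zero-width-tolerance warning path, and a
    ready-to-run model config.  Bytes are identical for a fixed seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(path: Path, text: str) -> None:
        path.write_text(text, encoding="utf-8")
        written.append(path)

    # study-replica table, IE pool split across three sub-populations
    replica_rows = ["population\tgroup\tn\tcarriers"]
    for label, group, n, carriers in STUDY_COUNTS:
        if group == "indo_european":
            for i, n_sub in enumerate(_split_sample(n, 3), 1):
                replica_rows.append(f"{label}_{i}\t{group}\t{n_sub}\t0")
        else:
            replica_rows.append(f"{label}\t{group}\t{n}\t{carriers}")
    emit(outdir / "study_replica_counts.tsv", "\n".join(replica_rows) + "\n")

    # one simulated table per scenario, with ground truth alongside
    specs = {
        "pure_drift": ScenarioSpec("pure_drift", p0=0.13, seed=seed),
        "shared_pulse": ScenarioSpec("shared_pulse", p0=0.5, alpha_sekler=0.2, seed=seed + 1),
        "independent_pulses": ScenarioSpec(
            "independent_pulses", p0=0.4, alpha_sekler=0.3,
            alpha_indo_european=0.0, seed=seed + 2,
        ),
    }
    for name, spec in specs.items():
        table, truth = generate_counts(spec)
        emit(
            outdir / f"{name}_counts.tsv",
            table.data.to_csv(sep="\t", index=False),
        )
        emit(
            outdir / f"{name}_truth.json",
            json.dumps(truth, indent=2, sort_keys=True) + "\n",
        )

    # degenerate table: every sampled man a carrier -> zero-width tolerance
    emit(
        outdir / "degenerate_counts.tsv",
        "population\tgroup\tn\tcarriers\nFixedPool\tfixed\t10\t10\n",
    )

    config = {
        "model": "A",
        "effective_size": DEFAULT_POPULATION_SIZE,
        "total_generations": 100,
        "admixture_generation": 30,
        "blocks": 100,
        "sims_per_block": 100,
        "observed": [
            {"role": group, "label": label, "n": n, "carriers": carriers}
            for label, group, n, carriers in STUDY_COUNTS
        ],
    }
    emit(outdir / "study_config.yaml", yaml.safe_dump(config, sort_keys=True))
    return written
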