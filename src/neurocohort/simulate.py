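"""Synthetic cohort generation via a Gaussian copula.

Each group's 21 outcome measures are drawn from a latent correlated
standard-normal vector pushed through per-measure marginals: a plain
normal for most pen-and-paper scores, a moment-matched lognormal for
right-skewed timing measures (Stroop interference, CPT RT variability,
flanker cost), and a rounded non-negative normal for error counts.  The
copula keeps a single correlation model valid across these mixed
marginals.  Demographics come from per-group category probabilities and
the ASRS screener from a normal truncated to [0, 24] and rounded.

Defaults reproduce the published group sizes, measure means/SDs and
demographic frequencies of the age-40 perinatal-risk ADHD cohort.

All randomness flows from one integer master seed; per-group and
per-stage substreams are spawned deterministically, so a fixed seed
yields a bit-identical cohort.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import printed
from .battery import BatteryConfig, default_battery
from .cohort import ASRS_RANGE, CohortTable, DEMO_COLUMNS

__all__ = [
    "CorrelationModel",
    "GroupParams",
    "SimConfig",
    "SimulationError",
    "default_sim_config",
    "generate_cohort",
    "inject_missingness",
]


class SimulationError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class CorrelationModel:
    """Inter-measure correlation: exchangeable, block, or explicit matrix.

    ``exchangeable(rho)`` gives every pair of measures the same latent
    correlation; ``within_between(rho_within, rho_between)`` correlates
    measures of the same cognitive domain at ``rho_within`` and measures
    of different domains at ``rho_between``; ``from_matrix`` pins a full
    matrix (ordered as the battery's measure list).
    """

    kind: str
    rho: float = 0.0
    rho_within: float = 0.0
    rho_between: float = 0.0
    matrix: np.ndarray | None = field(default=None, compare=False)

    @classmethod
    def exchangeable(cls, rho: float) -> "CorrelationModel":
        if not 0.0 <= rho < 1.0:
            raise SimulationError(f"rho must be in [0, 1), got {rho}")
        return cls(kind="exchangeable", rho=rho)

    @classmethod
    def within_between(cls, rho_within: float,
                       rho_between: float) -> "CorrelationModel":
        for name, r in (("rho_within", rho_within),
                        ("rho_between", rho_between)):
            if not 0.0 <= r < 1.0:
                raise SimulationError(f"{name} must be in [0, 1), got {r}")
        return cls(kind="within_between", rho_within=rho_within,
                   rho_between=rho_between)

    @classmethod
    def from_matrix(cls, matrix) -> "CorrelationModel":
        return cls(kind="matrix", matrix=np.asarray(matrix, dtype=float))

    def build(self, battery: BatteryConfig) -> np.ndarray:
        names = battery.measure_names
        p = len(names)
        if self.kind == "exchangeable":
            R = np.full((p, p), self.rho)
        elif self.kind == "within_between":
            domains = np.array([battery.domain_of(m) for m in names])
            same = domains[:, None] == domains[None, :]
            R = np.where(same, self.rho_within, self.rho_between)
        elif self.kind == "matrix":
            R = np.array(self.matrix, dtype=float)
            if R.shape != (p, p):
                raise SimulationError(
                    f"correlation matrix shape {R.shape} != ({p}, {p})"
                )
        else:  # pragma: no cover
            raise SimulationError(f"unknown correlation kind {self.kind!r}")
        np.fill_diagonal(R, 1.0)
        if not np.allclose(R, R.T):
            raise SimulationError("correlation matrix not symmetric")
        eigmin = float(np.linalg.eigvalsh(R).min())
        if eigmin < -1e-8:
            raise SimulationError(
                f"correlation matrix not positive semi-definite "
                f"(min eigenvalue {eigmin:.3g})"
            )
        return R

    def to_dict(self) -> dict:
        if self.kind == "exchangeable":
            return {"kind": self.kind, "rho": self.rho}
        if self.kind == "within_between":
            return {"kind": self.kind, "rho_within": self.rho_within,
                    "rho_between": self.rho_between}
        return {"kind": self.kind, "matrix": self.matrix.tolist()}

    @classmethod
    def from_dict(cls, d: Mapping) -> "CorrelationModel":
        kind = d["kind"]
        if kind == "exchangeable":
            return cls.exchangeable(d["rho"])
        if kind == "within_between":
            return cls.within_between(d["rho_within"], d["rho_between"])
        if kind == "matrix":
            return cls.from_matrix(d["matrix"])
        raise SimulationError(f"unknown correlation kind {kind!r}")


@dataclass(frozen=True)
class GroupParams:
    """Sampling parameters for one childhood group."""

    group: str
    n: int
    measure_params: Mapping[str, tuple[float, float]]
    demo_probs: Mapping[str, Mapping]
    asrs_mu: float
    asrs_sigma: float
    age_mu: float = 42.0
    age_sigma: float = 1.3

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise SimulationError(f"group {self.group!r}: n must be > 0")
        for m, (mu, sigma) in self.measure_params.items():
            if sigma <= 0:
                raise SimulationError(
                    f"group {self.group!r}, measure {m!r}: sigma must be > 0"
                )
        for var, probs in self.demo_probs.items():
            total = float(sum(probs.values()))
            if abs(total - 1.0) > 1e-9:
                raise SimulationError(
                    f"group {self.group!r}: {var} probabilities sum to "
                    f"{total}, expected 1"
                )


@dataclass(frozen=True)
class SimConfig:
    """Complete recipe for one synthetic cohort."""

    groups: tuple[GroupParams, ...]
    correlation: CorrelationModel
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "groups", tuple(self.groups))
        if not 0.0 <= self.missing_rate < 1.0:
            raise SimulationError(
                f"missing_rate must be in [0, 1), got {self.missing_rate}"
            )

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "missing_rate": self.missing_rate,
            "correlation": self.correlation.to_dict(),
            "groups": [
                {
                    "group": g.group, "n": g.n,
                    "asrs_mu": g.asrs_mu, "asrs_sigma": g.asrs_sigma,
                    "age_mu": g.age_mu, "age_sigma": g.age_sigma,
                    "measure_params": {m: list(p)
                                       for m, p in g.measure_params.items()},
                    "demo_probs": {k: {str(c): float(p)
                                       for c, p in v.items()}
                                   for k, v in g.demo_probs.items()},
                }
                for g in self.groups
            ],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimConfig":
        groups = []
        for g in d["groups"]:
            demo = {}
            for var, probs in g["demo_probs"].items():
                if var in ("ses", "education"):
                    demo[var] = {int(c): float(p) for c, p in probs.items()}
                else:
                    demo[var] = {str(c): float(p) for c, p in probs.items()}
            groups.append(GroupParams(
                group=g["group"], n=int(g["n"]),
                measure_params={m: tuple(p)
                                for m, p in g["measure_params"].items()},
                demo_probs=demo,
                asrs_mu=float(g["asrs_mu"]), asrs_sigma=float(g["asrs_sigma"]),
                age_mu=float(g.get("age_mu", 42.0)),
                age_sigma=float(g.get("age_sigma", 1.3)),
            ))
        return cls(groups=tuple(groups),
                   correlation=CorrelationModel.from_dict(d["correlation"]),
                   missing_rate=float(d.get("missing_rate", 0.0)),
                   seed=int(d.get("seed", 0)))

    @classmethod
    def from_file(cls, path) -> "SimConfig":
        path = Path(path)
        text = path.read_text(encoding="utf-8")
        doc = (json.loads(text) if path.suffix.lower() == ".json"
               else yaml.safe_load(text))
        return cls.from_dict(doc)

    def to_file(self, path) -> Path:
        path = Path(path)
        doc = self.to_dict()
        if path.suffix.lower() == ".json":
            path.write_text(json.dumps(doc, indent=2), encoding="utf-8")
        else:
            path.write_text(yaml.safe_dump(doc, sort_keys=False),
                            encoding="utf-8")
        return path


def default_sim_config(seed: int = 0, n_scale: float = 1.0,
                       missing_rate: float = 0.0,
                       rho_within: float = 0.5,
                       rho_between: float = 0.25) -> SimConfig:
    """The study-default simulation: published group sizes (optionally
    scaled), measure means/SDs, demographic frequencies, and a
    within-domain 0.5 / between-domain 0.25 latent correlation."""
    groups = []
    for g in printed.GROUPS:
        groups.append(GroupParams(
            group=g,
            n=max(2, round(printed.GROUP_NS[g] * n_scale)),
            measure_params={m: printed.MEASURE_STATS[m][g]
                            for m in printed.MEASURE_STATS},
            demo_probs=printed.demographic_probs(g),
            asrs_mu=printed.ASRS_STATS[g][0],
            asrs_sigma=printed.ASRS_STATS[g][1],
            age_mu=printed.AGE_STATS[g][0],
            age_sigma=printed.AGE_STATS[g][1],
        ))
    return SimConfig(
        groups=tuple(groups),
        correlation=CorrelationModel.within_between(rho_within, rho_between),
        missing_rate=missing_rate,
        seed=seed,
    )


def _marginal(spec, mu: float, sigma: float, z: np.ndarray) -> np.ndarray:
    """Push latent standard normals through one measure's marginal."""
    if spec.generator_family == "normal":
        return mu + sigma * z
    if spec.generator_family == "lognormal":
        if mu <= 0:
            raise SimulationError(
                f"measure {spec.name!r}: lognormal marginal needs mean > 0"
            )
        # moment-matched: E[X] = mu, SD[X] = sigma
        s2 = math.log1p((sigma / mu) ** 2)
        mu_ln = math.log(mu) - s2 / 2.0
        return np.exp(mu_ln + math.sqrt(s2) * z)
    if spec.generator_family == "count":
        return np.rint(np.clip(mu + sigma * z, 0.0, None))
    raise SimulationError(  # pragma: no cover
        f"unknown generator_family {spec.generator_family!r}"
    )


def generate_cohort(config: SimConfig,
                    battery: BatteryConfig | None = None) -> CohortTable:
    """Draw a cohort from a :class:`SimConfig`.

    Per group: latent MVN(0, R) scores mapped through each measure's
    marginal; demographics from the group's category probabilities; ASRS
    from a truncated, rounded normal.  Missingness (if any) is injected
    afterwards with a seed derived from the master seed.
    """
    if battery is None:
        battery = default_battery()
    names = battery.measure_names
    R = config.correlation.build(battery)
    # eigendecomposition square root tolerates semi-definite R
    w, V = np.linalg.eigh(R)
    L = V * np.sqrt(np.clip(w, 0.0, None))
    master = np.random.SeedSequence(config.seed)
    group_seeds = master.spawn(len(config.groups) + 1)
    frames = []
    for gp, gseed in zip(config.groups, group_seeds):
        missing = [m for m in names if m not in gp.measure_params]
        if missing:
            raise SimulationError(
                f"group {gp.group!r}: no parameters for measure(s) {missing}"
            )
        s_scores, s_demo, s_asrs = gseed.spawn(3)
        rng = np.random.default_rng(s_scores)
        z = rng.standard_normal((gp.n, len(names))) @ L.T
        scores = {}
        for j, m in enumerate(names):
            mu, sigma = gp.measure_params[m]
            scores[m] = _marginal(battery.measure(m), mu, sigma, z[:, j])
        rng_d = np.random.default_rng(s_demo)
        demo = {}
        for var in ("sex", "ses", "education", "birth_risks"):
            cats = list(gp.demo_probs[var])
            p = np.array([gp.demo_probs[var][c] for c in cats], dtype=float)
            demo[var] = rng_d.choice(np.array(cats, dtype=object),
                                     size=gp.n, p=p / p.sum())
        age = np.round(gp.age_mu + gp.age_sigma * rng_d.standard_normal(gp.n),
                       1)
        lo, hi = ASRS_RANGE
        a = (lo - gp.asrs_mu) / gp.asrs_sigma
        b = (hi - gp.asrs_mu) / gp.asrs_sigma
        rng_a = np.random.default_rng(s_asrs)
        asrs = np.rint(stats.truncnorm.rvs(
            a, b, loc=gp.asrs_mu, scale=gp.asrs_sigma, size=gp.n,
            random_state=rng_a))
        frame = pd.DataFrame({
            "id": [f"{gp.group}-{i:05d}" for i in range(gp.n)],
            "group": gp.group,
            "sex": demo["sex"],
            "age": age,
            "ses": demo["ses"].astype(float),
            "education": demo["education"].astype(float),
            "birth_risks": demo["birth_risks"],
            "asrs": asrs,
        })
        for m in names:
            frame[m] = scores[m]
        frames.append(frame)
    data = pd.concat(frames, ignore_index=True)[DEMO_COLUMNS + names]
    cohort = CohortTable(data=data, battery=battery)
    if config.missing_rate > 0:
        miss_seed = int(group_seeds[-1].generate_state(1)[0] % (2**31))
        cohort = inject_missingness(cohort, config.missing_rate, miss_seed)
    return cohort


def inject_missingness(cohort: CohortTable, rate: float,
                       seed: int) -> CohortTable:
    """Blank each score cell independently with probability ``rate`` (MCAR).

    Demographics and ASRS are untouched.  Deterministic for a fixed seed.
    """
    if not 0.0 <= rate < 1.0:
        raise SimulationError(f"missing rate must be in [0, 1), got {rate}")
    if rate == 0.0:
        return cohort
    rng = np.random.default_rng(seed)
    names = cohort.battery.measure_names
    mask = rng.random((len(cohort), len(names))) < rate
    data = cohort.data.copy()
    block = data[names].to_numpy(dtype=float, copy=True)
    block[mask] = np.nan
    data[names] = block
    return cohort.with_data(data)
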