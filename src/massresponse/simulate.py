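"""Synthetic single-cell mass experiments.

Generates populations with the statistical structure the analysis assumes:

* a right-skewed baseline buoyant-mass distribution (lognormal, mean 60 pg,
  CV 0.35 by default — typical of cultured cancer cell lines);
* particle-class contamination: permeable cells at a fraction of intact
  mass, aggregates as sums of 2-3 cells, light debris — reproducing the
  characteristic class-mean ordering aggregate > intact > permeable > debris;
* drug mechanism-of-action effects expressed as mass-distribution changes:
  cell-cycle arrest consolidates the distribution around the arrested-stage
  mass (mean scale + CV shrink), metabolic disruption skews the mean,
  membrane loss moves an affected fraction into a well-separated low-mass
  permeable mode, and a uniform relative shift serves as the analytically
  tractable reference effect;
* partial response via mixtures with a defined responding fraction;
* slow time-linear phenotypic drift applied at each particle's measurement
  time; and
* additive sensor noise (0.5 pg SD by default).

Generated experiments can be written in the standard measurement-table
format, so the full pipeline runs on them unchanged.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .datamodel import (
    ExperimentSet,
    MassRecord,
    ParticleClass,
    Role,
    ValidationError,
    build_experiment,
)
from .response import mass_response

__all__ = [
    "SimulationSpec",
    "MoaKind",
    "MoaEffect",
    "DriftModel",
    "sample_masses",
    "simulate_population",
    "apply_moa",
    "mix_populations",
    "simulate_experiment",
    "noise_vs_n_scan",
]

_CLASS_ORDER = (
    ParticleClass.INTACT,
    ParticleClass.PERMEABLE,
    ParticleClass.AGGREGATE,
    ParticleClass.DEBRIS,
)


def _lognormal_params(mean: float, cv: float) -> tuple[float, float]:
    """(mu, sigma) of a lognormal with the given arithmetic mean and CV."""
    sigma2 = np.log1p(cv * cv)
    return np.log(mean) - sigma2 / 2.0, np.sqrt(sigma2)


@dataclass
class SimulationSpec:
    """Generative description of one synthetic cell population.

    Attributes
    ----------
    mean_mass, cv : float
        Arithmetic mean (pg) and coefficient of variation of the intact-cell
        lognormal baseline.
    class_weights : dict
        Mixture fractions over {intact, permeable, aggregate, debris};
        must sum to 1.  Default is a pure intact population.
    permeable_mass_factor : float
        Permeable-cell mass as a fraction of an intact draw.
    aggregate_multiplicity : (int, int)
        Inclusive range of cells summed into one aggregate.
    debris_mean_mass, debris_cv : float
        Lognormal parameters of the debris mass distribution.
    noise_sd : float
        Additive Gaussian sensor noise, pg SD.  Set 0 to disable.
    """

    mean_mass: float = 60.0
    cv: float = 0.35
    family: str = "lognormal"
    class_weights: dict[ParticleClass, float] = field(
        default_factory=lambda: {ParticleClass.INTACT: 1.0}
    )
    permeable_mass_factor: float = 0.5
    aggregate_multiplicity: tuple[int, int] = (2, 3)
    debris_mean_mass: float = 8.0
    debris_cv: float = 0.8
    noise_sd: float = 0.5

    def __post_init__(self) -> None:
        if self.family != "lognormal":
            raise ValidationError(f"unsupported baseline family {self.family!r}")
        if self.mean_mass <= 0 or self.cv <= 0:
            raise ValidationError("mean_mass and cv must be positive")
        w = {ParticleClass(k): float(v) for k, v in self.class_weights.items()}
        if any(v < 0 for v in w.values()):
            raise ValidationError("class weights must be non-negative")
        if abs(sum(w.values()) - 1.0) > 1e-9:
            raise ValidationError("class weights must sum to 1")
        self.class_weights = w
        lo, hi = self.aggregate_multiplicity
        if not (1 <= lo <= hi):
            raise ValidationError("aggregate_multiplicity must satisfy 1 <= lo <= hi")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")

    @classmethod
    def contaminated(cls, contamination: float = 0.2, **kw) -> "SimulationSpec":
        """Population with aggregates and debris at the given total fraction
        (split evenly) plus 10% permeable cells."""
        half = contamination / 2.0
        return cls(
            class_weights={
                ParticleClass.INTACT: 0.9 - contamination,
                ParticleClass.PERMEABLE: 0.1,
                ParticleClass.AGGREGATE: half,
                ParticleClass.DEBRIS: half,
            },
            **kw,
        )


def _class_masses(
    spec: SimulationSpec, cls: ParticleClass, n: int, gen: np.random.Generator
) -> np.ndarray:
    mu, sigma = _lognormal_params(spec.mean_mass, spec.cv)
    if cls is ParticleClass.INTACT:
        return gen.lognormal(mu, sigma, n)
    if cls is ParticleClass.PERMEABLE:
        return gen.lognormal(mu, sigma, n) * spec.permeable_mass_factor
    if cls is ParticleClass.AGGREGATE:
        lo, hi = spec.aggregate_multiplicity
        mult = gen.integers(lo, hi + 1, n)
        draws = gen.lognormal(mu, sigma, (n, hi))
        mask = np.arange(hi)[None, :] < mult[:, None]
        return (draws * mask).sum(axis=1)
    if cls is ParticleClass.DEBRIS:
        dmu, dsigma = _lognormal_params(spec.debris_mean_mass, spec.debris_cv)
        return gen.lognormal(dmu, dsigma, n)
    raise ValidationError(f"cannot generate masses for class {cls}")


def _add_noise(masses: np.ndarray, spec: SimulationSpec,
               gen: np.random.Generator) -> np.ndarray:
    if spec.noise_sd == 0:
        return masses
    noisy = masses + gen.normal(0.0, spec.noise_sd, masses.size)
    # sensor noise cannot make a particle's buoyant mass non-positive
    return np.maximum(noisy, 0.01)


def sample_masses(spec: SimulationSpec, n: int,
                  rng: np.random.Generator | int | None = None) -> np.ndarray:
    """Draw ``n`` masses from the full class mixture (classes discarded)."""
    gen = np.random.default_rng(rng)
    masses, classes = _sample_with_classes(spec, n, gen)
    return masses


def _sample_with_classes(
    spec: SimulationSpec, n: int, gen: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    classes_present = [c for c in _CLASS_ORDER if spec.class_weights.get(c, 0.0) > 0]
    probs = np.array([spec.class_weights[c] for c in classes_present])
    labels = gen.choice(len(classes_present), size=n, p=probs)
    masses = np.empty(n)
    out_classes = np.empty(n, dtype=object)
    for i, cls in enumerate(classes_present):
        idx = np.flatnonzero(labels == i)
        if idx.size:
            masses[idx] = _class_masses(spec, cls, idx.size, gen)
            out_classes[idx] = cls
    masses = _add_noise(masses, spec, gen)
    return masses, out_classes


def simulate_population(
    spec: SimulationSpec,
    n: int,
    rng: np.random.Generator | int | None = None,
    *,
    condition_id: str = "sim",
    role: Role = Role.TEST,
    t_meas: float = 0.0,
    instrument_id: str | None = None,
) -> list[MassRecord]:
    """Generate ``n`` records with ground-truth particle classes."""
    if n < 1:
        raise ValidationError("n must be >= 1")
    gen = np.random.default_rng(rng)
    masses, classes = _sample_with_classes(spec, n, gen)
    return [
        MassRecord(
            mass=float(m),
            particle_class=cls,
            condition_id=condition_id,
            role=role,
            t_meas=t_meas,
            instrument_id=instrument_id,
            true_class=cls,
        )
        for m, cls in zip(masses, classes)
    ]


class MoaKind(str, enum.Enum):
    G1_ARREST = "g1_arrest"
    G2_ARREST = "g2_arrest"
    CATABOLIC = "catabolic"
    ANABOLIC = "anabolic"
    MEMBRANE_LOSS = "membrane_loss"
    UNIFORM_SHIFT = "uniform_shift"


@dataclass(frozen=True)
class MoaEffect:
    """A drug mechanism-of-action expressed as a mass-distribution change.

    ``scale`` multiplies the population mean; ``spread`` multiplies the CV
    (arrest consolidates the distribution, spread < 1); ``affected_fraction``
    is the fraction of cells hit by membrane loss, whose masses drop to
    ``scale`` of their original value and which are relabelled permeable.
    """

    kind: MoaKind
    scale: float = 1.0
    spread: float = 1.0
    affected_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.scale <= 0 or self.spread <= 0:
            raise ValidationError("scale and spread factors must be > 0")
        if not 0.0 <= self.affected_fraction <= 1.0:
            raise ValidationError("affected_fraction must lie in [0, 1]")

    # mechanism presets; magnitudes chosen to mimic characteristic
    # distribution signatures of each drug class
    @classmethod
    def g1_arrest(cls, scale: float = 0.75, spread: float = 0.6) -> "MoaEffect":
        return cls(MoaKind.G1_ARREST, scale=scale, spread=spread)

    @classmethod
    def g2_arrest(cls, scale: float = 1.4, spread: float = 0.6) -> "MoaEffect":
        return cls(MoaKind.G2_ARREST, scale=scale, spread=spread)

    @classmethod
    def catabolic(cls, scale: float = 0.90) -> "MoaEffect":
        return cls(MoaKind.CATABOLIC, scale=scale)

    @classmethod
    def anabolic(cls, scale: float = 1.10) -> "MoaEffect":
        return cls(MoaKind.ANABOLIC, scale=scale)

    @classmethod
    def membrane_loss(cls, affected_fraction: float,
                      secondary_scale: float = 0.35) -> "MoaEffect":
        return cls(MoaKind.MEMBRANE_LOSS, scale=secondary_scale,
                   affected_fraction=affected_fraction)

    @classmethod
    def uniform_shift(cls, s: float) -> "MoaEffect":
        if s <= -1:
            raise ValidationError("uniform shift must keep masses positive")
        return cls(MoaKind.UNIFORM_SHIFT, scale=1.0 + s)


def apply_moa(
    records: Sequence[MassRecord],
    effect: MoaEffect,
    rng: np.random.Generator | int | None = None,
) -> list[MassRecord]:
    """Apply a drug effect to the cell records (intact cells; other particle
    classes pass through unchanged — drugs act on cells, not debris)."""
    gen = np.random.default_rng(rng)
    cell_idx = [i for i, r in enumerate(records)
                if r.particle_class is ParticleClass.INTACT]
    out = list(records)
    if not cell_idx:
        return out
    masses = np.array([records[i].mass for i in cell_idx])
    kind = effect.kind

    if kind in (MoaKind.G1_ARREST, MoaKind.G2_ARREST):
        mean = masses.mean()
        # linear contraction toward the (rescaled) mean: mean scales by
        # `scale`, CV shrinks by `spread` — the distribution consolidates
        # around the arrested-stage mass
        new = effect.scale * (mean + effect.spread * (masses - mean))
        for i, m in zip(cell_idx, new):
            out[i] = MassRecord(float(m), records[i].particle_class,
                                records[i].condition_id, records[i].role,
                                records[i].t_meas, records[i].instrument_id,
                                records[i].true_class)
    elif kind in (MoaKind.CATABOLIC, MoaKind.ANABOLIC, MoaKind.UNIFORM_SHIFT):
        new = effect.scale * masses
        for i, m in zip(cell_idx, new):
            out[i] = MassRecord(float(m), records[i].particle_class,
                                records[i].condition_id, records[i].role,
                                records[i].t_meas, records[i].instrument_id,
                                records[i].true_class)
    elif kind is MoaKind.MEMBRANE_LOSS:
        n_hit = int(round(effect.affected_fraction * len(cell_idx)))
        hit = set(gen.choice(len(cell_idx), size=n_hit, replace=False).tolist())
        for j, i in enumerate(cell_idx):
            if j in hit:
                r = records[i]
                out[i] = MassRecord(float(r.mass * effect.scale),
                                    ParticleClass.PERMEABLE,
                                    r.condition_id, r.role, r.t_meas,
                                    r.instrument_id, ParticleClass.PERMEABLE)
    else:  # pragma: no cover
        raise ValidationError(f"unknown effect kind {kind}")
    return out


def mix_populations(
    pops: Sequence[Sequence[MassRecord]],
    fractions: Sequence[float],
    n_total: int | None = None,
    rng: np.random.Generator | int | None = None,
) -> list[MassRecord]:
    """Mix populations at defined fractions (e.g. a responding fraction of
    drug-sensitive cells within a resistant background)."""
    fr = np.asarray(fractions, dtype=float)
    if len(pops) != fr.size:
        raise ValidationError("one fraction per population required")
    if np.any(fr < 0) or abs(fr.sum() - 1.0) > 1e-9:
        raise ValidationError("fractions must be non-negative and sum to 1")
    gen = np.random.default_rng(rng)
    if n_total is None:
        n_total = min(
            int(len(p) / f) if f > 0 else np.iinfo(np.int64).max
            for p, f in zip(pops, fr)
        )
    counts = np.floor(fr * n_total).astype(int)
    # distribute the rounding remainder to the largest fractions
    for i in np.argsort(-(fr * n_total - counts))[: n_total - counts.sum()]:
        counts[i] += 1
    out: list[MassRecord] = []
    for pop, k in zip(pops, counts):
        if k > len(pop):
            raise ValidationError("population too small for requested fraction")
        if k:
            picked = gen.choice(len(pop), size=k, replace=False)
            out.extend(pop[int(i)] for i in picked)
    return out


@dataclass(frozen=True)
class DriftModel:
    """Linear treatment-independent mass loss over the session:
    mass -> mass * (1 - rate * t_hours)."""

    rate: float  # fractional mass loss per hour

    def factor(self, t_hours: float) -> float:
        f = 1.0 - self.rate * t_hours
        if f <= 0:
            raise ValidationError(
                f"drift rate {self.rate}/h annihilates mass by t={t_hours} h"
            )
        return f

    def apply(self, records: Iterable[MassRecord]) -> list[MassRecord]:
        out = []
        for r in records:
            f = self.factor(r.t_meas / 3600.0)
            out.append(MassRecord(r.mass * f, r.particle_class, r.condition_id,
                                  r.role, r.t_meas, r.instrument_id, r.true_class))
        return out


def simulate_experiment(
    spec: SimulationSpec,
    effects: Mapping[str, MoaEffect | None],
    drift: DriftModel | None = None,
    n_per_condition: int = 2500,
    session_hours: float = 3.0,
    rng: np.random.Generator | int | None = None,
    *,
    instrument_id: str = "SIM-01",
    return_records: bool = False,
):
    """Generate a full reference/test/control session from one baseline spec.

    The vehicle-treated reference is measured at t=0, each test condition at
    evenly staggered times, and the vehicle-treated control at session end;
    all conditions share the baseline spec, vehicle conditions receive no
    drug effect, and drift (if any) acts on every particle at its
    measurement time.

    Returns an :class:`ExperimentSet` (or ``(ExperimentSet, records)`` when
    ``return_records`` is set).
    """
    if not effects:
        raise ValidationError("at least one test condition required")
    gen = np.random.default_rng(rng)
    cond_ids = list(effects)
    times = {cid: session_hours * (i + 1) / (len(cond_ids) + 1)
             for i, cid in enumerate(cond_ids)}
    plan: list[tuple[str, Role, float, MoaEffect | None]] = [
        ("VEHICLE_REF", Role.REFERENCE, 0.0, None),
        *[(cid, Role.TEST, times[cid], effects[cid]) for cid in cond_ids],
        ("VEHICLE_CTRL", Role.CONTROL, session_hours, None),
    ]
    records: list[MassRecord] = []
    for cid, role, t_h, effect in plan:
        recs = simulate_population(
            spec, n_per_condition, gen, condition_id=cid, role=role,
            t_meas=t_h * 3600.0, instrument_id=instrument_id,
        )
        if effect is not None:
            recs = apply_moa(recs, effect, gen)
        records.extend(recs)
    if drift is not None:
        records = drift.apply(records)
    exp = build_experiment(records, metadata={
        "instrument_id": instrument_id,
        "session_hours": session_hours,
        "n_per_condition": n_per_condition,
    })
    if return_records:
        return exp, records
    return exp


def noise_vs_n_scan(
    spec: SimulationSpec,
    n_values: Sequence[int],
    reps: int = 1000,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Baseline noise of the mass response versus cells measured.

    For each n, draws ``reps`` independent pairs of n-cell samples from the
    same population and records the mean and SD of the pairwise mass
    response — the signal one would (spuriously) measure between identical
    conditions.  Both decrease roughly as n^(-1/2).

    Returns a DataFrame with columns ``n``, ``mean_response``, ``sd_response``
    (fractions, not percent).
    """
    if reps < 2:
        raise ValidationError("reps must be >= 2")
    gen = np.random.default_rng(rng)
    rows = []
    for n in n_values:
        a = np.sort(sample_masses(spec, reps * int(n), gen).reshape(reps, int(n)),
                    axis=1)
        b = np.sort(sample_masses(spec, reps * int(n), gen).reshape(reps, int(n)),
                    axis=1)
        resp = np.abs(a - b).sum(axis=1) / b.sum(axis=1)
        rows.append({"n": int(n),
                     "mean_response": float(resp.mean()),
                     "sd_response": float(resp.std(ddof=1))})
    return pd.DataFrame(rows)
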