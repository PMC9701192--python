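"""Domain types for single-cell buoyant-mass drug-response analysis.

The measurement unit throughout is a *record*: one particle transiting the
mass sensor, carrying its buoyant mass in picograms (pg), an image-derived
particle-class label, the treatment condition it belongs to, the condition's
role in the experimental design, and the time it was measured.

An experiment follows a reference/control sandwich design: a vehicle-treated
sample is measured first (the *reference*, Z), drug-treated *test* conditions
(X) follow, and a second vehicle-treated replicate is measured last (the
*control*, Y).  The control-vs-reference distance quantifies treatment-
independent phenotypic drift over the session.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "ParticleClass",
    "Role",
    "Call",
    "MassRecord",
    "ConditionSample",
    "ExperimentSet",
    "InferenceConfig",
    "MassResponseResult",
    "TestResult",
    "ValidationError",
    "StructureError",
]


class ValidationError(ValueError):
    """A record, sample, or config violates a domain invariant."""


class StructureError(ValueError):
    """The experiment layout (reference/control/test roles) is malformed."""


class ParticleClass(str, enum.Enum):
    """Image-derived class of a measured particle."""

    INTACT = "intact"
    PERMEABLE = "permeable"
    AGGREGATE = "aggregate"
    DEBRIS = "debris"
    UNCLASSIFIED = "unclassified"


class Role(str, enum.Enum):
    """Role of a condition in the reference/test/control sandwich design."""

    REFERENCE = "reference"
    CONTROL = "control"
    TEST = "test"


class Call(str, enum.Enum):
    """Outcome of the response test for one drug condition."""

    RESPONSE = "response"
    NO_RESPONSE = "no_response"
    INCONCLUSIVE = "inconclusive"


# Classes whose mass must be strictly positive: cells and cell aggregates
# displace more fluid than they weigh only in pathological cases, and a
# non-positive mass there indicates a data error rather than physics.
_POSITIVE_MASS_CLASSES = frozenset(
    {ParticleClass.INTACT, ParticleClass.PERMEABLE, ParticleClass.AGGREGATE}
)


@dataclass(frozen=True)
class MassRecord:
    """One particle's measurement.

    Parameters
    ----------
    mass : float
        Buoyant mass in picograms.
    particle_class : ParticleClass
        Observed (image-derived or simulated-observed) class label.
    condition_id : str
        Identifier of the treatment condition.
    role : Role
        Role of the condition in the experiment design.
    t_meas : float
        Seconds since the start of the measurement session.
    instrument_id : str, optional
        Identifier of the measuring instrument.
    true_class : ParticleClass, optional
        Ground-truth class, retained by the simulator and the label-confusion
        emulator so classifier performance can be scored.
    """

    mass: float
    particle_class: ParticleClass = ParticleClass.UNCLASSIFIED
    condition_id: str = ""
    role: Role = Role.TEST
    t_meas: float = 0.0
    instrument_id: str | None = None
    true_class: ParticleClass | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.mass):
            raise ValidationError(f"mass must be finite, got {self.mass!r}")
        if self.particle_class in _POSITIVE_MASS_CLASSES and self.mass <= 0:
            raise ValidationError(
                f"{self.particle_class.value} particle must have mass > 0 pg, "
                f"got {self.mass!r}"
            )
        if self.t_meas < 0:
            raise ValidationError(f"t_meas must be >= 0, got {self.t_meas!r}")

    def with_observed_class(self, observed: ParticleClass) -> "MassRecord":
        """Return a copy relabelled with ``observed``, keeping the truth."""
        truth = self.true_class if self.true_class is not None else self.particle_class
        return replace(self, particle_class=observed, true_class=truth)


@dataclass
class ConditionSample:
    """The ordered mass sample for one condition/role.

    Masses are canonicalized to an ascending-sorted float array on
    construction, the form required by the order-statistic EMD pairing.
    """

    condition_id: str
    role: Role
    masses: np.ndarray
    curated: bool = False

    def __post_init__(self) -> None:
        m = np.asarray(self.masses, dtype=float)
        if m.ndim != 1 or m.size == 0:
            raise ValidationError(
                f"condition {self.condition_id!r}: masses must be a non-empty 1-D array"
            )
        if not np.all(np.isfinite(m)):
            raise ValidationError(f"condition {self.condition_id!r}: non-finite mass")
        if np.any(m <= 0):
            raise ValidationError(
                f"condition {self.condition_id!r}: all masses must be > 0 pg"
            )
        self.masses = np.sort(m)

    @property
    def n(self) -> int:
        return int(self.masses.size)

    def subsample(self, n: int, rng: np.random.Generator) -> "ConditionSample":
        """Seeded subsample of ``n`` cells without replacement (sorted)."""
        if n >= self.n:
            return self
        picked = rng.choice(self.masses, size=n, replace=False)
        return ConditionSample(self.condition_id, self.role, picked, self.curated)


@dataclass
class ExperimentSet:
    """One measurement session: reference (Z), control (Y), and test samples."""

    reference: ConditionSample
    control: ConditionSample
    tests: list[ConditionSample]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.reference.role is not Role.REFERENCE:
            raise StructureError("reference sample must have role 'reference'")
        if self.control.role is not Role.CONTROL:
            raise StructureError("control sample must have role 'control'")
        for t in self.tests:
            if t.role is not Role.TEST:
                raise StructureError(
                    f"test sample {t.condition_id!r} must have role 'test'"
                )

    @property
    def condition_ids(self) -> list[str]:
        return [t.condition_id for t in self.tests]


def build_experiment(
    records: Iterable[MassRecord],
    *,
    curated: bool = False,
    metadata: dict | None = None,
) -> ExperimentSet:
    """Group records by condition into an :class:`ExperimentSet`.

    Exactly one condition must carry role ``reference`` and one role
    ``control``.  Masses within each condition are sorted ascending.  The
    sandwich design expects the reference measured first and the control
    last; a violation of that time ordering is warned about, not rejected.
    """
    by_condition: dict[str, list[MassRecord]] = {}
    order: list[str] = []
    for rec in records:
        if rec.condition_id not in by_condition:
            by_condition[rec.condition_id] = []
            order.append(rec.condition_id)
        by_condition[rec.condition_id].append(rec)
    if not by_condition:
        raise StructureError("no records supplied")

    samples: dict[str, ConditionSample] = {}
    roles: dict[str, Role] = {}
    times: dict[str, float] = {}
    for cid in sorted(order):
        recs = by_condition[cid]
        role_set = {r.role for r in recs}
        if len(role_set) != 1:
            raise StructureError(f"condition {cid!r} has mixed roles {role_set}")
        role = role_set.pop()
        roles[cid] = role
        times[cid] = float(np.median([r.t_meas for r in recs]))
        samples[cid] = ConditionSample(
            cid, role, np.array([r.mass for r in recs]), curated=curated
        )

    refs = [c for c, r in roles.items() if r is Role.REFERENCE]
    ctrls = [c for c, r in roles.items() if r is Role.CONTROL]
    if len(refs) != 1:
        raise StructureError(f"expected exactly one reference condition, got {refs}")
    if len(ctrls) != 1:
        raise StructureError(f"expected exactly one control condition, got {ctrls}")

    ref, ctrl = samples[refs[0]], samples[ctrls[0]]
    test_ids = sorted(c for c, r in roles.items() if r is Role.TEST)
    measured = [times[refs[0]]] + [times[c] for c in test_ids] + [times[ctrls[0]]]
    if measured != sorted(measured):
        warnings.warn(
            "measurement times violate the reference-first / control-last "
            "sandwich ordering",
            stacklevel=2,
        )
    return ExperimentSet(
        reference=ref,
        control=ctrl,
        tests=[samples[c] for c in test_ids],
        metadata=dict(metadata or {}),
    )


@dataclass
class InferenceConfig:
    """Tuning parameters of the response test.

    Attributes
    ----------
    theta0 : float
        Limit of decision, as a fraction (0.03 = 3%): the smallest mass
        response considered biologically meaningful, three sigma of the
        500-cell resampling distance.
    alpha : float
        Significance level for the one-sided test of H0: theta <= theta0.
    N : int
        Cells per distribution used for inference; larger samples are
        subsampled to N (seeded, without replacement).
    R_ci : int
        Bootstrap replicates for the mass-response confidence interval.
    R_test : int
        Outer replicates of the embedded bootstrap-t test.  The smallest
        attainable p-value is 1/(1+R_test).
    r_inner : int
        Inner replicates used to estimate the standard error S of theta.
    ci_level : float
        Confidence level of the reported interval (0.90 default, 0.95
        supported).
    ci_method : str
        Interval estimator: "bca" (default) or "percentile".
    drift_limit : float
        Control-vs-reference mass response above which the run is called
        inconclusive (phenotypic drift too large).
    min_n : int
        Sample size below which results carry a low-n warning flag.
    seed : int
        Master seed for all resampling.
    """

    theta0: float = 0.03
    alpha: float = 0.05
    N: int = 2500
    R_ci: int = 5000
    R_test: int = 999
    r_inner: int = 19
    ci_level: float = 0.90
    ci_method: str = "bca"
    drift_limit: float = 0.10
    min_n: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.theta0 < 1:
            raise ValidationError("theta0 must be in (0, 1)")
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must be in (0, 1)")
        if self.R_test < 1:
            raise ValidationError("R_test must be >= 1")
        if self.r_inner < 2:
            raise ValidationError("r_inner must be >= 2")
        if not 0 < self.ci_level < 1:
            raise ValidationError("ci_level must be in (0, 1)")
        if self.ci_method not in ("bca", "percentile"):
            raise ValidationError("ci_method must be 'bca' or 'percentile'")

    def to_dict(self) -> dict:
        return {
            "theta0": self.theta0,
            "alpha": self.alpha,
            "N": self.N,
            "R_ci": self.R_ci,
            "R_test": self.R_test,
            "r_inner": self.r_inner,
            "ci_level": self.ci_level,
            "ci_method": self.ci_method,
            "drift_limit": self.drift_limit,
            "min_n": self.min_n,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "InferenceConfig":
        known = {k: d[k] for k in cls.__dataclass_fields__ if k in d}
        unknown = set(d) - set(known)
        if unknown:
            raise ValidationError(f"unknown config fields: {sorted(unknown)}")
        return cls(**known)


@dataclass
class MassResponseResult:
    """A normalized-EMD mass response with its bootstrap confidence interval.

    ``value`` is a unitless fraction of the reference mean mass; reports
    render it as a percent.
    """

    value: float
    n_x: int
    n_z: int
    ci_low: float | None = None
    ci_high: float | None = None
    ci_level: float | None = None
    R_ci: int | None = None
    direction_hint: int = 0
    low_n: bool = False
    degenerate_ci: bool = False

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValidationError("mass response is non-negative by construction")


@dataclass
class TestResult:
    """Outcome of the embedded bootstrap-t response test for one condition."""

    __test__ = False  # not a pytest class, despite the name

    condition_id: str
    test_signal: float
    ctrl_signal: float
    theta_hat: float
    se_hat: float
    t_obs: float
    p_value: float
    call: Call | None = None
    n_used: dict = field(default_factory=dict)
    seed: int | None = None
    test_ci: tuple[float, float] | None = None
    ctrl_ci: tuple[float, float] | None = None
    ci_level: float | None = None
    low_n: bool = False

    def to_dict(self) -> dict:
        return {
            "condition_id": self.condition_id,
            "test_signal": self.test_signal,
            "ctrl_signal": self.ctrl_signal,
            "theta_hat": self.theta_hat,
            "se_hat": self.se_hat,
            "t_obs": self.t_obs,
            "p_value": self.p_value,
            "call": self.call.value if self.call is not None else None,
            "n_used": dict(self.n_used),
            "seed": self.seed,
            "test_ci": list(self.test_ci) if self.test_ci is not None else None,
            "ctrl_ci": list(self.ctrl_ci) if self.ctrl_ci is not None else None,
            "ci_level": self.ci_level,
            "low_n": self.low_n,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TestResult":
        d = dict(d)
        if d.get("call") is not None:
            d["call"] = Call(d["call"])
        for k in ("test_ci", "ctrl_ci"):
            if d.get(k) is not None:
                d[k] = tuple(d[k])
        return cls(**{k: d[k] for k in cls.__dataclass_fields__ if k in d})


def coerce_particle_class(label: object) -> ParticleClass:
    """Map a free-text class label to the enum; unknown -> UNCLASSIFIED."""
    if isinstance(label, ParticleClass):
        return label
    text = str(label).strip().lower()
    try:
        return ParticleClass(text)
    except ValueError:
        warnings.warn(f"unknown particle class {label!r} mapped to unclassified",
                      stacklevel=2)
        return ParticleClass.UNCLASSIFIED


def records_from_arrays(
    masses: Sequence[float] | np.ndarray,
    *,
    particle_class: ParticleClass = ParticleClass.INTACT,
    condition_id: str = "",
    role: Role = Role.TEST,
    t_meas: float = 0.0,
    instrument_id: str | None = None,
) -> list[MassRecord]:
    """Convenience constructor: one record per mass, shared metadata."""
    return [
        MassRecord(
            mass=float(m),
            particle_class=particle_class,
            condition_id=condition_id,
            role=role,
            t_meas=t_meas,
            instrument_id=instrument_id,
        )
        for m in np.asarray(masses, dtype=float)
    ]
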