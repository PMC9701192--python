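"""Measurement curation by particle class.

Processed specimens contain, besides the intact single cells of interest,
permeabilized cells, cell aggregates, and debris.  Mass alone cannot
separate these, so each measurement carries an image-derived class label;
curation restricts the analysis to accepted classes (intact and permeable
single cells by default) before any statistic is computed.  The classifier
itself is out of scope here — curation consumes labels from any source, and
:class:`ConfusionSpec` emulates an imperfect classifier by drawing observed
labels from per-class confusion rows, so the benefit of curation can be
studied as a function of label fidelity.

The fidelity benefit is quantified as *sampling error*: the spread of the
mass response across random fixed-size subsets of a condition.  Removing
aggregates and debris removes heavy-tailed contamination, shrinking that
spread.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from .datamodel import (
    ConditionSample,
    MassRecord,
    ParticleClass,
    ValidationError,
)
from .response import _as_masses, mass_response

__all__ = [
    "CurationPolicy",
    "ConfusionSpec",
    "curate",
    "sampling_error",
    "apply_confusion",
    "precision_recall",
]

#: classes a confusion matrix is defined over (unclassified is an output of
#: ingestion, not of a classifier)
CONFUSABLE_CLASSES = (
    ParticleClass.INTACT,
    ParticleClass.PERMEABLE,
    ParticleClass.AGGREGATE,
    ParticleClass.DEBRIS,
)


@dataclass(frozen=True)
class CurationPolicy:
    """Which particle classes enter the analysis.

    The default accepts intact and permeable single cells — permeability is
    a viability readout, not a rejection criterion — and rejects aggregates,
    debris, and unclassified events.
    """

    accepted_classes: frozenset[ParticleClass] = frozenset(
        {ParticleClass.INTACT, ParticleClass.PERMEABLE}
    )
    treat_unclassified: str = "reject"  # or "accept"

    def __post_init__(self) -> None:
        accepted = frozenset(ParticleClass(c) for c in self.accepted_classes)
        if not accepted:
            raise ValidationError("accepted_classes must be non-empty")
        object.__setattr__(self, "accepted_classes", accepted)
        if self.treat_unclassified not in ("reject", "accept"):
            raise ValidationError("treat_unclassified must be 'reject' or 'accept'")

    def accepts(self, cls: ParticleClass) -> bool:
        if cls is ParticleClass.UNCLASSIFIED:
            return (self.treat_unclassified == "accept"
                    or ParticleClass.UNCLASSIFIED in self.accepted_classes)
        return cls in self.accepted_classes

    @classmethod
    def strict_intact(cls) -> "CurationPolicy":
        """Intact single cells only."""
        return cls(accepted_classes=frozenset({ParticleClass.INTACT}))


def curate(
    records: Iterable[MassRecord],
    policy: CurationPolicy | None = None,
) -> tuple[dict[str, ConditionSample], dict[str, Counter]]:
    """Filter records by particle class and group them per condition.

    Returns ``(samples, removed)`` where ``samples`` maps condition_id to a
    curated :class:`ConditionSample` (sorted masses) and ``removed`` maps
    condition_id to a per-class counter of rejected events.  Mass values are
    never altered, only excluded.

    Raises an error naming the condition if curation removes every record
    of a condition.
    """
    policy = policy if policy is not None else CurationPolicy()
    kept: dict[str, list[MassRecord]] = {}
    removed: dict[str, Counter] = {}
    roles: dict[str, object] = {}
    for rec in records:
        cid = rec.condition_id
        removed.setdefault(cid, Counter())
        kept.setdefault(cid, [])
        roles[cid] = rec.role
        if policy.accepts(rec.particle_class):
            kept[cid].append(rec)
        else:
            removed[cid][rec.particle_class.value] += 1
    samples: dict[str, ConditionSample] = {}
    for cid, recs in kept.items():
        if not recs:
            raise ValidationError(
                f"curation removed every record of condition {cid!r}"
            )
        samples[cid] = ConditionSample(
            cid, roles[cid], np.array([r.mass for r in recs]), curated=True
        )
    return samples, removed


def sampling_error(
    masses,
    reference,
    subset_size: int = 1000,
    reps: int = 100,
    rng: np.random.Generator | int | None = None,
) -> tuple[float, float]:
    """Subset-resampling noise of the mass response for one condition.

    Draws ``reps`` random ``subset_size``-cell subsets of ``masses`` (each
    without replacement), computes the mass response of every subset against
    ``reference``, and returns ``(mean, sd)`` of those responses.  The SD is
    the sampling-error metric: how much the reported response would wobble
    had a different subset of the same condition been measured.
    """
    m = _as_masses(masses)
    ref = _as_masses(reference)
    if subset_size > m.size:
        raise ValidationError(
            f"subset_size {subset_size} exceeds sample size {m.size}"
        )
    gen = np.random.default_rng(rng)
    vals = np.empty(reps)
    for i in range(reps):
        sub = gen.choice(m, size=subset_size, replace=False)
        vals[i] = mass_response(sub, ref)
    return float(vals.mean()), float(vals.std(ddof=1))


@dataclass
class ConfusionSpec:
    """Row-stochastic label-confusion matrix over the four particle classes.

    ``rows[true_class][observed_class]`` is the probability that a particle
    of ``true_class`` is labelled ``observed_class``.
    """

    rows: dict[ParticleClass, dict[ParticleClass, float]] = field(default_factory=dict)
    tol: float = 1e-9

    def __post_init__(self) -> None:
        canon: dict[ParticleClass, dict[ParticleClass, float]] = {}
        for true_cls, row in self.rows.items():
            true_cls = ParticleClass(true_cls)
            crow = {ParticleClass(k): float(v) for k, v in row.items()}
            if any(v < 0 or v > 1 for v in crow.values()):
                raise ValidationError(f"confusion row for {true_cls.value}: "
                                      "entries must lie in [0, 1]")
            total = sum(crow.values())
            if abs(total - 1.0) > self.tol:
                raise ValidationError(
                    f"confusion row for {true_cls.value} sums to {total}, not 1"
                )
            canon[true_cls] = crow
        self.rows = canon

    @classmethod
    def identity(cls) -> "ConfusionSpec":
        return cls(rows={c: {c: 1.0} for c in CONFUSABLE_CLASSES})

    @classmethod
    def uniform_diagonal(cls, diag: float) -> "ConfusionSpec":
        """Each class kept with probability ``diag``, errors spread evenly."""
        off = (1.0 - diag) / (len(CONFUSABLE_CLASSES) - 1)
        return cls(rows={
            c: {d: (diag if d is c else off) for d in CONFUSABLE_CLASSES}
            for c in CONFUSABLE_CLASSES
        })

    @classmethod
    def from_dict(cls, d: Mapping[str, Mapping[str, float]]) -> "ConfusionSpec":
        return cls(rows={ParticleClass(k): dict(v) for k, v in d.items()})

    def to_dict(self) -> dict:
        return {t.value: {o.value: p for o, p in row.items()}
                for t, row in self.rows.items()}


def apply_confusion(
    records: Iterable[MassRecord],
    spec: ConfusionSpec,
    rng: np.random.Generator | int | None = None,
) -> list[MassRecord]:
    """Draw an observed class for each record from its true class's
    confusion row; the true class is retained on the record."""
    gen = np.random.default_rng(rng)
    out: list[MassRecord] = []
    for rec in records:
        truth = rec.true_class if rec.true_class is not None else rec.particle_class
        row = spec.rows.get(truth)
        if row is None:
            out.append(rec.with_observed_class(truth))
            continue
        classes = list(row.keys())
        probs = np.array([row[c] for c in classes])
        observed = classes[gen.choice(len(classes), p=probs)]
        out.append(rec.with_observed_class(observed))
    return out


def precision_recall(
    records: Iterable[MassRecord],
) -> dict[str, dict[str, float]]:
    """Per-class precision and recall of observed vs true labels.

    Returns ``{class: {"precision": .., "recall": ..}}``; a metric whose
    denominator is empty (class absent from predictions or from truth) is
    omitted rather than reported as zero.
    """
    records = list(records)
    if not records:
        raise ValidationError("no records to score")
    tp: Counter = Counter()
    pred: Counter = Counter()
    truth: Counter = Counter()
    for rec in records:
        if rec.true_class is None:
            raise ValidationError("records must carry true_class to score labels")
        t, o = rec.true_class, rec.particle_class
        truth[t] += 1
        pred[o] += 1
        if t is o:
            tp[t] += 1
    out: dict[str, dict[str, float]] = {}
    for cls in set(truth) | set(pred):
        metrics: dict[str, float] = {}
        if pred[cls] > 0:
            metrics["precision"] = tp[cls] / pred[cls]
        if truth[cls] > 0:
            metrics["recall"] = tp[cls] / truth[cls]
        out[cls.value] = metrics
    return out
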