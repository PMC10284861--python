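"""Trustworthiness certificates.

Every inference can be labelled ``pass`` / ``warning`` / ``fail`` per
property by the flow

    inference -> property value (nonnegative scalar) -> empirical CDF -> label.

Property values quantify one aspect of an inference (sparsity, measurement
fidelity, constraint distance, total variation, iterate residual, proximal
residual); the CDF is calibrated from property values of model inferences on
training data or of ground truths; labels cut the CDF at configured
probabilities, e.g. (p_pass, p_warn, p_fail) = (0.95, 0, 0.05).

Tie handling: the empirical CDF counts ties inclusively
(``#{alpha_i <= alpha}/N``), but labels are derived from the *strict* count
``#{alpha_i < alpha}/N`` — "fails if worse than 95% of calibration values".
The two coincide almost surely for continuous property distributions, and the
strict form makes properties that hold by construction (e.g. box-constraint
distance, identically zero) pass rather than sit at CDF 1.  Certificates
record both values so labels stay re-derivable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Callable, Dict, Iterable, List

import numpy as np

from .prox_ops import project_box

__all__ = [
    "PropertySpec",
    "CalibrationTable",
    "LabelPolicy",
    "Certificate",
    "property_sparsity",
    "property_l1",
    "property_rel_error",
    "property_total_variation",
    "property_box_distance",
    "property_ball_distance",
    "property_iterate_residual",
    "property_prox_residual",
    "property_classifier_confidence",
    "empirical_cdf",
    "assign_label",
    "calibrate",
    "certify",
    "is_trustworthy",
]


# ---------------------------------------------------------------------------
# property value functions (each maps an inference to a nonnegative scalar)
# ---------------------------------------------------------------------------

def property_sparsity(x, zero_tol=None):
    """Number of entries with magnitude above ``zero_tol``.

    The default tolerance ``1e-6 * max(1, ||x||_inf)`` is scale-invariant:
    shrinkage produces exact zeros but L-ADMM limits are approximate.
    """
    x = np.asarray(x, dtype=float)
    if zero_tol is None:
        zero_tol = 1e-6 * max(1.0, float(np.max(np.abs(x))) if x.size else 1.0)
    if zero_tol < 0:
        raise ValueError("zero_tol must be nonnegative")
    return float(np.count_nonzero(np.abs(x) > zero_tol))

def property_l1(x):
    """l1 norm — the sparsity quantification used for IDM codes ``Kx``."""
    return float(np.sum(np.abs(np.asarray(x, dtype=float))))


def property_rel_error(A, x, d):
    """Measurement fidelity ``||Ax - d|| / ||d||``."""
    d = np.asarray(d, dtype=float)
    nd = float(np.linalg.norm(d))
    if nd == 0.0:
        raise ValueError("relative error undefined for d = 0")
    return float(np.linalg.norm(A.forward(x) - d)) / nd


def property_total_variation(image):
    """Anisotropic total variation: sum of |forward differences| along both
    axes, no wraparound."""
    img = np.atleast_2d(np.asarray(image, dtype=float))
    return float(np.sum(np.abs(np.diff(img, axis=0))) +
                 np.sum(np.abs(np.diff(img, axis=1))))


def property_box_distance(x, lo=0.0, hi=1.0):
    """Euclidean distance from ``x`` to the box ``[lo, hi]^n``."""
    x = np.asarray(x, dtype=float)
    return float(np.linalg.norm(x - project_box(x, lo, hi)))


def property_ball_distance(A, x, d, delta, tol=0.0):
    """Distance beyond the fidelity ball: ``max(||Ax-d|| - delta - tol, 0)``.

    ``tol`` absorbs solver feasibility slack so that a constraint satisfied
    to numerical tolerance reports exactly zero.
    """
    r = float(np.linalg.norm(A.forward(x) - np.asarray(d, dtype=float)))
    return max(r - float(delta) - tol, 0.0)


def property_iterate_residual(state):
    """``||x^k - x^{k-1}||`` at the stopping iterate of a fixed-point run."""
    if state.k < 1:
        raise ValueError("no iterations recorded")
    return float(state.residual)


def property_prox_residual(x, prox):
    """``||x - prox(x)||`` for the data-driven regularizer."""
    from .prox_ops import learned_prox_residual
    return learned_prox_residual(x, prox)


def property_classifier_confidence(x):
    """``1 - max_i x_i`` for a unit-simplex output (registered for
    completeness; no classification experiment ships with the package)."""
    return float(1.0 - np.max(np.asarray(x, dtype=float)))


@dataclass
class PropertySpec:
    """A named property-value function over inference records."""

    name: str
    evaluate: Callable[[dict], float]
    description: str = ""

    def __call__(self, record):
        value = float(self.evaluate(record))
        if not np.isfinite(value) or value < 0:
            raise ValueError(f"property {self.name!r} produced {value}")
        return value


# ---------------------------------------------------------------------------
# calibration and labels
# ---------------------------------------------------------------------------

@dataclass
class CalibrationTable:
    """Sorted property-value samples defining the empirical CDF."""

    name: str
    samples: np.ndarray
    source: str = "training-inferences"

    def __post_init__(self):
        s = np.sort(np.asarray(self.samples, dtype=float))
        if s.size < 1:
            raise ValueError("calibration requires at least one sample")
        self.samples = s

    @property
    def N(self):
        return int(self.samples.size)

    def cdf(self, alpha):
        return empirical_cdf(alpha, self)

    def cdf_lower(self, alpha):
        """Strict-count CDF ``#{alpha_i < alpha}/N`` used for labelling."""
        return float(np.searchsorted(self.samples, alpha, side="left")) / self.N


def empirical_cdf(alpha, table: CalibrationTable):
    """Inclusive empirical CDF ``#{alpha_i <= alpha}/N`` (right-continuous
    step function, evaluated by binary search on the sorted samples)."""
    return float(np.searchsorted(table.samples, alpha, side="right")) / table.N


@dataclass
class LabelPolicy:
    """Pass/warning/fail probabilities, stored exactly as rationals."""

    p_pass: Fraction
    p_warn: Fraction
    p_fail: Fraction

    def __init__(self, p_pass, p_warn=None, p_fail=None):
        self.p_pass = _as_fraction(p_pass)
        if p_warn is None and p_fail is None:
            raise ValueError("give at least one of p_warn, p_fail")
        if p_warn is None:
            self.p_fail = _as_fraction(p_fail)
            self.p_warn = 1 - self.p_pass - self.p_fail
        elif p_fail is None:
            self.p_warn = _as_fraction(p_warn)
            self.p_fail = 1 - self.p_pass - self.p_warn
        else:
            self.p_warn = _as_fraction(p_warn)
            self.p_fail = _as_fraction(p_fail)
        if self.p_pass + self.p_warn + self.p_fail != 1:
            raise ValueError("label probabilities must sum to 1 exactly")
        for p in (self.p_pass, self.p_warn, self.p_fail):
            if p < 0 or p > 1:
                raise ValueError("label probabilities must lie in [0, 1]")


def _as_fraction(p):
    if isinstance(p, Fraction):
        return p
    if isinstance(p, str):
        return Fraction(p)
    return Fraction(str(float(p)))


def assign_label(cdf, policy: LabelPolicy):
    """``pass`` if CDF < p_pass; ``warning`` on [p_pass, 1-p_fail);
    ``fail`` otherwise — half-open boundaries."""
    if not (0.0 <= cdf <= 1.0):
        raise ValueError("cdf value must lie in [0, 1]")
    c = Fraction(str(float(cdf))) if not isinstance(cdf, Fraction) else cdf
    if c < policy.p_pass:
        return "pass"
    if c < 1 - policy.p_fail:
        return "warning"
    return "fail"


@dataclass
class Certificate:
    """One labelled property of one inference."""

    name: str
    label: str
    value: float
    cdf: float          # inclusive empirical CDF at value
    cdf_lower: float    # strict-count CDF at value (drives the label)

    def to_json(self):
        return json.dumps(self.__dict__)


def calibrate(property: PropertySpec, records: Iterable, source="training-inferences"):
    """Evaluate a property over calibration records and store the sorted
    sample table with provenance."""
    values = [property(rec) for rec in records]
    if not values:
        raise ValueError("calibration records are empty")
    return CalibrationTable(name=property.name, samples=np.asarray(values),
                            source=source)


def certify(record, properties: List[PropertySpec],
            tables: Dict[str, CalibrationTable], policy: LabelPolicy):
    """One :class:`Certificate` per property, order preserved."""
    certs = []
    for prop in properties:
        table = tables.get(prop.name)
        if table is None:
            raise KeyError(f"no calibration table for property {prop.name!r}")
        value = prop(record)
        certs.append(Certificate(
            name=prop.name,
            label=assign_label(table.cdf_lower(value), policy),
            value=value,
            cdf=table.cdf(value),
            cdf_lower=table.cdf_lower(value),
        ))
    return certs


def is_trustworthy(certificates):
    """An inference is trustworthy iff every certificate passes."""
    return all(c.label == "pass" for c in certificates)
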