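"""Library of sonographic fetal-weight estimation formulas.

Each formula maps a subset of the four standard biometric parameters —
biparietal diameter (BPD), head circumference (HC), abdominal circumference
(AC) and femur length (FL), all in centimetres — to an estimated fetal
weight (EFW) in grams.  Formulas are encoded declaratively: a structural
form tag (``linear``, ``log10`` or ``exp``), an output scale factor, and a
list of polynomial terms, optionally carrying a logarithmic factor.  This
keeps the registry data-driven and the coefficients introspectable, so that
e.g. a log10-linear formula's exponent can be cross-checked term by term.

The registry is built from the packaged manifest ``data/formulas.json`` and
contains every multi-parameter formula under study (29 entries).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, Iterator, Mapping, Optional, Sequence, Tuple

import numpy as np

from .exceptions import (
    MissingParameterError,
    UnknownFormulaError,
    ValidationError,
)

#: Canonical ordering of the biometric parameters used throughout the package.
PARAMETERS: Tuple[str, ...] = ("BPD", "HC", "AC", "FL")

_FIELD_TO_PARAM = {"bpd": "BPD", "hc": "HC", "ac": "AC", "fl": "FL"}


@dataclass(frozen=True)
class BiometricVector:
    """One fetus's ultrasound measurements, in centimetres.

    Any subset of the four parameters may be present; absent ones are None.
    Present values must be finite and strictly positive.
    """

    bpd: Optional[float] = None
    hc: Optional[float] = None
    ac: Optional[float] = None
    fl: Optional[float] = None

    def __post_init__(self):
        for f, p in _FIELD_TO_PARAM.items():
            v = getattr(self, f)
            if v is None:
                continue
            if not math.isfinite(v) or v <= 0:
                raise ValidationError(
                    f"{p} must be finite and > 0 (cm), got {v!r}"
                )

    @property
    def present(self) -> Tuple[str, ...]:
        """Parameters carrying a value, in canonical order."""
        return tuple(
            p for f, p in _FIELD_TO_PARAM.items() if getattr(self, f) is not None
        )

    def as_dict(self) -> Dict[str, float]:
        return {
            p: getattr(self, f)
            for f, p in _FIELD_TO_PARAM.items()
            if getattr(self, f) is not None
        }


@dataclass(frozen=True)
class Term:
    """One additive term: ``coef * prod(param**power) [* log_base(param/denom)]``."""

    coef: float
    powers: Mapping[str, int]
    log_param: Optional[str] = None
    log_base: str = "e"  # "e" or "10"
    log_denom: float = 1.0

    def __call__(self, values: Mapping[str, np.ndarray]) -> np.ndarray:
        out = np.asarray(self.coef, dtype=float)
        for p, k in self.powers.items():
            out = out * np.asarray(values[p], dtype=float) ** k
        if self.log_param is not None:
            x = np.asarray(values[self.log_param], dtype=float) / self.log_denom
            out = out * (np.log10(x) if self.log_base == "10" else np.log(x))
        return out

    @property
    def parameters(self) -> frozenset:
        ps = set(self.powers)
        if self.log_param is not None:
            ps.add(self.log_param)
        return frozenset(ps)


@dataclass(frozen=True)
class FormulaSpec:
    """A single EFW formula: identity, required parameters, evaluation rule.

    ``form`` selects the outer map applied to the summed terms:
    ``linear`` (identity), ``log10`` (10**sum) or ``exp`` (e**sum); the result
    is multiplied by ``scale_grams`` (1000 for formulas whose original
    publication reports kilograms).
    """

    name: str
    display_name: str
    form: str
    terms: Tuple[Term, ...]
    scale_grams: float = 1.0
    source_citation: str = ""

    def __post_init__(self):
        if self.form not in ("linear", "log10", "exp"):
            raise ValidationError(f"unknown structural form {self.form!r}")
        if len(self.required_params) < 2:
            raise ValidationError(
                f"formula {self.name!r} uses fewer than two parameters"
            )

    @property
    def required_params(self) -> Tuple[str, ...]:
        """Parameters appearing in the expression, in canonical order."""
        used = set().union(*(t.parameters for t in self.terms))
        return tuple(p for p in PARAMETERS if p in used)

    def exponent(self, values: Mapping[str, np.ndarray]) -> np.ndarray:
        """Sum of terms before the outer map (the log10/ln exponent for
        log-form formulas, the weight itself for linear ones)."""
        return sum(t(values) for t in self.terms)

    def evaluate_arrays(self, values: Mapping[str, np.ndarray]) -> np.ndarray:
        """Vectorized evaluation on arrays of measurements (cm) -> grams.

        No positivity validation is applied here; callers sampling within
        physiological bounds (or probing limits such as vanishing biometry)
        use this path directly.
        """
        for p in self.required_params:
            if p not in values:
                raise MissingParameterError(self.name, p)
        s = self.exponent(values)
        if self.form == "log10":
            out = 10.0 ** s
        elif self.form == "exp":
            out = np.exp(s)
        else:
            out = s
        return self.scale_grams * np.asarray(out, dtype=float)

    def __call__(self, biometrics: BiometricVector) -> float:
        return evaluate_formula(self, biometrics)


def evaluate_formula(spec: FormulaSpec, biometrics: BiometricVector) -> float:
    """Evaluate one formula on one validated measurement vector -> grams."""
    values = biometrics.as_dict()
    for p in spec.required_params:
        if p not in values:
            raise MissingParameterError(spec.name, p)
    out = float(spec.evaluate_arrays({p: np.float64(values[p]) for p in spec.required_params}))
    if not math.isfinite(out):
        raise ValidationError(
            f"formula {spec.name!r} produced a non-finite weight for {values}"
        )
    return out


@dataclass
class MonotonicityReport:
    """Diagnostic outcome of a grid monotonicity check for one parameter."""

    parameter: str
    monotone_increasing: bool
    violations: list = field(default_factory=list)  # grid points (dicts)


def check_monotonicity(
    spec: FormulaSpec,
    bounds: Mapping[str, Tuple[float, float]],
    grid_size: int = 5,
    max_violations: int = 20,
) -> Dict[str, MonotonicityReport]:
    """Check that EFW is non-decreasing in each parameter on a regular grid.

    A clinically sensible formula grows with every biometric parameter; this
    is a diagnostic (it reports violations, never raises on them).  ``bounds``
    maps each required parameter to its (lower, upper) interval in cm.
    """
    if grid_size < 2:
        raise ValidationError("grid_size must be >= 2")
    params = spec.required_params
    for p in params:
        if p not in bounds:
            raise ValidationError(f"bounds missing required parameter {p!r}")
        lo, hi = bounds[p]
        if not (0 < lo < hi):
            raise ValidationError(f"invalid bounds for {p!r}: ({lo}, {hi})")
    axes = [np.linspace(bounds[p][0], bounds[p][1], grid_size) for p in params]
    mesh = np.meshgrid(*axes, indexing="ij")
    efw = spec.evaluate_arrays({p: m for p, m in zip(params, mesh)})
    reports = {}
    for i, p in enumerate(params):
        d = np.diff(efw, axis=i)
        tol = 1e-9 * max(1.0, float(np.abs(efw).max()))
        bad = np.argwhere(d < -tol)
        violations = []
        for idx in bad[:max_violations]:
            point = {q: float(axes[j][idx[j]]) for j, q in enumerate(params)}
            violations.append(point)
        reports[p] = MonotonicityReport(p, len(bad) == 0, violations)
    return reports


class FormulaRegistry:
    """Immutable name -> FormulaSpec mapping over the packaged manifest."""

    def __init__(self, specs: Sequence[FormulaSpec]):
        self._entries: Dict[str, FormulaSpec] = {}
        for s in specs:
            if s.name in self._entries:
                raise ValidationError(f"duplicate formula name {s.name!r}")
            self._entries[s.name] = s

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self) -> Iterator[FormulaSpec]:
        return iter(self._entries.values())

    def __contains__(self, name: str) -> bool:
        return name in self._entries

    @property
    def names(self) -> Tuple[str, ...]:
        return tuple(self._entries)

    def get(self, name: str) -> FormulaSpec:
        try:
            return self._entries[name]
        except KeyError:
            raise UnknownFormulaError(name) from None

    def subset(self, names: Sequence[str]) -> "FormulaRegistry":
        return FormulaRegistry([self.get(n) for n in names])


def _term_from_manifest(d: Mapping) -> Term:
    log = d.get("log")
    return Term(
        coef=float(d["coef"]),
        powers={k: int(v) for k, v in d.get("powers", {}).items()},
        log_param=None if log is None else log["param"],
        log_base="e" if log is None else str(log.get("base", "e")),
        log_denom=1.0 if log is None else float(log.get("denom", 1.0)),
    )


def load_registry() -> FormulaRegistry:
    """Build the full registry from the packaged formula manifest."""
    text = resources.files("efwsens.data").joinpath("formulas.json").read_text()
    manifest = json.loads(text)
    specs = [
        FormulaSpec(
            name=f["name"],
            display_name=f["display_name"],
            form=f["form"],
            scale_grams=float(f.get("scale_grams", 1.0)),
            terms=tuple(_term_from_manifest(t) for t in f["terms"]),
            source_citation=f.get("source", ""),
        )
        for f in manifest["formulas"]
    ]
    return FormulaRegistry(specs)


def required_parameters(name_or_spec, registry: Optional[FormulaRegistry] = None) -> Tuple[str, ...]:
    """Required parameters of a formula, by spec or by registry name."""
    if isinstance(name_or_spec, FormulaSpec):
        return name_or_spec.required_params
    reg = registry if registry is not None else load_registry()
    return reg.get(name_or_spec).required_params
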