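"""Drug-likeness rule filters, GI-absorption classification, marker admission.

Five published descriptor-threshold rule sets (Lipinski, Ghose, Veber, Egan,
Muegge) are evaluated against a per-compound descriptor record; the rule
engine never computes descriptors itself — they come from a CSV or from the
optional cheminformatics adapter in :mod:`phytomarker.descriptors`.

Gastrointestinal absorption (GA) is classified high/low by a point-in-ellipse
test in the (TPSA, WLOGP) plane; the default ellipse is the published
BOILED-Egg white (HIA) region (Daina & Zoete 2016). A candidate is admitted
as a quality marker when GA is high and at least ``min_rules_passed`` rule
sets pass — or, regardless of ADME, when its content exceeds the median of
the other constituents by more than ``content_override_fold`` (the
high-abundance override).

All thresholds live in editable config tables, not code constants.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

from .errors import ConfigError

RULE_NAMES = ("lipinski", "ghose", "veber", "egan", "muegge")

#: published thresholds per rule set; each entry is
#: (descriptor, comparator, bound) with comparators "<=", ">=", "<", ">"
DEFAULT_RULE_TABLE: dict[str, dict] = {
    # Lipinski et al. 2001 ("rule of five"); pass tolerates <= 1 violation
    "lipinski": {
        "conditions": [
            ("mw", "<=", 500.0),
            ("logp_lipinski", "<=", 5.0),
            ("hbd", "<=", 5.0),
            ("hba", "<=", 10.0),
        ],
        "max_violations": 1,
    },
    # Ghose et al. 1999 property box
    "ghose": {
        "conditions": [
            ("mw", ">=", 160.0), ("mw", "<=", 480.0),
            ("logp_wlogp", ">=", -0.4), ("logp_wlogp", "<=", 5.6),
            ("molar_refractivity", ">=", 40.0),
            ("molar_refractivity", "<=", 130.0),
            ("heavy_atoms", ">=", 20.0), ("heavy_atoms", "<=", 70.0),
        ],
        "max_violations": 0,
    },
    # Veber et al. 2002 oral bioavailability criteria
    "veber": {
        "conditions": [
            ("rotatable_bonds", "<=", 10.0),
            ("tpsa", "<=", 140.0),
        ],
        "max_violations": 0,
    },
    # Egan et al. 2000 passive-absorption box
    "egan": {
        "conditions": [
            ("logp_wlogp", "<=", 5.88),
            ("tpsa", "<=", 131.6),
        ],
        "max_violations": 0,
    },
    # Muegge et al. 2001 pharmacophore-point filter
    "muegge": {
        "conditions": [
            ("mw", ">=", 200.0), ("mw", "<=", 600.0),
            ("logp_muegge", ">=", -2.0), ("logp_muegge", "<=", 5.0),
            ("tpsa", "<=", 150.0),
            ("rings", "<=", 7.0),
            ("carbons", ">", 4.0),
            ("heteroatoms", ">", 1.0),
            ("rotatable_bonds", "<=", 15.0),
            ("hbd", "<=", 5.0),
            ("hba", "<=", 10.0),
        ],
        "max_violations": 0,
    },
}

_COMPARATORS = {
    "<=": lambda v, b: v <= b,
    ">=": lambda v, b: v >= b,
    "<": lambda v, b: v < b,
    ">": lambda v, b: v > b,
}


@dataclass
class DescriptorRecord:
    """Per-compound physicochemical descriptors (units in field names/docs).

    ``None`` marks a descriptor that was not supplied; any rule needing it
    is reported "not evaluable" rather than guessed.
    """

    compound_id: str
    mw: float | None = None                 # g/mol
    logp_mlogp: float | None = None         # Moriguchi logP
    logp_wlogp: float | None = None         # Wildman-Crippen logP
    logp_xlogp: float | None = None         # XLOGP3
    tpsa: float | None = None               # Å²
    hbd: float | None = None
    hba: float | None = None
    rotatable_bonds: float | None = None
    molar_refractivity: float | None = None
    heavy_atoms: float | None = None
    rings: float | None = None
    carbons: float | None = None
    heteroatoms: float | None = None

    def __post_init__(self) -> None:
        if self.mw is not None and self.mw <= 0:
            raise ConfigError("molecular weight must be > 0")
        for f in ("hbd", "hba", "rotatable_bonds", "heavy_atoms",
                  "rings", "carbons", "heteroatoms"):
            v = getattr(self, f)
            if v is not None and v < 0:
                raise ConfigError(f"{f} must be >= 0")

    def resolve(self, name: str) -> float | None:
        """Descriptor lookup with logP-estimator fallbacks.

        Lipinski's bound was stated for computed logP; the Moriguchi
        estimator is preferred when present, otherwise Wildman-Crippen is
        used. Muegge's bound prefers XLOGP3 with the same fallback.
        """
        if name == "logp_lipinski":
            for cand in (self.logp_mlogp, self.logp_wlogp, self.logp_xlogp):
                if cand is not None:
                    return cand
            return None
        if name == "logp_muegge":
            for cand in (self.logp_xlogp, self.logp_wlogp, self.logp_mlogp):
                if cand is not None:
                    return cand
            return None
        return getattr(self, name)


@dataclass
class RuleVerdict:
    rule: str
    passed: bool | None              # None = not evaluable
    violations: list[str] = field(default_factory=list)
    missing: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class GAEllipse:
    """Rotated ellipse in the (TPSA, WLOGP) plane; angle in degrees.

    Defaults: the published human-intestinal-absorption (white) region of
    the BOILED-Egg plot.
    """

    center_tpsa: float = 71.051
    center_wlogp: float = 2.292
    width: float = 142.081           # full axis along the rotated x direction
    height: float = 8.740
    angle_deg: float = -1.031325

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ConfigError("ellipse axes must be positive")


@dataclass
class AdmissionConfig:
    min_rules_passed: int = 3        # "over two" rule sets passing
    content_override_fold: float = 20.0
    ellipse: GAEllipse = field(default_factory=GAEllipse)

    def __post_init__(self) -> None:
        if self.content_override_fold <= 1:
            raise ConfigError("content_override_fold must exceed 1")


@dataclass
class DruglikenessReport:
    compound_id: str
    verdicts: dict[str, RuleVerdict]
    rules_passed: int
    rules_evaluable: int
    ga_class: str                    # "high" | "low" | "unknown"
    admissible: bool
    override_applied: bool
    content_ratio: float | None = None


def evaluate_rules(
    d: DescriptorRecord,
    rule_table: dict[str, dict] | None = None,
) -> dict[str, RuleVerdict]:
    """Evaluate every rule set; missing descriptors make a rule not evaluable."""
    table = rule_table or DEFAULT_RULE_TABLE
    verdicts: dict[str, RuleVerdict] = {}
    for rule, spec in table.items():
        violations: list[str] = []
        missing: list[str] = []
        for name, cmp_op, bound in spec["conditions"]:
            value = d.resolve(name)
            if value is None:
                missing.append(name)
                continue
            if not _COMPARATORS[cmp_op](value, bound):
                violations.append(f"{name} {value:g} violates {cmp_op} {bound:g}")
        if missing:
            verdicts[rule] = RuleVerdict(rule, None, violations, missing)
        else:
            ok = len(violations) <= spec.get("max_violations", 0)
            verdicts[rule] = RuleVerdict(rule, ok, violations)
    return verdicts


def classify_ga(tpsa: float, wlogp: float,
                ellipse: GAEllipse | None = None) -> str:
    """"high" iff (tpsa, wlogp) lies inside/on the absorption ellipse."""
    ellipse = ellipse or GAEllipse()
    if not (math.isfinite(tpsa) and math.isfinite(wlogp)):
        raise ConfigError("tpsa and wlogp must be finite")
    theta = math.radians(ellipse.angle_deg)
    dx = tpsa - ellipse.center_tpsa
    dy = wlogp - ellipse.center_wlogp
    u = dx * math.cos(theta) + dy * math.sin(theta)
    v = -dx * math.sin(theta) + dy * math.cos(theta)
    val = (u / (ellipse.width / 2.0)) ** 2 + (v / (ellipse.height / 2.0)) ** 2
    return "high" if val <= 1.0 else "low"   # boundary counts as inside


def admission_decision(
    ga_class: str,
    rules_passed: int,
    content_ratio: float | None,
    config: AdmissionConfig | None = None,
) -> tuple[bool, bool]:
    """The bare admission rule; returns (admissible, override_applied)."""
    config = config or AdmissionConfig()
    base = ga_class == "high" and rules_passed >= config.min_rules_passed
    override = (content_ratio is not None
                and content_ratio > config.content_override_fold)
    return bool(base or override), bool(override and not base)


def admit_marker(
    d: DescriptorRecord,
    relative_content: float,
    others_median_content: float,
    config: AdmissionConfig | None = None,
    rule_table: dict[str, dict] | None = None,
) -> DruglikenessReport:
    """Full admission decision for one candidate compound.

    admissible = (GA high AND >= min_rules_passed rule sets pass)
                 OR content ratio > content_override_fold
    """
    config = config or AdmissionConfig()
    if relative_content < 0 or others_median_content < 0:
        raise ConfigError("contents must be >= 0")
    verdicts = evaluate_rules(d, rule_table)
    evaluable = [v for v in verdicts.values() if v.passed is not None]
    n_passed = sum(v.passed for v in evaluable)
    if len(evaluable) < len(verdicts):
        skipped = sorted(r for r, v in verdicts.items() if v.passed is None)
        warnings.warn(f"rules not evaluable (missing descriptors): {skipped}")
    if d.tpsa is not None and d.logp_wlogp is not None:
        ga = classify_ga(d.tpsa, d.logp_wlogp, config.ellipse)
    else:
        ga = "unknown"
    ratio = (relative_content / others_median_content
             if others_median_content > 0 else None)
    admissible, override_applied = admission_decision(ga, int(n_passed),
                                                      ratio, config)
    return DruglikenessReport(
        compound_id=d.compound_id,
        verdicts=verdicts,
        rules_passed=int(n_passed),
        rules_evaluable=len(evaluable),
        ga_class=ga,
        admissible=admissible,
        override_applied=override_applied,
        content_ratio=ratio,
    )
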