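"""Candidate-marker screening rules over GRA and PLS outputs.

A compound becomes a candidate for an assay when both its VIP and its
standardized regression coefficient clear their thresholds (strictly:
VIP > 1 and coefficient > 0.1 by default). Assays probing the same
activity (DPPH and FRAP for antioxidant capacity) have different
sensitivities, so their candidate sets are unioned to reduce false
negatives. Grey relational degrees corroborate but never veto a
candidate: a GRD below the floor only raises a flag.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import AlignmentError, ConfigError, LookupError_
from .gra import GRAConfig, GRAResult, grey_relational_degree
from .io_tables import ActivityTable, PeakTable, align_tables
from .pls import (PermutationResult, cross_validate_q2, fit_pls,
                  permutation_test, select_components)


def _id_key(cid: str):
    return (0, int(cid)) if str(cid).isdigit() else (1, str(cid))


def sorted_ids(ids) -> list[str]:
    return sorted((str(c) for c in ids), key=_id_key)


@dataclass
class ScreeningConfig:
    vip_threshold: float = 1.0
    coef_threshold: float = 0.1
    grd_floor: float = 0.9            # annotation only, never exclusion
    union_assays: dict[str, list[str]] = field(
        default_factory=lambda: {
            "antioxidant": ["DPPH", "FRAP"],
            "anti_inflammatory": ["NO_inhibition"],
        })
    coef_mode: str = "signed"         # or "absolute"

    def __post_init__(self) -> None:
        if not (np.isfinite(self.vip_threshold)
                and np.isfinite(self.coef_threshold)):
            raise ConfigError("thresholds must be finite")
        if self.coef_mode not in ("signed", "absolute"):
            raise ConfigError("coef_mode must be 'signed' or 'absolute'")


@dataclass
class ModelSummary:
    """Quality block of one per-assay PLS model."""

    assay: str
    n_components: int
    r2y_cum: float
    q2_cum: float
    q2_by_component: list[float]
    permutation: PermutationResult | None = None


@dataclass
class ScreeningResult:
    per_assay: dict[str, list[str]]            # assay -> sorted candidate ids
    per_group: dict[str, list[str]]            # group -> sorted union ids
    provenance: dict[str, dict[str, list[str]]]  # group -> cid -> assays
    evidence: pd.DataFrame                     # compound × (vip/coef/grd/flags)
    models: dict[str, ModelSummary]
    gra: GRAResult | None
    config: ScreeningConfig

    def to_json(self) -> str:
        """Deterministic serialization (sorted keys, fixed float repr)."""
        payload = {
            "per_assay": {a: self.per_assay[a] for a in sorted(self.per_assay)},
            "per_group": {g: self.per_group[g] for g in sorted(self.per_group)},
            "provenance": {
                g: {c: sorted(v) for c, v in sorted(self.provenance[g].items())}
                for g in sorted(self.provenance)},
            "models": {
                a: {"n_components": m.n_components,
                    "r2y_cum": round(m.r2y_cum, 10),
                    "q2_cum": round(m.q2_cum, 10)}
                for a, m in sorted(self.models.items())},
        }
        return json.dumps(payload, sort_keys=True, indent=2)


def select_by_assay(
    vip: pd.Series | np.ndarray,
    coef: pd.Series | np.ndarray,
    config: ScreeningConfig | None = None,
    compound_ids: list[str] | None = None,
) -> set[str]:
    """{j : VIP_j > vip_threshold and coef_j > coef_threshold} (strict)."""
    config = config or ScreeningConfig()
    if isinstance(vip, pd.Series) and compound_ids is None:
        compound_ids = [str(i) for i in vip.index]
    vip = np.asarray(vip, dtype=float)
    coef = np.asarray(coef, dtype=float)
    if vip.shape != coef.shape:
        raise AlignmentError("VIP and coefficient vectors differ in length")
    if compound_ids is None:
        compound_ids = [str(j + 1) for j in range(vip.size)]
    if len(compound_ids) != vip.size:
        raise AlignmentError("compound_ids length does not match vectors")
    c = np.abs(coef) if config.coef_mode == "absolute" else coef
    mask = (vip > config.vip_threshold) & (c > config.coef_threshold)
    return {compound_ids[j] for j in np.flatnonzero(mask)}


def union_candidates(
    per_assay_sets: dict[str, set[str]],
    group: str,
    config: ScreeningConfig | None = None,
) -> tuple[set[str], dict[str, list[str]]]:
    """Union over the group's assays, with per-compound assay provenance."""
    config = config or ScreeningConfig()
    if group not in config.union_assays or not config.union_assays[group]:
        raise ConfigError(f"activity group {group!r} is empty or undefined")
    union: set[str] = set()
    provenance: dict[str, list[str]] = {}
    for assay in config.union_assays[group]:
        if assay not in per_assay_sets:
            raise LookupError_(f"no screened set for assay {assay!r}")
        for cid in per_assay_sets[assay]:
            union.add(cid)
            provenance.setdefault(cid, []).append(assay)
    return union, provenance


def annotate_with_grd(
    candidates: set[str],
    gra: GRAResult,
    config: ScreeningConfig | None = None,
    assays: list[str] | None = None,
) -> pd.DataFrame:
    """Attach each candidate's GRDs and a below-floor flag (never removes)."""
    config = config or ScreeningConfig()
    assays = assays or list(gra.grd.columns)
    missing = set(candidates) - set(gra.grd.index)
    if missing:
        raise LookupError_(
            f"compounds absent from the GRA result: {sorted_ids(missing)}")
    if not candidates:
        return pd.DataFrame(
            columns=[f"grd_{a}" for a in assays] + ["grd_below_floor"],
            index=pd.Index([], name="compound"))
    rows = []
    for cid in sorted_ids(candidates):
        grds = gra.grd.loc[cid, assays]
        rows.append({
            "compound": cid,
            **{f"grd_{a}": float(grds[a]) for a in assays},
            "grd_below_floor": bool((grds < config.grd_floor).any()),
        })
    return pd.DataFrame(rows).set_index("compound")


def screen_pipeline(
    peaks: PeakTable,
    acts: ActivityTable,
    screening: ScreeningConfig | None = None,
    gra_config: GRAConfig | None = None,
    max_components: int = 5,
    folds: int = 7,
    n_permutations: int = 0,
    seed: int = 0,
) -> ScreeningResult:
    """GRA + per-assay PLS (CV component choice, optional permutation test),
    threshold selection, per-group union and GRD annotation, in one pass.

    ``n_permutations = 0`` skips the permutation test (it dominates runtime);
    any value >= 20 runs it per assay.
    """
    screening = screening or ScreeningConfig()
    if peaks.n_compounds < 2 or peaks.n_samples < 3:
        raise ConfigError("need at least 3 samples and 2 compounds to screen")
    peaks, acts = align_tables(peaks, acts)
    gra = grey_relational_degree(peaks, acts, gra_config)

    X = peaks.values
    ids = peaks.compound_ids
    per_assay: dict[str, list[str]] = {}
    per_assay_sets: dict[str, set[str]] = {}
    models: dict[str, ModelSummary] = {}
    evidence = pd.DataFrame(index=pd.Index(ids, name="compound"))
    rng = np.random.default_rng(seed)
    for assay in acts.assay_ids:
        y = acts.data[assay].to_numpy()
        sub_seed = int(rng.integers(2 ** 31 - 1))
        max_A = min(max_components, peaks.n_samples - 1, peaks.n_compounds)
        q2 = cross_validate_q2(X, y, max_A, folds=folds, seed=sub_seed)
        A = select_components(q2)
        model = fit_pls(X, y, A, feature_names=ids)
        model.q2_cum = float(q2[A - 1])
        perm = None
        if n_permutations >= 20:
            perm = permutation_test(X, y, A, n_permutations,
                                    seed=sub_seed, folds=folds)
        selected = select_by_assay(model.vip, model.coefficients,
                                   screening, compound_ids=ids)
        per_assay_sets[assay] = selected
        per_assay[assay] = sorted_ids(selected)
        models[assay] = ModelSummary(
            assay=assay, n_components=model.n_components,
            r2y_cum=model.r2y_cum, q2_cum=model.q2_cum,
            q2_by_component=[float(v) for v in q2], permutation=perm)
        evidence[f"vip_{assay}"] = model.vip
        evidence[f"coef_{assay}"] = model.coefficients
        evidence[f"selected_{assay}"] = [cid in selected for cid in ids]
        evidence[f"grd_{assay}"] = gra.grd[assay]

    per_group: dict[str, list[str]] = {}
    provenance: dict[str, dict[str, list[str]]] = {}
    for group, members in screening.union_assays.items():
        if not all(a in per_assay_sets for a in members):
            continue  # group references assays absent from this activity table
        union, prov = union_candidates(per_assay_sets, group, screening)
        per_group[group] = sorted_ids(union)
        provenance[group] = prov
        flags = annotate_with_grd(union, gra, screening)
        evidence[f"in_{group}_union"] = [cid in union for cid in ids]
        evidence[f"{group}_grd_below_floor"] = [
            bool(flags.loc[cid, "grd_below_floor"]) if cid in union else False
            for cid in ids]
    return ScreeningResult(per_assay, per_group, provenance,
                           evidence, models, gra, screening)
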