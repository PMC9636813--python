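"""Deng-style grey relational analysis between compounds and bioactivities.

For each assay the activity series across samples is the reference series
x₀ and every compound's abundance series is a comparison series xᵢ. After
normalizing all series onto a common scale, the absolute deviations
Δᵢ(k) = |x₀'(k) − xᵢ'(k)| are mapped to grey relational coefficients

    ξᵢ(k) = (Δmin + ρ·Δmax) / (Δᵢ(k) + ρ·Δmax)

with Δmin/Δmax the extreme deviations over all compounds and samples of that
assay (the global convention), and ρ the distinguishing coefficient. The
grey relational degree GRDᵢ is the arithmetic mean of ξᵢ(k) over samples;
GRD ∈ (0,1], with 1 exactly when the normalized series coincide.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import AlignmentError, ConfigError, FitError, LookupError_
from .io_tables import ActivityTable, PeakTable

NORMALIZATIONS = ("mean", "initial_value", "min_max", "none")


@dataclass
class GRAConfig:
    rho: float = 0.5
    normalization: str = "mean"

    def __post_init__(self) -> None:
        if not self.rho > 0:
            raise ConfigError("distinguishing coefficient rho must be > 0")
        if self.normalization not in NORMALIZATIONS:
            raise ConfigError(
                f"normalization must be one of {NORMALIZATIONS}")


@dataclass
class GRAResult:
    """Per compound × assay grey relational degrees (plus ξ tensor on request)."""

    grd: pd.DataFrame                      # compounds × assays
    config: GRAConfig
    per_sample_coefficients: dict[str, pd.DataFrame] | None = None

    def rank_by_grd(self, assay: str) -> list[str]:
        """Compounds by descending GRD; ties broken by compound id ascending."""
        if assay not in self.grd.columns:
            raise LookupError_(f"unknown assay {assay!r}")
        col = self.grd[assay]

        def id_key(cid: str):
            return (0, int(cid)) if cid.isdigit() else (1, cid)

        return sorted(col.index, key=lambda c: (-col[c], id_key(c)))


def normalize_series(series: np.ndarray, method: str = "mean") -> np.ndarray:
    """Bring one series onto the dimensionless GRA scale."""
    x = np.asarray(series, dtype=float)
    if not np.all(np.isfinite(x)):
        raise FitError("series contains non-finite values")
    if method == "mean":
        m = x.mean()
        if m == 0:
            raise FitError("cannot mean-normalize a zero-mean series")
        return x / m
    if method == "initial_value":
        if x[0] == 0:
            raise FitError("cannot initial-value-normalize: first value is 0")
        return x / x[0]
    if method == "min_max":
        rng = x.max() - x.min()
        if rng == 0:
            return np.zeros_like(x)
        return (x - x.min()) / rng
    if method == "none":
        return x.copy()
    raise ConfigError(f"unknown normalization {method!r}")


def grey_relational_degree(
    peaks: PeakTable,
    acts: ActivityTable,
    config: GRAConfig | None = None,
    keep_coefficients: bool = False,
) -> GRAResult:
    """Compute GRD for every compound against every assay."""
    config = config or GRAConfig()
    if peaks.sample_ids != acts.sample_ids:
        raise AlignmentError(
            "peak and activity tables are not aligned; call align_tables first")
    if peaks.n_samples < 2:
        raise AlignmentError("grey relational analysis needs at least 2 samples")

    comp_norm = np.column_stack([
        normalize_series(peaks.values[:, j], config.normalization)
        for j in range(peaks.n_compounds)
    ])
    grd = {}
    coeffs: dict[str, pd.DataFrame] = {}
    for assay in acts.assay_ids:
        ref = normalize_series(acts.data[assay].to_numpy(), config.normalization)
        delta = np.abs(comp_norm - ref[:, None])       # samples × compounds
        d_min, d_max = delta.min(), delta.max()
        if d_max == 0:
            xi = np.ones_like(delta)
        else:
            xi = (d_min + config.rho * d_max) / (delta + config.rho * d_max)
        grd[assay] = xi.mean(axis=0)
        if keep_coefficients:
            coeffs[assay] = pd.DataFrame(
                xi, index=peaks.sample_ids, columns=peaks.compound_ids)
    grd_df = pd.DataFrame(grd, index=peaks.compound_ids)
    return GRAResult(grd_df, config, coeffs if keep_coefficients else None)


def rank_by_grd(result: GRAResult, assay: str) -> list[str]:
    return result.rank_by_grd(assay)
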