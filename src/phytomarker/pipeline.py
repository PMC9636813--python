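"""End-to-end pipeline: screening plus ADME admission, with artifacts.

``run_full`` executes the whole chain — align tables, GRA, per-assay PLS
with cross-validated component choice (and optional permutation tests),
threshold screening, group unions, drug-likeness admission — and writes the
evidence tables, JSON summary, figures and a plain-text log. Every artifact
embeds the package version, a hash of the configuration, and the seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import pandas as pd

from . import __version__
from .druglikeness import (AdmissionConfig, DescriptorRecord, GAEllipse,
                           admit_marker)
from .errors import ConfigError
from .gra import GRAConfig
from .io_tables import align_tables, read_activity_table, read_peak_table
from .report import (correlation_heatmap_data, pca_scores,
                     plot_correlation_heatmap, plot_pca)
from .screening import ScreeningConfig, screen_pipeline, sorted_ids

logger = logging.getLogger(__name__)

_DESCRIPTOR_FIELDS = (
    "mw", "logp_mlogp", "logp_wlogp", "logp_xlogp", "tpsa", "hbd", "hba",
    "rotatable_bonds", "molar_refractivity", "heavy_atoms", "rings",
    "carbons", "heteroatoms",
)


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _stamp(config: dict, seed: int) -> dict:
    return {"package_version": __version__,
            "config_hash": config_hash(config), "seed": seed}


def load_descriptor_table(path: str | Path) -> dict[str, DescriptorRecord]:
    """Read a per-compound descriptor CSV (index column = compound id).

    Columns matching descriptor field names are used directly; rows that
    only carry a ``smiles`` column are filled via the RDKit adapter when
    it is installed.
    """
    df = pd.read_csv(path, index_col=0)
    df.index = [str(i) for i in df.index]
    records: dict[str, DescriptorRecord] = {}
    for cid, row in df.iterrows():
        kwargs = {}
        for f in _DESCRIPTOR_FIELDS:
            if f in row.index and pd.notna(row[f]):
                kwargs[f] = float(row[f])
        if not kwargs and "smiles" in row.index and pd.notna(row["smiles"]):
            from .descriptors import descriptors_from_smiles
            records[cid], _ = descriptors_from_smiles(str(row["smiles"]), cid)
        else:
            records[cid] = DescriptorRecord(compound_id=cid, **kwargs)
    return records


def _build_configs(config: dict):
    gra = GRAConfig(**config.get("gra", {}))
    screening = ScreeningConfig(**config.get("screening", {}))
    adm = dict(config.get("admission", {}))
    if "ellipse" in adm:
        adm["ellipse"] = GAEllipse(**adm["ellipse"])
    admission = AdmissionConfig(**adm)
    pls = dict(config.get("pls", {}))
    return gra, screening, admission, pls


def run_full(config: dict, out_dir: str | Path) -> dict:
    """Run the complete pipeline from a configuration mapping.

    Required keys: ``peaks`` and ``activities`` (CSV paths). Optional:
    ``descriptors`` (CSV path), ``seed``, and ``gra`` / ``pls`` /
    ``screening`` / ``admission`` sub-mappings. Returns the summary dict
    that is also written to ``summary.json``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "pipeline.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    root = logging.getLogger("phytomarker")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    seed = int(config.get("seed", 0))
    stamp = _stamp(config, seed)
    try:
        return _run_full_inner(config, out, seed, stamp)
    finally:
        root.removeHandler(handler)
        handler.close()


def _run_full_inner(config: dict, out: Path, seed: int, stamp: dict) -> dict:
    for key in ("peaks", "activities"):
        if key not in config:
            raise ConfigError(f"config lacks required path {key!r}")
        if not Path(config[key]).exists():
            raise ConfigError(f"{key} file not found: {config[key]}")
    gra_cfg, screening_cfg, admission_cfg, pls_cfg = _build_configs(config)

    t0 = time.perf_counter()
    peaks = read_peak_table(config["peaks"])
    acts = read_activity_table(config["activities"])
    peaks, acts = align_tables(peaks, acts)
    logger.info("stage=load shapes=%s/%s elapsed=%.3fs",
                peaks.data.shape, acts.data.shape, time.perf_counter() - t0)

    t0 = time.perf_counter()
    result = screen_pipeline(
        peaks, acts, screening_cfg, gra_cfg,
        max_components=int(pls_cfg.get("max_components", 5)),
        folds=int(pls_cfg.get("folds", 7)),
        n_permutations=int(pls_cfg.get("n_permutations", 0)),
        seed=seed,
    )
    logger.info("stage=screen assays=%d elapsed=%.3fs",
                len(result.per_assay), time.perf_counter() - t0)

    # ---- ADME admission on the screened candidates -----------------------
    t0 = time.perf_counter()
    candidates = sorted_ids(set().union(*result.per_group.values())
                            if result.per_group else set())
    descriptor_records = {}
    if config.get("descriptors"):
        descriptor_records = load_descriptor_table(config["descriptors"])
    mean_area = peaks.data.mean(axis=0)
    admission_rows = []
    admitted: list[str] = []
    for cid in candidates:
        if cid not in descriptor_records:
            admission_rows.append({"compound": cid, "status": "no_descriptors"})
            continue
        others = mean_area.drop(cid)
        report = admit_marker(descriptor_records[cid], float(mean_area[cid]),
                              float(others.median()), admission_cfg)
        if report.admissible:
            admitted.append(cid)
        admission_rows.append({
            "compound": cid, "status": "evaluated",
            "rules_passed": report.rules_passed,
            "rules_evaluable": report.rules_evaluable,
            "ga_class": report.ga_class,
            "content_ratio": report.content_ratio,
            "admissible": report.admissible,
            "override_applied": report.override_applied,
        })
    logger.info("stage=adme candidates=%d admitted=%d elapsed=%.3fs",
                len(candidates), len(admitted), time.perf_counter() - t0)

    # ---- descriptive report ----------------------------------------------
    t0 = time.perf_counter()
    scores, explained = pca_scores(peaks)
    corr = correlation_heatmap_data(peaks, acts)
    plot_pca(scores, config.get("group_labels"), out / "pca_scores.png")
    plot_correlation_heatmap(corr, out / "correlation_heatmap.png")
    logger.info("stage=report elapsed=%.3fs", time.perf_counter() - t0)

    # ---- artifacts --------------------------------------------------------
    header = "\n".join(f"# {k}: {v}" for k, v in sorted(stamp.items()))
    for name, df in (("evidence", result.evidence),
                     ("grd", result.gra.grd),
                     ("correlations", corr),
                     ("pca_scores", scores)):
        path = out / f"{name}.csv"
        with open(path, "w") as fh:
            fh.write(header + "\n")
            df.to_csv(fh)
    admission_df = pd.DataFrame(admission_rows)
    with open(out / "admission.csv", "w") as fh:
        fh.write(header + "\n")
        admission_df.to_csv(fh, index=False)

    summary = {
        **stamp,
        "per_assay_candidates": result.per_assay,
        "per_group_candidates": result.per_group,
        "models": {a: {"n_components": m.n_components,
                       "r2y_cum": round(m.r2y_cum, 10),
                       "q2_cum": round(m.q2_cum, 10),
                       **({"permutation_p_q2": m.permutation.empirical_p_q2,
                           "q2_intercept": round(m.permutation.q2_intercept, 10),
                           "r2_intercept": round(m.permutation.r2_intercept, 10)}
                          if m.permutation else {})}
                   for a, m in sorted(result.models.items())},
        "admitted_markers": admitted,
        "pca_explained_variance": [round(float(v), 10) for v in explained[:2]],
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary
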