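"""Descriptive reporting: PCA score plots and chemical-activity correlations.

These are presentation-layer summaries of the fingerprint (species
separation, compound-activity association); screening decisions never
depend on them.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .errors import AlignmentError, ConfigError
from .io_tables import ActivityTable, PeakTable


def pca_scores(peaks: PeakTable, n_components: int = 2
               ) -> tuple[pd.DataFrame, np.ndarray]:
    """Autoscaled principal-component scores of the sample fingerprints.

    Returns (scores DataFrame samples × PCs, explained-variance fractions).
    Sign convention: within each loading vector the largest-|value| element
    is made positive, so scores are reproducible across BLAS builds.
    Zero-variance compounds are dropped with a warning.
    """
    if peaks.n_samples < 2 or peaks.n_compounds < 2:
        raise ConfigError("PCA needs at least 2 samples and 2 compounds")
    X = peaks.values
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.all():
        dropped = [c for c, k in zip(peaks.compound_ids, keep) if not k]
        warnings.warn(f"dropping zero-variance compounds: {dropped}")
        X = X[:, keep]
        sd = sd[keep]
    Z = (X - X.mean(axis=0)) / sd
    U, S, Vt = np.linalg.svd(Z, full_matrices=False)
    n_components = min(n_components, S.size)
    scores = U[:, :n_components] * S[:n_components]
    for k in range(n_components):
        j = np.argmax(np.abs(Vt[k]))
        if Vt[k, j] < 0:
            scores[:, k] *= -1.0
    var = S ** 2 / np.sum(S ** 2)
    df = pd.DataFrame(scores, index=peaks.sample_ids,
                      columns=[f"PC{k + 1}" for k in range(n_components)])
    return df, var[:n_components]


def correlation_heatmap_data(peaks: PeakTable,
                             acts: ActivityTable) -> pd.DataFrame:
    """Pearson correlation of each compound with each assay (compound × assay).

    Constant series yield NaN (undefined), never a silent 0.
    """
    if peaks.sample_ids != acts.sample_ids:
        raise AlignmentError("tables are not aligned; call align_tables first")
    out = pd.DataFrame(index=peaks.compound_ids, columns=acts.assay_ids,
                       dtype=float)
    X = peaks.values
    Y = acts.values
    for j, cid in enumerate(peaks.compound_ids):
        for k, aid in enumerate(acts.assay_ids):
            x, y = X[:, j], Y[:, k]
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                out.loc[cid, aid] = np.nan
            else:
                out.loc[cid, aid] = float(np.corrcoef(x, y)[0, 1])
    return out


def plot_pca(scores: pd.DataFrame, groups: list[str] | None, path) -> None:
    """Render a PC1/PC2 score plot (side artifact; nothing asserts on it)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    if groups is None:
        ax.scatter(scores.iloc[:, 0], scores.iloc[:, 1], s=25)
    else:
        for g in dict.fromkeys(groups):
            mask = [x == g for x in groups]
            ax.scatter(scores.iloc[mask, 0], scores.iloc[mask, 1],
                       s=25, label=g)
        ax.legend()
    ax.set_xlabel(scores.columns[0])
    ax.set_ylabel(scores.columns[1] if scores.shape[1] > 1 else "")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_correlation_heatmap(corr: pd.DataFrame, path) -> None:
    """Render the compound × assay correlation matrix as a heatmap."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 0.3 * len(corr) + 1.5))
    im = ax.imshow(corr.to_numpy(dtype=float), vmin=-1, vmax=1, cmap="RdBu_r",
                   aspect="auto")
    ax.set_xticks(range(corr.shape[1]), corr.columns, rotation=45, ha="right")
    ax.set_yticks(range(corr.shape[0]), corr.index, fontsize=6)
    fig.colorbar(im, ax=ax, label="Pearson r")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
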