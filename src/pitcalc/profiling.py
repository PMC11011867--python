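"""Tumor-level responsiveness fingerprints, PCA, clustering, and the
recurrence decision rule.

Each tumor is summarized by the percentages of viable cells that are
spontaneously active, non-, mono- and multi-responsive, the per-secretagogue
response percentages, and the maximal tumor diameter. Tumors are projected
by PCA and grouped by hierarchical clustering on correlation distance. The
recurrence rule is a conjunction of three clauses on the fingerprint:
spontaneous activity present, more than 20% multi-responsive cells, and
fewer than 50% non-responsive cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage
from scipy.spatial.distance import squareform

from .protocol import SECRETAGOGUES

__all__ = [
    "TumorProfile",
    "PcaResult",
    "RecurrenceThresholds",
    "build_feature_table",
    "run_pca",
    "cluster_tumors",
    "predict_recurrence",
    "summarize_cohort",
    "load_cohort_table",
]


@dataclass
class TumorProfile:
    """Responsiveness fingerprint of one tumor (percentages of viable cells)."""

    tumor_id: str
    pct_spontaneous: float
    pct_non: float
    pct_mono: float
    pct_multi: float
    per_stimulus_pct: dict[str, float] = field(default_factory=dict)
    max_diameter_cm: float = float("nan")
    n_viable: int | None = None
    recurrent_observed: bool | None = None
    recurrent_predicted: bool | None = None

    def __post_init__(self) -> None:
        total = self.pct_non + self.pct_mono + self.pct_multi
        if abs(total - 100.0) > 1e-6:
            raise ValueError(f"category percentages sum to {total}, expected 100")
        for name in ("pct_spontaneous", "pct_non", "pct_mono", "pct_multi"):
            v = getattr(self, name)
            if not -1e-9 <= v <= 100.0 + 1e-9:
                raise ValueError(f"{name}={v} outside [0, 100]")
        for s, v in self.per_stimulus_pct.items():
            if not -1e-9 <= v <= 100.0 + 1e-9:
                raise ValueError(f"per_stimulus_pct[{s}]={v} outside [0, 100]")

    def features(self) -> dict[str, float]:
        out = {
            "pct_spontaneous": self.pct_spontaneous,
            "pct_non": self.pct_non,
            "pct_mono": self.pct_mono,
            "pct_multi": self.pct_multi,
        }
        for s in SECRETAGOGUES:
            out[f"pct_{s}"] = self.per_stimulus_pct.get(s, float("nan"))
        out["max_diameter_cm"] = self.max_diameter_cm
        return out


@dataclass(frozen=True)
class PcaResult:
    scores: pd.DataFrame  # tumors x components
    loadings: pd.DataFrame  # features x components
    explained_pct: np.ndarray

    def __post_init__(self) -> None:
        e = self.explained_pct
        if np.any(np.diff(e) > 1e-9):
            raise ValueError("explained variance must be non-increasing")
        if e.sum() > 100.0 + 1e-6:
            raise ValueError("explained variance exceeds 100%")


@dataclass(frozen=True)
class RecurrenceThresholds:
    """Cut-offs of the recurrence rule (each clause configurable)."""

    min_spontaneous_pct: float = 0.0  # strict: spontaneous activity present
    min_multi_pct: float = 20.0  # strict: more than 20% multi-responsive
    max_non_pct: float = 50.0  # strict: fewer than 50% non-responsive


def build_feature_table(
    profiles: list[TumorProfile], drop_na_diameter: bool = False
) -> tuple[pd.DataFrame, list[str]]:
    """Assemble and standardize the tumors × features matrix.

    Columns are z-scored (mean 0, unit variance, ddof=1); constant columns
    carry no information for PCA/clustering and are dropped, their names
    returned alongside. Missing entries raise, naming tumor and feature.
    """
    if len(profiles) < 2:
        raise ValueError("need at least 2 tumors")
    raw = pd.DataFrame({p.tumor_id: p.features() for p in profiles}).T
    if drop_na_diameter and raw["max_diameter_cm"].isna().all():
        raw = raw.drop(columns=["max_diameter_cm"])
    for tumor, row in raw.iterrows():
        bad = row.index[row.isna()]
        if len(bad):
            raise ValueError(f"tumor {tumor}: missing feature(s) {list(bad)}")
    std = raw.std(axis=0, ddof=1)
    dropped = list(std.index[std <= 1e-12])
    kept = raw.drop(columns=dropped)
    scaled = (kept - kept.mean(axis=0)) / kept.std(axis=0, ddof=1)
    return scaled, dropped


def run_pca(features: pd.DataFrame) -> PcaResult:
    """PCA by eigendecomposition of the feature covariance matrix.

    Component signs are fixed so each loading vector's largest-magnitude
    entry is positive, making results reproducible across linear-algebra
    backends. Explained percentages come from the eigenvalues.
    """
    X = features.to_numpy(dtype=float)
    if X.shape[0] < 2 or X.shape[1] < 1:
        raise ValueError("need >= 2 rows and >= 1 column")
    Xc = X - X.mean(axis=0)
    cov = Xc.T @ Xc / (X.shape[0] - 1)
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]
    total = eigval.sum()
    if total <= 0:
        raise ValueError("degenerate feature matrix: zero total variance")
    for j in range(eigvec.shape[1]):
        i = int(np.argmax(np.abs(eigvec[:, j])))
        if eigvec[i, j] < 0:
            eigvec[:, j] *= -1.0
    comp_names = [f"PC{j + 1}" for j in range(eigvec.shape[1])]
    return PcaResult(
        scores=pd.DataFrame(Xc @ eigvec, index=features.index, columns=comp_names),
        loadings=pd.DataFrame(eigvec, index=features.columns, columns=comp_names),
        explained_pct=100.0 * eigval / total,
    )


def cluster_tumors(
    features: pd.DataFrame, linkage_method: str = "complete", k: int = 2
) -> tuple[list[str], dict[str, int]]:
    """Agglomerative clustering of tumors on correlation distance.

    Distance is 1 − Pearson r between tumor feature rows; default complete
    linkage. Ties merge lowest-index pair first (scipy's convention).
    Returns the dendrogram leaf order and the k-cluster labels.
    """
    n = features.shape[0]
    if n < 2:
        raise ValueError("need at least 2 tumors")
    if k > n:
        raise ValueError(f"cannot form {k} clusters from {n} tumors")
    X = features.to_numpy(dtype=float)
    Xc = X - X.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(Xc, axis=1)
    if (norms <= 1e-12).any():
        raise ValueError("constant tumor row: correlation distance undefined")
    corr = (Xc / norms[:, None]) @ (Xc / norms[:, None]).T
    dist = np.clip(1.0 - corr, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    Z = linkage(squareform(dist, checks=False), method=linkage_method)
    order = [features.index[i] for i in leaves_list(Z)]
    labels = fcluster(Z, t=k, criterion="maxclust")
    return order, {features.index[i]: int(labels[i]) for i in range(n)}


def predict_recurrence(
    profile: TumorProfile, thresholds: RecurrenceThresholds = RecurrenceThresholds()
) -> tuple[bool, dict[str, bool]]:
    """Apply the recurrence rule and report which clauses fired.

    Predicted recurrent iff spontaneous activity is present
    (pct_spontaneous > ``min_spontaneous_pct``), more than
    ``min_multi_pct`` % of cells are multi-responsive, and fewer than
    ``max_non_pct`` % are non-responsive.
    """
    clauses = {
        "spontaneous_present": profile.pct_spontaneous > thresholds.min_spontaneous_pct,
        "multi_above_20": profile.pct_multi > thresholds.min_multi_pct,
        "non_below_50": profile.pct_non < thresholds.max_non_pct,
    }
    return all(clauses.values()), clauses


# ---------------------------------------------------------------------------
# Cohort table (patient/tumor characteristics fixture)
# ---------------------------------------------------------------------------

DEFICIENCY_AXES = ("TSH", "ACTH", "GH", "PRL", "LH", "FSH")
TREATMENT_TOKENS = ("TSS", "TC", "XRT", "CBG", "TMZ")


def load_cohort_table() -> pd.DataFrame:
    """The packaged 13-patient cohort characteristics table."""
    with resources.files("pitcalc.data").joinpath("cohort_table.tsv").open() as fh:
        # keep_default_na=False: "None" is a real category (no deficiency)
        return pd.read_csv(fh, sep="\t", dtype={"tumor_id": str}, keep_default_na=False)


def _tokens(entry: str) -> list[str]:
    return [t.strip() for t in str(entry).split(",") if t.strip()]


def summarize_cohort(table: pd.DataFrame | None = None) -> dict:
    """Counts and percentages over the cohort table.

    Deficiency entries are exact string categories; ``All`` counts toward
    every hormone axis and ``None`` toward none. Percentages are
    count/n_patients rounded to one decimal. Unknown tokens raise.
    """
    if table is None:
        table = load_cohort_table()
    n = len(table)
    if n == 0:
        raise ValueError("empty cohort table: percentages undefined")

    def pct(c: int) -> float:
        return round(100.0 * c / n, 1)

    deficiency_counts = dict.fromkeys(DEFICIENCY_AXES, 0)
    n_any_deficiency = 0
    for entry in table["deficiency"]:
        toks = _tokens(entry)
        if toks == ["None"]:
            continue
        n_any_deficiency += 1
        if toks == ["All"]:
            for ax in DEFICIENCY_AXES:
                deficiency_counts[ax] += 1
            continue
        for t in toks:
            if t not in DEFICIENCY_AXES:
                raise ValueError(f"unknown deficiency token {t!r}")
            deficiency_counts[t] += 1

    treatment_counts = dict.fromkeys(TREATMENT_TOKENS, 0)
    for entry in table["treatments"]:
        for t in _tokens(entry):
            if t not in TREATMENT_TOKENS:
                raise ValueError(f"unknown treatment token {t!r}")
            treatment_counts[t] += 1

    marker_counts = table["lineage_marker"].value_counts().to_dict()
    recurrent = table["recurrent"].astype(str).str.lower().isin(["yes", "true", "1"])
    n_rec = int(recurrent.sum())
    return {
        "n_patients": n,
        "n_recurrent": n_rec,
        "pct_recurrent": pct(n_rec),
        "n_any_deficiency": n_any_deficiency,
        "deficiency_counts": deficiency_counts,
        "deficiency_pct": {k: pct(v) for k, v in deficiency_counts.items()},
        "lineage_marker_counts": {k: int(v) for k, v in marker_counts.items()},
        "lineage_marker_pct": {k: pct(int(v)) for k, v in marker_counts.items()},
        "treatment_counts": treatment_counts,
        "treatment_pct": {k: pct(v) for k, v in treatment_counts.items()},
        "mean_age": round(float(table["age"].mean()), 1),
        "sd_age": round(float(table["age"].std(ddof=1)), 1),
        "mean_diameter_cm": round(float(table["max_diameter_cm"].mean()), 2),
        "sd_diameter_cm": round(float(table["max_diameter_cm"].std(ddof=1)), 2),
    }


def profiles_to_table(profiles: list[TumorProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        row = {
            "tumor_id": p.tumor_id,
            "n_viable": p.n_viable,
            "pct_spontaneous": p.pct_spontaneous,
            "pct_non": p.pct_non,
            "pct_mono": p.pct_mono,
            "pct_multi": p.pct_multi,
            "max_diameter_cm": p.max_diameter_cm,
            "recurrent_observed": p.recurrent_observed,
            "recurrent_predicted": p.recurrent_predicted,
        }
        for s in SECRETAGOGUES:
            row[f"pct_{s}"] = p.per_stimulus_pct.get(s, float("nan"))
        rows.append(row)
    return pd.DataFrame(rows).set_index("tumor_id")
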