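"""Compound cardiac-activity prediction from normalised waveform parameters.

The modelling pipeline mirrors standard early-safety practice: point-biserial
correlation screens parameters against the binary activity label per
concentration, redundant parameters (pairwise |Pearson| above a threshold)
are pruned, the top-k survivors feed a 100-tree Gini random forest, and the
model is evaluated with leave-one-compound-out cross-validation (LOCO-CV) --
all replicates of a compound are held out together so compound identity never
leaks.  Metrics are reported sample-wise and compound-wise (per-compound
probabilities are the mean over that compound's samples).

A Morgan-fingerprint (ECFP4, 2,048 bits) baseline quantifies how much of the
signal is attributable to the waveform read-out rather than the structures.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import binom
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import (
    accuracy_score,
    f1_score,
    precision_score,
    recall_score,
    roc_auc_score,
    roc_curve,
)

__all__ = [
    "point_biserial",
    "correlation_tables",
    "select_features",
    "pca_projection",
    "loco_cv",
    "ecfp_features",
    "compute_metrics",
    "replicate_distance_analysis",
    "multi_peak_enrichment",
    "ModelReport",
    "CardiacActivityModel",
    "CardiacActivityResults",
]

DEFAULT_SEED = 20220210


def point_biserial(feature_values: np.ndarray, binary_labels: np.ndarray) -> float:
    """Point-biserial correlation: Pearson correlation with 0/1 dummy coding."""
    x = np.asarray(feature_values, dtype=float)
    y = np.asarray(binary_labels, dtype=float)
    if x.size != y.size or x.size < 2:
        raise ValueError("need two aligned vectors of length >= 2")
    if np.unique(y).size < 2:
        raise ValueError("point_biserial undefined for single-class labels")
    if np.ptp(x) == 0:
        raise ValueError("point_biserial undefined for zero-variance feature")
    return float(np.corrcoef(x, y)[0, 1])


def correlation_tables(
    features: pd.DataFrame,
    labels: np.ndarray,
    concentrations: Optional[np.ndarray] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-concentration point-biserial table and feature intercorrelation.

    Returns ``(corrs, inter)`` where ``corrs`` is indexed by parameter with
    one column per concentration stratum (a single ``all`` column without
    concentrations) and ``inter`` is the parameter x parameter Pearson matrix.
    Zero-variance or single-class strata yield NaN entries.
    """
    labels = np.asarray(labels, dtype=float)
    if concentrations is None:
        strata = {"all": np.ones(len(features), dtype=bool)}
    else:
        concentrations = np.asarray(concentrations, dtype=float)
        strata = {c: concentrations == c for c in np.unique(concentrations)}
    corrs = pd.DataFrame(index=features.columns, columns=list(strata), dtype=float)
    for key, mask in strata.items():
        sub_y = labels[mask]
        for name in features.columns:
            sub_x = features.loc[mask, name].to_numpy(dtype=float)
            try:
                corrs.loc[name, key] = point_biserial(sub_x, sub_y)
            except ValueError:
                corrs.loc[name, key] = np.nan
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        inter = features.corr(method="pearson")
    return corrs, inter


def select_features(
    per_concentration_corrs: pd.DataFrame,
    intercorrelation: pd.DataFrame,
    k: int = 25,
    redundancy_threshold: float = 0.95,
) -> list[str]:
    """Redundancy pruning followed by mean-|r_pb| ranking.

    Of each parameter pair with |Pearson| above the threshold, the member
    with the lower mean absolute point-biserial correlation is dropped;
    survivors are ranked by mean |r_pb| across concentrations and the top k
    returned (all survivors, with a warning, when fewer than k remain).
    """
    mean_abs = per_concentration_corrs.abs().mean(axis=1, skipna=True).fillna(0.0)
    names = list(per_concentration_corrs.index)
    dropped: set[str] = set()
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            if a in dropped or b in dropped:
                continue
            r = intercorrelation.loc[a, b]
            if np.isfinite(r) and abs(r) > redundancy_threshold:
                dropped.add(a if mean_abs[a] < mean_abs[b] else b)
    survivors = [n for n in names if n not in dropped]
    survivors.sort(key=lambda n: (-mean_abs[n], n))
    if k > len(survivors):
        warnings.warn(
            f"requested {k} features but only {len(survivors)} survive pruning",
            stacklevel=2,
        )
        return survivors
    return survivors[:k]


def pca_projection(features: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """2-D principal-component projection of column-centred data.

    Returns (coordinates, explained-variance fractions).  Rank-deficient
    input yields a zero-variance second component.
    """
    X = np.asarray(features, dtype=float)
    if X.shape[0] < 3 or X.shape[1] < 2:
        raise ValueError("PCA projection needs >= 3 samples and >= 2 features")
    pca = PCA(n_components=2)
    coords = pca.fit_transform(X)
    return coords, pca.explained_variance_ratio_


def ecfp_features(smiles: str, n_bits: int = 2048, radius: int = 2) -> np.ndarray:
    """Morgan circular fingerprint (radius 2 = ECFP4) folded to 2,048 bits."""
    from rdkit import Chem
    from rdkit.Chem import rdFingerprintGenerator

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    fp = gen.GetFingerprint(mol)
    return np.array(fp, dtype=np.uint8)


def compute_metrics(
    probabilities: np.ndarray,
    labels: np.ndarray,
    compounds: Optional[Sequence[str]] = None,
    mode: str = "sample_wise",
) -> tuple[dict[str, float], pd.DataFrame]:
    """Accuracy/precision/recall/F1 at threshold 0.5 plus ROC AUC.

    ``compound_wise`` first averages probabilities per compound (one item and
    one label per compound).  Returns (metric map, ROC point table).
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=int)
    if mode == "compound_wise":
        if compounds is None:
            raise ValueError("compound_wise metrics need compound ids")
        df = pd.DataFrame({"compound": compounds, "p": p, "y": y})
        agg = df.groupby("compound", sort=True).agg(p=("p", "mean"), y=("y", "first"))
        if (df.groupby("compound")["y"].nunique() > 1).any():
            raise ValueError("samples of one compound carry conflicting labels")
        p, y = agg["p"].to_numpy(), agg["y"].to_numpy()
    elif mode != "sample_wise":
        raise ValueError(f"unknown metrics mode {mode!r}")
    if np.unique(y).size < 2:
        raise ValueError("AUC undefined for single-class labels")
    pred = (p >= 0.5).astype(int)
    metrics = {
        "accuracy": float(accuracy_score(y, pred)),
        "precision": float(precision_score(y, pred, zero_division=0)),
        "recall": float(recall_score(y, pred, zero_division=0)),
        "f1": float(f1_score(y, pred, zero_division=0)),
        "auc": float(roc_auc_score(y, p)),
    }
    fpr, tpr, thr = roc_curve(y, p)
    roc = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})
    return metrics, roc


@dataclass
class ModelReport:
    """LOCO-CV predictions and metrics."""

    sample_predictions: pd.DataFrame  # compound, label, probability (one row/sample)
    compound_predictions: pd.DataFrame  # compound, label, probability (averaged)
    metrics_sample_wise: dict[str, float]
    metrics_compound_wise: dict[str, float]
    roc_compound_wise: pd.DataFrame
    selected_features: dict[str, list[str]] = field(default_factory=dict)

    @property
    def auc_compound_wise(self) -> float:
        return self.metrics_compound_wise["auc"]


def loco_cv(
    features: pd.DataFrame,
    compounds: Sequence[str],
    labels: Sequence[int],
    concentrations: Optional[Sequence[float]] = None,
    n_features: int = 25,
    redundancy_threshold: float = 0.95,
    per_fold_selection: bool = True,
    select: bool = True,
    seed: int = DEFAULT_SEED,
    n_trees: int = 100,
) -> ModelReport:
    """Leave-one-compound-out cross-validated random forest.

    For every compound the forest trains on all other compounds' samples and
    predicts the held-out compound's samples.  With ``per_fold_selection``
    (default) the correlation-based feature selection is re-run inside each
    training fold, so the held-out compound influences neither training nor
    selection; ``per_fold_selection=False`` reproduces a single global
    selection.  ``select=False`` skips selection (used for the fingerprint
    baseline and the two-parameter simple model).
    """
    compounds = np.asarray(compounds)
    labels = np.asarray(labels, dtype=int)
    concs = None if concentrations is None else np.asarray(concentrations, dtype=float)
    unique = sorted(set(compounds.tolist()))
    for comp in unique:
        lab = np.unique(labels[compounds == comp])
        if lab.size != 1:
            raise ValueError(f"compound {comp} has conflicting labels")
    global_selection: Optional[list[str]] = None
    if select and not per_fold_selection:
        corrs, inter = correlation_tables(features, labels, concs)
        global_selection = select_features(corrs, inter, n_features, redundancy_threshold)

    rows = []
    selected_per_fold: dict[str, list[str]] = {}
    for comp in unique:
        test_mask = compounds == comp
        train_mask = ~test_mask
        y_train = labels[train_mask]
        if np.unique(y_train).size < 2:
            raise ValueError(
                f"training fold for held-out compound {comp} is single-class"
            )
        if select:
            if per_fold_selection:
                corrs, inter = correlation_tables(
                    features[train_mask],
                    y_train,
                    None if concs is None else concs[train_mask],
                )
                cols = select_features(corrs, inter, n_features, redundancy_threshold)
            else:
                cols = list(global_selection)
            selected_per_fold[comp] = cols
            X_train = features.loc[train_mask, cols].to_numpy(dtype=float)
            X_test = features.loc[test_mask, cols].to_numpy(dtype=float)
        else:
            X_train = features[train_mask].to_numpy(dtype=float)
            X_test = features[test_mask].to_numpy(dtype=float)
        clf = RandomForestClassifier(
            n_estimators=n_trees, criterion="gini", random_state=seed
        )
        clf.fit(X_train, y_train)
        proba = clf.predict_proba(X_test)[:, list(clf.classes_).index(1)]
        for pr, lab in zip(proba, labels[test_mask]):
            rows.append({"compound": comp, "label": int(lab), "probability": float(pr)})

    samples = pd.DataFrame(rows)
    comp_pred = (
        samples.groupby("compound", sort=True)
        .agg(label=("label", "first"), probability=("probability", "mean"))
        .reset_index()
    )
    m_s, _ = compute_metrics(
        samples["probability"], samples["label"], mode="sample_wise"
    )
    m_c, roc_c = compute_metrics(
        samples["probability"], samples["label"], samples["compound"],
        mode="compound_wise",
    )
    return ModelReport(
        sample_predictions=samples,
        compound_predictions=comp_pred,
        metrics_sample_wise=m_s,
        metrics_compound_wise=m_c,
        roc_compound_wise=roc_c,
        selected_features=selected_per_fold,
    )


def replicate_distance_analysis(
    features: pd.DataFrame,
    compounds: Sequence[str],
    concentrations: Sequence[float],
    labels: Sequence[int],
) -> dict[tuple[str, str], np.ndarray]:
    """Euclidean distance distributions over the selected-feature space.

    Pairs are partitioned into replicate (same compound, same concentration)
    vs non-replicate and stratified by label; mixed-label non-replicate pairs
    are excluded so each stratum is label-pure.  Empty strata are allowed.
    """
    X = features.to_numpy(dtype=float)
    comp = np.asarray(compounds)
    conc = np.asarray(concentrations, dtype=float)
    lab = np.asarray(labels, dtype=int)
    d = squareform(pdist(X))
    out: dict[tuple[str, str], list[float]] = {
        (kind, cls): []
        for kind in ("replicate", "non_replicate")
        for cls in ("active", "inactive")
    }
    n = len(comp)
    for i in range(n):
        for j in range(i + 1, n):
            if lab[i] != lab[j]:
                continue
            cls = "active" if lab[i] == 1 else "inactive"
            kind = (
                "replicate"
                if comp[i] == comp[j] and conc[i] == conc[j]
                else "non_replicate"
            )
            out[(kind, cls)].append(d[i, j])
    return {k: np.asarray(v) for k, v in out.items()}


def multi_peak_enrichment(
    compound_multipeak_count: int, compound_n: int, background_rate: float
) -> float:
    """One-sided exact binomial tail probability of observing at least the
    given number of multi-peak samples under the vehicle background rate."""
    if compound_n <= 0:
        raise ValueError("compound sample count must be positive")
    if not 0 <= background_rate <= 1:
        raise ValueError("background rate must lie in [0, 1]")
    k = int(compound_multipeak_count)
    if k <= 0:
        return 1.0
    return float(binom.sf(k - 1, compound_n, background_rate))


# ---------------------------------------------------------------------------
# model / results objects


class CardiacActivityModel:
    """LOCO-CV random-forest model of compound cardiac activity.

    Built from a normalised feature matrix with per-sample compound ids and
    per-compound binary labels; ``fit`` runs the cross-validated pipeline and
    returns a :class:`CardiacActivityResults`.
    """

    def __init__(
        self,
        features: pd.DataFrame,
        compounds: Sequence[str],
        labels: Sequence[int],
        concentrations: Optional[Sequence[float]] = None,
        smiles: Optional[dict[str, str]] = None,
        n_features: int = 25,
        redundancy_threshold: float = 0.95,
        per_fold_selection: bool = True,
    ) -> None:
        self.features = features.reset_index(drop=True)
        self.compounds = np.asarray(compounds)
        self.labels = np.asarray(labels, dtype=int)
        self.concentrations = (
            None if concentrations is None else np.asarray(concentrations, dtype=float)
        )
        self.smiles = smiles or {}
        self.n_features = n_features
        self.redundancy_threshold = redundancy_threshold
        self.per_fold_selection = per_fold_selection

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        feature_columns: Sequence[str],
        compound_col: str = "compound_id",
        label_col: str = "cardiac_active",
        conc_col: Optional[str] = "std_concentration",
        smiles_col: Optional[str] = "smiles",
        **kwargs,
    ) -> "CardiacActivityModel":
        smiles = None
        if smiles_col and smiles_col in df.columns:
            smiles = (
                df.dropna(subset=[smiles_col])
                .groupby(compound_col)[smiles_col]
                .first()
                .to_dict()
            )
        concs = df[conc_col] if conc_col and conc_col in df.columns else None
        return cls(
            df[list(feature_columns)],
            df[compound_col],
            df[label_col],
            concentrations=concs,
            smiles=smiles,
            **kwargs,
        )

    def fit(self, seed: int = DEFAULT_SEED) -> "CardiacActivityResults":
        report = loco_cv(
            self.features,
            self.compounds,
            self.labels,
            self.concentrations,
            n_features=self.n_features,
            redundancy_threshold=self.redundancy_threshold,
            per_fold_selection=self.per_fold_selection,
            seed=seed,
        )
        return CardiacActivityResults(self, report, seed)

    def fit_fingerprint_baseline(self, seed: int = DEFAULT_SEED) -> "CardiacActivityResults":
        """ECFP4 baseline over the same LOCO folds (structure-only features)."""
        if not self.smiles:
            raise ValueError("fingerprint baseline needs per-compound SMILES")
        fps = {c: ecfp_features(s) for c, s in self.smiles.items()}
        missing = set(self.compounds) - set(fps)
        if missing:
            raise ValueError(f"no SMILES for compounds: {sorted(missing)}")
        X = pd.DataFrame(np.stack([fps[c] for c in self.compounds]))
        report = loco_cv(
            X, self.compounds, self.labels, self.concentrations,
            select=False, seed=seed,
        )
        return CardiacActivityResults(self, report, seed)


class CardiacActivityResults:
    """Results container: predictions, metrics, and a text summary."""

    def __init__(
        self, model: CardiacActivityModel, report: ModelReport, seed: int
    ) -> None:
        self.model = model
        self.report = report
        self.seed = seed

    @property
    def sample_predictions(self) -> pd.DataFrame:
        return self.report.sample_predictions

    @property
    def compound_predictions(self) -> pd.DataFrame:
        return self.report.compound_predictions

    def metrics(self, mode: str = "compound_wise") -> dict[str, float]:
        if mode == "compound_wise":
            return dict(self.report.metrics_compound_wise)
        if mode == "sample_wise":
            return dict(self.report.metrics_sample_wise)
        raise ValueError(f"unknown metrics mode {mode!r}")

    def summary(self) -> str:
        mc = self.report.metrics_compound_wise
        ms = self.report.metrics_sample_wise
        n_comp = len(self.report.compound_predictions)
        n_samp = len(self.report.sample_predictions)
        lines = [
            "Cardiac activity LOCO-CV random forest",
            "=" * 54,
            f"compounds: {n_comp}    samples: {n_samp}    seed: {self.seed}",
            "",
            f"{'metric':<12}{'compound-wise':>16}{'sample-wise':>16}",
            "-" * 44,
        ]
        for key in ("accuracy", "precision", "recall", "f1", "auc"):
            lines.append(f"{key:<12}{mc[key]:>16.3f}{ms[key]:>16.3f}")
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover
        return f"<CardiacActivityResults auc={self.report.auc_compound_wise:.3f}>"
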