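"""Fused-data chemometrics: Kruskal-Wallis feature filtering, autoscaling,
PCA, distance-to-centroid classification and Monte Carlo cross-validation.

The chain mirrors a standard food-authenticity workflow: the 300 binned
FT-NIR variables are fused with the three isotope deltas into a 303-column
table per cultivar; the Kruskal-Wallis H statistic (midranks, tie-corrected)
scores how strongly each variable separates the harvest-year classes; the
top-50 variables are autoscaled (column mean 0, sd 1 with the n-1
denominator) and decomposed by SVD-based PCA; each class is summarised by
its centroid in the PC1-PC2 score plane and a 95% radius
r_c = s_c * sqrt(chi2_{2; 0.95}) with the radial scale
s_c = sqrt(mean squared centroid distance / 2); a sample is assigned to the
nearest centroid within radius, or left "unassigned" (counted as
incorrect).  Model validation repeats the whole chain on 100 random
stratified 90/10 splits (Monte Carlo cross-validation) with feature
selection, scaling and loadings refit on each training fold so no test
information leaks into the model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .isotope_stats import IsotopeRecord
from .spectra_prep import BinnedSpectrum

__all__ = [
    "FeatureTable",
    "KWScore",
    "PCAModel",
    "CentroidClassifier",
    "CVResult",
    "FittedPipeline",
    "fuse",
    "kw_filter_scores",
    "select_top_k",
    "autoscale",
    "apply_autoscale",
    "pca_fit",
    "fit_centroid_classifier",
    "classify",
    "accuracy",
    "fit_pipeline",
    "monte_carlo_cv",
    "UNASSIGNED",
    "CHI2_2_95",
]

UNASSIGNED = "unassigned"
#: chi-square 0.95 quantile with 2 degrees of freedom (score-plane radius).
CHI2_2_95 = float(stats.chi2.ppf(0.95, 2))

ISOTOPE_VARS = ("d13C", "d15N", "d18O")


@dataclass(frozen=True)
class FeatureTable:
    """Samples x named variables matrix with per-sample class labels."""

    matrix: np.ndarray
    variable_names: list[str]
    labels: np.ndarray
    sample_ids: list[str]
    cultivar: str = ""

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        labels = np.asarray(self.labels)
        if m.ndim != 2:
            raise ValueError("matrix must be 2-D")
        if m.shape[1] != len(self.variable_names):
            raise ValueError("variable_names length must match matrix columns")
        if m.shape[0] != labels.size or m.shape[0] != len(self.sample_ids):
            raise ValueError("labels/sample_ids length must match matrix rows")
        if len(set(self.variable_names)) != len(self.variable_names):
            raise ValueError("variable names must be unique")
        if not np.all(np.isfinite(m)):
            raise ValueError("matrix contains non-finite values")
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "labels", labels)

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_variables(self) -> int:
        return self.matrix.shape[1]

    def subset_rows(self, idx) -> "FeatureTable":
        idx = np.asarray(idx)
        return FeatureTable(
            self.matrix[idx],
            list(self.variable_names),
            self.labels[idx],
            [self.sample_ids[i] for i in idx],
            self.cultivar,
        )

    def subset_columns(self, names: list[str]) -> "FeatureTable":
        pos = {v: j for j, v in enumerate(self.variable_names)}
        cols = [pos[v] for v in names]
        return FeatureTable(
            self.matrix[:, cols], list(names), self.labels, list(self.sample_ids),
            self.cultivar,
        )

    def to_dataframe(self):
        import pandas as pd

        df = pd.DataFrame(self.matrix, columns=self.variable_names)
        df.insert(0, "sample_id", self.sample_ids)
        df.insert(1, "year", self.labels)
        return df


@dataclass(frozen=True)
class KWScore:
    variable_name: str
    H: float
    rank: int


@dataclass(frozen=True)
class PCAModel:
    """Autoscale parameters plus SVD loadings and explained variance."""

    column_means: np.ndarray
    column_sds: np.ndarray
    loadings: np.ndarray  # variables x components
    explained_variance_pct: np.ndarray
    variable_names: list[str]

    def transform(self, table: FeatureTable) -> np.ndarray:
        """Project (raw, unscaled) rows using the stored training
        means/sds and loadings."""
        sub = table.subset_columns(self.variable_names)
        scaled = (sub.matrix - self.column_means) / self.column_sds
        return scaled @ self.loadings


@dataclass(frozen=True)
class CentroidClassifier:
    """Per-class centroid, radial scale and 95% threshold radius in the
    PC1-PC2 score plane."""

    classes: list
    centroids: np.ndarray  # n_classes x 2
    radial_scales: np.ndarray
    radii: np.ndarray
    alpha: float = 0.05


@dataclass(frozen=True)
class CVResult:
    accuracies: np.ndarray  # per-iteration test accuracy, %
    n_iterations: int
    train_fraction: float
    seed: int

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.accuracies))


def fuse(
    binned: dict[str, BinnedSpectrum],
    isotopes: list[IsotopeRecord],
    cultivar: str = "",
) -> FeatureTable:
    """Attach the isotope deltas to the binned spectra: 303 columns per
    sample (300 bins in ascending bin-center order, then d13C, d15N, d18O).

    When ``cultivar`` is given only that cultivar's isotope records are
    used; every sample must appear in both modalities.
    """
    recs = [r for r in isotopes if not cultivar or r.cultivar == cultivar]
    iso_ids = [r.sample_id for r in recs]
    missing_nir = sorted(set(iso_ids) - set(binned))
    missing_iso = sorted(set(binned) - set(iso_ids)) if not cultivar else []
    if missing_nir or missing_iso:
        raise ValueError(
            "samples present in one modality only: "
            f"no spectra for {missing_nir}; no isotopes for {missing_iso}"
        )
    if not recs:
        raise ValueError("no isotope records to fuse")
    ref_centers = binned[iso_ids[0]].bin_centers
    names = [f"bin_{c:.4f}" for c in ref_centers] + list(ISOTOPE_VARS)
    rows = []
    for r in recs:
        b = binned[r.sample_id]
        if not np.array_equal(b.bin_centers, ref_centers):
            raise ValueError(f"{r.sample_id}: bin grid differs from the others")
        rows.append(np.concatenate([b.bin_values, [r.d13C, r.d15N, r.d18O]]))
    return FeatureTable(
        np.asarray(rows),
        names,
        np.array([r.year for r in recs]),
        iso_ids,
        cultivar or (recs[0].cultivar if len({r.cultivar for r in recs}) == 1 else ""),
    )


def _kw_h(column: np.ndarray, labels: np.ndarray, classes: np.ndarray) -> float:
    """Kruskal-Wallis H with midrank ties and the standard tie correction."""
    n = column.size
    ranks = stats.rankdata(column)
    h = 0.0
    for c in classes:
        r = ranks[labels == c]
        h += r.size * (r.mean() - (n + 1) / 2.0) ** 2
    h *= 12.0 / (n * (n + 1))
    _, counts = np.unique(column, return_counts=True)
    tie_term = np.sum(counts**3 - counts)
    denom = 1.0 - tie_term / (n**3 - n)
    if denom == 0.0:  # all values identical
        return 0.0
    return float(h / denom)


def kw_filter_scores(table: FeatureTable) -> list[KWScore]:
    """Per-variable Kruskal-Wallis H as a class-separation filter score.

    Ranks (1 = most relevant) follow descending H; ties in H break by
    ascending variable name.  A constant variable gets H = 0.
    """
    classes = np.unique(table.labels)
    if classes.size < 2:
        raise ValueError("need at least 2 classes")
    for c in classes:
        if np.sum(table.labels == c) < 2:
            raise ValueError(f"class {c} has fewer than 2 samples")
    hs = np.array(
        [_kw_h(table.matrix[:, j], table.labels, classes) for j in range(table.n_variables)]
    )
    order = sorted(range(hs.size), key=lambda j: (-hs[j], table.variable_names[j]))
    ranks = np.empty(hs.size, dtype=int)
    for r, j in enumerate(order, start=1):
        ranks[j] = r
    return [
        KWScore(variable_name=table.variable_names[j], H=float(hs[j]), rank=int(ranks[j]))
        for j in range(hs.size)
    ]


def select_top_k(
    scores: list[KWScore], table: FeatureTable, k: int = 50
) -> FeatureTable:
    """Keep the k variables ranked most class-relevant, preserving the
    original column order among survivors."""
    if k > table.n_variables:
        raise ValueError(f"k={k} exceeds {table.n_variables} variables")
    keep = {s.variable_name for s in scores if s.rank <= k}
    names = [v for v in table.variable_names if v in keep]
    return table.subset_columns(names)


def autoscale(table: FeatureTable):
    """Mean-center and divide each column by its sample sd (n-1 denominator).

    Returns the scaled table plus the column means and sds for projecting
    held-out data with training parameters.
    """
    means = table.matrix.mean(axis=0)
    sds = table.matrix.std(axis=0, ddof=1)
    zero = np.flatnonzero(sds == 0)
    if zero.size:
        names = [table.variable_names[j] for j in zero[:5]]
        raise ValueError(f"zero-variance column(s): {names}")
    scaled = FeatureTable(
        (table.matrix - means) / sds,
        list(table.variable_names),
        table.labels,
        list(table.sample_ids),
        table.cultivar,
    )
    return scaled, means, sds


def apply_autoscale(
    table: FeatureTable, means: np.ndarray, sds: np.ndarray
) -> FeatureTable:
    """Scale rows with previously stored (training) means and sds."""
    return FeatureTable(
        (table.matrix - means) / sds,
        list(table.variable_names),
        table.labels,
        list(table.sample_ids),
        table.cultivar,
    )


def pca_fit(
    scaled: FeatureTable,
    n_components: int = 2,
    column_means: np.ndarray | None = None,
    column_sds: np.ndarray | None = None,
):
    """PCA of an autoscaled table via singular value decomposition.

    Explained variance per component is 100 * sigma_k^2 / sum(sigma_i^2).
    Component signs are fixed so the largest-magnitude loading of each
    component is positive.  Returns (PCAModel, scores).
    """
    X = scaled.matrix
    max_comp = min(X.shape[0] - 1, X.shape[1])
    if X.shape[0] < 2:
        raise ValueError("PCA needs at least 2 rows")
    if n_components > max_comp:
        raise ValueError(f"n_components={n_components} exceeds rank bound {max_comp}")
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    total = np.sum(s**2)
    ev_pct = 100.0 * s[:n_components] ** 2 / total
    V = Vt[:n_components].T
    scores = U[:, :n_components] * s[:n_components]
    for k in range(n_components):
        j = int(np.argmax(np.abs(V[:, k])))
        if V[j, k] < 0:
            V[:, k] = -V[:, k]
            scores[:, k] = -scores[:, k]
    model = PCAModel(
        column_means=column_means if column_means is not None else np.zeros(X.shape[1]),
        column_sds=column_sds if column_sds is not None else np.ones(X.shape[1]),
        loadings=V,
        explained_variance_pct=ev_pct,
        variable_names=list(scaled.variable_names),
    )
    return model, scores


def fit_centroid_classifier(
    scores2d: np.ndarray, labels: np.ndarray, alpha: float = 0.05
) -> CentroidClassifier:
    """Per-class centroid and 95% distance threshold in the score plane.

    The radial scale is s_c = sqrt(mean(||x - mu_c||^2) / 2) and the radius
    r_c = s_c * sqrt(chi2_{2; 1-alpha}) -- an isotropic two-dimensional
    normal-theory confidence circle.
    """
    scores2d = np.asarray(scores2d, dtype=float)
    if scores2d.ndim != 2 or scores2d.shape[1] != 2:
        raise ValueError("scores must be n x 2")
    classes = sorted(np.unique(labels).tolist())
    centroids, scales = [], []
    for c in classes:
        pts = scores2d[np.asarray(labels) == c]
        if pts.shape[0] < 2:
            raise ValueError(f"class {c} has fewer than 2 samples")
        mu = pts.mean(axis=0)
        msd = np.mean(np.sum((pts - mu) ** 2, axis=1))
        s_c = np.sqrt(msd / 2.0)
        if s_c == 0:
            raise ValueError(f"class {c} has zero score dispersion")
        centroids.append(mu)
        scales.append(s_c)
    scales = np.asarray(scales)
    q = stats.chi2.ppf(1.0 - alpha, 2)
    return CentroidClassifier(
        classes=classes,
        centroids=np.asarray(centroids),
        radial_scales=scales,
        radii=scales * np.sqrt(q),
        alpha=alpha,
    )


def classify(model: CentroidClassifier, scores2d: np.ndarray) -> list:
    """Assign each point to the nearest centroid within its class radius,
    or to "unassigned" when no class qualifies."""
    scores2d = np.asarray(scores2d, dtype=float)
    dists = np.linalg.norm(
        scores2d[:, None, :] - model.centroids[None, :, :], axis=2
    )
    out = []
    for i in range(scores2d.shape[0]):
        ok = np.flatnonzero(dists[i] <= model.radii)
        if ok.size == 0:
            out.append(UNASSIGNED)
        else:
            out.append(model.classes[int(ok[np.argmin(dists[i, ok])])])
    return out


def accuracy(pred, truth) -> float:
    """Percent correct; 'unassigned' predictions count as incorrect."""
    pred = list(pred)
    truth = list(truth)
    if len(pred) != len(truth):
        raise ValueError("prediction/truth length mismatch")
    correct = sum(p == t for p, t in zip(pred, truth))
    return 100.0 * correct / len(truth)


@dataclass(frozen=True)
class FittedPipeline:
    """The full trained chain: selected variables, scaling parameters,
    loadings and the centroid classifier."""

    selected: list[str]
    scores_train: np.ndarray
    pca: PCAModel
    classifier: CentroidClassifier
    kw_scores: list[KWScore] = field(repr=False, default_factory=list)

    def predict(self, table: FeatureTable) -> list:
        return classify(self.classifier, self.pca.transform(table))


def fit_pipeline(
    table: FeatureTable,
    k: int = 50,
    n_components: int = 2,
    alpha: float = 0.05,
) -> FittedPipeline:
    """KW filter -> top-k selection -> autoscale -> PCA -> centroid model,
    fitted on the given rows only."""
    scores = kw_filter_scores(table)
    selected = select_top_k(scores, table, k=min(k, table.n_variables))
    scaled, means, sds = autoscale(selected)
    pca, train_scores = pca_fit(
        scaled, n_components=n_components, column_means=means, column_sds=sds
    )
    clf = fit_centroid_classifier(train_scores, table.labels, alpha=alpha)
    return FittedPipeline(
        selected=list(selected.variable_names),
        scores_train=train_scores,
        pca=pca,
        classifier=clf,
        kw_scores=scores,
    )


def _stratified_split(
    rng: np.random.Generator, labels: np.ndarray, train_fraction: float
):
    train, test = [], []
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        idx = rng.permutation(idx)
        n_train = int(round(train_fraction * idx.size))
        n_train = min(max(n_train, 0), idx.size)
        train.extend(idx[:n_train])
        test.extend(idx[n_train:])
    return np.sort(np.asarray(train, dtype=int)), np.sort(np.asarray(test, dtype=int))


def monte_carlo_cv(
    table: FeatureTable,
    n_iter: int = 100,
    train_fraction: float = 0.9,
    k: int = 50,
    seed: int = 0,
    n_components: int = 2,
    alpha: float = 0.05,
    max_retries: int = 100,
) -> CVResult:
    """Monte Carlo cross-validation of the full chain.

    Each iteration draws a stratified random train/test split (both classes
    kept in training), refits feature selection, scaling, PCA and the
    centroid model on the training rows only, projects the test rows with
    the training parameters, and records test accuracy.  The seed fully
    determines the splits.
    """
    if np.unique(table.labels).size < 2:
        raise ValueError("need both classes present")
    rng = np.random.default_rng(seed)
    accs = np.empty(n_iter)
    for it in range(n_iter):
        for attempt in range(max_retries):
            train_idx, test_idx = _stratified_split(rng, table.labels, train_fraction)
            if test_idx.size == 0:
                continue
            counts = [
                np.sum(table.labels[train_idx] == c) for c in np.unique(table.labels)
            ]
            if min(counts) >= 2:
                break
        else:
            raise RuntimeError("could not draw a valid stratified split")
        fitted = fit_pipeline(
            table.subset_rows(train_idx), k=k, n_components=n_components, alpha=alpha
        )
        pred = fitted.predict(table.subset_rows(test_idx))
        accs[it] = accuracy(pred, table.labels[test_idx])
    return CVResult(
        accuracies=accs,
        n_iterations=n_iter,
        train_fraction=train_fraction,
        seed=seed,
    )
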