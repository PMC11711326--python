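"""Generative-model and batch-mixing evaluation.

Distribution distance is the Fréchet distance between Gaussian moment
summaries of image features, d² = ||m_g − m_r||² + Tr(C_g + C_r −
2(C_g C_r)^{1/2}); fidelity/diversity is complemented by Coverage, the
fraction of real points whose k-NN sphere (radius = distance to the k-th
nearest *real* neighbour) contains at least one generated point. Batch
mixing after correction is scored by batch-silhouette, iLISI (normalized
inverse Simpson index over k-NN batch frequencies), and per-cluster batch
impurity (entropy, Gini) over Leiden clusters.

Feature extractors are pluggable; the built-in "morphology" extractor
computes intensity/texture/shape statistics per image so everything runs
offline. Adapters for external pretrained extractors can be registered at
run time with :func:`register_extractor`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, ndimage
from skimage.filters import sobel, threshold_otsu
from skimage.measure import label, regionprops
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import silhouette_samples
from sklearn.neighbors import NearestNeighbors
from sklearn.preprocessing import StandardScaler


# ---------------------------------------------------------------------------
# feature extraction
# ---------------------------------------------------------------------------

def morphology_features(images):
    """Proxy morphological featurizer: per-channel intensity statistics plus
    texture and nuclear-shape summaries. A lightweight stand-in for heavy
    profiling pipelines; deterministic and dependency-free."""
    images = np.asarray(images, dtype=np.float64)
    rows = []
    for img in images:
        feats = []
        for ch in img:
            feats.extend(
                [
                    ch.mean(),
                    ch.std(),
                    np.percentile(ch, 25),
                    np.percentile(ch, 75),
                    np.abs(sobel(ch)).mean(),
                    ndimage.laplace(ch).var(),
                ]
            )
        nuclear = img[0]
        span = nuclear.max() - nuclear.min()
        if span > 1e-9:
            mask = nuclear > threshold_otsu(nuclear)
            objs = [p for p in regionprops(label(mask))] if mask.any() else []
            feats.extend(
                [
                    mask.mean(),
                    float(len(objs)),
                    float(np.mean([p.area for p in objs])) if objs else 0.0,
                    float(np.mean([p.eccentricity for p in objs])) if objs else 0.0,
                ]
            )
        else:
            feats.extend([0.0, 0.0, 0.0, 0.0])
        rows.append(feats)
    return np.asarray(rows)


_EXTRACTORS = {"morphology": morphology_features}


def register_extractor(name, fn):
    _EXTRACTORS[name] = fn


def extract_features(images, extractor="morphology"):
    """Feature matrix (n, F); rows align with input order."""
    if callable(extractor):
        fn = extractor
    else:
        fn = _EXTRACTORS.get(extractor)
        if fn is None:
            raise KeyError(
                f"extractor {extractor!r} not registered; "
                f"available: {sorted(_EXTRACTORS)}"
            )
    feats = np.asarray(fn(np.asarray(images)))
    if feats.ndim != 2 or feats.shape[0] != len(images):
        raise ValueError("extractor must return one feature row per image")
    return feats


# ---------------------------------------------------------------------------
# FID
# ---------------------------------------------------------------------------

@dataclass
class FeatureMoments:
    mean: np.ndarray
    cov: np.ndarray
    n: int

    @classmethod
    def from_features(cls, feats):
        feats = np.asarray(feats, dtype=np.float64)
        if feats.shape[0] < 2:
            raise ValueError("need at least two samples for moments")
        return cls(
            mean=feats.mean(axis=0), cov=np.cov(feats, rowvar=False), n=feats.shape[0]
        )


def fid(real: FeatureMoments, gen: FeatureMoments, psd_tol=1e-6):
    """Fréchet distance between Gaussian moment summaries.

    The cross-covariance square root is computed with a symmetrized matrix
    square root; small negative eigenvalues from floating-point are clipped
    at zero, larger ones raise.
    """
    if real.mean.shape != gen.mean.shape:
        raise ValueError("feature dimensionalities differ")
    diff = gen.mean - real.mean
    prod = gen.cov @ real.cov
    covmean = linalg.sqrtm(prod)
    if np.iscomplexobj(covmean):
        imag_max = np.abs(covmean.imag).max()
        scale = max(1.0, np.abs(covmean.real).max())
        if imag_max / scale > 1e-3:
            eig = np.linalg.eigvals(prod)
            raise ValueError(
                f"covariance product strongly non-PSD; eigenvalues: {np.sort(eig.real)}"
            )
        covmean = covmean.real
    tr_covmean = np.trace(covmean)
    value = float(diff @ diff + np.trace(gen.cov) + np.trace(real.cov) - 2 * tr_covmean)
    if value < 0:
        if value < -psd_tol:
            raise ValueError(f"FID evaluated to {value}; numerical failure")
        value = 0.0
    return value


def fid_from_features(real_feats, gen_feats):
    return fid(
        FeatureMoments.from_features(real_feats), FeatureMoments.from_features(gen_feats)
    )


def inverse_fid(value, eps=1e-12):
    """Reported as 1/FID so that, like the other scores, higher is better."""
    return 1.0 / (value + eps)


# ---------------------------------------------------------------------------
# coverage
# ---------------------------------------------------------------------------

def coverage(real_features, gen_features, k=5):
    """Fraction of real points with >= 1 generated point inside their k-NN
    sphere (radius = Euclidean distance to the k-th nearest real neighbour,
    boundary inclusive)."""
    real = np.asarray(real_features, dtype=np.float64)
    gen = np.asarray(gen_features, dtype=np.float64)
    n = real.shape[0]
    if k < 1 or k >= n:
        raise ValueError(f"need 1 <= k < n_real; got k={k}, n_real={n}")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(real)
    radii = nn.kneighbors(real)[0][:, k]  # k-th neighbour excluding self
    d_gen = NearestNeighbors(n_neighbors=1).fit(gen)
    nearest_gen = d_gen.kneighbors(real)[0][:, 0]
    return float(np.mean(nearest_gen <= radii))


# ---------------------------------------------------------------------------
# classification-based scores
# ---------------------------------------------------------------------------

class FeatureProbeClassifier:
    """Logistic-regression probe on morphology features.

    A fast, deterministic stand-in for a convolutional classifier; used to
    check that transformed images carry the target condition's signature.
    """

    def __init__(self, extractor="morphology", seed=0, max_iter=2000):
        self.extractor = extractor
        self.seed = seed
        self._scaler = StandardScaler()
        self._clf = LogisticRegression(max_iter=max_iter, random_state=seed)

    def fit(self, images, labels):
        feats = self._scaler.fit_transform(extract_features(images, self.extractor))
        self._clf.fit(feats, np.asarray(labels))
        return self

    @property
    def classes_(self):
        return self._clf.classes_

    def predict(self, images):
        feats = self._scaler.transform(extract_features(images, self.extractor))
        return self._clf.predict(feats)

    def score(self, images, labels):
        return float(np.mean(self.predict(images) == np.asarray(labels)))


def moa_accuracy(generated_images, target_labels, classifier):
    """Fraction of generated images the classifier assigns to the target
    mode-of-action label."""
    targets = np.asarray(target_labels)
    known = set(np.asarray(classifier.classes_).tolist())
    unknown = set(targets.tolist()) - known
    if unknown:
        raise ValueError(f"labels absent from the classifier: {sorted(unknown)}")
    pred = classifier.predict(np.asarray(generated_images))
    return float(np.mean(pred == targets))


# ---------------------------------------------------------------------------
# batch-mixing scores
# ---------------------------------------------------------------------------

def batch_mixing_scores(features, batch_labels, k=15):
    """(silhouette_batch, iLISI), both in [0, 1], 1 = perfectly mixed.

    silhouette_batch averages 1 − |s_i| with batches as the cluster label;
    iLISI is the per-point inverse Simpson index of batch frequencies among
    the k nearest neighbours, rescaled from [1, n_batches] to [0, 1].
    """
    feats = np.asarray(features, dtype=np.float64)
    labels = np.asarray(batch_labels)
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("need at least two batches")
    if (counts < 2).any():
        small = uniq[counts < 2]
        raise ValueError(f"batches with fewer than two points: {small.tolist()}")
    sil = silhouette_samples(feats, labels)
    asw = float(np.mean(1.0 - np.abs(sil)))

    k_eff = min(k, len(feats) - 1)
    nn = NearestNeighbors(n_neighbors=k_eff + 1).fit(feats)
    idx = nn.kneighbors(feats)[1][:, 1:]  # drop self
    simpson = []
    for neigh in idx:
        freqs = np.array([(labels[neigh] == u).mean() for u in uniq])
        simpson.append(1.0 / np.sum(freqs**2))
    ilisi = (np.mean(simpson) - 1.0) / (len(uniq) - 1.0)
    return asw, float(np.clip(ilisi, 0.0, 1.0))


def leiden_clustering(features, resolution=1.0, seed=0, n_neighbors=15):
    """Leiden community labels on a k-NN graph of the features."""
    import anndata
    import scanpy as sc

    ad = anndata.AnnData(np.asarray(features, dtype=np.float64))
    sc.pp.neighbors(ad, n_neighbors=min(n_neighbors, len(features) - 1), use_rep="X")
    sc.tl.leiden(ad, resolution=resolution, random_state=seed, flavor="leidenalg")
    return ad.obs["leiden"].to_numpy()


def cluster_impurity(features, batch_labels, clustering=None):
    """Mean batch entropy and Gini impurity across clusters (unweighted).

    For cluster i with batch frequencies p_ij: H_i = −Σ_j p_ij log2 p_ij
    (0·log 0 := 0) and G_i = 1 − Σ_j p_ij². Returns (mean_H, mean_G,
    per-cluster DataFrame).
    """
    labels = np.asarray(batch_labels)
    clusters = np.asarray(
        clustering(features) if callable(clustering)
        else clustering if clustering is not None
        else leiden_clustering(features)
    )
    uniq_batches = np.unique(labels)
    rows = []
    for cl in np.unique(clusters):
        members = labels[clusters == cl]
        if members.size == 0:
            continue
        p = np.array([(members == b).mean() for b in uniq_batches])
        nz = p[p > 0]
        rows.append(
            {
                "cluster": cl,
                "size": members.size,
                "entropy": float(-(nz * np.log2(nz)).sum()),
                "gini": float(1.0 - (p**2).sum()),
            }
        )
    df = pd.DataFrame(rows)
    return float(df["entropy"].mean()), float(df["gini"].mean()), df


# ---------------------------------------------------------------------------
# random-forest feature importance
# ---------------------------------------------------------------------------

def rf_feature_importance(features, labels, n_runs=10, n_trees=500, seed=0,
                          feature_names=None):
    """Mean impurity importances over seeded random-forest runs.

    10 runs of a 500-tree forest with out-of-bag scoring; importances are
    averaged across runs and returned ranked.
    """
    X = np.asarray(features, dtype=np.float64)
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    importances = np.zeros(X.shape[1])
    oob = []
    for run in range(n_runs):
        rf = RandomForestClassifier(
            n_estimators=n_trees, oob_score=True, random_state=seed + run, n_jobs=1
        )
        rf.fit(X, y)
        importances += rf.feature_importances_
        oob.append(rf.oob_score_)
    importances /= n_runs
    names = (
        list(feature_names)
        if feature_names is not None
        else [f"f{i}" for i in range(X.shape[1])]
    )
    df = pd.DataFrame({"feature": names, "importance": importances})
    df["rank"] = df["importance"].rank(ascending=False, method="first").astype(int)
    return df.sort_values("rank").reset_index(drop=True), float(np.mean(oob))


@dataclass
class MetricReport:
    """A named metric value with the settings that produced it."""

    name: str
    value: float
    settings: dict = field(default_factory=dict)

    def as_dict(self):
        return {"name": self.name, "value": self.value, "settings": self.settings}
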