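"""Logistic-regression classification of genuine vs artifactual TSS clusters.

Count-based scores (cluster count, summit count, flanking count) are weak
classifiers because exon-painting artifact levels track transcript
abundance. Two abundance-independent properties — the unencoded-G fraction
(cap signature) and the background-corrected expression (flanking count in
excess of the local same-strand rate) — separate genuine TSS much better,
and the combined three-predictor model (flanking count, unencoded-G
fraction, corrected expression) is the classifier applied at the default
probability cutoff of 0.5.

Training labels come from chromatin accessibility: clusters in highly
accessible chromatin are taken as likely genuine (positives), clusters in
closed chromatin as likely artifactual (negatives), the middle is excluded.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import statsmodels.api as sm
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score

from .cluster import TssCluster
from .ctss import CtssIndex
from .io import SignalTrack

FLANK_HALF_WIDTH = 75  # summit +/- 75 nt, a 151-bp window

PREDICTORS = ("flanking_count", "unencoded_g_pct", "corrected_expression")
FEATURE_NAMES = (
    "cluster_count",
    "summit_count",
    "flanking_count",
    "unencoded_g_pct",
    "corrected_expression",
)


class TrainingDataError(ValueError):
    """Too few labeled examples of one class."""


class FitError(RuntimeError):
    """Logistic fit failed (perfect separation or collinearity)."""


@dataclass(frozen=True)
class ClusterFeatures:
    """The five per-cluster properties scored as TSS classifiers."""

    cluster_count: int
    summit_count: int
    flanking_count: int
    unencoded_g_pct: float
    corrected_expression: float

    def __post_init__(self) -> None:
        if not (0 <= self.summit_count <= self.cluster_count):
            raise ValueError("require 0 <= summit_count <= cluster_count")
        if self.flanking_count < self.summit_count:
            raise ValueError("flanking window contains the summit")
        if not (0.0 <= self.unencoded_g_pct <= 1.0):
            raise ValueError("unencoded_g_pct must be in [0, 1]")
        if self.corrected_expression < 0:
            raise ValueError("corrected_expression is clipped at 0")

    def get(self, name: str) -> float:
        return getattr(self, name)


def compute_features(
    cluster: TssCluster,
    index: CtssIndex,
    background_half_width: int = 2000,
) -> ClusterFeatures:
    """Compute the five classifier properties of one TSS cluster.

    ``corrected_expression`` subtracts from the 151-bp flanking count the
    count expected under the local same-strand background rate, estimated
    from a +/- ``background_half_width`` window around the summit with the
    flanking window excluded, and clips at 0.
    """
    if background_half_width <= FLANK_HALF_WIDTH:
        raise ValueError("background_half_width must exceed the flanking half-width")
    if not index.has(cluster.chrom, cluster.strand):
        raise KeyError(f"no CTSS data for {cluster.chrom} strand {cluster.strand}")
    s = cluster.summit
    chrom, strand = cluster.chrom, cluster.strand
    cluster_umi, cluster_g = index.window(chrom, strand, cluster.start, cluster.end)
    summit_umi = index.umi_in(chrom, strand, s, s + 1)
    flank_umi = index.umi_in(chrom, strand, s - FLANK_HALF_WIDTH, s + FLANK_HALF_WIDTH + 1)
    bg_umi = (
        index.umi_in(chrom, strand, s - background_half_width, s + background_half_width + 1)
        - flank_umi
    )
    window_bp = 2 * FLANK_HALF_WIDTH + 1  # 151
    lam = bg_umi / (2 * background_half_width - window_bp)
    corrected = max(0.0, flank_umi - lam * window_bp)
    return ClusterFeatures(
        cluster_count=cluster_umi,
        summit_count=summit_umi,
        flanking_count=flank_umi,
        unencoded_g_pct=cluster_g / cluster_umi if cluster_umi else 0.0,
        corrected_expression=corrected,
    )


@dataclass(frozen=True)
class TrainingLabel:
    cluster_name: str
    label: str  # "positive" | "negative" | "excluded"
    atac_summary: float


def label_by_atac(
    clusters: Sequence[TssCluster],
    atac: SignalTrack,
    pos_quantile: float = 0.75,
    neg_value: float = 0.0,
    min_per_class: int = 50,
) -> List[TrainingLabel]:
    """Label clusters by chromatin accessibility over the flanking window.

    The summary is the mean signal over summit +/- 75 bp. Clusters at or
    above the ``pos_quantile`` quantile of the positive-signal summaries are
    positives, clusters at or below ``neg_value`` are negatives, the rest are
    excluded from training.
    """
    summaries = np.array(
        [
            atac.mean_over(c.chrom, c.summit - FLANK_HALF_WIDTH, c.summit + FLANK_HALF_WIDTH + 1)
            for c in clusters
        ]
    )
    with_signal = summaries[summaries > neg_value]
    if len(with_signal) == 0:
        raise TrainingDataError("no cluster overlaps the training signal")
    threshold = float(np.quantile(with_signal, pos_quantile))
    labels = []
    for c, s in zip(clusters, summaries):
        if s >= threshold:
            lab = "positive"
        elif s <= neg_value:
            lab = "negative"
        else:
            lab = "excluded"
        labels.append(TrainingLabel(c.name, lab, float(s)))
    n_pos = sum(1 for l in labels if l.label == "positive")
    n_neg = sum(1 for l in labels if l.label == "negative")
    if n_pos < min_per_class or n_neg < min_per_class:
        raise TrainingDataError(
            f"need >= {min_per_class} examples per class, got "
            f"{n_pos} positives / {n_neg} negatives"
        )
    return labels


_TRANSFORMS = {"log2p1": lambda x: np.log2(np.asarray(x, dtype=float) + 1.0),
               "identity": lambda x: np.asarray(x, dtype=float)}

DEFAULT_TRANSFORM = {
    "flanking_count": "log2p1",
    "unencoded_g_pct": "identity",
    "corrected_expression": "log2p1",
}


@dataclass
class LogisticModel:
    """Fitted three-predictor TSS classifier with its transform spec."""

    intercept: float
    coef: Dict[str, float]
    transform: Dict[str, str] = field(default_factory=lambda: dict(DEFAULT_TRANSFORM))
    standard_errors: Optional[Dict[str, float]] = None  # keys: intercept + predictors
    metadata: Dict[str, str] = field(default_factory=dict)

    def design_matrix(self, features: Sequence[ClusterFeatures]) -> np.ndarray:
        cols = [
            _TRANSFORMS[self.transform[name]]([f.get(name) for f in features])
            for name in self.coef
        ]
        return np.column_stack(cols)

    def predict_probability(self, features) -> np.ndarray:
        """Inverse-logit of the linear predictor on transformed features."""
        single = isinstance(features, ClusterFeatures)
        feats = [features] if single else list(features)
        x = self.design_matrix(feats)
        z = self.intercept + x @ np.array([self.coef[n] for n in self.coef])
        p = 1.0 / (1.0 + np.exp(-np.clip(z, -700, 700)))
        return float(p[0]) if single else p

    def save(self, path: str) -> None:
        lines = ["# fivep-cre logistic TSS classifier", "format_version=1",
                 "predictors=" + ",".join(self.coef)]
        for name, t in self.transform.items():
            lines.append(f"transform.{name}={t}")
        lines.append(f"intercept={self.intercept!r}")
        for name, b in self.coef.items():
            lines.append(f"coef.{name}={b!r}")
        if self.standard_errors:
            for name, se in self.standard_errors.items():
                lines.append(f"se.{name}={se!r}")
        for key, val in self.metadata.items():
            lines.append(f"meta.{key}={val}")
        with open(path, "w") as out:
            out.write("\n".join(lines) + "\n")

    @classmethod
    def load(cls, path: str) -> "LogisticModel":
        kv: Dict[str, str] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                key, _, val = line.partition("=")
                kv[key] = val
        predictors = kv["predictors"].split(",")
        coef = {name: float(kv[f"coef.{name}"]) for name in predictors}
        transform = {name: kv[f"transform.{name}"] for name in predictors}
        ses = {
            key[3:]: float(val) for key, val in kv.items() if key.startswith("se.")
        } or None
        meta = {key[5:]: val for key, val in kv.items() if key.startswith("meta.")}
        return cls(float(kv["intercept"]), coef, transform, ses, meta)


def fit_logistic(
    features: Sequence[ClusterFeatures],
    labels: Sequence[int],
    allow_l2: bool = False,
    min_per_class: int = 50,
    transform: Optional[Dict[str, str]] = None,
) -> LogisticModel:
    """Maximum-likelihood logistic fit of the three-predictor classifier.

    ``labels`` are 1 for genuine (positive) and 0 for artifact (negative).
    Fitting is Newton-type iteratively reweighted least squares to tolerance
    1e-8 (max 100 iterations). On perfect separation or collinearity the fit
    raises :class:`FitError` unless ``allow_l2`` is set, in which case a
    weakly penalized (L2, strength 1e-6) fit is returned and flagged in the
    model metadata.
    """
    transform = dict(transform or DEFAULT_TRANSFORM)
    y = np.asarray(labels, dtype=float)
    if (y == 1).sum() < min_per_class or (y == 0).sum() < min_per_class:
        raise TrainingDataError(f"need >= {min_per_class} labeled examples per class")
    shell = LogisticModel(0.0, {name: 0.0 for name in PREDICTORS}, transform)
    x = shell.design_matrix(features)
    xc = sm.add_constant(x, has_constant="add")

    params = ses = None
    method = "mle"
    try:
        with np.errstate(all="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, xc).fit(method="newton", maxiter=100, tol=1e-8, disp=0)
        if res.mle_retvals.get("converged", False) and np.all(np.abs(res.params) < 30):
            params = np.asarray(res.params)
            ses = np.asarray(res.bse)
    except Exception:
        params = None
    if params is None:
        if not allow_l2:
            raise FitError(
                "logistic fit did not converge (perfect separation or collinear "
                "predictors); rerun with the L2 regularization flag enabled"
            )
        clf = LogisticRegression(
            C=1e6, tol=1e-10, max_iter=10000, solver="lbfgs"
        ).fit(x, y)
        params = np.concatenate([clf.intercept_, clf.coef_[0]])
        with np.errstate(all="ignore"):
            hess = sm.Logit(y, xc).hessian(params)
            cov = np.linalg.pinv(-hess)
            diag = np.diag(cov)
            ses = np.sqrt(np.where(diag > 0, diag, np.nan))
        method = "l2"

    names = ["intercept", *PREDICTORS]
    return LogisticModel(
        intercept=float(params[0]),
        coef={name: float(b) for name, b in zip(PREDICTORS, params[1:])},
        transform=transform,
        standard_errors={name: float(se) for name, se in zip(names, ses)},
        metadata={
            "n_pos": str(int((y == 1).sum())),
            "n_neg": str(int((y == 0).sum())),
            "method": method,
        },
    )


def predict_probability(model: LogisticModel, features) -> np.ndarray:
    return model.predict_probability(features)


def apply_cutoff(probabilities, cutoff: float = 0.5) -> np.ndarray:
    """Keep-mask at the probability cutoff (kept iff p >= cutoff)."""
    if not 0.0 < cutoff < 1.0:
        raise ValueError(f"cutoff must be in (0, 1), got {cutoff}")
    p = np.asarray(probabilities, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must be in [0, 1]")
    return p >= cutoff


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve = pairwise concordance with ties at 0.5."""
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("AUC undefined: both classes must be present")
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


def benchmark_predictors(
    features: Sequence[ClusterFeatures],
    labels: Sequence[int],
    min_per_class: int = 50,
) -> Tuple[Dict[str, float], LogisticModel]:
    """AUC of each single property and of the combined model's probability."""
    y = np.asarray(labels, dtype=int)
    aucs = {
        name: roc_auc([f.get(name) for f in features], y) for name in FEATURE_NAMES
    }
    model = fit_logistic(features, y, allow_l2=True, min_per_class=min_per_class)
    aucs["combined"] = roc_auc(model.predict_probability(features), y)
    return aucs, model


def classify_clusters(
    clusters: Sequence[TssCluster],
    index: CtssIndex,
    model: LogisticModel,
    cutoff: float = 0.5,
    background_half_width: int = 2000,
) -> Tuple[List[ClusterFeatures], np.ndarray, np.ndarray]:
    """Score clusters with a fitted model; returns (features, probs, keep mask)."""
    feats = [compute_features(c, index, background_half_width) for c in clusters]
    probs = model.predict_probability(feats) if feats else np.array([])
    return feats, probs, apply_cutoff(probs, cutoff) if len(probs) else np.array([], bool)
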