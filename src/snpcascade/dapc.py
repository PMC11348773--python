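"""Discriminant Analysis of Principal Components (DAPC).

DAPC first reduces a centered/scaled genotype matrix to ``n_pca``
principal components, then applies Fisher linear discriminant analysis on
the PC scores, maximizing the ratio of between-group to within-group
variance.  Group membership posteriors come from Gaussian class-conditional
densities in discriminant space with a shared spherical covariance (the
discriminant axes are scaled to unit pooled within-group variance).

Per-locus "LD values" — the contribution of each locus to each discriminant
axis, obtained by composing the PCA loadings with the discriminant
coefficients and squaring — are the ranking statistic used to pick
diagnostic SNPs.

Retained-PC choice is made by stratified cross-validation: repeated
train/test splits (default 90/10) scored by held-out assignment success.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.linalg
from scipy.special import logsumexp

from .genotype_io import GenotypeMatrix
from .matrix_core import pca as _pca

SERIAL_VERSION = 1


@dataclass
class DAPCModel:
    """A fitted DAPC classifier; everything needed for out-of-sample use."""

    locus_ids: list[str]
    classes: list[str]  # sorted group labels
    mean: np.ndarray  # per-locus centering (training means; also the
    # mean-fill value for missing loci at predict time)
    scale: np.ndarray | None
    pca_loadings: np.ndarray  # loci x n_pca
    disc_coef: np.ndarray  # n_pca x n_da
    centroids: np.ndarray  # n_classes x n_da (discriminant space)
    priors: np.ndarray  # sums to 1
    n_pca: int
    n_da: int

    @property
    def loci_loadings(self) -> np.ndarray:
        """Total per-locus loadings on each discriminant axis (loci x n_da)."""
        return self.pca_loadings @ self.disc_coef

    # -- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "format_version": SERIAL_VERSION,
            "locus_ids": self.locus_ids,
            "classes": self.classes,
            "mean": self.mean.tolist(),
            "scale": None if self.scale is None else self.scale.tolist(),
            "pca_loadings": self.pca_loadings.tolist(),
            "disc_coef": self.disc_coef.tolist(),
            "centroids": self.centroids.tolist(),
            "priors": self.priors.tolist(),
            "n_pca": self.n_pca,
            "n_da": self.n_da,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DAPCModel":
        if d.get("format_version") != SERIAL_VERSION:
            raise ValueError(f"unsupported model version {d.get('format_version')}")
        return cls(
            locus_ids=list(d["locus_ids"]),
            classes=list(d["classes"]),
            mean=np.array(d["mean"], dtype=float),
            scale=None if d["scale"] is None else np.array(d["scale"], dtype=float),
            pca_loadings=np.array(d["pca_loadings"], dtype=float),
            disc_coef=np.array(d["disc_coef"], dtype=float),
            centroids=np.array(d["centroids"], dtype=float),
            priors=np.array(d["priors"], dtype=float),
            n_pca=int(d["n_pca"]),
            n_da=int(d["n_da"]),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def load(cls, path) -> "DAPCModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class XValReport:
    """Cross-validation grid over candidate retained-PC counts."""

    grid: list[int]
    mean_success: list[float]  # held-out assignment success per candidate
    rmse: list[float]  # sqrt(mean (1 - posterior of true class)^2)
    chosen_n_pca: int
    reps: int
    training_fraction: float
    seed: int


def _design(gm, labels=None):
    """Coerce input to (float matrix, locus ids, label array)."""
    if isinstance(gm, GenotypeMatrix):
        X = gm.as_float(fill="mean")
        locus_ids = gm.locus_ids
    else:
        X = np.asarray(gm, dtype=float)
        locus_ids = [f"L{j}" for j in range(X.shape[1])]
    y = None if labels is None else np.asarray([str(l) for l in labels])
    return X, locus_ids, y


def fit_dapc(
    gm,
    labels: Sequence[str],
    n_pca: int | None = None,
    n_da: int | None = None,
    scale: bool = False,
    priors: str | np.ndarray = "uniform",
    ridge: float = 1e-8,
) -> DAPCModel:
    """Fit a DAPC model: PCA reduction followed by Fisher LDA on PC scores.

    Parameters
    ----------
    gm
        GenotypeMatrix (missing cells mean-filled) or complete float array.
    labels
        Group label per sample; >= 2 groups, each with >= 2 samples.
    n_pca
        Retained principal components (default: full rank).
    n_da
        Retained discriminant axes (default and cap: n_groups - 1).
    priors
        ``"uniform"`` (default), ``"proportional"``, or an explicit vector
        over the sorted class labels.
    ridge
        Within-group scatter regularization, as a fraction of its mean
        diagonal; guards against singular scatter in small groups.
    """
    X, locus_ids, y = _design(gm, labels)
    n, p = X.shape
    if y is None or len(y) != n:
        raise ValueError("labels length must equal number of samples")
    classes, y_idx = np.unique(y, return_inverse=True)
    g = len(classes)
    if g < 2:
        raise ValueError("need at least 2 groups")
    counts = np.bincount(y_idx, minlength=g)
    if counts.min() < 2:
        small = classes[counts < 2][0]
        raise ValueError(f"group {small!r} has fewer than 2 samples")

    full_rank = min(n - 1, p)
    if n_pca is None:
        n_pca = full_rank
    n_pca = int(min(n_pca, full_rank))
    if n_pca < 1:
        raise ValueError("n_pca must be >= 1")
    max_da = min(g - 1, n_pca)
    n_da = max_da if n_da is None else int(min(n_da, max_da))

    pres = _pca(X, k=n_pca, scale=scale)
    S = pres.scores  # n x n_pca

    # Fisher LDA on PC scores: pooled within-group and between-group scatter
    overall = S.mean(axis=0)
    Sw = np.zeros((n_pca, n_pca))
    Sb = np.zeros((n_pca, n_pca))
    for k in range(g):
        Sk = S[y_idx == k]
        mu = Sk.mean(axis=0)
        d = Sk - mu
        Sw += d.T @ d
        dm = (mu - overall)[:, None]
        Sb += counts[k] * (dm @ dm.T)
    Sw /= max(n - g, 1)
    Sb /= max(n - g, 1)
    reg = ridge * (np.trace(Sw) / n_pca if np.trace(Sw) > 0 else 1.0)
    Sw_reg = Sw + reg * np.eye(n_pca)

    evals, evecs = scipy.linalg.eigh(Sb, Sw_reg)
    order = np.argsort(evals)[::-1][:n_da]
    W = evecs[:, order]  # n_pca x n_da; eigh gives w' Sw_reg w = 1 already

    # deterministic sign via the composed per-locus loadings
    total = pres.loadings @ W
    for a in range(n_da):
        i = np.argmax(np.abs(total[:, a]))
        if total[i, a] < 0:
            W[:, a] = -W[:, a]

    Z = S @ W
    centroids = np.vstack([Z[y_idx == k].mean(axis=0) for k in range(g)])

    if isinstance(priors, str):
        if priors == "uniform":
            pri = np.full(g, 1.0 / g)
        elif priors == "proportional":
            pri = counts / counts.sum()
        else:
            raise ValueError(f"unknown priors {priors!r}")
    else:
        pri = np.asarray(priors, dtype=float)
        if pri.shape != (g,) or not np.isclose(pri.sum(), 1.0):
            raise ValueError("explicit priors must sum to 1 over the classes")

    # C-contiguous copies so serialized models reproduce predictions bit-exactly
    return DAPCModel(
        locus_ids=list(locus_ids),
        classes=[str(c) for c in classes],
        mean=np.ascontiguousarray(pres.mean),
        scale=None if pres.scale is None else np.ascontiguousarray(pres.scale),
        pca_loadings=np.ascontiguousarray(pres.loadings),
        disc_coef=np.ascontiguousarray(W),
        centroids=centroids,
        priors=pri,
        n_pca=n_pca,
        n_da=n_da,
    )


def transform_dapc(model: DAPCModel, gm) -> np.ndarray:
    """Project samples into the model's discriminant space.

    Accepts a GenotypeMatrix whose loci are a subset of the model's; loci
    absent from the sample (or missing cells) are filled with the model's
    training means, i.e. they contribute zero after centering.
    """
    if isinstance(gm, GenotypeMatrix):
        have = {l: j for j, l in enumerate(gm.locus_ids)}
        shared = [l for l in model.locus_ids if l in have]
        if not shared:
            raise ValueError("no overlap between sample loci and model loci")
        X = np.tile(model.mean, (gm.n_samples, 1))
        for mj, lid in enumerate(model.locus_ids):
            j = have.get(lid)
            if j is None:
                continue
            col = gm.values[:, j].astype(float)
            obs = gm.values[:, j] != -1
            X[obs, mj] = col[obs]
    else:
        X = np.asarray(gm, dtype=float)
        if X.shape[1] != len(model.locus_ids):
            raise ValueError("array input must have exactly the model's loci")
    Xc = X - model.mean
    if model.scale is not None:
        Xc = Xc / model.scale
    return Xc @ model.pca_loadings @ model.disc_coef


def predict_dapc(model: DAPCModel, gm) -> tuple[np.ndarray, list[str]]:
    """Posterior group membership and argmax labels for new samples.

    Posteriors use Gaussian class-conditional densities with shared unit
    spherical covariance in discriminant space (log posterior up to a
    constant: ``log prior - ||z - centroid||^2 / 2``).  Each row sums to 1;
    ties break to the lexicographically smallest class label.
    """
    Z = transform_dapc(model, gm)
    d2 = ((Z[:, None, :] - model.centroids[None, :, :]) ** 2).sum(axis=2)
    logp = np.log(model.priors)[None, :] - 0.5 * d2
    post = np.exp(logp - logsumexp(logp, axis=1, keepdims=True))
    # classes are sorted, so first argmax == lexicographically smallest tie
    labels = [model.classes[i] for i in np.argmax(post, axis=1)]
    return post, labels


def variable_contributions(model: DAPCModel) -> np.ndarray:
    """Per-locus contribution to each discriminant axis (columns sum to 1).

    Contribution of locus j to axis a is the squared composed loading
    (PCA loadings x discriminant coefficients), normalized per axis.
    """
    total = model.loci_loadings
    contrib = total**2
    s = contrib.sum(axis=0)
    s[s == 0] = 1.0
    return contrib / s


def ld_values(model: DAPCModel) -> np.ndarray:
    """Summed per-locus contributions over all retained discriminant axes."""
    return variable_contributions(model).sum(axis=1)


def _stratified_split(y_idx, n_groups, training_fraction, rng):
    train, test = [], []
    for k in range(n_groups):
        idx = np.where(y_idx == k)[0]
        rng.shuffle(idx)
        n_tr = int(round(training_fraction * len(idx)))
        n_tr = min(max(n_tr, 2), len(idx) - 1)  # both splits non-empty, train >= 2
        train.extend(idx[:n_tr])
        test.extend(idx[n_tr:])
    return np.array(sorted(train)), np.array(sorted(test))


def xval_select_npca(
    gm,
    labels: Sequence[str],
    grid: Sequence[int] | None = None,
    training_fraction: float = 0.9,
    reps: int = 30,
    seed: int = 0,
    scale: bool = False,
) -> XValReport:
    """Choose the retained-PC count by repeated stratified cross-validation.

    For each candidate ``n_pca``: ``reps`` stratified splits (default
    90/10), fit on the training part, score the held-out assignment
    success; the candidate with the highest mean success wins, ties going
    to the smallest ``n_pca``.  RMSE of (1 - posterior of the true class)
    is reported secondarily.
    """
    if not 0 < training_fraction < 1:
        raise ValueError("training_fraction must be in (0,1)")
    X, _, y = _design(gm, labels)
    n, p = X.shape
    classes, y_idx = np.unique(y, return_inverse=True)
    g = len(classes)
    if np.bincount(y_idx).min() < 3:
        raise ValueError("every group needs >= 3 samples for a stratified split")
    max_rank = min(n - 1, p)
    if grid is None:
        grid = list(range(10, min(max_rank, 300) + 1, 10)) or [max_rank]
    grid = sorted({int(c) for c in grid if 1 <= c})
    grid = [min(c, max_rank) for c in grid]
    grid = sorted(set(grid))
    if not grid:
        raise ValueError("empty candidate grid")

    rng = np.random.default_rng(seed)
    splits = [_stratified_split(y_idx, g, training_fraction, rng) for _ in range(reps)]

    mean_success, rmse = [], []
    for cand in grid:
        succ, sq = [], []
        for train, test in splits:
            model = fit_dapc(X[train], y[train], n_pca=cand, scale=scale)
            post, pred = predict_dapc(model, X[test])
            truth = y[test]
            succ.append(float(np.mean([a == b for a, b in zip(pred, truth)])))
            cls_index = {c: i for i, c in enumerate(model.classes)}
            p_true = np.array([post[i, cls_index[t]] for i, t in enumerate(truth)])
            sq.append(float(np.mean((1.0 - p_true) ** 2)))
        mean_success.append(float(np.mean(succ)))
        rmse.append(float(np.sqrt(np.mean(sq))))

    best = max(range(len(grid)), key=lambda i: (mean_success[i], -grid[i]))
    return XValReport(
        grid=list(grid),
        mean_success=mean_success,
        rmse=rmse,
        chosen_n_pca=grid[best],
        reps=reps,
        training_fraction=training_fraction,
        seed=seed,
    )
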