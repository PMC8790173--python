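"""Shuffled POST-PRE difference samples and regularized multiclass LDA.

The decoding question is whether the *change* in spectral power from before
(PRE) to after (POST) stimulation carries a protocol-specific signature.  The
sample unit is a shuffled trial pair: epochs are independently permuted along
the time axis within PRE and within POST, paired positionally, and the
per-pair power difference (channel x time-segment, at one frequency) becomes
one observation labelled with its stimulation protocol (lMC / rCB / sham).

Classification is a three-class shrinkage-regularized LDA: the within-class
scatter S_W is shrunk towards a scaled identity, (1-lambda) S_W + lambda nu I
with nu = trace(S_W)/d; the data are projected onto the top-2 generalized
eigenvectors of (S_W_shrunk, S_B) -- the 2-dimensional discriminative
subspace for 3 classes -- and classified there by the Gaussian linear
discriminant score with shared covariance and empirical priors.  Performance
is the cross-validated F1-score: tp/fp/fn are accumulated over stratified
folds and per-class precision = tp/(tp+fp), recall = tp/(tp+fn),
F1 = 2 pr. rc / (pr + rc), macro-averaged over the three classes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

from .exceptions import ConfigurationError, DegenerateDataError
from .spectral import BANDS, SpectralFeatures, band_average

logger = logging.getLogger(__name__)

PROTOCOLS = ("lMC", "rCB", "sham")


# ---------------------------------------------------------------------------
# Difference samples
# ---------------------------------------------------------------------------

@dataclass
class DiffFeatureSet:
    """Shuffled POST-PRE power differences with protocol labels.

    ``samples`` has shape (n_pairs, channels, frequencies, segments); the
    per-frequency slice is what one classifier sees.  ``labels`` holds the
    protocol string per sample.
    """

    samples: np.ndarray
    labels: np.ndarray
    freqs: np.ndarray
    channel_names: list[str]
    shuffle_seed: int | None = None

    @property
    def classes(self) -> list[str]:
        return sorted(set(self.labels.tolist()))

    def at(self, channel: int, freq_index: int) -> np.ndarray:
        """Feature matrix (n_samples, n_segments) for one channel/frequency."""
        return self.samples[:, channel, freq_index, :]


def build_diff_samples(pre: SpectralFeatures, post: SpectralFeatures,
                       seed=None) -> np.ndarray:
    """Positionally pair independently shuffled PRE and POST epochs.

    Only the epoch (time) order is shuffled; channels, frequencies and
    segments are untouched.  With unequal epoch counts the first
    ``min(n_pre, n_post)`` entries of each permutation are paired, so the
    used surplus-phase epochs form a random subset.  Deterministic given
    ``seed``.  Returns the array of POST-PRE differences,
    shape (n_pairs, channels, frequencies, segments).
    """
    n_pre, n_post = len(pre.power), len(post.power)
    if n_pre < 2 or n_post < 2:
        raise DegenerateDataError("need >= 2 epochs in each phase")
    rng = np.random.default_rng(seed)
    perm_pre = rng.permutation(n_pre)
    perm_post = rng.permutation(n_post)
    m = min(n_pre, n_post)
    return post.power[perm_post[:m]] - pre.power[perm_pre[:m]]


def pool_diff_features(per_protocol: dict[str, tuple[SpectralFeatures, SpectralFeatures]],
                       seed=None) -> DiffFeatureSet:
    """Build one labelled DiffFeatureSet from a subject's three sessions.

    ``per_protocol`` maps protocol label -> (PRE features, POST features).
    """
    rng = np.random.default_rng(seed)
    blocks, labels = [], []
    ref = None
    for proto in sorted(per_protocol):
        pre, post = per_protocol[proto]
        d = build_diff_samples(pre, post, rng)
        blocks.append(d)
        labels.extend([proto] * len(d))
        ref = pre
    return DiffFeatureSet(
        samples=np.concatenate(blocks, axis=0),
        labels=np.asarray(labels),
        freqs=np.asarray(ref.freqs),
        channel_names=list(ref.channel_names),
        shuffle_seed=seed if isinstance(seed, (int, np.integer)) else None,
    )


# ---------------------------------------------------------------------------
# Shrinkage LDA
# ---------------------------------------------------------------------------

@dataclass
class LDAModel:
    """Fitted shrinkage LDA with a 2-D discriminative subspace."""

    classes_: np.ndarray
    class_means: np.ndarray        # full feature space, per class
    pooled_cov: np.ndarray         # shrunk within-class scatter
    lam: float
    subspace: np.ndarray           # d x (n_classes - 1) projection
    means_z: np.ndarray            # class means in the subspace
    cov_z: np.ndarray              # shared covariance in the subspace
    priors: np.ndarray

    def transform(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X) @ self.subspace

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        z = self.transform(X)
        ci = linalg.inv(self.cov_z)
        a = self.means_z @ ci                      # k x 2
        b = -0.5 * np.einsum("ki,ki->k", a, self.means_z) + np.log(self.priors)
        return z @ a.T + b

    def predict(self, X: np.ndarray) -> np.ndarray:
        # argmax breaks ties towards the lowest class index (deterministic)
        return self.classes_[np.argmax(self.decision_scores(X), axis=1)]


def _ledoit_wolf_lambda(residuals: np.ndarray) -> float:
    from sklearn.covariance import ledoit_wolf

    _, lam = ledoit_wolf(residuals, assume_centered=True)
    return float(lam)


def fit_lda(X: np.ndarray, y: np.ndarray, lam: float | str = "auto",
            n_components: int | None = None) -> LDAModel:
    """Fit the shrinkage-regularized multiclass LDA.

    ``lam='auto'`` estimates the shrinkage weight analytically (Ledoit-Wolf,
    towards the scaled identity) from the within-class-centred training
    residuals only, so no information leaks across CV folds.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, y_idx = np.unique(y, return_inverse=True)
    k = len(classes)
    if k < 2:
        raise DegenerateDataError("need >= 2 classes to fit LDA")
    n, d = X.shape
    counts = np.bincount(y_idx, minlength=k)
    if counts.min() < 2:
        raise DegenerateDataError(
            f"class {classes[np.argmin(counts)]!r} has < 2 training samples"
        )
    means = np.stack([X[y_idx == c].mean(axis=0) for c in range(k)])
    resid = X - means[y_idx]
    s_w = resid.T @ resid
    if lam == "auto":
        lam = _ledoit_wolf_lambda(resid)
    lam = float(lam)
    if not 0.0 <= lam <= 1.0:
        raise ConfigurationError("shrinkage lambda must lie in [0, 1]")
    nu = np.trace(s_w) / d
    s_w_shrunk = (1.0 - lam) * s_w + lam * nu * np.eye(d)
    grand = X.mean(axis=0)
    dm = means - grand
    s_b = (counts[:, None] * dm).T @ dm
    try:
        evals, evecs = linalg.eigh(s_b, s_w_shrunk)
    except linalg.LinAlgError as err:
        raise linalg.LinAlgError(
            "singular within-class scatter; increase the shrinkage "
            "regularization lambda"
        ) from err
    n_comp = n_components or (k - 1)
    w = evecs[:, np.argsort(evals)[::-1][:n_comp]]
    z = X @ w
    mz = np.stack([z[y_idx == c].mean(axis=0) for c in range(k)])
    # the generalized eigenvectors are S_W-whitening (w^T S_shrunk w = I),
    # so the model's shared covariance in the subspace is the projected
    # shrunk scatter over its degrees of freedom: the identity / (n - k).
    # At lambda = 1 the decision therefore reduces to nearest-centroid
    # (plus priors) in the subspace.
    cov_z = np.eye(n_comp) / max(n - k, 1)
    return LDAModel(classes_=classes, class_means=means, pooled_cov=s_w_shrunk,
                    lam=lam, subspace=w, means_z=mz, cov_z=cov_z,
                    priors=counts / n)


# ---------------------------------------------------------------------------
# Cross-validated F1
# ---------------------------------------------------------------------------

def f1_from_counts(tp: np.ndarray, fp: np.ndarray, fn: np.ndarray):
    """Per-class precision, recall and F1 from accumulated counts."""
    tp, fp, fn = (np.asarray(a, dtype=float) for a in (tp, fp, fn))
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(tp + fp > 0, tp / (tp + fp), 0.0)
        recall = np.where(tp + fn > 0, tp / (tp + fn), 0.0)
        denom = precision + recall
        f1 = np.where(denom > 0, 2 * precision * recall / denom, 0.0)
    return precision, recall, f1


@dataclass
class F1Result:
    classes_: np.ndarray
    tp: np.ndarray
    fp: np.ndarray
    fn: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    macro_f1: float
    k: int


def stratified_folds(y: np.ndarray, k: int = 10, seed=0) -> np.ndarray:
    """Per-sample fold assignment, stratified by class and seeded.

    Folds are computed once per subject and reused across channels and
    frequencies so that scores are comparable.  If the smallest class has
    fewer than ``k`` members, ``k`` is reduced with a logged warning.
    """
    from sklearn.model_selection import StratifiedKFold

    y = np.asarray(y)
    min_count = np.bincount(np.unique(y, return_inverse=True)[1]).min()
    if min_count < 2:
        raise DegenerateDataError("each class needs >= 2 samples for CV")
    if min_count < k:
        warnings.warn(
            f"reducing folds from {k} to {min_count} (smallest class)",
            stacklevel=2,
        )
        logger.warning("reducing folds from %d to %d", k, min_count)
        k = int(min_count)
    skf = StratifiedKFold(n_splits=k, shuffle=True,
                          random_state=int(np.random.default_rng(seed).integers(2**31)))
    assignment = np.empty(len(y), dtype=int)
    for i, (_, test) in enumerate(skf.split(np.zeros(len(y)), y)):
        assignment[test] = i
    return assignment


def crossval_f1(X: np.ndarray, y: np.ndarray, k: int = 10, seed=0,
                lam: float | str = "auto",
                folds: np.ndarray | None = None) -> F1Result:
    """Stratified k-fold cross-validated per-class and macro F1."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if folds is None:
        folds = stratified_folds(y, k=k, seed=seed)
    classes = np.unique(y)
    kc = len(classes)
    tp = np.zeros(kc)
    fp = np.zeros(kc)
    fn = np.zeros(kc)
    for fold in np.unique(folds):
        test = folds == fold
        model = fit_lda(X[~test], y[~test], lam=lam)
        pred = model.predict(X[test])
        truth = y[test]
        for ci, c in enumerate(classes):
            tp[ci] += np.sum((pred == c) & (truth == c))
            fp[ci] += np.sum((pred == c) & (truth != c))
            fn[ci] += np.sum((pred != c) & (truth == c))
    precision, recall, f1 = f1_from_counts(tp, fp, fn)
    return F1Result(classes_=classes, tp=tp, fp=fp, fn=fn,
                    precision=precision, recall=recall, f1=f1,
                    macro_f1=float(f1.mean()), k=int(len(np.unique(folds))))


# ---------------------------------------------------------------------------
# Batched cross-validation (many channel/frequency problems at once)
# ---------------------------------------------------------------------------

def _lw_shrinkage_batch(resid: np.ndarray) -> np.ndarray:
    """Ledoit-Wolf shrinkage per problem for centred residuals (P, n, d).

    Same analytic formula as the single-problem estimator (shrinkage towards
    the scaled identity); equality with sklearn's ``ledoit_wolf`` is asserted
    in the test suite.
    """
    p, n, d = resid.shape
    x2 = resid ** 2
    emp_trace = x2.sum(axis=1) / n                     # (P, d)
    mu = emp_trace.sum(axis=1) / d
    beta_ = np.einsum("pnd,pne->p", x2, x2)
    gram = np.einsum("pnd,pne->pde", resid, resid)     # (P, d, d) = n * S
    delta_ = (gram ** 2).sum(axis=(1, 2)) / n ** 2
    beta_ = (beta_ / n - delta_) / (d * n)
    delta_ = (delta_ - 2.0 * mu * emp_trace.sum(axis=1) + d * mu ** 2) / d
    beta_ = np.minimum(beta_, delta_)
    with np.errstate(invalid="ignore", divide="ignore"):
        lam = np.where(delta_ > 0, beta_ / delta_, 0.0)
    return np.clip(np.where(beta_ <= 0, 0.0, lam), 0.0, 1.0)


def crossval_f1_batch(X: np.ndarray, y: np.ndarray, folds: np.ndarray,
                      lam: float | str = "auto"):
    """Cross-validated tp/fp/fn for P feature sets sharing labels and folds.

    ``X``: (P, n, d) -- e.g. one problem per channel x frequency.  The LDA
    math is identical to :func:`fit_lda`/:func:`crossval_f1` (equality is
    asserted in the tests); only the arithmetic is vectorized over P.
    Returns (classes, tp, fp, fn) with counts of shape (P, n_classes).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, y_idx = np.unique(y, return_inverse=True)
    k = len(classes)
    p, n, d = X.shape
    eye = np.eye(d)
    tp = np.zeros((p, k))
    fp = np.zeros((p, k))
    fn = np.zeros((p, k))
    for fold in np.unique(folds):
        test = folds == fold
        tr = ~test
        xtr = X[:, tr]
        ytr = y_idx[tr]
        ntr = int(tr.sum())
        counts = np.bincount(ytr, minlength=k).astype(float)
        mu = np.stack([xtr[:, ytr == c].mean(axis=1) for c in range(k)],
                      axis=1)                              # (P, k, d)
        resid = xtr - mu[:, ytr]
        sw = np.einsum("pnd,pne->pde", resid, resid)
        lam_p = (_lw_shrinkage_batch(resid) if lam == "auto"
                 else np.full(p, float(lam)))
        nu = np.trace(sw, axis1=1, axis2=2) / d
        sshr = ((1.0 - lam_p)[:, None, None] * sw
                + (lam_p * nu + 1e-10 * nu + 1e-300)[:, None, None] * eye)
        grand = xtr.mean(axis=1)
        dm = mu - grand[:, None, :]
        sb = np.einsum("k,pkd,pke->pde", counts, dm, dm)
        chol = np.linalg.cholesky(sshr)
        a = np.linalg.solve(chol, sb)
        m = np.linalg.solve(chol, a.transpose(0, 2, 1))
        m = 0.5 * (m + m.transpose(0, 2, 1))
        _, evecs = np.linalg.eigh(m)
        u = evecs[..., ::-1][..., :k - 1]                  # top k-1
        v = np.linalg.solve(chol.transpose(0, 2, 1), u)    # (P, d, c)
        z = np.einsum("pnd,pdc->pnc", X, v)
        ztr, zte = z[:, tr], z[:, test]
        mz = np.stack([ztr[:, ytr == c].mean(axis=1) for c in range(k)],
                      axis=1)                              # (P, k, c)
        # subspace is S_W-whitened: model covariance = I / (ntr - k)
        ak = mz * max(ntr - k, 1)
        bias = (-0.5 * np.einsum("pke,pke->pk", ak, mz)
                + np.log(counts / ntr))
        scores = np.einsum("pnc,pkc->pnk", zte, ak) + bias[:, None, :]
        pred = scores.argmax(axis=2)
        truth = y_idx[test]
        for c in range(k):
            pc = pred == c
            tc = truth == c
            tp[:, c] += (pc & tc).sum(axis=1)
            fp[:, c] += (pc & ~tc).sum(axis=1)
            fn[:, c] += (~pc & tc).sum(axis=1)
    return classes, tp, fp, fn


# ---------------------------------------------------------------------------
# Study-level decoding
# ---------------------------------------------------------------------------

@dataclass
class ScoreMap:
    """Cross-validated scores per subject x class x channel x frequency."""

    subjects: list[str]
    classes: list[str]
    channel_names: list[str]
    freqs: np.ndarray
    f1: np.ndarray          # subject x class x channel x freq
    precision: np.ndarray
    recall: np.ndarray
    macro_f1: np.ndarray    # subject x channel x freq
    cv_folds: int = 10
    extras: dict = field(default_factory=dict)

    def band_f1(self, band_name: str, per_class: bool = True) -> np.ndarray:
        """Band-averaged F1 (subject x class x channel or subject x channel)."""
        band = BANDS[band_name]
        src = self.f1 if per_class else self.macro_f1
        return band_average(src, self.freqs, band, axis=-1)


def classify_all(diff_sets: dict[str, DiffFeatureSet], *, freqs=None,
                 k: int = 10, seed=0, lam: float | str = "auto") -> ScoreMap:
    """Run the per-channel, per-frequency decoding for every subject.

    ``diff_sets`` maps subject id -> pooled :class:`DiffFeatureSet` (all three
    protocol sessions).  Classification runs separately at each frequency
    (the paper-default range is 4-49 Hz) and each channel, with the fold
    assignment fixed per subject.  Subjects whose set lacks one of the three
    classes are skipped with a warning.
    """
    subjects = sorted(diff_sets)
    sample = diff_sets[subjects[0]]
    all_freqs = np.asarray(sample.freqs)
    if freqs is None:
        fmask = (all_freqs >= 4) & (all_freqs <= 49)
    else:
        fmask = np.isin(all_freqs, np.asarray(freqs))
    fidx = np.flatnonzero(fmask)
    use_freqs = all_freqs[fidx]
    channels = sample.channel_names
    classes = list(PROTOCOLS)

    kept_subjects = []
    rows_f1, rows_prec, rows_rec, rows_macro = [], [], [], []
    folds_used = k
    rng = np.random.default_rng(seed)
    for subj in subjects:
        ds = diff_sets[subj]
        if set(ds.classes) != set(classes):
            warnings.warn(f"subject {subj!r} lacks a session; skipped",
                          stacklevel=2)
            continue
        folds = stratified_folds(ds.labels, k=k, seed=rng.integers(2**31))
        folds_used = len(np.unique(folds))
        n_ch = len(channels)
        # one problem per channel x frequency, batched
        xall = ds.samples[:, :, fidx, :]
        xall = xall.transpose(1, 2, 0, 3).reshape(
            n_ch * len(fidx), xall.shape[0], xall.shape[-1])
        found, tp, fp, fn = crossval_f1_batch(xall, ds.labels, folds, lam=lam)
        order = [list(found).index(c) for c in classes]
        p_, r_, f_ = f1_from_counts(tp[:, order], fp[:, order], fn[:, order])
        shape = (n_ch, len(fidx), len(classes))
        f1 = f_.reshape(shape).transpose(2, 0, 1)
        prec = p_.reshape(shape).transpose(2, 0, 1)
        rec = r_.reshape(shape).transpose(2, 0, 1)
        macro = f1.mean(axis=0)
        kept_subjects.append(subj)
        rows_f1.append(f1)
        rows_prec.append(prec)
        rows_rec.append(rec)
        rows_macro.append(macro)
    return ScoreMap(subjects=kept_subjects, classes=classes,
                    channel_names=list(channels), freqs=use_freqs,
                    f1=np.stack(rows_f1), precision=np.stack(rows_prec),
                    recall=np.stack(rows_rec), macro_f1=np.stack(rows_macro),
                    cv_folds=folds_used)
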