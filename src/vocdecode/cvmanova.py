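"""Cross-validated MANOVA pattern distinctness and cross-decoding.

The estimator quantifies how strongly a contrast of experimental conditions
modulates multichannel patterns. Per cross-validation fold, condition means
(GLM betas) and a noise precision matrix are estimated on the training split,
condition means and trial counts on the test split, and the pattern
distinctness is the noise-normalized dot product of the contrast-projected
betas:

    D = (1/n_test) * tr( B_train' P_train  X'X_test  P_test B_test  Sigma^-1 )

with P = C (C'C)^+ C' the projector onto the contrast subspace of the
condition axis. Cross-validation makes the expectation of D zero in the
absence of a true effect; negative values arise from sampling noise. Training
and test contrasts may address different time points (temporal
generalization), different variables (cross-variable decoding), condition
subsets (split-condition decoding) or different sessions, which is what makes
the estimator a general cross-decoding tool.

Sigma^-1 uses the unbiased inverse-Wishart correction
Sigma^-1 = (fE - p - 1) (Xi'Xi)^-1 on residuals of the window-mean training
data (window: first-cue offset to go-cue onset), with fE = n_train - rank(X).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .epochs import EpochArray
from .task_design import CUE1_OFFSET_MS, GO_ONSET_MS, condition_table

DEFAULT_NOISE_WINDOW_MS = (float(CUE1_OFFSET_MS), float(GO_ONSET_MS))


# ---------------------------------------------------------------------------
# domain types

@dataclass
class Contrast:
    """Zero-sum weighting over conditions defining a decoded variable."""

    condition_ids: np.ndarray  # (K,) conditions the contrast addresses
    matrix: np.ndarray  # (K, q)
    name: str = ""

    def __post_init__(self):
        self.condition_ids = np.asarray(self.condition_ids, dtype=int)
        self.matrix = np.atleast_2d(np.asarray(self.matrix, dtype=float))
        if self.matrix.shape[0] == 1 and self.condition_ids.size > 1:
            self.matrix = self.matrix.T
        if self.matrix.shape[0] != self.condition_ids.size:
            raise ValueError("contrast matrix rows must match condition_ids")
        if not np.allclose(self.matrix.sum(axis=0), 0.0, atol=1e-10):
            raise ValueError("contrast columns must sum to zero")

    def embed(self, cond_list: np.ndarray) -> np.ndarray:
        """Contrast matrix on a larger condition axis, zero elsewhere."""
        cond_list = np.asarray(cond_list)
        out = np.zeros((cond_list.size, self.matrix.shape[1]))
        for row, cid in zip(self.matrix, self.condition_ids):
            hit = np.flatnonzero(cond_list == cid)
            if hit.size != 1:
                raise ValueError(f"condition {cid} missing from data")
            out[hit[0]] = row
        return out


def variable_contrast(variable: str, order: str | None = None,
                      production: str | None = None, vowel: str | None = None) -> Contrast:
    """Contrast for decoding ``variable`` ('content' or 'production'),
    optionally restricted to a cue-order context and/or one level of the
    other variable (split-condition decoding)."""
    table = condition_table()
    if order is not None:
        table = table[table["order"] == order]
    if production is not None:
        table = table[table["production"] == production]
    if vowel is not None:
        table = table[table["vowel"] == vowel]
    if variable == "content":
        w = np.where(table["vowel"] == "u", 1.0, -1.0)
    elif variable == "production":
        w = np.where(table["production"] == "vocalized", 1.0, -1.0)
    else:
        raise ValueError("variable must be 'content' or 'production'")
    name = variable + ("" if order is None else f"|{order}")
    if production is not None:
        name += f"|prod={production}"
    if vowel is not None:
        name += f"|vowel={vowel}"
    return Contrast(condition_ids=table["condition_id"].to_numpy(),
                    matrix=w[:, None], name=name)


@dataclass
class NoisePrecision:
    """Unbiased inverse noise covariance with its degrees of freedom."""

    sigma_inv: np.ndarray
    fE: int
    p: int


@dataclass
class FoldScheme:
    """Condition-stratified k-fold assignment, repeated with fresh seeds."""

    n_folds: int = 5
    n_repetitions: int = 20
    seed: int = 0

    def assignments(self, y: np.ndarray):
        """Yield (repetition, fold_labels) with fold_labels in 0..n_folds-1."""
        y = np.asarray(y)
        for rep in range(self.n_repetitions):
            rng = np.random.default_rng([self.seed, rep])
            labels = np.empty(y.size, dtype=int)
            for cid in np.unique(y):
                idx = np.flatnonzero(y == cid)
                if idx.size < self.n_folds:
                    raise ValueError(
                        f"condition {cid} has {idx.size} trials; cannot stratify "
                        f"into {self.n_folds} folds")
                rng.shuffle(idx)
                labels[idx] = np.arange(idx.size) % self.n_folds
            yield rep, labels


@dataclass
class InformationResult:
    """Pattern distinctness over time (1-D) or train x test time (2-D)."""

    values: np.ndarray
    times_ms: np.ndarray  # test-time axis
    train_times_ms: np.ndarray | None = None  # set for cross-time results
    variable: str = ""
    n_test: float = 0.0
    meta: dict = field(default_factory=dict)

    def delay_average(self, start_ms: float, stop_ms: float) -> float:
        from .group_stats import average_delay  # local import avoids cycle
        return average_delay(self, [(start_ms, stop_ms)])[0]


# ---------------------------------------------------------------------------
# building blocks

def fit_condition_means(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Least-squares GLM betas for an indicator design (per-condition means)."""
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    counts = X.sum(axis=0)
    if np.any(counts == 0):
        empty = np.flatnonzero(counts == 0)
        raise ValueError(f"design has empty condition column(s) {empty.tolist()}")
    B, *_ = np.linalg.lstsq(X, Y, rcond=None)
    return B


def estimate_noise_precision(X_train: np.ndarray, Y_train_window_mean: np.ndarray) -> NoisePrecision:
    """Sigma^-1 = (fE - p - 1) (Xi'Xi)^-1 from window-mean training residuals."""
    X = np.asarray(X_train, dtype=float)
    Y = np.asarray(Y_train_window_mean, dtype=float)
    p = Y.shape[1]
    rank = np.linalg.matrix_rank(X)
    fE = X.shape[0] - rank
    if fE - p - 1 <= 0:
        raise ValueError(
            f"insufficient trials for channel count: fE={fE}, p={p} "
            f"(need fE - p - 1 > 0; reduce channels or add trials)")
    B = fit_condition_means(X, Y)
    xi = Y - X @ B
    sigma_inv = (fE - p - 1) * _checked_inverse(xi.T @ xi, p, fE)
    return NoisePrecision(sigma_inv=sigma_inv, fE=fE, p=p)


def _checked_inverse(gram: np.ndarray, p: int, fE: int) -> np.ndarray:
    """Invert a residual Gram, rejecting (near-)rank-deficient ones.

    Rank deficiency arises when derived channels outnumber the independent
    underlying sensors (e.g. wide searchlights on beamformed data); a plain
    inverse would then silently return garbage of huge magnitude.
    """
    w = np.linalg.eigvalsh(gram)
    if w[0] <= 1e-10 * max(w[-1], 1e-300):
        raise ValueError(
            f"insufficient trials for channel count: singular noise "
            f"covariance (p={p}, fE={fE})")
    return np.linalg.inv(gram)


def contrast_projector(C: np.ndarray) -> np.ndarray:
    """P = C (C'C)^+ C', projector onto the contrast subspace."""
    C = np.atleast_2d(np.asarray(C, dtype=float))
    if C.shape[0] == 1:
        C = C.T
    return C @ np.linalg.pinv(C.T @ C, rcond=1e-10) @ C.T


def pattern_distinctness(B_train: np.ndarray, B_test: np.ndarray, C_train: np.ndarray,
                         C_test: np.ndarray, XtX_test: np.ndarray, Sigma_inv: np.ndarray,
                         n_test: int) -> float:
    """One fold's pattern distinctness.

    With identical train and test contrasts this is the projector form

        D = (1/n) tr( B_train' P  X'X_test  P B_test  Sigma^-1 ),  P = C (C'C)^+ C'.

    With different contrasts (cross-variable, split-condition, cross-context
    decoding; single-column contrasts) the contrast-aligned form is used:

        v_i = (c_i'c_i)^-1 c_i' B_i          (pinv-normalized contrast estimate)
        w   = sqrt( (c1' X'X c1) (c2' X'X c2) )
        D   = (w / n) * v1 Sigma^-1 v2'

    which reduces exactly to the projector form when c1 = c2 and keeps the
    expected-cross-information benchmark consistent: if both contexts carry
    the same pattern, D12 equals the geometric mean of D1 and D2.
    """
    C1 = np.atleast_2d(np.asarray(C_train, dtype=float))
    C2 = np.atleast_2d(np.asarray(C_test, dtype=float))
    if C1.shape[0] == 1:
        C1 = C1.T
    if C2.shape[0] == 1:
        C2 = C2.T
    if np.array_equal(C1, C2):
        return _pattern_distinctness_projector(B_train, B_test, C1, XtX_test,
                                               Sigma_inv, n_test)
    if C1.shape[1] != 1 or C2.shape[1] != 1:
        raise ValueError("cross-contrast decoding implemented for single-column contrasts")
    c1 = C1[:, 0]
    c2 = C2[:, 0]
    v1 = c1 @ B_train / (c1 @ c1)
    v2 = c2 @ B_test / (c2 @ c2)
    w = np.sqrt((c1 @ XtX_test @ c1) * (c2 @ XtX_test @ c2))
    return float(w * (v1 @ Sigma_inv @ v2)) / n_test


def _pattern_distinctness_projector(B_train, B_test, C, XtX_test, Sigma_inv, n_test) -> float:
    P = contrast_projector(C)
    M = B_train.T @ P @ XtX_test @ P @ B_test @ Sigma_inv
    return float(np.trace(M)) / n_test


def expected_cross_information(D1: float, D2: float) -> float:
    """Benchmark cross-information for identical representations: the signed
    geometric mean of the two within-context informations."""
    D1 = np.asarray(D1, dtype=float)
    D2 = np.asarray(D2, dtype=float)
    out = np.sign(D1) * np.sign(D2) * np.sqrt(np.abs(D1 * D2))
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# core estimator

def _as_array_and_times(X, sfreq, tmin_ms):
    if isinstance(X, EpochArray):
        return X.data, X.times_ms
    X = np.asarray(X, dtype=float)
    if sfreq is None:
        raise ValueError("pass an EpochArray or provide sfreq/tmin_ms")
    times = (tmin_ms or 0.0) + np.arange(X.shape[2]) * 1000.0 / sfreq
    return X, times


class CVManova(BaseEstimator):
    """Cross-validated MANOVA estimator of pattern distinctness.

    Parameters
    ----------
    contrast : Contrast
        Training contrast (defines the decoded variable).
    contrast_test : Contrast or None
        Test contrast; defaults to the training contrast. A different test
        contrast yields cross-variable or split-condition decoding; disjoint
        condition support yields decoding across cue-order contexts.
    n_folds, n_reps : int
        Condition-stratified cross-validation scheme (folds partition trials;
        every condition appears in every fold).
    noise_window_ms : (float, float)
        Window whose per-trial mean feeds the noise-precision estimate.
    cross_time : bool
        If True, estimate the full train-time x test-time matrix.
    symmetric : bool
        Average the two decoding directions (train<->test contrasts swapped).
    decim : int
        Keep every ``decim``-th sample of the epoch for decoding.
    random_state : int
        Seeds the fold assignments.

    Attributes (after ``fit``)
    --------------------------
    information_ : InformationResult
    D_ : ndarray  — the values array of ``information_``
    conditions_ : ndarray of condition ids present in the data
    """

    def __init__(self, contrast=None, contrast_test=None, n_folds=5, n_reps=20,
                 noise_window_ms=DEFAULT_NOISE_WINDOW_MS, cross_time=False,
                 symmetric=False, decim=1, sfreq=None, tmin_ms=None, random_state=0):
        self.contrast = contrast
        self.contrast_test = contrast_test
        self.n_folds = n_folds
        self.n_reps = n_reps
        self.noise_window_ms = noise_window_ms
        self.cross_time = cross_time
        self.symmetric = symmetric
        self.decim = decim
        self.sfreq = sfreq
        self.tmin_ms = tmin_ms
        self.random_state = random_state

    # -- internals ---------------------------------------------------------

    def _prepare(self, X, y):
        data, times = _as_array_and_times(X, self.sfreq, self.tmin_ms)
        y = np.asarray(y)
        if data.shape[0] != y.size:
            raise ValueError("trial count of X and y differ")
        lo, hi = self.noise_window_ms
        nw = (times >= lo) & (times <= hi)
        if not nw.any():
            raise ValueError("noise window outside epoch")
        noise_mat = data[:, :, nw].mean(axis=-1)
        keep = slice(None, None, int(self.decim))
        return data[:, :, keep], times[keep], noise_mat, y

    @staticmethod
    def _embed(contrast, cond_list):
        return contrast.embed(cond_list)

    def _run(self, data, y, noise_mat, C_train, C_test, cond_list, folds):
        """Average D over the given (train_idx, test_idx) splits.

        The splits must partition the trials (test = complement of train), so
        training sufficient statistics are formed as whole-data totals minus
        the test split's contribution.
        """
        n, p, T = data.shape
        K = cond_list.size
        indicator = (y[:, None] == cond_list[None, :]).astype(float)
        same_contrast = np.array_equal(C_train, C_test)
        if same_contrast:
            P_train = P_test = contrast_projector(C_train)
        else:
            if C_train.shape[1] != 1 or C_test.shape[1] != 1:
                raise ValueError(
                    "cross-contrast decoding implemented for single-column contrasts")
            c1 = C_train[:, 0]
            c2 = C_test[:, 0]
        test_support = np.any(np.abs(C_test) > 0, axis=1)
        # whole-data sufficient statistics, shared by all folds
        tot_cnt = indicator.sum(axis=0)
        tot_sum = np.einsum("nk,npt->kpt", indicator, data, optimize=True)
        tot_nsum = indicator.T @ noise_mat  # (K, p) condition sums of window means
        tot_gram = noise_mat.T @ noise_mat
        acc = None
        n_test_acc = 0.0
        n_splits = 0
        for train_idx, test_idx in folds:
            I_te = indicator[test_idx]
            cnt_te = I_te.sum(axis=0)
            cnt_tr = tot_cnt - cnt_te
            if np.any(cnt_tr == 0) or np.any(cnt_te[test_support] == 0):
                raise ValueError("a condition is absent from a split")
            te_sum = np.einsum("nk,npt->kpt", I_te, data[test_idx], optimize=True)
            B_tr = (tot_sum - te_sum) / cnt_tr[:, None, None]
            B_te = te_sum / np.maximum(cnt_te, 1)[:, None, None]
            # noise precision from training window-mean residuals
            nm_te = noise_mat[test_idx]
            mu_tr = (tot_nsum - I_te.T @ nm_te) / cnt_tr[:, None]
            gram_tr = tot_gram - nm_te.T @ nm_te
            xi_gram = gram_tr - (mu_tr.T * cnt_tr) @ mu_tr
            fE = int(train_idx.size - K)
            if fE - p - 1 <= 0:
                raise ValueError(
                    f"insufficient trials for channel count: fE={fE}, p={p} "
                    f"(need fE - p - 1 > 0; reduce channels or add trials)")
            sigma_inv = (fE - p - 1) * _checked_inverse(xi_gram, p, fE)
            n_test = float(I_te[:, test_support].sum())
            if same_contrast:
                # D(t1,t2) = (1/n) sum_k cnt_te_k (P B_tr[t1])_k . (P B_te[t2] Sigma_inv)_k
                L = np.einsum("kl,lpt->kpt", P_train, B_tr, optimize=True)
                R = np.einsum("kl,lpt,pq->kqt", P_test, B_te, sigma_inv, optimize=True)
                wL = cnt_te[:, None, None] * L
                if self.cross_time:
                    D = np.einsum("kpa,kpb->ab", wL, R, optimize=True) / n_test
                else:
                    D = np.einsum("kpt,kpt->t", wL, R, optimize=True) / n_test
            else:
                # contrast-aligned cross form (see pattern_distinctness)
                v1 = np.einsum("k,kpt->pt", c1, B_tr) / (c1 @ c1)
                v2 = np.einsum("k,kpt,pq->qt", c2, B_te, sigma_inv, optimize=True) / (c2 @ c2)
                w = np.sqrt((cnt_te @ c1**2) * (cnt_te @ c2**2))
                if self.cross_time:
                    D = w * np.einsum("pa,pb->ab", v1, v2) / n_test
                else:
                    D = w * np.einsum("pt,pt->t", v1, v2) / n_test
            acc = D if acc is None else acc + D
            n_test_acc += n_test
            n_splits += 1
        return acc / n_splits, n_test_acc / n_splits

    def _fold_iter(self, y):
        scheme = FoldScheme(self.n_folds, self.n_reps, self.random_state)
        for _, labels in scheme.assignments(y):
            for f in range(self.n_folds):
                yield np.flatnonzero(labels != f), np.flatnonzero(labels == f)

    # -- API ---------------------------------------------------------------

    def fit(self, X, y):
        if self.contrast is None:
            raise ValueError("a training contrast is required")
        data, times, noise_mat, y = self._prepare(X, y)
        cond_list = np.unique(y)
        C_tr = self._embed(self.contrast, cond_list)
        ct = self.contrast_test if self.contrast_test is not None else self.contrast
        C_te = self._embed(ct, cond_list)
        folds = list(self._fold_iter(y))
        D, n_test = self._run(data, y, noise_mat, C_tr, C_te, cond_list, folds)
        if self.symmetric and self.contrast_test is not None:
            D2, _ = self._run(data, y, noise_mat, C_te, C_tr, cond_list, folds)
            D = 0.5 * (D + D2.T if self.cross_time else D + D2)
        self.conditions_ = cond_list
        self.D_ = D
        self.information_ = InformationResult(
            values=D, times_ms=times,
            train_times_ms=times if self.cross_time else None,
            variable=self.contrast.name, n_test=n_test,
            meta=dict(n_folds=self.n_folds, n_reps=self.n_reps,
                      seed=self.random_state, test_contrast=ct.name))
        return self

    def fit_sessions(self, X1, y1, X2, y2):
        """Twofold cross-session variant: train on one session, test on the
        other, alternately, and average. Per-(glyph, block) cue patterns do
        not survive this split in expectation because they are redrawn (and
        the block order reversed) in the second session."""
        if self.contrast is None:
            raise ValueError("a training contrast is required")
        d1, times, nm1, y1 = self._prepare(X1, y1)
        d2, times2, nm2, y2 = self._prepare(X2, y2)
        if d1.shape[1] != d2.shape[1] or d1.shape[2] != d2.shape[2]:
            raise ValueError("sessions must share channels and time axis")
        if not np.array_equal(np.unique(y1), np.unique(y2)):
            raise ValueError("sessions must share the condition set")
        data = np.concatenate([d1, d2], axis=0)
        noise_mat = np.concatenate([nm1, nm2], axis=0)
        y = np.concatenate([y1, y2])
        cond_list = np.unique(y)
        C_tr = self._embed(self.contrast, cond_list)
        ct = self.contrast_test if self.contrast_test is not None else self.contrast
        C_te = self._embed(ct, cond_list)
        s1 = np.arange(y1.size)
        s2 = y1.size + np.arange(y2.size)
        folds = [(s1, s2), (s2, s1)]
        D, n_test = self._run(data, y, noise_mat, C_tr, C_te, cond_list, folds)
        self.conditions_ = cond_list
        self.D_ = D
        self.information_ = InformationResult(
            values=D, times_ms=times,
            train_times_ms=times if self.cross_time else None,
            variable=self.contrast.name, n_test=n_test,
            meta=dict(scheme="cross-session", test_contrast=ct.name))
        return self


# ---------------------------------------------------------------------------
# thin functional wrappers

def cv_information(epochs, y, contrast, fold_scheme: FoldScheme | None = None,
                   noise_window_ms=DEFAULT_NOISE_WINDOW_MS, decim=1) -> InformationResult:
    """Within-session time-resolved pattern distinctness."""
    fs = fold_scheme or FoldScheme()
    est = CVManova(contrast=contrast, n_folds=fs.n_folds, n_reps=fs.n_repetitions,
                   noise_window_ms=noise_window_ms, decim=decim, random_state=fs.seed)
    return est.fit(epochs, y).information_


def cross_time_information(epochs, y, contrast, contrast_test=None,
                           fold_scheme: FoldScheme | None = None,
                           noise_window_ms=DEFAULT_NOISE_WINDOW_MS, decim=1) -> InformationResult:
    """Temporal-generalization matrix D(train time, test time)."""
    fs = fold_scheme or FoldScheme()
    est = CVManova(contrast=contrast, contrast_test=contrast_test, cross_time=True,
                   n_folds=fs.n_folds, n_reps=fs.n_repetitions,
                   noise_window_ms=noise_window_ms, decim=decim, random_state=fs.seed)
    return est.fit(epochs, y).information_


def cross_variable_information(epochs, y, contrast_train, contrast_test,
                               fold_scheme: FoldScheme | None = None, symmetric=True,
                               noise_window_ms=DEFAULT_NOISE_WINDOW_MS, decim=1) -> InformationResult:
    """Train on one variable's contrast, test on the other's."""
    fs = fold_scheme or FoldScheme()
    est = CVManova(contrast=contrast_train, contrast_test=contrast_test,
                   symmetric=symmetric, n_folds=fs.n_folds, n_reps=fs.n_repetitions,
                   noise_window_ms=noise_window_ms, decim=decim, random_state=fs.seed)
    return est.fit(epochs, y).information_


def split_condition_information(epochs, y, variable: str, split_variable: str,
                                split_level: str, order: str | None = None,
                                fold_scheme: FoldScheme | None = None,
                                noise_window_ms=DEFAULT_NOISE_WINDOW_MS, decim=1) -> InformationResult:
    """Train on all conditions of the context, test restricted to one level
    of the other variable (e.g. content information in vocalized trials)."""
    if split_variable not in ("production", "vowel"):
        raise ValueError("split_variable must be 'production' or 'vowel'")
    kw_test = {split_variable: split_level}
    c_train = variable_contrast(variable, order=order)
    c_test = variable_contrast(variable, order=order, **kw_test)
    if c_test.condition_ids.size == 0:
        raise ValueError("empty split")
    fs = fold_scheme or FoldScheme()
    est = CVManova(contrast=c_train, contrast_test=c_test,
                   n_folds=fs.n_folds, n_reps=fs.n_repetitions,
                   noise_window_ms=noise_window_ms, decim=decim, random_state=fs.seed)
    return est.fit(epochs, y).information_


def cross_session_information(epochs_s1, epochs_s2, y1, y2, contrast, contrast_test=None,
                              noise_window_ms=DEFAULT_NOISE_WINDOW_MS, decim=1,
                              cross_time=False) -> InformationResult:
    """Twofold decoding across the two sessions of a subject."""
    est = CVManova(contrast=contrast, contrast_test=contrast_test, cross_time=cross_time,
                   noise_window_ms=noise_window_ms, decim=decim)
    return est.fit_sessions(epochs_s1, y1, epochs_s2, y2).information_


def information_to_frame(results: dict, extra: dict | None = None) -> pd.DataFrame:
    """Tidy long-format table of named InformationResults."""
    rows = []
    base = extra or {}
    for name, res in results.items():
        if res.values.ndim == 1:
            for t, v in zip(res.times_ms, res.values):
                rows.append({**base, "analysis": name, "variable": res.variable,
                             "train_time_ms": t, "test_time_ms": t, "D": v})
        else:
            for i, t1 in enumerate(res.train_times_ms):
                for j, t2 in enumerate(res.times_ms):
                    rows.append({**base, "analysis": name, "variable": res.variable,
                                 "train_time_ms": t1, "test_time_ms": t2,
                                 "D": res.values[i, j]})
    return pd.DataFrame(rows)
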