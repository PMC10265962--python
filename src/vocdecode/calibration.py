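"""Null calibration of the decoding chain.

Two harnesses:

* :func:`null_information_means` runs the *actual* estimator
  (:class:`~vocdecode.cvmanova.CVManova` and variants) on small simulated
  sessions with zero planted effects and returns the per-simulation mean
  information — its grand mean must be statistically indistinguishable from
  zero for every decoding variant (cross-validation unbiasedness).

* :func:`type_one_error_rate` measures the full-chain false-positive rate:
  many simulated 24-subject null experiments, each decoded per subject,
  delay-averaged, t-tested and FDR-corrected exactly like the real analysis.
  To make hundreds of meta-simulations tractable it uses a batched
  reimplementation of the within-session estimator that is verified against
  ``CVManova`` (see :func:`batched_within_information`); epochs are drawn at
  analysis resolution from the same spatially mixed AR(1) noise model
  (filtering is linear and cannot affect the null).
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sstats

from .cvmanova import (
    FoldScheme, cross_session_information, cross_time_information,
    cross_variable_information, cv_information, variable_contrast,
)
from .group_stats import DelayWindows, fdr_bh
from .synth import (
    EffectSpec, NoiseSpec, make_leadfield, make_source_space, materialize_effect,
    simulate_session,
)
from .task_design import build_session_design

NULL_EFFECT = dict(a_content=0.0, a_prod=0.0, a_late=0.0, a_effort=0.0, a_cue=0.0)


def _tiny_session(seed: int, session: int = 1, n_channels: int = 6, n_sources: int = 12,
                  sfreq: float = 10.0, effect_kw: dict | None = None,
                  noise: NoiseSpec | None = None):
    """One fast, low-dimensional simulated session (defaults: null plant)."""
    space = make_source_space(n_sources, seed=0)
    lf = make_leadfield(space, n_channels, seed=0)
    eff = materialize_effect(EffectSpec(**(effect_kw or NULL_EFFECT)), space, seed=seed)
    noise = noise or NoiseSpec()
    design = build_session_design(f"N{seed}", session, seed)
    return simulate_session(design, eff, noise, lf, seed=seed, sfreq=sfreq)


def null_information_means(n_sims: int, seed: int = 0, variant: str = "within",
                           n_channels: int = 6, sfreq: float = 10.0) -> np.ndarray:
    """Mean D per null simulation for one decoding variant.

    ``variant`` is one of 'within', 'cross_time', 'cross_variable',
    'cross_session'. Each simulation draws a fresh zero-effect session
    (two for 'cross_session') and decodes it with the real estimator;
    the returned array holds each simulation's mean D over the epoch.
    """
    out = np.empty(n_sims)
    c_tr = variable_contrast("content", order="content_first")
    c_te = variable_contrast("production", order="content_first")
    fold = FoldScheme(5, 1, seed)
    for i in range(n_sims):
        s = seed * n_sims + i + 1
        ds = _tiny_session(s, n_channels=n_channels, sfreq=sfreq)
        y = ds.design_table["condition_id"].to_numpy()
        if variant == "within":
            res = cv_information(ds.epochs, y, c_tr, fold)
            out[i] = res.values.mean()
        elif variant == "cross_time":
            res = cross_time_information(ds.epochs, y, c_tr, fold_scheme=fold, decim=4)
            out[i] = res.values.mean()
        elif variant == "cross_variable":
            res = cross_variable_information(ds.epochs, y, c_tr, c_te, fold)
            out[i] = res.values.mean()
        elif variant == "cross_session":
            ds2 = _tiny_session(s + 10**6, session=2, n_channels=n_channels, sfreq=sfreq)
            y2 = ds2.design_table["condition_id"].to_numpy()
            res = cross_session_information(ds.epochs, ds2.epochs, y, y2, c_tr)
            out[i] = res.values.mean()
        else:
            raise ValueError(f"unknown variant {variant!r}")
    return out


def cue_confound_cross_session_means(n_sims: int, seed: int = 0, a_cue: float = 1.0,
                                     n_channels: int = 6, sfreq: float = 10.0) -> np.ndarray:
    """Cross-session information with ONLY the cue-glyph confound planted.

    Glyph-locked per-block pattern shifts inflate within-session information,
    but reverse-ordered sessions with fresh shifts cancel them: the returned
    means must be centred on zero.
    """
    out = np.empty(n_sims)
    eff_kw = dict(NULL_EFFECT, a_cue=a_cue)
    c = variable_contrast("content", order="content_first")
    for i in range(n_sims):
        s = seed * n_sims + i + 1
        ds1 = _tiny_session(s, session=1, n_channels=n_channels, sfreq=sfreq, effect_kw=eff_kw)
        ds2 = _tiny_session(s + 10**6, session=2, n_channels=n_channels, sfreq=sfreq, effect_kw=eff_kw)
        res = cross_session_information(
            ds1.epochs, ds2.epochs,
            ds1.design_table["condition_id"].to_numpy(),
            ds2.design_table["condition_id"].to_numpy(), c)
        out[i] = res.values.mean()
    return out


# ---------------------------------------------------------------------------
# batched type-I-error meta-simulation

def simulate_null_batch(n_datasets: int, trials_per_condition: int, n_channels: int,
                        times_ms: np.ndarray, rng: np.random.Generator,
                        ar_coef: float = 0.9, cond_cap: float = 10.0):
    """(data, y): spatially mixed AR(1) noise epochs for many null datasets."""
    K = 16
    n = K * trials_per_condition
    T = times_ms.size
    y = np.repeat(np.arange(1, K + 1), trials_per_condition)
    white = rng.standard_normal((n_datasets, n, n_channels, T))
    data = np.empty_like(white)
    data[..., 0] = white[..., 0]
    s = np.sqrt(1 - ar_coef**2)
    for t in range(1, T):
        data[..., t] = ar_coef * data[..., t - 1] + s * white[..., t]
    mix = rng.standard_normal((n_datasets, n_channels, n_channels))
    u, sv, vt = np.linalg.svd(mix)
    sv = np.clip(sv, sv.max(axis=1, keepdims=True) / cond_cap, None)
    mix = np.einsum("mij,mj,mjk->mik", u, sv, vt)
    mix /= np.sqrt(np.mean(np.sum(mix**2, axis=2), axis=1))[:, None, None]
    data = np.einsum("mij,mnjt->mnit", mix, data, optimize=True)
    return data, y


def stratified_fold_labels(y: np.ndarray, n_datasets: int, n_folds: int,
                           rng: np.random.Generator) -> np.ndarray:
    """(n_datasets, n_trials) fold labels, stratified by condition."""
    labels = np.empty((n_datasets, y.size), dtype=np.int8)
    base = np.arange(y.size)
    for cid in np.unique(y):
        idx = np.flatnonzero(y == cid)
        order = np.argsort(rng.random((n_datasets, idx.size)), axis=1)
        labels[:, idx] = (order % n_folds).astype(np.int8)
    return labels


def batched_within_information(data: np.ndarray, y: np.ndarray, fold_labels: np.ndarray,
                               contrasts: list, noise_mask: np.ndarray,
                               n_folds: int = 5) -> np.ndarray:
    """Within-session D(t) for many datasets at once.

    Vectorized equivalent of ``CVManova`` with single-column contrasts (the
    projector and contrast-aligned forms coincide there); returns
    (n_datasets, n_contrasts, T). Verified against ``CVManova`` in the test
    suite.
    """
    M, n, p, T = data.shape
    cond_list = np.unique(y)
    K = cond_list.size
    ind = (y[:, None] == cond_list[None, :]).astype(float)
    noise_mat = data[..., noise_mask].mean(axis=-1)  # (M, n, p)
    tot_sum = np.einsum("nk,mnpt->mkpt", ind, data, optimize=True)
    tot_cnt = ind.sum(axis=0)
    tot_nsum = np.einsum("nk,mnp->mkp", ind, noise_mat, optimize=True)
    tot_gram = np.einsum("mnp,mnq->mpq", noise_mat, noise_mat, optimize=True)
    cs = [np.asarray(c.embed(cond_list))[:, 0] for c in contrasts]
    D = np.zeros((M, len(cs), T))
    for f in range(n_folds):
        te = (fold_labels == f)  # (M, n)
        W = te.astype(float)
        WI = W[:, :, None] * ind[None, :, :]  # (M, n, K)
        cnt_te = WI.sum(axis=1)  # (M, K)
        cnt_tr = tot_cnt[None] - cnt_te
        te_sum = np.einsum("mnk,mnpt->mkpt", WI, data, optimize=True)
        B_tr = (tot_sum - te_sum) / cnt_tr[:, :, None, None]
        B_te = te_sum / np.maximum(cnt_te, 1)[:, :, None, None]
        nm_te_sum = np.einsum("mnk,mnp->mkp", WI, noise_mat, optimize=True)
        mu_tr = (tot_nsum - nm_te_sum) / cnt_tr[:, :, None]
        gram_te = np.einsum("mn,mnp,mnq->mpq", W, noise_mat, noise_mat, optimize=True)
        xi = (tot_gram - gram_te) - np.einsum("mkp,mk,mkq->mpq", mu_tr, cnt_tr, mu_tr,
                                              optimize=True)
        n_tr = (~te).sum(axis=1)  # (M,)
        fE = n_tr - K
        if np.any(fE - p - 1 <= 0):
            raise ValueError("insufficient trials for channel count")
        sigma_inv = (fE - p - 1)[:, None, None] * np.linalg.inv(xi)
        for j, c in enumerate(cs):
            support = np.abs(c) > 0
            n_test = cnt_te[:, support].sum(axis=1)  # (M,)
            v1 = np.einsum("k,mkpt->mpt", c, B_tr) / (c @ c)
            v2 = np.einsum("k,mkpt,mpq->mqt", c, B_te, sigma_inv, optimize=True) / (c @ c)
            w = cnt_te @ (c**2)
            D[:, j, :] += (w / n_test)[:, None] * np.einsum("mpt,mpt->mt", v1, v2)
    return D / n_folds


def type_one_error_rate(n_meta: int = 500, n_subjects: int = 24, seed: int = 0,
                        n_channels: int = 4, trials_per_condition: int = 5,
                        n_folds: int = 5, alpha: float = 0.05,
                        return_details: bool = False):
    """Fraction of null experiments with any FDR-significant delay-window test.

    Each meta-simulation: ``n_subjects`` zero-effect sessions are decoded for
    both variables in both cue-order contexts, delay-averaged in the standard
    windows, tested one-tailed against zero across subjects, and
    BH-corrected within the six-test family. A calibrated chain keeps the
    any-rejection rate near ``alpha``.
    """
    rng = np.random.default_rng(seed)
    times_ms = np.linspace(-500.0, 4450.0, 12)
    noise_mask = (times_ms >= 100.0) & (times_ms <= 4200.0)
    windows = DelayWindows()
    d1 = (times_ms >= windows.delay1[0]) & (times_ms <= windows.delay1[1])
    d2 = (times_ms >= windows.delay2[0]) & (times_ms <= windows.delay2[1])
    contrasts = [variable_contrast(v, order=o)
                 for v in ("content", "production")
                 for o in ("content_first", "production_first")]
    M = n_meta * n_subjects
    chunk = max(1, int(2e8 // (16 * trials_per_condition * n_channels * times_ms.size * 8)))
    D_parts = []
    done = 0
    while done < M:
        m = min(chunk, M - done)
        data, y = simulate_null_batch(m, trials_per_condition, n_channels, times_ms, rng)
        labels = stratified_fold_labels(y, m, n_folds, rng)
        D_parts.append(batched_within_information(data, y, labels, contrasts,
                                                  noise_mask, n_folds))
        done += m
    D = np.concatenate(D_parts).reshape(n_meta, n_subjects, len(contrasts), -1)
    # six-test family: first-instructed variable delay 1 + both delays 2
    vals = np.stack([
        D[:, :, 0, d1].mean(-1),  # content | content_first | delay1
        D[:, :, 0, d2].mean(-1),
        D[:, :, 1, d2].mean(-1),  # content | production_first | delay2
        D[:, :, 3, d1].mean(-1),  # production | production_first | delay1
        D[:, :, 2, d2].mean(-1),  # production | content_first | delay2
        D[:, :, 3, d2].mean(-1),
    ], axis=-1)  # (n_meta, n_subjects, 6)
    mean = vals.mean(axis=1)
    sd = vals.std(axis=1, ddof=1)
    t = mean / (sd / np.sqrt(n_subjects))
    p = sstats.t.sf(t, df=n_subjects - 1)
    any_sig = np.array([np.any(fdr_bh(pi) < alpha) for pi in p])
    rate = float(any_sig.mean())
    if return_details:
        return rate, dict(p=p, values=vals, any_sig=any_sig)
    return rate
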